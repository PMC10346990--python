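"""Synthetic VP-ITC data with known ground truth.

Every input the analysis pipeline consumes can be generated here:
integrated-heat series (SSIS forward model plus Gaussian noise), matched
dilution-control series (geometrically decaying heats), and raw
power-vs-time thermograms (exponentially modified Gaussian injection pulses
on a drifting baseline).  All generators are pure functions of their inputs
and a seed, so identical specifications yield identical data.

A registry of reference experiment designs emulates published
dPGS-divalent-ion titrations: 35 injections of 8 uL into a 1.43 mL cell at
303.15 K, with the five buffer compositions (ionic strength 16.5 or
21.5 mM) and the SSIS parameters estimated for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .binding import BindingParameters
from .preprocessing import CAL_TO_J, InjectionHeats, Thermogram
from .titration import InjectionSchedule, predicted_heats

__all__ = [
    "NoiseSpec",
    "ReferenceDesign",
    "REFERENCE_DESIGNS",
    "get_design",
    "simulate_heats",
    "simulate_dilution",
    "simulate_thermogram",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for the generators.

    ``heat_sigma`` is the s.d. of additive Gaussian noise on integrated
    heats, either in J (``heat_sigma_mode="absolute"``) or as a fraction of
    the series' largest |heat| (``"fraction_of_max"``).  ``baseline_drift``
    is a linear thermogram baseline slope in ucal/s per 1000 s;
    ``power_sigma`` is white power noise in ucal/s.
    """

    heat_sigma: float = 0.0
    heat_sigma_mode: str = "absolute"
    baseline_drift: float = 0.0
    power_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heat_sigma < 0 or self.power_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.heat_sigma_mode not in ("absolute", "fraction_of_max"):
            raise ValueError(f"unknown heat_sigma_mode {self.heat_sigma_mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ReferenceDesign:
    """A reference titration design paired with its SSIS ground truth."""

    name: str
    cation: str
    syringe_conc_mM: float
    macroion_conc_mM: float
    divalent_total_mM: float
    nacl_mM: float
    buffer_nominal_mM: float
    ionic_strength_mM: float
    params: BindingParameters
    delta_G_kJ_mol: float

    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule.uniform(
            n_injections=35,
            injection_volume=8e-6,
            cell_volume=1.43e-3,
            syringe_conc=self.syringe_conc_mM * 1e-3,
            cell_macroion_conc=self.macroion_conc_mM * 1e-3,
            spacing=300.0,
            temperature=303.15,
        )


REFERENCE_DESIGNS: dict[str, ReferenceDesign] = {
    d.name: d
    for d in (
        ReferenceDesign(
            "ca-16.5", "Ca2+", 5.1, 0.032, 0.8, 4.1, 10.0, 16.5,
            BindingParameters(7.9, 6.3e3, 6.8), -22.0,
        ),
        ReferenceDesign(
            "mg-16.5", "Mg2+", 5.0, 0.032, 0.8, 4.1, 10.0, 16.5,
            BindingParameters(7.5, 5.1e3, 8.1), -21.5,
        ),
        ReferenceDesign(
            "mg-21.5-0.8", "Mg2+", 5.0, 0.020, 0.8, 9.1, 10.0, 21.5,
            BindingParameters(4.5, 6.5e3, 10.1), -22.1,
        ),
        ReferenceDesign(
            "mg-21.5-1.7", "Mg2+", 10.0, 0.039, 1.7, 6.4, 10.0, 21.5,
            BindingParameters(4.9, 4.1e3, 10.0), -21.0,
        ),
        ReferenceDesign(
            "mg-21.5-2.5", "Mg2+", 15.2, 0.064, 2.5, 4.0, 10.0, 21.5,
            BindingParameters(6.4, 4.1e3, 8.5), -21.0,
        ),
    )
}


def get_design(name: str) -> ReferenceDesign:
    """Look up a reference design by name (e.g. ``"mg-16.5"``)."""
    try:
        return REFERENCE_DESIGNS[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; available: {sorted(REFERENCE_DESIGNS)}"
        ) from None


def simulate_heats(
    params: BindingParameters,
    schedule: InjectionSchedule,
    noise: NoiseSpec = NoiseSpec(),
    macroion_conc: float | None = None,
) -> InjectionHeats:
    """SSIS forward model heats plus iid Gaussian noise.

    The noiseless truth is retained on the result (``.truth``) and the
    applied absolute sigma recorded per injection.
    """
    truth = predicted_heats(params, schedule, macroion_conc=macroion_conc)
    if noise.heat_sigma_mode == "fraction_of_max":
        sigma = noise.heat_sigma * float(np.max(np.abs(truth)))
    else:
        sigma = noise.heat_sigma
    heats = truth + noise.rng().normal(0.0, sigma, size=truth.size) if sigma > 0 else truth.copy()
    return InjectionHeats(
        heat=heats,
        sigma=np.full(truth.size, sigma) if sigma > 0 else None,
        provenance="simulated",
        truth=truth,
    )


def simulate_dilution(
    schedule: InjectionSchedule,
    magnitude: float,
    decay: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
) -> InjectionHeats:
    """Dilution-control series: ``magnitude * decay**(i-1)`` J plus noise.

    Injecting titrant into buffer alone gives small heats that shrink as the
    cell's titrant concentration approaches the syringe's; a geometric decay
    captures that shape.
    """
    if not math.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    if not (0.0 < decay <= 1.0):
        raise ValueError(f"decay must be in (0, 1], got {decay}")
    truth = magnitude * decay ** np.arange(schedule.n_injections)
    if noise.heat_sigma_mode == "fraction_of_max":
        sigma = noise.heat_sigma * float(np.max(np.abs(truth))) if magnitude != 0 else 0.0
    else:
        sigma = noise.heat_sigma
    heats = truth + noise.rng().normal(0.0, sigma, size=truth.size) if sigma > 0 else truth
    return InjectionHeats(heat=heats, provenance="simulated", truth=truth.copy())


def _emg_shape(t: np.ndarray, t0: float, sigma: float, tau: float) -> np.ndarray:
    """Exponentially modified Gaussian pulse (unnormalized), peak onset t0."""
    z = (sigma / tau - (t - t0) / sigma) / math.sqrt(2.0)
    return np.exp((sigma**2 / (2 * tau**2)) - (t - t0) / tau) * erfc(z)


def simulate_thermogram(
    heats: InjectionHeats,
    schedule: InjectionSchedule,
    peak_width: float = 20.0,
    noise: NoiseSpec = NoiseSpec(),
    sampling_interval: float = 1.0,
) -> Thermogram:
    """Render integrated heats as a raw power trace (ucal/s, 1 Hz default).

    Each injection contributes an exponentially modified Gaussian pulse
    (Gaussian rise sigma = width/4, exponential decay tau = width) starting
    at its injection time.  The pulse is truncated where its monotone tail
    reaches 90% of the injection window and scaled so its discretely
    integrated (trapezoid) area equals the injection heat, which makes peak
    integration exact on noiseless, drift-free traces.  A linear baseline
    drift and white power noise are added on top.
    """
    if len(heats) != schedule.n_injections:
        raise ValueError(
            f"{len(heats)} heats for a schedule of {schedule.n_injections} injections"
        )
    if not peak_width < schedule.spacing / 3.0:
        raise ValueError(
            f"peak_width {peak_width} s too large for spacing {schedule.spacing} s "
            "(must be < spacing/3 to keep peaks separated)"
        )
    t_total = schedule.initial_delay + schedule.spacing * schedule.n_injections
    t = np.arange(0.0, t_total + sampling_interval / 2, sampling_interval)
    power = noise.baseline_drift * t / 1000.0

    sigma_g, tau = peak_width / 4.0, peak_width
    cutoff = 0.9 * schedule.spacing
    for ti, heat in zip(schedule.injection_times(), heats.heat):
        mask = (t >= ti) & (t <= ti + cutoff)
        tw = t[mask]
        shape = _emg_shape(tw, ti, sigma_g, tau)
        shape = np.clip(shape - _emg_shape(np.array([ti + cutoff]), ti, sigma_g, tau), 0.0, None)
        area = np.trapezoid(shape, tw)  # s
        if area <= 0:
            raise ValueError("degenerate pulse; increase sampling rate or width")
        amplitude = (heat / (1e-6 * CAL_TO_J)) / area  # ucal/s per unit shape
        power[mask] += amplitude * shape
    if noise.power_sigma > 0:
        power = power + noise.rng().normal(0.0, noise.power_sigma, size=t.size)
    return Thermogram(time=t, power=power)
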