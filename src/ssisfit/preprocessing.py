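"""Raw-thermogram reduction: peak integration and dilution correction.

A raw ITC thermogram is differential power vs time; each injection produces
a transient excursion that relaxes back to baseline before the next one.
Integration proceeds per injection window: a local baseline is interpolated
linearly between the quiescent tails (median of the final 10%) of the
preceding and current windows, subtracted, and the residual power integrated
by the trapezoid rule.  Upward (positive) power excursions integrate to
positive = endothermic heats.

The dilution control — titrant injected into buffer alone — is subtracted
injection-by-injection from the binding series before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .titration import InjectionSchedule

__all__ = ["CAL_TO_J", "Thermogram", "InjectionHeats", "integrate_peaks", "subtract_dilution"]

#: Thermochemical calorie, J.
CAL_TO_J = 4.184

#: Fraction of each injection window treated as quiescent baseline tail.
_TAIL_FRACTION = 0.10


@dataclass(frozen=True)
class Thermogram:
    """Differential-power trace: time in s, power in ucal/s."""

    time: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)
        if t.ndim != 1 or p.shape != t.shape:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("thermogram needs at least 2 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(p)):
            raise ValueError("thermogram contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class InjectionHeats:
    """Per-injection integrated heats in J (positive = endothermic).

    ``sigma`` carries optional per-injection uncertainties (J); ``provenance``
    is one of ``"raw"``, ``"dilution-corrected"``, ``"simulated"``.
    """

    heat: np.ndarray
    sigma: np.ndarray | None = None
    provenance: str = "raw"
    truth: np.ndarray | None = None  # noiseless generating heats, when simulated

    def __post_init__(self) -> None:
        h = np.asarray(self.heat, dtype=float)
        object.__setattr__(self, "heat", h)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("heat must be a non-empty 1-D array")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != h.shape:
                raise ValueError("sigma must match heat in length")
            if np.any(s < 0):
                raise ValueError("sigma must be >= 0")
            object.__setattr__(self, "sigma", s)
        if self.truth is not None:
            tr = np.asarray(self.truth, dtype=float)
            if tr.shape != h.shape:
                raise ValueError("truth must match heat in length")
            object.__setattr__(self, "truth", tr)

    @property
    def injection_index(self) -> np.ndarray:
        """1-based injection indices."""
        return np.arange(1, self.heat.size + 1)

    def __len__(self) -> int:
        return self.heat.size


def _window_tail(t: np.ndarray, p: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """(time midpoint, median power) of the final tail fraction of [lo, hi)."""
    tail_lo = hi - _TAIL_FRACTION * (hi - lo)
    mask = (t >= tail_lo) & (t < hi)
    if not np.any(mask):
        raise ValueError(f"no samples in baseline segment [{tail_lo:.1f}, {hi:.1f}) s")
    return 0.5 * (tail_lo + hi), float(np.median(p[mask]))


def integrate_peaks(thermogram: Thermogram, schedule: InjectionSchedule) -> InjectionHeats:
    """Integrate a thermogram into per-injection heats (J).

    Each injection owns the window ``[t_i, t_i + spacing)``.  The baseline
    under the window is the line through the quiescent-tail nodes (midpoint,
    median of the last 10% of the window) of the preceding and the current
    window; for the first injection the lead-in segment before it serves as
    the preceding window, or, if absent, the baseline is held flat at the
    first window's own tail level.
    """
    t, p = thermogram.time, thermogram.power
    times = schedule.injection_times()
    spacing = schedule.spacing
    t_end = times[-1] + spacing
    if t[-1] < t_end - spacing * _TAIL_FRACTION:
        missing = [i + 1 for i, ti in enumerate(times) if t[-1] < ti + spacing * (1 - _TAIL_FRACTION)]
        raise ValueError(
            f"thermogram ends at {t[-1]:.0f} s but schedule needs {t_end:.0f} s; "
            f"missing injections {missing}"
        )

    heats = np.empty(schedule.n_injections)
    prev_node: tuple[float, float] | None = None
    if times[0] > t[0]:
        prev_node = _window_tail(t, p, t[0], times[0])
    for i, ti in enumerate(times):
        hi = min(ti + spacing, t[-1] + (t[-1] - t[-2]))
        cur_node = _window_tail(t, p, ti, ti + spacing)
        mask = (t >= ti) & (t < hi)
        tw, pw = t[mask], p[mask]
        if prev_node is None:
            base = np.full_like(pw, cur_node[1])
        else:
            (t0, p0), (t1, p1) = prev_node, cur_node
            base = p0 + (tw - t0) * (p1 - p0) / (t1 - t0)
        heats[i] = np.trapezoid(pw - base, tw)
        prev_node = cur_node
    # ucal -> J
    return InjectionHeats(heat=heats * 1e-6 * CAL_TO_J, provenance="raw")


def subtract_dilution(binding: InjectionHeats, dilution: InjectionHeats) -> InjectionHeats:
    """Subtract the dilution-control heats from the binding heats.

    Sigmas, when present on both series, combine in quadrature.  Injection
    counts must match exactly; no silent truncation.
    """
    if len(binding) != len(dilution):
        raise ValueError(
            f"injection count mismatch: binding has {len(binding)}, "
            f"dilution has {len(dilution)}"
        )
    sigma = None
    if binding.sigma is not None and dilution.sigma is not None:
        sigma = np.hypot(binding.sigma, dilution.sigma)
    elif binding.sigma is not None:
        sigma = binding.sigma.copy()
    elif dilution.sigma is not None:
        sigma = dilution.sigma.copy()
    return InjectionHeats(
        heat=binding.heat - dilution.heat, sigma=sigma, provenance="dilution-corrected"
    )
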