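"""Injection-sequence bookkeeping and per-injection heat prediction.

A titration consists of successive small injections of titrant into a
fixed-volume (perfusion) calorimeter cell.  Each injection of volume ``dV``
displaces an equal volume of cell liquid, so both the macroion and the
accumulated titrant are diluted.  We adopt the standard instrument-vendor
convention in which the displaced liquid carries the *average* of the pre-
and post-injection composition; with cumulative injected volume ``DV``:

    [M]_i = [M]_0 * (1 - DV/(2 V0)) / (1 + DV/(2 V0))
    [A]_tot,i = c_syr * (DV/V0) / (1 + DV/(2 V0))

The measurable heat of injection ``i`` is the difference of cumulative
equilibrium heats corrected for the heat carried out with the displaced
volume, again at the average composition:

    dQ'_i = Q'_i + (dV_i/V0) * (Q'_i + Q'_{i-1})/2 - Q'_{i-1}

with Q'_0 = 0.  The same mid-point approximation is thus applied on the
concentration and the heat side, keeping the bookkeeping internally
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingParameters, CellComposition, cumulative_heat

__all__ = ["InjectionSchedule", "cell_trajectory", "predicted_heats", "normalize_heats"]


@dataclass(frozen=True)
class InjectionSchedule:
    """Instrument geometry and injection sequence.

    Parameters
    ----------
    cell_volume : float
        Active cell volume ``V0`` in litres.
    syringe_conc : float
        Titrant concentration in the syringe, mol/L.
    cell_macroion_conc : float
        Initial macroion concentration in the cell, mol/L.
    injection_volumes : tuple of float
        Ordered per-injection volumes ``dV_i`` in litres.
    spacing : float
        Time between injections, seconds.
    temperature : float
        Experiment temperature, K.
    cell_titrant_conc : float
        Titrant already in the cell before the first injection (normally 0).
    initial_delay : float
        Quiescent lead-in before the first injection, seconds; gives peak
        integration a pre-injection baseline segment.
    """

    cell_volume: float
    syringe_conc: float
    cell_macroion_conc: float
    injection_volumes: tuple[float, ...]
    spacing: float = 300.0
    temperature: float = 303.15
    cell_titrant_conc: float = 0.0
    initial_delay: float = 60.0

    def __post_init__(self) -> None:
        if not self.cell_volume > 0:
            raise ValueError(f"cell_volume must be > 0, got {self.cell_volume}")
        if not self.syringe_conc > 0:
            raise ValueError(f"syringe_conc must be > 0, got {self.syringe_conc}")
        if self.cell_macroion_conc < 0:
            raise ValueError("cell_macroion_conc must be >= 0")
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if len(vols) == 0:
            raise ValueError("injection_volumes must be non-empty")
        if any(v <= 0 for v in vols):
            raise ValueError("all injection volumes must be > 0")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if self.initial_delay < 0:
            raise ValueError("initial_delay must be >= 0")

    @classmethod
    def uniform(
        cls,
        n_injections: int = 35,
        injection_volume: float = 8e-6,
        cell_volume: float = 1.43e-3,
        syringe_conc: float = 5.0e-3,
        cell_macroion_conc: float = 0.032e-3,
        **kwargs,
    ) -> "InjectionSchedule":
        """Schedule of ``n`` equal injections (defaults: 35 x 8 uL into 1.43 mL)."""
        return cls(
            cell_volume=cell_volume,
            syringe_conc=syringe_conc,
            cell_macroion_conc=cell_macroion_conc,
            injection_volumes=(injection_volume,) * n_injections,
            **kwargs,
        )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def total_injected_volume(self) -> float:
        """Total titrant volume delivered, litres."""
        return float(sum(self.injection_volumes))

    def injection_times(self) -> np.ndarray:
        """Injection start times in seconds (1st at ``initial_delay``)."""
        return self.initial_delay + self.spacing * np.arange(self.n_injections)


def cell_trajectory(schedule: InjectionSchedule) -> pd.DataFrame:
    """Evolve the cell composition across injections.

    Returns a DataFrame indexed by 1-based ``injection`` with columns
    ``cumulative_volume_L``, ``macroion_total_M``, ``ligand_total_M`` and
    ``molar_ratio`` (= ligand_total / macroion_total, the isotherm x-axis).

    Raises on overfill (cumulative injected volume exceeding the cell volume).
    """
    dv = np.asarray(schedule.injection_volumes)
    dv_cum = np.cumsum(dv)
    v0 = schedule.cell_volume
    if dv_cum[-1] > v0:
        raise ValueError(
            f"cumulative injected volume {dv_cum[-1]:.3e} L exceeds cell volume {v0:.3e} L"
        )
    r = dv_cum / (2.0 * v0)
    macro = schedule.cell_macroion_conc * (1.0 - r) / (1.0 + r)
    ligand = schedule.syringe_conc * (dv_cum / v0) / (1.0 + r)
    if schedule.cell_titrant_conc:
        ligand = ligand + schedule.cell_titrant_conc * (1.0 - r) / (1.0 + r)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(macro > 0, ligand / macro, np.inf)
    return pd.DataFrame(
        {
            "cumulative_volume_L": dv_cum,
            "macroion_total_M": macro,
            "ligand_total_M": ligand,
            "molar_ratio": ratio,
        },
        index=pd.RangeIndex(1, len(dv) + 1, name="injection"),
    )


def predicted_heats(
    params: BindingParameters,
    schedule: InjectionSchedule,
    macroion_conc: float | None = None,
) -> np.ndarray:
    """Model per-injection heats (J) for an SSIS titration.

    For every injection the cell composition from :func:`cell_trajectory` is
    equilibrated with the SSIS model to obtain the cumulative heat Q'_i, and
    the displaced-volume-corrected injection heat

        dQ'_i = Q'_i + (dV_i/V0) * (Q'_i + Q'_{i-1})/2 - Q'_{i-1}

    is returned.  ``macroion_conc`` overrides the schedule's initial macroion
    concentration when given.
    """
    if macroion_conc is not None:
        schedule = InjectionSchedule(
            cell_volume=schedule.cell_volume,
            syringe_conc=schedule.syringe_conc,
            cell_macroion_conc=macroion_conc,
            injection_volumes=schedule.injection_volumes,
            spacing=schedule.spacing,
            temperature=schedule.temperature,
            cell_titrant_conc=schedule.cell_titrant_conc,
            initial_delay=schedule.initial_delay,
        )
    traj = cell_trajectory(schedule)
    v0 = schedule.cell_volume
    q = np.empty(schedule.n_injections)
    q_prev = 0.0
    for i, (dv, row) in enumerate(zip(schedule.injection_volumes, traj.itertuples())):
        comp = CellComposition(
            macroion_total=row.macroion_total_M,
            ligand_total=row.ligand_total_M,
            temperature=schedule.temperature,
            cell_volume=v0,
        )
        q_i = cumulative_heat(params, comp)
        q[i] = q_i + (dv / v0) * 0.5 * (q_i + q_prev) - q_prev
        q_prev = q_i
    return q


def normalize_heats(heats: np.ndarray, schedule: InjectionSchedule) -> np.ndarray:
    """Convert per-injection heats (J) to kJ per mole of injected titrant.

    This is the ordinate convention of the usual ITC isotherm plot:
    ``heat_i / (c_syr * dV_i)`` in kJ/mol.
    """
    heats = np.asarray(heats, dtype=float)
    dv = np.asarray(schedule.injection_volumes)
    if heats.shape[0] != dv.shape[0]:
        raise ValueError(
            f"got {heats.shape[0]} heats for {dv.shape[0]} injections"
        )
    moles = schedule.syringe_conc * dv
    if np.any(moles <= 0):
        raise ValueError("zero moles injected; cannot normalize")
    return heats / moles / 1e3
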