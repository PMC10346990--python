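"""CSV and YAML interchange for heats, thermograms and experiment configs.

Formats are deliberately plain:

* heats CSV — columns ``injection,heat_J,sigma_J,provenance`` (UTF-8, "."
  decimal); heats in joules, positive = endothermic.  A ``heat_ucal``
  column is accepted on read and converted (1 cal = 4.184 J).
* thermogram CSV — columns ``time_s,power_ucal_per_s``.
* experiment config — YAML mirroring :class:`ExperimentConfig`, with the
  user-facing units practitioners use (mL, mM, uL, degrees C).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import CAL_TO_J, InjectionHeats, Thermogram
from .titration import InjectionSchedule

__all__ = [
    "ExperimentConfig",
    "read_heats_csv",
    "write_heats_csv",
    "read_thermogram_csv",
    "write_thermogram_csv",
    "read_config",
    "write_config",
    "config_hash",
]

HEATS_COLUMNS = ["injection", "heat_J", "sigma_J", "provenance"]
THERMOGRAM_COLUMNS = ["time_s", "power_ucal_per_s"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Serializable titration design in bench units."""

    cell_volume_mL: float = 1.43
    syringe_conc_mM: float = 5.0
    cell_macroion_conc_mM: float = 0.032
    temperature_C: float = 30.0
    n_injections: int = 35
    injection_volume_uL: float = 8.0
    spacing_s: float = 300.0
    initial_delay_s: float = 60.0
    buffer_name: str = "MOPS"
    buffer_nominal_mM: float = 10.0
    salts: tuple[dict, ...] = field(default_factory=tuple)

    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule.uniform(
            n_injections=self.n_injections,
            injection_volume=self.injection_volume_uL * 1e-6,
            cell_volume=self.cell_volume_mL * 1e-3,
            syringe_conc=self.syringe_conc_mM * 1e-3,
            cell_macroion_conc=self.cell_macroion_conc_mM * 1e-3,
            spacing=self.spacing_s,
            temperature=self.temperature_C + 273.15,
            initial_delay=self.initial_delay_s,
        )


def write_heats_csv(heats: InjectionHeats, path: str | Path) -> None:
    sigma = heats.sigma if heats.sigma is not None else np.full(len(heats), np.nan)
    pd.DataFrame(
        {
            "injection": heats.injection_index,
            "heat_J": heats.heat,
            "sigma_J": sigma,
            "provenance": heats.provenance,
        }
    ).to_csv(path, index=False)


def read_heats_csv(path: str | Path) -> InjectionHeats:
    df = pd.read_csv(path)
    if "heat_ucal" in df.columns and "heat_J" not in df.columns:
        df["heat_J"] = df["heat_ucal"] * 1e-6 * CAL_TO_J
    missing = [c for c in ("injection", "heat_J") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header line 1")
    bad = df.index[~np.isfinite(df["heat_J"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"{path}: malformed heat at data line {bad[0] + 2}")
    idx = df["injection"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError(f"{path}: injection indices must be contiguous from 1")
    sigma = None
    if "sigma_J" in df.columns and np.isfinite(df["sigma_J"]).all():
        sigma = df["sigma_J"].to_numpy(dtype=float)
    provenance = "raw"
    if "provenance" in df.columns and len(df):
        provenance = str(df["provenance"].iloc[0])
    return InjectionHeats(heat=df["heat_J"].to_numpy(dtype=float), sigma=sigma,
                          provenance=provenance)


def write_thermogram_csv(tg: Thermogram, path: str | Path) -> None:
    pd.DataFrame({"time_s": tg.time, "power_ucal_per_s": tg.power}).to_csv(path, index=False)


def read_thermogram_csv(path: str | Path) -> Thermogram:
    df = pd.read_csv(path)
    missing = [c for c in THERMOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header line 1")
    return Thermogram(
        time=df["time_s"].to_numpy(dtype=float),
        power=df["power_ucal_per_s"].to_numpy(dtype=float),
    )


def write_config(config: ExperimentConfig, path: str | Path) -> None:
    data = asdict(config)
    data["salts"] = [dict(s) for s in config.salts]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config(path: str | Path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    salts = tuple(data.pop("salts", ()) or ())
    try:
        return ExperimentConfig(salts=salts, **data)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from None


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash identifying a config (for run logging)."""
    data = asdict(config)
    data["salts"] = [dict(s) for s in config.salts]
    blob = yaml.safe_dump(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
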