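"""Ionic-strength accounting and buffer design for titration experiments.

The ionic strength is I = 1/2 * sum_i c_i z_i^2 over dissolved ions.  The
organic buffer (e.g. 10 mM MOPS titrated to pH 7.2 with NaOH) is counted at
its *nominal* concentration as a fully dissociated 1:1 electrolyte, the
accounting convention under which the published dPGS-divalent-ion buffer
compositions close exactly: a divalent chloride MX2 at concentration c
contributes 3c, NaCl at c contributes c, and the macroion's own counterions
are excluded.  An optional Henderson-Hasselbalch mode scales the buffer
contribution by its ionization fraction instead.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IonicComposition",
    "ionic_strength",
    "required_monovalent",
    "mops_ionized_fraction",
]


@dataclass(frozen=True)
class IonicComposition:
    """Fully dissociated ionic species plus a nominal 1:1 buffer.

    ``species`` holds (name, concentration in mol/L, integer charge) for each
    dissolved ion; enter salts as their neutral ion combinations (MgCl2 at c
    becomes Mg2+ at c and Cl- at 2c).  ``buffer_nominal`` is the buffer
    concentration counted as a 1:1 salt.
    """

    species: tuple[tuple[str, float, int], ...] = ()
    buffer_nominal: float = 0.0

    def __post_init__(self) -> None:
        sp = tuple((str(n), float(c), int(z)) for n, c, z in self.species)
        object.__setattr__(self, "species", sp)
        for name, conc, _z in sp:
            if conc < 0:
                raise ValueError(f"negative concentration for species {name!r}: {conc}")
        if self.buffer_nominal < 0:
            raise ValueError(f"buffer_nominal must be >= 0, got {self.buffer_nominal}")
        charge = sum(c * z for _n, c, z in sp)
        scale = max((c * abs(z) for _n, c, z in sp), default=0.0)
        if scale > 0 and abs(charge) > 1e-9 * scale:
            raise ValueError(
                f"species are not electroneutral (net charge {charge:.3e} eq/L); "
                "enter salts as neutral combinations"
            )

    @classmethod
    def from_salts(
        cls,
        buffer_nominal: float = 0.0,
        divalent_chloride: float = 0.0,
        nacl: float = 0.0,
        cation: str = "Mg2+",
    ) -> "IonicComposition":
        """Compose buffer + MX2 + NaCl (concentrations in mol/L)."""
        species: list[tuple[str, float, int]] = []
        if divalent_chloride > 0:
            species += [(cation, divalent_chloride, 2), ("Cl-", 2 * divalent_chloride, -1)]
        if nacl > 0:
            species += [("Na+", nacl, 1), ("Cl-", nacl, -1)]
        return cls(species=tuple(species), buffer_nominal=buffer_nominal)


def mops_ionized_fraction(ph: float = 7.2, pka: float = 7.2) -> float:
    """Henderson-Hasselbalch anionic fraction of a monoprotic buffer."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def ionic_strength(comp: IonicComposition, buffer_mode: str = "nominal", ph: float = 7.2,
                   pka: float = 7.2) -> float:
    """Ionic strength in mol/L.

    ``buffer_mode="nominal"`` (default) counts the buffer at its nominal
    concentration as a 1:1 electrolyte, so it contributes ``buffer_nominal``
    to I.  ``buffer_mode="henderson"`` scales that contribution by the
    ionized fraction at the given pH/pKa instead.
    """
    if buffer_mode == "nominal":
        i_buffer = comp.buffer_nominal
    elif buffer_mode == "henderson":
        i_buffer = comp.buffer_nominal * mops_ionized_fraction(ph, pka)
    else:
        raise ValueError(f"unknown buffer_mode {buffer_mode!r}")
    return i_buffer + 0.5 * sum(c * z * z for _n, c, z in comp.species)


def required_monovalent(
    target_ionic_strength: float,
    divalent_chloride_conc: float,
    buffer_nominal: float,
) -> float:
    """NaCl concentration (mol/L) needed to reach a target ionic strength.

    Under the nominal-buffer convention, I = buffer + 3*c_MX2 + c_NaCl, so
    the answer is the difference; an infeasible target (below what buffer
    and divalent salt alone provide) raises with the minimum achievable I.
    """
    floor = buffer_nominal + 3.0 * divalent_chloride_conc
    nacl = target_ionic_strength - floor
    if nacl < -1e-15:
        raise ValueError(
            f"target ionic strength {target_ionic_strength:.6g} M is below the "
            f"minimum {floor:.6g} M set by buffer and divalent salt"
        )
    return max(nacl, 0.0)
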