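"""Single-set-of-identical-sites (SSIS) equilibrium binding model.

The SSIS (Langmuir) model describes a macroion carrying ``N`` independent,
identical adsorption sites for a ligand (here a divalent counterion binding
to dendritic polyglycerol sulfate).  At equilibrium the site occupancy is

    theta = Kb * [A] / (1 + Kb * [A])

with ``Kb`` the binding constant (M^-1) and ``[A]`` the *free* ligand
concentration.  Mass balance ties ``[A]`` to the known total concentration,

    [A]_tot = [A] + N * theta * [M]

where ``[M]`` is the total macroion concentration.  Substituting the mass
balance into the isotherm gives a quadratic in ``theta`` which this module
solves in closed, cancellation-safe form.  The cumulative heat evolved once
the cell equilibrates is

    Q' = [M] * V0 * N * theta * dH

with ``V0`` the cell volume and ``dH`` the molar binding enthalpy.

All quantities are SI internally: mol/L, L, K, J.  Enthalpies are carried in
kJ/mol (the unit practitioners quote) and converted at the point of use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "BindingParameters",
    "CellComposition",
    "TitrationState",
    "ThermoSummary",
    "occupancy",
    "cumulative_heat",
    "gibbs_free_energy",
    "thermo_summary",
]

#: Molar gas constant, J mol^-1 K^-1 (exact by convention here).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class BindingParameters:
    """SSIS parameter triple.

    Attributes
    ----------
    n_sites : float
        Number of identical binding sites per macroion, ``N`` (dimensionless).
    binding_constant : float
        Site binding constant ``Kb`` in M^-1.
    enthalpy : float
        Molar binding enthalpy ``dH`` in kJ/mol of bound ligand.  Positive
        means endothermic.
    """

    n_sites: float
    binding_constant: float
    enthalpy: float

    def __post_init__(self) -> None:
        if not (self.n_sites > 0 and math.isfinite(self.n_sites)):
            raise ValueError(f"n_sites must be positive and finite, got {self.n_sites}")
        if not (self.binding_constant > 0 and math.isfinite(self.binding_constant)):
            raise ValueError(
                f"binding_constant must be positive and finite, got {self.binding_constant}"
            )
        if not math.isfinite(self.enthalpy):
            raise ValueError(f"enthalpy must be finite, got {self.enthalpy}")


@dataclass(frozen=True)
class CellComposition:
    """Instantaneous composition of the calorimeter cell.

    Concentrations in mol/L, temperature in K, volume in L.
    """

    macroion_total: float
    ligand_total: float
    temperature: float = 303.15
    cell_volume: float = 1.43e-3

    def __post_init__(self) -> None:
        if self.macroion_total < 0:
            raise ValueError(f"macroion_total must be >= 0, got {self.macroion_total}")
        if self.ligand_total < 0:
            raise ValueError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not self.cell_volume > 0:
            raise ValueError(f"cell_volume must be > 0, got {self.cell_volume}")


@dataclass(frozen=True)
class TitrationState:
    """Equilibrium state of the cell: occupancy, free ligand, bound count, heat."""

    occupancy: float
    free_ligand: float
    bound_per_macroion: float
    cumulative_heat: float


@dataclass(frozen=True)
class ThermoSummary:
    """Thermodynamic decomposition dG = dH - T dS, all in kJ/mol."""

    delta_G: float
    delta_H: float
    minus_T_delta_S: float
    gas_constant: float = GAS_CONSTANT


def _solve_occupancy(n_sites: float, kb: float, macroion: float, ligand_tot: float) -> float:
    """Root in [0, 1] of the SSIS occupancy quadratic.

    Substituting the mass balance into the isotherm yields

        a*theta^2 + b*theta + c = 0,
        a = Kb*N*[M],  b = -(1 + Kb*[A]_tot + Kb*N*[M]),  c = Kb*[A]_tot.

    ``b`` is always negative and the physical root is the smaller one.  It is
    computed as ``c/q`` with ``q = (-b + sqrt(b^2 - 4ac)) / 2`` so that no
    subtraction of nearly equal quantities occurs — important at the low
    Wiseman c-values (~1) typical of weak polyelectrolyte-ion binding.
    """
    if ligand_tot == 0.0:
        return 0.0
    a = kb * n_sites * macroion
    c = kb * ligand_tot
    if a == 0.0:
        # no depletion: theta = Kb*A_tot / (1 + Kb*A_tot)
        return c / (1.0 + c)
    b = -(1.0 + c + a)
    disc = b * b - 4.0 * a * c
    if disc < 0.0:  # cannot happen for valid inputs; guard fp pathologies
        raise ArithmeticError("occupancy quadratic has no real root; inconsistent state")
    q = 0.5 * (-b + math.sqrt(disc))
    theta = c / q
    # fp guard: clamp a root that lands epsilon outside [0, 1]
    if theta < 0.0 or theta > 1.0:
        if -1e-12 < theta < 0.0:
            return 0.0
        if 1.0 < theta < 1.0 + 1e-12:
            return 1.0
        raise ArithmeticError(f"occupancy root {theta} outside [0, 1]")
    return theta


def occupancy(params: BindingParameters, comp: CellComposition) -> TitrationState:
    """Solve the SSIS equilibrium for the given cell composition.

    Returns the full :class:`TitrationState`: site occupancy ``theta``, free
    ligand concentration ``[A] = [A]_tot - N*theta*[M]`` (mol/L), bound ions
    per macroion ``N*theta``, and the cumulative heat ``Q'`` in joules.
    """
    theta = _solve_occupancy(
        params.n_sites, params.binding_constant, comp.macroion_total, comp.ligand_total
    )
    free = comp.ligand_total - params.n_sites * theta * comp.macroion_total
    if free < 0.0:  # fp dust only
        free = 0.0
    q = (
        comp.macroion_total
        * comp.cell_volume
        * params.n_sites
        * theta
        * params.enthalpy
        * 1e3  # kJ/mol -> J/mol
    )
    return TitrationState(
        occupancy=theta,
        free_ligand=free,
        bound_per_macroion=params.n_sites * theta,
        cumulative_heat=q,
    )


def cumulative_heat(params: BindingParameters, comp: CellComposition) -> float:
    """Cumulative heat ``Q' = [M] V0 N theta dH`` in joules."""
    return occupancy(params, comp).cumulative_heat


def gibbs_free_energy(binding_constant: float, temperature: float) -> float:
    """Standard binding free energy ``dG = -R T ln(Kb)`` in kJ/mol.

    ``Kb`` is nondimensionalized by the 1 M standard state, so ``Kb = 1 M^-1``
    gives ``dG = 0``.
    """
    if not binding_constant > 0:
        raise ValueError(f"binding_constant must be > 0, got {binding_constant}")
    if not temperature > 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return -GAS_CONSTANT * temperature * math.log(binding_constant) / 1e3


def thermo_summary(params: BindingParameters, temperature: float = 303.15) -> ThermoSummary:
    """Decompose the binding thermodynamics: dG, dH and -T dS = dG - dH.

    A negative ``-T dS`` alongside a positive (endothermic) ``dH`` signals an
    entropy-driven process, the signature of counterion release.
    """
    dg = gibbs_free_energy(params.binding_constant, temperature)
    return ThermoSummary(
        delta_G=dg, delta_H=params.enthalpy, minus_T_delta_S=dg - params.enthalpy
    )
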