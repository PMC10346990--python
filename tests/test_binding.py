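"""SSIS equilibrium model: occupancy, mass balance, heats, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ssisfit import (
    BindingParameters,
    CellComposition,
    cumulative_heat,
    gibbs_free_energy,
    occupancy,
    thermo_summary,
)


def theta_bisection(n, kb, macro, ligand_tot):
    """Independent oracle: root of the fixed-point residual of the isotherm."""
    if ligand_tot == 0:
        return 0.0

    def residual(th):
        free = ligand_tot - n * th * macro
        return th - kb * free / (1.0 + kb * free)

    hi = min(1.0, ligand_tot / (n * macro)) if n * macro > 0 else 1.0
    return brentq(residual, 0.0, hi, xtol=1e-16, rtol=8.9e-16)


class TestOccupancy:
    def test_no_ligand_gives_zero_occupancy(self):
        st_ = occupancy(BindingParameters(7.5, 5.1e3, 8.1), CellComposition(0.032e-3, 0.0))
        assert st_.occupancy == 0.0
        assert st_.free_ligand == 0.0
        assert st_.cumulative_heat == 0.0

    def test_no_macroion_reduces_to_bare_isotherm(self):
        kb, atot = 5.1e3, 1.0e-3
        st_ = occupancy(BindingParameters(7.5, kb, 8.1), CellComposition(0.0, atot))
        assert st_.occupancy == pytest.approx(kb * atot / (1 + kb * atot), rel=1e-15)
        assert st_.free_ligand == atot

    def test_reference_composition_matches_bisection(self):
        # Kb=5.1e3/M, N=7.5, [M]=0.032 mM, [A]tot=1.0 mM -> theta ~ 0.804
        st_ = occupancy(BindingParameters(7.5, 5.1e3, 8.1), CellComposition(0.032e-3, 1.0e-3))
        oracle = theta_bisection(7.5, 5.1e3, 0.032e-3, 1.0e-3)
        assert st_.occupancy == pytest.approx(oracle, abs=1e-12)
        assert st_.occupancy == pytest.approx(0.804, abs=1e-3)
        assert st_.free_ligand == pytest.approx(0.807e-3, abs=5e-7)

    @given(
        n=st.floats(0.5, 50),
        log_kb=st.floats(1.0, 7.0),
        macro=st.floats(1e-6, 1e-3),
        ligand=st.floats(0.0, 1e-2),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mass_balance_and_fixed_point(self, n, log_kb, macro, ligand):
        kb = 10.0**log_kb
        st_ = occupancy(BindingParameters(n, kb, 1.0), CellComposition(macro, ligand))
        assert 0.0 <= st_.occupancy <= 1.0
        bound = n * st_.occupancy * macro
        assert st_.free_ligand + bound == pytest.approx(ligand, rel=1e-12, abs=1e-300)
        if ligand > 0:
            iso = kb * st_.free_ligand / (1.0 + kb * st_.free_ligand)
            assert st_.occupancy == pytest.approx(iso, rel=1e-10, abs=1e-12)

    @given(
        log_kb=st.floats(1.0, 6.0),
        macro=st.floats(1e-6, 1e-3),
        ligand=st.floats(1e-6, 5e-3),
        bump=st.floats(1.1, 10.0),
    )
    @settings(max_examples=150, derandomize=True)
    def test_monotonicity(self, log_kb, macro, ligand, bump):
        kb = 10.0**log_kb
        base = occupancy(BindingParameters(5.0, kb, 1.0), CellComposition(macro, ligand))
        more_ligand = occupancy(BindingParameters(5.0, kb, 1.0), CellComposition(macro, ligand * bump))
        stronger = occupancy(BindingParameters(5.0, kb * bump, 1.0), CellComposition(macro, ligand))
        more_sites = occupancy(BindingParameters(5.0 * bump, kb, 1.0), CellComposition(macro, ligand))
        assert more_ligand.occupancy >= base.occupancy - 1e-12
        assert stronger.occupancy >= base.occupancy - 1e-12
        assert more_sites.occupancy <= base.occupancy + 1e-12

    def test_saturation_and_weak_binding_limits(self):
        n, macro = 5.0, 1e-5
        sat = occupancy(BindingParameters(n, 1e9, 1.0), CellComposition(macro, 1e-2))
        assert sat.occupancy == pytest.approx(1.0, abs=1e-5)
        weak = occupancy(BindingParameters(n, 1e-4, 1.0), CellComposition(macro, 1e-3))
        assert weak.occupancy == pytest.approx(1e-4 * 1e-3, rel=1e-3)

    def test_invalid_parameters_name_the_field(self):
        with pytest.raises(ValueError, match="n_sites"):
            BindingParameters(-1.0, 5e3, 8.1)
        with pytest.raises(ValueError, match="binding_constant"):
            BindingParameters(7.5, 0.0, 8.1)
        with pytest.raises(ValueError, match="enthalpy"):
            BindingParameters(7.5, 5e3, math.nan)
        with pytest.raises(ValueError, match="ligand_total"):
            CellComposition(0.032e-3, -1e-3)


class TestHeatsAndThermo:
    def test_zero_enthalpy_or_zero_ligand_gives_zero_heat(self):
        comp = CellComposition(0.032e-3, 1.0e-3)
        assert cumulative_heat(BindingParameters(7.5, 5.1e3, 0.0), comp) == 0.0
        empty = CellComposition(0.032e-3, 0.0)
        assert cumulative_heat(BindingParameters(7.5, 5.1e3, 8.1), empty) == 0.0

    def test_cumulative_heat_matches_independent_arithmetic(self):
        comp = CellComposition(0.032e-3, 1.0e-3, cell_volume=1.43e-3)
        params = BindingParameters(7.5, 5.1e3, 8.1)
        theta = theta_bisection(7.5, 5.1e3, 0.032e-3, 1.0e-3)
        expected = 0.032e-3 * 1.43e-3 * 7.5 * theta * 8.1e3
        assert cumulative_heat(params, comp) == pytest.approx(expected, rel=1e-10)

    def test_gibbs_free_energy_unit_constant(self):
        assert gibbs_free_energy(1.0, 303.15) == 0.0

    @pytest.mark.parametrize(
        "kb,expected",
        [(6.3e3, -22.0), (5.1e3, -21.5), (6.5e3, -22.1), (4.1e3, -21.0)],
    )
    def test_gibbs_free_energy_reference_values(self, kb, expected):
        assert round(gibbs_free_energy(kb, 303.15), 1) == expected

    def test_gibbs_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(0.0, 303.15)
        with pytest.raises(ValueError):
            gibbs_free_energy(5e3, -1.0)

    def test_delta_g_negative_iff_kb_above_unity(self):
        assert gibbs_free_energy(1.0 + 1e-9, 300.0) < 0
        assert gibbs_free_energy(1.0 - 1e-9, 300.0) > 0

    def test_thermo_summary_decomposition(self):
        ts = thermo_summary(BindingParameters(7.5, 5.1e3, 8.1), 303.15)
        assert round(ts.delta_G, 1) == -21.5
        assert round(ts.minus_T_delta_S, 1) == -29.6
        # identity by construction, up to one fp rounding in the subtraction
        assert ts.delta_H + ts.minus_T_delta_S == pytest.approx(ts.delta_G, rel=1e-15)
        ca = thermo_summary(BindingParameters(7.9, 6.3e3, 6.8), 303.15)
        assert round(ca.delta_G, 1) == -22.0
        assert ca.minus_T_delta_S == ca.delta_G - 6.8

    def test_degenerate_summary_is_all_zero(self):
        ts = thermo_summary(BindingParameters(1.0, 1.0, 0.0), 303.15)
        assert ts.delta_G == ts.delta_H == ts.minus_T_delta_S == 0.0
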