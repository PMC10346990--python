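"""Forward SSIS model: occupancy, free ligand and heat for one composition.

Evaluates the single-set-of-identical-sites equilibrium for dPGS
(N = 7.5 sites, Kb = 5.1e3 1/M, dH = +8.1 kJ/mol) in a cell containing
0.032 mM macroion and 1.0 mM total divalent ion.
"""

from ssisfit import BindingParameters, CellComposition, occupancy, thermo_summary

params = BindingParameters(n_sites=7.5, binding_constant=5.1e3, enthalpy=8.1)
comp = CellComposition(macroion_total=0.032e-3, ligand_total=1.0e-3)

state = occupancy(params, comp)
print(f"site occupancy theta      = {state.occupancy:.4f}")
print(f"free divalent ion [A]     = {state.free_ligand * 1e3:.4f} mM")
print(f"bound ions per macroion   = {state.bound_per_macroion:.3f}")
print(f"cumulative heat Q'        = {state.cumulative_heat * 1e6:.1f} uJ")

ts = thermo_summary(params, 303.15)
print(f"dG = {ts.delta_G:.1f}  dH = {ts.delta_H:.1f}  -TdS = {ts.minus_T_delta_S:.1f} kJ/mol")
print("Positive dH with negative -TdS: binding is entropy-driven (counterion release).")
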