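"""Ionic-strength buffer design: how much NaCl reaches a target I?

Reproduces the five reference buffer compositions (10 mM nominal buffer plus
a divalent chloride and NaCl) at ionic strengths of 16.5 and 21.5 mM.
"""

from ssisfit import IonicComposition, ionic_strength, required_monovalent

rows = [
    ("Ca2+ / I=16.5", 0.8, 16.5),
    ("Mg2+ / I=16.5", 0.8, 16.5),
    ("Mg2+ / I=21.5", 0.8, 21.5),
    ("Mg2+ / I=21.5", 1.7, 21.5),
    ("Mg2+ / I=21.5", 2.5, 21.5),
]

print(f"{'system':<15} {'MX2 (mM)':>9} {'NaCl (mM)':>10} {'I check (mM)':>13}")
for label, di_mM, target_mM in rows:
    nacl = required_monovalent(target_mM * 1e-3, di_mM * 1e-3, 10e-3)
    comp = IonicComposition.from_salts(10e-3, di_mM * 1e-3, nacl)
    print(f"{label:<15} {di_mM:>9.1f} {nacl * 1e3:>10.1f} {ionic_strength(comp) * 1e3:>13.1f}")
print("A divalent chloride at c contributes 3c to I; NaCl contributes c.")
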