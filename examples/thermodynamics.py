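"""Activation thermodynamics from published rate constants.

Feeds the published TAC rate constants through the full chain — noiseless
series, kinetic re-fit, Arrhenius Ea, Eyring dH/dG/dS per temperature — and
prints the thermodynamic table.
"""

from phytokin import arrhenius_fit, fit_first_order, reference_noiseless_series, thermo_table

fits = [fit_first_order(s) for s in reference_noiseless_series("TAC")]
arr = arrhenius_fit([(f.temperature_c, f.k) for f in fits])
rows = thermo_table(arr, fits)

print("T (K)    dH (kJ/mol)   dG (kJ/mol)   dS (J/(mol*K))")
for r in rows:
    print(f"{r.t_kelvin:6.1f}   {r.dh:10.2f}   {r.dg:10.2f}   {r.ds:12.2f}")

print(
    "\nPositive dH: the degradation is endothermic. Positive dG, growing with"
    "\ntemperature: the activated step is non-spontaneous. Negative dS: the"
    "\ntransition state is more ordered than the reactant (entropy barrier)."
)
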