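"""Standard free energy and balance audit of the thiosulfate/arsenate couple.

Builds the shipped reaction 4 HAsO4^2- + S2O3^2- + 7 H2O ->
4 H3AsO3 + 2 SO4^2- + 6 OH- and reports its thermodynamic bookkeeping.
"""

from soasr.thermo import balance_report, gibbs_free_energy, soasr_reaction, stoichiometric_ratio

rxn = soasr_reaction()

dg = gibbs_free_energy(rxn)
rep = balance_report(rxn)
ratio = stoichiometric_ratio(rxn, "H3AsO3", "SO4^2-")

print(f"ΔG° = {dg:+.0f} kJ/mol (per 4 mol As(V) reduced; positive = endergonic at standard state)")
print(f"balanced: {rep.balanced}  charge: {rep.charge_balance[0]:g} -> {rep.charge_balance[1]:g}")
print(f"electrons transferred: {rep.electrons_transferred:g} (As +5->+3 x4, S +2->+6 x2)")
print(f"As(III):SO4 product stoichiometry = {ratio:g} : 1")
# The 2:1 product ratio is the fingerprint used to recognise
# sulfur-oxidation-coupled arsenate reduction in incubation data.
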