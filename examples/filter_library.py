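"""Prefilter a small compound library for lead-likeness and reactive groups.

Builds a six-compound library in memory, computes the physicochemical
descriptors, and applies the lead-likeness window (MW 150-450, cLogP <= 5,
Lipinski HBD/HBA, Veber RotB/TPSA) followed by the reactive-group alerts.
"""

from vsfuse import MoleculeRecord, compute_properties, filter_druglike, filter_reactive

library = [
    MoleculeRecord("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    MoleculeRecord("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    MoleculeRecord("glycerol", "OCC(O)CO"),  # too small: MW < 150
    MoleculeRecord("eicosane", "CCCCCCCCCCCCCCCCCCCC"),  # cLogP and RotB out
    MoleculeRecord("aroyl_chloride", "O=C(Cl)c1ccc(Oc2ccccc2)cc1"),  # reactive acyl halide
    MoleculeRecord("benzanilide", "O=C(Nc1ccccc1)c1ccccc1"),
]

records = [compute_properties(r) for r in library]
passed, drug_report = filter_druglike(records)
passed, alert_report = filter_reactive(passed)

print(f"input: {drug_report.n_input} compounds")
print(f"lead-likeness failures by first failing rule: {drug_report.failures}")
print(f"reactive-alert failures: {alert_report.failures}")
print(f"passed: {[r.id for r in passed]}")
# The failure map attributes each rejected compound to the first rule it
# broke; the survivors are the compounds a 2D screen would actually rank.
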