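"""Compare the four 2D fingerprint schemes on a few related molecules.

Tanimoto similarity (|A&B| / |A|B|) on binary fingerprints is the score
every screening method in this package ranks by.  Structural analogs
score high; an unrelated scaffold scores low under every scheme.
"""

from vsfuse import MoleculeRecord, fingerprint, tanimoto
from vsfuse.fingerprints import MEASURES

query = MoleculeRecord("salicylanilide", "O=C(Nc1ccccc1)c1ccccc1O")
library = [
    MoleculeRecord("analog_Cl", "O=C(Nc1ccc(Cl)cc1)c1ccccc1O"),
    MoleculeRecord("analog_Me", "Cc1ccc(NC(=O)c2ccccc2O)cc1"),
    MoleculeRecord("unrelated", "C1CCC(CC2CCNCC2)CC1"),
]

header = f"{'compound':<12}" + "".join(f"{m:>12}" for m in MEASURES)
print(header)
for rec in library:
    sims = [tanimoto(fingerprint(query, m), fingerprint(rec, m)) for m in MEASURES]
    print(f"{rec.id:<12}" + "".join(f"{s:>12.3f}" for s in sims))
# Each column is one similarity measure; rows near 1 are close analogs of
# the query, rows near 0 share almost no substructure environments.
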