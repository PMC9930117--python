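# Methods

`vsfuse` implements a ligand-based virtual-screening funnel: prefilter a
compound library, rank it by 2D fingerprint similarity to known actives
with MAX/SUM data fusion, validate the ranking with early-enrichment
metrics against a property-matched decoy set, and optionally rescreen
with a 3D pharmacophore. This note records the models, the defaults and
why, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Prefilters

A compound passes the lead-likeness filter iff 150 ≤ MW ≤ 450 g/mol,
cLogP ≤ 5.0, HBD ≤ 5, HBA ≤ 10, RotB ≤ 10 and TPSA ≤ 140 Å². The MW and
logP windows are the lead-like override of the classical Lipinski/Veber
thresholds; all six are configurable (`DruglikeRules`). cLogP is
Wildman–Crippen atom-contribution logP, and the estimator name is
written into every `FilterReport` so numbers stay attributable.
Mixtures/salts are reduced to the largest organic fragment before
property computation. Failure attribution is to the *first* failing
rule in the fixed order MW, cLogP, HBD, HBA, RotB, TPSA, which makes
reports deterministic and gives the accounting identity
`n_passed + Σ failures + n_failed_parse = n_input`.

The reactive-group filter ships a deliberately small, documented alert
list (acyl halide, aldehyde, enone Michael acceptor, alkyl halide,
isocyanate, epoxide/aziridine, quinone, azo, anhydride, peroxide). It is
a stand-in for full REOS/PAINS catalogs, which users can supply as their
own SMARTS mapping; exhaustive rule transcription is a non-goal.

## Fingerprints

All four schemes are binary ("bit"-scaled) and compared with the
Tanimoto index |A∩B|/|A∪B| (defined as 0 when both sets are empty).

* **MACCS** — the public 166-key structural-key set, via RDKit's
  implementation; `KeyedFingerprint` drops the unused bit 0.
* **radial** — ECFP-style circular environments of radius 0..*r* around
  each heavy atom; default *r* = 2 (ECFP4-equivalent diameter), chosen
  as the community standard and configurable.
* **dendritic** — every connected fragment that is a simple path or a
  tree with at most one branching vertex, up to 5 bonds. "At most one
  branching vertex" is a conservative reading of growth "in linear and
  branched directions"; the bond limit is configurable.
* **MOLPRINT2D** — each heavy atom encoded as its SYBYL-style type plus
  the sorted multiset of (graph distance 1 or 2, neighbor type) pairs.

Hashed schemes type atoms with the daylight scheme (atomic number,
total valence, formal charge, H count, heavy-neighbor count); MOLPRINT2D
uses a documented SYBYL mol2-type subset (C.1/2/3/ar, N.1/2/3/4/ar/am/pl3,
O.2/3/co2, S.2/3, P.3, halogens). Each fragment is canonicalized — the
fragment's canonical SMILES with atom symbols replaced by type tokens,
using whole-molecule canonical ranks, so bit sets are invariant under
input atom renumbering — then hashed into the 2³² space with FNV-1a
(offset 2166136261, prime 16777619), pinned for bit-exact
reproducibility. Collisions are accepted: only "on" bits are stored.
Bit-for-bit compatibility with any proprietary implementation is
explicitly out of scope; what is guaranteed is determinism, renumbering
invariance and the documented fragment semantics.

## Similarity fusion and screening methods

`similarity_search` produces the complete (query, measure, library)
Tanimoto table. Three reductions mirror standard screening practice:

* **Method A** — no fusion: one ranking per (query active, measure);
  28 actives × 4 measures = 112 rankings.
* **Method B** — similarity fusion: per active, its 4 measure scores
  fused by MAX and by SUM → 56 rankings.
* **Method C** — group fusion: per measure, the 28 per-active scores of
  each library compound fused by MAX and SUM → 8 rankings.

SUM is a plain arithmetic sum (no normalization): with equal score
counts per compound it ranks identically to the mean. MAX of a group
fusion is exactly 1 for any query active present in the library — the
signature block of top-scoring actives in a validation deck. Ties are
broken by lexicographic compound id after score. This is declared, not
optimistic: tie-heavy score tables are common with small fingerprints,
and a random tie order would make EF at a cut irreproducible. Rankings
always materialize all N compounds; top-x% selection belongs to the
metrics layer.

## Enrichment metrics

`EF(x) = (hits_in_top / n_top) / (N_act / N)` with
`n_top = round_half_away_from_zero(x·N)`, minimum 1. This rounding is
the one consistent with cut sizes 12/60/120 for a 1198-compound deck at
1/5/10%. Compounds are taken strictly by rank at the cut (no fractional
attribution of boundary ties).

ROC/AUC is computed in the Mann–Whitney form: the fraction of
(active, decoy) pairs where the active outranks the decoy; the stepwise
curve over all cut positions integrates to the same value.

BEDROC follows the Truchon–Bailey construction: the sum of
`exp(-α·r_i/N)` over active ranks, normalized by its random expectation
(RIE) and mapped to [0,1] with the sinh/cosh closed form. Default
α = 20, under which the top 8% of the deck carries
`(1−e^{−1.6})/(1−e^{−20})` ≈ 80% of the achievable weight
(`bedroc_weight_fraction`). As α → 0 BEDROC approaches AUC; both limits
are property-tested against brute-force oracles.

## Dataset preparation

Actives are clustered by average-linkage agglomeration (scipy) on
1 − Tanimoto over a chosen fingerprint (MOLPRINT2D by default), cut at a
merge-distance threshold. The threshold is a required, explicit
parameter: a given cluster count cannot be inferred from a distance cut
alone. Representatives per cluster: the most potent compound first
(lowest IC50/Ki), then greedy MaxMin diversity, capped at three.

Decoy eligibility: property deltas within tolerance of at least one
active (defaults MW ±25 Da, cLogP ±1.0, HBD/HBA ±1, RotB ±1 — common
property-matched-decoy practice) AND Tanimoto ≤ 0.35 (default ceiling)
to *every* active. Accepted decoys are attributed to the matched active
with the fewest decoys so far, between a minimum and maximum
decoys-per-ligand ratio (defaults 4 and 36). `verify_decoys` re-checks
an emitted set from scratch and is used by the tests so that no
generator bookkeeping is trusted.

## Pharmacophore screening

Features: donor, acceptor, positive and negative ionizable from small
documented SMARTS sets (a negative-ionizable feature sits on the
carboxyl carbon, not its oxygens); aromatic rings at ring centroids;
hydrophobes at centroids of connected aliphatic-carbon patches of ≥ 2
atoms with no heteroatom substituent. A hypothesis holds 4–10 features
with tolerance spheres (default 1.6 Å) and a minimum interfeature
distance of 2.97 Å, enforced at construction.

Conformers: seeded ETKDG distance-geometry embedding plus MMFF94
minimization, standing in for proprietary systematic-search generators,
with a 255-conformer cap and a 20 kcal/mol energy window as defaults.
The number of embedding attempts scales with rotatable-bond count
(1 for rigid molecules, 20·RotB + 10 otherwise, capped), with RMS
pruning at 0.3 Å.

Matching searches all injective kind-compatible assignments of
hypothesis features to perceived features, pruning partial assignments
whose internal distance deviates by more than the summed tolerances of
the pair; a surviving full assignment is superposed by least-squares
rigid (Kabsch) alignment, and the conformer is a hit iff every assigned
feature lies inside its tolerance sphere. The fit value is the RMS
residual and is used only to rank hits (the weighting of commercial fit
functions is unpublished). The pruned search is tested equivalent to an
unpruned exhaustive oracle. Degenerate note: with fewer than three
non-collinear points the superposition is not unique, but hypotheses
have ≥ 4 features so this does not arise in practice.

## Synthetic benchmark

The generator emulates the statistical shape of a ligand-enrichment
validation set, not its chemistry. Actives are an N-phenylbenzamide
scaffold decorated with 1–3 substituents from a fixed vocabulary
(methyl, F, Cl, hydroxyl, methoxy, amino, carboxyl), accepted only when
pairwise radial Tanimoto stays ≥ 0.35 (floor); synthetic potencies are
log-uniform on 0.005–20 µM. Decoys are decorated variants of twelve
unrelated scaffolds, accepted only when they pass the full decoy
eligibility check with a 0.30 similarity ceiling. The default benchmark
is 28 actives + 1170 decoys (N = 1198) with four measures, so methods
A/B/C emit exactly 112/56/8 rankings; ratio-driven generation defaults
to the [4, 36] decoys-per-ligand window. Planted rankings provide
closed-form expectations (top-block: EF(x) = min(N_act, n_top)/n_top ·
N/N_act, AUC = 1; uniform: E[EF] = 1) for metric tests, and planted
pharmacophore geometries (hypothesis positions + Gaussian noise for
actives, scrambled positions for decoys) exercise the matcher with
known ground truth.

Because generated actives contain each other's query structures and
decoys are constructed to be dissimilar, separations on this benchmark
are near-perfect (AUC ≈ 1). Passing tests therefore demonstrate the
correctness of the machinery — score tables, fusion algebra, metric
formulas, eligibility constraints — not the screening power of any
fingerprint on real chemistry, which depends on the actives/decoys at
hand.

## Problem sizes and determinism

Test and example runs use scaled-down instances chosen as the smallest
sizes that still exercise every code path meaningfully: the full
28/1170 deck for the cardinality contract, 8–10 active benchmarks for
stochastic properties (20 seeds), ≤ 50-compound rankings for exact
oracle comparisons, and ≤ 10 conformers for pharmacophore tests. Every
stochastic component takes an explicit seed; pipeline runs with
identical config and seed reproduce `summary.json` byte for byte.

## Known limitations

* Fingerprints are not bit-compatible with Canvas/Pipeline-Pilot
  implementations of the same names; comparisons across toolkits should
  be made at the ranking level, not the bit level.
* The alert list is a small stand-in for REOS/PAINS.
* Tie handling at EF cuts can differ from tools that attribute
  fractionally or randomize ties.
* Common-feature hypothesis *generation* across multiple actives is out
  of scope; hypotheses are consumed (JSON) or derived from a single
  reference conformation.
* One printed EF pair in the source validation table (similarity-fusion
  method at the 1% and 5% cuts) is not reproducible from any rounding
  of the EF definition that reproduces the other six values; the
  package computes the definition and does not special-case those
  entries.
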