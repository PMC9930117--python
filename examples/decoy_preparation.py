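"""Cluster an active series and select property-matched decoys.

Average-linkage clustering on MOLPRINT2D Tanimoto distance groups the
actives; up to three representatives per cluster are kept (most potent,
then MaxMin-diverse).  Decoys are drawn from a candidate pool only when
they match some active's properties while staying topologically
dissimilar to all of them, and the emitted set is independently
re-verified.
"""

from vsfuse import (
    BenchmarkSpec,
    DecoySpec,
    cluster_actives,
    generate_decoys,
    make_active_series,
    make_decoy_pool,
    select_representatives,
    verify_decoys,
)

spec = BenchmarkSpec(n_actives=12, decoy_ratio=8, seed=4)
actives, activities = make_active_series(spec)
pool = make_decoy_pool(spec, actives)

assignment = cluster_actives(actives, fingerprint_kind="molprint2d", threshold=0.6)
reps = select_representatives(assignment, actives, activities, max_per_cluster=3)
print(f"{len(actives)} actives -> {assignment.n_clusters} clusters -> {len(reps)} representatives")

dspec = DecoySpec(max_tanimoto_to_actives=spec.similarity_ceiling)
decoys, report = generate_decoys(actives, pool, dspec)
violations = verify_decoys(decoys, actives, dspec)
print(f"decoys accepted: {len(decoys)} / pool {report['n_pool']}")
print(f"independent eligibility violations: {len(violations)}")
# Zero violations means every decoy sits inside a real active's property
# window yet below the similarity ceiling -- a fair negative set.
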