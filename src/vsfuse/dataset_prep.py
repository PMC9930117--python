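"""Active clustering, representative selection and decoy generation.

Actives are clustered by average-linkage agglomeration on Tanimoto
distance (1 - similarity) over a chosen fingerprint, cut at a merge
distance.  Per cluster, up to three representatives are taken: the most
potent first, then greedily the compound most dissimilar to those
already selected (MaxMin).

Decoys mimic the actives physically — molecular weight, cLogP, H-bond
donor/acceptor counts and rotatable bonds within tolerances — while
staying topologically dissimilar (Tanimoto to every active below a
ceiling).  Default tolerances follow common property-matched decoy
practice (DUD-E style) and are configuration-exposed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from vsfuse.compound_io import MoleculeRecord
from vsfuse.fingerprints import fingerprint, tanimoto


@dataclass
class ClusterAssignment:
    """Compound id -> cluster index (1-based), with clustering provenance."""

    assignment: dict[str, int]
    linkage: str = "average"
    metric: str = "tanimoto-distance"
    fingerprint_kind: str = "molprint2d"
    threshold: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, c in self.assignment.items() if c == cluster]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id,cluster\n")
            for cid, c in self.assignment.items():
                fh.write(f"{cid},{c}\n")


@dataclass(frozen=True)
class DecoySpec:
    """Property tolerances and similarity ceiling for decoy eligibility."""

    mw_tol: float = 25.0  # Da
    clogp_tol: float = 1.0
    hbd_tol: int = 1
    hba_tol: int = 1
    rotb_tol: int = 1
    max_tanimoto_to_actives: float = 0.35
    min_ratio: int = 4
    max_ratio: int = 36
    fingerprint_kind: str = "radial"

    def __post_init__(self) -> None:
        if not 0 < self.max_tanimoto_to_actives < 1:
            raise ValueError("similarity ceiling must lie strictly in (0, 1)")
        if self.min_ratio > self.max_ratio:
            raise ValueError("min_ratio must not exceed max_ratio")


def _pairwise_tanimoto_distance(records: Sequence[MoleculeRecord], kind: str) -> np.ndarray:
    fps = [fingerprint(r, kind) for r in records]
    n = len(fps)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(fps[i], fps[j])
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_actives(
    actives: Sequence[MoleculeRecord],
    fingerprint_kind: str = "molprint2d",
    threshold: float = 0.6,
) -> ClusterAssignment:
    """Average-linkage hierarchical clustering on Tanimoto distance, cut
    at *threshold* merge distance."""
    if len(actives) < 2:
        raise ValueError("need at least two actives to cluster")
    ids = [r.id for r in actives]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in the active set")
    dist = _pairwise_tanimoto_distance(actives, fingerprint_kind)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")
    return ClusterAssignment(
        assignment=dict(zip(ids, (int(c) for c in labels))),
        fingerprint_kind=fingerprint_kind,
        threshold=threshold,
    )


def select_representatives(
    assignment: ClusterAssignment,
    actives: Sequence[MoleculeRecord],
    activities: Mapping[str, float],
    max_per_cluster: int = 3,
) -> list[str]:
    """Per cluster, up to *max_per_cluster* ids: the most potent compound
    first (lowest IC50/Ki), then greedily the most dissimilar to the
    already-selected (MaxMin diversity)."""
    by_id = {r.id: r for r in actives}
    missing = [cid for cid in assignment.assignment if cid not in activities]
    if missing:
        raise ValueError(f"missing activity values for {missing[:3]}")
    fps = {cid: fingerprint(by_id[cid], assignment.fingerprint_kind) for cid in assignment.assignment}
    selected: list[str] = []
    for cluster in sorted(set(assignment.assignment.values())):
        members = assignment.members(cluster)
        if len(members) <= max_per_cluster:
            selected.extend(sorted(members))
            continue
        # most potent = lowest activity value (IC50/Ki in uM)
        chosen = [min(members, key=lambda c: (activities[c], c))]
        while len(chosen) < max_per_cluster:
            rest = [m for m in members if m not in chosen]
            # MaxMin: maximize the minimum distance to the chosen set
            best = max(
                rest,
                key=lambda m: (min(1.0 - tanimoto(fps[m], fps[c]) for c in chosen), m),
            )
            chosen.append(best)
        selected.extend(chosen)
    return selected


def decoy_eligible(
    candidate: MoleculeRecord,
    actives: Sequence[MoleculeRecord],
    spec: DecoySpec,
    active_fps: Sequence | None = None,
) -> bool:
    """A candidate is an eligible decoy iff its properties fall within the
    tolerances of at least one active AND its Tanimoto similarity to
    EVERY active stays at or below the ceiling."""
    if not candidate.has_properties:
        raise ValueError(f"candidate {candidate.id!r}: properties not computed")
    matched = any(
        abs(candidate.mw - a.mw) <= spec.mw_tol
        and abs(candidate.clogp - a.clogp) <= spec.clogp_tol
        and abs(candidate.hbd - a.hbd) <= spec.hbd_tol
        and abs(candidate.hba - a.hba) <= spec.hba_tol
        and abs(candidate.rotb - a.rotb) <= spec.rotb_tol
        for a in actives
    )
    if not matched:
        return False
    cfp = fingerprint(candidate, spec.fingerprint_kind)
    if active_fps is None:
        active_fps = [fingerprint(a, spec.fingerprint_kind) for a in actives]
    return all(tanimoto(cfp, afp) <= spec.max_tanimoto_to_actives for afp in active_fps)


def generate_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    spec: DecoySpec | None = None,
) -> tuple[list[MoleculeRecord], dict]:
    """Select property-matched, topologically dissimilar decoys from *pool*.

    Per active, between ``spec.min_ratio`` and ``spec.max_ratio`` decoys
    are accepted; each decoy is attributed to the property-matched active
    with the fewest decoys so far (ties by id), which balances coverage.
    Returns the decoy set and a report with per-active counts and
    shortfalls.
    """
    spec = spec or DecoySpec()
    if not pool:
        raise ValueError("empty candidate pool")
    active_ids = {a.id for a in actives}
    active_fps = [fingerprint(a, spec.fingerprint_kind) for a in actives]
    per_active: dict[str, int] = {a.id: 0 for a in actives}
    decoys: list[MoleculeRecord] = []
    for cand in pool:
        if cand.id in active_ids:
            continue
        if not decoy_eligible(cand, actives, spec, active_fps):
            continue
        matched = [
            a.id
            for a in actives
            if per_active[a.id] < spec.max_ratio
            and abs(cand.mw - a.mw) <= spec.mw_tol
            and abs(cand.clogp - a.clogp) <= spec.clogp_tol
            and abs(cand.hbd - a.hbd) <= spec.hbd_tol
            and abs(cand.hba - a.hba) <= spec.hba_tol
            and abs(cand.rotb - a.rotb) <= spec.rotb_tol
        ]
        if not matched:
            continue
        owner = min(matched, key=lambda aid: (per_active[aid], aid))
        per_active[owner] += 1
        decoys.append(cand)
    shortfalls = {aid: n for aid, n in per_active.items() if n < spec.min_ratio}
    if shortfalls:
        warnings.warn(
            f"{len(shortfalls)} active(s) below the minimum decoy ratio "
            f"{spec.min_ratio}: {dict(list(shortfalls.items())[:5])}"
        )
    report = {
        "n_pool": len(pool),
        "n_decoys": len(decoys),
        "per_active": per_active,
        "shortfalls": shortfalls,
        "spec": {
            "mw_tol": spec.mw_tol,
            "clogp_tol": spec.clogp_tol,
            "hbd_tol": spec.hbd_tol,
            "hba_tol": spec.hba_tol,
            "rotb_tol": spec.rotb_tol,
            "max_tanimoto_to_actives": spec.max_tanimoto_to_actives,
            "min_ratio": spec.min_ratio,
            "max_ratio": spec.max_ratio,
            "fingerprint_kind": spec.fingerprint_kind,
        },
    }
    return decoys, report


def verify_decoys(
    decoys: Sequence[MoleculeRecord],
    actives: Sequence[MoleculeRecord],
    spec: DecoySpec | None = None,
) -> list[str]:
    """Independent post-hoc check: return ids of decoys violating any
    eligibility constraint (empty list == all constraints hold)."""
    spec = spec or DecoySpec()
    active_ids = {a.id for a in actives}
    active_fps = [fingerprint(a, spec.fingerprint_kind) for a in actives]
    bad = [d.id for d in decoys if d.id in active_ids or not decoy_eligible(d, actives, spec, active_fps)]
    return bad
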