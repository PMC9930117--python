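"""Similarity search and MAX/SUM data fusion.

A *ScoreTable* holds Tanimoto similarity for every (query, measure,
library compound) triple.  Three screening strategies reduce it to
rank-ordered lists:

* **method A** — no fusion: one ranking per (query active, measure).
* **method B** — similarity fusion: per query active, combine its scores
  across measures (MAX and SUM rules).
* **method C** — group fusion: per measure, combine scores across all
  query actives (MAX and SUM rules).

Ties are broken by lexicographic compound id after score, so rankings
are deterministic and permutation-stable.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from vsfuse.compound_io import MoleculeRecord
from vsfuse.fingerprints import MEASURES, fingerprint, tanimoto


@dataclass
class ScoreTable:
    """Complete (query, measure, library) -> similarity table in [0, 1]."""

    queries: list[str]
    measures: list[str]
    library_ids: list[str]
    scores: np.ndarray  # shape (n_queries, n_measures, n_library)

    def __post_init__(self) -> None:
        expected = (len(self.queries), len(self.measures), len(self.library_ids))
        if self.scores.shape != expected:
            raise ValueError(f"score array shape {self.scores.shape} != {expected}")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("similarity scores must lie in [0, 1]")

    def get(self, query: str, measure: str, library_id: str) -> float:
        return float(
            self.scores[
                self.queries.index(query),
                self.measures.index(measure),
                self.library_ids.index(library_id),
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["query", "measure", "library_id", "score"])
            for qi, q in enumerate(self.queries):
                for mi, m in enumerate(self.measures):
                    for li, lid in enumerate(self.library_ids):
                        w.writerow([q, m, lid, f"{self.scores[qi, mi, li]:.6f}"])


@dataclass
class FusedRanking:
    """Rank-ordered library with fused scores and provenance."""

    entries: list[tuple[str, float, int]]  # (library id, fused score, rank)
    rule: str  # "MAX", "SUM" or "RAW" (method A, no fusion)
    method: str  # "A", "B" or "C"
    query: str | None = None  # query id (methods A, B)
    measure: str | None = None  # measure name (methods A, C)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["library_id", "score", "rank", "rule", "method", "query", "measure"])
            for lid, score, rank in self.entries:
                w.writerow([lid, f"{score:.6f}", rank, self.rule, self.method,
                            self.query or "", self.measure or ""])


def _rank(ids: Sequence[str], scores: np.ndarray, rule: str, method: str,
          query: str | None = None, measure: str | None = None) -> FusedRanking:
    # sort by score descending, ties by lexicographic id ascending
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    entries = [(ids[i], float(scores[i]), rank + 1) for rank, i in enumerate(order)]
    return FusedRanking(entries=entries, rule=rule, method=method, query=query, measure=measure)


def similarity_search(
    queries: Sequence[MoleculeRecord],
    library: Sequence[MoleculeRecord],
    measures: Sequence[str] = MEASURES,
) -> ScoreTable:
    """Tanimoto similarity of every query against every library compound
    under every measure."""
    if not queries or not library or not measures:
        raise ValueError("queries, library and measures must all be nonempty")
    scores = np.zeros((len(queries), len(measures), len(library)))
    for mi, measure in enumerate(measures):
        qfps = [fingerprint(q, measure) for q in queries]
        lfps = [fingerprint(rec, measure) for rec in library]
        for qi, qfp in enumerate(qfps):
            for li, lfp in enumerate(lfps):
                scores[qi, mi, li] = tanimoto(qfp, lfp)
    return ScoreTable(
        queries=[q.id for q in queries],
        measures=list(measures),
        library_ids=[rec.id for rec in library],
        scores=scores,
    )


def fuse_max(scores: Sequence[float]) -> float:
    """MAX rule: the highest similarity a compound achieved."""
    if len(scores) == 0:
        raise ValueError("cannot fuse an empty score list")
    return float(max(scores))


def fuse_sum(scores: Sequence[float]) -> float:
    """SUM rule: the plain arithmetic sum of a compound's scores."""
    if len(scores) == 0:
        raise ValueError("cannot fuse an empty score list")
    return float(sum(scores))


def run_method_a(
    actives: Sequence[MoleculeRecord],
    library: Sequence[MoleculeRecord],
    measures: Sequence[str] = MEASURES,
    table: ScoreTable | None = None,
) -> list[FusedRanking]:
    """One raw-similarity ranking per (active, measure): no fusion.

    28 actives and 4 measures give the canonical 112 screening
    combinations.
    """
    table = table or similarity_search(actives, library, measures)
    rankings = []
    for qi, q in enumerate(table.queries):
        for mi, m in enumerate(table.measures):
            rankings.append(
                _rank(table.library_ids, table.scores[qi, mi], "RAW", "A", query=q, measure=m)
            )
    return rankings


def run_method_b(
    actives: Sequence[MoleculeRecord],
    library: Sequence[MoleculeRecord],
    measures: Sequence[str] = MEASURES,
    table: ScoreTable | None = None,
) -> list[FusedRanking]:
    """Similarity fusion: per active, fuse across measures with both
    rules -> 2 x n_actives rankings (56 for the canonical 28/4 setup)."""
    if len(measures) < 2:
        warnings.warn("similarity fusion over a single measure is degenerate")
    table = table or similarity_search(actives, library, measures)
    rankings = []
    for qi, q in enumerate(table.queries):
        per_compound = table.scores[qi]  # (n_measures, n_library)
        rankings.append(_rank(table.library_ids, per_compound.max(axis=0), "MAX", "B", query=q))
        rankings.append(_rank(table.library_ids, per_compound.sum(axis=0), "SUM", "B", query=q))
    return rankings


def run_method_c(
    actives: Sequence[MoleculeRecord],
    library: Sequence[MoleculeRecord],
    measures: Sequence[str] = MEASURES,
    table: ScoreTable | None = None,
) -> list[FusedRanking]:
    """Group fusion: per measure, fuse across all query actives with both
    rules -> 2 x n_measures rankings (8 for the canonical 28/4 setup)."""
    if len(actives) < 2 and table is None:
        warnings.warn("group fusion over a single query active is degenerate")
    table = table or similarity_search(actives, library, measures)
    if len(table.queries) < 2:
        warnings.warn("group fusion over a single query active is degenerate")
    rankings = []
    for mi, m in enumerate(table.measures):
        per_compound = table.scores[:, mi]  # (n_queries, n_library)
        rankings.append(_rank(table.library_ids, per_compound.max(axis=0), "MAX", "C", measure=m))
        rankings.append(_rank(table.library_ids, per_compound.sum(axis=0), "SUM", "C", measure=m))
    return rankings
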