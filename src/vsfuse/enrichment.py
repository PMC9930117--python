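"""Early-enrichment metrics for labeled rankings.

Given an ordered list of compounds labeled active/decoy, computes the
enrichment factor EF@x%, sensitivity and specificity at a cut, the ROC
curve with its AUC (Mann–Whitney form: the probability that a randomly
chosen active outranks a randomly chosen decoy, ties counted one half),
and the BEDROC early-recognition score.

BEDROC follows the Truchon–Bailey construction: the robust initial
enhancement RIE is the mean exponential weight sum(exp(-alpha * r_i/N))
over active ranks r_i, normalized by its random expectation, then mapped
onto [0, 1] between the best- and worst-case orderings.  At the default
alpha = 20, 80% of the score weight falls in the top 8% of the ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass
class LabeledRanking:
    """An ordered compound list with active/decoy labels.

    ``entries[i]`` is (compound id, label) for rank i+1; rank 1 is the
    best-scored compound.
    """

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        bad = {lab for _, lab in self.entries} - {"active", "decoy"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def N_act(self) -> int:
        return sum(1 for _, lab in self.entries if lab == "active")

    @property
    def active_ranks(self) -> list[int]:
        """1-based ranks of the actives."""
        return [i + 1 for i, (_, lab) in enumerate(self.entries) if lab == "active"]

    @classmethod
    def from_labels(cls, labels: Sequence[str], ids: Sequence[str] | None = None) -> "LabeledRanking":
        if ids is None:
            ids = [f"CPD{i + 1}" for i in range(len(labels))]
        return cls(entries=list(zip(ids, labels)))


@dataclass
class MetricsReport:
    """Enrichment metrics computed from one labeled ranking."""

    ef: dict[float, float] = field(default_factory=dict)
    auc: float | None = None
    bedroc: float | None = None
    alpha: float = 20.0
    se: float | None = None
    sp: float | None = None

    def to_dict(self) -> dict:
        return {
            "ef": {str(k): v for k, v in self.ef.items()},
            "auc": self.auc,
            "bedroc": self.bedroc,
            "alpha": self.alpha,
            "se": self.se,
            "sp": self.sp,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def top_count(N: int, top_fraction: float) -> int:
    """Number of compounds in the top x% cut: round half away from zero,
    minimum 1."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    return max(1, math.floor(top_fraction * N + 0.5))


def enrichment_factor(ranking: LabeledRanking, top_fraction: float) -> float:
    """EF@x%: the active rate in the top x% over the database-wide rate.

    EF = (hits_in_top / n_top) / (N_act / N) with n_top rounded half
    away from zero (minimum 1).
    """
    N, N_act = ranking.N, ranking.N_act
    if N_act == 0:
        raise ValueError("ranking contains no actives")
    n_top = top_count(N, top_fraction)
    hits = sum(1 for _, lab in ranking.entries[:n_top] if lab == "active")
    return (hits / n_top) / (N_act / N)


def sensitivity(tp: int, fn: int) -> float:
    """True-positive rate: fraction of all actives that are retrieved."""
    if tp + fn == 0:
        raise ValueError("no actives (tp + fn == 0)")
    return tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    """True-negative rate: fraction of all decoys that are discarded."""
    if tn + fp == 0:
        raise ValueError("no decoys (tn + fp == 0)")
    return tn / (tn + fp)


def roc_auc(ranking: LabeledRanking) -> tuple[list[tuple[float, float]], float]:
    """Stepwise ROC curve over all cut positions, and its AUC.

    The AUC equals the Mann–Whitney statistic: the fraction of
    (active, decoy) pairs in which the active is ranked higher.
    """
    N, N_act = ranking.N, ranking.N_act
    n_dec = N - N_act
    if N_act == 0 or n_dec == 0:
        raise ValueError("ROC needs both actives and decoys")
    points = [(0.0, 0.0)]
    tp = fp = 0
    area = 0.0
    for _, lab in ranking.entries:
        if lab == "active":
            tp += 1
        else:
            fp += 1
            area += tp  # each decoy passed contributes the actives above it
        points.append((fp / n_dec, tp / N_act))
    return points, area / (N_act * n_dec)


def bedroc(ranking: LabeledRanking, alpha: float = 20.0) -> float:
    """BEDROC early-recognition score in [0, 1].

    RIE = (sum_i exp(-alpha * r_i / N)) / (Ra * N * (1 - e^-alpha) /
    (N * (e^(alpha/N) - 1))) with Ra = N_act / N, then min/max-normalized.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    N, N_act = ranking.N, ranking.N_act
    n_dec = N - N_act
    if N_act == 0 or n_dec == 0:
        raise ValueError("BEDROC needs both actives and decoys")
    ra = N_act / N
    s = sum(math.exp(-alpha * r / N) for r in ranking.active_ranks)
    rand_sum = N_act * (1 - math.exp(-alpha)) / (N * (math.exp(alpha / N) - 1))
    rie = s / rand_sum
    num = ra * math.sinh(alpha / 2)
    den = math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    return rie * num / den + 1 / (1 - math.exp(alpha * (1 - ra)))


def bedroc_weight_fraction(alpha: float, top_fraction: float) -> float:
    """Fraction of the total exponential score weight contained in the top
    *top_fraction* of an (idealized, continuous) ranking:
    (1 - e^(-alpha * x)) / (1 - e^(-alpha)).

    At alpha = 20 and x = 0.08 this is 0.80: four-fifths of the BEDROC
    score comes from the top 8% of the database.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    return (1 - math.exp(-alpha * top_fraction)) / (1 - math.exp(-alpha))


def compute_metrics(
    ranking: LabeledRanking,
    ef_fractions: Sequence[float] = (0.01, 0.05, 0.10),
    alpha: float = 20.0,
    cut_fraction: float | None = None,
) -> MetricsReport:
    """All metrics in one pass; Se/Sp are evaluated at *cut_fraction*
    (defaults to the smallest EF fraction)."""
    _, auc = roc_auc(ranking)
    report = MetricsReport(
        ef={x: enrichment_factor(ranking, x) for x in ef_fractions},
        auc=auc,
        bedroc=bedroc(ranking, alpha),
        alpha=alpha,
    )
    cut = cut_fraction if cut_fraction is not None else min(ef_fractions, default=None)
    if cut is not None:
        n_top = top_count(ranking.N, cut)
        tp = sum(1 for _, lab in ranking.entries[:n_top] if lab == "active")
        fp = n_top - tp
        fn = ranking.N_act - tp
        tn = (ranking.N - ranking.N_act) - fp
        report.se = sensitivity(tp, fn)
        report.sp = specificity(tn, fp)
    return report


def labeled_from_ranking(ids: Sequence[str], labels: dict[str, str]) -> LabeledRanking:
    """Attach labels (id -> 'active'/'decoy') to an ordered id list."""
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"{len(missing)} compounds without labels, e.g. {missing[:3]}")
    return LabeledRanking(entries=[(i, labels[i]) for i in ids])
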