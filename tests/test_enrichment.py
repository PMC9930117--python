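"""Enrichment metrics: EF, Se/Sp, ROC/AUC, BEDROC against independent oracles."""

import itertools
import math
import random

import pytest

from vsfuse import (
    LabeledRanking,
    bedroc,
    bedroc_weight_fraction,
    compute_metrics,
    enrichment_factor,
    roc_auc,
    sensitivity,
    specificity,
)
from vsfuse.enrichment import top_count


def planted(N, N_act, hits_in_top, n_top):
    """Ranking with a fixed number of actives inside the top block and the
    remaining actives at the very bottom."""
    labels = ["decoy"] * N
    for i in range(hits_in_top):
        labels[i] = "active"
    for j in range(N_act - hits_in_top):
        labels[N - 1 - j] = "active"
    return LabeledRanking.from_labels(labels)


def brute_force_auc(ranking):
    """Mann–Whitney pair-counting oracle."""
    act = ranking.active_ranks
    dec = [i + 1 for i, (_, lab) in enumerate(ranking.entries) if lab == "decoy"]
    wins = sum(1 for a in act for d in dec if a < d)
    return wins / (len(act) * len(dec))


def brute_force_bedroc(ranking, alpha):
    """One-line exponential-sum oracle with explicit min/max normalization."""
    N, n = ranking.N, ranking.N_act
    s = sum(math.exp(-alpha * r / N) for r in ranking.active_ranks)
    smin = sum(math.exp(-alpha * r / N) for r in range(N - n + 1, N + 1))
    smax = sum(math.exp(-alpha * r / N) for r in range(1, n + 1))
    return (s - smin) / (smax - smin)


class TestEnrichmentFactor:
    def test_top_count_rounds_half_away_from_zero(self):
        assert top_count(1198, 0.01) == 12
        assert top_count(1198, 0.05) == 60
        assert top_count(1198, 0.10) == 120
        assert top_count(10, 0.01) == 1  # minimum of one compound

    @pytest.mark.parametrize(
        "hits,frac,expected",
        [
            (12, 0.01, 42.8),
            (21, 0.05, 15.0),
            (22, 0.10, 7.8),
            (6, 0.01, 21.4),
            (10, 0.05, 7.1),
            (28, 0.10, 10.0),
            (13, 0.10, 4.6),
        ],
    )
    def test_worked_examples_1198_28(self, hits, frac, expected):
        r = planted(1198, 28, hits, top_count(1198, frac))
        assert round(enrichment_factor(r, frac), 1) == expected

    def test_all_active_database_gives_unity(self):
        r = LabeledRanking.from_labels(["active"] * 20)
        for frac in (0.1, 0.5, 1.0):
            assert enrichment_factor(r, frac) == 1.0

    def test_no_actives_fatal(self):
        r = LabeledRanking.from_labels(["decoy"] * 5)
        with pytest.raises(ValueError):
            enrichment_factor(r, 0.2)

    def test_upper_bounds(self):
        rng = random.Random(4)
        for _ in range(50):
            N = rng.randint(20, 200)
            N_act = rng.randint(1, N - 1)
            labels = ["active"] * N_act + ["decoy"] * (N - N_act)
            rng.shuffle(labels)
            r = LabeledRanking.from_labels(labels)
            x = rng.choice([0.01, 0.05, 0.1, 0.5])
            n_top = top_count(N, x)
            ef = enrichment_factor(r, x)
            assert 0 <= ef <= min(N / n_top, N / N_act) + 1e-9

    def test_uniform_random_ranking_averages_one(self):
        rng = random.Random(5)
        total = 0.0
        n_seeds = 200
        for _ in range(n_seeds):
            labels = ["active"] * 30 + ["decoy"] * 270
            rng.shuffle(labels)
            total += enrichment_factor(LabeledRanking.from_labels(labels), 0.10)
        assert total / n_seeds == pytest.approx(1.0, abs=0.1)


class TestSeSp:
    @pytest.mark.parametrize("tp,fn,expected", [(28, 0, 1.0), (0, 28, 0.0), (12, 16, 12 / 28)])
    def test_sensitivity(self, tp, fn, expected):
        assert sensitivity(tp, fn) == pytest.approx(expected)

    @pytest.mark.parametrize("tn,fp,expected", [(1170, 0, 1.0), (0, 1170, 0.0), (1080, 90, 1080 / 1170)])
    def test_specificity(self, tn, fp, expected):
        assert specificity(tn, fp) == pytest.approx(expected)

    def test_degenerate_fatal(self):
        with pytest.raises(ValueError):
            sensitivity(0, 0)
        with pytest.raises(ValueError):
            specificity(0, 0)


class TestRocAuc:
    def test_perfect_ranking(self):
        r = planted(100, 10, 10, 10)
        _, auc = roc_auc(r)
        assert auc == 1.0

    def test_toy_ranking_pair_count(self):
        # actives at ranks 1, 3, 6 beat decoys at 2, 4, 5 in 5 of 9 pairs
        r = LabeledRanking.from_labels(["active", "decoy", "active", "decoy", "decoy", "active"])
        _, auc = roc_auc(r)
        assert auc == pytest.approx(5 / 9)

    def test_random_labels_near_half(self):
        rng = random.Random(6)
        aucs = []
        for _ in range(30):
            labels = ["active"] * 200 + ["decoy"] * 1800
            rng.shuffle(labels)
            aucs.append(roc_auc(LabeledRanking.from_labels(labels))[1])
        assert sum(aucs) / len(aucs) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_pair_counting(self):
        rng = random.Random(7)
        for _ in range(50):
            N = rng.randint(4, 50)
            N_act = rng.randint(1, N - 1)
            labels = ["active"] * N_act + ["decoy"] * (N - N_act)
            rng.shuffle(labels)
            r = LabeledRanking.from_labels(labels)
            _, auc = roc_auc(r)
            assert auc == pytest.approx(brute_force_auc(r), abs=1e-12)

    def test_curve_endpoints(self):
        r = planted(50, 5, 3, 10)
        points, _ = roc_auc(r)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_one_class_fatal(self):
        with pytest.raises(ValueError):
            roc_auc(LabeledRanking.from_labels(["active"] * 5))


class TestBedroc:
    def test_perfect_early_recognition_near_one(self):
        r = planted(10000, 50, 50, 50)
        assert bedroc(r, 20.0) == pytest.approx(1.0, abs=0.01)

    def test_weight_fraction_top_8_percent(self):
        assert round(bedroc_weight_fraction(20.0, 0.08), 2) == 0.80

    def test_toy_ranking_matches_exponential_sum_oracle(self):
        labels = ["decoy"] * 20
        for r_ in (1, 5, 17):
            labels[r_ - 1] = "active"
        r = LabeledRanking.from_labels(labels)
        assert bedroc(r, 20.0) == pytest.approx(brute_force_bedroc(r, 20.0), abs=1e-6)

    def test_random_rankings_match_oracle(self):
        rng = random.Random(8)
        for _ in range(30):
            N = rng.randint(10, 120)
            N_act = rng.randint(1, N - 1)
            labels = ["active"] * N_act + ["decoy"] * (N - N_act)
            rng.shuffle(labels)
            r = LabeledRanking.from_labels(labels)
            for alpha in (5.0, 20.0, 80.5):
                assert bedroc(r, alpha) == pytest.approx(brute_force_bedroc(r, alpha), abs=1e-6)

    def test_matches_reference_implementation(self):
        # independent cross-check against the RDKit scoring module
        from rdkit.ML.Scoring import Scoring

        rng = random.Random(9)
        for _ in range(10):
            labels = ["active"] * 15 + ["decoy"] * 185
            rng.shuffle(labels)
            r = LabeledRanking.from_labels(labels)
            scores = [[1.0 - i, 1 if lab == "active" else 0] for i, (_, lab) in enumerate(r.entries)]
            assert bedroc(r, 20.0) == pytest.approx(Scoring.CalcBEDROC(scores, 1, 20.0), abs=1e-9)

    def test_small_alpha_approaches_auc(self):
        rng = random.Random(10)
        labels = ["active"] * 20 + ["decoy"] * 180
        rng.shuffle(labels)
        r = LabeledRanking.from_labels(labels)
        _, auc = roc_auc(r)
        assert bedroc(r, 0.05) == pytest.approx(auc, abs=0.02)

    def test_invalid_alpha_fatal(self):
        r = planted(10, 2, 2, 2)
        with pytest.raises(ValueError):
            bedroc(r, 0.0)

    def test_range(self):
        rng = random.Random(11)
        for _ in range(20):
            labels = ["active"] * 5 + ["decoy"] * 45
            rng.shuffle(labels)
            b = bedroc(LabeledRanking.from_labels(labels), 20.0)
            assert 0.0 <= b <= 1.0


class TestMonotonicity:
    def test_promoting_an_active_never_decreases_metrics(self):
        rng = random.Random(12)
        for _ in range(20):
            labels = ["active"] * 10 + ["decoy"] * 90
            rng.shuffle(labels)
            r = LabeledRanking.from_labels(labels)
            # swap a random active upward past the decoy above it
            act_positions = [i for i, (_, lab) in enumerate(r.entries) if lab == "active" and i > 0
                             and r.entries[i - 1][1] == "decoy"]
            if not act_positions:
                continue
            i = rng.choice(act_positions)
            swapped = list(labels)
            swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
            r2 = LabeledRanking.from_labels(swapped)
            assert enrichment_factor(r2, 0.1) >= enrichment_factor(r, 0.1)
            assert roc_auc(r2)[1] >= roc_auc(r)[1]
            assert bedroc(r2, 20.0) >= bedroc(r, 20.0)


class TestReport:
    def test_compute_metrics_aggregates(self):
        r = planted(1198, 28, 12, 12)
        report = compute_metrics(r)
        assert round(report.ef[0.01], 1) == 42.8
        assert report.se == pytest.approx(12 / 28)
        assert report.sp == pytest.approx(1170 / 1170)
        assert 0 <= report.auc <= 1 and 0 <= report.bedroc <= 1
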