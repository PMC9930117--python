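"""Pharmacophore perception, conformers and assignment matching."""

import itertools

import numpy as np
import pytest

from vsfuse import (
    Hypothesis,
    MoleculeRecord,
    PharmacophoreFeature,
    generate_conformers,
    hypothesis_from_reference,
    match,
    perceive_features,
    screen_and_validate,
)
from vsfuse.pharmacophore import _kabsch_residuals, match_conformers
from vsfuse.synthetic import example_hypothesis, make_planted_pharmacophore

from conftest import record

REFERENCE_SMILES = "O=C(Nc1ccc(CCC(C)C)cc1)c1ccc(C(=O)O)cc1"


def brute_force_match(hypothesis, perceived):
    """Unpruned exhaustive assignment search (independent oracle)."""
    hfeats = hypothesis.features
    hpos = np.array([f.xyz for f in hfeats])
    candidates = [[i for i, (k, _) in enumerate(perceived) if k == f.kind] for f in hfeats]
    best = None
    for combo in itertools.product(*candidates):
        if len(set(combo)) != len(combo):
            continue
        P = np.array([np.asarray(perceived[i][1], dtype=float) for i in combo])
        res = _kabsch_residuals(P, hpos)
        if all(r <= f.tolerance + 1e-9 for r, f in zip(res, hfeats)):
            fit = float(np.sqrt(np.mean(res**2)))
            if best is None or fit < best:
                best = fit
    return best is not None, best


@pytest.fixture(scope="module")
def reference():
    rec = record(REFERENCE_SMILES, "ref")
    confs = generate_conformers(rec, seed=5)
    feats = perceive_features(rec, confs.coords[0])
    return rec, confs, feats


class TestPerception:
    def test_benzene_single_ring_feature_at_centroid(self):
        rec = record("c1ccccc1")
        confs = generate_conformers(rec, seed=1)
        feats = perceive_features(rec, confs.coords[0])
        assert [k for k, _ in feats] == ["R"]
        centroid = confs.coords[0].mean(axis=0)
        assert np.allclose(feats[0][1], centroid, atol=1e-6)

    def test_ethanol_donor_and_acceptor_on_oxygen(self):
        rec = record("CCO")
        confs = generate_conformers(rec, seed=1)
        feats = perceive_features(rec, confs.coords[0])
        kinds = sorted(k for k, _ in feats)
        assert kinds == ["A", "D"]
        positions = np.array([p for _, p in feats])
        assert np.allclose(positions[0], positions[1])  # both on the O

    def test_acetate_single_negative_ionizable(self):
        rec = record("CC(=O)[O-]")
        confs = generate_conformers(rec, seed=1)
        feats = perceive_features(rec, confs.coords[0])
        assert sum(1 for k, _ in feats if k == "N") == 1

    def test_wrong_coordinate_shape_fatal(self):
        with pytest.raises(ValueError):
            perceive_features(record("CCO"), np.zeros((5, 3)))


class TestConformers:
    def test_rigid_benzene_single_conformer(self):
        assert len(generate_conformers(record("c1ccccc1"), seed=2).coords) == 1

    def test_butane_has_multiple_rotamers(self):
        confs = generate_conformers(record("CCCC"), energy_window=20.0, seed=2)
        assert len(confs.coords) >= 2  # anti + gauche minima

    def test_same_seed_identical_coordinates(self):
        a = generate_conformers(record("CCCCO"), seed=7)
        b = generate_conformers(record("CCCCO"), seed=7)
        assert len(a.coords) == len(b.coords)
        for ca, cb in zip(a.coords, b.coords):
            assert np.allclose(ca, cb)

    def test_energy_window_and_cap_respected(self):
        confs = generate_conformers(record("CCCCCCO"), max_conformers=5, energy_window=3.0, seed=3)
        assert len(confs.coords) <= 5
        assert all(0 <= e <= 3.0 for e in confs.energies)


class TestHypothesis:
    def test_feature_count_bounds(self):
        f = PharmacophoreFeature("A", (0, 0, 0))
        with pytest.raises(ValueError):
            Hypothesis(name="too-few", features=(f,) * 3)

    def test_min_interfeature_distance_enforced(self):
        feats = tuple(
            PharmacophoreFeature("A", (i * 1.0, 0, 0)) for i in range(4)
        )
        with pytest.raises(ValueError, match="apart"):
            Hypothesis(name="crowded", features=feats)

    def test_json_round_trip(self, tmp_path):
        h = example_hypothesis()
        p = tmp_path / "h.json"
        h.to_json(p)
        again = Hypothesis.from_json(p)
        assert again.composition == h.composition
        assert all(
            np.allclose(a.xyz, b.xyz) and a.tolerance == b.tolerance
            for a, b in zip(again.features, h.features)
        )

    def test_from_reference_self_match_fit_zero(self, reference):
        _, _, feats = reference
        h = hypothesis_from_reference(feats, name="self")
        hit, _, fit = match(h, feats)
        assert hit and fit == pytest.approx(0.0, abs=1e-9)


class TestMatching:
    def test_kind_infeasibility_is_miss(self):
        # hypothesis demands an acceptor; pure hydrocarbon has none
        h = example_hypothesis()
        rec = record("CCCCCCCC")
        confs = generate_conformers(rec, seed=4)
        feats = perceive_features(rec, confs.coords[0])
        hit, assignment, fit = match(h, feats)
        assert not hit and assignment is None and fit is None

    def test_planted_toy_hit_and_miss(self):
        rng = np.random.default_rng(13)
        h = example_hypothesis(tolerance=1.0)
        hpos = np.array([f.xyz for f in h.features])
        kinds = [f.kind for f in h.features]
        near = [(k, hpos[i] + rng.normal(scale=0.3 / np.sqrt(3), size=3)) for i, k in enumerate(kinds)]
        far = [(k, hpos[i] + rng.uniform(3, 5, size=3)) for i, k in enumerate(kinds)]
        assert match(h, near)[0]
        assert match(h, near)[0] == brute_force_match(h, near)[0]
        assert not match(h, far)[0]
        assert match(h, far)[0] == brute_force_match(h, far)[0]

    def test_agrees_with_unpruned_oracle(self, reference):
        rec, confs, feats = reference
        assert len(feats) <= 9
        h = hypothesis_from_reference(feats, name="self")
        for conf in confs.coords[:6]:
            pf = perceive_features(rec, conf)
            mine = match(h, pf)
            oracle = brute_force_match(h, pf)
            assert mine[0] == oracle[0]
            if mine[0]:
                assert mine[2] == pytest.approx(oracle[1], abs=1e-9)

    def test_rigid_motion_invariance(self, reference):
        rec, confs, feats = reference
        h = hypothesis_from_reference(feats, name="self")
        rng = np.random.default_rng(14)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = [(k, p @ R.T + np.array([5.0, -3.0, 2.0])) for k, p in feats]
        hit, _, fit = match(h, moved)
        assert hit and fit == pytest.approx(0.0, abs=1e-6)

    def test_tightening_tolerance_never_creates_hits(self):
        rng = np.random.default_rng(15)
        h_loose = example_hypothesis(tolerance=1.5)
        h_tight = example_hypothesis(tolerance=0.5)
        hpos = np.array([f.xyz for f in h_loose.features])
        kinds = [f.kind for f in h_loose.features]
        for _ in range(20):
            feats = [(k, hpos[i] + rng.normal(scale=0.6, size=3)) for i, k in enumerate(kinds)]
            if match(h_tight, feats)[0]:
                assert match(h_loose, feats)[0]


class TestScreening:
    def test_planted_actives_separate_from_decoys(self):
        h = example_hypothesis()
        for seed in range(3):
            data = make_planted_pharmacophore(15, 45, h, noise_sd=0.3, seed=seed)
            report, rows = screen_and_validate(h, data)
            assert report.se >= 0.9 and report.sp >= 0.9

    def test_all_miss_screen(self):
        h = example_hypothesis()
        data = make_planted_pharmacophore(5, 5, h, noise_sd=50.0, seed=1)
        # huge noise: actives cannot satisfy the geometry either
        report, rows = screen_and_validate(h, data)
        if not any(r["hit"] for r in rows):
            assert report.se == 0.0 and report.sp == 1.0

    def test_reference_molecule_counts_as_true_positive(self, reference):
        rec, confs, feats = reference
        h = hypothesis_from_reference(feats, name="self")
        report, rows = screen_and_validate(h, [(rec.id, "active", rec)], max_conformers=10, seed=5)
        assert rows[0]["hit"] and report.se == 1.0

    def test_hits_ranked_by_fit_before_misses(self):
        h = example_hypothesis()
        data = make_planted_pharmacophore(8, 8, h, noise_sd=0.4, seed=2)
        _, rows = screen_and_validate(h, data)
        fits = [r["fit"] for r in rows if r["hit"]]
        assert fits == sorted(fits)
        tail = [r["hit"] for r in rows]
        assert tail == sorted(tail, reverse=True)
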