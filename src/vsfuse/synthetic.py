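"""Seeded, download-free synthetic inputs for the screening pipeline.

Emulates the statistical structure of a ligand-enrichment validation
set: a small series of mutually similar "actives" decorated from a
shared scaffold, a larger pool of property-matched but topologically
dissimilar "decoys", planted labeled rankings with known enrichment, and
planted pharmacophore geometries.  The default benchmark mirrors the
canonical validation-set shape of 28 actives and 1170 decoys (N = 1198)
screened with four fingerprint measures, so screening methods A/B/C
emit 112, 56 and 8 rankings.

Every generator is a pure function of its spec and seed, and every
emitted set is re-verified against its own constraints by direct
computation (no trust in generator bookkeeping).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from vsfuse.compound_io import MoleculeRecord, compute_properties
from vsfuse.dataset_prep import DecoySpec, decoy_eligible
from vsfuse.enrichment import LabeledRanking
from vsfuse.fingerprints import fingerprint, tanimoto
from vsfuse.pharmacophore import Hypothesis, PharmacophoreFeature

#: Shared scaffold of the synthetic active series (an N-phenylbenzamide,
#: a common small-molecule enzyme-inhibitor chemotype).
ACTIVE_SCAFFOLD = "O=C(Nc1ccccc1)c1ccccc1"

#: Fixed substituent vocabulary for decoration (keeps chemistry valid).
SUBSTITUENTS = ("C", "F", "Cl", "O", "OC", "N", "C(=O)O")

#: Topologically unrelated scaffolds used for decoys, sized so that
#: decorated variants fall inside the actives' property windows.
DECOY_SCAFFOLDS = (
    "c1ccc(OCC2CCCCC2)cc1",
    "c1ccc(CN2CCOCC2)cc1",
    "c1ccc(-c2ccncc2)cc1",
    "c1ccc(S(=O)(=O)N2CCCC2)cc1",
    "c1ccc(CCc2ccco2)cc1",
    "O=C(OCc1ccccc1)C1CCC1",
    "c1ccc(COc2ccccn2)cc1",
    "C1CCC(CC2CCNCC2)CC1",
    "c1ccc(N2CCN(C)CC2)cc1",
    "c1ccc(CC2CCCN2C)cc1",
    "c1ccc(OC2CCOC2)cc1",
    "c1ccc(CSc2ncccn2)cc1",
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Conditions of the synthetic enrichment benchmark."""

    n_actives: int = 28
    decoy_ratio: float = 36.0  # decoys per active when n_decoys is unset
    n_decoys: int | None = None  # explicit decoy count (overrides the ratio)
    scaffold: str = ACTIVE_SCAFFOLD
    similarity_floor: float = 0.35  # min active-active radial Tanimoto
    similarity_ceiling: float = 0.30  # max active-decoy radial Tanimoto
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys is None and not 4 <= self.decoy_ratio <= 36:
            raise ValueError("decoy_ratio must lie in [4, 36]")
        if not 0 < self.similarity_ceiling < self.similarity_floor <= 1:
            raise ValueError("need 0 < ceiling < floor <= 1")
        if Chem.MolFromSmiles(self.scaffold) is None:
            raise ValueError(f"invalid scaffold SMILES {self.scaffold!r}")

    @property
    def total_decoys(self) -> int:
        if self.n_decoys is not None:
            return self.n_decoys
        return int(round(self.decoy_ratio * self.n_actives))


@dataclass(frozen=True)
class PlantedRanking:
    """Spec for a labeled ranking with a known placement model."""

    N: int
    N_act: int
    placement: str = "top-block"  # top-block | uniform | exponential
    lam: float = 10.0  # decay rate for the exponential model
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.N_act < self.N:
            raise ValueError("need 0 < N_act < N")
        if self.placement not in ("top-block", "uniform", "exponential"):
            raise ValueError(f"unknown placement {self.placement!r}")


def _attach(mol: Chem.Mol, atom_idx: int, substituent: str) -> Chem.Mol | None:
    sub = Chem.MolFromSmiles(substituent)
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _substitutable_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _decorate(scaffold: Chem.Mol, rng: np.random.Generator, max_subs: int = 3) -> str | None:
    mol = Chem.Mol(scaffold)
    n_subs = int(rng.integers(1, max_subs + 1))
    for _ in range(n_subs):
        positions = _substitutable_positions(mol)
        if not positions:
            break
        pos = int(rng.choice(positions))
        sub = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
        grown = _attach(mol, pos, sub)
        if grown is None:
            continue
        mol = grown
    return Chem.MolToSmiles(mol)


def make_active_series(spec: BenchmarkSpec) -> tuple[list[MoleculeRecord], dict[str, float]]:
    """Decorated scaffold variants with pairwise radial Tanimoto at or
    above the similarity floor, plus synthetic potencies (log-uniform
    IC50 in uM).

    Returns ``(records, activities)``.  Raises if the floor cannot be
    satisfied within a bounded number of attempts.
    """
    scaffold = Chem.MolFromSmiles(spec.scaffold)
    rng = np.random.default_rng(spec.seed)
    records = [compute_properties(MoleculeRecord(id="ACT001", structure=Chem.MolToSmiles(scaffold)))]
    fps = [fingerprint(records[0], "radial")]
    seen = {records[0].structure}
    attempts = 0
    max_attempts = 400 * spec.n_actives
    while len(records) < spec.n_actives:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not build {spec.n_actives} actives with floor "
                f"{spec.similarity_floor} after {attempts} attempts "
                f"(got {len(records)})"
            )
        smi = _decorate(scaffold, rng)
        if smi is None or smi in seen:
            continue
        rec = compute_properties(MoleculeRecord(id=f"ACT{len(records) + 1:03d}", structure=smi))
        fp = fingerprint(rec, "radial")
        if any(tanimoto(fp, other) < spec.similarity_floor for other in fps):
            continue
        records.append(rec)
        fps.append(fp)
        seen.add(smi)
    activities = {
        r.id: float(10 ** rng.uniform(math.log10(0.005), math.log10(20.0)))
        for r in records
    }
    return records, activities


def make_decoy_pool(spec: BenchmarkSpec, actives: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Property-matched, topologically dissimilar decoys.

    Candidates are decorated variants of unrelated scaffolds, accepted
    only when they pass the full decoy-eligibility check (property
    deltas within the default tolerances of some active and radial
    Tanimoto to every active at or below the spec ceiling).
    """
    rng = np.random.default_rng(spec.seed + 1)
    dspec = DecoySpec(max_tanimoto_to_actives=spec.similarity_ceiling)
    active_fps = [fingerprint(a, dspec.fingerprint_kind) for a in actives]
    scaffolds = [Chem.MolFromSmiles(s) for s in DECOY_SCAFFOLDS]
    target = spec.total_decoys
    seen = {a.structure for a in actives}
    decoys: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 60 * target + 1000
    while len(decoys) < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not build {target} eligible decoys after {attempts} "
                f"attempts (got {len(decoys)})"
            )
        scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
        if rng.random() < 0.15:  # some decoys are bare scaffolds
            smi = Chem.MolToSmiles(scaffold)
        else:
            smi = _decorate(scaffold, rng)
        if smi is None or smi in seen:
            continue
        rec = compute_properties(MoleculeRecord(id=f"DEC{len(decoys) + 1:04d}", structure=smi))
        if not decoy_eligible(rec, actives, dspec, active_fps):
            continue
        decoys.append(rec)
        seen.add(smi)
    return decoys


def default_benchmark(seed: int = 0) -> tuple[list[MoleculeRecord], list[MoleculeRecord], dict[str, float]]:
    """The canonical-shape benchmark: 28 actives + 1170 decoys (N = 1198).

    Returns ``(actives, decoys, activities)``.
    """
    spec = BenchmarkSpec(n_actives=28, n_decoys=1170, seed=seed)
    actives, activities = make_active_series(spec)
    decoys = make_decoy_pool(spec, actives)
    return actives, decoys, activities


def make_planted_ranking(p: PlantedRanking) -> LabeledRanking:
    """Labeled ranking with actives placed by the chosen model.

    * ``top-block`` — actives occupy ranks 1..N_act, so
      EF(x) = min(N_act, n_top)/n_top * N/N_act and AUC = 1.
    * ``uniform`` — active positions uniform at random: E[EF] = 1.
    * ``exponential`` — active positions drawn without replacement with
      weight exp(-lam * rank/N): tunable early enrichment.
    """
    rng = np.random.default_rng(p.seed)
    labels = ["decoy"] * p.N
    if p.placement == "top-block":
        positions = np.arange(p.N_act)
    elif p.placement == "uniform":
        positions = rng.choice(p.N, size=p.N_act, replace=False)
    else:
        w = np.exp(-p.lam * np.arange(p.N) / p.N)
        positions = rng.choice(p.N, size=p.N_act, replace=False, p=w / w.sum())
    for pos in positions:
        labels[int(pos)] = "active"
    return LabeledRanking.from_labels(labels)


def make_planted_pharmacophore(
    n_active: int,
    n_decoy: int,
    hypothesis: Hypothesis,
    noise_sd: float = 0.3,
    seed: int = 0,
    n_conformers: int = 1,
) -> list[tuple[str, str, list]]:
    """Labeled per-conformer feature sets with planted geometry.

    Actives carry the hypothesis feature kinds at the hypothesis
    positions plus isotropic Gaussian noise (*noise_sd* Angstrom), under
    a random rigid motion; decoys carry the same kinds at scrambled
    positions inside a box twice the hypothesis extent.  Output items
    are ``(id, label, [feature list per conformer])``, directly
    screenable.
    """
    rng = np.random.default_rng(seed)
    hpos = np.array([f.xyz for f in hypothesis.features])
    kinds = [f.kind for f in hypothesis.features]
    center = hpos.mean(axis=0)
    extent = float(np.max(np.abs(hpos - center))) + 1.0
    out: list[tuple[str, str, list]] = []

    def random_rotation() -> np.ndarray:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    for i in range(n_active):
        confs = []
        for _ in range(n_conformers):
            R, t = random_rotation(), rng.normal(scale=5.0, size=3)
            noisy = (hpos - center) @ R.T + t + rng.normal(scale=noise_sd, size=hpos.shape)
            confs.append([(k, noisy[j]) for j, k in enumerate(kinds)])
        out.append((f"PACT{i + 1:03d}", "active", confs))
    for i in range(n_decoy):
        confs = []
        for _ in range(n_conformers):
            pos = rng.uniform(-2 * extent, 2 * extent, size=hpos.shape)
            confs.append([(k, pos[j]) for j, k in enumerate(kinds)])
        out.append((f"PDEC{i + 1:03d}", "decoy", confs))
    return out


def example_hypothesis(name: str = "planted", tolerance: float = 1.6) -> Hypothesis:
    """A four-feature RRAA-composition hypothesis with synthetic
    coordinates (illustrative geometry, not a reproduction of any fitted
    model), spaced above the minimum interfeature distance."""
    feats = (
        PharmacophoreFeature("R", (0.0, 0.0, 0.0), tolerance),
        PharmacophoreFeature("R", (5.0, 0.5, 0.0), tolerance),
        PharmacophoreFeature("A", (2.5, 3.5, 1.0), tolerance),
        PharmacophoreFeature("A", (7.5, 3.0, -1.0), tolerance),
    )
    return Hypothesis(name=name, features=feats)
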