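"""Simplified 3D pharmacophore screening.

A pharmacophore hypothesis is a set of typed interaction features —
donor (D), acceptor (A), hydrophobic (H), aromatic ring (R), positive
(P) and negative (N) ionizable — each with a 3D position and a tolerance
sphere.  A conformer matches when some injective, kind-compatible
assignment of hypothesis features to perceived molecular features exists
such that, after least-squares rigid superposition, every assigned
feature falls inside its tolerance sphere.  The assignment search is
exhaustive with pairwise-distance pruning; the fit value is the RMS of
residual distances and is used only for ranking hits.

Conformer ensembles come from seeded distance-geometry embedding (ETKDG)
followed by MMFF94 minimization, capped by count and by an energy window
above the lowest-energy conformer (255 conformers / 20 kcal/mol by
default).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from vsfuse.compound_io import MoleculeRecord
from vsfuse.enrichment import LabeledRanking, MetricsReport, roc_auc, sensitivity, specificity

FEATURE_KINDS = ("D", "A", "H", "R", "P", "N")

#: Feature-detection SMARTS (documented, deliberately small):
#: D — N/O bearing a hydrogen; A — N/O lone-pair acceptors;
#: P — positively charged atoms and protonatable non-amide amines;
#: N — carboxylate / carboxylic acid carbon and other anionic atoms.
#: R (aromatic rings) and H (hydrophobic aliphatic carbon patches of >= 2
#: atoms with no attached heteroatom) are perceived from the graph.
_SMARTS = {
    "D": ["[#7!H0;!$([#7-])]", "[#8!H0;!$([#8-])]"],
    "A": [
        "[OX2;!$([OX2+])]",
        "[OX1;!$([OX1-][#7])]",
        "[OX1-]",
        "[NX2;!$([NX2+]);!$([NX2-])]",
        "[nX2]",
        "[NX3;H0;!$([NX3+]);!$([NX3][CX3]=[OX1])]",
    ],
    "P": ["[+;!$([+]~[-])]", "[NX3;H2,H1;!$([NX3][CX3]=[OX1]);!$([NX3+]);!$(N~a)]"],
    "N": [
        "[CX3](=[OX1])[OX1-,OX2H1]",
        # other anionic atoms, excluding carboxylate oxygens (already
        # represented by the carboxyl-carbon feature) and zwitterion pairs
        "[-;!$([OX1-][CX3]=[OX1]);!$([-]~[+])]",
    ],
}
_COMPILED = {k: [Chem.MolFromSmarts(s) for s in pats] for k, pats in _SMARTS.items()}


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One typed feature: kind, 3D position (Angstrom), tolerance radius."""

    kind: str
    position: tuple[float, float, float]
    tolerance: float = 1.6

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


MIN_INTERFEATURE_DISTANCE = 2.97  # Angstrom


@dataclass(frozen=True)
class Hypothesis:
    """A pharmacophore: 4–10 typed features with tolerance spheres, all
    pairwise at least the minimum interfeature distance apart."""

    name: str
    features: tuple[PharmacophoreFeature, ...]
    min_interfeature_distance: float = MIN_INTERFEATURE_DISTANCE

    def __post_init__(self) -> None:
        if not 4 <= len(self.features) <= 10:
            raise ValueError("a hypothesis needs between 4 and 10 features")
        pos = np.array([f.xyz for f in self.features])
        for i, j in itertools.combinations(range(len(pos)), 2):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < self.min_interfeature_distance:
                raise ValueError(
                    f"features {i} and {j} are {d:.2f} A apart "
                    f"(minimum {self.min_interfeature_distance})"
                )

    @property
    def composition(self) -> str:
        return "".join(sorted(f.kind for f in self.features))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "features": [
                        {"kind": f.kind, "x": f.position[0], "y": f.position[1],
                         "z": f.position[2], "tolerance": f.tolerance}
                        for f in self.features
                    ],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Hypothesis":
        data = json.loads(Path(path).read_text())
        feats = tuple(
            PharmacophoreFeature(f["kind"], (f["x"], f["y"], f["z"]), f["tolerance"])
            for f in data["features"]
        )
        return cls(name=data["name"], features=feats)


@dataclass
class ConformerSet:
    """Heavy-atom coordinate sets with relative energies (kcal/mol)."""

    record_id: str
    coords: list[np.ndarray]  # each (n_heavy_atoms, 3)
    energies: list[float]  # relative to the lowest-energy member


def generate_conformers(
    record: MoleculeRecord,
    max_conformers: int = 255,
    energy_window: float = 20.0,
    seed: int = 0,
) -> ConformerSet:
    """Seeded ETKDG embedding + MMFF94 minimization, pruned to
    *max_conformers* members within *energy_window* kcal/mol of the
    lowest-energy conformer.  Deterministic for a fixed seed."""
    mol = record.mol()
    n_heavy = mol.GetNumAtoms()
    molh = Chem.AddHs(mol)
    rotb = Chem.rdMolDescriptors.CalcNumRotatableBonds(mol)
    n_request = 1 if rotb == 0 else min(max_conformers, 20 * rotb + 10)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    params.pruneRmsThresh = 0.3
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_request, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"record {record.id!r}: conformer embedding failed")
    results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    energies = [e for _, e in results]
    order = sorted(range(len(conf_ids)), key=lambda i: energies[i])
    e_min = energies[order[0]]
    coords, rel = [], []
    for i in order:
        if energies[i] - e_min > energy_window or len(coords) >= max_conformers:
            break
        pos = molh.GetConformer(conf_ids[i]).GetPositions()[:n_heavy]
        coords.append(np.asarray(pos, dtype=float))
        rel.append(energies[i] - e_min)
    return ConformerSet(record_id=record.id, coords=coords, energies=rel)


def perceive_features(
    record: MoleculeRecord, conformer: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Detect pharmacophore features on one conformer.

    *conformer* holds heavy-atom coordinates in the record's canonical
    atom order.  D/A/P/N features sit on their heavy atom (N on the
    carboxyl carbon); R at the aromatic-ring centroid; H at the centroid
    of each aliphatic hydrophobic patch.
    """
    mol = record.mol()
    coords = np.asarray(conformer, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError(
            f"conformer shape {coords.shape} does not match "
            f"{mol.GetNumAtoms()} heavy atoms"
        )
    feats: list[tuple[str, np.ndarray]] = []
    for kind in ("D", "A", "P", "N"):
        hits: set[int] = set()
        for patt in _COMPILED[kind]:
            for m in mol.GetSubstructMatches(patt):
                hits.add(m[0])
        for idx in sorted(hits):
            feats.append((kind, coords[idx]))
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            feats.append(("R", coords[list(ring)].mean(axis=0)))
    feats.extend(("H", c) for c in _hydrophobic_patches(mol, coords))
    return feats


def _hydrophobic_patches(mol: Chem.Mol, coords: np.ndarray) -> list[np.ndarray]:
    # aliphatic carbons with no heteroatom neighbors, grouped into
    # connected components; patches of >= 2 atoms count as hydrophobes
    eligible = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if any(n.GetAtomicNum() not in (1, 6) for n in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    patches, seen = [], set()
    for start in sorted(eligible):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                ni = n.GetIdx()
                if ni in eligible and ni not in seen:
                    seen.add(ni)
                    stack.append(ni)
        if len(comp) >= 2:
            patches.append(coords[comp].mean(axis=0))
    return patches


def _kabsch_residuals(P: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-point distances after least-squares rigid superposition of P
    onto H (proper rotation + translation)."""
    Pc, Hc = P - P.mean(axis=0), H - H.mean(axis=0)
    U, _, Vt = np.linalg.svd(Pc.T @ Hc)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    aligned = Pc @ R + H.mean(axis=0)
    return np.linalg.norm(aligned - H, axis=1)


def match(
    hypothesis: Hypothesis,
    perceived: Sequence[tuple[str, np.ndarray]],
) -> tuple[bool, list[int] | None, float | None]:
    """Match one conformer's perceived features against a hypothesis.

    Searches all injective kind-compatible assignments of hypothesis
    features to perceived features, pruning partial assignments whose
    internal distances deviate by more than the summed tolerances.  A
    full assignment is a hit when, after optimal rigid superposition,
    every assigned feature lies inside its tolerance sphere.

    Returns ``(is_hit, best_assignment, best_fit)`` where the assignment
    maps hypothesis-feature index -> perceived-feature index and the fit
    is the RMS residual distance (lower is better).
    """
    hfeats = hypothesis.features
    hpos = np.array([f.xyz for f in hfeats])
    ppos = [np.asarray(p, dtype=float) for _, p in perceived]
    candidates = [
        [i for i, (k, _) in enumerate(perceived) if k == f.kind] for f in hfeats
    ]
    if any(not c for c in candidates):
        return False, None, None
    hdist = np.linalg.norm(hpos[:, None] - hpos[None, :], axis=-1)

    best: tuple[float, list[int]] | None = None
    assignment: list[int] = []

    def extend(i: int) -> None:
        nonlocal best
        if i == len(hfeats):
            P = np.array([ppos[j] for j in assignment])
            res = _kabsch_residuals(P, hpos)
            if all(r <= f.tolerance + 1e-9 for r, f in zip(res, hfeats)):
                fit = float(math.sqrt(float(np.mean(res**2))))
                if best is None or fit < best[0]:
                    best = (fit, list(assignment))
            return
        for p in candidates[i]:
            if p in assignment:
                continue
            ok = all(
                abs(np.linalg.norm(ppos[p] - ppos[assignment[j]]) - hdist[i, j])
                <= hfeats[i].tolerance + hfeats[j].tolerance + 1e-9
                for j in range(i)
            )
            if not ok:
                continue
            assignment.append(p)
            extend(i + 1)
            assignment.pop()

    extend(0)
    if best is None:
        return False, None, None
    return True, best[1], best[0]


def match_conformers(
    hypothesis: Hypothesis,
    feature_sets: Sequence[Sequence[tuple[str, np.ndarray]]],
) -> tuple[bool, float | None]:
    """Best match over an ensemble of per-conformer feature sets."""
    best_fit = None
    for feats in feature_sets:
        hit, _, fit = match(hypothesis, feats)
        if hit and (best_fit is None or fit < best_fit):
            best_fit = fit
    return best_fit is not None, best_fit


def hypothesis_from_reference(
    perceived: Sequence[tuple[str, np.ndarray]],
    select: Sequence[int] | None = None,
    tolerance: float = 1.6,
    min_distance: float = MIN_INTERFEATURE_DISTANCE,
    name: str = "reference",
) -> Hypothesis:
    """Build a hypothesis from one reference conformation's features.

    *select* picks perceived-feature indices; by default features are
    taken greedily in order, skipping any closer than *min_distance* to
    an already-accepted feature, up to ten features.
    """
    if select is not None:
        chosen = [perceived[i] for i in select]
    else:
        chosen = []
        for kind, pos in perceived:
            if len(chosen) == 10:
                break
            if all(np.linalg.norm(pos - q) >= min_distance for _, q in chosen):
                chosen.append((kind, np.asarray(pos, dtype=float)))
    feats = tuple(
        PharmacophoreFeature(kind, tuple(float(x) for x in pos), tolerance)
        for kind, pos in chosen
    )
    return Hypothesis(name=name, features=feats, min_interfeature_distance=min_distance)


def screen_and_validate(
    hypothesis: Hypothesis,
    labeled: Sequence[tuple[str, str, object]],
    max_conformers: int = 255,
    energy_window: float = 20.0,
    seed: int = 0,
) -> tuple[MetricsReport, list[dict]]:
    """Screen a labeled set and report Se, Sp, hit rate and ROC/AUC.

    Each labeled item is ``(id, label, payload)`` where the payload is
    either a :class:`MoleculeRecord` (conformers are generated) or a
    pre-built sequence of per-conformer feature lists.  A compound is a
    hit when any conformer matches; hits are ranked by fit value
    ascending and misses placed last, in input order.
    """
    rows = []
    for cid, label, payload in labeled:
        if isinstance(payload, MoleculeRecord):
            confs = generate_conformers(payload, max_conformers, energy_window, seed)
            feature_sets = [perceive_features(payload, c) for c in confs.coords]
        else:
            feature_sets = payload  # pre-perceived per-conformer feature lists
        is_hit, fit = match_conformers(hypothesis, feature_sets)
        rows.append({"id": cid, "label": label, "hit": is_hit, "fit": fit})
    hits = [r for r in rows if r["hit"]]
    misses = [r for r in rows if not r["hit"]]
    ordered = sorted(hits, key=lambda r: (r["fit"], r["id"])) + misses
    n_act = sum(1 for r in rows if r["label"] == "active")
    n_dec = len(rows) - n_act
    tp = sum(1 for r in hits if r["label"] == "active")
    fp = len(hits) - tp
    report = MetricsReport(
        se=sensitivity(tp, n_act - tp) if n_act else None,
        sp=specificity(n_dec - fp, fp) if n_dec else None,
    )
    if n_act and n_dec:
        ranking = LabeledRanking(entries=[(r["id"], r["label"]) for r in ordered])
        _, report.auc = roc_auc(ranking)
    return report, ordered
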