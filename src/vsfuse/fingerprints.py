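"""2D molecular fingerprints and Tanimoto similarity.

Four binary ("bit"-scaled) fingerprint schemes:

* **MACCS** — the public 166-key structural-key set (via RDKit).
* **radial** — circular atom environments grown over a fixed number of
  iterations from every heavy atom (ECFP-style; 2 iterations by default,
  i.e. ECFP4-equivalent diameter).
* **dendritic** — all connected fragments that are simple paths or
  single-branch trees with up to five bonds.
* **MOLPRINT2D** — each heavy atom encoded by the multiset of
  SYBYL-typed heavy atoms within a 2-bond graph distance.

Hashed schemes type atoms with the daylight scheme (atomic number,
valence, formal charge, hydrogen and heavy-atom connection counts),
except MOLPRINT2D which uses SYBYL-style mol2 types.  Each fragment is
canonicalized to a string and hashed into a 2^32 bit space with FNV-1a
(pinned for bit-exact reproducibility); only "on" bits are stored, and
hash collisions are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import MACCSkeys

from vsfuse.compound_io import MoleculeRecord

#: Fingerprint kinds usable as similarity measures, in canonical order.
MEASURES = ("maccs", "radial", "dendritic", "molprint2d")

_FNV_OFFSET = 2166136261
_FNV_PRIME = 16777619


def fnv1a_32(s: str) -> int:
    """FNV-1a hash of *s* into the 32-bit space [0, 2^32)."""
    h = _FNV_OFFSET
    for b in s.encode("utf-8"):
        h ^= b
        h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class SparseFingerprint:
    """Hashed on-bit set over the 32-bit space."""

    kind: str
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if any(not (0 <= b < 2**32) for b in self.bits):
            raise ValueError("bit outside 32-bit range")

    def to_line(self, rec_id: str) -> str:
        return f"{rec_id}\t{self.kind}\t{','.join(map(str, sorted(self.bits)))}"


@dataclass(frozen=True)
class KeyedFingerprint:
    """Fixed 166-position structural-key bit vector (MACCS)."""

    keys: tuple[int, ...]
    kind: str = "maccs"

    def __post_init__(self) -> None:
        if len(self.keys) != 166:
            raise ValueError(f"expected 166 keys, got {len(self.keys)}")

    @property
    def bits(self) -> frozenset[int]:
        return frozenset(i for i, k in enumerate(self.keys) if k)

    def to_line(self, rec_id: str) -> str:
        return f"{rec_id}\tmaccs\t{''.join(map(str, self.keys))}"


# --- atom typing -----------------------------------------------------------


def daylight_atom_type(atom: Chem.Atom) -> str:
    """Daylight-scheme atom code: element, valence, charge, H and heavy
    connection counts.  Identical chemical environments map to identical
    codes."""
    return (
        f"{atom.GetAtomicNum()}v{atom.GetTotalValence()}"
        f"c{atom.GetFormalCharge():+d}h{atom.GetTotalNumHs()}"
        f"D{atom.GetDegree()}"
    )


def sybyl_atom_type(atom: Chem.Atom) -> str:
    """SYBYL mol2-style atom type (documented subset).

    Covers C.1/C.2/C.3/C.ar, N.ar/N.am/N.pl3/N.2/N.3/N.4, O.co2/O.2/O.3,
    S.2/S.3, P.3 and halogens; anything else falls back to
    ``<symbol>.<hybridization>``.
    """
    z = atom.GetAtomicNum()
    sym = atom.GetSymbol()
    hyb = atom.GetHybridization()
    HybType = Chem.HybridizationType
    if z == 6:
        if atom.GetIsAromatic():
            return "C.ar"
        return {HybType.SP: "C.1", HybType.SP2: "C.2"}.get(hyb, "C.3")
    if z == 7:
        if atom.GetIsAromatic():
            return "N.ar"
        # amide nitrogen: bonded to a carbonyl carbon
        for nbr in atom.GetNeighbors():
            if nbr.GetAtomicNum() == 6 and any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(nbr).GetAtomicNum() in (8, 16)
                for b in nbr.GetBonds()
            ):
                return "N.am"
        if atom.GetFormalCharge() > 0 and hyb == HybType.SP3:
            return "N.4"
        if hyb == HybType.SP2:
            return "N.pl3" if atom.GetTotalDegree() == 3 else "N.2"
        if hyb == HybType.SP:
            return "N.1"
        return "N.3"
    if z == 8:
        # carboxylate / phosphate-style oxygen
        for nbr in atom.GetNeighbors():
            if nbr.GetAtomicNum() in (6, 15):
                others = [
                    b.GetOtherAtom(nbr)
                    for b in nbr.GetBonds()
                    if b.GetOtherAtom(nbr).GetAtomicNum() == 8
                ]
                if len(others) >= 2 and any(o.GetFormalCharge() < 0 for o in others):
                    return "O.co2"
        if hyb == HybType.SP2 or atom.GetIsAromatic():
            return "O.2"
        return "O.3"
    if z == 16:
        return "S.2" if hyb == HybType.SP2 or atom.GetIsAromatic() else "S.3"
    if z == 15:
        return "P.3"
    if z in (9, 17, 35, 53):
        return sym
    return f"{sym}.{str(hyb).lower()}"


def _typed_symbols(mol: Chem.Mol) -> list[str]:
    return [f"[{daylight_atom_type(a)}]" for a in mol.GetAtoms()]


def _fragment_string(mol: Chem.Mol, atoms: Iterable[int], bonds: Iterable[int], symbols: list[str], root: int = -1) -> str:
    """Canonical SMILES-like string of a fragment with typed atom symbols.

    Canonicalization uses whole-molecule canonical ranks, so the string is
    invariant under input atom renumbering.
    """
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=list(atoms),
        bondsToUse=list(bonds),
        atomSymbols=symbols,
        canonical=True,
        rootedAtAtom=root,
        allBondsExplicit=True,
    )


# --- fingerprint generators ------------------------------------------------


@lru_cache(maxsize=4096)
def _radial_bits(smiles: str, iterations: int) -> frozenset[int]:
    mol = Chem.MolFromSmiles(smiles)
    symbols = _typed_symbols(mol)
    bits: set[int] = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        prev_env: frozenset[int] | None = None
        for radius in range(iterations + 1):
            if radius == 0:
                frag = symbols[idx]
                prev_env = frozenset()
            else:
                env = frozenset(Chem.FindAtomEnvironmentOfRadiusN(mol, radius, idx))
                if not env or env == prev_env:
                    break  # environment stopped growing
                prev_env = env
                atoms = {idx}
                for b in env:
                    bond = mol.GetBondWithIdx(b)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                frag = _fragment_string(mol, atoms, env, symbols, root=idx)
            bits.add(fnv1a_32(f"radial|{frag}"))
    return frozenset(bits)


def radial_fingerprint(record: MoleculeRecord, iterations: int = 2) -> SparseFingerprint:
    """Circular environments of radius 0..*iterations* around every heavy
    atom, daylight-typed, canonicalized and hashed to one bit each."""
    return SparseFingerprint("radial", _radial_bits(record.structure, iterations))


def _connected_edge_subsets(mol: Chem.Mol, max_bonds: int) -> set[frozenset[int]]:
    bond_atoms = {
        b.GetIdx(): (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    }
    atom_bonds: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for bid, (i, j) in bond_atoms.items():
        atom_bonds[i].append(bid)
        atom_bonds[j].append(bid)
    frontier: set[frozenset[int]] = {frozenset({b}) for b in bond_atoms}
    out: set[frozenset[int]] = set(frontier)
    for _ in range(max_bonds - 1):
        nxt: set[frozenset[int]] = set()
        for sub in frontier:
            atoms = {a for b in sub for a in bond_atoms[b]}
            for a in atoms:
                for b in atom_bonds[a]:
                    if b not in sub:
                        grown = sub | {b}
                        if grown not in out:
                            nxt.add(grown)
        out |= nxt
        frontier = nxt
    return out


def _is_path_or_single_branch_tree(mol: Chem.Mol, bonds: frozenset[int]) -> bool:
    deg: dict[int, int] = {}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        for a in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
            deg[a] = deg.get(a, 0) + 1
    if len(bonds) != len(deg) - 1:
        return False  # contains a cycle
    return sum(1 for d in deg.values() if d >= 3) <= 1


@lru_cache(maxsize=4096)
def _dendritic_bits(smiles: str, max_bonds: int) -> frozenset[int]:
    mol = Chem.MolFromSmiles(smiles)
    symbols = _typed_symbols(mol)
    bits: set[int] = set()
    for atom in mol.GetAtoms():  # 0-bond fragments: lone typed atoms
        bits.add(fnv1a_32(f"dendritic|{symbols[atom.GetIdx()]}"))
    for sub in _connected_edge_subsets(mol, max_bonds):
        if not _is_path_or_single_branch_tree(mol, sub):
            continue
        atoms = set()
        for b in sub:
            bond = mol.GetBondWithIdx(b)
            atoms.add(bond.GetBeginAtomIdx())
            atoms.add(bond.GetEndAtomIdx())
        frag = _fragment_string(mol, atoms, sub, symbols)
        bits.add(fnv1a_32(f"dendritic|{frag}"))
    return frozenset(bits)


def dendritic_fingerprint(record: MoleculeRecord, max_bonds: int = 5) -> SparseFingerprint:
    """Fragments grown in linear and singly-branched directions with up to
    *max_bonds* bonds, daylight-typed, canonicalized and hashed."""
    return SparseFingerprint("dendritic", _dendritic_bits(record.structure, max_bonds))


@lru_cache(maxsize=4096)
def _molprint2d_bits(smiles: str) -> frozenset[int]:
    mol = Chem.MolFromSmiles(smiles)
    types = [sybyl_atom_type(a) for a in mol.GetAtoms()]
    dm = Chem.GetDistanceMatrix(mol)
    bits: set[int] = set()
    n = mol.GetNumAtoms()
    for i in range(n):
        shells = {1: [], 2: []}
        for j in range(n):
            d = int(dm[i][j])
            if d in (1, 2):
                shells[d].append(types[j])
        env = (
            f"{types[i]};1:{','.join(sorted(shells[1]))}"
            f";2:{','.join(sorted(shells[2]))}"
        )
        bits.add(fnv1a_32(f"molprint2d|{env}"))
    return frozenset(bits)


def molprint2d_fingerprint(record: MoleculeRecord) -> SparseFingerprint:
    """Per heavy atom: the SYBYL-typed neighbor multiset at graph distance
    1 and 2, serialized with the center type and hashed to one bit."""
    return SparseFingerprint("molprint2d", _molprint2d_bits(record.structure))


@lru_cache(maxsize=4096)
def _maccs_keys(smiles: str) -> tuple[int, ...]:
    mol = Chem.MolFromSmiles(smiles)
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    on = set(bv.GetOnBits())
    return tuple(1 if (k + 1) in on else 0 for k in range(166))


def maccs_fingerprint(record: MoleculeRecord) -> KeyedFingerprint:
    """Public 166-key MACCS structural keys; position k set iff key k+1's
    SMARTS pattern matches."""
    return KeyedFingerprint(_maccs_keys(record.structure))


def fingerprint(record: MoleculeRecord, kind: str, **kwargs) -> SparseFingerprint | KeyedFingerprint:
    """Compute the fingerprint of the given *kind* (one of :data:`MEASURES`)."""
    if kind == "maccs":
        return maccs_fingerprint(record)
    if kind == "radial":
        return radial_fingerprint(record, **kwargs)
    if kind == "dendritic":
        return dendritic_fingerprint(record, **kwargs)
    if kind == "molprint2d":
        return molprint2d_fingerprint(record)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto(a: SparseFingerprint | KeyedFingerprint, b: SparseFingerprint | KeyedFingerprint) -> float:
    """Tanimoto index |A∩B| / |A∪B| over on-bit sets.

    Defined as 0.0 when both sets are empty.  Fingerprints must be of the
    same kind.
    """
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind!r} vs {b.kind!r}")
    sa, sb = a.bits, b.bits
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union
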