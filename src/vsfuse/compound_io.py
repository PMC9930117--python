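"""Compound library I/O, physicochemical properties and prefilters.

Reads SMILES/SDF libraries into :class:`MoleculeRecord` objects, computes
the descriptors the screening funnel filters on (MW, cLogP, HBD, HBA,
rotatable bonds, TPSA) and applies lead-likeness and reactive-group
prefilters.  Salt/mixture inputs are reduced to the largest organic
fragment before property calculation.

The logP estimator is Wildman–Crippen atom-contribution logP as
implemented in RDKit; its name is recorded in every filter report so
downstream numbers are attributable to a specific estimator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

LOGP_ESTIMATOR = "Wildman-Crippen (RDKit Crippen.MolLogP)"


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES and its 2D properties.

    Properties are deterministic functions of the structure; ``None``
    until :func:`compute_properties` fills them.
    """

    id: str
    structure: str
    mw: float | None = None
    clogp: float | None = None
    hbd: int | None = None
    hba: int | None = None
    rotb: int | None = None
    tpsa: float | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise ValueError(f"record {self.id!r}: unparseable structure")
        return m

    @property
    def has_properties(self) -> bool:
        return self.mw is not None


@dataclass
class FilterReport:
    """Accounting of a filter pass with first-failing-rule attribution."""

    n_input: int = 0
    n_passed: int = 0
    n_failed_parse: int = 0
    failures: dict[str, int] = field(default_factory=dict)
    logp_estimator: str = LOGP_ESTIMATOR

    def check_identity(self) -> bool:
        return self.n_passed + sum(self.failures.values()) + self.n_failed_parse == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "n_failed_parse": self.n_failed_parse,
            "failures": dict(self.failures),
            "logp_estimator": self.logp_estimator,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class DruglikeRules:
    """Lead-likeness window: MW 150–450 g/mol and cLogP <= 5 tighten the
    classical Lipinski (HBD <= 5, HBA <= 10) and Veber (RotB <= 10,
    TPSA <= 140 A^2) rules.  All thresholds configurable."""

    mw_min: float = 150.0
    mw_max: float = 450.0
    clogp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10
    rotb_max: int = 10
    tpsa_max: float = 140.0


#: Documented stand-in alert list (name -> SMARTS).  The funnel's source
#: screen used full REOS/PAINS lists; users may supply their own.
DEFAULT_ALERTS: dict[str, str] = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "michael_acceptor_enone": "[CX3]=[CX3][CX3]=[OX1]",
    "alkyl_halide": "[CX4][Cl,Br,I]",
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    "epoxide_aziridine": "[OX2r3,NX3r3]1[#6r3][#6r3]1",
    "quinone": "O=C1C=CC(=O)C=C1",
    "azo": "[#6][NX2]=[NX2][#6]",
    "anhydride": "[CX3](=O)[OX2][CX3](=O)",
    "peroxide": "[OX2][OX2]",
}


def _largest_organic_fragment(mol: Chem.Mol, rec_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic or list(frags)
    best = max(pool, key=lambda f: f.GetNumHeavyAtoms())
    logger.info("record %s: stripped %d fragment(s), kept largest organic", rec_id, len(frags) - 1)
    return best


def read_library(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a compound library from a .smi or .sdf file.

    SMILES files are whitespace-separated ``SMILES id`` lines; SDF is
    V2000 with ids from the title line (or an ``ID``/``_Name`` tag).
    Unparseable entries are skipped and logged; ids default to
    ``REC<n>``.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` when nothing parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    records: list[MoleculeRecord] = []
    n_failed = 0
    if format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            rec_id = parts[1].strip() if len(parts) > 1 else f"REC{i + 1}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                n_failed += 1
                logger.warning("line %d: unparseable SMILES %r", i + 1, smiles)
                continue
            mol = _largest_organic_fragment(mol, rec_id)
            records.append(MoleculeRecord(id=rec_id, structure=Chem.MolToSmiles(mol)))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_failed += 1
                logger.warning("SDF entry %d: unparseable", i + 1)
                continue
            rec_id = None
            if mol.HasProp("ID"):
                rec_id = mol.GetProp("ID")
            elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rec_id = mol.GetProp("_Name").strip()
            if not rec_id:
                rec_id = f"REC{i + 1}"
            mol = _largest_organic_fragment(mol, rec_id)
            records.append(MoleculeRecord(id=rec_id, structure=Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"{path}: no parseable records (failed: {n_failed})")
    if n_failed:
        logger.warning("%s: skipped %d unparseable entries", path, n_failed)
    return records


def write_library(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as a .smi file, one ``SMILES id`` line per record."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.structure}\t{rec.id}\n")


def compute_properties(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy of *record* with all physicochemical properties filled.

    Idempotent; properties are deterministic functions of the canonical
    structure.
    """
    mol = record.mol()
    return replace(
        record,
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        tpsa=Descriptors.TPSA(mol),
    )


# Fixed attribution order: the first failing rule is the one reported.
_DRUGLIKE_RULE_ORDER = ("mw", "clogp", "hbd", "hba", "rotb", "tpsa")


def _first_failing_rule(rec: MoleculeRecord, rules: DruglikeRules) -> str | None:
    checks = {
        "mw": rules.mw_min <= rec.mw <= rules.mw_max,
        "clogp": rec.clogp <= rules.clogp_max,
        "hbd": rec.hbd <= rules.hbd_max,
        "hba": rec.hba <= rules.hba_max,
        "rotb": rec.rotb <= rules.rotb_max,
        "tpsa": rec.tpsa <= rules.tpsa_max,
    }
    for name in _DRUGLIKE_RULE_ORDER:
        if not checks[name]:
            return name
    return None


def filter_druglike(
    records: Sequence[MoleculeRecord], rules: DruglikeRules | None = None
) -> tuple[list[MoleculeRecord], FilterReport]:
    """Keep records inside the lead-likeness window (see :class:`DruglikeRules`)."""
    rules = rules or DruglikeRules()
    report = FilterReport(n_input=len(records))
    passed: list[MoleculeRecord] = []
    for rec in records:
        if not rec.has_properties:
            raise ValueError(f"record {rec.id!r}: properties not computed")
        rule = _first_failing_rule(rec, rules)
        if rule is None:
            passed.append(rec)
        else:
            report.failures[rule] = report.failures.get(rule, 0) + 1
    report.n_passed = len(passed)
    return passed, report


def filter_reactive(
    records: Sequence[MoleculeRecord], alert_smarts: dict[str, str] | None = None
) -> tuple[list[MoleculeRecord], FilterReport]:
    """Remove records matching any reactive/problematic substructure alert.

    *alert_smarts* maps alert name -> SMARTS; defaults to
    :data:`DEFAULT_ALERTS`.  Attribution is to the first matching alert
    in mapping order.  Invalid patterns raise at load time.
    """
    if alert_smarts is None:
        alert_smarts = DEFAULT_ALERTS
    patterns: list[tuple[str, Chem.Mol]] = []
    for name, smarts in alert_smarts.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"alert {name!r}: invalid SMARTS {smarts!r}")
        patterns.append((name, patt))
    report = FilterReport(n_input=len(records))
    passed: list[MoleculeRecord] = []
    for rec in records:
        mol = rec.mol()
        hit = next((name for name, patt in patterns if mol.HasSubstructMatch(patt)), None)
        if hit is None:
            passed.append(rec)
        else:
            report.failures[hit] = report.failures.get(hit, 0) + 1
    report.n_passed = len(passed)
    return passed, report
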