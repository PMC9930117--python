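"""Config-driven orchestration: synth -> filter -> screen -> validate
(-> pharm).

Each stage writes its outputs plus a record of its parameters and an
input hash into the run directory; when a stage's inputs and parameters
are unchanged, it is skipped and its previous outputs are reused
(content-addressed caching).  A final ``summary.json`` aggregates the
filter report, ranking inventory and enrichment metrics, and is
byte-identical across reruns with the same config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from vsfuse.compound_io import (
    DruglikeRules,
    compute_properties,
    filter_druglike,
    filter_reactive,
    read_library,
    write_library,
)
from vsfuse.enrichment import compute_metrics, labeled_from_ranking
from vsfuse.fingerprints import MEASURES
from vsfuse.fusion import run_method_a, run_method_b, run_method_c, similarity_search
from vsfuse.pharmacophore import Hypothesis, screen_and_validate
from vsfuse.synthetic import BenchmarkSpec, make_active_series, make_decoy_pool

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "stages", "synth", "filter", "screen", "validate", "pharm"}
_KNOWN_STAGES = ("synth", "filter", "screen", "validate", "pharm")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["synth", "filter", "screen", "validate"])
    synth: dict[str, Any] = field(default_factory=dict)
    filter: dict[str, Any] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)
    validate: dict[str, Any] = field(default_factory=dict)
    pharm: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _hash(*parts: Any) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_cached(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / ".stage_hash"
    return marker.exists() and marker.read_text() == digest


def _mark_stage(stage_dir: Path, digest: str) -> None:
    (stage_dir / ".stage_hash").write_text(digest)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in order under *out_dir*.

    Returns the aggregated summary (also written to ``summary.json``).
    Any stage failure aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}
    try:
        for stage in config.stages:
            t0 = time.monotonic()
            summary["stages"][stage] = _STAGE_FUNCS[stage](config, out)
            logger.info("stage %s done in %.1fs", stage, time.monotonic() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _stage_synth(config: PipelineConfig, out: Path) -> dict:
    stage_dir = out / "synth"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.synth)
    params.setdefault("seed", config.seed)
    digest = _hash("synth", params)
    actives_path = stage_dir / "actives.smi"
    decoys_path = stage_dir / "decoys.smi"
    labels_path = stage_dir / "labels.csv"
    if not _stage_cached(stage_dir, digest):
        spec = BenchmarkSpec(**params)
        actives, activities = make_active_series(spec)
        decoys = make_decoy_pool(spec, actives)
        write_library(actives, actives_path)
        write_library(decoys, decoys_path)
        with open(labels_path, "w") as fh:
            fh.write("id,label,activity_uM\n")
            for a in actives:
                fh.write(f"{a.id},active,{activities[a.id]:.4f}\n")
            for d in decoys:
                fh.write(f"{d.id},decoy,\n")
        _mark_stage(stage_dir, digest)
    n_act = sum(1 for _ in open(actives_path))
    n_dec = sum(1 for _ in open(decoys_path))
    return {"n_actives": n_act, "n_decoys": n_dec,
            "actives": str(actives_path), "decoys": str(decoys_path),
            "labels": str(labels_path)}


def _stage_filter(config: PipelineConfig, out: Path) -> dict:
    stage_dir = out / "filter"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.filter)
    library_path = Path(params.pop("library", out / "synth" / "decoys.smi"))
    rules = DruglikeRules(**params.pop("rules", {}))
    if params:
        raise ValueError(f"unknown filter option(s): {sorted(params)}")
    digest = _hash("filter", rules.__dict__, library_path)
    out_path = stage_dir / "filtered.smi"
    report_path = stage_dir / "filter_report.json"
    if not _stage_cached(stage_dir, digest):
        records = [compute_properties(r) for r in read_library(library_path)]
        passed, drug_report = filter_druglike(records, rules)
        passed, alert_report = filter_reactive(passed)
        write_library(passed, out_path)
        report_path.write_text(json.dumps(
            {"druglike": drug_report.to_dict(), "reactive": alert_report.to_dict()},
            indent=2, sort_keys=True))
        _mark_stage(stage_dir, digest)
    report = json.loads(report_path.read_text())
    return {"library": str(library_path), "filtered": str(out_path), "report": report}


def _stage_screen(config: PipelineConfig, out: Path) -> dict:
    stage_dir = out / "screen"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.screen)
    actives_path = Path(params.pop("actives", out / "synth" / "actives.smi"))
    library_path = Path(params.pop("library", out / "synth" / "decoys.smi"))
    measures = params.pop("measures", list(MEASURES))
    methods = [m.upper() for m in params.pop("methods", ["A", "B", "C"])]
    include_actives = params.pop("include_actives_in_library", True)
    if params:
        raise ValueError(f"unknown screen option(s): {sorted(params)}")
    digest = _hash("screen", {"measures": measures, "methods": methods,
                              "include_actives": include_actives},
                   actives_path, library_path)
    inventory_path = stage_dir / "rankings.json"
    if not _stage_cached(stage_dir, digest):
        actives = read_library(actives_path)
        library = read_library(library_path)
        if include_actives:  # validation-style screen: actives are in the deck
            library = actives + library
        table = similarity_search(actives, library, measures)
        rankings = []
        if "A" in methods:
            rankings += run_method_a(actives, library, measures, table=table)
        if "B" in methods:
            rankings += run_method_b(actives, library, measures, table=table)
        if "C" in methods:
            rankings += run_method_c(actives, library, measures, table=table)
        inventory = []
        for i, r in enumerate(rankings):
            name = f"ranking_{i + 1:03d}_{r.method}_{r.rule}"
            if r.query:
                name += f"_{r.query}"
            if r.measure:
                name += f"_{r.measure}"
            path = stage_dir / f"{name}.csv"
            r.to_csv(path)
            inventory.append({"file": str(path), "method": r.method, "rule": r.rule,
                              "query": r.query, "measure": r.measure})
        inventory_path.write_text(json.dumps(inventory, indent=2, sort_keys=True))
        _mark_stage(stage_dir, digest)
    inventory = json.loads(inventory_path.read_text())
    counts: dict[str, int] = {}
    for item in inventory:
        counts[item["method"]] = counts.get(item["method"], 0) + 1
    return {"n_rankings": len(inventory), "per_method": counts,
            "inventory": str(inventory_path)}


def _read_labels(path: Path) -> dict[str, str]:
    labels = {}
    for line in path.read_text().splitlines()[1:]:
        parts = line.split(",")
        labels[parts[0]] = parts[1]
    return labels


def _stage_validate(config: PipelineConfig, out: Path) -> dict:
    stage_dir = out / "validate"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.validate)
    labels_path = Path(params.pop("labels", out / "synth" / "labels.csv"))
    ef_fractions = params.pop("ef_fractions", [0.01, 0.05, 0.10])
    alpha = params.pop("alpha", 20.0)
    if params:
        raise ValueError(f"unknown validate option(s): {sorted(params)}")
    inventory_path = out / "screen" / "rankings.json"
    digest = _hash("validate", {"ef": ef_fractions, "alpha": alpha},
                   labels_path, inventory_path)
    metrics_path = stage_dir / "metrics.json"
    if not _stage_cached(stage_dir, digest):
        labels = _read_labels(labels_path)
        inventory = json.loads(inventory_path.read_text())
        results = []
        for item in inventory:
            ids = [line.split(",")[0]
                   for line in Path(item["file"]).read_text().splitlines()[1:]]
            ranking = labeled_from_ranking(ids, labels)
            report = compute_metrics(ranking, ef_fractions, alpha)
            results.append({"method": item["method"], "rule": item["rule"],
                            "query": item["query"], "measure": item["measure"],
                            "metrics": report.to_dict()})
        best = max(results, key=lambda r: r["metrics"]["auc"])
        metrics_path.write_text(json.dumps(
            {"rankings": results, "best_by_auc": best}, indent=2, sort_keys=True))
        _mark_stage(stage_dir, digest)
    metrics = json.loads(metrics_path.read_text())
    return {"n_validated": len(metrics["rankings"]),
            "best_by_auc": metrics["best_by_auc"], "metrics": str(metrics_path)}


def _stage_pharm(config: PipelineConfig, out: Path) -> dict:
    stage_dir = out / "pharm"
    stage_dir.mkdir(exist_ok=True)
    params = dict(config.pharm)
    hypothesis_path = Path(params.pop("hypothesis"))
    library_path = Path(params.pop("library", out / "synth" / "actives.smi"))
    labels_path = params.pop("labels", None)
    max_confs = params.pop("max_conformers", 50)
    window = params.pop("energy_window", 20.0)
    if params:
        raise ValueError(f"unknown pharm option(s): {sorted(params)}")
    digest = _hash("pharm", {"max_confs": max_confs, "window": window},
                   hypothesis_path, library_path)
    hits_path = stage_dir / "hits.csv"
    report_path = stage_dir / "pharm_report.json"
    if not _stage_cached(stage_dir, digest):
        hypothesis = Hypothesis.from_json(hypothesis_path)
        records = read_library(library_path)
        labels = _read_labels(Path(labels_path)) if labels_path else {}
        labeled = [(r.id, labels.get(r.id, "active"), r) for r in records]
        report, rows = screen_and_validate(
            hypothesis, labeled, max_conformers=max_confs,
            energy_window=window, seed=config.seed)
        with open(hits_path, "w") as fh:
            fh.write("id,label,hit,fit\n")
            for row in rows:
                fit = "" if row["fit"] is None else f"{row['fit']:.4f}"
                fh.write(f"{row['id']},{row['label']},{int(row['hit'])},{fit}\n")
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        _mark_stage(stage_dir, digest)
    return {"hits": str(hits_path), "report": json.loads(report_path.read_text())}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "filter": _stage_filter,
    "screen": _stage_screen,
    "validate": _stage_validate,
    "pharm": _stage_pharm,
}
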