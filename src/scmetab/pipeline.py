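"""One-config orchestration: simulate -> score -> permtest -> deg -> intersect
-> cluster stats, with strict config validation and a machine-readable report.

A single mandatory top-level seed feeds per-stage child seeds derived
deterministically, so one config + seed pins every output byte. CSV outputs
use a fixed column order and 6-significant-digit floats for diffability.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .cluster import compare_proportions, coexpression_network, proportions_by_sample
from .deg import call_degs, intersect_degs, volcano_table
from .errors import ConfigValidationError, ScmetabError
from .scoring import aggregate_categories, permutation_pvalues, score_pathways
from .synthetic import (
    SimConfig,
    generate_bulk_cohorts,
    generate_pathway_sets,
    generate_sc_counts,
)

FLOAT_FORMAT = "%.6g"

_SIM_KEYS = {
    f: getattr(SimConfig, f)
    for f in (
        "n_cell_types", "cells_per_type", "n_genes", "n_pathways", "genes_per_pathway",
        "overlap_fraction", "baseline_mean", "dispersion", "celltype_baseline_sd",
        "libsize_cv", "n_samples_per_condition", "n_bulk_cohorts", "samples_per_group",
        "bulk_log2_sd", "bulk_base_log2_mean", "bulk_scale_sd",
    )
}

SCHEMA: dict[str, dict] = {
    "seed": None,
    "out_dir": None,
    "simulate": {"enabled": False, "planted_effects": [], "planted_degs": [], **_SIM_KEYS},
    "inputs": {
        "expression": None, "annotation": None, "gene_sets": None,
        "categories": None, "bulk": [], "bulk_scale": "linear",
    },
    "score": {"enabled": True, "min_genes": 3, "normalize": "median-libsize"},
    "permtest": {"enabled": True, "n_perm": 999, "adjust": "none"},
    "deg": {"enabled": True, "p_threshold": 0.05, "fc_threshold": 1.0},
    "intersect": {"enabled": True},
    "proportions": {"enabled": True, "cell_types": None},
    "coexpr": {
        "enabled": False, "cluster": None, "focal_gene": None,
        "markers": None, "alpha": 0.05,
    },
}

STAGE_ORDER = [
    "simulate", "score", "permtest", "deg", "intersect", "proportions", "coexpr",
]


class PipelineError(ScmetabError):
    """A stage failed; the message names the stage, prior outputs are kept."""


@dataclass
class RunConfig:
    """Validated, defaulted run configuration."""

    seed: int | None
    out_dir: str | None
    sections: dict[str, dict]

    def stage(self, name: str) -> dict:
        return self.sections[name]

    def enabled(self, name: str) -> bool:
        return bool(self.sections[name].get("enabled", False))

    def sim_config(self, seed: int) -> SimConfig:
        kwargs = {k: v for k, v in self.sections["simulate"].items() if k != "enabled"}
        kwargs["planted_effects"] = [tuple(e) for e in kwargs.get("planted_effects", [])]
        kwargs["planted_degs"] = [tuple(e) for e in kwargs.get("planted_degs", [])]
        return SimConfig(seed=seed, **kwargs)


@dataclass
class RunReport:
    seed: int | None
    stage_order: list[str] = field(default_factory=list)
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stage_order": self.stage_order,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _suggest(key: str, known) -> str:
    match = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {match[0]!r}?)" if match else ""


def validate_config(raw) -> RunConfig:
    """Parse and validate YAML text / a mapping into a RunConfig.

    Unknown keys are rejected with a suggestion; every violation is
    collected and reported at once.
    """
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigValidationError(["top-level config must be a mapping"])
    problems: list[str] = []
    sections: dict[str, dict] = {}
    for key in raw:
        if key not in SCHEMA:
            problems.append(f"unknown key {key!r}{_suggest(key, SCHEMA)}")
    for name, default in SCHEMA.items():
        if not isinstance(default, dict):
            continue
        given = raw.get(name, {})
        if given is None:
            given = {}
        if not isinstance(given, dict):
            problems.append(f"section {name!r} must be a mapping")
            given = {}
        for key in given:
            if key not in default:
                problems.append(f"unknown key {name}.{key!r}{_suggest(key, default)}")
        sections[name] = {
            k: (given[k] if k in given else v) for k, v in default.items()
        }

    seed = raw.get("seed")
    out_dir = raw.get("out_dir")
    if seed is not None and not isinstance(seed, int):
        problems.append("seed must be an integer")
        seed = None

    sim, inputs = sections["simulate"], sections["inputs"]
    score, permtest = sections["score"], sections["permtest"]
    deg, coexpr = sections["deg"], sections["coexpr"]

    if permtest["n_perm"] < 1:
        problems.append("permtest.n_perm must be >= 1")
    if permtest["adjust"] not in ("none", "bh"):
        problems.append("permtest.adjust must be 'none' or 'bh'")
    if score["min_genes"] < 1:
        problems.append("score.min_genes must be >= 1")
    if score["normalize"] not in ("median-libsize", "none"):
        problems.append("score.normalize must be 'median-libsize' or 'none'")
    if not deg["p_threshold"] > 0:
        problems.append("deg.p_threshold must be > 0")
    if not deg["fc_threshold"] >= 0:
        problems.append("deg.fc_threshold must be >= 0")
    if inputs["bulk_scale"] not in ("linear", "log2"):
        problems.append("inputs.bulk_scale must be 'linear' or 'log2'")
    if not 0 < coexpr["alpha"] < 1:
        problems.append("coexpr.alpha must lie in (0, 1)")

    stochastic = sim["enabled"] or bool(permtest["enabled"])
    if stochastic and seed is None:
        problems.append("seed is required when a stochastic stage (simulate/permtest) is enabled")

    sc_from_files = inputs["expression"] is not None or inputs["annotation"] is not None
    bulk_from_files = bool(inputs["bulk"])
    if sim["enabled"] and sc_from_files:
        problems.append("provide either a simulate block or inputs.expression/annotation, not both")
    if sim["enabled"] and bulk_from_files:
        problems.append("provide either a simulate block or inputs.bulk, not both")
    sc_needed = any(sections[s]["enabled"] for s in ("score", "permtest", "proportions", "coexpr"))
    if sc_needed and not sim["enabled"] and not sc_from_files:
        problems.append("score/permtest/proportions/coexpr need single-cell data: enable simulate or set inputs.expression and inputs.annotation")
    if sc_from_files and (inputs["expression"] is None or inputs["annotation"] is None):
        problems.append("inputs.expression and inputs.annotation must be given together")
    if (sections["score"]["enabled"] or sections["permtest"]["enabled"]) and not sim["enabled"]:
        if sc_from_files and inputs["gene_sets"] is None:
            problems.append("score/permtest on file inputs need inputs.gene_sets (GMT)")
    if sections["intersect"]["enabled"] and not sections["deg"]["enabled"]:
        problems.append("intersect requires the deg stage to be enabled")
    bulk_needed = sections["deg"]["enabled"] or sections["intersect"]["enabled"]
    if bulk_needed and not sim["enabled"] and not bulk_from_files:
        problems.append("deg/intersect need bulk data: enable simulate or set inputs.bulk")
    if coexpr["enabled"]:
        for k in ("cluster", "focal_gene", "markers"):
            if coexpr[k] is None:
                problems.append(f"coexpr.{k} is required when coexpr is enabled")

    if problems:
        raise ConfigValidationError(problems)
    return RunConfig(seed=seed, out_dir=out_dir, sections=sections)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    idx = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _StageRecorder:
    def __init__(self, report: RunReport, out_dir: Path):
        self.report = report
        self.out_dir = out_dir

    def record(self, stage: str, params: dict, counts: dict, files: list[Path], warnings=()):
        self.report.stage_order.append(stage)
        self.report.stages[stage] = {
            "enabled": True,
            "params": params,
            "counts": counts,
            "warnings": list(warnings),
            "outputs": {str(f.relative_to(self.out_dir)): _sha256(f) for f in files},
        }
        self.report.warnings.extend(f"{stage}: {w}" for w in warnings)


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the enabled stages in dependency order.

    Identical config + seed produce byte-identical outputs. A failing
    stage raises :class:`PipelineError` naming the stage; outputs written
    by earlier stages are preserved on disk.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    rec = _StageRecorder(report, out)

    expr = ann = sets = None
    cohorts = []
    pa = None

    def _run(stage, fn):
        try:
            fn()
        except ScmetabError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------------ simulate
    if config.enabled("simulate"):
        def _simulate():
            nonlocal expr, ann, sets, cohorts
            sim_cfg = config.sim_config(seed=stage_seed(config.seed, "simulate"))
            sets = generate_pathway_sets(sim_cfg)
            expr, ann, truth_sc = generate_sc_counts(sim_cfg, sets)
            cohorts[:], truth_bulk = generate_bulk_cohorts(sim_cfg)
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            _io.write_expression_mtx(expr, sim_dir)
            _io.write_annotation(ann, sim_dir / "annotation.tsv")
            _io.write_gmt(sets, sim_dir / "pathways.gmt")
            files = [
                sim_dir / "matrix.mtx", sim_dir / "features.tsv",
                sim_dir / "barcodes.tsv", sim_dir / "annotation.tsv",
                sim_dir / "pathways.gmt",
            ]
            for cohort in cohorts:
                p = sim_dir / f"bulk_{cohort.cohort_id}.csv"
                _io.write_bulk_csv(cohort, p)
                files.append(p)
            truth = truth_sc
            truth.planted_degs = truth_bulk.planted_degs
            _io.write_truth(truth, sim_dir / "truth.json")
            files.append(sim_dir / "truth.json")
            rec.record(
                "simulate",
                params={k: v for k, v in config.stage("simulate").items() if k != "enabled"},
                counts={
                    "n_cells": int(expr.shape[1]),
                    "n_genes": int(expr.shape[0]),
                    "n_pathways": len(sets),
                    "n_bulk_cohorts": len(cohorts),
                },
                files=files,
            )
        _run("simulate", _simulate)
    else:
        inputs = config.stage("inputs")
        if inputs["expression"] is not None:
            expr = _io.read_expression(inputs["expression"])
            ann = _io.read_annotation(inputs["annotation"])
        if inputs["gene_sets"] is not None:
            cat = _io.read_category_map(inputs["categories"]) if inputs["categories"] else None
            sets = _io.read_gmt(inputs["gene_sets"], category_map=cat)
        for entry in inputs["bulk"]:
            if isinstance(entry, str):
                cohorts.append(_io.read_bulk_csv(entry, scale=inputs["bulk_scale"]))
            else:
                cohorts.append(
                    _io.read_bulk_csv(
                        entry["path"],
                        scale=entry.get("scale", inputs["bulk_scale"]),
                        cohort_id=entry.get("cohort_id"),
                    )
                )

    # ------------------------------------------------------------------ score
    if config.enabled("score"):
        def _score():
            nonlocal pa
            p = config.stage("score")
            pa = score_pathways(
                expr, ann, sets, min_genes=p["min_genes"], normalize=p["normalize"]
            )
            files = [out / "scores.csv"]
            _write_csv(pa.scores, files[0])
            if sets.categories is not None:
                cat = aggregate_categories(pa, sets)
                _write_csv(cat, out / "categories.csv")
                files.append(out / "categories.csv")
            _write_json(
                {"dropped_genes": pa.dropped_genes, "unscored_pathways": pa.unscored},
                out / "scoring_report.json",
            )
            files.append(out / "scoring_report.json")
            warnings = []
            if pa.dropped_genes:
                warnings.append(f"{len(pa.dropped_genes)} zero-mean genes dropped")
            if pa.unscored:
                warnings.append(f"{len(pa.unscored)} pathways unscored (below min_genes)")
            rec.record(
                "score",
                params={k: v for k, v in p.items() if k != "enabled"},
                counts={
                    "pathways_scored": int(pa.scores.shape[0]),
                    "cell_types": int(pa.scores.shape[1]),
                    "genes_dropped": len(pa.dropped_genes),
                },
                files=files,
                warnings=warnings,
            )
        _run("score", _score)

    # ------------------------------------------------------------------ permtest
    if config.enabled("permtest"):
        def _permtest():
            nonlocal pa
            p = config.stage("permtest")
            s = config.stage("score")
            result = permutation_pvalues(
                expr, ann, sets,
                n_perm=p["n_perm"],
                seed=stage_seed(config.seed, "permtest"),
                min_genes=s["min_genes"],
                normalize=s["normalize"],
                adjust=p["adjust"],
            )
            pa = result
            files = [out / "pvalues.csv"]
            _write_csv(result.pvalues, files[0])
            if result.pvalues_adj is not None:
                _write_csv(result.pvalues_adj, out / "pvalues_bh.csv")
                files.append(out / "pvalues_bh.csv")
            if not (out / "scores.csv").exists():
                _write_csv(result.scores, out / "scores.csv")
                files.append(out / "scores.csv")
            n_sig = int((result.pvalues.to_numpy() < 0.05).sum())
            rec.record(
                "permtest",
                params={k: v for k, v in p.items() if k != "enabled"},
                counts={
                    "pathways_scored": int(result.scores.shape[0]),
                    "significant_pairs_p05": n_sig,
                },
                files=files,
            )
        _run("permtest", _permtest)

    # ------------------------------------------------------------------ deg
    tables = []
    if config.enabled("deg"):
        def _deg():
            p = config.stage("deg")
            files = []
            for cohort in cohorts:
                t = call_degs(cohort, p_threshold=p["p_threshold"], fc_threshold=p["fc_threshold"])
                tables.append(t)
                f1 = out / f"deg_{t.cohort_id}.csv"
                _write_csv(t.table, f1)
                f2 = out / f"volcano_{t.cohort_id}.csv"
                _write_csv(volcano_table(t), f2)
                files.extend([f1, f2])
            rec.record(
                "deg",
                params={k: v for k, v in p.items() if k != "enabled"},
                counts={
                    t.cohort_id: int((t.table["direction"] != "ns").sum()) for t in tables
                },
                files=files,
            )
        _run("deg", _deg)

    # ------------------------------------------------------------------ intersect
    if config.enabled("intersect"):
        def _intersect():
            res = intersect_degs(tables)
            direction = {g: "up" for g in res.up}
            direction.update({g: "down" for g in res.down})
            direction.update({g: "conflict" for g in res.conflicting})
            ev = res.evidence.copy()
            ev.insert(0, "direction", [direction[g] for g in ev.index])
            _write_csv(ev, out / "intersection.csv")
            venn = {
                "per_cohort": res.per_cohort_counts,
                "overlap_all": len(res.any_direction),
                "consistent_up": len(res.up),
                "consistent_down": len(res.down),
                "sign_conflicts": len(res.conflicting),
                "up_genes": res.up,
                "down_genes": res.down,
                "conflict_genes": res.conflicting,
            }
            _write_json(venn, out / "venn_counts.json")
            warnings = (
                [f"{len(res.conflicting)} genes significant everywhere with conflicting sign"]
                if res.conflicting else []
            )
            rec.record(
                "intersect",
                params={},
                counts={
                    "overlap_all": len(res.any_direction),
                    "consistent_up": len(res.up),
                    "consistent_down": len(res.down),
                    "sign_conflicts": len(res.conflicting),
                },
                files=[out / "intersection.csv", out / "venn_counts.json"],
                warnings=warnings,
            )
        _run("intersect", _intersect)

    # ------------------------------------------------------------------ proportions
    if config.enabled("proportions"):
        def _proportions():
            p = config.stage("proportions")
            pt = proportions_by_sample(ann)
            frac = pt.fractions.copy()
            frac.insert(0, "condition", pt.condition)
            _write_csv(frac, out / "proportions.csv")
            types = p["cell_types"] or list(pt.fractions.columns)
            results = {}
            warnings = []
            for ct in types:
                n_case = int((pt.condition == "case").sum())
                n_control = int((pt.condition == "control").sum())
                if min(n_case, n_control) < 2:
                    warnings.append(f"skipped {ct}: fewer than 2 samples in a condition")
                    continue
                r = compare_proportions(pt, ct)
                results[ct] = {
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "median_case": r.median_case,
                    "median_control": r.median_control,
                    "method": r.method,
                }
            _write_json(results, out / "proportion_tests.json")
            rec.record(
                "proportions",
                params={k: v for k, v in p.items() if k != "enabled"},
                counts={"n_samples": int(pt.counts.shape[0]), "n_cell_types_tested": len(results)},
                files=[out / "proportions.csv", out / "proportion_tests.json"],
                warnings=warnings,
            )
        _run("proportions", _proportions)

    # ------------------------------------------------------------------ coexpr
    if config.enabled("coexpr"):
        def _coexpr():
            p = config.stage("coexpr")
            markers = p["markers"]
            if isinstance(markers, str):
                markers = [
                    line.strip() for line in Path(markers).read_text().splitlines() if line.strip()
                ]
            net = coexpression_network(
                expr, ann, cluster=p["cluster"], focal_gene=p["focal_gene"],
                markers=markers, alpha=p["alpha"],
            )
            _write_csv(net.edges, out / "coexpression.csv")
            rec.record(
                "coexpr",
                params={k: v for k, v in p.items() if k not in ("enabled", "markers")},
                counts={
                    "n_markers": int(net.edges.shape[0]),
                    "n_positive": net.n_positive,
                    "n_negative": net.n_negative,
                },
                files=[out / "coexpression.csv"],
            )
        _run("coexpr", _coexpr)

    _write_json(report.to_dict(), out / "report.json")
    return report
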