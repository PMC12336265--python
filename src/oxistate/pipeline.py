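"""End-to-end pipeline: QC -> scoring -> states -> DE/composition ->
modules -> candidate genes -> ensemble selection -> bulk validation.

A single YAML-able configuration drives every stage; one global seed fans
out to stage-specific derived seeds.  Every intermediate is persisted as TSV
under the output directory and a machine-readable run report (JSON) plus a
human summary (Markdown) is written at the end.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
import yaml

from ._utils import derive_seed
from .coexpression import (
    build_metacells,
    detect_modules,
    module_eigengenes,
    module_state_summary,
    scan_soft_powers,
)
from .feature_select import select_hub_genes
from .io import (
    load_bulk,
    load_matrix,
    read_gene_set,
    write_bulk_fixtures,
    write_cell_fixtures,
    write_gmt,
)
from .preprocess import QCParams, log_normalize, qc_filter, select_hvg
from .bulk_validate import validate_hub_genes
from .scoring import score_cells
from .simulate import SimConfig, simulate_study
from .state_analysis import composition_test, differential_expression

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

# stage parameter defaults; every key can be overridden from the config
STAGE_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "qc": {
        "max_mito_frac": 0.20,
        "min_genes_per_cell": 200,
        "max_genes_per_cell": 7000,
        "min_cells_per_gene": 3,
        "mito_prefix": "MT-",
    },
    "normalize": {"scale_factor": 10_000.0},
    "hvg": {"n": 3000},
    "score": {
        "methods": "all",
        "top_frac": 0.05,
        "r_max": 1500,
        "alpha": 0.25,
        "n_bins": 24,
        "n_ctrl": 100,
    },
    "deg": {
        "min_log2fc": 0.25,
        "alpha": 0.05,
        "min_pct": 0.10,
        "adjust": "bonferroni",
    },
    "composition": {"expected_min": 5.0},
    "coexpr": {
        "k": 25,
        "max_shared": 10,
        "group_by": "sample",
        "min_size": 30,
        "cut_height_frac": 0.99,
        "r2_target": 0.9,
        "fallback_power": 6,
    },
    "select": {},
    "validate": {},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (a :class:`SimConfig` parameter block) or
    ``inputs`` (paths to single-cell MTX triplet + metadata, bulk expression
    + labels, and a gene-set file) must be given.
    """

    out_dir: Path
    seed: int
    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    stages: Dict[str, Dict[str, Any]] = field(default_factory=dict)

    REQUIRED_INPUT_KEYS = ("mtx", "genes", "cells", "meta", "bulk_expr",
                           "bulk_labels", "gene_set")

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must provide exactly one of 'simulate' or 'inputs'"
            )
        if self.seed is None:
            raise ValueError("config field 'seed' is required")
        if self.inputs is not None:
            missing = [k for k in self.REQUIRED_INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs block missing field(s): {missing}")
        unknown = set(self.stages) - set(STAGE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown stage section(s): {sorted(unknown)}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"out_dir", "seed", "simulate", "inputs", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config field 'out_dir' is required")
        if "seed" not in raw:
            raise ValueError("config field 'seed' is required")
        return cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw["seed"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            stages=raw.get("stages", {}),
        )

    def stage_params(self, stage: str) -> Dict[str, Any]:
        params = dict(STAGE_DEFAULTS[stage])
        params.update(self.stages.get(stage, {}))
        return params


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    stages: Dict[str, dict] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    timings: Dict[str, float] = field(default_factory=dict)
    summary: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "checksums": self.checksums,
            "warnings": self.warnings,
            "timings": self.timings,
            "summary": self.summary,
        }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _save(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, sep="\t")
    report.checksums[path.name] = _checksum(path)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order, persisting every intermediate."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config={
            "seed": cfg.seed,
            "out_dir": str(cfg.out_dir),
            "simulate": cfg.simulate,
            "inputs": {k: str(v) for k, v in cfg.inputs.items()}
            if cfg.inputs
            else None,
            "stages": {s: cfg.stage_params(s) for s in STAGE_DEFAULTS},
        }
    )

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.caught = warnings.catch_warnings(record=True)
                self.log = self.caught.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                report.timings[stage] = round(time.perf_counter() - self.t0, 3)
                for w in self.log:
                    report.warnings.append(f"{stage}: {w.message}")
                self.caught.__exit__(exc_type, exc, tb)
                if exc is not None:
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        return _T()

    # ---- data -------------------------------------------------------------
    with timed("data"):
        if cfg.simulate is not None:
            sim_params = dict(cfg.simulate)
            sim_params.setdefault("seed", derive_seed(cfg.seed, "simulate"))
            if "module_size" in sim_params and isinstance(
                sim_params["module_size"], list
            ):
                sim_params["module_size"] = tuple(sim_params["module_size"])
            sim_cfg = SimConfig(**sim_params)
            cells, bulk, os_set, truth = simulate_study(sim_cfg)
            write_cell_fixtures(cells, out / "data", truth)
            write_bulk_fixtures(bulk, out / "data")
            write_gmt(os_set, out / "data" / "os_set.gmt")
            report.stages["data"] = {
                "source": "simulated",
                "n_cells": cells.n_cells,
                "n_genes": cells.n_genes,
                "bulk_samples": int(bulk.expr.shape[0]),
            }
        else:
            paths = cfg.inputs
            for key in cfg.REQUIRED_INPUT_KEYS:
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"inputs.{key}: no such file {paths[key]!r}"
                    )
            cells = load_matrix(
                paths["mtx"], paths["genes"], paths["cells"], paths["meta"]
            )
            bulk = load_bulk(paths["bulk_expr"], paths["bulk_labels"])
            os_set = read_gene_set(paths["gene_set"])
            report.stages["data"] = {
                "source": "loaded",
                "n_cells": cells.n_cells,
                "n_genes": cells.n_genes,
                "bulk_samples": int(bulk.expr.shape[0]),
            }

    # ---- preprocess -------------------------------------------------------
    with timed("qc"):
        qc = qc_filter(cells, QCParams(**cfg.stage_params("qc")))
        report.stages["qc"] = qc.qc_report
    with timed("normalize"):
        qc = log_normalize(qc, **cfg.stage_params("normalize"))
    with timed("hvg"):
        hvg = select_hvg(qc, **cfg.stage_params("hvg"))
        (out / "hvg.txt").write_text("\n".join(hvg) + "\n")
        report.stages["hvg"] = {"n_selected": len(hvg)}

    # ---- scoring / states -------------------------------------------------
    with timed("score"):
        sp = cfg.stage_params("score")
        methods = sp.pop("methods")
        if methods == "all":
            from .scoring import METHODS as methods
        panel = score_cells(
            qc, os_set, methods=methods, seed=derive_seed(cfg.seed, "score"), **sp
        )
        scores = panel.raw.copy()
        scores["composite"] = panel.composite
        scores["state"] = panel.state.astype(str).to_numpy()
        _save(scores, out / "scores.tsv", report)
        state_counts = panel.state.value_counts().to_dict()
        report.stages["score"] = {
            "q1": panel.q1,
            "q3": panel.q3,
            "state_counts": {str(k): int(v) for k, v in state_counts.items()},
        }

    # ---- differential expression & composition ----------------------------
    with timed("deg"):
        deg = differential_expression(qc, panel.state, **cfg.stage_params("deg"))
        _save(deg, out / "deg.tsv", report)
        report.stages["deg"] = {
            "n_tested": int(deg.shape[0]),
            "n_passing": int(deg["passes"].sum()),
        }
    with timed("composition"):
        if "cell_type" in qc.cell_meta.columns:
            comp = composition_test(
                qc.cell_meta["cell_type"],
                panel.state,
                seed=derive_seed(cfg.seed, "composition"),
                **cfg.stage_params("composition"),
            )
            _save(comp.drop(columns="table"), out / "composition.tsv", report)
            report.stages["composition"] = {
                "n_types": int(comp.shape[0]),
                "n_significant": int((comp["q_value"] < 0.05).sum()),
            }
        else:
            report.stages["composition"] = {"skipped": "no cell_type column"}

    # ---- co-expression modules --------------------------------------------
    with timed("coexpr"):
        cp = cfg.stage_params("coexpr")
        groups = (
            qc.cell_meta["sample"].astype(str)
            if cp["group_by"] == "sample"
            else None
        )
        mc = build_metacells(
            qc, k=cp["k"], max_shared=cp["max_shared"], groups=groups
        )
        scan = scan_soft_powers(mc, r2_target=cp["r2_target"])
        best_r2 = float(scan.table["r2"].max())
        power = (
            scan.chosen_power
            if best_r2 >= cp["r2_target"]
            else cp["fallback_power"]
        )
        _save(scan.table, out / "softpower.tsv", report)
        assignment = detect_modules(
            mc, power, min_size=cp["min_size"],
            cut_height_frac=cp["cut_height_frac"],
        )
        _save(assignment.labels.to_frame(), out / "modules.tsv", report)
        eig, _ = module_eigengenes(mc, assignment)
        _save(eig, out / "eigengenes.tsv", report)
        mstate = module_state_summary(qc, assignment, panel.state)
        _save(mstate, out / "module_state.tsv", report)
        # module selection rule: modules whose mean activity peaks in the
        # high state feed the candidate gene pool
        peak_high = mstate.index[mstate.idxmax(axis=1) == "high"]
        report.stages["coexpr"] = {
            "n_metacells": mc.n_metacells,
            "power": int(power),
            "scan_best_r2": best_r2,
            "n_modules": len(assignment.modules),
            "modules_peaking_high": list(peak_high),
        }

    # ---- candidate genes & ensemble selection ------------------------------
    with timed("select"):
        module_genes = set()
        for mod in peak_high:
            module_genes.update(assignment.genes_of(mod))
        deg_genes = set(deg.index[deg["passes"]])
        candidates = sorted(deg_genes & module_genes)
        if len(candidates) < 2:
            warnings.warn(
                "DEG/module intersection has fewer than 2 genes; "
                "falling back to the passing DEGs as candidates"
            )
            candidates = sorted(deg_genes)
        report.stages["select"] = {
            "n_deg": len(deg_genes),
            "n_module_genes": len(module_genes),
            "n_candidates": len(candidates),
        }
        sel = select_hub_genes(
            bulk,
            candidates,
            seed=derive_seed(cfg.seed, "select"),
            params=cfg.stage_params("select") or None,
        )
        for method, genes in sel.selected.items():
            (out / f"selected_{method}.txt").write_text(
                "\n".join(genes) + ("\n" if genes else "")
            )
        (out / "intersection.txt").write_text(
            "\n".join(sel.intersection) + ("\n" if sel.intersection else "")
        )
        report.checksums["intersection.txt"] = _checksum(out / "intersection.txt")
        report.stages["select"].update(
            {
                "per_method": {m: len(g) for m, g in sel.selected.items()},
                "hub_genes": sel.intersection,
            }
        )

    # ---- bulk validation ---------------------------------------------------
    with timed("validate"):
        if sel.intersection:
            table, os_score = validate_hub_genes(bulk, sel.intersection, os_set)
            _save(table, out / "gene_stats.tsv", report)
            _save(os_score.to_frame(), out / "os_scores.tsv", report)
            report.stages["validate"] = {
                "auc": {g: float(v) for g, v in table["auc"].items()},
            }
        else:
            report.stages["validate"] = {"skipped": "empty hub gene list"}

    # ---- summary -----------------------------------------------------------
    sc = report.stages["score"]["state_counts"]
    report.summary = {
        "cells_after_qc": report.stages["qc"]["cells_out"],
        "state_counts": sc,
        "state_total": sum(sc.values()),
        "n_passing_degs": report.stages["deg"]["n_passing"],
        "n_modules": report.stages["coexpr"]["n_modules"],
        "hub_genes": report.stages["select"]["hub_genes"],
        "hub_auc": report.stages["validate"].get("auc", {}),
    }
    assert report.summary["state_total"] == report.summary["cells_after_qc"]
    write_report(report, out / "report.json")
    return report


def write_report(report: RunReport, path) -> None:
    """Write the JSON report and a Markdown summary next to it."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    s = report.summary
    md = ["# Pipeline run summary", ""]
    if s:
        counts = s["state_counts"]
        md += [
            f"- cells after QC: {s['cells_after_qc']}",
            "- OS states: "
            + ", ".join(f"{k}={counts.get(k, 0)}" for k in ("low", "transition", "high"))
            + f" (total {s['state_total']})",
            f"- passing DEGs (high vs low): {s['n_passing_degs']}",
            f"- co-expression modules: {s['n_modules']}",
            f"- hub genes: {', '.join(s['hub_genes']) if s['hub_genes'] else '(none)'}",
        ]
        if s["hub_auc"]:
            md.append(
                "- bulk AUCs: "
                + ", ".join(f"{g}={v:.3f}" for g, v in s["hub_auc"].items())
            )
    path.with_suffix(".md").write_text("\n".join(md) + "\n")


def read_report(path) -> RunReport:
    d = json.loads(Path(path).read_text())
    return RunReport(
        config=d["config"],
        stages=d["stages"],
        checksums=d["checksums"],
        warnings=d["warnings"],
        timings=d["timings"],
        summary=d["summary"],
    )
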