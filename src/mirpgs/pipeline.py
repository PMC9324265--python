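"""End-to-end pipeline: QC → association → orientation → pruning → scores → ROC.

``run_pipeline`` executes the full analysis on either real input files or a
simulated dataset, writing every intermediate table plus a run manifest so a
rerun with the same config and seed reproduces every output byte.
``make_report`` renders a human-readable summary: the association table with
study-wide-significant rows starred, both score-level ORs, and the ROC
operating points.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .assoc import bonferroni_threshold, snp_association, write_association_table
from .datamodel import GenotypeMatrix
from .errors import ConfigError
from .io import (
    attach_phenotypes,
    read_dosage_tsv,
    read_phenotypes,
    read_variant_table,
    write_dosage_tsv,
    write_phenotypes,
)
from .ld import greedy_prune, ld_matrix, priority_by_pvalue
from .orientation import orient_panel, write_oriented_panel
from .qc import apply_qc
from .roc import roc_summary
from .score import build_unweighted_model, build_weighted_model, compute_pgs, pgs_association
from .simulate import SimConfig, default_config, simulate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report",
           "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of input paths / simulation."""

    genotypes: str | None = None       # dosage TSV path
    phenotypes: str | None = None
    variants: str | None = None        # optional annotation TSV
    sim: SimConfig | None = None
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-3
    covariates: tuple[str, ...] = ("age", "sex", "ethnicity")
    ld_threshold: float = 0.2
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "mirpgs_out"

    def validate(self) -> None:
        has_files = self.genotypes is not None
        has_sim = self.sim is not None
        if has_files == has_sim:
            raise ConfigError("supply exactly one of {genotype files, simulation config}")
        if has_files and self.phenotypes is None:
            raise ConfigError("file input needs a phenotype table")
        if not 0.0 <= self.ld_threshold <= 1.0:
            raise ConfigError(f"LD threshold must lie in [0, 1], got {self.ld_threshold}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    sim = None
    if "sim" in raw and raw["sim"] is not None:
        sim_raw = dict(raw["sim"])
        if sim_raw.pop("default_panel", False):
            base = default_config(seed=int(raw.get("seed", 0)))
            sim = SimConfig(
                variants=base.variants,
                proxies=base.proxies,
                n_case=int(sim_raw.get("n_case", base.n_case)),
                n_control=int(sim_raw.get("n_control", base.n_control)),
                missing_rate=float(sim_raw.get("missing_rate", base.missing_rate)),
                covariates=base.covariates,
                mode=str(sim_raw.get("mode", base.mode)),
                seed=int(raw.get("seed", 0)),
            )
        else:
            raise ConfigError(
                "config-file simulation currently supports default_panel: true; "
                "build custom SimConfig objects through the Python API"
            )
    cfg = PipelineConfig(
        genotypes=raw.get("genotypes"),
        phenotypes=raw.get("phenotypes"),
        variants=raw.get("variants"),
        sim=sim,
        call_rate_min=float(raw.get("call_rate_min", 0.95)),
        hwe_p_min=float(raw.get("hwe_p_min", 1e-3)),
        covariates=tuple(raw.get("covariates", ("age", "sex", "ethnicity"))),
        ld_threshold=float(raw.get("ld_threshold", 0.2)),
        alpha=float(raw.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "mirpgs_out")),
    )
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    """Bundle of every stage output plus the run manifest."""

    matrix: GenotypeMatrix
    qc_report: Any
    assoc: Any
    oriented: Any
    prune: Any
    models: dict
    scores: dict
    pgs_assoc: dict          # {mode: {"adjusted": ..., "unadjusted": ...}}
    roc: dict
    bonferroni: float
    manifest: dict = field(default_factory=dict)


def _load_input(config: PipelineConfig) -> GenotypeMatrix:
    if config.sim is not None:
        return simulate(config.sim)
    variants = read_variant_table(config.variants) if config.variants else None
    matrix = read_dosage_tsv(config.genotypes, variants=variants)
    return attach_phenotypes(matrix, read_phenotypes(config.phenotypes))


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis; optionally write all outputs to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    matrix = _load_input(config)
    matrix.require_status()
    counts = {"input": {"samples": matrix.n_samples, "variants": matrix.n_variants}}

    qc_matrix, qc_report = apply_qc(
        matrix, call_rate_min=config.call_rate_min, hwe_p_min=config.hwe_p_min
    )
    counts["qc"] = {"variants": qc_matrix.n_variants}

    assoc = snp_association(qc_matrix, covariates=config.covariates)
    oriented = orient_panel(assoc)

    ld = ld_matrix(qc_matrix)
    prune = greedy_prune(ld, priority_by_pvalue(assoc), threshold=config.ld_threshold)
    counts["prune"] = {"kept": len(prune.kept), "dropped": len(prune.dropped)}

    n_tests = len(prune.kept)
    bonf = bonferroni_threshold(config.alpha, n_tests) if n_tests else float("nan")

    models, scores, pgs_res, rocs = {}, {}, {}, {}
    for mode, builder in (
        ("weighted", build_weighted_model),
        ("unweighted", build_unweighted_model),
    ):
        model = builder(oriented, kept=prune.kept)
        result = compute_pgs(qc_matrix, model)
        adj = pgs_association(result, qc_matrix, covariates=config.covariates)
        unadj = pgs_association(result, qc_matrix)
        case = result.standardized[qc_matrix.case_mask]
        ctrl = result.standardized[qc_matrix.control_mask]
        models[mode] = model
        scores[mode] = result
        pgs_res[mode] = {"adjusted": adj, "unadjusted": unadj}
        rocs[mode] = roc_summary(case, ctrl)

    manifest = {
        "mirpgs_version": __version__,
        "seed": config.seed,
        # hash only the scientific settings, not the output location
        "config_hash": hashlib.sha256(
            repr((config.genotypes, config.phenotypes, config.variants,
                  config.sim, config.call_rate_min, config.hwe_p_min,
                  config.covariates, config.ld_threshold, config.alpha,
                  config.seed)).encode()
        ).hexdigest()[:16],
        "counts": counts,
        "bonferroni_threshold": bonf,
        "n_tests": n_tests,
        "covariates": list(config.covariates),
    }
    result = PipelineResult(
        matrix=matrix, qc_report=qc_report, assoc=assoc, oriented=oriented,
        prune=prune, models=models, scores=scores, pgs_assoc=pgs_res,
        roc=rocs, bonferroni=bonf, manifest=manifest,
    )

    if write:
        write_dosage_tsv(matrix, out / "genotypes.tsv")
        write_phenotypes(matrix, out / "phenotypes.tsv")
        qc_report.to_tsv(out / "qc_report.tsv")
        write_association_table(assoc, out / "association.tsv")
        write_oriented_panel(oriented, out / "oriented_panel.tsv")
        ld.to_tsv(out / "ld_matrix.tsv")
        prune.to_tsv(out / "prune_log.tsv")
        for mode in models:
            models[mode].to_tsv(out / f"model_{mode}.tsv")
            scores[mode].to_tsv(out / f"scores_{mode}.tsv")
            rocs[mode].curve_to_tsv(out / f"roc_curve_{mode}.tsv")
            with open(out / f"roc_summary_{mode}.json", "w") as fh:
                json.dump(rocs[mode].to_json_dict(), fh, indent=2, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        (out / "report.md").write_text(make_report(result))
    return result


def _floor_sig(x: float, digits: int = 2) -> float:
    """Round toward zero at ``digits`` significant figures.

    Used to print "p < threshold" bounds conservatively (never rounding a
    threshold upward past its exact value).
    """
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    factor = 10 ** (exp - digits + 1)
    return math.floor(x / factor) * factor


def make_report(result: PipelineResult) -> str:
    """Render the run as readable markdown."""
    lines = ["# mirpgs analysis report", ""]
    m = result.manifest
    lines.append(
        f"Samples: {m['counts']['input']['samples']} "
        f"(variants in: {m['counts']['input']['variants']}, "
        f"after QC: {m['counts']['qc']['variants']}, "
        f"after LD pruning: {m['counts']['prune']['kept']})."
    )
    lines.append("")

    lines.append("## Per-variant association")
    lines.append("")
    if len(result.assoc) == 0:
        lines.append("No variants survived quality control.")
    else:
        thr = result.bonferroni
        lines.append(
            f"Study-wide (Bonferroni) threshold: p < {_floor_sig(thr):.2g} "
            f"({m['n_tests']} independent tests)."
        )
        lines.append("")
        lines.append("| gene | rsid | EA/OA | EAF case/ctrl | OR (95% CI) | p | |")
        lines.append("|---|---|---|---|---|---|---|")
        for row in result.assoc.itertuples():
            star = "**" if (math.isfinite(thr) and row.p < thr) else ""
            mark = "*" if (math.isfinite(thr) and row.p < thr) else ""
            lines.append(
                f"| {row.gene_label} | {row.rsid} | {row.effect_allele}/{row.other_allele} "
                f"| {row.eaf_case:.2f}/{row.eaf_control:.2f} "
                f"| {star}{row.or_:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f}){star} "
                f"| {star}{row.p:.2g}{star} | {mark} |"
            )
    lines.append("")

    lines.append("## LD pruning")
    lines.append("")
    dropped = result.prune.log[~result.prune.log["kept"]]
    lines.append(
        f"{len(result.prune.kept)} variants kept, {len(dropped)} excluded at "
        f"r² > {result.prune.threshold}."
    )
    for row in dropped.itertuples():
        lines.append(f"- {row.rsid} dropped (r² = {row.r2:.2f} with {row.excluded_by})")
    lines.append("")

    lines.append("## Polygenic score")
    lines.append("")
    for mode in ("weighted", "unweighted"):
        if mode not in result.pgs_assoc:
            lines.append(f"({mode} model outputs missing)")
            continue
        adj = result.pgs_assoc[mode]["adjusted"]
        unadj = result.pgs_assoc[mode]["unadjusted"]
        roc = result.roc[mode]
        lines.append(
            f"- **{mode}**: OR per SD = {adj.or_per_sd:.2f} "
            f"({adj.ci_low:.2f}-{adj.ci_high:.2f}), p = {adj.p:.3g} "
            f"[adjusted]; {unadj.or_per_sd:.2f} "
            f"({unadj.ci_low:.2f}-{unadj.ci_high:.2f}) [unadjusted]. "
            f"AUC = {roc.auc:.3f} ({roc.ci_low:.2f}-{roc.ci_high:.2f}); "
            f"best cutoff {roc.youden_cutoff:.3g} "
            f"(sensitivity {roc.sensitivity:.2f}, specificity {roc.specificity:.2f})."
        )
    lines.append("")
    return "\n".join(lines)
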