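"""End-to-end orchestration: normalize, screen outliers, select genes
per tissue, call browning-specific DEGs and write a run manifest.

The manifest records the DEG bookkeeping chain per tissue
(selected → fold-change filtered → browning-specific after ripening
subtraction), the outliers removed and the explained-variance figures,
so a run is auditable end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg import (
    DEGSet,
    build_deg_table,
    filter_degs,
    ripening_contrast,
    subtract_ripening,
    summarize_bins,
    tissue_overlap,
)
from .ingest import (
    ExpressionMatrix,
    classify_samples,
    compute_rpkm,
    expressed_gene_counts,
    read_counts,
    read_gene_annotation,
    read_samples,
)
from .outliers import pca_outlier_scan
from .pls import design_matrix, iterative_selection
from .qpcr import (
    group_ttest,
    qpcr_log2_ratio,
    read_qpcr,
    relative_expression_table,
    validate_correlation,
)

logger = logging.getLogger("pomebrown")

__all__ = ["RunConfig", "RunManifest", "PipelineResult", "run_pipeline", "run_pipeline_frames"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    counts_path: str | None = None
    genes_path: str | None = None
    samples_path: str | None = None
    qpcr_path: str | None = None
    out_dir: str | None = None
    tissues: tuple[str, ...] = ("inner", "outer")
    bi_cutoff: float = 3.0
    alpha: float = 0.05
    p_max: float = 0.05
    fc_min: float = 1.5
    min_rpkm: float = 0.0
    cv: str = "loo"
    seed: int = 0
    a_max: int | None = None
    autoscale: bool = True
    outlier_components: int = 2
    outlier_alpha: float = 0.05
    skip_outlier_scan: bool = False
    qpcr_efficiency: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "tissues" in data:
            data["tissues"] = tuple(data["tissues"])
        return cls(**data)


@dataclass
class RunManifest:
    """Auditable record of one run: config, versions, per-stage counts."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=1,
            default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class PipelineResult:
    manifest: RunManifest
    expression: ExpressionMatrix
    samples: object
    selections: dict  # tissue -> SelectionResult
    deg_selected: dict  # tissue -> DEGSet (all selected genes)
    deg_filtered: dict  # tissue -> DEGSet (p/FC filtered)
    deg_browning: dict  # tissue -> DEGSet (after ripening subtraction)
    ripening_genes: dict  # tissue -> pd.Index
    overlap: pd.DataFrame | None
    bin_summaries: dict
    validation: dict | None = None


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline from TSV inputs on disk."""
    counts = read_counts(config.counts_path)
    genes = read_gene_annotation(config.genes_path)
    samples = read_samples(config.samples_path)
    qpcr = read_qpcr(config.qpcr_path) if config.qpcr_path else None
    return run_pipeline_frames(counts, genes, samples, config, qpcr=qpcr)


def run_pipeline_frames(counts, genes, samples, config=None, qpcr=None) -> PipelineResult:
    """Run the full pipeline on in-memory tables.

    Stages: RPKM normalization → class assignment → global PCA outlier
    removal → per-tissue iterative PLS-DA selection (healthy vs
    affected) → DEG table → p/FC filter → ripening contrast and
    subtraction → tissue overlap → bin summary → optional qPCR
    validation.  Deterministic given the seed.  The filter chain is
    asserted non-increasing and the subtraction disjoint on every run.
    """
    cfg = config or RunConfig()
    manifest = RunManifest(config=dataclasses.asdict(cfg))
    stage = "ingest"
    try:
        manifest.record(
            stage,
            n_genes=counts.shape[0],
            n_samples=counts.shape[1],
            counts_hash=_hash_frame(counts.counts),
        )

        stage = "normalize"
        expr = compute_rpkm(counts, genes, samples)
        samples = classify_samples(samples, bi_cutoff=cfg.bi_cutoff)
        expressed = expressed_gene_counts(expr, min_rpkm=cfg.min_rpkm)
        manifest.record(
            stage,
            expressed_genes_mean=float(expressed.mean()),
            expressed_genes_sd=float(expressed.std(ddof=1)),
            class_counts={
                f"{t}/{c}": int(n)
                for (t, c), n in samples.table.groupby(["tissue", "class"]).size().items()
            },
        )

        stage = "outlier_scan"
        removed: list = []
        if not cfg.skip_outlier_scan:
            report = pca_outlier_scan(
                expr, n_components=cfg.outlier_components, alpha=cfg.outlier_alpha
            )
            removed = report.flagged
            if removed:
                keep = [s for s in expr.sample_ids if s not in removed]
                expr = ExpressionMatrix(expr.rpkm[keep])
                samples = samples.subset(keep)
        manifest.record(stage, outliers_removed=removed, skipped=cfg.skip_outlier_scan)

        selections, deg_sel, deg_filt, deg_brown, ripening = {}, {}, {}, {}, {}
        for tissue in cfg.tissues:
            stage = f"select[{tissue}]"
            X, y = design_matrix(expr, samples, tissue)
            sel = iterative_selection(
                X,
                y,
                alpha=cfg.alpha,
                a_max=cfg.a_max,
                scheme=cfg.cv,
                seed=cfg.seed,
                autoscale=cfg.autoscale,
            )
            selections[tissue] = sel

            stage = f"deg[{tissue}]"
            if len(sel.gene_ids):
                degs = build_deg_table(
                    expr, samples, sel.p_values.loc[sel.gene_ids], tissue
                )
            else:
                degs = DEGSet(tissue=tissue, table=pd.DataFrame(
                    columns=["p_value", "mean_rpkm_healthy", "mean_rpkm_affected",
                             "fold_change", "direction"]))
            deg_sel[tissue] = degs
            filtered = filter_degs(degs, p_max=cfg.p_max, fc_min=cfg.fc_min) if len(
                degs
            ) else degs
            deg_filt[tissue] = filtered

            stage = f"ripening[{tissue}]"
            rip = ripening_contrast(
                expr,
                samples,
                tissue,
                alpha=cfg.alpha,
                p_max=cfg.p_max,
                fc_min=cfg.fc_min,
                a_max=cfg.a_max,
                scheme=cfg.cv,
                seed=cfg.seed,
                autoscale=cfg.autoscale,
            )
            ripening[tissue] = rip
            browning = subtract_ripening(filtered, rip)
            deg_brown[tissue] = browning

            chain = (len(degs), len(filtered), len(browning))
            assert chain[0] >= chain[1] >= chain[2], "filter chain must be non-increasing"
            final = sel.model
            manifest.record(
                f"degs[{tissue}]",
                selected=chain[0],
                fold_change_filtered=chain[1],
                browning_specific=chain[2],
                ripening_genes=len(rip),
                n_factors=final.n_factors if final else 0,
                explained_y_cal=float(final.explained_y_cal[-1]) if final else 0.0,
                explained_y_val=final.explained_y_val if final else 0.0,
            )

        stage = "overlap"
        overlap = None
        if len(cfg.tissues) >= 2:
            overlap = tissue_overlap(
                deg_brown[cfg.tissues[0]], deg_brown[cfg.tissues[1]]
            )
            manifest.record(
                stage,
                n_overlap=len(overlap),
                concordant=int(overlap["concordant"].sum()) if len(overlap) else 0,
            )

        stage = "bins"
        bin_summaries = {
            t: summarize_bins(deg_brown[t], genes) for t in cfg.tissues
        }
        manifest.record(
            stage,
            **{
                t: {"with_bin": b.n_with_bin, "unassigned": b.n_unassigned}
                for t, b in bin_summaries.items()
            },
        )

        validation = None
        if qpcr is not None:
            stage = "qpcr_validation"
            validation = _validate_qpcr(qpcr, expr, samples, cfg)
            manifest.record(
                stage,
                n_genes=len(validation["report"]),
                pearson_r=validation["pearson_r"],
                r_squared=validation["r_squared"],
            )
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}\nmanifest so far:\n"
            + manifest.to_json()
        ) from err

    result = PipelineResult(
        manifest=manifest,
        expression=expr,
        samples=samples,
        selections=selections,
        deg_selected=deg_sel,
        deg_filtered=deg_filt,
        deg_browning=deg_brown,
        ripening_genes=ripening,
        overlap=overlap,
        bin_summaries=bin_summaries,
        validation=validation,
    )
    if cfg.out_dir:
        write_outputs(result, cfg.out_dir)
    return result


def _validate_qpcr(qpcr, expr, samples, cfg):
    """RNA-Seq vs qPCR cross-platform check on the measured genes."""
    rel = relative_expression_table(qpcr, efficiency=cfg.qpcr_efficiency)
    classes = samples.table["class"].reindex(rel.index)
    log2_qpcr = qpcr_log2_ratio(rel, classes)

    meta = samples.table
    stored = meta.index[(meta["timepoint"] == "stored") & meta.index.isin(rel.index)]
    healthy = [s for s in stored if meta.loc[s, "class"] == "healthy"]
    affected = [s for s in stored if meta.loc[s, "class"] == "affected"]
    shared = log2_qpcr.index.intersection(expr.gene_ids)
    mh = expr.rpkm.loc[shared, healthy].mean(axis=1)
    ma = expr.rpkm.loc[shared, affected].mean(axis=1)
    log2_rnaseq = np.log2(mh / ma)
    r, r2 = validate_correlation(log2_rnaseq, log2_qpcr)

    rows = []
    for g in log2_qpcr.index:
        t, p, star = group_ttest(rel[g], classes)
        rows.append(
            {
                "gene_id": g,
                "qpcr_log2_ratio": log2_qpcr[g],
                "rnaseq_log2_ratio": log2_rnaseq.get(g, float("nan")),
                "t": t,
                "p_value": p,
                "stars": star,
            }
        )
    report = pd.DataFrame(rows).set_index("gene_id")
    return {"report": report, "pearson_r": r, "r_squared": r2}


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue, degs in result.deg_browning.items():
        degs.table.to_csv(out / f"deg_table_{tissue}.tsv", sep="\t", index_label="gene_id")
        result.selections[tissue].trace.to_frame().to_csv(
            out / f"selection_trace_{tissue}.tsv", sep="\t", index=False
        )
        result.bin_summaries[tissue].table.to_csv(
            out / f"bins_summary_{tissue}.tsv", sep="\t", index_label="bin"
        )
    if result.overlap is not None:
        result.overlap.to_csv(out / "overlap.tsv", sep="\t", index_label="gene_id")
    if result.validation is not None:
        result.validation["report"].to_csv(
            out / "validation_report.tsv", sep="\t", index_label="gene_id"
        )
    result.manifest.to_json(out / "manifest.json")
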