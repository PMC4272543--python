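"""Synthetic storage-trial generator with planted browning and ripening
effects.

The generator emulates the design of the storage experiment the
pipeline targets: per tissue (inner and outer cortex), 4 fruit sampled
at harvest and 16 after storage, the stored fruit split into healthy and
affected classes by a browning index.  Counts are negative-binomial
around a per-sample mean proportional to library size, CDS length and a
log-normal baseline abundance; a planted set of browning genes carries
class-dependent log2 shifts (per tissue) and a disjoint planted set of
ripening genes carries storage-dependent shifts present in healthy and
affected fruit alike, so the ripening-subtraction step is genuinely
exercised.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ingest import CountMatrix, GeneAnnotation, SampleTable

__all__ = ["SimConfig", "SimTruth", "generate_experiment", "generate_qpcr"]

_BINS = (
    "stress",
    "signalling",
    "transport",
    "cell",
    "lipids",
    "energy",
    "redox",
    "secondary_metabolism",
    "cell_wall",
    "protein",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic storage trial.

    Defaults mirror the target study design: two tissues, 4 harvest +
    16 stored fruit per tissue with half of the stored fruit affected,
    2,000 genes with log-uniform CDS lengths, negative-binomial counts
    with moderate overdispersion, and 50 planted browning plus 50
    planted ripening genes whose |log2 FC| is at least 1.
    """

    n_genes: int = 2000
    length_range_bp: tuple[int, int] = (300, 6000)  # log-uniform
    tissues: tuple[str, ...] = ("inner", "outer")
    n_harvest: int = 4
    n_stored: int = 16
    affected_fraction: float = 0.5
    baseline_log2_mean: float = 0.0
    baseline_log2_sd: float = 2.0
    nb_dispersion: float = 0.05
    libsize_mean: float = 5e5
    libsize_cv: float = 0.1
    n_browning_genes: int = 50
    browning_log2fc_range: tuple[float, float] = (1.0, 2.0)  # magnitude
    n_ripening_genes: int = 50
    ripening_log2fc_range: tuple[float, float] = (1.0, 2.0)
    bi_healthy_mean: float = 1.8
    bi_healthy_sd: float = 0.5
    bi_affected_mean: float = 7.0
    bi_affected_sd: float = 1.0
    bi_cutoff: float = 3.0
    qpcr_noise_sd: float = 0.25
    bin_fraction_unassigned: float = 0.10
    bin_fraction_multi: float = 0.05
    allow_effect_overlap: bool = False
    seed: int = 0


@dataclass
class SimTruth:
    """Planted ground truth, serialized alongside the generated tables."""

    browning_genes: list
    browning_effects: pd.DataFrame  # genes × tissues, log2 (affected - healthy)
    ripening_genes: list
    ripening_effects: pd.Series  # log2 (stored - harvest)
    baseline_log2: pd.Series  # per-gene baseline relative abundance (log2)
    sample_class: pd.Series  # true class per sample
    sample_bi: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "browning_genes": list(self.browning_genes),
            "browning_effects": {
                t: self.browning_effects[t].to_dict() for t in self.browning_effects
            },
            "ripening_genes": list(self.ripening_genes),
            "ripening_effects": self.ripening_effects.to_dict(),
            "sample_class": self.sample_class.to_dict(),
            "sample_bi": self.sample_bi.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Rejection-sampled normal clipped to (lo, hi]; keeps BI classes
    on the correct side of the cutoff."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out <= lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo + 1e-6, hi)


def generate_experiment(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[CountMatrix, GeneAnnotation, SampleTable, SimTruth]:
    """Draw one synthetic experiment; byte-reproducible from the seed.

    The per-cell negative-binomial mean is
    mu[g, s] = libsize_s * (length_g/1e3) * base_g * 2^(effects active
    for sample s) / Z_s, with Z_s normalizing the relative abundances so
    counts sum to the library size in expectation.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if cfg.n_browning_genes + cfg.n_ripening_genes > cfg.n_genes and not cfg.allow_effect_overlap:
        raise ValueError("more planted effect genes than genes")
    if not (0 <= cfg.affected_fraction <= 1):
        raise ValueError("affected_fraction must lie in [0, 1]")

    gene_ids = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    lo, hi = cfg.length_range_bp
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes)).astype(int)
    base_log2 = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    # planted effect genes: disjoint sets unless overlap is allowed
    perm = rng.permutation(cfg.n_genes)
    browning_idx = perm[: cfg.n_browning_genes]
    if cfg.allow_effect_overlap:
        ripening_idx = rng.choice(cfg.n_genes, cfg.n_ripening_genes, replace=False)
    else:
        ripening_idx = perm[
            cfg.n_browning_genes : cfg.n_browning_genes + cfg.n_ripening_genes
        ]

    def _effects(n, rng_, rang):
        mag = rng_.uniform(rang[0], rang[1], n)
        sign = rng_.choice([-1.0, 1.0], n)
        return mag * sign

    browning_eff = pd.DataFrame(
        0.0, index=gene_ids, columns=list(cfg.tissues)
    )
    for t in cfg.tissues:
        browning_eff.loc[gene_ids[browning_idx], t] = _effects(
            cfg.n_browning_genes, rng, cfg.browning_log2fc_range
        )
    ripening_eff = pd.Series(0.0, index=gene_ids)
    ripening_eff.loc[gene_ids[ripening_idx]] = _effects(
        cfg.n_ripening_genes, rng, cfg.ripening_log2fc_range
    )

    # samples
    rows = []
    for t in cfg.tissues:
        n_aff = int(round(cfg.n_stored * cfg.affected_fraction))
        for i in range(cfg.n_harvest):
            rows.append((f"{t}_H{i + 1:02d}", t, "harvest", "healthy"))
        for i in range(cfg.n_stored):
            cls = "affected" if i < n_aff else "healthy"
            rows.append((f"{t}_S{i + 1:02d}", t, "stored", cls))
    sample_ids = [r[0] for r in rows]
    tissue = pd.Series({r[0]: r[1] for r in rows})
    timepoint = pd.Series({r[0]: r[2] for r in rows})
    true_class = pd.Series({r[0]: r[3] for r in rows})

    bi = pd.Series(0.0, index=pd.Index(sample_ids))
    healthy = true_class == "healthy"
    bi[healthy] = _truncnorm(
        rng, cfg.bi_healthy_mean, cfg.bi_healthy_sd, 1.0 - 1e-6, cfg.bi_cutoff,
        int(healthy.sum()),
    )
    bi[~healthy] = _truncnorm(
        rng, cfg.bi_affected_mean, cfg.bi_affected_sd, cfg.bi_cutoff, 10.0,
        int((~healthy).sum()),
    )

    libsizes = rng.lognormal(
        np.log(cfg.libsize_mean) - 0.5 * np.log1p(cfg.libsize_cv**2),
        np.sqrt(np.log1p(cfg.libsize_cv**2)),
        len(sample_ids),
    )

    # counts
    counts = np.zeros((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    rel_base = (lengths / 1e3) * 2.0**base_log2
    r = 1.0 / cfg.nb_dispersion
    for j, sid in enumerate(sample_ids):
        log2_eff = np.zeros(cfg.n_genes)
        if timepoint[sid] == "stored":
            log2_eff += ripening_eff.to_numpy()
            if true_class[sid] == "affected":
                log2_eff += browning_eff[tissue[sid]].to_numpy()
        rel = rel_base * 2.0**log2_eff
        mu = libsizes[j] * rel / rel.sum()
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    count_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    total_mapped = count_df.sum(axis=0)

    # functional bins (for the bin-summary step)
    bins = rng.choice(_BINS, cfg.n_genes)
    extra = rng.choice(_BINS, cfg.n_genes)
    u = rng.uniform(size=cfg.n_genes)
    bin_label = np.where(
        u < cfg.bin_fraction_unassigned,
        "",
        np.where(
            u < cfg.bin_fraction_unassigned + cfg.bin_fraction_multi,
            [f"{a};{b}" for a, b in zip(bins, extra)],
            bins,
        ),
    )

    annotation = GeneAnnotation(
        pd.DataFrame(
            {"cds_length_bp": lengths, "bin_label": bin_label}, index=gene_ids
        )
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "tissue": tissue,
                "timepoint": timepoint,
                "browning_index": bi.round(3),
                "total_mapped_reads": total_mapped,
                "class": "unassigned",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SimTruth(
        browning_genes=list(gene_ids[np.sort(browning_idx)]),
        browning_effects=browning_eff,
        ripening_genes=list(gene_ids[np.sort(ripening_idx)]),
        ripening_effects=ripening_eff,
        baseline_log2=pd.Series(base_log2, index=gene_ids),
        sample_class=true_class,
        sample_bi=bi,
    )
    return CountMatrix(count_df), annotation, samples, truth


def generate_qpcr(
    truth: SimTruth,
    samples: SampleTable,
    gene_ids,
    ref_gene_ids,
    tissue: str = "inner",
    noise_sd: float = 0.25,
    seed: int = 0,
    ct_offset: float = 30.0,
    stored_only: bool = True,
) -> pd.DataFrame:
    """Ct measurements consistent with the planted expression truth.

    Ct = offset − log2(true relative abundance) + N(0, noise_sd); a
    two-fold higher abundance lowers Ct by exactly one cycle.  Reference
    genes must carry no planted effect (validated).  By default only
    stored samples of the tissue are measured, matching the healthy vs
    affected validation design.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    ref_gene_ids = list(ref_gene_ids)
    for g in ref_gene_ids:
        if (
            abs(truth.ripening_effects.get(g, 0.0)) > 0
            or (truth.browning_effects.loc[g].abs() > 0).any()
        ):
            raise ValueError(f"reference gene {g!r} has a planted effect")

    meta = samples.table
    keep = meta.index[meta["tissue"] == tissue]
    if stored_only:
        keep = [s for s in keep if meta.loc[s, "timepoint"] == "stored"]
    rows = []
    for sid in keep:
        stored = meta.loc[sid, "timepoint"] == "stored"
        affected = truth.sample_class[sid] == "affected"
        for g, role in [(g, "target") for g in gene_ids] + [
            (g, "reference") for g in ref_gene_ids
        ]:
            log2_abund = float(truth.baseline_log2[g])
            if stored:
                log2_abund += float(truth.ripening_effects[g])
                if affected:
                    log2_abund += float(truth.browning_effects.loc[g, tissue])
            ct = ct_offset - log2_abund + rng.normal(0.0, noise_sd) if noise_sd > 0 else (
                ct_offset - log2_abund
            )
            rows.append((sid, g, ct, role))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct", "role"])
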