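"""qRT-PCR relative expression, two-group tests and the RNA-Seq
cross-platform correlation.

Target Ct values are normalized against the geometric mean of the
reference-gene expressions, implemented as the arithmetic mean on the Ct
scale (mathematically identical, numerically safer): with
ΔCt = Ct_target − mean(Ct_refs), relative expression is E^(−ΔCt) for
amplification efficiency E (2.0 = perfect doubling).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pomebrown")

__all__ = [
    "read_qpcr",
    "relative_expression",
    "relative_expression_table",
    "qpcr_log2_ratio",
    "validate_correlation",
    "group_ttest",
    "star_code",
]

QPCR_COLUMNS = ("sample_id", "gene_id", "ct", "role")


def read_qpcr(path) -> pd.DataFrame:
    """Read a long-format qPCR table (sample_id, gene_id, ct, role)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad_role = set(df["role"]) - {"target", "reference"}
    if bad_role:
        raise ValueError(f"unknown role value(s): {sorted(bad_role)}")
    refs = df[df["role"] == "reference"]
    per_sample = refs.groupby("sample_id")["gene_id"].nunique()
    n_refs = refs["gene_id"].nunique()
    if n_refs == 0 or (per_sample.reindex(df["sample_id"].unique()) != n_refs).any():
        raise ValueError("every sample must have every reference gene measured")
    return df


def relative_expression(
    ct_target: float, ct_refs: Sequence[float], efficiency: float = 2.0
) -> float:
    """Reference-normalized relative expression of one measurement.

    ΔCt = ct_target − mean(ct_refs); returns efficiency^(−ΔCt).
    """
    if not (1 < efficiency <= 2):
        raise ValueError("amplification efficiency must lie in (1, 2]")
    refs = np.asarray(ct_refs, float)
    if refs.size == 0:
        raise ValueError("at least one reference Ct is required")
    dct = float(ct_target) - float(refs.mean())
    return float(efficiency ** (-dct))


def relative_expression_table(qpcr: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-(sample, target gene) relative expression, samples × genes."""
    ref_mean = (
        qpcr[qpcr["role"] == "reference"].groupby("sample_id")["ct"].mean()
    )
    if ref_mean.empty:
        raise ValueError("qPCR table has no reference genes")
    targets = qpcr[qpcr["role"] == "target"]
    dct = targets["ct"].to_numpy() - ref_mean.reindex(targets["sample_id"]).to_numpy()
    rel = targets.assign(rel=efficiency ** (-dct))
    return rel.pivot_table(index="sample_id", columns="gene_id", values="rel")


def qpcr_log2_ratio(rel_expr: pd.DataFrame, classes: pd.Series) -> pd.Series:
    """Per-gene log2 ratio of healthy over affected class-mean expression."""
    classes = classes.reindex(rel_expr.index)
    groups = {c: rel_expr[classes == c].mean(axis=0) for c in ("healthy", "affected")}
    for c, m in groups.items():
        if m.isna().all():
            raise ValueError(f"class {c!r} absent from the qPCR samples")
        if (m <= 0).any():
            raise ValueError(f"zero class-mean expression in class {c!r}")
    out = np.log2(groups["healthy"] / groups["affected"])
    out.name = "qpcr_log2_ratio"
    return out


def validate_correlation(rnaseq_log2fc: pd.Series, qpcr_log2fc: pd.Series):
    """Pearson r and R² between RNA-Seq and qPCR log2 fold changes.

    The two series are matched on gene id; at least 3 shared genes are
    required and either vector being constant is an error.
    """
    shared = rnaseq_log2fc.index.intersection(qpcr_log2fc.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for a correlation")
    x = rnaseq_log2fc.loc[shared].to_numpy(float)
    y = qpcr_log2fc.loc[shared].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the fold-change vectors")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_ttest(values: pd.Series, classes: pd.Series, welch: bool = False):
    """Two-sample Student t-test of relative expression between classes.

    Equal-variance by default (``welch=True`` for the unequal-variance
    variant).  Returns (t, p, star).  Identical groups give t=0, p=1.
    """
    classes = classes.reindex(values.index)
    a = values[classes == "healthy"].dropna()
    b = values[classes == "affected"].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0, ""
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), star_code(float(p))
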