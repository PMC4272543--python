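"""DEG tables: signed fold change, threshold filtering, ripening
subtraction, tissue overlap and functional-bin summaries.

Fold change follows the symmetric signed convention: with r the ratio of
the affected to the healthy group mean, FC = r when r >= 1 and -1/r
otherwise, so magnitudes are comparable around +/-1 (e.g. a halving is
-2, a doubling +2).  A group mean of zero yields an infinite sentinel
that is excluded from threshold filtering rather than given an invented
magnitude (a pseudocount option exists for users who want numeric FCs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import iterative_selection

logger = logging.getLogger("pomebrown")

__all__ = [
    "DEGSet",
    "BinSummary",
    "signed_fold_change",
    "build_deg_table",
    "filter_degs",
    "ripening_contrast",
    "subtract_ripening",
    "tissue_overlap",
    "summarize_bins",
]


@dataclass
class DEGSet:
    """A per-tissue table of differentially expressed genes.

    ``table`` is indexed by gene id with columns p_value,
    mean_rpkm_healthy, mean_rpkm_affected, fold_change, direction.
    ``provenance`` records the contrast and any filters applied.
    """

    tissue: str
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in DEG set")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class BinSummary:
    """Per-bin DEG counts and percentages.

    Percentages use the number of DEG records with at least one bin as
    denominator; multi-bin genes contribute to each of their bins, so
    percentages can sum above 100.
    """

    table: pd.DataFrame  # index bin, columns count, percentage
    n_with_bin: int
    n_unassigned: int
    n_multi_bin: int


def signed_fold_change(
    mean_healthy: float, mean_affected: float, pseudocount: float = 0.0
) -> float:
    """Symmetric signed fold change of the affected over the healthy mean.

    Returns r = affected/healthy when r >= 1, else -1/r; 1.0 for equal
    positive means.  When either mean is zero (and no pseudocount is
    given) an infinite sentinel is returned: +inf for induction from
    zero, -inf for repression to zero, NaN when both means are zero.
    """
    if mean_healthy < 0 or mean_affected < 0:
        raise ValueError("group means must be non-negative")
    h = mean_healthy + pseudocount
    a = mean_affected + pseudocount
    if h == 0 and a == 0:
        return math.nan
    if h == 0:
        return math.inf
    if a == 0:
        return -math.inf
    r = a / h
    return r if r >= 1 else -1.0 / r


def _direction(fc: float) -> str:
    if fc > 1:
        return "induced"
    if fc < -1:
        return "repressed"
    return "unchanged"


def build_deg_table(
    expr,
    samples,
    p_values: pd.Series,
    tissue: str,
    groups: tuple[str, str] = ("healthy", "affected"),
    group_masks: tuple[pd.Index, pd.Index] | None = None,
    pseudocount: float = 0.0,
) -> DEGSet:
    """Group mean RPKMs, signed fold change and direction per selected gene.

    The two groups default to the healthy/affected classes of ``tissue``;
    ``group_masks`` can supply explicit (reference, test) sample id lists
    for other contrasts (e.g. harvest vs stored-healthy).
    """
    if group_masks is None:
        meta = samples.table
        in_tissue = meta["tissue"] == tissue
        ref_ids = meta.index[in_tissue & (meta["class"] == groups[0])]
        test_ids = meta.index[in_tissue & (meta["class"] == groups[1])]
    else:
        ref_ids, test_ids = (pd.Index(m) for m in group_masks)
    ref_ids = [s for s in ref_ids if s in expr.sample_ids]
    test_ids = [s for s in test_ids if s in expr.sample_ids]
    if not ref_ids or not test_ids:
        raise ValueError(f"empty class in tissue {tissue!r} for contrast {groups}")

    genes = p_values.index
    missing = genes.difference(expr.gene_ids)
    if len(missing):
        raise ValueError(f"selected gene(s) absent from expression: {missing.tolist()[:5]}")
    mean_ref = expr.rpkm.loc[genes, ref_ids].mean(axis=1)
    mean_test = expr.rpkm.loc[genes, test_ids].mean(axis=1)
    fc = np.array(
        [
            signed_fold_change(h, a, pseudocount=pseudocount)
            for h, a in zip(mean_ref, mean_test)
        ]
    )
    table = pd.DataFrame(
        {
            "p_value": p_values,
            "mean_rpkm_healthy": mean_ref,
            "mean_rpkm_affected": mean_test,
            "fold_change": fc,
            "direction": [_direction(v) for v in fc],
        },
        index=genes,
    )
    return DEGSet(
        tissue=tissue,
        table=table,
        provenance={"contrast": f"{groups[0]}-vs-{groups[1]}", "filters": []},
    )


def filter_degs(degs: DEGSet, p_max: float = 0.05, fc_min: float = 1.5) -> DEGSet:
    """Keep records with p < ``p_max`` and |FC| > ``fc_min``.

    Sentinel (non-finite) fold changes are excluded and logged.
    Monotone: shrinking p_max or growing fc_min never adds a record.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    t = degs.table
    finite = np.isfinite(t["fold_change"])
    n_sentinel = int((~finite).sum())
    if n_sentinel:
        logger.info(
            "%d record(s) with sentinel fold change excluded from filtering",
            n_sentinel,
        )
    keep = finite & (t["p_value"] < p_max) & (t["fold_change"].abs() > fc_min)
    prov = dict(degs.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [
        f"p<{p_max}", f"|FC|>{fc_min}", f"sentinels_excluded={n_sentinel}"
    ]
    return DEGSet(tissue=degs.tissue, table=t[keep].copy(), provenance=prov)


def ripening_contrast(
    expr,
    samples,
    tissue: str,
    alpha: float = 0.05,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    a_max: int | None = None,
    scheme="loo",
    seed: int = 0,
    autoscale: bool = True,
) -> pd.Index:
    """Genes differential between harvest and stored-healthy fruit.

    Runs the full iterative PLS-DA selection and fold-change filter with
    the harvest vs stored-healthy contrast of one tissue; the returned
    gene ids are interpreted as ripening/storage-related and subtracted
    from the browning DEG set.
    """
    meta = samples.table
    in_tissue = meta["tissue"] == tissue
    harvest = meta.index[in_tissue & (meta["timepoint"] == "harvest")]
    stored_healthy = meta.index[
        in_tissue & (meta["timepoint"] == "stored") & (meta["class"] == "healthy")
    ]
    harvest = [s for s in harvest if s in expr.sample_ids]
    stored_healthy = [s for s in stored_healthy if s in expr.sample_ids]
    if not harvest:
        raise ValueError(f"no harvest samples for tissue {tissue!r}")
    if not stored_healthy:
        raise ValueError(f"no stored-healthy samples for tissue {tissue!r}")

    ids = list(harvest) + list(stored_healthy)
    X = expr.rpkm[ids].T
    y = pd.Series([0.0] * len(harvest) + [1.0] * len(stored_healthy), index=ids)
    sel = iterative_selection(
        X, y, alpha=alpha, a_max=a_max, scheme=scheme, seed=seed, autoscale=autoscale
    )
    if len(sel.gene_ids) == 0:
        return pd.Index([])
    degs = build_deg_table(
        expr,
        samples,
        sel.p_values.loc[sel.gene_ids],
        tissue,
        groups=("harvest", "stored_healthy"),
        group_masks=(pd.Index(harvest), pd.Index(stored_healthy)),
    )
    return filter_degs(degs, p_max=p_max, fc_min=fc_min).gene_ids


def subtract_ripening(browning: DEGSet, ripening) -> DEGSet:
    """Remove ripening-associated genes from a browning DEG set.

    The result is always a subset of the input and disjoint from the
    ripening set (asserted).
    """
    ripening = set(ripening)
    keep = [g for g in browning.gene_ids if g not in ripening]
    out = DEGSet(
        tissue=browning.tissue,
        table=browning.table.loc[keep].copy(),
        provenance={
            **browning.provenance,
            "ripening_subtracted": len(browning) - len(keep),
        },
    )
    assert set(out.gene_ids).isdisjoint(ripening)
    assert set(out.gene_ids) <= set(browning.gene_ids)
    return out


def tissue_overlap(inner: DEGSet, outer: DEGSet) -> pd.DataFrame:
    """Genes shared between the inner- and outer-cortex DEG sets.

    One row per shared gene with its direction in each tissue and a
    concordance flag (same direction in both).
    """
    shared = inner.gene_ids.intersection(outer.gene_ids)
    di = inner.table.loc[shared, "direction"]
    do = outer.table.loc[shared, "direction"]
    return pd.DataFrame(
        {
            "direction_inner": di,
            "direction_outer": do,
            "concordant": (di == do),
        },
        index=shared,
    )


def summarize_bins(degs: DEGSet, genes) -> BinSummary:
    """Count DEGs per functional bin with percentages.

    ``genes`` is a GeneAnnotation whose ``bin_label`` may hold several
    ';'-separated bins per gene.  Genes without a bin are tallied as
    unassigned and excluded from the percentage denominator; multi-bin
    genes are counted once per bin and flagged in the summary.
    """
    labels = genes.bin_label.reindex(degs.gene_ids).fillna("")
    counts: dict[str, int] = {}
    n_with_bin = 0
    n_unassigned = 0
    n_multi = 0
    for lab in labels:
        bins = [b.strip() for b in str(lab).split(";") if b.strip()]
        if not bins:
            n_unassigned += 1
            continue
        n_with_bin += 1
        if len(bins) > 1:
            n_multi += 1
        for b in bins:
            counts[b] = counts.get(b, 0) + 1
    table = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype=int),
            "percentage": {
                b: 100.0 * c / n_with_bin for b, c in counts.items()
            } if n_with_bin else {},
        }
    ).sort_values("count", ascending=False)
    return BinSummary(
        table=table,
        n_with_bin=n_with_bin,
        n_unassigned=n_unassigned,
        n_multi_bin=n_multi,
    )
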