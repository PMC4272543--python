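import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pomebrown import (
    DEGSet,
    GeneAnnotation,
    build_deg_table,
    filter_degs,
    ripening_contrast,
    signed_fold_change,
    subtract_ripening,
    summarize_bins,
    tissue_overlap,
)

# group-mean RPKM pairs as printed for browning-related genes in the two
# cortex tissues, with the published signed fold change at 2 decimals
PRINTED_ROWS = [
    ("pyruvate dehydrogenase", 14.53, 29.39, 2.02),
    ("phosphoglycerate mutase", 0.91, 1.80, 1.98),
    ("phosphoenolpyruvate carboxylase", 8.35, 5.47, -1.53),
    ("aconitate hydratase", 19.75, 11.72, -1.69),
    ("succinate dehydrogenase", 25.49, 42.53, 1.67),
    ("pyruvate kinase", 80.59, 125.23, 1.55),
]


class TestSignedFoldChange:
    @pytest.mark.parametrize("name,healthy,affected,printed", PRINTED_ROWS)
    def test_published_worked_examples(self, name, healthy, affected, printed):
        assert round(signed_fold_change(healthy, affected), 2) == printed

    def test_equal_positive_means_give_one(self):
        assert signed_fold_change(7.3, 7.3) == 1.0

    def test_zero_mean_yields_sentinel(self):
        assert signed_fold_change(0.0, 5.0) == math.inf
        assert signed_fold_change(5.0, 0.0) == -math.inf
        assert math.isnan(signed_fold_change(0.0, 0.0))

    def test_pseudocount_makes_sentinels_numeric(self):
        fc = signed_fold_change(0.0, 5.0, pseudocount=0.5)
        assert math.isfinite(fc) and fc == pytest.approx(11.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(-1.0, 2.0)

    @given(
        a=st.floats(min_value=1e-6, max_value=1e6),
        b=st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_magnitude_floor(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        if fc != 1.0:
            assert signed_fold_change(b, a) == pytest.approx(-fc, rel=1e-12)


@pytest.fixture
def deg_fixture(small_experiment):
    counts, genes, samples, expr, truth = small_experiment
    picked = expr.gene_ids[:30]
    pvals = pd.Series(np.linspace(0.001, 0.2, 30), index=picked)
    degs = build_deg_table(expr, samples, pvals, "inner")
    return expr, samples, genes, degs


class TestBuildDEGTable:
    def test_group_means_and_fc_hand_oracle(self):
        from pomebrown import ExpressionMatrix, SampleTable

        expr = ExpressionMatrix(
            pd.DataFrame(
                {"h1": [10.0], "h2": [20.0], "a1": [30.0], "a2": [28.78]},
                index=["g"],
            )
        )
        samples = SampleTable(
            pd.DataFrame(
                {
                    "tissue": ["inner"] * 4,
                    "timepoint": ["stored"] * 4,
                    "browning_index": [2, 2, 8, 8],
                    "class": ["healthy", "healthy", "affected", "affected"],
                },
                index=["h1", "h2", "a1", "a2"],
            )
        )
        degs = build_deg_table(expr, samples, pd.Series({"g": 0.01}), "inner")
        row = degs.table.loc["g"]
        assert row["mean_rpkm_healthy"] == pytest.approx(15.0)
        assert row["mean_rpkm_affected"] == pytest.approx(29.39)
        assert round(row["fold_change"], 2) == 1.96
        assert row["direction"] == "induced"

    def test_only_selected_genes_appear(self, deg_fixture):
        expr, samples, _, degs = deg_fixture
        assert len(degs) == 30
        assert set(degs.gene_ids) <= set(expr.gene_ids)

    def test_direction_consistent_with_fold_change(self, deg_fixture):
        _, _, _, degs = deg_fixture
        t = degs.table
        induced = t["direction"] == "induced"
        repressed = t["direction"] == "repressed"
        assert (t.loc[induced, "fold_change"] > 1).all()
        assert (t.loc[repressed, "fold_change"] < -1).all()


class TestFilter:
    @pytest.mark.parametrize(
        "fc,p,kept",
        [(1.4, 0.01, False), (-1.6, 0.03, True), (2.0, 0.06, False), (1.6, 0.04, True)],
    )
    def test_threshold_examples(self, fc, p, kept):
        degs = DEGSet(
            tissue="inner",
            table=pd.DataFrame(
                {
                    "p_value": [p],
                    "mean_rpkm_healthy": [1.0],
                    "mean_rpkm_affected": [2.0],
                    "fold_change": [fc],
                    "direction": ["induced" if fc > 1 else "repressed"],
                },
                index=["g"],
            ),
        )
        assert (len(filter_degs(degs)) == 1) is kept

    def test_sentinel_records_are_excluded(self):
        degs = DEGSet(
            tissue="inner",
            table=pd.DataFrame(
                {
                    "p_value": [0.001],
                    "mean_rpkm_healthy": [0.0],
                    "mean_rpkm_affected": [5.0],
                    "fold_change": [math.inf],
                    "direction": ["induced"],
                },
                index=["g"],
            ),
        )
        assert len(filter_degs(degs)) == 0

    def test_monotone_in_both_thresholds(self, deg_fixture):
        _, _, _, degs = deg_fixture
        base = set(filter_degs(degs, p_max=0.05, fc_min=1.5).gene_ids)
        tighter_p = set(filter_degs(degs, p_max=0.01, fc_min=1.5).gene_ids)
        tighter_fc = set(filter_degs(degs, p_max=0.05, fc_min=2.0).gene_ids)
        assert tighter_p <= base and tighter_fc <= base

    def test_fc_min_must_exceed_one(self, deg_fixture):
        _, _, _, degs = deg_fixture
        with pytest.raises(ValueError):
            filter_degs(degs, fc_min=1.0)


class TestSubtractAndOverlap:
    def _degset(self, tissue, genes_dirs):
        table = pd.DataFrame(
            {
                "p_value": 0.01,
                "mean_rpkm_healthy": 1.0,
                "mean_rpkm_affected": 2.0,
                "fold_change": [2.0 if d == "induced" else -2.0 for d in genes_dirs.values()],
                "direction": list(genes_dirs.values()),
            },
            index=list(genes_dirs),
        )
        return DEGSet(tissue=tissue, table=table)

    def test_subtraction_examples(self):
        browning = self._degset("inner", {"a": "induced", "b": "induced", "c": "repressed"})
        assert list(subtract_ripening(browning, {"b"}).gene_ids) == ["a", "c"]
        assert list(subtract_ripening(browning, {"z"}).gene_ids) == ["a", "b", "c"]
        assert len(subtract_ripening(browning, {"a", "b", "c", "d"})) == 0

    def test_subtraction_is_subset_and_disjoint(self, deg_fixture):
        _, _, _, degs = deg_fixture
        ripening = set(degs.gene_ids[::3])
        out = subtract_ripening(degs, ripening)
        assert set(out.gene_ids) <= set(degs.gene_ids)
        assert set(out.gene_ids).isdisjoint(ripening)

    def test_overlap_concordance(self):
        inner = self._degset("inner", {"a": "induced", "b": "repressed"})
        outer = self._degset("outer", {"b": "repressed", "c": "induced"})
        report = tissue_overlap(inner, outer)
        assert list(report.index) == ["b"]
        assert bool(report.loc["b", "concordant"])

        outer2 = self._degset("outer", {"a": "repressed"})
        report2 = tissue_overlap(inner, outer2)
        assert not bool(report2.loc["a", "concordant"])

        disjoint = tissue_overlap(inner, self._degset("outer", {"z": "induced"}))
        assert len(disjoint) == 0


class TestRipeningContrast:
    def test_recovers_planted_ripening_genes(self, small_experiment):
        counts, genes, samples, expr, truth = small_experiment
        found = ripening_contrast(expr, samples, "inner", seed=0)
        ripening = set(truth.ripening_genes)
        others = set(expr.gene_ids) - ripening
        assert len(ripening & set(found)) / len(ripening) >= 0.7
        assert len(others & set(found)) / len(others) <= 0.05

    def test_requires_harvest_samples(self, small_experiment):
        counts, genes, samples, expr, truth = small_experiment
        from pomebrown import SampleTable

        stored_only = SampleTable(
            samples.table[samples.table["timepoint"] == "stored"].copy()
        )
        keep = [s for s in expr.sample_ids if s in stored_only.sample_ids]
        from pomebrown import ExpressionMatrix

        with pytest.raises(ValueError, match="harvest"):
            ripening_contrast(ExpressionMatrix(expr.rpkm[keep]), stored_only, "inner")

    def test_deterministic(self, small_experiment):
        counts, genes, samples, expr, truth = small_experiment
        a = ripening_contrast(expr, samples, "outer", seed=3)
        b = ripening_contrast(expr, samples, "outer", seed=3)
        assert list(a) == list(b)


class TestBins:
    def test_single_bin_is_hundred_percent(self):
        genes = GeneAnnotation(
            pd.DataFrame(
                {"cds_length_bp": [500] * 4, "bin_label": ["stress"] * 4},
                index=list("abcd"),
            )
        )
        degs = DEGSet(
            tissue="inner",
            table=pd.DataFrame(
                {
                    "p_value": 0.01,
                    "mean_rpkm_healthy": 1.0,
                    "mean_rpkm_affected": 2.0,
                    "fold_change": 2.0,
                    "direction": "induced",
                },
                index=list("abcd"),
            ),
        )
        summary = summarize_bins(degs, genes)
        assert summary.table.loc["stress", "percentage"] == pytest.approx(100.0)

    def test_two_bin_arithmetic_and_unassigned(self):
        genes = GeneAnnotation(
            pd.DataFrame(
                {"cds_length_bp": [500] * 4, "bin_label": ["A", "A", "B", ""]},
                index=list("abcd"),
            )
        )
        degs = DEGSet(
            tissue="inner",
            table=pd.DataFrame(
                {
                    "p_value": 0.01,
                    "mean_rpkm_healthy": 1.0,
                    "mean_rpkm_affected": 2.0,
                    "fold_change": 2.0,
                    "direction": "induced",
                },
                index=list("abcd"),
            ),
        )
        summary = summarize_bins(degs, genes)
        assert summary.table.loc["A", "percentage"] == pytest.approx(66.67, abs=0.01)
        assert summary.table.loc["B", "percentage"] == pytest.approx(33.33, abs=0.01)
        assert summary.n_unassigned == 1
        assert summary.n_with_bin == 3

    def test_multi_bin_gene_counts_in_each_bin(self):
        genes = GeneAnnotation(
            pd.DataFrame(
                {"cds_length_bp": [500, 500], "bin_label": ["A;B", "A"]},
                index=list("ab"),
            )
        )
        degs = DEGSet(
            tissue="inner",
            table=pd.DataFrame(
                {
                    "p_value": 0.01,
                    "mean_rpkm_healthy": 1.0,
                    "mean_rpkm_affected": 2.0,
                    "fold_change": 2.0,
                    "direction": "induced",
                },
                index=list("ab"),
            ),
        )
        summary = summarize_bins(degs, genes)
        assert summary.table.loc["A", "count"] == 2
        assert summary.table.loc["B", "count"] == 1
        assert summary.n_multi_bin == 1
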