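# Methods

## The discrimination model

The central statistic is a single-response partial least squares
regression (PLS1, NIPALS algorithm) of a mean-centered 0/1 class
indicator on gene expression. For a tissue with samples
`X (n × p genes, RPKM)` and classes `y ∈ {healthy=0, affected=1}`:

- predictors are mean-centered and, by default, scaled to unit
  variance; the response is mean-centered;
- factors are extracted by NIPALS: `w = X'y/‖X'y‖`, `t = Xw`,
  `p = X't/t't`, `q = y't/t't`, deflate and repeat; coefficients in
  the original variable space are `b = W(P'W)⁻¹q`, rescaled by the
  gene standard deviations;
- calibrated explained class variance is `R² = 1 − SSE/SSY`;
  cross-validated explained variance is `Q² = 1 − PRESS/TSS`.

PLS-DA is used here as a *selection engine*, not a classifier: genes
are ranked and tested by their regression coefficients.

### Why unit-variance scaling is the default

RPKM values span four to five orders of magnitude across genes. With
mean-centering alone, the leading latent factors track the most
abundant genes rather than the class contrast, and the coefficient
jackknife (below) loses most of its power at storage-trial sample
sizes (n ≈ 20): in simulations with planted two- to four-fold effects,
centering-only recovery of planted genes drops to roughly half the
runs, whereas autoscaled recovery is near-complete. Centering-only
remains available (`autoscale=False`). The gene scales are estimated
once on the full matrix and held fixed during cross-validation and
jackknife refits: they are a preprocessing transform, so every refit
coefficient lives in the same variable space. (Re-estimating scales
per fold couples the coefficient and scale perturbations and visibly
deflates the jackknife variance — measured null type-I error rose from
0.03 to 0.09.)

### Choosing the number of factors

`cross_validate` computes PRESS(a) for a = 1..A_max (default
A_max = min(10, n−2)) over leave-one-out segments (default; seeded
k-fold available). The returned `a_opt` is the **first local minimum**
of the PRESS curve, the classical chemometric stopping point; the
curve typically flattens past the optimum and its later shallow dips
are noise, so the global argmin systematically overfits the factor
count — and an overfit A destroys the uncertainty test (coefficient
perturbations across folds swamp the coefficients themselves).
A Haaland–Thomas F-ratio rule and the literal argmin are available via
`a_rule`. Factor extraction also stops once all but a millionth of the
response variance is explained.

### The jackknife uncertainty test

With `b_g` the full-model coefficient and `b_g^(−m)` the coefficient
refit with cross-validation segment m left out (same A, same scales):

    s²(b_g) = Σ_m (b_g^(−m) − b_g)² · (M−1)/M
    t_g     = b_g / s(b_g)

two-sided p from Student t with M−1 degrees of freedom. Genes with
zero jackknife variance get p = 1 when b = 0 (constant predictors) and
p = 0 otherwise. Under permuted labels the test is mildly
conservative — empirical type-I error ≈ 0.03 at the 0.05 level —
because the shared weight-normalizer's fold-to-fold fluctuation
contributes a variance term proportional to b². This conservatism is
a property of the variance formula itself and is left as is.

### The iterative selection loop

Round k fits the model on gene set G_k (G_0 = all genes), runs the
jackknife, and passes the genes with p < α (default 0.05) to round
k+1. The candidate results are the reduced sets G_1, G_2, …, each
scored by the Q² of the model refit on it. The loop stops when the
score no longer improves by more than one percentage point
(`min_improvement = 0.01`; explained variance is bookkept in percent,
so smaller gains do not count as improvement), when the set is stable,
or when it would become empty. The earliest candidate within the
tolerance of the best score is returned — ties resolve toward the
larger, earlier set. Two conventions matter:

- the p-value reported for each returned gene is the one from the
  round that admitted it into the returned set, so every reported p is
  below α by construction and the downstream p-filter never silently
  re-tests the set;
- the all-genes round 0 is recorded in the selection trace as the
  baseline (it shows the poor discrimination of the full model) but is
  never itself a candidate.

Note that Q² values of selected gene sets are re-validated on the same
data that selected them and are therefore optimistically biased; they
are comparable across rounds, which is all the stop rule needs, but
they are not honest estimates of out-of-sample performance. This is
also why a "null data should give Q² < 0.5" check is not meaningful
for reduced sets: even noise genes chosen for their apparent class
association re-validate well. Null behaviour is instead controlled at
the level of the final DEG set size.

## Outlier screening

Samples are projected onto the first k = 2 principal components of the
centered expression matrix (SVD). Because the scores come from the
same samples the model was built on, T² for an in-model sample is
bounded by (n−1)²/n and follows a scaled Beta distribution, not the
out-of-model F form — at small n the F limit exceeds the attainable
maximum and could never flag anything. The limit used is
`(n−1)²/n · Beta_{1−α'}(k/2, (n−k−1)/2)` with per-sample level
α' = α/n (Bonferroni; family-wise α defaults to 0.05), so a clean run
is rarely stripped of samples while extreme samples are flagged
reliably. Outlier removal happens once, globally, before per-tissue
selection.

## DEG calling conventions

- **Signed fold change**: `FC = r` if `r = affected/healthy ≥ 1`, else
  `−1/r`; equal positive means give 1.0. A zero group mean yields an
  infinite sentinel that is excluded from threshold filtering and
  logged, rather than being given an invented magnitude; a
  `pseudocount` option produces numeric FCs when preferred. FCs are
  computed from unrounded group means; rounding to two decimals is
  display-only.
- **Thresholds**: p < 0.05 and |FC| > 1.5 (strict inequalities),
  identical for the browning and the ripening contrast.
- **Ripening subtraction**: the ripening contrast (harvest vs
  stored-healthy, same tissue) runs the full selection + filter
  machinery; its gene ids are removed from the browning DEG set. The
  result is asserted disjoint from the ripening set and a subset of
  its input on every run, and the manifest chain
  selected ≥ FC-filtered ≥ browning-specific is asserted
  non-increasing.
- **Bin summaries**: percentage denominator is the number of DEG
  records with at least one functional bin; multi-bin genes count once
  per bin (totals can exceed 100%), unassigned genes are tallied
  separately.

## qRT-PCR validation

Relative expression is `E^(−ΔCt)` with
`ΔCt = Ct_target − mean(Ct_refs)`; the arithmetic mean on the Ct scale
equals geometric-mean normalization on the linear scale and is
numerically safer. Amplification efficiency defaults to 2.0 (perfect
doubling). Group comparisons use the equal-variance Student t-test
(Welch behind a flag) with the star convention * p<0.05, ** p<0.01,
*** p<0.001. The cross-platform check is the Pearson R² between
RNA-Seq and qPCR log2(healthy/affected) ratios over the measured
genes.

## The synthetic generator

`generate_experiment` emulates the storage-trial design: per tissue
(inner, outer), 4 harvest + 16 stored fruit, half of the stored fruit
affected. Counts are negative-binomial with mean
`μ[g,s] = N_s · (L_g/10³) · base_g · 2^(effects active for s) / Z_s`,
where `base_g` is log-normal (log2 sd 2.0), `L_g` is log-uniform on
[300, 6000] bp, `N_s` is log-normal around 5·10⁵ reads (CV 0.1,
scaled to the default 2,000 genes so per-gene coverage matches a
~16M-read library over a full transcriptome), and dispersion is fixed
at 0.05. Browning effects (|log2 FC| uniform on [1, 2], random sign,
drawn per tissue for one shared set of 50 genes) apply only to
stored-affected samples; ripening effects (same magnitude law, 50
disjoint genes) apply to **all** stored samples, so the subtraction
step is genuinely exercised. Browning-index values are drawn from
truncated normals on the correct side of the class cutoff (healthy
≈ N(1.8, 0.5) on [1, 3]; affected ≈ N(7, 1) on (3, 10]). Synthetic
qPCR Ct values derive from the same planted truth:
`Ct = offset − log2(abundance) + N(0, σ)`, with reference genes
required to carry no planted effect.

All randomness flows through one `numpy.random.default_rng(seed)`; the
same seed reproduces every table byte for byte.

What the generator does **not** emulate: gene–gene correlation beyond
the shared library-size factor, GC/length biases, mapping artifacts,
batch effects, or realistic *Malus* annotation structure. Passing
recovery tests therefore demonstrate that the machinery identifies the
planted class structure at realistic depth and sample size — not that
it is robust to every failure mode of real sequencing data.

## Problem sizes used in tests

The acceptance-style checks run the full pipeline on 100 simulated
trials at the default design (2,000 genes × 40 samples) for recovery
and null control, pool six permuted 1,000-gene datasets for the
jackknife calibration, and use 20 random instances for the PLS/OLS
oracle; the whole suite completes in a couple of minutes on one CPU.
`scripts/acceptance.py` uses 30–40 seeds per Monte-Carlo quantity.

## Known limitations

- The uncertainty test's conservatism (above) means the effective
  gene-level α is nearer 0.03 than 0.05.
- Q² values in the selection trace are selection-biased upward from
  round 1 on.
- With n = 4 harvest fruit the ripening contrast has limited power;
  planted ripening genes are recovered at ~80–90%, and the residual
  leak-through into the browning-specific set is what the subtraction
  bound (≤10%) controls.
- RPKM inherits its usual compositional caveats; the pipeline treats
  library size as given in the metadata (uniquely mapped reads
  intended) and falls back to column sums only when absent.
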