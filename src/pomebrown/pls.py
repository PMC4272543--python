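"""PLS-DA gene selection with a jackknife uncertainty test.

The discriminant model is a single-response partial least squares
regression (PLS1, NIPALS algorithm): RPKM values are the predictors, a
mean-centered 0/1 class indicator is the response.  Significance of the
per-gene regression coefficients is assessed with a Martens-style
jackknife over the cross-validation segments, and genes are selected by
iterating model fitting and coefficient testing until the
cross-validated explained response variance stops improving.

Predictors are mean-centered and scaled to unit variance by default
(``autoscale=False`` gives centering only).  RPKM values span several
orders of magnitude across genes; without scaling the leading latent
factors follow the most abundant genes rather than the class contrast,
and the jackknife test on the coefficients loses most of its power at
storage-trial sample sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pomebrown")

__all__ = [
    "PLSModel",
    "CVResult",
    "SelectionTrace",
    "SelectionResult",
    "design_matrix",
    "make_segments",
    "fit_plsda",
    "cross_validate",
    "jackknife_uncertainty",
    "iterative_selection",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class PLSModel:
    """A fitted PLS1 discriminant model.

    ``beta`` holds the regression coefficients in the original
    (centered) variable space for the full ``n_factors`` model;
    ``explained_y_cal`` is the cumulative calibrated response variance
    explained by factors 1..a (non-decreasing in a).
    """

    gene_ids: pd.Index
    n_factors: int
    weights: np.ndarray  # (p, A)
    loadings: np.ndarray  # (p, A)
    scores: np.ndarray  # (n, A)
    y_loadings: np.ndarray  # (A,)
    beta: np.ndarray  # (p,) at A factors
    beta_per_a: np.ndarray  # (p, A): coefficients using 1..a factors
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    explained_y_cal: np.ndarray  # (A,), cumulative
    explained_y_val: float | None = None

    @property
    def beta_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.gene_ids, name="beta")

    def predict(self, X: pd.DataFrame | np.ndarray, n_factors: int | None = None):
        a = self.n_factors if n_factors is None else n_factors
        arr = X.to_numpy(float) if hasattr(X, "to_numpy") else np.asarray(X, float)
        b = self.beta_per_a[:, a - 1]
        return self.y_mean + ((arr - self.x_mean) / self.x_scale) @ b


@dataclass
class CVResult:
    """Cross-validated model-size choice."""

    a_opt: int
    press: np.ndarray  # (A_max,)
    explained_y_val: np.ndarray  # (A_max,), 1 - PRESS/TSS
    segments: list  # list of np.ndarray of held-out positional indices


@dataclass
class SelectionTrace:
    """Iteration history of the selection loop.

    One record per fitted model: iteration index, gene count, number of
    factors, cross-validated and calibrated explained response variance,
    and the gene ids the model was fitted on.  ``selected_iteration``
    marks the record whose model/gene set is returned.
    """

    records: list = field(default_factory=list)
    selected_iteration: int | None = None

    def add(self, iteration, n_genes, n_factors, explained_val, explained_cal, genes):
        self.records.append(
            {
                "iteration": iteration,
                "n_genes": n_genes,
                "n_factors": n_factors,
                "explained_y_val": explained_val,
                "explained_y_cal": explained_cal,
                "gene_ids": list(genes),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{k: v for k, v in r.items() if k != "gene_ids"} for r in self.records]
        )
        if len(df):
            df["selected"] = df["iteration"] == self.selected_iteration
        return df


@dataclass
class SelectionResult:
    gene_ids: pd.Index
    model: PLSModel | None
    p_values: pd.Series
    trace: SelectionTrace


# ---------------------------------------------------------------------------
# helpers


def design_matrix(expr, samples, tissue, classes=("healthy", "affected")):
    """Build (X, y) for one tissue: X samples × genes, y 0/1 indicator.

    ``classes[0]`` is encoded 0 (reference), ``classes[1]`` as 1.
    """
    meta = samples.table
    keep = meta.index[(meta["tissue"] == tissue) & meta["class"].isin(classes)]
    keep = [s for s in keep if s in expr.sample_ids]
    X = expr.rpkm[keep].T
    y = (meta.loc[keep, "class"] == classes[1]).astype(float)
    return X, y


def make_segments(n: int, scheme="loo", seed: int = 0, y=None) -> list:
    """Cross-validation segments as arrays of held-out positional indices.

    ``scheme`` is "loo" (default) or "kfold:K".  K-fold splits are a
    seeded random partition applied after canonical sample ordering.
    Every training fold must retain both classes when ``y`` is given.
    """
    if scheme == "loo":
        segments = [np.array([i]) for i in range(n)]
    elif isinstance(scheme, str) and scheme.startswith("kfold"):
        k = int(scheme.split(":", 1)[1]) if ":" in scheme else 7
        if k < 2 or k > n:
            raise ValueError(f"kfold K must be in [2, n]; got {k} for n={n}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        segments = [np.sort(perm[i::k]) for i in range(k)]
    else:
        raise ValueError(f"unknown CV scheme: {scheme!r}")
    if y is not None:
        y = np.asarray(y, float)
        for m, seg in enumerate(segments):
            train = np.delete(np.arange(n), seg)
            if len(np.unique(y[train])) < 2:
                raise ValueError(f"fold {m} leaves a single class in training")
    return segments


def _gene_scales(X, autoscale):
    """Unit-variance scales estimated once per matrix.

    The scales are treated as a fixed preprocessing transform: CV and
    jackknife refits re-center per training fold but keep the full-data
    scales, so all refit coefficients live in one variable space.
    (Re-estimating scales per fold induces a spurious correlation
    between the coefficient and scale perturbations that deflates the
    jackknife variance.)
    """
    if not autoscale:
        return np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=1)
    return np.where(sd > _EPS, sd, 1.0)


def _center_scale(X, y, xs):
    xm = X.mean(axis=0)
    ym = float(y.mean())
    return (X - xm) / xs, y - ym, xm, xs, ym


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """NIPALS factor extraction for a single response.

    Returns weights W, x-loadings P, scores T, y-loadings q and the
    per-a coefficient matrix B (p × a_eff).  Extraction stops early,
    with a warning, when the residual weight vector degenerates
    (rank exhausted).
    """
    n, p = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    scale = max(float(np.abs(Xc).max()), 1.0) * max(float(np.abs(yc).max()), 1.0)
    W, P, T, q = [], [], [], []
    for _ in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _EPS * scale * np.sqrt(p):
            warnings.warn(
                "NIPALS deflation degenerate; stopping factor extraction early",
                stacklevel=3,
            )
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W.append(w)
        P.append(pa)
        T.append(t)
        q.append(qa)
    a_eff = len(W)
    W = np.array(W).T.reshape(p, a_eff)
    P = np.array(P).T.reshape(p, a_eff)
    T = np.array(T).T.reshape(n, a_eff)
    q = np.asarray(q)
    # coefficients for models with 1..a factors: B_a = W_a (P_a^T W_a)^-1 q_a
    B = np.zeros((p, a_eff))
    for a in range(1, a_eff + 1):
        R = np.linalg.solve((P[:, :a].T @ W[:, :a]), q[:a])
        B[:, a - 1] = W[:, :a] @ R
    return W, P, T, q, B


def fit_plsda(
    X: pd.DataFrame,
    y,
    n_factors: int,
    autoscale: bool = True,
) -> PLSModel:
    """Fit a PLS1 discriminant model on mean-centered X and y.

    ``X`` is samples × genes; ``y`` a numeric two-class indicator.
    ``n_factors`` beyond the rank of centered X is truncated with a
    warning.  Raises on a single-class response.
    """
    Xa = X.to_numpy(float) if hasattr(X, "to_numpy") else np.asarray(X, float)
    ya = np.asarray(y, float)
    if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
        raise ValueError("X must be samples × genes aligned with y")
    if len(np.unique(ya)) < 2:
        raise ValueError("response has a single class; PLS-DA needs two")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    gene_ids = X.columns if hasattr(X, "columns") else pd.RangeIndex(Xa.shape[1])

    Xc, yc, xm, xs, ym = _center_scale(Xa, ya, _gene_scales(Xa, autoscale))
    rank = np.linalg.matrix_rank(Xc)
    if n_factors > rank:
        warnings.warn(
            f"n_factors={n_factors} exceeds rank {rank}; truncating", stacklevel=2
        )
        n_factors = rank
    W, P, T, q, B = _nipals_pls1(Xc, yc, n_factors)
    a_eff = W.shape[1]
    ssy = float(yc @ yc)
    fitted = np.cumsum(T * q[None, :], axis=1)  # (n, a_eff), scores orthogonal
    sse = ((yc[:, None] - fitted) ** 2).sum(axis=0)
    explained = 1.0 - sse / ssy if ssy > 0 else np.zeros(a_eff)
    return PLSModel(
        gene_ids=gene_ids,
        n_factors=a_eff,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        beta=B[:, a_eff - 1] / xs if a_eff else np.zeros(Xa.shape[1]),
        beta_per_a=B,
        x_mean=xm,
        x_scale=xs,
        y_mean=ym,
        explained_y_cal=explained,
    )


# ---------------------------------------------------------------------------
# cross-validation and the uncertainty test


def _fold_coefficients(Xa, ya, segments, a_max, autoscale):
    """Per-fold fits (re-centered, fixed full-data scales)."""
    n = Xa.shape[0]
    xs_full = _gene_scales(Xa, autoscale)
    out = []
    for m, seg in enumerate(segments):
        train = np.delete(np.arange(n), seg)
        if len(np.unique(ya[train])) < 2:
            raise ValueError(f"fold {m} leaves a single class in training")
        Xc, yc, xm, xs, ym = _center_scale(Xa[train], ya[train], xs_full)
        *_, B = _nipals_pls1(Xc, yc, a_max)
        out.append((B, xm, xs, ym))
    return out


def cross_validate(
    X: pd.DataFrame,
    y,
    a_max: int,
    scheme="loo",
    seed: int = 0,
    autoscale: bool = True,
    a_rule: str = "localmin",
    press_f_alpha: float = 0.25,
) -> CVResult:
    """Choose the number of PLS factors by segmented cross-validation.

    For each candidate a = 1..``a_max``, each segment is held out once,
    the model is refit on the rest and the held-out response predicted;
    PRESS(a) is the accumulated squared prediction error.  ``a_rule``
    sets the parsimony convention for ``a_opt``:

    - "localmin" (default): the first local minimum of the PRESS curve,
      the classical chemometric stopping point.  The global argmin
      routinely overfits the factor count, because past the first
      minimum the curve flattens and later shallow dips are noise.
    - "ftest": the smallest a whose PRESS is statistically
      indistinguishable from the global minimum under an F-ratio test
      at level ``press_f_alpha`` (Haaland–Thomas rule).
    - "argmin": the exact global minimum, smallest a on ties.

    ``explained_y_val`` reports 1 − PRESS/TSS against the overall mean.
    """
    Xa = X.to_numpy(float) if hasattr(X, "to_numpy") else np.asarray(X, float)
    ya = np.asarray(y, float)
    n = Xa.shape[0]
    segments = make_segments(n, scheme, seed, y=ya)
    if len(segments) < 2:
        raise ValueError("cross-validation needs at least 2 segments")
    press = np.zeros(a_max)
    for seg, (B, xm, xs, ym) in zip(
        segments, _fold_coefficients(Xa, ya, segments, a_max, autoscale)
    ):
        a_eff = B.shape[1]
        Xh = (Xa[seg] - xm) / xs
        for a in range(1, a_max + 1):
            b = B[:, min(a, a_eff) - 1] if a_eff else np.zeros(Xa.shape[1])
            pred = ym + Xh @ b
            press[a - 1] += float(((ya[seg] - pred) ** 2).sum())

    tss = float(((ya - ya.mean()) ** 2).sum())
    explained = 1.0 - press / tss if tss > 0 else np.zeros(a_max)
    p_min = float(press.min())
    if a_rule == "localmin":
        a_opt = a_max
        floor = 1e-6 * max(tss, 1.0)
        for a in range(1, a_max):
            # stop at the first non-improvement, or once all but a
            # millionth of the response variance is already explained
            # (numerically perfect prediction)
            if press[a] >= press[a - 1] or press[a - 1] <= floor:
                a_opt = a
                break
    elif a_rule == "ftest" and p_min > 0:
        f_crit = stats.f.ppf(1.0 - press_f_alpha, n, n)
        a_opt = int(np.argmax(press <= f_crit * p_min)) + 1
    elif a_rule in ("argmin", "ftest"):
        a_opt = int(np.argmin(press)) + 1
    else:
        raise ValueError(f"unknown a_rule: {a_rule!r}")
    return CVResult(a_opt=a_opt, press=press, explained_y_val=explained, segments=segments)


def jackknife_uncertainty(
    X: pd.DataFrame,
    y,
    n_factors: int,
    segments,
    autoscale: bool = True,
) -> pd.DataFrame:
    """Martens jackknife significance of PLS regression coefficients.

    With b_g the full-model coefficient of gene g and b_g^(−m) the
    coefficient refit with cross-validation segment m left out:

        s²(b_g) = Σ_m (b_g^(−m) − b_g)² · (M−1)/M
        t_g     = b_g / s(b_g),  two-sided p from Student t, M−1 df.

    Genes with zero jackknife variance get p = 1 when b = 0 (degenerate
    predictors) and p = 0 otherwise.  Returns a DataFrame indexed by
    gene id with columns beta, jackknife_var, t, p_value.
    """
    M = len(segments)
    if M < 2:
        raise ValueError("jackknife needs at least 2 segments")
    Xa = X.to_numpy(float) if hasattr(X, "to_numpy") else np.asarray(X, float)
    ya = np.asarray(y, float)
    gene_ids = X.columns if hasattr(X, "columns") else pd.RangeIndex(Xa.shape[1])

    full = fit_plsda(X, y, n_factors, autoscale=autoscale)
    b_full = full.beta  # on the original (per-unit) scale
    s2 = np.zeros_like(b_full)
    for B, xm, xs, ym in _fold_coefficients(Xa, ya, segments, n_factors, autoscale):
        a_eff = B.shape[1]
        b_m = (B[:, min(n_factors, a_eff) - 1] / xs) if a_eff else np.zeros_like(b_full)
        s2 += (b_m - b_full) ** 2
    s2 *= (M - 1) / M

    with np.errstate(divide="ignore", invalid="ignore"):
        t = b_full / np.sqrt(s2)
    p = 2.0 * stats.t.sf(np.abs(t), df=M - 1)
    zero_var = s2 <= 0
    p[zero_var & (b_full == 0)] = 1.0
    p[zero_var & (b_full != 0)] = 0.0
    t[zero_var] = 0.0
    return pd.DataFrame(
        {"beta": b_full, "jackknife_var": s2, "t": t, "p_value": p}, index=gene_ids
    )


# ---------------------------------------------------------------------------
# the iterative selection loop


def iterative_selection(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    a_max: int | None = None,
    scheme="loo",
    seed: int = 0,
    autoscale: bool = True,
    max_iterations: int = 50,
    min_improvement: float = 0.01,
) -> SelectionResult:
    """Iterate PLS-DA fitting and jackknife testing to select genes.

    Each round (i) chooses the number of factors by cross-validation,
    (ii) runs the jackknife uncertainty test on the current gene set,
    (iii) passes the genes with p < ``alpha`` to the next round.  The
    candidate results are the reduced sets produced from round 1 on,
    each scored by the cross-validated explained variance of the model
    refit on it; the loop stops when that score no longer improves by
    more than ``min_improvement`` (explained variance is tracked in
    percent; a gain below one percentage point does not count as an
    improvement), when the set is stable, or when it would become
    empty.  The best-so-far candidate (maximal score, earliest on ties)
    is returned.  Round 0, the all-genes model, is recorded in the
    trace as the baseline but is never itself a candidate.

    The p-value reported for each returned gene is the one from the
    round at which it was last retained — the test that admitted it into
    the returned set — so every reported p is < ``alpha`` by
    construction.  An empty round-0 retention returns an empty set with
    the trace rather than raising.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n = X.shape[0]
    if a_max is None:
        a_max = max(1, min(10, n - 2))
    genes = list(X.columns)
    trace = SelectionTrace()
    candidates = []  # (explained_val, trace index, genes, model, admitting p-values)
    admitting_p = None
    prev_val = None

    for iteration in range(max_iterations):
        Xg = X[genes]
        cv = cross_validate(Xg, y, a_max, scheme=scheme, seed=seed, autoscale=autoscale)
        unc = jackknife_uncertainty(Xg, y, cv.a_opt, cv.segments, autoscale=autoscale)
        model = fit_plsda(Xg, y, cv.a_opt, autoscale=autoscale)
        explained_val = float(cv.explained_y_val[cv.a_opt - 1])
        model.explained_y_val = explained_val
        trace.add(
            iteration,
            len(genes),
            model.n_factors,
            explained_val,
            float(model.explained_y_cal[-1]),
            genes,
        )
        if iteration >= 1:
            candidates.append(
                (explained_val, iteration, genes, model, admitting_p.loc[genes])
            )
            if prev_val is not None and explained_val <= prev_val + min_improvement:
                break  # explained variance no longer improved
            prev_val = explained_val

        retained = unc.index[unc["p_value"] < alpha].tolist()
        if len(retained) == 0:
            if iteration == 0:
                trace.selected_iteration = 0
                return SelectionResult(
                    gene_ids=pd.Index([], name=X.columns.name),
                    model=None,
                    p_values=unc["p_value"].iloc[0:0],
                    trace=trace,
                )
            break
        if len(retained) == len(genes):
            if iteration == 0:
                # nothing to reduce: the full set is the only candidate
                candidates.append(
                    (explained_val, 0, genes, model, unc["p_value"])
                )
            break
        admitting_p = unc["p_value"]
        genes = retained

    # earliest candidate within the improvement tolerance of the maximum:
    # a later, smaller set must improve meaningfully to displace it
    top = max(c[0] for c in candidates)
    best = next(c for c in candidates if c[0] >= top - min_improvement)
    explained_best, it_best, genes_best, model_best, pvals_best = best
    trace.selected_iteration = it_best
    return SelectionResult(
        gene_ids=pd.Index(genes_best, name=X.columns.name),
        model=model_best,
        p_values=pvals_best,
        trace=trace,
    )
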