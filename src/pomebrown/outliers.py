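"""PCA screening of samples with Hotelling's T² outlier flagging.

Samples are projected onto the first k principal components of the
mean-centered expression matrix; a sample whose T² statistic on those
components exceeds the F-distribution critical value at level alpha is
flagged as an outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pomebrown")

__all__ = ["OutlierReport", "pca_outlier_scan"]

_EPS = 1e-10


@dataclass
class OutlierReport:
    scores: pd.DataFrame  # samples × PCs
    explained_variance: np.ndarray  # per-PC score variance
    t2: pd.Series  # Hotelling T² per sample
    threshold: float
    flagged: list

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_outlier_scan(
    expr, n_components: int = 2, alpha: float = 0.05, bonferroni: bool = True
) -> OutlierReport:
    """Flag outlying samples by Hotelling's T² on PCA scores.

    ``expr`` is an ExpressionMatrix (genes × samples) or a samples × genes
    DataFrame.  Because the scores come from the same samples the model
    was built on, T² for an in-model sample follows a scaled Beta
    distribution, T² ~ ((n−1)²/n) · Beta(k/2, (n−k−1)/2), not the
    out-of-model F form — with small n the F limit exceeds the largest
    T² an in-model sample can attain, so a single extreme outlier could
    never be flagged.  ``alpha`` is the family-wise level: the
    per-sample level is alpha/n under the default Bonferroni correction
    (``bonferroni=False`` uses alpha per sample).  A zero-variance
    input yields no flags (logged as a warning).  Deterministic.
    """
    if hasattr(expr, "rpkm"):
        X = expr.rpkm.T
    else:
        X = expr
    n = X.shape[0]
    if n < 3:
        raise ValueError("outlier scan needs at least 3 samples")
    if n_components >= n:
        raise ValueError("n_components must be smaller than the sample count")

    Xc = X.to_numpy(float) - X.to_numpy(float).mean(axis=0)
    # SVD-based PCA; scores = U S
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum()) / max(n - 1, 1)
    if total_var <= _EPS:
        logger.warning("zero-variance expression matrix: no outliers flagged")
        empty = pd.DataFrame(
            np.zeros((n, n_components)),
            index=X.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        return OutlierReport(
            scores=empty,
            explained_variance=np.zeros(n_components),
            t2=pd.Series(np.zeros(n), index=X.index, name="T2"),
            threshold=np.inf,
            flagged=[],
        )

    lam = S**2 / (n - 1)
    keep = min(n_components, int((lam > _EPS * lam[0]).sum()))
    scores = U[:, :keep] * S[:keep]
    t2 = (scores**2 / lam[:keep]).sum(axis=1)
    k = keep
    level = alpha / n if bonferroni else alpha
    threshold = (n - 1) ** 2 / n * stats.beta.ppf(1 - level, k / 2, (n - k - 1) / 2)
    flagged = list(X.index[t2 > threshold])
    if flagged:
        logger.info("flagged %d outlier sample(s): %s", len(flagged), flagged)
    return OutlierReport(
        scores=pd.DataFrame(
            scores, index=X.index, columns=[f"PC{i + 1}" for i in range(keep)]
        ),
        explained_variance=lam[:keep],
        t2=pd.Series(t2, index=X.index, name="T2"),
        threshold=float(threshold),
        flagged=flagged,
    )
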