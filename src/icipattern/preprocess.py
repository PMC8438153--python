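"""Unit conversion, log transform, and cross-cohort batch correction.

The batch correction is the parametric empirical-Bayes location/scale model
(ComBat): per-gene standardization, per-batch additive (gamma) and
multiplicative (delta) effect estimates, shrinkage of gamma toward a normal
prior and delta toward an inverse-gamma prior with moment-matched
hyperparameters, iterated to the joint conditional posterior means, then
back-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so transcript abundances sum to 1e6.

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6.
    """
    if m.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {m.unit}")
    colsum = m.values.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero expression for sample(s) {list(zero.index)[:5]}")
    return ExpressionMatrix(m.values / colsum * 1e6, "TPM")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); TPM in, log2TPM1 out."""
    if m.unit != "TPM":
        raise ValueError(f"expected TPM input, got {m.unit}")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), "log2TPM1")


@dataclass
class BatchModel:
    """Fitted parameters of the empirical-Bayes batch model."""

    batches: list[str]
    grand_mean: np.ndarray          # per gene
    pooled_var: np.ndarray          # per gene
    gamma_hat: pd.DataFrame         # batch x gene, unshrunken location
    delta_hat: pd.DataFrame         # batch x gene, unshrunken scale (variance)
    gamma_star: pd.DataFrame        # shrunken location
    delta_star: pd.DataFrame        # shrunken scale
    gamma_bar: np.ndarray           # per batch prior mean
    t2: np.ndarray                  # per batch prior variance
    a_prior: np.ndarray             # per batch inverse-gamma shape
    b_prior: np.ndarray             # per batch inverse-gamma rate
    n_iter: dict[str, int] | None = None


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    s_data: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means for one batch to convergence."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change, it = 1.0, 0
    while change > tol and it < max_iter:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        it += 1
    return g_old, d_old, it


class ComBat(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes batch-effect correction.

    sklearn-style transformer over a (samples x genes) array; batch labels are
    passed as ``y`` to :meth:`fit`. No covariates are modeled.

    Parameters
    ----------
    tol : float
        Relative-change convergence tolerance of the posterior iteration.
    max_iter : int
        Iteration cap per batch.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("batch labels are required (pass as y)")
        batches = pd.Series(np.asarray(y))
        levels = sorted(batches.unique().tolist())
        if len(levels) < 2:
            raise ValueError("need >= 2 batches; a single batch is an identity correction")
        counts = batches.value_counts()
        small = counts[counts < 2]
        if len(small) > 0:
            raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

        n, p = X.shape
        idx = {lv: np.flatnonzero(batches.to_numpy() == lv) for lv in levels}
        n_b = np.array([len(idx[lv]) for lv in levels], dtype=float)
        for lv in levels:
            if (X[idx[lv]].var(axis=0) == 0).all():
                raise ValueError(f"batch {lv!r} has zero variance in every gene")

        # design-based grand mean weighted by batch sizes, as in the reference model
        batch_means = np.vstack([X[idx[lv]].mean(axis=0) for lv in levels])  # B x p
        grand_mean = (n_b / n) @ batch_means
        resid = X - batch_means[[levels.index(lv) for lv in batches], :]
        pooled_var = (resid**2).sum(axis=0) / n

        if (pooled_var <= 0).any():
            # genes constant across every sample carry no batch information
            pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)

        s_data = (X - grand_mean) / np.sqrt(pooled_var)  # n x p standardized

        gamma_hat = np.vstack([s_data[idx[lv]].mean(axis=0) for lv in levels])
        delta_hat = np.vstack([s_data[idx[lv]].var(axis=0, ddof=1) for lv in levels])
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        a_prior = np.array([_aprior(delta_hat[i]) for i in range(len(levels))])
        b_prior = np.array([_bprior(delta_hat[i]) for i in range(len(levels))])

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        n_iter: dict[str, int] = {}
        for i, lv in enumerate(levels):
            g, d, it = _it_sol(
                s_data[idx[lv]].T,
                gamma_hat[i],
                delta_hat[i],
                gamma_bar[i],
                t2[i],
                a_prior[i],
                b_prior[i],
                self.tol,
                self.max_iter,
            )
            gamma_star[i], delta_star[i], n_iter[str(lv)] = g, d, it

        cols = pd.RangeIndex(p)
        self.model_ = BatchModel(
            batches=[str(lv) for lv in levels],
            grand_mean=grand_mean,
            pooled_var=pooled_var,
            gamma_hat=pd.DataFrame(gamma_hat, index=levels, columns=cols),
            delta_hat=pd.DataFrame(delta_hat, index=levels, columns=cols),
            gamma_star=pd.DataFrame(gamma_star, index=levels, columns=cols),
            delta_star=pd.DataFrame(delta_star, index=levels, columns=cols),
            gamma_bar=gamma_bar,
            t2=t2,
            a_prior=a_prior,
            b_prior=b_prior,
            n_iter=n_iter,
        )
        self._levels = levels
        self.n_features_in_ = p
        return self

    def transform(self, X, y=None):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("batch labels are required (pass as y)")
        m = self.model_
        batches = np.asarray(y)
        out = np.empty_like(X)
        for lv in np.unique(batches):
            if str(lv) not in m.batches:
                raise ValueError(f"unseen batch {lv!r}")
            rows = np.flatnonzero(batches == lv)
            g = m.gamma_star.loc[lv].to_numpy()
            d = m.delta_star.loc[lv].to_numpy()
            s = (X[rows] - m.grand_mean) / np.sqrt(m.pooled_var)
            out[rows] = (s - g) / np.sqrt(d) * np.sqrt(m.pooled_var) + m.grand_mean
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X, y)


def combat_correct(
    m: ExpressionMatrix,
    batches: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, BatchModel | None]:
    """Batch-correct a log-scale expression matrix.

    ``batches`` maps sample id -> batch label. A single batch returns the
    input unchanged (identity) with a ``None`` model.
    """
    if m.unit != "log2TPM1":
        raise ValueError(f"batch correction expects log2TPM1 expression, got {m.unit}")
    b = batches.reindex(m.samples)
    if b.isna().any():
        missing = b.index[b.isna()].tolist()
        raise ValueError(f"samples without a batch label: {missing[:5]}")
    if b.nunique() == 1:
        return m, None
    est = ComBat(tol=tol, max_iter=max_iter)
    corrected = est.fit_transform(m.values.to_numpy().T, b.to_numpy())
    out = pd.DataFrame(corrected.T, index=m.genes, columns=m.samples)
    return ExpressionMatrix(out, "log2TPM1"), est.model_
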