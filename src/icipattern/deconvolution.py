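"""Immune-cell fraction estimation from bulk expression (CIBERSORT-style).

Each sample's expression over the genes shared with the signature matrix is
regressed on the cell-type columns with linear-kernel nu-support-vector
regression over a small nu grid; the best fit (smallest residual RMSE) gives
the coefficients, negatives are clamped to zero and the rest normalized to
fractions. Both the mixture and the signature are z-standardized first, which
makes the fractions invariant to per-sample scaling. A non-negative
least-squares solver is available behind ``method="nnls"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, SignatureMatrix


@dataclass
class FractionMatrix:
    """Per-sample cell-type fractions with fit diagnostics."""

    fractions: pd.DataFrame   # samples x cell types
    diagnostics: pd.DataFrame  # samples x (rmse, correlation, nu, degenerate)

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)


def select_signature_genes(s: SignatureMatrix, top_n: int = 150) -> SignatureMatrix:
    """Keep the ``top_n`` most discriminative signature rows (largest
    across-cell-type contrast), mirroring how curated deconvolution
    references restrict themselves to marker genes."""
    if s.values.shape[0] <= top_n:
        return s
    contrast = s.values.max(axis=1) - s.values.min(axis=1)
    keep = contrast.sort_values(ascending=False).index[:top_n]
    keep = [g for g in s.genes if g in set(keep)]
    return SignatureMatrix(s.values.loc[keep])


def _fit_sample_svr(S: np.ndarray, y: np.ndarray, nu_grid) -> tuple[np.ndarray, float, float]:
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(S, y)
        resid = model.predict(S) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        if best is None or rmse < best[1]:
            best = (model.coef_.ravel().copy(), rmse, nu)
    return best


def _fit_sample_nnls(S: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    coef, rnorm = nnls(S, y)
    rmse = float(rnorm / np.sqrt(len(y)))
    return coef, rmse, np.nan


class SVRDeconvolution(TransformerMixin, BaseEstimator):
    """nu-SVR deconvolution estimator.

    ``fit`` aligns the signature with the expression genes; ``transform`` maps
    a (samples x genes) frame to (samples x cell types) fractions.

    Parameters
    ----------
    signature : SignatureMatrix or DataFrame (genes x cell types)
    nu_grid : iterable of float
        Candidate nu values; the per-sample fit with smallest residual RMSE wins.
    method : {"svr", "nnls"}
    """

    def __init__(self, signature=None, nu_grid=(0.25, 0.5, 0.75), method: str = "svr"):
        self.signature = signature
        self.nu_grid = nu_grid
        self.method = method

    def _sig_frame(self) -> pd.DataFrame:
        if self.signature is None:
            raise ValueError("a signature matrix is required")
        if isinstance(self.signature, SignatureMatrix):
            return self.signature.values
        return pd.DataFrame(self.signature)

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene-symbol columns")
        sig = self._sig_frame()
        shared = [g for g in sig.index if g in set(X.columns)]
        if len(shared) < sig.shape[1]:
            raise ValueError(
                f"only {len(shared)} genes shared between expression and signature; "
                f"need at least {sig.shape[1]}"
            )
        self.shared_genes_ = shared
        self.signature_matrix_ = sig.loc[shared]
        S = self.signature_matrix_.to_numpy()
        self.column_scale_ = S.std(axis=0)
        if (self.column_scale_ == 0).any():
            raise ValueError("signature has a constant cell-type column")
        self.signature_std_ = (S - S.mean(axis=0)) / self.column_scale_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "signature_std_")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene-symbol columns")
        E = X[self.shared_genes_].to_numpy(dtype=float)
        k = self.signature_std_.shape[1]
        fracs = np.full((E.shape[0], k), np.nan)
        diag = []
        for i in range(E.shape[0]):
            y = E[i]
            sd = y.std()
            if sd == 0:
                warnings.warn(f"sample {X.index[i]!r} constant over signature genes; flagged")
                diag.append((np.nan, np.nan, np.nan, True))
                continue
            yz = (y - y.mean()) / sd
            if self.method == "svr":
                coef, rmse, nu = _fit_sample_svr(self.signature_std_, yz, self.nu_grid)
            elif self.method == "nnls":
                coef, rmse, nu = _fit_sample_nnls(self.signature_std_, yz)
            else:
                raise ValueError(f"unknown method {self.method!r}")
            coef = coef / self.column_scale_  # undo per-column standardization
            coef = np.clip(coef, 0.0, None)
            total = coef.sum()
            if total <= 0:
                warnings.warn(f"sample {X.index[i]!r}: all coefficients non-positive; flagged")
                diag.append((rmse, np.nan, nu, True))
                continue
            fracs[i] = coef / total
            fitted = self.signature_std_ @ coef
            corr = float(np.corrcoef(fitted, yz)[0, 1]) if fitted.std() > 0 else np.nan
            diag.append((rmse, corr, nu, False))
        self.diagnostics_ = pd.DataFrame(
            diag, index=X.index, columns=["rmse", "correlation", "nu", "degenerate"]
        )
        return pd.DataFrame(fracs, index=X.index, columns=self.signature_matrix_.columns)


def deconvolve(
    m: ExpressionMatrix,
    s: SignatureMatrix,
    nu_grid=(0.25, 0.5, 0.75),
    method: str = "svr",
) -> FractionMatrix:
    """Estimate cell-type fractions for every sample of an expression matrix.

    Log-scale expression is anti-logged back to the linear scale before
    fitting; the signature is assumed linear-scale.
    """
    vals = m.values
    if m.unit == "log2TPM1":
        vals = np.power(2.0, vals) - 1.0
    est = SVRDeconvolution(signature=s, nu_grid=nu_grid, method=method)
    wide = vals.T  # samples x genes
    fractions = est.fit(wide).transform(wide)
    return FractionMatrix(fractions, est.diagnostics_)
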