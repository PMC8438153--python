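"""Single-sample gene-set enrichment (ssGSEA) and immune/stroma scores.

The per-sample score is the weighted Kolmogorov-Smirnov-style running sum:
genes are ranked by expression within the sample, and the enrichment score of
a set is the *sum* over all list positions of the gap between the weighted
in-set ECDF (weights |rank statistic|^alpha, normalized over the set) and the
uniform out-of-set ECDF. The rank statistic is the per-sample expression
midrank, which makes the score invariant to the unit the expression arrived in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, GeneSetCollection


@dataclass
class EnrichmentScoreMatrix:
    """Gene-set x sample enrichment scores."""

    scores: pd.DataFrame  # sets x samples
    alpha: float
    normalized: bool

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


def _sample_es(order: np.ndarray, weights: np.ndarray, in_set: np.ndarray) -> float:
    """Running-sum ES for one sample.

    order: gene indices sorted best-first; weights: |rank statistic|^alpha per
    gene; in_set: boolean per gene.
    """
    members = in_set[order]
    w = np.where(members, weights[order], 0.0)
    wsum = w.sum()
    n_out = len(order) - members.sum()
    p_in = np.cumsum(w) / wsum
    p_out = np.cumsum(~members) / n_out
    return float(np.sum(p_in - p_out))


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping (samples x genes) to (samples x sets).

    Parameters
    ----------
    gene_sets : GeneSetCollection or mapping of name -> gene list
    alpha : float
        Rank-weighting exponent (0 gives the unweighted KS running sum).
    normalize : bool
        Divide every score by (max ES - min ES) over the whole matrix.
    """

    def __init__(self, gene_sets=None, alpha: float = 0.25, normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def _sets(self) -> dict[str, list[str]]:
        if self.gene_sets is None:
            raise ValueError("gene_sets is required")
        if isinstance(self.gene_sets, GeneSetCollection):
            return self.gene_sets.sets
        return dict(self.gene_sets)

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene-symbol columns")
        genes = list(X.columns)
        gene_pos = {g: i for i, g in enumerate(genes)}
        self.set_masks_ = {}
        for name, members in self._sets().items():
            mask = np.zeros(len(genes), dtype=bool)
            hit = [gene_pos[g] for g in members if g in gene_pos]
            if not hit:
                raise ValueError(f"gene set {name!r} has no overlap with the expression genes")
            mask[hit] = True
            if mask.all():
                raise ValueError(
                    f"gene set {name!r} covers the whole gene universe; out-of-set ECDF undefined"
                )
            self.set_masks_[name] = mask
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        return self

    def transform(self, X):
        check_is_fitted(self, "set_masks_")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene-symbol columns")
        if list(X.columns) != list(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        vals = X.to_numpy(dtype=float)
        n_samples, n_genes = vals.shape
        out = np.empty((n_samples, len(self.set_masks_)))
        for i in range(n_samples):
            v = vals[i]
            # midranks, so equal expression gets equal weight regardless of order
            stat = rankdata(v, method="average")
            # best-first walk; ties broken by stable gene position
            order = np.lexsort((np.arange(n_genes), -v))
            weights = np.abs(stat) ** self.alpha
            for j, mask in enumerate(self.set_masks_.values()):
                out[i, j] = _sample_es(order, weights, mask)
        if self.normalize:
            rng = out.max() - out.min()
            if rng > 0:
                out = out / rng
        return pd.DataFrame(out, index=X.index, columns=list(self.set_masks_))


def ssgsea_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScoreMatrix:
    """Score every gene set in every sample of an expression matrix."""
    scorer = SSGSEAScorer(gene_sets=sets, alpha=alpha, normalize=normalize)
    wide = m.values.T  # samples x genes
    scores = scorer.fit(wide).transform(wide)
    return EnrichmentScoreMatrix(scores.T, alpha=alpha, normalized=normalize)


def estimate_scores(
    m: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
) -> EnrichmentScoreMatrix:
    """Immune and stroma infiltration scores: unnormalized ssGSEA (alpha=0.25)
    of the two curated sets, returned as a 2-row matrix."""
    sets = GeneSetCollection({"ImmuneScore": list(immune_set), "StromaScore": list(stromal_set)})
    es = ssgsea_scores(m, sets, alpha=0.25, normalize=False)
    return es
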