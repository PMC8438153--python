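"""DEG discovery, signed signature construction, and the ICI score.

The score construction: differentially expressed genes between the
infiltration subtypes are split by the sign of their Pearson correlation with
a per-sample cluster signature into signature A (positive) and signature B
(negative); each signature is optionally reduced by Boruta all-relevant
selection; per-sample ssGSEA scores of the two signatures give

    ICIscore = ScoreA - ScoreB

and the cohort is dichotomized at the median (ties to the low group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .enrichment import ssgsea_scores
from .io import ExpressionMatrix, GeneSetCollection


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Moderated-t differential expression
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma-style)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-8:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes variance shrinkage by moment-matching a scaled-F model.

    Returns (prior df d0, prior variance s0^2, posterior variances). d0 may be
    inf when the sample variances are more concordant than chance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, np.nan))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = np.nanmean(e)
    evar = np.nanvar(e, ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
        post = np.full_like(s2, s0_2)
    return float(d0), float(s0_2), post


def _two_group_moderated(
    X1: np.ndarray, X0: np.ndarray, prior_df: float | None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-gene moderated t between two groups (rows = genes)."""
    n1, n0 = X1.shape[1], X0.shape[1]
    df = n1 + n0 - 2
    m1, m0 = X1.mean(axis=1), X0.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X0 - m0[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if prior_df is not None and prior_df == 0:
        d0, post = 0.0, s2
    else:
        d0, _, post = squeeze_variances(s2, df)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m0) / se, 0.0)
    total_df = df + (0 if not np.isfinite(d0) else d0)
    if np.isfinite(d0):
        p = 2 * stats.t.sf(np.abs(t), df + d0)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    return t, p, total_df


def find_degs(
    m: ExpressionMatrix,
    labels: pd.Series,
    fc_cutoff: float = 1.65,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression, one-vs-rest per subtype.

    Expression must be on the log2 scale so group mean differences are log2
    fold changes. Significance: BH-adjusted p < ``alpha`` within contrast and
    |log2FC| >= log2(``fc_cutoff``). The pooled DEG set is the union of
    significant genes over contrasts (see :func:`significant_genes`).

    Set ``prior_df=0`` to disable shrinkage (ordinary two-sample t).
    """
    labels = labels.reindex(m.samples)
    if labels.isna().any():
        raise ValueError("every sample needs a subtype label")
    levels = sorted(labels.unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 subtypes for differential expression")
    counts = labels.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"subtypes with fewer than 3 samples: {small}")

    X = m.values.to_numpy()
    lab = labels.to_numpy()
    frames = []
    lfc_thresh = np.log2(fc_cutoff)
    for lv in levels:
        in_g = lab == lv
        X1, X0 = X[:, in_g], X[:, ~in_g]
        if np.allclose(X1.var(axis=1), 0) or np.allclose(X0.var(axis=1), 0):
            raise ValueError(f"group {lv!r} (or its complement) has zero variance in all genes")
        t, p, _ = _two_group_moderated(X1, X0, prior_df)
        lfc = X1.mean(axis=1) - X0.mean(axis=1)
        adj = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "gene": m.genes,
                    "contrast": f"{lv}_vs_rest",
                    "log2_fc": lfc,
                    "t": t,
                    "p": p,
                    "adj_p": adj,
                    "significant": (adj < alpha) & (np.abs(lfc) >= lfc_thresh),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def significant_genes(degs: pd.DataFrame) -> list[str]:
    """Union of significant genes over all contrasts, in stable gene order."""
    sig = degs.loc[degs["significant"], "gene"]
    seen: set[str] = set()
    return [g for g in sig if not (g in seen or seen.add(g))]


# ---------------------------------------------------------------------------
# Signed signature partitioning
# ---------------------------------------------------------------------------


@dataclass
class SignatureSet:
    """Signed DEG signatures: A correlates positively with the cluster
    signature, B negatively. ``reduced_*`` hold the Boruta-confirmed subsets."""

    genes_a: list[str]
    genes_b: list[str]
    correlations: pd.Series
    reduced_a: list[str] | None = None
    reduced_b: list[str] | None = None
    excluded: list[str] = field(default_factory=list)

    def active(self) -> tuple[list[str], list[str]]:
        a = self.reduced_a if self.reduced_a is not None else self.genes_a
        b = self.reduced_b if self.reduced_b is not None else self.genes_b
        return a, b


def encode_cluster_signature(
    gene_cluster_labels: pd.Series, immune_score: pd.Series, scheme: str = "ordinal"
) -> pd.Series:
    """Turn gene-cluster labels into the numeric per-sample cluster signature.

    ``ordinal``: clusters ranked by mean immune score (coldest = 0). ``indicator``:
    1 for the hottest cluster, 0 otherwise.
    """
    means = immune_score.groupby(gene_cluster_labels).mean().sort_values()
    rank = {c: i for i, c in enumerate(means.index)}
    ordinal = gene_cluster_labels.map(rank).astype(float)
    if scheme == "ordinal":
        return ordinal.rename("cluster_signature")
    if scheme == "indicator":
        return (ordinal == ordinal.max()).astype(float).rename("cluster_signature")
    raise ValueError(f"unknown cluster-signature scheme {scheme!r}")


def partition_signatures(
    m: ExpressionMatrix, degs: list[str], cluster_signature: pd.Series
) -> SignatureSet:
    """Split DEGs by the sign of their Pearson correlation with the cluster signature."""
    sig = cluster_signature.reindex(m.samples)
    if sig.isna().any():
        raise ValueError("cluster signature must be defined for every sample")
    s = sig.to_numpy(dtype=float)
    if np.std(s) == 0:
        raise ValueError("cluster signature is constant; correlations undefined")
    sc = (s - s.mean())
    sden = np.sqrt((sc**2).sum())
    genes_a, genes_b, excluded, rs = [], [], [], {}
    X = m.values.loc[degs].to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    xden = np.sqrt((Xc**2).sum(axis=1))
    for i, gene in enumerate(degs):
        if xden[i] == 0:
            warnings.warn(f"gene {gene!r} is constant; excluded from signatures")
            excluded.append(gene)
            continue
        r = float(Xc[i] @ sc / (xden[i] * sden))
        rs[gene] = r
        if r > 0:
            genes_a.append(gene)
        elif r < 0:
            genes_b.append(gene)
        else:
            excluded.append(gene)
    return SignatureSet(genes_a, genes_b, pd.Series(rs, name="pearson_r"), excluded=excluded)


# ---------------------------------------------------------------------------
# Boruta all-relevant feature selection
# ---------------------------------------------------------------------------


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Boruta feature selection against shadow (permuted) features.

    Each iteration appends a shuffled copy of every still-active feature,
    fits a random forest, and scores a *hit* for features whose importance
    beats the best shadow. Accumulated hits are tested against Binomial(n, 1/2)
    two-sidedly (BH-corrected): significantly many hits confirms a feature,
    significantly few rejects it. Features still undecided at ``max_iter``
    are dropped (conservative).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_iter: int = 100,
        alpha: float = 0.05,
        min_iter_before_test: int = 5,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.min_iter_before_test = min_iter_before_test
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least 2 target classes")
        if n < len(classes):
            raise ValueError("fewer samples than classes")
        rng = np.random.default_rng(self.random_state)

        status = np.zeros(p, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
        hits = np.zeros(p, dtype=int)
        trials = 0
        for it in range(self.max_iter):
            active = np.flatnonzero(status == 0)
            if len(active) == 0:
                break
            Xa = X[:, active]
            shadows = Xa.copy()
            for j in range(shadows.shape[1]):
                shadows[:, j] = rng.permutation(shadows[:, j])
            rf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(np.hstack([Xa, shadows]), y)
            imp = rf.feature_importances_
            real, shadow = imp[: len(active)], imp[len(active) :]
            thresh = shadow.max()
            hits[active[real > thresh]] += 1
            trials += 1
            if trials < self.min_iter_before_test:
                continue
            tentative = np.flatnonzero(status == 0)
            k = hits[tentative]
            p_hi = stats.binom.sf(k - 1, trials, 0.5)   # P[K >= k]: many hits
            p_lo = stats.binom.cdf(k, trials, 0.5)      # P[K <= k]: few hits
            adj_hi = bh_adjust(np.minimum(1.0, 2 * p_hi))
            adj_lo = bh_adjust(np.minimum(1.0, 2 * p_lo))
            status[tentative[adj_hi < self.alpha]] = 1
            status[tentative[(adj_lo < self.alpha) & (adj_hi >= self.alpha)]] = -1

        self.support_ = status == 1
        self.confirmed_ = np.flatnonzero(status == 1)
        self.rejected_ = np.flatnonzero(status == -1)
        self.tentative_ = np.flatnonzero(status == 0)
        self.n_iterations_ = trials
        self.hit_counts_ = hits
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def boruta_reduce(
    m: ExpressionMatrix,
    candidate_genes: list[str],
    target: pd.Series,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    n_estimators: int = 100,
) -> list[str]:
    """Boruta-confirmed subset of ``candidate_genes`` for predicting ``target``."""
    missing = [g for g in candidate_genes if g not in m.values.index]
    if missing:
        raise ValueError(f"candidate genes not in expression matrix: {missing[:5]}")
    y = target.reindex(m.samples)
    if y.isna().any():
        raise ValueError("target label must be defined for every sample")
    X = m.values.loc[candidate_genes].to_numpy().T  # samples x genes
    sel = BorutaSelector(
        n_estimators=n_estimators, max_iter=max_iter, alpha=alpha, random_state=seed
    )
    sel.fit(X, y.to_numpy())
    return [candidate_genes[i] for i in sel.confirmed_]


# ---------------------------------------------------------------------------
# The ICI score
# ---------------------------------------------------------------------------


@dataclass
class ICIScoreTable:
    """Per-sample ScoreA, ScoreB, ICIscore and the median-split group."""

    table: pd.DataFrame  # sample_id, score_a, score_b, ici_score, group
    median: float

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("sample_id")["ici_score"]

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]


def median_split(scores: pd.Series) -> tuple[pd.Series, float]:
    """High/low split at the cohort median; ties go to the low group."""
    med = float(scores.median())
    groups = pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="group")
    return groups, med


def ici_score(
    m: ExpressionMatrix,
    sig: SignatureSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ICIScoreTable:
    """Score a cohort with a signed signature pair: ICIscore = ScoreA - ScoreB."""
    genes_a, genes_b = sig.active()
    if not genes_a or not genes_b:
        raise ValueError("both signatures must be non-empty to compute the ICI score")
    sets = GeneSetCollection({"ICI_signature_A": genes_a, "ICI_signature_B": genes_b})
    es = ssgsea_scores(m, sets, alpha=alpha, normalize=normalize)
    score_a = es.scores.loc["ICI_signature_A"]
    score_b = es.scores.loc["ICI_signature_B"]
    ici = score_a - score_b
    groups, med = median_split(ici)
    table = pd.DataFrame(
        {
            "sample_id": m.samples,
            "score_a": score_a.to_numpy(),
            "score_b": score_b.to_numpy(),
            "ici_score": ici.to_numpy(),
            "group": groups.to_numpy(),
        }
    )
    return ICIScoreTable(table, med)
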