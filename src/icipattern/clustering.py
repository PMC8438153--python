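"""Resampling consensus clustering with CDF/delta-area model selection.

For each candidate k, samples are repeatedly subsampled (default 90%) and
clustered; the consensus matrix holds, for every sample pair, the fraction of
co-sampled repetitions in which the pair landed in the same cluster. The
number of clusters is chosen from the relative change in area under the CDF
of consensus values (delta-area), and final labels come from clustering the
consensus matrix itself as a similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if metric == "spearman":
        # 1 - Spearman correlation between sample profiles
        ranks = np.apply_along_axis(rankdata, 1, X)
        c = np.corrcoef(ranks)
        return 1.0 - c
    raise ValueError(f"unknown distance {metric!r}")


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator | None = None, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix.

    Deterministic BUILD initialization (first medoid minimizes total distance,
    each next one maximizes the drop in cost) followed by alternating
    assignment/medoid-update passes.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    for _ in range(1, k):
        # gain of promoting candidate c: sum over points of max(nearest - D[:, c], 0)
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])
    medoids = np.array(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


def _base_cluster(
    X: np.ndarray,
    D: np.ndarray,
    k: int,
    method: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if method == "pam":
        return _kmedoids(D, k, rng)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
        return km.fit_predict(X)
    if method == "hierarchical":
        Z = linkage(squareform(D, checks=False), method="average")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base method {method!r}")


@dataclass
class ConsensusResult:
    """Consensus matrices over k, CDF areas, delta-areas, the chosen k and labels."""

    k_range: list[int]
    consensus: dict[int, np.ndarray]
    cosampled: np.ndarray                 # pair co-sampling counts
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    labels: pd.Series
    reps: int
    subsample_fraction: float
    distance: str
    base_method: str
    seed: int | None
    delta_threshold: float = 0.1
    never_cosampled_pairs: int = 0

    def manifest(self) -> dict:
        return {
            "k_range": self.k_range,
            "reps": self.reps,
            "subsample_fraction": self.subsample_fraction,
            "distance": self.distance,
            "base_method": self.base_method,
            "seed": self.seed,
            "chosen_k": int(self.chosen_k),
            "delta_threshold": self.delta_threshold,
            "cdf_areas": {str(k): v for k, v in self.cdf_areas.items()},
            "delta_areas": {str(k): v for k, v in self.delta_areas.items()},
            "never_cosampled_pairs": int(self.never_cosampled_pairs),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        idx = self.labels.index
        for k, M in self.consensus.items():
            pd.DataFrame(M, index=idx, columns=idx).to_csv(
                outdir / f"consensus_k{k}.tsv", sep="\t"
            )
        self.labels.to_csv(outdir / "labels.tsv", sep="\t", header=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


class ConsensusCluster(ClusterMixin, BaseEstimator):
    """Consensus clustering estimator over a (samples x features) matrix.

    Parameters
    ----------
    k_range : iterable of int
        Candidate cluster counts (each >= 2).
    reps : int
        Number of subsampling repetitions.
    subsample_fraction : float
        Fraction of samples drawn (without replacement) per repetition.
    distance : {"euclidean", "spearman"}
    base_method : {"pam", "kmeans", "hierarchical"}
        Inner clustering algorithm; kmeans requires euclidean distance.
    delta_threshold : float
        Chosen k = the largest k whose relative delta-area is >= this
        threshold, falling back to the argmax of the delta-area.
    random_state : int or None
    """

    def __init__(
        self,
        k_range=(2, 3, 4, 5, 6),
        reps: int = 100,
        subsample_fraction: float = 0.9,
        distance: str = "euclidean",
        base_method: str = "pam",
        delta_threshold: float = 0.1,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.reps = reps
        self.subsample_fraction = subsample_fraction
        self.distance = distance
        self.base_method = base_method
        self.delta_threshold = delta_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        ks = sorted(int(k) for k in self.k_range)
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if min(ks) < 2:
            raise ValueError("k_range values must be >= 2")
        m = int(np.ceil(self.subsample_fraction * n))
        if max(ks) > m:
            raise ValueError(f"max k ({max(ks)}) exceeds subsample size ({m})")
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("constant feature matrix cannot be clustered")
        if self.base_method == "kmeans" and self.distance != "euclidean":
            raise ValueError("kmeans supports only euclidean distance")

        rng = np.random.default_rng(self.random_state)
        D = _distance_matrix(X, self.distance)

        together = {k: np.zeros((n, n)) for k in ks}
        cosampled = np.zeros((n, n))
        for _ in range(self.reps):
            idx = rng.choice(n, size=m, replace=False)
            idx.sort()
            sub = np.ix_(idx, idx)
            cosampled[sub] += 1
            Dsub = D[sub]
            Xsub = X[idx]
            for k in ks:
                labels = _base_cluster(Xsub, Dsub, k, self.base_method, rng)
                same = labels[:, None] == labels[None, :]
                together[k][sub] += same

        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = {k: np.where(cosampled > 0, together[k] / cosampled, np.nan) for k in ks}
        for k in ks:
            np.fill_diagonal(consensus[k], 1.0)

        iu = np.triu_indices(n, k=1)
        never = int(np.isnan(consensus[ks[0]][iu]).sum())
        areas: dict[int, float] = {}
        for k in ks:
            vals = consensus[k][iu]
            vals = vals[~np.isnan(vals)]
            # area under the empirical CDF of consensus values over [0, 1]
            areas[k] = float(1.0 - vals.mean())
        deltas: dict[int, float] = {}
        prev = None
        for k in ks:
            if prev is None:
                deltas[k] = areas[k]
            else:
                deltas[k] = max(0.0, (areas[k] - areas[prev]) / areas[prev]) if areas[prev] > 0 else 0.0
            prev = k

        eligible = [k for k in ks if deltas[k] >= self.delta_threshold]
        chosen = max(eligible) if eligible else max(deltas, key=deltas.get)

        labels = self._labels_from_consensus(consensus[chosen], chosen, rng)

        self.consensus_matrices_ = consensus
        self.cosampled_counts_ = cosampled
        self.cdf_areas_ = areas
        self.delta_areas_ = deltas
        self.chosen_k_ = int(chosen)
        self.labels_ = labels
        self.result_ = ConsensusResult(
            k_range=ks,
            consensus=consensus,
            cosampled=cosampled,
            cdf_areas=areas,
            delta_areas=deltas,
            chosen_k=int(chosen),
            labels=pd.Series(labels, index=index, name="cluster"),
            reps=self.reps,
            subsample_fraction=self.subsample_fraction,
            distance=self.distance,
            base_method=self.base_method,
            seed=self.random_state,
            delta_threshold=self.delta_threshold,
            never_cosampled_pairs=never,
        )
        return self

    @staticmethod
    def _labels_from_consensus(M: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        M = M.copy()
        nan = np.isnan(M)
        if nan.any():
            # never co-sampled pairs: impute the mean observed consensus
            M[nan] = np.nanmean(M)
        Dc = 1.0 - M
        np.fill_diagonal(Dc, 0.0)
        Dc = (Dc + Dc.T) / 2
        Z = linkage(squareform(Dc, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) != k:
            labels = _kmedoids(Dc, k, rng)
        return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster(
    features,
    k_range=(2, 3, 4, 5, 6),
    reps: int = 100,
    subsample_fraction: float = 0.9,
    distance: str = "euclidean",
    base_method: str = "pam",
    delta_threshold: float = 0.1,
    seed: int | None = None,
) -> ConsensusResult:
    """Functional wrapper over :class:`ConsensusCluster`; features are samples x columns."""
    est = ConsensusCluster(
        k_range=k_range,
        reps=reps,
        subsample_fraction=subsample_fraction,
        distance=distance,
        base_method=base_method,
        delta_threshold=delta_threshold,
        random_state=seed,
    )
    est.fit(features)
    return est.result_
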