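"""Subspace extraction, k-means subtyping and per-cluster signatures.

Once the low-rank parameter matrix Theta is fitted, its SVD
``Theta = U S V^T`` has at most r non-zero singular values, and the leading r
components of ``S V^T`` are an r-vector of coordinates per sample — the
dimension-reduction result.  Samples are clustered in that space with
k-means; the cluster number is chosen where the mean silhouette value peaks.
A light-weight signature step ranks features by a two-group test of each
cluster against the rest (rank-sum for continuous/count features, two-
proportion z-test for binary), with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import mannwhitneyu, norm
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .likelihoods import OmicsBlock, ParameterMatrix

__all__ = [
    "ReducedRepresentation",
    "ClusterResult",
    "reduce",
    "kmeans_cluster",
    "silhouette_value",
    "silhouette_samples",
    "scan_clusters",
    "best_k",
    "signature_features",
    "KScanEntry",
]


@dataclass
class ReducedRepresentation:
    """r-dimensional sample coordinates, rows ordered by singular value."""

    coords: np.ndarray  # (rank, n_samples)
    sample_ids: list[str] = field(default_factory=list)
    rank: int = 0
    singular_values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.rank == 0:
            self.rank = self.coords.shape[0]
        if self.coords.shape[0] != self.rank:
            raise ValueError("coords row count must equal rank")
        if not self.sample_ids:
            self.sample_ids = [f"S{j}" for j in range(self.coords.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterResult:
    """k-means assignment with silhouette diagnostics, labels in 1..k."""

    labels: np.ndarray
    k: int
    silhouette: float
    per_sample_silhouette: np.ndarray
    seed: int
    restarts: int


def reduce(theta: ParameterMatrix, rank: int) -> ReducedRepresentation:
    """Project the fitted Theta onto its top ``rank`` singular directions.

    Returns the leading ``rank`` rows of ``S V^T`` from ``Theta = U S V^T``;
    each column is one sample's coordinates.  Sign convention: the largest-
    magnitude entry of each row is made non-negative (SVD signs are
    arbitrary; fixing them makes plots reproducible).
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    _, s, Vt = np.linalg.svd(theta.theta, full_matrices=False)
    if rank > s.size:
        raise ValueError(f"rank {rank} exceeds matrix dimension {s.size}")
    nonzero = int((s > 1e-12 * max(s[0], 1.0)).sum())
    if nonzero < rank:
        warnings.warn(
            f"only {nonzero} non-zero singular values; trailing coordinate "
            "rows are zero",
            UserWarning,
        )
    coords = s[:rank, None] * Vt[:rank]
    for i in range(rank):
        j = int(np.argmax(np.abs(coords[i])))
        if coords[i, j] < 0:
            coords[i] = -coords[i]
    return ReducedRepresentation(
        coords=coords,
        sample_ids=list(theta.sample_ids),
        rank=rank,
        singular_values=s[:rank].copy(),
    )


def silhouette_samples(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette values ``(b - a) / max(a, b)``.

    ``coords`` holds one sample per column; distances are Euclidean in that
    space.  ``a`` is the mean distance to the sample's own cluster (excluding
    itself), ``b`` the smallest mean distance to another cluster.  Samples in
    singleton clusters score 0 (Rousseeuw's convention), as does the
    degenerate 0/0 case of coincident points.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = coords.shape[1]
    if labels.shape != (n,):
        raise ValueError("labels length must equal the number of samples")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = squareform(pdist(coords.T))
    sil = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        own = labels == c
        a = D[i, own].sum() / (sizes[c] - 1)
        b = min(D[i, labels == other].mean() for other in uniq if other != c)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return sil


def silhouette_value(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette value over all samples."""
    return float(silhouette_samples(coords, labels).mean())


def kmeans_cluster(
    rep: ReducedRepresentation,
    k: int,
    restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-restarts Lloyd k-means on the sample coordinates.

    Deterministic given ``seed``; silhouette values are computed in the
    reduced space.  A fully degenerate geometry (all samples coincident)
    yields silhouette 0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > rep.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples {rep.n_samples}")
    X = rep.coords.T
    if np.allclose(X, X[0]):
        # every partition of coincident points is equivalent; return a
        # deterministic one rather than whatever k-means collapses to
        warnings.warn("all samples coincide; silhouette set to 0", UserWarning)
        return ClusterResult(
            labels=np.arange(rep.n_samples) % k + 1,
            k=k,
            silhouette=0.0,
            per_sample_silhouette=np.zeros(rep.n_samples),
            seed=seed,
            restarts=restarts,
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X) + 1  # 1-based cluster ids
    if np.unique(labels).size < k:
        raise RuntimeError("k-means produced an empty cluster")
    per = silhouette_samples(rep.coords, labels)
    return ClusterResult(
        labels=labels,
        k=k,
        silhouette=float(per.mean()),
        per_sample_silhouette=per,
        seed=seed,
        restarts=restarts,
    )


class KScanEntry(NamedTuple):
    k: int
    silhouette: float
    result: ClusterResult


def scan_clusters(
    rep: ReducedRepresentation,
    ks: Sequence[int],
    restarts: int = 20,
    seed: int = 0,
) -> list[KScanEntry]:
    """Cluster at each candidate k and collect the silhouette curve."""
    if any(k < 2 for k in ks):
        raise ValueError("all candidate k must be >= 2")
    return [
        KScanEntry(k, (res := kmeans_cluster(rep, k, restarts, seed)).silhouette, res)
        for k in ks
    ]


def best_k(curve: Sequence[KScanEntry]) -> int:
    """Recommended cluster number: the k with the largest mean silhouette."""
    return max(curve, key=lambda e: e.silhouette).k


def _binary_two_proportion(x_in, x_out):
    """Two-sided two-proportion z-test with pooled variance."""
    n1, n2 = x_in.size, x_out.size
    p1, p2 = x_in.mean(), x_out.mean()
    pooled = (x_in.sum() + x_out.sum()) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


def signature_features(
    blocks: list[OmicsBlock],
    labels: np.ndarray,
    cluster,
) -> pd.DataFrame:
    """Rank features by a two-group comparison: one cluster versus the rest.

    Continuous and count features use the Wilcoxon rank-sum (Mann-Whitney U)
    test, binary features a two-proportion z-test.  P-values are Benjamini-
    Hochberg adjusted across all features of all blocks; ``direction`` is the
    sign of the in-cluster minus out-of-cluster mean.  All-constant features
    get p = 1 and are flagged.  This is a post-hoc description of clusters,
    not part of the model fit.
    """
    labels = np.asarray(labels)
    in_group = labels == cluster
    if not in_group.any():
        raise ValueError(f"cluster {cluster!r} is empty")
    if in_group.all():
        raise ValueError(f"cluster {cluster!r} has an empty complement")

    rows = []
    for b in blocks:
        for i in range(b.n_features):
            m = b.mask[i]
            x_in = b.data[i, in_group & m]
            x_out = b.data[i, ~in_group & m]
            if x_in.size == 0 or x_out.size == 0:
                rows.append((b.name, b.feature_ids[i], np.nan, 1.0, 0.0, True))
                continue
            constant = np.unique(np.concatenate([x_in, x_out])).size == 1
            diff = float(x_in.mean() - x_out.mean())
            if constant:
                stat, p = np.nan, 1.0
            elif b.dtype == "binary":
                stat, p = _binary_two_proportion(x_in, x_out)
            else:
                stat, p = mannwhitneyu(x_in, x_out, alternative="two-sided")
            rows.append((b.name, b.feature_ids[i], float(stat), float(p), diff, constant))

    df = pd.DataFrame(
        rows, columns=["block", "feature_id", "statistic", "p_value", "effect", "constant"]
    )
    df["adj_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["direction"] = np.where(df["effect"] > 0, "up", np.where(df["effect"] < 0, "down", "none"))
    return df.sort_values(["adj_p", "p_value"], kind="stable").reset_index(drop=True)
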