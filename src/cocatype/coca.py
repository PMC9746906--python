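"""Cluster-of-clusters (COCA) integration by resampled consensus clustering.

Per-platform cluster memberships are one-hot encoded into a sample x
(total clusters) binary matrix.  The Monti consensus procedure then
repeatedly subsamples the cohort, clusters each subsample by average-
linkage hierarchical clustering on Euclidean distance, and accumulates
co-assignment frequencies into a per-K consensus matrix.  The number of
integrated subtypes is chosen from the area under the empirical CDF of
consensus entries: the largest K whose relative area gain over K-1 still
exceeds a threshold.  Final labels come from average-linkage clustering of
1 - consensus at the selected K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .platform_clustering import ClusterAssignment, _relabel_first_occurrence

logger = logging.getLogger(__name__)


@dataclass
class BinaryMembershipMatrix:
    values: pd.DataFrame  # sample x (platform:cluster) 0/1
    n_platforms: int


@dataclass
class ConsensusResult:
    consensus_by_k: dict[int, pd.DataFrame]
    area_by_k: dict[int, float]
    delta_by_k: dict[int, float]  # relative area change, defined for K > min
    selected_k: int
    labels: pd.Series  # final labels at selected_k
    labels_by_k: dict[int, pd.Series] = field(default_factory=dict)
    item_fraction: float = 0.8
    repetitions: int = 1000
    seed: int = 0
    n_never_cosampled: int = 0


def encode_binary_membership(assignments: list[ClusterAssignment]) -> BinaryMembershipMatrix:
    """One-hot encode platform cluster memberships; every sample must carry a
    label on every platform (samples lacking a platform are an error, not an
    imputation case)."""
    if not assignments:
        raise ValueError("no platform assignments supplied")
    samples = assignments[0].labels.index
    for a in assignments[1:]:
        missing = samples.symmetric_difference(a.labels.index)
        if len(missing):
            raise ValueError(
                f"samples not shared across platforms: {sorted(map(str, missing))[:10]}"
            )
    blocks = []
    for a in assignments:
        onehot = pd.get_dummies(a.labels.loc[samples]).astype(int)
        onehot.columns = [f"{a.platform}:{c}" for c in onehot.columns]
        blocks.append(onehot)
    values = pd.concat(blocks, axis=1)
    assert (values.sum(axis=1) == len(assignments)).all()
    return BinaryMembershipMatrix(values=values, n_platforms=len(assignments))


def _consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    d = squareform(1.0 - consensus, checks=False)
    Z = hierarchy.linkage(d, method="average")
    return _relabel_first_occurrence(hierarchy.fcluster(Z, t=k, criterion="maxclust"))


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangular consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    x = np.sort(consensus[iu])
    n = x.size
    xs, idx = np.unique(x, return_index=True)
    cdf = (np.append(idx[1:], n)) / n  # P(X <= x) at each unique value
    if xs[0] > 0:
        xs = np.insert(xs, 0, 0.0)
        cdf = np.insert(cdf, 0, 0.0)
    return float(np.sum(np.diff(xs) * cdf[1:])) if len(xs) > 1 else 0.0


def consensus_cluster(
    binary: BinaryMembershipMatrix,
    k_range: range | list[int],
    item_fraction: float = 0.8,
    repetitions: int = 1000,
    seed: int = 0,
    *,
    delta_threshold: float = 0.05,
    linkage: str = "average",
) -> ConsensusResult:
    """Resampled consensus clustering of the binary membership matrix.

    consensus(i, j) = (# repetitions clustering i with j) / (# repetitions
    sampling both), with never-co-sampled pairs set to 0 and counted in the
    result.  Requires >= 50 repetitions.
    """
    if repetitions < 50:
        raise ValueError("need at least 50 resampling repetitions")
    if not 0 < item_fraction <= 1:
        raise ValueError("item_fraction must be in (0, 1]")
    # operate in sorted-sample-id order so the result is invariant to the
    # caller's sample permutation (the RNG stream sees the same ordering)
    values = binary.values.sort_index()
    X = values.to_numpy(dtype=float)
    samples = values.index
    n = X.shape[0]
    ks = sorted(k_range)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    m = math.ceil(item_fraction * n)
    rng = np.random.default_rng(seed)
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(repetitions):
        idx = rng.choice(n, size=m, replace=False)
        idx.sort()
        co_sampled[np.ix_(idx, idx)] += 1
        Z = hierarchy.linkage(X[idx], method=linkage, metric="euclidean")
        for k in ks:
            lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
    never = int(((co_sampled == 0).sum() - (np.diag(co_sampled) == 0).sum()) // 2)
    if never:
        logger.warning("%d sample pairs never co-sampled; consensus set to 0", never)
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus_by_k = {}
        for k in ks:
            c = np.where(co_sampled > 0, co_clustered[k] / np.maximum(co_sampled, 1), 0.0)
            np.fill_diagonal(c, 1.0)
            c = (c + c.T) / 2
            consensus_by_k[k] = pd.DataFrame(c, index=samples, columns=samples)
    area_by_k = {k: _cdf_area(consensus_by_k[k].to_numpy()) for k in ks}
    labels_by_k = {
        k: pd.Series(_consensus_labels(consensus_by_k[k].to_numpy(), k), index=samples)
        for k in ks
    }
    result = ConsensusResult(
        consensus_by_k=consensus_by_k,
        area_by_k=area_by_k,
        delta_by_k={},
        selected_k=ks[0],
        labels=labels_by_k[ks[0]],
        labels_by_k=labels_by_k,
        item_fraction=item_fraction,
        repetitions=repetitions,
        seed=seed,
        n_never_cosampled=never,
    )
    result.selected_k = select_k_by_cdf(result, delta_threshold)
    result.labels = labels_by_k[result.selected_k]
    return result


def select_k_by_cdf(result: ConsensusResult, threshold: float = 0.05) -> int:
    """Largest K whose relative CDF-area gain over K-1,
    delta(K) = (A(K) - A(K-1)) / A(K-1), still reaches ``threshold``;
    falls back to the smallest K when no gain qualifies."""
    ks = sorted(result.area_by_k)
    if len(ks) == 1:
        logger.info("single-K range; selecting K=%d", ks[0])
        return ks[0]
    delta = {}
    for prev, k in zip(ks, ks[1:]):
        a_prev = result.area_by_k[prev]
        delta[k] = (result.area_by_k[k] - a_prev) / a_prev if a_prev > 0 else float("inf")
    result.delta_by_k = delta
    qualifying = [k for k in ks[1:] if delta[k] >= threshold]
    return max(qualifying) if qualifying else ks[0]
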