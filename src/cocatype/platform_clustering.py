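"""Single-platform clustering: copy number and DNA methylation.

Copy-number input is a GISTIC-thresholded fragment x sample matrix over
{-2,-1,0,1,2}; it is collapsed to a trinary {-1,0,1} matrix (any gain -> 1,
any loss -> -1) and clustered as numeric values under Euclidean distance
with Ward linkage.  Methylation is reduced to candidate driver CpGs by a
three-criterion filter (quiet in normal tissue, recurrently methylated in
tumors, not on a sex chromosome or SNP-overlapping), then to the most
variable sites, and clustered the same way.  The hierarchical-clustering
core here is shared by the mutation-signature stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Per-platform sample -> cluster labels (labels are 1..k, numbered by
    first occurrence in sample order)."""

    platform: str
    labels: pd.Series  # sample -> int

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.labels.index, "label": self.labels.values})


@dataclass
class CpgFilterReport:
    n_input: int
    n_pass_normal_criterion: int
    n_pass_tumor_criterion: int
    n_removed_sex_or_snp: int
    retained: list[str]
    first_failure: dict[str, str]  # probe -> "a" | "b" | "c"
    tumor_variance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def trinarize_gistic(cnv: pd.DataFrame) -> pd.DataFrame:
    """Collapse 5-level GISTIC calls to trinary: 2,1 -> 1; -1,-2 -> -1; 0 -> 0."""
    values = cnv.to_numpy()
    bad = ~np.isin(values, (-2, -1, 0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-GISTIC value {values[i, j]!r} at fragment {cnv.index[i]!r}, "
            f"sample {cnv.columns[j]!r}"
        )
    return pd.DataFrame(np.sign(values).astype(int), index=cnv.index, columns=cnv.columns)


def filter_driver_cpgs(
    beta_tumor: pd.DataFrame,
    beta_normal: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    *,
    normal_mean_max: float = 0.2,
    beta_positive: float = 0.3,
    max_normal_positive: int = 5,
    min_tumor_fraction: float = 0.10,
) -> CpgFilterReport:
    """Three-criterion candidate driver-CpG filter.

    (a) mean beta < ``normal_mean_max`` in normals AND at most
        ``max_normal_positive`` normal samples with beta > ``beta_positive``;
    (b) beta > ``beta_positive`` in strictly more than ``min_tumor_fraction``
        of tumors;
    (c) autosomal and not SNP-overlapping.

    Criteria are evaluated independently (the retained set is order-free);
    each excluded probe is attributed to its first failing criterion in the
    order a, b, c.
    """
    probes = beta_tumor.index
    if not probes.equals(beta_normal.index):
        raise ValueError("tumor and normal matrices must share probe ids")
    ann = probe_annotation.set_index("probe")
    missing = probes.difference(ann.index)
    if len(missing):
        raise ValueError(f"probes missing from annotation: {sorted(missing)[:10]}")
    ann = ann.loc[probes]

    normal = beta_normal.to_numpy()
    tumor = beta_tumor.to_numpy()
    pass_a = (normal.mean(axis=1) < normal_mean_max) & (
        (normal > beta_positive).sum(axis=1) <= max_normal_positive
    )
    pass_b = (tumor > beta_positive).mean(axis=1) > min_tumor_fraction
    chrom = ann["chromosome"].astype(str).str.lower()
    pass_c = (~chrom.isin(["chrx", "chry", "x", "y"])) & (~ann["snp_overlap"].astype(bool))
    pass_c = pass_c.to_numpy()

    keep = pass_a & pass_b & pass_c
    first_failure = {}
    for i, probe in enumerate(probes):
        if keep[i]:
            continue
        first_failure[probe] = "a" if not pass_a[i] else ("b" if not pass_b[i] else "c")
    retained = list(probes[keep])
    return CpgFilterReport(
        n_input=len(probes),
        n_pass_normal_criterion=int(pass_a.sum()),
        n_pass_tumor_criterion=int(pass_b.sum()),
        n_removed_sex_or_snp=int((~pass_c).sum()),
        retained=retained,
        first_failure=first_failure,
        tumor_variance=beta_tumor.var(axis=1, ddof=1),
    )


def select_top_variable_sites(
    beta_tumor: pd.DataFrame, retained: list[str], n: int = 1000
) -> list[str]:
    """The ``n`` retained probes with largest tumor beta variance; ties (and
    the all-constant degenerate case) break deterministically by probe id."""
    if n > len(retained):
        raise ValueError(f"requested {n} sites but only {len(retained)} retained")
    var = beta_tumor.loc[retained].var(axis=1, ddof=1)
    if (var == 0).all():
        logger.warning("all retained probes have zero variance; returning in id order")
    order = sorted(retained, key=lambda p: (-var[p], p))
    return order[:n]


def _linkage(X: np.ndarray, linkage: str) -> np.ndarray:
    if linkage not in ("ward", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    # scipy's 'ward' on raw observations is the Ward.D2 convention
    # (cluster distances updated on squared Euclidean, reported unsquared).
    return hierarchy.linkage(X, method=linkage, metric="euclidean")


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    linkage: str = "ward",
    platform: str = "generic",
) -> ClusterAssignment:
    """Agglomerative clustering of samples (columns) under Euclidean distance.

    The tree is cut to exactly ``k`` clusters and labels renumbered 1..k by
    first occurrence, making the assignment invariant to sample permutation
    up to relabeling.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute explicitly first")
    X = matrix.to_numpy().T
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} samples")
    Z = _linkage(X, linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    return ClusterAssignment(platform=platform, labels=pd.Series(labels, index=matrix.columns))


def choose_k(
    matrix: pd.DataFrame,
    k_range: range | list[int],
    linkage: str = "ward",
) -> tuple[int, dict[int, float]]:
    """Pick k by mean silhouette width over ``k_range`` (ties -> smaller k).

    Returns the chosen k and the full silhouette profile.
    """
    X = matrix.to_numpy().T
    if pdist(X).max() == 0:
        raise ValueError("all samples identical; no cluster structure to score")
    Z = _linkage(X, linkage)
    profile: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, n_samples-1]")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            profile[k] = float("-inf")
            continue
        profile[k] = float(silhouette_score(X, labels))
    best = max(sorted(profile), key=lambda k: profile[k])
    return best, profile
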