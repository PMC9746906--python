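"""Mutational-signature extraction and exposure clustering.

A sample x 96 motif matrix of trinucleotide-substitution counts is factored
by nonnegative matrix factorization under the generalized Kullback-Leibler
divergence with multiplicative updates (the Brunet variant standard for
mutation signatures).  For each candidate rank, many random restarts are
consensus-combined: each restart assigns every sample to its dominant
signature, the restart-averaged connectivity matrix is the consensus, and
the cophenetic correlation of that consensus measures restart stability.
The selected rank is the largest one whose cophenetic coefficient has not
yet fallen away from the maximum by more than a tolerance — the point where
stability "begins to fall".  Samples are then clustered on their exposures
with Ward linkage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .platform_clustering import ClusterAssignment, choose_k, hierarchical_cluster
from .synthetic import CONTEXT_LABELS, _COMPLEMENT

logger = logging.getLogger(__name__)

_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


@dataclass
class MotifMatrix:
    """Sample x 96 trinucleotide-substitution count matrix (pyrimidine-
    normalized classes, substitution-major column order)."""

    counts: pd.DataFrame
    n_skipped: int = 0

    @property
    def context_labels(self) -> tuple[str, ...]:
        return CONTEXT_LABELS


@dataclass
class SignatureModel:
    rank: int
    signatures: pd.DataFrame  # rank x 96, rows sum to 1
    exposures: pd.DataFrame  # sample x rank
    cophenetic_by_rank: dict[int, float]
    selected_rank: int
    reconstruction_error_by_rank: dict[int, float] = field(default_factory=dict)
    reference_correlations: pd.DataFrame | None = None


def _pyrimidine_class(ref: str, alt: str, context: str) -> str:
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_motif_matrix(mutation_records: pd.DataFrame, sample_ids: list[str]) -> MotifMatrix:
    """Count single-nucleotide substitutions into the 96 pyrimidine-normalized
    classes.  Malformed records (context length != 3, middle base != ref,
    non-ACGT alleles, or ref == alt) are skipped with a logged count."""
    counts = np.zeros((len(sample_ids), 96), dtype=int)
    row_of = {s: i for i, s in enumerate(sample_ids)}
    skipped = 0
    for rec in mutation_records.itertuples(index=False):
        sample, ref, alt, context = rec.sample, rec.ref, rec.alt, rec.context
        if sample not in row_of:
            skipped += 1
            continue
        if (
            len(ref) != 1
            or len(alt) != 1
            or ref not in "ACGT"
            or alt not in "ACGT"
            or ref == alt
            or not isinstance(context, str)
            or len(context) != 3
            or context[1] != ref
            or any(b not in "ACGT" for b in context)
        ):
            skipped += 1
            continue
        counts[row_of[sample], _CONTEXT_INDEX[_pyrimidine_class(ref, alt, context)]] += 1
    if skipped:
        logger.warning("build_motif_matrix: skipped %d malformed/unknown records", skipped)
    return MotifMatrix(
        counts=pd.DataFrame(counts, index=sample_ids, columns=list(CONTEXT_LABELS)),
        n_skipped=skipped,
    )


def _cophenetic_of_consensus(consensus: np.ndarray) -> float:
    """Cophenetic correlation of an average-linkage tree on 1 - consensus."""
    d = squareform(1.0 - consensus, checks=False)
    if np.allclose(d, d.flat[0] if d.size else 0.0):
        return 1.0  # all pairwise distances identical: tree fits exactly
    Z = hierarchy.linkage(d, method="average")
    coph, _ = hierarchy.cophenet(Z, d)
    return float(coph)


def extract_signatures(
    motif: MotifMatrix,
    rank_range: range | list[int],
    n_restarts: int = 50,
    seed: int = 0,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    drop_tolerance: float = 0.05,
) -> SignatureModel:
    """Multi-restart KL-NMF over a rank range with cophenetic rank selection.

    For each rank, ``n_restarts`` randomly initialized factorizations are
    run; the best-objective restart provides the factors and the restart
    consensus provides the cophenetic coefficient.  The selected rank is the
    largest rank whose cophenetic coefficient is within ``drop_tolerance``
    of the maximum over the evaluated range.  Signatures are row-normalized
    with exposures rescaled to preserve the factorization product.
    """
    ranks = sorted(rank_range)
    V = motif.counts.to_numpy(dtype=float)
    if V.sum() == 0:
        raise ValueError("all-zero motif matrix: nothing to factorize")
    n_samples = V.shape[0]
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be >= 1")
    if max(ranks) >= min(n_samples, 96):
        raise ValueError(f"max rank {max(ranks)} >= min(n_samples, 96)")
    # zero rows break the KL objective; factor the nonzero rows, leave zero exposures
    nonzero = V.sum(axis=1) > 0
    Vnz = V[nonzero]

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=(len(ranks), n_restarts))
    cophenetic_by_rank: dict[int, float] = {}
    recon_by_rank: dict[int, float] = {}
    best_factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    norm_V = np.linalg.norm(Vnz)
    for r_i, rank in enumerate(ranks):
        connectivity = np.zeros((Vnz.shape[0], Vnz.shape[0]))
        best_obj = np.inf
        for j in range(n_restarts):
            model = NMF(
                n_components=rank,
                init="random",
                solver="mu",
                beta_loss="kullback-leibler",
                max_iter=max_iter,
                tol=tol,
                random_state=int(restart_seeds[r_i, j]),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(Vnz)
            H = model.components_
            assign = W.argmax(axis=1)
            connectivity += assign[:, None] == assign[None, :]
            if model.reconstruction_err_ < best_obj:
                best_obj = model.reconstruction_err_
                best_factors[rank] = (W, H)
        consensus = connectivity / n_restarts
        cophenetic_by_rank[rank] = _cophenetic_of_consensus(consensus)
        W, H = best_factors[rank]
        recon_by_rank[rank] = float(np.linalg.norm(Vnz - W @ H) / norm_V)

    selected = select_rank_by_cophenetic(cophenetic_by_rank, drop_tolerance)
    W, H = best_factors[selected]
    row_sums = H.sum(axis=1)
    H_norm = H / row_sums[:, None]
    W_scaled = W * row_sums[None, :]
    exposures_full = np.zeros((n_samples, selected))
    exposures_full[nonzero] = W_scaled
    sig_names = [f"SIG{j}" for j in range(1, selected + 1)]
    return SignatureModel(
        rank=selected,
        signatures=pd.DataFrame(H_norm, index=sig_names, columns=list(CONTEXT_LABELS)),
        exposures=pd.DataFrame(exposures_full, index=motif.counts.index, columns=sig_names),
        cophenetic_by_rank=cophenetic_by_rank,
        selected_rank=selected,
        reconstruction_error_by_rank=recon_by_rank,
    )


def select_rank_by_cophenetic(cophenetic_by_rank: dict[int, float], tolerance: float = 0.05) -> int:
    """The largest rank before the first cophenetic drop exceeding
    ``tolerance`` — the point where restart stability begins to fall.

    Scanning ranks in ascending order, the first successive drop larger
    than ``tolerance`` ends the stable regime and the rank immediately
    before it is selected.  When no drop that large exists the coefficient
    never sharply falls, and the stability peak (global argmax, ties broken
    toward the smaller rank) is returned instead."""
    ranks = sorted(cophenetic_by_rank)
    for prev, nxt in zip(ranks, ranks[1:]):
        if cophenetic_by_rank[nxt] < cophenetic_by_rank[prev] - tolerance:
            return prev
    return max(ranks, key=lambda r: (cophenetic_by_rank[r], -r))


def match_reference_signatures(
    model: SignatureModel, reference: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between every extracted and reference signature.

    ``reference`` is a named-signature x 96 profile table whose columns must
    already be in the model's context order (no silent reordering).  Zero-
    variance reference profiles are excluded from best-match with NaN r.
    Returns the full correlation table with a ``best_match``/``best_r``
    summary in ``DataFrame.attrs``.
    """
    if list(reference.columns) != list(model.signatures.columns):
        raise ValueError("reference context columns do not match the 96-class order")
    ext = model.signatures.to_numpy()
    ref = reference.to_numpy()
    ext_c = ext - ext.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    ext_n = np.linalg.norm(ext_c, axis=1)
    ref_n = np.linalg.norm(ref_c, axis=1)
    zero_var = ref_n <= 1e-12 * np.abs(ref).max(axis=1).clip(min=1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ext_c @ ref_c.T) / np.outer(ext_n, ref_n)
    r[:, zero_var] = np.nan
    table = pd.DataFrame(r, index=model.signatures.index, columns=reference.index)
    best = table.apply(lambda row: row.dropna().idxmax() if row.notna().any() else None, axis=1)
    table.attrs["best_match"] = best.to_dict()
    table.attrs["best_r"] = table.max(axis=1, skipna=True).to_dict()
    return table


def cluster_exposures(
    model: SignatureModel,
    k: int | str = "auto",
    k_range: range | list[int] = range(2, 9),
    normalize: bool = False,
) -> ClusterAssignment:
    """Ward/Euclidean hierarchical clustering of samples on signature
    exposures.  ``k="auto"`` selects k by mean silhouette over ``k_range``;
    ``normalize=True`` converts exposures to per-sample proportions first."""
    expo = model.exposures
    if normalize:
        totals = expo.sum(axis=1).replace(0, 1.0)
        expo = expo.div(totals, axis=0)
    matrix = expo.T  # clustering core expects feature x sample
    if k == "auto":
        k, _ = choose_k(matrix, k_range, linkage="ward")
    return hierarchical_cluster(matrix, int(k), linkage="ward", platform="mutation")
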