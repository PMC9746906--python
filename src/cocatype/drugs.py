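"""Drug-sensitivity screening for the focal subtype across two panels.

A drug x cell-line AUC matrix (lower AUC = more sensitive) is first
cleaned: drugs missing in more than 20% of cell lines are removed, and the
remaining holes are imputed by K-nearest-neighbor averaging over drug rows
(distance over co-observed cell lines).  Patient AUCs are then imputed by
ridge regression of AUC on harmonized cell-line expression applied to
harmonized patient expression.  Finally, per panel, each drug is tested for
lower AUC in the focal subtype (rank-sum), and candidates are the drugs
significant with the sensitive direction in both panels at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV

from .classifier import harmonize_cohorts

logger = logging.getLogger(__name__)


@dataclass
class DrugMatrixReport:
    removed_drugs: list[str]
    n_imputed: int
    n_drugs_kept: int
    n_cell_lines: int


@dataclass
class DrugScreenResult:
    per_panel: dict[str, pd.DataFrame]  # panel -> drug table (stat, p, medians, direction)
    candidates: list[str]  # significant + sensitive in every panel, sorted by max p
    single_panel_only: list[str] = field(default_factory=list)
    alpha: float = 0.05


def prepare_drug_matrix(
    auc: pd.DataFrame, max_missing: float = 0.2, k_neighbors: int = 5
) -> tuple[pd.DataFrame, DrugMatrixReport]:
    """Missingness filter then KNN imputation over drug rows.

    Drugs with a missing fraction strictly above ``max_missing`` are dropped
    before any imputation (so an over-missing drug never receives imputed
    values); each remaining hole is filled with the mean of the
    ``k_neighbors`` nearest drugs (Euclidean over co-observed cell lines,
    normalized per shared entry) that observe that cell line.
    """
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    missing_frac = auc.isna().mean(axis=1)
    removed = list(auc.index[missing_frac > max_missing])
    kept = auc.drop(index=removed)
    if (kept.isna().all(axis=1)).any():
        bad = list(kept.index[kept.isna().all(axis=1)])
        raise ValueError(f"drugs with zero observed entries cannot be imputed: {bad}")
    X = kept.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n_imputed = 0
    if not obs.all():
        # mean squared difference over co-observed cell lines, per drug pair
        Xz = np.where(obs, X, 0.0)
        co = obs.astype(float) @ obs.astype(float).T
        sq = (Xz**2) @ obs.T + obs.astype(float) @ (Xz**2).T - 2 * Xz @ Xz.T
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(np.where(co > 0, sq / np.maximum(co, 1), np.inf))
        np.fill_diagonal(dist, np.inf)
        filled = X.copy()
        for i in range(X.shape[0]):
            holes = np.where(~obs[i])[0]
            if holes.size == 0:
                continue
            order = np.argsort(dist[i], kind="stable")
            for j in holes:
                donors = [d for d in order if np.isfinite(dist[i, d]) and obs[d, j]]
                if not donors:
                    raise ValueError(
                        f"no donor drug observes cell line {kept.columns[j]!r} "
                        f"for drug {kept.index[i]!r}"
                    )
                filled[i, j] = X[donors[: k_neighbors], j].mean()
                n_imputed += 1
        X = filled
    complete = pd.DataFrame(X, index=kept.index, columns=kept.columns)
    report = DrugMatrixReport(
        removed_drugs=removed,
        n_imputed=n_imputed,
        n_drugs_kept=len(kept),
        n_cell_lines=auc.shape[1],
    )
    return complete, report


def predict_patient_auc(
    ccl_expression: pd.DataFrame,
    ccl_auc: pd.DataFrame,
    patient_expression: pd.DataFrame,
    ridge_penalty: float | str = "auto",
    max_genes: int = 5000,
) -> pd.DataFrame:
    """Impute per-patient AUC for every drug by ridge regression of AUC on
    harmonized cell-line expression.

    Expression cohorts are harmonized (shared genes, within-cohort per-gene
    z-scores); when the shared gene count exceeds ``max_genes`` a variance-
    ranked pre-filter (on the cell-line cohort) is applied.  ``ridge_penalty``
    is the L2 strength, or "auto" for leave-one-out generalized
    cross-validation over a log grid.  Returns a drug x patient matrix.
    """
    ref, target = harmonize_cohorts(ccl_expression, patient_expression)
    if ref.shape[0] > max_genes:
        var = ccl_expression.loc[ref.index].var(axis=1)
        keep = var.sort_values(ascending=False).index[:max_genes]
        logger.info("predict_patient_auc: variance pre-filter %d -> %d genes",
                    ref.shape[0], max_genes)
        ref, target = ref.loc[keep], target.loc[keep]
    X = ref.T.to_numpy(dtype=float)  # cell lines x genes
    Xp = target.T.to_numpy(dtype=float)  # patients x genes
    preds = {}
    for drug in ccl_auc.index:
        y = ccl_auc.loc[drug, ref.columns].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"drug {drug!r} still has missing AUC; impute first")
        if ridge_penalty == "auto":
            model = RidgeCV(alphas=np.logspace(-2, 4, 13))
        else:
            model = Ridge(alpha=float(ridge_penalty))
        model.fit(X, y)
        preds[drug] = model.predict(Xp)
    return pd.DataFrame(preds, index=patient_expression.columns).T


def rank_candidate_drugs(
    predicted_auc_by_panel: dict[str, pd.DataFrame],
    subtype_labels: pd.Series,
    focal_subtype: int,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> DrugScreenResult:
    """Screen for drugs preferentially effective in the focal subtype.

    Per panel and drug, predicted AUC in focal-subtype patients is compared
    with the rest (two-sided rank-sum by default, Welch t optional).
    Candidates must have P < alpha AND a lower focal-subtype median in every
    panel; they are sorted by the worst (largest) per-panel P.  Drugs absent
    from any panel are evaluated where present and listed separately.
    """
    if test not in ("ranksum", "ttest"):
        raise ValueError("test must be 'ranksum' or 'ttest'")
    per_panel: dict[str, pd.DataFrame] = {}
    sensitive_by_panel: dict[str, dict[str, float]] = {}
    for panel, auc in predicted_auc_by_panel.items():
        lab = subtype_labels.loc[auc.columns]
        focal = (lab == focal_subtype).to_numpy()
        if focal.sum() < 2 or (~focal).sum() < 2:
            raise ValueError("need >= 2 samples on each side of the focal split")
        rows = []
        sens: dict[str, float] = {}
        for drug in auc.index:
            v = auc.loc[drug].to_numpy(dtype=float)
            a, b = v[focal], v[~focal]
            if test == "ranksum":
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
            lower = float(np.median(a)) < float(np.median(b))
            rows.append(
                {
                    "drug": drug,
                    "stat": float(stat),
                    "p": float(p),
                    "median_focal": float(np.median(a)),
                    "median_rest": float(np.median(b)),
                    "direction": "lower" if lower else "higher",
                }
            )
            if p < alpha and lower:
                sens[drug] = float(p)
        per_panel[panel] = pd.DataFrame(rows).set_index("drug")
        sensitive_by_panel[panel] = sens
    all_drugs = set().union(*(set(df.index) for df in per_panel.values()))
    shared = set.intersection(*(set(df.index) for df in per_panel.values()))
    single_only = sorted(all_drugs - shared)
    candidates = [d for d in shared if all(d in s for s in sensitive_by_panel.values())]
    candidates.sort(key=lambda d: (max(s[d] for s in sensitive_by_panel.values()), d))
    return DrugScreenResult(
        per_panel=per_panel,
        candidates=candidates,
        single_panel_only=single_only,
        alpha=alpha,
    )
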