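"""Single-sample gene-set enrichment scoring of immune checkpoints.

Each sample's stimulatory and inhibitory checkpoint activity is scored by
the ssGSEA running sum: genes are ranked by expression (descending, ties
broken by gene id), and the score is the integral of the difference between
the weighted in-set empirical CDF (weights |value|^exponent) and the
uniform out-of-set CDF.  A sample is categorized stimulatory or inhibitory
by direct comparison of the two scores (exact ties -> stimulatory, a fixed
documented rule), and subtype enrichment of a category is tested by
chi-square with the same small-count Fisher fallback as driver detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import chi2_or_fisher_2x2
from .platform_clustering import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class CheckpointScores:
    scores: pd.DataFrame  # sample x (stimulatory_score, inhibitory_score)
    categories: pd.Series  # sample -> "stimulatory" | "inhibitory"


def ssgsea_score(
    expression_column: pd.Series, gene_set: list[str] | set[str], exponent: float = 0.25
) -> float:
    """ssGSEA running-sum enrichment score of one gene set in one sample.

    score = sum_i [ P_in(i) - P_out(i) ] over the descending expression
    ranking, where P_in is the |value|^exponent-weighted in-set ECDF and
    P_out the unweighted out-of-set ECDF.  Deterministic tie-break by gene
    id; with exponent 0 the score depends on ranks only.
    """
    genes = expression_column.index
    gene_set = set(gene_set)
    in_set = genes.isin(gene_set)
    if not in_set.any():
        raise ValueError("no gene of the set is present in the expression index")
    if in_set.all():
        raise ValueError("gene set covers every gene: out-of-set ECDF undefined")
    order = sorted(range(len(genes)), key=lambda i: (-expression_column.iloc[i], genes[i]))
    values = expression_column.to_numpy()[order]
    member = in_set[order]
    weights = np.abs(values) ** exponent
    w_in = np.where(member, weights, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        raise ValueError("in-set weights sum to zero (all set genes at value 0)")
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~member) / (len(genes) - member.sum())
    return float(np.sum(p_in - p_out))


def score_checkpoints(
    expression: pd.DataFrame,
    stimulatory: list[str],
    inhibitory: list[str],
    exponent: float = 0.25,
) -> CheckpointScores:
    """Score every sample against the stimulatory and inhibitory checkpoint
    sets and categorize by the larger score."""
    rows = {}
    for sample in expression.columns:
        col = expression[sample]
        rows[sample] = (
            ssgsea_score(col, stimulatory, exponent),
            ssgsea_score(col, inhibitory, exponent),
        )
    scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=["stimulatory_score", "inhibitory_score"]
    )
    categories = checkpoint_categorize(scores)
    return CheckpointScores(scores=scores, categories=categories)


def checkpoint_categorize(scores: pd.DataFrame) -> pd.Series:
    """Per-sample category: stimulatory iff stimulatory_score >= inhibitory
    score (exact ties are assigned stimulatory — arbitrary but fixed)."""
    ties = int((scores["stimulatory_score"] == scores["inhibitory_score"]).sum())
    if ties:
        logger.info("checkpoint_categorize: %d exact score ties assigned stimulatory", ties)
    cat = np.where(
        scores["stimulatory_score"] >= scores["inhibitory_score"], "stimulatory", "inhibitory"
    )
    return pd.Series(cat, index=scores.index, name="category")


def category_enrichment_test(
    categories: pd.Series, labels: ClusterAssignment, focal_subtype: int
) -> tuple[float, float]:
    """Chi-square (Fisher fallback) test of checkpoint category against
    focal-subtype membership.  Returns (statistic, p); the statistic is NaN
    on the Fisher branch."""
    lab = labels.labels.loc[categories.index]
    if lab.nunique() < 2:
        raise ValueError("need at least two subtypes for an enrichment test")
    in_focal = (lab == focal_subtype).to_numpy()
    inhib = (categories == "inhibitory").to_numpy()
    table = np.array(
        [
            [np.sum(inhib & in_focal), np.sum(~inhib & in_focal)],
            [np.sum(inhib & ~in_focal), np.sum(~inhib & ~in_focal)],
        ]
    )
    stat, p, _ = chi2_or_fisher_2x2(table)
    return stat, p
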