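"""Subtype driver-event detection.

Three cascades identify the genomic events that define each integrated
subtype:

* mutation drivers — per gene (from a consumed significantly-mutated-gene
  list) and per subtype, a two-sided Fisher exact test of mutation status
  against subtype membership at P < 0.001;
* SCNA drivers — amplification (trinary value 1) and deletion (value -1)
  indicators tested one-vs-rest per subtype; a fragment is a candidate when
  it is significant (P < 0.001) in exactly one subtype and that subtype has
  the maximal alteration frequency, and becomes a driver only when a mapped
  oncogene / tumor-suppressor shows the concordant expression shift
  (one-sided rank-sum, P < 0.05);
* methylation drivers — beta >= 0.3 dichotomization; a probe passes when
  every pairwise test between its most-methylated subtype and each other
  subtype is significant (chi-square, Fisher fallback on small expected
  counts, P < 0.001) and its gene's expression is negatively correlated
  with beta (one-sided Pearson, P < 0.05).

Raw P thresholds are used (no multiple-testing correction), matching the
screening character of the cascades; a Benjamini-Hochberg option is
available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import chi2_or_fisher_2x2, fisher_exact_2x2
from .platform_clustering import ClusterAssignment

logger = logging.getLogger(__name__)

ENRICHMENT_ALPHA = 0.001
CONCORDANCE_ALPHA = 0.05


@dataclass
class DriverEvent:
    feature: str
    event_type: str  # mutation | amplification | deletion | hypermethylation
    subtype: int
    enrichment_p: float
    effect_direction: str  # enriched | depleted
    concordance_stat: float | None
    concordance_p: float | None
    passes: bool


def _events_frame(events: list[DriverEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


def _one_vs_rest_fisher(indicator: np.ndarray, in_subtype: np.ndarray) -> tuple[float, str]:
    a = int(np.sum(indicator & in_subtype))
    b = int(np.sum(~indicator & in_subtype))
    c = int(np.sum(indicator & ~in_subtype))
    d = int(np.sum(~indicator & ~in_subtype))
    p = fisher_exact_2x2(a, b, c, d)
    freq_in = a / max(a + b, 1)
    freq_out = c / max(c + d, 1)
    return p, ("enriched" if freq_in >= freq_out else "depleted")


def mutation_driver_test(
    mutation_status: pd.DataFrame,
    labels: ClusterAssignment,
    gene_list: list[str],
    *,
    alpha: float = ENRICHMENT_ALPHA,
    bh_correct: bool = False,
) -> tuple[list[DriverEvent], list[str]]:
    """Differential mutation testing of every listed gene against every
    subtype (two-sided Fisher, one-vs-rest).  Returns passing and
    non-passing events plus the list of untested genes (absent from the
    status matrix or with a degenerate all-0/all-1 margin)."""
    if not gene_list:
        raise ValueError("gene_list must be nonempty")
    lab = labels.labels.loc[mutation_status.columns]
    subtypes = sorted(lab.unique())
    events: list[DriverEvent] = []
    untested: list[str] = []
    for gene in gene_list:
        if gene not in mutation_status.index:
            untested.append(gene)
            continue
        status = mutation_status.loc[gene].to_numpy().astype(bool)
        if status.all() or not status.any():
            untested.append(gene)
            continue
        for s in subtypes:
            in_sub = (lab == s).to_numpy()
            p, direction = _one_vs_rest_fisher(status, in_sub)
            events.append(
                DriverEvent(
                    feature=gene,
                    event_type="mutation",
                    subtype=int(s),
                    enrichment_p=p,
                    effect_direction=direction,
                    concordance_stat=None,
                    concordance_p=None,
                    passes=p < alpha,
                )
            )
    if bh_correct and events:
        reject, _, _, _ = multipletests([e.enrichment_p for e in events], alpha=alpha, method="fdr_bh")
        for e, rej in zip(events, reject):
            e.passes = bool(rej)
    if untested:
        logger.info("mutation_driver_test: %d genes untested", len(untested))
    return events, untested


def _candidate_subtype(
    indicator: np.ndarray, lab: pd.Series, alpha: float
) -> tuple[int | None, dict[int, tuple[float, str]]]:
    """One-vs-rest Fisher per subtype; the candidate is the unique subtype
    that is both significant-and-enriched and carries the maximal frequency."""
    subtypes = sorted(lab.unique())
    results = {}
    freqs = {}
    for s in subtypes:
        in_sub = (lab == s).to_numpy()
        results[int(s)] = _one_vs_rest_fisher(indicator, in_sub)
        freqs[int(s)] = indicator[in_sub].mean() if in_sub.any() else 0.0
    significant = [
        s for s, (p, direction) in results.items() if p < alpha and direction == "enriched"
    ]
    if len(significant) != 1:
        return None, results
    s = significant[0]
    if freqs[s] < max(freqs.values()):
        return None, results
    return s, results


def scna_driver_test(
    trinary: pd.DataFrame,
    labels: ClusterAssignment,
    expression: pd.DataFrame,
    fragment_to_genes: dict[str, list[str]],
    *,
    alpha: float = ENRICHMENT_ALPHA,
    concordance_alpha: float = CONCORDANCE_ALPHA,
) -> list[DriverEvent]:
    """SCNA driver screen: per-direction enrichment then expression
    concordance of mapped oncogenes / suppressors.  Amplified samples must
    express the gene higher, deleted samples lower (one-sided Mann-Whitney)."""
    lab = labels.labels.loc[trinary.columns]
    events: list[DriverEvent] = []
    for fragment in trinary.index:
        values = trinary.loc[fragment].to_numpy()
        for direction, event_type in ((1, "amplification"), (-1, "deletion")):
            indicator = values == direction
            if not indicator.any():
                continue
            subtype, results = _candidate_subtype(indicator, lab, alpha)
            if subtype is None:
                continue
            p_enrich = results[subtype][0]
            genes = [g for g in fragment_to_genes.get(fragment, []) if g in expression.index]
            if not genes:
                events.append(
                    DriverEvent(
                        feature=fragment,
                        event_type=event_type,
                        subtype=subtype,
                        enrichment_p=p_enrich,
                        effect_direction="enriched",
                        concordance_stat=None,
                        concordance_p=None,
                        passes=False,
                    )
                )
                continue
            best_stat, best_p = None, 1.0
            for gene in genes:
                expr = expression.loc[gene, trinary.columns].to_numpy()
                alt, rest = expr[indicator], expr[~indicator]
                alternative = "greater" if event_type == "amplification" else "less"
                stat, p = stats.mannwhitneyu(alt, rest, alternative=alternative)
                if p < best_p:
                    best_stat, best_p = float(stat), float(p)
            events.append(
                DriverEvent(
                    feature=fragment,
                    event_type=event_type,
                    subtype=subtype,
                    enrichment_p=p_enrich,
                    effect_direction="enriched",
                    concordance_stat=best_stat,
                    concordance_p=best_p,
                    passes=best_p < concordance_alpha,
                )
            )
    return events


def methylation_driver_test(
    beta: pd.DataFrame,
    labels: ClusterAssignment,
    expression: pd.DataFrame,
    probe_to_gene: dict[str, str],
    top_sites: list[str],
    *,
    beta_positive: float = 0.3,
    alpha: float = ENRICHMENT_ALPHA,
    concordance_alpha: float = CONCORDANCE_ALPHA,
    all_pairs: bool = False,
) -> list[DriverEvent]:
    """Methylation driver screen on the top variable sites.

    Step (a): dichotomize at beta >= ``beta_positive``; the probe's candidate
    subtype is its most-methylated one, and every pairwise test between that
    subtype and each other subtype must reach P < ``alpha`` (chi-square with
    Fisher fallback).  ``all_pairs=True`` instead demands significance on
    every subtype pair.  Step (b): Pearson correlation between beta and the
    mapped gene's expression must be negative (one-sided P < 0.05)."""
    lab = labels.labels.loc[beta.columns]
    subtypes = sorted(lab.unique())
    events: list[DriverEvent] = []
    for probe in top_sites:
        if probe not in beta.index:
            continue
        methylated = (beta.loc[probe] >= beta_positive).to_numpy()
        fractions = {int(s): methylated[(lab == s).to_numpy()].mean() for s in subtypes}
        candidate = max(sorted(fractions), key=lambda s: fractions[s])
        if all_pairs:
            pairs = [(s, t) for i, s in enumerate(subtypes) for t in subtypes[i + 1 :]]
        else:
            pairs = [(candidate, t) for t in subtypes if t != candidate]
        p_max = 0.0
        for s, t in pairs:
            mask = ((lab == s) | (lab == t)).to_numpy()
            in_s = (lab == s).to_numpy()[mask]
            m = methylated[mask]
            table = np.array(
                [
                    [np.sum(m & in_s), np.sum(~m & in_s)],
                    [np.sum(m & ~in_s), np.sum(~m & ~in_s)],
                ]
            )
            _, p, _ = chi2_or_fisher_2x2(table)
            p_max = max(p_max, p)
        passes_a = p_max < alpha
        gene = probe_to_gene.get(probe)
        if gene is None or gene not in expression.index:
            events.append(
                DriverEvent(
                    feature=probe,
                    event_type="hypermethylation",
                    subtype=candidate,
                    enrichment_p=p_max,
                    effect_direction="enriched",
                    concordance_stat=None,
                    concordance_p=None,
                    passes=False,
                )
            )
            continue
        b = beta.loc[probe].to_numpy()
        e = expression.loc[gene, beta.columns].to_numpy()
        r, p_corr = stats.pearsonr(b, e, alternative="less")
        events.append(
            DriverEvent(
                feature=probe,
                event_type="hypermethylation",
                subtype=candidate,
                enrichment_p=p_max,
                effect_direction="enriched",
                concordance_stat=float(r),
                concordance_p=float(p_corr),
                passes=passes_a and (r < 0) and (p_corr < concordance_alpha),
            )
        )
    return events


def passing_events(events: list[DriverEvent]) -> list[DriverEvent]:
    return [e for e in events if e.passes]


def driver_precision_recall(
    detected: list[DriverEvent], planted: list[dict]
) -> tuple[float, float]:
    """Precision/recall of passing enriched events against a planted-driver
    list; a hit must match feature, event type, and subtype.  Depleted-
    direction events are the logical complement of an enrichment elsewhere
    and are not scored against the planted (enrichment) truth."""
    det = {
        (e.feature, e.event_type, e.subtype)
        for e in detected
        if e.passes and e.effect_direction == "enriched"
    }
    truth = {(d["feature"], d["event_type"], d["subtype"]) for d in planted}
    if not det:
        return (1.0 if not truth else 0.0), 0.0 if truth else 1.0
    tp = len(det & truth)
    return tp / len(det), tp / len(truth) if truth else 1.0
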