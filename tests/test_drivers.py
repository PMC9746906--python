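"""Driver cascades: exact-test agreement, planted recovery, direction rules."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cocatype._stats import chi2_or_fisher_2x2, fisher_exact_2x2
from cocatype.drivers import (
    driver_precision_recall,
    methylation_driver_test,
    mutation_driver_test,
    scna_driver_test,
)
from cocatype.platform_clustering import ClusterAssignment


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher P by hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom) for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table", [(3, 7, 9, 1), (0, 10, 10, 0), (5, 5, 5, 5), (1, 0, 0, 1), (0, 0, 0, 0), (12, 2, 3, 11)]
    )
    def test_agrees_with_rational_enumeration(self, table):
        assert fisher_exact_2x2(*table) == pytest.approx(fisher_oracle(*table), abs=1e-12)

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            ours = fisher_exact_2x2(a, b, c, d)
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 0, 0, 0)


class TestChi2Fallback:
    def test_small_expected_counts_use_fisher(self):
        stat, p, method = chi2_or_fisher_2x2(np.array([[2, 3], [1, 4]]))
        assert method == "fisher"
        assert np.isnan(stat)

    def test_large_table_uses_chi2_without_correction(self):
        table = np.array([[30, 10], [10, 30]])
        stat, p, method = chi2_or_fisher_2x2(table)
        assert method == "chi2"
        # closed form: n(ad-bc)^2 / (r1 r2 c1 c2)
        assert stat == pytest.approx(80 * (30 * 30 - 10 * 10) ** 2 / (40 * 40 * 40 * 40))


def _labels(per_subtype: dict[int, int]) -> ClusterAssignment:
    items = {}
    i = 0
    for s, count in per_subtype.items():
        for _ in range(count):
            items[f"s{i:04d}"] = s
            i += 1
    return ClusterAssignment(platform="coca", labels=pd.Series(items))


class TestMutationDrivers:
    def test_strong_enrichment_detected(self):
        labels = _labels({1: 100, 2: 400})
        status = pd.Series(0, index=labels.labels.index)
        status.iloc[:60] = 1  # 60/100 in subtype 1
        status.iloc[100:120] = 1  # 20/400 elsewhere
        matrix = pd.DataFrame([status], index=["GENE"])
        events, untested = mutation_driver_test(matrix, labels, ["GENE"])
        hit = [e for e in events if e.subtype == 1][0]
        assert hit.enrichment_p < 0.001
        assert hit.effect_direction == "enriched"
        assert hit.passes

    def test_equal_frequency_not_significant(self):
        labels = _labels({1: 100, 2: 100})
        status = pd.Series([1] * 30 + [0] * 70 + [1] * 30 + [0] * 70, index=labels.labels.index)
        matrix = pd.DataFrame([status], index=["GENE"])
        events, _ = mutation_driver_test(matrix, labels, ["GENE"])
        assert all(e.enrichment_p == pytest.approx(1.0, abs=0.1) for e in events)
        assert not any(e.passes for e in events)

    def test_degenerate_margins_untested(self):
        labels = _labels({1: 10, 2: 10})
        matrix = pd.DataFrame(
            [np.zeros(20, dtype=int), np.ones(20, dtype=int)],
            index=["NEVER", "ALWAYS"],
            columns=labels.labels.index,
        )
        events, untested = mutation_driver_test(matrix, labels, ["NEVER", "ALWAYS", "ABSENT"])
        assert set(untested) == {"NEVER", "ALWAYS", "ABSENT"}
        assert events == []


class TestScnaDrivers:
    def _planted(self, rng, couple_expression=True):
        labels = _labels({1: 80, 2: 80, 3: 80})
        samples = labels.labels.index
        deleted = np.where(
            labels.labels == 1, rng.random(240) < 0.7, rng.random(240) < 0.05
        )
        trinary = pd.DataFrame(
            [np.where(deleted, -1, 0)], index=["FRAG1"], columns=samples
        )
        expr = rng.normal(5, 1, 240)
        if couple_expression:
            expr = expr - 1.5 * deleted
        expression = pd.DataFrame([expr], index=["TSG1"], columns=samples)
        return trinary, labels, expression

    def test_planted_deletion_driver_passes(self, rng):
        trinary, labels, expression = self._planted(rng)
        events = scna_driver_test(trinary, labels, expression, {"FRAG1": ["TSG1"]})
        assert len(events) == 1
        e = events[0]
        assert (e.event_type, e.subtype, e.passes) == ("deletion", 1, True)
        assert e.concordance_p < 0.05

    def test_uncoupled_expression_fails_concordance(self):
        rng = np.random.default_rng(1234)
        trinary, labels, expression = self._planted(rng, couple_expression=False)
        events = scna_driver_test(trinary, labels, expression, {"FRAG1": ["TSG1"]})
        assert len(events) == 1
        assert events[0].enrichment_p < 0.001
        assert not events[0].passes

    def test_unmapped_fragment_reported_not_passing(self, rng):
        trinary, labels, expression = self._planted(rng)
        events = scna_driver_test(trinary, labels, expression, {})
        assert len(events) == 1
        assert events[0].concordance_p is None
        assert not events[0].passes

    def test_unaltered_fragment_emits_nothing(self):
        labels = _labels({1: 20, 2: 20})
        trinary = pd.DataFrame(
            np.zeros((1, 40), dtype=int), index=["FRAG1"], columns=labels.labels.index
        )
        expr = pd.DataFrame(np.ones((1, 40)), index=["G"], columns=labels.labels.index)
        assert scna_driver_test(trinary, labels, expr, {"FRAG1": ["G"]}) == []


class TestMethylationDrivers:
    def _planted(self, rng, corr_sign=-1.0, informative=True):
        labels = _labels({1: 120, 2: 120, 3: 120})
        samples = labels.labels.index
        n = len(samples)
        if informative:
            methylated = np.where(labels.labels == 2, rng.random(n) < 0.8, rng.random(n) < 0.05)
        else:
            methylated = rng.random(n) < 0.3
        beta = np.where(methylated, rng.beta(10, 2, n), rng.beta(2, 10, n))
        expr = rng.normal(6, 1, n) + corr_sign * 2.0 * beta
        beta_df = pd.DataFrame([beta], index=["cg1"], columns=samples)
        expr_df = pd.DataFrame([expr], index=["GENE1"], columns=samples)
        return beta_df, labels, expr_df

    def test_planted_hypermethylation_driver_passes(self, rng):
        beta, labels, expr = self._planted(rng)
        events = methylation_driver_test(beta, labels, expr, {"cg1": "GENE1"}, ["cg1"])
        e = events[0]
        assert (e.event_type, e.subtype, e.passes) == ("hypermethylation", 2, True)
        assert e.concordance_stat < 0

    def test_uniform_methylation_fails_step_a(self, rng):
        beta, labels, expr = self._planted(rng, informative=False)
        events = methylation_driver_test(beta, labels, expr, {"cg1": "GENE1"}, ["cg1"])
        assert not events[0].passes
        assert events[0].enrichment_p > 0.001

    def test_positive_correlation_fails_step_b(self, rng):
        beta, labels, expr = self._planted(rng, corr_sign=+1.0)
        events = methylation_driver_test(beta, labels, expr, {"cg1": "GENE1"}, ["cg1"])
        assert events[0].enrichment_p < 0.001  # step (a) passes
        assert not events[0].passes


class TestPrecisionRecall:
    def test_cascades_recover_planted_drivers_on_true_labels(self, cohort, default_config):
        labels = ClusterAssignment(platform="truth", labels=cohort.truth["subtype"])
        smg = default_config.smg_list()
        mut_events, _ = mutation_driver_test(cohort.mutation_status(smg), labels, smg)
        from cocatype.platform_clustering import trinarize_gistic

        frag_to_genes = {
            f: [f"{'AMPG' if d == 'amp' else 'DELG'}{s}"]
            for f, s, d, _, _ in default_config.driver_fragments
        }
        scna_events = scna_driver_test(
            trinarize_gistic(cohort.cnv), labels, cohort.expression, frag_to_genes
        )
        probe_to_gene = {p: g for p, g, _, _, _ in default_config.driver_cpgs}
        meth_events = methylation_driver_test(
            cohort.methylation,
            labels,
            cohort.expression,
            probe_to_gene,
            [p for p, *_ in default_config.driver_cpgs],
        )
        precision, recall = driver_precision_recall(
            mut_events + scna_events + meth_events, cohort.truth["drivers"]
        )
        assert precision >= 0.9
        assert recall >= 0.9
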