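"""CNV trinarization, driver-CpG filtering, and the shared clustering core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from cocatype.platform_clustering import (
    choose_k,
    filter_driver_cpgs,
    hierarchical_cluster,
    select_top_variable_sites,
    trinarize_gistic,
)


class TestTrinarize:
    @pytest.mark.parametrize("value,expected", [(2, 1), (1, 1), (0, 0), (-1, -1), (-2, -1)])
    def test_level_collapse(self, value, expected):
        df = pd.DataFrame([[value]], index=["f1"], columns=["s1"])
        assert trinarize_gistic(df).iloc[0, 0] == expected

    def test_all_zero_unchanged(self):
        df = pd.DataFrame(np.zeros((3, 4), dtype=int))
        pd.testing.assert_frame_equal(trinarize_gistic(df), df)

    @given(st.lists(st.integers(-2, 2), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_value_closed(self, values):
        df = pd.DataFrame({"s": values})
        once = trinarize_gistic(df)
        assert once.isin([-1, 0, 1]).all().all()
        pd.testing.assert_frame_equal(trinarize_gistic(once), once)

    def test_offending_entry_named(self):
        df = pd.DataFrame([[0, 3]], index=["fragX"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="fragX.*s2"):
            trinarize_gistic(df)


class TestCpgFilter:
    @staticmethod
    def _annotation(probes, chrom="chr1", snp=False):
        return pd.DataFrame(
            {"probe": probes, "chromosome": chrom, "snp_overlap": snp, "gene": ""}
        )

    def test_three_probe_toy_matches_hand_evaluation(self):
        # p1 passes everything; p2 fails the tumor criterion (b);
        # p3 fails the normal criterion (a) by mean
        tumors = pd.DataFrame(
            {
                f"t{i}": [0.8 if i < 20 else 0.05, 0.05, 0.8 if i < 20 else 0.05]
                for i in range(100)
            },
            index=["p1", "p2", "p3"],
        )
        normals = pd.DataFrame(
            {f"n{i}": [0.05, 0.05, 0.5] for i in range(20)}, index=["p1", "p2", "p3"]
        )
        report = filter_driver_cpgs(tumors, normals, self._annotation(["p1", "p2", "p3"]))
        assert report.n_input == 3
        assert report.retained == ["p1"]
        assert report.first_failure == {"p2": "b", "p3": "a"}

    def test_sex_chromosome_probe_removed_under_c(self):
        tumors = pd.DataFrame({f"t{i}": [0.8 if i < 50 else 0.05] for i in range(100)}, index=["pX"])
        normals = pd.DataFrame({f"n{i}": [0.05] for i in range(20)}, index=["pX"])
        ann = self._annotation(["pX"], chrom="chrX")
        report = filter_driver_cpgs(tumors, normals, ann)
        assert report.retained == []
        assert report.first_failure["pX"] == "c"
        # SNP overlap removes equally
        ann2 = self._annotation(["pX"], snp=True)
        assert filter_driver_cpgs(tumors, normals, ann2).first_failure["pX"] == "c"

    def test_boundary_inequalities(self):
        # exactly 10% of tumors positive is NOT enough ("more than 10%");
        # 12 of 100 is
        def tumor_with(k):
            return pd.DataFrame(
                {f"t{i}": [0.8 if i < k else 0.05] for i in range(100)}, index=["p"]
            )

        normals = pd.DataFrame({f"n{i}": [0.05] for i in range(20)}, index=["p"])
        ann = self._annotation(["p"])
        assert filter_driver_cpgs(tumor_with(10), normals, ann).retained == []
        assert filter_driver_cpgs(tumor_with(12), normals, ann).retained == ["p"]
        # "no more than 5" normal positives is inclusive at 5
        normals5 = pd.DataFrame(
            {f"n{i}": [0.8 if i < 5 else 0.01] for i in range(40)}, index=["p"]
        )
        assert filter_driver_cpgs(tumor_with(12), normals5, ann).retained == ["p"]
        normals6 = pd.DataFrame(
            {f"n{i}": [0.8 if i < 6 else 0.01] for i in range(40)}, index=["p"]
        )
        assert filter_driver_cpgs(tumor_with(12), normals6, ann).retained == []

    def test_missing_annotation_reported(self):
        tumors = pd.DataFrame({"t1": [0.5]}, index=["p1"])
        normals = pd.DataFrame({"n1": [0.1]}, index=["p1"])
        with pytest.raises(ValueError, match="p1"):
            filter_driver_cpgs(tumors, normals, self._annotation(["other"]))


class TestTopVariableSites:
    def test_variance_ranking(self):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            {
                "s%d" % i: [rng.normal(0.5, sd) for sd in (0.3, 0.2, 0.1)]
                for i in range(200)
            },
            index=["hi", "mid", "lo"],
        ).clip(0, 1)
        assert select_top_variable_sites(beta, ["hi", "mid", "lo"], 2) == ["hi", "mid"]

    def test_identity_when_n_equals_retained(self):
        beta = pd.DataFrame(np.random.default_rng(1).random((4, 10)), index=list("abcd"))
        assert set(select_top_variable_sites(beta, list("abcd"), 4)) == set("abcd")

    def test_constant_probes_returned_in_id_order(self):
        beta = pd.DataFrame(0.5, index=["b", "a", "c"], columns=["s1", "s2"])
        assert select_top_variable_sites(beta, ["b", "a", "c"], 2) == ["a", "b"]

    def test_requesting_too_many_rejected(self):
        beta = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"])
        with pytest.raises(ValueError):
            select_top_variable_sites(beta, ["a", "b"], 3)


class TestHierarchicalCluster:
    def test_duplicate_groups_cocluster(self):
        X = pd.DataFrame(
            np.hstack([np.tile([[0.0], [0.0]], 10), np.tile([[5.0], [5.0]], 10)]),
            columns=[f"s{i}" for i in range(20)],
        )
        labels = hierarchical_cluster(X, 2).labels
        assert labels.iloc[:10].nunique() == 1 and labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] == 1  # first-occurrence numbering

    def test_three_blobs_recovered(self, rng):
        centers = rng.normal(0, 10, size=(3, 5))
        X = np.vstack([rng.normal(c, 0.5, size=(30, 5)) for c in centers])
        truth = np.repeat([0, 1, 2], 30)
        df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(90)])
        labels = hierarchical_cluster(df, 3).labels
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        df = pd.DataFrame(np.arange(12.0).reshape(3, 4), columns=list("abcd"))
        assert hierarchical_cluster(df, 4).labels.nunique() == 4

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            hierarchical_cluster(df, 2)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        X = np.vstack([rng.normal(m, 0.3, size=(20, 4)) for m in (0, 5, 10)])
        df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(60)])
        a = hierarchical_cluster(df, 3).labels
        perm = rng.permutation(60)
        b = hierarchical_cluster(df.iloc[:, perm], 3).labels
        joined = pd.DataFrame({"a": a, "b": b.reindex(a.index)})
        assert joined.groupby("a")["b"].nunique().eq(1).all()

    def test_average_linkage_supported_others_rejected(self):
        df = pd.DataFrame(np.random.default_rng(2).random((3, 8)))
        hierarchical_cluster(df, 2, linkage="average")
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(df, 2, linkage="single")


class TestChooseK:
    def test_four_blobs_selects_four(self, rng):
        centers = rng.normal(0, 20, size=(4, 5))
        X = np.vstack([rng.normal(c, 0.5, size=(25, 5)) for c in centers])
        df = pd.DataFrame(X.T)
        k, profile = choose_k(df, range(2, 9))
        assert k == 4
        assert set(profile) == set(range(2, 9))

    def test_single_candidate_returned(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 3)), rng.normal(8, 0.3, (10, 3))])
        assert choose_k(pd.DataFrame(X.T), [2])[0] == 2

    def test_identical_samples_rejected(self):
        df = pd.DataFrame(np.ones((4, 10)))
        with pytest.raises(ValueError, match="identical"):
            choose_k(df, range(2, 4))
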