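"""Motif-matrix construction, NMF signature extraction, and rank selection."""

import numpy as np
import pandas as pd
import pytest

from cocatype.signatures import (
    CONTEXT_LABELS,
    build_motif_matrix,
    cluster_exposures,
    extract_signatures,
    match_reference_signatures,
    select_rank_by_cophenetic,
)
from cocatype.synthetic import SyntheticConfig, generate_cohort


def _records(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "chromosome", "position", "ref", "alt", "context"])


class TestMotifMatrix:
    def test_empty_records_give_zero_matrix(self):
        motif = build_motif_matrix(_records([]), ["a", "b", "c"])
        assert motif.counts.shape == (3, 96)
        assert (motif.counts.to_numpy() == 0).all()

    def test_pyrimidine_record_maps_to_its_class(self):
        rec = _records([("s1", "G1", "chr1", 100, "C", "A", "ACA")])
        motif = build_motif_matrix(rec, ["s1"])
        assert motif.counts.loc["s1", "A[C>A]A"] == 1
        assert motif.counts.loc["s1"].sum() == 1

    def test_purine_record_reverse_complemented(self):
        # G>T in context TGT is the reverse complement of C>A in ACA
        rec = _records([("s1", "G1", "chr1", 100, "G", "T", "TGT")])
        motif = build_motif_matrix(rec, ["s1"])
        assert motif.counts.loc["s1", "A[C>A]A"] == 1

    @pytest.mark.parametrize(
        "ref,alt,context",
        [("C", "A", "AC"), ("C", "A", "ATA"), ("C", "C", "ACA"), ("C", "A", "ANA")],
    )
    def test_malformed_records_skipped_and_counted(self, ref, alt, context):
        rec = _records([("s1", "G1", "chr1", 100, ref, alt, context)])
        motif = build_motif_matrix(rec, ["s1"])
        assert motif.counts.to_numpy().sum() == 0
        assert motif.n_skipped == 1

    def test_total_equals_valid_record_count(self, cohort):
        motif = build_motif_matrix(cohort.mutation_records, cohort.sample_ids)
        assert motif.counts.to_numpy().sum() + motif.n_skipped == len(cohort.mutation_records)
        assert motif.n_skipped == 0  # generator emits only valid substitutions


class TestRankSelection:
    def test_first_big_drop_rule(self):
        coph = {2: 0.99, 3: 0.99, 4: 0.98, 5: 0.80, 6: 0.75}
        assert select_rank_by_cophenetic(coph, tolerance=0.05) == 4

    def test_no_sharp_fall_falls_back_to_stability_peak(self):
        coph = {2: 0.96, 3: 0.992, 4: 0.985, 5: 0.97}
        assert select_rank_by_cophenetic(coph, tolerance=0.05) == 3

    def test_peak_tie_breaks_to_smaller_rank(self):
        coph = {2: 0.99, 3: 0.99, 4: 0.98}
        assert select_rank_by_cophenetic(coph, tolerance=0.05) == 2


class TestExtraction:
    def test_exact_rank_one_matrix_reconstructed(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 5, size=20)
        h = rng.dirichlet(np.ones(96))
        V = np.outer(w, h) * 200
        from cocatype.signatures import MotifMatrix

        motif_exact = MotifMatrix(pd.DataFrame(V, columns=list(CONTEXT_LABELS)))
        model = extract_signatures(motif_exact, [1, 2, 3], n_restarts=5, seed=0)
        assert model.reconstruction_error_by_rank[1] < 1e-6

    def test_signatures_normalized_and_nonnegative(self, cohort):
        motif = build_motif_matrix(cohort.mutation_records, cohort.sample_ids)
        model = extract_signatures(motif, range(2, 4), n_restarts=10, seed=1)
        S = model.signatures.to_numpy()
        E = model.exposures.to_numpy()
        assert (S >= 0).all() and (E >= 0).all()
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-6)

    def test_reconstruction_error_non_increasing_in_rank(self, cohort):
        motif = build_motif_matrix(cohort.mutation_records, cohort.sample_ids)
        model = extract_signatures(motif, range(2, 5), n_restarts=30, seed=2)
        errs = [model.reconstruction_error_by_rank[r] for r in sorted(model.reconstruction_error_by_rank)]
        assert all(b <= a + 1e-6 for a, b in zip(errs, errs[1:]))

    def test_duplicated_samples_give_perfect_cophenetic(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(20, size=(2, 96)).astype(float)
        V = np.repeat(base, 25, axis=0)  # 50 samples, two exact profiles
        from cocatype.signatures import MotifMatrix

        motif = MotifMatrix(pd.DataFrame(V, columns=list(CONTEXT_LABELS)))
        model = extract_signatures(motif, [2], n_restarts=10, seed=3)
        assert model.cophenetic_by_rank[2] == pytest.approx(1.0)

    def test_planted_three_signature_recovery_small(self):
        cfg = SyntheticConfig.default(
            n_samples=120, seed=102, n_signatures=3,
            exposure_concentration=0.5, exposure_background=0.5,
        )
        cohort = generate_cohort(cfg)
        motif = build_motif_matrix(cohort.mutation_records, cohort.sample_ids)
        model = extract_signatures(motif, range(2, 5), n_restarts=12, seed=4)
        assert model.selected_rank == 3
        P = cohort.truth["signature_profiles"]
        S = model.signatures.to_numpy()
        cos = (P @ S.T) / (
            np.linalg.norm(P, axis=1)[:, None] * np.linalg.norm(S, axis=1)[None, :]
        )
        assert cos.max(axis=1).min() >= 0.9

    def test_degenerate_inputs_rejected(self):
        from cocatype.signatures import MotifMatrix

        zero = MotifMatrix(pd.DataFrame(np.zeros((5, 96)), columns=list(CONTEXT_LABELS)))
        with pytest.raises(ValueError, match="all-zero"):
            extract_signatures(zero, [2], n_restarts=10, seed=0)
        small = MotifMatrix(pd.DataFrame(np.ones((4, 96)), columns=list(CONTEXT_LABELS)))
        with pytest.raises(ValueError, match="rank"):
            extract_signatures(small, [5], n_restarts=10, seed=0)


class TestReferenceMatching:
    def _model(self, n=3, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.dirichlet(np.ones(96) * 0.3, size=n)
        from cocatype.signatures import SignatureModel

        return SignatureModel(
            rank=n,
            signatures=pd.DataFrame(S, index=[f"SIG{i}" for i in range(n)], columns=list(CONTEXT_LABELS)),
            exposures=pd.DataFrame(np.ones((5, n)), columns=[f"SIG{i}" for i in range(n)]),
            cophenetic_by_rank={n: 1.0},
            selected_rank=n,
        )

    def test_identity_reference_gives_unit_diagonal(self):
        model = self._model()
        ref = model.signatures.copy()
        ref.index = ["R0", "R1", "R2"]
        table = match_reference_signatures(model, ref)
        assert np.allclose(np.diag(table.to_numpy()), 1.0)

    def test_noisy_reference_still_best_matched(self):
        model = self._model(seed=1)
        rng = np.random.default_rng(2)
        ref = model.signatures + rng.normal(0, 0.001, size=model.signatures.shape)
        ref = ref.clip(lower=0)
        ref.index = ["R0", "R1", "R2"]
        table = match_reference_signatures(model, ref)
        assert min(table.attrs["best_r"].values()) > 0.99

    def test_flat_reference_flagged_not_best_matched(self):
        model = self._model(seed=3)
        ref = pd.DataFrame(
            [np.full(96, 1 / 96), model.signatures.iloc[0].to_numpy()],
            index=["FLAT", "GOOD"],
            columns=list(CONTEXT_LABELS),
        )
        table = match_reference_signatures(model, ref)
        assert table["FLAT"].isna().all()
        assert table.attrs["best_match"]["SIG0"] == "GOOD"

    def test_column_order_mismatch_rejected(self):
        model = self._model()
        ref = model.signatures[list(reversed(model.signatures.columns))]
        with pytest.raises(ValueError, match="context"):
            match_reference_signatures(model, ref)


class TestExposureClustering:
    def test_two_point_masses_split_perfectly(self):
        from cocatype.signatures import SignatureModel

        E = np.vstack([np.tile([10.0, 0.0], (50, 1)), np.tile([0.0, 10.0], (50, 1))])
        model = SignatureModel(
            rank=2,
            signatures=pd.DataFrame(np.full((2, 96), 1 / 96), columns=list(CONTEXT_LABELS)),
            exposures=pd.DataFrame(E, index=[f"s{i}" for i in range(100)], columns=["SIG1", "SIG2"]),
            cophenetic_by_rank={2: 1.0},
            selected_rank=2,
        )
        assignment = cluster_exposures(model, k=2)
        labels = assignment.labels
        assert labels.iloc[:50].nunique() == 1
        assert labels.iloc[50:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_sample_permutation_gives_permuted_labels(self):
        from cocatype.signatures import SignatureModel

        rng = np.random.default_rng(5)
        E = np.vstack([rng.normal(0, 0.1, (30, 3)) + mu for mu in ([5, 0, 0], [0, 5, 0], [0, 0, 5])])
        E = np.abs(E)
        idx = [f"s{i}" for i in range(90)]
        model = SignatureModel(
            rank=3,
            signatures=pd.DataFrame(np.full((3, 96), 1 / 96), columns=list(CONTEXT_LABELS)),
            exposures=pd.DataFrame(E, index=idx, columns=["SIG1", "SIG2", "SIG3"]),
            cophenetic_by_rank={3: 1.0},
            selected_rank=3,
        )
        a = cluster_exposures(model, k=3).labels
        perm = rng.permutation(90)
        model_p = SignatureModel(
            rank=3,
            signatures=model.signatures,
            exposures=model.exposures.iloc[perm],
            cophenetic_by_rank={3: 1.0},
            selected_rank=3,
        )
        b = cluster_exposures(model_p, k=3).labels
        # same partition: co-membership identical after reindexing
        joined = pd.DataFrame({"a": a, "b": b.reindex(a.index)})
        assert joined.groupby("a")["b"].nunique().eq(1).all()
        assert joined.groupby("b")["a"].nunique().eq(1).all()
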