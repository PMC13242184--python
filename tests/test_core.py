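import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracle
from msaneff import (
    EmptyAlignmentError,
    MsaFormat,
    NeffOptions,
    OptionError,
    compute_neff,
    encode_msa,
    pairwise_similarity,
    per_residue_neff,
    preprocess,
    sequence_weights,
)

from conftest import make_msa, random_rows


def none_opts(**kwargs):
    kwargs.setdefault("norm", "none")
    return NeffOptions(**kwargs)


class TestWorkedExample:
    """4 rows ACDEF/ACDEG/ACDGG/ACDEF at theta=0.8: pair identities are
    {q,s1}=.8 {q,s2}=.6 {q,s3}=1 {s1,s2}=.8 {s1,s3}=.8 {s2,s3}=.6."""

    def test_weights(self, worked_msa):
        res = compute_neff(worked_msa, none_opts())
        assert res.weights.tolist() == pytest.approx(
            [1 / 3, 1 / 4, 1 / 2, 1 / 3], abs=0
        )

    def test_raw_sum_and_normalizations(self, worked_msa):
        res = compute_neff(worked_msa, none_opts())
        assert res.raw_sum == pytest.approx(17 / 12, abs=1e-12)
        by_len = compute_neff(worked_msa, NeffOptions(norm="by_length"))
        assert by_len.neff == pytest.approx(17 / 60, abs=1e-12)
        by_sqrt = compute_neff(worked_msa, NeffOptions(norm="by_sqrt_length"))
        assert by_sqrt.neff == pytest.approx((17 / 12) / np.sqrt(5), abs=1e-12)

    def test_matches_naive_oracle(self, worked_msa):
        _, raw, w, _ = oracle.neff([r.seq for r in worked_msa.records], norm="none")
        res = compute_neff(worked_msa, none_opts())
        assert res.weights.tolist() == w
        assert res.raw_sum == pytest.approx(raw, abs=1e-12)


class TestClosedForms:
    @pytest.mark.parametrize("k", [1, 2, 10, 100])
    def test_k_identical_rows_have_unit_neff(self, k):
        msa = make_msa(["ACDEFGHIKL"] * k)
        res = compute_neff(msa, none_opts())
        assert res.neff == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.weights, 1.0 / k)

    def test_mutually_dissimilar_rows_count_fully(self):
        msa = make_msa(["AAAA", "CCCC", "GGGG"])
        res = compute_neff(msa, none_opts())
        assert res.weights.tolist() == [1.0, 1.0, 1.0]
        assert res.neff == 3.0

    def test_duplicating_the_msa_leaves_neff_unchanged(self, rng):
        rows = random_rows(rng, 12, 25)
        base = compute_neff(make_msa(rows), none_opts())
        doubled = compute_neff(make_msa(rows + rows), none_opts())
        assert doubled.neff == pytest.approx(base.neff, abs=1e-9)


class TestPairwiseSimilarity:
    def test_identical_rows(self):
        enc = encode_msa(make_msa(["ACDEF", "ACDEF"]))
        assert pairwise_similarity(enc, 0, 1) == 1.0
        assert pairwise_similarity(enc, 0, 1, symmetric=False) == (1.0, 1.0)

    def test_symmetric_fraction(self):
        enc = encode_msa(make_msa(["ACDEF", "ACDEG"]))
        assert pairwise_similarity(enc, 0, 1) == pytest.approx(0.8)

    def test_gap_gap_counts_as_match_in_symmetric_mode(self):
        enc = encode_msa(make_msa(["AC--", "AC--"]))
        assert pairwise_similarity(enc, 0, 1) == 1.0

    def test_asymmetric_directional_pair(self):
        enc = encode_msa(make_msa(["AC--", "ACGT"]), alphabet="dna")
        s_into_j, s_into_i = pairwise_similarity(enc, 0, 1, symmetric=False)
        assert s_into_j == pytest.approx(0.5)  # 2 matches / 4 residues of j
        assert s_into_i == pytest.approx(1.0)  # 2 matches / 2 residues of i

    def test_symmetric_matrix_property(self, rng):
        enc = encode_msa(make_msa(random_rows(rng, 8, 15)))
        for i in range(8):
            for j in range(8):
                assert pairwise_similarity(enc, i, j) == pairwise_similarity(enc, j, i)

    def test_all_gap_row_has_zero_similarity_into_it(self):
        enc = encode_msa(make_msa(["ACGT", "----"]), alphabet="dna")
        s_into_j, s_into_i = pairwise_similarity(enc, 0, 1, symmetric=False)
        assert s_into_j == 0.0


class TestPreprocess:
    def test_query_gap_columns_removed(self):
        enc = encode_msa(make_msa(["A-C", "AGC"]))
        out = preprocess(enc, NeffOptions())
        assert out.n_cols == 2
        assert out.column_map == [0, 2]
        assert out.columns_removed == (1, 0)

    def test_keep_query_gaps(self):
        enc = encode_msa(make_msa(["A-C", "AGC"]))
        out = preprocess(enc, NeffOptions(keep_query_gaps=True))
        assert out.n_cols == 3

    def test_gappy_column_dropped_on_strict_exceedance(self):
        rows = ["AA", "A-", "A-", "A-"]  # col 2: 3/4 gaps > 0.5
        enc = encode_msa(make_msa(rows))
        out = preprocess(enc, NeffOptions(gap_cutoff=0.5))
        assert out.n_cols == 1 and out.columns_removed == (0, 1)

    def test_gap_fraction_equal_to_cutoff_is_kept(self):
        rows = ["AA", "A-", "A-", "AA"]  # col 2: 2/4 gaps, not > 0.5
        enc = encode_msa(make_msa(rows))
        out = preprocess(enc, NeffOptions(gap_cutoff=0.5))
        assert out.n_cols == 2

    def test_depth_cap_keeps_first_rows(self):
        enc = encode_msa(make_msa(["AC", "AD", "AE", "AF", "AG"]))
        out = preprocess(enc, NeffOptions(depth=2))
        assert out.n_rows == 2
        assert out.matrix.tolist() == enc.matrix[:2].tolist()

    def test_depth_cap_always_retains_query(self):
        msa = make_msa(["AC", "AD", "AE", "AF"], query_index=3)
        enc = encode_msa(msa)
        out = preprocess(enc, NeffOptions(depth=2))
        assert out.n_rows == 2
        assert out.matrix.tolist() == [enc.matrix[0].tolist(), enc.matrix[3].tolist()]
        assert out.query_row == 1

    def test_all_columns_removed_raises(self):
        enc = encode_msa(make_msa(["--", "AC"]))
        with pytest.raises(EmptyAlignmentError):
            preprocess(enc, NeffOptions())

    def test_invalid_options_rejected(self):
        with pytest.raises(OptionError):
            NeffOptions(theta=0.0)
        with pytest.raises(OptionError):
            NeffOptions(gap_cutoff=1.5)
        with pytest.raises(OptionError):
            NeffOptions(depth=0)


class TestInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounds_raw_sum_between_one_and_n(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, int(rng.integers(2, 20)), int(rng.integers(5, 30)))
        res = compute_neff(make_msa(rows), none_opts())
        assert 1.0 - 1e-12 <= res.raw_sum <= res.n_rows + 1e-12
        assert np.all(res.weights > 0) and np.all(res.weights <= 1)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_neff_nondecreasing_in_theta(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, 15, 25)
        msa = make_msa(rows)
        grid = np.linspace(0.1, 1.0, 10)
        values = [compute_neff(msa, none_opts(theta=t)).raw_sum for t in grid]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, 10, 20)
        base = compute_neff(make_msa(rows), none_opts())
        perm = rng.permutation(10)
        permuted_msa = make_msa(
            [rows[i] for i in perm], query_index=int(np.argwhere(perm == 0)[0][0])
        )
        permuted = compute_neff(permuted_msa, none_opts())
        assert permuted.neff == pytest.approx(base.neff, abs=1e-12)
        assert sorted(permuted.weights) == pytest.approx(sorted(base.weights))

    def test_a3m_source_is_reduced_to_match_columns(self):
        a3m = make_msa(["ACD", "AgCD"], fmt=MsaFormat.A3M)
        flat = make_msa(["ACD", "ACD"])
        assert compute_neff(a3m, none_opts()).neff == compute_neff(flat, none_opts()).neff


class TestOracleEquivalence:
    """Vectorized weights must equal the naive double loop exactly."""

    @pytest.mark.parametrize("symmetric", [True, False])
    @pytest.mark.parametrize("theta", [0.5, 0.8, 1.0])
    def test_weights_match_naive_reference(self, rng, symmetric, theta):
        for _ in range(10):
            n, length = int(rng.integers(2, 30)), int(rng.integers(5, 30))
            rows = random_rows(rng, n, length)
            msa = make_msa(rows)
            res = compute_neff(msa, none_opts(theta=theta, symmetric=symmetric))
            norm_rows = oracle.normalize_rows(rows)
            expected = oracle.weights(norm_rows, theta=theta, symmetric=symmetric)
            assert res.weights.tolist() == expected

    def test_full_pipeline_matches_oracle_with_preprocessing(self, rng):
        for _ in range(10):
            rows = random_rows(rng, 12, 24)
            msa = make_msa(rows)
            opts = none_opts(gap_cutoff=0.5, depth=8)
            res = compute_neff(msa, opts)
            _, raw, w, _ = oracle.neff(
                rows, norm="none", gap_cutoff=0.5, depth=8
            )
            assert res.weights.tolist() == w
            assert res.raw_sum == pytest.approx(raw, abs=1e-12)


class TestPerResidue:
    def test_gap_free_columns_equal_raw_sum(self, rng):
        rows = [r.replace("-", "A").replace(".", "A") for r in random_rows(rng, 8, 12)]
        pr = per_residue_neff(make_msa(rows), none_opts())
        assert np.allclose(pr.values, pr.sequence_result.raw_sum)

    def test_query_only_column_equals_query_weight(self):
        msa = make_msa(["ACDEF", "AC-EG", "AC-GG"])
        pr = per_residue_neff(msa, none_opts())
        res = pr.sequence_result
        assert pr.values[2] == pytest.approx(res.weights[0])

    def test_values_never_exceed_raw_sum(self, rng):
        rows = random_rows(rng, 10, 20)
        pr = per_residue_neff(make_msa(rows), none_opts())
        assert np.all(pr.values <= pr.sequence_result.raw_sum + 1e-12)

    def test_gapping_one_residue_recomputes_that_column(self, worked_msa):
        # change s2's last residue to a gap and recompute from scratch
        rows = [r.seq for r in worked_msa.records]
        rows_mod = rows[:3] + [rows[3]]
        rows_mod[2] = rows_mod[2][:-1] + "-"
        pr = per_residue_neff(make_msa(rows_mod), none_opts())
        res = pr.sequence_result
        assert pr.values[4] == pytest.approx(res.raw_sum - res.weights[2], abs=1e-12)

    def test_columns_report_original_coordinates(self):
        msa = make_msa(["A-CDE", "AGCDE"])
        pr = per_residue_neff(msa, none_opts())
        assert pr.columns == [0, 2, 3, 4]

    def test_matches_naive_recomputation(self, rng):
        rows = random_rows(rng, 9, 14)
        pr = per_residue_neff(make_msa(rows), none_opts())
        norm = oracle.normalize_rows(rows)
        pre, _ = oracle.preprocess_rows(norm)
        w = oracle.weights(pre)
        for j in range(len(pre[0])):
            expected = sum(w[i] for i in range(len(pre)) if pre[i][j] != "-")
            assert pr.values[j] == pytest.approx(expected, abs=1e-12)
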