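import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexnet.correlation import (
    CorrelationEdgeList,
    pairwise_correlations,
    pearson,
    read_pearson_file,
    sample_correlation_matrix,
    write_pearson_file,
)
from conftest import make_matrix, naive_pairwise_correlations


class TestPearson:
    def test_perfect_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # direct summation: covariance 1, both variances 2 -> r = 1/2
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(pearson([5, 5, 5], [1, 2, 3]))

    def test_length_mismatch_and_short_vectors_error(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=12),
        st.floats(0.1, 10.0),
        st.floats(-100.0, 100.0),
    )
    def test_invariant_under_positive_affine_transform(self, xs, a, b):
        ys = [v * 1.7 + 3 for v in xs]  # arbitrary second profile
        r0 = pearson(xs, ys)
        r1 = pearson([a * v + b for v in xs], ys)
        if not math.isnan(r0):
            assert r1 == pytest.approx(r0, abs=1e-9)


class TestPairwiseCorrelations:
    def test_identical_rows_all_perfect(self):
        m = make_matrix(np.tile([1.0, 2.0, 3.0], (3, 1)))
        edges = pairwise_correlations(m, save_threshold=0.75)
        assert len(edges) == 3
        assert all(r == pytest.approx(1.0) for _, _, r in edges.edges)

    def test_planted_scaled_module_forms_clique(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(1, 100, size=20)
        k = 6
        scales = rng.uniform(0.5, 5, size=k)
        values = np.vstack([s * profile for s in scales] + [rng.uniform(1, 100, (10, 20))])
        edges = pairwise_correlations(make_matrix(values), save_threshold=0.999999)
        module_ids = {make_matrix(values).probeset_ids[i] for i in range(k)}
        in_module = [e for e in edges.edges if e[0] in module_ids and e[1] in module_ids]
        assert len(in_module) == k * (k - 1) // 2
        assert all(r == pytest.approx(1.0) for _, _, r in in_module)

    def test_iid_gaussian_rows_produce_no_edges(self):
        # under independence, r*sqrt((n-2)/(1-r^2)) is t(n-2); the tail
        # beyond r = 0.75 at n = 743 is far below 1e-30, so zero edges is
        # the certain outcome
        rng = np.random.default_rng(42)
        m = make_matrix(rng.standard_normal((1000, 743)) + 100.0)
        assert len(pairwise_correlations(m, save_threshold=0.75)) == 0

    @pytest.mark.parametrize("chunk_size", [1, 7, 64, 500])
    def test_chunking_matches_naive_oracle(self, chunk_size):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, size=(60, 20))
        values[5] = values[4] * 2.0  # guarantee some edges
        values[11] = 0.0  # zero-variance row
        m = make_matrix(values)
        got = pairwise_correlations(m, save_threshold=0.3, chunk_size=chunk_size)
        expected = {
            (m.probeset_ids[i], m.probeset_ids[j]): r
            for i, j, r in naive_pairwise_correlations(values, 0.3)
        }
        assert {(a, b) for a, b, _ in got.edges} == set(expected)
        for a, b, r in got.edges:
            assert r == pytest.approx(expected[(a, b)], abs=1e-12)

    def test_result_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 10, size=(30, 15))
        values[3] = values[2] * 1.5 + 1
        m = make_matrix(values)
        perm = rng.permutation(30)
        m2 = make_matrix(values[perm], probeset_ids=[m.probeset_ids[i] for i in perm])
        e1 = pairwise_correlations(m, save_threshold=0.5)
        e2 = pairwise_correlations(m2, save_threshold=0.5)
        assert [(a, b) for a, b, _ in e1.edges] == [(a, b) for a, b, _ in e2.edges]

    def test_positive_threshold_never_emits_negative_edges(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((40, 10)) + 5
        values[1] = -values[0] + 10  # perfectly anti-correlated pair
        edges = pairwise_correlations(make_matrix(values), save_threshold=0.5)
        assert all(r >= 0.5 for _, _, r in edges.edges)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match="3 observations"):
            pairwise_correlations(make_matrix([[1.0, 2.0], [3.0, 4.0]]))

    def test_edge_list_rejects_below_threshold_entries(self):
        with pytest.raises(ValueError):
            CorrelationEdgeList([("a", "b", 0.5)], save_threshold=0.7, axis="probesets")


class TestSampleCorrelationMatrix:
    def test_identical_columns_all_ones(self):
        m = make_matrix(np.tile([[1.0], [2.0], [5.0]], (1, 2)))
        np.testing.assert_allclose(sample_correlation_matrix(m).values, 1.0)

    def test_hand_computed_off_diagonal(self):
        m = make_matrix(np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]]))
        assert sample_correlation_matrix(m).values[0, 1] == pytest.approx(0.5)

    def test_symmetry_unit_diagonal_and_agreement_with_edge_list(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.uniform(1, 50, size=(25, 8)))
        corr = sample_correlation_matrix(m)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        edges = pairwise_correlations(m, axis="samples", save_threshold=-0.999999)
        for a, b, r in edges.edges:
            assert corr.loc[a, b] == pytest.approx(r, abs=1e-12)


def test_pearson_file_round_trip(tmp_path):
    edges = CorrelationEdgeList(
        [("a_at", "b_at", 0.901234), ("a_at", "c_at", 0.75)],
        save_threshold=0.7,
        axis="probesets",
    )
    path = tmp_path / "edges.pearson"
    write_pearson_file(edges, path)
    back = read_pearson_file(path, save_threshold=0.7)
    assert [(a, b) for a, b, _ in back.edges] == [(a, b) for a, b, _ in edges.edges]
    for (_, _, r1), (_, _, r2) in zip(back.edges, edges.edges):
        assert r1 == pytest.approx(r2, abs=5e-7)  # 6-decimal file format
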