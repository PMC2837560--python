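"""QC gates, quantile normalization and median polish behave as specified."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform
from statistics import median as stat_median

from sigrev import (
    above_background_fraction,
    median_polish_summarize,
    quantile_normalize,
    replicate_distance_check,
)
from sigrev.io import InputError
from sigrev.preprocess import present_call_gate


def _matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=samples)


class TestAboveBackground:
    def test_all_above_passes_all_below_fails(self):
        m = _matrix([[5.0], [6.0], [7.0], [8.0]])
        assert above_background_fraction(m, 1.0).iloc[0] == 1.0
        assert present_call_gate(above_background_fraction(m, 1.0)).iloc[0]
        assert above_background_fraction(m, 10.0).iloc[0] == 0.0
        assert not present_call_gate(above_background_fraction(m, 10.0)).iloc[0]

    def test_exactly_quarter_above_fails_strict_gate(self):
        m = _matrix([[9.0], [1.0], [1.0], [1.0]])
        frac = above_background_fraction(m, 5.0)
        assert frac.iloc[0] == 0.25
        assert not present_call_gate(frac).iloc[0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            above_background_fraction(pd.DataFrame(), 0.0)


def test_background_correction_hook_is_identity_by_default():
    from sigrev.preprocess import background_correct

    m = _matrix([[1.0, 2.0], [3.0, 4.0]])
    pd.testing.assert_frame_equal(background_correct(m), m)
    pd.testing.assert_frame_equal(background_correct(m, method=lambda x: x + 1), m + 1)


class TestReplicateDistance:
    def test_duplicate_columns_all_pass(self):
        m = _matrix(np.tile([[1.0], [2.0], [3.0]], (1, 4)))
        ann = pd.Series({s: "g" for s in m.columns})
        report = replicate_distance_check(m, ann)
        assert report.flagged == {}
        assert np.allclose(report.distances.to_numpy(), 0.0)

    def test_outlier_sample_is_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        cols = {f"s{j}": base + rng.normal(0, 1.0, 30) for j in range(5)}
        cols["s5"] = base + 6.0  # far from the group, distances computed below
        m = _matrix(np.column_stack(list(cols.values())), samples=list(cols))
        ann = pd.Series({s: "g" for s in m.columns})
        report = replicate_distance_check(m, ann)
        # the report's distances are the plain Euclidean distances
        expected = squareform(pdist(m.to_numpy().T))
        assert np.allclose(report.distances.to_numpy(), expected)
        assert set(report.flagged) == {"s5"}

    def test_two_tight_groups_within_zero_between_positive(self):
        a = np.tile([[1.0], [2.0]], (1, 3))
        b = np.tile([[5.0], [6.0]], (1, 3))
        m = _matrix(np.hstack([a, b]))
        ann = pd.Series({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
        report = replicate_distance_check(m, ann)
        assert report.flagged == {}
        within = report.distances.iloc[:3, :3].to_numpy()
        between = report.distances.iloc[:3, 3:].to_numpy()
        assert np.allclose(within, 0.0)
        assert (between > 0).all()

    def test_singleton_group_is_unevaluable_not_failed(self):
        m = _matrix(np.random.default_rng(1).normal(size=(10, 3)))
        ann = pd.Series({"s0": "A", "s1": "A", "s2": "B"})
        report = replicate_distance_check(m, ann)
        assert report.unevaluable == ["s2"]
        assert "s2" not in report.flagged


class TestQuantileNormalize:
    def test_two_column_forced_example(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.to_numpy(), expected)

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        m = _matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_ties_get_mean_of_reference_values_at_tied_ranks(self):
        m = _matrix(np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 3.0]]))
        out = quantile_normalize(m)
        # reference = rowwise mean of sorted columns = [1, 1.5, 2.5]
        assert np.allclose(out.iloc[:, 0], [1.25, 1.25, 2.5])
        assert np.allclose(out.iloc[:, 1], [1.0, 1.5, 2.5])

    @given(hnp.arrays(np.float64, (7, 4), elements=st.floats(-50, 50)))
    def test_columns_share_sorted_vector_and_ranks_survive(self, values):
        m = _matrix(values + np.random.default_rng(0).normal(0, 1e-6, values.shape))
        out = quantile_normalize(m)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-12)
        for j in range(m.shape[1]):
            before = np.argsort(m.iloc[:, j].to_numpy(), kind="stable")
            after = np.argsort(out.iloc[:, j].to_numpy(), kind="stable")
            assert (before == after).all()

    def test_column_means_equal_after_normalization(self):
        m = _matrix(np.random.default_rng(3).normal(size=(50, 5)) * [1, 2, 3, 4, 5])
        out = quantile_normalize(m)
        means = out.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0])


def _oracle_median_polish(x, n_iter=200):
    """Independent scalar-loop median polish (rows first), for cross-checking."""
    z = [list(map(float, row)) for row in x]
    nr, nc = len(z), len(z[0])
    t, r, c = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(n_iter):
        for i in range(nr):
            med = stat_median(z[i])
            r[i] += med
            for j in range(nc):
                z[i][j] -= med
        dr = stat_median(r)
        t += dr
        r = [v - dr for v in r]
        for j in range(nc):
            med = stat_median([z[i][j] for i in range(nr)])
            c[j] += med
            for i in range(nr):
                z[i][j] -= med
        dc = stat_median(c)
        t += dc
        c = [v - dc for v in c]
    return [t + v for v in c]


class TestMedianPolish:
    def test_exactly_additive_matrix_recovered(self):
        mu, r, c = 3.0, np.array([0.0, 1.0, -1.0]), np.array([0.5, -0.5, 2.0, 0.0])
        x = mu + r[:, None] + c[None, :]
        res = median_polish_summarize(x)
        assert res.converged
        assert np.allclose(res.residuals, 0.0, atol=1e-12)
        assert np.allclose(res.summaries, mu + c)

    def test_single_row_summaries_equal_the_row(self):
        row = np.array([[4.0, 7.0, 1.0]])
        res = median_polish_summarize(row)
        assert np.allclose(res.summaries, row[0])

    @pytest.mark.parametrize("shape, seed", [((3, 3), 0), ((5, 4), 1), ((6, 7), 2)])
    def test_matches_independent_oracle(self, shape, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=shape)
        x[0, 0] += 10.0  # outlier cell
        res = median_polish_summarize(x, max_iter=300, tol=1e-13)
        assert np.allclose(res.summaries, _oracle_median_polish(x), atol=1e-9)

    def test_row_permutation_leaves_summaries_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        a = median_polish_summarize(x, max_iter=100, tol=1e-12)
        b = median_polish_summarize(x[perm], max_iter=100, tol=1e-12)
        assert np.allclose(a.summaries, b.summaries, atol=1e-9)

    def test_constant_added_to_one_column_moves_only_its_summary(self):
        mu, r, c = 1.0, np.array([0.0, 2.0, -1.0]), np.array([0.0, 1.0, -2.0])
        x = mu + r[:, None] + c[None, :]
        shifted = x.copy()
        shifted[:, 1] += 5.0
        a = median_polish_summarize(x)
        b = median_polish_summarize(shifted)
        assert np.allclose(b.summaries - a.summaries, [0.0, 5.0, 0.0])

    def test_non_convergence_is_flagged(self):
        rng = np.random.default_rng(5)
        res = median_polish_summarize(rng.normal(size=(9, 9)), max_iter=1)
        assert not res.converged
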