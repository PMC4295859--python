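"""Cuzick trend statistic: hand values, exhaustive-permutation oracle,
rank-statistic invariances, and the composite/chronic rankings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosetrend import (
    ExpressionMatrix,
    acute_sigma_z,
    chronic_ttest_rank,
    cuzick_trend_test,
    generate_acute_experiment,
    generate_chronic_experiment,
    max_sigma_z,
    AcuteDesign,
    ChronicDesign,
)
from dosetrend.trend import DegenerateInputError


def exact_trend_moments(scores):
    """Oracle: moments and exact two-sided p-values of T = sum l_j r_j by
    enumerating every assignment of distinct ranks to positions."""
    n = len(scores)
    scores = np.asarray(scores, dtype=float)
    ts = np.fromiter(
        (scores @ np.asarray(perm) for perm in itertools.permutations(range(1, n + 1))),
        dtype=float,
    )
    return ts.mean(), ts.var(), ts


class TestCuzickAgainstHandValues:
    def test_worked_example(self):
        res = cuzick_trend_test([1, 2, 3, 4, 5, 6], [1, 1, 2, 2, 3, 3])
        assert res.T == 50
        assert res.expected_T == 42
        assert res.variance_T == 14
        assert res.Z == pytest.approx(8 / np.sqrt(14), abs=1e-12)
        assert res.Z == pytest.approx(2.1381, abs=5e-5)

    def test_symmetric_arrangement_scores_zero(self):
        # groups {1,6},{2,5},{3,4}: rank sums balance exactly
        res = cuzick_trend_test([1, 6, 2, 5, 3, 4], [1, 1, 2, 2, 3, 3])
        assert res.T == res.expected_T == 42
        assert res.Z == 0.0

    def test_reversed_scores_flip_sign(self):
        fwd = cuzick_trend_test([1, 2, 3, 4, 5, 6], [1, 1, 2, 2, 3, 3])
        rev = cuzick_trend_test([1, 2, 3, 4, 5, 6], [3, 3, 2, 2, 1, 1])
        assert rev.Z == pytest.approx(-fwd.Z, abs=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            cuzick_trend_test([1, 2], [1, 2])
        with pytest.raises(ValueError):
            cuzick_trend_test([1, 2, 3], [1, 1, 1])
        with pytest.raises(DegenerateInputError):
            cuzick_trend_test([5, 5, 5, 5], [1, 1, 2, 2])


@pytest.mark.parametrize(
    "group_sizes",
    [(2, 2, 2), (1, 2, 3), (3, 3, 2), (2, 2, 2, 2), (1, 1, 1), (4, 4), (3, 2, 3)],
)
def test_moments_and_p_match_exhaustive_permutation(group_sizes):
    """Z standardizes by the exact permutation moments (to 1e-12); in the
    rejection region (exact two-sided p <= 0.1, where selection decisions
    live) the normal-approximation p stays within 0.05 of the exact
    permutation p.  Mid-distribution p-values of a discrete null at N <= 8
    necessarily deviate more and carry no decision."""
    scores = np.concatenate([[i + 1] * g for i, g in enumerate(group_sizes)]).astype(float)
    n = scores.size
    mean_t, var_t, ts = exact_trend_moments(scores)

    values = np.arange(1, n + 1, dtype=float)  # one arbitrary tie-free arrangement
    res = cuzick_trend_test(values, scores)
    assert res.expected_T == pytest.approx(mean_t, abs=1e-12)
    assert res.variance_T == pytest.approx(var_t, rel=1e-12)
    assert res.Z == pytest.approx((res.T - mean_t) / np.sqrt(var_t), abs=1e-12)

    from scipy.stats import norm

    checked = 0
    for t_obs in np.unique(ts):
        p_exact = np.mean(np.abs(ts - mean_t) >= abs(t_obs - mean_t) - 1e-12)
        if p_exact > 0.1:
            continue
        z = (t_obs - mean_t) / np.sqrt(var_t)
        p_normal = 2 * norm.sf(abs(z))
        assert abs(p_normal - p_exact) <= 0.05
        checked += 1
    if n >= 6:  # N=3 has only 6 permutations, no attainable p below 0.1
        assert checked > 0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-50, 50), unique=True, min_size=6, max_size=6),
    st.integers(-100, 100),
)
def test_location_shift_and_monotone_transform_invariance(vals, shift):
    """A rank statistic ignores location shifts and strictly monotone
    transforms (stated over tie-free observations)."""
    scores = [1, 1, 2, 2, 3, 3]
    base = cuzick_trend_test(vals, scores)
    shifted = cuzick_trend_test(np.asarray(vals) + shift, scores)
    assert shifted.Z == pytest.approx(base.Z, abs=1e-9)
    monotone = cuzick_trend_test(np.exp(np.asarray(vals) / 25.0), scores)
    assert monotone.Z == pytest.approx(base.Z, abs=1e-9)


def test_type_i_error_near_nominal(rng):
    """Two-sided rejection rate at alpha=0.05 under the null, N=12."""
    scores = np.repeat([1.0, 2.0, 3.0], 4)
    values = rng.standard_normal((10_000, 12))
    from dosetrend.trend import cuzick_trend_matrix

    z, p, *_ = cuzick_trend_matrix(values, scores)
    rate = np.mean(p < 0.05)
    assert 0.03 <= rate <= 0.07


class TestAcuteComposite:
    def test_sigma_z_is_exact_sum_of_time_scores(self, spiked_acute):
        matrix, _ = spiked_acute
        tr = acute_sigma_z(matrix, add_bh=False)
        total = tr["z_t6"] + tr["z_t24"] + tr["z_t48"]
        assert (tr["sigma_z"] == total).all()
        assert sorted(tr["rank"]) == list(range(1, len(tr) + 1))

    def test_identical_data_at_all_times_triples_z(self):
        block = pd.DataFrame(
            np.tile(np.array([[1.0, 2, 3, 4, 5, 6], [6, 2, 4, 3, 5, 1]]), 3),
            index=["gA", "gB"],
        )
        cols = [f"s{i}" for i in range(18)]
        block.columns = cols
        design = pd.DataFrame(
            {
                "drug": "x",
                "dose_score": [1, 1, 2, 2, 3, 3] * 3,
                "time_h": [6] * 6 + [24] * 6 + [48] * 6,
                "replicate": [1, 2] * 9,
            },
            index=cols,
        )
        m = ExpressionMatrix(values=block, design=design, level="gene")
        tr = acute_sigma_z(m, add_bh=False)
        assert tr.loc["gA", "sigma_z"] == pytest.approx(3 * tr.loc["gA", "z_t6"], abs=1e-12)

    def test_missing_time_point_is_reported(self, tiny_matrix):
        with pytest.raises(ValueError, match="48"):
            acute_sigma_z(tiny_matrix, time_points=(6, 24, 48))

    def test_null_sigma_z_variance_near_three(self):
        design = AcuteDesign(
            n_genes=5000, n_trend_genes=0, effect_size_log2=0.0,
            replicates_per_group=20, hybridizations_per_specimen=1, seed=11,
        )
        matrix, _ = generate_acute_experiment(design)
        tr = acute_sigma_z(matrix, add_bh=False)
        var = tr["sigma_z"].var()
        assert abs(var - 3.0) <= 0.3
        se = tr["sigma_z"].std() / np.sqrt(len(tr))
        assert abs(tr["sigma_z"].mean()) <= 3 * se


class TestChronicRanking:
    def test_welch_t_matches_closed_form(self):
        # control (1,2,3) vs treated (4,5,6): equal variances s^2 = 1,
        # Welch t = (4.5-2)... = 3 / sqrt(2/3)
        values = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["g"],
                              columns=[f"s{i}" for i in range(6)])
        design = pd.DataFrame(
            {"drug": "x", "dose_score": [0, 0, 0, 1, 1, 1], "time_h": 720,
             "replicate": [1, 2, 3, 1, 2, 3],
             "arm": ["control"] * 3 + ["IC10"] * 3},
            index=values.columns,
        )
        m = ExpressionMatrix(values=values, design=design, level="gene")
        tr = chronic_ttest_rank(m, add_bh=False)
        assert tr.loc["g", "t"] == pytest.approx(3 / np.sqrt(2 / 3), rel=1e-12)
        assert tr.loc["g", "direction"] == "up"

    def test_null_p_values_uniform(self):
        design = ChronicDesign(n_genes=5000, n_affected_genes=0, effect_size_log2=0.0,
                               replicates_per_arm=10, seed=21)
        matrix, _ = generate_chronic_experiment(design)
        tr = chronic_ttest_rank(matrix, add_bh=False)
        from scipy.stats import kstest

        assert kstest(tr["p"], "uniform").pvalue > 0.01

    def test_single_replicate_arm_rejected(self, tiny_matrix):
        design = tiny_matrix.design.assign(arm=["control", "control", "IC10", "IC10"])
        m = ExpressionMatrix(values=tiny_matrix.values, design=design, level="gene")
        m2 = m.subset_samples(["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            chronic_ttest_rank(m2)


class TestMaxSigmaZ:
    def test_known_bounds(self):
        assert max_sigma_z(3, 2, 3) == pytest.approx(3 * 8 / np.sqrt(14), abs=1e-12)
        assert max_sigma_z(3, 1, 3) == pytest.approx(3 * np.sqrt(2), abs=1e-12)

    def test_monotone_in_replication(self):
        bounds = [max_sigma_z(3, r, 3) for r in range(1, 7)]
        assert all(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:]))
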