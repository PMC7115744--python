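"""Divergence scores, significance, consensus and selection rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adipodyn import (
    DEFAULT_INTERVALS,
    IntervalSpec,
    TimeCourseDivergence,
    consensus_scores,
    dynamic_score,
    instability_flag,
    integral_scores,
    peak_score,
    relevance_score,
    score_significance,
    select_candidates,
    select_top_set,
)

from conftest import DAYS, make_curves, make_experiment


# ----------------------------------------------------------------------
# closed-form score checks
# ----------------------------------------------------------------------
def test_integral_of_constant_offset_is_rectangle():
    curves = make_curves(np.full((1, 6), 2.0))
    scores = integral_scores(curves)
    assert scores.loc["g0", "whole"] == pytest.approx(20.0, abs=1e-9)
    assert scores.loc["g0", "early"] == pytest.approx(4.0, abs=1e-9)


def test_integral_triangle_over_middle_interval():
    # d = 0 at day 0, linear to 4 at day 4
    d = np.array([[0.0, 0.0, 2.0, 4.0, 4.0, 4.0]])
    scores = integral_scores(make_curves(d))
    assert scores.loc["g0", "middle"] == pytest.approx(8.0, abs=1e-9)


def test_integral_zero_difference_scores_zero_everywhere():
    scores = integral_scores(make_curves(np.zeros((1, 6))))
    assert np.allclose(scores.to_numpy(), 0.0, atol=1e-12)


def test_interval_off_grid_rejected():
    curves = make_curves(np.ones((1, 6)))
    with pytest.raises(ValueError):
        integral_scores(curves, (IntervalSpec("bad", -2, 3),))
    with pytest.raises(ValueError):
        IntervalSpec("inverted", 4, 0)


def test_dynamic_score_exact_for_linear_difference():
    d = np.array([DAYS]) + 2.0  # d(day) = day + 2, slope 1 over 10 days
    assert dynamic_score(make_curves(d)).loc["g0"] == pytest.approx(10.0, abs=1e-9)


def test_dynamic_score_zero_for_constant_difference():
    assert dynamic_score(make_curves(np.full((1, 6), 5.0))).loc["g0"] == pytest.approx(
        0.0, abs=1e-12
    )


def test_dynamic_score_zero_for_symmetric_difference():
    d = np.array([[0.0, 1, 2, 2, 1, 0]])
    # independent oracle: OLS slope via normal equations
    days = np.array(DAYS)
    slope = np.polyfit(days, d[0], 1)[0]
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert dynamic_score(make_curves(d)).loc["g0"] == pytest.approx(0.0, abs=1e-9)


def test_peak_score_ignores_pure_offset():
    assert peak_score(make_curves(np.full((1, 6), 2.0))).loc["g0"] == pytest.approx(
        0.0, abs=1e-12
    )


def test_peak_score_detects_single_spike():
    d = np.array([[0.0, 0, 0, 0, 0, 5]])
    assert peak_score(make_curves(d)).loc["g0"] == pytest.approx(5.0)
    spiked = np.array([[1.0, 1, 1, 4, 1, 1]])
    assert peak_score(make_curves(spiked)).loc["g0"] == pytest.approx(3.0)


def test_relevance_score_log_counts():
    scores = relevance_score(["a", "b", "c", "d"], {"a": 0, "b": 9, "c": 3, "d": 3})
    assert scores["a"] == 0.0
    assert scores["b"] == pytest.approx(np.log(10.0), abs=1e-9)
    assert scores["c"] == scores["d"]
    # unknown genes score 0
    assert relevance_score(["zz"], {"a": 5})["zz"] == 0.0
    with pytest.raises(ValueError):
        relevance_score(["a"], {"a": -1})


def test_scores_invariant_to_shared_baseline_shift(rng):
    """Adding a gene-specific constant to BOTH conditions leaves d-based
    scores unchanged; relevance ignores expression entirely."""
    a = rng.normal(8, 1, size=(5, 6))
    b = rng.normal(8, 1, size=(5, 6))
    shift = rng.normal(0, 3, size=(5, 1))
    c1 = make_experiment({"epi": a, "ing": b}).condition_mean_curves()
    c2 = make_experiment({"epi": a + shift, "ing": b + shift}).condition_mean_curves()
    pd.testing.assert_series_equal(dynamic_score(c1), dynamic_score(c2))
    pd.testing.assert_series_equal(peak_score(c1), peak_score(c2))
    pd.testing.assert_frame_equal(integral_scores(c1), integral_scores(c2))


# ----------------------------------------------------------------------
# instability
# ----------------------------------------------------------------------
def test_identical_replicates_are_stable():
    base = np.tile(np.arange(6.0), (3, 1))
    exp = make_experiment({"epi": base, "ing": base}, noise_sd=0.0)
    index, flag = instability_flag(exp, quantile=0.95)
    assert np.allclose(index.to_numpy(), 0.0)
    assert not flag.any()


def test_inflated_replicate_noise_flagged():
    rng = np.random.default_rng(0)
    base = np.zeros((100, 6))
    exp = make_experiment({"epi": base, "ing": base}, noise_sd=0.2, seed=1)
    noisy_cols = exp.samples.index[exp.samples["condition"] == "epi"]
    exp.values.loc["g7", noisy_cols] += rng.normal(0, 20, size=len(noisy_cols))
    index, flag = instability_flag(exp, quantile=0.95)
    assert flag["g7"]
    assert index["g7"] == index.max()


def test_quantile_one_flags_nothing():
    exp = make_experiment({"epi": np.zeros((20, 6)), "ing": np.zeros((20, 6))},
                          noise_sd=0.3, seed=2)
    _, flag = instability_flag(exp, quantile=1.0)
    assert not flag.any()


def test_single_replicate_rejected():
    exp = make_experiment({"epi": np.zeros((5, 6)), "ing": np.zeros((5, 6))},
                          n_replicates=1)
    with pytest.raises(ValueError):
        instability_flag(exp)


# ----------------------------------------------------------------------
# significance
# ----------------------------------------------------------------------
def test_median_gene_not_significant():
    scores = pd.Series(np.arange(101, dtype=float))
    flags, p = score_significance(scores)
    assert p[50] == pytest.approx(0.5)
    assert not flags[50]


def test_three_robust_sd_outlier_significant():
    rng = np.random.default_rng(3)
    x = pd.Series(rng.normal(0, 1, 1001))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    x.iloc[0] = med + 3 * 1.4826 * mad
    flags, p = score_significance(x)
    assert p.iloc[0] == pytest.approx(stats.norm.sf(3.0), rel=1e-6)
    assert flags.iloc[0]


def test_degenerate_null_nothing_significant():
    flags, p = score_significance(pd.Series(np.full(50, 2.0)))
    assert not flags.any()
    assert (p == 1.0).all()


def test_mad_zero_falls_back_to_sd():
    # >half the genes identical -> MAD 0, SD > 0; outlier still found
    x = pd.Series(np.concatenate([np.zeros(60), np.ones(10), [50.0]]))
    flags, _ = score_significance(x)
    assert flags.iloc[-1]


def test_too_few_genes_rejected():
    with pytest.raises(ValueError):
        score_significance(pd.Series(np.arange(5.0)))


# ----------------------------------------------------------------------
# consensus and selection
# ----------------------------------------------------------------------
def _score_frame(rows):
    return pd.DataFrame(rows, columns=["dynamic", "peak", "integral", "relevance"])


def test_consensus_extremes():
    frame = _score_frame([[1, 1, 1, 1], [5, 4, 3, 2], [9, 8, 7, 6]])
    cons = consensus_scores(frame)
    assert cons.iloc[2] == pytest.approx(1.0)  # maximal in all four -> 1.000
    assert cons.iloc[0] == pytest.approx(0.0)  # minimal in all four -> 0
    two = consensus_scores(_score_frame([[1, 1, 1, 1], [2, 2, 2, 2]]))
    assert sorted(two.tolist()) == [0.0, 1.0]


def test_consensus_constant_column_convention():
    frame = _score_frame([[1, 5, 1, 3], [2, 5, 2, 3], [3, 5, 3, 3]])
    cons = consensus_scores(frame)
    assert cons.iloc[0] == 0.0 and cons.iloc[2] == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 9999), bump=st.floats(0.1, 10.0), col=st.integers(0, 3))
def test_consensus_monotone_in_any_raw_score(seed, bump, col):
    rng = np.random.default_rng(seed)
    frame = _score_frame(rng.uniform(0, 5, size=(12, 4)))
    gene = 4
    before = consensus_scores(frame)
    bumped = frame.copy()
    bumped.iloc[gene, col] += bump
    after = consensus_scores(bumped)
    rank_before = (before < before.iloc[gene]).sum()
    rank_after = (after < after.iloc[gene]).sum()
    assert rank_after >= rank_before


def test_select_candidates_matches_set_comprehension(rng):
    n = 40
    records = pd.DataFrame(
        {
            "sig_dynamic": rng.random(n) < 0.5,
            "sig_peak": rng.random(n) < 0.5,
            "sig_integral": rng.random(n) < 0.5,
            "sig_relevance": rng.random(n) < 0.5,
            "unstable": rng.random(n) < 0.2,
        },
        index=[f"g{i}" for i in range(n)],
    )
    expected = [
        g
        for g in records.index
        if records.loc[g, ["sig_dynamic", "sig_peak", "sig_integral",
                           "sig_relevance"]].all()
        and not records.loc[g, "unstable"]
    ]
    assert select_candidates(records) == expected


def test_partial_significance_or_instability_excludes():
    records = pd.DataFrame(
        {
            "sig_dynamic": [True, True],
            "sig_peak": [True, True],
            "sig_integral": [False, True],
            "sig_relevance": [True, True],
            "unstable": [False, True],
        },
        index=["three_of_four", "unstable_gene"],
    )
    assert select_candidates(records) == []


def test_upper_quartile_rule_on_137_distinct_scores():
    scores = pd.Series(np.linspace(0.01, 0.99, 137), index=[f"g{i}" for i in range(137)])
    assert len(select_top_set(scores)) == 34


def test_upper_quartile_small_example():
    scores = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
    assert set(select_top_set(scores)) == {"g", "h"}  # Q3 = 6.25, strict >


def test_upper_quartile_all_tied_selects_nothing():
    scores = pd.Series(np.full(10, 0.5))
    assert select_top_set(scores) == []


def test_fewer_than_four_candidates_returned_with_warning():
    scores = pd.Series([0.9, 0.1], index=["a", "b"])
    with pytest.warns(UserWarning):
        assert select_top_set(scores) == ["a", "b"]


# ----------------------------------------------------------------------
# model surface
# ----------------------------------------------------------------------
def test_model_fit_produces_consistent_results(rng):
    from adipodyn import SimulationConfig, generate_literature_counts, generate_timecourse

    exp, truth = generate_timecourse(
        SimulationConfig(n_genes=300, fraction_divergent=0.1, seed=33)
    )
    lit = generate_literature_counts(truth, seed=34)
    res = TimeCourseDivergence(exp, literature_counts=lit).fit()
    assert set(res.top_genes) <= set(res.candidates) <= set(exp.genes)
    assert res.scores["consensus"].max() == pytest.approx(1.0)
    assert res.scores["consensus"].is_monotonic_decreasing
    assert (res.scores[["dynamic", "peak", "relevance", "integral_whole"]] >= 0).all().all()
    text = res.summary()
    assert "candidates" in text and str(len(res.candidates)) in text
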