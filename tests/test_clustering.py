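"""Slope vectors, k-means clustering and congruence classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipodyn import (
    SlopeKMeans,
    bss_tss_profile,
    congruence_classification,
    slope_vectors,
)

from conftest import DAYS, make_curves, make_experiment


def test_slopes_exact_for_linear_profile():
    values = np.array([[0.0, 2, 4, 6, 8, 10]])
    exp = make_experiment({"epi": values, "ing": values})
    slopes = slope_vectors(exp.condition_mean_curves())
    assert np.allclose(slopes.loc[("g0", "epi")].to_numpy(), 1.0)


def test_slopes_zero_for_constant_profile():
    values = np.full((1, 6), 7.0)
    exp = make_experiment({"epi": values, "ing": values})
    slopes = slope_vectors(exp.condition_mean_curves())
    assert np.allclose(slopes.to_numpy(), 0.0)


def test_central_difference_exact_for_quadratic_interior():
    days = np.array(DAYS)
    values = (days**2)[None, :]
    exp = make_experiment({"epi": values, "ing": values})
    slopes = slope_vectors(exp.condition_mean_curves()).loc[("g0", "epi")].to_numpy()
    # interior: central differences are exact for quadratics (slope = 2*day)
    assert np.allclose(slopes[1:-1], 2 * days[1:-1])
    # endpoints: one-sided differences
    assert slopes[0] == pytest.approx((values[0, 1] - values[0, 0]) / 2.0)
    assert slopes[-1] == pytest.approx((values[0, -1] - values[0, -2]) / 2.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    slope=st.floats(-5, 5, allow_nan=False),
    intercept=st.floats(-20, 20, allow_nan=False),
)
def test_slopes_exact_for_affine_profiles(slope, intercept):
    days = np.array(DAYS)
    values = (slope * days + intercept)[None, :]
    exp = make_experiment({"epi": values, "ing": values})
    slopes = slope_vectors(exp.condition_mean_curves())
    assert np.allclose(slopes.to_numpy(), slope, atol=1e-9)


def test_duplicate_days_rejected():
    curves = make_curves(np.zeros((1, 6)))
    curves.days = np.array([-2.0, 0, 0, 4, 6, 8])
    with pytest.raises(ValueError):
        slope_vectors(curves)


# ----------------------------------------------------------------------
# k-means
# ----------------------------------------------------------------------
def _two_archetype_profiles(n_per=20, spread=0.01, seed=0):
    rng = np.random.default_rng(seed)
    up = np.full(6, 1.0)
    down = np.full(6, -1.0)
    obs = np.vstack(
        [up + rng.normal(0, spread, (n_per, 6)), down + rng.normal(0, spread, (n_per, 6))]
    )
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "epi") for i in range(2 * n_per)], names=["gene", "condition"]
    )
    return pd.DataFrame(obs, index=idx, columns=np.array(DAYS))


def test_two_separated_archetypes_recovered_perfectly():
    profiles = _two_archetype_profiles()
    fit = SlopeKMeans(profiles, k=2).fit(seed=0)
    assert fit.bss_tss > 0.99
    labels = fit.assignments.to_numpy()
    assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
    assert labels[0] != labels[-1]


def test_k_equal_to_distinct_observations_gives_bss_tss_one():
    obs = np.array([[0.0] * 6, [1.0] * 6, [2.0] * 6, [5.0] * 6])
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "epi") for i in range(4)], names=["gene", "condition"]
    )
    profiles = pd.DataFrame(obs, index=idx, columns=np.array(DAYS))
    fit = SlopeKMeans(profiles, k=4).fit(seed=0)
    assert fit.inertia == pytest.approx(0.0, abs=1e-12)
    assert fit.bss_tss == pytest.approx(1.0)


def test_same_seed_reproduces_assignments():
    profiles = _two_archetype_profiles(seed=5)
    f1 = SlopeKMeans(profiles, k=3).fit(seed=9)
    f2 = SlopeKMeans(profiles, k=3).fit(seed=9)
    pd.testing.assert_series_equal(f1.assignments, f2.assignments)
    assert f1.bss_tss == f2.bss_tss


def test_identical_observations_rejected():
    obs = np.zeros((10, 6))
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "epi") for i in range(10)], names=["gene", "condition"]
    )
    profiles = pd.DataFrame(obs, index=idx, columns=np.array(DAYS))
    with pytest.raises(ValueError, match="sum of squares"):
        SlopeKMeans(profiles, k=2).fit(seed=0)
    with pytest.raises(ValueError, match="at least k"):
        SlopeKMeans(profiles.iloc[:1], k=2)


def test_bss_tss_profile_is_nondecreasing_in_k(rng):
    obs = rng.normal(0, 1, size=(60, 6))
    idx = pd.MultiIndex.from_tuples(
        [(f"g{i}", "epi") for i in range(60)], names=["gene", "condition"]
    )
    profiles = pd.DataFrame(obs, index=idx, columns=np.array(DAYS))
    prof = bss_tss_profile(profiles, ks=range(2, 7), seed=0, n_restarts=10)
    assert (prof.diff().dropna() > -0.02).all()  # allow tiny restart noise
    assert ((prof >= 0) & (prof <= 1)).all()


# ----------------------------------------------------------------------
# congruence
# ----------------------------------------------------------------------
def _paired_profiles(assignment_pairs, seed=0):
    """Profiles engineered so k-means recovers the intended pairing."""
    rng = np.random.default_rng(seed)
    centers = {c: np.full(6, 3.0 * c) for c in {c for pair in assignment_pairs for c in pair}}
    rows, idx = [], []
    for g, (ca, cb) in enumerate(assignment_pairs):
        rows.append(centers[ca] + rng.normal(0, 0.01, 6))
        idx.append((f"g{g}", "epi"))
        rows.append(centers[cb] + rng.normal(0, 0.01, 6))
        idx.append((f"g{g}", "ing"))
    profiles = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(idx, names=["gene", "condition"]),
        columns=np.array(DAYS),
    )
    return profiles


def test_congruence_counts_match_tally_oracle():
    pairs = [(1, 1), (1, 2), (2, 2), (2, 1), (1, 1), (2, 2), (1, 2), (1, 1), (2, 2), (1, 1)]
    profiles = _paired_profiles(pairs)
    fit = SlopeKMeans(profiles, k=2).fit(seed=0)
    records, combos = congruence_classification(fit)
    n_congruent = sum(a == b for a, b in pairs)
    assert int(records["congruent"].sum()) == n_congruent
    assert int((~records["congruent"]).sum()) == len(pairs) - n_congruent
    # conservation: congruent + divergent = total genes
    assert combos["n_genes"].sum() == len(pairs)


def test_congruent_iff_same_cluster():
    fit = SlopeKMeans(_paired_profiles([(1, 1), (1, 2)]), k=2).fit(seed=0)
    records, _ = congruence_classification(fit)
    cols = [c for c in records.columns if c.startswith("cluster_")]
    same = records[cols[0]] == records[cols[1]]
    assert (records["congruent"] == same).all()


def test_congruent_partition_invariant_to_cluster_relabeling():
    """Different seeds may permute cluster ids; the congruent/divergent
    partition must not change."""
    pairs = [(1, 1), (1, 2), (2, 2), (2, 1), (1, 1), (2, 1)]
    profiles = _paired_profiles(pairs)
    parts = []
    for seed in (0, 1, 2):
        records, _ = congruence_classification(SlopeKMeans(profiles, k=2).fit(seed=seed))
        parts.append(records["congruent"].sort_index())
    pd.testing.assert_series_equal(parts[0], parts[1])
    pd.testing.assert_series_equal(parts[0], parts[2])


def test_constant_one_side_flag():
    # cluster of zero slopes = "constant" pattern; flag fires when exactly
    # one condition sits in it
    rng = np.random.default_rng(0)
    rows, idx = [], []
    pairs = [("zero", "up"), ("zero", "zero"), ("up", "up"), ("up", "zero")]
    centers = {"zero": np.zeros(6), "up": np.full(6, 2.0)}
    for g, (ca, cb) in enumerate(pairs):
        rows.append(centers[ca] + rng.normal(0, 0.005, 6))
        idx.append((f"g{g}", "epi"))
        rows.append(centers[cb] + rng.normal(0, 0.005, 6))
        idx.append((f"g{g}", "ing"))
    profiles = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(idx, names=["gene", "condition"]),
        columns=np.array(DAYS),
    )
    fit = SlopeKMeans(profiles, k=2).fit(seed=0)
    records, _ = congruence_classification(fit)
    assert records.loc["g0", "constant_one_side"]
    assert records.loc["g3", "constant_one_side"]
    assert not records.loc["g1", "constant_one_side"]
    assert not records.loc["g2", "constant_one_side"]


def test_missing_condition_rejected():
    profiles = _paired_profiles([(1, 2), (2, 1)])
    fit = SlopeKMeans(profiles, k=2).fit(seed=0)
    fit.assignments = fit.assignments.drop(("g0", "ing"))
    with pytest.raises(ValueError, match="missing"):
        congruence_classification(fit)
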