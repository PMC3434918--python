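"""MANOVA cross-products, method-of-moments components, correlations,
jackknife SEs, genotypic means and the major-axis fit."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from rhizocorr.errors import (
    DegenerateDesignError,
    DegenerateFitError,
    UnbalancedDesignError,
)
from rhizocorr.gencorr import (
    Correlation,
    CrossProducts,
    correlation_from_cov,
    crossproducts_from_stats,
    estimate_environment,
    genotypic_means,
    group_stats,
    jackknife_se,
    major_axis_fit,
    manova_crossproducts,
    mom_covariances,
    total_crossproducts,
)
from rhizocorr.io import DesignSpec
from rhizocorr.simulate import SimParams, generate_dataset, study_params

from conftest import make_frame


# ---------------------------------------------------------------------------
# independent oracles

def oracle_crossproducts(nodules, fruit, groups, k):
    """Plain-loop H and E from raw values (trait 2 = ln(fruit + 1))."""
    y = np.column_stack([np.asarray(nodules, float),
                         np.log1p(np.asarray(fruit, float))])
    labels = sorted(set(groups))
    means = np.array([y[[g == lab for g in groups]].mean(axis=0) for lab in labels])
    grand = means.mean(axis=0)
    H = np.zeros((2, 2))
    for m in means:
        d = m - grand
        H += k * np.outer(d, d)
    E = np.zeros((2, 2))
    for lab, m in zip(labels, means):
        for row in y[[g == lab for g in groups]]:
            d = row - m
            E += np.outer(d, d)
    return H, E


def _random_balanced_frame(rng, g=4, k=3):
    assoc = [(f"G{i}", "b") for i in range(g)]
    groups = [a for a in assoc for _ in range(k)]
    nod = rng.integers(0, 120, size=g * k)
    fruit = rng.integers(0, 40, size=g * k)
    return make_frame(nod, fruit, groups), nod, fruit, groups


# ---------------------------------------------------------------------------
# cross-products

def test_hand_computed_two_group_example():
    """Two associations x two replicates with group means (0, 0) and
    (2, ln 7): H follows the k * outer-product identity, E = 0."""
    df = make_frame([0, 0, 2, 2], [0, 0, 6, 6],
                    [("A", "b"), ("A", "b"), ("B", "b"), ("B", "b")])
    cp = manova_crossproducts(df)
    b = np.log(7.0)
    expected_H = np.array([[4.0, 2 * b], [2 * b, b * b]])
    assert np.allclose(cp.H, expected_H, atol=1e-12)
    assert np.allclose(cp.E, 0.0, atol=1e-12)
    assert cp.H[0, 0] == pytest.approx(4.0)  # nodule trait alone
    assert (cp.g, cp.k) == (2, 2)


def test_identical_observations_give_zero_matrices():
    df = make_frame([5, 5, 5, 5], [3, 3, 3, 3],
                    [("A", "b"), ("A", "b"), ("B", "b"), ("B", "b")])
    cp = manova_crossproducts(df)
    assert np.allclose(cp.H, 0) and np.allclose(cp.E, 0)


def test_crossproducts_match_plain_loop_oracle_and_conserve_total():
    rng = np.random.default_rng(0)
    for _ in range(25):
        df, nod, fruit, groups = _random_balanced_frame(rng)
        cp = manova_crossproducts(df)
        H, E = oracle_crossproducts(nod, fruit, groups, k=3)
        assert np.allclose(cp.H, H, rtol=1e-10, atol=1e-9)
        assert np.allclose(cp.E, E, rtol=1e-10, atol=1e-9)
        total = total_crossproducts(df)
        assert np.allclose(cp.H + cp.E, total, rtol=1e-10, atol=1e-9)


def test_unbalanced_groups_refused():
    df = make_frame([1, 2, 3, 4, 5], [1, 1, 1, 1, 1],
                    [("A", "b")] * 3 + [("B", "b")] * 2)
    with pytest.raises(UnbalancedDesignError):
        manova_crossproducts(df)


@pytest.mark.parametrize("g, k", [(1, 3), (3, 1)])
def test_degenerate_design_refused(g, k):
    groups = [(f"G{i}", "b") for i in range(g) for _ in range(k)]
    df = make_frame(range(g * k), [1] * (g * k), groups)
    with pytest.raises(DegenerateDesignError):
        manova_crossproducts(df)


# ---------------------------------------------------------------------------
# method of moments

def test_mom_inverts_the_defining_identities_exactly():
    g, k = 12, 5
    A = np.array([[1.0, 0.5], [0.5, 1.0]])
    B = np.eye(2)
    cp = CrossProducts(H=(g - 1) * (k * A + B), E=g * (k - 1) * B, g=g, k=k)
    est = mom_covariances(cp)
    assert np.allclose(est.cov_E, B, atol=1e-14)
    assert np.allclose(est.cov_G, A, atol=1e-14)
    assert est.negative_variance_flags == (False, False)


def test_mom_flags_negative_genetic_variances():
    g, k = 12, 5
    B = np.eye(2)
    cp = CrossProducts(H=np.zeros((2, 2)), E=g * (k - 1) * B, g=g, k=k)
    est = mom_covariances(cp)
    assert np.allclose(est.cov_G, -B / k)
    assert est.negative_variance_flags == (True, True)


def test_mom_consistency_large_simulation():
    """g = 2000 associations from known covariances: cov_G entrywise within
    10% of the generative matrix."""
    A = np.array([[900.0, 10.8], [10.8, 0.36]])
    B = np.array([[1936.0, 1.9712], [1.9712, 0.3136]])
    params = SimParams(
        design=DesignSpec(n_genotypes=1000, n_mixes=2, include_control=False,
                          n_soils=1, k=5),
        mu_by_env={"control": (110.0, 3.0)},
        cov_G_by_env={"control": A},
        cov_E=B,
        seed=8,
    )
    _, latent = generate_dataset(params, return_latent=True)
    stats = group_stats_from_latent(latent)
    est = mom_covariances(crossproducts_from_stats(stats))
    assert np.allclose(est.cov_G, A, rtol=0.10)
    assert np.allclose(est.cov_E, B, rtol=0.10)


def group_stats_from_latent(latent):
    """Build GroupStats from the pre-rounding latent values (test helper:
    keeps moment assertions free of rounding bias)."""
    from rhizocorr.gencorr import GroupStats

    grouped = latent.groupby(["medicago_genotype", "rhizobium_mix"], sort=True)
    labels, means, within = [], [], []
    for lab, block in grouped:
        y = block[["latent_nodules", "latent_ln_fruit"]].to_numpy()
        m = y.mean(axis=0)
        dev = y - m
        labels.append(":".join(lab))
        means.append(m)
        within.append(dev.T @ dev)
    k = len(latent) // len(labels)
    return GroupStats(labels=tuple(labels), means=np.array(means),
                      within_sscp=np.array(within), k=k)


def test_large_k_limit_recovers_genotypic_value_covariance():
    """As k grows with the genotypic values held fixed, cov_G converges to
    the sample covariance of those values (latent debug data)."""
    params = SimParams(
        design=DesignSpec(n_genotypes=6, n_mixes=2, include_control=False,
                          n_soils=1, k=4000),
        mu_by_env={"control": (110.0, 3.0)},
        cov_G_by_env={"control": np.array([[900.0, 10.8], [10.8, 0.36]])},
        cov_E=np.array([[1936.0, 1.9712], [1.9712, 0.3136]]),
        seed=9,
    )
    _, latent = generate_dataset(params, return_latent=True)
    genovals = (
        latent.groupby(["medicago_genotype", "rhizobium_mix"], sort=True)[
            ["geno_nodules", "geno_ln_fruit"]
        ]
        .first()
        .to_numpy()
    )
    est = mom_covariances(
        crossproducts_from_stats(group_stats_from_latent(latent))
    )
    assert np.allclose(est.cov_G, np.cov(genovals.T), rtol=0.05)


def test_cov_g_offdiagonal_equals_group_mean_covariance_route(study_dataset):
    """Independent route: off-diagonal cov_G equals the sample covariance of
    association means minus cov_E off-diagonal / k, to 1e-10."""
    for env in ("control", "carvacrol"):
        sub = study_dataset[study_dataset["soil_treatment"] == env]
        stats = group_stats(sub)
        est = mom_covariances(crossproducts_from_stats(stats))
        means_cov = np.cov(stats.means.T, ddof=1)
        expected = means_cov[0, 1] - est.cov_E[0, 1] / stats.k
        assert est.cov_G[0, 1] == pytest.approx(expected, rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# correlations

@pytest.mark.parametrize("cov, expected", [
    (np.array([[4.0, 2.0], [2.0, 4.0]]), 0.5),
    (np.eye(2), 0.0),
])
def test_correlation_from_cov_values(cov, expected):
    res = correlation_from_cov(cov)
    assert res.defined and res.value == pytest.approx(expected)


def test_correlation_undefined_for_negative_variance():
    res = correlation_from_cov(np.array([[-0.1, 0.3], [0.3, 2.0]]))
    assert not res.defined
    assert "nodules" in res.reason


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_environmental_correlation_bounded(seed):
    """|r_E| <= 1 on any input: Cov_E is a rescaled PSD residual matrix."""
    rng = np.random.default_rng(seed)
    df, *_ = _random_balanced_frame(rng, g=int(rng.integers(2, 7)),
                                    k=int(rng.integers(2, 5)))
    est = mom_covariances(manova_crossproducts(df))
    r = correlation_from_cov(est.cov_E)
    if r.defined:
        assert abs(r.value) <= 1 + 1e-12


# ---------------------------------------------------------------------------
# jackknife

def test_jackknife_identical_groups_has_zero_se():
    """Replicated identical blocks: every leave-one-out replicate equals the
    full estimate, so the SE is exactly zero (r_E; r_G is undefined because
    H = 0 forces negative moment variances, and is flagged as such)."""
    block_nod, block_fruit = [10, 30, 50], [2, 8, 20]
    groups, nod, fruit = [], [], []
    for i in range(4):
        groups += [(f"G{i}", "b")] * 3
        nod += block_nod
        fruit += block_fruit
    df = make_frame(nod, fruit, groups)
    jk = jackknife_se(group_stats(df), "r_E")
    assert jk.point.defined
    assert jk.se == pytest.approx(0.0, abs=1e-12)
    assert len(set(round(r, 12) for r in jk.replicates)) == 1

    jk_g = jackknife_se(group_stats(df), "r_G")
    assert not jk_g.point.defined


def test_jackknife_matches_hand_unrolled_three_groups():
    rng = np.random.default_rng(4)
    g, k = 3, 4
    groups = [(f"G{i}", "b") for i in range(g) for _ in range(k)]
    nod = rng.integers(10, 200, size=g * k)
    fruit = rng.integers(1, 50, size=g * k)
    df = make_frame(nod, fruit, groups)

    jk = jackknife_se(group_stats(df), "r_E")

    # unroll the three leave-one-out fits with the plain-loop oracle
    labels = [f"G{i}:b" for i in range(g)]
    reps = []
    for left_out in labels:
        keep_mask = [f"{a}:{b}" != left_out for a, b in groups]
        H, E = oracle_crossproducts(
            np.asarray(nod)[keep_mask], np.asarray(fruit)[keep_mask],
            [f"{a}:{b}" for (a, b), m in zip(groups, keep_mask) if m], k)
        cov_E = E / ((g - 1) * (k - 1))
        reps.append(cov_E[0, 1] / np.sqrt(cov_E[0, 0] * cov_E[1, 1]))
    reps = np.array(reps)
    se = np.sqrt((g - 1) / g * ((reps - reps.mean()) ** 2).sum())
    assert np.allclose(sorted(jk.replicates), sorted(reps), rtol=1e-10)
    assert jk.se == pytest.approx(se, rel=1e-10)


def test_jackknife_needs_three_groups():
    df = make_frame([1, 2, 3, 4], [1, 2, 3, 4],
                    [("A", "b"), ("A", "b"), ("B", "b"), ("B", "b")])
    with pytest.raises(DegenerateDesignError):
        jackknife_se(group_stats(df), "r_G")


# ---------------------------------------------------------------------------
# genotypic means and major axis

def test_genotypic_means_match_brute_force(study_dataset):
    sub = study_dataset[study_dataset["soil_treatment"] == "carvacrol"]
    means = genotypic_means(sub)
    assert len(means) == 12
    inoc = sub[sub["rhizobium_mix"] != "control"]
    for _, row in means.iterrows():
        geno, mix = row["association"].split(":")
        block = inoc[(inoc["medicago_genotype"] == geno)
                     & (inoc["rhizobium_mix"] == mix)]
        assert row["mean_nodules"] == pytest.approx(block["nodule_count"].mean())
        assert row["mean_ln_fruit"] == pytest.approx(
            np.log1p(block["fruit_count"]).mean())


def test_major_axis_exact_line():
    x = np.array([0.0, 1.0, 2.0, 5.0])
    slope, intercept = major_axis_fit(np.column_stack([x, 2 * x + 1]))
    assert slope == pytest.approx(2.0, abs=1e-10)
    assert intercept == pytest.approx(1.0, abs=1e-10)


def test_major_axis_degenerate_contracts():
    with pytest.raises(DegenerateFitError):
        major_axis_fit(np.array([[1.0, 1.0]] * 5))       # identical points
    circle = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
    with pytest.raises(DegenerateFitError):
        major_axis_fit(circle)                            # eigenvalue tie


def test_major_axis_matches_rotation_construction():
    """An axis-aligned anisotropic cloud rotated by a known angle has a major
    axis of slope tan(theta)."""
    rng = np.random.default_rng(12)
    theta = 0.4
    base = np.column_stack([rng.normal(0, 5, 4000), rng.normal(0, 0.5, 4000)])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    slope, _ = major_axis_fit(base @ rot.T)
    assert slope == pytest.approx(np.tan(theta), abs=0.02)


# ---------------------------------------------------------------------------
# per-environment composition

def test_estimate_environment_table_row(study_dataset):
    results = [estimate_environment(study_dataset, env)
               for env in ("control", "carvacrol")]
    assert [r.n for r in results] == [12, 12]
    for res in results:
        assert res.r_E.defined and abs(res.r_E.value) <= 1
        assert len(res.jackknife_replicates["r_G"]) == 12
        assert res.diagnostics["k"] == 5


def test_zero_generative_covariance_gives_near_zero_r_g():
    """Huge g with a diagonal genetic covariance: r_G-hat converges to 0."""
    params = SimParams(
        design=DesignSpec(n_genotypes=500, n_mixes=2, include_control=False,
                          n_soils=1, k=5),
        mu_by_env={"control": (110.0, 3.0)},
        cov_G_by_env={"control": np.diag([900.0, 0.36])},
        cov_E=np.array([[1936.0, 1.9712], [1.9712, 0.3136]]),
        seed=21,
    )
    df = generate_dataset(params)
    stats = group_stats(df)
    est = mom_covariances(crossproducts_from_stats(stats))
    r = correlation_from_cov(est.cov_G)
    assert r.defined and abs(r.value) < 0.08
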