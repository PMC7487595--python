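"""Likelihood construction: partition, observation matrix, Eq.-style log-likelihood,
theta profiling and low-dimensional ML."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvsmis import (
    CovariateMatrix,
    ModelData,
    ProfileError,
    SelfReportPanel,
    TestAccuracy,
    build_partition,
    fit_ml,
    log_likelihood,
    observation_matrix,
    profile_theta,
)
from bvsmis.simulate import (
    SimulationDesign,
    apply_ntfp,
    baseline_hazard_from_cir,
    generate_continuous_matrix,
    generate_dataset,
    simulate_event_times,
    simulate_self_reports,
)

from conftest import DIABETES_SELF_REPORT, random_instance, simulated_instance


# ---------------------------------------------------------------- partition

def test_partition_pools_distinct_sorted_times():
    panels = [
        SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1]),
        SelfReportPanel("b", [2, 4, 6, 8], [0, 0, 0, 0]),
    ]
    part = build_partition(panels)
    assert np.array_equal(part.tau, [2, 4, 6, 8])
    assert part.J == 4 and part.n_intervals == 5

    mixed = [SelfReportPanel("a", [1, 3], [0, 0]), SelfReportPanel("b", [2, 3], [0, 1])]
    assert np.array_equal(build_partition(mixed).tau, [1, 2, 3])


def test_partition_rejects_bad_inputs():
    with pytest.raises(ValueError, match="no panels|no visits"):
        build_partition([])
    with pytest.raises(ValueError, match="> 0"):
        SelfReportPanel("a", [0.0, 2.0], [0, 1])  # enrollment visit at t=0 disallowed
    with pytest.raises(ValueError, match="finite|> 0"):
        SelfReportPanel("a", [np.inf], [0])
    with pytest.raises(ValueError, match="strictly increasing"):
        SelfReportPanel("a", [2.0, 2.0], [0, 1])


# ------------------------------------------------------- observation matrix

def brute_force_row(visit_pos, results, n_intervals, acc):
    """Direct enumeration: per interval hypothesis, classify each visit as pre/post."""
    row = np.empty(n_intervals)
    for j in range(1, n_intervals + 1):  # hypothesis: event in interval j (1-based)
        prob = 1.0
        for pos, r in zip(visit_pos, results):  # pos: 1-based index of the visit time
            if pos <= j - 1:  # strictly before the event interval
                prob *= (1 - acc.specificity) if r == 1 else acc.specificity
            else:  # at or after the right endpoint of the interval
                prob *= acc.sensitivity if r == 1 else (1 - acc.sensitivity)
        row[j - 1] = prob
    return row


def test_perfect_test_row_is_interval_indicator():
    panels = [SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1])]
    obs = observation_matrix(panels, build_partition(panels), TestAccuracy(1, 1))
    # last negative at 4, first positive at 6 -> event in (4, 6]
    assert np.array_equal(obs.raw[0], [0, 0, 1, 0, 0])


def test_error_prone_row_matches_brute_force_enumeration():
    panels = [SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1])]
    obs = observation_matrix(panels, build_partition(panels), DIABETES_SELF_REPORT)
    expected = brute_force_row([1, 2, 3, 4], [0, 0, 1, 1], 5, DIABETES_SELF_REPORT)
    assert obs.raw[0][2] == pytest.approx(0.995**2 * 0.61**2, abs=1e-15)
    np.testing.assert_allclose(obs.raw[0], expected, rtol=0, atol=1e-14)


def test_observation_rows_match_brute_force_on_random_panels():
    rng = np.random.default_rng(7)
    for _ in range(50):
        panels, part, acc, obs, *_ = random_instance(rng, n=8)
        for i, panel in enumerate(panels):
            pos = np.searchsorted(part.tau, panel.times) + 1
            expected = brute_force_row(pos, panel.results, part.n_intervals, acc)
            np.testing.assert_allclose(obs.raw[i], expected, atol=1e-13)


def test_zero_visit_subject_has_all_ones_row():
    panels = [
        SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1]),
        SelfReportPanel("b", [], []),
    ]
    obs = observation_matrix(panels, build_partition(panels), DIABETES_SELF_REPORT)
    assert np.array_equal(obs.raw[1], np.ones(5))
    assert np.array_equal(obs.differenced[1], [1, 0, 0, 0, 0])


def test_visit_off_grid_is_rejected():
    panels = [SelfReportPanel("a", [2, 4], [0, 1])]
    part = build_partition(panels)
    stray = [SelfReportPanel("b", [3.0], [1])]
    with pytest.raises(ValueError, match="grid"):
        observation_matrix(stray, part, TestAccuracy(1, 1))


def test_accuracy_outside_unit_interval_rejected():
    for bad in [(0.0, 1.0), (1.0, 0.0), (1.2, 1.0), (1.0, -0.1)]:
        with pytest.raises(ValueError):
            TestAccuracy(*bad)


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_observation_matrix_invariants(seed):
    """Entries in [0, 1]; differenced rows telescope to the last raw entry."""
    rng = np.random.default_rng(seed)
    _, _, _, obs, *_ = random_instance(rng, n=6)
    assert np.all(obs.raw >= 0) and np.all(obs.raw <= 1)
    np.testing.assert_allclose(obs.differenced.sum(axis=1), obs.raw[:, -1], atol=1e-12)


def test_marginalizing_an_extra_visit_conserves_probability():
    """Summing D rows over both outcomes of an added visit recovers the original row."""
    rng = np.random.default_rng(3)
    base = SelfReportPanel("a", [2.0, 6.0], [0, 1])
    others = [SelfReportPanel("b", [2.0, 4.0, 6.0], [0, 0, 0])]  # puts 4.0 on the grid
    part = build_partition([base] + others)
    acc = TestAccuracy(0.7, 0.9)
    row_without = observation_matrix([base], part, acc).raw[0]
    rows = [
        observation_matrix(
            [SelfReportPanel("a", [2.0, 4.0, 6.0], [0, r, 1])], part, acc
        ).raw[0]
        for r in (0, 1)
    ]
    np.testing.assert_allclose(rows[0] + rows[1], row_without, atol=1e-12)


# ----------------------------------------------------------- log-likelihood

def differenced_form(theta, beta, Z, obs):
    """Independent implementation via C_ij (sum_{k>=j} theta_k)^{h_i}."""
    h = np.exp(Z @ beta)
    G = np.cumsum(theta[::-1])[::-1]  # G_j = sum_{k>=j} theta_k
    L = (obs.differenced * G[None, :] ** h[:, None]).sum(axis=1)
    return np.log(L).sum()


def test_single_subject_unit_hazard_reduces_to_theta_mass():
    panels = [SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1])]
    obs = observation_matrix(panels, build_partition(panels), TestAccuracy(1, 1))
    theta = np.full(5, 0.2)
    ll = log_likelihood(theta, np.zeros(1), np.zeros((1, 1)), obs)
    assert ll == pytest.approx(np.log(0.2), abs=1e-12)


def test_raw_and_differenced_forms_agree_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(100):
        _, _, _, obs, Z, beta, theta = random_instance(rng)
        ll = log_likelihood(theta, beta, Z, obs)
        assert ll == pytest.approx(differenced_form(theta, beta, Z, obs), abs=1e-10)


def test_subject_permutation_leaves_loglik_unchanged():
    rng = np.random.default_rng(5)
    _, _, _, obs, Z, beta, theta = random_instance(rng)
    perm = rng.permutation(Z.shape[0])
    from bvsmis import ObservationMatrix

    ll = log_likelihood(theta, beta, Z, obs)
    ll_perm = log_likelihood(theta, beta, Z[perm], ObservationMatrix(obs.raw[perm], obs.accuracy))
    assert ll == pytest.approx(ll_perm, abs=1e-9)


def test_impossible_observation_under_perfect_test_gives_minus_inf():
    panels = [SelfReportPanel("a", [2.0, 4.0], [1, 0])]  # negative after positive
    obs = observation_matrix(panels, build_partition(panels), TestAccuracy(1, 1))
    theta = np.full(3, 1 / 3)
    assert log_likelihood(theta, np.zeros(1), np.zeros((1, 1)), obs) == -np.inf


def test_perfect_test_equals_textbook_grouped_ph_likelihood():
    """With phi = (1,1) on NTFP panels the likelihood is the classic interval-censored
    grouped proportional-hazards one: S(tau_L)^h - S(tau_R)^h."""
    design = SimulationDesign(n=10, P=2, n_true=1, cir=0.4, accuracy=TestAccuracy(1, 1))
    ds = generate_dataset(design, 99)
    panels = [apply_ntfp(p) for p in ds.panels]
    part = build_partition(panels)
    obs = observation_matrix(panels, part, TestAccuracy(1, 1))
    rng = np.random.default_rng(2)
    theta = rng.dirichlet(np.ones(part.n_intervals))
    beta = rng.normal(0, 0.5, 2)
    h = np.exp(ds.Z.values[:, :2] @ beta)
    S = np.concatenate([[1.0], 1.0 - np.cumsum(theta)])  # S_0..S_{J+1}; S at tau_j
    ref = 0.0
    for i, p in enumerate(panels):
        pos = np.searchsorted(part.tau, p.times) + 1  # 1-based grid indices
        if p.results.sum() == 0:  # right-censored after last (negative) visit
            left = pos[-1]
            ref += np.log(S[left] ** h[i])
        else:  # event bracketed by last negative and first positive
            first_pos = pos[np.argmax(p.results == 1)]
            left = pos[p.results == 0][-1] if (p.results == 0).any() else 0
            ref += np.log(S[left] ** h[i] - S[first_pos] ** h[i])
    ll = log_likelihood(theta, beta, ds.Z.values[:, :2], obs)
    assert ll == pytest.approx(ref, abs=1e-9)


# ------------------------------------------------------------ profile_theta

def test_profile_at_null_beta_is_multinomial_mle():
    """Perfect tests, beta = 0: theta_hat_j = n_j / N in closed form."""
    rng = np.random.default_rng(0)
    design = SimulationDesign(n=60, P=3, n_true=0, cir=0.5, accuracy=TestAccuracy(1, 1))
    ds = generate_dataset(design, 17)
    panels = [apply_ntfp(p) for p in ds.panels]
    part = build_partition(panels)
    obs = observation_matrix(panels, part, TestAccuracy(1, 1))
    counts = obs.raw.sum(axis=0)  # with a perfect test each row is an indicator
    theta, ll = profile_theta(np.zeros(3), ds.Z.values[:, :3], obs)
    np.testing.assert_allclose(theta, counts / counts.sum(), atol=1e-6)
    expected_ll = np.sum(counts[counts > 0] * np.log(counts[counts > 0] / len(panels)))
    assert ll == pytest.approx(expected_ll, abs=1e-8)


def test_profile_single_subject_concentrates_on_event_interval():
    panels = [SelfReportPanel("a", [2, 4, 6, 8], [0, 0, 1, 1])]
    obs = observation_matrix(panels, build_partition(panels), TestAccuracy(1, 1))
    theta, ll = profile_theta(np.zeros(1), np.zeros((1, 1)), obs)
    assert theta[2] > 1 - 1e-6
    assert -1e-6 < ll <= 0


def test_profile_beats_random_simplex_search():
    """On instances from the generative regime, the profiled theta dominates random
    simplex points and local perturbations (the profiler is a local method; see the
    methods note on adversarial unstructured instances)."""
    rng = np.random.default_rng(21)
    for _ in range(10):
        _, part, obs, Z, beta = simulated_instance(rng)
        theta_star, ll_star = profile_theta(beta, Z, obs)
        assert theta_star.sum() == pytest.approx(1.0, abs=1e-10)
        M = part.n_intervals
        for cand in rng.dirichlet(np.ones(M), size=100):
            cand = np.maximum(cand, 1e-12)
            cand /= cand.sum()
            assert ll_star >= log_likelihood(cand, beta, Z, obs) - 1e-9
        for _ in range(25):
            pert = theta_star * np.exp(rng.normal(0, 0.05, M))
            pert /= pert.sum()
            assert ll_star >= log_likelihood(pert, beta, Z, obs) - 1e-9


def test_profile_failure_raises():
    # impossible data: perfect test, negative after positive
    panels = [SelfReportPanel("a", [2.0, 4.0], [1, 0])]
    obs = observation_matrix(panels, build_partition(panels), TestAccuracy(1, 1))
    with pytest.raises(ProfileError):
        profile_theta(np.zeros(1), np.zeros((1, 1)), obs)


# --------------------------------------------------------------- covariates

def test_standardization_contract():
    rng = np.random.default_rng(4)
    Z = CovariateMatrix(rng.integers(0, 3, size=(200, 5)).astype(float)).standardized()
    np.testing.assert_allclose(Z.values.mean(axis=0), 0, atol=1e-8)
    np.testing.assert_allclose(Z.values.std(axis=0, ddof=1), 1, atol=1e-8)


def test_constant_column_rejected():
    Z = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="constant"):
        CovariateMatrix(Z).standardized()


# ------------------------------------------------------------------- fit_ml

def test_fit_ml_requires_low_dimension():
    design = SimulationDesign(n=30, P=25, n_true=0, cir=0.3)
    ds = generate_dataset(design, 3)
    with pytest.raises(ValueError, match="at most"):
        fit_ml(ds.panels, ds.Z, TestAccuracy(1, 1))


def test_fit_ml_recovers_effect_and_matches_loglik():
    acc = DIABETES_SELF_REPORT
    lam0 = baseline_hazard_from_cir(0.3, 8.0)
    rng = np.random.default_rng(42)
    Z = generate_continuous_matrix(1500, 1, rng)
    x = simulate_event_times(Z.values, [0], 1.0, lam0, rng)
    panels = simulate_self_reports(x, (2.0, 4.0, 6.0, 8.0), acc, rng)
    fit = fit_ml(panels, Z, acc)
    assert fit.converged
    assert abs(fit.beta[0] - 1.0) < 3 * fit.se[0]
    assert fit.p_values[0] < 1e-6
    # the reported maximum is a genuine log-likelihood value of the model
    part = build_partition(panels)
    obs = observation_matrix(panels, part, acc)
    assert fit.loglik == pytest.approx(
        log_likelihood(fit.theta, fit.beta, Z.values, obs), abs=1e-6
    )
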