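import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    oracle_composite_loglik,
    oracle_pln_pmf,
    oracle_resight_prob,
)
from zipne.data_model import EncounterData, ModelSpec, ParameterSet
from zipne.likelihood import (
    composite_loglik,
    ht_mark_estimate,
    marked_loglik_across,
    marked_loglik_within,
    pln_marginal_pmf,
    pln_moments,
    resight_prob,
    state_vectors,
    transition_matrix,
    unidentified_loglik,
    unmarked_loglik,
)
from zipne.quadrature import gh_rule


# ---------------------------------------------------------------------------
# Marginal pmf and moments
# ---------------------------------------------------------------------------

def test_pln_pmf_special_cases(rule101):
    # sigma=0 reduces to an exact Poisson mass
    assert pln_marginal_pmf(0, np.log(2.0), 0.0, 0.5, rule101) == pytest.approx(
        np.exp(-1.0), abs=1e-12
    )
    # r=0: no identifications, point mass at zero
    assert pln_marginal_pmf(0, 1.0, 0.4, 0.0, rule101) == pytest.approx(1.0)
    assert pln_marginal_pmf(3, 1.0, 0.4, 0.0, rule101) == 0.0


def test_pln_pmf_normalises(rule101):
    ys = np.arange(201)
    total = pln_marginal_pmf(ys, np.log(5.0), 0.427, 0.9, rule101).sum()
    assert total == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("y", [0, 1, 2, 7])
def test_pln_pmf_matches_fine_grid_integration(y, rule101):
    got = pln_marginal_pmf(y, 1.51828, 0.42699, 0.9, rule101)
    want = oracle_pln_pmf(y, 1.51828, 0.42699, 0.9)
    assert got == pytest.approx(want, rel=1e-8)


def test_moments_limits():
    lam_bar, eta, kappa = pln_moments(1.2, 0.0, 0.7)
    assert eta == pytest.approx(lam_bar)          # Poisson limit at sigma=0
    _, _, kappa1 = pln_moments(1.2, 0.5, 1.0)
    assert kappa1 == pytest.approx(0.0, abs=1e-14)  # r=1: no unidentified marks
    lam_bar2, eta2, _ = pln_moments(0.3, 0.8, 0.5)
    assert eta2 >= lam_bar2


# ---------------------------------------------------------------------------
# State model structure
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=50)
@given(
    w=st.floats(0, 1), g=st.floats(0, 1), phi=st.floats(0, 1),
    gp=st.floats(0, 1), gpp=st.floats(0, 1),
)
def test_state_model_is_stochastic(w, g, phi, gp, gpp):
    ps = ParameterSet.constant(2, w=w, g=g, phi=phi, gammaP=gp, gammaPP=gpp)
    entry = state_vectors(ps)
    assert entry.shape == (2, 3)
    assert np.all(entry >= -1e-12)
    assert entry.sum(axis=1) == pytest.approx([1.0, 1.0])
    G = transition_matrix(ps, 1)
    assert np.all((G >= -1e-12) & (G <= 1 + 1e-12))
    assert G.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])


def test_single_occasion_reduces_to_state3_emission(rule101):
    data = EncounterData(T=1, y=[[0]], b=[1], e=[0], u=[1], R=[1],
                         n_known=[True], n=[1])
    ps = ParameterSet.constant(1, alpha=0.4, sigma=0.5, r=0.8, w=1.0, g=1.0, U=5.0)
    got = marked_loglik_within(data, ps, rule101)
    want = np.log(pln_marginal_pmf(0, 0.4, 0.5, 0.8, rule101))
    assert got == pytest.approx(want, rel=1e-12)


def test_positive_entry_count_kills_dead_and_off_states(rule101, micro):
    # zeroing the w-vector mass on states 1-2 must not change the likelihood
    data, ps = micro["m3_t3"]
    base = marked_loglik_within(data, ps, rule101)
    # individual 0 was sighted at entry; collapse entry to state 3 for it only
    only3 = ParameterSet(**{**{f: getattr(ps, f) for f in
                               ("alpha", "sigma", "r", "phi", "gammaPP", "gammaP", "U")},
                            "w": np.ones(data.T), "g": np.ones(data.T)})
    sighted_at_entry = data.y[np.arange(data.M_T), data.b - 1] > 0
    sub_seen = EncounterData(T=3, y=data.y[sighted_at_entry],
                             b=data.b[sighted_at_entry],
                             e=data.e, u=data.u,
                             R=np.bincount(data.b[sighted_at_entry], minlength=4)[1:],
                             n_known=data.n_known, n=[1, 0, 0])
    lik_w = marked_loglik_within(sub_seen, ps, rule101)
    lik_3 = marked_loglik_within(sub_seen, only3, rule101)
    # entry-occasion sighting forces state 3: only the w*g entry mass differs
    for s in range(sub_seen.M_T):
        b = sub_seen.b[s]
        lik_w -= np.log(ps.w[b - 1] * ps.g[b - 1])
    assert lik_w == pytest.approx(lik_3, rel=1e-10)
    assert base < 0.0  # full data includes an all-zero history


def test_zero_inflation_limit_equals_plain_product(rule101):
    # w=g=1, phi=1, gamma''=0: everyone stays in state 3, so the history is
    # an independent product of marginal masses
    data = EncounterData(T=3, y=[[1, 0, 2], [0, 1, 0]], b=[1, 1], e=[0, 0, 0],
                         u=[5, 4, 3], R=[2, 0, 0],
                         n_known=[True, False, False], n=[2, 0, 0])
    ps = ParameterSet.constant(3, alpha=0.2, sigma=0.4, r=0.9, w=1.0, g=1.0,
                               phi=1.0, gammaPP=0.0, gammaP=0.0, U=10.0)
    got = marked_loglik_within(data, ps, rule101)
    want = sum(
        np.log(pln_marginal_pmf(int(y), 0.2, 0.4, 0.9, rule101))
        for y in data.y.ravel()
    )
    assert got == pytest.approx(want, rel=1e-10)


def test_within_equals_across_without_heterogeneity(rule101, micro):
    for name, (data, ps) in micro.items():
        ps0 = ParameterSet(**{**ps.to_dict(), "sigma": np.zeros(data.T)})
        a = marked_loglik_within(data, ps0, rule101)
        b = marked_loglik_across(data, ps0, rule101)
        assert a == pytest.approx(b, rel=1e-12), name


def test_all_zero_history_bounded_by_dead_mass(rule101):
    data = EncounterData(T=2, y=[[0, 0]], b=[1], e=[0, 0], u=[1, 1], R=[1, 0],
                         n_known=[False, False], n=[0, 0])
    ps = ParameterSet.constant(2, alpha=1.0, sigma=0.3, r=0.9, w=0.7, g=0.8,
                               phi=0.9, gammaPP=0.1, gammaP=0.1, U=5.0)
    lik = np.exp(marked_loglik_across(data, ps, rule101))
    assert lik >= (1.0 - 0.7) - 1e-12


# ---------------------------------------------------------------------------
# Detection probability and Horvitz-Thompson
# ---------------------------------------------------------------------------

def test_ht_estimate_arithmetic(rule101):
    y = np.zeros((10, 1), dtype=int)
    y[:7, 0] = 1
    data = EncounterData(T=1, y=y, b=np.ones(10, int), e=[0], u=[0], R=[10],
                         n_known=[False], n=[0])
    # enormous sighting rate: p ~ 1
    ps = ParameterSet.constant(1, alpha=5.0, sigma=0.0, r=1.0, U=1.0)
    assert ht_mark_estimate(data, 1, ps, rule101) == pytest.approx(7.0, rel=1e-6)
    # p = 0.5 exactly: alpha chosen so exp(-lambda r) = 0.5
    y[:, 0] = 0
    y[:4, 0] = 2
    data2 = EncounterData(T=1, y=y, b=np.ones(10, int), e=[0], u=[0], R=[10],
                          n_known=[False], n=[0])
    lam = np.log(2.0)
    ps2 = ParameterSet.constant(1, alpha=np.log(lam), sigma=0.0, r=1.0, U=1.0)
    assert resight_prob(1, ps2, rule101) == pytest.approx(0.5, rel=1e-10)
    assert ht_mark_estimate(data2, 1, ps2, rule101) == pytest.approx(8.0, rel=1e-8)
    # known occasions short-circuit
    data3 = EncounterData(T=1, y=y, b=np.ones(10, int), e=[0], u=[0], R=[10],
                          n_known=[True], n=[9])
    assert ht_mark_estimate(data3, 1, ps2, rule101) == 9.0


def test_ht_errors_when_detection_vanishes(rule101):
    data = EncounterData(T=1, y=[[0]], b=[1], e=[0], u=[0], R=[1],
                         n_known=[False], n=[0])
    ps = ParameterSet.constant(1, alpha=-40.0, sigma=0.0, r=0.5, U=1.0)
    with pytest.raises(FloatingPointError, match="numerically zero"):
        ht_mark_estimate(data, 1, ps, rule101)


@settings(derandomize=True, max_examples=40)
@given(a=st.floats(-2, 2), da=st.floats(0.01, 1.5),
       r=st.floats(0.05, 0.95), dr=st.floats(0.01, 0.05))
def test_resight_prob_monotone(a, da, r, dr):
    rule = gh_rule(31)
    p1 = resight_prob(1, ParameterSet.constant(1, alpha=a, sigma=0.4, r=r, U=1.0), rule)
    p2 = resight_prob(1, ParameterSet.constant(1, alpha=a + da, sigma=0.4, r=r, U=1.0), rule)
    p3 = resight_prob(1, ParameterSet.constant(1, alpha=a, sigma=0.4, r=r + dr, U=1.0), rule)
    assert p2 >= p1 - 1e-12
    assert p3 >= p1 - 1e-12


def test_ht_tracks_true_marks_on_area(rule101):
    from zipne.simulator import Scenario, simulate

    vals, truths = [], []
    for k in range(300):
        data, truth = simulate(Scenario(lam=5.0, tau=0.0, r=0.9, seed=3000 + k))
        ps = truth.params
        vals.append(ht_mark_estimate(data, 4, ps, rule101))
        truths.append(truth.n[3])
    err = np.mean(vals) - np.mean(truths)
    se = np.std(np.array(vals) - np.array(truths)) / np.sqrt(len(vals))
    assert abs(err) < max(3.5 * se, 0.5)


# ---------------------------------------------------------------------------
# Truncated-normal components
# ---------------------------------------------------------------------------

def test_unmarked_component_against_direct_evaluation():
    from _oracles import oracle_tn_logpdf

    # lam_bar=5, eta=10 at these values
    got = unmarked_loglik(480.0, 100.0, 1.51828, 0.42699)
    lam_bar = np.exp(1.51828 + 0.42699**2 / 2)
    eta = lam_bar + np.exp(2 * 1.51828) * (np.exp(2 * 0.42699**2) - np.exp(0.42699**2))
    assert lam_bar == pytest.approx(5.0, abs=1e-4)
    assert eta == pytest.approx(10.0, abs=2e-3)
    assert got == pytest.approx(oracle_tn_logpdf(480.0, 100 * lam_bar, 100 * eta), rel=1e-9)
    # large mean: truncation negligible, density at the mode is the normal one
    at_mode = unmarked_loglik(100 * lam_bar, 100.0, 1.51828, 0.42699)
    assert at_mode == pytest.approx(-0.5 * np.log(2 * np.pi * 100 * eta), abs=1e-10)


def test_unidentified_component_against_direct_evaluation():
    from _oracles import oracle_tn_logpdf

    lam_bar, _, kappa = pln_moments(np.log(2.0), 0.3, 0.8)
    got = unidentified_loglik(18.0, 50.0, np.log(2.0), 0.3, 0.8)
    assert got == pytest.approx(oracle_tn_logpdf(18.0, 50 * lam_bar * 0.2, 50 * kappa), rel=1e-9)
    # location check: n=50, lam_bar=2, r=0.9 -> mean 10
    assert 50 * 2.0 * (1 - 0.9) == pytest.approx(10.0)


def test_unidentified_degenerate_when_all_marks_identified():
    assert unidentified_loglik(0.0, 30.0, 0.5, 0.2, 1.0) == 0.0
    with pytest.raises(ValueError, match="r=1"):
        unidentified_loglik(3.0, 30.0, 0.5, 0.2, 1.0)


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------

def test_composite_is_sum_of_components(rule101, micro):
    data, ps = micro["m3_t3"]
    total = composite_loglik(data, ps, ModelSpec(heterogeneity="within"), rule101)
    parts = marked_loglik_within(data, ps, rule101)
    for t in range(1, 4):
        n_t = ht_mark_estimate(data, t, ps, rule101)
        parts += unidentified_loglik(data.e[t - 1], n_t, ps.alpha[t - 1],
                                     ps.sigma[t - 1], ps.r[t - 1])
        parts += unmarked_loglik(data.u[t - 1], ps.U[t - 1], ps.alpha[t - 1],
                                 ps.sigma[t - 1])
    assert total == pytest.approx(parts, rel=1e-12)


def test_composite_matches_bruteforce_oracle(rule101, micro):
    for name, (data, ps) in micro.items():
        for het in ("within", "across"):
            got = composite_loglik(data, ps, ModelSpec(heterogeneity=het), rule101)
            want = oracle_composite_loglik(data, ps, het)
            assert got == pytest.approx(want, rel=1e-6), (name, het)


def test_likelihood_flat_along_terminal_product_ridge(rule101):
    # fully time-dependent w, g: scaling (w_T, g_T) -> (c w_T, g_T / c)
    # leaves the likelihood unchanged
    data = EncounterData(
        T=3, y=[[0, 2, 0], [0, 0, 1], [0, 0, 0]], b=[1, 2, 3],
        e=[0, 1, 1], u=[6, 5, 4], R=[1, 1, 1],
        n_known=[False, False, False], n=[0, 0, 0],
    )
    ps = ParameterSet.constant(3, alpha=0.3, sigma=0.2, r=0.8, w=0.8, g=0.7,
                               phi=0.9, gammaPP=0.15, gammaP=0.25, U=8.0)
    base = composite_loglik(data, ps, ModelSpec(heterogeneity="within"), rule101)
    for c in (0.85, 1.1):
        scaled = ParameterSet(**{**ps.to_dict(),
                                 "w": np.array([0.8, 0.8, 0.8 * c]),
                                 "g": np.array([0.7, 0.7, 0.7 / c])})
        moved = composite_loglik(data, scaled, ModelSpec(heterogeneity="within"), rule101)
        assert moved == pytest.approx(base, rel=1e-10)


def test_resight_prob_matches_oracle(rule101):
    ps = ParameterSet.constant(1, alpha=0.4, sigma=0.7, r=0.6, U=1.0)
    assert resight_prob(1, ps, rule101) == pytest.approx(
        oracle_resight_prob(0.4, 0.7, 0.6), rel=1e-8
    )
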