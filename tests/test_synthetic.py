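"""Synthetic registry generator: determinism, laws, and ground-truth checks."""

import numpy as np
import pandas as pd
import pytest

import ramarkov as rm
from ramarkov import reference
from ramarkov.synthetic import _truncated_gamma_params


def test_same_seed_is_byte_identical():
    cfg = rm.SimulationConfig(n_patients=50, seed=123, visits_mean=4.0)
    a = rm.simulate_cohort(cfg)
    b = rm.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.visits, b.visits)
    pd.testing.assert_frame_equal(a.truth_states, b.truth_states)
    assert a.visits.to_csv() == b.visits.to_csv()


def test_patient_substreams_stable_under_cohort_growth():
    small = rm.simulate_cohort(rm.SimulationConfig(n_patients=20, seed=5))
    large = rm.simulate_cohort(rm.SimulationConfig(n_patients=40, seed=5))
    cols = ["patient_id", "t", "year", "duration", "age"]
    pd.testing.assert_frame_equal(
        small.visits[cols],
        large.visits[large.visits["patient_id"].isin(small.visits["patient_id"])][
            cols
        ].reset_index(drop=True),
    )


def test_identity_matrix_freezes_every_path():
    cfg = rm.SimulationConfig(
        n_patients=100, seed=9, transition_matrix=np.eye(3), visits_mean=5.0
    )
    sim = rm.simulate_cohort(cfg)
    n_states = sim.truth_states.groupby("patient_id")["true_state"].nunique()
    assert (n_states == 1).all()


def test_invalid_matrix_rejected_before_sampling():
    bad = np.array([[0.9, 0.2, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]])
    with pytest.raises(ValueError, match="matrix"):
        rm.simulate_cohort(rm.SimulationConfig(n_patients=5, transition_matrix=bad))


def test_latent_states_round_trip_through_cdai(discrete_sim):
    visits = rm.derive_states(discrete_sim.visits)
    assert (
        visits["state"].to_numpy() == discrete_sim.truth_states["true_state"].to_numpy()
    ).all()
    comp_sum = (
        visits[["tjc28", "sjc28", "ptga", "pga"]].sum(axis=1) - visits["cdai"]
    )
    assert np.abs(comp_sum).max() < 1e-9


def test_components_within_ranges(discrete_sim):
    v = discrete_sim.visits
    assert v["tjc28"].between(0, 28).all() and v["sjc28"].between(0, 28).all()
    assert v["ptga"].between(0, 10).all() and v["pga"].between(0, 10).all()
    assert (v["tjc28"] == v["tjc28"].astype(int)).all()


def test_decompose_round_trip_remission(rng):
    states = np.zeros(10_000, dtype=int)  # remission in the 4-state scheme
    comp = rm.decompose_cdai(states, rm.FOUR_STATE, rng)
    assert comp["cdai"].between(0, 2.8).all()
    back = rm.classify_scores(comp["cdai"].to_numpy(), rm.FOUR_STATE)
    assert (back == 0).all()


def test_regular_law_moments_and_support(rng):
    times = rm.sample_visit_schedule("regular", 100_001, rng)
    gaps = np.diff(times)
    n = len(gaps)
    assert gaps.min() >= 3.0 and gaps.max() <= 9.0
    # sample moments within 3 SE of the configured truncated-law moments
    se_mean = gaps.std() / np.sqrt(n)
    assert abs(gaps.mean() - 5.3) < 3 * se_mean
    assert abs(gaps.std() - 1.5) < 0.02


def test_full_law_moments_and_tail(rng):
    gaps = np.diff(rm.sample_visit_schedule("full", 100_001, rng))
    assert abs(gaps.mean() - 5.4) < 0.05
    assert abs(gaps.std() - 3.1) < 0.1
    assert (gaps > 9.0).any()  # long visits exist, unlike the regular law
    assert gaps.min() >= 0.5


def test_single_visit_schedule():
    rng = np.random.default_rng(0)
    assert rm.sample_visit_schedule("regular", 1, rng).tolist() == [0.0]
    with pytest.raises(ValueError):
        rm.sample_visit_schedule("regular", 0, rng)


def test_truncated_gamma_solver_hits_requested_moments():
    from scipy import stats

    k, theta = _truncated_gamma_params(5.3, 1.5, 3.0, 9.0)
    dist = stats.gamma(k, scale=theta)
    # numerical moments of the truncated law
    from scipy.integrate import quad

    w = dist.cdf(9) - dist.cdf(3)
    m1 = quad(lambda x: x * dist.pdf(x), 3, 9)[0] / w
    m2 = quad(lambda x: x * x * dist.pdf(x), 3, 9)[0] / w
    assert m1 == pytest.approx(5.3, abs=1e-6)
    assert np.sqrt(m2 - m1**2) == pytest.approx(1.5, abs=1e-6)


def test_empirical_matrix_converges_to_generator(discrete_transitions):
    m = rm.mle_transition_matrix(rm.count_transitions(discrete_transitions))
    counts = rm.count_transitions(discrete_transitions).n_ij
    truth = reference.PERVISIT_FULL
    for i in range(3):
        bound = 3 * np.sqrt(truth[i] * (1 - truth[i]) / counts[i].sum())
        assert (np.abs(m.probs[i] - truth[i]) <= np.maximum(bound, 0.005)).all()


def test_ctmc_mode_visit_frequencies_match_interval_averaged_exponential(ctmc_sim):
    """Observed frequencies ~ exp(Q*gap) averaged over the realized gaps."""
    visits = rm.derive_states(ctmc_sim.visits)
    trans = rm.pair_consecutive_visits(visits)
    truth = rm.reference_intensity()
    gaps = trans["interval"].to_numpy()
    # expected transition matrix: average P(gap) over the empirical gap law
    sample = np.quantile(gaps, np.linspace(0.005, 0.995, 100))
    expected = np.mean(
        [rm.transition_matrix_at(truth, g).probs for g in sample], axis=0
    )
    observed = rm.mle_transition_matrix(rm.count_transitions(trans)).probs
    assert np.abs(observed - expected).max() < 0.015


def test_covariate_effect_shifts_transition_odds():
    effect = rm.CovariateEffect(
        "duration", ">10", np.log(3.0), prior_states=("modsev",), outcomes=("modsev",)
    )
    cfg = rm.SimulationConfig(
        n_patients=3000, seed=77, scheme=rm.TWO_STATE, mode="discrete",
        transition_matrix=np.array([[0.8, 0.2], [0.4, 0.6]]),
        initial_probs=np.array([0.5, 0.5]), visits_mean=6.0,
        covariate_effects=(effect,),
    )
    sim = rm.simulate_cohort(cfg)
    visits = rm.categorize_covariates(rm.derive_states(sim.visits, rm.TWO_STATE))
    trans = rm.pair_consecutive_visits(visits, rm.TWO_STATE)
    ms = trans[trans["prior_state"] == "modsev"]
    stay = ms.groupby(ms["duration"] == ">10")["current_idx"].mean()
    odds = stay / (1 - stay)
    assert odds[True] / odds[False] == pytest.approx(3.0, rel=0.15)
    # the low stratum is untouched by the stratum-restricted effect
    lo = trans[trans["prior_state"] == "low"]
    move = lo.groupby(lo["duration"] == ">10")["current_idx"].mean()
    assert move[True] == pytest.approx(move[False], abs=0.03)


def test_covariates_advance_with_time():
    sim = rm.simulate_cohort(rm.SimulationConfig(n_patients=30, seed=1, visits_mean=8.0))
    v = sim.visits
    for col in ("year", "duration", "age"):
        deltas = v.groupby("patient_id")[col].diff().dropna()
        assert (deltas > 0).all()
    # elapsed calendar time equals elapsed visit time
    grp = v.groupby("patient_id")
    np.testing.assert_allclose(
        grp["year"].apply(lambda s: s.iloc[-1] - s.iloc[0]) * 12,
        grp["t"].apply(lambda s: s.iloc[-1] - s.iloc[0]),
        atol=1e-9,
    )


def test_reference_intensity_has_published_sojourns():
    q = rm.reference_intensity()
    est = {e.state: e.mean for e in rm.mean_sojourn_ctmc(q)}
    for state, months in reference.SOJOURN_MONTHS.items():
        assert est[state] == pytest.approx(months, rel=1e-12)
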