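"""Markov logistic regression: fits, sandwich variance, ORs, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ramarkov as rm
from ramarkov.regression import ModelSpec, build_design, cluster_robust_vcov


def _toy_binary_transitions(n=30, seed=5, n_patients=None):
    rng = np.random.default_rng(seed)
    n_patients = n_patients or n
    pid = rng.integers(0, n_patients, n)
    prior = rng.integers(0, 2, n)
    p = 0.3 + 0.4 * prior
    current = (rng.random(n) < p).astype(int)
    labels = np.array(rm.TWO_STATE.labels, dtype=object)
    return pd.DataFrame(
        dict(
            patient_id=[f"P{i}" for i in pid],
            prior_state=labels[prior],
            current_state=labels[current],
            prior_idx=prior,
            current_idx=current,
            interval_bin=np.array(["3-4", "4-5", "5-6"], dtype=object)[
                rng.integers(0, 3, n)
            ],
        )
    )


PRIOR_ONLY = ModelSpec(
    scheme=rm.THREE_STATE, covariates=(), include_interval=False, interactions=()
)
BINARY_PRIOR_INTERVAL = ModelSpec(
    scheme=rm.TWO_STATE, covariates=(), interactions=("interval_bin",)
)


def test_saturated_prior_model_reproduces_empirical_mle(discrete_transitions):
    """With prior state the only regressor the multinomial fit is saturated."""
    fit = rm.fit_markov_logit(discrete_transitions, PRIOR_ONLY)
    pred = rm.predicted_transition_matrix(fit, discrete_transitions)
    emp = rm.mle_transition_matrix(rm.count_transitions(discrete_transitions))
    np.testing.assert_allclose(pred.probs, emp.probs, atol=1e-8)


def test_null_data_gives_null_coefficients(rng):
    """Outcome independent of all predictors: non-intercept |z| < 4."""
    n = 4000
    labels = np.array(rm.TWO_STATE.labels, dtype=object)
    prior = rng.integers(0, 2, n)
    df = pd.DataFrame(
        dict(
            patient_id=[f"P{i % 500}" for i in range(n)],
            prior_state=labels[prior],
            prior_idx=prior,
            current_idx=rng.integers(0, 2, n),
            interval_bin=np.array(["3-4", "4-5"], dtype=object)[rng.integers(0, 2, n)],
        )
    )
    df["current_state"] = labels[df["current_idx"]]
    fit = rm.fit_markov_logit(df, ModelSpec(rm.TWO_STATE, covariates=(), interactions=()))
    se = np.sqrt(np.diag(fit.vcov))
    z = (fit.params / se).drop("const")
    assert (np.abs(z) < 4).all()


def test_loglik_beats_intercept_only(discrete_transitions):
    fit = rm.fit_markov_logit(discrete_transitions, PRIOR_ONLY)
    assert fit.loglik >= fit.loglik_null


def test_fit_is_row_order_invariant():
    trans = _toy_binary_transitions(n=400, seed=9, n_patients=50)
    spec = ModelSpec(rm.TWO_STATE, covariates=(), interactions=())
    fit1 = rm.fit_markov_logit(trans, spec)
    shuffled = trans.sample(frac=1.0, random_state=1)
    fit2 = rm.fit_markov_logit(shuffled, spec)
    np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-10)
    np.testing.assert_allclose(fit1.vcov, fit2.vcov, atol=1e-10)


def test_rank_deficiency_names_aliased_terms():
    trans = _toy_binary_transitions(n=200, seed=3)
    rng = np.random.default_rng(3)
    trans["year"] = np.where(rng.random(len(trans)) < 0.5, "2001-2004", "2005-2006")
    trans["duration"] = trans["year"].map(
        {"2001-2004": "0-3", "2005-2006": "3-10"}
    )  # perfectly collinear with year
    spec = ModelSpec(
        rm.TWO_STATE, covariates=("year", "duration"), interactions=(),
        include_interval=False,
    )
    with pytest.raises(ValueError, match="aliased"):
        rm.fit_markov_logit(trans, spec)


# ---------------------------------------------------------------------------
# sandwich variance


def test_singleton_clusters_equal_hc0_brute_force():
    trans = _toy_binary_transitions(n=30, seed=5)
    X = build_design(trans, ModelSpec(rm.TWO_STATE, covariates=(), interactions=()))
    y = trans["current_idx"].to_numpy()
    model = sm.Logit(y, X)
    res = model.fit(disp=False)
    s = model.score_obs(np.asarray(res.params))
    h = model.hessian(np.asarray(res.params))
    hc0 = np.linalg.inv(h) @ (s.T @ s) @ np.linalg.inv(h)  # brute-force HC0
    ours = cluster_robust_vcov(s, h, np.arange(len(y)), small_sample=False)
    np.testing.assert_allclose(ours, hc0, rtol=1e-10)


def test_duplicating_clusters_roughly_halves_variance():
    trans = _toy_binary_transitions(n=200, seed=7, n_patients=40)
    spec = ModelSpec(rm.TWO_STATE, covariates=(), interactions=())
    fit1 = rm.fit_markov_logit(trans, spec, small_sample=False)
    doubled = pd.concat(
        [trans, trans.assign(patient_id=trans["patient_id"] + "_copy")],
        ignore_index=True,
    )
    fit2 = rm.fit_markov_logit(doubled, spec, small_sample=False)
    ratio = np.diag(fit2.vcov) / np.diag(fit1.vcov)
    np.testing.assert_allclose(ratio, 0.5, rtol=0.05)


def test_clustered_matches_statsmodels_cluster_cov():
    """Independent route: statsmodels' cov_type='cluster' on the same fit."""
    trans = _toy_binary_transitions(n=500, seed=11, n_patients=60)
    spec = ModelSpec(rm.TWO_STATE, covariates=(), interactions=())
    fit = rm.fit_markov_logit(trans, spec, small_sample=True)
    X = build_design(trans, spec)
    groups = pd.factorize(trans["patient_id"])[0]
    res = sm.Logit(trans["current_idx"].to_numpy(), X).fit(
        disp=False, cov_type="cluster", cov_kwds={"groups": groups}
    )
    # statsmodels additionally applies the (n-1)/(n-k) df factor on top of
    # the G/(G-1) cluster correction this package uses
    n, k = X.shape
    np.testing.assert_allclose(
        fit.vcov.to_numpy() * (n - 1) / (n - k),
        np.asarray(res.cov_params()),
        rtol=1e-6,
    )


def test_iid_data_clustered_close_to_classical(rng):
    """With one observation per patient, clustering changes little."""
    trans = _toy_binary_transitions(n=2000, seed=13)  # unique patients
    spec = ModelSpec(rm.TWO_STATE, covariates=(), interactions=())
    fit = rm.fit_markov_logit(trans, spec, small_sample=False)
    np.testing.assert_allclose(
        np.diag(fit.vcov), np.diag(fit.vcov_classical), rtol=0.2
    )


def test_single_cluster_rejected():
    trans = _toy_binary_transitions(n=50, seed=2)
    trans["patient_id"] = "only-one"
    with pytest.raises(ValueError, match="cluster"):
        rm.fit_markov_logit(trans, ModelSpec(rm.TWO_STATE, covariates=(), interactions=()))


# ---------------------------------------------------------------------------
# odds ratios


def test_null_contrast_gives_unit_or():
    trans = _toy_binary_transitions(n=300, seed=21)
    fit = rm.fit_markov_logit(trans, BINARY_PRIOR_INTERVAL)
    e = rm.odds_ratio(fit, {"prior[modsev]": 0.0})
    assert e.or_ == pytest.approx(1.0) and e.ci_lo == pytest.approx(1.0)
    assert e.ci_hi == pytest.approx(1.0)


def test_or_is_exp_of_contrast_to_machine_precision():
    trans = _toy_binary_transitions(n=300, seed=22)
    fit = rm.fit_markov_logit(trans, BINARY_PRIOR_INTERVAL)
    beta = fit.params
    c = {"prior[modsev]": 1.0, "interval_bin[4-5]": 1.0}
    e = rm.odds_ratio(fit, c)
    assert e.or_ == pytest.approx(
        np.exp(beta["prior[modsev]"] + beta["interval_bin[4-5]"]), rel=1e-12
    )


def test_interaction_decomposition_is_exact():
    """OR within the moderate/severe stratum = OR(main) x OR(interaction)."""
    trans = _toy_binary_transitions(n=600, seed=23, n_patients=80)
    fit = rm.fit_markov_logit(trans, BINARY_PRIOR_INTERVAL)
    main = rm.odds_ratio(fit, {"interval_bin[4-5]": 1.0})
    inter = rm.odds_ratio(fit, {"prior[modsev]:interval_bin[4-5]": 1.0})
    within = rm.odds_ratio(
        fit, {"interval_bin[4-5]": 1.0, "prior[modsev]:interval_bin[4-5]": 1.0}
    )
    assert within.or_ == pytest.approx(main.or_ * inter.or_, rel=1e-12)


def test_unknown_contrast_rejected():
    trans = _toy_binary_transitions(n=100, seed=24)
    fit = rm.fit_markov_logit(trans, ModelSpec(rm.TWO_STATE, covariates=(), interactions=()))
    with pytest.raises(ValueError, match="not in model"):
        rm.odds_ratio(fit, {"year[2005-2006]": 1.0})


# ---------------------------------------------------------------------------
# predicted matrices


def test_intercept_only_prediction_is_marginal_distribution(discrete_transitions):
    """Without a prior-state term every predicted row is the outcome marginal."""
    spec = ModelSpec(
        rm.THREE_STATE, covariates=(), include_prior=False,
        include_interval=False, interactions=(),
    )
    fit = rm.fit_markov_logit(discrete_transitions, spec)
    pred = rm.predicted_transition_matrix(fit, discrete_transitions)
    marginal = np.bincount(discrete_transitions["current_idx"], minlength=3) / len(
        discrete_transitions
    )
    for i in range(3):
        np.testing.assert_allclose(pred.probs[i], marginal, atol=1e-8)


def test_prediction_matches_brute_force_loop():
    trans = _toy_binary_transitions(n=400, seed=31, n_patients=50)
    fit = rm.fit_markov_logit(trans, BINARY_PRIOR_INTERVAL)
    pred = rm.predicted_transition_matrix(fit, trans)
    from scipy.special import expit

    from ramarkov.regression import _design_like

    for i, label in enumerate(rm.TWO_STATE.labels):
        df = trans.copy()
        df["prior_state"] = label
        X = _design_like(df, fit).to_numpy()
        p1 = np.array([expit(x @ fit.params.to_numpy()) for x in X]).mean()
        np.testing.assert_allclose(pred.probs[i], [1 - p1, p1], atol=1e-12)
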