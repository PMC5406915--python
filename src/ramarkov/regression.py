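"""Covariate-dependent transition models via Markov logistic regression.

The current disease state at a visit is regressed on the prior state, the
visit-interval bin, and visit-level covariates (calendar-year, disease
duration, and age categories), with selected covariate-by-prior-state
interactions — a first-order Markov model in regression form.  The 3-state
scheme uses multinomial logit with "low" as the outcome base category; the
2-state scheme (low vs moderate/severe) uses binary logit.

Because each patient contributes many transitions, coefficient covariances
use the cluster-robust (sandwich) estimator with patients as clusters,
with an optional G/(G-1) small-sample factor (on by default).  Odds
ratios are Wald contrasts on the clustered covariance; for interacted
covariates the effect within the prior = moderate/severe stratum combines
the main and interaction terms.  Population-level transition matrices come
from marginal standardization: set every observed covariate row's prior
state to i, predict, and average to get row i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cdai import StateScheme, THREE_STATE, TWO_STATE
from .cohort import AGE_CATEGORIES, DURATION_CATEGORIES, YEAR_CATEGORIES
from .empirical import TransitionMatrix

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "EffectEstimate",
    "build_design",
    "fit_markov_logit",
    "cluster_robust_vcov",
    "odds_ratio",
    "or_table",
    "predicted_transition_matrix",
]

_Z975 = 1.959964

DEFAULT_LEVELS: dict[str, tuple[str, ...]] = {
    "year": YEAR_CATEGORIES,
    "duration": DURATION_CATEGORIES,
    "age": AGE_CATEGORIES,
}
DEFAULT_REFERENCES: dict[str, str] = {
    "prior": "low",
    "interval_bin": "3-4",
    "year": "2001-2004",
    "duration": "0-3",
    "age": "<50",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the transition regression.

    covariates    : covariate columns included as main effects.
    interactions  : subset of {"interval_bin"} | covariates whose effect is
                    allowed to differ by prior state (the headline model
                    interacts interval, year and duration but not age).
    references    : reference level per factor (defaults above).
    levels        : admissible category order per factor; levels absent
                    from the data are dropped from the design.
    """

    scheme: StateScheme = THREE_STATE
    covariates: tuple[str, ...] = ("year", "duration", "age")
    include_prior: bool = True   # False: intercept/covariate-only (no Markov term)
    include_interval: bool = True
    interactions: tuple[str, ...] = ("interval_bin", "year", "duration")
    references: dict[str, str] = field(default_factory=dict)
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def reference(self, factor: str) -> str:
        return self.references.get(factor, DEFAULT_REFERENCES[factor])

    def factor_levels(self, factor: str, observed) -> list[str]:
        ref = self.reference(factor)
        declared = self.levels.get(
            factor,
            (self.scheme.labels if factor == "prior" else DEFAULT_LEVELS.get(factor)),
        )
        present = set(map(str, observed))
        if declared is None:
            ordered = sorted(present)
        else:
            ordered = [l for l in declared if l in present]
        if ref not in ordered:
            raise ValueError(f"reference level {ref!r} for {factor!r} not in data")
        return [ref] + [l for l in ordered if l != ref]


def _dummies(values: pd.Series, levels: list[str], prefix: str) -> pd.DataFrame:
    """Reference-coded indicator columns (reference = levels[0], dropped)."""
    out = {}
    vals = values.astype(str).to_numpy()
    for lvl in levels[1:]:
        out[f"{prefix}[{lvl}]"] = (vals == lvl).astype(float)
    return pd.DataFrame(out, index=values.index)


def build_design(
    transitions: pd.DataFrame,
    spec: ModelSpec,
    levels: dict[str, list[str]] | None = None,
    check_rank: bool = True,
) -> pd.DataFrame:
    """Design matrix (with intercept) for a transition-observation table.

    ``levels`` fixes the per-factor level order (reference first) — used
    when rebuilding the fitted design for prediction; by default levels
    come from the spec restricted to what the data contain.  The levels
    actually used are attached as ``X.attrs["levels"]``.
    """
    levels = levels or {}
    used: dict[str, list[str]] = {}

    def factor_levels(fac: str, series: pd.Series) -> list[str]:
        lv = list(levels[fac]) if fac in levels else spec.factor_levels(fac, series.unique())
        used[fac] = lv
        return lv

    parts = [pd.DataFrame({"const": np.ones(len(transitions))}, index=transitions.index)]
    if spec.include_prior:
        prior = _dummies(
            transitions["prior_state"],
            factor_levels("prior", transitions["prior_state"]),
            "prior",
        )
    else:
        prior = pd.DataFrame(index=transitions.index)
    parts.append(prior)

    factors = []
    if spec.include_interval and "interval_bin" in transitions.columns:
        factors.append("interval_bin")
    factors.extend(c for c in spec.covariates if c in transitions.columns)
    for fac in factors:
        cols = _dummies(transitions[fac], factor_levels(fac, transitions[fac]), fac)
        parts.append(cols)
        if fac in spec.interactions:
            inter = {}
            for pcol in prior.columns:
                for ccol in cols.columns:
                    inter[f"{pcol}:{ccol}"] = prior[pcol] * cols[ccol]
            parts.append(pd.DataFrame(inter, index=transitions.index))
    X = pd.concat(parts, axis=1)
    X.attrs["levels"] = used
    if check_rank:
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # QR with pivoting to name the aliased columns
            from scipy.linalg import qr

            _, _, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
            bad = [X.columns[p] for p in piv[rank:]]
            raise ValueError(f"design matrix rank deficient; aliased terms: {bad}")
    return X


def cluster_robust_vcov(
    score_obs: np.ndarray,
    hessian: np.ndarray,
    groups: np.ndarray,
    small_sample: bool = True,
) -> np.ndarray:
    """Sandwich covariance H^-1 (sum_c s_c s_c^T) H^-1 over clusters.

    ``score_obs`` holds per-observation score contributions at the MLE,
    ``hessian`` the log-likelihood Hessian there, ``groups`` the cluster
    id per observation.  With every observation its own cluster this is
    the HC0 heteroskedasticity-robust sandwich.  ``small_sample`` applies
    the usual G/(G-1) factor.  A single cluster leaves the variance
    undefined and raises.
    """
    s = np.asarray(score_obs, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    s_c = np.zeros((n_groups, s.shape[1]))
    np.add.at(s_c, codes, s)
    meat = s_c.T @ s_c
    bread = np.linalg.inv(np.asarray(hessian, dtype=float))
    v = bread @ meat @ bread
    if small_sample:
        v = v * (n_groups / (n_groups - 1))
    return (v + v.T) / 2


@dataclass
class RegressionFit:
    """A fitted Markov transition regression with clustered covariance."""

    spec: ModelSpec
    params: pd.Series            # named coefficients (MNLogit: "outcome:term")
    vcov: pd.DataFrame           # patient-clustered sandwich covariance
    vcov_classical: pd.DataFrame
    loglik: float
    loglik_null: float
    n_obs: int
    n_clusters: int
    exog_names: list[str]
    outcome_labels: list[str]    # non-base outcomes (empty string prefixing for binary)
    design_levels: dict[str, list[str]] = field(default_factory=dict)
    results: Any = field(repr=False, default=None)  # underlying statsmodels results

    def param_names(self) -> list[str]:
        return list(self.params.index)


def _flat_names(exog_names, outcome_labels, binary: bool) -> list[str]:
    if binary:
        return list(exog_names)
    return [f"{lab}:{name}" for lab in outcome_labels for name in exog_names]


def fit_markov_logit(
    transitions: pd.DataFrame,
    spec: ModelSpec,
    cluster_col: str = "patient_id",
    small_sample: bool = True,
) -> RegressionFit:
    """Fit the transition regression by Newton's method from a zero start.

    Binary logit for the 2-state scheme (outcome: current state
    moderate/severe), multinomial logit with base "low" for the 3-state
    scheme.  The clustered sandwich uses ``cluster_col`` (patients).
    Near-separated terms (|coef| > 15) trigger a warning naming them.
    """
    X = build_design(transitions, spec)
    binary = spec.scheme.n_states == 2
    y = np.asarray(transitions["current_idx"], dtype=int)
    if len(np.unique(y)) < spec.scheme.n_states:
        raise ValueError("some outcome categories have no observations")

    model = sm.Logit(y, X) if binary else sm.MNLogit(y, X)
    n_params = X.shape[1] * (1 if binary else spec.scheme.n_states - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels convergence chatter
        res = model.fit(
            start_params=np.zeros(n_params), method="newton",
            maxiter=200, tol=1e-10, disp=False,
        )
    flat_for_score = np.asarray(res.params)
    if not binary:
        flat_for_score = flat_for_score.ravel(order="F")
    score = model.score(flat_for_score)
    if np.max(np.abs(score)) > 1e-6 * max(1.0, abs(res.llf)):
        raise RuntimeError(f"Newton fit not converged; |score|={np.max(np.abs(score)):.3g}")

    if binary:
        flat_params = np.asarray(res.params)
        outcome_labels = [spec.scheme.labels[1]]
        names = list(X.columns)
        score_obs = model.score_obs(flat_params)
        hess = model.hessian(flat_params)
    else:
        # MNLogit params: (k_exog, K-1); flatten outcome-major to match names
        params2d = np.asarray(res.params)
        flat_params = params2d.ravel(order="F")
        outcome_labels = [spec.scheme.labels[k] for k in range(1, spec.scheme.n_states)]
        names = _flat_names(X.columns, outcome_labels, binary=False)
        score_obs = _mnlogit_score_obs(model, params2d)
        hess = _mnlogit_hessian(model, params2d)

    big = [n for n, v in zip(names, flat_params) if abs(v) > 15]
    if big:
        warnings.warn(f"possible separation; extreme coefficients: {big}", stacklevel=2)

    groups = transitions[cluster_col].to_numpy()
    vc = cluster_robust_vcov(score_obs, hess, groups, small_sample=small_sample)
    vclassic = np.linalg.inv(-hess)
    null_ll = _null_loglik(y, spec.scheme.n_states)
    return RegressionFit(
        spec=spec,
        params=pd.Series(flat_params, index=names),
        vcov=pd.DataFrame(vc, index=names, columns=names),
        vcov_classical=pd.DataFrame(vclassic, index=names, columns=names),
        loglik=float(res.llf),
        loglik_null=null_ll,
        n_obs=len(transitions),
        n_clusters=int(pd.unique(groups).size),
        exog_names=list(X.columns),
        outcome_labels=outcome_labels,
        design_levels=X.attrs["levels"],
        results=res,
    )


def _null_loglik(y: np.ndarray, k: int) -> float:
    p = np.bincount(y, minlength=k) / len(y)
    return float(np.sum(np.bincount(y, minlength=k) * np.log(np.clip(p, 1e-300, None))))


def _mnlogit_score_obs(model, params2d: np.ndarray) -> np.ndarray:
    """Per-observation multinomial score in outcome-major flat order."""
    X = model.exog
    probs = model.predict(params2d, X)  # (n, K)
    y = model.endog
    k = probs.shape[1]
    resid = np.zeros((len(y), k - 1))
    for j in range(1, k):
        resid[:, j - 1] = (y == j).astype(float) - probs[:, j]
    # score for (outcome j, term p) = resid_j * x_p; flatten outcome-major
    n, p = X.shape
    out = np.einsum("nj,np->njp", resid, X).reshape(n, (k - 1) * p)
    return out


def _mnlogit_hessian(model, params2d: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood Hessian, outcome-major parameter order.

    statsmodels' MNLogit.hessian uses the same (outcome-major) block
    layout; computed here directly so the sandwich is self-contained.
    """
    X = model.exog
    probs = model.predict(params2d, X)
    n, p = X.shape
    k = probs.shape[1]
    h = np.zeros(((k - 1) * p, (k - 1) * p))
    for a in range(1, k):
        for b in range(1, k):
            w = probs[:, a] * ((a == b) - probs[:, b])
            block = -(X * w[:, None]).T @ X
            h[(a - 1) * p:a * p, (b - 1) * p:b * p] = block
    return h


# ---------------------------------------------------------------------------
# effects


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with its 95% Wald interval on the clustered variance."""

    description: str
    stratum: str       # prior-state stratum the OR applies to
    or_: float
    ci_lo: float
    ci_hi: float
    log_or: float
    se_log: float


def odds_ratio(
    fit: RegressionFit, contrast: dict[str, float], description: str = "", stratum: str = ""
) -> EffectEstimate:
    """OR = exp(c'beta) with CI exp(c'beta +/- 1.96 sqrt(c'Vc)).

    ``contrast`` maps parameter names to weights; for an interacted
    covariate the within-stratum effect puts weight 1 on both the main
    and the interaction term.
    """
    c = pd.Series(0.0, index=fit.params.index)
    for name, w in contrast.items():
        if name not in c.index:
            raise ValueError(f"contrast term {name!r} not in model parameters")
        c[name] = w
    est = float(c @ fit.params)
    var = float(c @ fit.vcov.to_numpy() @ c)
    se = np.sqrt(max(var, 0.0))
    return EffectEstimate(
        description=description or "+".join(f"{w:g}*{n}" for n, w in contrast.items()),
        stratum=stratum,
        or_=float(np.exp(est)),
        ci_lo=float(np.exp(est - _Z975 * se)),
        ci_hi=float(np.exp(est + _Z975 * se)),
        log_or=est,
        se_log=se,
    )


def or_table(fit: RegressionFit, outcome: str | None = None) -> pd.DataFrame:
    """Covariate OR table in the published layout.

    For each non-reference covariate level: the effect on the transition
    from low (main effect) and — when the covariate interacts with prior
    state — the effect on remaining in moderate/severe (main +
    interaction).  Non-interacted covariates get a single common row.
    For the 3-state model, ``outcome`` picks the contrast (default: the
    first non-base outcome).
    """
    binary = fit.spec.scheme.n_states == 2
    prefix = "" if binary else f"{outcome or fit.outcome_labels[0]}:"
    prior_terms = [n for n in fit.exog_names if n.startswith("prior[") and ":" not in n]
    rows = []

    def add(term: str, desc: str, stratum: str, extra: dict[str, float] | None = None):
        contrast = {f"{prefix}{term}": 1.0}
        if extra:
            contrast.update({f"{prefix}{k}": v for k, v in extra.items()})
        e = odds_ratio(fit, contrast, description=desc, stratum=stratum)
        rows.append(
            {"covariate": desc, "stratum": stratum, "or": e.or_,
             "ci_lo": e.ci_lo, "ci_hi": e.ci_hi}
        )

    factors = (["interval_bin"] if fit.spec.include_interval else []) + list(
        fit.spec.covariates
    )
    for fac in factors:
        cols = [n for n in fit.exog_names if n.startswith(f"{fac}[")]
        interacted = fac in fit.spec.interactions
        for col in cols:
            lvl = col[len(fac) + 1:-1]
            if interacted:
                add(col, f"{fac}={lvl}", "from low")
                for pterm in prior_terms:
                    add(col, f"{fac}={lvl}", f"remain {pterm[6:-1]}",
                        extra={f"{pterm}:{col}": 1.0})
            else:
                add(col, f"{fac}={lvl}", "any prior state")
    return pd.DataFrame(rows)


def predicted_transition_matrix(
    fit: RegressionFit, transitions: pd.DataFrame, cohort: str = ""
) -> TransitionMatrix:
    """Marginally standardized transition matrix from a fitted regression.

    Row i: set prior state to i on every observed covariate row, predict
    outcome probabilities, and average over rows.
    """
    scheme = fit.spec.scheme
    k = scheme.n_states
    out = np.zeros((k, k))
    for i, label in enumerate(scheme.labels):
        df = transitions.copy()
        df["prior_state"] = label
        X = _design_like(df, fit)
        if k == 2:
            p1 = fit.results.model.predict(fit.params.to_numpy(), X.to_numpy())
            probs = np.column_stack([1 - p1, p1])
        else:
            params2d = fit.params.to_numpy().reshape(k - 1, len(fit.exog_names)).T
            probs = fit.results.model.predict(params2d, X.to_numpy())
        out[i] = probs.mean(axis=0)
    out = out / out.sum(axis=1, keepdims=True)
    return TransitionMatrix(scheme, out, horizon="per-visit", cohort=cohort)


def _design_like(df: pd.DataFrame, fit: RegressionFit) -> pd.DataFrame:
    """Design matrix with exactly the fitted model's columns."""
    X = build_design(df, fit.spec, levels=fit.design_levels, check_rank=False)
    missing = [c for c in fit.exog_names if c not in X.columns]
    for c in missing:
        X[c] = 0.0
    return X[fit.exog_names]
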