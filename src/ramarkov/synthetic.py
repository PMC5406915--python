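"""Synthetic RA registry generator with known ground truth.

The real registry behind the published transition estimates is
proprietary, so every estimator in this package is exercised on simulated
cohorts that emulate its structure:

* ~tens of thousands of patients, each with a handful of visits;
* irregular inter-visit intervals — a "regular" law (truncated gamma on
  [3, 9] months, mean 5.3, SD 1.5, matching the regular-visit sub-cohort)
  and a "full" law (lognormal, mean 5.4, SD 3.1, floored at 0.5 months,
  matching the long-tailed full cohort);
* latent disease-state dynamics with configurable truth — either a
  per-visit transition matrix (discrete mode) or a continuous-time
  generator simulated as an exact jump chain and read off at visit times
  (ctmc mode);
* covariate effects on transition log-odds, per covariate category,
  optionally restricted to prior-state strata and outcome states;
* CDAI scores drawn within each latent state's score interval and split
  into components (integer joint counts, fractional globals) so that
  classifying the recomputed CDAI always returns the latent state.

A single global seed expands to per-patient substreams through
``SeedSequence((seed, patient_index))``, so cohorts are bit-reproducible
and individual patients are independent of cohort ordering or size
changes downstream of their index.  Covariate marginals are independent
across patients — a documented simplification; real registries correlate
age, duration and calendar time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cdai import StateScheme, THREE_STATE, TWO_STATE
from .cohort import age_category, duration_category, year_category
from .ctmc import IntensityMatrix
from . import reference

__all__ = [
    "CovariateEffect",
    "SimulationConfig",
    "SimulatedCohort",
    "sample_visit_schedule",
    "decompose_cdai",
    "simulate_cohort",
    "two_state_matrix_from_or",
    "reference_intensity",
]

# CDAI score interval per state label (severe capped below the 76 scale
# maximum to keep component splits realistic; configurable via state_caps)
_STATE_SCORE_INTERVALS = {
    "remission": (0.0, 2.8),
    "low": (2.8, 10.0),
    "moderate": (10.0, 22.0),
    "severe": (22.0, 50.0),
    "modsev": (10.0, 50.0),
}
# the three_state "low" folds remission in, so it starts at 0
_LOW_FOLDED = (0.0, 10.0)


@dataclass(frozen=True)
class CovariateEffect:
    """A log-odds increment for one covariate category.

    Applied to the transition log-odds of each outcome in ``outcomes``
    (default: every non-base outcome) whenever the departing state is in
    ``prior_states`` (default: every prior state) and the visit's
    covariate equals ``category``.
    """

    covariate: str
    category: str
    delta: float
    prior_states: tuple[str, ...] | None = None
    outcomes: tuple[str, ...] | None = None

    def applies(self, prior: str, outcome: str) -> bool:
        if self.prior_states is not None and prior not in self.prior_states:
            return False
        if self.outcomes is not None and outcome not in self.outcomes:
            return False
        return True


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults emulate the published full-cohort conditions: state dynamics
    at the published per-visit matrix, initial states at the published
    first-visit CDAI mix, visits per patient averaging ~8.4 (min 2), and
    the regular interval law.
    """

    n_patients: int = 1000
    seed: int = 0
    scheme: StateScheme = THREE_STATE
    mode: str = "discrete"                       # "discrete" | "ctmc"
    transition_matrix: np.ndarray | None = None  # discrete-mode truth
    intensity: IntensityMatrix | None = None     # ctmc-mode truth
    initial_probs: np.ndarray | None = None
    visits_min: int = 2
    visits_mean: float = 8.4
    interval_law: str = "regular"                # "regular" | "full"
    interval_mean: float | None = None
    interval_sd: float | None = None
    covariate_effects: tuple[CovariateEffect, ...] = ()
    enroll_year_range: tuple[float, float] = (2001.75, 2013.5)
    baseline_age_mean: float = 58.0
    baseline_age_sd: float = 13.4
    baseline_duration_mean: float = 9.0
    severe_cdai_cap: float = 50.0

    def resolved_matrix(self) -> np.ndarray:
        if self.transition_matrix is not None:
            m = np.asarray(self.transition_matrix, dtype=float)
        elif self.scheme.n_states == 3:
            m = reference.PERVISIT_FULL
        else:
            raise ValueError("transition_matrix required for non-3-state discrete mode")
        if m.shape != (self.scheme.n_states,) * 2 or (m < 0).any() or (
            np.abs(m.sum(axis=1) - 1).max() > 1e-9
        ):
            raise ValueError("invalid per-visit transition matrix in config")
        return m

    def resolved_initial(self) -> np.ndarray:
        if self.initial_probs is not None:
            p = np.asarray(self.initial_probs, dtype=float)
        elif self.scheme.n_states == 3:
            p = reference.INITIAL_STATE_PROBS
        else:
            p = np.full(self.scheme.n_states, 1.0 / self.scheme.n_states)
        if p.shape != (self.scheme.n_states,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("invalid initial state distribution")
        return p


@dataclass
class SimulatedCohort:
    """A simulated registry plus the ground truth that generated it."""

    visits: pd.DataFrame        # registry-contract table (numeric covariates)
    truth_states: pd.DataFrame  # (patient_id, t, true_state)
    jump_chain: pd.DataFrame | None  # ctmc mode: (patient_id, time, state)
    config: SimulationConfig


def reference_intensity(
    sojourn_means: dict[str, float] | None = None,
    scheme: StateScheme = THREE_STATE,
) -> IntensityMatrix:
    """A 3-state generator whose sojourn means are the published values.

    Exit rates are the reciprocals of the per-state mean sojourn times
    (defaults: low 19.38, moderate 4.25, severe 5.30 months); on leaving
    a state the jump distribution follows the published per-visit
    matrix's off-diagonal proportions.
    """
    from .ctmc import intensity_from_sojourns

    sojourn_means = sojourn_means or reference.SOJOURN_MONTHS
    means = np.array([sojourn_means[lab] for lab in scheme.labels])
    m = reference.PERVISIT_FULL.copy()
    np.fill_diagonal(m, 0.0)
    jumps = m / m.sum(axis=1, keepdims=True)
    return intensity_from_sojourns(means, jumps, scheme)


def two_state_matrix_from_or(
    p_low_to_modsev: float, or_prior: float
) -> np.ndarray:
    """2-state per-visit matrix with a given prior-state odds ratio.

    Row "low" moves to moderate/severe with probability
    ``p_low_to_modsev``; row "modsev" stays with the probability whose
    odds are ``or_prior`` times the low row's odds.
    """
    lo = special.logit(p_low_to_modsev)
    p_stay = special.expit(lo + np.log(or_prior))
    return np.array([[1 - p_low_to_modsev, p_low_to_modsev], [1 - p_stay, p_stay]])


# ---------------------------------------------------------------------------
# visit schedules


@lru_cache(maxsize=8)
def _truncated_gamma_params(mean: float, sd: float, lo: float, hi: float):
    """Gamma (shape, scale) whose truncation to [lo, hi] has given moments.

    Uses the incomplete-gamma identities E[X^r | lo<X<hi] proportional to
    F_{k+r}(hi) - F_{k+r}(lo) and solves the two moment equations.
    """

    def trunc_moments(k, theta):
        z = stats.gamma(k, scale=theta)
        w = z.cdf(hi) - z.cdf(lo)
        m1 = k * theta * (stats.gamma(k + 1, scale=theta).cdf(hi)
                          - stats.gamma(k + 1, scale=theta).cdf(lo)) / w
        m2 = k * (k + 1) * theta ** 2 * (stats.gamma(k + 2, scale=theta).cdf(hi)
                                         - stats.gamma(k + 2, scale=theta).cdf(lo)) / w
        return m1, np.sqrt(m2 - m1 ** 2)

    def eqs(x):
        k, theta = np.exp(x)
        m, s = trunc_moments(k, theta)
        return [m - mean, s - sd]

    x0 = np.log([(mean / sd) ** 2, sd ** 2 / mean])
    sol = optimize.fsolve(eqs, x0, full_output=True)
    x, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"truncated-gamma moment match failed: {msg}")
    return tuple(np.exp(x))


def _sample_gaps(law: str, mean: float, sd: float, n: int, rng: np.random.Generator):
    if law == "regular":
        lo, hi = 3.0, 9.0
        k, theta = _truncated_gamma_params(mean, sd, lo, hi)
        dist = stats.gamma(k, scale=theta)
        u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=n)
        return dist.ppf(u)
    if law == "full":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return np.maximum(rng.lognormal(mu, np.sqrt(sigma2), size=n), 0.5)
    raise ValueError(f"unknown interval law {law!r}")


def sample_visit_schedule(
    law: str, n_visits: int, rng: np.random.Generator,
    mean: float | None = None, sd: float | None = None,
) -> np.ndarray:
    """Strictly increasing visit times (months), first visit at 0.

    ``law="regular"`` draws gaps from the truncated gamma on [3, 9]
    (defaults mean 5.3, SD 1.5); ``law="full"`` from the floored
    lognormal (defaults mean 5.4, SD 3.1).
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    defaults = (
        reference.INTERVAL_LAW_REGULAR if law == "regular" else reference.INTERVAL_LAW_FULL
    )
    mean = defaults["mean"] if mean is None else mean
    sd = defaults["sd"] if sd is None else sd
    gaps = _sample_gaps(law, mean, sd, n_visits - 1, rng)
    return np.concatenate([[0.0], np.cumsum(gaps)])


# ---------------------------------------------------------------------------
# CDAI decomposition


def decompose_cdai(
    states: np.ndarray, scheme: StateScheme, rng: np.random.Generator,
    severe_cap: float = 50.0,
) -> pd.DataFrame:
    """Draw CDAI scores and component splits consistent with latent states.

    For each state index, a score is drawn uniformly inside the state's
    CDAI interval (three_state "low" spans [0, 10] since it folds
    remission in; "severe"/"modsev" are capped at ``severe_cap``).  The
    score is split into integer joint counts and fractional globals that
    sum to it exactly, each component within its range, so that
    classifying the recomputed CDAI returns the latent state.
    """
    idx = np.asarray(states, dtype=int)
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    lo = np.empty(len(idx))
    hi = np.empty(len(idx))
    for lab in np.unique(labels):
        a, b = _STATE_SCORE_INTERVALS[lab]
        if lab == "low" and "remission" not in scheme.labels:
            a, b = _LOW_FOLDED
        if lab in ("severe", "modsev"):
            b = severe_cap
        m = labels == lab
        lo[m], hi[m] = a, b
    # score strictly above the lower boundary (boundaries belong below)
    s = lo + (hi - lo) * (1.0 - rng.random(len(idx)))

    # joints total: integer j with max(0, s-20) <= j <= min(56, s)
    j_lo = np.ceil(np.maximum(0.0, s - 20.0)).astype(int)
    j_hi = np.floor(np.minimum(56.0, s)).astype(int)
    j = rng.integers(j_lo, j_hi + 1)
    g = s - j  # globals total, in [0, 20] by construction
    tjc = rng.integers(np.maximum(0, j - 28), np.minimum(28, j) + 1)
    sjc = j - tjc
    ptga = rng.uniform(np.maximum(0.0, g - 10.0), np.minimum(10.0, g))
    pga = g - ptga
    return pd.DataFrame(
        {"tjc28": tjc, "sjc28": sjc, "ptga": ptga, "pga": pga, "cdai": s}
    )


# ---------------------------------------------------------------------------
# state dynamics


def _logits_from_matrix(matrix: np.ndarray) -> np.ndarray:
    """Row-wise multinomial logits vs base class 0, clipped away from 0."""
    p = np.clip(matrix, 1e-12, None)
    return np.log(p[:, 1:] / p[:, [0]])


def _effect_tensor(
    config: SimulationConfig, covariate_values: dict[str, np.ndarray]
) -> np.ndarray | None:
    """Per-visit log-odds increments, shape (n, K_prior, K-1 outcomes)."""
    if not config.covariate_effects:
        return None
    labels = config.scheme.labels
    n = len(next(iter(covariate_values.values())))
    delta = np.zeros((n, len(labels), len(labels) - 1))
    for eff in config.covariate_effects:
        if eff.covariate not in covariate_values:
            raise ValueError(f"effect on unknown covariate {eff.covariate!r}")
        visit_match = covariate_values[eff.covariate] == eff.category
        for i, prior in enumerate(labels):
            for jj, outcome in enumerate(labels[1:]):
                if eff.applies(prior, outcome):
                    delta[visit_match, i, jj] += eff.delta
    return delta


def _evolve_discrete(
    matrix: np.ndarray, init: np.ndarray, visit_of_patient: np.ndarray,
    delta: np.ndarray | None, uniforms: np.ndarray,
) -> np.ndarray:
    """Latent state at each visit row (rows ordered patient-major by time)."""
    k = matrix.shape[0]
    base_logits = _logits_from_matrix(matrix)
    init_cum = np.cumsum(init)
    states = np.empty(len(visit_of_patient), dtype=int)
    prev = -1
    for r in range(len(states)):
        if visit_of_patient[r] == 0:
            states[r] = np.searchsorted(init_cum, uniforms[r] * init_cum[-1])
        else:
            i = prev
            if delta is None:
                probs = matrix[i]
            else:
                # covariates act at the visit being departed (row r-1),
                # matching the regression's prior-visit attachment
                eta = base_logits[i] + delta[r - 1, i]
                e = np.exp(np.concatenate([[0.0], eta]))
                probs = e / e.sum()
            states[r] = np.searchsorted(np.cumsum(probs), uniforms[r] * probs.sum())
        prev = states[r]
    return states


def _simulate_jump_chain(
    q: np.ndarray, init_cum: np.ndarray, horizon: float, rng: np.random.Generator
):
    """One exact CTMC path on [0, horizon]: (jump times, states)."""
    exit_rates = -np.diag(q)
    k = q.shape[0]
    jump_cum = []
    for i in range(k):
        row = q[i].copy()
        row[i] = 0.0
        tot = row.sum()
        jump_cum.append(np.cumsum(row / tot) if tot > 0 else None)
    t, state = 0.0, int(np.searchsorted(init_cum, rng.random() * init_cum[-1]))
    times, states = [0.0], [state]
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        state = int(np.searchsorted(jump_cum[state], rng.random()))
        times.append(t)
        states.append(state)
    return np.array(times), np.array(states, dtype=int)


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic registry under ``config``.

    Deterministic given ``config.seed``.  The returned ``visits`` table
    follows the registry column contract (numeric year/duration/age; CDAI
    components plus score); ``truth_states`` carries the latent state at
    every visit, and ctmc mode additionally returns the full jump chain.
    """
    scheme = config.scheme
    if config.mode == "discrete":
        matrix = config.resolved_matrix()
    elif config.mode == "ctmc":
        if config.intensity is None:
            raise ValueError("ctmc mode requires config.intensity")
        if config.intensity.scheme.n_states != scheme.n_states:
            raise ValueError("intensity scheme does not match config scheme")
        if config.covariate_effects:
            raise ValueError("covariate effects are only supported in discrete mode")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    init = config.resolved_initial()
    init_cum = np.cumsum(init)

    law_defaults = (
        reference.INTERVAL_LAW_REGULAR
        if config.interval_law == "regular"
        else reference.INTERVAL_LAW_FULL
    )
    gap_mean = config.interval_mean or law_defaults["mean"]
    gap_sd = config.interval_sd or law_defaults["sd"]

    pid_col, t_col, vno_col = [], [], []
    cov_year, cov_dur, cov_age = [], [], []
    chain_pid, chain_t, chain_s = [], [], []
    ctmc_states_col = []

    for p in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, p)))
        n_visits = config.visits_min + rng.poisson(
            max(config.visits_mean - config.visits_min, 0.0)
        )
        times = sample_visit_schedule(
            config.interval_law, n_visits, rng, mean=gap_mean, sd=gap_sd
        )
        enroll = rng.uniform(*config.enroll_year_range)
        age0 = float(np.clip(rng.normal(config.baseline_age_mean, config.baseline_age_sd),
                             18.0, 95.0))
        dur0 = float(rng.exponential(config.baseline_duration_mean))
        pid = f"P{p:06d}"
        pid_col.extend([pid] * n_visits)
        t_col.append(times)
        vno_col.append(np.arange(n_visits))
        cov_year.append(enroll + times / 12.0)
        cov_dur.append(dur0 + times / 12.0)
        cov_age.append(age0 + times / 12.0)

        if config.mode == "ctmc":
            jt, js = _simulate_jump_chain(
                np.asarray(config.intensity.q), init_cum, times[-1] + 1e-9, rng
            )
            at_visits = js[np.searchsorted(jt, times, side="right") - 1]
            ctmc_states_col.append(at_visits)
            chain_pid.extend([pid] * len(jt))
            chain_t.append(jt)
            chain_s.append(js)

    t_all = np.concatenate(t_col)
    vno = np.concatenate(vno_col)
    pid_all = np.asarray(pid_col, dtype=object)
    year_num = np.concatenate(cov_year)
    dur_num = np.concatenate(cov_dur)
    age_num = np.concatenate(cov_age)

    # state evolution needs one uniform per visit row; draw from a cohort
    # substream so the per-patient streams above stay alignment-free
    state_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2**31)))
    if config.mode == "discrete":
        cov_cats = {
            "year": np.array([year_category(v) for v in year_num], dtype=object),
            "duration": np.array([duration_category(v) for v in dur_num], dtype=object),
            "age": np.array([age_category(v) for v in age_num], dtype=object),
        }
        delta = _effect_tensor(config, cov_cats)
        states = _evolve_discrete(
            matrix, init, vno, delta, state_rng.random(len(t_all))
        )
    else:
        states = np.concatenate(ctmc_states_col)

    comp = decompose_cdai(states, scheme, state_rng, severe_cap=config.severe_cdai_cap)
    visits = pd.DataFrame(
        {
            "patient_id": pid_all,
            "t": t_all,
            "tjc28": comp["tjc28"].to_numpy(),
            "sjc28": comp["sjc28"].to_numpy(),
            "ptga": comp["ptga"].to_numpy(),
            "pga": comp["pga"].to_numpy(),
            "cdai": comp["cdai"].to_numpy(),
            "year": year_num,
            "duration": dur_num,
            "age": age_num,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": pid_all,
            "t": t_all,
            "true_state": np.asarray(scheme.labels, dtype=object)[states],
        }
    )
    chain = None
    if config.mode == "ctmc":
        chain = pd.DataFrame(
            {
                "patient_id": np.asarray(chain_pid, dtype=object),
                "time": np.concatenate(chain_t) if chain_t else np.array([]),
                "state": np.asarray(scheme.labels, dtype=object)[
                    np.concatenate(chain_s).astype(int)
                ] if chain_s else np.array([]),
            }
        )
    return SimulatedCohort(visits=visits, truth_states=truth, jump_chain=chain, config=config)
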