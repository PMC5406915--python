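"""Continuous-time multi-state model for panel-observed disease states.

Visits give the state only at irregular times t_1 < t_2 < ...; between
visits the path is unobserved.  A time-homogeneous continuous-time Markov
chain with intensity (generator) matrix Q — off-diagonal rates q_ij >= 0,
rows summing to zero — implies visit-pair likelihood contributions
[P(dt)]_{ij} with P(t) = exp(Qt), so the panel log-likelihood is

    l(Q) = sum over pairs log [exp(Q * interval)]_{prior, current}.

Q is estimated by maximizing l in log-intensity space (positivity for
free), with the observed-information covariance from a numerical Hessian.
The fitted Q yields interval-standardized matrices (e.g. P(6 months),
comparable across cohorts with different visit spacing) and mean sojourn
times -1/q_ii.  A discrete-time geometric sojourn estimator
(mean_interval / (1 - pi_ii)) is provided alongside for comparison with
the per-visit matrix route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import approx_fprime, minimize
from statsmodels.tools.numdiff import approx_hess

from .cdai import StateScheme, THREE_STATE
from .empirical import TransitionMatrix

__all__ = [
    "IntensityMatrix",
    "CtmcFit",
    "SojournEstimate",
    "intensity_from_sojourns",
    "transition_matrix_at",
    "panel_loglik",
    "fit_ctmc",
    "mean_sojourn_ctmc",
    "mean_sojourn_discrete",
]

_Z975 = 1.959964  # normal 97.5% quantile for Wald intervals


@dataclass(frozen=True)
class IntensityMatrix:
    """A valid CTMC generator over a state scheme (rates per month)."""

    scheme: StateScheme
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        k = self.scheme.n_states
        problems = []
        if q.shape != (k, k):
            raise ValueError(f"generator shape {q.shape} does not match {k} states")
        off = q[~np.eye(k, dtype=bool)]
        if (off < 0).any():
            problems.append("negative off-diagonal intensity")
        if (np.diag(q) > 1e-12).any():
            problems.append("positive diagonal")
        if np.abs(q.sum(axis=1)).max() > 1e-9:
            problems.append("row sums differ from 0")
        if problems:
            raise ValueError("invalid generator: " + "; ".join(problems))

    @property
    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.q)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.scheme.labels)
        return pd.DataFrame(self.q, index=labels, columns=labels)


@dataclass(frozen=True)
class SojournEstimate:
    """Mean continuous time in a state before leaving it, in months."""

    state: str
    mean: float
    se: float | None
    ci_lo: float | None
    ci_hi: float | None
    method: str  # "ctmc" or "discrete"


@dataclass(frozen=True)
class CtmcFit:
    intensity: IntensityMatrix
    theta: np.ndarray       # log off-diagonal intensities, row-major
    cov_theta: np.ndarray   # observed-information covariance in theta space
    loglik: float
    grad_norm: float
    converged: bool
    n_obs: int
    flags: tuple[str, ...] = ()


def intensity_from_sojourns(
    sojourn_means, jump_probs, scheme: StateScheme = THREE_STATE
) -> IntensityMatrix:
    """Build Q from per-state mean sojourn times and jump probabilities.

    ``sojourn_means[i]`` is the mean holding time of state i in months
    (exit rate 1/mean); ``jump_probs[i, j]`` is the probability the chain
    moves to j when it leaves i (rows sum to 1, zero diagonal).
    """
    m = np.asarray(sojourn_means, dtype=float)
    r = np.asarray(jump_probs, dtype=float)
    k = scheme.n_states
    if m.shape != (k,) or (m <= 0).any():
        raise ValueError("sojourn means must be positive, one per state")
    if r.shape != (k, k) or np.abs(np.diag(r)).max() > 0 or np.abs(r.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("jump_probs must be zero-diagonal with rows summing to 1")
    q = (r.T / m).T
    np.fill_diagonal(q, -1.0 / m)
    return IntensityMatrix(scheme, q)


def transition_matrix_at(
    intensity: IntensityMatrix, t: float, cohort: str = ""
) -> TransitionMatrix:
    """P(t) = exp(Qt); rows renormalized within 1e-10, tiny negatives clipped."""
    if t < 0:
        raise ValueError(f"negative horizon t={t}")
    p = expm(np.asarray(intensity.q) * t)
    if (p < -1e-12).any():
        raise ValueError("matrix exponential produced substantially negative entries")
    p = np.clip(p, 0.0, None)
    rows = p.sum(axis=1)
    if np.abs(rows - 1).max() > 1e-10:
        raise ValueError("exp(Qt) rows do not sum to 1 within 1e-10")
    p = p / rows[:, None]
    return TransitionMatrix(intensity.scheme, p, horizon=float(t), cohort=cohort)


# ---------------------------------------------------------------------------
# panel MLE


def _off_diagonal_mask(k: int) -> np.ndarray:
    return ~np.eye(k, dtype=bool)


def _theta_to_q(theta: np.ndarray, k: int) -> np.ndarray:
    q = np.zeros((k, k))
    q[_off_diagonal_mask(k)] = np.exp(theta)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _aggregate_panel(transitions: pd.DataFrame, k: int, round_intervals: float):
    """Collapse observations to (unique interval, count matrix) pairs.

    Intervals are rounded to ``round_intervals`` months before grouping:
    the likelihood is smooth in t, so a 0.01-month grid changes it
    negligibly while making each objective evaluation O(#unique).
    """
    t = np.round(np.asarray(transitions["interval"], dtype=float) / round_intervals)
    if (t <= 0).any():
        raise ValueError("zero-length intervals in panel data")
    i = np.asarray(transitions["prior_idx"], dtype=int)
    j = np.asarray(transitions["current_idx"], dtype=int)
    keys = t.astype(np.int64) * (k * k) + i * k + j
    uniq, counts = np.unique(keys, return_counts=True)
    t_u = (uniq // (k * k)).astype(float) * round_intervals
    cell = (uniq % (k * k)).astype(int)
    return t_u, cell, counts.astype(float)


def _panel_probs(q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """P(t) for every t in ``times`` at once, shape (len(times), k, k)."""
    k = q.shape[0]
    w, u = np.linalg.eig(q)
    try:
        uinv = np.linalg.inv(u)
        if np.linalg.cond(u) < 1e10:
            e = np.exp(np.multiply.outer(times, w))  # (T, k)
            p = np.einsum("ik,tk,kj->tij", u, e, uinv).real
            return np.clip(p, 1e-300, None)
    except np.linalg.LinAlgError:
        pass
    # defective/ill-conditioned generator: fall back to expm per interval
    p = np.stack([expm(q * t) for t in times])
    return np.clip(p, 1e-300, None)


def panel_loglik(
    transitions: pd.DataFrame,
    intensity: IntensityMatrix,
    round_intervals: float = 0.01,
) -> float:
    """Panel log-likelihood of a generator on transition observations."""
    k = intensity.scheme.n_states
    t_u, cell, counts = _aggregate_panel(transitions, k, round_intervals)
    times = np.unique(t_u)
    time_idx = np.searchsorted(times, t_u)
    p = _panel_probs(np.asarray(intensity.q), times).reshape(len(times), k * k)
    return float(np.sum(counts * np.log(p[time_idx, cell])))


def fit_ctmc(
    transitions: pd.DataFrame,
    scheme: StateScheme = THREE_STATE,
    init: IntensityMatrix | None = None,
    n_starts: int = 3,
    seed: int = 0,
    round_intervals: float = 0.01,
    gtol: float = 1e-6,
) -> CtmcFit:
    """Maximum-likelihood generator from panel transition observations.

    Optimizes the log off-diagonal intensities with L-BFGS-B from
    ``n_starts`` starting points (the supplied/default init plus jittered
    copies, seeded), keeps the best optimum, and takes the covariance from
    the inverse observed information.  Rates driven below 1e-8/month are
    flagged as unbounded (effectively-never transitions are not
    identified from panel data).
    """
    k = scheme.n_states
    n_params = k * (k - 1)
    n_obs = len(transitions)
    if n_obs < n_params:
        raise ValueError(
            f"{n_obs} observations cannot identify {n_params} intensities"
        )
    t_u, cell, counts = _aggregate_panel(transitions, k, round_intervals)
    times = np.unique(t_u)
    time_idx = np.searchsorted(times, t_u)

    def nll(theta: np.ndarray) -> float:
        q = _theta_to_q(theta, k)
        p = _panel_probs(q, times)
        flat = p.reshape(len(times), k * k)
        return -float(np.sum(counts * np.log(flat[time_idx, cell])))

    rng = np.random.default_rng(seed)
    if init is not None:
        theta0 = np.log(np.clip(init.q[_off_diagonal_mask(k)], 1e-6, None))
    else:
        theta0 = np.full(n_params, np.log(0.1))
    starts = [theta0] + [theta0 + rng.normal(0, 0.5, n_params) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(-20.0, 5.0)] * n_params,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol / 10},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    grad = approx_fprime(theta, nll, 1e-6)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(best.success) and grad_norm < gtol * max(1.0, abs(best.fun))
    if not best.success and grad_norm > 1e-2 * max(1.0, abs(best.fun)):
        raise RuntimeError(
            f"CTMC fit did not converge: {best.message}; |grad|={grad_norm:.3g}"
        )

    flags = []
    rates = np.exp(theta)
    if (rates < 1e-8).any():
        flags.append("unbounded: some intensities driven to ~0; not identified")
        warnings.warn(flags[-1], stacklevel=2)

    hess = approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((n_params, n_params), np.nan)
        flags.append("singular information matrix")
    return CtmcFit(
        intensity=IntensityMatrix(scheme, _theta_to_q(theta, k)),
        theta=theta,
        cov_theta=cov,
        loglik=-float(best.fun),
        grad_norm=grad_norm,
        converged=converged,
        n_obs=n_obs,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# sojourn times


def mean_sojourn_ctmc(fit_or_q: "CtmcFit | IntensityMatrix") -> list[SojournEstimate]:
    """Mean sojourn -1/q_ii per state, with delta-method SE / log-scale CI.

    Accepts either a fitted model (SEs from the fitted covariance) or a
    bare generator (point estimates only).  Absorbing states (q_ii = 0)
    yield an infinite mean rather than an error.
    """
    if isinstance(fit_or_q, CtmcFit):
        intensity, cov = fit_or_q.intensity, fit_or_q.cov_theta
        theta = fit_or_q.theta
    else:
        intensity, cov, theta = fit_or_q, None, None
    k = intensity.scheme.n_states
    mask = _off_diagonal_mask(k)
    out = []
    for i, state in enumerate(intensity.scheme.labels):
        exit_rate = intensity.exit_rates[i]
        if exit_rate <= 0:
            out.append(SojournEstimate(state, np.inf, None, None, None, "ctmc"))
            continue
        mean = 1.0 / exit_rate
        se = ci_lo = ci_hi = None
        if cov is not None and np.isfinite(cov).all():
            # log(mean) = -log(sum_j exp(theta_ij)); gradient = -softmax row
            g = np.zeros(len(theta))
            row_params = np.where(mask.reshape(-1))[0]  # flat positions of off-diags
            flat_row = np.arange(k * k).reshape(k, k)[i][mask[i]]
            sel = np.searchsorted(row_params, flat_row)
            rates_i = np.exp(theta[sel])
            g[sel] = -rates_i / rates_i.sum()
            var_log = float(g @ cov @ g)
            if var_log >= 0:
                sd_log = np.sqrt(var_log)
                se = mean * sd_log
                ci_lo = mean * np.exp(-_Z975 * sd_log)
                ci_hi = mean * np.exp(_Z975 * sd_log)
        out.append(SojournEstimate(state, mean, se, ci_lo, ci_hi, "ctmc"))
    return out


def mean_sojourn_discrete(
    matrix: TransitionMatrix, mean_interval: float
) -> list[SojournEstimate]:
    """Geometric holding-time estimate from a per-visit matrix.

    The number of visits spent in state i before leaving is geometric with
    stay probability pi_ii, so the expected stay is mean_interval /
    (1 - pi_ii) months.  pi_ii = 1 yields an infinite mean (flagged, not
    an error); no SE is attached (the matrix alone carries no sampling
    information).
    """
    if matrix.horizon != "per-visit":
        raise ValueError("discrete sojourns need a per-visit matrix")
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    out = []
    for i, state in enumerate(matrix.scheme.labels):
        stay = float(matrix.probs[i, i])
        mean = np.inf if stay >= 1.0 else mean_interval / (1.0 - stay)
        out.append(SojournEstimate(state, mean, None, None, None, "discrete"))
    return out
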