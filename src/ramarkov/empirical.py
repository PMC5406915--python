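"""Nonparametric (empirical) transition-matrix estimation.

Under a first-order Markov model observed at visits, the transition counts
n_ij (prior state i, current state j) are the sufficient statistic and the
maximum-likelihood estimate of the per-visit transition probability is the
row-wise proportion pi_ij = n_ij / sum_j n_ij.  Rows never observed as a
prior state have an undefined distribution and are carried as NaN rather
than silently zeroed; an optional add-1/2 (Jeffreys) smoother exists for
tiny simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdai import StateScheme, THREE_STATE

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "count_transitions",
    "mle_transition_matrix",
    "matrix_difference_report",
]


@dataclass(frozen=True)
class TransitionCounts:
    scheme: StateScheme
    n_ij: np.ndarray  # (K, K) prior x current counts
    n_patients: int
    n_observations: int

    def __post_init__(self) -> None:
        n = np.asarray(self.n_ij)
        if n.shape != (self.scheme.n_states,) * 2:
            raise ValueError("count matrix shape does not match scheme")
        if (n < 0).any():
            raise ValueError("negative transition counts")
        if int(n.sum()) != self.n_observations:
            raise ValueError("count total != n_observations")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities with a time interpretation.

    ``horizon`` is either the string "per-visit" or a fixed number of
    months; ``cohort`` tags which cohort produced it (e.g. "full",
    "regular").  Undefined rows (never-visited prior states) are NaN.
    """

    scheme: StateScheme
    probs: np.ndarray
    horizon: str | float = "per-visit"
    cohort: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.scheme.n_states,) * 2:
            raise ValueError("probability matrix shape does not match scheme")
        defined = ~np.isnan(p).any(axis=1)
        if ((p[defined] < 0) | (p[defined] > 1)).any():
            raise ValueError("probabilities outside [0, 1]")
        if defined.any() and np.abs(p[defined].sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("rows must sum to 1 within 1e-12")

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.scheme.labels)
        return pd.DataFrame(self.probs, index=labels, columns=labels)


def count_transitions(
    transitions: pd.DataFrame, scheme: StateScheme = THREE_STATE
) -> TransitionCounts:
    """Tally prior->current counts from a transition-observation table."""
    k = scheme.n_states
    i = np.asarray(transitions["prior_idx"], dtype=int)
    j = np.asarray(transitions["current_idx"], dtype=int)
    if len(i) and (i.min() < 0 or i.max() >= k or j.min() < 0 or j.max() >= k):
        raise ValueError("state indices outside scheme")
    n_ij = np.bincount(i * k + j, minlength=k * k).reshape(k, k)
    n_patients = int(transitions["patient_id"].nunique()) if len(i) else 0
    return TransitionCounts(scheme, n_ij, n_patients, int(len(i)))


def mle_transition_matrix(
    counts: TransitionCounts, cohort: str = "", smooth: bool = False
) -> TransitionMatrix:
    """Row-proportion MLE of the per-visit transition matrix.

    Zero-count rows become NaN (undefined), unless ``smooth`` adds 1/2 to
    every cell first (Jeffreys), which also regularizes tiny simulations.
    """
    n = np.asarray(counts.n_ij, dtype=float)
    if n.sum() == 0:
        raise ValueError("no transition observations: all counts zero")
    if smooth:
        n = n + 0.5
    row = n.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, n / row, np.nan)
    return TransitionMatrix(counts.scheme, probs, horizon="per-visit", cohort=cohort)


def matrix_difference_report(a: TransitionMatrix, b: TransitionMatrix) -> dict:
    """Per-cell absolute differences and their maximum between two matrices."""
    if a.scheme.name != b.scheme.name:
        raise ValueError(f"scheme mismatch: {a.scheme.name} vs {b.scheme.name}")
    if a.horizon != b.horizon:
        raise ValueError(f"horizon mismatch: {a.horizon} vs {b.horizon}")
    diff = np.abs(np.asarray(a.probs) - np.asarray(b.probs))
    return {"abs_diff": diff, "max_abs_diff": float(np.nanmax(diff))}
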