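"""End-to-end registry analysis: read -> states -> transitions -> estimates.

``run_analysis`` executes the full study on a registry table and returns
(and optionally writes) the report bundle:

1. read and validate the registry; log exclusions;
2. classify CDAI into 3-state disease activity; pair consecutive visits;
3. split into the full cohort and the regular-visit sub-cohort (every
   gap in [3, 9] months);
4. empirical per-visit transition matrices for both cohorts, plus their
   per-cell difference report;
5. continuous-time multi-state fits standardized to a 6-month interval,
   with mean sojourn times (CTMC and discrete-geometric, side by side);
6. transition regressions on the regular sub-cohort — 3-state
   multinomial and 2-state binary logit with prior-state interactions and
   patient-clustered variance — with the covariate OR table and the
   interval-by-prior-state OR table.

All numbers are computed at full precision; report CSVs round
probabilities to 2 decimals and ORs to 3, with full-precision JSON
sidecars.  File writes are atomic (temp file + rename) and each output
records the config hash, so regenerating a report is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cdai import SCHEMES, THREE_STATE, TWO_STATE
from .cohort import (
    FIXED_BINS,
    categorize_covariates,
    derive_states,
    interval_quintiles,
    pair_consecutive_visits,
    read_registry,
    regular_visit_filter,
)
from .ctmc import CtmcFit, fit_ctmc, mean_sojourn_ctmc, mean_sojourn_discrete, transition_matrix_at
from .empirical import TransitionMatrix, count_transitions, matrix_difference_report, mle_transition_matrix
from .regression import ModelSpec, RegressionFit, fit_markov_logit, or_table, predicted_transition_matrix

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_analysis",
    "load_config",
    "two_state_recovery_study",
]

DEFAULT_CONFIG = {
    "scheme": "three_state",
    "covariate_timing": "prior",
    "regular_bounds": [3.0, 9.0],
    "horizon_months": 6.0,
    "ctmc": {"n_starts": 3, "seed": 0},
    "regression": {
        "covariates": ["year", "duration", "age"],
        "interactions": ["interval_bin", "year", "duration"],
        "small_sample": True,
    },
}


@dataclass(frozen=True)
class AnalysisConfig:
    raw: dict

    @property
    def scheme(self):
        return SCHEMES[self.raw.get("scheme", "three_state")]

    def get(self, *keys, default=None):
        node = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path=None) -> AnalysisConfig:
    """Merge a YAML config file (if any) over the documented defaults."""
    raw = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(raw.get(k), dict):
                raw[k].update(v)
            else:
                raw[k] = v
    return AnalysisConfig(raw)


@dataclass
class AnalysisReport:
    pervisit_full: TransitionMatrix
    pervisit_regular: TransitionMatrix
    predicted_full: TransitionMatrix | None
    predicted_regular: TransitionMatrix | None
    sixmonth_full: TransitionMatrix
    sixmonth_regular: TransitionMatrix
    matrix_difference: dict
    sojourns: pd.DataFrame
    or_table: pd.DataFrame
    interval_or_table: pd.DataFrame
    ctmc_full: CtmcFit
    ctmc_regular: CtmcFit
    fit_two_state: RegressionFit
    fit_three_state: RegressionFit | None
    exclusion_log: dict
    metadata: dict


def _stage(name):
    """Decorate-in-place error context: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_analysis(registry, config: AnalysisConfig | None = None, out_dir=None) -> AnalysisReport:
    """Run the full analysis on a registry CSV path or visit DataFrame."""
    config = config or AnalysisConfig(json.loads(json.dumps(DEFAULT_CONFIG)))
    scheme = config.scheme
    lo, hi = config.get("regular_bounds", default=[3.0, 9.0])
    horizon = float(config.get("horizon_months", default=6.0))
    timing = config.get("covariate_timing", default="prior")

    with _stage("read"):
        if isinstance(registry, (str, Path)):
            visits, read_log = read_registry(registry)
        else:
            visits, read_log = registry.copy(), {"rows_read": len(registry)}
        if visits.empty:
            raise ValueError("empty registry")
        visits = categorize_covariates(visits)

    with _stage("classify"):
        visits3 = derive_states(visits, scheme)

    with _stage("pair"):
        trans_full = pair_consecutive_visits(visits3, scheme, covariate_timing=timing)

    with _stage("regular_filter"):
        regular_visits, filter_log = regular_visit_filter(visits3, lo=lo, hi=hi)
        trans_reg = pair_consecutive_visits(
            regular_visits, scheme, bins=FIXED_BINS, covariate_timing=timing
        )

    with _stage("empirical"):
        emp_full = mle_transition_matrix(count_transitions(trans_full, scheme), cohort="full")
        emp_reg = mle_transition_matrix(count_transitions(trans_reg, scheme), cohort="regular")
        diff = matrix_difference_report(emp_full, emp_reg)

    with _stage("ctmc"):
        n_starts = int(config.get("ctmc", "n_starts", default=3))
        ctmc_seed = int(config.get("ctmc", "seed", default=0))
        ctmc_full = fit_ctmc(trans_full, scheme, n_starts=n_starts, seed=ctmc_seed)
        ctmc_reg = fit_ctmc(trans_reg, scheme, n_starts=n_starts, seed=ctmc_seed)
        p6_full = transition_matrix_at(ctmc_full.intensity, horizon, cohort="full")
        p6_reg = transition_matrix_at(ctmc_reg.intensity, horizon, cohort="regular")

    with _stage("sojourn"):
        rows = []
        for fit, trans, tag in ((ctmc_full, trans_full, "full"), (ctmc_reg, trans_reg, "regular")):
            for est in mean_sojourn_ctmc(fit):
                rows.append((tag, est.state, est.method, est.mean, est.se, est.ci_lo, est.ci_hi))
            emp = emp_full if tag == "full" else emp_reg
            for est in mean_sojourn_discrete(emp, float(trans["interval"].mean())):
                rows.append((tag, est.state, est.method, est.mean, est.se, est.ci_lo, est.ci_hi))
        sojourns = pd.DataFrame(
            rows, columns=["cohort", "state", "method", "mean", "se", "ci_lo", "ci_hi"]
        )

    with _stage("regression"):
        covs = tuple(config.get("regression", "covariates", default=["year", "duration", "age"]))
        inters = tuple(
            config.get("regression", "interactions",
                       default=["interval_bin", "year", "duration"])
        )
        small = bool(config.get("regression", "small_sample", default=True))
        covs = tuple(c for c in covs if c in trans_reg.columns)
        inters = tuple(i for i in inters if i == "interval_bin" or i in covs)
        # drop factors with a single observed level (non-identifiable)
        covs = tuple(c for c in covs if trans_reg[c].nunique() > 1)
        inters = tuple(i for i in inters if i == "interval_bin" or i in covs)

        visits2 = derive_states(regular_visits.drop(columns=["state", "state_idx"]), TWO_STATE)
        trans2 = pair_consecutive_visits(
            visits2, TWO_STATE, bins=FIXED_BINS, covariate_timing=timing
        )
        spec2 = ModelSpec(scheme=TWO_STATE, covariates=covs, interactions=inters)
        fit2 = fit_markov_logit(trans2, spec2, small_sample=small)
        table3 = or_table(fit2)
        interval_table = table3[table3["covariate"].str.startswith("interval_bin=")]
        covariate_table = table3[~table3["covariate"].str.startswith("interval_bin=")]

        fit3 = pred_full = pred_reg = None
        if config.get("regression", "three_state", default=True):
            spec3 = ModelSpec(scheme=scheme, covariates=(), interactions=("interval_bin",))
            fit3 = fit_markov_logit(trans_reg, spec3, small_sample=small)
            pred_reg = predicted_transition_matrix(fit3, trans_reg, cohort="regular")
            # full cohort: interval-quintile bins (its gaps exceed the fixed span)
            try:
                qbins = interval_quintiles(trans_full["interval"].to_numpy())
                trans_full_b = trans_full.assign(
                    interval_bin=qbins.assign(trans_full["interval"].to_numpy())
                )
                spec3f = ModelSpec(
                    scheme=scheme, covariates=(), interactions=("interval_bin",),
                    references={"prior": "low", "interval_bin": "q1"},
                )
                fit3f = fit_markov_logit(trans_full_b, spec3f, small_sample=small)
                pred_full = predicted_transition_matrix(fit3f, trans_full_b, cohort="full")
            except ValueError:
                pred_full = None

    metadata = {
        "package_version": __version__,
        "config": config.raw,
        "config_hash": config.digest(),
        "n_patients_full": int(visits3["patient_id"].nunique()),
        "n_visits_full": int(len(visits3)),
        "n_transitions_full": int(len(trans_full)),
        "n_patients_regular": int(regular_visits["patient_id"].nunique()),
        "n_transitions_regular": int(len(trans_reg)),
    }
    report = AnalysisReport(
        pervisit_full=emp_full,
        pervisit_regular=emp_reg,
        predicted_full=pred_full,
        predicted_regular=pred_reg,
        sixmonth_full=p6_full,
        sixmonth_regular=p6_reg,
        matrix_difference=diff,
        sojourns=sojourns,
        or_table=covariate_table.reset_index(drop=True),
        interval_or_table=interval_table.reset_index(drop=True),
        ctmc_full=ctmc_full,
        ctmc_regular=ctmc_reg,
        fit_two_state=fit2,
        fit_three_state=fit3,
        exclusion_log={**read_log, **filter_log},
        metadata=metadata,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# parameter recovery


def fit_two_state_effects(
    visits: pd.DataFrame, small_sample: bool = True
) -> tuple[RegressionFit, dict]:
    """Fit the interacted 2-state model and extract the headline contrasts.

    Returns the fit plus a dict with the prior-state OR at the reference
    interval and the within-moderate/severe duration >10 OR, each with
    its 95% CI.
    """
    from .regression import odds_ratio

    visits2 = derive_states(categorize_covariates(visits), TWO_STATE)
    trans2 = pair_consecutive_visits(visits2, TWO_STATE, bins=FIXED_BINS)
    covs = ("duration",) if "duration" in trans2.columns else ()
    spec = ModelSpec(
        scheme=TWO_STATE, covariates=covs, interactions=("interval_bin",) + covs
    )
    fit = fit_markov_logit(trans2, spec, small_sample=small_sample)
    effects = {}
    e = odds_ratio(fit, {"prior[modsev]": 1.0}, stratum="reference interval")
    effects["or_prior_modsev"] = (e.or_, e.ci_lo, e.ci_hi)
    if "duration[>10]" in fit.params.index:
        e = odds_ratio(
            fit,
            {"duration[>10]": 1.0, "prior[modsev]:duration[>10]": 1.0},
            stratum="remain modsev",
        )
        effects["or_duration_gt10_modsev"] = (e.or_, e.ci_lo, e.ci_hi)
    return fit, effects


def two_state_recovery_study(
    n_replicates: int = 100,
    n_patients: int = 800,
    seed: int = 0,
    or_prior: float | None = None,
    or_duration: float | None = None,
    visits_mean: float = 6.0,
) -> pd.DataFrame:
    """Coverage study for the 2-state transition regression.

    Each replicate simulates a cohort whose prior-state log-odds (at the
    reference interval) and duration>10-within-moderate/severe log-odds
    are set to the published odds ratios, refits the interacted model,
    and records the estimates and whether each 95% CI covers its truth.
    """
    from . import reference
    from .synthetic import CovariateEffect, SimulationConfig, simulate_cohort, two_state_matrix_from_or

    or_prior = or_prior if or_prior is not None else reference.OR_PRIOR_MODSEV
    or_duration = (
        or_duration if or_duration is not None else reference.OR_DURATION_GT10_MODSEV
    )
    matrix = two_state_matrix_from_or(0.16, or_prior)
    effects = (
        CovariateEffect(
            "duration", ">10", float(np.log(or_duration)),
            prior_states=("modsev",), outcomes=("modsev",),
        ),
    )
    rows = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_patients=n_patients,
            seed=(seed + 10_000 * r) % (2**31 - 1),
            scheme=TWO_STATE,
            mode="discrete",
            transition_matrix=matrix,
            initial_probs=np.array([0.6, 0.4]),
            visits_min=2,
            visits_mean=visits_mean,
            interval_law="regular",
            covariate_effects=effects,
        )
        sim = simulate_cohort(cfg)
        _, est = fit_two_state_effects(sim.visits)
        op, oplo, ophi = est["or_prior_modsev"]
        od, odlo, odhi = est["or_duration_gt10_modsev"]
        rows.append(
            {
                "replicate": r,
                "or_prior": op, "or_prior_lo": oplo, "or_prior_hi": ophi,
                "covers_prior": oplo <= or_prior <= ophi,
                "or_duration": od, "or_duration_lo": odlo, "or_duration_hi": odhi,
                "covers_duration": odlo <= or_duration <= odhi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report output


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _matrix_csv(matrix: TransitionMatrix, meta: dict) -> str:
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    return header + matrix.to_frame().round(2).to_csv()


def write_report(report: AnalysisReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = report.metadata["config_hash"]

    matrices = {
        "pervisit_full": report.pervisit_full,
        "pervisit_regular": report.pervisit_regular,
        "sixmonth_full": report.sixmonth_full,
        "sixmonth_regular": report.sixmonth_regular,
    }
    for name, m in ((k, v) for k, v in matrices.items() if v is not None):
        _atomic_write(
            out / f"{name}.csv",
            _matrix_csv(m, {"cohort": m.cohort, "horizon": m.horizon, "config": h}),
        )
    full_precision = {
        name: np.asarray(m.probs).tolist() for name, m in matrices.items() if m is not None
    }
    for name, m in (("predicted_full", report.predicted_full),
                    ("predicted_regular", report.predicted_regular)):
        if m is not None:
            full_precision[name] = np.asarray(m.probs).tolist()
    _atomic_write(out / "matrices.json", json.dumps(
        {"config_hash": h, "matrices": full_precision,
         "max_abs_difference_pervisit": report.matrix_difference["max_abs_diff"]},
        indent=2))

    _atomic_write(out / "sojourns.csv",
                  f"# config: {h}\n" + report.sojourns.round(3).to_csv(index=False))
    _atomic_write(out / "or_table.csv",
                  f"# config: {h}\n" + report.or_table.round(3).to_csv(index=False))
    _atomic_write(out / "interval_or_table.csv",
                  f"# config: {h}\n" + report.interval_or_table.round(3).to_csv(index=False))
    _atomic_write(out / "exclusions.json", json.dumps(report.exclusion_log, indent=2))
    _atomic_write(out / "metadata.json", json.dumps(report.metadata, indent=2, default=str))
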