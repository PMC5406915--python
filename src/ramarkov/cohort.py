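"""Registry tables, per-visit states, and transition observations.

A registry table is a pandas DataFrame with one row per patient-visit:

======================  =====================================================
column                  meaning
======================  =====================================================
patient_id              opaque patient identifier
t                       visit time in months from the patient's baseline
                        (alternatively a ``visit_date`` column of dates,
                        converted at read time using 30.4375 days/month)
tjc28, sjc28            28-joint tender / swollen counts
ptga, pga               patient / physician global assessments (0-10)
cdai                    precomputed CDAI score (optional if components given)
year                    calendar-year category at the visit
duration                disease duration in years at the visit
age                     age in years at the visit
======================  =====================================================

Visits lacking both a CDAI score and a complete component set are
non-analyzable and are dropped (with counts reported) before modelling.

Consecutive visit pairs become *transition observations*: prior state,
current state, the interval between the visits, the interval bin, and the
covariates attached to the pair (taken at the prior visit by default: the
model predicts the current state from the state being departed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdai import StateScheme, THREE_STATE, classify_scores

__all__ = [
    "DAYS_PER_MONTH",
    "YEAR_CATEGORIES",
    "DURATION_CATEGORIES",
    "AGE_CATEGORIES",
    "IntervalBins",
    "FIXED_BINS",
    "read_registry",
    "write_registry",
    "derive_states",
    "pair_consecutive_visits",
    "regular_visit_filter",
    "bin_interval",
    "interval_quintiles",
    "incident_moderate_cohort",
    "year_category",
    "duration_category",
    "age_category",
    "categorize_covariates",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12, deterministic date -> month conversion

_CORE_COLUMNS = ("patient_id",)
_COMPONENT_COLUMNS = ("tjc28", "sjc28", "ptga", "pga")
_COVARIATE_COLUMNS = ("year", "duration", "age")

YEAR_CATEGORIES = (
    "2001-2004", "2005-2006", "2007-2008", "2009-2010", "2011-2012", "2013-2014",
)
DURATION_CATEGORIES = ("0-3", "3-10", ">10")
AGE_CATEGORIES = ("<50", "50-64", ">=65")


def year_category(year: float) -> str:
    """Calendar year -> category; years past the last window stay in it."""
    edges = (2005, 2007, 2009, 2011, 2013)
    return YEAR_CATEGORIES[int(np.searchsorted(edges, year, side="right"))]


def duration_category(years: float) -> str:
    """Disease duration (years) -> {0-3, 3-10, >10}, lower-inclusive."""
    if years < 0:
        raise ValueError(f"negative disease duration: {years}")
    return DURATION_CATEGORIES[int(np.searchsorted((3.0, 10.0), years, side="right"))]


def age_category(years: float) -> str:
    """Age (years) -> {<50, 50-64, >=65}; 50 -> 50-64, 65 -> >=65."""
    return AGE_CATEGORIES[int(np.searchsorted((50.0, 65.0), years, side="right"))]


def categorize_covariates(visits: pd.DataFrame) -> pd.DataFrame:
    """Replace numeric year/duration/age columns with their categories.

    Columns already holding category strings are left unchanged, so the
    function is idempotent and tolerant of mixed registries.
    """
    df = visits.copy()
    converters = {
        "year": year_category,
        "duration": duration_category,
        "age": age_category,
    }
    for col, fn in converters.items():
        if col in df.columns and pd.api.types.is_numeric_dtype(df[col]):
            df[col] = [fn(v) for v in df[col].to_numpy()]
    return df


# ---------------------------------------------------------------------------
# registry I/O


def read_registry(path) -> tuple[pd.DataFrame, dict]:
    """Read a registry CSV into a sorted, analyzability-flagged visit table.

    Returns ``(visits, log)`` where ``log`` counts dropped/flagged rows.
    ``visits`` is sorted by (patient_id, t); a ``visit_date`` column is
    converted to months from each patient's first visit.  A row is
    analyzable when it has a CDAI score or all four components; CDAI is
    filled in from components where absent.  Duplicate (patient_id, t)
    rows raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if "t" not in df.columns and "visit_date" not in df.columns:
        missing.append("t or visit_date")
    has_components = all(c in df.columns for c in _COMPONENT_COLUMNS)
    if not has_components and "cdai" not in df.columns:
        missing.append("cdai or tjc28/sjc28/ptga/pga")
    if missing:
        raise ValueError(f"registry is missing mandatory columns: {missing}")

    if "t" not in df.columns:
        dates = pd.to_datetime(df["visit_date"])
        baseline = dates.groupby(df["patient_id"]).transform("min")
        df = df.assign(t=(dates - baseline).dt.days / DAYS_PER_MONTH)

    df = df.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["patient_id", "t"]).any():
        dups = df.loc[df.duplicated(["patient_id", "t"]), ["patient_id", "t"]]
        raise ValueError(f"duplicate (patient_id, t) rows:\n{dups.head()}")
    if (df["t"] < 0).any():
        raise ValueError("negative visit times")

    if has_components:
        component_ok = df[list(_COMPONENT_COLUMNS)].notna().all(axis=1)
        computed = df[list(_COMPONENT_COLUMNS)].sum(axis=1).where(component_ok)
    else:
        computed = pd.Series(np.nan, index=df.index)
    if "cdai" not in df.columns:
        df["cdai"] = computed
    else:
        df["cdai"] = df["cdai"].fillna(computed)
    analyzable = df["cdai"].notna()

    n_rows = len(df)
    dropped_patients = (
        df.loc[~analyzable, "patient_id"].nunique() if (~analyzable).any() else 0
    )
    log = {
        "rows_read": n_rows,
        "rows_non_analyzable": int((~analyzable).sum()),
        "patients_with_non_analyzable_visit": int(dropped_patients),
    }
    return df[analyzable].reset_index(drop=True), log


def write_registry(visits: pd.DataFrame, path) -> None:
    """Write a visit table as CSV (inverse of :func:`read_registry`)."""
    visits.to_csv(path, index=False)


def derive_states(visits: pd.DataFrame, scheme: StateScheme = THREE_STATE) -> pd.DataFrame:
    """Attach ``state`` (label) and ``state_idx`` columns from CDAI scores."""
    idx = classify_scores(visits["cdai"].to_numpy(), scheme)
    return visits.assign(
        state_idx=idx, state=np.asarray(scheme.labels, dtype=object)[idx]
    )


# ---------------------------------------------------------------------------
# interval bins


@dataclass(frozen=True)
class IntervalBins:
    """An ordered partition of an interval range into half-open bins.

    Bin k covers [edges[k], edges[k+1]); the last bin is closed on the
    right so the partition is total on [edges[0], edges[-1]].
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need one label per bin")
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return self.edges[0], self.edges[-1]

    def assign(self, intervals) -> np.ndarray:
        """Vectorized bin labels for an array of intervals."""
        x = np.asarray(intervals, dtype=float)
        lo, hi = self.span
        if np.any(x < lo) or np.any(x > hi):
            bad = x[(x < lo) | (x > hi)]
            raise ValueError(
                f"interval(s) {bad[:5]!r} outside bin span [{lo}, {hi}]"
            )
        k = np.searchsorted(self.edges[1:-1], x, side="right")
        return np.asarray(self.labels, dtype=object)[k]


FIXED_BINS = IntervalBins(
    edges=(3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0),
    labels=("3-4", "4-5", "5-6", "6-7", "7-8", "8-9"),
)


def bin_interval(interval: float, bins: IntervalBins = FIXED_BINS) -> str:
    """Bin label for one interval; half-open, last bin closed (9.0 -> 8-9)."""
    return bins.assign([interval])[0]


def interval_quintiles(intervals) -> IntervalBins:
    """Data-driven quintile bins at the 20/40/60/80th percentiles."""
    x = np.asarray(intervals, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct interval values for quintiles")
    cuts = np.percentile(x, [20, 40, 60, 80])
    edges = (float(x.min()), *map(float, cuts), float(x.max()))
    if list(edges) != sorted(set(edges)):
        raise ValueError(f"degenerate quintile edges {edges}; intervals too tied")
    labels = tuple(f"q{k + 1}" for k in range(5))
    return IntervalBins(edges=edges, labels=labels)


# ---------------------------------------------------------------------------
# transitions


def pair_consecutive_visits(
    visits: pd.DataFrame,
    scheme: StateScheme = THREE_STATE,
    bins: IntervalBins | None = None,
    covariate_timing: str = "prior",
) -> pd.DataFrame:
    """Build transition observations from consecutive visit pairs.

    Each patient with n visits contributes n-1 rows with columns
    (patient_id, prior_state, current_state, prior_idx, current_idx,
    interval, and the covariate columns present).  Covariates are taken at
    the prior visit by default (``covariate_timing="current"`` switches to
    the arriving visit, for sensitivity analyses).  When ``bins`` is given,
    an ``interval_bin`` column is attached; intervals outside the bin span
    then raise, so filter the cohort first.
    """
    if covariate_timing not in ("prior", "current"):
        raise ValueError(f"covariate_timing must be prior|current, got {covariate_timing!r}")
    if "state_idx" not in visits.columns:
        visits = derive_states(visits, scheme)
    df = visits.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)

    same_patient = df["patient_id"].to_numpy()[:-1] == df["patient_id"].to_numpy()[1:]
    idx = np.nonzero(same_patient)[0]
    prior = df.iloc[idx]
    current = df.iloc[idx + 1]

    interval = current["t"].to_numpy() - prior["t"].to_numpy()
    if np.any(interval <= 0):
        raise ValueError("non-increasing visit times within a patient")

    src = prior if covariate_timing == "prior" else current
    out = pd.DataFrame(
        {
            "patient_id": prior["patient_id"].to_numpy(),
            "prior_state": prior["state"].to_numpy(),
            "current_state": current["state"].to_numpy(),
            "prior_idx": prior["state_idx"].to_numpy(),
            "current_idx": current["state_idx"].to_numpy(),
            "interval": interval,
        }
    )
    for col in _COVARIATE_COLUMNS:
        if col in src.columns:
            out[col] = src[col].to_numpy()
    if bins is not None:
        out["interval_bin"] = bins.assign(interval)
    return out


def regular_visit_filter(
    visits: pd.DataFrame, lo: float = 3.0, hi: float = 9.0
) -> tuple[pd.DataFrame, dict]:
    """Keep only patients whose *every* inter-visit gap lies in [lo, hi].

    Single-visit patients have no gaps and are dropped (they contribute no
    transitions).  Returns the retained visit rows and an exclusion report.
    """
    if visits.empty:
        return visits.copy(), {"patients_in": 0, "patients_kept": 0, "patients_dropped": 0}
    df = visits.sort_values(["patient_id", "t"], kind="mergesort")
    gaps = df.groupby("patient_id")["t"].diff().dropna()
    ok_patient = gaps.groupby(df.loc[gaps.index, "patient_id"]).apply(
        lambda g: bool(((g >= lo) & (g <= hi)).all())
    )
    keep = set(ok_patient[ok_patient].index)
    out = df[df["patient_id"].isin(keep)].reset_index(drop=True)
    report = {
        "patients_in": int(df["patient_id"].nunique()),
        "patients_kept": len(keep),
        "patients_dropped": int(df["patient_id"].nunique()) - len(keep),
    }
    return out, report


def incident_moderate_cohort(
    visits: pd.DataFrame, scheme: StateScheme = THREE_STATE
) -> pd.DataFrame:
    """Patients whose path first steps from remission/low into moderate.

    Cohort entry is the first visit at which the state is moderate and the
    immediately preceding visit was remission or low.  Returns one row per
    included patient: (patient_id, entry_visit) with entry_visit the
    1-based visit number of that moderate visit.
    """
    if "state" not in visits.columns:
        visits = derive_states(visits, scheme)
    low_like = {"remission", "low"}
    rows = []
    for pid, grp in visits.sort_values(["patient_id", "t"], kind="mergesort").groupby(
        "patient_id", sort=False
    ):
        states = grp["state"].to_numpy()
        for k in range(1, len(states)):
            if states[k] == "moderate" and states[k - 1] in low_like:
                rows.append((pid, k + 1))
                break
    return pd.DataFrame(rows, columns=["patient_id", "entry_visit"])
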