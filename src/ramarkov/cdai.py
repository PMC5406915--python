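"""Clinical Disease Activity Index (CDAI) scoring and disease-activity states.

The CDAI is the sum of the 28-joint tender and swollen joint counts and the
patient and physician global assessments of disease activity (each 0-10), so
it ranges from 0 to 76 and needs no acute-phase reactant.  Established
cutoffs partition the scale into disease-activity states:

* remission        CDAI <= 2.8
* low              2.8 < CDAI <= 10
* moderate         10  < CDAI <= 22
* severe (high)    CDAI > 22

Three nested schemes are exposed: ``four_state`` keeps remission separate,
``three_state`` folds remission into "low" (the scheme used for the
transition matrices), and ``two_state`` folds moderate and severe into a
single "modsev" state (the scheme used for the binary transition
regressions).  All cutoffs are inclusive on the lower side: a score exactly
at a boundary belongs to the less-active state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CdaiComponents",
    "StateScheme",
    "FOUR_STATE",
    "THREE_STATE",
    "TWO_STATE",
    "SCHEMES",
    "compute_cdai",
    "classify_state",
    "classify_scores",
    "collapse_scheme",
]

CDAI_MAX = 76.0


@dataclass(frozen=True)
class CdaiComponents:
    """The four CDAI components for one visit.

    tjc28, sjc28 : tender / swollen joint counts on the 28-joint scale.
    ptga, pga    : patient / physician global assessments on a 0-10 scale
                   (fractional values allowed, as registries record them).
    """

    tjc28: float
    sjc28: float
    ptga: float
    pga: float

    def __post_init__(self) -> None:
        for name, value, hi in (
            ("tjc28", self.tjc28, 28),
            ("sjc28", self.sjc28, 28),
            ("ptga", self.ptga, 10),
            ("pga", self.pga, 10),
        ):
            if not np.isfinite(value) or value < 0 or value > hi:
                raise ValueError(
                    f"CDAI component {name}={value!r} outside [0, {hi}]"
                )


@dataclass(frozen=True)
class StateScheme:
    """An ordered partition of the CDAI scale into disease-activity states.

    ``thresholds`` are the strictly increasing interior cut points;
    ``labels[k]`` covers scores in (thresholds[k-1], thresholds[k]], with
    the first label starting at 0 and the last ending at 76.
    """

    name: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("labels count must be thresholds count + 1")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


FOUR_STATE = StateScheme(
    "four_state", (2.8, 10.0, 22.0), ("remission", "low", "moderate", "severe")
)
THREE_STATE = StateScheme("three_state", (10.0, 22.0), ("low", "moderate", "severe"))
TWO_STATE = StateScheme("two_state", (10.0,), ("low", "modsev"))

SCHEMES: dict[str, StateScheme] = {
    s.name: s for s in (FOUR_STATE, THREE_STATE, TWO_STATE)
}

# order-preserving label merges between nested schemes
_COLLAPSE: dict[tuple[str, str], dict[str, str]] = {
    ("four_state", "three_state"): {
        "remission": "low", "low": "low", "moderate": "moderate", "severe": "severe",
    },
    ("four_state", "two_state"): {
        "remission": "low", "low": "low", "moderate": "modsev", "severe": "modsev",
    },
    ("three_state", "two_state"): {
        "low": "low", "moderate": "modsev", "severe": "modsev",
    },
}


def compute_cdai(components: CdaiComponents) -> float:
    """CDAI score: TJC28 + SJC28 + PtGA + PGA, in [0, 76]."""
    return components.tjc28 + components.sjc28 + components.ptga + components.pga


def classify_state(cdai: float, scheme: StateScheme = THREE_STATE) -> str:
    """Map a CDAI score to its state label under ``scheme``.

    Boundaries are inclusive below: 2.8 is remission, 10 is low, 22 is
    moderate.
    """
    if not np.isfinite(cdai) or cdai < 0 or cdai > CDAI_MAX:
        raise ValueError(f"CDAI score {cdai!r} outside [0, {CDAI_MAX}]")
    for cut, label in zip(scheme.thresholds, scheme.labels):
        if cdai <= cut:
            return label
    return scheme.labels[-1]


def classify_scores(cdai: np.ndarray, scheme: StateScheme = THREE_STATE) -> np.ndarray:
    """Vectorized :func:`classify_state`: scores -> state indices (0-based)."""
    scores = np.asarray(cdai, dtype=float)
    if np.any(~np.isfinite(scores)) or np.any(scores < 0) or np.any(scores > CDAI_MAX):
        bad = scores[~((scores >= 0) & (scores <= CDAI_MAX))]
        raise ValueError(f"CDAI scores outside [0, {CDAI_MAX}]: {bad[:5]!r}")
    # searchsorted with side='left' makes each threshold inclusive below
    return np.searchsorted(np.asarray(scheme.thresholds), scores, side="left")


def collapse_scheme(label: str, src: StateScheme, dst: StateScheme) -> str:
    """Merge a state label from a finer scheme into a nested coarser one.

    Collapsing then classifying equals classifying directly in the coarser
    scheme; non-nested scheme pairs raise.
    """
    key = (src.name, dst.name)
    if src.name == dst.name:
        return label
    if key not in _COLLAPSE:
        raise ValueError(f"{dst.name} is not a coarsening of {src.name}")
    mapping = _COLLAPSE[key]
    if label not in mapping:
        raise ValueError(f"label {label!r} not in scheme {src.name}")
    return mapping[label]
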