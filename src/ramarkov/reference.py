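"""Published 3-state CDAI transition estimates from a large US RA registry.

These numbers are the published headline estimates of the analysis this
package implements: per-visit and 6-month 3-state transition matrices for
the full cohort (~30,000 patients) and for the regular-visit sub-cohort
(every inter-visit gap in 3-9 months), mean sojourn times per state, and
two headline odds ratios from the binary transition regression.  The real
registry is proprietary, so inside this package they serve two roles:

* generator truths for the synthetic registry (parameter-recovery studies
  simulate cohorts from these values and check the estimators get them
  back), and
* fixtures for worked-example arithmetic (row sums, matrix differences).

State order everywhere is (low, moderate, severe).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STATE_ORDER",
    "PERVISIT_FULL",
    "PERVISIT_REGULAR",
    "SIXMONTH_FULL",
    "SIXMONTH_REGULAR",
    "SOJOURN_MONTHS",
    "OR_PRIOR_MODSEV",
    "OR_DURATION_GT10_MODSEV",
    "INTERVAL_LAW_FULL",
    "INTERVAL_LAW_REGULAR",
    "INITIAL_STATE_PROBS",
]

STATE_ORDER = ("low", "moderate", "severe")

# Per-visit transition probabilities (rows: prior state; cols: current state).
PERVISIT_FULL = np.array(
    [
        [0.82, 0.15, 0.03],
        [0.47, 0.35, 0.18],
        [0.13, 0.39, 0.48],
    ]
)

PERVISIT_REGULAR = np.array(
    [
        [0.84, 0.13, 0.03],
        [0.52, 0.33, 0.15],
        [0.16, 0.41, 0.43],
    ]
)

# Transition probabilities standardized to a 6-month interval via the
# continuous-time multi-state fit.
SIXMONTH_FULL = np.array(
    [
        [0.81, 0.15, 0.05],
        [0.46, 0.37, 0.17],
        [0.26, 0.33, 0.41],
    ]
)

SIXMONTH_REGULAR = np.array(
    [
        [0.84, 0.13, 0.03],
        [0.48, 0.38, 0.14],
        [0.28, 0.34, 0.38],
    ]
)

# Mean sojourn time (months) per state: low 19.38, moderate 4.25, severe 5.30.
SOJOURN_MONTHS = {"low": 19.38, "moderate": 4.25, "severe": 5.30}

# Binary (low vs moderate/severe) transition regression, regular sub-cohort:
# odds of a moderate/severe current state for prior moderate/severe vs prior
# low at the reference 3-4 month visit interval ...
OR_PRIOR_MODSEV = 12.4
# ... and for disease duration >10 years (vs 0-3) on *remaining* in
# moderate/severe (the within-stratum, main-plus-interaction contrast).
OR_DURATION_GT10_MODSEV = 1.379

# Inter-visit interval moments (months).  The full cohort's gaps are
# long-tailed; the regular sub-cohort's are confined to [3, 9].
INTERVAL_LAW_FULL = {"mean": 5.4, "sd": 3.1}
INTERVAL_LAW_REGULAR = {"mean": 5.3, "sd": 1.5, "lo": 3.0, "hi": 9.0}

# First-visit CDAI category mix (low, moderate, severe), from the published
# cohort description; used as the default initial-state distribution.
INITIAL_STATE_PROBS = np.array([0.471, 0.283, 0.246]) / 1.000
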