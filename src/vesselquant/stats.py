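"""Group-level statistics for metric samples.

Mirrors the analysis flow used for the n = 20 per-group comparisons: a
Shapiro–Wilk normality check (warn, don't fail, on rejection), then a
two-sample t-test per metric per contrast with the conventional
significance labels (ns, *, **, ***) at 0.05 / 0.01 / 0.001.  No
multiple-testing correction is applied across the five metrics; reports
state this explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "normality_check", "compare_groups", "significance_label"]

log = logging.getLogger(__name__)

_LABELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_label(p: float) -> str:
    for thr, lab in _LABELS:
        if p < thr:
            return lab
    return "ns"


@dataclass
class GroupComparison:
    """Two-sample comparison of one metric between two groups."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    label: str
    shapiro_p_a: float | None = None
    shapiro_p_b: float | None = None
    equal_var: bool = True


def normality_check(sample, warn_alpha: float = 0.05) -> float:
    """Shapiro–Wilk p-value; warns (does not fail) when normality is rejected."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    p = float(sps.shapiro(x).pvalue)
    if p < warn_alpha:
        log.warning("Shapiro-Wilk rejects normality (p=%.4g); "
                    "proceeding with t-test anyway", p)
    return p


def compare_groups(a, b, equal_var: bool = True, check_normality: bool = True
                   ) -> GroupComparison:
    """Two-sample t-test (equal-variance by default; Welch via flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    sp_a = sp_b = None
    if check_normality and len(a) >= 3 and np.ptp(a) > 0:
        sp_a = normality_check(a)
    if check_normality and len(b) >= 3 and np.ptp(b) > 0:
        sp_b = normality_check(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance groups: identical means are maximally
        # non-significant, distinct means maximally significant
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else np.inf
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        t, p, significance_label(p), sp_a, sp_b, equal_var,
    )
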