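"""Group summaries and the comparative statistics reported for bead counts:
per-group mean ± SEM, fold change, percent reduction with delta-method
uncertainty, and a one-tailed Student's (pooled-variance) t-test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleCount",
    "GroupComparison",
    "group_summary",
    "fold_change",
    "percent_reduction",
    "one_tailed_t",
    "compare_groups",
]


@dataclass(frozen=True)
class SampleCount:
    """Bead count for one animal."""

    group_label: str
    animal_id: str
    bead_count: int

    def __post_init__(self) -> None:
        if self.bead_count < 0:
            raise ValueError("bead_count must be >= 0")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of bead counts.

    ``fold_change`` is mean_a / mean_b and ``reduction_percent`` is
    100 * (1 - mean_a / mean_b), i.e. group *a* plays the treated role and
    group *b* the control/reference role; ``reduction_se`` is the
    delta-method standard error of the reduction.  ``p_value`` is one-tailed
    in the direction supplied by the caller.
    """

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    reduction_percent: float
    reduction_se: float
    p_value: float


CountsLike = Union[Sequence[SampleCount], pd.DataFrame]


def _as_frame(counts: CountsLike) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        df = counts.rename(columns={"group": "group_label", "animal": "animal_id",
                                    "count": "bead_count"})
        return df[["group_label", "animal_id", "bead_count"]]
    return pd.DataFrame([
        {"group_label": c.group_label, "animal_id": c.animal_id,
         "bead_count": c.bead_count}
        for c in counts
    ])


def group_summary(counts: CountsLike) -> pd.DataFrame:
    """Per-group n, mean and SEM (sd with n-1 denominator over sqrt(n)).

    A single-sample group gets SEM 0 with ``sem_defined`` False rather than
    NaN, so downstream reports stay numeric.
    """
    df = _as_frame(counts)
    if df.empty:
        raise ValueError("at least one sample is required")
    rows = []
    for label, grp in df.groupby("group_label", sort=True):
        values = grp["bead_count"].to_numpy(dtype=float)
        n = len(values)
        sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"group_label": label, "n": n,
                     "mean": float(values.mean()), "sem": sem,
                     "sem_defined": n > 1})
    return pd.DataFrame(rows).set_index("group_label")


def fold_change(group_a_counts: Iterable[float],
                group_b_counts: Iterable[float]) -> float:
    """Ratio of group means, mean(a) / mean(b)."""
    mean_a = float(np.mean(list(group_a_counts)))
    mean_b = float(np.mean(list(group_b_counts)))
    if mean_b == 0:
        raise ZeroDivisionError("denominator group has zero mean")
    return mean_a / mean_b


def percent_reduction(control_counts: Iterable[float],
                      treated_counts: Iterable[float]) -> Tuple[float, float]:
    """Percent reduction of the treated mean relative to control, with its
    first-order delta-method standard error propagated from the group SEMs.

    Returns ``(reduction_percent, se_percent)`` where reduction is
    ``100 * (1 - mean_treated / mean_control)``.
    """
    control = np.asarray(list(control_counts), dtype=float)
    treated = np.asarray(list(treated_counts), dtype=float)
    mc, mt = control.mean(), treated.mean()
    if mc == 0:
        raise ZeroDivisionError("control group has zero mean")
    sem_c = control.std(ddof=1) / np.sqrt(len(control)) if len(control) > 1 else 0.0
    sem_t = treated.std(ddof=1) / np.sqrt(len(treated)) if len(treated) > 1 else 0.0
    reduction = 100.0 * (1.0 - mt / mc)
    # var(1 - t/c) ~ (sem_t/c)^2 + (t * sem_c / c^2)^2 to first order
    se = 100.0 * np.sqrt((sem_t / mc) ** 2 + (mt * sem_c / mc**2) ** 2)
    return float(reduction), float(se)


def one_tailed_t(group_a: Sequence[float], group_b: Sequence[float],
                 direction: str) -> float:
    """One-tailed pooled-variance Student's t-test p-value.

    ``direction`` states the alternative hypothesis: ``"greater"`` for
    mean(a) > mean(b), ``"less"`` for mean(a) < mean(b).  The direction must
    be fixed a priori by the experimental hypothesis, never chosen from the
    data.  Identical groups give p = 0.5 (zero t-statistic).
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    result = sps.ttest_ind(a, b, equal_var=True, alternative=direction)
    return float(result.pvalue)


def compare_groups(
    treated_counts: Sequence[float],
    control_counts: Sequence[float],
    direction: str,
    label_a: str = "treated",
    label_b: str = "control",
) -> GroupComparison:
    """Assemble the full two-group report (means, SEMs, fold change,
    reduction with delta-method SE, one-tailed p)."""
    a = np.asarray(treated_counts, dtype=float)
    b = np.asarray(control_counts, dtype=float)
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    reduction, se = percent_reduction(b, a)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=sem(a),
        sem_b=sem(b),
        fold_change=fold_change(a, b),
        reduction_percent=reduction,
        reduction_se=se,
        p_value=one_tailed_t(a, b, direction),
    )
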