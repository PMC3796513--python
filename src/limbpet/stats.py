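"""Group-level statistics for the per-arm metrics table.

Mirrors the analysis layer of the study: arm-wise group means,
Student's t-test (paired, pooled and Welch modes — for two groups the
pooled t is the exact equivalent of the unbalanced one-way ANOVA,
F = t^2), unbalanced one-way ANOVA, and Spearman rank correlation with
average ranks for ties. All tests are two-tailed and use the exact
t / F distributions, not normal approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateStatisticsError
from .metrics import SubjectRecord

#: Columns summarised per group, in the order of the published table.
SUMMARY_COLUMNS = (
    "pain_vas",
    "examined_voxels",
    "mean_bq",
    "sd_bq",
    "volume_ml",
    "mean_z",
    "vis",
)


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic column means for one (arm x timepoint) group."""

    arm: str  # "affected" | "unaffected"
    timepoint: str  # "before" | "after"
    n: int
    means: dict[str, float]

    @property
    def label(self) -> str:
        return f"{self.arm} {self.timepoint}"


@dataclass(frozen=True)
class TestResult:
    """A two-tailed test statistic with its degrees of freedom and p-value."""

    statistic: float
    degrees_of_freedom: float
    p_two_tailed: float

    def __post_init__(self) -> None:
        if not (0 < self.p_two_tailed <= 1 or np.isnan(self.p_two_tailed)):
            raise DegenerateStatisticsError(f"p-value out of range: {self.p_two_tailed}")


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records to one row per arm x timepoint."""
    rows = []
    for rec in records:
        for arm_name in ("unaffected", "affected"):
            m = rec.arm(arm_name)
            rows.append(
                {
                    "subject": rec.subject_id,
                    "timepoint": rec.timepoint,
                    "arm": arm_name,
                    "pain_vas": m.pain_vas,
                    "examined_voxels": m.n_voxels_examined,
                    "mean_bq": m.mean_bq,
                    "sd_bq": m.sd_bq,
                    "volume_ml": m.supra_volume_ml,
                    "mean_z": m.supra_mean_z,
                    "vis": m.vis,
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(
    records: Iterable[SubjectRecord] | pd.DataFrame,
) -> list[GroupSummary]:
    """Arithmetic means per column for each (arm, timepoint) group.

    Subjects without an after-treatment examination simply contribute no
    rows to the "after" groups.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise DegenerateStatisticsError("no records to summarise")
    out = []
    for timepoint in ("before", "after"):
        for arm in ("unaffected", "affected"):
            grp = df[(df["timepoint"] == timepoint) & (df["arm"] == arm)]
            if grp.empty:
                continue
            means = {c: float(grp[c].mean()) for c in SUMMARY_COLUMNS if c in grp}
            out.append(GroupSummary(arm=arm, timepoint=timepoint, n=len(grp), means=means))
    if not out:
        raise DegenerateStatisticsError("no non-empty groups")
    return out


def t_test(x: Sequence[float], y: Sequence[float], mode: str = "paired") -> TestResult:
    """Student's t-test between two samples.

    Parameters
    ----------
    x, y : sequences of float
    mode : {"paired", "pooled", "welch"}
        ``paired`` compares within-subject differences (requires equal
        lengths >= 2); ``pooled`` assumes equal variances; ``welch``
        does not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode not in ("paired", "pooled", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "paired":
        if len(x) != len(y) or len(x) < 2:
            raise DegenerateStatisticsError("paired t needs equal lengths >= 2")
        d = x - y
        if np.all(d == d[0]) and d[0] == 0:
            # identical samples: t = 0, p = 1 by convention
            return TestResult(0.0, float(len(x) - 1), 1.0)
        if d.std(ddof=1) == 0:
            raise DegenerateStatisticsError("constant nonzero differences: t undefined")
        res = sps.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise DegenerateStatisticsError("two-sample t needs n >= 2 per group")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise DegenerateStatisticsError("zero variance in both samples")
        res = sps.ttest_ind(x, y, equal_var=(mode == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def oneway_anova_unbalanced(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; group sizes may differ.

    Returns F with (k-1, N-k) degrees of freedom. For two groups this is
    algebraically the pooled two-sample t-test (F = t^2, identical p).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DegenerateStatisticsError("ANOVA needs >= 2 groups")
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    if n_total - k < 1:
        raise DegenerateStatisticsError("insufficient residual degrees of freedom")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise DegenerateStatisticsError("all values identical: F undefined")
    f, p = sps.f_oneway(*arrays)
    return TestResult(float(f), float(n_total - k), float(p))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Equivalent to the Pearson correlation of the two rank vectors; with
    no ties this equals 1 - 6*sum(d^2)/(n(n^2-1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateStatisticsError("Spearman needs equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateStatisticsError("constant sample: rank correlation undefined")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)
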