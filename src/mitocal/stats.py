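"""Group-comparison statistics and the mean ± SE summary format.

Three procedures cover every comparison the pipeline reports: an unpaired
two-tailed Student's t-test (pooled variance) for two numeric groups,
one-way ANOVA for three or more, and a two-sided Fisher's exact test for
binary outcomes (fused yes/no, SR contact yes/no) tabulated per object.
Group summaries are mean ± SE (sample SD/√n); censored clearance values
are excluded with the exclusion count reported.  No multiple-testing
correction is applied: p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "TestResult",
    "ttest_unpaired",
    "anova_oneway",
    "fisher_exact",
    "summarize_groups",
]


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    se: float  # sample SD / sqrt(n)
    n_censored_excluded: int = 0


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...] | None  # None for exact tests
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def _as_array(values, name: str) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return a


def ttest_unpaired(group_a, group_b, welch: bool = False) -> TestResult:
    """Unpaired two-tailed Student's t-test (pooled variance by default).

    ``welch=True`` switches to Welch's unequal-variance form
    (Welch–Satterthwaite df).
    """
    a = _as_array(group_a, "group_a")
    b = _as_array(group_b, "group_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("pooled variance is zero; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(a.size + b.size - 2)
    return TestResult(
        test_name="welch_t" if welch else "student_t",
        statistic=float(res.statistic),
        df=(df,),
        p=float(res.pvalue),
    )


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA across two or more groups."""
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(a.std(ddof=1) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("all values identical; ANOVA undefined")
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    # identical groups give F = 0 and p exactly 1
    f = float(res.statistic)
    p = float(res.pvalue)
    return TestResult(test_name="anova_oneway", statistic=f, df=(k - 1, n_total - k), p=p)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding the observed table's
    (probability-mass rule, with a small relative tolerance for ties).
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if tab.sum() < 1:
        raise ValueError("table total must be >= 1")
    res = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult(
        test_name="fisher_exact",
        statistic=float(res.statistic),
        df=None,
        p=float(min(res.pvalue, 1.0)),
    )


def _group_stats(label: str, values: np.ndarray, n_censored: int = 0) -> GroupStats:
    n = values.size
    if n < 1:
        raise ValueError(f"group {label!r} has no usable values")
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupStats(label=label, n=n, mean=float(values.mean()),
                      se=se, n_censored_excluded=n_censored)


def summarize_groups(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    censored_col: str | None = None,
) -> tuple[list[GroupStats], list[TestResult]]:
    """Per-group mean ± SE plus the appropriate comparison test.

    Numeric metrics get a t-test (2 groups) or one-way ANOVA (>= 3);
    boolean metrics get pairwise Fisher's exact tests on the per-object
    2x2 tables.  Rows flagged in ``censored_col`` are excluded from the
    summary and their count reported per group.
    """
    if group_col not in data.columns:
        raise ValueError(f"missing group column {group_col!r}")
    labels = list(pd.unique(data[group_col]))
    is_bool = (
        data[value_col].dtype == bool
        or set(data[value_col].dropna().unique()) <= {0, 1, True, False}
        and data[value_col].dtype != float
    )

    stats_out: list[GroupStats] = []
    per_group: dict[str, np.ndarray] = {}
    for lab in labels:
        sub = data[data[group_col] == lab]
        n_cens = 0
        if censored_col is not None and censored_col in sub.columns:
            n_cens = int(sub[censored_col].sum())
            sub = sub[~sub[censored_col].astype(bool)]
        vals = sub[value_col].dropna().to_numpy(dtype=float)
        per_group[lab] = vals
        stats_out.append(_group_stats(str(lab), vals, n_cens))

    tests: list[TestResult] = []
    if is_bool:
        for la, lb in combinations(labels, 2):
            a, b = per_group[la], per_group[lb]
            tab = [
                [int(a.sum()), int(a.size - a.sum())],
                [int(b.sum()), int(b.size - b.sum())],
            ]
            tests.append(fisher_exact(tab))
    elif len(labels) == 2:
        tests.append(ttest_unpaired(per_group[labels[0]], per_group[labels[1]]))
    elif len(labels) >= 3:
        tests.append(anova_oneway([per_group[lab] for lab in labels]))
    return stats_out, tests
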