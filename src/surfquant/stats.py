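"""Group comparisons for replicate-level surface-delivery metrics.

All tests operate on replicate-level values (one value per biological
replicate per sample): an unequal-variance Welch t-test for single pairs,
Dunnett's many-to-one test for several treatments against one control,
Tukey's all-pairs studentized-range test, and the Pearson correlation.

Tail direction is always an explicit parameter — for one-tailed tests the
alternative is that the treatment is *greater* than (or *less* than) the
control, never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "TestResult",
    "welch_t",
    "dunnett",
    "tukey",
    "pearson",
    "results_to_frame",
]


@dataclass(frozen=True)
class GroupData:
    """Replicate-level values for one sample/construct."""

    group_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class TestResult:
    comparison: tuple[str, str]
    statistic: float
    p_value: float
    tails: str  # "one" | "two"
    method: str  # "welch" | "dunnett" | "tukey" | "pearson"


def _check_group(values, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < min_n:
        raise ValueError(f"group {name!r} needs >= {min_n} values, got {arr.size}")
    return arr


def welch_t(
    a,
    b,
    tails: str = "one",
    direction: str = "greater",
    labels: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
    freedom.

    ``direction`` states the one-tailed alternative for group ``a`` relative
    to ``b`` (``"greater"`` or ``"less"``); it is ignored for two-tailed
    tests.
    """
    a = _check_group(a, labels[0])
    b = _check_group(b, labels[1])
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    alternative = "two-sided" if tails == "two" else direction
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(
        comparison=labels,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tails=tails,
        method="welch",
    )


def dunnett(
    control: GroupData,
    treatments: list[GroupData],
    tails: str = "one",
    direction: str = "greater",
) -> list[TestResult]:
    """Dunnett's many-to-one comparisons against a shared control.

    Family-wise-adjusted p-values under the many-to-one multivariate t
    distribution with a pooled (homogeneous-variance) error term from the
    one-way layout.  With a single treatment group this reduces to the
    pooled-variance two-sample t-test.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    ctrl = _check_group(control.values, control.group_id)
    samples = [_check_group(t.values, t.group_id) for t in treatments]
    if not samples:
        raise ValueError("need at least one treatment group")
    alternative = "two-sided" if tails == "two" else direction
    if len(samples) == 1:
        # one treatment: the many-to-one multivariate t is 1-D, i.e. exactly
        # the pooled-variance Student t — evaluate it exactly instead of by
        # the randomized quadrature used for k > 1
        t = samples[0]
        df = t.size + ctrl.size - 2
        s2 = (
            (t.size - 1) * t.var(ddof=1) + (ctrl.size - 1) * ctrl.var(ddof=1)
        ) / df
        stat = (t.mean() - ctrl.mean()) / np.sqrt(s2 * (1 / t.size + 1 / ctrl.size))
        if alternative == "two-sided":
            p = 2.0 * sps.t.sf(abs(stat), df)
        elif alternative == "greater":
            p = sps.t.sf(stat, df)
        else:
            p = sps.t.cdf(stat, df)
        return [
            TestResult(
                comparison=(treatments[0].group_id, control.group_id),
                statistic=float(stat),
                p_value=float(min(p, 1.0)),
                tails=tails,
                method="dunnett",
            )
        ]
    # fixed rng: the multivariate-t integral is evaluated by randomized
    # quadrature; pinning the stream keeps re-runs byte-identical
    res = sps.dunnett(
        *samples, control=ctrl, alternative=alternative,
        rng=np.random.default_rng(171717),
    )
    return [
        TestResult(
            comparison=(t.group_id, control.group_id),
            statistic=float(s),
            p_value=float(min(p, 1.0)),
            tails=tails,
            method="dunnett",
        )
        for t, s, p in zip(treatments, res.statistic, res.pvalue)
    ]


def tukey(groups: list[GroupData]) -> list[TestResult]:
    """Tukey's all-pairs comparisons (studentized-range adjusted, two-tailed)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [_check_group(g.values, g.group_id) for g in groups]
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(
                TestResult(
                    comparison=(groups[i].group_id, groups[j].group_id),
                    statistic=float(res.statistic[i, j]),
                    p_value=float(res.pvalue[i, j]),
                    tails="two",
                    method="tukey",
                )
            )
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-tailed p-value from the t transform.

    Requires ``n >= 3`` and non-constant inputs (r is undefined otherwise).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy table of test results."""
    return pd.DataFrame(
        {
            "group_a": [r.comparison[0] for r in results],
            "group_b": [r.comparison[1] for r in results],
            "method": [r.method for r in results],
            "tails": [r.tails for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
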