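"""Study-level aggregation and group comparisons.

Per-image metric values are first averaged per mouse within each
(day, region) cell, so the mouse — not the image — is the statistical
unit. Group comparisons (wild-type vs TNF-overexpressing line; day vs day
within a line) then run on the per-mouse means through a normality-gated
procedure: Shapiro–Wilk per group; if either group is non-normal, the
values are natural-log transformed and re-tested; the two-sample test is
Welch's t-test on the (possibly transformed) values. Multi-day comparisons
report raw p-values alongside Holm-adjusted ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MOUSE_LINES = ("wild_type", "tnf_overexpressing")
STUDY_DAYS = (3, 7, 14)
REGIONS = ("CA3", "CA1_2", "DG")

_REQUIRED_COLUMNS = ("mouse", "line", "day", "region", "metric", "value")

#: significance level of the Shapiro–Wilk normality gate
NORMALITY_ALPHA = 0.05


def validate_study_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy per-image study table.

    Expected columns: mouse, line, day, region, metric, value — one row per
    image measurement.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"study frame missing columns {missing}")
    if frame.empty:
        raise ValueError("study frame is empty")
    if not np.isfinite(frame["value"].to_numpy(dtype=float)).all():
        raise ValueError("metric values must be finite")
    bad_lines = set(frame["line"]) - set(MOUSE_LINES)
    if bad_lines:
        raise ValueError(f"unknown mouse lines {sorted(bad_lines)}")
    return frame


def aggregate(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse mean over images within (mouse, line, day, region, metric)."""
    validate_study_frame(frame)
    out = (
        frame.groupby(["mouse", "line", "day", "region", "metric"], as_index=False)[
            "value"
        ]
        .mean()
        .rename(columns={"value": "mean_value"})
    )
    return out


@dataclass(frozen=True)
class LineComparison:
    """Result of one wild-type vs transgenic comparison."""

    metric: str
    day: int
    region: str
    n_a: int
    n_b: int
    log_transformed: bool
    shapiro_p: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float


def _normality_gate(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool, tuple[float, float]]:
    """Shapiro–Wilk gate: log-transform both groups if either is non-normal."""
    pa = float(stats.shapiro(a).pvalue)
    pb = float(stats.shapiro(b).pvalue)
    if pa >= NORMALITY_ALPHA and pb >= NORMALITY_ALPHA:
        return a, b, False, (pa, pb)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("non-positive values cannot be log-transformed")
    la, lb = np.log(a), np.log(b)
    pa = float(stats.shapiro(la).pvalue)
    pb = float(stats.shapiro(lb).pvalue)
    return la, lb, True, (pa, pb)


def compare_lines(
    table: pd.DataFrame,
    metric: str,
    day: int,
    region: str,
) -> LineComparison:
    """Compare the two mouse lines on per-mouse means for one metric cell.

    ``table`` is the output of :func:`aggregate`. Both lines need at least
    3 mice. Welch's t-test is used (variances may differ between lines).
    """
    sel = table[
        (table["metric"] == metric) & (table["day"] == day) & (table["region"] == region)
    ]
    a = sel[sel["line"] == MOUSE_LINES[0]]["mean_value"].to_numpy(dtype=float)
    b = sel[sel["line"] == MOUSE_LINES[1]]["mean_value"].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each line needs at least 3 mice")
    ta, tb, logged, shapiro_p = _normality_gate(a, b)
    res = stats.ttest_ind(ta, tb, equal_var=False)
    return LineComparison(
        metric=metric,
        day=day,
        region=region,
        n_a=len(a),
        n_b=len(b),
        log_transformed=logged,
        shapiro_p=shapiro_p,
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class TimeCourse:
    """Per-day summary and pairwise day comparisons for one line/region."""

    metric: str
    line: str
    region: str
    day_means: dict[int, float]
    day_n: dict[int, int]
    comparisons: tuple[dict, ...]  # day_a, day_b, t, df, p_raw, p_holm, log_transformed


def time_course(
    table: pd.DataFrame,
    metric: str,
    line: str,
    region: str,
) -> TimeCourse:
    """Analyze a metric over culture days within one line and region.

    Per-day means over mice plus all pairwise day-vs-day comparisons using
    the same normality-gated Welch procedure; pairwise p-values are
    reported raw and Holm-adjusted.
    """
    sel = table[
        (table["metric"] == metric)
        & (table["line"] == line)
        & (table["region"] == region)
    ]
    days = sorted(sel["day"].unique())
    if len(days) < 2:
        raise ValueError("time course needs at least two days")
    groups = {
        int(day): sel[sel["day"] == day]["mean_value"].to_numpy(dtype=float)
        for day in days
    }
    comparisons = []
    raw = []
    for i, da in enumerate(days):
        for db in days[i + 1 :]:
            ga, gb = groups[int(da)], groups[int(db)]
            if len(ga) < 3 or len(gb) < 3:
                raise ValueError("each day needs at least 3 mice")
            ta, tb, logged, _ = _normality_gate(ga, gb)
            res = stats.ttest_ind(ta, tb, equal_var=False)
            comparisons.append(
                {
                    "day_a": int(da),
                    "day_b": int(db),
                    "t": float(res.statistic),
                    "df": float(res.df),
                    "p_raw": float(res.pvalue),
                    "log_transformed": logged,
                }
            )
            raw.append(res.pvalue)
    _, adj, _, _ = multipletests(raw, method="holm")
    for rec, p_adj in zip(comparisons, adj):
        rec["p_holm"] = float(p_adj)
    return TimeCourse(
        metric=metric,
        line=line,
        region=region,
        day_means={int(d): float(groups[int(d)].mean()) for d in days},
        day_n={int(d): int(len(groups[int(d)])) for d in days},
        comparisons=tuple(comparisons),
    )
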