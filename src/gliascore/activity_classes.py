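"""Activity-state classification of microglia from relative nucleus area.

Microglia shift from a ramified (resting) morphology through hyper-ramified
and bushy stages to an amoeboid (fully activated) one, and the relative
area of the nucleus (percent of total image area) grows along that axis.
The classifier is built in two steps:

1. per labeled state, fit the mean relative nucleus area and its two-sided
   95% t-confidence interval (mean ± t_{0.975, n-1} · s / sqrt(n));
2. merge states whose intervals overlap (transitive closure) into groups;
   the decision boundary between adjacent groups is the midpoint of the
   gap between their effective intervals.

On the published calibration set of 197 visually staged cells this merging
collapses ramified and hyper-ramified into one group, leaving three
distinguishable activity stages. ``REFERENCE_STATE_TABLE`` carries that
calibration (per-state n, mean and 95% CI bounds) so the reference
classifier can be rebuilt without raw data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

STATE_LABELS = ("ramified", "hyper_ramified", "bushy", "amoeboid")

#: Published calibration of the four activity states on 197 visually staged
#: microglia: label -> (n, mean relative nucleus area %, CI low, CI high).
REFERENCE_STATE_TABLE: dict[str, tuple[int, float, float, float]] = {
    "ramified": (14, 0.20, 0.15, 0.25),
    "hyper_ramified": (102, 0.16, 0.15, 0.18),
    "bushy": (68, 0.41, 0.39, 0.44),
    "amoeboid": (13, 0.70, 0.59, 0.81),
}


@dataclass(frozen=True)
class ActivityState:
    """One activity state's fitted nucleus-area interval."""

    label: str
    n: int
    mean_rel_area: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("state needs at least one sample")
        if not self.ci_low <= self.mean_rel_area <= self.ci_high:
            raise ValueError("CI must bracket the mean")

    def overlaps(self, other: "ActivityState") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


@dataclass(frozen=True)
class MergedGroup:
    labels: tuple[str, ...]
    interval: tuple[float, float]  # [min ci_low, max ci_high] over members

    @property
    def name(self) -> str:
        return "+".join(self.labels)


@dataclass(frozen=True)
class MergedClassifier:
    """Ordered merged activity groups with midpoint decision boundaries."""

    groups: tuple[MergedGroup, ...]
    boundaries: tuple[float, ...]  # len(groups) - 1, ascending

    def __post_init__(self) -> None:
        lows = [g.interval[0] for g in self.groups]
        if lows != sorted(lows):
            raise ValueError("groups must be ordered by interval")
        for a, b in zip(self.groups, self.groups[1:]):
            if a.interval[1] >= b.interval[0]:
                raise ValueError("merged group intervals must be disjoint")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": [
                    {"labels": list(g.labels), "interval": list(g.interval)}
                    for g in self.groups
                ],
                "boundaries": list(self.boundaries),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MergedClassifier":
        obj = json.loads(text)
        return cls(
            groups=tuple(
                MergedGroup(labels=tuple(g["labels"]), interval=tuple(g["interval"]))
                for g in obj["groups"]
            ),
            boundaries=tuple(obj["boundaries"]),
        )


def t_interval(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and two-sided t-confidence interval of a sample.

    Returns (mean, low, high). A zero-variance sample yields a degenerate
    interval [mean, mean].
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two samples for a t-interval")
    mean = float(values.mean())
    s = float(values.std(ddof=1))
    # an all-equal sample is degenerate even when the mean picks up float noise
    if s == 0.0 or np.ptp(values) == 0.0:
        return mean, mean, mean
    half = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1)) * s / math.sqrt(n)
    return mean, mean - half, mean + half


def fit_state_intervals(
    samples: Mapping[str, Sequence[float]], confidence: float = 0.95
) -> list[ActivityState]:
    """Fit per-state mean and 95% t-CI of relative nucleus areas.

    ``samples`` maps state label -> per-cell relative nucleus areas (%).
    """
    states = []
    for label, values in samples.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError(f"state {label!r} has fewer than 2 samples")
        mean, low, high = t_interval(values, confidence)
        states.append(
            ActivityState(
                label=label, n=values.size, mean_rel_area=mean, ci_low=low, ci_high=high
            )
        )
    return states


def states_from_table(
    table: Mapping[str, tuple[int, float, float, float]] = REFERENCE_STATE_TABLE,
) -> list[ActivityState]:
    """Build ActivityStates from a printed (n, mean, ci_low, ci_high) table."""
    return [
        ActivityState(label=label, n=n, mean_rel_area=mean, ci_low=lo, ci_high=hi)
        for label, (n, mean, lo, hi) in table.items()
    ]


def merge_overlapping(states: Sequence[ActivityState]) -> MergedClassifier:
    """Merge states whose 95% CIs overlap (transitive closure) into groups.

    Groups are ordered by mean; each group's effective interval is the union
    hull [min ci_low, max ci_high] of its members, and the boundary between
    adjacent groups is the midpoint of the gap between their intervals.
    """
    if not states:
        raise ValueError("need at least one state")
    ordered = sorted(states, key=lambda s: s.mean_rel_area)
    # union-find over pairwise overlap
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if ordered[i].overlaps(ordered[j]):
                parent[find(i)] = find(j)

    members: dict[int, list[ActivityState]] = {}
    for i, state in enumerate(ordered):
        members.setdefault(find(i), []).append(state)

    groups = sorted(
        (
            MergedGroup(
                labels=tuple(s.label for s in group),
                interval=(min(s.ci_low for s in group), max(s.ci_high for s in group)),
            )
            for group in members.values()
        ),
        key=lambda g: g.interval[0],
    )
    boundaries = tuple(
        (a.interval[1] + b.interval[0]) / 2.0 for a, b in zip(groups, groups[1:])
    )
    return MergedClassifier(groups=tuple(groups), boundaries=boundaries)


def reference_classifier() -> MergedClassifier:
    """The classifier rebuilt from the published calibration table."""
    return merge_overlapping(states_from_table())


def classify_cell(rel_area: float, classifier: MergedClassifier) -> str:
    """Assign a relative nucleus area (%) to a merged activity group.

    Values inside a group interval map to that group; values in a gap go to
    the nearer boundary's group, with midpoint ties broken toward the lower
    group; out-of-range values clamp to the extreme groups.
    """
    if not math.isfinite(rel_area):
        raise ValueError("rel_area must be finite")
    for boundary, group in zip(classifier.boundaries, classifier.groups):
        if rel_area <= boundary:
            return group.name
    return classifier.groups[-1].name


def assign_activity_classes(records, classifier: MergedClassifier | None = None):
    """Fill ``activity_class`` on a list of MicrogliaRecords, in place."""
    clf = classifier or reference_classifier()
    for rec in records:
        rec.activity_class = classify_cell(rec.nucleus.relative_area_pct, clf)
    return records


@dataclass(frozen=True)
class SeparationReport:
    """Kruskal–Wallis plus pairwise rank-sum validation of state separation."""

    h_statistic: float
    p_value: float
    pairwise: tuple[dict, ...]  # label_a, label_b, u, p_raw, p_holm


def validate_separation(samples: Mapping[str, Sequence[float]]) -> SeparationReport:
    """Test whether the labeled states differ in relative nucleus area.

    Runs a Kruskal–Wallis test over all states, then all pairwise
    Mann–Whitney rank-sum tests, reporting raw and Holm-adjusted p-values.
    """
    labels = [k for k in samples]
    groups = [np.asarray(samples[k], dtype=float) for k in labels]
    if len(groups) < 2:
        raise ValueError("need at least two states")
    for label, g in zip(labels, groups):
        if g.size < 2:
            raise ValueError(f"state {label!r} has fewer than 2 samples")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate all-tied data")
    h, p = stats.kruskal(*groups)
    pairs = []
    raw = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u, pu = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            pairs.append({"label_a": labels[i], "label_b": labels[j], "u": float(u), "p_raw": float(pu)})
            raw.append(pu)
    _, adj, _, _ = multipletests(raw, method="holm")
    for rec, p_adj in zip(pairs, adj):
        rec["p_holm"] = float(p_adj)
    return SeparationReport(h_statistic=float(h), p_value=float(p), pairwise=tuple(pairs))


def state_sd_from_ci(n: int, mean: float, ci_high: float, confidence: float = 0.95) -> float:
    """Back-compute the sample SD from a printed t-CI half-width.

    s = sqrt(n) * (ci_high - mean) / t_{0.975, n-1}; used to parameterize
    class-conditional generators from the printed calibration table.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return math.sqrt(n) * (ci_high - mean) / tcrit
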