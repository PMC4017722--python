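"""Correlation-based evaluation of individual prediction systems.

A prediction system is judged by the Pearson correlation r between
experimental and estimated activities over a fixed inhibitor set — r_train on
the training set, r_test on the testing set. Activities span several orders
of magnitude, so the default (and the scale that reproduces the study's
reported correlations) is log10-transformed IC50; the raw nM scale is kept as
an option.

Also here: the four training/testing-split selection rules used by the source
study — (1) complete records, (2) at least 16 training inhibitors, (3) the
training set contains the most- and least-active inhibitor overall, (4) the
training activities span at least 4 orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CoverageError, DegenerateInputError
from .io import ActivityTable, ScoreTable

__all__ = [
    "SystemPerformance",
    "SplitReport",
    "to_log_activity",
    "pearson_r",
    "evaluate_system",
    "validate_training_split",
]


@dataclass(frozen=True)
class SystemPerformance:
    """Pearson correlation of one system against experiment.

    ``scale`` records whether r was computed on log10 or raw activities.
    """

    label: str
    n: int
    r: float
    scale: str = "log10"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class SplitReport:
    """Outcome of the training/testing split validation rules."""

    n_train: int
    span_orders: float
    has_most_active: bool
    has_least_active: bool
    rule_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.rule_flags.values())


def to_log_activity(value):
    """log10 of an activity in nM; the working scale for all correlations.

    Accepts a scalar or array; non-positive input raises ``ValueError``.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("activities must be positive to take log10")
    out = np.log10(arr)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _aligned_scores(
    pred: ScoreTable, exptl: ActivityTable, missing: str
) -> tuple[np.ndarray, np.ndarray, int]:
    absent = pred.covers(exptl.ids)
    if absent and missing == "strict":
        raise CoverageError(
            f"system {pred.label!r} is missing predictions for "
            f"{len(absent)} ids: {absent[:10]}{'…' if len(absent) > 10 else ''}",
            missing=absent,
        )
    ids = [i for i in exptl.ids if i not in set(absent)]
    x = np.array([exptl.activities[i] for i in ids])
    y = np.array([pred[i] for i in ids])
    return x, y, len(ids)


def evaluate_system(
    pred: ScoreTable,
    exptl: ActivityTable,
    scale: str = "log10",
    missing: str = "strict",
) -> SystemPerformance:
    """Correlate one system's estimates with experiment over a table's ids.

    ``missing="strict"`` (default) raises :class:`CoverageError` if any id of
    ``exptl`` lacks a prediction; ``missing="pairwise"`` drops uncovered ids
    and reports the reduced n (exploratory use only).
    """
    if scale not in ("log10", "raw"):
        raise ValueError(f"unknown scale {scale!r}")
    if missing not in ("strict", "pairwise"):
        raise ValueError(f"unknown missing-data mode {missing!r}")
    x, y, n = _aligned_scores(pred, exptl, missing)
    if scale == "log10":
        x, y = to_log_activity(x), to_log_activity(y)
    return SystemPerformance(label=pred.label, n=n, r=pearson_r(x, y), scale=scale)


def validate_training_split(
    train: ActivityTable,
    test: ActivityTable,
    min_n: int = 16,
    min_span_orders: float = 4.0,
) -> SplitReport:
    """Check a train/test split against the study's four selection rules.

    Rule 1 (complete records) is enforced structurally by the data model, so
    it is reported as the absence of id overlap between the two sets; rules
    2–4 are the size, extreme-membership, and activity-span requirements.
    Violations are reported as flags, not exceptions.
    """
    if not train.records or not test.records:
        raise ValueError("both train and test tables must be non-empty")
    train_acts = [r.ic50_nM for r in train.records]
    all_acts = train_acts + [r.ic50_nM for r in test.records]
    span = math.log10(max(train_acts) / min(train_acts))
    has_most = min(train_acts) == min(all_acts)  # most active = lowest IC50
    has_least = max(train_acts) == max(all_acts)
    overlap = set(train.ids) & set(test.ids)
    flags = {
        "disjoint_ids": not overlap,
        "min_training_size": train.t >= min_n,
        "contains_extremes": has_most and has_least,
        "activity_span": span >= min_span_orders,
    }
    return SplitReport(
        n_train=train.t,
        span_orders=span,
        has_most_active=has_most,
        has_least_active=has_least,
        rule_flags=flags,
    )
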