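"""Youden-optimal short-scale cutoffs reproducing full-scale decision rules.

Each titration decision rule on the full MNAS scale defines a binary
indicator at every metrics row — e.g. "24-h average score < 8" or "single
score >= 12".  To replace the rule with a short-scale (sMNAS-9) counterpart,
the matching short-scale metric (24-h average for 24-h average, sum-of-3 for
sum-of-3, single score for single score) is treated as a continuous
predictor of that indicator, and the optimal dichotomizing cutoff is the
point on the empirical ROC curve maximizing the Youden index
J = sensitivity + specificity - 1.

Candidate cutoffs are the distinct observed predictor values (plus a
sentinel that classifies nothing as positive); the classification rule is
oriented to mirror the full-scale comparator (``>=``-type indicators use
"predictor >= c", ``<``/``<=``-type use "predictor <= c").  Ties are broken
toward the smallest maximizing cutoff, which is deterministic and favors
sensitivity for treatment-escalation rules.  Rounding (one decimal for 24-h
averages, integers for sums and single scores) is applied only to the
*reported* cutoff, after optimization.

A depth-1 classification tree (decision stump, Gini impurity) is provided as
an independent cross-check of each threshold; the Youden optimum is the
authoritative cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .engine import FULL_INDICATOR_THRESHOLDS


@dataclass(frozen=True)
class IndicatorSpec:
    """One full-scale decision-rule indicator (label definition)."""

    name: str            # "i" .. "vi"
    metric: str          # "avg24" | "sum3" | "single_score"
    comparator: str      # "<", "<=", ">=", ">"
    full_threshold: float

    @property
    def orientation(self) -> str:
        """Direction of the matching short-scale classification rule."""
        return "<=" if self.comparator in ("<", "<=") else ">="

    @property
    def full_column(self) -> str:
        return {"avg24": "avg24_full", "sum3": "sum3_full",
                "single_score": "full_score"}[self.metric]

    @property
    def short_column(self) -> str:
        return {"avg24": "avg24_short", "sum3": "sum3_short",
                "single_score": "short_score"}[self.metric]

    @property
    def round_decimals(self) -> int:
        # 24-h-average cutoffs are reported to the nearest tenth,
        # sum and single-score cutoffs to integers
        return 1 if self.metric == "avg24" else 0


FULL_INDICATORS: tuple[IndicatorSpec, ...] = tuple(
    IndicatorSpec(name, metric, comp, thr)
    for name, (metric, comp, thr) in FULL_INDICATOR_THRESHOLDS.items()
)


@dataclass(frozen=True)
class CutoffResult:
    indicator: str
    short_metric: str
    direction: str
    cutoff: float            # value from the candidate grid
    cutoff_reported: float   # rounded for reporting
    youden: float
    train_sensitivity: float
    train_specificity: float
    n_positive: int
    n_negative: int
    stump_cutoff: float | None = None


class DegenerateLabelsError(ValueError):
    """Both classes must be present to trace an ROC curve."""


def make_labels(
    metrics: pd.DataFrame, spec: IndicatorSpec
) -> tuple[pd.Series, int]:
    """Binary labels of the full-scale indicator; drops rows missing the metric.

    Returns ``(labels, n_dropped)``; labels are indexed by the kept rows so
    the matching predictor can be aligned on the same index.
    """
    col = metrics[spec.full_column]
    keep = col.notna()
    n_dropped = int((~keep).sum())
    import operator

    ops = {"<": operator.lt, "<=": operator.le, ">=": operator.ge, ">": operator.gt}
    labels = ops[spec.comparator](col[keep], spec.full_threshold).astype(int)
    return labels, n_dropped


def _class_sorted(labels: np.ndarray, predictor: np.ndarray):
    labels = np.asarray(labels)
    predictor = np.asarray(predictor, dtype=float)
    if labels.shape != predictor.shape:
        raise ValueError("labels and predictor must have equal length")
    pos = np.sort(predictor[labels == 1])
    neg = np.sort(predictor[labels == 0])
    if pos.size == 0 or neg.size == 0:
        raise DegenerateLabelsError("degenerate ROC: only one class present")
    return pos, neg


def empirical_roc(labels, predictor, orientation: str = ">=") -> pd.DataFrame:
    """Sensitivity/specificity at every candidate cutoff.

    Candidates are the distinct observed predictor values plus a sentinel
    cutoff at which nothing is classified positive (+inf for ``>=``
    orientation, -inf for ``<=``).
    """
    pos, neg = _class_sorted(labels, predictor)
    values = np.unique(np.concatenate([pos, neg]))
    if orientation == ">=":
        cand = np.concatenate([values, [np.inf]])
        sens = (pos.size - np.searchsorted(pos, cand, side="left")) / pos.size
        spec = np.searchsorted(neg, cand, side="left") / neg.size
    elif orientation == "<=":
        cand = np.concatenate([[-np.inf], values])
        sens = np.searchsorted(pos, cand, side="right") / pos.size
        spec = (neg.size - np.searchsorted(neg, cand, side="right")) / neg.size
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return pd.DataFrame(
        {"cutoff": cand, "sensitivity": sens, "specificity": spec}
    )


def youden_optimal_cutoff(
    labels,
    predictor,
    orientation: str = ">=",
    round_decimals: int | None = None,
    indicator: str = "",
    short_metric: str = "",
) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1 on the empirical ROC.

    Ties are broken toward the smallest maximizing cutoff.  Sentinel cutoffs
    (classify-nothing) can only win when no finite cutoff beats chance; the
    smallest-cutoff tie-break keeps the result finite whenever possible.
    """
    roc = empirical_roc(labels, predictor, orientation)
    j = roc["sensitivity"].to_numpy() + roc["specificity"].to_numpy() - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    cand = roc["cutoff"].to_numpy()
    pick = best[np.argmin(cand[best])]
    cutoff = float(cand[pick])
    reported = cutoff
    if round_decimals is not None and math.isfinite(cutoff):
        reported = round(cutoff, round_decimals)
        if round_decimals == 0:
            reported = float(int(reported))
    labels = np.asarray(labels)
    return CutoffResult(
        indicator=indicator,
        short_metric=short_metric,
        direction=orientation,
        cutoff=cutoff,
        cutoff_reported=reported,
        youden=float(j[pick]),
        train_sensitivity=float(roc["sensitivity"].iloc[pick]),
        train_specificity=float(roc["specificity"].iloc[pick]),
        n_positive=int((labels == 1).sum()),
        n_negative=int((labels == 0).sum()),
    )


def stump_cutoff(labels, predictor) -> float | None:
    """Depth-1 CART (Gini) split threshold; ``None`` if no informative split.

    Cross-check only: the split is a midpoint between adjacent observed
    values, whereas the Youden cutoff is an observed value, so the two agree
    as partitions rather than as numbers.
    """
    _class_sorted(labels, predictor)  # degenerate-labels check
    x = np.asarray(predictor, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
    if tree.tree_.node_count == 1:
        return None
    return float(tree.tree_.threshold[0])


def derive_all(
    metrics: pd.DataFrame,
    specs: Sequence[IndicatorSpec] = FULL_INDICATORS,
    with_stump: bool = True,
) -> list[CutoffResult]:
    """One Youden-optimal short-scale cutoff per full-scale indicator.

    Pairs each indicator with the same-form short-scale metric and pools
    observations across infants (training-set rows only should be passed).
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    results = []
    for spec in specs:
        labels, _ = make_labels(metrics, spec)
        pred = metrics.loc[labels.index, spec.short_column]
        keep = pred.notna()
        labels, pred = labels[keep], pred[keep]
        if len(labels) == 0:
            raise ValueError(f"no usable rows for indicator {spec.name}")
        res = youden_optimal_cutoff(
            labels.to_numpy(),
            pred.to_numpy(dtype=float),
            orientation=spec.orientation,
            round_decimals=spec.round_decimals,
            indicator=spec.name,
            short_metric=spec.metric,
        )
        if with_stump:
            res = CutoffResult(
                **{**res.__dict__, "stump_cutoff": stump_cutoff(
                    labels.to_numpy(), pred.to_numpy(dtype=float))}
            )
        results.append(res)
    return results


def cutoffs_to_frame(results: Iterable[CutoffResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
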