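"""Train/test evaluation of short-scale rules against full-scale rules.

Infants (not observations) are split into training and test sets by
independent Bernoulli draws, cutoffs are derived on training-set rows only,
and agreement of the short-scale rules with the full-scale "gold standard"
rules is measured on test-set rows as sensitivity and specificity with
bootstrap percentile confidence intervals.

Two bootstrap units are offered, because within-infant observations are
autocorrelated and the appropriate unit is a modeling choice:

* ``observation`` (default): observations are resampled with replacement
  within each label class (stratified, mirroring common ROC-bootstrap
  practice).  For binary predictions this is carried out through the exact
  binomial identity — resampling n_k exchangeable Bernoulli outcomes with
  replacement gives Binomial(n_k, p-hat_k) successes — which is
  distributionally identical to index resampling and much faster.
* ``infant``: whole infants are resampled with replacement (clustered
  bootstrap); degenerate resamples missing a class are redrawn and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cutoffs import (
    FULL_INDICATORS,
    CutoffResult,
    IndicatorSpec,
    make_labels,
)


class LeakageError(RuntimeError):
    """Training and test infants overlap."""


def split_infants(ids: Iterable, p: float = 0.5, seed: int = 0) -> pd.Series:
    """Assign each infant independently to train (probability ``p``) or test.

    Deterministic given ``seed`` and the *set* of ids (ids are sorted before
    drawing, so input order does not matter).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    uniq = sorted(set(ids))
    rng = np.random.default_rng(seed)
    draw = rng.random(len(uniq)) < p
    return pd.Series(
        np.where(draw, "train", "test"), index=pd.Index(uniq, name="infant_id"),
        name="split",
    )


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with label = full-scale rule, prediction = short rule."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return tp, fp, tn, fn


def sens_spec(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    tp, fp, tn, fn = counts
    if tp + fn == 0:
        raise ValueError("no positives")
    if tn + fp == 0:
        raise ValueError("no negatives")
    return tp / (tp + fn), tn / (tn + fp)


@dataclass(frozen=True)
class EvaluationResult:
    indicator: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sens_ci_low: float
    sens_ci_high: float
    spec_ci_low: float
    spec_ci_high: float
    n_boot: int
    ci_level: float
    seed: int
    unit: str
    n_degenerate_redraws: int = 0


def bootstrap_ci(
    labels,
    predictions,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    unit: str = "observation",
    infant_ids=None,
    indicator: str = "",
) -> EvaluationResult:
    """Percentile bootstrap CIs for sensitivity and specificity.

    Point estimates are computed once from the data and do not depend on the
    bootstrap seed; only the intervals do.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    counts = confusion(y, p)
    sens, spec = sens_spec(counts)
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    redraws = 0

    if unit == "observation":
        n1 = int((y == 1).sum())
        n0 = int((y == 0).sum())
        # stratified resampling of exchangeable binary outcomes == binomial draw
        sens_boot = rng.binomial(n1, sens, size=n_boot) / n1
        spec_boot = rng.binomial(n0, spec, size=n_boot) / n0
    elif unit == "infant":
        if infant_ids is None:
            raise ValueError("infant-unit bootstrap needs infant_ids")
        ids = np.asarray(infant_ids)
        uniq = np.unique(ids)
        groups = {u: (y[ids == u], p[ids == u]) for u in uniq}
        sens_boot = np.empty(n_boot)
        spec_boot = np.empty(n_boot)
        for b in range(n_boot):
            for _attempt in range(1000):
                pick = rng.choice(uniq, size=len(uniq), replace=True)
                yy = np.concatenate([groups[u][0] for u in pick])
                pp = np.concatenate([groups[u][1] for u in pick])
                if yy.min() == 0 and yy.max() == 1:
                    break
                redraws += 1
            else:
                raise RuntimeError("could not draw a non-degenerate resample")
            s, sp = sens_spec(confusion(yy, pp))
            sens_boot[b] = s
            spec_boot[b] = sp
    else:
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    qs = [alpha / 2, 1 - alpha / 2]
    s_lo, s_hi = np.quantile(sens_boot, qs)
    sp_lo, sp_hi = np.quantile(spec_boot, qs)
    tp, fp, tn, fn = counts
    return EvaluationResult(
        indicator=indicator,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sens_ci_low=float(s_lo), sens_ci_high=float(s_hi),
        spec_ci_low=float(sp_lo), spec_ci_high=float(sp_hi),
        n_boot=n_boot, ci_level=level, seed=seed, unit=unit,
        n_degenerate_redraws=redraws,
    )


def _as_cutoff_list(cutoffs) -> list[CutoffResult]:
    if isinstance(cutoffs, pd.DataFrame):
        fields = [f for f in CutoffResult.__dataclass_fields__ if f in cutoffs.columns]
        return [
            CutoffResult(**{f: row[f] for f in fields})
            for _, row in cutoffs.iterrows()
        ]
    return list(cutoffs)


def apply_short_rule(
    metrics: pd.DataFrame, spec: IndicatorSpec, cutoff: float
) -> pd.Series:
    """Binary short-scale predictions at a cutoff, oriented per the indicator."""
    pred = metrics[spec.short_column]
    if spec.orientation == ">=":
        return (pred >= cutoff).astype(int)
    return (pred <= cutoff).astype(int)


def evaluate_rules_on_test(
    metrics: pd.DataFrame,
    split: pd.Series,
    cutoffs,
    specs: Sequence[IndicatorSpec] = FULL_INDICATORS,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    unit: str = "observation",
) -> list[EvaluationResult]:
    """Evaluate each derived short-scale rule on test-set rows only.

    Asserts infant-level train/test disjointness before touching the data
    (:class:`LeakageError` otherwise).
    """
    train_ids = set(split.index[split == "train"])
    test_ids = set(split.index[split == "test"])
    if train_ids & test_ids:
        raise LeakageError(f"infants in both sets: {sorted(train_ids & test_ids)}")
    missing = set(metrics["infant_id"]) - train_ids - test_ids
    if missing:
        raise LeakageError(f"infants with no split assignment: {sorted(missing)}")

    test = metrics[metrics["infant_id"].isin(test_ids)]
    by_name = {c.indicator: c for c in _as_cutoff_list(cutoffs)}
    results = []
    for spec in specs:
        cut = by_name[spec.name]
        labels, _ = make_labels(test, spec)
        sub = test.loc[labels.index]
        keep = sub[spec.short_column].notna()
        labels, sub = labels[keep], sub[keep]
        preds = apply_short_rule(sub, spec, cut.cutoff)
        results.append(
            bootstrap_ci(
                labels.to_numpy(), preds.to_numpy(),
                n_boot=n_boot, level=level, seed=seed, unit=unit,
                infant_ids=sub["infant_id"].to_numpy(), indicator=spec.name,
            )
        )
    return results


def evaluation_to_frame(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
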