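"""Youden-optimal cutoff derivation against exhaustive-search oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smnas import (
    FULL_INDICATORS,
    CohortConfig,
    IndicatorSpec,
    build_metrics_table,
    derive_all,
    empirical_roc,
    generate_planted_mapping_cohort,
    planted_short_map,
    planted_truths,
    stump_cutoff,
    youden_optimal_cutoff,
)
from smnas.cutoffs import DegenerateLabelsError, make_labels


def brute_youden(labels, pred, orientation):
    """Oracle: evaluate J at every candidate by direct counting."""
    labels = np.asarray(labels)
    pred = np.asarray(pred, dtype=float)
    cands = sorted(set(pred)) + [np.inf] if orientation == ">=" else \
        [-np.inf] + sorted(set(pred))
    best = None
    for c in cands:
        cls = pred >= c if orientation == ">=" else pred <= c
        sens = cls[labels == 1].mean()
        spec = (~cls[labels == 0]).mean()
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (c, j)
    return best


def brute_gini_stump(labels, pred):
    """Oracle: weighted Gini over every midpoint split; None if uninformative."""
    labels = np.asarray(labels)
    pred = np.asarray(pred, dtype=float)
    vals = np.unique(pred)
    n = len(labels)

    def gini(y):
        if len(y) == 0:
            return 0.0
        p = y.mean()
        return 2 * p * (1 - p)

    parent = gini(labels)
    best = None
    for lo, hi in zip(vals, vals[1:]):
        mid = (lo + hi) / 2
        left, right = labels[pred <= mid], labels[pred > mid]
        g = (len(left) * gini(left) + len(right) * gini(right)) / n
        if parent - g > 1e-12 and (best is None or g < best[1] - 1e-12):
            best = (mid, g)
    return None if best is None else best[0]


class TestMakeLabels:
    def test_strict_boundary(self):
        m = pd.DataFrame({"avg24_full": [7.9, 8.0, 8.1]})
        labels, dropped = make_labels(m, FULL_INDICATORS[0])  # avg24 < 8
        assert labels.tolist() == [1, 0, 0] and dropped == 0

    def test_non_strict_boundary(self):
        m = pd.DataFrame({"avg24_full": [7.9, 8.0, 8.1]})
        labels, _ = make_labels(m, FULL_INDICATORS[1])  # avg24 <= 8
        assert labels.tolist() == [1, 1, 0]

    def test_missing_metric_rows_dropped_and_counted(self):
        m = pd.DataFrame({"sum3_full": [np.nan, np.nan]})
        labels, dropped = make_labels(m, FULL_INDICATORS[3])
        assert len(labels) == 0 and dropped == 2


class TestEmpiricalRoc:
    def test_perfect_separation_reaches_corner(self):
        roc = empirical_roc([0, 0, 1, 1], [1, 2, 5, 6], ">=")
        assert ((roc.sensitivity == 1) & (roc.specificity == 1)).any()

    def test_constant_predictor_sits_on_chance_line(self):
        roc = empirical_roc([0, 1, 0, 1], [3, 3, 3, 3], ">=")
        np.testing.assert_allclose(roc.sensitivity + roc.specificity, 1.0)

    def test_four_point_enumeration(self):
        # oracle by hand: candidates 1,2,3,4,inf; J maximized at c=2 and c=4
        roc = empirical_roc([0, 1, 0, 1], [1, 2, 3, 4], ">=")
        j = roc.sensitivity + roc.specificity - 1
        assert j.max() == pytest.approx(0.5)
        assert sorted(roc.cutoff[j == j.max()]) == [2, 4]

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError, match="degenerate"):
            empirical_roc([1, 1, 1], [1, 2, 3], ">=")


class TestYoudenCutoff:
    def test_smallest_maximizer_tie_break(self):
        res = youden_optimal_cutoff([0, 1, 0, 1], [1, 2, 3, 4], ">=")
        assert res.cutoff == 2 and res.youden == pytest.approx(0.5)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        res = youden_optimal_cutoff(labels, labels * 10.0, ">=")
        assert res.cutoff == 10 and res.youden == 1.0

    def test_planted_single_score_calibration(self):
        """Enumerating full scores 0..43 with the interpolating map recovers
        the published calibration pairs: full >=12 -> short >=7, >=8 -> >=5."""
        full = np.arange(44)
        short = planted_short_map(full)
        for thr, expect in [(12, 7), (8, 5)]:
            res = youden_optimal_cutoff((full >= thr).astype(int), short, ">=")
            assert res.cutoff == expect and res.youden == 1.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for orientation in (">=", "<="):
            for _ in range(40):
                n = int(rng.integers(5, 500))
                pred = rng.integers(0, 30, n).astype(float)
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    continue
                res = youden_optimal_cutoff(labels, pred, orientation)
                c, j = brute_youden(labels, pred, orientation)
                assert res.youden == pytest.approx(j)
                assert res.cutoff == c

    def test_youden_dominates_every_other_candidate(self):
        rng = np.random.default_rng(13)
        pred = rng.normal(size=200)
        labels = (pred + rng.normal(size=200) > 0).astype(int)
        res = youden_optimal_cutoff(labels, pred, ">=")
        roc = empirical_roc(labels, pred, ">=")
        assert res.youden >= (roc.sensitivity + roc.specificity - 1).max() - 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        pred = rng.uniform(0, 5, 300)
        labels = (pred > 2.5).astype(int)
        labels[rng.random(300) < 0.1] ^= 1
        if labels.min() == labels.max():
            pytest.skip("degenerate draw")
        base = youden_optimal_cutoff(labels, pred, ">=")
        trans = youden_optimal_cutoff(labels, np.exp(pred), ">=")
        assert trans.youden == pytest.approx(base.youden)
        assert trans.cutoff == pytest.approx(np.exp(base.cutoff))

    def test_reported_cutoff_rounding(self):
        res = youden_optimal_cutoff(
            [0, 1, 0, 1], [1.03, 2.27, 1.9, 4.0], ">=", round_decimals=1
        )
        assert res.cutoff == 2.27 and res.cutoff_reported == 2.3


class TestStump:
    def test_separable_data_agrees_with_youden_partition(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        pred = np.array([1.0, 2, 3, 7, 8, 9])
        y = youden_optimal_cutoff(labels, pred, ">=")
        s = stump_cutoff(labels, pred)
        # same induced partition: stump midpoint lies below the Youden value
        assert (pred >= y.cutoff).tolist() == (pred > s).tolist()

    def test_matches_exhaustive_gini(self):
        """The stump attains the oracle's minimal weighted Gini impurity
        (cutoffs may differ only between impurity-tied splits)."""

        def weighted_gini(labels, pred, mid):
            def gini(y):
                return 0.0 if len(y) == 0 else 2 * y.mean() * (1 - y.mean())

            left, right = labels[pred <= mid], labels[pred > mid]
            return (len(left) * gini(left) + len(right) * gini(right)) / len(labels)

        rng = np.random.default_rng(15)
        checked = 0
        for _ in range(40):
            n = int(rng.integers(6, 80))
            pred = rng.integers(0, 10, n).astype(float)
            labels = (pred + rng.normal(0, 2, n) > 5).astype(int)
            if labels.min() == labels.max():
                continue
            oracle = brute_gini_stump(labels, pred)
            got = stump_cutoff(labels, pred)
            if oracle is None:
                assert got is None
            else:
                assert weighted_gini(labels, pred, got) == pytest.approx(
                    weighted_gini(labels, pred, oracle)
                )
                checked += 1
        assert checked > 10

    def test_exchangeable_predictor_has_no_informative_split(self):
        assert stump_cutoff([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0]) is None


class TestDeriveAll:
    def test_recovers_planted_cutoffs_noise_free(self, planted_cohort):
        _, metrics = planted_cohort
        results = {r.indicator: r for r in derive_all(metrics)}
        truths = planted_truths()
        assert set(results) == set(truths)
        for name, truth in truths.items():
            r = results[name]
            tol = 0.1 if r.short_metric == "avg24" else 1.0
            assert abs(r.cutoff_reported - truth) <= tol, (name, r.cutoff_reported)
            assert r.youden > 0.97

    def test_result_schema_fully_populated(self, planted_cohort):
        _, metrics = planted_cohort
        for r in derive_all(metrics):
            assert r.direction in (">=", "<=")
            assert -1 <= r.youden <= 1
            assert r.n_positive > 0 and r.n_negative > 0
            assert r.youden == pytest.approx(
                r.train_sensitivity + r.train_specificity - 1
            )

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_all(pd.DataFrame())
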