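"""Titration rule engine: indicators, guarded stepping, episode traces."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from smnas import evaluate_indicators, load_ruleset, run_episode
from smnas.engine import (
    SHIPPED_RULESETS,
    EngineError,
    EngineState,
    GuardedRule,
    RuleCondition,
    RuleSet,
    ruleset_from_config,
    ruleset_to_config,
    save_ruleset,
    step,
)

from conftest import make_scores


def row(t=0.0, full=0, short=0, avg_f=0.0, avg_s=0.0, s3_f=0.0, s3_s=0.0):
    return {
        "timestamp_h": t,
        "full_score": full, "short_score": short,
        "avg24_full": avg_f, "avg24_short": avg_s,
        "sum3_full": s3_f, "sum3_short": s3_s,
    }


class TestIndicators:
    def test_full_scale_average_boundary(self):
        ind, _ = evaluate_indicators(row(avg_f=7.9), "full")
        assert ind["i"] and ind["ii"]
        ind, _ = evaluate_indicators(row(avg_f=8.0), "full")
        assert not ind["i"] and ind["ii"]

    def test_short_scale_weaning_boundary(self):
        ind, _ = evaluate_indicators(row(avg_s=4.5), "short")
        assert ind["i"]
        ind, _ = evaluate_indicators(row(avg_s=4.6), "short")
        assert not ind["i"] and ind["ii"]

    def test_short_single_score_initiation(self):
        ind, _ = evaluate_indicators(row(short=7), "short")
        assert ind["vi"]

    def test_missing_sum3_is_false_and_flagged(self):
        ind, missing = evaluate_indicators(row(s3_f=None), "full")
        assert missing and not ind["iii"] and not ind["iv"]

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="unknown scale"):
            evaluate_indicators(row(), "medium")


@pytest.fixture(scope="module")
def morphine_short():
    return load_ruleset("morphine_short")


class TestStep:
    def test_untreated_high_single_score_initiates(self, morphine_short):
        state = EngineState(first_score_t=0.0)
        ev = step(state, row(t=10.0, short=7), morphine_short)
        assert ev["action"] == "initiate"
        assert ev["dose"] == morphine_short.start_dose
        assert state.treating

    def test_high_sum3_escalates(self, morphine_short):
        state = EngineState(first_score_t=0.0, treating=True, dose=0.4,
                            last_increase_t=0.0)
        ev = step(state, row(t=10.0, short=5, s3_s=14, avg_s=5.0), morphine_short)
        assert ev["action"] == "increase" and ev["dose"] > 0.4

    def test_stability_guard_blocks_weaning(self, morphine_short):
        state = EngineState(first_score_t=0.0, treating=True, dose=0.4,
                            last_increase_t=40.0)
        # avg below the weaning cutoff but only 10 h since the last increase
        ev = step(state, row(t=50.0, avg_s=3.0, s3_s=12.0), morphine_short)
        assert ev is None

    def test_highest_priority_rule_wins(self, morphine_short):
        # row satisfying wean, escalate and rescue at once: wean has priority
        state = EngineState(first_score_t=0.0, treating=True, dose=0.4,
                            last_increase_t=0.0)
        ev = step(state, row(t=100.0, short=7, avg_s=4.0, s3_s=16.0), morphine_short)
        assert ev["action"] == "decrease"

    def test_step_after_discontinue_rejected(self, morphine_short):
        state = EngineState(first_score_t=0.0, discontinued=True)
        with pytest.raises(EngineError, match="discontinue"):
            step(state, row(t=1.0), morphine_short)

    def test_dose_clipped_at_max(self, morphine_short):
        state = EngineState(first_score_t=0.0, treating=True,
                            dose=morphine_short.max_dose, last_increase_t=0.0)
        ev = step(state, row(t=10.0, short=12, s3_s=20, avg_s=8.0), morphine_short)
        assert ev["dose"] == morphine_short.max_dose

    def test_dose_never_negative(self, morphine_short):
        state = EngineState(first_score_t=0.0, treating=True, dose=0.05,
                            last_increase_t=0.0)
        ev = step(state, row(t=100.0, avg_s=4.0), morphine_short)
        assert ev["action"] == "decrease" and ev["dose"] == 0.0


def forced_trajectory():
    """Severity rises above every escalation cutoff, then collapses.

    Long enough for the complete arc: the dose caps at max during the high
    phase, and weaning steps are spaced >= 24 h, so reaching the
    discontinuation floor takes ~300 h after the scores settle.
    """
    times = np.arange(0, 460, 4.0)
    short = np.where(times < 60, 8, 1)
    return make_scores("a", times, short * 2, short)


class TestRunEpisode:
    def test_all_zero_scores_never_initiate(self, morphine_short):
        sc = make_scores("a", np.arange(0, 100, 3.5), np.zeros(29, dtype=int))
        assert len(run_episode(sc, morphine_short)) == 0

    def test_full_episode_fires_in_order(self, morphine_short):
        trace = run_episode(forced_trajectory(), morphine_short)
        actions = list(trace.action)
        assert actions[0] == "initiate"
        assert "increase" in actions
        assert "decrease" in actions
        assert actions[-1] == "discontinue"
        first = {a: actions.index(a) for a in ("initiate", "increase", "decrease")}
        assert first["initiate"] < first["increase"] < first["decrease"]
        assert first["decrease"] < actions.index("discontinue")

    def test_trace_is_deterministic(self, morphine_short):
        a = run_episode(forced_trajectory(), morphine_short)
        b = run_episode(forced_trajectory(), morphine_short)
        pd.testing.assert_frame_equal(a, b)

    def test_doses_bounded_throughout(self, morphine_short):
        rng = np.random.default_rng(3)
        for seed in range(5):
            n = 60
            sc = make_scores("a", np.arange(n) * 3.5,
                             rng.integers(0, 44, n), rng.integers(0, 20, n))
            trace = run_episode(sc, morphine_short)
            if len(trace):
                assert (trace.dose >= 0).all()
                assert (trace.dose <= morphine_short.max_dose + 1e-12).all()

    def test_no_actions_after_discontinue(self, morphine_short):
        trace = run_episode(forced_trajectory(), morphine_short)
        assert (trace.action == "discontinue").sum() == 1
        assert trace.action.iloc[-1] == "discontinue"


class TestGuardMonotonicity:
    def test_tightening_guards_only_removes_firings(self, morphine_short):
        """Per step, adding a guard to a rule can only suppress its firing."""
        rng = np.random.default_rng(9)
        tight_rules = tuple(
            dataclasses.replace(
                r, timer_guards=tuple(set(r.timer_guards) | {"48h_since_increase"})
            )
            for r in morphine_short.rules
        )
        tight = dataclasses.replace(morphine_short, rules=tight_rules)
        for _ in range(200):
            state = EngineState(
                first_score_t=0.0,
                treating=bool(rng.integers(2)),
                dose=float(rng.uniform(0, 1.2)),
                last_increase_t=float(rng.uniform(0, 100)),
                last_decrease_t=float(rng.uniform(0, 100)),
                had_first_decrease=bool(rng.integers(2)),
            )
            r = row(t=100.0, short=int(rng.integers(0, 20)),
                    avg_s=float(rng.uniform(0, 15)), s3_s=float(rng.uniform(0, 50)))
            ev_loose = step(dataclasses.replace(state), r, morphine_short)
            ev_tight = step(dataclasses.replace(state), r, tight)
            if ev_tight is not None:
                assert ev_loose is not None


class TestConcordance:
    def test_full_and_mapped_short_rulesets_agree_on_planted_data(self, planted_cohort):
        """With cutoffs mapped through the planted affine calibration, the
        full- and short-scale algorithms make identical decisions."""
        scores, _ = planted_cohort
        full_rs = load_ruleset("morphine_full")

        def map_thr(metric, thr):
            return {"avg24": thr / 2 + 1, "single_score": thr / 2 + 1,
                    "sum3": thr / 2 + 3}[metric]

        mapped_rules = tuple(
            dataclasses.replace(
                r,
                condition=dataclasses.replace(
                    r.condition,
                    threshold=map_thr(r.condition.metric, r.condition.threshold),
                ),
            )
            for r in full_rs.rules
        )
        short_rs = dataclasses.replace(full_rs, scale="short", rules=mapped_rules)
        for infant, g in scores.groupby("infant_id"):
            a = run_episode(g, full_rs)
            b = run_episode(g, short_rs)
            assert list(a.action) == list(b.action)
            assert list(a.timestamp_h) == list(b.timestamp_h)


class TestRuleSetConfig:
    @pytest.mark.parametrize("name", SHIPPED_RULESETS)
    def test_shipped_rulesets_load_and_validate(self, name):
        rs = load_ruleset(name)
        actions = {r.action for r in rs.rules}
        assert {"initiate", "decrease", "discontinue"} <= actions

    def test_yaml_round_trip(self, morphine_short, tmp_path):
        path = tmp_path / "rs.yaml"
        save_ruleset(morphine_short, path)
        assert load_ruleset(str(path)) == morphine_short

    def test_duplicate_priorities_rejected(self, morphine_short):
        cfg = ruleset_to_config(morphine_short)
        cfg["rules"][0]["priority"] = cfg["rules"][1]["priority"]
        with pytest.raises(ValueError, match="unique"):
            ruleset_from_config(cfg)

    def test_missing_rule_class_rejected(self, morphine_short):
        cfg = ruleset_to_config(morphine_short)
        cfg["rules"] = [r for r in cfg["rules"] if r["action"] != "discontinue"]
        with pytest.raises(ValueError, match="discontinue"):
            ruleset_from_config(cfg)
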