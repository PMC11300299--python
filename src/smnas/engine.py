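"""Configurable dose-titration rule engine for NOWS treatment algorithms.

A titration algorithm maps the longitudinal score metrics of one infant to
dose actions: initiate treatment on a high single score, escalate on a high
sum of three consecutive scores, give a rescue dose on a breakthrough score,
wean once the 24-h average is low and the dose has been stable, and
discontinue after weaning is established.  The engine executes such an
algorithm as a prioritized list of guarded rules over a metrics stream; at
each scoring time the highest-priority rule whose score condition and timer
guards all hold fires (at most one), and the emitted dose event feeds back
into the timers.

Rule sets for morphine and buprenorphine are shipped in both a full-scale
(MNAS) and a short-scale (sMNAS-9) variant, with the published threshold
pairs (e.g. 24-h average < 8 on the full scale pairing with < 4.6 on the
short scale).  Dose magnitudes in the shipped files are placeholders for
simulation plumbing, not clinical guidance.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .metrics import MetricsConfig, average_24h, sum_last3

COMPARATORS = {"<": operator.lt, "<=": operator.le, ">=": operator.ge, ">": operator.gt}
METRICS = ("single_score", "avg24", "sum3")
GUARDS = (
    "not_yet_treating",
    "treating",
    "48h_since_increase",
    "24h_since_decrease",
    "had_first_decrease",
)
SCALES = ("full", "short")

#: the six indicator conditions on the full MNAS scale, keyed i..vi
FULL_INDICATOR_THRESHOLDS: dict[str, tuple[str, str, float]] = {
    "i": ("avg24", "<", 8.0),
    "ii": ("avg24", "<=", 8.0),
    "iii": ("sum3", "<", 18.0),
    "iv": ("sum3", ">=", 24.0),
    "v": ("sum3", ">=", 28.0),
    "vi": ("single_score", ">=", 12.0),
}

#: published short-scale (sMNAS-9) counterparts of the six indicators
SHORT_INDICATOR_THRESHOLDS: dict[str, tuple[str, str, float]] = {
    "i": ("avg24", "<", 4.6),
    "ii": ("avg24", "<=", 4.6),
    "iii": ("sum3", "<=", 10.0),
    "iv": ("sum3", ">=", 14.0),
    "v": ("sum3", ">=", 16.0),
    "vi": ("single_score", ">=", 7.0),
}


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RuleCondition:
    metric: str
    comparator: str
    threshold: float

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def holds(self, value: float | None) -> bool:
        """False (fail-safe, no dose change) when the metric is unavailable."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        return COMPARATORS[self.comparator](value, self.threshold)


@dataclass(frozen=True)
class GuardedRule:
    name: str
    condition: RuleCondition
    action: str
    priority: int
    timer_guards: tuple[str, ...] = ()
    dose_delta: float = 0.0
    #: rule fires only when the current dose is at or below this (dose floor)
    dose_at_most: float | None = None

    def __post_init__(self):
        from .metrics import ACTIONS

        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        bad = set(self.timer_guards) - set(GUARDS)
        if bad:
            raise ValueError(f"unknown timer guards {sorted(bad)}")


@dataclass(frozen=True)
class RuleSet:
    drug: str
    scale: str
    rules: tuple[GuardedRule, ...]
    start_dose: float
    max_dose: float
    min_dose: float = 0.0
    dose_units: str = "arbitrary units (placeholder)"

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        prios = [r.priority for r in self.rules]
        if len(set(prios)) != len(prios):
            raise ValueError("rule priorities must be unique within a rule set")
        actions = {r.action for r in self.rules}
        for needed in ("initiate", "decrease", "discontinue"):
            if needed not in actions:
                raise ValueError(f"rule set lacks a {needed!r} rule")
        if not actions & {"increase", "rescue"}:
            raise ValueError("rule set lacks an escalation rule")

    @property
    def ordered_rules(self) -> tuple[GuardedRule, ...]:
        return tuple(sorted(self.rules, key=lambda r: -r.priority))


@dataclass
class EngineState:
    """Mutable per-infant titration state carried between steps."""

    first_score_t: float
    treating: bool = False
    discontinued: bool = False
    dose: float = 0.0
    last_increase_t: float | None = None
    last_decrease_t: float | None = None
    had_first_decrease: bool = False


# ---------------------------------------------------------------------------
# config (de)serialization


def ruleset_from_config(cfg: Mapping) -> RuleSet:
    rules = tuple(
        GuardedRule(
            name=str(r["name"]),
            condition=RuleCondition(
                metric=str(r["condition"]["metric"]),
                comparator=str(r["condition"]["comparator"]),
                threshold=float(r["condition"]["threshold"]),
            ),
            action=str(r["action"]),
            priority=int(r["priority"]),
            timer_guards=tuple(r.get("timer_guards", ())),
            dose_delta=float(r.get("dose_delta", 0.0)),
            dose_at_most=(
                float(r["dose_at_most"]) if r.get("dose_at_most") is not None else None
            ),
        )
        for r in cfg["rules"]
    )
    return RuleSet(
        drug=str(cfg["drug"]),
        scale=str(cfg["scale"]),
        rules=rules,
        start_dose=float(cfg["start_dose"]),
        max_dose=float(cfg["max_dose"]),
        min_dose=float(cfg.get("min_dose", 0.0)),
        dose_units=str(cfg.get("dose_units", "arbitrary units (placeholder)")),
    )


def ruleset_to_config(rs: RuleSet) -> dict:
    return {
        "drug": rs.drug,
        "scale": rs.scale,
        "start_dose": rs.start_dose,
        "max_dose": rs.max_dose,
        "min_dose": rs.min_dose,
        "dose_units": rs.dose_units,
        "rules": [
            {
                "name": r.name,
                "action": r.action,
                "priority": r.priority,
                "condition": {
                    "metric": r.condition.metric,
                    "comparator": r.condition.comparator,
                    "threshold": r.condition.threshold,
                },
                "timer_guards": list(r.timer_guards),
                "dose_delta": r.dose_delta,
                "dose_at_most": r.dose_at_most,
            }
            for r in rs.rules
        ],
    }


SHIPPED_RULESETS = (
    "morphine_full",
    "morphine_short",
    "buprenorphine_full",
    "buprenorphine_short",
)


def load_ruleset(name_or_path: str) -> RuleSet:
    """Load a rule set by shipped name (e.g. ``morphine_short``) or file path."""
    if name_or_path in SHIPPED_RULESETS:
        ref = resources.files("smnas.data") / "rulesets" / f"{name_or_path}.yaml"
        cfg = yaml.safe_load(ref.read_text())
    else:
        with open(name_or_path) as fh:
            cfg = yaml.safe_load(fh)
    return ruleset_from_config(cfg)


def save_ruleset(rs: RuleSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ruleset_to_config(rs), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# indicator evaluation


def evaluate_indicators(
    row: Mapping,
    scale: str,
    thresholds: Mapping[str, tuple[str, str, float]] | None = None,
) -> tuple[dict[str, bool], bool]:
    """The six indicator conditions at one metrics row, on one scale.

    Returns ``(indicators, sum3_missing)`` where ``indicators`` maps the
    roman-numeral names i..vi to booleans.  Indicators based on the sum of
    three are False (and flagged) when that sum is missing.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    if thresholds is None:
        thresholds = (
            FULL_INDICATOR_THRESHOLDS if scale == "full" else SHORT_INDICATOR_THRESHOLDS
        )
    vals = {
        "single_score": row[f"{scale}_score"],
        "avg24": row[f"avg24_{scale}"],
        "sum3": row[f"sum3_{scale}"],
    }
    s3 = vals["sum3"]
    sum3_missing = s3 is None or (isinstance(s3, float) and math.isnan(s3))
    out = {}
    for name, (metric, comp, thr) in thresholds.items():
        out[name] = RuleCondition(metric, comp, thr).holds(vals[metric])
    return out, sum3_missing


# ---------------------------------------------------------------------------
# stepping


def _guards_hold(rule: GuardedRule, state: EngineState, t: float, cfg: MetricsConfig) -> bool:
    inc_ref = state.last_increase_t if state.last_increase_t is not None else state.first_score_t
    dec_ref = state.last_decrease_t if state.last_decrease_t is not None else state.first_score_t
    for g in rule.timer_guards:
        if g == "not_yet_treating":
            if state.treating or state.discontinued:
                return False
        elif g == "treating":
            if not state.treating:
                return False
        elif g == "48h_since_increase":
            if not (t - inc_ref >= cfg.increase_flag_h if cfg.inclusive_flags
                    else t - inc_ref > cfg.increase_flag_h):
                return False
        elif g == "24h_since_decrease":
            if not (t - dec_ref >= cfg.decrease_flag_h if cfg.inclusive_flags
                    else t - dec_ref > cfg.decrease_flag_h):
                return False
        elif g == "had_first_decrease":
            if not state.had_first_decrease:
                return False
    if rule.dose_at_most is not None and state.dose > rule.dose_at_most + 1e-12:
        return False
    return True


def step(
    state: EngineState,
    row: Mapping,
    ruleset: RuleSet,
    metrics_config: MetricsConfig | None = None,
) -> dict | None:
    """Fire at most one rule at one metrics row, mutating ``state``.

    ``row`` must carry ``timestamp_h`` and the scale-resolved metric values
    ``full_score``/``short_score``, ``avg24_*`` and ``sum3_*``.  Returns the
    emitted dose event as a dict (``timestamp_h``, ``drug``, ``action``,
    ``dose`` after the action, ``rule``) or ``None`` for a no-op.
    """
    cfg = metrics_config or MetricsConfig()
    if state.discontinued:
        raise EngineError("step after discontinue")
    t = float(row["timestamp_h"])
    vals = {
        "single_score": row[f"{ruleset.scale}_score"],
        "avg24": row[f"avg24_{ruleset.scale}"],
        "sum3": row[f"sum3_{ruleset.scale}"],
    }
    for rule in ruleset.ordered_rules:
        if not rule.condition.holds(vals[rule.condition.metric]):
            continue
        if not _guards_hold(rule, state, t, cfg):
            continue
        _apply(state, rule, ruleset, t)
        return {
            "timestamp_h": t,
            "drug": ruleset.drug,
            "action": rule.action,
            "dose": state.dose,
            "rule": rule.name,
        }
    return None


def _apply(state: EngineState, rule: GuardedRule, rs: RuleSet, t: float) -> None:
    if rule.action == "initiate":
        state.treating = True
        state.dose = min(rs.start_dose, rs.max_dose)
        state.last_increase_t = t
    elif rule.action in ("increase", "rescue"):
        state.dose = min(state.dose + rule.dose_delta, rs.max_dose)
        state.last_increase_t = t
    elif rule.action == "decrease":
        state.dose = max(state.dose + rule.dose_delta, 0.0)
        state.last_decrease_t = t
        state.had_first_decrease = True
    elif rule.action == "discontinue":
        state.dose = 0.0
        state.treating = False
        state.discontinued = True
        state.last_decrease_t = t
        state.had_first_decrease = True
    # "maintain" and phenobarbital-adjunct hooks change no state


def run_episode(
    scores: pd.DataFrame,
    ruleset: RuleSet,
    metrics_config: MetricsConfig | None = None,
) -> pd.DataFrame:
    """Run the algorithm over one infant's chronological scores.

    Metrics are computed incrementally and every emitted dose event feeds
    back into the timers, exactly as in prospective use.  The trace ends at
    discontinuation or when scores run out.  Returns the episode trace: one
    row per fired rule with ``timestamp_h``, ``rule``, ``action`` and the
    dose after the action.
    """
    cfg = metrics_config or MetricsConfig()
    if scores["infant_id"].nunique() > 1:
        raise ValueError("run_episode expects a single infant's scores")
    g = scores.sort_values("timestamp_h", kind="stable")
    t_arr = g["timestamp_h"].to_numpy(dtype=float)
    full = g["full_score"].to_numpy(dtype=float)
    short = g["short_score"].to_numpy(dtype=float)
    infant = g["infant_id"].iloc[0] if len(g) else None

    state = EngineState(first_score_t=t_arr[0]) if len(g) else None
    events: list[dict] = []
    for i in range(len(g)):
        t = t_arr[i]
        hist_t, hist_f, hist_s = t_arr[: i + 1], full[: i + 1], short[: i + 1]
        row = {
            "timestamp_h": t,
            "full_score": full[i],
            "short_score": short[i],
            "avg24_full": average_24h(hist_t, hist_f, t, cfg.window_h, cfg.include_current),
            "avg24_short": average_24h(hist_t, hist_s, t, cfg.window_h, cfg.include_current),
            "sum3_full": sum_last3(hist_t, hist_f, t, cfg.n_consecutive, cfg.include_current),
            "sum3_short": sum_last3(hist_t, hist_s, t, cfg.n_consecutive, cfg.include_current),
        }
        ev = step(state, row, ruleset, cfg)
        if ev is not None:
            ev["infant_id"] = infant
            events.append(ev)
        if state.discontinued:
            break
    cols = ["infant_id", "timestamp_h", "rule", "action", "dose", "drug"]
    return pd.DataFrame(events, columns=cols)
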