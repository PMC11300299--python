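"""Glue between cutoff derivation and the titration engine.

The published short-scale rule sets carry cutoffs calibrated on the original
cohort.  For any other cohort — synthetic or new — the short-scale algorithm
should instead use cutoffs derived on that cohort's training set; this
module rewrites a full-scale rule set into its short-scale counterpart by
substituting derived cutoffs rule by rule.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from .cutoffs import CutoffResult
from .engine import (
    FULL_INDICATOR_THRESHOLDS,
    SHORT_INDICATOR_THRESHOLDS,
    RuleSet,
)


def short_ruleset_from_cutoffs(
    full_ruleset: RuleSet, cutoffs: Iterable[CutoffResult]
) -> RuleSet:
    """Rewrite a full-scale rule set with derived short-scale cutoffs.

    Each rule condition matching one of the six full-scale indicator
    definitions gets that indicator's derived cutoff (the reported, rounded
    value) and the short-scale comparator of the published pairing (which
    may flip strictness, e.g. full ``sum3 < 18`` pairs with short
    ``sum3 <= c``).  Rules not matching any indicator are rejected.
    """
    by_cond = {cond: name for name, cond in FULL_INDICATOR_THRESHOLDS.items()}
    by_name = {c.indicator: c for c in cutoffs}
    new_rules = []
    for rule in full_ruleset.rules:
        key = (rule.condition.metric, rule.condition.comparator,
               rule.condition.threshold)
        if key not in by_cond:
            raise ValueError(
                f"rule {rule.name!r} condition {key} matches no indicator"
            )
        ind = by_cond[key]
        metric, short_comp, _ = SHORT_INDICATOR_THRESHOLDS[ind]
        new_rules.append(
            dataclasses.replace(
                rule,
                condition=dataclasses.replace(
                    rule.condition,
                    comparator=short_comp,
                    threshold=float(by_name[ind].cutoff_reported),
                ),
            )
        )
    return dataclasses.replace(full_ruleset, scale="short",
                               rules=tuple(new_rules))
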