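"""The MNAS and sMNAS-9 withdrawal-severity scoring instruments.

Severity of neonatal opioid withdrawal syndrome (NOWS) is assessed at the
bedside with ordinal sign checklists every 3-4 hours.  The MOTHER NAS scale
(MNAS) scores 19 signs, each on a small ordered set of point values, summing
to 0-43.  The abbreviated sMNAS-9 scores a 9-sign subset of the same sheet,
summing to 0-19, so a single assessment yields both scores.  A further set of
elements (e.g. myoclonic jerks, watery stools) is recorded as present/absent
but never summed.

This module encodes an instrument as data, validates a definition against the
published summed-score ranges, and computes full- and short-scale summed
scores from item-level points.  "Sign absent" is an explicit zero for every
item; a record that omits a scored item entirely is invalid rather than
silently zero-filled, so data-entry gaps surface as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: explicit "assessed, sign absent" marker — legal for every item
ABSENT = 0

#: published summed-score ranges and item counts the shipped definition must meet
FULL_MAX_EXPECTED = 43
SHORT_MAX_EXPECTED = 19
N_FULL_EXPECTED = 19
N_SHORT_EXPECTED = 9


class InstrumentError(ValueError):
    """Structural problem in an instrument definition or a score record.

    ``item`` names the offending item when one is identifiable.
    """

    def __init__(self, message: str, item: str | None = None):
        super().__init__(message)
        self.item = item


@dataclass(frozen=True)
class SeverityLevel:
    """One ordinal severity level of an item: a description and its points."""

    description: str
    points: int

    def __post_init__(self):
        if self.points < 0:
            raise InstrumentError(f"negative points {self.points!r}")


@dataclass(frozen=True)
class InstrumentItem:
    """One scored sign, with its ordered severity levels and scale membership."""

    name: str
    levels: tuple[SeverityLevel, ...]
    in_full: bool = True
    in_short: bool = False

    def __post_init__(self):
        if not self.levels:
            raise InstrumentError(f"item {self.name!r} has no levels", self.name)
        pts = [lv.points for lv in self.levels]
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise InstrumentError(
                f"non-monotone points for item {self.name!r}: {pts}", self.name
            )
        if self.in_short and not self.in_full:
            raise InstrumentError(
                f"short item not in full: {self.name!r}", self.name
            )

    @property
    def legal_points(self) -> frozenset[int]:
        return frozenset({ABSENT} | {lv.points for lv in self.levels})

    @property
    def max_points(self) -> int:
        return self.levels[-1].points


@dataclass(frozen=True)
class InstrumentDefinition:
    """A full instrument: scored items plus recorded-but-unscored elements."""

    items: tuple[InstrumentItem, ...]
    unscored_elements: tuple[str, ...] = ()
    name: str = "instrument"

    def __post_init__(self):
        seen: set[str] = set()
        for it in self.items:
            if it.name in seen:
                raise InstrumentError(f"duplicate item name: {it.name!r}", it.name)
            seen.add(it.name)
        dup = seen & set(self.unscored_elements)
        if dup:
            raise InstrumentError(f"unscored element duplicates a scored item: {sorted(dup)}")

    def item(self, name: str) -> InstrumentItem:
        for it in self.items:
            if it.name == name:
                return it
        raise InstrumentError(f"unknown item: {name!r}", name)

    @property
    def full_items(self) -> tuple[InstrumentItem, ...]:
        return tuple(it for it in self.items if it.in_full)

    @property
    def short_items(self) -> tuple[InstrumentItem, ...]:
        return tuple(it for it in self.items if it.in_short)

    @property
    def full_max(self) -> int:
        return sum(it.max_points for it in self.full_items)

    @property
    def short_max(self) -> int:
        return sum(it.max_points for it in self.short_items)


@dataclass(frozen=True)
class ValidationReport:
    """Summary of an instrument against the published ranges; never raises."""

    full_max: int
    short_max: int
    n_full: int
    n_short: int
    flags: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_instrument(instr: InstrumentDefinition) -> ValidationReport:
    """Report scale maxima and item counts, flagging deviations from 43/19."""
    flags = []
    if instr.full_max != FULL_MAX_EXPECTED:
        flags.append(f"full-scale max {instr.full_max} != {FULL_MAX_EXPECTED}")
    if instr.short_max != SHORT_MAX_EXPECTED:
        flags.append(f"short-scale max {instr.short_max} != {SHORT_MAX_EXPECTED}")
    if len(instr.full_items) != N_FULL_EXPECTED:
        flags.append(f"{len(instr.full_items)} full items != {N_FULL_EXPECTED}")
    if len(instr.short_items) != N_SHORT_EXPECTED:
        flags.append(f"{len(instr.short_items)} short items != {N_SHORT_EXPECTED}")
    return ValidationReport(
        full_max=instr.full_max,
        short_max=instr.short_max,
        n_full=len(instr.full_items),
        n_short=len(instr.short_items),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# config (de)serialization


def instrument_from_config(cfg: Mapping) -> InstrumentDefinition:
    items = tuple(
        InstrumentItem(
            name=str(it["name"]),
            levels=tuple(
                SeverityLevel(str(lv["description"]), int(lv["points"]))
                for lv in it["levels"]
            ),
            in_full=bool(it.get("in_full", True)),
            in_short=bool(it.get("in_short", False)),
        )
        for it in cfg["items"]
    )
    return InstrumentDefinition(
        items=items,
        unscored_elements=tuple(str(u) for u in cfg.get("unscored_elements", ())),
        name=str(cfg.get("name", "instrument")),
    )


def instrument_to_config(instr: InstrumentDefinition) -> dict:
    return {
        "name": instr.name,
        "items": [
            {
                "name": it.name,
                "in_full": it.in_full,
                "in_short": it.in_short,
                "levels": [
                    {"description": lv.description, "points": lv.points}
                    for lv in it.levels
                ],
            }
            for it in instr.items
        ],
        "unscored_elements": list(instr.unscored_elements),
    }


def load_instrument(path=None) -> InstrumentDefinition:
    """Load an instrument from a YAML config; default is the shipped MNAS."""
    if path is None:
        ref = resources.files("smnas.data") / "mnas_instrument.yaml"
        cfg = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    return instrument_from_config(cfg)


def save_instrument(instr: InstrumentDefinition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(instrument_to_config(instr), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# scoring


def score_record(
    instr: InstrumentDefinition, item_points: Mapping[str, int]
) -> tuple[int, int]:
    """Sum one assessment into (full_score, short_score).

    Every scored item must appear in ``item_points`` — with its points value,
    or 0 for "assessed, sign absent".  Unscored elements may appear with 0/1
    presence values and are ignored by the sums.  Unknown keys, illegal point
    values and missing items raise :class:`InstrumentError`.
    """
    known = {it.name for it in instr.items}
    unscored = set(instr.unscored_elements)
    for key in item_points:
        if key not in known and key not in unscored:
            raise InstrumentError(f"unknown item: {key!r}", key)
    full = short = 0
    for it in instr.items:
        if it.name not in item_points:
            raise InstrumentError(
                f"item {it.name!r} neither scored nor marked absent", it.name
            )
        val = int(item_points[it.name])
        if val not in it.legal_points:
            raise InstrumentError(
                f"illegal points {val} for item {it.name!r} "
                f"(legal: {sorted(it.legal_points)})",
                it.name,
            )
        if it.in_full:
            full += val
        if it.in_short:
            short += val
    return full, short


def score_table(instr: InstrumentDefinition, sheet: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`score_record` over a score-sheet table.

    ``sheet`` has one row per infant per scoring time with columns
    ``infant_id``, ``timestamp_h`` and one column per scored item.  Returns a
    copy with ``full_score`` and ``short_score`` columns appended.
    """
    out = sheet.copy()
    full = np.zeros(len(sheet), dtype=np.int64)
    short = np.zeros(len(sheet), dtype=np.int64)
    for it in instr.items:
        if it.name not in sheet.columns:
            raise InstrumentError(
                f"item {it.name!r} neither scored nor marked absent", it.name
            )
        col = sheet[it.name]
        if col.isna().any():
            raise InstrumentError(f"missing values in item {it.name!r}", it.name)
        vals = col.to_numpy(dtype=np.int64)
        if not np.isin(vals, sorted(it.legal_points)).all():
            bad = vals[~np.isin(vals, sorted(it.legal_points))][0]
            raise InstrumentError(
                f"illegal points {bad} for item {it.name!r}", it.name
            )
        if it.in_full:
            full += vals
        if it.in_short:
            short += vals
    out["full_score"] = full
    out["short_score"] = short
    return out
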