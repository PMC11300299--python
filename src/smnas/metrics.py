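"""Longitudinal per-observation metrics feeding the titration decision rules.

For every scoring time of every infant the titration algorithms consult three
kinds of quantity, computed here for both the full MNAS and the short sMNAS-9
summed scores:

* the arithmetic mean of all scores in the trailing 24-hour window,
* the sum of the three most recent consecutive scores,
* dose timers — hours since the last dose increase and the last decrease —
  and the derived stability flags (>=48 h since an increase, >=24 h since a
  decrease) plus whether a first weaning step has happened yet.

Time is real-valued hours relative to each infant's first score; there is no
calendar handling.  Before any dose event both timers run from the first
score, which defines time zero for that infant.  By default the trailing
window is half-open, ``(t - 24, t]``, and the sum of three includes the
current score; both conventions are switchable in :class:`MetricsConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ACTIONS = ("initiate", "increase", "decrease", "maintain", "rescue", "discontinue")
DRUGS = ("morphine", "buprenorphine", "phenobarbital")

SCORE_COLUMNS = ("infant_id", "timestamp_h", "full_score", "short_score")
DOSE_COLUMNS = ("infant_id", "timestamp_h", "drug", "action", "dose")


@dataclass(frozen=True)
class MetricsConfig:
    """Conventions for the rolling metrics and dose timers."""

    window_h: float = 24.0
    n_consecutive: int = 3
    include_current: bool = True
    #: any dose escalation restarts the stability clock gating weaning
    increase_actions: tuple[str, ...] = ("initiate", "increase", "rescue")
    decrease_actions: tuple[str, ...] = ("decrease",)
    increase_flag_h: float = 48.0
    decrease_flag_h: float = 24.0
    #: flags read "had passed" inclusively: timer >= threshold
    inclusive_flags: bool = True


def _flag(elapsed: np.ndarray, threshold: float, inclusive: bool) -> np.ndarray:
    return elapsed >= threshold if inclusive else elapsed > threshold


def _locate(times: np.ndarray, t: float) -> int:
    idx = np.flatnonzero(np.isclose(times, t))
    if idx.size == 0:
        raise ValueError(f"t={t} is not an observation time")
    return int(idx[-1])


def average_24h(
    times,
    scores,
    t: float,
    window_h: float = 24.0,
    include_current: bool = True,
) -> float:
    """Mean score in the trailing window at observation time ``t``.

    Window is ``(t - window_h, t]`` including the current score, or
    ``(t - window_h, t)`` when ``include_current`` is false (NaN if empty).
    """
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    _locate(times, t)
    if include_current:
        mask = (times > t - window_h) & (times <= t)
    else:
        mask = (times > t - window_h) & (times < t)
    if not mask.any():
        return float("nan")
    return float(scores[mask].mean())


def sum_last3(
    times,
    scores,
    t: float,
    n: int = 3,
    include_current: bool = True,
) -> float | None:
    """Sum of the ``n`` most recent consecutive scores at time ``t``.

    Includes the score at ``t`` plus the ``n - 1`` before it (or the ``n``
    strictly before it when ``include_current`` is false).  Returns ``None``
    when fewer than ``n`` scores exist.
    """
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    i = _locate(times, t)
    hi = i + 1 if include_current else i
    lo = hi - n
    if lo < 0:
        return None
    return float(scores[lo:hi].sum())


def validate_dose_events(doses: pd.DataFrame) -> None:
    """Check dose-event structural invariants; raises ValueError."""
    for col in DOSE_COLUMNS:
        if col not in doses.columns:
            raise ValueError(f"dose table missing column {col!r}")
    bad_action = set(doses["action"]) - set(ACTIONS)
    if bad_action:
        raise ValueError(f"unknown dose actions: {sorted(bad_action)}")
    bad_drug = set(doses["drug"]) - set(DRUGS)
    if bad_drug:
        raise ValueError(f"unknown drugs: {sorted(bad_drug)}")
    if (doses["dose"] < 0).any():
        raise ValueError("negative dose")
    for infant, g in doses.groupby("infant_id", sort=False):
        ts = g["timestamp_h"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            raise ValueError(f"decreasing dose timestamps for infant {infant!r}")
        for drug, gd in g.groupby("drug", sort=False):
            actions = list(gd["action"])
            if "initiate" in actions and actions[0] != "initiate":
                raise ValueError(
                    f"initiate is not the first {drug} action for infant {infant!r}"
                )
            if "discontinue" in actions and actions[-1] != "discontinue":
                raise ValueError(
                    f"actions after discontinue of {drug} for infant {infant!r}"
                )


def annotate_timers(
    scores: pd.DataFrame,
    doses: pd.DataFrame | None = None,
    config: MetricsConfig | None = None,
) -> pd.DataFrame:
    """Attach dose-timer columns to a (sorted) score table.

    Adds ``t_since_increase``, ``t_since_decrease``,
    ``flag_48h_since_increase``, ``flag_24h_since_decrease`` and
    ``had_first_decrease``.  Timers run from the infant's first score until a
    qualifying dose event occurs.
    """
    config = config or MetricsConfig()
    if doses is None:
        doses = pd.DataFrame(columns=list(DOSE_COLUMNS))
    validate_dose_events(doses)
    unknown = set(doses["infant_id"]) - set(scores["infant_id"])
    if unknown:
        raise ValueError(f"dose event for unknown infant(s): {sorted(unknown)}")

    out = scores.sort_values(["infant_id", "timestamp_h"], kind="stable").reset_index(
        drop=True
    )
    t_inc = np.empty(len(out))
    t_dec = np.empty(len(out))
    had_dec = np.empty(len(out), dtype=bool)

    dose_groups = dict(tuple(doses.groupby("infant_id", sort=False)))
    pos = 0
    for infant, g in out.groupby("infant_id", sort=False):
        t = g["timestamp_h"].to_numpy(dtype=float)
        n = len(t)
        t0 = t[0]
        dg = dose_groups.get(infant)
        if dg is None:
            inc_times = np.empty(0)
            dec_times = np.empty(0)
        else:
            inc_times = np.sort(
                dg.loc[dg["action"].isin(config.increase_actions), "timestamp_h"]
                .to_numpy(dtype=float)
            )
            dec_times = np.sort(
                dg.loc[dg["action"].isin(config.decrease_actions), "timestamp_h"]
                .to_numpy(dtype=float)
            )
        # most recent qualifying event at or before each score time, else t0
        if inc_times.size:
            ii = np.searchsorted(inc_times, t, side="right") - 1
            last_inc = np.where(ii >= 0, inc_times[np.maximum(ii, 0)], t0)
        else:
            last_inc = np.full(n, t0)
        if dec_times.size:
            jj = np.searchsorted(dec_times, t, side="right") - 1
            last_dec = np.where(jj >= 0, dec_times[np.maximum(jj, 0)], t0)
            had = jj >= 0
        else:
            last_dec = np.full(n, t0)
            had = np.zeros(n, dtype=bool)
        t_inc[pos : pos + n] = t - last_inc
        t_dec[pos : pos + n] = t - last_dec
        had_dec[pos : pos + n] = had
        pos += n

    out["t_since_increase"] = t_inc
    out["t_since_decrease"] = t_dec
    out["flag_48h_since_increase"] = _flag(
        t_inc, config.increase_flag_h, config.inclusive_flags
    )
    out["flag_24h_since_decrease"] = _flag(
        t_dec, config.decrease_flag_h, config.inclusive_flags
    )
    out["had_first_decrease"] = had_dec
    return out


def build_metrics_table(
    scores: pd.DataFrame,
    doses: pd.DataFrame | None = None,
    config: MetricsConfig | None = None,
) -> pd.DataFrame:
    """One metrics row per score record, chronological within infant.

    Combines the 24-h rolling averages and sums of three consecutive scores
    (computed separately on the full and short scales) with the dose-timer
    annotations.  Infants are processed independently.  Missing sums (fewer
    than three scores so far) are NaN.
    """
    config = config or MetricsConfig()
    for col in SCORE_COLUMNS:
        if col not in scores.columns:
            raise ValueError(f"score table missing column {col!r}")
    if len(scores) == 0:
        cols = list(SCORE_COLUMNS) + [
            "avg24_full", "avg24_short", "sum3_full", "sum3_short",
            "t_since_increase", "t_since_decrease",
            "flag_48h_since_increase", "flag_24h_since_decrease",
            "had_first_decrease",
        ]
        return pd.DataFrame(columns=cols)

    out = annotate_timers(scores, doses, config)

    n_total = len(out)
    avg_f = np.empty(n_total)
    avg_s = np.empty(n_total)
    sum_f = np.full(n_total, np.nan)
    sum_s = np.full(n_total, np.nan)
    pos = 0
    for _, g in out.groupby("infant_id", sort=False):
        t = g["timestamp_h"].to_numpy(dtype=float)
        sf = g["full_score"].to_numpy(dtype=float)
        ss = g["short_score"].to_numpy(dtype=float)
        n = len(t)
        idx = np.arange(n)
        lo = np.searchsorted(t, t - config.window_h, side="right")
        hi = idx + 1 if config.include_current else idx
        csf = np.concatenate([[0.0], np.cumsum(sf)])
        css = np.concatenate([[0.0], np.cumsum(ss)])
        cnt = hi - lo
        with np.errstate(invalid="ignore"):
            avg_f[pos : pos + n] = np.where(
                cnt > 0, (csf[hi] - csf[lo]) / np.where(cnt > 0, cnt, 1), np.nan
            )
            avg_s[pos : pos + n] = np.where(
                cnt > 0, (css[hi] - css[lo]) / np.where(cnt > 0, cnt, 1), np.nan
            )
        k = config.n_consecutive
        shi = idx + 1 if config.include_current else idx
        slo = shi - k
        ok = slo >= 0
        sum_f[pos : pos + n][ok] = csf[shi[ok]] - csf[slo[ok]]
        sum_s[pos : pos + n][ok] = css[shi[ok]] - css[slo[ok]]
        pos += n

    out["avg24_full"] = avg_f
    out["avg24_short"] = avg_s
    out["sum3_full"] = sum_f
    out["sum3_short"] = sum_s
    # put metric columns before timer columns for readability
    timer_cols = [
        "t_since_increase", "t_since_decrease",
        "flag_48h_since_increase", "flag_24h_since_decrease", "had_first_decrease",
    ]
    other = [c for c in out.columns if c not in timer_cols]
    return out[other + timer_cols]
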