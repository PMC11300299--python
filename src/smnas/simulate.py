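"""Synthetic NOWS cohorts: item-level score trajectories with dose feedback.

No public dataset of item-level withdrawal scores exists, so every stage of
the pipeline is exercised on synthetic cohorts.  Two generator modes are
provided:

``item_level``
    Each infant carries a latent withdrawal-severity process: a rise-decay
    mean curve (severity climbs over the first ~2 days of monitoring, then
    wanes) with an infant-specific peak and first-order autoregressive noise,
    reduced in proportion to the current opioid dose when treatment feedback
    is enabled.  At scoring times drawn every 3-4 h, each instrument item is
    emitted by snapping a jittered share of the latent severity to the item's
    legal ordinal levels, so the full and short summed scores are positively
    correlated by construction.  With feedback on, the titration rule engine
    runs prospectively on the accumulating scores and its dose events shape
    the remaining trajectory.

``planted_mapping``
    A calibration construct with known ground truth rather than a realistic
    cohort: full-scale scores are generated directly (no items) and the
    short score is the integer map ``floor(full/2) + 1`` interpolating the
    two published calibration pairs (full 8 -> short 5, full 12 -> short 7),
    optionally perturbed by +/-1 with probability ``epsilon``.  Full scores
    are quantized to even values so the map is exactly affine and the
    windowed metrics inherit crisp planted cutoffs for all six indicators.
    This map is a construction of this package, not a published result.

All parameters are synthetic defaults chosen to emulate the published data
*structure* (cohort size, scoring cadence, score ranges), not its score
distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import EngineState, RuleSet, load_ruleset, step
from .instrument import InstrumentDefinition, load_instrument
from .metrics import DOSE_COLUMNS, MetricsConfig, average_24h, sum_last3


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults emulate the published cohort structure."""

    n_infants: int = 373          # published cohort size (train + test)
    seed: int = 0
    interval_min_h: float = 3.0   # scoring every 3-4 h
    interval_max_h: float = 4.0
    follow_up_h: float = 600.0    # ~170 scores/infant, matching ~63k total scores

    # latent severity model (full-scale points)
    baseline: float = 3.0
    peak_mean: float = 24.0
    peak_sd: float = 5.0
    t_peak_h: float = 48.0
    decay_h: float = 150.0
    ar_rho: float = 0.8           # AR(1) at the reference 3.5 h step
    noise_sd: float = 3.0
    item_jitter_sd: float = 0.08  # on the 0-1 severity-propensity scale

    # treatment feedback
    feedback: bool = True
    ruleset: str = "morphine_full"
    treatment_effect: float = 12.0  # severity points removed per dose unit

    # planted-mapping mode
    mode: str = "item_level"      # or "planted_mapping"
    epsilon: float = 0.0          # +/-1 short-score perturbation probability

    def __post_init__(self):
        if self.n_infants < 1:
            raise ValueError("n_infants must be >= 1")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.interval_min_h > self.interval_max_h:
            raise ValueError("interval_min_h must be <= interval_max_h")
        if self.mode not in ("item_level", "planted_mapping"):
            raise ValueError(f"unknown mode {self.mode!r}")


def planted_short_map(full):
    """Integer map interpolating the published calibration pairs 8->5, 12->7."""
    return np.asarray(full, dtype=int) // 2 + 1


def planted_truths() -> dict[str, float]:
    """Ground-truth short-scale cutoffs implied by the planted (even) map.

    Full scores are even, so short = full/2 + 1 exactly and the metric-level
    boundaries map through: 24-h averages at 8 -> 5.0, sums of three at
    18/24/28 -> 12/15/17, single score at 12 -> 7.  For the strict "<"
    indicators on integer metrics the optimal grid cutoff is the largest
    value below the mapped boundary (sum3 < 12 == sum3 <= 11).
    """
    return {"i": 5.0, "ii": 5.0, "iii": 11.0, "iv": 15.0, "v": 17.0, "vi": 7.0}


def _scoring_times(rng, cfg: CohortConfig) -> np.ndarray:
    times = [0.0]
    while True:
        t = times[-1] + rng.uniform(cfg.interval_min_h, cfg.interval_max_h)
        if t > cfg.follow_up_h:
            break
        times.append(t)
    return np.asarray(times)


def _latent_path(rng, cfg: CohortConfig, times: np.ndarray, peak: float,
                 doses: np.ndarray | None = None) -> np.ndarray:
    """AR(1) noise around the rise-decay mean, minus the treatment effect."""
    n = len(times)
    e = np.empty(n)
    e[0] = rng.normal(0.0, cfg.noise_sd)
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        rho = cfg.ar_rho ** (dt / 3.5)
        e[i] = rho * e[i - 1] + rng.normal(0.0, cfg.noise_sd * np.sqrt(1 - rho**2))
    m = cfg.baseline + (peak - cfg.baseline) * _surge(times, cfg)
    lat = m + e
    if doses is not None:
        lat = lat - cfg.treatment_effect * doses
    return np.maximum(lat, 0.0)


def _surge(t: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Unit-peak rise-decay shape ``(t/t_peak)^a * exp(a (1 - t/t_peak))``.

    Maximum 1 at ``t_peak``; the late exponential decay rate is ``1/decay_h``
    (``a = t_peak_h / decay_h``).
    """
    a = cfg.t_peak_h / cfg.decay_h
    x = np.maximum(np.asarray(t, dtype=float), 0.0) / cfg.t_peak_h
    return x**a * np.exp(a * (1.0 - x))


def _emit_items(rng, instr: InstrumentDefinition, latent: float,
                jitter_sd: float) -> dict[str, int]:
    """Snap a jittered severity share to each item's legal ordinal levels."""
    p = latent / instr.full_max
    points = {}
    for it in instr.items:
        target = (p + rng.normal(0.0, jitter_sd)) * it.max_points
        legal = sorted(it.legal_points)
        points[it.name] = min(legal, key=lambda v: (abs(v - target), v))
    return points


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item-level cohort with (optional) prospective treatment feedback.

    Returns ``(scores, doses)``.  ``scores`` has one row per infant per
    scoring time with every item column, the summed ``full_score`` and
    ``short_score``, and the diagnostic ``latent_severity``.  ``doses`` holds
    the engine-emitted dose events (empty when feedback is off).  Fully
    reproducible from ``config.seed``.
    """
    if config.mode != "item_level":
        raise ValueError("generate_cohort requires mode='item_level'")
    rng = np.random.default_rng(config.seed)
    instr = load_instrument()
    ruleset = load_ruleset(config.ruleset) if config.feedback else None
    mcfg = MetricsConfig()

    score_rows: list[dict] = []
    dose_rows: list[dict] = []
    for i in range(config.n_infants):
        infant = f"inf{i:04d}"
        peak = max(config.baseline + 1.0, rng.normal(config.peak_mean, config.peak_sd))
        times = _scoring_times(rng, config)
        state = EngineState(first_score_t=times[0])
        e_prev = rng.normal(0.0, config.noise_sd)
        hist_t: list[float] = []
        hist_f: list[float] = []
        hist_s: list[float] = []
        for k, t in enumerate(times):
            if k > 0:
                dt = t - times[k - 1]
                rho = config.ar_rho ** (dt / 3.5)
                e_prev = rho * e_prev + rng.normal(
                    0.0, config.noise_sd * np.sqrt(1 - rho**2)
                )
            m = config.baseline + (peak - config.baseline) * float(
                _surge(np.asarray([t]), config)[0]
            )
            latent = max(m + e_prev - config.treatment_effect * state.dose, 0.0)
            points = _emit_items(rng, instr, latent, config.item_jitter_sd)
            full = sum(v for n_, v in points.items() if instr.item(n_).in_full)
            short = sum(v for n_, v in points.items() if instr.item(n_).in_short)
            hist_t.append(t)
            hist_f.append(full)
            hist_s.append(short)
            row = {"infant_id": infant, "timestamp_h": t, **points,
                   "full_score": full, "short_score": short,
                   "latent_severity": latent}
            score_rows.append(row)
            if ruleset is not None and not state.discontinued:
                mrow = {
                    "timestamp_h": t,
                    "full_score": full, "short_score": short,
                    "avg24_full": average_24h(hist_t, hist_f, t, mcfg.window_h),
                    "avg24_short": average_24h(hist_t, hist_s, t, mcfg.window_h),
                    "sum3_full": sum_last3(hist_t, hist_f, t, mcfg.n_consecutive),
                    "sum3_short": sum_last3(hist_t, hist_s, t, mcfg.n_consecutive),
                }
                ev = step(state, mrow, ruleset, mcfg)
                if ev is not None:
                    ev["infant_id"] = infant
                    dose_rows.append(ev)

    scores = pd.DataFrame(score_rows)
    doses = pd.DataFrame(dose_rows, columns=["infant_id", "timestamp_h", "drug",
                                             "action", "dose", "rule"])
    return scores, doses[list(DOSE_COLUMNS) + ["rule"]]


def generate_planted_mapping_cohort(config: CohortConfig) -> pd.DataFrame:
    """Summed-score cohort with the planted full->short calibration map.

    Full scores follow the same latent trajectory model, quantized to even
    integers in [0, 42]; short scores apply ``floor(full/2) + 1`` and the
    optional +/-1 perturbation with probability ``epsilon``.
    """
    if config.mode != "planted_mapping":
        raise ValueError("generate_planted_mapping_cohort requires mode='planted_mapping'")
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_infants):
        infant = f"inf{i:04d}"
        peak = max(config.baseline + 1.0, rng.normal(config.peak_mean, config.peak_sd))
        times = _scoring_times(rng, config)
        lat = _latent_path(rng, config, times, peak)
        full = np.clip(2 * np.round(lat / 2.0), 0, 42).astype(int)
        short = planted_short_map(full)
        flip = rng.random(len(full)) < config.epsilon
        short = short + np.where(flip, rng.choice([-1, 1], size=len(full)), 0)
        short = np.maximum(short, 0)
        for t, f, s in zip(times, full, short):
            rows.append({"infant_id": infant, "timestamp_h": t,
                         "full_score": int(f), "short_score": int(s)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixture(scores: pd.DataFrame, doses: pd.DataFrame | None,
                  directory, truth: dict | None = None) -> dict[str, Path]:
    """Serialize a cohort to the CSV dialects consumed by the other modules."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"scores": directory / "scores.csv"}
    scores.to_csv(paths["scores"], index=False)
    if doses is None:
        doses = pd.DataFrame(columns=list(DOSE_COLUMNS))
    paths["doses"] = directory / "doses.csv"
    doses.to_csv(paths["doses"], index=False)
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def read_fixture(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    directory = Path(directory)
    scores = pd.read_csv(directory / "scores.csv")
    doses = pd.read_csv(directory / "doses.csv")
    return scores, doses
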