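"""Synthetic datasets standing in for access-restricted empirical data.

Two generators are provided, both fully seeded:

* **onset trains** — sentences whose word-to-word onset differences are
  generated *by* the time-shift transform (a planted oscillation amplitude
  and phase) plus rate and previous-word-duration effects and Gaussian
  noise, so the grid-search regression can be validated by parameter
  recovery;
* **behavioural curves** — delay-response curves of the /da/–/ga/ experiment
  emulated as a damped sinusoid at the presentation rate with binomial
  trial noise, mimicking the qualitative shape of published phase-dependent
  categorisation data (stronger bias at short delays).

These are synthetic stand-ins: they reproduce the *structure* the analyses
expect, not any empirical dataset.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .temporal import OnsetTrain, relative_time_shift

__all__ = [
    "behavioral_curves_frame",
    "generate_behavioral_curves",
    "generate_onset_trains",
    "onset_trains_frame",
]


def generate_onset_trains(
    seed: int,
    n_sentences: int = 60,
    words_per_sentence: int = 10,
    amplitude: float = 1.5,
    phase_rad: float = -0.15 * np.pi,
    noise_sd_s: float = 0.0,
    base_interval_s: float = 0.32,
    rate_effect: float = -0.02,
    duration_effect: float = 0.5,
    mean_rate_hz: float = 4.0,
    rate_sd_hz: float = 0.5,
) -> list[OnsetTrain]:
    """Sentences whose timing is planted by the time-shift transform.

    Word predictions are drawn from a right-skewed Beta(0.6, 3) (most words
    weakly predicted, few strongly — the shape of language-model prediction
    distributions); the onset difference of word k is exactly the linear
    model the regression fits,

        base interval + shift(p_k) + b_r * rate + b_d * duration_{k-1} + noise

    where ``shift`` is the transform at the planted (amplitude, phase) and
    the sentence's own rate, so that with zero noise the planted parameters
    are recoverable with R² = 1.
    """
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_sentences):
        rate = float(np.clip(rng.normal(mean_rate_hz, rate_sd_hz), 2.0, 8.0))
        preds = rng.beta(0.6, 3.0, size=words_per_sentence)
        durations = rng.uniform(0.1, 0.4, size=words_per_sentence)
        diffs = []
        for k in range(1, words_per_sentence):
            shift = relative_time_shift(float(preds[k]), amplitude, phase_rad, rate)
            dt = (
                base_interval_s
                + shift
                + rate_effect * rate
                + duration_effect * durations[k - 1]
                + (rng.normal(0.0, noise_sd_s) if noise_sd_s > 0 else 0.0)
            )
            diffs.append(max(dt, 0.02))
        onsets = np.concatenate([[0.0], np.cumsum(diffs)])
        trains.append(OnsetTrain(onsets, preds, rate, durations))
    return trains


def onset_trains_frame(trains: Sequence[OnsetTrain]) -> pd.DataFrame:
    """Tidy CSV-ready view: one row per word."""
    rows = []
    for si, tr in enumerate(trains):
        for k in range(tr.onsets_s.size):
            rows.append(
                {
                    "sentence_id": si,
                    "onset_s": tr.onsets_s[k],
                    "prediction": tr.predictions[k],
                    "rate_hz": tr.rate_hz,
                    "duration_s": tr.durations_s[k] if tr.durations_s is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def trains_from_frame(df: pd.DataFrame) -> list[OnsetTrain]:
    trains = []
    for _, g in df.groupby("sentence_id"):
        g = g.sort_values("onset_s")
        trains.append(
            OnsetTrain(
                g["onset_s"].to_numpy(),
                g["prediction"].to_numpy(),
                float(g["rate_hz"].iloc[0]),
                g["duration_s"].to_numpy() if "duration_s" in g else None,
            )
        )
    return trains


@dataclass
class BehavioralCurve:
    rate_hz: float
    delays_ms: np.ndarray
    response: np.ndarray      # min-max normalised proportion /da/
    n_trials: int


def generate_behavioral_curves(
    seed: int,
    rates_hz: Sequence[float] = (6.25, 10.0),
    n_delays: int = 12,
    n_cycles: int = 2,
    amplitude: float = 0.35,
    damping_tau_s: float = 0.25,
    phase_rad: float = 0.5,
    baseline: float = 0.5,
    n_trials: int = 24,
) -> list[BehavioralCurve]:
    """Damped-sinusoid delay-response curves with binomial noise.

    The underlying probability of reporting /da/ at delay ``t`` is
    ``baseline + amplitude * exp(-t / tau) * sin(2*pi*rate*t + phase)``
    (clipped to [0, 1]); per delay, ``n_trials`` Bernoulli responses are
    drawn and the proportions are min-max normalised per rate, as done
    before fitting.  ``amplitude=0`` yields a delay-flat null curve.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for rate in rates_hz:
        span = n_cycles * 1000.0 / rate
        delays = np.arange(n_delays) * span / n_delays
        t = delays / 1000.0
        p = baseline + amplitude * np.exp(-t / damping_tau_s) * np.sin(
            2 * np.pi * rate * t + phase_rad
        )
        p = np.clip(p, 0.0, 1.0)
        prop = rng.binomial(n_trials, p) / n_trials
        lo, hi = prop.min(), prop.max()
        resp = np.full(prop.shape, 0.5) if hi == lo else (prop - lo) / (hi - lo)
        curves.append(BehavioralCurve(float(rate), delays, resp, n_trials))
    return curves


def behavioral_curves_frame(curves: Sequence[BehavioralCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for d, r in zip(c.delays_ms, c.response):
            rows.append(
                {
                    "rate_hz": c.rate_hz,
                    "delay_ms": d,
                    "response": r,
                    "n_trials": c.n_trials,
                }
            )
    return pd.DataFrame(rows)
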