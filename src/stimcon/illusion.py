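"""Phase-dependent categorisation of an ambiguous /da/–/ga/ syllable.

Two entrainer stimuli at a fixed rate set the oscillation's frame; an
ambiguous mixture of /da/ and /ga/ evidence follows at a variable delay.
Because /da/ receives stronger base prediction than /ga/ (0.2 vs 0.1), the
held feedback tips the race between the two nodes differently at different
delays: the delay (i.e. the oscillatory phase) of the final sound decides
which interpretation wins.

Two decoders summarise a trial: the identity of the first node to cross
threshold (1 = /da/, 0 = /ga/, 0.5 = tie or neither), and a graded index
``(da - ga) / (da + ga)`` of rectified mean activity over 500 ms after
onset.  A grid search over stimulus proportion, feedback onset, feedback
decay and a temporal offset fits either decoder to a behavioural
delay-response curve; a rectified fixed-frequency sinusoid serves as the
baseline model, and fits are compared by Gaussian-residual AIC.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core import ModelParams, OscillationParams, phase_for_peak_at, simulate
from .stimuli import ambiguous_mixture, build_sentence, daga_language_model, merge_trains

__all__ = [
    "GridSearchResult",
    "GridSearchSpec",
    "IllusionOutcome",
    "SinusFitResult",
    "aic",
    "grid_search_fit",
    "model_curve",
    "normalized_activity_curve",
    "outcome_curve",
    "rectified_sinus_fit",
    "run_daga_trial",
]

Decoder = Literal["first_active", "mean_activity"]


@dataclass
class IllusionOutcome:
    """Decoded percept for one delay of the ambiguous syllable."""

    delay_ms: float
    first_active: float          # 1 = /da/, 0 = /ga/, 0.5 = tie or neither
    activity_index: float        # raw (da-ga)/(da+ga) in [-1, 1]


def _default_params(rate_hz: float) -> ModelParams:
    return ModelParams(oscillation=OscillationParams(frequency_hz=rate_hz))


def run_daga_trial(
    p_da: float,
    delay_ms: float,
    rate_hz: float = 6.25,
    params: ModelParams | None = None,
    lm=None,
    intensity: float = 1.0,
    window_ms: float = 500.0,
    ramp_duration_ms: float = 125.0,
) -> IllusionOutcome:
    """Simulate /S1 S2 XXX/ with the ambiguous final sound at ``delay_ms``.

    The two entrainers are presented at the rate's SOA with unit intensity;
    the ambiguous input starts ``delay_ms`` after the isochronous position of
    the third stimulus.  The entrainment rate sets the oscillator frequency,
    and the phase is anchored to the first entrainer's input peak.
    """
    if lm is None:
        lm = daga_language_model()
    if params is None:
        params = _default_params(rate_hz)
    else:
        params = params.with_oscillation(frequency_hz=rate_hz)
    soa = 1000.0 / rate_hz
    onset = 2 * soa + delay_ms

    entrainers = build_sentence(
        lm, ["N1", "N2"], soa_ms=soa, dt_ms=params.dt_ms,
        ramp_duration_ms=ramp_duration_ms,
        padding_ms=delay_ms + ramp_duration_ms + window_ms + 2 * soa,
    )
    mixture = ambiguous_mixture(
        lm, "da", "ga", p_da, onset, intensity,
        time_ms=entrainers.time_ms, dt_ms=params.dt_ms,
        ramp_duration_ms=ramp_duration_ms,
    )
    stim = merge_trains(entrainers, mixture)
    params = params.with_oscillation(
        phase_rad=phase_for_peak_at(stim.first_input_peak_ms(), rate_hz)
    )
    res = simulate(lm, stim, params)

    i_da, i_ga = lm.index("da"), lm.index("ga")
    ev_da = res.events[i_da][res.events[i_da] >= onset]
    ev_ga = res.events[i_ga][res.events[i_ga] >= onset]
    t_da = ev_da[0] if ev_da.size else math.inf
    t_ga = ev_ga[0] if ev_ga.size else math.inf
    if t_da < t_ga:
        first = 1.0
    elif t_ga < t_da:
        first = 0.0
    elif math.isinf(t_da):
        first = 0.5
    else:  # same sample: higher activation wins
        it = int(round(t_da / params.dt_ms))
        a_da, a_ga = res.activation[i_da, it], res.activation[i_ga, it]
        first = 1.0 if a_da > a_ga else 0.0 if a_ga > a_da else 0.5

    i0 = int(round(onset / params.dt_ms))
    i1 = min(i0 + int(round(window_ms / params.dt_ms)), res.time_ms.size)
    act = np.maximum(res.activation[:, i0:i1], 0.0)
    m_da, m_ga = act[i_da].mean(), act[i_ga].mean()
    index = 0.0 if m_da + m_ga == 0 else (m_da - m_ga) / (m_da + m_ga)
    return IllusionOutcome(delay_ms, first, float(index))


def outcome_curve(
    p_da: float,
    rate_hz: float = 6.25,
    n_delays: int = 12,
    n_cycles: int = 2,
    params: ModelParams | None = None,
    lm=None,
    delay_offset_ms: float = 0.0,
    **trial_kwargs,
) -> list[IllusionOutcome]:
    """Outcomes at evenly spaced delays covering ``n_cycles`` of the rate.

    ``delay_offset_ms`` shifts the simulated onset of the final sound while
    keeping the nominal delay labels (the grid-search temporal offset).
    """
    if n_delays < 2:
        raise ValueError("need at least two delays")
    span = n_cycles * 1000.0 / rate_hz
    delays = np.arange(n_delays) * span / n_delays
    out = []
    for d in delays:
        o = run_daga_trial(
            p_da, float(d) + delay_offset_ms, rate_hz, params, lm, **trial_kwargs
        )
        out.append(IllusionOutcome(float(d), o.first_active, o.activity_index))
    return out


def normalized_activity_curve(outcomes: Sequence[IllusionOutcome]) -> np.ndarray:
    """Min-max scale the activity indices of a delay sweep to [0, 1]."""
    idx = np.array([o.activity_index for o in outcomes])
    lo, hi = idx.min(), idx.max()
    if hi == lo:
        return np.full(idx.shape, 0.5)
    return (idx - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# grid-search fit to behavioural curves
# ---------------------------------------------------------------------------

def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + k * step, 10) for k in range(n))


@dataclass(frozen=True)
class GridSearchSpec:
    """Sweep of the four fitted parameters (defaults as in the protocol)."""

    p_da_grid: tuple[float, ...] = field(default_factory=lambda: _grid(0.10, 0.80, 0.05))
    feedback_onset_grid: tuple[float, ...] = field(default_factory=lambda: _grid(0.1, 1.0, 0.1))
    decay_grid: tuple[float, ...] = field(default_factory=lambda: _grid(0.0, 0.10, 0.01))
    offset_grid_s: tuple[float, ...] = field(default_factory=lambda: _grid(-0.05, 0.05, 0.01))

    def size(self) -> int:
        return (
            len(self.p_da_grid)
            * len(self.feedback_onset_grid)
            * len(self.decay_grid)
            * len(self.offset_grid_s)
        )


@dataclass
class GridSearchResult:
    best: dict
    r2: float
    surface: "object"            # pandas DataFrame of all combinations
    decoder: str


def model_curve(
    p_da: float,
    feedback_onset_cycles: float,
    decay_per_ms: float,
    offset_s: float,
    delays_ms: np.ndarray,
    rate_hz: float,
    decoder: Decoder,
    params: ModelParams | None = None,
    lm=None,
) -> np.ndarray:
    """Model response at the behavioural delays for one parameter combo."""
    if params is None:
        params = _default_params(rate_hz)
    params = replace(
        params,
        feedback=replace(
            params.feedback,
            delay_cycles=feedback_onset_cycles,
            decay_per_ms=decay_per_ms,
        ),
    )
    outcomes = [
        run_daga_trial(p_da, float(d) + offset_s * 1000.0, rate_hz, params, lm)
        for d in delays_ms
    ]
    if decoder == "first_active":
        return np.array([o.first_active for o in outcomes])
    if decoder == "mean_activity":
        return normalized_activity_curve(outcomes)
    raise ValueError(f"unknown decoder {decoder!r}")


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0:
        return 0.0 if rss < 1e-12 else -math.inf
    return 1.0 - rss / tss


def grid_search_fit(
    delays_ms: Sequence[float],
    responses: Sequence[float],
    rate_hz: float,
    spec: GridSearchSpec = GridSearchSpec(),
    decoder: Decoder = "first_active",
    params: ModelParams | None = None,
    lm=None,
) -> GridSearchResult:
    """Exhaustive sweep of the spec's grids against a behavioural curve.

    ``responses`` should be min-max normalised to [0, 1] (matching the model
    outcome scale).  Returns the best parameter combination, its R², and the
    full surface.
    """
    import pandas as pd

    if spec.size() == 0:
        raise ValueError("empty parameter grid")
    delays = np.asarray(delays_ms, dtype=float)
    obs = np.asarray(responses, dtype=float)
    rows = []
    best_row, best_pred = None, None
    for p_da in spec.p_da_grid:
        for onset in spec.feedback_onset_grid:
            for decay in spec.decay_grid:
                for off in spec.offset_grid_s:
                    pred = model_curve(
                        p_da, onset, decay, off, delays, rate_hz, decoder, params, lm
                    )
                    r2 = _r_squared(obs, pred)
                    row = {
                        "p_da": p_da,
                        "feedback_onset_cycles": onset,
                        "decay_per_ms": decay,
                        "offset_s": off,
                        "r2": r2,
                    }
                    rows.append(row)
                    if best_row is None or r2 > best_row["r2"]:
                        best_row, best_pred = row, pred
    surface = pd.DataFrame(rows)
    best = dict(best_row)
    r2 = best.pop("r2")
    best["predicted"] = best_pred
    return GridSearchResult(best, r2, surface, decoder)


# ---------------------------------------------------------------------------
# rectified-sinusoid baseline and AIC
# ---------------------------------------------------------------------------

@dataclass
class SinusFitResult:
    amplitude: float
    phase_rad: float
    mean: float
    r2: float
    predicted: np.ndarray


def rectified_sinus_fit(
    delays_ms: Sequence[float],
    responses: Sequence[float],
    rate_hz: float,
    amplitude_grid: Sequence[float] | None = None,
    phase_grid: Sequence[float] | None = None,
    mean_grid: Sequence[float] | None = None,
    snap_levels: Sequence[float] | None = None,
) -> SinusFitResult:
    """Fixed-frequency sinusoid fitted by grid search.

    The model is ``mean + amplitude * sin(2*pi*rate*t + phase)``; when
    ``snap_levels`` is given (e.g. ``(0, 0.5, 1)``), predictions are snapped
    to the nearest level before scoring, matching a decoder that can only
    produce those values.
    """
    delays_s = np.asarray(delays_ms, dtype=float) / 1000.0
    obs = np.asarray(responses, dtype=float)
    if amplitude_grid is None:
        amplitude_grid = np.arange(0.0, 0.761, 0.02)
    if phase_grid is None:
        phase_grid = np.arange(0.0, 2 * np.pi, np.pi / 24)
    if mean_grid is None:
        mean_grid = np.arange(0.0, 1.001, 0.02)
    levels = None if snap_levels is None else np.asarray(snap_levels, dtype=float)
    best = None
    for amp in amplitude_grid:
        for ph in phase_grid:
            s = np.sin(2 * np.pi * rate_hz * delays_s + ph)
            for mu in mean_grid:
                pred = mu + amp * s
                if levels is not None:
                    pred = levels[np.argmin(np.abs(pred[:, None] - levels[None, :]), axis=1)]
                r2 = _r_squared(obs, pred)
                if best is None or r2 > best.r2:
                    best = SinusFitResult(float(amp), float(ph), float(mu), r2, pred)
    return best


def aic(rss: float, n: int, k: int) -> float:
    """Gaussian-residual Akaike information criterion, ``n ln(rss/n) + 2k``."""
    if n <= k:
        raise ValueError("need more observations than parameters")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("zero residual sum of squares; AIC is -inf", RuntimeWarning)
        return -math.inf
    return n * math.log(rss / n) + 2 * k
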