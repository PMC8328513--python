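"""Core oscillating-network model.

A single layer of word nodes is driven by four additive terms at every
integration step (1 ms by default):

    A[j, t] = bottom_up[j, t] + feedback[j, t] + inhib(Ta[j]) + osc(t)

``Ta[j]`` is the time since node *j* last crossed the activation threshold
(infinite before the first crossing), ``inhib`` is a three-regime gate that
briefly excites a node after it fires and then suppresses it, and ``osc`` is
a fixed sinusoidal excitability drive that is *not* phase-reset by the input.

Top-down feedback implements the internal language model: when a node crosses
threshold while receiving bottom-up input, the prediction row of that word is
projected back onto the layer after a delay of ``delay_cycles`` oscillatory
cycles.  The projected signal holds at ``gain * p`` for as long as the source
node remains suprathreshold (shifted by the same delay) and afterwards decays
linearly at ``decay_per_ms``, so that a word's predictions pre-activate the
likely next words for roughly one cycle.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .stimuli import StimulusTrain

__all__ = [
    "ConfigurationError",
    "FeedbackParams",
    "InhibitionParams",
    "LanguageModel",
    "ModelParams",
    "OscillationParams",
    "SimulationResult",
    "feedback_drive",
    "first_event_time",
    "inhibition_gate",
    "oscillation",
    "phase_for_peak_at",
    "simulate",
]

NEVER_ACTIVATED = math.inf
"""Sentinel for the time-since-activation of a node that has never fired."""


class ConfigurationError(ValueError):
    """A simulation was configured inconsistently (step size, axes, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LanguageModel:
    """A word-to-word prediction matrix over a fixed vocabulary.

    ``prediction[i, j]`` is the probability that word ``j`` follows word
    ``i``.  Rows need not sum to one: the mass assigned outside the modelled
    vocabulary is simply dropped (a terminal word may have an all-zero row).
    """

    vocabulary: tuple[str, ...]
    prediction: np.ndarray

    def __post_init__(self) -> None:
        pred = np.asarray(self.prediction, dtype=float)
        object.__setattr__(self, "prediction", pred)
        n = len(self.vocabulary)
        if pred.shape != (n, n):
            raise ValueError(
                f"prediction matrix shape {pred.shape} does not match "
                f"vocabulary of {n} words"
            )
        if np.any(pred < 0) or np.any(pred > 1):
            raise ValueError("prediction probabilities must lie in [0, 1]")
        if len(set(self.vocabulary)) != n:
            raise ValueError("vocabulary labels must be unique")

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    def index(self, word: str) -> int:
        try:
            return self.vocabulary.index(word)
        except ValueError:
            raise KeyError(f"unknown word {word!r}") from None

    def row(self, word: str) -> np.ndarray:
        """Prediction distribution over the next word, given ``word``."""
        return self.prediction[self.index(word)]

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "vocabulary": list(self.vocabulary),
            "prediction": self.prediction.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LanguageModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(tuple(payload["vocabulary"]), np.array(payload["prediction"]))


@dataclass(frozen=True)
class OscillationParams:
    """Constant sinusoidal excitability drive ``Am * cos(2*pi*f*t + phi)``."""

    amplitude: float = 1.0
    frequency_hz: float = 4.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.frequency_hz


@dataclass(frozen=True)
class InhibitionParams:
    """Three-regime gate on time-since-activation.

    A node that fired ``Ta`` ms ago receives ``-3 * base_inhib`` (net
    excitation, since ``base_inhib`` is negative) while ``Ta`` is inside the
    excitation window, ``+3 * base_inhib`` (refractory suppression) until
    ``recovery_ms``, and the base inhibition afterwards and before any
    activation.
    """

    base_inhib: float = -0.2
    excitation_window_ms: float = 20.0
    recovery_ms: float = 100.0
    activation_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.base_inhib >= 0:
            raise ValueError("base_inhib must be negative")
        if not 0 < self.excitation_window_ms < self.recovery_ms:
            raise ValueError("need 0 < excitation_window_ms < recovery_ms")
        if self.activation_threshold <= 0:
            raise ValueError("activation_threshold must be positive")


@dataclass(frozen=True)
class FeedbackParams:
    """Timing and strength of the language-model feedback projection."""

    delay_cycles: float = 0.9
    decay_per_ms: float = 0.01
    gain: float = 1.5

    def __post_init__(self) -> None:
        if self.delay_cycles <= 0:
            raise ValueError("delay_cycles must be positive")
        if self.decay_per_ms < 0:
            raise ValueError("decay_per_ms must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class ModelParams:
    oscillation: OscillationParams = field(default_factory=OscillationParams)
    inhibition: InhibitionParams = field(default_factory=InhibitionParams)
    feedback: FeedbackParams = field(default_factory=FeedbackParams)
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigurationError("integration step dt_ms must be positive")

    def with_oscillation(self, **kwargs) -> "ModelParams":
        from dataclasses import replace
        return replace(self, oscillation=replace(self.oscillation, **kwargs))

    def with_feedback(self, **kwargs) -> "ModelParams":
        from dataclasses import replace
        return replace(self, feedback=replace(self.feedback, **kwargs))


@dataclass
class SimulationResult:
    """Per-node traces and suprathreshold event times of one simulation."""

    vocabulary: tuple[str, ...]
    time_ms: np.ndarray
    activation: np.ndarray           # (n_nodes, n_times)
    ta: np.ndarray                   # (n_nodes, n_times), inf before 1st event
    events: list[np.ndarray]         # per-node crossing times, ms

    def events_for(self, word: str) -> np.ndarray:
        return self.events[self.vocabulary.index(word)]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def inhibition_gate(ta_ms, params: InhibitionParams = InhibitionParams()):
    """Inhibition as a function of time since activation.

    Accepts scalars or arrays; ``math.inf`` (or ``NEVER_ACTIVATED``) encodes a
    node that has not yet fired and receives base inhibition.  Negative finite
    times are rejected.
    """
    ta = np.asarray(ta_ms, dtype=float)
    if np.any(np.isfinite(ta) & (ta < 0)):
        raise ValueError("time-since-activation must be non-negative")
    b = params.base_inhib
    out = np.full(ta.shape, b)
    out[ta < params.recovery_ms] = 3 * b
    out[ta < params.excitation_window_ms] = -3 * b
    return float(out) if np.isscalar(ta_ms) else out


def oscillation(t_ms, params: OscillationParams = OscillationParams()):
    """Excitability drive at time ``t_ms``: the real (cosine) projection."""
    t = np.asarray(t_ms, dtype=float)
    out = params.amplitude * np.cos(
        2 * np.pi * params.frequency_hz * t / 1000.0 + params.phase_rad
    )
    return float(out) if np.isscalar(t_ms) else out


def phase_for_peak_at(t_peak_ms: float, frequency_hz: float) -> float:
    """Phase offset placing the oscillation peak at ``t_peak_ms``.

    The convention throughout is that the excitability peak is aligned with
    the maximum of the first word's sensory input.
    """
    return float(-2 * np.pi * frequency_hz * t_peak_ms / 1000.0)


def feedback_drive(
    lm: LanguageModel,
    context_word: str,
    t_since_arrival_ms: float,
    params: FeedbackParams = FeedbackParams(),
    hold_ms: float = 0.0,
) -> np.ndarray:
    """Per-node top-down drive from ``context_word``'s prediction row.

    Returns zero for all nodes before arrival (``t_since_arrival_ms < 0``).
    From arrival the drive is ``gain * p`` for ``hold_ms`` (the duration for
    which the source node stayed suprathreshold; 0 for an instantaneous
    source) and then decays linearly at ``decay_per_ms``, floored at zero.
    """
    row = lm.row(context_word)
    if t_since_arrival_ms < 0:
        return np.zeros(lm.n_words)
    full = params.gain * row
    if t_since_arrival_ms <= hold_ms:
        return full
    return np.maximum(0.0, full - params.decay_per_ms * (t_since_arrival_ms - hold_ms))


# ---------------------------------------------------------------------------
# time-stepped integration
# ---------------------------------------------------------------------------

class _FeedbackSource:
    """One triggered prediction projection (source node fired once)."""

    __slots__ = ("arrival_ms", "row", "hold_end_ms", "source")

    def __init__(self, arrival_ms: float, row: np.ndarray, source: int):
        self.arrival_ms = arrival_ms
        self.row = row                  # gain-scaled prediction row
        self.hold_end_ms: float | None = None  # None while source is supra
        self.source = source

    def value_at(self, t_ms: float, decay_per_ms: float) -> np.ndarray | None:
        if t_ms < self.arrival_ms:
            return None
        end = self.hold_end_ms if self.hold_end_ms is not None else math.inf
        if t_ms <= end:
            return self.row
        return np.maximum(0.0, self.row - decay_per_ms * (t_ms - end))


def simulate(
    lm: LanguageModel,
    stim: "StimulusTrain",
    params: ModelParams = ModelParams(),
) -> SimulationResult:
    """Integrate the network over the stimulus train.

    At every step each node's activation is the sum of bottom-up input,
    current feedback drive, the inhibition gate at its time-since-activation,
    and the oscillation.  Threshold crossings *from below* are recorded as
    events; an event resets the node's time-since-activation and — if the
    node was receiving bottom-up input from one of the train's words — its
    prediction row is scheduled as feedback, once per word occurrence.
    """
    n = lm.n_words
    if stim.input.shape[0] != n:
        raise ConfigurationError(
            f"stimulus has {stim.input.shape[0]} node rows, "
            f"language model has {n} words"
        )
    if stim.dt_ms != params.dt_ms:
        raise ConfigurationError(
            f"stimulus step ({stim.dt_ms} ms) differs from model step "
            f"({params.dt_ms} ms)"
        )
    dt = params.dt_ms
    time = stim.time_ms
    nt = time.size
    U = stim.input
    osc = oscillation(time, params.oscillation)
    inh = params.inhibition
    thresh = inh.activation_threshold
    arrival_delay = params.feedback.delay_cycles * params.oscillation.cycle_ms
    decay = params.feedback.decay_per_ms
    gain = params.feedback.gain

    ta = np.full(n, NEVER_ACTIVATED)
    a_prev = np.full(n, -np.inf)
    supra_prev = np.zeros(n, dtype=bool)
    activation = np.empty((n, nt))
    ta_trace = np.empty((n, nt))
    events: list[list[float]] = [[] for _ in range(n)]
    sources: list[_FeedbackSource] = []
    occurrence_used = [False] * len(stim.word_onsets)

    b = inh.base_inhib
    for it in range(nt):
        t = float(time[it])
        fb = np.zeros(n)
        for src in sources:
            v = src.value_at(t, decay)
            if v is not None:
                fb += v
        gate = np.full(n, b)
        gate[ta < inh.recovery_ms] = 3 * b
        gate[ta < inh.excitation_window_ms] = -3 * b
        a = U[:, it] + fb + gate + osc[it]
        supra = a >= thresh
        crossed = supra & (a_prev < thresh)
        ta = np.where(crossed, 0.0, ta + dt)
        activation[:, it] = a
        ta_trace[:, it] = ta
        for j in np.flatnonzero(crossed):
            events[j].append(t)
            if U[j, it] > 0:
                for k, occ in enumerate(stim.word_onsets):
                    if (
                        occ.node == j
                        and not occurrence_used[k]
                        and occ.support_start_ms <= t <= occ.support_end_ms
                        and occ.intensity > 0
                    ):
                        occurrence_used[k] = True
                        sources.append(
                            _FeedbackSource(t + arrival_delay, gain * lm.prediction[j], j)
                        )
                        break
        for src in sources:
            if src.hold_end_ms is None and supra_prev[src.source] and not supra[src.source]:
                # source dropped below threshold: hold covers its supra period
                src.hold_end_ms = (t - dt) + arrival_delay
        a_prev = a
        supra_prev = supra

    return SimulationResult(
        vocabulary=lm.vocabulary,
        time_ms=time,
        activation=activation,
        ta=ta_trace,
        events=[np.asarray(e) for e in events],
    )


def first_event_time(
    result: SimulationResult, word: str, reference_ms: float = 0.0
) -> float | None:
    """First suprathreshold event of ``word`` at/after ``reference_ms``,
    expressed relative to the reference; ``None`` if there is none."""
    ev = result.events_for(word)
    later = ev[ev >= reference_ms]
    if later.size == 0:
        return None
    return float(later[0] - reference_ms)
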