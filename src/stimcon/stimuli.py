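"""Bottom-up stimulus construction.

Word input is an abstract evidence trace per node, not an acoustic waveform:
a linear ramp models the increasing confidence that the incoming word is the
node's word (0 to peak over 125 ms, half a 4-Hz cycle), a truncated Gaussian
models a symmetric evidence profile.  Sentences place one such trace per word
at a base stimulus onset asynchrony, and an ambiguous syllable splits a fixed
total intensity between two candidate nodes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import LanguageModel

__all__ = [
    "StimulusTrain",
    "WordOnset",
    "ambiguous_mixture",
    "build_sentence",
    "chain_language_model",
    "daga_language_model",
    "gaussian_input",
    "linear_ramp",
    "fixture_language_models",
    "table_language_model",
]

GAUSSIAN_TRUNCATE_SD = 3.0


@dataclass(frozen=True)
class WordOnset:
    """One word occurrence in a train: which node, when, how strong."""

    node: int
    onset_ms: float
    intensity: float
    peak_ms: float            # time of the input maximum (phase anchor)
    support_start_ms: float
    support_end_ms: float


@dataclass
class StimulusTrain:
    """Per-node bottom-up input sampled on the integration grid."""

    input: np.ndarray               # (n_nodes, n_times)
    dt_ms: float = 1.0
    word_onsets: list[WordOnset] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.input.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.input.shape[1] * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.input.shape[1]) * self.dt_ms

    def first_input_peak_ms(self) -> float:
        """Time of the first word's input maximum (oscillation anchor)."""
        if not self.word_onsets:
            return 0.0
        first = min(self.word_onsets, key=lambda w: w.onset_ms)
        return first.peak_ms


def _time_axis(duration_ms: float, dt_ms: float) -> np.ndarray:
    return np.arange(0.0, duration_ms, dt_ms)


def linear_ramp(
    time_ms: np.ndarray,
    onset_ms: float,
    duration_ms: float = 125.0,
    intensity: float = 1.0,
) -> np.ndarray:
    """Linear evidence ramp: 0 at onset, ``intensity`` at onset+duration.

    The endpoint sample is included (the peak is attained); the trace is zero
    outside the closed support.
    """
    if duration_ms <= 0:
        raise ValueError("ramp duration must be positive")
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    out = np.zeros_like(time_ms, dtype=float)
    m = (time_ms >= onset_ms) & (time_ms <= onset_ms + duration_ms)
    out[m] = intensity * (time_ms[m] - onset_ms) / duration_ms
    return out


def gaussian_input(
    time_ms: np.ndarray,
    center_ms: float,
    sd_ms: float = 42.0,
    intensity: float = 1.0,
) -> np.ndarray:
    """Gaussian evidence bump peaking at ``intensity``, truncated at ±3 sd."""
    if sd_ms <= 0:
        raise ValueError("sd must be positive")
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    out = intensity * np.exp(-0.5 * ((time_ms - center_ms) / sd_ms) ** 2)
    out[np.abs(time_ms - center_ms) > GAUSSIAN_TRUNCATE_SD * sd_ms] = 0.0
    return out


Shape = Literal["ramp", "gaussian"]


def _word_trace(shape: Shape, time_ms, onset_ms, intensity,
                ramp_duration_ms: float, gaussian_sd_ms: float):
    if shape == "ramp":
        trace = linear_ramp(time_ms, onset_ms, ramp_duration_ms, intensity)
        return trace, onset_ms + ramp_duration_ms, onset_ms, onset_ms + ramp_duration_ms
    if shape == "gaussian":
        trace = gaussian_input(time_ms, onset_ms, gaussian_sd_ms, intensity)
        half = GAUSSIAN_TRUNCATE_SD * gaussian_sd_ms
        return trace, onset_ms, onset_ms - half, onset_ms + half
    raise ValueError(f"unknown input shape {shape!r}")


def build_sentence(
    lm: LanguageModel,
    words: Sequence[str],
    soa_ms: float = 250.0,
    intensities: Sequence[float] | float = 1.0,
    shifts_ms: Sequence[float] | float = 0.0,
    shape: Shape = "ramp",
    dt_ms: float = 1.0,
    ramp_duration_ms: float = 125.0,
    gaussian_sd_ms: float = 42.0,
    padding_ms: float | None = None,
) -> StimulusTrain:
    """Place word ``k`` at ``k * soa_ms + shift_k`` with its intensity.

    For a ramp the onset is the ramp start; for a Gaussian the onset is the
    mean (so with zero shift the means sit on the isochronous grid).  The
    train extends one full cycle (``soa_ms``) past the last word's support
    unless ``padding_ms`` overrides that.  Overlapping inputs on a node sum.
    """
    if soa_ms <= 0:
        raise ValueError("soa must be positive")
    n_words = len(words)
    if np.isscalar(intensities):
        intensities = [float(intensities)] * n_words
    if np.isscalar(shifts_ms):
        shifts_ms = [float(shifts_ms)] * n_words
    if not (len(intensities) == len(shifts_ms) == n_words):
        raise ValueError("intensities and shifts must match the word list")
    nodes = [lm.index(w) for w in words]

    if n_words == 0:
        return StimulusTrain(np.zeros((lm.n_words, 0)), dt_ms, [])

    onsets = [k * soa_ms + shifts_ms[k] for k in range(n_words)]
    support = ramp_duration_ms if shape == "ramp" else GAUSSIAN_TRUNCATE_SD * gaussian_sd_ms
    pad = soa_ms if padding_ms is None else padding_ms
    duration = max(onsets) + support + pad
    time = _time_axis(duration, dt_ms)
    U = np.zeros((lm.n_words, time.size))
    word_onsets = []
    for node, onset, inten in zip(nodes, onsets, intensities):
        trace, peak, s0, s1 = _word_trace(
            shape, time, onset, inten, ramp_duration_ms, gaussian_sd_ms
        )
        U[node] += trace
        word_onsets.append(WordOnset(node, onset, inten, peak, s0, s1))
    return StimulusTrain(U, dt_ms, word_onsets)


def ambiguous_mixture(
    lm: LanguageModel,
    da_word: str,
    ga_word: str,
    p_da: float,
    onset_ms: float,
    intensity: float = 1.0,
    time_ms: np.ndarray | None = None,
    shape: Shape = "ramp",
    dt_ms: float = 1.0,
    ramp_duration_ms: float = 125.0,
    gaussian_sd_ms: float = 42.0,
) -> StimulusTrain:
    """Ambiguous two-node input: peaks ``p_da*I`` and ``(1-p_da)*I``.

    The two component inputs share onset and shape, so their peak intensities
    always sum to ``intensity``.
    """
    if not 0 <= p_da <= 1:
        raise ValueError("p_da must lie in [0, 1]")
    if time_ms is None:
        support = ramp_duration_ms if shape == "ramp" else GAUSSIAN_TRUNCATE_SD * gaussian_sd_ms
        time_ms = _time_axis(onset_ms + support + 1000.0 / 4.0, dt_ms)
    U = np.zeros((lm.n_words, time_ms.size))
    word_onsets = []
    for word, inten in ((da_word, p_da * intensity), (ga_word, (1 - p_da) * intensity)):
        node = lm.index(word)
        trace, peak, s0, s1 = _word_trace(
            shape, time_ms, onset_ms, inten, ramp_duration_ms, gaussian_sd_ms
        )
        U[node] += trace
        word_onsets.append(WordOnset(node, onset_ms, inten, peak, s0, s1))
    return StimulusTrain(U, dt_ms, word_onsets)


def merge_trains(a: StimulusTrain, b: StimulusTrain) -> StimulusTrain:
    """Superpose two trains built on the same node set and step."""
    if a.dt_ms != b.dt_ms or a.n_nodes != b.n_nodes:
        raise ValueError("trains must share node set and step size")
    nt = max(a.input.shape[1], b.input.shape[1])
    U = np.zeros((a.n_nodes, nt))
    U[:, : a.input.shape[1]] += a.input
    U[:, : b.input.shape[1]] += b.input
    return StimulusTrain(U, a.dt_ms, list(a.word_onsets) + list(b.word_onsets))


# ---------------------------------------------------------------------------
# fixture language models
# ---------------------------------------------------------------------------

def table_language_model() -> LanguageModel:
    """Five-word toy model trained on three sentences.

    The sentences /I eat cake/, /I eat nice cake/ and /I eat very nice cake/
    were seen with probabilities 0.5, 0.3 and 0.2, so /I/ predicts /eat/ with
    certainty while /eat/ spreads its prediction over /very/, /nice/ and
    /cake/ (0.2 / 0.3 / 0.5); /cake/, sentence-final, predicts nothing.
    """
    vocab = ("I", "eat", "very", "nice", "cake")
    P = np.zeros((5, 5))
    P[0, 1] = 1.0                       # I -> eat
    P[1, 2], P[1, 3], P[1, 4] = 0.2, 0.3, 0.5   # eat -> very/nice/cake
    P[2, 3] = 1.0                       # very -> nice
    P[3, 4] = 1.0                       # nice -> cake
    return LanguageModel(vocab, P)


def daga_language_model(p_da: float = 0.2, p_ga: float = 0.1) -> LanguageModel:
    """Four-node entrainment model for the /da/–/ga/ experiment.

    N1 (first entrainer) predicts N2 with certainty; N2 predicts the /da/
    and /ga/ interpretations at unequal base rates (0.2 vs 0.1 by default),
    reflecting the higher prevalence of /da/.
    """
    vocab = ("N1", "N2", "da", "ga")
    P = np.zeros((4, 4))
    P[0, 1] = 1.0
    P[1, 2], P[1, 3] = p_da, p_ga
    return LanguageModel(vocab, P)


def fixture_language_models() -> tuple[LanguageModel, LanguageModel]:
    """The two toy models used throughout: (five-word, /da/–/ga/)."""
    return table_language_model(), daga_language_model()


def chain_language_model(predictabilities: Sequence[float]) -> LanguageModel:
    """Chain of ``len(p)+1`` words where word k predicts word k+1 at p[k].

    Used for the rhythmicity experiment, where word-to-word predictability is
    constant or alternates along a 10-word sequence.
    """
    n = len(predictabilities) + 1
    vocab = tuple(f"w{k}" for k in range(n))
    P = np.zeros((n, n))
    for k, p in enumerate(predictabilities):
        if not 0 <= p <= 1:
            raise ValueError("predictabilities must lie in [0, 1]")
        P[k, k + 1] = p
    return LanguageModel(vocab, P)
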