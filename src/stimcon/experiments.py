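"""Simulation experiments: processing-efficiency maps, timing compression,
and rhythmicity of the network response to (pseudo-)rhythmic input.

The efficiency experiment presents /context ... target/ with the final word
varied in onset delay (relative to the isochronous grid) and peak intensity,
and records when the target node first crosses threshold — relative to the
stimulus onset (*supra-time*) and relative to the isochronous grid
(*iso-time*).  The compression statistic compares how much the stimulus
moved against how much the response moved on the oscillation clock.

The rhythmicity experiment drives the network with a 10-word train whose
odd words are shifted in time and whose word-to-word predictability is
constant or alternating, and measures the spectral magnitude of the summed
rectified activation at the stimulation rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    LanguageModel,
    ModelParams,
    first_event_time,
    phase_for_peak_at,
    simulate,
)
from .stimuli import StimulusTrain, build_sentence, chain_language_model

__all__ = [
    "Contour",
    "ContourGapError",
    "CompressionResult",
    "EfficiencyMap",
    "RhythmicityGrid",
    "compression_ratio",
    "efficiency_map",
    "fixed_intensity_contour",
    "magnitude_spectrum",
    "monotone_section",
    "overall_activity",
    "rhythmicity_experiment",
    "saturation_intensity",
    "threshold_contour",
]


class ContourGapError(ValueError):
    """The requested delay window contains cells with no suprathreshold event."""


# ---------------------------------------------------------------------------
# efficiency maps
# ---------------------------------------------------------------------------

@dataclass
class EfficiencyMap:
    """Supra-/iso-times of the target node over a delay x intensity grid."""

    target: str
    delays_ms: np.ndarray
    intensities: np.ndarray
    supra_time_ms: np.ndarray   # (n_delays, n_intensities); NaN = no event
    iso_time_ms: np.ndarray     # supra + delay

    def to_frame(self):
        import pandas as pd

        d, i = np.meshgrid(self.delays_ms, self.intensities, indexing="ij")
        return pd.DataFrame(
            {
                "delay_ms": d.ravel(),
                "intensity": i.ravel(),
                "supra_time_ms": self.supra_time_ms.ravel(),
                "iso_time_ms": self.iso_time_ms.ravel(),
            }
        )


def _aligned_params(stim: StimulusTrain, params: ModelParams) -> ModelParams:
    phi = phase_for_peak_at(stim.first_input_peak_ms(), params.oscillation.frequency_hz)
    return params.with_oscillation(phase_rad=phi)


def efficiency_map(
    lm: LanguageModel,
    context: Sequence[str],
    target: str,
    delays_ms: Sequence[float],
    intensities: Sequence[float],
    params: ModelParams = ModelParams(),
    soa_ms: float = 250.0,
    context_intensity: float = 1.0,
    shape: str = "ramp",
) -> EfficiencyMap:
    """Sweep the final word's onset delay and intensity.

    The oscillation phase is re-anchored to the first context word's input
    peak for every cell (the context is identical across cells, so this is a
    fixed alignment).  Cells whose target node never crosses threshold at or
    after the stimulus onset are NaN.
    """
    lm.index(target)
    delays = np.asarray(delays_ms, dtype=float)
    intens = np.asarray(intensities, dtype=float)
    n_ctx = len(context)
    supra = np.full((delays.size, intens.size), np.nan)
    for di, d in enumerate(delays):
        for ii, inten in enumerate(intens):
            words = list(context) + [target]
            word_int = [context_intensity] * n_ctx + [float(inten)]
            shifts = [0.0] * n_ctx + [float(d)]
            stim = build_sentence(
                lm, words, soa_ms=soa_ms, intensities=word_int,
                shifts_ms=shifts, shape=shape, dt_ms=params.dt_ms,
                padding_ms=2 * soa_ms,
            )
            res = simulate(lm, stim, _aligned_params(stim, params))
            onset = n_ctx * soa_ms + d
            st = first_event_time(res, target, onset)
            if st is not None:
                supra[di, ii] = st
    iso = supra + delays[:, None]
    return EfficiencyMap(target, delays, intens, supra, iso)


@dataclass
class Contour:
    """One line through an efficiency map: event times vs onset delay."""

    delays_ms: np.ndarray
    supra_time_ms: np.ndarray   # NaN where undefined
    iso_time_ms: np.ndarray
    intensity: np.ndarray       # intensity at which the event was measured

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.supra_time_ms)


def fixed_intensity_contour(emap: EfficiencyMap, intensity: float) -> Contour:
    """The map line at a single stimulus intensity."""
    ii = int(np.argmin(np.abs(emap.intensities - intensity)))
    if abs(emap.intensities[ii] - intensity) > 1e-9:
        raise ValueError(
            f"intensity {intensity} not on the map grid "
            f"(nearest: {emap.intensities[ii]})"
        )
    return Contour(
        emap.delays_ms,
        emap.supra_time_ms[:, ii],
        emap.iso_time_ms[:, ii],
        np.full(emap.delays_ms.shape, emap.intensities[ii]),
    )


def threshold_contour(emap: EfficiencyMap) -> Contour:
    """Per delay, the lowest intensity with an event, and its times."""
    nd = emap.delays_ms.size
    supra = np.full(nd, np.nan)
    iso = np.full(nd, np.nan)
    inten = np.full(nd, np.nan)
    for di in range(nd):
        defined = np.flatnonzero(~np.isnan(emap.supra_time_ms[di]))
        if defined.size:
            ii = defined[np.argmin(emap.intensities[defined])]
            supra[di] = emap.supra_time_ms[di, ii]
            iso[di] = emap.iso_time_ms[di, ii]
            inten[di] = emap.intensities[ii]
    return Contour(emap.delays_ms, supra, iso, inten)


def monotone_section(contour: Contour) -> tuple[float, float]:
    """Maximal contiguous delay window with monotone iso-time.

    Contiguity means consecutive grid delays all defined; monotone is
    non-strict, in either direction.  Returns the (lo, hi) delay bounds.
    """
    d = contour.delays_ms
    iso = contour.iso_time_ms
    ok = contour.defined
    best = None
    for direction in (1, -1):
        i = 0
        while i < d.size:
            if not ok[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < d.size
                and ok[j + 1]
                and direction * (iso[j + 1] - iso[j]) >= 0
            ):
                j += 1
            if best is None or d[j] - d[i] > best[1] - best[0]:
                best = (float(d[i]), float(d[j]))
            i = j + 1 if j > i else i + 1
    if best is None:
        raise ContourGapError("contour has no defined cells")
    return best


@dataclass
class CompressionResult:
    """Stimulus-vs-response timing variation over a delay window."""

    window_ms: tuple[float, float]
    stimulus_range_ms: float
    response_range_ms: float
    ratio: float                    # stimulus / response; inf if response flat
    cycle_ms: float

    @property
    def stimulus_pct_of_cycle(self) -> float:
        return 100.0 * self.stimulus_range_ms / self.cycle_ms

    @property
    def response_pct_of_cycle(self) -> float:
        return 100.0 * self.response_range_ms / self.cycle_ms

    @property
    def perfect_compression(self) -> bool:
        return not np.isfinite(self.ratio)


def compression_ratio(
    contour: Contour,
    window_ms: tuple[float, float] | None = None,
    cycle_ms: float = 250.0,
) -> CompressionResult:
    """Width of the delay window over the iso-time range across it.

    ``window_ms`` defaults to the contour's maximal monotone section.  Every
    grid delay inside the window must carry an event, otherwise a
    :class:`ContourGapError` is raised.  A response range of zero (perfectly
    pinned events) yields an infinite ratio flagged as perfect compression.
    """
    if window_ms is None:
        window_ms = monotone_section(contour)
    lo, hi = window_ms
    m = (contour.delays_ms >= lo) & (contour.delays_ms <= hi)
    if not m.any():
        raise ContourGapError("window contains no grid delays")
    if np.isnan(contour.iso_time_ms[m]).any():
        raise ContourGapError(
            f"undefined cells inside the window [{lo}, {hi}] ms"
        )
    iso = contour.iso_time_ms[m]
    d = contour.delays_ms[m]
    stim_range = float(d.max() - d.min())
    resp_range = float(iso.max() - iso.min())
    ratio = np.inf if resp_range == 0 else stim_range / resp_range
    return CompressionResult((lo, hi), stim_range, resp_range, ratio, cycle_ms)


def full_line_window(contour: Contour) -> tuple[float, float]:
    """Bounds of the longest contiguous defined segment of the contour."""
    d = contour.delays_ms
    ok = contour.defined
    best = None
    i = 0
    while i < d.size:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < d.size and ok[j + 1]:
            j += 1
        if best is None or d[j] - d[i] > best[1] - best[0]:
            best = (float(d[i]), float(d[j]))
        i = j + 1
    if best is None:
        raise ContourGapError("contour has no defined cells")
    return best


# ---------------------------------------------------------------------------
# saturation intensity
# ---------------------------------------------------------------------------

def saturation_intensity(
    params: ModelParams = ModelParams(),
    intensity_step: float = 0.01,
    onset_step_ms: float = 1.0,
    max_intensity: float = 4.0,
    ramp_duration_ms: float = 125.0,
) -> float:
    """Minimal ramp peak intensity that activates a feedback-free node at
    *every* onset phase of the oscillation.

    For each onset delay across one cycle the smallest intensity producing a
    threshold crossing is found (bisection on the intensity grid); the
    saturation intensity is the maximum over onsets, i.e. the intensity
    needed at the least excitable phase.
    """
    lm = LanguageModel(("x",), np.zeros((1, 1)))
    cycle = params.oscillation.cycle_ms
    grid = np.round(
        np.arange(intensity_step, max_intensity + intensity_step / 2, intensity_step),
        10,
    )

    def has_event(onset: float, inten: float) -> bool:
        stim = build_sentence(
            lm, ["x"], soa_ms=cycle, intensities=[inten],
            shifts_ms=[onset], dt_ms=params.dt_ms,
            ramp_duration_ms=ramp_duration_ms, padding_ms=2 * cycle,
        )
        # fixed phase: peak at the zero-delay ramp end, onset shifts the word
        p = params.with_oscillation(
            phase_rad=phase_for_peak_at(ramp_duration_ms, params.oscillation.frequency_hz)
        )
        res = simulate(lm, stim, p)
        return first_event_time(res, "x", onset) is not None

    worst = 0.0
    for onset in np.arange(0.0, cycle, onset_step_ms):
        a, b = 0, grid.size - 1
        if not has_event(onset, float(grid[b])):
            raise ValueError("max_intensity too small to saturate")
        while a < b:
            mid = (a + b) // 2
            if has_event(onset, float(grid[mid])):
                b = mid
            else:
                a = mid + 1
        worst = max(worst, float(grid[a]))
    return worst


# ---------------------------------------------------------------------------
# rhythmicity
# ---------------------------------------------------------------------------

PATTERNS = ("low", "high", "low-high", "high-low")


def pattern_predictabilities(
    pattern: str, n_words: int = 10, low: float = 0.0, high: float = 0.8
) -> list[float]:
    """Word-to-word predictability schedule along the sequence.

    The label reads off the per-word predictability along the sentence,
    starting with the (never predicted) first word: in ``low-high`` the
    odd-numbered words (0-based 1, 3, 5, ... — the ones whose onsets the
    experiment shifts) are the highly predicted ones, in ``high-low`` the
    even-numbered words are.  Returned are the ``n_words - 1`` transition
    probabilities P(word k+1 | word k).
    """
    n_tr = n_words - 1
    if pattern == "low":
        return [low] * n_tr
    if pattern == "high":
        return [high] * n_tr
    if pattern == "low-high":
        return [high if k % 2 == 0 else low for k in range(n_tr)]
    if pattern == "high-low":
        return [low if k % 2 == 0 else high for k in range(n_tr)]
    raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")


def overall_activity(result) -> np.ndarray:
    """Summed, zero-rectified activation across all word nodes."""
    return np.maximum(result.activation, 0.0).sum(axis=0)


def magnitude_spectrum(
    signal: np.ndarray,
    dt_ms: float,
    segment_ms: tuple[float, float] = (500.0, 2500.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered magnitude spectrum of the mean-removed segment."""
    i0 = int(round(segment_ms[0] / dt_ms))
    i1 = int(round(segment_ms[1] / dt_ms))
    if i1 > signal.size:
        raise ValueError("analysis segment exceeds the simulated duration")
    seg = signal[i0:i1]
    seg = (seg - seg.mean()) * np.hanning(seg.size)
    mag = np.abs(np.fft.rfft(seg))
    freqs = np.fft.rfftfreq(seg.size, d=dt_ms / 1000.0)
    return freqs, mag


@dataclass
class RhythmicityGrid:
    """Spectral magnitude at the stimulation rate per (offset, intensity)."""

    pattern: str
    odd_offsets_ms: np.ndarray
    intensities: np.ndarray
    power_at_rate: np.ndarray   # (n_offsets, n_intensities)

    def to_frame(self):
        import pandas as pd

        o, i = np.meshgrid(self.odd_offsets_ms, self.intensities, indexing="ij")
        return pd.DataFrame(
            {
                "odd_offset_ms": o.ravel(),
                "intensity": i.ravel(),
                "power_at_rate": self.power_at_rate.ravel(),
            }
        )

    def peak_offset(self, intensity: float) -> float:
        """Odd-word offset maximising power at the given intensity."""
        ii = int(np.argmin(np.abs(self.intensities - intensity)))
        return float(self.odd_offsets_ms[np.argmax(self.power_at_rate[:, ii])])


def rhythmicity_experiment(
    pattern: str,
    odd_offsets_ms: Sequence[float],
    intensities: Sequence[float],
    params: ModelParams = ModelParams(),
    n_words: int = 10,
    rate_hz: float = 4.0,
    segment_ms: tuple[float, float] = (500.0, 2500.0),
    low: float = 0.0,
    high: float = 0.8,
) -> RhythmicityGrid:
    """4-Hz response magnitude under shifted odd words.

    A 10-word train at the base rate with Gaussian inputs is simulated for
    every (odd offset, intensity) cell; the summed rectified activation is
    tapered and Fourier-transformed, and the magnitude at the bin nearest
    the stimulation rate is recorded.
    """
    lm = chain_language_model(pattern_predictabilities(pattern, n_words, low, high))
    soa = 1000.0 / rate_hz
    offsets = np.asarray(odd_offsets_ms, dtype=float)
    intens = np.asarray(intensities, dtype=float)
    power = np.zeros((offsets.size, intens.size))
    words = list(lm.vocabulary)
    for oi, off in enumerate(offsets):
        shifts = [float(off) if k % 2 == 1 else 0.0 for k in range(n_words)]
        for ii, inten in enumerate(intens):
            stim = build_sentence(
                lm, words, soa_ms=soa, intensities=float(inten),
                shifts_ms=shifts, shape="gaussian", dt_ms=params.dt_ms,
                padding_ms=segment_ms[1] - (n_words - 1) * soa + soa,
            )
            res = simulate(lm, stim, _aligned_params(stim, params))
            freqs, mag = magnitude_spectrum(
                overall_activity(res), params.dt_ms, segment_ms
            )
            power[oi, ii] = mag[np.argmin(np.abs(freqs - rate_hz))]
    return RhythmicityGrid(pattern, offsets, intens, power)
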