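"""Closed-form timing statistics and onset-train analysis.

When all terms of the network equation except the top-down prediction and
the oscillation are held fixed, the moment at which a prediction of strength
``p`` can first tip a node over threshold is where the sinusoid balances the
prediction, ``-Am * sin(2*pi*omega*T + phi) = p``.  Solving for ``T`` on the
principal branch gives the *relative time shift*

    T = (arcsin(p / -Am) - phi) / (2*pi*omega)

which is negative (earlier processing) for stronger predictions: a phase
code for predictability.  The sine convention measures phase from the
ascending zero-crossing of the excitability drive; the same sinusoid in the
core model's cosine convention is ``oscillation(t, phi - pi/2)``.

The module also provides the spectral isochrony statistic for word-onset
impulse trains and the grid-search regression that recovers the oscillation
amplitude and phase from onset timing data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OnsetTrain",
    "SpectrumResult",
    "TimeShiftFit",
    "fit_expected_onsets",
    "onset_spectrum",
    "rate_from_duration",
    "relative_time_shift",
]


@dataclass
class OnsetTrain:
    """Word onsets of one sentence with per-word predictions.

    ``durations_s`` are per-word durations (used as the previous-word
    duration covariate in the regression); ``rate_hz`` is the sentence's
    syllable/word rate, which sets the oscillator frequency for the
    time-shift transform.
    """

    onsets_s: np.ndarray
    predictions: np.ndarray
    rate_hz: float
    durations_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any((self.predictions < 0) | (self.predictions > 1)):
            raise ValueError("predictions must lie in [0, 1]")
        if self.durations_s is not None:
            self.durations_s = np.asarray(self.durations_s, dtype=float)


def relative_time_shift(
    prediction,
    amplitude: float = 1.5,
    phase_rad: float = 0.0,
    frequency_hz: float = 4.0,
):
    """Expected processing-time shift (s) for a prediction strength.

    Monotonically decreasing in ``prediction``: a fully predicted word can be
    processed up to a quarter cycle early.  Predictions exceeding the
    oscillation amplitude are clamped to the branch limit with a warning
    (grid searches may legitimately cross it).
    """
    if amplitude == 0:
        raise ValueError("amplitude must be non-zero")
    p = np.asarray(prediction, dtype=float)
    x = p / -amplitude
    if np.any(np.abs(x) > 1):
        warnings.warn(
            "prediction exceeds oscillation amplitude; clamped to branch limit",
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.clip(x, -1.0, 1.0)
    out = (np.arcsin(x) - phase_rad) / (2 * np.pi * frequency_hz)
    return float(out) if np.isscalar(prediction) else out


def rate_from_duration(duration_s: float, n_units: int = 1) -> float:
    """Unit rate implied by a duration: a 250 ms bisyllabic word is 8 Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    return n_units / duration_s


@dataclass
class SpectrumResult:
    freqs_hz: np.ndarray
    z_power: np.ndarray
    band_peak_z: float
    band_peak_hz: float


def onset_spectrum(
    onsets_s: Sequence[float],
    fs_hz: float = 100.0,
    band_hz: tuple[float, float] = (3.0, 8.0),
    fmax_hz: float = 15.0,
) -> SpectrumResult:
    """Theta-band isochrony statistic of an onset train.

    Onsets are binarised into an impulse train at ``fs_hz``, Fourier power is
    z-scored across the 0..``fmax_hz`` bins, and the maximal z within the
    band is returned.  Uniformly shifting all onsets leaves the statistic
    unchanged; jittering them lowers it.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if onsets.size < 2:
        raise ValueError("need at least two onsets")
    duration = onsets.max() - onsets.min()
    if duration < 1.0:
        raise ValueError("train must span at least one second")
    t0 = onsets.min()
    n = int(np.floor((duration) * fs_hz)) + 1
    train = np.zeros(n)
    idx = np.round((onsets - t0) * fs_hz).astype(int)
    train[np.clip(idx, 0, n - 1)] = 1.0
    power = np.abs(np.fft.rfft(train)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    keep = freqs <= fmax_hz
    freqs, power = freqs[keep], power[keep]
    z = (power - power.mean()) / power.std(ddof=0)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("band contains no frequency bins")
    bi = np.flatnonzero(in_band)[np.argmax(z[in_band])]
    return SpectrumResult(freqs, z, float(z[bi]), float(freqs[bi]))


# ---------------------------------------------------------------------------
# onset-difference regression
# ---------------------------------------------------------------------------

@dataclass
class TimeShiftFit:
    """Out-of-sample R² surface of the grid search over (amplitude, phase)."""

    amplitudes: np.ndarray
    phases_rad: np.ndarray
    r2: np.ndarray                # (n_amplitudes, n_phases)
    best_amplitude: float
    best_phase_rad: float
    baseline_r2: float            # covariates only, no transform

    def to_frame(self):
        import pandas as pd

        a, p = np.meshgrid(self.amplitudes, self.phases_rad, indexing="ij")
        return pd.DataFrame(
            {"amplitude": a.ravel(), "phase_rad": p.ravel(), "r2": self.r2.ravel()}
        )


def _design(trains: Sequence[OnsetTrain], amplitude, phase):
    """Stack (onset difference, transform, rate, previous duration) rows."""
    ys, xs = [], []
    for tr in trains:
        diffs = np.diff(tr.onsets_s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            shift = relative_time_shift(
                tr.predictions[1:], amplitude, phase, tr.rate_hz
            )
        prev_dur = (
            tr.durations_s[:-1]
            if tr.durations_s is not None
            else np.zeros(diffs.size)
        )
        ys.append(diffs)
        xs.append(
            np.column_stack([shift, np.full(diffs.size, tr.rate_hz), prev_dur])
        )
    return np.concatenate(ys), np.vstack(xs)


def _cv_r2(y, X, rng, n_splits, test_frac) -> float:
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    n = y.size
    n_test = max(1, int(round(test_frac * n)))
    scores = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        try:
            res = sm.OLS(y[train], Xc[train]).fit()
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise np.linalg.LinAlgError("singular design matrix") from err
        pred = res.predict(Xc[test])
        ss_res = np.sum((y[test] - pred) ** 2)
        ss_tot = np.sum((y[test] - y[test].mean()) ** 2)
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(np.mean(scores))


def fit_expected_onsets(
    trains: Sequence[OnsetTrain],
    amplitudes: Sequence[float],
    phases_rad: Sequence[float],
    n_splits: int = 100,
    test_frac: float = 0.1,
    seed: int | None = 0,
) -> TimeShiftFit:
    """Grid-search the oscillation (amplitude, phase) against onset timing.

    For each grid point the per-word predictions are passed through the
    time-shift transform (with the sentence's own rate as frequency) and the
    actual word-to-word onset differences are regressed on the transform plus
    the rate and previous-word-duration covariates.  The score is the
    out-of-sample R² averaged over repeated random train/test splits; a
    covariate-only baseline is fitted for comparison.
    """
    amps = np.asarray(amplitudes, dtype=float)
    phis = np.asarray(phases_rad, dtype=float)
    rng = np.random.default_rng(seed)
    r2 = np.zeros((amps.size, phis.size))
    for ai, am in enumerate(amps):
        for pi, ph in enumerate(phis):
            y, X = _design(trains, am, ph)
            split_rng = np.random.default_rng(rng.integers(2**31))
            r2[ai, pi] = _cv_r2(y, X, split_rng, n_splits, test_frac)
    y, X = _design(trains, float(amps[0]), 0.0)
    baseline = _cv_r2(
        y, X[:, 1:], np.random.default_rng(rng.integers(2**31)), n_splits, test_frac
    )
    bi = np.unravel_index(np.argmax(r2), r2.shape)
    return TimeShiftFit(
        amps, phis, r2, float(amps[bi[0]]), float(phis[bi[1]]), baseline
    )
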