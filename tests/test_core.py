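import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimcon import (
    ConfigurationError,
    FeedbackParams,
    InhibitionParams,
    LanguageModel,
    ModelParams,
    OscillationParams,
    build_sentence,
    feedback_drive,
    first_event_time,
    inhibition_gate,
    oscillation,
    simulate,
)
from stimcon.core import NEVER_ACTIVATED

from conftest import aligned_params, run_sentence


class TestInhibitionGate:
    @pytest.mark.parametrize(
        "ta, expected",
        [
            (10.0, 0.6),               # early excitation window
            (0.0, 0.6),
            (19.999, 0.6),
            (20.0, -0.6),              # refractory suppression
            (50.0, -0.6),
            (99.999, -0.6),
            (100.0, -0.2),             # recovered to base
            (150.0, -0.2),
            (NEVER_ACTIVATED, -0.2),   # never activated -> base
        ],
    )
    def test_three_regimes(self, ta, expected):
        assert inhibition_gate(ta) == pytest.approx(expected)

    def test_negative_ta_rejected(self):
        with pytest.raises(ValueError):
            inhibition_gate(-1.0)

    def test_only_three_values_over_dense_sweep(self):
        """The gate is piecewise constant with exactly {-3b, 3b, b}."""
        params = InhibitionParams(base_inhib=-0.3)
        ta = np.arange(0.0, 400.0, 0.25)
        values = set(np.round(inhibition_gate(ta, params), 12))
        assert values == {0.9, -0.9, -0.3}


class TestOscillation:
    @pytest.mark.parametrize(
        "t, expected", [(0.0, 1.0), (62.5, 0.0), (125.0, -1.0), (250.0, 1.0)]
    )
    def test_cosine_values_at_4hz(self, t, expected):
        assert oscillation(t) == pytest.approx(expected, abs=1e-12)

    @given(
        t=st.floats(-500, 500),
        k=st.integers(-3, 3),
        freq=st.floats(1.0, 10.0),
        phi=st.floats(-np.pi, np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t, k, freq, phi):
        p = OscillationParams(1.3, freq, phi)
        period_ms = 1000.0 / freq
        assert oscillation(t, p) == pytest.approx(
            oscillation(t + k * period_ms, p), abs=1e-9
        )


class TestFeedbackDrive:
    def test_certain_prediction_arrives_at_full_gain(self, table_lm):
        drive = feedback_drive(table_lm, "I", 0.0)
        assert drive[table_lm.index("eat")] == pytest.approx(1.5)
        assert np.count_nonzero(drive) == 1

    def test_spread_prediction_scales_each_row_entry(self, table_lm):
        drive = feedback_drive(table_lm, "eat", 0.0)
        expect = {"cake": 0.75, "nice": 0.45, "very": 0.30}
        for word, val in expect.items():
            assert drive[table_lm.index(word)] == pytest.approx(val)

    def test_zero_before_arrival_and_after_decay(self, table_lm):
        assert not feedback_drive(table_lm, "I", -1.0).any()
        # 1.5 / 0.01 = 150 ms to the floor
        assert not feedback_drive(table_lm, "I", 151.0).any()

    def test_hold_postpones_decay(self, table_lm):
        held = feedback_drive(table_lm, "I", 100.0, hold_ms=90.0)
        assert held[table_lm.index("eat")] == pytest.approx(1.5 - 0.01 * 10)

    def test_unknown_context_is_key_error(self, table_lm):
        with pytest.raises(KeyError):
            feedback_drive(table_lm, "pie", 0.0)


class TestSimulate:
    def test_oscillation_plus_base_inhibition_stays_subthreshold(self, table_lm):
        """Am=1 with base -0.2 peaks at 0.8 < threshold: silence without input."""
        from stimcon.stimuli import StimulusTrain

        stim = StimulusTrain(np.zeros((table_lm.n_words, 500)), 1.0, [])
        res = simulate(table_lm, stim, ModelParams())
        assert all(ev.size == 0 for ev in res.events)

    def test_predicted_word_reaches_threshold_earlier(self, table_lm):
        sup = {}
        for w in ("cake", "nice", "very", "I"):
            res = run_sentence(table_lm, ["I", "eat", w])
            sup[w] = first_event_time(res, w, 500.0)
        assert sup["cake"] < sup["nice"] < sup["very"] < sup["I"]

    def test_event_samples_are_suprathreshold_and_reset_ta(self, table_lm):
        res = run_sentence(table_lm, ["I", "eat", "cake"])
        for j, ev in enumerate(res.events):
            for t in ev:
                it = int(round(t))
                assert res.activation[j, it] >= 1.0
                assert res.ta[j, it] == 0.0
        # ta grows by the step away from events and is never negative
        assert (res.ta[np.isfinite(res.ta)] >= 0).all()

    def test_step_mismatch_is_configuration_error(self, table_lm):
        stim = build_sentence(table_lm, ["I"], dt_ms=2.0)
        with pytest.raises(ConfigurationError):
            simulate(table_lm, stim, ModelParams(dt_ms=1.0))

    def test_node_count_mismatch_is_configuration_error(self, table_lm):
        small = LanguageModel(("a",), np.zeros((1, 1)))
        stim = build_sentence(small, ["a"])
        with pytest.raises(ConfigurationError):
            simulate(table_lm, stim, ModelParams())


class TestFirstEventTime:
    def test_subtracts_reference(self, table_lm):
        res = run_sentence(table_lm, ["I"])
        ev = res.events_for("I")[0]
        assert first_event_time(res, "I", 10.0) == pytest.approx(ev - 10.0)

    def test_absent_without_events(self, table_lm):
        res = run_sentence(table_lm, ["I"], intensities=0.0)
        assert first_event_time(res, "I", 0.0) is None

    def test_skips_events_before_reference(self, table_lm):
        res = run_sentence(table_lm, ["I", "eat"])
        # /eat/ fires once; referencing past it yields absent
        t = res.events_for("eat")[-1]
        assert first_event_time(res, "eat", t + 1.0) is None


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_events(P, words, duration_ms, *, amplitude, frequency, phi,
                  base=-0.2, exc=20.0, rec=100.0, thresh=1.0,
                  delay_cycles=0.9, decay=0.01, gain=1.5, ramp_dur=125.0):
    """Naive scalar transcription of the update rule (independent oracle).

    ``words`` is a list of (node, onset, intensity) ramps.  Returns per-node
    event-time lists.  Everything is plain-Python on a 1 ms grid.
    """
    n = len(P)
    steps = int(duration_ms)
    delay = delay_cycles / frequency * 1000.0

    def inp(j, t):
        total = 0.0
        for (node, onset, inten) in words:
            if node == j and onset <= t <= onset + ramp_dur:
                total += inten * (t - onset) / ramp_dur
        return total

    ta = [None] * n                    # None = never activated
    prev_a = [-1e18] * n
    prev_supra = [False] * n
    used = [False] * len(words)
    feedbacks = []                     # dict: arrival, row, hold_end, source
    events = [[] for _ in range(n)]
    for t in range(steps):
        osc = amplitude * math.cos(2 * math.pi * frequency * t / 1000.0 + phi)
        acts = []
        for j in range(n):
            fb = 0.0
            for f in feedbacks:
                if t < f["arrival"]:
                    continue
                end = f["hold_end"]
                if end is None or t <= end:
                    fb += f["row"][j]
                else:
                    fb += max(0.0, f["row"][j] - decay * (t - end))
            if ta[j] is None or ta[j] >= rec:
                gate = base
            elif ta[j] >= exc:
                gate = 3 * base
            else:
                gate = -3 * base
            acts.append(inp(j, t) + fb + gate + osc)
        supra = [a >= thresh for a in acts]
        for j in range(n):
            if supra[j] and prev_a[j] < thresh:
                events[j].append(float(t))
                ta[j] = 0.0
                if inp(j, t) > 0:
                    for k, (node, onset, inten) in enumerate(words):
                        if (node == j and not used[k]
                                and onset <= t <= onset + ramp_dur and inten > 0):
                            used[k] = True
                            feedbacks.append({
                                "arrival": t + delay,
                                "row": [gain * p for p in P[j]],
                                "hold_end": None,
                                "source": j,
                            })
                            break
            elif ta[j] is not None:
                ta[j] += 1.0
        for f in feedbacks:
            if f["hold_end"] is None and prev_supra[f["source"]] and not supra[f["source"]]:
                f["hold_end"] = (t - 1.0) + delay
        prev_a = acts
        prev_supra = supra
    return events


def test_simulator_matches_brute_force_oracle():
    """Identical event times on random small trains (10 seeded draws)."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        n = 3
        P = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(P, 0.0)
        n_words = rng.integers(2, 5)
        words = [
            (int(rng.integers(n)), float(rng.integers(0, 400)),
             float(np.round(rng.uniform(0.5, 2.0), 2)))
            for _ in range(n_words)
        ]
        phi = float(rng.uniform(-np.pi, np.pi))
        lm = LanguageModel(tuple("abc"), P)
        duration = 800.0
        time = np.arange(0.0, duration)
        from stimcon.stimuli import StimulusTrain, WordOnset, linear_ramp

        U = np.zeros((n, time.size))
        onsets = []
        for (j, onset, inten) in words:
            U[j] += linear_ramp(time, onset, 125.0, inten)
            onsets.append(WordOnset(j, onset, inten, onset + 125.0, onset, onset + 125.0))
        stim = StimulusTrain(U, 1.0, onsets)
        params = ModelParams(oscillation=OscillationParams(1.0, 4.0, phi))
        res = simulate(lm, stim, params)
        expected = oracle_events(
            P.tolist(), words, duration, amplitude=1.0, frequency=4.0, phi=phi
        )
        for j in range(n):
            assert list(res.events[j]) == expected[j], f"trial {trial}, node {j}"
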