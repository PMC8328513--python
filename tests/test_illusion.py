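import math

import numpy as np
import pytest

from stimcon import (
    GridSearchSpec,
    ModelParams,
    OscillationParams,
    aic,
    grid_search_fit,
    outcome_curve,
    rectified_sinus_fit,
    run_daga_trial,
)
from stimcon.illusion import model_curve, normalized_activity_curve
from stimcon.stimuli import daga_language_model
from stimcon.fixtures import generate_behavioral_curves

ABLATION_SPEC = GridSearchSpec(
    p_da_grid=(0.35, 0.5), feedback_onset_grid=(0.3, 0.6, 0.9),
    decay_grid=(0.01,), offset_grid_s=(-0.04, -0.02, 0.0, 0.02, 0.04),
)


@pytest.fixture(scope="module")
def fixture_curve():
    return generate_behavioral_curves(seed=2, rates_hz=(6.25,))[0]


@pytest.fixture(scope="module")
def full_fit(fixture_curve):
    return grid_search_fit(
        fixture_curve.delays_ms, fixture_curve.response, 6.25,
        ABLATION_SPEC, "first_active",
    )


class TestRunDagaTrial:
    def test_unopposed_stimulus_is_perceived(self):
        out = run_daga_trial(1.0, 40.0)
        assert out.first_active == 1.0

    def test_exact_symmetry_yields_tie(self):
        lm = daga_language_model(0.15, 0.15)
        for delay in (0.0, 60.0, 130.0):
            out = run_daga_trial(0.5, delay, lm=lm)
            assert out.first_active == 0.5
            assert out.activity_index == pytest.approx(0.0)

    def test_delay_changes_the_percept(self):
        values = {run_daga_trial(0.4, d).first_active for d in (30.0, 160.0)}
        assert len(values) > 1


class TestOutcomeCurve:
    def test_delay_spacing_covers_two_cycles(self):
        cur = outcome_curve(0.5, 6.25)
        delays = [o.delay_ms for o in cur]
        assert len(delays) == 12
        assert delays[1] - delays[0] == pytest.approx(320.0 / 12)
        cur10 = outcome_curve(0.5, 10.0)
        assert max(o.delay_ms for o in cur10) < 200.0 <= max(
            o.delay_ms for o in cur10
        ) + 200.0 / 12

    def test_needs_at_least_two_delays(self):
        with pytest.raises(ValueError):
            outcome_curve(0.5, 6.25, n_delays=1)

    def test_da_bias_at_ambiguity_and_stronger_at_short_delays(self):
        """Uneven 0.2/0.1 feedback tips a 50/50 stimulus toward /da/,
        more strongly early in the sweep."""
        cur = outcome_curve(0.5, 6.25)
        fa = np.array([o.first_active for o in cur])
        assert fa.mean() >= 0.5
        assert fa[:6].mean() >= fa[6:].mean()

    def test_decoders_agree_at_ambiguity(self):
        """Where /da/ fires first the graded index is on the /da/ side."""
        cur = outcome_curve(0.5, 6.25)
        norm = normalized_activity_curve(cur)
        for o, g in zip(cur, norm):
            if o.first_active == 1.0:
                assert g >= 0.5
            elif o.first_active == 0.0:
                assert g <= 0.5

    def test_without_oscillation_the_curve_is_delay_flat(self):
        params = ModelParams(oscillation=OscillationParams(amplitude=0.0))
        cur = outcome_curve(0.4, 6.25, params=params)
        fa = {o.first_active for o in cur}
        idx = np.array([o.activity_index for o in cur])
        assert len(fa) == 1
        assert np.ptp(idx) < 0.01


class TestGridSearchFit:
    delays = np.array([o.delay_ms for o in outcome_curve(0.5, 6.25)])

    def test_recovers_self_generated_curve_exactly(self):
        planted = dict(p_da=0.4, feedback_onset_cycles=0.9,
                       decay_per_ms=0.01, offset_s=0.0)
        target = model_curve(
            planted["p_da"], planted["feedback_onset_cycles"],
            planted["decay_per_ms"], planted["offset_s"],
            self.delays, 6.25, "first_active",
        )
        spec = GridSearchSpec(
            p_da_grid=(0.3, 0.4), feedback_onset_grid=(0.7, 0.9),
            decay_grid=(0.01,), offset_grid_s=(0.0,),
        )
        res = grid_search_fit(self.delays, target, 6.25, spec, "first_active")
        assert res.r2 == pytest.approx(1.0)
        for key, val in planted.items():
            assert res.best[key] == pytest.approx(val)

    ablation_spec = ABLATION_SPEC

    def test_oscillation_ablation_cannot_beat_the_mean(self, fixture_curve, full_fit):
        """Fitting a fixture curve without the oscillation leaves R² <= 0."""
        no_osc = grid_search_fit(
            fixture_curve.delays_ms, fixture_curve.response, 6.25,
            self.ablation_spec, "first_active",
            params=ModelParams(oscillation=OscillationParams(amplitude=0.0)),
        )
        assert no_osc.r2 <= 0.0
        assert full_fit.r2 > no_osc.r2

    def test_feedback_equalisation_degrades_the_fit(self, fixture_curve, full_fit):
        equal = grid_search_fit(
            fixture_curve.delays_ms, fixture_curve.response, 6.25,
            self.ablation_spec, "first_active",
            lm=daga_language_model(0.15, 0.15),
        )
        assert full_fit.r2 >= equal.r2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_fit(
                self.delays, np.zeros(12), 6.25,
                GridSearchSpec(p_da_grid=(), feedback_onset_grid=(0.9,),
                               decay_grid=(0.01,), offset_grid_s=(0.0,)),
            )


class TestRectifiedSinusFit:
    delays = np.arange(12) * 320.0 / 12

    def test_pure_sinusoid_is_fit_exactly(self):
        t = self.delays / 1000.0
        resp = 0.5 + 0.2 * np.sin(2 * np.pi * 6.25 * t + np.pi / 2)
        fit = rectified_sinus_fit(
            self.delays, resp, 6.25,
            amplitude_grid=[0.1, 0.2, 0.3],
            phase_grid=[0.0, np.pi / 2, np.pi],
            mean_grid=[0.4, 0.5, 0.6],
        )
        assert fit.r2 == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(0.2)

    def test_snapping_helps_on_a_discrete_curve(self):
        t = self.delays / 1000.0
        resp = (np.sin(2 * np.pi * 6.25 * t + 0.3) > 0).astype(float)
        plain = rectified_sinus_fit(self.delays, resp, 6.25)
        snapped = rectified_sinus_fit(
            self.delays, resp, 6.25, snap_levels=(0.0, 0.5, 1.0)
        )
        assert snapped.r2 >= plain.r2

    def test_constant_curve_is_mean_only(self):
        fit = rectified_sinus_fit(
            self.delays, np.full(12, 0.5), 6.25,
            amplitude_grid=[0.0, 0.2], phase_grid=[0.0], mean_grid=[0.4, 0.5],
        )
        assert fit.amplitude == 0.0
        assert fit.r2 == pytest.approx(0.0)


class TestAic:
    def test_unit_rss_per_observation_scores_zero(self):
        assert aic(12.0, 12, 0) == pytest.approx(0.0)

    def test_parameter_penalty_is_monotone(self):
        assert aic(1.0, 12, 4) > aic(1.0, 12, 3)

    def test_zero_rss_warns_and_returns_minus_inf(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 12, 3) == -math.inf

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            aic(1.0, 3, 3)
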