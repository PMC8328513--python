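import numpy as np
import pytest

from stimcon import (
    ModelParams,
    build_sentence,
    phase_for_peak_at,
    simulate,
    table_language_model,
)


@pytest.fixture(scope="session")
def table_lm():
    return table_language_model()


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


def aligned_params(stim, params=None, frequency_hz=4.0):
    """Model parameters with the oscillation peak on the first input peak."""
    params = params or ModelParams()
    return params.with_oscillation(
        frequency_hz=frequency_hz,
        phase_rad=phase_for_peak_at(stim.first_input_peak_ms(), frequency_hz),
    )


def run_sentence(lm, words, **kwargs):
    """Build, align and simulate a ramp sentence in one call."""
    params = kwargs.pop("params", None)
    stim = build_sentence(lm, words, **kwargs)
    return simulate(lm, stim, aligned_params(stim, params))
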