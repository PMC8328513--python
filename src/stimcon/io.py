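"""Tidy CSV views of simulations and stimuli."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SimulationResult
from .stimuli import StimulusTrain

__all__ = ["events_frame", "stimulus_frame", "traces_frame"]


def traces_frame(result: SimulationResult) -> pd.DataFrame:
    """Long format: time_ms, node, activation, ta (inf ta left as inf)."""
    n, nt = result.activation.shape
    return pd.DataFrame(
        {
            "time_ms": np.tile(result.time_ms, n),
            "node": np.repeat(list(result.vocabulary), nt),
            "activation": result.activation.ravel(),
            "ta": result.ta.ravel(),
        }
    )


def events_frame(result: SimulationResult) -> pd.DataFrame:
    rows = [
        {"node": word, "event_time_ms": t}
        for word, ev in zip(result.vocabulary, result.events)
        for t in ev
    ]
    return pd.DataFrame(rows, columns=["node", "event_time_ms"])


def stimulus_frame(stim: StimulusTrain, vocabulary) -> pd.DataFrame:
    n, nt = stim.input.shape
    return pd.DataFrame(
        {
            "time_ms": np.tile(stim.time_ms, n),
            "node": np.repeat(list(vocabulary), nt),
            "input": stim.input.ravel(),
        }
    )
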