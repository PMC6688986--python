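from __future__ import annotations

import numpy as np
import pytest

from spikelearn.inputs import AsyncExample, InputGenParams
from spikelearn.lif_neuron import OutputTrace


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def gen_params() -> InputGenParams:
    return InputGenParams()


def make_example(
    units,
    times,
    amps=None,
    n_units=None,
    scenario="synaptic",
    resolution_ms=0.01,
    primary=None,
    dendrite_order=None,
) -> AsyncExample:
    """Hand-build a sorted example from plain lists."""
    units = np.asarray(units, dtype=np.int64)
    times = np.asarray(times, dtype=np.float64)
    if amps is None:
        amps = np.ones(len(units))
    if primary is None:
        primary = np.ones(len(units), dtype=bool)
    if n_units is None:
        n_units = int(units.max()) + 1 if len(units) else 2
    order = np.lexsort((units, times))
    return AsyncExample(
        unit_index=units[order],
        time_ms=times[order],
        amplitude=np.asarray(amps, dtype=np.float64)[order],
        primary=np.asarray(primary, dtype=bool)[order],
        n_units=n_units,
        scenario=scenario,
        resolution_ms=resolution_ms,
        dendrite_order=dendrite_order,
    )


def make_trace(bits, times) -> OutputTrace:
    bits = np.asarray(bits, dtype=np.int8)
    times = np.asarray(times, dtype=np.float64)
    return OutputTrace(per_event_output=bits, spike_times=times[bits == 1])
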