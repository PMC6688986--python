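"""Event-driven leaky integrate-and-fire output unit.

Input is a train of delta pulses, so the membrane voltage obeys the exact
closed form ``v(t+dt) = v_rest + (v - v_rest) * exp(-dt/tau)`` between
events and can only cross threshold at an event instant.  A crossing
(``v >= v_threshold``) emits an output bit 1 and resets the voltage to
``v_rest``; otherwise the bit is 0.  No refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inputs import AsyncExample

__all__ = [
    "LIFParams",
    "NeuronState",
    "OutputTrace",
    "decay_voltage",
    "apply_event",
    "run_example_single_unit",
    "run_example_dendritic",
    "integrate_events",
]


@dataclass(frozen=True)
class LIFParams:
    tau_mem: float = 20.0
    v_threshold: float = 1.0
    v_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")


@dataclass
class NeuronState:
    voltage: float = 0.0
    last_event_time: float = 0.0
    spike_times: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class OutputTrace:
    """Per-event binary outputs of one network on one example."""

    per_event_output: np.ndarray  # int8, aligned to example event order
    spike_times: np.ndarray  # float64, sorted

    def __post_init__(self) -> None:
        if int(np.count_nonzero(self.per_event_output)) != len(self.spike_times):
            raise ValueError("spike count must equal number of output-1 events")

    @property
    def subthreshold_events(self) -> np.ndarray:
        return np.flatnonzero(self.per_event_output == 0)

    def to_tsv(self, path: str | Path, example: AsyncExample) -> None:
        with open(path, "w") as fh:
            fh.write("event_index\ttime_ms\toutput_bit\n")
            for k, (t, o) in enumerate(zip(example.time_ms, self.per_event_output)):
                fh.write(f"{k}\t{float(t)!r}\t{int(o)}\n")


def decay_voltage(v: float, dt: float, params: LIFParams) -> float:
    """Exact exponential relaxation of the voltage toward rest over ``dt``."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    return params.v_rest + (v - params.v_rest) * math.exp(-dt / params.tau_mem)


def apply_event(
    state: NeuronState, time: float, drive: float, params: LIFParams
) -> tuple[NeuronState, int]:
    """Decay to ``time``, add ``drive``, emit/reset on threshold crossing."""
    if time < state.last_event_time:
        raise ValueError(
            f"event time {time} precedes last event time {state.last_event_time}"
        )
    if drive < 0:
        raise ValueError(f"drive must be non-negative, got {drive}")
    v = decay_voltage(state.voltage, time - state.last_event_time, params) + drive
    if v >= params.v_threshold:
        state.spike_times.append(time)
        state.voltage = params.v_rest
        bit = 1
    else:
        state.voltage = v
        bit = 0
    state.last_event_time = time
    return state, bit


def _integrate_py(times, drives, tau, v_rest, v_th, out_bits):
    v = v_rest
    t_last = 0.0
    for k in range(times.shape[0]):
        t = times[k]
        v = v_rest + (v - v_rest) * math.exp((t_last - t) / tau)
        v = v + drives[k]
        if v >= v_th:
            out_bits[k] = 1
            v = v_rest
        t_last = t
    return v


try:  # optional JIT of the hot loop; semantics identical to the Python path
    from numba import njit

    _integrate = njit(cache=True)(_integrate_py)
except Exception:  # pragma: no cover
    _integrate = _integrate_py


def integrate_events(
    times: np.ndarray, drives: np.ndarray, params: LIFParams
) -> np.ndarray:
    """Output bits for a sorted delta-pulse train starting from rest."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    drives = np.ascontiguousarray(drives, dtype=np.float64)
    if times.shape != drives.shape:
        raise ValueError("times and drives must have equal length")
    bits = np.zeros(len(times), dtype=np.int8)
    _integrate(times, drives, params.tau_mem, params.v_rest, params.v_threshold, bits)
    return bits


def run_example_single_unit(
    effective_drives: np.ndarray, example: AsyncExample, params: LIFParams
) -> OutputTrace:
    """Feed one example into a single LIF unit, one drive per event."""
    drives = np.asarray(effective_drives, dtype=np.float64)
    if len(drives) != example.n_events:
        raise ValueError(
            f"{len(drives)} drives for {example.n_events} events"
        )
    bits = integrate_events(example.time_ms, drives, params)
    return OutputTrace(
        per_event_output=bits, spike_times=example.time_ms[bits == 1].copy()
    )


def run_example_dendritic(
    strengths: np.ndarray,
    weights: np.ndarray,
    example: AsyncExample,
    params: LIFParams,
) -> OutputTrace:
    """Per-dendrite LIF integration; dendrite ``i`` owns units ``5i..5i+4``.

    Each dendrite integrates only its own members' events, scaled by its
    strength ``J_i``; a spike resets that dendrite's voltage only.  The
    network output train is the union of the dendritic spikes.
    """
    strengths = np.asarray(strengths, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    members = len(weights) // len(strengths)
    dend = example.unit_index // members
    drives = strengths[dend] * weights[example.unit_index] * example.amplitude
    bits = np.zeros(example.n_events, dtype=np.int8)
    for i in np.unique(dend):
        sel = np.flatnonzero(dend == i)
        bits[sel] = integrate_events(example.time_ms[sel], drives[sel], params)
    return OutputTrace(
        per_event_output=bits, spike_times=example.time_ms[bits == 1].copy()
    )
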