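"""Independent oracles used by the test suite.

These deliberately avoid the package's event-driven code paths: the LIF
oracle is a blind fixed-step integrator that marches the membrane
equation on a uniform grid and checks the threshold at every step.
"""

from __future__ import annotations

import math

import numpy as np


def _brute_force_steps(event_ticks, drives, n_ticks, decay, v_rest, v_th, bits, voltages):
    v = v_rest
    ptr = 0
    for k in range(1, n_ticks + 1):
        v = v_rest + (v - v_rest) * decay
        while ptr < event_ticks.shape[0] and event_ticks[ptr] == k:
            v += drives[ptr]
            if v >= v_th:
                bits[ptr] = 1
                v = v_rest
            voltages[ptr] = v
            ptr += 1
        if v >= v_th:  # cannot happen for delta inputs, but the oracle checks
            v = v_rest
    return v


try:
    from numba import njit

    _brute_force_steps = njit(cache=True)(_brute_force_steps)
except Exception:  # pragma: no cover
    pass


def brute_force_lif(
    times: np.ndarray,
    drives: np.ndarray,
    tau: float = 20.0,
    v_rest: float = 0.0,
    v_th: float = 1.0,
    dt: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step integration of the membrane equation.

    Returns ``(bits, voltages)`` where ``voltages[k]`` is the membrane
    voltage immediately after processing event ``k``.  Event times must be
    integer multiples of ``dt``.
    """
    times = np.asarray(times, dtype=np.float64)
    drives = np.asarray(drives, dtype=np.float64)
    ticks = np.round(times / dt).astype(np.int64)
    assert np.allclose(ticks * dt, times, atol=1e-9), "event times must sit on the dt grid"
    n_ticks = int(ticks[-1]) if len(ticks) else 0
    bits = np.zeros(len(times), dtype=np.int8)
    voltages = np.zeros(len(times), dtype=np.float64)
    decay = math.exp(-dt / tau)
    _brute_force_steps(ticks, drives, n_ticks, decay, v_rest, v_th, bits, voltages)
    return bits, voltages


def random_trace(
    rng: np.random.Generator,
    n_events_range: tuple[int, int] = (5, 30),
    max_gap_ms: float = 10.0,
    max_drive: float = 1.3,
    resolution_ms: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """A random strictly increasing delta-pulse train on the 0.01 ms grid."""
    n = int(rng.integers(*n_events_range))
    gap_ticks = rng.integers(1, int(round(max_gap_ms / resolution_ms)) + 1, size=n)
    times = np.cumsum(gap_ticks) * resolution_ms
    drives = rng.uniform(0.0, max_drive, size=n)
    return times, drives


def uniform_spacing_expected_mean(span: float, n: int) -> float:
    """Expected mean consecutive gap of n i.i.d. uniforms on [0, span]:
    E[(max - min)] / (n - 1) = span * (n - 1)/(n + 1) / (n - 1) = span/(n+1)."""
    return span / (n + 1)
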