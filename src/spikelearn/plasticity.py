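"""STDP-like multiplicative adaptation of weights and dendritic strengths.

Only stimulations that did *not* evoke a spike adapt; the sign convention
is fixed by the lag ``t = t_stimulation - t_spike``: a stimulation arriving
*after* a reference spike (positive lag) is strengthened, one arriving
before it is weakened.  Two kernels are supported,

* ``exp``:  ``A * exp(-|t|/tau_stdp) * sign(t)``, zero beyond the cutoff,
* ``step``: ``A * sign(t)``, zero beyond the cutoff,

and two pairing modes,

* ``time_window`` — each sub-threshold event pairs with its nearest
  reference spike within ``cutoff_ms`` (ties broken toward the earlier
  spike); optionally with *all* spikes in the window,
* ``rank_window`` — dendritic variant: a sub-threshold stimulation of
  dendrite *i* pairs with every reference spike from a dendrite whose
  stimulation rank in the current example lies within ``rank_window`` of
  dendrite *i*'s rank (no time cutoff).

Updates are multiplicative, ``param *= (1 + delta)``, accumulated over the
example and clipped into hard bounds afterwards.  The clip is saturating:
simultaneous boundary hits by two networks receiving the same factors
leave them with exactly equal parameters, which is what synchronizes a
student to its teacher.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .inputs import AsyncExample
from .lif_neuron import OutputTrace

__all__ = [
    "STDPParams",
    "AdaptationSource",
    "stdp_delta",
    "adapt_synaptic",
    "adapt_dendritic",
    "stimulation_ranks",
]


@dataclass(frozen=True)
class STDPParams:
    amplitude: float = 0.003
    kernel: str = "step"  # "exp" | "step"
    tau_stdp: float = 15.0
    cutoff_ms: float = 50.0
    rank_window: int = 2
    mode: str = "time_window"  # "time_window" | "rank_window"
    pair_all_spikes: bool = False

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.tau_stdp <= 0:
            raise ValueError("tau_stdp must be positive")
        if self.cutoff_ms <= 0:
            raise ValueError("cutoff_ms must be positive")
        if self.rank_window < 1:
            raise ValueError("rank_window must be >= 1")
        if self.kernel not in ("exp", "step"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.mode not in ("time_window", "rank_window"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AdaptationSource:
    """The reference trace driving adaptation: the adapting network's own
    outputs (``origin='self'``) or the teacher's (``origin='teacher'``)."""

    trace: OutputTrace
    origin: str = "self"

    def __post_init__(self) -> None:
        if self.origin not in ("teacher", "self"):
            raise ValueError(f"unknown origin {self.origin!r}")
        st = self.trace.spike_times
        if len(st) > 1 and np.any(np.diff(st) < 0):
            raise ValueError("spike_times must be sorted ascending")

    @property
    def spike_times(self) -> np.ndarray:
        return self.trace.spike_times


def _delta_array(lags: np.ndarray, params: STDPParams, use_cutoff: bool) -> np.ndarray:
    """Vectorized kernel evaluation; ``lags`` are signed ms."""
    sign = np.sign(lags)
    if params.kernel == "exp":
        d = params.amplitude * np.exp(-np.abs(lags) / params.tau_stdp) * sign
    else:
        d = params.amplitude * sign
    if use_cutoff:
        d = np.where(np.abs(lags) > params.cutoff_ms, 0.0, d)
    return d


def stdp_delta(lag: float, params: STDPParams) -> float:
    """Signed fractional change for a stimulation-minus-spike lag in ms.

    Positive lag (stimulation after the spike) strengthens; zero lag is a
    no-op; lags beyond ``cutoff_ms`` contribute nothing.
    """
    return float(_delta_array(np.asarray([lag], dtype=float), params, use_cutoff=True)[0])


def _nearest_spike_lags(
    sub_times: np.ndarray, spikes: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Signed lag to the nearest spike for each sub-threshold time.

    Ties (equidistant earlier/later spikes) resolve toward the earlier
    spike.  Returns ``(lags, valid)`` with ``valid`` false where no spike
    lies within the cutoff.
    """
    pos = np.searchsorted(spikes, sub_times)
    lo = np.clip(pos - 1, 0, len(spikes) - 1)
    hi = np.clip(pos, 0, len(spikes) - 1)
    lag_lo = sub_times - spikes[lo]  # >= 0: earlier (or equal) spike
    lag_hi = sub_times - spikes[hi]  # <= 0: later spike
    use_lo = np.abs(lag_lo) <= np.abs(lag_hi)  # tie -> earlier spike
    has_lo = pos > 0
    has_hi = pos < len(spikes)
    use_lo = (use_lo & has_lo) | ~has_hi
    lags = np.where(use_lo, lag_lo, lag_hi)
    valid = (has_lo | has_hi) & (np.abs(lags) <= cutoff)
    return lags, valid


def _check_bounds(values: np.ndarray, bounds: tuple[float, float], name: str) -> None:
    lo, hi = bounds
    if np.any(values < lo) or np.any(values > hi):
        raise ValueError(f"{name} outside bounds [{lo}, {hi}] on input")


def adapt_synaptic(
    weights: np.ndarray,
    example: AsyncExample,
    trace: OutputTrace,
    source: AdaptationSource,
    params: STDPParams,
    bounds: tuple[float, float],
) -> np.ndarray:
    """One example's worth of multiplicative weight adaptation.

    ``trace`` supplies the sub-threshold classification (which events may
    adapt) and ``source`` the reference spike train; for a network
    adapting on its own outputs the two coincide, for a student following
    its teacher both come from the teacher.
    """
    weights = np.asarray(weights, dtype=np.float64)
    _check_bounds(weights, bounds, "weights")
    if len(trace.per_event_output) != example.n_events:
        raise ValueError("trace does not match example")
    new = weights.copy()
    spikes = np.asarray(source.spike_times, dtype=np.float64)
    sub = trace.subthreshold_events
    if len(sub) == 0 or len(spikes) == 0:
        return new
    sub_times = example.time_ms[sub]
    sub_units = example.unit_index[sub]
    if params.pair_all_spikes:
        lags = sub_times[:, None] - spikes[None, :]
        deltas = _delta_array(lags, params, use_cutoff=True)
        factors = np.prod(1.0 + deltas, axis=1)
    else:
        lags, valid = _nearest_spike_lags(sub_times, spikes, params.cutoff_ms)
        deltas = np.where(valid, _delta_array(lags, params, use_cutoff=True), 0.0)
        factors = 1.0 + deltas
    np.multiply.at(new, sub_units, factors)
    return np.clip(new, bounds[0], bounds[1])


def stimulation_ranks(example: AsyncExample, n_dendrites: int) -> np.ndarray:
    """Stimulation rank of every dendrite in this example.

    Dendrites are ranked by the time of their first event (chosen blocks
    are already ordered by dendrite index; weak-fill dendrites interleave
    by their random times).  Dendrites with no event get rank -1.
    """
    members = example.n_units // n_dendrites
    dend = example.unit_index // members
    first_time = np.full(n_dendrites, np.inf)
    # events are time-sorted, so the first occurrence is the earliest
    for d, t in zip(dend, example.time_ms):
        if t < first_time[d]:
            first_time[d] = t
    ranks = np.full(n_dendrites, -1, dtype=np.int64)
    active = np.flatnonzero(np.isfinite(first_time))
    order = active[np.argsort(first_time[active], kind="stable")]
    ranks[order] = np.arange(len(order))
    return ranks


def adapt_dendritic(
    strengths: np.ndarray,
    example: AsyncExample,
    trace: OutputTrace,
    source: AdaptationSource,
    params: STDPParams,
    bounds: tuple[float, float],
) -> np.ndarray:
    """One example's worth of multiplicative dendritic-strength adaptation.

    Reference spikes are the output-1 events of ``source``'s trace, tagged
    with their dendrite of origin; a sub-threshold stimulation of dendrite
    *i* only ever pairs with spikes from *other* dendrites.  In
    ``rank_window`` mode every qualifying spike contributes one factor;
    in ``time_window`` mode the nearest other-dendrite spike within the
    cutoff contributes.
    """
    strengths = np.asarray(strengths, dtype=np.float64)
    _check_bounds(strengths, bounds, "strengths")
    ref_bits = source.trace.per_event_output
    if len(trace.per_event_output) != example.n_events or len(ref_bits) != example.n_events:
        raise ValueError("trace does not match example")
    k = len(strengths)
    members = example.n_units // k
    dend = example.unit_index // members

    sub = trace.subthreshold_events
    spike_idx = np.flatnonzero(ref_bits == 1)
    if len(sub) == 0 or len(spike_idx) == 0:
        return strengths.copy()

    sub_times = example.time_ms[sub]
    sub_dend = dend[sub]
    spk_times = example.time_ms[spike_idx]
    spk_dend = dend[spike_idx]

    lags = sub_times[:, None] - spk_times[None, :]
    other = sub_dend[:, None] != spk_dend[None, :]
    if params.mode == "rank_window":
        ranks = stimulation_ranks(example, k)
        in_window = (
            np.abs(ranks[sub_dend][:, None] - ranks[spk_dend][None, :])
            <= params.rank_window
        )
        mask = other & in_window
        deltas = _delta_array(lags, params, use_cutoff=False) * mask
        event_factors = np.prod(1.0 + deltas, axis=1)
    else:
        masked_lags = np.where(other, lags, np.inf)
        nearest = np.argmin(np.abs(masked_lags), axis=1)
        lag = masked_lags[np.arange(len(sub)), nearest]
        valid = np.isfinite(lag) & (np.abs(lag) <= params.cutoff_ms)
        deltas = np.where(valid, _delta_array(np.where(valid, lag, 0.0), params, True), 0.0)
        event_factors = 1.0 + deltas

    factors = np.ones(k)
    np.multiply.at(factors, sub_dend, event_factors)
    return np.clip(strengths * factors, bounds[0], bounds[1])
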