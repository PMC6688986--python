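"""Generation of asynchronous stimulation examples.

Every example is a time-ordered sequence of stimulation events
``(unit_index, time_ms, amplitude)`` on a fixed time grid.  Three flavours
are produced:

* **synaptic** — half of the input units are stimulated once each, at
  independent uniform times, with amplitudes uniform in ``[0.8, 1.2]``.
* **dendritic** — units are grouped five-per-dendrite; half of the
  dendrites are stimulated as contiguous blocks of five sequential events
  (block order follows dendrite index), optionally with weak "fill"
  stimulations of the remaining units.
* **multilayer** — like synaptic but with all amplitudes equal to 1 and a
  finer time grid.

Times are drawn on an integer tick grid (``resolution_ms`` per tick) so
that the "time is an exact multiple of the resolution" invariant holds up
to one float rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "StimulationEvent",
    "AsyncExample",
    "InputGenParams",
    "generate_synaptic_example",
    "generate_dendritic_example",
    "generate_multilayer_example",
    "mean_consecutive_gap",
]


@dataclass(frozen=True)
class StimulationEvent:
    """A single stimulation: which unit, when, and how strongly."""

    unit_index: int
    time: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class InputGenParams:
    """Knobs for example generation.

    ``mean_gap_ms`` is the target mean time-lag between two consecutive
    stimulations.  ``weak_fill_amplitude`` (dendritic only) gives every
    unit of an unstimulated dendrite one low-amplitude event.
    """

    resolution_ms: float = 0.01
    mean_gap_ms: float = 5.0
    amplitude_range: tuple[float, float] = (0.8, 1.2)
    weak_fill_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.resolution_ms <= 0:
            raise ValueError("resolution_ms must be positive")
        if self.mean_gap_ms <= 0:
            raise ValueError("mean_gap_ms must be positive")
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid amplitude_range {self.amplitude_range}")
        if self.weak_fill_amplitude is not None and self.weak_fill_amplitude <= 0:
            raise ValueError("weak_fill_amplitude must be positive")

    @classmethod
    def for_multilayer(cls, n_units: int) -> "InputGenParams":
        # finer grid for small networks so stimulation routes stay distinct
        res = 0.0001 if n_units <= 100 else 0.001
        return cls(resolution_ms=res)


@dataclass(frozen=True)
class AsyncExample:
    """One asynchronous input example.

    Events are stored as parallel arrays sorted by time (ties broken by
    ascending ``unit_index``).  ``primary`` marks the genuinely stimulated
    events; weak-fill events of the dendritic variant are non-primary.
    """

    unit_index: np.ndarray
    time_ms: np.ndarray
    amplitude: np.ndarray
    primary: np.ndarray
    n_units: int
    scenario: str
    resolution_ms: float
    dendrite_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if not (len(self.unit_index) == len(self.amplitude) == len(self.primary) == n):
            raise ValueError("event arrays must have equal length")
        order = np.lexsort((self.unit_index, self.time_ms))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("events must be sorted by (time, unit_index)")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(self.time_ms < 0):
            raise ValueError("times must be non-negative")
        ticks = np.round(self.time_ms / self.resolution_ms)
        if not np.allclose(ticks * self.resolution_ms, self.time_ms, rtol=0, atol=1e-9):
            raise ValueError("times must lie on the resolution grid")

    @property
    def n_events(self) -> int:
        return len(self.time_ms)

    @property
    def n_primary(self) -> int:
        return int(np.count_nonzero(self.primary))

    @property
    def events(self) -> tuple[StimulationEvent, ...]:
        return tuple(
            StimulationEvent(int(u), float(t), float(a))
            for u, t, a in zip(self.unit_index, self.time_ms, self.amplitude)
        )

    def __iter__(self) -> Iterator[StimulationEvent]:
        return iter(self.events)

    # ---- serialization ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_units={self.n_units}\n")
            fh.write(f"# scenario={self.scenario}\n")
            fh.write(f"# resolution_ms={self.resolution_ms!r}\n")
            if self.dendrite_order is not None:
                fh.write("# dendrite_order=" + ",".join(map(str, self.dendrite_order)) + "\n")
            fh.write("unit_index\ttime_ms\tamplitude\tprimary\n")
            for u, t, a, p in zip(self.unit_index, self.time_ms, self.amplitude, self.primary):
                fh.write(f"{int(u)}\t{float(t)!r}\t{float(a)!r}\t{int(p)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AsyncExample":
        meta: dict[str, str] = {}
        units, times, amps, prim = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                elif line.startswith("unit_index") or not line:
                    continue
                else:
                    u, t, a, p = line.split("\t")
                    units.append(int(u))
                    times.append(float(t))
                    amps.append(float(a))
                    prim.append(bool(int(p)))
        dend = None
        if "dendrite_order" in meta:
            dend = np.array([int(x) for x in meta["dendrite_order"].split(",")])
        return cls(
            unit_index=np.array(units, dtype=np.int64),
            time_ms=np.array(times, dtype=np.float64),
            amplitude=np.array(amps, dtype=np.float64),
            primary=np.array(prim, dtype=bool),
            n_units=int(meta["n_units"]),
            scenario=meta["scenario"],
            resolution_ms=float(meta["resolution_ms"]),
            dendrite_order=dend,
        )

    def to_json(self) -> str:
        payload = {
            "n_units": self.n_units,
            "scenario": self.scenario,
            "resolution_ms": self.resolution_ms,
            "dendrite_order": None
            if self.dendrite_order is None
            else [int(x) for x in self.dendrite_order],
            "unit_index": [int(x) for x in self.unit_index],
            "time_ms": [float(x) for x in self.time_ms],
            "amplitude": [float(x) for x in self.amplitude],
            "primary": [int(x) for x in self.primary],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AsyncExample":
        d = json.loads(text)
        return cls(
            unit_index=np.array(d["unit_index"], dtype=np.int64),
            time_ms=np.array(d["time_ms"], dtype=np.float64),
            amplitude=np.array(d["amplitude"], dtype=np.float64),
            primary=np.array(d["primary"], dtype=bool),
            n_units=d["n_units"],
            scenario=d["scenario"],
            resolution_ms=d["resolution_ms"],
            dendrite_order=None
            if d["dendrite_order"] is None
            else np.array(d["dendrite_order"], dtype=np.int64),
        )


def _sorted_example(units, times, amps, primary, **kwargs) -> AsyncExample:
    order = np.lexsort((units, times))
    return AsyncExample(
        unit_index=np.asarray(units, dtype=np.int64)[order],
        time_ms=np.asarray(times, dtype=np.float64)[order],
        amplitude=np.asarray(amps, dtype=np.float64)[order],
        primary=np.asarray(primary, dtype=bool)[order],
        **kwargs,
    )


def _uniform_grid_times(
    n: int, mean_gap_ms: float, resolution_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. uniform times on [0, mean_gap*(n+1)] snapped to the grid.

    With n order statistics on a window of length ``mean_gap*(n+1)`` the
    expected spacing between consecutive points is exactly ``mean_gap``.
    """
    span = mean_gap_ms * (n + 1)
    max_tick = int(round(span / resolution_ms))
    ticks = rng.integers(0, max_tick + 1, size=n)
    return ticks * resolution_ms


def generate_synaptic_example(
    n_units: int, params: InputGenParams, rng: np.random.Generator
) -> AsyncExample:
    """Stimulate ``n_units/2`` randomly chosen units at uniform times.

    Amplitudes are uniform on ``params.amplitude_range``; times land on the
    ``params.resolution_ms`` grid with mean consecutive gap
    ``params.mean_gap_ms``.
    """
    if n_units <= 0 or n_units % 2 != 0:
        raise ValueError(f"n_units must be a positive even integer, got {n_units}")
    n = n_units // 2
    units = rng.choice(n_units, size=n, replace=False)
    times = _uniform_grid_times(n, params.mean_gap_ms, params.resolution_ms, rng)
    lo, hi = params.amplitude_range
    amps = rng.uniform(lo, hi, size=n)
    return _sorted_example(
        units,
        times,
        amps,
        np.ones(n, dtype=bool),
        n_units=n_units,
        scenario="synaptic",
        resolution_ms=params.resolution_ms,
    )


def generate_dendritic_example(
    n_units: int,
    n_dendrites: int | None = None,
    params: InputGenParams = InputGenParams(),
    rng: np.random.Generator | None = None,
) -> AsyncExample:
    """Stimulate half the dendrites as ordered contiguous blocks of five.

    Dendrite ``i`` owns units ``5i .. 5i+4``.  Half of the ``K = N/5``
    dendrites are chosen; each chosen dendrite's five units fire once in a
    random order, with consecutive gaps i.i.d. uniform on
    ``(0, 2*mean_gap_ms]``, and blocks ordered by dendrite index (every
    event of block *i* precedes every event of block *j* for chosen
    ``i < j``).  If ``weak_fill_amplitude`` is set, every unit of every
    unchosen dendrite additionally fires once, at that amplitude, at a
    uniform time within the span of the primary events.
    """
    if rng is None:
        raise ValueError("an explicit seeded rng is required")
    if n_units <= 0 or n_units % 10 != 0:
        raise ValueError(f"n_units must be a positive multiple of 10, got {n_units}")
    k = n_units // 5
    if n_dendrites is None:
        n_dendrites = k
    if n_dendrites != k or n_units != 5 * n_dendrites:
        raise ValueError(f"n_dendrites must equal n_units/5 = {k}, got {n_dendrites}")

    chosen = np.sort(rng.choice(k, size=k // 2, replace=False))
    n_strong = 5 * len(chosen)

    # sequential gaps: integer ticks in [1, 2*mean_gap/res] -> uniform (0, 2*mean_gap]
    max_gap_tick = int(round(2 * params.mean_gap_ms / params.resolution_ms))
    gap_ticks = rng.integers(1, max_gap_tick + 1, size=n_strong)
    times = np.cumsum(gap_ticks) * params.resolution_ms

    units = np.concatenate([5 * d + rng.permutation(5) for d in chosen])
    lo, hi = params.amplitude_range
    amps = rng.uniform(lo, hi, size=n_strong)
    primary = np.ones(n_strong, dtype=bool)

    if params.weak_fill_amplitude is not None:
        unchosen = np.setdiff1d(np.arange(k), chosen)
        weak_units = (5 * unchosen[:, None] + np.arange(5)[None, :]).ravel()
        span_tick = int(round(times[-1] / params.resolution_ms))
        weak_times = rng.integers(0, span_tick + 1, size=len(weak_units)) * params.resolution_ms
        units = np.concatenate([units, weak_units])
        times = np.concatenate([times, weak_times])
        amps = np.concatenate([amps, np.full(len(weak_units), params.weak_fill_amplitude)])
        primary = np.concatenate([primary, np.zeros(len(weak_units), dtype=bool)])

    return _sorted_example(
        units,
        times,
        amps,
        primary,
        n_units=n_units,
        scenario="dendritic",
        resolution_ms=params.resolution_ms,
        dendrite_order=chosen,
    )


def generate_multilayer_example(
    n_units: int, params: InputGenParams, rng: np.random.Generator
) -> AsyncExample:
    """Synaptic-style example with all amplitudes fixed to 1."""
    if n_units <= 0 or n_units % 2 != 0:
        raise ValueError(f"n_units must be a positive even integer, got {n_units}")
    n = n_units // 2
    units = rng.choice(n_units, size=n, replace=False)
    times = _uniform_grid_times(n, params.mean_gap_ms, params.resolution_ms, rng)
    amps = np.ones(n)
    ex = _sorted_example(
        units,
        times,
        amps,
        np.ones(n, dtype=bool),
        n_units=n_units,
        scenario="multilayer",
        resolution_ms=params.resolution_ms,
    )
    return ex


def mean_consecutive_gap(example: AsyncExample) -> float | None:
    """Mean time-lag between consecutive primary stimulations.

    Returns ``None`` for examples with fewer than two primary events,
    where the statistic is undefined.
    """
    t = example.time_ms[example.primary]
    if len(t) < 2:
        return None
    return float(np.mean(np.diff(t)))
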