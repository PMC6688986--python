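"""Scenario containers and the per-example teacher-student protocol.

Each example is processed in three phases: (1) both networks produce their
output traces with their current parameters, (2) the teacher adapts on its
own input/output relations and the student adapts on the configured source
(the teacher's trace by default), (3) with learning enabled, every event
with conflicting output bits triggers a correction step on the student,
applied sequentially in event order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .inputs import AsyncExample, InputGenParams
from .learning_rules import LearningParams, StepRecord, learning_step
from .lif_neuron import (
    LIFParams,
    OutputTrace,
    integrate_events,
    run_example_dendritic,
    run_example_single_unit,
)
from .plasticity import AdaptationSource, STDPParams, adapt_dendritic, adapt_synaptic

__all__ = [
    "SynapticPerceptron",
    "DendriticPerceptron",
    "TwoLayerNetwork",
    "TeacherStudentPair",
    "PresentResult",
    "MultilayerResult",
    "initial_weights",
    "make_synaptic_pair",
    "make_dendritic_pair",
    "make_two_layer_pair",
    "present_example",
    "present_example_multilayer",
    "DegenerateRoutesError",
]

W_BOUNDS_DEFAULT = (1e-4, 1.5)
J_BOUNDS_DEFAULT = (0.1, 2.0)


class DegenerateRoutesError(ValueError):
    """Two stimulations would arrive simultaneously at the same unit."""


def initial_weights(n: int, rng: np.random.Generator, mean: float = 0.5) -> np.ndarray:
    """Uniform draws on [0.1, 0.9] rescaled to the requested mean."""
    w = rng.uniform(0.1, 0.9, size=n)
    return w * (mean / w.mean())


@dataclass
class SynapticPerceptron:
    """N adaptive weights feeding one LIF output unit."""

    weights: np.ndarray
    bounds: tuple[float, float] = W_BOUNDS_DEFAULT
    lif: LIFParams = field(default_factory=LIFParams)
    scenario: str = field(default="synaptic", init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        lo, hi = self.bounds
        if np.any(self.weights < lo) or np.any(self.weights > hi):
            raise ValueError("weights outside bounds")

    @property
    def adaptive_params(self) -> np.ndarray:
        return self.weights

    def run(self, example: AsyncExample) -> OutputTrace:
        drives = self.weights[example.unit_index] * example.amplitude
        return run_example_single_unit(drives, example, self.lif)

    def adapt(self, example, trace, source, stdp) -> None:
        self.weights = adapt_synaptic(self.weights, example, trace, source, stdp, self.bounds)

    def copy(self) -> "SynapticPerceptron":
        return SynapticPerceptron(self.weights.copy(), self.bounds, self.lif)


@dataclass
class DendriticPerceptron:
    """K = N/5 adaptive dendritic strengths over fixed synaptic weights."""

    strengths: np.ndarray
    fixed_weights: np.ndarray
    bounds_J: tuple[float, float] = J_BOUNDS_DEFAULT
    lif: LIFParams = field(default_factory=LIFParams)
    scenario: str = field(default="dendritic", init=False)

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=np.float64)
        self.fixed_weights = np.asarray(self.fixed_weights, dtype=np.float64)
        self.fixed_weights.setflags(write=False)
        if len(self.fixed_weights) != 5 * len(self.strengths):
            raise ValueError("expected five fixed weights per dendrite")
        lo, hi = self.bounds_J
        if np.any(self.strengths < lo) or np.any(self.strengths > hi):
            raise ValueError("strengths outside bounds")

    @property
    def n_units(self) -> int:
        return len(self.fixed_weights)

    @property
    def adaptive_params(self) -> np.ndarray:
        return self.strengths

    def run(self, example: AsyncExample) -> OutputTrace:
        return run_example_dendritic(self.strengths, self.fixed_weights, example, self.lif)

    def adapt(self, example, trace, source, stdp) -> None:
        self.strengths = adapt_dendritic(
            self.strengths, example, trace, source, stdp, self.bounds_J
        )

    def copy(self) -> "DendriticPerceptron":
        return DendriticPerceptron(
            self.strengths.copy(), self.fixed_weights, self.bounds_J, self.lif
        )


@dataclass
class TwoLayerNetwork:
    """Fully connected input->hidden layer plus a single LIF output unit.

    ``layer1_weights[j, h]`` connects input unit *j* to hidden unit *h*
    with fixed delay ``layer1_delays[j, h]``; hidden spikes propagate to
    the output unit through ``layer2_weights[h]`` and ``layer2_delays[h]``.
    Delays are architecture and never change.
    """

    layer1_weights: np.ndarray
    layer2_weights: np.ndarray
    layer1_delays: np.ndarray
    layer2_delays: np.ndarray
    bounds: tuple[float, float] = W_BOUNDS_DEFAULT
    lif: LIFParams = field(default_factory=LIFParams)
    scenario: str = field(default="multilayer", init=False)

    def __post_init__(self) -> None:
        self.layer1_weights = np.asarray(self.layer1_weights, dtype=np.float64)
        self.layer2_weights = np.asarray(self.layer2_weights, dtype=np.float64)
        self.layer1_delays = np.asarray(self.layer1_delays, dtype=np.float64)
        self.layer2_delays = np.asarray(self.layer2_delays, dtype=np.float64)
        self.layer1_delays.setflags(write=False)
        self.layer2_delays.setflags(write=False)
        n = len(self.layer2_weights)
        if self.layer1_weights.shape != (n, n) or self.layer1_delays.shape != (n, n):
            raise ValueError("layer-1 arrays must be N x N")
        lo, hi = self.bounds
        for w in (self.layer1_weights, self.layer2_weights):
            if np.any(w < lo) or np.any(w > hi):
                raise ValueError("weights outside bounds")
        for h in range(n):
            if len(np.unique(self.layer1_delays[:, h])) != n:
                raise DegenerateRoutesError(f"duplicate layer-1 delays into hidden unit {h}")

    @property
    def n_units(self) -> int:
        return len(self.layer2_weights)

    def copy(self) -> "TwoLayerNetwork":
        return TwoLayerNetwork(
            self.layer1_weights.copy(),
            self.layer2_weights.copy(),
            self.layer1_delays,
            self.layer2_delays,
            self.bounds,
            self.lif,
        )


@dataclass
class TeacherStudentPair:
    """Two architecturally identical networks plus the protocol knobs."""

    teacher: object
    student: object
    stdp: STDPParams = field(default_factory=STDPParams)
    learning: LearningParams = field(default_factory=LearningParams)
    adaptation_source_mode: str = "teacher"  # "teacher" | "self"
    adaptation_enabled: bool = True

    def __post_init__(self) -> None:
        if type(self.teacher) is not type(self.student):
            raise ValueError("teacher and student must share the same scenario type")
        if self.adaptation_source_mode not in ("teacher", "self"):
            raise ValueError(f"unknown adaptation source {self.adaptation_source_mode!r}")

    @property
    def scenario(self) -> str:
        return self.teacher.scenario

    def copy(self) -> "TeacherStudentPair":
        return TeacherStudentPair(
            self.teacher.copy(),
            self.student.copy(),
            self.stdp,
            self.learning,
            self.adaptation_source_mode,
            self.adaptation_enabled,
        )

    def params_equal(self) -> bool:
        if self.scenario == "multilayer":
            return np.array_equal(
                self.teacher.layer1_weights, self.student.layer1_weights
            ) and np.array_equal(self.teacher.layer2_weights, self.student.layer2_weights)
        return np.array_equal(self.teacher.adaptive_params, self.student.adaptive_params)


def make_synaptic_pair(
    n_units: int,
    rng_teacher: np.random.Generator,
    rng_student: np.random.Generator,
    stdp: STDPParams | None = None,
    learning: LearningParams | None = None,
    bounds: tuple[float, float] = W_BOUNDS_DEFAULT,
    lif: LIFParams | None = None,
    adaptation_source_mode: str = "teacher",
) -> TeacherStudentPair:
    lif = lif or LIFParams()
    teacher = SynapticPerceptron(initial_weights(n_units, rng_teacher), bounds, lif)
    student = SynapticPerceptron(initial_weights(n_units, rng_student), bounds, lif)
    return TeacherStudentPair(
        teacher,
        student,
        stdp or STDPParams(),
        learning or LearningParams(),
        adaptation_source_mode,
    )


def make_dendritic_pair(
    n_units: int,
    rng_teacher: np.random.Generator,
    rng_student: np.random.Generator,
    stdp: STDPParams | None = None,
    learning: LearningParams | None = None,
    bounds_J: tuple[float, float] = J_BOUNDS_DEFAULT,
    lif: LIFParams | None = None,
    adaptation_source_mode: str = "teacher",
) -> TeacherStudentPair:
    """Shared fixed weights (drawn from the teacher stream); independent
    initial strengths uniform on [0.5, 1.5]."""
    if n_units % 10 != 0:
        raise ValueError("n_units must be a multiple of 10")
    lif = lif or LIFParams()
    k = n_units // 5
    fixed = initial_weights(n_units, rng_teacher)
    j_teacher = rng_teacher.uniform(0.5, 1.5, size=k)
    j_student = rng_student.uniform(0.5, 1.5, size=k)
    stdp = stdp or STDPParams(mode="rank_window")
    teacher = DendriticPerceptron(j_teacher, fixed, bounds_J, lif)
    student = DendriticPerceptron(j_student, fixed, bounds_J, lif)
    return TeacherStudentPair(
        teacher, student, stdp, learning or LearningParams(), adaptation_source_mode
    )


def make_two_layer_pair(
    n_units: int,
    rng_teacher: np.random.Generator,
    rng_student: np.random.Generator,
    rng_arch: np.random.Generator,
    stdp: STDPParams | None = None,
    learning: LearningParams | None = None,
    bounds: tuple[float, float] = W_BOUNDS_DEFAULT,
    lif: LIFParams | None = None,
    delay_resolution_ms: float = 0.001,
    max_tries: int = 100,
) -> TeacherStudentPair:
    """Shared random delays uniform on [0, 5N/2]; independent weights
    uniform on [0.1, 0.9].  Delay assignments with duplicate arrivals into
    any hidden unit are redrawn."""
    lif = lif or LIFParams()
    n = n_units
    max_tick = int(round(2.5 * n / delay_resolution_ms))
    for _ in range(max_tries):
        d1 = rng_arch.integers(0, max_tick + 1, size=(n, n)) * delay_resolution_ms
        d2 = rng_arch.integers(0, max_tick + 1, size=n) * delay_resolution_ms
        if all(len(np.unique(d1[:, h])) == n for h in range(n)):
            break
    else:  # pragma: no cover
        raise DegenerateRoutesError("could not draw a non-degenerate delay assignment")
    nets = []
    for rng in (rng_teacher, rng_student):
        nets.append(
            TwoLayerNetwork(
                rng.uniform(0.1, 0.9, size=(n, n)),
                rng.uniform(0.1, 0.9, size=n),
                d1,
                d2,
                bounds,
                lif,
            )
        )
    stdp = stdp or STDPParams(amplitude=0.001)
    return TeacherStudentPair(nets[0], nets[1], stdp, learning or LearningParams(), "teacher")


@dataclass(frozen=True)
class PresentResult:
    teacher_trace: OutputTrace
    student_trace: OutputTrace
    mismatch_count: int
    step_records: tuple[StepRecord, ...]


def present_example(
    pair: TeacherStudentPair,
    example: AsyncExample,
    example_index: int = 0,
    frozen: bool = False,
) -> PresentResult:
    """Run the output-production / adaptation / learning protocol once.

    With ``frozen=True`` only the traces and the mismatch count are
    computed (used for generalization-error measurement).
    """
    if example.scenario != pair.scenario:
        raise ValueError(
            f"example scenario {example.scenario!r} does not match pair {pair.scenario!r}"
        )
    if pair.scenario == "multilayer":
        raise ValueError("use present_example_multilayer for two-layer networks")

    teacher, student = pair.teacher, pair.student
    teacher_before = teacher.adaptive_params.copy()

    trace_t = teacher.run(example)
    trace_s = student.run(example)
    mismatch = trace_t.per_event_output != trace_s.per_event_output
    mismatch_count = int(np.count_nonzero(mismatch))

    records: list[StepRecord] = []
    if not frozen:
        if pair.adaptation_enabled:
            teacher.adapt(example, trace_t, AdaptationSource(trace_t, "self"), pair.stdp)
            if pair.adaptation_source_mode == "teacher":
                student.adapt(example, trace_t, AdaptationSource(trace_t, "teacher"), pair.stdp)
            else:
                student.adapt(example, trace_s, AdaptationSource(trace_s, "self"), pair.stdp)

        if pair.learning.enabled and pair.learning.step_size > 0 and mismatch_count:
            params = student.adaptive_params
            if pair.scenario == "dendritic":
                members = example.n_units // len(params)
                indices = example.unit_index // members
            else:
                indices = example.unit_index
            bounds = student.bounds_J if pair.scenario == "dendritic" else student.bounds
            for k in np.flatnonzero(mismatch):  # events are already time-ordered
                idx = int(indices[k])
                before = float(params[idx])
                after = learning_step(
                    before,
                    int(trace_t.per_event_output[k]),
                    int(trace_s.per_event_output[k]),
                    float(example.amplitude[k]),
                    pair.learning,
                    bounds,
                )
                params[idx] = after
                records.append(
                    StepRecord(
                        example_index=example_index,
                        parameter_index=idx,
                        teacher_value_before=float(teacher_before[idx]),
                        student_before=before,
                        student_after=after,
                    )
                )
    return PresentResult(trace_t, trace_s, mismatch_count, tuple(records))


# ---------------------------------------------------------------------------
# two-layer protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _LayerOutputs:
    """Route-aligned outputs of one network on one multilayer example.

    Routes are the pairs ``(event k, hidden unit h)``: arrival times are
    shared between teacher and student because delays are architecture.
    """

    hidden_bits: np.ndarray  # (n_events, N) int8
    hidden_arrivals: np.ndarray  # (n_events, N) float64, shared
    output_bits: np.ndarray  # (n_events, N) int8; 1 iff this route's hidden
    # spike evoked an output spike
    output_arrivals: np.ndarray  # (n_events, N) arrival time at the output unit
    output_spike_times: np.ndarray


def _forward_two_layer(net: TwoLayerNetwork, example: AsyncExample) -> _LayerOutputs:
    n = net.n_units
    t_in = example.time_ms
    units = example.unit_index
    amps = example.amplitude
    arrivals = t_in[:, None] + net.layer1_delays[units, :]  # (events, hidden)
    drives = net.layer1_weights[units, :] * amps[:, None]

    hidden_bits = np.zeros_like(arrivals, dtype=np.int8)
    for h in range(n):
        order = np.argsort(arrivals[:, h], kind="stable")
        if len(order) > 1 and np.any(np.diff(arrivals[order, h]) == 0):
            raise DegenerateRoutesError(f"simultaneous arrivals at hidden unit {h}")
        bits = integrate_events(arrivals[order, h], drives[order, h], net.lif)
        hidden_bits[order, h] = bits

    out_arrivals = arrivals + net.layer2_delays[None, :]
    spk = np.argwhere(hidden_bits == 1)
    output_bits = np.zeros_like(hidden_bits)
    out_spikes = np.empty(0)
    if len(spk):
        times = out_arrivals[spk[:, 0], spk[:, 1]]
        order = np.argsort(times, kind="stable")
        if len(order) > 1 and np.any(np.diff(times[order]) == 0):
            raise DegenerateRoutesError("simultaneous arrivals at the output unit")
        drives2 = net.layer2_weights[spk[order, 1]]
        bits2 = integrate_events(times[order], drives2, net.lif)
        output_bits[spk[order, 0], spk[order, 1]] = bits2
        out_spikes = np.sort(times[order][bits2 == 1])
    return _LayerOutputs(hidden_bits, arrivals, output_bits, out_arrivals, out_spikes)


def _adapt_layer1(net: TwoLayerNetwork, out: _LayerOutputs, example, stdp) -> None:
    """Each hidden unit adapts its incoming weights on its own trace."""
    units = example.unit_index
    new = net.layer1_weights.copy()
    for h in range(net.n_units):
        times = out.hidden_arrivals[:, h]
        bits = out.hidden_bits[:, h]
        spikes = np.sort(times[bits == 1])
        sub = np.flatnonzero(bits == 0)
        if len(sub) == 0 or len(spikes) == 0:
            continue
        from .plasticity import _delta_array, _nearest_spike_lags

        lags, valid = _nearest_spike_lags(times[sub], spikes, stdp.cutoff_ms)
        deltas = np.where(valid, _delta_array(lags, stdp, use_cutoff=True), 0.0)
        np.multiply.at(new, (units[sub], h), 1.0 + deltas)
    net.layer1_weights = np.clip(new, net.bounds[0], net.bounds[1])


def _adapt_layer2(
    net: TwoLayerNetwork, own: _LayerOutputs, ref_spikes: np.ndarray, stdp
) -> None:
    """Output-unit weights adapt on the network's own sub-threshold
    stimulations paired with the reference output spike train."""
    from .plasticity import _delta_array, _nearest_spike_lags

    spk = np.argwhere(own.hidden_bits == 1)  # stimulations of the output unit
    if len(spk) == 0 or len(ref_spikes) == 0:
        return
    times = own.output_arrivals[spk[:, 0], spk[:, 1]]
    bits = own.output_bits[spk[:, 0], spk[:, 1]]
    sub = bits == 0
    if not np.any(sub):
        return
    new = net.layer2_weights.copy()
    lags, valid = _nearest_spike_lags(times[sub], np.sort(ref_spikes), stdp.cutoff_ms)
    deltas = np.where(valid, _delta_array(lags, stdp, use_cutoff=True), 0.0)
    np.multiply.at(new, spk[sub, 1], 1.0 + deltas)
    net.layer2_weights = np.clip(new, net.bounds[0], net.bounds[1])


@dataclass(frozen=True)
class MultilayerResult:
    teacher_out: _LayerOutputs
    student_out: _LayerOutputs
    mismatch_count: int
    step_records: tuple[StepRecord, ...]


def present_example_multilayer(
    pair: TeacherStudentPair,
    example: AsyncExample,
    example_index: int = 0,
    frozen: bool = False,
) -> MultilayerResult:
    """Two-layer protocol: hidden outputs, then the output unit, then
    adaptation and learning on both layers.

    Route identifiability (shared delays) lets mismatches be localized:
    hidden-route conflicts correct ``layer1_weights[j, h]`` and
    output-route conflicts correct ``layer2_weights[h]``.
    """
    if example.scenario != "multilayer" or pair.scenario != "multilayer":
        raise ValueError("multilayer pair and example required")
    teacher, student = pair.teacher, pair.student
    t1_before = teacher.layer1_weights.copy()
    t2_before = teacher.layer2_weights.copy()

    out_t = _forward_two_layer(teacher, example)
    out_s = _forward_two_layer(student, example)

    mis1 = out_t.hidden_bits != out_s.hidden_bits
    mis2 = out_t.output_bits != out_s.output_bits
    mismatch_count = int(np.count_nonzero(mis1) + np.count_nonzero(mis2))

    records: list[StepRecord] = []
    if not frozen:
        if pair.adaptation_enabled:
            _adapt_layer1(teacher, out_t, example, pair.stdp)
            _adapt_layer1(student, out_s, example, pair.stdp)
            _adapt_layer2(teacher, out_t, out_t.output_spike_times, pair.stdp)
            _adapt_layer2(student, out_s, out_t.output_spike_times, pair.stdp)

        if pair.learning.enabled and pair.learning.step_size > 0:
            units = example.unit_index
            n = teacher.n_units
            lam = pair.learning
            w1 = student.layer1_weights
            for k, h in np.argwhere(mis1):
                j = int(units[k])
                before = float(w1[j, h])
                after = learning_step(
                    before,
                    int(out_t.hidden_bits[k, h]),
                    int(out_s.hidden_bits[k, h]),
                    float(example.amplitude[k]),
                    lam,
                    student.bounds,
                )
                w1[j, h] = after
                records.append(
                    StepRecord(example_index, j * n + h, float(t1_before[j, h]), before, after)
                )
            w2 = student.layer2_weights
            for k, h in np.argwhere(mis2):
                before = float(w2[h])
                after = learning_step(
                    before,
                    int(out_t.output_bits[k, h]),
                    int(out_s.output_bits[k, h]),
                    1.0,
                    lam,
                    student.bounds,
                )
                w2[h] = after
                records.append(
                    StepRecord(example_index, n * n + h, float(t2_before[h]), before, after)
                )
    return MultilayerResult(out_t, out_s, mismatch_count, tuple(records))
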