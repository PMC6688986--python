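"""Training loops, generalization-error measurement and curve diagnostics.

The generalization error is the fraction of primary stimulations on fresh
test examples for which teacher and student output bits disagree.  During
measurement both networks are frozen (no adaptation, no learning) and the
test examples come from a dedicated random stream, so the training
trajectory is identical with or without evaluation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .inputs import (
    AsyncExample,
    InputGenParams,
    generate_dendritic_example,
    generate_multilayer_example,
    generate_synaptic_example,
)
from .learning_rules import StepRecord, classify_step
from .networks import (
    DegenerateRoutesError,
    TeacherStudentPair,
    present_example,
    present_example_multilayer,
)

__all__ = [
    "EvalSchedule",
    "LearningCurve",
    "CurveFit",
    "generalization_error",
    "overlap_R",
    "eps_from_overlap",
    "detect_frozen",
    "run_learning_curve",
    "fit_power_exponent",
    "always_spiking_weight_threshold",
    "make_example",
]


@dataclass(frozen=True)
class EvalSchedule:
    """How often and how hard to measure the generalization error."""

    eval_every: int = 2000
    n_test: int = 10_000  # test inputs per measurement repetition
    n_repeats: int = 3

    def __post_init__(self) -> None:
        if self.eval_every < 1 or self.n_test < 1 or self.n_repeats < 1:
            raise ValueError("schedule fields must be positive")


@dataclass
class LearningCurve:
    """A sequence of (p, eps_g) measurements with provenance."""

    p: np.ndarray
    eps_g: np.ndarray
    stderr: np.ndarray
    overlap: np.ndarray
    frozen_fraction: np.ndarray
    n_units: int
    seed: int | None = None
    config_snapshot: dict = field(default_factory=dict)
    first_identity_p: int | None = None
    step_records: tuple[StepRecord, ...] = ()
    # optional per-example (p, parameter_index, teacher, student) snapshots
    trajectories: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.p) <= 0):
            raise ValueError("p must be strictly increasing")
        if np.any((self.eps_g < 0) | (self.eps_g > 1)):
            raise ValueError("eps_g must lie in [0, 1]")

    @property
    def alpha(self) -> np.ndarray:
        return self.p / self.n_units

    @property
    def max_stderr(self) -> float:
        return float(np.max(self.stderr)) if len(self.stderr) else 0.0

    def trajectories_to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        if self.trajectories is None:
            raise ValueError("run was not recorded with track_trajectories")
        with open(path, "w") as fh:
            if header_comment is not None:
                fh.write(f"# {header_comment}\n")
            fh.write("example_index\tparameter_index\tteacher\tstudent\n")
            for p, idx, t, s in self.trajectories:
                fh.write(f"{int(p)}\t{int(idx)}\t{float(t)!r}\t{float(s)!r}\n")

    def step_classification_counts(self) -> dict[str, int]:
        counts = {"attractive": 0, "repulsive": 0, "neutral": 0}
        for r in self.step_records:
            counts[classify_step(r)] += 1
        return counts

    def to_csv(self, path: str | Path, config_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            fh.write(f"# n_units={self.n_units}\n")
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            if self.first_identity_p is not None:
                fh.write(f"# first_identity_p={self.first_identity_p}\n")
            fh.write("p,alpha,eps_g,stderr,R,frozen_fraction\n")
            for p, a, e, s, r, f in zip(
                self.p, self.alpha, self.eps_g, self.stderr, self.overlap, self.frozen_fraction
            ):
                fh.write(
                    f"{int(p)},{float(a)!r},{float(e)!r},{float(s)!r},"
                    f"{float(r)!r},{float(f)!r}\n"
                )


@dataclass(frozen=True)
class CurveFit:
    exponent: float
    fit_range: tuple[float, float]
    goodness: float  # r^2 of the log-log fit
    n_points: int

    def to_json_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "fit_range": list(self.fit_range),
            "goodness": self.goodness,
            "n_points": self.n_points,
        }


def make_example(
    scenario: str, n_units: int, gen: InputGenParams, rng: np.random.Generator
) -> AsyncExample:
    """Scenario-dispatched example generation."""
    if scenario == "synaptic":
        return generate_synaptic_example(n_units, gen, rng)
    if scenario == "dendritic":
        return generate_dendritic_example(n_units, params=gen, rng=rng)
    if scenario == "multilayer":
        return generate_multilayer_example(n_units, gen, rng)
    raise ValueError(f"unknown scenario {scenario!r}")


def _n_units_of(pair: TeacherStudentPair) -> int:
    t = pair.teacher
    return len(t.weights) if pair.scenario == "synaptic" else t.n_units


def generalization_error(
    pair: TeacherStudentPair,
    schedule: EvalSchedule,
    rng: np.random.Generator,
    gen: InputGenParams | None = None,
) -> tuple[float, float]:
    """Mismatch firing fraction on fresh frozen-dynamics test examples.

    Returns ``(mean over repeats, half the spread between repeats)``.  The
    denominator counts primary stimulations only (``n_test * N/2`` per
    repeat; the multilayer scenario uses the route count ``n_test * N^2/2``).
    """
    gen = gen or InputGenParams()
    n_units = _n_units_of(pair)
    values = []
    for _ in range(schedule.n_repeats):
        mismatches = 0
        stimulations = 0
        for _ in range(schedule.n_test):
            ex = make_example(pair.scenario, n_units, gen, rng)
            if pair.scenario == "multilayer":
                res = present_example_multilayer(pair, ex, frozen=True)
                mismatches += res.mismatch_count
                stimulations += ex.n_primary * n_units
            else:
                res = present_example(pair, ex, frozen=True)
                prim = ex.primary
                diff = (
                    res.teacher_trace.per_event_output[prim]
                    != res.student_trace.per_event_output[prim]
                )
                mismatches += int(np.count_nonzero(diff))
                stimulations += ex.n_primary
        values.append(mismatches / stimulations)
    values = np.asarray(values)
    return float(values.mean()), float((values.max() - values.min()) / 2)


def overlap_R(student_params: np.ndarray, teacher_params: np.ndarray, shift: float = 1.0) -> float:
    """Cosine overlap of the threshold-shifted parameter vectors."""
    s = np.asarray(student_params, dtype=np.float64) - shift
    t = np.asarray(teacher_params, dtype=np.float64) - shift
    if s.shape != t.shape:
        raise ValueError("parameter vectors must have equal length")
    ns, nt = np.linalg.norm(s), np.linalg.norm(t)
    if ns == 0 or nt == 0:
        raise ValueError("overlap undefined: a shifted vector has zero norm")
    return float(np.dot(s, t) / (ns * nt))


def eps_from_overlap(R: float, tol: float = 1e-12) -> float:
    """Synchronous-perceptron generalization error, ``arccos(R) / pi``."""
    if R > 1 + tol or R < -1 - tol:
        raise ValueError(f"overlap {R} outside [-1, 1]")
    return float(math.acos(min(1.0, max(-1.0, R))) / math.pi)


def detect_frozen(
    history: Sequence[float], threshold: float = 1e-3, window: int = 500
) -> bool | None:
    """A strength is frozen when its variance over the last ``window``
    recorded values falls below ``threshold``; shorter histories are not
    assessable and yield ``None``."""
    h = np.asarray(history, dtype=np.float64)
    if len(h) < window:
        return None
    return bool(np.var(h[-window:]) < threshold)


def always_spiking_weight_threshold(
    amplitude_range: tuple[float, float] = (0.8, 1.2), v_threshold: float = 1.0
) -> float:
    """Smallest weight whose every stimulation evokes a spike on its own:
    the spike condition ``w * x >= v_threshold`` must hold even for the
    minimal amplitude, so the threshold is ``v_threshold / min(x)``."""
    return v_threshold / amplitude_range[0]


def _frozen_fraction(histories: deque | None) -> float:
    if histories is None or len(histories) == 0:
        return float("nan")
    arr = np.asarray(histories)  # (window, K)
    if arr.shape[0] < 500:
        return float("nan")
    return float(np.mean(np.var(arr, axis=0) < 1e-3))


def run_learning_curve(
    pair: TeacherStudentPair,
    p_max: int,
    schedule: EvalSchedule,
    seed: int,
    gen: InputGenParams | None = None,
    collect_step_records: bool = False,
    stop_on_identity: bool = False,
    measure_at_zero: bool = False,
    config_snapshot: dict | None = None,
    max_step_records: int = 2_000_000,
    track_trajectories: bool = False,
    trajectory_every: int = 1,
) -> LearningCurve:
    """Interleave training with frozen-dynamics error measurements.

    Training examples come from one child stream of ``seed`` and test
    examples from another, so evaluation never perturbs training.  The
    first example index at which teacher and student adaptive parameters
    are exactly identical is recorded; with ``stop_on_identity`` the run
    then short-circuits (remaining measurements are exactly zero).
    """
    gen = gen or InputGenParams()
    ss = np.random.SeedSequence(seed)
    rng_train, rng_test = (np.random.default_rng(s) for s in ss.spawn(2))
    n_units = _n_units_of(pair)

    present = present_example_multilayer if pair.scenario == "multilayer" else present_example
    track_frozen = pair.scenario == "dendritic"
    histories: deque | None = deque(maxlen=500) if track_frozen else None

    ps, eps, errs, overlaps, fracs = [], [], [], [], []
    records: list[StepRecord] = []
    traj_rows: list[tuple[int, int, float, float]] = []
    first_identity_p: int | None = None

    def measure(p: int) -> None:
        e, s = generalization_error(pair, schedule, rng_test, gen)
        ps.append(p)
        eps.append(e)
        errs.append(s)
        if pair.scenario == "multilayer":
            overlaps.append(float("nan"))
        else:
            overlaps.append(
                overlap_R(pair.student.adaptive_params, pair.teacher.adaptive_params)
            )
        fracs.append(_frozen_fraction(histories))

    if measure_at_zero:
        measure(0)

    for p in range(1, p_max + 1):
        for _ in range(100):
            ex = make_example(pair.scenario, n_units, gen, rng_train)
            try:
                res = present(pair, ex, example_index=p)
                break
            except DegenerateRoutesError:
                continue
        else:  # pragma: no cover
            raise DegenerateRoutesError("persistent degenerate stimulation routes")
        if collect_step_records and len(records) < max_step_records:
            records.extend(res.step_records)
        if track_trajectories and pair.scenario != "multilayer" and p % trajectory_every == 0:
            t_params = pair.teacher.adaptive_params
            s_params = pair.student.adaptive_params
            for i in range(len(t_params)):
                traj_rows.append((p, i, float(t_params[i]), float(s_params[i])))
        if track_frozen:
            histories.append(pair.teacher.strengths.copy())
        if first_identity_p is None and pair.params_equal():
            first_identity_p = p
            if stop_on_identity:
                if not ps or ps[-1] != p:
                    ps.append(p)
                    eps.append(0.0)
                    errs.append(0.0)
                    overlaps.append(
                        float("nan")
                        if pair.scenario == "multilayer"
                        else overlap_R(
                            pair.student.adaptive_params, pair.teacher.adaptive_params
                        )
                    )
                    fracs.append(_frozen_fraction(histories))
                break
        if p % schedule.eval_every == 0:
            measure(p)

    return LearningCurve(
        p=np.asarray(ps, dtype=np.int64),
        eps_g=np.asarray(eps),
        stderr=np.asarray(errs),
        overlap=np.asarray(overlaps),
        frozen_fraction=np.asarray(fracs),
        n_units=n_units,
        seed=seed,
        config_snapshot=config_snapshot or {},
        first_identity_p=first_identity_p,
        step_records=tuple(records),
        trajectories=np.asarray(traj_rows) if track_trajectories else None,
    )


def fit_power_exponent(
    curve: LearningCurve | tuple[np.ndarray, np.ndarray],
    fit_range: tuple[float, float],
) -> CurveFit:
    """Least-squares slope of ``log eps_g`` against ``log p`` on a range.

    The returned exponent is negated so that a decaying curve has a
    positive exponent.  Points with ``eps_g <= 0`` are excluded; at least
    four usable points are required.
    """
    if isinstance(curve, LearningCurve):
        p, e = curve.p, curve.eps_g
    else:
        p, e = (np.asarray(x, dtype=np.float64) for x in curve)
    lo, hi = fit_range
    if lo <= 0 or hi <= lo:
        raise ValueError(f"invalid fit range {fit_range}")
    sel = (p >= lo) & (p <= hi) & (e > 0)
    if int(np.count_nonzero(sel)) < 4:
        raise ValueError("need at least 4 points with eps_g > 0 in the fit range")
    x = np.log(p[sel].astype(np.float64))
    y = np.log(e[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CurveFit(
        exponent=float(-slope),
        fit_range=(float(lo), float(hi)),
        goodness=r2,
        n_points=int(np.count_nonzero(sel)),
    )
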