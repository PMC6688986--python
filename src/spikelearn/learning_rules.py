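"""Mismatch-driven learning steps and their attractive/repulsive bookkeeping.

A learning step moves a student parameter by ``step_size * (O_T - O_S) * x``
whenever teacher and student disagree on the output bit of a stimulation,
then clips into the hard bounds.  Each applied step is classified by
whether it moved the student toward (attractive) or away from (repulsive)
the teacher's value at the previous example.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "LearningParams",
    "StepRecord",
    "learning_step",
    "classify_step",
    "step_records_to_tsv",
]


@dataclass(frozen=True)
class LearningParams:
    step_size: float = 0.0
    enabled: bool = True
    # the cost-function derivation carries a factor x*exp((t - tau)/T);
    # at the evaluation time t = tau it equals 1 and is dropped by default
    drop_exponential_prefactor: bool = True

    def __post_init__(self) -> None:
        if self.step_size < 0:
            raise ValueError("step_size must be non-negative")


@dataclass(frozen=True)
class StepRecord:
    """Bookkeeping for one applied learning step.

    ``teacher_value_before`` is the teacher's parameter at the previous
    example boundary; ``student_before``/``student_after`` bracket the
    step itself.
    """

    example_index: int
    parameter_index: int
    teacher_value_before: float
    student_before: float
    student_after: float


def learning_step(
    param: float,
    o_teacher: int,
    o_student: int,
    amplitude: float,
    params: LearningParams,
    bounds: tuple[float, float],
    decay_lag_over_tau: float = 0.0,
) -> float:
    """Apply one perceptron-style correction step, clipped into bounds.

    No-op when the outputs agree or learning is disabled.  When the
    exponential prefactor is kept, ``decay_lag_over_tau`` supplies the
    ``(t - tau)/T`` exponent (zero at the stimulation instant).
    """
    if o_teacher not in (0, 1) or o_student not in (0, 1):
        raise ValueError("outputs must be binary")
    if not params.enabled or o_teacher == o_student:
        return param
    x = amplitude
    if not params.drop_exponential_prefactor:
        import math

        x = x * math.exp(decay_lag_over_tau)
    new = param + params.step_size * (o_teacher - o_student) * x
    lo, hi = bounds
    return min(max(new, lo), hi)


def classify_step(record: StepRecord) -> str:
    """'attractive' if the step moved the student toward the teacher's
    previous value, 'repulsive' if away, 'neutral' on a zero product."""
    product = (record.teacher_value_before - record.student_before) * (
        record.student_after - record.student_before
    )
    if product > 0:
        return "attractive"
    if product < 0:
        return "repulsive"
    return "neutral"


def step_records_to_tsv(
    records: Iterable[StepRecord], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment is not None:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "example_index\tparameter_index\tteacher_value_before\t"
            "student_before\tstudent_after\tclassification\n"
        )
        for r in records:
            fh.write(
                f"{r.example_index}\t{r.parameter_index}\t{r.teacher_value_before!r}\t"
                f"{r.student_before!r}\t{r.student_after!r}\t{classify_step(r)}\n"
            )
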