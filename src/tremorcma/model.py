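"""Core cost engine: stage sums, probability-weighted downstream events, totals.

The model is a staged direct-cost account over a 12-month horizon with no
discounting: a procedure's total cost is the sum of its pre-procedure,
procedure and post-procedure stage costs, plus the expected cost of
probability-weighted downstream events (re-treatment by radiofrequency
thalamotomy after tremor recurrence following MRgFUS; DBS electrode
extraction).  Event trees are depth 1: a downstream procedure may not itself
carry events, so the total is affine in every event probability with slope
equal to the referenced procedure's own total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

from .catalog import Catalog, CostItem, Stage, hospitalisation_cost
from .errors import ConfigurationError

__all__ = [
    "DownstreamEvent",
    "HospitalStay",
    "ProcedureModel",
    "StageBreakdown",
    "stage_cost",
    "expected_event_cost",
    "total_cost",
    "cost_difference",
]


@dataclass(frozen=True)
class DownstreamEvent:
    """A probability-weighted reference to another procedure's total cost.

    ``probability`` is a plain per-12-month probability (no half-cycle
    correction, no discounting).  The expected cost is allocated entirely to
    the POST stage of the owning procedure, since both modelled events
    (re-treatment, hardware extraction) occur after the index procedure.
    """

    name: str
    probability: float
    referenced_procedure: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError(
                f"event {self.name!r}: probability must be in [0, 1], got {self.probability}"
            )


@dataclass(frozen=True)
class HospitalStay:
    """An inpatient stay priced through a day-indexed catalog schedule."""

    schedule_id: str
    days: int
    stage: Stage = Stage.POST
    sampled: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage(self.stage))


@dataclass(frozen=True)
class ProcedureModel:
    """A named intervention as resolved, priceable cost bundles.

    ``items`` are concrete :class:`CostItem` lines already resolved to a
    tariff system (see :func:`tremorcma.scenarios.build_scenario`); ``stays``
    are day-indexed hospitalisations priced via ``schedules`` passed to the
    costing functions; ``events`` are depth-1 downstream events.
    """

    name: str
    items: Tuple[CostItem, ...] = ()
    stays: Tuple[HospitalStay, ...] = ()
    events: Tuple[DownstreamEvent, ...] = ()
    duration_hours: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "stays", tuple(self.stays))
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if ev.referenced_procedure == self.name:
                raise ConfigurationError(
                    f"procedure {self.name!r}: event {ev.name!r} references the "
                    f"owning procedure (self-recursion is not allowed)"
                )


@dataclass(frozen=True)
class StageBreakdown:
    """Pre / procedure / post costs and their exact (unrounded) sum."""

    pre: float
    procedure: float
    post: float

    @property
    def total(self) -> float:
        return self.pre + self.procedure + self.post

    def __sub__(self, other: "StageBreakdown") -> "StageBreakdown":
        return StageBreakdown(
            self.pre - other.pre,
            self.procedure - other.procedure,
            self.post - other.post,
        )


ScheduleMap = Mapping[str, "object"]  # schedule_id -> HospitalisationSchedule


def stage_cost(
    procedure: ProcedureModel,
    schedules: Mapping[str, object],
    stage: Stage,
) -> float:
    """Sum of unit_cost x quantity over the procedure's items in ``stage``,
    plus any hospital stays allocated to that stage.

    Downstream events are *not* included here; they enter in
    :func:`total_cost` via their stage allocation.
    """
    stage = Stage(stage)
    total = 0.0
    for item in procedure.items:
        if item.stage is stage:
            total += item.cost
    for stay in procedure.stays:
        if stay.stage is stage:
            schedule = schedules.get(stay.schedule_id)
            if schedule is None:
                raise ConfigurationError(
                    f"procedure {procedure.name!r}: stay references unknown "
                    f"schedule {stay.schedule_id!r}"
                )
            total += hospitalisation_cost(schedule, stay.days)
    return total


def expected_event_cost(
    event: DownstreamEvent,
    procedures: Mapping[str, ProcedureModel],
    schedules: Mapping[str, object],
) -> float:
    """probability x total cost of the referenced procedure, exact and unrounded."""
    ref = procedures.get(event.referenced_procedure)
    if ref is None:
        raise ConfigurationError(
            f"event {event.name!r}: referenced procedure "
            f"{event.referenced_procedure!r} is not resolved in this scenario"
        )
    if ref.events:
        raise ConfigurationError(
            f"event {event.name!r}: referenced procedure {ref.name!r} carries "
            f"events of its own; only depth-1 event trees are supported"
        )
    return event.probability * total_cost(ref, procedures, schedules).total


def total_cost(
    procedure: ProcedureModel,
    procedures: Mapping[str, ProcedureModel],
    schedules: Mapping[str, object],
) -> StageBreakdown:
    """Stage breakdown with each event's expected cost added to the POST stage.

    The total is the exact sum ``pre + procedure + post``; no rounding is
    applied anywhere in the computation.
    """
    pre = stage_cost(procedure, schedules, Stage.PRE)
    proc = stage_cost(procedure, schedules, Stage.PROCEDURE)
    post = stage_cost(procedure, schedules, Stage.POST)
    for event in procedure.events:
        post += expected_event_cost(event, procedures, schedules)
    return StageBreakdown(pre=pre, procedure=proc, post=post)


def cost_difference(a: StageBreakdown, b: StageBreakdown) -> float:
    """Signed difference of totals, ``a.total - b.total``, exact before rounding."""
    return a.total - b.total
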