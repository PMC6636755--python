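"""JHIFS healthcare-professional labour add-on costs.

Japanese FFS/DPC tariffs embed routine inpatient labour, but the Japanese
Health Insurance Federation for Surgery (JHIFS / Gaihoren) publishes hourly
labour rates meant to capture staff time the procedure tariffs understate.
The scenario analyses add these as: hourly rate x headcount x hours per
entry, with

* a correction factor (default 0.7) applied to *day-of-procedure* entries
  only, offsetting the JHIFS tariff's known ~40% overestimation relative to
  the FFS fee schedule;
* pre-procedure entries left uncorrected (a deliberately conservative
  choice, since they apply to MRgFUS only);
* entries flagged ``scales_with_procedure_duration`` evaluated at the
  procedure's duration rather than their nominal hours, making the labour
  cost affine in duration;
* an optional probability-weighted labour term for the downstream
  re-treatment procedure (labour is added to subsequent RFT, but not to DBS
  extraction or device management).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from .errors import ConfigurationError, DomainError

__all__ = [
    "LabourPhase",
    "LabourEntry",
    "WeightedLabour",
    "LabourModel",
    "labour_entry_cost",
    "procedure_labour_cost",
    "duration_sensitivity",
]


class LabourPhase(str, enum.Enum):
    PRE_PROCEDURE = "pre_procedure"
    DAY_OF_PROCEDURE = "day_of_procedure"


@dataclass(frozen=True)
class LabourEntry:
    """One staffing line: a role, year-keyed hourly rates, headcount and hours."""

    role: str
    hourly_rate: Mapping[int, float]  # year -> JPY per hour
    headcount: float = 1.0
    hours: float = 0.0
    phase: LabourPhase = LabourPhase.DAY_OF_PROCEDURE
    scales_with_procedure_duration: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", LabourPhase(self.phase))
        object.__setattr__(self, "hourly_rate", dict(self.hourly_rate))
        if any(r < 0 for r in self.hourly_rate.values()):
            raise ConfigurationError(f"entry {self.role!r}: hourly rates must be >= 0")
        if self.headcount < 0 or self.hours < 0:
            raise ConfigurationError(
                f"entry {self.role!r}: headcount and hours must be >= 0"
            )

    def rate(self, year: int) -> float:
        try:
            return self.hourly_rate[int(year)]
        except KeyError:
            raise ConfigurationError(
                f"entry {self.role!r}: no hourly rate defined for year {year}; "
                f"available years: {sorted(self.hourly_rate)}"
            ) from None


@dataclass(frozen=True)
class WeightedLabour:
    """Probability-weighted labour of a downstream procedure (e.g. RFT)."""

    probability: float
    model: "LabourModel"
    duration_hours: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError("weighted labour probability must be in [0, 1]")


@dataclass(frozen=True)
class LabourModel:
    """Phase-tagged labour entries plus the day-of-procedure correction factor."""

    entries: Tuple[LabourEntry, ...]
    correction_factor: float = 0.7
    event_labour: Tuple[WeightedLabour, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "event_labour", tuple(self.event_labour))
        if not 0.0 < self.correction_factor <= 1.0:
            raise ConfigurationError(
                f"correction_factor must be in (0, 1], got {self.correction_factor}"
            )


def labour_entry_cost(entry: LabourEntry, year: int, duration: Optional[float] = None) -> float:
    """hourly_rate(year) x headcount x hours.

    Entries that scale with procedure duration are evaluated at ``duration``
    when one is supplied.
    """
    hours = entry.hours
    if entry.scales_with_procedure_duration and duration is not None:
        hours = duration
    return entry.rate(year) * entry.headcount * hours


def procedure_labour_cost(model: LabourModel, year: int, duration: float) -> float:
    """Total labour add-on for one procedure at ``duration`` hours.

    Pre-procedure entries are summed uncorrected; day-of-procedure entries
    are summed, corrected by ``correction_factor``; probability-weighted
    downstream labour is evaluated recursively at its own base duration
    (the same correction rule applies inside it).  Exact, no rounding.
    """
    if duration <= 0:
        raise DomainError(f"duration must be > 0 hours, got {duration}")
    pre = sum(
        labour_entry_cost(e, year, duration)
        for e in model.entries
        if e.phase is LabourPhase.PRE_PROCEDURE
    )
    day = sum(
        labour_entry_cost(e, year, duration)
        for e in model.entries
        if e.phase is LabourPhase.DAY_OF_PROCEDURE
    )
    weighted = sum(
        w.probability * procedure_labour_cost(w.model, year, w.duration_hours)
        for w in model.event_labour
    )
    return pre + model.correction_factor * day + weighted


def duration_sensitivity(
    model: LabourModel, year: int, durations: Sequence[float]
) -> "dict[float, float]":
    """Labour cost at each duration.

    The result is affine in duration with slope ``correction_factor x
    sum(rate x headcount)`` over the duration-scaling day-of-procedure
    entries.
    """
    return {d: procedure_labour_cost(model, year, d) for d in durations}
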