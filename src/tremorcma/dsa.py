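"""One-way deterministic sensitivity analysis.

Each analysis varies a single model parameter across stated test values,
re-evaluates the whole scenario at every value (by rebuilding it, never by
mutation) and tabulates per-procedure grand totals plus the
MRgFUS-versus-DBS difference.  The four parameters mirror the study design:
the proportion of MRgFUS procedures followed by a re-treatment RFT, the DBS
electrode extraction rate, the DBS post-procedure hospitalisation duration,
and the MRgFUS procedure duration (labour scenarios only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .errors import ConfigurationError, DomainError
from .scenarios import (
    OVERRIDE_NAMES,
    Scenario,
    ScenarioResult,
    apply_override,
    run_scenario,
)

__all__ = ["DsaParameter", "DsaRow", "DsaTable", "run_one_way", "tornado_summary"]

_PROBABILITY_PARAMS = ("rft_proportion", "extraction_rate")


@dataclass(frozen=True)
class DsaParameter:
    """A one-way sensitivity parameter: base value plus test values."""

    name: str
    base_value: float
    test_values: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_values", tuple(self.test_values))
        if self.name not in OVERRIDE_NAMES:
            raise ConfigurationError(
                f"unknown DSA parameter {self.name!r}; known: {list(OVERRIDE_NAMES)}"
            )
        values = (self.base_value, *self.test_values)
        if self.name in _PROBABILITY_PARAMS and not all(0.0 <= v <= 1.0 for v in values):
            raise DomainError(f"{self.name}: probabilities must lie in [0, 1]")
        if self.name == "dbs_post_hospital_days" and not all(
            v == int(v) and v >= 0 for v in values
        ):
            raise DomainError(f"{self.name}: days must be non-negative integers")
        if self.name == "mrgfus_duration_hours" and not all(v > 0 for v in values):
            raise DomainError(f"{self.name}: durations must be > 0 hours")


@dataclass(frozen=True)
class DsaRow:
    value: float
    result: ScenarioResult

    @property
    def difference(self) -> float:
        return self.result.difference["grand_total"]


@dataclass(frozen=True)
class DsaTable:
    parameter: DsaParameter
    rows: Tuple[DsaRow, ...]

    def row_at(self, value: float) -> DsaRow:
        for row in self.rows:
            if row.value == value:
                return row
        raise KeyError(f"no DSA row at {self.parameter.name}={value!r}")

    @property
    def differences(self) -> List[float]:
        return [row.difference for row in self.rows]


def run_one_way(scenario: Scenario, parameter: DsaParameter) -> DsaTable:
    """Re-evaluate the scenario at the base value and every test value.

    The row at the base value reproduces the unmodified scenario exactly.
    Varying ``mrgfus_duration_hours`` without a labour year configured is a
    configuration error, since duration only enters through labour costs.
    """
    if parameter.name == "mrgfus_duration_hours" and scenario.config.labour_year is None:
        raise ConfigurationError(
            "mrgfus_duration_hours requires a scenario with labour costs enabled"
        )
    values = [parameter.base_value] + [
        v for v in parameter.test_values if v != parameter.base_value
    ]
    rows = tuple(
        DsaRow(value=v, result=run_scenario(apply_override(scenario, parameter.name, v)))
        for v in values
    )
    return DsaTable(parameter=parameter, rows=rows)


@dataclass(frozen=True)
class TornadoSpan:
    parameter: str
    min_difference: float
    max_difference: float

    @property
    def span(self) -> float:
        return abs(self.max_difference - self.min_difference)


def tornado_summary(tables: Sequence[DsaTable]) -> List[TornadoSpan]:
    """Per parameter, the min/max MRgFUS-vs-DBS difference, widest span first."""
    spans = []
    for table in tables:
        diffs = table.differences
        spans.append(
            TornadoSpan(
                parameter=table.parameter.name,
                min_difference=min(diffs),
                max_difference=max(diffs),
            )
        )
    return sorted(spans, key=lambda s: s.span, reverse=True)
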