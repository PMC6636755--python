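"""Scenario assembly: base case (FFS), DPC substitution, labour add-on variants.

A scenario resolves procedure *definitions* (lists of catalog item ids,
hospital stays, downstream events) against a catalog under one tariff mode:

* ``FFS`` — every item priced under fee-for-service (or the National Drug
  Tariff for drugs);
* ``DPC_substituted`` — Diagnosis Procedure Combination tariffs replace the
  FFS prices of exactly the pre-procedure items, post-procedure items and
  day-of-procedure hospitalisation items; procedure fees, devices and drugs
  keep their FFS / drug-tariff prices.

Optionally a JHIFS labour model (2016 or 2018 rates) is attached per
procedure; grand totals are then medical total + labour total, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .catalog import Catalog, CostItem, HospitalisationSchedule, Stage, TariffSystem
from .errors import ConfigurationError
from .labour import LabourModel, procedure_labour_cost
from .model import (
    DownstreamEvent,
    HospitalStay,
    ProcedureModel,
    StageBreakdown,
    cost_difference,
    total_cost,
)

__all__ = [
    "MRGFUS",
    "UNILATERAL_DBS",
    "RFT",
    "EXTRACTION",
    "ProcedureDefinition",
    "ScenarioConfig",
    "Scenario",
    "ScenarioResult",
    "build_scenario",
    "run_scenario",
    "apply_override",
]

# Canonical procedure names used throughout the package.
MRGFUS = "MRgFUS"
UNILATERAL_DBS = "unilateral_DBS"
RFT = "RFT"
EXTRACTION = "extraction"

OVERRIDE_NAMES = (
    "rft_proportion",
    "extraction_rate",
    "dbs_post_hospital_days",
    "mrgfus_duration_hours",
)


@dataclass(frozen=True)
class ProcedureDefinition:
    """An unresolved procedure: item ids rather than priced items."""

    name: str
    item_ids: Tuple[str, ...]
    stays: Tuple[HospitalStay, ...] = ()
    events: Tuple[DownstreamEvent, ...] = ()
    duration_hours: float = 4.0


@dataclass(frozen=True)
class ScenarioConfig:
    medical_tariff: str = "FFS"  # "FFS" | "DPC_substituted"
    labour_year: Optional[int] = None  # None, 2016 or 2018
    correction_factor: float = 0.7
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.medical_tariff not in ("FFS", "DPC_substituted"):
            raise ConfigurationError(
                f"medical_tariff must be 'FFS' or 'DPC_substituted', "
                f"got {self.medical_tariff!r}"
            )
        if self.labour_year not in (None, 2016, 2018):
            raise ConfigurationError(
                f"labour_year must be None, 2016 or 2018, got {self.labour_year!r}"
            )
        unknown = set(self.overrides) - set(OVERRIDE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown override parameters: {sorted(unknown)}")


@dataclass(frozen=True)
class Scenario:
    """A fully resolved analysis: priced procedures, schedules, labour models."""

    config: ScenarioConfig
    catalog: Catalog
    procedures: Mapping[str, ProcedureModel]
    schedules: Mapping[str, HospitalisationSchedule]
    labour: Mapping[str, LabourModel] = field(default_factory=dict)
    comparators: Tuple[str, str] = (MRGFUS, UNILATERAL_DBS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "procedures", dict(self.procedures))
        object.__setattr__(self, "schedules", dict(self.schedules))
        object.__setattr__(self, "labour", dict(self.labour))
        for proc in self.procedures.values():
            for ev in proc.events:
                if ev.referenced_procedure not in self.procedures:
                    raise ConfigurationError(
                        f"procedure {proc.name!r}: event {ev.name!r} references "
                        f"unresolved procedure {ev.referenced_procedure!r}"
                    )

    def total(self, name: str) -> StageBreakdown:
        return total_cost(self.procedures[name], self.procedures, self.schedules)

    def labour_cost(self, name: str) -> float:
        if self.config.labour_year is None:
            return 0.0
        model = self.labour.get(name)
        if model is None:
            raise ConfigurationError(
                f"labour_year={self.config.labour_year} but no labour model is "
                f"attached for procedure {name!r}"
            )
        return procedure_labour_cost(
            model, self.config.labour_year, self.procedures[name].duration_hours
        )


def _resolve_item(
    catalog: Catalog, item_id: str, dpc_mode: bool, procedure: str
) -> CostItem:
    systems = catalog.systems_for(item_id)
    if not systems:
        raise ConfigurationError(
            f"procedure {procedure!r}: item {item_id!r} not found in the catalog"
        )
    base = None
    for preference in (TariffSystem.FFS, TariffSystem.DRUG_TARIFF):
        if preference in systems:
            base = catalog.get(item_id, preference)
            break
    if base is None and TariffSystem.DPC in systems and dpc_mode:
        return catalog.get(item_id, TariffSystem.DPC)
    if base is None:
        raise ConfigurationError(
            f"procedure {procedure!r}: item {item_id!r} has no FFS or drug-tariff "
            f"price (available: {sorted(s.value for s in systems)})"
        )
    if dpc_mode and base.is_dpc_substitutable():
        if TariffSystem.DPC not in systems:
            raise ConfigurationError(
                f"DPC scenario requires a DPC price for substitutable item "
                f"{item_id!r} (procedure {procedure!r}) but none is in the catalog"
            )
        return catalog.get(item_id, TariffSystem.DPC)
    return base


def build_scenario(
    config: ScenarioConfig,
    catalog: Catalog,
    definitions: Sequence[ProcedureDefinition],
    labour_models: Optional[Mapping[str, LabourModel]] = None,
) -> Scenario:
    """Resolve definitions against the catalog under the configured tariff mode.

    In DPC mode, exactly the substitutable item classes (pre, post,
    day-of-procedure hospitalisation — or items explicitly flagged
    ``dpc_substitutable``) are swapped to their DPC prices, and hospital-stay
    schedules are swapped to their DPC variants; everything else keeps its
    FFS / drug-tariff price.  Missing DPC prices for required items raise a
    :class:`ConfigurationError` naming the item.
    """
    dpc_mode = config.medical_tariff == "DPC_substituted"
    procedures: Dict[str, ProcedureModel] = {}
    schedules: Dict[str, HospitalisationSchedule] = {}
    for definition in definitions:
        items = tuple(
            _resolve_item(catalog, iid, dpc_mode, definition.name)
            for iid in definition.item_ids
        )
        for stay in definition.stays:
            sid = stay.schedule_id
            if sid in schedules:
                continue
            available = {sys for (s, sys) in catalog.schedules if s == sid}
            wanted = TariffSystem.DPC if dpc_mode else TariffSystem.FFS
            if wanted not in available:
                raise ConfigurationError(
                    f"{config.medical_tariff} scenario requires schedule {sid!r} "
                    f"under {wanted.value!r} but the catalog only defines it for "
                    f"{sorted(s.value for s in available)}"
                )
            schedules[sid] = catalog.schedule(sid, wanted)
        procedures[definition.name] = ProcedureModel(
            name=definition.name,
            items=items,
            stays=definition.stays,
            events=definition.events,
            duration_hours=definition.duration_hours,
        )
    labour: Dict[str, LabourModel] = {}
    if config.labour_year is not None and labour_models:
        labour = {
            name: replace(model, correction_factor=config.correction_factor)
            for name, model in labour_models.items()
        }
    scenario = Scenario(
        config=config,
        catalog=catalog,
        procedures=procedures,
        schedules=schedules,
        labour=labour,
    )
    for name, value in config.overrides.items():
        scenario = apply_override(scenario, name, value)
    return scenario


def apply_override(scenario: Scenario, name: str, value: float) -> Scenario:
    """Return a new scenario with one sensitivity parameter overridden.

    Never mutates shared state, so sensitivity-analysis rows are independent
    and order-insensitive.
    """
    procedures = dict(scenario.procedures)

    def _with_event_probability(proc_name: str, referenced: str, p: float) -> None:
        proc = procedures[proc_name]
        events = tuple(
            replace(ev, probability=p) if ev.referenced_procedure == referenced else ev
            for ev in proc.events
        )
        if events == proc.events and not any(
            ev.referenced_procedure == referenced for ev in proc.events
        ):
            raise ConfigurationError(
                f"cannot override {name!r}: procedure {proc_name!r} has no event "
                f"referencing {referenced!r}"
            )
        procedures[proc_name] = replace(proc, events=events)

    if name == "rft_proportion":
        _with_event_probability(MRGFUS, RFT, float(value))
    elif name == "extraction_rate":
        _with_event_probability(UNILATERAL_DBS, EXTRACTION, float(value))
    elif name == "dbs_post_hospital_days":
        if value != int(value) or value < 0:
            raise ConfigurationError(
                f"dbs_post_hospital_days must be a non-negative integer, got {value!r}"
            )
        proc = procedures[UNILATERAL_DBS]
        post_stays = [s for s in proc.stays if s.stage is Stage.POST]
        if not post_stays:
            raise ConfigurationError(
                "cannot override dbs_post_hospital_days: the DBS procedure has "
                "no post-stage hospital stay"
            )
        stays = tuple(
            replace(s, days=int(value)) if s is post_stays[0] else s for s in proc.stays
        )
        procedures[UNILATERAL_DBS] = replace(proc, stays=stays)
    elif name == "mrgfus_duration_hours":
        if scenario.config.labour_year is None:
            raise ConfigurationError(
                "mrgfus_duration_hours only affects labour costs; enable a "
                "labour_year before varying it"
            )
        if value <= 0:
            raise ConfigurationError(f"duration must be > 0 hours, got {value!r}")
        procedures[MRGFUS] = replace(procedures[MRGFUS], duration_hours=float(value))
    else:
        raise ConfigurationError(
            f"unknown override parameter {name!r}; known: {list(OVERRIDE_NAMES)}"
        )
    return replace(scenario, procedures=procedures)


@dataclass(frozen=True)
class ScenarioResult:
    """Per-procedure stage breakdowns, labour costs and grand totals.

    ``difference`` rows are MRgFUS minus unilateral DBS, exact before
    rounding (rounding is a rendering concern).
    """

    config: ScenarioConfig
    breakdowns: Mapping[str, StageBreakdown]
    labour_costs: Mapping[str, float]
    comparators: Tuple[str, str]

    def medical_total(self, name: str) -> float:
        return self.breakdowns[name].total

    def grand_total(self, name: str) -> float:
        return self.breakdowns[name].total + self.labour_costs.get(name, 0.0)

    @property
    def difference(self) -> Dict[str, float]:
        a, b = self.comparators
        delta = self.breakdowns[a] - self.breakdowns[b]
        return {
            "pre": delta.pre,
            "procedure": delta.procedure,
            "post": delta.post,
            "total": cost_difference(self.breakdowns[a], self.breakdowns[b]),
            "labour": self.labour_costs.get(a, 0.0) - self.labour_costs.get(b, 0.0),
            "grand_total": self.grand_total(a) - self.grand_total(b),
        }


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Evaluate the scenario: stage breakdowns, labour add-ons, grand totals."""
    breakdowns = {name: scenario.total(name) for name in scenario.comparators}
    labour_costs = {}
    if scenario.config.labour_year is not None:
        labour_costs = {name: scenario.labour_cost(name) for name in scenario.comparators}
    return ScenarioResult(
        config=scenario.config,
        breakdowns=breakdowns,
        labour_costs=labour_costs,
        comparators=scenario.comparators,
    )
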