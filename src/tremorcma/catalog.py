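"""Tariff catalogs: priced resource-use line items and hospitalisation fee schedules.

A :class:`Catalog` is the atom store every cost in the model is built from.
Each :class:`CostItem` is one tariff-priced line (an imaging session, a
device, a per-procedure fee bundle, ...) tagged with the stage of the care
pathway it belongs to and the tariff system it is priced under (2018
fee-for-service tariffs, Diagnosis Procedure Combination per-diem tariffs,
the National Drug Tariff, or JHIFS hourly labour tariffs).  Hospitalisation
is priced through a day-indexed fee schedule because the marginal cost of an
inpatient day is not constant across the stay.

Money is carried as plain float JPY with no intermediate rounding; rounding
to the nearest yen happens only when a report is rendered
(:func:`tremorcma.report.round_jpy`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import CatalogValidationError, CostLookupError, DomainError

__all__ = [
    "Stage",
    "Category",
    "TariffSystem",
    "CostItem",
    "HospitalisationSchedule",
    "Catalog",
    "load_catalog",
    "write_catalog",
    "lookup_cost",
    "hospitalisation_cost",
]


class Stage(str, enum.Enum):
    """Stage of the care pathway a cost accrues in."""

    PRE = "pre"
    PROCEDURE = "procedure"
    POST = "post"


class Category(str, enum.Enum):
    IMAGING = "imaging"
    HOSPITALISATION = "hospitalisation"
    DRUG = "drug"
    DEVICE = "device"
    FEE = "fee"
    ANAESTHESIA = "anaesthesia"
    SESSION = "session"
    LABOUR = "labour"
    PREMIUM = "premium"


class TariffSystem(str, enum.Enum):
    FFS = "FFS"
    DPC = "DPC"
    DRUG_TARIFF = "drug_tariff"
    JHIFS2016 = "JHIFS2016"
    JHIFS2018 = "JHIFS2018"


@dataclass(frozen=True)
class CostItem:
    """One tariff-priced resource-use line item.

    ``dpc_substitutable`` declares whether the DPC scenario may reprice this
    item.  ``None`` means "use the structural default": pre- and
    post-procedure items and day-of-procedure hospitalisation items are
    substitutable, everything else (procedure fees, devices, drugs) stays on
    its original tariff.  ``sampled`` marks the item as a probabilistic-
    sensitivity-analysis parameter rather than a fixed constant.
    """

    item_id: str
    label: str
    stage: Stage
    category: Category
    unit_cost: float
    quantity: float = 1.0
    tariff_system: TariffSystem = TariffSystem.FFS
    parent_item: Optional[str] = None
    sampled: bool = True
    dpc_substitutable: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage(self.stage))
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "tariff_system", TariffSystem(self.tariff_system))
        if self.unit_cost < 0:
            raise CatalogValidationError(
                f"item {self.item_id!r}: unit_cost must be >= 0, got {self.unit_cost}"
            )
        if self.quantity < 0:
            raise CatalogValidationError(
                f"item {self.item_id!r}: quantity must be >= 0, got {self.quantity}"
            )
        if self.category is Category.PREMIUM and not self.parent_item:
            raise CatalogValidationError(
                f"item {self.item_id!r}: premium items must name a parent_item"
            )

    @property
    def cost(self) -> float:
        """unit_cost x quantity for this line."""
        return self.unit_cost * self.quantity

    def is_dpc_substitutable(self) -> bool:
        if self.dpc_substitutable is not None:
            return self.dpc_substitutable
        return self.stage in (Stage.PRE, Stage.POST) or (
            self.stage is Stage.PROCEDURE and self.category is Category.HOSPITALISATION
        )


@dataclass(frozen=True)
class HospitalisationSchedule:
    """Day-indexed inpatient fee schedule.

    ``bands`` is an ordered sequence of ``(first_day, last_day, fee_per_day)``
    triples; bands must be contiguous from day 1 and non-overlapping.  A
    ``last_day`` of ``None`` in the final band means "and every later day".
    """

    bands: Tuple[Tuple[int, Optional[int], float], ...]

    def __post_init__(self) -> None:
        norm = tuple(
            (int(a), (None if b is None else int(b)), float(f)) for a, b, f in self.bands
        )
        object.__setattr__(self, "bands", norm)
        if not norm:
            raise CatalogValidationError("schedule needs at least one band")
        expected_start = 1
        for i, (a, b, fee) in enumerate(norm):
            if a != expected_start:
                raise CatalogValidationError(
                    f"schedule bands must be contiguous from day 1; band {i} starts at "
                    f"day {a}, expected {expected_start}"
                )
            if fee < 0:
                raise CatalogValidationError(f"schedule band {i}: fee must be >= 0")
            if b is None:
                if i != len(norm) - 1:
                    raise CatalogValidationError("open-ended band must be last")
                expected_start = None
            else:
                if b < a:
                    raise CatalogValidationError(f"schedule band {i}: last_day < first_day")
                expected_start = b + 1

    def daily_fee(self, day: int) -> float:
        """Fee for inpatient day ``day`` (1-based)."""
        if day < 1:
            raise DomainError(f"day index must be >= 1, got {day}")
        for a, b, fee in self.bands:
            if day >= a and (b is None or day <= b):
                return fee
        raise DomainError(f"day {day} beyond the last schedule band")

    def cost(self, days: int) -> float:
        """Total fee for a stay of ``days`` days (sum over days 1..days)."""
        if days != int(days) or days < 0:
            raise DomainError(f"days must be a non-negative integer, got {days!r}")
        days = int(days)
        total = 0.0
        for a, b, fee in self.bands:
            if days < a:
                break
            hi = days if b is None else min(b, days)
            total += fee * (hi - a + 1)
        if self.bands[-1][1] is not None and days > self.bands[-1][1]:
            raise DomainError(
                f"stay of {days} days exceeds the schedule's last band "
                f"(day {self.bands[-1][1]})"
            )
        return total


def hospitalisation_cost(schedule: HospitalisationSchedule, days: int) -> float:
    """Cost of an inpatient stay of ``days`` days under ``schedule``."""
    return schedule.cost(days)


_CSV_COLUMNS = [
    "item_id",
    "label",
    "stage",
    "category",
    "unit_cost",
    "quantity",
    "tariff_system",
    "parent_item",
    "sampled",
    "dpc_substitutable",
]
_REQUIRED_COLUMNS = ["item_id", "stage", "category", "unit_cost", "quantity", "tariff_system"]


@dataclass(frozen=True)
class Catalog:
    """A validated set of cost items plus hospitalisation schedules.

    Items are keyed by ``(item_id, tariff_system)``: the same logical item may
    carry a different price under each tariff system.  Schedules are keyed the
    same way.
    """

    items: Tuple[CostItem, ...]
    schedules: Mapping[Tuple[str, TariffSystem], HospitalisationSchedule] = field(
        default_factory=dict
    )
    currency_year: int = 2018

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(
            self,
            "schedules",
            {(sid, TariffSystem(sys)): sch for (sid, sys), sch in dict(self.schedules).items()},
        )
        index = {}
        for item in self.items:
            key = (item.item_id, item.tariff_system)
            if key in index:
                raise CatalogValidationError(
                    f"duplicate item_id {item.item_id!r} under tariff system "
                    f"{item.tariff_system.value!r}"
                )
            index[key] = item
        object.__setattr__(self, "_index", index)
        for item in self.items:
            if item.category is Category.PREMIUM:
                parent = index.get((item.parent_item, item.tariff_system))
                if parent is None or parent.category is Category.PREMIUM:
                    raise CatalogValidationError(
                        f"premium item {item.item_id!r} ({item.tariff_system.value}): "
                        f"parent_item {item.parent_item!r} does not resolve to an "
                        f"existing non-premium item"
                    )

    def get(self, item_id: str, system: Union[str, TariffSystem]) -> CostItem:
        system = TariffSystem(system)
        try:
            return self._index[(item_id, system)]
        except KeyError:
            available = self.systems_for(item_id)
            if available:
                raise CostLookupError(
                    f"item {item_id!r} not priced under {system.value!r}; "
                    f"available systems: {sorted(s.value for s in available)}"
                ) from None
            raise CostLookupError(f"unknown item {item_id!r}") from None

    def systems_for(self, item_id: str) -> Tuple[TariffSystem, ...]:
        return tuple(s for (iid, s) in self._index if iid == item_id)

    def schedule(self, schedule_id: str, system: Union[str, TariffSystem]) -> HospitalisationSchedule:
        system = TariffSystem(system)
        try:
            return self.schedules[(schedule_id, system)]
        except KeyError:
            available = sorted(s.value for (sid, s) in self.schedules if sid == schedule_id)
            raise CostLookupError(
                f"schedule {schedule_id!r} not defined under {system.value!r}"
                + (f"; available systems: {available}" if available else "")
            ) from None


def lookup_cost(catalog: Catalog, item_id: str, system: Union[str, TariffSystem]) -> float:
    """unit_cost x quantity for ``(item_id, system)``.

    Raises :class:`CostLookupError` listing the systems the item *is* priced
    under when the pair is absent.
    """
    return catalog.get(item_id, system).cost


def _item_from_row(row: Mapping, where: str) -> CostItem:
    def _opt(name, default=None):
        v = row.get(name)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return default
        return v

    def _bool(v, default):
        if v is None:
            return default
        if isinstance(v, bool):
            return v
        return str(v).strip().lower() in ("1", "true", "yes")

    try:
        return CostItem(
            item_id=str(row["item_id"]),
            label=str(_opt("label", row["item_id"])),
            stage=Stage(str(row["stage"])),
            category=Category(str(row["category"])),
            unit_cost=float(row["unit_cost"]),
            quantity=float(row["quantity"]),
            tariff_system=TariffSystem(str(row["tariff_system"])),
            parent_item=_opt("parent_item"),
            sampled=_bool(_opt("sampled"), True),
            dpc_substitutable=(
                None
                if _opt("dpc_substitutable") is None
                else _bool(_opt("dpc_substitutable"), None)
            ),
        )
    except (CatalogValidationError, ValueError, KeyError) as exc:
        raise CatalogValidationError(f"{where}: {exc}") from exc


def load_catalog(path: Union[str, Path], format: Optional[str] = None) -> Catalog:
    """Load and validate a catalog from CSV (items only) or JSON (items + schedules).

    The CSV dialect is UTF-8, comma-separated, header row required, with
    columns ``item_id, label, stage, category, unit_cost, quantity,
    tariff_system`` and optional ``parent_item, sampled, dpc_substitutable``.
    Validation failures name the offending row.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(
            path,
            dtype={"item_id": str, "parent_item": str},
            float_precision="round_trip",
        )
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CatalogValidationError(f"{path}: missing required columns {missing}")
        items = [
            _item_from_row(row, f"{path} row {i + 2}")  # +2: header + 1-based
            for i, row in enumerate(frame.to_dict(orient="records"))
        ]
        return Catalog(items=items)
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        items = [
            _item_from_row(rec, f"{path} items[{i}]")
            for i, rec in enumerate(payload.get("items", []))
        ]
        schedules = {
            (rec["schedule_id"], TariffSystem(rec["tariff_system"])): HospitalisationSchedule(
                bands=tuple((b[0], b[1], b[2]) for b in rec["bands"])
            )
            for rec in payload.get("schedules", [])
        }
        return Catalog(
            items=items,
            schedules=schedules,
            currency_year=int(payload.get("currency_year", 2018)),
        )
    raise CatalogValidationError(f"unknown catalog format {fmt!r}")


def _item_record(item: CostItem) -> dict:
    return {
        "item_id": item.item_id,
        "label": item.label,
        "stage": item.stage.value,
        "category": item.category.value,
        "unit_cost": item.unit_cost,
        "quantity": item.quantity,
        "tariff_system": item.tariff_system.value,
        "parent_item": item.parent_item,
        "sampled": item.sampled,
        "dpc_substitutable": item.dpc_substitutable,
    }


def write_catalog(catalog: Catalog, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a catalog; inverse of :func:`load_catalog` on every field."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.DataFrame([_item_record(i) for i in catalog.items], columns=_CSV_COLUMNS)
        frame.to_csv(path, index=False, float_format="%.17g")  # exact round-trip
        return
    if fmt == "json":
        payload = {
            "currency_year": catalog.currency_year,
            "items": [_item_record(i) for i in catalog.items],
            "schedules": [
                {
                    "schedule_id": sid,
                    "tariff_system": sys.value,
                    "bands": [list(b) for b in sch.bands],
                }
                for (sid, sys), sch in catalog.schedules.items()
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return
    raise CatalogValidationError(f"unknown catalog format {fmt!r}")
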