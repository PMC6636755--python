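"""Scenario model files: catalog + procedure definitions + labour tables.

A model spec is a YAML or JSON document describing everything a scenario
needs besides the tariff mode and labour year:

```yaml
catalog: catalog.json          # path, relative to this file
procedures:
  - name: MRgFUS
    items: [pre_workup, mrgfus_procedure, mrgfus_post_care]
    duration_hours: 4
    events:
      - {name: rft_retreatment, probability: 0.0356, procedure: RFT}
  - name: unilateral_DBS
    items: [pre_workup, dbs_procedure, dbs_post_care]
    stays:
      - {schedule_id: dbs_post_stay, days: 8, stage: post}
    events:
      - {name: electrode_extraction, probability: 0.01, procedure: extraction}
  - {name: RFT, items: [rft_bundle]}
  - {name: extraction, items: [extraction_bundle], duration_hours: 2}
labour:
  2018:
    MRgFUS:
      correction_factor: 0.7
      entries:
        - role: day-of-procedure team
          rates: {2018: 295710}
          headcount: 1
          hours: 4
          phase: day_of_procedure
          scales_with_duration: true
```
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import yaml

from .catalog import Catalog, Stage, load_catalog
from .errors import ConfigurationError
from .labour import LabourEntry, LabourModel, LabourPhase
from .model import DownstreamEvent, HospitalStay
from .scenarios import ProcedureDefinition

__all__ = ["ModelSpec", "load_model_spec"]


@dataclass(frozen=True)
class ModelSpec:
    """Everything build_scenario needs, as loaded from a model file."""

    catalog: Catalog
    definitions: Tuple[ProcedureDefinition, ...]
    labour: Mapping[int, Mapping[str, LabourModel]]


def _definition(rec: Mapping) -> ProcedureDefinition:
    try:
        return ProcedureDefinition(
            name=rec["name"],
            item_ids=tuple(rec.get("items", ())),
            stays=tuple(
                HospitalStay(
                    schedule_id=s["schedule_id"],
                    days=int(s["days"]),
                    stage=Stage(s.get("stage", "post")),
                    sampled=bool(s.get("sampled", True)),
                )
                for s in rec.get("stays", ())
            ),
            events=tuple(
                DownstreamEvent(e["name"], float(e["probability"]), e["procedure"])
                for e in rec.get("events", ())
            ),
            duration_hours=float(rec.get("duration_hours", 4.0)),
        )
    except KeyError as exc:
        raise ConfigurationError(
            f"procedure entry {rec.get('name', rec)!r}: missing field {exc}"
        ) from exc


def _labour_model(rec: Mapping) -> LabourModel:
    entries = tuple(
        LabourEntry(
            role=e.get("role", "unnamed"),
            hourly_rate={int(y): float(r) for y, r in e["rates"].items()},
            headcount=float(e.get("headcount", 1)),
            hours=float(e.get("hours", 0.0)),
            phase=LabourPhase(e.get("phase", "day_of_procedure")),
            scales_with_procedure_duration=bool(e.get("scales_with_duration", False)),
        )
        for e in rec.get("entries", ())
    )
    return LabourModel(entries=entries,
                       correction_factor=float(rec.get("correction_factor", 0.7)))


def load_model_spec(path: Union[str, Path]) -> ModelSpec:
    """Load a YAML/JSON model file; the catalog path resolves relative to it."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict) or "catalog" not in payload or "procedures" not in payload:
        raise ConfigurationError(
            f"{path}: a model spec needs 'catalog' and 'procedures' keys"
        )
    catalog_path = Path(payload["catalog"])
    if not catalog_path.is_absolute():
        catalog_path = path.parent / catalog_path
    catalog = load_catalog(catalog_path)
    definitions = tuple(_definition(rec) for rec in payload["procedures"])
    labour: Dict[int, Dict[str, LabourModel]] = {}
    for year, models in (payload.get("labour") or {}).items():
        labour[int(year)] = {name: _labour_model(rec) for name, rec in models.items()}
    return ModelSpec(catalog=catalog, definitions=definitions, labour=labour)
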