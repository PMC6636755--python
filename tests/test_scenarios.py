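"""Scenario assembly: tariff substitution, labour attachment, grand totals."""

import pytest

from tremorcma import (
    Catalog,
    Category,
    ConfigurationError,
    CostItem,
    ProcedureDefinition,
    Scenario,
    ScenarioConfig,
    Stage,
    TariffSystem,
    build_scenario,
    procedure_labour_cost,
    run_scenario,
)
from tremorcma.report import round_jpy


def test_base_and_dpc_pre_stage_costs(ffs_scenario, dpc_scenario):
    from tremorcma import stage_cost

    assert stage_cost(ffs_scenario.procedures["MRgFUS"], ffs_scenario.schedules,
                      Stage.PRE) == 50_610
    assert stage_cost(dpc_scenario.procedures["MRgFUS"], dpc_scenario.schedules,
                      Stage.PRE) == 25_950


def test_no_labour_means_grand_equals_medical(ffs_scenario):
    result = run_scenario(ffs_scenario)
    for name in result.comparators:
        assert result.grand_total(name) == result.medical_total(name)


@pytest.mark.parametrize(
    "scenario_name, checks",
    [
        ("ffs_labour_2018", {"grand_MRgFUS": 3_076_014, "difference": -736_143}),
        ("ffs_labour_2016", {"difference": -515_910}),
        ("dpc_labour_2018", {"difference": -750_454}),
    ],
)
def test_labour_scenario_grand_totals(request, scenario_name, checks):
    result = run_scenario(request.getfixturevalue(scenario_name))
    if "grand_MRgFUS" in checks:
        assert round_jpy(result.grand_total("MRgFUS")) == checks["grand_MRgFUS"]
    assert round_jpy(result.difference["grand_total"]) == checks["difference"]


def test_labour_additivity_is_exact(ffs_labour_2018, ffs_scenario):
    """Grand total with labour = medical total + procedure_labour_cost, exactly."""
    with_labour = run_scenario(ffs_labour_2018)
    without = run_scenario(ffs_scenario)
    for name in with_labour.comparators:
        labour = procedure_labour_cost(
            ffs_labour_2018.labour[name],
            2018,
            ffs_labour_2018.procedures[name].duration_hours,
        )
        assert with_labour.grand_total(name) == without.medical_total(name) + labour


def _audit_catalog():
    items = (
        CostItem("scan", "pre scan", Stage.PRE, Category.IMAGING, 100.0),
        CostItem("scan", "pre scan", Stage.PRE, Category.IMAGING, 90.0,
                 tariff_system=TariffSystem.DPC),
        CostItem("surgery", "procedure fee", Stage.PROCEDURE, Category.FEE, 200.0),
        CostItem("surgery", "procedure fee", Stage.PROCEDURE, Category.FEE, 150.0,
                 tariff_system=TariffSystem.DPC),
        CostItem("dayof_bed", "day-of-procedure bed", Stage.PROCEDURE,
                 Category.HOSPITALISATION, 50.0),
        CostItem("dayof_bed", "day-of-procedure bed", Stage.PROCEDURE,
                 Category.HOSPITALISATION, 40.0, tariff_system=TariffSystem.DPC),
        CostItem("followup", "post visit", Stage.POST, Category.SESSION, 70.0),
        CostItem("followup", "post visit", Stage.POST, Category.SESSION, 55.0,
                 tariff_system=TariffSystem.DPC),
    )
    definition = ProcedureDefinition(
        name="MRgFUS", item_ids=("scan", "surgery", "dayof_bed", "followup")
    )
    dbs = ProcedureDefinition(name="unilateral_DBS", item_ids=("scan",))
    return Catalog(items=items), (definition, dbs)


def test_dpc_substitution_touches_only_declared_classes():
    """Differential audit: between the FFS and DPC scenarios only pre-stage,
    post-stage and day-of-procedure hospitalisation prices may change."""
    catalog, definitions = _audit_catalog()
    base = build_scenario(ScenarioConfig("FFS"), catalog, definitions)
    dpc = build_scenario(ScenarioConfig("DPC_substituted"), catalog, definitions)
    changed = {
        a.item_id
        for a, b in zip(base.procedures["MRgFUS"].items, dpc.procedures["MRgFUS"].items)
        if a.unit_cost != b.unit_cost
    }
    assert changed == {"scan", "dayof_bed", "followup"}
    # the procedure fee keeps its FFS price even though a DPC variant exists
    surgery = next(i for i in dpc.procedures["MRgFUS"].items if i.item_id == "surgery")
    assert surgery.unit_cost == 200.0


def test_dpc_mode_requires_dpc_price_for_substitutable_items():
    catalog, definitions = _audit_catalog()
    items = tuple(
        i for i in catalog.items
        if not (i.item_id == "followup" and i.tariff_system is TariffSystem.DPC)
    )
    with pytest.raises(ConfigurationError, match="followup"):
        build_scenario(ScenarioConfig("DPC_substituted"), Catalog(items=items), definitions)


def test_missing_item_is_reported_with_procedure():
    catalog, _ = _audit_catalog()
    bad = (ProcedureDefinition(name="MRgFUS", item_ids=("ghost",)),
           ProcedureDefinition(name="unilateral_DBS", item_ids=("scan",)))
    with pytest.raises(ConfigurationError, match="ghost"):
        build_scenario(ScenarioConfig("FFS"), catalog, bad)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(medical_tariff="DRG")
    with pytest.raises(ConfigurationError):
        ScenarioConfig(labour_year=2017)
    with pytest.raises(ConfigurationError):
        ScenarioConfig(overrides={"nonsense": 1.0})


def test_overrides_in_config_are_applied(fixture):
    from tremorcma import reference_scenario

    base = reference_scenario("ffs", fixture=fixture)
    config = ScenarioConfig("FFS", overrides={"rft_proportion": 0.0})
    overridden = build_scenario(config, fixture.catalog, fixture.definitions)
    assert overridden.procedures["MRgFUS"].events[0].probability == 0.0
    assert base.procedures["MRgFUS"].events[0].probability == pytest.approx(0.0356)
    assert round_jpy(overridden.total("MRgFUS").total) == 2_115_300


def test_labour_year_without_model_is_an_error(fixture):
    config = ScenarioConfig("FFS", labour_year=2018)
    scenario = build_scenario(config, fixture.catalog, fixture.definitions,
                              labour_models={"MRgFUS": fixture.labour[2018]["MRgFUS"]})
    with pytest.raises(ConfigurationError, match="unilateral_DBS"):
        run_scenario(scenario)
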