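"""Catalog loading, validation, pricing and hospitalisation schedules."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorcma import (
    Catalog,
    CatalogValidationError,
    Category,
    CostItem,
    CostLookupError,
    DomainError,
    HospitalisationSchedule,
    Stage,
    TariffSystem,
    generate_synthetic_catalog,
    hospitalisation_cost,
    load_catalog,
    lookup_cost,
    write_catalog,
)

GOOD_CSV = textwrap.dedent(
    """\
    item_id,label,stage,category,unit_cost,quantity,tariff_system
    mri,pre-procedure MRI,pre,imaging,10000,2,FFS
    fee,procedure fee,procedure,fee,250000,1,FFS
    stay,overnight stay,post,hospitalisation,8000,1,FFS
    """
)


def _catalog_from_csv(tmp_path, text, name="catalog.csv"):
    path = tmp_path / name
    path.write_text(text)
    return load_catalog(path)


def test_load_well_formed_csv(tmp_path):
    catalog = _catalog_from_csv(tmp_path, GOOD_CSV)
    assert len(catalog.items) == 3
    assert lookup_cost(catalog, "mri", "FFS") == 20000


@pytest.mark.parametrize(
    "mutation, message_part",
    [
        ("mri,MRI,pre,imaging,-1,2,FFS", "unit_cost"),
        ("mri,MRI,pre,imaging,10000,-2,FFS", "quantity"),
        ("extra,premium,pre,premium,100,1,FFS", "parent_item"),
    ],
)
def test_invalid_rows_name_the_offence(tmp_path, mutation, message_part):
    text = "item_id,label,stage,category,unit_cost,quantity,tariff_system\n" + mutation + "\n"
    with pytest.raises(CatalogValidationError, match=message_part):
        _catalog_from_csv(tmp_path, text)


def test_missing_column_rejected(tmp_path):
    text = "item_id,label,stage,unit_cost,quantity,tariff_system\nmri,MRI,pre,1,1,FFS\n"
    with pytest.raises(CatalogValidationError, match="category"):
        _catalog_from_csv(tmp_path, text)


def test_duplicate_id_within_system_rejected():
    item = CostItem("x", "x", Stage.PRE, Category.FEE, 1.0, tariff_system=TariffSystem.FFS)
    with pytest.raises(CatalogValidationError, match="duplicate"):
        Catalog(items=(item, item))
    # same id under two systems is the intended way to express dual pricing
    other = CostItem("x", "x", Stage.PRE, Category.FEE, 2.0, tariff_system=TariffSystem.DPC)
    assert len(Catalog(items=(item, other)).items) == 2


def test_premium_with_dangling_parent_rejected(tmp_path):
    text = textwrap.dedent(
        """\
        item_id,label,stage,category,unit_cost,quantity,tariff_system,parent_item
        mri,MRI,pre,imaging,10000,2,FFS,
        prem,premium on ghost,pre,premium,100,2,FFS,ghost
        """
    )
    with pytest.raises(CatalogValidationError, match="ghost"):
        _catalog_from_csv(tmp_path, text)


def test_premium_parent_must_not_be_a_premium():
    a = CostItem("a", "a", Stage.PRE, Category.FEE, 10.0)
    p1 = CostItem("p1", "p1", Stage.PRE, Category.PREMIUM, 1.0, parent_item="a")
    p2 = CostItem("p2", "p2", Stage.PRE, Category.PREMIUM, 1.0, parent_item="p1")
    with pytest.raises(CatalogValidationError, match="non-premium"):
        Catalog(items=(a, p1, p2))


def test_lookup_cost_cases(tmp_path):
    catalog = _catalog_from_csv(
        tmp_path,
        GOOD_CSV + "free,zero-use item,pre,drug,5000,0,drug_tariff\n",
    )
    assert lookup_cost(catalog, "free", "drug_tariff") == 0
    with pytest.raises(CostLookupError, match="FFS"):
        lookup_cost(catalog, "mri", "DPC")  # error lists the available systems
    with pytest.raises(CostLookupError, match="unknown"):
        lookup_cost(catalog, "nope", "FFS")


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_write_load_roundtrip_is_identity(tmp_path, fmt):
    truth = generate_synthetic_catalog(seed=11, n_items=15)
    path = tmp_path / f"cat.{fmt}"
    write_catalog(truth.catalog, path)
    back = load_catalog(path)
    assert back.items == truth.catalog.items
    if fmt == "json":
        assert back.schedules == truth.catalog.schedules
        assert back.currency_year == truth.catalog.currency_year


# ---------------------------------------------------------------------------
# hospitalisation schedules


def test_schedule_validation():
    with pytest.raises(CatalogValidationError, match="contiguous"):
        HospitalisationSchedule(bands=((2, 5, 100.0),))
    with pytest.raises(CatalogValidationError, match="contiguous"):
        HospitalisationSchedule(bands=((1, 3, 100.0), (5, None, 50.0)))
    with pytest.raises(CatalogValidationError, match="fee"):
        HospitalisationSchedule(bands=((1, None, -1.0),))


def test_hospitalisation_cost_basics():
    sched = HospitalisationSchedule(bands=((1, 3, 100.0), (4, None, 250.0)))
    assert hospitalisation_cost(sched, 0) == 0
    assert hospitalisation_cost(sched, 2) == 200
    assert hospitalisation_cost(sched, 5) == 3 * 100 + 2 * 250
    with pytest.raises(DomainError):
        hospitalisation_cost(sched, -1)
    with pytest.raises(DomainError):
        hospitalisation_cost(sched, 2.5)


def test_dbs_stay_marginal_day_costs(fixture):
    """The calibrated stay schedule carries the published marginal day costs:
    extending 8 -> 10 days adds 40,820 and shortening 8 -> 2 removes 102,460."""
    sched = fixture.catalog.schedule("dbs_post_stay", "FFS")
    assert sched.cost(10) - sched.cost(8) == pytest.approx(40_820)
    assert sched.cost(8) - sched.cost(2) == pytest.approx(102_460)


@settings(max_examples=50, deadline=None)
@given(
    fees=st.lists(st.floats(0, 50_000, allow_nan=False), min_size=1, max_size=4),
    breaks=st.lists(st.integers(1, 10), min_size=0, max_size=3),
    days=st.integers(0, 40),
)
def test_schedule_cost_equals_brute_force_day_loop(fees, breaks, days):
    """Banded evaluation agrees with summing the daily fee day by day, so the
    cumulative cost is exactly additive (and hence non-decreasing) in days."""
    edges = sorted(set(breaks))[: len(fees) - 1]
    bands, start = [], 1
    for i, fee in enumerate(fees[: len(edges) + 1]):
        if i < len(edges):
            end = start + edges[i] - 1
            bands.append((start, end, fee))
            start = end + 1
        else:
            bands.append((start, None, fee))
    sched = HospitalisationSchedule(bands=tuple(bands))
    brute = sum(sched.daily_fee(d) for d in range(1, days + 1))
    assert sched.cost(days) == pytest.approx(brute, abs=1e-9)
    assert sched.cost(days) <= sched.cost(days + 1) + 1e-9
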