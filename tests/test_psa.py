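"""Probabilistic sensitivity analysis: moment matching, sampling, testing."""

import numpy as np
import pytest
from scipy import stats

from tremorcma import (
    AnalysisError,
    ConfigurationError,
    DistributionSpec,
    DomainError,
    beta_params,
    compare_psa,
    default_psa_specs,
    gamma_params,
    reference_scenario,
    run_psa,
    run_scenario,
    scenario_parameters,
)
from tremorcma.psa import SummaryStats, perturbed_scenario


def test_gamma_moment_matching_closed_form():
    assert gamma_params(100, 20) == (25.0, 4.0)
    # sd = 20% of mean always gives shape 25
    for mean in (0.5, 1e3, 2.1e6):
        shape, scale = gamma_params(mean, 0.2 * mean)
        assert shape == pytest.approx(25.0)
        assert shape * scale == pytest.approx(mean)
        assert np.sqrt(shape) * scale == pytest.approx(0.2 * mean)
    with pytest.raises(DomainError):
        gamma_params(0, 1)
    with pytest.raises(DomainError):
        gamma_params(1, 0)


def test_beta_moment_matching_closed_form():
    assert beta_params(0.5, 0.1) == (pytest.approx(12.0), pytest.approx(12.0))
    alpha, beta = beta_params(0.0356, 0.00712)
    assert alpha == pytest.approx(24.0744, rel=1e-4)
    assert beta == pytest.approx(652.1725, rel=1e-4)
    # reconstructed moments
    assert alpha / (alpha + beta) == pytest.approx(0.0356)
    with pytest.raises(DomainError, match="mean"):
        beta_params(1.2, 0.1)
    with pytest.raises(DomainError, match="sd"):
        beta_params(0.5, 0.6)  # sd^2 >= mean(1-mean)


@pytest.mark.parametrize(
    "family, mean, sd",
    [("gamma", 2_032_440.0, 0.2 * 2_032_440.0), ("beta", 0.0356, 0.00712)],
)
def test_moment_recovery_at_one_million_draws(family, mean, sd):
    """Sampled mean within 3 standard errors of the target; sd within 1%."""
    rng = np.random.default_rng(12345)
    if family == "gamma":
        shape, scale = gamma_params(mean, sd)
        x = stats.gamma.rvs(a=shape, scale=scale, size=1_000_000, random_state=rng)
    else:
        a, b = beta_params(mean, sd)
        x = stats.beta.rvs(a=a, b=b, size=1_000_000, random_state=rng)
    assert abs(x.mean() - mean) < 3 * sd / 1000
    assert x.std() == pytest.approx(sd, rel=0.01)


def test_all_fixed_specs_reproduce_the_base_case(ffs_scenario):
    base = run_scenario(ffs_scenario)
    specs = [
        DistributionSpec(s.parameter_id, "fixed", s.mean)
        for s in default_psa_specs(ffs_scenario)
    ]
    result = run_psa(ffs_scenario, specs, iterations=10, seed=0)
    for name in result.comparators:
        assert result.samples[name] == pytest.approx(
            np.full(10, base.grand_total(name)), rel=1e-12
        )


def test_seed_determinism(ffs_scenario):
    a = run_psa(ffs_scenario, iterations=200, seed=42)
    b = run_psa(ffs_scenario, iterations=200, seed=42)
    c = run_psa(ffs_scenario, iterations=200, seed=43)
    for name in a.comparators:
        assert np.array_equal(a.samples[name], b.samples[name])  # bit-identical
        assert not np.array_equal(a.samples[name], c.samples[name])


def test_adding_a_parameter_does_not_perturb_other_draws(ffs_scenario):
    """Per-parameter child streams: freezing one parameter leaves every other
    parameter's draws untouched."""
    specs = default_psa_specs(ffs_scenario)
    frozen = [
        DistributionSpec(s.parameter_id, "fixed", s.mean)
        if s.parameter_id == "MRgFUS.pre_workup.unit_cost"
        else s
        for s in specs
    ]
    full = run_psa(ffs_scenario, specs, iterations=100, seed=7)
    partial = run_psa(ffs_scenario, frozen, iterations=100, seed=7)
    # DBS shares no parameter with the frozen one except its own draws,
    # which must be identical under both runs
    assert np.array_equal(
        full.samples["unilateral_DBS"], partial.samples["unilateral_DBS"]
    )


def test_premium_linkage_shares_draws(fixture):
    scenario = reference_scenario("ffs", granularity="item", seed=5, fixture=fixture)
    refs = scenario_parameters(scenario)
    premiums = [r for r in refs if r.kind == "item_quantity" and r.linkage_group
                and r.parameter_id.endswith("__3.quantity")]
    assert premiums, "itemised scenario must contain linked premium quantities"
    result_specs = default_psa_specs(scenario)
    from tremorcma.psa import _draw_samples

    samples = _draw_samples(refs, {s.parameter_id: s for s in result_specs}, 500, 9)
    for prem in premiums:
        parent_id = prem.linkage_group.rsplit(".", 1)[-1]
        parent = next(
            r for r in refs
            if r.kind == "item_quantity"
            and r.parameter_id == f"{prem.procedure}.{parent_id}.quantity"
        )
        x, y = samples[prem.parameter_id], samples[parent.parameter_id]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)
        assert np.array_equal(x, y)  # identical distributions -> identical draws


def test_vectorised_engine_matches_per_iteration_reevaluation(ffs_scenario):
    """Dual route: each PSA iteration equals a deterministic re-evaluation of
    the scenario with that iteration's parameter values substituted in."""
    result = run_psa(ffs_scenario, iterations=5, seed=11)
    refs = scenario_parameters(ffs_scenario)
    specs = {s.parameter_id: s for s in default_psa_specs(ffs_scenario)}
    from tremorcma.psa import _draw_samples

    samples = _draw_samples(refs, specs, 5, 11)
    for i in range(5):
        values = {pid: float(x[i]) for pid, x in samples.items()}
        redone = run_scenario(perturbed_scenario(ffs_scenario, values))
        for name in result.comparators:
            assert result.samples[name][i] == pytest.approx(
                redone.grand_total(name), abs=1e-6
            )


def test_unbiasedness_of_the_sampled_totals(ffs_scenario):
    """Moment matching preserves means and the model is affine in each
    parameter, so the expected PSA total equals the deterministic total."""
    base = run_scenario(ffs_scenario)
    result = run_psa(ffs_scenario, iterations=10_000, seed=2)
    for name in result.comparators:
        x = result.samples[name]
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - base.grand_total(name)) < 3 * se


def test_summary_matches_independent_recomputation(ffs_scenario):
    result = run_psa(ffs_scenario, iterations=500, seed=3)
    for name in result.comparators:
        x = np.sort(result.samples[name])
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lower = min(v for v in x if v >= q1 - 1.5 * iqr)
        upper = max(v for v in x if v <= q3 + 1.5 * iqr)
        s = result.summary[name]
        assert (s.q1, s.median, s.q3) == (pytest.approx(q1), pytest.approx(med),
                                          pytest.approx(q3))
        assert (s.lower_whisker, s.upper_whisker) == (pytest.approx(lower),
                                                      pytest.approx(upper))
        assert s.mean == pytest.approx(x.mean())
        assert 0.0 <= result.fraction_cheaper <= 1.0


def test_compare_identical_samples_gives_t_zero(ffs_scenario):
    result = run_psa(ffs_scenario, iterations=50, seed=1)
    twin = type(result)(
        iterations=result.iterations,
        seed=result.seed,
        samples={n: result.samples["MRgFUS"] for n in result.comparators},
        summary=result.summary,
        comparators=result.comparators,
    )
    report = compare_psa(twin)
    assert report.t_statistic == 0.0
    assert not report.significant


def test_compare_degenerate_samples_is_an_error(ffs_scenario):
    result = run_psa(ffs_scenario, iterations=50, seed=1)
    degenerate = type(result)(
        iterations=result.iterations,
        seed=result.seed,
        samples={
            "MRgFUS": np.zeros(50),
            "unilateral_DBS": result.samples["unilateral_DBS"],
        },
        summary=result.summary,
        comparators=result.comparators,
    )
    with pytest.raises(AnalysisError):
        compare_psa(degenerate)


def test_fixture_psa_is_significant_at_one_percent(ffs_scenario):
    result = run_psa(ffs_scenario, iterations=1000, seed=0)
    report = compare_psa(result, alpha_level=0.01)
    assert report.significant
    assert report.t_p_value < 0.001
    assert result.mean_difference < 0  # MRgFUS cheaper on average


def test_configuration_errors(ffs_scenario):
    with pytest.raises(ConfigurationError, match="iterations"):
        run_psa(ffs_scenario, iterations=1, seed=0)
    specs = default_psa_specs(ffs_scenario)[:-1]  # drop one parameter
    with pytest.raises(ConfigurationError, match="without a distribution"):
        run_psa(ffs_scenario, specs, iterations=10, seed=0)
    bad = default_psa_specs(ffs_scenario) + [
        DistributionSpec("no.such.parameter", "gamma", 10.0)
    ]
    with pytest.raises(ConfigurationError, match="unknown"):
        run_psa(ffs_scenario, bad, iterations=10, seed=0)


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        DistributionSpec("x", "lognormal", 1.0)
    # default sd is 20% of the mean
    spec = DistributionSpec("x", "gamma", 1000.0)
    assert spec.sd == pytest.approx(200.0)
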