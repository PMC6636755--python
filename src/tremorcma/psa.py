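"""Probabilistic sensitivity analysis.

Every sampled model parameter is given a moment-matched distribution —
gamma for costs and quantities, beta for percentages — with the standard
deviation defaulting to 20% of the mean, and all parameters are drawn
simultaneously in a Monte Carlo simulation (1,000 iterations in the study
design).  Conventions:

* moment matching: gamma shape = (mean/sd)^2, scale = sd^2/mean; beta via
  the method of moments (nu = mean(1-mean)/sd^2 - 1);
* premiums' quantities are linked to their parent activity's frequency:
  parameters sharing a ``linkage_group`` share one draw per iteration;
* every simulated patient undergoes exactly one primary procedure:
  per-procedure counts (quantity-1 items) are held fixed, while their
  costs are still sampled;
* one root seed; each parameter (or linkage group) gets its own
  deterministically derived child stream, so adding a parameter does not
  perturb the draws of the others.

The arms are compared with a variance-homogeneity check followed by a
pooled-variance two-tailed t-test (falling back to Welch's unequal-variance
test, with a logged warning, when the variances differ).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .catalog import Category, CostItem, Stage
from .errors import AnalysisError, ConfigurationError, DomainError
from .model import HospitalStay, ProcedureModel, total_cost
from .scenarios import Scenario

__all__ = [
    "DistributionSpec",
    "SummaryStats",
    "PsaResult",
    "TestReport",
    "gamma_params",
    "beta_params",
    "scenario_parameters",
    "default_psa_specs",
    "run_psa",
    "compare_psa",
    "perturbed_scenario",
]

logger = logging.getLogger(__name__)


def gamma_params(mean: float, sd: float) -> Tuple[float, float]:
    """Moment-matched gamma (shape, scale): shape=(mean/sd)^2, scale=sd^2/mean.

    The reconstructed mean (shape x scale) and sd (sqrt(shape) x scale)
    equal the inputs exactly.
    """
    if mean <= 0 or sd <= 0:
        raise DomainError(f"gamma moment matching needs mean > 0 and sd > 0, got "
                          f"mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def beta_params(mean: float, sd: float) -> Tuple[float, float]:
    """Moment-matched beta (alpha, beta): nu = mean(1-mean)/sd^2 - 1."""
    if not 0.0 < mean < 1.0:
        raise DomainError(f"beta moment matching needs 0 < mean < 1, got {mean}")
    if sd <= 0 or sd**2 >= mean * (1.0 - mean):
        raise DomainError(
            f"beta moment matching needs 0 < sd^2 < mean(1-mean) = "
            f"{mean * (1.0 - mean):.6g}, got sd={sd}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one model parameter.

    ``sd=None`` defaults to 20% of the mean.  Parameters sharing a
    ``linkage_group`` receive one underlying draw per iteration (identical
    values when their distributions coincide, comonotone otherwise).
    """

    parameter_id: str
    family: str  # "gamma" | "beta" | "fixed"
    mean: float
    sd: Optional[float] = None
    linkage_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "fixed"):
            raise ConfigurationError(
                f"{self.parameter_id}: unknown family {self.family!r}"
            )
        if self.family != "fixed" and self.sd is None:
            object.__setattr__(self, "sd", 0.2 * self.mean)
        if self.family == "gamma":
            gamma_params(self.mean, self.sd)  # validates
        elif self.family == "beta":
            beta_params(self.mean, self.sd)  # validates

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "fixed":
            return np.full_like(u, self.mean)
        if self.family == "gamma":
            shape, scale = gamma_params(self.mean, self.sd)
            return stats.gamma.ppf(u, a=shape, scale=scale)
        alpha, beta = beta_params(self.mean, self.sd)
        return stats.beta.ppf(u, a=alpha, b=beta)


# ---------------------------------------------------------------------------
# Parameter enumeration


@dataclass(frozen=True)
class ParameterRef:
    """Binding of a parameter id to a location in the scenario."""

    parameter_id: str
    kind: str  # "item_cost" | "item_quantity" | "stay_cost" | "event_probability"
    procedure: str
    index: int  # position in the procedure's items / stays / events
    base_value: float
    default_family: str
    linkage_group: Optional[str] = None


def scenario_parameters(scenario: Scenario) -> List[ParameterRef]:
    """Enumerate the sampleable parameters of a scenario, in a stable order.

    Sampled items contribute a unit-cost parameter (and a quantity parameter
    when quantity != 1 — quantity-1 lines are per-procedure counts held
    fixed); sampled hospital stays contribute their stay cost; every
    downstream event contributes its probability.  Premium quantities are
    linked to their parent activity's quantity parameter.
    """
    refs: List[ParameterRef] = []
    for proc_name in sorted(scenario.procedures):
        proc = scenario.procedures[proc_name]
        qty_sampled = {
            item.item_id
            for item in proc.items
            if item.sampled and item.quantity != 1.0
        }
        for i, item in enumerate(proc.items):
            if not item.sampled:
                continue
            if item.unit_cost > 0:
                refs.append(
                    ParameterRef(
                        parameter_id=f"{proc_name}.{item.item_id}.unit_cost",
                        kind="item_cost",
                        procedure=proc_name,
                        index=i,
                        base_value=item.unit_cost,
                        default_family="gamma",
                    )
                )
            linked = (
                item.category is Category.PREMIUM and item.parent_item in qty_sampled
            )
            if item.quantity != 1.0 and (item.quantity > 0 or linked):
                group = None
                if item.category is Category.PREMIUM and item.parent_item:
                    group = f"{proc_name}.quantity.{item.parent_item}"
                elif item.item_id in {
                    it.parent_item
                    for it in proc.items
                    if it.category is Category.PREMIUM and it.sampled
                }:
                    group = f"{proc_name}.quantity.{item.item_id}"
                refs.append(
                    ParameterRef(
                        parameter_id=f"{proc_name}.{item.item_id}.quantity",
                        kind="item_quantity",
                        procedure=proc_name,
                        index=i,
                        base_value=item.quantity,
                        default_family="gamma",
                        linkage_group=group,
                    )
                )
        for i, stay in enumerate(proc.stays):
            if not stay.sampled:
                continue
            schedule = scenario.schedules[stay.schedule_id]
            base = schedule.cost(stay.days)
            if base > 0:
                refs.append(
                    ParameterRef(
                        parameter_id=f"{proc_name}.{stay.schedule_id}.hospitalisation",
                        kind="stay_cost",
                        procedure=proc_name,
                        index=i,
                        base_value=base,
                        default_family="gamma",
                    )
                )
        for i, event in enumerate(proc.events):
            family = "beta" if 0.0 < event.probability < 1.0 else "fixed"
            refs.append(
                ParameterRef(
                    parameter_id=f"{proc_name}.{event.name}.probability",
                    kind="event_probability",
                    procedure=proc_name,
                    index=i,
                    base_value=event.probability,
                    default_family=family,
                )
            )
    return refs


def default_psa_specs(scenario: Scenario, sd_fraction: float = 0.2) -> List[DistributionSpec]:
    """Moment-matched specs for every scenario parameter (sd = 20% of mean)."""
    return [
        DistributionSpec(
            parameter_id=ref.parameter_id,
            family=ref.default_family,
            mean=ref.base_value,
            sd=None if ref.default_family == "fixed" else sd_fraction * ref.base_value,
            linkage_group=ref.linkage_group,
        )
        for ref in scenario_parameters(scenario)
    ]


# ---------------------------------------------------------------------------
# Sampling and evaluation


def _child_rng(seed: int, key: str) -> np.random.Generator:
    # one deterministic child stream per parameter / linkage group
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), zlib.crc32(key.encode())]))
    )


def _draw_samples(
    refs: Sequence[ParameterRef],
    specs: Mapping[str, DistributionSpec],
    iterations: int,
    seed: int,
) -> Dict[str, np.ndarray]:
    group_uniforms: Dict[str, np.ndarray] = {}
    samples: Dict[str, np.ndarray] = {}
    for ref in refs:
        spec = specs[ref.parameter_id]
        group = spec.linkage_group
        if group is not None:
            if group not in group_uniforms:
                group_uniforms[group] = _child_rng(seed, f"group:{group}").uniform(
                    size=iterations
                )
            u = group_uniforms[group]
        else:
            u = _child_rng(seed, f"param:{ref.parameter_id}").uniform(size=iterations)
        samples[ref.parameter_id] = spec.ppf(u)
    return samples


def _procedure_totals(
    scenario: Scenario,
    refs: Sequence[ParameterRef],
    samples: Mapping[str, np.ndarray],
    iterations: int,
) -> Dict[str, np.ndarray]:
    """Vectorised per-iteration totals, mirroring model.total_cost exactly."""
    by_loc: Dict[Tuple[str, str, int], np.ndarray] = {
        (r.kind, r.procedure, r.index): samples[r.parameter_id] for r in refs
    }

    def const(v: float) -> np.ndarray:
        return np.full(iterations, float(v))

    def medical(proc: ProcedureModel) -> np.ndarray:
        total = np.zeros(iterations)
        for i, item in enumerate(proc.items):
            cost = by_loc.get(("item_cost", proc.name, i), const(item.unit_cost))
            qty = by_loc.get(("item_quantity", proc.name, i), const(item.quantity))
            total += cost * qty
        for i, stay in enumerate(proc.stays):
            base = scenario.schedules[stay.schedule_id].cost(stay.days)
            total += by_loc.get(("stay_cost", proc.name, i), const(base))
        return total

    totals: Dict[str, np.ndarray] = {}
    # referenced (event-free) procedures first, then the comparators
    for name in sorted(scenario.procedures, key=lambda n: bool(scenario.procedures[n].events)):
        proc = scenario.procedures[name]
        total = medical(proc)
        for i, event in enumerate(proc.events):
            p = by_loc.get(("event_probability", name, i), const(event.probability))
            total = total + p * totals[event.referenced_procedure]
        totals[name] = total
    return totals


@dataclass(frozen=True)
class SummaryStats:
    """Box-and-whisker summary: quartiles plus Tukey 1.5 x IQR whiskers."""

    mean: float
    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "SummaryStats":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lower = float(x[x >= q1 - 1.5 * iqr].min())
        upper = float(x[x <= q3 + 1.5 * iqr].max())
        return cls(
            mean=float(x.mean()),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            lower_whisker=lower,
            upper_whisker=upper,
        )


@dataclass(frozen=True)
class PsaResult:
    iterations: int
    seed: int
    samples: Mapping[str, np.ndarray]  # comparator -> per-iteration grand totals
    summary: Mapping[str, SummaryStats]
    comparators: Tuple[str, str]

    @property
    def mean_difference(self) -> float:
        """Mean of per-iteration (MRgFUS - DBS); negative means MRgFUS saves."""
        a, b = self.comparators
        return float((self.samples[a] - self.samples[b]).mean())

    @property
    def fraction_cheaper(self) -> float:
        """Fraction of iterations in which MRgFUS is the cheaper arm."""
        a, b = self.comparators
        return float((self.samples[a] < self.samples[b]).mean())


def run_psa(
    scenario: Scenario,
    specs: Optional[Sequence[DistributionSpec]] = None,
    iterations: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty through the scenario.

    Every sampled parameter is drawn once per iteration (linked parameters
    share draws) and the scenario is re-evaluated; labour costs, when the
    scenario includes them, are added as deterministic constants (the
    probabilistic parameters are the base-case medical inputs).  Results are
    bit-reproducible for a given seed.
    """
    if iterations < 2:
        raise ConfigurationError(f"PSA needs at least 2 iterations, got {iterations}")
    refs = scenario_parameters(scenario)
    if specs is None:
        specs = default_psa_specs(scenario)
    spec_map = {s.parameter_id: s for s in specs}
    known = {r.parameter_id for r in refs}
    uncovered = [r.parameter_id for r in refs if r.parameter_id not in spec_map]
    if uncovered:
        raise ConfigurationError(
            f"parameters without a distribution spec (declare them 'fixed' to "
            f"exempt them): {uncovered}"
        )
    unknown = sorted(set(spec_map) - known)
    if unknown:
        raise ConfigurationError(f"specs refer to unknown parameters: {unknown}")

    samples = _draw_samples(refs, spec_map, iterations, seed)
    totals = _procedure_totals(scenario, refs, samples, iterations)
    arm_samples = {}
    for name in scenario.comparators:
        arm = totals[name]
        if scenario.config.labour_year is not None:
            arm = arm + scenario.labour_cost(name)
        arm_samples[name] = arm
    summary = {name: SummaryStats.from_samples(x) for name, x in arm_samples.items()}
    return PsaResult(
        iterations=iterations,
        seed=seed,
        samples=arm_samples,
        summary=summary,
        comparators=scenario.comparators,
    )


def perturbed_scenario(scenario: Scenario, values: Mapping[str, float]) -> Scenario:
    """Scenario with sampled parameter values substituted in.

    The deterministic cross-check for the vectorised PSA engine: evaluating
    ``run_scenario`` on the perturbed scenario must reproduce one PSA
    iteration exactly.  Stay costs are substituted as fixed post-stage cost
    lines (the day schedule no longer applies once the stay cost itself is
    the sampled parameter).
    """
    refs = {r.parameter_id: r for r in scenario_parameters(scenario)}
    unknown = sorted(set(values) - set(refs))
    if unknown:
        raise ConfigurationError(f"unknown parameters: {unknown}")
    procedures = {name: proc for name, proc in scenario.procedures.items()}
    for pid, value in values.items():
        ref = refs[pid]
        proc = procedures[ref.procedure]
        if ref.kind == "item_cost":
            items = list(proc.items)
            items[ref.index] = replace(items[ref.index], unit_cost=float(value))
            proc = replace(proc, items=tuple(items))
        elif ref.kind == "item_quantity":
            items = list(proc.items)
            items[ref.index] = replace(items[ref.index], quantity=float(value))
            proc = replace(proc, items=tuple(items))
        elif ref.kind == "stay_cost":
            stay = proc.stays[ref.index]
            stays = tuple(s for j, s in enumerate(proc.stays) if j != ref.index)
            extra = CostItem(
                item_id=f"__stay__{stay.schedule_id}",
                label=f"sampled stay cost ({stay.schedule_id})",
                stage=stay.stage,
                category=Category.HOSPITALISATION,
                unit_cost=float(value),
                quantity=1.0,
            )
            proc = replace(proc, stays=stays, items=proc.items + (extra,))
        elif ref.kind == "event_probability":
            events = list(proc.events)
            events[ref.index] = replace(events[ref.index], probability=float(value))
            proc = replace(proc, events=tuple(events))
        procedures[ref.procedure] = proc
    return replace(scenario, procedures=procedures)


@dataclass(frozen=True)
class TestReport:
    variance_check_p: float
    equal_variance_assumed: bool
    t_statistic: float
    t_p_value: float
    alpha_level: float

    @property
    def significant(self) -> bool:
        return self.t_p_value < self.alpha_level


def compare_psa(result: PsaResult, alpha_level: float = 0.01) -> TestReport:
    """Variance-homogeneity check, then a two-tailed t-test on the two arms.

    When the variance check (Levene) does not reject equality at the 5%
    level, a pooled-variance t-test is used; otherwise the analysis falls
    back to Welch's unequal-variance t-test and logs a warning.
    """
    a, b = result.comparators
    x, y = np.asarray(result.samples[a]), np.asarray(result.samples[b])
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("need at least 2 samples per arm")
    if np.var(x) == 0 or np.var(y) == 0:
        if np.array_equal(x, y):
            # identical degenerate samples: no difference by construction
            return TestReport(
                variance_check_p=1.0,
                equal_variance_assumed=True,
                t_statistic=0.0,
                t_p_value=1.0,
                alpha_level=alpha_level,
            )
        raise AnalysisError("zero-variance samples: the t-test is undefined")
    if np.array_equal(x, y):
        return TestReport(
            variance_check_p=1.0,
            equal_variance_assumed=True,
            t_statistic=0.0,
            t_p_value=1.0,
            alpha_level=alpha_level,
        )
    _, var_p = stats.levene(x, y)
    equal = bool(var_p > 0.05)
    if not equal:
        logger.warning(
            "variance-homogeneity check rejected equality (p=%.3g); "
            "falling back to Welch's unequal-variance t-test",
            var_p,
        )
    t_stat, t_p = stats.ttest_ind(x, y, equal_var=equal)
    return TestReport(
        variance_check_p=float(var_p),
        equal_variance_assumed=equal,
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        alpha_level=alpha_level,
    )
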