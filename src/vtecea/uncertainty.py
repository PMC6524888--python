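"""Probabilistic and univariate sensitivity analysis.

Parameter uncertainty propagates through the model by Monte Carlo: every
uncertain input is assigned a parametric distribution matched to its point
estimate and 95% CI (beta for probabilities, gamma or lognormal for ratios,
a joint Dirichlet for the recurrent-event split), all inputs are redrawn
jointly per iteration, and the two strategy arms are re-evaluated with the
shared draw.  The resulting incremental cost/effect cloud yields the
cost-effectiveness plane and the acceptability curve (CEAC).  One-way
(tornado) analysis re-runs the deterministic model at each parameter's CI
bounds.

The CI is converted to a standard error by the normal approximation
(width / 3.92); when no CI exists a 30% coefficient of variation is used.
Distribution parameters then follow by moment matching.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import Perspective, evaluate_arm, icer
from .engine import ArmSpec, LifeTable, run_cohort
from .parameters import (
    ARMS, CumulativeIncidenceCurve, HazardRatioEstimate, ParameterError,
    ParameterSet, ProbabilityEstimate,
)

logger = logging.getLogger("vtecea")

Z95 = 3.92            # CI width in SEs under the normal approximation
FALLBACK_CV = 0.30    # coefficient of variation when no CI is given
#: effective sample size behind the recurrent-event split proportions
#: (the printed proportions are exactly 12/101, 25/101, 64/101)
DIRICHLET_ESS = 101.0


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one model input."""

    family: str                    # beta | gamma | lognormal | dirichlet | fixed
    params: tuple[float, ...]
    mean: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            a, b = self.params
            return float(rng.beta(a, b))
        if self.family == "gamma":
            shape, scale = self.params
            return float(rng.gamma(shape, scale))
        if self.family == "lognormal":
            mu, sigma = self.params
            return float(rng.lognormal(mu, sigma))
        raise ParameterError(f"cannot sample family {self.family!r}")


def _se_from_ci(mean: float, ci_low: float, ci_high: float) -> float:
    width = ci_high - ci_low
    if width <= 0:
        return 0.0
    return width / Z95


def fit_distribution(
    est: ProbabilityEstimate | HazardRatioEstimate,
) -> DistributionSpec:
    """Fit the declared distribution family by moment matching.

    Beta parameters come from the method of moments on (mean, SE); gamma
    and lognormal match mean and SE exactly.  A zero-width CI, a "fixed"
    family, or a degenerate mean yields a degenerate spec.  Dirichlet
    components are fitted jointly in :func:`fit_dirichlet`.
    """
    mean = est.mean
    family = est.distribution_family
    se = _se_from_ci(mean, est.ci_low, est.ci_high)
    if se == 0.0 and family != "fixed":
        se = FALLBACK_CV * mean
    if family == "fixed" or se == 0.0:
        return DistributionSpec("fixed", (), mean)

    if family == "beta":
        if not 0 < mean < 1:
            return DistributionSpec("fixed", (), mean)
        bound = mean * (1 - mean)
        if se * se >= bound:
            raise ParameterError(
                f"implied variance {se*se:.3g} infeasible for a beta with "
                f"mean {mean}"
            )
        nu = bound / (se * se) - 1.0
        spec = DistributionSpec("beta", (mean * nu, (1 - mean) * nu), mean)
    elif family == "gamma":
        shape = (mean / se) ** 2
        scale = se * se / mean
        spec = DistributionSpec("gamma", (shape, scale), mean)
    elif family == "lognormal":
        sigma2 = math.log1p((se / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        spec = DistributionSpec("lognormal", (mu, math.sqrt(sigma2)), mean)
    elif family == "dirichlet_component":
        # marginally a beta with the split's common effective sample size
        spec = DistributionSpec(
            "beta",
            (mean * DIRICHLET_ESS, (1 - mean) * DIRICHLET_ESS),
            mean,
        )
    else:
        raise ParameterError(f"no fitting rule for family {family!r}")

    fitted_mean = _spec_mean(spec)
    if abs(fitted_mean - mean) > 0.01 * max(mean, 1e-12):
        raise ParameterError(
            f"fitted mean {fitted_mean} deviates >1% from input {mean}"
        )
    return spec


def _spec_mean(spec: DistributionSpec) -> float:
    if spec.family == "fixed":
        return spec.mean
    if spec.family == "beta":
        a, b = spec.params
        return a / (a + b)
    if spec.family == "gamma":
        shape, scale = spec.params
        return shape * scale
    if spec.family == "lognormal":
        mu, sigma = spec.params
        return math.exp(mu + sigma * sigma / 2.0)
    raise ParameterError(spec.family)


def fit_dirichlet(
    components: dict[str, ProbabilityEstimate], ess: float = DIRICHLET_ESS
) -> tuple[list[str], np.ndarray]:
    """Joint Dirichlet over the event-split proportions (common ESS)."""
    names = list(components)
    alphas = np.array([components[n].mean for n in names]) * ess
    return names, alphas


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_parameter_set(
    base: ParameterSet, seed: int, max_redraws: int = 100
) -> ParameterSet:
    """Draw one full parameter set; reproducible given the seed.

    All uncertain entries are drawn independently except the event split,
    which is drawn jointly from its Dirichlet.  Invalid draws (probability
    CIs are respected by family support, but e.g. a post-cessation curve
    losing monotonicity) are redrawn with a logged count.
    """
    rng = np.random.default_rng(seed)
    redraws = 0
    for _ in range(max_redraws):
        try:
            sampled = _draw_once(base, rng)
            if redraws:
                logger.info("parameter draw required %d redraws", redraws)
            return sampled
        except ParameterError:
            redraws += 1
    raise ParameterError(f"no valid parameter draw after {max_redraws} attempts")


def _draw_once(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    def draw(est):
        return fit_distribution(est).sample(rng)

    def prob(est, value):
        if est.distribution_family == "fixed":
            return est
        value = min(max(value, 0.0), 0.999999)
        return dataclasses.replace(
            est, mean=value, ci_low=min(est.ci_low, value),
            ci_high=max(est.ci_high, value),
        )

    def ratio(est, value):
        if est.distribution_family == "fixed":
            return est
        return dataclasses.replace(
            est, mean=value, ci_low=min(est.ci_low, value),
            ci_high=max(est.ci_high, value),
        )

    recurrence = {
        arm: tuple(prob(e, draw(e)) for e in base.recurrence[arm]) for arm in ARMS
    }
    names, alphas = fit_dirichlet(base.event_split)
    split_draw = rng.dirichlet(alphas)
    event_split = {
        name: dataclasses.replace(
            base.event_split[name], mean=float(value),
            ci_low=min(base.event_split[name].ci_low, float(value)),
            ci_high=max(base.event_split[name].ci_high, float(value)),
        )
        for name, value in zip(names, split_draw)
    }
    knots_drawn = tuple(
        prob(e, draw(e)) for e in base.post_cessation_estimates
    )
    times = [t for t, _ in base.post_cessation.knots[1:]]
    curve = CumulativeIncidenceCurve(
        tuple([(0.0, 0.0)] + [(t, e.mean) for t, e in zip(times, knots_drawn)])
    )
    return base.with_overrides(
        recurrence=recurrence,
        event_split=event_split,
        mb_risk={arm: prob(e, draw(e)) for arm, e in base.mb_risk.items()},
        crnmb_risk={arm: prob(e, draw(e)) for arm, e in base.crnmb_risk.items()},
        fatal_mb_fraction=prob(base.fatal_mb_fraction, draw(base.fatal_mb_fraction)),
        nonfatal_ic_fraction=prob(
            base.nonfatal_ic_fraction, draw(base.nonfatal_ic_fraction)
        ),
        bleeding_age_factor=ratio(
            base.bleeding_age_factor, draw(base.bleeding_age_factor)
        ),
        interruption_mb=prob(base.interruption_mb, draw(base.interruption_mb)),
        interruption_crnmb=prob(
            base.interruption_crnmb, draw(base.interruption_crnmb)
        ),
        other_discontinuation=prob(
            base.other_discontinuation, draw(base.other_discontinuation)
        ),
        cteph_annual=prob(base.cteph_annual, draw(base.cteph_annual)),
        pts_5yr=prob(base.pts_5yr, draw(base.pts_5yr)),
        mortality_hr={
            name: ratio(e, draw(e)) for name, e in base.mortality_hr.items()
        },
        post_cessation=curve,
        post_cessation_estimates=knots_drawn,
    )


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Paired incremental draws from the probabilistic analysis."""

    delta_costs: np.ndarray
    delta_effects: np.ndarray
    master_seed: int
    n_redrawn: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.delta_costs)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_costs, "delta_effect": self.delta_effects}
        )


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float
    icer_base: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Stable per-iteration seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(iteration)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_psa(
    arms: tuple[ArmSpec, ArmSpec],
    base: ParameterSet,
    life_table: LifeTable,
    n: int = 2000,
    master_seed: int = 0,
    perspective: Perspective = Perspective.SOCIETAL,
) -> PSAResult:
    """Probabilistic sensitivity analysis over n joint parameter draws.

    Both arms share each iteration's sampled parameter set.  Iteration i is
    reproducible in isolation through :func:`iteration_seed`.
    """
    if n < 1:
        raise ParameterError("need at least one iteration")
    new_arm, ref_arm = arms
    d_costs = np.empty(n)
    d_effects = np.empty(n)
    redrawn = 0
    for i in range(n):
        drawn = sample_parameter_set(base, iteration_seed(master_seed, i))
        results = {}
        for spec in (new_arm, ref_arm):
            trace = run_cohort(spec, drawn, life_table)
            cost, effect = evaluate_arm(trace, drawn, perspective)
            results[spec.arm] = (cost.total, effect.qalys)
        d_costs[i] = results[new_arm.arm][0] - results[ref_arm.arm][0]
        d_effects[i] = results[new_arm.arm][1] - results[ref_arm.arm][1]
    return PSAResult(d_costs, d_effects, master_seed, redrawn)


def ceac(result: PSAResult, thresholds: list[float]) -> list[CEACPoint]:
    """Probability of positive net monetary benefit at each threshold."""
    if result.n_iterations == 0:
        raise ParameterError("empty PSA result")
    points = []
    for wtp in thresholds:
        nmb = wtp * result.delta_effects - result.delta_costs
        points.append(CEACPoint(wtp, float((nmb >= 0).mean())))
    return points


# ---------------------------------------------------------------------------
# Univariate (tornado) analysis
# ---------------------------------------------------------------------------

def _deterministic_icer(
    arms: tuple[ArmSpec, ArmSpec],
    params: ParameterSet,
    life_table: LifeTable,
    perspective: Perspective,
) -> float:
    new_arm, ref_arm = arms
    outs = {}
    for spec in (new_arm, ref_arm):
        trace = run_cohort(spec, params, life_table)
        cost, effect = evaluate_arm(trace, params, perspective)
        outs[spec.arm] = (cost.total, effect.qalys)
    res = icer(
        outs[new_arm.arm][0], outs[ref_arm.arm][0],
        outs[new_arm.arm][1], outs[ref_arm.arm][1],
    )
    return float("nan") if res.icer is None else res.icer


def _override_parameter(base: ParameterSet, name: str, value: float) -> ParameterSet:
    """Set one dotted-name uncertain parameter to a fixed value."""
    parts = name.split(".")
    top = parts[0]

    def set_prob(est: ProbabilityEstimate, v: float) -> ProbabilityEstimate:
        v = min(max(v, 0.0), 0.999999)
        return dataclasses.replace(
            est, mean=v, ci_low=min(est.ci_low, v), ci_high=max(est.ci_high, v)
        )

    def set_ratio(est: HazardRatioEstimate, v: float) -> HazardRatioEstimate:
        return dataclasses.replace(
            est, mean=v, ci_low=min(est.ci_low, v), ci_high=max(est.ci_high, v)
        )

    if top == "recurrence":
        arm, interval = parts[1], parts[2]
        from .parameters import RECURRENCE_INTERVALS
        idx = RECURRENCE_INTERVALS.index(interval)
        rows = list(base.recurrence[arm])
        rows[idx] = set_prob(rows[idx], value)
        return base.with_overrides(
            recurrence={**base.recurrence, arm: tuple(rows)}
        )
    if top in ("mb_risk", "crnmb_risk"):
        arm = parts[1]
        block = dict(getattr(base, top))
        block[arm] = set_prob(block[arm], value)
        return base.with_overrides(**{top: block})
    if top == "event_split":
        # renormalise the other components to keep the simplex constraint
        name_ = parts[1]
        split = dict(base.event_split)
        others = [k for k in split if k != name_]
        rest = 1.0 - value
        old_rest = sum(split[k].mean for k in others)
        new_split = {name_: set_prob(split[name_], value)}
        for k in others:
            new_split[k] = set_prob(split[k], split[k].mean * rest / old_rest)
        return base.with_overrides(event_split=new_split)
    if top == "mortality_hr":
        block = dict(base.mortality_hr)
        block[parts[1]] = set_ratio(block[parts[1]], value)
        return base.with_overrides(mortality_hr=block)
    if top == "post_cessation":
        idx = int(parts[1].removeprefix("knot")) - 1
        knots = list(base.post_cessation_estimates)
        knots[idx] = set_prob(knots[idx], value)
        times = [t for t, _ in base.post_cessation.knots[1:]]
        curve = CumulativeIncidenceCurve(
            tuple([(0.0, 0.0)] + [(t, e.mean) for t, e in zip(times, knots)])
        )
        return base.with_overrides(
            post_cessation=curve, post_cessation_estimates=tuple(knots)
        )
    if top == "bleeding_age_factor":
        return base.with_overrides(
            bleeding_age_factor=set_ratio(base.bleeding_age_factor, value)
        )
    if top in (
        "fatal_mb_fraction", "nonfatal_ic_fraction", "interruption_mb",
        "interruption_crnmb", "other_discontinuation", "cteph_annual",
        "pts_5yr",
    ):
        return base.with_overrides(**{top: set_prob(getattr(base, top), value)})
    if top == "costs":
        # e.g. costs.drug_per_day.apixaban_extended
        group, key = parts[1], parts[2]
        registry = base.costs
        block = dict(getattr(registry, group))
        block[key] = max(value, 0.0)
        return base.with_overrides(
            costs=dataclasses.replace(registry, **{group: block})
        )
    if top == "utilities" and parts[1] == "baseline":
        return base.with_overrides(
            utilities=dataclasses.replace(
                base.utilities, baseline=min(max(value, 0.0), 1.0)
            )
        )
    raise ParameterError(f"unknown parameter name {name!r}")


def parameter_bounds(base: ParameterSet) -> dict[str, tuple[float, float]]:
    """Default sweep bounds: the 95% CI of every uncertain transition input
    plus a 30%-CV normal band for drug unit cost and baseline utility."""
    bounds = {
        name: (est.ci_low, est.ci_high)
        for name, est in base.iter_uncertain()
        if est.ci_high > est.ci_low
    }
    drug = base.costs.drug_per_day["apixaban_extended"]
    half = 1.96 * FALLBACK_CV * drug
    bounds["costs.drug_per_day.apixaban_extended"] = (
        max(drug - half, 0.0), drug + half
    )
    u = base.utilities.baseline
    half_u = 1.96 * FALLBACK_CV * u
    bounds["utilities.baseline"] = (max(u - half_u, 0.0), min(u + half_u, 1.0))
    return bounds


def univariate_sweep(
    arms: tuple[ArmSpec, ArmSpec],
    base: ParameterSet,
    life_table: LifeTable,
    bounds: dict[str, tuple[float, float]] | None = None,
    perspective: Perspective = Perspective.SOCIETAL,
) -> list[TornadoEntry]:
    """One-way sweeps of each parameter over its bounds, sorted by impact."""
    bounds = parameter_bounds(base) if bounds is None else bounds
    base_icer = _deterministic_icer(arms, base, life_table, perspective)
    entries = []
    for name, (low, high) in bounds.items():
        icer_low = _deterministic_icer(
            arms, _override_parameter(base, name, low), life_table, perspective
        )
        icer_high = _deterministic_icer(
            arms, _override_parameter(base, name, high), life_table, perspective
        )
        entries.append(TornadoEntry(name, icer_low, icer_high, base_icer))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries
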