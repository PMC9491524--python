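"""Monte-Carlo cost-effectiveness engine: iterations, ICERs, scenarios.

Each iteration makes one joint draw of the uncertain inputs — campaign
effects (lognormal on the pooled magnitude), wave durations (Pert) and cost
items (gamma/Pert) — and propagates it through the energy/weight model and
the multi-state lifetable.  Iterations use counter-based substreams
(``default_rng([master_seed, index])``) so results are reproducible and
scenarios can be compared on paired draws.  Summaries follow standard CEA
reporting: means, percentile 95% uncertainty intervals, dominance shares,
the proportion cost-effective at a willingness-to-pay threshold, and the
cost-effectiveness plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import costing, effect_meta, energy_weight
from .costing import CostItem, total_intervention_cost, default_cost_items
from .effect_meta import EffectEstimate, MetaResult, fixed_effects_pool, significant
from .energy_weight import (DEFAULT_SERVE_DEFS, EnergyModelParams, airing_weeks,
                            effect_draws_to_energy, energy_to_weight,
                            weight_to_bmi)
from .mslt import LifetableModel
from .synthetic_data import (DiseaseEpiBundle, PopulationBundle,
                             generate_disease_epi, generate_population)

__all__ = [
    "ScenarioConfig",
    "PipelineInputs",
    "IterationResult",
    "CEAResult",
    "ICER",
    "icer",
    "proportion_cost_effective",
    "run_iteration",
    "run_monte_carlo",
    "run_scenarios",
    "default_inputs",
    "default_scenarios",
    "campaign_effect_estimates",
    "pooled_effects",
]

#: default Pert spec (min, mode, max weeks) for the duration of one wave
WAVE_WEEKS_PERT = (3.0, 7.5, 13.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis configuration (base case or a sensitivity scenario)."""

    name: str = "base"
    age_range: tuple[int, int] = (25, 49)
    n_waves: int = 3
    horizon_years: int | None = None  # None = lifetime (to age 100)
    discount_rate: float = 0.07
    effect_age_scaling: pd.DataFrame | None = None
    threshold: float = 65_000.0

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years is not None and self.horizon_years < 1:
            raise ValueError("horizon must be >= 1 year")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")


@dataclass
class PipelineInputs:
    """Everything a scenario run needs, already in memory."""

    population: PopulationBundle
    diseases: DiseaseEpiBundle
    meta_results: list[MetaResult]
    serve_defs: dict = field(default_factory=lambda: dict(DEFAULT_SERVE_DEFS))
    energy_params: EnergyModelParams = field(default_factory=EnergyModelParams)
    cost_items: list[CostItem] = field(default_factory=default_cost_items)
    wave_weeks_pert: tuple = WAVE_WEEKS_PERT

    @property
    def significant_effects(self) -> list[MetaResult]:
        """Only pooled effects whose 95% CI excludes zero feed the model."""
        return [m for m in self.meta_results if significant(m)]


@dataclass(frozen=True)
class ICER:
    """ICER classification: dominant / dominated / ratio / indeterminate."""

    kind: str
    value: float | None = None

    def __str__(self):
        if self.kind == "ratio":
            return f"{self.value:,.0f}"
        return self.kind.capitalize()


def icer(net_cost: float, halys: float) -> ICER:
    """Classify an (incremental net cost, incremental HALY) pair.

    Dominant: saves money and gains health.  Dominated: costs money and
    loses health.  Otherwise the ratio net_cost/halys is reported; a zero
    HALY denominator yields a signed-infinity ratio with a warning.
    """
    if halys == 0:
        if net_cost == 0:
            warnings.warn("0/0 ICER is indeterminate", RuntimeWarning, stacklevel=2)
            return ICER("indeterminate")
        warnings.warn("zero HALY denominator in ICER", RuntimeWarning, stacklevel=2)
        return ICER("ratio", np.inf if net_cost > 0 else -np.inf)
    if net_cost < 0 and halys > 0:
        return ICER("dominant")
    if net_cost > 0 and halys < 0:
        return ICER("dominated")
    return ICER("ratio", net_cost / halys)


@dataclass(frozen=True)
class IterationResult:
    index: int
    intervention_cost: float
    healthcare_cost_diff: float
    halys: float
    icer_class: ICER

    @property
    def net_cost(self) -> float:
        return self.intervention_cost + self.healthcare_cost_diff


@dataclass
class CEAResult:
    """Monte-Carlo summary for one scenario."""

    scenario: str
    n_iterations: int
    summary: pd.DataFrame = field(repr=False)  # mean/ui_lower/ui_upper per field
    icer_mean: ICER = field(default=None)      # ratio of mean net cost to mean HALYs
    icer_ui: tuple = ("", "")                  # labels per the dominant-ordering convention
    proportion_dominant: float = 0.0
    proportion_cost_effective: float = 0.0
    ce_plane: pd.DataFrame = field(default=None, repr=False)
    iterations: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        out = {"scenario": self.scenario, "n_iterations": self.n_iterations,
               "proportion_dominant": self.proportion_dominant,
               "proportion_cost_effective": self.proportion_cost_effective,
               "icer_mean": str(self.icer_mean),
               "icer_ui": [str(x) for x in self.icer_ui]}
        for row in self.summary.itertuples():
            out[row.Index] = {"mean": row.mean, "ui_lower": row.ui_lower,
                              "ui_upper": row.ui_upper}
        return out


def proportion_cost_effective(iterations: list[IterationResult],
                              threshold: float) -> float:
    """Share of iterations dominant or with an ICER ratio below threshold."""
    if not iterations:
        raise ValueError("need at least one iteration")
    ok = sum(1 for it in iterations
             if it.icer_class.kind == "dominant"
             or (it.icer_class.kind == "ratio" and it.icer_class.value < threshold))
    return ok / len(iterations)


def _scaled_energy(delta_e: float, scenario: ScenarioConfig):
    """Apply a per-age effect-scaling table (scale 1 where not covered)."""
    tab = scenario.effect_age_scaling
    if tab is None:
        return delta_e
    lo, hi = scenario.age_range
    ages = np.arange(lo, hi + 1)
    scale = np.ones_like(ages, dtype=float)
    for row in tab.itertuples():
        scale[(ages >= row.age_low) & (ages <= row.age_high)] = row.scale
    return pd.Series(delta_e * scale, index=ages)


def run_iteration(inputs: PipelineInputs, scenario: ScenarioConfig,
                  rng: np.random.Generator, model: LifetableModel | None = None,
                  index: int = 0, deterministic: bool = False) -> IterationResult:
    """One joint draw propagated through the whole pipeline.

    ``deterministic`` collapses every distribution to its point value
    (pooled means, mean wave duration, mean costs), which reproduces the
    deterministic pipeline run exactly.
    """
    if model is None:
        model = LifetableModel(inputs.population, inputs.diseases,
                               age_range=scenario.age_range,
                               horizon_years=scenario.horizon_years,
                               discount_rate=scenario.discount_rate)
    effects = inputs.significant_effects
    if deterministic:
        changes = {m.food_category: m.pooled_change for m in effects}
        weeks = airing_weeks(scenario.n_waves, inputs.wave_weeks_pert)
        cost = total_intervention_cost(inputs.cost_items, scenario.n_waves)
    else:
        changes = {m.food_category: float(effect_meta.draw_effect(m, rng))
                   for m in effects}
        weeks = airing_weeks(scenario.n_waves, inputs.wave_weeks_pert, rng)
        cost = total_intervention_cost(inputs.cost_items, scenario.n_waves, rng)

    delta_e = effect_draws_to_energy(changes, inputs.serve_defs)
    delta_e = _scaled_energy(delta_e, scenario)
    delta_w = energy_to_weight(delta_e, weeks, inputs.energy_params)
    shift = weight_to_bmi(delta_w, inputs.population, ages=scenario.age_range)
    out = model.run(shift)
    return IterationResult(
        index=index,
        intervention_cost=cost.total,
        healthcare_cost_diff=out.healthcare_cost_difference,
        halys=out.halys_gained,
        icer_class=icer(cost.total + out.healthcare_cost_difference,
                        out.halys_gained),
    )


def _percentile(x: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (order statistic ceil(q n / 100)).

    Interpolation-free, so it is well defined for the ICER ordering keys
    (which place dominant iterations at -inf) and returns the min/max of
    two draws at (2.5, 97.5).
    """
    xs = np.sort(np.asarray(x))
    rank = max(1, int(np.ceil(q / 100.0 * xs.size)))
    return float(xs[rank - 1])


def _icer_sort_key(it: IterationResult) -> float:
    """Ordering for ICER percentiles: dominant below any positive ratio."""
    if it.icer_class.kind == "dominant":
        return -np.inf
    if it.icer_class.kind == "ratio":
        return it.icer_class.value
    return np.inf  # dominated / indeterminate sort above everything


def run_monte_carlo(inputs: PipelineInputs, scenario: ScenarioConfig,
                    n: int = 2000, seed: int = 0) -> CEAResult:
    """n iterations with independent substreams from one master seed."""
    if n < 2:
        raise ValueError("need n >= 2 iterations")
    model = LifetableModel(inputs.population, inputs.diseases,
                           age_range=scenario.age_range,
                           horizon_years=scenario.horizon_years,
                           discount_rate=scenario.discount_rate)
    model.baseline()
    iters = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        iters.append(run_iteration(inputs, scenario, rng, model=model, index=i))

    fields = {
        "intervention_cost": np.array([it.intervention_cost for it in iters]),
        "healthcare_cost_diff": np.array([it.healthcare_cost_diff for it in iters]),
        "net_cost": np.array([it.net_cost for it in iters]),
        "halys": np.array([it.halys for it in iters]),
    }
    summary = pd.DataFrame({
        "mean": {k: v.mean() for k, v in fields.items()},
        "ui_lower": {k: _percentile(v, 2.5) for k, v in fields.items()},
        "ui_upper": {k: _percentile(v, 97.5) for k, v in fields.items()},
    })
    keys = np.array([_icer_sort_key(it) for it in iters])
    ui = []
    for q in (2.5, 97.5):
        val = _percentile(keys, q)
        ui.append(ICER("dominant") if val == -np.inf else ICER("ratio", float(val)))
    return CEAResult(
        scenario=scenario.name,
        n_iterations=n,
        summary=summary,
        icer_mean=icer(float(fields["net_cost"].mean()), float(fields["halys"].mean())),
        icer_ui=tuple(ui),
        proportion_dominant=float(np.mean(
            [it.icer_class.kind == "dominant" for it in iters])),
        proportion_cost_effective=proportion_cost_effective(iters, scenario.threshold),
        ce_plane=pd.DataFrame({"halys": fields["halys"],
                               "net_cost": fields["net_cost"]}),
        iterations=iters,
    )


def run_scenarios(inputs: PipelineInputs,
                  scenarios: list[ScenarioConfig] | None = None,
                  n: int = 2000, seed: int = 0) -> dict[str, CEAResult]:
    """Base case plus scenarios, each on the same master seed (paired draws)."""
    scenarios = default_scenarios() if scenarios is None else scenarios
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError("scenario names must be unique")
    return {s.name: run_monte_carlo(inputs, s, n=n, seed=seed) for s in scenarios}


# ---------------------------------------------------------------------------
# Defaults


def campaign_effect_estimates() -> list[EffectEstimate]:
    """Published per-campaign changes in weekly serves (two cohort studies).

    Change in serves/week post- vs pre-campaign with 95% CIs; SEs are
    reconstructed from the printed CIs.  These are the bundled alternative
    to recomputing effects from paired survey microdata.
    """
    rows = [
        # (category, study, change, lo, hi, n)
        ("sugary_drinks", "drinks_2013", -0.60, -0.91, -0.30, 821),
        ("fast_food", "drinks_2013", 0.06, -0.04, 0.16, 813),
        ("sweet_food", "drinks_2013", -0.25, -0.60, 0.10, 630),
        ("sugary_drinks", "junkfood_2016", -0.96, -1.26, -0.66, 736),
        ("fast_food", "junkfood_2016", -0.10, -0.22, 0.02, 735),
        ("sweet_food", "junkfood_2016", -0.29, -0.54, -0.03, 736),
    ]
    return [EffectEstimate(c, d, effect_meta.se_from_ci(lo, hi), n, lo, hi, study=s)
            for c, s, d, lo, hi, n in rows]


def pooled_effects(estimates: list[EffectEstimate] | None = None) -> list[MetaResult]:
    """Fixed-effects pool per category across campaigns."""
    ests = campaign_effect_estimates() if estimates is None else estimates
    cats = list(dict.fromkeys(e.food_category for e in ests))
    return [fixed_effects_pool([e for e in ests if e.food_category == c])
            for c in cats]


def default_inputs(seed: int = 0) -> PipelineInputs:
    """Default synthetic bundle: generated population and epidemiology plus
    the bundled pooled campaign effects."""
    return PipelineInputs(
        population=generate_population(),
        diseases=generate_disease_epi(),
        meta_results=pooled_effects(),
    )


def default_scenarios() -> list[ScenarioConfig]:
    """Base case and the four standard sensitivity scenarios."""
    base = ScenarioConfig()
    return [
        base,
        replace(base, name="s1_population_18plus", age_range=(18, 100)),
        replace(base, name="s2_two_waves", n_waves=2),
        replace(base, name="s3_ten_year_horizon", horizon_years=10),
        replace(base, name="s4_discount_3pct", discount_rate=0.03),
    ]


# ---------------------------------------------------------------------------
# Config / output files


def load_scenarios_yaml(path) -> list[ScenarioConfig]:
    """Scenario blocks from a YAML config.

    Each block: name, age_range [lo, hi], n_waves, horizon ('lifetime' or
    years), discount_rate, threshold, effect_age_scaling (optional CSV path
    with columns age_low, age_high, scale).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = []
    for block in cfg.get("scenarios", []):
        horizon = block.get("horizon", "lifetime")
        scaling = block.get("effect_age_scaling")
        out.append(ScenarioConfig(
            name=block["name"],
            age_range=tuple(block.get("age_range", (25, 49))),
            n_waves=int(block.get("n_waves", 3)),
            horizon_years=None if horizon == "lifetime" else int(horizon),
            discount_rate=float(block.get("discount_rate", 0.07)),
            effect_age_scaling=pd.read_csv(scaling) if scaling else None,
            threshold=float(block.get("threshold", 65_000.0)),
        ))
    return out


def write_results(result: CEAResult, outdir) -> None:
    """results.json summary plus the CE-plane scatter as CSV."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    result.ce_plane.to_csv(outdir / "ce_plane.csv", index=False)
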