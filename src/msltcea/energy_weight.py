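"""Serve reductions -> daily energy change -> weight -> per-stratum BMI shift.

A pooled reduction in weekly serves of each discretionary-food category is
converted to an energy deficit (kJ/day) during campaign airing, then to a
body-weight reduction over the intervention year, and finally to a BMI
shift per (sex, age) stratum using stratum heights (delta BMI =
delta weight / height^2).  The weight effect lasts one year; afterwards
weight reverts to baseline, so the lifetable applies the BMI shift in the
first cycle only.

Two energy-balance forms are provided.  The default ``static`` form divides
the cumulative deficit by 37 000 kJ per kg of body tissue and holds the
resulting weight reduction for the remainder of the year.  The ``dynamic``
form is a first-order model: the deficit drives weight toward a
steady-state of (delta E / rho) kg with time constant tau, decaying back
between airing waves, and reports the year-average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import PopulationBundle
from .effect_meta import MetaResult

__all__ = [
    "ServeDefinition",
    "EnergyModelParams",
    "BMIShift",
    "DEFAULT_SERVE_DEFS",
    "effect_to_energy",
    "airing_weeks",
    "energy_to_weight",
    "weight_to_bmi",
]


@dataclass(frozen=True)
class ServeDefinition:
    """Energy content of one serve of a discretionary-food category."""

    food_category: str
    kj_per_serve: float

    def __post_init__(self):
        if not self.kj_per_serve > 0:
            raise ValueError("kj_per_serve must be positive")


#: one discretionary serve = 600 kJ (dietary-guideline convention); the
#: same default is used for drinks and sweet foods, both configurable
DEFAULT_SERVE_DEFS = {
    "sugary_drinks": ServeDefinition("sugary_drinks", 600.0),
    "sweet_food": ServeDefinition("sweet_food", 600.0),
    "fast_food": ServeDefinition("fast_food", 600.0),
}


@dataclass(frozen=True)
class EnergyModelParams:
    """Energy-balance coefficients.

    rho: steady-state kJ/day of deficit per kg of weight lost (dynamic
    mode); tau: time constant in years; static_kj_per_kg: energy content of
    a kg of tissue change (static mode).
    """

    rho: float = 94.0
    tau: float = 1.0
    mode: str = "static"
    static_kj_per_kg: float = 37_000.0

    def __post_init__(self):
        if not (self.rho > 0 and self.tau > 0 and self.static_kj_per_kg > 0):
            raise ValueError("rho, tau and static_kj_per_kg must be positive")
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class BMIShift:
    """Per-stratum weight and BMI reduction applied during year 1.

    ``table`` columns: sex, age, delta_weight (kg), delta_bmi (kg/m^2).
    Positive values are reductions.
    """

    table: pd.DataFrame
    duration_years: float = 1.0

    def __post_init__(self):
        if not self.duration_years > 0:
            raise ValueError("duration_years must be positive")

    @property
    def is_null(self) -> bool:
        return bool((self.table["delta_bmi"] == 0).all())


def effect_to_energy(meta_results: list[MetaResult],
                     serve_defs: dict[str, ServeDefinition] | None = None,
                     age_scaling: pd.DataFrame | None = None):
    """Daily energy reduction (kJ/day) while the campaign airs.

    delta E = sum over categories of |pooled change| * kJ/serve / 7.  Only
    the categories passed in contribute (the caller applies the significance
    gate).  With ``age_scaling`` (columns age_low, age_high, scale) a
    pd.Series of kJ/day indexed by single year of age is returned; otherwise
    a scalar.
    """
    defs = DEFAULT_SERVE_DEFS if serve_defs is None else serve_defs
    total = 0.0
    for m in meta_results:
        if m.food_category not in defs:
            raise KeyError(f"no serve definition for {m.food_category!r}")
        total += abs(m.pooled_change) * defs[m.food_category].kj_per_serve / 7.0
    if age_scaling is None:
        return total
    lo = int(age_scaling["age_low"].min())
    hi = int(age_scaling["age_high"].max())
    ages = np.arange(lo, hi + 1)
    scale = np.zeros_like(ages, dtype=float)
    for row in age_scaling.itertuples():
        mask = (ages >= row.age_low) & (ages <= row.age_high)
        scale[mask] = row.scale
    return pd.Series(total * scale, index=ages, name="kj_per_day")


def effect_draws_to_energy(changes: dict[str, float],
                           serve_defs: dict[str, ServeDefinition] | None = None) -> float:
    """Same arithmetic as :func:`effect_to_energy` on raw per-category draws."""
    defs = DEFAULT_SERVE_DEFS if serve_defs is None else serve_defs
    return sum(abs(v) * defs[k].kj_per_serve / 7.0 for k, v in changes.items())


def airing_weeks(n_waves: int, wave_weeks=7.5,
                 rng: np.random.Generator | None = None) -> float:
    """Total weeks of reduced consumption within the intervention year.

    Deterministic: n_waves * wave_weeks.  Probabilistic (``wave_weeks`` a
    (min, mode, max) tuple and ``rng`` given): the sum of n_waves
    independent Pert draws, defaults Pert(3, 7.5, 13) per wave.
    """
    from .costing import draw_pert  # local import avoids a module cycle

    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    if isinstance(wave_weeks, (tuple, list)):
        lo, mode, hi = wave_weeks
        if rng is None:
            total = n_waves * (lo + 4 * mode + hi) / 6.0  # Pert mean
        else:
            total = float(sum(draw_pert(lo, mode, hi, rng) for _ in range(n_waves)))
        if n_waves * hi > 52:
            raise ValueError("maximum possible airing exceeds one year")
    else:
        if not wave_weeks > 0:
            raise ValueError("wave_weeks must be positive")
        total = n_waves * float(wave_weeks)
        if total > 52:
            raise ValueError(f"total airing {total} weeks exceeds one year")
    return total


def energy_to_weight(delta_e, weeks_active: float,
                     params: EnergyModelParams | None = None):
    """Weight reduction (kg) attributed to the intervention year.

    static: cumulative deficit / static_kj_per_kg — the reduction reached at
    the end of airing, maintained for the rest of the year (this is the
    value the lifetable applies).  dynamic: daily first-order simulation
    with ``n_waves`` airing blocks spread evenly over the year, returning
    the time-average deficit.  Accepts scalar or per-age Series delta_e
    (both modes are linear in delta_e).
    """
    p = params or EnergyModelParams()
    scalar = np.isscalar(delta_e)
    de = np.asarray(delta_e, dtype=float)
    if (de < 0).any():
        raise ValueError("delta_e must be >= 0")
    if weeks_active < 0 or weeks_active > 52:
        raise ValueError("weeks_active must be in [0, 52]")

    if p.mode == "static":
        w = de * weeks_active * 7.0 / p.static_kj_per_kg
    else:
        w = de * _dynamic_unit_response(weeks_active, p)
    if scalar:
        return float(w)
    return pd.Series(w, index=delta_e.index) if isinstance(delta_e, pd.Series) else w


def _dynamic_unit_response(weeks_active: float, p: EnergyModelParams,
                           n_waves: int = 3) -> float:
    """Year-average kg deficit per unit kJ/day, first-order dynamics.

    tau dw/dt = on(t) / rho - w(t), with ``on`` 1 during airing blocks (the
    waves evenly spaced over 52 weeks) and 0 otherwise; symmetric
    exponential decay off-air.  Daily Euler steps; returns mean w over the
    year for delta_e = 1 kJ/day.
    """
    days = 365
    t = np.arange(days) / 365.0 * 52.0  # weeks
    on = np.zeros(days, dtype=bool)
    block = weeks_active / n_waves
    for k in range(n_waves):
        start = k * 52.0 / n_waves
        on |= (t >= start) & (t < start + block)
    dt = 1.0 / 365.0  # years
    w = 0.0
    acc = 0.0
    for i in range(days):
        target = (1.0 / p.rho) if on[i] else 0.0
        w += dt / p.tau * (target - w)
        acc += w
    return acc / days


def weight_to_bmi(delta_weight, population: PopulationBundle,
                  ages: tuple[int, int] | None = None,
                  duration_years: float = 1.0) -> BMIShift:
    """BMI shift per (sex, age) stratum: delta BMI = delta weight / height^2.

    ``delta_weight`` may be a scalar (kg for everyone) or a pd.Series
    indexed by age (per-age effects, e.g. from an age-scaling table).
    ``ages`` restricts the strata covered (default: all in the bundle).
    """
    t = population.table
    if ages is not None:
        t = t[(t["age"] >= ages[0]) & (t["age"] <= ages[1])]
        if t.empty:
            raise KeyError(f"no strata in age range {ages}")
    if isinstance(delta_weight, pd.Series):
        dw = t["age"].map(delta_weight)
        if dw.isna().any():
            missing = sorted(t.loc[dw.isna(), "age"].unique())
            raise KeyError(f"delta_weight series missing ages {missing}")
        dw = dw.to_numpy(float)
    else:
        dw = float(delta_weight) * np.ones(len(t))
    out = pd.DataFrame({
        "sex": t["sex"].to_numpy(),
        "age": t["age"].to_numpy(),
        "delta_weight": dw,
        "delta_bmi": dw / t["height_m"].to_numpy(float) ** 2,
    })
    return BMIShift(out, duration_years=duration_years)
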