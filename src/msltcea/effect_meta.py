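"""Campaign effect estimation and fixed-effects meta-analysis.

Paired pre/post survey records are reduced to a per-campaign change in
weekly consumption of each discretionary-food category (serves/week), and
per-campaign estimates are pooled across campaigns with inverse-variance
fixed-effects weights.  Pooled effects whose 95% CI excludes zero are the
ones carried into the downstream energy/weight model; the pooled estimate
also parameterises the lognormal effect distribution used by the
Monte-Carlo engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectEstimate",
    "MetaResult",
    "serves_per_week",
    "paired_change",
    "se_from_ci",
    "fixed_effects_pool",
    "draw_effect",
    "significant",
    "read_survey_csv",
    "read_effects_csv",
    "write_meta_csv",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Change in weekly consumption for one food category in one campaign.

    ``mean_change`` is signed (negative = reduction), in serves/week.
    """

    food_category: str
    mean_change: float
    se: float
    n: int | None = None
    ci_lower: float = field(default=np.nan)
    ci_upper: float = field(default=np.nan)
    p_value: float = field(default=np.nan)
    study: str = ""

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        lo, hi = self.ci_lower, self.ci_upper
        if np.isfinite(lo) and np.isfinite(hi) and not (lo <= self.mean_change <= hi):
            raise ValueError("mean_change must lie within its own CI")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance pooled change for one food category."""

    food_category: str
    pooled_change: float
    pooled_se: float
    ci_lower: float
    ci_upper: float
    study_weights: tuple[float, ...]
    n_studies: int


#: two-sided 95% standard-normal quantile used to reconstruct SEs from
#: printed CIs and to build pooled CIs (pooling is done on the z scale).
Z_95 = 1.959964


def serves_per_week(days_consumed: float, times_per_day: float) -> float:
    """Weekly serves: days the food was eaten (of the last 7) x times/day."""
    if not 0 <= days_consumed <= 7:
        raise ValueError(f"days_consumed must be in [0, 7], got {days_consumed}")
    if times_per_day < 0:
        raise ValueError(f"times_per_day must be >= 0, got {times_per_day}")
    return days_consumed * times_per_day


def paired_change(records: pd.DataFrame, food_category: str | None = None,
                  level: float = 0.95) -> EffectEstimate:
    """Paired pre/post change for one category, with a paired t-test.

    ``records`` needs columns ``pre`` and ``post`` (serves/week), one row per
    respondent with both waves observed; alternatively a long frame with a
    ``category`` column from which ``food_category`` is selected.  Returns
    mean(post - pre), SE = sd_diff/sqrt(n), a two-sided t p-value on n-1 df
    and the t-based CI.
    """
    df = records
    if food_category is not None and "category" in df.columns:
        df = df[df["category"] == food_category]
    label = food_category or (
        df["category"].iloc[0] if "category" in df.columns and len(df) else "")
    df = df.dropna(subset=["pre", "post"])
    n = len(df)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    diff = df["post"].to_numpy(float) - df["pre"].to_numpy(float)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        # All respondents shifted identically: the t statistic is undefined.
        warnings.warn("zero variance of paired differences; degenerate t-test",
                      RuntimeWarning, stacklevel=2)
        p = 1.0 if mean == 0.0 else 0.0
        # SE floor keeps the EffectEstimate invariant (se > 0) intact.
        se = np.finfo(float).tiny
        return EffectEstimate(label, mean, se, n, mean, mean, p)
    se = sd / np.sqrt(n)
    tstat = mean / se
    p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
    tq = float(stats.t.ppf(0.5 + level / 2, df=n - 1))
    return EffectEstimate(label, mean, se, n, mean - tq * se, mean + tq * se, p)


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal-theory CI."""
    if upper <= lower:
        raise ValueError(f"upper ({upper}) must exceed lower ({lower})")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    return (upper - lower) / (2 * z)


def fixed_effects_pool(estimates: list[EffectEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pool of per-campaign estimates.

    Weights w_i = 1/se_i^2; pooled = sum(w_i d_i)/sum(w_i);
    pooled SE = 1/sqrt(sum w_i); 95% CI on the z scale.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    cats = {e.food_category for e in estimates}
    if len(cats) != 1:
        raise ValueError(f"estimates mix categories: {sorted(cats)}")
    d = np.array([e.mean_change for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled = float((w * d).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return MetaResult(
        food_category=cats.pop(),
        pooled_change=pooled,
        pooled_se=se,
        ci_lower=pooled - Z_95 * se,
        ci_upper=pooled + Z_95 * se,
        study_weights=tuple(w / w.sum()),
        n_studies=len(estimates),
    )


def significant(meta: MetaResult) -> bool:
    """True when the pooled 95% CI excludes zero (two-sided alpha = 0.05)."""
    return meta.ci_lower > 0 or meta.ci_upper < 0


def draw_effect(meta: MetaResult, rng: np.random.Generator,
                size: int | None = None) -> float | np.ndarray:
    """Lognormal draw of the effect magnitude, re-signed.

    The lognormal is moment-matched so the draws have mean
    ``|pooled_change|`` and standard deviation ``pooled_se``; the sign of
    ``pooled_change`` is restored, so every draw has the pooled sign.
    """
    if meta.pooled_change == 0:
        raise ValueError("pooled change of 0 cannot define a lognormal magnitude")
    if not meta.pooled_se > 0:
        raise ValueError("pooled_se must be positive")
    m = abs(meta.pooled_change)
    s2 = np.log1p((meta.pooled_se / m) ** 2)
    mu = np.log(m) - s2 / 2
    draw = rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=size)
    return np.sign(meta.pooled_change) * draw


# ---------------------------------------------------------------------------
# CSV dialects


def read_survey_csv(path) -> pd.DataFrame:
    """Read the paired survey dialect into a long (category, pre, post) frame.

    Columns: respondent_id, category, days_pre, times_pre, days_post,
    times_post.  Serves are days x times per wave.
    """
    raw = pd.read_csv(path)
    pre = [serves_per_week(d, t) for d, t in zip(raw["days_pre"], raw["times_pre"])]
    post = [serves_per_week(d, t) for d, t in zip(raw["days_post"], raw["times_post"])]
    return pd.DataFrame({
        "respondent_id": raw["respondent_id"],
        "category": raw["category"],
        "pre": pre,
        "post": post,
    })


def read_effects_csv(path) -> list[EffectEstimate]:
    """Read pre-aggregated effects (category, study, mean_change, ci_lower,
    ci_upper, n) and reconstruct each SE from its CI."""
    raw = pd.read_csv(path)
    out = []
    for row in raw.itertuples():
        out.append(EffectEstimate(
            food_category=row.category,
            mean_change=float(row.mean_change),
            se=se_from_ci(float(row.ci_lower), float(row.ci_upper)),
            n=int(row.n) if "n" in raw.columns and pd.notna(row.n) else None,
            ci_lower=float(row.ci_lower),
            ci_upper=float(row.ci_upper),
            study=str(getattr(row, "study", "")),
        ))
    return out


def write_meta_csv(results: list[MetaResult], path) -> None:
    """Write pooled results in the tabular layout of the effects table."""
    pd.DataFrame([{
        "category": r.food_category,
        "pooled_change": round(r.pooled_change, 4),
        "ci_lower": round(r.ci_lower, 4),
        "ci_upper": round(r.ci_upper, 4),
        "pooled_se": round(r.pooled_se, 5),
        "n_studies": r.n_studies,
        "significant": significant(r),
    } for r in results]).to_csv(path, index=False)
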