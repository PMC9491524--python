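# Methods note

This note documents the modelling choices behind `msltcea`: the structure
of each stage, the defaults and their rationale, what the synthetic-data
generators do and do not emulate, and known limitations.

## Effect estimation and pooling

Weekly consumption is days (0–7) × times per day, per food category.  The
paired analysis is a completer analysis: the mean of (post − pre) with
SE = sd/√n, a two-sided *t* test on n−1 df and a *t*-based CI.  When the
paired differences have zero variance the *t* statistic is undefined; we
report p = 1 for a zero mean and p = 0 otherwise, with a warning, rather
than failing — degenerate inputs occur in small pilot extracts.

Pooling is inverse-variance fixed effects on the normal (z) scale.  SEs
reconstructed from printed CIs use z = 1.959964, and pooled CIs use the
same quantile; this reproduces the published pooled rows to 2 dp, which a
*t*-quantile reconstruction does not.  The downstream gate is two-sided
α = 0.05 on the pooled estimate (CI excluding zero): with the bundled
estimates, sugary drinks and sweet foods pass, fast food does not.

Monte-Carlo effect draws are lognormal on the magnitude of the pooled
change, moment-matched (mean = |δ̂|, sd = pooled SE) and re-signed, so a
reduction can never flip sign in a draw — matching the distribution family
declared for the effectiveness inputs.

## Energy, weight and BMI

One discretionary serve defaults to 600 kJ for every category.  Serve-size
assumptions are the least well-pinned part of the chain, so `kj_per_serve`
is a per-category parameter, not a constant.

Weight conversion offers two forms:

* **static** (default): Δw = ΔE × active days / 37 000 kJ·kg⁻¹, the
  energy content of body-tissue change.  The deficit accumulates while the
  campaign airs and the resulting weight reduction is held for the rest of
  the intervention year, consistent with treating the year-1 weight change
  as maintained for one year and reverting afterwards.
* **dynamic**: first-order energy balance, τ·dw/dt = ΔE(t)/ρ − w, with
  ρ = 94 kJ·day⁻¹ per kg and τ = 1 y, waves evenly spaced, symmetric decay
  off-air, reporting the year-average.  With these published-rule
  coefficients the year-average deficit for a ~23-week campaign is of
  order 0.1–0.2 kg.

Static is the default because, under the default serve sizes, it places
the base-case weight reduction (~0.40 kg) inside the published 95%
uncertainty band (0.31–0.92 kg), while the dynamic year-average falls
below it; the dynamic form is retained as a sensitivity lever.  Both forms
are linear in ΔE, so doubling all pooled effects doubles Δw exactly.

ΔBMI = Δw / h(a,s)² per (sex, single-year age) stratum.  Per-age effect
scaling (used by the 18+ scenario) multiplies ΔE by a configurable factor
per age band, defaulting to 1 where no factor is supplied.

## The proportional multi-state lifetable

Cohorts are closed, one per (sex, entry age) stratum in the modelled range
(default ages 25–49, i.e. 50 cohorts), simulated in annual cycles to age
100 or a configured horizon.  Conventions, chosen once and used by both
the vectorised model and the hand oracle in the tests:

* rates → probabilities as q = 1 − e^(−rate);
* disease prevalence updates first within a cycle
  (new = (1 − p)·q_i, then p' = p + new − p·(q_f + q_r)); the updated
  prevalence drives that cycle's excess mortality, morbidity and cost;
* cohorts start disease-free at entry age — baseline prevalence at entry
  is understated, but identically in both arms, and only arm differences
  are reported;
* the PIF, 1 − RR^(−ΔBMI), applies to incidence in cycle 0 only (weight
  reverts after the intervention year);
* intervention-arm mortality is μ' = μ + Σ_d (p'_d − p_d)·f_d and the
  morbidity rate is YLD' = YLD + Σ_d dw_d·(p'_d − p_d), capped into [0, 1)
  with a warning — the proportional-lifetable convention of additive
  excess-mortality and YLD-rate adjustments;
* person-years take a half-cycle correction, L = l − deaths/2, and HALYs
  per cycle are L·(1 − YLD);
* disease costs attach to prevalent cases alive at the cycle start
  (c_d·p_d·l); no unrelated healthcare costs in added life years;
* discounting is Σ x_t/(1+r)^t with t = 0 the intervention year, no
  half-cycle correction, base rate 7%.

The closed-form PIF assumes log-linear risk (RR per BMI unit) and a
uniform downward shift, under which the population BMI distribution
cancels exactly.  `pif_numeric` integrates ∫P·RR on a trapezoid grid for
arbitrary distributions and risk curves; under log-linear risk it agrees
with the closed form to < 1e-6, which the tests exploit as an equivalence
check.  Prevalence leaving [0, 1] raises an error (rates too large for
annual cycles) rather than being silently clipped.

Because the comparator arm does not depend on the intervention draw, a
`LifetableModel` computes it once and reuses it across Monte-Carlo
iterations; identical arms therefore produce bit-exact zero differences,
which the tests assert literally.

## Costing

Three aggregated components: pre-campaign (A$44 808), production
(A$688 879) and broadcast (per wave).  The published component table gives
means only, so per-item spreads default to a gamma CV of 0.10, which
reproduces a total spread of roughly ±8–9% over three independently drawn
waves, consistent with the published total interval.  The default per-wave
broadcast mean is A$576 667 (three waves ≈ A$1.73M, the published
base-case broadcast component) rather than the printed single new-phase
wave cost of A$621 427: the base case is one new wave plus two cheaper
re-runs, and their item-level split is not recoverable, so the per-wave
average is calibrated to the component total and the `per_wave` flag is
configurable per item.  Campaign evaluation costs are excluded.  Staff
costs are hours × rate × (1 + 0.145 on-costs + 0.175 leave loading).

## Monte-Carlo engine

Each iteration draws effects (lognormal), wave durations (Pert(3, 7.5, 13)
per wave) and cost items (gamma/Pert), propagates them through the chain
and classifies the ICER: *dominant* (net cost < 0, HALYs > 0), *dominated*
(net cost > 0, HALYs < 0), otherwise the ratio; a zero-HALY denominator
yields a signed-infinity ratio with a warning.  The epidemiology bundle is
held fixed across iterations: the uncertainty distributions of the
original lifetable inputs are unpublished, so redrawing them is out of
scope, and reported uncertainty reflects effect, duration and cost
uncertainty only.

The headline mean ICER is the ratio of mean net cost to mean HALYs
(robust to near-zero denominators); the iteration-level ICER distribution
is summarised separately.  Uncertainty intervals are nearest-rank 2.5/97.5
percentiles — interpolation-free, so the ICER ordering convention
(dominant iterations sort below any positive ratio; dominated above all)
is well defined, and an interval endpoint falling in the dominant set is
reported as "Dominant".  Iteration i uses `default_rng([master_seed, i])`,
giving reproducibility and paired draws across scenarios run on the same
master seed.

Scenarios: base (ages 25–49, 3 waves, lifetime, 7%); s1 ages 18–100 (with
optional per-age effect scaling, neutral by default since the original
age-adjustment table is unpublished); s2 two waves; s3 10-year horizon;
s4 3% discount.

## Synthetic data: what it does and does not emulate

The survey generator draws (pre, post) bivariate normal with configurable
correlation (default 0.7) and clips at zero; retention is binomial.
Defaults (pre mean 7, sd 3 serves/week, n = 1 504, retention 0.55) mimic
the scale of the two cohort evaluations.  At these defaults the clipping
bias on the paired mean is ~+0.01 serves/week — an order below the
sampling SE at realistic n — which is why the sd default is 3 rather than
a heavier-tailed value.  The CSV writer discretises serves into the
days × times survey dialect; heavy consumers (>7 serves/week) are rounded
to whole times/day, a small loss of fidelity that the in-memory path does
not incur.  Not emulated: sampling weights, nonresponse structure, recall
bias, within-person seasonality.

The population generator uses Gompertz mortality (level 3e-5, slope 0.095,
female ratio 0.6 — life-expectancy shape typical of a high-income
population), flat stratum counts (18 000/stratum ≈ a 10⁶-person adult
state population), and normal BMI (mean 27.5, sd 5).  The disease
generator produces exponential-in-age incidence with magnitudes in line
with burden-of-disease rates, constant case fatality and remission
(cancers remit, chronic diseases do not), and log-linear RRs per BMI unit
(1.03–1.20).  These bundles are *plausible*, not calibrated to any
jurisdiction: passing tests demonstrate correct mechanics and parameter
recovery, not that the absolute HALY or cost outputs match any published
population.  On this default bundle the 3%-vs-7% discount HALY ratio is
~2.0 and the base case is dominant in ~100% of iterations — structurally
consistent with the published analysis (ratio 1.99, 76% dominant) without
matching its absolute magnitudes.

## Problem sizes and numerics

The default base case is 50 cohorts × ≤76 annual cycles × 9 diseases × 2
arms; 2 000 iterations complete in well under a minute on one CPU because
only the intervention arm is resimulated per draw.  The dynamic energy
model uses daily Euler steps (365/year).  The PIF quadrature defaults to
4 001 points over ±12 sd.  Tolerances asserted in tests: 1e-12 (lifetable
vs hand oracle), 1e-6 (PIF equivalence), 3·SE (stochastic estimates).

## Limitations

No comorbidity interaction between diseases (additive excess mortality and
YLD); no incidence trends over calendar time; no disease prevalence at
cohort entry; no physical-activity pathway or between-category
substitution; effect maintenance fixed at one year; costs and HALYs share
a single discount rate.  The ICER-interval ordering of dominant vs ratio
iterations is a declared convention, since no standard one exists.
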