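# Methods

## Compositional representation

Tissue and soil test concentrations are compositional: closed to a
measurement unit, they carry only relative information. Leaf tests (N, P,
K, Ca, Mg in g/kg; B and Al converted from mg/kg) are completed with a
filling value Fv = 1000 − Σ(parts) and closed to κ = 1000 g/kg; soil
Mehlich-3 tests (P, K, Ca, Mg, mg/kg) are completed the same way at
κ = 10⁶ mg/kg. A single closure constant per material is required so the
filling value is computable; the ilr map itself is scale invariant, so the
choice of κ never affects balances or distances.

Balances follow two fixed sequential binary partitions:

* leaf: `[Fv | B,Al,Mg,Ca,K,P,N]`, `[Al | B,Mg,Ca,K,N,P]`,
  `[B | Mg,Ca,K,N,P]`, `[Mg,Ca,K | N,P]`, `[P | N]`, `[Mg,Ca | K]`,
  `[Mg | Ca]`;
* soil: `[Fv | Mg,Ca,K,P]`, `[Mg,Ca,K | P]`, `[Mg,Ca | K]`, `[Mg | Ca]`.

Sign convention: in `[left | right]` the right-hand group is the
numerator, so `[B | Mg,Ca,K,N,P]` *decreases* when leaf B rises relative
to the macronutrients. Partitions are stored as ordered contrast lists
(sign matrices plus display order), not tree objects; orthonormality of
the implied contrast matrix (ΨΨᵀ = I to 1e-10) is asserted in tests
against a scikit-bio oracle. Zero or below-detection concentrations in
input tables are replaced by 0.65 × the smallest positive observed value
of that column (simple multiplicative replacement, count logged); strict
positivity is otherwise enforced everywhere.

## Weather indices

Five phenological-stage windows (Julian days 92–125, 126–163, 164–180,
181–220, 221–244) cover bud opening through harvest; the seasonal window
is April 1 – August 31 (days 91–243). Per window we compute the mean of
daily mean temperature, total precipitation, the count of days with mean
temperature strictly below −5 °C ("freezing days"), and optionally
growing degree-days above a 4.4 °C base accumulated from day 91. The
freezing criterion applies to the daily *mean* by default (a `use_tmin`
flag switches to the daily minimum). Windows are fixed calendar windows
interpreted on each date's actual day-of-year; the ±1-day drift this
introduces in leap years is accepted. Missing temperature days are
excluded from means; missing precipitation is treated as 0 with a logged
warning; a window with more than 20 % of days missing logs a warning and
is computed on the available days.

Because future weather is unknown at recommendation time, predictive
features are the element-wise means of the stage indices over the six
years (three crop cycles) preceding the season of observation; fewer than
six available prior years is an error naming the missing years. Freezing
days are excluded from the predictive feature set by default: their
6-year averages are too erratic year-to-year to carry signal.

## Investigative regressions

Both investigative models are conjugate Normal–Inverse-Gamma linear
regressions: y | β, σ² ~ N(Xβ, σ²I), β | σ² ~ N(0, σ²·prior_sd² I),
σ² ~ InvGamma(0.001, 0.001), with prior_sd = 10 on standardized scale —
vague at crop-yield magnitudes. Predictors are centered and scaled to
unit *population* variance (divisor n); the outcome is centered and the
intercept profiled out. The posterior is available in closed form and is
sampled exactly (2000 draws by default, seeded), so no MCMC and no
hierarchy is involved; equal-tailed 95 % credible intervals summarize the
draws. As prior_sd → ∞ the posterior mean converges to least squares
(asserted at prior_sd = 10³ against an lstsq oracle); as prior_sd → 0 all
coefficients shrink to zero. A rank-deficient design is refused with the
collinear columns named via pivoted QR.

The 2-year-cycle model uses N-P-K doses, seasonal mean temperature, total
precipitation and freezing days for both the fruit-bearing and the
preceding vegetative year, the 7 leaf and 4 soil balances, and pH
(21 features). The bearing-year model replaces the seasonal block with
per-stage mean temperature and precipitation plus freezing days for the
earliest stage only — later windows essentially never freeze, making the
count degenerate there (26 features).

## Gaussian-process surrogate

The predictive model splits the data 70/30 uniformly at random (seeded),
standardizes features and outcome on the training rows only, and fits
`ConstantKernel · RBF + WhiteKernel` by L-BFGS maximization of the log
marginal likelihood with 4 random restarts. A single isotropic
length-scale is the default; per-feature (ARD) length-scales are available
behind a flag but overfit at these sample sizes. Noise variance may fall
to 1e-10, so noise-free data are interpolated. Predictions are
de-standardized to kg/ha; the closed-form posterior-mean formula is
cross-checked in tests against a hand-computed small-matrix oracle.

The fitted model stores its applicability domain: the training-feature
mean, covariance (ridge jitter starting at 1e-8 and escalating ×10 until
Cholesky succeeds, capped at 1e-2, logged) and per-feature min/max, all in
standardized space. Classification mode thresholds continuous predictions
at 5000 kg/ha with the low yielder as the positive class; PPV/NPV are NaN
(flagged) when a predicted class is empty.

## Random-walk optimization

The walk operates in the surrogate's standardized space. Free features are
the controllables (7 leaf balances, 4 soil balances, pH, 3 doses); weather
coordinates are bit-identical along the whole trace (conditioning). Each
iteration draws `n_candidates = 60` points uniformly in the Euclidean ball
of the current radius over the free coordinates (a Gaussian proposal is
available), removes candidates with Mahalanobis distance above
sqrt(χ²₀.₉₇₅(p)) or outside the training min/max box (rejected, not
clipped — the proposal stays honest within the envelope), and evaluates
the survivors in one batched prediction. If the best survivor beats the
current predicted yield the walk moves there and the radius shrinks ×0.95;
otherwise (including zero survivors) it stays and the radius grows ×1.03,
capped at 10× the initial radius and floored at 1e-4. Ties break to the
lowest candidate index in the seeded proposal order. The walk stops at
500 iterations, or earlier after 20 consecutive non-accepting iterations
at the radius floor. Accepted predicted yields are non-decreasing by
construction, and every accepted state after the (exempt) start lies
inside the envelope.

The shrink/growth pair was chosen for the stability of the radius
dynamics, which form a multiplicative random walk with drift
`a·ln(shrink) + (1−a)·ln(growth)` at acceptance rate a. Pairs whose
balance point requires a high acceptance rate (e.g. 0.9/1.1) let the
radius run away to its cap near an optimum, where no candidate survives
the envelope filter and the search dies; aggressive shrinking instead
exhausts the walk's total travel, bounded by ~r₀·shrink/(1−shrink), before
distant optima are reached. 0.95/1.03 balances at ~35 % acceptance and
tracks the error scale downward. A structural property of the
shrink-on-success rule is that precision is limited by the radius at which
improvements stop being findable, and that limit grows with the number of
free dimensions: on concave quadratics the walk reliably reaches the
optimum to < 0.05 standardized units in 2-D but plateaus near 0.1 in 3+
dimensions, where only qualitative convergence should be expected (and is
what the portrait relies on).

The 2-D demo climbs a synthetic bumpy terrain — an 87×61 grid summing one
dominant and two minor Gaussian bumps, built entirely in code — from
(42, 8) with initial radius 3, reaching the global peak's plateau within
one grid-cell height for every seed tested.

Recommendations back-transform the final leaf/soil balance blocks through
the inverse ilr, guaranteeing positive, closed compositions, and report
the predicted yield gain (≥ 0 by construction), Aitchison distances
between observed and optimal compositions, and per-part observed/optimal
ratios (> 1 relative excess, < 1 relative shortage). The portrait applies
this to every observation (or a seeded subsample), skipping and counting
per-row failures.

## Synthetic data generator

The generator emulates the structure of a boreal N-P-K trial dataset:
three sites; four bearing years with daily weather generated for the seven
preceding years as well (sinusoidal seasonal temperature, annual mean
2.5 °C, amplitude 16 °C, per-site offsets −0.8/0/+0.9 °C, per-year shocks
of sd 0.8 °C, daily noise sd 3 °C; precipitation as Bernoulli(0.45) wet
days with Gamma(1.2, 5) mm amounts and site/year multipliers); doses
uniform in 0–90 / 0–39 / 0–75 kg/ha; log-normal leaf (σ = 0.18) and soil
(σ = 0.35) concentrations around realistic medians; pH uniform in
4.0–5.6.

Ground truth is linear in the ten historical stage weather indices
(temperature coefficients 250/300/−150/200/350 kg/ha per °C, precipitation
3/−2/5/2/−3 kg/ha per mm, around fixed reference values) and concave
quadratic in the controllables around a known optimum: the balance vector
of the median composition (b*), pH 4.6, doses (55, 20, 35). Curvatures are
5000 (leaf) and 1100 (soil) kg/ha per squared balance unit, 600 per pH²
and small per-dose terms; the magnitudes were fixed so that weather
dominates the linear effects, dose effects are small, and the recoverable
yield gain from re-balancing nutrition is of the order 1–2 Mg/ha (median
yield factor ~1.2–1.4), matching what such systems exhibit. Yields add
N(0, 1000²) kg/ha noise and are clipped to 600–13800 kg/ha. Everything is
reproducible from a single seed, and the historical weather features
entering the truth are computed by the same code the pipeline uses.

What the generator does **not** emulate: clone genetics and stand
composition, pollinator dynamics, pest pressure, spatial correlation
within sites, measurement-protocol drift across years, and the long upper
yield tail of real trials. Passing tests therefore demonstrate the
machinery's correctness and the method's behaviour on a well-posed
surface, not field-scale predictive accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 800
observations (560 training rows — comfortably exact-GP territory), with
optimization portraits over seeded subsamples of 40–60 observations; these
sizes give stable medians while keeping a complete run in tens of seconds
on one CPU. Tolerances: closure and round-trip identities at 1e-9,
orthonormality at 1e-10, the GP oracle at 1e-8; envelope jitter and GP
kernel bounds as above. Degenerate inputs (zero-variance columns, empty
windows, rank deficiency, empty survivor sets, observations starting
outside the envelope) are either handled with a logged warning or refused
with a named error, as documented per module.

## Known limitations

* The optimizer finds local optima inside the training envelope; no
  global guarantee is intended or possible with this scheme.
* Refinement precision degrades with the number of free dimensions (see
  above); portrait results should be read as directional, not as exact
  optima.
* The investigative models are linear; a symmetric concave effect centered
  in the data projects to a near-zero linear coefficient, so small
  balance coefficients there do not imply unimportance.
* The conjugate prior scales coefficient variance by σ²; with vague
  settings this is indistinguishable from fixed-variance priors, but the
  two differ under strong shrinkage.
* Whether the walk should move all controllable blocks simultaneously or
  sequentially block-by-block is underdetermined; this implementation
  walks all free features simultaneously, which subsumes the sequential
  variant's reachable set.
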