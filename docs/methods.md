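# Methods

## Growth model and phase partition

Grain dry-matter accumulation is modelled as a three-parameter logistic
`W(t) = A/(1 + B e^(-Ct))` with `t` in days after flowering (`t = 0` on the
flowering day; days-after-pollination timestamps are treated as the same
origin). `A` is the asymptotic 100-grain weight in grams, `B > 0` a
dimensionless shape parameter and `C > 0` a rate constant per day. The model
assumes a single smooth sigmoid per experimental unit — no per-kernel
position effects, no late-season weight loss, no alternative growth laws
(Richards, Weibull).

The filling-rate curve `dW/dt` is a skewed bell; its concavity changes where
`d³W/dt³ = 0`. Writing `s = B e^(-Ct)`, the third derivative is proportional
to `s(s² − 4s + 1)`, with roots `s = 2 ± √3`, giving the fast-phase
boundaries `t1,2 = (lnB ∓ ln(2+√3))/C`. The effective filling period ends
when `W = 0.99A`, at `t3 = (lnB + ln 99)/C`. Agronomic tables print the
offsets truncated to 1.317 and 4.59512; the package defaults to those
truncated values (`constants="truncated"`) so published-style tables reproduce
digit-for-digit, with `constants="exact"` switching to full precision. The
difference in `t1` is about `4.2e-5/C` days — irrelevant agronomically,
visible to tight numerical tests, which therefore use `"exact"` when
comparing against root-finding oracles.

Closed-form consequences worth knowing:

* boundary weight fractions `W1/A = 1/(3+√3) ≈ 0.21132`, `W2/A ≈ 0.78868`,
  `W3/A = 0.99`;
* `w1 + w2 + w3 = 0.99A − W0` exactly (telescoping), `W0 = A/(1+B)`;
* `T3/T2 = (ln99 − ln(2+√3)) / (2 ln(2+√3)) ≈ 1.2446` and
  `V2/V3 ≈ 3.5692` are parameter-free. Any reanalysis therefore shows
  *identical* percentage treatment effects on `V2` and `V3` (and on `T2` and
  `T3`), and model-derived `V2`/`V3` columns are perfectly collinear —
  variable selection must not be offered both (see below).

`W0` is taken from the fitted model, not from data, because sampling starts
15 d after pollination; the flowering-day weight is never observed.

The empirical filling rate between consecutive samples is the secant slope
`(W_curr − W_prev)/D` attached to the interval midpoint (the midpoint
centres the secant estimate of the derivative; the source convention does
not specify a time stamp). A least-squares parabola through the rate points
summarises the "rise then fall" pattern; its vertex approximates the rate
peak only coarsely (for a noiseless logistic with A = 30, B = 40, C = 0.15
sampled 15–50 d the vertex lands ~3 d early and ~12% low, because the true
rate curve is skewed). The vertex is reported exactly as fitted; a
non-concave fit (within rounding tolerance of the fit scale) is an error.

## Curve fitting

Starting values: `A0 = 1.05 × max(W)`; `(B0, C0)` by ordinary least squares
on the linearization `ln(A0/W − 1) = lnB − Ct` over points below `A0`. The
5% inflation of `A0` flattens the logit near the plateau, biasing `B0`, `C0`
low by up to ~25% — deliberate robustness plumbing, not an estimator; the
bias is well inside the optimizer's basin of attraction.

Optimization: scipy trust-region-reflective least squares with analytic
Jacobian, bounds `(0, ∞)³`, `ftol = xtol = gtol = 1e-10`, iteration cap 200.
No random restarts, so fits are deterministic; `multistart=True` adds a
fixed lnB grid for pathological series. Non-convergence (including
unidentifiable constant series) is reported through `converged=False`,
never raised. Goodness of fit: `r² = 1 − SS_res/SS_tot` against the
mean-only model, NaN when the series has zero variance.

Identifiability: with the field schedule (9 points, 15–55 d) and noise of
1% of `A`, the Cramér–Rao bound gives relative standard deviations of
roughly 0.005–0.05 for `A`, 0.03–0.05 for `C`, but 0.10–0.17 for `B` — only
one sample precedes the fast phase, so the curve's early shape is weakly
constrained. Recovery expectations (and tests) are set accordingly: `A` and
`C` within 10% for ≥95% of fits; `B` errors at the information bound, with
`lnB` (what the phase boundaries actually consume, divided by `C`) far
better determined than `B` itself.

Curves may be fitted per replicate (default) or to treatment-mean series
(`per_replicate=False`); field practice varies and both are supported.

## Split-plot ANOVA and LSD

Replicates are random blocks; tillage (M) occupies main plots, variety (V)
subplots. Sums of squares are the textbook balanced-design quantities from
marginal means; Error I is the block × M interaction with `(r−1)(m−1)` df,
Error II the residual with `m(r−1)(v−1)` df. `F(M) = MS(M)/MS(Error I)`;
`F(V)` and `F(M×V)` use Error II. Unbalanced layouts are rejected outright
rather than approximated; zero error variance yields NaN F with an empty
significance mark. Significance marks: `**` p<0.01, `*` p<0.05, `ns`.

LSD: `t(1−α/2, df) √(2 MS/r)` with compact letters assigned by a
descending-mean sweep (levels share a letter iff their difference is within
one LSD). Comparing tillage levels at a fixed variety mixes both strata, so
those letters default to the combined standard error
`√(2[(v−1)MS_EII + MS_EI]/(rv))` with Satterthwaite df; an Error II-only
mode exists for compatibility with naive analyses. Years are always
analysed separately; no pooled-year model. No multiple-testing adjustment
beyond LSD is applied, matching standard practice for these tables.

## Multivariate layer

Pearson correlations carry unadjusted two-sided p-values from
`t = r√((n−2)/(1−r²))`. PCA is an eigendecomposition of the correlation
matrix; explained fractions are `λ_i/p`; loading signs are fixed so each
component's largest-magnitude loading is positive (biplot orientation is
otherwise arbitrary). Stepwise regression is classical forward entry /
backward elimination on partial-F p-values with entry and stay thresholds
`sle = sls = 0.15` by default — the convention of the major statistical
packages for this procedure, which retains terms with p ≈ 0.08–0.15 that a
0.05 rule would drop. A cycle guard terminates if a model recurs;
rank-deficient candidate designs are skipped with a warning (this is what
happens if both `V2` and `V3` are offered); once the residual is exact to
rounding (`SSE ≤ 1e-12 SST`) entry stops and redundant terms are dropped,
since partial F against rounding noise is meaningless. The per-candidate
entry test means the null "empty model" rate is ≈ `0.95^k` for k
candidates at `sle = 0.05`, not 95%.

## Synthetic trial generator

The generator emulates the 2-year × 9-tillage × 2-variety × 3-block design.
Unit-level truth: variety base parameters (XY696: A = 32 g, B = 40,
C = 0.155/d; XM6: A = 33 g, B = 45, C = 0.152/d — the second variety
slightly heavier with a later peak, maturities ~125/130 d) times tillage
multipliers on `A` and `C` plus additive lnB shifts, times lognormal
replicate jitter (σ = 0.02 on A and C, 0.03 on lnB — a 2–3% CV typical of
block-level field variation). Default tillage effects keep `A` shifts
within ±7% (best straw-incorporation treatments SSR/DPR at +4.5/+5%) and
peak-rate shifts within ±15%, the ranges reported for such trials.
Observations are the logistic curve at 15, 20, …, 55 d plus iid Gaussian
noise (σ = 0.3 g ≈ 1% of A). Quality traits are linear in the unit's true
phase parameters plus Gaussian noise, with signs matching the reported
trait–weight correlations (starch, fat positive; protein, sugar negative);
the maturity grain weight trait is the unit's asymptote re-expressed at 14%
moisture.

What the generator does *not* emulate: weather-driven year effects,
spatial field trends within blocks, kernel-position heterogeneity,
measurement-protocol drift, or any mechanistic link between soil nutrients
and filling. Passing tests therefore demonstrate statistical correctness of
the pipeline under its own assumptions, not agronomic validity on real
trials.

RNG streams for unit parameters, weight noise and trait noise are spawned
separately from one seed, so the ground-truth table can be reproduced
independently of the noise draws.

## Problem sizes used in checks

Oracle equivalence of the partition uses 1000 random parameter triples
(tolerance 1e-6 d against Brent root-finding). Type-I calibration of the
split-plot F tests uses 2000 null trials of the full 3 × 9 × 2 layout
(expected band 0.04–0.06 at α = 0.05). Power and size of the end-to-end
simulate → fit → ANOVA chain use 200 single-year trials each (a +5% DPR
effect on `A` must be detected in ≥80%; false positives ≤6% with the effect
off). Recovery studies use 100–200 fits per configuration.

## Known limitations

* `B` is weakly identified from the 9-point field schedule (see above);
  conclusions should rest on `A`, `C` and the phase summaries, not `B`.
* The exact `V2/V3` and `T3/T2` collinearity means regressions "on all
  three rates" are structurally rank-deficient when the rates come from
  fitted curves; published coefficient sets over V1–V3 can only arise from
  rates computed by other means or from rounding noise.
* The quadratic rate-peak summary is biased for skewed rate curves; the
  logistic `t_max`, `G_max` are the model-consistent peak estimates.
* CSV is the only interchange format; no plotting beyond what users build
  from the returned tables.
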