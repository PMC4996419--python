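# Methods

## Model and assumptions

Two auxotrophic strains share one habitat and one carrying capacity
(normalized to 1).  Strain X (Trp⁻) grows on a nutrient pool `Y + a`: its
partner's density stands in for the tryptophan the partner leaks, plus the
supplemented level `a`.  Strain Y (Leu⁻) sees `βX + a`, with `β > 1` because
the Trp⁻ strain contributes more to the exchange.  Each pool enters through
a Monod factor `s/(s + κ)`, multiplying a shared logistic factor, minus a
constant death rate `δ` that stands in for continuous dilution.  Leucine and
tryptophan are always co-supplied at a fixed 8:1 ratio, which is why a
single coordinate `a` suffices; with that ratio roughly matching
intracellular abundances, one Monod constant serves both strains.

Assumptions worth keeping in mind: nutrient pools are slaved to densities
(no explicit resource dynamics — valid when amino-acid turnover is fast
compared to consumption); strains are fixed types (no adaptation or
evolution); the environment is well mixed; death is strain-independent.

Time is dimensionless: `r_x = 1` defines the unit.  This is a documented
convention, not a configurable parameter.

### Parameters

| name | default | meaning / why this value |
|------|---------|--------------------------|
| `r_x` | 1.0 | Trp⁻ maximal growth rate; sets the time unit |
| `r_y` | 0.925 | Leu⁻ maximal rate; a ~7.5 % disadvantage measured in saturating-nutrient competition |
| `kappa` | 0.12 | Monod constant shared by both pools (8:1 supply ratio balances the pools) |
| `beta` | 2.0 | benefit asymmetry; the Leu⁻ strain dominates unsupplemented co-cultures |
| `delta` | 0.5 | death rate representing daily 10× dilution |
| `a` | 0 | supplemented amino-acid level, dimensionless |
| `c` | 1.0 | niche overlap; scales the partner's weight in the logistic term only (the strains are nearly isogenic, hence full overlap by default) |

The mapping from experimental concentrations to `a` is linear,
`a = 0.1 × (tryptophan µM)`, chosen so that 1 µM — the experimentally
obligate condition — lands near the model's obligate window (`a ≈ 0.1`).
The true correspondence is unknown; the scale is exposed as a config knob
and nothing downstream depends on its exact value (regime *order* along the
axis, not µM positions, is the reproducible content).

## Equilibria and bifurcations

Interior fixed points are found by eliminating X from the two balance
conditions: `X(Y) = 1 − cY − δ/(r_x g_x(Y + a))`, substituted into the Y
condition with the Monod denominator cleared (so the scalar residual is
pole-free at unphysical negative densities).  The residual is scanned on a
10⁴-point grid in `Y ∈ (0, 1)` and every sign change is polished by Brent's
method; this brute-force scan guarantees all roots at desk scale, which is
why no continuation method is used.  Stability comes from the analytic
Jacobian (cross-checked against central finite differences in the tests);
eigenpairs are ordered slow-first by real part, the ordering relevant for
early-warning analysis.

The two collapse boundaries are bisected to `1e−8` in `a` on the predicate
"a stable interior equilibrium exists": the saddle-node at
`a* ≈ 0.08237` and the transcritical exclusion point at `a ≈ 0.73276` for
the reference parameters.  Bisection tolerance is far below any printed
precision; the thresholds are grid-refinement-stable to `1e−6`.

Degenerate cases: with `δ = 0` there is no saddle-node (the mutualism
cannot collapse) and bisection raises a bracketing error rather than
inventing a boundary; `a = 0` monocultures return equilibrium 0, not an
error.

## Regime classification

A pure decision table maps four densities — co-culture attractor (X*, Y*)
and monoculture equilibria (X_m, Y_m) — to a label with per-strain effect
codes (+, −, 0, X).  Both mono extinct: collapse (no interior) or obligate
mutualism (interior).  One mono viable with coexistence:
obligatory/facultative.  Both viable: compare each strain's co-culture
density to its monoculture density with a relative neutrality band
`rel_tol`; (+,+) facultative mutualism, mixed signs parasitism, a neutral
strain beside a harmed one amensalism, (−,−) competition.  No coexistence
with a viable winner: competitive exclusion.  The same table serves the
model-side classifier and the experimental-data classifier, so predictions
and estimates are judged by identical rules.

Two tolerance conventions coexist deliberately.  Pointwise classification
defaults to `rel_tol = 0.01`: amensalism is a boundary phenomenon and needs
a finite band to be reportable at all (and in measured data the band is
real, set by uncertainty).  The scan and map functions default to the
strict band `rel_tol = 0` because any finite band turns the
parasitism/competition boundary — and the approach to exclusion, where the
winner's co-culture density converges to its monoculture value — into thin
spurious "amensalism" stripes on a fine grid.  With the strict convention a
generic scan yields exactly the seven robust regimes in canonical order,
which matches how the model's regime diagram is meant to be read, while
amensalism remains obtainable where it belongs: exactly on the boundary,
or from data with a finite uncertainty band.

When a stable interior attractor coexists with a stable axis or origin
attractor (bistability is intrinsic to the obligate regime), the interior
attractor defines the label.  Conflicting labels from multiple stable
interior points would raise an ambiguity error carrying all candidates;
this does not occur for the reference parameters.

## Trajectories and the daily-dilution map

Continuous trajectories use LSODA with `rtol 1e−9`, `atol 1e−12`.
Densities crossing `1e−10` trigger an event stop, are snapped to exactly
zero, and integration resumes — preventing underflow chatter near the
absorbing axes.  Terminal fates are assigned by proximity (`1e−4`) to a
stable fixed point at the final time; near-critical parameters genuinely
relax slowly and are honestly reported `unresolved` if the horizon (default
500 time units) is too short, rather than extrapolated.

The batch map grows for `t_day` with `δ = 0` (dilution *is* the death
process) and then divides both densities by the dilution factor.  The
default `t_day = ln(10)/0.5 ≈ 4.605` makes the protocol's effective death
rate `ln(D)/t_day` equal the continuous model's `δ = 0.5`, so the daily map
shares the continuous model's regime topology; a saturated monoculture can
complete ~6.6 doublings in such a day, comfortably above the `log2(10) ≈
3.3` needed to outpace dilution.  (A shorter day is still viable for
survival but raises the effective death rate enough to reorder the regime
windows, which would misrepresent the experiment the generator emulates.)
Batch equilibria are end-of-day, pre-dilution states — what a plate reader
measures — iterated to a sup-norm tolerance of `1e−10`.

Relaxation diagnostics report the fast/slow eigenvalue magnitude ratio and
the |cosine| of the slow eigenvector against two reference directions: the
radial direction `(X*, Y*)/‖·‖` (constant strain ratio) and
`(1, −1)/√2` (constant total).  Near the saddle-node the radial alignment
exceeds 0.95 (total density is slow); near exclusion the constant-total
alignment exceeds 0.95 (the ratio is slow); in between the ratio of
timescales stays below ~3 and no direction dominates.

## Stochastic simulation

The continuous model is the mean-field limit of a birth–death process on
counts with system size Ω (individuals at carrying capacity).  The
propensity split is the canonical one — saturating growth times the
logistic factor as birth, `δx` as death — with the logistic factor clamped
at zero above carrying capacity so all propensities are provably
non-negative.  The exact direct method is used; populations at this scale
do not need tau-leaping.  The split and Ω are constructions of this
package: the mean-field limit constrains only the difference of birth and
death rates, and this choice is the minimal non-negative one.  Default
`Ω = 10⁴` tracks the deterministic model while showing near-collapse
fluctuations; ensembles derive per-replicate seeds from one master seed
and reject duplicates.

## Four-strain invasion

The double producer D makes both amino acids (contributing to both pools
with weights `w = w_β = 1`), gains nothing from supplementation, and pays a
growth-rate cost; the non-producer N needs both pools at once and grows
fastest.  Only the rate *ordering* `r_d < r_y < r_x < r_n` is specified by
the biology, so the defaults are conventions: `r_n = 1.05`, and
`r_d = 0.6`.  The double-producer rate matters: D invades the pair's
equilibrium whenever `r_d > r_x·g_x` there, and `r_x·g_x` ranges over
~0.65–0.82 along the coexistence branch, so any `r_d` above ~0.65 would let
the double producer overrun the mutualistic window entirely and no
invasion-resistant zone would exist.  `0.6` keeps the cost of double
production decisive while still letting D outgrow dilution alone
(`r_d > δ`).  Scans seed the pair's attractor with both invaders at 10⁻⁴
and integrate to t = 2000; an invader ending above 10× (below 0.1×) its
inoculum has invaded (been repelled).  The resulting structure: double
producer takes over at low supplementation, the cross-feeding pair repels
both cheaters at intermediate levels, the non-producer invades at high
levels — first coexisting with the Trp⁻ strain, then dominating outright.

## Synthetic experiments

The generator emulates the daily protocol: wells seeded as monocultures or
co-cultures, grown `t_day`, measured, diluted 10× into fresh identical
medium, for 7 days by default.  Optical density carries multiplicative
lognormal noise (σ = 0.05 by default; the real instrument's noise model is
unknown, so this is a documented convention, as is the OD unit of 1.0 at
carrying capacity).  Flow-cytometry fractions are binomial draws of 10⁴
cells.  Extinct wells report the detection floor (OD 10⁻⁴) and an *empty*
fraction field — never zero, never a numeric NaN.  Everything is exactly
reproducible under the config seed, and the noise-free, infinite-sample
limit reproduces the deterministic daily map bit-for-bit, which anchors the
estimation stage's regression tests.

What the generator does **not** emulate: strain adaptation over the
experiment, instrument drift, evaporation or edge effects, OD
nonlinearity at high density, or any real OD-to-cell-count calibration.
Tests passing on synthetic data therefore validate the estimation
machinery under the stated noise model, not robustness to those artifacts.

## Estimation

Relative fitness over one cycle is the odds-ratio fold change of the Leu⁻
fraction, `W = odds(f₁)/odds(f₀)`.  The formula needs only cytometry
fractions, is symmetric under strain relabeling (W → 1/W), and equals the
ratio of the strains' fold growths.  `log W` is regressed linearly on the
day-start fraction; the zero crossing estimates the equal-fitness
equilibrium fraction, with a percentile bootstrap CI (default 2000
resamples of day records).  A fit with no crossing in the observed range is
reported as a no-equilibrium error carrying the sweep direction — that is
evidence of exclusion, not a failure.

Convergence of a well is judged over its last 3 days: relative OD spread
below 10 %, and fraction drift below 0.1 on the *log-odds* scale (a slow
sweep at an extreme fraction barely moves the raw fraction but moves log
odds steadily; equal fitness is a log-odds fixed point).  A track at the
detection floor, halving per day, or sliding monotonically by ≥ 25 % over
the window is flagged as extinction in progress.  Non-converged co-cultures
are extrapolated through the fitted crossing.

The per-day growth-rate disadvantage of the Leu⁻ strain is estimated at
saturating supplementation as `1 − ln(fold_Y)/ln(fold_X)` per dilution
cycle, which cancels the shared logistic history and converges to
`1 − r_y/r_x` (7.5 % at the defaults); the bootstrap CI on synthetic data
covers that truth.

Experimental regime calls use the shared decision table with estimated
equilibria and a wider neutrality band (`rel_tol = 0.05`) reflecting
measurement uncertainty.

## End-to-end validation design

Ground truth for pipeline validation is the daily map itself, not the
continuous model: a plate experiment converges to batch equilibria, whose
regime boundaries sit at slightly different supplementation levels.  One
condition per regime is selected by bisecting the batch boundaries
(co-culture viability, the two monoculture viabilities, and — for
amensalism — the level where the Leu⁻ strain's co-culture and monoculture
equilibria coincide); interval regimes are probed at interior points.
Wells are seeded with post-dilution equilibrium states so the first
measurement already sits on the daily-map attractor, except the exclusion
condition (seeded at five fractions, all of which yield negative log
fitness — the sweep signature) and the collapse condition (seeded
generically and diluted away).  On noise-free plates the pipeline recovers
all eight labels.

## Problem sizes and runtimes

The shipped tests and the acceptance script run at desk scale: 10⁴-point
interior scans, 10³-point regime scans, stochastic ensembles of 10–200
replicates at Ω up to 10⁵, 100-replicate coverage studies with 10³
bootstrap resamples, and invasion scans at a handful of supplementation
levels.  These sizes were chosen as the smallest at which every qualitative
conclusion is stable under refinement (thresholds move < 10⁻⁶, label
sequences unchanged at half the grid step).

## Known limitations

- The concentration↔`a` mapping is a convention; µM-axis positions of
  regime boundaries are not reproducible, only their order and existence.
- Fate classification near criticality needs long horizons; `unresolved`
  is a deliberate honest outcome, not an error.
- The stochastic propensity split is one consistent choice among several
  with the same mean-field limit; quantities that depend on the split only
  through the deterministic limit (means at large Ω) are insensitive, but
  fluctuation magnitudes could differ under another split.
- The bootstrap CI for the equilibrium fraction assumes the local
  linearity of log fitness in the fraction; with start fractions spread
  far from equilibrium, curvature would bias the crossing.
- Estimation assumes day-indexed tracks with one measurement per day;
  irregular sampling is not supported.
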