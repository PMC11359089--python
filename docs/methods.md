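# Methods

`synaptome_sd` re-implements, as a reusable and tested pipeline, the
computational core of a sleep-deprivation synaptome analysis: region-level
Bayesian effect mapping of punctum parameters, a subtype-diversity
statistic, a protein-lifetime-ranked subtype contrast, and a spatially
scaled short-term-plasticity (STP) simulation of CA1 stratum radiatum
(CA1sr) responses to oscillatory activity.  Because the underlying imaging
dataset is raw microscopy, the package ships a synthetic-data generator
that emulates the *post-quantification* tables with known ground truth;
every statistical claim the test suite makes is therefore a claim about
recovery of injected effects, not about real tissue.

## Synthetic cohorts

The generator produces tidy per-animal × per-region tables for a
four-group design — ZT6 (undisturbed controls, n = 8), ZT6SD (6 h sleep
deprivation ending at zeitgeber time 6, n = 10), ZT11 and ZT23 (circadian
time points, n = 10 each).  The default brain catalog has 125 regions in
seven areas (68 isocortex/CTX, 23 hippocampal formation/HPF, the rest
split over OLF, CTXsp, STR, TH, HY), with exactly one region flagged as
CA1sr.

**Noise model.**  All measured quantities (densities, median intensities,
median sizes, subtype densities) are strictly positive, so noise is
multiplicative log-normal with a fixed coefficient of variation
(`noise_cv`, default 0.15) and unit mean.  Region baselines and per-area
subtype proportions are fixed constants derived from a dedicated seed that
is deliberately decoupled from the cohort seed: different cohorts sample
the same underlying "brain".

**Injected effects.**
- *Circadian null*: ZT6, ZT11 and ZT23 are drawn from identical
  distributions.  No circadian effect is modeled.
- *PSD95 size reduction*: in CTX and HPF regions only, the ZT6SD expected
  PSD95 median size is multiplied by a factor `r` chosen so the expected
  pooled-SD Cohen's d versus ZT6 equals `size_effect_d` (default −1.0).
  Because group SDs scale with their means under constant CV, `r` solves
  `r = 1 + d·cv·sqrt(((n1−1)r² + (n2−1))/(n1+n2−2))` (fixed-point
  iteration); at the defaults `r ≈ 0.861`.  Realized per-region d retains
  the usual small-sample inflation (~5–10 % at these group sizes), which
  the Monte-Carlo tolerance (±0.2 over 200 cohorts) absorbs.
- *Subtype shift*: each of the 30 PSD95-expressing subtypes is shifted in
  proportion to `slope · (lifetime_pct − 50)/50 · baseline`, then the
  shifts are re-centred so they sum to zero within every region — total
  synapse density is conserved exactly in expectation.  SAP102-only
  subtypes are never shifted.  The default slope 0.3 (a ±30 % fractional
  shift at the lifetime extremes) is a moderate effect chosen to mirror a
  clearly detectable long-versus-short-lifetime reorganisation at these
  group sizes.
- Animal sex is generated as metadata and has no effect on any quantity.

**Subtype catalog.**  37 subtypes; 30 express PSD95 and carry strictly
distinct lifetime percentiles.  The six longest-lifetime (LPL) subtypes
are ids 2, 3, 5, 20, 34, 35 and the six shortest (SPL) are 6, 8, 11, 28,
29, 31 — these published set memberships are treated as a fact of the
catalog, so the generator places those ids at the extremes by
construction, with seeded jitter inside each block.  Per-area subtype
proportions come from fixed Dirichlet draws whose concentration is high
in CTX/HPF (even, diverse) and low subcortically (sparse), reproducing
the known diversity gradient.

**Spatial profiles.**  For the physiology model the generator emits, per
group and protein, the 4×4 matrix of geometric-mean punctum sizes over
individuals (tangential subregions CA1/CA2/CA3/DG × four radial layers)
with gentle monotone gradients along both axes, plus fixed 11×11 CA1sr
baseline scale-factor profiles in (0, 1].  The ZT6SD PSD95 matrix is
scaled by the same multiplier `r`, which shrinks its directional spans
relative to control.

## Effect mapping

**Cohen's d** uses the pooled standard deviation
`s = sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2))` with unbiased group
variances; the sign convention puts the sleep-deprived group first, so
reductions are negative.  Degenerate samples (pooled s = 0) raise.

**Bayesian two-group comparison.**  The posterior of the standardized
difference `δ = (μ1−μ2)/sqrt((σ1²+σ2²)/2)` can be sampled by two engines:

- `gaussian` (default): the exact posterior of the two-group normal model
  under Jeffreys priors — `σi² ~ (ni−1)si²/χ²(ni−1)`,
  `μi|σi ~ N(x̄i, σi²/ni)` (the Behrens–Fisher posterior).  Its two-sided
  tail probability closely tracks the Welch t-test p-value, which the
  tests use as an independent oracle.  Sampling is vectorized and fast
  enough to sweep 125-region maps over hundreds of simulated cohorts,
  which is what makes the calibration suites practical.
- `robust`: a heavy-tailed (Student-t likelihood) two-group model with a
  shifted-exponential prior on the normality parameter (mean 30),
  data-scaled normal priors on the means and broad uniform priors on the
  scales, sampled with affine-invariant ensemble MCMC (seeded,
  reproducible).  It is the slower, outlier-resistant variant and is
  cross-checked against the gaussian engine at large n.

The reported `p_bayes` is `2·min(P(δ>0), P(δ<0))` over the posterior
draws, floored at `1/n_draws` (default 2000 draws).  Per-region seeds are
spawned deterministically from the map seed.

**Multiple testing.**  Benjamini–Hochberg step-up correction is applied
across all regions of one map (one family per parameter), at α = 0.05 by
default.  Regions with fewer than two animals per group are flagged,
excluded from the BH family, and logged.

**Diversity.**  The 0–1 subtype-diversity statistic is normalized Shannon
evenness `H(p)/ln 37` of the density proportions: exactly 1 when all
subtypes have equal density, 0 when one subtype carries everything,
invariant to total-density scaling and permutation, and strictly
increased by any transfer of density from a larger to a smaller subtype.
An alternative `1 − CV/sqrt(K−1)` form with the same range and extremes
is selectable.

**Two-stage LPL/SPL contrast.**  Stage 1 estimates, per region, the
posterior of the group difference of the pooled LPL-set density and of
the pooled SPL-set density.  Stage 2 applies a Bayesian comparison *to
those two posterior distributions*: the contrast draws are the
elementwise differences of the independently drawn stage-1 δ samples,
the reported d is the standardized separation of the two draw sets, and
p is the two-sided tail of the contrast, floored at 1/n_draws.  A naive
alternative — feeding the 2×n_draws posterior samples into a second
t-model as if they were data — makes posterior uncertainty shrink with
the number of draws (an analysis artifact), so null regions would almost
always come out significant; the distribution-level comparison keeps the
null calibrated (verified by simulation) while preserving the two-stage
structure.  BH correction runs across regions as usual.

## CA1sr physiology model

Each synapse is an event-driven STP unit.  For event k at time t_k with
preceding events i (Δt_i = t_k − t_i):

    A_td(k) = max(1 − Σ_i A_d·exp(−Δt_i/τ_d), 0)          (depression)
    A_tf(k) = min(1 + Σ_i (A_f·exp(−Δt_i/τ_f)
                        + A_s·exp(−Δt_i/τ_s)), 3.3)      (facilitation)
    A_e(k)  = A_tf(k) · A_td(k)

The first response is exactly 1 and the total facilitatory multiplier
saturates at 3.3× the unit response.  The EPSP kernel is
`exp(−t/τ1) − exp(−t/τ2)` with τ1 = 3.0 ms, τ2 = 0.4 ms (AMPA-type time
course; analytic peak at ≈ 0.930 ms).  Event amplitudes are computed in
continuous time; voltage traces are sampled at 1 ms by default.

Defaults for the plastic components (`A_d0 = 0.10`, `τ_d0 = 300 ms`,
`A_f0 = 0.20`, `τ_f0 = 94 ms`, `A_s0 = 0.03`, `τ_s0 = 380 ms`) follow
classic cortical STP estimates, with per-spike increments small enough
that 100 Hz bursts modulate rather than silence the synapse.  Setting a
radial scale factor to 0 sends the corresponding time constant to 0,
which is treated as "no memory" (the decayed contribution vanishes).

**Spatial scaling.**  Per protein and direction, a group's directional
gradient is the span (max − min) of its mean 4×4 profile along that
axis; spans are normalized across groups by subtracting the minimum span
and dividing by the maximum, giving factors in [0, 1].  Tangential
factors scale the amplitudes (A_d via PSD95, A_f via SAP102) and radial
factors the time constants, per the model's symbol conventions.  The
mapping from those four scalars to the 11×11 grid is a design choice:
each per-protein CA1sr baseline profile is multiplied by
`0.5 + 0.5·factor` and clipped to [0, 1].  This blend keeps two contract
properties — identical group profiles give identical grids, and a
spatially uniform baseline gives a spatially uniform grid — while
letting group differences modulate the grid's operating point.

**Stimulus battery.**  Pattern definitions (frequencies and counts are
config-overridable defaults, chosen to represent the canonical rhythms):
gamma train 10 pulses @ 40 Hz; gamma burst 5 bursts @ 5 Hz of 4 pulses
@ 40 Hz; theta train 10 pulses @ 5 Hz; theta burst 10 bursts @ 5 Hz of
4 pulses @ 100 Hz (the protocol also used for fitting); sharp-wave
ripple 10 pulses @ 180 Hz.

**Map comparison.**  Per pattern, each group's 11×11 response map sums
the per-synapse event amplitudes (121 values).  `ed_intensity` is the
Euclidean distance between raw maps; `ed_spatial` the distance after
dividing each map by its mean (shape only).  The KS test is a two-sample
test on the two sets of 121 position-paired values (a one-sample test on
paired differences is an easy drop-in, but the two-sample form is the
default); Cohen's d of the paired differences is also reported.  The
battery BH-corrects the five KS p-values as one family.

## Parameter fitting

Free parameters (default `A_d0`, `τ_d0`, `A_f0` — the set that differs
between genotypes in the source physiology) are estimated by minimizing
the unweighted sum of squared residuals over per-burst mean amplitudes of
bursts 1, 2, 8, 10 of the theta-burst protocol plus paired-pulse ratios
at 25, 50, 100, 200 ms.  The optimizer is bounded L-BFGS-B from a
deterministic multi-start list (config init plus a coarse lattice in the
bounds); an exhaustive grid search is provided as an oracle.  The
original experimental target values are not tabulated anywhere in the
source, so validation is by parameter recovery: targets generated at
known parameters are fit back to within 5 % relative error.  Note the
loss surface is nearly degenerate along an `A_d0`/`τ_d0` trade-off, so
oracle agreement is asserted in objective space (the optimizer matches
or beats the grid, and polishing from the grid argmin reaches the same
minimum), not in parameter space.

## Numerical and design notes

- Determinism: every stochastic step takes an explicit seed; per-region
  and per-stage seeds are spawned from a master seed via seed sequences.
  Whole pipeline runs are byte-reproducible (checksummed in the report).
- The diversity statistic clips to [0, 1] to absorb float round-off at
  the extremes.
- `bh_adjust` rejects p-values outside (0, 1]; the posterior tail floor
  of 1/n_draws guarantees inputs are valid.
- Degenerate inputs raise informative errors: zero pooled SD, all-zero
  density vectors, non-increasing spike times, zero directional span in
  every group, inconsistent catalog counts.
- Problem sizes in the test suite: null calibration uses 50 simulated
  cohorts, effect-size recovery 100, the generator's Monte-Carlo d check
  200 two-group cohorts; these sizes give Monte-Carlo errors comfortably
  inside the asserted tolerances.

## Limitations

- The synthetic baselines are admitted stand-ins, not estimates of any
  deposited dataset; passing tests demonstrate correct and calibrated
  *methods*, not biological effect sizes.
- The generator's noise is independent across regions and animals; real
  synaptome maps have spatial and within-animal correlation, so real-data
  power will differ from the synthetic power observed here.
- The exact likelihood/priors and the "Bayesian p" of the source analysis
  are not fully specified anywhere; both engines here are documented,
  reproducible choices with the tail-probability definition above.
- The 4×4-to-11×11 spatial blending and the exact pairing convention of
  the KS comparison are design choices (documented above) where the
  source procedure is unstated.
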