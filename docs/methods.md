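# Methods

## The design and the inferential problem

A changing criterion design (CCD) measures one behaviour over `n` occasions.
After an optional baseline, a performance criterion is set and stepped
up (or down) across `I` intervention phases; experimental control is
demonstrated by the behaviour tracking the criterion steps. Because the
intervention is never withdrawn and only one treatment is in play, the
classic "randomly assign treatments to times" recipe for single-case
randomization tests does not apply directly. Two randomization schemes do:

* **Phase change moment (PCM).** The order of the criterion levels is fixed
  a priori; the *moments* of criterion change are randomized. With `m`
  intervention measurements, `I` phases and per-phase bounds
  `k_min ≤ k_i ≤ k_max`, the admissible assignments are the integer
  compositions `(k_1, …, k_I)` of `m`. When the maximum is non-binding the
  count is the stars-and-bars closed form `C(m − I·k_min + I − 1, I − 1)`.
* **BAC (blocked alternating criterion).** Phase lengths are fixed (they may
  be chosen response-guidedly); consecutive phases are paired into `B`
  blocks of two and the order of the two criterion levels within each block
  is randomized independently, giving `2^B` assignments. Mini-reversals are
  built in: a swapped block presents the more stringent criterion first.

Both tests use the mean absolute deviation pooled over measurements,

    MAD = (1/m) · Σ_t | y_t − c(t) |,

where `c(t)` is the criterion of the phase containing occasion `t`, and the
one-sided lower-tail p-value

    p = #{ r ∈ reference : r ≤ MAD_obs } / |reference|,

since a *small* MAD is evidence of criterion tracking. Under systematic
enumeration the observed assignment is a member of the reference set, so
`p ≥ 1/R` and the test is exact. Pooling over measurements (rather than
averaging per-phase means) weights each occasion equally; the two coincide
for equal phase lengths.

The baseline phase is excluded from both the randomization and the
statistic: no criterion was in force during baseline, so any comparison
level would be arbitrary, and excluding it leaves baseline length free to
be decided by stability criteria.

## Counting, enumeration, and uniform sampling of compositions

`count_randomizations` uses exact-integer dynamic programming over
(remaining sum, remaining phases); the closed form is recovered when the
maximum does not bind. `enumerate_compositions` lists the admissible set in
lexicographic order (deterministic, hence bit-reproducible reference
distributions) and refuses above a configurable cap (default 10^6),
directing the caller to Monte Carlo mode.

Uniform sampling cannot proceed phase by phase with naive bounds — early
lengths constrain later ones, and rejection sampling degenerates (for
example only 70 of the 5^5 = 3125 bound-respecting length tuples of a
19-measurement, five-phase design sum correctly). `sample_composition`
instead draws phase `i`'s length with probability proportional to the DP
count of completions of the remaining phases, which yields each admissible
composition with probability exactly `1/R`. A chi-square goodness-of-fit
test against the enumerated set (100,000 draws over the 20 compositions of
the 15/4/[3,6] design) is part of the test suite.

Monte Carlo PCM references sample compositions i.i.d. with replacement and
include the observed statistic: `p = (1 + #{sampled ≤ observed}) /
(mc_samples + 1)`, which keeps the Monte Carlo test valid. BAC references
are always systematic (`2^B` is small in practice).

## The data-generating model

The simulation engine emulates a behaviour shaped along a criterion
staircase. Criteria are `c_i = baseline_level + i · increment`
(defaults 10 and 5); with a mini-reversal, the penultimate phase steps one
increment below the phase before it and the last phase resumes one
increment above it (e.g. four phases: 15, 20, 15, 25).

Scores are Gaussian around the criterion profile:

    y_t = c(t) + s(t) · z_t,      s(t) = variability · |c(t) − baseline_level|

with `z` a single AR(1) stream spanning the whole series (serial dependence
is not reset at phase changes). Two modelling choices deserve emphasis:

* **Noise scales with the criterion's elevation above baseline**, not with
  the raw criterion level. The elevation is the size of the programmed
  behaviour change, so both signal (the steps) and noise are linear in the
  increment, and power is invariant to the increment's units — a one-unit
  staircase of frequencies and a five-unit staircase of durations are the
  same design statistically. Scaling noise by the raw level instead would
  make power depend on an arbitrary origin shift of the outcome scale and
  would break that invariance (the package's validity and power tests pin
  the elevation convention).
* **AR(1) innovations are standard normal by default**
  (`standardize_noise=False`): marginal variance `1/(1 − φ²)`, the common
  convention in single-case simulation code, under which positive serial
  dependence also inflates noise — one reason power is lowest at `φ = +.3`.
  `generate_ar1` also offers the marginally-standardised process (unit
  variance at every `φ`) for studies that want dependence decoupled from
  noise magnitude, and uses that standardisation as its own default, where
  its moment contracts (unit marginal variance, lag-1 correlation `φ`) are
  tested.

No-effect (type I error) replicates are flat: `y_t = L + variability ·
|L − baseline_level| · z_t`, where `L` is the *length-weighted* mean of the
criterion levels (the simple mean when lengths are equal), with constant
noise scale. The criterion labels are retained, so the test confronts
stepped criteria with unstepped data. `L` is always computed from the
condition's nominal phase lengths: under the null the data-generating
process must not depend on the realised randomization, otherwise the exact
validity of the test is destroyed (this is observable — letting `L` follow
the realised composition pushes the PCM null rejection rate above the
binomial band).

## Rejection-rate estimation

`estimate_rejection_rate` runs independent generate-and-test cycles.
The per-replicate *actual* assignment is realised as the design prescribes:
BAC flips a fair coin per block; PCM either keeps the actual lengths fixed
to the condition's pattern vector — the standard way a planned pattern is
treated as "the actual data", and the configuration under which
pattern-specific type I error behaviour is visible — or, with
`randomize_actual=True`, draws the composition uniformly from the
admissible set, the configuration under which the test is exactly valid and
which the validity tests use. Reference distributions are enumerated
systematically up to series length 36 and approximated by 1000-sample Monte
Carlo above. Rates are reported with the binomial standard error
`sqrt(r(1−r)/reps)`.

Phase-length patterns are deterministic: `uniform` (equal lengths),
`increasing` (first phase at the minimum of 3, surplus cycled from the last
phase backwards, giving a nondecreasing vector, e.g. 20 into 4 → 3,5,6,6),
and `triangular` (greedy pyramid fill from the centre, e.g. 19 into 5 →
3,4,5,4,3). Any deterministic rule satisfying the pattern definitions
would do; these are documented and user-overridable via explicit
`phase_lengths`.

Reproducibility: `run_condition_grid(conditions, seed)` gives condition `i`
the substream `SeedSequence([seed, i])`, so results are independent of
evaluation order and identical across runs.

Default problem sizes (1000 replications per condition, systematic PCM
references up to length 36) keep a full factorial cell under a second of
CPU; the benchmark conditions used in the acceptance script are 30-measure
designs with 32 (BAC) and 3,876 (PCM) reference assignments.

## Effect-size summaries

Grids of rejection rates are summarised by eta-squared
(`SS_effect / SS_total`, benchmarks .01–.05 small, .06–.14 medium, ≥ .15
large): one-way for main effects, and the interaction term of a two-way
ANOVA with both main effects (statsmodels, sequential sums of squares; the
grids produced here are balanced, where all SS types coincide, and
unbalanced input warns). Paired contrasts — the same conditions with and
without a reversal — use the paired-samples t and `r² = t²/(t² + ν)`,
`ν = n − 1`. Degenerate cases are pinned: constant response → η² = 0;
zero-variance differences → r² = 0 (zero mean) or 1 (nonzero mean).

## What the generator does and does not emulate

The generator reproduces the features that drive these tests' operating
characteristics: criterion-proportional noise, lag-1 serial dependence of
either sign, mini-reversals, and the three phase-length patterns. It does
not model trends within or across phases, integer/count outcomes (scores
are continuous; no rounding), floor/ceiling effects, response-guided phase
termination, or multiple tiers/participants. Passing tests therefore speak
to the procedures' behaviour under a stylised stepped-criterion process,
not to robustness against trend or bounded scales.

## Numerical choices and edge cases

* Ties in the p-value count use exact `<=` on binary floating point;
  reference statistics come from the same code path as the observed one, so
  exact ties (e.g. constant data, or criteria equal within a block) are
  reproducible and give `p = 1` in the fully tied case. No epsilon.
* Counts are exact Python integers (the DP never touches floats).
* Enumeration order is lexicographic; BAC orders are binary-counted with
  block 1 as the least significant bit, row 0 being the observed order.
* Infeasible designs (`m` outside `[I·k_min, I·k_max]`), odd BAC phase
  counts, reversals with fewer than four phases, missing scores, interleaved
  phases, and non-constant within-phase criteria are all hard errors.
* BAC designs with fewer than five blocks warn: their smallest attainable
  p-value `1/2^B` exceeds .05.
* Baseline detection in files: the first phase is baseline iff its
  `Criterion` cells are all empty; an explicit label can override. This NA
  convention is a file-format choice, not part of the statistics.

## Known limitations

* PCM systematic enumeration is capped (default 10^6 compositions); very
  long many-phase series must use Monte Carlo references, whose p-values
  carry `O(1/√mc_samples)` resolution.
* The elevation-proportional noise convention and the unscaled-innovation
  AR(1) are modelling commitments of the simulation defaults (both
  configurable); empirical CCD data may follow neither.
* Blocks of three criteria (odd phase counts), completely randomized
  criterion orders, distributed criterion designs, and response-guided
  randomization are out of scope.
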