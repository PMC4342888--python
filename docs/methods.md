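# Methods

## The experimental structure being modeled

A colony's hygienic behavior (HB) is scored in the field by the
freeze-killed brood assay: the proportions of killed sealed brood cells
uncapped (U) and cleared of pupae (R) at 24 and 48 h, from two tests a week
apart, averaged.  Antennal protein samples (three replicate pools per
colony) are quantified by triplex dimethyl labeling: each LC-MS/MS run
("block") compares three samples carrying the light/medium/heavy labels.
The analysis asks which proteins' expression tracks HB consistently across
sites, years and generations, and whether those proteins' expression levels
are themselves heritable.

## Block design

Constraints: each block holds three samples with three distinct labels; each
colony contributes three replicates, one per label, in three different
blocks; no two samples of one colony and no two colonies of one population
share a block.  A population may therefore hold at most one third of the
colonies, and at least three populations are required (a flag relaxes the
population constraint for degenerate inputs).

Objective: the phrase "minimize the variance of the HB variables" is
interpreted as minimizing the sampling variance of the estimated HB effect
in the block-adjusted linear model, i.e. maximizing the block-centered sum
of squares SSX of the HB covariate over sample slots; `design_information`
returns 1/SSX (+∞ when no block shows within-block HB contrast, in which
case the effect is inestimable).  This is what "maximizing statistical
power" requires; the literal alternative (homogeneous blocks, minimizing
within-block HB variance) is available via `criterion="within_block_variance"`.

Optimizer: random feasible initialization (random placement plus violation
repair), then greedy hill climbing over same-position colony swaps between
blocks (such swaps exchange same-label samples, so the label structure is
preserved), repeated over `n_restarts` restarts; ties break on the
lexicographic block signature, so results are a deterministic function of
inputs and seed.  Labels attach to the colony-block incidence by peeling
perfect matchings off the 3-regular bipartite incidence graph (König's
theorem guarantees a 3-edge-coloring); a colony's light/medium/heavy samples
are replicates 0/1/2 by convention.  On instances of ≤ 6 colonies the
optimizer's objective matches exhaustive enumeration of feasible incidences;
at 167 colonies a 3-restart search beats the best of 1000 random feasible
designs by ~25% (measured by the acceptance script).

## Quantification processing

* **Decoy FDR**: per block, the smallest score threshold t with
  `#decoys ≥ t / #targets ≥ t ≤ α` (plain ratio, no +1 correction), α = 1%
  by default; accepted PSMs additionally satisfy the ions-score ≥ 25
  quantification gate.  When a whole block already meets α at its lowest
  observed score, the reported threshold is the score gate itself.  Blocks
  where no threshold reaches α return an empty set with a warning.
* **Parsimony**: protein inference reports the minimal protein set covering
  all accepted peptides.  Instances with ≤ 16 candidate proteins are solved
  to the exact minimum (combination search capped by the greedy solution
  size; the first minimal cover in lexicographic order is taken, making ties
  deterministic); larger instances use the standard greedy heuristic.
  Identical peptide sets merge into one group; subset proteins are absorbed
  by the first selected superset.  Per group and block, label-pair ratios
  are arithmetic means of peptide log2 ratios (geometric mean of raw ratios,
  symmetric in label order).
* **Detection filter**: a protein is retained when present (any label) in at
  least `ceil(0.25 · n_blocks)` blocks — the ceiling convention reproduces
  "at least 10 of 38" at 25%.
* **Normalization**: natural log, then per-(protein, block) subtraction of
  the mean over present values (partial blocks centered by their present
  values; a flag drops them instead), then centering/scaling within each
  label across all proteins and blocks by median and normal-consistent MAD
  (×1.4826).  The block-mean-zero identity holds exactly in the
  block-centered state; the per-label rescaling that follows uses a
  different scale per label and therefore perturbs block means at the 1e-2
  level — the two identities are state-specific, and the state machine on
  `QuantMatrix` (raw → log → block_centered → standardized) makes that
  explicit.

## Per-protein association

Declared model: standardized expression ~ intercept + predictor + label
(fixed) [+ population when adjusting] + block random intercept, Wald test on
the predictor slope.  Because normalization already removes within-block
means, the block variance component sits at the boundary for essentially
every protein; the default engine detects this with an ANOVA moment estimate
and goes straight to the boundary solution — a fixed-effects fit in which
block enters as fixed intercepts, absorbed by within-block demeaning
(Frisch–Waugh), with one residual degree of freedom charged per present
block and an exact t-test.  Charging those degrees of freedom matters: a
fallback without block terms underestimates the residual variance exactly
where the optimized design concentrates the HB contrast, inflating the null
p < 0.05 rate to ~0.10; with block absorbed the rate is 0.047–0.052 in the
calibration runs.  A materially positive variance component (possible for
matrices that were not block-centered) triggers a genuine statsmodels
MixedLM fit with a normal-approximation Wald p-value; failed or degenerate
mixed fits fall back with a note.  The population predictor is categorical
and is tested by an ANOVA F-test (block and label absorbed), reporting the
between-population SD of means as the effect size.

Proteins present in fewer than 25% of blocks are skipped with a recorded
reason; a constant predictor raises an inestimable-effect error; a constant
response reports p = 1 without convergence.  Benjamini–Hochberg q-values are
computed per predictor over all fitted proteins (NaN p-values excluded from
the test count); BH was chosen as the Q-value procedure and is the only one
implemented.

**Known limitation** — the model contains no colony-level random effect
(each colony contributes three samples), mirroring the declared model.  When
colony-level biological variance is present, p-values are anticonservative:
at the generator's default `sigma_colony = 0.5` the realized null p < 0.05
rate is ~0.2.  Calibration checks therefore use the exchangeable
"pure measurement null" (`sigma_colony = 0`, no population offsets), which
is the regime where the test's advertised error rates hold; marker-recovery
scenarios keep the full structured generator, where the planted effects
dominate this miscalibration.

## Marker ranking and selection

Per dataset d, the HB factor of a protein is
`s_d · sign_d · (1 + b_d)/2` with `s_d = min(−log10 p_d, 10)`,
`b_d = min(|effect_d|, 2)`, and `sign_d = +1` when the effect direction
matches the protein's cross-dataset majority direction (ties positive).
The overall correlation score is the mean factor over datasets where the
protein was quantified plus the heritability factor
`max(0, slope_dam + slope_sire) · w(p_joint)` with weights 1 / 0.5 / 0.25
at p < .05 / < .5 / otherwise, from the joint regression of F1 daughter
colony expression on dam and sire levels.  These factor formulas are this
package's declared interpretation of "combining a biological and statistical
factor": unitless, direction-consistent, capped, and configurable through
`FactorConfig`; they place strong consistent markers at scores > 5.

Selection routes (thresholds are config values defaulting to the study's
printed numbers): (a) q < 0.1 in the designated reference dataset, with a
stricter `reference_strong` tag at p < 0.0005; (b) p < 0.05 for **all four**
field parameters (R24/R48/U24/U48 — "all field parameters" is read as all
four) in both first-year site datasets; (c) top-k by correlation score among
proteins quantified in ≥ 4 of 6 datasets (k = 10 by default).  The union is
returned with per-protein route tags.

## Synthetic data generator

All randomness descends from a single integer seed through numpy
SeedSequence spawning; identical seeds give bit-identical outputs.

* **Phenotypes**: latent propensity `hb_true` ~ Beta(1.5, 1.5) by default (a
  wide unimodal spread across [0, 1]; the real shape is not printed, so the
  distribution is configurable).  Each of two tests perturbs `hb_true` on
  the logit scale (SD 0.3 — repeatability is unreported, so this is a free
  parameter) and scores n = 100 cells with nested binomial draws
  (uncapped ⊇ removed, accumulating from 24 to 48 h), so the ordering
  invariants u24 ≥ r24, u48 ≥ r48 ≥ r24 hold for every draw.  Defaults: 15%
  extra uncapped-not-removed at 24 h, 50% of remaining work completed by 48 h.
* **Diallel F1**: `hb = pop_mean + h2_behavior · (midparent − pop_mean) +
  N(0, 0.08)`, truncated to [0, 1]; `h2_behavior` defaults to 0.6.
* **Expression**: log-intensity = protein baseline (N(14, 1.5²) natural-log
  units) + population offset (SD 0.2) + β·z(hb) + colony effect + block
  offset (SD 0.3) + label offset (SD 0.2) + residual (SD 0.5).  The colony
  effect (total SD 0.5) splits into an additive genetic part (fraction h2,
  default 0.4; transmitted as midparent mean plus segregation noise of half
  the founder genetic variance) and an environmental part.  Planted markers
  carry β = 0.6 per SD of `hb_true` by default.
* **Missingness**: whole (protein, block) triples drop out with probability
  `expit(−2.0 − (baseline − median))` (low abundance drops out more) plus a
  flat 8% MCAR rate — ≈ 25% of triples overall in the study scenario.
* **Heritability trios**: dams and sires carry genetic variance h2 of a unit
  total; each cross yields 4 daughter colonies (sister queens inseminated
  from one sire colony), whose mean is the observed daughter level.  The
  expected slope sum of the joint midparent regression equals h2 for any
  number of daughters; averaging 4 daughters brings the slope-sum SE at 60
  trios from ~0.17 down to ~0.10, which is what makes the h2 = 0.6 recovery
  band [0.4, 0.8] reliably attainable.  With a single daughter per cross the
  environmental share (1 − h2) is irreducible and the band cannot be met at
  this sample size — a genuine property of midparent designs.
* **PSMs**: one PSM per target peptide, score from a two-normal mixture
  (correct N(45, 8²) with probability 0.9, incorrect N(15, 7²)); each
  incorrect spectrum spawns decoy matches with odds
  `decoy_fraction : 1 − decoy_fraction` (default 0.5, emulating equal-size
  forward/reversed databases so the decoy count estimates incorrect target
  hits).  Shared peptides and subset proteins are injected at configurable
  rates.
* **Titrations**: bound probe from the exact 1:1 quadratic; competitive
  curves solve the coupled mass balance for free protein by Brent's method
  (residuals < 1e-10 of totals); fluorescence = 1000·bound, multiplied by
  lognormal noise of the requested CV; an optional micelle artifact adds
  signal above a critical concentration.

What the generator does **not** emulate: peptide sequences and their
physicochemistry, raw spectra, retention times, isotope impurity, or
Varroa-specific phenotypes.  Passing tests therefore demonstrate the
statistical machinery under the declared generative model, not performance
on real LC-MS/MS data.

## Binding constants

Saturation: with plateau guess F_sat, bound = (F/F_sat)·[P]_tot (1:1, 100%
active), free = total − bound (protein ~2 µM and K_d 1–5 µM make depletion
non-negligible, so free ≠ total), Scatchard regression of bound/free on
bound (slope −1/K_d, intercept B_max/K_d); the implied B_max recalibrates
F_sat to a fixed point (relative tolerance 1e-6, ≤ 100 iterations; the
iteration starts from 2·max(F) and converges in a handful of steps).  On
noiseless data the recovered K_d is within 0.1% of truth across 0.5–10 µM
and agrees with a direct nonlinear least-squares fit of the quadratic
isotherm to < 2%.

IC50: the competitor concentration where fluorescence crosses half the
initial (competitor-0) value, log-linearly interpolated between bracketing
points (linear when the lower bracket is concentration 0); curves that never
reach half-signal return the maximum tested concentration as a censored
lower bound.

K_D conversion: `kd_from_ic50` implements the conventional expression
`IC50 / (1 + [1-NPN]_free / K_1-NPN)` (the printed formula read with the
only dimensionally coherent grouping).  At study-like concentrations
(protein 2 µM, probe 2 µM, K_d ~1 µM) most of the competitor at the IC50 is
protein-bound, and the conventional formula — under any probe-concentration
convention — overestimates K_D by up to ~2×.  `fit_competition` therefore
defaults to an exact mass-balance conversion: at half displacement the bound
probe is half its initial value, which determines free probe, free protein
(via K_probe), bound competitor (protein balance) and free competitor
(competitor balance), giving `K_D = C_f·P_f/C_b` exactly for 1:1 competitive
binding.  The conventional conversion stays available
(`method="formula"`, `probe_mode="free"|"total"`).  With 2% fluorescence
noise the pipeline recovers a planted competitor K_d with a median error of
~4%.

## Problem sizes used in validation

The acceptance-style checks run at: 167 colonies / 5 populations (design,
vs 1000 random designs), 500 proteins × 40 blocks (normalization), 120
colonies × 500 proteins × 5 seeds (null calibration) and 50 replicates
(FDR control), a six-dataset study of ~24–44 colonies per dataset × 500
proteins × 20 replicates (marker recovery), 60 trios × 50 simulations
(heritability), 100 PSM sets and 200 parsimony instances, and the titration
grids above.  `scripts/acceptance.py` reports the same quantities with the
marker-recovery median taken over 5 study replicates and FDR over 20
replicates; all sizes are set in `beemarkers/scenarios.py`.
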