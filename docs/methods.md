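# Methods

## The problem

Steller sea lion (*Eumetopias jubatus*) pups alternate between feeding,
when the dam is ashore, and fasting, when she forages at sea.  A pup's
position on the fasting continuum can be read from two plasma markers:
blood urea nitrogen (BUN), which tracks protein catabolism, and
β-hydroxybutyrate (β-HBA), a ketone body that tracks lipid catabolism.
Over a fast these move in a characteristic sequence — recently fed or
early Phase I pups show elevated BUN with very low β-HBA; in the
protein-sparing Phase II, β-HBA rises while BUN falls; in the II–III
transition BUN climbs again while β-HBA remains elevated; in Phase III
BUN is high and β-HBA has returned toward baseline.  Classifying pups
from a single blood sample turns archived plasma into a retrospective
attendance monitor: subpopulations whose dams take longer foraging trips
show more pups deep in the fast.

## Threshold classifier

`classify_fasting_phase` implements a total, deterministic decision table
on the nonnegative (BUN, β-HBA) quadrant, with three cutpoints read from
`data/thresholds.yaml`:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| `bhba_elevated`  | 0.3 mmol/L | β-HBA at/above this is ketotic ("elevated") |
| `bun_phase2_max` | 5.0 mmol/L | with elevated β-HBA, BUN below this → II    |
| `bun_high`       | 9.0 mmol/L | BUN at/above this is "high" (III region)    |

Low β-HBA splits into Fed–I (BUN below `bun_high`) and III (at/above);
elevated β-HBA splits into II, II–III and the both-elevated Unclassified
region.  The 0.3 mmol/L β-HBA boundary is the field screening threshold
(handheld ketometer, 0.1 mmol/L resolution, with a 0.2–0.4 mmol/L
retest-by-assay band).  The two BUN cutpoints are package defaults
calibrated to the described concentration pattern and the cohort grand
means (≈5.7 mmol/L BUN, ≈0.23 mmol/L β-HBA); they are deliberately kept
in a config file, not in code, so a laboratory can substitute its own
validated cutpoints.  Boundary convention: lower bounds inclusive, upper
bounds exclusive.  An exhaustive grid test verifies that the regions
partition the quadrant with no gaps or overlaps.

Unclassified pups (both markers elevated — a data phenomenon, not a phase
on the continuum) are tabulated separately in all category tables and
merged into the Long class only for the duration model.

Duration collapse: Short = {Fed–I, II}, Long = {II–III, III,
Unclassified}.  Body condition index = mass / (−63.88 + 0.8966·standard
length); the denominator is positive only above ~71.25 cm, and shorter
animals get a flagged missing index.

## Attendance simulator

The generator exists so every downstream stage can be validated against
known ground truth.  Each pup gets an attendance timeline (perinatal
period, then alternating lognormal foraging trips and shore visits,
truncated below at 0.5 h), a fasting clock read at capture, a true phase
from piecewise hour cutpoints, and metabolite draws around phase-specific
means with lognormal noise.

Baseline regime (typical, unstressed): perinatal 9 d; trips 14 ± 6.5 h;
visits 24 ± 8 h.  Phase cutpoints 16 h (Fed–I→II), 48 h (II→II–III,
an interpolation — no published timing anchor exists for this transition,
only the 16 h entry into Phase II and Phase III entry within a 2.5-day
fast), 60 h (II–III→III).  Concentration means (mmol/L): BUN 6.0 / 3.5 /
6.5 / 10.5 and β-HBA 0.10 / 0.55 / 0.45 / 0.15 for Fed–I / II / II–III /
III; CVs 0.18 (BUN) and 0.25 (β-HBA).

A single mechanism differentiates subpopulations: with per-subpopulation
probability `long_fast_inflation`, a pup's dam follows a stressed regime
(trips 50 ± 18 h, visits 12 ± 4 h) and the pup follows an accelerated
trajectory (II→II–III from 24 h, III from 56 h).  The acceleration
mirrors the physiology of lean pups under repeated long fasts: limited
lipid reserves end the protein-sparing phase early.  Without it, a
stationary attendance cycle mathematically cannot produce Long-fast
proportions above ~0.15 while keeping Phase III rare, because the II–III
hour window occupies at most a small fraction of any cycle.  Female pups
get the stressed-dam probability scaled by 1.3 (capped at 1), encoding
the sexually dimorphic provisioning that makes female pups slightly more
likely to be caught in Long fasts.

The stock design (`default_design`) fixes the study conditions: 12
subpopulations, 1528 pups, 54:46 male:female, birth dates uniform over a
six-week window, capture events of ~20 pups in July–August.  Sample sizes
per subpopulation were chosen so that estimate precision matches the
reported interval widths (e.g. 50 pups in the western Aleutians, 230 in
southern Southeast Alaska), and the inflation weights were calibrated
once against the reported composition: grand Fed–I ≈ 0.72, Phase II
≈ 0.09, II–III ≈ 0.16, III ≈ 0.04, with Long-fast proportions ≈ 0.36
(western Aleutians), ≈ 0.27 (central Aleutians), ≈ 0.32 (southern
Southeast Alaska) and ≈ 0.10 (eastern Aleutians).  `calibrate_long_fast`
exposes the calibration: the Long probability is linear in the inflation
weight, so Monte-Carlo estimates of the two regime endpoints solve for
the weight directly; the stressed regime saturates near P(Long) ≈ 0.37.

Seeding: one integer seed spawns a `SeedSequence` child per
subpopulation; pups are drawn sequentially within a child, so identical
designs give byte-identical tables and any subset of subpopulations
reproduces independently.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: interannual variability, pup adiposity as a
continuous state (acceleration is binary), metabolite turnover dynamics
around feeding (post-prandial kinetics are instantaneous here), assay
batch effects, and any correlation between body condition index and
fasting state (BCI is drawn independently, so the duration model's BCI
term is truly null in simulation).

## Assay QC

Responses become concentrations through a four-parameter logistic
standard curve y = d + (a−d)/(1+(x/c)^b), fitted by bounded nonlinear
least squares with log-spaced multistart on the inflection c (the b > 0
bound excludes the (a,d,b) ↔ (d,a,−b) mirror solution).  Inversion is
defined strictly between the asymptotes; out-of-range responses exclude
the sample with a reason code.  Technical replicates pass at CV ≤ 10%
(sample standard deviation, n−1; boundary inclusive), with exactly one
repeat assay permitted before exclusion — the repeat count is bounded for
determinism since no limit is documented.  Moderate/severe hemolysis
excludes a sample outright.  The standards layout and repeat policy are
config-exposed.

## Statistical battery

Proportion comparisons use the sampling event (rookery × date, minimum
five pups) as the replicate unit: the tests compare event-level
proportions, not pups, because pups within an event share an attendance
history.  A rookery-year grouping is available via the `by` argument
where a coarser replicate is preferred.

* **Kruskal–Wallis** with mid-rank tie correction; p from the χ²
  approximation, or by exact enumeration of all group assignments for
  pooled n ≤ 10 (the asymptotic p is unreliable at event-level sample
  sizes).  All-identical data returns H = 0, p = 1.
* **Dunn post hoc** z tests with pooled-rank variance and tie correction;
  Bonferroni multiplier m = C(k, 2) over all pairs.
* **July-19 gate**: before late-season samples enter the analysis, each
  subpopulation's event-level Fed–I proportions are compared before vs
  strictly after July 19 (the documented inflection in dam trip
  durations); "post" means July 20 onward of any year.
* **Binomial duration model**: logit P(Long) with main effects BCI,
  subpopulation, sex, July-19 timing and all two-way interactions in the
  global model.  Backward selection removes the least-significant
  removable term by likelihood-ratio test (α = 0.05), interactions before
  their main effects; LRT degrees of freedom use design-matrix ranks so
  aliased columns in unbalanced designs are handled.  Separation (a cell
  all-Short or all-Long) is detected from fitted probabilities and
  extreme coefficients and flagged with a warning rather than silently
  reported.
* **Marginal means**: per-subpopulation linear predictors averaged over
  sex at equal 0.5/0.5 weights ("corrected for sex"; observed-frequency
  weights available by flag), other covariates at their mean/mode;
  Wald CI on the linear predictor back-transformed through the inverse
  logit, so estimates and bounds stay in (0, 1).
* **Tukey all-pairs contrasts** on the linear-predictor scale with
  single-step max-|z| adjustment: adjusted p is the tail probability of
  the maximum absolute z over the whole family under its joint normal
  law, evaluated by Monte Carlo (eigendecomposition of the contrast
  correlation matrix, 40 000 draws, fixed seed) — deterministic given the
  seed, exact two-sided normal p when the family has one member.
* **Sex ratios**: Pearson χ² without continuity correction per fasting
  category (subpopulation × sex), plus a goodness-of-fit test of the
  pooled ratio against 50:50; expected cells below 5 are flagged.

## Numerical and validation choices

Rank statistics are checked against independent brute-force oracles
(direct textbook formulas, full permutation enumeration) and against
scipy's reference Kruskal–Wallis; the GLM is checked against closed-form
log-odds of saturated contingency tables.  Marginal-mean CI coverage is
verified at 93–97% over 500 simulated replicates (200 pups per
subpopulation).  The Tukey family-wise error rate is verified at ≈ 0.05
over 1 000 null replicates of a 12-level design at 250 pups per level —
cell sizes where the Wald statistics the single-step method references
are near-normal; the same adjustment applied to exact joint-normal draws
attains the nominal level, so smaller-sample deviations are Wald
conservatism, not adjustment error.

## Limitations

The classifier's BUN cutpoints are calibrated defaults, not
laboratory-derived values; any deployment against real assay data should
substitute validated cutpoints in the thresholds config.  The simulator's
two-regime attendance mixture is a caricature of continuous variation in
trip durations; it reproduces the marginal composition and subpopulation
contrasts of a real cohort but not the full dependence structure.  The
pipeline deliberately makes no interannual inferences: sampling across
years is discontinuous and unbalanced, and no time-series machinery is
provided.
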