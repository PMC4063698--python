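# Methods

## The staging scheme as a combinatorial object

A staging scheme is an ordered table: eleven disc stages (A–K, nominal
times 0, 5, 10, 15, 20, 25, 30, 35, 40, 46 and 49 h after the
third-instar moult at 25 °C) by six gene products (Ac, Sens, Dac, Ct, N,
Wg), each cell an integer gene-specific stage.  Stage 0 encodes "not yet
expressed", so the combo is a total function even at the moult, where
Ac, Sens and Dac show nothing and Wg is the informative marker.  The
structural invariants enforced at load time are: unique stage labels;
strictly increasing nominal times; per-gene monotone non-decreasing
stages (patterning only advances); and pairwise-distinct full six-gene
combos.

The packaged table (`data/scheme_synthetic.tsv`) is a **synthetic
reconstruction**: its cell values were chosen once to satisfy the
scheme's documented structure — all six genes resolve the eleven
stages; Ac and Sens alone resolve nine (they merge F/G and I/J); adding
Dac separates I from J but not F from G, so the Ac/Sens/Dac panel
resolves ten with exactly the F/G pair merged; and the first Ac
transition occurs between the 5 h and 10 h stages.  The test suite
asserts these structural facts against whatever table is loaded, so a
re-transcription from the original figure panels can be dropped in
without code changes.

Marker-subset *distinguishability* partitions stages into classes with
identical restricted combos.  It is monotone (adding markers never
decreases the class count) and always a partition; both properties are
property-tested over random marker subsets.

## Permutation simulation

Real discs carry at most two scored genes, so per-gene empirical
marginals at a (condition, time point) are resampled — independently
per gene, with replacement — into `n` simulated fully-stained discs
(default 1000, the study's population size).  Independence across genes
is the modelling assumption that makes the simulated joint the product
of marginals; the tests check simulated marginals by chi-square
goodness of fit (α = 0.001, ≥95/100 seeds) and pairwise joint
frequencies against the product of marginals within 3 binomial standard
errors per simulation.  Time points are keyed by exact dissection time
plus an event override: wandering and pupariation discs group by event
label because wandering spans several hours.

## The classifier

A categorical Naive Bayes classifier is trained **on the scheme
itself** — one canonical exemplar per stage — not on dissected-disc
frequencies: the scheme is the staging authority and this choice
reproduces the documented deterministic behaviours (see below).  The
prior is uniform over the eleven stages (no stage privileged a priori).
The conditional for gene *g* at stage *s* puts mass
`(1[v = canonical] + α)/(1 + α·K_g)` on each value *v* of the gene's
modelled support (0 … the gene's maximum scheme stage, `K_g` values),
with Laplace weight α = 0.5 by default so that combos matching no
single stage still receive a defined posterior; α = 0 recovers
point-mass conditionals.  Values outside the modelled support
contribute zero likelihood.

Numerical decisions:

* **Tie rule.** Posteriors within 1e-12 of the maximum are tied; ties
  resolve to the lowest-rank (earliest) stage.  This is what collapses
  stage G onto F under the Ac/Sens/Dac panel, where the two stages
  share their canonical combo — the acceptance suite verifies the
  collapse is total (100% of simulated stage-G discs → F).
* **All-zero fallback.** At α = 0 a combo can zero out every stage; the
  classifier then assigns the earliest stage at minimum Hamming
  distance to the canonical combos (verified against exhaustive
  search).
* **Vectorisation.** `classify_set` classifies whole simulated
  populations with array indexing and is tested element-for-element
  against the scalar path.
* **Seeding.** One master seed; per-(condition, time point) child
  streams derive via a CRC-keyed `SeedSequence`, so results are
  independent of processing order and reproducible across platforms.

Posteriors are verified against an independent brute-force Bayes
enumeration over all 504 enumerable Ac/Sens/Dac combos to 1e-12.

## Time normalisation and milestone alignment

Relative developmental time is dissection time divided by the
condition's mean pupariation time; wandering discs use the condition's
mean wandering time, pupariation discs map to exactly 1, and slight
overshoots clamp to 1 with a warning.  Event-time means for the study's
seven conditions ship as a packaged CSV (confidence bounds optional and
left empty).

Alignment at a milestone is judged by a transparent two-part criterion:
equal modal stage **and** total-variation distance ≤ 0.25 (configurable)
between the stage distributions.  The criterion replaces visual
bubble-overlap judgement with something testable; it is symmetric, and
between milestones rows are matched by nearest relative time without
interpolation (stage distributions are categorical).

## Sens-vs-Ac coupling

For each Ac stage with at least two co-scored discs in both conditions,
Sens stages are compared with a two-sided Wilcoxon rank-sum test:
exact permutation enumeration when both groups have ≤8 observations
(small, heavily tied samples), otherwise the tie-corrected normal
approximation with continuity correction (scipy's implementation).  If
every pooled observation is identical the p-value is 1 by construction.
The Holm family is the set of Ac-stage comparisons within one condition
pair; the step-down adjustment is authored in-package (sort ascending,
multiply the i-th smallest by m−i, enforce monotonicity, cap at 1) and
cross-checked against statsmodels and a hand-computed reference.
Significance is adjusted p < 0.01.

## The synthetic-cohort generator

The generator emulates the study's sampling design, not its biology: no
ecdysone dynamics, growth or temperature per se — conditions differ
only in timing parameters.

* **Latent progression.** A monotone curve on relative time.  Anchored
  (the milestone hypothesis): identity plus a piecewise-cubic
  deflection (Hermite knots at 0, 0.5, 1 with zero slopes) peaking at
  `progression_lag` mid-instar; monotone for |lag| < 1/3, larger lags
  raise.  Unanchored (lock-step hypothesis shifted): `clip(t + lag, 0,
  1)`, so a lagged cohort misses the final stage at pupariation.
* **Disc emission.** A disc's true stage is the scheme stage whose
  nominal relative time is nearest to the latent value plus Gaussian
  disc-level jitter (`noise_sd`, default 0.03 of the instar — enough to
  spread discs over one-to-two neighbouring stages, the within-time-point
  variability scale seen in staged material).  Scored genes take the
  scheme's canonical values at the true stage; jitter acts on the
  whole-disc latent axis, not per gene.
* **Milestone convergence.** Anchoring pins the curve *and* the
  scatter: within `anchor_window` (default 0.05 relative time) of an
  anchored milestone, jitter attenuates linearly to zero, because
  anchoring means patterning converges at the milestone — anchored
  cohorts are exactly at stage A at the moult and stage K at
  pupariation, matching the generator's declared ground truth.
  Wandering (relative time ≈ 0.94, outside the window) keeps full
  jitter, so wandering remains variable and is not a milestone in the
  generated data.
* **Sampling design.** Per time point, each staining group (Ac+Sens
  co-scored; Dac and Wg singly, by default) receives an independently
  drawn 5–16 discs, the study's per-gene range.  Byte-identical output
  under a fixed seed.

What the generator does **not** emulate: per-gene decoupling within a
disc (available via custom pairing rules but off by default), real
inter-disc correlation structure, scorer error, and the empirical
within-time-point stage distributions of the archived data set.
Passing the recovery tests therefore shows the *pipeline* detects the
structures it is meant to detect under the study's sampling design —
not that any particular biological data set contains them.

## Problem sizes

Defaults mirror the study design: 1000 simulated discs per time point,
5–16 observed discs per gene per time point, eleven (baseline) time
points.  The self-validation experiments use 100 simulator seeds and 50
synthetic-cohort replicates (baseline vs a slow cohort, pupariation at
60 h, mid-instar lag −0.15), reporting recovery rates of the known
milestone structure; the whole validation suite runs in seconds.

## Known limitations

* The packaged scheme's cell values are a consistent reconstruction,
  not a transcription of the original panels; all structural claims are
  asserted, cell values themselves are not data.
* Training the classifier on scheme exemplars means assignment
  probabilities reflect scheme geometry plus sampling noise, not
  empirical stage confusability; frequency-trained conditionals are
  deliberately out of scope.
* The alignment criterion's total-variation threshold (0.25) is a
  declared convention; verdicts near the threshold should be read with
  the distance, which is always reported alongside.
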