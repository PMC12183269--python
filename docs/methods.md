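# Methods

## The experiment being modelled

A factorial greenhouse trial on quinoa: five genotypes whose seed
populations originate at 19, 29, 34, 35 and 39 °S (the two northern ones
Salares ecotype, the three southern ones Lowlands), each grown with its
native fungal endophyte community intact (E+) or removed (E−), under
daily watering at 0, 200 or 400 mM NaCl, with 12 replicate plants per
genotype × status × salinity cell (360 plants) in a randomised block
layout. Measured responses: dark-adapted chlorophyll fluorescence
(Fv/Fm), final survival, thousand-seed weight (TSW), soluble seed protein
(Bradford), and *CqNHX1* expression relative to *EF-1α* (qRT-PCR, five
biological replicates per condition).

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream claim is checked.

**Noise families** respect each trait's support: Fv/Fm is logit-normal
(support (0, 1)); per-100-seed mass and protein concentration are
lognormal (strictly positive); Ct values are Gaussian, clipped to a
plausible 10–40 cycle window; survival is Bernoulli on a logistic scale.
Raw fluorescence is emitted as an (Fm, F0) pair with Fm ~ N(30000, 2000²)
instrument counts and F0 = Fm·(1 − Fv/Fm), so Fm > F0 > 0 holds by
construction.

**Effect geometry.** Every endophyte effect enters a latent (logit or log)
scale as `benefit × s × shape(latitude)`, where `s = NaCl/400` is the
relative dose. Tolerance traits (survival, Fv/Fm, NHX1 induction) use a
southward *decay* shape `max(0, 1 − 0.045·(lat − 19))`; seed-quality
traits (seed mass, protein) use a southward *ramp* `(lat − 19)/20`. Because
every benefit is multiplied by `s`, the E+/E− difference is exactly zero in
expectation at 0 mM — the no-cost-under-control property — and the
`neutrality_gap` audit enforces a configurable bound on it.

**Calibration.** The survival logistic is anchored analytically: base
logit 3.0 at 0 mM (97.5 % survival), salt coefficient −(3 + ln 3) so the
E− probability at 400 mM is exactly 1/4, and benefit ln 15 so the E+
probability at 400 mM and 19 °S is exactly 5/6 — the 83.3 % vs 25 %
severe-stress contrast at the northern origin. Fv/Fm starts at
expit(1.586) ≈ 0.83 (the canonical healthy-leaf value) and loses 0.9 logit
units at full dose; seed mass (0.30 g per 100 seeds, i.e. TSW 3 g) and
protein (7 concentration units, matched to the Bradford standards so the
÷10 scaling lands in [0, 1]) decline under salt and gain an E+ benefit that
grows southward. NHX1 is induced 1.5 log2 units by full-dose salt plus up
to 1.0 log2 unit of E+ benefit decaying southward. No measurement-error
magnitudes are reported for the original assays, so the noise SDs (0.15
logit for Fv/Fm, 0.08 log for seed and protein, 0.2 cycles for Ct) were
chosen once as values typical of these instruments; under them the
simulated group contrasts have the same order of magnitude as the published
ones (composite contribution ≈ 20–24 percentage points at 19 °S / 400 mM,
single digits at mid-southern latitudes, near zero in controls).

**What the generator does not emulate:** spatial/temporal greenhouse
structure beyond an optional additive block term (default SD 0 — plants
were rotated), genotype-specific baseline differences other than through
latitude, correlated measurement error across traits of one plant,
qPCR technical replicates or plate effects, and any mechanistic link
between survival and the traits of surviving plants (no selection bias in
survivor trait distributions). Passing tests therefore demonstrate the
*estimators and inference machinery*, not the biology of any particular
dataset.

**Randomness.** One root seed; the design, trait and qPCR stages draw from
`SeedSequence(seed, spawn_key=(k,))` substreams, recorded in
`manifest.json`. Identical seed + config ⇒ byte-identical CSVs (readers
must use `float_precision="round_trip"`, as `endosym.pipeline.read_table`
does).

## qPCR quantification

Livak fold change 2^−ΔΔCt and the Pfaffl efficiency-corrected ratio
E_t^ΔCP_t / E_r^ΔCP_r are both provided and labelled; at efficiency 2 they
agree to machine precision. The calibrator condition is, by default, the
same genotype's E− 0 mM group (configurable): this makes "relative fold
expression" read as the endophyte × salinity response of each genotype.
Per-replicate ratios are computed against the *replicate-mean* calibrator
ΔCt (not replicate-to-replicate pairing), because results are reported as
mean ± SD of biological-replicate ratios. Efficiencies come from the input
table; no standard-curve estimation is implemented. Common Ct shifts cancel
in both estimators (scale equivariance), which the suite checks.

## Traits

- Fv/Fm = (Fm − F0)/Fm; inputs must satisfy Fm > F0 > 0.
- Survival % is computed in exact rational arithmetic (`fractions`) before
  the final float conversion, so S = N gives exactly 100.
- TSW = 10 × mean of the 100-seed sample masses (8 samples per plant by
  default; any positive count accepted). Rounding to the 0.01 g balance
  precision is left to reporting.
- Bradford protein fits A₅₉₅ = a + b·C to ≥ 3 BSA standards by least
  squares (`numpy.polyfit`), inverts for unknowns, applies the dilution
  factor, reports R², and flags (without rejecting) absorbances outside the
  standards' range. A quadratic saturation model was considered and left
  out: the synthetic read-out is linear and the linear fit is the assay's
  standard first-line treatment.
- Group summaries average Fv/Fm over **all** plants (fluorescence precedes
  death) but TSW and protein over **survivors only**; a group with zero
  survivors reports NaN yields — missingness is informative and is never
  silently imputed.

## PR and RECI

PR is computed on genotype × status × salinity **group means**, not per
plant, because survival exists only at group level. Scaling divisors
default to survival ÷ 100, TSW ÷ 10, protein ÷ 10, Fv/Fm ÷ 1; all are
configurable and recorded in output. Components that scale outside [0, 1]
are flagged in the output `flags` column, never clamped. The weighted sum
uses a fixed pairwise summation order, `(w₁c₁ + w₂c₂) + (w₃c₃ + w₄c₄)`,
so the default weights on unit components give exactly 1.0 in binary64.
RECI is the PR difference in percentage points; it is antisymmetric under
E+/E− swap and bounded by ±100 when components are in range.

Two deliberate policy choices: (1) the seed-biomass component is
thousand-seed weight (the measured yield proxy), with the column choice
exposed; (2) when one arm of a cell has zero survivors, its seed and
protein components are set to 0 — a dead group yields nothing — and the
row is flagged `extinct:`; setting `extinct_yield_is_zero=False` restores
strict propagation as a `MissingComponentError`.

## Trend inference

Each genotype contributes exactly one latitude, so a per-genotype random
effect is confounded with the latitude regressor; mixed-model machinery
adds nothing identifiable here. Instead:

- **Slopes** are closed-form OLS on genotype-level means (5 points per
  endophyte × salinity group), with the usual t test of slope = 0.
  Degenerate edges are defined: zero residual variance gives SE 0, p = 1
  for a zero slope and p = 0 otherwise.
- **Contrasts** between the 6 groups (15 pairs) use pooled SEs
  √(SE_a² + SE_b²) with n_a + n_b − 4 df and Holm adjustment — chosen over
  studentized-range (Tukey) machinery as the simpler, more conservative
  option; the adjustment label is written into the output. A compact letter
  display is built greedily in display order (E+ before E−, ascending
  salinity): a group joins every letter class whose members it does not
  differ from, guaranteeing that groups sharing a letter are pairwise
  non-significant.
- **Permutation inference** for the E+/E− slope difference reshuffles
  symbiotic-status labels among the plants of each genotype (labels never
  cross genotypes), preserving per-genotype group sizes; the p-value is the
  add-one estimator (1 + #{|T*| ≥ |T|})/(1 + n_perm) with n_perm ≥ 99
  (default 499 in the pipeline). Under the null generator its type-I error
  at α = 0.05 is within Monte-Carlo error of the nominal level (checked
  over 500 simulated experiments at a reduced size of 3 genotypes × 6
  replicates, chosen so the check completes in seconds).
- **Residual normality** is reported as the Filliben probability-plot
  correlation with a configurable critical value (default 0.879, the ~5 %
  point at n = 5). It is a flag only and never gates the analysis.

Expression (nhx1) has no plant-level record — it is assayed on pooled
biological replicates — so it receives slope fits and contrasts but no
plant-level permutation test.

## Pipeline

`RunConfig` is a versioned pydantic schema (`extra="forbid"`: unknown keys
are rejected before any stage runs). Stages run in order simulate →
quantify → summarize → score → trend → report; every intermediate table is
persisted as CSV with a one-line provenance header (`# endosym run
<config-hash>`), and failures abort with the stage name. Plain CSV + JSON
were preferred over binary formats: the data are desk-scale and
diff-friendliness matters more than disk economy.

## Problem sizes

The test suite and the acceptance script run Monte-Carlo studies at sizes
chosen for tight feedback loops: 100 full-design experiments for the
slope-sign study, 100 reduced-size (3 genotypes × 6 replicates) null
experiments for the RECI centre, 200 full-design experiments for the
survival/RECI summaries, and 300–500 null experiments × 199 permutations
for the type-I error study. At these sizes the Monte-Carlo standard errors
are comfortably below the decision thresholds they feed.

## Known limitations

- The composite-index calibration targets reported *group contrasts*; the
  original per-plant raw data are not public, so absolute agreement with
  the published index values is not a testable claim, and the printed
  values serve only as order-of-magnitude anchors for the generator.
- Genotype is fully confounded with latitude (5 genotypes, 5 latitudes, one
  ecotype boundary); "latitude slope" is a descriptive cline over
  genotypes, not a causal estimate.
- The permutation test assumes E+/E− exchangeability within genotype under
  the null; informative cluster sizes or heteroscedastic arms would violate
  it.
- The greedy compact-letter algorithm can, for adversarial significance
  graphs, use more letters than the minimal clique cover; letters remain
  sound (shared letter ⇒ no significant difference).
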