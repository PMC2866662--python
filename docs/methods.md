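# Methods

This note documents the models implemented in `simplexscreen`, the defaults
and their provenance, the synthetic-data generator's assumptions, and the
numerical choices made where the protocol leaves the design open.

## Limiting-dilution occupancy and MPN estimation

Template molecules are deposited into wells as independent Poisson(λ)
counts. The package treats λ (molecules/well at a reference reaction
volume, default 5 µL) as the design variable: `occupancy_pmf` gives the
occupancy distribution with the truncated tail mass reported separately,
and `multi_gene_fraction` the conditional P(k≥2 | k≥1) — the fraction of
occupied wells whose signal is an average over multiple genotypes. The
default design point λ = 2.3 leaves e^−2.3 ≈ 10% of wells empty; both
directions (λ → empty fraction and empty fraction → λ) are exposed.

Amplification of a well is treated as a deterministic indicator of ≥ 1
template molecule (no PCR-efficiency model). The zero-class/MPN estimator
is λ̂ = −ln(1 − f) with f the amplified fraction; its confidence interval
is a Clopper–Pearson binomial interval on f transformed through the same
map, chosen because it remains sensible at f near 0 and 1. A fully
amplified plate (f = 1) has no point estimate; the estimate is flagged
saturated and only the one-sided lower bound is reported.

`AmplificationTable.n_amplified` accepts real values so a series published
only as percentages can be analysed directly; the binomial likelihood then
acts as a quasi-likelihood. The default 31 wells per series row is a
96-well plate divided into thirds minus three no-template controls.

The graded-volume consistency check fits one concentration c to all rows,
f_i = 1 − e^(−c·V_i), by maximum likelihood (bounded scalar minimisation of
the negative log-likelihood, bracketed by the per-row MPN estimates) and
compares it to the saturated per-row model with a likelihood-ratio statistic
on (rows − 1) degrees of freedom. With ~31 wells per row the χ² reference is
an approximation; its type-I error is verified by simulation in the test
suite (within 3 SEs of nominal at α = 0.05 over 1000 tables).

`plan_dilution` does the serial-dilution logarithm arithmetic (default step
1001×, i.e. 1 µL into 1 mL) with the final step adjusted to land exactly on
target. Adsorptive template loss is not modelled mechanistically (the wet
protocol suppresses it chemically); a per-step recovery factor (default 1.0)
is available.

## Oxygen deactivation

Residual activity after exposure to V µL of air-equilibrated buffer is
modelled as R(V) = exp(−k·V). The exposure volume is the dose variable
because the O₂ concentration profile during the 10-minute incubation
(diffusion into the anaerobic atmosphere, scavenging by the extract) is
operationally unknowable; the dissolved-O₂ bookkeeping (µL × mM = nmol,
default 0.25 mM) is reported alongside but never enters the fit.

The intercept is pinned to R(0) = 1 by default, because residual activities
are already normalised to the unexposed slope; a free-intercept variant and
a nonzero-asymptote variant R(V) = (1−c)e^(−kV) + c are selectable but off
by default (complete O₂ removal is observed after incubation and no
oxygen-tolerant fraction has been seen). Fitting is nonlinear least squares
on the linear scale — log-linear regression would amplify noise at small
residuals — with a log-linear fallback behind a flag. Non-positive residual
activities are excluded with a warning (their logarithm is undefined and
they carry no information about k under multiplicative noise). An all-ones
curve returns k = 0 with a boundary flag.

The exposure volume for a target residual is the closed form
V\* = −ln(R\*)/k. The default decay constant in the simulator, k = 0.12/µL,
puts the protocol's 15 µL exposure at exp(−1.8) = 16.5% residual activity,
inside the 15–20% operating band.

## Methyl viologen assay

The A578 slope is fitted by ordinary least squares over the full trace
(default; a maximal-R² initial-window selector exists for saturating
traces). Traces need ≥ 3 points; R² < 0.9 flags nonlinearity. The
conversion coefficient 9.78 is treated as a lumped, path-length-inclusive
constant in AU per mM of reduced MV, so rate(mM/min) = slope(AU/min)/9.78;
it is configurable because whether it assumes a 1 cm path is unspecified.
Stoichiometry: 2 single-electron MV reductions per H₂ (`electrons_per_h2`
exposed). Sign convention: H₂-consumption slopes are positive; negative
slopes are kept but flagged background-dominated.

Specific activity is rate/protein-mass. Because the matured (active)
fraction depends on expression level, `fold_improvement` refuses to compare
samples whose protein yields differ by more than ±25% (configurable).
Radiolabel-counting chemistry is out of scope; a pure-arithmetic helper
converts counts to ng with every parameter user-supplied.

## Synthetic campaigns

The generator states a world and the analysis is tested inside it:

- **Library.** Mutants carry 2–10 DNA mutations (uniform). Effects are
  multiplicative factors on wild-type activity and on the decay constant.
  Defaults: 70% of mutants inactive (activity factor 0) — a realistic
  attrition for a complex metalloenzyme under heavy mutagenesis — active
  mutants' factors lognormal (median 1, log-SD 0.3), tolerance factors
  lognormal (median 1, log-SD 0.05). These distributions are invented
  stand-ins: the real effect spectrum is unknown. The tolerance default
  makes screen-detectable improvements (factor ≲ 0.8) vanishingly rare
  (~4·10⁻⁶), mirroring the empirical outcome that activity hits occur but
  tolerance hits do not; rare ~4× activity improvements do arise at
  campaign scale.
- **Plates.** Default layout per 96-well plate: 8 wild-type controls, 2
  no-template, 2 CAT controls, 84 sample wells (control counts are a
  package choice; every plate must carry wild-type controls because the
  analysis normalises to them). Sample wells draw Poisson(λ = 2.3) gene
  counts; members are drawn from the library with replacement. A well's
  true pre-exposure activity is the **mean** of its members' activities —
  the signal averaging that dilutes a good mutant sharing its well — and
  each member decays with its own tolerance factor:
  post = mean_i(a_i · exp(−t_i·k·V)).
- **Anchors.** Wild-type specific activity 150 pmol H₂/min/ng, CFPS yield
  40 ng/µL (so 6000 pmol H₂/min per µL CFPS product), k = 0.12/µL, 15 µL
  exposure, 5× post/pre volume factor.
- **Noise.** Measurement error is multiplicative lognormal per read
  (mean 1), CV-parameterised, because replicate precision is reported as a
  CV. Yield variation and read noise are separately lognormal but only
  their combination is identifiable from single reads; the configured
  replicate CV (default 0.20, inside the observed 15–25% band) is split
  evenly: each read has CV/√2 noise — making the pre/post ratio CV across
  wild-type replicates equal the configured CV — and CFPS yield has CV/√2
  variation, which cancels in the ratio (pre and post assay the same
  synthesis product) but gives single pre-exposure reads a replicate CV of
  ≈ CV as well.
- **Background.** Every read carries an additive floor of 5% of the
  wild-type pre-exposure signal (extract drift, what negative-control wells
  show). This floor is why empty and inactive wells have ratios near 1 —
  the noise-inflation that the QC cutoff exists to remove — and why QC must
  sit above the background band.
- **Traces.** `generate_trace` pushes an activity backward through the
  Beer's-law chain to a slope, adds Gaussian read noise (default 0.002 AU)
  over 13 points/2 minutes, and clips slopes that would reduce more than
  the 2 mM MV pool during the read (saturation flag).

What a green simulator-based test does *not* establish: correctness under
spatial plate effects (edge evaporation, thermal gradients), drift within a
read, non-lognormal error, PCR failure modes, or any genotype→phenotype
structure beyond the stated effect distributions.

## Hit calling and power

The tolerance score is (post/5)/pre. QC disqualifies wells whose
pre-exposure activity is below 25% of the plate's wild-type mean — the
protocol states the existence of a cutoff but not its value; 25% is the
package default, chosen to sit above the 5% background band with room for
noise, and is configurable. A well exactly at the cutoff passes.

Scores are normalised per plate to the wild-type control mean; thresholds
(mean + 2·SD, strict inequality, one-tailed) are computed from wild-type
controls only, per plate. Pooling across plates exists behind a flag but is
off by default because replicate experiments show between-day drift. No
multiple-testing correction is applied by default: the 2-SD rule is a
triage threshold with downstream re-testing, not a hypothesis test (a
Bonferroni option exists). With only ~8 wild-type wells per plate the SD
estimate is noisy, so realised per-plate false-positive rates scatter
around the nominal tail.

The detectability arithmetic: the minimal detectable improvement is
m·CV (m the SD multiplier), the improvement whose expected score sits
exactly at the threshold. `power_curve` verifies this by Monte Carlo.
Its default noise is Gaussian-multiplicative (symmetric), under which
detection probability at m·CV is exactly 50%; with lognormal noise the
right-tail skew raises the null per-tail rate above the Gaussian 2.28%
(to ≈ 3.6% at CV 20%) and shifts the curve slightly. Noise SD scales with
the mean score, so power approaches Φ(1/CV), not 1, as the improvement
grows.

## Numerical and interface choices

- All randomness flows from a single seed per entry point;
  `run_pipeline` spawns per-stage seeds via `numpy.random.SeedSequence`
  and its outputs are byte-identical across reruns of the same config.
- Comparisons with two-decimal reference dilution-series estimates use
  ±0.005 on the rounded scale.
- Plate coordinates are letter-row/number-column (A1..H12, A1..P24),
  case-insensitive in, uppercase out. Times are seconds in files; rates
  are per minute. CSV for inputs, TSV for result tables, JSON for
  summaries; result files carry the config hash and seed in a header line.
- Degenerate cases: zero wild-type variance makes the threshold equal the
  mean (flagged); plates with < 2 usable wild-type controls are rejected
  with an explicit error; all-zero or all-saturated amplification tables
  raise a degenerate-fit error.

## Known limitations

- No mechanistic O₂ transport/consumption model; exposure volume is the
  only dose variable, as in the protocol's own operational definition.
- No spatial plate-effect correction (B-score/median polish); wild-type
  normalisation is the only batch correction, matching the protocol.
- The simulator's effect distributions are stand-ins; power estimates
  against them characterise the pipeline, not any real library.
- MPN inference assumes perfect amplification of ≥ 1 molecule;
  contamination and PCR failure are outside the model.
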