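# Methods

## Data model

Counts from a targeted hybridization panel are held as a probes × samples
matrix with a processing-stage tag (`raw → pc_normalized → calibrated →
attenuation_corrected → fully_normalized`); stage transitions are only
allowed in that order, so a half-normalized matrix cannot silently enter a
fit. Probes carry a class (endogenous, positive control, housekeeping)
and an attenuation flag/factor; samples carry treatment, minutes since the
T0 addition event, experiment (ST = 6 h dense grid, LT = 22 h grid),
plate, lane, replicate, RNA input and a reference-lane flag. All times are
minutes internally; the decay model's slopes are per minute.

## Normalization

Four multiplicative stages, each recorded in a factor audit trail:

1. **Positive controls.** Per sample *s*, g(s) is the geometric mean of
   the three positive-control probes with the largest mean count ("top 3"
   is not defined more precisely by the assay convention; the
   highest-concentration spike-ins are the least noisy, so they are used).
   Every count of *s* is multiplied by mean(g)/g(s). After this stage the
   top-3 geometric means are equal across samples to float precision.
2. **Reference lane.** Each plate carries one lane loaded with the same
   1:1 high:low calibration mix. For each endogenous/housekeeping probe
   *p* and plate *q*, counts are multiplied by
   mean-over-plates(ref(p))/ref(p, q), correcting per-(plate, probe)
   biases. Requires ≥ 2 plates; single-plate runs skip the stage with a
   warning. A zero reference count yields factor 1 with a warning rather
   than an undefined correction.
3. **Attenuation.** Probes deliberately dampened with inactive probes
   (nominally a 90% count reduction, i.e. factor ≈ 10) are multiplied
   back up by titration-measured factors — the ratio of unattenuated to
   attenuated signal, averaged over titration pairs — but only in the
   samples that were actually run attenuated (by default: low-iron
   samples, and recovery samples within 30 min of iron addition; the rule
   is configurable).
4. **Housekeeping.** Global mode: the reference R is the arithmetic mean
   of the housekeeping counts over all non-actD, non-reference samples,
   and each such sample is scaled by R/hk(s); afterwards every in-scope
   housekeeping count equals R exactly. The actD arms are scaled per
   timepoint instead (R_t over the actD samples at t, pooled across the
   two actD arms by default): under global transcription arrest the
   housekeeping transcript itself decays, and only within-timepoint means
   cancel that common trend while still removing loading differences.
   Per-sample corrections (stages 1 and 4) are scalar, so within-sample
   ratios of endogenous probes are invariant under them.

Zero counts are permitted in endogenous probes throughout; zeros in
positive-control or housekeeping channels are hard errors because the
corrections divide by them.

## Broken-line decay model

Log counts (natural log of count + pseudocount, default pseudocount 1.0
because low-expression probes produce zeros) in one treatment follow

y = α + B·min(t − t₀, 0) + B′·max(t − t₀, 0) + ε,  ε ~ N(0, σ²),

with changepoint t₀, pre-changepoint slope B and post-changepoint slope
B′. At fixed t₀ this is ordinary least squares; t₀ is profiled out by
minimizing the residual sum of squares over candidates. Candidates are
the distinct observed times strictly inside the range, refined by
golden-section search inside *every* interval between consecutive
distinct times (not only around the best grid candidate: the continuous
minimum of the piecewise-smooth RSS profile can sit in an interval whose
endpoints are not the best observed time). Ties break toward the earliest
changepoint. The fit requires ≥ 4 observations at ≥ 3 distinct times;
replicates enter as independent observations (no pre-averaging, which
would discard degrees of freedom). The Gaussian profile log-likelihood is
evaluated at σ̂² = RSS/n.

The decay rate is k = −B and the half-life t½ = ln 2 / k, defined only
for k > 0. An estimate is flagged unreliable when k ≤ 0 or the implied
half-life exceeds the observed time span; unreliable estimates are
excluded from panel averages automatically, and an explicit gene
exclusion set (e.g. the long-lived transcripts) can be supplied on top.

**Slope-change test.** B = B′ is tested by the contrast's t statistic
with n − 4 residual degrees of freedom — one degree charged for the
profiled changepoint, which is otherwise treated as fixed at its
estimate. With the changepoint truly fixed the test is exact (null
rejection 0.044 at α = 0.05 in a 500-replicate simulation); with an
estimated changepoint it is anticonservative, like any post-selection
test.

**Decay-rate comparison.** For two treatments, a joint model with
per-treatment intercepts and slopes at fixed per-treatment changepoints
(basis: indicator, indicator·min(t, t₀), indicator·max(t − t₀, 0)) is fit
twice: free, and with the two pre-changepoint slopes tied. The statistic
Λ = n·ln(RSS_tied/RSS_free) is referred to χ²(1); an exact-F variant
(F(1, n − p)) is available behind a flag. Under Gaussian errors Λ is a
monotone transform of an exact F statistic, so the χ² reference is mildly
anticonservative at small n (implied size ≈ 0.068 at n = 50, ≈ 0.054 at
n = 200); the calibration experiment in the acceptance suite therefore
uses 10 replicates per timepoint (n = 200), where the measured null
rejection is 0.057 at α = 0.05.

**Known limitation — changepoint uncertainty.** Changepoints are
estimated per treatment and then conditioned on, following the standard
two-step procedure for this design. On simulated data where two
treatments share the true decay rate, the end-to-end two-step comparison
rejects at roughly 20–35% at α = 0.05, because changepoint estimation
error masquerades as a slope difference. Per-gene p-values from the full
pipeline should therefore be read as rankings rather than calibrated
error rates; the test is calibrated when changepoints are known or
shared. Benjamini–Hochberg adjusted values are reported alongside raw
p-values.

## Differential and correlation summaries

Fold changes are low-iron over high-iron arithmetic means of normalized
counts (ST and LT samples combined), with a two-sided Welch
(unequal-variance) t test on the counts themselves (a log-scale option
exists) and BH adjustment across genes. A zero group mean yields an
undefined, flagged fold change. The Spearman matrix uses log2(count + 1)
over all non-actD biological samples — transcription arrest decays
everything and would correlate all genes spuriously — with
average-linkage clustering on 1 − ρ supplying the heatmap order; genes
constant across the kept samples (notably the housekeeping probe, which
is pinned exactly to R by normalization) are reported absent. For gene
pairs, both squared Pearson and squared Spearman correlations of log2
counts are reported, since either convention is common for printed R²
values. PCA runs on gene-centered log2 counts with samples as
observations. The growth rate is μ = ((ln N_t − ln N₀)/t)·24 per day.

## Synthetic-data generator

The generator emulates the experimental design rather than any particular
dataset: 7 treatments (high, low, rec, actd, actd_fe, dmso, dmso_fe); an
ST grid {0, 5, 10, 15, 30, 45, 60, 120, 240, 360} min for all treatments
and an LT grid {0, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 22} h for the
high/low/rec arms (the published design's grids are only available as a
figure; these defaults approximate them and are overridable); triplicate
cultures with duplicate actD arms; one plate per experiment, each with a
reference lane carrying a 1:1 high:low mix.

Per-gene kinetics are broken lines on the natural-log scale. Decay genes
fall from their iron-limited baseline at a per-treatment slope until the
changepoint; induction genes rise symmetrically; flat genes stay at
baseline; diel genes oscillate with a 24-h period. The iron-replete
steady level is a separate parameter from the recovery plateau, because
iron-responsive transcripts need not return all the way to replete levels
within the sampling window. Under actD, *every* transcript decays at its
gene-specific arrest rate — including the housekeeping probe (default
arrest t½ 30 min), which is what makes the per-timepoint housekeeping
scheme necessary and testable.

The default 24-probe panel: 7 fast iron-responsive decay genes (arrest
t½ = 8 min; recovery t½ 8–16 min, with three genes decaying slower in
recovery than under arrest to exercise the decay-rate comparison), 4
long-lived genes with arrest half-lives {90, 58, 79, 67} min, 2 induction
genes, 2 diel and 2 flat background genes (arrest t½ 6–11 min, keeping
all non-long-lived transcripts under 12 min so the excluded average sits
near 8 min), 1 housekeeping probe and a 6-probe positive-control ladder
spanning three orders of magnitude. The three largest low/high fold
changes are set to ≈ 3279×, 2142× and 1550×. Four high-abundance probes
are attenuated (true factors ≈ 10, drawn once per run) in low-iron and
early-recovery samples, and a titration table carries one
unattenuated/attenuated pair per attenuated probe.

Counts are lognormal around the kinetic expectation (residual σ = 0.15 by
default — count noise of this assay is closer to multiplicative than to
Poisson at panel abundances, and the decay model assumes Gaussian
log-scale residuals), scaled by per-sample loading (lognormal σ = 0.2),
per-lane hybridization efficiency (σ = 0.1) and per-(plate, probe) bias
(σ = 0.05, the imperfection the reference lane exists to correct), then
divided by the attenuation factor where applicable and rounded half-even
to integers. Positive-control counts are deterministic up to lane
efficiency. Everything is exactly reproducible from the seed.

**What the generator does not emulate:** counting (Poisson/NB)
dispersion at very low counts, probe cross-hybridization, background from
negative controls, day/night sampling artifacts beyond the sinusoidal
diel term, or batch structure beyond two plates. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumption class, not robustness to every artifact of real runs (an
`integer_counts=False` switch and the configurable σ's support robustness
experiments).

## Verification strategy and problem sizes

The acceptance suite runs: changepoint-search optimality against
exhaustive 0.1-min grid enumeration on 50 random instances (the search
must never lose to the grid; it may be better, since the continuous
refinement can undercut any finite grid); median half-life recovery over
200 replicates per true value on the ST actD design (within 15% for all
of {8, 58, 67, 79, 90} min); LRT null calibration over 1000 replicates
(rejection in (0.03, 0.07)); exact normalization invariants; and
closed-form formula checks. These sizes keep the full suite under a few
minutes while holding Monte-Carlo error well below the tolerances.
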