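# Methods

## Scope and model

The package detects differential alternative-splicing events (ASEs)
between a treatment and a control condition from splice-junction read
counts, then associates detected events with cohort covariates and
survival, and filters proteome-microarray spots to binder candidates.
Read alignment and isoform quantification are upstream of the package: it
consumes STAR-style `SJ.out.tab` junction counts and RSEM-style isoform
abundances, never reads or BAMs.

### Splicing ratios and events

All coordinates are 1-based inclusive.  A junction is identified by its
intron's first and last base (the STAR convention); its donor site is the
exonic base 5' of the intron and its acceptor site the exonic base 3' of
it, swapped on the minus strand.  Junctions sharing a donor site form one
group, junctions sharing an acceptor site another; the splicing ratio (SR)
of a junction in a sample is its count over the group total, so SRs in a
group sum to 1 and a zero-coverage group yields missing SRs.  Junctions
with STAR strand code 0 are kept with an undefined strand and grouped by
coordinates; only uniquely-mapped counts (column 7) are used, since
multimapper handling upstream is aligner-specific.

Every unordered junction pair in a group is one candidate event.  With a
shared donor and two acceptors, the pair is a cassette exon (CA) when the
nearer acceptor coincides with an annotated exon start whose exon ends
before the farther acceptor — a skippable middle exon — and an
alternative 3' splice site (A3SS) otherwise; the shared-acceptor case is
symmetric (CA vs A5SS).  Without annotation support the pair defaults to
A3SS/A5SS and is flagged low-confidence: calling a cassette exon requires
evidence of a skippable exon.  Mutually exclusive exons (MXE) are merged
from reciprocal CA pairs whose middle exons do not overlap, whose skipping
junctions land on each other's middle exon, and which no annotated
transcript contains together — the minimal geometry satisfying mutual
exclusion.  Intron retention and alternative first/last exons are out of
scope.

### The srd score

For one event in treatment sample *j*:

    srd = (1 + Σ_{i=1..Nc} (SR_tj − SR_ci)) / (1 + s.d.(SR_c) / Nc)

with the sample standard deviation (Nc − 1 divisor).  `compute_srd`
implements this exactly as stated — the numerator sums, not averages, the
control differences, so the score scales with the number of controls; an
`average` switch provides the mean-difference variant.  An event's score
in a sample is the larger of its two junctions' scores: in a two-junction
group the SRs are complementary, so any change pushes exactly one junction
up, and the one-sided right-tail test then captures both directions.
Cassette-exon direction is read off the inclusion junction's mean SR
change (EX = exon lost, IN = gained); a zero change is flagged
undirected.  Events with a missing SR in any needed sample are skipped for
that comparison, not imputed — the formula has no missing-data rule.

### Tail significance

Score distributions are heavy-tailed: most events sit near 1 and changed
events far to the right.  Each comparison's scores are fitted with a
continuous power law above a cutoff: for each candidate cutoff `xmin` the
exponent is the maximum-likelihood estimate
`alpha = 1 + n / Σ log(x_i/xmin)`, and the cutoff minimising the
Kolmogorov–Smirnov distance between the empirical tail and the fit is
kept (the classic two-parameter tail-selection procedure).  Two numerical
choices stabilise the fit: the candidate-cutoff scan is capped at 256
evenly-spaced unique values (keeps fitting near-linear in n), and among
cutoffs whose KS distance lies within one sampling-noise band
(0.5/√n_tail) of the minimum the smallest is kept — the raw KS minimum is
noisy and otherwise discards valid tail data.  Significance of a score is
the fitted complementary CDF `(x/xmin)^(1−alpha)`, clamped to 1 below the
cutoff.  Degenerate inputs (all values equal, or fewer than `min_tail`
positive values) raise a fit error rather than returning a bogus tail.

### Selection: median significance against a relabeled background

The per-event summary is the median significance across treatment
samples; with an even number of samples the two middle values are
interpolated geometrically, since p-values are log-scale quantities (for
an odd count this is the ordinary median).  The selection threshold is
dynamic, derived from a background distribution of null medians.

Three calibration choices, made after the naive constructions proved
miscalibrated on synthetic data, make observed and background
significances commensurable:

1. **Relabeled background.**  The background scores every other
   assignment of the samples into a pseudo-treatment group of the same
   size (the remaining samples acting as pseudo-controls) with the
   identical statistic.  This gives the null medians the same control
   count and the same shared-control correlation as the observed
   comparison.  A leave-one-out-over-controls background — each control
   scored against the remaining controls — systematically mismatches both
   (one fewer control; no shared-control correlation between
   pseudo-treatments) and under-counts small null medians; it remains
   available through `select_candidates` for p-tables computed elsewhere.
2. **Mean-difference scale for significance.**  Because the as-stated
   numerator sums over controls, comparisons with different control
   counts live on different scales.  All scores entering the tail fit and
   significance are therefore computed with the mean-difference variant;
   the `srd_*` columns still report the as-stated formula (or the average
   variant when requested).
3. **Consensus tail model.**  With few events (thousands, not the tens of
   thousands of a transcriptome-wide run) a handful of genuine changes
   measurably flattens a treatment sample's own tail fit relative to the
   clean background fits, inflating p-values exactly where sensitivity is
   needed.  Significance is therefore assigned from the consensus fit —
   the median exponent and cutoff across all per-comparison fits — in
   which contaminated comparisons are a minority.

The default threshold is the largest cutoff whose estimated FDR (expected
background medians at the cutoff, times the number of events, over the
number selected) is at most `fdr_target = 0.20`, a conventional level for
exploratory splicing screens.  The estimate is conservative when real
effects exist, because planted effects leak into the relabeled null
(pseudo-groups mixing treatment and control samples score them
intermediate), so the realized FDR runs below the target.  A fixed
percentile rule — threshold at the q-th percentile (default 5) of the
background medians — is available as `selection="percentile"`.

Candidates are ranked by Σ |mean_treatment − mean_control| of
inclusion-class plus skipping-class isoform expression (inclusion
isoforms contain the middle exon; skipping isoforms of the same gene lack
it but retain flanking exons); events with no mapped isoform rank last
with score 0, and ties break by event id.  Large scores guard against
srd outliers driven by low expression.  Selections from replicate
comparisons intersect on event id with concordant direction; discordant
events are dropped and reported.

## Cohort association stage

Group labels are generic binary covariates.  ASEs occurring in strictly
more than 5% of samples pass the frequency filter.  Group association
uses the two-sided Fisher's exact test (probabilities of all fixed-margin
tables at most as likely as the observed are summed); a zero margin
yields p = 1 with a warning.  Survival association reports both the
log-rank test and the hazard ratio from a single-binary-covariate Cox
model fitted by Newton iteration on the Breslow partial likelihood, with
a Wald 95% interval; a group with no observed events yields an unbounded
HR, reported as such with the log-rank p only.  Raw p-values are reported
with Benjamini–Hochberg columns alongside; selection defaults to raw
p < 0.05, matching how unadjusted per-ASE correlations are typically
screened, with the adjusted columns available for stricter use.  Venn
intersections of the frequent / group-associated / survival-associated
sets report every region, with the all-sets core as the headline set.

## Microarray filter

Per spot, SNR = (F635 mean − B635 mean)/B635 s.d. and fold = F635
median / B635 median; per protein, CV = sample s.d. over mean of the two
duplicate spots' background-subtracted mean signals (the same quantity
the SNR numerator uses).  A protein passes with SNR ≥ 3 and fold ≥ 5 on
*both* spots and CV < 0.15.  Applying the cutoffs per spot is stricter
than filtering on the duplicate mean; the mean rule is exposed as an
option.  Zero background s.d. or median excludes the protein with a
reason code.  All three statistics are scale-free, so the filter is
invariant under fluorescence rescaling.

## Synthetic data

The generator emulates the structures the pipeline consumes; defaults are
the study conditions exercised by the analysis scripts and tests.

* **Gene models.**  One event per gene on a synthetic chromosome, genes
  alternating strands (minus-strand genes mirror the transcript geometry,
  exercising strand handling).  Templates realize CA, A3SS, A5SS and MXE
  exactly as the classifier defines them; only the event-defining
  junction pair (plus the reciprocal pair for MXE) is emitted, so each
  gene contributes exactly one typed event.
* **Junction counts.**  Baseline inclusion level (PSI) per event is
  Beta(2, 2) — symmetric, bounded away from 0/1.  Counts are independent
  negative binomials per junction, inclusion ~ NB(depth·PSI, dispersion)
  and skipping ~ NB(depth·(1 − PSI)), with variance m + dispersion·m²
  (default dispersion 0.05, typical bulk RNA-seq overdispersion; 0 gives
  Poisson).  Planted events shift treatment PSI by `delta_psi` (default
  0.3), signed away from the nearer boundary and clipped to (0.01, 0.99)
  with a warning.  Defaults: 1000 cassette-exon events, 50 planted,
  depth 100, 2 treatment + 3 control samples — a deliberately small,
  hard setting (few samples, moderate depth) at which the detector's
  sensitivity/FDR trade-off is genuinely stressed.
* **Isoform expression.**  Inclusion isoform ∝ gene level × PSI, skipping
  ∝ gene level × (1 − PSI), with multiplicative lognormal noise (σ = 0.1)
  on both the gene level and each isoform.
* **Cohort.**  Occurrence per ASE is Bernoulli at frequency 0.2; planted
  associated ASEs have their occurrence odds multiplied by the odds ratio
  (4) in the group = 1 stratum.  Survival is exponential with baseline
  hazard 0.1, multiplied by the hazard ratio (2) per occurring
  hazard-planted ASE, with independent exponential censoring (rate 0.05,
  roughly one-third censored).  Association- and hazard-planted sets are
  disjoint so the two effects are not confounded.
* **Spots.**  Null proteins fluoresce near background (per-spot SNR
  centred below 1, fold < 1.5 — never passing the fold cutoff); binders
  get signals of 8–20 background s.d. and folds of 8–15 with ~2%
  duplicate jitter, so CV sits well under 0.15.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: junction-depth heterogeneity across genes (real
srd null distributions owe much of their heavy tail to low-coverage
events), annotation incompleteness and novel junctions, correlated
biological replicate variation (counts here are independent given PSI),
intron retention, multi-isoform genes beyond one inclusion/skipping pair,
and batch effects in cohort or microarray data.

## Problem sizes and determinism

The test suite and the acceptance script run the full detection at 1000
events with the sample sizes above (seconds per run), fit power-law
recoveries at 5000 points × 20 replicates, estimate the hazard ratio at
500 per group, and verify Fisher agreement by exhaustive enumeration over
all 2×2 tables with total ≤ 30 — sizes at which every check is exact or
tight while the whole suite stays fast.  Every stochastic routine takes
an explicit seed (package default 17) through `numpy.random.default_rng`;
identical seeds give byte-identical simulated files and identical
detection tables.

## Known limitations

* The per-event score uses only the shared-site group of the defining
  junction pair; 5' and 3' evidence for the same physical exon are
  scored as separate events rather than pooled.
* The relabeled background requires at least 3 control samples and is
  combinatorially limited for very small designs (9 relabelings at
  2 + 3); the FDR estimate is correspondingly coarse and conservative.
* With two treatment samples the median-of-significances is a
  two-sample compromise; sensitivity at small effect sizes is limited by
  the design, not the threshold rule.
* The Cox fit is single-covariate by design; no multivariate adjustment.
* GTF is the only annotation dialect parsed, and only exon features are
  used.
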