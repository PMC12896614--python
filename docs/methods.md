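# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic panels do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Study design and grouping hypotheses

A clone panel is a set of isogenic lines from one parental background,
differing in which alternatively spliced, zinc-finger-encoding exons of a
transcription factor were disrupted.  The default panel mirrors a
24-clone design: 4 wild-type clones, 7 exon-4-targeted clones (3 with
near-normal protein on immunoblot, 4 with little or none), 5
exon-6-targeted clones, and 8 double-targeted clones.  Every clone
carries one label under each of four grouping hypotheses: H1 binary
(WT/targeted), H2 by targeted exon, H3 protein-informed (exon-4 clones
split by protein level), and H4 by number of targeted exons (0/1/2),
which proxies the number of intact N-terminal zinc fingers.  The same
clones are reused under every hypothesis; the hypotheses differ only in
how the group factor of the linear model is coded.

## Transcript detectability and normalization

Coverage arrives as average depth per nucleotide (APN = summed read depth
over feature length) and a raw read-support count per feature.  The
detection rule operates on read support: a feature is detected with at
least `detection.min_reads` (default 1) reads in at least
`detection.clone_fraction` (default 0.5) of clones, with the boundary
counting as detected (support in exactly half the clones passes).  A
transcript survives the first pass only when **all** of its constituent
features are detected — an intentionally conservative conjunction, since
one silent junction is evidence the annotated isoform is not expressed.
The second pass restricts the TPM matrix to survivors, recomputes
detection on TPM (> 0 in ≥ half the clones), and sums gene TPM exactly
over member transcripts, so a gene's TPM always equals the sum of its
retained transcripts.

Upper-quartile normalization divides each clone by the 75th percentile of
its strictly positive values, rescaled by the geometric mean of those
percentiles across clones so the output remains on a TPM-like scale; a
single-clone matrix gets factor 1 by convention.  The transform is
`log2(tpm / scale + 1)`; base and pseudo-count are exposed as
`normalize.log_base` and `normalize.pseudo`.  Positive-only quartiles and
geometric-mean anchoring are this package's choices — the upper-quartile
method itself fixes neither the reference constant nor the treatment of
zeros — and the quartile estimator is linear interpolation between order
statistics, fixed for reproducibility.

## Consensus peaks and accessibility normalization

Per-clone peak calls are intervals (0-based half-open) with a score and a
read count; calls overlapping within a clone violate the contract and are
merged with a warning.  Across clones, calls connected by ≥ 1 bp overlap
form one cluster under transitive closure (closure makes the result
independent of clone order; chains A–B–C merge even when A and C are
disjoint).  Each clone's scores are normalized to score-per-million
(score × 10⁶ / clone's total score) — the "per million" denominator is not
uniquely determined by the retention rule's phrasing, and per-clone score
normalization was chosen because it mirrors depth-normalized peak
scoring; it is exposed should a different convention be needed.  The
member call with the highest score-per-million supplies the consensus
coordinate (ties: longer interval, then lexicographically smaller clone
id, for determinism); a cluster is retained with ≥ `consensus.min_clones`
(2) distinct clones and consensus score-per-million ≥ 1.

The weighted count of clone *c* at consensus peak *p* sums, over clone-c
calls overlapping *p*, `count × overlap/len(sample peak)` — the sample
peak's length is the denominator, so a clone's weighted count never
exceeds its raw counts.  Peaks with fewer than `filter.min_reads` (10)
reads in ≥ `filter.sample_fraction` (0.5) of samples are excluded, with
the boundary (exactly half) triggering exclusion; the rule is evaluated
on rounded weighted counts by default (`round_counts`).

TMM scaling factors follow the published trimmed-mean-of-M-values
procedure: reference = sample whose upper quartile of count/library-size
is closest to the mean of those quartiles; M and A statistics on rows
positive in both samples; double trimming (30% on M, 5% on A by rank);
inverse-asymptotic-variance weights; factors rescaled to geometric mean 1.
The implementation agrees with an independent straight-line oracle to
1e-10 on random matrices (and with the reference R implementation to 6
decimal places during development).

The voom-style transform computes `log2((count + 0.5) / (lib × factor +
1) × 10⁶)`, smooths sqrt(residual SD) against average log-count with
lowess (span 0.5), and assigns each observation the predicted
sqrt-SD⁻⁴ at its own log-CPM, clamping predictions to the fitted range at
the extremes.  When a grouping is supplied the residual SD is taken about
group means (so real group effects do not inflate the trend); otherwise
about the row mean.  A degenerate flat trend yields equal weights.

Outlier screening clusters each peak's sample counts with 1-D 2-means —
centers initialized at the row minimum and maximum, Lloyd iterations to
1e-8 or 100 steps, all deterministic.  If either cluster is a single
sample, that observation is flagged and the whole peak row is excluded
from testing (exclusion is global, not per-comparison; a per-comparison
variant can be layered on the flags matrix).  Note the singleton rule has
no separation threshold: on overdispersed counts (negative-binomial
dispersion ~0.1) roughly 1% of null peaks contain one draw extreme enough
to cluster alone, and the screen removes them too.  That is the
procedure's intent — such draws are indistinguishable from technical
spikes — but it means "flagged" and "planted" sets differ slightly on
synthetic data with heavy-tailed noise.

Peak annotation is interval arithmetic: a peak is *genic* when its gap to
some gene body is ≤ 2000 nt (overlap = distance 0; the 2 kb boundary is
inclusive), else *intergenic*; peaks on chromosomes absent from the gene
models are intergenic with a warning.  A DA gene is any gene with at
least one significant proximal peak.

## Differential testing

Each feature is fit with the group-means model `Y_ij = μ + g_i + ε_ij`,
ε ~ N(0, σ²), by (weighted) least squares, vectorized across features.
Contrasts are two-sided t statistics on the pooled residual variance from
the single fit — equivalent to refitting per pair under this model, with
one fit instead of many.  Precision weights are applied to accessibility
fits only; expression fits are unweighted, matching how the two assays
are normalized.  Zero residual variance with a nonzero contrast is
reported as p = 0 with a `zero_variance` flag rather than NaN.

Fold changes are `log2((mean_A + δ)/(mean_B + δ))` with δ = 0.001 guarding
zeros, computed from group means on the normalized linear scale when a
linear matrix is supplied (expression), else from the difference of log
means (accessibility); both conventions are available because
mean-of-logs and log-of-means genuinely differ and neither is canonical.
FDR is Benjamini–Hochberg step-up within one comparison and one assay —
per-comparison families match how results are counted and reported; BH
was chosen as the default convention of this toolchain lineage.
Significance is `fdr < alpha` (default 0.05).

## Enrichment

Gene-set enrichment uses Pearson's χ² on the 2×2 table of membership ×
significance, df = 1, **without** Yates continuity correction — the
uncorrected statistic is what reproduces published risk-gene tables of
this size (the corrected one is ~1 unit lower on a table with N ≈ 33,000);
the correction is available behind a flag.  Degenerate tables (an empty
margin) return χ² = 0, p = 1, flagged.  The tested universe is supplied by
the caller rather than inferred, because published universes vary from
test to test depending on how each set was compiled; the suite defaults
to all classified genes.  Union modes pool significance across
comparisons by logical OR before building the table.

## What the synthetic panels emulate — and what they do not

`simulate_expression` draws transcript log₂-TPM as a gene baseline
(N(4, 2)) plus a Dirichlet split across transcripts, plus planted group
shifts, plus N(0, σ) clone noise with σ = 0.4 log₂ units by default
(log-normal noise: simple, positive, heavy-tailed enough), then
renormalizes each clone to the 10⁶ TPM convention.  A configurable
fraction of transcripts (default 10%) has its junction's read support
zeroed in a majority of clones so the two-pass reduction is exercised.
`simulate_atac` draws negative-binomial counts (dispersion 0.1, standard
count overdispersion) around per-peak baselines uniform on 100–400 reads,
adds `slope × (targeted-exon count)` for gradient peaks, raises planted
outlier observations to ≥ 10× the peak median (and > 5× every other
clone), and jitters intervals ± 50 nt on 500-nt peaks — enough to make
percent-overlap weighting nontrivial without destroying overlap.  Peaks
sit on a 10-kb grid with gene bodies of the same index at the same locus,
so the peak-to-gene annotation of planted effects is exact.

Not emulated: read-level artifacts (GC, duplication, mappability),
fragment-length and insertion-site structure, correlated gene programs,
batch effects, or compositional coupling between the two assays.  Passing
recovery tests therefore demonstrates that the statistical machinery is
correct under its own model assumptions, not that the pipeline is robust
to every failure mode of real libraries.  One real-data phenomenon the
simulation *does* reproduce is TPM compositionality: planting many strong
effects in one group measurably shifts all other genes' relative
abundance in that group (see `examples/04_differential.py`).

## Problem sizes and determinism

Tests and the acceptance script run panels of 24 clones with 200 genes ×
2 transcripts and 200–1000 peaks, and 20 replicates for calibration
checks — sizes chosen so the full suite completes in well under a minute
while keeping ≥ 100 observations behind every rate it asserts.  All
randomness flows from named `numpy` generator substreams rooted at a
single seed; the same configuration and seed reproduce every output file
byte-identically.

## Known limitations

- Variances are per-feature (no empirical-Bayes moderation); with n = 24
  clones the pooled-variance t-test is adequately powered but small
  panels will benefit less.
- The outlier screen's singleton rule conflates planted spikes with
  natural heavy-tail draws, as discussed above.
- Upper-quartile and TMM both assume most features are unchanged;
  panels where a majority of features respond violate both.
- Gene annotation uses gene bodies only (distance to the body's ends
  stands in for TSS/TTS distance); strand-aware promoter definitions are
  out of scope.
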