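# Methods

`taraclass` implements a genome/transcriptome concordance analysis for
paired tumor / cell-line cohorts: aCGH segmentation and state calling,
a gene-wise tumor-vs-cell-line (TM/CM) expression-concordance screen,
discovery of *genomic delegates* (stable genes whose expression tracks
their own DNA dosage), and unsupervised TARA classification of an
independent metastasis cohort on those delegates. A synthetic-cohort
generator provides planted ground truth for every stage. This note
records the models, the parameter choices and the design decisions.

## aCGH segmentation

Per-sample marker profiles (log2 ratio of sample vs diploid reference,
ordered by genomic position) are segmented chromosome by chromosome.

**Noise scale.** The marker noise SD is estimated per chromosome and
per sample as `1.4826 * median(|first differences|) / sqrt(2)`. The MAD
of successive differences is insensitive to a handful of true
copy-number steps, unlike the naive SD, which they inflate; a floor of
1e-6 guards the exactly-constant degenerate case.

**Splitting.** Recursive binary splitting: within an interval, the
candidate breakpoint maximises the normalised mean difference
`|mean_L - mean_R| / sqrt(1/n_L + 1/n_R)` over all splits leaving at
least `min_markers` (default 10) markers on each side; the split is
accepted while the statistic exceeds `split_t` (default 4) noise SDs,
and recursion continues on both children. The normalised statistic —
the standard two-sample change-point statistic — is essential: the raw
mean difference between the two halves of a long chromosome dilutes an
embedded event by the ratio of event length to half length, so a
30-marker 3-sigma event inside 500 markers would never reach any fixed
mean-difference bar. `split_t = 4` is deliberately conservative with
respect to the multiplicity of candidate split points (the null
maximum over ~500 candidates concentrates around 3.2–3.6 SDs);
spurious splits that slip through are removed by the merge pass.

**Merging and the segment definition.** The defining rule — a segment
differs from its *neighboring* regions by at least `snr` (default 2)
signal-to-noise ratios in at least `min_markers` markers — is enforced
directly: after splitting, adjacent segments whose means differ by less
than `snr * noise_sd` are merged iteratively (smallest difference
first) until every remaining boundary clears the bar. Segments tile
each chromosome exactly in marker-index space. A consequence of the
minimum-size rule is granularity, not suppression: a strong event
shorter than `min_markers` markers can surface as a `min_markers`-wide
segment with a correspondingly diluted mean — which is precisely how
mixed copy-number states inside a single gene become visible.

**State calling.** Strict thresholds on the segment mean: amplified
iff mean > 0.15, deleted iff mean < -0.3, otherwise unchanged. Applied
to segment means, not marker values. Ties, boundaries and the
asymmetry of the thresholds follow the convention of two-colour aCGH
against a diploid reference, where losses shift further in log2 than
gains of a single copy.

**Gene-level copy number.** Segment cover intervals place boundaries
at midpoints between flanking markers (so segments also tile the
chromosome in bp). For each gene (BED, 0-based half-open) the
composition is the fraction of the gene span overlapping segments of
each state (uncovered span counts as unchanged; genes with no
overlapping segment are flagged `no_coverage`); `weighted_log2` is the
bp-weighted mean of overlapping segment means. The dominant state
breaks ties toward unchanged, then amplified. SEG output uses 1-based
inclusive marker positions (Broad convention), seg.mean to 4 decimals.

## Stable-gene screen

For each gene, Pearson r between TM and CM expression across the
paired patients, with the exact two-sided p from
`t = r*sqrt(n-2)/sqrt(1-r^2)` on n-2 df (at n = 15 pairs, r ≈ 0.514
corresponds to p ≈ 0.05). Missing values use complete-pair deletion
with the per-gene n recorded. Genes with zero variance in either
vector (assessed against the rms scale, so constants survive float
rounding) are flagged undefined and excluded from selections.

The *stable* set at a cutoff requires `p < cutoff` **and** `r > 0`: a
significantly negative TM/CM correlation is not concordant expression.
This direction rule halves the null pass rate (≈ α/2), which the
calibration tests assert. No multiple-testing correction is applied in
the screens — significance is read as a ranking device, matching the
uniform p < 0.05 convention of the analysis this package models; a
Benjamini–Hochberg variant can be layered on by the caller.

The non-correlated control set samples n genes uniformly (seeded)
from those with defined r < 0.1. Reference-list enrichment
(housekeeping check) matches IDs case-insensitively and reports
percentages at one-decimal precision with the denominator stated
explicitly.

## Delegate discovery

Gene-level `weighted_log2` copy number (continuous, not the discrete
call) is correlated with CM expression across the cell lines; the same
t transform gives p. Genes whose CN never varies are undefined and
counted non-concordant. Delegates are stable genes with `r_cn > 0` and
`p_cn < alpha` (default 0.05). The summary reports counts, the
percentage of the stable set (nearest integer), a reconciliation
partition (delegate / stable-only / concordant-only / neither /
undefined; each gene exactly once) and the delegate composition by CN
category — the modal called state across samples, ties broken
gain > deletion > unchanged, integer percentages by largest-remainder
rounding (always summing to 100).

**Concordance-vs-stability curve.** Genes are ranked into 0.1-wide
intervals of TM/CM correlation, the top interval [0.5, 1.0] pooled
(r = 0.5 is where significance begins at n = 15). The table reports
per-interval percent concordant and, following the sequential-subset
construction, the cumulative percent concordant from the most stable
set downward. The trend statistic is the Pearson correlation between
set rank and cumulative percent concordant across non-empty intervals,
weighted by the number of genes each interval contributes. Two
deliberate choices here:

* *Cumulative, not per-interval.* The scientific claim is a plateau at
  the top (dosage influence saturating at the significance cutoff)
  with gradual dilution below. Cumulative sets express that claim
  robustly; per-interval percentages at n = 15 are dominated by the
  ±0.29 sampling noise of the observed correlation, which scatters
  genes across intervals regardless of their true stability.
* *Gene-count weights.* Tail intervals often hold a handful of genes;
  an unweighted correlation lets a 3-gene set count as much as a
  500-gene set. Weighting by interval size is ordinary
  precision-weighting.

Undefined-CN genes stay in interval denominators as non-concordant;
genes with undefined TM/CM correlation are excluded from the binning.

## TARA classification

Samples are clustered on per-gene z-scored delegate expression with
average-linkage agglomerative clustering on `1 - Pearson` distance
between samples, and the tree is cut at k (default 3) clusters. The
two clusters with maximal inter-centroid correlation distance are the
polar classes; A is the larger of the two (ties by lexicographically
smallest member), the remainder is C. Polarity of unsupervised labels
is intrinsically arbitrary; recovery metrics therefore use the
adjusted Rand index, and the labelling rule is chosen to be invariant
to sample order.

Class comparison fits, per gene, `expression ~ intercept + class +
batch` with fixed-effects batch dummies, testing the class coefficient
two-sided (significant at p < 0.001). The design matrix is shared
across genes, so the fit is a single pseudo-inverse application; with
one batch it reduces exactly (to machine precision) to the classic
equal-variance two-sample t test, which the tests assert at 1e-12. A
batch lying entirely inside one class is flagged as confounded (fully
confounded designs are rejected as rank-deficient). Top discriminants
are the n smallest p-values, ties by |t| then gene ID. PCA operates on
per-gene mean-centred data with a fixed sign convention (largest
loading positive). Signature scoring is the mean per-gene z-score over
the listed genes present, with missing-gene counts reported.

## Synthetic cohort

The generator emulates the study design: `n_pairs = 15` TM/CM pairs
with aCGH of the cell lines, plus an independent cohort of
`n_metastases = 112`; `n_genes = 5000` genes tile `n_chromosomes = 4`
chromosomes carrying `n_markers_per_chrom = 500` markers each (10 kb
spacing; the gene grid is finer than the marker grid, and true
gene-level CN is read off the piecewise-constant truth in bp, so the
gene↔segment mapping is exact).

**Copy number.** Per sample and chromosome, a Poisson number
(`segment_event_rate = 3`) of non-overlapping events of 30–120 markers
(each flanked by ≥ 10 background markers, so every true segment
respects the minimum-size rule), with level drawn from gains
{0.3, 0.45, 0.6, 1.0} (probability 0.55) or losses {-0.5, -0.7, -1.0}
— all beyond the calling thresholds and at least 3 noise SDs at the
default `noise_sd_cgh = 0.1`. Marker noise is i.i.d. Gaussian.

**Expression.** Gene categories are planted at random positions:
8% dosage-driven (CM expression = baseline + slope × true gene CN,
with per-gene slope `1.5 × U(2/3, 4/3)` — mild coupling heterogeneity
keeps every planted gene detectable while avoiding a single uniform
effect size), 12% stable-non-dosage (a patient-level N(0, 1) signal
shared by TM and CM), 10% stromal (a TM-only signal with near-constant
CM values, which decorrelates TM from CM — these emulate
microenvironment transcripts missing from culture), and the remainder
pure noise (`noise_sd_expr = 0.2` on the log2 scale everywhere,
matching log-transformed array convention). TM equals the
tumor-intrinsic CM signal plus independent noise.

**Classes and batches.** One quarter of the dosage genes are class-A
markers, one quarter class-B (shift `class_effect = 1.5` in their
class). The intermediate class C (`frac_class_c = 0.2`) draws
half-effect shifts on both polar marker sets *plus* a half-effect
C-specific signature on a reserved third quarter of the dosage genes.
The extra signature is a deliberate design decision: a purely
intermediate profile coincides with the cohort mean after per-gene
centring and is therefore invisible to correlation-distance
clustering — real intermediate subclusters are coherent enough to be
drawn as a group, and the generator has to reflect that for class C to
be a recoverable truth. Metastases additionally receive additive
per-gene batch shifts (`n_batches = 3`, `batch_sd = 0.15`, applied to
metastasis samples only) and stromal variation (they are tissues). The
batch SD is set below the class effect so the clustering sees biology
first while the batch term in class DE remains genuinely exercised;
with the two at comparable scale, correlation clustering recovers
batches instead of classes, which contradicts the clearly divergent
class structure this generator is meant to emulate.

All randomness flows from a single seed through per-domain
`SeedSequence` spawn keys, so `generate_cgh_profile(config, i)` alone
reproduces exactly the profile used inside `generate_cohort`, and
identical configs give byte-identical outputs.

**What the generator does not emulate.** Probe-level chemistry, GC
waves, replication-timing waves, clonal heterogeneity and purity,
correlated noise along the genome, heavy-tailed expression noise,
dosage response nonlinearity, and any realistic gene–gene correlation
structure beyond the planted programs. Passing recovery tests
therefore demonstrates that the pipeline's statistics behave as
designed under the stated model — calibration under independence,
detection at the planted effect sizes — not that real cohorts of this
size would yield delegate sets of comparable purity.

## Numerical choices and degenerate inputs

* Correlation p-values use the exact t transform, not Fisher z
  (standard small-n practice; at n = 15 the two differ visibly).
* Zero-variance detection is relative to the rms scale (`1e-20`
  ratio), so constants survive float rounding.
* Split ties break to the leftmost index; merge processes the smallest
  adjacent difference first; both for determinism.
* Chromosomes shorter than `2 * min_markers` are returned unsplit.
* Empty stable sets yield zero-count summaries, not errors; an empty
  delegate composition reports zeros.
* Largest-remainder rounding makes integer percentages sum to 100
  exactly, with stable ordering on equal remainders.
* The delegate percentage is rounded to the nearest integer with the
  stable-set size as the stated denominator; enrichment percentages
  round to one decimal with their denominator reported alongside.

## Problem sizes used in validation

The test suite and the acceptance script run the generator at its
default scale (5,000 genes, 15 pairs, 112 metastases, 2,000 markers)
for recovery checks, 10,000 genes for the null-calibration checks, and
200 simulated chromosomes for breakpoint recovery; these sizes give
Monte-Carlo error comfortably inside the asserted tolerances while
keeping any single check in the seconds range.

## Known limitations

* The SNR-based segmenter has no notion of integer ploidy, purity or
  allele-specific CN; it reports relative log2 levels only.
* The screen's direction rule and the concordance rule are one-sided
  by design; genes whose expression *anti*-tracks dosage (e.g. via
  feedback) are deliberately excluded from delegates.
* The k = 3 tree cut operationalises the intermediate class; the
  boundary of class C on real data is a judgement call, and silhouette
  values are reported so borderline samples can be inspected.
* Batch structure is additive and fixed-effects; no empirical-Bayes
  shrinkage of gene variances is applied in class DE.
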