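# Methods

This note documents the statistical procedures `isoswitch` implements, the
conventions chosen where several were defensible, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Problem setting

A splicing regulator (e.g. an epithelial splicing factor such as ESRP1)
varies in expression across a panel of samples. For a target gene with two
isoforms that differ by one alternative-splicing event — prototypically a
cassette exon — the question is whether the *relative* frequency of the two
isoforms tracks the regulator: an isoform switch. The pipeline starts from
transcript-level count or TPM matrices and junction count tables; read
alignment and transcript quantification are upstream of it.

## Quantification

**TPM.** Per sample, `TPM_i = (c_i/l_i) / Σ_j (c_j/l_j) × 10^6` with `l_i`
the annotated exonic (mature-transcript) length. No fragment-length
correction is applied; effective length equals annotated length. Columns sum
to 10^6 (relative tolerance 1e-6). A sample with zero total counts stays
all-zero and is warned about rather than producing NaNs.

**Isoform fractions.** A transcript's fraction is its TPM over its gene's
TPM sum, per sample. Where the gene sum is zero the fractions are *missing*,
not zero: coding an unexpressed gene as fraction 0 would manufacture
spurious anti-correlation with any covariate that tracks expression.
Missingness propagates; downstream statistics use only samples with defined
fractions.

**PSI.** For a cassette event, `psi = (I/L_I) / (I/L_I + E/L_E)` with
inclusion and exclusion junction counts `I`, `E` and normalization lengths
defaulting to `L_I = 2`, `L_E = 1`: two junctions (upstream and downstream)
support inclusion of a cassette exon while a single junction supports
skipping. The lengths are overridable; with equal lengths the formula
reduces to `I/(I+E)`. Both counts zero leaves PSI undefined (reported as
missing), not zero. The TPM-ratio fraction and the junction PSI are both
provided because inclusion can be measured either way; outputs are labelled
with which was used.

## Event classification

Two isoforms of one gene are compared as exon chains (0-based half-open
intervals, sorted by genomic start). The classifier is total over:

- **SE** — one chain carries an internal exon entirely absent from the
  other, all remaining exons (hence both flanking junctions) identical.
- **RI** — one chain's exon spans exactly two exons plus the intervening
  intron of the other; the coordinates reported are the retained intron.
- **A3 / A5** — the chains differ at exactly one internal exon boundary.
  Donor/acceptor is assigned relative to transcription direction: on the
  plus strand an exon's genomic start is its acceptor (3′ splice site) and
  its genomic end the donor (5′); on the minus strand the roles exchange.
  Relabeling the strand of a fixed coordinate difference therefore swaps
  A3↔A5, while mirroring the coordinates *and* flipping the strand — the
  same transcript written in the other orientation — leaves every label
  fixed.
- **AF / AL** — the first/last exon (in transcript direction) differs and
  the rest of the chain is shared. Ties with SE (a skipped *terminal* exon)
  resolve positionally: terminal differences are AF/AL, internal ones SE.
  A terminal exon differing only in its outer boundary (a transcript
  start/end shift with identical splice junctions) is also reported AF/AL;
  callers who want to exclude pure end-shifts can filter on the shared
  junction.
- **MX** — the chains are equal except at one internal position where the
  two exons are disjoint.
- **identical** / **complex** — equal chains, and everything else
  (multi-difference chains, overlapping-but-unaligned exons). Complex pairs
  are reported untyped rather than forced into a category.

Classification is symmetric in its two arguments and covers only the
designated isoform pair; collapsing a many-isoform gene to a pair is the
caller's choice (the switch scan uses exactly-two-isoform genes).

## Switch scores

**Correlation difference.** For each two-isoform gene,
`delta_r = r1 − r2` where `r1 = Pearson(regulator, fraction of isoform 1)`
and `r2` likewise for isoform 2, over the samples where both fractions are
defined (at least 3 required; Pearson with fewer observations, or with a
constant series, is undefined by fiat and the gene is marked unscorable).
Genes whose mean fractions sum below `min_total_fraction` (default 0.5)
fail the expression filter. Scorable, filter-passing genes are ranked by
descending `delta_r`, ties broken lexicographically by gene id, and the
top-K (default 20) flagged.

*Orientation.* Which isoform is "isoform 1" fixes the sign of `delta_r`.
The convention here: isoform 1 is the isoform with the higher mean fraction
among regulator-high samples (median split of the regulator), so a true
switch yields `delta_r` near +2 and the descending ranking puts switches
first. The output header states the convention; swapping the labels negates
`delta_r` exactly.

**kTSP-style score.** On a low/high dichotomy of the samples,
`p_g = P̂(f1 > f2 | group g)` with ties `f1 = f2` counted as ½, and
`score = |p_low − p_high| ∈ [0, 1]`. This is a reimplementation of the
rank-pair idea behind top-scoring-pairs isoform methods, chosen because it
depends only on the within-sample ordering of the two fractions (hence is
invariant to any monotone rescaling). Ranking is by descending score,
default top-K 100.

Both scores depend on relative frequencies only, so per-sample rescaling of
total expression (library size, any monotone normalization of gene totals)
leaves them unchanged.

**Dichotomization.** `split_by_regulator` supports a median split (samples
at or below the median are "low"), an explicit threshold, and a preset
mapping — the latter because published low/high assignments (e.g. a 5/13
split of 18 cell lines) rarely correspond to a recomputable cut. Each group
must have ≥ 2 samples.

**Group PSI comparison.** Classical pooled-variance two-sample Student's t
test, two-tailed. With zero pooled variance and unequal means the statistic
is infinite; the result is flagged `degenerate` with p reported as 0 rather
than raising a division error.

**Inference.** Discovery is score-ranked (top-K), not FDR-controlled,
matching how such screens are reported. As an optional extension,
permutation p-values are available: the regulator is permuted across
samples (default 200 permutations), |delta_r| recomputed for every gene,
and each gene's p-value taken against the pooled null with the add-one
estimator, then BH-adjusted. These are clearly labelled extra columns.

## Survival analysis

Patients are stratified by the tumor/normal expression ratio of a single
feature: `fold_change ≥ threshold` (default 2.0, boundary **inclusive**)
defines the upregulated stratum. Patients with normal-tissue expression 0
are unevaluable and excluded with a warning. Survival curves use the
Kaplan-Meier product-limit estimator and strata are compared with the
standard two-group log-rank test (ties handled by simultaneous risk-set
accounting); both are computed with `lifelines`. `event = 1` encodes an
observed death; censored observations carry `event = 0`.

## Differential-expression filter

Per gene: Welch (unequal-variance) t test on `log2(x + 1)` values between
two conditions (≥ 2 replicates each), Benjamini-Hochberg adjustment across
genes, and a pass decision `p_adjusted < 0.01 AND |log2FC| > 1.0` with both
inequalities **strict** — a gene at exactly |log2FC| = 1.0 fails. Genes with
zero variance in both groups get p = 1 when the means agree and p = 0 when
they differ. Welch was chosen over the pooled-variance form because
replicate variances in expression data are rarely equal; the thresholds are
parameters.

## In-silico RT-PCR

The forward primer is matched on the sense-strand cDNA directly and the
reverse primer as its reverse complement downstream of the forward site;
the leftmost forward site (warned when multiple) and its nearest downstream
reverse site are used. Product length runs from the first base of the
forward site through the last base of the reverse site inclusive — both
primers count, matching how gel band sizes are reported. Matching is exact
by default (`max_mismatches = 0`, plain-ACGT primers); a Hamming-distance
scan supports small mismatch tolerances. Inserting k bases strictly between
the sites grows the product by exactly k, which is what makes one primer
pair discriminate cassette-exon isoforms on a gel.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with known
ground truth:

- **Regulator**: log-normal TPM across samples (defaults: log-mean 3,
  log-sd 1 — a mid-abundance gene with a strong gradient). The link operates
  on the *standardized log* regulator `z`, since expression gradients are
  multiplicative.
- **Switch genes**: inclusion-isoform fraction `f1 = logistic(β(z − c))`,
  defaults β = 4, c = 0. The logistic is the minimal bounded monotone link;
  the analysis itself assumes nothing about its form.
- **Null genes**: `f1` constant per gene, drawn once from U(0.2, 0.8).
- **Counts**: negative binomial with mean = gene level × fraction ×
  (transcript length / 1000) and shared dispersion α = 0.1
  (variance m + αm²), gene levels log-normal (log-mean 5.5, log-sd 0.8) —
  moderately expressed genes with typical bulk RNA-seq overdispersion.
  Because the mean is length-weighted, TPM ratios recover the planted
  fractions.
- **Structure**: every gene has exactly two isoforms differing by one
  90-bp cassette exon (so the event classifier sees SE throughout);
  junction counts are binomial(depth, f1) with Poisson depth (mean 50).
- **Default design**: 18 samples, 20 switch genes among 2000 — a small
  cell-line panel with a sparse planted signal.
- **Seeding**: one global seed drives counter-based per-gene substreams
  (`SeedSequence((seed, kind, index))`), so enlarging a cohort never
  reshuffles previously generated genes, and fixed seeds are bit-stable.

The survival generator draws exponential event times (baseline median 20
months), multiplies the hazard by `hazard_ratio` (default 3) for patients
whose simulated tumor/normal ratio clears the fold threshold, and censors
uniformly on (0, 60) months. The DE generator plants a given fold change
(default 4×, 50 of 2000 genes) with log2-scale replicate noise; its default
4 replicates at sd 0.05 define a deliberately near-noiseless scenario in
which the planted genes are unambiguously recoverable, so the filter's
thresholds — not the noise — are what is being tested.

**What the synthetic cohorts do not emulate**: more than two isoforms per
gene, batch effects, GC/length biases, correlated genes, dropout,
non-exponential hazards, informative censoring. Passing the planted-signal
and calibration checks therefore demonstrates correctness of the statistics
under the model's assumptions, not performance on arbitrary real cohorts.

## Problem sizes and tolerances

The test suite and the acceptance script use: 10 cohorts of 2000 genes × 18
samples for planted-signal recovery (the planted 20 genes must average
≥ 90% presence in the top 40); 400 null genes × 200 permutations for
delta_r calibration and 500 replicate cohorts of 40 patients for log-rank
type-I error, both checked against 5% within a 3σ binomial interval; exact
agreement (to 1e-9 relative or better) for all closed-form oracles; TPM
column sums at 1e-6 relative tolerance. Fraction sums per gene hold to
1e-9 where defined.

## Known limitations

- The event classifier types the designated pair only; it does not generate
  events from a full annotation against all isoform combinations.
- Pearson on raw TPM is sensitive to the regulator's heavy right tail;
  rank-based alternatives are deliberately not substituted because the
  correlation-difference statistic is defined on Pearson.
- The kTSP score's tie handling (½ per tie) makes it conservative for
  heavily tied, low-depth fraction estimates.
- PSI length normalization assumes a simple cassette geometry; complex
  multi-exon events are out of scope.
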