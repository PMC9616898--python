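# isoswitch

Regulator-conditioned isoform-switch analysis for bulk RNA-seq.

`isoswitch` is for transcriptomicists asking a specific question: *as a
splicing regulator's expression varies across samples, which genes switch
which isoform they predominantly express?* The canonical instance is an
epithelial splicing factor (such as ESRP1) driving cassette-exon choice in
a cancer cell-line panel, where the exon-included and exon-skipped isoforms
of a target gene trade places along the regulator gradient. The package
covers the downstream analysis chain — everything after transcript
quantification:

- **TPM normalization** and per-gene **isoform relative frequencies**;
  junction-based **PSI** for cassette exons
  (`psi = (I/L_I) / (I/L_I + E/L_E)`, defaults `L_I=2, L_E=1`).
- **Splice-event classification** of an isoform pair into SE, RI, A3, A5,
  AF, AL or MX (strand-aware, with `complex`/`identical` catch-alls).
- **Switch scoring**: the correlation-difference statistic
  `Δr = r(reg, f₁) − r(reg, f₂)` with an expression filter
  (mean f₁ + mean f₂ ≥ 0.5) and top-K ranking, and a two-group kTSP-style
  rank-pair score `|P̂(f₁>f₂|low) − P̂(f₁>f₂|high)|`; group PSI comparison
  by Student's t test; optional permutation p-values (BH-adjusted).
- **Survival analysis**: ≥ k-fold tumor/normal stratification (boundary
  inclusive), Kaplan-Meier curves, log-rank test; a threshold **DE filter**
  (Welch t on log2(x+1), BH, pass iff adjusted p < 0.01 and |log2FC| > 1.0,
  strict).
- **In-silico RT-PCR**: predicted amplicon sizes showing a single primer
  pair discriminates cassette isoforms by product length.
- A **synthetic cohort generator** with planted switch genes, null genes,
  negative-binomial counts, junction counts and paired tumor/normal
  survival cohorts, so the whole chain is testable without any downloads.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

Simulate an 18-sample cohort (20 planted switch genes among 2000), quantify
it, and scan for switches against the simulated regulator gene `REG`:

```sh
isoswitch simulate --seed 7 --out-dir demo/cohort
isoswitch quantify --counts demo/cohort/transcript_counts.tsv \
    --gtf demo/cohort/transcripts.gtf \
    --junctions demo/cohort/junction_counts.tsv --out-dir demo/quant
isoswitch switch-scan --fractions demo/quant/isoform_fractions.tsv \
    --tpm demo/quant/tpm.tsv --regulator REG --top-k 20 --out-dir demo/scan
```

```
scored 2000 genes -> demo/scan
```

The first lines of `demo/scan/switch_scores.tsv` (isoform1 is the isoform
favored in regulator-high samples):

```
gene_id  isoform1    isoform2    r1     r2      delta_r  ...  rank  in_top_k
NL1533   NL1533.skp  NL1533.inc  0.766  -0.766  1.532    ...  1     True
SW0001   SW0001.inc  SW0001.skp  0.698  -0.698  1.396    ...  2     True
```

A planted switch gene (`SW0001`) scores Δr ≈ 1.4: its inclusion isoform's
fraction correlates at r ≈ +0.70 with the regulator and the skipped
isoform at −0.70. (One null gene happens to outscore it here — with 1980
null genes and 18 samples, a top-ranked chance correlation is expected;
recovery is assessed against the top 40, where on average > 99% of planted
genes land.)

In-silico PCR on a synthetic exon-skipped/exon-included transcript pair
built around an isoform-discriminating primer pair:

```sh
isoswitch amplicon --fasta demo/isoforms.fa \
    --fwd CCTCAGCAACAACCCCTCTA --rev CCTGCTCTTCAATAACATCC \
    --out demo/amplicons.tsv
```

```
transcript_id  product_length  forward_pos  reverse_pos  mismatches
 exon_skipped             222           30          232           0
exon_included             294           30          304           0
```

One primer pair, two products: 222 bp without the cassette exon, 294 bp
with it — the 72-bp difference is exactly the cassette length.

Survival on a simulated 37-patient paired tumor/normal cohort, stratified
at ≥ 2-fold upregulation:

```sh
isoswitch survival --survival demo/survival.tsv --threshold 2.0 --out-dir demo/surv
```

```
log-rank chi2=6.0031 p=0.01428 (upregulated n=10, other n=27)
```

Patients whose tumor upregulates the feature ≥ 2-fold (here with a planted
hazard ratio of 3) show significantly shorter survival.

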