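# Methods

This document records the statistical models, the conventions and default
parameters, the scope of the simulator, the numerical choices, and the known
limitations of the `mpradnv` package. Every empirical claim here is computed
by the test suite (`tests/`) or by `scripts/acceptance.py`; nothing is quoted
from external data.

## 1. Data model and notation

A library sequence *s* (a 200-nt candidate regulatory sequence: a
reference-allele window, an alternate-allele window, a positive control, or
a scrambled negative control) is tagged by a set of 15-nt barcodes. For
barcode *b* of sequence *s* in replicate *t* we observe a DNA (construct)
count and an RNA (transcript) count. The estimand is the induced
transcription rate `alpha_st`: transcripts produced per construct copy,
up to a global scale fixed by a normalisation convention (§3).

## 2. Barcode association

Association reads are (barcode, UMI, sequence_id) triples; `*` denotes a
read mapping to no library sequence. A barcode is **confidently** assigned
to the sequence with the most supporting unique UMIs when

- the supporting unique-UMI count is ≥ `min_umis` (default 3), and
- the support fraction (supporting UMIs / all unique UMIs for the barcode,
  unmapped included in the denominator) is ≥ `min_fraction` (default 0.8),

both thresholds inclusive. A tie for the best-supported sequence is
ambiguous regardless of counts. Duplicate reads (PCR copies of the same
triple) are counted once. Barcodes whose length is not 15 are skipped and
counted.

Count tables keep only confidently assigned barcodes observed with positive
counts in **both** the DNA and RNA library of the same replicate. QC
fractions (confident / ambiguous / unobserved) are read-weighted and sum
to 1.

These decisions are verified exhaustively against direct rule evaluation for
every UMI split up to 10 UMIs (286 cases).

## 3. Size factors

Sequencing depth differs between replicates and library types. Per library
type (DNA, RNA), per-sequence total counts are normalised by
median-of-ratios across replicates: for the matrix of per-sequence totals
(restricted to sequences positive in every replicate), the size factor of
replicate *t* is `exp(median_s(log k_st − mean_t log k_st))`, rescaled to
**geometric mean one** across replicates. The product-one constraint is the
identifiability convention: multiplying all DNA and RNA factors by a common
constant leaves every alpha unchanged, while multiplying only the RNA
factors by *c* divides every alpha by *c* (both properties are tested).
The simulator draws its true factors log-uniform in [0.5, 2] and renormalises
them to geometric mean one, so estimated alphas are directly comparable to
the simulated truth.

## 4. Transcription-rate estimation (nested GLMs)

Two nested likelihoods:

1. **DNA (gamma).** The latent construct abundance `d_sb` is gamma
   distributed. With a single DNA observation per barcode the gamma MLE of
   its mean is the observation itself, so
   `d̂_sb = dna_count / sf_dna_t`.
2. **RNA (negative binomial, NB2).** `y_sbt ~ NB(mu, r_s)` with
   `log mu = theta_st + log(d̂_sb · sf_rna_t)`; `alpha_st = exp(theta_st)`.
   The dispersion `r_s` is shared across the sequence's barcodes and
   replicates.

For fixed `r`, the log-likelihood is concave in `theta`; it is maximised by
Newton iterations with step halving (score `y − mu(y+r)/(r+mu)`, weight
`(y+r)·mu·r/(r+mu)²`), with the linear predictor clipped at ±40 and a 1e-12
ridge on the Hessian solve. The dispersion is profiled by bounded scalar
minimisation of the negative profile log-likelihood over
`log r ∈ [log 1e-2, log 1e6]` (`xatol` 5e-3), warm-starting `theta` between
evaluations. A fixture in which `rna = 3 × dna` exactly recovers
`alpha = 3` to 1e-6 (the score vanishes at the exact ratio for every `r`).

On simulated data at the default design (3 replicates, ~125 barcodes per
sequence) the median relative error of alpha is ≈1.3% over 2000 sequences
(acceptance output `alpha_median_rel_err_pct`), and the error decreases with
barcode depth.

## 5. Activity classification

Alpha means are MAD-normalised against the scrambled-negative null:
`z = (alpha − median(neg)) / (1.4826 · MAD(neg))`. The add-one empirical
upper-tail p-value is `(1 + #{neg ≥ alpha}) / (1 + #neg)`, BH-corrected
across tested sequences; `active` means FDR ≤ the configured threshold
(default 0.05). At least 20 negatives are required; a zero MAD raises a
degenerate-null error.

**Granularity caveat.** The smallest attainable empirical p is
`1/(#neg + 1)`. With 150 negatives and thousands of tested sequences of
which only a small fraction is truly active, no call can survive BH at
FDR 0.05 — the classifier is conservative by construction at this design,
although positive-control alphas themselves are recovered accurately.
Under the global null the active fraction satisfies the nominal bound
(tested).

## 6. Allelic differential activity

Per variant, the reference and alternate barcode observations are pooled.
The **full** model fits one alpha per replicate plus a shared allelic log
fold change (coefficient on an alternate-allele indicator); the **null**
model drops the allelic term. The dispersion is profiled under the full
model and held fixed for the null fit, giving a 1-df likelihood-ratio
statistic referred to chi-square. BH FDR is applied across variants. The
reported `lfc` is `ln(mean_t alpha_ref,t / mean_t alpha_alt,t)`.

**HcDNV** (high-confidence de novo variant): FDR ≤ 0.2 **and** |lfc| ≥ 0.1,
both inclusive. `activator` means the reference alpha exceeds the alternate
(the variant destroyed activity); `inhibitor` the reverse.

At the default design with planted |ln FC| = 0.5 effects, detection power is
100% on 50 planted effects with zero false discoveries (acceptance outputs
`hcdnv_power_pct`, `empirical_fdr`); the empirical FDR bound
`≤ q + 3·SE` is asserted rather than the point value, since the Monte-Carlo
SE at ~50 calls is large.

## 7. Case/control contrast and enrichment

The 2×2 table (HcDNV vs background) × (case vs control) is tested two-sided
by Fisher's exact test; both the sample odds ratio `ad/bc` and the
conditional-MLE odds ratio with a 95% CI are reported. Rank-sum
(Mann–Whitney) comparisons of |lfc| are run within four strata (all HcDNVs,
activators, inhibitors, background) and Bonferroni-corrected by 4.

Annotation enrichment runs one Fisher test per `anno_*` column against the
HcDNV flag over the tested-variant universe, Bonferroni-corrected by the
family size (the number of categories, 28 by default). Peak overlap uses
0-based half-open intervals — a point interval for SNVs and insertions, the
deleted span for deletions — against an interval tree; results match an
all-pairs oracle. GC content (ambiguous bases excluded from numerator and
denominator) is compared between groups by two-sided rank-sum.

The published contingency table (78, 87; 1554, 1371) reproduces exactly:
FET p = 0.1496 (published as the 2-decimal truncation 0.14), sample and
conditional OR 0.79, CI 0.57–1.10, proportions 47.27% / 53.13% (published
truncations 47.2% / 53.1%).

## 8. Motif scanning with exact p-values

A PWM (probability matrix, rows sum to 1; background defaults to uniform;
pseudocount 0.1) is scored as
`log2((p + pc·bg) / ((1 + pc) · bg))`, with zero-probability entries floored
at −30 bits. Per-position scores are discretised to integers at a
granularity of 1e-3 bits; the exact distribution of a random background
window's integer score is computed by dynamic-programming convolution, and
the p-value of an observed window is the exact upper tail. This matches
exhaustive 4^w enumeration to relative 1e-9 for widths ≤ 8 at several
granularities. Both strands are scanned (the reverse-complement PWM with its
own null); windows containing ambiguous bases are skipped.

A **hit** requires p < 1e-5 (strict), so informative motifs must be at least
9 nt wide (a uniform-background width-8 word has probability 4⁻⁸ ≈ 1.5e-5);
the bundled toy collection uses widths 10–14. Disruption is classified on
the motif-identity sets of variant-covering hits (the window must intersect
the variant interval at offset 99): `disrupted = ref \ alt`,
`gained = alt \ ref`, `unchanged = ref ∩ alt`.

## 9. Library design

- Reference/alternate windows: the allele whose sequence is genomic
  (reference for SNVs/deletions, alternate for insertions) is exactly 200 nt
  with the variant start at 0-based offset 99; the partner is obtained by
  allele substitution, so indel pairs differ in length by the indel size.
  The input reference allele is checked against the genome
  (reference-mismatch error) and windows must fit the chromosome
  (boundary error).
- Scrambled negatives: uniform random permutations of randomly chosen
  reference sequences, half from case variants and half from control
  variants, preserving base composition exactly.
- Positive controls: (1) top 5000 H3K27ac peaks by score, (2) the
  highest-scoring ATAC peak contained in each, (3) ATAC midpoint within
  [150, 2000] bp (inclusive) of a TSS, (4) that TSS's expression ≥ 2,
  (5) a 200-bp window centred on the ATAC midpoint; ranked by ATAC score
  with (chromosome, start) tie-breaking.

## 10. Simulator scope and defaults

The simulator emulates the assayed design; its defaults *are* the study
conditions and are not tuned to any test outcome:

| parameter | default | rationale |
|---|---|---|
| `n_variants` | 3600 | library scale (1888 case / 1712 control via `frac_case`) |
| `n_replicates` | 3 | assay design |
| `barcodes_per_seq_mean` | 125 | truncated-Poisson barcodes per sequence |
| `n_pos_controls`, `n_neg_controls` | 150, 150 | library design |
| `dna_gamma_shape`, `dna_gamma_scale` | 4, 12.5 | construct abundance mean 50, CV 0.5 — a plausible sequencing depth; free parameters, documented not fitted |
| `rna_dispersion` | 10 | moderate NB overdispersion; a free parameter (no published dispersion to match) |
| `baseline_alpha` | 1.0 | with geometric-mean-one size factors this makes simulated truth directly comparable to estimates |
| `positive_alpha_mult` | 8 | strong positive controls |
| `frac_true_effect`, `effect_size_log` | 0.05, 0.5 | planted allelic effects, alternating activator/inhibitor |
| `gc_effect_target`, `gc_null_target` | 0.63, 0.50 | planted GC correlate of effect windows |
| `alpha_log_sd` | 0.25 | biological variation of per-sequence rates |
| `n_annotation_categories` / enriched | 28 / 10 | annotation flags; enriched categories have rate 0.35 vs 0.15 among effect variants |
| `assoc_umi_mean`, `assoc_ambiguous_frac` | 10, 0.05 | association depth and contamination |

Counts are generated exactly per the §4 model: `d_sb ~ Gamma(shape, scale)`
shared across replicates, DNA `= round(d_sb · sf_dna_t)`, RNA
`~ NB(alpha_s · d_sb · sf_rna_t, r)`. Association reads give every barcode
≥ 3 unique true UMIs; contaminated barcodes get an equal number of UMIs to a
second sequence (support fraction ~0.5 → ambiguous). The synthetic
epigenome pairs each H3K27ac peak with one contained ATAC peak and a nearby
TSS with log-normal expression, so roughly half the candidates survive the
positive-control filters.

## 11. Numerical choices

- All randomness uses `numpy.random.default_rng` with explicit seeds;
  sub-generators derive from `[seed, k]` sequences, and the acceptance
  script derives 31-bit seeds via `SeedSequence`.
- BH adjustment uses `statsmodels.stats.multitest.multipletests`; Fisher
  tests and the conditional odds-ratio CI use `scipy.stats`; interval
  overlap uses `intervaltree`; FASTA/MEME I/O uses Biopython.
- MEME probability rows are validated to sum to 1 within 1e-3 (6-decimal
  files cannot satisfy a tighter bound) and renormalised; motifs are written
  with `nsites = 1e6` so count-based parsers round-trip at 6-decimal
  precision.
- The LRT statistic is clipped at 0 (profiling under the full model can
  leave the null fit marginally better at the fixed dispersion).

## 12. Limitations

- The activity classifier's empirical null is granular (§5): with few
  negatives relative to tested sequences it cannot reach small FDRs; it is
  conservative, never anticonservative.
- The one-observation gamma step passes the normalised DNA count through as
  a point estimate; DNA measurement noise is not propagated into the alpha
  standard errors, so allelic p-values rely on the NB dispersion absorbing
  it (adequate in simulation: empirical FDR ≤ nominal).
- Sequences observed in fewer than all replicates are fitted on the
  replicates present; a variant is excluded from allelic testing only if an
  entire allele is missing.
- The simulator plants a single effect size per run and draws independent
  barcodes per sequence; it does not model barcode-sharing artefacts,
  integration-site effects, or guide-strand biases.
- Published-value checks reproduce arithmetic printed in the source table
  (the published p-value and proportions are truncations of the computed
  0.1496 / 47.27% / 53.13%); the full variant-level result set is not
  derivable without the original sequencing data, so parameter recovery is
  established on simulation instead.
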