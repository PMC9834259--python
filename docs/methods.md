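# Methods

## Model and procedure

`medipdmr` treats MeDIP-seq as a window-count problem.  The reference
genome is tiled into consecutive 1000 bp windows (the final window of
each chromosome is truncated, never dropped, and its true length is
used wherever length matters, e.g. RPKM).  Aligned single-end reads
are deduplicated within each sample — records sharing (chromosome,
5′ alignment coordinate, strand) are collapsed to one, the usual
treatment of PCR duplicates for single-end data — and each retained
read is assigned to the one window containing its alignment midpoint.
Midpoint assignment conserves total counts and makes simulation →
SAM → recount an exact round trip.  Library sizes are the per-sample
deduplicated totals over the whole genome and are fixed **before** any
window filtering, so normalization reflects sequencing effort rather
than the analysis subset.  Windows whose mean raw count across all
samples (groups pooled) is below 10 are excluded from testing.

Counts for window *w*, sample *s* are modelled as negative binomial
with mean μ·lib_s and common dispersion φ, Var = μ + φμ².  Analysis
steps:

1. **TMM normalization.**  Standard trimmed mean of M-values: the
   reference sample is the one whose 75th-percentile count fraction is
   closest to the across-sample mean of those fractions; per sample,
   log2 ratios M and mean log2 abundances A are formed over windows
   positive in both sample and reference, the extreme 30% of M and 5%
   of A are trimmed by rank, and the factor is 2 to the inverse-variance
   weighted mean of the surviving M.  Factors are rescaled to geometric
   mean 1.  The implementation reproduces Bioconductor edgeR's
   `calcNormFactors(method="TMM")` to ~1e-9 on test fixtures.

2. **Common dispersion (qCML).**  Counts are scaled to the geometric
   mean effective library size ("pseudo-counts"); within each group the
   distribution of the counts given their total is Dirichlet-multinomial
   with per-sample shape 1/φ, and the summed conditional log-likelihood
   is maximized over φ by bounded golden-section search on log φ in
   [1e-6, 5].  One common φ is used for all windows: per-window
   estimation is unstable at cohort-scale sample sizes, and the
   conditional (exact-test) framework expects a shared shape.  A
   method-of-moments fallback guards optimizer failure.

3. **Exact test.**  Per window, rounded pseudo-count group totals
   y₁ (n₁ case samples) and y₂ (n₂ controls) are treated as NB with
   shapes n₁/φ and n₂/φ (a sum of n i.i.d. NB(μ, φ) is NB(nμ, φ/n)).
   Conditional on s = y₁+y₂ the mean cancels, leaving a beta-binomial
   pmf computed stably through log-gamma functions; φ = 0 uses the
   binomial limit.  The two-sided p value sums the probabilities of all
   outcomes no more likely than the observed one (minimum-likelihood
   rule).  Outcome probabilities are compared with a relative tolerance
   of 1e-10 so mathematically tied outcomes (the symmetric design) stay
   together under floating point.  s = 0 yields p = 1 and log2FC 0.
   The per-window log2 fold change is
   log2((mean case + 0.5)/(mean control + 0.5)) on pseudo-counts; the
   0.5 prior avoids infinities on zero groups.  P values match both a
   brute-force enumeration of the conditional law and edgeR's
   `exactTest(rejection.region="smallp")` to better than 1e-9.
   Windows sharing a total s reuse one pmf evaluation, so 20,000
   windows test in well under a second.

4. **FDR.**  Benjamini–Hochberg across all tested windows of a
   comparison, one family per comparison (statsmodels implementation).

5. **DMR calling.**  Seeds are windows with p below 10⁻⁵.  Edges extend
   iteratively: any tested window with p < 0.1 within 1000 bp
   (edge-to-edge, so a touching window always qualifies) of the current
   span is absorbed until a fixed point; this is implemented as
   single-linkage chaining of extension-qualified windows with gaps
   ≤ 1000 bp, keeping chains that contain a seed — provably the same
   fixed point, since any window inside a chain's span lies within
   1000 bp of a member.  Depth-filtered windows carry no p value: they
   neither trigger nor block extension but are spanned when flanked.
   Overlapping calls merge.  Each DMR reports its significant-window
   count, minimum p, the BH-adjusted p and log2FC of that minimum-p
   window (the per-DMR direction), length, and CpG count/density, where
   a CG dinucleotide straddling the right boundary counts if its C is
   inside.  A threshold table re-calls DMRs over a ladder of seed
   thresholds and reports totals and multi-window counts.

6. **Comparisons.**  Genes are read from GFF3 (gene-type features,
   converted to 0-based half-open) and associated with any DMR whose
   edge-to-edge gap to the gene body is ≤ 10 kb inclusive — the gene
   body rather than the TSS, to capture proximal and distal promoter
   neighbourhoods on either side.  Venn overlap between 2–4 named DMR
   sets uses a ≥ 1 bp shared-span predicate; extended overlap re-calls
   one comparison's windows at a relaxed seed (p < 0.05, same extension
   rule) and reports the fraction of the other's strict DMRs that are
   covered.  RPKM(w, s) = count/(length_kb · lib_s/10⁶) with raw library
   sizes; PCA (samples as observations, DMR windows as features) is run
   on centered, unscaled RPKM — MeDIP RPKM is already on a common scale
   — with component signs fixed by making each component's
   largest-magnitude loading positive, and zero scores returned for
   degenerate (identical-sample) input.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window_size | 1000 | bp | resolution/power balance standard for MeDIP |
| min_avg_depth | 10 | reads/window | excludes windows too shallow for the NB test |
| p_seed | 1e-05 | — | stringent seed; genome-wide scale |
| p_extend | 0.1 | — | permissive edge growth around a confident core |
| neighborhood_bp | 1000 | bp | one window of slack across noisy/filtered gaps |
| p_relaxed | 0.05 | — | extended-overlap recall threshold |
| gene_max_distance | 10000 | bp | proximal + distal promoter capture |

## The synthetic-data generator

The generator emulates a desk-scale two-group MeDIP cohort and is the
substrate for every end-to-end test.  Defaults: 2 chromosomes of
300 kb; CpG background 2 per 100 bp (CGs are planted explicitly and the
remaining sequence is filled so no spontaneous CG arises, so realized
density tracks the target tightly); 8 cases vs 8 controls (a scaled-down
rendition of ~15-per-group clinical cohorts); mean 30 deduplicated
reads per window with window means proportional to CpG count + 1 (the
+1 floor keeps zero-CpG windows at nonzero background, as MeDIP input
is, and keeps the depth filter exercisable); NB dispersion 0.1;
per-sample library factors drawn lognormal (σ = 0.15) unless supplied;
20 spiked regions, window-aligned, 1 or 2 kb, ≥ 3 windows apart, half
hyper- and half hypomethylated at |log2FC| = 2 applied to case means.
Counts are drawn gamma-Poisson so φ = 0 is exactly Poisson.  SAM
emission places each counted read uniformly on a distinct
(offset, strand) slot inside its window and can append exact positional
duplicates at a configurable expected rate per read, so deduplicated
recounting reproduces the matrix exactly.

What it does **not** emulate: fragment-length distributions, antibody
efficiency and CpG-density-dependent capture saturation, GC bias,
mappability, paired ends, or FASTQ-level errors.  Passing recovery
tests therefore demonstrates the statistical machinery is correct under
the stated model, not that real tissue comparisons will reach the same
sensitivity.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; BED is written
  natively, GFF3 converted on read.
- All randomness flows from one integer seed through named
  `SeedSequence` sub-streams (genome / counts / reads), so partial
  regeneration is reproducible and reruns are byte-identical.
- Group orientation: the label "control" (case-insensitive) is taken as
  the reference when present; otherwise labels resolve alphabetically
  and can be set explicitly.  Positive log2FC always means higher
  coverage (methylation) in cases.
- The TMM delta-method weight is floored at 1e-12 to keep the
  degenerate y = N case finite.
- The exact test's per-DMR score column is round(−10·log10 min p),
  capped at 1000.
- Merged DMRs inherit the minimum-p window's statistics; DMRs are named
  `<chrom>:<start>-<end>`.

## Validation and problem sizes

The test suite validates the exact test against brute-force enumeration
(all totals ≤ 40, three dispersions, to 1e-12) and against edgeR via
Rscript; TMM against `calcNormFactors`; calibration on a null
simulation of ~20,200 windows (5 vs 5, φ = 0.1: observed type-I rate
≈ 0.047 at α = 0.05, zero windows below 10⁻⁵); dispersion recovery
within a factor of 2 at φ ∈ {0.01, 0.1, 0.5} (10 vs 10, ~5,000
windows); DMR recovery ≥ 90% sensitivity and precision on 100 spiked
regions (8 vs 8, φ = 0.05, depth 30) with a hyper/hypo split of
0.5 ± 0.1; 1,000-track fuzzing of the extension postconditions; and
exact file round trips.  These sizes keep the full suite under a
minute of simulation time while leaving Monte-Carlo margins wide
relative to the asserted tolerances.

## Known limitations

- One common dispersion; no tagwise shrinkage or GLM/covariate path.
- Single-end reads only; no BAM indexing (plain SAM text is read).
- A DMR can rarely bridge two opposite-direction differential regions
  when a chance p < 0.1 window links them; its reported direction then
  reflects the stronger side only.
- The per-DMR FDR is descriptive (the adjusted p of the minimum-p
  window), not a calling filter.
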