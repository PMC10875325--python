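# Methods

## The analysis in one paragraph

Plant mitochondrial genomes segregate variants whose within-individual
allele balance (heteroplasmy) can be shaped by nuclear genes — restorers
of fertility, RNA-editing factors, and other mitonuclear machinery.
`mitolink` treats each mitochondrial variant as a quantitative trait:
the per-individual fraction of sequencing reads supporting the reference
allele. Each such trait is tested for association against genome-wide
nuclear SNPs with a kinship mixed model, clusters of significant SNPs
become "signals" with candidate genes, and companion modules cover the
supporting analyses: strict filtering of organelle variant calls,
windowed nucleotide diversity contrasts, NG86 Ka/Ks between a population
consensus CDS and an outgroup, and C-to-U RNA-editing detection from
replicate RNA-seq variant calls.

## Mitochondrial variant filtering

Organelle calls are vulnerable to two artifact classes: repeated tracts
inside the mitochondrial genome, and tracts shared with the nuclear or
plastid genome (numts and plastid transfers) that cross-map reads. The
cascade applies, in fixed order:

1. **Biallelic / missingness** — drop sites with more than one alternate
   allele or with missing genotype calls in more than 40% of
   individuals (boundary inclusive: exactly 40% is kept).
2. **Depth** — drop sites whose mean sample depth exceeds 1.5× the
   genome-wide mean depth (multi-copy signature). The genome mean is
   computed as the mean over called sites of the per-site mean sample
   depth, since a VCF carries no per-base coverage; a precomputed mean
   can be supplied instead. Individual observations covered by fewer
   than 4 reads are set missing (not zero — zero would fabricate a
   measured frequency), after which the missingness rule is re-applied.
3. **Region masks** — drop sites inside detected self-repeats (≥ 100 bp,
   both strands), cross-genome homology tracts (≥ 100 bp), or
   user-supplied BED intervals.

Repeat and homology detection uses exact maximal matches found by
duplicated-k-mer span union with k equal to the length threshold: the
union of the spans of all k-mers occurring more than once equals the
union of all maximal exact repeats of length ≥ k. This is deterministic
and exactly matches the length-threshold criterion; scored aligners
(BLAST, mummer) would additionally admit mismatched homology, which a
user can emulate by passing their own BED mask. `min_len < 20` is
rejected as a guard: short words recur by chance and would mask
everything.

Every removal is recorded with its first-cause reason
(`non_biallelic`, `missing_gt`, `high_depth`, `low_reads_all`,
`repeat_region`, `cross_homology`); kept + removed always equals the
input count, and the cascade is idempotent.

## Heteroplasmy phenotypes

For each surviving variant, the phenotype of individual *i* is
`ref_reads / total_reads`, in [0, 1], missing when coverage is absent or
masked. The matrix is written as TSV with `NA` for missing. A binary
companion maps fractions < 0.05 to 0 and > 0.95 to 1 (strict
inequalities; intermediate heteroplasmy is excluded), supporting the
binary-trait re-analysis. Variants are classified as
`homoplasmic_both_alleles`, `exclusively_heteroplasmic_alt` (the
alternate allele occurs but never at homoplasmic level — using the same
0.05/0.95 thresholds as the operational meaning of "pure", since raw
read ratios are never exactly 0 or 1 at finite depth), or
`monomorphic`.

## Mixed-model association

The model per phenotype is `y = Xβ + u + e`, `u ~ N(0, σg²K)`,
`e ~ N(0, σe²I)` with `X` an intercept and `K` the identity-by-state
kinship `K_ij = 1 − mean_s |g_is − g_js| / 2` (a standardized genomic
relationship matrix is available behind a flag). Missing dosages are
mean-imputed per SNP for kinship and testing; nuclear SNPs are
pre-filtered at missingness > 40% and MAF < 0.05.

Variance components are estimated once per phenotype by REML, profiled
in `δ = σe²/σg²` via a single eigendecomposition of `S K S` (`S` the
projection orthogonal to `X`), evaluated on a 100-point log₁₀δ grid on
[−5, 5] and refined by bounded scalar minimization; boundary optima are
flagged (pure-noise phenotypes drive δ to the upper boundary, σg² → 0).
Each SNP is then tested with the null covariance held fixed — the
single-rotation approximation used by EMMAX — by rotating `y`, `X` and
the genotype columns by `Σ^{-1/2}` and running ordinary regression on
the rotated data. The per-SNP standard error re-estimates the residual
scale from the rotated residuals, and the p-value is two-sided t with
`n − q − 1` degrees of freedom; this makes the `K = I` case collapse
exactly onto OLS and makes p-values invariant to affine transformations
of the phenotype. Zero-variance SNPs are recorded as skipped, and one
degenerate phenotype never aborts a multi-phenotype run.

Signals are maximal runs of SNPs with −log₁₀(p) strictly above 6 in
which consecutive members are separated by at most `max_gap_bp`
(default 1 Mb — the span of a signal is defined by its outermost
members, but when two above-threshold runs count as distinct is a free
parameter, so it is exposed). The lead SNP has minimal p (ties to the
smaller position); genes are attached by whole-gene interval overlap
with the signal span, and summaries report de-duplicated associated
genes as a percentage of the annotated universe. Term enrichment is a
one-sided hypergeometric test with Benjamini–Hochberg correction over
terms; term databases are external inputs.

## Diversity and Ka/Ks

Site π is `2·c0·c1 / (n(n−1))` over non-missing allele copies (each
diploid genotype contributes two copies). Window π sums site π over a
sliding window (default 100 kb window, 10 kb step) and divides by the
window length in bp, so monomorphic positions dilute but never add —
the semantics of the vcftools `--window-pi` track. Gene-level diversity
for target-vs-background contrasts is the mean π of windows overlapping
the gene span (switchable to site-level π inside the span; the
window→gene mapping is a genuinely open choice). Group differences use
the two-sided Wilcoxon rank-sum test, exact for combined n ≤ 30 without
ties, normal approximation with tie correction otherwise.

Ka/Ks uses the Nei–Gojobori (1986) counting estimator between a
population consensus CDS (majority allele at each variant site, ties
keep the reference) and an aligned outgroup CDS: synonymous site
fractions per codon averaged over both sequences, substitutions in
multi-hit codons averaged over all substitution pathways that avoid
intermediate stop codons, and the Jukes–Cantor correction applied to pN
and pS where valid (saturated proportions ≥ 3/4, which only arise on
very short or very divergent alignments, are reported uncorrected).
Changes to stop codons count as nonsynonymous in site counting, so
N + S = 3 per codon exactly. NG86 was chosen over ML codon models
because it is fully checkable by exhaustive pathway enumeration; the
Ka/Ks ratio is flagged undefined when Ks = 0.

## RNA-editing detection

C-to-U editing appears as C→T RNA-seq mismatches on the transcribed
strand (G→A in genome coordinates for minus-strand genes). A candidate
site must be variant-called in all replicates of its condition
(presence, not merely coverage), absent from matched WGS calls at the
same position (which would mark a genomic SNP), and inside an annotated
gene so the transcribed strand is defined. Efficiency is edited reads ÷
covering reads per replicate; the condition value is the unweighted
replicate mean. Differential editing between conditions uses an
absolute mean-difference threshold (default 0.10) rather than a formal
test — with 3 replicates per condition a parametric test has almost no
power and no statistic is canonical — and every flagged site satisfies
the threshold exactly. Codon positions are computed on spliced CDS
coordinates in transcription order, honoring segment phase;
inconsistent phase annotations are an error rather than a guess.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, under a
single seed:

- **Population structure** — Balding–Nichols subpopulation frequencies
  (default 3 subpopulations, F_ST 0.3, 300 individuals, 5,000 SNPs with
  ancestral MAF uniform on (0.05, 0.5)), binomial diploid genotypes.
  This produces both stratification and kinship signal that the mixed
  model must absorb.
- **Heteroplasmy phenotypes** — fraction = clip(μ + β·g_causal +
  polygenic + noise, 0, 1) with μ = 0.5, β = 0.2 per allele copy for
  the causal variant, a polygenic term drawn with covariance
  proportional to the realized IBS kinship scaled to contribute 40% of
  latent variance, and N(0, 0.05²) residuals. Clipping, not
  logit-scale simulation, because the phenotype is a raw read ratio.
- **Read sampling** — per-sample depth Poisson(100), reference reads
  Binomial(depth, fraction); zero depth is missing. Mean depth 100×
  reflects typical organelle coverage in resequencing panels (the
  motivating datasets average ≈128×).
- **Genomes** — random sequence with exact planted repeat pairs and a
  numt tract copied into a nuclear decoy contig; the bases flanking
  each planted copy are forced to mismatch so the planted tract is the
  maximal repeat by construction and truth masks are exact.
- **Editing data** — per-replicate binomial edited-read counts at
  planted strand-aware C sites, plus three decoy classes (WGS-shared,
  non-C-to-U, present in only 2 of 3 replicates).

Not emulated: linkage disequilibrium along the nuclear chromosome
(SNPs are exchangeable given the subpopulation), sequencing error,
index hopping, mapping bias, and recombination. Passing tests therefore
demonstrate the statistical engine and bookkeeping, not robustness to
alignment artifacts; on real data the filter cascade is the defense
against the latter.

## Numerical choices and problem sizes

- REML grid 100 points on log₁₀δ ∈ [−5, 5] plus Brent refinement to
  xatol 1e−8; kinship eigenvalues clipped at 0 when above −1e−8,
  otherwise an error.
- Lead-SNP ties break to the smaller position; consensus ties keep the
  reference base; exact-threshold values (−log₁₀p = 6, fractions at
  0.05/0.95) are excluded by the strict inequalities.
- The test suite exercises cohorts of 100–300 individuals with
  1,200–5,000 SNPs, 50-seed recovery experiments, and 20-seed editing
  recovery; these sizes give stable Monte-Carlo estimates while keeping
  the default suite fast. Calibration quantities (type-I error,
  genomic-control λ) are averaged over several null phenotypes because
  all tests of one phenotype share a single polygenic draw, making
  single-draw estimates far noisier than the nominal 1/√m.

## Known limitations

- Exact-match repeat detection does not emulate mismatch-tolerant
  homology search; supply a BED mask from an external aligner for that.
- The same linear mixed model is used for continuous, binary and indel
  phenotypes; a liability-scale model for binary traits is out of
  scope.
- Per-SNP variance components are not re-estimated (the single-rotation
  approximation); exact per-marker REML would be slower and changes
  little away from extremely strong associations.
- Differential-editing calls are threshold-based, not inferential.
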