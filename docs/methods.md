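# Methods

This note records the models, parameter choices and numerical
decisions behind `trfseq`, and what the synthetic validation does and
does not demonstrate.

## Read model and preprocessing

Raw reads are modeled as `[UMI][insert][untemplated base][adapter]`,
the layout produced by end-labeling small-RNA library chemistry in
which a template-switching RT appends one non-templated base and a
fixed 3′ adapter, with a 7-nt unique molecular identifier at the 5′
end. Trimming inverts this in three fixed steps: adapter removal
(first occurrence, ≤10% mismatches over the matched length, minimum
overlap 3, partial matches only at the 3′ read end), removal of the
single trailing untemplated base, then removal of the 7-nt UMI.
Parameters (adapter sequence, UMI length, trailing-base count,
mismatch tolerance) are all config-exposed; the defaults are the
values used throughout validation. Reads with no adapter occurrence
are kept whole, since inserts longer than the cycle count legitimately
lack adapter sequence. UMIs are recorded in read headers but not used
for deduplication — the pipeline takes no position on whether
libraries should be collapsed by UMI.

Length filtering is deferred: inserts under 16 nt are flagged during
trimming but dropped only after classification, and only when they do
*not* resolve to the tRNA category. tRNA-classified reads have their
own absolute floor of 15 nt (one below the non-tRNA minimum; a
documented package choice — the 16-nt rule is defined for non-tRNA
reads and some anchor must exist below it).

## Reference construction

Mature tRNAs = splice(genomic gene, introns) + `CCA`, with `G`
prepended for histidine isotypes. Intron coordinates are 0-based
half-open on the gene sequence, chosen so length arithmetic is closed
form (`len(mature) = len(gene) − introns + 3 (+1 His)`). By default
the `CCA` is always appended (`assume_cca_absent=True`), matching gene
sets that store untailed genomic sequences; the flag exists so
pre-tailed inputs are not double-tailed. Mitochondrial rRNA is one
subunit without repeat variants. Two distinct 28S records are allowed
and collapse to the single subunit key `28S` at classification, so
reads ambiguous between the two records are still counted once.

## Mapping

The classification rules consume only the *set of best mappings* per
read, so the mapper implements exactly that contract: all end-to-end
ungapped alignments at the minimum achievable Hamming distance (≤1
mismatch by default), on either strand, found via a pigeonhole chunk
index and verified directly. At tRF lengths on high-quality reads this
coincides with what a gapped seed-and-extend aligner reports as its
best-alignment set, and the equivalence to exhaustive sliding-window
search is enforced by property tests rather than assumed. `N` bases
score one mismatch each. Hit lists are sorted (class rank: tRNA <
rRNA < annotated gene < background, then ref id, position, strand)
before the 100-hit cap, so the cap can never discard a tRNA hit in
favor of a background hit and category precedence is stable under
truncation. Reverse-strand hits on mature tRNAs are *not* tRNA
evidence (antisense fragments are out of scope) and demote to
background. SAM import/export is provided so an external aligner can
stand in for the built-in search if it reproduces the same contract.

## Classification

Category precedence (tRNA ≻ rRNA/repeat ≻ annotated gene ≻
unannotated) and the positional typing rules are described in the
README. Two operationalizations deserve note. First, the end
tolerances: the whole-tRNA rule fixes 3 nt (5′) and 5 nt (3′); the
same tolerances are reused for tRF_5′/tRF_3′ end proximity, a symmetry
choice exposed in `ClassifierParams` rather than hard-coded. Second,
rule order (whole, then 5′, then 3′, then other) only matters inside
the tolerance bands; any alignment with d5 > 3 and d3 > 5 is
`tRF_other` under every ordering, which the exhaustive-substring
oracle test confirms. Distances are measured on the mature sequence
including the CCA tail, since classification operates on mature
references. Acceptor-only-specific reads are excluded from
decoder-level counts by default; a flag enables counting them at the
acceptor level, because the counting rule for that tier is genuinely
ambiguous and both behaviors should be available.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-condition definition. Defaults:

- 6 libraries (3 WT, 3 KO), ~50,000 reads each; library-size factors
  log-uniform on [0.5, 2] to exercise normalization.
- Counts per feature NB with `Var = μ + αμ²`, α = 0.1 (a typical
  biological-replicate overdispersion for bulk small RNA counts);
  α = 0 degenerates to Poisson.
- Composition (WT read mass): ~56% tRFs (45% tRF_5′, 9% tRF_3′, 2%
  tRF_other), 0.4% whole tRNA (full-length tRNAs clone poorly in
  small-RNA libraries), 30% rsRNA, 6% miRNA spread over 60 genes,
  ~7.6% unannotated.
- KO effect preset: log₂FC −2 on every tRF-class feature, −1 on rsRNA
  subunits, 0 on miRNA and unannotated features. These are test-harness
  contrasts chosen to mirror the qualitative depletion signature, not
  estimates of in vivo effect sizes.
- Fragment lengths: tRF_5′ 28–36 nt (5′ fragments cluster in the
  low-30s), tRF_3′ 18–36, tRF_other 16–40, rsRNA 20–50, unannotated
  16–45, miRNA = gene length (21–23). Whole-tRNA reads span the mature
  transcript within the classifier tolerances. All ranges are
  configurable.

The 60-gene miRNA block matters: median-of-ratios normalization is
only identified when the median feature is non-differential. Real
small-RNA count tables contain hundreds of condition-stable features;
a toy table in which nearly every feature is depleted makes the median
track the depletion and inverts apparent fold changes (the classic
compositionality failure). The default feature table therefore keeps
null features in the majority *by feature count* while tRFs dominate
*read mass* — both properties of the real libraries being emulated.

Inserts are placed so the classifier's rules recover the intended
label exactly (e.g. a tRF_5′ insert starts within 3 nt of the 5′ end
and ends > 5 nt from the 3′ end). Consequently, 100% classification
accuracy on error-free synthetic reads validates the internal
consistency of generator + trimmer + mapper + classifier — it does not
measure robustness to modification-induced misincorporation, indels,
ligation bias, PCR duplication or genomic multi-mapping beyond the
bundled reference, none of which the generator models (substitution
errors are available via `error_rate` but default to 0).

## Differential testing

Normalization, dispersion and testing are deliberately a small,
fully specified procedure rather than a re-implementation of a large
GLM framework; outputs on real data will differ from such frameworks
(no Cox–Reid shrinkage, no LFC shrinkage, no outlier replacement, no
independent filtering).

- **Size factors**: median-of-ratios over features with nonzero counts
  in every sample; an all-equal table yields unit factors; absence of
  any all-nonzero feature is an error advising a pseudo-reference.
- **Dispersion**: the default is a *single* α pooled across features,
  solved from `Σ (K − μ̂)²/(μ̂ + αμ̂²) = residual df` on
  within-condition residuals (Pearson moment matching, solved by
  Brent's method on [0, 100], floored at 1e−8). A per-feature
  method-of-moments estimator (`(s² − μ̄)/μ̄²` averaged across
  conditions, floored) is provided and selectable. The pooling default
  is deliberate: with 3 replicates a per-feature variance estimate has
  ~4 df, and a normal-reference Wald test built on it is strongly
  anti-conservative (empirical p<0.05 rate ≈ 0.12), while switching to
  a t reference with matching df destroys power (BH-surviving p-values
  become unreachable at realistic effect sizes). Sharing one α across
  features — exactly the regime the generator produces, and a
  reasonable approximation for count tables without a strong
  mean-dispersion trend — gives calibrated p-values *and* retains
  power, at the cost of mis-stating the variance of features whose
  true dispersion deviates from the pool; this is the procedure's main
  known limitation on real data.
- **Wald test**: log₂ ratio of normalized group means, delta-method
  standard error `[(1/μ̂₂ + α)/n₂ + (1/μ̂₁ + α)/n₁]/ln²2`, two-sided
  normal reference. A group that is all-zero for a feature gets a 0.5
  normalized pseudo-count so fold changes stay finite; features that
  are all-zero everywhere are reported with NA statistics and excluded
  from the BH denominator m. Significance: |log₂FC| > 1 and
  padj < 0.05. The overlap analysis between two comparisons defaults
  to padj < 0.05 alone, with the fold-change requirement optional,
  because the two rules serve different figures of merit (volcano
  calls vs shared-change sets).

Operating characteristics measured by replicated simulation at the
study design (1,000 features, n = 3 vs 3, μ = 200, α = 0.1; five
replicate draws averaged, since single-draw realized FDR at ~50 calls
has large Monte-Carlo variance): null p < 0.05 rate ≈ 0.054, null KS
statistic ≈ 0.03, power for log₂FC = −2 ≈ 0.98, false-discovery
fraction ≈ 0.06. These are recomputed, not quoted, by
`scripts/acceptance.py` and the acceptance tests.

## Numerical and degenerate-input conventions

- Reads of exactly 40 nt fall in the "short" bucket of the length
  partition (strict `>40`), config-exposed.
- Class percentages are available on two bases — all mapped reads, or
  annotated reads only with renormalization — because both conventions
  are in common use; neither is hard-coded downstream.
- Ties in hit ordering are broken lexicographically after class rank;
  identical (ref, position) pairs reached on both strands (palindromic
  inserts) are reported once.
- Degenerate reads (too short at any trimming step) become discarded
  records with a reason, never exceptions; empty annotation sets yield
  empty count tables with intact sample columns.
- Gzipped outputs pin the gzip mtime/filename header fields so
  identical content is byte-identical across reruns; the pipeline
  manifest records seed and all parameters, and a rerun with the same
  config reproduces classification TSVs exactly.

## Problem sizes used in validation

The bundled reference is ~6 kb (13 tRNA genes over 7 decoders
including multi-copy, intron-containing and histidine cases; 6 rRNA
subunit records with 2 exact-substring repeats; 60 miRNA genes; 3
background segments). Full-scale validation runs 6 × 50,000 reads
(~25 s on one CPU); mapper-oracle equivalence is checked on 1,000
random inserts against exhaustive search; trimming inversion on
10,000 reads; classifier-rule equivalence on all 2,926 substrings of
a 76-nt mature tRNA. These sizes give exact or tight Monte-Carlo
checks while keeping the whole suite under a minute of compute.
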