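# Methods

This note records the statistical models behind `cernanet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## The ceRNA calling model

For a lncRNA *l* and an mRNA *g*, let *A* and *B* be the sets of miRNAs
predicted to target them inside a fixed universe of *N* miRNAs, and
*k* = |*A* ∩ *B*|.  Under the null that *A* and *B* are independent draws,
*k* is hypergeometric; `hypergeom_overlap_test` returns the upper tail
P(X ≥ k) (computed with `scipy.stats.hypergeom.sf`, and verified against
exhaustive enumeration in the tests).  A pair is *called* when

* hypergeometric *P* < 0.01 **and** Benjamini–Hochberg *q* < 0.01 (the BH
  batch is all tested pairs at once, not per-lncRNA), **and**
* the pair is positively co-expressed: Pearson *r* > 0 with two-sided
  *P* < 0.05 across all samples.

Decisions where the underlying procedure is commonly left unstated:

* **miRNA universe.** The network is built from differentially expressed
  features only, so the natural universe is the DE miRNA set entering the
  analysis (`universe="de"`); an explicit integer override is available.
  A larger universe makes a fixed overlap more surprising, so this choice
  is the conservative one.
* **Minimum shared miRNAs.** Pairs are tested from *k* ≥ 1 (most
  permissive reading); configurable.
* **Correlation layer.** Correlations (both here and for *trans* lncRNA
  targets) are computed on log2(FPKM + 1).  The log transform stabilizes
  variance across the dynamic range; without it a single high-expression
  sample dominates *r*.  Configurable via `log_transform`.
* With six samples, *r* > 0 at *P* < 0.05 requires *r* ≳ 0.81 — the
  correlation filter is genuinely strict at this design size.

Triplets are enumerated as (l, m, g) for every m ∈ *A* ∩ *B* of a called
pair, so the triplet count equals Σ k over called pairs.

## Differential expression

A two-group negative-binomial Wald test in the DESeq2 mould, kept fully
self-contained:

1. **Size factors** — median-of-ratios against the geometric-mean
   reference over features with all-positive counts.  Note the reference
   absorbs any common constant: rescaling one sample by *c* changes its
   factor by *c* only relative to the others, and a global depth change
   leaves factors untouched.  What is invariant is the relative
   normalization, hence the fold changes.
2. **Dispersion** — per-feature method of moments on normalized counts,
   α = max(10⁻⁸, (s² − m̄)/m̄²), with within-group variances pooled.  At
   three replicates per group this estimator has ~4 degrees of freedom and
   plugging it into a normal-reference Wald test inflates the type-I error
   to ≈ 0.11.  `de_test` therefore moderates each estimate toward an
   across-feature trend (mean raw dispersion within five mean-rank bins)
   with a prior weight of 20 pseudo-degrees of freedom.  The trend uses bin
   *means*, not medians: the method-of-moments sampling distribution is
   strongly right-skewed at small n, and a median trend systematically
   underestimates dispersion (measured residual inflation ≈ 0.07).  With
   the mean trend the null rejection rate at 0.05 is ≈ 0.048.
   `dispersion_prior_df=0` recovers the raw per-feature estimator, which is
   also exposed unchanged as `estimate_dispersion`.
3. **Wald test** — log2FC of normalized group means with pseudo-count 0.5
   (positive = higher in the first-named group), SE from the NB variance
   μ + αμ² by the delta method, two-sided normal *P*, BH *q* attached.
4. **Calling** — |log2FC| > 1 and raw *P* < 0.05.  Raw *P* is the
   published calling rule; calling on *q* instead is a flag.

No fold-change shrinkage and no independent filtering are attempted;
numerical agreement with DESeq2 is explicitly not a goal.

## Target prediction

Canonical seed taxonomy, strict Watson–Crick (no G:U), for a miRNA read
5'→3' with seed positions 2–8.  A site read 5'→3' in the target is
`[complement of m8] [reverse complement of positions 2–7] [A]`, and the
presence of the two flanks distinguishes 8mer / 7mer-m8 / 7mer-A1 / 6mer.
Overlapping candidate sites are resolved by type precedence then leftmost
start; this resolution rule is part of the documented contract and the
brute-force test oracle applies the same rule.  Free-energy scoring,
context scores and 3'-supplementary pairing are out of scope.  Interaction
recording defaults to sites of at least 7mer-A1.

*Cis* lncRNA targets: gene span to lncRNA span gap ≤ 100 kb (inclusive;
overlap = 0) on the same contig, spans rather than TSSs.  *Trans* targets:
significantly positive correlation as above.

## lncRNA identification

The coding-potential screen replaces the usual battery of external tools
with three in-repo scorers (longest ORF < 300 nt; ORF coverage < 0.5;
hexamer log2 likelihood ratio < 0, trained with add-one smoothing over all
4096 hexamers) and a ≥ 2/3 majority vote.  The ORF scanner requires a
complete AUG…stop frame on the annotated strand and counts the stop codon
in the length.  The FPKM ≥ 0.1 filter is applied to the per-transcript
*maximum* across samples — the permissive reading that keeps
group-specific transcripts.  Positional classes use the precedence exon
overlap (same strand → sense, opposite → antisense) > intron containment >
intergenic, which makes the four classes mutually exclusive and total.

When no labelled training sequences are supplied, the pipeline bootstraps
the hexamer model from the annotation itself (ORF ≥ 300 nt → coding
training set, ORF ≤ 100 nt → noncoding); frame length is a high-precision
though incomplete label, which is all a training set needs.

## qPCR analysis

ΔCt = Ct_target − Ct_reference per sample (per-sample pairing, preserving
replicate variance for the reported SE), ΔΔCt = mean ΔCt(test) − mean
ΔCt(control), fold change 2^−ΔΔCt.  Group comparison by one-way two-group
ANOVA, which equals the squared pooled t test; reference assays are a
configuration mapping, not hard-coded.

## The synthetic study generator

The generator emulates the statistical structure the pipeline assumes —
two breeds × three replicate libraries of mRNA/lncRNA/miRNA counts — with
complete ground truth.  Defaults (500 mRNAs, 200 lncRNAs, 60 miRNAs, 40
sponging triplets, 2×3 libraries) are a desk-scale rendition of the study
design; they run in under a second and are the conditions under which the
recovery properties in the test suite are stated.

* **Counts.** NB with mean μ and dispersion α (variance μ + αμ²), α shared
  within a class.  Default α = 0.02 (CV ≈ 14%): each library is a pool of
  three individuals, which suppresses biological variance relative to
  single-animal replicates.  Baseline means are log-uniform on [50, 5000].
* **Planted DE.** A fraction of each class (defaults 0.05 / 0.05 / 0.10
  for mRNA / lncRNA / miRNA, of the order of the published DE rates) gets
  a signed log2 fold change uniform on [1.5, 4]; group means are shifted
  by ±lfc/2 so the generating-mean ratio equals the truth exactly.
* **Sponging triplets.** Triplet rows are grouped into lncRNA–mRNA pairs
  sharing 8 planted miRNAs each (40 triplets → 5 pairs).  A single shared
  miRNA can never make an overlap significant at *P* < 0.01 in a
  60-miRNA universe (the tail is bounded below by 1/N), so multi-miRNA
  sharing is the only regime in which the hypergeometric filter is
  meaningful; eight shared miRNAs put planted pairs well clear of both the
  raw-P and the FDR thresholds while background overlaps stay null.
  Every shared miRNA receives one canonical site (default 8mer) planted
  with guard bases in the lncRNA and in the mRNA 3' UTR, at recorded
  positions the scanner provably recovers.
  A per-pair latent factor a_s ~ N(0,1) scales the natural-log mean by
  +β·a_s for the lncRNA and mRNA and −β·a_s for the shared miRNAs
  (β = 1 by default), producing the sponge's correlation signature.  The
  multiplicative effect is normalized to mean one within each group so
  that sponging redistributes expression across samples *without moving
  group means*: planted DE stays exact, and a finite-sample imbalance of
  the latent factor cannot masquerade as — or cancel — a group contrast,
  which at n = 6 it otherwise sometimes did.
  Pair members also carry coordinated DE (lncRNA and mRNA share a sign,
  their miRNAs the opposite sign), as in a network built from DE features
  only and as the sponge mechanism itself predicts.
* **Sequences.** mRNAs: uniform UTRs (5' 20–50 nt, 3' 100–200 nt) around
  a codon-biased ORF of 300–600 nt (one preferred codon per amino acid at
  6× weight).  lncRNAs: 200–400 nt uniform sequence, resampled until no
  frame reaches 300 nt.  This gives the hexamer scorer a learnable signal
  without external corpora.
* **Genome layout.** Genes are laid along synthetic contigs (8 × 5 Mb);
  half of the lncRNAs (configurable) are placed 1–80 kb downstream of a
  host gene, the rest on gene-desert contigs, fixing the within-100-kb
  fraction by construction.  Exon counts are 1–10 (lncRNAs ≥ 2), intron
  lengths 50–2000 nt.
* **Reads.** Each mature miRNA sequence is emitted count-many times with
  the standard Illumina small-RNA 3' adapter, plus a configurable
  contaminant fraction split evenly between too-short, too-long and
  high-N reads, all recorded in the truth.

**What the generator does not emulate:** alignment artifacts and multimapping,
sequencing errors beyond N-injection, isoform switching, batch effects,
within-pool mixing of the three individuals per library, GC or length
biases in quantification, and real genomic sequence composition.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the inference machinery under its own model assumptions, not performance
on real libraries.

## Numerical choices and degenerate inputs

* All coordinates are 0-based half-open internally; GTF conversion is
  exactly (start − 1, end) at the file boundary.
* T/U are equivalent everywhere sequences are compared.
* BH FDR: step-up with enforced monotonicity via a reverse cumulative
  minimum; ties handled by stable sort.
* Hypergeometric test arguments are validated (k ≤ min(|A|, |B|) ≤ N);
  k = 0 returns exactly 1.
* TPM/FPKM refuse zero mapped totals; FPKM refuses missing or non-positive
  lengths.  Counts layers must be integer-valued.
* Size factors refuse matrices with no all-positive feature rather than
  silently switching reference.
* `two_group_anova` raises on zero within-group variance with equal means
  (F undefined) and returns F = ∞, P = 0 when the means differ.
* The bundled key-gene table is SHA-256–verified at load.
* Determinism: every stochastic routine takes its stream from the config
  seed (`numpy.random.default_rng` with fixed spawn keys; sample names are
  hashed with CRC32, not Python's randomized `hash`), giving byte-identical
  outputs for identical configs.

## Problem sizes used in the checks

The recovery and calibration checks run at the generator defaults
(500/200/60 features, 40 triplets, 2×3 libraries), with 2000 features for
the null calibration of the DE test, 400 held-out transcripts for the
coding-potential vote, 500 random miRNA/transcript pairs for the seed-site
oracle, 1000 random vectors for the FDR oracle, and full enumeration up to
a 12-miRNA universe for the hypergeometric oracle.  These sizes were chosen
so the whole battery completes in seconds while leaving the binomial noise
of each rate estimate well inside its stated tolerance.

## Known limitations

* The full published network (hundreds of pairs from genome-scale input)
  requires the original sequencing data and external tool chains; it is
  out of scope by design, and the bundled key-gene table is the only
  real-data artifact.
* The NB Wald test targets calibration, not DESeq2 equivalence: no
  shrinkage, no outlier handling, two-group designs only.
* Exact-match miRNA counting tolerates no mismatches by default; real
  small-RNA data would need alignment upstream.
* The qPCR module assumes technical replicates have already been averaged
  into one Ct per sample and assay.
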