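# Methods

## The problem

RNA editing shows up in RNA-seq as reproducible mismatches between
aligned reads and the genome. In a two-condition design (control vs
elicitor-treated, N = 3 each) the questions are: which positions are
edited, what kind of substitution each one is and what it does to the
protein, which sites and genes change their editing activity between
conditions, and how those changes relate to expression changes. The
package implements that analysis end to end and validates it on
simulated studies with known truth, because the real measurements it
emulates are not redistributable.

## Synthetic studies (`synthio`)

The simulator is first-class code: its defaults define the study
conditions the rest of the package is tested under.

* **Genome and genes.** A uniform-random genome (default 0.6 Mb)
  carries 200 non-overlapping genes on both strands, separated by
  ≥ 2.1 kb so the 1 kb flank windows of neighbours never reach into a
  gene body. ~85% are coding: 1–3 exons, CDS of 100–300 codons that
  starts with ATG, ends with one stop, and contains no internal stop
  (codons drawn from the sense set). The rest are single-exon ncRNAs.
* **Planted editing.** 2000 sites are placed in gene bodies or their
  1 kb flanks (never intergenic). Substitution classes are drawn from
  a mix putting 0.20 on each of C→T, G→A, A→G, T→C (80% combined
  deaminase classes, the proportion reported for this system) and the
  remaining 0.20 spread over the other eight classes; a class draw is
  matched to a position whose reference base fits. Non-differential
  sites get one frequency per site from Beta(2, 2) truncated to
  [0.10, 1.00] — the caller's detection band — used in both
  conditions. 15% of sites are differential: they toggle between 0.20
  and 0.50 across conditions (direction random), the shift magnitude
  the power experiment is defined at.
* **Expression and reads.** Each gene's read count per sample is
  negative binomial (dispersion 0.05) around mean depth 30 scaled by a
  lognormal(0, 0.3) per-gene baseline; 10% of genes shift by
  |log₂FC| = 1.5 in the treated condition. Reads (single-end, 100 bp,
  all-match alignments) are placed uniformly over the gene body plus
  1 kb flanks — a pre-mRNA-with-readthrough abstraction that gives
  exonic, intronic and flank positions real coverage without
  splice-aware CIGARs. Each read crossing a planted site carries the
  alt allele with that sample's condition frequency. Sequencing errors
  (rate 0.001) substitute a random base and are written at quality 15,
  against quality 35 elsewhere, so the base-quality filter is
  exercised; the truth table records the quality-35 allele counts
  actually emitted, which the caller should reproduce exactly.
* **Determinism.** One seed drives three spawned generators (genome,
  planting, reads); identical seeds give byte-identical FASTA, GFF3,
  SAM and truth outputs.

What the simulator does **not** emulate: instrument error profiles,
indels, paired ends, splice-aware placement, multi-isoform genes,
strand-specific libraries, genomic SNPs, or mapping artefacts. Passing
tests therefore demonstrate the pipeline's statistical behaviour under
its own model assumptions, not robustness to alignment noise or
DNA-level variation in real data. Because gene bodies are compact
(~0.5–1 kb) relative to the 2 kb of flank around each, the simulated
region mix is flank-heavy rather than exon-heavy; all recovery and
mix properties are independent of that ratio.

## Site calling (`calling`)

Base calls below quality 25 and N bases are excluded before any
counting. Per sample and position, the alt allele is the most frequent
non-reference base (ties broken A<C<G<T); depth is defined as
ref + alt after quality filtering, so the frequency
f = alt/(ref + alt) is consistent with the counts the filters see. A
sample's observation passes at depth ≥ 5, alt ≥ 3 and f ∈ [0.10, 1.00]
(closed at both ends: fully edited sites are kept). A site keyed by
(chromosome, position, alt) is retained when ≥ 2 samples pass at
f ≥ 0.10; the stated band and level criteria are read as a per-sample
filter plus a cohort retention rule. For retained sites, counts are
re-queried for every sample, so unedited samples contribute their
actual depth with zero alt reads and a missing frequency when depth
is 0.

Conventions worth noting:

* **Reference-forward reporting.** The library is treated as
  unstranded; minus-strand C-to-U editing is recorded as G→A. The
  class map pairs the two arms of each biological class. One
  consequence: the complement pairing of A→G is T→C, and that is what
  the classifier uses, even though descriptions of this class
  sometimes write "T→A" — surfaced here rather than silently matched.
* **No genomic-DNA subtraction.** Every reference mismatch passing the
  filters is a candidate editing site. Without a DNA-seq control,
  genomic SNPs are indistinguishable from fixed editing; a documented
  caveat, not a removable one at this design.
* **Multi-allelic columns.** Only the top alt is called; if the
  second-best alt would also pass, the site is flagged `ambiguous`.

Counting is commutative, so results do not depend on read order, and
raising any threshold can only shrink the retained set. On small
genomes the caller is checked exactly against an independent
text-level recount.

## Annotation (`annotate`)

Region precedence: exonic > splicing > ncRNA exonic > ncRNA intronic >
UTR > intronic > upstream > downstream > intergenic; every site gets
exactly one label. Splicing is ±2 bp inside an intron; flanks are 1 kb
from the transcript start/end on the feature's strand (both windows
follow common annotator defaults). UTR is exon-minus-CDS on a coding
transcript and is kept distinct in tables even where figure-style
summaries would fold it into "other". Consequences locate the codon
via spliced CDS coordinates honouring strand and phase, substitute the
(strand-complemented) edited base, and translate with the standard
code; when several transcripts' CDS cover a site the longest CDS wins
and the others are recorded as secondary. All 576 single-base codon
substitutions are verified against direct translate-and-compare.

## Differential engine (`diffstats`)

One NB engine serves three matrices: site-level editing reads (alt
counts), gene-aggregated editing reads, and annotation-based
expression counts (a read is assigned to the gene whose exons it
overlaps most). Editing matrices are normalized with size factors from
the editing matrix itself, not expression library sizes: editing reads
are the unit of interest and their totals need not track library
depth.

* **Size factors**: median-of-ratios against the per-feature geometric
  mean over features positive in all samples, rescaled to geometric
  mean 1; total-count fallback (with a warning) when no such feature
  exists.
* **Dispersion**: pooled within-condition method-of-moments
  α̂ = (s² − μ̄)/μ̄² on normalized counts, then a trend
  α(μ) = a₀ + a₁/μ fitted by least squares to the **unclipped**
  estimates (including negative ones — clipping first would bias the
  trend upward for low-dispersion data and cost power). The default
  takes the per-feature value fully from the trend
  (`trend_weight = 1.0`): with 2 × 3 replicates the per-feature moment
  estimate has ~4 df and its noise is correlated with the Wald
  statistic, which inflates the type-I error; full trend shrinkage is
  what makes the null calibration below hold. The weight is
  configurable for designs with real replication.
* **Wald test**: per-feature NB GLM (log link, intercept + condition)
  fitted with statsmodels at the fixed α, on size-factor-normalized
  counts. Fitting the normalized scale rather than raw counts with
  offsets is deliberate: at size factors near 1 the two are
  numerically indistinguishable, and the normalized fit makes log₂
  fold changes exactly invariant to rescaling a sample's column — a
  normalization identity the package guarantees. The statistic is
  coefficient/SE with a two-sided normal p; all-zero features get NA
  and are excluded from correction. A moment fallback (pseudocount
  0.5, delta-method SE) covers non-converged fits.
* **Multiplicity**: in-repo BH step-up with monotonicity enforcement;
  NAs propagate and do not count toward m.
* **Calls**: editing uses adjusted p < 0.05 only; expression adds
  |log₂FC| > 1.2, read literally on the log₂ scale. The engine makes
  no claim of numerical equivalence with DESeq2-style tools and omits
  LFC shrinkage, Cox–Reid adjustment and independent filtering; the
  contract is behavioural and is measured directly (below).
* **TPM**: counts/merged-exon-length, scaled so each column sums to
  10⁶.

### Measured guarantees (`experiments`)

* *Null calibration*: 2000 NB features, 3v3, means lognormal(log 30,
  0.6), α = 0.05, no effect — p-values pass a KS uniformity test and
  the p < 0.05 fraction sits at 4.4–5.8% across seeds.
* *FDR control*: 20 seeds × 1000 features with 10% alternates at
  |log₂FC| = 1.5 — pooled false discovery proportion ≈ 0.05 at the
  0.05 BH level.
* *Power*: 2000 sites at per-sample depth exactly 30 (alt reads
  binomial), 15% shifted 0.2 ↔ 0.5, 3v3 — ≥ 70% of shifted sites at
  adjusted p < 0.05. The depth is the stated condition of the
  experiment; within the full read-level demo, where coverage also
  carries NB dispersion and per-gene expression variation, per-site
  power is necessarily lower (~0.5) while calling recovery stays
  ≥ 95%.

## Integration (`integrate`)

The Venn of the three differential analyses is computed on host-gene
ids (significant-site hosts vs significant editing genes vs DE genes),
the only id space the three sets share. Quadrant classification is a
pure function of the two (log₂FC, call) pairs; genes missing from one
table take the non-significant state on that axis. PCA centres each
site across samples, imputes missing frequencies with the site mean
(the simplest policy that keeps all samples), and projects samples by
SVD; variance percentages are non-increasing and a near-zero total
variance (constant matrix) reports as all-zero rather than amplifying
centering residue. Gene-level MAF is the unweighted mean over a gene's
sites (a depth-weighted variant is a flag); the enzyme–target
correlation is Pearson with a t-reference p on n − 2 df, refusing
n < 3 or constant vectors. The cohort report counts loci per sample
from the per-sample pass flags and reports group totals as the *sum*
of per-sample counts — the convention of the published summary tables
this report mirrors — plus up/down/total significant sites and host
genes, including genes carrying shifts in both directions.

## Numerical and degenerate-input choices

* Base order A<C<G<T breaks every allele tie deterministically.
* Frequencies at depth 0 are missing, never 0, and are excluded from
  means; an all-missing group yields a missing mean.
* Constant vectors: correlation raises; PCA reports zero variance
  (both use exact peak-to-peak/threshold guards against ~1e-17
  centering residue).
* BH rejects p outside [0, 1]; empty inputs yield empty outputs
  throughout (0 genes, 0 sites, empty matrices).
* Packing failures in the simulator (genome too small, site count
  exceeding plantable positions) raise sizing errors naming the
  constraint.

## Problem sizes

The default demo — 0.6 Mb genome, 200 genes, 2000 planted sites, six
samples at ~30× — runs the full simulate-through-integrate path in
about 1–2 minutes on one CPU; the engine benchmarks add under a
minute. These sizes give every recovery and calibration measurement a
few thousand observations, which is where the acceptance bands
(binomial error on a proportion of ~2000) are meaningful.

## Known limitations

* No DNA control: fixed SNPs masquerade as 100%-frequency editing.
* Unstranded reference-forward reporting cannot separate the two arms
  of a deaminase class.
* Single-isoform consequence annotation; multi-isoform ambiguity is
  flagged, not resolved.
* The NB engine's normal-reference Wald p is approximate at n = 3 + 3;
  its calibration is demonstrated under the simulator's conditions,
  not proven generally.
* Expression changes move editing-read counts even at constant editing
  frequency, so site-level differential editing partially reflects
  expression; the gene-level editing analysis inherits the same
  coupling. This is a property of count-based differential editing
  itself, shared with the tools it emulates.
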