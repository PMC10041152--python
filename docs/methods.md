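# Methods

## Experimental design the pipeline assumes

A pooled transposon mutant library of one focal bacterial species is
inoculated into phytoplankton co-cultures under several community
compositions (here: the focal species alone, `Rp`; with one of two other
bacteria, `Rp+V`, `Rp+M`; or with both, `Rp+V+M`), with n replicate flasks
per treatment (default 4). The pool is sequenced at the start (several
inoculum aliquots, the t1 observations) and at the end of the growth period
(one sample per flask, t2). Sequencing reads cover transposon–genome
junctions, so each mapped position is one mutant strain and its read count
tracks that mutant's abundance.

## Pipeline stages and the choices behind them

**Junction trimming.** A read is informative when the transposon end motif
(`AGATGTGTATAAGAGACAG`) starts within the first 60 bp; the 22 bases
following it are the genomic fragment used for mapping. Both window and
fragment length are parameters (`search_window`, `keep_length`); matching is
exact, and the first motif occurrence is used, since the junction is the
transposon/genome boundary nearest the read start. Mapping itself is outside
the package — the pipeline consumes per-site count tracks (text wiggle,
`variableStep` or `fixedStep`).

**Count matrix.** Per-sample tracks are merged over the union of
(replicon, position) keys with zero fill; sites with no reads in any sample
are dropped. Duplicate positions within one track are an error rather than
being summed, because they indicate a malformed track.

**Curation.** Insertions near the ends of a coding region often leave
function intact, so only sites within the central fraction (default 0.9) of
a gene count as knockouts. The window trims `ceil(L·(1−f)/2)` positions from
each end — the ceiling guarantees at most `f·L` qualifying positions; for
very short genes the window may be empty. Window membership is inclusive at
both bounds. A site inside two overlapping genes' windows is credited to
both (fitness is per-gene and independent) and flagged; distinct curated
sites are counted once in library totals. Strand is ignored — insertion
disrupts either strand. Sites outside every window, including those on
unannotated replicons, stay in the pool for read totals but join no gene.

**Normalization and filtering.** Each sample is scaled so its read total
equals the grand mean of all sample totals, inoculum aliquots included.
Scaled counts stay fractional; frequencies are ratios and re-rounding would
only add error. Site counts are then summed within genes. Genes averaging
fewer than 10 reads across the two timepoints are removed; the criterion is
the mean of the two timepoint means, which is symmetric and robust to
unequal replicate counts, applied separately per treatment (a gene may be
analyzable in one treatment pair and not another).

**Growth accounting.** The expansion factor d is the fold change of the
focal species' pool over the growth period: flow-cytometry totals give
community size, CFU proportions apportion it among species, and
d = [total(t2)·prop(t2)] / [total(t1)·prop(t1)], with generations = log2 d.
d is computed per replicate and used in that replicate's fitness; a
treatment-mean d is a one-line change if replicate-level cell counts are
unavailable.

**Relative fitness.** For each gene, treatment and replicate,

    W = ln(N2·d/N1 + 1) / ln((1−N2)·d/(1−N1) + 1)

with N1 the mean frequency over the inoculum aliquots (aliquots are not
paired to flasks; per-aliquot pairing would only add noise) and N2 the
frequency in the flask's t2 sample. Frequencies are taken over the curated,
filtered gene set of that treatment, so the frequency denominator always
matches the analyzed gene universe. The "+1" terms regularize the common
zero cases: an extinct mutant (N2 = 0) gets W = 0 exactly. Genuinely
undefined cases — N1 = 0 with N2 > 0, or N2 = 1 — propagate as missing
rather than being clamped, since clamping would bias downstream contrasts.
Replicate-mean W is reported with the count of contributing replicates.

Two anchors pin the statistic's reading: a mutant growing with the pool
(N2 = N1) has W = 1 for every d, and a mutant growing at half the pool's
exponential rate (abundance × d^½ while the pool grows by d) approaches
W = 0.5 as d → ∞ (0.50 at d = 2³⁰ from N1 = 10⁻⁸).

**Contrasts and significance.** Fitness differences between a multispecies
treatment and the single-bacterium treatment are
log2((W_multi + Ψ)/(W_single + Ψ)) with Ψ = 0.01, which keeps the ratio
finite when either fitness is 0. Significance uses a two-sided
randomization test on the replicate-level W values: the statistic is the
absolute log2 fold-change of group means, and the null reassigns the pooled
replicate values to two groups of the original sizes. All C(n1+n2, n1)
reassignments are enumerated exactly whenever that count is at most the
permutation budget (70 for 4-vs-4, far below the 10,000 default); the exact
p is the fraction of reassignments at or above the observed statistic
(identity included, so p is never 0). When sampling is needed,
p = (1 + hits)/(n_perm + 1).

*Null model.* A single gene's 4-vs-4 permutation distribution has only 35
distinct absolute statistics, so its smallest attainable p is 2/70 ≈ 0.029.
That granularity makes genome-wide FDR control impossible: with m genes the
Benjamini–Hochberg threshold for a handful of discoveries lies orders of
magnitude below 0.029, so no gene could ever be called. The pipeline
therefore pools each gene's exactly-enumerated permutation statistics across
genes within a contrast and ranks every observed statistic against this
common null, in the spirit of the pooled permutation nulls long used for
microarray/sequencing statistics. Pooling assumes neutral genes share a
statistic distribution; replicate scatter here is dominated by sequencing
sampling noise, which makes that assumption reasonable, and on all-neutral
synthetic data the resulting raw p-values are uniform to within Monte-Carlo
error (observed false-positive rate 0.049 at nominal 0.05). The strict
per-gene test remains available (`null="per_gene"`). BH adjustment is
performed within each contrast across genes, and adjusted p < 0.05 (strict)
flags significance.

*Reproducibility.* One experiment-level seed is used; per-gene RNG
substreams are derived from the seed and a hash of the gene identifier, so
results do not depend on gene order or parallelism. Ties against the
observed statistic are counted with a 10⁻¹² tolerance so that the mirror
reassignment (which equals the observed statistic analytically) is never
lost to floating-point rounding.

**Mode classification.** Assigning significant genes to ecological
interaction modes (competition, crossfeeding, chemically mediated, altered
environment, plus central-metabolism / regulation / mixed / hypothetical
bookkeeping categories) is expert curation, not inference; the package ships
the curated mapping for the motivating experiment's reported genes as a
versioned fixture (`src/phycofit/data/table*.tsv`, 81 genes) and accepts any
user mapping of the same shape. Genes outside the mapping default to
`hypothetical`. Report tables show per-contrast log2 fold-changes rounded to
two significant figures where significant and blank cells elsewhere;
machine-readable output keeps full precision.

## The synthetic-data generator

`simulate_library` tiles genes (default 900 bp, 100 bp gaps) along a
synthetic replicon and scatters insertion sites: Poisson counts per gene
(mean 15) with uniform positions, plus 15% of sites in intergenic gaps so
that the curated fraction of unique mutants (~0.85 × 0.9 ≈ 0.77) matches
what deep mutant libraries of this kind typically retain after central-90%
curation. Because curation then removes the outer-10% in-gene sites, the
post-curation mean is ~13.6 sites per gene.

`simulate_experiment` gives every mutant a lognormal initial-abundance
jitter (σ = 0.5), grows it deterministically — abundance multiplies by
d^m where d is the treatment's pool expansion (defaults 2^6.4 alone,
2^4.4 with both competitors, 2^5.4 interpolated for the two-species
treatments) and m the gene's growth-rate multiplier (1 = neutral) — and
sequences every sample multinomially at the configured depth (default
2 × 10⁶ reads; Dirichlet-multinomial overdispersion available, default
off). Effects are parameterized as rate multipliers rather than target W
because W depends on d and the pool composition; the ground-truth W is
computed from the closed-form frequencies and the realized pool expansion,
and cell-abundance records are generated consistent with that expansion, so
growth accounting recovers d exactly.

What the generator does *not* emulate: demographic (birth–death)
stochasticity, flask-to-flask biological variability beyond sampling noise,
PCR/jackpot artifacts, position-dependent insertion bias, and polar effects
of insertions. Consequently replicate scatter is purely multinomial, which
is the most favorable regime for the randomization test; passing recovery
tests demonstrates the statistical machinery is correct and calibrated
under the stated model, not that real libraries are free of overdispersion
(the `dispersion` knob exists to probe that robustness).

One genuine property of pool-relative fitness shows up clearly at small
scale: strong effect genes change the pool mean, so every neutral mutant's
W shifts slightly in that treatment. With few genes (each holding ~1/n of
the pool) the shift is real signal and the test correctly detects it; at
the benchmark scale of 500 genes with 5% mild effects the shift is
negligible, mirroring a genome-scale library where each gene holds a tiny
pool share.

## Problem sizes and runtimes

The benchmark analyses and recovery tests use 500 genes, 4 + 4 replicates
and 2 × 10⁶ reads per sample (one experiment simulates and analyzes in a
few seconds); the FDR study repeats that design over 10 seeds. These sizes
give per-gene read depths (~4,000 reads/gene) comparable to a deeply
sequenced genome-scale library, so noise levels per gene are realistic even
though the gene count is scaled down.

## Known limitations

- The wig reader accepts the two UCSC step dialects but not bedGraph.
- The pooled null assumes cross-gene exchangeability of the permutation
  statistic; strong variance heterogeneity across genes (e.g., extreme
  overdispersion confined to a few genes) would miscalibrate tails. The
  per-gene exact test is the fallback, at the cost of a p-value floor.
- Essentiality calling is out of scope; genes absent from the library are
  simply reported as uncovered.
- Mode classification reproduces whatever curation it is given; it does not
  infer function.
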