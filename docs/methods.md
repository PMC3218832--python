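# Methods

`emsaseq` implements the computational half of a selection-sequencing
(EMSA-Seq / single-round SELEX) workflow for profiling transcription-factor
binding preferences, together with the downstream machinery for interpreting
allele-specific ChIP-Seq binding differences. This note records the models,
the tunable parameters, the numerical conventions, and what the synthetic
world does and does not establish.

## 1. k-mer enrichment model

Reads from a protein-selected pool and an unselected control pool are reduced
to their degenerate regions, and every length-k window is counted in
*canonical* (strand-collapsed) form: a k-mer and its reverse complement are
the same double-stranded binding substrate, so each window contributes to
`min(kmer, revcomp(kmer))`. The canonical 11-mer universe therefore has
4^11 / 2 = 2,097,152 members (for even k the 4^(k/2) reverse-complement
palindromes are their own partner, giving (4^k + 4^(k/2)) / 2).

For each k-mer, the count in a pool is modeled as Binomial(n, p) with n the
pool's total number of k-mer observations. The null hypothesis shares one
probability between pools, p0 = (x_sel + x_ctrl) / (n_sel + n_ctrl); the
alternative gives each pool its own MLE proportion. The statistic
2(l1 − l0) is referred to chi-square(1); because only enrichment (not
depletion) is of interest, the p-value is halved when the selected proportion
exceeds the control proportion and set to 1 otherwise. Benjamini–Hochberg
step-up correction is applied at FDR 0.01 over the union of k-mers observed
in either pool — untested members of the universe are not hypotheses. A
pooled two-proportion z-score,

    z = (p_sel − p_ctrl) / sqrt(p0 (1 − p0) (1/n_sel + 1/n_ctrl)),

accompanies every test. The published method names an enrichment z-score
without defining its exact form; the pooled statistic is chosen because it is
the normal-approximation twin of the LRT, and the two rank k-mers essentially
identically (measured Spearman 0.9997 across a grid of count configurations —
not exactly 1, because the pooled baseline p0 varies between configurations).
Degenerate pooled proportions (0 or 1) define z = 0. Zero counts enter the
LRT raw (it is well defined at 0); a reporting-only pseudocount of 0.5 is
used for fold-change columns.

Known limitation, shared with the assay's standard analysis: overlapping
k-mers from one read are correlated observations, and this dependence is
ignored; the FDR is interpreted per-k-mer.

Cross-pool normalization ("scale every table to the smallest pool's total")
is used for reporting and ranking only; the test always consumes raw integer
counts, which the binomial model requires.

## 2. Binding models and MATCH similarity

A binding model is a width × 4 base-frequency matrix, built either from a
reference PWM (TRANSFAC- and JASPAR-format readers are provided) or from the
top-N enriched k-mers weighted by their z-scores (an affinity-weighted count
matrix; default pseudocount 1e-3 per cell before renormalization so that
logarithmic weights stay finite).

Similarity of a fixed-width sequence to a model follows the matrix-similarity
part of the MATCH scheme: position weight
I(i) = Σ_b f(i,b)·ln(4·f(i,b)) (zero for an uninformative column, ln 4 in the
one-hot limit), Current = Σ_i I(i)·f(i, s_i), and

    MSS = (Current − Min) / (Max − Min)

with Min/Max assembled from per-column extreme frequencies. The per-column
argmax sequence scores exactly 1, the argmin sequence 0. Because fixed-width
k-mers are scored rather than genome scans, no core-similarity pre-filter is
used. By default the better of the forward and reverse-complement scores is
reported (double-stranded substrate); a fully uniform matrix is defined to
score 0. The consensus of a model with tied column maxima is degenerate —
several sequences share score 1.

Binder sets:

* **canonical binders** — k-mers with MATCH score > 0.75 against the
  reference model;
* **extended binders** — enriched k-mers retained by a per-bin filter:
  within each MATCH-score bin (five bins, [0,0.2], (0.2,0.4], (0.4,0.6],
  (0.6,0.8], (0.8,1.0]; half-open on the left, lowest bin closed), keep
  k-mers whose z is at least 90% of the bin's median z. The 10% slack is
  applied to z, not rank (the published wording is ambiguous; z is the
  quantity the filter's median is taken over, so the slack is read the same
  way).

The licensed TRANSFAC NF-κB matrix cannot be redistributed, so the packaged
reference model is a documented synthetic stand-in built from the generalized
11-mer consensus RGGRNNHHYYB (each IUPAC code spread uniformly over its
allowed bases). A 10-bp consensus form of the motif exists, but 11-mer
scoring requires width 11, so the expanded 11-base consensus is used. All
threshold-dependent binder counts are reproducible only relative to this
stand-in.

## 3. Microarray profiles

Probe intensities are log2-transformed and z-standardized within each array
(mean/SD; the robust median/MAD alternative is defensible but mean/SD is the
conventional reading), the per-probe median across replicate arrays is taken,
and a dimer's profile is the element-wise median across the four
flank-specific probe sets. A zero-variance array yields all-zero z rather
than an error. Dimer profiles are compared by Pearson correlation (constant
profiles reported as missing) and clustered by complete linkage on Euclidean
distance.

## 4. Binding potential over summit windows

Each ChIP-Seq binding region (BR) contributes one fixed window, the BRS:
300 bp centered on the summit, `[summit − 150, summit + 150)` in 0-based
half-open coordinates (the parity convention is unstated upstream; the
summit sits at offset 150). BRS coordinates are BR-specific and identical
across individuals.

An individual's personalized window applies their SNP genotypes to the
reference sequence (SNPs only; indels are out of scope). Heterozygous
genotypes expand to two haplotypes; unphased multi-het windows use the two
reference-vs-alternate expansions rather than all allele combinations — the
ChIP signal aggregates both alleles, and without phase information the
all-ref/all-alt pair is the canonical two-haplotype representation.

The binding potential B of a haplotype is the sum of enrichment z-scores of
every enriched k-mer found at any of the 290 window offsets (canonical
lookup, so B is invariant to reverse-complementing the window). A
heterozygous individual's B is the mean of the two haplotype sums. Two
methods combine dimer datasets: `summed_dimers` pools all dimers' enriched
k-mer z-scores into one table; `per_dimer_fallback` scores one dimer at a
time in a configurable order (default RELAp50, RELAp52, RELARELA —
heterodimers first) and stops at the first direct positive correlation.

A pair of individuals at one BRS is classified by sign agreement:
`no_difference` when B_a = B_b exactly (both potentials are computed from the
same finite sums, so exact equality is meaningful), `direct_positive` when
sign(B_a − B_b) = sign(Δ peak height) ≠ 0, `no_correlation` otherwise. Peak
heights and their differences are upstream inputs; only direction is
classified.

Trait-associated SNPs map to the nearest summit by absolute distance (ties to
the lower coordinate); over-representation of a category among TASs within
1 kb is an upper-tail hypergeometric test.

## 5. The synthetic world

The generator produces every input format with known ground truth, all
randomness flowing from one seed (identical seeds reproduce every file
byte-identically).

* **True model**: an NF-κB-like width-11 frequency matrix built from the
  sharpened consensus GGGGRNNTTCC (IUPAC-uniform columns, pseudocount 0.02).
* **Control pool**: i.i.d. uniform degenerate 20-mers between constant 4-bp
  flanks, written as Sanger FASTQ.
* **Selection**: one round; control molecules are resampled with Boltzmann
  weight exp(β · best-window MATCH score), the simplest monotone link between
  model score and binding probability. β = 10 makes a consensus-containing
  molecule ~60-fold more likely to be drawn than a typical background
  molecule, emulating the strong single-round enrichment the assay is
  designed for.
* **Planted affinity ladder**: the consensus plus sampled mutants at 1–4
  substitutions (~200 canonical k-mers) with true relative weight
  exp(β·(score − 1)); recovery is always asserted against this ladder, never
  against real-data percentages.
* **Depth**: 2 × 10^6 reads per pool by default. This is deliberate: with
  10 windows per 20-mer read, the control pool carries ~9.5 expected
  observations of every canonical 11-mer (>99.99% coverage), matching the
  near-complete coverage of real control pools. An order of magnitude
  shallower, a large fraction of any planted k-mer set is simply absent from
  the control — and a selected pool resampled from the control can then never
  observe it — so rank-recovery claims would measure a presence lottery, not
  the caller.
* **Cohort**: one synthetic chromosome; 40 BRSs spaced 2 kb apart (default),
  each window carrying 1–3 planted high-affinity k-mers on random strands;
  ~2 SNPs per window, placed preferentially inside planted binders, with
  Hardy–Weinberg genotypes at allele frequency 0.5 across 4 individuals;
  peak height = 10 + B_true + σ·N(0,1), where B_true uses the planted
  affinity map (consensus scaled to 100). At σ = 0 every resolvable pair is
  direct-positive by construction; at σ → ∞ the direct-positive fraction
  among resolvable pairs tends to 1/2.

Not modeled (and therefore not established by green tests): PCR bias,
sequencing error profiles, position effects within reads, chromatin
accessibility or nucleosome occupancy, linkage disequilibrium structure, and
cooperative or dimer-specific binding beyond the single planted model.

## 6. Numerical and I/O conventions

* Counting uses a dense vectorized path (base-4 integer encoding plus
  bincount) for equal-length pools with k ≤ 13, and a dictionary path for
  ragged input; both produce identical tables, and tests pin them to a naive
  double-loop oracle.
* Quality filtering of reads defaults to mean Phred ≥ 20 over the degenerate
  region; the original read-QC protocol is not public, so this is a
  documented, configurable stand-in. Reads with N in the degenerate region
  are always rejected (the model assumes a 4-letter alphabet). Flank
  matching is anchored at fixed offsets by default (fixed-layout library
  reads), with an optional sliding search for ragged reads.
* Tables are TSV with provenance headers (tool version, parameter hash,
  seed); coordinates are 0-based half-open internally, converted at the BED
  and VCF boundaries; enrichment records sort by descending z with a stable
  tie-break.
* The canonical 10-mer universe is (4^10 + 4^5)/2 = 524,800; published
  analyses cite a slightly smaller 10-mer universe (522,857) produced by an
  unstated additional filter, which is deliberately not guessed at or
  reproduced.
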