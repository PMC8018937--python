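# Methods

## Junction counting from spliced alignments

A spliced alignment represents each intron as a skip (`N`) operation. For
every skip in a primary mapped record, the junction is identified by its
flanking exonic bases — the last aligned reference base before the skip and
the first after it (1-based, ascending genomic order regardless of strand) —
and incremented by one, provided both flanking aligned blocks span at least
`min_anchor` reference bases. A single record with two skips increments two
junctions. Unmapped, secondary and supplementary records are ignored;
duplicates are not collapsed. `library_size` is the number of primary
mapped records processed, used as the per-million denominator for
depth-normalized junction counts. The cassette usage statistic is a ratio
of counts from the same library, so it is identical whether computed on raw
or depth-normalized counts; normalization matters only for cross-sample
comparison of individual junctions.

`min_anchor` defaults to 1 (any overhang counts). Common junction counters
behave this way by default, and the simulator's truth ledger applies the
identical anchor rule, so extractor and ledger are comparable at any
setting. The anchor of a block is its full aligned span between skips;
deletions inside a block extend the reference span but create no junction.

Junction tables can also be imported directly: a plain
`chrom/donor/acceptor/strand/count` TSV (with an optional
`# library_size: N` sidecar line), STAR `SJ.out.tab` (intron first/last
coordinates, shifted −1/+1 to exonic flanks on read), or a
featureCounts-style `.jcounts` layout. An `intron_coords` option applies
the same ±1 shift to the other dialects, because published junction
coordinates do not always state which convention they use; the shipped
MAPT fixtures follow the exonic-flank reading, under which the printed
human positions coincide with annotated exon edges.

## The cassette usage statistic

For an event with inclusion junctions J₁…J_k and exclusion junction J_x:

    usage% = 100 · (1/k) Σᵢ X(Jᵢ) / X(J_x)

reducing to 100·½(X₉,₁₀+X₁₀,₁₁)/X₉,₁₁ for a single cassette exon (k = 2).
When X(J_x) = 0 — a pure-inclusion sample, e.g. an adult-rodent cortex
pattern expressing only 4R — the ratio is undefined and flagged rather than
raised, since that outcome is biologically meaningful. Junctions named by
the event but absent from the table count as zero with a warning, because
pure-isoform samples legitimately never produce the other isoform's
junctions. The inferred inclusion fraction is f̂ = u/(100+u), the exact
algebraic inverse of u = 100f/(1−f); hence u/100 = f̂/(1−f̂) identically.
Group summaries report mean, sample standard deviation (n−1) and n over
defined results, with undefined results excluded and counted.

## Why usage estimates 100·f/(1−f): the sampling model

The simulator (and the estimator's justification) assumes uniform fragment
sampling: a read's isoform is drawn with probability proportional to
(molar proportion) × (transcript length − read length + 1), i.e. uniformly
over all admissible read placements in the pooled transcript population,
and its start uniformly within the transcript. Every junction then has the
same expected number of spanning reads per unit of isoform abundance
(read_length − 2·min_anchor + 1 admissible starts, provided flanking exons
are at least read_length − min_anchor long), so the inclusion-mean over
exclusion ratio is an unbiased transform of the molar inclusion fraction f.
Drawing isoforms by molar proportion *without* the length weighting would
couple junction-crossing probability to transcript length (the inclusion
transcript is 93 bp longer) and bias the ratio downward by
(T_excl − L + 1)/(T_incl − L + 1) ≈ 15 % on the toy gene; the
length-weighted model is both the standard RNA-seq generative model and the
one under which the halved-sum formula means what it is used to mean.

## Synthetic data

The toy gene (`toy_maptlike`) has constitutive 300 bp exons E9 and E11
flanking a 93 bp cassette E10 — the length of the MAPT exon-10 repeat
cassette — with ≥ 200 bp introns on a synthetic chromosome. Defaults:
75 bp reads (shorter than the cassette, so the two inclusion junctions are
spanned by disjoint read populations), min_anchor 1, 10⁵ reads per
library, inclusion fraction f = 0.148 — the mixture whose closed-form
usage 100·0.148/0.852 = 17.37 % sits at the porcine induced-neuron scale
the package targets. Depth is either fixed at `n_reads` or Poisson with
that mean. The read simulator emits a random reference FASTA, SAM records
with exact match/skip alignment strings, and a truth ledger counting every
junction each read spans under the anchor rule; `simulate_junction_table`
is the fast path that skips read generation and draws junction counts
binomially with the exact crossing probabilities implied by read length,
anchors and exon lengths (junctions of one isoform are drawn independently,
which matches the read-level process in all marginal means and variances
but ignores their weak positive coupling through shared reads — irrelevant
to the ratio statistics tested). All generators are deterministic given
their integer seed.

Deliberately absent from the generative model: sequencing errors, indels,
positional/GC bias, fragment-length distributions, paired ends,
multimapping and alignment ambiguity. Passing tests therefore demonstrate
the correctness of the counting and ratio arithmetic under clean uniform
coverage, not robustness to alignment artefacts in real libraries.

## TPM and exon-bin usage

TPM divides each gene's count by its effective length — the union-exonic
length from the gene model, matching gene-level counting conventions —
then rescales rates to sum to 10⁶ per sample, so Σ TPM = 10⁶ holds to
floating-point precision whenever any count is nonzero (an all-zero sample
reports zeros with a warning). Expression displays use log₂(TPM+1).

Exon-bin counting flattens all isoform exon structures into disjoint bins:
every isoform-exon boundary induces a bin boundary, so each bin is a
maximal exonic run with a constant contributing-isoform set (verified
against a per-base labeling oracle). A record increments every bin that any
of its aligned blocks overlaps by ≥ 1 base, once per bin — a read spanning
a skipped cassette hits the flanking bins but not the cassette bin. A
record counts toward a gene iff it hits ≥ 1 of that gene's bins. Relative
usage divides each bin count by the summed bin counts of its gene, a
within-gene composition (summing to exactly 1) that is invariant to the
gene's expression level. Two-sample comparison adds a 0.5 pseudocount to
raw bin counts before forming usages so log₂ usage ratios stay finite on
zero bins, and flags genes with zero total counts in either sample;
differential testing (dispersion modelling, GLMs) is intentionally out of
scope.

## qPCR standard-curve quantification

Per target, Cq is regressed on log₁₀(relative template amount) over a
serial dilution series (≥ 3 distinct dilutions) of pooled cDNA; amplification
efficiency is 10^(−1/slope) − 1, exactly 1.0 at the perfect-doubling slope
−1/log₁₀2 = −3.321928. Technical replicates are collapsed to mean Cq
before interpolation (the replicate s.d. is carried through to reports),
and a sample's relative quantity is 10^((Cq − intercept)/slope) — one
|slope| of extra cycles means tenfold less template. Quantities are
normalized to the geometric mean of the reference targets (GAPDH and
HPRT1 by default) within each sample, making them invariant to per-sample
global scaling, and isoform ratios are reported as
100 · normalized(4R)/normalized(3R). Curves with non-negative slope are
flagged invalid (warned) and refuse interpolation. No-RT and water
controls are checked against a Cq threshold (default 38) and reported, not
used numerically. No ΔΔCq shortcut, inter-plate calibration or
fluorescence-curve processing. Published qPCR ratios cannot be recomputed
without the underlying Cq values, so validation is by round trip: Cq
tables forward-simulated from known quantities are inverted exactly when
noise-free and within Monte-Carlo tolerance under Gaussian Cq noise.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere in the API; junction keys
  compare on (chrom, donor, acceptor) only, so strand annotation never
  affects matching and descending-printed minus-strand spans normalize to
  the same key.
- Reverse-strand genes (porcine MAPT) store exons in ascending genomic
  order with an explicit strand field; exon numbering follows the tau
  literature (exon 10 = second microtubule-binding repeat) and is carried
  as explicit labels in model files so numbering conventions never affect
  computation.
- The MAPT fixtures' flanking-exon outer edges are nominal 200 bp synthetic
  extents (marked as such in the files); only the junction-facing
  boundaries are annotation-derived, and only those enter any computation.
- TSV reports use 6-decimal fixed formatting for reproducible diffs; the
  CLI echoes every defaulted setting to the log and exits nonzero when no
  sample yields a defined ratio.
- Simulation sizes used by the test-suite and acceptance script (200
  libraries of 10⁵ reads for recovery; 50 random configurations of ≤ 5000
  reads for ledger equivalence; 50 random models for the bin oracles) keep
  Monte-Carlo error well inside the asserted tolerances while running in
  seconds.

## Known limitations

- Only junctions named in a gene model are interpreted; novel junction
  discovery is out of scope (raw tables do retain all observed junctions).
- The estimator's unbiasedness argument assumes uniform coverage; 3′ bias
  or short flanking exons (< read_length − min_anchor) break the equal-
  crossing-probability premise and would require an effective-length
  correction per junction.
- Gene models are per-gene documents, not genome-wide annotations.
- No hypothesis testing between groups anywhere in the package.
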