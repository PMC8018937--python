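# splicequant

Quantification of cassette-exon splice isoforms from junction-spanning
reads, built around the MAPT 3R/4R tau ratio used to characterise directly
reprogrammed (induced) neurons, plus the surrounding normalization and
validation arithmetic: TPM expression profiling, flattened exon-bin usage
counting, and qPCR standard-curve relative quantification. A seeded
spliced-read simulator with known ground truth makes every step testable
without any sequencing data.

**Who it is for.** Anyone asking "which splice form of this cassette exon
does my sample express, and in what proportion?" from bulk RNA-seq
alignments or precomputed junction tables — the motivating case being
whether induced neurons express the adult pattern of MAPT (tau) isoforms,
where inclusion of exon 10 (the second microtubule-binding repeat) yields
4R tau and skipping yields 3R tau.

## The statistic

A read whose alignment skips an intron evidences one exon–exon junction;
X<sub>i,j</sub> is the count of reads spanning the junction between exons
*i* and *j*. For a cassette exon 10 between constitutive exons 9 and 11:

```
usage% = 100 · ½ (X₉,₁₀ + X₁₀,₁₁) / X₉,₁₁        (4R/3R ratio, in %)
f̂      = usage / (100 + usage)                    (inclusion fraction)
```

Under uniform fragment sampling every junction of an isoform is crossed
with the same probability, so usage% estimates 100·f/(1−f) where f is the
molar fraction of the inclusion (4R) isoform. The statistic is invariant to
sequencing depth and to any global rescaling of counts.

Shipped gene models carry the porcine (ENSSSCG00000017311, chr12, − strand)
and human (ENSG00000186868, chr17, + strand) MAPT exon-9/10/11 junction
coordinates, and a synthetic three-exon toy gene with a 93 bp cassette.

## Worked example

```bash
splicequant simulate --out sim --f 0.148 --n-reads 100000 --seed 7 --sample-id s1
splicequant quantify --alignments sim/s1.sam --fixture toy_maptlike --out quant
```

prints

```
E10_cassette: usage 17.40 % (n=1, undefined=0)
```

The simulator drew 100 000 spliced 75 bp reads from a 14.8 % inclusion /
85.2 % exclusion isoform mixture; `quantify` extracted the junction counts
from the SAM file (X₉,₁₀ = 2012, X₁₀,₁₁ = 1971, X₉,₁₁ = 11444), applied
the formula above and recovered a 4R/3R-style usage of 17.40 % against the
closed-form expectation 100·0.148/0.852 = 17.37 % (single-sample binomial
noise accounts for the gap; f̂ = 0.148). `quant/` also holds the
per-junction table and a TSV report. The same subcommand accepts real junction tables
(`--junctions ... --dialect star_sj|plain_tsv|jcounts`).

For qPCR data, `splicequant qpcr --cq cq.tsv --dilutions dil.tsv --out out`
fits per-target standard curves (Cq vs log₁₀ dilution), interpolates
relative quantities, normalizes to the geometric mean of GAPDH and HPRT1,
and reports per-sample 4R/3R percentages.

As a library:

```python
import splicequant as sq
model = sq.load_fixture("pig_mapt")
table = sq.extract_junctions("sample.sam", min_anchor=1)
result = sq.compute_usage(table, model.event("MAPT_4R"))
print(result.usage_percent, result.inclusion_fraction_hat)
```

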