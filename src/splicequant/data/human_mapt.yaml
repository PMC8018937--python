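# Human MAPT 3R/4R cassette (exon 10), GRCh38 chr17, plus strand.
# Junction flanking positions are annotated exon edges; outer edges of the
# flanking exons are nominal synthetic extents (200 bp).
gene_id: ENSG00000186868
chrom: chr17
strand: "+"
isoforms:
  MAPT_4R:
    - [45996465, 45996664]  # exon 9
    - [46010310, 46010402]  # exon 10 cassette, 93 bp
    - [46014243, 46014442]  # exon 11
  MAPT_3R:
    - [45996465, 45996664]
    - [46014243, 46014442]
events:
  MAPT_4R:
    inclusion:
      - [45996664, 46010310]  # X9,10
      - [46010402, 46014243]  # X10,11
    exclusion: [45996664, 46014243]  # X9,11
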