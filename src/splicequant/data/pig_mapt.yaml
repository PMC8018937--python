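# Porcine MAPT 3R/4R cassette (exon 10), Sscrofa11.1 chr12, minus strand.
# Junction flanking positions are the published Ensembl-release-98 exon
# edges; the OUTER edges of exons 9 and 11 are nominal synthetic extents
# (200 bp) -- only the junction-facing boundaries carry meaning here.
gene_id: ENSSSCG00000017311
chrom: chr12
strand: "-"
isoforms:
  MAPT_4R:  # exon 10 included
    - [17108562, 17108761]  # exon 11 (genome-left; gene is minus strand)
    - [17112207, 17112299]  # exon 10 cassette, 93 bp
    - [17122167, 17122366]  # exon 9
  MAPT_3R:  # exon 10 skipped
    - [17108562, 17108761]
    - [17122167, 17122366]
events:
  MAPT_4R:
    inclusion:
      - [17112299, 17122167]  # X9,10  (printed 17,122,167 to 17,112,299)
      - [17108761, 17112207]  # X10,11 (printed 17,112,207 to 17,108,761)
    exclusion: [17108761, 17122167]  # X9,11 (printed 17,122,167 to 17,108,761)
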