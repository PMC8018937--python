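# Fully synthetic three-exon cassette gene mirroring the MAPT 3R/4R
# structure: constitutive E9 and E11 flanking a 93 bp cassette E10.
# Used as the simulator's default gene model and in the test-suite.
gene_id: MAPTLIKE
chrom: chrT
strand: "+"
isoforms:
  inc:  # cassette included ("4R-like"), transcript length 693
    - [201, 500]    # E9, 300 bp
    - [701, 793]    # E10 cassette, 93 bp
    - [994, 1293]   # E11, 300 bp
  exc:  # cassette skipped ("3R-like"), transcript length 600
    - [201, 500]
    - [994, 1293]
events:
  E10_cassette:
    inclusion:
      - [500, 701]   # J(E9, E10)
      - [793, 994]   # J(E10, E11)
    exclusion: [500, 994]  # J(E9, E11)
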