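# Example run configuration.
# The primer sequences below are the synthetic placeholder pair shipped for
# tests and examples; replace them with the assay's real primers.
primers:
  forward: "AGCTGCATTCGAAAGGTAAA"
  reverse: "TAAGCTTATCCCCAAGGTTC"
  forward_site: [31, 50]   # 1-based closed interval on the exon sense strand
  reverse_site: [152, 171]
pabs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57,
              60, 61, 65, 67, 68, 70, 71, 74, 78, 81, 82, 85]
thresholds:
  max_artifact_count: 2
  max_nt_diff: 2
  min_individuals: 2
  min_clones: 1
trim:
  max_mismatch_frac: 0.1
  drop_trailing: 3       # nucleotides removed when amplicons trim to 270 bp
seeds:
  run: 1
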