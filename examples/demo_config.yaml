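# Demo locus for the CLI walkthrough: an E-box (CACGTG -> TATTTA) embedded in
# a synthetic 150-nt amplicon. Same locus as cge.simulate.demo_locus(seed=7).
loci:
  - locus_name: EBOX_DEMO
    amplicon_ref: TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACAAGTCTTTGCGCCCATAAATGTACACGTGGAGCTTAGTTGGAGCAAGGGGTGCGGAAGCGCAACTCCGTCGCGCGGGTAGCCAACTACTTAAGACCTAGGA
    variant_start: 72
    original_seq: CACGTG
    mutant_seq: TATTTA
analysis:
  min_baseline_count: 50
  tag_mutation_filter: [2]
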