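# Bundled toy study: 8 simulated consanguineous families segregating a fully
# penetrant recessive allele on a planted 322 kb founder haplotype
# (chr1:108,820,610-109,142,651), mapped end to end.
seed: 1
out_dir: study_out
families:
  - {template: first_cousin, n_affected: 2, n_unaffected: 1}
  - {template: first_cousin, n_affected: 1, n_unaffected: 1}
  - {template: nuclear, n_affected: 2, n_unaffected: 1}
  - {template: nuclear, n_affected: 1, n_unaffected: 1}
  - {template: nuclear, n_affected: 1, n_unaffected: 1}
  - {template: nuclear, n_affected: 1, n_unaffected: 1}
  - {template: nuclear, n_affected: 1, n_unaffected: 1}
  - {template: nuclear, n_affected: 1, n_unaffected: 1}
region:
  chromosome: chr1
  start_bp: 108820610
  end_bp: 109142651
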