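# Severity ranking for the a_style vocabulary, most severe first.
# One possible way to prioritise consequences: the orderings that matter
# are the category blocks (LoF > missense > synonymous > everything else)
# and stop-gain above frameshift; order within a block is a convention and
# may be overridden by a custom config.
vocabulary: a_style
ranking:
  - stopgain_SNV
  - stoploss_SNV
  - frameshift_insertion
  - frameshift_deletion
  - frameshift_substitution
  - splicing
  - nonframeshift_insertion
  - nonframeshift_deletion
  - nonframeshift_substitution
  - nonsynonymous_SNV
  - synonymous_SNV
  - UTR5
  - UTR3
  - UTR5_UTR3
  - ncRNA_splicing
  - ncRNA_exonic
  - ncRNA_UTR5
  - ncRNA_UTR3
  - ncRNA_UTR5_ncRNA_UTR3
  - ncRNA_intronic
  - intronic
  - upstream
  - downstream
  - upstream_downstream
  - intergenic
  - unknown
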