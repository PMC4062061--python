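# Severity ranking for the v_style vocabulary, most severe first.
# Splice donor/acceptor sit in the LoF block; splice_region sits at
# missense level; stop_retained and coding_sequence_variant (other coding)
# sit with synonymous.
vocabulary: v_style
ranking:
  - splice_acceptor_variant
  - splice_donor_variant
  - stop_gained
  - frameshift_variant
  - stop_lost
  - initiator_codon_variant
  - inframe_insertion
  - inframe_deletion
  - missense_variant
  - splice_region_variant
  - synonymous_variant
  - stop_retained_variant
  - coding_sequence_variant
  - 5_prime_UTR_variant
  - 3_prime_UTR_variant
  - non_coding_splice_variant
  - non_coding_exon_variant
  - non_coding_intron_variant
  - intron_variant
  - upstream_gene_variant
  - downstream_gene_variant
  - intergenic_variant
  - unknown
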