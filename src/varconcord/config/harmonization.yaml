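# High-level category map for both vocabularies, plus the cross-vocabulary
# exact-equivalence map.
#
# Category conventions:
#   * frameshift*, stop-gain, stop-loss, splice donor/acceptor and the broad
#     a_style "splicing" term are LOF.
#   * splice_region_variant and initiator_codon_variant are MISSENSE level.
#   * stop_retained_variant and coding_sequence_variant ("other coding") are
#     SYNONYMOUS_OTHER.
#   * "unknown" matches nothing, not even itself.
#
# Equivalence assumptions not derivable from category structure alone:
#   * a_style "splicing" is exact-equivalent to splice donor/acceptor only;
#     splice_region_variant is missense-level and therefore cannot be an
#     exact equivalent of a LoF term.
#   * ncRNA_splicing <-> non_coding_splice_variant is an equivalence by
#     convention (a splice hit reported on a non-coding transcript) and can
#     be disabled (CategoryMap(nc_splicing_equivalent=False)).
#   * nonframeshift_substitution has no v_style equivalent: an in-frame
#     block substitution is classified coding_sequence_variant there.
categories:
  a_style:
    stopgain_SNV: LOF
    stoploss_SNV: LOF
    frameshift_insertion: LOF
    frameshift_deletion: LOF
    frameshift_substitution: LOF
    splicing: LOF
    nonframeshift_insertion: MISSENSE
    nonframeshift_deletion: MISSENSE
    nonframeshift_substitution: MISSENSE
    nonsynonymous_SNV: MISSENSE
    synonymous_SNV: SYNONYMOUS_OTHER
    UTR5: UTR
    UTR3: UTR
    UTR5_UTR3: UTR
    ncRNA_splicing: NCRNA
    ncRNA_exonic: NCRNA
    ncRNA_UTR5: NCRNA
    ncRNA_UTR3: NCRNA
    ncRNA_UTR5_ncRNA_UTR3: NCRNA
    ncRNA_intronic: NCRNA
    intronic: INTRONIC
    upstream: INTERGENIC_FLANK
    downstream: INTERGENIC_FLANK
    upstream_downstream: INTERGENIC_FLANK
    intergenic: INTERGENIC_FLANK
    unknown: UNKNOWN
  v_style:
    splice_acceptor_variant: LOF
    splice_donor_variant: LOF
    stop_gained: LOF
    frameshift_variant: LOF
    stop_lost: LOF
    initiator_codon_variant: MISSENSE
    inframe_insertion: MISSENSE
    inframe_deletion: MISSENSE
    missense_variant: MISSENSE
    splice_region_variant: MISSENSE
    synonymous_variant: SYNONYMOUS_OTHER
    stop_retained_variant: SYNONYMOUS_OTHER
    coding_sequence_variant: SYNONYMOUS_OTHER
    5_prime_UTR_variant: UTR
    3_prime_UTR_variant: UTR
    non_coding_splice_variant: NCRNA
    non_coding_exon_variant: NCRNA
    non_coding_intron_variant: NCRNA
    intron_variant: INTRONIC
    upstream_gene_variant: INTERGENIC_FLANK
    downstream_gene_variant: INTERGENIC_FLANK
    intergenic_variant: INTERGENIC_FLANK
    unknown: UNKNOWN
equivalence:
  - [stopgain_SNV, stop_gained]
  - [stoploss_SNV, stop_lost]
  - [frameshift_insertion, frameshift_variant]
  - [frameshift_deletion, frameshift_variant]
  - [frameshift_substitution, frameshift_variant]
  - [splicing, splice_donor_variant]
  - [splicing, splice_acceptor_variant]
  - [nonframeshift_insertion, inframe_insertion]
  - [nonframeshift_deletion, inframe_deletion]
  - [nonsynonymous_SNV, missense_variant]
  - [synonymous_SNV, synonymous_variant]
  - [UTR5, 5_prime_UTR_variant]
  - [UTR3, 3_prime_UTR_variant]
  - [ncRNA_exonic, non_coding_exon_variant]
  - [ncRNA_intronic, non_coding_intron_variant]
  - [intronic, intron_variant]
  - [upstream, upstream_gene_variant]
  - [downstream, downstream_gene_variant]
  - [intergenic, intergenic_variant]
nc_splicing_equivalence:
  - [ncRNA_splicing, non_coding_splice_variant]
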