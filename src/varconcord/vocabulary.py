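"""Consequence-term vocabularies and high-level categories.

Two vocabularies are supported:

* ``a_style`` — a single broad ``splicing`` category, indel consequences
  split by variant class (``frameshift_insertion`` / ``_deletion`` /
  ``_substitution``), classic table labels like ``nonsynonymous_SNV``.
* ``v_style`` — fine splice terms (donor / acceptor / region), a single
  ``frameshift_variant`` term, and three exonic terms with no a_style
  equivalent (initiator codon, stop retained, other coding).

The combined a_style labels (``UTR5_UTR3``, ``upstream_downstream``, the
``ncRNA_UTR*`` family) occur in published summary tables and are part of
the vocabulary for reporting/validation purposes, but the engine does not
emit them.
"""

A_STYLE = "a_style"
V_STYLE = "v_style"

# High-level categories
LOF = "LOF"
MISSENSE = "MISSENSE"
SYNONYMOUS_OTHER = "SYNONYMOUS_OTHER"
UTR = "UTR"
NCRNA = "NCRNA"
INTRONIC = "INTRONIC"
INTERGENIC_FLANK = "INTERGENIC_FLANK"
UNKNOWN = "UNKNOWN"

CATEGORIES = (
    LOF,
    MISSENSE,
    SYNONYMOUS_OTHER,
    UTR,
    NCRNA,
    INTRONIC,
    INTERGENIC_FLANK,
    UNKNOWN,
)

#: categories counted as exonic (coding-relevant) in rollups
EXONIC_CATEGORIES = (LOF, MISSENSE, SYNONYMOUS_OTHER)

A_STYLE_TERMS = (
    "stopgain_SNV",
    "stoploss_SNV",
    "frameshift_insertion",
    "frameshift_deletion",
    "frameshift_substitution",
    "splicing",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "nonframeshift_substitution",
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "UTR5",
    "UTR3",
    "UTR5_UTR3",
    "ncRNA_splicing",
    "ncRNA_exonic",
    "ncRNA_UTR5",
    "ncRNA_UTR3",
    "ncRNA_UTR5_ncRNA_UTR3",
    "ncRNA_intronic",
    "intronic",
    "upstream",
    "downstream",
    "upstream_downstream",
    "intergenic",
    "unknown",
)

V_STYLE_TERMS = (
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "initiator_codon_variant",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "coding_sequence_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_splice_variant",
    "non_coding_exon_variant",
    "non_coding_intron_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "unknown",
)

TERMS = {A_STYLE: A_STYLE_TERMS, V_STYLE: V_STYLE_TERMS}

#: marker used in comparison records for a variant absent from one run
ABSENT = "absent"


def check_vocabulary(vocabulary: str) -> str:
    if vocabulary not in TERMS:
        raise ValueError(f"unknown vocabulary {vocabulary!r}")
    return vocabulary
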