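"""Rule-based consequence classification of (variant, transcript) pairs.

A :class:`Regime` bundles the definitional choices that differ between
annotation tools:

* vocabulary (``a_style`` or ``v_style``),
* the splicing definition — a single broad window of ``x`` intronic bases
  around every exon/intron junction (a_style, default x=6) versus the fine
  donor (intronic 1-2 bp at the intron 5' end) / acceptor (intronic 1-2 bp
  at the 3' end) / splice-region (exonic 1-3 bp or intronic 3-8 bp) terms
  (v_style),
* whether an indel that introduces a premature stop codon is reported as a
  stop-gain instead of a frameshift (``stop_scan_indels``),
* whether a variant that leaves the terminal stop codon intact at the same
  protein position is demoted to synonymous / stop-retained
  (``stop_retained_detection``),
* the reporting policy (a single most-severe call, or all calls with a
  designated primary).

Coding classification rebuilds the spliced CDS, applies the variant, and
compares the reference and alternate translations; all decisions are made
from that comparison plus the position of the edit, so an insertion inside
a terminal TGA that leaves the codon reading TGA is recognised as
synonymous/stop-retained rather than frameshift or stop-loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from varconcord import vocabulary as vocab
from varconcord.genome_model import (
    GenomeSequence,
    TranscriptModel,
    TranscriptSet,
    Variant,
)
from varconcord.severity_rules import SeverityRanking, load_ranking, most_severe

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Regime
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Regime:
    """A named bundle of vocabulary + splicing definition + reporting policy."""

    name: str
    vocabulary: str
    splicing_window_bp: int = 6
    splice_donor_len: int = 2
    splice_acceptor_len: int = 2
    splice_region_exonic_bp: tuple[int, int] = (1, 3)
    splice_region_intronic_bp: tuple[int, int] = (3, 8)
    stop_scan_indels: bool = False
    stop_retained_detection: bool = True
    flank_bp: int = 1000
    report_policy: str = "most_severe_only"
    window_side: str = "intronic_only"  # or "both"

    def __post_init__(self) -> None:
        vocab.check_vocabulary(self.vocabulary)
        if self.splicing_window_bp < 0:
            raise ValueError("splicing_window_bp must be >= 0")
        if self.vocabulary == vocab.V_STYLE and (
            self.splice_donor_len < 1 or self.splice_acceptor_len < 1
        ):
            raise ValueError("donor/acceptor lengths must be >= 1 under v_style")
        if self.report_policy not in ("most_severe_only", "all_then_prioritise"):
            raise ValueError(f"bad report_policy {self.report_policy!r}")
        if self.window_side not in ("intronic_only", "both"):
            raise ValueError(f"bad window_side {self.window_side!r}")

    @classmethod
    def a_style(cls, **overrides) -> "Regime":
        """Broad-splicing-window regime: one 'splicing' term within x bp of a
        junction, indel stop-scan on, most-severe reporting."""
        kw = dict(
            name="a_style",
            vocabulary=vocab.A_STYLE,
            splicing_window_bp=6,
            stop_scan_indels=True,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def v_style(cls, **overrides) -> "Regime":
        """Fine splice-term regime: donor/acceptor/region splice terms, no
        indel stop-scan, most-severe reporting."""
        kw = dict(
            name="v_style",
            vocabulary=vocab.V_STYLE,
            stop_scan_indels=False,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ConsequenceCall:
    """One (variant, transcript, term) assignment with supporting detail."""

    variant_key: str
    transcript_id: str | None
    term: str
    detail: dict | None = None
    low_confidence: bool = False
    primary: bool = False


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------

def _effective_span(variant: Variant) -> tuple[int, int]:
    """Genomic span occupied by the variant for interval arithmetic.

    An insertion goes immediately before ``pos``; by convention it binds to
    the right base, so its effective span is ``[pos, pos+1)``.
    """
    if variant.var_class == "insertion":
        return variant.pos, variant.pos + 1
    return variant.pos, variant.end


def _overlaps(span: tuple[int, int], iv: tuple[int, int]) -> bool:
    return span[0] < iv[1] and iv[0] < span[1]


def locate(variant: Variant, transcript: TranscriptModel,
           flank_bp: int = 1000) -> str:
    """Locate a variant relative to one transcript.

    Returns one of ``cds_exonic, utr5, utr3, intronic, nc_exonic,
    nc_intronic, upstream, downstream, outside``. An indel spanning a
    boundary reports the highest-priority overlapped class
    (CDS > UTR > intron).
    """
    span = _effective_span(variant)
    if not _overlaps(span, (transcript.start, transcript.end)):
        if span[1] <= transcript.start:
            dist = transcript.start - span[1] + 1
            side_5prime = transcript.strand == "+"
        else:
            dist = span[0] - transcript.end + 1
            side_5prime = transcript.strand == "-"
        if dist > flank_bp:
            return "outside"
        return "upstream" if side_5prime else "downstream"
    in_exon = any(_overlaps(span, e) for e in transcript.exons)
    if transcript.biotype == "noncoding":
        return "nc_exonic" if in_exon else "nc_intronic"
    cds_start = transcript.cds_intervals[0][0]
    cds_end = transcript.cds_intervals[-1][1]
    if variant.var_class == "insertion":
        # an insertion alters the CDS only when its insertion point is
        # strictly inside a CDS interval; boundary insertions belong to the
        # flanking UTR/intron
        if any(s < variant.pos < e for s, e in transcript.cds_intervals):
            return "cds_exonic"
        if in_exon and variant.pos <= cds_start:
            return "utr5" if transcript.strand == "+" else "utr3"
        if in_exon and variant.pos >= cds_end:
            return "utr3" if transcript.strand == "+" else "utr5"
        return "intronic"
    if any(_overlaps(span, c) for c in transcript.cds_intervals):
        return "cds_exonic"
    if in_exon:
        if span[1] <= cds_start:
            return "utr5" if transcript.strand == "+" else "utr3"
        if span[0] >= cds_end:
            return "utr3" if transcript.strand == "+" else "utr5"
        return "cds_exonic"  # straddles CDS without base overlap: treat as CDS
    return "intronic"


# ---------------------------------------------------------------------------
# Splicing classification
# ---------------------------------------------------------------------------

def classify_splicing(variant: Variant, transcript: TranscriptModel,
                      regime: Regime) -> list[str]:
    """Splice terms hit by the variant on this transcript (may be empty).

    a_style: a single ``splicing`` hit iff the variant lies within
    ``splicing_window_bp`` intronic bases of any junction (plus the exonic
    side when ``window_side == 'both'``).

    v_style: ``splice_donor_variant`` / ``splice_acceptor_variant`` for the
    donor/acceptor termini of an intron (strand-aware: the donor is the
    intron's 5' end), ``splice_region_variant`` for exonic positions within
    1-3 bp of a junction or intronic positions 3-8 bp in. For non-coding
    transcripts the caller maps any hit to the non-coding splice term.
    """
    if len(transcript.exons) < 2:
        return []
    span = _effective_span(variant)
    hits: list[str] = []
    for istart, iend in transcript.introns:
        ilen = iend - istart
        if regime.vocabulary == vocab.A_STYLE:
            w = min(regime.splicing_window_bp, ilen)
            windows = [(istart, istart + w), (iend - w, iend)]
            if regime.window_side == "both":
                we = regime.splicing_window_bp
                windows += [(istart - we, istart), (iend, iend + we)]
            if any(_overlaps(span, iv) for iv in windows):
                hits.append("splicing")
            continue
        # v_style
        if transcript.strand == "+":
            donor = (istart, min(istart + regime.splice_donor_len, iend))
            acceptor = (max(iend - regime.splice_acceptor_len, istart), iend)
        else:
            donor = (max(iend - regime.splice_donor_len, istart), iend)
            acceptor = (istart, min(istart + regime.splice_acceptor_len, iend))
        if _overlaps(span, donor):
            hits.append("splice_donor_variant")
        if _overlaps(span, acceptor):
            hits.append("splice_acceptor_variant")
        rlo, rhi = regime.splice_region_intronic_bp
        elo, ehi = regime.splice_region_exonic_bp
        region_windows = [
            # intronic, measured from each junction (first intron base = 1)
            (istart + rlo - 1, min(istart + rhi, iend)),
            (max(iend - rhi, istart), iend - rlo + 1),
            # exonic, measured from the junction (last exon base = 1)
            (istart - ehi, istart - elo + 1),
            (iend + elo - 1, iend + ehi),
        ]
        if any(_overlaps(span, iv) for iv in region_windows):
            hits.append("splice_region_variant")
    # deduplicate, keep deterministic order
    out: list[str] = []
    for h in hits:
        if h not in out:
            out.append(h)
    return out


def _junction_distance(variant: Variant, transcript: TranscriptModel) -> int | None:
    """Distance (bp) from the variant start to the nearest junction."""
    if len(transcript.exons) < 2:
        return None
    pos = variant.pos
    return min(
        min(abs(pos - istart), abs(iend - 1 - pos))
        for istart, iend in transcript.introns
    )


# ---------------------------------------------------------------------------
# Coding classification
# ---------------------------------------------------------------------------

def _apply_to_cds(variant: Variant, transcript: TranscriptModel,
                  genome: GenomeSequence) -> str | None:
    """Spliced alternate CDS after applying the variant; None if untouched.

    Deletions/substitutions are intersected with the CDS intervals (bases
    outside the CDS are ignored); an insertion is applied only when its
    insertion point is strictly inside a CDS interval. The result is
    strand-oriented.
    """
    out: list[str] = []
    applied = False
    for s, e in transcript.cds_intervals:
        seg = genome.fetch(transcript.chrom, s, e)
        if variant.var_class == "insertion":
            if s < variant.pos < e:
                k = variant.pos - s
                seg = seg[:k] + variant.alt + seg[k:]
                applied = True
        else:
            ovs, ove = max(s, variant.pos), min(e, variant.end)
            if ovs < ove:
                ins = variant.alt if s <= variant.pos < e else ""
                seg = seg[: ovs - s] + ins + seg[ove - s :]
                applied = True
        out.append(seg)
    if not applied:
        return None
    seq = "".join(out)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def _to_first_stop(protein: str) -> str:
    """Protein truncated at (and including) the first stop."""
    idx = protein.find("*")
    return protein if idx < 0 else protein[: idx + 1]


def _cds_positions(variant: Variant, transcript: TranscriptModel) -> list[int]:
    """Strand-oriented CDS coordinates touched by the variant."""
    if variant.var_class == "insertion":
        candidates = [variant.pos, variant.pos - 1]
    else:
        candidates = list(range(variant.pos, variant.end))
    out = [
        c for p in candidates if (c := transcript.genomic_to_cds(p)) is not None
    ]
    return sorted(out)


def classify_coding(variant: Variant, transcript: TranscriptModel,
                    genome: GenomeSequence, regime: Regime
                    ) -> ConsequenceCall | None:
    """Classify a variant that touches the CDS of a coding transcript.

    Returns None when the variant does not alter the CDS. The decision is
    made by comparing the reference and alternate CDS translations (both
    truncated at their first stop codon):

    1. identical proteins -> synonymous, or stop-retained when the edit
       overlaps the terminal stop codon;
    2. CDS length change not a multiple of 3 -> frameshift, unless the
       stop-scan is enabled and a premature stop appears (stop-gain), or —
       a_style only — the edit destroys the stop codon (stop-loss);
    3. in-frame changes -> stop-gain / stop-loss / initiator-codon /
       missense / in-frame indel / other coding, by codon comparison.
    """
    if not transcript.cds_intervals:
        return None
    ref_cds = transcript.spliced_cds(genome)
    alt_cds = _apply_to_cds(variant, transcript, genome)
    if alt_cds is None:
        return None
    a_style = regime.vocabulary == vocab.A_STYLE
    low_conf = transcript.cds_incomplete
    key = variant.key
    tid = transcript.transcript_id

    cds_pos = _cds_positions(variant, transcript)
    usable = len(ref_cds) - len(ref_cds) % 3

    # N in the affected codons (or in the inserted sequence) -> unknown
    if cds_pos:
        lo = (min(cds_pos) // 3) * 3
        hi = (max(cds_pos) // 3 + 1) * 3
        if "N" in ref_cds[lo:hi] or "N" in variant.alt:
            return ConsequenceCall(key, tid, "unknown", low_confidence=True)

    ref_prot = _translate(ref_cds)
    alt_prot = _translate(alt_cds)
    ref_p = _to_first_stop(ref_prot)
    alt_p = _to_first_stop(alt_prot)
    ref_stop_idx = ref_prot.find("*")
    cds_delta = len(alt_cds) - len(ref_cds)
    overlaps_stop = bool(cds_pos) and ref_stop_idx >= 0 and (
        max(cds_pos) >= 3 * ref_stop_idx
    )

    detail: dict = {
        "distance_to_junction_bp": _junction_distance(variant, transcript),
        "side": "exonic",
    }
    if variant.var_class == "SNV" and cds_pos:
        ci = cds_pos[0] // 3
        ref_codon = ref_cds[ci * 3 : ci * 3 + 3]
        alt_codon = alt_cds[ci * 3 : ci * 3 + 3]
        detail.update(
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            ref_aa=str(Seq(ref_codon).translate()) if len(ref_codon) == 3 else None,
            alt_aa=str(Seq(alt_codon).translate()) if len(alt_codon) == 3 else None,
        )

    def call(term: str) -> ConsequenceCall:
        return ConsequenceCall(key, tid, term, detail=detail,
                               low_confidence=low_conf)

    # 1. protein unchanged -----------------------------------------------
    if alt_p == ref_p and ref_p:
        if overlaps_stop and regime.stop_retained_detection:
            return call("synonymous_SNV" if a_style else "stop_retained_variant")
        if not overlaps_stop or regime.stop_retained_detection:
            return call("synonymous_SNV" if a_style else "synonymous_variant")
        # stop_retained_detection off and edit overlaps the stop: fall
        # through so a length-changing edit is named by its variant class.

    # premature stop: a stop strictly before where the original terminal
    # stop codon maps to in the alternate CDS
    alt_stop_idx = alt_p.find("*") if "*" in alt_p else -1
    if ref_stop_idx >= 0 and cds_pos:
        mapped_ref_stop = 3 * ref_stop_idx
        if min(cds_pos) <= mapped_ref_stop:
            mapped_ref_stop += cds_delta
        premature = alt_stop_idx >= 0 and 3 * alt_stop_idx < mapped_ref_stop
    else:
        premature = False

    # 2. frameshift-class ------------------------------------------------
    if cds_delta % 3 != 0:
        if regime.stop_scan_indels and premature:
            return call("stopgain_SNV" if a_style else "stop_gained")
        if a_style and overlaps_stop:
            return call("stoploss_SNV")
        if a_style:
            return call(
                {
                    "insertion": "frameshift_insertion",
                    "deletion": "frameshift_deletion",
                }.get(variant.var_class, "frameshift_substitution")
            )
        return call("frameshift_variant")

    # 3. in-frame --------------------------------------------------------
    # initiator codon: first codon moved away from ATG
    if (
        cds_pos
        and min(cds_pos) < 3
        and ref_cds[:3] == "ATG"
        and alt_cds[:3] != "ATG"
    ):
        if not a_style:
            return call("initiator_codon_variant")
        if variant.var_class == "SNV":
            return call("nonsynonymous_SNV")

    if variant.var_class == "SNV":
        ref_aa = detail.get("ref_aa")
        alt_aa = detail.get("alt_aa")
        if ref_aa == "*" and alt_aa != "*":
            return call("stoploss_SNV" if a_style else "stop_lost")
        if alt_aa == "*" and ref_aa != "*":
            return call("stopgain_SNV" if a_style else "stop_gained")
        if ref_aa == alt_aa:
            return call("synonymous_SNV" if a_style else "synonymous_variant")
        return call("nonsynonymous_SNV" if a_style else "missense_variant")

    # in-frame indel / block substitution
    if premature and (regime.stop_scan_indels or cds_delta == 0):
        return call("stopgain_SNV" if a_style else "stop_gained")
    if overlaps_stop:
        # the edit touches the stop codon and the protein changed
        return call("stoploss_SNV" if a_style else "stop_lost")
    if cds_delta == 0:
        return call(
            "nonframeshift_substitution" if a_style else "coding_sequence_variant"
        )
    if variant.var_class == "insertion" or cds_delta > 0:
        return call("nonframeshift_insertion" if a_style else "inframe_insertion")
    return call("nonframeshift_deletion" if a_style else "inframe_deletion")


# ---------------------------------------------------------------------------
# Per-transcript and per-variant annotation
# ---------------------------------------------------------------------------

_A_LOCATION_TERMS = {
    "utr5": "UTR5",
    "utr3": "UTR3",
    "intronic": "intronic",
    "nc_exonic": "ncRNA_exonic",
    "nc_intronic": "ncRNA_intronic",
    "upstream": "upstream",
    "downstream": "downstream",
}
_V_LOCATION_TERMS = {
    "utr5": "5_prime_UTR_variant",
    "utr3": "3_prime_UTR_variant",
    "intronic": "intron_variant",
    "nc_exonic": "non_coding_exon_variant",
    "nc_intronic": "non_coding_intron_variant",
    "upstream": "upstream_gene_variant",
    "downstream": "downstream_gene_variant",
}


def transcript_calls(variant: Variant, transcript: TranscriptModel,
                     genome: GenomeSequence, regime: Regime
                     ) -> list[ConsequenceCall]:
    """All consequence calls for one (variant, transcript) pair.

    a_style resolves to a single call per transcript (splicing beats coding
    calls at junction-spanning edits, except when the protein is provably
    unchanged); v_style may emit several calls (e.g. a splice term plus a
    coding term) and leaves selection to severity precedence.
    """
    loc = locate(variant, transcript, regime.flank_bp)
    if loc == "outside":
        return []
    key = variant.key
    tid = transcript.transcript_id
    a_style = regime.vocabulary == vocab.A_STYLE
    loc_terms = _A_LOCATION_TERMS if a_style else _V_LOCATION_TERMS

    if loc in ("upstream", "downstream"):
        return [ConsequenceCall(key, tid, loc_terms[loc])]

    splice_hits = classify_splicing(variant, transcript, regime)
    if transcript.biotype == "noncoding":
        calls = []
        if splice_hits:
            term = "ncRNA_splicing" if a_style else "non_coding_splice_variant"
            calls.append(ConsequenceCall(
                key, tid, term,
                detail={"distance_to_junction_bp": _junction_distance(variant, transcript)},
            ))
        if a_style and calls:
            return calls  # broad splicing beats the exon/intron location
        calls.append(ConsequenceCall(key, tid, loc_terms[loc]))
        return calls

    coding_call = classify_coding(variant, transcript, genome, regime)

    if a_style:
        if (
            coding_call is not None
            and coding_call.term == "synonymous_SNV"
            and regime.stop_retained_detection
        ):
            # protein provably unchanged: beats the splicing window
            return [coding_call]
        if splice_hits:
            return [ConsequenceCall(
                key, tid, "splicing",
                detail={"distance_to_junction_bp": _junction_distance(variant, transcript)},
            )]
        if coding_call is not None:
            return [coding_call]
        return [ConsequenceCall(key, tid, loc_terms[loc])]

    # v_style: emit everything applicable, severity selection resolves
    calls = [
        ConsequenceCall(
            key, tid, t,
            detail={"distance_to_junction_bp": _junction_distance(variant, transcript)},
        )
        for t in splice_hits
    ]
    if coding_call is not None:
        calls.append(coding_call)
    elif loc in loc_terms:
        calls.append(ConsequenceCall(key, tid, loc_terms[loc]))
    return calls


def annotate(variant: Variant, tset: TranscriptSet, genome: GenomeSequence,
             regime: Regime, ranking: SeverityRanking | None = None
             ) -> list[ConsequenceCall]:
    """Annotate one variant against a transcript set.

    Produces per-transcript calls for every overlapping transcript, plus
    upstream/downstream calls for transcripts within ``flank_bp``; a single
    ``intergenic`` call if nothing is in range. Under the
    ``most_severe_only`` policy exactly one call survives (ties broken by
    transcript id); under ``all_then_prioritise`` all calls are returned
    with the primary marked.
    """
    if ranking is None:
        ranking = load_ranking(vocabulary=regime.vocabulary)
    pos = variant.pos if variant.var_class != "insertion" else max(variant.pos - 1, 0)
    candidates: dict[str, TranscriptModel] = {}
    for p in range(variant.pos, max(variant.end, variant.pos + 1)):
        for tx in tset.overlapping(variant.chrom, p):
            candidates[tx.transcript_id] = tx
    for tx in tset.near(variant.chrom, pos, regime.flank_bp):
        candidates.setdefault(tx.transcript_id, tx)
    calls: list[ConsequenceCall] = []
    for tid in sorted(candidates):
        calls.extend(transcript_calls(variant, candidates[tid], genome, regime))
    if not calls:
        term = "intergenic" if regime.vocabulary == vocab.A_STYLE else "intergenic_variant"
        calls = [ConsequenceCall(variant.key, None, term)]
    best = most_severe(calls, ranking)
    if regime.report_policy == "most_severe_only":
        return [replace(best, primary=True)]
    return [replace(c, primary=(c is best)) for c in calls]


def annotate_all(variants, tset: TranscriptSet, genome: GenomeSequence,
                 regime: Regime, ranking: SeverityRanking | None = None):
    """Annotate a list of variants; returns a pandas DataFrame.

    Columns: variant_key, term, transcript_id, primary, low_confidence,
    ref_codon, alt_codon, ref_aa, alt_aa, distance_to_junction_bp.
    """
    import pandas as pd

    if ranking is None:
        ranking = load_ranking(vocabulary=regime.vocabulary)
    rows = []
    for v in variants:
        for c in annotate(v, tset, genome, regime, ranking):
            d = c.detail or {}
            rows.append(
                {
                    "variant_key": c.variant_key,
                    "term": c.term,
                    "transcript_id": c.transcript_id,
                    "primary": c.primary,
                    "low_confidence": c.low_confidence,
                    "ref_codon": d.get("ref_codon"),
                    "alt_codon": d.get("alt_codon"),
                    "ref_aa": d.get("ref_aa"),
                    "alt_aa": d.get("alt_aa"),
                    "distance_to_junction_bp": d.get("distance_to_junction_bp"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "term",
            "transcript_id",
            "primary",
            "low_confidence",
            "ref_codon",
            "alt_codon",
            "ref_aa",
            "alt_aa",
            "distance_to_junction_bp",
        ],
    )
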