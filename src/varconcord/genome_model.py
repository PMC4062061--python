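"""Data model and I/O for genome sequences, transcript sets and variants.

Coordinate conventions are fixed once, at the boundary: everything internal
is 0-based half-open on the forward strand of the reference. GTF input
(1-based inclusive) and VCF input (1-based, anchor-base indel encoding) are
converted on read; writers convert back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GenomeModelError(ValueError):
    """Raised for malformed genome / transcript / variant input."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise GenomeModelError("empty chromosome name")
            if name in clean:
                raise GenomeModelError(f"duplicate chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeModelError(
                    f"chromosome {name!r} contains invalid bases {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)``; raises on unknown chromosome."""
        if chrom not in self.sequences:
            raise GenomeModelError(f"unknown chromosome {chrom!r}")
        return self.sequences[chrom][start:end]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def read_genome(path: str) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate headers are rejected.
    """
    seqs: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise GenomeModelError(f"duplicate chromosome {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
        n += 1
    if n == 0:
        raise GenomeModelError(f"no FASTA records in {path}")
    logger.info("read %d sequences from %s", n, path)
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genome.

    ``exons`` and ``cds_intervals`` are 0-based half-open genomic intervals
    in genomic (ascending) order regardless of strand; ``strand`` says how
    to read them. A coding transcript has non-empty ``cds_intervals``.
    ``cds_incomplete`` flags a CDS whose total length is not a multiple of
    three; such transcripts are annotated best-effort, never rejected.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"bad strand {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise GenomeModelError(
                    f"{self.transcript_id}: empty exon interval ({s},{e})"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GenomeModelError(
                    f"{self.transcript_id}: overlapping exons"
                )
        self.exons = [tuple(e) for e in exons]
        cds = sorted(tuple(c) for c in self.cds_intervals)
        for c in cds:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                raise GenomeModelError(
                    f"{self.transcript_id}: CDS interval {c} outside exons"
                )
        self.cds_intervals = cds

    # -- derived structure ------------------------------------------------

    @property
    def biotype(self) -> str:
        return "coding" if self.cds_intervals else "noncoding"

    @property
    def cds_incomplete(self) -> bool:
        return bool(self.cds_intervals) and self.cds_length % 3 != 0

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """Strand-oriented CDS nucleotide sequence (start codon first)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e in self.cds_intervals]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic position of strand-oriented CDS coordinate ``cds_pos``."""
        if cds_pos < 0 or cds_pos >= self.cds_length:
            raise GenomeModelError(f"CDS position {cds_pos} out of range")
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if cds_pos < offset + (e - s):
                    return s + (cds_pos - offset)
                offset += e - s
        else:
            for s, e in reversed(self.cds_intervals):
                if cds_pos < offset + (e - s):
                    return e - 1 - (cds_pos - offset)
                offset += e - s
        raise AssertionError("unreachable")

    def genomic_to_cds(self, pos: int) -> int | None:
        """CDS coordinate (0-based, strand-oriented) of genomic ``pos``.

        None if ``pos`` is not inside the CDS.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos < e:
                    return offset + (pos - s)
                offset += e - s
            return None
        for s, e in reversed(self.cds_intervals):
            if s <= pos < e:
                return offset + (e - 1 - pos)
            offset += e - s
        return None


class TranscriptSet:
    """A named collection of transcripts with a positional interval index."""

    def __init__(self, name: str, transcripts: list[TranscriptModel]):
        self.name = name
        self.transcripts: dict[str, TranscriptModel] = {}
        trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            if tx.transcript_id in self.transcripts:
                raise GenomeModelError(
                    f"duplicate transcript_id {tx.transcript_id!r} in set {name!r}"
                )
            self.transcripts[tx.transcript_id] = tx
            trees.setdefault(tx.chrom, IntervalTree()).addi(
                tx.start, tx.end, tx.transcript_id
            )
        self._trees = trees

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose exon-intron span contains genomic ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.at(pos)
        return sorted(
            (self.transcripts[h.data] for h in hits),
            key=lambda t: t.transcript_id,
        )

    def near(self, chrom: str, pos: int, flank: int) -> list[TranscriptModel]:
        """Transcripts within ``flank`` bp of ``pos`` (excluding overlaps)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(pos - flank, pos + flank + 1)
        out = [
            self.transcripts[h.data]
            for h in hits
            if not self.transcripts[h.data].contains(pos)
        ]
        return sorted(out, key=lambda t: t.transcript_id)


def read_transcripts(path: str, set_name: str) -> TranscriptSet:
    """Read a GTF file of exon/CDS features into a :class:`TranscriptSet`.

    1-based inclusive GTF coordinates become 0-based half-open. Transcripts
    whose CDS falls outside their exons are rejected with a warning, never
    a crash.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise GenomeModelError(
                f"{path}: {feat.featuretype} feature without transcript_id"
            )
        tid = tids[0]
        gid = (feat.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)
    transcripts = []
    n_rejected = 0
    for tid, (gid, chrom, strand) in meta.items():
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=_merge_intervals(exons.get(tid, [])),
                    cds_intervals=cds.get(tid, []),
                )
            )
        except GenomeModelError as exc:
            logger.warning("rejecting transcript %s: %s", tid, exc)
            n_rejected += 1
    logger.info(
        "read %d transcripts (%d rejected) from %s", len(transcripts),
        n_rejected, path,
    )
    return TranscriptSet(set_name, transcripts)


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge touching/overlapping intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def write_transcripts(tset: TranscriptSet, path: str, source: str = "varconcord") -> None:
    """Write a TranscriptSet as GTF (exon and CDS features)."""
    with open(path, "w") as fh:
        for tx in sorted(tset, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            rows = [("exon", s, e) for s, e in tx.exons]
            rows += [("CDS", s, e) for s, e in tx.cds_intervals]
            for ftype, s, e in rows:
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            ftype,
                            str(s + 1),  # back to 1-based inclusive
                            str(e),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A normalized sequence change: left-aligned, shared prefix/suffix trimmed.

    ``pos`` is the 0-based coordinate of the first reference base; for a
    pure insertion (``ref == ""``) the inserted sequence goes immediately
    before ``pos``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise GenomeModelError("ref == alt after normalization")
        if self.ref and self.alt and not (len(self.ref) == 1 and len(self.alt) == 1):
            if self.ref[0] == self.alt[0] or self.ref[-1] == self.alt[-1]:
                raise GenomeModelError(
                    f"variant {self.chrom}:{self.pos}:{self.ref}>{self.alt} "
                    "not minimal: shared flanking base"
                )

    @property
    def var_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == 0:
            return "insertion"
        if len(self.alt) == 0:
            return "deletion"
        return "block_substitution"

    @property
    def end(self) -> int:
        """End (exclusive) of the reference span; == pos for insertions."""
        return self.pos + len(self.ref)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref or '-'}:{self.alt or '-'}"

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.key


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      genome: GenomeSequence | None = None) -> Variant:
    """Trim shared prefix/suffix and left-align against ``genome``.

    ``pos`` is 0-based. Left-alignment shifts a pure indel leftwards while
    the base preceding it equals its last base (the standard VCF
    normalization move), so classification does not depend on the input
    dialect.
    """
    ref = ref.upper()
    alt = alt.upper()
    # trim shared suffix, then shared prefix (stop when minimal SNV remains)
    while ref and alt and ref[-1] == alt[-1] and not (
        len(ref) == 1 and len(alt) == 1
    ):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and not (
        len(ref) == 1 and len(alt) == 1
    ):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if genome is not None and (len(ref) == 0 or len(alt) == 0):
        seq = genome[chrom]
        indel = alt if len(ref) == 0 else ref
        while pos > 0 and indel and seq[pos - 1] == indel[-1]:
            indel = seq[pos - 1] + indel[:-1]
            pos -= 1
        if len(ref) == 0:
            alt = indel
        else:
            ref = indel
    if genome is not None and ref:
        observed = genome.fetch(chrom, pos, pos + len(ref))
        if observed != ref:
            raise GenomeModelError(
                f"REF mismatch at {chrom}:{pos}: VCF {ref!r} vs genome {observed!r}"
            )
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)


def read_variants(path: str, genome: GenomeSequence) -> list[Variant]:
    """Read a VCF into normalized :class:`Variant` records.

    Multi-allelic records are split; the VCF anchor-base encoding is reduced
    to the minimal left-aligned representation; REF alleles are checked
    against the genome. Symbolic alleles are skipped with a warning count.
    """
    out: list[Variant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or "*" in alt or "." == alt:
                    n_skipped += 1
                    continue
                observed = genome.fetch(
                    rec.chrom, rec.start, rec.start + len(rec.ref)
                )
                if observed != rec.ref.upper():
                    raise GenomeModelError(
                        f"REF mismatch for record {rec.chrom}:{rec.pos} "
                        f"{rec.ref}>{alt}: genome has {observed!r}"
                    )
                out.append(
                    normalize_variant(rec.chrom, rec.start, rec.ref, alt, genome)
                )
    if n_skipped:
        logger.warning("skipped %d symbolic/star alleles in %s", n_skipped, path)
    logger.info("read %d variants from %s", len(out), path)
    return out
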