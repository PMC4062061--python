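"""Seeded synthetic genomes, paired transcript sets and designed variants.

The generator builds a study in miniature: a random genome carrying
non-overlapping genes (each with one or more isoforms differing only in
UTR extent, so a designed variant has the same consequence in every
isoform of its host gene), two transcript catalogues A and B where B
additionally contains genes absent from A (emulating one catalogue being
richer than the other without being a superset in general), and variants
placed by construction to realise a designed consequence class, each with
a :class:`TruthRecord` stating the expected term under each regime.

Feasibility of a placement (e.g. "this 1-bp deletion must not create a
premature stop codon") is checked at generation time with plain
translation arithmetic local to this module, independent of the
consequence engine — so recovering 100% of the expected terms with the
engine is a genuine cross-check of two implementations.

Everything is deterministic given the seed: placement scans candidate
positions in a fixed order and takes the first feasible one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from varconcord.genome_model import (
    GenomeSequence,
    TranscriptModel,
    TranscriptSet,
    Variant,
    normalize_variant,
)

CHROM = "chr1"
STOP = "TGA"
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_COMP = str.maketrans("ACGT", "TGCA")

#: designed consequence classes and the term each is expected to receive
#: under the default a_style / v_style regimes (annotated against set A)
EXPECTED_TERMS: dict[str, dict[str, str]] = {
    "stop_loss_snv": {"a_style": "stoploss_SNV", "v_style": "stop_lost"},
    "stop_retained_insertion": {
        "a_style": "synonymous_SNV", "v_style": "stop_retained_variant",
    },
    "stop_gain_snv": {"a_style": "stopgain_SNV", "v_style": "stop_gained"},
    "frameshift_indel": {
        "a_style": "frameshift_deletion", "v_style": "frameshift_variant",
    },
    "stopgain_via_indel": {
        "a_style": "stopgain_SNV", "v_style": "frameshift_variant",
    },
    "inframe_indel": {
        "a_style": "nonframeshift_deletion", "v_style": "inframe_deletion",
    },
    "missense_snv": {"a_style": "nonsynonymous_SNV", "v_style": "missense_variant"},
    "synonymous_snv": {"a_style": "synonymous_SNV", "v_style": "synonymous_variant"},
    "initiator_codon_snv": {
        "a_style": "nonsynonymous_SNV", "v_style": "initiator_codon_variant",
    },
    "splice_donor_snv": {"a_style": "splicing", "v_style": "splice_donor_variant"},
    "splice_acceptor_snv": {
        "a_style": "splicing", "v_style": "splice_acceptor_variant",
    },
    "splice_region_snv": {"a_style": "splicing", "v_style": "splice_region_variant"},
    "deep_intronic_snv": {"a_style": "intronic", "v_style": "intron_variant"},
    "utr5_snv": {"a_style": "UTR5", "v_style": "5_prime_UTR_variant"},
    "utr3_snv": {"a_style": "UTR3", "v_style": "3_prime_UTR_variant"},
    "intergenic_snv": {"a_style": "intergenic", "v_style": "intergenic_variant"},
    "ncrna_exonic_snv": {
        "a_style": "ncRNA_exonic", "v_style": "non_coding_exon_variant",
    },
    "upstream_snv": {"a_style": "upstream", "v_style": "upstream_gene_variant"},
    "downstream_snv": {"a_style": "downstream", "v_style": "downstream_gene_variant"},
}

DEFAULT_CLASS_MIX: dict[str, int] = {
    "stop_loss_snv": 13,
    "stop_retained_insertion": 13,
    "stop_gain_snv": 13,
    "frameshift_indel": 13,
    "stopgain_via_indel": 13,
    "inframe_indel": 13,
    "missense_snv": 13,
    "synonymous_snv": 13,
    "initiator_codon_snv": 13,
    "splice_donor_snv": 13,
    "splice_acceptor_snv": 13,
    "splice_region_snv": 13,
    "deep_intronic_snv": 13,
    "utr5_snv": 13,
    "utr3_snv": 13,
    "intergenic_snv": 13,
    "ncrna_exonic_snv": 8,
    "upstream_snv": 6,
    "downstream_snv": 6,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length_bp: int = 400_000
    n_genes: int = 40
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 4)
    exon_length_bp: tuple[int, int] = (90, 210)
    intron_length_bp: tuple[int, int] = (80, 300)
    utr_length_bp: tuple[int, int] = (20, 60)
    intergenic_gap_bp: int = 2600
    utr_extension_bp: tuple[int, int] = (10, 50)
    extra_transcript_fraction: float = 0.15
    a_only_fraction: float = 0.0
    noncoding_fraction: float = 0.15
    variant_class_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )

    def __post_init__(self) -> None:
        for frac in (self.extra_transcript_fraction, self.a_only_fraction,
                     self.noncoding_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must be in [0, 1]")
        for cls, n in self.variant_class_mix.items():
            if cls not in EXPECTED_TERMS:
                raise SimulationError(f"unknown designed class {cls!r}")
            if n < 0:
                raise SimulationError(f"negative count for class {cls!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one designed variant (against transcript set A)."""

    variant: Variant
    designed_class: str
    transcript_id: str | None
    expected: dict[str, str]  # regime name -> expected term

    @property
    def variant_key(self) -> str:
        return self.variant.key


@dataclass
class GenePlan:
    gene_id: str
    strand: str
    coding: bool
    membership: str  # shared | b_only | a_only
    isoforms: list[TranscriptModel]

    @property
    def core(self) -> TranscriptModel:
        return self.isoforms[0]


# ---------------------------------------------------------------------------
# Genome + transcript simulation
# ---------------------------------------------------------------------------

def simulate_genome_and_transcripts(
    config: SimulationConfig,
) -> tuple[GenomeSequence, TranscriptSet, TranscriptSet, list[GenePlan]]:
    """Build the genome and the paired transcript sets A and B.

    Genes are placed left to right with fixed intergenic gaps; every coding
    transcript gets an ATG start, a TGA stop, no internal stop and a CDS
    length that is a multiple of three. A fraction of genes is present only
    in set B (and optionally only in set A); isoforms of one gene share the
    exon/CDS skeleton and differ only in UTR extension.
    """
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(list("ACGT"), size=config.genome_length_bp)
    seq = bytearray("".join(seq), "ascii")

    n_nc = int(round(config.noncoding_fraction * config.n_genes))
    n_b_only = int(round(config.extra_transcript_fraction * config.n_genes))
    n_a_only = int(round(config.a_only_fraction * config.n_genes))
    if n_nc + n_b_only + n_a_only > config.n_genes:
        raise SimulationError("gene-fraction configuration exceeds n_genes")
    # membership layout (deterministic): b_only/a_only genes taken from the
    # coding genes at the end of the chromosome, noncoding before them
    roles = ["shared_coding"] * (config.n_genes - n_nc - n_b_only - n_a_only)
    roles += ["shared_noncoding"] * n_nc
    roles += ["b_only"] * n_b_only + ["a_only"] * n_a_only

    genes: list[GenePlan] = []
    cursor = 0
    ext_max = config.utr_extension_bp[1]
    for gi, role in enumerate(roles):
        cursor += config.intergenic_gap_bp
        start = cursor + ext_max  # room for 5' isoform extensions
        n_exons = int(rng.integers(*config.exons_per_transcript, endpoint=True))
        exon_lens = rng.integers(*config.exon_length_bp, size=n_exons, endpoint=True)
        intron_lens = rng.integers(
            *config.intron_length_bp, size=max(n_exons - 1, 0), endpoint=True
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        p = start
        for k, el in enumerate(exon_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if k < len(intron_lens):
                p += int(intron_lens[k])
        gene_end = p
        if gene_end + ext_max > config.genome_length_bp:
            raise SimulationError(
                "infeasible config: genes exceed genome length "
                f"(gene {gi} would end at {gene_end + ext_max})"
            )
        cursor = gene_end + ext_max

        coding = role in ("shared_coding", "b_only", "a_only")
        gene_id = f"G{gi:03d}"
        cds_intervals: list[tuple[int, int]] = []
        if coding:
            utr5 = int(rng.integers(*config.utr_length_bp, endpoint=True))
            utr3 = int(rng.integers(*config.utr_length_bp, endpoint=True))
            cds_intervals = _carve_cds(exons, strand, utr5, utr3)
            _write_cds_sequence(seq, cds_intervals, strand, rng)
        n_iso = int(rng.integers(*config.isoforms_per_gene, endpoint=True))
        isoforms = []
        for ii in range(n_iso):
            iso_exons = [list(e) for e in exons]
            if ii > 0:  # non-core isoforms extend the outer UTRs
                iso_exons[0][0] -= int(rng.integers(*config.utr_extension_bp, endpoint=True))
                iso_exons[-1][1] += int(rng.integers(*config.utr_extension_bp, endpoint=True))
            isoforms.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.{ii + 1}",
                    gene_id=gene_id,
                    chrom=CHROM,
                    strand=strand,
                    exons=[tuple(e) for e in iso_exons],
                    cds_intervals=list(cds_intervals),
                )
            )
        membership = {"shared_coding": "shared", "shared_noncoding": "shared"}.get(
            role, role
        )
        genes.append(GenePlan(gene_id, strand, coding, membership, isoforms))

    genome = GenomeSequence({CHROM: seq.decode("ascii")})
    set_a = TranscriptSet(
        "setA",
        [t for g in genes if g.membership in ("shared", "a_only") for t in g.isoforms],
    )
    set_b = TranscriptSet(
        "setB",
        [t for g in genes if g.membership in ("shared", "b_only") for t in g.isoforms],
    )
    return genome, set_a, set_b, genes


def _carve_cds(exons, strand, utr5, utr3) -> list[tuple[int, int]]:
    """CDS intervals = exons minus UTRs; total length forced to 3k >= 60."""
    total = sum(e - s for s, e in exons)
    if strand == "+":
        left, right = utr5, utr3
    else:
        left, right = utr3, utr5
    # trim so the CDS length is a multiple of 3
    cds_len = total - left - right
    right += cds_len % 3
    cds_len -= cds_len % 3
    if cds_len < 60:
        raise SimulationError("exon configuration leaves CDS shorter than 60 bp")
    # walk exonic bases in genomic order, keep those in [left, total-right)
    out = []
    idx = 0
    for s, e in exons:
        a = max(s, s + (left - idx))
        b = min(e, e - max(0, idx + (e - s) - (total - right)))
        if a < b:
            out.append((a, b))
        idx += e - s
    return out


def _write_cds_sequence(seq: bytearray, cds_intervals, strand,
                        rng: np.random.Generator) -> None:
    """Overwrite genome bases so the spliced CDS is ATG..sense..TGA."""
    cds_len = sum(e - s for s, e in cds_intervals)
    n_codons = cds_len // 3
    codons = ["ATG"]
    codons += [
        _SENSE_CODONS[int(i)]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    ]
    codons.append(STOP)
    cds_seq = "".join(codons)
    if strand == "-":
        cds_seq = cds_seq.translate(_COMP)[::-1]
    k = 0
    for s, e in cds_intervals:
        seq[s:e] = cds_seq[k : k + (e - s)].encode("ascii")
        k += e - s


# ---------------------------------------------------------------------------
# Variant placement
# ---------------------------------------------------------------------------

@dataclass
class _Placer:
    """Deterministic designed-variant placement over a simulated genome."""

    genome: GenomeSequence
    genes: list[GenePlan]
    config: SimulationConfig
    rng: np.random.Generator
    used: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coding = [g for g in self.genes if g.coding and g.membership == "shared"]
        self.noncoding = [
            g for g in self.genes if not g.coding and g.membership == "shared"
        ]
        self._round = {c: 0 for c in EXPECTED_TERMS}

    # -- helpers ---------------------------------------------------------

    def _claim(self, lo: int, hi: int) -> bool:
        span = range(lo - 1, hi + 1)
        if any(p in self.used for p in span):
            return False
        self.used.update(span)
        return True

    def _host(self, pool: list[GenePlan], designed_class: str) -> list[GenePlan]:
        """Gene pool rotated per class so placements spread over genes."""
        if not pool:
            raise SimulationError(f"no host gene available for {designed_class!r}")
        k = self._round[designed_class] % len(pool)
        self._round[designed_class] += 1
        return pool[k:] + pool[:k]

    def _exonic_junction_distance(self, tx: TranscriptModel, pos: int) -> int:
        """Distance (1 = adjacent) from exonic pos to the nearest junction."""
        best = 10**9
        for i, (s, e) in enumerate(tx.exons):
            if not s <= pos < e:
                continue
            if i > 0:
                best = min(best, pos - s + 1)
            if i < len(tx.exons) - 1:
                best = min(best, e - pos)
        return best

    def _mk(self, pos: int, ref: str, alt: str) -> Variant | None:
        v = normalize_variant(CHROM, pos, ref, alt, self.genome)
        lo, hi = v.pos, max(v.end, v.pos + 1)
        if not self._claim(lo, hi):
            return None
        return v

    def _alt_cds_of(self, tx: TranscriptModel, v: Variant) -> str:
        """Local re-implementation of 'apply variant to spliced CDS'."""
        parts = []
        for s, e in tx.cds_intervals:
            seg = self.genome.fetch(CHROM, s, e)
            if v.var_class == "insertion":
                if s < v.pos < e:
                    seg = seg[: v.pos - s] + v.alt + seg[v.pos - s :]
            else:
                a, b = max(s, v.pos), min(e, v.end)
                if a < b:
                    ins = v.alt if s <= v.pos < e else ""
                    seg = seg[: a - s] + ins + seg[b - s :]
            parts.append(seg)
        seq = "".join(parts)
        if tx.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def _frameshift_profile(self, tx: TranscriptModel, v: Variant
                            ) -> tuple[bool, bool]:
        """(premature_stop, touches_stop_codon) for an indel, by translation."""
        ref_cds = tx.spliced_cds(self.genome)
        alt_cds = self._alt_cds_of(tx, v)
        ref_prot = str(Seq(ref_cds).translate())
        ref_stop = ref_prot.find("*")
        alt_use = len(alt_cds) - len(alt_cds) % 3
        alt_prot = str(Seq(alt_cds[:alt_use]).translate())
        alt_stop = alt_prot.find("*")
        delta = len(alt_cds) - len(ref_cds)
        cds_positions = [
            c
            for p in (
                [v.pos, v.pos - 1] if v.var_class == "insertion"
                else range(v.pos, v.end)
            )
            if (c := tx.genomic_to_cds(p)) is not None
        ]
        touches_stop = bool(cds_positions) and max(cds_positions) >= 3 * ref_stop
        mapped = 3 * ref_stop + (delta if cds_positions and min(cds_positions) <= 3 * ref_stop else 0)
        premature = alt_stop >= 0 and 3 * alt_stop < mapped
        return premature, touches_stop

    # -- one method per designed class -----------------------------------

    def place(self, designed_class: str) -> tuple[Variant, str | None]:
        method = getattr(self, f"_place_{designed_class}")
        for gene in self._host(
            self.noncoding
            if designed_class == "ncrna_exonic_snv"
            else self.coding
            if designed_class not in ("intergenic_snv",)
            else [None],  # intergenic needs no host gene
            designed_class,
        ):
            got = method(gene)
            if got is not None:
                return got
        raise SimulationError(f"could not place designed class {designed_class!r}")

    def _codon(self, tx: TranscriptModel, idx: int) -> str:
        cds = tx.spliced_cds(self.genome)
        return cds[idx * 3 : idx * 3 + 3]

    def _snv_at_cds(self, tx: TranscriptModel, cds_pos: int, alt_tx_base: str
                    ) -> Variant | None:
        g = tx.cds_to_genomic(cds_pos)
        ref = self.genome.fetch(CHROM, g, g + 1)
        alt = alt_tx_base if tx.strand == "+" else alt_tx_base.translate(_COMP)
        if alt == ref:
            return None
        return self._mk(g, ref, alt)

    def _codon_indices(self, tx: TranscriptModel) -> range:
        return range(2, tx.cds_length // 3 - 2)

    def _interior_codon_ok(self, tx: TranscriptModel, idx: int,
                           span_codons: int = 1) -> bool:
        """Codon(s) fully inside one CDS interval, >= 4 bp from junctions."""
        for cp in range(idx * 3, (idx + span_codons) * 3):
            g = tx.cds_to_genomic(cp)
            if self._exonic_junction_distance(tx, g) < 4 + 3:
                return False
        return True

    def _place_missense_snv(self, gene: GenePlan):
        tx = gene.core
        for idx in self._codon_indices(tx):
            if not self._interior_codon_ok(tx, idx):
                continue
            codon = self._codon(tx, idx)
            aa = str(Seq(codon).translate())
            for k in range(3):
                for b in "ACGT":
                    if b == codon[k]:
                        continue
                    alt_codon = codon[:k] + b + codon[k + 1 :]
                    alt_aa = str(Seq(alt_codon).translate())
                    if alt_aa in ("*", aa):
                        continue
                    v = self._snv_at_cds(tx, idx * 3 + k, b)
                    if v is not None:
                        return v, tx.transcript_id
        return None

    def _place_synonymous_snv(self, gene: GenePlan):
        tx = gene.core
        for idx in self._codon_indices(tx):
            if not self._interior_codon_ok(tx, idx):
                continue
            codon = self._codon(tx, idx)
            aa = str(Seq(codon).translate())
            for b in "ACGT":
                if b == codon[2]:
                    continue
                alt_codon = codon[:2] + b
                if str(Seq(alt_codon).translate()) != aa:
                    continue
                v = self._snv_at_cds(tx, idx * 3 + 2, b)
                if v is not None:
                    return v, tx.transcript_id
        return None

    def _place_stop_gain_snv(self, gene: GenePlan):
        tx = gene.core
        for idx in self._codon_indices(tx):
            if not self._interior_codon_ok(tx, idx):
                continue
            codon = self._codon(tx, idx)
            for k in range(3):
                for b in "ACGT":
                    if b == codon[k]:
                        continue
                    alt_codon = codon[:k] + b + codon[k + 1 :]
                    if str(Seq(alt_codon).translate()) != "*":
                        continue
                    v = self._snv_at_cds(tx, idx * 3 + k, b)
                    if v is not None:
                        return v, tx.transcript_id
        return None

    def _place_stop_loss_snv(self, gene: GenePlan):
        tx = gene.core
        last = tx.cds_length // 3 - 1  # the TGA codon
        if not self._interior_codon_ok(tx, last):
            return None
        # TGA -> TGG (tryptophan)
        v = self._snv_at_cds(tx, last * 3 + 2, "G")
        return None if v is None else (v, tx.transcript_id)

    def _place_stop_retained_insertion(self, gene: GenePlan):
        """Single-base insertion inside the TGA stop codon that leaves a
        stop at the same protein position.

        Plus strand: insert an A before the codon's third base (the first
        three bases still read TGA). Minus strand: insert an A between the
        first and second codon bases (the codon reads TAG — still a stop),
        chosen so left-alignment cannot shift the insertion out of the
        codon.
        """
        tx = gene.core
        last = tx.cds_length // 3 - 1
        if not self._interior_codon_ok(tx, last):
            return None
        if tx.strand == "+":
            g3 = tx.cds_to_genomic(last * 3 + 2)
            pos, ins = g3, "A"
        else:
            g1 = tx.cds_to_genomic(last * 3)  # genomic pos of codon base 1
            pos, ins = g1, "T"  # transcript 'A' between bases 1 and 2
        v = self._mk(pos, "", ins)
        if v is None:
            return None
        # the normalized insertion point must still be strictly inside the
        # CDS and within the stop codon
        inside = any(s < v.pos < e for s, e in tx.cds_intervals)
        cps = [
            c for p in (v.pos, v.pos - 1)
            if (c := tx.genomic_to_cds(p)) is not None
        ]
        if not inside or not cps or max(cps) < last * 3:
            return None
        return v, tx.transcript_id

    def _place_initiator_codon_snv(self, gene: GenePlan):
        tx = gene.core
        if not self._interior_codon_ok(tx, 0):
            return None
        v = self._snv_at_cds(tx, 0, "C")  # ATG -> CTG (Met -> Leu)
        return None if v is None else (v, tx.transcript_id)

    def _place_frameshift_indel(self, gene: GenePlan):
        """1-bp CDS deletion with no premature stop in the shifted frame."""
        tx = gene.core
        n = tx.cds_length // 3
        for idx in range(n - 2, max(n - 30, 2), -1):
            if not self._interior_codon_ok(tx, idx):
                continue
            g = tx.cds_to_genomic(idx * 3)
            ref = self.genome.fetch(CHROM, g, g + 1)
            v = normalize_variant(CHROM, g, ref, "", self.genome)
            premature, touches_stop = self._frameshift_profile(tx, v)
            if premature or touches_stop:
                continue
            cps = [tx.genomic_to_cds(p) for p in range(v.pos, v.end)]
            if any(c is None for c in cps):
                continue
            gv = tx.cds_to_genomic(min(cps))
            if self._exonic_junction_distance(tx, gv) < 6:
                continue
            if self._claim(v.pos, v.end):
                return v, tx.transcript_id
        return None

    def _place_stopgain_via_indel(self, gene: GenePlan):
        """1-bp CDS deletion whose shifted frame hits a premature stop."""
        tx = gene.core
        n = tx.cds_length // 3
        for idx in range(3, n - 6):
            if not self._interior_codon_ok(tx, idx):
                continue
            g = tx.cds_to_genomic(idx * 3)
            ref = self.genome.fetch(CHROM, g, g + 1)
            v = normalize_variant(CHROM, g, ref, "", self.genome)
            premature, touches_stop = self._frameshift_profile(tx, v)
            if not premature or touches_stop:
                continue
            cps = [tx.genomic_to_cds(p) for p in range(v.pos, v.end)]
            if any(c is None for c in cps):
                continue
            gv = tx.cds_to_genomic(min(cps))
            if self._exonic_junction_distance(tx, gv) < 6:
                continue
            if self._claim(v.pos, v.end):
                return v, tx.transcript_id
        return None

    def _place_inframe_indel(self, gene: GenePlan):
        """Codon-aligned 3-bp deletion away from junctions and termini."""
        tx = gene.core
        for idx in self._codon_indices(tx):
            if not self._interior_codon_ok(tx, idx, span_codons=1):
                continue
            gs = sorted(tx.cds_to_genomic(idx * 3 + k) for k in range(3))
            if gs[2] - gs[0] != 2:  # codon split by an intron
                continue
            g = gs[0]
            ref = self.genome.fetch(CHROM, g, g + 3)
            v = normalize_variant(CHROM, g, ref, "", self.genome)
            premature, touches_stop = self._frameshift_profile(tx, v)
            if premature or touches_stop:
                continue
            cps = [tx.genomic_to_cds(p) for p in range(v.pos, v.end)]
            if any(c is None for c in cps):
                continue
            gv = tx.cds_to_genomic(min(cps))
            if self._exonic_junction_distance(tx, gv) < 8:
                continue
            if self._claim(v.pos, v.end):
                return v, tx.transcript_id
        return None

    # splice-site classes: offsets measured with first intron base = 1
    def _intron_offset_pos(self, tx: TranscriptModel, intron_idx: int,
                           offset: int, from_five_prime: bool) -> int:
        istart, iend = tx.introns[intron_idx]
        five_left = tx.strand == "+"  # intron 5' end is its genomic left?
        take_left = five_left == from_five_prime
        return istart + offset - 1 if take_left else iend - offset

    def _place_splice_snv(self, gene: GenePlan, offset: int, five_prime: bool):
        tx = gene.core
        for ii in range(len(tx.introns)):
            pos = self._intron_offset_pos(tx, ii, offset, five_prime)
            ref = self.genome.fetch(CHROM, pos, pos + 1)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = self._mk(pos, ref, alt)
            if v is not None:
                return v, tx.transcript_id
        return None

    def _place_splice_donor_snv(self, gene: GenePlan):
        return self._place_splice_snv(gene, offset=1, five_prime=True)

    def _place_splice_acceptor_snv(self, gene: GenePlan):
        return self._place_splice_snv(gene, offset=1, five_prime=False)

    def _place_splice_region_snv(self, gene: GenePlan):
        # intronic offset 5: inside the broad a_style window (<=6) and the
        # v_style intronic splice region (3..8), outside donor/acceptor
        return self._place_splice_snv(gene, offset=5, five_prime=True)

    def _place_deep_intronic_snv(self, gene: GenePlan):
        tx = gene.core
        for istart, iend in tx.introns:
            mid = (istart + iend) // 2
            if mid - istart < 12 or iend - mid < 12:
                continue
            ref = self.genome.fetch(CHROM, mid, mid + 1)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = self._mk(mid, ref, alt)
            if v is not None:
                return v, tx.transcript_id
        return None

    def _utr_positions(self, tx: TranscriptModel, five_prime: bool) -> range:
        cds_start = tx.cds_intervals[0][0]
        cds_end = tx.cds_intervals[-1][1]
        left_is_5p = tx.strand == "+"
        if five_prime == left_is_5p:
            s, e = tx.exons[0][0], cds_start  # left outer exon portion
            return range(s + 2, e - 2)
        s, e = cds_end, tx.exons[-1][1]
        return range(s + 2, e - 2)

    def _place_utr_snv(self, gene: GenePlan, five_prime: bool):
        tx = gene.core
        for pos in self._utr_positions(tx, five_prime):
            if self._exonic_junction_distance(tx, pos) < 5:
                continue
            ref = self.genome.fetch(CHROM, pos, pos + 1)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = self._mk(pos, ref, alt)
            if v is not None:
                return v, tx.transcript_id
        return None

    def _place_utr5_snv(self, gene: GenePlan):
        return self._place_utr_snv(gene, five_prime=True)

    def _place_utr3_snv(self, gene: GenePlan):
        return self._place_utr_snv(gene, five_prime=False)

    def _place_ncrna_exonic_snv(self, gene: GenePlan):
        tx = gene.core
        for s, e in tx.exons:
            for pos in range(s + 5, e - 5, 7):
                if self._exonic_junction_distance(tx, pos) < 5:
                    continue
                ref = self.genome.fetch(CHROM, pos, pos + 1)
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                v = self._mk(pos, ref, alt)
                if v is not None:
                    return v, tx.transcript_id
        return None

    def _flank_pos(self, gene: GenePlan, upstream: bool) -> int:
        tx = gene.core
        lo = min(t.start for t in gene.isoforms)
        hi = max(t.end for t in gene.isoforms)
        left = (tx.strand == "+") == upstream
        return lo - 200 if left else hi + 199

    def _place_upstream_snv(self, gene: GenePlan):
        pos = self._flank_pos(gene, upstream=True)
        ref = self.genome.fetch(CHROM, pos, pos + 1)
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        v = self._mk(pos, ref, alt)
        return None if v is None else (v, gene.core.transcript_id)

    def _place_downstream_snv(self, gene: GenePlan):
        pos = self._flank_pos(gene, upstream=False)
        ref = self.genome.fetch(CHROM, pos, pos + 1)
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        v = self._mk(pos, ref, alt)
        return None if v is None else (v, gene.core.transcript_id)

    def _place_intergenic_snv(self, gene=None):
        if not hasattr(self, "_intergenic_iter"):
            spans = sorted(
                (min(t.start for t in g.isoforms), max(t.end for t in g.isoforms))
                for g in self.genes
            )
            margin = 1050  # flank_bp + margin
            gaps = []
            prev = 0
            for s, e in spans:
                if s - margin > prev + margin:
                    gaps.append((prev + margin, s - margin))
                prev = max(prev, e)
            glen = len(self.genome[CHROM])
            if glen - margin > prev + margin:
                gaps.append((prev + margin, glen - margin))
            self._intergenic_iter = iter(
                pos for lo, hi in gaps for pos in range(lo, hi, 37)
            )
        for pos in self._intergenic_iter:
            ref = self.genome.fetch(CHROM, pos, pos + 1)
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            v = self._mk(pos, ref, alt)
            if v is not None:
                return v, None
        return None


def simulate_variants(
    genome: GenomeSequence,
    genes: list[GenePlan],
    config: SimulationConfig,
) -> tuple[list[Variant], list[TruthRecord]]:
    """Place the configured class mix; every variant gets a TruthRecord."""
    rng = np.random.default_rng(config.seed + 1)
    placer = _Placer(genome, genes, config, rng)
    variants: list[Variant] = []
    truth: list[TruthRecord] = []
    for designed_class in EXPECTED_TERMS:  # fixed class order
        count = config.variant_class_mix.get(designed_class, 0)
        for _ in range(count):
            v, tid = placer.place(designed_class)
            variants.append(v)
            truth.append(
                TruthRecord(
                    variant=v,
                    designed_class=designed_class,
                    transcript_id=tid,
                    expected=dict(EXPECTED_TERMS[designed_class]),
                )
            )
    order = np.argsort([v.pos for v in variants], kind="stable")
    return [variants[i] for i in order], [truth[i] for i in order]


def simulate_study(config: SimulationConfig):
    """Genome, sets A/B, variants and truth in one call."""
    genome, set_a, set_b, genes = simulate_genome_and_transcripts(config)
    variants, truth = simulate_variants(genome, genes, config)
    return genome, set_a, set_b, genes, variants, truth


# ---------------------------------------------------------------------------
# Discordance scenario
# ---------------------------------------------------------------------------

@dataclass
class DiscordanceScenario:
    """A paired-run fixture with closed-form expected concordance.

    ``n_shared`` missense SNVs sit in genes present in both sets (both runs
    report missense); ``n_b_only`` missense SNVs sit in the CDS of
    B-only genes (set A reports intergenic, set B missense). The expected
    overall exonic match rate is therefore exactly
    ``100 * n_shared / (n_shared + n_b_only)``.
    """

    genome: GenomeSequence
    set_a: TranscriptSet
    set_b: TranscriptSet
    variants: list[Variant]
    b_only_keys: set[str]
    n_shared: int
    n_b_only: int

    @property
    def expected_exonic_overall_rate(self) -> float:
        total = self.n_shared + self.n_b_only
        return 100.0 * self.n_shared / total if total else float("nan")


def make_discordance_scenario(
    config: SimulationConfig | None = None,
    n_shared: int = 30,
    n_b_only: int = 10,
) -> DiscordanceScenario:
    """Build the transcript-set-asymmetry fixture.

    Requires ``extra_transcript_fraction > 0`` so B-only genes exist.
    """
    if config is None:
        config = SimulationConfig()
    if config.extra_transcript_fraction <= 0:
        raise SimulationError("discordance scenario needs extra_transcript_fraction > 0")
    genome, set_a, set_b, genes = simulate_genome_and_transcripts(config)
    rng = np.random.default_rng(config.seed + 2)
    placer = _Placer(genome, genes, config, rng)
    shared_pool = [g for g in genes if g.coding and g.membership == "shared"]
    b_only_pool = [g for g in genes if g.coding and g.membership == "b_only"]
    if not b_only_pool:
        raise SimulationError("no B-only genes were generated")
    variants: list[Variant] = []
    b_only_keys: set[str] = set()
    for i in range(n_shared):
        got = None
        for gene in shared_pool[i % len(shared_pool):] + shared_pool[: i % len(shared_pool)]:
            got = placer._place_missense_snv(gene)
            if got is not None:
                break
        if got is None:
            raise SimulationError("could not place shared missense variant")
        variants.append(got[0])
    for i in range(n_b_only):
        got = None
        for gene in b_only_pool[i % len(b_only_pool):] + b_only_pool[: i % len(b_only_pool)]:
            got = placer._place_missense_snv(gene)
            if got is not None:
                break
        if got is None:
            raise SimulationError("could not place B-only missense variant")
        variants.append(got[0])
        b_only_keys.add(got[0].key)
    return DiscordanceScenario(
        genome=genome,
        set_a=set_a,
        set_b=set_b,
        variants=variants,
        b_only_keys=b_only_keys,
        n_shared=n_shared,
        n_b_only=n_b_only,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_vcf(variants: list[Variant], genome: GenomeSequence, path: str) -> None:
    """Write normalized variants as VCF 4.2 with anchor-base indel encoding."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.lengths().items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            if v.var_class in ("SNV", "block_substitution"):
                pos1, ref, alt = v.pos + 1, v.ref, v.alt
            else:
                anchor = genome.fetch(v.chrom, v.pos - 1, v.pos)
                pos1 = v.pos  # 1-based position of the anchor base
                ref = anchor + v.ref
                alt = anchor + v.alt
            fh.write(f"{v.chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_truth(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant_key\tdesigned_class\ttranscript_id\t"
            "expected_a_style\texpected_v_style\n"
        )
        for t in truth:
            fh.write(
                f"{t.variant_key}\t{t.designed_class}\t{t.transcript_id or '-'}\t"
                f"{t.expected['a_style']}\t{t.expected['v_style']}\n"
            )
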