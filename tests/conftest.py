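"""Shared fixtures: a seeded synthetic study, default configs, and small
hand-built transcripts with known structure (including the two worked
stop-codon cases: a stop-loss SNV and a stop-retained single-base
insertion in a terminal TGA)."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from varconcord.consequence_engine import Regime
from varconcord.genome_model import GenomeSequence, TranscriptModel, TranscriptSet
from varconcord.harmonization import load_category_map
from varconcord.severity_rules import load_ranking
from varconcord.synthetic_data import SimulationConfig, simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: genome, sets A/B, designed variants, truth."""
    genome, set_a, set_b, genes, variants, truth = simulate_study(
        SimulationConfig(seed=STUDY_SEED)
    )
    return {
        "genome": genome,
        "set_a": set_a,
        "set_b": set_b,
        "genes": genes,
        "variants": variants,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def rankings():
    return {
        "a_style": load_ranking(vocabulary="a_style"),
        "v_style": load_ranking(vocabulary="v_style"),
    }


@pytest.fixture(scope="session")
def regimes():
    return {"a_style": Regime.a_style(), "v_style": Regime.v_style()}


@pytest.fixture(scope="session")
def category_map():
    return load_category_map()


# ---------------------------------------------------------------------------
# Hand-built single-exon coding transcript ending ...TGA (both strands)
# ---------------------------------------------------------------------------

# 3 bp 5'UTR + 7 codons (ATG .. TGA) + 5 bp 3'UTR
_PLUS_SEQ = "GGG" + "ATGAAACCCGGGTTTCTT" + "TGA" + "ACGTA"


@pytest.fixture(scope="session")
def stop_fixture_plus():
    genome = GenomeSequence({"chrP": _PLUS_SEQ})
    tx = TranscriptModel(
        transcript_id="TXP",
        gene_id="GP",
        chrom="chrP",
        strand="+",
        exons=[(0, len(_PLUS_SEQ))],
        cds_intervals=[(3, 24)],  # stop codon TGA at [21, 24)
    )
    return genome, tx, TranscriptSet("plus", [tx])


@pytest.fixture(scope="session")
def stop_fixture_minus():
    seq = str(Seq(_PLUS_SEQ).reverse_complement())
    n = len(seq)
    genome = GenomeSequence({"chrM": seq})
    tx = TranscriptModel(
        transcript_id="TXM",
        gene_id="GM",
        chrom="chrM",
        strand="-",
        exons=[(0, n)],
        cds_intervals=[(n - 24, n - 3)],
    )
    return genome, tx, TranscriptSet("minus", [tx])


# ---------------------------------------------------------------------------
# Three-exon transcript for exhaustive splice-window scans
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def splice_fixture():
    """Noncoding 3-exon transcripts (one per strand) on a 120 bp genome."""
    seq = ("ACGT" * 30)[:120]
    genome = GenomeSequence({"chrS": seq})
    exons = [(10, 30), (40, 60), (70, 90)]
    txs = {
        strand: TranscriptModel(
            transcript_id=f"TXS{strand}",
            gene_id="GS",
            chrom="chrS",
            strand=strand,
            exons=exons,
        )
        for strand in "+-"
    }
    return genome, txs


# ---------------------------------------------------------------------------
# Independent CDS-rebuild oracle (chromosome-level edit + coordinate lift)
# ---------------------------------------------------------------------------

def oracle_proteins(variant, tx, genome):
    """(ref_protein, alt_protein, cds_delta) by an independent route.

    Applies the variant to the whole chromosome, lifts the CDS interval
    boundaries over the edit, re-extracts and translates. Both proteins are
    truncated at (and include) their first stop.
    """
    chrom = genome[tx.chrom]
    alt_chrom = chrom[: variant.pos] + variant.alt + chrom[variant.end :]
    delta = len(variant.alt) - len(variant.ref)
    m = len(variant.alt)

    if variant.var_class == "insertion":
        def lift_start(p):
            return p + delta if p >= variant.pos else p

        def lift_end(p):
            return p + delta if p > variant.pos else p
    else:
        def lift_start(p):
            if p <= variant.pos:
                return p
            if p >= variant.end:
                return p + delta
            return variant.pos + m

        def lift_end(p):
            if p <= variant.pos:
                return p
            if p >= variant.end:
                return p + delta
            return variant.pos

    def splice(seq, intervals):
        s = "".join(seq[a:b] for a, b in intervals)
        return str(Seq(s).reverse_complement()) if tx.strand == "-" else s

    ref_cds = splice(chrom, tx.cds_intervals)
    alt_cds = splice(
        alt_chrom, [(lift_start(s), lift_end(e)) for s, e in tx.cds_intervals]
    )

    def protein(cds):
        p = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        i = p.find("*")
        return p if i < 0 else p[: i + 1]

    return protein(ref_cds), protein(alt_cds), len(alt_cds) - len(ref_cds)
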