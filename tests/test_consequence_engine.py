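"""Consequence classification: the worked stop-codon cases, exhaustive
splice-window scans against independent distance arithmetic, strand
symmetry, the indel stop-scan toggle, and protein-level oracle agreement."""

import pytest

from varconcord.consequence_engine import (
    Regime,
    annotate,
    classify_coding,
    classify_splicing,
    locate,
    transcript_calls,
)
from varconcord.genome_model import (
    GenomeSequence,
    TranscriptModel,
    TranscriptSet,
    Variant,
    normalize_variant,
)
from varconcord.severity_rules import load_ranking
from tests.conftest import oracle_proteins


class TestWorkedStopCodonCases:
    """A stop-codon SNV TGA->TGG is unambiguously stop-loss; a single-base
    insertion that leaves the terminal codon reading TGA is synonymous /
    stop-retained — not frameshift and not stop-loss."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("regime_name", ["a_style", "v_style"])
    def test_stop_loss_snv(self, strand, regime_name, regimes,
                           stop_fixture_plus, stop_fixture_minus):
        genome, tx, _ = stop_fixture_plus if strand == "+" else stop_fixture_minus
        g = tx.cds_to_genomic(tx.cds_length - 1)  # third base of the TGA
        ref = genome.fetch(tx.chrom, g, g + 1)
        alt = "G" if strand == "+" else "C"  # transcript A->G
        v = Variant(tx.chrom, g, ref, alt)
        call = classify_coding(v, tx, genome, regimes[regime_name])
        expected = "stoploss_SNV" if regime_name == "a_style" else "stop_lost"
        assert call.term == expected
        if strand == "+":
            assert (call.detail["ref_codon"], call.detail["alt_codon"]) == (
                "TGA", "TGG",
            )

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("regime_name", ["a_style", "v_style"])
    def test_stop_retained_insertion(self, strand, regime_name, regimes,
                                     stop_fixture_plus, stop_fixture_minus):
        genome, tx, _ = stop_fixture_plus if strand == "+" else stop_fixture_minus
        if strand == "+":
            # insert A before the codon's third base: TG[A]A reads TGA
            pos, ins = tx.cds_to_genomic(tx.cds_length - 1), "A"
        else:
            # insert transcript-A between bases 1 and 2: T[A]GA reads TAG
            pos, ins = tx.cds_to_genomic(tx.cds_length - 3), "T"
        v = normalize_variant(tx.chrom, pos, "", ins, genome)
        call = classify_coding(v, tx, genome, regimes[regime_name])
        expected = (
            "synonymous_SNV" if regime_name == "a_style" else "stop_retained_variant"
        )
        assert call.term == expected
        assert "frameshift" not in call.term
        assert "loss" not in call.term and "lost" not in call.term


class TestLocate:
    def test_intronic_and_flanks(self, splice_fixture):
        genome, txs = splice_fixture
        tx = txs["+"]
        snv = lambda p: Variant("chrS", p, genome.fetch("chrS", p, p + 1),
                                "A" if genome.fetch("chrS", p, p + 1) != "A" else "C")
        assert locate(snv(35), tx) == "nc_intronic"
        assert locate(snv(5), tx, flank_bp=1000) == "upstream"
        assert locate(snv(95), tx, flank_bp=1000) == "downstream"
        assert locate(snv(95), txs["-"], flank_bp=1000) == "upstream"
        assert locate(snv(95), tx, flank_bp=3) == "outside"

    def test_utr_labels_flip_with_strand(self):
        seq = "A" * 100
        genome = GenomeSequence({"c": seq})
        mk = lambda strand: TranscriptModel(
            "t" + strand, "g", "c", strand, [(10, 40), (60, 90)], [(20, 40), (60, 80)]
        )
        v = Variant("c", 15, "A", "G")  # exonic, before the CDS genomically
        assert locate(v, mk("+")) == "utr5"
        assert locate(v, mk("-")) == "utr3"
        v2 = Variant("c", 85, "A", "G")
        assert locate(v2, mk("+")) == "utr3"
        assert locate(v2, mk("-")) == "utr5"


class TestSpliceClassification:
    @staticmethod
    def _expected_terms(tx, pos, regime):
        """Independent distance arithmetic over all introns."""
        hits = set()
        for istart, iend in tx.introns:
            d_left = pos - istart + 1 if istart <= pos < iend else None
            d_right = iend - pos if istart <= pos < iend else None
            if regime.vocabulary == "a_style":
                if d_left is not None and (
                    d_left <= regime.splicing_window_bp
                    or d_right <= regime.splicing_window_bp
                ):
                    hits.add("splicing")
                continue
            five_is_left = tx.strand == "+"
            if d_left is not None:
                d5 = d_left if five_is_left else d_right
                d3 = d_right if five_is_left else d_left
                if d5 <= 2:
                    hits.add("splice_donor_variant")
                if d3 <= 2:
                    hits.add("splice_acceptor_variant")
                if 3 <= d_left <= 8 or 3 <= d_right <= 8:
                    hits.add("splice_region_variant")
            else:  # exonic distances: 1 = base adjacent to the junction
                for s, e in tx.exons:
                    if not s <= pos < e:
                        continue
                    if e == istart and 1 <= istart - pos <= 3:
                        hits.add("splice_region_variant")
                    if s == iend and 1 <= pos - iend + 1 <= 3:
                        hits.add("splice_region_variant")
        return hits

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("regime_name", ["a_style", "v_style"])
    def test_exhaustive_position_scan(self, strand, regime_name, regimes,
                                      splice_fixture):
        """Every genomic position of a 3-exon transcript classifies exactly
        as brute-force distance arithmetic says it should."""
        genome, txs = splice_fixture
        tx, regime = txs[strand], regimes[regime_name]
        for pos in range(tx.start, tx.end):
            ref = genome.fetch("chrS", pos, pos + 1)
            alt = "A" if ref != "A" else "C"
            v = Variant("chrS", pos, ref, alt)
            got = set(classify_splicing(v, tx, regime))
            assert got == self._expected_terms(tx, pos, regime), (
                f"pos={pos} strand={strand} regime={regime_name}"
            )

    def test_donor_at_first_intron_base_plus_strand(self, splice_fixture, regimes):
        genome, txs = splice_fixture
        v = Variant("chrS", 30, genome.fetch("chrS", 30, 31), "A"
                    if genome.fetch("chrS", 30, 31) != "A" else "C")
        assert classify_splicing(v, txs["+"], regimes["v_style"]) == [
            "splice_donor_variant"
        ]
        assert classify_splicing(v, txs["+"], regimes["a_style"]) == ["splicing"]

    def test_single_exon_transcript_has_no_splice_sites(self, stop_fixture_plus,
                                                        regimes):
        genome, tx, _ = stop_fixture_plus
        v = Variant("chrP", 10, genome.fetch("chrP", 10, 11), "T"
                    if genome.fetch("chrP", 10, 11) != "T" else "G")
        assert classify_splicing(v, tx, regimes["v_style"]) == []

    def test_window_size_is_configurable(self, splice_fixture):
        genome, txs = splice_fixture
        tx = txs["+"]
        pos = 30 + 3  # 4th intron base: 4 bp from one junction, 7 the other
        ref = genome.fetch("chrS", pos, pos + 1)
        v = Variant("chrS", pos, ref, "A" if ref != "A" else "C")
        assert classify_splicing(v, tx, Regime.a_style(splicing_window_bp=2)) == []
        assert classify_splicing(v, tx, Regime.a_style()) == ["splicing"]


class TestStopScanToggle:
    def test_frameshifting_deletion_with_premature_stop(self, study, regimes):
        """With the stop-scan on, an indel that introduces a premature stop
        is reported stop-gain; with it off, frameshift."""
        genome, set_a = study["genome"], study["set_a"]
        cases = [
            t for t in study["truth"] if t.designed_class == "stopgain_via_indel"
        ]
        assert cases
        for t in cases:
            tx = set_a[t.transcript_id]
            on = classify_coding(t.variant, tx, genome, Regime.a_style())
            off = classify_coding(
                t.variant, tx, genome, Regime.a_style(stop_scan_indels=False)
            )
            assert on.term == "stopgain_SNV"
            assert off.term == "frameshift_deletion"


class TestAnnotateAggregation:
    def test_intergenic_when_nothing_in_range(self, stop_fixture_plus, regimes,
                                              rankings):
        genome = GenomeSequence({"chrP": "A" * 5000})
        tx = TranscriptModel("t", "g", "chrP", "+", [(0, 30)], [(3, 24)])
        tset = TranscriptSet("s", [tx])
        v = Variant("chrP", 4000, "A", "G")
        (call,) = annotate(v, tset, genome, regimes["a_style"], rankings["a_style"])
        assert call.term == "intergenic" and call.transcript_id is None

    def test_most_severe_across_transcripts(self, regimes, rankings):
        """A variant missense in one transcript and synonymous in another
        reports the missense call under most-severe-only."""
        # two overlapping single-exon transcripts whose reading frames
        # differ by one base; both have a clean ATG..TGA CDS
        seq = "ATGCATGCACTGCTTTCCTGAATGA" + "GGGGG"
        genome = GenomeSequence({"c": seq})
        t1 = TranscriptModel("t1", "g1", "c", "+", [(0, 30)], [(0, 21)])
        t2 = TranscriptModel("t2", "g2", "c", "+", [(0, 30)], [(4, 25)])
        tset = TranscriptSet("s", [t1, t2])
        # pos 15 T->C: t1 codon TCC->CCC (Ser->Pro, missense),
        #              t2 codon TTT->TTC (Phe->Phe, synonymous)
        v = Variant("c", 15, "T", "C")
        a = Regime.a_style()
        assert classify_coding(v, t1, genome, a).term == "nonsynonymous_SNV"
        assert classify_coding(v, t2, genome, a).term == "synonymous_SNV"
        (best,) = annotate(v, tset, genome, a, rankings["a_style"])
        assert (best.term, best.transcript_id) == ("nonsynonymous_SNV", "t1")
        calls = annotate(
            v, tset, genome, Regime.a_style(report_policy="all_then_prioritise"),
            rankings["a_style"],
        )
        assert {c.term for c in calls} == {"nonsynonymous_SNV", "synonymous_SNV"}
        assert [c.term for c in calls if c.primary] == ["nonsynonymous_SNV"]

    def test_superset_reports_at_least_as_severe(self, study, regimes, rankings):
        """Annotating against the larger set B never yields a less severe
        report than set A (the transcript-set asymmetry mechanism)."""
        genome = study["genome"]
        rank = rankings["a_style"]
        regime = regimes["a_style"]
        for t in study["truth"][::5]:
            (a,) = annotate(t.variant, study["set_a"], genome, regime, rank)
            (b,) = annotate(t.variant, study["set_b"], genome, regime, rank)
            assert rank.rank(b.term) <= rank.rank(a.term)


class TestCodingOracleAgreement:
    def test_engine_terms_consistent_with_protein_comparison(self, study,
                                                             regimes):
        """For every designed coding variant, the engine's term agrees with
        an independent chromosome-level rebuild-and-translate oracle."""
        genome, set_a = study["genome"], study["set_a"]
        coding_classes = {
            "stop_loss_snv", "stop_retained_insertion", "stop_gain_snv",
            "frameshift_indel", "stopgain_via_indel", "inframe_indel",
            "missense_snv", "synonymous_snv", "initiator_codon_snv",
        }
        n_checked = 0
        for t in study["truth"]:
            if t.designed_class not in coding_classes:
                continue
            tx = set_a[t.transcript_id]
            ref_p, alt_p, cds_delta = oracle_proteins(t.variant, tx, genome)
            for name, regime in regimes.items():
                term = classify_coding(t.variant, tx, genome, regime).term
                if term in ("synonymous_SNV", "synonymous_variant",
                            "stop_retained_variant"):
                    assert alt_p == ref_p
                elif term in ("nonsynonymous_SNV", "missense_variant",
                              "initiator_codon_variant"):
                    assert len(alt_p) == len(ref_p) and alt_p != ref_p
                    assert alt_p.endswith("*") == ref_p.endswith("*")
                elif term in ("stopgain_SNV", "stop_gained"):
                    assert alt_p.endswith("*")
                    assert 3 * (len(alt_p) - 1) < 3 * (len(ref_p) - 1) + cds_delta
                elif term in ("stoploss_SNV", "stop_lost"):
                    assert not alt_p.endswith("*") or len(alt_p) > len(ref_p)
                elif term in ("nonframeshift_deletion", "inframe_deletion",
                              "nonframeshift_insertion", "inframe_insertion"):
                    assert cds_delta % 3 == 0 and cds_delta != 0
                    assert alt_p != ref_p
                elif term in ("frameshift_insertion", "frameshift_deletion",
                              "frameshift_substitution", "frameshift_variant"):
                    assert cds_delta % 3 != 0
                else:  # pragma: no cover - unexpected term fails loudly
                    raise AssertionError(f"unexpected coding term {term}")
            n_checked += 1
        assert n_checked >= 100


class TestSnvNeverFrameshift:
    def test_no_snv_receives_a_frameshift_term(self, study, regimes, rankings):
        """SNVs must never be called frameshift, in any transcript call of
        either regime (the negative invariant)."""
        from dataclasses import replace

        genome = study["genome"]
        for t in study["truth"]:
            if t.variant.var_class != "SNV":
                continue
            for name, regime in regimes.items():
                # inspect every per-transcript call, not just the report
                all_calls = replace(regime, report_policy="all_then_prioritise")
                for tset in (study["set_a"], study["set_b"]):
                    calls = annotate(t.variant, tset, genome, all_calls,
                                     rankings[name])
                    assert all("frameshift" not in c.term for c in calls)
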