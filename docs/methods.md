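# Methods

## Coordinate and representation conventions

All internal coordinates are 0-based half-open on the forward strand of
the reference; GTF (1-based inclusive) and VCF (1-based, anchor-base indel
encoding) are converted at the I/O boundary. Variants are reduced to a
minimal representation — shared prefix/suffix trimmed — and pure indels
are left-aligned against the genome before any classification, so the
consequence of a variant never depends on the VCF dialect it arrived in.
An insertion with normalized position *p* goes immediately before base
*p*; for interval arithmetic it binds to the right base, and it is
considered to alter the CDS only when its insertion point is strictly
inside a CDS interval (a boundary insertion belongs to the flanking
UTR or intron).

## Consequence classification

A `Regime` bundles the definitional choices that differ between annotation
tools. Classification of a (variant, transcript) pair proceeds in three
layers:

1. **Location** (`locate`): interval arithmetic on the exon/CDS structure
   with strand-aware 5′/3′ labelling (UTR5 vs UTR3, upstream vs
   downstream). An indel spanning a boundary takes the highest-priority
   overlapped class (CDS > UTR > intron). Upstream/downstream flanks
   default to 1000 bp (`flank_bp`, configurable); nothing in range means
   intergenic.

2. **Splicing** (`classify_splicing`). Under `a_style` a single `splicing`
   term fires for any variant within `splicing_window_bp` (default 6)
   intronic bases of a junction. The window is interpreted as intronic
   positions only: the phrase "within *x* bases of an intron/exon
   boundary" is ambiguous about the exonic side, so the choice is exposed
   as `window_side ∈ {intronic_only, both}` with `intronic_only` the
   default (near-junction exonic SNVs then receive their exonic
   consequence). Under `v_style` the donor is the first two intronic bases
   at the intron's 5′ end (strand-aware), the acceptor the last two at the
   3′ end, and the splice region is exonic distance 1–3 or intronic
   distance 3–8 from a junction (distance 1 = adjacent base). Splice hits
   on non-coding transcripts are reported as non-coding splice terms.
   Single-exon transcripts have no splice sites.

3. **Coding** (`classify_coding`): the spliced CDS is rebuilt
   (reverse-complemented for − strand), the variant applied
   (deletions/substitutions intersected with the CDS; bases outside it are
   ignored), and both translations compared after truncation at their
   first stop codon. The decision order is:

   * identical proteins → synonymous, or stop-retained when the edit
     overlaps the terminal stop codon (`stop_retained_detection`, on by
     default in both regimes). This check precedes everything else, which
     is what keeps a stop-codon insertion that leaves the codon reading
     TGA from being called frameshift or stop-loss.
   * CDS length change ≢ 0 (mod 3) → frameshift — unless
     `stop_scan_indels` is on and the shifted frame contains a stop
     strictly before where the original stop maps to (→ stop-gain;
     `a_style` default), or, under `a_style`, the edit destroys the stop
     codon (→ stop-loss, mirroring the tool behaviour that `v_style`
     reports as frameshift).
   * in-frame changes → stop-gain / stop-loss / initiator-codon /
     missense / synonymous by codon comparison for SNVs; in-frame
     insertion/deletion for length-preserving-frame indels; an in-frame
     block substitution is `nonframeshift_substitution` (`a_style`) or
     `coding_sequence_variant` ("other coding", `v_style`) — the latter
     has deliberately no exact `a_style` equivalent.

   "Premature stop" is defined relative to the original terminal stop
   lifted through the edit (`3·ref_stop_index + cds_delta` when the edit
   lies 5′ of the stop), so an in-frame deletion that merely shortens the
   protein is not mistaken for a stop-gain. Codons containing N, and
   transcripts whose CDS length is not a multiple of 3
   (`cds_incomplete`), yield `unknown` / low-confidence calls rather than
   crashes.

Per variant, calls from all overlapping transcripts (plus flanking
upstream/downstream calls) are pooled and the severity ranking selects the
report (`most_severe_only`), or all calls are returned with the primary
marked (`all_then_prioritise`). Ties break by lexicographic transcript id,
making every report deterministic.

## Severity and harmonization

Rankings are validated total orders over a vocabulary, loaded from YAML.
The orderings the package commits to are the category blocks — every LoF
term above every missense-level term, above synonymous-level, above
non-exonic — plus stop-gain above frameshift; order *within* a block is a
convention, and any permutation respecting the blocks validates. The
`a_style` label set matches the classic summary-table row names, including
combined labels (`UTR5_UTR3`, `upstream_downstream`, the `ncRNA_UTR*`
family) that the engine itself never emits but that reports and validation
must be able to carry.

The category map assigns every term of both vocabularies to exactly one
high-level category. The exact-equivalence map is constrained by
construction: a pair may only be declared equivalent if both terms share a
category, which is what guarantees *exact ⇒ category* over the full
cross-product. Two consequences follow: the broad `splicing` term is
exact-equivalent to splice donor/acceptor only (splice region being
missense-level), and the three `v_style`-only exonic terms are structural
zeros against `a_style`. The ncRNA-splicing equivalence is a convention
and can be disabled. `unknown` matches nothing, not even itself.

## Concordance statistics

Comparison records are a full outer join on the normalized variant key; a
variant annotated in only one run carries an explicit `absent` marker and
participates in union counts but not in the cross-tabulation. Fine-term
rows use term identity (same vocabulary) or exact equivalence (cross
vocabulary) as the match; rollup rows (ALL_LOF, ALL_LOF_AND_MISSENSE,
ALL_EXONIC, ALL) use the category-level intersection for the union
identity and report exact and category matches side by side. Rates with a
zero denominator print as `-`. Printed percentages are half-up rounded to
two decimals; `report.json` keeps full precision, so rounding is purely
presentational.

Matrix normalization is log10(count+1) followed by per-row or per-column
z-scaling. The standard deviation uses the population formula (divide by
*n*); the source tables do not say which convention they used, and the
choice is documented here and pinned by tests. Axes that are constant
after the log transform map to all zeros; constancy is detected with a
relative tolerance of 1e-12 because the floating-point standard deviation
of identical values is not exactly zero.

The shipped `table1_fixture.tsv` / `table2_fixture.tsv` transcribe
published summary tables of ~81 M-variant annotation comparisons;
`validate_fixture_tables` recomputes every union and rate cell from the
count columns alone. One quirk is preserved: rollup rows satisfy
union = a + b − match mechanically, except a row where both runs annotate
the entire variant universe, whose printed union equals both run counts;
the validator accepts exactly that case.

## Synthetic data: what it emulates, and what it does not

The generator builds non-overlapping genes left to right with fixed
intergenic gaps (2.6 kb — wide enough that a designed intergenic or flank
variant cannot fall inside another gene's 1 kb flank). Isoforms of one
gene share the exon/CDS skeleton and differ only in UTR extension, so a
designed variant has the same consequence in every isoform of its host
gene and truth is well-defined under most-severe reporting. Every coding
transcript gets an ATG start, a TGA terminal stop, no internal stop, and a
CDS length divisible by three. Set B is a strict superset of set A by
default (`extra_transcript_fraction` = 0.15 of genes are B-only); a
non-zero `a_only_fraction` makes neither set a subset of the other, for
tests that need that shape. Defaults: 40 genes on a 400 kb chromosome,
1–3 isoforms per gene, 2–4 exons of 90–210 bp, introns of 80–300 bp, 15%
non-coding genes.

Variants are placed by deterministic scan: candidate positions are tried
in a fixed order and the first feasible one wins, so a seed fully
determines every output byte. Feasibility (e.g. "this 1-bp deletion must
not create a premature stop", "this synonymous wobble position is ≥4
exonic bases from a junction") is checked with plain translation
arithmetic local to the generator — deliberately not by calling the
consequence engine — so the 100% truth-recovery test is a genuine
cross-check of two independent implementations. The default mix covers 19
designed classes (~228 variants): the 16 core classes from stop-loss SNV
through stop-gain-via-indel, plus ncRNA-exonic, upstream and downstream.
Stop-retained insertions duplicate the stop codon's third base on the +
strand; on the − strand that construction always left-aligns out of the
codon, so there the insertion goes between codon bases 1 and 2 (TGA →
TAG, still a stop at the same position).

What the generator does **not** emulate: overlapping or nested genes
(multi-gene overlap is excluded from truth-bearing fixtures and covered
only by crash-free behaviour), realistic human exon/intron length
statistics, mutation-rate or allele-frequency structure, N bases (handled
by separate unit tests), and sequencing or calling error. Passing the
truth-recovery suite therefore demonstrates correctness of the
classification rules on clean, unambiguous gene models — not robustness
to the pathological transcript structures of a real annotation catalogue.

The discordance scenario places 30 missense SNVs in shared genes and 10
in B-only genes (intergenic under A), giving a closed-form expected
exonic overall match rate of 100·30/40 = 75.0% and a strict LoF+missense
excess under B.

## Problem sizes and runtime

The default study (400 kb genome, ~80 transcripts, 228 variants) is sized
so that the full test suite — including annotating every variant under
both regimes and both transcript sets, the exhaustive per-position splice
scans, and the hypothesis property tests — completes in a few seconds,
and `scripts/acceptance.py` in well under a minute. These sizes are the
package's chosen study conditions, not tuned quantities; the engine
streams per variant and has no global state, so larger inputs scale
linearly.

## Known limitations

* Fidelity to any specific real tool's corner-case behaviour is
  explicitly not claimed; the regimes implement the *definitions*, and
  documented tool bugs (such as SNVs labelled frameshift) are excluded by
  invariant rather than reproduced.
* Combined location labels (`UTR5_UTR3`, `upstream_downstream`) are never
  emitted: the engine reports one consequence per variant per run.
* Variants spanning a junction receive best-effort calls (`a_style`:
  splicing unless the protein is provably unchanged; `v_style`: both
  splice and coding calls, severity resolves); phase between nearby
  variants is not used; no NMD prediction or protein-impact scoring.
* `two_regimes` comparisons key fine-term rows by the `a_style` term, so
  the three `frameshift_*` rows each compare against the single
  `frameshift_variant` term on the other side.
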