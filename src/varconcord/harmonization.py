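"""Harmonization of the two consequence vocabularies.

Maps every term of each vocabulary onto one of the high-level categories
(LOF, MISSENSE, SYNONYMOUS_OTHER, UTR, NCRNA, INTRONIC, INTERGENIC_FLANK,
UNKNOWN) and decides whether two calls from different runs are an *exact*
match (cross-vocabulary equivalent terms), a *category* match (same
high-level category) or a mismatch. Exact implies category by construction:
the loader rejects an equivalence pair whose two terms sit in different
categories.
"""

from __future__ import annotations

from importlib import resources

import yaml

from varconcord import vocabulary as vocab


class HarmonizationError(ValueError):
    pass


class CategoryMap:
    """Per-vocabulary term -> category map plus cross-vocabulary equivalence."""

    def __init__(
        self,
        categories: dict[str, dict[str, str]],
        equivalence: list[tuple[str, str]],
        nc_splicing_pairs: list[tuple[str, str]] | None = None,
        nc_splicing_equivalent: bool = True,
    ):
        for voc in (vocab.A_STYLE, vocab.V_STYLE):
            if voc not in categories:
                raise HarmonizationError(f"missing category map for {voc}")
            terms = set(vocab.TERMS[voc])
            mapped = set(categories[voc])
            if mapped != terms:
                missing = terms - mapped
                extra = mapped - terms
                raise HarmonizationError(
                    f"{voc} category map mismatch: missing={sorted(missing)} "
                    f"extra={sorted(extra)}"
                )
            for term, cat in categories[voc].items():
                if cat not in vocab.CATEGORIES:
                    raise HarmonizationError(
                        f"unknown category {cat!r} for term {term!r}"
                    )
        self._categories = categories
        pairs = list(equivalence)
        if nc_splicing_equivalent and nc_splicing_pairs:
            pairs += list(nc_splicing_pairs)
        self._pairs: set[tuple[str, str]] = set()
        for a_term, v_term in pairs:
            if a_term not in categories[vocab.A_STYLE]:
                raise HarmonizationError(f"equivalence names unknown a_style term {a_term!r}")
            if v_term not in categories[vocab.V_STYLE]:
                raise HarmonizationError(f"equivalence names unknown v_style term {v_term!r}")
            if categories[vocab.A_STYLE][a_term] != categories[vocab.V_STYLE][v_term]:
                raise HarmonizationError(
                    f"equivalence {a_term!r} <-> {v_term!r} crosses categories"
                )
            self._pairs.add((a_term, v_term))

    # ------------------------------------------------------------------

    def category(self, term: str, vocabulary: str) -> str:
        """High-level category of ``term`` under ``vocabulary``."""
        vocab.check_vocabulary(vocabulary)
        try:
            return self._categories[vocabulary][term]
        except KeyError:
            raise HarmonizationError(
                f"term {term!r} not in {vocabulary} vocabulary"
            ) from None

    def equivalent(self, term_a: str, vocab_a: str, term_b: str, vocab_b: str) -> bool:
        """Are two terms exact cross-vocabulary (or same-vocabulary) equivalents?

        Within one vocabulary, equivalence is plain equality (except
        ``unknown``, which matches nothing). Across vocabularies the shipped
        equivalence pairs decide.
        """
        if vocab.ABSENT in (term_a, term_b):
            return False
        if "unknown" in (term_a, term_b):
            return False
        if vocab_a == vocab_b:
            return term_a == term_b
        if vocab_a == vocab.V_STYLE:  # orient as (a_style, v_style)
            term_a, term_b = term_b, term_a
        return (term_a, term_b) in self._pairs

    def match_type(self, term_a: str, vocab_a: str, term_b: str, vocab_b: str) -> str:
        """'exact', 'category' or 'mismatch' for a pair of reported terms."""
        if self.equivalent(term_a, vocab_a, term_b, vocab_b):
            return "exact"
        if vocab.ABSENT in (term_a, term_b) or "unknown" in (term_a, term_b):
            return "mismatch"
        if self.category(term_a, vocab_a) == self.category(term_b, vocab_b):
            return "category"
        return "mismatch"


def load_category_map(path: str | None = None,
                      nc_splicing_equivalent: bool = True) -> CategoryMap:
    """Load the category + equivalence map (packaged default if no path)."""
    if path is None:
        ref = resources.files("varconcord.config") / "harmonization.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return CategoryMap(
        categories=raw["categories"],
        equivalence=[tuple(p) for p in raw.get("equivalence", [])],
        nc_splicing_pairs=[tuple(p) for p in raw.get("nc_splicing_equivalence", [])],
        nc_splicing_equivalent=nc_splicing_equivalent,
    )
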