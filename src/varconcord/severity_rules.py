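"""Consequence-severity precedence and most-severe selection.

When several consequence calls compete for one variant (several transcripts,
or several applicable rules under one transcript), a total order on terms —
the severity ranking — decides which single call is reported. The shipped
rankings honour the constraints that matter for interpretation (LoF terms
above missense-level terms, missense above synonymous, exonic above
non-exonic, stop-gain above frameshift); the remaining within-block order is
a convention and can be overridden by a custom config.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from varconcord import vocabulary as vocab


class SeverityConfigError(ValueError):
    """Raised for invalid severity ranking configuration."""


# relative order imposed on category blocks by the ranking validator;
# the four non-exonic categories may interleave freely among themselves.
_BLOCK_LEVEL = {
    vocab.LOF: 0,
    vocab.MISSENSE: 1,
    vocab.SYNONYMOUS_OTHER: 2,
    vocab.UTR: 3,
    vocab.NCRNA: 3,
    vocab.INTRONIC: 3,
    vocab.INTERGENIC_FLANK: 3,
    vocab.UNKNOWN: 3,
}


@dataclass(frozen=True)
class SeverityRanking:
    """A validated total order on the terms of one vocabulary."""

    vocabulary: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab.check_vocabulary(self.vocabulary)
        expected = set(vocab.TERMS[self.vocabulary])
        seen: set[str] = set()
        for term in self.terms:
            if term not in expected:
                raise SeverityConfigError(
                    f"term {term!r} is not in the {self.vocabulary} vocabulary"
                )
            if term in seen:
                raise SeverityConfigError(f"duplicate term {term!r} in ranking")
            seen.add(term)
        missing = expected - seen
        if missing:
            raise SeverityConfigError(
                f"ranking omits terms: {', '.join(sorted(missing))}"
            )

    def rank(self, term: str) -> int:
        """Index of ``term`` in the ranking; 0 is most severe."""
        try:
            return self.terms.index(term)
        except ValueError:
            raise SeverityConfigError(
                f"term {term!r} absent from {self.vocabulary} ranking"
            ) from None


def _validate_category_consistency(ranking: SeverityRanking) -> None:
    """Reject rankings that interleave category blocks.

    LoF terms must all rank above missense-level terms, those above
    synonymous-level terms, and those above all non-exonic terms.
    """
    from varconcord.harmonization import load_category_map

    cmap = load_category_map()
    levels = [
        _BLOCK_LEVEL[cmap.category(t, ranking.vocabulary)] for t in ranking.terms
    ]
    for i, (a, b) in enumerate(zip(levels, levels[1:])):
        if b < a:
            raise SeverityConfigError(
                f"ranking violates category ordering at "
                f"{ranking.terms[i]!r} > {ranking.terms[i + 1]!r}"
            )


def load_ranking(path: str | None = None, vocabulary: str | None = None
                 ) -> SeverityRanking:
    """Load a severity ranking from YAML.

    With ``path=None`` the packaged default for ``vocabulary`` is used.
    The config must list every vocabulary term exactly once, and must not
    interleave high-level category blocks.
    """
    if path is None:
        if vocabulary is None:
            raise SeverityConfigError("need a path or a vocabulary")
        vocab.check_vocabulary(vocabulary)
        ref = resources.files("varconcord.config") / f"{vocabulary}_severity.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "ranking" not in raw:
        raise SeverityConfigError("severity config must map 'vocabulary'/'ranking'")
    voc = raw.get("vocabulary", vocabulary)
    if vocabulary is not None and voc != vocabulary:
        raise SeverityConfigError(
            f"config is for vocabulary {voc!r}, expected {vocabulary!r}"
        )
    ranking = SeverityRanking(vocabulary=voc, terms=tuple(raw["ranking"]))
    _validate_category_consistency(ranking)
    return ranking


def most_severe(calls, ranking: SeverityRanking):
    """Select the most severe call; ties broken by transcript_id then term.

    The selection is idempotent and independent of input order, and adding
    a call can only keep or increase the severity of the result — the
    mechanism by which a larger transcript set can only push reported
    consequences toward more severe terms.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("most_severe() needs a non-empty call list")
    return min(
        calls,
        key=lambda c: (ranking.rank(c.term), c.transcript_id or "", c.term),
    )
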