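"""Concordance statistics for a pair of annotation runs.

Given two per-variant annotation tables (one reported term per variant per
run), this module builds the full-outer-join comparison records, per-term
and high-level summary rows with the three match rates

    rate_a    = 100 * match / count_a
    rate_b    = 100 * match / count_b
    overall   = 100 * match / union,   union = count_a + count_b - match

(with the category-level intersection as the match for high-level rows),
and raw / normalized cross-tabulation matrices. Printed percentages use
half-up rounding to two decimals; the machine-readable output keeps full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from varconcord import vocabulary as vocab
from varconcord.harmonization import CategoryMap, load_category_map

ROLLUPS = ("ALL_LOF", "ALL_LOF_AND_MISSENSE", "ALL_EXONIC", "ALL")

_ROLLUP_CATEGORIES = {
    "ALL_LOF": (vocab.LOF,),
    "ALL_LOF_AND_MISSENSE": (vocab.LOF, vocab.MISSENSE),
    "ALL_EXONIC": vocab.EXONIC_CATEGORIES,
    "ALL": tuple(c for c in vocab.CATEGORIES if c != vocab.UNKNOWN),
}


def round2(x: float) -> float:
    """Half-up rounding to 2 decimal places (presentation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRecord:
    """One variant's reported annotation in each of two runs."""

    variant_key: str
    term_a: str
    term_b: str
    transcript_a: str | None = None
    transcript_b: str | None = None

    @property
    def same_transcript(self) -> bool | None:
        if self.transcript_a is None or self.transcript_b is None:
            return None
        return self.transcript_a == self.transcript_b


def build_comparison(calls_a: pd.DataFrame, calls_b: pd.DataFrame
                     ) -> list[ComparisonRecord]:
    """Full outer join of two primary-annotation tables on variant key.

    Each input needs columns ``variant_key`` and ``term`` (plus optional
    ``transcript_id``), one row per variant (the most-severe report);
    duplicate keys within one run are an error. Variants annotated in only
    one run carry the explicit ``absent`` marker on the other side.
    """
    frames = []
    for side, df in (("a", calls_a), ("b", calls_b)):
        if "primary" in df.columns:
            df = df[df["primary"]]
        if df["variant_key"].duplicated().any():
            dup = df.loc[df["variant_key"].duplicated(), "variant_key"].iloc[0]
            raise ValueError(
                f"duplicate variant key {dup!r} in run {side}: the most-severe "
                "report must be unique per variant"
            )
        cols = {"variant_key": df["variant_key"], f"term_{side}": df["term"]}
        if "transcript_id" in df.columns:
            cols[f"transcript_{side}"] = df["transcript_id"]
        frames.append(pd.DataFrame(cols))
    merged = frames[0].merge(frames[1], on="variant_key", how="outer")
    records = []
    for row in merged.itertuples(index=False):
        d = row._asdict()
        records.append(
            ComparisonRecord(
                variant_key=d["variant_key"],
                term_a=d.get("term_a") if pd.notna(d.get("term_a")) else vocab.ABSENT,
                term_b=d.get("term_b") if pd.notna(d.get("term_b")) else vocab.ABSENT,
                transcript_a=_opt(d.get("transcript_a")),
                transcript_b=_opt(d.get("transcript_b")),
            )
        )
    return records


def _opt(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else x


def summarize(records: list[ComparisonRecord], category_map: CategoryMap | None,
              vocab_a: str, vocab_b: str) -> pd.DataFrame:
    """Per-term and rollup concordance rows for a pair of runs.

    Fine-term rows: for each term observed in either run, ``count_a`` /
    ``count_b`` are the variants given that term per run, ``match`` those
    given it by both (same-vocabulary runs) or exact cross-vocabulary
    equivalents (different vocabularies; the row is keyed by the a-side
    term and ``match`` counts variants whose two terms are exact
    equivalents with this a-side term). Rollup rows ALL_LOF,
    ALL_LOF_AND_MISSENSE, ALL_EXONIC and ALL count category-level
    intersections and report both exact and category match columns.

    Rates are percentages in [0, 100]; a rate with a zero denominator is
    NaN (printed as '-'). Terms with zero count in both runs are omitted.
    """
    if category_map is None:
        category_map = load_category_map()
    cross = vocab_a != vocab_b
    df = pd.DataFrame(
        {
            "term_a": [r.term_a for r in records],
            "term_b": [r.term_b for r in records],
        }
    )
    df["exact"] = [
        category_map.equivalent(r.term_a, vocab_a, r.term_b, vocab_b)
        for r in records
    ]
    df["cat_a"] = [_safe_cat(category_map, t, vocab_a) for t in df["term_a"]]
    df["cat_b"] = [_safe_cat(category_map, t, vocab_b) for t in df["term_b"]]
    df["cat_match"] = (
        (df["cat_a"] == df["cat_b"])
        & (df["cat_a"] != vocab.ABSENT)
        & (df["cat_a"] != vocab.UNKNOWN)
    )

    rows = []
    terms_a = [t for t in df["term_a"].unique() if t != vocab.ABSENT]
    terms_b = [t for t in df["term_b"].unique() if t != vocab.ABSENT]
    if not cross:
        fine_terms = sorted(set(terms_a) | set(terms_b))
    else:
        fine_terms = sorted(set(terms_a))
        # v_style-only terms (no a-side equivalent) still get a row, keyed
        # by the b-side term, with count_a = 0 (the structural zeros).
        b_only = sorted(
            t for t in terms_b
            if not any(category_map.equivalent(a, vocab_a, t, vocab_b) for a in fine_terms)
        )
    for term in fine_terms:
        in_a = df["term_a"] == term
        if cross:
            in_b = df["term_b"].map(
                lambda tb: category_map.equivalent(term, vocab_a, tb, vocab_b)
            )
        else:
            in_b = df["term_b"] == term
        count_a = int(in_a.sum())
        count_b = int(in_b.sum())
        match = int((in_a & in_b & df["exact"]).sum()) if cross else int((in_a & in_b).sum())
        if count_a == 0 and count_b == 0:
            continue
        rows.append(_rate_row(term, count_a, count_b, match, None))
    if cross:
        for term in b_only:
            in_b = df["term_b"] == term
            count_b = int(in_b.sum())
            if count_b == 0:
                continue
            rows.append(_rate_row(term, 0, count_b, 0, None))

    for name in ROLLUPS:
        cats = _ROLLUP_CATEGORIES[name]
        in_a = df["cat_a"].isin(cats)
        in_b = df["cat_b"].isin(cats)
        count_a = int(in_a.sum())
        count_b = int(in_b.sum())
        exact = int((in_a & in_b & df["exact"]).sum())
        cat_match = int((in_a & in_b & df["cat_match"]).sum())
        if count_a == 0 and count_b == 0:
            continue
        rows.append(_rate_row(name, count_a, count_b, exact, cat_match))
    return pd.DataFrame(rows)


def _safe_cat(cmap: CategoryMap, term: str, vocabulary: str) -> str:
    if term == vocab.ABSENT:
        return vocab.ABSENT
    return cmap.category(term, vocabulary)


def _rate_row(label: str, count_a: int, count_b: int, match: int,
              category_match: int | None) -> dict:
    union_match = match if category_match is None else category_match
    union = count_a + count_b - union_match
    row = {
        "row": label,
        "union_count": union,
        "count_a": count_a,
        "count_b": count_b,
        "match_count": match,
        "category_match_count": category_match,
        "rate_a": 100.0 * match / count_a if count_a else np.nan,
        "rate_b": 100.0 * match / count_b if count_b else np.nan,
        "overall_rate": 100.0 * match / union if union else np.nan,
    }
    row["overall_category_rate"] = (
        100.0 * category_match / union if category_match is not None and union else np.nan
    )
    return row


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: rates half-up rounded to 2 dp, NaN printed '-'."""
    out = report.copy()
    for col in ("rate_a", "rate_b", "overall_rate", "overall_category_rate"):
        out[col] = [
            "-" if pd.isna(x) else f"{round2(x):.2f}" for x in out[col]
        ]
    out["category_match_count"] = [
        "-" if pd.isna(x) else int(x) for x in out["category_match_count"]
    ]
    return out


def crosstab(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Dense matrix of variant counts term_a x term_b.

    Variants absent from one run are excluded (the matrix compares
    annotation pairs); the sum over cells is the number of variants
    annotated in both runs.
    """
    both = [
        r for r in records
        if r.term_a != vocab.ABSENT and r.term_b != vocab.ABSENT
    ]
    if not both:
        return pd.DataFrame()
    m = pd.crosstab(
        pd.Series([r.term_a for r in both], name="term_a"),
        pd.Series([r.term_b for r in both], name="term_b"),
    )
    return m.sort_index(axis=0).sort_index(axis=1)


def normalize_matrix(m: pd.DataFrame, axis: str = "row") -> pd.DataFrame:
    """log10(count+1), then z-scale per row or per column.

    Zero-variance axes (constant after the log transform) map to all
    zeros. Standard deviation uses the population formula (divide by n).
    """
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    t = np.log10(m.to_numpy(dtype=float) + 1.0)
    ax = 1 if axis == "row" else 0
    mean = t.mean(axis=ax, keepdims=True)
    sd = t.std(axis=ax, keepdims=True)  # population sd
    # constant axes have sd 0 up to float rounding; map them to all-zeros
    const = sd <= 1e-12 * np.maximum(1.0, np.abs(t).max(axis=ax, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (t - mean) / sd
    z[np.broadcast_to(const, z.shape)] = 0.0
    return pd.DataFrame(z, index=m.index, columns=m.columns)


def plot_heatmap(m: pd.DataFrame, path: str, title: str = "") -> None:
    """Write a heatmap image of a (normalized) cross-tabulation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.4 * m.shape[1] + 2), max(3.0, 0.4 * m.shape[0] + 2))
    )
    im = ax.imshow(m.to_numpy(dtype=float), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(m.shape[1]), labels=m.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(m.shape[0]), labels=m.index, fontsize=7)
    ax.set_xlabel("run B term")
    ax.set_ylabel("run A term")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
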