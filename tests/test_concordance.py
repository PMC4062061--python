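"""Concordance statistics: union identities, match rates, cross-tabulation
and the log10/z-scale matrix normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from varconcord import concordance as conc
from varconcord.concordance import (
    ComparisonRecord,
    build_comparison,
    crosstab,
    normalize_matrix,
    round2,
    summarize,
)
from varconcord.vocabulary import ABSENT


def _df(pairs):
    return pd.DataFrame(
        {"variant_key": [k for k, _ in pairs], "term": [t for _, t in pairs]}
    )


class TestBuildComparison:
    def test_identical_runs(self):
        pairs = [(f"v{i}", "intronic") for i in range(10)]
        recs = build_comparison(_df(pairs), _df(pairs))
        assert len(recs) == 10
        assert all(r.term_a == r.term_b == "intronic" for r in recs)

    def test_absent_marker(self):
        recs = build_comparison(_df([("v1", "intronic")]),
                                _df([("v1", "intronic"), ("v2", "UTR3")]))
        by_key = {r.variant_key: r for r in recs}
        assert by_key["v2"].term_a == ABSENT
        assert by_key["v2"].term_b == "UTR3"

    def test_duplicate_key_is_an_error(self):
        dup = _df([("v1", "intronic"), ("v1", "UTR3")])
        with pytest.raises(ValueError, match="duplicate variant key"):
            build_comparison(dup, _df([("v1", "intronic")]))

    def test_record_count_is_set_union(self):
        rng = np.random.default_rng(4)
        keys_a = [f"v{i}" for i in rng.choice(200, size=120, replace=False)]
        keys_b = [f"v{i}" for i in rng.choice(200, size=90, replace=False)]
        recs = build_comparison(
            _df([(k, "intronic") for k in keys_a]),
            _df([(k, "intronic") for k in keys_b]),
        )
        assert len(recs) == len(set(keys_a) | set(keys_b))

    def test_same_transcript_flag(self):
        a = pd.DataFrame({"variant_key": ["v1"], "term": ["intronic"],
                          "transcript_id": ["tx1"]})
        b = pd.DataFrame({"variant_key": ["v1"], "term": ["intronic"],
                          "transcript_id": ["tx2"]})
        (rec,) = build_comparison(a, b)
        assert rec.same_transcript is False


class TestSummarize:
    def test_printed_fine_row_arithmetic(self, category_map):
        """A fine row with counts 14,183 / 14,960 and 13,308 matches must
        give union 15,835 and rates 93.83 / 88.96 / 84.04."""
        row = conc._rate_row("stopgain_SNV", 14183, 14960, 13308, None)
        assert row["union_count"] == 15835
        assert round2(row["rate_a"]) == 93.83
        assert round2(row["rate_b"]) == 88.96
        assert round2(row["overall_rate"]) == 84.04

    def test_printed_highlevel_row_arithmetic(self):
        """A high-level row with exact and category matches reproduces the
        printed union and both overall rates."""
        row = conc._rate_row("ALL_LOF", 77527, 96761, 68284, 69373)
        assert row["union_count"] == 104915
        assert round2(row["rate_a"]) == 88.08
        assert round2(row["rate_b"]) == 70.57
        assert round2(row["overall_rate"]) == 65.09
        assert round2(row["overall_category_rate"]) == 66.12

    def test_identical_runs_give_all_100(self, category_map):
        pairs = [("v1", "stopgain_SNV"), ("v2", "intronic"), ("v3", "UTR3"),
                 ("v4", "nonsynonymous_SNV")]
        recs = build_comparison(_df(pairs), _df(pairs))
        rep = summarize(recs, category_map, "a_style", "a_style")
        rates = rep[["rate_a", "rate_b", "overall_rate"]].to_numpy(float)
        assert np.allclose(rates, 100.0)
        m = crosstab(recs)
        off_diag = m.to_numpy().sum() - np.trace(m.to_numpy())
        assert off_diag == 0

    def test_union_identity_and_bounds_on_synthetic_runs(self, category_map):
        rng = np.random.default_rng(9)
        terms = ["stopgain_SNV", "splicing", "nonsynonymous_SNV",
                 "synonymous_SNV", "intronic", "UTR3", "intergenic"]
        n = 400
        keys = [f"v{i}" for i in range(n)]
        a = _df(list(zip(keys, rng.choice(terms, size=n))))
        # b drops some variants and perturbs some terms
        keep = rng.random(n) > 0.1
        b_terms = [
            t if rng.random() > 0.3 else str(rng.choice(terms))
            for t in a["term"]
        ]
        b = _df([(k, t) for k, t, kp in zip(keys, b_terms, keep) if kp])
        recs = build_comparison(a, b)
        rep = summarize(recs, category_map, "a_style", "a_style")
        for row in rep.itertuples(index=False):
            match = (
                row.category_match_count
                if row.category_match_count is not None
                and not pd.isna(row.category_match_count)
                else row.match_count
            )
            assert row.union_count == row.count_a + row.count_b - match
            assert row.match_count <= min(row.count_a, row.count_b)
            for rate in (row.rate_a, row.rate_b, row.overall_rate):
                if not pd.isna(rate):
                    assert 0.0 <= rate <= 100.0
            if not pd.isna(row.overall_category_rate):
                assert row.match_count <= row.category_match_count

    def test_zero_denominator_prints_dash(self, category_map):
        recs = build_comparison(
            _df([("v1", "nonsynonymous_SNV")]),
            pd.DataFrame({"variant_key": ["v1", "v2"],
                          "term": ["missense_variant", "initiator_codon_variant"]}),
        )
        rep = summarize(recs, category_map, "a_style", "v_style")
        printed = conc.format_report(rep)
        init = printed[printed["row"] == "initiator_codon_variant"].iloc[0]
        assert init["rate_a"] == "-"


class TestCrosstab:
    def test_small_matrix(self):
        recs = [
            ComparisonRecord("v1", "x", "x"),
            ComparisonRecord("v2", "x", "y"),
            ComparisonRecord("v3", "y", "y"),
        ]
        m = crosstab(recs)
        assert m.loc["x", "x"] == 1 and m.loc["x", "y"] == 1 and m.loc["y", "y"] == 1

    def test_absent_excluded_and_rowsums_match_recount(self, category_map):
        rng = np.random.default_rng(3)
        terms = ["splicing", "intronic", "UTR5"]
        recs = []
        for i in range(300):
            ta = str(rng.choice(terms + [ABSENT]))
            tb = str(rng.choice(terms + [ABSENT]))
            recs.append(ComparisonRecord(f"v{i}", ta, tb))
        m = crosstab(recs)
        both = [r for r in recs if ABSENT not in (r.term_a, r.term_b)]
        assert m.to_numpy().sum() == len(both)
        for term in m.index:
            expected = sum(1 for r in both if r.term_a == term)
            assert m.loc[term].sum() == expected


class TestNormalizeMatrix:
    def test_zero_count_maps_to_zero_before_scaling(self):
        m = pd.DataFrame([[0, 0], [0, 0]])
        assert (normalize_matrix(m, "row") == 0).all().all()

    def test_constant_row_maps_to_zeros(self):
        m = pd.DataFrame([[5, 5, 5], [1, 2, 3]])
        z = normalize_matrix(m, "row")
        assert (z.iloc[0] == 0).all()
        assert abs(z.iloc[1].mean()) < 1e-9

    def test_2x2_arithmetic_oracle(self):
        """[[9,0],[99,9]] row-normalized: log10 -> [[1,0],[2,1]]; each row
        z-scales to [+1,-1]."""
        m = pd.DataFrame([[9, 0], [99, 9]])
        z = normalize_matrix(m, "row")
        assert np.allclose(z.to_numpy(), [[1.0, -1.0], [1.0, -1.0]])

    @settings(max_examples=50, derandomize=True)
    @given(
        m=arrays(
            dtype=np.int64,
            shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
            elements=st.integers(0, 10_000),
        )
    )
    def test_axis_mean_zero_sd_one(self, m):
        df = pd.DataFrame(m)
        for axis, np_axis in (("row", 1), ("column", 0)):
            z = normalize_matrix(df, axis).to_numpy()
            # a constant axis = all integer counts along it are equal
            const = np.all(
                m == np.expand_dims(m.take(0, axis=np_axis), np_axis),
                axis=np_axis,
            )
            means = z.mean(axis=np_axis)
            sds = z.std(axis=np_axis)
            assert np.allclose(means[~const], 0, atol=1e-9)
            assert np.allclose(sds[~const], 1, atol=1e-9)
            assert np.allclose(z.mean(axis=np_axis)[const], 0)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(84.035, 84.04), (84.0349, 84.03), (9.285, 9.29), (100.0, 100.0)],
    )
    def test_half_up_two_decimals(self, value, expected):
        assert round2(value) == expected
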