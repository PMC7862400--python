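from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iddtools.family_categories import (
    NORMALIZATION_ANCHORS,
    classify_variation,
    compare_family_disorder_between_clades,
    dominant_category,
    family_profiles,
    fit_normalization_cubic,
    no_variation_proportion_test,
    normalize_dsdr,
    pairwise_variation,
    repetition_category,
    variation_records,
)


def exact_cubic(x):
    """Oracle: the normalization cubic in exact rational arithmetic."""
    xf = Fraction(x)  # exact binary-float conversion
    return float(
        xf**3 / 78750 - Fraction(137, 63000) * xf**2 + Fraction(253, 2100) * xf
    )


class TestNormalization:
    @pytest.mark.parametrize("x,y", [(0, 0), (10, 1), (30, 2), (100, 3)])
    def test_anchor_points(self, x, y):
        assert normalize_dsdr(x) == pytest.approx(y, abs=1e-9)

    def test_value_at_20(self):
        # 1.641270 computed from the exact rational polynomial
        assert normalize_dsdr(20) == pytest.approx(1.641270, abs=1e-5)
        assert normalize_dsdr(20) == pytest.approx(exact_cubic(20), abs=1e-12)

    def test_refit_recovers_printed_coefficients(self):
        a, b, c, d = fit_normalization_cubic()
        assert a == pytest.approx(1 / 78750, rel=1e-9)
        assert b == pytest.approx(-137 / 63000, rel=1e-9)
        assert c == pytest.approx(253 / 2100, rel=1e-9)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_range_and_nonmonotonicity(self):
        """The cubic maps [0,100] into [0,3], rises over the grade range
        [0,30], and has an interior dip (local max near 47.3, local min near
        66.9) — it is deliberately not globally monotone."""
        xs = np.linspace(0, 100, 10001)
        ys = normalize_dsdr(xs)
        assert ys.min() >= 0 and ys.max() <= 3 + 1e-12
        grade_range = normalize_dsdr(np.linspace(0, 30, 301))
        assert np.all(np.diff(grade_range) > 0)
        # derivative roots of the cubic bracket the dip
        peak_x = xs[np.argmax(ys[:6000])]
        assert 45 < peak_x < 50
        dip_x = xs[5000 + np.argmin(ys[5000:8000])]
        assert 64 < dip_x < 70
        assert normalize_dsdr(float(dip_x)) < normalize_dsdr(float(peak_x))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_dsdr(101)

    @given(st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_rational_oracle(self, x):
        assert normalize_dsdr(x) == pytest.approx(exact_cubic(x), abs=1e-9)


class TestDominantCategory:
    @pytest.mark.parametrize(
        "labels,expected",
        [(["A", "A", "A", "B"], "A"), (["A", "A", "B", "B"], None), (["A"], "A")],
    )
    def test_majority_rule(self, labels, expected):
        assert dominant_category(labels) == expected

    def test_exhaustive_small_multisets(self):
        """None is returned exactly when no label exceeds half — checked
        against exhaustive enumeration of all label vectors up to length 5."""
        for n in range(1, 6):
            for combo in product("ABC", repeat=n):
                got = dominant_category(list(combo))
                counts = {l: combo.count(l) for l in set(combo)}
                over_half = [l for l, c in counts.items() if c / n > 0.5]
                assert got == (over_half[0] if over_half else None)


class TestRepetition:
    @pytest.mark.parametrize(
        "proteins,expected",
        [
            (["p1"], "single_copy"),
            (["p1", "p1", "p1"], "within_protein_only"),
            (["p1", "p2"], "across_proteins_only"),
            (["p1", "p1", "p2", "p2"], "both"),
            (["p1", "p1", "p2"], "both"),
        ],
    )
    def test_categories(self, proteins, expected):
        assert repetition_category(proteins) == expected


class TestVariation:
    @pytest.mark.parametrize(
        "values,expected",
        [((2.5, 2.5), "no_variation"), ((0.0, 2.5), "high_variation"),
         ((1.0, 1.8), "low_variation")],
    )
    def test_pair_classes(self, values, expected):
        inst = [("p1", values[0]), ("p2", values[1])]
        rec = pairwise_variation("PF1", "s", inst, "across_proteins")
        assert rec.variation_dominant == expected

    def test_single_instance_not_applicable(self):
        rec = pairwise_variation("PF1", "s", [("p1", 1.0)], "within_protein")
        assert not rec.applicable and rec.pair_values == []

    def test_scope_separation(self):
        inst = [("p1", 0.0), ("p1", 3.0), ("p2", 0.0)]
        within = pairwise_variation("PF1", "s", inst, "within_protein")
        across = pairwise_variation("PF1", "s", inst, "across_proteins")
        assert within.pair_values == [3.0]
        assert sorted(across.pair_values) == [0.0, 3.0]

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_pair_values_bounded_by_scale(self, dsdrs):
        """|Δ| of normalized values never exceeds 3, so the variation
        classes are exhaustive."""
        inst = [(f"p{i}", normalize_dsdr(v)) for i, v in enumerate(dsdrs)]
        rec = pairwise_variation("PF1", "s", inst, "across_proteins")
        assert all(0 <= v <= 3 for v in rec.pair_values)
        for v in rec.pair_values:
            assert classify_variation(v) in (
                "no_variation", "low_variation", "high_variation"
            )


class TestFisher:
    def test_symmetric_table(self):
        res = no_variation_proportion_test(5, 5, 5, 5)
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated(self):
        # exact two-sided P of [[10,0],[0,10]] = 2/C(20,10)
        res = no_variation_proportion_test(10, 0, 0, 10)
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-9)
        assert res.direction == "within_higher"

    def test_zero_margin_undefined(self):
        res = no_variation_proportion_test(1, 0, 0, 0)
        assert not res.defined


class TestFamilyProfiles:
    def test_median_and_flags(self):
        df = pd.DataFrame(
            {
                "species_id": ["s"] * 3,
                "family_id": ["PF1"] * 3,
                "protein_id": ["p1", "p2", "p3"],
                "dsdr": [0.0, 10.0, 30.0],
                "dsdr_grade": ["completely_structured", "highly_structured",
                               "moderately_unstructured"],
                "cdrn": [0, 0, 1],
            }
        )
        fam = family_profiles(df)
        assert len(fam) == 1
        row = fam.iloc[0]
        assert row["median_norm_dsdr"] == pytest.approx(1.0)  # median dsdr 10 -> 1
        assert row["dominant_category"] is None
        assert row["repetition_category"] == "across_proteins_only"
        assert bool(row["family_cdrn_flag"]) and bool(row["is_idd_family"])

    def test_variation_records_scopes(self):
        df = pd.DataFrame(
            {
                "species_id": ["s"] * 3,
                "family_id": ["PF1"] * 3,
                "protein_id": ["p1", "p1", "p2"],
                "dsdr": [0.0, 100.0, 0.0],
                "dsdr_grade": ["completely_structured"] * 3,
                "cdrn": [0, 0, 0],
            }
        )
        recs = variation_records(df)
        scopes = {r.scope for r in recs}
        assert scopes == {"within_protein", "across_proteins"}


class TestCladeComparison:
    def test_threshold_rules(self):
        a = {"PF1": 2.5, "PF2": 1.0, "PF3": 1.0, "PF4": 0.2}
        b = {"PF1": 1.0, "PF2": 1.0, "PF3": 1.5, "PF5": 3.0}
        out = compare_family_disorder_between_clades(a, b, delta_threshold=1.0)
        verdicts = dict(zip(out["family_id"], out["verdict"]))
        assert verdicts == {"PF1": "higher_in_a", "PF2": "similar", "PF3": "similar"}
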