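from fractions import Fraction
from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iddtools.disorder_metrics import (
    classify_dsdr_grade,
    classify_quadrant,
    compute_dsdr,
    compute_protein_metrics,
    domain_table,
    find_cdrs,
    maximal_runs,
    non_domain_regions,
    region_metrics,
    representative_proteins,
    species_summary,
)
from iddtools.records import DisorderProfile, DomainInstance, ProteinRecord


def brute_force_cdrs(calls):
    """Independent oracle: enumerate maximal runs by groupby, qualify with
    exact rational arithmetic."""
    n = len(calls)
    runs, pos = [], 0
    for val, grp in groupby(calls):
        length = len(list(grp))
        if val:
            runs.append((pos, pos + length))
        pos += length
    if n > 50:
        return [(a, b) for a, b in runs if b - a > 20]
    return [(a, b) for a, b in runs if Fraction(b - a, n) > Fraction(2, 5)]


class TestDSDR:
    @pytest.mark.parametrize(
        "n_dis,n_tot,expected", [(30, 60, 50.0), (0, 80, 0.0), (80, 80, 100.0)]
    )
    def test_percentage(self, n_dis, n_tot, expected):
        calls = np.r_[np.ones(n_dis, bool), np.zeros(n_tot - n_dis, bool)]
        assert compute_dsdr(calls) == expected

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_dsdr(np.ones(5, bool), 3, 3)

    def test_region_additivity(self, rng):
        """Disordered counts over any partition sum to the whole-protein count."""
        calls = rng.random(200) > 0.5
        cuts = sorted(rng.choice(np.arange(1, 200), size=5, replace=False))
        edges = [0, *cuts, 200]
        total = sum(
            region_metrics(calls, a, b).n_disordered
            for a, b in zip(edges[:-1], edges[1:])
        )
        assert total == int(calls.sum())


class TestFindCDRs:
    @pytest.mark.parametrize(
        "length,run,expected_n",
        [
            (100, 21, 1),   # > 20 rule, long domain
            (100, 20, 0),   # exactly 20 fails, strict
            (40, 16, 0),    # exactly 40% fails, strict
            (40, 17, 1),
            (50, 21, 1),    # short-domain rule still applies at exactly 50
        ],
    )
    def test_rule_boundaries(self, length, run, expected_n):
        calls = np.zeros(length, bool)
        calls[:run] = True
        assert len(find_cdrs(calls)) == expected_n

    def test_runs_are_maximal_and_ordered(self):
        calls = np.zeros(120, bool)
        calls[5:30] = True
        calls[60:95] = True
        assert find_cdrs(calls) == [(5, 30), (60, 95)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(2000):
            n = int(rng.integers(1, 160))
            p = rng.random()
            calls = rng.random(n) < p
            assert find_cdrs(calls) == brute_force_cdrs(calls.tolist()), (
                n, calls.astype(int).tolist()
            )

    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    @settings(max_examples=300, deadline=None)
    def test_property_matches_oracle(self, bits):
        calls = np.array(bits, dtype=bool)
        assert find_cdrs(calls) == brute_force_cdrs(bits)

    @given(st.lists(st.booleans(), min_size=1, max_size=80), st.integers(0, 79))
    @settings(max_examples=200, deadline=None)
    def test_idd_flag_monotone_in_disorder(self, bits, idx):
        """Flipping a structured residue to disordered never un-IDDs a region."""
        calls = np.array(bits, dtype=bool)
        before = region_metrics(calls).is_idd
        calls2 = calls.copy()
        calls2[idx % len(calls2)] = True
        after = region_metrics(calls2).is_idd
        assert after or not before


class TestClassification:
    @pytest.mark.parametrize(
        "dsdr,grade",
        [
            (0.0, "completely_structured"),
            (10.0, "highly_structured"),
            (0.5, "highly_structured"),
            (30.0, "moderately_unstructured"),
            (30.1, "intrinsically_disordered"),
            (100.0, "intrinsically_disordered"),
        ],
    )
    def test_grade_bins(self, dsdr, grade):
        assert classify_dsdr_grade(dsdr) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_dsdr_grade(101.0)

    @pytest.mark.parametrize(
        "dsdr,cdrn,quadrant",
        [(50, 2, "I"), (10, 1, "II"), (5, 0, "III"), (45, 0, "IV"), (30, 0, "III")],
    )
    def test_quadrants(self, dsdr, cdrn, quadrant):
        assert classify_quadrant(dsdr, cdrn) == quadrant

    def test_quadrant_sums_match_idd_rules(self, rng):
        """%I + %IV equals the DSDR-rule IDD percentage and %I + %II the
        CDRN-rule percentage, per species."""
        profiles, domains = {}, []
        for i in range(60):
            pid = f"p{i}"
            calls = rng.random(90) < rng.random()
            profiles[pid] = DisorderProfile(pid, calls)
            domains.append(DomainInstance(pid, "PF1", 1, 90, species_id="s"))
        df = domain_table(profiles, domains)
        s = species_summary(df)
        assert s["pct_class_I"] + s["pct_class_IV"] == pytest.approx(s["pct_idd_dsdr"])
        assert s["pct_class_I"] + s["pct_class_II"] == pytest.approx(s["pct_idd_cdrn"])


class TestProteinLevel:
    def test_psdr_and_idp_flag(self):
        prof = DisorderProfile("p", np.r_[np.ones(3, bool), np.zeros(7, bool)])
        m = compute_protein_metrics(prof)
        assert m.psdr == 30.0 and not m.is_idp  # strict > 30

    def test_representative_longest_then_lexicographic(self):
        recs = [
            ProteinRecord("pB", "MKVLA", gene_id="g1"),
            ProteinRecord("pA", "MKVLA", gene_id="g1"),
            ProteinRecord("pC", "MKV", gene_id="g1"),
            ProteinRecord("pD", "MK", gene_id="g2"),
        ]
        reps = representative_proteins(recs)
        assert [r.protein_id for r in reps] == ["pA", "pD"]


class TestNonDomainRegions:
    def test_single_domain(self):
        d = DomainInstance("p", "PF1", 21, 40)
        assert non_domain_regions(100, [d]) == [(0, 20), (40, 100)]

    def test_no_domains(self):
        assert non_domain_regions(100, []) == [(0, 100)]

    def test_tiling_domains(self):
        ds = [DomainInstance("p", "PF1", 1, 50), DomainInstance("p", "PF2", 51, 100)]
        assert non_domain_regions(100, ds) == []


class TestSpeciesSummary:
    def test_idd_percentage(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "dsdr": [50.0, 40.0] + [0.0] * 8,
                "cdrn": [1, 0] + [0] * 8,
                "is_idd": [True, True] + [False] * 8,
                "quadrant": ["I", "IV"] + ["III"] * 8,
            }
        )
        assert species_summary(df)["pct_idd_dsdr"] == 20.0

    def test_empty_reported_missing(self):
        import pandas as pd

        s = species_summary(pd.DataFrame(columns=["dsdr", "cdrn", "is_idd", "quadrant"]))
        assert np.isnan(s["pct_idd_dsdr"])
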