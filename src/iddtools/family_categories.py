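"""Family-level analysis: DSDR normalization, dominant categories,
repetition categories and disorder-variation of repeating domains.

Raw DSDR percentages are mapped onto a 0–3 scale by a cubic interpolation
polynomial fixed by the four anchor points (0, 0), (10, 1), (30, 2) and
(100, 3), so that one unit of the normalized scale corresponds to one DSDR
grade step. The cubic is

    y = x^3/78750 - 137 x^2/63000 + 253 x/2100

It is increasing over the grade boundaries (0–30) but not globally monotone:
it has a local maximum near x = 47.3 and a local minimum near x = 66.9 —
a documented property of the interpolant, not a defect of this code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: exact rational coefficients of the normalization cubic (a, b, c, d)
NORMALIZATION_COEFFS = (
    Fraction(1, 78750),
    Fraction(-137, 63000),
    Fraction(253, 2100),
    Fraction(0),
)

#: the four (raw DSDR, normalized) anchor points the cubic interpolates
NORMALIZATION_ANCHORS = ((0.0, 0.0), (10.0, 1.0), (30.0, 2.0), (100.0, 3.0))

VARIATION_CLASSES = ("no_variation", "low_variation", "high_variation")

REPETITION_CATEGORIES = (
    "single_copy",
    "within_protein_only",
    "across_proteins_only",
    "both",
)


def normalize_dsdr(x):
    """Normalized DSDR: evaluate the interpolation cubic at raw DSDR ``x``
    (percent, in [0, 100]). Accepts scalars or arrays."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("DSDR outside [0, 100]")
    a, b, c, d = (float(f) for f in NORMALIZATION_COEFFS)
    y = ((a * arr + b) * arr + c) * arr + d
    return float(y) if np.isscalar(x) else y


def fit_normalization_cubic(
    anchors: Sequence[tuple[float, float]] = NORMALIZATION_ANCHORS,
) -> np.ndarray:
    """Re-derive the cubic's coefficients (a, b, c, d) by solving the 4x4
    Vandermonde system through the anchor points."""
    xs = np.array([p[0] for p in anchors], dtype=float)
    ys = np.array([p[1] for p in anchors], dtype=float)
    V = np.vander(xs, 4)  # columns x^3, x^2, x, 1
    return np.linalg.solve(V, ys)


def classify_variation(delta: float) -> str:
    """Variation class of one |Δ normalized DSDR|: 0 / (0,1] / (1,3]."""
    if delta < 0 or delta > 3:
        raise ValueError(f"variation value {delta} outside [0, 3]")
    if delta == 0:
        return "no_variation"
    if delta <= 1:
        return "low_variation"
    return "high_variation"


def dominant_category(labels: Sequence[str]) -> Optional[str]:
    """The unique label covering more than half of the instances, else None
    ("no dominant category")."""
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    label, count = counts.most_common(1)[0]
    return label if count / len(labels) > 0.5 else None


@dataclass
class FamilyProfile:
    """One domain family in one species."""

    family_id: str
    species_id: str
    n_instances: int
    median_norm_dsdr: float
    dominant_category: Optional[str]
    repetition_category: str
    family_cdrn_flag: bool  # any instance with CDRN >= 1

    @property
    def is_idd_family(self) -> bool:
        """Family-level IDD call: dominant category intrinsically disordered
        or any instance carrying a CDR."""
        return (
            self.dominant_category == "intrinsically_disordered"
            or self.family_cdrn_flag
        )


def repetition_category(protein_ids: Sequence[str]) -> str:
    """Repetition pattern of one family in one species, from the protein id
    of each instance: single copy; repeating only within one protein;
    spread over several proteins with at most one copy each; or both."""
    if not protein_ids:
        raise ValueError("family with no instances")
    counts = Counter(protein_ids)
    n_proteins = len(counts)
    repeats_within = any(c > 1 for c in counts.values())
    if len(protein_ids) == 1:
        return "single_copy"
    if n_proteins == 1:
        return "within_protein_only"
    if not repeats_within:
        return "across_proteins_only"
    return "both"


def family_profiles(domain_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-domain-instance metrics table into per-(species,
    family) profiles: median normalized DSDR, DSDR dominant category,
    repetition category and the any-CDR flag."""
    rows = []
    for (species, family), grp in domain_df.groupby(
        ["species_id", "family_id"], sort=True
    ):
        norm = normalize_dsdr(grp["dsdr"].to_numpy())
        rows.append(
            {
                "species_id": species,
                "family_id": family,
                "n_instances": len(grp),
                "median_norm_dsdr": float(np.median(norm)),
                "dominant_category": dominant_category(list(grp["dsdr_grade"])),
                "repetition_category": repetition_category(list(grp["protein_id"])),
                "family_cdrn_flag": bool((grp["cdrn"] >= 1).any()),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "species_id", "family_id", "n_instances", "median_norm_dsdr",
            "dominant_category", "repetition_category", "family_cdrn_flag",
        ],
    )
    if len(df):
        df["is_idd_family"] = (
            (df["dominant_category"] == "intrinsically_disordered")
            | df["family_cdrn_flag"]
        )
    else:
        df["is_idd_family"] = pd.Series(dtype=bool)
    return df


@dataclass
class VariationRecord:
    """Pairwise normalized-DSDR differences for one repeating family."""

    family_id: str
    species_id: str
    scope: str  # "within_protein" | "across_proteins"
    pair_values: list[float]
    variation_dominant: Optional[str]  # None = no dominant category
    applicable: bool = True


def pairwise_variation(
    family_id: str,
    species_id: str,
    instances: Sequence[tuple[str, float]],
    scope: str,
) -> VariationRecord:
    """Variation record over all unordered instance pairs in scope.

    ``instances`` are (protein_id, normalized DSDR) pairs. Scope
    ``within_protein`` enumerates pairs sharing a protein; scope
    ``across_proteins`` enumerates pairs on distinct proteins. Fewer than two
    instances in scope yields a not-applicable record.
    """
    if scope not in ("within_protein", "across_proteins"):
        raise ValueError(f"unknown scope {scope!r}")
    same = scope == "within_protein"
    values = [
        abs(v1 - v2)
        for (p1, v1), (p2, v2) in combinations(instances, 2)
        if (p1 == p2) == same
    ]
    if not values:
        return VariationRecord(family_id, species_id, scope, [], None, applicable=False)
    classes = [classify_variation(v) for v in values]
    return VariationRecord(
        family_id, species_id, scope, values, dominant_category(classes)
    )


def variation_records(domain_df: pd.DataFrame) -> list[VariationRecord]:
    """All applicable variation records (both scopes) for every repeating
    family in every species of a per-instance metrics table."""
    out: list[VariationRecord] = []
    for (species, family), grp in domain_df.groupby(
        ["species_id", "family_id"], sort=True
    ):
        if len(grp) < 2:
            continue
        inst = list(zip(grp["protein_id"], normalize_dsdr(grp["dsdr"].to_numpy())))
        for scope in ("within_protein", "across_proteins"):
            rec = pairwise_variation(family, species, inst, scope)
            if rec.applicable:
                out.append(rec)
    return out


def variation_table(records: Iterable[VariationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "family_id": r.family_id,
                "scope": r.scope,
                "n_pairs": len(r.pair_values),
                "max_variation": max(r.pair_values) if r.pair_values else float("nan"),
                "variation_dominant": r.variation_dominant or "no_dominant_category",
            }
            for r in records
        ],
        columns=[
            "species_id", "family_id", "scope", "n_pairs", "max_variation",
            "variation_dominant",
        ],
    )


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float
    direction: str  # "within_higher" | "across_higher" | "none"
    defined: bool = True


def no_variation_proportion_test(
    within_no: int, within_other: int, across_no: int, across_other: int
) -> FisherResult:
    """Two-sided Fisher exact test comparing the proportion of the
    no-variation dominant category between families repeating within one
    protein and families repeating across proteins."""
    table = ((within_no, within_other), (across_no, across_other))
    margins = (
        within_no + within_other,
        across_no + across_other,
        within_no + across_no,
        within_other + across_other,
    )
    if 0 in margins:
        return FisherResult(table, float("nan"), float("nan"), "none", defined=False)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    pw = within_no / (within_no + within_other)
    pa = across_no / (across_no + across_other)
    direction = (
        "within_higher" if pw > pa else "across_higher" if pa > pw else "none"
    )
    return FisherResult(table, float(p), float(odds), direction)


def no_variation_tests_by_species(records: Iterable[VariationRecord]) -> pd.DataFrame:
    """Per-species 2x2 Fisher tests of the no-variation proportion, within-
    protein scope against across-protein scope."""
    df = variation_table(records)
    rows = []
    for species, grp in df.groupby("species_id", sort=True):
        counts = {}
        for scope in ("within_protein", "across_proteins"):
            sub = grp[grp["scope"] == scope]
            no = int((sub["variation_dominant"] == "no_variation").sum())
            counts[scope] = (no, len(sub) - no)
        res = no_variation_proportion_test(
            *counts["within_protein"], *counts["across_proteins"]
        )
        rows.append(
            {
                "species_id": species,
                "within_no": counts["within_protein"][0],
                "within_other": counts["within_protein"][1],
                "across_no": counts["across_proteins"][0],
                "across_other": counts["across_proteins"][1],
                "p_value": res.p_value,
                "direction": res.direction,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)


def compare_family_disorder_between_clades(
    medians_a: dict[str, float],
    medians_b: dict[str, float],
    delta_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify families shared by two clades by the difference of their
    median normalized DSDR: higher_in_a / higher_in_b when |Δ| exceeds
    ``delta_threshold`` (default one grade step on the normalized scale),
    similar otherwise."""
    shared = sorted(set(medians_a) & set(medians_b))
    rows = []
    for fam in shared:
        delta = medians_a[fam] - medians_b[fam]
        if delta > delta_threshold:
            verdict = "higher_in_a"
        elif delta < -delta_threshold:
            verdict = "higher_in_b"
        else:
            verdict = "similar"
        rows.append({"family_id": fam, "delta": delta, "verdict": verdict})
    return pd.DataFrame(rows, columns=["family_id", "delta", "verdict"])
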