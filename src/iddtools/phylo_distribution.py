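"""Species-distribution width, domain age grades and disordered width.

The taxonomic breadth of the species carrying a domain family serves as a
proxy for the family's evolutionary origin time: a family confined to one
species is young, a family shared across superkingdoms is ancient. Lineages
come from a user-supplied ranked-lineage table (root first); no tree
inference happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .records import LineageTable

# ---------------------------------------------------------------------------
# Distribution width

#: A scheme is an ordered list of (category name, predicate). The predicate
#: receives the list of lineages (tuples of taxon names, root first) of the
#: species carrying the family; the first matching category wins.
SchemePredicate = Callable[[list[tuple[str, ...]]], bool]
Scheme = Sequence[tuple[str, SchemePredicate]]


def _shared_depth(lineages: list[tuple[str, ...]]) -> int:
    """Depth (0 = root rank) of the deepest rank on which all lineages
    agree; -1 when they disagree already at the root."""
    depth = -1
    for level in zip(*lineages):
        if len(set(level)) != 1:
            break
        depth += 1
    return depth


def _rank_specific(offset_from_species: int) -> SchemePredicate:
    """All lineages agree on the taxon *offset_from_species* ranks above the
    species level. End-anchored so a virtual common root prepended to mixed-
    superkingdom tables does not shift the ranks."""

    def pred(lineages: list[tuple[str, ...]]) -> bool:
        idx = -(offset_from_species + 1)
        if any(len(lin) < offset_from_species + 1 for lin in lineages):
            return False
        return len({lin[idx] for lin in lineages}) == 1

    return pred


def default_scheme() -> Scheme:
    """Default width scheme for lineages laid out as
    (superkingdom, kingdom, phylum, species).

    Categories, narrowest first: species_specific (one species),
    phylum_specific, kingdom_specific, superkingdom_specific, and shared
    (present in more than one superkingdom). Supply a custom scheme for
    other lineage layouts.
    """
    def species_specific(lineages):
        return len(lineages) == 1

    return [
        ("species_specific", species_specific),
        ("phylum_specific", _rank_specific(1)),
        ("kingdom_specific", _rank_specific(2)),
        ("superkingdom_specific", _rank_specific(3)),
        ("shared_across_superkingdoms", lambda lineages: True),
    ]


@dataclass
class DistributionWidth:
    family_id: str
    n_species: int
    category: str


def distribution_width(
    family_id: str,
    species_ids: Sequence[str],
    lineage_table: LineageTable,
    scheme: Optional[Scheme] = None,
) -> DistributionWidth:
    """Width category of one family from the lineages of the species that
    carry it; the first matching category of the (ordered) scheme wins."""
    if not species_ids:
        raise ValueError(f"{family_id}: no species")
    missing = [s for s in species_ids if s not in lineage_table]
    if missing:
        raise KeyError(f"{family_id}: species missing from lineage table: {missing}")
    scheme = scheme if scheme is not None else default_scheme()
    lineages = [lineage_table[s] for s in species_ids]
    for name, pred in scheme:
        if pred(lineages):
            return DistributionWidth(family_id, len(set(species_ids)), name)
    raise ValueError(f"{family_id}: no scheme category matched")


# ---------------------------------------------------------------------------
# Domain age


@dataclass
class AgeGrade:
    family_id: str
    representative_species: str
    grade: str  # taxon name on the representative's lineage
    grade_depth: int  # 0 = root


def domain_age(
    family_id: str,
    species_ids: Sequence[str],
    representative_species: str,
    lineage_table: LineageTable,
) -> AgeGrade:
    """Age grade of a family for one representative species: the taxon on
    the representative's lineage at the depth of the lowest common ancestor
    of every species carrying the family. Disjoint lineages resolve to the
    root."""
    if representative_species not in species_ids:
        raise ValueError(
            f"{family_id}: representative {representative_species} does not "
            "carry the family"
        )
    depth = lineage_table.lca_depth(list(species_ids))
    rep_lineage = lineage_table[representative_species]
    depth = min(depth, len(rep_lineage) - 1)
    return AgeGrade(family_id, representative_species, rep_lineage[depth], depth)


# ---------------------------------------------------------------------------
# Disordered width


@dataclass
class DisorderedWidth:
    family_id: str
    n_species: int
    pct_species_idd: float

    @property
    def widely_disordered(self) -> bool:
        return self.pct_species_idd > 50.0


def disordered_width(family_id: str, idd_calls: dict[str, bool]) -> DisorderedWidth:
    """Percentage of family-carrying species in which the family is an IDD.
    ``idd_calls`` maps species -> per-species family IDD call (by default
    the family dominant-category rule: dominant category intrinsically
    disordered or any instance with a CDR)."""
    if not idd_calls:
        raise ValueError(f"{family_id}: no species")
    n = len(idd_calls)
    pct = 100.0 * sum(bool(v) for v in idd_calls.values()) / n
    return DisorderedWidth(family_id, n, pct)


def disordered_width_table(family_df: pd.DataFrame) -> pd.DataFrame:
    """Disordered width for every family of a family-profile table (from
    :func:`iddtools.family_categories.family_profiles`)."""
    rows = []
    for fam, grp in family_df.groupby("family_id", sort=True):
        calls = dict(zip(grp["species_id"], grp["is_idd_family"]))
        w = disordered_width(fam, calls)
        rows.append(
            {
                "family_id": fam,
                "n_species": w.n_species,
                "pct_species_idd": w.pct_species_idd,
                "widely_disordered": w.widely_disordered,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family_id", "n_species", "pct_species_idd", "widely_disordered"],
    )


# ---------------------------------------------------------------------------
# IDD fraction by age grade


def idd_fraction_by_age(
    domain_df: pd.DataFrame, age_grades: dict[str, AgeGrade]
) -> pd.DataFrame:
    """Per age grade of one representative species: the fraction of domain
    instances (and of families) that are intrinsically disordered. Families
    without an age grade are skipped; empty grades do not appear."""
    df = domain_df.copy()
    df["grade_depth"] = df["family_id"].map(
        lambda f: age_grades[f].grade_depth if f in age_grades else None
    )
    df = df[df["grade_depth"].notna()]
    rows = []
    for depth, grp in df.groupby("grade_depth", sort=True):
        fam_idd = grp.groupby("family_id")["is_idd"].mean() > 0.5
        rows.append(
            {
                "grade_depth": int(depth),
                "grade": next(
                    a.grade for a in age_grades.values() if a.grade_depth == depth
                ),
                "n_instances": len(grp),
                "idd_fraction_instances": float(grp["is_idd"].mean()),
                "n_families": int(grp["family_id"].nunique()),
                "idd_fraction_families": float(fam_idd.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "grade_depth", "grade", "n_instances", "idd_fraction_instances",
            "n_families", "idd_fraction_families",
        ],
    )
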