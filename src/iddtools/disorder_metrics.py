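"""Per-domain and per-region disorder metrics.

Two measures quantify the disorder of a protein domain:

* **DSDR** (domain structural disorder ratio) — the percentage of predicted
  disordered residues within the domain;
* **CDRN** — the number of consecutive disordered regions (CDRs). For
  domains longer than 50 residues a CDR is a maximal run of more than 20
  consecutive disordered residues; for domains of 50 residues or fewer it is
  a maximal run covering more than 40% of the domain length.

A domain is an intrinsically disordered domain (IDD) when DSDR > 30% or
CDRN >= 1. The same operators apply to whole proteins (PSDR, IDP when
PSDR > 30%) and to non-domain regions (linkers and termini).

All thresholds are strict on the disordered side: DSDR exactly 30 is not an
IDD, a run of exactly 20 residues is not a CDR, and a run of exactly 40% of
a short domain is not a CDR. Boundary values therefore fall to the
structured side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import DisorderProfile, DomainInstance, ProteinRecord

DSDR_GRADES = (
    "completely_structured",
    "highly_structured",
    "moderately_unstructured",
    "intrinsically_disordered",
)

#: domains longer than this use the absolute run-length CDR rule
LONG_DOMAIN_CUTOFF = 50
#: minimal qualifying run for long domains is ``> CDR_MIN_RUN``
CDR_MIN_RUN = 20
#: minimal qualifying run fraction for short domains is ``> CDR_MIN_FRACTION``
CDR_MIN_FRACTION = 0.40
#: IDD / IDP percentage cutoff, strict
IDD_DSDR_CUTOFF = 30.0


@dataclass
class RegionMetrics:
    """Disorder metrics for one region (domain instance or non-domain)."""

    length: int
    n_disordered: int
    dsdr: float
    cdr_intervals: list[tuple[int, int]]  # 0-based half-open, within region
    cdrn: int
    dsdr_grade: str
    quadrant: str
    is_idd: bool


def compute_dsdr(calls: np.ndarray, start: int = 0, end: Optional[int] = None) -> float:
    """Percentage of disordered residues in ``calls[start:end]`` (0-based
    half-open). Raises on an empty interval."""
    calls = np.asarray(calls, dtype=bool)
    if end is None:
        end = len(calls)
    if not (0 <= start < end <= len(calls)):
        raise ValueError(f"empty or out-of-bounds interval [{start}, {end})")
    window = calls[start:end]
    return 100.0 * float(np.count_nonzero(window)) / window.size


def maximal_runs(calls: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True values as 0-based half-open (start, end) pairs."""
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        return []
    padded = np.concatenate(([False], calls, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def find_cdrs(
    calls: np.ndarray, start: int = 0, end: Optional[int] = None
) -> list[tuple[int, int]]:
    """Consecutive disordered regions within ``calls[start:end]``.

    Returned intervals are 0-based half-open, relative to the region start,
    in coordinate order. A run qualifies when its length exceeds 20 residues
    (regions longer than 50) or exceeds 40% of the region length (regions of
    at most 50 residues).
    """
    calls = np.asarray(calls, dtype=bool)
    if end is None:
        end = len(calls)
    if not (0 <= start < end <= len(calls)):
        raise ValueError(f"empty or out-of-bounds interval [{start}, {end})")
    region = calls[start:end]
    n = region.size
    if n > LONG_DOMAIN_CUTOFF:
        min_len = CDR_MIN_RUN + 1
    else:
        # strict "> 40%" in exact integer arithmetic: smallest L with 5L > 2n
        min_len = (2 * n) // 5 + 1
    runs = maximal_runs(region)
    return [(a, b) for a, b in runs if b - a >= min_len]


def classify_dsdr_grade(dsdr: float) -> str:
    """Four-grade classification: 0 | (0,10] | (10,30] | (30,100]."""
    if not (0.0 <= dsdr <= 100.0):
        raise ValueError(f"DSDR {dsdr} outside [0, 100]")
    if dsdr == 0.0:
        return "completely_structured"
    if dsdr <= 10.0:
        return "highly_structured"
    if dsdr <= IDD_DSDR_CUTOFF:
        return "moderately_unstructured"
    return "intrinsically_disordered"


def classify_quadrant(dsdr: float, cdrn: int) -> str:
    """DSDR x CDRN quadrant: I (high DSDR, has CDR), II (low DSDR, has CDR),
    III (low DSDR, no CDR), IV (high DSDR, no CDR)."""
    high = dsdr > IDD_DSDR_CUTOFF
    has_cdr = cdrn >= 1
    if high and has_cdr:
        return "I"
    if has_cdr:
        return "II"
    if high:
        return "IV"
    return "III"


def region_metrics(
    calls: np.ndarray, start: int = 0, end: Optional[int] = None
) -> RegionMetrics:
    """All disorder metrics for one region of a per-residue call vector."""
    calls = np.asarray(calls, dtype=bool)
    if end is None:
        end = len(calls)
    dsdr = compute_dsdr(calls, start, end)
    cdrs = find_cdrs(calls, start, end)
    cdrn = len(cdrs)
    return RegionMetrics(
        length=end - start,
        n_disordered=int(np.count_nonzero(calls[start:end])),
        dsdr=dsdr,
        cdr_intervals=cdrs,
        cdrn=cdrn,
        dsdr_grade=classify_dsdr_grade(dsdr),
        quadrant=classify_quadrant(dsdr, cdrn),
        is_idd=(dsdr > IDD_DSDR_CUTOFF) or (cdrn >= 1),
    )


def domain_metrics(profile: DisorderProfile, domain: DomainInstance) -> RegionMetrics:
    if domain.end > len(profile):
        raise ValueError(
            f"{domain.protein_id}/{domain.family_id}: domain end {domain.end} "
            f"beyond profile length {len(profile)}"
        )
    return region_metrics(profile.calls, domain.start - 1, domain.end)


@dataclass
class ProteinMetrics:
    protein_id: str
    psdr: float
    is_idp: bool


def compute_protein_metrics(profile: DisorderProfile) -> ProteinMetrics:
    """Whole-protein disorder ratio; IDP when PSDR > 30%."""
    psdr = compute_dsdr(profile.calls)
    return ProteinMetrics(profile.protein_id, psdr, psdr > IDD_DSDR_CUTOFF)


def representative_proteins(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One representative per gene: the longest protein, ties broken by the
    lexicographically smallest protein id. Records without a gene id are
    their own representative."""
    best: dict[str, ProteinRecord] = {}
    for rec in records:
        key = rec.gene_id or rec.protein_id
        cur = best.get(key)
        if cur is None or (len(rec), _neg_lex(rec.protein_id)) > (
            len(cur),
            _neg_lex(cur.protein_id),
        ):
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.protein_id)


def _neg_lex(s: str):
    # invert lexicographic order so that max() prefers the smaller id
    return tuple(-ord(c) for c in s)


def non_domain_regions(
    protein_length: int, domains: Sequence[DomainInstance]
) -> list[tuple[int, int]]:
    """Complement of the union of domain intervals over one protein, as
    0-based half-open intervals in coordinate order (linkers and termini)."""
    occupied = np.zeros(protein_length, dtype=bool)
    for d in domains:
        if d.end > protein_length:
            raise ValueError(f"domain {d.family_id} beyond protein end")
        occupied[d.slice()] = True
    return maximal_runs(~occupied)


def domain_table(
    profiles: dict[str, DisorderProfile], domains: Sequence[DomainInstance]
) -> pd.DataFrame:
    """Per-domain-instance metrics table (one row per retained Pfam hit)."""
    rows = []
    for d in domains:
        prof = profiles.get(d.protein_id)
        if prof is None:
            raise KeyError(f"no disorder profile for protein {d.protein_id}")
        m = domain_metrics(prof, d)
        rows.append(
            {
                "protein_id": d.protein_id,
                "species_id": d.species_id,
                "family_id": d.family_id,
                "family_name": d.family_name,
                "start": d.start,
                "end": d.end,
                "length": m.length,
                "n_disordered": m.n_disordered,
                "dsdr": m.dsdr,
                "cdrn": m.cdrn,
                "dsdr_grade": m.dsdr_grade,
                "quadrant": m.quadrant,
                "is_idd": m.is_idd,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "species_id", "family_id", "family_name", "start",
            "end", "length", "n_disordered", "dsdr", "cdrn", "dsdr_grade",
            "quadrant", "is_idd",
        ],
    )


def species_summary(
    domain_df: pd.DataFrame,
    protein_metrics: Optional[Sequence[ProteinMetrics]] = None,
) -> dict:
    """Species-level disorder summary.

    Percentages of IDDs by the DSDR rule (DSDR > 30) and by the CDRN rule
    (CDRN >= 1) — these are the X and Y coordinates of the per-species
    DSDR-vs-CDRN scatter — plus quadrant percentages, and protein-level
    figures when protein metrics are supplied. Percentages are reported as
    NaN when there is nothing to count.
    """
    n_domains = len(domain_df)
    out: dict = {"n_domains": n_domains}
    if n_domains:
        out["pct_idd_dsdr"] = 100.0 * float((domain_df["dsdr"] > IDD_DSDR_CUTOFF).mean())
        out["pct_idd_cdrn"] = 100.0 * float((domain_df["cdrn"] >= 1).mean())
        out["pct_idd"] = 100.0 * float(domain_df["is_idd"].mean())
        for q in ("I", "II", "III", "IV"):
            out[f"pct_class_{q}"] = 100.0 * float((domain_df["quadrant"] == q).mean())
    else:
        out.update(
            {k: float("nan")
             for k in ("pct_idd_dsdr", "pct_idd_cdrn", "pct_idd",
                       "pct_class_I", "pct_class_II", "pct_class_III", "pct_class_IV")}
        )
    if protein_metrics is not None:
        n = len(protein_metrics)
        out["n_proteins"] = n
        out["mean_psdr"] = (
            float(np.mean([p.psdr for p in protein_metrics])) if n else float("nan")
        )
        out["pct_idp"] = (
            100.0 * float(np.mean([p.is_idp for p in protein_metrics])) if n else float("nan")
        )
    return out
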