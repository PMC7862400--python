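"""Post-translational-modification density by domain disorder class.

"Proportion of PTM sites" is read as sites per residue within a category,
the only unit comparable across categories of different sizes. Per-domain
proportions are also retained so that categories can be compared with the
Mann–Whitney test, mirroring box-plot style comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .disorder_metrics import DisorderProfile, RegionMetrics, domain_metrics
from .records import DomainInstance, PTMSite
from .stats_enrichment import EnrichmentResult, enrich

logger = logging.getLogger(__name__)


@dataclass
class PTMDensity:
    category: str
    n_sites: int
    n_residues: int

    @property
    def proportion(self) -> float:
        return self.n_sites / self.n_residues if self.n_residues else float("nan")


def classify_by_grade(m: RegionMetrics) -> str:
    return m.dsdr_grade


def classify_by_cdrn(m: RegionMetrics) -> str:
    if m.cdrn == 0:
        return "no_cdr"
    return "one_cdr" if m.cdrn == 1 else "multiple_cdrs"


def ptm_density_by_class(
    domains: Sequence[DomainInstance],
    profiles: dict[str, DisorderProfile],
    sites: Sequence[PTMSite],
    classifier: Callable[[RegionMetrics], str] = classify_by_grade,
) -> tuple[list[PTMDensity], pd.DataFrame]:
    """PTM-site density per domain disorder class.

    Returns pooled per-category densities and a per-domain table (one row
    per domain with its category, site count and per-domain proportion) for
    rank-test comparisons. Sites on proteins absent from the domain table or
    outside every domain are counted in no category (logged at debug level).
    """
    sites_by_protein: dict[str, list[PTMSite]] = {}
    for s in sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)

    pooled: dict[str, list[int]] = {}
    rows = []
    used = 0
    for d in domains:
        prof = profiles.get(d.protein_id)
        if prof is None:
            raise KeyError(f"no disorder profile for protein {d.protein_id}")
        m = domain_metrics(prof, d)
        cat = classifier(m)
        in_domain = [
            s for s in sites_by_protein.get(d.protein_id, [])
            if d.start <= s.position <= d.end
        ]
        used += len(in_domain)
        pooled.setdefault(cat, [0, 0])
        pooled[cat][0] += len(in_domain)
        pooled[cat][1] += m.length
        rows.append(
            {
                "protein_id": d.protein_id,
                "family_id": d.family_id,
                "category": cat,
                "n_sites": len(in_domain),
                "length": m.length,
                "proportion": len(in_domain) / m.length,
            }
        )
    n_total = sum(len(v) for v in sites_by_protein.values())
    if used < n_total:
        logger.debug("%d of %d PTM sites fall in no domain", n_total - used, n_total)
    densities = [
        PTMDensity(cat, counts[0], counts[1]) for cat, counts in sorted(pooled.items())
    ]
    per_domain = pd.DataFrame(
        rows,
        columns=["protein_id", "family_id", "category", "n_sites", "length", "proportion"],
    )
    return densities, per_domain


def cdr_vs_noncdr_density(
    domains: Sequence[DomainInstance],
    profiles: dict[str, DisorderProfile],
    sites: Sequence[PTMSite],
) -> pd.DataFrame:
    """For every IDD that has at least one CDR: PTM density inside its CDRs
    versus in the rest of the domain. Domains without a CDR are excluded.
    Site counts over the two parts always sum to the whole-domain count."""
    sites_by_protein: dict[str, list[int]] = {}
    for s in sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s.position)
    rows = []
    for d in domains:
        prof = profiles[d.protein_id]
        m = domain_metrics(prof, d)
        if not m.is_idd or m.cdrn == 0:
            continue
        cdr_res = sum(b - a for a, b in m.cdr_intervals)
        positions = sites_by_protein.get(d.protein_id, [])
        in_domain = [p - d.start for p in positions if d.start <= p <= d.end]
        in_cdr = sum(
            any(a <= p < b for a, b in m.cdr_intervals) for p in in_domain
        )
        rows.append(
            {
                "protein_id": d.protein_id,
                "family_id": d.family_id,
                "cdr_sites": in_cdr,
                "cdr_residues": cdr_res,
                "cdr_density": in_cdr / cdr_res,
                "noncdr_sites": len(in_domain) - in_cdr,
                "noncdr_residues": m.length - cdr_res,
                "noncdr_density": (
                    (len(in_domain) - in_cdr) / (m.length - cdr_res)
                    if m.length > cdr_res
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "family_id", "cdr_sites", "cdr_residues",
            "cdr_density", "noncdr_sites", "noncdr_residues", "noncdr_density",
        ],
    )


def ptm_type_enrichment(
    domains: Sequence[DomainInstance],
    profiles: dict[str, DisorderProfile],
    sites: Sequence[PTMSite],
) -> list[EnrichmentResult]:
    """Over/under-representation of each modification type among the sites
    falling in IDDs, against all sites falling in any domain as universe.
    Mod types are compared at the description-string level (e.g.
    "Phosphoserine")."""
    sites_by_protein: dict[str, list[PTMSite]] = {}
    for s in sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)
    site_ids: list[str] = []
    seen: set[str] = set()
    in_idd: list[str] = []
    ann_rows = []
    for d in domains:
        prof = profiles[d.protein_id]
        m = domain_metrics(prof, d)
        for s in sites_by_protein.get(d.protein_id, []):
            if d.start <= s.position <= d.end:
                sid = f"{s.protein_id}:{s.position}:{s.mod_type}"
                if sid not in seen:
                    seen.add(sid)
                    site_ids.append(sid)
                    ann_rows.append({"family_id": sid, "term": s.mod_type})
                if m.is_idd:
                    in_idd.append(sid)
    if not site_ids:
        return []
    annotation = pd.DataFrame(ann_rows)
    return enrich(set(in_idd), site_ids, annotation)
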