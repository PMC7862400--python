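"""Config-driven end-to-end runs over one input bundle.

Each ``run_*`` function loads what it needs through :mod:`iddtools.io_formats`,
executes the corresponding analyses and writes deterministic TSV outputs plus
a ``run_metadata.json`` echoing the configuration. The published analysis
constants (IDD at DSDR > 30, CDR run > 20 / > 40%, dominant category > 0.5,
variation bins 0 / (0,1] / (1,3]) are fixed; only the disorder-call
threshold and scheme selections are configurable, and every override is
echoed into the run metadata.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .disorder_metrics import (
    compute_protein_metrics,
    domain_table,
    representative_proteins,
    species_summary,
)
from .family_categories import (
    family_profiles,
    no_variation_tests_by_species,
    variation_records,
    variation_table,
)
from .phylo_distribution import disordered_width_table
from .ptm_analysis import classify_by_cdrn, classify_by_grade, ptm_density_by_class
from .similarity import similarity_table
from .stats_enrichment import enrichment_table, enrich, spearman

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and the few tunables of one pipeline run."""

    disorder_path: str
    domains_path: str
    outdir: str
    fasta_path: Optional[str] = None
    lineage_path: Optional[str] = None
    cell_types_path: Optional[str] = None
    annotation_path: Optional[str] = None
    ptm_path: Optional[str] = None
    blast_path: Optional[str] = None
    call_threshold: float = 0.5
    deoverlap: bool = False
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_metadata(config: RunConfig, stage: str, timings: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "seed": config.seed,
        "call_threshold": config.call_threshold,
        "deoverlap": config.deoverlap,
        "overrides": config.overrides,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _load_core(config: RunConfig):
    profiles = {
        p.protein_id: p
        for p in io_formats.read_disorder_scores(
            config.disorder_path, config.call_threshold
        )
    }
    domains = io_formats.read_domtblout(
        config.domains_path, deoverlap=config.deoverlap
    )
    missing = sorted({d.protein_id for d in domains} - set(profiles))
    if missing:
        raise FileNotFoundError(
            f"domains reference proteins with no disorder profile: {missing[:5]}"
        )
    # species identity rides on the FASTA description (species= token); a
    # domtblout alone carries none
    if config.fasta_path:
        species_map = {
            r.protein_id: r.species_id
            for r in io_formats.read_fasta(config.fasta_path)
            if r.species_id
        }
        for d in domains:
            if not d.species_id:
                d.species_id = species_map.get(d.protein_id, "")
    return profiles, domains


def run_profile(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-domain metrics and per-species summaries."""
    t0 = time.monotonic()
    profiles, domains = _load_core(config)
    species_of = {d.protein_id: d.species_id for d in domains}
    df = domain_table(profiles, domains)
    if df.empty:
        raise ValueError("no domains retained; nothing to profile")

    prot_metrics_by_species: dict[str, list] = {}
    if config.fasta_path:
        records = io_formats.read_fasta(config.fasta_path)
        for rec in representative_proteins(records):
            if rec.protein_id in profiles:
                sid = species_of.get(rec.protein_id, rec.species_id)
                prot_metrics_by_species.setdefault(sid, []).append(
                    compute_protein_metrics(profiles[rec.protein_id])
                )

    rows = []
    for sid, grp in df.groupby("species_id", sort=True):
        summary = species_summary(grp, prot_metrics_by_species.get(sid))
        summary["species_id"] = sid
        rows.append(summary)
    species_df = pd.DataFrame(rows).set_index("species_id").reset_index()
    fam_df = family_profiles(df)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "domain_metrics.tsv", sep="\t", index=False)
    species_df.to_csv(outdir / "species_summary.tsv", sep="\t", index=False)
    fam_df.to_csv(outdir / "family_profiles.tsv", sep="\t", index=False)
    _write_metadata(config, "profile", {"total": time.monotonic() - t0})
    return {"domains": df, "species": species_df, "families": fam_df}


def run_correlate(config: RunConfig) -> pd.DataFrame:
    """Spearman correlations of six disorder measures against organism
    complexity (cell-type number), one row per measure: mean PSDR, %IDP,
    %IDD by DSDR, %IDD by CDRN, %IDD families by DSDR dominant category,
    %IDD families by family CDR flag."""
    if not config.cell_types_path:
        raise ValueError("correlate requires cell_types_path")
    t0 = time.monotonic()
    tables = run_profile(config)
    cell = io_formats.read_cell_type_table(config.cell_types_path)
    species_df = tables["species"].set_index("species_id")
    fam = tables["families"]
    fam_by_species = fam.groupby("species_id").agg(
        pct_idd_fam_dsdr=(
            "dominant_category",
            lambda s: 100.0 * float((s == "intrinsically_disordered").mean()),
        ),
        pct_idd_fam_cdrn=("family_cdrn_flag", lambda s: 100.0 * float(s.mean())),
    )
    joined = species_df.join(fam_by_species).join(cell.rename("cell_types"))
    joined = joined[joined["cell_types"].notna()]
    measures = [
        ("mean_psdr", "mean PSDR"),
        ("pct_idp", "% disordered proteins (PSDR > 30)"),
        ("pct_idd_dsdr", "% IDDs (DSDR > 30)"),
        ("pct_idd_cdrn", "% IDDs (CDRN >= 1)"),
        ("pct_idd_fam_dsdr", "% IDD families (dominant DSDR grade)"),
        ("pct_idd_fam_cdrn", "% IDD families (family CDRN >= 1)"),
    ]
    rows = []
    for col, label in measures:
        if col not in joined.columns or joined[col].isna().all():
            continue
        sub = joined[joined[col].notna()]
        if len(sub) < 3:
            continue
        res = spearman(sub["cell_types"], sub[col], measure=label)
        rows.append(
            {"measure": label, "rho": res.rho, "p": res.p, "n": res.n,
             "defined": res.defined}
        )
    out = pd.DataFrame(rows, columns=["measure", "rho", "p", "n", "defined"])
    outdir = Path(config.outdir)
    out.to_csv(outdir / "complexity_correlations.tsv", sep="\t", index=False)
    _write_metadata(config, "correlate", {"total": time.monotonic() - t0})
    return out


def run_variation(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Pairwise DSDR-variation records for repeating families plus the
    per-species Fisher tests of the no-variation proportion."""
    t0 = time.monotonic()
    profiles, domains = _load_core(config)
    df = domain_table(profiles, domains)
    records = variation_records(df)
    var_df = variation_table(records)
    fisher_df = no_variation_tests_by_species(records)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    var_df.to_csv(outdir / "variation_records.tsv", sep="\t", index=False)
    fisher_df.to_csv(outdir / "no_variation_fisher.tsv", sep="\t", index=False)
    out = {"variation": var_df, "fisher": fisher_df}
    if config.blast_path:
        sim = similarity_table(io_formats.read_blast_tabular(config.blast_path))
        sim.to_csv(outdir / "similarity.tsv", sep="\t", index=False)
        out["similarity"] = sim
    _write_metadata(config, "variation", {"total": time.monotonic() - t0})
    return out


def run_enrich(config: RunConfig) -> pd.DataFrame:
    """Term over/under-representation of IDD families against all families,
    per species and pooled, written as a long table and a grade matrix."""
    if not config.annotation_path:
        raise ValueError("enrich requires annotation_path")
    t0 = time.monotonic()
    profiles, domains = _load_core(config)
    df = domain_table(profiles, domains)
    fam = family_profiles(df)
    annotation = io_formats.read_annotation_table(config.annotation_path)
    universe = sorted(fam["family_id"].unique())
    selection = sorted(fam.loc[fam["is_idd_family"], "family_id"].unique())
    results = enrich(selection, universe, annotation)
    table = enrichment_table(results)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    table.set_index("term")[["grade"]].rename(columns={"grade": "idd_families"}).to_csv(
        outdir / "grade_matrix.tsv", sep="\t"
    )
    _write_metadata(config, "enrich", {"total": time.monotonic() - t0})
    return table


def run_all(config: RunConfig) -> dict:
    """profile + correlate/variation/enrich where inputs permit, plus the
    disordered-width table."""
    out: dict = {"profile": run_profile(config)}
    fam = out["profile"]["families"]
    width = disordered_width_table(fam)
    width.to_csv(Path(config.outdir) / "disordered_width.tsv", sep="\t", index=False)
    out["disordered_width"] = width
    if config.cell_types_path:
        out["correlate"] = run_correlate(config)
    out["variation"] = run_variation(config)
    if config.annotation_path:
        out["enrich"] = run_enrich(config)
    if config.ptm_path:
        profiles, domains = _load_core(config)
        sites = io_formats.read_ptm_table(config.ptm_path)
        densities, per_domain = ptm_density_by_class(
            domains, profiles, sites, classify_by_grade
        )
        ptm_df = pd.DataFrame(
            [
                {"category": d.category, "n_sites": d.n_sites,
                 "n_residues": d.n_residues, "proportion": d.proportion}
                for d in densities
            ]
        )
        ptm_df.to_csv(Path(config.outdir) / "ptm_density.tsv", sep="\t", index=False)
        out["ptm_density"] = ptm_df
    return out
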