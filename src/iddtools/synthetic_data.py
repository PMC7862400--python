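"""Seeded generator of synthetic proteome bundles.

The generator emulates the statistical structure the downstream analyses
assume: block-structured per-residue disorder calls (alternating ordered /
disordered blocks with geometric lengths, so consecutive-run statistics are
controllable independently of the overall disorder ratio), domain families
drawn from archetypes of known disorder propensity, clade-structured species
sets in which the fraction of disorder-prone families rises with organism
complexity (cell-type number), annotation tables with one planted enriched
term, and PTM sites planted at a higher per-residue density in disordered
residues. Sequences are uniform random residues; repeat-pair alignments are
constructed summaries rather than real BLAST runs.

Everything is driven by a single integer seed; identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .disorder_metrics import region_metrics
from .family_categories import dominant_category, normalize_dsdr
from .records import (
    AlignmentSummary,
    DisorderProfile,
    DomainInstance,
    LineageTable,
    ProteinRecord,
    PTMSite,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PTM_TYPES = ("Phosphoserine", "Phosphothreonine", "N6-acetyllysine", "Omega-N-methylarginine")


@dataclass
class Archetype:
    """Disorder behaviour of one family: per-residue disorder probability
    inside domain blocks, mean disordered block length (residues), and an
    optionally planted contiguous disordered block forcing a CDR."""

    name: str
    p_disordered: float
    mean_block: float = 8.0
    planted_cdr_len: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_disordered <= 1.0):
            raise ValueError("p_disordered outside [0, 1]")
        if self.planted_cdr_len < 0:
            raise ValueError("negative planted CDR length")


#: default archetypes: clearly structured, intermediate, and disorder-prone
DEFAULT_ARCHETYPES = (
    Archetype("structured", p_disordered=0.06, mean_block=3.0),
    Archetype("moderate", p_disordered=0.20, mean_block=5.0),
    Archetype("disordered", p_disordered=0.65, mean_block=15.0),
)


@dataclass
class CladeConfig:
    name: str
    lineage_prefix: tuple[str, ...]  # (superkingdom, kingdom, phylum)
    n_species: int
    complexity_range: tuple[float, float]  # cell-type numbers, low..high


DEFAULT_CLADES = (
    CladeConfig("Metazoa", ("Eukaryota", "Metazoa", "Chordata"), 6, (30.0, 300.0)),
    CladeConfig("Fungi", ("Eukaryota", "Fungi", "Ascomycota"), 4, (3.0, 30.0)),
    CladeConfig("Bacteria", ("Bacteria", "Proteobacteria", "Gammaproteobacteria"), 2, (1.0, 2.0)),
)


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    Defaults give a small clade-structured bundle with a positive
    complexity gradient (the fraction of disorder-prone families per species
    rises linearly with complexity rank from ``base_disordered_fraction`` by
    ``gradient_strength``), within- and across-protein family repetition,
    one annotation term planted at ``planted_odds_ratio`` among
    disorder-prone families, and PTM sites ``ptm_disordered_multiplier``
    times denser on disordered residues.
    """

    seed: int = 0
    clades: tuple[CladeConfig, ...] = DEFAULT_CLADES
    n_families: int = 60
    families_per_species: int = 30
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    base_disordered_fraction: float = 0.2
    gradient_strength: float = 0.4
    domain_length_range: tuple[int, int] = (60, 140)
    linker_length_range: tuple[int, int] = (15, 50)
    background_p_disordered: float = 0.05
    background_mean_block: float = 3.0
    p_repeat_within: float = 0.15
    p_repeat_across: float = 0.25
    n_terms: int = 20
    terms_per_family: int = 3
    planted_term: str = "T_planted"
    planted_odds_ratio: float = 5.0
    baseline_term_p: float = 0.15
    ptm_base_density: float = 0.01
    ptm_disordered_multiplier: float = 3.0
    call_threshold: float = 0.5

    def validate(self) -> None:
        if self.families_per_species > self.n_families:
            raise ValueError("families_per_species exceeds n_families")
        if self.domain_length_range[0] > self.domain_length_range[1]:
            raise ValueError("bad domain length range")
        probs = [
            self.base_disordered_fraction, self.p_repeat_within,
            self.p_repeat_across, self.baseline_term_p,
            self.background_p_disordered,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probability outside [0, 1]")
        if self.ptm_disordered_multiplier < 0:
            raise ValueError("negative PTM multiplier")


@dataclass
class SimBundle:
    """In-memory result of one simulation."""

    proteins: list[ProteinRecord]
    profiles: dict[str, DisorderProfile]
    domains: list[DomainInstance]
    lineage: LineageTable
    cell_types: pd.Series
    annotation: pd.DataFrame
    ptm_sites: list[PTMSite]
    alignments: list[AlignmentSummary]
    ground_truth: dict


# ---------------------------------------------------------------------------
# call-vector primitives


def block_calls(
    rng: np.random.Generator, length: int, p_disordered: float, mean_block: float
) -> np.ndarray:
    """Alternating ordered/disordered blocks with geometric lengths whose
    stationary disordered fraction is ``p_disordered``; mean disordered
    block length is ``mean_block``."""
    if length < 1:
        raise ValueError("length < 1")
    if p_disordered <= 0.0:
        return np.zeros(length, dtype=bool)
    if p_disordered >= 1.0:
        return np.ones(length, dtype=bool)
    mean_dis = max(mean_block, 1.0)
    mean_ord = max(mean_dis * (1.0 - p_disordered) / p_disordered, 1.0)
    out = np.empty(length, dtype=bool)
    pos = 0
    state = bool(rng.random() < p_disordered)
    while pos < length:
        mean = mean_dis if state else mean_ord
        run = int(rng.geometric(1.0 / mean))
        end = min(pos + run, length)
        out[pos:end] = state
        pos = end
        state = not state
    return out


def domain_calls(rng: np.random.Generator, length: int, archetype: Archetype) -> np.ndarray:
    calls = block_calls(rng, length, archetype.p_disordered, archetype.mean_block)
    if archetype.planted_cdr_len:
        if archetype.planted_cdr_len > length:
            raise ValueError("planted CDR longer than the domain")
        start = int(rng.integers(0, length - archetype.planted_cdr_len + 1))
        calls[start : start + archetype.planted_cdr_len] = True
    return calls


def scores_from_calls(
    rng: np.random.Generator, calls: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Per-residue scores consistent with the calls at the given threshold
    (disordered residues uniform in (threshold, 1], others in [0, threshold))."""
    n = len(calls)
    lo = rng.uniform(0.0, threshold * 0.9, size=n)
    hi = rng.uniform(threshold * 1.1, 1.0, size=n)
    return np.round(np.where(calls, hi, lo), 4)


# ---------------------------------------------------------------------------
# species layer


def _species_complexities(config: SimConfig, rng: np.random.Generator):
    """(species_id, lineage, cell_types) triples; cell-type numbers are
    log-uniform within each clade's range, jittered to avoid ties."""
    rows = []
    for clade in config.clades:
        lo, hi = clade.complexity_range
        vals = np.exp(
            np.linspace(np.log(lo), np.log(hi), clade.n_species)
            + rng.normal(0, 0.02, clade.n_species)
        )
        for i, v in enumerate(sorted(vals)):
            sid = f"{clade.name[:4].lower()}_{i:03d}"
            lineage = clade.lineage_prefix + (sid,)
            rows.append((sid, lineage, float(v)))
    return rows


def _assign_families(config: SimConfig, rng: np.random.Generator):
    """Family pool: ids, archetype index, annotation terms, planted term
    membership. Disorder-prone families receive the planted term at the
    configured odds ratio."""
    arch_idx = rng.integers(0, len(config.archetypes), size=config.n_families)
    p0 = config.baseline_term_p
    odds1 = config.planted_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    terms = [f"T{i:03d}" for i in range(config.n_terms)]
    fam_rows = []
    ann_rows = []
    for i in range(config.n_families):
        fid = f"PF{i:05d}"
        arch = config.archetypes[arch_idx[i]]
        fam_rows.append({"family_id": fid, "archetype": arch.name,
                         "p_disordered": arch.p_disordered})
        for t in rng.choice(terms, size=min(config.terms_per_family, len(terms)),
                            replace=False):
            ann_rows.append({"family_id": fid, "term": str(t)})
        p_term = p1 if arch.p_disordered > 0.3 else p0
        if rng.random() < p_term:
            ann_rows.append({"family_id": fid, "term": config.planted_term})
    return arch_idx, pd.DataFrame(fam_rows), pd.DataFrame(ann_rows)


def _pick_species_families(
    config: SimConfig, rng: np.random.Generator, arch_idx: np.ndarray, rank: float
) -> np.ndarray:
    """Family ids (indices) carried by one species: the probability of
    drawing from the disorder-prone pool rises with complexity rank."""
    q = min(config.base_disordered_fraction + config.gradient_strength * rank, 1.0)
    p_dis = np.array([config.archetypes[i].p_disordered for i in arch_idx])
    dis_pool = np.flatnonzero(p_dis > 0.3)
    str_pool = np.flatnonzero(p_dis <= 0.3)
    n = config.families_per_species
    n_dis = int(np.round(q * n))
    n_dis = min(n_dis, len(dis_pool))
    n_str = min(n - n_dis, len(str_pool))
    chosen = np.concatenate(
        [
            rng.choice(dis_pool, size=n_dis, replace=False),
            rng.choice(str_pool, size=n_str, replace=False),
        ]
    )
    return np.sort(chosen)


def generate(config: Optional[SimConfig] = None, seed: Optional[int] = None) -> SimBundle:
    """Generate a complete in-memory bundle under *config* (defaults plus an
    optional seed override). Deterministic in the seed."""
    config = config or SimConfig()
    if seed is not None:
        config = SimConfig(**{**asdict_shallow(config), "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)

    species = _species_complexities(config, rng)
    complexities = {sid: c for sid, _, c in species}
    ranks = pd.Series(complexities).rank(method="average")
    ranks = (ranks - 1) / max(len(ranks) - 1, 1)

    arch_idx, fam_truth, annotation = _assign_families(config, rng)

    proteins: list[ProteinRecord] = []
    profiles: dict[str, DisorderProfile] = {}
    domains: list[DomainInstance] = []
    ptm_sites: list[PTMSite] = []
    alignments: list[AlignmentSummary] = []
    domain_truth = []

    for sid, _, _ in species:
        fam_ids = _pick_species_families(config, rng, arch_idx, float(ranks[sid]))
        p_counter = 0
        for fi in fam_ids:
            arch = config.archetypes[arch_idx[fi]]
            fid = f"PF{fi:05d}"
            # repetition pattern for this family in this species
            u = rng.random()
            if u < config.p_repeat_within:
                layout = [2]  # two copies on one protein
            elif u < config.p_repeat_within + config.p_repeat_across:
                layout = [1, 1]  # one copy on each of two proteins
            else:
                layout = [1]
            for copies in layout:
                pid = f"{sid}_p{p_counter:04d}"
                p_counter += 1
                proteins_calls = []
                coords = []
                pos = 0
                for c in range(copies + 1):
                    llen = int(rng.integers(*config.linker_length_range))
                    proteins_calls.append(
                        block_calls(rng, llen, config.background_p_disordered,
                                    config.background_mean_block)
                    )
                    pos += llen
                    if c < copies:
                        dlen = int(rng.integers(config.domain_length_range[0],
                                                config.domain_length_range[1] + 1))
                        dcalls = domain_calls(rng, dlen, arch)
                        proteins_calls.append(dcalls)
                        coords.append((pos + 1, pos + dlen))  # 1-based inclusive
                        pos += dlen
                calls = np.concatenate(proteins_calls)
                seq = "".join(rng.choice(AMINO_ACIDS, size=len(calls)))
                scores = scores_from_calls(rng, calls, config.call_threshold)
                proteins.append(ProteinRecord(pid, seq, species_id=sid, gene_id=pid))
                profiles[pid] = DisorderProfile(
                    pid, calls, scores, config.call_threshold
                )
                for start, end in coords:
                    domains.append(
                        DomainInstance(
                            protein_id=pid, family_id=fid, family_name=arch.name,
                            start=start, end=end,
                            full_seq_evalue=float(rng.uniform(1e-30, 1e-3)),
                            c_evalue=float(rng.uniform(1e-30, 1e-3)),
                            species_id=sid,
                        )
                    )
                    window = calls[start - 1 : end]
                    domain_truth.append(
                        {
                            "protein_id": pid, "family_id": fid, "start": start,
                            "end": end,
                            "true_dsdr": 100.0 * float(window.mean()),
                            "archetype": arch.name,
                        }
                    )
                # PTM sites: Bernoulli per residue, denser where disordered
                p_site = np.where(
                    calls,
                    config.ptm_base_density * config.ptm_disordered_multiplier,
                    config.ptm_base_density,
                )
                hit = np.flatnonzero(rng.random(len(calls)) < p_site)
                for h in hit:
                    mod = PTM_TYPES[0] if calls[h] and rng.random() < 0.6 else (
                        PTM_TYPES[int(rng.integers(0, len(PTM_TYPES)))]
                    )
                    ptm_sites.append(PTMSite(pid, int(h) + 1, seq[h], mod))

    alignments = _repeat_alignments(rng, domains, profiles)

    lineage = LineageTable({sid: lin for sid, lin, _ in species})
    cell_types = pd.Series(complexities, name="cell_types").rename_axis("species_id")
    ground_truth = {
        "seed": config.seed,
        "planted_term": config.planted_term,
        "planted_odds_ratio": config.planted_odds_ratio,
        "gradient_strength": config.gradient_strength,
        "ptm_disordered_multiplier": config.ptm_disordered_multiplier,
        "complexities": complexities,
        "families": fam_truth.to_dict(orient="records"),
        "domains": domain_truth,
    }
    return SimBundle(
        proteins, profiles, domains, lineage, cell_types, annotation,
        ptm_sites, alignments, ground_truth,
    )


def asdict_shallow(config: SimConfig) -> dict:
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def _repeat_alignments(
    rng: np.random.Generator,
    domains: Sequence[DomainInstance],
    profiles: dict[str, DisorderProfile],
) -> list[AlignmentSummary]:
    """Constructed pairwise alignment summaries for repeat instances of the
    same family within one species. Percent identity is planted to co-vary
    with the pair's normalized-DSDR difference (low-similarity pairs get low
    variation), so rank statistics on the join have a known sign."""
    by_key: dict[tuple[str, str], list[DomainInstance]] = {}
    for d in domains:
        by_key.setdefault((d.species_id, d.family_id), []).append(d)
    out = []
    for key in sorted(by_key):
        insts = by_key[key]
        if len(insts) < 2:
            continue
        for a, b in zip(insts[:-1], insts[1:]):
            da = 100.0 * float(profiles[a.protein_id].calls[a.slice()].mean())
            db = 100.0 * float(profiles[b.protein_id].calls[b.slice()].mean())
            var = abs(normalize_dsdr(da) - normalize_dsdr(db))  # in [0, 3]
            ident = float(np.clip(20 + 25 * var + rng.normal(0, 3), 5, 100))
            qlen, slen = a.length, b.length
            span_q = max(int(qlen * rng.uniform(0.8, 1.0)), 1)
            q_start = int(rng.integers(1, qlen - span_q + 2))
            span_s = max(int(slen * rng.uniform(0.8, 1.0)), 1)
            s_start = int(rng.integers(1, slen - span_s + 2))
            out.append(
                AlignmentSummary(
                    query_id=f"{a.protein_id}/{a.start}-{a.end}",
                    subject_id=f"{b.protein_id}/{b.start}-{b.end}",
                    identity_pct=round(ident, 2),
                    aln_length=span_q,
                    query_len=qlen,
                    subject_len=slen,
                    q_start=q_start,
                    q_end=q_start + span_q - 1,
                    s_start=s_start,
                    s_end=s_start + span_s - 1,
                    evalue=float(rng.uniform(1e-20, 1.0)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# file emission


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write every table of a bundle in its external format plus the
    ground-truth ledger; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "disorder": outdir / "disorder_scores.tsv",
        "domains": outdir / "domains.domtblout",
        "lineage": outdir / "lineage.tsv",
        "cell_types": outdir / "cell_types.tsv",
        "annotation": outdir / "annotation.tsv",
        "ptm": outdir / "ptm_sites.tsv",
        "blast": outdir / "repeat_pairs.blast.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    io_formats.write_fasta(paths["fasta"], bundle.proteins)
    residues = {p.protein_id: p.sequence for p in bundle.proteins}
    io_formats.write_disorder_scores(
        paths["disorder"], list(bundle.profiles.values()), residues
    )
    lengths = {p.protein_id: len(p) for p in bundle.proteins}
    io_formats.write_domtblout(paths["domains"], bundle.domains, lengths)
    io_formats.write_lineage_table(paths["lineage"], bundle.lineage)
    io_formats.write_cell_type_table(paths["cell_types"], bundle.cell_types)
    io_formats.write_annotation_table(paths["annotation"], bundle.annotation)
    io_formats.write_ptm_table(paths["ptm"], bundle.ptm_sites)
    io_formats.write_blast_tabular(paths["blast"], bundle.alignments)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# fast family-level experiment for recovery studies


def gradient_experiment(
    seed: int,
    n_species: int = 51,
    families_per_species: int = 40,
    gradient_strength: float = 0.4,
    base_disordered_fraction: float = 0.2,
    n_families: int = 120,
    archetypes: Sequence[Archetype] = DEFAULT_ARCHETYPES,
    domain_length_range: tuple[int, int] = (60, 140),
) -> tuple[np.ndarray, np.ndarray]:
    """One complexity-gradient study at family level.

    Generates *n_species* species whose complexity rank sets the fraction of
    disorder-prone families they carry, materialises two domain instances
    per family as block-structured call vectors, and measures each species'
    percentage of intrinsically disordered families through the family
    dominant-category rule (dominant grade intrinsically disordered, or any
    instance with a CDR). Returns (cell-type numbers, IDD-family
    percentages), one entry per species.
    """
    rng = np.random.default_rng(seed)
    arch_idx = rng.integers(0, len(archetypes), size=n_families)
    p_dis = np.array([archetypes[i].p_disordered for i in arch_idx])
    dis_pool = np.flatnonzero(p_dis > 0.3)
    str_pool = np.flatnonzero(p_dis <= 0.3)
    complexities = np.exp(
        np.linspace(np.log(2.0), np.log(500.0), n_species)
        + rng.normal(0, 0.02, n_species)
    )
    order = np.argsort(np.argsort(complexities))
    ranks = order / max(n_species - 1, 1)
    pct_idd = np.empty(n_species)
    for s in range(n_species):
        q = min(base_disordered_fraction + gradient_strength * ranks[s], 1.0)
        n_dis = min(int(np.round(q * families_per_species)), len(dis_pool))
        n_str = min(families_per_species - n_dis, len(str_pool))
        chosen = np.concatenate(
            [
                rng.choice(dis_pool, size=n_dis, replace=False),
                rng.choice(str_pool, size=n_str, replace=False),
            ]
        )
        n_idd = 0
        for fi in chosen:
            arch = archetypes[arch_idx[fi]]
            grades, any_cdr = [], False
            for _ in range(2):  # two instances per family
                dlen = int(rng.integers(domain_length_range[0], domain_length_range[1] + 1))
                m = region_metrics(domain_calls(rng, dlen, arch))
                grades.append(m.dsdr_grade)
                any_cdr = any_cdr or m.cdrn >= 1
            dom = dominant_category(grades)
            if dom == "intrinsically_disordered" or any_cdr:
                n_idd += 1
        pct_idd[s] = 100.0 * n_idd / len(chosen)
    return complexities, pct_idd


def enrichment_experiment(
    seed: int,
    n_families: int = 200,
    odds_ratio: float = 5.0,
    n_terms: int = 20,
    archetypes: Sequence[Archetype] = DEFAULT_ARCHETYPES,
    domain_length_range: tuple[int, int] = (60, 140),
):
    """Recovery study for planted term enrichment.

    Families drawn from the default archetypes receive random annotation
    terms; disorder-prone families additionally receive the planted term at
    the configured odds ratio (odds_ratio = 1 plants nothing, the null).
    Each family is materialised as two block-structured domain instances,
    its IDD call is made through the dominant-category rule, and the
    over/under-representation driver is run with the IDD families as
    selection. Returns the full result list and the planted term's result.
    """
    from .stats_enrichment import enrich

    config = SimConfig(
        seed=seed, n_families=n_families, archetypes=tuple(archetypes),
        n_terms=n_terms, planted_odds_ratio=odds_ratio,
    )
    rng = np.random.default_rng(seed)
    arch_idx, fam_truth, annotation = _assign_families(config, rng)
    selection = []
    universe = []
    for i in range(n_families):
        fid = f"PF{i:05d}"
        arch = config.archetypes[arch_idx[i]]
        universe.append(fid)
        grades, any_cdr = [], False
        for _ in range(2):
            dlen = int(rng.integers(domain_length_range[0], domain_length_range[1] + 1))
            m = region_metrics(domain_calls(rng, dlen, arch))
            grades.append(m.dsdr_grade)
            any_cdr = any_cdr or m.cdrn >= 1
        if dominant_category(grades) == "intrinsically_disordered" or any_cdr:
            selection.append(fid)
    results = enrich(selection, universe, annotation)
    planted = next(
        (r for r in results if r.term == config.planted_term), None
    )
    return results, planted


def ptm_experiment(
    seed: int,
    n_sites_target: int = 10_000,
    base_density: float = 0.02,
    disordered_multiplier: float = 3.0,
    domain_length: int = 100,
) -> tuple[float, float]:
    """Recovery study for the planted PTM density excess.

    Builds equal numbers of fully disordered and fully structured domains
    (so the per-residue contrast between the intrinsically disordered and
    the completely structured grade is exactly the planted multiplier),
    plants sites at ``base_density`` per structured residue and
    ``disordered_multiplier`` times that per disordered residue until about
    ``n_sites_target`` sites exist, then measures the two pooled densities
    through :func:`iddtools.ptm_analysis.ptm_density_by_class`. Returns
    (density in IDD-grade domains, density in completely-structured-grade
    domains).
    """
    from .ptm_analysis import classify_by_grade, ptm_density_by_class

    rng = np.random.default_rng(seed)
    mean_density = base_density * (1 + disordered_multiplier) / 2
    n_domains = int(np.ceil(n_sites_target / (mean_density * domain_length)))
    n_domains += n_domains % 2
    proteins_calls: dict[str, DisorderProfile] = {}
    domains: list[DomainInstance] = []
    sites: list[PTMSite] = []
    for i in range(n_domains):
        disordered = i % 2 == 0
        pid = f"p{i:05d}"
        calls = np.full(domain_length, disordered, dtype=bool)
        proteins_calls[pid] = DisorderProfile(pid, calls)
        domains.append(
            DomainInstance(protein_id=pid, family_id="PF_ptm", start=1,
                           end=domain_length)
        )
        rate = base_density * (disordered_multiplier if disordered else 1.0)
        for h in np.flatnonzero(rng.random(domain_length) < rate):
            sites.append(PTMSite(pid, int(h) + 1, "S", PTM_TYPES[0]))
    densities, _ = ptm_density_by_class(
        domains, proteins_calls, sites, classify_by_grade
    )
    by_cat = {d.category: d.proportion for d in densities}
    return by_cat["intrinsically_disordered"], by_cat["completely_structured"]
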