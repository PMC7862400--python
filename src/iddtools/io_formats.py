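"""Readers and writers for every external format the pipeline touches.

External formats are 1-based inclusive (HMMER / Swiss-Prot / BLAST
convention); all conversion to Python slices happens downstream via
``DomainInstance.slice()``. Downstream modules consume only the record types
defined in :mod:`iddtools.records`.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    ALLOWED_RESIDUES,
    AlignmentSummary,
    DisorderProfile,
    DomainInstance,
    FormatError,
    LineageTable,
    ProteinRecord,
    PTMSite,
)

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike, species_id: str = "") -> list[ProteinRecord]:
    """Read a proteome FASTA; the header token before the first whitespace is
    the protein id. A ``gene=`` key in the description is picked up as the
    gene id. Raises :class:`FormatError` naming the offending line on illegal
    residues or malformed headers."""
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FormatError(
                    f"{path}:{_find_line(path, '>')}: empty FASTA header"
                )
            gene_id = None
            rec_species = species_id
            for token in rec.description.split():
                if token.startswith("gene="):
                    gene_id = token[5:]
                elif token.startswith("species="):
                    rec_species = token[8:]
            try:
                records.append(
                    ProteinRecord(
                        protein_id=rec.id,
                        sequence=str(rec.seq).upper(),
                        species_id=rec_species,
                        gene_id=gene_id,
                    )
                )
            except ValueError as exc:
                line = _find_bad_residue_line(path, rec.id)
                raise FormatError(f"{path}:{line}: {exc}") from exc
    return records


def _find_line(path: Path, prefix: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(prefix):
                return i
    return 0


def _find_bad_residue_line(path: Path, protein_id: str) -> int:
    """Locate the first sequence line of *protein_id* containing an illegal
    residue, for error reporting."""
    in_record = False
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == protein_id if line[1:].split() else False
                continue
            if in_record:
                if set(line.strip().upper()) - ALLOWED_RESIDUES:
                    return i
    return 0


def write_fasta(path: PathLike, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" gene={rec.gene_id}" if rec.gene_id else ""
            if rec.species_id:
                desc += f" species={rec.species_id}"
            fh.write(f">{rec.protein_id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Per-residue disorder scores


def read_disorder_scores(path: PathLike, threshold: float = 0.5) -> list[DisorderProfile]:
    """Read an IUPred-style per-residue score table.

    Two dialects are accepted:

    * three columns ``position residue score`` with ``# protein_id`` comment
      lines separating proteins (IUPred output layout);
    * two columns ``protein_id  score,score,...`` (one protein per row).

    Calls are derived strictly: a residue is disordered iff
    ``score > threshold``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    path = Path(path)
    profiles: list[DisorderProfile] = []
    current_id: Optional[str] = None
    positions: list[int] = []
    scores: list[float] = []

    def flush(lineno: int) -> None:
        nonlocal positions, scores
        if current_id is None:
            return
        if positions != list(range(1, len(positions) + 1)):
            raise FormatError(
                f"{path}:{lineno}: non-contiguous positions for {current_id}"
            )
        arr = np.asarray(scores, dtype=float)
        profiles.append(_make_profile(current_id, arr, threshold, path, lineno))
        positions, scores = [], []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                flush(lineno)
                current_id = line.lstrip("#").strip().split()[0] if line.lstrip("#").strip() else None
                continue
            fields = line.split()
            if len(fields) == 2 and ("," in fields[1] or not _is_number(fields[0])):
                # two-column dialect: id <tab> comma-joined scores
                flush(lineno)
                arr = np.array([float(s) for s in fields[1].split(",")], dtype=float)
                profiles.append(_make_profile(fields[0], arr, threshold, path, lineno))
                current_id = None
                continue
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (position residue score)"
                )
            if current_id is None:
                raise FormatError(f"{path}:{lineno}: score row before any '# id' line")
            positions.append(int(fields[0]))
            scores.append(float(fields[2]))
    flush(lineno)
    return profiles


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _make_profile(pid, arr, threshold, path, lineno) -> DisorderProfile:
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise FormatError(f"{path}:{lineno}: score outside [0, 1] for {pid}")
    return DisorderProfile(
        protein_id=pid, calls=arr > threshold, scores=arr, threshold=threshold
    )


def write_disorder_scores(
    path: PathLike, profiles: Iterable[DisorderProfile], residues: Optional[dict] = None
) -> None:
    """Write IUPred-style three-column tables, one ``# id`` block per protein.
    *residues* optionally maps protein_id -> sequence for the residue column."""
    with open(path, "w") as fh:
        for prof in profiles:
            fh.write(f"# {prof.protein_id}\n")
            seq = residues.get(prof.protein_id) if residues else None
            scores = (
                prof.scores
                if prof.scores is not None
                else np.where(prof.calls, 1.0, 0.0)
            )
            for i, sc in enumerate(scores):
                res = seq[i] if seq else "X"
                fh.write(f"{i + 1}\t{res}\t{sc:.4f}\n")


# ---------------------------------------------------------------------------
# HMMER3 domtblout

_DOMTBL_MIN_COLS = 23


def read_domtblout(
    path: PathLike,
    max_full_evalue: float = 0.01,
    max_c_evalue: float = 0.01,
    species_id: str = "",
    deoverlap: bool = False,
) -> list[DomainInstance]:
    """Parse an ``hmmscan --domtblout`` table into domain instances.

    Envelope coordinates (``env from``/``env to``) define the domain
    boundaries. Rows with full-sequence E-value or conditional c-Evalue at or
    above the cutoffs are dropped (the filter is strict: values must be
    *less than* the cutoff). With ``deoverlap=True``, overlapping hits on the
    same protein are resolved greedily by best c-Evalue.
    """
    path = Path(path)
    instances: list[DomainInstance] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("#") or not raw.strip():
                continue
            fields = raw.split(None, _DOMTBL_MIN_COLS - 1)
            if len(fields) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: domtblout row has {len(fields)} columns, "
                    f"expected >= {_DOMTBL_MIN_COLS}"
                )
            full_e = float(fields[6])
            c_e = float(fields[11])
            if not (full_e < max_full_evalue and c_e < max_c_evalue):
                continue
            instances.append(
                DomainInstance(
                    protein_id=fields[3],
                    family_id=fields[1],
                    family_name=fields[0],
                    start=int(fields[19]),
                    end=int(fields[20]),
                    full_seq_evalue=full_e,
                    c_evalue=c_e,
                    species_id=species_id,
                )
            )
    if deoverlap:
        instances = _greedy_deoverlap(instances)
    return instances


def _greedy_deoverlap(instances: list[DomainInstance]) -> list[DomainInstance]:
    kept: list[DomainInstance] = []
    by_protein: dict[str, list[DomainInstance]] = {}
    for inst in instances:
        by_protein.setdefault(inst.protein_id, []).append(inst)
    for pid in sorted(by_protein):
        hits = sorted(by_protein[pid], key=lambda d: (d.c_evalue, d.start, d.end))
        chosen: list[DomainInstance] = []
        for hit in hits:
            if all(hit.end < c.start or hit.start > c.end for c in chosen):
                chosen.append(hit)
        kept.extend(sorted(chosen, key=lambda d: d.start))
    return kept


def write_domtblout(path: PathLike, instances: Iterable[DomainInstance],
                    protein_lengths: Optional[dict] = None) -> None:
    """Emit a minimal but column-correct hmmscan domtblout table."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        for d in instances:
            qlen = protein_lengths.get(d.protein_id, d.end) if protein_lengths else d.end
            fh.write(
                f"{d.family_name or d.family_id} {d.family_id} {d.length} "
                f"{d.protein_id} - {qlen} "
                f"{d.full_seq_evalue:.2g} 10.0 0.1 1 1 {d.c_evalue:.2g} "
                f"{d.c_evalue:.2g} 10.0 0.1 1 {d.length} {d.start} {d.end} "
                f"{d.start} {d.end} 0.90 -\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "qlen", "slen",
    "qstart", "qend", "sstart", "send", "evalue",
]


def read_blast_tabular(path: PathLike) -> list[AlignmentSummary]:
    """Parse BLAST ``-outfmt "6 qseqid sseqid pident length qlen slen qstart
    qend sstart send evalue"`` output."""
    path = Path(path)
    out: list[AlignmentSummary] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != len(BLAST_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} columns "
                    f"(got {len(fields)}); regenerate with -outfmt "
                    f"\"6 {' '.join(BLAST_COLUMNS)}\" — qlen/slen are required"
                )
            out.append(
                AlignmentSummary(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=float(fields[2]),
                    aln_length=int(fields[3]),
                    query_len=int(fields[4]),
                    subject_len=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                )
            )
    return out


def write_blast_tabular(path: PathLike, rows: Iterable[AlignmentSummary]) -> None:
    with open(path, "w") as fh:
        for a in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id, a.subject_id, a.identity_pct, a.aln_length,
                        a.query_len, a.subject_len, a.q_start, a.q_end,
                        a.s_start, a.s_end, a.evalue,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Simple TSV tables (lineage, cell types, annotations, PTM)


def read_lineage_table(path: PathLike) -> LineageTable:
    """TSV with columns ``species_id`` and ``lineage`` (semicolon-joined taxon
    names from superkingdom to species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["species_id", "lineage"], path)
    lineages = {
        row.species_id: tuple(t.strip() for t in row.lineage.split(";") if t.strip())
        for row in df.itertuples()
    }
    return LineageTable(lineages)


def write_lineage_table(path: PathLike, table: LineageTable) -> None:
    df = pd.DataFrame(
        {
            "species_id": list(table.lineages),
            "lineage": [";".join(v) for v in table.lineages.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cell_type_table(path: PathLike) -> pd.Series:
    """TSV ``species_id``, ``cell_types`` -> Series indexed by species."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["species_id", "cell_types"], path)
    return df.set_index("species_id")["cell_types"].astype(float)


def write_cell_type_table(path: PathLike, series: pd.Series) -> None:
    series.rename("cell_types").rename_axis("species_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_annotation_table(path: PathLike) -> pd.DataFrame:
    """TSV ``family_id``, ``term`` (one association per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["family_id", "term"], path)
    return df


def write_annotation_table(path: PathLike, df: pd.DataFrame) -> None:
    df[["family_id", "term"]].to_csv(path, sep="\t", index=False)


def read_ptm_table(path: PathLike) -> list[PTMSite]:
    """TSV ``protein_id``, ``position``, ``residue``, ``mod_type``."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "mod_type": str})
    _require_columns(df, ["protein_id", "position", "residue", "mod_type"], path)
    return [
        PTMSite(row.protein_id, int(row.position), str(row.residue), row.mod_type)
        for row in df.itertuples()
    ]


def write_ptm_table(path: PathLike, sites: Iterable[PTMSite]) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.mod_type) for s in sites],
        columns=["protein_id", "position", "residue", "mod_type"],
    )
    df.to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Minimal Swiss-Prot flat-text parser (ID / AC / SQ / FT MOD_RES only)


def read_swissprot_mod_res(
    path: PathLike,
) -> tuple[list[ProteinRecord], list[PTMSite]]:
    """Extract sequences and MOD_RES feature sites from a Swiss-Prot flat
    text file. Handles both the post-2019 layout (position line followed by a
    ``/note="..."`` qualifier) and the legacy fixed-column layout. A site
    whose residue disagrees with the sequence triggers a warning, not a
    failure."""
    import warnings

    proteins: list[ProteinRecord] = []
    sites: list[PTMSite] = []
    acc: Optional[str] = None
    seq_lines: list[str] = []
    in_seq = False
    pending: list[tuple[int, Optional[str]]] = []  # (position, mod or None)

    def flush() -> None:
        nonlocal acc, seq_lines, pending, in_seq
        if acc is None:
            return
        seq = "".join(seq_lines)
        if seq:
            proteins.append(ProteinRecord(protein_id=acc, sequence=seq))
        for pos, mod in pending:
            if mod is None:
                continue
            residue = seq[pos - 1] if pos <= len(seq) else "?"
            if pos > len(seq):
                warnings.warn(f"{acc}: MOD_RES position {pos} beyond sequence")
            sites.append(PTMSite(acc, pos, residue, mod))
        acc, seq_lines, pending, in_seq = None, [], [], False

    with open(path) as fh:
        for raw in fh:
            code = raw[:2]
            if code == "ID":
                flush()
            elif code == "AC" and acc is None:
                acc = raw[5:].split(";")[0].strip()
            elif code == "SQ":
                in_seq = True
            elif code == "//":
                flush()
            elif code == "  " and in_seq:
                seq_lines.append(raw.strip().replace(" ", ""))
            elif code == "FT":
                body = raw[5:].rstrip("\n")
                if body.startswith("MOD_RES"):
                    rest = body[len("MOD_RES"):].strip()
                    parts = rest.split()
                    if len(parts) >= 2 and parts[0].isdigit():
                        # legacy: MOD_RES  start  end  description.
                        mod = " ".join(parts[2:]).rstrip(".") or None
                        pending.append((int(parts[0]), mod))
                    elif parts and parts[0].split("..")[0].isdigit():
                        pending.append((int(parts[0].split("..")[0]), None))
                elif body.lstrip().startswith("/note=") and pending and pending[-1][1] is None:
                    note = body.split("=", 1)[1].strip().strip('"')
                    pending[-1] = (pending[-1][0], note)
    flush()
    return proteins, sites
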