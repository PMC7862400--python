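"""Core record types shared across the pipeline.

All coordinates stored on these records are 1-based inclusive (the convention
of HMMER, Swiss-Prot and BLAST output). Interval arithmetic inside the package
converts to 0-based half-open slices at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: the 20 standard residues plus the common ambiguity/rare codes
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from a proteome FASTA."""

    protein_id: str
    sequence: str
    species_id: str = ""
    gene_id: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence.upper()) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderProfile:
    """Per-residue disorder annotation for one protein.

    ``calls[i]`` is True when residue ``i+1`` is predicted disordered. When
    raw predictor scores are present, ``calls`` is derived by strict
    comparison ``score > threshold``.
    """

    protein_id: str
    calls: np.ndarray  # bool, one per residue
    scores: Optional[np.ndarray] = None  # float in [0, 1]
    threshold: Optional[float] = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.calls):
                raise ValueError(
                    f"{self.protein_id}: scores/calls length mismatch"
                )
            if np.any((self.scores < 0) | (self.scores > 1)):
                raise ValueError(f"{self.protein_id}: score outside [0, 1]")
            if self.threshold is not None and not np.array_equal(
                self.calls, self.scores > self.threshold
            ):
                raise ValueError(
                    f"{self.protein_id}: calls inconsistent with scores at "
                    f"threshold {self.threshold}"
                )

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class DomainInstance:
    """One Pfam-style domain hit on one protein (envelope coordinates)."""

    protein_id: str
    family_id: str
    start: int  # 1-based inclusive
    end: int
    family_name: str = ""
    full_seq_evalue: float = 0.0
    c_evalue: float = 0.0
    species_id: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.family_id}: bad interval "
                f"[{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        """0-based half-open slice into a per-residue array."""
        return slice(self.start - 1, self.end)


@dataclass
class LineageTable:
    """species_id -> ordered taxon names, root (superkingdom) first."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self):
        self.lineages = {k: tuple(v) for k, v in self.lineages.items()}
        roots = {v[0] for v in self.lineages.values() if v}
        if len(roots) > 1:
            # lineages may span superkingdoms; a virtual common root is
            # prepended so every pair has a defined LCA
            self.lineages = {
                k: ("cellular organisms",) + v for k, v in self.lineages.items()
            }

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.lineages

    def __getitem__(self, species_id: str) -> tuple[str, ...]:
        return self.lineages[species_id]

    def species(self) -> list[str]:
        return list(self.lineages)

    def lca_depth(self, species_ids: Sequence[str]) -> int:
        """Depth (0 = root) of the lowest common ancestor of the lineages."""
        missing = [s for s in species_ids if s not in self.lineages]
        if missing:
            raise KeyError(f"species missing from lineage table: {missing}")
        lineages = [self.lineages[s] for s in species_ids]
        depth = -1
        for level in zip(*lineages):
            if len(set(level)) != 1:
                break
            depth += 1
        return max(depth, 0)


@dataclass(frozen=True)
class PTMSite:
    """One post-translational modification site (Swiss-Prot MOD_RES style)."""

    protein_id: str
    position: int  # 1-based
    residue: str
    mod_type: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.protein_id}: PTM position < 1")


@dataclass(frozen=True)
class AlignmentSummary:
    """One BLAST tabular row (best HSP of a query/subject pair)."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    query_len: int
    subject_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")
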