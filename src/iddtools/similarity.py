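"""Sequence-similarity score for repeat-domain pairs.

The score combines BLAST percent identity with the alignment's coverage of
query and subject and a penalty for alignments starting late in the query:

    similarity = identity% * ([100 - |100 - match_query%|]
                              + [100 - |100 - match_subject%|])
                 / (2 * (100 - query_first%))

where match_query% (match_subject%) is the aligned span as a percentage of
the query (subject) length and query_first% is the percentage of the query
preceding the first aligned position. A perfect full-length self hit scores
exactly 100. The score is not symmetric under query/subject swap unless
query_first% is equal both ways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import AlignmentSummary


@dataclass
class SimilarityResult:
    query_id: str
    subject_id: str
    identity_pct: float
    match_query_pct: float
    match_subject_pct: float
    query_first_pct: float
    similarity: float
    defined: bool = True


def derive_components(a: AlignmentSummary) -> tuple[float, float, float]:
    """(match_query_pct, match_subject_pct, query_first_pct) of one HSP."""
    if a.query_len <= 0 or a.subject_len <= 0:
        raise ValueError("zero-length query or subject")
    match_query = 100.0 * (a.q_end - a.q_start + 1) / a.query_len
    match_subject = 100.0 * (abs(a.s_end - a.s_start) + 1) / a.subject_len
    query_first = 100.0 * (a.q_start - 1) / a.query_len
    return match_query, match_subject, query_first


def sequence_similarity(
    identity_pct: float,
    match_query_pct: float,
    match_subject_pct: float,
    query_first_pct: float,
) -> float:
    """Evaluate the similarity formula; raises on query_first_pct = 100
    (the alignment would start past the query end)."""
    if query_first_pct >= 100.0:
        raise ZeroDivisionError("query_first_pct = 100: similarity undefined")
    return (
        identity_pct
        * (
            (100.0 - abs(100.0 - match_query_pct))
            + (100.0 - abs(100.0 - match_subject_pct))
        )
        / (2.0 * (100.0 - query_first_pct))
    )


def score_alignment(a: AlignmentSummary) -> SimilarityResult:
    mq, ms, qf = derive_components(a)
    try:
        sim = sequence_similarity(a.identity_pct, mq, ms, qf)
        defined = True
    except ZeroDivisionError:
        sim, defined = float("nan"), False
    return SimilarityResult(
        a.query_id, a.subject_id, a.identity_pct, mq, ms, qf, sim, defined
    )


def best_hsp_per_pair(alignments: Sequence[AlignmentSummary]) -> list[AlignmentSummary]:
    """Keep one HSP per (query, subject) pair: lowest E-value, ties broken by
    longest alignment, then input order."""
    best: dict[tuple[str, str], tuple[float, int, int]] = {}
    chosen: dict[tuple[str, str], AlignmentSummary] = {}
    for i, a in enumerate(alignments):
        key = (a.query_id, a.subject_id)
        rank = (a.evalue, -a.aln_length, i)
        if key not in best or rank < best[key]:
            best[key] = rank
            chosen[key] = a
    return [chosen[k] for k in sorted(chosen)]


def similarity_table(alignments: Sequence[AlignmentSummary]) -> pd.DataFrame:
    """Similarity scores for the best HSP of every pair."""
    results = [score_alignment(a) for a in best_hsp_per_pair(alignments)]
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "subject_id": r.subject_id,
                "identity_pct": r.identity_pct,
                "match_query_pct": r.match_query_pct,
                "match_subject_pct": r.match_subject_pct,
                "query_first_pct": r.query_first_pct,
                "similarity": r.similarity,
            }
            for r in results
        ],
        columns=[
            "query_id", "subject_id", "identity_pct", "match_query_pct",
            "match_subject_pct", "query_first_pct", "similarity",
        ],
    )


def similarity_vs_variation(
    similarity_df: pd.DataFrame,
    pair_variation: dict[tuple[str, str], float],
    bin_edges: Sequence[float] = (0, 20, 40, 60, 80, 100),
) -> pd.DataFrame:
    """Join per-pair similarity scores with per-pair DSDR variation values
    (|Δ normalized DSDR| of the two repeat instances) and bin the similarity
    for downstream plotting or rank statistics. Pairs present in only one
    input are dropped."""
    rows = []
    for rec in similarity_df.itertuples():
        key = (rec.query_id, rec.subject_id)
        if key not in pair_variation:
            key = (rec.subject_id, rec.query_id)
            if key not in pair_variation:
                continue
        rows.append(
            {
                "query_id": rec.query_id,
                "subject_id": rec.subject_id,
                "similarity": rec.similarity,
                "variation": pair_variation[key],
            }
        )
    df = pd.DataFrame(
        rows, columns=["query_id", "subject_id", "similarity", "variation"]
    )
    if len(df):
        df["similarity_bin"] = pd.cut(
            df["similarity"].clip(upper=bin_edges[-1]), bin_edges,
            include_lowest=True,
        ).astype(str)
    else:
        df["similarity_bin"] = pd.Series(dtype=str)
    return df
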