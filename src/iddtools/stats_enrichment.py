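"""Statistics used across the analyses: hypergeometric over/under-
representation with Benjamini–Hochberg correction and a signed 14-grade
log10(P) scale, plus the Spearman, Mann–Whitney, Fisher and least-squares
helpers the figure-level analyses rely on.

The 14-grade scale maps a one-sided P value to a heat-map grade: positive
grades for over-representation, negative for under-representation. The
magnitude bins on -log10(P) are [1.301, 2) -> 2, [2, 3) -> 3, [3, 6) -> 4,
[6, 9) -> 5, [9, 12) -> 6, [12, inf) -> 7; anything short of 1.301 (i.e.
P > 0.05 territory) collapses to the near-zero grade +/-0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# (lower -log10(P) bound, grade magnitude), most significant first
_GRADE_BINS = ((12.0, 7.0), (9.0, 6.0), (6.0, 5.0), (3.0, 4.0), (2.0, 3.0), (1.301, 2.0))


def hypergeom_tails(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact upper and lower tail of Hypergeometric(N, K, n) at k.

    k = hits in the selection, K = hits in the universe, n = selection size,
    N = universe size. ``p_over = P(X >= k)``, ``p_under = P(X <= k)``; both
    tails include the point mass at k, so they always sum to >= 1.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    p_over = float(sps.hypergeom.sf(k - 1, N, K, n))
    p_under = float(sps.hypergeom.cdf(k, N, K, n))
    return min(p_over, 1.0), min(p_under, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def grade_magnitude(p: float) -> float:
    """Unsigned grade of one one-sided P value on the 14-grade scale."""
    if not (0 < p <= 1):
        raise ValueError("P value must be in (0, 1]")
    neg_log = -np.log10(p)
    for bound, grade in _GRADE_BINS:
        if neg_log >= bound:
            return grade
    return 0.25


def signed_grade(p_over: float, p_under: float) -> float:
    """Signed grade: positive for over-representation (p_over <= p_under),
    negative for under-representation."""
    if p_over <= p_under:
        return grade_magnitude(p_over)
    return -grade_magnitude(p_under)


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_over: float
    p_under: float
    q_over: float
    q_under: float
    grade: float


def enrich(
    selection: Iterable[str],
    universe: Iterable[str],
    annotation: pd.DataFrame,
    grade_on: str = "adjusted",
) -> list[EnrichmentResult]:
    """Over/under-representation of every annotated term in a selection.

    ``annotation`` has columns ``family_id`` and ``term``. Over- and
    under-tail P values are BH-corrected as two separate one-sided families;
    the signed grade is computed from the corrected values by default
    (``grade_on="raw"`` grades the uncorrected tails). Results are ordered
    by term id.
    """
    if grade_on not in ("adjusted", "raw"):
        raise ValueError("grade_on must be 'adjusted' or 'raw'")
    universe_set = set(universe)
    selection_set = set(selection) & universe_set
    ann = annotation[annotation["family_id"].isin(universe_set)]
    if ann.empty:
        return []
    N = len(universe_set)
    n = len(selection_set)
    terms = sorted(ann["term"].unique())
    by_term = ann.groupby("term")["family_id"]
    raw: list[tuple[str, int, int, float, float]] = []
    for term in terms:
        members = set(by_term.get_group(term))
        K = len(members)
        k = len(members & selection_set)
        p_over, p_under = hypergeom_tails(k, K, n, N)
        raw.append((term, k, K, p_over, p_under))
    q_over = bh_adjust([r[3] for r in raw])
    q_under = bh_adjust([r[4] for r in raw])
    results = []
    for (term, k, K, p_o, p_u), q_o, q_u in zip(raw, q_over, q_under):
        if grade_on == "adjusted":
            grade = signed_grade(q_o, q_u)
        else:
            grade = signed_grade(p_o, p_u)
        results.append(EnrichmentResult(term, k, n, K, N, p_o, p_u, q_o, q_u, grade))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_over": r.p_over, "p_under": r.p_under,
                "q_over": r.q_over, "q_under": r.q_under, "grade": r.grade,
            }
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p_over", "p_under",
                 "q_over", "q_under", "grade"],
    )


def grade_matrix(results_by_group: dict[str, Sequence[EnrichmentResult]]) -> pd.DataFrame:
    """Heat-map-ready matrix of signed grades, terms x groups."""
    cols = {}
    for group, results in results_by_group.items():
        cols[group] = {r.term: r.grade for r in results}
    return pd.DataFrame(cols).sort_index()


# ---------------------------------------------------------------------------
# General-purpose tests


@dataclass
class CorrelationResult:
    measure: str
    rho: float
    p: float
    n: int
    defined: bool = True


def spearman(x: Sequence[float], y: Sequence[float], measure: str = "") -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; undefined
    (flagged) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(measure, float("nan"), float("nan"), x.size, False)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(measure, float(rho), float(p), x.size)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (U of the first sample). The default is the
    tie-corrected normal approximation; ``method="exact"`` enumerates the
    null distribution (no ties only)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fit_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares straight line; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two points")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
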