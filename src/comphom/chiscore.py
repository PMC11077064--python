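"""Normalized chi-square compositional dissimilarity (the chi-score).

Two sequences are compared by a chi-square test of homogeneity on their
amino-acid counts: a 2xK contingency table (rows = sequences, columns =
amino acids present in at least one sequence) yields the classical
statistic ``chi2 = sum (O-E)^2 / E`` with expectations from the row and
column margins. Rather than testing a null hypothesis, the statistic is
normalized to ``score = sqrt(chi2 / N)`` with N the combined residue count
— Cramér's V for a two-row table — so that compositionally identical
sequences score 0 and sequences sharing no amino-acid letters score 1.

Counts, not fractions, enter the table, so longer sequences carry more
weight exactly as in the classical test; ``equal_weight=True`` rescales
both rows to a common total before tabulation for a length-balanced
variant. The raw chi2 and N are carried on every result, so the phi-square
normalization (chi2/N) is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_core import (
    AMINO_ACIDS,
    CompositionVector,
    SequenceRecord,
    composition,
)

NORMALIZATION = "cramers_v"  # score = sqrt(chi2 / N); phi2 = chi2 / N


@dataclass(frozen=True)
class ChiScoreResult:
    """Chi-score between two compositions, with the raw statistic."""

    score: float
    chi2: float
    n_total: float
    dropped_columns: frozenset[str]


@dataclass(frozen=True)
class ChiScoreMatrix:
    """All-vs-all chi-score matrix over a set of sequences."""

    ids: tuple[str, ...]
    values: np.ndarray
    reference_column: np.ndarray | None = None

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            a: {b: float(self.values[i, j]) for j, b in enumerate(self.ids)}
            for i, a in enumerate(self.ids)
        }


def _counts_of(x: SequenceRecord | CompositionVector | str) -> np.ndarray:
    if isinstance(x, CompositionVector):
        return np.asarray(x.counts, dtype=float)
    if isinstance(x, (SequenceRecord, str)):
        return composition(x).counts.astype(float)
    if isinstance(x, np.ndarray) and x.shape == (20,):
        return x.astype(float)
    raise TypeError(f"cannot take a composition of {type(x).__name__}")


def chi_score_counts(c1: np.ndarray, c2: np.ndarray) -> ChiScoreResult:
    """Chi-score from two length-20 count vectors (the core computation)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1, n2 = c1.sum(), c2.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("chi-score requires two non-empty compositions")
    col = c1 + c2
    present = col > 0
    dropped = frozenset(aa for aa, p in zip(AMINO_ACIDS, present) if not p)
    n = n1 + n2
    # E[i,j] = row_i * col_j / N; zero-total columns contribute 0/0 and drop.
    e1 = n1 * col[present] / n
    e2 = n2 * col[present] / n
    chi2 = float(
        ((c1[present] - e1) ** 2 / e1).sum() + ((c2[present] - e2) ** 2 / e2).sum()
    )
    if not np.any((c1 > 0) & (c2 > 0)):
        # disjoint alphabets: chi2 = N exactly in real arithmetic
        return ChiScoreResult(1.0, chi2, float(n), dropped)
    score = float(np.sqrt(max(chi2, 0.0) / n))
    return ChiScoreResult(min(score, 1.0), chi2, float(n), dropped)


def chi_score(
    a: SequenceRecord | CompositionVector | str,
    b: SequenceRecord | CompositionVector | str,
    equal_weight: bool = False,
) -> ChiScoreResult:
    """Compositional dissimilarity between two sequences (or compositions).

    Symmetric in its arguments; 0 iff the fraction vectors coincide, 1 iff
    the amino-acid alphabets are disjoint.
    """
    c1, c2 = _counts_of(a), _counts_of(b)
    if equal_weight:
        target = (c1.sum() + c2.sum()) / 2.0
        c1 = c1 * (target / c1.sum())
        c2 = c2 * (target / c2.sum())
    return chi_score_counts(c1, c2)


def score_vs_uniform(a: SequenceRecord | CompositionVector | str) -> ChiScoreResult:
    """Chi-score against a standardized reference of 5% of each amino acid.

    The reference enters the table as a pseudo-row with the same total as
    the query (fractional expected counts are permitted), so the score
    depends only on the query's fractions.
    """
    c1 = _counts_of(a)
    ref = np.full(20, c1.sum() * 0.05)
    return chi_score_counts(c1, ref)


def chi_score_matrix(
    seqs: list[SequenceRecord],
    include_reference: bool = False,
    equal_weight: bool = False,
) -> ChiScoreMatrix:
    """All unordered pairs evaluated once and mirrored; diagonal 0.

    With ``include_reference`` a per-sequence score against the 5%-uniform
    standardized composition is attached as ``reference_column``.
    """
    if len(seqs) < 2:
        raise ValueError("chi_score_matrix requires at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")
    k = len(seqs)
    comps = [composition(s) for s in seqs]
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = chi_score(comps[i], comps[j], equal_weight=equal_weight).score
            values[i, j] = values[j, i] = s
    ref = None
    if include_reference:
        ref = np.array([score_vs_uniform(c).score for c in comps])
    return ChiScoreMatrix(tuple(ids), values, ref)
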