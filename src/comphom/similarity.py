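"""Linear sequence conservation: global alignment identity/similarity.

The counterpoint to the chi-score: where compositional dissimilarity
ignores residue order entirely, these metrics measure order-dependent
(alignable) conservation. Pairs of sequences are globally aligned
(Needleman-Wunsch, affine gaps, BLOSUM62 by default) and scored as the
percentage of alignment columns that are identical, or whose residue pair
has a positive substitution score ("similar", identities included). Gap
columns count in the denominator and score zero.

Because a permuted sequence keeps its composition, aligning a sequence
against random scrambles of itself gives the level of "similarity"
expected from composition alone with no linear homology — the
scrambled-self baseline against which ortholog similarities are judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_core import SequenceRecord, scramble


@dataclass(frozen=True)
class AlignmentParams:
    """Aligner configuration (EMBOSS-needle-style defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: "columns" divides by all alignment columns (gaps included);
    #: "shorter" divides by the shorter sequence's length.
    denominator: str = "columns"

    def __post_init__(self) -> None:
        if self.denominator not in ("columns", "shorter"):
            raise ValueError(f"unknown denominator {self.denominator!r}")


@dataclass(frozen=True)
class AlignmentSimilarity:
    id_a: str
    id_b: str
    pct_identity: float
    pct_similarity: float
    aln_length: int
    params: AlignmentParams


@dataclass(frozen=True)
class ScrambledBaseline:
    """Summary of pct_similarity of a sequence vs n scrambles of itself."""

    id: str
    n: int
    mean: float
    min: float
    max: float
    values: tuple[float, ...]


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def align_similarity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: AlignmentParams | None = None,
) -> AlignmentSimilarity:
    """Global-alignment percent identity and percent similarity.

    Identity counts columns with equal residues; similarity additionally
    counts columns whose residue pair scores positive in the substitution
    matrix. ``0 <= pct_identity <= pct_similarity <= 100``.
    """
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    matrix = aligner.substitution_matrix
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident = similar = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            similar += 1
        elif matrix[x, y] > 0:
            similar += 1
    denom = len(row_a) if params.denominator == "columns" else min(len(a), len(b))
    return AlignmentSimilarity(
        a.id, b.id, 100.0 * ident / denom, 100.0 * similar / denom, len(row_a), params
    )


def scrambled_baseline(
    a: SequenceRecord,
    n: int = 10,
    seed: int = 0,
    params: AlignmentParams | None = None,
) -> ScrambledBaseline:
    """Align ``a`` against ``n`` seeded scrambles of itself.

    The mean pct_similarity estimates the alignment similarity expected
    from composition alone (no conserved residue order).
    """
    if n < 1:
        raise ValueError("scrambled_baseline requires n >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n):
        scr = scramble(a, int(rng.integers(0, 2**31)))
        values.append(align_similarity(a, scr, params).pct_similarity)
    arr = np.array(values)
    return ScrambledBaseline(
        a.id, n, float(arr.mean()), float(arr.min()), float(arr.max()), tuple(values)
    )


def similarity_matrix(
    seqs: list[SequenceRecord],
    params: AlignmentParams | None = None,
    with_scrambled: int = 0,
    seed: int = 0,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray, np.ndarray | None]:
    """All-vs-all percent identity and similarity; optional scrambled column.

    Returns ``(ids, pct_identity, pct_similarity, scrambled_means)`` where
    the matrices are symmetric with a 100.0 diagonal and, when
    ``with_scrambled`` is a positive repeat count, ``scrambled_means`` is
    the per-sequence scrambled-self baseline (the "*" column).
    """
    if len(seqs) < 2:
        raise ValueError("similarity_matrix requires at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    k = len(seqs)
    ident = np.full((k, k), 100.0)
    simil = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            r = align_similarity(seqs[i], seqs[j], params)
            ident[i, j] = ident[j, i] = r.pct_identity
            simil[i, j] = simil[j, i] = r.pct_similarity
    scr = None
    if with_scrambled:
        scr = np.array(
            [
                scrambled_baseline(s, with_scrambled, seed + i, params).mean
                for i, s in enumerate(seqs)
            ]
        )
    return tuple(ids), ident, simil, scr
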