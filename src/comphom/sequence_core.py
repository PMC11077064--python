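"""Sequence ingestion, residue-range extraction, composition and scrambling.

Everything downstream (chi-score matrices, modularity segmentation,
alignment baselines, feature profiling) operates on :class:`SequenceRecord`
objects over the 20 canonical amino acids. Coordinates are 1-based and
inclusive throughout, matching the residue-range convention of the
experimental literature (e.g. "residues 187-549").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical one-letter codes. Index order
#: is shared by every composition vector and count array in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class SequenceError(ValueError):
    """Raised for invalid sequences, ranges or FASTA content."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, optionally a slice of a parent protein.

    Parameters
    ----------
    id :
        Sequence label (FASTA header word).
    residues :
        Uppercase string over the 20 canonical amino-acid letters.
    source_range :
        Optional ``(start, end)`` 1-based inclusive positions locating this
        sequence within a parent protein; when present the span length must
        equal ``len(residues)``.
    """

    id: str
    residues: str
    source_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )
        if self.source_range is not None:
            start, end = self.source_range
            if end - start + 1 != len(self.residues):
                raise SequenceError(
                    f"record {self.id!r}: source_range {start}-{end} spans "
                    f"{end - start + 1} residues but sequence has {len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def counts(self) -> np.ndarray:
        """Length-20 integer count vector in :data:`AMINO_ACIDS` order."""
        return residue_counts(self.residues)


@dataclass(frozen=True)
class CompositionVector:
    """Fractional and count content of the 20 canonical amino acids."""

    counts: np.ndarray
    fractions: np.ndarray = field(init=False)
    total: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (20,) or (counts < 0).any():
            raise SequenceError("composition requires 20 non-negative counts")
        total = counts.sum()
        if total <= 0:
            raise SequenceError("composition requires a positive total count")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", float(total))
        object.__setattr__(self, "fractions", counts / total)

    def fraction_of(self, aa: str) -> float:
        return float(self.fractions[AA_INDEX[aa]])


def residue_counts(residues: str) -> np.ndarray:
    """Count residues into a length-20 vector in :data:`AMINO_ACIDS` order."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    # Offsets of the canonical letters within A..Y; non-canonical already
    # excluded by SequenceRecord validation when called through it.
    lut = np.full(91, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    idx = lut[arr]
    if (idx < 0).any():
        bad = sorted({chr(c) for c in arr[idx < 0]})
        raise SequenceError(f"non-canonical residue(s) {bad}")
    return np.bincount(idx, minlength=20).astype(np.int64)


def composition(rec: SequenceRecord | str) -> CompositionVector:
    """Fractional amino-acid content of a sequence.

    Counts sum to the sequence length; fractions sum to 1.
    """
    residues = rec.residues if isinstance(rec, SequenceRecord) else rec
    return CompositionVector(residue_counts(residues))


def read_fasta(path: str | Path, ambiguity_policy: str = "drop") -> list[SequenceRecord]:
    """Read a multi-record FASTA file of protein sequences.

    Non-canonical letters (B, J, O, U, X, Z, gaps, ``*``) are handled per
    ``ambiguity_policy``: ``"drop"`` removes them with a logged warning,
    ``"error"`` aborts naming the offending record.
    """
    if ambiguity_policy not in ("drop", "error"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise SequenceError(f"{path}: FASTA entry with empty header")
        raw = str(entry.seq).upper()
        residues = "".join(c for c in raw if c in AA_INDEX)
        if residues != raw:
            dropped = sorted(set(raw) - set(AMINO_ACIDS))
            if ambiguity_policy == "error":
                raise SequenceError(
                    f"record {entry.id!r}: non-canonical residue(s) {dropped}"
                )
            logger.warning(
                "record %r: dropped %d non-canonical residue(s) %s",
                entry.id, len(raw) - len(residues), dropped,
            )
        if not residues:
            raise SequenceError(
                f"record {entry.id!r}: sequence empty after dropping "
                "non-canonical residues"
            )
        rec_id, source_range = entry.id, None
        # Headers written by write_fasta carry "id/start-end" for slices.
        if "/" in entry.id:
            head, _, tail = entry.id.rpartition("/")
            if head and "-" in tail:
                a, _, b = tail.partition("-")
                if a.isdigit() and b.isdigit() and int(b) - int(a) + 1 == len(residues):
                    rec_id, source_range = head, (int(a), int(b))
        records.append(SequenceRecord(rec_id, residues, source_range))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns.

    Headers carry ``id/start-end`` when a source range is recorded, so a
    round trip through :func:`read_fasta` restores it.
    """
    entries = []
    for rec in records:
        header = rec.id
        if rec.source_range is not None:
            header = f"{rec.id}/{rec.source_range[0]}-{rec.source_range[1]}"
        entries.append(_BioSeqRecord(Seq(rec.residues), id=header, description=""))
    writer_path = Path(path)
    with writer_path.open("w") as fh:
        for entry in entries:
            fh.write(f">{entry.id}\n")
            seq = str(entry.seq)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_range(rec: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Extract residues ``start..end`` (1-based inclusive) as a new record.

    The returned record has length ``end - start + 1`` and remembers its
    coordinates relative to the parent protein: slicing an already-sliced
    record composes the offsets.
    """
    if not (1 <= start <= end <= len(rec)):
        raise SequenceError(
            f"record {rec.id!r}: range {start}-{end} invalid for length {len(rec)}"
        )
    offset = rec.source_range[0] - 1 if rec.source_range else 0
    return SequenceRecord(
        rec.id,
        rec.residues[start - 1 : end],
        (offset + start, offset + end),
    )


def scramble(rec: SequenceRecord, seed: int) -> SequenceRecord:
    """Uniform-random permutation of the residues (Fisher-Yates), seeded.

    The output is a distinct record (id suffixed ``_scr``) with exactly the
    same residue multiset, hence identical composition.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return SequenceRecord(f"{rec.id}_scr", arr.tobytes().decode("ascii"))


def parse_range_spec(spec: str) -> tuple[str, int, int]:
    """Parse an ``id:start-end`` range flag into its parts."""
    try:
        ident, _, span = spec.rpartition(":")
        a, _, b = span.partition("-")
        start, end = int(a), int(b)
    except ValueError as exc:
        raise ValueError(f"malformed range spec {spec!r}; expected id:start-end") from exc
    if not ident:
        raise ValueError(f"malformed range spec {spec!r}; expected id:start-end")
    return ident, start, end


def apply_ranges(
    records: Sequence[SequenceRecord], ranges: dict[str, tuple[int, int]]
) -> list[SequenceRecord]:
    """Slice each record named in ``ranges``; pass others through unchanged."""
    out = []
    for rec in records:
        if rec.id in ranges:
            start, end = ranges[rec.id]
            out.append(extract_range(rec, start, end))
        else:
            out.append(rec)
    return out
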