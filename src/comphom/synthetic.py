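"""Seeded generators for synthetic test data.

Three kinds of input are emulated, matching the statistical structure the
analyses assume:

* **ortholog families** — sets of sequences drawn i.i.d. from one shared
  amino-acid composition, so they are compositionally homologous (chi-score
  near 0 for long sequences) while their residue order is unrelated
  (alignment similarity near the scrambled-self baseline);
* **modular sequences** — juxtaposed segments of distinct compositional
  bias with known junction positions, the ground truth for segmentation
  recovery tests;
* **ROI intensity series** — per-cell, per-timepoint chromosome/cytosol
  intensities with programmed stage means and multiplicative lognormal
  noise, the ground truth for partition-quantitation recovery.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition_quant import ROIStats
from .sequence_core import AMINO_ACIDS, SequenceRecord

#: A disordered-region-like composition preset: enriched in S/T/P and the
#: basic residues K/R, depleted in the order-promoting aromatics and
#: cysteine (W/C/F), qualitatively mirroring basic, phospho-site-rich
#: replication-licensing IDRs. Repository constants, not measured values.
IDR_COMPOSITION: dict[str, float] = {
    "A": 0.070, "C": 0.005, "D": 0.045, "E": 0.055, "F": 0.015,
    "G": 0.060, "H": 0.020, "I": 0.030, "K": 0.090, "L": 0.055,
    "M": 0.015, "N": 0.045, "P": 0.085, "Q": 0.045, "R": 0.070,
    "S": 0.120, "T": 0.090, "V": 0.045, "W": 0.005, "Y": 0.035,
}


def _as_vector(composition: dict[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(composition, dict):
        vec = np.zeros(20)
        for aa, f in composition.items():
            vec[AMINO_ACIDS.index(aa)] = f
    else:
        vec = np.asarray(composition, dtype=float)
    if vec.shape != (20,) or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 20 non-negative fractions summing to 1")
    return vec


@dataclass(frozen=True)
class FamilySpec:
    """A family of i.i.d. sequences sharing one composition."""

    composition: dict[str, float] | np.ndarray
    n_members: int
    lengths: tuple[int, int] | list[int]
    seed: int

    def __post_init__(self) -> None:
        _as_vector(self.composition)
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        lengths = list(self.lengths)
        if not lengths or min(lengths) < 20:
            raise ValueError("family sequence lengths must be >= 20")
        if isinstance(self.lengths, list) and len(self.lengths) != self.n_members:
            raise ValueError("lengths list must have one entry per member")


@dataclass(frozen=True)
class ModularSpec:
    """A sequence concatenated from segments of distinct composition."""

    segments: tuple[tuple[dict[str, float] | np.ndarray, int], ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("modular sequences need >= 2 segments")
        for comp, length in self.segments:
            _as_vector(comp)
            if length < 1:
                raise ValueError("segment lengths must be positive")


def sample_sequence(
    composition: dict[str, float] | np.ndarray,
    length: int,
    seed: int,
    seq_id: str = "synthetic",
) -> SequenceRecord:
    """One sequence of i.i.d. draws from a composition, seeded."""
    vec = _as_vector(composition)
    rng = np.random.default_rng(seed)
    idx = rng.choice(20, size=length, p=vec)
    residues = "".join(AMINO_ACIDS[i] for i in idx)
    return SequenceRecord(seq_id, residues)


def make_family(spec: FamilySpec) -> list[SequenceRecord]:
    """Independent sequences from the shared family composition.

    Members share fractional content in expectation but have unrelated
    residue order, emulating compositional homology without linear
    sequence similarity.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.lengths, list):
        lengths = list(spec.lengths)
    else:
        lo, hi = spec.lengths
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_members)]
    return [
        sample_sequence(
            spec.composition, lengths[i], int(rng.integers(0, 2**31)), f"fam{i:02d}"
        )
        for i in range(spec.n_members)
    ]


def make_modular(spec: ModularSpec, seq_id: str = "modular") -> tuple[SequenceRecord, list[int]]:
    """Concatenated biased segments plus the true junction positions.

    The returned boundary list holds the cumulative segment lengths
    (1-based cut indices, boundary between residues b and b+1); junctions
    between identically composed segments are still listed — by
    construction they exist in the truth but are not expected to be
    detectable.
    """
    rng = np.random.default_rng(spec.seed)
    parts = []
    boundaries = []
    total = 0
    for comp, length in spec.segments:
        parts.append(
            sample_sequence(comp, length, int(rng.integers(0, 2**31))).residues
        )
        total += length
        boundaries.append(total)
    return SequenceRecord(seq_id, "".join(parts)), boundaries[:-1]


def biased_composition(major: str, weight: float = 0.8) -> dict[str, float]:
    """A composition dominated by one residue, remainder spread uniformly."""
    rest = (1.0 - weight) / 19.0
    return {aa: (weight if aa == major else rest) for aa in AMINO_ACIDS}


def make_roi_series(
    n_cells: int,
    stage_effects: dict[str, float],
    noise_cv: float = 0.1,
    seed: int = 0,
    timepoints_per_stage: int = 2,
    total_intensity: float = 1000.0,
    a_chr: float = 50.0,
    a_cyt: float = 200.0,
) -> list[ROIStats]:
    """ROI tables with programmed per-stage partition coefficients.

    ``stage_effects`` maps stage labels (visited in dict order, cycling
    metaphase -> anaphase -> telophase by convention) to target partition
    coefficients in (0, 1). Intensities are scaled so the noise-free
    partition equals the target exactly, then perturbed multiplicatively
    with lognormal noise of coefficient of variation ``noise_cv``. Areas
    are mildly jittered but identical in expectation across stages.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    mu = -(sigma**2) / 2.0  # unit-mean lognormal

    def noise() -> float:
        return float(rng.lognormal(mu, sigma)) if noise_cv > 0 else 1.0

    rows = []
    for c in range(n_cells):
        t = 0
        for stage, target in stage_effects.items():
            if not 0.0 < target < 1.0:
                raise ValueError(f"stage {stage!r}: partition target must be in (0,1)")
            for _ in range(timepoints_per_stage):
                area_chr = a_chr * (1.0 + 0.1 * (rng.random() - 0.5) * (noise_cv > 0))
                area_cyt = a_cyt * (1.0 + 0.1 * (rng.random() - 0.5) * (noise_cv > 0))
                i_chr = target * total_intensity / area_chr
                i_cyt = (1.0 - target) * total_intensity / area_cyt
                rows.append(
                    ROIStats(
                        cell_id=f"cell{c:02d}",
                        timepoint=float(t),
                        stage=stage,
                        i_chr=i_chr * noise(),
                        a_chr=area_chr,
                        i_cyt=i_cyt * noise(),
                        a_cyt=area_cyt,
                    )
                )
                t += 1
    return rows
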