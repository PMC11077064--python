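"""Physicochemical and motif profiling of disordered regions.

Covers the feature set used to characterize DNA-binding IDRs: the net
charge per residue (NCPR) track and charged-residue map, fraction of
charged residues (FCR), Henderson-Hasselbalch isoelectric point, CDK
phosphorylation consensus sites (minimal "[S/T]P" and optimal
"[S/T]PX[R/K]"), the phospho-dead transform ([S/T]P -> AP), AT-hook motif
detection (G-R-P core in a basic context), phospho-site window frequency
matrices for sequence logos, and the site-count-versus-length regression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_core import AMINO_ACIDS, SequenceRecord

#: Side-chain pKa tables. "bjellqvist" is the ExPASy set; "emboss" the
#: EMBOSS iep defaults. Keys: titratable side chains plus termini.
PKA_TABLES: dict[str, dict[str, float]] = {
    "bjellqvist": {
        "D": 4.05, "E": 4.45, "H": 5.98, "C": 9.0, "Y": 10.0,
        "K": 10.0, "R": 12.0, "Nterm": 7.5, "Cterm": 3.55,
    },
    "emboss": {
        "D": 3.9, "E": 4.1, "H": 6.5, "C": 8.5, "Y": 10.1,
        "K": 10.8, "R": 12.5, "Nterm": 8.6, "Cterm": 3.6,
    },
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")
_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}  # H neutral at pH 7.4


@dataclass(frozen=True)
class FeatureProfile:
    """Per-sequence physicochemical and motif summary."""

    sequence_id: str
    length: int
    ncpr_track: np.ndarray
    basic_positions: tuple[int, ...]
    acidic_positions: tuple[int, ...]
    fcr: float
    pi: float
    cdk_minimal: tuple[int, ...]
    cdk_optimal: tuple[int, ...]
    at_hooks: tuple[tuple[int, int, str], ...]


def ncpr_track(rec: SequenceRecord, window: int = 25) -> np.ndarray:
    """Centered sliding-mean net charge per residue (K,R = +1; D,E = -1).

    Histidine counts 0 (neutral at physiological pH). Edge positions
    average over the truncated window. Window must be odd.
    """
    if window % 2 == 0:
        raise ValueError("NCPR window must be odd")
    if window > len(rec):
        raise ValueError("NCPR window exceeds sequence length")
    charges = np.array([_CHARGE.get(c, 0.0) for c in rec.residues])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(charges)])
    L = len(charges)
    lo = np.maximum(np.arange(L) - half, 0)
    hi = np.minimum(np.arange(L) + half + 1, L)
    return (csum[hi] - csum[lo]) / (hi - lo)


def charge_positions(rec: SequenceRecord) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """1-based positions of basic (K,R) and acidic (D,E) residues."""
    basic = tuple(i + 1 for i, c in enumerate(rec.residues) if c in "KR")
    acidic = tuple(i + 1 for i, c in enumerate(rec.residues) if c in "DE")
    return basic, acidic


def fcr(rec: SequenceRecord) -> float:
    """Fraction of charged residues: (K + R + D + E) / length."""
    return sum(rec.residues.count(c) for c in "KRDE") / len(rec)


def net_charge(rec: SequenceRecord, ph: float, pka_set: str = "bjellqvist",
               include_termini: bool = True) -> float:
    """Henderson-Hasselbalch net charge of the sequence at a given pH."""
    table = PKA_TABLES[pka_set]
    q = 0.0
    for aa in _POSITIVE:
        n = rec.residues.count(aa)
        if n:
            q += n / (1.0 + 10.0 ** (ph - table[aa]))
    for aa in _NEGATIVE:
        n = rec.residues.count(aa)
        if n:
            q -= n / (1.0 + 10.0 ** (table[aa] - ph))
    if include_termini:
        q += 1.0 / (1.0 + 10.0 ** (ph - table["Nterm"]))
        q -= 1.0 / (1.0 + 10.0 ** (table["Cterm"] - ph))
    return q


def isoelectric_point(rec: SequenceRecord, pka_set: str = "bjellqvist",
                      include_termini: bool = True, tol: float = 1e-3) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique; for
    sequences with no titratable group the charge is identically zero
    (termini excluded) and pH 7 is returned.
    """
    lo, hi = 0.0, 14.0
    q_lo = net_charge(rec, lo, pka_set, include_termini)
    q_hi = net_charge(rec, hi, pka_set, include_termini)
    if q_lo <= 0.0:
        return lo
    if q_hi >= 0.0:
        return 7.0 if q_lo == q_hi == 0.0 else hi
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(rec, mid, pka_set, include_termini) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def cdk_sites(rec: SequenceRecord) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """CDK consensus phospho-acceptor positions (1-based, overlapping scan).

    Minimal sites are every S or T immediately followed by P; optimal
    sites additionally have K or R three residues downstream
    ("[S/T]PX[R/K]").
    """
    s = rec.residues
    minimal = tuple(
        i + 1 for i in range(len(s) - 1) if s[i] in "ST" and s[i + 1] == "P"
    )
    optimal = tuple(
        p for p in minimal if p + 3 <= len(s) and s[p + 2] in "KR"
    )
    return minimal, optimal


def phospho_dead(rec: SequenceRecord) -> SequenceRecord:
    """Mutate every minimal CDK site acceptor to alanine ([S/T]P -> AP).

    Length is preserved and the output contains no minimal sites;
    applying the transform twice is a no-op.
    """
    chars = list(rec.residues)
    for pos in cdk_sites(rec)[0]:
        chars[pos - 1] = "A"
    return SequenceRecord(rec.id, "".join(chars), rec.source_range)


def find_at_hooks(
    rec: SequenceRecord,
    core: str = "GRP",
    flank: int = 3,
    min_basic: int = 2,
) -> tuple[tuple[int, int, str], ...]:
    """AT-hook motifs: a G-R-P core within a basic (K/R-rich) context.

    Each non-overlapping occurrence of the core pattern is accepted when
    at least ``min_basic`` K/R residues lie within ``flank`` positions of
    the core on the two sides combined. Returns 1-based (start, end) of
    the core and the surrounding matched text (core plus clipped flanks).
    """
    s = rec.residues
    hits = []
    for m in re.finditer(core, s):
        a, b = m.start(), m.end()
        left = s[max(0, a - flank) : a]
        right = s[b : b + flank]
        n_basic = sum(c in "KR" for c in left + right)
        if n_basic >= min_basic:
            hits.append((a + 1, b, s[max(0, a - flank) : b + flank]))
    return tuple(hits)


def site_window_matrix(
    seqs_and_sites: list[tuple[SequenceRecord, list[int]]],
    flank: int = 4,
    include_center: bool = True,
) -> pd.DataFrame:
    """Position frequency matrix of residues around phospho-sites.

    Windows span ``flank`` residues on each side of every 1-based site
    position (9 columns at the default flank of 4, site centered); sites
    near sequence ends contribute gap-padded windows whose gaps are
    excluded from the per-column normalization. Each site counts once.
    Columns are offsets from the site; rows the 20 amino acids; every
    column sums to 1 where any residue was observed.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    offsets = [o for o in range(-flank, flank + 1) if include_center or o != 0]
    counts = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=offsets)
    n_sites = 0
    for rec, sites in seqs_and_sites:
        for pos in sites:
            if not 1 <= pos <= len(rec):
                raise ValueError(
                    f"site {pos} out of range for {rec.id!r} (length {len(rec)})"
                )
            n_sites += 1
            for o in offsets:
                j = pos + o
                if 1 <= j <= len(rec):
                    counts.loc[rec.residues[j - 1], o] += 1
    if n_sites == 0:
        raise ValueError("site_window_matrix requires at least one site")
    sums = counts.sum(axis=0)
    return counts / sums.where(sums > 0, 1.0)


def sites_vs_length_fit(
    profiles: list[FeatureProfile],
) -> tuple[float, float, float]:
    """OLS fit of minimal CDK site count on sequence length.

    Returns (slope, intercept, Pearson r). A linear relationship with
    slope ~ the per-residue site density indicates that site number
    scales with IDR length.
    """
    if len(profiles) < 3:
        raise ValueError("sites_vs_length_fit requires >= 3 profiles")
    x = np.array([p.length for p in profiles], dtype=float)
    y = np.array([len(p.cdk_minimal) for p in profiles], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("sites_vs_length_fit requires length variance")
    res = stats.linregress(x, y)
    r = 0.0 if np.isnan(res.rvalue) else float(res.rvalue)
    return float(res.slope), float(res.intercept), r


def feature_profile(
    rec: SequenceRecord,
    ncpr_window: int = 25,
    pka_set: str = "bjellqvist",
    include_termini: bool = True,
) -> FeatureProfile:
    """Compute the full feature set for one sequence."""
    basic, acidic = charge_positions(rec)
    minimal, optimal = cdk_sites(rec)
    return FeatureProfile(
        sequence_id=rec.id,
        length=len(rec),
        ncpr_track=ncpr_track(rec, ncpr_window),
        basic_positions=basic,
        acidic_positions=acidic,
        fcr=fcr(rec),
        pi=isoelectric_point(rec, pka_set, include_termini),
        cdk_minimal=minimal,
        cdk_optimal=optimal,
        at_hooks=find_at_hooks(rec),
    )
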