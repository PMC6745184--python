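"""Physicochemical profiling: length, MW, pI, hydropathy TM segments.

Molecular weights use average (not monoisotopic) residue masses with the
N-terminal Met retained, reproducing ProtParam-style values.  The
isoelectric point solves net_charge(pH) = 0 by bisection with the
Bjellqvist/ExPASy pK set by default (EMBOSS set available).  Transmembrane
segments come from Kyte-Doolittle sliding-window hydropathy, the package's
stand-in for topology web predictors: plant AQPs are expected to show six
TM helices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import ProteinSequence

# average residue (i.e., amino acid minus water) masses, Da
RESIDUE_MASS_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524  # Da

# pK sets: (negative side chains, positive side chains, C-term, default N-term,
# residue-specific N-term overrides).  Bjellqvist values are the ExPASy set.
PK_SETS = {
    "bjellqvist": {
        "neg": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
        "pos": {"H": 5.98, "K": 10.0, "R": 12.0},
        "cterm": 3.55,
        "nterm": 7.5,
        "nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                             "T": 6.82, "V": 7.44, "E": 7.7},
        "cterm_by_residue": {"D": 4.55, "E": 4.75},
    },
    "emboss": {
        "neg": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
        "pos": {"H": 6.5, "K": 10.8, "R": 12.5},
        "cterm": 3.6,
        "nterm": 8.6,
        "nterm_by_residue": {},
        "cterm_by_residue": {},
    },
}

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class HydropathyParams:
    """Sliding-window TM segmentation parameters (residues / hydropathy units)."""

    window: int = 19
    threshold: float = 1.6
    merge_gap: int = 4
    min_len: int = 15
    max_len: int = 30


@dataclass(frozen=True)
class PhysChemProfile:
    """Table-2-style physicochemical summary of one protein."""

    query_id: str
    length_aa: int
    mw_kda: float
    pi: float
    tm_segments: tuple[tuple[int, int], ...]

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)


def molecular_weight(seq: ProteinSequence) -> float:
    """Average-isotopic molecular weight in kDa (residue masses + one water).

    Ambiguous residues (X) have no defined mass and raise ``ValueError``.
    """
    if "X" in seq.residues:
        raise ValueError(f"{seq.id}: ambiguous residue X has no defined mass")
    mass = sum(RESIDUE_MASS_AVG[a] for a in seq.residues) + WATER_MASS
    return mass / 1000.0


def net_charge(seq: ProteinSequence, ph, pk_set: str = "bjellqvist"):
    """Net protein charge at pH by Henderson-Hasselbalch summation.

    Sums fractional charges of the N-terminus, C-terminus and the ionizable
    side chains (D, E, C, Y on the acidic side; H, K, R on the basic side).
    ``ph`` may be a scalar or an array; the result matches its shape.
    """
    pk = PK_SETS[pk_set]
    ph = np.asarray(ph, dtype=float)
    counts_neg = {a: seq.residues.count(a) for a in pk["neg"]}
    counts_pos = {a: seq.residues.count(a) for a in pk["pos"]}

    def frac_pos(pka):
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def frac_neg(pka):
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    nterm_pk = pk["nterm_by_residue"].get(seq.residues[0], pk["nterm"])
    cterm_pk = pk["cterm_by_residue"].get(seq.residues[-1], pk["cterm"])
    charge = frac_pos(nterm_pk) + frac_neg(cterm_pk)
    for a, n in counts_pos.items():
        if n:
            charge = charge + n * frac_pos(pk["pos"][a])
    for a, n in counts_neg.items():
        if n:
            charge = charge + n * frac_neg(pk["neg"][a])
    return charge if charge.shape else float(charge)


def isoelectric_point(seq: ProteinSequence, pk_set: str = "bjellqvist",
                      tol: float = 1e-10) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is continuous and strictly decreasing in pH, so the
    root is unique.  Bisection runs to a very tight pH tolerance so the
    residual charge is negligible; callers wanting the conventional
    2-decimal report can round.
    """
    lo, hi = 0.0, 14.0
    f_lo = net_charge(seq, lo, pk_set)
    if f_lo <= 0:
        return lo
    if net_charge(seq, hi, pk_set) >= 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pk_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydropathy_profile(seq: ProteinSequence, window: int = 19) -> np.ndarray:
    """Windowed mean Kyte-Doolittle hydropathy, one value per window center.

    Entry ``i`` (0-based) is the mean over the window centered at 1-based
    residue position ``i + window//2 + 1``.
    """
    values = np.array([KYTE_DOOLITTLE[a] for a in seq.residues])
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tm_segments(seq: ProteinSequence,
                        params: HydropathyParams = HydropathyParams()
                        ) -> list[tuple[int, int]]:
    """Predict transmembrane segments from Kyte-Doolittle hydropathy.

    Maximal runs of window centers above the threshold become candidate
    segments; runs separated by fewer than ``merge_gap`` positions are
    merged, runs shorter than ``min_len`` dropped, and runs longer than
    ``max_len`` trimmed symmetrically around their hydropathy peak.
    Returns ordered, non-overlapping 1-based (start, end) intervals.
    """
    w = params.window
    if len(seq) < w:
        warnings.warn(f"{seq.id}: shorter than hydropathy window ({w}); no TM call")
        return []
    profile = hydropathy_profile(seq, w)
    offset = w // 2 + 1  # 1-based position of the first window center
    above = profile > params.threshold

    runs: list[list[int]] = []  # [start_center, end_center] in 1-based coords
    for i, flag in enumerate(above):
        pos = i + offset
        if flag:
            if runs and pos - runs[-1][1] == 1:
                runs[-1][1] = pos
            else:
                runs.append([pos, pos])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    segments: list[tuple[int, int]] = []
    for start, end in merged:
        if end - start + 1 < params.min_len:
            continue
        if end - start + 1 > params.max_len:
            centers = np.arange(start, end + 1)
            peak = int(centers[np.argmax(profile[centers - offset])])
            half = params.max_len // 2
            start = max(start, peak - half)
            end = start + params.max_len - 1
        segments.append((start, end))
    return segments


def physchem_profile(seq: ProteinSequence,
                     pk_set: str = "bjellqvist",
                     hydropathy: HydropathyParams = HydropathyParams()
                     ) -> PhysChemProfile:
    """Length, MW, pI and TM segments for one protein."""
    return PhysChemProfile(
        query_id=seq.id,
        length_aa=len(seq),
        mw_kda=molecular_weight(seq),
        pi=round(isoelectric_point(seq, pk_set), 2),
        tm_segments=tuple(predict_tm_segments(seq, hydropathy)),
    )
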