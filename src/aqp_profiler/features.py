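"""Alignment-anchored feature extraction.

The central procedure of the package: a query is globally aligned to a
panel of function-known reference AQPs (affine-gap Needleman-Wunsch,
BLOSUM62), the best-scoring reference is taken as the anchor, and the
anchor's annotated positions (NPA starts, ar/R filter, Froger's P1-P5,
SDP1-9) are projected through the alignment columns onto the query.  NPA
motifs are additionally located de novo from N-P-X scans between the
hydropathy-predicted TM helices; when the TM count is not the canonical
six, the anchor projection is trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .physchem import HydropathyParams, predict_tm_segments
from .seqio import FEATURE_KEYS, ProteinSequence, ReferenceAnchor

UNRESOLVED = "-"


class FeatureNotFoundError(LookupError):
    """A required motif could not be located and no anchor fallback exists."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring configuration: substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  ``matrix``
    is a named matrix shipped with Biopython or a path to an NCBI-format
    matrix file.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        return substitution_matrices.read(name)


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment with gapped strings of equal length."""

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    identity: float

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")


@dataclass(frozen=True)
class MotifHit:
    """An N-P-X tripeptide occurrence: motif string plus 1-based start."""

    motif: str
    start: int


@dataclass
class FeatureProfile:
    """Extracted feature residues of one query (Table-2/3-style symbols).

    ``arr`` holds (H2, H5, LE1, LE2), ``froger`` (P1..P5), ``sdp``
    (SDP1..SDP9); unresolved features (reference position aligned to a
    query gap) carry the sentinel ``-`` and are listed in ``unresolved``.
    """

    query_id: str
    anchor_ref_id: str
    npa_lb: str
    npa_lb_pos: int | None
    npa_le: str
    npa_le_pos: int | None
    arr: tuple[str, str, str, str]
    froger: tuple[str, str, str, str, str]
    sdp: tuple[str, ...]
    positions: dict[str, int | None] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Needleman-Wunsch with affine gaps (Gotoh), deterministic traceback

_NEG = -1e30  # effectively -inf, safe under addition


def global_align(query: ProteinSequence, ref: ProteinSequence,
                 params: AlignParams = AlignParams()) -> Alignment:
    """Optimal global alignment under substitution matrix + affine gaps.

    Three-state Gotoh dynamic programming; traceback ties are broken in the
    fixed order diagonal, then up (gap in reference), then left (gap in
    query), so the returned alignment is reproducible.
    """
    sub = _load_matrix(params.matrix)
    q, r = query.residues, ref.residues
    n, m = len(q), len(r)
    go, ge = params.gap_open, params.gap_extend

    alpha = {c: i for i, c in enumerate(sub.alphabet)}
    qi = np.array([alpha[c] for c in q])
    ri = np.array([alpha[c] for c in r])
    S = np.asarray(sub)[np.ix_(qi, ri)]  # pairwise substitution scores

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in reference (consumes query; "up")
    Y = np.full((n + 1, m + 1), _NEG)  # gap in query (consumes reference; "left")
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -(go + ge * np.arange(n))
    if m:
        Y[0, 1:] = -(go + ge * np.arange(m))

    idx = np.arange(m)
    for i in range(1, n + 1):
        M[i, 1:] = S[i - 1] + np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - go, X[i - 1, 1:] - ge, Y[i - 1, 1:] - go])
        X[i, 0] = -(go + ge * (i - 1))
        # Y row: Y[i,j] = max(Z[j-1], Y[i,j-1] - ge) with Z[k] = max(M,X)[i,k] - go,
        # which unrolls to a prefix max of Z[k] + ge*k
        Z = np.maximum(M[i, :-1], X[i, :-1]) - go
        Y[i, 1:] = np.maximum.accumulate(Z + ge * idx) - ge * idx

    aligned_q, aligned_r = _traceback(q, r, S, M, X, Y, go, ge)
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    pairs = [(a, b) for a, b in zip(aligned_q, aligned_r) if a != "-" and b != "-"]
    identity = (sum(a == b for a, b in pairs) / len(pairs)) if pairs else 0.0
    return Alignment(query_id=query.id, ref_id=ref.id, aligned_query=aligned_q,
                     aligned_ref=aligned_r, score=score, identity=identity)


def _traceback(q, r, S, M, X, Y, go, ge):
    i, j = len(q), len(r)
    # final state preference mirrors the move preference: diagonal, up, left
    best = max(M[i, j], X[i, j], Y[i, j])
    state = "M" if M[i, j] == best else ("X" if X[i, j] == best else "Y")
    out_q, out_r = [], []
    while i > 0 or j > 0:
        if state == "M":
            out_q.append(q[i - 1])
            out_r.append(r[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick(M[i, j], X[i, j], Y[i, j], target)
        elif state == "X":
            out_q.append(q[i - 1])
            out_r.append("-")
            if i == 1 and j == 0:
                break
            prev = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            target = X[i, j]
            i -= 1
            state = _pick(*prev, target)
        else:
            out_q.append("-")
            out_r.append(r[j - 1])
            if j == 1 and i == 0:
                break
            prev = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            target = Y[i, j]
            j -= 1
            state = _pick(*prev, target)
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    return "".join(reversed(out_q)), "".join(reversed(out_r))


def _pick(m_val, x_val, y_val, target):
    # exact float comparison is safe: scores are sums of matrix entries and
    # half-integer gap penalties
    if m_val == target:
        return "M"
    if x_val == target:
        return "X"
    if y_val == target:
        return "Y"
    raise AssertionError("traceback lost the optimal path")


def select_best_reference(query: ProteinSequence,
                          refs: list[ReferenceAnchor],
                          params: AlignParams = AlignParams()
                          ) -> tuple[ReferenceAnchor, Alignment]:
    """Anchor with the maximal alignment score; ties keep input order."""
    if not refs:
        raise ValueError("reference panel is empty")
    best: tuple[ReferenceAnchor, Alignment] | None = None
    for ref in refs:
        aln = global_align(query, ref.sequence, params)
        if best is None or aln.score > best[1].score:
            best = (ref, aln)
    return best


def project_positions(aln: Alignment, ref_positions) -> dict[str, int | None]:
    """Carry reference feature positions through alignment columns.

    A reference position whose column pairs with a query gap maps to
    ``None`` (unresolved).  Positions are 1-based on both sides.
    """
    ref_len = sum(c != "-" for c in aln.aligned_ref)
    for name, pos in ref_positions.items():
        if not 1 <= pos <= ref_len:
            raise ValueError(f"feature {name}: position {pos} outside reference")
    ref_to_query: dict[int, int | None] = {}
    ref_pos = query_pos = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if qc != "-":
            query_pos += 1
        if rc != "-":
            ref_pos += 1
            ref_to_query[ref_pos] = query_pos if qc != "-" else None
    return {name: ref_to_query[pos] for name, pos in ref_positions.items()}


# ---------------------------------------------------------------------------
# NPA motifs

def _scan_npx(residues: str) -> list[MotifHit]:
    hits = []
    for i in range(len(residues) - 2):
        if residues[i] == "N" and residues[i + 1] == "P":
            hits.append(MotifHit(motif=residues[i:i + 3], start=i + 1))
    return hits


def find_npa_motifs(seq: ProteinSequence,
                    tm_segments: list[tuple[int, int]] | None = None,
                    anchor_positions: dict[str, int | None] | None = None
                    ) -> tuple[MotifHit, MotifHit]:
    """Locate the loop-B and loop-E NPA motifs (variants N-P-X).

    With six TM segments, the loop-B candidate is the first N-P-X strictly
    between TM2 and TM3 and the loop-E candidate the first between TM5 and
    TM6.  With any other TM count the positions projected from the anchor
    are used; failing both, a whole-sequence scan needs at least two N-P-X
    occurrences (first = LB, last = LE) before giving up with
    :class:`FeatureNotFoundError`.
    """
    if tm_segments is not None and len(tm_segments) == 6:
        lb = _first_hit_between(seq, tm_segments[1][1], tm_segments[2][0])
        le = _first_hit_between(seq, tm_segments[4][1], tm_segments[5][0])
        if lb and le:
            return lb, le
    if anchor_positions is not None:
        lb_pos = anchor_positions.get("NPA_LB")
        le_pos = anchor_positions.get("NPA_LE")
        if lb_pos and le_pos and le_pos + 2 <= len(seq):
            return (MotifHit(seq.residues[lb_pos - 1:lb_pos + 2], lb_pos),
                    MotifHit(seq.residues[le_pos - 1:le_pos + 2], le_pos))
    hits = _scan_npx(seq.residues)
    if len(hits) >= 2:
        return hits[0], hits[-1]
    raise FeatureNotFoundError(
        f"{seq.id}: NPA motifs not found (N-P-X hits: {len(hits)}, no anchor)")


def _first_hit_between(seq: ProteinSequence, loop_start_excl: int,
                       loop_end_excl: int) -> MotifHit | None:
    for hit in _scan_npx(seq.residues):
        if loop_start_excl < hit.start and hit.start + 2 < loop_end_excl:
            return hit
    return None


# ---------------------------------------------------------------------------
# Profile assembly

def extract_feature_profile(query: ProteinSequence,
                            refs: list[ReferenceAnchor],
                            params: AlignParams = AlignParams(),
                            hydropathy: HydropathyParams = HydropathyParams()
                            ) -> FeatureProfile:
    """Project all 20 anchored feature positions onto a query.

    Selects the best-scoring anchor, projects its positions and reads the
    query residues there.  NPA motif strings are the three query residues
    from the projected starts; when hydropathy finds exactly six TM
    segments the de novo N-P-X scan cross-checks the projection, and any
    discrepancy is recorded as a warning (projection wins).
    """
    anchor, aln = select_best_reference(query, refs, params)
    projected = project_positions(aln, dict(anchor.feature_positions))
    notes: list[str] = []
    unresolved = {k for k, v in projected.items() if v is None}

    def residue(key: str) -> str:
        pos = projected.get(key)
        return query.residues[pos - 1] if pos else UNRESOLVED

    def motif(key: str) -> tuple[str, int | None]:
        pos = projected.get(key)
        if pos is None or pos + 2 > len(query):
            unresolved.add(key)
            return UNRESOLVED * 3, None
        return query.residues[pos - 1:pos + 2], pos

    npa_lb, lb_pos = motif("NPA_LB")
    npa_le, le_pos = motif("NPA_LE")

    tm = predict_tm_segments(query, hydropathy)
    if len(tm) == 6:
        try:
            scan_lb, scan_le = find_npa_motifs(query, tm)
            if lb_pos is not None and scan_lb.start != lb_pos:
                notes.append(
                    f"NPA_LB scan ({scan_lb.motif}@{scan_lb.start}) disagrees "
                    f"with projection (@{lb_pos}); projection kept")
            if le_pos is not None and scan_le.start != le_pos:
                notes.append(
                    f"NPA_LE scan ({scan_le.motif}@{scan_le.start}) disagrees "
                    f"with projection (@{le_pos}); projection kept")
        except FeatureNotFoundError:
            notes.append("six TM segments but no N-P-X in loop windows")

    return FeatureProfile(
        query_id=query.id,
        anchor_ref_id=anchor.id,
        npa_lb=npa_lb, npa_lb_pos=lb_pos,
        npa_le=npa_le, npa_le_pos=le_pos,
        arr=(residue("H2"), residue("H5"), residue("LE1"), residue("LE2")),
        froger=tuple(residue(f"P{k}") for k in range(1, 6)),
        sdp=tuple(residue(f"SDP{k}") for k in range(1, 10)),
        positions=projected,
        unresolved=unresolved,
        warnings=notes,
    )
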