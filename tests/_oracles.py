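"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic-programming / bisection /
agglomerative code paths: alignment scores come from exhaustive path
enumeration, pI from a dense grid scan, and quartet topologies from
least-squares fits over all three pairings.
"""

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def exhaustive_align_score(q: str, r: str, gap_open=10.0, gap_extend=0.5) -> float:
    """Best global alignment score by enumerating every alignment path.

    Affine convention: a gap of length L costs gap_open + (L-1)*gap_extend.
    Exponential; only for short sequences.
    """
    best = [-np.inf]

    def walk(i, j, score, prev):
        if i == len(q) and j == len(r):
            best[0] = max(best[0], score)
            return
        if i < len(q) and j < len(r):
            walk(i + 1, j + 1, score + _BLOSUM62[q[i], r[j]], "D")
        if i < len(q):
            cost = gap_extend if prev == "U" else gap_open
            walk(i + 1, j, score - cost, "U")
        if j < len(r):
            cost = gap_extend if prev == "L" else gap_open
            walk(i, j + 1, score - cost, "L")

    walk(0, 0, 0.0, "")
    return best[0]


def grid_pi(charge_fn, step=0.001) -> float:
    """pH grid scan minimizing |net charge| on [0, 14]."""
    grid = np.arange(0.0, 14.0 + step / 2, step)
    charges = np.abs(charge_fn(grid))
    return float(grid[np.argmin(charges)])


def quartet_topology_ls(dm) -> frozenset:
    """Best 4-taxon topology by least-squares over the three pairings.

    For the pairing (AB|CD) the five branch lengths have a closed-form
    least-squares fit; the pairing with the smallest residual wins.
    Returns the winning cherry as a frozenset of two taxon ids.
    """
    ids = list(dm.ids)
    assert len(ids) == 4
    best = None
    for pair in itertools.combinations(ids, 2):
        a, b = pair
        c, d = [x for x in ids if x not in pair]
        residual = _ls_residual(dm, (a, b), (c, d))
        if best is None or residual < best[0] - 1e-12:
            best = (residual, frozenset((a, b)))
    return best[1]


def _ls_residual(dm, cherry1, cherry2):
    """Sum of squared errors of the best additive fit for one quartet pairing."""
    a, b = cherry1
    c, d = cherry2
    ids = [a, b, c, d]
    pairs = list(itertools.combinations(range(4), 2))
    # unknowns: external branches ea, eb, ec, ed and internal m
    A = np.zeros((6, 5))
    y = np.zeros(6)
    for row, (i, j) in enumerate(pairs):
        A[row, i] = 1
        A[row, j] = 1
        same_side = {i, j} in ({0, 1}, {2, 3})
        if not same_side:
            A[row, 4] = 1
        y[row] = dm[ids[i], ids[j]]
    x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ x
    return float(((fit - y) ** 2).sum())
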