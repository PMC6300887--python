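"""Cheng-Church biclustering of the substructure-ADR bipartite matrix.

Significant substructure-ADR associations form a binary bipartite adjacency
(rows: substructures, columns: ADRs).  The Cheng-Church algorithm finds
submatrices with low mean squared residue H(I,J) — coherence under an
additive row+column model — by multiple/single node deletion followed by
node addition, then masks each found bicluster with random values before
searching for the next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .assoc_stats import SubstructureAssociation

logger = logging.getLogger(__name__)


@dataclass
class BipartiteMatrix:
    rows: list[str]  # substructure SMARTS
    cols: list[str]  # ADR ids
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.rows), len(self.cols)):
            raise ValueError("bipartite matrix shape mismatch")
        if set(np.unique(self.A)) - {0, 1}:
            raise ValueError("bipartite matrix must be binary")


@dataclass
class Bicluster:
    row_set: list
    col_set: list
    residue: float

    @property
    def area(self) -> int:
        return len(self.row_set) * len(self.col_set)


def build_bipartite(associations: list[SubstructureAssociation], alpha: float = 0.05) -> BipartiteMatrix:
    """Adjacency over substructures/ADRs with >= 1 significant association.

    An edge is a scored association with p <= alpha; duplicate (smarts, adr)
    pairs collapse.  Entities without any significant edge are dropped.
    """
    edges = {(x.smarts, x.adr) for x in associations if x.p_value <= alpha}
    if not edges:
        logger.warning("no significant association at alpha=%g; empty bipartite graph", alpha)
        return BipartiteMatrix(rows=[], cols=[], A=np.zeros((0, 0), dtype=np.int8))
    rows = sorted({s for s, _ in edges})
    cols = sorted({a for _, a in edges})
    A = np.zeros((len(rows), len(cols)), dtype=np.int8)
    ri = {s: i for i, s in enumerate(rows)}
    ci = {a: j for j, a in enumerate(cols)}
    for s, a in edges:
        A[ri[s], ci[a]] = 1
    return BipartiteMatrix(rows=rows, cols=cols, A=A)


def msr(A: np.ndarray, row_set, col_set) -> float:
    """Mean squared residue H(I,J) of the submatrix A[I, J].

    H = mean over (i,j) of (a_ij - rowmean_i - colmean_j + overallmean)^2;
    zero for any submatrix of the form a_ij = r_i + c_j.
    """
    I = np.asarray(list(row_set), dtype=np.intp)
    J = np.asarray(list(col_set), dtype=np.intp)
    if len(I) == 0 or len(J) == 0:
        raise ValueError("row and column sets must be non-empty")
    sub = np.asarray(A, dtype=float)[np.ix_(I, J)]
    res = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(res * res))


def _residues(A: np.ndarray, I: np.ndarray, J: np.ndarray):
    """Per-row and per-column mean squared residues and overall H."""
    sub = A[np.ix_(I, J)]
    res = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    sq = res * res
    return sq.mean(axis=1), sq.mean(axis=0), sq.mean()


def _single_deletion(A, I, J, delta):
    while len(I) > 1 or len(J) > 1:
        d_i, e_j, H = _residues(A, I, J)
        if H <= delta:
            break
        ri, cj = int(np.argmax(d_i)), int(np.argmax(e_j))
        if len(J) == 1 or (len(I) > 1 and d_i[ri] >= e_j[cj]):
            I = np.delete(I, ri)
        else:
            J = np.delete(J, cj)
    return I, J


def _multiple_deletion(A, I, J, delta, alpha_multi):
    while True:
        d_i, e_j, H = _residues(A, I, J)
        if H <= delta:
            return I, J
        changed = False
        keep = d_i <= alpha_multi * H
        if keep.sum() >= 1 and not keep.all():
            I = I[keep]
            changed = True
        d_i, e_j, H = _residues(A, I, J)
        if H <= delta:
            return I, J
        keep = e_j <= alpha_multi * H
        if keep.sum() >= 1 and not keep.all():
            J = J[keep]
            changed = True
        if not changed:
            return I, J


def _node_addition(A, I, J, delta):
    n, m = A.shape
    while True:
        changed = False
        _, _, H = _residues(A, I, J)
        for j in range(m):
            if j in J:
                continue
            Jx = np.append(J, j)
            if msr(A, I, Jx) <= max(H, delta):
                J = np.sort(Jx)
                changed = True
                _, _, H = _residues(A, I, J)
        for i in range(n):
            if i in I:
                continue
            Ix = np.append(I, i)
            if msr(A, Ix, J) <= max(H, delta):
                I = np.sort(Ix)
                changed = True
                _, _, H = _residues(A, I, J)
        if not changed:
            return I, J


def _refine_biclique(M: np.ndarray, I: np.ndarray, J: np.ndarray, min_mean: float):
    """Extract the dense biclique core of a low-residue region.

    The mean squared residue cannot tell an all-ones block from the same
    block padded with all-zero rows (both are additively coherent), so a raw
    low-residue bicluster on a binary adjacency is often a block/background
    mixture.  This step trims rows and columns whose mean inside the
    bicluster is below ``min_mean``, then re-adds any row or column of the
    original matrix that is dense against the trimmed core.
    """
    I, J = I.copy(), J.copy()
    while len(I) and len(J):
        sub = M[np.ix_(I, J)]
        rmeans, cmeans = sub.mean(axis=1), sub.mean(axis=0)
        wr, wc = int(rmeans.argmin()), int(cmeans.argmin())
        if rmeans[wr] >= min_mean and cmeans[wc] >= min_mean:
            break
        if rmeans[wr] <= cmeans[wc]:
            I = np.delete(I, wr)
        else:
            J = np.delete(J, wc)
    if not (len(I) and len(J)):
        return I, J
    changed = True
    while changed:
        changed = False
        for i in range(M.shape[0]):
            if i not in I and M[i, J].mean() >= min_mean:
                I = np.sort(np.append(I, i))
                changed = True
        for j in range(M.shape[1]):
            if j not in J and M[I, j].mean() >= min_mean:
                J = np.sort(np.append(J, j))
                changed = True
    return I, J


def cheng_church(
    A: np.ndarray,
    delta: float = 0.05,
    n_biclusters: int = 10,
    alpha_multi: float = 1.2,
    seed: int = 0,
    min_density: float | None = 0.5,
) -> list[Bicluster]:
    """Find up to ``n_biclusters`` dense low-residue biclusters.

    Each round: multiple node deletion (rows/columns whose mean residue
    exceeds alpha_multi * H), single node deletion until H <= delta, node
    addition, then — because the target objects are bicliques of a binary
    adjacency — refinement to the dense core against the original matrix
    (disable with ``min_density=None`` for the raw low-residue behaviour).
    The found region is masked with Bernoulli(0.5) draws (binary analogue of
    random-range masking) before the next round; regions whose core density
    falls below ``min_density`` are treated as trivial background: masked
    but not reported.  Deterministic given the seed.  Results sorted by
    area, largest first.
    """
    if delta < 0 or alpha_multi < 1:
        raise ValueError("need delta >= 0 and alpha_multi >= 1")
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        return []
    work = A.copy()
    rng = np.random.default_rng(seed)
    found: list[Bicluster] = []
    seen: set[tuple] = set()
    reported: set[tuple] = set()
    for _ in range(max(5 * n_biclusters, 20)):
        if len(found) >= n_biclusters:
            break
        I = np.arange(A.shape[0], dtype=np.intp)
        J = np.arange(A.shape[1], dtype=np.intp)
        I, J = _multiple_deletion(work, I, J, delta, alpha_multi)
        I, J = _single_deletion(work, I, J, delta)
        if msr(work, I, J) > delta:
            logger.warning("could not reach residue <= %g; stopping at %d biclusters", delta, len(found))
            break
        I, J = _node_addition(work, I, J, delta)
        key = (tuple(I), tuple(J))
        if key in seen:
            break
        seen.add(key)
        if min_density is not None:
            Ic, Jc = _refine_biclique(A, I, J, min_density)
        else:
            Ic, Jc = I, J
        work[np.ix_(I, J)] = (rng.random((len(I), len(J))) < 0.5).astype(float)
        if len(Ic) == 0 or len(Jc) == 0 or len(Ic) * len(Jc) <= 1:
            continue
        if min_density is not None and A[np.ix_(Ic, Jc)].mean() < min_density:
            continue
        ckey = (tuple(Ic), tuple(Jc))
        if ckey in reported:
            continue
        reported.add(ckey)
        found.append(Bicluster(row_set=list(map(int, Ic)), col_set=list(map(int, Jc)),
                               residue=msr(A, Ic, Jc)))
    if len(found) < n_biclusters:
        logger.warning("found %d/%d biclusters", len(found), n_biclusters)
    return sorted(found, key=lambda bc: (-bc.area, bc.row_set, bc.col_set))


def biclusters_to_json(bip: BipartiteMatrix, biclusters: list[Bicluster]) -> list[dict]:
    return [
        {
            "rows": [bip.rows[i] for i in bc.row_set],
            "cols": [bip.cols[j] for j in bc.col_set],
            "residue": bc.residue,
        }
        for bc in biclusters
    ]
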