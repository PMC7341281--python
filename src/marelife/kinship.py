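"""Pedigree relationship matrices and inbreeding coefficients.

Implements the classical machinery of pedigree-based quantitative genetics:

* ``compute_inbreeding`` — inbreeding coefficient ``F`` per animal, where
  ``F_x = a(sire_x, dam_x) / 2`` and ``a`` is the additive relationship.
* ``build_A`` — the numerator (additive) relationship matrix by the tabular
  method, with ``diag(A) = 1 + F``.
* ``build_A_inverse`` — Henderson's direct sparse rules for ``A^{-1}``,
  accounting for parental inbreeding through the Mendelian-sampling
  variance ``m_x = 1 − 0.25(1 + F_s) − 0.25(1 + F_d)`` (terms for unknown
  parents dropped).
* ``build_D`` — the dominance relationship matrix in the classical
  non-inbred approximation
  ``d_ij = 0.25 (a_{s_i s_j} a_{d_i d_j} + a_{s_i d_j} a_{d_i s_j})``.

Pedigrees are pandas DataFrames with columns ``animal_id``, ``sire_id``,
``dam_id`` (0 = unknown), ``birth_year``, ``sex``.  Unknown parents are
treated as unrelated, non-inbred founders.  ``A`` is materialized dense
(vectorized tabular recurrence), which is practical up to pedigrees of a
few thousand animals — the scale this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0

__all__ = [
    "KinshipMatrices",
    "sort_pedigree",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "build_D",
    "compute_kinship",
    "export_triplets",
]


class PedigreeError(ValueError):
    """Raised for cyclic or otherwise inconsistent pedigrees."""


@dataclass
class KinshipMatrices:
    """Bundle of pedigree relationship structures, aligned to ``ids``."""

    ids: np.ndarray                    # animal ids in ancestor-first order
    A: np.ndarray                      # dense numerator relationship matrix
    A_inv: sp.csr_matrix               # sparse inverse of A
    F: np.ndarray                      # inbreeding coefficients, diag(A) - 1
    index: dict = field(repr=False, default_factory=dict)  # id -> row

    def subset_D(self, ids) -> np.ndarray:
        """Dominance relationship matrix restricted to ``ids`` (see build_D)."""
        ped = self._ped
        return build_D(ped, self.A, ids=ids, index=self.index)

    _ped: pd.DataFrame = field(repr=False, default=None)


def sort_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Return the pedigree ordered ancestors-first (topological order).

    Raises :class:`PedigreeError` on cycles (including an animal listed as
    its own ancestor) or on parents missing from the animal column.
    """
    ped = pedigree.reset_index(drop=True)
    ids = ped["animal_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise PedigreeError("duplicate animal_id in pedigree")
    known = set(ids)
    for col in ("sire_id", "dam_id"):
        bad = set(ped[col]) - known - {UNKNOWN}
        if bad:
            raise PedigreeError(f"{col} values not in pedigree: {sorted(bad)[:5]}")

    pos = {a: i for i, a in enumerate(ids)}
    sire = ped["sire_id"].to_numpy()
    dam = ped["dam_id"].to_numpy()
    n = len(ids)
    # Kahn's algorithm on parent -> offspring edges
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                j = pos[p]
                if j == i:
                    raise PedigreeError(f"animal {ids[i]} is its own parent")
                children[j].append(i)
                indeg[i] += 1
    order: list[int] = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        j = order[head]
        head += 1
        for c in children[j]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) != n:
        cyc = [ids[i] for i in range(n) if indeg[i] > 0]
        raise PedigreeError(f"pedigree contains a cycle involving {cyc[:5]}")
    return ped.iloc[order].reset_index(drop=True)


def _parent_indices(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict]:
    index = {a: i for i, a in enumerate(ped["animal_id"].to_numpy())}
    s = np.array([index.get(x, -1) for x in ped["sire_id"]], dtype=int)
    d = np.array([index.get(x, -1) for x in ped["dam_id"]], dtype=int)
    return s, d, index


def build_A(pedigree: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Numerator relationship matrix by the tabular method.

    Returns ``(A, sorted_pedigree)``; row/column order of ``A`` follows the
    sorted pedigree.  The recurrence is
    ``a_ij = (a_{i,s_j} + a_{i,d_j}) / 2`` for ``i < j`` and
    ``a_jj = 1 + a_{s_j,d_j} / 2``.
    """
    ped = sort_pedigree(pedigree)
    s, d, _ = _parent_indices(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for j in range(n):
        sj, dj = s[j], d[j]
        if sj >= 0 and dj >= 0:
            row = 0.5 * (A[:j, sj] + A[:j, dj])
            ajj = 1.0 + 0.5 * A[sj, dj]
        elif sj >= 0 or dj >= 0:
            p = sj if sj >= 0 else dj
            row = 0.5 * A[:j, p]
            ajj = 1.0
        else:
            row = np.zeros(j)
            ajj = 1.0
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = ajj
    return A, ped


def compute_inbreeding(pedigree: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficient per animal (index = animal_id).

    ``F_x = a(sire_x, dam_x) / 2``; any unknown parent contributes zero
    relationship, so founders and animals with an unknown parent have F = 0.
    """
    A, ped = build_A(pedigree)
    return pd.Series(np.diag(A) - 1.0, index=ped["animal_id"].to_numpy(), name="F")


def build_A_inverse(pedigree: pd.DataFrame, F: pd.Series | None = None) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    ``F`` may be supplied (indexed by animal_id) to skip recomputation; it
    must cover every animal in the pedigree.
    """
    ped = sort_pedigree(pedigree)
    ids = ped["animal_id"].to_numpy()
    if F is None:
        F = compute_inbreeding(ped)
    try:
        Fv = F.loc[ids].to_numpy(dtype=float)
    except KeyError as e:
        raise PedigreeError(f"F missing for pedigree animal: {e}") from e
    if np.any(Fv < -1e-12) or np.any(Fv >= 1.0):
        raise PedigreeError("inbreeding coefficients outside [0, 1)")
    s, d, _ = _parent_indices(ped)
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for x in range(n):
        sx, dx = s[x], d[x]
        m = 1.0
        if sx >= 0:
            m -= 0.25 * (1.0 + Fv[sx])
        if dx >= 0:
            m -= 0.25 * (1.0 + Fv[dx])
        alpha = 1.0 / m
        add(x, x, alpha)
        for p in (sx, dx):
            if p >= 0:
                add(x, p, -0.5 * alpha)
                add(p, x, -0.5 * alpha)
        for p in (sx, dx):
            for q in (sx, dx):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    A_inv = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    return A_inv, ped


def build_D(
    pedigree: pd.DataFrame,
    A: np.ndarray,
    ids=None,
    index: dict | None = None,
) -> np.ndarray:
    """Dominance relationship matrix (classical non-inbred approximation).

    ``d_ij = 0.25 (a_{s_i s_j} a_{d_i d_j} + a_{s_i d_j} a_{d_i s_j})`` for
    animals with both parents known; off-diagonals involving an animal with
    an unknown parent are 0; ``d_ii = 1``.  ``A`` and ``pedigree`` must be
    aligned (output of :func:`build_A`).  ``ids`` restricts the result to a
    subset of animals (rows/cols in the given order).
    """
    if index is None:
        index = {a: i for i, a in enumerate(pedigree["animal_id"].to_numpy())}
    s, d, _ = _parent_indices(pedigree)
    if ids is None:
        rows = np.arange(len(pedigree))
    else:
        rows = np.array([index[a] for a in ids], dtype=int)
    ss = s[rows]
    dd = d[rows]
    both = (ss >= 0) & (dd >= 0)
    # clamp unknown-parent indices to 0 for fancy indexing; masked out below
    sc = np.where(both, ss, 0)
    dc = np.where(both, dd, 0)
    D = 0.25 * (A[np.ix_(sc, sc)] * A[np.ix_(dc, dc)] + A[np.ix_(sc, dc)] * A[np.ix_(dc, sc)])
    D[~both, :] = 0.0
    D[:, ~both] = 0.0
    np.fill_diagonal(D, 1.0)
    return D


def compute_kinship(pedigree: pd.DataFrame) -> KinshipMatrices:
    """Convenience: A, A^{-1}, F and id index in one aligned bundle."""
    A, ped = build_A(pedigree)
    F = pd.Series(np.diag(A) - 1.0, index=ped["animal_id"].to_numpy(), name="F")
    A_inv, _ = build_A_inverse(ped, F)
    ids = ped["animal_id"].to_numpy()
    km = KinshipMatrices(
        ids=ids,
        A=A,
        A_inv=A_inv,
        F=F.to_numpy(),
        index={a: i for i, a in enumerate(ids)},
    )
    km._ped = ped
    return km


def export_triplets(M, path, ids=None) -> None:
    """Write a matrix as (i, j, value) triplets, one per line, 1-based."""
    if sp.issparse(M):
        M = M.tocoo()
        rows, cols, vals = M.row, M.col, M.data
    else:
        rows, cols = np.nonzero(M)
        vals = np.asarray(M)[rows, cols]
    with open(path, "w") as fh:
        fh.write("i,j,value\n")
        for r, c, v in zip(rows, cols, vals):
            i = ids[r] if ids is not None else r + 1
            j = ids[c] if ids is not None else c + 1
            fh.write(f"{i},{j},{v:.10g}\n")
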