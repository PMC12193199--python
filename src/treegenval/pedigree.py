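"""Numerator relationship matrices, with and without metafounders.

A pedigree is renumbered to a topological integer coding (parents precede
offspring). The additive relationship matrix A follows the tabular recursion;
its sparse inverse follows Henderson's rules with inbreeding. In metafounder
mode each base population is a pseudo-individual with self-relationship
``gamma_jj`` and across-population relationships ``gamma_jk``; the recursion is
seeded with that ``Gamma`` block, so a founder of group j gets diagonal
``1 + gamma_jj / 2`` and the whole matrix A(Gamma) stays compatible with a
genomic matrix built at allele frequency 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .io_prep import UNKNOWN, PedigreeCycleError, RawPedigreeTable

#: Pedigrees above this size are not materialized densely.
DENSE_LIMIT = 6000


@dataclass
class GammaMatrix:
    """Symmetric PSD relationship matrix among metafounders."""

    values: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        g = np.atleast_2d(np.asarray(self.values, dtype=float))
        if g.shape[0] != g.shape[1] or not np.allclose(g, g.T, atol=1e-12):
            raise ValueError("Gamma must be square and symmetric")
        if np.linalg.eigvalsh(g).min() < -1e-10:
            raise ValueError("Gamma must be positive semidefinite")
        if np.any(np.diag(g) < 0) or np.any(np.diag(g) > 2):
            raise ValueError("Gamma diagonal entries must lie in [0, 2]")
        self.values = g
        if not self.labels:
            self.labels = tuple(f"g{j}" for j in range(g.shape[0]))

    @property
    def g(self) -> int:
        return self.values.shape[0]

    def inverse(self, ridge: float = 1e-8) -> np.ndarray:
        """Inverse of Gamma; a PSD-but-singular Gamma gets a ridge ``eps``."""
        try:
            return np.linalg.inv(self.values)
        except np.linalg.LinAlgError:
            pass
        cond = np.linalg.cond(self.values)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"Gamma is singular (cond={cond:.2e}); add a ridge or merge groups"
            )
        return np.linalg.inv(self.values + ridge * np.eye(self.g))


@dataclass
class Pedigree:
    """Renumbered pedigree in topological order.

    ``sire``/``dam`` hold row indices (< own row) or −1 for unknown. In
    metafounder mode the first ``n_mf`` rows are the metafounders themselves
    and no slot below them is −1. ``groups`` keeps the origin label each
    individual's unknown-parent slots map to.
    """

    ids: np.ndarray  # object array
    sire: np.ndarray  # int64, -1 = unknown
    dam: np.ndarray
    groups: np.ndarray  # object array of labels ('' = none)
    n_mf: int = 0
    mf_labels: tuple = ()

    def __post_init__(self) -> None:
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= np.arange(self.n)[known]):
                raise ValueError("pedigree is not topologically ordered")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_mf(self) -> bool:
        return self.n_mf > 0

    def rows_of(self, ids) -> np.ndarray:
        index = {ident: k for k, ident in enumerate(self.ids)}
        return np.asarray([index[i] for i in ids], dtype=np.int64)


def renumber(raw: RawPedigreeTable) -> Pedigree:
    """Topologically order a raw pedigree and recode parents as row indices.

    Parents referenced but never listed as individuals are appended as
    founders (empty group). Cycles are reported with their member ids.
    """
    df = raw.df
    ids = list(df["id"])
    known = set(ids)
    parents = {}
    groups = {}
    for ident, s, d, g in zip(df["id"], df["sire"], df["dam"], df["group"]):
        parents[ident] = (s, d)
        groups[ident] = g
    for ident in ids:
        for p in parents[ident]:
            if p != UNKNOWN and p not in known:
                parents[p] = (UNKNOWN, UNKNOWN)
                groups[p] = ""
                known.add(p)
                ids.append(p)

    # Kahn's algorithm with a FIFO queue keeps file order among ready nodes.
    children = {i: [] for i in ids}
    indeg = {}
    for ident in ids:
        deg = 0
        for p in parents[ident]:
            if p != UNKNOWN:
                children[p].append(ident)
                deg += 1
        indeg[ident] = deg
    from collections import deque

    queue = deque(i for i in ids if indeg[i] == 0)
    order = []
    while queue:
        ident = queue.popleft()
        order.append(ident)
        for child in children[ident]:
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(child)
    if len(order) != len(ids):
        cycle = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeCycleError(f"pedigree contains a cycle involving: {cycle}")

    row = {ident: k for k, ident in enumerate(order)}
    sire = np.asarray([row[parents[i][0]] if parents[i][0] != UNKNOWN else -1 for i in order],
                      dtype=np.int64)
    dam = np.asarray([row[parents[i][1]] if parents[i][1] != UNKNOWN else -1 for i in order],
                     dtype=np.int64)
    grp = np.asarray([groups[i] for i in order], dtype=object)
    return Pedigree(np.asarray(order, dtype=object), sire, dam, grp)


def attach_metafounders(ped: Pedigree, group_map: dict | None = None,
                        labels: tuple | None = None) -> Pedigree:
    """Rewire every unknown-parent slot to its group's metafounder.

    ``group_map`` optionally collapses raw origin labels into metafounder
    labels. An unknown slot whose individual has no (mapped) label is an
    assignment error. Metafounders are prepended to the pedigree.
    """
    if ped.is_mf:
        raise ValueError("pedigree already has metafounders attached")
    mapped = [group_map.get(g, g) if group_map else g for g in ped.groups]
    needs = (ped.sire < 0) | (ped.dam < 0)
    missing = [ped.ids[k] for k in np.flatnonzero(needs) if mapped[k] == ""]
    if missing:
        raise ValueError(f"unknown-parent individuals without a group label: {missing[:10]}")
    if labels is None:
        labels = tuple(dict.fromkeys(mapped[k] for k in np.flatnonzero(needs)))
    mf_row = {lab: j for j, lab in enumerate(labels)}
    g = len(labels)

    sire = ped.sire + g
    dam = ped.dam + g
    for k in np.flatnonzero(needs):
        if mapped[k] not in mf_row:
            raise ValueError(f"group label {mapped[k]!r} not among metafounders {labels}")
        if ped.sire[k] < 0:
            sire[k] = mf_row[mapped[k]]
        if ped.dam[k] < 0:
            dam[k] = mf_row[mapped[k]]
    mf_ids = np.asarray([f"MF:{lab}" for lab in labels], dtype=object)
    neg = np.full(g, -1, dtype=np.int64)
    return Pedigree(
        ids=np.concatenate([mf_ids, ped.ids]),
        sire=np.concatenate([neg, sire]),
        dam=np.concatenate([neg, dam]),
        groups=np.concatenate([np.asarray(labels, dtype=object), ped.groups]),
        n_mf=g,
        mf_labels=tuple(labels),
    )


@njit(cache=True)
def _tabular_kernel(sire, dam, A, start):  # pragma: no cover - numba
    n = A.shape[0]
    for i in range(start, n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[j, i] = a
            A[i, j] = a
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def _check_dense(n: int) -> None:
    if n > DENSE_LIMIT:
        raise MemoryError(
            f"pedigree of {n} exceeds the dense materialization limit {DENSE_LIMIT}"
        )


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix by the tabular method (plain mode)."""
    if ped.is_mf:
        raise ValueError("use tabular_A_gamma for a metafounder pedigree")
    _check_dense(ped.n)
    A = np.zeros((ped.n, ped.n))
    return _tabular_kernel(ped.sire, ped.dam, A, 0)


def tabular_A_gamma(ped: Pedigree, gamma: GammaMatrix) -> np.ndarray:
    """Dense A(Gamma): tabular recursion seeded with the metafounder block.

    The metafounder block of the result is Gamma itself (self-relationship
    ``gamma_jj`` on the diagonal); descendants follow the standard rules, so a
    founder of group j has diagonal ``1 + gamma_jj / 2``.
    """
    if not ped.is_mf:
        raise ValueError("attach_metafounders first")
    if gamma.g != ped.n_mf:
        raise ValueError(f"Gamma is {gamma.g}x{gamma.g} but pedigree has {ped.n_mf} metafounders")
    _check_dense(ped.n)
    A = np.zeros((ped.n, ped.n))
    A[: ped.n_mf, : ped.n_mf] = gamma.values
    return _tabular_kernel(ped.sire, ped.dam, A, ped.n_mf)


def inbreeding(ped: Pedigree, gamma: GammaMatrix | None = None) -> np.ndarray:
    """Per-individual inbreeding F_i = a(sire, dam)/2 (diagonal of A minus 1).

    In metafounder mode F is relative to the Gamma base, so founders of group
    j carry F = gamma_jj / 2; metafounder rows are excluded from the result.
    """
    A = tabular_A_gamma(ped, gamma) if ped.is_mf else tabular_A(ped)
    return np.diag(A)[ped.n_mf:] - 1.0


def _henderson_inverse(ped: Pedigree, diag: np.ndarray,
                       gamma: GammaMatrix | None) -> sp.csr_matrix:
    """Generalized Henderson rules from the diagonal of A (or A(Gamma))."""
    n = ped.n
    rows, cols, vals = [], [], []
    if ped.is_mf:
        ginv = gamma.inverse()
        for a in range(ped.n_mf):
            for b in range(ped.n_mf):
                rows.append(a)
                cols.append(b)
                vals.append(ginv[a, b])
    for i in range(ped.n_mf, n):
        s, d = ped.sire[i], ped.dam[i]
        delta = 1.0
        if s >= 0:
            delta -= 0.25 * diag[s]
        if d >= 0:
            delta -= 0.25 * diag[d]
        if delta <= 0:
            raise FloatingPointError(
                f"non-positive Mendelian sampling variance at row {i} (delta={delta:.3e})"
            )
        w = 1.0 / delta
        idx = [i] + [p for p in (s, d) if p >= 0]
        coef = [1.0] + [-0.5] * (len(idx) - 1)
        for a, ca in zip(idx, coef):
            for b, cb in zip(idx, coef):
                rows.append(a)
                cols.append(b)
                vals.append(w * ca * cb)
    out = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out.sum_duplicates()
    return out


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A via Henderson's rules with inbreeding."""
    if ped.is_mf:
        raise ValueError("use a_gamma_inverse for a metafounder pedigree")
    return _henderson_inverse(ped, 1.0 + inbreeding(ped), None)


def a_gamma_inverse(ped: Pedigree, gamma: GammaMatrix) -> sp.csr_matrix:
    """Sparse inverse of A(Gamma): Henderson rules + Gamma^{-1} on the MF block."""
    A_diag = np.diag(tabular_A_gamma(ped, gamma))
    return _henderson_inverse(ped, A_diag, gamma)


def subset_A22(A: np.ndarray, genotyped_rows: np.ndarray):
    """Genotyped block of A and its inverse.

    A22^{-1} is the inverse of the genotyped *block* of A — not the genotyped
    block of A^{-1}.
    """
    genotyped_rows = np.asarray(genotyped_rows, dtype=np.int64)
    if genotyped_rows.size == 0:
        raise ValueError("empty genotyped set")
    A22 = A[np.ix_(genotyped_rows, genotyped_rows)]
    A22_inv = np.linalg.inv(A22)
    return A22, A22_inv


def export_triplets(mat, path, tol: float = 0.0) -> None:
    """Write the upper triangle as 1-based ``i j value`` triplet text."""
    coo = sp.coo_matrix(mat)
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i <= j and abs(v) > tol:
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


def drop_metafounder_block(mat, n_mf: int):
    """Restrict a (sparse or dense) MF-augmented matrix to real individuals."""
    if sp.issparse(mat):
        return mat.tocsr()[n_mf:, n_mf:]
    return np.asarray(mat)[n_mf:, n_mf:]
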