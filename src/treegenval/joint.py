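"""Single-step inverse relationship matrices (plain and metafounder modes).

H combines pedigree relationships for everybody with genomic relationships for
the genotyped subset. Its inverse never needs H itself:

    H^{-1} = A^{-1} + [0 0; 0 G^{-1} − A22^{-1}]

scattered on the genotyped rows/columns. In metafounder mode the same formula
holds with the Gamma-augmented pedigree pieces and the allele-frequency-0.5
genomic matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class HInverse:
    """Sparse H^{-1} kept as pedigree part + dense genotyped-block correction.

    ``base`` is A^{-1} (or A(Gamma)^{-1}); ``correction`` is the dense
    G^{-1} − A22^{-1} block over ``genotyped_rows``. Keeping the two pieces
    separate lets quadratic forms u'H^{-1}u be computed at sparse cost plus
    one small dense product.
    """

    base: sp.csr_matrix
    correction: np.ndarray
    genotyped_rows: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.base.shape

    def to_sparse(self) -> sp.csr_matrix:
        """Assemble the full sparse matrix (genotyped block densifies)."""
        n = self.base.shape[0]
        idx = self.genotyped_rows
        corr = sp.coo_matrix(
            (self.correction.ravel(),
             (np.repeat(idx, idx.size), np.tile(idx, idx.size))),
            shape=(n, n),
        )
        return (self.base + corr.tocsr()).tocsr()

    def quad_form(self, U: np.ndarray) -> np.ndarray:
        """U' H^{-1} U for a dense n×t matrix U."""
        Ug = U[self.genotyped_rows]
        return U.T @ (self.base @ U) + Ug.T @ self.correction @ Ug


def h_inverse(A_inv: sp.spmatrix, G: np.ndarray, A22_inv: np.ndarray,
              genotyped_rows: np.ndarray, provenance: dict | None = None) -> HInverse:
    """Assemble H^{-1} from its three ingredients (plain mode).

    ``G`` must be invertible — blend it with A22 first if markers make it
    singular (duplicate genotypes, m < n).
    """
    genotyped_rows = np.asarray(genotyped_rows, dtype=np.int64)
    if genotyped_rows.size == 0:
        return HInverse(sp.csr_matrix(A_inv), np.zeros((0, 0)), genotyped_rows,
                        dict(provenance or {}, mode="plain"))
    if G.shape[0] != genotyped_rows.size or A22_inv.shape != G.shape:
        raise ValueError("G / A22_inv / genotyped index sets are not aligned")
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G is not positive definite; blend it with A22 (e.g. alpha=0.95) first"
        ) from err
    eye = np.eye(G.shape[0])
    G_inv = np.linalg.solve(L.T, np.linalg.solve(L, eye))
    return HInverse(sp.csr_matrix(A_inv), G_inv - A22_inv, genotyped_rows,
                    dict(provenance or {}, mode="plain"))


def h_inverse_mf(A_gamma_inv: sp.spmatrix, G05: np.ndarray, A_gamma_22_inv: np.ndarray,
                 genotyped_rows: np.ndarray, provenance: dict | None = None) -> HInverse:
    """Assemble H(Gamma)^{-1}: same scatter-add with Gamma-consistent blocks.

    ``genotyped_rows`` index the metafounder-augmented pedigree; ``G05`` is
    the allele-frequency-0.5 genomic matrix (blended if needed).
    """
    out = h_inverse(A_gamma_inv, G05, A_gamma_22_inv, genotyped_rows, provenance)
    out.provenance["mode"] = "mf"
    return out


def dense_H(A: np.ndarray, G: np.ndarray, genotyped_rows: np.ndarray) -> np.ndarray:
    """Dense H from the conditional-Gaussian joint formula (test scaffolding).

    The genotyped block is replaced by G and the rest is projected through the
    pedigree: with partitions 1 = non-genotyped, 2 = genotyped,

        H11 = A11 + A12 A22^{-1} (G − A22) A22^{-1} A21
        H12 = A12 A22^{-1} G,   H22 = G.

    This is an oracle for tests, not a runtime path.
    """
    n = A.shape[0]
    g = np.asarray(genotyped_rows, dtype=np.int64)
    rest = np.setdiff1d(np.arange(n), g)
    A11 = A[np.ix_(rest, rest)]
    A12 = A[np.ix_(rest, g)]
    A22 = A[np.ix_(g, g)]
    K = np.linalg.solve(A22, A12.T).T  # A12 A22^{-1}
    H = np.empty_like(A)
    H[np.ix_(rest, rest)] = A11 + K @ (G - A22) @ K.T
    H[np.ix_(rest, g)] = K @ G
    H[np.ix_(g, rest)] = (K @ G).T
    H[np.ix_(g, g)] = G
    return H
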