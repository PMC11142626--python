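"""Non-negative matrix tri-factorization of PPMI matrices.

The embedding model decomposes a non-negative matrix ``X`` (the PPMI
representation of a network) as

    X ~= P S B^T,   P (n x d), S (d x d), B (n x d), all >= 0,

where the rows of ``E = P S`` are the gene embedding vectors and the
columns of ``B`` are the *axes* (basis vectors) of the embedding space.
The orthonormal variant (ONMTF) additionally drives ``B^T B`` toward the
identity, which minimizes co-linearity between axes.

Both objectives minimize the squared Frobenius reconstruction error and
are solved by a deterministic fixed-point iteration: an SVD-based
(NNDSVD-style) initialization followed by multiplicative updates.
Quality is tracked by the relative square error

    RSE = ||X - P S B^T||_F^2 / ||X||_F^2,

and the solver stops when the RSE stops decreasing (relative improvement
below ``tol``) or after ``max_iter`` iterations.

The module also recovers an implicit basis for embeddings learned by
external algorithms (e.g. skip-gram random-walk methods), which output a
gene embedding matrix ``E1`` but no basis: since such methods implicitly
factorize a random-walk mutual-information matrix approximated by the
PPMI, the basis follows in closed form as ``B1 = X^T pinv(E1^T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PPMIMatrix

__all__ = ["NMTF", "NMTFResults", "ExternalEmbedding", "svd_init", "rse",
           "recover_basis"]

_EPS = 1e-10  # denominator guard in the multiplicative updates


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, PPMIMatrix):
        return X.matrix
    return np.asarray(X, dtype=float)


def svd_init(X, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic non-negative initial factors from the leading SVD.

    Follows the NNDSVD pattern: each of the leading ``d`` singular pairs
    (u_k, s_k, v_k) is split into positive and negative parts and the
    dominant non-negative pair is kept (normalized); ``S`` starts as
    ``diag(s_1..s_d)``.  Zero entries are lifted by a small constant so
    the multiplicative updates cannot lock them at zero.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}], got {d}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    P = np.empty((n, d))
    B = np.empty((n, d))
    for k in range(d):
        u, v = U[:, k], Vt[k, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        if np.linalg.norm(up) * np.linalg.norm(vp) >= \
                np.linalg.norm(un) * np.linalg.norm(vn):
            uu, vv = up, vp
        else:
            uu, vv = un, vn
        P[:, k] = uu / max(np.linalg.norm(uu), _EPS)
        B[:, k] = vv / max(np.linalg.norm(vv), _EPS)
    S = np.diag(s[:d]).copy()
    # lift exact zeros: multiplicative updates preserve the zero pattern
    floor = 1e-6 * max(M.mean(), _EPS)
    P[P == 0] = floor
    B[B == 0] = floor
    S[S == 0] = floor
    return P, S, B


def rse(X, P: np.ndarray, S: np.ndarray, B: np.ndarray) -> float:
    """Relative square error ||X - P S B^T||_F^2 / ||X||_F^2."""
    M = _as_matrix(X)
    denom = np.linalg.norm(M) ** 2
    if denom == 0:
        raise ValueError("RSE undefined for an all-zero matrix")
    return float(np.linalg.norm(M - P @ S @ B.T) ** 2 / denom)


class NMTF:
    """Tri-factorization embedding model for a non-negative matrix.

    Parameters
    ----------
    X : PPMIMatrix or ndarray
        Non-negative input matrix (n x n for a network PPMI, but any
        non-negative rectangular matrix factorizes; B then has one row
        per column of X).
    rank : int
        Dimensionality ``d`` of the embedding space.
    orthonormal : bool
        If True, fit the ONMTF variant with the soft orthonormality
        constraint ``B^T B ~= I`` on the basis factor.

    Examples
    --------
    >>> model = NMTF(ppmi, rank=8, orthonormal=True)
    >>> res = model.fit()
    >>> res.E.shape, res.rse
    """

    def __init__(self, X, rank: int, orthonormal: bool = False,
                 ortho_weight: float = 1.0):
        M = _as_matrix(X)
        if np.any(M < 0):
            raise ValueError("input matrix must be non-negative")
        if np.linalg.norm(M) == 0:
            raise ValueError("input matrix is all zero")
        self.X = X
        self._M = M
        self.rank = int(rank)
        self.orthonormal = bool(orthonormal)
        self.ortho_weight = float(ortho_weight)
        if not 1 <= self.rank <= min(M.shape):
            raise ValueError(
                f"rank must be in [1, {min(M.shape)}], got {rank}")

    def fit(self, max_iter: int = 500, tol: float = 1e-5) -> "NMTFResults":
        """Run the multiplicative-update solver.

        Stops when the relative RSE improvement drops below ``tol`` or
        after ``max_iter`` iterations (default 500).  Deterministic:
        repeated calls give bit-identical traces.
        """
        M = self._M
        P, S, B = svd_init(M, self.rank)
        # penalty weight for the soft orthonormality constraint,
        # scale-free relative to the data norm
        lam = self.ortho_weight * np.linalg.norm(M) ** 2
        trace = [rse(M, P, S, B)]
        for it in range(1, max_iter + 1):
            XB = M @ B
            P *= (XB @ S.T) / (P @ (S @ (B.T @ B) @ S.T) + _EPS)
            S *= (P.T @ (M @ B)) / ((P.T @ P) @ S @ (B.T @ B) + _EPS)
            num = M.T @ (P @ S)
            if self.orthonormal:
                # Ding-style orthogonality-preserving multiplicative rule
                # (damped by the square root), augmented with a
                # ||B^T B - I||^2 penalty that holds the basis near the
                # Stiefel manifold at convergence
                num = num + lam * B
                den = B @ (S.T @ (P.T @ P) @ S) + lam * B @ (B.T @ B) + _EPS
                B *= np.sqrt(num / den)
            else:
                B *= num / (B @ (S.T @ (P.T @ P) @ S) + _EPS)
            if not (np.all(np.isfinite(P)) and np.all(np.isfinite(S))
                    and np.all(np.isfinite(B))):
                raise FloatingPointError(
                    f"non-finite factor entries at iteration {it}")
            trace.append(rse(M, P, S, B))
            rel = (trace[-2] - trace[-1]) / trace[-2] if trace[-2] > 0 else 0.0
            if 0 <= rel < tol:
                break
        return NMTFResults(model=self, P=P, S=S, B=B,
                           rse_trace=np.asarray(trace))


@dataclass
class NMTFResults:
    """Fitted tri-factorization.

    Attributes
    ----------
    P, S, B : ndarray
        Non-negative factors; columns of ``B`` are the embedding axes.
    E : ndarray
        Gene embedding matrix ``P @ S`` (rows = genes).
    rse_trace : ndarray
        RSE after initialization and after each iteration.
    """

    model: NMTF = field(repr=False)
    P: np.ndarray = field(repr=False)
    S: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)
    rse_trace: np.ndarray = field(repr=False)

    @property
    def d(self) -> int:
        return self.model.rank

    @property
    def orthonormal(self) -> bool:
        return self.model.orthonormal

    @property
    def E(self) -> np.ndarray:
        return self.P @ self.S

    @property
    def rse(self) -> float:
        return float(self.rse_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.rse_trace) - 1

    def orthonormality_residual(self) -> float:
        """``||B^T B - I||_F / sqrt(d)`` — 0 for an exactly orthonormal basis."""
        d = self.d
        return float(np.linalg.norm(self.B.T @ self.B - np.eye(d))
                     / np.sqrt(d))

    def summary(self) -> str:
        lines = [
            "Tri-factorization results",
            "=" * 41,
            f"mode:            {'ONMTF' if self.orthonormal else 'NMTF'}",
            f"matrix shape:    {self.model._M.shape}",
            f"rank (d):        {self.d}",
            f"iterations:      {self.n_iter}",
            f"initial RSE:     {self.rse_trace[0]:.6f}",
            f"final RSE:       {self.rse:.6f}",
            f"||B'B - I||_F/sqrt(d): {self.orthonormality_residual():.4f}",
        ]
        return "\n".join(lines)

    def plot_rse(self, ax=None):
        """Plot the RSE trace over iterations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.rse_trace)), self.rse_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("RSE")
        ax.set_title("ONMTF" if self.orthonormal else "NMTF")
        return ax


@dataclass
class ExternalEmbedding:
    """A gene embedding learned outside this package, plus its recovered basis.

    External random-walk embedding algorithms output only the gene
    embedding matrix ``E1`` (rows aligned with the network node order,
    entries possibly negative); the basis ``B1`` is recovered against
    the network's PPMI matrix via :func:`recover_basis`.
    """

    E1: np.ndarray
    B1: np.ndarray | None = None
    source_label: str = ""


def recover_basis(X, E1: np.ndarray) -> np.ndarray:
    """Closed-form basis for an externally learned embedding.

    Solves ``X ~= E1 B1^T`` in least squares:
    ``B1 = X^T pinv(E1^T)`` with the Moore-Penrose pseudoinverse.

    Raises if ``E1`` is column-rank deficient (reduce d instead).
    """
    M = _as_matrix(X)
    E1 = np.asarray(E1, dtype=float)
    if E1.shape[0] != M.shape[0]:
        raise ValueError("E1 rows must align with X's node order")
    if np.linalg.matrix_rank(E1) < E1.shape[1]:
        raise ValueError(
            "E1 is rank-deficient; reduce the embedding dimensionality")
    return M.T @ np.linalg.pinv(E1.T)
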