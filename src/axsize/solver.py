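"""Non-negative least-squares inversion of the dictionary model.

Solves ``argmin_{x >= 0} ||A x - y||^2``.  Two paths share one interface:

* ``method="fista"`` — monotone FISTA (projected gradient with Nesterov
  momentum, a function-value safeguard and gradient-based restart) on the
  column-normalized problem.  This is the path used for the large sparse
  streamline dictionaries.
* ``method="exact"`` — dense active-set NNLS (scipy) for small problems,
  e.g. the per-voxel fits.

``method="auto"`` picks "exact" for small dense systems and "fista"
otherwise.

The minimizer of the streamline problem is not unique: distinct coefficient
vectors can produce nearly identical fitted signals (flat directions of the
objective).  The monotone iteration with an objective-change stopping rule
yields a deterministic, reproducible representative; see the methods note
for the sensitivity of downstream indices to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps

__all__ = ["FitResult", "fit"]

_EXACT_MAX_ENTRIES = 2_000_000


@dataclass
class FitResult:
    """Non-negative coefficients and convergence diagnostics."""

    x: np.ndarray
    residual_norm: float
    iterations: int
    converged: bool
    method: str
    objective_history: np.ndarray | None = None

    @property
    def objective(self) -> float:
        return self.residual_norm**2


def _as_operator(A):
    from .dictionary import DictionaryOperator

    if isinstance(A, DictionaryOperator):
        return A.A
    return A


def _lipschitz(An, AnT, n_iter=30):
    v = np.ones(An.shape[1]) / np.sqrt(An.shape[1])
    lam = 1.0
    for _ in range(n_iter):
        w = AnT @ (An @ v)
        lam = np.linalg.norm(w)
        if lam == 0:
            return 1.0
        v = w / lam
    return lam


def fit(
    A,
    y,
    method="auto",
    tol_objective=1e-5,
    tol_grad=1e-6,
    max_iter=1000,
    normalize_columns=True,
    track_objective=False,
):
    """Solve the non-negative least-squares problem.

    Parameters
    ----------
    A : DictionaryOperator, sparse matrix or ndarray
    y : (n_rows,) signal vector
    tol_objective : float
        Stop when the relative objective change per iteration falls below
        this (FISTA path).
    tol_grad : float
        Also stop when the projected-gradient norm falls below
        ``tol_grad * ||A^T y||``.
    max_iter : int
        Iteration cap; the result is flagged unconverged if reached without
        meeting either tolerance.
    normalize_columns : bool
        Solve on unit-norm columns and rescale (recommended: the b=0 rows
        give cylinder and tensor columns very different norms).

    Notes
    -----
    The FISTA path is monotone: the reported iterate sequence has
    non-increasing residual norm.
    """
    Amat = _as_operator(A)
    y = np.asarray(y, dtype=float).ravel()
    if Amat.shape[0] != len(y):
        raise ValueError(f"A has {Amat.shape[0]} rows but y has {len(y)} entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    dense = not sps.issparse(Amat)
    if method == "auto":
        method = "exact" if dense and Amat.size <= _EXACT_MAX_ENTRIES else "fista"

    if method == "exact":
        from scipy.optimize import nnls

        Ad = Amat.toarray() if sps.issparse(Amat) else np.asarray(Amat, dtype=float)
        x, rnorm = nnls(Ad, y)
        return FitResult(
            x=x, residual_norm=float(rnorm), iterations=0, converged=True, method="exact"
        )
    if method != "fista":
        raise ValueError(f"unknown method {method!r}")

    if sps.issparse(Amat):
        Amat = Amat.tocsr()
        col_norms = np.sqrt(np.asarray(Amat.multiply(Amat).sum(axis=0)).ravel())
    else:
        Amat = np.asarray(Amat, dtype=float)
        col_norms = np.linalg.norm(Amat, axis=0)
    if normalize_columns:
        scale = np.where(col_norms > 0, col_norms, 1.0)
        D_inv = sps.diags(1.0 / scale)
        An = (Amat @ D_inv).tocsr() if sps.issparse(Amat) else Amat / scale
    else:
        scale = np.ones(Amat.shape[1])
        An = Amat
    AnT = An.T.tocsr() if sps.issparse(An) else An.T

    L = _lipschitz(An, AnT) * 1.02
    gref = np.linalg.norm(AnT @ y)
    if gref == 0:  # y = 0 -> x = 0 is the exact solution
        x0 = np.zeros(An.shape[1])
        return FitResult(x0, 0.0, 0, True, "fista",
                         np.array([0.0]) if track_objective else None)

    # Monotone FISTA (MFISTA) with gradient restart.  The forward products
    # A@x of all iterates are linear combinations of cached products, so one
    # iteration costs exactly two matvecs including the monotone objective.
    n = An.shape[1]
    x = np.zeros(n)
    x_prev = x
    zv = x
    Ax = np.zeros_like(y)
    Ax_prev = Ax
    Az = Ax
    t = 1.0
    f_x = float(y @ y)
    f_cand_prev = np.inf
    history = [np.sqrt(f_x)] if track_objective else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = AnT @ (Az - y)
        cand = np.maximum(zv - g / L, 0.0)
        A_cand = An @ cand
        r = A_cand - y
        f_cand = float(r @ r)
        restart = g @ (cand - x) > 0
        if f_cand <= f_x:  # monotone acceptance
            x_prev, Ax_prev = x, Ax
            x, Ax, f_x = cand, A_cand, f_cand
        else:
            x_prev, Ax_prev = x, Ax
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        if restart:
            zv, Az, t_new = x, Ax, 1.0
        else:
            a = t / t_new
            b = (t - 1.0) / t_new
            zv = x + a * (cand - x) + b * (x - x_prev)
            Az = Ax + a * (A_cand - Ax) + b * (Ax - Ax_prev)
        t = t_new
        if history is not None:
            history.append(np.sqrt(f_x))
        rel_change = abs(f_cand_prev - f_cand) / max(f_cand, 1e-300)
        f_cand_prev = f_cand
        if it > 1 and rel_change < tol_objective:
            converged = True
            break
        if it % 25 == 0:
            pg = x - np.maximum(x - (AnT @ (Ax - y)), 0.0)
            if np.linalg.norm(pg) <= tol_grad * gref:
                converged = True
                break

    x_out = x / scale
    return FitResult(
        x=x_out,
        residual_norm=float(np.sqrt(f_x)),
        iterations=it,
        converged=converged,
        method="fista",
        objective_history=np.asarray(history) if history is not None else None,
    )
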