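"""Bounded-nuclear-norm matrix completion and the block machinery around it.

The model completes two "spliced" blocks, one per space:

* circRNA space:  ``M1 = [KC | Ac]``  with ``Ac = normalize(CC @ A)``
* disease space:  ``M2 = [KD | Ad^T]`` with ``Ad = normalize(A @ DD)``

Each block is denoised by solving

    min  ||X||_*  +  (alpha/2) ||X - M||_F^2     s.t.  0 <= X <= 1

via ADMM: a box-projected fidelity step on the auxiliary variable W, a
singular-value soft-thresholding (SVT) step on the low-rank iterate, and a
multiplier update.  The recovered block is the box-feasible W at
convergence; the association sub-block is then cut back out and the two
spaces are blended with a convex mixing weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import AssociationData

__all__ = [
    "CompletionConfig",
    "AdmmState",
    "BlockMatrix",
    "space_update",
    "build_block",
    "svt_shrink",
    "BNNRCompleter",
    "bnnr_complete",
    "integrate_scores",
]


@dataclass
class CompletionConfig:
    """Solver and integration hyperparameters.

    alpha_admm : fidelity weight of the completion objective (> 0).
    beta_admm : ADMM penalty coefficient (> 0); the SVT threshold is its
        reciprocal.
    tol : relative tolerance; the solver stops once both the relative change
        of the low-rank iterate and the relative primal residual fall below it.
    max_iter : iteration cap.
    alpha_mix : weight of the circRNA-space scores in the final blend
        (1 - alpha_mix goes to the disease space); 0.7 by default.
    """

    alpha_admm: float = 1.0
    beta_admm: float = 10.0
    tol: float = 1e-6
    max_iter: int = 300
    alpha_mix: float = 0.7

    def __post_init__(self) -> None:
        if self.alpha_admm <= 0:
            raise ValueError(f"alpha_admm must be positive, got {self.alpha_admm}")
        if self.beta_admm <= 0:
            raise ValueError(f"beta_admm must be positive, got {self.beta_admm}")
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError(f"alpha_mix must lie in [0, 1], got {self.alpha_mix}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be at least 1, got {self.max_iter}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


@dataclass
class AdmmState:
    """Final ADMM iterates plus convergence diagnostics."""

    M1: np.ndarray
    W: np.ndarray
    Y: np.ndarray
    k: int
    residual: float  # relative change of M1 at the last step
    primal_residual: float  # ||M1 - W||_F / ||M1||_F at the last step
    trace: list[tuple[int, float, float]] = field(default_factory=list)


@dataclass
class BlockMatrix:
    """A spliced block and the location of its association sub-block."""

    M: np.ndarray
    score_slice: slice
    space: str  # "circ" or "disease"

    def extract_scores(self) -> np.ndarray:
        """The association sub-block, oriented circRNA x disease."""
        sub = self.M[:, self.score_slice]
        return sub if self.space == "circ" else sub.T

    def with_matrix(self, M: np.ndarray) -> "BlockMatrix":
        if M.shape != self.M.shape:
            raise ValueError(f"shape {M.shape} does not match block {self.M.shape}")
        return BlockMatrix(M, self.score_slice, self.space)


def space_update(
    A: AssociationData | np.ndarray, CC: np.ndarray, DD: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-propagated association matrices Ac and Ad.

    ``Ac = CC @ A`` with each column scaled by the Euclidean norm of the
    corresponding column of A; ``Ad = A @ DD`` with each row scaled by the
    norm of A's row.  Zero columns/rows of A stay exactly zero (0/0 := 0),
    which is what lets a new node be scored purely through similarity.
    """
    M = A.A if isinstance(A, AssociationData) else np.asarray(A, dtype=float)
    CC = np.asarray(CC, dtype=float)
    DD = np.asarray(DD, dtype=float)
    nc, nd = M.shape
    if CC.shape != (nc, nc):
        raise ValueError(f"CC shape {CC.shape} does not match {nc} circRNAs")
    if DD.shape != (nd, nd):
        raise ValueError(f"DD shape {DD.shape} does not match {nd} diseases")
    col_norms = np.linalg.norm(M, axis=0)
    row_norms = np.linalg.norm(M, axis=1)
    Ac = CC @ M
    Ad = M @ DD
    nonzero_cols = col_norms > 0
    nonzero_rows = row_norms > 0
    Ac[:, nonzero_cols] /= col_norms[nonzero_cols]
    Ac[:, ~nonzero_cols] = 0.0
    Ad[nonzero_rows, :] /= row_norms[nonzero_rows, None]
    Ad[~nonzero_rows, :] = 0.0
    return Ac, Ad


def build_block(scores: np.ndarray, K: np.ndarray, space: str) -> BlockMatrix:
    """Splice a GIP kernel with an association matrix into one block.

    circRNA space: ``[KC | Ac]`` (nc x (nc+nd)); disease space:
    ``[KD | Ad^T]`` (nd x (nd+nc)).  ``extract_scores`` undoes the splice
    (and the transpose) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    K = np.asarray(K, dtype=float)
    if space == "circ":
        nc = scores.shape[0]
        if K.shape != (nc, nc):
            raise ValueError(f"KC shape {K.shape} does not match {nc} circRNAs")
        M = np.hstack([K, scores])
        return BlockMatrix(M, slice(nc, M.shape[1]), "circ")
    if space == "disease":
        nd = scores.shape[1]
        if K.shape != (nd, nd):
            raise ValueError(f"KD shape {K.shape} does not match {nd} diseases")
        M = np.hstack([K, scores.T])
        return BlockMatrix(M, slice(nd, M.shape[1]), "disease")
    raise ValueError(f"space must be 'circ' or 'disease', got {space!r}")


def svt_shrink(X: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding, the proximal map of the nuclear norm.

    Computes the SVD of ``X`` and shrinks every singular value by ``tau``
    (clipping at zero).  ``tau = 0`` reproduces ``X``.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("svt_shrink requires finite input")
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return (U * np.maximum(s - tau, 0.0)) @ Vt


class BNNRCompleter(TransformerMixin, BaseEstimator):
    """Bounded-nuclear-norm denoiser as a scikit-learn transformer.

    ``fit_transform(M)`` returns the solution of
    ``min ||X||_* + (alpha/2)||X - M||_F^2  s.t.  0 <= X <= 1``
    obtained by ADMM.  The low-rank iterate, multiplier and convergence
    diagnostics are exposed as fitted attributes.

    Parameters
    ----------
    alpha : float, default=1.0
        Fidelity weight.
    beta : float, default=10.0
        ADMM penalty; the SVT threshold is ``1 / beta``.
    tol : float, default=1e-6
        Stop once the relative change of the low-rank iterate and the
        relative primal residual are both below ``tol``.
    max_iter : int, default=300
        Iteration cap.
    record_trace : bool, default=False
        Keep the per-iteration (k, relative change, primal residual) trace
        in ``state_.trace``.

    Attributes
    ----------
    recovered_ : ndarray
        The box-feasible recovery W.
    state_ : AdmmState
        Final iterates and residuals.
    n_iter_ : int
        Iterations performed.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 10.0,
        tol: float = 1e-6,
        max_iter: int = 300,
        record_trace: bool = False,
    ):
        self.alpha = alpha
        self.beta = beta
        self.tol = tol
        self.max_iter = max_iter
        self.record_trace = record_trace

    def fit(self, X, y=None):
        # reuse CompletionConfig's validation for the shared hyperparameters
        CompletionConfig(
            alpha_admm=self.alpha, beta_admm=self.beta, tol=self.tol,
            max_iter=self.max_iter,
        )
        M = check_array(X, dtype=float, ensure_all_finite=True, copy=True)
        alpha, beta = float(self.alpha), float(self.beta)
        M1 = M.copy()
        W = M1.copy()
        Y = np.zeros_like(M)
        trace: list[tuple[int, float, float]] = []
        rel_change = np.inf
        primal = np.inf
        k = 0
        for k in range(1, self.max_iter + 1):
            W = np.clip((alpha * M + Y + beta * M1) / (alpha + beta), 0.0, 1.0)
            M1_next = svt_shrink(W - Y / beta, 1.0 / beta)
            Y = Y + beta * (M1_next - W)
            denom = max(np.linalg.norm(M1), np.finfo(float).tiny)
            rel_change = float(np.linalg.norm(M1_next - M1) / denom)
            denom_next = max(np.linalg.norm(M1_next), np.finfo(float).tiny)
            primal = float(np.linalg.norm(M1_next - W) / denom_next)
            M1 = M1_next
            if not (np.isfinite(rel_change) and np.isfinite(primal)):
                raise FloatingPointError(
                    f"ADMM diverged at iteration {k} "
                    f"(relative change {rel_change}, primal residual {primal}); "
                    f"trace: {trace[-5:]}"
                )
            if self.record_trace:
                trace.append((k, rel_change, primal))
            if rel_change < self.tol and primal < self.tol:
                break
        self.recovered_ = W
        self.state_ = AdmmState(M1, W, Y, k, rel_change, primal, trace)
        self.n_iter_ = k
        return self

    def transform(self, X):
        check_is_fitted(self)
        return self.recovered_

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).recovered_


def bnnr_complete(
    block: BlockMatrix, cfg: CompletionConfig | None = None
) -> tuple[np.ndarray, AdmmState]:
    """Complete one spliced block; returns (recovered W, solver state)."""
    if cfg is None:
        cfg = CompletionConfig()
    est = BNNRCompleter(
        alpha=cfg.alpha_admm, beta=cfg.beta_admm, tol=cfg.tol, max_iter=cfg.max_iter
    ).fit(block.M)
    return est.recovered_, est.state_


def integrate_scores(
    Ac_star: np.ndarray, Ad_star: np.ndarray, alpha_mix: float = 0.7
) -> np.ndarray:
    """Convex blend of the two per-space score matrices."""
    Ac_star = np.asarray(Ac_star, dtype=float)
    Ad_star = np.asarray(Ad_star, dtype=float)
    if Ac_star.shape != Ad_star.shape:
        raise ValueError(
            f"score shapes disagree: {Ac_star.shape} vs {Ad_star.shape}"
        )
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError(f"alpha_mix must lie in [0, 1], got {alpha_mix}")
    return alpha_mix * Ac_star + (1.0 - alpha_mix) * Ad_star
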