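"""End-to-end orchestration: from an association matrix plus similarity
matrices to the blended prediction scores.

The full model runs four stages:

1. GIP kernels KC, KD from the association matrix actually passed in
   (recomputed on every call, which is what makes cross-validation and
   new-node protocols honest — masking a pair changes the kernels too).
2. Similarity propagation: Ac = normalize(CC @ A), Ad = normalize(A @ DD).
3. Two bounded-nuclear-norm completions on the spliced blocks
   [KC | Ac] and [KD | Ad^T].
4. Convex integration of the two extracted score matrices.

Two ablations are exposed as modes: ``mult-only`` stops after stage 2
(no completion) and ``mc-only`` completes blocks built from the raw A
(no similarity propagation).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .completion import (
    CompletionConfig,
    bnnr_complete,
    build_block,
    integrate_scores,
    space_update,
)
from .data import AssociationData, ScoreMatrix
from .similarity import GipParams, gip_similarity_matrix

__all__ = ["DmccdaResult", "DMCCDA", "dmccda_predict", "rank_candidates", "MODES"]

MODES = ("full", "mult-only", "mc-only")


@dataclass
class DmccdaResult:
    """Blended scores plus the per-space matrices and solver diagnostics."""

    scores: ScoreMatrix
    ac_star: np.ndarray
    ad_star: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


class DMCCDA(BaseEstimator):
    """Double-matrix-completion association predictor.

    A transductive estimator: ``fit`` takes the binary association matrix
    together with the circRNA and disease similarity matrices and computes
    prediction scores for *every* pair, stored in ``scores_``.

    Parameters
    ----------
    alpha_admm : float, default=1.0
        Fidelity weight of the completion objective.
    beta_admm : float, default=10.0
        ADMM penalty coefficient.
    tol : float, default=1e-6
        Solver stopping tolerance.
    max_iter : int, default=300
        Solver iteration cap.
    alpha_mix : float, default=0.7
        Weight of the circRNA-space scores in the final blend.
    beta_prime : float, default=1.0
        Original GIP bandwidth.
    mode : {"full", "mult-only", "mc-only"}, default="full"
        Full model or one of the two ablations.

    Attributes
    ----------
    scores_ : ndarray of shape (n_circ, n_disease)
        Blended prediction scores.
    circ_space_scores_, disease_space_scores_ : ndarray
        Per-space score matrices (Ac*, Ad*).
    diagnostics_ : dict
        Per-space ADMM iteration counts and residuals (completion modes).

    Examples
    --------
    >>> import numpy as np
    >>> A = np.eye(3)
    >>> S = np.full((3, 3), 0.2) + 0.8 * np.eye(3)
    >>> model = DMCCDA().fit(A, circ_sim=S, disease_sim=S)
    >>> model.scores_.shape
    (3, 3)
    """

    def __init__(
        self,
        alpha_admm: float = 1.0,
        beta_admm: float = 10.0,
        tol: float = 1e-6,
        max_iter: int = 300,
        alpha_mix: float = 0.7,
        beta_prime: float = 1.0,
        mode: str = "full",
    ):
        self.alpha_admm = alpha_admm
        self.beta_admm = beta_admm
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_mix = alpha_mix
        self.beta_prime = beta_prime
        self.mode = mode

    def _config(self) -> CompletionConfig:
        return CompletionConfig(
            alpha_admm=self.alpha_admm,
            beta_admm=self.beta_admm,
            tol=self.tol,
            max_iter=self.max_iter,
            alpha_mix=self.alpha_mix,
        )

    def fit(self, A, circ_sim=None, disease_sim=None):
        """Compute scores for every circRNA-disease pair.

        Parameters
        ----------
        A : AssociationData or 0/1 ndarray of shape (n_circ, n_disease)
        circ_sim : ndarray (n_circ, n_circ)
            Sequence similarity CC.  Required unless ``mode="mc-only"``.
        disease_sim : ndarray (n_disease, n_disease)
            Semantic similarity DD.  Required unless ``mode="mc-only"``.
        """
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        cfg = self._config()
        M = A.A if isinstance(A, AssociationData) else np.asarray(A, dtype=float)
        if M.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        needs_sim = self.mode in ("full", "mult-only")
        if needs_sim and (circ_sim is None or disease_sim is None):
            raise ValueError(f"mode {self.mode!r} requires circ_sim and disease_sim")

        diagnostics: dict = {"mode": self.mode}

        if self.mode == "mult-only":
            with _stage("space_update"):
                ac_star, ad_star = space_update(M, circ_sim, disease_sim)
        else:
            with _stage("gip_kernels"):
                params = GipParams(beta_prime=self.beta_prime)
                KC = gip_similarity_matrix(M, axis="circ", params=params)
                KD = gip_similarity_matrix(M, axis="disease", params=params)
            if self.mode == "full":
                with _stage("space_update"):
                    Ac, Ad = space_update(M, circ_sim, disease_sim)
            else:  # mc-only: complete blocks built from the raw matrix
                Ac, Ad = M, M
            with _stage("build_block"):
                block_c = build_block(Ac, KC, "circ")
                block_d = build_block(Ad, KD, "disease")
            with _stage("completion_circ_space"):
                Wc, state_c = bnnr_complete(block_c, cfg)
            with _stage("completion_disease_space"):
                Wd, state_d = bnnr_complete(block_d, cfg)
            ac_star = block_c.with_matrix(Wc).extract_scores()
            ad_star = block_d.with_matrix(Wd).extract_scores()
            diagnostics["circ_space"] = {
                "n_iter": state_c.k,
                "residual": state_c.residual,
                "primal_residual": state_c.primal_residual,
            }
            diagnostics["disease_space"] = {
                "n_iter": state_d.k,
                "residual": state_d.residual,
                "primal_residual": state_d.primal_residual,
            }

        with _stage("integration"):
            scores = integrate_scores(ac_star, ad_star, cfg.alpha_mix)

        self.circ_space_scores_ = ac_star
        self.disease_space_scores_ = ad_star
        self.scores_ = scores
        self.diagnostics_ = diagnostics
        return self


def dmccda_predict(
    A: AssociationData,
    CC: np.ndarray | None,
    DD: np.ndarray | None,
    cfg: CompletionConfig | None = None,
    mode: str = "full",
    beta_prime: float = 1.0,
) -> DmccdaResult:
    """Run the full pipeline on an :class:`AssociationData` instance."""
    if cfg is None:
        cfg = CompletionConfig()
    model = DMCCDA(
        alpha_admm=cfg.alpha_admm,
        beta_admm=cfg.beta_admm,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        alpha_mix=cfg.alpha_mix,
        beta_prime=beta_prime,
        mode=mode,
    ).fit(A, circ_sim=CC, disease_sim=DD)
    scores = ScoreMatrix(A.circ_ids, A.disease_ids, model.scores_)
    return DmccdaResult(
        scores=scores,
        ac_star=model.circ_space_scores_,
        ad_star=model.disease_space_scores_,
        diagnostics=model.diagnostics_,
    )


def rank_candidates(
    result: DmccdaResult,
    A: AssociationData,
    disease: str,
    k: int = 10,
) -> list[tuple[str, float, int]]:
    """Top-k circRNAs for one disease: (circRNA ID, score, known flag).

    Sorted by descending score; exact ties break on the circRNA ID so the
    ranking is deterministic.  ``k`` larger than the circRNA count returns
    every circRNA.
    """
    j = A.disease_index(disease)
    col = result.scores.S[:, j]
    rows = sorted(
        ((A.circ_ids[i], float(col[i]), int(A.A[i, j])) for i in range(A.n_circ)),
        key=lambda r: (-r[1], r[0]),
    )
    return rows[: min(k, A.n_circ)]
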