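"""ROC/AUC machinery and the three evaluation protocols.

All protocols treat the known associations as the positive class and every
never-observed pair as a candidate (negative):

* LOOCV — each positive is masked in turn, the model is refit on the rest
  and the held-out pair's score recorded; the pooled held-out scores are
  ranked against the candidate scores from the full-data model.
* Repeated five-fold CV — positives are shuffled into folds per repeat;
  each fold is masked and scored; folds pool into one AUC per repeat.
* New-node — one disease column is zeroed wholesale, the model (including
  its GIP kernels) refit, and the column's top-k ranks checked against the
  originally known partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .completion import CompletionConfig
from .data import AssociationData
from .pipeline import dmccda_predict, rank_candidates

__all__ = ["RocResult", "CvReport", "roc_auc", "loocv", "kfold_cv", "new_node_eval"]


@dataclass
class RocResult:
    """ROC sweep: descending thresholds with the TPR/FPR at each cut."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CvReport:
    """Cross-validation summary; mean/std re-derivable from ``per_run_auc``."""

    per_run_auc: list[float]
    mean_auc: float
    std_auc: float
    n_folds: int
    n_repeats: int
    seed: int = 0
    protocol: str = ""
    notes: dict = field(default_factory=dict)


def roc_auc(scores, labels) -> RocResult:
    """Threshold-sweep ROC with trapezoidal AUC.

    Every distinct score is tried as a cut; samples at or above the cut are
    called positive.  The trapezoidal integral handles tied scores as
    midranks, so the AUC equals the probability that a random positive
    outranks a random negative (ties counting one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all() or len(classes) < 2:
        raise ValueError("labels must contain both classes (0 and 1)")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(thresholds, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def _candidate_scores(
    result_scores: np.ndarray, A: AssociationData
) -> np.ndarray:
    """Scores of every pair that is 0 in the original association matrix."""
    return result_scores[A.A == 0]


def loocv(
    A: AssociationData,
    CC: np.ndarray | None,
    DD: np.ndarray | None,
    cfg: CompletionConfig | None = None,
    mode: str = "full",
) -> CvReport:
    """Leave-one-out over the known associations, pooled into one AUC.

    Each positive is zeroed in turn and rescored by a model trained on the
    remaining positives; candidates are scored once, by the full-data model.
    """
    positives = A.positives()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    full = dmccda_predict(A, CC, DD, cfg, mode=mode)
    neg_scores = _candidate_scores(full.scores.S, A)
    pos_scores = []
    for i, j in positives:
        masked = A.A.copy()
        masked[i, j] = 0.0
        res = dmccda_predict(A.with_matrix(masked), CC, DD, cfg, mode=mode)
        pos_scores.append(res.scores.S[i, j])
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    a = roc_auc(scores, labels).auc
    return CvReport(
        per_run_auc=[a],
        mean_auc=a,
        std_auc=0.0,
        n_folds=len(positives),
        n_repeats=1,
        protocol="loocv",
        notes={"n_positives": len(positives), "n_candidates": int(len(neg_scores))},
    )


def kfold_cv(
    A: AssociationData,
    CC: np.ndarray | None,
    DD: np.ndarray | None,
    cfg: CompletionConfig | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    mode: str = "full",
    rescore_candidates: bool = False,
) -> CvReport:
    """Repeated k-fold CV over positives; one pooled AUC per repeat.

    Fold partitions are unstratified uniform shuffles drawn from
    per-repeat substreams of the master seed, so each repeat is
    independently reproducible.  Candidates are scored by the full-data
    model unless ``rescore_candidates`` asks for per-fold rescoring.
    """
    positives = A.positives()
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives for {k}-fold CV")
    streams = np.random.SeedSequence(seed).spawn(repeats)
    if not rescore_candidates:
        full = dmccda_predict(A, CC, DD, cfg, mode=mode)
        fixed_neg = _candidate_scores(full.scores.S, A)
    per_run = []
    for rep in range(repeats):
        rng = np.random.default_rng(streams[rep])
        order = rng.permutation(len(positives))
        folds = np.array_split(order, k)
        pos_scores: list[float] = []
        neg_chunks: list[np.ndarray] = []
        for fold in folds:
            masked = A.A.copy()
            for idx in fold:
                i, j = positives[idx]
                masked[i, j] = 0.0
            res = dmccda_predict(A.with_matrix(masked), CC, DD, cfg, mode=mode)
            for idx in fold:
                i, j = positives[idx]
                pos_scores.append(res.scores.S[i, j])
            if rescore_candidates:
                neg_chunks.append(_candidate_scores(res.scores.S, A))
        neg = np.concatenate(neg_chunks) if rescore_candidates else fixed_neg
        scores = np.concatenate([pos_scores, neg])
        labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg))])
        per_run.append(roc_auc(scores, labels).auc)
    mean = float(np.mean(per_run))
    std = float(np.std(per_run, ddof=1)) if len(per_run) > 1 else 0.0
    return CvReport(
        per_run_auc=[float(a) for a in per_run],
        mean_auc=mean,
        std_auc=std,
        n_folds=k,
        n_repeats=repeats,
        seed=seed,
        protocol=f"{k}-fold, {repeats} repeats, unstratified uniform shuffling",
    )


def new_node_eval(
    A: AssociationData,
    CC: np.ndarray | None,
    DD: np.ndarray | None,
    cfg: CompletionConfig | None = None,
    disease: str = "",
    top_k: int = 50,
    mode: str = "full",
) -> int:
    """Count of a zeroed disease's known partners recovered in its top-k.

    The disease's whole column is set to 0 (making it a new node), the
    model — GIP kernels included — is refit, and the column re-ranked; the
    return value is how many originally known partners land in the top-k.
    """
    j = A.disease_index(disease)
    known = np.nonzero(A.A[:, j])[0]
    if len(known) == 0:
        raise ValueError(f"disease {disease!r} has no known associations")
    masked = A.A.copy()
    masked[:, j] = 0.0
    res = dmccda_predict(A.with_matrix(masked), CC, DD, cfg, mode=mode)
    top = rank_candidates(res, A, disease, k=top_k)
    known_ids = {A.circ_ids[i] for i in known}
    return sum(1 for circ_id, _, _ in top if circ_id in known_ids)
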