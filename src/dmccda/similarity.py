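"""The four similarity kernels feeding the completion model.

* ``CC`` — circRNA sequence similarity from Levenshtein edit distance,
  ``1 - dis / (len_i + len_j)``.
* ``DD`` — disease semantic similarity on the Disease Ontology DAG
  (Wang-style decayed ancestor contributions).
* ``KC`` / ``KD`` — Gaussian interaction-profile (GIP) kernels computed
  from the rows / columns of the binary association matrix.

All four are square, symmetric, have unit diagonal and live in [0, 1]
(GIP entries are strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import AssociationData, DiseaseOntology, SequenceRecord

__all__ = [
    "GipParams",
    "levenshtein_distance",
    "sequence_similarity_matrix",
    "semantic_contributions",
    "semantic_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity_matrix",
    "validate_similarity_matrix",
]


@dataclass(frozen=True)
class GipParams:
    """GIP kernel settings: original bandwidth and the profile axis.

    ``beta_prime`` is the unnormalized bandwidth, 1 by convention; the
    effective bandwidth divides it by the mean squared profile norm of the
    chosen axis (``"circ"`` uses rows of A, ``"disease"`` uses columns).
    """

    beta_prime: float = 1.0
    axis: str = "circ"

    def __post_init__(self) -> None:
        if self.beta_prime <= 0:
            raise ValueError(f"beta_prime must be positive, got {self.beta_prime}")
        if self.axis not in ("circ", "disease"):
            raise ValueError(f"axis must be 'circ' or 'disease', got {self.axis!r}")


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def sequence_similarity_matrix(
    records: list[SequenceRecord], circ_ids: list[str]
) -> np.ndarray:
    """Sequence similarity ``CC(i, j) = 1 - dis(i, j) / (len_i + len_j)``.

    ``records`` must cover every ID in ``circ_ids``; the output rows/columns
    follow ``circ_ids`` order.
    """
    by_id = {rec.id: rec.seq for rec in records}
    missing = [c for c in circ_ids if c not in by_id]
    if missing:
        raise KeyError(f"no sequence provided for circRNA {missing[0]!r}")
    seqs = [by_id[c] for c in circ_ids]
    n = len(seqs)
    CC = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dis = levenshtein_distance(seqs[i], seqs[j])
            CC[i, j] = CC[j, i] = 1.0 - dis / (len(seqs[i]) + len(seqs[j]))
    return CC


def semantic_contributions(ont: DiseaseOntology, d: str) -> dict[str, float]:
    """Decayed contribution of each ancestor of ``d`` to ``d``'s semantics.

    The disease itself contributes 1; every other term ``t`` in the ancestor
    closure contributes ``max(w_e * S[t'])`` over its children ``t'`` inside
    the closure — i.e. ``w_e`` to the power of the shortest upward hop count.
    """
    closure = ont.ancestors(d)  # raises KeyError for unknown terms
    # children of t restricted to the closure (edges run child -> parent)
    children: dict[str, list[str]] = {t: [] for t in closure}
    for c in closure:
        for p in ont.parents.get(c, ()):
            if p in closure:
                children[p].append(c)
    # process in BFS order outward from d so every child is done before its parent
    S: dict[str, float] = {d: 1.0}
    frontier = [d]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for p in ont.parents.get(t, ()):
                if p in closure and p not in S:
                    nxt.append(p)
        for p in dict.fromkeys(nxt):
            done = [c for c in children[p] if c in S]
            S[p] = max(ont.w_e * S[c] for c in done)
        frontier = list(dict.fromkeys(nxt))
    return S


def semantic_similarity_matrix(
    ont: DiseaseOntology, disease_ids: list[str]
) -> np.ndarray:
    """Wang-style semantic similarity over shared DAG ancestors.

    ``DD(i, j)`` is the sum of both diseases' contributions over the shared
    part of their ancestor closures, divided by the two total contribution
    sums.  Diseases with disjoint closures score 0; the diagonal is 1.
    """
    contribs = [semantic_contributions(ont, d) for d in disease_ids]
    totals = [sum(c.values()) for c in contribs]
    n = len(disease_ids)
    DD = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            num = sum(contribs[i][t] + contribs[j][t] for t in shared)
            DD[i, j] = DD[j, i] = num / (totals[i] + totals[j])
    return DD


def _profiles(A: AssociationData | np.ndarray, axis: str) -> np.ndarray:
    M = A.A if isinstance(A, AssociationData) else np.asarray(A, dtype=float)
    if axis == "circ":
        return M
    if axis == "disease":
        return M.T
    raise ValueError(f"axis must be 'circ' or 'disease', got {axis!r}")


def gip_bandwidth(
    A: AssociationData | np.ndarray,
    axis: str = "circ",
    params: GipParams | None = None,
) -> float:
    """Effective GIP bandwidth: ``beta_prime`` over the mean squared profile norm."""
    if params is None:
        params = GipParams(axis=axis)
    P = _profiles(A, axis)
    mean_sq = float(np.mean(np.sum(P * P, axis=1)))
    if mean_sq == 0.0:
        raise ValueError(
            "GIP bandwidth undefined: association matrix has no known pairs"
        )
    return params.beta_prime / mean_sq


def gip_similarity_matrix(
    A: AssociationData | np.ndarray,
    axis: str = "circ",
    params: GipParams | None = None,
) -> np.ndarray:
    """Gaussian interaction-profile kernel on one axis of the association matrix.

    ``K(i, j) = exp(-beta * ||IP_i - IP_j||^2)`` with the bandwidth from
    :func:`gip_bandwidth`.  Empty profiles (new nodes) are allowed; only a
    fully zero matrix is an error.
    """
    if params is None:
        params = GipParams(axis=axis)
    beta = gip_bandwidth(A, axis=axis, params=params)
    P = _profiles(A, axis)
    if P.shape[0] == 1:
        return np.ones((1, 1))
    d2 = squareform(pdist(P, metric="sqeuclidean"))
    return np.exp(-beta * d2)


def validate_similarity_matrix(S: np.ndarray, name: str = "similarity") -> None:
    """Raise unless ``S`` is square, symmetric, unit-diagonal and in [0, 1]."""
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} matrix must be square, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError(f"{name} matrix is not symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-10):
        raise ValueError(f"{name} matrix diagonal must be 1")
    if S.min() < -1e-12 or S.max() > 1 + 1e-12:
        raise ValueError(f"{name} matrix entries must lie in [0, 1]")
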