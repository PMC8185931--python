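"""Core in-memory containers shared by every pipeline stage.

The prediction problem is a bipartite one: ``nc`` circRNAs against ``nd``
diseases, with experimentally verified associations recorded as a binary
adjacency matrix ``A`` (rows = circRNAs, columns = diseases).  Everything
downstream — similarity kernels, the matrix-completion blocks, the score
matrix — is keyed to the same two ordered ID axes, so the containers here
carry the ID lists alongside the arrays and validate the pairing once, at
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AssociationData",
    "SequenceRecord",
    "DiseaseOntology",
    "ScoreMatrix",
]


def _check_unique(ids: list[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {axis} identifier: {dup!r}")


@dataclass
class AssociationData:
    """Binary circRNA-disease adjacency matrix with its ID axes.

    Parameters
    ----------
    circ_ids : list of str
        Ordered circRNA identifiers (row axis).
    disease_ids : list of str
        Ordered disease identifiers (column axis), typically DOIDs.
    A : ndarray of shape (n_circ, n_disease)
        0/1 matrix; ``A[i, j] == 1`` iff circRNA ``i`` is a verified
        partner of disease ``j``.
    """

    circ_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.circ_ids = list(self.circ_ids)
        self.disease_ids = list(self.disease_ids)
        _check_unique(self.circ_ids, "circRNA")
        _check_unique(self.disease_ids, "disease")
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match axes "
                f"({len(self.circ_ids)}, {len(self.disease_ids)})"
            )
        vals = np.unique(self.A)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("association matrix must contain only 0/1 values")

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    def circ_index(self, circ_id: str) -> int:
        try:
            return self.circ_ids.index(circ_id)
        except ValueError:
            raise KeyError(f"unknown circRNA identifier: {circ_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease identifier: {disease_id!r}") from None

    def positives(self) -> list[tuple[int, int]]:
        """Index pairs of the known (value 1) associations, row-major order."""
        rows, cols = np.nonzero(self.A)
        return list(zip(rows.tolist(), cols.tolist()))

    def with_matrix(self, A: np.ndarray) -> "AssociationData":
        """A copy of this container carrying a different 0/1 matrix."""
        return AssociationData(self.circ_ids, self.disease_ids, A)


@dataclass(frozen=True)
class SequenceRecord:
    """One circRNA nucleotide sequence (DNA alphabet, U already mapped to T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty identifier")
        if len(self.seq) < 1:
            raise ValueError(f"sequence for {self.id!r} is empty")


@dataclass
class DiseaseOntology:
    """Disease DAG under is_a relations, with the semantic decay weight.

    ``parents`` maps each term to its set of direct is_a parents; terms with
    no entry (or an empty set) are roots.  ``w_e`` is the per-edge decay
    applied when an ancestor's semantic contribution is propagated one hop,
    0.5 by default (the standard choice for Wang-style DAG similarity).
    """

    terms: set[str]
    parents: dict[str, set[str]] = field(default_factory=dict)
    w_e: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.w_e < 1.0:
            raise ValueError(f"w_e must lie in (0, 1), got {self.w_e}")
        self.terms = set(self.terms)
        self.parents = {t: set(ps) for t, ps in self.parents.items() if ps}
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge references unknown child term {child!r}")
            missing = ps - self.terms
            if missing:
                raise ValueError(
                    f"term {child!r} references unknown parent {sorted(missing)[0]!r}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"ontology is not a DAG; cycle: {path}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> set[str]:
        """Ancestor closure of ``term``, including the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term: {term!r}")
        closure = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self.parents.get(t, ()):
                if p not in closure:
                    closure.add(p)
                    frontier.append(p)
        return closure


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores on the same axes as an association matrix."""

    circ_ids: list[str]
    disease_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.circ_ids = list(self.circ_ids)
        self.disease_ids = list(self.disease_ids)
        _check_unique(self.circ_ids, "circRNA")
        _check_unique(self.disease_ids, "disease")
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError(
                f"score matrix shape {self.S.shape} does not match axes "
                f"({len(self.circ_ids)}, {len(self.disease_ids)})"
            )
        if not np.isfinite(self.S).all():
            raise ValueError("score matrix contains non-finite entries")
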