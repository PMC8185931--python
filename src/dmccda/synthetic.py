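"""Seeded generator of desk-scale benchmark instances.

The generator plants the very structure the predictor assumes: circRNAs
and diseases carry low-rank latent factors, the binary association matrix
is a thresholding of the latent product, and both similarity matrices are
(jittered) cosine similarities of the same factors.  Guilt-by-association
therefore holds by construction — similar circRNAs really do partner with
similar diseases — which makes the instances suitable for certifying that
the method recovers signal, while the jitter, the hard thresholding and
the sparsity keep them from being trivial.

Each circRNA/disease also belongs to one dominant latent cluster; the
cluster drives the sequence families (one mutated prototype per cluster)
and the placement of diseases on the random ontology (same-cluster
diseases become sibling leaves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .data import AssociationData, DiseaseOntology, SequenceRecord

__all__ = ["SynthConfig", "simulate_instance", "mutate_sequences", "random_ontology"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark instance parameters.

    The defaults mirror the structure of real curated circRNA-disease data:
    a sparse bipartite matrix (a few percent dense) over a few dozen
    diseases, low-rank association-generating signal, sequences of a few
    hundred bases within mutation families, and mild similarity jitter.
    """

    nc: int = 60
    nd: int = 20
    rank: int = 3
    density: float = 0.05
    seq_len: int = 200
    mut_rate: float = 0.05
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError(f"density must lie in (0, 1), got {self.density}")
        if self.rank > min(self.nc, self.nd):
            raise ValueError(
                f"rank {self.rank} exceeds min axis size {min(self.nc, self.nd)}"
            )
        if self.rank < 1 or self.nc < 1 or self.nd < 1:
            raise ValueError("nc, nd and rank must be positive")
        if not 0.0 <= self.mut_rate <= 1.0:
            raise ValueError(f"mut_rate must lie in [0, 1], got {self.mut_rate}")
        if self.noise < 0:
            raise ValueError(f"noise must be non-negative, got {self.noise}")
        if self.seq_len < 1:
            raise ValueError(f"seq_len must be positive, got {self.seq_len}")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    # fixed substreams so simulate_instance / mutate_sequences / the
    # ontology all agree on the latent clusters for one seed
    return np.random.default_rng([cfg.seed, stream])


def _clusters(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(cfg, 1)
    g_circ = rng.integers(cfg.rank, size=cfg.nc)
    g_dis = rng.integers(cfg.rank, size=cfg.nd)
    return g_circ, g_dis


def _factors(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    g_circ, g_dis = _clusters(cfg)
    rng = _rng(cfg, 2)
    U = 0.15 * rng.uniform(size=(cfg.nc, cfg.rank))
    U[np.arange(cfg.nc), g_circ] += rng.uniform(0.5, 1.0, size=cfg.nc)
    V = 0.15 * rng.uniform(size=(cfg.nd, cfg.rank))
    V[np.arange(cfg.nd), g_dis] += rng.uniform(0.5, 1.0, size=cfg.nd)
    return U, V


def _jittered_cosine(X: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    S = cosine_similarity(X)
    if noise > 0:
        N = rng.normal(scale=noise, size=S.shape)
        S = S + (N + N.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def circ_ids_for(cfg: SynthConfig) -> list[str]:
    return [f"circ{i:04d}" for i in range(cfg.nc)]


def disease_ids_for(cfg: SynthConfig) -> list[str]:
    return [f"DOID:9{j:03d}" for j in range(cfg.nd)]


def simulate_instance(
    cfg: SynthConfig,
) -> tuple[AssociationData, np.ndarray, np.ndarray, np.ndarray]:
    """One benchmark instance: (associations, CC, DD, latent truth matrix).

    The truth matrix is the min-max-rescaled latent product U V^T; the top
    ``density`` fraction of its entries become the known (1) associations,
    so the positive count is exact and deterministic.
    """
    U, V = _factors(cfg)
    truth = U @ V.T
    tmin, tmax = truth.min(), truth.max()
    truth = (truth - tmin) / (tmax - tmin) if tmax > tmin else np.zeros_like(truth)
    n_pos = int(round(cfg.density * cfg.nc * cfg.nd))
    if n_pos < 2:
        raise ValueError(
            f"density {cfg.density} yields {n_pos} positives on a "
            f"{cfg.nc}x{cfg.nd} matrix; need at least 2"
        )
    flat_order = np.argsort(-truth, axis=None, kind="stable")
    A = np.zeros(cfg.nc * cfg.nd)
    A[flat_order[:n_pos]] = 1.0
    A = A.reshape(cfg.nc, cfg.nd)
    rng = _rng(cfg, 3)
    CC = _jittered_cosine(U, cfg.noise, rng)
    DD = _jittered_cosine(V, cfg.noise, rng)
    data = AssociationData(circ_ids_for(cfg), disease_ids_for(cfg), A)
    return data, CC, DD, truth


def mutate_sequences(cfg: SynthConfig) -> list[SequenceRecord]:
    """Sequence families aligned with the instance's circRNA clusters.

    One random prototype of length ``seq_len`` per latent cluster; each
    circRNA gets the prototype of its cluster with i.i.d. substitutions at
    ``mut_rate`` (always to a different base).
    """
    g_circ, _ = _clusters(cfg)
    rng = _rng(cfg, 4)
    prototypes = [
        rng.choice(_BASES, size=cfg.seq_len) for _ in range(cfg.rank)
    ]
    records = []
    for cid, g in zip(circ_ids_for(cfg), g_circ):
        seq = prototypes[g].copy()
        hit = rng.uniform(size=cfg.seq_len) < cfg.mut_rate
        if hit.any():
            # substitute with a uniformly random *different* base
            shift = rng.integers(1, 4, size=int(hit.sum()))
            idx = (np.searchsorted(_BASES, seq[hit]) + shift) % 4
            seq[hit] = _BASES[idx]
        records.append(SequenceRecord(cid, "".join(seq)))
    return records


def random_ontology(
    nd: int,
    depth: int = 3,
    branching: int = 3,
    seed: int = 0,
    clusters: np.ndarray | None = None,
) -> tuple[DiseaseOntology, dict[str, str]]:
    """A rooted random tree ontology with the disease axis on its leaves.

    The tree has ``branching`` children per internal node down to ``depth``
    levels, so ``branching**depth`` leaves; it must have at least ``nd``.
    Diseases are laid onto consecutive leaves grouped by latent cluster, so
    same-cluster diseases end up as siblings (higher semantic similarity
    than cross-branch pairs).  Returns the ontology plus the map from
    disease axis ID to its leaf term — leaves are simply named by the
    disease IDs, unused leaves by placeholders.
    """
    if depth < 1:
        raise ValueError(f"depth must be at least 1, got {depth}")
    n_leaves = branching**depth
    if n_leaves < nd:
        raise ValueError(
            f"tree with depth {depth} and branching {branching} has only "
            f"{n_leaves} leaves for {nd} diseases"
        )
    rng = np.random.default_rng([seed, 5])
    disease_ids = [f"DOID:9{j:03d}" for j in range(nd)]
    if clusters is None:
        clusters = np.zeros(nd, dtype=int)
    # same-cluster diseases occupy consecutive leaves (hence share low
    # ancestors); the order of cluster blocks is drawn from the seed
    block_rank = {c: r for r, c in enumerate(rng.permutation(np.unique(clusters)))}
    order = sorted(range(nd), key=lambda j: (block_rank[int(clusters[j])], j))
    leaf_names = [f"leaf{s:04d}" for s in range(n_leaves)]
    for slot, j in enumerate(order):
        leaf_names[slot] = disease_ids[j]
    terms = {"DOID:4"}  # root
    parents: dict[str, set[str]] = {}
    level_nodes = ["DOID:4"]
    for lvl in range(1, depth + 1):
        nxt = []
        for p_idx, parent in enumerate(level_nodes):
            for b in range(branching):
                child_idx = p_idx * branching + b
                if lvl == depth:
                    name = leaf_names[child_idx]
                else:
                    name = f"int{lvl}_{child_idx:04d}"
                terms.add(name)
                parents.setdefault(name, set()).add(parent)
                nxt.append(name)
        level_nodes = nxt
    ont = DiseaseOntology(terms, parents)
    assignment = {d: d for d in disease_ids}
    return ont, assignment
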