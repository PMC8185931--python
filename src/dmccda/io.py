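"""Readers and writers for the external file formats.

Associations arrive as a two-column TSV of (circRNA ID, disease DOID) pairs,
sequences as FASTA, the disease ontology as OBO or a (child, parent) TSV
edge list, and similarity/score matrices as header-addressed TSV.  All ID
axes are sorted lexicographically at load time so that every matrix in a
run shares one deterministic ordering.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

from .data import AssociationData, DiseaseOntology, ScoreMatrix, SequenceRecord

__all__ = [
    "read_associations",
    "write_associations",
    "read_fasta",
    "write_fasta",
    "read_ontology",
    "write_ontology_edges",
    "read_matrix",
    "write_matrix",
    "write_scores",
    "read_scores",
]


def read_associations(path: str | os.PathLike) -> AssociationData:
    """Load a two-column (circRNA, disease) pair list into a binary matrix.

    Duplicate pairs collapse to a single 1.  Both axes are sorted
    lexicographically, so re-reading a written pair list reproduces the
    matrix and its ID ordering exactly.
    """
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected at least two tab-separated "
                    f"columns (circRNA ID, disease ID), got {line!r}"
                )
            pairs.add((fields[0].strip(), fields[1].strip()))
            n_rows += 1
    if not pairs:
        raise ValueError(f"{path}: no association pairs found")
    circ_ids = sorted({c for c, _ in pairs})
    disease_ids = sorted({d for _, d in pairs})
    ci = {c: i for i, c in enumerate(circ_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    A = np.zeros((len(circ_ids), len(disease_ids)))
    for c, d in pairs:
        A[ci[c], di[d]] = 1.0
    return AssociationData(circ_ids, disease_ids, A)


def write_associations(data: AssociationData, path: str | os.PathLike) -> None:
    """Write the known pairs back out as a two-column TSV (row-major order)."""
    with open(path, "w") as fh:
        for i, j in data.positives():
            fh.write(f"{data.circ_ids[i]}\t{data.disease_ids[j]}\n")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read circRNA sequences, upper-casing and mapping U to T.

    The record ID is the first whitespace-delimited header token.  Order is
    preserved; duplicate IDs and empty sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.seq), 70):
                fh.write(rec.seq[k : k + 70] + "\n")


def _is_obo(path: str | os.PathLike) -> bool:
    if str(path).endswith(".obo"):
        return True
    with open(path) as fh:
        head = fh.read(2048)
    return "[Term]" in head or "format-version" in head


def read_ontology(path: str | os.PathLike, w_e: float = 0.5) -> DiseaseOntology:
    """Load the disease DAG from an OBO file or a (child, parent) TSV.

    OBO parsing uses obonet, which skips obsolete terms; only is_a edges are
    kept.  Cycles and references to unknown parents are errors (raised by
    the ``DiseaseOntology`` constructor).
    """
    if _is_obo(path):
        graph = obonet.read_obo(str(path))
        terms = set(graph.nodes)
        parents: dict[str, set[str]] = {}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents.setdefault(child, set()).add(parent)
        return DiseaseOntology(terms, parents, w_e=w_e)
    terms = set()
    parents = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected (child, parent) columns, "
                    f"got {line!r}"
                )
            child, parent = fields[0].strip(), fields[1].strip()
            terms.add(child)
            terms.add(parent)
            parents.setdefault(child, set()).add(parent)
    if not terms:
        raise ValueError(f"{path}: no ontology edges found")
    return DiseaseOntology(terms, parents, w_e=w_e)


def write_ontology_edges(ont: DiseaseOntology, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for child in sorted(ont.parents):
            for parent in sorted(ont.parents[child]):
                fh.write(f"{child}\t{parent}\n")


def read_matrix(path: str | os.PathLike) -> tuple[list[str], list[str], np.ndarray]:
    """Read a header-addressed TSV matrix: (row IDs, column IDs, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(r) for r in df.index], [str(c) for c in df.columns], df.to_numpy(float)


def write_matrix(
    row_ids: list[str],
    col_ids: list[str],
    M: np.ndarray,
    path: str | os.PathLike,
) -> None:
    pd.DataFrame(M, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def write_scores(
    scores: ScoreMatrix, mask: AssociationData, path: str | os.PathLike
) -> None:
    """Write a ranked pair table: circRNA, disease, score, known flag.

    Rows are sorted by descending score; exact ties fall back to the
    (circRNA ID, disease ID) lexicographic order so output is deterministic.
    """
    if scores.S.shape != mask.A.shape or scores.circ_ids != mask.circ_ids or (
        scores.disease_ids != mask.disease_ids
    ):
        raise ValueError("score matrix and association matrix axes disagree")
    rows = [
        (scores.circ_ids[i], scores.disease_ids[j], float(scores.S[i, j]), int(mask.A[i, j]))
        for i in range(len(scores.circ_ids))
        for j in range(len(scores.disease_ids))
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("circRNA\tdisease\tscore\tknown\n")
        for c, d, s, k in rows:
            fh.write(f"{c}\t{d}\t{s!r}\t{k}\n")


def read_scores(path: str | os.PathLike) -> ScoreMatrix:
    """Re-read a ranked pair table into a ScoreMatrix (axes sorted)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    circ_ids = sorted(df["circRNA"].astype(str).unique())
    disease_ids = sorted(df["disease"].astype(str).unique())
    ci = {c: i for i, c in enumerate(circ_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    S = np.zeros((len(circ_ids), len(disease_ids)))
    for c, d, s in zip(df["circRNA"].astype(str), df["disease"].astype(str), df["score"]):
        S[ci[c], di[d]] = float(s)
    return ScoreMatrix(circ_ids, disease_ids, S)
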