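"""Readers and writers for the package's plain-text file formats.

Three formats are supported:

* two-column association tables (TSV by default, CSV selectable) — one
  ``entity_A<TAB>entity_B`` pair per line, ``#`` comments allowed;
* labelled dense similarity matrices — first row and first column carry
  identifiers, numeric body;
* a minimal MeSH record format — blank-line-separated blocks, each with a
  ``name`` line followed by one or more ``tree: <number>`` lines — plus a
  parser hook for the ASCII MeSH d-file dialect (``*NEWRECORD`` / ``MH =``
  / ``MN =``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AssociationMatrix, MeshDescriptor, SimilarityMatrix, normalize_id

logger = logging.getLogger(__name__)

__all__ = [
    "read_association_table",
    "write_association_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_mesh_descriptors",
    "write_mesh_descriptors",
]

_ASYMMETRY_TOL = 1e-6


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_association_table(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a two-column association table into a binary incidence matrix.

    Every (row, col) pair occurring at least once becomes a 1; duplicates
    collapse.  Identifiers are ordered by first appearance.
    """
    path = Path(path)
    rows: list[str] = []
    cols: list[str] = []
    row_index: dict[str, int] = {}
    col_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    def register(token: str, index: dict[str, int], order: list[str]) -> None:
        key = normalize_id(token)
        if key not in index:
            index[key] = len(order)
            order.append(token.strip())

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                # optional registry directives preserve entities that have
                # no associations (exact round-trip of empty rows/columns)
                body = line.lstrip()[1:]
                if body.startswith(f"rows{delimiter}") or body.startswith(f"cols{delimiter}"):
                    kind, *tokens = body.split(delimiter)
                    for tok in tokens:
                        if tok.strip():
                            register(tok, row_index if kind == "rows" else col_index,
                                     rows if kind == "rows" else cols)
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 2 fields "
                    f"separated by {delimiter!r}, got {line!r}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            ka, kb = normalize_id(a), normalize_id(b)
            if ka not in row_index:
                row_index[ka] = len(rows)
                rows.append(a)
            if kb not in col_index:
                col_index[kb] = len(cols)
                cols.append(b)
            pairs.add((row_index[ka], col_index[kb]))
    if not pairs:
        raise ParseError(f"{path}: no association records found")
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for i, j in pairs:
        values[i, j] = 1
    return AssociationMatrix(rows, cols, values)


def write_association_table(
    assoc: AssociationMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the 1-entries of an association matrix as a two-column table.

    Registry directives (``#rows``/``#cols`` comment lines) record the
    full id order, including entities with no associations, so a
    read-back reproduces values and id order exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#rows" + delimiter + delimiter.join(assoc.row_ids) + "\n")
        fh.write("#cols" + delimiter + delimiter.join(assoc.col_ids) + "\n")
        for i, r in enumerate(assoc.row_ids):
            for j, c in enumerate(assoc.col_ids):
                if assoc.values[i, j]:
                    fh.write(f"{r}{delimiter}{c}\n")


def read_similarity_matrix(path: str | Path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a labelled dense matrix file into a :class:`SimilarityMatrix`.

    Asymmetry up to 1e-6 is repaired by averaging with the transpose;
    larger asymmetry is a consistency error.  Values outside [0, 1] by
    more than 1e-6 are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    body = frame.to_numpy(dtype=np.float64)
    if body.shape[0] != body.shape[1]:
        raise ValueError(f"{path}: matrix body is {body.shape[0]} x {body.shape[1]}, not square")
    row_labels = [str(x) for x in frame.index]
    col_labels = [str(x) for x in frame.columns]
    if [normalize_id(x) for x in row_labels] != [normalize_id(x) for x in col_labels]:
        raise ValueError(f"{path}: row and column labels disagree")
    asym = np.abs(body - body.T).max() if body.size else 0.0
    if asym > _ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {_ASYMMETRY_TOL}")
    body = (body + body.T) / 2.0
    lo, hi = float(body.min()), float(body.max())
    if lo < -_ASYMMETRY_TOL or hi > 1 + _ASYMMETRY_TOL:
        raise ValueError(f"{path}: values outside [0, 1]: range [{lo:.6g}, {hi:.6g}]")
    np.clip(body, 0.0, 1.0, out=body)
    return SimilarityMatrix(row_labels, body)


def write_similarity_matrix(
    sim: SimilarityMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    frame = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def _merge_records(raw: list[tuple[str, list[str]]]) -> list[MeshDescriptor]:
    """Keep category-C tree numbers, merge duplicate names, skip empties."""
    merged: dict[str, tuple[str, list[str]]] = {}
    order: list[str] = []
    for name, trees in raw:
        c_trees = [t for t in trees if t.startswith("C")]
        if not trees:
            logger.warning("MeSH record %r has no tree numbers; skipped", name)
            continue
        if not c_trees:
            continue  # not a disease descriptor
        key = normalize_id(name)
        if key in merged:
            kept_name, kept = merged[key]
            merged[key] = (kept_name, kept + [t for t in c_trees if t not in kept])
        else:
            merged[key] = (name, list(dict.fromkeys(c_trees)))
            order.append(key)
    return [MeshDescriptor(*merged[k]) for k in order]


def read_mesh_descriptors(path: str | Path, dialect: str = "block") -> list[MeshDescriptor]:
    """Read disease descriptors, retaining only category-C tree numbers.

    ``dialect="block"`` is the package's minimal format; ``dialect="ascii"``
    parses the NLM ASCII d-file records (``MH =`` heading, ``MN =`` tree
    number).  Records for the same heading are merged; records without any
    tree number are skipped with a warning.
    """
    path = Path(path)
    if dialect == "block":
        raw = _parse_block_format(path)
    elif dialect == "ascii":
        raw = _parse_ascii_format(path)
    else:
        raise ValueError(f"unknown MeSH dialect {dialect!r}")
    descriptors = _merge_records(raw)
    if not descriptors:
        raise ValueError(f"{path}: no category-C descriptors found")
    return descriptors


def _parse_block_format(path: Path) -> list[tuple[str, list[str]]]:
    records: list[tuple[str, list[str]]] = []
    name: str | None = None
    trees: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if name is not None:
                    records.append((name, trees))
                name, trees = None, []
                continue
            if line.startswith("#"):
                continue
            if line.lower().startswith("tree:"):
                if name is None:
                    raise ParseError(f"{path}: tree number before any record name")
                trees.append(line.split(":", 1)[1].strip())
            elif line.lower().startswith("name:"):
                name = line.split(":", 1)[1].strip()
            elif name is None:
                name = line
            else:
                raise ParseError(f"{path}: unexpected line {line!r} inside record {name!r}")
    if name is not None:
        records.append((name, trees))
    return records


def _parse_ascii_format(path: Path) -> list[tuple[str, list[str]]]:
    records: list[tuple[str, list[str]]] = []
    name: str | None = None
    trees: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("*NEWRECORD"):
                if name is not None:
                    records.append((name, trees))
                name, trees = None, []
            elif line.startswith("MH = "):
                name = line[5:].strip()
            elif line.startswith("MN = "):
                trees.append(line[5:].strip())
    if name is not None:
        records.append((name, trees))
    return records


def write_mesh_descriptors(descriptors: list[MeshDescriptor], path: str | Path) -> None:
    """Write descriptors in the minimal block format."""
    with Path(path).open("w") as fh:
        for d in descriptors:
            fh.write(f"name: {d.disease_name}\n")
            for t in d.tree_numbers:
                fh.write(f"tree: {t}\n")
            fh.write("\n")
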