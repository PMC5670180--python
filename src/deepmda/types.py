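"""Core in-memory containers shared by every stage of the pipeline.

Three containers cover the whole data model: a binary bipartite incidence
matrix (``AssociationMatrix``), a symmetric similarity matrix with an
identifier registry (``SimilarityMatrix``), and a MeSH disease descriptor
(``MeshDescriptor``) carrying tree-number positions used to build disease
DAGs.  Identifier matching everywhere is exact, case-insensitive, after
whitespace trimming; the first-seen spelling is kept for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "MeshDescriptor",
    "normalize_id",
]

SYMMETRY_TOL = 1e-10
VALUE_TOL = 1e-6


def normalize_id(identifier: str) -> str:
    """Canonical key for identifier matching: trimmed, case-folded."""
    return identifier.strip().casefold()


def _check_unique(ids: list[str], axis: str) -> None:
    keys = [normalize_id(i) for i in ids]
    if len(set(keys)) != len(keys):
        seen: set[str] = set()
        dup = next(k for k in keys if k in seen or seen.add(k))
        raise ValueError(f"duplicate identifier {dup!r} on {axis} axis")


@dataclass
class AssociationMatrix:
    """Binary bipartite incidence matrix with row/column id registries.

    ``values[i, j] == 1`` iff an association between ``row_ids[i]`` and
    ``col_ids[j]`` was reported.  Houses the miRNA-disease, miRNA-target,
    lncRNA-disease and gene-disease adjacency matrices.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not self.row_ids or not self.col_ids:
            raise ValueError("association matrix must have at least one row and one column id")
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match id registries "
                f"({len(self.row_ids)} x {len(self.col_ids)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self._row_index = {normalize_id(r): i for i, r in enumerate(self.row_ids)}
        self._col_index = {normalize_id(c): j for j, c in enumerate(self.col_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        return self._row_index[normalize_id(row_id)]

    def col_index(self, col_id: str) -> int:
        return self._col_index[normalize_id(col_id)]

    def has_row(self, row_id: str) -> bool:
        return normalize_id(row_id) in self._row_index

    def has_col(self, col_id: str) -> bool:
        return normalize_id(col_id) in self._col_index

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.row_ids), list(self.col_ids), self.values.copy())


@dataclass
class SimilarityMatrix:
    """Symmetric square similarity matrix with an id registry.

    Values live in [0, 1]; symmetry is enforced within 1e-10.  Kernel and
    semantic matrices additionally have a unit diagonal, which the
    producing operations guarantee.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.ids:
            raise ValueError("similarity matrix must cover at least one identifier")
        _check_unique(self.ids, "similarity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"expected a {n} x {n} matrix, got shape {self.values.shape}")
        asym = np.abs(self.values - self.values.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:.3g})")
        self.values = (self.values + self.values.T) / 2.0
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < -VALUE_TOL or hi > 1 + VALUE_TOL:
            raise ValueError(f"similarity values outside [0, 1]: range [{lo:.6g}, {hi:.6g}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        self._index = {normalize_id(i): k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, identifier: str) -> int:
        return self._index[normalize_id(identifier)]

    def covers(self, identifier: str) -> bool:
        return normalize_id(identifier) in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def row(self, identifier: str) -> np.ndarray:
        return self.values[self.index(identifier)]

    def submatrix(self, keep: list[str]) -> "SimilarityMatrix":
        """Principal submatrix on ``keep``, preserving the given order."""
        if not keep:
            raise ValueError("empty selection")
        missing = [k for k in keep if not self.covers(k)]
        if missing:
            raise KeyError(f"identifiers not covered by similarity matrix: {missing}")
        idx = np.array([self.index(k) for k in keep])
        return SimilarityMatrix([self.ids[i] for i in idx], self.values[np.ix_(idx, idx)])


@dataclass
class MeshDescriptor:
    """A category-C MeSH disease descriptor: a heading plus its tree numbers.

    Each tree number (e.g. ``"C04.557.337"``) encodes one position in the
    MeSH hierarchy; ancestors are obtained by truncating dot-delimited
    components from the right.
    """

    disease_name: str
    tree_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tree_numbers = [t.strip() for t in self.tree_numbers]
        if not self.tree_numbers:
            raise ValueError(f"descriptor {self.disease_name!r} has no tree numbers")
        bad = [t for t in self.tree_numbers if not t.startswith("C")]
        if bad:
            raise ValueError(
                f"descriptor {self.disease_name!r} has non-disease tree numbers {bad}; "
                "only category-C positions describe diseases"
            )
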