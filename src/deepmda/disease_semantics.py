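"""Frequency-weighted disease semantic similarity over MeSH DAGs.

Each disease D is represented by a DAG(D) = (D, T(D), E(D)) built from
its MeSH tree numbers: T(D) is the set of terms comprising D and all of
its ancestors (tree-number prefixes), and E(D) links parents to children.
The information contribution of a term t is its negative log document
frequency across the disease set,

    C(t) = -log(#DAGs containing t / #diseases),

so rare terms contribute more.  The semantic value of a disease is the
sum of contributions over its DAG, and the similarity of two diseases is
the ratio of shared contributions to total contributions:

    SD(A, B) = sum_{t in T(A) & T(B)} (C(t) + C(t)) / (C(A) + C(B)).

This replaces the classic layer-based decay weighting: two terms on the
same DAG layer no longer contribute equally if their corpus frequencies
differ.  SD is invariant to the logarithm base (numerator and denominator
rescale identically); natural log is used for reproducible intermediate
values.

Terms are identified by MeSH heading, not tree position: a disease
occupying several tree positions contributes a single term whose ancestor
set is the union over positions, and document frequency counts DAGs, not
positions.  Ancestor positions not claimed by any descriptor in the set
keep their position string as term identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .types import MeshDescriptor, SimilarityMatrix, normalize_id

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAG",
    "SemanticContext",
    "tree_ancestors",
    "build_dags",
    "semantic_contribution",
    "semantic_similarity",
    "semantic_matrix",
]


def tree_ancestors(tree_number: str) -> list[str]:
    """Ancestor positions of a tree number, nearest first.

    ``"C04.557.337"`` -> ``["C04.557", "C04"]``.
    """
    parts = tree_number.split(".")
    return [".".join(parts[:k]) for k in range(len(parts) - 1, 0, -1)]


@dataclass
class DiseaseDAG:
    """Per-disease DAG: the disease, its term set and parent->child edges."""

    disease: str
    term_set: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if normalize_id(self.disease) not in self.term_set:
            raise ValueError(f"DAG of {self.disease!r} must contain the disease itself")
        for parent, child in self.edges:
            if parent not in self.term_set or child not in self.term_set:
                raise ValueError(f"edge ({parent!r}, {child!r}) leaves the term set")


@dataclass
class SemanticContext:
    """All disease DAGs plus the term document frequencies they induce."""

    dags: dict[str, DiseaseDAG]
    n_diseases: int
    term_df: dict[str, int]
    _semantic_values: dict[str, float] = field(default_factory=dict, repr=False)

    def dag(self, disease: str) -> DiseaseDAG:
        key = normalize_id(disease)
        if key not in self.dags:
            raise KeyError(f"no DAG for disease {disease!r}")
        return self.dags[key]


def build_dags(descriptors: list[MeshDescriptor], n_diseases: int | None = None) -> SemanticContext:
    """Construct per-disease DAGs and term document frequencies.

    Ancestor positions are mapped back to the heading of the descriptor
    occupying that position, when one exists in the input set.  Duplicate
    disease names are merged with a warning.  ``n_diseases`` (the
    denominator of the contribution formula) defaults to the number of
    DAGs built, i.e. the analysis set size.
    """
    if not descriptors:
        raise ValueError("no descriptors given")

    merged: dict[str, MeshDescriptor] = {}
    for d in descriptors:
        key = normalize_id(d.disease_name)
        if key in merged:
            logger.warning("duplicate descriptor for %r; merging tree numbers", d.disease_name)
            trees = merged[key].tree_numbers + [
                t for t in d.tree_numbers if t not in merged[key].tree_numbers
            ]
            merged[key] = MeshDescriptor(merged[key].disease_name, trees)
        else:
            merged[key] = MeshDescriptor(d.disease_name, list(d.tree_numbers))

    # Position -> term identity (heading key when a descriptor claims it).
    position_term: dict[str, str] = {}
    for key, d in merged.items():
        for t in d.tree_numbers:
            position_term[t] = key

    def term_of(position: str) -> str:
        return position_term.get(position, position)

    dags: dict[str, DiseaseDAG] = {}
    for key, d in merged.items():
        terms: set[str] = {key}
        edges: set[tuple[str, str]] = set()
        for tree in d.tree_numbers:
            chain = [tree, *tree_ancestors(tree)]  # position chain, leaf first
            chain_terms = [term_of(p) for p in chain]
            terms.update(chain_terms)
            for child, parent in zip(chain_terms, chain_terms[1:]):
                if parent != child:
                    edges.add((parent, child))
        dags[key] = DiseaseDAG(d.disease_name, terms, edges)

    term_df: dict[str, int] = {}
    for dag in dags.values():
        for t in dag.term_set:
            term_df[t] = term_df.get(t, 0) + 1

    n = n_diseases if n_diseases is not None else len(dags)
    return SemanticContext(dags=dags, n_diseases=n, term_df=term_df)


def semantic_contribution(term: str, ctx: SemanticContext) -> float:
    """Information contribution -log(df(term) / n_diseases); >= 0."""
    key = term if term in ctx.term_df else normalize_id(term)
    if key not in ctx.term_df:
        raise KeyError(f"term {term!r} appears in no DAG")
    return -math.log(ctx.term_df[key] / ctx.n_diseases)


def _semantic_value(disease_key: str, ctx: SemanticContext) -> float:
    if disease_key not in ctx._semantic_values:
        dag = ctx.dags[disease_key]
        ctx._semantic_values[disease_key] = sum(
            semantic_contribution(t, ctx) for t in dag.term_set
        )
    return ctx._semantic_values[disease_key]


def semantic_similarity(a: str, b: str, ctx: SemanticContext) -> float:
    """Shared-contribution ratio SD(A, B) in [0, 1]; SD(A, A) = 1.

    When every term of both DAGs is universal (all contributions zero) the
    ratio is 0/0; it is defined as 0 since the shared terms then carry no
    discriminative information.
    """
    dag_a, dag_b = ctx.dag(a), ctx.dag(b)
    denom = _semantic_value(normalize_id(a), ctx) + _semantic_value(normalize_id(b), ctx)
    if denom == 0.0:
        logger.warning(
            "semantic values of %r and %r are both zero (all terms universal); SD := 0", a, b
        )
        return 0.0
    shared = dag_a.term_set & dag_b.term_set
    numer = sum(2.0 * semantic_contribution(t, ctx) for t in shared)
    sd = numer / denom
    return min(max(sd, 0.0), 1.0)


def semantic_matrix(ctx: SemanticContext, diseases: list[str]) -> SimilarityMatrix:
    """Pairwise SD over an ordered disease list, diagonal exactly 1."""
    missing = [d for d in diseases if normalize_id(d) not in ctx.dags]
    if missing:
        raise KeyError(f"diseases without DAGs: {missing}")
    n = len(diseases)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = semantic_similarity(diseases[i], diseases[j], ctx)
    return SimilarityMatrix(list(diseases), values)
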