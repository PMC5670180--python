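"""Gaussian interaction profile (GIP) kernel similarity.

The GIP kernel scores two entities by the Gaussian of the squared
Euclidean distance between their binary interaction profiles:

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2)

with the bandwidth normalised by the mean squared profile norm,

    gamma = gamma' / ((1/n) * sum_k ||IP(k)||^2),

so that gamma' = 1 (the conventional choice) adapts the kernel width to
the density of the association data.  One generic routine serves all five
kernels used in the pipeline: the two miRNA kernels (rows of the
miRNA-disease and miRNA-target matrices) and the three disease kernels
(columns of the miRNA-disease, lncRNA-disease and gene-disease matrices).
"""

from __future__ import annotations

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix

__all__ = ["gip_kernel"]


def gip_kernel(
    assoc: AssociationMatrix, axis: str = "rows", gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel over one axis of a binary association matrix.

    Parameters
    ----------
    assoc
        Binary bipartite incidence matrix.
    axis
        ``"rows"`` — profiles are matrix rows; ``"cols"`` — columns.
    gamma_prime
        Raw bandwidth, normalised internally by the mean squared profile
        norm (the average number of associations per entity, since
        profiles are binary).

    Entities with empty profiles are handled by the formula as-is: they
    are at distance ``||IP(j)||`` from entity ``j`` and identical to each
    other.  An all-zero matrix leaves the bandwidth undefined and raises.
    """
    if axis == "rows":
        profiles = assoc.values.astype(np.float64)
        ids = assoc.row_ids
    elif axis == "cols":
        profiles = assoc.values.T.astype(np.float64)
        ids = assoc.col_ids
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be positive, got {gamma_prime}")

    sq_norms = profiles.sum(axis=1)  # binary: squared norm == row sum
    mean_sq_norm = sq_norms.mean()
    if mean_sq_norm == 0:
        raise ValueError(
            "association matrix has no interactions along the chosen axis; "
            "kernel bandwidth is undefined"
        )
    gamma = gamma_prime / mean_sq_norm

    gram = profiles @ profiles.T
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.maximum(sq_dist, 0.0, out=sq_dist)
    kernel = np.exp(-gamma * sq_dist)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix(list(ids), kernel)
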