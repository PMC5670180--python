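"""Case-based fusion of heterogeneous similarity sources.

The miRNA side fuses the functional similarity matrix FS (which covers
only a subset of miRNAs) with two GIP kernels: KM1 from miRNA-disease
associations (defined for every miRNA) and KM2 from miRNA-target
associations (subset coverage).  The disease side fuses three GIP
kernels: KD1 from miRNA-disease (full coverage), KD2 from lncRNA-disease
and KD3 from gene-disease (subset coverage).  Membership is decided per
pair — both endpoints must be covered by a source for its branch to
apply.

miRNA branches, in order:
  both in FS and in targets  ->  (FS + KM2) / 2
  both in FS only            ->  FS
  both in targets, not FS    ->  KM2
  otherwise                  ->  KM1

Disease branches:
  both in lncRNA-disease     ->  KD2
  else both in gene-disease  ->  KD3
  otherwise                  ->  KD1

The averaged branch pairs FS with KM2 (matching the quantity actually
averaged; KM1 covers every miRNA by construction, so conditioning the
average on KM1 would be vacuous); ``strict_average_km1=True`` switches
the averaged partner to KM1 for comparison.  Diagonals are forced to 1
after fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix, normalize_id

__all__ = ["MembershipIndex", "integrate_mirna", "integrate_disease", "restrict_similarity"]


@dataclass
class MembershipIndex:
    """Which entities each side dataset covers (normalized id sets)."""

    in_fs: set[str] = field(default_factory=set)
    in_targets: set[str] = field(default_factory=set)
    in_lnc: set[str] = field(default_factory=set)
    in_gene: set[str] = field(default_factory=set)

    @classmethod
    def from_sources(
        cls,
        fs: SimilarityMatrix | None = None,
        amt: AssociationMatrix | None = None,
        ald: AssociationMatrix | None = None,
        agd: AssociationMatrix | None = None,
    ) -> "MembershipIndex":
        """Derive membership from the source matrices' id registries."""
        return cls(
            in_fs={normalize_id(i) for i in fs.ids} if fs is not None else set(),
            in_targets={normalize_id(i) for i in amt.row_ids} if amt is not None else set(),
            in_lnc={normalize_id(i) for i in ald.col_ids} if ald is not None else set(),
            in_gene={normalize_id(i) for i in agd.col_ids} if agd is not None else set(),
        )


def _membership_mask(ids: list[str], members: set[str], source: SimilarityMatrix | None,
                     source_name: str) -> np.ndarray:
    """Boolean per-entity membership vector; members must be covered by the source."""
    keys = [normalize_id(i) for i in ids]
    mask = np.array([k in members for k in keys])
    if mask.any():
        if source is None:
            raise ValueError(f"membership declared for {source_name} but no matrix supplied")
        missing = [ids[i] for i in np.flatnonzero(mask) if not source.covers(ids[i])]
        if missing:
            raise ValueError(f"ids declared members of {source_name} but absent from its matrix: {missing}")
    return mask


def _embed(ids: list[str], source: SimilarityMatrix | None, mask: np.ndarray) -> np.ndarray:
    """Source values scattered into an n x n frame (NaN where not covered)."""
    n = len(ids)
    out = np.full((n, n), np.nan)
    if source is None or not mask.any():
        return out
    member_pos = np.flatnonzero(mask)
    src_idx = np.array([source.index(ids[i]) for i in member_pos])
    out[np.ix_(member_pos, member_pos)] = source.values[np.ix_(src_idx, src_idx)]
    return out


def integrate_mirna(
    fs: SimilarityMatrix | None,
    km1: SimilarityMatrix,
    km2: SimilarityMatrix | None,
    members: MembershipIndex,
    mirnas: list[str],
    strict_average_km1: bool = False,
) -> SimilarityMatrix:
    """Fuse FS, KM1 and KM2 into the integrated miRNA similarity SM."""
    missing = [m for m in mirnas if not km1.covers(m)]
    if missing:
        raise ValueError(f"KM1 must cover every miRNA; missing {missing}")
    fs_mask = _membership_mask(mirnas, members.in_fs, fs, "FS")
    t_mask = _membership_mask(mirnas, members.in_targets, km2, "KM2")

    n = len(mirnas)
    km1_full = km1.submatrix(mirnas).values
    fs_full = _embed(mirnas, fs, fs_mask)
    km2_full = _embed(mirnas, km2, t_mask)

    pair_fs = fs_mask[:, None] & fs_mask[None, :]
    pair_t = t_mask[:, None] & t_mask[None, :]

    out = km1_full.copy()  # "otherwise" branch
    only_t = pair_t & ~pair_fs
    out[only_t] = km2_full[only_t]
    only_fs = pair_fs & ~pair_t
    out[only_fs] = fs_full[only_fs]
    both = pair_fs & pair_t
    partner = km1_full if strict_average_km1 else km2_full
    out[both] = (fs_full[both] + partner[both]) / 2.0

    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    return SimilarityMatrix(list(mirnas), out)


def integrate_disease(
    kd1: SimilarityMatrix,
    kd2: SimilarityMatrix | None,
    kd3: SimilarityMatrix | None,
    members: MembershipIndex,
    diseases: list[str],
) -> SimilarityMatrix:
    """Fuse the three disease GIP kernels into the integrated kernel KD."""
    missing = [d for d in diseases if not kd1.covers(d)]
    if missing:
        raise ValueError(f"KD1 must cover every disease; missing {missing}")
    lnc_mask = _membership_mask(diseases, members.in_lnc, kd2, "KD2")
    gene_mask = _membership_mask(diseases, members.in_gene, kd3, "KD3")

    kd1_full = kd1.submatrix(diseases).values
    kd2_full = _embed(diseases, kd2, lnc_mask)
    kd3_full = _embed(diseases, kd3, gene_mask)

    pair_lnc = lnc_mask[:, None] & lnc_mask[None, :]
    pair_gene = gene_mask[:, None] & gene_mask[None, :]

    out = kd1_full.copy()
    gene_branch = pair_gene & ~pair_lnc
    out[gene_branch] = kd3_full[gene_branch]
    out[pair_lnc] = kd2_full[pair_lnc]

    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    return SimilarityMatrix(list(diseases), out)


def restrict_similarity(sim: SimilarityMatrix, keep: list[str]) -> SimilarityMatrix:
    """Principal submatrix on ``keep`` in the given order.

    Used to carve the small-dataset matrices: the functional-similarity
    restriction (miRNAs in both the association data and FS) and the
    target-kernel restriction (miRNAs in both the association and target
    data).
    """
    if not keep:
        raise ValueError("empty selection: nothing to restrict to")
    return sim.submatrix(keep)
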