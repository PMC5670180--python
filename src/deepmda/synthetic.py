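"""Self-contained synthetic worlds with planted association structure.

A world draws latent factors for miRNAs and diseases; the probability of
a true association is a logistic link on their inner product, with the
bias calibrated by bisection so the expected density of the sampled
miRNA-disease matrix matches the target (~3%, the density of the
curated association data the model is designed for).  The same latents
drive the side datasets, so every similarity source carries (noisy)
information about the planted structure:

* miRNA-target, lncRNA-disease and gene-disease tables are sampled from
  logistic links on the same miRNA/disease latents against fresh latent
  target/lncRNA/gene axes, restricted to random coverage subsets;
* the functional similarity matrix is a rescaled cosine similarity of
  miRNA latents plus truncated Gaussian noise, on its own coverage
  subset;
* diseases are clustered by nearest latent centroid and each cluster is
  grown into a random rooted tree emitted as MeSH-like descriptors, so
  semantic similarity correlates with latent proximity.

Partial coverage subsets guarantee that every branch of both similarity
fusion rules is exercised.  All sampling flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    write_association_table,
    write_mesh_descriptors,
    write_similarity_matrix,
)
from .types import AssociationMatrix, MeshDescriptor, SimilarityMatrix

__all__ = ["SynthConfig", "SynthWorld", "generate_world", "planted_recovery_check"]


@dataclass
class SynthConfig:
    """Generation parameters; defaults emulate the curated data's shape.

    Coverage fractions mirror the real sources: roughly half of the
    miRNAs have functional-similarity entries, a third have target
    interactions, about 60% of diseases appear in lncRNA-disease data
    and most in gene-disease data.
    """

    nm: int = 200
    nd: int = 100
    latent_dim: int = 8
    density: float = 0.03
    fs_coverage: float = 0.52
    target_coverage: float = 0.31
    lnc_coverage: float = 0.58
    gene_coverage: float = 0.90
    noise_sd: float = 0.05
    n_targets: int = 300
    n_lncrnas: int = 150
    n_genes: int = 400
    side_density: float = 0.05
    n_clusters: int = 8
    link_slope: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if self.density * self.nm * self.nd < 5:
            raise ValueError("expected positive count below 5; enlarge nm/nd or density")
        for name in ("fs_coverage", "target_coverage", "lnc_coverage", "gene_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynthWorld:
    """A generated world: ground truth plus every emitted artifact."""

    config: SynthConfig
    mirna_latents: np.ndarray
    disease_latents: np.ndarray
    pair_probs: np.ndarray
    amd: AssociationMatrix
    amt: AssociationMatrix | None
    ald: AssociationMatrix | None
    agd: AssociationMatrix | None
    fs: SimilarityMatrix | None
    descriptors: list[MeshDescriptor] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every artifact in the package's canonical text formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        write_association_table(self.amd, outdir / "mirna_disease.tsv")
        paths["amd"] = outdir / "mirna_disease.tsv"
        for name, assoc in (("mirna_target", self.amt), ("lncrna_disease", self.ald),
                            ("gene_disease", self.agd)):
            if assoc is not None:
                write_association_table(assoc, outdir / f"{name}.tsv")
                paths[name] = outdir / f"{name}.tsv"
        if self.fs is not None:
            write_similarity_matrix(self.fs, outdir / "functional_similarity.tsv")
            paths["fs"] = outdir / "functional_similarity.tsv"
        if self.descriptors:
            write_mesh_descriptors(self.descriptors, outdir / "mesh_descriptors.txt")
            paths["mesh"] = outdir / "mesh_descriptors.txt"
        return paths


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _calibrate_bias(scores: np.ndarray, target_density: float) -> float:
    """Bisect the logistic bias so mean link probability hits the target."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if _sigmoid(scores + mid).mean() < target_density:
            lo = mid
        else:
            hi = mid
    bias = (lo + hi) / 2.0
    if abs(_sigmoid(scores + bias).mean() - target_density) > 0.25 * target_density:
        raise ValueError("density calibration infeasible for the given latent scores")
    return bias


def _sample_bipartite(
    row_latents: np.ndarray,
    col_latents: np.ndarray,
    density: float,
    slope: float,
    rng: np.random.Generator,
    row_ids: list[str],
    col_ids: list[str],
) -> tuple[AssociationMatrix | None, np.ndarray]:
    scores = slope * (row_latents @ col_latents.T) / np.sqrt(row_latents.shape[1])
    probs = _sigmoid(scores + _calibrate_bias(scores, density))
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    # drop empty columns/rows silently only if everything vanished
    if values.sum() == 0:
        return None, probs
    return AssociationMatrix(row_ids, col_ids, values), probs


def _coverage_subset(ids: list[str], fraction: float, rng: np.random.Generator) -> list[str]:
    k = int(round(fraction * len(ids)))
    if k == 0:
        return []
    chosen = np.sort(rng.choice(len(ids), size=k, replace=False))
    return [ids[i] for i in chosen]


def _mesh_forest(
    disease_ids: list[str],
    latents: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator,
) -> list[MeshDescriptor]:
    """Rooted trees per latent cluster, emitted as descriptors.

    Cluster centroids are latent vectors of randomly chosen diseases;
    within a cluster each disease attaches below its latent-nearest
    earlier member, so ancestor overlap tracks latent proximity the way
    phenotypically similar diseases nest together in real disease
    hierarchies.  A small fraction of diseases receive a second tree
    number in another cluster.
    """
    nd = len(disease_ids)
    k = min(n_clusters, nd)
    centroid_idx = rng.choice(nd, size=k, replace=False)
    centroids = latents[centroid_idx]
    dists = ((latents[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assignment = dists.argmin(axis=1)

    positions: dict[int, str] = {}
    cluster_positions: dict[int, list[str]] = {c: [f"C{c + 1:02d}"] for c in range(k)}
    cluster_members: dict[int, list[int]] = {c: [] for c in range(k)}
    for i in range(nd):
        c = assignment[i]
        if cluster_members[c]:
            gaps = ((latents[cluster_members[c]] - latents[i]) ** 2).sum(axis=1)
            parent = positions[cluster_members[c][int(gaps.argmin())]]
        else:
            parent = cluster_positions[c][0]
        pos = f"{parent}.{rng.integers(100, 999)}"
        while pos in cluster_positions[c]:
            pos = f"{parent}.{rng.integers(100, 999)}"
        positions[i] = pos
        cluster_positions[c].append(pos)
        cluster_members[c].append(i)

    descriptors = []
    for i, did in enumerate(disease_ids):
        trees = [positions[i]]
        if k > 1 and rng.random() < 0.1:  # occasional multi-branch descriptor
            other = int(rng.integers(k))
            if other != assignment[i]:
                parent = cluster_positions[other][rng.integers(len(cluster_positions[other]))]
                trees.append(f"{parent}.{rng.integers(100, 999)}")
        descriptors.append(MeshDescriptor(did, trees))
    return descriptors


def generate_world(cfg: SynthConfig) -> SynthWorld:
    """Sample a complete synthetic world from the configuration."""
    root = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(7)]
    r_latent, r_amd, r_side, r_fs, r_mesh, r_cov, r_extra = rngs

    mirna_ids = [f"mir-{i + 1}" for i in range(cfg.nm)]
    disease_ids = [f"disease-{j + 1}" for j in range(cfg.nd)]

    U = r_latent.standard_normal((cfg.nm, cfg.latent_dim))
    V = r_latent.standard_normal((cfg.nd, cfg.latent_dim))

    amd, probs = _sample_bipartite(
        U, V, cfg.density, cfg.link_slope, r_amd, mirna_ids, disease_ids
    )
    if amd is None:
        raise ValueError("sampled association matrix is empty; increase density or size")

    # side association tables on coverage subsets, driven by the same latents
    def side_table(
        entity_latents: np.ndarray,
        entity_ids: list[str],
        n_other: int,
        coverage: float,
        transpose: bool,
        tag: str,
    ) -> AssociationMatrix | None:
        subset = _coverage_subset(entity_ids, coverage, r_cov)
        if len(subset) < 2:
            return None
        idx = [entity_ids.index(s) for s in subset]
        other_latents = r_side.standard_normal((n_other, cfg.latent_dim))
        other_ids = [f"{tag}-{i + 1}" for i in range(n_other)]
        assoc, _ = _sample_bipartite(
            entity_latents[idx], other_latents, cfg.side_density, cfg.link_slope,
            r_side, subset, other_ids,
        )
        if assoc is None:
            return None
        if transpose:
            return AssociationMatrix(other_ids, subset, assoc.values.T)
        return assoc

    amt = side_table(U, mirna_ids, cfg.n_targets, cfg.target_coverage, False, "target")
    ald = side_table(V, disease_ids, cfg.n_lncrnas, cfg.lnc_coverage, True, "lnc")
    agd = side_table(V, disease_ids, cfg.n_genes, cfg.gene_coverage, True, "gene")

    # functional similarity: rescaled cosine of miRNA latents + noise
    fs = None
    fs_subset = _coverage_subset(mirna_ids, cfg.fs_coverage, r_cov)
    if len(fs_subset) >= 2:
        idx = [mirna_ids.index(s) for s in fs_subset]
        sub = U[idx]
        norms = np.linalg.norm(sub, axis=1, keepdims=True)
        cos = (sub @ sub.T) / (norms * norms.T)
        vals = (1.0 + cos) / 2.0
        noise = r_fs.standard_normal(vals.shape) * cfg.noise_sd
        noise = (noise + noise.T) / 2.0
        vals = np.clip(vals + noise, 0.0, 1.0)
        np.fill_diagonal(vals, 1.0)
        fs = SimilarityMatrix(fs_subset, vals)

    descriptors = _mesh_forest(disease_ids, V, cfg.n_clusters, r_mesh)

    return SynthWorld(
        config=cfg,
        mirna_latents=U,
        disease_latents=V,
        pair_probs=probs,
        amd=amd,
        amt=amt,
        ald=ald,
        agd=agd,
        fs=fs,
        descriptors=descriptors,
    )


def planted_recovery_check(
    world: SynthWorld,
    report,
    auc_threshold: float = 0.85,
) -> dict:
    """Score a CV report against the world's planted structure.

    Reports the mean held-out AUC, the AUC of pooled scores against held-
    out labels, the rank agreement of pooled scores with the true pair
    probabilities (AUC using the oracle's top-density fraction as
    positives), and pass/fail at the configured threshold.
    """
    from .evaluate import compute_auc  # local import avoids cycle

    scores, labels = report.pooled()
    pooled_auc = compute_auc(scores, labels)

    prob_lookup = {
        (world.amd.row_ids[i], world.amd.col_ids[j]): world.pair_probs[i, j]
        for i in range(len(world.amd.row_ids))
        for j in range(len(world.amd.col_ids))
    }
    true_probs = np.array(
        [prob_lookup[pair] for fold in report.folds for pair in fold.test_pairs]
    )
    cut = np.quantile(true_probs, 1.0 - world.config.density)
    oracle_labels = (true_probs >= cut).astype(int)
    prob_rank_auc = compute_auc(scores, oracle_labels)

    return {
        "mean_fold_auc": report.mean_auc,
        "pooled_auc": pooled_auc,
        "prob_rank_auc": prob_rank_auc,
        "threshold": auc_threshold,
        "passed": bool(report.mean_auc >= auc_threshold),
    }
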