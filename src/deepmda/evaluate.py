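"""Evaluation protocols: 5-fold CV, leave-one-disease-out CV, robustness.

The central objects are :class:`PipelineInputs` (the raw association and
side data from which every similarity view is derived) and
:func:`build_similarities`, which turns them into the three matrices the
model consumes (integrated miRNA similarity SM, disease semantic
similarity SD, integrated disease kernel KD).  The CV drivers rebuild
the association-derived kernels *inside* each fold from a masked copy of
the miRNA-disease matrix (leakage guard), so held-out positives cannot
inform training-time similarities.  Leave-one-disease-out CV always
zeroes the held-out disease column before any similarity computation.

Metrics: AUC is the rank-based (Mann-Whitney) probability that a random
positive outranks a random negative, ties counted one half; AUPR is the
step-wise area under precision-recall across descending-score
thresholds (average precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .disease_semantics import build_dags, semantic_matrix
from .integrate import MembershipIndex, integrate_disease, integrate_mirna
from .kernels import gip_kernel
from .model import DeepMDA, PairDataset, SklearnHead, TrainConfig, assemble_pairs
from .types import AssociationMatrix, MeshDescriptor, SimilarityMatrix
from .util import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineInputs",
    "build_similarities",
    "compute_auc",
    "compute_aupr",
    "FoldPlan",
    "FoldResult",
    "EvalReport",
    "five_fold_cv",
    "lodocv",
    "add_white_noise",
    "robustness_experiment",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank / Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, scores))


def compute_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels = np.asarray(labels)
    if not (labels == 1).any():
        raise ValueError("AUPR undefined: no positive labels")
    return float(average_precision_score(labels, scores))


# --------------------------------------------------------------------------
# pipeline inputs -> similarity views
# --------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Raw inputs of one analysis: association data plus side sources.

    ``amd`` is required; the side sources are optional and their absence
    simply routes the corresponding fusion branches to the association-
    derived kernels.  The semantic similarity SD depends only on the MeSH
    descriptors, never on the association matrix, so it is computed once
    and cached.
    """

    amd: AssociationMatrix
    fs: SimilarityMatrix | None = None
    amt: AssociationMatrix | None = None
    ald: AssociationMatrix | None = None
    agd: AssociationMatrix | None = None
    descriptors: list[MeshDescriptor] | None = None
    gamma_prime: float = 1.0
    strict_average_km1: bool = False
    _sd_cache: SimilarityMatrix | None = field(default=None, repr=False)

    def semantic_similarity_matrix(self) -> SimilarityMatrix:
        if self._sd_cache is None:
            if self.descriptors is None:
                raise ValueError("no MeSH descriptors supplied; cannot build semantic similarity")
            ctx = build_dags(self.descriptors)
            self._sd_cache = semantic_matrix(ctx, self.amd.col_ids)
        return self._sd_cache


def build_similarities(
    inputs: PipelineInputs, amd_override: AssociationMatrix | None = None
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """(SM, SD, KD) from the inputs, optionally from a masked A_md.

    ``amd_override`` replaces the miRNA-disease matrix in every kernel
    that derives from it (KM1, KD1) — the hook used by the fold-level
    leakage guard and by LODOCV column masking.  Side-data kernels and
    the semantic similarity are unaffected by the override.
    """
    amd = amd_override if amd_override is not None else inputs.amd
    members = MembershipIndex.from_sources(inputs.fs, inputs.amt, inputs.ald, inputs.agd)

    km1 = gip_kernel(amd, axis="rows", gamma_prime=inputs.gamma_prime)
    km2 = gip_kernel(inputs.amt, axis="rows", gamma_prime=inputs.gamma_prime) \
        if inputs.amt is not None else None
    sm = integrate_mirna(inputs.fs, km1, km2, members, amd.row_ids,
                         strict_average_km1=inputs.strict_average_km1)

    kd1 = gip_kernel(amd, axis="cols", gamma_prime=inputs.gamma_prime)
    kd2 = gip_kernel(inputs.ald, axis="cols", gamma_prime=inputs.gamma_prime) \
        if inputs.ald is not None else None
    kd3 = gip_kernel(inputs.agd, axis="cols", gamma_prime=inputs.gamma_prime) \
        if inputs.agd is not None else None
    kd = integrate_disease(kd1, kd2, kd3, members, amd.col_ids)

    sd = inputs.semantic_similarity_matrix()
    return sm, sd, kd


# --------------------------------------------------------------------------
# fold plans and reports
# --------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Assignment of positive (and negative) pairs to folds.

    ``pos_pairs``/``neg_pairs`` are (row, col) index arrays into A_md and
    ``pos_folds``/``neg_folds`` the fold index of each pair.
    """

    scheme: str
    seed: int
    n_folds: int
    pos_pairs: np.ndarray
    pos_folds: np.ndarray
    neg_pairs: np.ndarray
    neg_folds: np.ndarray

    @classmethod
    def fivefold(cls, amd: AssociationMatrix, seed: int, n_folds: int = 5) -> "FoldPlan":
        pos = np.argwhere(amd.values == 1)
        neg = np.argwhere(amd.values == 0)
        if len(pos) < n_folds:
            raise ValueError(
                f"need at least {n_folds} known associations for {n_folds}-fold CV, "
                f"got {len(pos)}"
            )
        rng = np.random.default_rng(seed)

        def assign(n: int, r: np.random.Generator) -> np.ndarray:
            folds = np.empty(n, dtype=np.int64)
            order = r.permutation(n)
            for f, chunk in enumerate(np.array_split(order, n_folds)):
                folds[chunk] = f
            return folds

        return cls("fivefold", seed, n_folds, pos, assign(len(pos), rng),
                   neg, assign(len(neg), rng))


@dataclass
class FoldResult:
    """Per-fold (or per-disease) scores, labels and metrics."""

    fold: int | str
    auc: float
    aupr: float
    n_test: int
    scores: np.ndarray
    labels: np.ndarray
    test_pairs: list[tuple[str, str]]
    details: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    """Aggregate of fold results: mean and standard error of AUC/AUPR."""

    scheme: str
    seed: int
    folds: list[FoldResult]
    skipped: list[str] = field(default_factory=list)

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=np.float64)
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return float(vals.mean()), se

    @property
    def mean_auc(self) -> float:
        return self._agg("auc")[0]

    @property
    def se_auc(self) -> float:
        return self._agg("auc")[1]

    @property
    def mean_aupr(self) -> float:
        return self._agg("aupr")[0]

    @property
    def se_aupr(self) -> float:
        return self._agg("aupr")[1]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All test scores and labels concatenated across folds."""
        return (
            np.concatenate([f.scores for f in self.folds]),
            np.concatenate([f.labels for f in self.folds]),
        )

    def to_dict(self, include_scores: bool = False) -> dict:
        out = {
            "scheme": self.scheme,
            "seed": self.seed,
            "mean_auc": self.mean_auc,
            "se_auc": self.se_auc,
            "mean_aupr": self.mean_aupr,
            "se_aupr": self.se_aupr,
            "folds": [
                {
                    "fold": f.fold,
                    "auc": f.auc,
                    "aupr": f.aupr,
                    "n_test": f.n_test,
                    **(
                        {
                            "scores": f.scores.tolist(),
                            "labels": f.labels.tolist(),
                            "pairs": f.test_pairs,
                        }
                        if include_scores
                        else {}
                    ),
                }
                for f in self.folds
            ],
            "skipped": self.skipped,
        }
        return out


# --------------------------------------------------------------------------
# shared fold runner
# --------------------------------------------------------------------------

def _pairs_to_ids(amd: AssociationMatrix, pairs: np.ndarray) -> list[tuple[str, str]]:
    return [(amd.row_ids[i], amd.col_ids[j]) for i, j in pairs]


def _train_and_score(
    train_ds: PairDataset,
    test_ds: PairDataset,
    cfg: TrainConfig,
    encoder: str,
    head,
    fold_seed: int,
    code_noise: tuple[float, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Pretrain encoders, optionally inject code noise, train head, score.

    ``head`` is ``"dnn"`` or a factory ``seed -> sklearn estimator``.
    ``code_noise`` is (sigma_scale, noise_seed); the noise standard
    deviation is estimated per feature on the training codes and the same
    law applied to train and test codes with separate seeded draws.
    """
    cfg_fold = replace(cfg, seed=fold_seed)
    model = DeepMDA(cfg_fold, encoder=encoder)
    if head == "dnn" and code_noise is None:
        # plain path: full fit so encoder fine-tuning (if configured) applies
        model.fit(train_ds)
        scores = model.predict(test_ds)
        return scores, {"train_trace": list(model.classifier.train_trace)}
    model.fit_encoders(train_ds)
    codes_train = model.encode_pairs(train_ds)
    codes_test = model.encode_pairs(test_ds)
    if code_noise is not None:
        sigma_scale, noise_seed = code_noise
        feat_sd = codes_train.std(axis=0)
        codes_train = _add_noise_with_sd(codes_train, feat_sd, sigma_scale,
                                         derive_seed(noise_seed, "train"))
        codes_test = _add_noise_with_sd(codes_test, feat_sd, sigma_scale,
                                        derive_seed(noise_seed, "test"))
    details: dict = {}
    if head == "dnn":
        model.fit_head(codes_train, train_ds.labels)
        scores = model.classifier.scores(codes_test)
        details["train_trace"] = list(model.classifier.train_trace)
    else:
        shallow = SklearnHead(head(fold_seed))
        shallow.fit(codes_train, train_ds.labels)
        scores = shallow.scores(codes_test)
    return scores, details


# --------------------------------------------------------------------------
# five-fold cross-validation
# --------------------------------------------------------------------------

def five_fold_cv(
    inputs: PipelineInputs,
    cfg: TrainConfig,
    seed: int,
    n_folds: int = 5,
    leakage_guard: bool = True,
    encoder: str = "sae",
    head="dnn",
    test_vs_all_unknown: bool = False,
    code_noise: tuple[float, int] | None = None,
    fold_plan: FoldPlan | None = None,
    return_details: bool = False,
) -> EvalReport:
    """Seeded k-fold cross-validation over miRNA-disease pairs.

    Known associations are split into ``n_folds`` folds; unknown pairs
    are split into folds the same way so train and test pair sets are
    disjoint.  With the leakage guard on (default) the association-
    derived kernels are recomputed per fold from a copy of A_md whose
    test positives are zeroed.  ``test_vs_all_unknown=True`` reproduces
    the alternative convention of ranking each fold's positives against
    every unknown pair (which then appears in both training and testing).
    """
    amd = inputs.amd
    plan = fold_plan if fold_plan is not None else FoldPlan.fivefold(amd, seed, n_folds)
    folds: list[FoldResult] = []
    for f in range(plan.n_folds):
        test_pos = plan.pos_pairs[plan.pos_folds == f]
        train_pos = plan.pos_pairs[plan.pos_folds != f]
        if test_vs_all_unknown:
            test_neg = plan.neg_pairs
            train_neg = plan.neg_pairs
        else:
            test_neg = plan.neg_pairs[plan.neg_folds == f]
            train_neg = plan.neg_pairs[plan.neg_folds != f]

        if leakage_guard:
            masked = amd.copy()
            masked.values[test_pos[:, 0], test_pos[:, 1]] = 0
            sm, sd, kd = build_similarities(inputs, masked)
        else:
            masked = amd
            sm, sd, kd = build_similarities(inputs)

        train_pairs = _pairs_to_ids(amd, np.vstack([train_pos, train_neg]))
        test_pairs = _pairs_to_ids(amd, np.vstack([test_pos, test_neg]))
        train_ds = assemble_pairs(sm, sd, kd, amd, pairs=train_pairs)
        test_ds = assemble_pairs(sm, sd, kd, amd, pairs=test_pairs)

        noise = None
        if code_noise is not None:
            noise = (code_noise[0], derive_seed(code_noise[1], "fold", f))
        scores, details = _train_and_score(
            train_ds, test_ds, cfg, encoder, head, derive_seed(seed, "fold", f), noise
        )
        if return_details:
            details["masked_amd"] = masked
            details["sm"], details["sd"], details["kd"] = sm, sd, kd
        folds.append(
            FoldResult(
                fold=f,
                auc=compute_auc(scores, test_ds.labels),
                aupr=compute_aupr(scores, test_ds.labels),
                n_test=len(test_ds),
                scores=scores,
                labels=np.asarray(test_ds.labels),
                test_pairs=test_pairs,
                details=details,
            )
        )
    return EvalReport("fivefold", seed, folds)


# --------------------------------------------------------------------------
# leave-one-disease-out cross-validation
# --------------------------------------------------------------------------

def lodocv(
    inputs: PipelineInputs,
    cfg: TrainConfig,
    seed: int,
    diseases: list[str] | None = None,
    encoder: str = "sae",
    head="dnn",
    return_details: bool = False,
) -> EvalReport:
    """Leave-one-disease-out CV: hold out one whole disease column.

    For each disease, its column of A_md is zeroed before *all*
    similarity computation and training, so the held-out disease enters
    the model with no known associations; its nm pairs form the test
    set.  Diseases with no positives (nothing to recover) or no
    negatives (AUC undefined) are skipped with a note.
    """
    amd = inputs.amd
    targets = diseases if diseases is not None else list(amd.col_ids)
    folds: list[FoldResult] = []
    skipped: list[str] = []
    for disease in targets:
        j = amd.col_index(disease)
        col = amd.values[:, j]
        if col.sum() == 0:
            skipped.append(f"{disease}: no known associations")
            continue
        if col.sum() == len(col):
            skipped.append(f"{disease}: no negative pairs, AUC undefined")
            continue
        masked = amd.copy()
        masked.values[:, j] = 0
        sm, sd, kd = build_similarities(inputs, masked)

        all_pairs = np.argwhere(np.ones_like(amd.values, dtype=bool))
        train_mask = all_pairs[:, 1] != j
        train_pairs = _pairs_to_ids(amd, all_pairs[train_mask])
        test_pairs = [(m, amd.col_ids[j]) for m in amd.row_ids]

        # training labels come from the masked matrix (the held-out
        # column is all zero there anyway, and it is excluded from the
        # training pairs); test labels come from the true matrix
        train_ds = assemble_pairs(sm, sd, kd, masked, pairs=train_pairs)
        test_ds = assemble_pairs(sm, sd, kd, amd, pairs=test_pairs)

        scores, details = _train_and_score(
            train_ds, test_ds, cfg, encoder, head, derive_seed(seed, "lodocv", disease)
        )
        if return_details:
            details["masked_amd"] = masked
            details["sm"], details["sd"], details["kd"] = sm, sd, kd
        folds.append(
            FoldResult(
                fold=disease,
                auc=compute_auc(scores, test_ds.labels),
                aupr=compute_aupr(scores, test_ds.labels),
                n_test=len(test_ds),
                scores=scores,
                labels=np.asarray(test_ds.labels),
                test_pairs=test_pairs,
                details=details,
            )
        )
    if not folds:
        raise ValueError("no disease column was evaluable")
    return EvalReport("lodocv", seed, folds, skipped=skipped)


# --------------------------------------------------------------------------
# white-noise robustness
# --------------------------------------------------------------------------

def _add_noise_with_sd(
    features: np.ndarray, feat_sd: np.ndarray, sigma_scale: float, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return features + rng.standard_normal(features.shape) * (sigma_scale * feat_sd)


def add_white_noise(features: np.ndarray, sigma_scale: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise, per-feature sd = sigma_scale * sd_j.

    ``sd_j`` is the feature's empirical standard deviation, so
    ``sigma_scale`` is a signal-relative noise level.
    """
    if sigma_scale < 0:
        raise ValueError(f"sigma_scale must be non-negative, got {sigma_scale}")
    features = np.asarray(features, dtype=np.float64)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if sigma_scale == 0:
        return features.copy()
    return _add_noise_with_sd(features, features.std(axis=0), sigma_scale, seed)


def robustness_experiment(
    inputs: PipelineInputs,
    cfg: TrainConfig,
    sigma_scale: float,
    seed: int,
    heads: dict | None = None,
    n_folds: int = 5,
    leakage_guard: bool = True,
) -> dict:
    """Clean vs noise-injected 5-fold CV for one or more classifier heads.

    White noise is injected on the encoder codes (training and test)
    before classification.  ``heads`` maps head name to ``"dnn"`` or a
    factory ``seed -> sklearn estimator``; default is the DNN head only.
    Returns per-head clean/noisy reports plus the AUC drop.
    """
    if sigma_scale < 0:
        raise ValueError(f"sigma_scale must be non-negative, got {sigma_scale}")
    heads = heads or {"dnn": "dnn"}
    amd = inputs.amd
    plan = FoldPlan.fivefold(amd, seed, n_folds)

    # encoders are pretrained once per fold; every head and both noise
    # conditions share the same codes, as in the original design where
    # noise is injected downstream of the (fixed) feature extractor
    per_head: dict[str, dict[str, list[FoldResult]]] = {
        name: {"clean": [], "noisy": []} for name in heads
    }
    for f in range(plan.n_folds):
        test_pos = plan.pos_pairs[plan.pos_folds == f]
        train_pos = plan.pos_pairs[plan.pos_folds != f]
        test_neg = plan.neg_pairs[plan.neg_folds == f]
        train_neg = plan.neg_pairs[plan.neg_folds != f]
        if leakage_guard:
            masked = amd.copy()
            masked.values[test_pos[:, 0], test_pos[:, 1]] = 0
            sm, sd, kd = build_similarities(inputs, masked)
        else:
            sm, sd, kd = build_similarities(inputs)
        train_pairs = _pairs_to_ids(amd, np.vstack([train_pos, train_neg]))
        test_pairs = _pairs_to_ids(amd, np.vstack([test_pos, test_neg]))
        train_ds = assemble_pairs(sm, sd, kd, amd, pairs=train_pairs)
        test_ds = assemble_pairs(sm, sd, kd, amd, pairs=test_pairs)

        fold_seed = derive_seed(seed, "fold", f)
        cfg_fold = replace(cfg, seed=fold_seed)
        extractor = DeepMDA(cfg_fold, encoder="sae").fit_encoders(train_ds)
        codes = {"clean": (extractor.encode_pairs(train_ds), extractor.encode_pairs(test_ds))}
        feat_sd = codes["clean"][0].std(axis=0)
        noise_seed = derive_seed(seed, "noise", f)
        codes["noisy"] = (
            _add_noise_with_sd(codes["clean"][0], feat_sd, sigma_scale,
                               derive_seed(noise_seed, "train")),
            _add_noise_with_sd(codes["clean"][1], feat_sd, sigma_scale,
                               derive_seed(noise_seed, "test")),
        )
        for name, head in heads.items():
            for condition in ("clean", "noisy"):
                ctr, cte = codes[condition]
                if head == "dnn":
                    scorer = DeepMDA(cfg_fold, encoder="sae")
                    scorer.mirna_stack = extractor.mirna_stack
                    scorer.disease_stack = extractor.disease_stack
                    scorer.fit_head(ctr, train_ds.labels)
                    scores = scorer.classifier.scores(cte)
                else:
                    shallow = SklearnHead(head(fold_seed))
                    shallow.fit(ctr, train_ds.labels)
                    scores = shallow.scores(cte)
                per_head[name][condition].append(
                    FoldResult(
                        fold=f,
                        auc=compute_auc(scores, test_ds.labels),
                        aupr=compute_aupr(scores, test_ds.labels),
                        n_test=len(test_ds),
                        scores=scores,
                        labels=np.asarray(test_ds.labels),
                        test_pairs=test_pairs,
                    )
                )

    out: dict = {}
    for name in heads:
        clean = EvalReport("fivefold", seed, per_head[name]["clean"])
        noisy = EvalReport("fivefold", seed, per_head[name]["noisy"])
        out[name] = {
            "clean": clean,
            "noisy": noisy,
            "auc_drop": clean.mean_auc - noisy.mean_auc,
            "per_fold_auc_drop": [
                c.auc - n.auc for c, n in zip(clean.folds, noisy.folds)
            ],
        }
    return out
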