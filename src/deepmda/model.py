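"""The association predictor: two stacked autoencoders plus a DNN head.

Every (miRNA, disease) pair is one sample.  The miRNA half of the sample
is that miRNA's row of the integrated miRNA similarity matrix SM (width
nm); the disease half concatenates the disease's row of the semantic
similarity matrix SD with its row of the integrated disease GIP kernel
KD (width 2*nd).  Each half is compressed by a stacked autoencoder,
pretrained greedily layer by layer to minimise reconstruction MSE; the
two 64-dimensional codes are concatenated into a 128-dimensional feature
vector and classified by a three-layer fully connected network (ReLU
hidden units, sigmoid output, dropout 0.5, binary cross-entropy,
ADADELTA with mini-batches of 200).

Weight initialisation is Gaussian with standard deviation 0.05 and bias
initialisation uniform-negative (default range (-0.05, 0); see
``TrainConfig``).  Encoders are frozen after greedy
pretraining by default; ``fine_tune_encoders`` lets classifier gradients
flow back into them.  An ``encoder="identity"`` variant bypasses the
autoencoders and feeds the raw concatenated similarity rows straight to
the classifier (the RAW+DNN ablation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Adadelta, Dense, FeedForward, SGD, bce_loss, minibatches, mse_loss, relu, sigmoid
from .types import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "PairDataset",
    "AutoencoderStack",
    "ClassifierNet",
    "DeepMDA",
    "SklearnHead",
    "assemble_pairs",
    "pretrain_autoencoder",
    "encode",
    "train_classifier",
    "predict",
    "relu",
    "sigmoid",
]


@dataclass
class TrainConfig:
    """Hyperparameters of pretraining and classifier training.

    Defaults follow the model's stated protocol: ADADELTA with batch 200
    for the classifier, SGD for reconstruction pretraining, dropout 0.5,
    Gaussian(0, 0.05) weights and small negative-uniform biases, 64-dim
    codes.  Hidden widths and epoch counts are configurable.
    """

    batch_size: int = 200
    pretrain_epochs: int = 20
    train_epochs: int = 50
    sgd_lr: float = 0.2
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    adadelta_lr: float = 1.0
    weight_init_std: float = 0.05
    # negative-uniform bias convention; kept small because large negative
    # biases silence ReLU units permanently (zero gradient, no recovery)
    bias_init_range: tuple[float, float] = (-0.05, 0.0)
    dropout_rate: float = 0.5
    code_dim: int = 64
    mirna_hidden: tuple[int, ...] = (256,)
    disease_hidden: tuple[int, ...] = (256,)
    classifier_hidden: tuple[int, ...] = (64, 32)
    early_stopping: bool = True
    val_fraction: float = 0.1
    patience: int = 10
    fine_tune_encoders: bool = False
    fine_tune_epochs: int = 10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        lo, hi = self.bias_init_range
        if lo > hi:
            raise ValueError("bias_init_range must be (low, high)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class PairDataset:
    """Per-pair features and labels for classifier training/scoring."""

    mirna_features: np.ndarray
    disease_features: np.ndarray
    labels: np.ndarray
    pair_index: list[tuple[str, str]]

    def __post_init__(self) -> None:
        n = len(self.pair_index)
        if not (self.mirna_features.shape[0] == self.disease_features.shape[0]
                == self.labels.shape[0] == n):
            raise ValueError("features, labels and pair index must be aligned in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.pair_index)

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            self.mirna_features[idx],
            self.disease_features[idx],
            self.labels[idx],
            [self.pair_index[i] for i in idx],
        )


def assemble_pairs(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    kd: SimilarityMatrix,
    amd: AssociationMatrix,
    pairs: list[tuple[str, str]] | None = None,
    labels_from: AssociationMatrix | None = None,
) -> PairDataset:
    """Build the pair sample matrix from the three similarity views.

    By default every (miRNA, disease) combination of the association
    matrix becomes a sample (nm * nd rows).  ``labels_from`` lets labels
    be read from a different (e.g. unmasked) association matrix than the
    one defining the registries.
    """
    for mid in amd.row_ids:
        if not sm.covers(mid):
            raise ValueError(f"miRNA {mid!r} missing from integrated miRNA similarity")
    for did in amd.col_ids:
        if not sd.covers(did):
            raise ValueError(f"disease {did!r} missing from semantic similarity")
        if not kd.covers(did):
            raise ValueError(f"disease {did!r} missing from disease kernel")

    label_src = labels_from if labels_from is not None else amd
    if pairs is None:
        mi = np.repeat(np.arange(len(amd.row_ids)), len(amd.col_ids))
        di = np.tile(np.arange(len(amd.col_ids)), len(amd.row_ids))
        pair_index = [(amd.row_ids[i], amd.col_ids[j]) for i, j in zip(mi, di)]
    else:
        mi = np.array([amd.row_index(m) for m, _ in pairs])
        di = np.array([amd.col_index(d) for _, d in pairs])
        pair_index = list(pairs)

    sm_rows = np.array([sm.index(m) for m in amd.row_ids])
    sd_rows = np.array([sd.index(d) for d in amd.col_ids])
    kd_rows = np.array([kd.index(d) for d in amd.col_ids])

    mirna_features = sm.values[sm_rows[mi]]
    disease_features = np.hstack([sd.values[sd_rows[di]], kd.values[kd_rows[di]]])
    labels = label_src.values[mi, di].astype(np.int8)
    return PairDataset(mirna_features, disease_features, labels, pair_index)


@dataclass
class AutoencoderStack:
    """Greedily pretrained encoder layers plus their training record."""

    encoder: FeedForward
    layer_widths: list[int]
    dropout_rate: float
    pretrain_losses: list[list[float]] = field(default_factory=list)

    @property
    def code_dim(self) -> int:
        return self.layer_widths[-1]


def pretrain_autoencoder(
    features: np.ndarray, widths: list[int], cfg: TrainConfig, rng: np.random.Generator
) -> AutoencoderStack:
    """Greedy layer-wise reconstruction pretraining.

    ``widths`` runs from the input width down to the code width, strictly
    decreasing.  Layer k is trained as a one-hidden-layer autoencoder on
    the (fixed) codes of layers < k, minimising MSE with SGD; earlier
    layers are frozen, so training layer k leaves them bit-identical.
    """
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if len(widths) < 2:
        raise ValueError("need at least an input and a code width")
    if widths[-1] >= widths[0]:
        raise ValueError(f"code width must be smaller than the input width: {widths}")
    for a, b in zip(widths[1:], widths[2:]):
        if b >= a:
            raise ValueError(f"hidden widths must strictly decrease toward the code: {widths}")

    stack_layers: list[Dense] = []
    losses_per_layer: list[list[float]] = []
    h = features
    for d_in, d_out in zip(widths, widths[1:]):
        # linear reconstruction output: a ReLU output unit that initialises
        # dead can never recover (zero gradient), and MSE pairs naturally
        # with a linear readout; the hidden (code) layer stays ReLU
        ae = FeedForward(
            [d_in, d_out, d_in],
            ["relu", "linear"],
            rng,
            cfg.weight_init_std,
            cfg.bias_init_range,
            cfg.dropout_rate,
        )
        opt = SGD(cfg.sgd_lr)
        trace: list[float] = []
        n = h.shape[0]
        for epoch in range(cfg.pretrain_epochs):
            epoch_losses = []
            for idx in minibatches(n, cfg.batch_size, rng):
                x = h[idx]
                z = ae.forward(x, cache=True, dropout_rng=rng)
                loss = mse_loss(z, x)
                if not np.isfinite(loss):
                    raise ArithmeticError(
                        f"reconstruction loss diverged at layer width {d_out}, epoch {epoch}"
                    )
                d_out_grad = 2.0 * (z - x) / z.size
                _, grads = ae.backward(d_out_grad)
                ae.apply_grads(opt, grads)
                epoch_losses.append(loss)
            trace.append(float(np.mean(epoch_losses)))
        stack_layers.append(ae.layers[0])
        losses_per_layer.append(trace)
        h = ae.layers[0].forward(h)  # code of this layer, dropout off

    encoder = FeedForward.__new__(FeedForward)
    encoder.layers = stack_layers
    encoder.dropout_rate = cfg.dropout_rate
    encoder._masks = []
    return AutoencoderStack(encoder, list(widths), cfg.dropout_rate, losses_per_layer)


def encode(stack: AutoencoderStack, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass through the encoder (dropout off)."""
    if features.shape[1] != stack.layer_widths[0]:
        raise ValueError(
            f"feature width {features.shape[1]} does not match encoder input "
            f"width {stack.layer_widths[0]}"
        )
    return stack.encoder.forward(features)


@dataclass
class ClassifierNet:
    """Three-weight-layer fully connected head with sigmoid output."""

    net: FeedForward
    input_dim: int
    trained: bool = False
    train_trace: list[float] = field(default_factory=list)
    val_trace: list[float] = field(default_factory=list)

    @classmethod
    def build(cls, input_dim: int, cfg: TrainConfig, rng: np.random.Generator) -> "ClassifierNet":
        widths = [input_dim, *cfg.classifier_hidden, 1]
        # linear output layer; sigmoid applied at scoring time for a
        # numerically stable cross-entropy gradient (a - y on the logit)
        activations = ["relu"] * len(cfg.classifier_hidden) + ["linear"]
        return cls(
            FeedForward(widths, activations, rng, cfg.weight_init_std,
                        cfg.bias_init_range, cfg.dropout_rate),
            input_dim,
        )

    def scores(self, codes: np.ndarray) -> np.ndarray:
        return sigmoid(self.net.forward(codes))[:, 0]


def train_classifier(
    codes: np.ndarray,
    labels: np.ndarray,
    net: ClassifierNet,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> ClassifierNet:
    """Mini-batch ADADELTA on binary cross-entropy, with optional early
    stopping on a held-out fraction of the training pairs."""
    if codes.shape[1] != net.input_dim:
        raise ValueError(f"code width {codes.shape[1]} != classifier input {net.input_dim}")
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        logger.warning("training labels are single-class; ranking metrics will be undefined")

    n = codes.shape[0]
    val_idx = np.array([], dtype=int)
    train_idx = np.arange(n)
    if cfg.early_stopping and n >= 20:
        n_val = max(1, int(round(n * cfg.val_fraction)))
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adadelta(cfg.adadelta_rho, cfg.adadelta_eps, cfg.adadelta_lr)
    best_val = np.inf
    best_snap = None
    stale = 0
    for epoch in range(cfg.train_epochs):
        epoch_losses = []
        for idx in minibatches(len(train_idx), cfg.batch_size, rng):
            batch = train_idx[idx]
            logits = net.net.forward(codes[batch], cache=True, dropout_rng=rng)[:, 0]
            a = sigmoid(logits)
            loss = bce_loss(a, y[batch])
            if not np.isfinite(loss):
                raise ArithmeticError(f"classifier loss diverged at epoch {epoch}")
            d_logit = ((a - y[batch]) / len(batch))[:, None]
            _, grads = net.net.backward(d_logit)
            net.net.apply_grads(opt, grads)
            epoch_losses.append(loss)
        net.train_trace.append(float(np.mean(epoch_losses)))
        if len(val_idx):
            val_loss = bce_loss(net.scores(codes[val_idx]), y[val_idx])
            net.val_trace.append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val, best_snap, stale = val_loss, net.net.snapshot(), 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
    if best_snap is not None:
        net.net.restore(best_snap)
    net.trained = True
    return net


class DeepMDA:
    """Trained model bundle: encoder stacks + classifier + config + seed.

    ``encoder="sae"`` (default) uses the two stacked autoencoders;
    ``encoder="identity"`` feeds raw concatenated similarity rows to the
    classifier (RAW+DNN ablation).
    """

    def __init__(self, config: TrainConfig | None = None, encoder: str = "sae") -> None:
        if encoder not in ("sae", "identity"):
            raise ValueError(f"encoder must be 'sae' or 'identity', got {encoder!r}")
        self.config = config or TrainConfig()
        self.encoder_kind = encoder
        self.mirna_stack: AutoencoderStack | None = None
        self.disease_stack: AutoencoderStack | None = None
        self.classifier: ClassifierNet | None = None
        self.trained = False

    # -- internal ------------------------------------------------------
    def _rngs(self) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.config.seed).spawn(4)
        return [np.random.default_rng(s) for s in seqs]

    def _code_dim(self, dataset: PairDataset) -> int:
        if self.encoder_kind == "identity":
            return dataset.mirna_features.shape[1] + dataset.disease_features.shape[1]
        return 2 * self.config.code_dim

    # -- public --------------------------------------------------------
    def fit_encoders(self, dataset: PairDataset) -> "DeepMDA":
        """Greedy layer-wise pretraining of both autoencoder stacks."""
        cfg = self.config
        rng_m, rng_d, _, _ = self._rngs()
        if self.encoder_kind == "sae":
            m_widths = [dataset.mirna_features.shape[1], *cfg.mirna_hidden, cfg.code_dim]
            d_widths = [dataset.disease_features.shape[1], *cfg.disease_hidden, cfg.code_dim]
            self.mirna_stack = pretrain_autoencoder(dataset.mirna_features, m_widths, cfg, rng_m)
            self.disease_stack = pretrain_autoencoder(
                dataset.disease_features, d_widths, cfg, rng_d
            )
        return self

    def fit_head(self, codes: np.ndarray, labels: np.ndarray) -> "DeepMDA":
        """Train the DNN classifier on (possibly noise-injected) codes."""
        _, _, rng_c, rng_t = self._rngs()
        self.classifier = ClassifierNet.build(codes.shape[1], self.config, rng_c)
        train_classifier(codes, labels, self.classifier, self.config, rng_t)
        self.trained = True
        return self

    def fit(self, dataset: PairDataset) -> "DeepMDA":
        self.fit_encoders(dataset)
        self.fit_head(self.encode_pairs(dataset), dataset.labels)
        if self.config.fine_tune_encoders and self.encoder_kind == "sae":
            _, _, _, rng_t = self._rngs()
            self._joint_finetune(dataset, rng_t)
        return self

    def encode_pairs(self, dataset: PairDataset) -> np.ndarray:
        """Concatenated codes (or raw features for the identity variant)."""
        if self.encoder_kind == "identity":
            return np.hstack([dataset.mirna_features, dataset.disease_features])
        if self.mirna_stack is None or self.disease_stack is None:
            raise RuntimeError("encoders not trained; call fit() first")
        return np.hstack(
            [
                encode(self.mirna_stack, dataset.mirna_features),
                encode(self.disease_stack, dataset.disease_features),
            ]
        )

    def _joint_finetune(self, dataset: PairDataset, rng: np.random.Generator) -> None:
        """Backprop classifier gradients into both encoder stacks."""
        cfg = self.config
        opt = Adadelta(cfg.adadelta_rho, cfg.adadelta_eps, cfg.adadelta_lr)
        y = dataset.labels.astype(np.float64)
        n = len(dataset)
        enc_m, enc_d = self.mirna_stack.encoder, self.disease_stack.encoder
        clf = self.classifier.net
        dm = self.mirna_stack.code_dim
        for _ in range(cfg.fine_tune_epochs):
            for idx in minibatches(n, cfg.batch_size, rng):
                cm = enc_m.forward(dataset.mirna_features[idx], cache=True, dropout_rng=rng)
                cd = enc_d.forward(dataset.disease_features[idx], cache=True, dropout_rng=rng)
                codes = np.hstack([cm, cd])
                logits = clf.forward(codes, cache=True, dropout_rng=rng)[:, 0]
                a = sigmoid(logits)
                d_logit = ((a - y[idx]) / len(idx))[:, None]
                d_codes, g_clf = clf.backward(d_logit)
                _, g_m = enc_m.backward(d_codes[:, :dm])
                _, g_d = enc_d.backward(d_codes[:, dm:])
                clf.apply_grads(opt, g_clf)
                enc_m.apply_grads(opt, g_m)
                enc_d.apply_grads(opt, g_d)

    def predict(self, dataset: PairDataset) -> np.ndarray:
        """Association score in [0, 1] for every pair of the dataset."""
        if not self.trained:
            raise RuntimeError("model not trained; call fit() first")
        return self.classifier.scores(self.encode_pairs(dataset))

    def predict_binary(self, dataset: PairDataset) -> np.ndarray:
        return (self.predict(dataset) >= self.config.decision_threshold).astype(np.int8)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialise weights plus the full config and seed to ``.npz``."""
        arrays: dict[str, np.ndarray] = {}
        meta = {"encoder_kind": self.encoder_kind, "trained": self.trained,
                "config": asdict(self.config)}
        for tag, stack in (("m", self.mirna_stack), ("d", self.disease_stack)):
            if stack is not None:
                meta[f"{tag}_widths"] = stack.layer_widths
                for k, layer in enumerate(stack.encoder.layers):
                    arrays[f"{tag}_W{k}"] = layer.W
                    arrays[f"{tag}_b{k}"] = layer.b
        if self.classifier is not None:
            meta["clf_acts"] = [l.activation for l in self.classifier.net.layers]
            meta["clf_input"] = self.classifier.input_dim
            for k, layer in enumerate(self.classifier.net.layers):
                arrays[f"c_W{k}"] = layer.W
                arrays[f"c_b{k}"] = layer.b
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DeepMDA":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["bias_init_range"] = tuple(cfg_dict["bias_init_range"])
        for key in ("mirna_hidden", "disease_hidden", "classifier_hidden"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(TrainConfig(**cfg_dict), encoder=meta["encoder_kind"])

        def load_stack(tag: str) -> AutoencoderStack | None:
            if f"{tag}_widths" not in meta:
                return None
            widths = meta[f"{tag}_widths"]
            ff = FeedForward.__new__(FeedForward)
            ff.dropout_rate = model.config.dropout_rate
            ff._masks = []
            ff.layers = []
            for k in range(len(widths) - 1):
                layer = Dense.__new__(Dense)
                layer.W = data[f"{tag}_W{k}"]
                layer.b = data[f"{tag}_b{k}"]
                layer.activation = "relu"
                ff.layers.append(layer)
            return AutoencoderStack(ff, widths, model.config.dropout_rate)

        model.mirna_stack = load_stack("m")
        model.disease_stack = load_stack("d")
        if "clf_acts" in meta:
            ff = FeedForward.__new__(FeedForward)
            ff.dropout_rate = model.config.dropout_rate
            ff._masks = []
            ff.layers = []
            for k, act in enumerate(meta["clf_acts"]):
                layer = Dense.__new__(Dense)
                layer.W = data[f"c_W{k}"]
                layer.b = data[f"c_b{k}"]
                layer.activation = act
                ff.layers.append(layer)
            model.classifier = ClassifierNet(ff, meta["clf_input"], trained=True)
        model.trained = meta["trained"]
        return model


def predict(model: DeepMDA, dataset: PairDataset) -> np.ndarray:
    """Functional alias for :meth:`DeepMDA.predict`."""
    return model.predict(dataset)


class SklearnHead:
    """Adapter plugging a scikit-learn classifier onto the encoder codes.

    Used for the comparison heads of the robustness experiment (e.g.
    AdaBoost, random forest).  The estimator must expose ``fit`` and
    ``predict_proba``.
    """

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def fit(self, codes: np.ndarray, labels: np.ndarray) -> "SklearnHead":
        self.estimator.fit(codes, labels)
        return self

    def scores(self, codes: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(codes)
        return proba[:, -1]
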