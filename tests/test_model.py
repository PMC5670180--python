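"""Autoencoder stacks, classifier head and the assembled predictor."""

import numpy as np
import pytest

from deepmda.evaluate import compute_auc
from deepmda.model import (
    ClassifierNet,
    DeepMDA,
    PairDataset,
    TrainConfig,
    assemble_pairs,
    encode,
    pretrain_autoencoder,
    relu,
    sigmoid,
    train_classifier,
)
from deepmda.nn import bce_loss
from deepmda.types import AssociationMatrix, SimilarityMatrix


def test_relu_and_sigmoid_pointwise():
    assert relu(np.array([-3.0]))[0] == 0.0
    assert relu(np.array([2.5]))[0] == 2.5
    assert sigmoid(np.array([0.0]))[0] == 0.5
    assert sigmoid(np.array([1e3]))[0] == pytest.approx(1.0, abs=1e-12)
    assert sigmoid(np.array([-1e3]))[0] == pytest.approx(0.0, abs=1e-12)


def test_cross_entropy_hand_value():
    # predictions of 0.5 on one positive and one negative: loss = ln 2
    assert bce_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(
        np.log(2), abs=1e-12
    )


def _sim(ids, rng):
    n = len(ids)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(ids, v)


class TestAssemblePairs:
    @pytest.fixture()
    def small_inputs(self, rng):
        mirnas = ["m1", "m2", "m3"]
        diseases = ["d1", "d2"]
        amd = AssociationMatrix(mirnas, diseases, np.array([[1, 0], [0, 1], [0, 0]]))
        return _sim(mirnas, rng), _sim(diseases, rng), _sim(diseases, rng), amd

    def test_cartesian_product_and_widths(self, small_inputs):
        sm, sd, kd, amd = small_inputs
        ds = assemble_pairs(sm, sd, kd, amd)
        assert len(ds) == 6
        assert ds.mirna_features.shape == (6, 3)
        assert ds.disease_features.shape == (6, 4)  # SD row + KD row

    def test_labels_follow_association_matrix(self, small_inputs):
        sm, sd, kd, amd = small_inputs
        ds = assemble_pairs(sm, sd, kd, amd, pairs=[("m1", "d1"), ("m1", "d2")])
        assert ds.labels.tolist() == [1, 0]

    def test_id_mismatch_names_offender(self, small_inputs, rng):
        sm, sd, kd, amd = small_inputs
        sm_missing = _sim(["m1", "m2"], rng)
        with pytest.raises(ValueError, match="m3"):
            assemble_pairs(sm_missing, sd, kd, amd)


class TestPretraining:
    def test_constant_input_reconstructed(self, rng):
        cfg = TrainConfig(pretrain_epochs=60, batch_size=16, dropout_rate=0.0,
                          weight_init_std=0.5)
        x = np.full((64, 6), 0.7)
        stack = pretrain_autoencoder(x, [6, 3], cfg, rng)
        assert stack.pretrain_losses[0][-1] < 1e-3

    def test_fixed_seed_reproduces_weights(self):
        cfg = TrainConfig(pretrain_epochs=5)
        x = np.random.default_rng(3).random((50, 10))
        s1 = pretrain_autoencoder(x, [10, 6, 4], cfg, np.random.default_rng(7))
        s2 = pretrain_autoencoder(x, [10, 6, 4], cfg, np.random.default_rng(7))
        for l1, l2 in zip(s1.encoder.layers, s2.encoder.layers):
            assert np.array_equal(l1.W, l2.W) and np.array_equal(l1.b, l2.b)

    def test_loss_decreases_on_structured_data(self):
        rng = np.random.default_rng(0)
        latent = rng.random((80, 3))
        x = np.clip(latent @ rng.random((3, 12)), 0, 1)
        cfg = TrainConfig(pretrain_epochs=20, batch_size=20)
        stack = pretrain_autoencoder(x, [12, 6], cfg, np.random.default_rng(0))
        trace = stack.pretrain_losses[0]
        assert trace[-1] <= trace[0]

    def test_greedy_training_is_layer_local(self):
        """Earlier layers are bit-identical whether or not deeper layers exist."""
        x = np.random.default_rng(5).random((60, 12))
        cfg = TrainConfig(pretrain_epochs=5)
        shallow = pretrain_autoencoder(x, [12, 8], cfg, np.random.default_rng(9))
        deep = pretrain_autoencoder(x, [12, 8, 4], cfg, np.random.default_rng(9))
        assert np.array_equal(shallow.encoder.layers[0].W, deep.encoder.layers[0].W)
        assert np.array_equal(shallow.encoder.layers[0].b, deep.encoder.layers[0].b)

    def test_non_decreasing_widths_rejected(self, rng):
        with pytest.raises(ValueError, match="decrease"):
            pretrain_autoencoder(np.zeros((4, 10)), [10, 4, 6], TrainConfig(), rng)


class TestEncode:
    def test_code_width_and_determinism(self, rng):
        x = rng.random((30, 20))
        stack = pretrain_autoencoder(x, [20, 12, 5], TrainConfig(pretrain_epochs=2), rng)
        c1, c2 = encode(stack, x), encode(stack, x)
        assert c1.shape == (30, 5)
        assert np.array_equal(c1, c2)

    def test_zero_weights_give_zero_code(self, rng):
        x = rng.random((10, 6))
        stack = pretrain_autoencoder(x, [6, 3], TrainConfig(pretrain_epochs=1), rng)
        stack.encoder.layers[0].W[...] = 0.0
        stack.encoder.layers[0].b[...] = 0.0
        assert np.all(encode(stack, x) == 0.0)

    def test_width_mismatch_rejected(self, rng):
        stack = pretrain_autoencoder(rng.random((10, 6)), [6, 3],
                                     TrainConfig(pretrain_epochs=1), rng)
        with pytest.raises(ValueError, match="width"):
            encode(stack, rng.random((4, 9)))


class TestClassifier:
    def test_separable_codes_reach_high_auc(self, rng):
        n = 400
        labels = (rng.random(n) < 0.5).astype(int)
        codes = rng.normal(0, 0.3, (n, 4)) + labels[:, None] * 2.0
        cfg = TrainConfig(train_epochs=60, batch_size=64, classifier_hidden=(16, 8),
                          early_stopping=False, dropout_rate=0.2, weight_init_std=0.5)
        net = ClassifierNet.build(4, cfg, np.random.default_rng(1))
        train_classifier(codes, labels, net, cfg, np.random.default_rng(2))
        assert compute_auc(net.scores(codes), labels) >= 0.99

    def test_two_point_toy_loss_collapses(self):
        codes = np.array([[0.0, 1.0], [1.0, 0.0]] * 8)
        labels = np.array([1, 0] * 8)
        cfg = TrainConfig(train_epochs=2000, batch_size=16, classifier_hidden=(8,),
                          early_stopping=False, dropout_rate=0.0, weight_init_std=0.5)
        net = ClassifierNet.build(2, cfg, np.random.default_rng(0))
        train_classifier(codes, labels, net, cfg, np.random.default_rng(0))
        assert net.train_trace[-1] < 1e-2

    def test_fixed_seed_reproduces_loss_trace(self, rng):
        codes = rng.random((100, 6))
        labels = (rng.random(100) < 0.3).astype(int)
        cfg = TrainConfig(train_epochs=8)
        traces = []
        for _ in range(2):
            net = ClassifierNet.build(6, cfg, np.random.default_rng(4))
            train_classifier(codes, labels, net, cfg, np.random.default_rng(5))
            traces.append(net.train_trace)
        assert traces[0] == traces[1]

    def test_single_class_labels_warn_but_train(self, rng, caplog):
        codes = rng.random((50, 3))
        cfg = TrainConfig(train_epochs=2, early_stopping=False)
        net = ClassifierNet.build(3, cfg, rng)
        with caplog.at_level("WARNING"):
            train_classifier(codes, np.ones(50), net, cfg, rng)
        assert net.trained
        assert any("single-class" in r.message for r in caplog.records)


def _toy_dataset(rng, n_mirna=12, n_disease=6):
    mirnas = [f"m{i}" for i in range(n_mirna)]
    diseases = [f"d{j}" for j in range(n_disease)]
    amd = AssociationMatrix(
        mirnas, diseases, (rng.random((n_mirna, n_disease)) < 0.2).astype(int)
    )
    if amd.values.sum() == 0:
        amd.values[0, 0] = 1
    return assemble_pairs(_sim(mirnas, rng), _sim(diseases, rng), _sim(diseases, rng), amd)


class TestDeepMDA:
    # toy widths need a width-matched init scale (the default std is
    # calibrated for the hundreds-wide layers of the full-size model)
    CFG = dict(pretrain_epochs=3, train_epochs=5, code_dim=4, weight_init_std=0.5,
               mirna_hidden=(8,), disease_hidden=(8,), classifier_hidden=(8, 4))

    def test_end_to_end_determinism(self, rng):
        ds = _toy_dataset(rng)
        s = [DeepMDA(TrainConfig(seed=3, **self.CFG)).fit(ds).predict(ds) for _ in range(2)]
        assert np.array_equal(s[0], s[1])

    def test_scores_in_unit_interval_and_threshold_calls(self, rng):
        ds = _toy_dataset(rng)
        model = DeepMDA(TrainConfig(seed=0, **self.CFG)).fit(ds)
        scores = model.predict(ds)
        assert scores.min() >= 0.0 and scores.max() <= 1.0
        calls = model.predict_binary(ds)
        assert set(np.unique(calls)) <= {0, 1}
        assert np.array_equal(calls, (scores >= 0.5).astype(int))

    def test_prediction_permutation_equivariance(self, rng):
        ds = _toy_dataset(rng)
        model = DeepMDA(TrainConfig(seed=0, **self.CFG)).fit(ds)
        perm = rng.permutation(len(ds))
        np.testing.assert_allclose(
            model.predict(ds.subset(perm)), model.predict(ds)[perm], atol=1e-12
        )

    def test_untrained_model_refuses_to_predict(self, rng):
        with pytest.raises(RuntimeError, match="not trained"):
            DeepMDA(TrainConfig(**self.CFG)).predict(_toy_dataset(rng))

    def test_identity_encoder_uses_raw_features(self, rng):
        """The encoder-bypass ablation trains on raw concatenated rows."""
        ds = _toy_dataset(rng)
        model = DeepMDA(TrainConfig(seed=1, **self.CFG), encoder="identity").fit(ds)
        codes = model.encode_pairs(ds)
        assert codes.shape[1] == ds.mirna_features.shape[1] + ds.disease_features.shape[1]
        assert np.array_equal(codes, np.hstack([ds.mirna_features, ds.disease_features]))
        assert model.predict(ds).shape == (len(ds),)

    def test_fine_tuning_changes_encoder_weights(self, rng):
        ds = _toy_dataset(rng)
        frozen = DeepMDA(TrainConfig(seed=2, **self.CFG)).fit(ds)
        tuned = DeepMDA(
            TrainConfig(seed=2, fine_tune_encoders=True, fine_tune_epochs=2, **self.CFG)
        ).fit(ds)
        w_frozen = frozen.mirna_stack.encoder.layers[0].W
        w_tuned = tuned.mirna_stack.encoder.layers[0].W
        assert not np.array_equal(w_frozen, w_tuned)

    def test_save_load_round_trip(self, rng, tmp_path):
        ds = _toy_dataset(rng)
        model = DeepMDA(TrainConfig(seed=0, **self.CFG)).fit(ds)
        path = tmp_path / "model.npz"
        model.save(path)
        back = DeepMDA.load(path)
        np.testing.assert_allclose(back.predict(ds), model.predict(ds), atol=1e-15)
        assert back.config == model.config
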