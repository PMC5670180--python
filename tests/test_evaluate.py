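"""Metrics against brute-force oracles; CV protocols and their guards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepmda.evaluate import (
    FoldPlan,
    PipelineInputs,
    add_white_noise,
    build_similarities,
    compute_auc,
    compute_aupr,
    five_fold_cv,
    lodocv,
    robustness_experiment,
)
from deepmda.kernels import gip_kernel
from deepmda.model import TrainConfig
from deepmda.synthetic import SynthConfig, generate_world


def auc_pair_enumeration(scores, labels):
    """Oracle: P(random positive outranks random negative), ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_sweep(scores, labels):
    """Oracle: precision/recall at every distinct descending threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAUC:
    def test_perfect_and_tied_rankings(self):
        assert compute_auc(np.array([0.9, 0.1]), np.array([1, 0])) == 1.0
        assert compute_auc(np.array([0.5, 0.5, 0.5]), np.array([1, 0, 0])) == 0.5

    def test_interleaved_hand_value(self):
        # pairs: (.8 vs .6) win, (.8 vs .2) win, (.4 vs .6) loss, (.4 vs .2) win
        got = compute_auc(np.array([0.8, 0.6, 0.4, 0.2]), np.array([1, 0, 1, 0]))
        assert got == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(2, 12),
        seed=st.integers(0, 100_000),
        grid=st.integers(2, 6),
    )
    def test_matches_exhaustive_enumeration_with_ties(self, n, seed, grid):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, grid, n) / grid  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert compute_auc(scores, labels) == pytest.approx(
            auc_pair_enumeration(scores, labels), abs=1e-12
        )


class TestAUPR:
    def test_perfect_separation(self):
        assert compute_aupr(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_single_positive_ranked_last(self):
        n = 5
        scores = np.linspace(1.0, 0.2, n)
        labels = np.zeros(n, dtype=int)
        labels[-1] = 1
        assert compute_aupr(scores, labels) == pytest.approx(1 / n, abs=1e-12)

    def test_three_point_hand_sweep(self):
        scores = np.array([0.8, 0.6, 0.4])
        labels = np.array([1, 0, 1])
        # t=.8: P=1, R=1/2; t=.6: R unchanged; t=.4: P=2/3, R=1
        assert compute_aupr(scores, labels) == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-12)
        assert compute_aupr(scores, labels) == pytest.approx(
            aupr_threshold_sweep(scores, labels), abs=1e-12
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            compute_aupr(np.array([0.5, 0.2]), np.array([0, 0]))

    @settings(max_examples=200, deadline=None)
    @given(n=st.integers(2, 12), seed=st.integers(0, 100_000), grid=st.integers(2, 6))
    def test_matches_threshold_sweep(self, n, seed, grid):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, grid, n) / grid
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            labels[0] = 1
        assert compute_aupr(scores, labels) == pytest.approx(
            aupr_threshold_sweep(scores, labels), abs=1e-12
        )


class TestFoldPlan:
    def test_sizes_partition_and_determinism(self, tiny_world):
        amd = tiny_world.amd
        plan = FoldPlan.fivefold(amd, seed=4)
        sizes = [int((plan.pos_folds == f).sum()) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == int(amd.values.sum())
        # identical assignment on replay
        plan2 = FoldPlan.fivefold(amd, seed=4)
        assert np.array_equal(plan.pos_folds, plan2.pos_folds)
        assert np.array_equal(plan.neg_folds, plan2.neg_folds)

    def test_ten_positives_make_five_even_folds(self):
        from deepmda.types import AssociationMatrix

        values = np.zeros((5, 4), dtype=int)
        values.flat[:10] = 1
        amd = AssociationMatrix([f"m{i}" for i in range(5)], [f"d{j}" for j in range(4)],
                                values)
        plan = FoldPlan.fivefold(amd, seed=0)
        assert sorted((plan.pos_folds == f).sum() for f in range(5)) == [2] * 5

    def test_too_few_positives_is_protocol_error(self):
        from deepmda.types import AssociationMatrix

        amd = AssociationMatrix(["m1", "m2"], ["d1"], np.array([[1], [0]]))
        with pytest.raises(ValueError, match="5-fold"):
            FoldPlan.fivefold(amd, seed=0)


class TestFiveFoldCV:
    def test_partition_determinism_and_leakage_guard(self, tiny_inputs, fast_config):
        rep1 = five_fold_cv(tiny_inputs, fast_config, seed=5, return_details=True)
        rep2 = five_fold_cv(tiny_inputs, fast_config, seed=5, return_details=True)
        amd = tiny_inputs.amd

        # test folds partition the positives
        seen = set()
        for fold in rep1.folds:
            pos_pairs = {p for p, y in zip(fold.test_pairs, fold.labels) if y == 1}
            assert not (pos_pairs & seen)
            seen |= pos_pairs
        n_pos = int(amd.values.sum())
        assert len(seen) == n_pos

        # determinism: identical scores bit for bit
        for f1, f2 in zip(rep1.folds, rep2.folds):
            assert np.array_equal(f1.scores, f2.scores)

        # guard: test positives are absent from the fold's kernel inputs,
        # and the integrated matrices really derive from the masked matrix
        for fold in rep1.folds:
            masked = fold.details["masked_amd"]
            for (m, d), y in zip(fold.test_pairs, fold.labels):
                if y == 1:
                    assert masked.values[masked.row_index(m), masked.col_index(d)] == 0
            sm_expect, _, kd_expect = build_similarities(tiny_inputs, masked)
            np.testing.assert_array_equal(fold.details["sm"].values, sm_expect.values)
            np.testing.assert_array_equal(fold.details["kd"].values, kd_expect.values)

    def test_guard_off_keeps_full_matrix_kernels(self, tiny_inputs, fast_config):
        rep = five_fold_cv(tiny_inputs, fast_config, seed=5, leakage_guard=False,
                           return_details=True)
        sm_full, _, _ = build_similarities(tiny_inputs)
        for fold in rep.folds:
            np.testing.assert_array_equal(fold.details["sm"].values, sm_full.values)

    def test_aggregates_match_fold_dumps(self, tiny_inputs, fast_config):
        rep = five_fold_cv(tiny_inputs, fast_config, seed=6)
        recomputed = np.mean([compute_auc(f.scores, f.labels) for f in rep.folds])
        assert rep.mean_auc == pytest.approx(recomputed, abs=1e-12)

    def test_test_vs_all_unknown_mode(self, tiny_inputs, fast_config):
        rep = five_fold_cv(tiny_inputs, fast_config, seed=7, test_vs_all_unknown=True)
        n_neg = int((tiny_inputs.amd.values == 0).sum())
        for fold in rep.folds:
            assert (fold.labels == 0).sum() == n_neg


class TestLODOCV:
    def test_masking_and_skips(self, tiny_inputs, fast_config):
        rep = lodocv(tiny_inputs, fast_config, seed=3,
                     diseases=tiny_inputs.amd.col_ids[:6], return_details=True)
        amd = tiny_inputs.amd
        for fold in rep.folds:
            d = fold.fold
            j = amd.col_index(d)
            masked = fold.details["masked_amd"]
            # held-out column contributed nothing to similarity building
            assert masked.values[:, j].sum() == 0
            sm_expect, _, kd_expect = build_similarities(tiny_inputs, masked)
            np.testing.assert_array_equal(fold.details["sm"].values, sm_expect.values)
            np.testing.assert_array_equal(fold.details["kd"].values, kd_expect.values)
            # the test set is the whole column
            assert fold.n_test == len(amd.row_ids)
            assert fold.labels.sum() == amd.values[:, j].sum()
            # no training pair touches the held-out disease
            # (train pairs are everything except column j by construction)

    def test_column_masking_invariance(self, tiny_inputs):
        """Similarities inside an iteration ignore the held-out column's values."""
        amd = tiny_inputs.amd
        j = 0
        masked = amd.copy()
        masked.values[:, j] = 0
        sm1, sd1, kd1 = build_similarities(tiny_inputs, masked)
        # flip the true column entirely, re-mask: identical matrices
        scrambled = amd.copy()
        scrambled.values[:, j] = 1 - scrambled.values[:, j]
        scrambled.values[:, j] = 0
        sm2, sd2, kd2 = build_similarities(tiny_inputs, scrambled)
        np.testing.assert_array_equal(sm1.values, sm2.values)
        np.testing.assert_array_equal(sd1.values, sd2.values)
        np.testing.assert_array_equal(kd1.values, kd2.values)

    def test_diseases_without_positives_skipped(self, fast_config, tiny_inputs):
        amd = tiny_inputs.amd
        empty_cols = [d for j, d in enumerate(amd.col_ids) if amd.values[:, j].sum() == 0]
        some_pos = [d for j, d in enumerate(amd.col_ids) if amd.values[:, j].sum() > 0]
        targets = empty_cols[:1] + some_pos[:2]
        if not empty_cols:
            pytest.skip("fixture world has no empty disease column")
        rep = lodocv(tiny_inputs, fast_config, seed=0, diseases=targets)
        assert len(rep.folds) == len(targets) - 1
        assert any(empty_cols[0] in s for s in rep.skipped)


class TestWhiteNoise:
    def test_zero_scale_is_identity(self, rng):
        x = rng.random((20, 5))
        assert np.array_equal(add_white_noise(x, 0.0, seed=1), x)

    def test_seeded_reproducibility(self, rng):
        x = rng.random((20, 5))
        assert np.array_equal(add_white_noise(x, 0.3, seed=9), add_white_noise(x, 0.3, seed=9))

    def test_negative_scale_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            add_white_noise(rng.random((4, 2)), -0.1, seed=0)

    def test_noise_law_mean_and_scale(self, rng):
        n = 10_000
        x = rng.random((n, 3))
        noisy = add_white_noise(x, 0.5, seed=2)
        delta = noisy - x
        # zero mean within 4 standard errors per feature
        se = delta.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(delta.mean(axis=0)) < 4 * se)
        # realized sd close to sigma_scale * feature sd
        np.testing.assert_allclose(delta.std(axis=0), 0.5 * x.std(axis=0), rtol=0.05)


class TestRobustness:
    def test_zero_noise_reports_identical(self, tiny_inputs, fast_config):
        res = robustness_experiment(tiny_inputs, fast_config, sigma_scale=0.0, seed=2)
        clean, noisy = res["dnn"]["clean"], res["dnn"]["noisy"]
        for fc, fn in zip(clean.folds, noisy.folds):
            assert np.array_equal(fc.scores, fn.scores)
        assert res["dnn"]["auc_drop"] == 0.0
        assert len(res["dnn"]["per_fold_auc_drop"]) == 5

    def test_shallow_head_plug_in(self, tiny_inputs, fast_config):
        from sklearn.ensemble import AdaBoostClassifier

        heads = {"dnn": "dnn",
                 "ada": lambda s: AdaBoostClassifier(n_estimators=10, random_state=s)}
        res = robustness_experiment(tiny_inputs, fast_config, sigma_scale=0.3, seed=2,
                                    heads=heads)
        assert set(res) == {"dnn", "ada"}
        for r in res.values():
            assert np.isfinite(r["auc_drop"])
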