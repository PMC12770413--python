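"""Feature extraction, fusion arithmetic, attention and the classifier."""

import numpy as np
import pytest

from oncosurv import fuse
from oncosurv._layers import MLP
from oncosurv.fuse import (
    ClassifierTrainConfig,
    CrossAttentionParams,
    FusionConfig,
    ImageCNN,
    classify_subtype,
    cross_attention,
    extract_genomic_features,
    extract_image_features,
    fuse_features,
)

# Worked sum-fusion examples: per-patient CNN and MLP embeddings and their sums
FUSION_ROWS = [
    ([0.56, 0.44, 0.78], [0.61, 0.75, 0.69], [1.17, 1.19, 1.47]),
    ([0.63, 0.52, 0.74], [0.58, 0.68, 0.71], [1.21, 1.20, 1.45]),
    ([0.68, 0.55, 0.81], [0.66, 0.79, 0.73], [1.34, 1.34, 1.54]),
    ([0.52, 0.47, 0.69], [0.57, 0.71, 0.64], [1.09, 1.18, 1.33]),
    ([0.75, 0.61, 0.88], [0.72, 0.81, 0.77], [1.47, 1.42, 1.65]),
]


class TestImageFeatures:
    def test_zero_mask_yields_bias_determined_constant(self):
        cnn = ImageCNN(feature_dim=6, seed=0)
        img = np.random.default_rng(0).uniform(size=(16, 16))
        f_masked = extract_image_features(img, np.zeros_like(img), cnn)
        f_zero = extract_image_features(np.zeros_like(img), np.ones_like(img), cnn)
        assert np.allclose(f_masked, f_zero)

    def test_deterministic_and_mask_invariant_outside(self):
        cnn = ImageCNN(feature_dim=6, seed=1)
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(16, 16))
        mask = np.zeros((16, 16)); mask[4:10, 4:10] = 1
        other = img.copy()
        other[mask == 0] = rng.uniform(size=int((mask == 0).sum()))
        f1 = extract_image_features(img, mask, cnn)
        f2 = extract_image_features(img, mask, cnn)
        f3 = extract_image_features(other, mask, cnn)
        assert np.array_equal(f1, f2)
        assert np.allclose(f1, f3)


class TestGenomicFeatures:
    def test_sigmoid_output_range(self):
        mlp = MLP((5, 8, 4), output_activation="sigmoid", seed=0)
        f = extract_genomic_features(np.random.default_rng(2).normal(size=5), mlp)
        assert ((f > 0) & (f < 1)).all()

    def test_zero_weights_give_half(self):
        mlp = MLP((3, 4), output_activation="sigmoid", seed=0)
        mlp.weights[0].value[:] = 0.0
        assert np.allclose(extract_genomic_features([1.0, -2.0, 3.0], mlp), 0.5)

    def test_hand_evaluated_two_feature_toy(self):
        mlp = MLP((2, 2), output_activation="sigmoid", seed=0)
        mlp.weights[0].value[:] = [[0.5, -1.0], [0.25, 2.0]]
        mlp.biases[0].value[:] = [0.1, -0.2]
        g = np.array([2.0, -1.0])
        z = np.array([0.5 * 2 + 0.25 * -1 + 0.1, -1.0 * 2 + 2.0 * -1 - 0.2])
        assert np.allclose(extract_genomic_features(g, mlp), 1 / (1 + np.exp(-z)))

    def test_first_layer_permutation_equivariance(self):
        mlp = MLP((6, 5, 3), output_activation="sigmoid", seed=3)
        g = np.random.default_rng(3).normal(size=6)
        perm = np.random.default_rng(4).permutation(6)
        mlp_p = MLP((6, 5, 3), output_activation="sigmoid", seed=3)
        mlp_p.weights[0].value = mlp.weights[0].value[perm]
        assert np.allclose(
            extract_genomic_features(g, mlp), extract_genomic_features(g[perm], mlp_p)
        )


class TestCrossAttention:
    def test_single_key_position_gets_full_weight(self):
        p = CrossAttentionParams(8, n_heads=4, d_k=4, seed=0)
        rng = np.random.default_rng(0)
        _, w = cross_attention(rng.normal(size=8), rng.normal(size=(1, 8)), p)
        assert np.allclose(w, 1.0)

    def test_identical_keys_give_uniform_weights(self):
        p = CrossAttentionParams(8, n_heads=2, d_k=4, seed=1)
        rng = np.random.default_rng(1)
        key = rng.normal(size=8)
        _, w = cross_attention(rng.normal(size=8), np.tile(key, (5, 1)), p)
        assert np.allclose(w, 0.2)

    def test_rows_sum_to_one_and_shift_invariance(self):
        p = CrossAttentionParams(8, n_heads=4, d_k=2, seed=2)
        rng = np.random.default_rng(2)
        q, kv = rng.normal(size=8), rng.normal(size=(3, 8))
        _, w = cross_attention(q, kv, p)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_hand_computed_softmax_of_scaled_scores(self):
        p = CrossAttentionParams(2, n_heads=1, d_k=2, seed=0)
        p.wq.value[0] = np.eye(2)
        p.wk.value[0] = np.eye(2)
        q = np.array([1.0, 0.0])
        kv = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, w = cross_attention(q, kv, p)
        scores = kv @ q / np.sqrt(2)
        expect = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(w[0], expect, atol=1e-12)


class TestFusion:
    @pytest.mark.parametrize("f_img,f_gen,expected", FUSION_ROWS)
    def test_sum_mode_reproduces_worked_examples(self, f_img, f_gen, expected):
        fused = fuse_features(f_img, f_gen, config=FusionConfig(mode="sum"))
        assert np.allclose(fused, expected, atol=1e-12)

    def test_sum_mode_commutative(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=4), rng.normal(size=4)
        cfg = FusionConfig(mode="sum")
        assert np.allclose(fuse_features(a, b, config=cfg), fuse_features(b, a, config=cfg))

    def test_concat_preserves_components_in_order(self):
        fused = fuse_features([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], config=FusionConfig(mode="concat"))
        assert fused.tolist() == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]

    def test_attention_with_zero_weights_returns_image_features(self):
        f_img = np.array([0.3, 0.6, 0.9, 0.1])
        fused = fuse_features(
            f_img,
            [1.0, 1.0, 1.0, 1.0],
            config=FusionConfig(mode="attention", n_heads=2, feature_dim=4),
            attention_weights=[0.0],
        )
        assert np.array_equal(fused, f_img)

    def test_sum_mode_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fuse_features([1.0, 2.0], [1.0, 2.0, 3.0], config=FusionConfig(mode="sum"))


class TestSubtypeHead:
    def test_zero_head_gives_uniform_probabilities(self):
        probs = classify_subtype([1.0, -1.0], (np.zeros((2, 3)), np.zeros(3)))
        assert np.allclose(probs, 1 / 3)

    def test_crafted_logits_dominant_class(self):
        w = np.zeros((1, 3)); w[0, 0] = 10.0
        probs = classify_subtype([1.0], (w, np.zeros(3)))
        assert probs.argmax() == 0 and probs[0] > 0.99

    def test_matches_scalar_softmax(self):
        w = np.array([[1.0, -1.0, 0.5], [0.2, 0.3, -0.4]])
        b = np.array([0.1, 0.0, -0.1])
        f = np.array([0.7, -1.2])
        z = f @ w + b
        expect = np.exp(z - z.max()); expect /= expect.sum()
        probs = classify_subtype(f, (w, b))
        assert np.allclose(probs, expect, atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)


class TestClassifierTraining:
    def test_heldout_accuracy_on_strong_signal_cohort(self, trained_classifier):
        _, metrics = trained_classifier
        assert metrics["accuracy"] >= 0.85

    def test_confusion_matrix_rows_sum_to_class_counts(self, trained_classifier, clf_cohort):
        _, metrics = trained_classifier
        labels = np.array([s.subtype for s in clf_cohort])
        counts = np.bincount(labels[metrics["test_indices"]], minlength=3)
        assert metrics["confusion_matrix"].sum(axis=1).tolist() == counts.tolist()

    def test_shuffled_labels_fall_to_chance(self, clf_cohort):
        import copy

        shuffled = [copy.copy(s) for s in clf_cohort[:150]]
        perm = np.random.default_rng(0).permutation(len(shuffled))
        labels = [shuffled[i].subtype for i in perm]
        for s, lab in zip(shuffled, labels):
            s.subtype = lab
        _, metrics = fuse.train_classifier(
            shuffled,
            FusionConfig(mode="attention", seed=0),
            ClassifierTrainConfig(epochs=8, seed=0),
        )
        assert abs(metrics["accuracy"] - 1 / 3) <= 0.15

    def test_missing_class_in_training_split_rejected(self, clf_cohort):
        only_two = [s for s in clf_cohort if s.subtype != 2][:60]
        with pytest.raises(ValueError, match="2"):
            fuse.train_classifier(
                only_two, FusionConfig(seed=0), ClassifierTrainConfig(seed=0)
            )
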