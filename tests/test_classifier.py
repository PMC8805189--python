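"""Classifier configuration, augmentation, training mechanics, epoch
selection and patch-level evaluation."""

import numpy as np
import pytest

import vesiclepick as vp
from vesiclepick.classifier import TrainHistory, auc_from_scores

TINY = dict(conv_channels=(4, 4, 4, 4), fc_sizes=(16, 8, 2), batch_size=32)


@pytest.mark.parametrize(
    "side,sides,pooled,flat",
    [
        (40, [38, 36, 34, 32], 16, 128 * 16 * 16),
        (80, [78, 76, 74, 72], 36, 128 * 36 * 36),
    ],
)
def test_conv_shape_arithmetic(side, sides, pooled, flat):
    """Each 7x7 conv with padding 2 shrinks the side by 6; the final 2x2
    pool halves it."""
    config = vp.ClassifierConfig.published(side)
    assert config.conv_output_sides() == sides
    assert config.pooled_side == pooled
    assert config.flattened_size == flat


def test_learning_rate_defaults_by_input_side():
    assert vp.ClassifierConfig(input_side_px=40).effective_learning_rate == 0.0002
    assert vp.ClassifierConfig(input_side_px=80).effective_learning_rate == 0.0004
    assert vp.ClassifierConfig(input_side_px=40, learning_rate=0.01).effective_learning_rate == 0.01


def test_config_validation():
    with pytest.raises(ValueError):
        vp.ClassifierConfig(input_side_px=50)
    with pytest.raises(ValueError):
        vp.ClassifierConfig(fc_sizes=(64, 32, 3))


def test_forward_pass_measures_declared_flattened_size(rng):
    """Building runs a zero-patch forward through the conv stack and checks
    it against the closed-form size (desk-scale widths for speed)."""
    config = vp.ClassifierConfig.desk_scale(40, **TINY)
    model = vp.build_classifier(config)
    patch = np.zeros((1, 1, 40, 40), dtype=np.float32)
    logits = model.forward(patch)
    assert logits.shape == (1, 2)
    from vesiclepick import nn

    p = nn.softmax(logits)
    assert np.isfinite(logits).all()
    assert p.sum() == pytest.approx(1.0)


class TestAugmentation:
    def test_degenerate_spec_is_identity(self, rng):
        patch = rng.random((40, 40)).astype(np.float32)
        out = vp.augment_patch(patch, vp.AugmentationSpec.none(), rng)
        assert np.array_equal(out, patch)

    def test_fixed_seed_is_deterministic(self, rng):
        patch = rng.random((40, 40)).astype(np.float32)
        spec = vp.AugmentationSpec.first_default()
        a = vp.augment_patch(patch, spec, 42)
        b = vp.augment_patch(patch, spec, 42)
        assert np.array_equal(a, b)

    def test_noise_component_sd_matches_stated_sigma(self):
        """sigma=0.1 with p=1 on a constant 0.5 patch: the sample SD over
        10000 pixels is within 5% of 0.1 (clipping is negligible there)."""
        spec = vp.AugmentationSpec(rotation_amount_deg=0, jitter_amount=0,
                                   noise_components=((0.1, 1.0),))
        patch = np.full((100, 100), 0.5, dtype=np.float32)
        out = vp.augment_patch(patch, spec, 7)
        assert out.std() == pytest.approx(0.1, rel=0.05)

    def test_output_clipped_to_unit_interval(self, rng):
        spec = vp.AugmentationSpec(noise_components=((0.5, 1.0),))
        out = vp.augment_patch(rng.random((40, 40)).astype(np.float32), spec, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_noise_probability_rejected(self):
        with pytest.raises(ValueError):
            vp.AugmentationSpec(noise_components=((0.1, 1.5),))


class TestSelectBestEpoch:
    def _history(self, f1, loss):
        h = TrainHistory()
        h.f1 = list(f1)
        h.test_loss = list(loss)
        h.train_loss = [0.0] * len(f1)
        return h

    def test_short_history_falls_back_to_max_f1(self, caplog):
        h = self._history([0.5, 0.9, 0.8], [1.0, 0.5, 0.6])
        with caplog.at_level("WARNING"):
            assert vp.select_best_epoch(h) == 1
        assert "falling back" in caplog.text

    def test_epoch_followed_by_three_loss_rises_wins(self):
        h = self._history([0.5, 0.92, 0.90, 0.91, 0.89, 0.88],
                          [1.0, 0.40, 0.42, 0.45, 0.50, 0.55])
        assert vp.select_best_epoch(h) == 1

    def test_constant_history_ties_break_to_earliest(self):
        h = self._history([0.7] * 5, [0.3] * 5)
        assert vp.select_best_epoch(h) == 0

    def test_qualifying_epoch_preferred_over_higher_f1_without_rises(self):
        # epoch 4 has the best F1 but no three rises after it; epoch 0 qualifies
        h = self._history([0.8, 0.7, 0.6, 0.6, 0.95],
                          [0.5, 0.6, 0.7, 0.8, 0.2])
        assert vp.select_best_epoch(h) == 0

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            vp.select_best_epoch(TrainHistory())


class TestEvaluation:
    def test_perfect_separation_gives_unit_metrics(self):
        labels = np.array([1, 1, 0, 0])
        assert auc_from_scores(labels, np.array([0.9, 0.8, 0.1, 0.2])) == 1.0

    def test_constant_scores_give_chance_auc(self):
        labels = np.array([1, 0, 1, 0, 0])
        assert auc_from_scores(labels, np.full(5, 0.5)) == pytest.approx(0.5)

    def test_auc_equals_brute_force_concordance(self, rng):
        """Rank-statistic AUC equals the exhaustive pairwise concordance
        count over all positive-negative pairs."""
        labels = (rng.random(50) < 0.4).astype(int)
        scores = rng.random(50)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        expected = concordant / (len(pos) * len(neg))
        assert auc_from_scores(labels, scores) == pytest.approx(expected)

    def test_single_class_auc_is_nan(self):
        assert np.isnan(auc_from_scores(np.ones(5), np.random.rand(5)))


def _tiny_dataset(rng, n=120, side=40):
    """Separable toy patches: positives have a dark center block."""
    patches = rng.random((n, side, side)).astype(np.float32) * 0.2 + 0.6
    labels = (rng.random(n) < 0.5).astype(int)
    for i in np.flatnonzero(labels):
        patches[i, 14:26, 14:26] = 0.1
    return vp.PatchDataset(patches, labels, side)


class TestTraining:
    def test_single_class_training_set_rejected(self, rng):
        ds = _tiny_dataset(rng)
        single = ds.subset(ds.labels == 1)
        config = vp.ClassifierConfig.desk_scale(40, **TINY, max_epochs=1)
        model = vp.build_classifier(config)
        with pytest.raises(ValueError, match="both classes"):
            vp.train_classifier(model, single, ds, config)

    def test_loss_decreases_and_seeded_training_reproduces(self, rng):
        train, test = _tiny_dataset(rng, 160), _tiny_dataset(rng, 60)
        config = vp.ClassifierConfig.desk_scale(40, **TINY, max_epochs=3, seed=5)
        spec = vp.AugmentationSpec.none()

        model = vp.build_classifier(config)
        hist, _ = vp.train_classifier(model, train, test, config, spec,
                                      keep_snapshots=False)
        assert hist.train_loss[-1] < hist.train_loss[0]

        rerun = vp.build_classifier(config)
        hist2, _ = vp.train_classifier(rerun, train, test, config, spec,
                                       keep_snapshots=False)
        assert hist.train_loss == hist2.train_loss
        x = train.patches[:8]
        assert np.array_equal(vp.predict_proba(model, x), vp.predict_proba(rerun, x))

    def test_permuted_labels_destroy_generalization(self, rng):
        """Shuffled-label control: the same training budget that learns the
        real labels well cannot learn permuted ones."""
        train, test = _tiny_dataset(rng, 200), _tiny_dataset(rng, 80)
        config = vp.ClassifierConfig.desk_scale(40, **TINY, max_epochs=6, seed=2,
                                                learning_rate=0.001)
        spec = vp.AugmentationSpec.none()

        real = vp.build_classifier(config)
        hist_real, _ = vp.train_classifier(real, train, test, config, spec,
                                           keep_snapshots=False)

        f1_perm = []
        for seed in range(3):
            perm_rng = np.random.default_rng(seed)
            shuffled = vp.PatchDataset(
                train.patches, perm_rng.permutation(train.labels), train.side_px
            )
            model = vp.build_classifier(config.with_(seed=seed))
            hist, _ = vp.train_classifier(model, shuffled, test, config, spec,
                                          keep_snapshots=False)
            f1_perm.append(hist.f1[-1])
        assert hist_real.f1[-1] > 0.9
        assert np.mean(f1_perm) < hist_real.f1[-1] - 0.2
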