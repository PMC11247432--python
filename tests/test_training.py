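"""Training orchestration: GAN loop, augmentation policy, classifier, pipeline."""

import numpy as np
import pytest

from eeggan import (
    CropSpec,
    TrainConfig,
    augment_dataset,
    generate_session,
    load_checkpoint,
    normalize,
    predict_proba,
    run_pipeline,
    save_checkpoint,
    session_spec_2b,
    train_classifier,
    train_gan,
)


class TestTrainGan:
    def test_smoke_writes_checkpoints(self, tiny_2b_session, tmp_path):
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(gan_epochs=2, batch_size=16, seed=0)
        G, D, state = train_gan(epochs, tcfg=tcfg, run_dir=tmp_path)
        assert (tmp_path / "generator.npz").exists()
        assert (tmp_path / "discriminator.npz").exists()
        assert (tmp_path / "gan_losses.csv").exists()
        assert state.gan_epochs_done == 2
        assert len(state.gan_losses) > 0

    def test_deterministic_given_seed(self, tiny_2b_session):
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(gan_epochs=1, batch_size=16, seed=11)
        _, _, a = train_gan(epochs, tcfg=tcfg)
        _, _, b = train_gan(epochs, tcfg=tcfg)
        assert np.array_equal(a.gan_loss_array(), b.gan_loss_array())

    def test_discriminator_loss_decreases(self):
        """Mean L_D over the last epoch drops below the first (majority of seeds)."""
        wins = 0
        for seed in range(3):
            spec = session_spec_2b(trials_per_class=8, snr=0.5, seed=100 + seed)
            epochs, _ = normalize(generate_session(spec))
            tcfg = TrainConfig(gan_epochs=3, batch_size=16, seed=seed)
            _, _, state = train_gan(epochs, tcfg=tcfg)
            arr = state.gan_loss_array()[:, 3]
            steps = len(arr) // 3
            if arr[-steps:].mean() < arr[:steps].mean():
                wins += 1
        assert wins >= 2

    def test_missing_class_rejected(self, tiny_2b_session):
        _, epochs, _ = tiny_2b_session
        only_zero = epochs.subset(np.where(epochs.labels == 0)[0])
        with pytest.raises(ValueError, match="every class"):
            train_gan(only_zero, tcfg=TrainConfig(gan_epochs=1))


class TestAugmentDataset:
    def test_half_ratio_balanced_split(self, trained_tiny_gan, tiny_2b_session):
        """Ratio 0.5 on 16 trials adds 8 generated trials, 4 per class."""
        G, _, _, tcfg = trained_tiny_gan
        _, epochs, _ = tiny_2b_session
        out = augment_dataset(G, epochs, tcfg)
        assert out.n_trials == epochs.n_trials + 8
        gen = out.subset(np.where(out.generated_mask)[0])
        assert np.array_equal(gen.class_counts(), [4, 4])

    def test_generated_trials_in_tanh_range(self, trained_tiny_gan, tiny_2b_session):
        G, _, _, tcfg = trained_tiny_gan
        _, epochs, _ = tiny_2b_session
        out = augment_dataset(G, epochs, tcfg)
        gen_data = out.data[out.generated_mask]
        assert gen_data.shape[1:] == (3, 1125)
        assert (np.abs(gen_data) < 1.0).all()

    def test_zero_ratio_is_identity(self, trained_tiny_gan, tiny_2b_session):
        G, _, _, _ = trained_tiny_gan
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(augmentation_ratio=0.0)
        out = augment_dataset(G, epochs, tcfg)
        assert out.n_trials == epochs.n_trials

    def test_remainder_distributed_deterministically(self, trained_tiny_gan,
                                                     tiny_2b_session):
        G, _, _, _ = trained_tiny_gan
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(augmentation_ratio=0.3, seed=5)  # 5 trials over 2 classes
        out = augment_dataset(G, epochs, tcfg)
        gen = out.subset(np.where(out.generated_mask)[0])
        assert np.array_equal(gen.class_counts(), [3, 2])


class TestTrainClassifier:
    def test_from_discriminator_body(self, trained_tiny_gan, tiny_2b_session):
        _, D, _, tcfg = trained_tiny_gan
        _, epochs, _ = tiny_2b_session
        clf, state = train_classifier(epochs, D, CropSpec(), tcfg)
        assert clf.cfg.head == "classifier"
        assert state.clf_epochs_done == tcfg.clf_epochs
        proba = predict_proba(clf, epochs, CropSpec())
        assert proba.shape == (epochs.n_trials, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_no_cropping_uses_full_trials(self, tiny_2b_session):
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(clf_epochs=1, use_cropping=False, seed=0)
        clf, _ = train_classifier(epochs, None, None, tcfg)
        assert clf.cfg.input_time == epochs.n_times  # one full-length "crop"

    def test_missing_class_rejected(self, tiny_2b_session):
        _, epochs, _ = tiny_2b_session
        only_zero = epochs.subset(np.where(epochs.labels == 0)[0])
        with pytest.raises(ValueError, match="every class"):
            train_classifier(only_zero, None, None, TrainConfig(clf_epochs=1))

    def test_checkpoint_round_trip_predictions(self, tiny_2b_session, tmp_path):
        _, epochs, _ = tiny_2b_session
        tcfg = TrainConfig(clf_epochs=1, seed=4)
        clf, _ = train_classifier(epochs, None, CropSpec(), tcfg)
        save_checkpoint(tmp_path / "clf.npz", clf)
        clf2 = load_checkpoint(tmp_path / "clf.npz")
        a = predict_proba(clf, epochs, CropSpec())
        b = predict_proba(clf2, epochs, CropSpec())
        assert np.allclose(a, b, atol=1e-6)


@pytest.fixture(scope="module")
def sessions():
    train = generate_session(session_spec_2b(trials_per_class=8, snr=0.5, seed=21))
    test = generate_session(session_spec_2b(trials_per_class=8, snr=0.5, seed=22))
    return train, test


class TestRunPipeline:
    def test_end_to_end_with_all_components(self, sessions):
        train, test = sessions
        tcfg = TrainConfig(gan_epochs=1, clf_epochs=1, batch_size=16, seed=0)
        out = run_pipeline(train, test, tcfg)
        assert 0.0 <= out["accuracy"] <= 1.0
        assert out["generator"] is not None
        assert out["probabilities"].shape == (test.n_trials, 2)

    def test_all_ablations_off_reduces_to_plain_training(self, sessions):
        train, test = sessions
        tcfg = TrainConfig(clf_epochs=1, batch_size=16, seed=0,
                           use_cgan=False, use_cropping=False, use_se=False)
        out = run_pipeline(train, test, tcfg)
        assert out["generator"] is None  # no GAN stage ran
        assert out["classifier"].se is None
        assert out["classifier"].cfg.input_time == test.n_times
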