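"""Model structure: printed dimensions, conditioning, SE gating, head swap."""

import numpy as np
import pytest

from eeggan import nn
from eeggan.architecture import (
    DiscriminatorConfig,
    GeneratorConfig,
    SEBlock,
    build_discriminator,
    build_generator,
    condition_input,
    decode_label,
    encode_label,
    load_checkpoint,
    sample_latent,
    save_checkpoint,
    se_recalibrate,
    to_classifier,
)


class TestGeneratorStructure:
    def test_transposed_conv_length_chain(self):
        """Stride-1 64-tap transposed convolutions: 936 -> 999 -> 1062 -> 1125."""
        cfg = GeneratorConfig()
        assert cfg.intermediate_lengths() == (999, 1062, 1125)
        # closed form: out = (in - 1) * stride + kernel
        assert (936 - 1) * 1 + 64 == 999

    def test_forward_shape_and_range(self, rng):
        G = build_generator(GeneratorConfig(out_channels=22, n_c=4), seed=0)
        x = nn.Tensor(rng.normal(size=(5, 101)))
        y = G(x)
        assert y.shape == (5, 22, 1125)
        assert (np.abs(y.data) < 1.0).all()

    def test_eval_mode_deterministic(self, rng):
        G = build_generator(GeneratorConfig(out_channels=3, n_c=2), seed=0).eval()
        x = nn.Tensor(rng.normal(size=(2, 101)))
        assert np.array_equal(G(x).data, G(x).data)

    def test_inconsistent_config_rejected_at_build(self):
        with pytest.raises(ValueError, match="transposed-convolution stack"):
            build_generator(GeneratorConfig(out_length=1000))

    def test_trace_matches_forward(self, rng):
        G = build_generator(GeneratorConfig(out_channels=7, n_c=4), seed=1)
        trace = dict(G.trace_shapes(n=3))
        y = G(nn.Tensor(rng.normal(size=(3, 101))))
        assert y.shape == trace["output"] == (3, 7, 1125)


class TestLatentSampling:
    def test_reproducible(self):
        a = sample_latent(10, (0.0, 1.0), 4, seed=5)
        b = sample_latent(10, (0.0, 1.0), 4, seed=5)
        assert np.array_equal(a.z, b.z) and np.array_equal(a.labels, b.labels)

    def test_mean_within_clt_bound(self):
        batch = sample_latent(2000, (0.0, 1.0), 4, seed=0)
        n_total = batch.z.size
        assert abs(batch.z.mean()) < 3.0 / np.sqrt(n_total)

    def test_stats_estimated_from_data(self, rng):
        data = rng.normal(loc=2.0, scale=3.0, size=(50, 4, 100))
        batch = sample_latent(500, data, 2, seed=1)
        assert abs(batch.mu - 2.0) < 0.1
        assert abs(batch.sigma - 3.0) < 0.1

    def test_labels_uniform_within_binomial_tolerance(self):
        batch = sample_latent(4000, (0.0, 1.0), 4, seed=2)
        freqs = np.bincount(batch.labels, minlength=4) / 4000
        # 4 sigma binomial tolerance around 0.25
        assert (np.abs(freqs - 0.25) < 4 * np.sqrt(0.25 * 0.75 / 4000)).all()


class TestDiscriminatorStructure:
    def test_flatten_width_full_trial(self, rng):
        """With F2=16 and T=1125 the flatten stage is F2 * ((T+1)//32) wide."""
        cfg = DiscriminatorConfig(in_channels=22, input_time=1126)
        D = build_discriminator(cfg, seed=0)
        _, feats = D(nn.Tensor(rng.normal(size=(2, 22, 1126))), return_features=True)
        assert feats.shape == (2, 16 * (1126 // 32)) == (2, 560)

    def test_pooled_lengths_cropped_input(self):
        cfg = DiscriminatorConfig(in_channels=22, input_time=501)
        assert 501 // 4 == 125 and 125 // 8 == 15
        assert cfg.flatten_size == 16 * (501 // 32) == 16 * 15

    def test_real_fake_scores_strictly_inside_unit_interval(self, rng):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=501),
                                seed=0)
        s = D(nn.Tensor(rng.normal(size=(8, 3, 501))))
        assert ((s.data > 0) & (s.data < 1)).all()

    def test_wrong_input_length_rejected(self, rng):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=501))
        with pytest.raises(ValueError, match="input time length"):
            D(nn.Tensor(rng.normal(size=(2, 3, 500))))

    def test_parameter_count_varies_only_in_head(self):
        """The convolutional body is time-length agnostic."""
        def split_counts(t):
            D = build_discriminator(
                DiscriminatorConfig(in_channels=5, input_time=t), seed=0
            )
            body = sum(p.data.size for n, p in D.named_parameters()
                       if not n.startswith("head."))
            head = sum(p.data.size for n, p in D.named_parameters()
                       if n.startswith("head."))
            return body, head

        (body_a, head_a), (body_b, head_b) = split_counts(501), split_counts(1126)
        assert body_a == body_b
        assert head_a != head_b

    def test_trace_matches_table_rows(self):
        cfg = DiscriminatorConfig(in_channels=22, input_time=1126)
        trace = dict(build_discriminator(cfg).trace_shapes(n=1))
        assert trace["conv2d"] == (1, 8, 22, 1126)
        assert trace["depthwise"] == (1, 16, 1, 1126)
        assert trace["avgpool1"] == (1, 16, 1, 281)
        assert trace["avgpool2"] == (1, 16, 1, 35)
        assert trace["flatten"] == (1, 560)


class TestConditioning:
    def test_appends_one_column(self, rng):
        x = rng.normal(size=(22, 1125))
        assert condition_input(x, 2, 4).shape == (22, 1126)

    def test_labels_differ_only_in_last_column(self, rng):
        x = rng.normal(size=(5, 1125))
        a = condition_input(x, 0, 4)
        b = condition_input(x, 3, 4)
        assert np.array_equal(a[:, :-1], b[:, :-1])
        assert not np.array_equal(a[:, -1], b[:, -1])

    @pytest.mark.parametrize("n_c", [2, 4, 9])
    def test_label_round_trip(self, n_c, rng):
        labels = np.arange(n_c)
        decoded = decode_label(encode_label(labels, n_c), n_c)
        assert np.array_equal(decoded, labels)

    def test_out_of_range_label_rejected(self, rng):
        with pytest.raises(ValueError, match="labels must lie"):
            condition_input(rng.normal(size=(3, 10)), 4, 4)


class TestSEBlock:
    def test_zero_features_stay_zero(self):
        out = se_recalibrate(np.zeros((2, 16, 1, 30)), reduction=8)
        assert np.allclose(out, 0.0)

    def test_forced_half_gate_halves_one_map(self, rng):
        block = SEBlock(4, reduction=2, rng=np.random.default_rng(0))
        # zero the excitation weights, then pin per-map biases: map 0 gets
        # sigmoid(0) = 0.5, the rest saturate to ~1
        block.fc1.weight.data[:] = 0.0
        block.fc1.bias.data[:] = 0.0
        block.fc2.weight.data[:] = 0.0
        block.fc2.bias.data[:] = np.array([0.0, 30.0, 30.0, 30.0])
        x = rng.normal(size=(3, 4, 20))
        out = block(nn.Tensor(x)).data
        assert np.allclose(out[:, 0], 0.5 * x[:, 0], atol=1e-6)
        assert np.allclose(out[:, 1:], x[:, 1:], atol=1e-6)

    def test_gate_constant_across_positions(self, rng):
        x = rng.normal(size=(2, 8, 40)) + 3.0
        out = se_recalibrate(x, reduction=4, seed=3)
        ratio = out / x
        assert np.allclose(ratio.std(axis=-1), 0.0, atol=1e-7)
        assert ((ratio > 0) & (ratio < 1)).all()


class TestHeadSwap:
    @pytest.mark.parametrize("n_c", [2, 4])
    def test_classifier_output_width(self, n_c, rng):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=1126),
                                seed=0)
        clf = to_classifier(D, n_c, input_time=500)
        out = clf(nn.Tensor(rng.normal(size=(6, 3, 500))))
        assert out.shape == (6, n_c)

    def test_body_parameters_identical_before_training(self):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=501),
                                seed=0)
        clf = to_classifier(D, 4)
        d_params = dict(D.named_parameters())
        for name, p in clf.named_parameters():
            if not name.startswith("head."):
                assert p is d_params[name]  # shared by reference

    def test_copy_mode_detaches_body(self):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=501),
                                seed=0)
        clf = to_classifier(D, 2, share_body=False)
        clf.w_temporal.data += 1.0
        assert not np.allclose(clf.w_temporal.data, D.w_temporal.data)


class TestCheckpoints:
    def test_round_trip_identical_predictions(self, tmp_path, rng):
        D = build_discriminator(DiscriminatorConfig(in_channels=3, input_time=501),
                                seed=0).eval()
        x = nn.Tensor(rng.normal(size=(4, 3, 501)))
        save_checkpoint(tmp_path / "d.npz", D)
        D2 = load_checkpoint(tmp_path / "d.npz")
        assert np.allclose(D(x).data, D2(x).data, atol=1e-6)

    def test_generator_round_trip(self, tmp_path, rng):
        G = build_generator(GeneratorConfig(out_channels=3, n_c=2), seed=0).eval()
        x = nn.Tensor(rng.normal(size=(2, 101)))
        save_checkpoint(tmp_path / "g.npz", G)
        G2 = load_checkpoint(tmp_path / "g.npz")
        assert np.allclose(G(x).data, G2(x).data, atol=1e-6)
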