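"""Autoencoder architecture fidelity, gradient correctness, training
contracts and PSNR."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio as sk_psnr

from ictalnet._nn import conv2d, conv2d_backward, conv2d_transpose, conv2d_transpose_backward
from ictalnet.cae import CAEArchitecture, ConvAutoencoder, parameter_report, psnr

# reference per-layer trainable parameter counts of the canonical model
ENCODER_PARAMS = [160, 4640, 18496, 73856, 294015]
DECODER_PARAMS = [293888, 73792, 18464, 4624, 145]


class TestCanonicalArchitecture:
    def test_encoder_layer_parameter_counts(self):
        report = parameter_report(CAEArchitecture())
        assert [r["params"] for r in report["encoder"]] == ENCODER_PARAMS
        assert report["encoder_total"] == 391167

    def test_decoder_layer_parameter_counts(self):
        report = parameter_report(CAEArchitecture())
        assert [r["params"] for r in report["decoder"]] == DECODER_PARAMS
        assert report["decoder_total"] == 390913

    def test_output_shape_chain(self):
        report = parameter_report(CAEArchitecture())
        enc_sizes = [r["output_shape"][0] for r in report["encoder"]]
        dec_sizes = [r["output_shape"][0] for r in report["decoder"]]
        assert enc_sizes == [128, 64, 32, 16, 8]
        assert dec_sizes == [16, 32, 64, 128, 256]
        assert report["encoder"][-1]["output_shape"] == (8, 8, 255)
        assert report["decoder"][-1]["output_shape"] == (256, 256, 1)

    def test_latent_dimension(self):
        arch = CAEArchitecture()
        assert arch.latent_shape == (8, 8, 255)
        assert arch.latent_dim == 16320

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            CAEArchitecture(image_size=100)


def _num_grad(f, a, eps=1e-6):
    g = np.zeros_like(a)
    it = np.nditer(a, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        a[i] += eps
        fp = f()
        a[i] -= 2 * eps
        fm = f()
        a[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestConvGradients:
    def test_conv2d_gradients_match_finite_differences(self, rng):
        x = rng.standard_normal((2, 6, 6, 2))
        w = rng.standard_normal((3, 3, 2, 3)) * 0.2
        b = rng.standard_normal(3) * 0.1
        dy = rng.standard_normal(conv2d(x, w, b).shape)
        loss = lambda: float((conv2d(x, w, b) * dy).sum())
        dx, dw, db = conv2d_backward(dy, x, w)
        assert np.abs(_num_grad(loss, x) - dx).max() < 1e-7
        assert np.abs(_num_grad(loss, w) - dw).max() < 1e-7
        assert np.abs(_num_grad(loss, b) - db).max() < 1e-7

    def test_transpose_gradients_match_finite_differences(self, rng):
        x = rng.standard_normal((2, 3, 3, 4))
        w = rng.standard_normal((3, 3, 2, 4)) * 0.2
        b = rng.standard_normal(2) * 0.1
        dy = rng.standard_normal(conv2d_transpose(x, w, b).shape)
        loss = lambda: float((conv2d_transpose(x, w, b) * dy).sum())
        dx, dw, db = conv2d_transpose_backward(dy, x, w)
        assert np.abs(_num_grad(loss, x) - dx).max() < 1e-7
        assert np.abs(_num_grad(loss, w) - dw).max() < 1e-7
        assert np.abs(_num_grad(loss, b) - db).max() < 1e-7

    def test_transpose_is_exact_adjoint_of_conv(self, rng):
        x = rng.standard_normal((1, 8, 8, 3))
        u = rng.standard_normal((1, 4, 4, 5))
        w = rng.standard_normal((3, 3, 3, 5))
        lhs = float((conv2d(x, w, np.zeros(5)) * u).sum())
        rhs = float((x * conv2d_transpose(u, w, np.zeros(3))).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


@pytest.fixture(scope="module")
def tiny_images():
    rng = np.random.default_rng(3)
    # smooth blobs, not pure noise, so compression has structure to learn
    x = rng.uniform(0, 1, (32, 8, 8))
    from scipy.ndimage import gaussian_filter

    x = np.stack([gaussian_filter(im, 1.5) for im in x])
    x -= x.min()
    x /= x.max()
    return np.kron(x, np.ones((1, 4, 4)))  # 32 x 32 images


class TestEncodingDecoding:
    def test_code_length_matches_bottleneck(self, tiny_images):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), seed=0).initialize()
        codes = cae.encode(tiny_images)
        assert codes.shape == (32, 8 * 8 * 8)

    def test_encode_deterministic_for_fixed_weights(self, tiny_images):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), seed=0).initialize()
        np.testing.assert_array_equal(cae.encode(tiny_images), cae.encode(tiny_images))

    def test_zero_image_gives_zero_code_with_relu_and_zero_bias(self):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), seed=0).initialize()
        codes = cae.encode(np.zeros((1, 32, 32)))
        np.testing.assert_array_equal(codes, 0)

    def test_decode_output_in_unit_interval(self, tiny_images):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), seed=0).initialize()
        rec = cae.decode(cae.encode(tiny_images))
        assert rec.shape == (32, 32, 32, 1)
        assert rec.min() >= 0.0 and rec.max() <= 1.0

    def test_wrong_shapes_rejected(self, tiny_images):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), seed=0).initialize()
        with pytest.raises(ValueError):
            cae.encode(np.zeros((1, 16, 16)))
        with pytest.raises(ValueError):
            cae.decode(np.zeros((1, 7)))

    def test_untrained_model_rejected(self, tiny_images):
        with pytest.raises(ValueError, match="neither trained nor initialized"):
            ConvAutoencoder(image_size=32, encoder_filters=(4, 8)).encode(tiny_images)


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, tiny_images):
        kw = dict(image_size=32, encoder_filters=(4, 8), epochs=5, seed=3,
                  learning_rate=3e-3)
        a = ConvAutoencoder(**kw).fit(tiny_images)
        b = ConvAutoencoder(**kw).fit(tiny_images)
        assert len(a.loss_history_) == 5
        assert a.loss_history_[-1] < a.loss_history_[0]
        assert a.loss_history_ == b.loss_history_

    def test_zero_epochs_rejected(self, tiny_images):
        with pytest.raises(ValueError, match="epochs"):
            ConvAutoencoder(image_size=32, encoder_filters=(4, 8), epochs=0).fit(tiny_images)

    def test_empty_image_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ConvAutoencoder(image_size=32, encoder_filters=(4, 8)).fit(np.zeros((0, 32, 32)))

    def test_transform_equals_encode(self, tiny_images):
        cae = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), epochs=2, seed=1)
        cae.fit(tiny_images)
        np.testing.assert_array_equal(cae.transform(tiny_images), cae.encode(tiny_images))


class TestPSNR:
    def test_identical_images_hit_the_cap(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert psnr(x, x) == 100.0

    def test_half_gray_vs_black_is_6dB(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 0.5)
        assert psnr(x, y) == pytest.approx(10 * np.log10(4), rel=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.uniform(0, 1, (2, 12, 12))
        assert psnr(a, b) == psnr(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_agrees_with_skimage_reference(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert psnr(a, b) == pytest.approx(sk_psnr(a, b, data_range=1.0), rel=1e-10)


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_codes(self, tiny_images, tmp_path):
        path = tmp_path / "cae.npz"
        a = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), epochs=2, seed=1)
        a.fit(tiny_images)
        a.save_weights(path)
        b = ConvAutoencoder(image_size=32, encoder_filters=(4, 8), epochs=2, seed=1)
        b.load_weights(path)
        np.testing.assert_array_equal(a.encode(tiny_images), b.encode(tiny_images))
        assert b.loss_history_ == a.loss_history_

    def test_load_into_mismatched_architecture_rejected(self, tiny_images, tmp_path):
        path = tmp_path / "cae.npz"
        ConvAutoencoder(image_size=32, encoder_filters=(4, 8), epochs=1).fit(tiny_images)\
            .save_weights(path)
        with pytest.raises(ValueError, match="does not match"):
            ConvAutoencoder(image_size=32, encoder_filters=(8, 16)).load_weights(path)
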