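"""Autoencoder construction, cost function, training, and determinism."""

import numpy as np
import pytest

from caemgbdt.cae import (
    CAEMFeatureExtractor,
    CAEMNetwork,
    DivergenceError,
    build_cae,
    cae_loss,
    encode,
    train_cae,
)
from caemgbdt.attention import CBAM1D
from caemgbdt.shapes import ArchitectureSpec, BRCA_WIDE, ConvBlock, NARROW, shape_trace

SMALL = ArchitectureSpec(dense_units=(32,), conv_blocks=(ConvBlock(4, 3, 2, 4),))


class TestCaeLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 7))
        assert cae_loss(x, x) == 0.0

    def test_half_sse_single_sample(self):
        assert cae_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])) == pytest.approx(0.5)

    def test_l2_term_is_additive(self):
        got = cae_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]]),
                       weight_norm_sq=4.0, lam=0.001)
        assert got == pytest.approx(0.504)

    def test_equals_half_mse_brute_force(self):
        rng = np.random.default_rng(5)
        x, xh = rng.normal(size=(6, 11)), rng.normal(size=(6, 11))
        brute = sum(
            sum((x[i, j] - xh[i, j]) ** 2 for j in range(11)) for i in range(6)
        ) / (2 * 6)
        assert abs(cae_loss(x, xh) - brute) < 1e-9

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cae_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestBuild:
    def test_encode_decode_shapes_match_trace(self):
        net = build_cae(NARROW, 534, seed=0)
        X = np.random.default_rng(0).normal(size=(5, 534))
        Z, Z2, R = net.forward(X)
        assert Z.shape == (5, 16, 4)
        assert R.shape == (5, 534)

    def test_single_sample_batch(self):
        net = build_cae(SMALL, 100, seed=0)
        assert net.encode(np.zeros((1, 100))).shape[0] == 1

    def test_same_seed_identical_parameters(self):
        a = build_cae(SMALL, 64, seed=3)
        b = build_cae(SMALL, 64, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_geometry_error_propagates(self):
        bad = ArchitectureSpec(dense_units=(8,), conv_blocks=(ConvBlock(4, 3, 2, 16),))
        with pytest.raises(Exception):
            build_cae(bad, 64, seed=0)

    def test_wrong_width_rejected(self):
        net = build_cae(SMALL, 100, seed=0)
        with pytest.raises(ValueError, match="expected"):
            net.encode(np.zeros((2, 99)))

    def test_built_model_shapes_equal_symbolic_trace(self):
        """Every layer output of the realized network matches shape_trace."""
        for spec, dim in [(BRCA_WIDE, 17814), (NARROW, 354), (NARROW, 12042)]:
            net = build_cae(spec, dim, seed=0, dtype=np.float32)
            trace = dict(shape_trace(spec, dim))
            x = np.zeros((2, dim), dtype=np.float32)
            enc = net.encoders[0]
            probes = iter([k for k in trace if k.startswith("enc_")])
            h = x
            for layer in enc.layers:
                h = layer.forward(h)
                if h.ndim == 2 and layer.__class__.__name__ == "Dense":
                    assert h.shape[1:] == trace[next(probes)]
                elif layer.__class__.__name__ in ("Conv1D", "MaxPool1D"):
                    assert h.shape[1:] == trace[next(probes)]
            assert h.shape[1:] == trace["latent"]
            out = net.decoders[0].forward(h)
            assert out.shape[1:] == (dim,)


class TestTraining:
    def _low_rank_data(self, n=48, d=120, rank=3, seed=0):
        rng = np.random.default_rng(seed)
        U = rng.normal(size=(n, rank))
        V = rng.normal(size=(rank, d))
        return U @ V + 0.05 * rng.normal(size=(n, d))

    def test_loss_descends_on_low_rank_data(self):
        X = self._low_rank_data()
        net = build_cae(SMALL, 120, seed=1)
        log = train_cae(net, X, epochs=30, lam=1e-4)
        assert len(log) == 30
        assert log[-1] < log[0]

    def test_beats_mean_predictor(self):
        X = self._low_rank_data()
        net = build_cae(SMALL, 120, seed=1)
        train_cae(net, X, epochs=60, lam=0.0)
        _, _, R = net.forward(X)
        mse = np.mean((X - R) ** 2)
        assert mse < X.var()

    def test_zero_epochs_is_noop(self):
        net = build_cae(SMALL, 64, seed=2)
        before = [p.value.copy() for p in net.params()]
        log = train_cae(net, np.random.default_rng(0).normal(size=(8, 64)), epochs=0)
        assert log == []
        for p, b in zip(net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_wrong_width_raises(self):
        net = build_cae(SMALL, 64, seed=2)
        with pytest.raises(ValueError):
            train_cae(net, np.zeros((4, 63)), epochs=1)

    def test_training_log_bitwise_deterministic(self):
        X = self._low_rank_data(n=20, d=64)
        logs = []
        for _ in range(2):
            net = build_cae(SMALL, 64, seed=9)
            logs.append(train_cae(net, X, epochs=5, lam=1e-4))
        assert logs[0] == logs[1]

    def test_divergence_reported_with_epoch(self):
        net = build_cae(SMALL, 64, seed=2)
        net.params()[0].value[0, 0] = np.nan  # poison one weight
        X = np.random.default_rng(1).normal(size=(8, 64))
        with pytest.raises(DivergenceError) as err:
            train_cae(net, X, epochs=3, lam=0.0)
        assert err.value.epoch == 0


class TestJointMultiOmics:
    def test_latents_concatenate_along_positions(self):
        cbam = CBAM1D(4, rng=np.random.default_rng(0))
        net = CAEMNetwork([SMALL, SMALL, SMALL], [100, 40, 120],
                          attention=cbam, seed=0)
        X = np.random.default_rng(2).normal(size=(6, 260))
        Z, Z2, R = net.forward(X)
        # SMALL: dense 32 -> conv/2 -> 16 -> pool/4 -> 4 positions per block
        assert Z.shape == (6, 12, 4)
        assert Z2.shape == Z.shape
        assert R.shape == (6, 260)

    def test_mismatched_channels_rejected(self):
        other = ArchitectureSpec(dense_units=(32,), conv_blocks=(ConvBlock(8, 3, 2, 4),))
        with pytest.raises(ValueError, match="channel"):
            CAEMNetwork([SMALL, other], [64, 64], seed=0)


class TestExtractorEstimator:
    def test_fit_transform_layout(self):
        X = np.random.default_rng(0).normal(size=(12, 90))
        ext = CAEMFeatureExtractor(block_dims=[60, 30], epochs=2, random_state=0)
        M = ext.fit_transform(X)
        latent_width = ext.latent_shape_[0] * ext.latent_shape_[1]
        assert M.shape == (12, latent_width + 90)
        ext2 = CAEMFeatureExtractor(block_dims=[60, 30], epochs=2,
                                    latent_only=True, random_state=0)
        assert ext2.fit_transform(X).shape == (12, latent_width)

    def test_block_dims_must_cover_matrix(self):
        with pytest.raises(ValueError, match="block_dims"):
            CAEMFeatureExtractor(block_dims=[10, 10]).fit(np.zeros((4, 30)))

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        ext = CAEMFeatureExtractor(epochs=3, lam=0.01)
        cloned = clone(ext)
        assert cloned.get_params()["lam"] == 0.01

    def test_save_and_reload_roundtrip(self, tmp_path):
        X = np.random.default_rng(3).normal(size=(10, 64))
        ext = CAEMFeatureExtractor(epochs=2, random_state=1).fit(X)
        ref = ext.transform(X)
        ext.save(str(tmp_path / "ckpt"))
        ext.network_.params()[0].value[...] = 0.0
        ext.load_weights(str(tmp_path / "ckpt"))
        np.testing.assert_array_equal(ext.transform(X), ref)


def test_encode_wrapper_matches_method():
    net = build_cae(SMALL, 64, seed=5)
    X = np.random.default_rng(4).normal(size=(3, 64))
    np.testing.assert_array_equal(encode(net, X), net.encode(X))
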