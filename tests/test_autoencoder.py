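"""Autoencoder: presets, forward passes, gradients, training behaviour."""

import numpy as np
import pytest

from aefs.autoencoder import (
    AEArchitecture,
    TrainConfig,
    decode,
    encode,
    encode_dataset,
    init_model,
    load_model,
    loss_and_grads,
    preset_architecture,
    reconstruction_error,
    save_model,
    train,
)
from aefs.fingerprints import FingerprintDataset


class TestPresets:
    @pytest.mark.parametrize(
        "name,sizes,code",
        [
            ("AE1-DR", (1024, 900, 700, 500), 500),
            ("AE2-DR", (1024, 800, 600, 400, 300), 300),
            ("AE3-DR", (1024, 900, 800, 600, 400), 400),
        ],
    )
    def test_layer_widths(self, name, sizes, code):
        arch = preset_architecture(name)
        assert arch.encoder_sizes == sizes
        assert arch.code_size == code
        # tied decoder mirrors the encoder widths
        assert arch.decoder_sizes == sizes[::-1]

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            preset_architecture("AE9-DR")

    def test_untied_free_decoder(self):
        arch = AEArchitecture(name="free", encoder_sizes=(8, 4), tied=False,
                              decoder_sizes=(4, 6, 8))
        assert arch.decoder_sizes == (4, 6, 8)


class TestInit:
    def test_deterministic_given_seed(self):
        arch = preset_architecture("AE3-DR")
        cfg = TrainConfig(seed=9)
        m1, m2 = init_model(arch, cfg), init_model(arch, cfg)
        for w1, w2 in zip(m1.enc_w, m2.enc_w):
            assert np.array_equal(w1, w2)

    def test_shapes_chain_through_encoder(self):
        arch = preset_architecture("AE3-DR")
        model = init_model(arch, TrainConfig())
        for w, (fi, fo) in zip(model.enc_w,
                               zip(arch.encoder_sizes[:-1], arch.encoder_sizes[1:])):
            assert w.shape == (fi, fo)

    def test_uniform01_init_in_unit_interval(self):
        arch = AEArchitecture(name="t", encoder_sizes=(8, 4, 2))
        model = init_model(arch, TrainConfig(init_mode="uniform01", seed=1))
        for arr in model.enc_w + model.enc_b + model.dec_b:
            assert arr.min() > 0.0 and arr.max() < 1.0


class TestForward:
    def test_zero_parameters_give_half(self):
        arch = AEArchitecture(name="t", encoder_sizes=(4, 2))
        model = init_model(arch, TrainConfig())
        for w in model.enc_w:
            w[:] = 0.0
        h = encode(model, np.array([0.3, 0.7, 0.1, 0.9]))
        assert np.allclose(h, 0.5)
        assert np.allclose(decode(model, h), 0.5)

    def test_scalar_sigmoid_value(self):
        arch = AEArchitecture(name="t", encoder_sizes=(1, 1))
        model = init_model(arch, TrainConfig())
        model.enc_w[0][:] = 1.0
        model.enc_b[0][:] = 0.0
        assert encode(model, np.array([1.0]))[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-4)

    def test_codes_in_open_unit_interval_and_shapes(self):
        arch = AEArchitecture(name="t", encoder_sizes=(6, 4, 3))
        model = init_model(arch, TrainConfig(seed=2))
        X = np.random.default_rng(0).random((10, 6))
        H = encode(model, X)
        assert H.shape == (10, 3)
        assert np.all((H > 0) & (H < 1))
        Z = decode(model, H)
        assert Z.shape == (10, 6)

    def test_tied_weight_mutation_visible_in_decoder(self):
        arch = AEArchitecture(name="t", encoder_sizes=(4, 2))
        model = init_model(arch, TrainConfig(seed=0))
        h = np.array([0.4, 0.6])
        before = decode(model, h)
        model.enc_w[0][0, 0] += 1.0
        after = decode(model, h)
        assert not np.allclose(before, after)

    def test_monotone_in_input_for_nonnegative_weights(self):
        arch = AEArchitecture(name="t", encoder_sizes=(3, 2))
        model = init_model(arch, TrainConfig(seed=0))
        model.enc_w[0][:] = np.abs(model.enc_w[0])
        x = np.array([0.2, 0.5, 0.8])
        h0 = encode(model, x)
        x[1] += 0.1
        assert np.all(encode(model, x) >= h0)

    def test_dimension_mismatch(self):
        arch = AEArchitecture(name="t", encoder_sizes=(4, 2))
        model = init_model(arch, TrainConfig())
        with pytest.raises(ValueError):
            encode(model, np.zeros(5))
        with pytest.raises(ValueError):
            decode(model, np.zeros(3))


class TestReconstructionError:
    def test_worked_values(self):
        assert reconstruction_error([1.0, 0.0], [1.0, 0.0]) == 0.0
        assert reconstruction_error([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        x, z = rng.random(17), rng.random(17)
        expected = sum((a - b) ** 2 for a, b in zip(x, z)) / 17
        assert reconstruction_error(x, z) == pytest.approx(expected)


def _finite_difference_check(arch: AEArchitecture, seed: int = 0) -> float:
    """Max relative error between analytic and central-difference gradients."""
    cfg = TrainConfig(seed=seed)
    model = init_model(arch, cfg)
    rng = np.random.default_rng(seed + 1)
    X = rng.random((4, arch.input_dim))
    _, grads = loss_and_grads(model, X)

    def loss():
        from aefs.autoencoder import dataset_loss
        return dataset_loss(model, X)

    eps = 1e-6
    fd_vals, an_vals = [], []
    params = [(model.enc_w, grads["enc_w"]), (model.enc_b, grads["enc_b"]),
              (model.dec_b, grads["dec_b"])]
    if not arch.tied:
        params.append((model.dec_w, grads["dec_w"]))
    for arrays, garrays in params:
        for arr, g in zip(arrays, garrays):
            flat, gflat = arr.ravel(), g.ravel()
            idx = np.random.default_rng(seed + 2).choice(flat.size,
                                                         size=min(20, flat.size),
                                                         replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                fd_vals.append((lp - lm) / (2 * eps))
                an_vals.append(gflat[i])
    fd = np.array(fd_vals)
    an = np.array(an_vals)
    return float(np.linalg.norm(fd - an) / max(np.linalg.norm(fd), np.linalg.norm(an)))


class TestGradients:
    def test_tied_5_3_5_matches_finite_differences(self):
        arch = AEArchitecture(name="t", encoder_sizes=(5, 3))
        assert _finite_difference_check(arch) < 1e-5

    @pytest.mark.parametrize("tied", [True, False])
    @pytest.mark.parametrize("preset", ["AE1-DR", "AE2-DR", "AE3-DR"])
    def test_scaled_down_presets(self, preset, tied):
        sizes = tuple(max(2, s // 32) for s in preset_architecture(preset).encoder_sizes)
        arch = AEArchitecture(name=f"{preset}/32", encoder_sizes=sizes, tied=tied)
        assert _finite_difference_check(arch, seed=3) < 1e-5


class TestTraining:
    def _dataset(self, X):
        return FingerprintDataset(ids=[f"m{i}" for i in range(len(X))],
                                  labels=["x"] * len(X), counts=X, scaled=True)

    def test_memorizes_single_repeated_vector(self):
        X = np.tile([0.2, 0.8, 0.4, 0.6], (8, 1))
        arch = AEArchitecture(name="t", encoder_sizes=(4, 2))
        cfg = TrainConfig(tolerance=0.01, max_epochs=2000, step_size=0.5,
                          batch_size=8, seed=0)
        _, report = train(self._dataset(X), arch, cfg)
        assert report.stopped_by == "tolerance"
        assert report.errors[-1] < cfg.tolerance

    def test_loss_decreases_on_rank2_data(self):
        # rank-2 structure embedded in 16 features: compressible by a tiny code
        rng = np.random.default_rng(0)
        basis = rng.random((2, 16))
        coeffs = rng.random((40, 2))
        X = np.clip(coeffs @ basis / 2, 0, 1)
        arch = AEArchitecture(name="t", encoder_sizes=(16, 4))
        cfg = TrainConfig(tolerance=1e-6, max_epochs=100, step_size=0.01, seed=1)
        model, report = train(self._dataset(X), arch, cfg)
        assert np.all(np.isfinite(report.errors))
        assert report.errors[-1] < report.errors[0]
        # tied invariant: decoder weights remain views of encoder transposes
        assert np.shares_memory(model.decoder_weight(0), model.enc_w[0])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 8))
        arch = AEArchitecture(name="t", encoder_sizes=(8, 3))
        cfg = TrainConfig(max_epochs=5, seed=7)
        _, r1 = train(self._dataset(X), arch, cfg)
        _, r2 = train(self._dataset(X), arch, cfg)
        assert r1.errors == r2.errors

    def test_rejects_unscaled_and_empty(self):
        arch = AEArchitecture(name="t", encoder_sizes=(3, 2))
        bad = FingerprintDataset(ids=["a"], labels=["x"],
                                 counts=np.array([[0.0, 2.0, 5.0]]))
        with pytest.raises(ValueError):
            train(bad, arch, TrainConfig())
        empty = FingerprintDataset(ids=[], labels=[], counts=np.zeros((0, 3)),
                                   scaled=True)
        with pytest.raises(ValueError):
            train(empty, arch, TrainConfig())


class TestEncodeDataset:
    def test_metadata_and_rows_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 8))
        ds = FingerprintDataset(ids=[f"m{i}" for i in range(6)],
                                labels=["a", "a", "b", "b", "b", "a"],
                                counts=X, scaled=True)
        arch = AEArchitecture(name="t", encoder_sizes=(8, 3))
        model = init_model(arch, TrainConfig(seed=0))
        codes = encode_dataset(model, ds)
        assert codes.ids == ds.ids and codes.labels == ds.labels
        assert codes.feature_dim == 3 and codes.scaled
        for i in range(6):
            assert np.allclose(codes.counts[i], encode(model, X[i]))


class TestPersistence:
    def test_save_load_round_trip_bit_exact(self, tmp_path):
        arch = AEArchitecture(name="t", encoder_sizes=(6, 4, 2))
        model = init_model(arch, TrainConfig(seed=4))
        path = tmp_path / "model.npz"
        save_model(model, path, extra={"note": "fit"})
        back, extra = load_model(path)
        assert extra == {"note": "fit"}
        assert back.architecture == arch
        for w1, w2 in zip(model.enc_w, back.enc_w):
            assert np.array_equal(w1, w2)
        for b1, b2 in zip(model.dec_b, back.dec_b):
            assert np.array_equal(b1, b2)
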