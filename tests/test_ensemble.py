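"""Stacking contracts: linearity, freezing, serialization, prediction."""

import numpy as np
import pytest

from attcrispr import ensemble, spatial, temporal
from attcrispr.config import RunConfig
from attcrispr.errors import NotFittedError


def random_seqs(n, length=21, seed=0):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


TINY_SPA = spatial.SpatialConfig(attention_channels=2, kernel_heights=(3,), filters=4, hidden=8)
TINY_TEM = temporal.TemporalConfig(m=6, hidden=4)


@pytest.fixture(scope="module")
def tiny_model():
    seqs = random_seqs(60, seed=1)
    y = np.random.default_rng(2).uniform(0.2, 0.8, 60)
    cfg = RunConfig(epochs=1, batch_size=32, seed=7, stack_steps=50)
    return ensemble.train_stacked(seqs, y, cfg, mode="enac",
                                  spatial_arch=TINY_SPA, temporal_arch=TINY_TEM)


class TestStackForward:
    def test_selector_weights(self):
        assert ensemble.stack_forward(0.3, 0.6, 0.9, np.array([1.0, 0, 0])) == 0.3

    def test_uniform_mean(self):
        out = ensemble.stack_forward(0.3, 0.6, 0.9, np.full(3, 1 / 3))
        assert out == pytest.approx(0.6)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.normal(size=3)
            x = rng.normal(size=3)
            a = rng.normal()
            assert ensemble.stack_forward(*(a * x), w) == pytest.approx(
                a * ensemble.stack_forward(*x, w), abs=1e-12
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ensemble.stack_forward(np.nan, 0.5, 0.5, np.ones(3))


class TestTrainStacked:
    def test_phase1_freeze_contract(self, tiny_model):
        cks = tiny_model.meta["phase1_checksums"]
        assert cks["before"] == cks["after"]

    def test_two_phase_reproducibility(self):
        seqs = random_seqs(40, seed=4)
        y = np.random.default_rng(5).uniform(0.3, 0.7, 40)
        cfg = RunConfig(epochs=1, batch_size=32, seed=11, stack_steps=20)
        m1 = ensemble.train_stacked(seqs, y, cfg, mode="enac",
                                    spatial_arch=TINY_SPA, temporal_arch=TINY_TEM)
        m2 = ensemble.train_stacked(seqs, y, cfg, mode="enac",
                                    spatial_arch=TINY_SPA, temporal_arch=TINY_TEM)
        np.testing.assert_array_equal(m1.stack_w, m2.stack_w)
        assert ensemble.param_checksum(m1.spatial.params) == ensemble.param_checksum(m2.spatial.params)
        assert ensemble.param_checksum(m1.temporal.params) == ensemble.param_checksum(m2.temporal.params)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            ensemble.train_stacked(random_seqs(5), np.full(5, 0.5), RunConfig(epochs=1), mode="nope")

    def test_branch_residuals_not_perfectly_correlated(self, tiny_model):
        seqs = random_seqs(80, seed=6)
        y = np.random.default_rng(7).uniform(0.2, 0.8, 80)
        rs = spatial.spatial_forward(seqs, tiny_model.spatial) - y
        rt = temporal.temporal_forward(seqs, tiny_model.temporal) - y
        assert abs(np.corrcoef(rs, rt)[0, 1]) < 0.999


class TestPredict:
    def test_order_preserving_permutation(self, tiny_model):
        seqs = random_seqs(12, seed=8)
        out = ensemble.predict(tiny_model, seqs)
        perm = np.random.default_rng(9).permutation(12)
        out_perm = ensemble.predict(tiny_model, [seqs[i] for i in perm])
        np.testing.assert_array_equal(out[perm], out_perm)

    def test_batch_of_one_matches_batch(self, tiny_model):
        seqs = random_seqs(6, seed=10)
        batch = ensemble.predict(tiny_model, seqs)
        singles = np.array([ensemble.predict(tiny_model, [s])[0] for s in seqs])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_checkpoint_round_trip_bit_exact(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        ensemble.save_model(tiny_model, path)
        loaded = ensemble.load_model(path)
        assert loaded.mode == tiny_model.mode
        np.testing.assert_array_equal(loaded.stack_w, tiny_model.stack_w)
        assert ensemble.param_checksum(loaded.spatial.params) == ensemble.param_checksum(
            tiny_model.spatial.params
        )
        seqs = random_seqs(5, seed=11)
        np.testing.assert_array_equal(
            ensemble.predict(loaded, seqs), ensemble.predict(tiny_model, seqs)
        )

    def test_standard_mode_requires_bio(self, tiny_model):
        broken = ensemble.EnsembleModel(
            mode="stac", spatial=tiny_model.spatial, temporal=tiny_model.temporal,
            stack_w=np.ones(3),
        )
        with pytest.raises(NotFittedError):
            ensemble.predict(broken, random_seqs(2, seed=12))


class TestStandardMode:
    def test_stac_trains_and_predicts_with_native_features(self):
        seqs = random_seqs(50, seed=13)
        y = np.random.default_rng(14).uniform(0.2, 0.8, 50)
        cfg = RunConfig(epochs=1, batch_size=32, seed=15, stack_steps=20)
        model = ensemble.train_stacked(seqs, y, cfg, mode="stac",
                                       spatial_arch=TINY_SPA, temporal_arch=TINY_TEM)
        assert model.bio is not None and model.stats is not None
        out = ensemble.predict(model, seqs[:5])
        assert out.shape == (5,) and np.isfinite(out).all()
        cks = model.meta["phase1_checksums"]
        assert cks["before"] == cks["after"]


class TestSimplexConstraint:
    def test_simplex_weights_nonnegative_and_sum_to_one(self):
        seqs = random_seqs(40, seed=20)
        y = np.random.default_rng(21).uniform(0.3, 0.7, 40)
        cfg = RunConfig(epochs=1, batch_size=32, seed=22, stack_steps=40)
        model = ensemble.train_stacked(seqs, y, cfg, mode="enac",
                                       spatial_arch=TINY_SPA, temporal_arch=TINY_TEM,
                                       finetune=False, simplex=True)
        w = model.stack_w
        assert (w >= 0).all()
        assert w[0] == 0.0  # bio slot masked in enac mode
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
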