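"""Interpretability operations on fixed (mostly untrained) models."""

import numpy as np
import pytest

from attcrispr import ensemble, interpret, spatial, temporal
from attcrispr.codec import encode_batch
from attcrispr.errors import NotFittedError


def random_seqs(n, length=21, seed=0):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


@pytest.fixture(scope="module")
def spatial_model():
    sp = spatial.init_spatial_params(seed=0)
    rng = np.random.default_rng(1)
    sp.params["att_w2"].data[...] = rng.normal(0, 0.5, size=(1, 2, 3, 2))
    return ensemble.EnsembleModel(mode="spac", spatial=sp, stack_w=np.array([0, 1.0, 0]))


@pytest.fixture(scope="module")
def temporal_model():
    tp = temporal.init_temporal_params(temporal.TemporalConfig(m=8, hidden=6), seed=2)
    return ensemble.EnsembleModel(mode="tac", temporal=tp, stack_w=np.array([0, 0, 1.0]))


class TestGlobalPreference:
    def test_single_sequence_equals_zscored_map(self, spatial_model):
        seq = random_seqs(1, seed=3)[0]
        a_s, _ = spatial.spatial_attention(encode_batch([seq])[0], spatial_model.spatial)
        from attcrispr.codec import COMPLEMENT_COLUMN_PERM

        relabeled = a_s[:, COMPLEMENT_COLUMN_PERM]
        expected = (relabeled - relabeled.mean()) / relabeled.std()
        np.testing.assert_allclose(interpret.global_preference(spatial_model, [seq]), expected, atol=1e-12)

    def test_grand_mean_zero_sd_one(self, spatial_model):
        pref = interpret.global_preference(spatial_model, random_seqs(20, seed=4))
        assert abs(pref.mean()) < 1e-8
        assert abs(pref.std() - 1) < 1e-8

    def test_invariant_to_order_and_duplication(self, spatial_model):
        seqs = random_seqs(10, seed=5)
        a = interpret.global_preference(spatial_model, seqs)
        b = interpret.global_preference(spatial_model, seqs[::-1])
        c = interpret.global_preference(spatial_model, seqs + seqs)
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_empty_dataset(self, spatial_model):
        with pytest.raises(ValueError):
            interpret.global_preference(spatial_model, [])

    def test_unfitted_model(self):
        bad = ensemble.EnsembleModel(mode="spac")
        with pytest.raises(NotFittedError):
            interpret.global_preference(bad, random_seqs(1))


class TestLocalScores:
    def test_uniform_scores_flag_nothing(self):
        tp = temporal.init_temporal_params(temporal.TemporalConfig(m=4, hidden=4), seed=0)
        for t in tp.params.values():
            t.data[...] = 0.0  # zero network -> all scores identical (0)
        model = ensemble.EnsembleModel(mode="tac", temporal=tp, stack_w=np.array([0, 0, 1.0]))
        expl = interpret.local_scores(model, random_seqs(1, seed=6)[0])
        assert expl.flagged == ()
        assert expl.baseline == 0.0

    def test_flags_are_exactly_below_baseline(self, temporal_model):
        expl = interpret.local_scores(temporal_model, random_seqs(1, seed=7)[0])
        below = {int(i + 1) for i in np.nonzero(expl.scores < expl.baseline)[0]}
        assert set(expl.flagged) == below
        assert expl.baseline == pytest.approx(expl.scores.mean())

    def test_ties_to_temporal_decomposition(self, temporal_model):
        seq = random_seqs(1, seed=8)[0]
        expl = interpret.local_scores(temporal_model, seq)
        det = temporal.temporal_details(seq, temporal_model.temporal)
        np.testing.assert_allclose(expl.scores, det["position_scores"], atol=0)
        assert expl.scores.sum() == pytest.approx(det["pre_sigmoid"], abs=1e-10)


class TestSecondOrder:
    def test_band_and_row_sum_invariants(self, temporal_model):
        b = interpret.second_order_matrix(temporal_model, random_seqs(1, seed=9)[0])
        g = temporal_model.temporal.damping
        assert (b[g == 0] == 0).all()
        assert (b >= 0).all()
        assert (b.sum(axis=1) <= 1 + 1e-12).all()


class TestSubstitutions:
    def test_no_flags_gives_empty_list(self):
        tp = temporal.init_temporal_params(temporal.TemporalConfig(m=4, hidden=4), seed=0)
        for t in tp.params.values():
            t.data[...] = 0.0
        sp = spatial.init_spatial_params(seed=1)
        model = ensemble.EnsembleModel(
            mode="enac", spatial=sp, temporal=tp, stack_w=np.array([0, 0.5, 0.5])
        )
        assert interpret.suggest_substitutions(model, random_seqs(1, seed=10)[0]) == []

    def test_contract_and_call_budget(self, monkeypatch):
        sp = spatial.init_spatial_params(seed=2)
        tp = temporal.init_temporal_params(temporal.TemporalConfig(m=8, hidden=6), seed=3)
        model = ensemble.EnsembleModel(
            mode="enac", spatial=sp, temporal=tp, stack_w=np.array([0, 0.5, 0.5])
        )
        calls = {"n": 0}
        real_predict = ensemble.predict

        def counting_predict(m, seqs, features=None):
            calls["n"] += len(seqs) if not isinstance(seqs, str) else 1
            return real_predict(m, seqs, features)

        monkeypatch.setattr(interpret.ens, "predict", counting_predict)
        max_positions = 3
        out = interpret.suggest_substitutions(model, random_seqs(1, seed=11)[0], max_positions)
        assert calls["n"] <= 1 + 3 * max_positions
        seq = random_seqs(1, seed=11)[0]
        for s in out:
            assert s.proposed != s.original
            assert s.original == seq[s.position - 1]
            assert s.delta > 0


class TestTrimerScan:
    def test_identity_matrix_scores_zero(self):
        assert (interpret.scan_trimer_influence(np.eye(21)) == 0).all()

    def test_constructed_interaction_peaks_at_center(self):
        b = np.eye(21) * 0.5
        b[13, 14] = 0.4  # (14, 15) in 1-based coordinates
        b[15, 14] = 0.4  # (16, 15)
        scores = interpret.scan_trimer_influence(b)
        center = int(np.argmax(scores)) + 2  # scores start at position 2
        assert center == 15

    def test_zero_kernel(self):
        b = np.random.default_rng(12).uniform(size=(10, 10))
        assert (interpret.scan_trimer_influence(b, np.zeros((3, 3))) == 0).all()

    def test_too_small_matrix(self):
        with pytest.raises(ValueError):
            interpret.scan_trimer_influence(np.eye(2))
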