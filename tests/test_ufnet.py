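"""Fusion network: projections, calibrated attention, training, selective
prediction, and parameter counting."""

import numpy as np
import pytest

from pdscreen import nn
from pdscreen.synthetic_cohort import MODALITIES
from pdscreen.task_models import summarize_mc_samples
from pdscreen.ufnet import (FusionSpec, IncompleteSessionError, UFNetModel,
                            calibrated_attention, count_parameters, decide,
                            fuse_predict_from_stats, project_modality,
                            train_ufnet)

DIMS = {"finger_tapping": 12, "smile": 7, "speech": 20}


def _toy_model(seed=0, **kw):
    base = dict(projection_dim=8, query_dim=4, hidden_dim=6, dropout_p=0.2,
                eta=1.0, epochs=3, batch_size=32, seed=seed)
    base.update(kw)
    return UFNetModel(FusionSpec(**base), DIMS, np.random.default_rng(seed))


def _toy_batch(rng, n=16):
    feats = {m: rng.normal(size=(n, d)) for m, d in DIMS.items()}
    probs = rng.random((n, 3))
    sigmas = rng.random((n, 3)) * 0.3
    y = rng.integers(0, 2, n).astype(float)
    return feats, probs, sigmas, y


class TestProjection:
    def test_layer_norm_contract(self, rng):
        W = rng.normal(size=(10, 32))
        b = rng.normal(size=32)
        out = project_modality(rng.normal(size=(5, 10)), W, b)
        assert np.all(np.abs(out.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(out.var(axis=1) - 1.0) < 1e-4)

    def test_zero_weights_guard(self, rng):
        out = project_modality(rng.normal(size=(3, 6)), np.zeros((6, 16)),
                               np.zeros(16))
        assert np.all(out == 0.0)

    def test_deterministic_without_dropout(self, rng):
        W = rng.normal(size=(6, 16))
        b = rng.normal(size=16)
        x = rng.normal(size=(4, 6))
        np.testing.assert_array_equal(project_modality(x, W, b),
                                      project_modality(x, W, b))

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError, match="width"):
            project_modality(rng.normal(size=(2, 5)), np.zeros((6, 8)),
                             np.zeros(8))


class TestCalibratedAttention:
    def test_equal_sigmas_match_uncalibrated(self, rng):
        model = _toy_model()
        H = rng.normal(size=(3, 8))
        _, R_cal = calibrated_attention(H, np.full(3, 0.2), model)
        model0 = _toy_model()
        model0.spec.eta = 0.0
        _, R_plain = calibrated_attention(H, np.zeros(3), model0)
        np.testing.assert_allclose(R_cal, R_plain, atol=1e-12)

    def test_eta_zero_is_noop_for_any_sigmas(self, rng):
        model = _toy_model()
        model.spec.eta = 0.0
        H = rng.normal(size=(3, 8))
        _, R_a = calibrated_attention(H, np.array([0.0, 5.0, 0.1]), model)
        _, R_b = calibrated_attention(H, np.zeros(3), model)
        np.testing.assert_allclose(R_a, R_b, atol=1e-15)

    def test_huge_sigma_starves_that_key(self, rng):
        model = _toy_model(eta=10.0)
        H = rng.normal(size=(3, 8))
        sig = np.array([0.0, 10.0, 0.0])    # smile token unreliable
        _, R = calibrated_attention(H, sig, model)
        assert np.all(R[:, 1] < 1e-6)
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-9)

    def test_rows_sum_to_one_and_monotone_in_sigma(self, rng):
        model = _toy_model(eta=2.0)
        H = rng.normal(size=(3, 8))
        prev = None
        for s in (0.0, 0.2, 0.5, 1.0):
            _, R = calibrated_attention(H, np.array([0.0, s, 0.0]), model)
            np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-9)
            if prev is not None:
                assert np.all(R[:, 1] <= prev[:, 1] + 1e-12)
            prev = R

    def test_negative_sigma_rejected(self, rng):
        model = _toy_model()
        with pytest.raises(ValueError, match="nonnegative"):
            calibrated_attention(rng.normal(size=(3, 8)),
                                 np.array([0.1, -0.2, 0.0]), model)


class TestForwardBackward:
    def test_gradients_match_finite_differences(self, rng):
        model = _toy_model(dropout_p=0.3)
        feats, probs, sigmas, y = _toy_batch(rng, n=6)

        def loss_fn():
            logits = model.forward(feats, probs, sigmas,
                                   rng=np.random.default_rng(99))
            return nn.bce_with_logits(logits, y)[0]

        logits = model.forward(feats, probs, sigmas,
                               rng=np.random.default_rng(99))
        _, dlog = nn.bce_with_logits(logits, y)
        for p in model.parameters():
            p.grad[...] = 0.0
        model.backward(dlog)
        errs = []
        for p in model.parameters():
            for _ in range(4):
                ix = tuple(int(rng.integers(0, s)) for s in p.value.shape)
                eps = 1e-6
                orig = p.value[ix]
                p.value[ix] = orig + eps
                lp = loss_fn()
                p.value[ix] = orig - eps
                lm = loss_fn()
                p.value[ix] = orig
                errs.append(abs((lp - lm) / (2 * eps) - p.grad[ix]))
        assert np.median(errs) < 1e-8
        assert max(errs) < 1e-4

    def test_head_input_width_is_3p_plus_3(self):
        model = _toy_model(projection_dim=8)
        assert model.head1.W.value.shape[0] == 3 * 8 + 3

    def test_incomplete_session_named_in_error(self, rng):
        feats, probs, sigmas, y = _toy_batch(rng, n=5)
        feats["smile"][2, 0] = np.nan
        spec = FusionSpec(projection_dim=8, query_dim=4, hidden_dim=6,
                          epochs=1, seed=0)
        with pytest.raises(IncompleteSessionError, match="S2.*smile"):
            train_ufnet(feats, y, probs, sigmas, spec,
                        session_ids=[f"S{i}" for i in range(5)])

    def test_training_reduces_loss_and_is_seeded(self, rng):
        feats, probs, sigmas, y = _toy_batch(rng, n=64)
        # give the labels real signal through the probs channel
        probs = np.column_stack([y * 0.6 + 0.2] * 3)
        spec = FusionSpec(projection_dim=8, query_dim=4, hidden_dim=6,
                          dropout_p=0.1, epochs=30, learning_rate=0.01,
                          seed=3)
        a = train_ufnet(feats, y, probs, sigmas, spec)
        b = train_ufnet(feats, y, probs, sigmas, spec)
        assert a.loss_history[-1] <= a.loss_history[0]
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestFusePredict:
    def test_zero_dropout_zero_spread(self, rng):
        model = _toy_model(dropout_p=0.0)
        feats, probs, sigmas, _ = _toy_batch(rng, n=4)
        preds = fuse_predict_from_stats(model, feats, probs, sigmas, T=10,
                                        rng=np.random.default_rng(0))
        assert all(p.sd_p == 0.0 for p in preds)
        assert all(p.ci_low == p.ci_high == p.mean_p for p in preds)

    def test_summary_matches_brute_force_on_logged_samples(self, rng):
        model = _toy_model(dropout_p=0.3)
        feats, probs, sigmas, _ = _toy_batch(rng, n=3)
        preds = fuse_predict_from_stats(model, feats, probs, sigmas, T=30,
                                        rng=np.random.default_rng(1))
        for p in preds:
            redo = summarize_mc_samples(p.samples, 0.95)
            assert p.mean_p == redo.mean_p
            assert p.sd_p == redo.sd_p
            assert (p.ci_low, p.ci_high) == (redo.ci_low, redo.ci_high)

    def test_incomplete_prediction_rejected(self, rng):
        model = _toy_model()
        feats, probs, sigmas, _ = _toy_batch(rng, n=3)
        feats["speech"][1, 3] = np.nan
        with pytest.raises(IncompleteSessionError):
            fuse_predict_from_stats(model, feats, probs, sigmas, T=5,
                                    rng=np.random.default_rng(0))


class TestDecide:
    def _mc(self, samples):
        return summarize_mc_samples(np.asarray(samples, dtype=float))

    def test_confident_positive(self):
        assert decide(self._mc([0.9] * 30)).verdict == "positive"

    def test_confident_negative(self):
        assert decide(self._mc([0.2] * 30)).verdict == "negative"

    def test_straddling_interval_withheld(self):
        assert decide(self._mc(np.linspace(0.3, 0.7, 30))).verdict == "withheld"

    def test_custom_threshold(self):
        mc = self._mc([0.6] * 10)
        assert decide(mc, threshold=0.7).verdict == "negative"

    def test_relevel_from_samples_monotone_coverage(self):
        g = np.random.default_rng(0)
        mcs = [self._mc(np.clip(g.normal(0.55, 0.15, 30), 0, 1))
               for _ in range(200)]
        coverages = []
        for level in (0.80, 0.90, 0.99):
            v = [decide(mc, ci_level=level).verdict for mc in mcs]
            coverages.append(np.mean([x != "withheld" for x in v]))
        assert coverages[0] >= coverages[1] >= coverages[2]


class TestCountParameters:
    def test_hand_computed_toy_config(self):
        spec = FusionSpec(projection_dim=4, query_dim=2, hidden_dim=2,
                          epochs=1, seed=0)
        dims = {"finger_tapping": 3, "smile": 5, "speech": 7}
        model = UFNetModel(spec, dims, np.random.default_rng(0))
        total, items = count_parameters(model)
        hand = ((3 * 4 + 4) + (5 * 4 + 4) + (7 * 4 + 4)   # projections
                + (4 * 2 + 2) * 2                          # query, key
                + (4 * 4 + 4)                              # value
                + ((3 * 4 + 3) * 2 + 2)                    # head hidden
                + (2 * 1 + 1))                             # head out
        assert total == hand
        assert sum(items.values()) == total

    def test_monotone_in_hidden_dim_and_training_invariant(self, rng):
        small = _toy_model(hidden_dim=4)
        big = _toy_model(hidden_dim=8)
        assert count_parameters(big)[0] > count_parameters(small)[0]
        feats, probs, sigmas, y = _toy_batch(rng, n=32)
        before = count_parameters(small)[0]
        trained = train_ufnet(feats, y, probs, sigmas, small.spec)
        assert count_parameters(trained)[0] == before
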