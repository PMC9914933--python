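"""Forecaster internals: sparsity measure, ProbSparse attention against a
dense oracle, encoder/decoder structure contracts, and training behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ricerisk import autodiff as ad
from ricerisk.autodiff import Tensor
from ricerisk.informer import (
    ForecastConfig,
    InformerModel,
    _DataEmbedding,
    _DecoderLayer,
    _EncoderStack,
    n_selected_queries,
    persistence_forecast,
    probsparse_attention,
    sparsity_measure,
)


def dense_attention(Q, K, V, causal=False):
    s = Q @ K.T / math.sqrt(Q.shape[-1])
    if causal:
        s = np.where(np.tril(np.ones(s.shape, bool)), s, -np.inf)
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    a = e / e.sum(axis=-1, keepdims=True)
    return a @ V


class TestSparsityMeasure:
    def test_single_key_gives_zero(self, rng):
        q = rng.normal(size=4)
        K = rng.normal(size=(1, 4))
        assert sparsity_measure(q, K) == pytest.approx(0.0, abs=1e-12)

    def test_constant_scores_give_log_lk(self, rng):
        q = rng.normal(size=4)
        K = np.tile(rng.normal(size=4), (9, 1))  # all dot products equal
        assert sparsity_measure(q, K) == pytest.approx(math.log(9), abs=1e-10)

    @given(
        q=arrays(float, 4, elements=st.floats(-5, 5)),
        K=arrays(float, (6, 4), elements=st.floats(-5, 5)),
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, q, K):
        """log-sum-exp of the scores always dominates their mean."""
        assert sparsity_measure(q, K) >= -1e-10


class TestProbSparseAttention:
    def test_full_u_equals_dense(self, rng):
        for _ in range(20):
            Q, K, V = (rng.normal(size=(8, 4)) for _ in range(3))
            np.testing.assert_allclose(
                probsparse_attention(Q, K, V, u=8),
                dense_attention(Q, K, V),
                atol=1e-5,
            )

    def test_selected_rows_match_dense_oracle(self, rng):
        """Rows chosen by the sparsity measure reproduce dense attention;
        the rest carry the mean of the values."""
        Q, K, V = (rng.normal(size=(8, 4)) for _ in range(3))
        u = 3
        out = probsparse_attention(Q, K, V, u=u)
        dense = dense_attention(Q, K, V)
        M = sparsity_measure(Q, K)
        top = np.argsort(-M, kind="stable")[:u]
        np.testing.assert_allclose(out[top], dense[top], atol=1e-6)
        rest = np.setdiff1d(np.arange(8), top)
        np.testing.assert_allclose(
            out[rest], np.tile(V.mean(axis=0), (len(rest), 1)), atol=1e-6
        )

    def test_single_key_returns_value(self, rng):
        Q = rng.normal(size=(5, 4))
        K = rng.normal(size=(1, 4))
        V = rng.normal(size=(1, 3))
        out = probsparse_attention(Q, K, V, u=5)
        np.testing.assert_allclose(out, np.tile(V[0], (5, 1)), atol=1e-12)

    def test_causal_fallback_is_cumulative_mean(self, rng):
        Q, K, V = (rng.normal(size=(6, 4)) for _ in range(3))
        out = probsparse_attention(Q, K, V, u=1, causal_mask=True)
        cum = np.cumsum(V, axis=0) / np.arange(1, 7)[:, None]
        # all rows except the single selected one carry the running mean
        matches = np.isclose(out, cum, atol=1e-9).all(axis=1)
        assert matches.sum() >= 5

    def test_causal_selected_rows_ignore_future(self, rng):
        Q, K, V = (rng.normal(size=(6, 4)) for _ in range(3))
        out = probsparse_attention(Q, K, V, u=6, causal_mask=True)
        np.testing.assert_allclose(out, dense_attention(Q, K, V, causal=True), atol=1e-5)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            probsparse_attention(rng.normal(size=(4, 3)), rng.normal(size=(4, 4)),
                                 rng.normal(size=(4, 4)), u=2)

    def test_u_formula(self):
        assert n_selected_queries(1.0, 36) == math.ceil(math.log(36))
        assert n_selected_queries(1.0, 1) == 1
        assert n_selected_queries(100.0, 8) == 8  # clamped to L_Q


class TestEncoderStructure:
    def test_one_distillation_halves_length(self, rng):
        cfg = ForecastConfig(d_model=8, n_heads=2, d_ff=16, dropout=0.0)
        stack = _EncoderStack(cfg, 2, rng, rng)
        for L in (12, 13):
            x = Tensor(rng.normal(size=(2, L, 8)))
            out = stack(x)
            assert out.shape == (2, (L + 1) // 2, 8)

    def test_elu_branch_values(self):
        x = Tensor(np.array([0.0, 2.0, -1.0]))
        out = ad.elu(x).data
        np.testing.assert_allclose(out, [0.0, 2.0, math.exp(-1) - 1], atol=1e-12)

    def test_embedding_output_shape(self, rng):
        cfg = ForecastConfig(d_model=16, n_heads=2, dropout=0.0)
        emb = _DataEmbedding(cfg, 3, rng, rng)
        vals = rng.normal(size=(4, 10))
        weeks = np.tile(np.arange(1, 11), (4, 1))
        out = emb(vals, weeks, np.array([0, 1, 2, 0]))
        assert out.shape == (4, 10, 16)

    def test_shifted_windows_differ_only_through_encodings(self, rng):
        cfg = ForecastConfig(d_model=16, n_heads=2, dropout=0.0)
        emb = _DataEmbedding(cfg, 1, rng, rng)
        vals = rng.normal(size=(1, 10))
        weeks = np.arange(1, 11)[None]
        a = emb(vals, weeks, np.zeros(1, int)).data
        b = emb(vals, weeks + 53, np.zeros(1, int)).data  # same week-of-year
        np.testing.assert_allclose(a, b, atol=1e-12)
        c = emb(vals, weeks + 5, np.zeros(1, int)).data
        assert not np.allclose(a, c)


class TestDecoder:
    @pytest.fixture()
    def decoder_setup(self, rng):
        cfg = ForecastConfig(d_model=16, n_heads=2, d_ff=32, dropout=0.0)
        layer = _DecoderLayer(cfg, rng, rng)
        memory = Tensor(rng.normal(size=(1, 12, 16)))
        x = rng.normal(size=(1, 9, 16))
        return layer, memory, x

    def test_causality_under_perturbation(self, decoder_setup, rng):
        layer, memory, x = decoder_setup
        base = layer(Tensor(x), memory).data
        for t in (3, 6, 8):
            xp = x.copy()
            xp[0, t] += rng.normal(size=16)
            out = layer(Tensor(xp), memory).data
            assert np.abs(out[0, :t] - base[0, :t]).max() <= 1e-6

    def test_memory_perturbation_reaches_all_positions(self, decoder_setup, rng):
        layer, memory, x = decoder_setup
        base = layer(Tensor(x), memory).data
        m2 = Tensor(memory.data + rng.normal(size=memory.shape))
        out = layer(Tensor(x), m2).data
        assert (np.abs(out - base).max(axis=-1) > 1e-8).all()


@pytest.fixture(scope="module")
def toy_series():
    """Two provinces, 60 weeks of noisy seasonal signal."""
    rng = np.random.default_rng(0)
    weeks = np.arange(1, 61)
    rows = []
    for i, prov in enumerate(("A", "B")):
        vals = 1.0 + 0.4 * np.sin(2 * np.pi * weeks / 20) + i \
            + 0.05 * rng.normal(size=60)
        rows += [(prov, int(w), float(v)) for w, v in zip(weeks, vals)]
    return pd.DataFrame(rows, columns=["province", "week", "value"])


class TestTraining:
    SMALL = dict(input_length=16, label_length=6, horizon=8, d_model=16,
                 n_heads=2, d_ff=32, epochs=4, batch_size=32)

    def test_same_seed_reproduces_loss_and_predictions(self, toy_series):
        results = [
            InformerModel(toy_series, ForecastConfig(seed=9, **self.SMALL)).fit(50)
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(
            results[0].training_log, results[1].training_log
        )
        pd.testing.assert_frame_equal(results[0].predict(), results[1].predict())

    def test_loss_decreases(self, toy_series):
        res = InformerModel(toy_series, ForecastConfig(seed=1, **self.SMALL)).fit(50)
        log = res.training_log.train_loss
        assert log.iloc[-1] < log.iloc[0]

    def test_constant_series_predicted_within_five_percent(self):
        rows = [(p, w, 5.0) for p in ("A", "B") for w in range(1, 61)]
        series = pd.DataFrame(rows, columns=["province", "week", "value"])
        cfg = ForecastConfig(seed=3, epochs=8, **{k: v for k, v in self.SMALL.items()
                                                  if k not in ("epochs",)})
        res = InformerModel(series, cfg).fit(50)
        pred = res.predict()
        assert np.abs(pred.value - 5.0).max() < 0.25  # within 5 %

    def test_too_short_series_errors(self, toy_series):
        cfg = ForecastConfig(seed=1, **self.SMALL)
        with pytest.raises(ValueError, match="shorter"):
            InformerModel(toy_series, cfg).fit(split_week=20)

    def test_predict_shape_and_weeks(self, toy_series):
        res = InformerModel(toy_series, ForecastConfig(seed=2, **self.SMALL)).fit(50)
        pred = res.predict()
        assert set(pred.week) == set(range(51, 59))
        assert sorted(pred.province.unique()) == ["A", "B"]
        short = res.predict(horizon=3)
        assert set(short.week) == {51, 52, 53}

    def test_weight_checkpoint_round_trips(self, toy_series, tmp_path):
        cfg = ForecastConfig(seed=6, **self.SMALL)
        res = InformerModel(toy_series, cfg).fit(50)
        expected = res.predict()
        res.save_weights(tmp_path / "w.npz")
        fresh = InformerModel(toy_series, ForecastConfig(seed=7, **self.SMALL)).fit(50)
        fresh.load_weights(tmp_path / "w.npz")
        pd.testing.assert_frame_equal(fresh.predict(), expected)

    def test_gradient_reaches_every_parameter(self, toy_series):
        from ricerisk.informer import _InformerNetwork

        cfg = ForecastConfig(seed=4, **self.SMALL)
        model = InformerModel(toy_series, cfg)
        z, mu, sd = model._standardize(50)
        enc_x, enc_w, dec_x, dec_w, tgt, prov = model._windows(z, 50)
        net = _InformerNetwork(cfg, 2, 0)
        pred = net(enc_x[:8], enc_w[:8], dec_x[:8], dec_w[:8], prov[:8])
        err = ad.sub(ad.getitem(pred, (slice(None), slice(cfg.label_length, None))),
                     tgt[:8])
        ad.tmean(ad.mul(err, err)).backward()
        for p in net.parameters():
            assert p.grad is not None
            assert np.abs(p.grad).max() > 0 or p.data.size > 100  # embeddings: used rows only


def test_persistence_repeats_last_value():
    series = pd.DataFrame(
        [("A", w, float(w)) for w in range(1, 11)],
        columns=["province", "week", "value"],
    )
    out = persistence_forecast(series, split_week=8, horizon=3)
    assert list(out.week) == [9, 10, 11]
    assert (out.value == 8.0).all()
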