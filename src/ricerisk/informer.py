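"""ProbSparse-attention encoder–decoder forecaster for weekly risk indicators.

The network follows the Informer design for long-sequence forecasting:

* **ProbSparse self-attention** — only the ``u = ⌈c·ln L_Q⌉`` queries with
  the largest sparsity measure ``M(q, K) = lse(qKᵀ/√d) − mean(qKᵀ/√d)``
  receive full softmax attention; the remaining rows fall back to the mean
  of the values (a cumulative mean under a causal mask).
* **Distillation** — between encoder attention layers a kernel-3
  convolution + ELU + stride-2 max-pooling halves the sequence length.
  The encoder runs two stacks: the main stack sees the whole input, a
  replica with one fewer layer sees the last half; their outputs are
  concatenated along time into the feature map.
* **Generative decoding** — the decoder input is a label segment of known
  history followed by zero placeholders for the horizon; masked ProbSparse
  self-attention plus full cross-attention onto the feature map produce all
  horizon steps in a single forward pass.

One model is fitted per indicator, pooled over provinces with a learned
province embedding; series are standardised per province on training weeks
only. Everything runs on the package's own numpy autodiff engine and is
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "ForecastConfig",
    "sparsity_measure",
    "probsparse_attention",
    "InformerModel",
    "InformerResults",
    "persistence_forecast",
]

WEEK_PERIOD = 53  # calendar period of the week-of-year embedding


# ---------------------------------------------------------------------------
# functional attention pieces (numpy in / numpy out; used by the layers)


def sparsity_measure(q: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Sparsity measure of queries against keys.

    ``M = ln Σ_j exp(q·k_j/√d) − (1/L_K) Σ_j q·k_j/√d`` per query, computed
    with a max-shifted log-sum-exp. ``q`` may be a single query ``(d,)`` or
    a stack ``(..., L_Q, d)``; ``K`` is ``(..., L_K, d)``. M is always ≥ 0
    and equals ``ln L_K`` when all scores of a query coincide.
    """
    q = np.asarray(q, dtype=float)
    K = np.asarray(K, dtype=float)
    single = q.ndim == 1
    if single:
        q = q[None, :]
    d = K.shape[-1]
    scores = q @ np.swapaxes(K, -1, -2) / math.sqrt(d)
    m = scores.max(axis=-1, keepdims=True)
    lse = m[..., 0] + np.log(np.exp(scores - m).sum(axis=-1))
    M = lse - scores.mean(axis=-1)
    return float(M[0]) if single else M


def _masked_sparsity(scores: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Sparsity measure per row of a score matrix restricted to allowed keys."""
    neg = np.where(allowed, scores, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    lse = m[..., 0] + np.log(np.exp(neg - m).sum(axis=-1))
    counts = allowed.sum(axis=-1)
    mean = np.where(allowed, scores, 0.0).sum(axis=-1) / counts
    return lse - mean


def _probsparse(
    Q: Tensor, K: Tensor, V: Tensor, u: int, causal: bool
) -> Tensor:
    """ProbSparse attention on tensors of shape (..., L, d)."""
    Lq, dk = Q.shape[-2], Q.shape[-1]
    Lk = K.shape[-2]
    u = max(1, min(int(u), Lq))
    scale = 1.0 / math.sqrt(dk)
    scores = ad.mul(ad.matmul(Q, ad.transpose(K, _swap_axes(Q.ndim))), scale)

    if causal:
        if Lq != Lk:
            raise ValueError("causal ProbSparse attention needs L_Q == L_K")
        allowed = np.tril(np.ones((Lq, Lk), dtype=bool))
    else:
        allowed = np.ones((Lq, Lk), dtype=bool)
    allowed_b = np.broadcast_to(allowed, scores.shape)

    # query selection is not differentiated: measure on detached scores
    M = _masked_sparsity(scores.data, allowed_b)
    idx = np.argsort(-M, axis=-1, kind="stable")[..., :u]

    lead = scores.shape[:-2]
    grid = np.ix_(*[np.arange(s) for s in lead]) if lead else ()
    sel_index = tuple(g[..., None] for g in grid) + (idx,)
    sel_scores = ad.getitem(scores, sel_index)  # (..., u, Lk)

    if causal:
        sel_allowed = allowed[idx]  # (..., u, Lk)
        sel_scores = ad.add(sel_scores, np.where(sel_allowed, 0.0, -1e9))
    attn = ad.softmax(sel_scores, axis=-1)
    out_sel = ad.matmul(attn, V)  # (..., u, dv)

    if causal:
        counts = np.arange(1, Lk + 1, dtype=float)[:, None]
        fallback = ad.mul(ad.cumsum(V, axis=-2), 1.0 / counts)
    else:
        mean_v = ad.tmean(V, axis=-2, keepdims=True)
        fallback = ad.add(
            mean_v, np.zeros(lead + (Lq, V.shape[-1]))
        )  # broadcast to full length
    return ad.row_scatter(fallback, out_sel, idx)


def _swap_axes(ndim: int) -> Tuple[int, ...]:
    axes = list(range(ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return tuple(axes)


def probsparse_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    u: int,
    causal_mask: bool = False,
) -> np.ndarray:
    """Single-head ProbSparse attention on plain arrays ``(L, d)``.

    The ``u`` queries with the largest sparsity measure get full softmax
    attention ``softmax(Q̄Kᵀ/√d)V``; the others return the (cumulative,
    when causal) mean of ``V``.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("inconsistent attention shapes")
    return _probsparse(Tensor(Q), Tensor(K), Tensor(V), u, causal_mask).data


def _dense_attention(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    scale = 1.0 / math.sqrt(Q.shape[-1])
    scores = ad.mul(ad.matmul(Q, ad.transpose(K, _swap_axes(Q.ndim))), scale)
    return ad.matmul(ad.softmax(scores, axis=-1), V)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ForecastConfig:
    """Hyperparameters of the forecaster (desk-scale defaults)."""

    input_length: int = 36
    label_length: int = 12
    horizon: int = 21
    d_model: int = 32
    n_heads: int = 4
    sampling_factor: float = 1.0  # u = ceil(c · ln L_Q)
    encode_layers: int = 2  # main stack; replica has one fewer
    conv_kernel: int = 3
    d_ff: int = 64
    dropout: float = 0.05
    learning_rate: float = 1e-3
    epochs: int = 25
    batch_size: int = 64
    seed: int = 0
    exact_sparsity: bool = True  # exact measure (cheap at these lengths)

    def validate(self) -> None:
        if not self.label_length < self.input_length:
            raise ValueError("label_length must be < input_length")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.input_length < 4:
            raise ValueError("input_length too short for distillation")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def n_selected_queries(c: float, L_Q: int) -> int:
    """``u = ⌈c·ln L_Q⌉`` clamped to [1, L_Q]."""
    return max(1, min(int(math.ceil(c * math.log(max(L_Q, 2)))), L_Q))


# ---------------------------------------------------------------------------
# layers


class _MultiHead(nn.Module):
    """Multi-head attention: ProbSparse (self) or dense (cross)."""

    def __init__(self, d: int, n_heads: int, rng, sparse: bool,
                 causal: bool, factor: float):
        self.h = n_heads
        self.dh = d // n_heads
        self.sparse = sparse
        self.causal = causal
        self.factor = factor
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)

    def _split(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        return ad.transpose(ad.reshape(x, (B, L, self.h, self.dh)), (0, 2, 1, 3))

    def _merge(self, x: Tensor) -> Tensor:
        B, H, L, dh = x.shape
        return ad.reshape(ad.transpose(x, (0, 2, 1, 3)), (B, L, H * dh))

    def __call__(self, xq: Tensor, kv: Optional[Tensor] = None) -> Tensor:
        kv = xq if kv is None else kv
        Q = self._split(self.wq(xq))
        K = self._split(self.wk(kv))
        V = self._split(self.wv(kv))
        if self.sparse:
            u = n_selected_queries(self.factor, Q.shape[-2])
            out = _probsparse(Q, K, V, u, self.causal)
        else:
            out = _dense_attention(Q, K, V)
        return self.wo(self._merge(out))


class _FeedForward(nn.Module):
    def __init__(self, d: int, d_ff: int, rng):
        self.fc1 = nn.Linear(d, d_ff, rng)
        self.fc2 = nn.Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.elu(self.fc1(x)))


class _EncoderLayer(nn.Module):
    """Residual + LayerNorm wrapping of self-attention and feed-forward."""

    def __init__(self, cfg: ForecastConfig, rng, dropout_rng):
        d = cfg.d_model
        self.attn = _MultiHead(d, cfg.n_heads, rng, sparse=True,
                               causal=False, factor=cfg.sampling_factor)
        self.ffn = _FeedForward(d, cfg.d_ff, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        self.drop = nn.Dropout(cfg.dropout, dropout_rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(ad.add(x, self.drop(self.attn(x))))
        return self.ln2(ad.add(x, self.drop(self.ffn(x))))


class _Distill(nn.Module):
    """Conv1d + ELU + max-pool: halves the temporal length (⌈L/2⌉)."""

    def __init__(self, cfg: ForecastConfig, rng):
        self.conv = nn.Conv1dSame(cfg.d_model, cfg.d_model, cfg.conv_kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2] < 2:
            raise ValueError("sequence too short to distil")
        return ad.maxpool1d(ad.elu(self.conv(x)))


class _EncoderStack(nn.Module):
    """Alternating attention and distillation layers (one distil fewer)."""

    def __init__(self, cfg: ForecastConfig, n_layers: int, rng, dropout_rng):
        self.layers = [_EncoderLayer(cfg, rng, dropout_rng) for _ in range(n_layers)]
        self.distills = [_Distill(cfg, rng) for _ in range(max(n_layers - 1, 0))]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.distills):
                x = self.distills[i](x)
        return x


class _Encoder(nn.Module):
    """Main stack on the full input, replica stack on the last half."""

    def __init__(self, cfg: ForecastConfig, rng, dropout_rng):
        self.main = _EncoderStack(cfg, cfg.encode_layers, rng, dropout_rng)
        self.half = (
            _EncoderStack(cfg, cfg.encode_layers - 1, rng, dropout_rng)
            if cfg.encode_layers > 1
            else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2] < 4:
            raise ValueError("encoder input too short")
        outs = [self.main(x)]
        if self.half is not None:
            L = x.shape[-2]
            outs.append(self.half(ad.getitem(x, (slice(None), slice(L // 2, L)))))
        return ad.concat(outs, axis=-2) if len(outs) > 1 else outs[0]


class _DecoderLayer(nn.Module):
    def __init__(self, cfg: ForecastConfig, rng, dropout_rng):
        d = cfg.d_model
        self.self_attn = _MultiHead(d, cfg.n_heads, rng, sparse=True,
                                    causal=True, factor=cfg.sampling_factor)
        self.cross_attn = _MultiHead(d, cfg.n_heads, rng, sparse=False,
                                     causal=False, factor=cfg.sampling_factor)
        self.ffn = _FeedForward(d, cfg.d_ff, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        self.ln3 = nn.LayerNorm(d)
        self.drop = nn.Dropout(cfg.dropout, dropout_rng)

    def __call__(self, x: Tensor, memory: Tensor) -> Tensor:
        x = self.ln1(ad.add(x, self.drop(self.self_attn(x))))
        x = self.ln2(ad.add(x, self.drop(self.cross_attn(x, memory))))
        return self.ln3(ad.add(x, self.drop(self.ffn(x))))


def _sinusoidal(length: int, d: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class _DataEmbedding(nn.Module):
    """Value projection + local sinusoidal + global calendar + province."""

    def __init__(self, cfg: ForecastConfig, n_provinces: int, rng, dropout_rng):
        d = cfg.d_model
        self.value = nn.Linear(1, d, rng)
        self.week = nn.Embedding(WEEK_PERIOD, d, rng)
        self.province = nn.Embedding(n_provinces, d, rng)
        self.drop = nn.Dropout(cfg.dropout, dropout_rng)
        self.d = d

    def __call__(self, values: np.ndarray, weeks: np.ndarray,
                 provinces: np.ndarray) -> Tensor:
        B, L = values.shape
        x = self.value(Tensor(values[..., None]))
        x = ad.add(x, _sinusoidal(L, self.d))
        x = ad.add(x, self.week((weeks - 1) % WEEK_PERIOD))
        prov = self.province(provinces)  # (B, d)
        x = ad.add(x, ad.reshape(prov, (B, 1, self.d)))
        return self.drop(x)


class _InformerNetwork(nn.Module):
    def __init__(self, cfg: ForecastConfig, n_provinces: int, seed: int):
        rng = np.random.default_rng(seed)
        dropout_rng = np.random.default_rng(seed + 1)
        self.cfg = cfg
        self.enc_embed = _DataEmbedding(cfg, n_provinces, rng, dropout_rng)
        self.dec_embed = _DataEmbedding(cfg, n_provinces, rng, dropout_rng)
        self.encoder = _Encoder(cfg, rng, dropout_rng)
        self.decoder = _DecoderLayer(cfg, rng, dropout_rng)
        self.head = nn.Linear(cfg.d_model, 1, rng)

    def __call__(self, x_enc, weeks_enc, x_dec, weeks_dec, provinces) -> Tensor:
        memory = self.encoder(self.enc_embed(x_enc, weeks_enc, provinces))
        dec = self.decoder(self.dec_embed(x_dec, weeks_dec, provinces), memory)
        out = self.head(dec)  # (B, L_dec, 1)
        return ad.reshape(out, (out.shape[0], out.shape[1]))


# ---------------------------------------------------------------------------
# model / results


def _to_wide(series: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """(province, week, value) long frame -> weeks × provinces wide frame."""
    wide = series.pivot(index="week", columns="province", values=value_col)
    if wide.isna().any().any():
        raise ValueError("series has missing province-weeks; gap-fill first")
    return wide.sort_index()


class InformerModel:
    """Forecaster for one indicator series, pooled across provinces.

    Parameters
    ----------
    series : pandas.DataFrame
        Either a long frame with columns ``province, week`` and the
        indicator value column named by ``value_col``, or a wide frame
        (index = week, one column per province).
    config : ForecastConfig, optional
    value_col : str
        Name of the value column when ``series`` is long.
    """

    def __init__(self, series: pd.DataFrame, config: Optional[ForecastConfig] = None,
                 value_col: str = "value"):
        config = config or ForecastConfig()
        config.validate()
        if {"province", "week"}.issubset(series.columns):
            series = _to_wide(series, value_col)
        self.wide = series.sort_index()
        self.config = config
        self.provinces = list(self.wide.columns)
        self.weeks = self.wide.index.to_numpy(dtype=int)

    # -- internals ----------------------------------------------------------

    def _standardize(self, split_week: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        train = self.wide.loc[self.wide.index <= split_week]
        mu = train.mean(axis=0).to_numpy()
        sd = np.maximum(train.std(axis=0, ddof=0).to_numpy(), 1e-8)
        z = (self.wide.to_numpy() - mu) / sd
        return z, mu, sd

    def _windows(self, z: np.ndarray, split_week: int):
        cfg = self.config
        L, H, Lab = cfg.input_length, cfg.horizon, cfg.label_length
        week_of = self.weeks
        n_train = int(np.searchsorted(week_of, split_week, side="right"))
        span = L + H
        if n_train < span:
            raise ValueError(
                f"training span ({n_train} weeks) shorter than "
                f"input_length + horizon = {span}"
            )
        enc_x, enc_w, dec_x, dec_w, tgt, prov = [], [], [], [], [], []
        for pi in range(z.shape[1]):
            for t0 in range(n_train - span + 1):
                sl_enc = slice(t0, t0 + L)
                sl_tgt = slice(t0 + L, t0 + span)
                lab = z[t0 + L - Lab : t0 + L, pi]
                enc_x.append(z[sl_enc, pi])
                enc_w.append(week_of[sl_enc])
                dec_x.append(np.concatenate([lab, np.zeros(H)]))
                dec_w.append(week_of[t0 + L - Lab : t0 + span])
                tgt.append(z[sl_tgt, pi])
                prov.append(pi)
        return (np.array(enc_x), np.array(enc_w), np.array(dec_x),
                np.array(dec_w), np.array(tgt), np.array(prov))

    # -- API ----------------------------------------------------------------

    def fit(self, split_week: int = 138, verbose: bool = False) -> "InformerResults":
        """Train on weeks ≤ ``split_week``; later weeks are held out."""
        cfg = self.config
        z, mu, sd = self._standardize(split_week)
        enc_x, enc_w, dec_x, dec_w, tgt, prov = self._windows(z, split_week)
        net = _InformerNetwork(cfg, len(self.provinces), cfg.seed)
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 2)
        n = len(enc_x)
        log: List[Dict[str, float]] = []
        net.train()
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total, batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                b = order[start : start + cfg.batch_size]
                pred = net(enc_x[b], enc_w[b], dec_x[b], dec_w[b], prov[b])
                horizon_pred = ad.getitem(
                    pred, (slice(None), slice(cfg.label_length, None))
                )
                err = ad.sub(horizon_pred, tgt[b])
                loss = ad.tmean(ad.mul(err, err))
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data)
                batches += 1
            log.append({"epoch": epoch + 1, "train_loss": total / batches})
            if verbose:
                print(f"epoch {epoch + 1:3d}  loss {total / batches:.6f}")
        net.eval()
        return InformerResults(self, net, split_week, mu, sd, pd.DataFrame(log))


@dataclass
class InformerResults:
    """Fitted forecaster: predictions, training log, summary."""

    model: InformerModel
    network: _InformerNetwork
    split_week: int
    mu: np.ndarray
    sd: np.ndarray
    training_log: pd.DataFrame

    def predict(self, horizon: Optional[int] = None) -> pd.DataFrame:
        """Forecast the ``horizon`` weeks after the training split.

        Returns a long frame ``province, week, value`` in original units.
        All horizon steps come from one generative forward pass per
        province batch.
        """
        cfg = self.model.config
        horizon = horizon or cfg.horizon
        if horizon > cfg.horizon:
            raise ValueError("horizon exceeds the trained decoder length")
        weeks = self.model.weeks
        n_train = int(np.searchsorted(weeks, self.split_week, side="right"))
        if n_train < cfg.input_length:
            raise ValueError("not enough history before the split")
        z = (self.model.wide.to_numpy() - self.mu) / self.sd
        P = len(self.model.provinces)
        sl_enc = slice(n_train - cfg.input_length, n_train)
        enc_x = z[sl_enc].T  # (P, L)
        enc_w = np.tile(weeks[sl_enc], (P, 1))
        lab = z[n_train - cfg.label_length : n_train].T
        dec_x = np.concatenate([lab, np.zeros((P, cfg.horizon))], axis=1)
        future_weeks = weeks[n_train - 1] + 1 + np.arange(cfg.horizon)
        dec_w = np.concatenate(
            [np.tile(weeks[n_train - cfg.label_length : n_train], (P, 1)),
             np.tile(future_weeks, (P, 1))], axis=1
        )
        self.network.eval()
        out = self.network(enc_x, enc_w, dec_x, dec_w, np.arange(P)).data
        zhat = out[:, cfg.label_length : cfg.label_length + horizon]
        yhat = zhat * self.sd[:, None] + self.mu[:, None]
        rows = [
            (prov, int(future_weeks[t]), yhat[pi, t])
            for pi, prov in enumerate(self.model.provinces)
            for t in range(horizon)
        ]
        return pd.DataFrame(rows, columns=["province", "week", "value"])

    def save_weights(self, path) -> None:
        """Checkpoint all network parameters plus the scaler to one file."""
        arrays = {f"p{i}": a for i, a in enumerate(self.network.state_dict())}
        np.savez(path, mu=self.mu, sd=self.sd, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.mu = data["mu"]
            self.sd = data["sd"]
            n = len([k for k in data.files if k.startswith("p")])
            self.network.load_state_dict([data[f"p{i}"] for i in range(n)])

    def summary(self) -> str:
        log = self.training_log
        return "\n".join(
            [
                "Indicator forecaster (ProbSparse attention encoder–decoder)",
                f"provinces: {len(self.model.provinces)}  "
                f"weeks: {len(self.model.weeks)}  split: week {self.split_week}",
                f"config: d={self.model.config.d_model}, "
                f"heads={self.model.config.n_heads}, "
                f"L_enc={self.model.config.input_length}, "
                f"label={self.model.config.label_length}, "
                f"horizon={self.model.config.horizon}, "
                f"epochs={self.model.config.epochs}",
                f"train loss: first epoch {log.train_loss.iloc[0]:.6f}, "
                f"final epoch {log.train_loss.iloc[-1]:.6f}",
            ]
        )


def persistence_forecast(
    series: pd.DataFrame, split_week: int, horizon: int, value_col: str = "value"
) -> pd.DataFrame:
    """Naive baseline: repeat the last observed value across the horizon."""
    if {"province", "week"}.issubset(series.columns):
        wide = _to_wide(series, value_col)
    else:
        wide = series.sort_index()
    last = wide.loc[wide.index <= split_week].iloc[-1]
    rows = [
        (prov, split_week + t, last[prov])
        for prov in wide.columns
        for t in range(1, horizon + 1)
    ]
    return pd.DataFrame(rows, columns=["province", "week", "value"])
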