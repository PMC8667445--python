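"""The temporal branch: GRU encoder-decoder with damped attention.

The embedded sequence ``X_e`` (l x m) is consumed by two independent
(by default bidirectional) GRU passes over the same input -- there is no
autoregressive feedback; the "decoder" simply provides a second view:

    K_i = Encoder(X_e,i, theta_E, K_{i-1})     keys   (l x h)
    Q_i = Decoder(X_e,i, theta_D, Q_{i-1})     queries (l x h)
    V   = K                                    values

Attention alignment produces the second-order preference matrix ``B``:

    B_i = softmax(Q_i K^T) (x) G_i

with the Gaussian damping matrix

    G_ij = exp(-(i-j)^2 / (2 sigma))  if |i-j| <= sigma, else 0

(note the division by 2*sigma -- a length threshold, not a variance).
The softmax runs over all l positions first; damping is applied after,
with no renormalization, so rows of ``B`` sum to at most 1 and are
exactly zero outside the band.

The first-order preference is ``A~ = B V``, linearly projected from
hidden width h back to embedding width m so that row-wise dot products
with ``X_e`` are defined (with ``tie_widths`` the projection is the
identity and h = m).  Per-position scores

    s_i = W_i * (A~_i . X_e,i)

use a trainable non-negative weight vector W (softplus-reparameterized)
and sum, bias-free, to the pre-sigmoid branch output: the bar-plot
decomposition of ``y_t`` is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, glorot_uniform
from .codec import DEFAULT_LENGTH, encode_batch
from .config import RunConfig
from .errors import NotFittedError

__all__ = [
    "TemporalConfig",
    "TemporalParams",
    "PositionScores",
    "build_damping_matrix",
    "init_temporal_params",
    "encode_decode",
    "align",
    "first_order",
    "position_scores",
    "temporal_forward",
    "temporal_details",
    "train_temporal",
]


def build_damping_matrix(length: int, sigma: float) -> np.ndarray:
    """Gaussian band matrix with hard cutoff beyond ``sigma`` positions."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    i = np.arange(length)
    d = i[:, None] - i[None, :]
    g = np.exp(-(d.astype(np.float64) ** 2) / (2.0 * sigma))
    g[np.abs(d) > sigma] = 0.0
    return g


@dataclass(frozen=True)
class TemporalConfig:
    length: int = DEFAULT_LENGTH
    m: int = 32  # embedding width
    hidden: int = 32  # per GRU direction
    sigma: float = 3.0
    bidirectional: bool = True
    tie_widths: bool = False  # h == m with identity projection

    @property
    def h(self) -> int:
        return self.hidden * (2 if self.bidirectional else 1)


@dataclass
class TemporalParams:
    """Opaque, serializable parameter set of the temporal branch."""

    params: dict[str, Tensor]
    config: TemporalConfig = field(default_factory=TemporalConfig)
    version: str = "1"

    @property
    def fitted(self) -> bool:
        return bool(self.params)

    @property
    def damping(self) -> np.ndarray:
        return build_damping_matrix(self.config.length, self.config.sigma)


def _gru_param_block(rng, m: int, h: int, prefix: str, params: dict[str, Tensor]) -> None:
    params[f"{prefix}_wx"] = Tensor(glorot_uniform(rng, (m, 3 * h), m, h), requires_grad=True)
    params[f"{prefix}_wh"] = Tensor(glorot_uniform(rng, (h, 3 * h), h, h), requires_grad=True)
    params[f"{prefix}_b"] = Tensor(np.zeros(3 * h), requires_grad=True)


def init_temporal_params(config: TemporalConfig = TemporalConfig(), seed: int = 0) -> TemporalParams:
    if config.tie_widths and config.h != config.m:
        raise ValueError(
            f"tie_widths requires hidden width {config.h} == embedding width {config.m}"
        )
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {
        "embed": Tensor(rng.normal(0.0, 0.3, size=(4, config.m)), requires_grad=True),
        "w_raw": Tensor(np.zeros(config.length), requires_grad=True),
    }
    directions = ("fwd", "bwd") if config.bidirectional else ("fwd",)
    for side in ("enc", "dec"):
        for d in directions:
            _gru_param_block(rng, config.m, config.hidden, f"{side}_{d}", p)
    if not config.tie_widths:
        p["proj"] = Tensor(
            glorot_uniform(rng, (config.h, config.m), config.h, config.m), requires_grad=True
        )
    return TemporalParams(params=p, config=config)


def _require_fitted(tp: TemporalParams) -> None:
    if not tp.fitted:
        raise NotFittedError("temporal branch has no parameters; train or load first")


def _gru_pass(xe: Tensor, tp: TemporalParams, side: str) -> Tensor:
    """Hidden states (B, l, h) of one (bi)GRU over the embedded input."""
    cfg = tp.config
    batch, length = xe.shape[0], cfg.length
    outputs = []
    directions = ("fwd", "bwd") if cfg.bidirectional else ("fwd",)
    for d in directions:
        wx = tp.params[f"{side}_{d}_wx"]
        wh = tp.params[f"{side}_{d}_wh"]
        b = tp.params[f"{side}_{d}_b"]
        hdim = cfg.hidden
        h = Tensor(np.zeros((batch, hdim)))
        states: list[Tensor] = []
        order = range(length) if d == "fwd" else range(length - 1, -1, -1)
        for t in order:
            x_t = xe[:, t, :]
            gx = x_t @ wx + b
            gh = h @ wh
            r = (gx[:, 0:hdim] + gh[:, 0:hdim]).sigmoid()
            z = (gx[:, hdim : 2 * hdim] + gh[:, hdim : 2 * hdim]).sigmoid()
            n = (gx[:, 2 * hdim : 3 * hdim] + r * gh[:, 2 * hdim : 3 * hdim]).tanh()
            h = (1.0 - z) * n + z * h
            states.append(h)
        if d == "bwd":
            states = states[::-1]
        outputs.append(ad.stack_rows(states))
    return outputs[0] if len(outputs) == 1 else ad.concatenate(outputs, axis=2)


def _embed_graph(oh: np.ndarray, tp: TemporalParams) -> Tensor:
    batch = oh.shape[0]
    cfg = tp.config
    flat = Tensor(oh.reshape(batch * cfg.length, 4))
    return (flat @ tp.params["embed"]).reshape(batch, cfg.length, cfg.m)


def _project(atilde: Tensor, tp: TemporalParams) -> Tensor:
    cfg = tp.config
    if cfg.tie_widths:
        return atilde
    batch = atilde.shape[0]
    return (atilde.reshape(batch * cfg.length, cfg.h) @ tp.params["proj"]).reshape(
        batch, cfg.length, cfg.m
    )


def _forward_graph(oh: np.ndarray, tp: TemporalParams) -> dict[str, Tensor]:
    cfg = tp.config
    xe = _embed_graph(np.asarray(oh, dtype=np.float64), tp)
    k = _gru_pass(xe, tp, "enc")
    q = _gru_pass(xe, tp, "dec")
    scores = q @ k.swapaxes(1, 2)
    b = ad.softmax(scores, axis=-1) * Tensor(tp.damping[None])
    atilde = _project(b @ k, tp)  # V = K
    w = tp.params["w_raw"].softplus()
    s = (atilde * xe).sum(axis=2) * w.reshape(1, cfg.length)
    pre = s.sum(axis=1)
    return {"xe": xe, "K": k, "Q": q, "B": b, "atilde": atilde, "scores": s, "pre": pre,
            "y": pre.sigmoid(), "w": w}


# ---------------------------------------------------------------------------
# public (numpy) operations


def encode_decode(xe: np.ndarray, tp: TemporalParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keys K, queries Q and values V (= K) for an embedded input.

    ``xe`` may be (l, m) or batched (B, l, m); K and Q are (l, h) per
    input with h = 2 x hidden for the bidirectional default.
    """
    _require_fitted(tp)
    xe = np.asarray(xe, dtype=np.float64)
    single = xe.ndim == 2
    xt = Tensor(xe[None] if single else xe)
    k = _gru_pass(xt, tp, "enc").data
    q = _gru_pass(xt, tp, "dec").data
    if single:
        k, q = k[0], q[0]
    return k, q.copy(), k.copy()


def align(q: np.ndarray, k: np.ndarray, damping: np.ndarray) -> np.ndarray:
    """Second-order preference: row-softmax of Q K^T, then Gaussian damping.

    No renormalization after damping; rows sum to at most 1 and vanish
    outside the band.
    """
    q = np.asarray(q, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if q.shape != k.shape:
        raise ValueError(f"Q and K shapes differ: {q.shape} vs {k.shape}")
    if damping.shape != (q.shape[-2], k.shape[-2]):
        raise ValueError(f"damping shape {damping.shape} incompatible with {q.shape}")
    scores = q @ np.swapaxes(k, -1, -2)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    soft = e / e.sum(axis=-1, keepdims=True)
    return soft * damping


def first_order(b: np.ndarray, v: np.ndarray, projection: np.ndarray | None = None) -> np.ndarray:
    """First-order preference ``A~ = B V``, optionally projected h -> m."""
    b = np.asarray(b, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if b.shape[-1] != v.shape[-2]:
        raise ValueError(f"B shape {b.shape} incompatible with V shape {v.shape}")
    out = b @ v
    if projection is not None:
        projection = np.asarray(projection, dtype=np.float64)
        if out.shape[-1] != projection.shape[0]:
            raise ValueError(
                f"projection shape {projection.shape} incompatible with width {out.shape[-1]}"
            )
        out = out @ projection
    return out


@dataclass(frozen=True)
class PositionScores:
    """Additive per-position decomposition of the pre-sigmoid output."""

    values: np.ndarray  # length-l
    baseline: float  # arithmetic mean of values

    @property
    def total(self) -> float:
        return float(self.values.sum())


def position_scores(atilde: np.ndarray, xe: np.ndarray, w: np.ndarray) -> PositionScores:
    """``s_i = W_i * (A~_i . X_e,i)``; the values sum to the pre-sigmoid y_t."""
    atilde = np.asarray(atilde, dtype=np.float64)
    xe = np.asarray(xe, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if atilde.shape != xe.shape:
        raise ValueError(f"shapes differ: {atilde.shape} vs {xe.shape}")
    if (w < 0).any():
        raise ValueError("position weights must be non-negative")
    values = w * np.einsum("ij,ij->i", atilde, xe)
    return PositionScores(values=values, baseline=float(values.mean()))


def temporal_forward(seqs_or_oh, tp: TemporalParams) -> np.ndarray | float:
    """Branch score y_t = sigmoid(sum_i s_i) in (0, 1); deterministic."""
    _require_fitted(tp)
    if isinstance(seqs_or_oh, str):
        oh = encode_batch([seqs_or_oh], tp.config.length)
        return float(_forward_graph(oh, tp)["y"].data[0])
    if isinstance(seqs_or_oh, np.ndarray) and seqs_or_oh.ndim == 2:
        return float(_forward_graph(seqs_or_oh[None], tp)["y"].data[0])
    oh = (
        seqs_or_oh
        if isinstance(seqs_or_oh, np.ndarray)
        else encode_batch(list(seqs_or_oh), tp.config.length)
    )
    return _forward_graph(oh, tp)["y"].data


def temporal_details(seq: str, tp: TemporalParams) -> dict[str, np.ndarray | float]:
    """All intermediate quantities for one guide (for interpretability)."""
    _require_fitted(tp)
    oh = encode_batch([seq], tp.config.length)
    g = _forward_graph(oh, tp)
    return {
        "xe": g["xe"].data[0],
        "K": g["K"].data[0],
        "Q": g["Q"].data[0],
        "B": g["B"].data[0],
        "atilde": g["atilde"].data[0],
        "position_scores": g["scores"].data[0],
        "w": g["w"].data,
        "pre_sigmoid": float(g["pre"].data[0]),
        "y": float(g["y"].data[0]),
    }


def train_temporal(
    sequences,
    activities,
    config: RunConfig = RunConfig(),
    arch: TemporalConfig = TemporalConfig(),
    params: TemporalParams | None = None,
) -> TemporalParams:
    """Fit the branch with Adam on MSE; reproducible for a fixed seed.

    The softplus reparameterization keeps the position-weight vector W
    non-negative after every update by construction.
    """
    y = np.asarray(activities, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty dataset")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("activities must lie in [0, 1]")
    oh = encode_batch(list(sequences), arch.length)
    tp = params if params is not None else init_temporal_params(arch, seed=config.seed)
    opt = Adam(tp.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            opt.zero_grad()
            pred = _forward_graph(oh[idx], tp)["y"]
            loss = ((pred - Tensor(y[idx])) ** 2.0).mean()
            loss.backward()
            opt.step()
    return tp
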