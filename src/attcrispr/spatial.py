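"""The spatial branch: attention-gated CNN over the one-hot image.

The one-hot image ``X_oh`` (l x 4) is refined by a spatial attention
module before any feature extraction:

    X_mc = ReLU(f_{3x4}(X_oh))                    multi-channel map
    A_s  = sigmoid(f_{3x2}([AvgPool(X_mc); MaxPool(X_mc)]))
    X_rf = A_s (x) X_oh                           element-wise gate

where ``f_{pxq}`` is a same-padded convolution with a p x q filter and
the pooling is across channels, producing a 2-channel (average, max)
summary map.  ``A_s`` is the spatial first-order preference: sigmoid-
bounded in (0, 1), shaped like ``X_oh``, and the ONLY path from the
input into the downstream network, so it fully gates the prediction.

Downstream, parallel 1-D convolutions of several heights spanning all 4
columns extract features from ``X_rf``; their concatenation is
flattened into an MLP with a sigmoid head, giving the branch score
``y_s`` in (0, 1).  Training minimizes MSE with Adam.
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
    "SpatialConfig",
    "SpatialParams",
    "init_spatial_params",
    "spatial_attention",
    "spatial_forward",
    "train_spatial",
]


@dataclass(frozen=True)
class SpatialConfig:
    length: int = DEFAULT_LENGTH
    attention_channels: int = 8  # channel count of the 3x4 attention conv
    kernel_heights: tuple[int, ...] = (3, 5, 7)
    filters: int = 32  # per kernel height
    hidden: int = 64
    dropout: float = 0.2
    # boundary handling of the attention convs: "partial" rescales
    # zero-padded windows by total/valid cells; "mean-edge" pads the
    # one-hot image with its uniform-composition mean and replicates
    # borders of the pooled map
    attention_pad: str = "partial"


@dataclass
class SpatialParams:
    """Opaque, serializable parameter set of the spatial branch."""

    params: dict[str, Tensor]
    config: SpatialConfig = field(default_factory=SpatialConfig)
    version: str = "1"

    @property
    def fitted(self) -> bool:
        return bool(self.params)


def init_spatial_params(config: SpatialConfig = SpatialConfig(), seed: int = 0) -> SpatialParams:
    rng = np.random.default_rng(seed)
    c = config.attention_channels
    p: dict[str, Tensor] = {
        # attention path
        "att_w1": Tensor(glorot_uniform(rng, (c, 1, 3, 4), 12, 12 * c), requires_grad=True),
        "att_b1": Tensor(np.zeros(c), requires_grad=True),
        # zero logit init: A_s starts exactly flat at 0.5, so any structure
        # in the mean attention map is learned rather than initialization noise
        "att_w2": Tensor(np.zeros((1, 2, 3, 2)), requires_grad=True),
        "att_b2": Tensor(np.zeros(1), requires_grad=True),
    }
    # feature extractor
    for k in config.kernel_heights:
        fan_in = k * 4
        p[f"fe_w{k}"] = Tensor(
            glorot_uniform(rng, (config.filters, 1, k, 4), fan_in, fan_in * config.filters),
            requires_grad=True,
        )
        p[f"fe_b{k}"] = Tensor(np.zeros(config.filters), requires_grad=True)
    flat = config.filters * len(config.kernel_heights) * config.length
    p["mlp_w1"] = Tensor(glorot_uniform(rng, (flat, config.hidden), flat, config.hidden), requires_grad=True)
    p["mlp_b1"] = Tensor(np.zeros(config.hidden), requires_grad=True)
    p["mlp_w2"] = Tensor(glorot_uniform(rng, (config.hidden, 1), config.hidden, 1), requires_grad=True)
    p["mlp_b2"] = Tensor(np.zeros(1), requires_grad=True)
    return SpatialParams(params=p, config=config)


def _require_fitted(sp: SpatialParams) -> None:
    if not sp.fitted:
        raise NotFittedError("spatial branch has no parameters; train or load first")


def _boundary_scale(shape_hw: tuple[int, int], kh: int, kw: int,
                    pad: tuple[tuple[int, int], tuple[int, int]]) -> np.ndarray:
    """Partial-convolution rescaling: total / valid window cells."""
    ones = np.ones((1, 1) + shape_hw)
    (ph0, ph1), (pw0, pw1) = pad
    padded = np.pad(ones, ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(2, 3))
    valid = win.sum(axis=(-1, -2))[0, 0]
    return (kh * kw) / valid


def _att_conv(x: Tensor, w: Tensor, b: Tensor, pad, scheme: str, first: bool) -> Tensor:
    """One attention conv with the configured boundary handling.

    Small sequence images make the border a sizeable fraction of the
    map, and naive padding imprints systematic row offsets on the
    attention logits; both schemes here keep the expected logit roughly
    flat across positions.
    """
    if scheme == "partial":
        out = ad.conv2d(x, w, None, pad, pad_mode="zero")
        kh, kw = w.shape[2], w.shape[3]
        scale = _boundary_scale((x.shape[2], x.shape[3]), kh, kw, pad)
        return out * Tensor(scale[None, None]) + b.reshape(1, -1, 1, 1)
    if scheme == "mean-edge":
        if first:  # one-hot input: pad with its uniform-composition mean
            return ad.conv2d(x, w, b, pad, pad_mode="constant", pad_value=0.25)
        return ad.conv2d(x, w, b, pad, pad_mode="edge")
    raise ValueError(f"unknown attention_pad scheme {scheme!r}")


def _attention_graph(x: Tensor, sp: SpatialParams) -> tuple[Tensor, Tensor]:
    """(A_s, X_rf) tensors for a (B, 1, l, 4) input image."""
    p = sp.params
    scheme = sp.config.attention_pad
    xmc = _att_conv(x, p["att_w1"], p["att_b1"], ((1, 1), (1, 2)), scheme, first=True)
    pooled = ad.concatenate(
        [xmc.mean(axis=1, keepdims=True), xmc.max(axis=1, keepdims=True)], axis=1
    )
    a_s = _att_conv(pooled, p["att_w2"], p["att_b2"], ((1, 1), (0, 1)), scheme, first=False).sigmoid()
    x_rf = a_s * x
    return a_s, x_rf


def _forward_graph(
    oh: np.ndarray,
    sp: SpatialParams,
    dropout_rng: np.random.Generator | None = None,
    attention_override: np.ndarray | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """(y, A_s, X_rf) for a batch of one-hot images (B, l, 4)."""
    cfg = sp.config
    x = Tensor(np.asarray(oh, dtype=np.float64).reshape(-1, 1, cfg.length, 4))
    a_s, x_rf = _attention_graph(x, sp)
    if attention_override is not None:
        a_s = Tensor(np.broadcast_to(
            np.asarray(attention_override, dtype=np.float64).reshape(-1, 1, cfg.length, 4),
            x.shape,
        ).copy())
        x_rf = a_s * x
    p = sp.params
    feats = [
        ad.conv2d(
            x_rf, p[f"fe_w{k}"], p[f"fe_b{k}"], ((k // 2, k // 2), (0, 0)), pad_mode="zero"
        ).relu()
        for k in cfg.kernel_heights
    ]
    flat = ad.concatenate(feats, axis=1).reshape(x.shape[0], -1)
    h = (flat @ p["mlp_w1"] + p["mlp_b1"]).relu()
    h = ad.dropout(h, cfg.dropout, dropout_rng)
    y = (h @ p["mlp_w2"] + p["mlp_b2"]).sigmoid().reshape(-1)
    return y, a_s, x_rf


def spatial_attention(oh: np.ndarray, sp: SpatialParams) -> tuple[np.ndarray, np.ndarray]:
    """Spatial attention map A_s and refined input X_rf for one image or a batch.

    A_s has the same shape as the input with entries strictly in (0, 1);
    X_rf is its element-wise product with the binary image, so it is zero
    exactly where the image is zero.
    """
    _require_fitted(sp)
    oh = np.asarray(oh, dtype=np.float64)
    single = oh.ndim == 2
    _, a_s, x_rf = _forward_graph(oh[None] if single else oh, sp)
    l4 = (sp.config.length, 4)
    a = a_s.data.reshape(-1, *l4)
    r = x_rf.data.reshape(-1, *l4)
    return (a[0], r[0]) if single else (a, r)


def spatial_forward(
    seqs_or_oh,
    sp: SpatialParams,
    attention_override: np.ndarray | None = None,
) -> np.ndarray | float:
    """Branch score y_s in (0, 1); accepts sequences or one-hot arrays.

    ``attention_override`` replaces A_s with a fixed map (used to probe
    the gating invariant); inference never applies dropout, so repeated
    calls are bit-identical.
    """
    _require_fitted(sp)
    if isinstance(seqs_or_oh, str):
        oh = encode_batch([seqs_or_oh], sp.config.length)
        return float(_forward_graph(oh, sp, attention_override=attention_override)[0].data[0])
    if isinstance(seqs_or_oh, np.ndarray) and seqs_or_oh.ndim == 2:
        return float(
            _forward_graph(seqs_or_oh[None], sp, attention_override=attention_override)[0].data[0]
        )
    oh = (
        seqs_or_oh
        if isinstance(seqs_or_oh, np.ndarray)
        else encode_batch(list(seqs_or_oh), sp.config.length)
    )
    return _forward_graph(oh, sp, attention_override=attention_override)[0].data


def train_spatial(
    sequences,
    activities,
    config: RunConfig = RunConfig(),
    arch: SpatialConfig = SpatialConfig(),
    params: SpatialParams | None = None,
) -> SpatialParams:
    """Fit the branch with Adam on MSE; reproducible for a fixed seed."""
    y = np.asarray(activities, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty dataset")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("activities must lie in [0, 1]")
    oh = encode_batch(list(sequences), arch.length)
    sp = params if params is not None else init_spatial_params(arch, seed=config.seed)
    opt = Adam(sp.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            opt.zero_grad()
            pred, _, _ = _forward_graph(oh[idx], sp, dropout_rng=rng)
            loss = ((pred - Tensor(y[idx])) ** 2.0).mean()
            loss.backward()
            opt.step()
    return sp
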