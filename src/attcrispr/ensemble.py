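"""Stacking ensemble of the bio, spatial and temporal branch scores.

The three branch outputs are combined by a learned linear weighting

    y = W [y_bio; y_s; y_t]        W in R^3 (+ optional bias, off by default)

with component order fixed as (bio, spatial, temporal).  Training follows
a freeze-then-finetune protocol: the branches are trained first, then
frozen while only the stacking weights W are learned (phase 1, provable
via parameter checksums), and finally the entire network is fine-tuned
end-to-end at a reduced learning rate (phase 2).

Two ensemble modes exist: ``enac`` stacks only the two sequence branches
(the bio slot is fixed at zero), ``stac`` additionally includes the
hand-crafted biological-feature branch.  Single-branch "models"
(``spac``, ``tac``) are represented in the same container with selector
weights, so the experiment harness can treat all variants uniformly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import spatial as spa
from . import temporal as tem
from .autodiff import Adam, Tensor
from .codec import encode_batch
from .config import RunConfig, replace_seed
from .errors import NotFittedError, SchemaError

__all__ = [
    "RunConfig",
    "replace_seed",
    "EnsembleModel",
    "stack_forward",
    "train_stacked",
    "train_variant",
    "predict",
    "param_checksum",
    "save_model",
    "load_model",
]

STACK_ORDER = ("bio", "spatial", "temporal")


def param_checksum(params: dict[str, Tensor]) -> str:
    """SHA-256 over the sorted parameter arrays (bit-exact identity)."""
    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name].data).tobytes())
    return h.hexdigest()


@dataclass
class EnsembleModel:
    """Full model state: branch parameters, feature stats, stack weights."""

    mode: str  # spac | tac | enac | stac
    spatial: spa.SpatialParams | None = None
    temporal: tem.TemporalParams | None = None
    bio: feat.BioParams | None = None
    stats: feat.StandardizationStats | None = None
    stack_w: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stack_bias: float | None = None  # None = bias disabled
    version: str = "1"
    meta: dict = field(default_factory=dict)


def stack_forward(y_bio, y_s, y_t, w: np.ndarray, bias: float | None = None):
    """Linear stack ``y = w1*y_bio + w2*y_s + w3*y_t (+ bias)``."""
    parts = [np.asarray(v, dtype=np.float64) for v in (y_bio, y_s, y_t)]
    for v in parts:
        if not np.all(np.isfinite(v)):
            raise ValueError("branch scores must be finite")
    w = np.asarray(w, dtype=np.float64)
    out = w[0] * parts[0] + w[1] * parts[1] + w[2] * parts[2]
    if bias is not None:
        out = out + bias
    return out


def _branch_scores(
    model: EnsembleModel, seqs: list[str], features: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(seqs)
    y_s = np.zeros(n)
    y_t = np.zeros(n)
    y_b = np.zeros(n)
    if model.spatial is not None:
        y_s = np.atleast_1d(spa.spatial_forward(seqs, model.spatial))
    if model.temporal is not None:
        y_t = np.atleast_1d(tem.temporal_forward(seqs, model.temporal))
    if model.mode == "stac":
        if model.bio is None or model.stats is None:
            raise NotFittedError("standard mode requires a fitted bio branch")
        if features is None:
            features = feat.compute_feature_table(seqs)
        std, _ = feat.zscore_standardize(features, model.stats)
        y_b = feat.bio_forward(std, model.bio)
    return y_b, y_s, y_t


def predict(model: EnsembleModel, seqs, features: pd.DataFrame | None = None) -> np.ndarray:
    """Per-guide final scores; order-preserving and deterministic.

    In ``stac`` mode, ``features`` may be omitted when every fitted
    feature is sequence-computable; externally supplied features must
    match the training schema.
    """
    seqs = [seqs] if isinstance(seqs, str) else list(seqs)
    y_b, y_s, y_t = _branch_scores(model, seqs, features)
    return stack_forward(y_b, y_s, y_t, model.stack_w, model.stack_bias)


def _simplex_weights(raw: Tensor, mask: Tensor) -> Tensor:
    """Softmax of the raw logits over the included (masked) components."""
    e = raw.exp() * mask
    return e * (e.sum() ** -1.0)


def _fit_stack_weights(
    targets: np.ndarray,
    y_b: np.ndarray,
    y_s: np.ndarray,
    y_t: np.ndarray,
    use_bio: bool,
    config: RunConfig,
    simplex: bool = False,
) -> np.ndarray:
    """Phase 1: learn W on frozen branch outputs (full-batch Adam).

    With ``simplex`` the weights are softmax-reparameterized so they
    stay non-negative and sum to one over the included branches.
    """
    mask = Tensor(np.array([1.0 if use_bio else 0.0, 1.0, 1.0]))
    if simplex:
        w = Tensor(np.zeros(3), requires_grad=True)
    else:
        w = Tensor(np.array([1.0 / 3 if use_bio else 0.0, 0.5, 0.5]), requires_grad=True)
    x = Tensor(np.stack([y_b, y_s, y_t], axis=1))  # (n, 3)
    t = Tensor(targets)
    opt = Adam({"w": w}, lr=config.stack_lr)
    for _ in range(config.stack_steps):
        opt.zero_grad()
        wm = _simplex_weights(w, mask) if simplex else w * mask
        pred = x @ wm
        loss = ((pred - t) ** 2.0).mean()
        loss.backward()
        opt.step()
    wm = _simplex_weights(w, mask) if simplex else w * mask
    return wm.data


def _finetune(
    model: EnsembleModel,
    seqs: list[str],
    targets: np.ndarray,
    features_std: np.ndarray | None,
    config: RunConfig,
) -> None:
    """Phase 2: unfreeze everything, jointly fine-tune at reduced lr."""
    use_bio = model.mode == "stac"
    params: dict[str, Tensor] = {}
    for prefix, branch in (("s", model.spatial), ("t", model.temporal)):
        for k, v in branch.params.items():
            params[f"{prefix}/{k}"] = v
    if use_bio:
        for k, v in model.bio.params.items():
            params[f"b/{k}"] = v
    w = Tensor(model.stack_w.copy(), requires_grad=True)
    params["stack_w"] = w
    mask = Tensor(np.array([1.0 if use_bio else 0.0, 1.0, 1.0]))

    oh = encode_batch(seqs, model.spatial.config.length)
    opt = Adam(params, lr=config.lr * config.finetune_lr_factor)
    rng = np.random.default_rng(config.seed + 7)
    n = len(targets)
    for _ in range(config.finetune_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            opt.zero_grad()
            y_s, _, _ = spa._forward_graph(oh[idx], model.spatial, dropout_rng=rng)
            y_t = tem._forward_graph(oh[idx], model.temporal)["y"]
            wm = w * mask
            pred = wm[1] * y_s + wm[2] * y_t
            if use_bio:
                y_b = feat._bio_graph(Tensor(features_std[idx]), model.bio)
                pred = pred + wm[0] * y_b
            loss = ((pred - Tensor(targets[idx])) ** 2.0).mean()
            loss.backward()
            opt.step()
    model.stack_w = w.data * mask.data


def train_stacked(
    sequences,
    activities,
    config: RunConfig = RunConfig(),
    mode: str = "enac",
    spatial_arch: spa.SpatialConfig = spa.SpatialConfig(),
    temporal_arch: tem.TemporalConfig = tem.TemporalConfig(),
    features: pd.DataFrame | None = None,
    finetune: bool = True,
    simplex: bool = False,
) -> EnsembleModel:
    """Two-phase stacked training; see the module docstring.

    The returned model's ``meta`` records branch checksums before and
    after phase 1, making the freeze contract externally verifiable.
    ``simplex`` constrains the stack weights to the probability simplex
    over the included branches (phase 1 only; fine-tuning then keeps
    the weights unconstrained).
    """
    if mode not in {"enac", "stac"}:
        raise ValueError(f"mode must be 'enac' or 'stac', got {mode!r}")
    seqs = list(sequences)
    y = np.asarray(activities, dtype=np.float64)

    spatial = spa.train_spatial(seqs, y, config, spatial_arch)
    temporal = tem.train_temporal(seqs, y, replace_seed(config, config.seed + 1), temporal_arch)

    model = EnsembleModel(mode=mode, spatial=spatial, temporal=temporal)
    features_std = None
    if mode == "stac":
        table = feat.compute_feature_table(seqs, extra=features)
        std, stats = feat.zscore_standardize(table)
        model.stats = stats
        model.bio = feat.train_bio(std, y, seed=config.seed + 2)
        features_std = std.to_numpy(dtype=np.float64)

    # phase 1: branches frozen, only W learns
    before = {
        "spatial": param_checksum(spatial.params),
        "temporal": param_checksum(temporal.params),
    }
    if model.bio is not None:
        before["bio"] = param_checksum(model.bio.params)
    y_b, y_s, y_t = _branch_scores(model, seqs, features)
    model.stack_w = _fit_stack_weights(y, y_b, y_s, y_t, mode == "stac", config, simplex)
    after = {
        "spatial": param_checksum(spatial.params),
        "temporal": param_checksum(temporal.params),
    }
    if model.bio is not None:
        after["bio"] = param_checksum(model.bio.params)
    model.meta["phase1_checksums"] = {"before": before, "after": after}

    # phase 2: joint fine-tuning
    if finetune and config.finetune_epochs > 0:
        _finetune(model, seqs, y, features_std, config)
    return model


def train_variant(variant: str, data: pd.DataFrame, split, config: RunConfig) -> EnsembleModel:
    """Train one ablation variant (spac/tac/enac/stac) on a split's train set."""
    seqs = data["sequence"].iloc[split.train].tolist()
    y = data["activity"].iloc[split.train].to_numpy(dtype=np.float64)
    variant = variant.lower()
    if variant == "spac":
        params = spa.train_spatial(seqs, y, config)
        return EnsembleModel(mode="spac", spatial=params, stack_w=np.array([0.0, 1.0, 0.0]))
    if variant == "tac":
        params = tem.train_temporal(seqs, y, config)
        return EnsembleModel(mode="tac", temporal=params, stack_w=np.array([0.0, 0.0, 1.0]))
    if variant in {"enac", "stac"}:
        return train_stacked(seqs, y, config, mode=variant)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# checkpointing (single .npz container, float64 preserved bit-exactly)


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(json.dumps(meta, sort_keys=True).encode()).hexdigest()[:16]


def save_model(model: EnsembleModel, path) -> None:
    arrays: dict[str, np.ndarray] = {"stack_w": model.stack_w}
    meta: dict = {"mode": model.mode, "version": model.version,
                  "stack_bias": model.stack_bias, "meta": model.meta}
    if model.spatial is not None:
        meta["spatial_config"] = asdict(model.spatial.config)
        for k, v in model.spatial.params.items():
            arrays[f"spatial/{k}"] = v.data
    if model.temporal is not None:
        meta["temporal_config"] = asdict(model.temporal.config)
        for k, v in model.temporal.params.items():
            arrays[f"temporal/{k}"] = v.data
    if model.bio is not None:
        meta["bio"] = {"names": list(model.bio.names), "hidden": model.bio.hidden}
        for k, v in model.bio.params.items():
            arrays[f"bio/{k}"] = v.data
    if model.stats is not None:
        meta["stats_names"] = list(model.stats.names)
        arrays["stats/mean"] = model.stats.mean
        arrays["stats/sd"] = model.stats.sd
    meta["config_hash"] = _config_hash({k: v for k, v in meta.items() if k != "meta"})
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:  # keep the exact filename (no .npz appended)
        np.savez(fh, **arrays)


def load_model(path) -> EnsembleModel:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    model = EnsembleModel(
        mode=meta["mode"],
        stack_w=arrays.pop("stack_w"),
        stack_bias=meta.get("stack_bias"),
        version=meta.get("version", "1"),
        meta=meta.get("meta", {}),
    )

    def collect(prefix: str) -> dict[str, Tensor]:
        return {
            k.split("/", 1)[1]: Tensor(arrays[k], requires_grad=True)
            for k in list(arrays)
            if k.startswith(prefix + "/")
        }

    if "spatial_config" in meta:
        cfg = spa.SpatialConfig(**{
            **meta["spatial_config"],
            "kernel_heights": tuple(meta["spatial_config"]["kernel_heights"]),
        })
        model.spatial = spa.SpatialParams(params=collect("spatial"), config=cfg)
    if "temporal_config" in meta:
        model.temporal = tem.TemporalParams(
            params=collect("temporal"), config=tem.TemporalConfig(**meta["temporal_config"])
        )
    if "bio" in meta:
        model.bio = feat.BioParams(
            params=collect("bio"),
            names=tuple(meta["bio"]["names"]),
            hidden=meta["bio"]["hidden"],
        )
    if "stats_names" in meta:
        model.stats = feat.StandardizationStats(
            names=tuple(meta["stats_names"]),
            mean=arrays["stats/mean"],
            sd=arrays["stats/sd"],
        )
    return model
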