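"""Hand-crafted biological features and the small bio-feature network.

Sequence-intrinsic features (GC content, melting temperature) are
computed natively; structure-derived features (per-position secondary
structure accessibility, stem-loop indicators) are accepted from an
external CSV produced by any RNA-folding tool, keeping the core free of
a folding dependency.  Features are Z-score standardized with statistics
learned on the training split only, then reduced to a scalar branch
score ``y_bio`` in (0, 1) by a one-hidden-layer perceptron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .autodiff import Adam, Tensor, glorot_uniform
from .codec import normalize_sequence
from .errors import NotFittedError, SchemaError

__all__ = [
    "gc_content",
    "melting_temperature",
    "compute_feature_table",
    "StandardizationStats",
    "zscore_standardize",
    "BioParams",
    "init_bio_params",
    "bio_forward",
    "train_bio",
]


def gc_content(seq: str) -> float:
    """(#G + #C) / length, in [0, 1]."""
    s = normalize_sequence(seq)
    return (s.count("G") + s.count("C")) / len(s)


def melting_temperature(seq: str, method: str = "wallace") -> float:
    """Melting temperature in deg C.

    ``wallace``: the Wallace rule 2(A+T) + 4(G+C); ``nn``: nearest-
    neighbor thermodynamics (Biopython defaults).
    """
    s = normalize_sequence(seq)
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(s))
    if method == "nn":
        return float(MeltingTemp.Tm_NN(s))
    raise ValueError(f"unknown melting-temperature method {method!r}")


def compute_feature_table(
    seqs,
    extra: pd.DataFrame | None = None,
    tm_method: str = "wallace",
) -> pd.DataFrame:
    """Per-guide feature table: gc_content, tm, plus optional external columns.

    ``extra`` (e.g. secondary-structure accessibilities) must be aligned
    row-for-row with ``seqs``.
    """
    table = pd.DataFrame(
        {
            "gc_content": [gc_content(s) for s in seqs],
            "tm": [melting_temperature(s, tm_method) for s in seqs],
        }
    )
    if extra is not None:
        if len(extra) != len(table):
            raise SchemaError(
                f"external feature table has {len(extra)} rows for {len(table)} sequences"
            )
        for col in extra.columns:
            if col in table.columns:
                raise SchemaError(f"duplicate feature name {col!r}")
            table[col] = np.asarray(extra[col], dtype=np.float64)
    return table


@dataclass(frozen=True)
class StandardizationStats:
    """Per-feature mean/sd learned on the training split and frozen."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray


def zscore_standardize(
    table: pd.DataFrame, stats: StandardizationStats | None = None
) -> tuple[pd.DataFrame, StandardizationStats]:
    """Z-score a feature table.

    Fit mode (``stats=None``): learn mean/sd per column, dropping
    zero-variance columns with a warning; transform mode: apply the
    stored statistics (training-split stats applied to test data, never
    refit).
    """
    import warnings

    if stats is None:
        means = table.mean(axis=0)
        sds = table.std(axis=0, ddof=0)
        keep = [c for c in table.columns if sds[c] > 0]
        dropped = [c for c in table.columns if sds[c] == 0]
        if dropped:
            warnings.warn(f"dropping zero-variance feature(s): {dropped}", stacklevel=2)
        stats = StandardizationStats(
            names=tuple(keep),
            mean=means[keep].to_numpy(dtype=np.float64),
            sd=sds[keep].to_numpy(dtype=np.float64),
        )
    missing = [c for c in stats.names if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing fitted column(s) {missing}")
    values = table[list(stats.names)].to_numpy(dtype=np.float64)
    out = pd.DataFrame((values - stats.mean) / stats.sd, columns=list(stats.names))
    return out, stats


# ---------------------------------------------------------------------------
# the y_bio network


@dataclass
class BioParams:
    """Parameters of the feature perceptron (n_features -> hidden -> 1)."""

    params: dict[str, Tensor]
    names: tuple[str, ...]
    hidden: int
    version: str = "1"

    @property
    def fitted(self) -> bool:
        return bool(self.params)


def init_bio_params(names, hidden: int = 16, seed: int = 0) -> BioParams:
    rng = np.random.default_rng(seed)
    n = len(names)
    params = {
        "w1": Tensor(glorot_uniform(rng, (n, hidden), n, hidden), requires_grad=True),
        "b1": Tensor(np.zeros(hidden), requires_grad=True),
        "w2": Tensor(glorot_uniform(rng, (hidden, 1), hidden, 1), requires_grad=True),
        "b2": Tensor(np.zeros(1), requires_grad=True),
    }
    return BioParams(params=params, names=tuple(names), hidden=hidden)


def _bio_graph(x: Tensor, bp: BioParams) -> Tensor:
    h = (x @ bp.params["w1"] + bp.params["b1"]).relu()
    return (h @ bp.params["w2"] + bp.params["b2"]).sigmoid().reshape(-1)


def bio_forward(features_std: pd.DataFrame | np.ndarray, bp: BioParams) -> np.ndarray:
    """Branch score ``y_bio`` in (0, 1) per guide; deterministic."""
    if not bp.fitted:
        raise NotFittedError("bio branch has no parameters; train or load first")
    if isinstance(features_std, pd.DataFrame):
        missing = [c for c in bp.names if c not in features_std.columns]
        if missing:
            raise SchemaError(f"missing feature column(s) {missing}")
        x = features_std[list(bp.names)].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(features_std, dtype=np.float64)
        if x.shape[1] != len(bp.names):
            raise SchemaError(
                f"expected {len(bp.names)} features, got {x.shape[1]}"
            )
    return _bio_graph(Tensor(x), bp).data


def train_bio(
    features_std: pd.DataFrame,
    activities,
    hidden: int = 16,
    epochs: int = 20,
    lr: float = 1e-2,
    batch_size: int = 64,
    seed: int = 0,
) -> BioParams:
    """Fit the perceptron with Adam on MSE loss."""
    y = np.asarray(activities, dtype=np.float64)
    if len(features_std) == 0:
        raise ValueError("empty dataset")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("activities must lie in [0, 1]")
    bp = init_bio_params(features_std.columns, hidden=hidden, seed=seed)
    x = features_std.to_numpy(dtype=np.float64)
    opt = Adam(bp.params, lr=lr)
    rng = np.random.default_rng(seed)
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            opt.zero_grad()
            pred = _bio_graph(Tensor(x[idx]), bp)
            loss = ((pred - Tensor(y[idx])) ** 2.0).mean()
            loss.backward()
            opt.step()
    return bp
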