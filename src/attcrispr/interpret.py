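"""Global and local interpretability of a trained model.

Global: average the spatial attention map ``A_s`` over a dataset and
Z-score it over all l x 4 cells, giving the position x nucleotide
preference matrix.  Because the codec encodes the *complement* of the
guide, exported matrices relabel columns back to original base space so
that statements like "G is favored at position 20" read off directly.

Local: the temporal branch decomposes its pre-sigmoid output exactly
into per-position scores; positions scoring below the mean (the
baseline) are flagged as depressing the prediction.  The second-order
preference matrix ``B`` explains which neighbouring positions drive each
position's first-order preference, and a 3x3 kernel moved along its
diagonal scores candidate trimer interactions.  Flagged positions seed a
budgeted substitution search (3 variants per position -- never a 4^l
enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ensemble as ens
from . import spatial as spa
from . import temporal as tem
from .codec import BASES, COMPLEMENT_COLUMN_PERM, encode_batch
from .errors import NotFittedError

__all__ = [
    "global_preference",
    "LocalExplanation",
    "local_scores",
    "second_order_matrix",
    "SubstitutionSuggestion",
    "suggest_substitutions",
    "scan_trimer_influence",
    "DEFAULT_TRIMER_KERNEL",
]


def _spatial_of(model) -> spa.SpatialParams:
    sp = model.spatial if isinstance(model, ens.EnsembleModel) else model
    if sp is None or not sp.fitted:
        raise NotFittedError("model has no fitted spatial branch")
    return sp


def _temporal_of(model) -> tem.TemporalParams:
    tp = model.temporal if isinstance(model, ens.EnsembleModel) else model
    if tp is None or not tp.fitted:
        raise NotFittedError("model has no fitted temporal branch")
    return tp


def global_preference(model, seqs, per_position: bool = False) -> np.ndarray:
    """Z-scored mean spatial attention, in original-base column space.

    Columns follow the canonical (A, T, G, C) order but refer to the
    ORIGINAL guide nucleotides (the complement convention is undone).
    ``per_position`` Z-scores each row separately instead of all cells
    jointly.
    """
    sp = _spatial_of(model)
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty dataset")
    oh = encode_batch(seqs, sp.config.length)
    a_s, _ = spa.spatial_attention(oh, sp)
    mean_as = a_s.mean(axis=0)[:, COMPLEMENT_COLUMN_PERM]
    if per_position:
        mu = mean_as.mean(axis=1, keepdims=True)
        sd = mean_as.std(axis=1, keepdims=True)
    else:
        mu, sd = mean_as.mean(), mean_as.std()
    return (mean_as - mu) / sd


@dataclass(frozen=True)
class LocalExplanation:
    """Per-position score decomposition of the temporal branch."""

    scores: np.ndarray  # length-l, pre-sigmoid contributions
    baseline: float  # mean score (the dashed line)
    flagged: tuple[int, ...]  # 1-based positions with score < baseline


def local_scores(model, seq: str) -> LocalExplanation:
    """Per-position scores, their mean baseline, and below-baseline flags."""
    tp = _temporal_of(model)
    det = tem.temporal_details(seq, tp)
    scores = det["position_scores"]
    baseline = float(scores.mean())
    flagged = tuple(int(i + 1) for i in np.nonzero(scores < baseline)[0])
    return LocalExplanation(scores=scores, baseline=baseline, flagged=flagged)


def second_order_matrix(model, seq: str) -> np.ndarray:
    """The l x l second-order preference B for one guide (1-based axes)."""
    tp = _temporal_of(model)
    return tem.temporal_details(seq, tp)["B"]


@dataclass(frozen=True)
class SubstitutionSuggestion:
    """A single-base edit predicted to raise activity."""

    position: int  # 1-based
    original: str
    proposed: str
    delta: float  # predicted(variant) - predicted(source)


def suggest_substitutions(
    model: ens.EnsembleModel,
    seq: str,
    max_positions: int = 3,
    features=None,
) -> list[SubstitutionSuggestion]:
    """Budgeted single-base optimization seeded by flagged positions.

    Only the ``max_positions`` most-depressed below-baseline positions
    are probed, with the 3 alternative bases each, so the model is
    evaluated at most ``1 + 3 * max_positions`` times; suggestions with
    positive predicted delta are returned sorted by delta descending.
    """
    expl = local_scores(model, seq)
    if not expl.flagged:
        return []
    ranked = sorted(expl.flagged, key=lambda p: expl.scores[p - 1])[:max_positions]
    base_score = float(ens.predict(model, [seq], features)[0])
    variants: list[tuple[int, str, str]] = []
    for pos in ranked:
        orig = seq[pos - 1]
        for alt in BASES:
            if alt != orig:
                variants.append((pos, orig, alt))
    var_seqs = [seq[: p - 1] + alt + seq[p:] for (p, _, alt) in variants]
    scores = ens.predict(model, var_seqs)
    out = [
        SubstitutionSuggestion(position=p, original=o, proposed=a, delta=float(sc - base_score))
        for (p, o, a), sc in zip(variants, scores)
        if sc - base_score > 0
    ]
    return sorted(out, key=lambda s: s.delta, reverse=True)


#: cross-shaped kernel: immediate neighbours on the row/column, diagonal zero
DEFAULT_TRIMER_KERNEL = np.array(
    [[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
)


def scan_trimer_influence(b: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Slide a 3x3 kernel along the diagonal of B (experimental).

    For each center position i (1-based 2..l-1), the window of B centered
    at (i, i) is weighted by the kernel and summed; the default kernel
    emphasizes neighbour influence and ignores the diagonal itself.
    Returns a length-(l-2) vector indexed by center position.
    """
    b = np.asarray(b, dtype=np.float64)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError(f"B must be square, got shape {b.shape}")
    length = b.shape[0]
    if length < 3:
        raise ValueError("B must be at least 3 x 3")
    kernel = DEFAULT_TRIMER_KERNEL if kernel is None else np.asarray(kernel, dtype=np.float64)
    if kernel.shape != (3, 3):
        raise ValueError("kernel must be 3 x 3")
    out = np.empty(length - 2)
    for c in range(1, length - 1):
        out[c - 1] = (b[c - 1 : c + 2, c - 1 : c + 2] * kernel).sum()
    return out
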