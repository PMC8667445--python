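"""Experiment harness: splits, metrics, and repeated ablation runs.

The evaluation protocol mirrors common practice for activity screens:
each repeat reshuffles the data into train / test / validation fractions
of 76.5% / 15% / 8.5%, trains the requested model variants, and scores
the held-out test split with the Spearman rank correlation and the mean
squared error.  Repeats are aggregated as mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FRACTIONS = (0.765, 0.15, 0.085)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive index lists for one shuffled partition."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle ``range(n)`` and partition it into train/test/validation.

    Sizes: test and validation get ``round(fraction * n)``; the
    remainder goes to train.  Fractions are (train, test, validation)
    and must sum to 1.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = round(fractions[1] * n)
    n_val = round(fractions[2] * n)
    test = np.sort(perm[:n_test])
    validation = np.sort(perm[n_test : n_test + n_val])
    train = np.sort(perm[n_test + n_val :])
    return DatasetSplit(train=train, test=test, validation=validation, fractions=fractions, seed=seed)


def evaluate(predictions, truths) -> tuple[float, float]:
    """(Spearman rank correlation, mean squared error) on paired vectors.

    Spearman uses average ranks for ties; constant truths make the
    correlation undefined and raise a ``ValueError``.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("predictions and truths must be equal-length vectors of size >= 2")
    if np.all(t == t[0]):
        raise ValueError("Spearman correlation is undefined for constant truths")
    rho = stats.spearmanr(p, t).statistic
    mse = float(np.mean((p - t) ** 2))
    return float(rho), mse


def repeat_seed(master_seed: int, repeat: int) -> int:
    """Derive a per-repeat seed from the master seed (documented scheme)."""
    return int(np.random.SeedSequence([master_seed, repeat]).generate_state(1)[0] % (2**31))


def run_ablation(
    data: pd.DataFrame,
    variants=("spac", "tac", "enac"),
    repeats: int = 10,
    seed: int = 0,
    config=None,
    reshuffle: bool = True,
) -> pd.DataFrame:
    """Train each variant over repeated shuffled splits and aggregate.

    ``variants`` may contain ``spac`` (spatial-only), ``tac``
    (temporal-only), ``enac`` (ensemble, sequence-only) and ``stac``
    (ensemble with hand-crafted biological features).  Returns a tidy
    table with per-variant mean/sd of Spearman and MSE over repeats,
    plus the per-run values for exact recomputation.
    """
    from . import ensemble as ens  # local import: heavy module

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = config or ens.RunConfig()
    rows = []
    for rep in range(repeats):
        rep_seed = repeat_seed(seed, rep) if reshuffle else repeat_seed(seed, 0)
        split = split_dataset(len(data), seed=rep_seed)
        run_cfg = ens.replace_seed(config, repeat_seed(seed, 1000 + rep))
        for variant in variants:
            model = ens.train_variant(variant, data, split, run_cfg)
            preds = ens.predict(model, data["sequence"].iloc[split.test].tolist())
            rho, mse = evaluate(preds, data["activity"].iloc[split.test].to_numpy())
            rows.append({"variant": variant, "repeat": rep, "spearman": rho, "mse": mse})
    runs = pd.DataFrame(rows)
    agg = (
        runs.groupby("variant", sort=False)
        .agg(
            spearman_mean=("spearman", "mean"),
            spearman_sd=("spearman", lambda s: s.std(ddof=0)),
            mse_mean=("mse", "mean"),
            mse_sd=("mse", lambda s: s.std(ddof=0)),
            runs=("spearman", "size"),
        )
        .reset_index()
    )
    agg.attrs["per_run"] = runs
    return agg
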