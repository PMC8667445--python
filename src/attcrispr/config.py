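"""Shared training-run configuration."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters common to every branch training loop.

    Defaults are sized for desk-scale CPU experiments on synthetic
    datasets of a few thousand guides.
    """

    epochs: int = 5
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    finetune_epochs: int = 1
    finetune_lr_factor: float = 0.1  # fine-tuning uses lr * factor
    stack_steps: int = 400  # full-batch Adam steps for the stacking weights
    stack_lr: float = 0.05


def replace_seed(config: RunConfig, seed: int) -> RunConfig:
    return replace(config, seed=seed)
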