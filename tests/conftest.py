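"""Shared fixtures: the scaled-down synthetic training study.

The expensive trained models are session-scoped and shared between the
training-quality and interpretability-recovery tests: three independent
replicate runs (seeds 1-3) of both branches at the standard desk-scale
conditions (n=2000 guides, 5 epochs), plus one stacked ensemble run.
"""

from dataclasses import dataclass

import pytest

from attcrispr import ensemble, harness, spatial, synthetic, temporal
from attcrispr.config import RunConfig

STUDY_N = 2000
STUDY_EPOCHS = 5
STUDY_SEEDS = (1, 2, 3)


@dataclass
class StudyRun:
    seed: int
    data: "object"
    split: harness.DatasetSplit
    spatial: spatial.SpatialParams
    temporal: temporal.TemporalParams

    @property
    def train_seqs(self):
        return self.data["sequence"].iloc[self.split.train].tolist()

    @property
    def test_seqs(self):
        return self.data["sequence"].iloc[self.split.test].tolist()

    def test_activity(self):
        return self.data["activity"].iloc[self.split.test].to_numpy()

    def ttt_probes(self, k=30):
        """Held-out guides with the penalized TTT trimer substituted in."""
        return [s[:13] + "TTT" + s[16:] for s in self.test_seqs[:k]]


def run_study(seed: int, n: int = STUDY_N, epochs: int = STUDY_EPOCHS) -> StudyRun:
    data = synthetic.generate(synthetic.SyntheticSpec(n=n, seed=seed))
    split = harness.split_dataset(n, seed=seed)
    cfg = RunConfig(epochs=epochs, seed=seed)
    seqs = data["sequence"].iloc[split.train].tolist()
    y = data["activity"].iloc[split.train].to_numpy()
    sp = spatial.train_spatial(seqs, y, cfg)
    tp = temporal.train_temporal(seqs, y, cfg)
    return StudyRun(seed=seed, data=data, split=split, spatial=sp, temporal=tp)


@pytest.fixture(scope="session")
def study_runs():
    return {seed: run_study(seed) for seed in STUDY_SEEDS}


@pytest.fixture(scope="session")
def ensemble_run(study_runs):
    """Two-phase stacked (sequence-only) ensemble at the seed-1 conditions."""
    run = study_runs[STUDY_SEEDS[0]]
    cfg = RunConfig(epochs=STUDY_EPOCHS, seed=run.seed)
    model = ensemble.train_stacked(
        run.train_seqs,
        run.data["activity"].iloc[run.split.train].to_numpy(),
        cfg,
        mode="enac",
    )
    return run, model
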