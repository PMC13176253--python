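"""Desk-scale experiment harness: a seeded end-to-end training run on
simulator data with a held-out split, returning the loss history and the
full metric report.  This is the configuration exercised by the test suite
and the reproduction script; tile size, counts and step budget are chosen to
fit a single CPU."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ablations import apply_variant
from .metrics import MetricsReport
from .network import MSCFNet, NetworkConfig, PatchDiscriminator
from .synthetic import SynthParams, generate_dataset
from .training import AugmentSpec, LossBundle, TrainConfig, Trainer

__all__ = ["SmokeResult", "smoke_run", "SMOKE_PARAMS"]

# study conditions of the desk-scale run: 64x64 tiles, ~12 nuclei per tile,
# 30% marker-positive, 32 train / 8 val tiles, 300 alternating steps with a
# 60-step generation-only warm-up
SMOKE_PARAMS = SynthParams(tile_size=64, n_nuclei=12, positive_fraction=0.3)
SMOKE_N_TRAIN = 32
SMOKE_N_VAL = 8
SMOKE_STEPS = 300
SMOKE_WARMUP_FRACTION = 0.2


@dataclass
class SmokeResult:
    history: list[LossBundle]
    report: MetricsReport
    trainer: Trainer
    warmup_steps: int

    def seg_loss_curve(self) -> np.ndarray:
        return np.array([b.total_seg for b in self.history[self.warmup_steps:]])


def smoke_run(seed: int = 7, variant: str = "full",
              steps: int = SMOKE_STEPS,
              n_train: int = SMOKE_N_TRAIN, n_val: int = SMOKE_N_VAL,
              params: SynthParams = SMOKE_PARAMS) -> SmokeResult:
    """Train the test-scale network (depth 3, base width 8) on freshly
    simulated tiles and evaluate on the held-out split."""
    data = generate_dataset(params, n_train + n_val, seed=seed)
    train, val = data[:n_train], data[n_train:]

    net_cfg = apply_variant(NetworkConfig.test_scale(), variant)
    model = MSCFNet(net_cfg, seed=seed + 1)
    disc = PatchDiscriminator(3, net_cfg.n_aux_channels, net_cfg.discriminator,
                              seed=seed + 2)
    train_cfg = TrainConfig(steps=steps, warmup_fraction=SMOKE_WARMUP_FRACTION,
                            seed=seed + 3)
    # flips only: photometric/elastic augmentation is unnecessary for the
    # simulator's appearance model at this step budget
    aug = AugmentSpec(flip_prob=0.5, jitter_strength=0.0, elastic_alpha=0.0,
                      seed=seed)
    trainer = Trainer(model, disc, train, train_cfg, augment_spec=aug)
    history = trainer.run()
    report = trainer.evaluate(val)
    return SmokeResult(history=history, report=report, trainer=trainer,
                       warmup_steps=trainer.warmup_steps)
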