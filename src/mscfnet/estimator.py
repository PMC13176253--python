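"""Scikit-learn style estimator facade.

``MSCFNetSegmenter`` wraps the simulator-free training loop behind the
familiar fit/predict contract so the model composes with sklearn tooling
(``get_params``/``set_params``, ``clone``, pipelines).  ``fit`` consumes
images with instance-labeled ground truth (and optionally per-instance
marker classes and explicit auxiliary staining targets); ``predict`` returns
instance label maps; ``predict_proba`` the per-pixel class distributions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import dice as dice_score
from .network import (FiLMConfig, GateConfig, MSCFNet, NetworkConfig,
                      PatchDiscriminator)
from .nn import Tensor
from .synthetic import SyntheticSample
from .training import AugmentSpec, TrainConfig, Trainer

__all__ = ["MSCFNetSegmenter"]


class MSCFNetSegmenter(BaseEstimator):
    """Joint nucleus segmentation + virtual staining network.

    Parameters mirror the run configuration: architecture (depth,
    base_width), optimization (steps, lr, batch_size, loss weights,
    warmup_fraction), the adversarial-consistency settings of the fusion
    gate and the FiLM skip modulation, and the instance-extraction
    post-processing (threshold, min_size).

    Fitted attributes: ``model_`` (the trained network), ``discriminator_``,
    ``trainer_``, ``history_`` (per-step loss bundles), ``n_iter_``.
    """

    def __init__(self, depth: int = 3, base_width: int = 8, steps: int = 300,
                 lr: float = 2e-4, batch_size: int = 4,
                 lambda_rec: float = 100.0, lambda_perc: float = 1.0,
                 lambda_cons: float = 1.0, lambda_tv: float = 1e-4,
                 warmup_fraction: float = 0.2,
                 gate_enabled: bool = True, gate_epsilon: float = 0.03,
                 atfilm_mode: str = "full", film_epsilon: float = 0.03,
                 threshold: float = 0.5, min_size: int | None = None,
                 flip_augment: bool = True, random_state: int = 0):
        self.depth = depth
        self.base_width = base_width
        self.steps = steps
        self.lr = lr
        self.batch_size = batch_size
        self.lambda_rec = lambda_rec
        self.lambda_perc = lambda_perc
        self.lambda_cons = lambda_cons
        self.lambda_tv = lambda_tv
        self.warmup_fraction = warmup_fraction
        self.gate_enabled = gate_enabled
        self.gate_epsilon = gate_epsilon
        self.atfilm_mode = atfilm_mode
        self.film_epsilon = film_epsilon
        self.threshold = threshold
        self.min_size = min_size
        self.flip_augment = flip_augment
        self.random_state = random_state

    # ..................................................................
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            depth=self.depth, base_width=self.base_width,
            tradesgate=GateConfig(enabled=self.gate_enabled,
                                  epsilon=self.gate_epsilon),
            atfilm=FiLMConfig(mode=self.atfilm_mode,
                              epsilon=self.film_epsilon))

    @staticmethod
    def _to_samples(X, y, classes=None, aux=None) -> list[SyntheticSample]:
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n_samples, H, W, 3) RGB in [0,1]")
        if y.shape != X.shape[:3]:
            raise ValueError("y must be (n_samples, H, W) instance labels")
        samples = []
        for i in range(len(X)):
            inst = y[i].astype(np.int32)
            ids = np.unique(inst[inst > 0])
            cls = (dict(classes[i]) if classes is not None
                   else {int(k): "negative" for k in ids})
            if aux is not None:
                a_pos = np.asarray(aux[i][0], dtype=np.float32)
                a_neg = np.asarray(aux[i][1], dtype=np.float32)
            else:
                pos_ids = [k for k, v in cls.items() if v == "positive"]
                pos_mask = np.isin(inst, pos_ids)
                a_pos = (pos_mask & (inst > 0)).astype(np.float32)
                a_neg = ((inst > 0) & ~pos_mask).astype(np.float32)
            samples.append(SyntheticSample(image=X[i], aux_pos=a_pos,
                                           aux_neg=a_neg, instances=inst,
                                           classes=cls))
        return samples

    # ..................................................................
    def fit(self, X, y, classes=None, aux=None):
        """X: (n, H, W, 3) images in [0,1]; y: (n, H, W) instance labels
        (binary masks are accepted as a single instance per component);
        classes: optional per-sample dict id -> positive|negative;
        aux: optional (n, 2, H, W) staining targets."""
        samples = self._to_samples(X, y, classes, aux)
        cfg = self._network_config()
        model = MSCFNet(cfg, seed=self.random_state + 1)
        disc = PatchDiscriminator(3, cfg.n_aux_channels, cfg.discriminator,
                                  seed=self.random_state + 2)
        train_cfg = TrainConfig(
            lr=self.lr, lambda_rec=self.lambda_rec,
            lambda_perc=self.lambda_perc, lambda_cons=self.lambda_cons,
            lambda_tv=self.lambda_tv, batch_size=self.batch_size,
            warmup_fraction=self.warmup_fraction, seed=self.random_state,
            steps=self.steps)
        aug = (AugmentSpec(flip_prob=0.5, jitter_strength=0.0,
                           elastic_alpha=0.0, seed=self.random_state)
               if self.flip_augment else None)
        self.trainer_ = Trainer(model, disc, samples, train_cfg,
                                augment_spec=aug)
        self.history_ = self.trainer_.run()
        self.model_ = model
        self.discriminator_ = disc
        self.n_iter_ = len(self.history_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class distributions, (n, n_classes, H, W)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        out = [self.model_(Tensor(x.transpose(2, 0, 1)[None]),
                           mode="eval").seg_probs.data[0] for x in X]
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """Instance label maps, (n, H, W) int32."""
        from .metrics import instances_from_probs
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        maps = []
        for x in X:
            out = self.model_(Tensor(x.transpose(2, 0, 1)[None]), mode="eval")
            inst = instances_from_probs(out.seg_probs.data[0],
                                        out.aux_pred.data[0],
                                        threshold=self.threshold,
                                        min_size=self.min_size)
            maps.append(inst.labels)
        return np.stack(maps)

    def score(self, X, y) -> float:
        """Mean foreground Dice against instance (or binary) label maps."""
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dice_score(pred[i] > 0, y[i] > 0)
                              for i in range(len(pred))]))
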