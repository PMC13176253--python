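"""Losses and the alternating optimization scheme.

Per mini-batch the update order is: (1) discriminator (least-squares patch
objective on real vs generated marker channels), (2) generator — encoder +
generation decoder — by

    L_adv + lambda_rec * L_rec + lambda_perc * L_perc,

(3) segmentation pathway — segmentation decoder, gates, FiLM conditioners — by

    L_seg + lambda_cons * (L_cons_gate + L_cons_film) + lambda_tv * L_tv,

where L_seg is cross-entropy + soft Dice in equal weights, the consistency
terms are the KL divergences of clean vs adversarially perturbed predictions
produced within the same forward pass, and L_tv is the total variation of
the clean gate maps.  Each phase steps exactly one block of the parameter
partition.  A warm-up fraction of the schedule runs generation-only
(progressive coupling: the staining branch is optimized before segmentation
starts consuming its features).

Augmentation: random flips and elastic deformation applied identically to
image, marker targets and instance map (nearest-neighbor for labels), color
jitter applied to the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .gate import kl_consistency, tv_penalty
from .metrics import InstanceLabelMap, evaluate_pairs, instances_from_probs
from .network import MSCFNet, ModelOutputs, PatchDiscriminator
from .nn import AdamW, Conv2d, Module, Tensor, frozen
from .synthetic import SyntheticSample

__all__ = ["TrainConfig", "AugmentSpec", "LossBundle", "augment",
           "generator_objective", "segmentation_objective", "Trainer"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 2e-4
    optimizer: str = "adamw"
    lambda_rec: float = 100.0
    lambda_perc: float = 1.0
    lambda_cons: float = 1.0
    lambda_tv: float = 1e-4
    batch_size: int = 4
    warmup_fraction: float = 0.2
    seed: int = 0
    steps: int = 300

    def validate(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 <= self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must be in [0, 1)")
        for name in ("lambda_rec", "lambda_perc", "lambda_cons", "lambda_tv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.optimizer != "adamw":
            raise ValueError("only the AdamW optimizer is supported")


@dataclass(frozen=True)
class AugmentSpec:
    flip_prob: float = 0.5            # per axis
    jitter_strength: float = 0.2      # relative channel gain range
    elastic_alpha: float = 10.0       # displacement magnitude, px
    elastic_sigma: float = 4.0        # displacement smoothing, px
    seed: int = 0

    def validate(self):
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if min(self.jitter_strength, self.elastic_alpha, self.elastic_sigma) < 0:
            raise ValueError("augmentation magnitudes must be >= 0")


@dataclass
class LossBundle:
    """Named scalar loss terms of one training step."""

    l_adv: float = 0.0
    l_rec: float = 0.0
    l_perc: float = 0.0
    l_seg: float = 0.0
    l_cons_gate: float = 0.0
    l_cons_film: float = 0.0
    l_tv: float = 0.0
    l_disc: float = 0.0
    total_gen: float = 0.0
    total_seg: float = 0.0

    FIELDS = ("l_adv", "l_rec", "l_perc", "l_seg", "l_cons_gate",
              "l_cons_film", "l_tv", "l_disc", "total_gen", "total_seg")

    def row(self) -> list[float]:
        return [getattr(self, f) for f in self.FIELDS]


# -- augmentation -------------------------------------------------------------

def augment(sample: SyntheticSample, spec: AugmentSpec,
            rng: np.random.Generator | None = None) -> SyntheticSample:
    """Geometric transforms move image, marker channels and labels together;
    photometric jitter touches the image only."""
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    image = sample.image
    aux_pos, aux_neg = sample.aux_pos, sample.aux_neg
    inst = sample.instances

    if rng.random() < spec.flip_prob:       # horizontal
        image = image[:, ::-1]
        aux_pos, aux_neg = aux_pos[:, ::-1], aux_neg[:, ::-1]
        inst = inst[:, ::-1]
    if rng.random() < spec.flip_prob:       # vertical
        image = image[::-1]
        aux_pos, aux_neg = aux_pos[::-1], aux_neg[::-1]
        inst = inst[::-1]

    gains = 1.0 + spec.jitter_strength * rng.uniform(-1.0, 1.0, size=3)
    image = np.clip(image * gains[None, None, :], 0.0, 1.0).astype(np.float32)

    if spec.elastic_alpha > 0:
        h, w = inst.shape
        dy = gaussian_filter(rng.standard_normal((h, w)), spec.elastic_sigma)
        dx = gaussian_filter(rng.standard_normal((h, w)), spec.elastic_sigma)
        for d in (dy, dx):
            m = np.abs(d).max()
            if m > 0:
                d *= spec.elastic_alpha / m / 4.0
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = [yy + dy, xx + dx]
        image = np.stack([map_coordinates(image[..., c], coords, order=1,
                                          mode="reflect") for c in range(3)],
                         axis=-1).astype(np.float32)
        aux_pos = map_coordinates(aux_pos, coords, order=1, mode="reflect").astype(np.float32)
        aux_neg = map_coordinates(aux_neg, coords, order=1, mode="reflect").astype(np.float32)
        inst = map_coordinates(inst, coords, order=0, mode="reflect")

    inst = np.ascontiguousarray(inst)
    surviving = set(np.unique(inst[inst > 0]).tolist())
    classes = {i: c for i, c in sample.classes.items() if i in surviving}
    return SyntheticSample(image=np.ascontiguousarray(image),
                           aux_pos=np.ascontiguousarray(aux_pos),
                           aux_neg=np.ascontiguousarray(aux_neg),
                           instances=inst, classes=classes)


# -- objectives ---------------------------------------------------------------

class PerceptualEncoder(Module):
    """Fixed, seeded 3-layer conv feature extractor for the perceptual loss.

    Its parameters are frozen constants (never trained); the loss is the mean
    squared distance between its features of prediction and target.
    """

    def __init__(self, c_in: int = 2, width: int = 8, seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.c1 = Conv2d(c_in, width, 3, rng=rng)
        self.c2 = Conv2d(width, width * 2, 3, stride=2, padding=1, rng=rng)
        self.c3 = Conv2d(width * 2, width * 2, 3, rng=rng)
        for p in self.parameters():
            p.requires_grad = False
            p._needs_grad = False

    def forward(self, x: Tensor) -> Tensor:
        return self.c3(self.c2(self.c1(x).relu()).relu())


def generator_objective(aux_pred: Tensor, targets: np.ndarray,
                        disc_scores: Tensor | None, cfg: TrainConfig,
                        perc_encoder: PerceptualEncoder | None = None):
    """Returns (total_gen Tensor, bundle fields dict)."""
    if targets is None:
        raise ValueError("auxiliary targets are required for the generator objective")
    y = Tensor(np.asarray(targets, dtype=np.float32))
    l_rec = (aux_pred - y).abs().mean()
    if perc_encoder is not None:
        diff = perc_encoder(aux_pred) - perc_encoder(y)
        l_perc = (diff * diff).mean()
    else:
        l_perc = Tensor(np.float32(0.0))
    if disc_scores is not None:
        l_adv = (0.5 * (disc_scores - 1.0) ** 2).mean()
    else:
        l_adv = Tensor(np.float32(0.0))
    total = l_adv + cfg.lambda_rec * l_rec + cfg.lambda_perc * l_perc
    fields = {"l_adv": float(l_adv.data), "l_rec": float(l_rec.data),
              "l_perc": float(l_perc.data), "total_gen": float(total.data)}
    return total, fields


def cross_entropy(logp: Tensor, target: np.ndarray) -> Tensor:
    """-mean log p at the true class; target is an integer (B,H,W) raster."""
    k = logp.shape[1]
    onehot = np.moveaxis(np.eye(k, dtype=np.float32)[target], -1, 1)
    return -(logp * Tensor(onehot)).sum(axis=1).mean()


def soft_dice_loss(fg_prob: Tensor, target_fg: np.ndarray, eps: float = 1e-6) -> Tensor:
    y = Tensor(np.asarray(target_fg, dtype=np.float32))
    inter = (fg_prob * y).sum()
    return 1.0 - (2.0 * inter + eps) / (fg_prob.sum() + y.sum() + eps)


def segmentation_objective(outputs: ModelOutputs, gt_mask: np.ndarray,
                           cfg: TrainConfig, tv_reduction: str = "mean"):
    """Returns (total_seg Tensor, bundle fields dict).

    gt_mask: integer (B,H,W) class raster (0 background, 1 nucleus).
    """
    logp = outputs.seg_logp
    l_seg = cross_entropy(logp, gt_mask) + soft_dice_loss(
        logp.exp()[:, 1], (np.asarray(gt_mask) > 0).astype(np.float32))

    zero = Tensor(np.float32(0.0))
    p_clean = outputs.seg_logp.exp()
    l_cg = (kl_consistency(p_clean, outputs.seg_logp_pert_gate.exp())
            if outputs.seg_logp_pert_gate is not None else zero)
    l_cf = (kl_consistency(p_clean, outputs.seg_logp_pert_film.exp())
            if outputs.seg_logp_pert_film is not None else zero)
    l_tv = zero
    for s in outputs.gates:
        l_tv = l_tv + tv_penalty(s.gate, reduction=tv_reduction)
    total = l_seg + cfg.lambda_cons * (l_cg + l_cf) + cfg.lambda_tv * l_tv
    fields = {"l_seg": float(l_seg.data), "l_cons_gate": float(l_cg.data),
              "l_cons_film": float(l_cf.data), "l_tv": float(l_tv.data),
              "total_seg": float(total.data)}
    return total, fields


# -- trainer ------------------------------------------------------------------

def _batch_arrays(samples: list[SyntheticSample]):
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    y_aux = np.stack([np.stack([s.aux_pos, s.aux_neg]) for s in samples]).astype(np.float32)
    y_mask = np.stack([(s.instances > 0).astype(np.int64) for s in samples])
    return x, y_aux, y_mask


class Trainer:
    """Alternating optimizer over the model's parameter partition."""

    def __init__(self, model: MSCFNet, disc: PatchDiscriminator,
                 train_samples: list[SyntheticSample],
                 cfg: TrainConfig | None = None,
                 augment_spec: AugmentSpec | None = None):
        cfg = cfg or TrainConfig()
        cfg.validate()
        self.model = model
        self.disc = disc
        self.cfg = cfg
        self.train_samples = list(train_samples)
        self.augment_spec = augment_spec
        self.rng = np.random.default_rng(cfg.seed)
        groups = model.param_groups()
        self.gen_params = groups["encoder"] + groups["gen_decoder"]
        self.seg_params = groups["seg_decoder"] + groups["gates"] + groups["film"]
        self.opt_gen = AdamW(self.gen_params, lr=cfg.lr)
        self.opt_seg = AdamW(self.seg_params, lr=cfg.lr)
        self.opt_disc = AdamW(disc.parameters(), lr=cfg.lr)
        self.perc = PerceptualEncoder(c_in=model.cfg.n_aux_channels)
        self.warmup_steps = int(round(cfg.warmup_fraction * cfg.steps))
        self.step_count = 0
        self.history: list[LossBundle] = []

    # ..................................................................
    def _sample_batch(self):
        idx = self.rng.integers(0, len(self.train_samples), size=self.cfg.batch_size)
        samples = [self.train_samples[i] for i in idx]
        if self.augment_spec is not None:
            samples = [augment(s, self.augment_spec, self.rng) for s in samples]
        return _batch_arrays(samples)

    def _zero_all(self):
        self.model.zero_grad()
        self.disc.zero_grad()

    def train_step(self, batch=None) -> LossBundle:
        """One alternating update: discriminator, generator, then (after
        warm-up) the segmentation pathway."""
        x_np, y_aux, y_mask = batch if batch is not None else self._sample_batch()
        x = Tensor(x_np)
        bundle = LossBundle()
        model, disc, cfg = self.model, self.disc, self.cfg

        # one generation forward serves phases (1) and (2): the discriminator
        # update does not touch model parameters, so the fake stays current
        skips, bottom = model.encode(x)
        _, aux_pred = model.gen_decode(skips, bottom)

        # (1) discriminator, on the detached fake
        d_real = disc(x, Tensor(y_aux))
        d_fake = disc(x, aux_pred.detach())
        l_disc = (0.5 * (d_real - 1.0) ** 2).mean() + (0.5 * d_fake ** 2).mean()
        self._zero_all()
        l_disc.backward()
        self.opt_disc.step()
        bundle.l_disc = float(l_disc.data)

        # (2) generator (encoder + generation decoder), against the updated critic
        with frozen(disc.parameters()):
            scores = disc(x, aux_pred)
        total_gen, gf = generator_objective(aux_pred, y_aux, scores, cfg, self.perc)
        self._zero_all()
        total_gen.backward()
        self.opt_gen.step()
        for k, v in gf.items():
            setattr(bundle, k, v)

        # (3) segmentation pathway (decoder + gates + FiLM conditioners)
        if self.step_count >= self.warmup_steps:
            with frozen(self.gen_params):
                outputs = model(x, mode="train")
            total_seg, sf = segmentation_objective(
                outputs, y_mask, cfg,
                tv_reduction=model.cfg.tradesgate.tv_reduction)
            self._zero_all()
            total_seg.backward()
            self.opt_seg.step()
            for k, v in sf.items():
                setattr(bundle, k, v)

        self.step_count += 1
        self.history.append(bundle)
        return bundle

    def run(self, log_file=None) -> list[LossBundle]:
        header = "step\t" + "\t".join(LossBundle.FIELDS)
        if log_file is not None:
            log_file.write(header + "\n")
        for _ in range(self.cfg.steps):
            b = self.train_step()
            if log_file is not None:
                log_file.write(f"{self.step_count - 1}\t" +
                               "\t".join(f"{v:.6f}" for v in b.row()) + "\n")
        return self.history

    # ..................................................................
    def predict(self, samples: list[SyntheticSample], threshold: float = 0.5,
                min_size: int | None = None) -> list[InstanceLabelMap]:
        preds = []
        for s in samples:
            x = Tensor(s.image.transpose(2, 0, 1)[None])
            out = self.model(x, mode="eval")
            preds.append(instances_from_probs(
                out.seg_probs.data[0], out.aux_pred.data[0],
                threshold=threshold, min_size=min_size))
        return preds

    def evaluate(self, samples: list[SyntheticSample], threshold: float = 0.5,
                 min_size: int | None = None):
        preds = self.predict(samples, threshold, min_size)
        gts = [InstanceLabelMap(s.instances, dict(s.classes)) for s in samples]
        return evaluate_pairs(preds, gts)
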