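"""Full network assembly: shared multi-scale encoder, auxiliary
virtual-staining decoder (with patch discriminator), and segmentation decoder
whose skips are FiLM-modulated and whose stream is fused with same-scale
auxiliary features through adversarially regularized gates.

Layout (depth D, base width w): encoder levels carry w, 2w, ..., 2^(D-1) w
channels, each level an MDE block followed by instance normalization, with
strided-conv downsampling between levels.  Both decoders upsample by
nearest-neighbor + conv.  The generation decoder emits per-level auxiliary
features and, at full resolution, the logistic-squashed virtual marker
channels (positive / negative).  The segmentation decoder, at each level,
modulates the encoder skip with ATFiLM conditioned on the same-level
auxiliary feature, concatenates it with the upsampled stream, and fuses the
result with the auxiliary feature through a TRADESGate; a 1x1 head emits the
per-pixel class distribution.  In train mode the forward pass additionally
runs the adversarial searches and the two perturbed predictions needed by
the consistency losses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

from .blocks import MDEBlock, MDEConfig
from .film import (ConcatSkip, FiLMConditioner, FiLMParams,
                   adversarial_film_perturbation, film_modulate)
from .gate import (GateState, PerturbConfig, TRADESGate,
                   adversarial_gate_perturbation)
from .nn import (Conv2d, ConvNormAct, InstanceNorm2d, Module, Tensor, concat,
                 frozen, upsample_nearest2x)

__all__ = ["GateConfig", "FiLMConfig", "DiscConfig", "NetworkConfig",
           "ModelOutputs", "MSCFNet", "PatchDiscriminator",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class GateConfig:
    enabled: bool = True
    simple_gate: bool = False          # gate without perturbation/TV/KL
    epsilon: float = 0.03
    n_steps: int = 1
    step_size: float | None = None
    tv_weight: float = 1e-4
    tv_reduction: str = "mean"

    def perturb(self) -> PerturbConfig:
        return PerturbConfig(self.epsilon, self.n_steps, self.step_size, "gate")


@dataclass(frozen=True)
class FiLMConfig:
    enabled: bool = True
    mode: str = "full"                 # full | beta_only | gamma_only | concat
    epsilon: float = 0.03
    n_steps: int = 1

    def effective_mode(self) -> str:
        return self.mode if self.enabled else "off"

    def perturb(self) -> PerturbConfig:
        return PerturbConfig(self.epsilon, self.n_steps, None, "film")


@dataclass(frozen=True)
class DiscConfig:
    n_layers: int = 3
    width: int = 32
    norm: bool = True     # instance norm couples spatial positions globally


@dataclass(frozen=True)
class NetworkConfig:
    depth: int = 4
    base_width: int = 32
    n_aux_channels: int = 2
    n_classes: int = 2
    mde: MDEConfig = field(default_factory=MDEConfig)
    tradesgate: GateConfig = field(default_factory=GateConfig)
    atfilm: FiLMConfig = field(default_factory=FiLMConfig)
    discriminator: DiscConfig = field(default_factory=DiscConfig)

    def validate(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        self.mde.validate()
        if self.atfilm.mode not in ("full", "beta_only", "gamma_only", "concat"):
            raise ValueError(f"unknown atfilm mode: {self.atfilm.mode}")

    @staticmethod
    def test_scale(**overrides) -> "NetworkConfig":
        """Small configuration for CPU-scale experiments."""
        return NetworkConfig(depth=3, base_width=8,
                             discriminator=DiscConfig(n_layers=2, width=16),
                             **overrides)


@dataclass
class ModelOutputs:
    """Everything one forward pass produces.  Perturbed predictions are only
    present in train mode (and only for pathways with epsilon > 0)."""

    seg_probs: Tensor                      # (B, K, H, W), softmax
    seg_logp: Tensor                       # (B, K, H, W), log-softmax
    aux_pred: Tensor                       # (B, n_aux, H, W) in [0,1]
    gates: list[GateState]
    film: list[FiLMParams]
    seg_logp_pert_gate: Tensor | None = None
    seg_logp_pert_film: Tensor | None = None


class MSCFNet(Module):
    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        cfg = cfg or NetworkConfig()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        D = cfg.depth
        widths = [cfg.base_width * 2 ** l for l in range(D)]
        self.widths = widths

        self.stem = ConvNormAct(3, widths[0], rng=rng)
        self.enc = [MDEBlock(w, cfg.mde, rng=rng) for w in widths]
        self.enc_norm = [InstanceNorm2d(w) for w in widths]
        self.down = [ConvNormAct(widths[l], widths[l + 1], stride=2, rng=rng)
                     for l in range(D - 1)]

        # generation (virtual staining) decoder, plain skips
        self.gen_up = [ConvNormAct(widths[l + 1] + widths[l], widths[l], rng=rng)
                       for l in range(D - 1)]
        self.aux_head = Conv2d(widths[0], cfg.n_aux_channels, 1, rng=rng)

        # segmentation decoder: ATFiLM on skips, TRADESGate fusion per level
        mode = cfg.atfilm.effective_mode()
        self.film_cond: list[Module | None] = []
        for l in range(D - 1):
            if mode in ("full", "beta_only", "gamma_only"):
                self.film_cond.append(FiLMConditioner(widths[l], widths[l],
                                                      mode=mode, rng=rng))
            elif mode == "concat":
                self.film_cond.append(ConcatSkip(widths[l], widths[l], rng=rng))
            else:
                self.film_cond.append(None)
        self.seg_up = [ConvNormAct(widths[l + 1] + widths[l], widths[l], rng=rng)
                       for l in range(D - 1)]
        self.gates = ([TRADESGate(widths[l], rng=rng) for l in range(D - 1)]
                      if cfg.tradesgate.enabled else [])
        self.seg_head = Conv2d(widths[0], cfg.n_classes, 1, rng=rng)

    # -- parameter partition ------------------------------------------------
    def param_groups(self) -> dict[str, list[Tensor]]:
        """Disjoint, exhaustive partition used by the alternating updates."""
        def collect(mods):
            out = []
            for m in mods:
                if m is not None:
                    out.extend(m.parameters())
            return out

        groups = {
            "encoder": collect([self.stem] + self.enc + self.enc_norm + self.down),
            "gen_decoder": collect(self.gen_up + [self.aux_head]),
            "seg_decoder": collect(self.seg_up + [self.seg_head]),
            "gates": collect(self.gates),
            "film": collect(self.film_cond),
        }
        return groups

    # -- forward pieces ------------------------------------------------------
    def _check_input(self, x: Tensor):
        H, W = x.shape[-2:]
        f = 2 ** (self.cfg.depth - 1)
        if H % f or W % f:
            raise ValueError(f"input size {H}x{W} must be divisible by {f}")

    def encode(self, x: Tensor):
        h = self.stem(x)
        skips = []
        for l in range(self.cfg.depth - 1):
            h = self.enc_norm[l](self.enc[l](h))
            skips.append(h)
            h = self.down[l](h)
        bottom = self.enc_norm[-1](self.enc[-1](h))
        return skips, bottom

    def gen_decode(self, skips, bottom):
        h = bottom
        aux_feats: list[Tensor | None] = [None] * (self.cfg.depth - 1)
        for l in range(self.cfg.depth - 2, -1, -1):
            h = self.gen_up[l](concat([upsample_nearest2x(h), skips[l]], axis=1))
            aux_feats[l] = h
        aux_pred = self.aux_head(h).sigmoid()
        return aux_feats, aux_pred

    def seg_decode(self, skips, bottom, aux_feats, gate_overrides=None,
                   film_overrides=None):
        """Returns (log-probs, gate states, film params).

        gate_overrides / film_overrides substitute per-level gate rasters or
        (gamma, beta) pairs — used for the perturbed passes; ``None`` entries
        fall back to the clean computation.
        """
        h = bottom
        gates: list[GateState] = []
        films: list[FiLMParams] = []
        mode = self.cfg.atfilm.effective_mode()
        for i, l in enumerate(range(self.cfg.depth - 2, -1, -1)):
            s, a = skips[l], aux_feats[l]
            if mode in ("full", "beta_only", "gamma_only"):
                params = (film_overrides[i] if film_overrides is not None
                          and film_overrides[i] is not None
                          else self.film_cond[l](a, source=f"level{l}"))
                s = film_modulate(s, params)
                films.append(params)
            elif mode == "concat":
                s = self.film_cond[l](s, a)
            h = self.seg_up[l](concat([upsample_nearest2x(h), s], axis=1))
            if self.gates:
                override = (gate_overrides[i] if gate_overrides is not None
                            else None)
                fused, gate, logits = self.gates[l](h, a, gate_override=override)
                gates.append(GateState(gate=np.asarray(gate.data),
                                       gate_logits=np.asarray(logits.data)))
                h = fused
        logits = self.seg_head(h)
        return logits.log_softmax(axis=1), gates, films

    # -- public forward -------------------------------------------------------
    def forward(self, x: Tensor, mode: str = "eval") -> ModelOutputs:
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        self._check_input(x)
        skips, bottom = self.encode(x)
        aux_feats, aux_pred = self.gen_decode(skips, bottom)
        logp, gates, films = self.seg_decode(skips, bottom, aux_feats)
        out = ModelOutputs(seg_probs=logp.exp(), seg_logp=logp,
                           aux_pred=aux_pred, gates=gates,
                           film=[p.detached() for p in films])
        if mode != "train":
            return out

        gcfg, fcfg = self.cfg.tradesgate, self.cfg.atfilm
        do_gate = (self.gates and not gcfg.simple_gate and gcfg.epsilon > 0)
        do_film = (fcfg.effective_mode() in ("full", "beta_only", "gamma_only")
                   and fcfg.epsilon > 0)
        if not (do_gate or do_film):
            return out

        # inner maximization on detached features with frozen parameters
        skips_d = [s.detach() for s in skips]
        bottom_d = bottom.detach()
        aux_d = [a.detach() for a in aux_feats]
        clean_film = [p.detached() for p in films]

        if do_gate:
            with frozen(self.parameters()):
                def gate_fwd(gate_ts):
                    lp, _, _ = self.seg_decode(
                        skips_d, bottom_d, aux_d, gate_overrides=gate_ts,
                        film_overrides=[FiLMParams(p.gamma, p.beta, p.source)
                                        for p in clean_film] or None)
                    return lp.exp()
                pert_states = adversarial_gate_perturbation(
                    gate_fwd, out.gates, gcfg.perturb(),
                    p_clean=out.seg_probs.data)
            out.gates = pert_states
            gate_ov = [Tensor(s.perturbed_gate()) for s in pert_states]
            out.seg_logp_pert_gate, _, _ = self.seg_decode(
                skips, bottom, aux_feats, gate_overrides=gate_ov)

        if do_film:
            with frozen(self.parameters()):
                def film_fwd(film_ts):
                    lp, _, _ = self.seg_decode(
                        skips_d, bottom_d, aux_d, film_overrides=film_ts)
                    return lp.exp()
                pert_films = adversarial_film_perturbation(
                    film_fwd, clean_film, fcfg.perturb(),
                    p_clean=out.seg_probs.data)
            film_ov = [FiLMParams(Tensor(p.gamma), Tensor(p.beta), p.source)
                       for p in pert_films]
            out.seg_logp_pert_film, _, _ = self.seg_decode(
                skips, bottom, aux_feats, film_overrides=film_ov)
        return out


class PatchDiscriminator(Module):
    """Conditional patch critic on channel-concat [image ; aux channels].

    n_layers strided 4x4 convolutions (leaky rectifier, instance norm from
    the second on) followed by a stride-1 4x4 scoring conv: each output unit
    scores one receptive-field patch.
    """

    def __init__(self, c_image: int = 3, c_aux: int = 2,
                 cfg: DiscConfig | None = None, seed: int = 0):
        cfg = cfg or DiscConfig()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.convs = []
        self.norms: list[InstanceNorm2d | None] = []
        c_in = c_image + c_aux
        w = cfg.width
        for i in range(cfg.n_layers):
            self.convs.append(Conv2d(c_in, w, 4, stride=2, padding=1, rng=rng))
            self.norms.append(InstanceNorm2d(w) if (i > 0 and cfg.norm) else None)
            c_in, w = w, min(w * 2, 8 * cfg.width)
        self.score = Conv2d(c_in, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape[0] != y.shape[0] or x.shape[-2:] != y.shape[-2:]:
            raise ValueError("image and aux tensors must share batch and size")
        h = concat([x, y], axis=1)
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        return self.score(h)

    def receptive_field(self) -> int:
        """Analytic receptive field of one output unit, in input pixels."""
        rf, jump = 1, 1
        for _ in range(self.cfg.n_layers):
            rf += (4 - 1) * jump
            jump *= 2
        rf += (4 - 1) * jump   # final stride-1 scoring conv
        return rf


# -- checkpointing -----------------------------------------------------------

def _cfg_to_dict(cfg) -> dict:
    def conv(v):
        if is_dataclass(v):
            return {k: conv(x) for k, x in asdict(v).items()}
        if isinstance(v, tuple):
            return list(v)
        return v
    return conv(cfg)


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    mde = d.pop("mde", {})
    if "dilation_rates" in mde:
        mde["dilation_rates"] = tuple(mde["dilation_rates"])
    return NetworkConfig(
        mde=MDEConfig(**mde),
        tradesgate=GateConfig(**d.pop("tradesgate", {})),
        atfilm=FiLMConfig(**d.pop("atfilm", {})),
        discriminator=DiscConfig(**d.pop("discriminator", {})),
        **d)


def save_checkpoint(path, model: MSCFNet, disc: PatchDiscriminator | None = None):
    """Single-file parameter archive with the embedded network config."""
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    if disc is not None:
        arrays.update({f"disc.{k}": v for k, v in disc.state_dict().items()})
    arrays["__config__"] = np.frombuffer(
        json.dumps(_cfg_to_dict(model.cfg)).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path) -> tuple[MSCFNet, PatchDiscriminator | None]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
    with np.load(str(path)) as z:
        cfg = config_from_dict(json.loads(bytes(z["__config__"]).decode()))
        model = MSCFNet(cfg)
        model.load_state_dict({k[len("model."):]: z[k] for k in z.files
                               if k.startswith("model.")})
        disc_keys = [k for k in z.files if k.startswith("disc.")]
        disc = None
        if disc_keys:
            disc = PatchDiscriminator(3, cfg.n_aux_channels, cfg.discriminator)
            disc.load_state_dict({k[len("disc."):]: z[k] for k in disc_keys})
    return model, disc
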