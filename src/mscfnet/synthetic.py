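"""Synthetic IHC-like tile simulator.

Generates co-registered triples of (RGB image, auxiliary marker channels,
instance ground truth) with the structure the segmentation/staining network
assumes: densely packed elliptical nuclei of two classes (marker-positive,
rendered DAB-brown, and marker-negative, rendered hematoxylin-blue), allowed
to touch or overlap for a controlled fraction of instances, on a textured
background, with per-tile stain jitter and additive noise applied to the
image only.  The auxiliary channels are the clean virtual-staining targets:
``aux_pos`` is bright exactly on marker-positive nuclei and ``aux_neg`` on
marker-negative nuclei (smooth radial profile per nucleus).

Everything is driven by a single integer seed; identical parameters produce
bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = ["SynthParams", "SyntheticSample", "PlacementError",
           "generate_sample", "generate_dataset"]

# base chromogen colors (RGB in [0,1]): DAB brown for marker-positive nuclei,
# hematoxylin blue for marker-negative; light eosinophilic background
_POS_COLOR = np.array([0.55, 0.33, 0.14], dtype=np.float32)
_NEG_COLOR = np.array([0.26, 0.28, 0.55], dtype=np.float32)
_BG_COLOR = np.array([0.92, 0.87, 0.89], dtype=np.float32)


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested number of nuclei."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic tile.

    tile_size: square tile edge in pixels (>= 32).
    n_nuclei: number of nuclei to place.
    radius_range: (min, max) semi-major axis in pixels.
    eccentricity_range: (min, max) in [0, 1); 0 = circle.
    overlap_fraction: fraction of nuclei exempt from the minimum
        center-distance test, i.e. allowed to touch/overlap a neighbor.
    positive_fraction: fraction of nuclei labeled marker-positive
        (count = round(positive_fraction * n_nuclei)).
    stain_jitter: per-tile relative hue/intensity perturbation scale.
    noise_sigma: std of additive Gaussian image noise, intensity units.
    background_texture_scale: correlation length of background texture, px.
    seed: RNG seed; same params (incl. seed) -> bit-identical sample.
    """

    tile_size: int = 64
    n_nuclei: int = 12
    radius_range: tuple[float, float] = (4.0, 8.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    overlap_fraction: float = 0.3
    positive_fraction: float = 0.3
    stain_jitter: float = 0.1
    noise_sigma: float = 0.03
    background_texture_scale: float = 8.0
    seed: int = 0

    def validate(self):
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range min must be <= max")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("eccentricity_range must satisfy 0 <= min <= max < 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass
class SyntheticSample:
    """One co-registered tile: image, clean aux targets, instance labels, classes."""

    image: np.ndarray          # H x W x 3 float32 in [0,1]
    aux_pos: np.ndarray        # H x W float32 in [0,1]
    aux_neg: np.ndarray        # H x W float32 in [0,1]
    instances: np.ndarray      # H x W int32, 0 = background
    classes: dict[int, str] = field(default_factory=dict)  # id -> positive|negative


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _place_nuclei(params: SynthParams, rng: np.random.Generator):
    """Rejection-sample ellipse geometry honoring the overlap budget."""
    n = params.n_nuclei
    n_overlap = _round_half_up(params.overlap_fraction * n)
    placed = []  # (cy, cx, r_major, r_minor, theta)
    max_attempts = 400 * max(n, 1)
    attempts = 0
    t = params.tile_size
    while len(placed) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} nuclei in a {t}x{t} tile after "
                f"{max_attempts} attempts; reduce n_nuclei or radius_range")
        attempts += 1
        r_major = rng.uniform(*params.radius_range)
        ecc = rng.uniform(*params.eccentricity_range)
        r_minor = r_major * np.sqrt(1.0 - ecc ** 2)
        theta = rng.uniform(0.0, np.pi)
        margin = 1.0
        cy = rng.uniform(r_minor + margin, t - r_minor - margin)
        cx = rng.uniform(r_minor + margin, t - r_minor - margin)
        may_overlap = len(placed) < n_overlap
        ok = True
        for (py, px, pr, _, _) in placed:
            d = np.hypot(cy - py, cx - px)
            if may_overlap:
                # keep overlappers from being fully engulfed
                if d < 0.5 * (r_major + pr):
                    ok = False
                    break
            elif d < (r_major + pr) + 1.0:
                ok = False
                break
        if ok:
            placed.append((cy, cx, r_major, r_minor, theta))
    return placed


def generate_sample(params: SynthParams) -> SyntheticSample:
    """Generate one tile.  Raises PlacementError if nuclei cannot be placed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    t = params.tile_size
    n = params.n_nuclei

    n_pos = _round_half_up(params.positive_fraction * n)
    order = rng.permutation(n) if n else np.array([], dtype=int)
    pos_ids = set(int(i) + 1 for i in order[:n_pos])
    classes = {i + 1: ("positive" if (i + 1) in pos_ids else "negative")
               for i in range(n)}

    # Rasterize; later nuclei overwrite earlier pixels, so in rare overlap
    # geometries an instance can lose all its pixels — re-draw the layout then.
    for _attempt in range(20):
        nuclei = _place_nuclei(params, rng)
        instances = np.zeros((t, t), dtype=np.int32)
        profile = np.zeros((t, t), dtype=np.float32)  # radial brightness per nucleus
        for idx, (cy, cx, ra, rb, theta) in enumerate(nuclei, start=1):
            rr, cc = draw_ellipse(cy, cx, rb, ra, shape=(t, t), rotation=theta)
            instances[rr, cc] = idx  # one id per pixel
            # normalized elliptical radius on this nucleus's pixels
            dy, dx = rr - cy, cc - cx
            ry = dy * np.cos(theta) - dx * np.sin(theta)
            rx = dy * np.sin(theta) + dx * np.cos(theta)
            d2 = (ry / max(rb, 1e-6)) ** 2 + (rx / max(ra, 1e-6)) ** 2
            profile[rr, cc] = np.clip(1.0 - 0.7 * d2, 0.3, 1.0)
        if len(np.unique(instances[instances > 0])) == n:
            break
    else:
        raise PlacementError("an instance was repeatedly engulfed by its neighbors")

    pos_mask = np.isin(instances, list(pos_ids)) if pos_ids else np.zeros_like(instances, bool)
    fg = instances > 0
    neg_mask = fg & ~pos_mask
    aux_pos = np.where(pos_mask, profile, 0.0).astype(np.float32)
    aux_neg = np.where(neg_mask, profile, 0.0).astype(np.float32)

    # textured background
    texture = rng.standard_normal((t, t)).astype(np.float32)
    texture = gaussian_filter(texture, params.background_texture_scale / 4.0)
    std = texture.std()
    if std > 0:
        texture = texture / std * 0.05
    image = _BG_COLOR[None, None, :] * (1.0 + texture[:, :, None])

    # nuclei: base chromogen color darkened toward the center via the profile
    shade = (0.6 + 0.4 * (1.0 - profile))[:, :, None]
    image = np.where(pos_mask[:, :, None], _POS_COLOR[None, None, :] * shade, image)
    image = np.where(neg_mask[:, :, None], _NEG_COLOR[None, None, :] * shade, image)

    # per-tile stain jitter (channel-wise gain) then pixel noise; image only
    gain = 1.0 + params.stain_jitter * rng.uniform(-1.0, 1.0, size=3)
    image = image * gain[None, None, :].astype(np.float32)
    image = image + params.noise_sigma * rng.standard_normal((t, t, 3)).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return SyntheticSample(image=image, aux_pos=aux_pos, aux_neg=aux_neg,
                           instances=instances, classes=classes)


def derive_seed(seed: int, index: int) -> int:
    """Deterministic per-sample seed, kept below 2**31."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2 ** 31))


def generate_dataset(params: SynthParams, n_samples: int, seed: int) -> list[SyntheticSample]:
    """A reproducible list of samples with per-index derived seeds."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return [generate_sample(replace(params, seed=derive_seed(seed, i)))
            for i in range(n_samples)]
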