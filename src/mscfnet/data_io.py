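"""Raster I/O and dataset indexing.

Sample directory layout (one directory per sample):

    <root>/<name>/image.png        8-bit RGB
    <root>/<name>/aux_pos.png      16-bit grayscale marker-positive target
    <root>/<name>/aux_neg.png      16-bit grayscale marker-negative target
    <root>/<name>/instances.tif    16-bit integer instance labels
    <root>/<name>/classes.json     instance id -> positive|negative
    <root>/manifest.yaml           sample list, splits, generating parameters

Images normalize to [0,1] by their bit depth; instance TIFFs are read as
integer labels without rescaling.  Shape disagreements between the rasters
of one sample are hard errors, never a silent resize.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .synthetic import SynthParams, SyntheticSample

__all__ = ["DatasetIndex", "write_sample", "load_sample", "write_dataset",
           "load_dataset", "load_index"]


@dataclass
class DatasetIndex:
    root: Path
    samples: list[dict]                      # {name, image, aux_pos, aux_neg, instances, classes}
    split: dict[str, list[str]] = field(default_factory=dict)
    params: SynthParams | None = None

    def __post_init__(self):
        names = [s["name"] for s in self.samples]
        assigned: set[str] = set()
        for part, members in self.split.items():
            dup = assigned & set(members)
            if dup:
                raise ValueError(f"samples in more than one split: {sorted(dup)}")
            assigned |= set(members)
            unknown = set(members) - set(names)
            if unknown:
                raise ValueError(f"split '{part}' references unknown samples: {sorted(unknown)}")
        for s in self.samples:
            for key in ("image", "aux_pos", "aux_neg", "instances", "classes"):
                p = self.root / s[key]
                if not p.exists():
                    raise FileNotFoundError(f"indexed file missing: {p}")

    def names(self, part: str | None = None) -> list[str]:
        if part is None:
            return [s["name"] for s in self.samples]
        return list(self.split.get(part, []))


def _read_raster(path: Path) -> np.ndarray:
    try:
        if path.suffix in (".tif", ".tiff"):
            return tifffile.imread(str(path))
        return iio.imread(str(path))
    except Exception as e:                               # noqa: BLE001
        raise IOError(f"failed to decode raster {path}: {e}") from e


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Normalize by bit depth so 8- and 16-bit encodings of the same physical
    intensity load to the same value."""
    if img.dtype == np.uint8:
        return (img / 255.0).astype(np.float32)
    if img.dtype == np.uint16:
        return (img / 65535.0).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def write_sample(dirpath, sample: SyntheticSample):
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / "image.png",
                np.round(sample.image * 255.0).astype(np.uint8))
    iio.imwrite(d / "aux_pos.png",
                np.round(sample.aux_pos * 65535.0).astype(np.uint16))
    iio.imwrite(d / "aux_neg.png",
                np.round(sample.aux_neg * 65535.0).astype(np.uint16))
    if sample.instances.max() > 65535:
        raise ValueError("instance ids exceed the 16-bit label format")
    tifffile.imwrite(d / "instances.tif", sample.instances.astype(np.uint16))
    (d / "classes.json").write_text(
        json.dumps({str(k): v for k, v in sample.classes.items()},
                   indent=0, sort_keys=True))


def load_sample(dirpath) -> SyntheticSample:
    d = Path(dirpath)
    image = _to_unit(_read_raster(d / "image.png"))
    aux_pos = _to_unit(_read_raster(d / "aux_pos.png"))
    aux_neg = _to_unit(_read_raster(d / "aux_neg.png"))
    instances = _read_raster(d / "instances.tif").astype(np.int32)
    shapes = {a.shape[:2] for a in (image, aux_pos, aux_neg, instances)}
    if len(shapes) != 1:
        raise ValueError(f"rasters of sample {d} disagree in shape: {shapes}")
    classes = {int(k): v for k, v in
               json.loads((d / "classes.json").read_text()).items()}
    return SyntheticSample(image=image, aux_pos=aux_pos, aux_neg=aux_neg,
                           instances=instances, classes=classes)


def write_dataset(root, samples: list[SyntheticSample],
                  params: SynthParams | None = None,
                  split: dict[str, list[str]] | None = None) -> DatasetIndex:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        name = f"sample_{i:04d}"
        write_sample(root / name, s)
        entries.append({"name": name,
                        "image": f"{name}/image.png",
                        "aux_pos": f"{name}/aux_pos.png",
                        "aux_neg": f"{name}/aux_neg.png",
                        "instances": f"{name}/instances.tif",
                        "classes": f"{name}/classes.json"})
    manifest = {"samples": entries,
                "split": split or {},
                "params": asdict(params) if params is not None else None}
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return DatasetIndex(root=root, samples=entries, split=split or {},
                        params=params)


def load_index(root) -> DatasetIndex:
    root = Path(root)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    params = manifest.get("params")
    if params is not None:
        for key in ("radius_range", "eccentricity_range"):
            if key in params and params[key] is not None:
                params[key] = tuple(params[key])
        params = SynthParams(**params)
    return DatasetIndex(root=root, samples=manifest["samples"],
                        split=manifest.get("split") or {}, params=params)


def load_dataset(root, part: str | None = None) -> list[SyntheticSample]:
    idx = load_index(root)
    names = idx.names(part) if part else idx.names()
    return [load_sample(idx.root / n) for n in names]
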