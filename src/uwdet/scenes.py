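"""Synthetic underwater-like labeled scenes.

The generator emulates the statistical character of shallow-water benthic
imagery used for organism detection: a textured seafloor background, a handful
of organism classes rendered as class-distinct parametric shapes, and the
degradations typical of underwater optics — a blue-green color cast, contrast
compression, blur and sensor noise.  Five classes mirror the usual benthic
survey palette:

====  ===========  ==========================================
 id    organism     shape family
====  ===========  ==========================================
 0     echinus      spiky disc (many-lobed polar curve), dark
 1     starfish     five-armed star, warm orange
 2     holothurian  elongated rotated ellipse, olive brown
 3     scallop      fan / half disc, pale
 4     waterweeds   thin wavy blade, green
====  ===========  ==========================================

Every emitted bounding box is the exact bounding box of the rendered shape
mask, and all degradations are purely photometric, so labels are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import (DatasetManifest, LabelRecord, save_image, save_labels,
                   write_dataset_meta, xyxy_to_labels)

__all__ = ["SceneSpec", "GenerationError", "generate_scene",
           "generate_dataset", "render_clean_scene", "degrade"]

CLASS_NAMES = ["echinus", "starfish", "holothurian", "scallop", "waterweeds"]

_BASE_COLORS = np.array([
    [0.15, 0.12, 0.18],   # echinus: dark purple-black
    [0.85, 0.45, 0.20],   # starfish: orange
    [0.45, 0.42, 0.25],   # holothurian: olive
    [0.85, 0.80, 0.70],   # scallop: pale shell
    [0.20, 0.65, 0.30],   # waterweeds: green
])


class GenerationError(RuntimeError):
    """Object placement failed within the retry budget."""


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene."""

    size: int = 416
    n_objects: tuple[int, int] = (3, 10)
    num_classes: int = 5
    scale_range: tuple[float, float] = (0.08, 0.28)  # object diameter / image
    occlusion_prob: float = 0.3
    cast_strength: float = 0.4
    contrast_compression: float = 0.5
    blur_sigma: float = 1.2
    noise_sigma: float = 0.03
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        if self.n_objects[0] > self.n_objects[1] or self.n_objects[0] < 1:
            raise ValueError("n_objects range must be ordered and positive")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must lie in [0, 1]")
        if not 1 <= self.num_classes <= len(CLASS_NAMES):
            raise ValueError(f"num_classes must be in [1, {len(CLASS_NAMES)}]")


# -- shape masks -------------------------------------------------------------

def _polar_mask(size: int, cx: float, cy: float, radius_fn, rot: float,
                aspect: float = 1.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    # rotate then squash to create anisotropic bodies
    ca, sa = np.cos(rot), np.sin(rot)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    return r <= radius_fn(theta)


def _shape_mask(cls: int, size: int, cx: float, cy: float, r0: float,
                rng: np.random.Generator) -> np.ndarray:
    rot = rng.uniform(0, 2 * np.pi)
    if cls == 0:      # echinus: spiky disc
        lobes = rng.integers(8, 14)
        return _polar_mask(size, cx, cy,
                           lambda t: r0 * (0.7 + 0.3 * np.abs(np.cos(lobes * t / 2))),
                           rot)
    if cls == 1:      # starfish: 5-armed star
        return _polar_mask(size, cx, cy,
                           lambda t: r0 * (0.55 + 0.45 * np.cos(5 * t)), rot)
    if cls == 2:      # holothurian: elongated ellipse
        return _polar_mask(size, cx, cy, lambda t: r0, rot,
                           aspect=rng.uniform(0.35, 0.5))
    if cls == 3:      # scallop: fan (half disc with scalloped rim)
        def rim(t):
            half = (np.cos(t) > -0.15)
            return r0 * (0.92 + 0.08 * np.cos(9 * t)) * half
        return _polar_mask(size, cx, cy, rim, rot)
    if cls == 4:      # waterweeds: thin wavy blade
        def blade(t):
            return r0 * (0.18 + 0.82 * np.abs(np.cos(t)) ** 6
                         + 0.08 * np.cos(7 * t))
        return _polar_mask(size, cx, cy, blade, rot, aspect=0.9)
    raise ValueError(f"unknown class {cls}")


# -- rendering ---------------------------------------------------------------

def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Sandy seafloor with smooth large-scale structure."""
    base = np.array([0.55, 0.50, 0.42])
    field_ = rng.normal(0, 1, (size, size))
    slow = ndimage.gaussian_filter(field_, sigma=size / 8)
    fast = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), sigma=2.0)
    tex = 0.08 * slow / (np.abs(slow).max() + 1e-9) + 0.03 * fast
    img = np.clip(base[None, None, :] + tex[..., None], 0, 1)
    return img


def render_clean_scene(spec: SceneSpec, rng: np.random.Generator,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Render the un-degraded scene; returns (image, boxes (n, 5) xyxy+cls)."""
    size = spec.size
    img = _background(size, rng)
    occupied = np.zeros((size, size), dtype=bool)
    n_obj = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
    boxes = []
    for _ in range(n_obj):
        placed = False
        for _attempt in range(spec.max_retries):
            cls = int(rng.integers(0, spec.num_classes))
            frac = rng.uniform(*spec.scale_range)
            r0 = frac * size / 2
            cx = rng.uniform(r0, size - r0)
            cy = rng.uniform(r0, size - r0)
            mask = _shape_mask(cls, size, cx, cy, r0, rng)
            if not mask.any():
                continue
            overlap = (mask & occupied).sum() / mask.sum()
            allow = overlap == 0 or (overlap < 0.5
                                     and rng.random() < spec.occlusion_prob)
            if not allow:
                continue
            color = _BASE_COLORS[cls] * rng.uniform(0.85, 1.15, 3)
            shade = 1.0 + 0.15 * ndimage.gaussian_filter(
                rng.normal(0, 1, (size, size)), sigma=3.0)
            patch = np.clip(color[None, None, :] * shade[..., None], 0, 1)
            img = np.where(mask[..., None], patch, img)
            occupied |= mask
            ys, xs = np.nonzero(mask)
            boxes.append((xs.min(), ys.min(), xs.max() + 1, ys.max() + 1, cls))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place object after {spec.max_retries} retries")
    return img, np.array(boxes, dtype=float).reshape(-1, 5)


def degrade(img: np.ndarray, spec: SceneSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Underwater degradation chain: cast -> contrast compression -> blur ->
    noise (the order is fixed).  Purely photometric, so labels are preserved."""
    ambient = np.array([0.05, 0.55, 0.60])   # blue-green water color
    out = (1 - spec.cast_strength) * img + spec.cast_strength * ambient
    k = 1.0 - spec.contrast_compression
    out = 0.5 + (out - 0.5) * k
    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=(spec.blur_sigma,
                                                  spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        out = out + rng.normal(0, spec.noise_sigma, out.shape)
    return np.clip(out, 0, 1)


def generate_scene(spec: SceneSpec, seed: int | None = None,
                   ) -> tuple[np.ndarray, list[LabelRecord]]:
    """One degraded labeled scene.  The same (spec, seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clean, boxes = render_clean_scene(spec, rng)
    img = degrade(clean, spec, rng)
    return img, xyxy_to_labels(boxes, spec.size, spec.size)


def generate_dataset(spec: SceneSpec, n_train: int, n_val: int,
                     out_dir: Path) -> tuple[DatasetManifest, DatasetManifest]:
    """Write a YOLO-layout dataset (train/val) with disjoint per-image seeds."""
    if n_train < 1 or n_val < 1:
        raise ValueError("need at least one image per split")
    out_dir = Path(out_dir)
    manifests = []
    for split, count, offset in (("train", n_train, 0),
                                 ("val", n_val, 1_000_003)):
        img_dir = out_dir / "images" / split
        lbl_dir = out_dir / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        pairs = []
        for i in range(count):
            img, records = generate_scene(spec, seed=spec.seed + offset + i)
            ip = img_dir / f"{split}_{i:05d}.png"
            lp = lbl_dir / f"{split}_{i:05d}.txt"
            save_image(ip, img)
            save_labels(lp, records)
            pairs.append((ip, lp))
        manifests.append(DatasetManifest(
            split=split, pairs=pairs,
            class_names=CLASS_NAMES[:spec.num_classes]))
    write_dataset_meta(out_dir, CLASS_NAMES[:spec.num_classes], ["train", "val"])
    return manifests[0], manifests[1]
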