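"""Two-step underwater image enhancement and union dataset augmentation (UDA).

The enhancement follows the minimal-color-loss / locally-adaptive-contrast
recipe at contract level:

1. **Local adaptive color correction** — identify the dominant (least
   attenuated) channel by its global mean, then pull each attenuated channel
   toward the dominant channel's *local* mean.  The dominant channel itself is
   left untouched, so the correction is minimal in the sense that it only adds
   back lost energy.  This shrinks the blue-green channel-mean imbalance.
2. **Local adaptive contrast enhancement** — remap each pixel around its
   local mean with a gain inversely proportional to the local standard
   deviation, clamped to configured bounds, which lifts contrast exactly where
   it is flat while leaving crisp regions alone.

UDA trains on the union of the raw training split and its enhanced copy.
Enhancement is photometric only (bounding boxes never move) and is applied
strictly to the training split — evaluation images are never enhanced.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import (DatasetManifest, load_image, save_image, write_dataset_meta)

__all__ = ["EnhancementParams", "FormatError", "ParameterError",
           "channel_imbalance", "mean_local_std", "mlle_color_correct",
           "mlle_contrast_enhance", "mlle_enhance", "contrast_gain_map",
           "build_uda_dataset"]


class FormatError(ValueError):
    """Input is not a 3-channel RGB image in [0, 1]."""


class ParameterError(ValueError):
    """Enhancement parameters incompatible with the image."""


@dataclass
class EnhancementParams:
    """Tunables of the two enhancement steps.

    ``color_strength`` in [0, inf) scales how far attenuated channels move
    toward the dominant channel (1 = full local compensation);
    ``window_radius`` (pixels) sets the locality of both steps;
    ``gain_bounds`` clamps the adaptive contrast gain;
    ``target_std`` is the local standard deviation the gain aims for.
    """

    color_strength: float = 0.9
    window_radius: int = 16
    gain_bounds: tuple[float, float] = (1.0, 8.0)
    target_std: float = 0.12

    def __post_init__(self):
        if self.color_strength < 0:
            raise ParameterError("color_strength must be nonnegative")
        if self.window_radius < 1:
            raise ParameterError("window_radius must be >= 1")
        if self.gain_bounds[0] > self.gain_bounds[1]:
            raise ParameterError("gain bounds must be ordered")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError("expected an (H, W, 3) RGB image")
    if not np.isfinite(img).all():
        raise FormatError("image contains non-finite values")
    return img


def _local_mean(channel: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(channel, size=2 * radius + 1, mode="reflect")


# -- measurements (the module's own contract metrics) ------------------------

def channel_imbalance(img: np.ndarray) -> float:
    """max_c |mean_c - gray_mean|: the color-cast severity measure."""
    img = _check_rgb(img)
    means = img.mean(axis=(0, 1))
    return float(np.abs(means - means.mean()).max())


def mean_local_std(img: np.ndarray, radius: int = 16) -> float:
    """Mean over pixels of the local (windowed) standard deviation of the
    gray image: the contrast measure both steps are judged by."""
    img = _check_rgb(img)
    gray = img.mean(axis=2)
    mu = _local_mean(gray, radius)
    var = _local_mean(gray * gray, radius) - mu * mu
    return float(np.sqrt(np.clip(var, 0, None)).mean())


# -- step 1: color correction -------------------------------------------------

def mlle_color_correct(img: np.ndarray,
                       p: EnhancementParams | None = None) -> np.ndarray:
    p = p or EnhancementParams()
    img = _check_rgb(img)
    means = img.mean(axis=(0, 1))
    dom = int(np.argmax(means))
    local = np.stack([_local_mean(img[..., c], p.window_radius)
                      for c in range(3)], axis=-1)
    out = img.copy()
    for c in range(3):
        if c == dom:
            continue
        shift = p.color_strength * (local[..., dom] - local[..., c])
        out[..., c] = img[..., c] + np.maximum(shift, 0.0)
    return np.clip(out, 0.0, 1.0)


# -- step 2: contrast enhancement ---------------------------------------------

def contrast_gain_map(img: np.ndarray,
                      p: EnhancementParams | None = None) -> np.ndarray:
    """The adaptive gain field, clamped to ``p.gain_bounds`` everywhere."""
    p = p or EnhancementParams()
    img = _check_rgb(img)
    if 2 * p.window_radius + 1 > min(img.shape[:2]):
        raise ParameterError("window larger than the image")
    gray = img.mean(axis=2)
    mu = _local_mean(gray, p.window_radius)
    var = _local_mean(gray * gray, p.window_radius) - mu * mu
    sigma = np.sqrt(np.clip(var, 0, None))
    gain = p.target_std / (sigma + 1e-6)
    return np.clip(gain, p.gain_bounds[0], p.gain_bounds[1])


def mlle_contrast_enhance(img: np.ndarray,
                          p: EnhancementParams | None = None) -> np.ndarray:
    p = p or EnhancementParams()
    img = _check_rgb(img)
    gain = contrast_gain_map(img, p)
    out = np.empty_like(img)
    for c in range(3):
        mu = _local_mean(img[..., c], p.window_radius)
        out[..., c] = mu + gain * (img[..., c] - mu)
    return np.clip(out, 0.0, 1.0)


def mlle_enhance(img: np.ndarray,
                 p: EnhancementParams | None = None) -> np.ndarray:
    """Full pipeline: color correction followed by contrast enhancement."""
    p = p or EnhancementParams()
    return mlle_contrast_enhance(mlle_color_correct(img, p), p)


# -- union dataset augmentation ----------------------------------------------

ENHANCED_SUFFIX = "_mlle"


def build_uda_dataset(train: DatasetManifest,
                      p: EnhancementParams | None = None,
                      out_dir: Path | str = "uda") -> DatasetManifest:
    """Union of the raw training split and its enhanced copy (size 2N).

    Originals are copied verbatim; each enhanced image carries a byte-identical
    copy of its source label file (enhancement never moves a box).  Only the
    training split is touched — validation/test manifests are not an input and
    cannot be altered.  Deterministic: rebuilding yields an identical layout.
    """
    p = p or EnhancementParams()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images" / train.split
    lbl_dir = out_dir / "labels" / train.split
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    missing = [str(lp) for _, lp in train.pairs if not Path(lp).exists()]
    if missing:
        from .data import ManifestError
        raise ManifestError("missing label files: " + ", ".join(missing))
    pairs = []
    for img_path, lbl_path in train.pairs:
        img_path, lbl_path = Path(img_path), Path(lbl_path)
        raw_img = img_dir / img_path.name
        raw_lbl = lbl_dir / f"{img_path.stem}.txt"
        shutil.copyfile(img_path, raw_img)
        shutil.copyfile(lbl_path, raw_lbl)
        enh_img = img_dir / f"{img_path.stem}{ENHANCED_SUFFIX}.png"
        enh_lbl = lbl_dir / f"{img_path.stem}{ENHANCED_SUFFIX}.txt"
        save_image(enh_img, mlle_enhance(load_image(img_path), p))
        shutil.copyfile(lbl_path, enh_lbl)
        pairs.extend([(raw_img, raw_lbl), (enh_img, enh_lbl)])
    write_dataset_meta(out_dir, train.class_names, [train.split])
    return DatasetManifest(split=train.split, pairs=pairs,
                           class_names=list(train.class_names))
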