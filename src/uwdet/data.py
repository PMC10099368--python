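"""YOLO-layout dataset reading/writing, letterbox resizing and mosaic.

Conventions (used everywhere in the package):

* label files hold one line per box, ``class_id cx cy w h``, center-format
  floats normalized to the image dimensions;
* in memory, pixel boxes are ``xyxy`` with 0-based, half-open coordinates;
* the dataset root contains ``images/<split>/`` and ``labels/<split>/`` plus
  an optional ``data.yaml`` naming the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "LabelRecord", "DatasetManifest", "ManifestError", "LabelParseError",
    "read_yolo_dataset", "load_labels", "save_labels", "load_image",
    "save_image", "letterbox", "plain_resize", "unletterbox_boxes",
    "mosaic_augment", "labels_to_xyxy", "xyxy_to_labels",
]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp")
PAD_GRAY = 114 / 255.0   # border fill used by letterbox and mosaic


class ManifestError(ValueError):
    """Dataset layout problems: missing directories, labels or classes."""


class LabelParseError(ValueError):
    """A label line that cannot be parsed or validated (carries file + line)."""


@dataclass(frozen=True)
class LabelRecord:
    """A ground-truth box: class id plus normalized center-format geometry."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise LabelParseError(f"negative class id {self.class_id}")
        if not (self.w > 0 and self.h > 0):
            raise LabelParseError("box width/height must be positive")
        for v in (self.cx, self.cy, self.w, self.h):
            if not (0.0 <= v <= 1.0):
                raise LabelParseError(f"coordinate {v} outside [0, 1]")


@dataclass
class DatasetManifest:
    """Images, labels and class names for one split of a YOLO-layout dataset."""

    split: str
    pairs: list[tuple[Path, Path]]
    class_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


# -- label files ------------------------------------------------------------

def load_labels(path: Path, num_classes: int | None = None) -> list[LabelRecord]:
    records: list[LabelRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            rec = LabelRecord(cls, *vals)
        except LabelParseError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
        if num_classes is not None and cls >= num_classes:
            raise LabelParseError(
                f"{path}:{lineno}: class {cls} out of range [0, {num_classes})")
        records.append(rec)
    return records


def save_labels(path: Path, records: list[LabelRecord]) -> None:
    lines = [f"{r.class_id} {r.cx:.6f} {r.cy:.6f} {r.w:.6f} {r.h:.6f}"
             for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_dataset(root: Path, split: str,
                      class_names: list[str] | None = None) -> DatasetManifest:
    """Build and validate a manifest for ``root/images/<split>``.

    Empty label files are allowed (background images); a missing label file,
    a malformed line or an out-of-range class id is an error.
    """
    root = Path(root)
    img_dir = root / "images" / split
    lbl_dir = root / "labels" / split
    if not img_dir.is_dir():
        raise ManifestError(f"missing image directory {img_dir}")
    if not lbl_dir.is_dir():
        raise ManifestError(f"missing label directory {lbl_dir}")
    if class_names is None:
        meta = root / "data.yaml"
        if meta.exists():
            class_names = list(yaml.safe_load(meta.read_text()).get("names", []))
        else:
            class_names = []
    images = sorted(p for p in img_dir.iterdir()
                    if p.suffix.lower() in IMAGE_SUFFIXES)
    if not images:
        raise ManifestError(f"no images found under {img_dir}")
    pairs, missing = [], []
    for img in images:
        lbl = lbl_dir / f"{img.stem}.txt"
        if not lbl.exists():
            missing.append(str(lbl))
            continue
        load_labels(lbl, num_classes=len(class_names) or None)  # validate
        pairs.append((img, lbl))
    if missing:
        raise ManifestError("missing label files: " + ", ".join(missing))
    return DatasetManifest(split=split, pairs=pairs, class_names=class_names)


# -- image files ------------------------------------------------------------

def load_image(path: Path) -> np.ndarray:
    """RGB image as float64 (H, W, 3) in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def save_image(path: Path, img: np.ndarray) -> None:
    arr = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


# -- geometry ---------------------------------------------------------------

def labels_to_xyxy(records: list[LabelRecord], width: int,
                   height: int) -> np.ndarray:
    """Normalized center-format records -> pixel xyxy array (n, 5): box + cls."""
    if not records:
        return np.zeros((0, 5))
    out = np.empty((len(records), 5))
    for i, r in enumerate(records):
        out[i] = (
            (r.cx - r.w / 2) * width, (r.cy - r.h / 2) * height,
            (r.cx + r.w / 2) * width, (r.cy + r.h / 2) * height, r.class_id,
        )
    return out


def xyxy_to_labels(boxes: np.ndarray, width: int, height: int) -> list[LabelRecord]:
    records = []
    for x1, y1, x2, y2, cls in boxes:
        records.append(LabelRecord(
            int(cls),
            cx=np.clip((x1 + x2) / 2 / width, 0, 1),
            cy=np.clip((y1 + y2) / 2 / height, 0, 1),
            w=min((x2 - x1) / width, 1.0),
            h=min((y2 - y1) / height, 1.0),
        ))
    return records


def _resize(img: np.ndarray, new_h: int, new_w: int) -> np.ndarray:
    pil = Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8))
    out = pil.resize((new_w, new_h), Image.BILINEAR)
    return np.asarray(out, dtype=np.float64) / 255.0


def letterbox(img: np.ndarray, records: list[LabelRecord], size: int,
              ) -> tuple[np.ndarray, list[LabelRecord]]:
    """Aspect-preserving resize onto a ``size x size`` gray-padded canvas.

    Labels are remapped into the new frame and stay normalized.  Padding is
    split symmetrically (extra pixel goes to the bottom/right).
    """
    if size % 32:
        raise ValueError("target size must be divisible by 32")
    h, w = img.shape[:2]
    scale = size / max(h, w)
    new_h, new_w = round(h * scale), round(w * scale)
    resized = img if (new_h, new_w) == (h, w) else _resize(img, new_h, new_w)
    top = (size - new_h) // 2
    left = (size - new_w) // 2
    canvas = np.full((size, size, 3), PAD_GRAY)
    canvas[top:top + new_h, left:left + new_w] = resized
    out_records = [LabelRecord(
        r.class_id,
        cx=(r.cx * new_w + left) / size,
        cy=(r.cy * new_h + top) / size,
        w=r.w * new_w / size,
        h=r.h * new_h / size,
    ) for r in records]
    return canvas, out_records


def unletterbox_boxes(boxes_xyxy: np.ndarray, orig_hw: tuple[int, int],
                      size: int) -> np.ndarray:
    """Map pixel boxes from the letterboxed frame back to the original image."""
    h, w = orig_hw
    scale = size / max(h, w)
    new_h, new_w = round(h * scale), round(w * scale)
    top = (size - new_h) // 2
    left = (size - new_w) // 2
    out = boxes_xyxy.copy().astype(float)
    out[:, [0, 2]] = (out[:, [0, 2]] - left) / scale
    out[:, [1, 3]] = (out[:, [1, 3]] - top) / scale
    out[:, [0, 2]] = np.clip(out[:, [0, 2]], 0, w)
    out[:, [1, 3]] = np.clip(out[:, [1, 3]], 0, h)
    return out


def plain_resize(img: np.ndarray, records: list[LabelRecord], size: int,
                 ) -> tuple[np.ndarray, list[LabelRecord]]:
    """Non-aspect-preserving square resize; normalized labels are unchanged."""
    return _resize(img, size, size), list(records)


# -- mosaic -----------------------------------------------------------------

MIN_BOX_AREA_PX = 4.0       # boxes smaller than this after clipping are dropped
MIN_BOX_SIDE_PX = 1.0


class AugmentationError(ValueError):
    pass


def mosaic_augment(manifest: DatasetManifest, rng_seed: int, size: int,
                   ) -> tuple[np.ndarray, list[LabelRecord]]:
    """Stitch four randomly chosen images around a random center point.

    Each source image is scaled to the mosaic size and cropped into its
    quadrant; boxes are transformed, clipped to the canvas, and dropped when
    the visible remnant degenerates (area < 4 px^2 or a side < 1 px).
    """
    if len(manifest) < 4:
        raise AugmentationError("mosaic needs at least 4 images")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(manifest), size=4, replace=False)
    cx = int(rng.uniform(0.3, 0.7) * size)
    cy = int(rng.uniform(0.3, 0.7) * size)
    canvas = np.full((size, size, 3), PAD_GRAY)
    out_boxes = []
    corners = [(0, 0, cx, cy), (cx, 0, size, cy), (0, cy, cx, size),
               (cx, cy, size, size)]
    for (x1, y1, x2, y2), i in zip(corners, idx):
        img_path, lbl_path = manifest.pairs[i]
        img = load_image(img_path)
        records = load_labels(lbl_path)
        h, w = img.shape[:2]
        scale = size / max(h, w)
        tile = _resize(img, round(h * scale), round(w * scale))
        th, tw = tile.shape[:2]
        # anchor the tile so its corner meets the mosaic center
        if x2 == cx:     # left column: right edge at cx
            off_x = cx - tw
        else:            # right column: left edge at cx
            off_x = x1
        if y2 == cy:     # top row
            off_y = cy - th
        else:
            off_y = y1
        # visible region of the tile
        vx1, vy1 = max(x1, off_x), max(y1, off_y)
        vx2 = min(x2, off_x + tw)
        vy2 = min(y2, off_y + th)
        if vx2 <= vx1 or vy2 <= vy1:
            continue
        canvas[vy1:vy2, vx1:vx2] = tile[vy1 - off_y:vy2 - off_y,
                                        vx1 - off_x:vx2 - off_x]
        boxes = labels_to_xyxy(records, tw, th)
        if len(boxes):
            boxes[:, [0, 2]] += off_x
            boxes[:, [1, 3]] += off_y
            boxes[:, 0] = np.clip(boxes[:, 0], vx1, vx2)
            boxes[:, 2] = np.clip(boxes[:, 2], vx1, vx2)
            boxes[:, 1] = np.clip(boxes[:, 1], vy1, vy2)
            boxes[:, 3] = np.clip(boxes[:, 3], vy1, vy2)
            out_boxes.append(boxes)
    if out_boxes:
        boxes = np.concatenate(out_boxes, axis=0)
        wpx = boxes[:, 2] - boxes[:, 0]
        hpx = boxes[:, 3] - boxes[:, 1]
        keep = ((wpx >= MIN_BOX_SIDE_PX) & (hpx >= MIN_BOX_SIDE_PX)
                & (wpx * hpx >= MIN_BOX_AREA_PX))
        boxes = boxes[keep]
    else:
        boxes = np.zeros((0, 5))
    return canvas, xyxy_to_labels(boxes, size, size)


# -- writing ----------------------------------------------------------------

def write_dataset_meta(root: Path, class_names: list[str],
                       splits: list[str]) -> None:
    payload = {"names": list(class_names), "splits": list(splits)}
    (Path(root) / "data.yaml").write_text(yaml.safe_dump(payload))
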