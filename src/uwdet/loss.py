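"""Training loss: CIoU box regression + BCE objectness and classification.

Target assignment follows the anchor-matching recipe of YOLOv5: a ground-truth
box is assigned to every anchor whose width/height ratio to the box is within
``anchor_t`` (both ways), in its own grid cell and in the up-to-two adjacent
cells nearest the box center.  Box decoding is the sigmoid-based YOLOv5
parameterization: ``xy = 2*sigmoid(t) - 0.5 + cell`` and
``wh = (2*sigmoid(t))^2 * anchor`` (grid units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor, concatenate

__all__ = ["LossParts", "build_targets", "ciou_xywh", "yolo_loss"]

LEVEL_BALANCE = (4.0, 1.0, 0.4)   # objectness weight per pyramid level


@dataclass
class LossParts:
    """Unweighted loss terms plus the gain-weighted total (all Tensors)."""

    box: Tensor
    obj: Tensor
    cls: Tensor
    total: Tensor

    def as_floats(self) -> tuple[float, float, float, float]:
        return (self.box.item(), self.obj.item(), self.cls.item(),
                self.total.item())


def build_targets(targets: np.ndarray, anchors: np.ndarray,
                  strides: np.ndarray, grid_sizes: list[tuple[int, int]],
                  anchor_t: float = 4.0):
    """Assign normalized targets to (level, image, anchor, cell) slots.

    ``targets`` is (nt, 6): image index, class, cx, cy, w, h (normalized).
    Returns, per level: ``(b, a, gj, gi)`` index arrays, the regression target
    ``(dx, dy, gw, gh)`` (offsets within the cell and sizes in grid units),
    the matched anchor (grid units) and the class ids.
    """
    out = []
    targets = np.asarray(targets, float).reshape(-1, 6)
    offsets = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]], float)
    for level, (stride, (gh_n, gw_n)) in enumerate(zip(strides, grid_sizes)):
        anch = anchors[level] / stride            # grid units
        if len(targets) == 0:
            out.append((np.zeros(0, int), np.zeros(0, int), np.zeros(0, int),
                        np.zeros(0, int), np.zeros((0, 4)), np.zeros((0, 2)),
                        np.zeros(0, int)))
            continue
        g = targets.copy()
        g[:, 2] *= gw_n
        g[:, 4] *= gw_n
        g[:, 3] *= gh_n
        g[:, 5] *= gh_n
        # anchor ratio filter
        matches = []
        for ai, (aw, ah) in enumerate(anch):
            r = np.stack([g[:, 4] / aw, g[:, 5] / ah], axis=1)
            ok = np.maximum(r, 1 / r).max(axis=1) < anchor_t
            m = g[ok]
            if len(m):
                matches.append(np.column_stack([m, np.full(len(m), ai)]))
        if not matches:
            out.append((np.zeros(0, int), np.zeros(0, int), np.zeros(0, int),
                        np.zeros(0, int), np.zeros((0, 4)), np.zeros((0, 2)),
                        np.zeros(0, int)))
            continue
        m = np.concatenate(matches, axis=0)       # (nm, 7)
        gx, gy = m[:, 2], m[:, 3]
        fx, fy = gx % 1.0, gy % 1.0
        picks = [np.ones(len(m), bool),
                 (fx < 0.5) & (gx > 1.0),
                 (fx > 0.5) & (gx < gw_n - 1.0),
                 (fy < 0.5) & (gy > 1.0),
                 (fy > 0.5) & (gy < gh_n - 1.0)]
        rows, offs = [], []
        for take, off in zip(picks, offsets):
            rows.append(m[take])
            offs.append(np.broadcast_to(off * 0.5, (take.sum(), 2)))
        m = np.concatenate(rows, axis=0)
        off = np.concatenate(offs, axis=0)
        b = m[:, 0].astype(int)
        cls = m[:, 1].astype(int)
        a = m[:, 6].astype(int)
        gi = np.clip((m[:, 2] - off[:, 0]).astype(int), 0, gw_n - 1)
        gj = np.clip((m[:, 3] - off[:, 1]).astype(int), 0, gh_n - 1)
        tbox = np.column_stack([m[:, 2] - gi, m[:, 3] - gj, m[:, 4], m[:, 5]])
        out.append((b, a, gj, gi, tbox, anch[a], cls))
    return out


def ciou_xywh(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between predicted (n, 4) center-format boxes (autograd)
    and target boxes (plain array), both in the same units."""
    t = np.asarray(target, float).reshape(-1, 4)
    eps = 1e-9
    px, py, pw, ph = (pred[:, i] for i in range(4))
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = (p_x2.minimum(Tensor(t_x2)) - p_x1.maximum(Tensor(t_x1))).maximum(0.0)
    ih = (p_y2.minimum(Tensor(t_y2)) - p_y1.maximum(Tensor(t_y1))).maximum(0.0)
    inter = iw * ih
    union = pw * ph + Tensor(tw * th) - inter + eps
    iou = inter / union
    cw = p_x2.maximum(Tensor(t_x2)) - p_x1.minimum(Tensor(t_x1))
    ch = p_y2.maximum(Tensor(t_y2)) - p_y1.minimum(Tensor(t_y1))
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - Tensor(tx)) ** 2 + (py - Tensor(ty)) ** 2
    v = (4.0 / np.pi ** 2) * ((Tensor(np.arctan(tw / (th + eps)))
                               - (pw / (ph + eps)).atan()) ** 2)
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))   # detached
    return iou - rho2 / c2 - alpha * v


def yolo_loss(preds: list[Tensor], targets: np.ndarray, anchors: np.ndarray,
              strides: np.ndarray, num_classes: int,
              gains: dict | None = None, anchor_t: float = 4.0) -> LossParts:
    """Three-term detection loss over the raw per-scale prediction maps.

    ``preds[l]`` has shape (N, n_anchors, H, W, 5 + nc).  Returns the
    unweighted box/objectness/classification terms and the gain-weighted
    total.  Raises ``FloatingPointError`` naming the term if one goes
    non-finite.
    """
    gains = {"box": 0.05, "obj": 1.0, "cls": 0.5, **(gains or {})}
    grid_sizes = [(p.shape[2], p.shape[3]) for p in preds]
    assigned = build_targets(targets, anchors, strides, grid_sizes,
                             anchor_t=anchor_t)
    lbox = Tensor(0.0)
    lcls = Tensor(0.0)
    lobj = Tensor(0.0)
    n_box_terms = 0
    for level, (p, (b, a, gj, gi, tbox, anch, cls)) in enumerate(
            zip(preds, assigned)):
        tobj = np.zeros(p.shape[:4])
        if len(b):
            ps = p[(b, a, gj, gi)]                      # (nm, 5+nc)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(anch)
            pbox = concatenate([pxy, pwh], axis=1)
            ciou = ciou_xywh(pbox, tbox)
            lbox = lbox + (1.0 - ciou).sum()
            n_box_terms += len(b)
            np.maximum.at(tobj, (b, a, gj, gi), np.clip(ciou.data, 0, None))
            if num_classes > 1:
                onehot = np.zeros((len(b), num_classes))
                onehot[np.arange(len(b)), cls] = 1.0
                lcls = lcls + ps[:, 5:].bce_with_logits(onehot).mean()
        lobj = lobj + p[..., 4].bce_with_logits(tobj).mean() \
            * LEVEL_BALANCE[level]
    if n_box_terms:
        lbox = lbox * (1.0 / n_box_terms)
    total = gains["box"] * lbox + gains["obj"] * lobj + gains["cls"] * lcls
    for name, term in (("box", lbox), ("obj", lobj), ("cls", lcls)):
        if not np.isfinite(term.data).all():
            raise FloatingPointError(f"non-finite {name} loss term")
    return LossParts(box=lbox, obj=lobj, cls=lcls, total=total)
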