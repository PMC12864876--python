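"""Anchor-free pest localization with a Feature Pyramid Network.

A small strided convolutional backbone produces bottom-up maps C1..C4 at
strides 4/8/16/32. The pyramid merge follows the classic top-down rule

    D_j = Upsample(D_p) + D_h

where ``D_p`` is the already-merged coarser map, ``D_h`` the 1x1 lateral
projection of the bottom-up map at this level, and Upsample is nearest
neighbour x2. An adaptive feature-upsampling (AdaUp) stage then scales each
pyramid level by a learnable sigmoid gate before a shared dense head predicts,
per cell, an objectness logit and four box offsets (center offsets in units of
the level stride, log-size relative to the stride).

The two tunable hyperparameters exposed to the optimizer are the pyramid
channel width (``hidden_width``, integer in [5, 255]) and the learning-rate
gene (real in [0.01, 0.99], applied multiplicatively onto a 0.01 base rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .metrics import box_iou
from .synthetic_scenes import DatasetSplit, SyntheticScene

__all__ = ["DetectorConfig", "Detection", "FeaturePyramid", "FPNDetector",
           "fpn_merge", "upsample_nearest2x", "decode_cell", "encode_box",
           "nms", "detect", "train_detector"]

_STRIDES = (4, 8, 16, 32)


@dataclass(frozen=True)
class DetectorConfig:
    hidden_width: int = 32        # pyramid channels; tunable gene in [5, 255]
    learning_rate: float = 0.3    # gene in [0.01, 0.99]; effective = gene * 0.01
    epochs: int = 40
    batch_size: int = 16
    score_threshold: float = 0.5
    nms_iou: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 5 <= self.hidden_width <= 255:
            raise ValueError("hidden_width must lie in [5, 255]")
        if not 0.01 <= self.learning_rate <= 0.99:
            raise ValueError("learning_rate gene must lie in [0.01, 0.99]")
        if not 1 <= self.epochs <= 250:
            raise ValueError("epochs must lie in [1, 250]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def effective_lr(self) -> float:
        return self.learning_rate * 0.01


@dataclass(frozen=True)
class Detection:
    box: tuple[float, float, float, float]
    score: float


@dataclass
class FeaturePyramid:
    """Ordered multi-scale maps, finest first; all share ``channels_common``."""

    levels: list          # each (N, channels_common, H/2^(l+1), W/2^(l+1))
    channels_common: int


def _stage_widths(hidden_width: int) -> list[int]:
    base = max(2, hidden_width // 8)
    return [base, 2 * base, 4 * base, 4 * base]


# -- pure merge (array form, used by tests and by the model) ------------------

def upsample_nearest2x(a: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 on the trailing two axes."""
    return a.repeat(2, axis=-2).repeat(2, axis=-1)


def fpn_merge(projected: list[np.ndarray]) -> list[np.ndarray]:
    """Top-down merge of laterally projected maps (finest first).

    The coarsest level passes through; every finer level is the sum of its
    lateral map and the x2-upsampled previously merged map.
    """
    if len(projected) < 2:
        raise ValueError("fpn_merge needs at least 2 levels")
    merged = [None] * len(projected)
    merged[-1] = projected[-1]
    for lvl in range(len(projected) - 2, -1, -1):
        up = upsample_nearest2x(merged[lvl + 1])
        if up.shape != projected[lvl].shape:
            raise ValueError(
                f"level {lvl}: upsampled shape {up.shape} does not match "
                f"lateral shape {projected[lvl].shape}")
        merged[lvl] = up + projected[lvl]
    return merged


# -- box encode / decode ------------------------------------------------------

def decode_cell(i: int, j: int, stride: int, dx: float, dy: float,
                dw: float, dh: float) -> tuple[float, float, float, float]:
    """Cell-relative offsets -> box. ``dx, dy`` are pixel offsets of the center
    from the cell center; ``dw, dh`` log sizes relative to the stride."""
    cx = (j + 0.5) * stride + dx
    cy = (i + 0.5) * stride + dy
    w = stride * np.exp(dw)
    h = stride * np.exp(dh)
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def encode_box(box, i: int, j: int, stride: int) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    dx = cx - (j + 0.5) * stride
    dy = cy - (i + 0.5) * stride
    dw = np.log((x1 - x0) / stride)
    dh = np.log((y1 - y0) / stride)
    return dx, dy, dw, dh


def nms(dets: list[Detection], iou_threshold: float) -> list[Detection]:
    kept: list[Detection] = []
    for d in sorted(dets, key=lambda d: -d.score):
        if all(box_iou(d.box, k.box) < iou_threshold for k in kept):
            kept.append(d)
    return kept


# -- the model ----------------------------------------------------------------

class FPNDetector:
    """Backbone + FPN + AdaUp gates + shared anchor-free head."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.trained = False
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
        widths = _stage_widths(config.hidden_width)
        c = config.hidden_width
        head_hidden = min(c, 64)
        p: dict[str, nn.Tensor] = {}
        chans = [3] + widths[:1] + widths   # conv0 (stem) + 4 strided stages
        for k in range(5):
            p[f"bb_w{k}"] = nn.he(rng, chans[k + 1], chans[k], 3, 3)
            p[f"bb_b{k}"] = nn.Tensor(np.zeros(chans[k + 1]), requires_grad=True)
        for lvl, w in enumerate(widths):
            p[f"lat_w{lvl}"] = nn.he(rng, c, w, 1, 1)
            p[f"lat_b{lvl}"] = nn.Tensor(np.zeros(c), requires_grad=True)
        p["gates"] = nn.Tensor(np.zeros(4), requires_grad=True)  # AdaUp init
        p["head_w1"] = nn.he(rng, head_hidden, c, 1, 1)
        p["head_b1"] = nn.Tensor(np.zeros(head_hidden), requires_grad=True)
        p["head_w2"] = nn.he(rng, 5, head_hidden, 1, 1)
        # bias objectness low so the untrained detector predicts background
        hb = np.zeros(5)
        hb[0] = -3.0
        p["head_b2"] = nn.Tensor(hb, requires_grad=True)
        self.params = p

    # - forward pieces -
    def backbone_forward(self, x: nn.Tensor) -> list[nn.Tensor]:
        """Bottom-up maps C1..C4 at strides 4, 8, 16, 32."""
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {h}x{w}")
        maps = []
        for k in range(5):
            x = nn.relu(nn.conv2d(x, self.params[f"bb_w{k}"],
                                  self.params[f"bb_b{k}"], stride=2, pad=1))
            if k >= 1:
                maps.append(x)
        return maps

    def fpn_forward(self, bottom_up: list[nn.Tensor]) -> FeaturePyramid:
        projected = [nn.conv2d(m, self.params[f"lat_w{l}"], self.params[f"lat_b{l}"])
                     for l, m in enumerate(bottom_up)]
        merged: list[nn.Tensor] = [None] * 4
        merged[-1] = projected[-1]
        for lvl in range(2, -1, -1):
            merged[lvl] = nn.upsample2x(merged[lvl + 1]) + projected[lvl]
        return FeaturePyramid(levels=merged, channels_common=self.config.hidden_width)

    def adaup_fuse(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        gates = nn.sigmoid(self.params["gates"])
        fused = [lvl * gates[l].reshape(1, 1, 1, 1)
                 for l, lvl in enumerate(pyramid.levels)]
        return FeaturePyramid(levels=fused, channels_common=pyramid.channels_common)

    def head_forward(self, pyramid: FeaturePyramid) -> list[nn.Tensor]:
        out = []
        for lvl in pyramid.levels:
            h = nn.relu(nn.conv2d(lvl, self.params["head_w1"], self.params["head_b1"]))
            out.append(nn.conv2d(h, self.params["head_w2"], self.params["head_b2"]))
        return out

    def forward(self, images: nn.Tensor) -> list[nn.Tensor]:
        return self.head_forward(self.adaup_fuse(self.fpn_forward(
            self.backbone_forward(images))))

    def parameters(self) -> list[nn.Tensor]:
        return list(self.params.values())

    # - persistence -
    def save(self, path: str | Path) -> None:
        with open(Path(path), "wb") as fh:
            np.savez(fh, **{k: v.data for k, v in self.params.items()},
                     __config__=np.frombuffer(
                         json.dumps(self.config.__dict__).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "FPNDetector":
        with np.load(Path(path)) as z:
            cfg = DetectorConfig(**json.loads(z["__config__"].tobytes().decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = z[k].astype(np.float64)
        model.trained = True
        return model


# -- training -----------------------------------------------------------------

def _level_for_size(size: float) -> list[int]:
    """All pyramid levels whose stride lies in [size/8, size]; finest if none."""
    lv = [l for l, s in enumerate(_STRIDES) if size / 8 <= s <= size]
    return lv or [0]


def _build_targets(scenes: list[SyntheticScene], h: int, w: int):
    """Per-level objectness maps, offset maps and positive masks."""
    n = len(scenes)
    obj, off, pos = [], [], []
    for s in _STRIDES:
        hl, wl = h // s, w // s
        obj.append(np.zeros((n, 1, hl, wl)))
        off.append(np.zeros((n, 4, hl, wl)))
        pos.append(np.zeros((n, 1, hl, wl), dtype=bool))
    for si, scene in enumerate(scenes):
        for ann in scene.annotations:
            x0, y0, x1, y1 = ann.box
            size = float(np.sqrt((x1 - x0) * (y1 - y0)))
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            radius = 0.35 * size   # center sampling: positives near the center
            for lvl in _level_for_size(size):
                s = _STRIDES[lvl]
                hl, wl = h // s, w // s
                ii = np.arange(hl)
                jj = np.arange(wl)
                r = max(radius, s / 2 + 1e-6)   # the containing cell always counts
                in_y = (np.abs((ii + 0.5) * s - cy) <= r) & \
                       (((ii + 0.5) * s >= y0) & ((ii + 0.5) * s < y1))
                in_x = (np.abs((jj + 0.5) * s - cx) <= r) & \
                       (((jj + 0.5) * s >= x0) & ((jj + 0.5) * s < x1))
                for i in np.nonzero(in_y)[0]:
                    for j in np.nonzero(in_x)[0]:
                        obj[lvl][si, 0, i, j] = 1.0
                        pos[lvl][si, 0, i, j] = True
                        dx, dy, dw, dh = encode_box(ann.box, i, j, s)
                        off[lvl][si, :, i, j] = (dx / s, dy / s, dw, dh)
    return obj, off, pos


# loss term weights: background suppression and box regression are upweighted
# relative to the (rare) positive-cell objectness term
_W_NEG = 2.0
_W_BOX = 2.0


def _detector_loss(model: FPNDetector, images: nn.Tensor, obj, off, pos) -> nn.Tensor:
    outs = model.forward(images)
    eps = 1e-7
    total = nn.Tensor(0.0)
    for lvl, out in enumerate(outs):
        p = nn.sigmoid(out[:, 0:1])
        t = obj[lvl]
        bce = -(t * nn.log(p + eps) + (1 - t) * nn.log(1 - p + eps))
        n_pos = pos[lvl].sum()
        n_neg = pos[lvl].size - n_pos
        mask = pos[lvl].astype(float)
        if n_pos > 0:
            total = total + (bce * mask).sum() * (1.0 / n_pos)
            # smooth-L1 on normalized offsets at positive cells
            diff = out[:, 1:5] - off[lvl]
            mask4 = np.broadcast_to(mask, diff.shape).copy()
            beta = 0.1
            absdiff = diff * np.sign(diff.data)
            sel = (absdiff.data < beta).astype(float)
            sl1 = (diff * diff) * (0.5 / beta) * sel + (absdiff - 0.5 * beta) * (1 - sel)
            total = total + (sl1 * mask4).sum() * (_W_BOX / (4 * n_pos))
        if n_neg > 0:
            total = total + (bce * (1 - mask)).sum() * (_W_NEG / n_neg)
    return total


def train_detector(split: DatasetSplit, config: DetectorConfig
                   ) -> tuple[FPNDetector, list[float]]:
    """Train on the split's train scenes; returns the model and per-epoch cost."""
    scenes = split.train
    if not scenes:
        raise ValueError("train split is empty")
    h, w = scenes[0].image.shape[:2]
    images = np.stack([s.image.transpose(2, 0, 1) for s in scenes])
    obj, off, pos = _build_targets(scenes, h, w)
    model = FPNDetector(config)
    opt = nn.Adam(model.parameters(), lr=config.effective_lr)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 29)))
    n = len(scenes)
    costs: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            bidx = order[start:start + config.batch_size]
            bobj = [o[bidx] for o in obj]
            boff = [o[bidx] for o in off]
            bpos = [p[bidx] for p in pos]
            loss = _detector_loss(model, nn.Tensor(images[bidx]), bobj, boff, bpos)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"detector training diverged (non-finite loss) at epoch "
                    f"{_epoch}, lr gene {config.learning_rate}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        costs.append(epoch_loss / n_batches)
    model.trained = True
    return model, costs


def detect(image: np.ndarray, model: FPNDetector,
           config: DetectorConfig | None = None) -> list[Detection]:
    """Detections on one HxWx3 image: threshold, decode, NMS, sort by score."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train_detector first")
    cfg = config or model.config
    x = nn.Tensor(image.transpose(2, 0, 1)[None])
    outs = model.forward(x)
    h, w = image.shape[:2]
    dets: list[Detection] = []
    for lvl, out in enumerate(outs):
        s = _STRIDES[lvl]
        arr = out.data[0]
        prob = 1.0 / (1.0 + np.exp(-arr[0]))
        ii, jj = np.nonzero(prob >= cfg.score_threshold)
        for i, j in zip(ii, jj):
            tx, ty, tw, th = arr[1:5, i, j]
            box = decode_cell(i, j, s, tx * s, ty * s, tw, th)
            box = (max(0.0, box[0]), max(0.0, box[1]),
                   min(float(w), box[2]), min(float(h), box[3]))
            if box[2] > box[0] and box[3] > box[1]:
                dets.append(Detection(box=box, score=float(prob[i, j])))
    return nms(dets, cfg.nms_iou)
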