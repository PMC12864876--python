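"""Synthetic pest scenes with known bounding boxes and class labels.

Field-collected pest imagery (IoT camera traps over crops) has three
properties that make detection and classification hard: pests appear at very
different scales, backgrounds are cluttered vegetation, and class identity is
carried by body texture rather than gross shape. The generator reproduces
those properties with fully known ground truth: a low-frequency green/brown
background with optional high-frequency clutter, plus elliptical "pest" blobs
whose texture family (spots / stripes / rings, cycling with hue shifts for
higher class counts) encodes the class.

Boxes are 0-based half-open pixel rectangles ``(x_min, y_min, x_max, y_max)``.
Every scene is a pure function of ``(config.seed, index)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["SceneConfig", "Annotation", "SyntheticScene", "DatasetSplit",
           "generate_scene", "generate_dataset", "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution."""

    image_height: int = 64
    image_width: int = 64
    n_classes: int = 3
    pests_per_image: tuple[int, int] = (1, 3)
    pest_scale: tuple[int, int] = (10, 22)      # object diameter range, px
    background_complexity: float = 0.5          # clutter amount in [0, 1]
    noise_sigma: float = 0.02                   # additive Gaussian, [0,1] scale
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions must be at least 8 px")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        lo, hi = self.pests_per_image
        if lo < 0 or hi < lo:
            raise ValueError("pests_per_image must be a valid range with min >= 0")
        slo, shi = self.pest_scale
        if slo < 4:
            raise ValueError("pest_scale min must be >= 4 px")
        if shi < slo or shi > min(self.image_height, self.image_width) // 2:
            raise ValueError("pest_scale max must be <= min(H, W)/2")
        if not 0.0 <= self.background_complexity <= 1.0:
            raise ValueError("background_complexity must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class Annotation:
    """A single labelled pest: half-open pixel box plus class id."""

    box: tuple[int, int, int, int]
    class_id: int

    def validate(self, height: int, width: int, n_classes: int) -> None:
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
            raise ValueError(f"box {self.box} invalid for {width}x{height} image")
        if not 0 <= self.class_id < n_classes:
            raise ValueError(f"class_id {self.class_id} outside [0, {n_classes})")


@dataclass
class SyntheticScene:
    image: np.ndarray                 # (H, W, 3) float64 in [0, 1]
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class DatasetSplit:
    train: list[SyntheticScene]
    test: list[SyntheticScene]


# -- scene synthesis ----------------------------------------------------------

_BASE_GREEN = np.array([0.28, 0.42, 0.18])
_BASE_BROWN = np.array([0.42, 0.33, 0.20])


def _background(rng: np.random.Generator, h: int, w: int, complexity: float) -> np.ndarray:
    """Vegetation-like background: smooth color field + optional clutter."""
    coarse = rng.normal(size=(6, 6))
    fld = ndimage.zoom(coarse, (h / 6, w / 6), order=3)[:h, :w]
    fld = (fld - fld.min()) / (np.ptp(fld) + 1e-12)
    img = fld[..., None] * _BASE_GREEN + (1 - fld[..., None]) * _BASE_BROWN
    if complexity > 0:
        # high-frequency clutter: speckled leaf litter
        fine = rng.normal(size=(h // 4 + 1, w // 4 + 1))
        fine = ndimage.zoom(fine, 4, order=1)[:h, :w]
        img = img + 0.12 * complexity * fine[..., None]
        n_blades = int(10 * complexity)
        for _ in range(n_blades):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            ln = rng.integers(4, max(5, h // 4))
            ang = rng.uniform(0, np.pi)
            ys = (cy + np.arange(ln) * np.sin(ang)).astype(int) % h
            xs = (cx + np.arange(ln) * np.cos(ang)).astype(int) % w
            img[ys, xs] += rng.uniform(-0.15, 0.15) * complexity
    return np.clip(img, 0, 1)


def _pest_texture(rng: np.random.Generator, d: int, class_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask, rgb patch) for one pest of diameter ``d``.

    Class identity is encoded by texture family — 0: spotted, 1: striped,
    2: ringed — with a hue rotation every 3 classes, so arbitrary class counts
    remain visually distinct.
    """
    yy, xx = np.mgrid[0:d, 0:d]
    cy = cx = (d - 1) / 2.0
    ry = d / 2.0
    rx = d / 2.0 * rng.uniform(0.7, 1.0)         # mild ellipticity
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    mask = r2 <= 1.0

    family = class_id % 3
    hue_cycle = class_id // 3
    body = np.array([0.55, 0.18, 0.12])          # reddish-brown carapace
    accent = np.array([0.92, 0.85, 0.35])        # pale yellow markings
    body = np.roll(body, hue_cycle)
    accent = np.roll(accent, -hue_cycle)

    patch = np.zeros((d, d, 3)) + body
    if family == 0:                               # spots
        n_spots = max(3, d // 3)
        for _ in range(n_spots):
            sy, sx = rng.uniform(0, d, 2)
            sr = max(1.0, d / 10.0)
            sp = (yy - sy) ** 2 + (xx - sx) ** 2 <= sr ** 2
            patch[sp] = accent
    elif family == 1:                             # stripes
        period = max(3, d // 4)
        stripes = ((yy + xx) // (period // 2 + 1)) % 2 == 0
        patch[stripes] = accent
    else:                                         # concentric rings
        rings = (np.sqrt(r2) * 3.0).astype(int) % 2 == 0
        patch[rings] = accent
    # darken the rim so the silhouette reads against clutter
    rim = (r2 > 0.72) & mask
    patch[rim] *= 0.45
    patch += rng.normal(0, 0.02, patch.shape)
    return mask, np.clip(patch, 0, 1)


_MAX_PLACEMENT_TRIES = 40


def generate_scene(config: SceneConfig, index: int) -> SyntheticScene:
    """Render scene ``index`` of the distribution defined by ``config``.

    Pests are placed by rejection sampling so their boxes never overlap; when
    the canvas cannot fit another pest the scene degrades to fewer pests
    rather than raising.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, index)))
    h, w = config.image_height, config.image_width
    img = _background(rng, h, w, config.background_complexity)

    k = int(rng.integers(config.pests_per_image[0], config.pests_per_image[1] + 1))
    annotations: list[Annotation] = []
    boxes: list[tuple[int, int, int, int]] = []
    for _ in range(k):
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            d = int(rng.integers(config.pest_scale[0], config.pest_scale[1] + 1))
            if d > min(h, w):
                continue
            y0 = int(rng.integers(0, h - d + 1))
            x0 = int(rng.integers(0, w - d + 1))
            cand = (x0, y0, x0 + d, y0 + d)
            if any(_boxes_overlap(cand, b) for b in boxes):
                continue
            class_id = int(rng.integers(0, config.n_classes))
            mask, patch = _pest_texture(rng, d, class_id)
            region = img[y0:y0 + d, x0:x0 + d]
            region[mask] = patch[mask]
            # tight box of the rendered mask, half-open
            ys, xs = np.nonzero(mask)
            box = (x0 + int(xs.min()), y0 + int(ys.min()),
                   x0 + int(xs.max()) + 1, y0 + int(ys.max()) + 1)
            boxes.append(cand)
            annotations.append(Annotation(box=box, class_id=class_id))
            placed = True
            break
        if not placed:
            break  # degrade gracefully: fewer pests than drawn

    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, img.shape)
    img = np.clip(img, 0, 1)
    scene = SyntheticScene(image=img, annotations=annotations)
    for a in scene.annotations:
        a.validate(h, w, config.n_classes)
    return scene


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def generate_dataset(config: SceneConfig, n_total: int,
                     train_fraction: float = 0.75,
                     shuffle: bool = False) -> DatasetSplit:
    """Generate ``n_total`` scenes and split train/test.

    ``|train| = floor(train_fraction * n_total)``; assignment is sequential by
    scene index (scene content is i.i.d. across indices) unless ``shuffle``,
    which permutes indices with ``config.seed`` before splitting.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n_total))
    idx = np.arange(n_total)
    if shuffle:
        np.random.default_rng(config.seed).shuffle(idx)
    scenes = {int(i): generate_scene(config, int(i)) for i in idx}
    train = [scenes[int(i)] for i in idx[:n_train]]
    test = [scenes[int(i)] for i in idx[n_train:]]
    return DatasetSplit(train=train, test=test)


def split_sizes(n_total: int, train_fraction: float = 0.75) -> tuple[int, int]:
    """Train/test counts under the floor split rule, without rendering scenes."""
    n_train = int(np.floor(train_fraction * n_total))
    return n_train, n_total - n_train


# -- persistence --------------------------------------------------------------

def write_dataset(split: DatasetSplit, directory: str | Path) -> dict:
    """Write PNGs plus COCO-style JSON and a flat CSV mirror per split.

    Returns a manifest with per-split and per-class counts.
    """
    directory = Path(directory)
    manifest: dict = {"splits": {}}
    for name, scenes in (("train", split.train), ("test", split.test)):
        sub = directory / name
        try:
            sub.mkdir(parents=True, exist_ok=True)
        except OSError as e:
            raise OSError(f"cannot create dataset directory {sub}: {e}") from e
        images, anns = [], []
        class_counts: dict[int, int] = {}
        ann_id = 0
        csv_rows = []
        for i, scene in enumerate(scenes):
            fname = f"{name}_{i:05d}.png"
            arr = (np.clip(scene.image, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(sub / fname)
            h, w = scene.image.shape[:2]
            images.append({"id": i, "file_name": fname, "width": w, "height": h})
            for a in scene.annotations:
                x0, y0, x1, y1 = a.box
                anns.append({"id": ann_id, "image_id": i,
                             "bbox": [x0, y0, x1 - x0, y1 - y0],
                             "category_id": a.class_id, "area": (x1 - x0) * (y1 - y0),
                             "iscrowd": 0})
                csv_rows.append([fname, x0, y0, x1, y1, a.class_id])
                class_counts[a.class_id] = class_counts.get(a.class_id, 0) + 1
                ann_id += 1
        cats = sorted({a["category_id"] for a in anns})
        coco = {"images": images, "annotations": anns,
                "categories": [{"id": c, "name": f"class_{c}"} for c in cats]}
        (sub / "annotations.json").write_text(json.dumps(coco, indent=1))
        with open(sub / "annotations.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["image", "x_min", "y_min", "x_max", "y_max", "class_id"])
            wr.writerows(csv_rows)
        manifest["splits"][name] = {"n_images": len(scenes),
                                    "n_annotations": ann_id,
                                    "per_class": {str(k): v for k, v in
                                                  sorted(class_counts.items())}}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(directory: str | Path) -> DatasetSplit:
    """Inverse of :func:`write_dataset` on its own output layout."""
    directory = Path(directory)
    out: dict[str, list[SyntheticScene]] = {}
    for name in ("train", "test"):
        sub = directory / name
        if not sub.exists():
            out[name] = []
            continue
        try:
            coco = json.loads((sub / "annotations.json").read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ValueError(f"malformed annotation file in {sub}: {e}") from e
        by_image: dict[int, list[Annotation]] = {}
        for rec_idx, rec in enumerate(coco.get("annotations", [])):
            try:
                x, y, bw, bh = rec["bbox"]
                ann = Annotation(box=(int(x), int(y), int(x + bw), int(y + bh)),
                                 class_id=int(rec["category_id"]))
                by_image.setdefault(int(rec["image_id"]), []).append(ann)
            except (KeyError, TypeError, ValueError) as e:
                raise ValueError(
                    f"malformed annotation record {rec_idx} in "
                    f"{sub / 'annotations.json'}: {e}") from e
        scenes = []
        for rec_idx, im in enumerate(coco.get("images", [])):
            try:
                arr = np.asarray(Image.open(sub / im["file_name"])).astype(np.float64) / 255.0
            except (KeyError, OSError) as e:
                raise ValueError(
                    f"malformed image record {rec_idx} in {sub}: {e}") from e
            scenes.append(SyntheticScene(image=arr,
                                         annotations=by_image.get(int(im["id"]), [])))
        out[name] = scenes
    return DatasetSplit(train=out["train"], test=out["test"])
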