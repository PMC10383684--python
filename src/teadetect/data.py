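"""Dataset plumbing and the synthetic tea-scene generator.

Pascal VOC XML is the on-disk annotation dialect: 1-based inclusive pixel
coordinates.  In memory everything is 0-based half-open; the conversion is
centralized in :func:`read_voc` / :func:`write_voc`.

The synthetic generator stands in for field imagery of tea rows: dense,
small, elongated bright-green shoots ("buds", a tip plus a leaf lobe drawn
as overlapping rotated ellipses) scattered over a darker textured green
canopy under a smooth illumination gradient, about a dozen targets per
image.  It emulates the geometry and photometry the detector and the
enhancement pipeline care about — small low-contrast targets, strong
low-frequency lighting — not leaf-level realism.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import resize as sk_resize

__all__ = [
    "LabeledScene",
    "SynthConfig",
    "read_voc",
    "write_voc",
    "letterbox",
    "letterbox_params",
    "mosaic",
    "split_dataset",
    "synth_scene",
    "build_synthetic_dataset",
    "load_image",
    "save_image",
]

CLASS_NAME = "tea bud"
PAD_VALUE = 114  # neutral gray letterbox fill


@dataclass
class LabeledScene:
    image: np.ndarray  # HxWx3 uint8
    boxes: np.ndarray  # (M, 4) xyxy, 0-based half-open
    labels: list = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        if not self.labels:
            self.labels = [CLASS_NAME] * len(self.boxes)
        h, w = self.image.shape[:2]
        if len(self.boxes):
            if np.any(self.boxes[:, 2] <= self.boxes[:, 0]) or np.any(
                self.boxes[:, 3] <= self.boxes[:, 1]
            ):
                raise ValueError("boxes must satisfy x2 > x1, y2 > y1")
            if (
                self.boxes.min() < 0
                or self.boxes[:, [0, 2]].max() > w
                or self.boxes[:, [1, 3]].max() > h
            ):
                raise ValueError("boxes must lie within image bounds")


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(img: np.ndarray, path):
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


# -- Pascal VOC ---------------------------------------------------------------

def read_voc(xml_path, clip: bool = True) -> LabeledScene:
    """Parse a VOC XML file; the image itself is loaded if present on disk."""
    xml_path = Path(xml_path)
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML at {xml_path}: {exc}") from exc
    size = root.find("size")
    w = int(size.findtext("width"))
    h = int(size.findtext("height"))
    filename = root.findtext("filename") or xml_path.stem
    boxes, labels = [], []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        # VOC is 1-based inclusive; internal is 0-based half-open
        x1 = float(bb.findtext("xmin")) - 1
        y1 = float(bb.findtext("ymin")) - 1
        x2 = float(bb.findtext("xmax"))
        y2 = float(bb.findtext("ymax"))
        if x1 < 0 or y1 < 0 or x2 > w or y2 > h:
            warnings.warn(f"box outside image in {xml_path.name}; clipped")
            if clip:
                x1, y1 = max(x1, 0), max(y1, 0)
                x2, y2 = min(x2, w), min(y2, h)
        boxes.append([x1, y1, x2, y2])
        labels.append(obj.findtext("name") or CLASS_NAME)
    img_path = xml_path.parent.parent / "images" / filename
    if img_path.exists():
        image = load_image(img_path)
    else:
        image = np.zeros((h, w, 3), dtype=np.uint8)
    return LabeledScene(
        image=image,
        boxes=np.array(boxes, dtype=np.float64).reshape(-1, 4),
        labels=labels,
        source_id=Path(filename).stem,
    )


def write_voc(scene: LabeledScene, path):
    path = Path(path)
    h, w = scene.image.shape[:2]
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name
    ET.SubElement(root, "filename").text = f"{scene.source_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for (x1, y1, x2, y2), label in zip(scene.boxes, scene.labels):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(int(round(x1)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(y1)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(x2)))
        ET.SubElement(bb, "ymax").text = str(int(round(y2)))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


# -- geometry -----------------------------------------------------------------

def letterbox_params(h: int, w: int, target: int):
    """Scale and symmetric padding taking (h, w) onto a target square."""
    scale = min(target / w, target / h)
    new_w, new_h = int(round(w * scale)), int(round(h * scale))
    pad_x = (target - new_w) // 2
    pad_y = (target - new_h) // 2
    return scale, pad_x, pad_y


def letterbox(scene: LabeledScene, target: int = 640) -> LabeledScene:
    """Aspect-preserving resize with gray padding to target x target."""
    if target % 32:
        raise ValueError("letterbox target must be a multiple of 32")
    h, w = scene.image.shape[:2]
    scale, pad_x, pad_y = letterbox_params(h, w, target)
    new_w, new_h = int(round(w * scale)), int(round(h * scale))
    resized = np.asarray(
        Image.fromarray(scene.image).resize((new_w, new_h), Image.BILINEAR)
    )
    canvas = np.full((target, target, 3), PAD_VALUE, dtype=np.uint8)
    canvas[pad_y : pad_y + new_h, pad_x : pad_x + new_w] = resized
    boxes = scene.boxes.copy()
    if len(boxes):
        boxes[:, [0, 2]] = boxes[:, [0, 2]] * scale + pad_x
        boxes[:, [1, 3]] = boxes[:, [1, 3]] * scale + pad_y
    return LabeledScene(canvas, boxes, list(scene.labels), scene.source_id)


MIN_BOX_SIDE = 2.0  # sub-2-px mosaic fragments are dropped


def mosaic(scenes, canvas: int = 640, seed: int = 0) -> LabeledScene:
    """Compose four scenes around a random center point on one canvas."""
    if len(scenes) != 4:
        raise ValueError("mosaic requires exactly four scenes")
    rng = np.random.default_rng(seed)
    cx = int(rng.uniform(0.25, 0.75) * canvas)
    cy = int(rng.uniform(0.25, 0.75) * canvas)
    out = np.full((canvas, canvas, 3), PAD_VALUE, dtype=np.uint8)
    quads = [
        (0, 0, cx, cy),
        (cx, 0, canvas, cy),
        (0, cy, cx, canvas),
        (cx, cy, canvas, canvas),
    ]
    all_boxes, all_labels = [], []
    for scene, (qx1, qy1, qx2, qy2) in zip(scenes, quads):
        qw, qh = qx2 - qx1, qy2 - qy1
        if qw < 2 or qh < 2:
            continue
        h, w = scene.image.shape[:2]
        s = rng.uniform(0.5, 1.5) * max(qw / w, qh / h)
        new_w, new_h = max(int(w * s), qw), max(int(h * s), qh)
        img = np.asarray(
            Image.fromarray(scene.image).resize((new_w, new_h), Image.BILINEAR)
        )
        ox = rng.integers(0, new_w - qw + 1)
        oy = rng.integers(0, new_h - qh + 1)
        out[qy1:qy2, qx1:qx2] = img[oy : oy + qh, ox : ox + qw]
        if len(scene.boxes):
            b = scene.boxes.copy()
            b[:, [0, 2]] = b[:, [0, 2]] * s - ox + qx1
            b[:, [1, 3]] = b[:, [1, 3]] * s - oy + qy1
            b[:, [0, 2]] = np.clip(b[:, [0, 2]], qx1, qx2)
            b[:, [1, 3]] = np.clip(b[:, [1, 3]], qy1, qy2)
            ok = (b[:, 2] - b[:, 0] >= MIN_BOX_SIDE) & (b[:, 3] - b[:, 1] >= MIN_BOX_SIDE)
            all_boxes.append(b[ok])
            all_labels.extend(
                lbl for lbl, keep in zip(scene.labels, ok) if keep
            )
    boxes = (
        np.concatenate(all_boxes, 0) if all_boxes else np.zeros((0, 4))
    )
    return LabeledScene(out, boxes, all_labels, source_id=f"mosaic{seed}")


def split_dataset(scenes, ratios=(0.70, 0.20, 0.10), seed: int = 0):
    """Seeded shuffle, contiguous partition into train/val/test index lists."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n = len(scenes) if not isinstance(scenes, int) else scenes
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(ratios[0] * n)
    n_val = int(ratios[1] * n)
    return (
        idx[:n_train].tolist(),
        idx[n_train : n_train + n_val].tolist(),
        idx[n_train + n_val :].tolist(),
    )


# -- synthetic scenes ---------------------------------------------------------

@dataclass
class SynthConfig:
    image_size: int = 640
    n_buds: tuple = (8, 16)          # matches roughly a dozen targets/image
    bud_length: tuple = (14.0, 30.0)  # semi-major axis of the shoot, px
    bud_aspect: tuple = (0.35, 0.50)  # semi-minor / semi-major
    bud_color: tuple = (96, 168, 64)  # bright young-shoot green
    bg_color: tuple = (30, 64, 32)    # mature-canopy green
    color_jitter: float = 14.0
    texture_amp: float = 16.0         # high-frequency canopy texture, levels
    illum_amp: float = 0.55           # fractional smooth lighting gradient
    occlusion_prob: float = 0.15
    seed: int = 0


def _draw_bud(img, mask_buf, cy, cx, length, aspect, angle, color, rng):
    """Tip + leaf-lobe ellipse pair; returns the bud's pixel mask."""
    h, w = img.shape[:2]
    mask_buf[:] = False
    rr, cc = draw_ellipse(
        cy, cx, length, max(length * aspect, 1.5), shape=(h, w), rotation=angle
    )
    mask_buf[rr, cc] = True
    # leaf lobe offset sideways near the base, shorter and rounder
    off = 0.3 * length
    lc_y = cy + off * np.sin(angle + 0.9)
    lc_x = cx + off * np.cos(angle + 0.9)
    rr, cc = draw_ellipse(
        lc_y, lc_x, 0.65 * length, max(0.55 * length, 1.5),
        shape=(h, w), rotation=angle + 0.7,
    )
    mask_buf[rr, cc] = True
    img[mask_buf] = np.clip(
        np.array(color, dtype=np.float64) + rng.normal(0, 4, 3), 0, 255
    )
    return mask_buf.copy()


def synth_scene(cfg: SynthConfig, return_mask: bool = False):
    """One seeded scene: textured background, illumination ramp, n buds.

    With ``return_mask`` also returns the boolean union of all bud masks
    (before illumination), the generator's own record of which pixels are
    bud-colored.
    """
    rng = np.random.default_rng(cfg.seed)
    sz = cfg.image_size
    base = np.array(cfg.bg_color, dtype=np.float64)
    # low-frequency canopy patches + per-pixel texture
    coarse = rng.normal(0, 1, (8, 8, 3))
    lowfreq = sk_resize(coarse, (sz, sz, 3), order=1, mode="reflect",
                        anti_aliasing=False) * cfg.color_jitter
    texture = rng.normal(0, cfg.texture_amp, (sz, sz, 3))
    img = base[None, None, :] + lowfreq + texture

    n_lo, n_hi = cfg.n_buds
    n = int(rng.integers(n_lo, n_hi + 1)) if n_hi >= n_lo else 0
    boxes = []
    mask_buf = np.zeros((sz, sz), dtype=bool)
    union_mask = np.zeros((sz, sz), dtype=bool)
    margin = int(cfg.bud_length[1]) + 4
    prev_center = None
    for _ in range(n):
        if prev_center is not None and rng.uniform() < cfg.occlusion_prob:
            # partially occluding neighbor: drop next to the previous bud
            cy = int(np.clip(prev_center[0] + rng.integers(-12, 13), margin, sz - margin))
            cx = int(np.clip(prev_center[1] + rng.integers(-12, 13), margin, sz - margin))
        else:
            cy = int(rng.integers(margin, sz - margin))
            cx = int(rng.integers(margin, sz - margin))
        length = rng.uniform(*cfg.bud_length)
        aspect = rng.uniform(*cfg.bud_aspect)
        angle = rng.uniform(0, np.pi)
        mask = _draw_bud(img, mask_buf, cy, cx, length, aspect, angle,
                         cfg.bud_color, rng)
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            continue
        union_mask |= mask
        boxes.append([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1])
        prev_center = (cy, cx)

    # smooth multiplicative illumination gradient across a random direction
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:sz, 0:sz]
    proj = (np.cos(theta) * xx + np.sin(theta) * yy) / (np.sqrt(2) * sz)
    proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
    illum = 1.0 + cfg.illum_amp * (proj - 0.5) * 2.0
    img = np.clip(img * illum[..., None], 0, 255).astype(np.uint8)
    scene = LabeledScene(
        img,
        np.array(boxes, dtype=np.float64).reshape(-1, 4),
        source_id=f"synth{cfg.seed:06d}",
    )
    return (scene, union_mask) if return_mask else scene


def build_synthetic_dataset(cfg: SynthConfig, n_scenes: int, out_dir,
                            ratios=(0.70, 0.20, 0.10), force: bool = False):
    """Write a VOC-layout directory: images/, annotations/, split lists."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    names = []
    for i in range(n_scenes):
        scene_cfg = SynthConfig(**{**asdict(cfg), "seed": cfg.seed + i})
        scene = synth_scene(scene_cfg)
        save_image(scene.image, out / "images" / f"{scene.source_id}.png")
        write_voc(scene, out / "annotations" / f"{scene.source_id}.xml")
        names.append(scene.source_id)
    tr, va, te = split_dataset(n_scenes, ratios, seed=cfg.seed)
    for part, ids in zip(("train", "val", "test"), (tr, va, te)):
        (out / f"{part}.txt").write_text(
            "".join(names[i] + "\n" for i in sorted(ids))
        )
    (out / "manifest.json").write_text(
        json.dumps({"config": asdict(cfg), "n_scenes": n_scenes}, indent=2)
    )
    return out
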