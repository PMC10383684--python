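"""Detector assembly: backbone, PAN-FPN neck, decoupled anchor-free head.

Eight ablation variants of a YOLOv8s-scale single-class detector are built
from three independent toggles:

* ``use_dcn`` — the last three backbone C2f blocks become C2f_DCN (both
  bottleneck convolutions modulated-deformable);
* ``use_gam`` — a global-attention block follows each of those three stages
  (at 128, 256 and 512 channels, reduction 4);
* ``use_sppfcspc`` — the SPPF tail is replaced by the CSP-wrapped pyramid
  pooling block with hidden width 512.

The scale follows the "s" compound: width 0.50, depth 0.33, giving backbone
channels 32/64/128/256/512 and C2f depths 1/2/2/1.  The head is decoupled
and anchor-free; box regression uses a discretized distance distribution
with ``reg_max`` bins per side (channels 4*reg_max), classification one
logit per class.  The neck feeds backbone taps straight into nearest-
neighbour up-sampling with no extra convolutions on the up path.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor, no_grad
from .nn.layers import ConvBNSiLU, Conv2d, Module, ModuleList, SGD
from .blocks import C2f, C2fDCN, GAM, SPPF, SPPFCSPC
from . import losses as L

__all__ = [
    "ModelSpec",
    "Detector",
    "RawPrediction",
    "build_model",
    "count_parameters",
    "forward_detect",
    "decode_predictions",
    "train_smoke",
    "VARIANTS",
]

STRIDES = (8, 16, 32)

#: named flag combinations for the eight ablation architectures
VARIANTS = {
    "base": dict(),
    "gam": dict(use_gam=True),
    "dcn": dict(use_dcn=True),
    "sppfcspc": dict(use_sppfcspc=True),
    "gam+dcn": dict(use_gam=True, use_dcn=True),
    "gam+sppfcspc": dict(use_gam=True, use_sppfcspc=True),
    "sppfcspc+dcn": dict(use_sppfcspc=True, use_dcn=True),
    "tea": dict(use_gam=True, use_dcn=True, use_sppfcspc=True),
}


@dataclass
class ModelSpec:
    nc: int = 1
    width_mult: float = 0.50
    depth_mult: float = 0.33
    reg_max: int = 16
    use_dcn: bool = False
    use_gam: bool = False
    use_sppfcspc: bool = False
    gam_reduction: int = 4
    sppfcspc_hidden: int = 512
    # Table-2 training defaults carried as configuration
    img_size: int = 640
    lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    batch_size: int = 4
    epochs: int = 300
    mixup_prob: float = 0.5  # listed in the training recipe; inert here

    def __post_init__(self):
        if self.nc < 1 or self.reg_max < 1:
            raise ValueError("nc and reg_max must be >= 1")
        if self.width_mult <= 0 or self.depth_mult <= 0:
            raise ValueError("multipliers must be positive")

    @classmethod
    def from_variant(cls, name: str, **overrides) -> "ModelSpec":
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; options: {sorted(VARIANTS)}")
        return cls(**{**VARIANTS[name], **overrides})


@dataclass
class RawPrediction:
    """Per-scale head outputs (stride 8/16/32), channels 4*reg_max + nc."""

    maps: list  # three arrays, each (N, 4*reg_max+nc, H, W)
    img_size: tuple  # (H, W) of the network input
    reg_max: int
    nc: int


class DetectHead(Module):
    """Decoupled regression / classification branches at each scale."""

    def __init__(self, nc, reg_max, channels, rng):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(nc, 100))
        self.cv2 = ModuleList(
            _seq(
                ConvBNSiLU(ch, c2, 3, rng=rng),
                ConvBNSiLU(c2, c2, 3, rng=rng),
                Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng),
            )
            for ch in channels
        )
        self.cv3 = ModuleList(
            _seq(
                ConvBNSiLU(ch, c3, 3, rng=rng),
                ConvBNSiLU(c3, c3, 3, rng=rng),
                Conv2d(c3, nc, 1, bias=True, rng=rng),
            )
            for ch in channels
        )

    def forward(self, feats):
        out = []
        for x, reg, cls in zip(feats, self.cv2, self.cv3):
            out.append(nn.concat([reg(x), cls(x)], axis=1))
        return out


class _Sequential(Module):
    def __init__(self, modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


def _seq(*modules):
    return _Sequential(modules)


class Detector(Module):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.width_mult
        # base widths 64..1024 scaled, with the deepest stage capped at 512
        ch = [int(c * w) for c in (64, 128, 256, 512, min(1024, 512 / w))]
        d = [max(1, round(3 * spec.depth_mult)), max(1, round(6 * spec.depth_mult)),
             max(1, round(6 * spec.depth_mult)), max(1, round(3 * spec.depth_mult))]
        c2f_late = C2fDCN if spec.use_dcn else C2f

        self.stem = ConvBNSiLU(3, ch[0], 3, 2, rng=rng)
        self.conv1 = ConvBNSiLU(ch[0], ch[1], 3, 2, rng=rng)
        self.c2f1 = C2f(ch[1], ch[1], d[0], shortcut=True, rng=rng)
        self.conv2 = ConvBNSiLU(ch[1], ch[2], 3, 2, rng=rng)
        self.c2f2 = c2f_late(ch[2], ch[2], d[1], shortcut=True, rng=rng)
        self.conv3 = ConvBNSiLU(ch[2], ch[3], 3, 2, rng=rng)
        self.c2f3 = c2f_late(ch[3], ch[3], d[2], shortcut=True, rng=rng)
        self.conv4 = ConvBNSiLU(ch[3], ch[4], 3, 2, rng=rng)
        self.c2f4 = c2f_late(ch[4], ch[4], d[3], shortcut=True, rng=rng)
        if spec.use_gam:
            self.gam2 = GAM(ch[2], spec.gam_reduction, rng=rng)
            self.gam3 = GAM(ch[3], spec.gam_reduction, rng=rng)
            self.gam4 = GAM(ch[4], spec.gam_reduction, rng=rng)
        if spec.use_sppfcspc:
            self.spp = SPPFCSPC(ch[4], ch[4], c_hidden=spec.sppfcspc_hidden, rng=rng)
        else:
            self.spp = SPPF(ch[4], ch[4], rng=rng)

        # PAN-FPN neck: plain up-sampling, C2f fusion blocks
        self.up_c2f1 = C2f(ch[4] + ch[3], ch[3], d[3], rng=rng)
        self.up_c2f2 = C2f(ch[3] + ch[2], ch[2], d[3], rng=rng)
        self.down_conv1 = ConvBNSiLU(ch[2], ch[2], 3, 2, rng=rng)
        self.down_c2f1 = C2f(ch[2] + ch[3], ch[3], d[3], rng=rng)
        self.down_conv2 = ConvBNSiLU(ch[3], ch[3], 3, 2, rng=rng)
        self.down_c2f2 = C2f(ch[3] + ch[4], ch[4], d[3], rng=rng)

        self.head = DetectHead(spec.nc, spec.reg_max, (ch[2], ch[3], ch[4]), rng)

    # -- inference ------------------------------------------------------------
    def forward(self, x: Tensor):
        h, w = x.shape[2:]
        if h % 32 or w % 32:
            raise ValueError("input spatial size must be a multiple of 32")
        spec = self.spec
        x = self.c2f1(self.conv1(self.stem(x)))
        p3 = self.c2f2(self.conv2(x))
        if spec.use_gam:
            p3 = self.gam2(p3)
        p4 = self.c2f3(self.conv3(p3))
        if spec.use_gam:
            p4 = self.gam3(p4)
        p5 = self.c2f4(self.conv4(p4))
        if spec.use_gam:
            p5 = self.gam4(p5)
        p5 = self.spp(p5)

        n4 = self.up_c2f1(nn.concat([nn.functional.upsample_nearest2x(p5), p4], axis=1))
        n3 = self.up_c2f2(nn.concat([nn.functional.upsample_nearest2x(n4), p3], axis=1))
        n4b = self.down_c2f1(nn.concat([self.down_conv1(n3), n4], axis=1))
        n5b = self.down_c2f2(nn.concat([self.down_conv2(n4b), p5], axis=1))
        return self.head([n3, n4b, n5b])

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        """Single-file checkpoint: JSON architecture header + zlib weights."""
        state = self.state_dict()
        header = {
            "spec": asdict(self.spec),
            "params": {k: list(v.shape) for k, v in state.items()},
        }
        blob = zlib.compress(
            b"".join(np.ascontiguousarray(v, np.float32).tobytes() for v in state.values())
        )
        with open(path, "wb") as fh:
            hdr = json.dumps(header).encode()
            fh.write(len(hdr).to_bytes(8, "little"))
            fh.write(hdr)
            fh.write(blob)

    @classmethod
    def load(cls, path) -> "Detector":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(n).decode())
            raw = zlib.decompress(fh.read())
        spec = ModelSpec(**header["spec"])
        model = cls(spec)
        buf, state = io.BytesIO(raw), {}
        for name, shape in header["params"].items():
            count = int(np.prod(shape)) if shape else 1
            state[name] = np.frombuffer(
                buf.read(4 * count), dtype=np.float32
            ).reshape(shape)
        model.load_state_dict(state)
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> Detector:
    return Detector(spec, seed=seed)


def count_parameters(model: Detector) -> int:
    """Total trainable scalar parameters."""
    return model.num_parameters()


def params_millions(model: Detector) -> float:
    """Parameter total in millions, rounded to one decimal."""
    return round(count_parameters(model) / 1e6, 1)


# -- prediction ---------------------------------------------------------------

def forward_detect(model: Detector, image: np.ndarray) -> RawPrediction:
    """Run inference on a letterboxed HxWx3 image (values 0..255)."""
    h, w = image.shape[:2]
    x = Tensor(image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    model.eval()
    with no_grad():
        maps = model(x)
    return RawPrediction(
        maps=[m.data for m in maps],
        img_size=(h, w),
        reg_max=model.spec.reg_max,
        nc=model.spec.nc,
    )


def _flatten_raw(raw: RawPrediction):
    """Concatenate scales -> (A, 4*reg_max+nc), anchor centers, strides."""
    feats, centers, strides = [], [], []
    for m, s in zip(raw.maps, STRIDES):
        n, c, h, w = m.shape
        feats.append(m[0].reshape(c, h * w).T)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        centers.append(
            np.stack([(xx.ravel() + 0.5) * s, (yy.ravel() + 0.5) * s], axis=1)
        )
        strides.append(np.full(h * w, s, dtype=np.float32))
    return (
        np.concatenate(feats, 0),
        np.concatenate(centers, 0).astype(np.float32),
        np.concatenate(strides, 0),
    )


def decode_distances(reg_logits: np.ndarray, reg_max: int) -> np.ndarray:
    """Expectation of the softmaxed per-side bin distribution (grid units)."""
    r = reg_logits.reshape(-1, 4, reg_max)
    r = r - r.max(axis=-1, keepdims=True)
    e = np.exp(r)
    p = e / e.sum(axis=-1, keepdims=True)
    return p @ np.arange(reg_max, dtype=np.float32)


def decode_predictions(raw: RawPrediction, conf_thresh: float = 0.25,
                       iou_thresh: float = 0.45, letterbox_meta=None):
    """Raw maps -> scored boxes after distribution decoding and NMS.

    Returns a :class:`~teadetect.evalmetrics.DetectionSet` in letterboxed
    pixel coordinates, or in original-image coordinates when
    ``letterbox_meta`` (scale, pad_x, pad_y) is given.
    """
    from .evalmetrics import DetectionSet, nms

    if not (0 < conf_thresh < 1 and 0 < iou_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    feat, centers, strides = _flatten_raw(raw)
    nreg = 4 * raw.reg_max
    dist = decode_distances(feat[:, :nreg], raw.reg_max) * strides[:, None]
    scores_all = 1.0 / (1.0 + np.exp(-feat[:, nreg:]))
    scores = scores_all.max(axis=1)
    keep = scores >= conf_thresh
    boxes = np.stack(
        [
            centers[keep, 0] - dist[keep, 0],
            centers[keep, 1] - dist[keep, 1],
            centers[keep, 0] + dist[keep, 2],
            centers[keep, 1] + dist[keep, 3],
        ],
        axis=1,
    )
    scores = scores[keep]
    idx = nms(boxes, scores, iou_thresh)
    boxes, scores = boxes[idx], scores[idx]
    if letterbox_meta is not None:
        scale, px, py = letterbox_meta
        boxes[:, [0, 2]] = (boxes[:, [0, 2]] - px) / scale
        boxes[:, [1, 3]] = (boxes[:, [1, 3]] - py) / scale
    order = np.argsort(-scores, kind="stable")
    return DetectionSet(boxes=boxes[order], scores=scores[order], image_id="")


# -- smoke training -----------------------------------------------------------

def train_smoke(model: Detector, dataset, steps: int, seed: int = 0,
                img_size: int = 96, batch_size: int = 4, lr: float | None = None):
    """Short seeded SGD run returning the per-step total-loss trace.

    A sanity harness, not a training recipe: scenes are letterboxed to a
    small square input so the numpy backward pass stays desk-scale.
    """
    from .data import letterbox, letterbox_params

    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    spec = model.spec
    opt = SGD(
        model.parameters(),
        lr=spec.lr if lr is None else lr,
        momentum=spec.momentum,
        weight_decay=spec.weight_decay,
    )
    boxed = [letterbox(s, img_size) for s in dataset]
    model.train()
    trace = []
    for _ in range(steps):
        pick = rng.choice(len(boxed), size=min(batch_size, len(boxed)), replace=False)
        batch = [boxed[i] for i in pick]
        x = Tensor(
            np.stack([b.image for b in batch]).astype(np.float32).transpose(0, 3, 1, 2)
            / 255.0
        )
        maps = model(x)
        targets = [b.boxes for b in batch]
        loss, parts = L.detection_loss(maps, targets, reg_max=spec.reg_max,
                                       nc=spec.nc, strides=STRIDES)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace
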