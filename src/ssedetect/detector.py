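"""Rectangle-pattern detector for contact maps.

A small, CPU-trainable object-detection stack in the Mask-RCNN family:

* a feature pyramid with bottom-up stride-2 convolutions and a top-down
  pathway merged through 1x1 lateral connections;
* a region-proposal head emitting objectness and box refinements for 9
  anchors (3 scales x 3 aspect ratios) at every feature-map element,
  with every box capped at 1/4 of the map area;
* ROI-pooled classification / box-refinement / mask heads over the four
  classes {background, HH, EE_PAR, EE_ANTI};
* a weighted multi-task training loss (classification + localisation +
  mask, with the mask term deliberately down-weighted because helix
  pairs trace dashed rather than continuous lines).

Contact maps are symmetric, so the detector consumes the upper triangle
only; detections are reported in upper-triangle coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .types import CONTACT_TYPES, ConfigError, ContactMap, Detection, RectRegion

#: head box-regression targets are divided by these per-coordinate scales
#: so that sub-cell localisation errors still produce useful gradients
_HEAD_DELTA_STD = np.array([0.1, 0.1, 0.2, 0.2])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 16
    batch_size: int = 1
    learning_rate: float = 1e-3
    seed: int = 0
    rois_per_image: int = 48
    anchor_samples: int = 64


@dataclass
class DetectorConfig:
    strides: tuple[int, ...] = (4, 8, 16)
    channels: int = 32
    anchors_per_loc: int = 9
    anchor_scales: tuple[float, ...] = (4.0, 8.0, 16.0)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    roi_size: int = 14
    n_classes: int = 4
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 0.1)  # (cls, box, mask)
    proposal_score_floor: float = 0.5
    proposal_cap: int = 200
    max_region_area_frac: float = 0.25
    head_width: int = 128
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        self.validate()

    def validate(self) -> None:
        w_cls, w_box, w_mask = self.loss_weights
        if not w_mask < min(w_cls, w_box):
            raise ConfigError(
                "mask-loss weight must be smaller than the classification "
                f"and localization weights, got {self.loss_weights}"
            )
        if self.anchors_per_loc != len(self.anchor_scales) * len(self.anchor_ratios):
            raise ConfigError(
                "anchors_per_loc must equal len(anchor_scales) * len(anchor_ratios)"
            )
        for s in self.strides:
            if s < 1 or (s & (s - 1)) != 0:
                raise ConfigError("strides must be powers of two")
        if self.n_classes != 1 + len(CONTACT_TYPES):
            raise ConfigError("n_classes must be 4 (background + 3 contact types)")


@dataclass
class Proposal:
    """A candidate rectangle from the proposal head."""

    region: RectRegion
    objectness: float
    level: int
    box: tuple[float, float, float, float]  # (y0, x0, y1, x1) float, map coords


@dataclass
class HeadPredictions:
    cls_logits: nn.Tensor          # (N, 4)
    box_deltas: nn.Tensor          # (N, 4)
    mask_logits: nn.Tensor | None  # (P, 1, S, S), positives only


@dataclass
class HeadTargets:
    labels: np.ndarray        # (N,) int class indices, 0 = background
    pos_idx: np.ndarray       # (P,) row indices of positives
    box_targets: np.ndarray   # (P, 4) encoded deltas
    mask_targets: np.ndarray  # (P, S, S) binary


@dataclass
class LossTerms:
    total: nn.Tensor
    cls: float
    box: float
    mask: float
    has_positives: bool


# --------------------------------------------------------------------------
# box arithmetic (plain numpy, no gradients)
# --------------------------------------------------------------------------

def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of float boxes (N, 4) x (M, 4), boxes as (y0, x0, y1, x1)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    iy = np.maximum(
        0.0,
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
    )
    ix = np.maximum(
        0.0,
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
    )
    inter = iy * ix
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def encode_boxes(gt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Deltas that map reference boxes onto ground-truth boxes."""
    gy, gx = (gt[:, 0] + gt[:, 2]) / 2, (gt[:, 1] + gt[:, 3]) / 2
    gh, gw = gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]
    ry, rx = (ref[:, 0] + ref[:, 2]) / 2, (ref[:, 1] + ref[:, 3]) / 2
    rh = np.maximum(ref[:, 2] - ref[:, 0], 1e-6)
    rw = np.maximum(ref[:, 3] - ref[:, 1], 1e-6)
    return np.stack(
        [(gy - ry) / rh, (gx - rx) / rw, np.log(gh / rh), np.log(gw / rw)], axis=1
    )


def decode_boxes(ref: np.ndarray, deltas: np.ndarray, L: int) -> np.ndarray:
    """Apply predicted deltas to reference boxes, clipping to the map."""
    ry, rx = (ref[:, 0] + ref[:, 2]) / 2, (ref[:, 1] + ref[:, 3]) / 2
    rh = np.maximum(ref[:, 2] - ref[:, 0], 1e-6)
    rw = np.maximum(ref[:, 3] - ref[:, 1], 1e-6)
    d = np.clip(deltas, -4.0, 4.0)
    cy, cx = ry + d[:, 0] * rh, rx + d[:, 1] * rw
    h, w = rh * np.exp(d[:, 2]), rw * np.exp(d[:, 3])
    boxes = np.stack([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2], axis=1)
    return np.clip(boxes, 0.0, float(L))


def _shrink_to_cap(boxes: np.ndarray, cap_area: float) -> np.ndarray:
    h = boxes[:, 2] - boxes[:, 0]
    w = boxes[:, 3] - boxes[:, 1]
    area = h * w
    f = np.where(area > cap_area, np.sqrt(cap_area / np.maximum(area, 1e-12)), 1.0)
    cy, cx = (boxes[:, 0] + boxes[:, 2]) / 2, (boxes[:, 1] + boxes[:, 3]) / 2
    h, w = h * f, w * f
    return np.stack([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2], axis=1)


def _box_to_region(box: np.ndarray, L: int) -> RectRegion | None:
    i0, j0, i1, j1 = (
        int(round(box[0])), int(round(box[1])), int(round(box[2])), int(round(box[3]))
    )
    i0, j0 = max(i0, 0), max(j0, 0)
    i1, j1 = min(max(i1, i0 + 1), L), min(max(j1, j0 + 1), L)
    if i1 <= i0 or j1 <= j0:
        return None
    return RectRegion(i0, i1, j0, j1)


# --------------------------------------------------------------------------
# anchors
# --------------------------------------------------------------------------

def anchor_shapes(config: DetectorConfig, L: int) -> np.ndarray:
    """(A, 2) anchor heights/widths: scale*sqrt(ratio) x scale/sqrt(ratio),
    shrunk where the area would exceed the 1/4-map cap."""
    cap = config.max_region_area_frac * L * L
    shapes = []
    for scale in config.anchor_scales:
        for ratio in config.anchor_ratios:
            h = scale * math.sqrt(ratio)
            w = scale / math.sqrt(ratio)
            if h * w > cap:
                f = math.sqrt(cap / (h * w))
                h, w = h * f, w * f
            shapes.append((h, w))
    return np.asarray(shapes)


def generate_anchors(config: DetectorConfig, L: int) -> dict[int, np.ndarray]:
    """Anchor boxes per pyramid level.

    Returns, for each stride s, an array of shape (ceil(L/s)**2 * A, 4)
    of (y0, x0, y1, x1) boxes centred at the back-projected map
    coordinate of every feature-map element, clipped to the map bounds.
    Ordering is row-major over locations, anchor index fastest.
    """
    shapes = anchor_shapes(config, L)
    out: dict[int, np.ndarray] = {}
    for s in config.strides:
        n = math.ceil(L / s)
        centers = (np.arange(n) + 0.5) * s
        cy = np.repeat(centers, n * len(shapes))
        cx = np.tile(np.repeat(centers, len(shapes)), n)
        hh = np.tile(shapes[:, 0], n * n)
        ww = np.tile(shapes[:, 1], n * n)
        boxes = np.stack([cy - hh / 2, cx - ww / 2, cy + hh / 2, cx + ww / 2], axis=1)
        out[s] = np.clip(boxes, 0.0, float(L))
    return out


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

def _width_schedule(config: DetectorConfig) -> list[int]:
    n_down = int(round(math.log2(max(config.strides))))
    widths = [8]
    for _ in range(n_down):
        widths.append(min(config.channels, widths[-1] * 2))
    return widths


def init_params(config: DetectorConfig, rng: np.random.Generator) -> dict[str, nn.Tensor]:
    ch = config.channels
    widths = _width_schedule(config)
    p: dict[str, nn.Tensor] = {}
    p["stem_w"] = nn.parameter(rng, (widths[0], 1, 3, 3), 9)
    p["stem_b"] = nn.zeros((widths[0],))
    for k in range(len(widths) - 1):
        p[f"down{k}_w"] = nn.parameter(rng, (widths[k + 1], widths[k], 3, 3), widths[k] * 9)
        p[f"down{k}_b"] = nn.zeros((widths[k + 1],))
    for s in config.strides:
        cin = widths[int(round(math.log2(s)))]
        p[f"lat{s}_w"] = nn.parameter(rng, (ch, cin, 1, 1), cin)
        p[f"lat{s}_b"] = nn.zeros((ch,))
        p[f"smooth{s}_w"] = nn.parameter(rng, (ch, ch, 3, 3), ch * 9)
        p[f"smooth{s}_b"] = nn.zeros((ch,))
    A = config.anchors_per_loc
    p["rpn_w"] = nn.parameter(rng, (ch, ch, 3, 3), ch * 9)
    p["rpn_b"] = nn.zeros((ch,))
    p["rpn_obj_w"] = nn.parameter(rng, (A, ch, 1, 1), ch)
    p["rpn_obj_b"] = nn.zeros((A,))
    p["rpn_box_w"] = nn.parameter(rng, (4 * A, ch, 1, 1), ch)
    p["rpn_box_b"] = nn.zeros((4 * A,))
    # heads operate on the pooled (channels + 1 raw) patch: all channels
    # average-pooled 2x, plus the raw-map channel at full resolution so
    # the box branch can localise pattern ends to sub-cell accuracy
    half = config.roi_size // 2
    fdim = (ch + 1) * half * half + config.roi_size * config.roi_size
    p["fc1_w"] = nn.parameter(rng, (fdim, config.head_width), fdim)
    p["fc1_b"] = nn.zeros((config.head_width,))
    p["cls_w"] = nn.parameter(rng, (config.head_width, config.n_classes), config.head_width)
    p["cls_b"] = nn.zeros((config.n_classes,))
    p["box_w"] = nn.parameter(rng, (config.head_width, 4), config.head_width)
    p["box_b"] = nn.zeros((4,))
    p["mask1_w"] = nn.parameter(rng, (16, ch + 1, 3, 3), (ch + 1) * 9)
    p["mask1_b"] = nn.zeros((16,))
    p["mask2_w"] = nn.parameter(rng, (1, 16, 1, 1), 16)
    p["mask2_b"] = nn.zeros((1,))
    return p


@dataclass
class DetectorModel:
    """Architecture config plus trained parameters."""

    config: DetectorConfig
    params: dict[str, nn.Tensor]
    version: str = "ssedetect-detector-1"
    history: list[dict] = field(default_factory=list)

    def save(self, path: str) -> None:
        meta = json.dumps(
            {"config": asdict(self.config), "version": self.version,
             "history": self.history}
        )
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {
                k: nn.Tensor(data[k]) for k in data.files if k != "__meta__"
            }
        cfg = meta["config"]
        config = DetectorConfig(
            strides=tuple(cfg["strides"]),
            channels=cfg["channels"],
            anchors_per_loc=cfg["anchors_per_loc"],
            anchor_scales=tuple(cfg["anchor_scales"]),
            anchor_ratios=tuple(cfg["anchor_ratios"]),
            roi_size=cfg["roi_size"],
            n_classes=cfg["n_classes"],
            loss_weights=tuple(cfg["loss_weights"]),
            proposal_score_floor=cfg["proposal_score_floor"],
            proposal_cap=cfg["proposal_cap"],
            max_region_area_frac=cfg["max_region_area_frac"],
            head_width=cfg.get("head_width", 128),
            train=TrainConfig(**cfg["train"]),
        )
        return cls(config=config, params=params, version=meta["version"],
                   history=meta.get("history", []))


def untrained_model(config: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    config = config or DetectorConfig()
    return DetectorModel(config=config, params=init_params(config, np.random.default_rng(seed)))


# --------------------------------------------------------------------------
# forward passes
# --------------------------------------------------------------------------

def _prepare_input(cmap: ContactMap | np.ndarray, config: DetectorConfig) -> tuple[np.ndarray, int]:
    """Upper-triangle-masked map, zero-padded to a multiple of the max stride."""
    P = cmap.P if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    L = P.shape[0]
    smax = max(config.strides)
    if L < smax:
        raise ConfigError(f"map size {L} smaller than the maximum stride {smax}")
    upper = np.triu(P, k=1)
    Lp = math.ceil(L / smax) * smax
    if Lp != L:
        padded = np.zeros((Lp, Lp))
        padded[:L, :L] = upper
        upper = padded
    return upper, L


def _forward_pyramid(
    params: dict[str, nn.Tensor], x: np.ndarray, config: DetectorConfig
) -> tuple[dict[int, nn.Tensor], nn.Tensor]:
    """Bottom-up + top-down feature pyramid; returns per-stride features
    and the raw input tensor (used as a stride-1 lateral for pooling)."""
    raw = nn.Tensor(x[None])
    h = nn.relu(nn.conv2d(raw, params["stem_w"], params["stem_b"], stride=1, pad=1))
    bottom_up: dict[int, nn.Tensor] = {1: h}
    stride = 1
    n_down = int(round(math.log2(max(config.strides))))
    cur = h
    for k in range(n_down):
        cur = nn.relu(nn.conv2d(cur, params[f"down{k}_w"], params[f"down{k}_b"],
                                stride=2, pad=1))
        stride *= 2
        bottom_up[stride] = cur

    pyramid: dict[int, nn.Tensor] = {}
    prev: nn.Tensor | None = None
    prev_stride = 0
    for s in sorted(config.strides, reverse=True):
        lat = nn.conv2d(bottom_up[s], params[f"lat{s}_w"], params[f"lat{s}_b"])
        if prev is not None:
            up = prev
            f = prev_stride // s
            while f > 1:
                up = nn.upsample2x(up)
                f //= 2
            lat = lat + up
        merged = nn.conv2d(lat, params[f"smooth{s}_w"], params[f"smooth{s}_b"], pad=1)
        pyramid[s] = merged
        prev, prev_stride = merged, s
    return pyramid, raw


def build_feature_pyramid(
    cmap: ContactMap | np.ndarray, model: DetectorModel
) -> dict[int, np.ndarray]:
    """Multi-scale features for a contact map: one (channels, L/s, L/s)
    array per stride s (map zero-padded to a multiple of the largest
    stride first)."""
    x, _ = _prepare_input(cmap, model.config)
    pyramid, _ = _forward_pyramid(model.params, x, model.config)
    return {s: t.data for s, t in pyramid.items()}


def _rpn_forward(
    params: dict[str, nn.Tensor],
    pyramid: dict[int, nn.Tensor],
    config: DetectorConfig,
) -> tuple[nn.Tensor, nn.Tensor, list[int]]:
    """Flattened objectness logits (N,), box deltas (N, 4) and the level
    stride of each row, ordered to match :func:`generate_anchors`."""
    A = config.anchors_per_loc
    objs, boxes, levels = [], [], []
    for s in sorted(config.strides):
        h = nn.relu(nn.conv2d(pyramid[s], params["rpn_w"], params["rpn_b"], pad=1))
        o = nn.conv2d(h, params["rpn_obj_w"], params["rpn_obj_b"])
        b = nn.conv2d(h, params["rpn_box_w"], params["rpn_box_b"])
        H, W = o.shape[1], o.shape[2]
        objs.append(nn.reshape(nn.transpose(o, (1, 2, 0)), (H * W * A,)))
        boxes.append(
            nn.reshape(
                nn.transpose(nn.reshape(b, (A, 4, H, W)), (2, 3, 0, 1)),
                (H * W * A, 4),
            )
        )
        levels.extend([s] * (H * W * A))
    return nn.concat(objs), nn.concat(boxes), levels


#: pooled windows are expanded by this fraction per side so the heads
#: can see past a proposal's edge (where the evidence for the true box
#: boundary often lies)
_POOL_MARGIN = 0.25


def expand_boxes(boxes: np.ndarray, margin: float = _POOL_MARGIN) -> np.ndarray:
    h = boxes[:, 2] - boxes[:, 0]
    w = boxes[:, 3] - boxes[:, 1]
    return boxes + np.stack([-margin * h, -margin * w, margin * h, margin * w], axis=1)


def _pool_rois(
    params: dict[str, nn.Tensor],
    pyramid: dict[int, nn.Tensor],
    raw: nn.Tensor,
    boxes: np.ndarray,
    config: DetectorConfig,
) -> nn.Tensor:
    """ROI-align features from the finest level plus a raw-map channel.

    Pooling covers the box plus a context margin; box deltas stay
    relative to the unexpanded box."""
    s = min(config.strides)
    exp = expand_boxes(boxes)
    feat_pool = nn.roi_align(pyramid[s], exp / s, config.roi_size)
    raw_pool = nn.roi_align(raw, exp, config.roi_size)
    return nn.concat([feat_pool, raw_pool], axis=1)


def _heads_forward(
    params: dict[str, nn.Tensor],
    pooled: nn.Tensor,
    config: DetectorConfig,
    mask_rows: np.ndarray | None = None,
) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor | None]:
    """Classification logits, box deltas and (optionally) mask logits."""
    r = pooled.shape[0]
    ch = pooled.shape[1]
    s = config.roi_size
    half = s // 2
    # 2x2 average pooling before the dense layers keeps them small ...
    x = nn.reshape(pooled, (r, ch, half, 2, half, 2))
    x = nn.transpose(x, (0, 1, 2, 4, 3, 5))
    x = nn.reshape(x, (r * ch * half * half, 4))
    ones = nn.Tensor(np.full((4, 1), 0.25))
    x = nn.linear(x, ones, nn.Tensor(np.zeros(1)))
    x = nn.reshape(x, (r, ch * half * half))
    # ... while the raw-map channel also enters at full resolution, so
    # localisation is not limited by the coarse pooled grid
    raw_full = nn.transpose(pooled, (1, 0, 2, 3))
    raw_full = nn.gather_rows(raw_full, np.array([ch - 1]))
    raw_full = nn.reshape(nn.transpose(raw_full, (1, 0, 2, 3)), (r, s * s))
    x = nn.concat([x, raw_full], axis=1)
    h = nn.relu(nn.linear(x, params["fc1_w"], params["fc1_b"]))
    cls_logits = nn.linear(h, params["cls_w"], params["cls_b"])
    box_deltas = nn.linear(h, params["box_w"], params["box_b"])

    mask_logits = None
    if mask_rows is not None and len(mask_rows):
        sel = nn.gather_rows(pooled, mask_rows)
        per_roi = []
        for k in range(len(mask_rows)):
            patch = nn.reshape(
                nn.gather_rows(sel, np.array([k])),
                (ch, config.roi_size, config.roi_size),
            )
            m = nn.relu(nn.conv2d(patch, params["mask1_w"], params["mask1_b"], pad=1))
            m = nn.conv2d(m, params["mask2_w"], params["mask2_b"])
            per_roi.append(nn.reshape(m, (1, 1, config.roi_size, config.roi_size)))
        mask_logits = nn.concat(per_roi, axis=0)
    return cls_logits, box_deltas, mask_logits


# --------------------------------------------------------------------------
# proposals and inference
# --------------------------------------------------------------------------

def _cap_region(region: RectRegion, cap_area: float) -> RectRegion:
    i0, i1, j0, j1 = region.as_tuple()
    while (i1 - i0) * (j1 - j0) > cap_area:
        if i1 - i0 >= j1 - j0 and i1 - i0 > 1:
            i1 -= 1
        elif j1 - j0 > 1:
            j1 -= 1
        else:
            break
    return RectRegion(i0, i1, j0, j1)


def _decode_proposals(
    obj_logits: np.ndarray,
    deltas: np.ndarray,
    levels: list[int],
    anchors: np.ndarray,
    config: DetectorConfig,
    L: int,
) -> list[Proposal]:
    scores = nn.sigmoid(obj_logits)
    boxes = decode_boxes(anchors, deltas, L)
    keep = np.flatnonzero(scores >= config.proposal_score_floor)
    keep = keep[np.argsort(-scores[keep], kind="stable")][: config.proposal_cap]
    cap_area = config.max_region_area_frac * L * L
    boxes = _shrink_to_cap(boxes[keep], cap_area)
    out: list[Proposal] = []
    for row, box in zip(keep, boxes):
        region = _box_to_region(box, L)
        if region is None:
            continue
        region = _cap_region(region, cap_area)
        out.append(
            Proposal(
                region=region,
                objectness=float(scores[row]),
                level=levels[row],
                box=tuple(box),
            )
        )
    return out


def _level_anchors(config: DetectorConfig, Lp: int, L: int) -> tuple[np.ndarray, list[int]]:
    """Anchors over the padded grid, clipped to the unpadded map bounds."""
    per_level = generate_anchors(config, Lp)
    anchors, levels = [], []
    for s in sorted(config.strides):
        a = np.clip(per_level[s], 0.0, float(L))
        anchors.append(a)
        levels.extend([s] * len(a))
    return np.concatenate(anchors, axis=0), levels


def propose_regions(
    features: dict[int, np.ndarray | nn.Tensor], model: DetectorModel
) -> list[Proposal]:
    """Run the proposal head over a feature pyramid.

    The map size is recovered from the finest feature level, so
    proposals are clipped to the padded map bounds.
    """
    config = model.config
    pyramid = {
        s: (f if isinstance(f, nn.Tensor) else nn.Tensor(f))
        for s, f in features.items()
    }
    smin = min(config.strides)
    Lp = pyramid[smin].shape[1] * smin
    obj_t, box_t, levels = _rpn_forward(model.params, pyramid, config)
    anchors, levels = _level_anchors(config, Lp, Lp)
    return _decode_proposals(obj_t.data, box_t.data, levels, anchors, config, Lp)


def roi_align(
    feature_map: np.ndarray | nn.Tensor,
    region: RectRegion | np.ndarray,
    roi_size: int,
) -> np.ndarray:
    """Pool a rectangle from a feature map by bilinear sampling.

    ``feature_map`` may be (C, H, W) or a bare (H, W) plane; the region
    is either a :class:`RectRegion` or a float box (y0, x0, y1, x1) in
    the feature map's coordinate frame.  No coordinate quantisation is
    performed; out-of-bounds samples clamp to the border.
    """
    x = feature_map.data if isinstance(feature_map, nn.Tensor) else np.asarray(feature_map, float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if isinstance(region, RectRegion):
        box = np.array([[region.i0, region.j0, region.i1, region.j1]], dtype=float)
    else:
        box = np.atleast_2d(np.asarray(region, dtype=float))
    pooled = nn.roi_align(nn.Tensor(x), box, roi_size).data[0]
    return pooled[0] if squeeze else pooled


def classify_and_refine(
    pooled: np.ndarray | nn.Tensor,
    model: DetectorModel,
    proposal_boxes: np.ndarray | None = None,
    L: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Head pass over pooled ROI patches.

    Returns (class probabilities (R, 4), refined boxes or None, mask
    logits (R, S, S)).  Refined boxes are decoded from the predicted
    deltas relative to ``proposal_boxes``; with zero deltas the refined
    box equals the proposal.
    """
    config = model.config
    t = pooled if isinstance(pooled, nn.Tensor) else nn.Tensor(np.asarray(pooled, float))
    if len(t.shape) == 3:
        t = nn.reshape(t, (1,) + t.shape)
    r = t.shape[0]
    cls_logits, box_deltas, mask_logits = _heads_forward(
        model.params, t, config, mask_rows=np.arange(r)
    )
    probs = nn.softmax(cls_logits.data)
    refined = None
    if proposal_boxes is not None:
        classes = np.argmax(probs[:, 1:], axis=1) + 1
        deltas = _select_class_deltas(box_deltas.data, classes)
        refined = decode_boxes(
            np.atleast_2d(np.asarray(proposal_boxes, float)),
            deltas * _HEAD_DELTA_STD,
            L if L is not None else 10 ** 9,
        )
    return probs, refined, mask_logits.data[:, 0]


def _select_class_deltas(box_deltas: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Pick each row's deltas for its predicted class; tolerate a
    class-agnostic (N, 4) head."""
    if box_deltas.shape[1] == 4:
        return box_deltas
    n = len(box_deltas)
    return box_deltas.reshape(n, -1, 4)[np.arange(n), classes]


def _mask_for_region(logits: np.ndarray, frame: np.ndarray, region: RectRegion) -> np.ndarray:
    """Sample per-cell mask probabilities for a region from head logits
    predicted over the (expanded) pooled frame."""
    S = logits.shape[0]
    fy0, fx0, fy1, fx1 = frame
    ys = (np.arange(region.i0, region.i1) + 0.5 - fy0) / max(fy1 - fy0, 1e-6) * S
    xs = (np.arange(region.j0, region.j1) + 0.5 - fx0) / max(fx1 - fx0, 1e-6) * S
    yi = np.clip(np.floor(ys).astype(int), 0, S - 1)
    xi = np.clip(np.floor(xs).astype(int), 0, S - 1)
    return (nn.sigmoid(logits[yi][:, xi]) > 0.5).astype(np.uint8)


def _fold_upper(region: RectRegion) -> RectRegion:
    return region.transpose() if region.i0 > region.j0 else region


def _frame_candidates(
    model: DetectorModel,
    x: np.ndarray,
    L: int,
    refine_stages: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run proposals + iterative head refinement on one prepared frame.

    Returns the refined float boxes (N, 4) and class probabilities
    (N, n_classes)."""
    config = model.config
    Lp = x.shape[0]
    pyramid, raw = _forward_pyramid(model.params, x, config)
    obj_t, box_t, _ = _rpn_forward(model.params, pyramid, config)
    anchors, levels = _level_anchors(config, Lp, L)
    proposals = _decode_proposals(obj_t.data, box_t.data, levels, anchors, config, L)
    boxes = np.array([p.box for p in proposals]).reshape(-1, 4)
    probs = np.zeros((0, config.n_classes))
    for _ in range(max(refine_stages, 1)):
        if not len(boxes):
            break
        pooled = _pool_rois(model.params, pyramid, raw, boxes, config)
        cls_logits, box_deltas, _ = _heads_forward(model.params, pooled, config)
        probs = nn.softmax(cls_logits.data)
        stage_cls = np.argmax(probs[:, 1:], axis=1) + 1
        deltas = _select_class_deltas(box_deltas.data, stage_cls)
        boxes = decode_boxes(boxes, deltas * _HEAD_DELTA_STD, L)
        ok = (boxes[:, 2] - boxes[:, 0] >= 0.5) & (boxes[:, 3] - boxes[:, 1] >= 0.5)
        boxes, probs = boxes[ok], probs[ok]
    return boxes, probs


def _compute_masks(
    model: DetectorModel,
    x: np.ndarray,
    detections: list[Detection],
) -> None:
    """Predict contacting-cell masks in place for final detections."""
    if not detections:
        return
    config = model.config
    pyramid, raw = _forward_pyramid(model.params, x, config)
    boxes = np.array(
        [[d.region.i0, d.region.j0, d.region.i1, d.region.j1] for d in detections],
        dtype=float,
    )
    pooled = _pool_rois(model.params, pyramid, raw, boxes, config)
    _, _, mask_logits = _heads_forward(
        model.params, pooled, config, mask_rows=np.arange(len(detections))
    )
    frames = expand_boxes(boxes)
    for k, det in enumerate(detections):
        det.mask = _mask_for_region(mask_logits.data[k, 0], frames[k], det.region)


def detect(
    cmap: ContactMap | np.ndarray,
    model: DetectorModel,
    compute_masks: bool = True,
    refine_stages: int = 4,
    vote_iou: float = 0.7,
    symmetrize: bool = True,
) -> list[Detection]:
    """Full inference: pyramid -> proposals -> heads -> candidate detections.

    The box head is applied ``refine_stages`` times, each stage
    re-pooling at the previous stage's refined box.  With
    ``symmetrize`` the whole pass is repeated on the map's
    anti-diagonal reflection — which maps every contact class onto
    itself — and the reflected candidates are mapped back, so any
    directional localisation bias of the heads cancels.  Candidates of
    the same class agreeing at IoU >= ``vote_iou`` then vote
    (score-weighted mean) on the final rectangle.

    Returns pre-selection candidates: every surviving proposal, typed
    by its dominant non-background class and scored by that class's
    probability.  Regions are folded into the upper triangle; identical
    (region, type) duplicates keep the higher score.  Deterministic.
    """
    config = model.config
    P = cmap.P if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    x, L = _prepare_input(P, config)
    boxes, probs = _frame_candidates(model, x, L, refine_stages)
    if symmetrize:
        xr, _ = _prepare_input(P[::-1, ::-1].T, config)
        boxes_r, probs_r = _frame_candidates(model, xr, L, refine_stages)
        if len(boxes_r):
            boxes_r = float(L) - boxes_r[:, ::-1]
            boxes = np.concatenate([boxes, boxes_r], axis=0)
            probs = np.concatenate([probs, probs_r], axis=0)
    if not len(boxes):
        return []

    cap_area = config.max_region_area_frac * L * L
    classes = np.argmax(probs[:, 1:], axis=1) + 1
    cls_scores = probs[np.arange(len(probs)), classes]

    # box voting: each candidate's rectangle is replaced by the
    # score-weighted mean of all same-class candidates that agree with
    # it; independent localisation noise cancels
    agree = box_iou(boxes, boxes) >= vote_iou
    voted = boxes.copy()
    for k in range(len(boxes)):
        mates = np.flatnonzero(agree[k] & (classes == classes[k]))
        w = cls_scores[mates]
        if w.sum() > 0:
            voted[k] = (boxes[mates] * w[:, None]).sum(axis=0) / w.sum()

    best: dict[tuple, Detection] = {}
    for k in range(len(voted)):
        cls = int(classes[k])
        score = float(probs[k, cls])
        region = _box_to_region(voted[k], L)
        if region is None:
            continue
        region = _fold_upper(_cap_region(region, cap_area))
        det = Detection(region=region, type=CONTACT_TYPES[cls - 1], score=score,
                        id=getattr(cmap, "id", ""))
        key = (region.as_tuple(), det.type)
        if key not in best or det.score > best[key].score:
            best[key] = det
    out = sorted(best.values(), key=lambda d: -d.score)
    if compute_masks:
        _compute_masks(model, x, out)
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def multitask_loss(
    predictions: HeadPredictions,
    truth: HeadTargets,
    loss_weights: tuple[float, float, float],
) -> LossTerms:
    """Weighted sum of classification, localisation and mask losses.

    total = w_cls * L_cls + w_box * L_box + w_mask * L_mask, where
    L_cls is mean cross-entropy over all assigned proposals, L_box is
    smooth-L1 over positives, and L_mask is mean per-cell binary
    cross-entropy over positives.  With no positives the box and mask
    terms are zero and ``has_positives`` is False.
    """
    w_cls, w_box, w_mask = loss_weights
    cls_l = nn.softmax_cross_entropy(predictions.cls_logits, truth.labels)
    total = nn.scale(cls_l, w_cls)
    box_v = 0.0
    mask_v = 0.0
    has_pos = len(truth.pos_idx) > 0
    if has_pos:
        n, width = predictions.box_deltas.shape
        if width == 4:
            box_pred = nn.gather_rows(predictions.box_deltas, truth.pos_idx)
        else:
            # per-class regression: take each positive's own class slice
            flat = nn.reshape(predictions.box_deltas, (n * (width // 4), 4))
            idx = truth.pos_idx * (width // 4) + truth.labels[truth.pos_idx]
            box_pred = nn.gather_rows(flat, idx)
        box_l = nn.smooth_l1(box_pred, truth.box_targets)
        total = total + nn.scale(box_l, w_box)
        box_v = box_l.item()
        if predictions.mask_logits is not None:
            mask_l = nn.bce_with_logits(
                predictions.mask_logits, truth.mask_targets[:, None]
            )
            total = total + nn.scale(mask_l, w_mask)
            mask_v = mask_l.item()
    return LossTerms(total=total, cls=cls_l.item(), box=box_v, mask=mask_v,
                     has_positives=has_pos)


def _cells_matrix(truth, L: int) -> np.ndarray:
    M = np.zeros((L, L), dtype=bool)
    for contact in truth:
        for (i, j) in contact.cells:
            M[i, j] = True
    return M


def _mask_target(cells: np.ndarray, box: np.ndarray, S: int) -> np.ndarray:
    L = cells.shape[0]
    y = box[0] + (np.arange(S) + 0.5) * (box[2] - box[0]) / S
    x = box[1] + (np.arange(S) + 0.5) * (box[3] - box[1]) / S
    yi = np.clip(np.floor(y).astype(int), 0, L - 1)
    xi = np.clip(np.floor(x).astype(int), 0, L - 1)
    return cells[yi][:, xi].astype(float)


def _train_step(
    params: dict[str, nn.Tensor],
    config: DetectorConfig,
    sample,
    rng: np.random.Generator,
    anchor_cache: dict[int, tuple[np.ndarray, list[int]]],
    class_boost: dict[str, int] | None = None,
) -> dict[str, float]:
    x, L = _prepare_input(sample.map, config)
    Lp = x.shape[0]
    truth = sample.truth
    pyramid, raw = _forward_pyramid(params, x, config)
    obj_t, box_t, _ = _rpn_forward(params, pyramid, config)
    if Lp not in anchor_cache:
        anchor_cache[Lp] = _level_anchors(config, Lp, L)
    anchors, _levels = anchor_cache[Lp]

    gt_boxes = np.array(
        [[c.region.i0, c.region.j0, c.region.i1, c.region.j1] for c in truth],
        dtype=float,
    )
    gt_labels = np.array([1 + CONTACT_TYPES.index(c.type) for c in truth])
    cells = _cells_matrix(truth, Lp)

    # --- proposal-head (objectness + anchor refinement) loss
    iou_a = box_iou(anchors, gt_boxes)
    max_iou = iou_a.max(axis=1)
    arg = iou_a.argmax(axis=1)
    labels = np.full(len(anchors), -1, dtype=int)
    labels[max_iou >= 0.5] = 1
    labels[max_iou < 0.3] = 0
    best = iou_a.argmax(axis=0)
    labels[best] = 1
    arg[best] = np.arange(len(truth))

    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    half = config.train.anchor_samples // 2
    if len(pos) > half:
        pos = rng.choice(pos, half, replace=False)
    n_neg = min(len(neg), config.train.anchor_samples - len(pos))
    neg = rng.choice(neg, n_neg, replace=False)
    sampled = np.concatenate([pos, neg])
    rpn_cls = nn.bce_with_logits(
        nn.gather_rows(obj_t, sampled), (labels[sampled] == 1).astype(float)
    )
    total = rpn_cls
    rpn_box_v = 0.0
    if len(pos):
        rpn_box = nn.smooth_l1(
            nn.gather_rows(box_t, pos),
            encode_boxes(gt_boxes[arg[pos]], anchors[pos]),
        )
        total = total + rpn_box
        rpn_box_v = rpn_box.item()

    # --- head ROIs: current proposals + ground truth + jitter + randoms
    scores = nn.sigmoid(obj_t.data)
    top = np.argsort(-scores, kind="stable")[:30]
    decoded = decode_boxes(anchors[top], box_t.data[top], L)
    jitter = []
    schedule = ((1.5, 0.15), (1.5, 0.15), (1.0, 0.1),
                (0.5, 0.05), (0.5, 0.05), (0.3, 0.03))
    for g, contact in zip(gt_boxes, truth):
        # coarse jitters mimic first-stage boxes, fine jitters the
        # refinement stages' input distribution; rare classes get extra
        # repeats so box regression sees a balanced class diet
        repeats = 1 if class_boost is None else class_boost.get(contact.type, 1)
        for rep in range(repeats):
            for sigma, ssigma in schedule:
                dy, dx = rng.normal(0.0, sigma, size=2)
                sy, sx = np.exp(rng.normal(0.0, ssigma, size=2))
                cy, cx = (g[0] + g[2]) / 2 + dy, (g[1] + g[3]) / 2 + dx
                h, w = (g[2] - g[0]) * sy, (g[3] - g[1]) * sx
                jitter.append([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2])
    randoms = []
    for _ in range(4):
        h, w = rng.uniform(4, 16, size=2)
        cy, cx = rng.uniform(0, L, size=2)
        randoms.append([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2])
    rois = np.clip(
        np.vstack([decoded, gt_boxes, np.array(jitter), np.array(randoms)]), 0.0, float(L)
    )
    ok = (rois[:, 2] - rois[:, 0] >= 1.0) & (rois[:, 3] - rois[:, 1] >= 1.0)
    rois = rois[ok]

    iou_r = box_iou(rois, gt_boxes)
    m = iou_r.max(axis=1)
    a = iou_r.argmax(axis=1)
    lab = np.where(m >= 0.5, gt_labels[a], np.where(m < 0.3, 0, -1))
    keep = np.flatnonzero(lab >= 0)
    rois, lab, a = rois[keep], lab[keep], a[keep]

    pos_r = np.flatnonzero(lab > 0)
    neg_r = np.flatnonzero(lab == 0)
    if len(pos_r) > 24:
        pos_r = rng.choice(pos_r, 24, replace=False)
    n_neg = min(len(neg_r), max(config.train.rois_per_image - len(pos_r), 8))
    if len(neg_r) > n_neg:
        neg_r = rng.choice(neg_r, n_neg, replace=False)
    sel = np.concatenate([pos_r, neg_r])
    rois, lab, a = rois[sel], lab[sel], a[sel]
    pos_idx = np.flatnonzero(lab > 0)

    pooled = _pool_rois(params, pyramid, raw, rois, config)
    cls_logits, box_deltas, mask_logits = _heads_forward(
        params, pooled, config, mask_rows=pos_idx
    )
    box_targets = (
        encode_boxes(gt_boxes[a[pos_idx]], rois[pos_idx]) / _HEAD_DELTA_STD
        if len(pos_idx)
        else np.zeros((0, 4))
    )
    mask_targets = (
        np.stack([_mask_target(cells, expand_boxes(rois[k][None])[0],
                               config.roi_size) for k in pos_idx])
        if len(pos_idx)
        else np.zeros((0, config.roi_size, config.roi_size))
    )
    head = multitask_loss(
        HeadPredictions(cls_logits, box_deltas, mask_logits),
        HeadTargets(lab, pos_idx, box_targets, mask_targets),
        config.loss_weights,
    )
    total = total + head.total
    total.backward()
    return {
        "total": total.item(),
        "rpn_cls": rpn_cls.item(),
        "rpn_box": rpn_box_v,
        "cls": head.cls,
        "box": head.box,
        "mask": head.mask,
    }


def _clip_gradients(params: dict[str, nn.Tensor], max_norm: float = 10.0) -> None:
    sq = sum(
        float(np.sum(p.grad * p.grad)) for p in params.values() if p.grad is not None
    )
    norm = math.sqrt(sq)
    if norm > max_norm:
        f = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= f


def train(dataset, config: DetectorConfig | None = None) -> DetectorModel:
    """Train the detector on (map, truth) samples.

    ``dataset`` is a sequence of objects with ``.map`` (ContactMap) and
    ``.truth`` (list of SSEContact) attributes, e.g. synthetic samples.
    Training is deterministic given ``config.train.seed``.
    """
    config = config or DetectorConfig()
    config.validate()
    if not len(dataset):
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.train.seed)
    params = init_params(config, rng)
    opt = nn.Adam(list(params.values()), lr=config.train.learning_rate)
    anchor_cache: dict[int, tuple[np.ndarray, list[int]]] = {}
    # balance localisation training across contact types: rarer types
    # get proportionally more jittered ROI repeats
    counts = {t: 0 for t in CONTACT_TYPES}
    for sample in dataset:
        for c in sample.truth:
            counts[c.type] += 1
    top_count = max(max(counts.values()), 1)
    class_boost = {
        t: int(np.clip(round(top_count / n), 1, 4)) if n else 1
        for t, n in counts.items()
    }
    history: list[dict] = []
    for epoch in range(config.train.epochs):
        # geometric learning-rate decay down to 10% over the run: late
        # epochs polish box localisation below the Adam noise floor
        opt.lr = config.train.learning_rate * (
            0.1 ** (epoch / max(config.train.epochs - 1, 1))
        )
        order = rng.permutation(len(dataset))
        stats: dict[str, float] = {}
        for idx in order:
            opt.zero_grad()
            terms = _train_step(params, config, dataset[int(idx)], rng,
                                anchor_cache, class_boost)
            _clip_gradients(params)
            opt.step()
            for k, v in terms.items():
                stats[k] = stats.get(k, 0.0) + v
        history.append(
            {"epoch": epoch, **{k: v / len(dataset) for k, v in stats.items()}}
        )
    return DetectorModel(config=config, params=params, history=history)
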