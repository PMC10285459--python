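"""The two-stage rotated detector.

Architecture: a convolutional backbone (ResNet-50 layout, or a reduced
"tiny" CNN for CPU-scale experiments) feeds a feature pyramid (P2-P6,
strides 4-64, shared channel width). The first stage regresses *rotated*
proposals directly from three horizontal anchors per pyramid cell
(horizontal-to-rotated proposal head): per level the classification branch
emits W*H*3 objectness scores and the regression branch W*H*15 values —
five offsets (x, y, w, h, theta) per anchor. The second stage pools each
rotated proposal into a k x k grid with rotated RoI alignment, runs two
cascaded fully-connected layers, and emits a 2-way class probability and a
5-delta refinement per proposal (rotated-to-rotated head).

Training follows the combined loss: cross-entropy over the N sampled
anchors plus smooth-L1 over the Np positives, both normalized by the
shared 1/N factor; positives are picked by the adaptive mean+std skew-IoU
rule. The bundled demo trainer runs the reduced configuration on synthetic
scenes with SGD (momentum 0.9, step decay at 2/3 and 11/12 of the run,
mirroring a 36-epoch schedule with drops at epochs 24 and 33).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .anchors import (
    AnchorPyramid,
    adaptive_assign,
    build_anchor_pyramid,
    sample_training_batch,
)
from .annotations import load_dataset
from .coding import decode_batch, encode_batch
from .geometry import (
    RotatedBox,
    boxes_to_array,
    canonicalize,
    rotated_nms,
    skew_iou_one_to_many,
)
from .rroi import FeatureMap, project_proposal, rroi_align, sampling_points

__all__ = [
    "ModelConfig",
    "Detection",
    "ProposalSet",
    "Detector",
    "build_model",
    "count_parameters",
    "tiny_config",
    "resnet50_config",
    "train_demo",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONE_DEFAULTS = {
    # backbone: (fpn channels, rcnn hidden width, input size)
    "resnet50": (256, 1024, (1024, 1024)),
    "tiny": (32, 128, (192, 192)),
}


@dataclass(frozen=True)
class ModelConfig:
    """All architecture and pipeline knobs in one place."""

    backbone: str = "tiny"
    strides: tuple[int, ...] = (4, 8, 16, 32, 64)
    anchor_areas: tuple[float, ...] = (32.0**2, 64.0**2, 128.0**2, 256.0**2, 512.0**2)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    fpn_channels: int = 256
    rcnn_hidden: int = 1024
    k: int = 7
    l: int = 4
    image_size: tuple[int, int] = (1024, 1024)
    # proposal pipeline
    rpn_pre_nms: int = 2000
    rpn_nms_thr: float = 0.8
    rpn_post_nms_per_level: int = 1000
    proposal_cap_train: int = 2000
    proposal_cap_infer: int = 1000
    # final detections
    score_threshold: float = 0.05
    final_nms_thr: float = 0.1
    # training-time sampling
    n_per_level: int = 9
    rpn_batch: int = 256
    rcnn_pos_iou: float = 0.5
    rcnn_batch: int = 512
    rcnn_pos_fraction: float = 0.25
    seed: int = 0


def resnet50_config(**overrides) -> ModelConfig:
    fpn, hidden, size = _BACKBONE_DEFAULTS["resnet50"]
    return replace(
        ModelConfig(backbone="resnet50", fpn_channels=fpn, rcnn_hidden=hidden,
                    image_size=size),
        **overrides,
    )


def tiny_config(**overrides) -> ModelConfig:
    """Reduced configuration: same interface and pipeline, far fewer
    weights; sized so end-to-end CPU training is practical."""
    fpn, hidden, size = _BACKBONE_DEFAULTS["tiny"]
    return replace(
        ModelConfig(
            backbone="tiny", fpn_channels=fpn, rcnn_hidden=hidden, image_size=size,
            rpn_pre_nms=600, rpn_post_nms_per_level=150,
            proposal_cap_train=300, proposal_cap_infer=200, rcnn_batch=64,
        ),
        **overrides,
    )


@dataclass(frozen=True)
class Detection:
    box: RotatedBox
    score: float
    class_id: int = 0


@dataclass
class ProposalSet:
    boxes: np.ndarray  # (N, 5)
    scores: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class _Bottleneck(nn.Module):
    def __init__(self, c_in: int, mid: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = nn.Conv2d(c_in, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=stride, pad=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, c_out, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        if c_in != c_out or stride != 1:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None
            self.down_bn = None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(nn.add(out, identity))


class ResNet50Backbone(nn.Module):
    """Standard ResNet-50 trunk emitting C2-C5 (256/512/1024/2048 ch)."""

    out_channels = (256, 512, 1024, 2048)

    def __init__(self, rng: np.random.Generator) -> None:
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        spec = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
        self.stages = []
        c_in = 64
        for mid, c_out, blocks, stride in spec:
            stage = []
            for b in range(blocks):
                stage.append(_Bottleneck(c_in, mid, c_out, stride if b == 0 else 1, rng))
                c_in = c_out
            self.stages.append(stage)

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        x = nn.relu(self.stem_bn(self.stem_conv(x)))
        x = nn.maxpool2d(x, 3, 2, pad=1)
        outs = []
        for stage in self.stages:
            for block in stage:
                x = block(x)
            outs.append(x)
        return outs


class TinyBackbone(nn.Module):
    """Four-stage CNN (16/32/64/128 channels) with the same C2-C5 strides."""

    out_channels = (16, 32, 64, 128)

    def __init__(self, rng: np.random.Generator) -> None:
        def stage(c_in: int, c_out: int) -> nn.Sequential:
            return nn.Sequential(
                nn.Conv2d(c_in, c_out, 3, stride=2, pad=1, rng=rng),
                nn.relu,
                nn.Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng),
                nn.relu,
            )

        self.stem = nn.Sequential(nn.Conv2d(3, 16, 3, stride=2, pad=1, rng=rng), nn.relu)
        self.stages = [stage(16, 16), stage(16, 32), stage(32, 64), stage(64, 128)]

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        x = self.stem(x)
        outs = []
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        return outs


class FPN(nn.Module):
    """Top-down feature pyramid; P6 subsamples P5 (no extra parameters)."""

    def __init__(self, in_channels: tuple[int, ...], out_ch: int,
                 rng: np.random.Generator) -> None:
        self.laterals = [nn.Conv2d(c, out_ch, 1, rng=rng) for c in in_channels]
        self.out_convs = [nn.Conv2d(out_ch, out_ch, 3, pad=1, rng=rng) for _ in in_channels]

    def __call__(self, feats: list[nn.Tensor]) -> list[nn.Tensor]:
        lats = [lat(f) for lat, f in zip(self.laterals, feats)]
        for i in range(len(lats) - 2, -1, -1):
            up = nn.upsample_nearest2(lats[i + 1], out_hw=lats[i].data.shape[1:])
            lats[i] = nn.add(lats[i], up)
        outs = [conv(lat) for conv, lat in zip(self.out_convs, lats)]
        outs.append(nn.maxpool2d(outs[-1], 1, 2))
        return outs


class RPNHead(nn.Module):
    """Shared 3x3 conv, then 1x1 objectness (3/cell) and delta (15/cell)."""

    def __init__(self, ch: int, n_anchors: int, rng: np.random.Generator) -> None:
        self.conv = nn.Conv2d(ch, ch, 3, pad=1, rng=rng)
        # prediction layers start near zero so initial proposals coincide
        # with their anchors instead of random noise
        self.cls = nn.Conv2d(ch, n_anchors, 1, rng=rng, init_std=0.01)
        self.reg = nn.Conv2d(ch, n_anchors * 5, 1, rng=rng, init_std=0.01)

    def __call__(self, feat: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = nn.relu(self.conv(feat))
        return self.cls(h), self.reg(h)


class ROIHead(nn.Module):
    """Two cascaded fully-connected layers then 2-way class and 5-delta
    regression heads."""

    def __init__(self, ch: int, k: int, hidden: int, rng: np.random.Generator) -> None:
        self.fc1 = nn.Linear(ch * k * k, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, hidden, rng=rng)
        # near-zero prediction layers: refinement starts at the identity
        self.cls = nn.Linear(hidden, 2, rng=rng, init_std=0.01)
        self.reg = nn.Linear(hidden, 5, rng=rng, init_std=0.001)

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = nn.relu(self.fc1(x))
        h = nn.relu(self.fc2(h))
        return self.cls(h), self.reg(h)


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class Detector(nn.Module):
    def __init__(self, config: ModelConfig) -> None:
        rng = np.random.default_rng(config.seed)
        if config.backbone == "resnet50":
            self.backbone = ResNet50Backbone(rng)
        elif config.backbone == "tiny":
            self.backbone = TinyBackbone(rng)
        else:
            raise ValueError(f"unknown backbone {config.backbone!r}")
        self.fpn = FPN(self.backbone.out_channels, config.fpn_channels, rng)
        self.rpn_head = RPNHead(config.fpn_channels, len(config.anchor_ratios), rng)
        self.roi_head = ROIHead(config.fpn_channels, config.k, config.rcnn_hidden, rng)
        self.config = config

    # -- feature extraction -------------------------------------------------
    @staticmethod
    def preprocess(image: np.ndarray) -> np.ndarray:
        """HWC uint8 -> normalized CHW float."""
        arr = np.asarray(image, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 image, got shape {arr.shape}")
        return ((arr / 255.0) - 0.5).transpose(2, 0, 1) / 0.25

    def pyramid_features(self, image_chw: np.ndarray) -> list[nn.Tensor]:
        x = nn.Tensor(image_chw)
        return self.fpn(self.backbone(x))

    def rpn_forward(self, feats: list[nn.Tensor]) -> list[tuple[nn.Tensor, nn.Tensor]]:
        return [self.rpn_head(f) for f in feats]

    # -- proposals ----------------------------------------------------------
    def propose(
        self,
        rpn_out: list[tuple[nn.Tensor, nn.Tensor]],
        pyramid: AnchorPyramid,
        training: bool = False,
    ) -> ProposalSet:
        """Decode, per-level top-k + rotated NMS, aggregate, global sort."""
        cfg = self.config
        all_boxes, all_scores = [], []
        for lvl, (cls_t, reg_t) in enumerate(rpn_out):
            scores = _flat_scores(cls_t.data)
            deltas = _flat_deltas(reg_t.data)
            anchors = pyramid.anchors[lvl]
            order = np.argsort(-scores, kind="stable")[: cfg.rpn_pre_nms]
            boxes = decode_batch(deltas[order], anchors[order])
            keep = rotated_nms(
                boxes, scores[order], cfg.rpn_nms_thr,
                max_keep=cfg.rpn_post_nms_per_level,
            )
            all_boxes.append(boxes[keep])
            all_scores.append(scores[order][keep])
        boxes = np.concatenate(all_boxes, axis=0)
        scores = np.concatenate(all_scores)
        cap = cfg.proposal_cap_train if training else cfg.proposal_cap_infer
        order = np.argsort(-scores, kind="stable")[:cap]
        return ProposalSet(boxes=boxes[order], scores=scores[order])

    # -- second stage -------------------------------------------------------
    def _assign_levels(self, boxes: np.ndarray) -> np.ndarray:
        """FPN level index (0-3, strides 4-32) per proposal by box scale."""
        scale = np.sqrt(boxes[:, 2] * boxes[:, 3])
        lvl = np.floor(np.log2(np.maximum(scale, 1e-6) / 56.0)) + 2
        return np.clip(lvl, 2, 5).astype(int) - 2

    def refine(
        self, feats: list[nn.Tensor], proposals: ProposalSet
    ) -> list[Detection]:
        """Pool rotated-aligned features and refine proposals into final
        scored detections (score threshold + rotated NMS)."""
        cfg = self.config
        if len(proposals) == 0:
            return []
        levels = self._assign_levels(proposals.boxes)
        pooled_rows = np.empty((len(proposals), cfg.fpn_channels * cfg.k * cfg.k))
        for i, (box_row, lvl) in enumerate(zip(proposals.boxes, levels)):
            fmap = FeatureMap(feats[lvl].data, stride=cfg.strides[lvl])
            region = rroi_align(fmap, canonicalize(*box_row), k=cfg.k, l=cfg.l)
            pooled_rows[i] = region.values.reshape(-1)
        cls_t, reg_t = self.roi_head(nn.Tensor(pooled_rows))
        z = cls_t.data - cls_t.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        fg = ez[:, 1] / ez.sum(axis=1)
        boxes = decode_batch(reg_t.data, proposals.boxes)
        keep = fg >= cfg.score_threshold
        boxes, fg = boxes[keep], fg[keep]
        if len(boxes) == 0:
            return []
        kept = rotated_nms(boxes, fg, cfg.final_nms_thr)
        return [
            Detection(box=canonicalize(*boxes[i]), score=float(fg[i])) for i in kept
        ]

    # -- end-to-end ---------------------------------------------------------
    def detect(self, image: np.ndarray) -> list[Detection]:
        """Run the full pipeline on an H x W x 3 uint8 image; detections are
        mapped back to the original image coordinates."""
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("detect expects an H x W x 3 RGB image")
        h0, w0 = image.shape[:2]
        w_in, h_in = self.config.image_size
        if (w0, h0) != (w_in, h_in):
            resized = np.asarray(
                Image.fromarray(image.astype(np.uint8)).resize((w_in, h_in), Image.BILINEAR)
            )
        else:
            resized = image
        feats = self.pyramid_features(self.preprocess(resized))
        pyramid = build_anchor_pyramid(
            (w_in, h_in), self.config.strides, self.config.anchor_areas,
            self.config.anchor_ratios,
        )
        proposals = self.propose(self.rpn_forward(feats), pyramid, training=False)
        dets = self.refine(feats, proposals)
        sx, sy = w0 / w_in, h0 / h_in
        if (sx, sy) != (1.0, 1.0):
            dets = [
                Detection(box=_rescale_box(d.box, sx, sy), score=d.score,
                          class_id=d.class_id)
                for d in dets
            ]
        return dets


def _rescale_box(b: RotatedBox, sx: float, sy: float) -> RotatedBox:
    """Map a rotated box through a diagonal scaling.

    Exact for uniform scaling; for anisotropic scaling the image of a
    rectangle is a parallelogram, approximated by the rotated box spanned
    by the transformed edge vectors.
    """
    c, s = math.cos(b.theta), math.sin(b.theta)
    ew = np.array([c * sx, s * sy])
    eh = np.array([-s * sx, c * sy])
    return canonicalize(
        b.x * sx, b.y * sy,
        b.w * float(np.linalg.norm(ew)), b.h * float(np.linalg.norm(eh)),
        math.atan2(ew[1], ew[0]),
    )


def _flat_scores(cls_data: np.ndarray) -> np.ndarray:
    """(A, H, W) objectness logits -> sigmoid scores in anchor-flat order
    (row-major grid, anchors fastest)."""
    flat = cls_data.transpose(1, 2, 0).reshape(-1)
    return 1.0 / (1.0 + np.exp(-flat))


def _flat_deltas(reg_data: np.ndarray) -> np.ndarray:
    """(A*5, H, W) regression map -> (H*W*A, 5) in anchor-flat order."""
    a5, h, w = reg_data.shape
    return reg_data.reshape(a5 // 5, 5, h, w).transpose(2, 3, 0, 1).reshape(-1, 5)


def build_model(config: ModelConfig) -> Detector:
    """Construct the detector with deterministic seeded initialization."""
    return Detector(config)


def config_from_file(path: str | Path, **overrides) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML or JSON file.

    The file holds a flat mapping of config fields (unknown keys are
    rejected); keyword overrides win over file values. A ``backbone`` key
    selects the matching defaults before the remaining fields apply.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    raw.update(overrides)
    unknown = set(raw) - set(ModelConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    for key in ("strides", "anchor_areas", "anchor_ratios", "image_size"):
        if key in raw:
            raw[key] = tuple(raw[key])
    backbone = raw.pop("backbone", "tiny")
    base = resnet50_config() if backbone == "resnet50" else tiny_config()
    return replace(base, **raw)


def count_parameters(model: Detector) -> int:
    """Total trainable scalars (conv/dense weights and biases plus batch-norm
    affine terms; running statistics excluded)."""
    return model.n_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Detector, path: str | Path) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, __config__=json.dumps(vars(model.config) | {}), **arrays)


def load_checkpoint(path: str | Path) -> Detector:
    with np.load(path, allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["__config__"]))
        for key in ("strides", "anchor_areas", "anchor_ratios", "image_size"):
            cfg_raw[key] = tuple(cfg_raw[key])
        model = Detector(ModelConfig(**cfg_raw))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"p{i}"]
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _pool_indices(
    proposal: RotatedBox, stride: float, k: int, l: int, h: int, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear gather indices/weights for one proposal on a feature map."""
    region = project_proposal(proposal, stride)
    pts = sampling_points(region, k, l).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    tx, ty = x - x0, y - y0
    idx = np.zeros((len(pts), 4), dtype=int)
    wgt = np.zeros((len(pts), 4))
    for j, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        xi, yi = x0 + dx, y0 + dy
        valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        weight = (tx if dx else 1 - tx) * (ty if dy else 1 - ty) * valid
        idx[:, j] = np.clip(yi, 0, h - 1) * w + np.clip(xi, 0, w - 1)
        wgt[:, j] = weight
    return idx, wgt


def _rpn_loss(
    model: Detector,
    rpn_out: list[tuple[nn.Tensor, nn.Tensor]],
    pyramid: AnchorPyramid,
    gts: np.ndarray,
    assignment,
    rng: np.random.Generator,
) -> nn.Tensor:
    cfg = model.config
    batch = sample_training_batch(assignment, cfg.rpn_batch, rng)
    sampled = np.concatenate([batch.positive_indices, batch.negative_indices])
    labels01 = np.concatenate(
        [np.ones(batch.n_pos), np.zeros(len(batch.negative_indices))]
    )
    n_total = len(sampled)

    terms: list[nn.Tensor] = []
    flat_anchors = pyramid.flat
    gt_of = assignment.labels
    for lvl, (cls_t, reg_t) in enumerate(rpn_out):
        sl = pyramid.level_slice(lvl)
        in_level = (sampled >= sl.start) & (sampled < sl.stop)
        if not in_level.any():
            continue
        local = sampled[in_level] - sl.start
        a, h, w = cls_t.data.shape
        cls_flat = nn.reshape(nn.transpose(cls_t, (1, 2, 0)), (h * w * a,))
        terms.append(
            nn.bce_with_logits_sum(nn.gather_rows(cls_flat, local), labels01[in_level])
        )
        pos_mask = in_level & (labels01 > 0)
        if pos_mask.any():
            pos_global = sampled[pos_mask]
            pos_local = pos_global - sl.start
            reg_flat = nn.reshape(
                nn.transpose(nn.reshape(reg_t, (a, 5, h, w)), (2, 3, 0, 1)),
                (h * w * a, 5),
            )
            pred = nn.gather_rows(reg_flat, pos_local)
            target = encode_batch(
                gts[gt_of[pos_global]], flat_anchors[pos_global]
            )
            terms.append(nn.smooth_l1_sum(pred, target))
    total = terms[0]
    for t in terms[1:]:
        total = nn.add(total, t)
    return nn.scale(total, 1.0 / n_total)


def _rcnn_loss(
    model: Detector,
    feats: list[nn.Tensor],
    proposals: ProposalSet,
    gts: np.ndarray,
    rng: np.random.Generator,
) -> nn.Tensor | None:
    cfg = model.config
    # ground-truth boxes join the candidate pool so the head always sees
    # well-aligned positives early in training
    cand = np.concatenate([proposals.boxes, gts], axis=0)
    best_iou = np.zeros(len(cand))
    best_gt = np.zeros(len(cand), dtype=int)
    for g in range(len(gts)):
        ious = skew_iou_one_to_many(gts[g], cand)
        better = ious > best_iou
        best_iou[better] = ious[better]
        best_gt[better] = g
    pos = np.nonzero(best_iou >= cfg.rcnn_pos_iou)[0]
    neg = np.nonzero(best_iou < cfg.rcnn_pos_iou)[0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    n_pos = min(len(pos), int(cfg.rcnn_batch * cfg.rcnn_pos_fraction))
    pos = np.sort(rng.choice(pos, size=n_pos, replace=False))
    n_neg = min(len(neg), cfg.rcnn_batch - n_pos)
    neg = np.sort(rng.choice(neg, size=n_neg, replace=False))
    chosen = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])

    levels = model._assign_levels(cand[chosen])
    rows = []
    for row, lvl in zip(cand[chosen], levels):
        f = feats[lvl]
        _, h, w = f.data.shape
        idx, wgt = _pool_indices(
            canonicalize(*row), cfg.strides[lvl], cfg.k, cfg.l, h, w
        )
        rows.append(nn.rroi_pool(f, idx, wgt, cfg.k))
    pooled = nn.stack_rows(rows)
    cls_t, reg_t = model.roi_head(pooled)
    n_total = len(chosen)
    loss = nn.softmax_ce_sum(cls_t, labels)
    pred_pos = nn.gather_rows(reg_t, np.arange(len(pos)))
    target = encode_batch(gts[best_gt[pos]], cand[pos])
    loss = nn.add(loss, nn.smooth_l1_sum(pred_pos, target))
    return nn.scale(loss, 1.0 / n_total)


def train_demo(
    dataset_dir: str | Path,
    model: Detector | None = None,
    iterations: int = 200,
    lr: float = 2e-3,
    momentum: float = 0.9,
    seed: int = 0,
    log_every: int = 10,
) -> tuple[Detector, list[dict]]:
    """Train the (reduced) detector on a synthetic scene directory.

    One image per step, SGD with momentum, learning rate dropped by 10x at
    2/3 and 11/12 of the run. Returns the trained model and the loss log.
    Deterministic for fixed seed and dataset.
    """
    dataset_dir = Path(dataset_dir)
    records = load_dataset(dataset_dir)
    if not records:
        raise ValueError("empty dataset")
    model = model or build_model(tiny_config(seed=seed))
    cfg = model.config

    images, gt_arrays = [], []
    for rec in records:
        png = dataset_dir / f"{rec.image_id}.png"
        img = np.asarray(Image.open(png).convert("RGB"))
        if img.shape[:2] != (cfg.image_size[1], cfg.image_size[0]):
            raise ValueError(
                f"{png}: image size {img.shape[1::-1]} != model input {cfg.image_size}"
            )
        images.append(model.preprocess(img))
        gt_arrays.append(boxes_to_array(rec.instances))

    pyramid = build_anchor_pyramid(
        cfg.image_size, cfg.strides, cfg.anchor_areas, cfg.anchor_ratios
    )
    assignments = [
        adaptive_assign(pyramid, gts, cfg.n_per_level) if len(gts) else None
        for gts in gt_arrays
    ]

    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.parameters(), lr=lr, momentum=momentum)
    drops = {int(iterations * 2 / 3), int(iterations * 11 / 12)}
    log: list[dict] = []
    for it in range(iterations):
        if it in drops:
            opt.lr *= 0.1
        i = it % len(records)
        gts = gt_arrays[i]
        if assignments[i] is None:
            continue
        opt.zero_grad()
        feats = model.pyramid_features(images[i])
        rpn_out = model.rpn_forward(feats)
        loss = _rpn_loss(model, rpn_out, pyramid, gts, assignments[i], rng)
        rpn_val = float(loss.data)
        proposals = model.propose(rpn_out, pyramid, training=True)
        rcnn = _rcnn_loss(model, feats, proposals, gts, rng)
        rcnn_val = float(rcnn.data) if rcnn is not None else 0.0
        if rcnn is not None:
            loss = nn.add(loss, rcnn)
        loss.backward()
        opt.step()
        entry = {
            "iteration": it,
            "loss": float(loss.data),
            "rpn_loss": rpn_val,
            "rcnn_loss": rcnn_val,
            "lr": opt.lr,
        }
        log.append(entry)
    return model, log
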