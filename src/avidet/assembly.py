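"""Model assembly, cost accounting, training and evaluation.

The baseline detector is a standard anchor-free one-stage network: C2f/SPPF
backbone, PAN neck, decoupled classification/regression heads with
distribution-style box regression (``reg_max`` bins per side).  Three flags
swap in the improvements, independently combinable for ablation:

* ``rfaconv`` — the backbone's strided downsampling convolutions become
  receptive-field attention convolutions (the stem stays standard);
* ``dyasf_p2`` — the PAN neck is replaced by the DyASF-P2 fusion neck,
  adding a stride-4 level and a fourth head;
* ``lsdecd`` — the per-level decoupled heads are replaced by the shared
  detail-enhanced head;
* the box-regression loss is selected by name (``ciou`` baseline,
  ``shape_iou``, ``inner_iou``, ``inner_shape_iou``).

FLOPs are counted as 2 x multiply-accumulate over convolution and affine
layers only, at the configured input size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import nn
from .blocks import C2f, CBS, SPPF
from .boxloss import make_box_loss, iou_t
from .dyasf import DyASFP2Neck, NeckConfig, PANNeck
from .evalkit import Detection, GroundTruth, map_range
from .boxloss import BoundingBox
from .lsdecd import HeadConfig, LSDECDHead
from .nn import functional as F
from .rfaconv import RFAConv

__all__ = [
    "ModelConfig", "Detector", "build_model", "count_params", "count_flops",
    "CostReport", "cost_report", "train", "TrainResult", "evaluate", "predict_image",
    "save_checkpoint", "load_checkpoint", "DetectionLoss",
]


# ------------------------------------------------------------------- configs
@dataclass
class ModelConfig:
    variant: str = "baseline"
    nc: int = 5
    depth: float = 0.33
    width: float = 0.25
    rfaconv: bool = False
    dyasf_p2: bool = False
    lsdecd: bool = False
    loss: dict = field(default_factory=lambda: {"name": "ciou"})
    img_size: int = 640
    reg_max: int = 16
    head_width: int = 24          # shared width of the LSDECD head
    seed: int = 0

    def __post_init__(self):
        if self.nc < 1:
            raise ValueError("nc must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass(frozen=True)
class CostReport:
    params: int
    flops: int
    img_size: int

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9


def _scaled_channels(width: float):
    base = (64, 128, 256, 512, 1024)
    return tuple(max(8, int(round(b * min(width, 1.0)))) for b in base)


def _scaled_depth(depth: float, n: int) -> int:
    return max(1, int(round(n * depth)))


# ------------------------------------------------------------------ backbone
class Backbone(nn.Module):
    """C2f/SPPF backbone emitting P2 (stride 4) .. P5 (stride 32)."""

    def __init__(self, width=0.25, depth=0.33, use_rfa=False):
        super().__init__()
        c1, c2, c3, c4, c5 = _scaled_channels(width)  # (16,32,64,128,256) at nano
        Down = (lambda a, b: RFAConv(a, b, 3, 2)) if use_rfa else \
               (lambda a, b: CBS(a, b, 3, 2))
        self.stem = CBS(3, c1, 3, 2)
        self.down1 = Down(c1, c2)
        self.c2f1 = C2f(c2, c2, _scaled_depth(depth, 3), shortcut=True)
        self.down2 = Down(c2, c3)
        self.c2f2 = C2f(c3, c3, _scaled_depth(depth, 6), shortcut=True)
        self.down3 = Down(c3, c4)
        self.c2f3 = C2f(c4, c4, _scaled_depth(depth, 6), shortcut=True)
        self.down4 = Down(c4, c5)
        self.c2f4 = C2f(c5, c5, _scaled_depth(depth, 3), shortcut=True)
        self.sppf = SPPF(c5, c5)
        self.out_channels = (c2, c3, c4, c5)

    def forward(self, x):
        p2 = self.c2f1(self.down1(self.stem(x)))
        p3 = self.c2f2(self.down2(p2))
        p4 = self.c2f3(self.down3(p3))
        p5 = self.sppf(self.c2f4(self.down4(p4)))
        return [p2, p3, p4, p5]


# -------------------------------------------------------------- detect heads
class DetectHead(nn.Module):
    """Stock decoupled anchor-free head: per-level cls and box branches."""

    def __init__(self, in_channels, nc, reg_max=16):
        super().__init__()
        c2 = max(16, in_channels[0] // 4, reg_max * 4)
        c3 = max(in_channels[0], min(nc, 100))
        self.levels = nn.ModuleList()
        for c in in_channels:
            lvl = nn.Module()
            lvl.box1, lvl.box2 = CBS(c, c2, 3), CBS(c2, c2, 3)
            lvl.box3 = nn.Conv2d(c2, 4 * reg_max, 1, bias=True)
            lvl.cls1, lvl.cls2 = CBS(c, c3, 3), CBS(c3, c3, 3)
            lvl.cls3 = nn.Conv2d(c3, nc, 1, bias=True)
            lvl.cls3.bias.data[...] = -4.6  # ~1% object prior
            lvl.box3.bias.data[...] = 1.0
            lvl.forward = lambda x, m=lvl: (
                m.cls3(m.cls2(m.cls1(x))), m.box3(m.box2(m.box1(x))))
            self.levels.append(lvl)

    def forward(self, feats):
        return [self.levels[i](x) for i, x in enumerate(feats)]


# -------------------------------------------------------------------- model
class Detector(nn.Module):
    """Assembled detector; forward returns per-level (cls_map, box_map)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        nn.set_seed(cfg.seed)
        self.cfg = cfg
        self.backbone = Backbone(cfg.width, cfg.depth, cfg.rfaconv)
        bb = self.backbone.out_channels
        if cfg.dyasf_p2:
            s = cfg.width / 0.25  # neck widths are specified at nano scale
            def sc(v):
                return max(8, int(round(v * s / 4)) * 4)
            ncfg = NeckConfig(in_channels=bb,
                              out_channels=tuple(sc(v) for v in (80, 64, 96, 128)),
                              tfe_width_hi=sc(128), tfe_width_lo=sc(80),
                              mid3=sc(84),
                              depth=_scaled_depth(cfg.depth, 3))
            self.neck = DyASFP2Neck(ncfg)
            head_ch = ncfg.out_channels
            self.strides = (4, 8, 16, 32)
        else:
            self.neck = PANNeck(*bb[1:], n=_scaled_depth(cfg.depth, 3))
            head_ch = bb[1:]
            self.strides = (8, 16, 32)
        if cfg.lsdecd:
            hc = HeadConfig(num_levels=len(head_ch), num_classes=cfg.nc,
                            reg_max=cfg.reg_max, width=cfg.head_width)
            self.head = LSDECDHead(head_ch, hc)
        else:
            self.head = DetectHead(head_ch, cfg.nc, cfg.reg_max)

    def forward(self, x):
        return self.head(self.neck(self.backbone(nn.as_tensor(x))))


def build_model(cfg: ModelConfig) -> Detector:
    return Detector(cfg)


def count_params(model: nn.Module) -> int:
    """Exact count of trainable scalars."""
    return model.num_params()


def count_flops(model: Detector, img_size: int | None = None) -> int:
    """2xMAC FLOPs of conv/affine layers for one image at ``img_size``."""
    s = img_size or model.cfg.img_size
    model.eval()
    with nn.no_grad(), F.flop_counter() as fc:
        model(np.zeros((1, 3, s, s), dtype=np.float32))
    model.train()
    return fc.flops


def flops_of(module: nn.Module, input_shape) -> int:
    """2xMAC FLOPs of any module for one forward at ``input_shape``."""
    module.eval()
    with nn.no_grad(), F.flop_counter() as fc:
        module(np.zeros(input_shape, dtype=np.float32))
    module.train()
    return fc.flops


def cost_report(model: Detector, img_size: int | None = None) -> CostReport:
    s = img_size or model.cfg.img_size
    return CostReport(count_params(model), count_flops(model, s), s)


# ------------------------------------------------------------ box decoding
def _anchor_points(shapes, strides):
    """Cell-center anchor points (in pixels) and per-anchor stride."""
    pts, strd = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.mgrid[0:h, 0:w]
        pts.append(np.stack([(xs + 0.5) * s, (ys + 0.5) * s], -1).reshape(-1, 2))
        strd.append(np.full(h * w, s))
    return np.concatenate(pts).astype(np.float32), np.concatenate(strd).astype(np.float32)


def _flatten_outputs(outputs):
    """Per-level (cls, box) maps -> (N, A, nc) logits and (N, A, 4*reg_max)."""
    cls_list, box_list, shapes = [], [], []
    for cls_map, box_map in outputs:
        N, C, H, W = cls_map.shape
        shapes.append((H, W))
        cls_list.append(cls_map.reshape(N, C, H * W).transpose(0, 2, 1))
        Nb, Cb, _, _ = box_map.shape
        box_list.append(box_map.reshape(Nb, Cb, H * W).transpose(0, 2, 1))
    return nn.concat(cls_list, axis=1), nn.concat(box_list, axis=1), shapes


def _dfl_expectation(box_logits, reg_max):
    """Distribution-focal decoding: softmax over bins -> expected distance."""
    N, A, _ = box_logits.shape
    p = box_logits.reshape(N, A, 4, reg_max).softmax(axis=3)
    bins = nn.Tensor(np.arange(reg_max, dtype=np.float32))
    return (p * bins.reshape(1, 1, 1, reg_max)).sum(axis=3)  # (N, A, 4) ltrb


def _decode_boxes(box_logits, anchors, strides, reg_max):
    """ltrb distances (stride units) -> xyxy pixel boxes, differentiable."""
    d = _dfl_expectation(box_logits, reg_max)
    ax = nn.Tensor(anchors[None, :, 0])
    ay = nn.Tensor(anchors[None, :, 1])
    st = nn.Tensor(strides[None, :])
    return nn.stack([ax - d[..., 0] * st, ay - d[..., 1] * st,
                     ax + d[..., 2] * st, ay + d[..., 3] * st], axis=-1)


# --------------------------------------------------------------- assignment
def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy boxes, (n, m)."""
    ix = np.maximum(0.0, np.minimum(a[:, None, 2], b[None, :, 2])
                    - np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = np.maximum(0.0, np.minimum(a[:, None, 3], b[None, :, 3])
                    - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = ix * iy
    aa = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    bb = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(aa[:, None] + bb[None, :] - inter, 1e-9)


def assign_targets(scores, pboxes, anchors, gt_boxes, gt_cls,
                   topk=10, alpha=0.5, beta=6.0):
    """Task-aligned assignment for one image (all numpy, no gradients).

    Returns (fg_mask, target_cls_scores, target_boxes, matched_gt_idx).
    """
    A = anchors.shape[0]
    nc = scores.shape[1]
    t_scores = np.zeros((A, nc), dtype=np.float32)
    t_boxes = np.zeros((A, 4), dtype=np.float32)
    fg = np.zeros(A, dtype=bool)
    gt_of = np.full(A, -1)
    if len(gt_boxes) == 0:
        return fg, t_scores, t_boxes, gt_of
    inside = ((anchors[:, 0] > gt_boxes[:, None, 0])
              & (anchors[:, 0] < gt_boxes[:, None, 2])
              & (anchors[:, 1] > gt_boxes[:, None, 1])
              & (anchors[:, 1] < gt_boxes[:, None, 3]))          # (G, A)
    ious = _iou_matrix(gt_boxes, pboxes)                          # (G, A)
    cls_p = scores[np.arange(A)[None, :], gt_cls[:, None]]        # (G, A)
    align = (cls_p ** alpha) * (ious ** beta) * inside
    G = len(gt_boxes)
    cand = np.zeros_like(inside)
    k = min(topk, A)
    top = np.argpartition(-align, k - 1, axis=1)[:, :k]
    for g in range(G):
        sel = top[g][align[g, top[g]] > 0]
        cand[g, sel] = True
    # an anchor claimed by several gts goes to the one with larger IoU
    claimed = cand.sum(axis=0)
    conflict = np.where(claimed > 1)[0]
    for a in conflict:
        gs = np.where(cand[:, a])[0]
        keep = gs[np.argmax(ious[gs, a])]
        cand[:, a] = False
        cand[keep, a] = True
    for g in range(G):
        sel = np.where(cand[g])[0]
        if sel.size == 0:
            continue
        m = align[g, sel]
        norm = m / max(m.max(), 1e-9) * max(ious[g, sel].max(), 1e-9)
        fg[sel] = True
        gt_of[sel] = g
        t_boxes[sel] = gt_boxes[g]
        t_scores[sel, gt_cls[g]] = norm
    return fg, t_scores, t_boxes, gt_of


# --------------------------------------------------------------------- loss
class DetectionLoss:
    """Composite detection loss: BCE classification + selected box loss +
    distribution-focal regression, weighted 7.5 / 0.5 / 1.5 (box/cls/dfl)."""

    def __init__(self, cfg: ModelConfig, w_box=7.5, w_cls=0.5, w_dfl=1.5):
        self.cfg = cfg
        self.box_fn = make_box_loss(cfg.loss)
        self.w_box, self.w_cls, self.w_dfl = w_box, w_cls, w_dfl

    def __call__(self, outputs, targets, strides):
        """``targets``: list (per image) of (cls_ids, xyxy pixel boxes)."""
        cls_logits, box_logits, shapes = _flatten_outputs(outputs)
        anchors, astr = _anchor_points(shapes, strides)
        pboxes = _decode_boxes(box_logits, anchors, astr, self.cfg.reg_max)
        N, A, nc = cls_logits.shape
        scores = cls_logits.sigmoid()

        fg_all, ts_all, tb_all = [], [], []
        for i in range(N):
            gt_cls, gt_boxes = targets[i]
            fg, ts, tb, _ = assign_targets(scores.data[i], pboxes.data[i],
                                           anchors, gt_boxes, gt_cls)
            fg_all.append(fg)
            ts_all.append(ts)
            tb_all.append(tb)
        fg = np.stack(fg_all)
        tscore = np.stack(ts_all)
        tbox = np.stack(tb_all)
        score_sum = max(float(tscore.sum()), 1.0)

        # classification: BCE-with-logits against aligned soft targets,
        # over every anchor
        t = nn.Tensor(tscore)
        z = cls_logits
        bce = z.clamp(0.0) - z * t + (1.0 + (-z.abs()).exp()).log()
        loss_cls = bce.sum() / score_sum

        idx = np.where(fg)
        if idx[0].size:
            w = nn.Tensor(tscore[idx].sum(axis=1))
            pb = pboxes[idx]
            gb = nn.Tensor(tbox[idx])
            loss_box = (self.box_fn(pb, gb) * w).sum() / score_sum
            # DFL on the ltrb bin distribution against the true distances
            d_true = np.stack([
                (anchors[idx[1], 0] - tbox[idx][:, 0]) / astr[idx[1]],
                (anchors[idx[1], 1] - tbox[idx][:, 1]) / astr[idx[1]],
                (tbox[idx][:, 2] - anchors[idx[1], 0]) / astr[idx[1]],
                (tbox[idx][:, 3] - anchors[idx[1], 1]) / astr[idx[1]],
            ], axis=1)
            d_true = np.clip(d_true, 0.0, self.cfg.reg_max - 1.001)
            lo = np.floor(d_true).astype(int)
            hi = lo + 1
            w_hi = d_true - lo
            logits = box_logits[idx].reshape(-1, 4, self.cfg.reg_max)
            mx = nn.Tensor(logits.data.max(axis=2, keepdims=True))
            logp = logits - mx - ((logits - mx).exp().sum(axis=2, keepdims=True)).log()
            oh_lo = np.zeros(logits.shape, dtype=np.float32)
            oh_hi = np.zeros(logits.shape, dtype=np.float32)
            np.put_along_axis(oh_lo, lo[..., None], (1 - w_hi)[..., None], axis=2)
            np.put_along_axis(oh_hi, hi[..., None], w_hi[..., None], axis=2)
            ce = -(logp * nn.Tensor(oh_lo + oh_hi)).sum(axis=(1, 2)) / 4.0
            loss_dfl = (ce * w).sum() / score_sum
        else:
            loss_box = nn.Tensor(np.float32(0.0))
            loss_dfl = nn.Tensor(np.float32(0.0))

        total = self.w_box * loss_box + self.w_cls * loss_cls + self.w_dfl * loss_dfl
        return total, {"box": float(loss_box.data), "cls": float(loss_cls.data),
                       "dfl": float(loss_dfl.data), "total": float(total.data)}


# ----------------------------------------------------------------- data I/O
def _load_split(data_cfg: dict, split: str):
    img_dir = Path(data_cfg[split])
    lbl_dir = img_dir.parent / "labels"
    items = []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        lbl = lbl_dir / (img_path.stem + ".txt")
        boxes, clss = [], []
        if lbl.exists():
            for line in lbl.read_text().splitlines():
                if line.strip():
                    c, xc, yc, w, h = map(float, line.split()[:5])
                    clss.append(int(c))
                    boxes.append((xc, yc, w, h))
        items.append((img_path, np.array(clss, dtype=int),
                      np.array(boxes, dtype=np.float32).reshape(-1, 4)))
    return items


def _read_image(path, img_size: int) -> np.ndarray:
    im = Image.open(path).convert("RGB")
    if im.size != (img_size, img_size):
        im = im.resize((img_size, img_size), Image.BILINEAR)
    a = np.asarray(im, dtype=np.float32) / 255.0
    return a.transpose(2, 0, 1)


def _targets_pixels(clss, boxes_n, img_size):
    if len(boxes_n) == 0:
        return clss, np.zeros((0, 4), dtype=np.float32)
    xc, yc, w, h = (boxes_n[:, 0], boxes_n[:, 1], boxes_n[:, 2], boxes_n[:, 3])
    xyxy = np.stack([(xc - w / 2), (yc - h / 2), (xc + w / 2), (yc + h / 2)], 1)
    return clss, (xyxy * img_size).astype(np.float32)


# ------------------------------------------------------------------ training
@dataclass
class TrainResult:
    history: list
    checkpoint: str | None = None


def train(model: Detector, data_yaml, epochs=20, batch_size=8, lr=0.01,
          momentum=0.937, weight_decay=5e-4, seed=0, img_size=None,
          checkpoint=None, log_every=0, loss_weights=(7.5, 0.5, 1.5)):
    """Plain SGD training loop; deterministic for a fixed seed.

    Aborts with a diagnostic if the loss turns non-finite.  Returns the
    per-epoch mean loss history.
    """
    data_cfg = yaml.safe_load(Path(data_yaml).read_text())
    items = _load_split(data_cfg, "train")
    if not items:
        raise ValueError("empty training split")
    s = img_size or model.cfg.img_size
    crit = DetectionLoss(model.cfg, *loss_weights)
    opt = nn.SGD(model.parameters(), lr=lr, momentum=momentum,
                 weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    model.train()
    step = 0
    for ep in range(epochs):
        order = rng.permutation(len(items))
        ep_losses = []
        for b0 in range(0, len(items), batch_size):
            batch = [items[i] for i in order[b0:b0 + batch_size]]
            imgs = np.stack([_read_image(p, s) for p, _, _ in batch])
            targets = [_targets_pixels(c, bx, s) for _, c, bx in batch]
            out = model(imgs)
            loss, parts = crit(out, targets, model.strides)
            if not np.isfinite(parts["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {ep} step {step}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(parts)
            step += 1
            if log_every and step % log_every == 0:
                print(f"epoch {ep} step {step} " +
                      " ".join(f"{k}={v:.4f}" for k, v in parts.items()))
        mean = {k: float(np.mean([p[k] for p in ep_losses]))
                for k in ep_losses[0]}
        history.append(mean)
    if checkpoint:
        save_checkpoint(model, checkpoint)
    return TrainResult(history, checkpoint)


# ----------------------------------------------------------------- inference
def _nms(boxes, scores, iou_thresh=0.6):
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = _iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_thresh]
    return keep


def predict_image(model: Detector, img: np.ndarray, conf_thresh=0.25,
                  iou_thresh=0.6, max_det=300):
    """Detections for one CHW float image; boxes in pixel xyxy."""
    model.eval()
    with nn.no_grad():
        out = model(img[None])
        cls_logits, box_logits, shapes = _flatten_outputs(out)
        anchors, astr = _anchor_points(shapes, model.strides)
        boxes = _decode_boxes(box_logits, anchors, astr, model.cfg.reg_max)
    model.train()
    scores = 1.0 / (1.0 + np.exp(-cls_logits.data[0]))
    bxs = boxes.data[0]
    results = []
    for c in range(scores.shape[1]):
        sc = scores[:, c]
        m = sc >= conf_thresh
        if not m.any():
            continue
        bb, ss = bxs[m], sc[m]
        for k in _nms(bb, ss, iou_thresh):
            results.append((c, float(ss[k]), bb[k].copy()))
    results.sort(key=lambda r: -r[1])
    return results[:max_det]


def evaluate(model: Detector, data_yaml, split="val", conf_thresh=0.05,
             iou_thresh=0.6, img_size=None):
    """Run the detector over a split and score it with the metric toolkit."""
    data_cfg = yaml.safe_load(Path(data_yaml).read_text())
    items = _load_split(data_cfg, split)
    s = img_size or model.cfg.img_size
    dets, gts = [], []
    for img_path, clss, boxes_n in items:
        img = _read_image(img_path, s)
        for c, conf, b in predict_image(model, img, conf_thresh, iou_thresh):
            x1, y1, x2, y2 = np.clip(b, 0, s)
            if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                continue
            dets.append(Detection(img_path.stem, int(c),
                                  BoundingBox.from_corners(x1, y1, x2, y2),
                                  min(conf, 1.0)))
        _, pix = _targets_pixels(clss, boxes_n, s)
        for c, b in zip(clss, pix):
            gts.append(GroundTruth(img_path.stem, int(c),
                                   BoundingBox.from_corners(*b)))
    return map_range(dets, gts, class_ids=list(range(model.cfg.nc))), dets, gts


# --------------------------------------------------------------- checkpoints
def save_checkpoint(model: Detector, path):
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> Detector:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
    model = Detector(cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
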