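"""Shared-encoder, multi-decoder segmentation network.

A compact 2D U-Net implemented directly on NumPy arrays (im2col
convolutions with hand-derived backward passes and an Adam optimizer),
sized for desk-scale grids.  The encoder is shared by K decoder paths;
during training the encoder receives gradient from every slice while each
slice's loss flows only through the decoder of its scan's subset, so the
decoders specialize on their assigned data subsets.  With K = 1 the network
and its training reduce exactly to the classical single-decoder baseline.

Architecture (three resolution levels, ``encoder_width`` = W):

    enc1: conv3x3(1 -> W)  relu          48x48
    enc2: pool2, conv3x3(W -> 2W) relu   24x24
    enc3: pool2, conv3x3(2W -> 4W) relu  12x12   (bottleneck)
    per decoder k:
      dec2: up2, concat enc2, conv3x3(6W -> 2W) relu
      dec1: up2, concat enc1, conv3x3(3W -> W)  relu
      out:  conv1x1(W -> 1), sigmoid

Loss is binary cross-entropy plus a soft-Dice term, averaged per slice.
Training is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import BinaryMask, VolumeImage


class PartitionError(ValueError):
    """A training-data partition is invalid (empty subset, bad coverage)."""


@dataclass(frozen=True)
class ModelConfig:
    """Network and training hyper-parameters.

    ``n_decoders`` is K, the number of segmentation variants produced.
    Slices are 2D transversal planes; the in-plane shape must be divisible
    by 4 (two pooling stages).
    """

    n_decoders: int = 2
    encoder_width: int = 8
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-3
    threshold: float = 0.5
    slice_margin: int | None = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_decoders < 1:
            raise ValueError("n_decoders must be >= 1")
        for name in ("encoder_width", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class VariantSet:
    """The K binary masks one model proposes for one scan."""

    variants: tuple[BinaryMask, ...]

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, k: int) -> BinaryMask:
        return self.variants[k]


@dataclass
class TrainedModel:
    params: dict[str, np.ndarray]
    config: ModelConfig
    partition_used: np.ndarray | None = None
    training_log: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Layer primitives (forward + backward)
# ---------------------------------------------------------------------------

_DTYPE = np.float32


def _im2col(x: np.ndarray, k: int):
    """Unfold k x k neighbourhoods into a (C*k*k, N*H*W) matrix.

    Built by k*k shifted slice copies into a preallocated buffer, which is
    far cheaper than materialising a sliding-window view.
    """
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((c, k * k, n, h * w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i:i + h, j:j + w]  # (N, C, H, W)
            cols[:, i * k + j] = patch.transpose(1, 0, 2, 3).reshape(c, n, h * w)
    return cols.reshape(c * k * k, n * h * w)


def _conv_forward(x, w, b):
    """Same-size convolution; kernel 3x3 (pad 1) or 1x1 (pad 0)."""
    n, _, h, wd = x.shape
    co, k = w.shape[0], w.shape[2]
    cols = _im2col(x, k)
    out = w.reshape(co, -1) @ cols + b[:, None]
    out = out.reshape(co, n, h, wd).transpose(1, 0, 2, 3)
    return np.ascontiguousarray(out), cols


def _conv_backward(dout, cols, w, need_dx: bool = True):
    n, co, h, wd = dout.shape
    d2 = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(co, -1)
    dw = (d2 @ cols.T).reshape(w.shape)
    db = d2.sum(axis=1)
    if not need_dx:
        return None, dw, db
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, k, k)
    dx, _ = _conv_forward(dout, np.ascontiguousarray(w_flip),
                          np.zeros(w.shape[1], dtype=w.dtype))
    return dx, dw, db


def _maxpool(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout, idx):
    n, c, ho, wo = dout.shape
    dr = np.zeros((n, c, ho, wo, 4), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dr.reshape(n, c, ho * 2, wo * 2)


def _upsample(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _sigmoid(z):
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _he_init(rng, co, ci, k):
    std = np.sqrt(2.0 / (ci * k * k))
    return rng.normal(0.0, std, (co, ci, k, k)).astype(_DTYPE)


def build_model(cfg: ModelConfig) -> TrainedModel:
    """Seeded parameter initialization for the shared encoder and K decoders.

    The encoder parameters do not depend on K, and every decoder has the
    same architecture with independently drawn parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    w = cfg.encoder_width
    params: dict[str, np.ndarray] = {
        "enc_w1": _he_init(rng, w, 1, 3), "enc_b1": np.zeros(w, dtype=_DTYPE),
        "enc_w2": _he_init(rng, 2 * w, w, 3), "enc_b2": np.zeros(2 * w, dtype=_DTYPE),
        "enc_w3": _he_init(rng, 4 * w, 2 * w, 3), "enc_b3": np.zeros(4 * w, dtype=_DTYPE),
    }
    for k in range(cfg.n_decoders):
        params[f"dec{k}_w2"] = _he_init(rng, 2 * w, 6 * w, 3)
        params[f"dec{k}_b2"] = np.zeros(2 * w, dtype=_DTYPE)
        params[f"dec{k}_w1"] = _he_init(rng, w, 3 * w, 3)
        params[f"dec{k}_b1"] = np.zeros(w, dtype=_DTYPE)
        params[f"dec{k}_wout"] = _he_init(rng, 1, w, 1)
        params[f"dec{k}_bout"] = np.zeros(1, dtype=_DTYPE)
    return TrainedModel(params=params, config=cfg)


def parameter_counts(model: TrainedModel) -> dict[str, int]:
    """Parameter totals for the encoder and each decoder."""
    out = {"encoder": sum(v.size for n, v in model.params.items()
                          if n.startswith("enc_"))}
    for k in range(model.config.n_decoders):
        out[f"decoder_{k}"] = sum(v.size for n, v in model.params.items()
                                  if n.startswith(f"dec{k}_"))
    return out


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------

def _encoder_forward(params, x):
    z1, c1 = _conv_forward(x, params["enc_w1"], params["enc_b1"])
    a1 = np.maximum(z1, 0.0)
    p1, i1 = _maxpool(a1)
    z2, c2 = _conv_forward(p1, params["enc_w2"], params["enc_b2"])
    a2 = np.maximum(z2, 0.0)
    p2, i2 = _maxpool(a2)
    z3, c3 = _conv_forward(p2, params["enc_w3"], params["enc_b3"])
    a3 = np.maximum(z3, 0.0)
    cache = {"c1": c1, "z1": z1, "a1": a1, "i1": i1,
             "c2": c2, "z2": z2, "a2": a2, "i2": i2,
             "c3": c3, "z3": z3, "a3": a3}
    return cache


def _decoder_forward(params, k, cache):
    w = cache["a1"].shape[1]
    u2 = _upsample(cache["a3"])
    cat2 = np.concatenate([u2, cache["a2"]], axis=1)
    z2, c2 = _conv_forward(cat2, params[f"dec{k}_w2"], params[f"dec{k}_b2"])
    d2 = np.maximum(z2, 0.0)
    u1 = _upsample(d2)
    cat1 = np.concatenate([u1, cache["a1"]], axis=1)
    z1, c1 = _conv_forward(cat1, params[f"dec{k}_w1"], params[f"dec{k}_b1"])
    d1 = np.maximum(z1, 0.0)
    logits, cout = _conv_forward(d1, params[f"dec{k}_wout"],
                                 params[f"dec{k}_bout"])
    prob = _sigmoid(logits)
    dcache = {"c2": c2, "z2": z2, "c1": c1, "z1": z1, "cout": cout,
              "d1": d1, "width": w, "logits": logits, "prob": prob}
    return prob, dcache


_DICE_EPS = 1.0


def _loss_and_grad(prob, y):
    """Per-slice BCE + soft-Dice loss; gradient w.r.t. the logits."""
    n = prob.shape[0]
    npix = prob[0].size
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).reshape(n, -1).mean(axis=1)
    inter = (prob * y).reshape(n, -1).sum(axis=1)
    sums = prob.reshape(n, -1).sum(axis=1) + y.reshape(n, -1).sum(axis=1)
    dice = (2 * inter + _DICE_EPS) / (sums + _DICE_EPS)
    loss = float((bce + 1.0 - dice).mean())
    # d(bce)/dlogit = (p - y)/npix ; soft-Dice term via quotient rule
    dl_dp_dice = -(2 * y * (sums + _DICE_EPS)[:, None, None, None]
                   - (2 * inter + _DICE_EPS)[:, None, None, None]) \
        / (sums + _DICE_EPS)[:, None, None, None] ** 2
    dlogit = (prob - y) / npix + dl_dp_dice * prob * (1 - prob)
    return loss, dlogit / n


def _decoder_backward(params, k, cache, dcache, dlogits, grads):
    dd1, dwout, dbout = _conv_backward(dlogits, dcache["cout"],
                                       params[f"dec{k}_wout"])
    grads[f"dec{k}_wout"] = grads.get(f"dec{k}_wout", 0) + dwout
    grads[f"dec{k}_bout"] = grads.get(f"dec{k}_bout", 0) + dbout
    dz1 = dd1 * (dcache["z1"] > 0)
    dcat1, dw1, db1 = _conv_backward(dz1, dcache["c1"], params[f"dec{k}_w1"])
    grads[f"dec{k}_w1"] = grads.get(f"dec{k}_w1", 0) + dw1
    grads[f"dec{k}_b1"] = grads.get(f"dec{k}_b1", 0) + db1
    w = dcache["width"]
    du1, da1 = dcat1[:, :2 * w], dcat1[:, 2 * w:]
    dd2 = _upsample_backward(du1)
    dz2 = dd2 * (dcache["z2"] > 0)
    dcat2, dw2, db2 = _conv_backward(dz2, dcache["c2"], params[f"dec{k}_w2"])
    grads[f"dec{k}_w2"] = grads.get(f"dec{k}_w2", 0) + dw2
    grads[f"dec{k}_b2"] = grads.get(f"dec{k}_b2", 0) + db2
    du2, da2 = dcat2[:, :4 * w], dcat2[:, 4 * w:]
    da3 = _upsample_backward(du2)
    return da3, da2, da1


def _encoder_backward(params, cache, da3, da2, da1, grads):
    dz3 = da3 * (cache["z3"] > 0)
    dp2, dw3, db3 = _conv_backward(dz3, cache["c3"], params["enc_w3"])
    grads["enc_w3"] = grads.get("enc_w3", 0) + dw3
    grads["enc_b3"] = grads.get("enc_b3", 0) + db3
    da2 = da2 + _maxpool_backward(dp2, cache["i2"])
    dz2 = da2 * (cache["z2"] > 0)
    dp1, dw2, db2 = _conv_backward(dz2, cache["c2"], params["enc_w2"])
    grads["enc_w2"] = grads.get("enc_w2", 0) + dw2
    grads["enc_b2"] = grads.get("enc_b2", 0) + db2
    da1 = da1 + _maxpool_backward(dp1, cache["i1"])
    dz1 = da1 * (cache["z1"] > 0)
    _, dw1, db1 = _conv_backward(dz1, cache["c1"], params["enc_w1"],
                                 need_dx=False)
    grads["enc_w1"] = grads.get("enc_w1", 0) + dw1
    grads["enc_b1"] = grads.get("enc_b1", 0) + db1


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, params, grads):
        """Update only the parameters that received gradient this step, so
        untouched decoders stay bit-identical."""
        for name, g in grads.items():
            self.m.setdefault(name, np.zeros_like(params[name]))
            self.v.setdefault(name, np.zeros_like(params[name]))
            t = self.t.get(name, 0) + 1
            self.t[name] = t
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** t)
            vhat = self.v[name] / (1 - self.b2 ** t)
            params[name] = params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Data preparation and training
# ---------------------------------------------------------------------------

def _normalize_volume(values: np.ndarray) -> np.ndarray:
    v = values.astype(_DTYPE)
    return (v - v.mean()) / (v.std() + _DTYPE(1e-6))


def _stack_slices(images, references, assignment, margin: int | None):
    """Flatten training volumes into (slice, subset-id) training samples.

    Slices with an empty reference are kept as negative examples.  With a
    finite ``margin``, only slices within ``margin`` of the organ's slice
    range are used, so the negatives retained are the ones adjacent to the
    organ borders; ``margin=None`` keeps every slice.
    """
    xs, ys, subsets = [], [], []
    for idx, (img, ref) in enumerate(zip(images, references, strict=True)):
        vol = _normalize_volume(img.values)
        if margin is None:
            lo, hi = 0, vol.shape[0] - 1
        else:
            zs = np.flatnonzero(ref.labels.any(axis=(1, 2)))
            lo = max(0, int(zs[0]) - margin)
            hi = min(vol.shape[0] - 1, int(zs[-1]) + margin)
        for z in range(lo, hi + 1):
            xs.append(vol[z])
            ys.append(ref.labels[z].astype(_DTYPE))
            subsets.append(assignment[idx])
    x = np.stack(xs)[:, None]
    y = np.stack(ys)[:, None]
    return x, y, np.asarray(subsets)


def _check_grid(shape):
    if shape[1] % 4 or shape[2] % 4:
        raise ValueError("in-plane shape must be divisible by 4")


def train_step(model: TrainedModel, opt: _Adam, xb, yb, sb) -> float:
    """One optimization step on a mini-batch that may mix subsets.

    The encoder runs once on the whole batch; each sample's loss is routed
    to the decoder of its subset and the per-decoder feature gradients are
    scattered back before a single encoder backward pass.  Decoders with no
    samples in the batch receive no gradient and no optimizer update.
    """
    params = model.params
    cache = _encoder_forward(params, xb)
    grads: dict[str, np.ndarray] = {}
    da3 = np.zeros_like(cache["a3"])
    da2 = np.zeros_like(cache["a2"])
    da1 = np.zeros_like(cache["a1"])
    total, nsamp = 0.0, xb.shape[0]
    for k in np.unique(sb):
        sel = np.flatnonzero(sb == k)
        sub_cache = {key: cache[key][sel] for key in ("a1", "a2", "a3")}
        prob, dcache = _decoder_forward(params, int(k), sub_cache)
        loss, dlogits = _loss_and_grad(prob, yb[sel])
        total += loss * len(sel)
        # rescale: _loss_and_grad averages over the subset, but the batch
        # loss averages over all samples
        dlogits = dlogits * (len(sel) / nsamp)
        g3, g2, g1 = _decoder_backward(params, int(k), sub_cache, dcache,
                                       dlogits, grads)
        da3[sel] += g3
        da2[sel] += g2
        da1[sel] += g1
    _encoder_backward(params, cache, da3, da2, da1, grads)
    opt.step(params, grads)
    return total / nsamp


def train_dvas(images, references, assignment, cfg: ModelConfig) -> TrainedModel:
    """Train the multi-decoder model on a partitioned training cohort.

    ``assignment`` maps each training scan to a subset 0..K-1; every subset
    must be nonempty.  The encoder is trained on all slices; decoder k only
    on slices from subset-k scans.  Deterministic given ``cfg.seed``.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(images):
        raise PartitionError("assignment length must equal the number of scans")
    present = set(np.unique(assignment).tolist())
    if present != set(range(cfg.n_decoders)):
        raise PartitionError(
            f"every subset 0..{cfg.n_decoders - 1} must be nonempty; "
            f"got subsets {sorted(present)}")
    _check_grid(images[0].shape)
    x, y, subsets = _stack_slices(images, references, assignment,
                                  cfg.slice_margin)
    model = build_model(cfg)
    model.partition_used = assignment.copy()
    opt = _Adam(cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            losses.append(train_step(model, opt, x[sel], y[sel], subsets[sel]))
        model.training_log.append(float(np.mean(losses)))
    return model


def train_classical(images, references, cfg: ModelConfig) -> TrainedModel:
    """Train the single-decoder baseline on all scans."""
    if cfg.n_decoders != 1:
        cfg = replace(cfg, n_decoders=1)
    return train_dvas(images, references, np.zeros(len(images), dtype=int), cfg)


def predict_variants(model: TrainedModel, image: VolumeImage) -> VariantSet:
    """Segment one volume: K probability maps, thresholded into binary masks.

    Slices are processed independently and restacked along the transversal
    axis; deterministic.
    """
    _check_grid(image.shape)
    x = _normalize_volume(image.values)[:, None]
    cache = _encoder_forward(model.params, x)
    variants = []
    for k in range(model.config.n_decoders):
        prob, _ = _decoder_forward(model.params, k, cache)
        labels = (prob[:, 0] >= model.config.threshold).astype(np.uint8)
        variants.append(BinaryMask(labels, image.spacing))
    return VariantSet(tuple(variants))
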