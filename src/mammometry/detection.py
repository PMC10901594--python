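"""Automatic landmark localization by heatmap regression.

The detector predicts one heatmap per landmark (30 channels) on a
stride-4 grid over the standardized input image and reads each
location off as a sub-pixel center of mass around the heatmap peak.
Training minimizes mean squared error against Gaussian target
heatmaps; forward pass, backpropagation and Adam updates are written
out directly on numpy arrays.

Three backbones are available:

* ``"conv"`` (default) — a matched-filter head: one learned
  convolution kernel per landmark, evaluated on the full-resolution
  image at every heatmap grid position, plus a learned per-landmark
  spatial prior map.  The kernel picks up the landmark's local
  appearance (nipple disk, contour edge orientation) and the prior
  resolves between look-alike locations (e.g. the two nipples).
* ``"mlp"`` — one hidden leaky-ReLU layer over the whole image.
* ``"dense"`` — two hidden blocks with their outputs concatenated
  (densely connected) before the heatmap head.

Decoded peak positions are then sharpened by a cascade of local
offset regressors (ridge regression from two-scale patch appearance
to the residual displacement, later stages trained on smaller
perturbations) — the classical supervised-descent refinement that
brings feature-bearing landmarks to sub-pixel accuracy.

Everything is seeded, so training twice with the same configuration
and data yields bit-identical weights.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .model import ROLE_ORDER, AffineTransform2D, ImageRecord, LandmarkPoint, LandmarkSet
from .preprocess import apply_transform, correct_ratio, normalize_8bit, standardize_size

N_LANDMARKS = len(ROLE_ORDER)

_LEAKY_SLOPE = 0.01


def _leaky(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, _LEAKY_SLOPE * z)


def _leaky_grad(activation: np.ndarray) -> np.ndarray:
    return np.where(activation > 0, 1.0, _LEAKY_SLOPE)


@dataclass(frozen=True)
class DetectorConfig:
    input_size: int = 128
    backbone: str = "conv"  # "conv", "mlp" or "dense"
    heatmap_stride: int = 4
    heatmap_sigma: float = 1.0  # in heatmap cells
    kernel_size: int = 17  # conv backbone receptive field, input px (odd)
    hidden: int = 256  # fully-connected backbones
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 3e-3
    refine_stage_sigmas: tuple = (2.5, 0.8)  # cascade stages; () disables
    refine_perturbs: int = 4  # training starts sampled per stage and landmark
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be a multiple of 32, got {self.input_size}")
        if self.heatmap_sigma <= 0:
            raise ValueError("heatmap_sigma must be positive")
        if self.backbone not in ("conv", "mlp", "dense"):
            raise ValueError(f"unknown backbone: {self.backbone}")
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ValueError("kernel_size must be odd and >= 3")

    @property
    def heatmap_size(self) -> int:
        return self.input_size // self.heatmap_stride


def split_dataset(items, fraction: float, seed: int):
    """Deterministic seeded shuffle split into (train, validation)."""
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fraction * n))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def preprocess_for_detector(image: ImageRecord, cfg: DetectorConfig):
    """Square letterbox + resize to input_size + 8-bit normalization.

    Returns (ImageRecord, source->input AffineTransform2D).
    """
    r1 = correct_ratio(image, 1.0)
    r2 = standardize_size(r1.image, cfg.input_size)
    final = normalize_8bit(r2.image)
    return final, r2.transform.compose(r1.transform)


def _standardized_plane(image: ImageRecord) -> np.ndarray:
    """Z-scored grayscale plane in [roughly] unit variance."""
    px = image.pixels
    if px.ndim == 3:
        px = px.mean(axis=2)
    x = px.astype(np.float32) / 255.0
    x = x - x.mean()
    sd = x.std()
    if sd > 1e-6:
        x = x / sd
    return x


def _to_feature(image: ImageRecord, cfg: DetectorConfig) -> np.ndarray:
    """Backbone input: patch matrix for conv, flat plane for mlp/dense."""
    plane = _standardized_plane(image)
    if cfg.backbone != "conv":
        return plane.ravel()
    k = cfg.kernel_size
    half = k // 2
    stride = cfg.heatmap_stride
    hm = cfg.heatmap_size
    # patch centered (up to the half-px grid offset, absorbed by the learned
    # kernel) on each heatmap cell's position in input pixels
    pad = np.pad(plane, half, mode="constant")
    win = np.lib.stride_tricks.sliding_window_view(pad, (k, k))
    centers = np.arange(hm) * stride + stride // 2
    patches = win[np.ix_(centers, centers)].reshape(hm * hm, k * k)
    # intensity and squared-intensity channels: the quadratic term lets the
    # head respond to local brightness structure (nipple disk, shading peak)
    # rather than only signed contrast
    return np.concatenate([patches, patches ** 2], axis=1).astype(np.float32)


def _refine_feature(plane: np.ndarray, x: float, y: float, k: int):
    """Two-scale local appearance at (x, y) for the refinement cascade.

    A fine k x k patch plus a 3k x 3k context window average-pooled to
    k x k, each with its squared channel.  The wide window gives
    low-texture landmarks (sternal notch, umbilicus) the body outline
    as context.  Returns (features, snapped integer position).
    """
    half = k // 2
    xi = min(max(int(round(x)), 0), plane.shape[1] - 1)
    yi = min(max(int(round(y)), 0), plane.shape[0] - 1)
    margin = 3 * half + 1
    pad = np.pad(plane, margin, mode="constant")
    cx, cy = xi + margin, yi + margin
    fine = pad[cy - half:cy + half + 1, cx - half:cx + half + 1]
    wide = pad[cy - 3 * half - 1:cy + 3 * half + 2, cx - 3 * half - 1:cx + 3 * half + 2]
    coarse = wide[:3 * k, :3 * k].reshape(k, 3, k, 3).mean(axis=(1, 3))
    f = np.concatenate([fine.ravel(), fine.ravel() ** 2,
                        coarse.ravel(), coarse.ravel() ** 2])
    return f.astype(np.float32), xi, yi


def _fit_refinement(planes, truths, cfg: DetectorConfig, rng) -> list:
    """Per-stage, per-landmark ridge regressors for offset refinement.

    Classical cascade: from the local appearance at a perturbed start
    position, regress the offset to the true landmark; later stages are
    trained on smaller perturbations.
    """
    k = cfg.kernel_size
    stages = []
    for sigma in cfg.refine_stage_sigmas:
        phi = [[] for _ in range(N_LANDMARKS)]
        tgt = [[] for _ in range(N_LANDMARKS)]
        for plane, truth in zip(planes, truths):
            starts = truth[None] + rng.normal(0.0, sigma, (cfg.refine_perturbs, N_LANDMARKS, 2))
            for p in starts:
                for l in range(N_LANDMARKS):
                    f, xi, yi = _refine_feature(plane, p[l, 0], p[l, 1], k)
                    phi[l].append(f)
                    tgt[l].append(truth[l] - [xi, yi])
        regs = []
        for l in range(N_LANDMARKS):
            X = np.column_stack([np.array(phi[l]), np.ones(len(phi[l]), dtype=np.float32)])
            Y = np.array(tgt[l], dtype=np.float64)
            G = (X.T @ X).astype(np.float64)
            lam = 1e-3 * np.trace(G) / G.shape[0]
            regs.append(np.linalg.solve(G + lam * np.eye(G.shape[0]),
                                        X.T.astype(np.float64) @ Y).astype(np.float32))
        stages.append(np.stack(regs))  # (30, f+1, 2)
    return stages


def _apply_refinement(plane: np.ndarray, coords: np.ndarray, stages, cfg: DetectorConfig):
    out = coords.copy()
    k = cfg.kernel_size
    for regs in stages:
        for l in range(N_LANDMARKS):
            f, xi, yi = _refine_feature(plane, out[l, 0], out[l, 1], k)
            delta = np.concatenate([f, [1.0]]) @ regs[l]
            delta = np.clip(delta, -4.0, 4.0)
            out[l] = [xi + delta[0], yi + delta[1]]
    return out


def _target_heatmaps(landmarks: LandmarkSet, cfg: DetectorConfig) -> np.ndarray:
    """(30, hm, hm) Gaussian targets, peak 1, in heatmap-cell coordinates."""
    hm = cfg.heatmap_size
    grid = np.arange(hm, dtype=np.float32)
    out = np.zeros((N_LANDMARKS, hm, hm), dtype=np.float32)
    half = (cfg.heatmap_stride - 1) / 2.0
    for i, role in enumerate(ROLE_ORDER):
        x, y = landmarks.xy(role)
        hx = (x - half) / cfg.heatmap_stride
        hy = (y - half) / cfg.heatmap_stride
        gx = np.exp(-((grid - hx) ** 2) / (2 * cfg.heatmap_sigma ** 2))
        gy = np.exp(-((grid - hy) ** 2) / (2 * cfg.heatmap_sigma ** 2))
        out[i] = gy[:, None] * gx[None, :]
    return out


class LandmarkDetector:
    """Trained heatmap-regression model plus its configuration."""

    FORMAT_VERSION = 1

    def __init__(self, cfg: DetectorConfig, weights: dict, history: list | None = None):
        self.cfg = cfg
        self.weights = weights
        self.history = list(history or [])

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, want_grads: bool = False):
        w = self.weights
        if self.cfg.backbone == "conv":
            # x: (batch, cells, k*k); response per cell and landmark plus prior
            resp = np.einsum("bcf,fl->bcl", x, w["K"])
            y = resp.transpose(0, 2, 1).reshape(x.shape[0], -1) + w["B"]
            cache = (x,)
        else:
            h1 = _leaky(x @ w["W1"] + w["b1"])
            if self.cfg.backbone == "dense":
                h2 = _leaky(h1 @ w["W1b"] + w["b1b"])
                h = np.concatenate([h1, h2], axis=-1)
            else:
                h2, h = None, h1
            y = h @ w["W2"] + w["b2"]
            cache = (x, h1, h2, h)
        if want_grads:
            return y, cache
        return y

    def _backward(self, d_out: np.ndarray, cache) -> dict:
        w, cfg = self.weights, self.cfg
        g = {}
        if cfg.backbone == "conv":
            (x,) = cache
            cells = cfg.heatmap_size ** 2
            e = d_out.reshape(len(d_out), N_LANDMARKS, cells).transpose(0, 2, 1)
            g["K"] = np.einsum("bcf,bcl->fl", x, e)
            g["B"] = d_out.sum(axis=0)
            return g
        x_in, h1, h2, h = cache
        g["W2"] = h.T @ d_out
        g["b2"] = d_out.sum(axis=0)
        dh = d_out @ w["W2"].T
        if cfg.backbone == "dense":
            dh1, dh2 = dh[:, :cfg.hidden], dh[:, cfg.hidden:]
            dh2 = dh2 * _leaky_grad(h2)
            g["W1b"] = h1.T @ dh2
            g["b1b"] = dh2.sum(axis=0)
            dh1 = dh1 + dh2 @ w["W1b"].T
        else:
            dh1 = dh
        dh1 = dh1 * _leaky_grad(h1)
        g["W1"] = x_in.T @ dh1
        g["b1"] = dh1.sum(axis=0)
        return g

    def predict_heatmaps(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == (2 if self.cfg.backbone == "conv" else 1):
            x = x[None]
        y = self._forward(x)
        hm = self.cfg.heatmap_size
        return y.reshape(-1, N_LANDMARKS, hm, hm)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps({"format": self.FORMAT_VERSION, "config": asdict(self.cfg),
                           "history": self.history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.weights)

    @classmethod
    def load(cls, path) -> "LandmarkDetector":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        conf = meta["config"]
        conf["refine_stage_sigmas"] = tuple(conf.get("refine_stage_sigmas", ()))
        return cls(DetectorConfig(**conf), weights, meta.get("history"))

    def weights_digest(self) -> str:
        buf = _io.BytesIO()
        for k in sorted(self.weights):
            buf.write(k.encode())
            buf.write(np.ascontiguousarray(self.weights[k]).tobytes())
        return hashlib.sha256(buf.getvalue()).hexdigest()


def _init_weights(cfg: DetectorConfig, rng: np.random.Generator) -> dict:
    d_out = N_LANDMARKS * cfg.heatmap_size ** 2
    if cfg.backbone == "conv":
        # kernels start at zero and the prior (set to the mean target in
        # train_detector) carries the initial prediction, so every gradient
        # step works on input-dependent structure
        return {"K": np.zeros((2 * cfg.kernel_size ** 2, N_LANDMARKS), dtype=np.float32),
                "B": np.zeros(d_out, dtype=np.float32)}
    d_in = cfg.input_size * cfg.input_size
    hid = cfg.hidden

    def he(fan_in, shape):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    w = {"W1": he(d_in, (d_in, hid)), "b1": np.zeros(hid, dtype=np.float32)}
    head_in = hid
    if cfg.backbone == "dense":
        w["W1b"] = he(hid, (hid, hid))
        w["b1b"] = np.zeros(hid, dtype=np.float32)
        head_in = 2 * hid
    w["W2"] = np.zeros((head_in, d_out), dtype=np.float32)
    w["b2"] = np.zeros(d_out, dtype=np.float32)
    return w


def train_detector(dataset, cfg: DetectorConfig | None = None) -> LandmarkDetector:
    """Train on (ImageRecord, LandmarkSet) pairs (TorsoSamples accepted).

    Images are standardized through the preprocessing pipeline and the
    landmark coordinates moved through the recorded transform; targets
    are per-landmark Gaussian heatmaps and the loss is their mean
    squared error.  Per-epoch training loss is recorded in
    ``detector.history``.
    """
    cfg = cfg or DetectorConfig()
    feats, targets, planes, truths = [], [], [], []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "truth"):
            image, marks = item.image, item.truth
        else:
            image, marks = item
        proc, t = preprocess_for_detector(image, cfg)
        moved = apply_transform(marks, t, out_size=(cfg.input_size, cfg.input_size))
        feats.append(_to_feature(proc, cfg))
        targets.append(_target_heatmaps(moved, cfg).ravel())
        planes.append(_standardized_plane(proc))
        truths.append(moved.as_array())
    if not feats:
        raise ValueError("empty training dataset")

    X = np.stack(feats).astype(np.float32)
    Y = np.stack(targets).astype(np.float32)

    whiten = None
    if cfg.backbone == "conv":
        # patch pixels are strongly correlated, which makes the least-squares
        # landscape badly conditioned; whiten the patch features so the
        # optimizer converges in a handful of epochs, and fold the whitening
        # back into the stored kernels afterwards
        flat = X.reshape(-1, X.shape[-1]).astype(np.float64)
        mu = flat.mean(axis=0)
        cov = (flat.T @ flat) / len(flat) - np.outer(mu, mu)
        lam = 1e-3 * np.trace(cov) / cov.shape[0]
        evals, evecs = np.linalg.eigh(cov + lam * np.eye(cov.shape[0]))
        wmat = (evecs / np.sqrt(evals)) @ evecs.T
        whiten = (mu.astype(np.float32), wmat.astype(np.float32))
        X = (X - whiten[0]) @ whiten[1]

    rng = np.random.default_rng(cfg.seed)
    model = LandmarkDetector(cfg, _init_weights(cfg, rng))
    w = model.weights
    # the additive prior/bias starts at the mean target, i.e. the model
    # begins as the cohort-mean predictor
    w["B" if cfg.backbone == "conv" else "b2"] = Y.mean(axis=0).astype(np.float32)

    adam_m = {k: np.zeros_like(v) for k, v in w.items()}
    adam_v = {k: np.zeros_like(v) for k, v in w.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(X)

    # history[0] is the loss of the initial (cohort-mean) predictor, so the
    # recorded curve shows the progress training makes beyond that baseline
    init_loss = 0.0
    for start in range(0, n, cfg.batch_size):
        xb, yb = X[start:start + cfg.batch_size], Y[start:start + cfg.batch_size]
        init_loss += float(np.mean((model._forward(xb) - yb) ** 2)) * len(xb)
    model.history.append(init_loss / n)

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            pred, cache = model._forward(xb, want_grads=True)
            err = pred - yb
            epoch_loss += float(np.mean(err ** 2)) * len(idx)
            g = model._backward(2.0 * err / err.size, cache)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for k in w:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g[k] ** 2
                w[k] -= (lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)).astype(np.float32)
        model.history.append(epoch_loss / n)

    if whiten is not None:
        # convert kernels back to raw-patch space: y = ((p - mu) W) K + B
        mu, wmat = whiten
        k_raw = (wmat @ w["K"]).astype(np.float32)
        offset = mu @ k_raw  # one scalar per landmark
        cells = cfg.heatmap_size ** 2
        w["K"] = k_raw
        w["B"] = (w["B"].reshape(N_LANDMARKS, cells) - offset[:, None]).ravel().astype(np.float32)

    for i, regs in enumerate(_fit_refinement(planes, truths, cfg, rng)):
        w[f"R{i}"] = regs
    return model


@dataclass(frozen=True)
class DetectionResult:
    landmarks: LandmarkSet
    confidence: dict = field(default_factory=dict)  # role -> [0, 1]


def _decode_heatmap(hm: np.ndarray, cfg: DetectorConfig):
    """Sub-pixel peak: center of mass over a 5x5 window around the argmax."""
    size = cfg.heatmap_size
    flat = int(np.argmax(hm))
    py, px = divmod(flat, size)
    y0, y1 = max(0, py - 2), min(size, py + 3)
    x0, x1 = max(0, px - 2), min(size, px + 3)
    win = np.clip(hm[y0:y1, x0:x1], 0.0, None)
    total = win.sum()
    if total <= 0:
        hx, hy = float(px), float(py)
    else:
        ys, xs = np.mgrid[y0:y1, x0:x1]
        hx = float((xs * win).sum() / total)
        hy = float((ys * win).sum() / total)
    half = (cfg.heatmap_stride - 1) / 2.0
    conf = float(np.clip(hm[py, px], 0.0, 1.0))
    return hx * cfg.heatmap_stride + half, hy * cfg.heatmap_stride + half, conf


def detect(model: LandmarkDetector, image: ImageRecord,
           transform: AffineTransform2D | None = None) -> DetectionResult:
    """Locate all 30 landmarks in source-image coordinates.

    ``image`` may be raw (it is then standardized internally) or
    already standardized to ``cfg.input_size`` with its source->input
    ``transform`` supplied; anything else is a size mismatch.
    """
    cfg = model.cfg
    if image.width == cfg.input_size and image.height == cfg.input_size:
        proc = normalize_8bit(image)
        t = transform or AffineTransform2D.identity()
    elif transform is not None:
        raise ValueError(
            f"image size {image.width}x{image.height} does not match "
            f"detector input {cfg.input_size}")
    else:
        proc, t = preprocess_for_detector(image, cfg)

    heatmaps = model.predict_heatmaps(_to_feature(proc, cfg))[0]
    coords = np.empty((N_LANDMARKS, 2))
    confidence = {}
    for i, role in enumerate(ROLE_ORDER):
        x, y, conf = _decode_heatmap(heatmaps[i], cfg)
        coords[i] = (x, y)
        confidence[role] = conf

    stages = [model.weights[f"R{i}"] for i in range(len(cfg.refine_stage_sigmas))
              if f"R{i}" in model.weights]
    if stages:
        coords = _apply_refinement(_standardized_plane(proc), coords, stages, cfg)
    coords = t.inverse().apply(coords)

    points = [LandmarkPoint(role, float(coords[i, 0]), float(coords[i, 1]))
              for i, role in enumerate(ROLE_ORDER)]
    lset = LandmarkSet(points, metadata={"detector": "heatmap", "backbone": cfg.backbone})
    return DetectionResult(landmarks=lset, confidence=confidence)


def mean_radial_error(detected: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean Euclidean distance over the 30 landmark pairs, in px."""
    return float(np.linalg.norm(detected.as_array() - truth.as_array(), axis=1).mean())
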