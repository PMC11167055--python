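"""Stage 1: per-sub-skill clip encoding and independent skill prediction.

Each sub-skill clip is mapped to a fixed-dimension feature vector (128 by
default) and an independent probability of ideal performance — the
"independent" arm of every comparison.  Two encoder paths exist:

* ``small_conv_stub`` — a random-feature convolutional encoder: a bank of
  fixed, seeded random filters over appearance frames (and, optionally,
  dense optical-flow fields between consecutive frames), ReLU, global
  average pooling, exponential-decay temporal pooling over the frame
  sequence, then a fixed random projection to ``feature_dim``.  Only the
  logistic classification head on top is trained.  This runs from raw frame
  arrays on one CPU in seconds and is the default for tests.
* precomputed features — when clips carry no media, stage 1 trains its head
  directly on an externally supplied / synthetic feature store.  This is the
  primary pipeline path.

Training minimizes the binary cross-entropy with Adam (learning rate 1e-3,
50 epochs by default) and is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import optical_flow_ilk
from skimage.transform import resize

from .datamodel import Cohort, FeatureStore, SubSkill, SUBSKILL_ORDER

__all__ = [
    "Stage1Config",
    "Stage1Model",
    "compute_flow",
    "extract_clip_feature",
    "train_stage1",
    "train_all_stage1",
    "predict_independent",
    "UntrainedModelError",
]


class UntrainedModelError(RuntimeError):
    pass


@dataclass
class Stage1Config:
    frame_size: int = 224
    backbone: str = "small_conv_stub"   # or "pretrained_imagenet_cnn" (unavailable offline)
    feature_dim: int = 128
    use_flow: bool = True
    n_filters: int = 8
    kernel: int = 5
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim <= 0 or self.frame_size <= 0:
            raise ValueError("feature_dim and frame_size must be positive")


@dataclass
class Stage1Model:
    subskill: SubSkill
    config: Stage1Config
    filters: np.ndarray | None = None       # (n_filters, k, k) fixed random bank
    flow_filters: np.ndarray | None = None  # (n_filters, k, k, 2)
    projection: np.ndarray | None = None    # (raw_dim, feature_dim) fixed random
    # trained head
    w: np.ndarray | None = None
    b: float = 0.0
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    loss_history: list = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return self.w is not None


# ---------------------------------------------------------------------------
# Optical flow
# ---------------------------------------------------------------------------


def compute_flow(frames: np.ndarray) -> np.ndarray:
    """Dense displacement field between consecutive frames.

    ``frames`` is (T, H, W) or (T, H, W, C); returns (T-1, 2, H, W) with
    channel 0 = row displacement, channel 1 = column displacement of frame
    t+1's content relative to frame t.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 4:
        frames = frames.mean(axis=-1)
    if frames.ndim != 3:
        raise ValueError(f"expected (T, H, W[, C]) clip, got shape {frames.shape}")
    if frames.shape[0] < 2:
        raise ValueError("optical flow needs at least two frames")
    out = []
    for t in range(frames.shape[0] - 1):
        # registration flow from frame t to t+1 equals the displacement of
        # scene content over that step
        out.append(optical_flow_ilk(frames[t], frames[t + 1]))
    return np.stack(out)


# ---------------------------------------------------------------------------
# Random-feature conv stub
# ---------------------------------------------------------------------------


def _init_backbone(model: Stage1Model) -> None:
    cfg = model.config
    rng = np.random.default_rng((cfg.seed, model.subskill.index, 17))
    k = cfg.kernel
    model.filters = rng.normal(0, 1.0 / k, size=(cfg.n_filters, k, k))
    model.flow_filters = rng.normal(0, 1.0 / k, size=(cfg.n_filters, k, k, 2))
    raw_dim = cfg.n_filters * (2 if cfg.use_flow else 1)
    model.projection = rng.normal(0, 1.0 / np.sqrt(raw_dim), size=(raw_dim, cfg.feature_dim))


def _conv_pool(img: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid 2-D correlation with each filter, ReLU, global average pool."""
    from scipy.signal import fftconvolve

    feats = []
    for f in filters:
        r = fftconvolve(img, f[::-1, ::-1], mode="valid")
        feats.append(np.maximum(r, 0).mean())
    return np.array(feats)


def _preprocess(frames: np.ndarray, size: int) -> np.ndarray:
    """Channel-collapse, center crop / resize to ``size`` and normalize."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 4:
        frames = frames.mean(axis=-1)
    T, H, W = frames.shape
    if (H, W) != (size, size):
        if H >= size and W >= size:
            top, left = (H - size) // 2, (W - size) // 2
            frames = frames[:, top:top + size, left:left + size]
        else:
            frames = np.stack([resize(f, (size, size), anti_aliasing=True) for f in frames])
    mu, sd = frames.mean(), frames.std()
    return (frames - mu) / (sd if sd > 0 else 1.0)


def extract_clip_feature(
    model: Stage1Model, clip: np.ndarray, flow: np.ndarray | None = None
) -> np.ndarray:
    """Encode one clip to a ``feature_dim`` vector; deterministic."""
    cfg = model.config
    if model.filters is None:
        _init_backbone(model)
    frames = _preprocess(clip, min(cfg.frame_size, np.asarray(clip).shape[1]))
    per_frame = np.stack([_conv_pool(f, model.filters) for f in frames])
    if cfg.use_flow:
        if flow is None:
            flow = compute_flow(frames)
        flow_feats = np.stack(
            [
                sum(_conv_pool(fl[c], model.flow_filters[:, :, :, c]) for c in range(2))
                for fl in flow
            ]
        )
        # flow sequence is one shorter; repeat the last field
        flow_feats = np.vstack([flow_feats, flow_feats[-1:]])
        per_frame = np.hstack([per_frame, flow_feats])
    # exponential-decay temporal pooling (most recent frames weighted up)
    T = per_frame.shape[0]
    wts = np.exp(np.linspace(-1.0, 0.0, T))
    pooled = (per_frame * wts[:, None]).sum(axis=0) / wts.sum()
    vec = pooled @ model.projection
    if vec.shape[0] != cfg.feature_dim:
        raise ValueError("projection dimension mismatch")
    return vec


# ---------------------------------------------------------------------------
# Head training (logistic, Adam)
# ---------------------------------------------------------------------------


def _train_logistic(
    X: np.ndarray, y: np.ndarray, lr: float, epochs: int, batch_size: int, seed: int
) -> tuple[np.ndarray, float, list]:
    rng = np.random.default_rng(seed)
    n, d = X.shape
    w, b = np.zeros(d), 0.0
    m = np.zeros(d + 1)
    v = np.zeros(d + 1)
    t = 0
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            z = X[idx] @ w + b
            p = 1.0 / (1.0 + np.exp(-z))
            eps = 1e-12
            loss = -np.mean(y[idx] * np.log(p + eps) + (1 - y[idx]) * np.log(1 - p + eps))
            g = (p - y[idx]) / len(idx)
            grad = np.concatenate([X[idx].T @ g, [g.sum()]])
            t += 1
            m = 0.9 * m + 0.1 * grad
            v = 0.999 * v + 0.001 * grad * grad
            mhat, vhat = m / (1 - 0.9**t), v / (1 - 0.999**t)
            upd = lr * mhat / (np.sqrt(vhat) + 1e-8)
            w -= upd[:-1]
            b -= upd[-1]
            epoch_loss += loss * len(idx)
        history.append({"epoch": epoch, "loss": epoch_loss / n})
    return w, b, history


def train_stage1(
    cohort: Cohort,
    subskill: SubSkill,
    config: Stage1Config,
    features: FeatureStore | None = None,
) -> tuple[Stage1Model, FeatureStore, np.ndarray]:
    """Train the independent model for one sub-skill.

    When ``features`` is given (or clips carry no media) the head is trained
    on those vectors; otherwise clip features are extracted with the conv
    stub first.  Returns the model, the feature store consumed by stage 2,
    and the per-stitch training probabilities.
    """
    model = Stage1Model(subskill=subskill, config=config)
    if features is None:
        if any(r.clips[subskill].media_path is None for r in cohort.records):
            raise ValueError(
                "no feature store given and clips carry no media; supply "
                "precomputed features"
            )
        features = FeatureStore(encoder_id="small_conv_stub", dim=config.feature_dim)
        for r in cohort.records:
            clip_arr = np.load(r.clips[subskill].media_path)
            features.put(r.stitch_id, subskill, extract_clip_feature(model, clip_arr))
    X = np.stack([features.get(r.stitch_id, subskill) for r in cohort.records])
    y = np.array([r.labels[subskill] for r in cohort.records], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"training split has a single class for {subskill.code}")
    model.scaler_mean = X.mean(axis=0)
    model.scaler_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - model.scaler_mean) / model.scaler_std
    model.w, model.b, model.loss_history = _train_logistic(
        Xs, y, config.learning_rate, config.epochs, config.batch_size,
        seed=(config.seed * 6 + subskill.index) % (2**31),
    )
    probs = predict_independent(model, features_matrix=X)
    return model, features, probs


def train_all_stage1(
    cohort: Cohort, config: Stage1Config, features: FeatureStore
) -> dict[SubSkill, Stage1Model]:
    return {
        s: train_stage1(cohort, s, config, features)[0] for s in SUBSKILL_ORDER
    }


def predict_independent(
    model: Stage1Model,
    clip: np.ndarray | None = None,
    flow: np.ndarray | None = None,
    features_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Probability of ideal performance from the independent model."""
    if not model.trained:
        raise UntrainedModelError("stage-1 model has not been trained")
    if features_matrix is None:
        if clip is None:
            raise ValueError("supply a clip or a feature matrix")
        features_matrix = extract_clip_feature(model, clip, flow)[None]
    X = (np.atleast_2d(features_matrix) - model.scaler_mean) / model.scaler_std
    return 1.0 / (1.0 + np.exp(-(X @ model.w + model.b)))
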