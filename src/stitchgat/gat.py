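"""Joint skill assessment over the prior sub-skill relationship graph.

Six sub-skills form the nodes of a small fixed graph whose edges encode
previously established associations between suturing sub-phases (hold ratio
to hold angle, hold angle to driving smoothness, hold angle to wrist
rotation).  Each node's input is the stage-1 clip feature concatenated with
the flattened, aligned kinematic sequence.  A single masked graph-attention
layer lets every node aggregate information from its graph neighbours (and
itself) with learned, softmax-normalized weights; six node-specific linear
heads then classify ideal vs non-ideal performance, trained with the sum of
the six cross-entropies.

The layer follows the standard single-head GAT formulation: a shared linear
map ``W``, an attention scorer on concatenated pairs ``[W h_i || W h_j]``
(one hidden layer, LeakyReLU slope 0.2 before the softmax), masked softmax
restricted to the prior graph's allowed entries, ELU after aggregation, a
shared output projection, and per-node heads.  Ablation switches reproduce
the "attention strength fixed to one" variant (unnormalized sum over allowed
neighbours) and the video-only variant (kinematics block zeroed).

The model is small enough (six nodes, one layer) that forward and backward
passes are written directly in NumPy; gradients are finite-difference
checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import SUBSKILL_ORDER, SubSkill

__all__ = [
    "DEFAULT_PAIRS",
    "PriorGraph",
    "build_prior_graph",
    "masked_attention",
    "JointConfig",
    "JointModelParams",
    "init_params",
    "gat_forward",
    "joint_loss",
    "train_stage2",
    "predict_joint",
    "extract_attention",
    "isolated_node_forward",
]

#: The three prior pairs: hold ratio-hold angle, hold angle-driving
#: smoothness, hold angle-wrist rotation.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("HR", "HA"), ("HA", "DS"), ("HA", "WR"))

N_NODES = 6


# ---------------------------------------------------------------------------
# Prior graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorGraph:
    edges: frozenset[frozenset[SubSkill]]
    adjacency: np.ndarray  # (6, 6) int, symmetric, unit diagonal

    @property
    def nodes(self) -> tuple[SubSkill, ...]:
        return SUBSKILL_ORDER

    def neighbors(self, s: SubSkill) -> list[SubSkill]:
        i = s.index
        return [t for t in SUBSKILL_ORDER if t is not s and self.adjacency[i, t.index]]


def build_prior_graph(
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> PriorGraph:
    """Symmetric 6x6 adjacency with self-loops from named sub-skill pairs."""
    adjacency = np.eye(N_NODES, dtype=int)
    edges: set[frozenset[SubSkill]] = set()
    for a, b in pairs:
        sa, sb = SubSkill.from_code(a), SubSkill.from_code(b)
        if sa is sb:
            raise ValueError(f"self-pair {a!r} not allowed (self-loops are implicit)")
        e = frozenset((sa, sb))
        if e in edges:
            warnings.warn(f"duplicate prior pair {a}-{b} ignored", stacklevel=2)
            continue
        edges.add(e)
        adjacency[sa.index, sb.index] = 1
        adjacency[sb.index, sa.index] = 1
    return PriorGraph(edges=frozenset(edges), adjacency=adjacency)


def masked_attention(scores: np.ndarray, graph: PriorGraph) -> np.ndarray:
    """Row-wise softmax of ``scores`` restricted to the graph's allowed
    entries; disallowed entries are exactly zero.

    Accepts (..., 6, 6) score arrays.  Self-loops guarantee every row has at
    least one allowed entry.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("attention scores must be finite")
    mask = graph.adjacency.astype(bool)
    shifted = np.where(mask, scores, -np.inf)
    shifted = shifted - shifted.max(axis=-1, keepdims=True)
    ex = np.where(mask, np.exp(shifted), 0.0)
    return ex / ex.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model definition
# ---------------------------------------------------------------------------


@dataclass
class JointConfig:
    """Stage-2 hyperparameters.

    Defaults mirror the published configuration: 128-dim clip features plus
    24 frames x 70 kinematic scalars (node input 1808), hidden width 1024,
    output width 128, a one-hidden-layer attention scorer of width 1024,
    learning rate 1e-3 and 50 epochs.
    """

    feature_dim: int = 128
    target_len: int = 24
    hidden: int = 1024
    att_hidden: int = 1024
    out_dim: int = 128
    use_attention: bool = True
    use_kinematics: bool = True
    no_attention_aggregation: str = "sum"  # "sum" (weights fixed to one) | "mean"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    leaky_slope: float = 0.2
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return self.feature_dim + 70 * self.target_len


@dataclass
class JointModelParams:
    W: np.ndarray        # (D, H) shared node-wise linear map
    bW: np.ndarray       # (H,)
    A1: np.ndarray       # (2H, Ah) attention scorer hidden layer
    b1: np.ndarray       # (Ah,)
    a2: np.ndarray       # (Ah,) attention scorer output
    b2: float
    Wo: np.ndarray       # (H, O) output projection
    bo: np.ndarray       # (O,)
    heads: np.ndarray    # (6, O, 2) node-specific classifier heads
    head_b: np.ndarray   # (6, 2)
    config: JointConfig = field(default_factory=JointConfig)

    def flat(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in
                ("W", "bW", "A1", "b1", "a2", "b2", "Wo", "bo", "heads", "head_b")}


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def init_params(config: JointConfig, rng: np.random.Generator | None = None) -> JointModelParams:
    rng = rng or np.random.default_rng(config.seed)
    D, H, Ah, O = config.input_dim, config.hidden, config.att_hidden, config.out_dim
    return JointModelParams(
        W=_glorot(rng, (D, H)),
        bW=np.zeros(H),
        A1=_glorot(rng, (2 * H, Ah)),
        b1=np.zeros(Ah),
        a2=np.zeros(Ah),  # zero scorer output => uniform attention at init
        b2=0.0,
        Wo=_glorot(rng, (H, O)),
        bo=np.zeros(O),
        heads=np.stack([_glorot(rng, (O, 2)) for _ in range(N_NODES)]),
        head_b=np.zeros((N_NODES, 2)),
        config=config,
    )


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))


def gat_forward(
    params: JointModelParams,
    X: np.ndarray,
    graph: PriorGraph,
    return_cache: bool = False,
):
    """Forward pass.

    Parameters
    ----------
    X : (B, 6, D) node inputs in canonical sub-skill order.

    Returns
    -------
    logits : (B, 6, 2), attention : (B, 6, 6), embeddings : (B, 6, O)
    (plus the backward cache when requested).
    """
    cfg = params.config
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != N_NODES or X.shape[2] != params.W.shape[0]:
        raise ValueError(
            f"expected node inputs of shape (B, {N_NODES}, {params.W.shape[0]}), got {X.shape}"
        )
    B = X.shape[0]
    H1 = X @ params.W + params.bW                      # (B, 6, H)

    mask = graph.adjacency.astype(bool)
    if cfg.use_attention:
        # pairwise concatenations [W h_i || W h_j] -> scalar scores
        Hi = np.broadcast_to(H1[:, :, None, :], (B, N_NODES, N_NODES, H1.shape[-1]))
        Hj = np.broadcast_to(H1[:, None, :, :], (B, N_NODES, N_NODES, H1.shape[-1]))
        C = np.concatenate([Hi, Hj], axis=-1)          # (B, 6, 6, 2H)
        S1 = C @ params.A1 + params.b1                 # (B, 6, 6, Ah)
        L = _leaky(S1, cfg.leaky_slope)
        e = L @ params.a2 + params.b2                  # (B, 6, 6)
        alpha = masked_attention(e, graph)
    else:
        weight = 1.0
        if cfg.no_attention_aggregation == "mean":
            weight = 1.0 / graph.adjacency.sum(axis=1, keepdims=True)
        alpha = np.broadcast_to(
            (graph.adjacency * weight).astype(np.float64), (B, N_NODES, N_NODES)
        ).copy()
        C = S1 = L = e = None

    M = np.einsum("bij,bjh->bih", alpha, H1)           # aggregate neighbours
    A_act = _elu(M)
    Z = A_act @ params.Wo + params.bo                  # (B, 6, O)
    logits = np.einsum("bko,koc->bkc", Z, params.heads) + params.head_b

    if not return_cache:
        return logits, alpha, Z
    cache = {"X": X, "H1": H1, "C": C, "S1": S1, "L": L, "alpha": alpha,
             "M": M, "A_act": A_act, "Z": Z, "mask": mask}
    return logits, alpha, Z, cache


def joint_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Sum over the six nodes of the cross-entropy, averaged over the batch."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim == 2:
        logits = logits[None]
    labels = np.asarray(labels, dtype=int)
    if labels.ndim == 1:
        labels = labels[None]
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=-1))
    picked = np.take_along_axis(shifted, labels[..., None], axis=-1)[..., 0]
    return float((logZ - picked).sum(axis=1).mean(axis=0))


def _softmax(logits: np.ndarray) -> np.ndarray:
    s = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(s)
    return ex / ex.sum(axis=-1, keepdims=True)


def gat_backward(
    params: JointModelParams,
    cache: dict,
    labels: np.ndarray,
    logits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of ``joint_loss`` w.r.t. every parameter."""
    cfg = params.config
    X, H1, alpha = cache["X"], cache["H1"], cache["alpha"]
    M, A_act, Z, mask = cache["M"], cache["A_act"], cache["Z"], cache["mask"]
    B = X.shape[0]
    labels = np.asarray(labels, dtype=int).reshape(B, N_NODES)

    probs = _softmax(logits)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    dlogits = (probs - onehot) / B                      # (B, 6, 2)

    g: dict[str, np.ndarray] = {}
    g["heads"] = np.einsum("bko,bkc->koc", Z, dlogits)
    g["head_b"] = dlogits.sum(axis=0)
    dZ = np.einsum("bkc,koc->bko", dlogits, params.heads)
    g["Wo"] = np.einsum("bih,bio->ho", A_act, dZ)
    g["bo"] = dZ.sum(axis=(0, 1))
    dA_act = dZ @ params.Wo.T
    dM = dA_act * np.where(M > 0, 1.0, A_act + 1.0)     # ELU'
    dalpha = np.einsum("bih,bjh->bij", dM, H1)
    dH1 = np.einsum("bij,bih->bjh", alpha, dM)

    if cfg.use_attention:
        C, S1, L = cache["C"], cache["S1"], cache["L"]
        # masked softmax backward, rows over allowed entries only
        inner = (dalpha * alpha).sum(axis=-1, keepdims=True)
        de = alpha * (dalpha - inner)
        de = np.where(mask, de, 0.0)
        g["a2"] = np.einsum("bija,bij->a", L, de)
        g["b2"] = float(de.sum())
        dL = de[..., None] * params.a2
        dS1 = dL * np.where(S1 > 0, 1.0, cfg.leaky_slope)
        g["A1"] = np.einsum("bijd,bija->da", C, dS1)
        g["b1"] = dS1.sum(axis=(0, 1, 2))
        dC = dS1 @ params.A1.T                          # (B, 6, 6, 2H)
        H = H1.shape[-1]
        dH1 += dC[..., :H].sum(axis=2)                  # h_i appears across row i
        dH1 += dC[..., H:].sum(axis=1)                  # h_j appears across column j
    else:
        g["a2"] = np.zeros_like(params.a2)
        g["b2"] = 0.0
        g["A1"] = np.zeros_like(params.A1)
        g["b1"] = np.zeros_like(params.b1)

    g["W"] = np.einsum("bid,bih->dh", X, dH1)
    g["bW"] = dH1.sum(axis=(0, 1))
    return g


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: JointModelParams, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=np.float64))
                  for k, v in params.flat().items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=np.float64))
                  for k, v in params.flat().items()}

    def step(self, params: JointModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gk in grads.items():
            gk = np.asarray(gk, dtype=np.float64)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + eps)
            if np.isscalar(getattr(params, k)) or np.ndim(getattr(params, k)) == 0:
                setattr(params, k, float(getattr(params, k) - upd))
            else:
                getattr(params, k)[...] -= upd


def zero_kinematics_block(X: np.ndarray, config: JointConfig) -> np.ndarray:
    """Video-only ablation: zero the kinematics block of each node input."""
    X = np.array(X, dtype=np.float64, copy=True)
    X[..., config.feature_dim:] = 0.0
    return X


def train_stage2(
    X: np.ndarray,
    Y: np.ndarray,
    graph: PriorGraph,
    config: JointConfig,
    log: list | None = None,
) -> JointModelParams:
    """Train the joint model on frozen stage-1 features plus kinematics.

    ``X`` is (n, 6, input_dim) node inputs, ``Y`` (n, 6) binary labels.
    Stage-1 parameters are never touched (features enter as data).  With
    ``use_kinematics=False`` the kinematics block of each node input is
    zeroed before training.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=int)
    for k in range(N_NODES):
        if len(np.unique(Y[:, k])) < 2:
            raise ValueError(
                f"training split has a single class for {SUBSKILL_ORDER[k].code}"
            )
    if not config.use_kinematics:
        X = zero_kinematics_block(X, config)
    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = _Adam(params, config.learning_rate)
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _, _, cache = gat_forward(params, X[idx], graph, return_cache=True)
            loss = joint_loss(logits, Y[idx])
            grads = gat_backward(params, cache, Y[idx], logits)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        if log is not None:
            log.append({"epoch": epoch, "loss": epoch_loss / n})
    return params


def predict_joint(
    params: JointModelParams, X: np.ndarray, graph: PriorGraph
) -> np.ndarray:
    """(n, 6) predicted probability of ideal performance per sub-skill."""
    X = np.asarray(X, dtype=np.float64)
    if not params.config.use_kinematics:
        X = zero_kinematics_block(X, params.config)
    logits, _, _ = gat_forward(params, X, graph)
    return _softmax(logits)[..., 1]


def extract_attention(
    params: JointModelParams, X: np.ndarray, graph: PriorGraph
) -> np.ndarray:
    """Per-stitch attention maps averaged over the dataset (6x6)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[0] == 0:
        raise ValueError("cannot extract attention from an empty dataset")
    if not params.config.use_kinematics:
        X = zero_kinematics_block(X, params.config)
    _, alpha, _ = gat_forward(params, X, graph)
    return alpha.mean(axis=0)


def isolated_node_forward(
    params: JointModelParams, x: np.ndarray, node: int
) -> np.ndarray:
    """Reference single-node network: W -> ELU -> projection -> node head.

    With the identity adjacency and unit attention weights the joint model
    must be function-equivalent to six of these.
    """
    h = np.asarray(x, dtype=np.float64) @ params.W + params.bW
    z = _elu(h) @ params.Wo + params.bo
    return z @ params.heads[node] + params.head_b[node]
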