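"""The multi-view information-fusion network for association prediction.

Architecture
------------
Each of the ``n`` heterogeneous network views is encoded by its own
``L``-layer graph convolutional encoder,

    X^(l+1) = sigma( D^{-1/2} M D^{-1/2} X^(l) W^(l) ),   X^(0) = M,

producing ``n * L`` per-node topology representations of width ``f_topology``.
A learned attention layer scores every representation,

    s_i = q^T tanh(W_a X_i + b_a)   (projected per node, averaged over nodes)
    beta = softmax(s),

and fuses them into one topology embedding ``sum_i beta_i X_i``.  In parallel,
the stacks of raw miRNA and disease similarity matrices are passed through a
one-layer convolutional attribute encoder whose filters span a full matrix
column (height = entity count, width 1, one shared filter per output channel
across the stacked views), yielding ``f_channel``-wide attribute embeddings.
Topology and attribute embeddings are concatenated per entity and scored for
every miRNA-disease pair by a bilinear decoder

    A' = sigmoid(Z_m W_b Z_d^T),

trained end-to-end with full-matrix cross-entropy (known pairs positive, all
other pairs negative) under Adam.

Ablation switches: ``use_topology=False`` drops the GCN branch (attribute-only
variant), ``use_attribute=False`` drops the CNN branch (topology-only
variant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat_cols
from .netbuild import DEGREE_FLOOR, HeteroNetwork
from .similarity import SimilarityMatrix

__all__ = [
    "ModelConfig",
    "MVIFMDA",
    "Adam",
    "normalize_adjacency",
    "gcn_forward",
    "attention_fuse",
    "cnn_encode",
    "concat_embeddings",
    "bilinear_decode",
    "bce_loss",
]

SCORE_CLAMP = 1e-10

_DTYPE = np.float32  # training dtype; full-batch dense model


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults follow the reference setting: two GCN layers, 256-dimensional
    topology and attribute embeddings, learning rate 1e-3.
    """

    n_layers: int = 2          # L, GCN depth per view
    f_topology: int = 256      # width of each GCN layer output
    f_channel: int = 256       # CNN output channels
    lr: float = 1e-3
    epochs: int = 200
    early_stop_patience: int = 0    # 0 disables early stopping
    early_stop_min_delta: float = 1e-4  # relative loss improvement threshold
    activation: str = "relu"   # GCN nonlinearity
    use_topology: bool = True  # False => attribute-only ablation (noTR)
    use_attribute: bool = True  # False => topology-only ablation (noAR)
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one GCN layer")
        if not (self.use_topology or self.use_attribute):
            raise ValueError("at least one of the two branches must be enabled")

    @property
    def embedding_width(self) -> int:
        return (self.f_topology if self.use_topology else 0) + (
            self.f_channel if self.use_attribute else 0
        )

    def to_dict(self) -> dict:
        return asdict(self)


# ------------------------------------------------------------- building blocks


def normalize_adjacency(M: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} M D^{-1/2}.

    Degrees are floored at a tiny constant so isolated nodes stay finite.
    """
    M = np.asarray(M)
    if (M < 0).any():
        raise ValueError("adjacency matrix has negative entries")
    d = np.maximum(M.sum(axis=1), DEGREE_FLOOR)
    inv_sqrt = 1.0 / np.sqrt(d)
    return (inv_sqrt[:, None] * M) * inv_sqrt[None, :]


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    raise ValueError(f"unknown activation {name!r}")


def gcn_forward(
    Ghat: np.ndarray,
    X0: np.ndarray,
    weights: list[Tensor],
    activation: str = "relu",
    GX0: np.ndarray | None = None,
) -> list[Tensor]:
    """Run the layer-wise propagation rule; returns all L layer outputs.

    `Ghat` is the normalized adjacency, `X0` the initial embedding (the view's
    own adjacency matrix by default upstream).  `GX0` optionally supplies the
    precomputed constant product Ghat @ X0 (it does not depend on any
    parameter, so callers training many epochs cache it).
    """
    if GX0 is None:
        GX0 = Ghat @ X0
    G = Tensor(Ghat)
    outs: list[Tensor] = []
    h = _activate(Tensor(GX0) @ weights[0], activation)
    outs.append(h)
    for W in weights[1:]:
        h = _activate(G @ (h @ W), activation)
        outs.append(h)
    return outs


def attention_fuse(
    reps: list[Tensor], Wa: Tensor, ba: Tensor, qa: Tensor
) -> tuple[Tensor, np.ndarray]:
    """Softmax-attention combination of node-embedding matrices.

    Each representation X_i (nodes x f) is scored by projecting every node row
    through tanh(X_i Wa^T + ba) qa and averaging over nodes; the softmax of
    the scores weights the convex combination.  Returns the fused matrix and
    the attention weights beta.
    """
    if not reps:
        raise ValueError("empty topology representation stack")
    scores = [((x @ Wa.T_() + ba).tanh() @ qa).mean() for x in reps]
    smax = max(float(s.data) for s in scores)  # constant shift for stability
    exps = [(s - smax).exp() for s in scores]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    betas = [e / denom for e in exps]
    fused = betas[0] * reps[0]
    for b, x in zip(betas[1:], reps[1:]):
        fused = fused + b * x
    beta_values = np.array([float(b.data) for b in betas])
    return fused, beta_values


def cnn_encode(stack: list[np.ndarray], W: Tensor, B: Tensor) -> Tensor:
    """Full-height width-1 convolution of stacked similarity views.

    Each output channel t applies one filter (height = entity count) to every
    view, sums over views and adds a per-position bias; sliding the width-1
    filter over the columns of an N x N view yields one value per column, so
    channel t of the output is (sum_i S_i)^T @ w_t + b_t and the stacked
    result is N x f_channel.
    """
    n = stack[0].shape[0]
    for s in stack:
        if s.shape != (n, n):
            raise ValueError(f"similarity views must be square: got {s.shape}")
    s_sum_T = np.sum(stack, axis=0, dtype=W.data.dtype).T
    return Tensor(s_sum_T) @ W + B


def concat_embeddings(Z1: Tensor | None, Z2: Tensor | None) -> Tensor:
    """Column-wise concatenation of topology and attribute embeddings.

    Either side may be absent (ablation variants); at least one is required.
    """
    if Z1 is None and Z2 is None:
        raise ValueError("no embeddings to concatenate")
    if Z1 is None:
        return Z2
    if Z2 is None:
        return Z1
    return concat_cols(Z1, Z2)


def bilinear_decode(Zm: Tensor, Zd: Tensor, Wb: Tensor) -> Tensor:
    """Pair scores A'_{ij} = sigmoid(z_m_i W_b z_d_j); shape Nm x Nd."""
    return ((Zm @ Wb) @ Zd.T_()).sigmoid()


def bce_loss(scores: Tensor, A: np.ndarray) -> Tensor:
    """Summed cross-entropy over every miRNA-disease pair.

    Known pairs of (the possibly masked) A are positives; all remaining pairs
    count as negatives.  No normalizer and no negative subsampling: class
    imbalance is part of the objective.  Scores are clamped away from {0, 1}
    before the logarithm.
    """
    A = np.asarray(A, dtype=scores.data.dtype)
    if A.shape != scores.data.shape:
        raise ValueError(f"label shape {A.shape} != score shape {scores.data.shape}")
    if (scores.data <= 0).any() or (scores.data >= 1).any():
        warnings.warn("scores at the {0,1} boundary were clamped before log")
    p = scores.clamp(SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    loss = -((A * p.log()).sum() + ((1.0 - A) * (1.0 - p).log()).sum())
    return loss


# --------------------------------------------------------------------- optimizer


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ------------------------------------------------------------------------ model


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


@dataclass
class _Inputs:
    """Per-dataset constants the forward pass consumes (rebuilt per CV fold)."""

    ghat: list[np.ndarray]
    gx0: list[np.ndarray]          # cached Ghat @ M per view
    mirna_stack: list[np.ndarray]  # P miRNA similarity views
    disease_stack: list[np.ndarray]  # Q disease similarity views
    n_mirna: int
    n_disease: int


class MVIFMDA(object):
    """Multi-view GCN + CNN association predictor with a bilinear decoder."""

    def __init__(self, config: ModelConfig, n_mirna: int, n_disease: int,
                 n_views: int = 4):
        self.config = config
        self.n_mirna = n_mirna
        self.n_disease = n_disease
        self.n_views = n_views
        self.n_nodes = n_mirna + n_disease
        rng = np.random.default_rng(config.seed)
        c = config

        self.gcn_weights: list[list[Tensor]] = []
        if c.use_topology:
            for _ in range(n_views):
                layers = []
                fan_in = self.n_nodes
                for _l in range(c.n_layers):
                    layers.append(Tensor(
                        _glorot(rng, fan_in, c.f_topology, (fan_in, c.f_topology)),
                        requires_grad=True))
                    fan_in = c.f_topology
                self.gcn_weights.append(layers)
            self.Wa = Tensor(_glorot(rng, c.f_topology, c.f_topology,
                                     (c.f_topology, c.f_topology)),
                             requires_grad=True)
            self.ba = Tensor(np.zeros(c.f_topology, dtype=_DTYPE),
                             requires_grad=True)
            self.qa = Tensor(_glorot(rng, c.f_topology, 1, (c.f_topology, 1)),
                             requires_grad=True)
        if c.use_attribute:
            self.Wm = Tensor(_glorot(rng, n_mirna, c.f_channel,
                                     (n_mirna, c.f_channel)), requires_grad=True)
            self.Bm = Tensor(np.zeros((n_mirna, c.f_channel), dtype=_DTYPE),
                             requires_grad=True)
            self.Wd = Tensor(_glorot(rng, n_disease, c.f_channel,
                                     (n_disease, c.f_channel)), requires_grad=True)
            self.Bd = Tensor(np.zeros((n_disease, c.f_channel), dtype=_DTYPE),
                             requires_grad=True)
        w = c.embedding_width
        # the decoder quadratic form z_m W_b z_d sums w^2 terms, so plain
        # Glorot saturates the sigmoid at init (clamped scores, dead
        # gradients); shrink the interaction matrix to start near logit 0
        self.Wb = Tensor(_glorot(rng, w, w, (w, w)) * 0.05, requires_grad=True)

        self.attention_weights_: np.ndarray | None = None

    # -------------------------------------------------------------- parameters
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.config.use_topology:
            for layers in self.gcn_weights:
                ps.extend(layers)
            ps += [self.Wa, self.ba, self.qa]
        if self.config.use_attribute:
            ps += [self.Wm, self.Bm, self.Wd, self.Bd]
        ps.append(self.Wb)
        return ps

    def state_dict(self) -> dict:
        state = {"config": self.config.to_dict(),
                 "n_mirna": self.n_mirna, "n_disease": self.n_disease,
                 "n_views": self.n_views,
                 "params": [p.data.copy() for p in self.parameters()]}
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state["params"]) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for p, d in zip(params, state["params"]):
            if p.data.shape != d.shape:
                raise ValueError(
                    f"checkpoint tensor shape {d.shape} != model {p.data.shape}")
            p.data = np.asarray(d, dtype=p.data.dtype)

    # ----------------------------------------------------------------- forward
    def prepare_inputs(
        self,
        networks: list[HeteroNetwork],
        mirna_sims: list[SimilarityMatrix],
        disease_sims: list[SimilarityMatrix],
    ) -> _Inputs:
        """Precompute the per-fold constants (normalized adjacencies etc.)."""
        if len(networks) != self.n_views:
            raise ValueError(f"expected {self.n_views} views, got {len(networks)}")
        ghat, gx0 = [], []
        for net in networks:
            M = net.M.astype(_DTYPE)
            G = normalize_adjacency(M).astype(_DTYPE)
            ghat.append(G)
            gx0.append(G @ M)  # initial embedding X^(0) = M
        return _Inputs(
            ghat=ghat,
            gx0=gx0,
            mirna_stack=[s.values.astype(_DTYPE) for s in mirna_sims],
            disease_stack=[s.values.astype(_DTYPE) for s in disease_sims],
            n_mirna=self.n_mirna,
            n_disease=self.n_disease,
        )

    def forward(self, inputs: _Inputs) -> Tensor:
        """Score every miRNA-disease pair; returns the Nm x Nd sigmoid matrix."""
        c = self.config
        nm = self.n_mirna
        Zm1 = Zd1 = Zm2 = Zd2 = None
        if c.use_topology:
            reps: list[Tensor] = []
            for v in range(self.n_views):
                reps.extend(gcn_forward(
                    inputs.ghat[v], None, self.gcn_weights[v],
                    activation=c.activation, GX0=inputs.gx0[v]))
            fused, beta = attention_fuse(reps, self.Wa, self.ba, self.qa)
            self.attention_weights_ = beta
            Zm1 = fused.rows(0, nm)
            Zd1 = fused.rows(nm, self.n_nodes)
        if c.use_attribute:
            Zm2 = cnn_encode(inputs.mirna_stack, self.Wm, self.Bm)
            Zd2 = cnn_encode(inputs.disease_stack, self.Wd, self.Bd)
        Zm = concat_embeddings(Zm1, Zm2)
        Zd = concat_embeddings(Zd1, Zd2)
        return bilinear_decode(Zm, Zd, self.Wb)

    def loss(self, inputs: _Inputs, A: np.ndarray) -> Tensor:
        return bce_loss(self.forward(inputs), A)

    def predict(self, inputs: _Inputs) -> np.ndarray:
        """Score matrix as a plain array (no gradient tape)."""
        return self.forward(inputs).data.copy()
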