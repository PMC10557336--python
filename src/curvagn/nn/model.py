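"""The curvature-based adaptive graph attention network.

Architecture, per forward pass on one featurized complex:

1. **Curvature block** — embeds each edge's multiscale curvature profile
   (dense layer, leaky ReLU, softmax over the embedding components) and its
   integer-binned distance (one-hot, dense layer), then fuses the two into
   an edge context vector ``crt_ij``.
2. **L stacked attention layers**, each decomposed into
   * node2edge: edge state from endpoint node states plus ``crt``;
   * edge2edge: angle-domain adaptive attention on the directed line
     graph — per domain q a tanh *vector* attention coefficient per
     neighbouring edge, Hadamard-combined, with a residual; domain
     results are concatenated;
   * edge2node: multi-head adaptive attention pooling edges into their
     target nodes, with ``crt`` injected into the attention logits.
3. **Pooling** — a pairwise-interaction pooling head (PiPool) predicting
   the protein/ligand atom-type co-occurrence table via a softmax over the
   |S_P| x |S_L| cells, and a sum-pool + MLP head predicting the binding
   affinity.

Ablation variants: ``no-curvature`` removes the curvature context from the
message passing entirely; ``vanilla-gat`` replaces the vector attention in
edge2edge by softmax-normalised scalar attention; ``scalar-adaptive``
collapses the attention vector to a single tanh scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from ..complexes import LIGAND_ELEMENTS, PROTEIN_ELEMENTS
from ..dataset import GraphSample
from ..featurize import NODE_FEATURE_DIM
from .autodiff import ScatterPlan, Tensor, concat, segment_sum, softmax

VARIANTS = ("full", "no-curvature", "vanilla-gat", "scalar-adaptive")

N_INTERACTION_CELLS = len(PROTEIN_ELEMENTS) * len(LIGAND_ELEMENTS)

ModelState = Dict[str, Tensor]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults follow the reference configuration: 4 attention layers,
    8 heads, 6 angle domains, 128-dimensional node/edge/curvature
    embeddings, dropout 0.2 and loss trade-off lambda = 1.75, with a
    5-Angstrom graph cutoff (hence 6 integer distance bins) and 50
    filtration values.
    """

    n_paga_layers: int = 4
    n_heads: int = 8
    n_angle_domains: int = 6
    node_emb_dim: int = 128
    edge_emb_dim: int = 128
    curvature_emb_dim: int = 128
    distance_onehot_dim: int = 6
    n_filtrations: int = 50
    dropout: float = 0.2
    lambda_tradeoff: float = 1.75
    variant: str = "full"
    mlp_hidden: Tuple[int, int] = (128, 64)
    loss_norm: str = "l2"
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_paga_layers < 1 or self.n_heads < 1 or self.n_angle_domains < 1:
            raise ValueError("layer, head and angle-domain counts must be >= 1")
        if min(self.node_emb_dim, self.edge_emb_dim, self.curvature_emb_dim,
               self.distance_onehot_dim, self.n_filtrations) < 1:
            raise ValueError("embedding dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.loss_norm not in ("l2", "l1"):
            raise ValueError("loss_norm must be 'l2' or 'l1'")
        self.mlp_hidden = tuple(int(h) for h in self.mlp_hidden)

    @property
    def uses_curvature(self) -> bool:
        return self.variant != "no-curvature"

    def node_in_dim(self, layer: int) -> int:
        return NODE_FEATURE_DIM if layer == 0 else self.node_emb_dim

    @property
    def edge2edge_out_dim(self) -> int:
        return self.n_angle_domains * self.edge_emb_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{**d, "mlp_hidden": tuple(d.get("mlp_hidden", (128, 64)))})


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, (fan_out, fan_in)), requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def init_state(config: ModelConfig, rng: np.random.Generator) -> ModelState:
    """Glorot-uniform matrices, zero bias vectors."""
    c = config
    state: ModelState = {}
    if c.uses_curvature:
        state["W_f"] = _glorot(rng, c.curvature_emb_dim, c.n_filtrations)
        state["W_d"] = _glorot(rng, c.curvature_emb_dim, c.distance_onehot_dim)
        state["W_fd"] = _glorot(rng, c.curvature_emb_dim, 2 * c.curvature_emb_dim)
    crt_dim = c.curvature_emb_dim if c.uses_curvature else 0
    att_dim = 1 if c.variant in ("vanilla-gat", "scalar-adaptive") else c.edge_emb_dim
    for l in range(c.n_paga_layers):
        d_in = c.node_in_dim(l)
        state[f"W_ab_{l}"] = _glorot(rng, c.edge_emb_dim, 2 * d_in + crt_dim)
        for q in range(1, c.n_angle_domains + 1):
            state[f"W_eq_{l}_{q}"] = _glorot(rng, att_dim, 2 * c.edge_emb_dim)
            state[f"b_eq_{l}_{q}"] = _zeros(att_dim)
        for h in range(c.n_heads):
            state[f"W_e_{l}_{h}"] = _glorot(rng, c.node_emb_dim, c.edge2edge_out_dim)
            state[f"W_a_{l}_{h}"] = _glorot(rng, c.node_emb_dim, d_in)
            if c.uses_curvature:
                state[f"W_dr_{l}_{h}"] = _glorot(rng, c.curvature_emb_dim, c.curvature_emb_dim)
            state[f"v_{l}_{h}"] = _glorot(
                rng, 1, 2 * c.node_emb_dim + (c.curvature_emb_dim if c.uses_curvature else 0)
            ).reshape(-1)
    state["W_h"] = _glorot(rng, c.edge_emb_dim, c.edge2edge_out_dim)
    state["q_vec"] = _glorot(rng, 1, c.edge_emb_dim).reshape(-1)
    h1, h2 = c.mlp_hidden
    state["mlp_W0"] = _glorot(rng, h1, c.node_emb_dim)
    state["mlp_b0"] = _zeros(h1)
    state["mlp_W1"] = _glorot(rng, h2, h1)
    state["mlp_b1"] = _zeros(h2)
    state["mlp_W2"] = _glorot(rng, 1, h2)
    state["mlp_b2"] = _zeros(1)
    return state


# -- blocks --------------------------------------------------------------

def curvature_block(
    profiles: np.ndarray,
    distances: np.ndarray,
    cutoff_d: float,
    config: ModelConfig,
    state: ModelState,
) -> Tensor:
    """Edge context vectors crt_ij from curvature profiles and distances.

    The profile goes through a dense layer, leaky ReLU and a softmax over
    the embedding components; the distance through an integer-bin one-hot
    and a dense layer; the concatenation through a fused dense + ReLU.
    """
    distances = np.asarray(distances, dtype=float)
    if np.any(distances < 0) or np.any(distances > cutoff_d):
        raise ValueError("edge distance outside [0, cutoff_d]; one-hot bin undefined")
    bins = np.floor(distances).astype(int)
    bins = np.minimum(bins, config.distance_onehot_dim - 1)
    onehot = np.zeros((distances.size, config.distance_onehot_dim))
    onehot[np.arange(distances.size), bins] = 1.0

    f = softmax(
        (Tensor(profiles) @ _t(state["W_f"])).leaky_relu(config.leaky_slope), axis=-1
    )
    d_emb = Tensor(onehot) @ _t(state["W_d"])
    return (concat([d_emb, f], axis=-1) @ _t(state["W_fd"])).relu()


def _t(w: Tensor) -> Tensor:
    """Transpose of a 2-D parameter tensor (differentiable)."""
    out = Tensor(w.data.T, _parents=(w,), _backward=None)

    def bw(g):
        if w.requires_grad:
            w._accumulate(g.T)

    out._backward = bw
    return out


def _plans(sample: GraphSample, n_dom: int) -> dict:
    """Per-sample cached scatter plans for the fixed index arrays."""
    cache = getattr(sample, "_scatter_plans", None)
    if cache is None or cache.get("n_dom") != n_dom:
        e, n = sample.n_edges, sample.n_nodes
        q0 = sample.arc_domain - 1
        cache = {
            "n_dom": n_dom,
            "edge_src": ScatterPlan(sample.edges[:, 0], n),
            "edge_dst": ScatterPlan(sample.edges[:, 1], n),
            "arc_key": ScatterPlan(sample.arc_tgt * n_dom + q0, e * n_dom),
            "arc_srckey": ScatterPlan(sample.arc_src * n_dom + q0, e * n_dom),
            "arc_q0": ScatterPlan(q0, n_dom),
            "arc_src": ScatterPlan(sample.arc_src, e),
            "pipool_edges": ScatterPlan(sample.pipool_edge_idx, e),
            "pipool_cell": ScatterPlan(sample.pipool_cell, N_INTERACTION_CELLS),
        }
        sample._scatter_plans = cache
    return cache


def node2edge(
    h_nodes: Tensor,
    crt: Optional[Tensor],
    sample: GraphSample,
    config: ModelConfig,
    state: ModelState,
    layer: int,
) -> Tensor:
    """Edge states from endpoint node states (plus curvature context)."""
    plans = _plans(sample, config.n_angle_domains)
    hi = h_nodes.gather_rows(sample.edges[:, 0], plan=plans["edge_src"])
    hj = h_nodes.gather_rows(sample.edges[:, 1], plan=plans["edge_dst"])
    parts = [hi, hj] + ([crt] if config.uses_curvature else [])
    return (concat(parts, axis=-1) @ _t(state[f"W_ab_{layer}"])).relu()


def edge2edge(
    h_edges: Tensor,
    sample: GraphSample,
    config: ModelConfig,
    state: ModelState,
    layer: int,
) -> Tensor:
    """Angle-domain adaptive attention over line-graph arcs.

    For each domain q the neighbouring edge states are weighted by a tanh
    attention vector (Hadamard product) and summed onto a residual; the N
    domain results are concatenated.  ``vanilla-gat`` uses softmax scalar
    attention instead; ``scalar-adaptive`` a tanh scalar.
    """
    n_edges = sample.n_edges
    n_dom = config.n_angle_domains
    de = config.edge_emb_dim
    residual = concat([h_edges] * n_dom, axis=-1)
    if sample.arc_src.size == 0:
        return residual

    # Attention logits decompose as W_q[:, :De] h_tgt + W_q[:, De:] h_src + b_q;
    # projecting per edge (not per arc) keeps the big matmuls small, and one
    # fused segment-sum over (target edge, domain) keys replaces the per-domain
    # loop.  Row t*N + (q-1) of the (E*N, att) projections is the q-domain
    # logit contribution of edge t.
    p_tgt = concat(
        [
            h_edges @ _t(state[f"W_eq_{layer}_{q}"].cols(0, de))
            for q in range(1, n_dom + 1)
        ],
        axis=-1,
    ).reshape(n_edges * n_dom, -1)
    p_src = concat(
        [
            h_edges @ _t(state[f"W_eq_{layer}_{q}"].cols(de, 2 * de))
            for q in range(1, n_dom + 1)
        ],
        axis=-1,
    ).reshape(n_edges * n_dom, -1)
    bias = concat(
        [state[f"b_eq_{layer}_{q}"] for q in range(1, n_dom + 1)], axis=-1
    ).reshape(n_dom, -1)

    plans = _plans(sample, n_dom)
    q0 = sample.arc_domain - 1
    key = sample.arc_tgt * n_dom + q0  # (target edge, domain) bucket per arc
    pre = (
        p_tgt.gather_rows(key, plan=plans["arc_key"])
        + p_src.gather_rows(sample.arc_src * n_dom + q0, plan=plans["arc_srckey"])
        + bias.gather_rows(q0, plan=plans["arc_q0"])
    )
    if config.variant == "vanilla-gat":
        score = pre.leaky_relu(config.leaky_slope)
        num = (score - Tensor(score.data.max())).exp()
        denom = segment_sum(num, key, n_edges * n_dom, plan=plans["arc_key"])
        alpha = num / denom.gather_rows(key, plan=plans["arc_key"])
    else:
        alpha = pre.tanh()
    msg = alpha * h_edges.gather_rows(sample.arc_src, plan=plans["arc_src"])
    agg = segment_sum(msg, key, n_edges * n_dom, plan=plans["arc_key"]).reshape(
        n_edges, n_dom * de
    )
    return agg + residual


def edge2node(
    h_edges: Tensor,
    h_nodes: Tensor,
    crt: Optional[Tensor],
    sample: GraphSample,
    config: ModelConfig,
    state: ModelState,
    layer: int,
) -> Tensor:
    """Multi-head adaptive attention pooling edges into target nodes."""
    plans = _plans(sample, config.n_angle_domains)
    dst = sample.edges[:, 1]
    n_nodes = sample.n_nodes
    total: Optional[Tensor] = None
    for h in range(config.n_heads):
        he = h_edges @ _t(state[f"W_e_{layer}_{h}"])
        ha = h_nodes @ _t(state[f"W_a_{layer}_{h}"])
        parts = [he, ha.gather_rows(dst, plan=plans["edge_dst"])]
        if config.uses_curvature:
            parts.append(crt @ _t(state[f"W_dr_{layer}_{h}"]))
        beta = (concat(parts, axis=-1) @ state[f"v_{layer}_{h}"]).tanh()
        msg = beta.reshape(-1, 1) * he
        head = segment_sum(msg, dst, n_nodes, plan=plans["edge_dst"]) + ha
        total = head if total is None else total + head
    return total * (1.0 / config.n_heads)


def pipool(
    h_edges_final: Tensor, sample: GraphSample, state: ModelState
) -> Tensor:
    """Predicted interaction table: per-type-pair pooling + cell softmax.

    Pools the final representations of directed protein-to-ligand edges
    into |S_P| x |S_L| cells by endpoint element types, scores each cell
    with a shared vector, and normalises with a softmax over all cells.
    With no intermolecular edges every cell scores 0 and the table is
    uniform.
    """
    n_cells = N_INTERACTION_CELLS
    if sample.pipool_edge_idx.size:
        plans = getattr(sample, "_scatter_plans", None) or {}
        proj = h_edges_final.gather_rows(
            sample.pipool_edge_idx, plan=plans.get("pipool_edges")
        ) @ _t(state["W_h"])
        cells = segment_sum(
            proj, sample.pipool_cell, n_cells, plan=plans.get("pipool_cell")
        )
    else:
        cells = Tensor(np.zeros((n_cells, state["W_h"].data.shape[0])))
    scores = cells @ state["q_vec"]
    return softmax(scores, axis=-1).reshape(
        len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)
    )


def output_pool(h_nodes_final: Tensor, state: ModelState) -> Tensor:
    """Affinity prediction: sum-pool over nodes, then a small MLP."""
    g = h_nodes_final.sum(axis=0)
    g = (g @ _t(state["mlp_W0"]) + state["mlp_b0"]).relu()
    g = (g @ _t(state["mlp_W1"]) + state["mlp_b1"]).relu()
    return (g @ _t(state["mlp_W2"]) + state["mlp_b2"]).reshape(())


def forward(
    sample: GraphSample,
    config: ModelConfig,
    state: ModelState,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Tensor, Tensor]:
    """Full forward pass on one featurized complex -> (y_hat, Z_tilde).

    Dropout on node and edge representations is applied after each
    attention layer only when ``training`` is true (requires ``rng``).
    """
    h_nodes = Tensor(sample.node_features)
    crt = None
    if config.uses_curvature:
        crt = curvature_block(
            sample.curvature_profiles,
            sample.edge_distance,
            sample.cutoff_d,
            config,
            state,
        )
    if sample.n_angle_domains != config.n_angle_domains:
        raise ValueError(
            "sample was featurized with a different number of angle domains "
            f"({sample.n_angle_domains}) than the model expects "
            f"({config.n_angle_domains})"
        )
    h_edges: Optional[Tensor] = None
    for l in range(config.n_paga_layers):
        h_e = node2edge(h_nodes, crt, sample, config, state, l)
        h_edges = edge2edge(h_e, sample, config, state, l)
        h_nodes = edge2node(h_edges, h_nodes, crt, sample, config, state, l)
        if training and config.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            keep = 1.0 - config.dropout
            h_nodes = h_nodes * Tensor(
                (rng.random(h_nodes.shape) < keep).astype(float) / keep
            )
            h_edges = h_edges * Tensor(
                (rng.random(h_edges.shape) < keep).astype(float) / keep
            )
    y_hat = output_pool(h_nodes, state)
    z_tilde = pipool(h_edges, sample, state)
    return y_hat, z_tilde


def loss(
    y_hat: Tensor,
    y: float,
    z_tilde: Tensor,
    z: np.ndarray,
    lambda_tradeoff: float,
    norm: str = "l2",
) -> Tensor:
    """Per-complex objective: |y_hat - y| + lambda * ||flatten(Z~ - Z)||."""
    if z_tilde.shape != np.asarray(z).shape:
        raise ValueError("interaction-matrix shapes differ")
    la = (y_hat - float(y)).abs()
    diff = (z_tilde - Tensor(z)).reshape(-1)
    if norm == "l2":
        lb = (diff * diff).sum().sqrt()
    elif norm == "l1":
        lb = diff.abs().sum()
    else:
        raise ValueError("norm must be 'l2' or 'l1'")
    return la + lambda_tradeoff * lb
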