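"""Per-gene embeddings from a knowledge graph, learned by link prediction.

The encoder assigns every node a trainable C-dimensional vector ``z^0`` and
refines it with L relation-stratified GIN blocks.  One block computes

    z^{l+1} = relu( sum_r  W_(r) · relu(GINConv(z^l, G_(r))) + b_(r) )

where ``G_(r)`` is the subgraph of edges carrying relation ``r`` and GINConv
is the sum-aggregating graph-isomorphism convolution
``MLP((1+eps)·z_v + sum_{u in N(v)} z_u)``.  The outputs of all layers
(including ``z^0``) are concatenated and linearly projected back to C, so the
final embedding ``z_u`` sees every depth of the message passing.

Training is self-supervised link prediction: for each observed edge (u, r, v)
a corrupted partner (u, r, v') is drawn with v' uniform over the node set,
and the logistic loss

    L = -log sigma(s(u, v)) - log sigma(-s(u, v'))

is minimized by Adam.  The score ``s`` is the embedding dot product, or — for
multi-relational graphs — the relation-weighted form ``z_u^T diag(w_r) z_v``.

Message passing treats each relation subgraph as undirected by default
(neighbors = in-neighbors ∪ out-neighbors); directed aggregation is available
via ``GnnConfig.undirected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Callable, Iterator, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

from .autodiff import Adam, Tensor, concat, gather, spmm
from .graph_io import KnowledgeGraph, RelationLabel

__all__ = [
    "GnnConfig",
    "LayerParams",
    "GnnParameters",
    "EmbeddingTable",
    "LinkExample",
    "init_parameters",
    "gin_conv",
    "gin_block",
    "encode",
    "score_link",
    "score_link_relational",
    "sample_negatives",
    "link_loss",
    "pretrain",
]


@dataclass(frozen=True)
class GnnConfig:
    """Hyperparameters of the graph encoder and its pretraining run.

    Defaults follow the reference setting: C=32 (16 also supported), two GIN
    layers, learning rate 1e-4, 50 epochs, one uniform negative per positive
    edge.  ``use_relation_scoring=None`` means automatic: relation-weighted
    scoring is enabled iff the graph has more than one relation.
    """

    dim: int = 32
    n_layers: int = 2
    learning_rate: float = 1e-4
    epochs: int = 50
    negatives_per_positive: int = 1
    use_relation_scoring: bool | None = None
    seed: int = 0
    epsilon: float = 0.0
    undirected: bool = True
    batch_size: int = 512
    full_batch_threshold: int = 100_000

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        if self.n_layers <= 0:
            raise ValueError("n_layers must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


@dataclass
class LayerParams:
    """One GIN block: a shared update MLP plus per-relation linear maps."""

    mlp_w1: np.ndarray
    mlp_b1: np.ndarray
    mlp_w2: np.ndarray
    mlp_b2: np.ndarray
    rel_w: dict[RelationLabel, np.ndarray]
    rel_b: dict[RelationLabel, np.ndarray]


@dataclass
class GnnParameters:
    """All trainable arrays of the encoder, keyed to a specific graph."""

    nodes: tuple[str, ...]
    relations: tuple[RelationLabel, ...]
    node_embedding: np.ndarray  # |V| x C, z^0
    layers: list[LayerParams]
    projection: np.ndarray  # (L+1)C x C
    projection_b: np.ndarray  # C
    relation_diag: dict[RelationLabel, np.ndarray]  # per-relation length-C w_r

    def flat_arrays(self) -> list[np.ndarray]:
        out = [self.node_embedding]
        for lp in self.layers:
            out += [lp.mlp_w1, lp.mlp_b1, lp.mlp_w2, lp.mlp_b2]
            out += [lp.rel_w[r] for r in self.relations]
            out += [lp.rel_b[r] for r in self.relations]
        out += [self.projection, self.projection_b]
        out += [self.relation_diag[r] for r in self.relations]
        return out


class EmbeddingTable(Mapping[str, np.ndarray]):
    """Node-id → length-C vector, stored as an aligned matrix."""

    def __init__(self, nodes: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(nodes):
            raise ValueError("matrix rows must match node list")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("embedding entries must be finite")
        self.nodes = tuple(nodes)
        self.matrix = matrix
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __getitem__(self, node: str) -> np.ndarray:
        return self.matrix[self._index[node]]

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def to_tsv(self, stream: IO[str]) -> None:
        cols = "\t".join(f"e{i}" for i in range(self.dim))
        stream.write(f"node\t{cols}\n")
        for i, n in enumerate(self.nodes):
            vals = "\t".join(repr(float(x)) for x in self.matrix[i])
            stream.write(f"{n}\t{vals}\n")

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "EmbeddingTable":
        header = stream.readline().rstrip("\n").split("\t")
        if header[0] != "node":
            raise ValueError("embedding TSV must start with a 'node' column")
        nodes, rows = [], []
        for line in stream:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError("ragged embedding TSV row")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(nodes, np.asarray(rows))


@dataclass(frozen=True)
class LinkExample:
    u: str
    r: RelationLabel
    v: str
    polarity: str  # "positive" | "negative"


# --------------------------------------------------------------------------
# parameter initialization


def init_parameters(g: KnowledgeGraph, config: GnnConfig) -> GnnParameters:
    """Random initial parameters; bit-identical for identical seeds."""
    if g.n_nodes == 0:
        raise ValueError("cannot initialize parameters for an empty graph")
    rng = np.random.default_rng(config.seed)
    c = config.dim
    scale = 1.0 / np.sqrt(c)
    emb = rng.standard_normal((g.n_nodes, c))
    layers = []
    for _ in range(config.n_layers):
        layers.append(
            LayerParams(
                mlp_w1=rng.standard_normal((c, c)) * scale,
                mlp_b1=np.zeros(c),
                mlp_w2=rng.standard_normal((c, c)) * scale,
                mlp_b2=np.zeros(c),
                rel_w={r: rng.standard_normal((c, c)) * scale for r in g.relations},
                rel_b={r: np.zeros(c) for r in g.relations},
            )
        )
    width = (config.n_layers + 1) * c
    projection = rng.standard_normal((width, c)) / np.sqrt(width)
    return GnnParameters(
        nodes=g.nodes,
        relations=g.relations,
        node_embedding=emb,
        layers=layers,
        projection=projection,
        projection_b=np.zeros(c),
        relation_diag={r: np.ones(c) for r in g.relations},
    )


# --------------------------------------------------------------------------
# adjacency and forward pass


def _adjacency(g: KnowledgeGraph, relation: RelationLabel | None,
               undirected: bool) -> sparse.csr_matrix:
    """Binary neighbor matrix: row v collects messages from N(v) (set semantics)."""
    idx = g.node_index()
    rows, cols = [], []
    for u, r, v in g.edges:
        if relation is not None and r != relation:
            continue
        rows.append(idx[v])
        cols.append(idx[u])
        if undirected:
            rows.append(idx[u])
            cols.append(idx[v])
    n = g.n_nodes
    a = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    a.data[:] = 1.0  # collapse duplicates: neighbors form a set
    return a


def _coerce_matrix(z, nodes: tuple[str, ...]) -> np.ndarray:
    if isinstance(z, EmbeddingTable):
        if z.nodes != nodes:
            raise ValueError("embedding table does not cover the graph's nodes")
        return z.matrix
    z = np.asarray(z, dtype=np.float64)
    if z.shape[0] != len(nodes):
        raise ValueError("row count does not match graph node count")
    return z


def gin_conv(
    z,
    g_r: KnowledgeGraph,
    update_map: Callable[[np.ndarray], np.ndarray] | None = None,
    epsilon: float = 0.0,
    undirected: bool = True,
):
    """One GINConv step: ``update_map((1+eps)·z_v + sum_{u in N(v)} z_u)``.

    Accepts and returns either an :class:`EmbeddingTable` or a plain matrix
    aligned to ``g_r.nodes``.  Permutation-equivariant by construction.
    """
    mat = _coerce_matrix(z, g_r.nodes)
    a = _adjacency(g_r, None, undirected)
    agg = (1.0 + epsilon) * mat + a @ mat
    out = agg if update_map is None else np.asarray(update_map(agg))
    if out.shape[0] != mat.shape[0]:
        raise ValueError("update_map changed the number of rows")
    if isinstance(z, EmbeddingTable):
        return EmbeddingTable(g_r.nodes, out)
    return out


def gin_block(
    z,
    g: KnowledgeGraph,
    layer: LayerParams,
    epsilon: float = 0.0,
    undirected: bool = True,
):
    """One relation-stratified block over all relation subgraphs of ``g``."""
    for r in g.relations:
        if r not in layer.rel_w or r not in layer.rel_b:
            raise KeyError(f"missing per-relation parameters for {r}")
    mat = _coerce_matrix(z, g.nodes)
    acc = np.zeros((mat.shape[0], layer.rel_b[g.relations[0]].shape[0]))
    for r in g.relations:
        a = _adjacency(g, r, undirected)
        agg = (1.0 + epsilon) * mat + a @ mat
        h = np.maximum(agg @ layer.mlp_w1 + layer.mlp_b1, 0.0) @ layer.mlp_w2
        h = np.maximum(h + layer.mlp_b2, 0.0)  # inner nonlinearity
        acc = acc + h @ layer.rel_w[r] + layer.rel_b[r]
    out = np.maximum(acc, 0.0)  # outer nonlinearity
    if isinstance(z, EmbeddingTable):
        return EmbeddingTable(g.nodes, out)
    return out


def _forward_tensors(
    emb_t: Tensor,
    layer_tensors: list[dict],
    proj_t: Tensor,
    proj_b_t: Tensor,
    adjacencies: list[sparse.csr_matrix],
    config: GnnConfig,
) -> Tensor:
    """Differentiable full-graph forward pass shared by encode and pretrain."""
    z = emb_t
    outs = [z]
    for lt in layer_tensors:
        acc = None
        for ri, a in enumerate(adjacencies):
            agg = spmm(a, z) + (1.0 + config.epsilon) * z
            h = ((agg @ lt["mlp_w1"] + lt["mlp_b1"]).relu() @ lt["mlp_w2"]
                 + lt["mlp_b2"]).relu()
            term = h @ lt["rel_w"][ri] + lt["rel_b"][ri]
            acc = term if acc is None else acc + term
        z = acc.relu()
        outs.append(z)
    return concat(outs, axis=1) @ proj_t + proj_b_t


def _tensorize(params: GnnParameters, requires_grad: bool):
    emb_t = Tensor(params.node_embedding, requires_grad=requires_grad)
    layer_tensors = []
    for lp in params.layers:
        layer_tensors.append(
            {
                "mlp_w1": Tensor(lp.mlp_w1, requires_grad=requires_grad),
                "mlp_b1": Tensor(lp.mlp_b1, requires_grad=requires_grad),
                "mlp_w2": Tensor(lp.mlp_w2, requires_grad=requires_grad),
                "mlp_b2": Tensor(lp.mlp_b2, requires_grad=requires_grad),
                "rel_w": [Tensor(lp.rel_w[r], requires_grad=requires_grad)
                          for r in params.relations],
                "rel_b": [Tensor(lp.rel_b[r], requires_grad=requires_grad)
                          for r in params.relations],
            }
        )
    proj_t = Tensor(params.projection, requires_grad=requires_grad)
    proj_b_t = Tensor(params.projection_b, requires_grad=requires_grad)
    diag_t = Tensor(
        np.stack([params.relation_diag[r] for r in params.relations]),
        requires_grad=requires_grad,
    )
    return emb_t, layer_tensors, proj_t, proj_b_t, diag_t


def _collect_tensors(emb_t, layer_tensors, proj_t, proj_b_t, diag_t) -> list[Tensor]:
    out = [emb_t]
    for lt in layer_tensors:
        out += [lt["mlp_w1"], lt["mlp_b1"], lt["mlp_w2"], lt["mlp_b2"]]
        out += lt["rel_w"] + lt["rel_b"]
    out += [proj_t, proj_b_t, diag_t]
    return out


def encode(g: KnowledgeGraph, params: GnnParameters, config: GnnConfig) -> EmbeddingTable:
    """Deterministic forward pass producing the C-dimensional z_u per node."""
    if params.nodes != g.nodes:
        raise ValueError("parameters were initialized for a different node set")
    if tuple(params.relations) != g.relations:
        raise ValueError("parameters were initialized for a different relation set")
    emb_t, layer_tensors, proj_t, proj_b_t, _ = _tensorize(params, requires_grad=False)
    adjacencies = [_adjacency(g, r, config.undirected) for r in g.relations]
    z = _forward_tensors(emb_t, layer_tensors, proj_t, proj_b_t, adjacencies, config)
    return EmbeddingTable(g.nodes, z.data)


# --------------------------------------------------------------------------
# link scoring and loss


def score_link(z_u: np.ndarray, z_v: np.ndarray) -> float:
    """Probability of a link: logistic of the embedding dot product."""
    z_u = np.asarray(z_u, dtype=np.float64)
    z_v = np.asarray(z_v, dtype=np.float64)
    if z_u.shape != z_v.shape:
        raise ValueError(f"dimension mismatch: {z_u.shape} vs {z_v.shape}")
    return float(expit(z_u @ z_v))


def score_link_relational(z_u: np.ndarray, z_v: np.ndarray, w_r: np.ndarray) -> float:
    """Relation-weighted link probability sigma(z_u^T diag(w_r) z_v)."""
    z_u = np.asarray(z_u, dtype=np.float64)
    z_v = np.asarray(z_v, dtype=np.float64)
    w_r = np.asarray(w_r, dtype=np.float64)
    if not (z_u.shape == z_v.shape == w_r.shape):
        raise ValueError("z_u, z_v and w_r must share a dimension")
    return float(expit(np.sum(z_u * w_r * z_v)))


def sample_negatives(
    batch: Sequence[LinkExample],
    g: KnowledgeGraph,
    rng: np.random.Generator,
    negatives_per_positive: int = 1,
) -> list[LinkExample]:
    """Corrupt each positive (u, r, v) into (u, r, v') with v' uniform on V.

    Sampling is unfiltered: v' may coincide with v or with another true
    neighbor, matching the loss definition literally.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    if g.n_nodes == 0:
        raise ValueError("graph has no nodes to sample from")
    out = []
    for ex in batch:
        for _ in range(negatives_per_positive):
            v_prime = g.nodes[int(rng.integers(0, g.n_nodes))]
            out.append(LinkExample(ex.u, ex.r, v_prime, "negative"))
    return out


def link_loss(positive_logits, negative_logits) -> float:
    """Mean of -log sigma(s+) - log sigma(-s-), in stable softplus form."""
    pos = np.atleast_1d(np.asarray(positive_logits, dtype=np.float64))
    neg = np.atleast_1d(np.asarray(negative_logits, dtype=np.float64))
    if pos.shape != neg.shape:
        raise ValueError("positive and negative logit counts must match")
    if np.isnan(pos).any() or np.isnan(neg).any():
        raise FloatingPointError("NaN logits passed to link_loss")
    # -log sigma(x) == softplus(-x)
    return float(np.mean(np.logaddexp(0.0, -pos) + np.logaddexp(0.0, neg)))


# --------------------------------------------------------------------------
# pretraining


def pretrain(
    g: KnowledgeGraph, config: GnnConfig
) -> tuple[GnnParameters, EmbeddingTable, np.ndarray]:
    """Pretrain the encoder by link prediction; fully seed-deterministic.

    Returns the parameters after the final epoch, the encoded embedding
    table, and the per-epoch mean loss trace.
    """
    if g.n_edges < 1:
        raise ValueError("pretraining requires a graph with at least one edge")
    params = init_parameters(g, config)
    emb_t, layer_tensors, proj_t, proj_b_t, diag_t = _tensorize(params, True)
    tensors = _collect_tensors(emb_t, layer_tensors, proj_t, proj_b_t, diag_t)
    adjacencies = [_adjacency(g, r, config.undirected) for r in g.relations]

    use_rel = config.use_relation_scoring
    if use_rel is None:
        use_rel = g.n_relations > 1
    if not use_rel:
        diag_t.requires_grad = False

    idx = g.node_index()
    ridx = g.relation_index()
    u_idx = np.array([idx[u] for u, _, _ in g.edges], dtype=np.intp)
    v_idx = np.array([idx[v] for _, _, v in g.edges], dtype=np.intp)
    r_idx = np.array([ridx[r] for _, r, _ in g.edges], dtype=np.intp)
    m = len(u_idx)
    npp = config.negatives_per_positive

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(tensors, lr=config.learning_rate)
    loss_trace = []
    for _epoch in range(config.epochs):
        order = rng.permutation(m)
        if m > config.full_batch_threshold:
            batches = [order[i:i + config.batch_size]
                       for i in range(0, m, config.batch_size)]
        else:
            batches = [order]
        epoch_loss, n_seen = 0.0, 0
        for b in batches:
            neg_v = rng.integers(0, g.n_nodes, size=len(b) * npp)
            bu = np.repeat(u_idx[b], npp)
            bv = np.repeat(v_idx[b], npp)
            br = np.repeat(r_idx[b], npp)

            z = _forward_tensors(emb_t, layer_tensors, proj_t, proj_b_t,
                                 adjacencies, config)
            zu, zv, zn = gather(z, bu), gather(z, bv), gather(z, neg_v)
            if use_rel:
                w = gather(diag_t, br)
                s_pos = (zu * w * zv).sum(axis=1)
                s_neg = (zu * w * zn).sum(axis=1)
            else:
                s_pos = (zu * zv).sum(axis=1)
                s_neg = (zu * zn).sum(axis=1)
            loss = ((-1.0 * s_pos).softplus() + s_neg.softplus()).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite link-prediction loss at epoch {_epoch + 1}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(b)
            n_seen += len(b)
        loss_trace.append(epoch_loss / n_seen)

    # relation_diag was stacked into one tensor for gathering; copy back
    for i, r in enumerate(params.relations):
        params.relation_diag[r][:] = diag_t.data[i]
    table = encode(g, params, config)
    return params, table, np.asarray(loss_trace)
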