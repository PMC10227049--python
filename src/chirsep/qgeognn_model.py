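"""Dual-graph isomorphism network with a three-quantile head.

The network runs GIN-style message passing on the bond-angle graph H
and the atom-bond graph G in tandem.  At every layer the H nodes (= G's
bonds) are updated first; their **pre-update** states are added to G's
edge representations — the bridge that carries 3D geometry into the
atom graph — and then the G nodes are updated.  After K layers the G
node states are sum-pooled per molecule and a fully connected layer
maps the graph representation to three outputs on the RTv scale: the
10th percentile, the point prediction, and the 90th percentile.

Each GIN convolution computes ``x'_i = MLP((1 + eps)·x_i +
sum_{j in N(i)} (x_j + proj(e_ji)))`` where ``proj`` is a learned
per-layer affine map of the edge features into the embedding space and
``MLP`` is two affine layers with an interior ReLU.

Everything runs on the package's numpy autograd core; a single integer
seed controls weight initialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import constants
from ._autograd import Tensor, gather, matmul, relu, segment_sum
from .chem_graphs import DualGraph
from .errors import ContractError
from .quantile_loss import LossConfig, loss_terms

ATOM_ONEHOT_DIM = sum(constants.ATOM_FEATURE_SIZES)
BOND_CAT_SIZES = (constants.BOND_DIR_SIZE, constants.BOND_TYPE_SIZE, constants.BOND_RING_SIZE)
BOND_ONEHOT_DIM = sum(BOND_CAT_SIZES)


@dataclass
class ModelConfig:
    num_layers: int = 5
    embed_dim: int = 128
    eps: float = 0.0
    readout: str = "sum"
    head_outputs: int = 3
    multi_column: bool = False
    use_bridge: bool = True   # ablation flag: False reduces to a plain GIN on G

    def __post_init__(self):
        if self.num_layers < 1:
            raise ContractError("num_layers must be >= 1")
        if self.head_outputs != 3:
            raise ContractError("the quantile head has exactly 3 outputs")
        if self.readout != "sum":
            raise ContractError("only sum readout is supported")

    @property
    def g_edge_cont_dim(self) -> int:
        # elution proportion, plus packing size / substrate / connection
        return 4 if self.multi_column else 1

    @property
    def h_edge_dim(self) -> int:
        # angle + 5 molecular descriptors, plus 5 CSP descriptors
        return 11 if self.multi_column else 6


@dataclass
class QuantilePrediction:
    """Model outputs on the RTv scale (min·mL/min)."""

    q10: float
    pred: float
    q90: float
    flow_rate: Optional[float] = None

    def rt(self) -> tuple[float, float, float]:
        """(q10, pred, q90) converted to retention time in minutes."""
        if self.flow_rate is None or self.flow_rate <= 0:
            raise ContractError("flow_rate required to convert RTv to RT")
        return (self.q10 / self.flow_rate, self.pred / self.flow_rate, self.q90 / self.flow_rate)


@dataclass
class NormStats:
    """Z-score statistics for the continuous feature blocks.

    Computed on the training set and stored with the model so inference
    normalizes identically.
    """

    g_edge_mean: np.ndarray
    g_edge_std: np.ndarray
    h_node_mean: np.ndarray
    h_node_std: np.ndarray
    h_edge_mean: np.ndarray
    h_edge_std: np.ndarray

    @classmethod
    def identity(cls, config: ModelConfig) -> "NormStats":
        return cls(
            np.zeros(config.g_edge_cont_dim), np.ones(config.g_edge_cont_dim),
            np.zeros(1), np.ones(1),
            np.zeros(config.h_edge_dim), np.ones(config.h_edge_dim),
        )

    @classmethod
    def fit(cls, batch: "GraphBatch", config: ModelConfig) -> "NormStats":
        def _ms(x):
            m = x.mean(axis=0) if x.size else np.zeros(x.shape[1])
            s = x.std(axis=0) if x.size else np.ones(x.shape[1])
            s = np.where(s < 1e-8, 1.0, s)
            return m, s

        gm, gs = _ms(batch.g_edge_cont)
        hnm, hns = _ms(batch.h_node)
        hem, hes = _ms(batch.h_edge)
        return cls(gm, gs, hnm, hns, hem, hes)


class GraphBatch:
    """Block-diagonal batch of DualGraphs as flat numpy arrays."""

    def __init__(self, duals: Sequence[DualGraph], config: ModelConfig):
        if not duals:
            raise ContractError("empty batch")
        expected_g = 3 + config.g_edge_cont_dim
        for d in duals:
            if d.g.edge_features.shape[1] != expected_g:
                raise ContractError(
                    f"graph for {d.smiles!r} has G edge width "
                    f"{d.g.edge_features.shape[1]}, model expects {expected_g}"
                )
            if d.h.edge_features.shape[1] != config.h_edge_dim:
                raise ContractError(
                    f"graph for {d.smiles!r} has H edge width "
                    f"{d.h.edge_features.shape[1]}, model expects {config.h_edge_dim}"
                )
        atom_oh, g_src, g_dst, g_cat, g_cont = [], [], [], [], []
        g_bond_ids, h_node, h_src, h_dst, h_edge = [], [], [], [], []
        atom_graph_ids = []
        atom_off = bond_off = 0
        for gi, d in enumerate(duals):
            n_atoms = d.g.num_atoms
            n_bonds = d.h.num_bonds
            atom_oh.append(_onehot_atoms(d.g.node_features))
            atom_graph_ids.append(np.full(n_atoms, gi))
            g_src.append(d.g.edge_index[0] + atom_off)
            g_dst.append(d.g.edge_index[1] + atom_off)
            g_cat.append(_onehot_bond_cats(d.g.edge_features[:, :3]))
            g_cont.append(d.g.edge_features[:, 3:])
            g_bond_ids.append(d.g.edge_bond_ids + bond_off)
            h_node.append(d.h.node_features)
            h_src.append(d.h.edge_index[0] + bond_off)
            h_dst.append(d.h.edge_index[1] + bond_off)
            h_edge.append(d.h.edge_features)
            atom_off += n_atoms
            bond_off += n_bonds
        self.n_graphs = len(duals)
        self.n_atoms = atom_off
        self.n_bonds = bond_off
        self.atom_onehot = np.vstack(atom_oh)
        self.atom_graph_ids = np.concatenate(atom_graph_ids)
        self.g_src = np.concatenate(g_src)
        self.g_dst = np.concatenate(g_dst)
        self.g_edge_cat = np.vstack(g_cat)
        self.g_edge_cont = np.vstack(g_cont)
        self.g_bond_ids = np.concatenate(g_bond_ids)
        self.h_node = np.vstack(h_node)
        self.h_src = np.concatenate(h_src)
        self.h_dst = np.concatenate(h_dst)
        self.h_edge = np.vstack(h_edge) if any(e.size for e in h_edge) else np.empty((0, config.h_edge_dim))


def _onehot_atoms(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    out = np.zeros((n, ATOM_ONEHOT_DIM))
    offset = 0
    for col, size in enumerate(constants.ATOM_FEATURE_SIZES):
        idx = np.clip(codes[:, col], 0, size - 1).astype(int)
        out[np.arange(n), offset + idx] = 1.0
        offset += size
    return out


def _onehot_bond_cats(cats: np.ndarray) -> np.ndarray:
    n = cats.shape[0]
    out = np.zeros((n, BOND_ONEHOT_DIM))
    offset = 0
    for col, size in enumerate(BOND_CAT_SIZES):
        idx = np.clip(cats[:, col], 0, size - 1).astype(int)
        out[np.arange(n), offset + idx] = 1.0
        offset += size
    return out


def gin_conv(node_states, edge_index, edge_features=None, mlp=None, eps: float = 0.0):
    """One GIN convolution: ``MLP((1+eps)·x_i + sum_{j in N(i)} (x_j + e_ji))``.

    ``edge_features`` must already live in the embedding space (or be
    ``None`` for zero edge contribution); ``mlp`` is a callable applied
    to the aggregate, identity when ``None``.  Accepts numpy arrays or
    autograd tensors.
    """
    x = node_states if isinstance(node_states, Tensor) else Tensor(np.asarray(node_states, float))
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    n = x.data.shape[0]
    if edge_index.size and edge_index.max() >= n:
        raise ContractError("edge_index refers to a node outside the batch")
    if edge_index.size:
        msg = gather(x, edge_index[0])
        if edge_features is not None:
            e = edge_features if isinstance(edge_features, Tensor) else Tensor(edge_features)
            if e.data.shape[0] != edge_index.shape[1]:
                raise ContractError("edge_features and edge_index disagree on message count")
            msg = msg + e
        agg = segment_sum(msg, edge_index[1], n)
        pre = (1.0 + eps) * x + agg
    else:
        pre = (1.0 + eps) * x
    out = mlp(pre) if mlp is not None else pre
    result = out if isinstance(node_states, Tensor) else out.data
    return result


class QGeoGNN:
    """The dual-graph quantile network."""

    def __init__(self, config: ModelConfig, seed: int = 0, norm: Optional[NormStats] = None):
        self.config = config
        self.seed = int(seed)
        self.norm = norm or NormStats.identity(config)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- parameters --------------------------------------------------------

    def _add_affine(self, name: str, fan_in: int, fan_out: int, rng) -> None:
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        self.params[f"{name}.W"] = Tensor(
            rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True
        )
        self.params[f"{name}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)

    def _init_params(self, rng) -> None:
        cfg = self.config
        d = cfg.embed_dim
        self._add_affine("node_emb_g", ATOM_ONEHOT_DIM, d, rng)
        self._add_affine("node_emb_h", 1, d, rng)
        g_edge_in = BOND_ONEHOT_DIM + cfg.g_edge_cont_dim
        for k in range(cfg.num_layers):
            # the bridge consumes previous-layer H states, so the final
            # layer's H update could never reach the output; skip it
            if k < cfg.num_layers - 1:
                self._add_affine(f"edge_h.{k}", cfg.h_edge_dim, d, rng)
                self._add_affine(f"mlp_h.{k}.0", d, d, rng)
                self._add_affine(f"mlp_h.{k}.1", d, d, rng)
            self._add_affine(f"edge_g.{k}", g_edge_in, d, rng)
            self._add_affine(f"mlp_g.{k}.0", d, d, rng)
            self._add_affine(f"mlp_g.{k}.1", d, d, rng)
        self._add_affine("head", d, cfg.head_outputs, rng)

    def _affine(self, name: str, x: Tensor) -> Tensor:
        return matmul(x, self.params[f"{name}.W"]) + self.params[f"{name}.b"]

    def _mlp(self, name: str, x: Tensor) -> Tensor:
        return self._affine(f"{name}.1", relu(self._affine(f"{name}.0", x)))

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    # -- forward -----------------------------------------------------------

    def forward_batch(self, batch: GraphBatch) -> Tensor:
        """Quantile outputs [n_graphs, 3] with gradient tracking."""
        cfg = self.config
        nm = self.norm
        g_cont = (batch.g_edge_cont - nm.g_edge_mean) / nm.g_edge_std
        h_node = (batch.h_node - nm.h_node_mean) / nm.h_node_std
        h_edge = (batch.h_edge - nm.h_edge_mean) / nm.h_edge_std
        g_edge_in = np.hstack([batch.g_edge_cat, g_cont])

        g_x = self._affine("node_emb_g", Tensor(batch.atom_onehot))
        h_x = self._affine("node_emb_h", Tensor(h_node))
        for k in range(cfg.num_layers):
            # H update (bond-angle graph); the last layer's update would
            # never reach the output through the previous-layer bridge
            h_new = h_x
            if k < cfg.num_layers - 1:
                h_edge_emb = (
                    self._affine(f"edge_h.{k}", Tensor(h_edge)) if h_edge.shape[0] else None
                )
                h_new = gin_conv(
                    h_x, np.vstack([batch.h_src, batch.h_dst]), h_edge_emb,
                    mlp=lambda t, kk=k: self._mlp(f"mlp_h.{kk}", t), eps=cfg.eps,
                )
            # bridge: previous-layer H states joined to G's edge representations
            g_edge_emb = self._affine(f"edge_g.{k}", Tensor(g_edge_in))
            if cfg.use_bridge:
                g_edge_emb = g_edge_emb + gather(h_x, batch.g_bond_ids)
            g_x = gin_conv(
                g_x, np.vstack([batch.g_src, batch.g_dst]), g_edge_emb,
                mlp=lambda t, kk=k: self._mlp(f"mlp_g.{kk}", t), eps=cfg.eps,
            )
            h_x = h_new
        graph_repr = segment_sum(g_x, batch.atom_graph_ids, batch.n_graphs)
        return self._affine("head", graph_repr)

    def forward(self, dual: DualGraph) -> QuantilePrediction:
        """Predict one molecule; outputs are (q10, pred, q90) on RTv scale."""
        out = self.forward_batch(GraphBatch([dual], self.config)).data[0]
        if not np.all(np.isfinite(out)):
            raise ContractError(f"non-finite model output for {dual.smiles!r}: {out}")
        return QuantilePrediction(
            q10=float(out[0]), pred=float(out[1]), q90=float(out[2]),
            flow_rate=dual.condition.flow_rate,
        )

    def predict(self, duals: Sequence[DualGraph]) -> list[QuantilePrediction]:
        out = self.forward_batch(GraphBatch(duals, self.config)).data
        if not np.all(np.isfinite(out)):
            raise ContractError("non-finite model outputs in batch")
        return [
            QuantilePrediction(float(r[0]), float(r[1]), float(r[2]), d.condition.flow_rate)
            for r, d in zip(out, duals)
        ]

    def batch_loss(self, batch: GraphBatch, y_true: np.ndarray, config: LossConfig):
        """(total loss tensor, per-term floats) for a training step."""
        out = self.forward_batch(batch)
        # slice columns via selector matmuls to stay inside supported ops
        sel = [np.zeros((3, 1)) for _ in range(3)]
        for c in range(3):
            sel[c][c, 0] = 1.0
        q10 = matmul(out, Tensor(sel[0]))
        pred = matmul(out, Tensor(sel[1]))
        q90 = matmul(out, Tensor(sel[2]))
        terms = loss_terms(y_true.reshape(-1, 1), q10, pred, q90, config)
        total = None
        for v in terms.values():
            total = v if total is None else total + v
        return total, {k: float(v.data) for k, v in terms.items()}

    # -- serialization -----------------------------------------------------

    def save(self, path: str) -> None:
        """Single-archive serialization: weights, config, norm stats, code-table version."""
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "code_table_version": constants.CODE_TABLE_VERSION,
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        arrays.update(
            norm__g_edge_mean=self.norm.g_edge_mean, norm__g_edge_std=self.norm.g_edge_std,
            norm__h_node_mean=self.norm.h_node_mean, norm__h_node_std=self.norm.h_node_std,
            norm__h_edge_mean=self.norm.h_edge_mean, norm__h_edge_std=self.norm.h_edge_std,
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "QGeoGNN":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
            if meta["code_table_version"] != constants.CODE_TABLE_VERSION:
                raise ContractError(
                    f"model was saved with feature code tables v{meta['code_table_version']}, "
                    f"this package uses v{constants.CODE_TABLE_VERSION}"
                )
            config = ModelConfig(**meta["config"])
            norm = NormStats(
                archive["norm__g_edge_mean"], archive["norm__g_edge_std"],
                archive["norm__h_node_mean"], archive["norm__h_node_std"],
                archive["norm__h_edge_mean"], archive["norm__h_edge_std"],
            )
            model = cls(config, seed=meta["seed"], norm=norm)
            for key in model.params:
                model.params[key].data = archive[key.replace(".", "__")].copy()
        return model
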