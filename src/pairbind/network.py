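"""Siamese physics-informed graph attention network for ΔpIC50 ranking.

Architecture, per pocket–ligand complex:

1. a GCN pre-encoder updates pocket atom features over the pocket's covalent
   graph alone (symmetric-normalized adjacency with self-loops);
2. node / edge features are projected into hidden size ``m``;
3. ``L`` alternating blocks run: a distance- and angle-aware edge-to-edge
   attention update (DAEE) followed by a distance-aware edge-to-node update
   (DEN). Attention scores carry two physics terms: a one-hot angle-domain
   embedding (six π/6 bins) inside the LeakyReLU, and an additive
   statistical-potential bias after it;
4. pocket nodes are dropped and an attentive super-node readout with a GRU
   cell pools the ligand nodes into a graph vector ``x``.

The two branches share one parameter set (Siamese). The pair representation
``x_i ⊕ x_j ⊕ (x_i − x_j)`` feeds two independent three-layer feedforward
heads: a ΔpIC50 regression and a "ligand i binds tighter" classification.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import (Tensor, concat, dropout, gather_rows, layer_norm,
                       segment_softmax, segment_sum)
from .graph import ComplexGraph, L_EDGE, L_NODE, angle_divider
from .potentials import PotentialTable, edge_bias_array


@dataclass
class NetworkConfig:
    """Hyperparameters of the encoder and heads.

    ``m`` is the hidden width and must be even (the intermediate edge
    encoding lives in dimension m/2); ``n_layers`` is the number of
    DAEE+DEN message-passing rounds.
    """

    m: int = 96
    n_layers: int = 3
    pocket_depth: int = 2
    readout_steps: int = 2
    dropout: float = 0.1
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.m % 2 != 0:
            raise ValueError("hidden width m must be even")
        if self.n_layers < 1:
            raise ValueError("need at least one message-passing layer")


@dataclass
class CompiledGraph:
    """A ComplexGraph lowered to flat index arrays ready for the network.

    Pocket atoms occupy node rows ``[0, n_pocket)``. A CompiledGraph may also
    be the disjoint union of several complexes (see :func:`merge_compiled`):
    ``ligand_seg`` assigns each readout node to its member graph.
    """

    x_node: np.ndarray
    x_edge: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_kind: np.ndarray
    edge_bias: np.ndarray        # statistical-potential bias per edge
    ku_target: np.ndarray        # flat: target edge index per neighbor pair
    ku_neighbor: np.ndarray      # flat: neighbor edge index per neighbor pair
    ku_angle: np.ndarray         # flat × 6 one-hot angle domains
    ligand_idx: np.ndarray       # node indices retained at readout
    pocket_adj: np.ndarray       # normalized pocket covalent adjacency (with self-loops)
    n_pocket: int
    ligand_seg: np.ndarray = None   # member-graph id per readout node
    n_graphs: int = 1
    pocket_signature: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.ligand_seg is None:
            self.ligand_seg = np.zeros(len(self.ligand_idx), dtype=np.intp)

    @property
    def n_nodes(self) -> int:
        return len(self.x_node)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


def merge_compiled(graphs: list[CompiledGraph]) -> CompiledGraph:
    """Disjoint union of compiled graphs for one vectorized encoder pass.

    Nodes are re-indexed so that all pocket atoms come first (the pocket
    pre-encoder runs on one block-diagonal adjacency); edge and neighbor-pair
    arrays are offset accordingly. ``encode`` on the result returns one graph
    vector per member, in input order.
    """
    n_pocket_total = sum(g.n_pocket for g in graphs)
    maps = []
    pocket_off, rest_off = 0, n_pocket_total
    for g in graphs:
        m = np.empty(g.n_nodes, dtype=np.intp)
        m[:g.n_pocket] = pocket_off + np.arange(g.n_pocket)
        m[g.n_pocket:] = rest_off + np.arange(g.n_nodes - g.n_pocket)
        pocket_off += g.n_pocket
        rest_off += g.n_nodes - g.n_pocket
        maps.append(m)

    x_node = np.concatenate(
        [g.x_node[:g.n_pocket] for g in graphs] + [g.x_node[g.n_pocket:] for g in graphs])
    adj = np.zeros((n_pocket_total, n_pocket_total))
    off = 0
    for g in graphs:
        adj[off:off + g.n_pocket, off:off + g.n_pocket] = g.pocket_adj
        off += g.n_pocket

    edge_off = np.cumsum([0] + [g.n_edges for g in graphs])
    return CompiledGraph(
        x_node=x_node,
        x_edge=np.concatenate([g.x_edge for g in graphs]),
        edge_src=np.concatenate([m[g.edge_src] for g, m in zip(graphs, maps)]),
        edge_dst=np.concatenate([m[g.edge_dst] for g, m in zip(graphs, maps)]),
        edge_kind=np.concatenate([g.edge_kind for g in graphs]),
        edge_bias=np.concatenate([g.edge_bias for g in graphs]),
        ku_target=np.concatenate([g.ku_target + o for g, o in zip(graphs, edge_off)]),
        ku_neighbor=np.concatenate([g.ku_neighbor + o for g, o in zip(graphs, edge_off)]),
        ku_angle=np.concatenate([g.ku_angle for g in graphs]),
        ligand_idx=np.concatenate([m[g.ligand_idx] for g, m in zip(graphs, maps)]),
        pocket_adj=adj,
        n_pocket=n_pocket_total,
        ligand_seg=np.concatenate(
            [np.full(len(g.ligand_idx), gi, dtype=np.intp) for gi, g in enumerate(graphs)]),
        n_graphs=len(graphs),
        name="merged",
    )


def compile_graph(graph: ComplexGraph, table: PotentialTable | None,
                  name: str = "") -> CompiledGraph:
    """Precompute neighbor-pair index arrays, angle domains, and biases."""
    E = graph.n_edges
    incoming: list[list[int]] = [[] for _ in range(graph.n_nodes)]
    for e in range(E):
        incoming[graph.edge_dst[e]].append(e)

    ku_t, ku_n, ku_a = [], [], []
    coords = graph.node_coords
    for e in range(E):
        u, v = graph.edge_src[e], graph.edge_dst[e]
        for e2 in incoming[u]:
            k = graph.edge_src[e2]
            if k == v:
                continue
            a = coords[k] - coords[u]
            b = coords[v] - coords[u]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            cosang = np.clip(a @ b / denom, -1.0, 1.0) if denom > 0 else 1.0
            ku_t.append(e)
            ku_n.append(e2)
            ku_a.append(angle_divider(float(np.arccos(cosang))))

    n_p = graph.n_pocket_atoms
    adj = np.eye(n_p)
    for i, j in graph.pocket_bonds:
        adj[i, j] = adj[j, i] = 1.0
    dinv = 1.0 / np.sqrt(adj.sum(axis=1))
    adj = adj * dinv[:, None] * dinv[None, :]

    pocket_elems = tuple(graph.node_element[i] for i in range(n_p))
    signature = (n_p, pocket_elems, tuple(np.round(graph.node_coords[:n_p].ravel(), 3)))

    return CompiledGraph(
        x_node=graph.node_features,
        x_edge=graph.edge_features,
        edge_src=graph.edge_src,
        edge_dst=graph.edge_dst,
        edge_kind=graph.edge_kind,
        edge_bias=edge_bias_array(table, graph),
        ku_target=np.asarray(ku_t, dtype=np.intp),
        ku_neighbor=np.asarray(ku_n, dtype=np.intp),
        ku_angle=np.asarray(ku_a, dtype=np.float64).reshape(-1, 6),
        ligand_idx=np.nonzero(graph.node_origin == 1)[0],
        pocket_adj=adj,
        n_pocket=n_p,
        pocket_signature=signature,
        name=name,
    )


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_in, fan_out))


class PairRankNet:
    """The Siamese encoder + dual heads, on the package's autodiff engine."""

    def __init__(self, config: NetworkConfig | None = None,
                 potential_table: PotentialTable | None = None):
        self.config = config or NetworkConfig()
        self.table = potential_table
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(self.config.seed)
        self._build_params()
        self.last_attention: list[dict] | None = None

    # --------------------------------------------------------------- params
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _add_linear(self, name: str, fan_in: int, fan_out: int) -> None:
        self._add(f"{name}.W", _xavier(self._rng, fan_in, fan_out))
        self._add(f"{name}.b", np.zeros(fan_out))

    def _add_ln(self, name: str, m: int) -> None:
        self._add(f"{name}.g", np.ones(m))
        self._add(f"{name}.b", np.zeros(m))

    def _build_params(self) -> None:
        m = self.config.m
        for d in range(self.config.pocket_depth):
            self._add_linear(f"gcn.{d}", L_NODE, L_NODE)
        self._add_linear("init.node", L_NODE, m)
        self._add_linear("init.edge", L_EDGE, m // 2)
        self._add_linear("init.cat", m + m // 2, m)
        for l in range(self.config.n_layers):
            for blk in ("daee", "den"):
                self._add_linear(f"{blk}.{l}.q", m, m)
                self._add_linear(f"{blk}.{l}.k", m, m)
                self._add(f"{blk}.{l}.w", _xavier(self._rng, m, 1))
                self._add(f"{blk}.{l}.W1", _xavier(self._rng, m, m))
                self._add(f"{blk}.{l}.W2", _xavier(self._rng, m, m))
                self._add_ln(f"{blk}.{l}.ln1", m)
                self._add_ln(f"{blk}.{l}.ln2", m)
            self._add(f"daee.{l}.Wang", _xavier(self._rng, 6, m))
        self._add("readout.Wa", _xavier(self._rng, m, m))
        self._add("readout.Wb", _xavier(self._rng, m, m))
        self._add("readout.w", _xavier(self._rng, m, 1))
        self._add("readout.Wc", _xavier(self._rng, m, m))
        for gate in ("z", "r", "n"):
            self._add(f"readout.gru.W{gate}", _xavier(self._rng, m, m))
            self._add(f"readout.gru.U{gate}", _xavier(self._rng, m, m))
            self._add(f"readout.gru.b{gate}", np.zeros(m))
        for head in ("reg_head", "cls_head"):
            self._add_linear(f"{head}.0", 3 * m, m)
            self._add_linear(f"{head}.1", m, m // 2)
            self._add_linear(f"{head}.2", m // 2, 1)

    def _lin(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _res(self, name: str, z: Tensor) -> Tensor:
        return layer_norm(z, self.params[f"{name}.g"], self.params[f"{name}.b"])

    # --------------------------------------------------------------- encoder
    def encode(self, cg: CompiledGraph, train: bool = False,
               rng: np.random.Generator | None = None,
               mask_nodes: np.ndarray | None = None,
               record: list | None = None) -> Tensor:
        """Graph-level ligand representation(s), a (n_graphs, m) tensor.

        ``mask_nodes`` (global node indices) zeroes those ligand hidden
        states right before the readout — used by substructure masking.
        """
        if len(cg.ligand_idx) == 0:
            raise ValueError("no ligand nodes to read out")
        slope = self.config.leaky_slope
        drop = self.config.dropout if train else 0.0

        # Pocket pre-encoding over its covalent graph only.
        x = Tensor(cg.x_node)
        hp = gather_rows(x, np.arange(cg.n_pocket))
        rest = gather_rows(x, np.arange(cg.n_pocket, cg.n_nodes))
        adj = Tensor(cg.pocket_adj)
        for d in range(self.config.pocket_depth):
            hp = (adj @ self._lin(f"gcn.{d}", hp)).relu()
        x = concat([hp, rest], axis=0)

        # Initial hidden representations.
        hv = self._lin("init.node", x).relu()
        xe = self._lin("init.edge", Tensor(cg.x_edge)).relu()
        he = self._lin("init.cat",
                       concat([gather_rows(hv, cg.edge_src), xe], axis=1)).relu()

        E, n = cg.n_edges, cg.n_nodes
        bias = Tensor(cg.edge_bias)
        for l in range(self.config.n_layers):
            # DAEE: edge-to-edge attention over KU with angle embedding + bias.
            q = self._lin(f"daee.{l}.q", he)
            k = self._lin(f"daee.{l}.k", he)
            qf = gather_rows(q, cg.ku_target)
            kf = gather_rows(k, cg.ku_neighbor)
            ang = Tensor(cg.ku_angle) @ self.params[f"daee.{l}.Wang"]
            scores = ((qf + kf + ang).leaky_relu(slope)
                      @ self.params[f"daee.{l}.w"]).reshape(-1)
            scores = scores + gather_rows(bias.reshape(-1, 1), cg.ku_neighbor).reshape(-1)
            alpha_e = segment_softmax(scores, cg.ku_target, E)
            msg = segment_sum(alpha_e.reshape(-1, 1) * kf, cg.ku_target, E)
            branch = (msg @ self.params[f"daee.{l}.W1"]).relu() @ self.params[f"daee.{l}.W2"]
            branch = dropout(branch, drop, rng)
            he = self._res(f"daee.{l}.ln2", self._res(f"daee.{l}.ln1", he + branch))

            # DEN: node update attending over incoming edges (same-layer edge states).
            qn = self._lin(f"den.{l}.q", hv)
            kn = self._lin(f"den.{l}.k", hv)
            sc = ((gather_rows(qn, cg.edge_dst) + gather_rows(kn, cg.edge_src))
                  .leaky_relu(slope) @ self.params[f"den.{l}.w"]).reshape(-1)
            sc = sc + bias
            alpha_n = segment_softmax(sc, cg.edge_dst, n)
            msg = segment_sum(alpha_n.reshape(-1, 1) * he, cg.edge_dst, n)
            branch = (msg @ self.params[f"den.{l}.W1"]).relu() @ self.params[f"den.{l}.W2"]
            branch = dropout(branch, drop, rng)
            hv = self._res(f"den.{l}.ln2", self._res(f"den.{l}.ln1", hv + branch))

            if record is not None:
                record.append({
                    "layer": l,
                    "daee_alpha": alpha_e.data.copy(),
                    "daee_target": cg.ku_target,
                    "daee_neighbor": cg.ku_neighbor,
                    "den_alpha": alpha_n.data.copy(),
                })

        # Attentive super-node readout over ligand nodes only.
        hlig = gather_rows(hv, cg.ligand_idx)
        if mask_nodes is not None and len(mask_nodes):
            keep = np.ones(len(cg.ligand_idx))
            pos = {int(g): i for i, g in enumerate(cg.ligand_idx)}
            for gidx in mask_nodes:
                if int(gidx) in pos:
                    keep[pos[int(gidx)]] = 0.0
            hlig = hlig * Tensor(keep[:, None])
        seg, G = cg.ligand_seg, cg.n_graphs
        counts = np.bincount(seg, minlength=G).astype(float).reshape(-1, 1)
        s = segment_sum(hlig, seg, G) * Tensor(1.0 / counts)
        for _ in range(self.config.readout_steps):
            sc = ((gather_rows(s, seg) @ self.params["readout.Wa"]
                   + hlig @ self.params["readout.Wb"])
                  .leaky_relu(slope) @ self.params["readout.w"]).reshape(-1)
            alpha = segment_softmax(sc, seg, G)
            c = segment_sum(alpha.reshape(-1, 1) * (hlig @ self.params["readout.Wc"]),
                            seg, G)
            z = (c @ self.params["readout.gru.Wz"] + s @ self.params["readout.gru.Uz"]
                 + self.params["readout.gru.bz"]).sigmoid()
            r = (c @ self.params["readout.gru.Wr"] + s @ self.params["readout.gru.Ur"]
                 + self.params["readout.gru.br"]).sigmoid()
            cand = (c @ self.params["readout.gru.Wn"]
                    + (r * s) @ self.params["readout.gru.Un"]
                    + self.params["readout.gru.bn"]).tanh()
            s = (1.0 - z) * cand + z * s
        return s

    # ------------------------------------------------------------------ heads
    @staticmethod
    def pair_representation(x_i: Tensor, x_j: Tensor) -> Tensor:
        """x_i ⊕ x_j ⊕ (x_i − x_j), dimension 3m."""
        if x_i.shape != x_j.shape:
            raise ValueError("pair representation needs equal dimensions")
        return concat([x_i, x_j, x_i - x_j], axis=-1)

    def _head(self, name: str, xt: Tensor) -> Tensor:
        h = self._lin(f"{name}.0", xt).relu()
        h = self._lin(f"{name}.1", h).relu()
        return self._lin(f"{name}.2", h)

    def pair_output(self, x_i: Tensor, x_j: Tensor) -> tuple[Tensor, Tensor]:
        """(ŷ, classification logit) for a batch of pair representations."""
        xt = self.pair_representation(x_i, x_j)
        return self._head("reg_head", xt), self._head("cls_head", xt)

    def forward_pair(self, cg_i: CompiledGraph, cg_j: CompiledGraph,
                     record_attention: bool = False) -> tuple[float, float]:
        """Deterministic inference on one complex pair: (ŷ(i,j), p̂(i,j))."""
        if cg_i.pocket_signature != cg_j.pocket_signature:
            warnings.warn("pocket structures of the two complexes differ; "
                          "the model assumes an identical pocket", stacklevel=2)
        rec_i: list | None = [] if record_attention else None
        rec_j: list | None = [] if record_attention else None
        x_i = self.encode(cg_i, record=rec_i)
        x_j = self.encode(cg_j, record=rec_j)
        y, logit = self.pair_output(x_i, x_j)
        if record_attention:
            self.last_attention = [{"branch": "i", "records": rec_i},
                                   {"branch": "j", "records": rec_j}]
        return float(y.data[0, 0]), float(logit.sigmoid().data[0, 0])

    # --------------------------------------------------------- serialization
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)
            p.grad = None

    def save(self, path: str) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str, potential_table: PotentialTable | None = None) -> "PairRankNet":
        blob = np.load(path, allow_pickle=False)
        config = NetworkConfig(**json.loads(str(blob["__config__"])))
        model = cls(config, potential_table)
        model.load_state_dict({k: blob[k] for k in blob.files if k != "__config__"})
        return model

    def clone(self) -> "PairRankNet":
        twin = PairRankNet(self.config, self.table)
        twin.load_state_dict(self.state_dict())
        return twin
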