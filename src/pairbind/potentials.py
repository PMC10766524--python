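"""Atom-pairwise statistical potentials and the attention bias term.

Knowledge-based potentials bias the edge-to-edge and edge-to-node attention
of the network: an edge between atom types with a favorable contact geometry
gets a larger pre-softmax score. The bias for a directed edge is

* ``1``                        for covalent bonds,
* ``2·ln P(type_k, type_u, dist)`` for virtual edges whose atom types the
  table covers,
* ``0.8``                      when either type is uncovered (virtual nodes,
  exotic elements).

``P`` is a strictly positive type×type×distance lookup. A Boltzmann-inverted
distance-histogram estimator (:func:`fit_reference_potential`) builds such a
table from observed ligand–pocket contacts, and a small default table fitted
on the bundled synthetic complexes ships with the package.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass

import numpy as np

from .graph import COVALENT, ComplexGraph, VIRTUAL_DISTANCE

COVALENT_BIAS = 1.0
UNCOVERED_BIAS = 0.8
DEFAULT_BIN_WIDTH = 0.25  # Å
DEFAULT_MAX_DIST = 5.0    # Å


@dataclass
class PotentialTable:
    """P(type_k, type_u, distance bin): symmetric, strictly positive."""

    alphabet: list[str]
    bin_edges: np.ndarray       # (B+1,), covering (0, max_dist]
    values: np.ndarray          # (T, T, B), > 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        t, b = len(self.alphabet), len(self.bin_edges) - 1
        if self.values.shape != (t, t, b):
            raise ValueError("table shape inconsistent with alphabet/bins")
        if not np.all(self.values > 0):
            raise ValueError("potential values must be strictly positive")
        if not np.allclose(self.values, np.transpose(self.values, (1, 0, 2))):
            raise ValueError("potential table must be symmetric in its type arguments")
        self._index = {t: i for i, t in enumerate(self.alphabet)}

    def covers(self, atom_type: str) -> bool:
        return atom_type in self._index

    def bin_of(self, dist: float) -> int:
        """Bin index for a distance; out-of-range distances clamp to the ends."""
        b = int(np.searchsorted(self.bin_edges, dist, side="left")) - 1
        return min(max(b, 0), len(self.bin_edges) - 2)

    def lookup(self, type_k: str, type_u: str, dist: float) -> float:
        return float(self.values[self._index[type_k], self._index[type_u], self.bin_of(dist)])

    # ----------------------------------------------------------- persistence
    def to_json(self) -> str:
        return json.dumps({
            "alphabet": self.alphabet,
            "bin_edges": self.bin_edges.tolist(),
            "values": self.values.ravel().tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PotentialTable":
        d = json.loads(text)
        t, b = len(d["alphabet"]), len(d["bin_edges"]) - 1
        return cls(d["alphabet"], np.asarray(d["bin_edges"]),
                   np.asarray(d["values"]).reshape(t, t, b))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "PotentialTable":
        with open(path) as fh:
            return cls.from_json(fh.read())


def pairwise_bias(table: PotentialTable | None, type_k: str, type_u: str,
                  dist: float, edge_kind: int) -> float:
    """Attention bias p_{k,u} for one directed edge.

    Covalent edges return exactly ``1``; virtual edges return
    ``2·ln P(type_k, type_u, dist)`` when both types are covered, and exactly
    ``0.8`` otherwise. The constants are deliberate and not silently
    configurable.
    """
    if edge_kind == COVALENT:
        return COVALENT_BIAS
    if table is None or not (table.covers(type_k) and table.covers(type_u)):
        return UNCOVERED_BIAS
    return 2.0 * math.log(table.lookup(type_k, type_u, dist))


def edge_bias_array(table: PotentialTable | None, graph: ComplexGraph) -> np.ndarray:
    """Vector of p biases, one per directed edge of ``graph``."""
    out = np.empty(graph.n_edges)
    for e in range(graph.n_edges):
        k, u = graph.edge_src[e], graph.edge_dst[e]
        out[e] = pairwise_bias(table, graph.node_element[k], graph.node_element[u],
                               float(graph.edge_dist[e]), int(graph.edge_kind[e]))
    return out


def fit_reference_potential(complexes: list[ComplexGraph],
                            bin_width: float = DEFAULT_BIN_WIDTH,
                            max_dist: float = DEFAULT_MAX_DIST,
                            pseudocount: float = 0.5) -> PotentialTable:
    """Boltzmann-inverted distance-histogram potential from observed contacts.

    For each atom-type pair the observed virtual-distance-edge histogram is
    divided by the type-agnostic distance-shell histogram:

        P(t1, t2, b) = (f_obs(t1, t2, b) + λ/B) / (f_ref(b) + λ/B)

    with pseudocount λ spread over the B bins, so uniform synthetic contacts
    give P ≈ 1 everywhere. Values are clipped to [1e-3, 1e3].
    """
    n_bins = int(round(max_dist / bin_width))
    edges = np.linspace(0.0, max_dist, n_bins + 1)

    types: set[str] = set()
    contacts: list[tuple[str, str, float]] = []
    for g in complexes:
        for e in np.nonzero(g.edge_kind == VIRTUAL_DISTANCE)[0]:
            k, u = g.edge_src[e], g.edge_dst[e]
            tk, tu = g.node_element[k], g.node_element[u]
            if tk and tu:
                contacts.append((tk, tu, float(g.edge_dist[e])))
                types.update((tk, tu))
    if not contacts:
        raise ValueError("no virtual distance edges to fit a potential on")

    alphabet = sorted(types)
    index = {t: i for i, t in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), len(alphabet), n_bins))
    ref = np.zeros(n_bins)
    for tk, tu, d in contacts:
        b = min(max(int(np.searchsorted(edges, d, side="left")) - 1, 0), n_bins - 1)
        i, j = index[tk], index[tu]
        counts[i, j, b] += 1.0
        if i != j:
            counts[j, i, b] += 1.0
        ref[b] += 1.0

    ps = pseudocount / n_bins
    f_obs = (counts + ps) / (counts.sum(axis=2, keepdims=True) + pseudocount)
    f_ref = (ref + ps) / (ref.sum() + pseudocount)
    values = np.clip(f_obs / f_ref[None, None, :], 1e-3, 1e3)
    values = 0.5 * (values + np.transpose(values, (1, 0, 2)))
    return PotentialTable(alphabet, edges, values)


def default_table() -> PotentialTable:
    """The bundled potential table fitted on the packaged synthetic complexes."""
    text = importlib.resources.files("pairbind.data").joinpath(
        "default_potentials.json").read_text()
    return PotentialTable.from_json(text)
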