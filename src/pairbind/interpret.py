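"""Model interpretability: attention maps and substructure-mask attribution.

Two complementary views of what drives a prediction:

* **Atom level** — the attention weights of the last distance-aware
  edge-to-node layer, one per directed edge. High attention on a
  ligand–pocket virtual distance edge flags a candidate key interaction.
* **Substructure level** — substructure-mask explanation: the ligand is cut
  into chemically meaningful fragments (BRICS by default), each fragment's
  node hidden states are zeroed at the readout phase, and the drop in the
  pairwise prediction ŷ − ŷ_sub is that fragment's attribution. Scores are
  normalized to sum to 1; with mixed signs the normalized values can leave
  [0, 1], so the raw scores are always reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .graph import ComplexGraph, EDGE_KIND_NAMES
from .network import CompiledGraph, PairRankNet


@dataclass
class AttentionMap:
    """Per-directed-edge attention of one encoder layer (last DEN by default)."""

    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_kind: np.ndarray
    alpha: np.ndarray
    layer: int

    def __post_init__(self):
        # Incoming attention of every node with >= 1 incoming edge sums to 1.
        sums = np.zeros(int(self.edge_dst.max()) + 1 if len(self.edge_dst) else 0)
        np.add.at(sums, self.edge_dst, self.alpha)
        occupied = np.unique(self.edge_dst)
        if len(occupied) and not np.allclose(sums[occupied], 1.0, atol=1e-8):
            raise ValueError("attention over incoming edges must sum to 1 per node")

    def incoming(self, node: int) -> list[tuple[int, str, float]]:
        """(source node, edge kind, attention) for every edge into ``node``."""
        idx = np.nonzero(self.edge_dst == node)[0]
        return [(int(self.edge_src[e]), EDGE_KIND_NAMES[int(self.edge_kind[e])],
                 float(self.alpha[e])) for e in idx]

    def to_json(self) -> str:
        return json.dumps({
            "layer": self.layer,
            "edges": [{"src": int(s), "dst": int(d), "kind": EDGE_KIND_NAMES[int(k)],
                       "alpha": float(a)}
                      for s, d, k, a in zip(self.edge_src, self.edge_dst,
                                            self.edge_kind, self.alpha)],
        })


def extract_attention(model: PairRankNet, cg_i: CompiledGraph, cg_j: CompiledGraph,
                      branch: str = "i") -> AttentionMap:
    """Attention of the last edge-to-node (DEN) layer for one branch of a pair.

    The forward pass is re-run with recording enabled; recording does not
    perturb the prediction.
    """
    model.forward_pair(cg_i, cg_j, record_attention=True)
    if model.last_attention is None:
        raise RuntimeError("attention recording disabled or forward pass missing")
    records = model.last_attention[0 if branch == "i" else 1]["records"]
    last = records[-1]
    cg = cg_i if branch == "i" else cg_j
    return AttentionMap(edge_src=cg.edge_src, edge_dst=cg.edge_dst,
                        edge_kind=cg.edge_kind, alpha=last["den_alpha"],
                        layer=last["layer"])


@dataclass
class AttributionResult:
    """Raw and normalized substructure attributions for one compound."""

    substructures: list[tuple[int, ...]]   # ligand atom indices per fragment
    raw: np.ndarray                        # ŷ − ŷ_sub per fragment
    normalized: np.ndarray                 # raw / Σ raw
    y_hat: float
    mixed_sign: bool = field(init=False)

    def __post_init__(self):
        self.mixed_sign = bool((self.raw > 0).any() and (self.raw < 0).any())

    def to_json(self) -> str:
        return json.dumps({
            "y_hat": self.y_hat,
            "substructures": [list(map(int, s)) for s in self.substructures],
            "attribution": self.raw.tolist(),
            "attribution_normalized": self.normalized.tolist(),
            "mixed_sign": self.mixed_sign,
        })


def brics_substructures(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Partition heavy atoms into BRICS fragments (whole molecule if uncuttable)."""
    bonds = [mol.GetBondBetweenAtoms(i, j).GetIdx()
             for (i, j), _ in BRICS.FindBRICSBonds(mol)]
    if not bonds:
        return [tuple(range(mol.GetNumAtoms()))]
    frag = Chem.FragmentOnBonds(mol, bonds, addDummies=False)
    return [tuple(f) for f in Chem.GetMolFrags(frag)]


def merge_groups(substructures: list[tuple[int, ...]],
                 groups: list[list[int]]) -> list[tuple[int, ...]]:
    """Manually merge fragments (e.g. the two halves of an amide).

    ``groups`` lists fragment indices to fuse; untouched fragments pass
    through in order.
    """
    merged: list[tuple[int, ...]] = []
    used: set[int] = set()
    for grp in groups:
        atoms: list[int] = []
        for gi in grp:
            atoms.extend(substructures[gi])
            used.add(gi)
        merged.append(tuple(sorted(atoms)))
    merged.extend(s for i, s in enumerate(substructures) if i not in used)
    return merged


def sme_attribution(model: PairRankNet, compound_cg: CompiledGraph,
                    compound_graph: ComplexGraph, compound_mol: Chem.Mol,
                    reference_cg: CompiledGraph,
                    substructures: list[tuple[int, ...]] | None = None) -> AttributionResult:
    """Substructure-mask attribution of a pairwise prediction.

    ŷ is the model's ΔpIC50 prediction of (compound, reference). For each
    substructure, the compound's readout is re-run with those ligand node
    states zeroed (message passing is not re-run), giving ŷ_sub; the
    attribution is ŷ − ŷ_sub. Atom indices in ``substructures`` refer to the
    ligand molecule; virtual centroid nodes are masked together with a
    fragment when the whole ring lies inside it.
    """
    if substructures is None:
        substructures = brics_substructures(compound_mol)
    _check_partition(substructures, compound_mol.GetNumAtoms())

    lig_nodes = np.nonzero(compound_graph.node_origin == 1)[0]
    real_lig = lig_nodes[~compound_graph.node_virtual[lig_nodes]]
    atom_to_node = {a: int(n) for a, n in enumerate(real_lig)}
    centroid_members = _ligand_centroid_members(compound_graph)

    x_ref = model.encode(reference_cg)
    x_full = model.encode(compound_cg)
    y_full = float(model.pair_output(x_full, x_ref)[0].data[0, 0])

    raw = np.empty(len(substructures))
    for s, sub in enumerate(substructures):
        mask = [atom_to_node[a] for a in sub]
        sub_set = set(sub)
        mask += [c for c, members in centroid_members.items()
                 if members <= sub_set]
        x_masked = model.encode(compound_cg, mask_nodes=np.asarray(mask))
        y_sub = float(model.pair_output(x_masked, x_ref)[0].data[0, 0])
        raw[s] = y_full - y_sub

    total = raw.sum()
    if abs(total) < 1e-12:
        normalized = np.zeros_like(raw)
    else:
        normalized = raw / total
    result = AttributionResult(list(substructures), raw, normalized, y_full)
    if result.mixed_sign:
        warnings.warn("mixed-sign attributions: normalized scores may leave [0, 1]; "
                      "prefer the raw scores", stacklevel=2)
    return result


def _check_partition(substructures, n_atoms: int) -> None:
    seen: list[int] = []
    for s in substructures:
        seen.extend(s)
    if sorted(seen) != list(range(n_atoms)):
        raise ValueError("substructures must partition the ligand's heavy atoms")


def _ligand_centroid_members(graph: ComplexGraph) -> dict[int, set[int]]:
    """Ligand-local atom indices of each ligand virtual centroid's ring."""
    lig_nodes = np.nonzero(graph.node_origin == 1)[0]
    real_lig = lig_nodes[~graph.node_virtual[lig_nodes]]
    node_to_atom = {int(n): a for a, n in enumerate(real_lig)}
    out: dict[int, set[int]] = {}
    for v in lig_nodes[graph.node_virtual[lig_nodes]]:
        members = {node_to_atom[int(s)] for s in graph.neighbors(int(v))
                   if int(s) in node_to_atom}
        out[int(v)] = members
    return out
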