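"""Directed pocket–ligand complex graphs with virtual nodes and edges.

The complex of a ligand and its binding pocket is represented as a directed
graph over heavy atoms. Three edge kinds exist:

* ``covalent`` — each chemical bond contributes two directed edges;
* ``virtual_distance`` — ligand↔pocket heavy-atom pairs at ≤ 5.0 Å;
* ``virtual_aromatic`` — each aromatic ring gains a virtual node at its
  centroid, connected in both directions to every ring member.

Feature vectors of virtual nodes and virtual edges are all-zero. Node
features span 15 atomic categories and edge features 5 bond categories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .structures import Structure

COVALENT = 0
VIRTUAL_DISTANCE = 1
VIRTUAL_AROMATIC = 2
EDGE_KIND_NAMES = {COVALENT: "covalent", VIRTUAL_DISTANCE: "virtual_distance",
                   VIRTUAL_AROMATIC: "virtual_aromatic"}

DISTANCE_CUTOFF = 5.0  # Å, ligand–pocket virtual distance edges
N_ANGLE_DOMAINS = 6

# ---------------------------------------------------------------------------
# Featurization schema: 15 atomic categories (4 scalars + 11 one-hot blocks)
# and 5 bond categories. Counts are asserted by the tests.
# ---------------------------------------------------------------------------
ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "other"]
DEGREES = list(range(6))
FORMAL_CHARGES = [-2, -1, 0, 1, 2]
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
    "other",
]
RING_SIZES = [3, 4, 5, 6, 7, 8]
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    "other",
]
NUM_HS = list(range(5))

N_ATOM_FEATURE_CATEGORIES = 15
N_BOND_FEATURE_CATEGORIES = 5

L_NODE = 4 + len(ELEMENTS) + len(DEGREES) + len(FORMAL_CHARGES) + len(HYBRIDIZATIONS) \
    + 1 + 1 + len(RING_SIZES) + 1 + 1 + len(CHIRAL_TAGS) + len(NUM_HS)

BOND_ORDERS = [Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE,
               Chem.BondType.AROMATIC]
BOND_STEREO = [Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOANY,
               Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE,
               Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS]
L_EDGE = len(BOND_ORDERS) + 1 + 1 + len(BOND_STEREO) + 3


def _one_hot(value, alphabet) -> list[float]:
    vec = [0.0] * len(alphabet)
    try:
        vec[alphabet.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # 'other' slot by convention (last entry)
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """15-category atomic feature vector (length ``L_NODE``).

    Scalars: atomic mass (/100), explicit valence, implicit valence, van der
    Waals radius. One-hots: element, heavy degree, formal charge,
    hybridization, aromaticity, in-ring, ring sizes 3–8, H-bond donor flag,
    H-bond acceptor flag, chirality tag, attached hydrogens. Elements outside
    the alphabet map to an "other" slot, never an exception.
    """
    pt = Chem.GetPeriodicTable()
    n_h = atom.GetTotalNumHs(includeNeighbors=True)
    sym = atom.GetSymbol()
    is_donor = float(sym in ("N", "O", "S") and n_h >= 1)
    is_acceptor = float(sym in ("N", "O") and atom.GetFormalCharge() <= 0)
    vec = [
        atom.GetMass() / 100.0,
        float(atom.GetExplicitValence()),
        float(atom.GetImplicitValence()),
        pt.GetRvdw(atom.GetAtomicNum()),
    ]
    vec += _one_hot(sym, ELEMENTS)
    vec += _one_hot(min(atom.GetDegree(), 5), DEGREES)
    vec += _one_hot(max(-2, min(2, atom.GetFormalCharge())), FORMAL_CHARGES)
    vec += _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
    vec += [float(atom.GetIsAromatic()), float(atom.IsInRing())]
    vec += [float(atom.IsInRingSize(s)) for s in RING_SIZES]
    vec += [is_donor, is_acceptor]
    vec += _one_hot(atom.GetChiralTag(), CHIRAL_TAGS)
    vec += _one_hot(min(n_h, 4), NUM_HS)
    return np.asarray(vec, dtype=np.float64)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """5-category covalent-bond feature vector (length ``L_EDGE``)."""
    vec = _one_hot(bond.GetBondType(), BOND_ORDERS)
    vec += [float(bond.GetIsConjugated()), float(bond.IsInRing())]
    vec += _one_hot(bond.GetStereo(), BOND_STEREO)
    vec += [1.0, 0.0, 0.0]  # edge-kind tag: covalent
    return np.asarray(vec, dtype=np.float64)


def angle_divider(theta: float) -> np.ndarray:
    """Map an angle in [0, π] to a one-hot over six π/6-wide domains.

    Domains are the half-open intervals [k·π/6, (k+1)·π/6); θ = π is clamped
    into the last domain. Values outside [0, π] beyond a 1e-9 numerical
    tolerance raise ``ValueError``.
    """
    if theta < -1e-9 or theta > math.pi + 1e-9:
        raise ValueError(f"angle {theta} outside [0, pi]")
    theta = min(max(theta, 0.0), math.pi)
    k = min(int(theta // (math.pi / N_ANGLE_DOMAINS)), N_ANGLE_DOMAINS - 1)
    vec = np.zeros(N_ANGLE_DOMAINS)
    vec[k] = 1.0
    return vec


@dataclass
class ComplexGraph:
    """Directed pocket–ligand graph ⟨Nd, E⟩ with precomputed features."""

    node_features: np.ndarray      # (n, L_NODE)
    node_coords: np.ndarray        # (n, 3)
    node_origin: np.ndarray        # (n,) 0 = pocket, 1 = ligand
    node_virtual: np.ndarray       # (n,) bool
    node_element: list[str]        # "" for virtual nodes
    edge_src: np.ndarray           # (E,)
    edge_dst: np.ndarray           # (E,)
    edge_kind: np.ndarray          # (E,) COVALENT / VIRTUAL_DISTANCE / VIRTUAL_AROMATIC
    edge_dist: np.ndarray          # (E,) Å
    edge_features: np.ndarray      # (E, L_EDGE)
    n_pocket_atoms: int            # real pocket atoms occupy indices [0, n_pocket_atoms)
    pocket_bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_origin)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def neighbors(self, v: int) -> np.ndarray:
        """V_nei(v): source nodes of edges pointing at v."""
        return self.edge_src[self.edge_dst == v]

    def incoming_edges(self, v: int) -> np.ndarray:
        """UV(v): indices of edges pointing at v."""
        return np.nonzero(self.edge_dst == v)[0]

    def edge_neighbors(self, e: int) -> np.ndarray:
        """KU(u→v): incoming edges of u, excluding those originating at v."""
        u, v = self.edge_src[e], self.edge_dst[e]
        mask = (self.edge_dst == u) & (self.edge_src != v)
        return np.nonzero(mask)[0]

    def to_json(self) -> str:
        """Debug dump of nodes, edges, and features."""
        return json.dumps({
            "nodes": [{
                "index": i,
                "origin": "ligand" if self.node_origin[i] else "pocket",
                "virtual": bool(self.node_virtual[i]),
                "element": self.node_element[i],
                "coords": self.node_coords[i].tolist(),
                "features": self.node_features[i].tolist(),
            } for i in range(self.n_nodes)],
            "edges": [{
                "src": int(self.edge_src[e]),
                "dst": int(self.edge_dst[e]),
                "kind": EDGE_KIND_NAMES[int(self.edge_kind[e])],
                "dist": float(self.edge_dist[e]),
                "features": self.edge_features[e].tolist(),
            } for e in range(self.n_edges)],
        })


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Symmetrized-SSSR rings whose atoms are all aromatic (one centroid each)."""
    rings = []
    for ring in Chem.GetSymmSSSR(mol):
        ring = tuple(ring)
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(ring)
    return rings


def build_complex_graph(pocket: Structure, ligand: Structure,
                        distance_cutoff: float = DISTANCE_CUTOFF) -> ComplexGraph:
    """Assemble the directed complex graph of a pocket–ligand pair.

    Covalent bonds become two directed edges each; ligand–pocket heavy-atom
    pairs at ≤ ``distance_cutoff`` Å become two directed virtual distance
    edges; every aromatic ring (in either partner) contributes one virtual
    centroid node plus two directed virtual aromatic edges per ring member.
    """
    if ligand.n_atoms == 0:
        raise ValueError("ligand has no heavy atoms")
    if pocket.n_atoms == 0:
        raise ValueError("pocket is empty")

    structures = [(pocket, 0), (ligand, 1)]
    n_pocket = pocket.n_atoms
    offsets = [0, n_pocket]

    feats, coords, origins, virtual, elements = [], [], [], [], []
    for struct, origin in structures:
        xyz = struct.coords
        for i, atom in enumerate(struct.mol.GetAtoms()):
            feats.append(featurize_atom(atom))
            coords.append(xyz[i])
            origins.append(origin)
            virtual.append(False)
            elements.append(atom.GetSymbol())

    src, dst, kind, dist, efeat = [], [], [], [], []
    pocket_bonds: list[tuple[int, int]] = []

    def add_edge_pair(i, j, k, d, fv):
        src.extend([i, j])
        dst.extend([j, i])
        kind.extend([k, k])
        dist.extend([d, d])
        efeat.extend([fv, fv])

    # Covalent edges within each partner.
    for struct, origin in structures:
        off = offsets[origin]
        xyz = struct.coords
        for bond in struct.mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            add_edge_pair(off + i, off + j, COVALENT, d, featurize_bond(bond))
            if origin == 0:
                pocket_bonds.append((i, j))

    # Virtual distance edges: real ligand atom ↔ real pocket atom at ≤ cutoff.
    pc, lc = pocket.coords, ligand.coords
    dmat = np.sqrt(((pc[:, None, :] - lc[None, :, :]) ** 2).sum(-1))
    zero_edge = np.zeros(L_EDGE)
    for pi, li in zip(*np.nonzero(dmat <= distance_cutoff)):
        add_edge_pair(int(pi), n_pocket + int(li), VIRTUAL_DISTANCE,
                      float(dmat[pi, li]), zero_edge)

    # Virtual aromatic centroid nodes for rings in both partners.
    zero_node = np.zeros(L_NODE)
    for struct, origin in structures:
        off = offsets[origin]
        xyz = struct.coords
        for ring in _aromatic_rings(struct.mol):
            centroid = xyz[list(ring)].mean(axis=0)
            vidx = len(feats)
            feats.append(zero_node)
            coords.append(centroid)
            origins.append(origin)
            virtual.append(True)
            elements.append("")
            for member in ring:
                d = float(np.linalg.norm(xyz[member] - centroid))
                add_edge_pair(off + member, vidx, VIRTUAL_AROMATIC, d, zero_edge)

    return ComplexGraph(
        node_features=np.asarray(feats),
        node_coords=np.asarray(coords),
        node_origin=np.asarray(origins, dtype=np.int8),
        node_virtual=np.asarray(virtual, dtype=bool),
        node_element=elements,
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        edge_kind=np.asarray(kind, dtype=np.int8),
        edge_dist=np.asarray(dist),
        edge_features=np.asarray(efeat) if efeat else np.zeros((0, L_EDGE)),
        n_pocket_atoms=n_pocket,
        pocket_bonds=pocket_bonds,
    )


# ---------------------------------------------------------------------------
# Pose selection against a co-crystallized reference
# ---------------------------------------------------------------------------

@dataclass
class PoseCandidate:
    mol: Chem.Mol
    score: float


def _mcs_rmsd(candidate: Chem.Mol, reference: Chem.Mol) -> float:
    """In-place heavy-atom r.m.s.d. over the maximum common substructure."""
    if candidate.HasSubstructMatch(reference):
        query = reference
    else:
        res = rdFMCS.FindMCS([candidate, reference], timeout=10)
        if res.numAtoms == 0 or res.numBonds == 0:
            raise ValueError("empty MCS: ligands are not congeneric")
        query = Chem.MolFromSmarts(res.smartsString)
    cand_match = candidate.GetSubstructMatch(query)
    ref_match = reference.GetSubstructMatch(query)
    if not cand_match or not ref_match:
        raise ValueError("empty MCS: ligands are not congeneric")
    cc = np.asarray(candidate.GetConformer().GetPositions())[list(cand_match)]
    rc = np.asarray(reference.GetConformer().GetPositions())[list(ref_match)]
    return float(np.sqrt(((cc - rc) ** 2).sum(-1).mean()))


def select_pose(candidates: list[PoseCandidate], cocrystal_reference: Chem.Mol,
                rmsd_cutoff: float = 2.0, lower_is_better: bool = True):
    """Pick the best-scored docking pose consistent with the reference binding mode.

    A pose is acceptable when its MCS r.m.s.d. against the co-crystallized
    reference pose is within ``rmsd_cutoff`` (2.0 Å). Among acceptable poses
    the most favorable docking score wins (``lower_is_better`` controls the
    score sense). Returns ``None`` when no pose is acceptable — the caller
    should discard the ligand.
    """
    acceptable = [c for c in candidates
                  if _mcs_rmsd(c.mol, cocrystal_reference) <= rmsd_cutoff]
    if not acceptable:
        return None
    key = (lambda c: c.score) if lower_is_better else (lambda c: -c.score)
    return min(acceptable, key=key)
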