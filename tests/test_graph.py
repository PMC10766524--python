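"""Complex-graph construction, featurization, angle domains, pose selection."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from pairbind.graph import (BOND_STEREO, COVALENT, ELEMENTS, L_EDGE, L_NODE,
                            N_ATOM_FEATURE_CATEGORIES, N_BOND_FEATURE_CATEGORIES,
                            PoseCandidate, VIRTUAL_AROMATIC, VIRTUAL_DISTANCE,
                            angle_divider, build_complex_graph, featurize_atom,
                            featurize_bond, select_pose)
from pairbind.structures import Structure


def _mol_with_coords(smiles: str, coords, role="ligand") -> Structure:
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*xyz))
    mol = Chem.Mol(mol)
    mol.AddConformer(conf)
    return Structure(mol, role)


def _embedded(smiles: str, seed=11, role="ligand") -> Structure:
    return Structure.from_smiles(smiles, role=role, seed=seed)


@pytest.fixture
def single_atom_pocket():
    return _mol_with_coords("O", [(0.0, 0.0, 4.0)], role="protein")


# ------------------------------------------------------------- construction

def test_ethane_plus_one_pocket_atom_edge_counts(single_atom_pocket):
    """Ethane at 4 Å from a single pocket atom: 2 covalent + 4 virtual edges."""
    ethane = _mol_with_coords("CC", [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0)])
    # distances to pocket atom: 4.0 and sqrt(1.5² + 4²) ≈ 4.27, both ≤ 5
    g = build_complex_graph(single_atom_pocket, ethane)
    kinds = Counter(g.edge_kind.tolist())
    assert kinds[COVALENT] == 2
    assert kinds[VIRTUAL_DISTANCE] == 4
    assert kinds.get(VIRTUAL_AROMATIC, 0) == 0


def test_benzene_gets_one_centroid_and_twelve_aromatic_edges(single_atom_pocket):
    benzene = _embedded("c1ccccc1")
    g = build_complex_graph(single_atom_pocket, benzene)
    assert int(g.node_virtual.sum()) == 1
    assert Counter(g.edge_kind.tolist())[VIRTUAL_AROMATIC] == 12
    centroid = g.node_coords[g.node_virtual][0]
    ring = benzene.coords
    np.testing.assert_allclose(centroid, ring.mean(axis=0), atol=1e-9)


def test_fixture_edge_counts_match_brute_force_scan(complexes7):
    """Per-kind directed-edge counts re-derived from raw coordinates (seed 7)."""
    pocket, items = complexes7
    _, lig, g = items[0]
    pc, lc = pocket.coords, lig.coords

    n_cov = pocket.mol.GetNumBonds() + lig.mol.GetNumBonds()
    n_vd = int((np.sqrt(((pc[:, None] - lc[None]) ** 2).sum(-1)) <= 5.0).sum())
    n_ar = 0
    for struct in (pocket, lig):
        for ring in Chem.GetSymmSSSR(struct.mol):
            if all(struct.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                n_ar += len(ring)

    kinds = Counter(g.edge_kind.tolist())
    assert kinds[COVALENT] == 2 * n_cov
    assert kinds[VIRTUAL_DISTANCE] == 2 * n_vd
    assert kinds.get(VIRTUAL_AROMATIC, 0) == 2 * n_ar


def test_every_edge_has_reverse_with_same_kind_and_length(complexes7):
    _, items = complexes7
    for _, _, g in items[:3]:
        fwd = {(int(s), int(d)): (int(k), round(float(l), 9))
               for s, d, k, l in zip(g.edge_src, g.edge_dst, g.edge_kind, g.edge_dist)}
        for (s, d), meta in fwd.items():
            assert fwd[(d, s)] == meta


def test_virtual_distance_edges_within_cutoff_and_cross_partner(complexes7):
    _, items = complexes7
    for _, _, g in items[:3]:
        vd = g.edge_kind == VIRTUAL_DISTANCE
        assert np.all(g.edge_dist[vd] > 0)
        assert np.all(g.edge_dist[vd] <= 5.0)
        assert np.all(g.node_origin[g.edge_src[vd]] != g.node_origin[g.edge_dst[vd]])
        assert not np.any(g.node_virtual[g.edge_src[vd]])
        assert not np.any(g.node_virtual[g.edge_dst[vd]])


def test_graph_invariant_to_ligand_atom_order(complexes7):
    """Canonical edge multiset unchanged under input atom relabeling."""
    pocket, items = complexes7
    _, lig, g1 = items[1]
    n = lig.mol.GetNumAtoms()
    perm = list(reversed(range(n)))
    permuted = Structure(Chem.RenumberAtoms(lig.mol, perm), "ligand")
    g2 = build_complex_graph(pocket, permuted)

    def canonical(g):
        return sorted(
            (int(k), round(float(dist), 6),
             tuple(np.round(g.node_coords[s], 4)), tuple(np.round(g.node_coords[d], 4)))
            for s, d, k, dist in zip(g.edge_src, g.edge_dst, g.edge_kind, g.edge_dist))

    assert canonical(g1) == canonical(g2)


def test_empty_ligand_rejected(single_atom_pocket):
    with pytest.raises(ValueError):
        mol = Chem.MolFromSmiles("[H][H]")
        mol = Chem.AddHs(mol)
        conf = Chem.Conformer(2)
        conf.SetAtomPosition(0, Point3D(0, 0, 0))
        conf.SetAtomPosition(1, Point3D(0.7, 0, 0))
        mol.AddConformer(conf)
        build_complex_graph(single_atom_pocket, Structure(mol, "ligand"))


# ------------------------------------------------------------- featurization

def test_feature_schema_has_15_atom_and_5_bond_categories():
    assert N_ATOM_FEATURE_CATEGORIES == 15
    assert N_BOND_FEATURE_CATEGORIES == 5


def test_virtual_entities_have_zero_feature_vectors(single_atom_pocket):
    g = build_complex_graph(single_atom_pocket, _embedded("c1ccccc1"))
    virt_nodes = np.nonzero(g.node_virtual)[0]
    np.testing.assert_array_equal(g.node_features[virt_nodes], 0.0)
    virt_edges = g.edge_kind != COVALENT
    np.testing.assert_array_equal(g.edge_features[virt_edges], 0.0)


def test_featurization_is_deterministic():
    mol = Chem.MolFromSmiles("c1ccccc1Cl")
    a = featurize_atom(mol.GetAtomWithIdx(0))
    b = featurize_atom(mol.GetAtomWithIdx(0))
    np.testing.assert_array_equal(a, b)


def test_aromatic_carbon_one_hot_blocks_match_schema():
    """Hand lookup of the declared schema for a benzene carbon."""
    mol = Chem.MolFromSmiles("c1ccccc1")
    v = featurize_atom(mol.GetAtomWithIdx(0))
    assert len(v) == L_NODE
    assert v[0] == pytest.approx(12.011 / 100.0, abs=1e-4)   # mass / 100
    assert v[1] == 3.0   # explicit valence (aromatic ring bonds)
    assert v[2] == 1.0   # implicit valence (the ring H)
    off = 4
    element = v[off:off + len(ELEMENTS)]
    assert element[ELEMENTS.index("C")] == 1.0 and element.sum() == 1.0
    off += len(ELEMENTS)
    degree = v[off:off + 6]
    assert degree[2] == 1.0 and degree.sum() == 1.0          # two heavy neighbors
    off += 6
    charge = v[off:off + 5]
    assert charge[2] == 1.0                                  # formal charge 0
    off += 5
    hybrid = v[off:off + 6]
    assert hybrid[1] == 1.0                                  # sp2
    off += 6
    assert v[off] == 1.0 and v[off + 1] == 1.0               # aromatic, in ring
    ring_sizes = v[off + 2:off + 8]
    assert ring_sizes[3] == 1.0                              # 6-membered ring


def test_unknown_element_maps_to_other_slot():
    mol = Chem.MolFromSmiles("[SiH4]")
    v = featurize_atom(mol.GetAtomWithIdx(0))
    element = v[4:4 + len(ELEMENTS)]
    assert element[ELEMENTS.index("other")] == 1.0


def test_bond_features_cover_declared_categories():
    mol = Chem.MolFromSmiles("C=CC=C")
    double = featurize_bond(mol.GetBondWithIdx(0))
    single = featurize_bond(mol.GetBondWithIdx(1))
    assert len(double) == L_EDGE
    assert double[1] == 1.0 and single[0] == 1.0             # order one-hots
    assert double[4] == 1.0                                  # conjugated
    assert double[6 + len(BOND_STEREO)] == 1.0               # covalent kind tag


# ------------------------------------------------------------ angle domains

def test_angle_divider_examples():
    np.testing.assert_array_equal(angle_divider(0.0), [1, 0, 0, 0, 0, 0])
    assert len(angle_divider(1.0)) == 6
    # 1.60 rad / (pi/6) = 3.055… → 4th domain (index 3)
    assert np.argmax(angle_divider(1.60)) == 3
    assert np.argmax(angle_divider(math.pi)) == 5   # clamped into last domain


@pytest.mark.parametrize("bad", [-0.1, math.pi + 0.1])
def test_angle_divider_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        angle_divider(bad)


def test_angle_domains_partition_zero_pi():
    """10⁴ uniform angles: exactly one bin fires, frequencies ≈ 1/6 within 3σ."""
    rng = np.random.default_rng(0)
    thetas = rng.uniform(0, math.pi, 10_000)
    hits = np.array([angle_divider(t) for t in thetas])
    assert np.all(hits.sum(axis=1) == 1)
    freq = hits.mean(axis=0)
    sigma = math.sqrt((1 / 6) * (5 / 6) / 10_000)
    assert np.all(np.abs(freq - 1 / 6) < 3 * sigma)


@given(st.floats(min_value=0.0, max_value=math.pi, allow_nan=False))
def test_angle_divider_bin_matches_floor_arithmetic(theta):
    k = min(int(theta // (math.pi / 6)), 5)
    assert np.argmax(angle_divider(theta)) == k


# ------------------------------------------------------------ pose selection

def _pose_from(structure: Structure, jitter: float, seed: int) -> Chem.Mol:
    rng = np.random.default_rng(seed)
    mol = Chem.Mol(structure.mol)
    conf = mol.GetConformer()
    xyz = np.asarray(conf.GetPositions()) + rng.normal(0, jitter, (mol.GetNumAtoms(), 3))
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, Point3D(*xyz[i]))
    return mol


def test_pose_within_two_angstrom_accepted():
    ref = _embedded("c1ccccc1C(=O)N")
    pose = _pose_from(ref, jitter=0.5, seed=1)
    picked = select_pose([PoseCandidate(pose, -7.0)], ref.mol)
    assert picked is not None and picked.mol is pose


def test_all_poses_beyond_cutoff_returns_none():
    ref = _embedded("c1ccccc1C(=O)N")
    far = _pose_from(ref, jitter=0.0, seed=0)
    conf = far.GetConformer()
    for i in range(far.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, Point3D(p.x + 10.0, p.y, p.z))
    assert select_pose([PoseCandidate(far, -9.0)], ref.mol) is None


def test_best_score_wins_among_acceptable_poses():
    ref = _embedded("c1ccccc1C(=O)N")
    a = _pose_from(ref, jitter=0.3, seed=2)
    b = _pose_from(ref, jitter=0.3, seed=3)
    picked = select_pose([PoseCandidate(a, -8.1), PoseCandidate(b, -7.2)], ref.mol)
    assert picked.score == -8.1
    picked_hi = select_pose([PoseCandidate(a, -8.1), PoseCandidate(b, -7.2)],
                            ref.mol, lower_is_better=False)
    assert picked_hi.score == -7.2


def test_non_congeneric_ligands_raise():
    ref = _embedded("c1ccccc1C(=O)N")
    alien = _embedded("C(F)(F)(F)F", seed=9)
    with pytest.raises(ValueError):
        select_pose([PoseCandidate(alien.mol, -5.0)], ref.mol)
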