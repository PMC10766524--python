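"""Encoder blocks, readout, Siamese heads — checked against an independent oracle.

The reference implementation in ``oracles.py`` is plain-Python scalar code
with no shared machinery; the toy graph below exercises every block
(pocket GCN, initial encodings, edge-to-edge attention with angle embedding
and potential bias, edge-to-node attention, GRU readout, pair heads),
including the degenerate empty-neighborhood cases.
"""

import numpy as np
import pytest

from pairbind.graph import COVALENT, L_EDGE, L_NODE, VIRTUAL_DISTANCE
from pairbind.network import (CompiledGraph, NetworkConfig, PairRankNet,
                              merge_compiled)
from pairbind.training import PairExample, hybrid_loss, _batch_forward
from pairbind.autodiff import Adam, Tensor

from oracles import reference_forward, reference_pair_heads

M = 2  # hidden width of the oracle toy


def _toy_graph(rng) -> tuple[CompiledGraph, dict]:
    """3 nodes (1 pocket C, ligand C–O), 4 directed edges, 2 KU pairs.

    Edges e0/e1 are the pocket↔ligand virtual distance pair (bias 0.8),
    e2/e3 the ligand covalent bond (bias 1). Edges e0 and e3 have empty
    neighbor sets, exercising the zero-message contract.
    """
    x_node = rng.normal(size=(3, L_NODE))
    x_edge = np.zeros((4, L_EDGE))
    x_edge[2] = rng.normal(size=L_EDGE)
    x_edge[3] = x_edge[2]
    angle = [0.0, 0.0, 0.0, 1.0, 0.0, 0.0]   # 90° at the shared ligand atom

    cg = CompiledGraph(
        x_node=x_node, x_edge=x_edge,
        edge_src=np.array([0, 1, 1, 2]), edge_dst=np.array([1, 0, 2, 1]),
        edge_kind=np.array([VIRTUAL_DISTANCE, VIRTUAL_DISTANCE, COVALENT, COVALENT]),
        edge_bias=np.array([0.8, 0.8, 1.0, 1.0]),
        ku_target=np.array([1, 2]), ku_neighbor=np.array([3, 0]),
        ku_angle=np.array([angle, angle]),
        ligand_idx=np.array([1, 2]),
        pocket_adj=np.array([[1.0]]), n_pocket=1)

    toy = {
        "n_pocket": 1,
        "x_node": x_node.tolist(),
        "pocket_adj": [[1.0]],
        "edges": [
            {"src": 0, "dst": 1, "features": x_edge[0].tolist(), "bias": 0.8},
            {"src": 1, "dst": 0, "features": x_edge[1].tolist(), "bias": 0.8},
            {"src": 1, "dst": 2, "features": x_edge[2].tolist(), "bias": 1.0},
            {"src": 2, "dst": 1, "features": x_edge[3].tolist(), "bias": 1.0},
        ],
        "ku_pairs": [
            {"target": 1, "neighbor": 3, "angle": angle},
            {"target": 2, "neighbor": 0, "angle": angle},
        ],
        "ligand_idx": [1, 2],
    }
    return cg, toy


@pytest.fixture(scope="module")
def toy_setup():
    rng = np.random.default_rng(42)
    model = PairRankNet(NetworkConfig(m=M, n_layers=1, pocket_depth=1,
                                      readout_steps=1, dropout=0.0, seed=0))
    # hand-set every parameter to small random values shared with the oracle
    state = {}
    for name, p in model.params.items():
        if name.endswith(("ln1.g", "ln2.g")):
            state[name] = 1.0 + 0.1 * rng.normal(size=p.data.shape)
        else:
            state[name] = 0.5 * rng.normal(size=p.data.shape)
    model.load_state_dict(state)
    W = {k: v.tolist() for k, v in state.items()}
    cg_i, toy_i = _toy_graph(np.random.default_rng(7))
    cg_j, toy_j = _toy_graph(np.random.default_rng(8))
    return model, W, (cg_i, toy_i), (cg_j, toy_j)


def test_encoder_matches_independent_oracle(toy_setup):
    model, W, (cg, toy), _ = toy_setup
    rec = []
    x = model.encode(cg, record=rec)
    ref = reference_forward(toy, W)
    np.testing.assert_allclose(x.data[0], ref["x"], atol=1e-9)


def test_attention_weights_match_oracle_softmax(toy_setup):
    model, W, (cg, toy), _ = toy_setup
    rec = []
    model.encode(cg, record=rec)
    ref = reference_forward(toy, W)
    layer = rec[-1]
    # DAEE: singleton neighborhoods → α = 1 regardless of scores
    np.testing.assert_allclose(layer["daee_alpha"], [1.0, 1.0])
    for ei, alphas in ref["daee_alpha"].items():
        got = layer["daee_alpha"][layer["daee_target"] == ei]
        np.testing.assert_allclose(got, alphas, atol=1e-12)
    # DEN: compare every per-node softmax
    for v, by_edge in ref["den_alpha"].items():
        for ei, a in by_edge.items():
            assert layer["den_alpha"][ei] == pytest.approx(a, abs=1e-12)
    # normalization within each node
    sums = np.zeros(3)
    np.add.at(sums, cg.edge_dst, layer["den_alpha"])
    np.testing.assert_allclose(sums, 1.0)


def test_pair_representation_and_heads_match_oracle(toy_setup):
    model, W, (cg_i, toy_i), (cg_j, toy_j) = toy_setup
    x_i, x_j = model.encode(cg_i), model.encode(cg_j)
    xt = model.pair_representation(x_i, x_j)
    assert xt.shape == (1, 3 * M)
    np.testing.assert_allclose(xt.data[0, 2 * M:], x_i.data[0] - x_j.data[0])

    y, logit = model.pair_output(x_i, x_j)
    ref_i = reference_forward(toy_i, W)
    ref_j = reference_forward(toy_j, W)
    xt_ref, y_ref, p_ref = reference_pair_heads(ref_i["x"], ref_j["x"], W)
    np.testing.assert_allclose(xt.data[0], xt_ref, atol=1e-9)
    assert float(y.data[0, 0]) == pytest.approx(y_ref, abs=1e-9)
    assert float(logit.sigmoid().data[0, 0]) == pytest.approx(p_ref, abs=1e-9)


def test_identical_inputs_zero_difference_block(toy_setup):
    model, _, (cg, _), _ = toy_setup
    x = model.encode(cg)
    xt = model.pair_representation(x, x)
    np.testing.assert_array_equal(xt.data[0, 2 * M:], 0.0)


def test_pair_representation_rejects_mismatched_dims():
    with pytest.raises(ValueError):
        PairRankNet.pair_representation(Tensor(np.zeros((1, 4))),
                                        Tensor(np.zeros((1, 6))))


def test_config_requires_even_hidden_width():
    with pytest.raises(ValueError):
        NetworkConfig(m=7)
    with pytest.raises(ValueError):
        NetworkConfig(n_layers=0)


def test_intermediate_edge_encoding_lives_in_half_width():
    model = PairRankNet(NetworkConfig(m=4, n_layers=1, seed=0))
    assert model.params["init.edge.W"].shape == (L_EDGE, 2)
    assert model.params["init.cat.W"].shape == (4 + 2, 4)


def test_heads_have_exactly_three_affine_layers(tiny_model):
    for head in ("reg_head", "cls_head"):
        layers = {k for k in tiny_model.params if k.startswith(head) and k.endswith(".W")}
        assert layers == {f"{head}.0.W", f"{head}.1.W", f"{head}.2.W"}
    # heads share no weights: disjoint parameter names by construction
    assert not {k for k in tiny_model.params if k.startswith("reg_head")} & \
        {k for k in tiny_model.params if k.startswith("cls_head")}


def test_probability_strictly_inside_unit_interval(tiny_model, compiled7):
    cgs = list(compiled7.values())
    _, p = tiny_model.forward_pair(cgs[0], cgs[1])
    assert 0.0 < p < 1.0


def test_zero_head_weights_give_bias_outputs(table7, compiled7):
    model = PairRankNet(NetworkConfig(m=8, n_layers=1, pocket_depth=1,
                                      readout_steps=1, dropout=0.0, seed=2), table7)
    state = model.state_dict()
    for head in ("reg_head", "cls_head"):
        for i in range(3):
            state[f"{head}.{i}.W"] = np.zeros_like(state[f"{head}.{i}.W"])
            state[f"{head}.{i}.b"] = np.zeros_like(state[f"{head}.{i}.b"])
    state["reg_head.2.b"] = np.array([0.7])
    state["cls_head.2.b"] = np.array([-0.2])
    model.load_state_dict(state)
    cgs = list(compiled7.values())
    y, p = model.forward_pair(cgs[0], cgs[1])
    assert y == pytest.approx(0.7)
    assert p == pytest.approx(1 / (1 + np.exp(0.2)))


def test_forward_is_deterministic(tiny_model, compiled7):
    cgs = list(compiled7.values())
    a = tiny_model.forward_pair(cgs[0], cgs[1])
    b = tiny_model.forward_pair(cgs[0], cgs[1])
    assert a == b


def test_same_seed_same_model():
    cfg = NetworkConfig(m=8, n_layers=1, seed=9)
    a, b = PairRankNet(cfg), PairRankNet(cfg)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k].data, b.params[k].data)


def test_prediction_invariant_to_ligand_atom_order(complexes7, table7, tiny_model):
    from rdkit import Chem
    from pairbind.graph import build_complex_graph
    from pairbind.network import compile_graph
    from pairbind.structures import Structure

    pocket, items = complexes7
    _, lig, g1 = items[2]
    perm = list(reversed(range(lig.mol.GetNumAtoms())))
    permuted = Structure(Chem.RenumberAtoms(lig.mol, perm), "ligand")
    g2 = build_complex_graph(pocket, permuted)
    cg_ref = compile_graph(items[0][2], table7)
    y1, p1 = tiny_model.forward_pair(compile_graph(g1, table7), cg_ref)
    y2, p2 = tiny_model.forward_pair(compile_graph(g2, table7), cg_ref)
    assert y1 == pytest.approx(y2, abs=1e-6)
    assert p1 == pytest.approx(p2, abs=1e-6)


def test_siamese_branches_share_parameters(tiny_model, compiled7):
    """Both branches route gradients into the single shared parameter set."""
    cgs = list(compiled7.values())
    x_i = tiny_model.encode(cgs[0])
    x_j = tiny_model.encode(cgs[1])
    y, _ = tiny_model.pair_output(x_i, x_j)
    for p in tiny_model.params.values():
        p.grad = None
    y.sum().backward()
    touched = {k for k, p in tiny_model.params.items() if p.grad is not None}
    assert any(k.startswith("init.node") for k in touched)
    assert any(k.startswith("daee.0") for k in touched)
    # the same Tensor objects serve both branches — there is no second copy
    assert len(tiny_model.params) == len({id(p) for p in tiny_model.params.values()})
    for p in tiny_model.params.values():
        p.grad = None


def test_merged_batch_equals_individual_forwards(tiny_model, compiled7):
    cgs = list(compiled7.values())[:4]
    merged = merge_compiled(cgs)
    x = tiny_model.encode(merged)
    for gi, cg in enumerate(cgs):
        np.testing.assert_allclose(x.data[gi], tiny_model.encode(cg).data[0],
                                   atol=1e-10)


def test_one_optimizer_step_reduces_pair_loss(table7, compiled7, labels7):
    model = PairRankNet(NetworkConfig(m=8, n_layers=1, pocket_depth=1,
                                      readout_steps=1, dropout=0.0, seed=5), table7)
    ids = list(compiled7)[:2]
    ex = PairExample(compiled7[ids[0]], compiled7[ids[1]],
                     labels7[ids[0]] - labels7[ids[1]])

    def loss_value():
        y, logit = _batch_forward(model, [ex], False, None)
        return hybrid_loss(y, [ex.label], logit, [ex.cls_label])

    opt = Adam(model.params, lr=1e-3)
    before = loss_value()
    opt.zero_grad()
    before.backward()
    opt.step()
    assert loss_value().item() < before.item()


def test_mismatched_pockets_warn(compiled7, table7, tiny_model):
    import dataclasses
    cgs = list(compiled7.values())
    other = dataclasses.replace(cgs[1], pocket_signature=("different",))
    with pytest.warns(UserWarning, match="pocket"):
        tiny_model.forward_pair(cgs[0], other)


def test_readout_rejects_graph_without_ligand_nodes(tiny_model, compiled7):
    import dataclasses
    cg = dataclasses.replace(list(compiled7.values())[0],
                             ligand_idx=np.array([], dtype=np.intp),
                             ligand_seg=np.array([], dtype=np.intp))
    with pytest.raises(ValueError):
        tiny_model.encode(cg)
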