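"""Independent plain-Python reference implementation of the network equations.

Everything here is deliberately written with lists, floats, and explicit
loops — no NumPy, no shared code with the package — so it can serve as an
independent oracle for the encoder blocks, readout, pair representation, and
heads on small hand-built graphs.
"""

from __future__ import annotations

import math


def matvec(W, x):
    """W is (in × out) as nested lists [row][col]; returns x @ W + nothing."""
    n_out = len(W[0])
    return [sum(x[i] * W[i][j] for i in range(len(x))) for j in range(n_out)]


def vadd(*vs):
    return [sum(t) for t in zip(*vs)]


def vsub(a, b):
    return [x - y for x, y in zip(a, b)]


def relu(v):
    return [max(0.0, x) for x in v]


def leaky_relu(v, slope=0.01):
    return [x if x > 0 else slope * x for x in v]


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def tanh_v(v):
    return [math.tanh(x) for x in v]


def dot(a, b):
    return sum(x * y for x, y in zip(a, b))


def layer_norm(v, gain, bias, eps=1e-5):
    mu = sum(v) / len(v)
    var = sum((x - mu) ** 2 for x in v) / len(v)
    return [(x - mu) / math.sqrt(var + eps) * g + b
            for x, g, b in zip(v, gain, bias)]


def softmax(scores):
    m = max(scores)
    es = [math.exp(s - m) for s in scores]
    z = sum(es)
    return [e / z for e in es]


def reference_forward(toy: dict, W: dict, slope: float = 0.01) -> dict:
    """Full forward pass of the encoder + heads on a hand-built toy graph.

    ``toy`` describes one complex: node features ``x_node`` (pocket atoms
    first), edge list with features/bias, the KU neighbor pairs with angle
    one-hots, pocket atom count, and ligand node indices. ``W`` maps the
    package's parameter names to nested-list matrices / vectors. One GCN
    depth, one message-passing layer, one readout step.
    Returns intermediate values so individual blocks can be checked.
    """
    n_pocket = toy["n_pocket"]
    x_node = [list(v) for v in toy["x_node"]]

    # Pocket pre-encoding: self-loop-normalized adjacency over pocket atoms.
    adj = toy["pocket_adj"]
    hp = []
    for i in range(n_pocket):
        proj = [vadd(matvec(W["gcn.0.W"], x_node[j]), W["gcn.0.b"])
                for j in range(n_pocket)]
        hp.append(relu([sum(adj[i][j] * proj[j][c] for j in range(n_pocket))
                        for c in range(len(proj[0]))]))
    for i in range(n_pocket):
        x_node[i] = hp[i]

    # Initial hidden representations.
    h_v = [relu(vadd(matvec(W["init.node.W"], x), W["init.node.b"])) for x in x_node]
    x_e = [relu(vadd(matvec(W["init.edge.W"], e["features"]), W["init.edge.b"]))
           for e in toy["edges"]]
    h_e = []
    for e, xp in zip(toy["edges"], x_e):
        cat = list(h_v[e["src"]]) + list(xp)
        h_e.append(relu(vadd(matvec(W["init.cat.W"], cat), W["init.cat.b"])))

    # DAEE: edge-to-edge attention with angle embedding and potential bias.
    q = [vadd(matvec(W["daee.0.q.W"], h), W["daee.0.q.b"]) for h in h_e]
    k = [vadd(matvec(W["daee.0.k.W"], h), W["daee.0.k.b"]) for h in h_e]
    w_edge = [row[0] for row in W["daee.0.w"]]
    new_h_e = []
    daee_alpha = {}
    for ei, e in enumerate(toy["edges"]):
        nbrs = [p for p in toy["ku_pairs"] if p["target"] == ei]
        if nbrs:
            eps = []
            for p in nbrs:
                ang = matvec(W["daee.0.Wang"], p["angle"])
                pre = leaky_relu(vadd(q[ei], k[p["neighbor"]], ang), slope)
                eps.append(dot(w_edge, pre) + toy["edges"][p["neighbor"]]["bias"])
            alpha = softmax(eps)
            daee_alpha[ei] = alpha
            msg = [sum(a * k[p["neighbor"]][c] for a, p in zip(alpha, nbrs))
                   for c in range(len(k[0]))]
        else:
            msg = [0.0] * len(h_e[ei])
        branch = matvec(W["daee.0.W2"], relu(matvec(W["daee.0.W1"], msg)))
        z = vadd(h_e[ei], branch)
        z = layer_norm(z, W["daee.0.ln1.g"], W["daee.0.ln1.b"])
        new_h_e.append(layer_norm(z, W["daee.0.ln2.g"], W["daee.0.ln2.b"]))
    h_e = new_h_e

    # DEN: node update attending over incoming edges (same-layer edge states).
    qn = [vadd(matvec(W["den.0.q.W"], h), W["den.0.q.b"]) for h in h_v]
    kn = [vadd(matvec(W["den.0.k.W"], h), W["den.0.k.b"]) for h in h_v]
    w_node = [row[0] for row in W["den.0.w"]]
    new_h_v = []
    den_alpha = {}
    for v in range(len(h_v)):
        inc = [ei for ei, e in enumerate(toy["edges"]) if e["dst"] == v]
        if inc:
            eps = [dot(w_node, leaky_relu(vadd(qn[v], kn[toy["edges"][ei]["src"]]), slope))
                   + toy["edges"][ei]["bias"] for ei in inc]
            alpha = softmax(eps)
            den_alpha[v] = {ei: a for ei, a in zip(inc, alpha)}
            msg = [sum(a * h_e[ei][c] for a, ei in zip(alpha, inc))
                   for c in range(len(h_e[0]))]
        else:
            msg = [0.0] * len(h_v[v])
        branch = matvec(W["den.0.W2"], relu(matvec(W["den.0.W1"], msg)))
        z = vadd(h_v[v], branch)
        z = layer_norm(z, W["den.0.ln1.g"], W["den.0.ln1.b"])
        new_h_v.append(layer_norm(z, W["den.0.ln2.g"], W["den.0.ln2.b"]))
    h_v = new_h_v

    # Attentive super-node readout over ligand nodes, one step.
    lig = [h_v[i] for i in toy["ligand_idx"]]
    m = len(lig[0])
    s = [sum(h[c] for h in lig) / len(lig) for c in range(m)]
    w_read = [row[0] for row in W["readout.w"]]
    sc = [dot(w_read, leaky_relu(vadd(matvec(W["readout.Wa"], s),
                                      matvec(W["readout.Wb"], h)), slope))
          for h in lig]
    alpha = softmax(sc)
    proj = [matvec(W["readout.Wc"], h) for h in lig]
    c_vec = [sum(a * p[cc] for a, p in zip(alpha, proj)) for cc in range(m)]
    z = [sigmoid(x) for x in vadd(matvec(W["readout.gru.Wz"], c_vec),
                                  matvec(W["readout.gru.Uz"], s), W["readout.gru.bz"])]
    r = [sigmoid(x) for x in vadd(matvec(W["readout.gru.Wr"], c_vec),
                                  matvec(W["readout.gru.Ur"], s), W["readout.gru.br"])]
    rs = [ri * si for ri, si in zip(r, s)]
    cand = tanh_v(vadd(matvec(W["readout.gru.Wn"], c_vec),
                       matvec(W["readout.gru.Un"], rs), W["readout.gru.bn"]))
    x_graph = [(1 - zi) * ci + zi * si for zi, ci, si in zip(z, cand, s)]

    return {"h_v": h_v, "h_e": h_e, "x": x_graph,
            "daee_alpha": daee_alpha, "den_alpha": den_alpha}


def reference_pair_heads(x_i, x_j, W):
    """Pair representation (⊕ with difference block) and the two 3-layer heads."""
    xt = list(x_i) + list(x_j) + vsub(x_i, x_j)

    def head(prefix):
        h = relu(vadd(matvec(W[f"{prefix}.0.W"], xt), W[f"{prefix}.0.b"]))
        h = relu(vadd(matvec(W[f"{prefix}.1.W"], h), W[f"{prefix}.1.b"]))
        return vadd(matvec(W[f"{prefix}.2.W"], h), W[f"{prefix}.2.b"])[0]

    y = head("reg_head")
    p = sigmoid(head("cls_head"))
    return xt, y, p
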