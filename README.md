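# pairbind

Siamese graph attention ranking of relative binding affinities for
congeneric ligand series.

## The problem

Lead optimization explores a series of analogs sharing a core scaffold and
asks: *which of these should we synthesize next?* Alchemical free-energy
methods answer this accurately but at enormous computational cost; docking
scores are fast but rank analogs poorly. `pairbind` takes the middle road: a
pairwise comparison network that reads the 3-D poses of **two** ligands
docked into the same protein pocket and predicts their *relative* affinity

    ΔpIC50(i, j) = pIC50(i) − pIC50(j),

eliminating the systematic error of absolute-affinity prediction and
exploiting the structural commonality of the pair.

## The model

Each pocket–ligand complex becomes a directed graph over heavy atoms:
covalent bonds, **virtual distance edges** between ligand and pocket atoms at
≤ 5.0 Å, and **virtual aromatic nodes** at ring centroids. A GCN pre-encodes
the pocket, then L alternating attention blocks run per layer:

* **edge→edge (DAEE)**: attention over the neighbor edges KU of each directed
  edge, with two physics terms — a one-hot embedding of the inter-edge angle
  θ (six π/6 domains) inside the LeakyReLU, and an additive bias from
  atom-pairwise statistical potentials:

      p(k,u) = 1                          covalent bond
             = 2·ln P(typeₖ, typeᵤ, dist) virtual edge, covered types
             = 0.8                        uncovered types

* **edge→node (DEN)**: each atom attends over its incoming edges with the
  same distance bias; updates use a double layer-norm residual.

An attentive super-node readout with a GRU cell pools the ligand atoms
(pocket dropped) into x ∈ ℝᵐ per branch, with shared weights. The pair
representation x⁽ⁱ⁾ ⊕ x⁽ʲ⁾ ⊕ (x⁽ⁱ⁾ − x⁽ʲ⁾) ∈ ℝ³ᵐ feeds two independent
3-layer heads: ΔpIC50 regression and a "ligand i binds tighter"
classification trained jointly (Loss = MSE + α·BCE, α = 1).

Given reference ligands with known activity, a candidate u is anchored via
ŷᵢ(u) = y(i) − ŷ(i, u); their mean is the prediction ŷ(u) and their
population variance σ²(u) the uncertainty. The acquisition score
a = ŷ + β·σ² (β ∈ {−2, 0, 2}) drives the active-learning campaign simulator.

The network runs on a small reverse-mode autodiff engine over NumPy
(`pairbind.autodiff`); chemistry I/O and perception use RDKit.

## Worked example

Everything runs offline on synthetic docked congeneric series (benzamide
core, substituent alphabet with planted additive pIC50 contributions,
jittered poses in a pseudo-protein cavity):

```bash
python examples/02_train_and_rank.py
```

prints (about 3 minutes on one CPU core):

```
potential table types: ['C', 'Cl', 'F', 'N', 'O']
held-out series, zero-shot (10 reference draws):
  spearman_rho: 0.853 ± 0.064
  pearson_r: 0.892 ± 0.045
  rmse_pw_pic50: 0.232 ± 0.031
```

The model, trained on five synthetic series, ranks a fresh series almost
perfectly from a single reference ligand; the pairwise r.m.s.e. is in pIC50
units (× 1.3588 for kcal/mol). The other examples cover graph building
(`01`), few-shot fine-tuning under a shifted structure–activity relationship
(`03`: ρ climbs 0.29 → 0.41 → 0.71 with 2 → 6 → 10 references),
active-learning campaigns (`04`: uncertainty-aware selection reveals ~4
compounds vs ~9 for random ordering), and attention/attribution
interpretability (`05`).

A thin CLI wraps the same library:

```bash
pairbind make-fixtures --seed 7 --out fixtures
pairbind train --fixtures fixtures --checkpoint model.npz --epochs 2 \
    --learning-rate 1e-3 --hidden 24 --layers 2
pairbind rank --checkpoint model.npz --pocket fixtures/pocket.pdb \
    --references refs.sdf --activities refs.csv --candidates cands.sdf
```

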