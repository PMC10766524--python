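# Methods

## Model

A pocket–ligand complex is a directed graph G = ⟨Nd, E⟩ over heavy atoms.
Hydrogens are stripped on input. Three edge kinds:

* **covalent** — every chemical bond contributes both directions;
* **virtual distance** — ligand↔pocket heavy-atom pairs with Euclidean
  distance ≤ 5.0 Å (both directions, length stored);
* **virtual aromatic** — each aromatic ring (symmetrized SSSR, all members
  aromatic, in ligand *and* pocket; fused systems get one centroid per ring)
  adds a virtual node at the centroid plus both directions to every member.

Virtual nodes and virtual edges carry all-zero feature vectors. Real atoms
carry 15 feature categories — scalars {atomic mass/100, explicit valence,
implicit valence, van der Waals radius} and one-hots {element
(C,N,O,S,P,F,Cl,Br,I,other), heavy degree 0–5, formal charge −2..+2,
hybridization, aromaticity, in-ring, ring sizes 3–8, H-bond donor, H-bond
acceptor, chirality tag, attached hydrogens 0–4} — and covalent bonds 5
categories {order, conjugation, in-ring, stereo, edge-kind tag}. Donor =
N/O/S bearing ≥ 1 H; acceptor = N/O with non-positive formal charge — a
deliberate simplification of SMARTS-based pharmacophore typing. Unknown
elements map to an "other" slot rather than failing.

The pocket is the set of whole residues whose minimum heavy-atom distance to
the ligand is ≤ 8.0 Å. The two complexes of a pair must share the pocket
bit-for-bit; a mismatch warns.

### Encoder

1. **Pocket pre-encoding.** A GCN (symmetric-normalized adjacency with
   self-loops, ReLU, default depth 2) updates pocket atom features over the
   pocket's covalent graph alone, before the complex is assembled.
2. **Initial encodings.** Node features project to h⁰ᵥ ∈ ℝᵐ; edge features
   project to an intermediate x′ ∈ ℝ^{m/2}; the concatenation (h⁰ᵤ, x′)
   projects to h⁰ᵤᵥ ∈ ℝᵐ (all ReLU). `m` must therefore be even.
3. **DAEE (edge→edge).** Per layer, queries/keys are affine maps of edge
   states; the pre-softmax score of neighbor edge k→u for target u→v is
   w·LeakyReLU(q + k + W_ang·onehot(θ_kuv)) plus the statistical-potential
   bias of the neighbor edge. θ_kuv is the angle at u between the raw
   coordinates of a_k, a_u, a_v (centroid coordinates for virtual nodes),
   binned into six half-open [kπ/6, (k+1)π/6) domains with θ = π clamped
   into the last. Attention normalizes over KU(u→v) = incoming edges of u
   except those from v; the message is the attention-weighted sum of key
   vectors; the update is h ← LN₂(LN₁(h_prev + dropout(W₂ ReLU(W₁ msg)))).
   Edges with empty KU receive a zero message.
4. **DEN (edge→node).** Node queries/keys, no angle term, the same per-edge
   bias; attention over incoming edges; the message aggregates the *current*
   layer's edge states (blocks alternate: edges first, then nodes); the same
   double layer-norm residual. The attention of the last DEN layer is the
   atom-level interpretability signal.
5. **Readout.** Pocket nodes are dropped; a super node initialized to the
   mean ligand state attends over ligand nodes (including ligand centroids)
   and updates through a GRU cell for `readout_steps` iterations.
   Permutation-invariant by construction.

The two branches share one parameter set. The pair representation is
x⁽ⁱ⁾ ⊕ x⁽ʲ⁾ ⊕ (x⁽ⁱ⁾ − x⁽ʲ⁾) and two independent three-layer feedforward
heads produce the ΔpIC50 regression ŷ and the classification logit (p̂ via
a logistic).

Open design points resolved here: Res(z) = LayerNorm(z) with dropout on the
pre-residual branch, applied twice as the update equations state; attention
is single-head (the score projections are single vectors); LeakyReLU slope
0.01; natural log in the potential bias; the DEN block consumes same-layer
edge states as the superscripts indicate.

### Statistical potentials

P(type_k, type_u, dist) is a symmetric, strictly positive lookup over
element-symbol pairs × 0.25 Å bins covering (0, 5] Å. The bundled default
table is Boltzmann-inverted from the synthetic fixtures' ligand–pocket
contacts: P = (f_obs + λ/B)/(f_ref + λ/B) with pseudocount λ = 0.5 spread
over B bins, clipped to [10⁻³, 10³]; uniform contacts give P ≈ 1. This is a
self-contained stand-in with the same interface and value range as published
knowledge-based potentials, not a reproduction of any published table. The
bias constants 1 (covalent) and 0.8 (uncovered types) are contractual, not
configurable.

### Training

Loss = MSE(ŷ, ỹ) + α·BCE(p̂, 1[ỹ > 0]) with α = 1; tie pairs (ỹ = 0)
carry a 0.5 soft class label and are excluded from the BCE term. Published
defaults are kept in `TrainConfig` (batch 96, lr 5·10⁻⁷, 5.75 epochs —
fractional epochs become a step budget — validation every 0.25 epoch,
patience 8 units) and `FineTuneConfig` (batch 30, lr 10⁻⁵, 10 epochs,
regression loss only so the classification head is bitwise untouched).
Optimizer: Adam, gradient-norm clip 5. Training pairs are used in both
directions (teaching antisymmetry); evaluation pairs one direction.
Training restricts pairs to Tanimoto similarity > 0.6 (Morgan radius 2,
2048 bits); evaluation pairs are never filtered. The ΔpIC50 histogram is
balanced into 0.5-wide bins with occupied-bin max/min ratio ≤ 4:1
(undersample dense bins without replacement, oversample sparse ones with
replacement, seeded).

Batches are encoded as one disjoint-union graph per step (`merge_compiled`),
which is numerically identical to per-graph encoding and is what makes CPU
training practical.

### Inference, metrics, campaigns

Anchoring: ŷᵢ(u) = y(i) − ŷ(i, u); prediction = mean, uncertainty =
population variance (1/N — a single reference gives exactly σ² = 0).
Zero-shot evaluation redraws the single reference 10× and reports mean ± SD.
Metrics: Pearson R, Spearman ρ (average ranks on ties; constant vectors are
an error, not a NaN), pairwise r.m.s.e. in pIC50 and kcal/mol. Unit bridge:
pIC50 = −ΔG/(RT·ln10) with R = 1.987·10⁻³ kcal K⁻¹ mol⁻¹, T = 297 K
(RT·ln10 ≈ 1.3588).

Campaign simulator: the earliest synthesized compound seeds the references;
each iteration scores candidates (iteration 1: ŷ from the single reference;
later: fine-tune on all pairs among current references, then a = ŷ + β·σ²)
and picks the top 3 (ties break by ligand id). Selection order counts the
initial reference as 1 (a reporting flag can exclude it). The target is the
highest-activity ligand, earliest synthesized on ties. The fine-tune set at
iteration k ≥ 2 uses all current references, the natural extension of the
second-iteration rule.

### Interpretability

Atom level: attention of the last DEN layer per directed edge, tagged by
edge kind; recording does not perturb predictions. Substructure level:
BRICS fragments (manual merging supported) are masked by zeroing their node
hidden states at readout — message passing is *not* re-run; attribution =
ŷ − ŷ_sub, normalized by the total. With mixed signs the normalized scores
can leave [0, 1]; the raw scores are always reported and a warning raised.
A ligand ring centroid is masked together with a fragment only when the
whole ring lies inside it. Attributions are not additive in general; the
additive check holds only for the linear surrogate used in the tests.

## Synthetic data generator

`SyntheticSpec` defines the study conditions: a pseudo-protein of 8
glycine-like residues (N, CA, C, O) on a jittered 6 Å spherical shell; a
benzamide core with substituents {H, F, Cl, C, N, O} at two meta positions,
contributions 0–0.9 pIC50, base 6.0, Gaussian label noise SD 0.1; 12
ligands per series; ETKDG conformers core-aligned into the cavity with
0.3 Å pose jitter (echoing docking-pose uncertainty); synthesis order =
generation order. It emulates the statistics the model consumes — element
types, covalent topology, ligand–pocket contact geometry, additive SAR —
but not protein chemistry, induced fit, tautomers/protonation, or
non-additive SAR; passing tests demonstrate the machinery recovers a
planted signal, not real-data accuracy.

## Reference experiments (desk scale)

`pairbind.experiments` freezes the protocols: 5 training series + 1
validation series per seed, a 24-wide 2-layer encoder with 1 readout step
and no dropout, lr 3·10⁻⁴ for 16 epochs at batch 110 — an elevated learning
rate and small width chosen so a full train/evaluate cycle takes ~40 s on
one core. Zero-shot recovery evaluates a fresh series (generator seeds
disjoint from training). The few-shot experiment uses a 16-ligand held-out
series whose substituent contributions are permuted (`SHIFTED_SAR`): with
the training SAR the zero-shot ranking is already near-ceiling and
fine-tuning has nothing to show; under a new SAR the benefit of 2 → 10
references is visible and monotone. Few-shot protocol: 20 epochs at
lr 10⁻³ on bidirectional reference pairs, 5 reference draws per count.
Campaigns use 16-ligand series with a heteroscedastic noisy oracle
(SD 0.5×U(0.5, 1.5)) over 6 seeds against a seeded uniform-random baseline.

## Known limitations

* Element-symbol atom typing for the potentials; published knowledge-based
  potentials type atoms more finely.
* The pseudo-pocket has no aromatic residues, so pocket-side centroid nodes
  are exercised only in unit tests.
* Virtual nodes receive no virtual distance edges (only real atoms do).
* CPU-scale: the engine is float64 NumPy; training beyond a few thousand
  pairs per epoch calls for a GPU framework.
* Pose selection trusts the maximum common substructure; degenerate MCS
  (no shared bond) is treated as non-congeneric and rejected.
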