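"""Desk-scale synthetic docked congeneric series with planted affinities.

Every stage of the pipeline — graph building, potentials, training,
inference, active learning, attribution — is testable offline against data
whose ground truth is known by construction:

* a pseudo-protein pocket of glycine-like residues on a jittered spherical
  shell enclosing a cavity at the origin;
* a congeneric series around a benzamide core, enumerated over a substituent
  alphabet at two meta positions of the ring, with 3-D conformers embedded,
  core-aligned into the cavity, and jittered to emulate docking-pose noise;
* ground-truth pIC50 = base + Σ substituent contributions + Gaussian noise,
  synthesis order = generation order.

The geometry is deliberately minimal: it preserves the statistics the model
consumes (element types, covalent topology, ligand–pocket contact distances)
without pretending to be a physical protein.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .pairdata import CongenericSeries, Ligand
from .structures import Structure, extract_pocket

DEFAULT_SUBSTITUENTS = {
    "H": 0.0, "F": 0.15, "Cl": 0.3, "C": 0.45, "N": 0.65, "O": 0.9,
}
CORE_TEMPLATE = "NC(=O)c1cc{r1}cc{r2}c1"
CORE_QUERY_SMILES = "NC(=O)c1ccccc1"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic series; the defaults are the study conditions."""

    seed: int = 7
    n_residues: int = 8
    pocket_radius: float = 6.0          # Å, shell around the cavity center
    core_smiles: str = CORE_TEMPLATE
    substituents: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUENTS))
    base_pic50: float = 6.0
    noise_sd: float = 0.1               # pIC50 units
    n_ligands: int = 12
    pose_jitter_sd: float = 0.3         # Å

    def __post_init__(self):
        if self.n_ligands < 2:
            raise ValueError("a pairable series needs at least 2 ligands")
        if not all(math.isfinite(v) for v in self.substituents.values()):
            raise ValueError("substituent contributions must be finite")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly even directions on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_pocket(spec: SyntheticSpec) -> Structure:
    """A rigid pseudo-protein: glycine-like residues on a jittered shell.

    Each residue carries N, CA, C, O heavy atoms with standard-ish bond
    lengths; the cavity center is the origin. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    dirs = _fibonacci_sphere(spec.n_residues)
    em = Chem.RWMol()
    conf_pos: list[np.ndarray] = []

    for ri in range(spec.n_residues):
        d = dirs[ri] + rng.normal(0.0, 0.05, 3)
        d /= np.linalg.norm(d)
        # local tangent frame
        t1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(d, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(d, t1)
        ca = d * (spec.pocket_radius + rng.normal(0.0, 0.2))
        atoms = {
            " N  ": ("N", ca + 1.45 * t1),
            " CA ": ("C", ca),
            " C  ": ("C", ca + 1.52 * t2),
            " O  ": ("O", ca + 1.52 * t2 + 1.23 * d),
        }
        idx = {}
        for name, (elem, pos) in atoms.items():
            a = Chem.Atom(elem)
            info = Chem.AtomPDBResidueInfo()
            info.SetName(name)
            info.SetResidueName("GLY")
            info.SetResidueNumber(ri + 1)
            info.SetChainId("A")
            a.SetMonomerInfo(info)
            a.SetNoImplicit(True)
            idx[name] = em.AddAtom(a)
            conf_pos.append(np.asarray(pos))
        em.AddBond(idx[" N  "], idx[" CA "], Chem.BondType.SINGLE)
        em.AddBond(idx[" CA "], idx[" C  "], Chem.BondType.SINGLE)
        em.AddBond(idx[" C  "], idx[" O  "], Chem.BondType.DOUBLE)

    mol = em.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(conf_pos):
        conf.SetAtomPosition(i, Point3D(*(float(x) for x in p)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, catchErrors=True)
    return Structure(mol, "protein", name=f"synthetic-pocket-{spec.seed}")


def _ligand_smiles(spec: SyntheticSpec) -> list[tuple[str, tuple[str, str]]]:
    """Deterministically enumerated (smiles, (sub1, sub2)) combinations."""
    names = sorted(spec.substituents)
    combos = [(a, b) for ai, a in enumerate(names) for b in names[ai:]]
    out = []
    for r1, r2 in combos:
        s1 = "" if r1 == "H" else f"({r1})"
        s2 = "" if r2 == "H" else f"({r2})"
        out.append((spec.core_smiles.format(r1=s1, r2=s2), (r1, r2)))
    return out


def make_series(spec: SyntheticSpec) -> tuple[CongenericSeries, dict]:
    """A congeneric series with 3-D poses placed in the cavity.

    Ligands enumerate core+substituent combinations (shuffled per seed, first
    ``n_ligands`` kept; synthesis order = generation order). Conformers are
    ETKDG-embedded, aligned onto the first ligand's core so the series shares
    a binding mode, centered in the cavity, and jittered by
    ``pose_jitter_sd``. Returns the series plus the ground-truth dict.
    Ligands that fail 3-D embedding are skipped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    combos = _ligand_smiles(spec)
    order = rng.permutation(len(combos))
    chosen = [combos[i] for i in order[:spec.n_ligands]]

    core_query = Chem.MolFromSmiles(CORE_QUERY_SMILES)
    ref_mol = None
    ref_match = None
    ligands: list[Ligand] = []
    truth: dict[str, dict] = {}

    for gen_idx, (smiles, (r1, r2)) in enumerate(chosen):
        mol = Chem.MolFromSmiles(smiles)
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(spec.seed * 1000 + gen_idx)
        if AllChem.EmbedMolecule(mol, params) != 0:
            import warnings
            warnings.warn(f"embedding failed for {smiles}; ligand skipped")
            continue
        mol = Chem.RemoveHs(mol)
        match = mol.GetSubstructMatch(core_query)
        if ref_mol is None:
            # First ligand defines the frame: core centroid at the origin.
            conf = mol.GetConformer()
            xyz = np.asarray(conf.GetPositions())
            shift = xyz[list(match)].mean(axis=0)
            for i in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(i, Point3D(*(xyz[i] - shift)))
            ref_mol, ref_match = mol, match
        else:
            AllChem.AlignMol(mol, ref_mol, atomMap=list(zip(match, ref_match)))
        conf = mol.GetConformer()
        xyz = np.asarray(conf.GetPositions())
        xyz = xyz + rng.normal(0.0, spec.pose_jitter_sd, xyz.shape)
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, Point3D(*xyz[i]))

        lig_id = f"L{gen_idx:03d}"
        clean = spec.base_pic50 + spec.substituents[r1] + spec.substituents[r2]
        pic50 = clean + float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 \
            else clean
        mol.SetProp("_Name", lig_id)
        ligands.append(Ligand(ligand_id=lig_id, smiles=Chem.MolToSmiles(Chem.MolFromSmiles(smiles)),
                              pic50=pic50, synth_order=gen_idx, mol=mol))
        truth[lig_id] = {"substituents": [r1, r2], "clean_pic50": clean,
                         "pic50": pic50, "synth_order": gen_idx}

    series = CongenericSeries(f"synthetic-{spec.seed}", ligands)
    if len(ligands) < 2:
        import warnings
        warnings.warn("series is un-pairable (fewer than 2 ligands)")
    return series, truth


def write_fixtures(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write pocket.pdb, ligands.sdf, activities.csv, and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pocket = make_pocket(spec)
    series, truth = make_series(spec)

    paths = {
        "pocket": outdir / "pocket.pdb",
        "ligands": outdir / "ligands.sdf",
        "activities": outdir / "activities.csv",
        "truth": outdir / "truth.json",
    }
    paths["pocket"].write_text(Chem.MolToPDBBlock(pocket.mol))
    writer = Chem.SDWriter(str(paths["ligands"]))
    for lig in series.ligands:
        lig.mol.SetProp("pic50", f"{lig.pic50:.6f}")
        lig.mol.SetProp("synth_order", str(lig.synth_order))
        writer.write(lig.mol)
    writer.close()
    with open(paths["activities"], "w") as fh:
        fh.write("ligand_id,series_id,pic50,qualifier,synth_order,smiles\n")
        for lig in series.ligands:
            fh.write(f"{lig.ligand_id},{series.series_id},{lig.pic50:.6f},=,"
                     f"{lig.synth_order},{lig.smiles}\n")
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def build_series_dataset(spec: SyntheticSpec, table=None, pocket_cutoff: float = 8.0):
    """Pocket + series + compiled complex graphs, ready for the network.

    Returns ``(series, graphs, compiled)`` where ``graphs`` maps ligand id to
    the :class:`~pairbind.graph.ComplexGraph` and ``compiled`` to the
    network-ready :class:`~pairbind.network.CompiledGraph`.
    """
    from .graph import build_complex_graph
    from .network import compile_graph

    protein = make_pocket(spec)
    series, _ = make_series(spec)
    # One shared pocket for the whole series: the model contract requires the
    # pocket parts of a pair to be identical, so extraction anchors on the
    # first ligand's pose.
    first = Structure(series.ligands[0].mol, "ligand")
    pocket = extract_pocket(protein, first, cutoff=pocket_cutoff)
    graphs, compiled = {}, {}
    for lig in series.ligands:
        ligand = Structure(lig.mol, "ligand", name=lig.ligand_id)
        g = build_complex_graph(pocket, ligand)
        graphs[lig.ligand_id] = g
        compiled[lig.ligand_id] = compile_graph(g, table, name=lig.ligand_id)
    return series, graphs, compiled
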