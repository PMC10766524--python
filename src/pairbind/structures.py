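"""Molecular structures: ligand poses, proteins, and binding-pocket extraction.

A :class:`Structure` is a thin wrapper around an RDKit molecule carrying a
single 3-D conformer, with a ``role`` tag (``"protein"`` or ``"ligand"``).
Hydrogens may be present on input but are stripped on construction: the
complex graph is built over heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


class PocketError(ValueError):
    """No protein residue lies within the cutoff of the ligand."""


@dataclass
class Structure:
    """A protein or ligand with heavy-atom coordinates in Å."""

    mol: Chem.Mol
    role: str  # "protein" | "ligand"
    name: str = ""

    def __post_init__(self):
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")
        if self.mol.GetNumConformers() == 0:
            raise ValueError("structure requires a 3-D conformer")
        mol = Chem.RemoveHs(self.mol, sanitize=False)
        if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            # RemoveHs keeps hydrogens without heavy neighbors; drop them too
            em = Chem.RWMol(mol)
            for idx in sorted((a.GetIdx() for a in mol.GetAtoms()
                               if a.GetAtomicNum() == 1), reverse=True):
                em.RemoveAtom(idx)
            mol = em.GetMol()
        Chem.SanitizeMol(mol, catchErrors=True)
        if mol.GetNumAtoms() == 0:
            raise ValueError("structure has no heavy atoms")
        self.mol = mol
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    # ------------------------------------------------------------ properties
    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) Cartesian coordinates in Å."""
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=np.float64)

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    def residue_keys(self) -> list[tuple]:
        """Per-atom (chain, residue number, residue name); ligands get one pseudo-residue."""
        keys = []
        for atom in self.mol.GetAtoms():
            info = atom.GetPDBResidueInfo()
            if info is None:
                keys.append(("", 1, self.name or "LIG"))
            else:
                keys.append((info.GetChainId(), info.GetResidueNumber(), info.GetResidueName()))
        return keys

    # -------------------------------------------------------------- builders
    @classmethod
    def from_pdb_file(cls, path: str, role: str = "protein") -> "Structure":
        mol = Chem.MolFromPDBFile(str(path), removeHs=True, sanitize=False)
        if mol is None:
            raise ValueError(f"could not parse PDB file {path}")
        return cls(mol, role, name=str(path))

    @classmethod
    def from_pdb_block(cls, block: str, role: str = "protein") -> "Structure":
        mol = Chem.MolFromPDBBlock(block, removeHs=True, sanitize=False)
        if mol is None:
            raise ValueError("could not parse PDB block")
        return cls(mol, role)

    @classmethod
    def from_sdf(cls, path: str, role: str = "ligand") -> list["Structure"]:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        out = []
        for mol in supplier:
            if mol is not None:
                out.append(cls(mol, role, name=mol.GetProp("_Name") if mol.HasProp("_Name") else ""))
        if not out:
            raise ValueError(f"no molecules parsed from {path}")
        return out

    @classmethod
    def from_mol2(cls, path: str, role: str = "ligand") -> "Structure":
        mol = Chem.MolFromMol2File(str(path), removeHs=True)
        if mol is None:
            raise ValueError(f"could not parse MOL2 file {path}")
        return cls(mol, role, name=str(path))

    @classmethod
    def from_smiles(cls, smiles: str, role: str = "ligand", seed: int = 0,
                    name: str = "") -> "Structure":
        """Parse SMILES and embed a 3-D conformer (ETKDG, seeded)."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(f"3-D embedding failed for {smiles!r}")
        return cls(Chem.RemoveHs(mol), role, name=name)


def _submol(structure: Structure, atom_idx: list[int]) -> Chem.Mol:
    """Copy of ``structure.mol`` restricted to ``atom_idx`` (bonds within)."""
    keep = sorted(atom_idx)
    old2new = {old: new for new, old in enumerate(keep)}
    em = Chem.RWMol()
    conf_src = structure.mol.GetConformer()
    conf = Chem.Conformer(len(keep))
    for new, old in enumerate(keep):
        atom = structure.mol.GetAtomWithIdx(old)
        na = Chem.Atom(atom.GetAtomicNum())
        na.SetFormalCharge(atom.GetFormalCharge())
        na.SetIsAromatic(atom.GetIsAromatic())
        na.SetNoImplicit(True)
        if atom.GetPDBResidueInfo() is not None:
            na.SetMonomerInfo(atom.GetPDBResidueInfo())
        em.AddAtom(na)
        conf.SetAtomPosition(new, conf_src.GetAtomPosition(old))
    for bond in structure.mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in old2new and j in old2new:
            em.AddBond(old2new[i], old2new[j], bond.GetBondType())
            em.GetBondBetweenAtoms(old2new[i], old2new[j]).SetIsAromatic(bond.GetIsAromatic())
    mol = em.GetMol()
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, catchErrors=True)
    return mol


def extract_pocket(protein: Structure, ligand: Structure, cutoff: float = 8.0) -> Structure:
    """Keep whole protein residues with any heavy atom within ``cutoff`` Å of the ligand.

    A residue is retained when its minimum heavy-atom distance to any ligand
    heavy atom is less than or equal to the cutoff (8.0 Å by default).
    Residues are kept or dropped atomically.

    Raises
    ------
    PocketError
        If no residue qualifies — the usual sign of a mis-posed ligand.
    """
    if protein.n_atoms == 0 or ligand.n_atoms == 0:
        raise ValueError("both structures need at least one heavy atom")
    pc, lc = protein.coords, ligand.coords
    dmin = np.sqrt(((pc[:, None, :] - lc[None, :, :]) ** 2).sum(-1)).min(axis=1)
    keys = protein.residue_keys()
    keep_res = {k for k, d in zip(keys, dmin) if d <= cutoff}
    keep_atoms = [i for i, k in enumerate(keys) if k in keep_res]
    if not keep_atoms:
        raise PocketError(f"no pocket within cutoff {cutoff} Å")
    return Structure(_submol(protein, keep_atoms), "protein", name=protein.name)
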