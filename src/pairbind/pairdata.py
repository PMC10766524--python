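"""Pairwise training/evaluation data built from per-ligand activity tables.

A congeneric series (shared scaffold, varying substituents) with N measured
ligands yields C(N, 2) ordered ligand pairs labeled ỹ(i,j) = pIC50(i) −
pIC50(j). Qualified measurements ('<' / '>') are discarded, training pairs
are restricted to Tanimoto similarity > 0.6, and the ΔpIC50 label histogram
is balanced by under-/over-sampling before training.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

log = logging.getLogger(__name__)

SIMILARITY_THRESHOLD = 0.6
BALANCE_BIN_WIDTH = 0.5   # pIC50 units
BALANCE_CAP_RATIO = 4.0


@dataclass
class Ligand:
    ligand_id: str
    smiles: str = ""
    pose_file: str = ""
    pic50: float = float("nan")
    ic50_raw: float = float("nan")
    qualifier: str = "="
    synth_order: int = -1
    mol: Chem.Mol | None = None


@dataclass
class CongenericSeries:
    series_id: str
    ligands: list[Ligand] = field(default_factory=list)
    target_ref: str = ""

    def __post_init__(self):
        ids = [l.ligand_id for l in self.ligands]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ligand ids in series {self.series_id}")

    def __len__(self) -> int:
        return len(self.ligands)

    def by_id(self, ligand_id: str) -> Ligand:
        for l in self.ligands:
            if l.ligand_id == ligand_id:
                return l
        raise KeyError(ligand_id)


@dataclass
class LigandPair:
    series_id: str
    i: str
    j: str
    label: float                 # ỹ(i, j) = pIC50(i) − pIC50(j)
    cls_label: float = field(init=False)   # 1[ỹ > 0]; 0.5 marks a tie
    similarity: float = float("nan")

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a pair needs two distinct ligands")
        self.cls_label = 0.5 if self.label == 0 else float(self.label > 0)


def log_convert(ic50_molar: float) -> float:
    """pIC50 = −log10(IC50 in mol/L)."""
    if ic50_molar <= 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50_molar)


def clean_activities(table: pd.DataFrame) -> list[CongenericSeries]:
    """Parse a per-ligand activity table into cleaned congeneric series.

    Expected columns: ``ligand_id``, ``series_id``, one of ``pic50`` or
    ``ic50_nM``, optional ``qualifier`` ('=', '<', '>'), optional
    ``synth_order``, optional ``smiles`` and ``pose_file``. Rows with
    qualified ('<'/'>') or missing activities are dropped; series left with
    fewer than two ligands cannot form pairs and are dropped whole.
    """
    if "ligand_id" not in table.columns or "series_id" not in table.columns:
        raise ValueError("table needs 'ligand_id' and 'series_id' columns")
    if "pic50" not in table.columns and "ic50_nM" not in table.columns:
        raise ValueError("table needs a 'pic50' or 'ic50_nM' column")

    out: list[CongenericSeries] = []
    parsed_any = False
    for sid, grp in table.groupby("series_id", sort=True):
        ligands = []
        for _, row in grp.iterrows():
            qual = str(row.get("qualifier", "=") or "=").strip()
            if qual in ("<", ">"):
                continue
            if "pic50" in grp.columns and pd.notna(row.get("pic50")):
                pic50 = float(row["pic50"])
            elif "ic50_nM" in grp.columns and pd.notna(row.get("ic50_nM")):
                val = row["ic50_nM"]
                if isinstance(val, str):
                    v = val.strip()
                    if v.startswith(("<", ">")):
                        continue
                    val = float(v)
                pic50 = log_convert(float(val) * 1e-9)
            else:
                continue
            parsed_any = True
            ligands.append(Ligand(
                ligand_id=str(row["ligand_id"]),
                smiles=str(row.get("smiles", "") or ""),
                pose_file=str(row.get("pose_file", "") or ""),
                pic50=pic50,
                synth_order=int(row.get("synth_order", -1) or -1),
            ))
        if len(ligands) >= 2:
            out.append(CongenericSeries(str(sid), ligands))
    if not parsed_any:
        raise ValueError("no parseable activity rows")
    return out


def enumerate_pairs(series: CongenericSeries, bidirectional: bool = False) -> list[LigandPair]:
    """All (i, j) pairs with i < j; labels ỹ(i,j) = y(i) − y(j).

    With ``bidirectional`` both directions are emitted, teaching the model
    the antisymmetry ỹ(i,j) = −ỹ(j,i).
    """
    if len(series) < 2:
        raise ValueError("need at least two ligands to form pairs")
    pairs = []
    ligs = series.ligands
    for a in range(len(ligs)):
        for b in range(a + 1, len(ligs)):
            li, lj = ligs[a], ligs[b]
            pairs.append(LigandPair(series.series_id, li.ligand_id, lj.ligand_id,
                                    li.pic50 - lj.pic50))
            if bidirectional:
                pairs.append(LigandPair(series.series_id, lj.ligand_id, li.ligand_id,
                                        lj.pic50 - li.pic50))
    return pairs


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def tanimoto(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto similarity of Morgan (radius-2, 2048-bit) fingerprints."""
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    if ma is None or mb is None:
        raise ValueError("unparseable SMILES")
    return DataStructs.TanimotoSimilarity(_FP_GEN.GetFingerprint(ma),
                                          _FP_GEN.GetFingerprint(mb))


def similarity_filter(pairs: list[LigandPair], smiles_by_id: dict[str, str],
                      threshold: float = SIMILARITY_THRESHOLD) -> list[LigandPair]:
    """Keep training pairs with Tanimoto similarity strictly above ``threshold``.

    Evaluation pairs are never passed through this filter. Pairs whose
    SMILES cannot be parsed are dropped with a logged warning.
    """
    kept = []
    for p in pairs:
        try:
            sim = tanimoto(smiles_by_id[p.i], smiles_by_id[p.j])
        except (ValueError, KeyError) as exc:
            log.warning("dropping pair (%s, %s): %s", p.i, p.j, exc)
            continue
        p.similarity = sim
        if sim > threshold:
            kept.append(p)
    return kept


def balance_labels(pairs: list[LigandPair], bin_width: float = BALANCE_BIN_WIDTH,
                   cap_ratio: float = BALANCE_CAP_RATIO, seed: int = 0) -> list[LigandPair]:
    """Flatten the ΔpIC50 label histogram by under-/over-sampling.

    Occupied-bin counts are clipped into a band whose max/min ratio is at
    most ``cap_ratio``: dense bins are undersampled without replacement,
    sparse bins oversampled with replacement. Labels are never altered, only
    multiplicities. Seeded and reproducible.
    """
    if not pairs:
        raise ValueError("no pairs to balance")
    labels = np.array([p.label for p in pairs])
    bins = np.floor(labels / bin_width).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    if len(uniq) == 1:
        warnings.warn("single occupied label bin; returning pairs unchanged")
        return list(pairs)

    g = math.sqrt(counts.max() * counts.min())
    hi = max(1, int(math.floor(g * math.sqrt(cap_ratio))))
    lo = max(1, int(math.ceil(g / math.sqrt(cap_ratio))))
    rng = np.random.default_rng(seed)
    out: list[LigandPair] = []
    for b, c in zip(uniq, counts):
        idx = np.nonzero(bins == b)[0]
        target = min(max(int(c), lo), hi)
        if target <= c:
            chosen = rng.choice(idx, size=target, replace=False)
        else:
            chosen = np.concatenate([idx, rng.choice(idx, size=target - c, replace=True)])
        out.extend(pairs[i] for i in sorted(chosen))
    return out


def pair_similarity_stats(pairs: list[LigandPair], smiles_by_id: dict[str, str],
                          edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0)) -> dict:
    """Histogram of pairwise Tanimoto similarities and the fraction below 0.6."""
    sims = np.array([tanimoto(smiles_by_id[p.i], smiles_by_id[p.j]) for p in pairs])
    counts, _ = np.histogram(sims, bins=np.asarray(edges))  # last bin closed at 1.0
    return {
        "bin_edges": list(edges),
        "bin_counts": counts.tolist(),
        "proportions": (counts / max(len(sims), 1)).tolist(),
        "fraction_below_0.6": float((sims < 0.6).mean()),
        "n": int(len(sims)),
    }


def pairs_to_frame(pairs: list[LigandPair]) -> pd.DataFrame:
    """Pairs as a CSV-ready manifest."""
    return pd.DataFrame([{
        "series_id": p.series_id, "ligand_i": p.i, "ligand_j": p.j,
        "delta_pic50": p.label, "cls_label": p.cls_label, "similarity": p.similarity,
    } for p in pairs])
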