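"""Reference-anchored inference, unit conversions, and evaluation metrics.

The Siamese model predicts relative affinities ŷ(i, u). Anchoring against N
reference ligands with known pIC50 gives per-reference absolute estimates
ŷ_i(u) = y(i) − ŷ(i, u); their mean is the final prediction and their
population variance (1/N) the uncertainty. Ranking quality is measured with
Pearson R and Spearman ρ, accuracy with the pairwise r.m.s.e. reported in
both pIC50 and kcal/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT_KCAL = 1.987e-3   # kcal K^-1 mol^-1
TEMPERATURE_K = 297.0
RT_LN10 = GAS_CONSTANT_KCAL * TEMPERATURE_K * math.log(10.0)  # ≈ 1.3588 kcal/mol per pIC50


@dataclass
class InferenceResult:
    """Absolute-affinity estimate of one test ligand from N references."""

    ligand_id: str
    per_reference: np.ndarray     # ŷ_i(u), one per reference
    mean: float                   # ŷ(u)
    variance: float               # σ²(u), population (1/N)

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def infer_absolute(pair_predictions: np.ndarray, reference_labels: np.ndarray,
                   ligand_id: str = "") -> InferenceResult:
    """Anchor pairwise predictions ŷ(i, u) to absolute affinities.

    ``pair_predictions[i]`` is the predicted ΔpIC50 of (reference i, test u);
    ``reference_labels[i]`` the known pIC50 of reference i. The variance is
    the population variance (divide by N), so a single reference gives
    exactly σ² = 0.
    """
    preds = np.asarray(pair_predictions, dtype=float)
    refs = np.asarray(reference_labels, dtype=float)
    if preds.shape != refs.shape or preds.ndim != 1 or len(preds) == 0:
        raise ValueError("need one pairwise prediction per reference label")
    per_ref = refs - preds
    mean = float(per_ref.mean())
    var = float(((mean - per_ref) ** 2).mean())
    return InferenceResult(ligand_id, per_ref, mean, var)


def dg_to_pic50(dg_kcal: float | np.ndarray) -> float | np.ndarray:
    """Convert a binding free energy ΔG (kcal/mol) to the pIC50 scale.

    pIC50 ≈ −log10(exp(ΔG / RT)) with R = 1.987e-3 kcal K⁻¹ mol⁻¹ and
    T = 297 K; linear in ΔG with slope −1/(RT·ln 10).
    """
    return -np.asarray(dg_kcal, dtype=float) / RT_LN10 if np.ndim(dg_kcal) \
        else -float(dg_kcal) / RT_LN10


def pic50_to_kcal(pic50_delta: float) -> float:
    """Scale a pIC50-unit quantity (e.g. an r.m.s.e.) to kcal/mol."""
    return float(pic50_delta) * RT_LN10


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error over samples."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(((y - y_hat) ** 2).mean()))


def rmse_pw(pair_labels: np.ndarray, pair_predictions: np.ndarray) -> float:
    """Pairwise r.m.s.e.: the rmse of ΔpIC50 predictions over ligand pairs."""
    return rmse(pair_labels, pair_predictions)


def pearson(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if len(y) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(y, y_hat).statistic)


def spearman(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    if len(y) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(y, y_hat).statistic)


@dataclass
class MetricsReport:
    """Ranking and accuracy metrics for one evaluation run."""

    pearson_r: float
    spearman_rho: float
    rmse_pw_pic50: float
    rmse_pw_kcal: float = field(init=False)
    n: int = 0

    def __post_init__(self):
        if not (-1.0 - 1e-9 <= self.pearson_r <= 1.0 + 1e-9):
            raise ValueError("Pearson R out of [-1, 1]")
        if not (-1.0 - 1e-9 <= self.spearman_rho <= 1.0 + 1e-9):
            raise ValueError("Spearman rho out of [-1, 1]")
        if self.rmse_pw_pic50 < 0:
            raise ValueError("r.m.s.e. must be non-negative")
        self.rmse_pw_kcal = pic50_to_kcal(self.rmse_pw_pic50)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def evaluate_ranking(y_true: np.ndarray, y_pred: np.ndarray,
                     pair_labels: np.ndarray | None = None,
                     pair_preds: np.ndarray | None = None) -> MetricsReport:
    """Build a MetricsReport from absolute values (and optionally pair errors)."""
    if pair_labels is None or pair_preds is None:
        pair_labels, pair_preds = np.asarray(y_true, float), np.asarray(y_pred, float)
    return MetricsReport(pearson(y_true, y_pred), spearman(y_true, y_pred),
                         rmse_pw(pair_labels, pair_preds), n=len(np.asarray(y_true)))


def reports_to_frame(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame({name: asdict(r) for name, r in reports.items()}).T


def lead_opt_metrics(experimental_order: int, model_selection_order: int,
                     n_ligands: int) -> tuple[int, float, float]:
    """Campaign acceleration metrics.

    Returns (advantage order, advantage ratio %, efficiency improvement
    ratio %): the raw difference between the experimental synthesis order of
    the best ligand and the model's selection order, that difference as a
    percentage of the series size (resources saved), and as a percentage of
    the model's selection order (speed-up of the campaign).
    """
    if experimental_order < 1 or model_selection_order < 1:
        raise ValueError("orders must be >= 1")
    if n_ligands < max(experimental_order, model_selection_order):
        raise ValueError("orders cannot exceed the number of ligands")
    diff = experimental_order - model_selection_order
    return (diff, 100.0 * diff / n_ligands, 100.0 * diff / model_selection_order)
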