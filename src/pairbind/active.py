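"""Uncertainty-guided active-learning campaign simulation for lead optimization.

The simulator retrospectively replays a congeneric series: the earliest
synthesized compound seeds the reference set, the model scores the remaining
candidates, and the top ``picks_per_iteration`` compounds are "synthesized"
(their labels revealed) each round until the highest-activity target ligand
is found. From the second iteration on, the model is fine-tuned on all pairs
among the current references, and the acquisition score trades off predicted
activity against uncertainty:

    a = ŷ               (iteration 1)
    a = ŷ + β·σ²        (iteration ≥ 2)

β > 0 favors exploration, β < 0 penalizes uncertain picks, β = 0 is purely
exploitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

import pandas as pd

from .network import CompiledGraph, PairRankNet
from .scoring import lead_opt_metrics
from .training import FineTuneConfig, fine_tune
from .inference import rank_candidates


def acquisition_score(y_hat: float, variance: float, beta: float, n_ite: int) -> float:
    """a = ŷ at the first iteration, ŷ + β·σ² afterwards."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return float(y_hat) if n_ite == 1 else float(y_hat) + beta * float(variance)


@dataclass
class AcquisitionConfig:
    beta: float = 0.0
    picks_per_iteration: int = 3
    count_initial_reference: bool = True   # reporting convention for selection order
    seed: int = 0

    def __post_init__(self):
        if self.picks_per_iteration < 1:
            raise ValueError("need at least one pick per iteration")


@dataclass
class SeriesForCampaign:
    """The simulation oracle: ids, graphs, true labels, synthesis order."""

    series_id: str
    ligand_ids: list[str]
    labels: dict[str, float]
    synth_order: dict[str, int]
    graphs: dict[str, CompiledGraph] = field(default_factory=dict)

    def __post_init__(self):
        missing = [l for l in self.ligand_ids if l not in self.synth_order
                   or self.synth_order[l] < 0]
        if missing:
            raise ValueError(f"ligands without synthesis order: {missing}")

    @property
    def target_ligand(self) -> str:
        """Highest activity; earliest synthesized breaks ties."""
        best = max(self.labels[l] for l in self.ligand_ids)
        tied = [l for l in self.ligand_ids if self.labels[l] == best]
        return min(tied, key=lambda l: self.synth_order[l])

    @property
    def initial_reference(self) -> str:
        return min(self.ligand_ids, key=lambda l: self.synth_order[l])


class Scorer(Protocol):
    """Scores candidates given the revealed references; the model's stand-in in tests."""

    def score(self, series: SeriesForCampaign, reference_ids: list[str],
              candidate_ids: list[str], iteration: int) -> tuple[dict, dict]:
        """Return ({id: ŷ}, {id: σ²})."""


class ModelScorer:
    """Fine-tunes a copy of the base model on the references, then ranks."""

    def __init__(self, base_model: PairRankNet,
                 finetune_config: FineTuneConfig | None = None):
        self.base_model = base_model
        self.finetune_config = finetune_config or FineTuneConfig()

    def score(self, series, reference_ids, candidate_ids, iteration):
        refs = [(lid, series.graphs[lid], series.labels[lid]) for lid in reference_ids]
        model = self.base_model
        if iteration >= 2 and len(reference_ids) >= 2:
            model = fine_tune(self.base_model,
                              [(g, y) for _, g, y in refs], self.finetune_config)
        results = rank_candidates(model, refs,
                                  [(lid, series.graphs[lid]) for lid in candidate_ids])
        return ({r.ligand_id: r.mean for r in results},
                {r.ligand_id: r.variance for r in results})


class OracleScorer:
    """Perfect scorer returning the planted truth; zero uncertainty."""

    def score(self, series, reference_ids, candidate_ids, iteration):
        return ({l: series.labels[l] for l in candidate_ids},
                {l: 0.0 for l in candidate_ids})


class NoisyOracleScorer:
    """Truth + Gaussian noise; σ² reports each ligand's true noise variance."""

    def __init__(self, noise_sd: float = 0.5, seed: int = 0):
        self.rng = np.random.default_rng(seed)
        self.noise_sd = noise_sd
        self._lig_sd: dict[str, float] = {}

    def score(self, series, reference_ids, candidate_ids, iteration):
        y_hat, var = {}, {}
        for l in candidate_ids:
            if l not in self._lig_sd:
                # heteroscedastic: some ligands are intrinsically harder
                self._lig_sd[l] = self.noise_sd * float(self.rng.uniform(0.5, 1.5))
            sd = self._lig_sd[l]
            y_hat[l] = series.labels[l] + float(self.rng.normal(0.0, sd))
            var[l] = sd ** 2
        return y_hat, var


@dataclass
class CampaignResult:
    series_id: str
    selection_order: int           # cumulative picks (incl. initial ref by convention)
    iterations: int
    target_ligand: str
    log: pd.DataFrame
    advantage_order: int = 0
    advantage_ratio: float = 0.0
    efficiency_improvement_ratio: float = 0.0


def run_campaign(series: SeriesForCampaign, scorer: Scorer,
                 config: AcquisitionConfig | None = None) -> CampaignResult:
    """Iterate pick-reveal-refine until the target ligand is selected.

    Selection order counts the initial reference as 1 (configurable) and
    increments through picks in batch order; acquisition ties break by
    ligand id for a stable, reproducible ordering.
    """
    config = config or AcquisitionConfig()
    target = series.target_ligand
    references = [series.initial_reference]
    remaining = [l for l in series.ligand_ids if l != references[0]]
    count = 1 if config.count_initial_reference else 0
    rows = []
    iteration = 0

    if references[0] == target:
        return _finalize(series, target, max(count, 1), 0, rows)

    while remaining:
        iteration += 1
        y_hat, var = scorer.score(series, references, remaining, iteration)
        scored = sorted(
            ((acquisition_score(y_hat[l], var[l], config.beta, iteration), l)
             for l in remaining),
            key=lambda t: (-t[0], t[1]))
        picks = [l for _, l in scored[:config.picks_per_iteration]]
        for rank, l in enumerate(picks):
            count += 1
            rows.append({"iteration": iteration, "ligand_id": l,
                         "y_hat": y_hat[l], "variance": var[l],
                         "acquisition": acquisition_score(y_hat[l], var[l],
                                                          config.beta, iteration),
                         "cumulative_count": count})
            if l == target:
                return _finalize(series, target, count, iteration, rows)
        references.extend(picks)
        remaining = [l for l in remaining if l not in picks]
    raise RuntimeError("campaign exhausted candidates without finding the target")


def _finalize(series, target, count, iterations, rows) -> CampaignResult:
    exp_order = sorted(series.synth_order[l] for l in series.ligand_ids).index(
        series.synth_order[target]) + 1
    adv, ratio, eff = lead_opt_metrics(exp_order, max(count, 1), len(series.ligand_ids))
    return CampaignResult(
        series_id=series.series_id, selection_order=count, iterations=iterations,
        target_ligand=target,
        log=pd.DataFrame(rows, columns=["iteration", "ligand_id", "y_hat",
                                        "variance", "acquisition", "cumulative_count"]),
        advantage_order=adv, advantage_ratio=ratio,
        efficiency_improvement_ratio=eff)
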