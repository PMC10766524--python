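"""Hybrid-loss training, early stopping, and the few-shot fine-tuning protocol.

Training minimizes Loss = MSE(ŷ, ỹ) + α·BCE(p̂, 1[ỹ > 0]) over ligand pairs:
the regression term fits the ΔpIC50 magnitude, the auxiliary classification
term penalizes small-error but wrongly-ranked pairs. Tie pairs (ỹ = 0) are
excluded from the entropy term. Fine-tuning on a handful of reference
ligands uses pairs among the references only, regression loss only, and
leaves the classification head untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, gather_rows
from .network import CompiledGraph, PairRankNet, merge_compiled


@dataclass
class TrainConfig:
    """Published training hyperparameters are the defaults.

    ``epochs`` may be fractional (implemented as a step budget); validation
    runs every ``eval_unit_epochs`` and the best-validation state is kept.
    """

    alpha: float = 1.0
    batch_size: int = 96
    learning_rate: float = 5e-7
    epochs: float = 5.75
    eval_unit_epochs: float = 0.25
    patience_units: int = 8
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.batch_size < 1:
            raise ValueError("alpha must be >= 0 and batch size >= 1")


@dataclass
class FineTuneConfig:
    """Few-shot fine-tuning: regression loss only, auxiliary head frozen."""

    batch_size: int = 30
    learning_rate: float = 1e-5
    epochs: int = 10
    clip_norm: float = 5.0
    seed: int = 0


@dataclass
class PairExample:
    """One training pair: two compiled complex graphs and their labels."""

    cg_i: CompiledGraph
    cg_j: CompiledGraph
    label: float                 # ỹ(i, j)
    cls_label: float = None      # 1[ỹ > 0], 0.5 for ties

    def __post_init__(self):
        if self.cls_label is None:
            self.cls_label = 0.5 if self.label == 0 else float(self.label > 0)


def hybrid_loss(y_pred: Tensor, labels: np.ndarray, logits: Tensor,
                cls_labels: np.ndarray, alpha: float = 1.0) -> Tensor:
    """MSE + α·binary-cross-entropy; tie labels excluded from the BCE term.

    ``y_pred`` and ``logits`` are (B, 1) tensors; the BCE is computed from
    logits for numerical stability.
    """
    labels = np.asarray(labels, float).reshape(-1, 1)
    resid = y_pred - Tensor(labels)
    loss = (resid * resid).mean()
    if alpha > 0:
        keep = np.asarray(cls_labels, float) != 0.5
        if keep.any():
            idx = np.nonzero(keep)[0]
            lg = gather_rows(logits, idx)
            t = np.asarray(cls_labels, float)[idx].reshape(-1, 1)
            # softplus(x) - t*x = -[t·log p + (1-t)·log(1-p)]
            bce = (lg.softplus() - Tensor(t) * lg).mean()
            loss = loss + alpha * bce
    return loss


def _batch_forward(model: PairRankNet, batch: list[PairExample], train: bool,
                   rng: np.random.Generator | None) -> tuple[Tensor, Tensor]:
    """Encode the batch's distinct graphs in one merged pass; return (ŷ, logits)."""
    uniq: dict[int, int] = {}
    graphs = []
    for ex in batch:
        for cg in (ex.cg_i, ex.cg_j):
            if id(cg) not in uniq:
                uniq[id(cg)] = len(graphs)
                graphs.append(cg)
    x = model.encode(merge_compiled(graphs) if len(graphs) > 1 else graphs[0],
                     train=train, rng=rng)
    x_i = gather_rows(x, np.array([uniq[id(ex.cg_i)] for ex in batch], dtype=np.intp))
    x_j = gather_rows(x, np.array([uniq[id(ex.cg_j)] for ex in batch], dtype=np.intp))
    return model.pair_output(x_i, x_j)


def predict_pairs(model: PairRankNet, pairs: list[PairExample]) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (ŷ, p̂) arrays for a list of pair examples."""
    y, logits = _batch_forward(model, pairs, train=False, rng=None)
    p = 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))
    return y.data.reshape(-1).copy(), p


def validation_rmse_pw(model: PairRankNet, pairs: list[PairExample]) -> float:
    y_hat, _ = predict_pairs(model, pairs)
    labels = np.array([ex.label for ex in pairs])
    return float(np.sqrt(((y_hat - labels) ** 2).mean()))


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_val: float
    log: list[dict] = field(default_factory=list)


def train(model: PairRankNet, train_pairs: list[PairExample],
          val_pairs: list[PairExample] | None = None,
          config: TrainConfig | None = None) -> TrainResult:
    """Seeded mini-batch optimization with periodic validation.

    Validation runs every ``eval_unit_epochs`` worth of steps; the state with
    the best validation pairwise r.m.s.e. is returned (and loaded back into
    the model). A NaN loss aborts with a diagnostic.
    """
    if not train_pairs:
        raise ValueError("empty training pair set")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate, clip_norm=config.clip_norm)

    steps_per_epoch = max(1, math.ceil(len(train_pairs) / config.batch_size))
    total_steps = math.ceil(config.epochs * steps_per_epoch)
    eval_every = max(1, round(config.eval_unit_epochs * steps_per_epoch))

    best_val = math.inf
    best_state = model.state_dict()
    log: list[dict] = []
    bad_units = 0
    order = rng.permutation(len(train_pairs))
    cursor = 0

    for step in range(1, total_steps + 1):
        if cursor + config.batch_size > len(order):
            order = rng.permutation(len(train_pairs))
            cursor = 0
        batch = [train_pairs[i] for i in order[cursor:cursor + config.batch_size]]
        cursor += config.batch_size

        y, logits = _batch_forward(model, batch, train=True, rng=rng)
        loss = hybrid_loss(y, [ex.label for ex in batch], logits,
                           [ex.cls_label for ex in batch], config.alpha)
        loss_val = loss.item()
        if not math.isfinite(loss_val):
            raise RuntimeError(f"training diverged: loss={loss_val} at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append({"step": step, "split": "train", "loss": loss_val})

        if step % eval_every == 0 or step == total_steps:
            if val_pairs:
                val = validation_rmse_pw(model, val_pairs)
                log.append({"step": step, "split": "val", "loss": val})
                if val < best_val - 1e-9:
                    best_val, best_state, bad_units = val, model.state_dict(), 0
                else:
                    bad_units += 1
                    if bad_units >= config.patience_units:
                        break
            else:
                best_val, best_state = loss_val, model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(best_state, best_val, log)


def reference_pairs(references: list[tuple[CompiledGraph, float]],
                    bidirectional: bool = True) -> list[PairExample]:
    """All pairs among the reference ligands (both directions by default)."""
    out = []
    for a in range(len(references)):
        for b in range(a + 1, len(references)):
            (gi, yi), (gj, yj) = references[a], references[b]
            out.append(PairExample(gi, gj, yi - yj))
            if bidirectional:
                out.append(PairExample(gj, gi, yj - yi))
    return out


def fine_tune(model: PairRankNet, references: list[tuple[CompiledGraph, float]],
              config: FineTuneConfig | None = None) -> PairRankNet:
    """Few-shot adaptation on pairs formed among reference ligands only.

    Returns a fine-tuned copy; the input model is left untouched. The
    classification head receives no gradient (regression loss only) and is
    therefore bitwise unchanged.
    """
    if len(references) < 2:
        raise ValueError("fine-tuning needs at least two reference ligands")
    config = config or FineTuneConfig()
    tuned = model.clone()
    pairs = reference_pairs(references, bidirectional=True)
    rng = np.random.default_rng(config.seed)
    opt = Adam(tuned.params, lr=config.learning_rate, clip_norm=config.clip_norm)
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), config.batch_size):
            batch = [pairs[i] for i in order[start:start + config.batch_size]]
            y, logits = _batch_forward(tuned, batch, train=True, rng=rng)
            loss = hybrid_loss(y, [ex.label for ex in batch], logits,
                               [ex.cls_label for ex in batch], alpha=0.0)
            if not math.isfinite(loss.item()):
                raise RuntimeError("fine-tuning diverged (NaN loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return tuned
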