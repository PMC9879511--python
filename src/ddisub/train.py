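"""Splitting, negative sampling, optimization, and evaluation metrics.

Training poses typed DDI prediction as binary tuple classification: every
known interaction (d_x, d_y, r) is a positive, and one negative is sampled
per positive by corrupting one side of the tuple (coin flip) with a random
drug such that the corrupted tuple is not itself a known positive — the
standard corruption protocol of knowledge-graph link prediction.  The
optimizer is Adam with L2 weight decay and an exponentially decaying
learning rate, lr_e = lr * 0.96^e.  The checkpoint with the lowest
validation loss is kept.

Metrics: accuracy, ROC AUC, F1, precision, recall and area under the
precision-recall curve, overall and restricted per interaction type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)

from .autodiff import Adam, Var
from .model import DDIModel, ModelConfig
from .molgraph import DDITuple, DrugRecord
from .scoring import bce_loss, bce_loss_logits

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsReport", "split_dataset", "negative_sampling",
           "train", "evaluate", "per_type_metrics", "lr_at_epoch"]


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the reference setting."""

    T: int = 3
    L: int = 3
    hidden: int = 64
    lr: float = 1e-4
    batch_size: int = 256
    epochs: int = 50
    weight_decay: float = 5e-4
    lr_decay: float = 0.96
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    recompute_beta: bool = True
    softmax_gamma: bool = False
    symmetrize_relations: bool = False

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.fractions} do not sum to 1")
        if min(self.T, self.L, self.hidden, self.batch_size) < 1 or self.lr <= 0:
            raise ValueError("T, L, hidden, batch_size must be >= 1 and lr > 0")


@dataclass
class MetricsReport:
    acc: float
    auc: float | None
    f1: float
    precision: float
    recall: float
    aupr: float | None
    n: int

    def to_dict(self) -> dict:
        return {"ACC": self.acc, "AUC": self.auc, "F1": self.f1,
                "Prec": self.precision, "Rec": self.recall,
                "AUPR": self.aupr, "n": self.n}


def lr_at_epoch(lr: float, epoch: int, decay: float = 0.96) -> float:
    """Learning rate under the exponential schedule, ``lr * decay**epoch``."""
    return lr * decay**epoch


def split_dataset(tuples: list[DDITuple],
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> tuple[list[DDITuple], list[DDITuple], list[DDITuple]]:
    """Disjoint random train/valid/test partition.

    Sizes are floor allocations of the valid/test fractions with the
    remainder going to train, so the union is always exact.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(tuples) < 5:
        raise ValueError("need at least 5 tuples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tuples))
    n = len(tuples)
    n_valid = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_valid - n_test
    shuffled = [tuples[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_valid],
            shuffled[n_train + n_valid:])


def negative_sampling(positives: list[DDITuple], drugs: list[DrugRecord],
                      seed: int = 0, max_tries: int = 1000,
                      extra_rejection: set[tuple[str, str, int]] | None = None
                      ) -> list[DDITuple]:
    """Labeled 1:1 positive/negative tuples via one-side corruption.

    For each positive (x, y, r) one corrupted tuple is produced by
    replacing x or y (fair coin) with a uniformly drawn drug; candidates
    colliding with the positive set (any label-1 tuple) are rejected and
    redrawn.  ``extra_rejection`` widens the collision set with additional
    (drug_x, drug_y, relation) keys — the *filtered* protocol of
    knowledge-graph link prediction, used when the full set of true
    interactions is known beyond the sampled positives.
    """
    if len(drugs) < 3:
        raise ValueError("drug set too small for corruption sampling")
    rng = np.random.default_rng(seed)
    ids = [d.id for d in drugs]
    positive_keys = {(t.drug_x, t.drug_y, t.relation) for t in positives}
    if extra_rejection:
        positive_keys = positive_keys | set(extra_rejection)
    out: list[DDITuple] = []
    for t in positives:
        if t.label != 1:
            raise ValueError("negative_sampling expects positives (label 1)")
        out.append(t)
        for _ in range(max_tries):
            replace_x = rng.random() < 0.5
            cand_id = ids[rng.integers(len(ids))]
            cand = ((cand_id, t.drug_y, t.relation) if replace_x
                    else (t.drug_x, cand_id, t.relation))
            if cand not in positive_keys and cand[0] != cand[1]:
                out.append(DDITuple(cand[0], cand[1], t.relation, label=0))
                break
        else:
            raise RuntimeError("could not corrupt tuple; drug set too small")
    return out


@dataclass
class TrainResult:
    model: DDIModel
    history: list[dict] = field(default_factory=list)  # per-epoch log rows
    best_epoch: int = -1
    best_valid_loss: float = float("inf")


def _epoch_loss(model: DDIModel, graphs, tuples: list[DDITuple]) -> float:
    logits = model.forward_batch(graphs, tuples)
    labels = np.array([t.label for t in tuples])
    return float(bce_loss_logits(logits, labels).data)


def train(config: TrainConfig, drugs: list[DrugRecord],
          train_tuples: list[DDITuple],
          valid_tuples: list[DDITuple] | None = None,
          model: DDIModel | None = None,
          resample_negatives: bool = False,
          rejection_keys: set[tuple[str, str, int]] | None = None) -> TrainResult:
    """Optimize the dual-GNN on labeled tuples.

    All randomness (weight init, batch shuffling) derives from
    ``config.seed``.  With ``epochs == 0`` the initialized model is
    returned untouched.  A NaN loss aborts with diagnostics.

    With ``resample_negatives`` the corruption negatives are redrawn every
    epoch (``train_tuples`` must then be positives only); the model then
    cannot memorize individual negatives and must separate positives from
    the corruption distribution itself.  ``rejection_keys`` optionally
    widens the set of tuples a fresh negative may not collide with
    (filtered protocol).
    """
    n_rel = max((t.relation for t in train_tuples), default=0) + 1
    if model is None:
        model = DDIModel(ModelConfig(
            hidden=config.hidden, T=config.T, L=config.L, n_relations=n_rel,
            recompute_beta=config.recompute_beta,
            softmax_gamma=config.softmax_gamma,
            symmetrize_relations=config.symmetrize_relations,
            seed=config.seed,
        ))
    graphs = {d.id: model.graph_for(d.smiles) for d in drugs}
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    result = TrainResult(model=model)
    best_state = [a.copy() for a in model.state_arrays()]
    result.best_epoch = -1

    if resample_negatives and any(t.label != 1 for t in train_tuples):
        raise ValueError("resample_negatives expects positives-only train_tuples")

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config.lr, epoch, config.lr_decay)
        if resample_negatives:
            epoch_tuples = negative_sampling(
                train_tuples, drugs, seed=config.seed + 100_003 * (epoch + 1),
                extra_rejection=rejection_keys)
        else:
            epoch_tuples = train_tuples
        order = rng.permutation(len(epoch_tuples))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [epoch_tuples[i] for i in order[start:start + config.batch_size]]
            logits = model.forward_batch(graphs, batch)
            loss = bce_loss_logits(logits, np.array([t.label for t in batch]))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={lr:.3g}, batch of {len(batch)}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_losses.append(float(loss.data))
        train_loss = float(np.mean(epoch_losses))
        row = {"epoch": epoch, "lr": lr, "train_loss": train_loss}
        if valid_tuples:
            valid_loss = _epoch_loss(model, graphs, valid_tuples)
            row["valid_loss"] = valid_loss
            if valid_loss < result.best_valid_loss:
                result.best_valid_loss = valid_loss
                result.best_epoch = epoch
                best_state = [a.copy() for a in model.state_arrays()]
        result.history.append(row)
        log.info("epoch %d lr %.3g train %.4f valid %s", epoch, lr, train_loss,
                 row.get("valid_loss"))

    if valid_tuples and result.best_epoch >= 0:
        model.load_state_arrays(best_state)
    return result


def predict_probs(model: DDIModel, drugs: list[DrugRecord],
                  tuples: list[DDITuple]) -> np.ndarray:
    """Probabilities for a list of tuples (no gradient bookkeeping kept)."""
    graphs = {d.id: model.graph_for(d.smiles) for d in drugs}
    from .autodiff import Var

    logits = model.forward_batch(graphs, tuples)
    return Var(logits.data).sigmoid().data


def _metrics(labels: np.ndarray, probs: np.ndarray) -> MetricsReport:
    preds = (probs >= 0.5).astype(int)
    single_class = len(np.unique(labels)) < 2
    return MetricsReport(
        acc=float(accuracy_score(labels, preds)),
        auc=None if single_class else float(roc_auc_score(labels, probs)),
        f1=float(f1_score(labels, preds, zero_division=0)),
        precision=float(precision_score(labels, preds, zero_division=0)),
        recall=float(recall_score(labels, preds, zero_division=0)),
        aupr=None if single_class else float(average_precision_score(labels, probs)),
        n=len(labels),
    )


def evaluate(model: DDIModel, drugs: list[DrugRecord],
             tuples: list[DDITuple]) -> MetricsReport:
    """Overall metrics on labeled tuples (threshold 0.5 for the hard ones)."""
    probs = predict_probs(model, drugs, tuples)
    labels = np.array([t.label for t in tuples])
    return _metrics(labels, probs)


def per_type_metrics(model: DDIModel, drugs: list[DrugRecord],
                     tuples: list[DDITuple]) -> dict[int, MetricsReport]:
    """Metrics restricted to each interaction type separately.

    Types whose restriction contains a single class get ``AUC``/``AUPR``
    reported as ``None`` (undefined for one-class rankings).
    """
    probs = predict_probs(model, drugs, tuples)
    labels = np.array([t.label for t in tuples])
    rels = np.array([t.relation for t in tuples])
    return {int(r): _metrics(labels[rels == r], probs[rels == r])
            for r in np.unique(rels)}
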