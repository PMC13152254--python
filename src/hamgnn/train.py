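"""Losses, data splitting, the optimization loop and evaluation metrics.

Training is transductive full-batch node classification: the whole cell
graph is in memory, masks pick out train/validation/test cells, and Adam
(lr 0.01, weight decay 5e-4) minimizes masked cross-entropy with early
stopping on validation loss (patience 50). The composite cell-type x
disease-state task runs either as a single joint softmax (default) or as
two heads combined by the weighted multi-task loss alpha*L_type +
beta*L_state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import _autodiff as ad
from ._autodiff import Tensor, grad
from .datatypes import CellGraph, LabelSet
from .model import ModelConfig, build_model
from .nn import Adam

__all__ = [
    "SplitSpec",
    "Split",
    "cross_entropy",
    "multitask_loss",
    "split_cells",
    "fit",
    "FitResult",
    "evaluate",
]


@dataclass
class SplitSpec:
    """How to partition cells: stratified cell-level or donor-grouped."""

    mode: str = "cell_level"  # "cell_level" | "donor_grouped"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("cell_level", "donor_grouped"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class Split:
    train: np.ndarray  # integer cell indices
    val: np.ndarray
    test: np.ndarray

    def masks(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for idx in (self.train, self.val, self.test):
            m = np.zeros(n, dtype=bool)
            m[idx] = True
            out.append(m)
        return tuple(out)


def cross_entropy(logits, labels: np.ndarray, labeled_mask: np.ndarray) -> Tensor:
    """Mean negative log softmax probability of the true class over the
    labeled nodes."""
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    idx = np.flatnonzero(labeled_mask)
    if idx.size == 0:
        raise ValueError("labeled mask is empty")
    logits = ad.astensor(logits)
    logp = ad.log_softmax(logits[idx, :])
    labels = np.asarray(labels)[idx]
    onehot = np.zeros((idx.size, logits.shape[1]))
    onehot[np.arange(idx.size), labels] = 1.0
    picked = ad.tsum(logp * Tensor(onehot), axis=1)
    return -ad.tsum(picked) / float(idx.size)


def multitask_loss(loss_type, loss_state, alpha: float = 0.7, beta: float = 0.3):
    """Weighted combination alpha * L_type + beta * L_state."""
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be non-negative")
    return ad.astensor(loss_type) * Tensor(alpha) + ad.astensor(loss_state) * Tensor(beta)


def _exact_sizes(n: int, fractions) -> tuple[int, int, int]:
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    return n - n_val - n_test, n_val, n_test


def split_cells(labels: LabelSet, spec: SplitSpec) -> Split:
    """Deterministic train/val/test partition.

    cell_level: stratified by the composite label where class sizes allow.
    donor_grouped: donors are shuffled and greedily assigned so no donor
    spans two partitions.
    """
    n = labels.n_cells
    comp, _ = labels.composite()
    if spec.mode == "cell_level":
        _, n_val, n_test = _exact_sizes(n, spec.fractions)
        idx = np.arange(n)
        strat = comp if np.bincount(comp).min() >= 3 else None
        rest, test = train_test_split(
            idx, test_size=n_test, random_state=spec.seed,
            stratify=strat if strat is not None else None,
        )
        strat_rest = comp[rest] if strat is not None else None
        train, val = train_test_split(
            rest, test_size=n_val, random_state=spec.seed + 1,
            stratify=strat_rest,
        )
        return Split(np.sort(train), np.sort(val), np.sort(test))

    if labels.donor_id is None:
        raise ValueError("donor_grouped split requires donor ids")
    donors = np.asarray(labels.donor_id)
    uniq = np.unique(donors)
    if len(uniq) < 3:
        raise ValueError("donor_grouped split needs at least 3 donors")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(uniq)
    counts = {d: int((donors == d).sum()) for d in uniq}
    targets = [f * n for f in spec.fractions]
    buckets: list[list] = [[], [], []]
    filled = [0.0, 0.0, 0.0]
    for d in order:
        # assign to the partition furthest below its target
        deficits = [targets[i] - filled[i] for i in range(3)]
        j = int(np.argmax(deficits))
        buckets[j].append(d)
        filled[j] += counts[d]
    parts = []
    for j in range(3):
        sel = np.isin(donors, buckets[j])
        parts.append(np.flatnonzero(sel))
    if any(len(p) == 0 for p in parts):
        raise ValueError("a partition received no cells; use more donors")
    return Split(*parts)


@dataclass
class FitResult:
    model: object
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    energies_per_epoch: list = field(default_factory=list)


def _task_labels(labels: LabelSet, task: str):
    comp, comp_names = labels.composite()
    if task == "single":
        return [comp], [comp_names]
    type_codes, type_names = labels.type_codes()
    state_codes, state_names = labels.state_codes()
    return [type_codes, state_codes], [type_names, state_names]


def fit(
    model_mode: str,
    X: np.ndarray,
    graph: CellGraph,
    labels: LabelSet,
    split: Split,
    config: ModelConfig,
    record_energy: bool = False,
) -> FitResult:
    """Train a model with Adam + early stopping; returns best-validation
    parameters and the per-epoch history.

    Fully seeded: parameter init and dropout masks derive from
    ``config.seed``, so identical calls are bit-reproducible.
    """
    ys, names = _task_labels(labels, config.task)
    n_classes = [len(nm) for nm in names]
    ss = np.random.SeedSequence(config.seed)
    init_seed, drop_seed = ss.spawn(2)
    model = build_model(
        model_mode,
        X.shape[1],
        n_classes if config.task == "multi" else n_classes[0],
        graph,
        config,
        rng=np.random.default_rng(init_seed),
    )
    drop_rng = np.random.default_rng(drop_seed)
    params = model.params()
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    train_mask, val_mask, _ = split.masks(labels.n_cells)

    def loss_on(logits_list, mask) -> Tensor:
        if config.task == "multi":
            lt = cross_entropy(logits_list[0], ys[0], mask)
            lst = cross_entropy(logits_list[1], ys[1], mask)
            return multitask_loss(lt, lst, config.alpha, config.beta)
        return cross_entropy(logits_list[0], ys[0], mask)

    history = []
    best_val = np.inf
    best_epoch = -1
    best_params = [p.data.copy() for p in params]
    stale = 0
    energies_per_epoch: list[list[float]] = []
    for epoch in range(config.epochs):
        logits = model.forward(X, training=True, dropout_rng=drop_rng,
                               record_energy=record_energy)
        if record_energy and model._last_energies is not None:
            energies_per_epoch.append(model._last_energies)
        loss = loss_on(logits, train_mask)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"training loss diverged (non-finite) at epoch {epoch}"
            )
        grads = [g.data for g in grad(loss, params)]
        opt.step(grads)

        eval_logits = model.forward(X, training=False)
        val_loss = float(loss_on(eval_logits, val_mask).item())
        pred = np.argmax(eval_logits[0].data, axis=1)
        val_acc = float((pred[val_mask] == ys[0][val_mask]).mean())
        train_acc = float((pred[train_mask] == ys[0][train_mask]).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(loss.item()),
                "val_loss": val_loss,
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for p, b in zip(params, best_params):
        p.data = b
    return FitResult(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        best_val_loss=best_val,
        energies_per_epoch=energies_per_epoch,
    )


def predict(model, X: np.ndarray) -> list[np.ndarray]:
    """Class predictions (one array per head) in eval mode."""
    logits = model.forward(X, training=False)
    return [np.argmax(l.data, axis=1) for l in logits]


def evaluate(preds: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy, macro/weighted F1 and a per-class table.

    Accuracy is the fraction of correct predictions; per-class F1 is the
    harmonic mean of precision and recall, averaged unweighted (macro,
    primary) and by class support (weighted, secondary). Classes absent
    from both predictions and labels are excluded from the averages with a
    warning.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    classes = np.union1d(np.unique(preds), np.unique(labels))
    rows = []
    for c in classes:
        tp = int(np.sum((preds == c) & (labels == c)))
        fp = int(np.sum((preds == c) & (labels != c)))
        fn = int(np.sum((preds != c) & (labels == c)))
        support = int(np.sum(labels == c))
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall)
            else 0.0
        )
        rows.append(
            {
                "class": c,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "support": support,
            }
        )
    table = pd.DataFrame(rows)
    present = table["support"] > 0
    absent = table[(table["support"] == 0) & ~table["class"].isin(np.unique(preds))]
    if len(absent):
        warnings.warn(f"{len(absent)} classes absent from preds and labels excluded")
    macro_pool = table[present | table["class"].isin(np.unique(preds))]
    f1_macro = float(macro_pool["f1"].mean()) if len(macro_pool) else 0.0
    supp = table.loc[present, "support"].to_numpy(dtype=float)
    f1_weighted = (
        float(np.average(table.loc[present, "f1"], weights=supp)) if supp.sum() else 0.0
    )
    return {
        "accuracy": float((preds == labels).mean()),
        "f1_macro": f1_macro,
        "f1_weighted": f1_weighted,
        "per_class": table,
    }
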