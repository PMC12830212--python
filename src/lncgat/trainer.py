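"""Cross-validated ensemble training and evaluation.

Training follows the original recipe: stratified 5-fold cross-
validation produces five independently trained attention networks;
each fold minimizes binary cross-entropy with Adam (learning rate
1e-4, batch size 64, at most 200 epochs) under early stopping on
validation loss, and the ensemble prediction for a transcript is the
arithmetic mean of the five member probabilities, thresholded at 0.5.

Evaluation metrics are the standard confusion-matrix quantities
(ACC, SN, SP, MCC) plus a rank-based (Mann-Whitney, midrank-tied)
AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import gatnet
from .debruijn import KmerGraph, graph_from_sequence
from .embeddings import EmbeddingTable, embed_nodes, train_embeddings
from .gatnet import GatParameters, batch_forward_backward, make_batch
from .seqio import LabeledDataset, NucleotideSequence, tokenize_kmers

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the baseline configuration."""

    k: int = 3
    d: int = 64
    hidden: int = 64
    heads: int = 3
    fc_hidden: int = 64
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    neg_pos_ratio: float = 1.0
    dropout: float = 0.1
    leaky_slope: float = 0.2
    edge_norm: str = "sqrt"
    edge_bias: str = "multiplicative"
    readout: str = "mean"
    embed_window: int = 5
    embed_epochs: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class FoldEnsemble:
    """The five fold models plus everything needed to rerun them."""

    members: list[GatParameters]
    embeddings: EmbeddingTable
    config: TrainConfig
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(directory / "config.yaml")
        self.embeddings.save_tsv(directory / "embeddings.tsv")
        for i, m in enumerate(self.members, start=1):
            m.save(directory / f"fold{i}")
        pd.DataFrame(
            sorted(self.fold_assignment.items()), columns=["id", "fold"]
        ).to_csv(directory / "folds.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "FoldEnsemble":
        directory = Path(directory)
        config = TrainConfig.from_yaml(directory / "config.yaml")
        table = EmbeddingTable.load_tsv(directory / "embeddings.tsv")
        if table.k != config.k:
            raise ValueError(
                f"bundle inconsistency: config k={config.k} but embeddings k={table.k}"
            )
        members = [
            GatParameters.load(directory / f"fold{i}")
            for i in range(1, config.folds + 1)
        ]
        folds_path = directory / "folds.tsv"
        assignment = {}
        if folds_path.exists():
            df = pd.read_csv(folds_path, sep="\t")
            assignment = dict(zip(df["id"], df["fold"]))
        return cls(members, table, config, assignment)


@dataclass
class MetricsReport:
    """Confusion counts and the five derived metrics."""

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SN: float
    SP: float
    MCC: float | None
    AUC: float | None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(dataset: LabeledDataset, folds: int, seed: int) -> dict[str, int]:
    """Stratified fold assignment id -> fold index (0-based), seeded."""
    ids = dataset.ids
    y = np.array(dataset.label_vector())
    for cls in (0, 1):
        if int((y == cls).sum()) < folds:
            raise ValueError(
                f"class {cls} has fewer than {folds} samples; cannot stratify"
            )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(ids)), y)):
        for i in val_idx:
            assignment[ids[i]] = fold
    return assignment


# ---------------------------------------------------------------------------
# single-fold training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            weights[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


GraphItem = tuple[np.ndarray, KmerGraph, int]  # (features, graph, label)


def prepare_graph_inputs(
    seqs: Sequence[NucleotideSequence],
    labels: dict[str, int] | None,
    table: EmbeddingTable,
    config: TrainConfig,
) -> tuple[list[GraphItem], list[tuple[str, str]]]:
    """Tokenize, build and normalize graphs, look up node features.

    Returns usable items and a list of (id, reason) for sequences that
    cannot form a graph; callers decide whether failures are fatal.
    """
    items: list[GraphItem] = []
    failures: list[tuple[str, str]] = []
    for s in seqs:
        try:
            g = graph_from_sequence(s, config.k, config.edge_norm)
        except ValueError as exc:
            reason = "too short" if s.length < config.k + 1 else str(exc)
            failures.append((s.id, reason))
            continue
        X = embed_nodes(g, table)
        y = labels[s.id] if labels is not None else -1
        items.append((X, g, y))
    return items, failures


def train_fold(
    train_items: Sequence[GraphItem],
    val_items: Sequence[GraphItem],
    config: TrainConfig,
    seed: int,
) -> tuple[GatParameters, dict]:
    """Train one ensemble member; return best-validation-epoch parameters.

    Minimizes binary cross-entropy with Adam; stops once validation
    loss has not improved for `patience` consecutive epochs; the
    returned parameters are from the epoch with minimal validation
    loss, not the final epoch.
    """
    rng = np.random.default_rng(seed)
    params = gatnet.init_params(
        d=config.d, hidden=config.hidden, heads=config.heads,
        fc_hidden=config.fc_hidden, seed=int(rng.integers(2**31)),
        leaky_slope=config.leaky_slope, dropout=config.dropout,
        edge_bias=config.edge_bias, readout_mode=config.readout,
    )
    opt = _Adam(params.weights, config.lr)
    val_batch = make_batch(val_items, config.edge_bias) if val_items else None
    n = len(train_items)
    best_loss = np.inf
    best_params = params.copy()
    best_epoch = -1
    bad_epochs = 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            batch = make_batch([train_items[i] for i in sel], config.edge_bias)
            loss, _, grads = batch_forward_backward(batch, params, train=True, rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.step(params.weights, grads)
            ep_loss += loss * len(sel)
        ep_loss /= n
        if val_batch is not None:
            val_loss, _, _ = batch_forward_backward(val_batch, params, train=False)
        else:
            val_loss = ep_loss
        history.append({"epoch": epoch, "train_loss": ep_loss, "val_loss": val_loss})
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = params.copy()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    info = {"best_epoch": best_epoch, "best_val_loss": float(best_loss),
            "epochs_run": len(history), "history": history}
    return best_params, info


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def balance_classes(dataset: LabeledDataset, ratio: float, seed: int) -> LabeledDataset:
    """Downsample negatives to `ratio` x positives (seeded, order-preserving)."""
    pos = [i for i in dataset.ids if dataset.labels[i] == 1]
    neg = [i for i in dataset.ids if dataset.labels[i] == 0]
    target = int(round(ratio * len(pos)))
    if len(neg) <= target:
        return dataset
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(neg, size=target, replace=False).tolist()) | set(pos)
    return dataset.subset(keep)


def train_model(dataset: LabeledDataset, config: TrainConfig) -> tuple[FoldEnsemble, list[dict]]:
    """Embeddings + 5-fold cross-validated ensemble on a labeled dataset.

    The embedding corpus is exactly the training dataset passed in —
    held-out test sequences must not be part of it (the caller keeps
    them apart; prediction only looks up vectors, it never retrains).
    Returns the ensemble and per-fold validation metric dicts.
    """
    dataset = balance_classes(dataset, config.neg_pos_ratio, config.seed)
    corpus = [tokenize_kmers(s, config.k) for s in dataset.sequences]
    table = train_embeddings(
        corpus, d=config.d, window=config.embed_window,
        epochs=config.embed_epochs, seed=config.seed,
    )
    items, failures = prepare_graph_inputs(
        dataset.sequences, dataset.labels, table, config
    )
    for sid, reason in failures:
        logger.warning("dropping training sequence %s: %s", sid, reason)
    usable = dataset.subset(set(dataset.ids) - {f[0] for f in failures})
    id_to_item = dict(zip([s.id for s in usable.sequences], items))
    assignment = make_folds(usable, config.folds, config.seed)

    members: list[GatParameters] = []
    fold_reports: list[dict] = []
    for fold in range(config.folds):
        tr = [id_to_item[i] for i in usable.ids if assignment[i] != fold]
        va = [id_to_item[i] for i in usable.ids if assignment[i] == fold]
        params, info = train_fold(tr, va, config, seed=config.seed * config.folds + fold)
        members.append(params)
        val_batch = make_batch(va, config.edge_bias)
        _, probs, _ = batch_forward_backward(val_batch, params, train=False)
        y_val = [usable.labels[i] for i in usable.ids if assignment[i] == fold]
        report = compute_metrics(y_val, probs.tolist(), config.threshold)
        fold_reports.append({
            "fold": fold, "best_epoch": info["best_epoch"],
            "epochs_run": info["epochs_run"], "val_loss": info["best_val_loss"],
            **report.to_dict(),
        })
        logger.info(
            "fold %d: epochs=%d val_loss=%.4f val_acc=%.3f",
            fold, info["epochs_run"], info["best_val_loss"], report.ACC,
        )
    return FoldEnsemble(members, table, config, assignment), fold_reports


def predict_ensemble(
    ensemble: FoldEnsemble,
    seqs: Sequence[NucleotideSequence],
    threshold: float | None = None,
) -> list[dict]:
    """Averaged five-member probability per sequence, thresholded (>=).

    Sequences that cannot form a graph are reported with NA probability
    and a reason rather than being dropped.
    """
    if not seqs:
        raise ValueError("empty input sequence list")
    if threshold is None:
        threshold = ensemble.config.threshold
    items, failures = prepare_graph_inputs(
        seqs, None, ensemble.embeddings, ensemble.config
    )
    failed = dict(failures)
    rows = []
    ok_iter = iter(items)
    for s in seqs:
        if s.id in failed:
            rows.append({"id": s.id, "probability": None, "label": None,
                         "reason": failed[s.id]})
            continue
        X, g, _ = next(ok_iter)
        probs = [gatnet.predict_proba(X, g, m) for m in ensemble.members]
        p = float(np.mean(probs))
        rows.append({"id": s.id, "probability": p,
                     "label": int(p >= threshold), "reason": None})
    return rows


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metrics_from_counts(
    TP: int, TN: int, FP: int, FN: int, AUC: float | None = None
) -> MetricsReport:
    """ACC/SN/SP/MCC from confusion counts.

    ACC = (TP+TN)/(TP+FP+TN+FN);  SN = TP/(TP+FN);  SP = TN/(TN+FP);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    total = TP + TN + FP + FN
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (TP + TN) / total
    sn = TP / (TP + FN) if TP + FN else float("nan")
    sp = TN / (TN + FP) if TN + FP else float("nan")
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / np.sqrt(denom) if denom > 0 else None
    return MetricsReport(TP, TN, FP, FN, acc, sn, sp,
                         float(mcc) if mcc is not None else None, AUC)


def rank_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for tied probabilities."""
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(probabilities)  # midranks
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Confusion counts at `threshold` plus ACC/SN/SP/MCC/AUC.

    Ties at the threshold are classified positive. With a single-class
    input, AUC and MCC are reported as None with a warning.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = (p >= threshold).astype(int)
    TP = int(np.sum((pred == 1) & (y == 1)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    single_class = len(np.unique(y)) < 2
    if single_class:
        warnings.warn("single-class labels: AUC and MCC are undefined (reported as NA)")
        auc = None
    else:
        auc = rank_auc(y, p)
    report = metrics_from_counts(TP, TN, FP, FN, auc)
    if single_class:
        report.MCC = None
    return report
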