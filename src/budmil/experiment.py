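"""Six-fold cross-validation harness, training loop, metrics and reporting.

Slides (or, for purely synthetic embedding studies, bags standing in for
slides) are split per fold into disjoint train/validation/test sets by an
independent seeded draw — the sizes default to the 10/10/9 split of 29
slides.  Training runs bag-wise Adam steps under bag-level binary
cross-entropy for 30 epochs, tracks validation AUC after every epoch, and
keeps the checkpoint of the best validation epoch (earliest on ties).  AUC
is the Mann-Whitney rank statistic (ties count one half); precision and
recall are computed at a configurable probability threshold, 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .abmil import AttentionParams, loss_and_grads, predict_bag
from .encoders import EmbeddingMatrix


@dataclass(frozen=True)
class FoldSplit:
    """One fold's disjoint unit-id partition (units are slides, or bags when
    bags are the sampling unit)."""

    fold_id: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(
                        f"fold {self.fold_id}: unit ids leak across partitions: "
                        f"{sorted(sets[i] & sets[j])}"
                    )


@dataclass
class TrainConfig:
    """Optimizer and model hyperparameters for one training run."""

    epochs: int = 30
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-5
    adam_eps: float = 1e-8
    attention_width: int = 128  # hidden width L of the gated attention
    threshold: float = 0.5  # precision/recall operating point
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _stratified_cuts(
    ids_by_class: dict, sizes: tuple[int, int, int], rng: np.random.Generator
) -> tuple[list, list, list]:
    """Cut each class proportionally into the three partitions."""
    n = sum(len(v) for v in ids_by_class.values())
    parts: tuple[list, list, list] = ([], [], [])
    capacity = list(sizes)
    for cls, ids in sorted(ids_by_class.items(), key=lambda kv: str(kv[0])):
        perm = [ids[i] for i in rng.permutation(len(ids))]
        counts = [int(np.floor(sizes[p] * len(ids) / n)) for p in range(3)]
        leftover = len(ids) - sum(counts)
        # hand leftover units to the partitions with the largest remainders
        remainders = sorted(
            range(3), key=lambda p: sizes[p] * len(ids) / n - counts[p], reverse=True
        )
        for p in remainders[:leftover]:
            counts[p] += 1
        start = 0
        for p in range(3):
            parts[p].extend(perm[start : start + counts[p]])
            capacity[p] -= counts[p]
            start += counts[p]
    # rebalance if rounding over/underfilled a partition
    for p in range(3):
        while capacity[p] < 0:
            q = max(range(3), key=lambda r: capacity[r])
            parts[q].append(parts[p].pop())
            capacity[p] += 1
            capacity[q] -= 1
    return parts


def make_folds(
    unit_ids: Sequence[str],
    n_folds: int,
    sizes: tuple[int, int, int],
    seed: int,
    stratify: Mapping[str, int] | None = None,
) -> list[FoldSplit]:
    """Draw ``n_folds`` independent seeded random train/val/test partitions.

    Each fold shuffles the full id list with a generator keyed by
    ``(seed, fold_id)`` and cuts it at the stated sizes, which must sum to
    the number of units.  With ``stratify`` (a unit-id -> class mapping),
    each class is apportioned proportionally across the partitions — useful
    when the sampling units are individual bags rather than slides, where an
    unstratified draw can land a single-class validation set.
    """
    ids = list(unit_ids)
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != len(ids):
        raise ValueError(
            f"sizes {sizes} sum to {n_train + n_val + n_test}, "
            f"but there are {len(ids)} unit ids"
        )
    if min(sizes) < 1:
        raise ValueError(f"every partition needs at least one unit, got sizes {sizes}")
    folds = []
    for fold_id in range(1, n_folds + 1):
        rng = np.random.default_rng([seed, fold_id])
        if stratify is None:
            perm = [ids[i] for i in rng.permutation(len(ids))]
            train = perm[:n_train]
            val = perm[n_train : n_train + n_val]
            test = perm[n_train + n_val :]
        else:
            by_class: dict = {}
            for uid in ids:
                by_class.setdefault(stratify[uid], []).append(uid)
            train, val, test = _stratified_cuts(by_class, sizes, rng)
        folds.append(
            FoldSplit(fold_id=fold_id, train=tuple(train), val=tuple(val),
                      test=tuple(test))
        )
    return folds


# ---------------------------------------------------------------------------
# Metrics


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability a random positive outscores a random negative.

    Mann-Whitney rank statistic with average ranks, so ties count 1/2.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC undefined for single-class input ({n_pos} positive, {n_neg} negative)"
        )
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def precision_recall(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN) at ``score >= threshold``.

    Precision is reported as 0.0 when nothing is predicted positive.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return precision, recall


def score_bags(params: AttentionParams, bags: Sequence[EmbeddingMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Bag probabilities and ground-truth labels, in input order."""
    scores = np.array([predict_bag(b.H, params, bag_id=b.bag_id).p for b in bags])
    labels = np.array([b.label for b in bags])
    if any(l is None for l in labels):
        raise ValueError("all bags must carry a ground-truth label for evaluation")
    return scores, labels.astype(int)


def evaluate(
    params: AttentionParams,
    bags: Sequence[EmbeddingMatrix],
    threshold: float = 0.5,
) -> tuple[float, float, float]:
    """(AUC, precision, recall) of a checkpoint on labeled bags."""
    scores, labels = score_bags(params, bags)
    auc = auc_score(scores, labels)
    precision, recall = precision_recall(scores, labels, threshold)
    return auc, precision, recall


# ---------------------------------------------------------------------------
# Training


class _Adam:
    """Classic Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: AttentionParams, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in self._as_dict(params).items()}
        self.v = {k: np.zeros_like(v) for k, v in self._as_dict(params).items()}

    @staticmethod
    def _as_dict(params: AttentionParams) -> dict:
        return {"V": params.V, "U": params.U, "w": params.w, "c": params.c,
                "b": np.array(params.b)}

    def step(self, params: AttentionParams, grads: dict) -> None:
        cfg = self.cfg
        self.t += 1
        p = self._as_dict(params)
        for k in p:
            g = np.asarray(grads[k], dtype=np.float64) + cfg.weight_decay * p[k]
            self.m[k] = cfg.beta1 * self.m[k] + (1 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1 - cfg.beta2) * g * g
            m_hat = self.m[k] / (1 - cfg.beta1**self.t)
            v_hat = self.v[k] / (1 - cfg.beta2**self.t)
            update = cfg.lr * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)
            if k == "b":
                params.b = float(p[k] - update)
            else:
                p[k] -= update


BagStore = Mapping[str, Sequence[EmbeddingMatrix]]
"""Mapping unit id -> that unit's labeled embedding bags."""


def _gather(store: BagStore, unit_ids: Sequence[str]) -> list[EmbeddingMatrix]:
    bags: list[EmbeddingMatrix] = []
    for uid in unit_ids:
        if uid not in store:
            raise KeyError(f"unit {uid!r} has no bags in the embedding store")
        bags.extend(store[uid])
    return bags


@dataclass
class FoldHistory:
    """Per-epoch training record of one fold.

    ``final_params`` holds the parameters after the last epoch.  Validation
    AUC saturates within a few epochs on well-separated bags while the
    attention branch keeps refining, so attention-localization analyses read
    the fully trained model here rather than the early best-validation
    checkpoint used for classification metrics.
    """

    fold_id: int
    epoch_loss: list[float] = field(default_factory=list)
    epoch_val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")
    final_params: "AttentionParams | None" = None


def train_fold(
    fold: FoldSplit,
    store: BagStore,
    config: TrainConfig,
) -> tuple[AttentionParams, FoldHistory]:
    """Train one fold and return the best-validation-AUC checkpoint.

    One Adam step per bag; bag order is reshuffled every epoch with a
    generator keyed by ``(seed, fold_id, epoch)``.  Ties in validation AUC
    resolve to the earliest epoch.
    """
    train_bags = _gather(store, fold.train)
    val_bags = _gather(store, fold.val)
    if not train_bags:
        raise ValueError(f"fold {fold.fold_id}: empty training set")
    labels = {b.label for b in train_bags}
    if labels != {0, 1}:
        raise ValueError(
            f"fold {fold.fold_id}: training set must contain both classes, "
            f"got labels {sorted(labels)}"
        )
    D = train_bags[0].D
    params = AttentionParams.init(D=D, L=config.attention_width,
                                  seed=int(np.random.default_rng([config.seed, fold.fold_id]).integers(2**31)))
    opt = _Adam(params, config)
    history = FoldHistory(fold_id=fold.fold_id)
    best_params = params.copy()
    best_auc = -np.inf
    best_epoch = -1
    for epoch in range(config.epochs):
        rng = np.random.default_rng([config.seed, fold.fold_id, epoch])
        order = rng.permutation(len(train_bags))
        total_loss = 0.0
        for idx in order:
            bag = train_bags[idx]
            loss, grads = loss_and_grads(bag.H, bag.label, params)
            opt.step(params, grads)
            total_loss += loss
        val_auc, _, _ = evaluate(params, val_bags, config.threshold)
        history.epoch_loss.append(total_loss / len(train_bags))
        history.epoch_val_auc.append(val_auc)
        if val_auc > best_auc:  # strict: ties keep the earliest epoch
            best_auc = val_auc
            best_epoch = epoch
            best_params = params.copy()
    history.best_epoch = best_epoch
    history.best_val_auc = float(best_auc)
    history.final_params = params.copy()
    return best_params, history


# ---------------------------------------------------------------------------
# Aggregation / reporting


@dataclass
class FoldReport:
    """Per-fold and aggregated metrics, plus optional hold-out results."""

    per_fold: list[dict]  # fold_id, auc, precision, recall, best_epoch
    mean: dict[str, float]
    sd: dict[str, float]  # sample standard deviation (ddof=1; 0 for one fold)
    se: dict[str, float]  # standard error of the mean
    holdout: dict[str, float] | None = None
    best_fold_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "holdout": self.holdout,
            "best_fold_id": self.best_fold_id,
        }


_METRICS = ("auc", "precision", "recall")


def aggregate_and_report(
    per_fold: list[dict],
    holdout: dict[str, float] | None = None,
) -> FoldReport:
    """Aggregate per-fold metrics into mean, sample SD and standard error.

    Both SD and SE are reported because "±" conventions differ between
    publications; the fold with the highest validation-selected test AUC is
    flagged as the candidate for hold-out evaluation.
    """
    if not per_fold:
        raise ValueError("need at least one fold to aggregate")
    n = len(per_fold)
    mean, sd, se = {}, {}, {}
    for m in _METRICS:
        vals = np.array([f[m] for f in per_fold], dtype=np.float64)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std(ddof=1)) if n > 1 else 0.0
        se[m] = sd[m] / np.sqrt(n) if n > 1 else 0.0
    best = max(per_fold, key=lambda f: f["auc"])
    return FoldReport(per_fold=per_fold, mean=mean, sd=sd, se=se,
                      holdout=holdout, best_fold_id=int(best["fold_id"]))


def render_table(report: FoldReport, model_name: str = "budmil-ABMIL") -> str:
    """Render the cross-validation summary as a plain-text table."""
    lines = [
        f"{'Dataset':<28}{'Model':<16}{'AUC':<18}{'Precision':<18}{'Recall':<18}",
        "-" * 98,
    ]
    row = f"{'Average over folds':<28}{model_name:<16}"
    for m in _METRICS:
        row += f"{report.mean[m]:.3f} ± {report.se[m]:.3f}    "
    lines.append(row)
    if report.holdout is not None:
        row = f"{'Hold-out test set':<28}{model_name:<16}"
        for m in _METRICS:
            row += f"{report.holdout[m]:.3f}            "
        lines.append(row)
    return "\n".join(lines)


def run_cross_validation(
    store: BagStore,
    n_folds: int,
    sizes: tuple[int, int, int],
    config: TrainConfig,
    holdout_bags: Sequence[EmbeddingMatrix] | None = None,
    stratify: Mapping[str, int] | None = None,
) -> tuple[FoldReport, list[FoldHistory], dict[int, AttentionParams]]:
    """Full protocol: fold construction, per-fold training, test evaluation,
    aggregation, and optional hold-out evaluation with the best fold's model."""
    folds = make_folds(sorted(store), n_folds, sizes, seed=config.seed,
                       stratify=stratify)
    per_fold, histories, checkpoints = [], [], {}
    for fold in folds:
        params, hist = train_fold(fold, store, config)
        test_bags = _gather(store, fold.test)
        auc, precision, recall = evaluate(params, test_bags, config.threshold)
        per_fold.append(
            {"fold_id": fold.fold_id, "auc": auc, "precision": precision,
             "recall": recall, "best_epoch": hist.best_epoch}
        )
        histories.append(hist)
        checkpoints[fold.fold_id] = params
    holdout = None
    best_fold = max(per_fold, key=lambda f: f["auc"])["fold_id"]
    if holdout_bags is not None:
        h_auc, h_prec, h_rec = evaluate(checkpoints[best_fold], holdout_bags, config.threshold)
        holdout = {"auc": h_auc, "precision": h_prec, "recall": h_rec}
    report = aggregate_and_report(per_fold, holdout)
    report.best_fold_id = best_fold
    return report, histories, checkpoints


def witness_attention_fraction(
    params: AttentionParams,
    bags: Sequence[EmbeddingMatrix],
    witness_masks: Mapping[str, np.ndarray],
) -> float:
    """Fraction of positive bags whose mean attention over witness instances
    exceeds the mean over non-witness instances.

    Scores how well the attention mechanism localizes the instances that
    actually carry the bag label (the synthetic analog of attention heatmaps
    aligning with annotated buds).
    """
    from .abmil import gated_attention

    hits = total = 0
    for bag in bags:
        if bag.label != 1:
            continue
        mask = np.asarray(witness_masks[bag.bag_id], dtype=bool)
        if not mask.any() or mask.all():
            continue
        a = gated_attention(bag.H, params)
        hits += a[mask].mean() > a[~mask].mean()
        total += 1
    if total == 0:
        raise ValueError("no positive bags with mixed witness masks to score")
    return hits / total


def roc_curve_figure(
    scores: np.ndarray, labels: np.ndarray, path: str | Path, title: str = "ROC"
) -> None:
    """Save an ROC curve (empirical, threshold-swept) with its AUC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    tpr = np.concatenate([[0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps / max(fps[-1], 1)])
    auc = auc_score(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


__all__ = [
    "FoldHistory",
    "FoldReport",
    "FoldSplit",
    "TrainConfig",
    "aggregate_and_report",
    "auc_score",
    "evaluate",
    "make_folds",
    "precision_recall",
    "render_table",
    "roc_curve_figure",
    "run_cross_validation",
    "score_bags",
    "train_fold",
]
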