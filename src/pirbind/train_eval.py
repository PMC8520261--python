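"""Split protocol, training loop, confusion metrics, ROC/AUC and the
rank-sum model comparison.

The evaluation protocol splits the balanced pair set into ten
label-stratified folds, using eight for training, one for validation and
one for testing, and repeats the random split 30 times; across 30 repeats
every pair is expected in the train/validation/test sets 24/3/3 times.
Training runs a fixed number of epochs (no early stopping) of Adam with a
reduce-on-plateau schedule monitored on validation loss, and final-epoch
weights are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .attention_net import NetConfig, PiRNATargetNet, cross_entropy
from .clash_prep import GroundTruth, PairExample
from .nn import Adam, ReduceLROnPlateau, softmax
from .seq_core import one_hot_encode


# ---------------------------------------------------------------------------
# Split protocol
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    n_items: int
    n_repeats: int
    seed: int
    #: per repeat: (train_idx, val_idx, test_idx) arrays partitioning 0..n-1
    repeats: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False)

    def membership_counts(self) -> np.ndarray:
        """(n_items, 3) counts of train/val/test membership across repeats."""
        counts = np.zeros((self.n_items, 3), dtype=int)
        for tr, va, te in self.repeats:
            counts[tr, 0] += 1
            counts[va, 1] += 1
            counts[te, 2] += 1
        return counts


def make_random_splits(
    n_items: int,
    labels: "np.ndarray | None" = None,
    n_repeats: int = 30,
    n_folds: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Repeated stratified 10-fold 8:1:1 train/val/test splits.

    Per repeat the items are shuffled into ten folds (stratified by label
    when labels are given, keeping the class balance in every fold); eight
    folds train, one validates, one tests.  Deterministic given ``seed``.
    """
    if n_items < n_folds:
        raise ValueError(f"need at least {n_folds} items, got {n_items}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_items, dtype=int) if labels is None else np.asarray(labels)
    repeats = []
    for _ in range(n_repeats):
        fold_of = np.empty(n_items, dtype=int)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            idx = idx[rng.permutation(len(idx))]
            fold_of[idx] = np.arange(len(idx)) % n_folds
        roles = rng.permutation(n_folds)
        val_fold, test_fold = roles[0], roles[1]
        tr = np.flatnonzero((fold_of != val_fold) & (fold_of != test_fold))
        va = np.flatnonzero(fold_of == val_fold)
        te = np.flatnonzero(fold_of == test_fold)
        repeats.append((tr, va, te))
    return SplitPlan(n_items=n_items, n_repeats=n_repeats, seed=seed, repeats=repeats)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 512
    epochs: int = 60
    scheduler_patience: int = 5
    scheduler_factor: float = 0.1
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.epochs) <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")


def encode_pairs(pairs: "list[PairExample]") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-hot arrays (N, Lp, 4), (N, Lm, 4) and integer labels."""
    p_oh = np.stack([one_hot_encode(p.pirna_seq) for p in pairs])
    m_oh = np.stack([one_hot_encode(p.mrna_segment) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.int64)
    return p_oh, m_oh, y


def _eval_loss_acc(model, p_oh, m_oh, y, batch_size=512):
    losses, correct = [], 0
    for lo in range(0, len(y), batch_size):
        logits, _, _ = model.forward(p_oh[lo:lo + batch_size], m_oh[lo:lo + batch_size])
        probs = softmax(logits).data
        yy = y[lo:lo + batch_size]
        losses.append(-np.log(np.maximum(probs[np.arange(len(yy)), yy], 1e-12)))
        correct += int((probs.argmax(axis=1) == yy).sum())
    return float(np.concatenate(losses).mean()), correct / len(y)


def train_model(
    model_kind: str,
    gt_or_arrays,
    split: "tuple[np.ndarray, np.ndarray] | None" = None,
    train_cfg: "TrainConfig | None" = None,
    net_cfg: "NetConfig | None" = None,
) -> tuple[PiRNATargetNet, list[dict]]:
    """Train a full or pure-CNN model; returns (model, per-epoch log).

    ``gt_or_arrays`` is a :class:`GroundTruth` (encoded on the fly) or a
    pre-encoded ``(p_oh, m_oh, labels)`` triple; ``split`` gives train/val
    index arrays (defaults to a 9:1 split).  Training runs the configured
    number of epochs with no early stopping; the scheduler steps on
    validation loss and the final-epoch weights are returned.  Raises on an
    empty train split and on divergence (non-finite loss), reporting the
    epoch index.
    """
    cfg = train_cfg or TrainConfig()
    if isinstance(gt_or_arrays, GroundTruth):
        p_oh, m_oh, y = encode_pairs(gt_or_arrays.examples)
    else:
        p_oh, m_oh, y = gt_or_arrays
    if split is None:
        n = len(y)
        rng0 = np.random.default_rng(cfg.seed)
        perm = rng0.permutation(n)
        cut = max(1, n // 10)
        split = (perm[cut:], perm[:cut])
    train_idx, val_idx = np.asarray(split[0]), np.asarray(split[1])
    if len(train_idx) == 0:
        raise ValueError("empty train split")

    net_cfg = net_cfg or NetConfig(pirna_len=p_oh.shape[1], mrna_len=m_oh.shape[1])
    model = PiRNATargetNet(net_cfg, kind=model_kind, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    sched = ReduceLROnPlateau(
        opt, patience=cfg.scheduler_patience, factor=cfg.scheduler_factor,
        min_lr=cfg.min_lr,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses, correct, seen = [], 0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = train_idx[order[lo : lo + cfg.batch_size]]
            if len(idx) < 2:
                continue  # batch statistics need at least two examples
            opt.zero_grad()
            logits, _, _ = model.forward(p_oh[idx], m_oh[idx], train=True, rng=rng)
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
        if len(val_idx):
            val_loss, val_acc = _eval_loss_acc(model, p_oh[val_idx], m_oh[val_idx], y[val_idx])
            sched.step(val_loss)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        log.append(
            dict(
                epoch=epoch,
                train_loss=float(np.mean(epoch_losses)),
                train_acc=correct / max(seen, 1),
                val_loss=val_loss,
                val_acc=val_acc,
                lr=opt.lr,
            )
        )
    return model, log


def predict_pairs(model: PiRNATargetNet, pairs: "list[PairExample]") -> np.ndarray:
    """Positive-class probabilities for a list of pairs."""
    p_oh, m_oh, _ = encode_pairs(pairs)
    return model.predict_proba(p_oh, m_oh)[:, 1]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: "float | None"
    specificity: "float | None"
    accuracy: "float | None"
    precision: "float | None"
    f1: "float | None"

    @property
    def recall(self) -> "float | None":
        return self.sensitivity


def _ratio(num: int, den: int) -> "float | None":
    return num / den if den else None


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_metrics(
    labels, scores, threshold: float = 0.5
) -> MetricsReport:
    """Counts and ratios at a decision threshold on positive-class scores.

    Ratios with zero denominators are reported as ``None`` (undefined),
    never as 0.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = (
        f1_score(precision, recall)
        if precision is not None and recall is not None
        else None
    )
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=recall,
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        precision=precision,
        f1=f1,
    )


@dataclass
class ROC:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_auc(labels, scores) -> ROC:
    """ROC curve by threshold sweep; AUC by the rank (Mann-Whitney)
    formulation with tie correction, which equals the trapezoidal area."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys == 1)[distinct]
    fps = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, ss[distinct]]
    return ROC(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


def compare_auc_ranksum(auc_list_a, auc_list_b) -> float:
    """One-tailed Mann-Whitney rank-sum p-value for median(a) > median(b),
    normal approximation with tie correction."""
    a = np.asarray(auc_list_a, dtype=float)
    b = np.asarray(auc_list_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two AUC values per model")
    res = stats.mannwhitneyu(
        a, b, alternative="greater", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)
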