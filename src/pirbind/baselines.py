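"""Whole-sequence baseline scores for piRNA-mRNA pair classification.

Eighteen features per pair: the CG content of the mRNA window, the four
nucleotide composition fractions, four tandem-repeat summaries for each of
k = 2, 3, 4 (counting maximal head-to-tail runs of a k-mer repeated at
least twice), and the piRNA-mRNA duplex energy.  Individually they make
single-score ROC baselines; jointly they feed a small MLP
(18 -> 128 -> 128 -> 128 -> 2, dropout 0.1, Adam at 2.6e-4) that serves as
the feature-based comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clash_prep import PairExample
from .nn import Adam, Tensor, dropout as nn_dropout, log_softmax, softmax
from .seq_core import NucleotideSequence, duplex_energy
from .train_eval import ROC, roc_auc

TANDEM_KS = (2, 3, 4)

FEATURE_NAMES = (
    ["cg_content", "comp_A", "comp_U", "comp_C", "comp_G"]
    + [
        f"k{k}_{name}"
        for k in TANDEM_KS
        for name in ("n_loci", "max_unit_count", "covered_fraction", "n_distinct_units")
    ]
    + ["duplex_energy"]
)


def composition_features(segment) -> tuple[float, float, float, float, float]:
    """(CG fraction, A%, U%, C%, G%) of a sequence; fractions sum to 1."""
    s = segment.bases if isinstance(segment, NucleotideSequence) else str(segment)
    if len(s) == 0:
        raise ValueError("empty sequence")
    n = len(s)
    a, u, c, g = (s.count(b) / n for b in "AUCG")
    return (c + g, a, u, c, g)


def tandem_repeat_features(segment, k: int) -> tuple[int, int, float, int]:
    """Summaries of maximal head-to-tail k-mer repeat runs.

    A run is a k-mer repeated >= 2 times back-to-back, maximal in the sense
    that it cannot be extended by one more unit on the left.  Returns
    (number of runs, maximum repeat multiplicity, fraction of positions
    covered by any run, number of distinct repeat units).
    """
    if k not in TANDEM_KS:
        raise ValueError(f"k must be one of {TANDEM_KS}")
    s = segment.bases if isinstance(segment, NucleotideSequence) else str(segment)
    if len(s) < 2 * k:
        raise ValueError("segment shorter than two repeat units")
    runs: list[tuple[int, int, str]] = []  # (start, multiplicity, unit)
    covered_free = 0  # greedy left-to-right scan; runs do not overlap
    for i in range(len(s) - 2 * k + 1):
        if i < covered_free:
            continue
        unit = s[i : i + k]
        r = 1
        while s[i + r * k : i + (r + 1) * k] == unit:
            r += 1
        if r >= 2:
            runs.append((i, r, unit))
            covered_free = i + r * k
    if not runs:
        return (0, 0, 0.0, 0)
    covered: set[int] = set()
    for start, r, _unit in runs:
        covered.update(range(start, start + r * k))
    return (
        len(runs),
        max(r for _s, r, _u in runs),
        len(covered) / len(s),
        len({u for _s, _r, u in runs}),
    )


def feature_vector(pair: PairExample, energy_scorer: str = "internal") -> np.ndarray:
    """The 18 whole-sequence features of one pair, ordered as FEATURE_NAMES."""
    vals = list(composition_features(pair.mrna_segment))
    for k in TANDEM_KS:
        vals.extend(tandem_repeat_features(pair.mrna_segment, k))
    vals.append(duplex_energy(pair.pirna_seq, pair.mrna_segment, scorer=energy_scorer))
    return np.array(vals, dtype=np.float64)


def feature_matrix(pairs: "list[PairExample]", energy_scorer: str = "internal") -> np.ndarray:
    return np.stack([feature_vector(p, energy_scorer) for p in pairs])


def single_feature_auc(pairs: "list[PairExample]", feature_name: str) -> ROC:
    """ROC of one raw feature, sign-oriented so that AUC >= 0.5."""
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")
    j = FEATURE_NAMES.index(feature_name)
    scores = np.array([feature_vector(p)[j] for p in pairs])
    labels = np.array([p.label for p in pairs])
    if np.allclose(scores, scores[0]):
        raise ValueError(f"feature {feature_name!r} is constant; ROC is degenerate")
    roc = roc_auc(labels, scores)
    if roc.auc < 0.5:
        roc = roc_auc(labels, -scores)
    return roc


@dataclass(frozen=True)
class MLPConfig:
    hidden: tuple[int, int, int] = (128, 128, 128)
    dropout: float = 0.1
    lr: float = 0.00026
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0


class FeatureMLP:
    """Feed-forward classifier on standardized 18-dim feature vectors."""

    def __init__(self, cfg: MLPConfig = MLPConfig(), n_features: int = 18):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [n_features, *cfg.hidden, 2]
        self.weights = []
        self.biases = []
        for din, dout in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(din)
            self.weights.append(Tensor.param(rng.uniform(-bound, bound, (din, dout))))
            self.biases.append(Tensor.param(np.zeros(dout)))
        self.mu = np.zeros(n_features)
        self.sd = np.ones(n_features)

    def parameters(self):
        return [*self.weights, *self.biases]

    def _forward(self, x: np.ndarray, train: bool, rng) -> Tensor:
        h = Tensor(x.astype(np.float32))
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = h.relu()
                h = nn_dropout(h, self.cfg.dropout, rng, train)
        return h

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureMLP":
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        self.mu = X.mean(axis=0)
        self.sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xz = (X - self.mu) / self.sd
        y = np.asarray(y, dtype=np.int64)
        opt = Adam(self.parameters(), lr=self.cfg.lr)
        rng = np.random.default_rng(self.cfg.seed + 1)
        onehot = np.eye(2, dtype=np.float32)[y]
        for _epoch in range(self.cfg.epochs):
            order = rng.permutation(len(y))
            for lo in range(0, len(y), self.cfg.batch_size):
                idx = order[lo : lo + self.cfg.batch_size]
                opt.zero_grad()
                logits = self._forward(Xz[idx], train=True, rng=rng)
                lp = log_softmax(logits)
                loss = -(lp * Tensor(onehot[idx])).sum() * (1.0 / len(idx))
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xz = (X - self.mu) / self.sd
        return softmax(self._forward(Xz, train=False, rng=None)).data


def train_mlp_baseline(
    features: np.ndarray, labels: np.ndarray, mlp_cfg: MLPConfig = MLPConfig()
) -> FeatureMLP:
    """Fit the feature-based MLP baseline; deterministic given cfg.seed."""
    return FeatureMLP(mlp_cfg, n_features=features.shape[1]).fit(features, labels)
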