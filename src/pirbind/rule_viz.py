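"""Attention-weight extraction and visualization for binding-rule mining.

The trained model's per-head attention matrices (mRNA positions x piRNA
positions, each row a probability distribution over piRNA positions) are
averaged over heads; per-piRNA-position salience is the column mean of that
matrix, and consensus regions are maximal runs of positions whose salience
exceeds mean + c * sd.  On models trained against a planted seed rule the
dominant consensus region is expected over the seed positions; randomly
paired sequences should yield no reproducible region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attention_net import PiRNATargetNet


@dataclass
class RuleSummary:
    mean_weights: np.ndarray  # (mrna_len, pirna_len), rows sum to 1
    per_position_salience: np.ndarray  # (pirna_len,)
    #: maximal runs above threshold: (start_nt, end_nt, mean_salience),
    #: 1-based inclusive piRNA coordinates
    consensus_regions: list[tuple[int, int, float]]
    threshold_c: float = 1.0
    p_positive: "float | None" = None
    trained: bool = True

    def region_positions(self) -> set[int]:
        out: set[int] = set()
        for start, end, _sal in self.consensus_regions:
            out.update(range(start, end + 1))
        return out


def consensus_regions_from_salience(
    salience: np.ndarray, c: float = 1.0
) -> list[tuple[int, int, float]]:
    """Maximal runs of positions with salience > mean + c * sd (1-based)."""
    salience = np.asarray(salience, dtype=float)
    thr = salience.mean() + c * salience.std()
    above = salience > thr
    regions = []
    start = None
    for j, flag in enumerate(above):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            regions.append((start + 1, j, float(salience[start:j].mean())))
            start = None
    if start is not None:
        regions.append((start + 1, len(above), float(salience[start:].mean())))
    return regions


def extract_rule(
    model: PiRNATargetNet,
    pirna_seq,
    mrna_seq,
    c: float = 1.0,
    trained: bool = True,
) -> RuleSummary:
    """Head-mean attention summary of one pair (eval mode).

    ``trained=False`` flags summaries taken from an untrained/random model
    in the output metadata rather than refusing them.
    """
    if model.kind != "full":
        raise ValueError("rule extraction requires the attention model")
    pred, attn = model.forward_pair(pirna_seq, mrna_seq, mode="eval")
    mean_w = attn.per_head_weights.mean(axis=0)
    salience = mean_w.mean(axis=0)
    return RuleSummary(
        mean_weights=mean_w,
        per_position_salience=salience,
        consensus_regions=consensus_regions_from_salience(salience, c),
        threshold_c=c,
        p_positive=pred.p_positive,
        trained=trained,
    )


def aggregate_rule(
    model: PiRNATargetNet, pairs, c: float = 1.0, trained: bool = True
) -> RuleSummary:
    """Head-mean attention averaged over several (piRNA, mRNA) pairs."""
    mats = []
    for p in pairs:
        _, attn = model.forward_pair(p.pirna_seq, p.mrna_segment, mode="eval")
        mats.append(attn.per_head_weights.mean(axis=0))
    mean_w = np.mean(mats, axis=0)
    salience = mean_w.mean(axis=0)
    return RuleSummary(
        mean_weights=mean_w,
        per_position_salience=salience,
        consensus_regions=consensus_regions_from_salience(salience, c),
        threshold_c=c,
        trained=trained,
    )


def export_heatmap(
    summary: RuleSummary, path: "str | Path", render_image: bool = True
) -> Path:
    """Write the head-mean weight matrix as TSV (and a PNG next to it).

    TSV rows are mRNA positions 1..L_m, columns piRNA positions 1..L_p;
    the matrix round-trips losslessly through the TSV.
    """
    path = Path(path)
    mat = summary.mean_weights
    n_m, n_p = mat.shape
    with open(path, "w") as fh:
        fh.write("mrna_pos\t" + "\t".join(f"pirna_{j + 1}" for j in range(n_p)) + "\n")
        for i in range(n_m):
            fh.write(
                str(i + 1) + "\t" + "\t".join(repr(float(v)) for v in mat[i]) + "\n"
            )
    if render_image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 7))
        im = ax.imshow(mat, aspect="auto", cmap="viridis", origin="upper")
        ax.set_xlabel("piRNA position")
        ax.set_ylabel("mRNA window position")
        ax.set_xticks(range(0, n_p, 2), [str(j + 1) for j in range(0, n_p, 2)])
        fig.colorbar(im, ax=ax, label="mean attention weight")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return path


def read_heatmap_tsv(path: "str | Path") -> np.ndarray:
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return np.array(rows)
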