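"""Ground-truth construction from CLASH chimeric reads.

A chimera is a single sequencing read containing a piRNA ligated to a
fragment of the mRNA it was bound to.  This module turns a chimera library,
a piRNA catalog and a transcriptome into

* the rigorous **positive set** — piRNA / 31-nt mRNA-window pairs passing five
  filters (read count >= 7; unambiguous piRNA excision with remaining
  fragment >= 14 nt; perfect transcriptome mapping; unique placement; duplex
  energy < 0),
* the **loose binding set (LBS)** — (piRNA, transcript) pairs with any weak
  chimera evidence (count >= 1, remaining >= 7, mapping within 1 mismatch),
  whose complement per piRNA defines the negative candidate transcripts
  ``NCS_i = U - {x | (i, x) in LBS}``, and
* the sampled **negative set** — random windows from negative-candidate
  transcripts, re-drawn when they resemble any positive window within 2
  mismatches or cannot physically pair with the piRNA (energy >= 0).

An attrition report counts every chimera exactly once (survivor or single
eliminating rule), so input count = survivors + sum of exclusions.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seq_core import (
    NucleotideSequence,
    SequenceError,
    duplex_energy,
    is_valid,
    scan_with_mismatches,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimeraRead:
    sequence: NucleotideSequence
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class PiRNARecord:
    id: str
    sequence: NucleotideSequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    center: int  # 0-based
    segment: NucleotideSequence  # length 2*extension_l + 1
    extension_l: int

    def __post_init__(self) -> None:
        if len(self.segment) != 2 * self.extension_l + 1:
            raise ValueError("segment length must equal 2*extension_l + 1")


@dataclass(frozen=True)
class PairExample:
    """One (piRNA, mRNA window) example; the unit of training/evaluation."""

    pirna_id: str
    pirna_seq: NucleotideSequence
    mrna_segment: NucleotideSequence
    label: int  # 1 = positive (binding), 0 = negative
    provenance: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.pirna_id, self.mrna_segment.bases)


@dataclass
class GroundTruth:
    positives: list[PairExample]
    negatives: list[PairExample]
    loose_set: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        pos_keys = {p.key for p in self.positives}
        neg_keys = {n.key for n in self.negatives}
        overlap = pos_keys & neg_keys
        if overlap:
            raise ValueError(f"positive/negative key overlap: {sorted(overlap)[:3]}")

    @property
    def examples(self) -> list[PairExample]:
        return list(self.positives) + list(self.negatives)

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.examples], dtype=np.int64)


class SplitOutcome(Enum):
    MATCHED = "matched"
    NO_MATCH = "no_match"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PrepConfig:
    """Thresholds of the rigorous and loose filtering rules."""

    min_read_count: int = 7
    min_remaining: int = 14
    max_mm: int = 0
    extension_l: int = 15
    loose_min_read_count: int = 1
    loose_min_remaining: int = 7
    loose_max_mm: int = 1
    energy_scorer: str = "internal"

    def __post_init__(self) -> None:
        for name in ("min_read_count", "min_remaining", "max_mm", "extension_l",
                     "loose_min_read_count", "loose_min_remaining", "loose_max_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def collapse_reads(raw_sequences: Sequence[str]) -> tuple[list[ChimeraRead], int]:
    """Collapse raw read strings into distinct chimeras with multiplicities.

    Reads containing ambiguous bases (e.g. ``N``) are dropped; the number of
    dropped reads is returned alongside the collapsed records.  The counts of
    the retained records sum to the number of retained raw reads.
    """
    if len(raw_sequences) == 0:
        raise ValueError("empty read input")
    dropped = 0
    counter: Counter[str] = Counter()
    for raw in raw_sequences:
        s = raw.upper().replace("T", "U")
        if not is_valid(s):
            dropped += 1
            continue
        counter[s] += 1
    reads = [
        ChimeraRead(NucleotideSequence(seq), count)
        for seq, count in sorted(counter.items())
    ]
    return reads, dropped


def split_chimera(
    read: ChimeraRead, catalog: Sequence[PiRNARecord]
) -> tuple[SplitOutcome, "PiRNARecord | None", "NucleotideSequence | None"]:
    """Excise the perfectly matching catalog piRNA from a chimera.

    Exactly one distinct catalog piRNA may match as an exact substring;
    zero matches -> NO_MATCH, two or more distinct piRNAs -> AMBIGUOUS
    (reads assumed to carry a unique piRNA each).  When the match is
    internal both flanks are candidates for the remaining (mRNA) fragment;
    the longer flank wins, ties broken toward the 3' flank.
    """
    if not catalog:
        raise ValueError("empty piRNA catalog")
    seq = read.sequence.bases
    matches: list[tuple[PiRNARecord, int]] = []
    matched_seqs = set()
    for p in catalog:
        idx = seq.find(p.sequence.bases)
        while idx != -1:
            matches.append((p, idx))
            matched_seqs.add(p.sequence.bases)
            idx = seq.find(p.sequence.bases, idx + 1)
    if not matches:
        return SplitOutcome.NO_MATCH, None, None
    if len(matched_seqs) > 1:
        return SplitOutcome.AMBIGUOUS, None, None
    # one distinct piRNA, possibly several occurrences: keep the occurrence
    # yielding the longest remaining fragment (ties toward the 3' flank).
    best: tuple[int, int, PiRNARecord, str] | None = None
    for p, idx in matches:
        head = seq[:idx]
        tail = seq[idx + len(p.sequence) :]
        # prefer the longer flank; on equal lengths take the 3' (tail) flank
        flank = tail if len(tail) >= len(head) else head
        cand = (len(flank), 1 if flank is tail else 0, p, flank)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    _, _, pirna, flank = best
    if len(flank) == 0:
        return SplitOutcome.MATCHED, pirna, None
    return SplitOutcome.MATCHED, pirna, NucleotideSequence(flank)


def map_segment(
    remaining: NucleotideSequence,
    transcriptome: Sequence[NucleotideSequence],
    max_mm: int = 0,
) -> list[tuple[str, int, int]]:
    """All ungapped transcriptome placements of a chimera fragment.

    Returns (transcript_id, start, mismatches) with 0-based starts.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    hits = []
    for t in transcriptome:
        for start, mm in scan_with_mismatches(remaining, t, max_mm):
            hits.append((t.name, start, mm))
    return hits


def site_from_alignment(
    transcript: NucleotideSequence, start: int, seg_len: int, extension_l: int
) -> "TargetSite | str":
    """Window extraction around the center of a mapped fragment.

    The site center is the floor midpoint of the mapped start/end positions;
    ``extension_l`` bases are extended on each side (degradation recovery).
    Windows overrunning a transcript end are rejected (returned as a reason
    string), never padded — the network requires fixed-length input.
    """
    if start < 0 or start + seg_len > len(transcript):
        raise ValueError("alignment outside transcript bounds")
    center = (start + start + seg_len - 1) // 2
    lo = center - extension_l
    hi = center + extension_l + 1
    if lo < 0:
        return "window_underrun"
    if hi > len(transcript):
        return "window_overrun"
    return TargetSite(
        transcript_id=transcript.name,
        center=center,
        segment=NucleotideSequence(transcript.bases[lo:hi]),
        extension_l=extension_l,
    )


# ---------------------------------------------------------------------------
# Positive / loose / negative set construction
# ---------------------------------------------------------------------------

_RIGOROUS_RULES = (
    "read_count",       # rule 1: chimera read count >= 7
    "split",            # piRNA excision failed (no match / ambiguous)
    "remaining_length", # rule 2: remaining fragment >= 14 nt
    "mapping",          # rule 3: no perfect transcriptome placement
    "multi_hit",        # rule 4: fragment found at >1 placement
    "window",           # 31-nt window overruns a transcript end
    "energy",           # rule 5: duplex energy must be < 0
)


def build_positive_set(
    chimeras: Sequence[ChimeraRead],
    catalog: Sequence[PiRNARecord],
    transcriptome: Sequence[NucleotideSequence],
    cfg: "PrepConfig | None" = None,
) -> tuple[list[PairExample], dict]:
    """Apply the five rigorous rules; return positives + attrition report.

    Rules are applied in order and each chimera is charged to the first rule
    that eliminates it, so the report conserves the input count.  Pairs are
    deduplicated on (piRNA id, window sequence).
    """
    cfg = cfg or PrepConfig()
    report = {rule: 0 for rule in _RIGOROUS_RULES}
    report["input"] = len(chimeras)
    by_id = {t.name: t for t in transcriptome}
    survivors: dict[tuple[str, str], PairExample] = {}
    n_surviving_chimeras = 0

    for read in chimeras:
        if read.read_count < cfg.min_read_count:
            report["read_count"] += 1
            continue
        outcome, pirna, remaining = split_chimera(read, catalog)
        if outcome is not SplitOutcome.MATCHED or remaining is None:
            report["split"] += 1
            continue
        if len(remaining) < cfg.min_remaining:
            report["remaining_length"] += 1
            continue
        hits = map_segment(remaining, transcriptome, cfg.max_mm)
        if not hits:
            report["mapping"] += 1
            continue
        if len(hits) > 1:
            # target sequence found multiple times among isoforms or within a
            # transcript: drop to avoid latent training weight on the pair
            report["multi_hit"] += 1
            continue
        tid, start, mm = hits[0]
        site = site_from_alignment(by_id[tid], start, len(remaining), cfg.extension_l)
        if isinstance(site, str):
            report["window"] += 1
            continue
        energy = duplex_energy(pirna.sequence, site.segment, scorer=cfg.energy_scorer)
        if not energy < 0:
            report["energy"] += 1
            continue
        n_surviving_chimeras += 1
        pair = PairExample(
            pirna_id=pirna.id,
            pirna_seq=pirna.sequence,
            mrna_segment=site.segment,
            label=1,
            provenance=dict(
                transcript_id=tid,
                center=site.center,
                read_count=read.read_count,
                remaining_len=len(remaining),
                mismatches=mm,
                energy=energy,
            ),
        )
        survivors.setdefault(pair.key, pair)

    report["survivors"] = n_surviving_chimeras
    report["unique_pairs"] = len(survivors)
    return list(survivors.values()), report


def build_loose_set(
    chimeras: Sequence[ChimeraRead],
    catalog: Sequence[PiRNARecord],
    transcriptome: Sequence[NucleotideSequence],
    cfg: "PrepConfig | None" = None,
) -> set[tuple[str, str]]:
    """The loose binding set: (piRNA id, transcript id) pairs with any
    chimera evidence under the relaxed rules (count >= 1, remaining >= 7,
    mapping within 1 mismatch).  No energy or uniqueness filtering."""
    cfg = cfg or PrepConfig()
    lbs: set[tuple[str, str]] = set()
    for read in chimeras:
        if read.read_count < cfg.loose_min_read_count:
            continue
        outcome, pirna, remaining = split_chimera(read, catalog)
        if outcome is not SplitOutcome.MATCHED or remaining is None:
            continue
        if len(remaining) < cfg.loose_min_remaining:
            continue
        for tid, _start, _mm in map_segment(remaining, transcriptome, cfg.loose_max_mm):
            lbs.add((pirna.id, tid))
    return lbs


def negative_candidates(
    pirna_id: str,
    universe: "set[str] | Sequence[str]",
    loose_set: set[tuple[str, str]],
    positive_pirna_ids: "set[str] | None" = None,
) -> set[str]:
    """``NCS_i = U - {x | (i, x) in LBS}`` for a positive-set piRNA."""
    if positive_pirna_ids is not None and pirna_id not in positive_pirna_ids:
        raise ValueError(
            f"{pirna_id!r} is not a positive-set piRNA; negative candidates "
            "are only defined for piRNAs with binding evidence"
        )
    return set(universe) - {x for (i, x) in loose_set if i == pirna_id}


def sample_negatives(
    positives: Sequence[PairExample],
    loose_set: set[tuple[str, str]],
    transcriptome: Sequence[NucleotideSequence],
    n_target: int,
    rng_seed: int = 0,
    cfg: "PrepConfig | None" = None,
    draw_budget_factor: int = 200,
) -> list[PairExample]:
    """Sample the verified random-association negative set.

    Draws (piRNA from the positive set, window from a negative-candidate
    transcript) uniformly; a draw is rejected when the window matches any
    positive window within 2 mismatches (ungapped, same length) or when the
    duplex energy is >= 0 (physically unpairable pairs are trivial).
    Deterministic given ``rng_seed``.
    """
    cfg = cfg or PrepConfig()
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(rng_seed)
    window_len = 2 * cfg.extension_l + 1
    universe = {t.name for t in transcriptome}
    by_id = {t.name: t for t in transcriptome}
    pirnas = sorted({(p.pirna_id, p.pirna_seq.bases) for p in positives})
    if not pirnas:
        raise ValueError("empty positive set")
    pos_ids = {pid for pid, _ in pirnas}
    ncs = {
        pid: sorted(negative_candidates(pid, universe, loose_set, pos_ids))
        for pid, _ in pirnas
    }
    pirnas = [(pid, pseq) for pid, pseq in pirnas if ncs[pid]]
    if not pirnas:
        raise ValueError("every positive-set piRNA has an empty candidate set")

    pos_matrix = np.array(
        [np.frombuffer(p.mrna_segment.bases.encode(), dtype=np.uint8)
         for p in positives if len(p.mrna_segment) == window_len]
    )
    pos_keys = {p.key for p in positives}

    negatives: list[PairExample] = []
    seen: set[tuple[str, str]] = set()
    budget = draw_budget_factor * n_target
    draws = rejected_similarity = rejected_energy = 0
    while len(negatives) < n_target:
        draws += 1
        if draws > budget:
            raise RuntimeError(
                f"negative sampling exhausted {budget} draws: "
                f"{len(negatives)}/{n_target} accepted, "
                f"{rejected_similarity} similarity / {rejected_energy} energy rejections"
            )
        pid, pseq = pirnas[int(rng.integers(0, len(pirnas)))]
        cands = ncs[pid]
        tid = cands[int(rng.integers(0, len(cands)))]
        t = by_id[tid].bases
        if len(t) < window_len:
            continue
        start = int(rng.integers(0, len(t) - window_len + 1))
        window = t[start : start + window_len]
        if (pid, window) in pos_keys or (pid, window) in seen:
            continue
        if len(pos_matrix):
            wa = np.frombuffer(window.encode(), dtype=np.uint8)
            if int((pos_matrix != wa).sum(axis=1).min()) <= 2:
                rejected_similarity += 1
                continue
        energy = duplex_energy(pseq, window, scorer=cfg.energy_scorer)
        if not energy < 0:
            rejected_energy += 1
            continue
        seen.add((pid, window))
        negatives.append(
            PairExample(
                pirna_id=pid,
                pirna_seq=NucleotideSequence(pseq),
                mrna_segment=NucleotideSequence(window),
                label=0,
                provenance=dict(transcript_id=tid, center=start + cfg.extension_l,
                                energy=energy),
            )
        )
    return negatives


def build_ground_truth(
    chimeras: Sequence[ChimeraRead],
    catalog: Sequence[PiRNARecord],
    transcriptome: Sequence[NucleotideSequence],
    cfg: "PrepConfig | None" = None,
    rng_seed: int = 0,
    n_negatives: "int | None" = None,
) -> tuple[GroundTruth, dict]:
    """Full pipeline: positives, LBS and a balanced sampled negative set."""
    cfg = cfg or PrepConfig()
    positives, report = build_positive_set(chimeras, catalog, transcriptome, cfg)
    lbs = build_loose_set(chimeras, catalog, transcriptome, cfg)
    n_neg = len(positives) if n_negatives is None else n_negatives
    negatives = (
        sample_negatives(positives, lbs, transcriptome, n_neg, rng_seed, cfg)
        if positives and n_neg
        else []
    )
    return GroundTruth(positives, negatives, lbs), report


def assemble_independent_set(
    independent_gt: GroundTruth,
    wildtype_gt: GroundTruth,
    n_pos: int,
    n_neg: int,
    rng_seed: int = 0,
) -> tuple[GroundTruth, dict]:
    """Build an independent test set excluding wild-type-observed pairs.

    Positives are drawn from the independent positives after removing any
    pair (keyed on piRNA id + window sequence) already observed in the
    wild-type positives; negatives are drawn from the independent negatives.
    Also reports whether any independent positive collides with the
    wild-type *negative* set (which would mean the wild-type model was
    trained on false negatives).
    """
    rng = np.random.default_rng(rng_seed)
    wt_pos_keys = {p.key for p in wildtype_gt.positives}
    wt_neg_keys = {n.key for n in wildtype_gt.negatives}
    pool_pos = [p for p in independent_gt.positives if p.key not in wt_pos_keys]
    conflicts = sorted(
        {p.key for p in independent_gt.positives} & wt_neg_keys
    )
    if len(pool_pos) < n_pos:
        raise ValueError(
            f"positive pool after wild-type exclusion has {len(pool_pos)} pairs, "
            f"need {n_pos}"
        )
    if len(independent_gt.negatives) < n_neg:
        raise ValueError(
            f"negative pool has {len(independent_gt.negatives)} pairs, need {n_neg}"
        )
    pos_idx = rng.permutation(len(pool_pos))[:n_pos]
    neg_idx = rng.permutation(len(independent_gt.negatives))[:n_neg]
    gt = GroundTruth(
        positives=[pool_pos[int(i)] for i in pos_idx],
        negatives=[independent_gt.negatives[int(i)] for i in neg_idx],
        loose_set=set(independent_gt.loose_set),
    )
    info = dict(
        removed_wildtype_overlap=len(independent_gt.positives) - len(pool_pos),
        wildtype_negative_conflicts=[list(k) for k in conflicts],
    )
    return gt, info


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_chimeras(path: "str | Path") -> tuple[list[ChimeraRead], int]:
    """Load chimeras from FASTQ (qualities ignored; duplicates collapsed)
    or from 2-column TSV (sequence, read_count)."""
    path = Path(path)
    if path.suffix.lower() in (".fastq", ".fq"):
        raw = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
        return collapse_reads(raw)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sequence", "read_count"])
    dropped = 0
    reads = []
    for _, row in df.iterrows():
        s = str(row["sequence"]).upper().replace("T", "U")
        if not is_valid(s):
            dropped += 1
            continue
        reads.append(ChimeraRead(NucleotideSequence(s), int(row["read_count"])))
    if not reads and dropped == 0:
        raise ValueError(f"no chimera records in {path}")
    return reads, dropped


def pairs_to_frame(pairs: Sequence[PairExample]) -> pd.DataFrame:
    """Pair table with 1-based user-facing center coordinates."""
    rows = []
    for p in pairs:
        prov = p.provenance or {}
        center = prov.get("center")
        rows.append(
            dict(
                pirna_id=p.pirna_id,
                pirna_seq=p.pirna_seq.bases,
                transcript_id=prov.get("transcript_id", ""),
                center=(center + 1) if center is not None else "",
                segment_seq=p.mrna_segment.bases,
                label="positive" if p.label == 1 else "negative",
                read_count=prov.get("read_count", ""),
                remaining_len=prov.get("remaining_len", ""),
                mismatches=prov.get("mismatches", ""),
                energy=prov.get("energy", ""),
            )
        )
    return pd.DataFrame(rows)


def write_pairs_tsv(pairs: Sequence[PairExample], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: center is 1-based\n")
        pairs_to_frame(pairs).to_csv(fh, sep="\t", index=False)


def read_pairs_tsv(path: "str | Path") -> list[PairExample]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        prov = {}
        if not pd.isna(row.get("transcript_id")):
            prov["transcript_id"] = row["transcript_id"]
        if "center" in row and not pd.isna(row["center"]) and row["center"] != "":
            prov["center"] = int(row["center"]) - 1
        out.append(
            PairExample(
                pirna_id=str(row["pirna_id"]),
                pirna_seq=NucleotideSequence(str(row["pirna_seq"])),
                mrna_segment=NucleotideSequence(str(row["segment_seq"])),
                label=1 if str(row["label"]).lower().startswith("pos") else 0,
                provenance=prov,
            )
        )
    return out


def write_attrition_report(report: dict, path: "str | Path") -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
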