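"""Sequence primitives for piRNA target analysis.

Everything downstream of this module operates on canonical RNA strings over
the alphabet ``{A, U, G, C}``.  The module provides validation, one-hot
encoding (the network input representation), reverse complementation,
ungapped Hamming-distance search (the internal stand-in for a short-read
aligner run in end-to-end mode), and the duplex-energy contract used by the
ground-truth filters.

Coordinates are 0-based half-open internally; user-facing tables written by
:mod:`pirbind.clash_prep` use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed one-hot channel order.
CHANNELS: tuple[str, str, str, str] = ("A", "U", "G", "C")

_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick and GU-wobble pairs scored by the internal duplex scorer.
#: More negative = more stable; GC pairs are the strongest.
PAIR_SCORES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
MISMATCH_PENALTY = 0.5


class SequenceError(ValueError):
    """Raised for invalid nucleotide content or incompatible lengths."""


def canonicalize(bases: str) -> str:
    """Upper-case a nucleotide string and map DNA T to RNA U.

    Raises :class:`SequenceError` naming the first offending position if a
    character outside ``{A,U,G,C}`` (after T->U) remains; ambiguous bases
    such as ``N`` are deliberately rejected rather than zero-encoded.
    """
    up = bases.upper().replace("T", "U")
    for i, ch in enumerate(up):
        if ch not in _CHANNEL_INDEX:
            raise SequenceError(
                f"invalid base {ch!r} at position {i} (0-based) in sequence"
            )
    return up


def is_valid(bases: str) -> bool:
    """True when every character canonicalizes into {A,U,G,C}."""
    try:
        canonicalize(bases)
    except SequenceError:
        return False
    return True


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated RNA sequence.

    ``T`` on input is silently canonicalized to ``U`` (a debug-level notice
    is logged); any other non-AUGC character raises :class:`SequenceError`.
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        canon = canonicalize(self.bases)
        if len(canon) < 1:
            raise SequenceError("empty sequence")
        if canon != self.bases:
            if "T" in self.bases.upper():
                logger.debug("canonicalized DNA-style sequence %r (T->U)", self.name)
            object.__setattr__(self, "bases", canon)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


def _as_seq(seq: "NucleotideSequence | str") -> NucleotideSequence:
    if isinstance(seq, NucleotideSequence):
        return seq
    return NucleotideSequence(seq)


def one_hot_encode(seq: "NucleotideSequence | str") -> np.ndarray:
    """Encode a sequence as an L x 4 binary matrix, channels (A, U, G, C).

    Row *i* holds a single 1 in the channel of base *i*.
    """
    s = _as_seq(seq)
    mat = np.zeros((len(s), 4), dtype=np.float32)
    for i, ch in enumerate(s.bases):
        mat[i, _CHANNEL_INDEX[ch]] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (argmax per row)."""
    return "".join(CHANNELS[int(j)] for j in np.argmax(np.asarray(mat), axis=1))


def reverse_complement(seq: "NucleotideSequence | str") -> NucleotideSequence:
    """Reverse-complement (A<->U, G<->C), preserving the name."""
    s = _as_seq(seq)
    rc = "".join(_COMPLEMENT[b] for b in reversed(s.bases))
    return NucleotideSequence(rc, name=s.name)


def mismatch_count(a: "NucleotideSequence | str", b: "NucleotideSequence | str") -> int:
    """Hamming distance between two equal-length sequences."""
    sa, sb = _as_seq(a).bases, _as_seq(b).bases
    if len(sa) != len(sb):
        raise SequenceError(
            f"mismatch_count requires equal lengths, got {len(sa)} and {len(sb)}"
        )
    return sum(1 for x, y in zip(sa, sb) if x != y)


def scan_with_mismatches(
    query: "NucleotideSequence | str",
    subject: "NucleotideSequence | str",
    max_mm: int = 0,
) -> list[tuple[int, int]]:
    """All ungapped occurrences of ``query`` in ``subject`` within ``max_mm``.

    Returns ``(start, mismatches)`` tuples, 0-based starts, sorted by start;
    overlapping occurrences are all reported.  This is an exhaustive Hamming
    scan, adequate at transcriptome-fixture scale.
    """
    q, s = _as_seq(query).bases, _as_seq(subject).bases
    if len(q) == 0:
        raise SequenceError("empty query")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if len(q) > len(s):
        return []
    # Vectorized Hamming profile over all offsets.
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    n_off = len(s) - len(q) + 1
    windows = np.lib.stride_tricks.sliding_window_view(sa, len(q))
    mm = (windows != qa).sum(axis=1)
    return [(int(i), int(mm[i])) for i in range(n_off) if mm[i] <= max_mm]


def duplex_energy(
    pirna: "NucleotideSequence | str",
    segment: "NucleotideSequence | str",
    scorer: str = "internal",
) -> float:
    """Hybridization score of a piRNA against an mRNA segment.

    More negative means more stable pairing; the ground-truth filters keep
    pairs with energy strictly below zero.

    ``scorer="internal"`` (default): best ungapped antiparallel alignment of
    the piRNA against the segment, scoring GC = -3, AU = -2, GU wobble = -1
    and mismatches +0.5 per position over the best-scoring overlap window.

    ``scorer="vienna"``: thermodynamic duplex energy (kcal/mol) from the
    ViennaRNA ``duplexfold`` bindings; raises :class:`RuntimeError` if the
    bindings are unavailable — there is no silent fallback.
    """
    p = _as_seq(pirna).bases
    m = _as_seq(segment).bases
    if scorer == "internal":
        return _internal_duplex_score(p, m)
    if scorer == "vienna":
        return _vienna_duplex_energy(p, m)
    raise ValueError(f"unknown duplex scorer {scorer!r}")


def _internal_duplex_score(pirna: str, segment: str) -> float:
    # Antiparallel pairing: piRNA position k pairs segment base
    # revcomp(segment)[k + offset]; a match in that frame is a WC pair.
    t = "".join(_COMPLEMENT[b] for b in reversed(segment))
    lp, lt = len(pirna), len(t)
    best = np.inf
    for off in range(-(lp - 1), lt):
        score = 0.0
        overlap = 0
        for k in range(lp):
            j = k + off
            if 0 <= j < lt:
                overlap += 1
                x = pirna[k]
                if x == t[j]:
                    score += PAIR_SCORES[(x, _COMPLEMENT[x])]
                else:
                    # In the revcomp frame, (G vs A) and (U vs C) are GU wobbles.
                    pair = (x, _COMPLEMENT[t[j]])
                    score += PAIR_SCORES.get(pair, MISMATCH_PENALTY)
        if overlap >= 1 and score < best:
            best = score
    return float(best)


def _vienna_duplex_energy(pirna: str, segment: str) -> float:
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "ViennaRNA python bindings not available; the 'vienna' duplex "
            "scorer cannot run (no fallback to the internal scorer)"
        ) from exc
    duplex = RNA.duplexfold(pirna, segment)
    return float(duplex.energy)


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence(str(rec.seq), name=rec.id))
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: "str | Path") -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_scan_tsv(
    hits: Sequence[tuple[str, int, int, int]], path: "str | Path"
) -> None:
    """Write scan hits as TSV: subject_id, start(1-based), end, mismatches.

    ``hits`` carries 0-based half-open (subject_id, start, end, mismatches);
    the written table is 1-based inclusive, as stated in its header.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        fh.write("subject_id\tstart\tend\tmismatches\n")
        for sid, start, end, mm in hits:
            fh.write(f"{sid}\t{start + 1}\t{end}\t{mm}\n")
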