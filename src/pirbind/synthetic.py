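"""Synthetic worlds for end-to-end testing of the target-identification stack.

The generator emulates the essential structure of a PIWI CLASH experiment in
*C. elegans*: a transcriptome, a catalog of 21-nt piRNAs, target sites planted
as antisense matches obeying the worm targeting rule (perfect complementarity
over the seed, piRNA positions 2-7; only a few mismatches elsewhere; the
5'-most piRNA base not participating), chimeric reads formed by ligating a
piRNA to a degradation-trimmed target fragment, background random-ligation
chimeras, and a read-count distribution whose noise component forms a
low-count spike below the rigorous count threshold.

It does *not* simulate sequencing errors, base qualities, adapters or
replicate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clash_prep import ChimeraRead, GroundTruth, PairExample, PiRNARecord
from .seq_core import NucleotideSequence, reverse_complement

_BASES = np.array(list("AUGC"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PlantedRule:
    """The targeting rule written into every planted site.

    ``seed_start``/``seed_end`` are 1-based piRNA positions (default 2-7)
    paired perfectly; up to ``nonseed_max_mm`` mismatches are introduced at
    non-seed positions; with ``first_base_free`` the target base opposite
    piRNA position 1 is drawn uniformly at random.
    """

    seed_start: int = 2
    seed_end: int = 7
    nonseed_max_mm: int = 3
    first_base_free: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.seed_start <= self.seed_end):
            raise ValueError("invalid seed range")

    def seed_positions(self, pirna_len: int = 21) -> list[int]:
        if self.seed_end > pirna_len:
            raise ValueError("seed range exceeds piRNA length")
        return list(range(self.seed_start, self.seed_end + 1))


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions of the synthetic world.

    Defaults are sized so that the default pair dataset (3,500 positives +
    3,500 negatives, an 8:1:1 split of 5k/1k/1k pairs) can be drawn without
    replacement, while keeping generation instantaneous.
    """

    n_transcripts: int = 500
    transcript_len_range: tuple[int, int] = (320, 480)
    n_pirnas: int = 300
    pirna_len: int = 21
    n_planted_sites: int = 3600
    noise_chimera_fraction: float = 0.35
    #: signal chimera counts: 5 + Poisson(8) (predominantly >= 7);
    #: noise chimera counts: uniform on 1..6 (the low-count spike).
    signal_count_offset: int = 5
    signal_count_lam: float = 8.0
    noise_count_max: int = 6
    #: degradation trim: remaining length ~ round(N(15, 2.5)) clipped to
    #: [8, 21] — mode near 14-15 as in real chimera libraries.
    trim_mean: float = 15.0
    trim_sd: float = 2.5
    trim_min: int = 8
    rule: PlantedRule = field(default_factory=PlantedRule)
    gc_skew: float = 0.0  # probability mass shifted from A/U onto G/C
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_transcripts, self.n_pirnas, self.n_planted_sites, self.pirna_len
        ) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.noise_chimera_fraction <= 1.0:
            raise ValueError("noise_chimera_fraction must lie in [0,1]")


@dataclass(frozen=True)
class PlantedSite:
    pirna_id: str
    transcript_id: str
    start: int  # 0-based start of the 21-nt antisense target on the transcript
    center: int  # 0-based center position (start + (pirna_len-1)//2)
    target: str  # the planted 21-nt target sequence (5'->3' on the mRNA)
    n_mismatches: int


@dataclass
class SynthWorld:
    spec: SynthSpec
    transcriptome: list[NucleotideSequence]
    pirna_catalog: list[PiRNARecord]
    planted_truth: list[PlantedSite]

    def transcript(self, tid: str) -> NucleotideSequence:
        return self._by_id[tid]

    def __post_init__(self) -> None:
        self._by_id = {t.name: t for t in self.transcriptome}


def _random_bases(rng: np.random.Generator, n: int, gc_skew: float = 0.0) -> str:
    p = np.array([0.25, 0.25, 0.25, 0.25])
    if gc_skew:
        p = p + np.array([-gc_skew / 2, -gc_skew / 2, gc_skew / 2, gc_skew / 2])
        p = p / p.sum()
    return "".join(rng.choice(_BASES, size=n, p=p))


def _plant_target(pirna: str, rule: PlantedRule, rng: np.random.Generator) -> tuple[str, int]:
    """Build the antisense 21-nt target for ``pirna`` under ``rule``.

    The target (read 5'->3' on the mRNA) is the reverse complement of the
    piRNA; piRNA position k (1-based) pairs target position L+1-k.  Seed
    positions stay perfectly complementary, up to ``nonseed_max_mm`` non-seed
    positions are mutated, and the base opposite piRNA position 1 is free.
    """
    L = len(pirna)
    target = list(str(reverse_complement(pirna)))
    seed = set(rule.seed_positions(L))
    mutable = [k for k in range(1, L + 1) if k not in seed]
    if rule.first_base_free and 1 in mutable:
        mutable.remove(1)
        j = L - 1  # target index opposite piRNA position 1
        target[j] = str(rng.choice(_BASES))
    n_mm = int(rng.integers(0, rule.nonseed_max_mm + 1))
    mm_positions = rng.choice(mutable, size=n_mm, replace=False) if n_mm else []
    realized = 0
    for k in mm_positions:
        j = L - k  # 0-based target index opposite piRNA position k
        wc = target[j]
        alt = [b for b in "AUGC" if b != wc]
        target[j] = str(rng.choice(alt))
        realized += 1
    return "".join(target), realized


def gen_world(spec: SynthSpec) -> SynthWorld:
    """Generate a transcriptome, piRNA catalog and planted target sites.

    Planted sites are non-overlapping within a transcript and keep a margin
    wide enough for the default +/-15 nt window extension around the site
    center.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.pirna_len
    margin = 16  # room for extension_l up to 15 plus trimming slack

    pirnas = [
        PiRNARecord(f"piR-{i:04d}", NucleotideSequence(_random_bases(rng, L, spec.gc_skew)))
        for i in range(spec.n_pirnas)
    ]

    lo, hi = spec.transcript_len_range
    if hi < L + 2 * margin:
        raise ValueError("transcripts too short for planting target sites")
    transcripts = [
        list(_random_bases(rng, int(rng.integers(lo, hi + 1)), spec.gc_skew))
        for _ in range(spec.n_transcripts)
    ]

    # Per-transcript occupied intervals to keep plantings non-overlapping.
    occupied: list[list[tuple[int, int]]] = [[] for _ in transcripts]
    planted: list[PlantedSite] = []
    attempts = 0
    while len(planted) < spec.n_planted_sites:
        attempts += 1
        if attempts > 50 * spec.n_planted_sites:
            raise ValueError(
                "transcriptome too small to plant the requested number of sites"
            )
        ti = int(rng.integers(0, spec.n_transcripts))
        tlen = len(transcripts[ti])
        start = int(rng.integers(margin, tlen - L - margin + 1))
        if any(start < e + 2 and start + L > s - 2 for s, e in occupied[ti]):
            continue
        pi = int(rng.integers(0, spec.n_pirnas))
        pirna = pirnas[pi]
        target, n_mm = _plant_target(pirna.sequence.bases, spec.rule, rng)
        transcripts[ti][start : start + L] = list(target)
        occupied[ti].append((start, start + L))
        planted.append(
            PlantedSite(
                pirna_id=pirna.id,
                transcript_id=f"tx-{ti:04d}",
                start=start,
                center=start + (L - 1) // 2,
                target=target,
                n_mismatches=n_mm,
            )
        )

    transcriptome = [
        NucleotideSequence("".join(t), name=f"tx-{i:04d}") for i, t in enumerate(transcripts)
    ]
    return SynthWorld(spec, transcriptome, pirnas, planted)


# ---------------------------------------------------------------------------
# Chimera library
# ---------------------------------------------------------------------------

@dataclass
class ChimeraBookkeeping:
    """Generator-side truth used by pipeline-recovery assertions."""

    signal: list[dict]
    noise: list[dict]

    def passing_sites(
        self,
        min_count: int = 7,
        min_remaining: int = 14,
        transcriptome: "list | None" = None,
    ) -> set[tuple[str, str]]:
        """(pirna_id, transcript_id) of signal chimeras passing the rigorous
        count and remaining-length thresholds at generation time.

        With ``transcriptome`` given, sites whose trimmed fragment occurs at
        more than one transcriptome location are also dropped — such sites
        are inherently ambiguous and the multi-hit rule removes them by
        design, so they are not recoverable evidence.
        """
        from .seq_core import scan_with_mismatches

        out = set()
        for rec in self.signal:
            if rec["read_count"] < min_count or rec["remaining_len"] < min_remaining:
                continue
            if transcriptome is not None:
                n_hits = sum(
                    len(scan_with_mismatches(rec["frag"], t, 0)) for t in transcriptome
                )
                if n_hits != 1:
                    continue
            out.add((rec["pirna_id"], rec["transcript_id"]))
        return out


def gen_chimera_library(
    world: SynthWorld, spec: "SynthSpec | None" = None
) -> tuple[list[ChimeraRead], ChimeraBookkeeping]:
    """Emulate a CLASH chimera library for ``world``.

    Signal chimeras ligate a catalog piRNA to a degradation-trimmed fragment
    of its planted target region (random 5'/3' ligation order); their read
    counts come from the signal component.  Noise chimeras ligate a random
    piRNA to a random transcript fragment with counts from the low-count
    spike (1..noise_count_max).
    """
    spec = spec or world.spec
    if not world.planted_truth:
        raise ValueError("world has no planted sites")
    rng = np.random.default_rng(spec.seed + 1)
    by_pirna = {p.id: p for p in world.pirna_catalog}

    signal_rows: list[dict] = []
    reads: list[ChimeraRead] = []
    for site in world.planted_truth:
        pirna = by_pirna[site.pirna_id]
        tseq = world.transcript(site.transcript_id).bases
        rem_len = int(np.clip(round(rng.normal(spec.trim_mean, spec.trim_sd)),
                              spec.trim_min, world.spec.pirna_len))
        # trimmed fragment stays inside the planted 21-nt target region
        off = int(rng.integers(0, world.spec.pirna_len - rem_len + 1))
        frag = tseq[site.start + off : site.start + off + rem_len]
        order_53 = bool(rng.integers(0, 2))
        seq = pirna.sequence.bases + frag if order_53 else frag + pirna.sequence.bases
        count = spec.signal_count_offset + int(rng.poisson(spec.signal_count_lam))
        reads.append(ChimeraRead(NucleotideSequence(seq), count))
        signal_rows.append(
            dict(
                pirna_id=site.pirna_id,
                transcript_id=site.transcript_id,
                site_start=site.start,
                frag_start=site.start + off,
                frag=frag,
                remaining_len=rem_len,
                read_count=count,
                pirna_first=order_53,
            )
        )

    n_noise = int(
        round(len(world.planted_truth) * spec.noise_chimera_fraction
              / max(1e-9, 1.0 - spec.noise_chimera_fraction))
    ) if spec.noise_chimera_fraction < 1.0 else len(world.planted_truth)
    noise_rows: list[dict] = []
    for _ in range(n_noise):
        pirna = world.pirna_catalog[int(rng.integers(0, len(world.pirna_catalog)))]
        ti = int(rng.integers(0, len(world.transcriptome)))
        tseq = world.transcriptome[ti].bases
        rem_len = int(np.clip(round(rng.normal(spec.trim_mean, spec.trim_sd)),
                              spec.trim_min, world.spec.pirna_len))
        start = int(rng.integers(0, len(tseq) - rem_len + 1))
        frag = tseq[start : start + rem_len]
        order_53 = bool(rng.integers(0, 2))
        seq = pirna.sequence.bases + frag if order_53 else frag + pirna.sequence.bases
        count = int(rng.integers(1, spec.noise_count_max + 1))
        reads.append(ChimeraRead(NucleotideSequence(seq), count))
        noise_rows.append(
            dict(
                pirna_id=pirna.id,
                transcript_id=world.transcriptome[ti].name,
                frag_start=start,
                remaining_len=rem_len,
                read_count=count,
                pirna_first=order_53,
            )
        )

    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    return reads, ChimeraBookkeeping(signal_rows, noise_rows)


# ---------------------------------------------------------------------------
# Direct labeled pair datasets (bypassing the chimera pipeline)
# ---------------------------------------------------------------------------

def _seed_complement(pirna: str, rule: PlantedRule) -> str:
    """The target-side motif complementary to the piRNA seed (5'->3')."""
    seed = rule.seed_positions(len(pirna))
    # piRNA positions seed_start..seed_end pair target indices L-k (0-based),
    # which read 5'->3' as the reverse complement of the seed subsequence.
    sub = pirna[seed[0] - 1 : seed[-1]]
    return str(reverse_complement(NucleotideSequence(sub)))


def gen_pair_dataset(
    world: SynthWorld,
    n_pos: int,
    n_neg: int,
    rule: "PlantedRule | None" = None,
    seed: int = 0,
    extension_l: int = 15,
) -> GroundTruth:
    """Labeled (piRNA, window) pairs straight from the planted truth.

    Positives are planted sites expanded to a ``2*extension_l + 1`` window
    centered on the site center.  Negatives pair a random catalog piRNA with
    a random transcript window rejected if it contains the reverse complement
    of that piRNA's seed (so no negative satisfies the planted rule).
    Balanced, shuffled and deterministic given ``seed``.
    """
    rule = rule or world.spec.rule
    rng = np.random.default_rng(seed)
    L = 2 * extension_l + 1
    by_pirna = {p.id: p for p in world.pirna_catalog}

    usable = []
    for site in world.planted_truth:
        t = world.transcript(site.transcript_id).bases
        lo, hi = site.center - extension_l, site.center + extension_l + 1
        if lo >= 0 and hi <= len(t):
            usable.append((site, t[lo:hi]))
    if len(usable) < n_pos:
        raise ValueError(
            f"insufficient planted sites: need {n_pos}, have {len(usable)} usable"
        )
    order = rng.permutation(len(usable))[:n_pos]
    positives = []
    for i in order:
        site, window = usable[int(i)]
        positives.append(
            PairExample(
                pirna_id=site.pirna_id,
                pirna_seq=by_pirna[site.pirna_id].sequence,
                mrna_segment=NucleotideSequence(window),
                label=1,
                provenance=dict(source="planted", transcript_id=site.transcript_id,
                                center=site.center, n_mismatches=site.n_mismatches),
            )
        )

    negatives = []
    budget = 200 * n_neg
    draws = 0
    while len(negatives) < n_neg:
        draws += 1
        if draws > budget:
            raise ValueError("negative sampling budget exhausted")
        pirna = world.pirna_catalog[int(rng.integers(0, len(world.pirna_catalog)))]
        ti = int(rng.integers(0, len(world.transcriptome)))
        t = world.transcriptome[ti].bases
        if len(t) < L:
            continue
        start = int(rng.integers(0, len(t) - L + 1))
        window = t[start : start + L]
        if _seed_complement(pirna.sequence.bases, rule) in window:
            continue  # would satisfy the planted seed rule: not a clean negative
        negatives.append(
            PairExample(
                pirna_id=pirna.id,
                pirna_seq=pirna.sequence,
                mrna_segment=NucleotideSequence(window),
                label=0,
                provenance=dict(source="random", transcript_id=world.transcriptome[ti].name,
                                center=start + extension_l),
            )
        )

    return GroundTruth(positives=positives, negatives=negatives, loose_set=set())
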