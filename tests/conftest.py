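"""Shared fixtures: synthetic worlds, a hand-built chimera fixture whose
rigorous filters each eliminate exactly one designed chimera, and
session-scoped trained models reused by the slower end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import pirbind as pb
from pirbind.clash_prep import ChimeraRead, PiRNARecord
from pirbind.seq_core import NucleotideSequence, reverse_complement
from pirbind.train_eval import TrainConfig, encode_pairs, roc_auc, train_model


def _rand_rna(rng: np.random.Generator, n: int, alphabet: str = "AUGC") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def default_world() -> pb.SynthWorld:
    return pb.gen_world(pb.SynthSpec())


@pytest.fixture(scope="session")
def default_pairs(default_world) -> pb.GroundTruth:
    return pb.gen_pair_dataset(default_world, 3500, 3500, seed=0)


@pytest.fixture(scope="session")
def encoded_default_pairs(default_pairs):
    return encode_pairs(default_pairs.examples)


@pytest.fixture(scope="session")
def default_split(encoded_default_pairs):
    """Fixed 5k/1k/1k train/val/test index split of the 7000-pair dataset."""
    _, _, y = encoded_default_pairs
    perm = np.random.default_rng(0).permutation(len(y))
    return perm[:5000], perm[5000:6000], perm[6000:]


@pytest.fixture(scope="session")
def trained_full_model(encoded_default_pairs, default_split):
    """Full attention model trained on the default planted-rule dataset
    (5k train / 1k val; desk-scale recipe: 18 epochs, batch 256); shared by
    the slow end-to-end tests."""
    tr, va, _te = default_split
    model, log = train_model(
        "full", encoded_default_pairs, split=(tr, va),
        train_cfg=TrainConfig(epochs=18, batch_size=256, seed=0),
    )
    return model, log


@pytest.fixture(scope="session")
def ablation_runs(default_world):
    """Full vs pure-CNN models trained from 5 seeds on a 3,500-pair planted
    dataset — the smallest scale at which the attention pathway converges
    enough for the comparison to be meaningful.  Returns per-seed test AUCs
    and the trained full models."""
    gt = pb.gen_pair_dataset(default_world, 1750, 1750, seed=1)
    p_oh, m_oh, y = encode_pairs(gt.examples)
    n = len(y)
    full_aucs, cnn_aucs, full_models = [], [], []
    for seed in range(5):
        perm = np.random.default_rng(100 + seed).permutation(n)
        tr, va, te = perm[: int(0.8 * n)], perm[int(0.8 * n): int(0.9 * n)], perm[int(0.9 * n):]
        cfg = TrainConfig(epochs=12, batch_size=256, seed=seed)
        full, _ = train_model("full", (p_oh, m_oh, y), split=(tr, va), train_cfg=cfg)
        cnn, _ = train_model("pure_cnn", (p_oh, m_oh, y), split=(tr, va), train_cfg=cfg)
        full_aucs.append(roc_auc(y[te], full.predict_proba(p_oh[te], m_oh[te])[:, 1]).auc)
        cnn_aucs.append(roc_auc(y[te], cnn.predict_proba(p_oh[te], m_oh[te])[:, 1]).auc)
        full_models.append(full)
    return dict(full_aucs=full_aucs, cnn_aucs=cnn_aucs, full_models=full_models, gt=gt)


# ---------------------------------------------------------------------------
# Hand-built chimera fixture: 4 designed survivors + 5 chimeras eliminated
# by exactly one rigorous rule each.
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def hand_fixture():
    rng = np.random.default_rng(42)

    # Catalog: three ordinary piRNAs plus an all-A piRNA that cannot pair
    # with a U-free segment (used to trip the energy rule).
    p1 = PiRNARecord("piR-1", NucleotideSequence(_rand_rna(rng, 21)))
    p2 = PiRNARecord("piR-2", NucleotideSequence(_rand_rna(rng, 21)))
    p3 = PiRNARecord("piR-3", NucleotideSequence(_rand_rna(rng, 21)))
    pA = PiRNARecord("piR-A", NucleotideSequence("A" * 21))
    catalog = [p1, p2, p3, pA]

    # Transcript 1 layout (all coordinates 0-based):
    #   [0:30)  filler
    #   [30:51) perfect antisense target of p1   (survivor S1 + count-kill)
    #   [51:80) filler
    #   [80:101) perfect antisense target of p2  (survivors S2: rem 14; kill: rem 13)
    #   [101:130) filler
    #   [130:151) perfect antisense target of p3 (survivor S3)
    #   [151:165) duplicated 14-mer DUP          (multi-hit kill)
    #   [165:196) U-free stretch                 (energy kill via piR-A)
    #   [196:226) filler
    #   [226:240) DUP again
    #   [240:270) filler
    t1_parts = [
        _rand_rna(rng, 30),
        str(reverse_complement(p1.sequence)),
        _rand_rna(rng, 29),
        str(reverse_complement(p2.sequence)),
        _rand_rna(rng, 29),
        str(reverse_complement(p3.sequence)),
    ]
    dup = _rand_rna(rng, 14)
    ufree = _rand_rna(rng, 31, alphabet="AGC")
    t1_parts += [dup, ufree, _rand_rna(rng, 30), dup, _rand_rna(rng, 30)]
    t1 = NucleotideSequence("".join(t1_parts), name="tx-1")
    assert len(t1) == 270

    def frag(start, length):
        return t1.bases[start : start + length]

    k3_frag = frag(134, 14)
    k3_mut = k3_frag[:13] + ("A" if k3_frag[13] != "A" else "C")
    chimeras = [
        # S1: survivor — count 7, remaining 14, perfect map, unique, energy < 0
        ChimeraRead(NucleotideSequence(p1.sequence.bases + frag(33, 14)), 7),
        # K1: equally good evidence but count 6 -> read_count rule
        ChimeraRead(NucleotideSequence(p1.sequence.bases + frag(35, 14)), 6),
        # S2: survivor on p2's site
        ChimeraRead(NucleotideSequence(p2.sequence.bases + frag(83, 14)), 9),
        # K2: remaining only 13 nt -> remaining_length rule
        ChimeraRead(NucleotideSequence(p2.sequence.bases + frag(84, 13)), 9),
        # S3: survivor on p3's site (fragment 5' of the piRNA)
        ChimeraRead(NucleotideSequence(frag(133, 15) + p3.sequence.bases), 8),
        # K3: fragment carries one substitution vs the transcript -> mapping rule
        ChimeraRead(NucleotideSequence(p3.sequence.bases + k3_mut), 8),
        # K4: fragment present at two transcript locations -> multi_hit rule
        ChimeraRead(NucleotideSequence(p1.sequence.bases + dup), 8),
        # S4: survivor for piR-2 at a second offset within its target
        ChimeraRead(NucleotideSequence(p2.sequence.bases + frag(80, 16)), 10),
        # K5: poly-A piRNA vs a fragment whose 31-nt window is U-free
        #     (no A-U pairing possible anywhere) -> energy rule
        ChimeraRead(NucleotideSequence(pA.sequence.bases + frag(174, 14)), 8),
    ]
    expected_survivor_pirnas = {"piR-1": 1, "piR-2": 2, "piR-3": 1}
    return dict(
        catalog=catalog,
        transcriptome=[t1],
        chimeras=chimeras,
        expected_survivor_pirnas=expected_survivor_pirnas,
    )
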