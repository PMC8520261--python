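"""Ground-truth construction: chimera splitting, mapping, the five rigorous
rules, the loose set / negative-candidate complement, and negative sampling."""

import numpy as np
import pytest

from pirbind.clash_prep import (
    ChimeraRead,
    GroundTruth,
    PairExample,
    PiRNARecord,
    PrepConfig,
    SplitOutcome,
    assemble_independent_set,
    build_ground_truth,
    build_loose_set,
    build_positive_set,
    collapse_reads,
    map_segment,
    negative_candidates,
    read_chimeras,
    read_pairs_tsv,
    sample_negatives,
    site_from_alignment,
    split_chimera,
    write_pairs_tsv,
)
from pirbind.seq_core import NucleotideSequence


def _seq(s, name=""):
    return NucleotideSequence(s, name=name)


class TestCollapseReads:
    def test_multiplicities(self):
        reads, dropped = collapse_reads(["AUG", "AUG", "GGC"])
        assert dropped == 0
        assert {(r.sequence.bases, r.read_count) for r in reads} == {("AUG", 2), ("GGC", 1)}

    def test_all_distinct(self):
        reads, _ = collapse_reads(["AAA", "CCC", "GGG"])
        assert all(r.read_count == 1 for r in reads)

    def test_n_reads_dropped_and_counted(self):
        reads, dropped = collapse_reads(["AUG", "ANG", "AUG"])
        assert dropped == 1
        assert sum(r.read_count for r in reads) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            collapse_reads([])


class TestSplitChimera:
    catalog = [PiRNARecord("p1", _seq("AUGCAUGCAUGCAUGCAUGCA"))]

    def test_pirna_plus_tail(self):
        tail = "GGCCGGCCGGCCGGCCGGCC"
        outcome, p, rem = split_chimera(
            ChimeraRead(_seq(self.catalog[0].sequence.bases + tail)), self.catalog
        )
        assert outcome is SplitOutcome.MATCHED
        assert p.id == "p1"
        assert rem.bases == tail

    def test_no_match(self):
        outcome, _, _ = split_chimera(ChimeraRead(_seq("G" * 40)), self.catalog)
        assert outcome is SplitOutcome.NO_MATCH

    def test_internal_match_takes_longer_flank(self):
        head, tail = "GGGCC", "C" * 16
        outcome, _, rem = split_chimera(
            ChimeraRead(_seq(head + self.catalog[0].sequence.bases + tail)), self.catalog
        )
        assert outcome is SplitOutcome.MATCHED
        assert rem.bases == tail

    def test_flank_tie_prefers_three_prime(self):
        head, tail = "GGGGG", "CCCCC"
        _, _, rem = split_chimera(
            ChimeraRead(_seq(head + self.catalog[0].sequence.bases + tail)), self.catalog
        )
        assert rem.bases == tail

    def test_two_distinct_pirnas_ambiguous(self):
        cat = self.catalog + [PiRNARecord("p2", _seq("GGCCGGCCGGCCGGCCGGCCG"))]
        read = ChimeraRead(
            _seq(cat[0].sequence.bases + cat[1].sequence.bases)
        )
        outcome, _, _ = split_chimera(read, cat)
        assert outcome is SplitOutcome.AMBIGUOUS

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            split_chimera(ChimeraRead(_seq("AAA")), [])


class TestMapSegment:
    tx = [_seq("AAUGGCCAAUUGGCCAAUUGG", name="t1"), _seq("CCCCGGGGCCCCGGGG", name="t2")]

    def test_verbatim_segment_found(self):
        hits = map_segment(_seq("AUGGCCAAUU"), self.tx, 0)
        assert hits == [("t1", 1, 0)]

    def test_absent_segment(self):
        assert map_segment(_seq("AUAUAUAUAU"), self.tx, 0) == []

    def test_one_substitution_needs_mm_budget(self):
        probe = _seq("AUGGCCAAUA")  # last base substituted
        assert map_segment(probe, self.tx, 0) == []
        assert ("t1", 1, 1) in map_segment(probe, self.tx, 1)

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            map_segment(_seq("AAA"), [], 0)


class TestSiteFromAlignment:
    tx = _seq("AUGC" * 25, name="t")  # length 100

    def test_center_and_window(self):
        site = site_from_alignment(self.tx, 40, 14, 15)
        assert site.center == 46
        assert site.segment.bases == self.tx.bases[31:62]
        assert len(site.segment) == 31

    def test_window_underrun_rejected(self):
        assert site_from_alignment(self.tx, 0, 14, 15) == "window_underrun"

    def test_degenerate_extension(self):
        site = site_from_alignment(self.tx, 40, 14, 0)
        assert site.segment.bases == self.tx.bases[46]


class TestRigorousPipeline:
    def test_hand_fixture_survivors_and_attrition(self, hand_fixture):
        positives, report = build_positive_set(
            hand_fixture["chimeras"],
            hand_fixture["catalog"],
            hand_fixture["transcriptome"],
        )
        assert report["input"] == 9
        assert report["read_count"] == 1
        assert report["remaining_length"] == 1
        assert report["mapping"] == 1
        assert report["multi_hit"] == 1
        assert report["energy"] == 1
        assert report["split"] == 0
        assert report["window"] == 0
        assert report["survivors"] == 4
        # attrition conservation: every chimera accounted for exactly once
        kills = sum(report[k] for k in
                    ("read_count", "split", "remaining_length", "mapping",
                     "multi_hit", "window", "energy"))
        assert kills + report["survivors"] == report["input"]
        from collections import Counter
        assert Counter(p.pirna_id for p in positives) == hand_fixture[
            "expected_survivor_pirnas"
        ]
        for p in positives:
            assert p.provenance["energy"] < 0
            assert p.provenance["read_count"] >= 7
            assert p.provenance["remaining_len"] >= 14
            assert len(p.mrna_segment) == 31

    def test_empty_chimeras(self, hand_fixture):
        positives, report = build_positive_set(
            [], hand_fixture["catalog"], hand_fixture["transcriptome"]
        )
        assert positives == [] and report["input"] == 0

    def test_loose_relaxation_is_superset(self, hand_fixture):
        lbs = build_loose_set(
            hand_fixture["chimeras"], hand_fixture["catalog"],
            hand_fixture["transcriptome"],
        )
        positives, _ = build_positive_set(
            hand_fixture["chimeras"], hand_fixture["catalog"],
            hand_fixture["transcriptome"],
        )
        projected = {(p.pirna_id, p.provenance["transcript_id"]) for p in positives}
        assert projected <= lbs
        # the count-6 and 13-nt-remaining chimeras contribute loose evidence
        assert ("piR-1", "tx-1") in lbs

    def test_short_loose_remaining_excluded(self, hand_fixture):
        cfg = PrepConfig()
        p2 = hand_fixture["catalog"][1]
        tx = hand_fixture["transcriptome"]
        # remaining of 6 nt is below even the loose threshold of 7
        read = ChimeraRead(_seq(p2.sequence.bases + tx[0].bases[83:89]), 1)
        assert build_loose_set([read], hand_fixture["catalog"], tx, cfg) == set()


class TestNegativeCandidates:
    def test_complement_semantics(self):
        lbs = {("i", "x1")}
        assert negative_candidates("i", {"x1", "x2", "x3"}, lbs) == {"x2", "x3"}

    def test_empty_lbs_gives_universe(self):
        assert negative_candidates("i", {"x1", "x2"}, set()) == {"x1", "x2"}

    def test_full_lbs_gives_empty(self):
        lbs = {("i", "x1"), ("i", "x2")}
        assert negative_candidates("i", {"x1", "x2"}, lbs) == set()

    def test_restricted_to_positive_set_pirnas(self):
        with pytest.raises(ValueError):
            negative_candidates("ghost", {"x"}, set(), positive_pirna_ids={"i"})


class TestSampleNegatives:
    def test_respects_candidate_complement_and_determinism(self, hand_fixture):
        positives, _ = build_positive_set(
            hand_fixture["chimeras"], hand_fixture["catalog"],
            hand_fixture["transcriptome"],
        )
        # decoy transcript so each piRNA has candidates outside the LBS
        rng = np.random.default_rng(5)
        decoy = _seq("".join(rng.choice(list("AUGC"), 200)), name="tx-decoy")
        tx = hand_fixture["transcriptome"] + [decoy]
        lbs = {(p.pirna_id, "tx-1") for p in positives}
        negs = sample_negatives(positives, lbs, tx, n_target=6, rng_seed=1)
        assert len(negs) == 6
        assert all(n.provenance["transcript_id"] == "tx-decoy" for n in negs)
        assert all(n.provenance["energy"] < 0 for n in negs)
        negs2 = sample_negatives(positives, lbs, tx, n_target=6, rng_seed=1)
        assert [n.key for n in negs] == [n2.key for n2 in negs2]

    def test_similar_to_positive_rejected(self):
        # one positive window; candidate windows at Hamming 2 are rejected,
        # Hamming 3 accepted
        rng = np.random.default_rng(7)
        window = "".join(rng.choice(list("AUGC"), 31))
        pos = [
            PairExample("p", _seq("A" * 21), _seq(window), 1,
                        provenance=dict(transcript_id="t1"))
        ]
        w2 = list(window); w3 = list(window)
        for i, j in [(3, 9)]:
            w2[i] = "A" if w2[i] != "A" else "C"
            w2[j] = "A" if w2[j] != "A" else "C"
        for i in (3, 9, 15):
            w3[i] = "U" if w3[i] != "U" else "G"
        tx2 = _seq("".join(w2), name="t2")
        tx3 = _seq("".join(w3), name="t3")
        with pytest.raises(RuntimeError):
            sample_negatives(pos, set(), [tx2], n_target=1, rng_seed=0,
                             draw_budget_factor=50)
        negs = sample_negatives(pos, set(), [tx3], n_target=1, rng_seed=0)
        assert negs[0].mrna_segment.bases == "".join(w3)

    def test_ground_truth_invariant_no_key_overlap(self, hand_fixture):
        rng = np.random.default_rng(5)
        decoy = _seq("".join(rng.choice(list("AUGC"), 200)), name="tx-decoy")
        tx = hand_fixture["transcriptome"] + [decoy]
        gt, _ = build_ground_truth(
            hand_fixture["chimeras"], hand_fixture["catalog"], tx, rng_seed=3
        )
        assert {p.key for p in gt.positives}.isdisjoint({n.key for n in gt.negatives})
        with pytest.raises(ValueError):
            GroundTruth(positives=gt.positives, negatives=gt.positives)


class TestIndependentSet:
    def _gt(self, keys, label, loose=()):
        pairs = [
            PairExample(pid, _seq("A" * 21), _seq(seg), label)
            for pid, seg in keys
        ]
        if label == 1:
            return GroundTruth(positives=pairs, negatives=[], loose_set=set(loose))
        return GroundTruth(positives=[], negatives=pairs, loose_set=set(loose))

    def _combined(self, pos_keys, neg_keys):
        return GroundTruth(
            positives=[PairExample(p, _seq("A" * 21), _seq(s), 1) for p, s in pos_keys],
            negatives=[PairExample(p, _seq("A" * 21), _seq(s), 0) for p, s in neg_keys],
        )

    def test_disjoint_pools_sampled(self):
        ind = self._combined(
            [(f"p{i}", ("AUGC" * 8)[:31]) for i in range(6)],
            [(f"q{i}", ("GGCC" * 8)[:31]) for i in range(6)],
        )
        wt = self._combined([("z", ("AAUU" * 8)[:31])], [("y", ("CCGG" * 8)[:31])])
        out, info = assemble_independent_set(ind, wt, n_pos=5, n_neg=5, rng_seed=0)
        assert len(out.positives) == 5 and len(out.negatives) == 5
        assert info["removed_wildtype_overlap"] == 0
        assert info["wildtype_negative_conflicts"] == []

    def test_full_overlap_errors(self):
        keys = [(f"p{i}", ("AUGC" * 8)[:31]) for i in range(4)]
        ind = self._combined(keys, [])
        wt = self._combined(keys, [])
        with pytest.raises(ValueError):
            assemble_independent_set(ind, wt, n_pos=1, n_neg=0, rng_seed=0)

    def test_planted_conflict_reported(self):
        shared = ("pX", ("AUCG" * 8)[:31])
        ind = self._combined(
            [shared] + [(f"p{i}", ("AUGC" * 8)[:31]) for i in range(3)],
            [(f"q{i}", ("GGCC" * 8)[:31]) for i in range(3)],
        )
        wt = self._combined([], [shared])
        out, info = assemble_independent_set(ind, wt, n_pos=2, n_neg=2, rng_seed=0)
        assert info["wildtype_negative_conflicts"] == [list(shared)]


def test_pairs_tsv_roundtrip(tmp_path, hand_fixture):
    positives, _ = build_positive_set(
        hand_fixture["chimeras"], hand_fixture["catalog"], hand_fixture["transcriptome"]
    )
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(positives, path)
    back = read_pairs_tsv(path)
    assert {p.key for p in back} == {p.key for p in positives}
    assert all(p.label == 1 for p in back)


def test_read_chimeras_tsv(tmp_path):
    path = tmp_path / "chimeras.tsv"
    path.write_text("AUGCAUGC\t5\nGGGGCCCC\t2\n")
    reads, dropped = read_chimeras(path)
    assert dropped == 0
    assert {(r.sequence.bases, r.read_count) for r in reads} == {
        ("AUGCAUGC", 5), ("GGGGCCCC", 2)
    }
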