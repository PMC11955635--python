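"""Read merging, V/J assignment, clonotype clustering and AIRR I/O."""

import numpy as np
import pytest

from tcrsift import (
    SimulationConfig,
    assign_vj_and_extract_junction,
    cluster_clonotypes,
    filter_productive,
    merge_read_pair,
    read_airr,
    write_airr,
)
from tcrsift.repertoire import (
    ReadPair,
    VJAssignment,
    is_productive,
    revcomp,
    run_clonotyping,
)
from tcrsift.simulate import simulate_read_pairs, simulate_repertoire

from conftest import make_pair, overlapping_pair, random_fragment


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMergeReadPair:
    def test_identity_overlap(self, rng):
        frag = random_fragment(rng, 260)
        cons = merge_read_pair(overlapping_pair(frag, 150))
        assert cons.sequence == frag
        assert cons.overlap_len == 40
        assert cons.mismatches_in_overlap == 0

    def test_full_length_reverse_complement_idempotent(self, rng):
        seq = random_fragment(rng, 150)
        cons = merge_read_pair(make_pair(seq, revcomp(seq)))
        assert cons.sequence == seq
        assert cons.overlap_len == 150

    def test_short_overlap_rejected(self, rng):
        frag = random_fragment(rng, 2 * 150 - 12)  # best overlap 12 < 20
        assert merge_read_pair(overlapping_pair(frag, 150),
                               min_overlap=20) is None

    def test_excess_mismatches_rejected(self, rng):
        frag = random_fragment(rng, 260)
        pair = overlapping_pair(frag, 150)
        # corrupt 8 of the 40 overlap bases of mate 1 (20% > 10%)
        s1 = list(pair.seq1)
        for i in range(120, 128):
            s1[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s1[i]]
        assert merge_read_pair(make_pair("".join(s1), pair.seq2)) is None

    def test_disagreement_resolved_by_quality(self, rng):
        frag = random_fragment(rng, 260)
        s1 = list(frag[:150])
        disagree_at = 130  # inside the 40 nt overlap
        true_base = s1[disagree_at]
        s1[disagree_at] = {"A": "C", "C": "A", "G": "T", "T": "G"}[true_base]
        qual1 = [38] * 150
        qual2 = [20] * 150
        pair = overlapping_pair(frag, 150, qual1, qual2)
        pair = make_pair("".join(s1), pair.seq2, qual1, qual2)
        cons = merge_read_pair(pair)
        assert cons.mismatches_in_overlap == 1
        # mate 1's (wrong) base has the higher Phred and must win
        assert cons.sequence[disagree_at] != true_base

        # flip the qualities: mate 2's true base wins
        pair_flipped = make_pair("".join(s1), pair.seq2, [20] * 150, [38] * 150)
        cons2 = merge_read_pair(pair_flipped)
        assert cons2.sequence[disagree_at] == true_base

    def test_n_never_wins_disagreement(self, rng):
        frag = random_fragment(rng, 260)
        s1 = list(frag[:150])
        s1[140] = "N"
        pair = overlapping_pair(frag, 150, [41] * 150, [10] * 150)
        pair = make_pair("".join(s1), pair.seq2, [41] * 150, [10] * 150)
        cons = merge_read_pair(pair)
        assert cons.sequence[140] == frag[140]

    def test_all_n_overlap_rejected(self):
        seq1 = "A" * 110 + "N" * 40
        frag_tail = "N" * 40 + "G" * 110
        pair = make_pair(seq1, revcomp(frag_tail))
        assert merge_read_pair(pair) is None

    def test_non_nucleotide_raises(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            make_pair("ACGX" * 10, "ACGT" * 10)

    def test_brute_force_overlap_oracle(self, rng):
        """Best overlap/mismatch bookkeeping matches an exhaustive scan."""
        for _ in range(20):
            frag = random_fragment(rng, int(rng.integers(160, 220)))
            pair = overlapping_pair(frag, 120)
            cons = merge_read_pair(pair, min_overlap=10)
            s1, s2 = pair.seq1, revcomp(pair.seq2)
            best = max(
                range(1, 121),
                key=lambda L: (sum(a == b for a, b in
                                   zip(s1[-L:], s2[:L])) * 2 - L, L),
            )
            assert cons is not None and cons.overlap_len == best


# ---------------------------------------------------------------------------
# V/J assignment
# ---------------------------------------------------------------------------

class TestAssignVJ:
    def _consensus(self, sequence):
        from tcrsift.repertoire import ConsensusSequence

        return ConsensusSequence("c", sequence, 100, 0)

    def test_planted_junction_recovered(self, library, rng):
        v = library.v_segments[0]
        j = library.j_segments[0]
        insert = "GCTGAA"
        junction = (v.sequence[v.anchor_start:] + insert
                    + j.sequence[: j.anchor_start + 3])
        consensus = v.sequence + insert + j.sequence
        asg = assign_vj_and_extract_junction(self._consensus(consensus),
                                             library)
        assert asg.junction_nt == junction
        assert asg.v_call == v.name and asg.j_call == j.name

    def test_hundred_random_junctions_recovered(self, library, rng):
        n_ok = 0
        for _ in range(100):
            v = library.v_segments[rng.integers(4)]
            j = library.j_segments[rng.integers(3)]
            insert = "".join(rng.choice(list("ACGT"))
                             for _ in range(3 * rng.integers(1, 5)))
            junction = (v.sequence[v.anchor_start:] + insert
                        + j.sequence[: j.anchor_start + 3])
            asg = assign_vj_and_extract_junction(
                self._consensus(v.sequence + insert + j.sequence), library)
            if asg and asg.junction_nt == junction:
                n_ok += 1
        assert n_ok == 100

    def test_scrambled_v_unassigned(self, library, rng):
        j = library.j_segments[0]
        scrambled = random_fragment(rng, 120)
        asg = assign_vj_and_extract_junction(
            self._consensus(scrambled + "GCTGAA" + j.sequence), library)
        assert asg is None


# ---------------------------------------------------------------------------
# clustering and productivity
# ---------------------------------------------------------------------------

def _asg(jnt, v="TRBV-T1", j="TRBJ-T1", pid="r"):
    return VJAssignment(pid, jnt, v, j)


class TestClusterClonotypes:
    def test_frequencies(self):
        profile = cluster_clonotypes(
            [_asg("TGTGCCAGCTTT")] * 3 + [_asg("TGTGCCTGGTTT")])
        assert [c.frequency for c in profile.clonotypes] == [75.0, 25.0]
        assert profile.total_reads == 4

    def test_v_call_distinguishes_clonotypes(self):
        profile = cluster_clonotypes([_asg("TGTGCCAGCTTT", v="TRBV-T1"),
                                      _asg("TGTGCCAGCTTT", v="TRBV-T2")])
        assert len(profile.clonotypes) == 2

    def test_order_invariance(self, rng):
        records = [_asg(f"TGTGCC{c}TTT") for c in
                   ("AAA", "CCC", "GGG", "TTT", "ACG")] * 7
        a = cluster_clonotypes(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = cluster_clonotypes(shuffled)
        assert a.clonotypes == b.clonotypes

    def test_simulated_draw_proportions(self, small_cfg):
        profile = simulate_repertoire(small_cfg, "s", "tumor")
        total = sum(c.read_count for c in profile.clonotypes)
        assert total == profile.total_reads == 1000
        for c in profile.clonotypes:
            assert c.frequency == pytest.approx(100 * c.read_count / total)

    def test_empty_input(self):
        profile = cluster_clonotypes([])
        assert profile.clonotypes == [] and profile.total_reads == 0

    def test_frequency_sum_invariant(self, small_cfg):
        profile = simulate_repertoire(small_cfg)
        assert sum(c.frequency for c in profile.clonotypes) == pytest.approx(
            100.0, abs=1e-9)


class TestProductivity:
    @pytest.mark.parametrize("junction,expected", [
        ("TGTGCCAGCTTT", True),        # C-A-S-F in frame
        ("TGTGCCTAGTTT", False),       # internal stop TAG
        ("TGTGCCAGCTTTA", False),      # 13 nt, frame-breaking
        ("TGTGCCAGCTGG", True),        # ends W
        ("GCTGCCAGCTTT", False),       # does not start with C
        ("TGTGCCAGCAAA", False),       # ends K
    ])
    def test_rules(self, junction, expected):
        assert is_productive(junction) is expected

    def test_filter_recomputes_frequencies(self):
        profile = cluster_clonotypes(
            [_asg("TGTGCCAGCTTT")] * 3 + [_asg("TGTGCCTAGTTT")] * 2)
        filtered = filter_productive(profile)
        assert len(filtered.clonotypes) == 1
        assert filtered.clonotypes[0].frequency == pytest.approx(100.0)
        assert filtered.total_reads == 3

    def test_all_nonproductive_warns(self):
        profile = cluster_clonotypes([_asg("TGTGCCTAGTTT")])
        with pytest.warns(UserWarning, match="non-productive"):
            filtered = filter_productive(profile)
        assert filtered.clonotypes == []


# ---------------------------------------------------------------------------
# end-to-end accounting
# ---------------------------------------------------------------------------

class TestPipelineAccounting:
    def test_every_read_accounted(self, library, small_cfg):
        profile = simulate_repertoire(small_cfg, "s", "tumor")
        pairs, _ = simulate_read_pairs(profile, small_cfg)
        # corrupt a few pairs so both rejection paths are exercised
        broken = [ReadPair(p.pair_id, p.seq1[:30], p.seq2[:30],
                           p.qual1[:30], p.qual2[:30]) for p in pairs[:3]]
        result = run_clonotyping(broken + pairs[3:], library)
        assert (result.n_assigned + result.n_unassigned
                + result.n_rejected_merge) == result.n_input
        assert result.n_input == len(pairs)


# ---------------------------------------------------------------------------
# AIRR I/O
# ---------------------------------------------------------------------------

class TestAirrIO:
    def test_round_trip(self, small_cfg, tmp_path):
        profile = simulate_repertoire(small_cfg, "rt", "tumor")
        path = tmp_path / "rt.tsv"
        write_airr(profile, path)
        back = read_airr(path, sample_id="rt", compartment="tumor")
        assert back.clonotypes == profile.clonotypes
        assert back.total_reads == profile.total_reads

    def test_missing_column_raises(self, small_cfg, tmp_path):
        import pandas as pd

        profile = simulate_repertoire(small_cfg)
        path = tmp_path / "bad.tsv"
        write_airr(profile, path)
        df = pd.read_csv(path, sep="\t").drop(columns=["duplicate_count"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing column duplicate_count"):
            read_airr(path)

    def test_extra_columns_ignored(self, small_cfg, tmp_path):
        import pandas as pd

        profile = simulate_repertoire(small_cfg)
        path = tmp_path / "extra.tsv"
        write_airr(profile, path)
        df = pd.read_csv(path, sep="\t")
        df["custom_annotation"] = "x"
        df.to_csv(path, sep="\t", index=False)
        back = read_airr(path)
        assert len(back.clonotypes) == len(profile.clonotypes)
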