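"""Indel left-normalization (against a brute-force oracle), tallying and
small-variant calling."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnish import (Category, Config, accumulate_pileups, call_small_indels,
                     call_snps, classify_scaffold, normalize_indel_left,
                     tally_indels)
from burnish.pileup import RawIndelObservation

from conftest import make_genome, make_record


def apply_edit(seq: str, position: int, kind: str, edit: str) -> str:
    if kind == "deletion":
        assert seq[position:position + len(edit)] == edit
        return seq[:position] + seq[position + len(edit):]
    return seq[:position] + edit + seq[position:]


def oracle_leftmost(seq: str, position: int, kind: str, edit: str):
    """Brute force: enumerate every placement producing the same edited
    string and take the smallest coordinate."""
    target = apply_edit(seq, position, kind, edit)
    L = len(edit)
    best = None
    if kind == "deletion":
        for p in range(len(seq) - L + 1):
            if apply_edit(seq, p, "deletion", seq[p:p + L]) == target:
                best = (p, seq[p:p + L])
                break
    else:
        for p in range(len(seq) + 1):
            for cand in map("".join, itertools.product("ACGT", repeat=L)):
                if apply_edit(seq, p, "insertion", cand) == target:
                    best = (p, cand)
                    break
            if best:
                break
    return best


class TestNormalizeLeft:
    def test_homopolymer_deletion_all_placements_agree(self):
        g = make_genome("ACCCCT")
        results = {normalize_indel_left(g, "s1", p, "deletion", "C")
                   for p in (1, 2, 3, 4)}
        assert results == {(1, "C")}

    def test_insertion_shifts_through_homopolymer(self):
        g = make_genome("AAAT")
        assert normalize_indel_left(g, "s1", 3, "insertion", "A") == (0, "A")

    def test_no_equivalent_shift_is_identity(self):
        g = make_genome("ACGT")
        assert normalize_indel_left(g, "s1", 1, "deletion", "C") == (1, "C")

    def test_deletion_past_end_rejected(self):
        g = make_genome("ACGT")
        with pytest.raises(ValueError):
            normalize_indel_left(g, "s1", 3, "deletion", "TT")

    def test_exhaustive_against_oracle_small_genomes(self):
        """Every deletion/insertion placement on every {A,C} genome up to
        length 6 normalizes to the brute-force leftmost placement."""
        for n in range(2, 7):
            for seq in map("".join, itertools.product("AC", repeat=n)):
                g = make_genome(seq)
                for L in (1, 2):
                    for p in range(n - L + 1):
                        got = normalize_indel_left(g, "s1", p, "deletion",
                                                   seq[p:p + L])
                        assert got == oracle_leftmost(seq, p, "deletion",
                                                      seq[p:p + L])
                    for p in range(n + 1):
                        for ins in map("".join,
                                       itertools.product("AC", repeat=L)):
                            got = normalize_indel_left(g, "s1", p,
                                                       "insertion", ins)
                            assert got == oracle_leftmost(seq, p,
                                                          "insertion", ins)

    @given(st.text("ACGT", min_size=2, max_size=8), st.data())
    @settings(max_examples=300, deadline=None)
    def test_random_genomes_match_oracle(self, seq, data):
        g = make_genome(seq)
        kind = data.draw(st.sampled_from(["deletion", "insertion"]))
        L = data.draw(st.integers(1, 2))
        if kind == "deletion":
            if len(seq) < L:
                return
            p = data.draw(st.integers(0, len(seq) - L))
            edit = seq[p:p + L]
        else:
            p = data.draw(st.integers(0, len(seq)))
            edit = data.draw(st.text("ACGT", min_size=L, max_size=L))
        assert normalize_indel_left(g, "s1", p, kind, edit) == \
            oracle_leftmost(seq, p, kind, edit)

    @given(st.text("ACGT", min_size=2, max_size=8), st.data())
    @settings(max_examples=200, deadline=None)
    def test_normalization_preserves_edited_sequence_and_is_idempotent(
            self, seq, data):
        g = make_genome(seq)
        L = data.draw(st.integers(1, 2))
        if len(seq) < L:
            return
        p = data.draw(st.integers(0, len(seq) - L))
        p2, s2 = normalize_indel_left(g, "s1", p, "deletion", seq[p:p + L])
        assert apply_edit(seq, p2, "deletion", s2) == \
            apply_edit(seq, p, "deletion", seq[p:p + L])
        assert normalize_indel_left(g, "s1", p2, "deletion", s2) == (p2, s2)


def _obs(pos, kind, seq, name, scaffold="s1", w=30.0):
    return RawIndelObservation(scaffold, pos, kind, seq, name, w)


class TestTally:
    def test_equivalent_homopolymer_deletions_merge(self):
        g = make_genome("ACCCCT")
        raw = [_obs(p, "deletion", "C", f"r{p}") for p in (1, 2, 3, 4)]
        tally = tally_indels(raw, g)
        assert len(tally) == 1
        ((_, pos, kind, seq),) = tally.keys()
        obs = next(iter(tally.values()))
        assert (pos, kind, seq) == (1, "deletion", "C")
        assert obs.support_count == 4

    def test_non_equivalent_events_stay_separate(self):
        g = make_genome("ACGTAGGT")
        raw = [_obs(1, "deletion", "C", "r1"), _obs(1, "deletion", "CG", "r2")]
        assert len(tally_indels(raw, g)) == 2

    def test_duplicate_read_names_counted_once(self):
        g = make_genome("ACCCCT")
        raw = [_obs(1, "deletion", "C", "r1"), _obs(2, "deletion", "C", "r1")]
        (obs,) = tally_indels(raw, g).values()
        assert obs.support_count == 1

    def test_empty_stream(self):
        assert tally_indels([], make_genome("ACGT")) == {}


class TestCallIndels:
    def _pileups(self, genome, depth, deleted=()):
        recs = [make_record(genome.sequences["s1"], name=f"r{i}")
                for i in range(depth)]
        return accumulate_pileups(genome, recs, Config(flank_trim=0))

    def test_majority_supported_deletion_called(self):
        g = make_genome("AACGTACGTACGTT")
        t = self._pileups(g, 10)
        raw = [_obs(4, "deletion", "T", f"d{i}") for i in range(8)]
        calls = call_small_indels(tally_indels(raw, g), t, Config())
        assert len(calls) == 1
        assert calls[0].kind == "deletion"

    def test_minority_supported_deletion_not_called(self):
        g = make_genome("AACGTACGTACGTT")
        t = self._pileups(g, 10)
        raw = [_obs(4, "deletion", "T", f"d{i}") for i in range(3)]
        assert call_small_indels(tally_indels(raw, g), t, Config()) == []

    def test_long_event_uses_relaxed_threshold(self):
        g = make_genome("AA" + "ACGTGTCAGCTAGCA" + "GGTT" + "C" * 10)
        t = self._pileups(g, 10)
        raw = [_obs(2, "deletion", "ACGTGTCAGCTAGCA", f"d{i}")
               for i in range(4)]    # 15 bp at 40% support
        calls = call_small_indels(tally_indels(raw, g), t, Config())
        assert len(calls) == 1

    def test_short_event_at_forty_percent_not_called(self):
        g = make_genome("AACGTACGTACGTT")
        t = self._pileups(g, 10)
        raw = [_obs(4, "deletion", "T", f"d{i}") for i in range(4)]
        assert call_small_indels(tally_indels(raw, g), t, Config()) == []


class TestCallSnps:
    def _classify(self, genome, recs, cfg):
        t = accumulate_pileups(genome, recs, cfg)
        return {"s1": classify_scaffold(genome, "s1", t["s1"], cfg,
                                        min_depth=5)}

    def test_changed_position_yields_fix_and_call(self):
        g = make_genome("A" * 20)
        recs = [make_record("A" * 8 + "C" + "A" * 11, name=f"r{i}")
                for i in range(10)]
        cfg = Config(flank_trim=0)
        calls, fixes = call_snps(g, self._classify(g, recs, cfg), cfg)
        assert [(c.position, c.ref_allele, c.alt_allele)
                for c in calls] == [(8, "A", "C")]
        assert [(f.position, f.alt) for f in fixes] == [(8, "C")]

    def test_ambiguous_not_fixed_by_default_but_fixed_when_enabled(self):
        g = make_genome("A" * 20)
        recs = ([make_record("A" * 8 + "C" + "A" * 11, name=f"c{i}")
                 for i in range(6)]
                + [make_record("A" * 20, name=f"a{i}") for i in range(4)])
        cfg = Config(flank_trim=0)
        cls = self._classify(g, recs, cfg)
        assert cls["s1"][8].category is Category.AMBIGUOUS
        calls, fixes = call_snps(g, cls, cfg)
        assert fixes == []
        cfg_fix = Config(flank_trim=0, fix_ambiguous=True)
        _, fixes2 = call_snps(g, cls, cfg_fix)
        assert [(f.position, f.alt, f.ambiguous) for f in fixes2] == \
            [(8, "C", True)]

    def test_confirmed_positions_produce_no_output(self):
        g = make_genome("A" * 20)
        recs = [make_record("A" * 20, name=f"r{i}") for i in range(10)]
        cfg = Config(flank_trim=0)
        calls, fixes = call_snps(g, self._classify(g, recs, cfg), cfg)
        assert calls == [] and fixes == []
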