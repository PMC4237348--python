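"""De Bruijn graph construction, flank walks, closure logic and
consensus extensions."""

import numpy as np
import pytest

from burnish import (Config, Extension, attempt_closure, build_graph,
                     consensus_extension, revcomp, walk_from_flank)

from conftest import reads_from_seqs


def rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def clean_seq(rng, n, k):
    """A random sequence with no repeated k-mer and no k-mer shared with
    its own reverse complement, so its graph is a simple chain."""
    while True:
        s = rng_seq(rng, n)
        fwd = {s[i:i + k] for i in range(n - k + 1)}
        rc = revcomp(s)
        rcs = {rc[i:i + k] for i in range(n - k + 1)}
        if len(fwd) == n - k + 1 and not (fwd & rcs):
            return s


SMALL = Config(k=11, min_link_coverage=2)


class TestGraph:
    def test_identical_reads_make_a_linear_chain(self):
        rng = np.random.default_rng(0)
        seq = clean_seq(rng, 60, 11)
        cfg = Config(k=11, min_link_coverage=5)
        g = build_graph(reads_from_seqs([seq] * 10), cfg)
        for i in range(len(seq) - 11):
            links = g.links(seq[i:i + 11])
            assert len(links) == 1
            assert links[0][0] == seq[i + 11]
            assert links[0][2] >= 10

    def test_link_coverage_cutoff_boundary(self):
        rng = np.random.default_rng(1)
        seq = clean_seq(rng, 40, 11)
        cfg = Config(k=11, min_link_coverage=5)
        kmer = seq[10:21]
        g4 = build_graph(reads_from_seqs([seq] * 4), cfg)
        g5 = build_graph(reads_from_seqs([seq] * 5), cfg)
        assert g4.links(kmer) == []
        assert len(g5.links(kmer)) == 1

    def test_balanced_biallelic_site_is_a_branch(self):
        rng = np.random.default_rng(2)
        a = clean_seq(rng, 60, 11)
        b = a[:30] + ("A" if a[30] != "A" else "C") + a[31:]
        cfg = Config(k=11, min_link_coverage=5)
        g = build_graph(reads_from_seqs([a] * 5 + [b] * 5), cfg)
        links = g.links(a[19:30])
        assert len(links) == 2

    def test_reads_shorter_than_k_plus_one_ignored(self):
        g = build_graph(reads_from_seqs(["ACGT"]), Config(k=5))
        assert len(g) == 0


def two_haplotype_graph(n_sites: int, spacing: int = 16, seed: int = 3):
    """Reads from two haplotypes differing at ``n_sites`` spaced positions;
    every inter-site segment is shared so walks explore all combinations."""
    rng = np.random.default_rng(seed)
    base = clean_seq(rng, 40 + spacing * n_sites, SMALL.k)
    hap_a = list(base)
    hap_b = list(base)
    sites = [30 + spacing * i for i in range(n_sites)]
    for s in sites:
        hap_a[s] = "A" if base[s] != "A" else "C"
        hap_b[s] = "G" if base[s] not in "G" else "T"
    a, b = "".join(hap_a), "".join(hap_b)
    g = build_graph(reads_from_seqs([a] * 6 + [b] * 6), SMALL)
    return g, base[:SMALL.k], a, b


class TestWalks:
    def test_linear_graph_single_extension(self):
        rng = np.random.default_rng(4)
        seq = clean_seq(rng, 80, 11)
        g = build_graph(reads_from_seqs([seq] * 6), SMALL)
        exts = walk_from_flank(g, seq[:11], SMALL)
        assert len(exts) == 1
        assert exts[0].sequence == seq
        assert exts[0].terminated_by == "dead_end"
        assert exts[0].branch_count == 0

    def test_six_branch_sites_give_thirty_two_extensions(self):
        g, seed, _, _ = two_haplotype_graph(6)
        exts = walk_from_flank(g, seed, SMALL)
        assert len(exts) == 32
        assert all(e.branch_count == 5 for e in exts)
        assert all(e.terminated_by == "branch_limit" for e in exts)

    def test_five_branch_sites_give_thirty_two_full_walks(self):
        g, seed, a, b = two_haplotype_graph(5)
        exts = walk_from_flank(g, seed, SMALL)
        assert len(exts) == 32
        assert all(e.terminated_by == "dead_end" for e in exts)
        assert {a, b} <= {e.sequence for e in exts}

    def test_missing_seed_returns_nothing(self):
        g = build_graph(reads_from_seqs(["ACGTACGTACGTACGT"] * 5), SMALL)
        assert walk_from_flank(g, "T" * 11, SMALL) == []

    def test_tandem_loop_detected_with_period(self):
        # tandem of period 13 > k=11 loops the graph
        rng = np.random.default_rng(5)
        unit = "ACGTGTCAGTTCA"
        flank = clean_seq(rng, 25, 11)
        seq = flank + unit * 6
        g = build_graph(reads_from_seqs([seq] * 6), SMALL)
        exts = walk_from_flank(g, flank[:11], SMALL)
        assert len(exts) == 1
        assert exts[0].terminated_by == "loop"
        assert exts[0].loop_period == 13

    def test_walks_match_exhaustive_path_oracle(self):
        """Iterative walk equals a recursive brute-force enumeration of all
        paths with at most branch_limit branch points on random graphs."""
        def oracle(graph, seed, cfg):
            out = []

            def recurse(seq, branches, visited):
                cur = seq[-cfg.k:]
                links = graph.links(cur)
                if not links:
                    out.append((seq, "dead_end"))
                    return
                if len(links) > 1:
                    if branches >= cfg.branch_limit:
                        out.append((seq, "branch_limit"))
                        return
                    branches += 1
                pos = len(seq) + 1 - cfg.k
                for base, _, _ in links:
                    nxt = cur[1:] + base
                    if nxt in visited:
                        out.append((seq + base, "loop"))
                        continue
                    recurse(seq + base, branches, {**visited, nxt: pos})

            if seed in graph:
                recurse(seed, 0, {seed: 0})
            return sorted(out)

        rng = np.random.default_rng(6)
        for trial in range(20):
            n_hap = int(rng.integers(1, 4))
            base = rng_seq(rng, 60)
            haps = []
            for _ in range(n_hap):
                h = list(base)
                for s in rng.choice(range(10, 55), size=int(rng.integers(0, 4)),
                                    replace=False):
                    h[s] = "ACGT"[int(rng.integers(0, 4))]
                haps.append("".join(h))
            cfg = Config(k=4, min_link_coverage=2, branch_limit=3)
            g = build_graph(reads_from_seqs([h for h in haps for _ in range(3)]),
                            cfg)
            seed = base[:4]
            got = sorted((e.sequence, e.terminated_by)
                         for e in walk_from_flank(g, seed, cfg))
            assert got == oracle(g, seed, cfg)


def ext(seq, terminated="dead_end", period=None, weights=None):
    return Extension(seq, 0, terminated, period,
                     weights if weights is not None else [1.0] * len(seq))


class TestClosure:
    def _pair(self, overlap_len, seed=7):
        rng = np.random.default_rng(seed)
        left_only = rng_seq(rng, 60)
        overlap = rng_seq(rng, overlap_len)
        right_only = rng_seq(rng, 60)
        return ext(left_only + overlap), ext(overlap + right_only), \
            left_only + overlap + right_only

    def test_exact_minimum_overlap_closes(self):
        cfg = Config()          # k=47 -> 95-base overlap required
        left, right, merged = self._pair(95)
        res = attempt_closure([left], [right], cfg)
        assert res.outcome == "closed"
        assert res.replacement_sequence == merged

    def test_one_base_short_overlap_does_not_close(self):
        cfg = Config()
        left, right, _ = self._pair(94)
        assert attempt_closure([left], [right], cfg).outcome == "extended"

    def test_overlap_requirement_tracks_k(self):
        cfg = Config(k=10)
        left, right, merged = self._pair(21)
        assert attempt_closure([left], [right], cfg).outcome == "closed"
        left, right, _ = self._pair(20)
        assert attempt_closure([left], [right], cfg).outcome == "extended"

    def test_two_distinct_closures_are_ambiguous(self):
        rng = np.random.default_rng(8)
        overlap = rng_seq(rng, 95)
        l1 = ext(rng_seq(rng, 30) + overlap)
        r1 = ext(overlap + rng_seq(rng, 30))
        l2 = ext(rng_seq(rng, 30) + overlap)
        res = attempt_closure([l1, l2], [r1], Config())
        assert res.outcome == "extended"

    def test_loop_terminated_extension_forces_tandem_repeat(self):
        left, right, _ = self._pair(95)
        left.terminated_by = "loop"
        left.loop_period = 57
        res = attempt_closure([left], [right], Config())
        assert res.outcome == "tandem_repeat"
        assert res.tandem_period == 57

    def test_closure_symmetric_under_reverse_complement(self):
        cfg = Config(k=10)
        left, right, merged = self._pair(30)
        fwd = attempt_closure([left], [right], cfg)
        rleft = ext(revcomp(right.sequence))
        rright = ext(revcomp(left.sequence))
        rev = attempt_closure([rleft], [rright], cfg)
        assert rev.outcome == fwd.outcome == "closed"
        assert rev.replacement_sequence == revcomp(fwd.replacement_sequence)

    def test_walk_past_opposite_anchor_still_closes(self):
        # the right walk reaches back past the left anchor entirely
        rng = np.random.default_rng(9)
        full = rng_seq(rng, 300)
        left = ext(full[:150])
        right = ext(full)           # covers everything incl. left anchor
        res = attempt_closure([left], [right], Config())
        assert res.outcome == "closed"
        assert res.replacement_sequence == full


class TestConsensus:
    def test_single_extension_is_its_own_consensus(self):
        e = ext("ACGTACGTAC")
        assert consensus_extension([e]) == "ACGTACGTAC"

    def test_majority_weight_branch_followed(self):
        rng = np.random.default_rng(10)
        prefix = rng_seq(rng, 120)
        a = ext(prefix + "A" + "CGT", weights=[1.0] * 120 + [80.0, 1, 1, 1])
        b = ext(prefix + "G" + "TTA", weights=[1.0] * 120 + [20.0, 1, 1, 1])
        cons = consensus_extension([a, b])
        assert cons.startswith(prefix + "A")
        assert cons == prefix + "ACGT"

    def test_even_split_stops_at_divergence(self):
        rng = np.random.default_rng(11)
        prefix = rng_seq(rng, 120)
        a = ext(prefix + "ACGT", weights=[1.0] * 120 + [50.0, 1, 1, 1])
        b = ext(prefix + "GTTA", weights=[1.0] * 120 + [50.0, 1, 1, 1])
        assert consensus_extension([a, b]) == prefix

    def test_empty_input_empty_consensus(self):
        assert consensus_extension([]) == ""
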