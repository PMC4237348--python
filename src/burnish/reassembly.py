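"""Local reassembly of suspicious regions and captured gaps.

For each target interval, reads anchored to the trusted flanks are
collected and assembled into a pruned De Bruijn graph whose forward links
carry quality-weighted support.  Walks seeded with flank k-mers extend into
the untrusted region from both sides; if exactly one pair of extensions
shares a perfect overlap of at least 2k+1 bases, the flank-to-flank
assembly replaces the region.  Otherwise consensus extensions shrink a gap
from each side, or the region is reported unresolved.  Tandem repeats with
period > k manifest as loops in the walk; they are reported with their
period and never closed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .alignment_ingest import (AlignmentRecord, InputGenome, LibraryKind,
                               LibrarySpec, LibraryStats, UnmappedRead)
from .config import Config
from .discontiguity import SuspiciousRegion

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# read collection

class AlignmentIndex:
    """Position and name indexes over all alignment records, for flank
    queries and mate lookup during read collection."""

    def __init__(self, records: list[AlignmentRecord],
                 unmapped: list[UnmappedRead] | None = None):
        self.by_scaffold: dict[str, list[AlignmentRecord]] = {}
        for rec in records:
            self.by_scaffold.setdefault(rec.scaffold, []).append(rec)
        self._starts: dict[str, list[int]] = {}
        self._max_span: dict[str, int] = {}
        for name, recs in self.by_scaffold.items():
            recs.sort(key=lambda r: r.start)
            self._starts[name] = [r.start for r in recs]
            self._max_span[name] = max((r.end - r.start for r in recs),
                                       default=0)
        self.by_name: dict[tuple, list[AlignmentRecord]] = {}
        for rec in records:
            self.by_name.setdefault((rec.library.name, rec.query_name),
                                    []).append(rec)
        self.unmapped_by_name: dict[tuple, list[UnmappedRead]] = {}
        for u in (unmapped or []):
            self.unmapped_by_name.setdefault((u.library.name, u.query_name),
                                             []).append(u)

    def overlapping(self, scaffold: str, lo: int, hi: int) -> list[AlignmentRecord]:
        recs = self.by_scaffold.get(scaffold, [])
        if not recs:
            return []
        starts = self._starts[scaffold]
        span = self._max_span[scaffold]
        i = bisect.bisect_left(starts, lo - span)
        out = []
        for rec in recs[i:]:
            if rec.start >= hi:
                break
            if rec.end > lo:
                out.append(rec)
        return out

    def mate_sequence(self, rec: AlignmentRecord) -> tuple[str, list] | None:
        """Sequence and qualities of the mate of ``rec`` (mapped or not),
        reverse-complemented out of alignment orientation is NOT applied —
        the caller uses both orientations."""
        key = (rec.library.name, rec.query_name)
        for m in self.by_name.get(key, []):
            if m.is_read1 != rec.is_read1:
                return m.bases, list(m.base_qualities)
        for u in self.unmapped_by_name.get(key, []):
            if u.is_read1 != rec.is_read1:
                return u.bases, list(u.base_qualities)
        return None


def collect_reads_for_region(region: SuspiciousRegion,
                             index: AlignmentIndex,
                             stats: list[LibraryStats],
                             config: Config) -> list[tuple[str, list]]:
    """Reads that may carry evidence for the true sequence of a region.

    Three sources: (1) reads overlapping the immediate flanks or the region
    itself, including partial (soft-clipped) alignments — these supply the
    trusted seed k-mers; (2) fragment pairs with a read anchored to a flank
    in the orientation pointing into the region whose mate is unmapped or
    improperly mapped — both reads are included; (3) the same situation in
    a long-insert library — only the unanchored mate is included.
    """
    read_len = max((s.read_length_mode for s in stats), default=100)
    local_pad = 2 * read_len
    seen: set[tuple] = set()
    out: list[tuple[str, list]] = []

    def add(name: str, r1: bool, seq: str, quals: list) -> None:
        key = (name, r1)
        if key in seen or not seq:
            return
        seen.add(key)
        out.append((seq, quals))

    # (1) local flank and region coverage
    for rec in index.overlapping(region.scaffold, region.start - local_pad,
                                 region.end + local_pad):
        add(rec.query_name, rec.is_read1, rec.bases,
            list(rec.base_qualities))

    # (2)/(3) pair recruitment per paired library
    for st in stats:
        if not st.library.paired or st.insert_mean is None:
            continue
        span = int(st.insert_mean + 3 * (st.insert_sd or 0.0))
        lo = region.start - span
        hi = region.end + span
        for rec in index.overlapping(region.scaffold, lo, hi):
            if rec.library != st.library:
                continue
            anchored_left = (not rec.is_reverse and rec.end <= region.end)
            anchored_right = (rec.is_reverse and rec.start >= region.start)
            if not (anchored_left or anchored_right):
                continue
            if rec.is_proper_pair or not rec.is_paired:
                continue
            mate = index.mate_sequence(rec)
            if st.library.kind is LibraryKind.FRAGMENT:
                add(rec.query_name, rec.is_read1, rec.bases,
                    list(rec.base_qualities))
                if mate is not None:
                    add(rec.query_name, not rec.is_read1, mate[0], mate[1])
            elif st.library.kind is LibraryKind.LONG_INSERT:
                if mate is not None:
                    add(rec.query_name, not rec.is_read1, mate[0], mate[1])
    return out


# ---------------------------------------------------------------------------
# graph

class KmerGraph:
    """De Bruijn graph over read k-mers.

    Each node records a pileup of the bases observed immediately after that
    k-mer (quality-weighted).  Forward links require both a minimum read
    count (``min_link_coverage``) and a minimum weight fraction
    (``ambiguous_fraction``); one surviving link is an unambiguous call,
    two or more are a branch.
    """

    def __init__(self, k: int, config: Config):
        self.k = k
        self.config = config
        self.nodes: dict[str, list] = {}   # kmer -> [weights(4), counts(4)]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def add_read(self, seq: str, quals: list) -> None:
        self._add_oriented(seq.upper(), quals)
        self._add_oriented(revcomp(seq.upper()), list(reversed(quals)))

    def _add_oriented(self, seq: str, quals: list) -> None:
        k = self.k
        n = len(seq)
        if n < k + 1:
            return
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        nodes = self.nodes
        for i in range(n - k):
            nxt = seq[i + k]
            j = idx.get(nxt)
            if j is None:
                continue
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            node = nodes.get(kmer)
            if node is None:
                node = [np.zeros(4), np.zeros(4, dtype=np.int64)]
                nodes[kmer] = node
            node[0][j] += quals[i + k] if i + k < len(quals) else 20.0
            node[1][j] += 1

    def links(self, kmer: str) -> list[tuple[str, float, int]]:
        """Surviving forward links from a node: (base, weight, count),
        heaviest first."""
        node = self.nodes.get(kmer)
        if node is None:
            return []
        weights, counts = node
        total = float(weights.sum())
        out = []
        candidates = [j for j in range(4)
                      if counts[j] >= self.config.min_link_coverage]
        if not candidates:
            return []
        passing = [j for j in candidates
                   if total > 0 and weights[j] / total
                   >= self.config.ambiguous_fraction]
        if not passing:
            passing = [max(candidates, key=lambda j: weights[j])]
        for j in sorted(passing, key=lambda j: -weights[j]):
            out.append(("ACGT"[j], float(weights[j]), int(counts[j])))
        return out


def build_graph(reads: list[tuple[str, list]], config: Config) -> KmerGraph:
    """Build the pruned local-assembly graph from collected reads.

    Reads are inserted in both orientations, so flank orientation handling
    is implicit.  Reads shorter than k+1 contribute nothing.
    """
    graph = KmerGraph(config.k, config)
    for seq, quals in reads:
        graph.add_read(seq, quals)
    return graph


# ---------------------------------------------------------------------------
# walks

@dataclass
class Extension:
    """One walk from a flank seed: the assembled sequence (seed included as
    prefix), how it terminated, and the link weight of every appended base
    (used for consensus)."""

    sequence: str
    branch_count: int
    terminated_by: str                    # dead_end | branch_limit | loop
    loop_period: int | None = None
    step_weights: list = field(default_factory=list)


def walk_from_flank(graph: KmerGraph, seed_kmer: str,
                    config: Config) -> list[Extension]:
    """Depth-first enumeration of all extensions from a seed k-mer.

    A walk forks at every branch node, each fork inheriting the path's
    branch count; a path terminates at a dead end, when it would pass its
    ``branch_limit``-th branch point, or when it revisits a k-mer already
    on its own path (a loop; the period is the distance since that k-mer
    was first incorporated).  At most ``2**branch_limit`` extensions are
    returned per seed.
    """
    if seed_kmer not in graph:
        return []
    k = graph.k
    done: list[Extension] = []
    # stack entries: (sequence, branch_count, visited{kmer: start index}, weights)
    stack = [(seed_kmer, 0, {seed_kmer: 0}, [])]
    while stack:
        seq, branches, visited, weights = stack.pop()
        while True:
            cur = seq[-k:]
            links = graph.links(cur)
            if not links:
                done.append(Extension(seq, branches, "dead_end",
                                      step_weights=weights))
                break
            if len(links) == 1:
                base, w, _ = links[0]
            else:
                if branches >= config.branch_limit:
                    done.append(Extension(seq, branches, "branch_limit",
                                          step_weights=weights))
                    break
                branches += 1
                # fork the non-first choices onto the stack
                pos2 = len(seq) + 1 - k
                for b2, w2, _ in links[1:]:
                    nxt2 = cur[1:] + b2
                    if nxt2 in visited:
                        done.append(Extension(seq + b2, branches, "loop",
                                              loop_period=pos2 - visited[nxt2],
                                              step_weights=weights + [w2]))
                        continue
                    forked = dict(visited)
                    forked[nxt2] = pos2
                    stack.append((seq + b2, branches, forked,
                                  weights + [w2]))
                base, w, _ = links[0]
            nxt = cur[1:] + base
            pos = len(seq) + 1 - k
            if nxt in visited:
                done.append(Extension(seq + base, branches, "loop",
                                      loop_period=pos - visited[nxt],
                                      step_weights=weights + [w]))
                break
            visited[nxt] = pos
            seq += base
            weights = weights + [w]
    return done


def consensus_extension(extensions: list[Extension]) -> str:
    """Single consensus sequence from a set of extensions.

    Follows the positions on which all surviving extensions agree; at a
    divergence the branch carrying the larger summed link weight wins and
    disagreeing extensions drop out; an exact weight tie stops the
    consensus (conservative: never guess).
    """
    if not extensions:
        return ""
    if len(extensions) == 1:
        return extensions[0].sequence
    seed_len = len(extensions[0].sequence) - len(extensions[0].step_weights)
    alive = list(extensions)
    out = extensions[0].sequence[:seed_len]
    i = 0  # index into step positions
    while alive:
        groups: dict[str, float] = {}
        for e in alive:
            if i < len(e.step_weights):
                b = e.sequence[seed_len + i]
                groups[b] = groups.get(b, 0.0) + e.step_weights[i]
        if not groups:
            break
        ranked = sorted(groups.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            break
        best = ranked[0][0]
        out += best
        alive = [e for e in alive
                 if i < len(e.step_weights) and e.sequence[seed_len + i] == best]
        i += 1
    return out


# ---------------------------------------------------------------------------
# closure

def _overlap_merges(left: str, right: str, min_ov: int) -> set[str]:
    """All flank-to-flank sequences produced by a perfect overlap of at
    least ``min_ov`` bases between a left and a right extension.

    The two walks may extend past each other's anchors, so the alignment
    offset ``t`` (position of ``right``'s start relative to ``left``) may
    be negative.  Candidate offsets are found by seeding with exact
    ``min_ov``-length windows (any overlap of length >= min_ov contains at
    least one), then verified over the full overlap.  The merged sequence
    always runs from the start of ``left`` (the left anchor) to the end of
    ``right`` (the right anchor).
    """
    out: set[str] = set()
    if len(left) < min_ov or len(right) < min_ov:
        return out
    window: dict[str, list[int]] = {}
    for i in range(len(left) - min_ov + 1):
        window.setdefault(left[i:i + min_ov], []).append(i)
    offsets: set[int] = set()
    for j in range(len(right) - min_ov + 1):
        for i in window.get(right[j:j + min_ov], ()):
            offsets.add(i - j)
    for t in offsets:
        a = max(0, t)
        b = min(len(left), t + len(right))
        if b - a < min_ov:
            continue
        if left[a:b] != right[a - t:b - t]:
            continue
        out.add(left[:a] + right[a - t:])
    return out


@dataclass
class ClosureResult:
    outcome: str                 # closed | extended | no_solution | tandem_repeat
    replacement_sequence: str | None = None
    left_extension: str | None = None
    right_extension: str | None = None
    tandem_period: int | None = None


def attempt_closure(left_extensions: list[Extension],
                    right_extensions: list[Extension],
                    config: Config) -> ClosureResult:
    """Combinatorially match left and right extensions for a unique closure.

    ``right_extensions`` must already be reverse-complemented into left
    orientation (so their sequences end with the right-flank anchor).  A
    closure is a perfect (exact-match) overlap of at least 2k+1 bases
    between a left suffix and a right prefix; the region is closed only
    when exactly one distinct flank-to-flank sequence results.  Any
    loop-terminated extension on either side reports a tandem repeat and
    blocks closure.
    """
    for e in left_extensions + right_extensions:
        if e.terminated_by == "loop":
            return ClosureResult("tandem_repeat", tandem_period=e.loop_period)
    min_ov = config.closure_overlap
    merged: set[str] = set()
    for le in left_extensions:
        for re_ in right_extensions:
            merged |= _overlap_merges(le.sequence, re_.sequence, min_ov)
    if len(merged) == 1:
        return ClosureResult("closed", replacement_sequence=merged.pop())
    left_cons = consensus_extension(left_extensions)
    right_cons = consensus_extension(right_extensions)
    return ClosureResult("extended", left_extension=left_cons or None,
                         right_extension=right_cons or None)


# ---------------------------------------------------------------------------
# region resolution

@dataclass
class RegionResolution:
    """Outcome of reassembling one target: the closure result plus the
    concrete genome edit (if any), in input-genome coordinates."""

    region: SuspiciousRegion
    closure: ClosureResult
    source_start: int | None = None
    source_end: int | None = None
    source_sequence: str | None = None
    dest_sequence: str | None = None
    category: str | None = None          # gap_fill | gap_shrink | break_fix


def _find_seed(graph: KmerGraph, genome_seq: str, pos: int, k: int,
               direction: str, max_probe: int) -> tuple[str, int] | None:
    """Find a flank k-mer present in the graph, probing away from the
    region.  Returns (kmer, anchor_start) or None.

    ``direction`` "left": k-mers ending at or before ``pos`` (anchor is the
    last k flank bases); "right": k-mers starting at or after ``pos``.
    """
    for d in range(max_probe):
        if direction == "left":
            start = pos - k - d
            if start < 0:
                return None
        else:
            start = pos + d
            if start + k > len(genome_seq):
                return None
        kmer = genome_seq[start:start + k]
        if "N" in kmer:
            continue
        if kmer in graph:
            return kmer, start
    return None


def reassemble_region(region: SuspiciousRegion, genome: InputGenome,
                      index: AlignmentIndex, stats: list[LibraryStats],
                      config: Config) -> RegionResolution:
    """Run the full local-reassembly procedure for one target region.

    Captured gaps (trigger ``gap``) may be filled (closure) or shrunk
    (consensus extensions from each side, residual distance kept as N);
    other regions are replaced only on a unique closure, unless
    ``open_new_gaps`` allows replacing them by extensions around a new gap.
    """
    is_gap = "gap" in region.triggers
    seq = genome.sequences[region.scaffold]
    k = config.k
    read_len = max((s.read_length_mode for s in stats), default=100)
    reads = collect_reads_for_region(region, index, stats, config)
    res = RegionResolution(region, ClosureResult("no_solution"))
    if not reads:
        region.status = "no_solution"
        return res
    graph = build_graph(reads, config)
    max_probe = 2 * read_len
    left = _find_seed(graph, seq, region.start, k, "left", max_probe)
    right = _find_seed(graph, seq, region.end, k, "right", max_probe)

    left_exts: list[Extension] = []
    right_exts: list[Extension] = []
    left_anchor = right_anchor = None
    if left is not None:
        left_seed, left_anchor = left
        left_exts = walk_from_flank(graph, left_seed, config)
    if right is not None:
        right_seed_fwd, right_anchor = right
        rc_exts = walk_from_flank(graph, revcomp(right_seed_fwd), config)
        right_exts = [Extension(revcomp(e.sequence), e.branch_count,
                                e.terminated_by, e.loop_period,
                                list(reversed(e.step_weights)))
                      for e in rc_exts]

    if not left_exts and not right_exts:
        region.status = "no_solution"
        return res

    closure = attempt_closure(left_exts, right_exts, config)
    res.closure = closure

    if closure.outcome == "tandem_repeat":
        region.status = "tandem_repeat"
        region.tandem_period = closure.tandem_period
        return res

    if closure.outcome == "closed":
        src_start = left_anchor
        src_end = right_anchor + k
        source = seq[src_start:src_end]
        dest = closure.replacement_sequence
        assert "N" not in dest
        if dest == source:
            region.status = "fixed"   # contiguity confirmed, nothing to edit
            return res
        # trim the shared prefix/suffix down to the minimal edit
        a, b = 0, 0
        while a < min(len(source), len(dest)) and source[a] == dest[a]:
            a += 1
        while (b < min(len(source), len(dest)) - a
               and source[len(source) - 1 - b] == dest[len(dest) - 1 - b]):
            b += 1
        res.source_start = src_start + a
        res.source_end = src_end - b
        res.source_sequence = source[a:len(source) - b]
        res.dest_sequence = dest[a:len(dest) - b]
        res.category = "gap_fill" if is_gap else "break_fix"
        region.status = "fixed"
        return res

    # not closed: consensus extensions beyond the trusted flank bases the
    # walks respell
    left_new = ""
    right_new = ""
    if closure.left_extension and left_anchor is not None:
        flank_len = region.start - left_anchor
        left_new = closure.left_extension[flank_len:]
    if closure.right_extension and right_anchor is not None:
        flank_len = (right_anchor + k) - region.end
        right_new = (closure.right_extension[:-flank_len]
                     if flank_len else closure.right_extension)

    if is_gap:
        gap_len = region.end - region.start
        left_new = left_new[:gap_len]
        right_new = right_new[:gap_len]
        if not left_new and not right_new:
            region.status = "no_solution"
            return res
        residual = max(config.min_residual_gap,
                       gap_len - len(left_new) - len(right_new))
        res.source_start = region.start
        res.source_end = region.end
        res.source_sequence = seq[region.start:region.end]
        res.dest_sequence = left_new + "N" * residual + right_new
        res.category = "gap_shrink"
        region.status = "fixed"
        return res

    if config.open_new_gaps and (left_new or right_new):
        res.source_start = region.start
        res.source_end = region.end
        res.source_sequence = seq[region.start:region.end]
        res.dest_sequence = (left_new + "N" * config.min_residual_gap
                             + right_new)
        res.category = "break_fix"
        region.status = "fixed"
        return res

    region.status = "no_solution"
    return res


def fill_captured_gap(gap_region: SuspiciousRegion, genome: InputGenome,
                      index: AlignmentIndex, stats: list[LibraryStats],
                      config: Config) -> RegionResolution:
    """Fill or shrink a captured gap via local reassembly (the gap is the
    untrusted region)."""
    gap_region.triggers.add("gap")
    return reassemble_region(gap_region, genome, index, stats, config)
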