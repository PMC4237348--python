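"""Discontiguity scanning: find regions where the alignments contradict the
input genome's contiguity.

Four heuristics seed suspicious positions — pile-ups of soft-clip
boundaries, a high ratio of invalid to valid pairs, extremely low valid
coverage, and rapid coverage drops over roughly a read length — plus
clusters of Ambiguous base calls.  Nearby seeds merge into a single region
which is handed to the local reassembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_ingest import Gap, InputGenome, LibraryStats
from .config import Config
from .pileup import BaseClassification, Category, PileupTable


@dataclass
class SuspiciousRegion:
    scaffold: str
    start: int
    end: int
    triggers: set = field(default_factory=set)
    status: str = "pending"     # pending | fixed | no_solution | tandem_repeat
    tandem_period: int | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _edge_exclusion(stats: list[LibraryStats]) -> int:
    """Bases at each scaffold end excluded from coverage-based seeding.

    Coverage necessarily ramps down toward scaffold ends (templates must
    lie within the scaffold), so low-coverage and coverage-drop tests
    there would flag every terminus.
    """
    spans = [s.insert_mean for s in stats if s.insert_mean]
    return int(max(spans)) if spans else 200


def flag_suspicious_regions(pileups: PileupTable,
                            stats: list[LibraryStats],
                            config: Config,
                            classifications: dict[str, list[BaseClassification]] | None = None,
                            ) -> list[SuspiciousRegion]:
    """Apply the discontiguity heuristics to every scaffold.

    Seeded positions within one modal read length of each other merge into
    a single region, padded by ``flank_trim`` on each side.  Gap intervals
    themselves are excluded from seeding (they are reassembly targets in
    their own right) as are the terminal coverage ramps at scaffold ends.
    """
    genome = pileups.genome
    read_len = max((s.read_length_mode for s in stats), default=100)
    edge = _edge_exclusion(stats)
    regions: list[SuspiciousRegion] = []

    for name in genome.names:
        sp = pileups[name]
        L = sp.length
        if L == 0:
            continue
        total = sp.total_cov
        # columns deleted in spanning reads are still covered by them
        valid = (sp.valid_cov + sp.del_count).astype(np.float64)
        bad = sp.bad_cov
        clip = sp.clip_starts

        in_gap = np.zeros(L, dtype=bool)
        near_gap = np.zeros(L, dtype=bool)
        for g in genome.gaps[name]:
            in_gap[g.start:g.end] = True
            near_gap[max(0, g.start - read_len):min(L, g.end + read_len)] = True

        interior = np.ones(L, dtype=bool)
        interior[:min(edge, L)] = False
        interior[max(0, L - edge):] = False

        seeds: dict[int, set[str]] = {}

        def add(idx: np.ndarray, trigger: str) -> None:
            for i in np.flatnonzero(idx):
                seeds.setdefault(int(i), set()).add(trigger)

        # gap boundaries legitimately show clips, invalid pairs and coverage
        # artifacts; gaps are reassembly targets of their own, so none of
        # the heuristics seed near them
        not_gappy = ~near_gap

        # (i) soft-clip pile-ups
        clip_frac = clip / np.maximum(1, total)
        add((clip_frac >= config.clip_fraction_threshold)
            & (clip >= config.min_clip_count) & not_gappy, "clip")

        # (ii) invalid:valid pair ratio
        ratio = bad / np.maximum(1, valid)
        add((ratio >= config.invalid_ratio_threshold)
            & (bad >= config.min_clip_count) & not_gappy, "invalid_pairs")

        # (iii) extremely low coverage (vs. scaffold mean over non-gap bases)
        mask = ~in_gap & ~near_gap & interior
        if mask.any():
            scaffold_mean = float(valid[~in_gap].mean())
            add((valid < config.low_coverage_fraction * scaffold_mean) & mask,
                "low_coverage")

            # (iv) rapid coverage drop within about one read length: the
            # mean over the next read-length window falls to below half the
            # mean over the previous one (window means rather than single
            # positions, so sampling noise cannot fake a cliff)
            if L > 2 * read_len:
                csum = np.concatenate(([0.0], np.cumsum(valid)))
                wmean = (csum[read_len:] - csum[:-read_len]) / read_len
                # wmean[i] = mean over [i, i+read_len)
                behind = wmean[:-read_len]
                ahead = wmean[read_len:]
                lo = np.minimum(behind, ahead)
                hi = np.maximum(behind, ahead)
                edge = ((hi - lo) >= config.coverage_drop_fraction * hi) \
                    & (hi >= 0.5 * scaffold_mean)
                drop = np.zeros(L, dtype=bool)
                drop[read_len:read_len + len(edge)] = edge
                add(drop & mask, "coverage_drop")

        # clusters of Ambiguous calls (block substitutions reassemble better
        # than they patch base-by-base)
        if classifications is not None and not_gappy.any():
            amb = np.fromiter(
                (c.category is Category.AMBIGUOUS for c in classifications[name]),
                dtype=bool, count=L)
            span = config.ambiguous_cluster_span
            if amb.any() and L > span:
                csum = np.concatenate(([0], np.cumsum(amb)))
                window = csum[span:] - csum[:-span]
                hot = np.zeros(L, dtype=bool)
                hits = np.flatnonzero(window >= config.ambiguous_cluster_count)
                for i in hits:
                    hot[i:i + span] = True
                add(hot & amb & not_gappy, "ambiguous_cluster")

        # merge nearby seeds into regions
        if not seeds:
            continue
        positions = sorted(seeds)
        cur_start = cur_end = positions[0]
        cur_triggers = set(seeds[positions[0]])
        for p in positions[1:]:
            if p - cur_end <= read_len:
                cur_end = p
                cur_triggers |= seeds[p]
            else:
                regions.append(_make_region(name, cur_start, cur_end,
                                            cur_triggers, config, L))
                cur_start = cur_end = p
                cur_triggers = set(seeds[p])
        regions.append(_make_region(name, cur_start, cur_end, cur_triggers,
                                    config, L))
    return regions


def _make_region(name: str, start: int, end: int, triggers: set,
                 config: Config, L: int) -> SuspiciousRegion:
    lo = max(0, start - config.flank_trim)
    hi = min(L, end + 1 + config.flank_trim)
    return SuspiciousRegion(name, lo, hi, triggers)


def enumerate_reassembly_targets(regions: list[SuspiciousRegion],
                                 genome: InputGenome,
                                 gap_pad: int = 0) -> list[SuspiciousRegion]:
    """Deduplicated, ordered work list for the reassembler.

    Flagged regions that overlap each other merge (union of triggers).
    Captured gaps are appended as targets with trigger ``gap``, keeping
    exactly the N-run interval (the shrink arithmetic depends on it);
    flagged regions within ``gap_pad`` of a gap are dropped as echoes of
    the gap itself.  Ordering is deterministic: (scaffold, start).
    """
    order = {name: i for i, name in enumerate(genome.names)}
    flagged = sorted((SuspiciousRegion(r.scaffold, r.start, r.end,
                                       set(r.triggers)) for r in regions),
                     key=lambda r: (order[r.scaffold], r.start, r.end))
    merged: list[SuspiciousRegion] = []
    for r in flagged:
        if merged and merged[-1].scaffold == r.scaffold \
                and r.start <= merged[-1].end:
            merged[-1].end = max(merged[-1].end, r.end)
            merged[-1].triggers |= r.triggers
        else:
            merged.append(r)
    gaps = genome.captured_gaps()
    out: list[SuspiciousRegion] = []
    for r in merged:
        if any(g.scaffold == r.scaffold and r.start < g.end + gap_pad
               and r.end > g.start - gap_pad for g in gaps):
            continue
        out.append(r)
    for g in gaps:
        out.append(SuspiciousRegion(g.scaffold, g.start, g.end, {"gap"}))
    out.sort(key=lambda r: (order[r.scaffold], r.start, r.end))
    return out
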