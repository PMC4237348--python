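"""Large collapsed-repeat / segmental-duplication detection.

Scans windowed valid coverage from fragment and unpaired libraries
(long-insert coverage is excluded as too variable) for long contiguous
runs at roughly double the scaffold's baseline coverage.  Flagged regions
are reported, never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config
from .pileup import PileupTable


@dataclass
class DuplicationRegion:
    scaffold: str
    start: int
    end: int
    mean_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_large_duplications(pileups: PileupTable,
                              config: Config) -> list[DuplicationRegion]:
    """Report runs of doubled coverage longer than ``dup_min_length``.

    Coverage is averaged over ``dup_window``-base windows and compared to
    the per-scaffold median window coverage (the baseline).  A window
    extends a run when its ratio is in
    ``[dup_coverage_ratio, dup_break_ratio)``; windows at or above
    ``dup_break_ratio`` look like short high-copy elements (IS elements and
    the like) and interrupt a run instead of extending it, so a true
    duplication containing one is reported as two pieces.  Ratios make the
    detector invariant to uniform coverage scaling.
    """
    out: list[DuplicationRegion] = []
    w = config.dup_window
    for name in pileups.genome.names:
        sp = pileups[name]
        L = sp.length
        n_win = L // w
        if n_win < 1:
            continue
        cov = sp.frag_valid_cov[:n_win * w].astype(np.float64)
        win = cov.reshape(n_win, w).mean(axis=1)
        baseline = float(np.median(win))
        if baseline <= 0:
            continue
        ratio = win / baseline
        # two-threshold segmentation: a run extends through windows at
        # >= dup_extend_ratio (tolerating sampling dips) but is reported
        # only when its mean reaches dup_coverage_ratio
        dup = (ratio >= config.dup_extend_ratio) & \
              (ratio < config.dup_break_ratio)
        i = 0
        while i < n_win:
            if not dup[i]:
                i += 1
                continue
            j = i
            while j < n_win and dup[j]:
                j += 1
            length = (j - i) * w
            mean_ratio = float(ratio[i:j].mean())
            if length > config.dup_min_length \
                    and mean_ratio >= config.dup_coverage_ratio:
                out.append(DuplicationRegion(name, i * w, j * w, mean_ratio))
            i = j
    return out
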