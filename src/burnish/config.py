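"""Shared configuration for the polishing pipeline.

Every tunable of the pipeline lives here so that the CLI, the library API
and the tests agree on a single source of defaults.  Thresholds that gate
evidence (the ``*_fraction`` values) are fractions in (0, 1]; lengths are in
bases; qualities are Phred-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Config:
    """Tunables for pileup classification, reassembly and reporting.

    Attributes
    ----------
    k:
        K-mer size for local reassembly.  The closure overlap requirement is
        derived from it (``2k + 1``), so with the default ``k=47`` a
        flank-to-flank closure needs a 95-base perfect overlap.
    min_link_coverage:
        Minimum read support for a forward link in the reassembly graph;
        links below this are pruned as likely sequencing error.
    branch_limit:
        Maximum number of branch points a single assembly walk may traverse
        (at most ``2**branch_limit`` extensions per flank).
    flank_trim:
        Bases ignored at each end of a read when accumulating allele
        evidence; alignments are least trustworthy near read ends.
    min_depth:
        Floor on valid-read depth below which a position is Unconfirmed.
        The pipeline raises this to ``0.1 x mean coverage`` when coverage is
        high (see :meth:`effective_min_depth`).
    changed_fraction:
        Weight fraction the top allele must reach for a Confirmed/Changed
        call ("the vast majority of evidence").
    ambiguous_fraction:
        Weight fraction at which a second allele makes the position
        Ambiguous.
    long_indel_fraction / long_indel_length:
        Indels longer than ``long_indel_length`` are called at the relaxed
        ``long_indel_fraction`` support threshold instead of a strict
        majority, since aligners under-report long indels.
    clip_fraction_threshold:
        Fraction of covering reads with a soft-clip boundary at a position
        that flags it as a candidate breakpoint.
    invalid_ratio_threshold:
        Ratio of invalid-pair to valid-pair coverage that flags a position.
    low_coverage_fraction:
        Positions with valid coverage below this fraction of the scaffold
        mean are flagged.
    coverage_drop_fraction:
        A drop of at least this fraction of coverage within one read length
        flags a position.
    dup_window / dup_min_length / dup_coverage_ratio / dup_break_ratio:
        Collapsed-repeat scan: window size, minimum reported run length,
        coverage ratio (vs. scaffold baseline) that marks a window as
        doubled, and the ratio above which a window is treated as a
        high-copy element that interrupts a doubled run rather than
        extending it.
    fix_ambiguous:
        When on, Ambiguous positions are rewritten to the top-weight allele
        (off by default).
    open_new_gaps:
        When on, unresolved suspicious regions are replaced by flank
        consensus extensions separated by new N gaps.
    fasta_line_width:
        Line width of emitted FASTA (fixed so output is byte-reproducible).
    """

    k: int = 47
    min_link_coverage: int = 5
    branch_limit: int = 5
    flank_trim: int = 5
    min_depth: int = 5
    changed_fraction: float = 0.75
    ambiguous_fraction: float = 0.25
    long_indel_fraction: float = 0.35
    long_indel_length: int = 10
    clip_fraction_threshold: float = 0.33
    min_clip_count: int = 5
    invalid_ratio_threshold: float = 1.0
    low_coverage_fraction: float = 0.20
    coverage_drop_fraction: float = 0.50
    dup_window: int = 1000
    dup_min_length: int = 10000
    dup_coverage_ratio: float = 1.8
    dup_extend_ratio: float = 1.5
    dup_break_ratio: float = 4.0
    ambiguous_cluster_count: int = 3
    ambiguous_cluster_span: int = 50
    fix_ambiguous: bool = False
    open_new_gaps: bool = False
    min_residual_gap: int = 10
    max_qual: float = 2000.0
    fasta_line_width: int = 70
    fix: frozenset = field(default_factory=lambda: frozenset({"bases", "gaps", "local"}))

    @property
    def closure_overlap(self) -> int:
        """Minimum perfect overlap (bases) required to close a region: 2k+1."""
        return 2 * self.k + 1

    def effective_min_depth(self, mean_coverage: float) -> int:
        """Valid-read depth below which a base is Unconfirmed.

        Scales with coverage (10% of the mean) but never drops below
        ``min_depth`` so sparse data cannot confirm bases on a handful of
        reads.
        """
        return max(self.min_depth, int(round(0.1 * mean_coverage)))

    def __post_init__(self) -> None:
        for name in ("changed_fraction", "ambiguous_fraction",
                     "long_indel_fraction", "clip_fraction_threshold",
                     "low_coverage_fraction", "coverage_drop_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
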