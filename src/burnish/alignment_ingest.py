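"""Genome and alignment ingestion.

Loads the input genome (FASTA), derives captured-gap intervals from N-runs,
streams SAM/BAM alignments into a normalized internal record, and computes
per-library statistics (insert size distribution, modal read length, mean
coverage) from proper pairs.

Coordinates are 0-based half-open throughout the package; 1-based
conventions appear only at serialization boundaries (VCF, wig, changes
file).
"""

from __future__ import annotations

import logging
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

log = logging.getLogger("burnish")

_N_RUN = re.compile(r"N+")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class LibraryKind(str, Enum):
    FRAGMENT = "fragment"
    LONG_INSERT = "long_insert"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class LibrarySpec:
    """Designation of an alignment file: fragment (short-insert FR pairs),
    long-insert (FR after any caller-side reorientation, >1 Kbp), or
    unpaired."""

    kind: LibraryKind
    name: str = ""

    @property
    def expected_orientation(self) -> str:
        return "none" if self.kind is LibraryKind.UNPAIRED else "FR"

    @property
    def paired(self) -> bool:
        return self.kind is not LibraryKind.UNPAIRED


@dataclass
class LibraryStats:
    """Per-library summary computed from the alignments.

    Insert statistics are over proper pairs only (absolute template length,
    counted once per pair on the leftmost record); the standard deviation is
    the population sd for determinism. ``insert_mean``/``insert_sd`` are
    ``None`` for unpaired libraries.
    """

    library: LibrarySpec
    insert_mean: float | None
    insert_sd: float | None
    read_length_mode: int
    mean_coverage: float
    n_records: int = 0
    n_proper_pairs: int = 0


@dataclass
class Gap:
    """A maximal N-run. Captured gaps have assembled flanks on both sides
    (i.e. the run touches neither scaffold end)."""

    scaffold: str
    start: int
    end: int
    captured: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InputGenome:
    """Scaffold sequences over {A,C,G,T,N} with derived gap intervals."""

    names: list[str]
    sequences: dict[str, str]
    gaps: dict[str, list[Gap]]

    def __len__(self) -> int:
        return len(self.names)

    def scaffold_length(self, name: str) -> int:
        return len(self.sequences[name])

    def non_n_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.sequences.values())

    def captured_gaps(self) -> list[Gap]:
        return [g for gaps in self.gaps.values() for g in gaps if g.captured]


@dataclass
class AlignmentRecord:
    """A mapped alignment in internal form.

    ``cigar`` uses pysam operation codes (0=M, 1=I, 2=D, 4=S, 7==, 8=X);
    only query- or reference-consuming operations are retained.
    """

    query_name: str
    scaffold: str
    start: int
    cigar: list[tuple[int, int]]
    mapping_quality: int
    bases: str
    base_qualities: Sequence[int]
    is_paired: bool
    is_proper_pair: bool
    is_reverse: bool
    is_read1: bool
    mate_unmapped: bool
    mate_scaffold: str | None
    mate_start: int | None
    template_length: int
    library: LibrarySpec

    @property
    def end(self) -> int:
        """Reference end (half-open)."""
        return self.start + sum(l for op, l in self.cigar if op in (0, 2, 7, 8))

    @property
    def valid(self) -> bool:
        """Whether this read contributes allele evidence: unpaired-library
        reads always do, paired reads only when the aligner flagged the pair
        proper."""
        if not self.library.paired:
            return True
        return self.is_proper_pair


@dataclass
class UnmappedRead:
    """An unmapped record retained for local reassembly (its sequence may
    still carry evidence for a region its mate anchors)."""

    query_name: str
    is_read1: bool
    bases: str
    base_qualities: list
    library: LibrarySpec


def find_gaps(name: str, sequence: str) -> list[Gap]:
    """Maximal N-runs of ``sequence`` as sorted, non-overlapping gaps."""
    gaps = []
    n = len(sequence)
    for m in _N_RUN.finditer(sequence):
        captured = m.start() > 0 and m.end() < n
        gaps.append(Gap(name, m.start(), m.end(), captured))
    return gaps


def load_genome(path: str) -> InputGenome:
    """Load a FASTA genome.

    Sequences are uppercased; characters outside {A,C,G,T,N} (lowercase
    is handled by the uppercasing; IUPAC ambiguity codes are not) are mapped
    to N with a warning.  Duplicate scaffold names and empty files are
    fatal.
    """
    names: list[str] = []
    sequences: dict[str, str] = {}
    gaps: dict[str, list[Gap]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate scaffold name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            log.warning("%s: %d non-ACGTN characters in %s mapped to N",
                        path, n_bad, rec.id)
            seq = _NON_ACGTN.sub("N", seq)
        names.append(rec.id)
        sequences[rec.id] = seq
        gaps[rec.id] = find_gaps(rec.id, seq)
    if not names:
        raise ValueError(f"no sequences found in {path}")
    return InputGenome(names, sequences, gaps)


def read_alignments(path: str, library: LibrarySpec,
                    genome: InputGenome
                    ) -> tuple[list[AlignmentRecord], list[UnmappedRead]]:
    """Read a SAM/BAM file into normalized records.

    Secondary, supplementary, duplicate-flagged and QC-fail records are
    dropped entirely so each template is counted once.  Unmapped records
    contribute no pileup evidence but their sequences are kept (second
    return value) for local reassembly.  Records aligned beyond scaffold
    bounds are skipped with a warning.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    out: list[AlignmentRecord] = []
    unmapped: list[UnmappedRead] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary or a.is_duplicate \
                    or a.is_qcfail:
                continue
            if a.is_unmapped:
                unmapped.append(UnmappedRead(
                    a.query_name, not a.is_paired or a.is_read1,
                    a.query_sequence or "",
                    list(a.query_qualities or []), library))
                continue
            ref = a.reference_name
            if ref not in genome.sequences:
                log.warning("alignment %s references unknown scaffold %s; skipped",
                            a.query_name, ref)
                continue
            cigar = [(op, l) for op, l in (a.cigartuples or [])
                     if op in (0, 1, 2, 4, 7, 8)]
            rec = AlignmentRecord(
                query_name=a.query_name,
                scaffold=ref,
                start=a.reference_start,
                cigar=cigar,
                mapping_quality=a.mapping_quality,
                bases=a.query_sequence or "",
                base_qualities=list(a.query_qualities or []),
                is_paired=a.is_paired,
                is_proper_pair=a.is_paired and a.is_proper_pair,
                is_reverse=a.is_reverse,
                is_read1=not a.is_paired or a.is_read1,
                mate_unmapped=a.is_paired and a.mate_is_unmapped,
                mate_scaffold=(a.next_reference_name
                               if a.is_paired and not a.mate_is_unmapped else None),
                mate_start=(a.next_reference_start
                            if a.is_paired and not a.mate_is_unmapped else None),
                template_length=a.template_length,
                library=library,
            )
            if rec.end > genome.scaffold_length(ref):
                log.warning("alignment %s extends past end of %s; skipped",
                            rec.query_name, ref)
                continue
            out.append(rec)
    order = {name: i for i, name in enumerate(genome.names)}
    out.sort(key=lambda r: (order[r.scaffold], r.start))
    return out, unmapped


def scan_library_stats(alignments: Iterable[AlignmentRecord],
                       library: LibrarySpec,
                       genome: InputGenome) -> LibraryStats:
    """Compute insert-size and coverage statistics for one library.

    Insert mean/sd use the absolute template length of proper pairs,
    counted once per pair (leftmost record, positive TLEN).  Mean coverage
    is total aligned bases divided by the genome's non-N length.
    A paired library with zero proper pairs is fatal: it indicates the
    aligner never set the PROPER_PAIR flag, which this tool relies on.
    """
    inserts: list[int] = []
    lengths: Counter[int] = Counter()
    aligned_bases = 0
    n_records = 0
    for rec in alignments:
        n_records += 1
        lengths[len(rec.bases)] += 1
        aligned_bases += sum(l for op, l in rec.cigar if op in (0, 7, 8))
        if rec.is_proper_pair and rec.template_length > 0:
            inserts.append(rec.template_length)
    if n_records == 0:
        raise ValueError(f"library {library.name or library.kind}: no usable alignments")
    mean_cov = aligned_bases / max(1, genome.non_n_length())
    mode_len = lengths.most_common(1)[0][0]
    if not library.paired:
        return LibraryStats(library, None, None, mode_len, mean_cov,
                            n_records, 0)
    if not inserts:
        raise ValueError(
            f"paired library {library.name or library.kind.value} has no proper "
            f"pairs; check that the aligner set the PROPER_PAIR flag")
    mean = statistics.fmean(inserts)
    sd = statistics.pstdev(inserts)
    return LibraryStats(library, mean, sd, mode_len, mean_cov,
                        n_records, len(inserts))


def validate_inputs(stats: Sequence[LibraryStats],
                    min_read_length: int = 75,
                    min_coverage: float = 50.0) -> list[str]:
    """Advisory checks on the input data.

    Defaults are tuned for reads of >=75 bases and total coverage of >=50x;
    shorter reads or thinner coverage produce warnings, not errors.
    """
    warnings: list[str] = []
    for s in stats:
        if s.read_length_mode < min_read_length:
            warnings.append(
                f"library {s.library.name or s.library.kind.value}: modal read "
                f"length {s.read_length_mode} < {min_read_length}")
    total = sum(s.mean_coverage for s in stats)
    if total < min_coverage:
        warnings.append(f"total coverage {total:.1f}x < {min_coverage:.0f}x")
    for w in warnings:
        log.warning("%s", w)
    return warnings
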