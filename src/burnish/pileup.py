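"""Quality-weighted pileups and per-base classification.

Every genome position accumulates, from valid reads only, a weighted tally
of the four alleles plus deletion evidence; separate counters track total
coverage, invalid-pair coverage, soft-clip boundaries and physical
(template) coverage.  From these tallies each base is classified as
Confirmed, Changed, Ambiguous or Unconfirmed.

A read's evidence weight is ``base_quality * (1 - 10^(-MQ/10))``: the base
quality scaled by the probability that the mapping is correct, so MQ0 reads
(placeable anywhere) contribute nothing while their better-anchored mates
can dominate — this is what lets long-insert pairs resolve repeat content.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import log10
from typing import Iterable, Sequence

import numpy as np

from .alignment_ingest import AlignmentRecord, InputGenome, LibraryKind
from .config import Config

ALLELES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALLELES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def read_weight(base_quality: float, mapping_quality: float) -> float:
    """Evidence weight of one read base.

    Monotone nondecreasing in both qualities; zero when either the base
    quality is zero or the mapping quality is zero (an MQ0 placement is as
    likely wrong as right, so it carries no allele evidence).
    """
    return base_quality * (1.0 - 10.0 ** (-mapping_quality / 10.0))


def mapping_factor(mapping_quality: float) -> float:
    """Probability the mapping is correct: ``1 - 10^(-MQ/10)``."""
    return 1.0 - 10.0 ** (-mapping_quality / 10.0)


@dataclass
class RawIndelObservation:
    """An indel seen in one read alignment, before left-normalization."""

    scaffold: str
    position: int          # reference coordinate (leftmost base of deletion,
                           # or insertion point) as reported by the alignment
    kind: str              # "insertion" | "deletion"
    sequence: str
    query_name: str
    weight: float


class ScaffoldPileup:
    """Per-position evidence arrays for one scaffold (all numpy, length L)."""

    __slots__ = ("length", "weights", "counts", "del_weight", "del_count",
                 "valid_cov", "total_cov", "bad_cov", "clip_starts",
                 "phys_cov", "frag_valid_cov")

    def __init__(self, length: int):
        self.length = length
        self.weights = np.zeros((length, 4), dtype=np.float64)
        self.counts = np.zeros((length, 4), dtype=np.int32)
        self.del_weight = np.zeros(length, dtype=np.float64)
        self.del_count = np.zeros(length, dtype=np.int32)
        self.valid_cov = np.zeros(length, dtype=np.int32)
        self.total_cov = np.zeros(length, dtype=np.int32)
        self.bad_cov = np.zeros(length, dtype=np.int32)
        self.clip_starts = np.zeros(length, dtype=np.int32)
        self.phys_cov = np.zeros(length, dtype=np.int32)
        # valid coverage from fragment + unpaired libraries only; the
        # duplication detector excludes long-insert data.
        self.frag_valid_cov = np.zeros(length, dtype=np.int32)


class PileupTable:
    """Pileups for every scaffold plus the raw indel observations."""

    def __init__(self, genome: InputGenome):
        self.genome = genome
        self.scaffolds: dict[str, ScaffoldPileup] = {
            name: ScaffoldPileup(len(genome.sequences[name]))
            for name in genome.names
        }
        self.indels: list[RawIndelObservation] = []

    def __getitem__(self, name: str) -> ScaffoldPileup:
        return self.scaffolds[name]


def accumulate_pileups(genome: InputGenome,
                       alignments: Iterable[AlignmentRecord],
                       config: Config) -> PileupTable:
    """Accumulate the evidence of every alignment into per-position arrays.

    Valid reads (proper pairs, or any read from an unpaired library)
    contribute allele weights for their aligned, non-clipped bases outside
    the ``flank_trim`` read-end margin; end-trimmed bases still count toward
    valid coverage but not toward allele evidence.  Reads failing validity
    contribute only to ``bad_cov`` and ``total_cov``.  Soft-clip boundaries
    increment ``clip_starts`` at the clip/match transition coordinate.
    Proper-pair templates add physical coverage over their full span.
    """
    table = PileupTable(genome)
    trim = config.flank_trim
    for rec in alignments:
        sp = table[rec.scaffold]
        L = sp.length
        mapfac = mapping_factor(rec.mapping_quality)
        quals = np.asarray(rec.base_qualities, dtype=np.float64)
        codes = _BASE_CODE[np.frombuffer(rec.bases.encode("ascii"),
                                         dtype=np.uint8)]
        rlen = len(rec.bases)
        valid = rec.valid
        is_frag = rec.library.kind is not LibraryKind.LONG_INSERT

        qpos = 0
        rpos = rec.start
        n_ops = len(rec.cigar)
        for i, (op, l) in enumerate(rec.cigar):
            if op in (0, 7, 8):          # aligned bases
                lo, hi = rpos, min(rpos + l, L)
                span = hi - lo
                sp.total_cov[lo:hi] += 1
                if valid:
                    sp.valid_cov[lo:hi] += 1
                    if is_frag:
                        sp.frag_valid_cov[lo:hi] += 1
                    # allele evidence only for non-end-trimmed bases
                    q0 = qpos
                    sel = np.arange(span)
                    keep = ((sel + q0 >= trim) & (sel + q0 < rlen - trim)
                            & (codes[q0:q0 + span] >= 0))
                    if keep.any():
                        ref_idx = lo + sel[keep]
                        base_idx = codes[q0 + sel[keep]]
                        w = quals[q0 + sel[keep]] * mapfac
                        np.add.at(sp.weights, (ref_idx, base_idx), w)
                        np.add.at(sp.counts, (ref_idx, base_idx), 1)
                else:
                    sp.bad_cov[lo:hi] += 1
                qpos += l
                rpos += l
            elif op == 1:                # insertion to the reference
                if valid and trim <= qpos and qpos + l <= rlen - trim:
                    w = float(quals[qpos:qpos + l].mean()) * mapfac
                    table.indels.append(RawIndelObservation(
                        rec.scaffold, rpos, "insertion",
                        rec.bases[qpos:qpos + l], rec.query_name, w))
                qpos += l
            elif op == 2:                # deletion from the reference
                lo, hi = rpos, min(rpos + l, L)
                if valid:
                    q_adj = max(0, min(qpos - 1, rlen - 1))
                    w = float(quals[q_adj]) * mapfac
                    sp.del_weight[lo:hi] += w
                    sp.del_count[lo:hi] += 1
                    if trim <= qpos <= rlen - trim:
                        table.indels.append(RawIndelObservation(
                            rec.scaffold, rpos, "deletion",
                            genome.sequences[rec.scaffold][rpos:rpos + l],
                            rec.query_name, w))
                rpos += l
            elif op == 4:                # soft clip: boundary at transition
                if valid:
                    coord = min(rpos, L - 1)
                    sp.clip_starts[coord] += 1
                qpos += l

        # physical coverage: count each proper template once, via the
        # leftmost record (positive template length)
        if rec.is_proper_pair and rec.template_length > 0:
            lo = rec.start
            hi = min(rec.start + rec.template_length, L)
            if hi > lo:
                sp.phys_cov[lo:hi] += 1
    return table


class Category(str, Enum):
    CONFIRMED = "Confirmed"
    CHANGED = "Changed"
    AMBIGUOUS = "Ambiguous"
    UNCONFIRMED = "Unconfirmed"


@dataclass
class BaseClassification:
    category: Category
    called_allele: str | None
    qual: float
    qd: float


def _phred_ratio(top: float, rest: float, cap: float) -> float:
    return min(cap, 100.0 * log10((1.0 + top) / (1.0 + rest)))


def classify_base(genome_base: str, weights: Sequence[float],
                  valid_coverage: int, config: Config,
                  min_depth: int | None = None) -> BaseClassification:
    """Classify one genome position from its allele weights.

    Unconfirmed when valid coverage is below the depth floor or no weighted
    evidence exists; Changed when the top allele differs from the genome
    base and carries at least ``changed_fraction`` of the weight; Ambiguous
    when a second allele reaches ``ambiguous_fraction`` (or no allele
    dominates, including exact ties); Confirmed when the genome base itself
    dominates.
    """
    if min_depth is None:
        min_depth = config.min_depth
    w = [float(x) for x in weights]
    total = sum(w)
    if valid_coverage < min_depth or total <= 0.0:
        return BaseClassification(Category.UNCONFIRMED, None, 0.0, 0.0)
    order = sorted(range(4), key=lambda i: w[i], reverse=True)
    top, second = order[0], order[1]
    f_top = w[top] / total
    f_second = w[second] / total
    qual = _phred_ratio(w[top], total - w[top], config.max_qual)
    qd = qual / valid_coverage if valid_coverage else 0.0
    top_allele = ALLELES[top]
    if f_second >= config.ambiguous_fraction or w[top] == w[second]:
        return BaseClassification(Category.AMBIGUOUS, top_allele, qual, qd)
    if top_allele == genome_base:
        if f_top >= config.changed_fraction:
            return BaseClassification(Category.CONFIRMED, top_allele, qual, qd)
        return BaseClassification(Category.AMBIGUOUS, top_allele, qual, qd)
    if f_top >= config.changed_fraction:
        return BaseClassification(Category.CHANGED, top_allele, qual, qd)
    return BaseClassification(Category.AMBIGUOUS, top_allele, qual, qd)


def classify_scaffold(genome: InputGenome, name: str, pile: ScaffoldPileup,
                      config: Config,
                      min_depth: int | None = None) -> list[BaseClassification]:
    """Classify every position of one scaffold (N positions are Unconfirmed)."""
    seq = genome.sequences[name]
    out: list[BaseClassification] = []
    unconf = BaseClassification(Category.UNCONFIRMED, None, 0.0, 0.0)
    weights = pile.weights
    vc = pile.valid_cov
    for i, base in enumerate(seq):
        if base == "N":
            out.append(unconf)
            continue
        out.append(classify_base(base, weights[i], int(vc[i]), config,
                                 min_depth))
    return out
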