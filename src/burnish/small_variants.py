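"""Small-variant calling: SNPs from base classifications, indels from
left-normalized alignment observations.

Equivalent indel placements (a C deleted anywhere in a CCCC homopolymer,
say) are shifted to their leftmost coordinate so the evidence from every
read combines into a single event, which is then called when a majority of
the valid reads at the site support it (a relaxed threshold applies to
longer events, which aligners under-report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10

import numpy as np

from .alignment_ingest import InputGenome
from .config import Config
from .pileup import (BaseClassification, Category, PileupTable,
                     RawIndelObservation)


@dataclass
class IndelObservation:
    """A left-normalized indel event with its pooled read support."""

    scaffold: str
    position: int
    kind: str                   # "insertion" | "deletion"
    sequence: str
    support_count: int = 0
    support_weight: float = 0.0
    readnames: set = field(default_factory=set)


@dataclass
class SmallVariantCall:
    scaffold: str
    position: int               # 0-based; for indels, the event coordinate
    ref_allele: str
    alt_allele: str
    kind: str                   # "snp" | "insertion" | "deletion"
    qual: float
    qd: float


def normalize_indel_left(genome: InputGenome, scaffold: str, position: int,
                         kind: str, sequence: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    Two placements are equivalent when applying them yields the same edited
    sequence.  A deletion of ``genome[p:p+L]`` can shift one base left
    whenever ``genome[p-1] == genome[p+L-1]``; an insertion of ``S`` before
    position ``p`` can shift left whenever ``genome[p-1] == S[-1]`` (the
    inserted string rotates as it moves).  The result is idempotent and the
    edited genome string is unchanged.
    """
    seq = genome.sequences[scaffold]
    if not sequence:
        raise ValueError("empty indel sequence")
    if kind == "deletion":
        L = len(sequence)
        if position + L > len(seq):
            raise ValueError("deletion extends past scaffold end")
        if seq[position:position + L] != sequence:
            raise ValueError("deletion sequence does not match genome")
        p = position
        while p > 0 and seq[p - 1] == seq[p + L - 1]:
            p -= 1
        return p, seq[p:p + L]
    elif kind == "insertion":
        p, s = position, sequence
        while p > 0 and seq[p - 1] == s[-1]:
            s = s[-1] + s[:-1]
            p -= 1
        return p, s
    raise ValueError(f"unknown indel kind {kind!r}")


def tally_indels(observations: list[RawIndelObservation],
                 genome: InputGenome) -> dict[tuple, IndelObservation]:
    """Normalize raw per-read indel observations and merge equivalents.

    Support counts distinct contributing reads, so a read that reports the
    same event twice (or mates sharing a name) is counted once.
    """
    tally: dict[tuple, IndelObservation] = {}
    for raw in observations:
        try:
            pos, seq = normalize_indel_left(genome, raw.scaffold,
                                            raw.position, raw.kind,
                                            raw.sequence)
        except ValueError:
            continue
        key = (raw.scaffold, pos, raw.kind, seq)
        obs = tally.get(key)
        if obs is None:
            obs = IndelObservation(raw.scaffold, pos, raw.kind, seq)
            tally[key] = obs
        if raw.query_name not in obs.readnames:
            obs.readnames.add(raw.query_name)
            obs.support_count += 1
            obs.support_weight += raw.weight
    return tally


def _local_valid_coverage(pileups: PileupTable, obs: IndelObservation) -> float:
    """Mean valid coverage over the event's reference footprint (the
    flanking base for insertions, which occupy no reference column)."""
    sp = pileups[obs.scaffold]
    if obs.kind == "deletion":
        # reads carrying the deletion have no aligned base in the deleted
        # columns, so spanning-read coverage is valid + deletion count
        lo, hi = obs.position, min(obs.position + len(obs.sequence), sp.length)
        if hi <= lo:
            return 0.0
        return float(np.mean(sp.valid_cov[lo:hi] + sp.del_count[lo:hi]))
    p = min(obs.position, sp.length - 1)
    return float(sp.valid_cov[p])


def call_small_indels(tally: dict[tuple, IndelObservation],
                      pileups: PileupTable,
                      config: Config) -> list[SmallVariantCall]:
    """Call indels supported by a majority of local valid reads.

    Events no longer than ``long_indel_length`` need support from at least
    half the local valid coverage; longer events need only
    ``long_indel_fraction``.
    """
    genome = pileups.genome
    calls: list[SmallVariantCall] = []
    for obs in tally.values():
        cov = _local_valid_coverage(pileups, obs)
        if cov <= 0:
            continue
        length = len(obs.sequence)
        threshold = (0.5 if length <= config.long_indel_length
                     else config.long_indel_fraction)
        frac = obs.support_count / cov
        if frac < threshold:
            continue
        seq = genome.sequences[obs.scaffold]
        # VCF-style anchor base: the base before the event
        anchor_pos = obs.position - 1
        if anchor_pos < 0:
            continue  # event at scaffold start cannot be anchored
        anchor = seq[anchor_pos]
        if anchor == "N":
            continue
        other = max(0.0, cov - obs.support_count)
        qual = min(config.max_qual,
                   100.0 * log10((1.0 + obs.support_weight)
                                 / (1.0 + other)))
        qual = max(qual, 0.0)
        qd = qual / cov
        if obs.kind == "deletion":
            ref = anchor + obs.sequence
            alt = anchor
            calls.append(SmallVariantCall(obs.scaffold, anchor_pos, ref, alt,
                                          "deletion", qual, qd))
        else:
            ref = anchor
            alt = anchor + obs.sequence
            calls.append(SmallVariantCall(obs.scaffold, anchor_pos, ref, alt,
                                          "insertion", qual, qd))
    calls.sort(key=lambda c: (c.scaffold, c.position))
    return calls


@dataclass
class BaseFix:
    """A single-base correction to apply to the output genome."""

    scaffold: str
    position: int
    ref: str
    alt: str
    ambiguous: bool = False


def call_snps(genome: InputGenome,
              classifications: dict[str, list[BaseClassification]],
              config: Config) -> tuple[list[SmallVariantCall], list[BaseFix]]:
    """Turn per-base classifications into SNP calls and base fixes.

    Every Changed position yields both a fix and a call.  Ambiguous
    positions yield fixes only when ``fix_ambiguous`` is on (choosing the
    top-weight allele); they are always available to the VCF writer via the
    classification table.
    """
    calls: list[SmallVariantCall] = []
    fixes: list[BaseFix] = []
    for name in genome.names:
        seq = genome.sequences[name]
        for pos, cls in enumerate(classifications[name]):
            if cls.category is Category.CHANGED:
                calls.append(SmallVariantCall(name, pos, seq[pos],
                                              cls.called_allele, "snp",
                                              cls.qual, cls.qd))
                fixes.append(BaseFix(name, pos, seq[pos], cls.called_allele))
            elif (cls.category is Category.AMBIGUOUS and config.fix_ambiguous
                  and cls.called_allele and cls.called_allele != seq[pos]):
                fixes.append(BaseFix(name, pos, seq[pos], cls.called_allele,
                                     ambiguous=True))
    return calls, fixes
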