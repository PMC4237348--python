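"""Output generation: apply accepted edits to the genome and serialize the
polished FASTA, VCF, changes ledger, browser tracks and run summary.

Internally everything is 0-based half-open; conversion to the 1-based
conventions of VCF, wig and the changes file happens here and only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .alignment_ingest import InputGenome, LibraryStats
from .config import Config
from .discontiguity import SuspiciousRegion
from .duplications import DuplicationRegion
from .pileup import BaseClassification, Category, PileupTable
from .reassembly import RegionResolution
from .small_variants import BaseFix, SmallVariantCall

log = logging.getLogger("burnish")

CHANGE_CATEGORIES = ("snp", "ambiguous_fix", "small_insertion",
                     "small_deletion", "gap_fill", "gap_shrink", "break_fix")


@dataclass
class ChangeRecord:
    """One edit from input to output genome.

    Applying every record's ``source_sequence -> dest_sequence``
    replacement at ``source_interval``, in ascending coordinate order,
    transforms the input genome into the output genome exactly; the
    ``dest_interval`` gives the location of the replacement in output
    coordinates.
    """

    scaffold: str
    source_start: int
    source_end: int
    source_sequence: str
    dest_sequence: str
    category: str
    dest_start: int = -1
    dest_end: int = -1

    def __post_init__(self) -> None:
        if self.category not in CHANGE_CATEGORIES:
            raise ValueError(f"unknown change category {self.category!r}")


def apply_changes(genome: InputGenome,
                  changes: list[ChangeRecord]) -> InputGenome:
    """Apply the edits and fill in destination coordinates.

    Changes must be non-overlapping in source coordinates; overlap is an
    internal logic error and fatal.
    """
    by_scaffold: dict[str, list[ChangeRecord]] = {n: [] for n in genome.names}
    for c in changes:
        by_scaffold[c.scaffold].append(c)
    new_seqs: dict[str, str] = {}
    from .alignment_ingest import find_gaps
    gaps = {}
    for name in genome.names:
        seq = genome.sequences[name]
        recs = sorted(by_scaffold[name], key=lambda c: c.source_start)
        pieces: list[str] = []
        cursor = 0
        offset = 0
        for c in recs:
            if c.source_start < cursor:
                raise ValueError(
                    f"overlapping changes on {name} at {c.source_start}")
            if seq[c.source_start:c.source_end] != c.source_sequence:
                raise ValueError(
                    f"change source mismatch on {name}:{c.source_start}")
            pieces.append(seq[cursor:c.source_start])
            pieces.append(c.dest_sequence)
            c.dest_start = c.source_start + offset
            c.dest_end = c.dest_start + len(c.dest_sequence)
            offset += len(c.dest_sequence) - (c.source_end - c.source_start)
            cursor = c.source_end
        pieces.append(seq[cursor:])
        new_seqs[name] = "".join(pieces)
        gaps[name] = find_gaps(name, new_seqs[name])
    return InputGenome(list(genome.names), new_seqs, gaps)


def write_fasta(genome: InputGenome, fh: TextIO, width: int = 70) -> None:
    """Emit the genome, uppercase, at a fixed line width (byte-reproducible)."""
    for name in genome.names:
        fh.write(f">{name}\n")
        seq = genome.sequences[name]
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_changes(changes: Sequence[ChangeRecord], fh: TextIO) -> None:
    """Tabular edit ledger.

    Columns (tab-separated): scaffold, source interval (1-based inclusive,
    ``start-end``; insertions before base ``p`` print ``p-p.``), source
    sequence ('.' when empty), destination interval in output coordinates,
    destination sequence, category.
    """
    fh.write("#scaffold\tsource_coords\tsource_sequence\t"
             "dest_coords\tdest_sequence\tcategory\n")
    for c in changes:
        fh.write("\t".join([
            c.scaffold,
            _coords(c.source_start, c.source_end),
            c.source_sequence or ".",
            _coords(c.dest_start, c.dest_end),
            c.dest_sequence or ".",
            c.category,
        ]) + "\n")


def _coords(start: int, end: int) -> str:
    if end > start:
        return f"{start + 1}-{end}"
    return f"{start}-{start}."      # zero-length (insertion point)


def parse_changes(fh: TextIO) -> list[ChangeRecord]:
    """Read a changes file back into records (used by the replay check)."""
    out = []
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        scaf, sc, ss, dc, ds, cat = line.rstrip("\n").split("\t")
        s0, s1 = _parse_coords(sc)
        d0, d1 = _parse_coords(dc)
        out.append(ChangeRecord(scaf, s0, s1, "" if ss == "." else ss,
                                "" if ds == "." else ds, cat, d0, d1))
    return out


def _parse_coords(text: str) -> tuple[int, int]:
    if text.endswith("."):
        p = int(text[:-1].split("-")[0])
        return p, p
    a, b = text.split("-")
    return int(a) - 1, int(b)


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=VC,Number=1,Type=Integer,Description="Valid-pair read depth">',
    '##INFO=<ID=BC,Number=1,Type=Integer,Description="Invalid-pair read depth">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Depth-normalized call quality (QUAL/VC)">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length difference of ALT vs REF">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Breakpoints not fully assembled">',
    '##INFO=<ID=LEFTEXT,Number=1,Type=String,Description="Consensus extension from the left flank of an unresolved region">',
    '##INFO=<ID=RIGHTEXT,Number=1,Type=String,Description="Consensus extension from the right flank of an unresolved region">',
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FILTER=<ID=LowCov,Description="Insufficient valid-read depth">',
    '##FILTER=<ID=Amb,Description="Evidence supports more than one allele">',
]


def write_vcf(genome: InputGenome, calls: Sequence[SmallVariantCall],
              classifications: dict[str, list[BaseClassification]],
              pileups: PileupTable,
              resolutions: Sequence[RegionResolution],
              fh: TextIO, mode: str = "variants_only") -> None:
    """Write calls (and, in ``all_sites`` mode, the evidence at every
    position) as VCF 4.2.

    Small indels use the anchor-base convention.  Closed large events carry
    the fully assembled ALT with SVTYPE/SVLEN; regions that could only be
    extended are emitted as imprecise symbolic records with the flank
    consensus extensions in INFO.
    """
    fh.write("##fileformat=VCFv4.2\n")
    fh.write("##source=burnish\n")
    for name in genome.names:
        fh.write(f"##contig=<ID={name},length={len(genome.sequences[name])}>\n")
    for line in VCF_HEADER_LINES:
        fh.write(line + "\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")

    rows: list[tuple[str, int, str]] = []   # (scaffold, 0-based pos, line)

    def emit(scaf: str, pos: int, ref: str, alt: str, qual: float,
             filt: str, info: str) -> None:
        line = (f"{scaf}\t{pos + 1}\t.\t{ref}\t{alt}\t"
                f"{qual:.1f}\t{filt}\t{info}")
        rows.append((scaf, pos, line))

    small_positions: set[tuple[str, int]] = set()
    for c in calls:
        sp = pileups[c.scaffold]
        p = min(c.position, sp.length - 1)
        info = (f"DP={int(sp.total_cov[p])};VC={int(sp.valid_cov[p])};"
                f"BC={int(sp.bad_cov[p])};QD={c.qd:.2f}")
        emit(c.scaffold, c.position, c.ref_allele, c.alt_allele, c.qual,
             "PASS", info)
        small_positions.add((c.scaffold, c.position))

    for res in resolutions:
        r = res.region
        if res.category is not None and res.source_start is not None:
            seq = genome.sequences[r.scaffold]
            s0, s1 = res.source_start, res.source_end
            if s0 > 0:
                anchor_pos = s0 - 1
                ref = seq[anchor_pos:s1]
                alt = seq[anchor_pos] + res.dest_sequence
            else:
                anchor_pos = 0
                ref = seq[s0:s1]
                alt = res.dest_sequence or "."
            if "N" in alt or "N" in ref:
                continue   # gap shrinks are genome edits, not variants
            svlen = len(res.dest_sequence) - (s1 - s0)
            svtype = "INS" if svlen > 0 else "DEL"
            sp = pileups[r.scaffold]
            p = min(anchor_pos, sp.length - 1)
            info = (f"SVTYPE={svtype};SVLEN={svlen};"
                    f"DP={int(sp.total_cov[p])};VC={int(sp.valid_cov[p])}")
            emit(r.scaffold, anchor_pos, ref, alt, 500.0, "PASS", info)
        elif (r.status in ("no_solution", "tandem_repeat")
              and res.closure.outcome == "extended"):
            seq = genome.sequences[r.scaffold]
            anchor_pos = max(0, r.start - 1)
            info_parts = ["SVTYPE=INS", "IMPRECISE"]
            if res.closure.left_extension:
                info_parts.append(f"LEFTEXT={res.closure.left_extension}")
            if res.closure.right_extension:
                info_parts.append(f"RIGHTEXT={res.closure.right_extension}")
            emit(r.scaffold, anchor_pos, seq[anchor_pos], "<INS>", 0.0,
                 "Amb", ";".join(info_parts))

    if mode == "all_sites":
        for name in genome.names:
            seq = genome.sequences[name]
            sp = pileups[name]
            cls = classifications[name]
            for pos in range(len(seq)):
                if (name, pos) in small_positions or seq[pos] == "N":
                    continue
                c = cls[pos]
                info = (f"DP={int(sp.total_cov[pos])};"
                        f"VC={int(sp.valid_cov[pos])};"
                        f"BC={int(sp.bad_cov[pos])};QD={c.qd:.2f}")
                filt = {"Unconfirmed": "LowCov",
                        "Ambiguous": "Amb"}.get(c.category.value, "PASS")
                alt = (c.called_allele
                       if c.called_allele and c.called_allele != seq[pos]
                       else ".")
                emit(name, pos, seq[pos], alt, c.qual, filt, info)
    else:
        # ambiguous positions are still reported, annotated as such
        for name in genome.names:
            seq = genome.sequences[name]
            sp = pileups[name]
            for pos, c in enumerate(classifications[name]):
                if c.category is not Category.AMBIGUOUS:
                    continue
                if (name, pos) in small_positions:
                    continue
                info = (f"DP={int(sp.total_cov[pos])};"
                        f"VC={int(sp.valid_cov[pos])};"
                        f"BC={int(sp.bad_cov[pos])};QD={c.qd:.2f}")
                alt = (c.called_allele
                       if c.called_allele and c.called_allele != seq[pos]
                       else ".")
                emit(name, pos, seq[pos], alt, c.qual, "Amb", info)

    order = {n: i for i, n in enumerate(genome.names)}
    rows.sort(key=lambda t: (order[t[0]], t[1]))
    for _, _, line in rows:
        fh.write(line + "\n")


# ---------------------------------------------------------------------------
# tracks

@dataclass
class TrackSet:
    """Per-position metric arrays plus interval features for browsers."""

    genome: InputGenome
    valid_coverage: dict[str, np.ndarray]
    physical_coverage: dict[str, np.ndarray]
    clipped_alignments: dict[str, np.ndarray]
    pct_bad_alignments: dict[str, np.ndarray]
    features: list[tuple[str, int, int, str]] = field(default_factory=list)


def build_tracks(pileups: PileupTable, regions: Sequence[SuspiciousRegion],
                 duplications: Sequence[DuplicationRegion],
                 changes: Sequence[ChangeRecord]) -> TrackSet:
    genome = pileups.genome
    valid, phys, clip, pct = {}, {}, {}, {}
    for name in genome.names:
        sp = pileups[name]
        valid[name] = sp.valid_cov.copy()
        phys[name] = sp.phys_cov.copy()
        clip[name] = sp.clip_starts.copy()
        pct[name] = np.round(
            100.0 * sp.bad_cov / np.maximum(1, sp.total_cov), 2)
    features: list[tuple[str, int, int, str]] = []
    for r in regions:
        label = "REGION:" + "+".join(sorted(r.triggers)) + ":" + r.status
        if r.tandem_period:
            label += f":period={r.tandem_period}"
        features.append((r.scaffold, r.start, r.end, label))
    for d in duplications:
        features.append((d.scaffold, d.start, d.end,
                         f"DUP:ratio={d.mean_ratio:.2f}"))
    for c in changes:
        features.append((c.scaffold, c.source_start,
                         max(c.source_end, c.source_start + 1),
                         f"CHANGE:{c.category}"))
    return TrackSet(genome, valid, phys, clip, pct, features)


def write_wig(track: dict[str, np.ndarray], name: str, fh: TextIO) -> None:
    """fixedStep wiggle, step 1, 1-based starts."""
    fh.write(f'track type=wiggle_0 name="{name}"\n')
    for scaffold, values in track.items():
        fh.write(f"fixedStep chrom={scaffold} start=1 step=1\n")
        if np.issubdtype(values.dtype, np.integer):
            fh.write("\n".join(str(int(v)) for v in values) + "\n")
        else:
            fh.write("\n".join(f"{v:g}" for v in values) + "\n")


def write_bed(features: Sequence[tuple[str, int, int, str]],
              name: str, fh: TextIO) -> None:
    """0-based half-open BED of interval features."""
    fh.write(f'track name="{name}"\n')
    for scaffold, start, end, label in features:
        fh.write(f"{scaffold}\t{start}\t{end}\t{label}\n")


def write_tracks(tracks: TrackSet, prefix: str) -> list[str]:
    paths = []
    for attr, label in [("valid_coverage", "ValidCoverage"),
                        ("physical_coverage", "PhysicalCoverage"),
                        ("clipped_alignments", "ClippedAlignments"),
                        ("pct_bad_alignments", "PctBadAlignments")]:
        path = f"{prefix}.{attr}.wig"
        with open(path, "w") as fh:
            write_wig(getattr(tracks, attr), label, fh)
        paths.append(path)
    path = f"{prefix}.features.bed"
    with open(path, "w") as fh:
        write_bed(tracks.features, "Features", fh)
    paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# summary

def summarize(genome: InputGenome,
              stats: Sequence[LibraryStats],
              classifications: dict[str, list[BaseClassification]],
              changes: Sequence[ChangeRecord],
              regions: Sequence[SuspiciousRegion],
              duplications: Sequence[DuplicationRegion]) -> str:
    """Human-readable run summary: coverage, % of the input genome
    confirmed, per-category change counts, unresolved regions (with tandem
    periods) and duplication flags."""
    lines = []
    total_cov = sum(s.mean_coverage for s in stats)
    lines.append(f"Mean total coverage: {total_cov:.1f}x")
    n_considered = 0
    n_confirmed = 0
    for name in genome.names:
        for base, cls in zip(genome.sequences[name], classifications[name]):
            if base == "N":
                continue
            n_considered += 1
            if cls.category is Category.CONFIRMED:
                n_confirmed += 1
    pct = 100.0 * n_confirmed / n_considered if n_considered else 0.0
    lines.append(f"Confirmed {n_confirmed} of {n_considered} bases ({pct:.2f}%)")
    counts = {c: 0 for c in CHANGE_CATEGORIES}
    for c in changes:
        counts[c.category] += 1
    lines.append("Changes: " + ", ".join(
        f"{cat}={n}" for cat, n in counts.items() if n) or "Changes: none")
    if not any(counts.values()):
        lines.append("No changes applied")
    for r in regions:
        if r.status == "tandem_repeat":
            lines.append(f"Unresolved tandem repeat at {r.scaffold}:"
                         f"{r.start + 1}-{r.end}, period {r.tandem_period}")
        elif r.status == "no_solution":
            lines.append(f"Unresolved region at {r.scaffold}:"
                         f"{r.start + 1}-{r.end} "
                         f"({'+'.join(sorted(r.triggers))})")
    for d in duplications:
        lines.append(f"Possible collapsed repeat/duplication at "
                     f"{d.scaffold}:{d.start + 1}-{d.end} "
                     f"(coverage ratio {d.mean_ratio:.2f})")
    return "\n".join(lines) + "\n"
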