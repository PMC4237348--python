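"""Synthetic data generation: genomes, mutated drafts with truth ledgers,
simulated paired reads and truth-projected alignments.

The generator exists so the whole pipeline can be exercised without an
external aligner or sequencing data.  Reads are simulated from a "truth"
genome; a draft is derived from the truth by planting defects (single-base
errors, small indels, N-run gaps, collapsed repeats, mis-joins, large
indels); the truth ledger then *projects* each read onto the draft —
deterministic liftover with CIGARs derived from the planted defects, so
tests control exactly which discordance signals exist (soft-clips at
draft-only sequence, unmapped mates inside draft-absent sequence, improper
pairs across large events, and low mapping quality inside multi-copy
repeats).

Everything is deterministic under the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_ingest import LibraryKind, LibrarySpec
from .reassembly import revcomp

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_ALPHABET, size=n).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome generation

@dataclass
class GenomeFeature:
    kind: str                       # tandem | dispersed | duplication | gc
    intervals: list[tuple[int, int]]
    period: int | None = None
    copies: int | None = None


@dataclass
class TandemSpec:
    period: int
    copies: int
    position: int | None = None


@dataclass
class DispersedRepeatSpec:
    length: int
    copies: int
    divergence: float = 0.0
    positions: list[int] | None = None


@dataclass
class DuplicationSpec:
    """Two identical adjacent copies of a segment (so a collapse defect can
    remove one and leave doubled coverage on the other)."""

    length: int
    position: int | None = None


def generate_genome(seed: int, length: int,
                    repeat_spec: list | None = None,
                    ) -> tuple[str, list[GenomeFeature]]:
    """An i.i.d. uniform ACGT background with planted repeat features.

    Features are written at their requested positions (or at deterministic
    pseudo-random non-overlapping positions) and every planted feature is
    returned in the annotation.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = bytearray(_random_seq(rng, length), "ascii")
    features: list[GenomeFeature] = []
    occupied: list[tuple[int, int]] = []

    def place(size: int, want: int | None) -> int:
        if want is not None:
            pos = want
        else:
            for _ in range(1000):
                pos = int(rng.integers(0, length - size))
                if all(pos + size <= a or pos >= b for a, b in occupied):
                    break
            else:
                raise ValueError("could not place feature (genome too full)")
        if pos < 0 or pos + size > length:
            raise ValueError("feature does not fit in genome")
        occupied.append((pos, pos + size))
        return pos

    for spec in (repeat_spec or []):
        if isinstance(spec, TandemSpec):
            unit = _random_seq(rng, spec.period)
            total = spec.period * spec.copies
            pos = place(total, spec.position)
            seq[pos:pos + total] = (unit * spec.copies).encode("ascii")
            features.append(GenomeFeature(
                "tandem", [(pos, pos + total)], spec.period, spec.copies))
        elif isinstance(spec, DispersedRepeatSpec):
            element = _random_seq(rng, spec.length)
            intervals = []
            positions = spec.positions or [None] * spec.copies
            for want in positions:
                pos = place(spec.length, want)
                copy = bytearray(element, "ascii")
                n_div = int(round(spec.divergence * spec.length))
                if n_div:
                    sites = rng.choice(spec.length, size=n_div, replace=False)
                    for s in sites:
                        copy[s] = int(rng.choice(
                            [b for b in _ALPHABET if b != copy[s]]))
                seq[pos:pos + spec.length] = copy
                intervals.append((pos, pos + spec.length))
            features.append(GenomeFeature("dispersed", intervals,
                                          copies=spec.copies))
        elif isinstance(spec, DuplicationSpec):
            unit = _random_seq(rng, spec.length)
            pos = place(2 * spec.length, spec.position)
            seq[pos:pos + 2 * spec.length] = (unit * 2).encode("ascii")
            features.append(GenomeFeature(
                "duplication", [(pos, pos + spec.length),
                                (pos + spec.length, pos + 2 * spec.length)],
                copies=2))
        else:
            raise ValueError(f"unknown repeat spec {spec!r}")
    return seq.decode("ascii"), features


# ---------------------------------------------------------------------------
# defects and the truth ledger

@dataclass
class SnpDefect:
    position: int                   # truth coordinate

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position + 1


@dataclass
class DeletionDefect:
    """The draft is missing ``length`` truth bases at ``position`` (reads
    show an insertion relative to the draft)."""

    position: int
    length: int

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position + self.length


@dataclass
class InsertionDefect:
    """The draft has extra bases the truth lacks (reads show a deletion)."""

    position: int
    length: int

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position


@dataclass
class GapDefect:
    """A truth segment replaced in the draft by an N-run of arbitrary
    length (the assembler's gap-size estimate is independent of the true
    insert)."""

    position: int
    length: int
    n_run: int = 200

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position + self.length


@dataclass
class MisjoinDefect:
    """Foreign sequence spliced into the draft: reads soft-clip at both
    junctions and spanning pairs become improper."""

    position: int
    length: int = 500

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position


@dataclass
class LargeInsertionDefect:
    """A truth segment entirely absent from the draft (no N placeholder):
    a large insertion in the sample relative to the reference."""

    position: int
    length: int

    @property
    def t0(self): return self.position
    @property
    def t1(self): return self.position + self.length


@dataclass
class CollapseDefect:
    """The draft keeps only one of two identical adjacent truth copies
    (requires a ``DuplicationSpec`` feature at the same place)."""

    position: int
    unit_length: int

    @property
    def t0(self): return self.position + self.unit_length
    @property
    def t1(self): return self.position + 2 * self.unit_length


@dataclass
class Zone:
    """A truth interval with one liftover behavior.

    kind "M": colinear mapping to draft offset ``d0`` (SNPs live inside M
    zones); "ins": truth bases absent from the draft, carried by reads as
    an insertion at draft point ``d0``; "abs": truth bases with no draft
    image at all (reads clip or go unmapped).  ``dgap_before`` is the
    number of draft-only bases immediately before the zone (a read
    spanning it gets a D op); ``break_before`` marks junctions a real
    aligner would not align across (large draft-only inserts, collapsed
    copy boundaries).
    """

    t0: int
    t1: int
    kind: str
    d0: int = -1
    dgap_before: int = 0
    break_before: bool = False


@dataclass
class DefectEvent:
    """A planted defect with both coordinate systems resolved: where it
    sits in the truth and what it looks like in the draft."""

    kind: str
    t0: int
    t1: int
    draft_start: int
    draft_end: int
    truth_seq: str = ""          # truth bases the draft misrepresents
    draft_seq: str = ""          # draft bases at the defect


@dataclass
class TruthLedger:
    scaffold: str
    truth: str
    draft: str
    zones: list[Zone]
    defects: list
    snp_draft: dict[int, str] = field(default_factory=dict)  # draft pos -> truth base
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    events: list[DefectEvent] = field(default_factory=list)

    def zone_at(self, t: int) -> Zone | None:
        for z in self.zones:
            if z.t0 <= t < z.t1:
                return z
        return None


def plant_defects(truth: str, defects: list, seed: int,
                  scaffold: str = "scaffold1",
                  features: list[GenomeFeature] | None = None) -> TruthLedger:
    """Derive a draft from the truth genome and record the liftover.

    Defects must be non-overlapping (in truth coordinates) and are applied
    left to right.  SNP defects rewrite one draft base; the other defect
    kinds carve the zone structure used to project reads.
    """
    rng = np.random.default_rng(seed)
    defects = sorted(defects, key=lambda d: (d.t0, d.t1))
    for a, b in zip(defects, defects[1:]):
        if b.t0 < a.t1:
            raise ValueError(f"overlapping defects at {a.t1}/{b.t0}")

    zones: list[Zone] = []
    pieces: list[str] = []
    snp_draft: dict[int, str] = {}
    events: list[DefectEvent] = []
    t_cursor = 0
    d_cursor = 0
    pending_dgap = 0
    pending_break = False

    def emit_background(t_end: int) -> None:
        nonlocal t_cursor, d_cursor, pending_dgap, pending_break
        if t_end > t_cursor:
            zones.append(Zone(t_cursor, t_end, "M", d_cursor,
                              pending_dgap, pending_break))
            pieces.append(truth[t_cursor:t_end])
            d_cursor += t_end - t_cursor
            t_cursor = t_end
            pending_dgap = 0
            pending_break = False

    for d in defects:
        if isinstance(d, SnpDefect):
            emit_background(d.position)
            orig = truth[d.position]
            alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}[orig][
                int(rng.integers(0, 3))]
            zones.append(Zone(d.position, d.position + 1, "M", d_cursor,
                              pending_dgap, pending_break))
            pending_dgap = 0
            pending_break = False
            pieces.append(alt)
            snp_draft[d_cursor] = orig
            events.append(DefectEvent("snp", d.position, d.position + 1,
                                      d_cursor, d_cursor + 1, orig, alt))
            d_cursor += 1
            t_cursor = d.position + 1
        elif isinstance(d, DeletionDefect):
            emit_background(d.t0)
            zones.append(Zone(d.t0, d.t1, "ins", d_cursor))
            events.append(DefectEvent("deletion", d.t0, d.t1, d_cursor,
                                      d_cursor, truth[d.t0:d.t1], ""))
            t_cursor = d.t1
        elif isinstance(d, InsertionDefect):
            emit_background(d.t0)
            extra = _random_seq(rng, d.length)
            pieces.append(extra)
            events.append(DefectEvent("insertion", d.t0, d.t0, d_cursor,
                                      d_cursor + d.length, "", extra))
            d_cursor += d.length
            pending_dgap += d.length
        elif isinstance(d, GapDefect):
            emit_background(d.t0)
            zones.append(Zone(d.t0, d.t1, "abs"))
            pieces.append("N" * d.n_run)
            events.append(DefectEvent("gap", d.t0, d.t1, d_cursor,
                                      d_cursor + d.n_run,
                                      truth[d.t0:d.t1], "N" * d.n_run))
            d_cursor += d.n_run
            t_cursor = d.t1
            pending_break = True
        elif isinstance(d, MisjoinDefect):
            emit_background(d.t0)
            junk = _random_seq(rng, d.length)
            pieces.append(junk)
            events.append(DefectEvent("misjoin", d.t0, d.t0, d_cursor,
                                      d_cursor + d.length, "", junk))
            d_cursor += d.length
            pending_break = True
        elif isinstance(d, LargeInsertionDefect):
            emit_background(d.t0)
            zones.append(Zone(d.t0, d.t1, "abs"))
            events.append(DefectEvent("large_insertion", d.t0, d.t1,
                                      d_cursor, d_cursor,
                                      truth[d.t0:d.t1], ""))
            t_cursor = d.t1
        elif isinstance(d, CollapseDefect):
            # background through copy1 first
            emit_background(d.position + d.unit_length)
            u = d.unit_length
            if truth[d.position:d.position + u] != \
                    truth[d.position + u:d.position + 2 * u]:
                raise ValueError("collapse defect requires identical copies")
            zones.append(Zone(d.t0, d.t1, "M", d_cursor - u,
                              break_before=True))
            events.append(DefectEvent("collapse", d.t0, d.t1,
                                      d_cursor - u, d_cursor,
                                      truth[d.t0:d.t1], ""))
            t_cursor = d.t1
            pending_break = False
        else:
            raise ValueError(f"unknown defect {d!r}")
    emit_background(len(truth))

    repeat_intervals = []
    for f in (features or []):
        if f.kind in ("dispersed", "tandem") and len(f.intervals) >= 1:
            if f.kind == "dispersed" and (f.copies or 1) >= 2:
                repeat_intervals.extend(f.intervals)
            elif f.kind == "tandem":
                repeat_intervals.extend(f.intervals)

    return TruthLedger(scaffold, truth, "".join(pieces), zones, defects,
                       snp_draft, repeat_intervals, events)


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimRead:
    """One read end in truth-forward orientation."""

    name: str
    t_start: int
    seq: str                        # truth-forward orientation, with errors
    quals: list
    is_reverse: bool
    is_read1: bool


@dataclass
class SimPair:
    r1: SimRead
    r2: SimRead | None


def simulate_reads(truth: str, library: LibrarySpec, seed: int,
                   depth: float = 60.0, read_length: int = 100,
                   insert_mean: float = 300.0, insert_sd: float = 30.0,
                   error_rate: float = 0.0,
                   name_prefix: str | None = None) -> list[SimPair]:
    """Uniformly sampled FR pairs (or unpaired reads) with Phred qualities
    consistent with the substitution error rate.

    Insert lengths are sampled from a normal distribution truncated at
    three standard deviations, so every simulated pair is a proper pair by
    the pipeline's own template-length rule.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    L = len(truth)
    paired = library.paired
    if paired and read_length >= insert_mean:
        raise ValueError("read length must be below the insert mean")
    q = 40 if error_rate <= 0 else int(np.clip(
        round(-10 * np.log10(error_rate)), 2, 40))
    prefix = name_prefix or (library.name or library.kind.value)

    def bases_with_errors(s: str) -> str:
        if error_rate <= 0:
            return s
        arr = bytearray(s, "ascii")
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for h in hits:
            choices = [b for b in b"ACGT" if b != arr[h]]
            arr[h] = choices[int(rng.integers(0, 3))]
        return arr.decode("ascii")

    out: list[SimPair] = []
    if paired:
        n_pairs = int(round(depth * L / (2 * read_length)))
        for i in range(n_pairs):
            ins = int(np.clip(rng.normal(insert_mean, insert_sd),
                              insert_mean - 3 * insert_sd,
                              insert_mean + 3 * insert_sd))
            ins = max(ins, read_length + 1)
            if ins >= L:
                ins = L - 1
            s = int(rng.integers(0, L - ins))
            e = s + ins
            name = f"{prefix}_{i}"
            r1 = SimRead(name, s, bases_with_errors(truth[s:s + read_length]),
                         [q] * read_length, False, True)
            r2 = SimRead(name, e - read_length,
                         bases_with_errors(truth[e - read_length:e]),
                         [q] * read_length, True, False)
            out.append(SimPair(r1, r2))
    else:
        n = int(round(depth * L / read_length))
        for i in range(n):
            s = int(rng.integers(0, L - read_length))
            rev = bool(rng.integers(0, 2))
            name = f"{prefix}_{i}"
            out.append(SimPair(
                SimRead(name, s,
                        bases_with_errors(truth[s:s + read_length]),
                        [q] * read_length, rev, True), None))
    return out


# ---------------------------------------------------------------------------
# truth projection onto the draft

@dataclass
class _Projection:
    pos: int                        # draft start of the aligned part
    cigar: list[tuple[int, int]]    # pysam op codes, truth-forward order
    mapped: bool


_MIN_ALIGN = 20                     # minimum aligned bases to call a read mapped


def _project_interval(ledger: TruthLedger, t0: int, t1: int) -> _Projection:
    """Project truth interval [t0, t1) onto the draft.

    Builds alignment chunks separated by break points (absent zones, large
    draft-only inserts, collapsed-copy junctions); the chunk with the most
    aligned bases wins and everything else becomes a soft clip, matching
    what a best-hit aligner would report.
    """
    chunks: list[dict] = []
    current: dict | None = None

    def close() -> None:
        nonlocal current
        if current is not None:
            # strip non-M edge ops into clips
            ops = current["ops"]
            while ops and ops[0][0] != 0:
                op, ln = ops.pop(0)
                if op == 1:
                    current["q_before"] += ln
                else:
                    current["pos"] += ln
            while ops and ops[-1][0] != 0:
                op, ln = ops.pop()
                if op == 1:
                    current["q_after"] += ln
            if ops:
                chunks.append(current)
            current = None

    q_used = 0
    for z in ledger.zones:
        if z.t1 <= t0 or z.t0 >= t1:
            continue
        lo, hi = max(t0, z.t0), min(t1, z.t1)
        seg = hi - lo
        at_zone_start = lo == z.t0
        if z.kind == "abs":
            close()
            q_used += seg
            continue
        if z.kind == "M":
            if at_zone_start and z.break_before:
                close()
            if current is not None and at_zone_start and z.dgap_before:
                current["ops"].append((2, z.dgap_before))
            d = z.d0 + (lo - z.t0)
            if current is None:
                current = {"pos": d, "ops": [], "q_before": q_used,
                           "q_after": 0}
            current["ops"].append((0, seg))
            q_used += seg
        elif z.kind == "ins":
            if current is not None:
                current["ops"].append((1, seg))
            q_used += seg
    close()
    total_q = q_used

    if not chunks:
        return _Projection(0, [], False)
    best = max(chunks, key=lambda c: sum(l for op, l in c["ops"] if op == 0))
    aligned = sum(l for op, l in best["ops"] if op == 0)
    if aligned < _MIN_ALIGN:
        return _Projection(0, [], False)
    q_before = best["q_before"]
    q_in = sum(l for op, l in best["ops"] if op in (0, 1))
    q_after = total_q - q_before - q_in
    cigar = []
    if q_before:
        cigar.append((4, q_before))
    # merge adjacent same-op runs
    for op, ln in best["ops"]:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))
    if q_after:
        cigar.append((4, q_after))
    return _Projection(best["pos"], cigar, True)


def _mapq(ledger: TruthLedger, t0: int, t1: int) -> int:
    for a, b in ledger.repeat_intervals:
        if t0 >= a and t1 <= b:
            return 2
    return 60


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_str(cigar: list[tuple[int, int]]) -> str:
    return "".join(f"{l}{_CIGAR_OPS[op]}" for op, l in cigar)


def project_alignments(pairs: list[SimPair], ledger: TruthLedger,
                       library: LibrarySpec,
                       insert_mean: float = 300.0,
                       insert_sd: float = 30.0) -> list[str]:
    """Project simulated reads onto the draft and render SAM record lines.

    Proper-pair flags follow the template-length rule: a pair is proper
    when both ends map to the draft in FR orientation with a template
    length within three standard deviations of the library mean.  Reads
    entirely inside draft-absent sequence are emitted unmapped (placed at
    their mate when it maps; dropped when neither end maps).
    """
    lines: list[tuple[int, str]] = []
    scaf = ledger.scaffold
    max_tlen = insert_mean + 3 * insert_sd + 1
    min_tlen = max(0.0, insert_mean - 3 * insert_sd - 1)

    for pair in pairs:
        ends = [pair.r1] + ([pair.r2] if pair.r2 else [])
        projs = [_project_interval(ledger, r.t_start,
                                   r.t_start + len(r.seq)) for r in ends]
        if pair.r2 is None:
            r, p = ends[0], projs[0]
            if not p.mapped:
                continue
            flag = 16 if r.is_reverse else 0
            seq, quals = _oriented(r)
            lines.append((p.pos, _sam_line(
                r.name, flag, scaf, p.pos, _mapq(ledger, r.t_start,
                                                 r.t_start + len(r.seq)),
                _cigar_str(p.cigar), "*", 0, 0, seq, quals)))
            continue

        r1, r2 = ends
        p1, p2 = projs
        if not p1.mapped and not p2.mapped:
            continue
        proper = False
        tlen1 = tlen2 = 0
        if p1.mapped and p2.mapped:
            left = min(p1.pos, p2.pos)
            right = max(_ref_end(p1), _ref_end(p2))
            span = right - left
            fr = ((not r1.is_reverse and r2.is_reverse and p1.pos <= p2.pos)
                  or (not r2.is_reverse and r1.is_reverse and p2.pos <= p1.pos))
            proper = fr and min_tlen <= span <= max_tlen
            if p1.pos <= p2.pos:
                tlen1, tlen2 = span, -span
            else:
                tlen1, tlen2 = -span, span
        for r, p, other_p, tlen in ((r1, p1, p2, tlen1),
                                    (r2, p2, p1, tlen2)):
            flag = 1                            # paired
            flag |= 64 if r.is_read1 else 128
            if proper:
                flag |= 2
            if not p.mapped:
                flag |= 4
            if r.is_reverse:
                flag |= 16
            other = r2 if r is r1 else r1
            if not other_p.mapped:
                flag |= 8
            if other.is_reverse and other_p.mapped:
                flag |= 32
            pos = p.pos if p.mapped else (other_p.pos if other_p.mapped else 0)
            cig = _cigar_str(p.cigar) if p.mapped else "*"
            mq = (_mapq(ledger, r.t_start, r.t_start + len(r.seq))
                  if p.mapped else 0)
            mate_pos = other_p.pos if other_p.mapped else pos
            seq, quals = _oriented(r)
            lines.append((pos, _sam_line(
                r.name, flag, scaf, pos, mq, cig, "=", mate_pos,
                tlen if (proper or (p.mapped and other_p.mapped)) else 0,
                seq, quals)))
    lines.sort(key=lambda t: t[0])
    return [line for _, line in lines]


def _oriented(r: SimRead) -> tuple[str, str]:
    """SEQ/QUAL in reference-forward orientation (SAM convention)."""
    qual = "".join(chr(q + 33) for q in r.quals)
    return r.seq, qual


def _ref_end(p: _Projection) -> int:
    return p.pos + sum(l for op, l in p.cigar if op in (0, 2))


def _sam_line(name, flag, rname, pos, mapq, cigar, rnext, pnext, tlen,
              seq, qual) -> str:
    return "\t".join([name, str(flag), rname, str(pos + 1), str(mapq),
                      cigar, rnext, str(pnext + 1), str(tlen), seq, qual])


def write_sam(lines: list[str], ledger: TruthLedger, path: str) -> None:
    """Write a coordinate-sorted SAM file with a minimal header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{ledger.scaffold}\tLN:{len(ledger.draft)}\n")
        for line in lines:
            fh.write(line + "\n")


def write_fasta_string(name: str, seq: str, path: str,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
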