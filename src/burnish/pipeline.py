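"""Pipeline orchestration: from genome + alignments to polished genome,
calls and reports.

The stages run in evidence order: library statistics, pileup accumulation,
base classification, small-variant calling, discontiguity scanning, local
reassembly of suspicious regions and captured gaps, duplication flagging,
change application and serialization.  ``run_pipeline`` works on in-memory
inputs (used heavily by the test-suite); ``polish`` is the file-based entry
point used by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_ingest import (AlignmentRecord, InputGenome, LibrarySpec,
                               LibraryStats, UnmappedRead, load_genome,
                               read_alignments, scan_library_stats,
                               validate_inputs)
from .config import Config
from .discontiguity import (SuspiciousRegion, enumerate_reassembly_targets,
                            flag_suspicious_regions)
from .duplications import DuplicationRegion, detect_large_duplications
from .pileup import (BaseClassification, PileupTable, accumulate_pileups,
                     classify_scaffold)
from .reassembly import AlignmentIndex, RegionResolution, reassemble_region
from .reporting import (ChangeRecord, apply_changes, build_tracks,
                        summarize, write_changes, write_fasta, write_tracks,
                        write_vcf)
from .small_variants import (BaseFix, SmallVariantCall, call_small_indels,
                             call_snps, tally_indels)

log = logging.getLogger("burnish")


@dataclass
class LibraryData:
    spec: LibrarySpec
    records: list[AlignmentRecord]
    unmapped: list[UnmappedRead]


@dataclass
class PolishResult:
    genome: InputGenome
    stats: list[LibraryStats]
    pileups: PileupTable
    classifications: dict[str, list[BaseClassification]]
    snp_calls: list[SmallVariantCall]
    indel_calls: list[SmallVariantCall]
    fixes: list[BaseFix]
    regions: list[SuspiciousRegion]
    resolutions: list[RegionResolution]
    duplications: list[DuplicationRegion]
    changes: list[ChangeRecord]
    output_genome: InputGenome
    summary: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def all_calls(self) -> list[SmallVariantCall]:
        return sorted(self.snp_calls + self.indel_calls,
                      key=lambda c: (c.scaffold, c.position))


def run_pipeline(genome: InputGenome, libraries: list[LibraryData],
                 config: Config | None = None) -> PolishResult:
    """Run every stage on in-memory inputs and return all intermediates."""
    config = config or Config()
    stats = [scan_library_stats(lib.records, lib.spec, genome)
             for lib in libraries]
    warnings = validate_inputs(stats)

    all_records = [r for lib in libraries for r in lib.records]
    pileups = accumulate_pileups(genome, all_records, config)

    total_cov = sum(s.mean_coverage for s in stats)
    min_depth = config.effective_min_depth(total_cov)
    classifications = {
        name: classify_scaffold(genome, name, pileups[name], config,
                                min_depth)
        for name in genome.names
    }

    tally = tally_indels(pileups.indels, genome)
    indel_calls = call_small_indels(tally, pileups, config)
    snp_calls, fixes = call_snps(genome, classifications, config)

    regions = flag_suspicious_regions(pileups, stats, config,
                                      classifications)
    read_len = max((s.read_length_mode for s in stats), default=100)
    targets = enumerate_reassembly_targets(regions, genome, gap_pad=read_len)

    all_unmapped = [u for lib in libraries for u in lib.unmapped]
    index = AlignmentIndex(all_records, all_unmapped)
    resolutions = [reassemble_region(t, genome, index, stats, config)
                   for t in targets]

    duplications = detect_large_duplications(pileups, config)

    changes = assemble_changes(genome, fixes, indel_calls, resolutions,
                               config)
    output_genome = apply_changes(genome, changes)

    result = PolishResult(genome, stats, pileups, classifications,
                          snp_calls, indel_calls, fixes, targets,
                          resolutions, duplications, changes,
                          output_genome, warnings=warnings)
    result.summary = summarize(genome, stats, classifications, changes,
                               targets, duplications)
    return result


def assemble_changes(genome: InputGenome, fixes, indel_calls, resolutions,
                     config: Config) -> list[ChangeRecord]:
    """Turn accepted calls and reassembly results into a non-overlapping,
    sorted change list.

    Reassembly edits take precedence: small fixes inside a replaced
    interval are dropped (the replacement already embodies them).  The
    ``fix`` set gates which categories are applied at all: ``bases`` for
    single-base and small-indel fixes, ``gaps`` for gap fills/shrinks,
    ``local`` for mis-assembly replacements.
    """
    changes: list[ChangeRecord] = []
    large_intervals: dict[str, list[tuple[int, int]]] = {}
    for res in resolutions:
        if res.category is None or res.source_start is None:
            continue
        gate = "gaps" if res.category in ("gap_fill", "gap_shrink") \
            else "local"
        if gate not in config.fix:
            continue
        changes.append(ChangeRecord(res.region.scaffold, res.source_start,
                                    res.source_end, res.source_sequence,
                                    res.dest_sequence, res.category))
        large_intervals.setdefault(res.region.scaffold, []).append(
            (res.source_start, res.source_end))

    def shadowed(scaffold: str, start: int, end: int) -> bool:
        for a, b in large_intervals.get(scaffold, []):
            if start < b and end > a:
                return True
        return False

    if "bases" in config.fix:
        for f in fixes:
            if shadowed(f.scaffold, f.position, f.position + 1):
                continue
            changes.append(ChangeRecord(
                f.scaffold, f.position, f.position + 1, f.ref, f.alt,
                "ambiguous_fix" if f.ambiguous else "snp"))
        for c in indel_calls:
            if c.kind == "deletion":
                s0 = c.position + 1
                s1 = s0 + len(c.ref_allele) - 1
                src, dst, cat = c.ref_allele[1:], "", "small_deletion"
            else:
                s0 = s1 = c.position + 1
                src, dst, cat = "", c.alt_allele[1:], "small_insertion"
            if shadowed(c.scaffold, s0, max(s1, s0 + 1)):
                continue
            changes.append(ChangeRecord(c.scaffold, s0, s1, src, dst, cat))

    order = {n: i for i, n in enumerate(genome.names)}
    changes.sort(key=lambda c: (order[c.scaffold], c.source_start,
                                c.source_end))
    # drop any residual overlaps (first writer wins)
    kept: list[ChangeRecord] = []
    for c in changes:
        if kept and kept[-1].scaffold == c.scaffold \
                and c.source_start < kept[-1].source_end:
            log.warning("dropping change at %s:%d overlapping a prior edit",
                        c.scaffold, c.source_start)
            continue
        kept.append(c)
    return kept


def polish(genome_path: str, frags: list[str] = (), jumps: list[str] = (),
           unpaired: list[str] = (), output_prefix: str = "burnish",
           config: Config | None = None, variant_mode: bool = False,
           vcf: bool = False, tracks: bool = False,
           changes_file: bool = False) -> PolishResult:
    """File-based pipeline entry point; writes ``<prefix>.fasta`` plus the
    requested optional outputs and returns the full result object."""
    from .alignment_ingest import LibraryKind
    config = config or Config()
    genome = load_genome(genome_path)
    libraries: list[LibraryData] = []
    for i, path in enumerate(frags):
        spec = LibrarySpec(kind=LibraryKind.FRAGMENT, name=f"frags{i}")
        rec, unm = read_alignments(path, spec, genome)
        libraries.append(LibraryData(spec, rec, unm))
    for i, path in enumerate(jumps):
        spec = LibrarySpec(kind=LibraryKind.LONG_INSERT, name=f"jumps{i}")
        rec, unm = read_alignments(path, spec, genome)
        libraries.append(LibraryData(spec, rec, unm))
    for i, path in enumerate(unpaired):
        spec = LibrarySpec(kind=LibraryKind.UNPAIRED, name=f"unpaired{i}")
        rec, unm = read_alignments(path, spec, genome)
        libraries.append(LibraryData(spec, rec, unm))
    if not libraries:
        raise ValueError("at least one alignment file is required")

    result = run_pipeline(genome, libraries, config)

    with open(f"{output_prefix}.fasta", "w") as fh:
        write_fasta(result.output_genome, fh, config.fasta_line_width)
    if changes_file:
        with open(f"{output_prefix}.changes", "w") as fh:
            write_changes(result.changes, fh)
    if vcf or variant_mode:
        mode = "all_sites" if variant_mode else "variants_only"
        with open(f"{output_prefix}.vcf", "w") as fh:
            write_vcf(genome, result.all_calls, result.classifications,
                      result.pileups, result.resolutions, fh, mode)
    if tracks:
        ts = build_tracks(result.pileups, result.regions,
                          result.duplications, result.changes)
        write_tracks(ts, output_prefix)
    return result
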