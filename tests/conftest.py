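"""Shared fixtures: tiny in-memory genomes/records and one large
end-to-end polishing scenario reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from burnish import (AlignmentRecord, Config, InputGenome, LibraryKind,
                     LibrarySpec, find_gaps, run_pipeline)
from burnish.pipeline import LibraryData, PolishResult
from burnish.simulate import (CollapseDefect, DeletionDefect,
                              DuplicationSpec, GapDefect, InsertionDefect,
                              MisjoinDefect, SnpDefect, TruthLedger,
                              generate_genome, plant_defects,
                              project_alignments, simulate_reads)

FRAG = LibrarySpec(LibraryKind.FRAGMENT, "frag0")
JUMP = LibrarySpec(LibraryKind.LONG_INSERT, "jump0")
UNPAIRED = LibrarySpec(LibraryKind.UNPAIRED, "un0")


def make_genome(seqs) -> InputGenome:
    """Build an InputGenome from a string or {name: seq} dict."""
    if isinstance(seqs, str):
        seqs = {"s1": seqs}
    names = list(seqs)
    sequences = {n: s.upper() for n, s in seqs.items()}
    gaps = {n: find_gaps(n, s) for n, s in sequences.items()}
    return InputGenome(names, sequences, gaps)


def make_record(bases: str, start: int = 0, scaffold: str = "s1",
                name: str = "r1", cigar=None, mq: int = 60, bq: int = 30,
                proper: bool = True, paired: bool = True,
                reverse: bool = False, library: LibrarySpec = FRAG,
                tlen: int = 0, mate_unmapped: bool = False,
                is_read1: bool = True) -> AlignmentRecord:
    cigar = cigar if cigar is not None else [(0, len(bases))]
    return AlignmentRecord(
        query_name=name, scaffold=scaffold, start=start, cigar=cigar,
        mapping_quality=mq, bases=bases,
        base_qualities=[bq] * len(bases), is_paired=paired,
        is_proper_pair=proper and paired, is_reverse=reverse,
        is_read1=is_read1, mate_unmapped=mate_unmapped,
        mate_scaffold=None, mate_start=None, template_length=tlen,
        library=library)


def reads_from_seqs(seqs, q: int = 30):
    """(sequence, qualities) pairs for graph construction."""
    return [(s, [q] * len(s)) for s in seqs]


@dataclass
class Scenario:
    truth: str
    ledger: TruthLedger
    genome: InputGenome
    libraries: list
    result: PolishResult
    defects: list = field(default_factory=list)


def build_scenario(truth: str, ledger: TruthLedger, lib_params,
                   config: Config | None = None) -> Scenario:
    """Simulate reads per library, project them onto the draft, round-trip
    through SAM, and run the pipeline.

    ``lib_params`` entries: (spec, depth, insert_mean, insert_sd, seed).
    """
    import os
    import tempfile

    from burnish import read_alignments
    from burnish.simulate import write_sam

    genome = make_genome({ledger.scaffold: ledger.draft})
    libraries = []
    with tempfile.TemporaryDirectory() as td:
        for spec, depth, imean, isd, seed in lib_params:
            pairs = simulate_reads(truth, spec, seed, depth=depth,
                                   read_length=100, insert_mean=imean,
                                   insert_sd=isd)
            lines = project_alignments(pairs, ledger, spec, imean, isd)
            path = os.path.join(td, f"{spec.name}.sam")
            write_sam(lines, ledger, path)
            recs, unm = read_alignments(path, spec, genome)
            libraries.append(LibraryData(spec, recs, unm))
    result = run_pipeline(genome, libraries, config)
    return Scenario(truth, ledger, genome, libraries, result)


# ---------------------------------------------------------------------------
# the large end-to-end scenario: 50 SNPs, 20 small indels, 5 gaps, one
# mis-join, one collapsed 15 kb duplication; 60x fragments + 20x long insert

E2E_SEED = 11


def e2e_defects():
    defects = [SnpDefect(2000 + 550 * i) for i in range(50)]
    for i in range(20):
        pos = 33000 + 600 * i
        size = 1 + i % 3
        if i % 2 == 0:
            defects.append(DeletionDefect(pos, size))
        else:
            defects.append(InsertionDefect(pos, size))
    for i in range(5):
        defects.append(GapDefect(50000 + 4000 * i, 300, n_run=200))
    defects.append(MisjoinDefect(75000, 500))
    defects.append(CollapseDefect(82000, 15000))
    return defects


@pytest.fixture(scope="session")
def e2e() -> Scenario:
    truth, feats = generate_genome(E2E_SEED, 120000,
                                   [DuplicationSpec(15000, position=82000)])
    defects = e2e_defects()
    ledger = plant_defects(truth, defects, E2E_SEED, features=feats)
    scenario = build_scenario(truth, ledger, [
        (FRAG, 60.0, 300.0, 30.0, 101),
        (JUMP, 20.0, 3000.0, 300.0, 102),
    ])
    scenario.defects = defects
    return scenario


@pytest.fixture(scope="session")
def clean_run() -> Scenario:
    """An error-free, defect-free 40 kb control: nothing should be flagged
    or changed."""
    truth, feats = generate_genome(23, 40000, [])
    ledger = plant_defects(truth, [], 23, features=feats)
    return build_scenario(truth, ledger, [(FRAG, 60.0, 300.0, 30.0, 7)])
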