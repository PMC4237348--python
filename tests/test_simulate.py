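"""The synthetic-data generator: genomes, defect planting, read simulation
and truth-projected alignments."""

import numpy as np
import pysam
import pytest

from burnish import LibraryKind, LibrarySpec
from burnish.simulate import (CollapseDefect, DeletionDefect,
                              DuplicationSpec, GapDefect, InsertionDefect,
                              MisjoinDefect, SnpDefect, TandemSpec,
                              generate_genome, plant_defects,
                              project_alignments, simulate_reads, write_sam)

from conftest import FRAG, UNPAIRED


class TestGenerateGenome:
    def test_seeded_determinism(self):
        a, _ = generate_genome(1, 10000)
        b, _ = generate_genome(1, 10000)
        assert a == b and len(a) == 10000

    def test_tandem_feature_annotated(self):
        seq, feats = generate_genome(2, 5000, [TandemSpec(57, 4)])
        (f,) = [f for f in feats if f.kind == "tandem"]
        assert f.period == 57
        (a, b) = f.intervals[0]
        assert seq[a:a + 57] * 4 == seq[a:b]

    def test_duplication_copies_identical(self):
        seq, feats = generate_genome(3, 10000, [DuplicationSpec(1300)])
        (f,) = [f for f in feats if f.kind == "duplication"]
        (a1, b1), (a2, b2) = f.intervals
        assert seq[a1:b1] == seq[a2:b2]

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 500)

    def test_infeasible_feature_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, 2000, [DuplicationSpec(5000, position=0)])


class TestPlantDefects:
    def test_snps_change_exactly_their_positions(self):
        truth, _ = generate_genome(4, 5000)
        defects = [SnpDefect(100 * i) for i in range(1, 50)]
        ledger = plant_defects(truth, defects, 4)
        diffs = [i for i, (a, b) in enumerate(zip(truth, ledger.draft))
                 if a != b]
        assert diffs == [100 * i for i in range(1, 50)]
        assert all(ledger.snp_draft[p] == truth[p] for p in diffs)

    def test_gap_defect_replaces_sequence_with_n_run(self):
        truth, _ = generate_genome(5, 5000)
        ledger = plant_defects(truth, [GapDefect(2000, 300, n_run=200)], 5)
        assert ledger.draft[2000:2200] == "N" * 200
        assert len(ledger.draft) == 4900
        assert ledger.draft[:2000] == truth[:2000]
        assert ledger.draft[2200:] == truth[2300:]

    def test_empty_defect_list_is_identity(self):
        truth, _ = generate_genome(6, 2000)
        ledger = plant_defects(truth, [], 6)
        assert ledger.draft == truth

    def test_overlapping_defects_fatal(self):
        truth, _ = generate_genome(7, 2000)
        with pytest.raises(ValueError, match="overlap"):
            plant_defects(truth, [DeletionDefect(100, 5),
                                  SnpDefect(102)], 7)


class TestSimulateReads:
    def test_depth_is_realized(self):
        truth, _ = generate_genome(8, 20000)
        pairs = simulate_reads(truth, FRAG, 8, depth=60, read_length=100)
        bases = sum(len(p.r1.seq) + len(p.r2.seq) for p in pairs)
        assert bases / len(truth) == pytest.approx(60, rel=0.05)

    def test_error_rate_is_realized(self):
        truth, _ = generate_genome(9, 20000)
        pairs = simulate_reads(truth, FRAG, 9, depth=30, read_length=100,
                               error_rate=0.01)
        mism = total = 0
        for p in pairs:
            for r in (p.r1, p.r2):
                ref = truth[r.t_start:r.t_start + len(r.seq)]
                mism += sum(a != b for a, b in zip(ref, r.seq))
                total += len(r.seq)
        assert mism / total == pytest.approx(0.01, rel=0.2)
        assert all(q == 20 for q in pairs[0].r1.quals)

    def test_same_seed_identical_reads(self):
        truth, _ = generate_genome(10, 5000)
        a = simulate_reads(truth, FRAG, 42, depth=10)
        b = simulate_reads(truth, FRAG, 42, depth=10)
        assert [(p.r1.t_start, p.r1.seq) for p in a] == \
            [(p.r1.t_start, p.r1.seq) for p in b]

    def test_zero_depth_fatal(self):
        truth, _ = generate_genome(11, 2000)
        with pytest.raises(ValueError):
            simulate_reads(truth, FRAG, 1, depth=0)


class TestProjection:
    def _sam(self, truth, ledger, tmp_path, seed=12, depth=30):
        pairs = simulate_reads(truth, FRAG, seed, depth=depth,
                               read_length=100, insert_mean=300,
                               insert_sd=30)
        lines = project_alignments(pairs, ledger, FRAG, 300, 30)
        path = tmp_path / "a.sam"
        write_sam(lines, ledger, str(path))
        return path

    def test_sam_is_parseable_and_internally_consistent(self, tmp_path):
        truth, _ = generate_genome(13, 10000)
        ledger = plant_defects(truth, [SnpDefect(5000),
                                       DeletionDefect(7000, 2)], 13)
        path = self._sam(truth, ledger, tmp_path)
        n = 0
        with pysam.AlignmentFile(str(path), "r") as fh:
            for a in fh:
                n += 1
                if a.is_unmapped:
                    continue
                q = sum(l for op, l in a.cigartuples if op in (0, 1, 4))
                assert q == len(a.query_sequence)
                assert len(a.query_qualities) == len(a.query_sequence)
                assert 0 <= a.reference_start < len(ledger.draft)
        assert n > 1000

    def test_clean_read_is_simple_match_and_proper(self, tmp_path):
        truth, _ = generate_genome(14, 10000)
        ledger = plant_defects(truth, [], 14)
        path = self._sam(truth, ledger, tmp_path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            recs = list(fh)
        assert all(r.is_proper_pair for r in recs)
        assert all(r.cigartuples == [(0, 100)] for r in recs)

    def test_reads_clip_at_misjoin_junction(self, tmp_path):
        truth, _ = generate_genome(15, 10000)
        ledger = plant_defects(truth, [MisjoinDefect(5000, 400)], 15)
        path = self._sam(truth, ledger, tmp_path)
        clips_at = []
        with pysam.AlignmentFile(str(path), "r") as fh:
            for a in fh:
                if a.is_unmapped or not a.cigartuples:
                    continue
                ops = [op for op, _ in a.cigartuples]
                if 4 in ops:
                    clips_at.append(a.reference_start)
        assert clips_at  # junction produces soft-clipped projections
        # clips concentrate around the junk interval [5000, 5400)
        assert any(4500 < p < 5500 for p in clips_at)

    def test_pair_spanning_draft_only_sequence_is_improper(self, tmp_path):
        truth, _ = generate_genome(16, 10000)
        ledger = plant_defects(truth, [MisjoinDefect(5000, 400)], 16)
        path = self._sam(truth, ledger, tmp_path)
        improper = 0
        with pysam.AlignmentFile(str(path), "r") as fh:
            for a in fh:
                if (not a.is_unmapped and a.is_paired
                        and not a.is_proper_pair):
                    improper += 1
        assert improper > 10

    def test_collapsed_copy_reads_pile_onto_kept_copy(self, tmp_path):
        truth, feats = generate_genome(17, 30000,
                                       [DuplicationSpec(5000,
                                                        position=10000)])
        ledger = plant_defects(truth, [CollapseDefect(10000, 5000)], 17,
                               features=feats)
        path = self._sam(truth, ledger, tmp_path)
        cov = np.zeros(len(ledger.draft))
        with pysam.AlignmentFile(str(path), "r") as fh:
            for a in fh:
                if not a.is_unmapped and a.is_proper_pair:
                    cov[a.reference_start:a.reference_end] += 1
        inside = cov[11000:14000].mean()
        outside = np.concatenate([cov[2000:8000], cov[18000:28000]]).mean()
        assert inside / outside == pytest.approx(2.0, rel=0.2)
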