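# burnish

Automated improvement of draft microbial genome assemblies and
comprehensive variant detection from aligned short reads.

Given a genome in FASTA (a draft assembly, or a reference to compare a
sequenced strain against) and one or more coordinate-sorted SAM/BAM files
of Illumina-style reads aligned to it, `burnish`:

- corrects single-base errors and small indels by quality-weighted pileup
  consensus;
- detects regions where the alignments contradict the genome's contiguity
  (soft-clip pile-ups, invalid-pair excess, coverage anomalies) and
  locally **reassembles** them with a De Bruijn graph built from reads
  anchored to the trusted flanks, repairing mis-assemblies and calling
  large insertions/deletions;
- fills captured gaps (N-runs between contigs in a scaffold) with the same
  local-reassembly machinery;
- flags large (>10 Kbp) collapsed repeats / segmental duplications from
  doubled fragment coverage (report only);
- emits a corrected FASTA, a VCF (small variants plus `SVTYPE=INS/DEL`
  records with fully assembled ALT sequences), a tabular changes ledger,
  genome-browser tracks (wig/bed), and a run summary.

## The model in brief

Each read base contributes evidence weight

```
w = Q_base · (1 − 10^(−MQ/10))
```

the Phred base quality scaled by the probability that the mapping is
correct. Only reads from *valid* pairs (the aligner's `PROPER_PAIR` flag)
or from unpaired libraries contribute allele evidence; counts of invalid
alignments and soft-clip boundaries are kept per position as mis-assembly
signals. From the weighted pileup every position is classified
**Confirmed** / **Changed** / **Ambiguous** / **Unconfirmed**; Changed
positions become corrections and SNP calls. Indel observations are shifted
to their leftmost equivalent placement (so every read supporting "delete
one C from `ACCCCT`" is pooled into a single event) and called by
valid-read majority, relaxed for longer events.

Local reassembly builds a De Bruijn graph (default K = 47) whose forward
links carry quality-weighted support and are pruned below five supporting
reads. Walks seeded with flank k-mers enumerate up to 2⁵ extensions per
side (five branch points); a region is replaced only when exactly one pair
of extensions shares a perfect overlap of at least 2K+1 = 95 bases. Tandem
repeats with period > K appear as walk loops; they are reported with their
period and never closed.

## Worked example

The package ships a deterministic simulator (`burnish.simulate`) used by
the test-suite; it also makes a self-contained demo:

```python
from burnish.simulate import (generate_genome, plant_defects, simulate_reads,
                              project_alignments, write_sam, write_fasta_string,
                              SnpDefect, GapDefect, MisjoinDefect)
from burnish import LibrarySpec, LibraryKind

truth, _ = generate_genome(seed=1, length=30000)
defects = [SnpDefect(2000), SnpDefect(5000), SnpDefect(7500),
           GapDefect(15000, 300, n_run=200), MisjoinDefect(20000, 400)]
ledger = plant_defects(truth, defects, seed=1)
frag = LibrarySpec(LibraryKind.FRAGMENT, "frag0")
pairs = simulate_reads(truth, frag, seed=1, depth=60, read_length=100,
                       insert_mean=300, insert_sd=30)
write_sam(project_alignments(pairs, ledger, frag, 300, 30), ledger, "frags.sam")
write_fasta_string("scaffold1", ledger.draft, "draft.fa")
```

```
$ burnish --genome draft.fa --frags frags.sam --output polished --changes
Mean total coverage: 59.1x
Confirmed 29654 of 30100 bases (98.52%)
Changes: snp=3, gap_fill=1, break_fix=1
```

The three planted single-base errors are corrected (`snp=3`), the 200-N
gap is filled with the 300 true bases hidden behind it (`gap_fill`), and
the 400 bp mis-join splice is excised by local reassembly (`break_fix`);
`polished.fasta` is byte-identical to the simulated truth genome, and
`polished.changes` lists every edit with source and destination
coordinates and sequences.

Variant-calling mode (`--variant`) writes an all-sites VCF against the
input genome instead; `--tracks` adds wig coverage/clipping tracks and a
features bed for genome browsers.

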