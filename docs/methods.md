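# Methods

This note documents the model, the tunable parameters, the numerical and
design choices, and what the synthetic fixtures do and do not demonstrate.

## Evidence model

All internal coordinates are 0-based half-open; conversion to 1-based
conventions happens once, in the serializers (VCF, wig, changes file).

A read base contributes allele evidence weight
`Q_base · (1 − 10^(−MQ/10))`: base quality scaled by the probability the
mapping is correct. The form is chosen so that MQ0 reads (placeable in
more than one location) contribute nothing, while their uniquely anchored
mates do — which is what lets long-insert pairs dominate repeat content
over fragment pairs trapped inside the repeat. Only *valid* reads
contribute allele evidence: members of proper pairs (the aligner's
`PROPER_PAIR` flag is taken as authoritative and never re-derived) and all
reads of unpaired libraries. The first and last `flank_trim` bases of each
read (default 5) are excluded from allele evidence but still count toward
valid coverage, because alignments near read ends confuse indels with
substitutions. Secondary, supplementary, duplicate and QC-fail records
are dropped entirely to avoid double-counting templates. Per position the
pileup also tracks: total coverage, invalid-pair coverage, soft-clip
boundary counts, physical (template) coverage, and deletion evidence.

### Base classification

With `f(a)` the weight fraction of allele `a` at a position of valid
coverage `v`:

- **Unconfirmed** — `v < min_depth` or no weighted evidence. The depth
  floor is `max(5, 0.1 × mean coverage)`, so high-coverage runs do not
  confirm bases on a handful of stray reads.
- **Ambiguous** — the second-best allele reaches `ambiguous_fraction`
  (default 0.25), or no allele reaches `changed_fraction`, or an exact
  tie. Ties are never broken arbitrarily.
- **Changed** — the top allele differs from the genome base and carries at
  least `changed_fraction` (default 0.75) of the weight.
- **Confirmed** — the genome base itself carries ≥ `changed_fraction`.

`QUAL = min(2000, 100·log10((1+w_top)/(1+w_rest)))` — a monotone, finite,
Phred-like contrast between the winning allele and everything else; `QD =
QUAL / v`. The fractions and the QUAL form are package choices (exposed on
the CLI); the classification semantics ("vast majority" vs. mixed
evidence) are the method's.

## Small indels

Raw alignment indels are left-normalized: a deletion shifts left while
`g[p−1] == g[p+L−1]`, an insertion while `g[p−1] == s[−1]` (rotating the
inserted string), which provably reaches the minimal equivalent
coordinate; the test-suite checks equivalence against a brute-force
placement-enumeration oracle. Normalized events pool support across
reads (distinct read names). An event is called when its support reaches
half the local valid coverage, relaxed to `long_indel_fraction` (0.35)
for events longer than 10 bases, since aligners under-report long indels.
The local coverage denominator for deletions is `valid + deletion-count`
averaged over the deleted footprint — reads carrying the deletion have no
aligned base in those columns but certainly span the site; insertions use
the flanking column. The step-at-10 relaxation schedule is a package
choice.

## Discontiguity scanning

Four heuristics seed suspicious positions:

1. soft-clip boundaries at ≥ 33% of covering reads (and ≥ 5 reads);
2. invalid-pair coverage ≥ valid-pair coverage (and ≥ 5 invalid);
3. valid coverage below 20% of the scaffold mean;
4. a coverage cliff: the mean over the next read-length window at most
   half the mean over the previous one. Window means (not single
   positions) are compared: at 60× a read-length window mean is accurate
   to a few percent, so sampling noise cannot fake a cliff, while a real
   breakpoint always produces a sustained drop.

Seeds within one modal read length merge into a region, padded by
`flank_trim`. Clusters of ≥ 3 Ambiguous calls within 50 bases also seed a
region (block substitutions reassemble better than they patch
base-by-base). Coverage-based seeding is suppressed within one insert
length of scaffold ends (coverage necessarily ramps there) and all
seeding is suppressed within a read length of N-gaps, whose boundaries
legitimately show clips and invalid pairs — gaps become reassembly
targets in their own right. All thresholds are invented calibrations of
qualitative criteria, fixed once so that clean 60× simulations produce
zero false flags, and exposed as configuration.

Deleted columns count as covered (`valid + deletion count`) so a genuine
small deletion is owned by the indel caller, not flagged as a coverage
hole.

## Local reassembly

For each target (flagged region or captured gap) reads are collected
from: (a) anything overlapping the region ± two read lengths, including
partial, soft-clipped alignments — these carry the trusted flank k-mers;
(b) fragment pairs with a read anchored to a flank pointing into the
region whose mate is unmapped or improperly mapped — both reads; (c) the
same situation in long-insert libraries — the unanchored mate only. The
pair-recruitment span per library is `insert mean + 3·sd`. Unmapped
records are retained at ingest precisely so these mates are available.

Reads enter the De Bruijn graph in both orientations, which makes flank
orientation handling implicit. Each k-mer node keeps a quality-weighted
pileup of following bases; forward links need ≥ `min_link_coverage` (5)
reads and ≥ `ambiguous_fraction` of the node's weight — one surviving
link is a call, two or more a branch. Walks from flank seed k-mers
(probing up to two read lengths back into the flank for a seeded k-mer
present in the graph) fork at branches up to `branch_limit` (5) branch
points, i.e. at most 2⁵ = 32 extensions per side; a path terminates at a
dead end, at the branch budget, or on revisiting a k-mer on its own path
(a loop — the signature of a tandem repeat with period > K; the period is
reported, the copy number is not called, and the region is never closed).
Loop detection is per-walk: sibling paths may legitimately revisit each
other's k-mers when haplotypes reconverge.

Left and right extensions are matched combinatorially for perfect
(exact-match) overlaps of ≥ 2K+1 bases (95 at the default K=47).
Because either walk may extend past the other side's anchor, matching
considers every alignment offset — candidate offsets are seeded with
exact 95-base windows and verified over the full overlap — and the merged
sequence always runs left anchor → right anchor. The region is replaced
only when exactly one distinct flank-to-flank sequence results; multiple
candidates or none fall back to consensus extensions. A consensus follows
positions where surviving extensions agree and takes the heavier branch
at divergences, stopping on exact weight ties (conservative: never
guess). Gaps are shrunk from each side by the consensus extensions
(capped at the gap length, with a minimum 10-base residual N-run);
non-gap regions without a unique closure are reported unresolved unless
`open_new_gaps` is set. Closed replacements never contain N.

## Duplication flagging

Fragment + unpaired valid coverage (long-insert coverage is excluded as
too variable) is averaged over 1 kb windows and compared to the
per-scaffold median window coverage. Runs of windows with ratio in
[1.5, 4.0) whose mean ratio reaches 1.8 and whose length exceeds 10 kb
are reported (never fixed). The two-threshold segmentation (extend at
1.5, report-mean 1.8) keeps a true doubled run intact across sampling
dips at 60×; the 4.0 break ratio makes a short high-copy element (an
IS-like repeat) interrupt a run, so a true duplication containing one is
reported as two pieces — a documented behavior, not a defect. Window
size and all three ratios are package calibrations of "double (or
higher) coverage over large contiguous areas".

## Outputs

FASTA is emitted uppercase at line width 70 (fixed for byte-exact
round-trip tests). The changes file is tab-separated with 1-based
inclusive coordinates (`p-p.` marks a zero-length insertion point); its
defining invariant is replay: applying the listed edits to the input
FASTA reproduces the output FASTA bit-exactly. VCF 4.2 records carry
`DP/VC/BC/QD` evidence fields; small indels use the anchor-base
convention; closed large events carry the fully assembled ALT with
`SVTYPE`/`SVLEN`; unresolved-but-extended regions are emitted as
imprecise symbolic records with the flank consensus extensions in INFO.
Reassembly edits take precedence over small fixes within their replaced
interval. The `--fix` gates (`bases`, `gaps`, `local`) control which
change categories are applied to the output genome.

## Synthetic fixtures

The simulator generates i.i.d. uniform ACGT genomes with planted repeat
features (tandem arrays, dispersed families with divergence, adjacent
duplications), derives a draft by planting defects (single-base errors,
small indels, N-run gaps of arbitrary placeholder length, mis-join
splices, large indels, collapsed duplications), and **projects** reads
simulated from the truth onto the draft through the defect ledger:
deterministic liftover with CIGARs derived from the planted defects.
Reads crossing draft-only sequence soft-clip at the junction (the longer
side wins, as a best-hit aligner would report); reads inside draft-absent
sequence go unmapped; pairs are proper exactly when both ends map in FR
orientation within ±3 sd of the library's insert mean (inserts are
sampled from a ±3 sd truncated normal, so all undisturbed pairs are
proper); reads fully inside multi-copy repeat features get MQ 2, all
others MQ 60. Base qualities are constant and consistent with the
substitution error rate (Q40 for error-free reads).

Default study conditions used by the test-suite: a 120 kb genome with 50
planted SNPs, 20 small (1–3 bp) indels, 5 captured gaps (300 bp hidden
behind 200-N runs), one 500 bp mis-join and one collapsed 15 kb
duplication, sequenced error-free at 60× with a 180–300 bp-insert
fragment library and 20× with a 3 kb long-insert library. On these
conditions the pipeline achieves 100% SNP/indel recall and precision,
closes the gaps with zero incorrect closures, repairs the mis-join and
flags the duplication. The genome size is chosen so the whole suite runs
in well under a minute; the algorithms are linear in genome length and
read count.

What the fixtures do **not** emulate: quality-by-cycle Illumina error
profiles, indel sequencing errors, GC-coverage bias, chimeric reads,
aligner-specific mismapping patterns, and real repeat structure at
genome scale. Passing these tests therefore demonstrates algorithmic
correctness under controlled discordance signals, not performance on
real sequencing data; the CLI accepts externally produced BAMs for that.

## Known limitations

- Haploid consensus only: no diploid genotype likelihoods, no
  heterozygous indel calling (Ambiguous positions are reported, and
  rewritten only under `--fix-ambiguous`).
- Scaffolds are never joined or broken; unresolved regions are reported
  for manual review.
- Tandem repeat copy number is not estimated; only the period is
  reported.
- A single polishing pass; iterating polish → realign → polish can
  recover defects masked by earlier ones.
- CRAM input and bgzip/tabix outputs are not supported.
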