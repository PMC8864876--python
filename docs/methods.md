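# Methods

## The problem

PacBio HiFi (CCS) reads are consensus sequences of circularized library
molecules. The 45 bp SMRTbell blunt adapter and the 35 bp C2 sequencing
primer are supposed to be removed on-instrument, but copies occasionally
survive into the delivered reads. When such reads enter a de novo
assembly, the adapter sequence can be integrated into contigs, producing
errant insertions, truncated duplicate contigs, chimeric mis-joins,
inverted duplications, or wholly spurious contigs. Because contaminated
reads are a tiny fraction of any dataset (well under 1%), the safest
remedy is to drop each contaminated read whole before assembly rather
than trim it — a read carrying an interior adapter may be a chimeric
molecule whose flanks do not belong together.

`ccsfilt` detects adapter copies inside reads with a strict local
aligner, removes contaminated reads whole, reports what it found, and
can apply the identical detector to assembled contigs as a pre-submission
check.

## Detection model

### Alignment

Adapters are located by exact Smith–Waterman local alignment (Gotoh
affine-gap recurrences) of each adapter, in both orientations, against
each read. The scoring scheme is the VecScreen-style strict regime used
for vector screening:

| parameter | value |
| --- | --- |
| match reward | +1 |
| mismatch penalty | −5 |
| gap of length k | 3 + 3k (a 1-base gap costs 6) |

Under this regime one mismatch erases five matches, so any alignment
with a meaningful score is nearly exact. That has two consequences we
rely on:

* No heuristics are needed. The DP is O(n·m) per orientation with
  m ≤ 45; a 10 kb read scans in ~10 ms. There is no seeding, banding,
  X-drop, or E-value machinery. (E-value-based reporting cutoffs used by
  BLAST-style tools are dominated here by the downstream length/identity
  thresholds, so they are not emulated.)
* Random 10 kb background sequence essentially never produces a passing
  hit, which the specificity tests confirm on thousands of clean reads.

The kernel is a rolling-row numba routine that returns the optimal score
and the read interval of one optimum (tracking alignment start positions
through the recurrence); column-level counts (matches, mismatches, gap
opens, aligned columns) are then recovered by a full traceback restricted
to that interval, which is at most ~60 bp wide. An assertion checks the
traceback reproduces the kernel's score. `N` (and any non-ACGT code)
scores as a mismatch against everything, including itself; no masking of
low-complexity sequence is performed. Correctness is tested against an
independent exhaustive oracle that enumerates local alignments as
monotone chains of aligned pairs, and against `blastn` run with the same
scoring parameters on spiked fixtures.

Ties between equal-scoring alignments are broken toward the smaller read
start, then the smaller interval; traceback prefers diagonal moves, then
read-consuming gaps, then adapter-consuming gaps, and closing a gap over
extending one. These choices make outputs bit-reproducible.

### Multiple hits

All hits in a read are needed (positional classification distinguishes
one 5′ copy from copies distributed across the read), so discovery per
(adapter, orientation) iterates: take the best local alignment, mask its
read interval with a code that matches nothing, and repeat while the best
score clears a reporting floor. At default thresholds the floor is 20.
When the `-l`/`-m` overrides relax the acceptance thresholds, the floor
is lowered to the worst score a just-passing hit could have
(`ceil(L·M/100)` matches with every other column a 1-base gap), so
relaxed settings actually surface the weaker alignments they are meant to
accept. Masked-interval hits are non-overlapping within each
(adapter, orientation) because an optimal local alignment never starts or
ends on a penalized column.

### Acceptance thresholds

A hit passes when `alignment_columns >= L` and `identity >= M`:

| adapter | length | default L | default M |
| --- | --- | --- | --- |
| SMRTbell blunt adapter | 45 bp | 44 | 97% |
| C2 primer | 35 bp | 34 | 97% |

i.e. at most one missing base and ~one substitution. CLI overrides
(`-l`, `-m`) replace the per-adapter defaults uniformly across all
adapters. User-supplied adapters from `--adapter-fasta` get the same
one-missing-base pattern: L = length − 1, M = 97%. A read with any
passing hit is blocklisted; identity is `100·matches/columns` with gap
columns counted in the denominator.

### Positional classification

Each blocklisted read is categorized by where its passing hits fall.
A hit is 5′ if it starts within the first 10% of the read, 3′ if it ends
within the last 10%, internal otherwise; a hit qualifying for both ends
(only possible on very short reads) counts as 5′. If all hits share one
zone the read takes that category; otherwise it is `distributed`. Reads
whose passing hits cover more than 80% of the read are adapter-dimer-like
artifacts and are reported as `other`. The 10% end-zone fraction and the
80% coverage threshold are package choices — published descriptions of
the four categories are qualitative — and both are exposed in
`FilterConfig`. Classification is reporting only; it never affects which
reads are removed.

## Whole-read removal

Filtering is record selection, not re-serialization: the FASTQ/FASTA
input is re-read as raw record text and surviving records are copied
byte-for-byte (BAM input is emitted as FASTQ, since the container
changes anyway). Read ids are matched exactly and completely — never by
prefix — and duplicate ids in the input are fatal, since id-based removal
is ill-defined under collisions. Gzip output omits the timestamp and
filename fields so identical content gives identical bytes.

## Contig screening

`screen` applies the same detector with the same thresholds to assembly
FASTA. Contigs are scanned in 1 Mb windows with a 100 bp overlap
(more than twice the adapter length, so a boundary-straddling hit is
always fully contained in some window); window hits are mapped back to
contig coordinates and de-duplicated. The command exits 3 when any
contig has a passing hit, for pipeline gating. Remediation is left to
the user: dropping, splitting or masking contaminated contigs each harm
the assembly in a different way, which is the argument for filtering
reads before assembly in the first place.

## Synthetic data generator

`simulate` produces HiFi-like pools with known contamination so the whole
pipeline is testable without downloads. What it emulates, and defaults:

* read lengths: normal(10 kb, 3 kb) rounded, floored at 500 bp —
  typical HiFi length scale;
* background: i.i.d. bases at 40% GC; constant quality `U` (Q52);
* contamination rate 0.25% — the ceiling observed across surveyed public
  HiFi datasets (tests override this upward to get usable counts);
* orientation: 89.6% of spiked copies reverse-complemented, matching the
  surveyed orientation split;
* position categories weighted 5′ 0.45, 3′ 0.25, internal 0.20,
  distributed 0.10 — the surveyed abundance order (5′ most, distributed
  fewest); the exact weights are a package choice, as only the order is
  reported;
* distributed reads carry 2–4 copies in distinct zones; placement ranges
  are buffered by one adapter length so copies never overlap;
* spiked copies replace read bases (read-length distribution is
  independent of contamination), optionally degraded by per-base
  substitutions.

One seeded generator drives everything, consumed in a fixed order (read
lengths, read bases, spiked-read selection, per-spike decisions), so a
config is reproducible to the byte. The spike count is exactly
`round(n_reads x rate)`, which makes recall/specificity and proportion
checks exact rather than statistical when the error rate is 0.

What the generator does not emulate: CCS error profiles (pass-number
dependent indels), quality-value variation, repeat structure, and the
empirical length–contamination coupling seen in real data (contamination
enriched in very short and ~10 kb reads). Passing spike-in tests
therefore demonstrate detector correctness on near-exact adapter copies
in random background — the regime the strict scoring targets — not
performance on repeat-rich genomes, where a 44/45-at-97% match remains
equally discriminative but the background model is unrealistic.

## Numerical and interface choices

* Lowercase bases are preserved on output but uppercased for alignment;
  no dust/soft-masking is applied.
* Reads shorter than an adapter pass through trivially (no ≥44-column
  hit can exist).
* Medians in reports use the lower-median convention for even counts;
  proportions are printed with 6 decimals; GC excludes N from numerator
  and denominator.
* `-t/--threads` is accepted and recorded in the run manifest, but
  scanning is single-threaded in this implementation; the determinism
  contract (outputs independent of `-t`) holds trivially. The per-read
  scan is embarrassingly parallel if throughput ever demands it.
* Every run writes a JSON manifest (resolved options, inputs, outputs,
  timestamps, status) sufficient to reproduce the command.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to keep
full runs fast while preserving the statistical meaning of each check:
oracle comparisons use 2,000+ exhaustive short-pair alignments; spike-in
recall/specificity uses 1,000 reads at default 10 kb lengths across five
seeds (200 exact spikes each, recall 1.0, zero false positives);
orientation recovery uses 500 spiked reads at 2 kb (the share is a
property of spike bookkeeping, not read length); the contamination
proportion demonstration uses 2,000 reads at the 0.25% default (5 spiked
reads, recovered exactly).

## Known limitations

* Only substitution-degraded spikes are simulated; indel-degraded
  adapter copies are handled by the aligner (gap costs are tested) but
  not generated.
* The four positional categories use one defensible quantitative reading
  of qualitative published descriptions; other zone boundaries would
  shuffle counts between categories without affecting filtering.
* IUPAC ambiguity codes other than N in adapters are not supported.
* Screening is limited to the two bundled PacBio contaminants plus any
  user-supplied FASTA; it is not a general UniVec screen.
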