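# Methods

## Model

`kmerlca` implements exact-*k*-mer taxonomic classification.  The premise
is that for a suitably large *k* (default 31), most *k*-mers occurring in
sequenced genomes are specific to a single species, so a database mapping
each *k*-mer to the lowest common ancestor (LCA) of all genomes containing
it provides strong, cheap evidence about a read's origin.  Classification
then has to reconcile the disparate LCA taxa returned by a read's *k*-mers:
the hit taxa plus their taxonomy ancestors form a pruned *classification
tree*, each node weighted by the number of read windows whose stored LCA
is exactly that taxon, and the read takes the label of the leaf of the
maximum-weight root-to-leaf path (ties resolve to the LCA of the tied
leaves).  This lets a small minority of stray hits — conserved sequence,
contamination — be outvoted by the dominant lineage, while a read whose
evidence is genuinely split backs off to a coarser (ancestral) label
rather than guessing.

Assumptions worth stating: taxon IDs fit 4 bytes (matching the record
payload); the taxonomy is a single rooted tree with free-form rank
strings, of which the seven named ranks (species … kingdom) are used for
rank-level queries; *k*-mer evidence is counted per window occurrence, so
a *k*-mer repeated within a read contributes weight each time it occurs.
That last choice is genuinely open — evidence could equally be counted
once per distinct *k*-mer — but per-occurrence counting matches the view
of each window as an independent observation and keeps the weight total
equal to the number of found windows.

## Database layout and numerical choices

Records are 12 bytes (8-byte canonical *k*-mer code, 2 bits per base;
4-byte LCA taxon ID, with 0 reserved for "absent").  Integer comparison of
equal-length codes coincides with lexicographic string comparison, so
canonicalization (min of *k*-mer and reverse complement) runs entirely on
integers.

Records are bucketed by *minimizer*: the canonical *M*-mer of the *k*-mer
whose XOR-scrambled code is smallest.  Plain lexicographic minimizers pile
low-complexity *M*-mers (poly-A) into enormous buckets; XOR-ing a fixed
constant before comparison scrambles the order and flattens the bucket
distribution.  Which bits to toggle is a free choice: the default constant
is the alternating pattern `0101…01` over 2·M bits, which toggles exactly
half the bits; it is stored in the database header so files are
self-describing, and `scramble=0` disables scrambling.  Minimizers are
computed on the canonical *k*-mer; because the canonical *M*-mer candidate
set of a *k*-mer equals that of its reverse complement, the result is
strand-invariant and the implementation may scan either strand.  Ties
among equal scrambled values take the leftmost occurrence — only the value
matters for bucketing, so any deterministic rule is equivalent.  Within a
bucket, records are sorted by unscrambled canonical code; the scrambled
value orders buckets only.

The offset index has 4^M + 1 entries so each bucket is a half-open range
(the final entry is the record count); on disk that is 8·4^M bytes plus
one 8-byte sentinel, after a 20-byte header (magic, version, k, M, pad,
scramble, record count; all little-endian).  The dense index makes the
declared default of M = 15 an 8.6 GB array, appropriate for server-scale
libraries; the benchmarks in this repository use M = 9–11 (index 2–34 MB),
chosen the same way a memory-constrained deployment would choose M = 13.
M is fixed at build time and never changed by shrinking.

Queries carry a cursor holding the previous bucket range: (1) binary-search
that range; (2) on a miss, recompute the minimizer — if unchanged, the miss
is definitive; (3) otherwise fetch the new range and search it.  The
cursor only saves work; answers are identical with or without it, which
the tests check by replaying query streams in permuted order.

Database construction enumerates every distinct canonical *k*-mer
internally (vectorized window encoding + sort/unique; windows containing
non-ACGT characters are skipped), folding the LCA over all contributing
taxa.  The result is independent of sequence processing order — permuting
the library yields byte-identical files.  Optional contamination
filtering removes *k*-mers occurring in known adapter sequences outright,
and suppresses the first and last 20 *k*-mer windows of draft contigs; a
*k*-mer trimmed from a contig edge survives if it also occurs in an
untrimmed region (the choice is documented, not claimed canonical).

Shrinking partitions the globally sorted record array into consecutive
blocks of `factor` (default 19) and keeps the last record of each complete
block, dropping a trailing partial block; retained records keep their
payloads and the offset index is rebuilt.  Keeping "the last of each 19"
realizes the same 19-fold reduction as removing the first 18.

## Error model of the read simulator

Reads carry position-dependent substitution errors plus uniform indels.
The per-position substitution probability follows an exponential ramp
p(t) = begin + (end − begin)·(e^{at} − 1)/(e^a − 1) between the
read-start rate (default 1%) and read-end rate (default 6%), with the
shape parameter *a* solved by root-finding so the positional average
equals the target mean (default 2%) to ~1e-12; insertions and deletions
each default to 0.5% per base.  The true positional error curve of real
instruments is not recoverable from three summary statistics, so the ramp
is an explicit, calibrated stand-in that reproduces exactly those summary
statistics (begin, end, mean) without pretending to model a specific
platform.  Indels are applied to the template first; the read is then
truncated/padded to its nominal length and substitutions imposed along the
read as synthesized.  Substitutions always change the base (uniform over
the other three), so observed mismatch fractions estimate the configured
rate directly.

Genome divergence is two-tier: species genomes diverge from an
independent random genus-ancestor genome (default 2% SNPs, 0.2% indels —
enough that ≈(0.98)^31 ≈ 53% of 31-mers are shared between congeneric
species, the property clade-exclusion experiments rely on), and reads are
drawn from a strain genome further diverged from the database genome by
0.1% SNPs and 0.1% indels, the common read-simulator default.  A
"zero-error" configuration zeroes both the read error profile and the
strain divergence, yielding reads that are exact substrings of database
genomes; the generator consumes its per-species seeds unconditionally so
the error-free variant uses the *same* genomes as the error-bearing one.

What the generator does not emulate: real genome repeat structure and
shared mobile elements (i.i.d. genomes make cross-genus *k*-mer collisions
vanishingly rare, which the benchmark verifies explicitly rather than
assumes), GC-dependent coverage bias, quality-score information (qualities
are constant placeholders; the classifier ignores them), and realistic
taxonomic breadth — the synthetic taxonomies have complete seven-rank
lineages, so code paths for genomes lacking a rank are exercised only by
dedicated unit fixtures.  Passing benchmarks therefore demonstrate the
correctness of the machinery and the qualitative accuracy signature of
exact-match classification, not absolute accuracy on real metagenomes,
where conserved sequence depresses precision and database incompleteness
depresses sensitivity further.

## Evaluation conventions

Sensitivity at a rank is A/B; precision is C/(D+E) (see README).  Reads
whose origin lacks the measured rank are excluded from all tallies (the
"correct taxon at the rank" is undefined for them); unclassified reads
count only in the sensitivity denominator.  A label above the measured
rank on the correct lineage — including a root label — affects no tally.
Clade-exclusion runs skip reads whose origin lacks either rank, and
require at least two other excluded-rank taxa represented in the database
(library taxa and their ancestors, not the record array) to share the
origin's measured-rank ancestor; with fewer, no classifier could recover
the measured rank once the clade is masked.  Masking applies to the
stored LCA value of each hit — per-genome provenance is not stored — so a
hit is suppressed when its LCA lies inside the excluded clade.

## Problem sizes

The shipped benchmark uses ten 100 kb genomes in ten genera with 10,000
100-bp reads (≈1M database records), a scale at which the full pipeline —
generation, build, three classification passes and scoring — completes in
about a minute on one core while leaving every qualitative effect
(error-driven sensitivity loss, shrink-driven sensitivity loss without
precision collapse, near-total clade-exclusion precision) comfortably
measurable.  The clade-exclusion fixture uses five genera of three species
at 30 kb.  These sizes are the package's own benchmark conditions; all of
them are plain `BenchmarkConfig` fields.

## Known limitations

Single-threaded; databases must fit in memory; no confidence scoring or
abundance re-estimation; merged/deleted taxonomy nodes are not resolved
(inputs must be self-consistent — taxa present in the sequence map but
absent from the taxonomy are an error, not silently remapped); the on-disk
format is this package's own and deliberately not compatible with other
tools' database files.
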