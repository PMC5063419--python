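# Methods

## The problem

Small RNAs (miRNAs, siRNAs, piRNAs) are shorter than a sequencing read, so
every full-length small RNA read continues into the 3′ adapter that was
ligated before sequencing. Downstream analysis requires removing that
adapter, but public repositories often lack the adapter sequence in their
metadata, record it incorrectly, or contain libraries whose adapters were
already removed. `srnadapt` infers the adapter directly from the reads and,
when a reference genome and mapper are available, validates the inference by
the genome-mapping rate of the clipped reads.

## Prediction model

The core assumption: in an unprocessed library most reads contain the 3′
adapter or a prefix of it, so adapter-derived k-mers dominate the k-mer
frequency spectrum of a read sample.

Single mode, for one setting (k, R):

1. **Count** all k-mers over the first N reads (default N = 50,000, file
   order). Windows containing N bases are excluded from both the counts and
   the window total, so ambiguous bases cannot deflate scores.
2. **Low-complexity filter**: discard any k-mer containing a homopolymer
   run of length ≥ ⌊k/2⌋ (k = 9 → runs of 4). Homopolymer artifacts such as
   fragmented poly(A) recur across reads as strongly as a real adapter
   would. ⌊k/2⌋ rather than ⌈k/2⌉ is the stricter reading and removes the
   4-base runs that dominate low-complexity artifacts at the default k;
   a consequence is that homopolymeric adapters (e.g. poly(A)-tailed
   protocols) are out of reach by construction (see Limitations).
3. **Ratio filter**: with f(S) the count of the most abundant surviving
   k-mer, keep exactly the k-mers s with f(S)/f(s) ≤ R. The boundary is
   inclusive: a k-mer exactly at the ratio survives. The comparison is
   computed as the division `f(S)/f(s) ≤ R`, matching the definition of the
   ratio r (the algebraically equivalent multiplied form can disagree at
   the boundary in floating point).
4. **Assembly**: chain surviving k-mers by perfect (k−1) suffix–prefix
   overlap. The strategy is greedy chain extension: seed at the
   highest-count unused k-mer; extend rightward while any unused k-mer's
   (k−1)-prefix equals the chain suffix, picking the highest count (ties:
   lexicographic); extend leftward symmetrically; repeat. Each k-mer joins
   at most one chain, so overlap cycles terminate. On overlap graphs that
   are disjoint unions of simple paths — the expected shape when the
   k-mers come from one adapter — greedy extension is exact, which the
   test suite verifies against brute-force enumeration.
5. **Scoring**: each chain scores (Σ member counts) / (total window count
   of the run, *before* filtering). Normalizing by the pre-filter total
   makes scores comparable across runs with different k, which the
   iterative tally relies on. The top-scoring chain is the putative
   adapter. Ties are broken toward the lexicographically smaller sequence
   for cross-platform determinism.

Iterative mode runs single mode over a grid (default k ∈ {9, 11},
R ∈ {1.2, 1.3, 1.4}; the per-k count table is computed once and re-filtered
per R) and re-ranks candidates by the *sum* of their normalized scores over
all runs. Identity is exact string equality: a shorter assembled sequence is
not merged into a longer one containing it, because prefix-merging is an
extension with no principled weight assignment; the grid is configurable
(e.g. add k = 8 for very short adapters). With a singleton grid the
iterative result equals the single-mode result exactly.

The predicted adapter is reported as the full assembled chain, untruncated:
clipping uses only its 7-mer prefix, so over-assembly into the adapter body
is harmless. A prediction "matches" a reference adapter when the shorter of
the two is a prefix of the longer with at least 9 nt of overlap — prefix
agreement is exactly what clipping requires.

## Exhaustive mode

After removal of the correct adapter, the remaining inserts are genuine
small RNAs and should map to the reference genome at a high rate; the
mapping rate therefore selects among candidates without any metadata. For
every (k, R) in the grid the top candidate is collected (top-1 per run;
deduplicated by exact string equality to avoid redundant mapper runs), each
candidate is clipped and the clipped reads are mapped with a user-supplied
shell command (`{input}`/`{output}` placeholders, SAM output; mapping
strictness, such as "no mismatches", lives inside the user's template). The
raw, unclipped reads are mapped as an additional RAW arm.

Clipping searches the *leftmost* exact occurrence of the candidate's 7-mer
prefix — the adapter junction is the first place the prefix can occur, and
leftmost minimizes retained adapter sequence. Only clipped inserts of at
least `min_insert` (default 16 nt, the lower edge of real small RNA sizes)
are submitted to the mapper; adapter-dimer reads (junction at position 0)
are counted as clipped but never mapped. Both the clipped and the mapped
fraction use the number of sampled input reads as denominator, so
"mapped ≤ clipped" always holds and the two numbers are directly
comparable per library. Mapped reads are primary SAM records that are not
unmapped, secondary, or supplementary (flags 0x4, 0x100, 0x800), parsed
with pysam.

Decision rules:

* **optimal adapter** — the clipped candidate with the highest mapped
  fraction (ties: higher clipped fraction, then lexicographic);
* **quality flag** — if the governing mapping rate (optimal candidate's,
  or RAW's for a processed library) is *below* 20% the library is flagged
  as poor; 20% exactly passes. Warnings do not change the exit status — a
  warning is advice, not failure — and `--strict` upgrades them to exit 3
  for pipelines;
* **already processed** — RAW mapping at least as well as the best clipped
  candidate *and* clearing the 20% line means the adapters were evidently
  removed upstream; the library is reported ready-to-map. The ≥-and-≥-20%
  rule keeps the mapping rate as the sole arbiter while preventing a
  garbage library (everything maps at 1%) from being called processed.

## Quality trimming

Mott trimming (the 3′ trimmer of BWA/cutadapt) is available but **off by
default**: adapter prediction is empirically better on raw reads, because
trimming removes exactly the low-quality 3′ tails where the adapter lives.
When enabled (`--trim-quality 10|20`), the sample is taken first and
trimmed second, so the sample window is defined on the raw file. The
algorithm scans from the 3′ end accumulating Σ(cutoff − qᵢ) and truncates
at the maximum positive value; ties are broken toward the 3′ end (retain
more bases, preserving adapter signal — the choice is otherwise arbitrary).
A fully trimmed (empty) read is returned empty and filtered by the caller.
The Phred offset is auto-detected by the minimum-code rule (any code < 64
implies offset 33), overridable by flag since older libraries mix
encodings.

## Synthetic libraries

`srnadapt.simulate` generates the study conditions for all tests: a
uniform random toy genome (default 10 kb) and libraries of 36-cycle reads
built from four classes — **adapter** reads (genomic insert of 18–26 nt +
optional 4-nt barcode + adapter, padded with random bases when short of
the cycle count), **abundant** reads (one fixed species per library,
emulating highly sequenced small RNAs), **dimer** reads (pure adapter
concatenations, the ligation-product failure mode), and **genomic** reads
(full-cycle genomic sequence: both already-processed libraries and
long-insert dropout). Class counts follow a largest-remainder quota (exact
to ±1 read); all randomness flows from one NumPy PCG64 stream per library,
so identical specs give byte-identical FASTQ and manifests. Per-cycle
Phred means decline linearly (defaults 38 → 30, Gaussian sd 2, clamped to
[2, 40]) — the early-vs-late platform contrast can be emulated by lowering
the means, without modeling any specific instrument.

Random ground-truth adapters are generated with homopolymer runs capped at
3: real adapter oligos are designed, complexity-screened sequences, and an
unconstrained random string would (with probability ≈ 0.3 at 20 nt)
contain a run that the low-complexity filter is explicitly built to
discard — a property no vendor adapter has.

The exact-match stub mapper reports a read as mapped iff it or its reverse
complement occurs exactly in the genome, emitting minimal valid SAM; it
plays the role of a strict no-mismatch aligner in offline tests.

What the generator does **not** model: sequencing errors, instrument-
specific quality-string structure, multiplexed pools needing
de-multiplexing, chimeric or partially degraded adapters. Passing tests
therefore show correctness of the algorithmic pipeline under clean,
known-truth conditions, not robustness to every artifact of real data.

## Evaluation conditions

`srnadapt.benchmark` fixes the self-evaluation batches used by the test
suite and `scripts/acceptance.py`: 20 libraries per recovery batch, each
with its own 10-kb genome and distinct random 20-nt adapter, 50,000 reads
(the predictor's sampling window), adapter fraction 0.8 (0.7 + 0.3
abundant in the contamination batch; barcode length 4 in the barcoded
batch). Mapping-based batches (processed-library detection: 10 adapter-free
and 10 adapter-bearing fixtures; quality probes) use 20,000-read
libraries, which keeps a full exhaustive run to a couple of seconds per
library without changing any per-read statistic. A recovery hit is a
≥ 9-nt prefix match against the ground-truth (barcoded) adapter.

## Limitations

* Homopolymeric adapters (poly(A)-tailing protocols) are filtered out by
  design and cannot be predicted.
* Libraries dominated by adapter dimers violate the frequency assumption:
  the dimer junction k-mers can outscore the true junction.
* Libraries whose inserts exceed the read length carry no adapter signal;
  only the exhaustive mode's low mapping rate will flag them.
* Adapters shorter than k cannot be represented by a single k-mer; the
  grid is configurable (add a smaller k) but the defaults assume adapters
  of ≥ 9 nt usable prefix.
* Clipping is exact-match over a 7-mer prefix; sequencing errors inside
  the junction 7-mer leave the adapter in place. Mismatch-tolerant
  clipping is deliberately out of scope — dedicated trimmers do it well
  once the adapter is known.
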