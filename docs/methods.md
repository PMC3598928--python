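# Methods

## Problem and model

Short-read mapping locates each read (here up to 100 bp, single- or
paired-end) on a reference genome, tolerating sequencing errors. bandmap
follows the seed-and-extend strategy: exact 15 bp matches (seeds) between
read and genome nominate candidate diagonals, and a banded semi-global
alignment verifies each candidate.

The alignment model is a unit-cost edit distance — 0 per match, 1 per
mismatch or indel — computed semi-globally: the read must align end to
end, leading and trailing reference gaps are free (initialisation
`S(i,0) = 0`, `S(0,j) = j`; the optimum is the minimum over the last read
column). The band restricts cells to `|i - j| <= d` with `d = 1`
throughout the production engine, so at most one net indel is
representable; this matches the error regime the threshold enforces
("at most one indel, the rest substitutions"). A read of length `L` is
accepted when its score is at most `floor(L x (1 - identity))`,
`identity = 0.90` by default (a 36 bp read may carry 3 errors, a 76 bp
read 7, a 100 bp read 10).

## Block decomposition

Within the band, read column `j` touches three cells — the upper
(`i = j-1`), main (`i = j`) and lower (`i = j+1`) diagonals. The band is
cut into consecutive, non-overlapping v-shaped blocks: a head of 4 read
columns, then blocks of 8 (twelve such blocks cover a 100 bp read; the
12 bp illustration geometry — no head, three 4-wide blocks — is available
through `BandedParams`). Each block reduces to a 3 x w match/mismatch
matrix; cells whose reference base does not exist (outside the window or
the genome) are unreachable.

Each block is scored on its own: the best within-block path cost to each
exit diagonal, as the triple `(S_u, S_m, S_l)`, with the entry
("start-location") diagonals that achieve each exit recorded as label
sets (ties keep all labels). Block scores are then concatenated over a
balanced tree: each exit of the right block adds the best left-block exit
among its start labels, partial sums above the threshold are pruned to
the sentinel x (an absorbing infinite cost), and the final score is the
minimum over the three exits of the fully concatenated triple. The cost
model `estimate_cycles` counts `block_width` lockstep steps plus
`ceil(log2(blocks))` concatenation steps for the parallel scheme versus
one step per read column sequentially.

Two concatenation modes exist:

- **heuristic** — one score per exit with start labels, the formulation
  the original hardware uses. When the minimising entries of different
  continuations diverge it can overestimate (never underestimate: any
  returned score is the cost of a realisable banded path).
- **exact** (default) — each block carries its full 3 x 3 entry-to-exit
  min-plus transfer matrix; composition is associative and the result
  provably equals the conventional banded DP. The production kernel
  sweeps the same recurrence column by column over the genome (optionally
  numba-compiled); tests verify kernel == transfer-matrix composition ==
  banded DP on exhaustive small inputs.

Entry states: the full alignment starts at the origin (main diagonal,
cost 0) and, per the semi-global model, may enter the lower diagonal at
cost 0 (one free leading reference gap) when that reference base exists.
The hardware-style heuristic initial block starts at the origin only, with
the lower diagonal reachable through a cost-1 vertical move — hence an
all-match block scores (1, 0, 1) with all start labels `m`.

## Dual engines and window boundaries

Seeds vote for a single diagonal, but an alignment with a leading indel
needs one reference base outside the candidate window. Every candidate is
therefore scored twice — at its window and one base to the left — and the
better engine wins (ties favour the normal engine). The lower-diagonal
exit of the last column consumes one base *right* of the window; that
base is read from the genome when it exists. When it does not (window at
the genome end), the exit is treated as unreachable rather than charged a
mismatch: charging a mismatch could report a score lower than any
realisable alignment on the true, truncated region, i.e. a false
positive. With this choice the engine equals the banded DP run on the
true boundary-widened (or truncated) region, which the tests assert.

Candidate diagonals left of the genome start are clamped to 0; the
missing reference coverage then surfaces as unreachable cells and gap
charges inside the engine, never as fabricated bases.

Reported positions are the window start of the winning engine (the
position of the read's first aligned base up to the one-base uncertainty
a single indel introduces, well inside the +/-5 bp evaluation rule).
The engine reports scores and positions, not tracebacks, so SAM output
uses a `<read_len>M` CIGAR with the edit cost in the `NM` tag and MAPQ
255 (no mapping-quality model is defined).

## Seed index

Geometry: seed length 15 (packed big-endian, 2 bits per base, A=0, C=1,
G=2, T=3 — chosen so complementing is XOR 3), prefix 16 bits, suffix 14
bits, hash 12 bits; 2^28 addressable slots. Per-bucket H3 matrices
(suffix_bits rows x hash_bits columns) are drawn once from the index's
`rng_seed`, so an index is bit-reproducible from (genome, config). The
primary table is stored sparsely (slot -> 32-bit entry) with semantics
identical to the dense layout, which would cost 1 GiB regardless of
genome size; an entry packs as `c:1 | count:7 | ptr:24`. Count is the
total number of positions in the slot, whether they come from one
repeated seed or from distinct seeds colliding in the bucket; slots
beyond the 7-bit cap (127) keep their first 127 positions and are
reported in the build log. Genomes are limited to 2^24 bases by the
24-bit position fields. Only the forward strand is indexed; reads are
queried in both orientations (the staged read carries forward and
reverse-complement codes, 4 bits per base total — 400 kbit for a
1,000-read chunk of 100 bp reads). The index file embeds the 2-bit-coded,
N-resolved genome so that alignment needs no separate FASTA.

Seeding uses every read offset by default (stride 1, final offset always
included); hits are merged per (read, strand, diagonal) since duplicate
seeds on a diagonal would repeat identical extension work.

## Pairing

Both ends are aligned independently. Proper pairs require opposite
strands in forward/reverse orientation and an outer distance (leftmost
base of the left end to rightmost base of the right end, the wgsim
convention) within `D +/- k*sd`; `k = 3` captures ~99.7% of
normally-distributed inserts. When no cross-combination qualifies, the
best-mapped end anchors a windowed Smith–Waterman rescue of its mate
(both orientations, window of length `2*k*sd + read_len` placed by the
insert model, unit scores +1/-1/-1 through Biopython's PairwiseAligner);
a rescue is accepted at score >= `(2*identity - 1) * read_len`,
i.e. ~90% identity by default. The rescue's edit cost is estimated from
its SW score as `(L - score + 1) / 2` for ranking. One best pair is
reported per read pair (rank: combined score, then insert deviation,
then leftmost position).

## Simulator

The generator emulates wgsim's sampling: uniform start positions,
uniform strands, i.i.d. substitutions at `err_rate`, and at most one
1 bp indel per read with probability `indel_prob`. Defaults follow the
study conditions this package targets: 4% substitution error, paired
outer distance Normal(200, 20), read lengths 76–100 bp. `indel_prob`
defaults to 0.01, the rate wgsim's default mutation settings (rate
0.001/base, 15% of mutations indels) imply at these read lengths; the
single-indel cap matches the aligner's one-gap regime — multi-indel
reads are unalignable by design. Paired mode flips a fair coin for which
fragment end becomes read 1, as wgsim does. Truth (0-based leftmost
position, strand, error counts) travels in a TSV sidecar; a parser for
wgsim's name-encoded convention is provided for real wgsim output.

What the simulator does *not* model: sequencer-specific error profiles,
quality values (the aligner ignores them), coverage biases, repetitive
genome structure (random genomes are nearly repeat-free). Passing the
end-to-end tests therefore demonstrates correctness of the machinery
under the stated error model, not performance on real, repeat-rich
genomes.

Evaluation follows the +/-5 bp rule: an aligned read is correct when the
strand matches and the reported position is within 5 bp of truth;
sensitivity = aligned/total, accuracy = precision = correct/aligned,
recall = correct/total, F = harmonic mean of precision and recall.

## Numerical and design choices

- x (pruned/unreachable) is the integer sentinel `1 << 40`, absorbing
  under addition within the scores used here and ignored by min.
- Hit deduplication keys on (strand, position) keeping the minimum
  score; primary hits order by (score, position, strand).
- Results are independent of chunk size; chunking only bounds memory.
- Determinism: every random stream (genome, reads, N-resolution, H3
  matrices) derives from an explicit seed; rerunning a command with the
  same inputs and seeds reproduces output files byte for byte.
- Problem sizes in the test suite (genomes of 5–100 kb, 10,000 reads in
  the end-to-end check, exhaustive oracle sweeps to 8 bp plus 1,000
  random pairs to 96 bp) were chosen to exercise every code path and
  statistical claim at desk scale.

## Known limitations

- Band width is fixed at 1 in the block engine (the oracle accepts any
  d); alignments needing two or more net indels are rejected by design.
- No traceback/CIGAR with indel placement; positions carry a one-base
  uncertainty when an indel precedes the first aligned base.
- Single-contig references only, up to 2^24 bases (24-bit positions).
- Multi-mapping reporting is all threshold-passing hits (or `--best`);
  there is no mapping-quality model.
- The rescue edit-cost estimate from the SW score is approximate when
  the local alignment clips read ends.
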