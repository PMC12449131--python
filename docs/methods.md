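# Methods

## Scoring model

`actalign` computes local (Smith–Waterman) alignments under a two-valued
substitution function — `match_score` on identical residues,
`mismatch_score` otherwise — and Gotoh-style gap states. `gap_open_extend`
(Goe) is the cost of a gap's first position (open and extend combined);
`gap_extend` (Ge) is the cost of each further position, so a gap run of
length L costs `Goe + (L-1)·Ge`. The linear model is the special case
`Goe == Ge`, and it is the default because the package's default scoring
(`match=2, mismatch=-1, gap=-2`) prints a single gap value; the CLI accepts
signed gap values as conventionally printed and stores magnitudes. All
scoring is 64-bit integer; no floating point enters any kernel, which is
what makes bit-identical reproduction across block sizes and schedules
possible at all.

The F recursion is the standard vertical-gap state
`F(i,j) = max(H(i-1,j) - Goe, F(i-1,j) - Ge)`: F extends vertically through
F, and E horizontally through E; the two gap states never feed each other
directly. Gap states that do not exist (E in column 0, F in row 0, and the
corresponding halo edges) carry a large negative sentinel, `-(2^40)`, far
below any reachable score yet safe from int64 underflow after repeated
`-Ge` subtractions.

The alphabet is `ACGTN` with case folding; `N` scores as a mismatch against
everything, itself included, because ambiguity should never manufacture
alignment signal. Other alphabets can be declared per sequence.

## Determinism policy (tie-breaking)

Every choice with ties is fixed so that serial, blockwise and actor-based
paths agree bit-for-bit:

* cell provenance during traceback prefers, in order: diagonal, up (F),
  left (E) — configurable as any permutation via `BacktrackPolicy`;
* inside the F (or E) chain, returning to H is preferred over extending the
  gap when both reconstruct the same value;
* the matrix maximum breaks ties by smallest row index, then smallest
  column index; block-local maxima are reported in global coordinates and
  merged under the same rule, so the blockwise winner is always the serial
  winner (the worked-example pair has co-maxima at (3,6) and (4,8); every
  path picks (3,6)).

Traceback walks from the maximum until a cell whose H value is at or below
the policy threshold (default 0) or the matrix border. Pairs with no
positive-scoring cell yield an explicit empty alignment: score 0, zero
coordinates, empty strings (rendered with `*` as the CIGAR).

## Blockwise wavefront evaluation

The matrix interior is tiled by a `BlockGrid` (ragged last tiles allowed).
Block (I,J) needs exactly: the H and F values of the row above its column
span (F because a vertical gap can cross the row boundary), the H and E
values of the column left of its row span, and the H value of the
upper-left corner cell. Because a block's interior arithmetic is the same
kernel as the serial fill seeded with those halos, blockwise evaluation is
exact, not approximate — the test suite asserts entrywise equality of
H/E/F and field-for-field equality of final alignments for block shapes
from 1×1 cells to one block covering the whole matrix.

Blocks are evaluated level-by-level along antidiagonals `k = I + J`; blocks
within one level share no data, so any intra-level order (and any
assignment to block actors) gives identical results. A general 2-D grid is
implemented; row strips are the special case `block_cols = n`. The default
tile is 256×256 cells, a desk-scale balance between per-block kernel work
and per-block message overhead; it is not sensitive for correctness, only
for scheduling granularity.

Two memory regimes:

* **traceback mode** keeps every block's H/E/F tile and reassembles the
  full matrices before backtracking — memory is the full `O(mn)`, as in any
  full-traceback aligner;
* **score-only mode** retains only outgoing halos, and each halo is dropped
  as soon as its last consumer block has finished, so in-flight state is
  bounded by roughly three wavefront levels of halos (the serial score-only
  path similarly uses two rolling rows). Score-only results report the
  score and end coordinates; start coordinates would need a traceback (or a
  reverse pass) and are reported as 0.

## Actor runtime

A deliberately minimal in-process runtime: actors hold a behavior (a
mapping from message tag to handler plus private state), an unbounded FIFO
mailbox, and support `send` (asynchronous, returns immediately),
`spawn`/create (including from inside handlers) and `become` (takes effect
after the in-flight message). Delivery is in-process, exactly-once and
pairwise FIFO. A scheduler keeps a ready queue of actors with pending mail
(each actor queued at most once, never while executing — this is what
enforces per-actor serialization) served by `worker_count` lanes:
one lane runs as a deterministic event loop in the calling thread;
more lanes run as Python threads, which genuinely overlap because the DP
kernels are compiled with the GIL released. A handler exception fails only
that actor: its remaining mail is counted as dead letters, its creator
receives an `actor_failed` message, and the run continues — message
conservation (`sent == processed + dead letters`) holds at quiescence.
Back-pressure is the application's job; the alignment topology bounds
itself by task throttling rather than by bounding mailboxes.

## Alignment topology

The manager enumerates tasks (`all_pairs`, `query_vs_db`, or an explicit
`pair_list`), assigns deterministic task ids, and keeps at most
`max_in_flight` pair actors alive (default `2 × worker_count`: enough to
keep lanes busy while bounding the number of concurrent score matrices in
memory). Each pair actor either runs the serial kernel directly or spawns
a block-actor pool of size `min(worker_count, min(grid_rows, grid_cols))` —
no wavefront level is ever wider than `min(grid_rows, grid_cols)`, so more
actors could never run simultaneously — and feeds ready blocks to idle
actors as dependencies complete (block-actor reuse). Results are collected
by task id; the job report and its TSV rendering are byte-identical across
worker counts and intra on/off. One failing pair actor (or block actor)
converts exactly its own task to a failed result; all other results are
unchanged.

The job seed is threaded through the configuration for provenance but the
alignment itself is seed-free: only synthetic data generation consumes
randomness.

## Synthetic data

`random_sequences(DatasetSpec)` draws lengths uniformly on
`[min_len, max_len]` and residues uniformly over the alphabet, with an
independent counter-derived substream per sequence so earlier records never
change when a dataset grows. The bundled fixture profiles emulate, at
reduced scale, the shapes of typical gene-family benchmark collections
(tens of sequences, hundreds to ~1000 bases — e.g. the `gene_medium`
profile: 30 sequences of 500–1050 bases standing in for a few hundred
multi-kilobase gene sequences); uniform lengths are the simplest shape
consistent with knowing only a min/max/mean. What the generator does *not*
emulate: base composition bias, repeats, homology structure between
database entries, or read errors — so passing tests demonstrate algorithmic
exactness and scheduling correctness on realistic sizes, not biological
recall. `mutate_pair` applies independent per-site substitution / insertion
/ deletion rates and returns the true edit list plus the gapped truth
alignment, giving tests a lower bound the optimum must dominate.

## Verification strategy and problem sizes

The ground truth for the kernel is an independent top-down
recursive-with-memoization evaluation of the recursions, written against
plain Python ints and strings (tests/oracle.py and a second copy embedded
in scripts/acceptance.py); the suite checks 200+ random pairs (lengths ≤
40) entrywise, 50 pairs (lengths ≤ 300) across five block shapes for
field-identical alignments, 50-task jobs across eight worker/parallelism
settings for byte-identical TSV, and the actor contracts directly. The
scaling check times a score-only batch (32 pairs of 10 kb sequences,
roughly 20 s on one lane) on one versus four lanes; it is a qualitative
ordering check that needs a multi-core host to be meaningful, since thread
lanes on a single core cannot beat one lane. Problem sizes throughout were
chosen to exercise every code path (ragged tiles, empty levels, empty
sequences, co-maxima) at desk scale.

## Known limitations

* Traceback mode materializes full `O(mn)` integer matrices; there is no
  linear-memory (Hirschberg) traceback and no banding.
* No substitution matrices (BLOSUM/PAM), no global or semiglobal modes.
* The actor runtime is single-process; there is no distributed execution,
  actor persistence, or work-stealing scheduler.
* Thread-lane speedup requires free cores; on one core the runtime's value
  is scheduling structure and fault isolation, not throughput.
* Score-only mode reports end coordinates only (start coordinates are 0).
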