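# actalign

Actor-parallel Smith–Waterman local alignment of nucleotide sequences, with
exact blockwise antidiagonal-wavefront evaluation of the score matrix.

## What it is for

Pairwise local alignment — finding the highest-scoring pair of substrings of
two sequences — is the workhorse of sequence database search and homology
screening, and its dynamic programming is `O(mn)` per pair. `actalign`
parallelizes large batches of pairwise alignments on two levels using the
actor model of concurrency:

* **interalignment**: a *manager* actor dispatches independent pair
  alignments to *pair* actors (throttled to a configurable number in
  flight), and
* **intraalignment**: each pair actor may tile its score matrix into
  rectangular blocks and stream them to a pool of *block* actors along the
  antidiagonal wavefront — all blocks with the same `I + J` are mutually
  independent, so they can run concurrently once earlier antidiagonals are
  done.

All actors communicate only through asynchronous messages on a minimal
embedded runtime (`send`, `create`/spawn, `become`, per-actor mailboxes, a
fixed pool of execution lanes). The DP kernels are integer-only, GIL-free
compiled functions, so thread lanes genuinely overlap on multi-core hosts —
and every execution path (serial, blockwise, any worker count, any block
size) produces **bit-identical** results.

## The model

For sequences `p = p_1…p_m`, `q = q_1…q_n` and substitution score
`s(a, b)` (match/mismatch), the three Gotoh state matrices are

```
H[i][0] = H[0][j] = 0
H[i][j] = max(0, H[i-1][j-1] + s(p_i, q_j), E[i][j], F[i][j])
E[i][j] = max(H[i][j-1] - Goe, E[i][j-1] - Ge)    # gap in query
F[i][j] = max(H[i-1][j] - Goe, F[i-1][j] - Ge)    # gap in target
```

with `Goe` the combined gap open+extend penalty and `Ge` the per-position
extension penalty (`Goe == Ge` is the linear gap model, the default). The
optimal local score `S` is the maximum of `H`; the alignment is recovered by
walking each cell back to the cell it was computed from (diagonal, up, or
left) until a cell at or below the traceback threshold (0 by default).
Each cell depends only on its upper, left and upper-left neighbours, which
is what makes both the cell-level and the block-level antidiagonal
wavefronts legal.

## Worked example

```
$ printf '>p\nATCGACTT\n>q\nGATATCTG\n' > pair.fa
$ actalign align --in pair.fa --match 2 --mismatch -1 --gap -2 --format pretty
# p vs q
  score 6  query 1-3  target 4-6  cigar 3M
  q: ATC
     |||
  t: ATC
```

The best local alignment pairs `ATC` (positions 1–3 of `p`) with `ATC`
(positions 4–6 of `q`): three matches at +2 each, score 6; no gap or
mismatch improves on it under this scheme. The default TSV output of the
same run is one header plus one row per pair:

```
query_id  target_id  score  q_start  q_end  t_start  t_end  cigar  status
p         q          6      1        3      4        6      3M     ok
```

Batch usage: `--mode all_pairs` aligns every pair in `--in`;
`--mode query_vs_db --query q.fa --target d.fa` aligns each query against
each target; `--workers N` sets the lane count, `--intra` turns on blockwise
wavefront parallelism inside each pair (`--block-rows/--block-cols` set the
tile size, default 256×256), and `--score-only` skips traceback and keeps
memory at a few matrix rows. `actalign make-fixtures --out-dir d/ --seed 1`
writes seeded synthetic FASTA datasets.

## Library entry points

```python
from actalign import Sequence, ScoringScheme, align_serial, align_blockwise, run_job

p, q = Sequence("p", "ATCGACTT"), Sequence("q", "GATATCTG")
scheme = ScoringScheme.linear(2, -1, -2)
align_serial(p, q, scheme).score        # 6
align_blockwise(p, q, scheme, 2, 3)     # identical result, 2x3 tiles
```

`run_job(dataset, JobConfig(...))` is the top-level batch interface; its
report is ordered by task id and is byte-stable across worker counts.

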