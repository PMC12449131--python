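"""Blockwise antidiagonal-wavefront evaluation of the alignment recursions.

The (m x n) interior of the DP matrix is tiled into rectangular blocks.
Block (I, J) depends only on its upper, left and upper-left neighbours, so
all blocks on one antidiagonal level (constant I + J) are independent and
can be computed concurrently once the previous levels are done -- the same
wavefront structure the cell-level recursion has, lifted to tiles.

Each block imports a halo: the H and F values of the row directly above its
span (vertical gap state crosses row boundaries), the H and E values of the
column directly to its left, and the single H value diagonally above-left.
Matrix edges use the zero boundary for H and a large negative sentinel for
the gap states.  Because the arithmetic inside a block is identical to the
serial kernel's, blockwise evaluation reproduces the serial H/E/F matrices
exactly for every legal block size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Set, Tuple

import numpy as np

from actalign.core import (
    AlignmentResult,
    BacktrackPolicy,
    ConfigurationError,
    DPMatrices,
    NEG_SENTINEL,
    Sequence,
    ScoringScheme,
    _check_pair_alphabet,
    _empty_result,
    _fill_from_halo,
    backtrack,
    find_max,
)


class ContractViolationError(ValueError):
    """A block received halos inconsistent with its geometry."""


@dataclass(frozen=True)
class BlockGrid:
    """Tiling of the (m x n) matrix interior into blocks of at most
    block_rows x block_cols cells; the last row/column of tiles may be
    ragged."""

    m: int
    n: int
    block_rows: int
    block_cols: int
    grid_rows: int
    grid_cols: int

    def row_span(self, I: int) -> Tuple[int, int]:
        """Half-open 0-based residue span of block-row I within p."""
        lo = I * self.block_rows
        return lo, min(lo + self.block_rows, self.m)

    def col_span(self, J: int) -> Tuple[int, int]:
        lo = J * self.block_cols
        return lo, min(lo + self.block_cols, self.n)

    def __contains__(self, block_id: Tuple[int, int]) -> bool:
        I, J = block_id
        return 0 <= I < self.grid_rows and 0 <= J < self.grid_cols

    def blocks(self) -> Iterator[Tuple[int, int]]:
        for I in range(self.grid_rows):
            for J in range(self.grid_cols):
                yield (I, J)


@dataclass
class BlockBoundary:
    """Incoming halo of one block: H/F from the row above its column span,
    H/E from the column left of its row span, and the corner H value."""

    top_H: np.ndarray
    top_F: np.ndarray
    left_H: np.ndarray
    left_E: np.ndarray
    corner_H: int


@dataclass
class BlockResult:
    """Outgoing halos, local maximum and (optionally) the H tile of one
    block.  Halos equal the corresponding rows/columns of the serial
    matrices; ``local_max`` is (score, i, j) in global 1-based matrix
    coordinates with ties broken by smallest i then j."""

    block_id: Tuple[int, int]
    bottom_H: np.ndarray
    bottom_F: np.ndarray
    right_H: np.ndarray
    right_E: np.ndarray
    out_corner_H: int
    local_max: Tuple[int, int, int]
    tile_H: Optional[np.ndarray] = None
    tile_E: Optional[np.ndarray] = None
    tile_F: Optional[np.ndarray] = None


@dataclass(frozen=True)
class WavefrontSchedule:
    """Antidiagonal levels; level k holds every block with I + J == k."""

    levels: Tuple[Tuple[Tuple[int, int], ...], ...]

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    @property
    def max_width(self) -> int:
        return max((len(lv) for lv in self.levels), default=0)


def make_grid(m: int, n: int, block_rows: int, block_cols: int) -> BlockGrid:
    """Tile an (m x n) interior; every cell lands in exactly one block."""
    if m < 0 or n < 0:
        raise ConfigurationError("matrix dims must be >= 0")
    if block_rows < 1 or block_cols < 1:
        raise ConfigurationError("block dims must be >= 1")
    grid_rows = -(-m // block_rows) if m else 0
    grid_cols = -(-n // block_cols) if n else 0
    return BlockGrid(m, n, block_rows, block_cols, grid_rows, grid_cols)


def block_dependencies(grid: BlockGrid, I: int, J: int) -> Set[Tuple[int, int]]:
    """Blocks whose halos (I, J) needs: up, left and upper-left neighbours."""
    if (I, J) not in grid:
        raise IndexError(f"block ({I}, {J}) outside {grid.grid_rows}x{grid.grid_cols} grid")
    deps = set()
    if I > 0:
        deps.add((I - 1, J))
    if J > 0:
        deps.add((I, J - 1))
    if I > 0 and J > 0:
        deps.add((I - 1, J - 1))
    return deps


def wavefront_order(grid: BlockGrid) -> WavefrontSchedule:
    """Group blocks by antidiagonal level k = I + J; every dependency of a
    level-k block sits at level k-1 or k-2, so levels run left-to-right."""
    n_levels = grid.grid_rows + grid.grid_cols - 1 if grid.grid_rows and grid.grid_cols else 0
    levels: List[List[Tuple[int, int]]] = [[] for _ in range(n_levels)]
    for I, J in grid.blocks():
        levels[I + J].append((I, J))
    return WavefrontSchedule(tuple(tuple(lv) for lv in levels))


def edge_boundary(grid: BlockGrid, I: int, J: int) -> BlockBoundary:
    """Halo for a block touching the matrix border: zero H boundary and
    negative sentinels for the gap states (partial halos are overwritten
    by real neighbour outputs where neighbours exist)."""
    r0, r1 = grid.row_span(I)
    c0, c1 = grid.col_span(J)
    bm, bn = r1 - r0, c1 - c0
    return BlockBoundary(
        top_H=np.zeros(bn, np.int64),
        top_F=np.full(bn, NEG_SENTINEL, np.int64),
        left_H=np.zeros(bm, np.int64),
        left_E=np.full(bm, NEG_SENTINEL, np.int64),
        corner_H=0,
    )


def compute_block(
    block_id: Tuple[int, int],
    p_slice: np.ndarray,
    q_slice: np.ndarray,
    boundary: BlockBoundary,
    scheme: ScoringScheme,
    keep_tile: bool = False,
    row_offset: int = 0,
    col_offset: int = 0,
    ambiguity_code: int = 255,
) -> BlockResult:
    """Fill one block from its halo.

    ``p_slice`` / ``q_slice`` are the encoded residues covered by the block;
    ``row_offset`` / ``col_offset`` locate the block so local_max can be
    reported in global matrix coordinates.  With ``keep_tile`` the full
    H/E/F tiles (halo row/column included) are returned for traceback
    assembly; otherwise only the outgoing halos survive.
    """
    bm, bn = len(p_slice), len(q_slice)
    if len(boundary.top_H) != bn or len(boundary.top_F) != bn:
        raise ContractViolationError(
            f"block {block_id}: top halo length {len(boundary.top_H)} != {bn}"
        )
    if len(boundary.left_H) != bm or len(boundary.left_E) != bm:
        raise ContractViolationError(
            f"block {block_id}: left halo length {len(boundary.left_H)} != {bm}"
        )
    H, E, F = _fill_from_halo(
        p_slice,
        q_slice,
        boundary.top_H,
        boundary.top_F,
        boundary.left_H,
        boundary.left_E,
        boundary.corner_H,
        scheme.match_score,
        scheme.mismatch_score,
        scheme.gap_open_extend,
        scheme.gap_extend,
        ambiguity_code,
    )
    interior = H[1:, 1:]
    if interior.size:
        flat = int(np.argmax(interior))
        li, lj = divmod(flat, bn)
        local_max = (int(interior[li, lj]), row_offset + li + 1, col_offset + lj + 1)
    else:
        local_max = (0, 0, 0)
    return BlockResult(
        block_id=block_id,
        bottom_H=H[-1, 1:].copy(),
        bottom_F=F[-1, 1:].copy(),
        right_H=H[1:, -1].copy(),
        right_E=E[1:, -1].copy(),
        out_corner_H=int(H[-1, -1]),
        local_max=local_max,
        tile_H=H if keep_tile else None,
        tile_E=E if keep_tile else None,
        tile_F=F if keep_tile else None,
    )


def assemble_boundary(
    grid: BlockGrid, I: int, J: int, done: Dict[Tuple[int, int], BlockResult]
) -> BlockBoundary:
    """Build (I, J)'s halo from its finished neighbours (matrix edges where
    a neighbour does not exist)."""
    b = edge_boundary(grid, I, J)
    if I > 0:
        up = done[(I - 1, J)]
        b.top_H = up.bottom_H
        b.top_F = up.bottom_F
    if J > 0:
        left = done[(I, J - 1)]
        b.left_H = left.right_H
        b.left_E = left.right_E
    if I > 0 and J > 0:
        b.corner_H = done[(I - 1, J - 1)].out_corner_H
    return b


def better_max(a: Tuple[int, int, int], b: Tuple[int, int, int]) -> Tuple[int, int, int]:
    """Combine two (score, i, j) candidates under the global tie rule:
    higher score wins; on equal score, smaller i then smaller j."""
    if b[0] > a[0]:
        return b
    if b[0] == a[0] and b[0] > 0 and (b[1], b[2]) < (a[1], a[2]):
        return b
    return a


def _assemble_matrices(
    grid: BlockGrid, done: Dict[Tuple[int, int], BlockResult]
) -> DPMatrices:
    m, n = grid.m, grid.n
    H = np.zeros((m + 1, n + 1), np.int64)
    E = np.full((m + 1, n + 1), NEG_SENTINEL, np.int64)
    F = np.full((m + 1, n + 1), NEG_SENTINEL, np.int64)
    for (I, J), res in done.items():
        r0, r1 = grid.row_span(I)
        c0, c1 = grid.col_span(J)
        H[r0 + 1 : r1 + 1, c0 + 1 : c1 + 1] = res.tile_H[1:, 1:]
        E[r0 + 1 : r1 + 1, c0 + 1 : c1 + 1] = res.tile_E[1:, 1:]
        F[r0 + 1 : r1 + 1, c0 + 1 : c1 + 1] = res.tile_F[1:, 1:]
    return DPMatrices(H, E, F)


class BoundaryStore:
    """Holds finished BlockResults only while downstream blocks still need
    them; in score-only mode the retained state is therefore bounded by the
    halo sizes of the in-flight wavefront, never the full matrix."""

    def __init__(self, grid: BlockGrid, retain_all: bool = False):
        self.grid = grid
        self.retain_all = retain_all
        self._store: Dict[Tuple[int, int], BlockResult] = {}
        self._consumers_left: Dict[Tuple[int, int], int] = {}
        self.peak_size = 0

    def __getitem__(self, key):
        return self._store[key]

    def __len__(self):
        return len(self._store)

    def all_results(self) -> Dict[Tuple[int, int], BlockResult]:
        return self._store

    def add(self, res: BlockResult) -> None:
        I, J = res.block_id
        g = self.grid
        consumers = sum(
            1
            for c in ((I + 1, J), (I, J + 1), (I + 1, J + 1))
            if c in g
        )
        self._store[res.block_id] = res
        self._consumers_left[res.block_id] = consumers
        self.peak_size = max(self.peak_size, len(self._store))
        if consumers == 0 and not self.retain_all:
            del self._store[res.block_id]

    def consume(self, block_id: Tuple[int, int]) -> None:
        """Note that one downstream block of ``block_id`` has finished."""
        if block_id not in self._consumers_left:
            return
        self._consumers_left[block_id] -= 1
        if self._consumers_left[block_id] == 0 and not self.retain_all:
            self._store.pop(block_id, None)
            del self._consumers_left[block_id]


def align_blockwise(
    p: Sequence,
    q: Sequence,
    scheme: ScoringScheme,
    block_rows: int = 256,
    block_cols: int = 256,
    policy: BacktrackPolicy = BacktrackPolicy(),
    score_only: bool = False,
    level_order=None,
) -> AlignmentResult:
    """Blockwise alignment, identical field-for-field to ``align_serial``.

    Blocks are evaluated level-by-level along the wavefront schedule;
    ``level_order`` (a callable permuting each level, used by the safety
    tests) may reorder blocks within a level without changing the result.
    In traceback mode tiles are kept and reassembled into full matrices
    before backtracking; in score-only mode only halos and the running
    maximum are retained.
    """
    _check_pair_alphabet(p, q)
    grid = make_grid(len(p), len(q), block_rows, block_cols)
    if grid.grid_rows == 0 or grid.grid_cols == 0:
        return _empty_result()
    schedule = wavefront_order(grid)
    store = BoundaryStore(grid, retain_all=not score_only)
    pc, qc = p.codes, q.codes
    best = (0, 0, 0)
    for level in schedule:
        blocks = list(level) if level_order is None else level_order(list(level))
        for I, J in blocks:
            boundary = assemble_boundary(grid, I, J, store)
            r0, r1 = grid.row_span(I)
            c0, c1 = grid.col_span(J)
            res = compute_block(
                (I, J),
                pc[r0:r1],
                qc[c0:c1],
                boundary,
                scheme,
                keep_tile=not score_only,
                row_offset=r0,
                col_offset=c0,
                ambiguity_code=p.ambiguity_code,
            )
            store.add(res)
            best = better_max(best, res.local_max)
        for I, J in blocks:
            for dep in block_dependencies(grid, I, J):
                store.consume(dep)
    if best[0] == 0:
        return _empty_result()
    if score_only:
        return AlignmentResult(best[0], 0, best[1], 0, best[2], "", "", "*")
    mats = _assemble_matrices(grid, store.all_results())
    score, i, j = find_max(mats)
    return backtrack(mats, p, q, scheme, (i, j), policy)
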