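"""Manager / pair / block actor topology for parallel alignment jobs.

Interalignment parallelism: a manager actor enumerates pairwise alignment
tasks and spawns pair actors, throttled to a maximum number in flight; each
pair actor computes one alignment and replies with a task result, upon
which the manager dispatches the next pending task.

Intraalignment parallelism: a pair actor may additionally spawn a bounded
pool of block actors and release score-matrix blocks to them level-by-level
along the antidiagonal wavefront; each block actor reports its block's
outgoing halos and local maximum back to the pair actor and receives the
next ready block (block-actor reuse).  The pair actor aggregates halos and
maxima, reassembles the matrix for traceback (or skips it in score-only
mode), and replies to the manager.

Every path -- serial, intra on/off, any worker count, any block size --
produces field-identical results; the report is ordered by task id so job
output is byte-stable under concurrency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as SeqType, Tuple

from actalign.blockwave import (
    BoundaryStore,
    assemble_boundary,
    better_max,
    block_dependencies,
    compute_block,
    make_grid,
    wavefront_order,
    _assemble_matrices,
)
from actalign.core import (
    AlignmentResult,
    BacktrackPolicy,
    ConfigurationError,
    ScoringScheme,
    Sequence,
    _empty_result,
    align_serial,
    backtrack,
    find_max,
)
from actalign.runtime import ActorRef, Behavior, Runtime, RuntimeConfig


@dataclass(frozen=True)
class AlignmentTask:
    task_id: int
    query_index: int
    target_index: int
    scheme: ScoringScheme
    policy: BacktrackPolicy
    intra: bool
    block_rows: int
    block_cols: int
    score_only: bool


@dataclass(frozen=True)
class TaskResult:
    task_id: int
    query_id: str
    target_id: str
    status: str  # ok | failed
    result: Optional[AlignmentResult] = None
    error: str = ""
    cells: int = 0
    blocks: int = 0


@dataclass(frozen=True)
class JobConfig:
    """Job-level configuration.

    ``mode`` is ``all_pairs`` (C(N,2) unordered pairs), ``query_vs_db``
    (every query index against every target index) or ``pair_list`` (an
    explicit list of (query, target) sequence ids or indices).
    ``max_in_flight`` caps concurrently live pair actors (default twice the
    worker count, keeping memory predictable while lanes stay busy).
    ``fail_tasks`` is a fault-injection hook: the pair actor of a listed
    task id raises, exercising the supervision path.
    """

    scheme: ScoringScheme
    mode: str = "all_pairs"
    worker_count: int = 1
    max_in_flight: Optional[int] = None
    policy: BacktrackPolicy = BacktrackPolicy()
    intra: bool = False
    block_rows: int = 256
    block_cols: int = 256
    score_only: bool = False
    seed: int = 0
    query_indices: Optional[Tuple[int, ...]] = None
    target_indices: Optional[Tuple[int, ...]] = None
    pairs: Optional[Tuple[Tuple, ...]] = None
    fail_tasks: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in ("all_pairs", "query_vs_db", "pair_list"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.worker_count < 1:
            raise ConfigurationError("worker_count must be >= 1")
        if self.max_in_flight is not None and self.max_in_flight < 1:
            raise ConfigurationError("max_in_flight must be >= 1")
        if self.block_rows < 1 or self.block_cols < 1:
            raise ConfigurationError("block dims must be >= 1")

    @property
    def in_flight_cap(self) -> int:
        return self.max_in_flight if self.max_in_flight is not None else 2 * self.worker_count


@dataclass
class JobReport:
    """Results of one job, ordered by task id regardless of completion
    order.  ``totals`` are scheduling-independent; ``execution`` records
    scheduling artifacts (worker count, peak in-flight pair actors, message
    counts) and is excluded from canonical comparisons."""

    results: List[TaskResult]
    totals: Dict[str, int]
    config_echo: Dict[str, object]
    execution: Dict[str, object] = field(default_factory=dict)

    def canonical(self) -> dict:
        """Scheduling-independent view: byte-stable for fixed inputs."""
        return {
            "results": [
                (
                    r.task_id,
                    r.query_id,
                    r.target_id,
                    r.status,
                    r.result,
                    r.error,
                    r.cells,
                    r.blocks,
                )
                for r in self.results
            ],
            "totals": self.totals,
            "config": self.config_echo,
        }


def enumerate_tasks(dataset: SeqType[Sequence], config: JobConfig) -> List[AlignmentTask]:
    """Expand the job mode into a deterministic, id-ordered task list."""
    if not dataset:
        raise ConfigurationError("dataset is empty")
    pairs: List[Tuple[int, int]] = []
    n = len(dataset)
    if config.mode == "all_pairs":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif config.mode == "query_vs_db":
        qi = config.query_indices
        ti = config.target_indices
        if qi is None or ti is None:
            raise ConfigurationError("query_vs_db mode needs query_indices and target_indices")
        for k in list(qi) + list(ti):
            if not (0 <= k < n):
                raise ConfigurationError(f"sequence index {k} out of range")
        pairs = [(i, j) for i in qi for j in ti]
    else:  # pair_list
        if config.pairs is None:
            raise ConfigurationError("pair_list mode needs pairs")
        by_id = {s.id: k for k, s in enumerate(dataset)}
        for a, b in config.pairs:
            ia = a if isinstance(a, int) else by_id.get(a)
            ib = b if isinstance(b, int) else by_id.get(b)
            if ia is None or ib is None or not (0 <= ia < n and 0 <= ib < n):
                raise ConfigurationError(f"pair ({a!r}, {b!r}) references unknown sequence")
            pairs.append((ia, ib))
    return [
        AlignmentTask(
            task_id=k,
            query_index=i,
            target_index=j,
            scheme=config.scheme,
            policy=config.policy,
            intra=config.intra,
            block_rows=config.block_rows,
            block_cols=config.block_cols,
            score_only=config.score_only,
        )
        for k, (i, j) in enumerate(pairs)
    ]


def _align_task(p: Sequence, q: Sequence, task: AlignmentTask) -> AlignmentResult:
    return align_serial(p, q, task.scheme, task.policy, task.score_only)


def block_behavior(pair_ref: ActorRef, scheme: ScoringScheme, ambiguity_code: int) -> Behavior:
    """A reusable block worker: fills one block from its halo, reports the
    result to its pair actor and awaits the next block task."""

    def on_block(ctx, block_id, p_slice, q_slice, boundary, keep_tile, row_off, col_off):
        res = compute_block(
            block_id,
            p_slice,
            q_slice,
            boundary,
            scheme,
            keep_tile=keep_tile,
            row_offset=row_off,
            col_offset=col_off,
            ambiguity_code=ambiguity_code,
        )
        ctx.send(pair_ref, "block_result", res)

    return Behavior({"block": on_block}, name="block")


def _done_behavior() -> Behavior:
    """Terminal pair-actor state: ignores stragglers from its block pool."""
    return Behavior(
        {"block_result": lambda c, r: None, "actor_failed": lambda c, ref, err: None},
        name="pair-done",
    )


def pair_behavior(
    p: Sequence,
    q: Sequence,
    task: AlignmentTask,
    manager: ActorRef,
    worker_count: int = 1,
    fail: bool = False,
) -> Behavior:
    """One pair alignment.

    Without intra-parallelism the serial kernel runs inside the handler.
    With it, the pair actor spawns a block-actor pool bounded by the widest
    wavefront level, releases ready blocks as their dependencies finish,
    then becomes a collector until every block has reported.
    """
    cells = len(p) * len(q)

    def reply(ctx, result: AlignmentResult, blocks: int) -> None:
        ctx.send(
            manager,
            "result",
            TaskResult(
                task_id=task.task_id,
                query_id=p.id,
                target_id=q.id,
                status="ok",
                result=result,
                cells=cells,
                blocks=blocks,
            ),
        )

    def on_start_serial(ctx) -> None:
        if fail:
            raise RuntimeError(f"injected failure in task {task.task_id}")
        reply(ctx, _align_task(p, q, task), blocks=0)

    if not task.intra:
        return Behavior({"start": on_start_serial}, name=f"pair-{task.task_id}")

    grid = make_grid(len(p), len(q), task.block_rows, task.block_cols)
    schedule = wavefront_order(grid)
    total_blocks = grid.grid_rows * grid.grid_cols
    state: Dict[str, object] = {}

    def dispatch(ctx, block_id, worker: ActorRef) -> None:
        I, J = block_id
        boundary = assemble_boundary(grid, I, J, state["store"])
        r0, r1 = grid.row_span(I)
        c0, c1 = grid.col_span(J)
        ctx.send(
            worker,
            "block",
            block_id,
            p.codes[r0:r1],
            q.codes[c0:c1],
            boundary,
            not task.score_only,
            r0,
            c0,
        )

    def feed_ready(ctx) -> None:
        ready: List = state["ready"]
        idle: List = state["idle"]
        while ready and idle:
            dispatch(ctx, ready.pop(0), idle.pop(0))

    def finish(ctx) -> None:
        store: BoundaryStore = state["store"]
        best = state["best"]
        if best[0] == 0:
            result = _empty_result()
        elif task.score_only:
            result = AlignmentResult(best[0], 0, best[1], 0, best[2], "", "", "*")
        else:
            mats = _assemble_matrices(grid, store.all_results())
            score, i, j = find_max(mats)
            result = backtrack(mats, p, q, task.scheme, (i, j), task.policy)
        reply(ctx, result, blocks=total_blocks)
        ctx.become(_done_behavior())

    def on_block_result(ctx, res) -> None:
        store: BoundaryStore = state["store"]
        store.add(res)
        state["best"] = better_max(state["best"], res.local_max)
        state["done"] = state["done"] + 1
        for dep in block_dependencies(grid, *res.block_id):
            store.consume(dep)
        remaining: Dict = state["deps_remaining"]
        I, J = res.block_id
        for consumer in ((I + 1, J), (I, J + 1), (I + 1, J + 1)):
            if consumer in remaining:
                remaining[consumer] -= 1
                if remaining[consumer] == 0:
                    state["ready"].append(consumer)
                    del remaining[consumer]
        state["idle"].append(ctx.sender)
        feed_ready(ctx)
        if state["done"] == total_blocks:
            finish(ctx)

    def on_failed_block(ctx, ref, error) -> None:
        ctx.send(
            manager,
            "result",
            TaskResult(
                task_id=task.task_id,
                query_id=p.id,
                target_id=q.id,
                status="failed",
                error=f"block actor failed: {error}",
                cells=cells,
                blocks=total_blocks,
            ),
        )
        ctx.become(_done_behavior())

    def on_start_intra(ctx) -> None:
        if fail:
            raise RuntimeError(f"injected failure in task {task.task_id}")
        if total_blocks == 0:
            reply(ctx, _empty_result(), blocks=0)
            return
        pool = pool_size(worker_count, grid)
        workers = [
            ctx.spawn(block_behavior(ctx.self_ref, task.scheme, p.ambiguity_code))
            for _ in range(pool)
        ]
        state.update(
            store=BoundaryStore(grid, retain_all=not task.score_only),
            best=(0, 0, 0),
            done=0,
            ready=[(0, 0)],
            idle=workers,
            deps_remaining={
                b: len(block_dependencies(grid, *b)) for b in grid.blocks() if b != (0, 0)
            },
        )
        feed_ready(ctx)
        ctx.become(
            Behavior(
                {"block_result": on_block_result, "actor_failed": on_failed_block},
                name=f"pair-{task.task_id}-collecting",
            )
        )

    return Behavior({"start": on_start_intra}, name=f"pair-{task.task_id}")


def pool_size(worker_count: int, grid) -> int:
    """Block-actor pool per pair: min(worker_count, widest wavefront level)
    -- reuse means no more actors than lanes can serve, and no level is
    wider than min(grid_rows, grid_cols) so extra actors could never run."""
    widest = min(grid.grid_rows, grid.grid_cols)
    return max(1, min(worker_count, widest))


def manager_behavior(
    dataset: SeqType[Sequence], tasks: List[AlignmentTask], config: JobConfig, sink: dict
) -> Behavior:
    """Dispatches tasks to pair actors, at most ``in_flight_cap`` at once;
    records each TaskResult (or a failure from supervision) and dispatches
    the next pending task until all tasks have results."""
    state = {
        "next": 0,
        "in_flight": 0,
        "peak": 0,
        "by_ref": {},  # pair ActorRef id -> task
    }

    def launch(ctx) -> None:
        while state["next"] < len(tasks) and state["in_flight"] < config.in_flight_cap:
            task = tasks[state["next"]]
            state["next"] += 1
            p = dataset[task.query_index]
            q = dataset[task.target_index]
            ref = ctx.spawn(
                pair_behavior(
                    p,
                    q,
                    task,
                    ctx.self_ref,
                    worker_count=config.worker_count,
                    fail=task.task_id in config.fail_tasks,
                )
            )
            state["by_ref"][ref.actor_id] = task
            state["in_flight"] += 1
            state["peak"] = max(state["peak"], state["in_flight"])
            ctx.send(ref, "start")

    def record(ctx, tr: TaskResult) -> None:
        sink["results"][tr.task_id] = tr
        state["in_flight"] -= 1
        launch(ctx)

    def on_start(ctx) -> None:
        sink["results"] = {}
        if not tasks:
            sink["peak_in_flight"] = 0
            return
        launch(ctx)

    def on_result(ctx, tr: TaskResult) -> None:
        record(ctx, tr)
        sink["peak_in_flight"] = state["peak"]

    def on_actor_failed(ctx, ref: ActorRef, error: str) -> None:
        task = state["by_ref"].get(ref.actor_id)
        if task is None or task.task_id in sink["results"]:
            return
        p = dataset[task.query_index]
        q = dataset[task.target_index]
        record(
            ctx,
            TaskResult(
                task_id=task.task_id,
                query_id=p.id,
                target_id=q.id,
                status="failed",
                error=error,
                cells=len(p) * len(q),
            ),
        )
        sink["peak_in_flight"] = state["peak"]

    return Behavior(
        {"start": on_start, "result": on_result, "actor_failed": on_actor_failed},
        name="manager",
    )


def run_job(dataset: SeqType[Sequence], config: JobConfig) -> JobReport:
    """Run a full alignment job on the actor runtime and return its report.

    The report is deterministic for fixed inputs: identical for any
    worker count and any block-actor pool size (the alignment kernel is
    seed-free; the seed only matters to synthetic data generation upstream).
    """
    tasks = enumerate_tasks(dataset, config)
    runtime = Runtime(RuntimeConfig(worker_count=config.worker_count))
    sink: dict = {"results": {}, "peak_in_flight": 0}
    manager = runtime.spawn(manager_behavior(dataset, tasks, config, sink))
    runtime.send(manager, "start")
    stats = runtime.run_until_quiescent()
    runtime.shutdown()
    results = [sink["results"][k] for k in sorted(sink["results"])]
    if len(results) != len(tasks):
        missing = sorted(set(t.task_id for t in tasks) - set(sink["results"]))
        raise RuntimeError(f"job lost results for tasks {missing}")
    totals = {
        "tasks": len(tasks),
        "ok": sum(1 for r in results if r.status == "ok"),
        "failed": sum(1 for r in results if r.status == "failed"),
        "cells": sum(r.cells for r in results),
        "blocks": sum(r.blocks for r in results),
    }
    echo = {
        "mode": config.mode,
        "scheme": config.scheme,
        "policy": config.policy,
        "intra": config.intra,
        "block_rows": config.block_rows,
        "block_cols": config.block_cols,
        "score_only": config.score_only,
        "seed": config.seed,
    }
    execution = {
        "worker_count": config.worker_count,
        "in_flight_cap": config.in_flight_cap,
        "peak_in_flight": sink["peak_in_flight"],
        "messages_sent": stats.messages_sent,
        "messages_processed": stats.messages_processed,
        "dead_letters": stats.dead_letters,
        "actors_spawned": stats.actors_spawned,
        "per_worker": dict(stats.per_worker),
    }
    return JobReport(results=results, totals=totals, config_echo=echo, execution=execution)
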