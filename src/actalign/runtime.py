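"""A minimal in-process actor runtime.

Actors are isolated entities that communicate only through asynchronous
messages; the three primitive actions are *send* (enqueue a message in
another actor's mailbox), *create* (spawn a new actor) and *become* (swap
the actor's own behavior for subsequent messages).  Each actor owns a
mailbox (an unbounded FIFO queue); a scheduler keeps a ready queue of
actors with pending mail -- each actor appears there at most once -- and a
fixed pool of execution lanes drains it.

Two lane implementations satisfy the same contracts: ``worker_count == 1``
runs a deterministic event loop in the calling thread; ``worker_count > 1``
uses real worker threads (the alignment kernels release the GIL, so block
and pair actors genuinely overlap on multi-core hosts).

Delivery is in-process, exactly-once and pairwise FIFO: between one sender
and one receiver, messages arrive in send order.  A handler exception marks
only that actor failed; its creator is notified with an ``actor_failed``
message, undelivered and subsequent mail goes to the dead-letter count, and
the run continues.
"""

from __future__ import annotations

import itertools
import logging
import threading
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional, Tuple

logger = logging.getLogger(__name__)


class LifecycleError(RuntimeError):
    """Operation attempted on a stopped runtime."""


class UsageError(RuntimeError):
    """Actor primitive used outside its legal context (e.g. become outside
    a message handler)."""


@dataclass(frozen=True)
class Message:
    """An asynchronous message: a tag naming the handler, an immutable
    payload tuple and the sender's reference (None for external sends)."""

    tag: str
    payload: tuple
    sender: Optional["ActorRef"] = None


@dataclass(frozen=True)
class ActorRef:
    """Opaque, unique identifier of one actor for the runtime's lifetime."""

    actor_id: int
    name: str = ""

    def __repr__(self) -> str:
        return f"ActorRef({self.actor_id}{', ' + self.name if self.name else ''})"


class Behavior:
    """Maps message tags to handlers.

    Handlers receive ``(ctx, *payload)`` where ``ctx`` is the actor's
    :class:`ActorContext`.  Private state lives in the behavior instance
    (or its closure) and is never observable except through messages.
    """

    def __init__(self, handlers: Dict[str, Callable], name: str = ""):
        self.handlers = dict(handlers)
        self.name = name

    def handler_for(self, tag: str) -> Callable:
        try:
            return self.handlers[tag]
        except KeyError:
            raise UsageError(f"behavior {self.name!r} has no handler for {tag!r}") from None


@dataclass
class RuntimeConfig:
    """Scheduler configuration: number of execution lanes (>= 1)."""

    worker_count: int = 1

    def __post_init__(self) -> None:
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


@dataclass
class RunStatistics:
    messages_sent: int = 0
    messages_processed: int = 0
    dead_letters: int = 0
    actors_spawned: int = 0
    actors_failed: int = 0
    per_worker: Dict[int, int] = field(default_factory=dict)


class ActorContext:
    """Capabilities handed to a handler: who am I, who sent this, plus the
    spawn / send / become primitives.  Valid only for the duration of the
    handler invocation."""

    def __init__(self, runtime: "Runtime", actor: "_Actor", message: Message):
        self._runtime = runtime
        self._actor = actor
        self.self_ref = actor.ref
        self.sender = message.sender
        self._live = True

    def spawn(self, behavior: Behavior, name: str = "") -> ActorRef:
        return self._runtime._spawn(behavior, creator=self.self_ref, name=name)

    def send(self, ref: ActorRef, tag: str, *payload: Any) -> None:
        self._runtime._send(Message(tag, payload, sender=self.self_ref), ref)

    def become(self, new_behavior: Behavior) -> None:
        """Handle subsequent messages with ``new_behavior``; the message in
        flight completes under the current one."""
        if not self._live:
            raise UsageError("become() called outside a running handler")
        self._actor.pending_behavior = new_behavior

    def _invalidate(self) -> None:
        self._live = False


class _Actor:
    __slots__ = (
        "ref",
        "behavior",
        "pending_behavior",
        "mailbox",
        "creator",
        "state",
        "on_ready_queue",
        "executing",
    )

    def __init__(self, ref: ActorRef, behavior: Behavior, creator: Optional[ActorRef]):
        self.ref = ref
        self.behavior = behavior
        self.pending_behavior: Optional[Behavior] = None
        self.mailbox: deque = deque()
        self.creator = creator
        self.state = "alive"  # alive | failed | terminated
        self.on_ready_queue = False
        self.executing = False


class Runtime:
    """The actor system: registry, scheduler and lane pool."""

    def __init__(self, config: RuntimeConfig = RuntimeConfig()):
        self.config = config
        self._lock = threading.Lock()
        self._work_available = threading.Condition(self._lock)
        self._actors: Dict[int, _Actor] = {}
        self._ready: deque = deque()
        self._ids = itertools.count(1)
        self._pending = 0  # queued messages + executing handlers
        self._stopped = False
        self.stats = RunStatistics()
        self.dead_letter_log: List[Tuple[ActorRef, Message]] = []

    # -- primitives --------------------------------------------------------

    def spawn(self, behavior: Behavior, name: str = "") -> ActorRef:
        """Create an actor with an empty mailbox (external variant of the
        create primitive)."""
        return self._spawn(behavior, creator=None, name=name)

    def _spawn(self, behavior: Behavior, creator: Optional[ActorRef], name: str = "") -> ActorRef:
        with self._lock:
            if self._stopped:
                raise LifecycleError("spawn after runtime shutdown")
            ref = ActorRef(next(self._ids), name or behavior.name)
            self._actors[ref.actor_id] = _Actor(ref, behavior, creator)
            self.stats.actors_spawned += 1
            return ref

    def send(self, ref: ActorRef, tag: str, *payload: Any) -> None:
        """Enqueue a message from outside any actor; returns immediately."""
        self._send(Message(tag, payload, sender=None), ref)

    def _send(self, msg: Message, ref: ActorRef) -> None:
        with self._lock:
            if self._stopped:
                raise LifecycleError("send after runtime shutdown")
            self.stats.messages_sent += 1
            actor = self._actors.get(ref.actor_id)
            if actor is None or actor.state != "alive":
                self.stats.dead_letters += 1
                self.dead_letter_log.append((ref, msg))
                logger.debug("dead letter: %s to %r", msg.tag, ref)
                return
            actor.mailbox.append(msg)
            self._pending += 1
            self._mark_ready(actor)
            self._work_available.notify()

    def _mark_ready(self, actor: _Actor) -> None:
        # an actor sits on the ready queue at most once, and never while a
        # lane is executing one of its handlers (per-actor serialization)
        if not actor.on_ready_queue and not actor.executing and actor.mailbox:
            actor.on_ready_queue = True
            self._ready.append(actor)

    # -- scheduling --------------------------------------------------------

    def _take_actor(self) -> Optional[_Actor]:
        if self._ready:
            actor = self._ready.popleft()
            actor.on_ready_queue = False
            actor.executing = True
            return actor
        return None

    def _process_one(self, actor: _Actor, worker_id: int) -> None:
        with self._lock:
            if not actor.mailbox or actor.state != "alive":
                # mail may have been flushed by a failure
                actor.executing = False
                self._mark_ready(actor)
                return
            msg = actor.mailbox.popleft()
        ctx = ActorContext(self, actor, msg)
        error: Optional[BaseException] = None
        try:
            handler = actor.behavior.handler_for(msg.tag)
            handler(ctx, *msg.payload)
        except BaseException as exc:  # noqa: BLE001 - supervision boundary
            error = exc
        finally:
            ctx._invalidate()
        with self._lock:
            self._pending -= 1
            self.stats.messages_processed += 1
            self.stats.per_worker[worker_id] = self.stats.per_worker.get(worker_id, 0) + 1
            if actor.pending_behavior is not None:
                actor.behavior = actor.pending_behavior
                actor.pending_behavior = None
            actor.executing = False
            if error is not None:
                self._fail_actor_locked(actor, error)
            else:
                self._mark_ready(actor)
            if self._pending == 0:
                self._work_available.notify_all()
            elif actor.on_ready_queue:
                self._work_available.notify()

    def _fail_actor_locked(self, actor: _Actor, error: BaseException) -> None:
        actor.state = "failed"
        self.stats.actors_failed += 1
        logger.warning("actor %r failed: %r", actor.ref, error)
        # flush undelivered mail to dead letters
        while actor.mailbox:
            msg = actor.mailbox.popleft()
            self._pending -= 1
            self.stats.dead_letters += 1
            self.dead_letter_log.append((actor.ref, msg))
        # supervision: notify the creator
        creator = self._actors.get(actor.creator.actor_id) if actor.creator else None
        if creator is not None and creator.state == "alive":
            self.stats.messages_sent += 1
            creator.mailbox.append(
                Message("actor_failed", (actor.ref, repr(error)), sender=actor.ref)
            )
            self._pending += 1
            self._mark_ready(creator)
            self._work_available.notify()

    # -- execution ---------------------------------------------------------

    def run_until_quiescent(self) -> RunStatistics:
        """Process messages until every mailbox is empty and no handler is
        executing, then return run statistics."""
        with self._lock:
            if self._stopped:
                raise LifecycleError("run after runtime shutdown")
            if not self._actors:
                raise LifecycleError("no actors spawned")
        if self.config.worker_count == 1:
            self._run_single_lane()
        else:
            self._run_threaded()
        return self.stats

    def _run_single_lane(self) -> None:
        # deterministic event loop in the calling thread
        while True:
            with self._lock:
                if self._pending == 0:
                    return
                actor = self._take_actor()
            if actor is not None:
                self._process_one(actor, worker_id=0)

    def _run_threaded(self) -> None:
        done = threading.Event()

        def lane(worker_id: int) -> None:
            while True:
                with self._lock:
                    while not self._ready:
                        if self._pending == 0 or done.is_set():
                            done.set()
                            self._work_available.notify_all()
                            return
                        self._work_available.wait(timeout=0.1)
                    actor = self._take_actor()
                if actor is not None:
                    self._process_one(actor, worker_id)

        threads = [
            threading.Thread(target=lane, args=(k,), name=f"lane-{k}", daemon=True)
            for k in range(self.config.worker_count)
        ]
        for t in threads:
            t.start()
        for t in threads:
            t.join()

    def shutdown(self) -> None:
        with self._lock:
            self._stopped = True

    # -- introspection (tests only) ----------------------------------------

    def actor_state(self, ref: ActorRef) -> str:
        with self._lock:
            actor = self._actors.get(ref.actor_id)
            return actor.state if actor else "unknown"

    def live_actor_count(self) -> int:
        with self._lock:
            return sum(1 for a in self._actors.values() if a.state == "alive")
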