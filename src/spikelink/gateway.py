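"""Simulator-side gateway: the FIFO queue between the packet receiver and
the model consumer, with the latency-requirement (LR) gating policy.

In offline mode every delivered item is consumed without real-time
constraints (LR is set far above the stream duration, e.g. 1,000 s for a
100 s recording, so the gate never fires). In online mode the consumer is
paced against the wall clock; when the simulation falls behind real time,
whole queue items are discarded so it can catch up.

The gate reproduces the two-stage test of the original queue: if the
queue holds fewer than two items the simulation is assumed to be keeping
up and the head is returned directly; otherwise, while the lag between
the newest queued input time and the current simulation time exceeds LR,
the head item is discarded and the test repeats.
"""

from __future__ import annotations

import threading
import time
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Protocol

__all__ = [
    "GatewayQueue",
    "SimClock",
    "Consumer",
    "SessionReport",
    "pull_gated",
    "run_session",
]


class Consumer(Protocol):
    """Contract for the model-side consumer (callback style).

    ``callback_interval`` is the simulated-time period between queue
    checks in online mode; ``accept(item, sim_time)`` feeds one queue
    element to the model.
    """

    callback_interval: float

    def accept(self, item: Any, sim_time: float) -> None: ...


@dataclass
class SimClock:
    """Consumer/simulation time.

    ``sim_time`` is how far the simulation has progressed in simulated
    seconds: it advances to the input time of each consumed item (so a
    consumer that processes items slower than they arrive falls behind
    the newest queued input time, which is exactly the lag the LR gate
    measures). ``wall_anchor`` is set in online mode and paces the
    callback schedule against the wall clock; it does not drive
    ``sim_time``.
    """

    sim_time: float = 0.0
    wall_anchor: float | None = None

    def start_online(self) -> None:
        self.wall_anchor = time.monotonic()

    def wall_elapsed(self) -> float:
        assert self.wall_anchor is not None, "online clock not started"
        return time.monotonic() - self.wall_anchor

    def advance_to(self, t: float) -> None:
        if t > self.sim_time:
            self.sim_time = t


class GatewayQueue:
    """Thread-safe FIFO of (item, input_time) pairs.

    ``latest_t`` tracks the newest input time represented in the queue
    (window end for binned vectors, max real-entry timestamp for spike
    items); it is non-decreasing over enqueues. Safe under one producer
    and one consumer thread: no item is lost, duplicated, or delivered
    out of FIFO order.
    """

    def __init__(self) -> None:
        self._items: deque[tuple[Any, float]] = deque()
        self._lock = threading.Lock()
        self._not_empty = threading.Condition(self._lock)
        self.latest_t: float | None = None
        self.discard_count = 0
        self.enqueued_count = 0
        self._closed = False

    def __len__(self) -> int:
        with self._lock:
            return len(self._items)

    @property
    def closed(self) -> bool:
        with self._lock:
            return self._closed

    def enqueue(self, item: Any, input_time: float) -> None:
        with self._not_empty:
            if self._closed:
                raise RuntimeError("queue is closed (EXIT already received)")
            self._items.append((item, input_time))
            self.enqueued_count += 1
            if self.latest_t is None or input_time > self.latest_t:
                self.latest_t = input_time
            self._not_empty.notify()

    def close(self) -> None:
        """Mark end of stream (EXIT observed); waiting consumers wake up."""
        with self._not_empty:
            self._closed = True
            self._not_empty.notify_all()

    def pop_wait(self, timeout: float | None = None) -> tuple[Any, float] | None:
        """Blocking pop: waits for an item or for the queue to be closed
        and drained. Returns None only at end of stream (or timeout)."""
        deadline = None if timeout is None else time.monotonic() + timeout
        with self._not_empty:
            while not self._items:
                if self._closed:
                    return None
                remaining = None if deadline is None else deadline - time.monotonic()
                if remaining is not None and remaining <= 0:
                    return None
                self._not_empty.wait(remaining)
            return self._items.popleft()

    def pull_gated(self, sim_time: float, lr: float) -> tuple[Any, float] | None:
        """Latency-gated pop (non-blocking); see module docstring.

        Returns None only when the queue is empty. Discarded items count
        toward ``discard_count`` and are never delivered.
        """
        if lr <= 0:
            raise ValueError("latency requirement LR must be > 0")
        with self._lock:
            while True:
                if len(self._items) < 2:
                    # fewer than two items: assume the simulation keeps up
                    return self._items.popleft() if self._items else None
                assert self.latest_t is not None
                if self.latest_t - sim_time > lr:
                    self._items.popleft()
                    self.discard_count += 1
                    continue
                return self._items.popleft()


def pull_gated(q: GatewayQueue, clock: SimClock, lr: float):
    """Functional alias for :meth:`GatewayQueue.pull_gated`."""
    return q.pull_gated(clock.sim_time, lr)


@dataclass
class SessionReport:
    """Outcome of one gateway session."""

    processed: int = 0
    discarded: int = 0
    enqueued: int = 0
    mode: str = "offline"
    aborted: bool = False
    abort_reason: str | None = None
    wall_time: float = 0.0
    extra: dict = field(default_factory=dict)


def run_session(
    q: GatewayQueue,
    consumer: Consumer,
    mode: str,
    lr: float,
    poll_timeout: float = 0.05,
) -> SessionReport:
    """Drive the consumer from the queue until end of stream.

    Offline: every item is consumed in FIFO order with no gating; the
    simulation clock jumps to each item's input time. Online: the
    consumer's callback fires every ``callback_interval`` of wall time
    and pulls through the LR gate; consuming an item advances the
    simulation clock past the input times of whatever the gate skipped,
    mirroring a simulator that leaps over lagging input.
    """
    report = SessionReport(mode=mode)
    clock = SimClock()
    start = time.monotonic()
    try:
        if mode == "offline":
            while True:
                got = q.pop_wait()
                if got is None:
                    break
                item, t_in = got
                clock.advance_to(t_in)
                consumer.accept(item, clock.sim_time)
                report.processed += 1
        elif mode == "online":
            clock.start_online()
            interval = consumer.callback_interval
            next_cb = interval
            while True:
                wall = clock.wall_elapsed()
                if wall < next_cb:
                    if q.closed and len(q) == 0:
                        break
                    time.sleep(min(next_cb - wall, poll_timeout))
                    continue
                next_cb += interval
                got = q.pull_gated(clock.sim_time, lr)
                if got is None:
                    if q.closed and len(q) == 0:
                        break
                    continue
                item, t_in = got
                # the clock leaps past whatever the gate skipped
                clock.advance_to(t_in)
                consumer.accept(item, clock.sim_time)
                report.processed += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except Exception as exc:  # consumer failure aborts the session
        report.aborted = True
        report.abort_reason = f"{type(exc).__name__}: {exc}"
    report.discarded = q.discard_count
    report.enqueued = q.enqueued_count
    report.wall_time = time.monotonic() - start
    return report
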