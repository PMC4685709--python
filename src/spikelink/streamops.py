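"""Streaming data-processing operators: reordering, noise filtering,
binning, and itemizing.

All operators are explicit-state streaming steps: each call consumes one
batch, emits whatever can be finalized, and returns an updated carry-over
state. End-of-stream completion is handled by the matching ``flush_*``
function. This shape lets the same operators run unchanged on either side
of the transport (heavyweight vs lightweight client placement) with
bit-identical results.

Reordering
    The acquisition server occasionally delivers spikes out of order
    across chunks. Each step releases, time-sorted, every buffered spike
    with timestamp at most K, the maximum timestamp of the *previous*
    chunk, and retains the rest; output therefore trails input by one
    chunk, which is exactly the delay needed to absorb a one-chunk
    displacement.

Sync filtering
    Near-simultaneous spikes on multiple electrodes within a very short
    window T (e.g. 25 microseconds) are treated as noise. Time is tiled
    into absolute windows [T*p, T*(p+1)); a spike survives iff it is the
    only spike, over all channels and units, in its window. The last
    (still-open) window is deferred to the next step.

Binning
    Counts spikes per channel over fixed windows of width W, emitting one
    count vector per fully elapsed window (the continuous "P" input).

Itemizing
    Packs spikes into fixed-capacity groups of G with zero padding and a
    real-spike counter (the discrete "NSLOC" input; the queue element).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import Spike, SpikeChunk

__all__ = [
    "ReorderState",
    "SyncFilterState",
    "BinState",
    "BinnedVector",
    "SpikeItem",
    "FilterState",
    "reorder_step",
    "flush_reorder",
    "filter_unsorted",
    "filter_sync_step",
    "flush_sync",
    "bin_step",
    "flush_bin",
    "itemize_chunk",
    "apply_filter_option",
    "flush_filter_option",
]

_SORT_KEY = lambda s: (s.t, s.channel, s.unit)  # noqa: E731  stable sort keeps arrival order


def _check_sorted(spikes, what: str) -> None:
    for a, b in zip(spikes, spikes[1:]):
        if b.t < a.t:
            raise ValueError(f"{what} requires time-sorted input")


# ---------------------------------------------------------------------------
# reordering

@dataclass
class ReorderState:
    """Carry-over of the reordering operator.

    ``k_prev`` is the maximum timestamp observed in the previous chunk
    (None before the second chunk); ``rs`` holds the spikes not yet
    released, in arrival order.
    """

    k_prev: float | None = None
    rs: list[Spike] = field(default_factory=list)


def reorder_step(state: ReorderState, chunk: SpikeChunk) -> tuple[list[Spike], ReorderState]:
    """One reordering step; returns (released time-sorted spikes, state').

    The first chunk only primes the buffer (nothing can be released until
    a later chunk bounds how late a straggler may still arrive). From the
    second chunk on, every buffered spike with ``t <= K`` is released,
    where K is the previous chunk's maximum timestamp. Ties in ``t`` are
    broken by (channel, unit, arrival order).
    """
    temp = state.rs + list(chunk.spikes)
    chunk_max = chunk.max_t()
    new_k = state.k_prev if chunk_max is None else chunk_max
    if state.k_prev is None:
        return [], ReorderState(k_prev=new_k, rs=temp)
    released = sorted((s for s in temp if s.t <= state.k_prev), key=_SORT_KEY)
    remaining = [s for s in temp if s.t > state.k_prev]
    return released, ReorderState(k_prev=new_k, rs=remaining)


def flush_reorder(state: ReorderState) -> list[Spike]:
    """Release everything still buffered, time-sorted (end of stream)."""
    out = sorted(state.rs, key=_SORT_KEY)
    state.rs = []
    return out


# ---------------------------------------------------------------------------
# filtering

def filter_unsorted(spikes: list[Spike]) -> list[Spike]:
    """Drop unit-0 (unsorted) spikes; order preserved."""
    return [s for s in spikes if s.unit != 0]


@dataclass
class SyncFilterState:
    """Carry-over of the sync filter: the spikes of the newest, still-open
    detection window (all sharing one floor(t/T) index)."""

    T: float
    rs: list[Spike] = field(default_factory=list)


def _win(t: float, T: float) -> int:
    return int(math.floor(t / T))


def filter_sync_step(
    state: SyncFilterState, spikes: list[Spike]
) -> tuple[list[Spike], SyncFilterState]:
    """One sync-filter step on a time-sorted batch.

    Windows strictly before the newest one seen so far are finalized: a
    spike survives iff it is alone in its window. The newest window stays
    open in the carry-over until a later batch (or the flush) closes it.
    """
    temp = state.rs + list(spikes)
    _check_sorted(temp, "filter_sync_step")
    if not temp:
        return [], state
    T = state.T
    p_max = _win(temp[-1].t, T)
    kept: list[Spike] = []
    deferred: list[Spike] = []
    i = 0
    n = len(temp)
    while i < n:
        p = _win(temp[i].t, T)
        j = i
        while j < n and _win(temp[j].t, T) == p:
            j += 1
        if p == p_max:
            deferred.extend(temp[i:j])
        elif j - i == 1:
            kept.append(temp[i])
        i = j
    return kept, SyncFilterState(T=T, rs=deferred)


def flush_sync(state: SyncFilterState) -> list[Spike]:
    """Finalize the last open window at end of stream."""
    out = state.rs if len(state.rs) == 1 else []
    state.rs = []
    return out


# ---------------------------------------------------------------------------
# binning

@dataclass(eq=False)
class BinnedVector:
    """Per-channel spike counts for one binning window.

    ``counts`` has length n_channels (index 0 = channel 1); ``w`` is the
    window index, i.e. the window spans [w*W, (w+1)*W).
    """

    counts: np.ndarray
    w: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinnedVector):
            return NotImplemented
        return self.w == other.w and np.array_equal(self.counts, other.counts)

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinState:
    """Carry-over of the binning operator.

    ``w`` is the index of the currently open window; ``rs`` holds its
    spikes so far; ``dropped_late`` counts spikes that arrived with
    timestamps before the open window (upstream reordering should prevent
    these; they are discarded rather than corrupting already-emitted
    bins).
    """

    W: float
    w: int = 0
    rs: list[Spike] = field(default_factory=list)
    dropped_late: int = 0


def _count_window(spikes: list[Spike], w: int, n_channels: int) -> BinnedVector:
    counts = np.zeros(n_channels, dtype=np.int64)
    for s in spikes:
        counts[s.channel - 1] += 1
    return BinnedVector(counts=counts, w=w)


def bin_step(
    state: BinState, spikes: list[Spike], n_channels: int
) -> tuple[list[BinnedVector], BinState]:
    """One binning step on a time-sorted batch.

    Emits one :class:`BinnedVector` for every window that has fully
    elapsed (every window index below that of the newest spike seen),
    including empty intermediate windows so window indices are gapless.
    """
    for s in spikes:
        if not 1 <= s.channel <= n_channels:
            raise ValueError(f"channel {s.channel} outside [1, {n_channels}]")
    temp = state.rs + list(spikes)
    _check_sorted(temp, "bin_step")
    if not temp:
        return [], state
    W = state.W
    late = [s for s in temp if _win(s.t, W) < state.w]
    temp = [s for s in temp if _win(s.t, W) >= state.w]
    dropped = state.dropped_late + len(late)
    if not temp:
        return [], replace(state, dropped_late=dropped)
    open_w = _win(temp[-1].t, W)
    out: list[BinnedVector] = []
    for w in range(state.w, open_w):
        out.append(_count_window([s for s in temp if _win(s.t, W) == w], w, n_channels))
    rs = [s for s in temp if _win(s.t, W) == open_w]
    return out, BinState(W=W, w=open_w, rs=rs, dropped_late=dropped)


def flush_bin(state: BinState, n_channels: int) -> list[BinnedVector]:
    """Emit the final (still-open) window at end of stream, if non-empty."""
    if not state.rs:
        return []
    out = [_count_window(state.rs, state.w, n_channels)]
    state.rs = []
    return out


# ---------------------------------------------------------------------------
# itemizing

PAD_ENTRY = Spike(0.0, 0, 0)


@dataclass(eq=True)
class SpikeItem:
    """Fixed-capacity group of spikes: the discrete-input queue element.

    Exactly G entries; entries past ``n_real`` are the all-zero padding
    triple and must never be interpreted as spikes. ``serial`` numbers
    items consecutively across a session.
    """

    entries: tuple[Spike, ...]
    n_real: int
    serial: int

    def real_spikes(self) -> tuple[Spike, ...]:
        return self.entries[: self.n_real]

    def max_real_t(self) -> float | None:
        return max((s.t for s in self.real_spikes()), default=None)


def itemize_chunk(spikes: list[Spike], G: int, next_serial: int = 0) -> list[SpikeItem]:
    """Pack spikes into consecutive groups of G in arrival order.

    The final partial group is padded to capacity with zero triples; a
    real-spike counter per item ensures padding is never consumed
    downstream. Serials run consecutively from ``next_serial``; empty
    input yields no items.
    """
    if G < 1:
        raise ValueError("group size G must be >= 1")
    items: list[SpikeItem] = []
    for i in range(0, len(spikes), G):
        group = list(spikes[i : i + G])
        n_real = len(group)
        group.extend([PAD_ENTRY] * (G - n_real))
        items.append(SpikeItem(entries=tuple(group), n_real=n_real, serial=next_serial))
        next_serial += 1
    return items


# ---------------------------------------------------------------------------
# filter-option dispatch

@dataclass
class FilterState:
    """State wrapper for one of the four session filter options.

    ``unsort_sync`` removes unsorted spikes *before* sync detection, so a
    unit-0 spike cannot veto a sorted spike sharing its window.
    """

    option: str
    sync: SyncFilterState | None = None

    @classmethod
    def for_option(cls, option: str, T: float) -> "FilterState":
        if option in ("sync", "unsort_sync"):
            return cls(option=option, sync=SyncFilterState(T=T))
        if option in ("no_filter", "unsort"):
            return cls(option=option)
        raise ValueError(f"unknown filter option {option!r}")


def apply_filter_option(
    spikes: list[Spike], state: FilterState
) -> tuple[list[Spike], FilterState]:
    """Apply the session's filter option to one time-sorted batch."""
    if state.option == "no_filter":
        return list(spikes), state
    if state.option == "unsort":
        return filter_unsorted(spikes), state
    if state.option == "sync":
        out, sync = filter_sync_step(state.sync, spikes)
        return out, FilterState(option=state.option, sync=sync)
    if state.option == "unsort_sync":
        out, sync = filter_sync_step(state.sync, filter_unsorted(spikes))
        return out, FilterState(option=state.option, sync=sync)
    raise ValueError(f"unknown filter option {state.option!r}")


def flush_filter_option(state: FilterState) -> list[Spike]:
    """Finalize any deferred window at end of stream."""
    if state.sync is not None:
        return flush_sync(state.sync)
    return []
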