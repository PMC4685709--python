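"""Synthetic acquisition-server emulator.

Emulates the statistical structure of multielectrode recordings as seen by
a chunked acquisition interface: homogeneous Poisson background activity
split uniformly over channels, a fraction of unsorted (unit-0) spikes,
injected *sync* events (near-simultaneous spikes on multiple electrodes
within a few tens of microseconds, treated as noise downstream), partition
into periodic delivery chunks, and out-of-order delivery produced by
delaying a small fraction of spikes ("stragglers") into the following
chunk with their timestamps unchanged.

Defaults mirror an M1 multiunit recording: 96 channels, 100 s, an
aggregate rate of 1,399 Hz, and 11% unsorted spikes.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .model import Spike, SpikeChunk

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyncEvent",
    "generate_stream",
    "chunk_stream",
    "pace_stream",
]

LABEL_BACKGROUND = "background"
LABEL_UNSORTED = "unsorted"
LABEL_SYNC = "sync-member"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic stream generator.

    ``rate_total`` is the aggregate expected spike rate in Hz across all
    channels (homogeneous Poisson, split uniformly per channel).
    ``sync_rate`` is the expected number of injected sync events per
    second; each event places ``sync_multiplicity`` spikes on distinct
    channels within a span of ``sync_span`` seconds.
    """

    n_channels: int = 96
    duration: float = 100.0
    rate_total: float = 1399.0
    p_unsorted: float = 0.11
    sync_rate: float = 100.0
    sync_span: float = 10e-6
    sync_multiplicity: int = 2
    p_straggler: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.rate_total < 0 or self.sync_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.p_unsorted <= 1.0:
            raise ValueError("p_unsorted must be in [0, 1]")
        if not 0.0 <= self.p_straggler <= 1.0:
            raise ValueError("p_straggler must be in [0, 1]")
        if self.sync_multiplicity < 2:
            raise ValueError("sync_multiplicity must be >= 2")
        if self.sync_multiplicity > self.n_channels:
            raise ValueError("sync_multiplicity cannot exceed n_channels")
        if self.sync_span < 0:
            raise ValueError("sync_span must be >= 0")


@dataclass(frozen=True)
class SyncEvent:
    """Ground-truth record of one injected sync event."""

    t_start: float
    spike_indices: tuple[int, ...]  # indices into the generated stream


@dataclass
class GroundTruth:
    """Per-spike labels and sync-event bookkeeping for a generated stream.

    ``labels[i]`` is one of ``background``, ``unsorted``, ``sync-member``
    and is aligned with the returned (time-sorted) spike sequence.
    """

    labels: list[str] = field(default_factory=list)
    sync_events: list[SyncEvent] = field(default_factory=list)

    def count(self, label: str) -> int:
        return sum(1 for x in self.labels if x == label)

    def straddling_events(self, T: float) -> list[SyncEvent]:
        """Sync events whose spikes do not all share one floor(t/T) window.

        Such events straddle a detection-window boundary and are not
        guaranteed to be caught whole by a sync filter of width ``T``.
        """
        return [
            ev
            for ev in self.sync_events
            if len({math.floor(t / T) for t in ev.member_times}) > 1
        ]


# attach member_times lazily to keep SyncEvent frozen & small
@dataclass(frozen=True)
class _SyncEventFull(SyncEvent):
    member_times: tuple[float, ...] = ()


def generate_stream(gcfg: GeneratorConfig) -> tuple[list[Spike], GroundTruth]:
    """Generate a time-sorted synthetic spike stream with ground truth.

    Background spikes are homogeneous Poisson at ``rate_total`` aggregate,
    channels uniform, units uniform in 1..4 except a ``p_unsorted``
    fraction labelled unit 0. Sync events are Poisson at ``sync_rate``,
    each contributing ``sync_multiplicity`` spikes on distinct channels
    within ``sync_span``; their units are drawn from 1..4 so the unsorted
    and sync contaminations are independent axes. Reproducible given
    ``seed``.
    """
    rng = np.random.default_rng(gcfg.seed)

    n_bg = int(rng.poisson(gcfg.rate_total * gcfg.duration)) if gcfg.duration > 0 else 0
    bg_t = rng.uniform(0.0, gcfg.duration, size=n_bg)
    bg_ch = rng.integers(1, gcfg.n_channels + 1, size=n_bg)
    bg_unsorted = rng.random(n_bg) < gcfg.p_unsorted
    bg_unit = rng.integers(1, 5, size=n_bg)
    bg_unit[bg_unsorted] = 0

    n_ev = int(rng.poisson(gcfg.sync_rate * gcfg.duration)) if gcfg.duration > 0 else 0
    ev_t = rng.uniform(0.0, max(gcfg.duration - gcfg.sync_span, 0.0), size=n_ev)

    records: list[tuple[float, int, int, str, int]] = []  # (t, ch, unit, label, event_id)
    for t, ch, unit, uns in zip(bg_t, bg_ch, bg_unit, bg_unsorted):
        records.append(
            (float(t), int(ch), int(unit), LABEL_UNSORTED if uns else LABEL_BACKGROUND, -1)
        )
    for ev_id in range(n_ev):
        channels = rng.choice(gcfg.n_channels, size=gcfg.sync_multiplicity, replace=False) + 1
        offsets = rng.uniform(0.0, gcfg.sync_span, size=gcfg.sync_multiplicity)
        units = rng.integers(1, 5, size=gcfg.sync_multiplicity)
        for ch, off, unit in zip(channels, offsets, units):
            records.append(
                (float(ev_t[ev_id]) + float(off), int(ch), int(unit), LABEL_SYNC, ev_id)
            )

    order = sorted(range(len(records)), key=lambda i: (records[i][0], records[i][1], records[i][2], i))
    spikes = [Spike(records[i][0], records[i][1], records[i][2]) for i in order]
    labels = [records[i][3] for i in order]

    by_event: dict[int, list[int]] = {}
    for pos, i in enumerate(order):
        ev_id = records[i][4]
        if ev_id >= 0:
            by_event.setdefault(ev_id, []).append(pos)
    events = [
        _SyncEventFull(
            t_start=min(spikes[p].t for p in positions),
            spike_indices=tuple(positions),
            member_times=tuple(spikes[p].t for p in positions),
        )
        for ev_id, positions in sorted(by_event.items())
    ]
    return spikes, GroundTruth(labels=labels, sync_events=events)


def chunk_stream(
    spikes: Sequence[Spike],
    chunk_interval: float,
    p_straggler: float = 0.0,
    seed: int = 0,
) -> list[SpikeChunk]:
    """Partition a time-sorted stream into periodic delivery chunks.

    A spike with ``t`` in ``[k*chunk_interval, (k+1)*chunk_interval)`` is
    assigned to chunk ``k``; an independent ``p_straggler`` fraction is
    delayed into chunk ``k+1`` with timestamps unchanged, creating the
    out-of-order condition the reordering stage must repair. Delayed
    spikes are appended after the natives of their delivery chunk (they
    become available late), so chunks are also internally unsorted.
    Stragglers from the last populated interval land in a final extra
    chunk.
    """
    if chunk_interval <= 0:
        raise ValueError("chunk_interval must be > 0")
    for a, b in zip(spikes, spikes[1:]):
        if b.t < a.t:
            raise ValueError("chunk_stream requires a time-sorted input stream")
    rng = np.random.default_rng(seed)
    natives: dict[int, list[Spike]] = {}
    stragglers: dict[int, list[Spike]] = {}
    max_k = -1
    for s in spikes:
        k = int(math.floor(s.t / chunk_interval))
        if p_straggler > 0 and rng.random() < p_straggler:
            stragglers.setdefault(k + 1, []).append(s)
            max_k = max(max_k, k + 1)
        else:
            natives.setdefault(k, []).append(s)
            max_k = max(max_k, k)
    return [
        SpikeChunk(seq=k, spikes=natives.get(k, []) + stragglers.get(k, []))
        for k in range(max_k + 1)
    ]


def pace_stream(
    chunks: Sequence[SpikeChunk],
    chunk_interval: float,
    speed: float = math.inf,
) -> Iterator[SpikeChunk]:
    """Yield chunks no earlier than their nominal delivery time.

    Chunk ``k`` is released at wall time ``k*chunk_interval/speed`` after
    the first call; ``speed=math.inf`` delivers back-to-back (offline
    testing), ``speed=1`` emulates real-time acquisition pacing.
    """
    if not speed > 0:
        raise ValueError("speed must be > 0")
    start = time.monotonic()
    for chunk in chunks:
        if math.isfinite(speed):
            due = start + (chunk.seq * chunk_interval) / speed
            delay = due - time.monotonic()
            if delay > 0:
                time.sleep(delay)
        yield chunk
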