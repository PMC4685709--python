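"""Core domain types for multiunit spike streams and session configuration.

A *spike* is one detected threshold-crossing event on a microelectrode
channel: a timestamp (seconds), a channel id, and a sorted-unit label in
0..4 where unit 0 means the waveform was not assigned to any sorted unit.
Acquisition servers deliver spikes in periodic *chunks* (e.g. every 10 ms)
whose contents are not guaranteed to be time-ordered, and may contain
timestamps earlier than spikes already delivered in previous chunks.

Spike tables are stored as plain tab-separated text (``t``, ``channel``,
``unit`` columns) so that recordings and emission logs are diffable and
portable; timestamps are serialized at full double precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "Spike",
    "SpikeChunk",
    "SessionConfig",
    "StreamReport",
    "SpikeValidationError",
    "SpikeTableParseError",
    "MAX_UNIT",
    "read_spike_table",
    "write_spike_table",
    "validate_stream",
]

#: Highest sorted-unit label; unit 0 is reserved for unsorted spikes.
MAX_UNIT = 4

PROTOCOLS = ("tcp", "udp")
PLACEMENTS = ("hwc", "lwc")
INPUT_TYPES = ("p", "nsloc")
MODES = ("online", "offline")
FILTER_OPTIONS = ("no_filter", "unsort", "sync", "unsort_sync")


class SpikeValidationError(ValueError):
    """A spike violates the domain invariants (range or finiteness)."""


class SpikeTableParseError(ValueError):
    """A spike-table row failed to parse; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class Spike(NamedTuple):
    """One detected spike event.

    Attributes
    ----------
    t : float
        Event time in seconds (non-negative, finite).
    channel : int
        Microelectrode channel id, 1-based.
    unit : int
        Sorted-unit label in [0, 4]; 0 = unsorted.
    """

    t: float
    channel: int
    unit: int


def validate_spike(spike: Spike, n_channels: int) -> None:
    """Raise :class:`SpikeValidationError` if *spike* breaks an invariant."""
    if not math.isfinite(spike.t) or spike.t < 0:
        raise SpikeValidationError(f"timestamp must be finite and >= 0, got {spike.t!r}")
    if not 1 <= spike.channel <= n_channels:
        raise SpikeValidationError(
            f"channel {spike.channel} outside [1, {n_channels}]"
        )
    if not 0 <= spike.unit <= MAX_UNIT:
        raise SpikeValidationError(f"unit {spike.unit} outside [0, {MAX_UNIT}]")


@dataclass
class SpikeChunk:
    """One acquisition delivery: a sequence number plus the spikes made
    available during one polling interval, in as-received order (which is
    not necessarily time order)."""

    seq: int
    spikes: list[Spike] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spikes)

    def max_t(self) -> float | None:
        return max((s.t for s in self.spikes), default=None)


@dataclass(frozen=True)
class SessionConfig:
    """Negotiated run parameters for one streaming session.

    The configuration lives on the server side only; clients receive it
    through the handshake. ``placement`` selects where the processing
    pipeline runs: ``hwc`` (heavyweight client) runs reorder/filter and
    binning or itemizing on the client, ``lwc`` (lightweight client) ships
    reordered raw chunks and lets the server process them.
    """

    protocol: str = "tcp"
    placement: str = "hwc"
    input_type: str = "p"
    mode: str = "offline"
    bin_window: float = 0.1          # W, seconds
    sync_window: float = 25e-6       # T, seconds (25 us or 1 ms variants)
    filter_option: str = "no_filter"
    latency_requirement: float = 1000.0  # LR, seconds
    n_channels: int = 96
    group_size: int = 20             # G, spikes per queue item
    chunk_interval: float = 0.01     # acquisition polling period, seconds

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        if self.input_type not in INPUT_TYPES:
            raise ValueError(f"input_type must be one of {INPUT_TYPES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.filter_option not in FILTER_OPTIONS:
            raise ValueError(f"filter_option must be one of {FILTER_OPTIONS}")
        if self.bin_window <= 0:
            raise ValueError("bin_window must be > 0")
        if self.sync_window <= 0:
            raise ValueError("sync_window must be > 0")
        if self.latency_requirement <= 0:
            raise ValueError("latency_requirement must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.chunk_interval <= 0:
            raise ValueError("chunk_interval must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SessionConfig fields: {sorted(unknown)}")
        return cls(**d)


_HEADER = "t\tchannel\tunit"


def write_spike_table(spikes: Iterable[Spike], path: str | Path) -> None:
    """Write spikes as a TSV table (header ``t\\tchannel\\tunit``).

    Timestamps use Python's shortest-round-trip float repr, which preserves
    the full double value exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_HEADER + "\n")
        for s in spikes:
            fh.write(f"{s.t!r}\t{s.channel}\t{s.unit}\n")


def read_spike_table(path: str | Path, config: SessionConfig | None = None) -> list[Spike]:
    """Read a TSV spike table, preserving row order.

    Rows are validated against the spike invariants using the channel count
    from *config* (default 96). Malformed rows raise
    :class:`SpikeTableParseError` naming the offending line.
    """
    n_channels = config.n_channels if config is not None else 96
    spikes: list[Spike] = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line_no == 1:
                if line != _HEADER:
                    raise SpikeTableParseError(line_no, f"expected header {_HEADER!r}")
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SpikeTableParseError(line_no, f"expected 3 fields, got {len(parts)}")
            try:
                spike = Spike(float(parts[0]), int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise SpikeTableParseError(line_no, str(exc)) from exc
            try:
                validate_spike(spike, n_channels)
            except SpikeValidationError as exc:
                raise SpikeTableParseError(line_no, str(exc)) from exc
            spikes.append(spike)
    return spikes


@dataclass
class StreamReport:
    """Report-only summary of a chunked stream (never raises)."""

    n_spikes: int = 0
    per_channel: dict[int, int] = field(default_factory=dict)
    n_unsorted: int = 0
    n_out_of_order: int = 0
    t_min: float | None = None
    t_max: float | None = None


def validate_stream(chunks: Sequence[SpikeChunk], config: SessionConfig) -> StreamReport:
    """Summarize a chunked stream: totals, per-channel counts, unsorted
    count, and the number of out-of-order spikes.

    A spike is out-of-order when its timestamp is earlier than the running
    maximum over all spikes seen in *prior* chunks (the condition the
    reordering stage exists to repair).
    """
    report = StreamReport(per_channel={c: 0 for c in range(1, config.n_channels + 1)})
    running_max: float | None = None
    for chunk in chunks:
        for s in chunk.spikes:
            report.n_spikes += 1
            report.per_channel[s.channel] = report.per_channel.get(s.channel, 0) + 1
            if s.unit == 0:
                report.n_unsorted += 1
            if running_max is not None and s.t < running_max:
                report.n_out_of_order += 1
            report.t_min = s.t if report.t_min is None else min(report.t_min, s.t)
            report.t_max = s.t if report.t_max is None else max(report.t_max, s.t)
        chunk_max = chunk.max_t()
        if chunk_max is not None:
            running_max = chunk_max if running_max is None else max(running_max, chunk_max)
    return report
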