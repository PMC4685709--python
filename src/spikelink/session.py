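"""End-to-end loopback session: synthetic source -> client pipeline ->
packet codec -> gateway queue -> model scaffold, with per-stage
accounting.

The client side always performs the reordering (it owns the acquisition
interface); the remaining processing — noise filtering, then binning
(continuous input) or itemizing (discrete input) — runs on the client in
heavyweight-client (HWC) placement or on the server in lightweight-client
(LWC) placement. Both placements execute the identical operators on the
identical batch boundaries, so the delivered sequences are bit-identical;
the loopback runner routes every value through the wire codec either way.
"""

from __future__ import annotations

import dataclasses
import json
import math
import threading
import time
from dataclasses import dataclass
from pathlib import Path

from . import transport
from .gateway import GatewayQueue, run_session
from .model import SessionConfig, Spike, SpikeChunk, validate_stream
from .scaffold import ScaffoldNetwork, build_scaffold
from .streamops import (
    BinnedVector,
    BinState,
    FilterState,
    ReorderState,
    SpikeItem,
    apply_filter_option,
    bin_step,
    flush_bin,
    flush_filter_option,
    flush_reorder,
    itemize_chunk,
    reorder_step,
)
from .synthetic import GeneratorConfig, chunk_stream, generate_stream, pace_stream
from .transport import Packet

__all__ = [
    "EndToEndReport",
    "ScaffoldConsumer",
    "DataPipeline",
    "run_end_to_end",
    "summarize_session",
    "load_summary",
]


class DataPipeline:
    """Filter + bin/itemize stage, identical on either placement.

    Consumes time-sorted batches (the reorder stage's releases) and
    produces queue elements: :class:`BinnedVector` (continuous input) or
    :class:`SpikeItem` (discrete input).
    """

    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg
        self.fstate = FilterState.for_option(cfg.filter_option, cfg.sync_window)
        self.bstate = BinState(W=cfg.bin_window)
        self.next_serial = 0
        self.n_filtered_in = 0
        self.n_filtered_out = 0

    def _emit(self, filtered: list[Spike]):
        if self.cfg.input_type == "p":
            out, self.bstate = bin_step(self.bstate, filtered, self.cfg.n_channels)
            return out
        items = itemize_chunk(filtered, self.cfg.group_size, self.next_serial)
        self.next_serial += len(items)
        return items

    def process_batch(self, batch: list[Spike]):
        self.n_filtered_in += len(batch)
        filtered, self.fstate = apply_filter_option(batch, self.fstate)
        self.n_filtered_out += len(filtered)
        return self._emit(filtered)

    def finish(self):
        """Finalize deferred filter windows and the open bin window."""
        tail = flush_filter_option(self.fstate)
        self.n_filtered_out += len(tail)
        out = self._emit(tail)
        if self.cfg.input_type == "p":
            out = out + flush_bin(self.bstate, self.cfg.n_channels)
        return out

    @property
    def dropped_late(self) -> int:
        return self.bstate.dropped_late


def _encode_element(elem, cfg: SessionConfig) -> Packet:
    if isinstance(elem, BinnedVector):
        payload = transport.encode_binned_payload(elem, cfg.n_channels)
    else:
        payload = transport.encode_item_payload(elem, cfg.group_size)
    return Packet(header=transport.HEADER_DATA, payload=payload)


def _decode_element(payload: bytes, cfg: SessionConfig):
    if cfg.input_type == "p":
        return transport.decode_binned_payload(payload, cfg.n_channels)
    return transport.decode_item_payload(payload, cfg.group_size)


def input_time(elem, cfg: SessionConfig) -> float:
    """The input time an element represents: the window *end* for a bin
    (the bin stands for its whole window), the newest real-entry
    timestamp for a spike item."""
    if isinstance(elem, BinnedVector):
        return (elem.w + 1) * cfg.bin_window
    t = elem.max_real_t()
    return 0.0 if t is None else t


class ClientSide:
    """Reorder + (in HWC) the processing pipeline; emits wire packets."""

    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg
        self.rstate = ReorderState()
        self.pipeline = DataPipeline(cfg) if cfg.placement == "hwc" else None
        self.raw_seq = 0

    def _packets_for_batch(self, batch: list[Spike]) -> list[Packet]:
        if self.pipeline is not None:
            elems = self.pipeline.process_batch(batch)
            return [_encode_element(e, self.cfg) for e in elems]
        if not batch:
            return []
        pkt = Packet(
            header=transport.HEADER_DATA,
            payload=transport.encode_chunk_payload(
                SpikeChunk(seq=self.raw_seq, spikes=batch)
            ),
        )
        self.raw_seq += 1
        return [pkt]

    def process_chunk(self, chunk: SpikeChunk) -> list[Packet]:
        released, self.rstate = reorder_step(self.rstate, chunk)
        packets = self._packets_for_batch(released)
        # keep-alive when a delivery tick produced nothing to send
        return packets or [Packet(header=transport.HEADER_NODATA)]

    def finish(self) -> list[Packet]:
        packets = self._packets_for_batch(flush_reorder(self.rstate))
        if self.pipeline is not None:
            packets += [_encode_element(e, self.cfg) for e in self.pipeline.finish()]
        packets.append(Packet(header=transport.HEADER_EXIT))
        return packets


class ServerSide:
    """Decodes packets into queue elements; in LWC runs the pipeline."""

    def __init__(self, cfg: SessionConfig, queue: GatewayQueue):
        self.cfg = cfg
        self.queue = queue
        self.pipeline = DataPipeline(cfg) if cfg.placement == "lwc" else None
        self.packets_received = 0
        self.nodata_received = 0
        self.elements = 0

    def _enqueue(self, elems) -> None:
        for e in elems:
            self.queue.enqueue(e, input_time(e, self.cfg))
            self.elements += 1

    def handle_packet(self, pkt: Packet) -> bool:
        """Process one packet; returns False once EXIT is handled."""
        self.packets_received += 1
        if pkt.header == transport.HEADER_NODATA:
            self.nodata_received += 1
            return True
        if pkt.header == transport.HEADER_EXIT:
            if self.pipeline is not None:
                self._enqueue(self.pipeline.finish())
            self.queue.close()
            return False
        if self.pipeline is not None:
            batch = transport.decode_chunk_payload(pkt.payload).spikes
            self._enqueue(self.pipeline.process_batch(batch))
        else:
            self._enqueue([_decode_element(pkt.payload, self.cfg)])
        return True


class ScaffoldConsumer:
    """Feeds queue elements to the model scaffold.

    ``callback_interval`` defaults to the binning window for continuous
    input and 1 ms of simulated time for discrete input (the queue is
    checked at short intervals so a lagging simulation can skip forward).
    ``delay`` adds an artificial per-item processing cost, used to emulate
    a simulation slower than real time.
    """

    def __init__(self, net: ScaffoldNetwork, cfg: SessionConfig, delay: float = 0.0):
        self.net = net
        self.cfg = cfg
        self.delay = delay
        self.emitted = 0
        if cfg.input_type == "p":
            self.callback_interval = cfg.bin_window
        else:
            self.callback_interval = 1e-3

    def accept(self, item, sim_time: float) -> None:
        if self.delay > 0:
            time.sleep(self.delay)
        if isinstance(item, BinnedVector):
            self.emitted += len(self.net.feed_binned(item, sim_time))
        else:
            self.emitted += len(self.net.feed_discrete(item))


@dataclass
class EndToEndReport:
    """Per-stage accounting for one loopback session.

    Conservation identities: ``delivered + discarded == enqueued``;
    with no filtering, ``binned_total + dropped_late`` equals the number
    of generated spikes (continuous input), and the sum of item real
    counts equals it (discrete input).
    """

    mode: str = "offline"
    placement: str = "hwc"
    input_type: str = "p"
    protocol: str = "tcp"
    filter_option: str = "no_filter"
    generated: int = 0
    out_of_order: int = 0
    filter_input: int = 0
    filter_output: int = 0
    elements: int = 0
    packets_sent: int = 0
    packets_received: int = 0
    nodata: int = 0
    enqueued: int = 0
    discarded: int = 0
    delivered: int = 0
    emitted: int = 0
    dropped_late: int = 0
    aborted: bool = False
    abort_reason: str | None = None
    wall_time: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EndToEndReport":
        return cls(**d)


def run_end_to_end(
    cfg: SessionConfig,
    gcfg: GeneratorConfig,
    speed: float | None = None,
    consumer_delay: float = 0.0,
) -> tuple[EndToEndReport, ScaffoldNetwork]:
    """Run a full loopback session in one process.

    Every queue element passes through the byte codec (encode then
    decode), so the wire representation is exercised even without
    sockets. Offline sessions are bit-reproducible under fixed seeds;
    online sessions pace chunk delivery against the wall clock at
    ``speed`` (default 1.0, i.e. real time) and apply the LR gate.
    Returns the session report and the scaffold (whose emission log holds
    everything the model received).
    """
    if cfg.n_channels != gcfg.n_channels:
        raise ValueError("session and generator channel counts must agree")
    if speed is None:
        speed = 1.0 if cfg.mode == "online" else math.inf

    spikes, _gt = generate_stream(gcfg)
    chunks = chunk_stream(
        spikes, cfg.chunk_interval, gcfg.p_straggler, seed=(gcfg.seed + 1) % 2**31
    )
    stream_report = validate_stream(chunks, cfg)

    queue = GatewayQueue()
    client = ClientSide(cfg)
    server = ServerSide(cfg, queue)
    net = build_scaffold({"P": cfg.n_channels, "ES": cfg.n_channels})
    consumer = ScaffoldConsumer(net, cfg, delay=consumer_delay)

    packets_sent = 0

    def produce() -> int:
        sent = 0
        for chunk in pace_stream(chunks, cfg.chunk_interval, speed=speed):
            for pkt in client.process_chunk(chunk):
                server.handle_packet(transport.decode_packet(transport.encode_packet(pkt)))
                sent += 1
        for pkt in client.finish():
            server.handle_packet(transport.decode_packet(transport.encode_packet(pkt)))
            sent += 1
        return sent

    if cfg.mode == "offline":
        packets_sent = produce()
        session = run_session(
            queue, consumer, mode="offline", lr=cfg.latency_requirement,
        )
    else:
        result: dict[str, int] = {}

        def _producer() -> None:
            result["sent"] = produce()

        prod = threading.Thread(target=_producer, daemon=True)
        prod.start()
        session = run_session(
            queue, consumer, mode="online", lr=cfg.latency_requirement,
        )
        prod.join()
        packets_sent = result.get("sent", 0)

    pipeline = client.pipeline if client.pipeline is not None else server.pipeline
    report = EndToEndReport(
        mode=cfg.mode,
        placement=cfg.placement,
        input_type=cfg.input_type,
        protocol=cfg.protocol,
        filter_option=cfg.filter_option,
        generated=len(spikes),
        out_of_order=stream_report.n_out_of_order,
        filter_input=pipeline.n_filtered_in,
        filter_output=pipeline.n_filtered_out,
        elements=server.elements,
        packets_sent=packets_sent,
        packets_received=server.packets_received,
        nodata=server.nodata_received,
        enqueued=session.enqueued,
        discarded=session.discarded,
        delivered=session.processed,
        emitted=consumer.emitted,
        dropped_late=pipeline.dropped_late,
        aborted=session.aborted,
        abort_reason=session.abort_reason,
        wall_time=session.wall_time,
    )
    return report, net


def summarize_session(report: EndToEndReport, path: str | Path) -> None:
    """Write the session report as a machine-readable JSON summary."""
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_summary(path: str | Path) -> EndToEndReport:
    with Path(path).open("r", encoding="utf-8") as fh:
        return EndToEndReport.from_dict(json.load(fh))
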