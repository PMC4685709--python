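"""Packetized transport: bit-exact codecs, TCP/UDP channels, handshake.

Wire format
-----------
Every packet is framed as::

    8-byte ASCII header tag  ("DATA\\0\\0\\0\\0" | "NODATA\\0\\0" | "EXIT\\0\\0\\0\\0")
    4-byte big-endian unsigned payload length
    payload bytes

Every 8-byte payload slot is a little-endian IEEE-754 double, including
counts, window indices and serials; all such values are integral and far
below 2**53, so they round-trip exactly.

Payload layouts (sizes at the defaults of 96 channels and 20-spike
groups):

* binned vector (continuous "P" input): ``n_channels`` per-channel counts
  followed by the window index — ``8*n_channels + 8`` bytes = **776**;
* queue item (discrete "NSLOC" input): ``G`` (t, channel, unit) triples,
  then the real-spike count, then the item serial — ``24*G + 16`` bytes
  = **496**;
* raw chunk (lightweight-client placement): chunk seq, spike count, then
  the (t, channel, unit) triples.

TCP connections disable Nagle's algorithm (each small packet is flushed
immediately rather than coalesced, which matters for real-time
streaming). UDP sends one packet per datagram with no delivery or order
guarantee; receivers must tolerate loss.

The configuration handshake always runs over TCP, even for UDP data
sessions: the server transmits the full session configuration as one
JSON line and the client acknowledges, so configuration lives only on
the server side.
"""

from __future__ import annotations

import json
import socket
import struct
from dataclasses import dataclass

import numpy as np

from .model import SessionConfig, Spike, SpikeChunk
from .streamops import BinnedVector, SpikeItem

__all__ = [
    "Packet",
    "FramingError",
    "CodecError",
    "HandshakeError",
    "HEADER_DATA",
    "HEADER_NODATA",
    "HEADER_EXIT",
    "encode_binned_payload",
    "decode_binned_payload",
    "encode_item_payload",
    "decode_item_payload",
    "encode_chunk_payload",
    "decode_chunk_payload",
    "encode_packet",
    "decode_packet",
    "TcpChannel",
    "UdpChannel",
    "handshake_server",
    "handshake_client",
    "send_stream",
]

HEADER_DATA = "DATA"
HEADER_NODATA = "NODATA"
HEADER_EXIT = "EXIT"

_TAGS = {
    HEADER_DATA: b"DATA\x00\x00\x00\x00",
    HEADER_NODATA: b"NODATA\x00\x00",
    HEADER_EXIT: b"EXIT\x00\x00\x00\x00",
}
_TAG_LOOKUP = {v: k for k, v in _TAGS.items()}
_LEN_STRUCT = struct.Struct(">I")
FRAME_OVERHEAD = 12  # 8-byte tag + 4-byte length


class FramingError(ValueError):
    """Malformed wire frame: short read, unknown tag, or length mismatch."""


class CodecError(ValueError):
    """Payload does not match the declared layout."""


class HandshakeError(RuntimeError):
    """Configuration handshake was refused or malformed."""


@dataclass(frozen=True)
class Packet:
    header: str
    payload: bytes = b""

    def __post_init__(self) -> None:
        if self.header not in _TAGS:
            raise ValueError(f"unknown packet header {self.header!r}")
        if self.header != HEADER_DATA and self.payload:
            raise ValueError(f"{self.header} packets carry no payload")


# ---------------------------------------------------------------------------
# payload codecs

def encode_binned_payload(bv: BinnedVector, n_channels: int) -> bytes:
    """Serialize a binned vector: n_channels count doubles + window index."""
    if len(bv.counts) != n_channels:
        raise CodecError(
            f"counts length {len(bv.counts)} does not match n_channels {n_channels}"
        )
    vals = np.empty(n_channels + 1, dtype="<f8")
    vals[:n_channels] = bv.counts
    vals[n_channels] = bv.w
    return vals.tobytes()


def decode_binned_payload(payload: bytes, n_channels: int) -> BinnedVector:
    expected = 8 * n_channels + 8
    if len(payload) != expected:
        raise CodecError(f"binned payload must be {expected} bytes, got {len(payload)}")
    vals = np.frombuffer(payload, dtype="<f8")
    counts = vals[:n_channels].astype(np.int64)
    if not np.array_equal(counts, vals[:n_channels]):
        raise CodecError("binned counts are not integral")
    return BinnedVector(counts=counts, w=int(vals[n_channels]))


def encode_item_payload(item: SpikeItem, G: int) -> bytes:
    """Serialize a queue item: G (t,channel,unit) triples + n_real + serial."""
    if len(item.entries) != G:
        raise CodecError(f"item must have exactly {G} entries, got {len(item.entries)}")
    vals = np.empty(3 * G + 2, dtype="<f8")
    for i, s in enumerate(item.entries):
        vals[3 * i : 3 * i + 3] = (s.t, s.channel, s.unit)
    vals[3 * G] = item.n_real
    vals[3 * G + 1] = item.serial
    return vals.tobytes()


def decode_item_payload(payload: bytes, G: int) -> SpikeItem:
    expected = 24 * G + 16
    if len(payload) != expected:
        raise CodecError(f"item payload must be {expected} bytes, got {len(payload)}")
    vals = np.frombuffer(payload, dtype="<f8")
    entries = tuple(
        Spike(float(vals[3 * i]), int(vals[3 * i + 1]), int(vals[3 * i + 2]))
        for i in range(G)
    )
    n_real = int(vals[3 * G])
    serial = int(vals[3 * G + 1])
    if not 0 <= n_real <= G:
        raise CodecError(f"n_real {n_real} outside [0, {G}]")
    return SpikeItem(entries=entries, n_real=n_real, serial=serial)


def encode_chunk_payload(chunk: SpikeChunk) -> bytes:
    """Serialize a raw chunk (lightweight-client placement): seq, count,
    then the spike triples in as-received order."""
    vals = np.empty(2 + 3 * len(chunk.spikes), dtype="<f8")
    vals[0] = chunk.seq
    vals[1] = len(chunk.spikes)
    for i, s in enumerate(chunk.spikes):
        vals[2 + 3 * i : 5 + 3 * i] = (s.t, s.channel, s.unit)
    return vals.tobytes()


def decode_chunk_payload(payload: bytes) -> SpikeChunk:
    if len(payload) < 16 or len(payload) % 8:
        raise CodecError(f"chunk payload length {len(payload)} malformed")
    vals = np.frombuffer(payload, dtype="<f8")
    n = int(vals[1])
    if len(vals) != 2 + 3 * n:
        raise CodecError(f"chunk payload declares {n} spikes but carries {(len(vals) - 2) // 3}")
    spikes = [
        Spike(float(vals[2 + 3 * i]), int(vals[3 + 3 * i]), int(vals[4 + 3 * i]))
        for i in range(n)
    ]
    return SpikeChunk(seq=int(vals[0]), spikes=spikes)


# ---------------------------------------------------------------------------
# packet framing

def encode_packet(p: Packet) -> bytes:
    return _TAGS[p.header] + _LEN_STRUCT.pack(len(p.payload)) + p.payload


def decode_packet(data: bytes) -> Packet:
    """Decode one complete frame; the frame must be exactly one packet."""
    if len(data) < FRAME_OVERHEAD:
        raise FramingError(f"frame too short ({len(data)} bytes)")
    tag = data[:8]
    if tag not in _TAG_LOOKUP:
        raise FramingError(f"unknown header tag {tag!r}")
    (length,) = _LEN_STRUCT.unpack(data[8:12])
    if len(data) != FRAME_OVERHEAD + length:
        raise FramingError(
            f"frame length {len(data)} does not match declared payload {length}"
        )
    return Packet(header=_TAG_LOOKUP[tag], payload=data[12:])


# ---------------------------------------------------------------------------
# channels

def _recv_exact(sock: socket.socket, n: int) -> bytes:
    buf = bytearray()
    while len(buf) < n:
        part = sock.recv(n - len(buf))
        if not part:
            raise FramingError(f"connection closed mid-frame ({len(buf)}/{n} bytes)")
        buf.extend(part)
    return bytes(buf)


class TcpChannel:
    """Reliable ordered packet channel over a connected TCP socket.

    Nagle's algorithm is disabled so each packet is flushed immediately.
    Framing errors on TCP are connection-fatal.
    """

    def __init__(self, sock: socket.socket):
        sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
        self.sock = sock

    def send_packet(self, p: Packet) -> None:
        self.sock.sendall(encode_packet(p))

    def recv_packet(self) -> Packet:
        head = _recv_exact(self.sock, FRAME_OVERHEAD)
        tag = head[:8]
        if tag not in _TAG_LOOKUP:
            raise FramingError(f"unknown header tag {tag!r}")
        (length,) = _LEN_STRUCT.unpack(head[8:12])
        payload = _recv_exact(self.sock, length) if length else b""
        return Packet(header=_TAG_LOOKUP[tag], payload=payload)

    def close(self) -> None:
        try:
            self.sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self.sock.close()


class UdpChannel:
    """Best-effort packet channel: one packet per datagram.

    Malformed datagrams are dropped (counted), not fatal; callers must
    tolerate loss and reordering.
    """

    MAX_DGRAM = 65507

    def __init__(self, sock: socket.socket, peer: tuple[str, int] | None = None):
        self.sock = sock
        self.peer = peer
        self.dropped = 0

    def send_packet(self, p: Packet) -> None:
        data = encode_packet(p)
        if self.peer is not None:
            self.sock.sendto(data, self.peer)
        else:
            self.sock.send(data)

    def recv_packet(self) -> Packet | None:
        """Receive one datagram; returns None for a malformed one."""
        data, _addr = self.sock.recvfrom(self.MAX_DGRAM)
        try:
            return decode_packet(data)
        except FramingError:
            self.dropped += 1
            return None

    def close(self) -> None:
        self.sock.close()


# ---------------------------------------------------------------------------
# handshake (always over TCP)

PROTOCOL_VERSION = 1
_MAGIC = "spikelink"


def handshake_client(sock: socket.socket, client_name: str = "client") -> SessionConfig:
    """Client side: send an identification hello, receive the full session
    configuration, acknowledge. Returns the negotiated configuration."""
    fh = sock.makefile("rw", encoding="utf-8", newline="\n")
    hello = {"magic": _MAGIC, "version": PROTOCOL_VERSION, "name": client_name}
    fh.write(json.dumps(hello) + "\n")
    fh.flush()
    reply = json.loads(fh.readline())
    if reply.get("status") != "ok":
        raise HandshakeError(f"server refused handshake: {reply.get('reason', 'unknown')}")
    cfg = SessionConfig.from_dict(reply["config"])
    fh.write(json.dumps({"status": "ok"}) + "\n")
    fh.flush()
    return cfg


def handshake_server(sock: socket.socket, cfg: SessionConfig) -> dict:
    """Server side: validate the client hello and transmit *cfg*.

    A malformed hello or a version mismatch is refused with a reason and
    no session state is created. Returns the accepted hello record.
    """
    fh = sock.makefile("rw", encoding="utf-8", newline="\n")
    line = fh.readline()
    try:
        hello = json.loads(line)
        if not isinstance(hello, dict):
            raise ValueError("hello is not an object")
    except ValueError as exc:
        fh.write(json.dumps({"status": "refused", "reason": f"malformed hello: {exc}"}) + "\n")
        fh.flush()
        raise HandshakeError(f"malformed hello: {exc}") from exc
    if hello.get("magic") != _MAGIC or hello.get("version") != PROTOCOL_VERSION:
        reason = "magic/version mismatch"
        fh.write(json.dumps({"status": "refused", "reason": reason}) + "\n")
        fh.flush()
        raise HandshakeError(reason)
    fh.write(json.dumps({"status": "ok", "config": cfg.to_dict()}) + "\n")
    fh.flush()
    ack = json.loads(fh.readline())
    if ack.get("status") != "ok":
        raise HandshakeError("client did not acknowledge configuration")
    return hello


def send_stream(channel, packets) -> dict:
    """Send a packet sequence over a channel; EXIT must be final if present.

    Returns a delivery report ``{"sent": n, "data": n_data}``.
    """
    sent = 0
    n_data = 0
    seen_exit = False
    for p in packets:
        if seen_exit:
            raise ValueError("EXIT must be the final packet")
        channel.send_packet(p)
        sent += 1
        if p.header == HEADER_DATA:
            n_data += 1
        if p.header == HEADER_EXIT:
            seen_exit = True
    return {"sent": sent, "data": n_data}
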