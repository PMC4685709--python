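# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `spikelink`.

## Problem setting

An acquisition server polls implanted microelectrode arrays and exposes
detected spikes in periodic chunks (default polling interval 10 ms). Each
spike is a `(t, channel, unit)` triple: channels are 1..96 at the
defaults, units are the waveform-sorting labels 1–4 with 0 meaning
unsorted. Two properties of real acquisition streams drive the design:
chunks are occasionally out of order across chunk boundaries, and the
stream carries noise in two recognizable forms — unsorted spikes and
near-simultaneous multi-electrode "sync" events.

Timestamps are seconds as IEEE-754 doubles throughout. The acquisition
hardware's tick resolution is abstracted away; one unit everywhere
removes conversion bugs, and doubles carry microsecond-scale resolution
exactly over any realistic session length.

## Streaming operators

All processing stages are explicit-state streaming steps with a
matching end-of-stream `flush`. This makes the pipeline placement-
agnostic: the same operators run on the client (heavyweight client, HWC)
or the server (lightweight client, LWC) with bit-identical results, which
the test suite and acceptance script verify.

**Reordering.** State: the carry-over set RS and *K*, the maximum
timestamp of the previous chunk. Each step merges RS with the incoming
chunk, releases (time-sorted) every spike with `t ≤ K`, and retains the
rest. Nothing is released until the second chunk arrives, so output
trails input by one chunk — exactly enough delay to absorb displacement
of one chunk, which is the disorder model of the synthetic source. Ties
in `t` break by `(channel, unit, arrival order)` so output is a
deterministic function of the multiset of inputs. An alternative reading
of the algorithm sets *K* to the maximum of the *current* chunk; under
that reading no delay is introduced and a straggler arriving one chunk
late would be lost, so this package uses the previous-chunk maximum.

**Unsorted filter.** Drops `unit == 0`, order preserved.

**Sync filter.** Time is tiled into absolute windows `[T·p, T·(p+1))`
(window index `floor(t/T)`); a spike survives iff it is the only spike —
any channel, any unit — in its window. The newest window stays open in
the carry-over until a later batch or the flush closes it; the flush
applies the same singleton rule to the final window. Window alignment is
absolute (multiples of *T*), not first-spike-relative, so streaming and
offline evaluation agree exactly; the streaming output is property-tested
against a brute-force whole-stream grouping oracle. Supported widths are
the two study variants, 25 µs and 1 ms, but any positive *T* works.

**Composition order.** The `unsort_sync` option removes unsorted spikes
*before* sync detection, so a unit-0 spike cannot veto a sorted spike
that shares its window. The opposite order is defensible; this one was
fixed as the package's convention because the unsorted label already
marks those spikes as noise, and noise should not influence the
coincidence test.

**Binning.** Counts spikes per channel over windows of width *W*
(default 100 ms). A window is emitted once a spike beyond its end has
been seen; empty intermediate windows are emitted too, so window indices
are gapless. Spikes older than the open window ("late", possible only if
upstream reordering was bypassed) are dropped and counted in
`dropped_late` rather than back-assigned — silently mutating an
already-emitted bin would corrupt downstream consumers. The final open
window is emitted at flush.

**Itemizing.** Groups of *G* = 20 spikes in arrival order per batch; the
final partial group is zero-padded with an explicit real-spike count, and
serials are gapless across the session. Padding is a fixed all-zero
triple and is never interpreted downstream.

## Wire format

Frames are an 8-byte NUL-padded ASCII tag (`DATA`, `NODATA`, `EXIT`), a
4-byte big-endian payload length, then the payload. Every 8-byte payload
slot is a little-endian double (integral values round-trip exactly below
2^53): the binned payload is 96 counts + the window index = 776 bytes;
the queue-item payload is 20 `(t, channel, unit)` triples + real count +
serial = 496 bytes; the raw-chunk payload (LWC placement) is seq + count
+ triples. The header byte layout and the length field are this
package's convention — only the payload sizes and header semantics are
externally fixed. TCP disables Nagle's algorithm so small packets flush
immediately; UDP maps one packet per datagram and receivers tolerate
loss and malformed datagrams. NODATA is sent when a delivery tick
produces nothing, serving as a keep-alive; EXIT is always final. The
handshake always runs over TCP regardless of the data protocol: the
server transmits the full session configuration as a JSON line and the
client acknowledges, so configuration lives only server-side.

## Latency gating

The gateway queue holds `(item, input_time)` pairs; `input_time` is the
window *end* `(w+1)·W` for a bin (a bin represents its whole window) and
the newest real-entry timestamp for a queue item. The gate is a two-stage
test, looped: if the queue holds fewer than two items, the simulation is
assumed to keep up and the head is returned; otherwise, if the newest
queued input time exceeds the simulation time by more than the latency
requirement LR, the head is discarded and the test repeats. Discarding is
queue-element-granular (a whole bin or whole 20-spike item). A
consequence of the fewer-than-two fast path is that a single very stale
item is still delivered; this is reproduced deliberately rather than
"fixed". Discard counts are non-increasing in LR (property-tested).

**Simulation clock.** The simulation's progress is modeled as the input
time of the last consumed item: a consumer that processes items more
slowly than they arrive falls behind the newest queued input time, which
is precisely the lag the gate measures. The wall clock paces only the
online callback schedule (default interval: *W* for continuous input,
1 ms for discrete input). Anchoring the simulation time itself to the
wall clock would make the lag identically zero in a real-time session —
queued input times track the wall — and the gate could never fire; the
consumption-progress clock reproduces the intended comparison between
data time and simulator time without embedding a real simulator. One
limitation: after a long silent gap in the stream, the progress clock
lags the next arrivals by the gap length, so the first post-gap pull may
discard up to a queue's worth of items; real sessions at physiological
rates never exhibit this.

Offline mode sets LR above the stream duration (e.g. 1,000 s for a 100 s
recording) and consumes everything in FIFO order, blocking while the
queue is empty and terminating when EXIT has been observed and the queue
drained. Online and offline runs of the same input produce identical
delivered sequences whenever the consumer keeps up.

## Model scaffold

Populations and default sizes: P=96, ES=96, IS=22, ILS=10 (sensory),
EM=96, IM=22, ILM=10 (motor); excitatory = {P, ES, EM} (288), inhibitory
= the interneurons (64). Channel *c* maps identically to P cell *c* and
to ES cell *c*. P cells are leaky threshold accumulators:
`v ← v·decay + gain·count`, firing at most once per binning window when
`v ≥ theta`, then resetting to zero. Defaults `gain=1, theta=10,
decay=1` are dimensionless placeholders — the original biophysical model
is not being calibrated here, and these values must not be read as its
parameters. Discrete input is replayed verbatim: each item's first
`n_real` entries become events on the matching ES cells at the recorded
spike times; padding contributes nothing (conservation is asserted in the
tests). Downstream connectivity, synaptic dynamics, plasticity and any
motor read-out are out of scope; the emission log is the scaffold's
output surface.

## Synthetic source

The generator emulates the statistics the pipeline must survive, not the
biology. Background activity is homogeneous Poisson at an aggregate rate
split uniformly over channels — matching the aggregate rates of the two
study conditions (1,399 Hz and 3,173 Hz over 96 channels for 100 s) —
with a `p_unsorted` fraction labelled unit 0 (default 0.11, the unsorted
share of the first condition). Sync events are Poisson in time
(default 100 events/s), each placing `sync_multiplicity=2` spikes on
distinct channels within `sync_span=10 µs`; these defaults are the
package's choice of a realistic contamination level — the underlying
recordings report only post-filter survivor counts, which accidental
Poisson coincidences already dominate at these rates. Out-of-order
delivery moves each spike with probability `p_straggler` (default 0.01)
into the following chunk with its timestamp unchanged, the one-chunk
displacement the reorder stage is built for. Ground truth labels every
spike (background / unsorted / sync-member), records each sync event's
members, and can report events that straddle a detection-window boundary
(such events are not guaranteed to be caught whole by the filter).

What the generator does **not** model: non-stationary firing rates,
refractoriness, channel-rate heterogeneity, electrode drift, waveforms,
and displacement deeper than one chunk. Passing tests therefore
demonstrate correctness of the streaming machinery under the stated
statistical structure, not robustness to every pathology of real
recordings.

## Problem sizes and numerical choices

The test suite and acceptance script run at the native study scale where
that is cheap (full 100 s, 1,399 Hz streams for the offline-gating and
rate-recovery checks) and at reduced scale where wall-clock pacing is
involved (a 5 s online stream for the forced-slow-consumer check; 300 to
1,000 random streams for the reorder-vs-sort property). Window indices
use `floor(t/T)` consistently on both the assignment and the
finalization side, so floating-point edge cases cannot disagree between
the streaming and oracle paths. All randomness flows from explicit seeds
(sub-seeds are derived arithmetically and kept below 2^31); offline runs
are bit-reproducible.

## Known limitations

* No real acquisition-hardware or simulator integration: both ends are
  emulated (synthetic source, model scaffold) behind the same interfaces
  a hardware client and simulator coupling would use.
* The UDP path relies on the item serial alone for ordering; no
  retransmission or sequencing layer is added.
* The queue is unbounded; back-pressure and memory management are out of
  scope.
* Latency/round-trip benchmarking of the transport is intentionally not
  part of the test surface — timing assertions are limited to coarse
  pacing bounds.
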