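# spikelink

Middleware for streaming *in vivo* multielectrode spiking activity into a
spiking-network simulator in real time.

Closed-loop brain-machine-interface research needs a bridge between two
systems with very different clocks: a data-acquisition server that makes
multiunit activity (MUA) available in periodic ~10 ms chunks, and a
biomimetic network model whose simulation may run slower or faster than
real time. `spikelink` implements that bridge end to end:

* **Reordering** — acquisition servers occasionally deliver spikes out of
  order across chunks. A streaming operator releases, at each chunk, every
  buffered spike with timestamp ≤ *K*, the maximum timestamp of the
  previous chunk. Output trails input by exactly one chunk, which absorbs
  one-chunk displacement losslessly.
* **Noise filtering** — spikes left unsorted by waveform sorting (unit 0)
  and *sync spikes* (near-simultaneous events on multiple electrodes
  within a very short window *T*, e.g. 25 µs, attributable to shared
  noise sources) can be removed. The sync filter tiles time into absolute
  windows [*T·p*, *T·(p+1)*) and keeps a spike iff it is alone in its
  window.
* **Binning / itemizing** — continuous model input ("P" pathway): spike
  counts per channel per window *W* (default 100 ms). Discrete input
  ("NSLOC" pathway): spikes packed into fixed groups of *G* = 20 with
  zero padding and a real-spike counter so padding is never consumed.
* **Transport** — a bit-exact packet codec (DATA / NODATA / EXIT) over
  TCP with Nagle's algorithm disabled, or UDP. At the defaults the binned
  payload is exactly 776 bytes (96 channels × 8 + 8) and a queue item is
  exactly 496 bytes (20 × 3 × 8 + 8 + 8). A TCP handshake distributes the
  server-side session configuration, so clients need no local config.
* **Latency-gated queue** — delivered items enter a FIFO read by the
  simulator's callback. Offline mode consumes everything (the latency
  requirement LR is set above the stream duration, e.g. 1,000 s). Online
  mode compares the newest queued input time against the simulation's
  progress; if the lag exceeds LR, whole queue items are discarded until
  the simulation catches up — real time is maintained at the cost of
  dropped input.
* **Model scaffold** — the input side of the target sensorimotor network:
  96 proprioceptive (P) threshold cells and a 96-ES/22-IS/10-ILS sensory
  plus 96-EM/22-IM/10-ILM motor layer (288 excitatory, 64 inhibitory
  cells). Binned input drives P-cell accumulators; itemized input is
  replayed verbatim onto ES cells.
* **Synthetic source** — a generator emulating the acquisition server's
  statistics (Poisson MUA at a configurable aggregate rate over 96
  channels, unsorted and sync contamination, out-of-order "stragglers"),
  with ground-truth labels for every injected artifact.

## Worked example

Run a 10 s offline loopback session (synthetic 96-channel stream at a
1,399 Hz aggregate rate with sync and unsorted contamination, unsorted +
25 µs sync filtering, continuous input):

```
$ spikelink loopback --config demo.yaml --seed 7
{
  "delivered": 100,
  "discarded": 0,
  "dropped_late": 0,
  "elements": 100,
  "emitted": 1123,
  "enqueued": 100,
  "filter_input": 16074,
  "filter_output": 12415,
  "generated": 16074,
  "nodata": 901,
  "out_of_order": 123,
  "packets_received": 1002,
  "packets_sent": 1002,
  ...
}
```

Reading the report: 16,074 spikes were generated, of which 123 arrived
out of order (all repaired by the reorder stage: `dropped_late` is 0).
The unsort + 25 µs sync filter removed 3,659 spikes (12,415 survived).
The 10 s stream produced 100 binning windows of 100 ms, delivered as 100
DATA packets among 1,002 total (901 keep-alive NODATA ticks plus the
final EXIT). All 100 bins were enqueued and consumed — offline mode
discards nothing — and the P cells emitted 1,123 threshold spikes.

The same session can be split across two machines:

```
$ spikelink serve --config demo.yaml &          # on the server
$ spikelink client --host <server> --speed 1    # on the acquisition side
```

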