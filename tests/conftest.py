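"""Shared fixtures and independent oracles.

The oracles here are deliberately naive whole-stream computations
(full sort, brute-force window grouping, direct counting); the streaming
operators under test must reproduce them exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from spikelink.model import Spike, SpikeChunk
from spikelink.streamops import flush_reorder, reorder_step, ReorderState

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def offline_sync_oracle(spikes: list[Spike], T: float) -> list[Spike]:
    """Keep exactly the spikes that are alone in their floor(t/T) window
    (any channel, any unit), in time order."""
    windows: dict[int, list[Spike]] = {}
    for s in spikes:
        windows.setdefault(math.floor(s.t / T), []).append(s)
    out = [group[0] for group in windows.values() if len(group) == 1]
    return sorted(out, key=lambda s: (s.t, s.channel, s.unit))


def full_sort_oracle(spikes: list[Spike]) -> list[Spike]:
    return sorted(spikes, key=lambda s: (s.t, s.channel, s.unit))


def run_reorder(chunks: list[SpikeChunk]) -> list[Spike]:
    """Concatenated reorder_step outputs plus the final flush."""
    state = ReorderState()
    out: list[Spike] = []
    for chunk in chunks:
        released, state = reorder_step(state, chunk)
        out.extend(released)
    out.extend(flush_reorder(state))
    return out


def random_sorted_stream(
    rng: np.random.Generator,
    n: int,
    duration: float = 1.0,
    n_channels: int = 8,
    p_unsorted: float = 0.2,
) -> list[Spike]:
    t = np.sort(rng.uniform(0.0, duration, size=n))
    ch = rng.integers(1, n_channels + 1, size=n)
    unit = np.where(rng.random(n) < p_unsorted, 0, rng.integers(1, 5, size=n))
    return [Spike(float(a), int(b), int(c)) for a, b, c in zip(t, ch, unit)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
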