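"""Input side of the biomimetic sensorimotor model.

Instantiates the population structure of the target network — 96
proprioceptive (P) input cells, a sensory layer of 96 excitatory cells
(ES) with 22 fast-spiking (IS) and 10 low-threshold-spiking (ILS)
interneurons, and a motor layer of 96 excitatory cells (EM) with 22 IM
and 10 ILM interneurons: 288 excitatory and 64 inhibitory cells at the
defaults — and implements the two input pathways:

* continuous input: each binned per-channel count drives the matching P
  cell, a leakless threshold accumulator that fires (at most once per
  binning window) when its accumulated drive crosses threshold, then
  resets;
* discrete input: each queue item's real entries are replayed verbatim
  as events onto the matching ES cell at the recorded spike times
  (spike-generator semantics); padding entries are never used.

Downstream synaptic dynamics, plasticity and the virtual arm are out of
scope: the emission log is this module's output surface. The P-cell
parameters are dimensionless conventions of this scaffold, not values of
the original biophysical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .streamops import BinnedVector, SpikeItem

__all__ = [
    "Population",
    "EmittedSpike",
    "ScaffoldNetwork",
    "DEFAULT_SIZES",
    "EXCITATORY",
    "INHIBITORY",
    "build_scaffold",
]

DEFAULT_SIZES = {"P": 96, "ES": 96, "IS": 22, "ILS": 10, "EM": 96, "IM": 22, "ILM": 10}
EXCITATORY = frozenset({"P", "ES", "EM"})
INHIBITORY = frozenset({"IS", "ILS", "IM", "ILM"})

SOURCE_P = "P-threshold"
SOURCE_NSLOC = "NSLOC-passthrough"


@dataclass(frozen=True)
class Population:
    name: str
    size: int
    kind: str  # "excitatory" | "inhibitory"

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_SIZES:
            raise ValueError(f"unknown population {self.name!r}")
        if self.size < 1:
            raise ValueError("population size must be positive")


@dataclass(frozen=True)
class EmittedSpike:
    t: float
    cell: tuple[str, int]  # (population name, 1-based index)
    source: str


@dataclass
class ScaffoldNetwork:
    """Seven populations plus the P-cell accumulator state.

    Channel ``c`` maps identically to P cell ``c`` (continuous input) and
    to ES cell ``c`` via its spike-generator unit (discrete input).
    """

    populations: dict[str, Population]
    gain: float = 1.0
    theta: float = 10.0
    decay: float = 1.0
    v: np.ndarray = field(init=False)
    emission_log: list[EmittedSpike] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        self.v = np.zeros(self.populations["P"].size, dtype=float)

    def count(self, kind: str) -> int:
        return sum(p.size for p in self.populations.values() if p.kind == kind)

    @property
    def n_excitatory(self) -> int:
        return self.count("excitatory")

    @property
    def n_inhibitory(self) -> int:
        return self.count("inhibitory")

    def feed_binned(self, bv: BinnedVector, sim_time: float) -> list[EmittedSpike]:
        """Drive the P cells with one binned count vector.

        Each cell's drive decays multiplicatively, is incremented by
        gain*count, and triggers at most one spike per window when it
        reaches threshold, after which it resets to zero.
        """
        n_p = self.populations["P"].size
        if len(bv.counts) != n_p:
            raise ValueError(f"binned vector length {len(bv.counts)} != P size {n_p}")
        self.v *= self.decay
        self.v += self.gain * np.asarray(bv.counts, dtype=float)
        fired = np.flatnonzero(self.v >= self.theta)
        self.v[fired] = 0.0
        out = [EmittedSpike(t=sim_time, cell=("P", int(c) + 1), source=SOURCE_P) for c in fired]
        self.emission_log.extend(out)
        return out

    def feed_discrete(self, item: SpikeItem) -> list[EmittedSpike]:
        """Replay a queue item's real entries onto the matching ES cells.

        Only the first ``n_real`` entries are events; padding is ignored
        by construction of the real-spike counter.
        """
        n_es = self.populations["ES"].size
        out: list[EmittedSpike] = []
        for s in item.real_spikes():
            if not 1 <= s.channel <= n_es:
                raise ValueError(f"channel {s.channel} outside ES range [1, {n_es}]")
            out.append(EmittedSpike(t=s.t, cell=("ES", s.channel), source=SOURCE_NSLOC))
        self.emission_log.extend(out)
        return out

    def write_emission_log(self, path: str | Path) -> None:
        """Write the emission log as a TSV spike table with population and
        cell-index columns appended."""
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("t\tpopulation\tindex\tsource\n")
            for e in self.emission_log:
                fh.write(f"{e.t!r}\t{e.cell[0]}\t{e.cell[1]}\t{e.source}\n")


def build_scaffold(
    sizes: dict[str, int] | None = None,
    *,
    gain: float = 1.0,
    theta: float = 10.0,
    decay: float = 1.0,
) -> ScaffoldNetwork:
    """Instantiate the seven populations (defaults: 288 excitatory and 64
    inhibitory cells) and the P-cell input state."""
    merged = dict(DEFAULT_SIZES)
    if sizes:
        unknown = set(sizes) - set(DEFAULT_SIZES)
        if unknown:
            raise ValueError(f"unknown population name(s): {sorted(unknown)}")
        merged.update(sizes)
    pops = {
        name: Population(
            name=name,
            size=size,
            kind="excitatory" if name in EXCITATORY else "inhibitory",
        )
        for name, size in merged.items()
    }
    return ScaffoldNetwork(populations=pops, gain=gain, theta=theta, decay=decay)
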