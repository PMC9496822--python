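"""Synthetic inputs for exercising the full pipeline without real EEG.

Three generators:

* planted-partition random graphs (known block structure, tunable
  within/between edge probabilities) for the detection core;
* coupled-phase oscillator signals that mimic theta-band EEG with planted
  group-level phase locking, for the signal-to-network chain;
* the Zachary karate-club graph with its two-faction split, embedded as a
  static fixture, as a small real-world benchmark.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .network import BinaryNetwork, Partition
from .signals import SignalEpoch

__all__ = [
    "PlantedSpec",
    "CoupledSignalSpec",
    "planted_partition_graph",
    "coupled_phase_signals",
    "karate_fixture",
    "DEAP_CHANNELS",
]

# 32-channel cap of the international 10-20 system, in standard order.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)


@dataclass(frozen=True)
class PlantedSpec:
    """Planted-partition graph: blocks with dense inside, sparse between."""

    sizes: tuple[int, ...]
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if any(s < 1 for s in self.sizes) or not self.sizes:
            raise InvalidParameterError("block sizes must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise InvalidParameterError("need 0 <= p_out < p_in <= 1")

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


def planted_partition_graph(spec: PlantedSpec) -> tuple[BinaryNetwork, Partition]:
    """Sample a planted-partition graph and its ground-truth partition.

    Every within-block pair becomes an edge with probability ``p_in``,
    every cross-block pair with probability ``p_out``.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.sizes)
    block = np.repeat(np.arange(len(spec.sizes)), spec.sizes)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if block[i] == block[j] else spec.p_out
            if rng.random() < p:
                edges.append((i, j))
    net = BinaryNetwork.from_edges(n, edges)
    truth = Partition.from_labels(block)
    return net, truth


@dataclass(frozen=True)
class CoupledSignalSpec:
    """Surrogate EEG with planted group-level phase locking.

    Each group shares a latent narrow-band phase process.  Per sample,
    each channel reads the latent phase with probability ``coupling`` and
    its own independent phase process otherwise, then a small independent
    phase jitter and additive Gaussian amplitude noise are applied.  The
    defaults emulate a 32-channel, 512 Hz, 60 s theta-band trial with four
    planted groups of eight channels.
    """

    group_assignment: tuple[int, ...] = tuple(i // 8 for i in range(32))
    within_group_coupling: float = 0.95
    fs: float = 512.0
    duration_s: float = 60.0
    carrier_band: tuple[float, float] = (4.0, 7.0)
    noise_sd: float = 0.1
    channel_names: tuple[str, ...] | None = DEAP_CHANNELS
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "group_assignment", tuple(int(g) for g in self.group_assignment)
        )
        if not (0.0 <= self.within_group_coupling <= 1.0):
            raise InvalidParameterError("coupling must lie in [0, 1]")
        if self.duration_s * self.fs < 2:
            raise InvalidParameterError("need at least 2 samples")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs / 2):
            raise InvalidParameterError("carrier band must fit below Nyquist")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")

    @property
    def n_channels(self) -> int:
        return len(self.group_assignment)

    def partition(self) -> Partition:
        return Partition.from_labels(self.group_assignment)


def _phase_walk(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unwrapped phase of a narrow-band process: drifting in-band frequency."""
    f0 = rng.uniform(*band)
    drift = rng.standard_normal(n).cumsum() * (0.05 / np.sqrt(fs))
    t = np.arange(n) / fs
    return 2 * np.pi * f0 * t + drift + rng.uniform(0, 2 * np.pi)


def coupled_phase_signals(spec: CoupledSignalSpec) -> SignalEpoch:
    """Generate group-locked oscillator signals per ``CoupledSignalSpec``."""
    rng = np.random.default_rng(spec.seed)
    n_samp = int(round(spec.duration_s * spec.fs))
    groups = sorted(set(spec.group_assignment))
    latent = {g: _phase_walk(rng, n_samp, spec.fs, spec.carrier_band) for g in groups}

    names = spec.channel_names
    if names is None or len(names) != spec.n_channels:
        names = tuple(f"ch{i}" for i in range(spec.n_channels))

    data = np.empty((spec.n_channels, n_samp))
    for c, g in enumerate(spec.group_assignment):
        own = _phase_walk(rng, n_samp, spec.fs, spec.carrier_band)
        use_latent = rng.random(n_samp) < spec.within_group_coupling
        phase = np.where(use_latent, latent[g], own)
        jitter = 0.05 * rng.standard_normal(n_samp)
        data[c] = np.cos(phase + jitter) + spec.noise_sd * rng.standard_normal(n_samp)
    return SignalEpoch(data=data, fs=spec.fs, channel_names=names)


# ---------------------------------------------------------------------------
# Zachary karate club, embedded (34 nodes, 78 edges) with the 2-faction split.

_KARATE_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6), (0, 7), (0, 8), (0, 10),
    (0, 11), (0, 12), (0, 13), (0, 17), (0, 19), (0, 21), (0, 31), (1, 2),
    (1, 3), (1, 7), (1, 13), (1, 17), (1, 19), (1, 21), (1, 30), (2, 3),
    (2, 7), (2, 8), (2, 9), (2, 13), (2, 27), (2, 28), (2, 32), (3, 7),
    (3, 12), (3, 13), (4, 6), (4, 10), (5, 6), (5, 10), (5, 16), (6, 16),
    (8, 30), (8, 32), (8, 33), (9, 33), (13, 33), (14, 32), (14, 33),
    (15, 32), (15, 33), (18, 32), (18, 33), (19, 33), (20, 32), (20, 33),
    (22, 32), (22, 33), (23, 25), (23, 27), (23, 29), (23, 32), (23, 33),
    (24, 25), (24, 27), (24, 31), (25, 31), (26, 29), (26, 33), (27, 33),
    (28, 31), (28, 33), (29, 32), (29, 33), (30, 32), (30, 33), (31, 32),
    (31, 33), (32, 33),
)

_KARATE_FACTION: tuple[int, ...] = (
    0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 1,
    1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
)


def karate_fixture() -> tuple[BinaryNetwork, Partition]:
    """The 34-node, 78-edge Zachary karate-club graph and its 2-faction split."""
    net = BinaryNetwork.from_edges(34, _KARATE_EDGES)
    assert net.n_nodes == 34 and net.n_edges == 78
    return net, Partition.from_labels(_KARATE_FACTION)
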