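"""From multichannel time series to a binarized functional network.

The chain is: band-pass filter (zero-phase, 4th-order Butterworth) ->
middle-window extraction -> analytic-signal instantaneous phase ->
phase-locking value (PLV) matrix -> edge-count binarization.

PLV between channels i and j is the resultant length of the phase
difference over time,

    PLV_ij = | (1/N) sum_t exp(i (phi_i(t) - phi_j(t))) |,

which is 1 for perfectly locked channels and decays like 1/sqrt(N) for
independent phases.  Rather than thresholding PLV at a fixed numeric
cutoff, binarization keeps the m strongest pairs, so networks from
different subjects are compared at equal edge count; the adaptive scan
picks m by re-running the community detector and scoring each m by
run-to-run stability (mean pairwise NMI) and modularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .community import GAParams, run_mfmicd
from .errors import (
    DegenerateSignalError,
    InvalidInputError,
    InvalidParameterError,
)
from .metrics import pairwise_stability
from .network import BinaryNetwork, Partition

__all__ = [
    "SignalEpoch",
    "PhaseSeries",
    "PLVMatrix",
    "bandpass_filter",
    "extract_middle_window",
    "instantaneous_phase",
    "compute_plv_matrix",
    "binarize_top_m",
    "adaptive_threshold_scan",
]


@dataclass(frozen=True)
class SignalEpoch:
    """channels x samples real matrix with its sampling rate."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise InvalidInputError("signal data must be 2-D (channels x samples)")
        # windowing can legally produce a 1-sample epoch; PLV itself
        # enforces >= 2 samples where it matters
        if data.shape[0] < 2 or data.shape[1] < 1:
            raise InvalidInputError("need >= 2 channels and >= 1 sample")
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if len(self.channel_names) != data.shape[0]:
            raise InvalidInputError("channel_names length must match channel count")
        if len(set(self.channel_names)) != data.shape[0]:
            raise InvalidInputError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PhaseSeries:
    """Per-channel instantaneous phase in radians (channels x samples)."""

    phases: np.ndarray

    def __post_init__(self):
        phases = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", phases)
        if phases.ndim != 2:
            raise InvalidInputError("phases must be 2-D")
        if not np.all(np.isfinite(phases)):
            raise InvalidInputError("phases must be finite")


@dataclass(frozen=True)
class PLVMatrix:
    """Symmetric [0,1] phase-locking matrix with unit diagonal."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    n_samples_used: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = vals.shape[0]
        if vals.ndim != 2 or vals.shape[1] != n:
            raise InvalidInputError("PLV matrix must be square")
        if len(self.channel_names) != n:
            raise InvalidInputError("channel_names length must match matrix size")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise InvalidInputError("PLV matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
            raise InvalidInputError("PLV diagonal must be 1")
        if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
            raise InvalidInputError("PLV entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def bandpass_filter(epoch: SignalEpoch, low_hz: float, high_hz: float) -> SignalEpoch:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel."""
    nyquist = epoch.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise InvalidParameterError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyquist})"
        )
    sos = butter(2, [low_hz, high_hz], btype="bandpass", fs=epoch.fs, output="sos")
    filtered = sosfiltfilt(sos, epoch.data, axis=1)
    return dc_replace(epoch, data=filtered)


def extract_middle_window(epoch: SignalEpoch, total_duration_s: float) -> SignalEpoch:
    """Middle third of the epoch, sample-exact: samples [floor(n/3), floor(2n/3)).

    The outer thirds of an emotion trial are discarded because functional
    connectivity is unstable while the stimulus ramps up and winds down.
    """
    declared = int(round(total_duration_s * epoch.fs))
    if epoch.n_samples < declared:
        raise InvalidInputError(
            f"epoch has {epoch.n_samples} samples but {declared} were declared"
        )
    n = epoch.n_samples
    lo, hi = n // 3, (2 * n) // 3
    if hi <= lo:  # n < 3: keep the (single) middle sample
        lo, hi = n // 2, n // 2 + 1
    return dc_replace(epoch, data=epoch.data[:, lo:hi])


def instantaneous_phase(epoch: SignalEpoch) -> PhaseSeries:
    """Analytic-signal (Hilbert) phase per channel, in radians.

    Meaningful only for narrow-band input; filter first.
    """
    rms = np.sqrt(np.mean(epoch.data**2, axis=1))
    if np.any(rms == 0):
        dead = [epoch.channel_names[i] for i in np.nonzero(rms == 0)[0]]
        raise DegenerateSignalError(f"all-zero channel(s): {dead}")
    analytic = hilbert(epoch.data, axis=1)
    return PhaseSeries(phases=np.angle(analytic))


def compute_plv_matrix(
    phases: PhaseSeries, channel_names: Sequence[str] | None = None
) -> PLVMatrix:
    """All-pairs PLV from per-channel phases.

    Computed at once as ``|Z Z^H| / N`` with ``Z = exp(i phi)``, which
    equals the pairwise resultant of the phase differences.
    """
    ph = phases.phases
    if ph.shape[1] < 2:
        raise InvalidInputError("need at least 2 samples for PLV")
    z = np.exp(1j * ph)
    n = ph.shape[1]
    vals = np.abs(z @ z.conj().T) / n
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    names = (
        tuple(channel_names)
        if channel_names is not None
        else tuple(str(i) for i in range(ph.shape[0]))
    )
    return PLVMatrix(values=vals, channel_names=names, n_samples_used=n)


def binarize_top_m(plv: PLVMatrix, m_edges: int) -> BinaryNetwork:
    """Keep exactly the ``m_edges`` strongest off-diagonal pairs as edges.

    Ties are resolved deterministically by sorting on (-value, i, j) with
    i < j.  A resulting empty or complete graph is almost certainly not a
    useful functional network, so it triggers a warning.
    """
    n = plv.n_channels
    max_edges = n * (n - 1) // 2
    if not (0 <= m_edges <= max_edges):
        raise InvalidParameterError(f"m_edges must be in [0, {max_edges}]")
    pairs = [(-plv.values[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort()
    edges = [(i, j) for _, i, j in pairs[:m_edges]]
    if m_edges == 0 or m_edges == max_edges:
        warnings.warn(
            "binarized network is empty or complete; community structure is undefined",
            stacklevel=2,
        )
    return BinaryNetwork.from_edges(n, edges, plv.channel_names)


def adaptive_threshold_scan(
    plv: PLVMatrix,
    m_min: int,
    m_max: int,
    detector_params: GAParams | None = None,
    seed: int = 0,
) -> tuple[int, list[dict]]:
    """Choose the edge count by re-running the detector across [m_min, m_max].

    For each candidate m the PLV matrix is binarized and the detector is
    run ``detector_params.runs_per_setting`` times (>= 2) with distinct
    derived seeds.  Each m is scored by the mean pairwise NMI of the runs'
    partitions (stability) and their mean Q; the scan returns the m with
    the highest stability, breaking ties by higher mean Q and then by
    smaller m, together with the per-m report.
    """
    n = plv.n_channels
    max_edges = n * (n - 1) // 2
    if not (0 <= m_min <= m_max <= max_edges):
        raise InvalidParameterError("need 0 <= m_min <= m_max <= n(n-1)/2")
    params = detector_params or GAParams()
    n_runs = max(2, params.runs_per_setting)

    report: list[dict] = []
    for m in range(m_min, m_max + 1):
        net = binarize_top_m(plv, m)
        partitions: list[Partition] = []
        qs: list[float] = []
        for r in range(n_runs):
            run_seed = (seed + 104729 * m + 9973 * r) % (2**31 - 1)
            try:
                res = run_mfmicd(
                    net, dc_replace(params, seed=run_seed, runs_per_setting=1)
                )
            except Exception as exc:  # propagate with context
                raise type(exc)(f"detector failed at m={m}: {exc}") from exc
            partitions.append(res.best_partition)
            qs.append(res.best_q)
        report.append(
            {
                "m": m,
                "mean_q": float(np.mean(qs)),
                "stability_nmi": pairwise_stability(partitions),
            }
        )
    chosen = max(report, key=lambda r: (r["stability_nmi"], r["mean_q"], -r["m"]))
    return chosen["m"], report
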