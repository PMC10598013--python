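"""Spike detection, regime classification, synchronisation metrics, sweeps.

The qualitative vocabulary quantified here: a trajectory is *quiescent*
when its post-transient voltage peak-to-peak amplitude collapses,
*tonic-spiking* when it fires regular large spikes, *bursting* when the
inter-spike interval (ISI) distribution splits into short within-burst and
long between-burst gaps, and *mixed-mode* (MMO) when small sub-threshold
oscillations coexist with full-size spikes.  Fractional memory makes
transients long, so half of every run is discarded by default before any
statistic is computed.

All thresholds live in :class:`RegimeConfig` and are deterministic, so a
given trajectory always maps to the same label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "RegimeConfig",
    "RegimeLabel",
    "SyncError",
    "detect_spikes",
    "classify_regime",
    "sync_error",
    "bifurcation_sweep",
]


@dataclass
class SpikeTrain:
    """Detected spikes of one voltage trace."""

    spike_times: np.ndarray
    peak_amplitudes: np.ndarray
    threshold: float
    refractory: int

    @property
    def inter_spike_intervals(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def count(self) -> int:
        return len(self.spike_times)

    @property
    def isi_cv(self) -> float:
        """Coefficient of variation of the ISIs (nan with < 2 intervals)."""
        isi = self.inter_spike_intervals
        if len(isi) < 2 or isi.mean() == 0:
            return float("nan")
        return float(isi.std() / isi.mean())


@dataclass
class RegimeConfig:
    """Deterministic thresholds of the regime classifier.

    quiescence_amplitude: peak-to-peak u1 below this is quiescent (same
    units as u1; ~1% of a typical spiking amplitude for the fixture set).
    burst_gap_factor: an ISI distribution is called bimodal (bursting)
    when the largest ISI gap exceeds this multiple of the median ISI.
    mmo_peak_ratio: small peaks below this fraction of the largest peak
    range mark mixed-mode oscillation when they coexist with large peaks.
    transient_fraction: leading fraction of the run discarded everywhere.
    """

    quiescence_amplitude: float = 1.0
    burst_gap_factor: float = 3.0
    mmo_peak_ratio: float = 0.4
    transient_fraction: float = 0.5
    spike_threshold: Optional[float] = None   # None: midpoint of u1 range
    refractory: int = 3


@dataclass
class RegimeLabel:
    label: str                     # quiescent / tonic-spiking / bursting / MMO
    evidence: dict = field(default_factory=dict)


def _local_maxima(u: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateaus take the first sample)."""
    if len(u) < 3:
        return np.array([], dtype=int)
    left = u[1:-1] > u[:-2]
    right = u[1:-1] >= u[2:]
    return np.where(left & right)[0] + 1


def detect_spikes(
    u1: Sequence[float],
    times: Optional[Sequence[float]] = None,
    threshold: Optional[float] = None,
    refractory: int = 3,
) -> SpikeTrain:
    """Local maxima of u1 above threshold, separated by the refractory gap.

    The default threshold is the midpoint of the trace's range, which
    cleanly splits large spikes from baseline for relaxation-type
    oscillators.  Detection is deterministic; an empty train is a valid
    result.
    """
    u = np.asarray(u1, dtype=float)
    if u.size < 3:
        raise ValueError("need at least three samples to detect spikes")
    t = np.arange(u.size, dtype=float) if times is None else np.asarray(times, float)
    if threshold is None:
        threshold = 0.5 * (u.min() + u.max())
    idx = _local_maxima(u)
    idx = idx[u[idx] > threshold]
    kept = []
    last = -np.inf
    for i in idx:
        if i - last >= refractory:
            kept.append(i)
            last = i
    kept = np.asarray(kept, dtype=int)
    return SpikeTrain(
        spike_times=t[kept],
        peak_amplitudes=u[kept],
        threshold=float(threshold),
        refractory=refractory,
    )


def classify_regime(
    u1: Sequence[float],
    config: Optional[RegimeConfig] = None,
    times: Optional[Sequence[float]] = None,
) -> RegimeLabel:
    """Label the post-transient dynamics of a voltage trace.

    Order of tests: quiescent (amplitude collapse) -> MMO (coexisting
    small and large peaks) -> bursting (bimodal ISI) -> tonic-spiking.
    """
    cfg = config or RegimeConfig()
    u = np.asarray(u1, dtype=float)
    cut = int(len(u) * cfg.transient_fraction)
    if len(u) - cut < 3:
        raise ValueError("trajectory shorter than the transient window")
    u = u[cut:]
    t = None if times is None else np.asarray(times, float)[cut:]
    amp = float(np.ptp(u))
    evidence = {"amplitude": amp}
    if amp < cfg.quiescence_amplitude:
        return RegimeLabel("quiescent", evidence)

    peaks_idx = _local_maxima(u)
    peak_vals = u[peaks_idx]
    evidence["n_peaks"] = int(len(peak_vals))
    if len(peak_vals) >= 4:
        spread = float(peak_vals.max() - peak_vals.min())
        evidence["peak_spread"] = spread
        # bimodal peak heights: split the peak range at the ratio cut and
        # require both sub-populations, with the spread a sizeable
        # fraction of the overall oscillation amplitude
        if spread > 0.25 * amp:
            rel = (peak_vals - peak_vals.min()) / spread
            small = np.where(rel < cfg.mmo_peak_ratio)[0]
            large = np.where(rel >= cfg.mmo_peak_ratio)[0]
            evidence["small_large_ratio"] = float(len(small) / max(1, len(large)))
            # the two peak families must interleave in time: a decaying
            # transient also has large-then-small peaks but never returns
            interleaved = (
                len(small) >= 2
                and len(large) >= 2
                and small.max() > large.min()
                and large.max() > small.min()
            )
            if interleaved:
                return RegimeLabel("MMO", evidence)

    train = detect_spikes(
        u, times=t, threshold=cfg.spike_threshold, refractory=cfg.refractory
    )
    isi = train.inter_spike_intervals
    evidence["n_spikes"] = train.count
    if len(isi) >= 3:
        med = float(np.median(isi))
        gap = float(isi.max())
        evidence["isi_gap_factor"] = gap / med if med > 0 else float("inf")
        if med > 0 and gap > cfg.burst_gap_factor * med:
            return RegimeLabel("bursting", evidence)
        evidence["isi_cv"] = train.isi_cv
        return RegimeLabel("tonic-spiking", evidence)
    if train.count >= 1:
        return RegimeLabel("tonic-spiking", evidence)
    # oscillation above the quiescence floor but no supra-threshold peaks
    return RegimeLabel("quiescent", evidence)


@dataclass
class SyncError:
    """Mean absolute deviation from the population (or cluster) mean."""

    per_time: np.ndarray
    time_average: float
    within_cluster: Optional[dict] = None


def sync_error(
    u1: np.ndarray,
    clusters: Optional[Sequence[Sequence[int]]] = None,
    transient_fraction: float = 0.5,
) -> SyncError:
    """Synchronisation error of a (T, N) voltage array.

    Global error E(t) = mean_i |u1_i(t) - mean_j u1_j(t)|; with a cluster
    partition, within-cluster errors are reported per cluster as well.
    The time average is taken over the post-transient window.
    """
    u = np.asarray(u1, dtype=float)
    if u.ndim != 2 or u.shape[1] < 2:
        raise ValueError("need a (T, N) array with at least two nodes")
    T, N = u.shape
    cut = int(T * transient_fraction)
    E = np.mean(np.abs(u - u.mean(axis=1, keepdims=True)), axis=1)
    within = None
    if clusters is not None:
        covered = sorted(i for c in clusters for i in c)
        if covered != list(range(N)):
            raise ValueError("cluster partition must cover every node exactly once")
        within = {}
        for k, c in enumerate(clusters):
            sub = u[:, list(c)]
            e = np.mean(np.abs(sub - sub.mean(axis=1, keepdims=True)), axis=1)
            within[k] = SyncError(per_time=e, time_average=float(e[cut:].mean()))
    return SyncError(
        per_time=E, time_average=float(E[cut:].mean()), within_cluster=within
    )


def bifurcation_sweep(
    simulate,
    grid: Sequence[float],
    transient_fraction: float = 0.5,
    config: Optional[RegimeConfig] = None,
) -> list:
    """Post-transient u1 extrema along a parameter grid.

    ``simulate(value)`` must return the u1 trace for one grid value (this
    keeps the sweep agnostic to whether the swept parameter is the
    fractional order or the applied current).  Each entry of the result is
    ``{"value", "peaks", "label", "diverged"}``; a diverging grid point is
    recorded as missing and the sweep continues.
    """
    from .frac_calculus import SolverDivergenceError

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty sweep grid")
    if np.any(np.diff(grid) <= 0) and np.any(np.diff(grid) >= 0) and grid.size > 1:
        if not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
            raise ValueError("sweep grid must be monotone")
    out = []
    for v in grid:
        try:
            u1 = np.asarray(simulate(float(v)), dtype=float)
        except SolverDivergenceError:
            out.append({"value": float(v), "peaks": None, "label": None, "diverged": True})
            continue
        cut = int(len(u1) * transient_fraction)
        tail = u1[cut:]
        peaks = tail[_local_maxima(tail)]
        label = classify_regime(u1, config=config).label
        out.append(
            {"value": float(v), "peaks": peaks, "label": label, "diverged": False}
        )
    return out
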