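"""Firing-rate correlations, mutual information and dependent-correlation
tests.

The central comparison of the analysis pipeline: is the in-field DC shift of
the membrane potential a better correlate of firing rate (and of in-field
position) than the theta-oscillation envelope?  Three protocols are
implemented:

* per interspike interval: rate = 1/ISI against the interval-mean DC and
  theta-envelope amplitudes, pooled across ten one-minute simulations,
  correlated both unbinned and after 8-bin averaging;
* sliding window: mean-normalised spike count in a 1 s window against the
  window-mean amplitudes;
* mutual information between each amplitude series and the field index
  (plug-in estimator on an 8x8 joint histogram), summarised as the DC:theta
  MI ratio per simulation.

Differences between the two dependent correlations (both share the firing
rate variable) are tested with Steiger's Z_H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import hilbert

from .band_model import BandParams
from .grid_cell import CellParams, simulate
from .precession import subsample_spikes_to_theta_peaks
from .signal_metrics import dc_series, theta_component
from .spatial_maps import field_index_map, field_index_series
from .trajectory import WalkParams, generate_random_walk

__all__ = [
    "CorrelationResult",
    "MIResult",
    "correlate",
    "isi_rate_pairs",
    "mutual_information",
    "run_isi_protocol",
    "run_mi_protocol",
    "run_window_protocol",
    "sliding_window_rate",
    "steiger_z",
    "window_means",
]


@dataclass
class CorrelationResult:
    """Pearson correlation of an amplitude variable with firing rate."""

    r: float
    p: float
    n: int
    binned: bool
    bin_centers: np.ndarray | None = None
    bin_means: np.ndarray | None = None
    bin_sems: np.ndarray | None = None


@dataclass
class MIResult:
    """Mutual information of both amplitude series with the field index."""

    mi_dc: float
    mi_mpo: float

    @property
    def ratio(self) -> float:
        return self.mi_dc / self.mi_mpo


def isi_rate_pairs(
    spike_indices: np.ndarray,
    dc: np.ndarray,
    mpo: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interspike-interval records (rate, mean DC, mean theta envelope).

    ``spike_indices`` are sample indices of the (theta-peak subsampled)
    spikes; each consecutive pair contributes one record with
    rate = 1/ISI and the mean of each amplitude series over the interval.
    """
    idx = np.asarray(spike_indices, int)
    if idx.size < 2:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    rates = 1.0 / (np.diff(idx) * dt)
    dc_means = np.empty(rates.size)
    mpo_means = np.empty(rates.size)
    for k, (a, b) in enumerate(zip(idx[:-1], idx[1:])):
        dc_means[k] = dc[a:b].mean()
        mpo_means[k] = mpo[a:b].mean()
    return rates, dc_means, mpo_means


def correlate(
    x: np.ndarray, y: np.ndarray, binned: bool = False, n_bins: int = 8
) -> CorrelationResult:
    """Pearson correlation of y on x, optionally after equal-width binning.

    Binned mode groups the records into ``n_bins`` equal-width bins spanning
    the range of x, averages y per bin (empty bins dropped, sparse bins kept
    with large s.e.m.) and correlates the bin means against bin centres.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if not binned:
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(float(r), float(p), x.size, False)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    centers, means, sems = [], [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(y[sel].mean())
        sems.append(sps.sem(y[sel]) if sel.sum() > 1 else np.nan)
    centers = np.asarray(centers)
    means = np.asarray(means)
    r, p = sps.pearsonr(centers, means)
    return CorrelationResult(float(r), float(p), centers.size, True,
                             centers, means, np.asarray(sems))


def sliding_window_rate(
    spike_indices: np.ndarray,
    n_samples: int,
    dt: float,
    window: float = 1.0,
) -> np.ndarray:
    """Mean-normalised firing rate in a sliding window.

    Spike count in each ``window``-second window (stepped one sample at a
    time), divided by the window length and normalised by the simulation's
    mean rate, so the returned series has mean ~= 1.
    """
    w = int(round(window / dt))
    if n_samples <= w:
        raise ValueError("trace shorter than the sliding window")
    spikes = np.zeros(n_samples)
    spikes[np.asarray(spike_indices, int)] = 1.0
    csum = np.concatenate([[0.0], np.cumsum(spikes)])
    counts = csum[w:] - csum[:-w]
    rate = counts / window
    mean_rate = spikes.sum() / (n_samples * dt)
    if mean_rate <= 0:
        raise ValueError("no spikes: sliding-window rate undefined")
    return rate / mean_rate


def window_means(series: np.ndarray, dt: float, window: float = 1.0) -> np.ndarray:
    """Mean of a series in the same sliding windows as
    :func:`sliding_window_rate`."""
    x = np.asarray(series, float)
    w = int(round(window / dt))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[w:] - csum[:-w]) / w


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (bits) on an equal-width joint histogram."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def steiger_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's Z_H for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` each correlate a different series with the same third
    variable, ``r12`` is the correlation between the two series and ``n``
    the common sample count.  Positive Z means r1 > r2; the p-value is
    two-sided.
    """
    for r in (r1, r2, r12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly within (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    det = 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12
    if det < 0:
        raise ValueError("correlation matrix is not positive semi-definite")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    rbar = 0.5 * (r1 + r2)
    psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    sbar = psi / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * sbar))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Multi-simulation protocols


def _simulate_batch(
    n_sims: int,
    duration: float,
    seed: int | None,
    walk_params: WalkParams | None,
    band_params: BandParams | None,
    cell_params: CellParams | None,
):
    """Yield (traj, trace, dc, env, subsampled spike indices) per simulation."""
    walk_params = walk_params or WalkParams()
    band_params = band_params or BandParams()
    cell_params = cell_params or CellParams(dt=walk_params.dt)
    master = np.random.SeedSequence(seed)
    for child in master.spawn(n_sims):
        traj = generate_random_walk(
            walk_params, duration, seed=int(child.generate_state(1)[0])
        )
        trace = simulate(traj, band_params, cell_params)
        theta = theta_component(trace.vm, trace.fs)
        dc = dc_series(trace.vm, trace.fs)
        env = np.abs(hilbert(theta))
        idx = subsample_spikes_to_theta_peaks(trace.spike_mask, theta)
        yield traj, trace, dc, env, idx


def run_isi_protocol(
    n_sims: int = 10,
    duration: float = 60.0,
    seed: int | None = None,
    walk_params: WalkParams | None = None,
    band_params: BandParams | None = None,
    cell_params: CellParams | None = None,
    n_bins: int = 8,
) -> dict:
    """Per-ISI correlation protocol pooled over short simulations.

    Returns unbinned and 8-bin-averaged Pearson correlations of rate
    (1/ISI) with the DC-shift and theta-envelope amplitudes, plus Steiger's
    Z_H for the unbinned pair.
    """
    rates, dcs, mpos = [], [], []
    for traj, trace, dc, env, idx in _simulate_batch(
        n_sims, duration, seed, walk_params, band_params, cell_params
    ):
        r, d, m = isi_rate_pairs(idx, dc, env, trace.dt)
        rates.append(r)
        dcs.append(d)
        mpos.append(m)
    rates = np.concatenate(rates)
    dcs = np.concatenate(dcs)
    mpos = np.concatenate(mpos)
    un_dc = correlate(dcs, rates, binned=False)
    un_mpo = correlate(mpos, rates, binned=False)
    bin_dc = correlate(dcs, rates, binned=True, n_bins=n_bins)
    bin_mpo = correlate(mpos, rates, binned=True, n_bins=n_bins)
    r12 = float(np.corrcoef(dcs, mpos)[0, 1])
    z, pz = steiger_z(un_dc.r, un_mpo.r, r12, rates.size)
    return {
        "n_pairs": int(rates.size),
        "unbinned_dc": un_dc,
        "unbinned_mpo": un_mpo,
        "binned_dc": bin_dc,
        "binned_mpo": bin_mpo,
        "steiger_z": z,
        "steiger_p": pz,
    }


def run_window_protocol(
    n_sims: int = 20,
    duration: float = 600.0,
    seed: int | None = None,
    walk_params: WalkParams | None = None,
    band_params: BandParams | None = None,
    cell_params: CellParams | None = None,
    window: float = 1.0,
) -> dict:
    """Sliding-window correlation protocol pooled over simulations."""
    rates, dcs, mpos = [], [], []
    for traj, trace, dc, env, idx in _simulate_batch(
        n_sims, duration, seed, walk_params, band_params, cell_params
    ):
        if idx.size == 0:
            continue
        rates.append(sliding_window_rate(idx, trace.t.size, trace.dt, window))
        dcs.append(window_means(dc, trace.dt, window))
        mpos.append(window_means(env, trace.dt, window))
    rates = np.concatenate(rates)
    dcs = np.concatenate(dcs)
    mpos = np.concatenate(mpos)
    r_dc = correlate(dcs, rates, binned=False)
    r_mpo = correlate(mpos, rates, binned=False)
    r12 = float(np.corrcoef(dcs, mpos)[0, 1])
    z, pz = steiger_z(r_dc.r, r_mpo.r, r12, rates.size)
    return {
        "n_windows": int(rates.size),
        "dc": r_dc,
        "mpo": r_mpo,
        "steiger_z": z,
        "steiger_p": pz,
    }


def run_mi_protocol(
    n_sims: int = 10,
    duration: float = 600.0,
    seed: int | None = None,
    walk_params: WalkParams | None = None,
    band_params: BandParams | None = None,
    cell_params: CellParams | None = None,
    n_bins: int = 8,
) -> dict:
    """Per-simulation MI of each amplitude series with the field index."""
    results = []
    for traj, trace, dc, env, idx in _simulate_batch(
        n_sims, duration, seed, walk_params, band_params, cell_params
    ):
        if not trace.spike_mask.any():
            continue
        fmap = field_index_map(traj, trace.spike_mask)
        fi = field_index_series(traj, fmap)
        results.append(
            MIResult(
                mutual_information(dc, fi, n_bins),
                mutual_information(env, fi, n_bins),
            )
        )
    ratios = np.array([r.ratio for r in results])
    return {
        "per_sim": results,
        "ratios": ratios,
        "mean_ratio": float(ratios.mean()) if ratios.size else float("nan"),
        "frac_above_one": float(np.mean(ratios > 1.0)) if ratios.size else float("nan"),
    }
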