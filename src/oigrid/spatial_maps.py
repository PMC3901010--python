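"""Spatial maps: occupancy-normalised rate maps, bootstrap field
classification, field-index maps, autocorrelograms and gridness.

Firing-field detection follows the circular-shuffle bootstrap: the spike
series is rotated relative to the (fixed) trajectory many times, giving each
5 cm bin an empirical null distribution of firing rates.  Bins firing above
the 85th percentile in full 3x3 blocks (extended by adjacent bins above the
70th) are in-field; bins below the 5th percentile in full 2x2 blocks are
out-of-field; everything else stays unassigned.

The gridness score quantifies six-fold rotational symmetry of the spatial
autocorrelogram: an annulus containing the inner ring of six peaks is
correlated with rotated copies of itself, and the score is
``min(r60, r120) - max(r30, r90, r150)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .trajectory import Trajectory

__all__ = [
    "FieldClassification",
    "RateMap",
    "autocorrelogram",
    "classify_fields",
    "compute_rate_map",
    "field_index_map",
    "field_index_series",
    "gridness_score",
    "shuffle_null",
]

IN_FIELD = 1
UNASSIGNED = 0
OUT_OF_FIELD = -1


@dataclass
class RateMap:
    """Occupancy-normalised firing-rate map on a square grid.

    ``rate`` is spike count / occupancy time (Hz); bins visited for fewer
    than ``min_samples`` trajectory samples are flagged NaN rather than
    zero-filled.
    """

    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # seconds, shape (nx, ny)
    counts: np.ndarray
    rate: np.ndarray  # Hz, NaN where undefined

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rate)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )


def _arena_edges(traj: Trajectory, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    if traj.arena_half_width is not None:
        hw = traj.arena_half_width
        lo_x = lo_y = -hw
        hi_x = hi_y = hw
    else:
        lo_x, hi_x = traj.x.min(), traj.x.max()
        lo_y, hi_y = traj.y.min(), traj.y.max()
    nx = max(1, int(np.ceil((hi_x - lo_x) / bin_size - 1e-9)))
    ny = max(1, int(np.ceil((hi_y - lo_y) / bin_size - 1e-9)))
    return lo_x + np.arange(nx + 1) * bin_size, lo_y + np.arange(ny + 1) * bin_size


def _bin_indices(traj: Trajectory, x_edges, y_edges) -> tuple[np.ndarray, np.ndarray]:
    ix = np.clip(np.searchsorted(x_edges, traj.x, side="right") - 1, 0, x_edges.size - 2)
    iy = np.clip(np.searchsorted(y_edges, traj.y, side="right") - 1, 0, y_edges.size - 2)
    return ix, iy


def compute_rate_map(
    traj: Trajectory,
    spike_mask: np.ndarray,
    bin_size: float = 5.0,
    min_samples: int = 2,
) -> RateMap:
    """Bin the trajectory and spikes into an occupancy-normalised rate map."""
    x_edges, y_edges = _arena_edges(traj, bin_size)
    ix, iy = _bin_indices(traj, x_edges, y_edges)
    nx, ny = x_edges.size - 1, y_edges.size - 1
    flat = ix * ny + iy
    occ_samples = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    counts = np.bincount(flat[np.asarray(spike_mask, bool)], minlength=nx * ny).reshape(nx, ny)
    occupancy = occ_samples * traj.dt
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_samples >= min_samples, counts / occupancy, np.nan)
    return RateMap(bin_size, x_edges, y_edges, occupancy, counts, rate)


def shuffle_null(
    spike_mask: np.ndarray,
    traj: Trajectory,
    bin_size: float = 5.0,
    n_shuffles: int = 1000,
    seed: int | None = None,
    min_samples: int = 2,
) -> np.ndarray:
    """Per-bin empirical percentile (1 - P) of the observed firing rate.

    Each shuffle rotates the spike sample indices circularly by an integer
    drawn uniformly from [0.05*N, 0.95*N] and recomputes the per-bin rate
    against the original occupancy.  The returned value per bin is the
    fraction of shuffles whose rate falls strictly below the observed rate.
    (Ties count against the observed rate: a bin that never fires scores 0
    and can qualify as below-chance, which is what makes the out-of-field
    criterion attainable for silent bins.)  Bins with undefined rates - and
    every bin when there are no spikes - are NaN.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    spike_mask = np.asarray(spike_mask, bool)
    rng = np.random.default_rng(seed)
    x_edges, y_edges = _arena_edges(traj, bin_size)
    ix, iy = _bin_indices(traj, x_edges, y_edges)
    nx, ny = x_edges.size - 1, y_edges.size - 1
    flat = ix * ny + iy
    n = flat.size
    occ_samples = np.bincount(flat, minlength=nx * ny)
    valid = occ_samples >= min_samples
    spike_idx = np.flatnonzero(spike_mask)
    if spike_idx.size == 0:
        return np.full((nx, ny), np.nan)

    observed = np.bincount(flat[spike_idx], minlength=nx * ny).astype(float)
    observed = np.where(valid, observed / np.maximum(occ_samples, 1), np.nan)

    shifts = rng.integers(int(0.05 * n), int(0.95 * n), size=n_shuffles, endpoint=True)
    below = np.zeros(nx * ny)
    for k in shifts:
        shuf = np.bincount(flat[(spike_idx + k) % n], minlength=nx * ny).astype(float)
        shuf /= np.maximum(occ_samples, 1)
        below += shuf < observed
    pct = np.where(valid, below / n_shuffles, np.nan)
    return pct.reshape(nx, ny)


@dataclass
class FieldClassification:
    """Per-bin and per-sample in/out/unassigned labels.

    ``labels`` is +1 (in-field), -1 (out-of-field) or 0 (unassigned) per
    spatial bin; ``sample_labels`` carries the label of the containing bin
    for every trajectory sample.
    """

    bin_size: float
    percentiles: np.ndarray
    labels: np.ndarray
    sample_labels: np.ndarray

    @property
    def in_field_samples(self) -> np.ndarray:
        return self.sample_labels == IN_FIELD

    @property
    def out_of_field_samples(self) -> np.ndarray:
        return self.sample_labels == OUT_OF_FIELD


def _block_all(cond: np.ndarray, size: int) -> np.ndarray:
    """Mark every bin belonging to a ``size x size`` block that is all True."""
    ok = cond.copy()
    for axis in (0, 1):
        view = ok
        for shift in range(1, size):
            view = view & np.roll(ok, -shift, axis=axis)
        view[(slice(-(size - 1), None),) if axis == 0 else (slice(None), slice(-(size - 1), None))] = False
        ok = view
    # ok[i, j] now flags block *anchors*; dilate back over the block extent
    out = np.zeros_like(cond)
    for di in range(size):
        for dj in range(size):
            out |= np.roll(np.roll(ok, di, axis=0), dj, axis=1)
    return out


def classify_fields(
    percentiles: np.ndarray,
    traj: Trajectory | None = None,
    bin_size: float = 5.0,
) -> FieldClassification:
    """Label bins as in-field / out-of-field / unassigned.

    In-field: every bin of an axis-aligned 3x3 block with all percentiles
    >= 0.85, extended (single pass) by 8-adjacent bins with percentile
    >= 0.70.  Out-of-field: every bin of a 2x2 block with all percentiles
    <= 0.05.  NaN percentiles never qualify.
    """
    p = np.asarray(percentiles, float)
    hi = np.nan_to_num(p, nan=-np.inf) >= 0.85
    lo = np.nan_to_num(p, nan=np.inf) <= 0.05
    in_field = _block_all(hi, 3)
    ext_candidates = (np.nan_to_num(p, nan=-np.inf) >= 0.70) & ~in_field
    neighbour = ndimage.binary_dilation(in_field, structure=np.ones((3, 3), bool))
    in_field = in_field | (ext_candidates & neighbour)
    out_field = _block_all(lo, 2) & ~in_field
    labels = np.zeros(p.shape, dtype=np.int8)
    labels[in_field] = IN_FIELD
    labels[out_field] = OUT_OF_FIELD

    if traj is not None:
        x_edges, y_edges = _arena_edges(traj, bin_size)
        ix, iy = _bin_indices(traj, x_edges, y_edges)
        sample_labels = labels[ix, iy]
    else:
        sample_labels = np.zeros(0, dtype=np.int8)
    return FieldClassification(bin_size, p, labels, sample_labels)


def field_index_map(
    traj: Trajectory,
    spike_mask: np.ndarray,
    bin_size: float = 1.0,
    smooth_sd_bins: float = 5.0,
) -> RateMap:
    """Smoothed, min-max-normalised rate map ("how in-field is each bin").

    A 1 cm occupancy-normalised rate map (unvisited bins zero) is smoothed
    with a Gaussian kernel of 5-bin standard deviation and normalised to
    [0, 1].  A degenerate map (no spatial contrast) normalises to all zeros
    with a warning.
    """
    spike_mask = np.asarray(spike_mask, bool)
    if not spike_mask.any():
        raise ValueError("field index map requires at least one spike")
    rm = compute_rate_map(traj, spike_mask, bin_size=bin_size, min_samples=1)
    raw = np.nan_to_num(rm.rate, nan=0.0)
    smooth = ndimage.gaussian_filter(raw, sigma=smooth_sd_bins, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo <= 0:
        warnings.warn("degenerate field index map (no spatial contrast)", RuntimeWarning)
        index = np.zeros_like(smooth)
    else:
        index = (smooth - lo) / (hi - lo)
    return RateMap(bin_size, rm.x_edges, rm.y_edges, rm.occupancy, rm.counts, index)


def field_index_series(traj: Trajectory, index_map: RateMap) -> np.ndarray:
    """Field-index value at the nearest bin centre of every trajectory sample."""
    ix, iy = _bin_indices(traj, index_map.x_edges, index_map.y_edges)
    return index_map.rate[ix, iy]


def autocorrelogram(rate_map: RateMap, min_overlap: int = 20) -> np.ndarray:
    """Pearson spatial autocorrelogram of a rate map.

    At every 2-D lag the correlation is computed over the overlapping valid
    bins only (standard overlap-normalised formula, evaluated with FFT
    convolutions); lags with fewer than ``min_overlap`` overlapping bins are
    NaN.  Output shape is ``(2*nx - 1, 2*ny - 1)`` with zero lag at the
    centre.
    """
    z = np.nan_to_num(rate_map.rate, nan=0.0)
    m = rate_map.valid.astype(float)
    zr, mr = z[::-1, ::-1], m[::-1, ::-1]
    n = fftconvolve(m, mr)
    sxy = fftconvolve(z, zr)
    sx = fftconvolve(z, mr)
    sy = fftconvolve(m, zr)
    sxx = fftconvolve(z * z, mr)
    syy = fftconvolve(m, (z * z)[::-1, ::-1])
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt(n * sxx - sx**2) * np.sqrt(n * syy - sy**2)
        ac = num / den
    ac[n < min_overlap] = np.nan
    return ac


def _ring_peaks(ac: np.ndarray, inner_r: float) -> np.ndarray:
    """Distances from centre of the six nearest local maxima outside inner_r."""
    cx, cy = (ac.shape[0] - 1) // 2, (ac.shape[1] - 1) // 2
    filled = np.nan_to_num(ac, nan=-1.0)
    local_max = (ndimage.maximum_filter(filled, size=5) == filled) & (filled > 0.1)
    px, py = np.nonzero(local_max)
    d = np.hypot(px - cx, py - cy)
    keep = d > inner_r
    d = np.sort(d[keep])
    return d[:6]


def gridness_score(
    rate_map: RateMap,
    n_angle: int = 360,
) -> float:
    """Rotational-symmetry gridness of a rate map's autocorrelogram.

    The annulus runs from the central peak's first zero crossing out to
    1.25x the median distance of the six nearest surrounding peaks (falling
    back to fixed fractions of the map size when no ring peaks are found).
    Values on the annulus are compared with copies rotated by 30..150 deg;
    the score is ``min(r60, r120) - max(r30, r90, r150)``.  Insufficient
    coverage yields NaN with a warning.
    """
    ac = autocorrelogram(rate_map)
    if np.isfinite(ac).sum() < 50:
        warnings.warn("autocorrelogram too sparse: gridness undefined", RuntimeWarning)
        return float("nan")
    cx, cy = (ac.shape[0] - 1) // 2, (ac.shape[1] - 1) // 2
    max_r = min(cx, cy)

    # central peak radius: first zero crossing of the angular-mean profile
    radii = np.arange(1, max_r)
    angles = np.linspace(0.0, 2 * np.pi, n_angle, endpoint=False)
    ring_x = cx + np.outer(radii, np.cos(angles))
    ring_y = cy + np.outer(radii, np.sin(angles))
    prof = ndimage.map_coordinates(
        np.nan_to_num(ac, nan=0.0), [ring_x.ravel(), ring_y.ravel()], order=1
    ).reshape(radii.size, n_angle)
    mean_prof = prof.mean(axis=1)
    below = np.flatnonzero(mean_prof <= 0)
    inner = float(radii[below[0]]) if below.size else 0.15 * max_r

    peaks = _ring_peaks(ac, inner)
    if peaks.size >= 3:
        outer = 1.25 * float(np.median(peaks))
    else:
        outer = 0.7 * max_r
    outer = min(outer, float(max_r - 1))
    if outer <= inner + 2:
        warnings.warn("gridness annulus degenerate: gridness undefined", RuntimeWarning)
        return float("nan")

    sel = (radii >= inner) & (radii <= outer)
    annulus = prof[sel]  # (n_radii, n_angle), angle step = 360/n_angle deg
    flat = annulus.ravel()

    def rot_corr(deg: float) -> float:
        shift = int(round(deg / 360.0 * n_angle))
        rotated = np.roll(annulus, shift, axis=1).ravel()
        return float(np.corrcoef(flat, rotated)[0, 1])

    on = min(rot_corr(60), rot_corr(120))
    off = max(rot_corr(30), rot_corr(90), rot_corr(150))
    return on - off
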