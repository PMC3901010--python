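"""Theta phase precession analysis.

As the animal crosses a firing field, spikes (and membrane-potential theta
peaks) drift to progressively earlier phases of the baseline theta rhythm.
This module extracts that effect the way it is measured experimentally:
spikes are thinned to at most one per membrane theta cycle (the sample
nearest the cycle peak), each retained spike gets the instantaneous phase of
the baseline oscillation received by the 0-degree head-direction population,
and phase is regressed against either the *pass index* (analytic-signal
phase of the field-index series, sweeping -pi..pi across a field pass) or,
for straight-line runs, position itself.  The association is quantified with
the circular-linear correlation coefficient rho of Kempter-style regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks, hilbert
from scipy.special import erfc, ndtri

from .band_model import BandParams
from .grid_cell import MembraneTrace
from .signal_metrics import theta_component
from .spatial_maps import FieldClassification, field_index_map, field_index_series
from .trajectory import Trajectory

__all__ = [
    "PrecessionResult",
    "baseline_theta_phase",
    "circular_linear_corr",
    "fit_phase_slope",
    "pass_index",
    "precession_analysis",
    "segmented_precession",
    "subsample_spikes_to_theta_peaks",
]


def _wrap(phase):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, float), 2.0 * np.pi)


def baseline_theta_phase(t, omega_b: float, phi_offset: float = 0.0):
    """Instantaneous phase of the baseline oscillation cos(w_b t + offset).

    Zero phase at the oscillation peak, wrapped to (-pi, pi].  The 0-degree
    population's baseline (offset 0) is the conventional reference.
    """
    return _wrap(omega_b * np.asarray(t, float) + phi_offset)[()]


def subsample_spikes_to_theta_peaks(
    spike_mask: np.ndarray, mpo_theta: np.ndarray
) -> np.ndarray:
    """Keep at most one spike sample per membrane theta cycle.

    Cycles are delimited by troughs of the 5-10 Hz membrane component; the
    cycle peak is the maximum between consecutive troughs, and the retained
    spike is the above-threshold sample nearest in time to that peak.
    Returns sample indices of the retained spikes.
    """
    spike_mask = np.asarray(spike_mask, bool)
    mpo = np.asarray(mpo_theta, float)
    if not spike_mask.any():
        return np.zeros(0, dtype=int)
    troughs, _ = find_peaks(-mpo)
    bounds = np.concatenate([[0], troughs, [mpo.size]])
    kept = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        in_cycle = np.flatnonzero(spike_mask[a:b])
        if in_cycle.size == 0:
            continue
        peak = a + int(np.argmax(mpo[a:b]))
        kept.append(a + in_cycle[np.argmin(np.abs(a + in_cycle - peak))])
    return np.asarray(kept, dtype=int)


def pass_index(field_index: np.ndarray) -> np.ndarray:
    """Progress through a field pass as an analytic-signal phase.

    The mean-centred field-index series is Hilbert-transformed; its angle
    sweeps roughly -pi -> 0 -> +pi across a complete pass, crossing zero at
    the field centre.  A constant series carries no pass information and is
    rejected.
    """
    fi = np.asarray(field_index, float)
    if np.ptp(fi) <= 0:
        raise ValueError("field index series is constant: pass index undefined")
    return np.angle(hilbert(fi - fi.mean()))


def fit_phase_slope(
    phases: np.ndarray,
    linear: np.ndarray,
    slope_bounds: tuple[float, float] | None = None,
    n_grid: int = 721,
) -> float:
    """Best-fitting circular regression slope, cycles per unit of ``linear``.

    Maximises the resultant length of ``phases - 2*pi*a*linear`` over a
    dense slope grid, then refines the winner with bounded optimisation.
    The default search allows up to +-2 cycles across the observed range of
    the linear variable.
    """
    phi = np.asarray(phases, float)
    x = np.asarray(linear, float)
    span = np.ptp(x)
    if span <= 0:
        raise ValueError("linear variable is degenerate (zero range)")
    if slope_bounds is None:
        slope_bounds = (-2.0 / span, 2.0 / span)

    def neg_resultant(a: float) -> float:
        z = phi - 2.0 * np.pi * a * x
        return -np.hypot(np.cos(z).sum(), np.sin(z).sum()) / x.size

    grid = np.linspace(slope_bounds[0], slope_bounds[1], n_grid)
    vals = [neg_resultant(a) for a in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(neg_resultant, bounds=(lo, hi), method="bounded")
    return float(res.x)


def circular_linear_corr(
    phases: np.ndarray,
    linear: np.ndarray,
    slope_bounds: tuple[float, float] | None = None,
    n_grid: int = 721,
) -> tuple[float, float]:
    """Circular-linear correlation (rho, p) of phase against a linear variable.

    The best-fitting slope ``a`` (cycles per unit of ``linear``) maximises
    the resultant length of ``phases - 2*pi*a*linear``; rho is then the
    circular-circular correlation between the measured phases and the
    fitted linear phase ``2*pi*|a|*linear``, so phase decreasing along the
    linear variable yields negative rho.  The p-value uses the standard
    large-sample normal approximation.
    """
    phi = np.asarray(phases, float)
    x = np.asarray(linear, float)
    if phi.size != x.size:
        raise ValueError("phases and linear variable must have equal length")
    n = phi.size
    if n < 5:
        return float("nan"), float("nan")
    slope = fit_phase_slope(phi, x, slope_bounds, n_grid)
    theta = _wrap(2.0 * np.pi * abs(slope) * x)
    phi_bar = np.angle(np.exp(1j * phi).sum())
    theta_bar = np.angle(np.exp(1j * theta).sum())
    sp = np.sin(phi - phi_bar)
    st = np.sin(theta - theta_bar)
    denom = np.sqrt((sp**2).sum() * (st**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((sp * st).sum() / denom)

    lam20 = np.mean(sp**2)
    lam02 = np.mean(st**2)
    lam22 = np.mean(sp**2 * st**2)
    if lam22 <= 0:
        return rho, float("nan")
    z = rho * np.sqrt(n * lam20 * lam02 / lam22)
    p = float(erfc(abs(z) / np.sqrt(2.0)))
    return rho, p


@dataclass
class PrecessionResult:
    """Per-spike phase/position pairs with their circular-linear correlation."""

    spike_indices: np.ndarray
    spike_times: np.ndarray
    linear: np.ndarray  # pass index (rad) or position (cm)
    theta_phase: np.ndarray  # rad, (-pi, pi]
    rho: float
    p_value: float
    mode: str

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


def precession_analysis(
    trace: MembraneTrace,
    traj: Trajectory,
    band_params: BandParams | None = None,
    mode: str = "pass_index",
    labels: FieldClassification | None = None,
) -> PrecessionResult:
    """Full phase-precession analysis of a simulated trace.

    Spikes are subsampled to one per membrane theta cycle; when a field
    classification is supplied only spikes at in-field positions are kept.
    ``mode='pass_index'`` regresses baseline theta phase on the pass index,
    ``mode='position'`` on x-position (straight-line runs).  With fewer
    than 5 retained spikes rho is undefined (NaN).
    """
    if mode not in ("pass_index", "position"):
        raise ValueError("mode must be 'pass_index' or 'position'")
    band_params = band_params or BandParams()
    mpo = theta_component(trace.vm, trace.fs)
    idx = subsample_spikes_to_theta_peaks(trace.spike_mask, mpo)
    trace.analysis_spikes = idx
    if labels is not None and idx.size:
        idx = idx[labels.sample_labels[idx] == 1]

    if mode == "pass_index":
        fmap = field_index_map(traj, trace.spike_mask)
        fi = field_index_series(traj, fmap)
        linear_series = pass_index(fi)
        linear = linear_series[idx]
    else:
        linear = traj.x[idx]

    phases = baseline_theta_phase(trace.t[idx], band_params.omega_b,
                                  band_params.phi_offsets_rad[0])
    if idx.size >= 5 and np.ptp(linear) > 0:
        rho, p = circular_linear_corr(phases, linear)
    else:
        rho, p = float("nan"), float("nan")
    return PrecessionResult(idx, trace.t[idx], linear, phases, rho, p, mode)


def segmented_precession(
    result: PrecessionResult,
    segment: float = 80.0,
    min_spikes: int = 10,
) -> dict:
    """Combine pass-index precession over consecutive analysis segments.

    Over a long open-field session the phase offset between passes varies
    (it depends on traversal geometry and on which band populations are
    active), so a single pooled regression underestimates the within-pass
    precession.  Following the convention of analysing short stretches of
    data, the session is cut into fixed-length segments, the circular-linear
    correlation is computed per segment (segments with fewer than
    ``min_spikes`` spikes are skipped) and the per-segment statistics are
    combined with Stouffer's method.  Returns the mean segment rho, the
    combined z and two-sided p, and the number of segments used.
    """
    t = result.spike_times
    rhos, zs = [], []
    if t.size:
        for t0 in np.arange(t.min(), t.max() + segment, segment):
            sel = (t >= t0) & (t < t0 + segment)
            if sel.sum() < min_spikes:
                continue
            rho, p = circular_linear_corr(result.theta_phase[sel], result.linear[sel])
            if np.isfinite(rho) and np.isfinite(p):
                rhos.append(rho)
                # signed normal score of the two-sided p-value
                zs.append(np.sign(rho) * -ndtri(max(p, 1e-300) / 2.0))
    if not zs:
        return {"mean_rho": float("nan"), "z": float("nan"),
                "p": float("nan"), "n_segments": 0}
    z = float(np.sum(zs) / np.sqrt(len(zs)))
    p = float(erfc(abs(z) / np.sqrt(2.0)))
    return {"mean_rho": float(np.mean(rhos)), "z": z, "p": p,
            "n_segments": len(zs)}
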