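"""Membrane-potential decomposition: DC shift and theta-envelope series.

The membrane trace is split into two bands with zero-phase (forward plus
backward) 2nd-order Butterworth filters: a slow 0.1-3 Hz component, whose
in-field elevation is the "DC shift" (ramp), and a 5-10 Hz theta component,
whose Hilbert envelope measures membrane-potential theta amplitude (MPO).
Field labels turn these series into the headline in-field-minus-out-of-field
amplitude differences, and the decay-constant sweep quantifies how both grow
with the membrane time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .band_model import BandParams
from .grid_cell import CellParams, MembraneTrace, simulate, threshold_for_tau
from .spatial_maps import FieldClassification, classify_fields, gridness_score, compute_rate_map, shuffle_null
from .trajectory import WalkParams, generate_random_walk

__all__ = [
    "AmplitudeSeries",
    "add_field_rhythm",
    "amplitude_series",
    "bandpass_zero_phase",
    "dc_series",
    "delta_amplitudes",
    "tau_sweep",
    "theta_component",
    "theta_envelope",
]

DC_BAND = (0.1, 3.0)
THETA_BAND = (5.0, 10.0)
#: seconds trimmed from each end of a trace before averaging (filter edges)
EDGE_EXCLUDE_S = 2.0


def bandpass_zero_phase(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass.

    The filter is applied forwards and backwards (``filtfilt``) so the net
    phase shift is zero, with reflective padding of three time constants of
    the low band edge.  Series shorter than three settling lengths are
    rejected.
    """
    x = np.asarray(x, float)
    if not 0 < lo < hi < fs / 2:
        raise ValueError("need 0 < lo < hi < fs/2")
    settle = int(3.0 * fs / (2.0 * np.pi * lo))  # 3 time constants, samples
    if x.size <= 3 * max(settle, 9):
        raise ValueError(
            f"series of {x.size} samples is too short for a {lo} Hz band edge"
        )
    b, a = butter(2, [lo, hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, x, padtype="even", padlen=min(settle, x.size - 1))


def dc_series(vm: np.ndarray, fs: float) -> np.ndarray:
    """DC-shift series: mean-removed trace band-passed at 0.1-3 Hz."""
    vm = np.asarray(vm, float)
    return bandpass_zero_phase(vm - vm.mean(), *DC_BAND, fs)


def theta_component(vm: np.ndarray, fs: float) -> np.ndarray:
    """Theta-band (5-10 Hz) component of the mean-removed trace."""
    vm = np.asarray(vm, float)
    return bandpass_zero_phase(vm - vm.mean(), *THETA_BAND, fs)


def theta_envelope(vm: np.ndarray, fs: float) -> np.ndarray:
    """Theta amplitude: absolute value of the Hilbert transform of the
    5-10 Hz component."""
    return np.abs(hilbert(theta_component(vm, fs)))


@dataclass
class AmplitudeSeries:
    """DC-shift and theta-envelope series aligned with a membrane trace.

    ``dc_shift`` has zero mean over out-of-field samples by construction;
    ``mpo_envelope`` is non-negative.
    """

    dc_shift: np.ndarray
    mpo_envelope: np.ndarray
    fs: float


def _edge_mask(n: int, fs: float, exclude_s: float = EDGE_EXCLUDE_S) -> np.ndarray:
    k = int(exclude_s * fs)
    mask = np.zeros(n, bool)
    mask[k : n - k if k else n] = True
    return mask


def amplitude_series(trace: MembraneTrace, labels: FieldClassification) -> AmplitudeSeries:
    """Decompose a membrane trace into DC-shift and theta-envelope series.

    The DC series is re-centred on its out-of-field mean (computed away from
    the filter edges), so out-of-field DC amplitude is zero by construction
    and the in-field mean directly reads out the ramp amplitude.
    """
    fs = trace.fs
    out = labels.out_of_field_samples & _edge_mask(trace.vm.size, fs)
    if not out.any():
        raise ValueError("no out-of-field samples: cannot reference the DC series")
    dc = dc_series(trace.vm, fs)
    dc = dc - dc[out].mean()
    env = theta_envelope(trace.vm, fs)
    return AmplitudeSeries(dc, env, fs)


def delta_amplitudes(
    series: AmplitudeSeries, labels: FieldClassification
) -> tuple[float, float]:
    """In-field minus out-of-field amplitude of the DC shift and theta
    envelope (mV), filter edges excluded from both means."""
    edge = _edge_mask(series.dc_shift.size, series.fs)
    infield = labels.in_field_samples & edge
    outfield = labels.out_of_field_samples & edge
    if not infield.any() or not outfield.any():
        raise ValueError("need both in-field and out-of-field samples")
    d_dc = series.dc_shift[infield].mean() - series.dc_shift[outfield].mean()
    d_mpo = series.mpo_envelope[infield].mean() - series.mpo_envelope[outfield].mean()
    return float(d_dc), float(d_mpo)


def add_field_rhythm(
    vm: np.ndarray, fs: float, freq: float = 6.5, amp: float = 0.0
) -> np.ndarray:
    """Superimpose a local-field-style sinusoid on the membrane trace.

    Emulates extracellular theta contamination at a slightly different
    frequency from the 6 Hz baseline; raising ``amp`` inflates the apparent
    out-of-field theta envelope.
    """
    if amp < 0:
        raise ValueError("amp must be non-negative")
    vm = np.asarray(vm, float)
    t = np.arange(vm.size) / fs
    return vm + amp * np.sin(2.0 * np.pi * freq * t)


def _episode_maxima(x: np.ndarray, mask: np.ndarray) -> list[float]:
    """Max of ``x`` within each contiguous run of True in ``mask``."""
    m = np.asarray(mask, bool)
    idx = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    return [float(x[a:b].max()) for a, b in zip(idx[::2], idx[1::2])]


def tau_sweep(
    taus_ms,
    n_reps: int = 50,
    duration: float = 600.0,
    seed: int | None = None,
    walk_params: WalkParams | None = None,
    band_params: BandParams | None = None,
    n_shuffles: int = 1000,
    adapt_threshold: bool = True,
    fixed_v_threshold: float = -65.0,
    with_gridness: bool = False,
) -> list[dict]:
    """Sweep the membrane decay constant over random-walk simulations.

    For each tau the spike threshold is either co-adapted via
    :func:`threshold_for_tau` or held at ``fixed_v_threshold``.  Each
    repetition simulates a fresh random walk, classifies fields and records
    the mean of the per-episode in-field DC maxima and the mean in-field
    theta envelope (and optionally the gridness of the 5 cm rate map).
    Returns one row (dict) per tau with per-rep values averaged.
    """
    walk_params = walk_params or WalkParams()
    band_params = band_params or BandParams()
    master = np.random.SeedSequence(seed)
    rows = []
    for tau_ms in taus_ms:
        v_t = threshold_for_tau(tau_ms) if adapt_threshold else fixed_v_threshold
        cell = CellParams(tau=tau_ms / 1000.0, v_threshold=v_t, dt=walk_params.dt)
        dc_max, mpo_in, grid = [], [], []
        for child in master.spawn(n_reps):
            s1, s2 = (int(v) for v in child.generate_state(2))
            traj = generate_random_walk(walk_params, duration, seed=s1)
            trace = simulate(traj, band_params, cell)
            if with_gridness:
                rm = compute_rate_map(traj, trace.spike_mask, bin_size=5.0)
                grid.append(gridness_score(rm))
            pct = shuffle_null(
                trace.spike_mask, traj, n_shuffles=n_shuffles, seed=s2
            )
            labels = classify_fields(pct, traj)
            if not labels.in_field_samples.any() or not labels.out_of_field_samples.any():
                continue
            series = amplitude_series(trace, labels)
            edge = _edge_mask(trace.vm.size, trace.fs)
            maxima = _episode_maxima(series.dc_shift, labels.in_field_samples & edge)
            if maxima:
                dc_max.append(float(np.mean(maxima)))
            mpo_in.append(float(series.mpo_envelope[labels.in_field_samples & edge].mean()))
        row = {
            "tau_ms": float(tau_ms),
            "v_threshold": float(v_t),
            "dc_infield_max": float(np.mean(dc_max)) if dc_max else float("nan"),
            "mpo_infield": float(np.mean(mpo_in)) if mpo_in else float("nan"),
            "n_reps": len(mpo_in),
        }
        if with_gridness:
            row["gridness"] = float(np.nanmean(grid)) if grid else float("nan")
        rows.append(row)
    return rows
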