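"""Leaky integrate-and-fire grid cell.

The grid cell integrates the summed, rectified band-cell input with explicit
Euler steps,

    Vm(t+dt) = Vm(t) + [I(t) - (Vm(t) - E_L)/tau_GL] * dt,

and registers a spike sample at every step with ``Vm > V_t``.  There is no
reset and no refractory period: with a 2 ms step those dynamics would be
sub-sample, so several spike samples can fall within one membrane theta
cycle (analyses that need sparse spikes subsample to one per cycle, see
:mod:`oigrid.precession`).  Because the input is non-negative, the membrane
never drops below the resting potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .band_model import BandParams, BandPopulationSet
from .trajectory import Trajectory

__all__ = [
    "CellParams",
    "MembraneTrace",
    "simulate",
    "step_membrane",
    "threshold_for_tau",
]


@dataclass
class CellParams:
    """Membrane parameters: leak time constant tau_GL (s), resting potential
    E_L (mV), spike threshold V_t (mV) and integration step dt (s)."""

    tau: float = 0.1
    e_leak: float = -67.0
    v_threshold: float = -56.0
    dt: float = 0.002

    @property
    def g_leak(self) -> float:
        """Leak rate constant G_L = 1/tau_GL, 1/s."""
        return 1.0 / self.tau

    def validate(self) -> None:
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.v_threshold <= self.e_leak:
            raise ValueError("spike threshold must exceed the resting potential")
        if self.tau < self.dt:
            warnings.warn(
                f"tau={self.tau}s is shorter than dt={self.dt}s: "
                "explicit Euler integration is unstable",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass
class MembraneTrace:
    """Simulated membrane potential with its driving current and spikes.

    ``spike_mask`` marks every sample with ``vm > V_t`` (the raw spike
    samples used for rate maps and field classification);
    ``analysis_spikes`` holds theta-peak-subsampled spike indices once an
    analysis has filled them in.
    """

    t: np.ndarray
    vm: np.ndarray
    current: np.ndarray
    spike_mask: np.ndarray
    params: CellParams
    analysis_spikes: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return self.params.dt

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.params.dt

    @property
    def spike_times(self) -> np.ndarray:
        return self.t[self.spike_mask]

    @property
    def n_spike_samples(self) -> int:
        return int(np.count_nonzero(self.spike_mask))


def step_membrane(vm: float, current: float, params: CellParams) -> float:
    """One explicit Euler update of the membrane potential.

    With a constant current the recurrence converges geometrically (factor
    ``1 - dt/tau`` per step) to the fixed point ``E_L + I*tau``.
    """
    return vm + (current - (vm - params.e_leak) / params.tau) * params.dt


def simulate(
    traj: Trajectory,
    bands: BandPopulationSet | BandParams | None = None,
    params: CellParams | None = None,
) -> MembraneTrace:
    """Forward-simulate the grid cell along a trajectory.

    The Euler recurrence is evaluated as the equivalent linear filter
    ``vm[i] = (1 - dt/tau)*vm[i-1] + (I[i-1] + E_L/tau)*dt`` (identical
    arithmetic, vectorised).  NaN input currents abort with the offending
    step index.
    """
    if params is None:
        params = CellParams()
    params.validate()
    if isinstance(bands, BandParams):
        bands = BandPopulationSet(bands)
    elif bands is None:
        bands = BandPopulationSet()
    if abs(traj.dt - params.dt) > 1e-12:
        raise ValueError(
            f"trajectory dt={traj.dt} does not match cell dt={params.dt}"
        )

    current = bands.summed_input(traj)
    bad = np.flatnonzero(~np.isfinite(current))
    if bad.size:
        raise ValueError(f"non-finite input current at step {bad[0]}")

    decay = 1.0 - params.dt / params.tau
    drive = np.empty_like(current)
    drive[0] = params.e_leak
    drive[1:] = (current[:-1] + params.e_leak / params.tau) * params.dt
    vm = lfilter([1.0], [1.0, -decay], drive)

    spike_mask = vm > params.v_threshold
    return MembraneTrace(traj.t, vm, current, spike_mask, params)


def threshold_for_tau(tau_ms: float) -> float:
    """Spike threshold co-adapted to the membrane time constant.

    The decay-constant sweep raises V_t by 1 mV for every 10 ms increase in
    tau_GL, mapping 10..100 ms onto -65..-56 mV (linearly interpolated in
    between).  This keeps field definition roughly constant as integration
    lengthens; without it, long time constants drive the cell to fire
    everywhere.
    """
    if not 10.0 <= tau_ms <= 100.0:
        raise ValueError("tau_ms must lie within [10, 100] ms")
    return -66.0 + tau_ms / 10.0
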