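"""Head-direction band cells acting as velocity-controlled oscillators.

Six populations of head-direction selective cells each combine a fixed
baseline theta oscillation (phase-offset between populations) with an active
oscillation whose instantaneous frequency rises above baseline in proportion
to the velocity component along the population's preferred direction:

    d(theta_n)/dt = omega_b + g * beta * s(t) * cos(phi_current - phi_pref_n)

The interference of the two cosines is half-wave rectified by a sigmoid and
gated off whenever the animal's heading differs from the preferred direction
by more than 90 deg.  Because the velocity term integrates to the projected
displacement, each population's (ungated) output forms spatial bands of
wavelength 2*pi/(g*beta) cm perpendicular to its preferred direction, and
the six populations together drive grid-patterned input to the downstream
cell.

``phase_gain`` (g) is a dimensionless calibration constant converting the
grid-spacing scale ``beta`` into a spatial wavenumber ``g*beta`` rad/cm; the
default is calibrated so that ``beta = 0.00385`` places two discrete firing
fields on a 200 cm straight transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "BandParams",
    "BandPopulationSet",
    "angular_difference",
    "band_output",
    "direction_gate",
    "sigmoid_activation",
    "summed_input",
    "update_band_phase",
]

#: Baseline phase offsets and preferred headings of the six populations (deg).
DEFAULT_OFFSETS_DEG = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)


@dataclass
class BandParams:
    """Parameters of the six-population band-cell set.

    omega_b : baseline angular frequency, rad/s (2*pi*6: 6 Hz theta).
    beta : grid-spacing scale factor (0.002 default; 0.00385 for the
        two-field straight-line protocol).
    phase_gain : dimensionless gain g; g*beta is the band wavenumber in
        rad/cm.
    sigmoid_a, sigmoid_T : slope and inflection of the rectifying sigmoid.
    input_gain : scaling constant G_I applied to each population's output
        before summation into the grid-cell input current.
    """

    omega_b: float = 2.0 * np.pi * 6.0
    beta: float = 0.002
    phase_gain: float = 30.0
    phi_offsets_deg: tuple[float, ...] = DEFAULT_OFFSETS_DEG
    phi_preferred_deg: tuple[float, ...] = DEFAULT_OFFSETS_DEG
    sigmoid_a: float = 4.0
    sigmoid_T: float = 1.0
    input_gain: float = 100.0

    @property
    def n_populations(self) -> int:
        return len(self.phi_preferred_deg)

    @property
    def phi_offsets_rad(self) -> np.ndarray:
        return np.radians(self.phi_offsets_deg)

    @property
    def band_wavelength(self) -> float:
        """Spatial period of one population's bands, cm."""
        return 2.0 * np.pi / (self.phase_gain * self.beta)


def angular_difference(a, b):
    """Signed wrapped difference ``a - b`` in degrees, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)[()]


def sigmoid_activation(x, a: float = 4.0, T: float = 1.0):
    """Half-wave rectifying sigmoid ``S(x) = 1/(1+e^{-a(x-T)}) - 1/(1+e^{aT})``.

    Monotone non-decreasing with ``S(0) = 0``, so an oscillation passed
    through it produces purely non-negative output.
    """
    x = np.asarray(x, dtype=float)
    return (1.0 / (1.0 + np.exp(-a * (x - T))) - 1.0 / (1.0 + np.exp(a * T)))[()]


def direction_gate(phi_current, phi_preferred):
    """Heaviside heading gate: 1 where |heading - preferred| <= 90 deg."""
    diff = np.abs(angular_difference(phi_current, phi_preferred))
    return (diff <= 90.0).astype(float)[()]


def update_band_phase(
    theta: np.ndarray,
    speed: float,
    heading: float,
    dt: float,
    params: BandParams,
) -> np.ndarray:
    """Advance the accumulated VCO phases by one time step.

    ``theta_n += [omega_b + g*beta*speed*cos(heading - pref_n)] * dt``.
    Motion perpendicular to a population's preferred direction leaves that
    population at baseline frequency.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pref = np.asarray(params.phi_preferred_deg, dtype=float)
    cosine = np.cos(np.radians(angular_difference(heading, pref)))
    omega = params.omega_b + params.phase_gain * params.beta * speed * cosine
    return theta + omega * dt


class BandPopulationSet:
    """Accumulated phase state of the six VCO populations along a trajectory.

    Phases are initialised to each population's own baseline offset, making
    the trajectory start a point of constructive interference, and advanced
    with the exact per-step projected displacement (``speed*cos(...)*dt``
    equals the step displacement projected on the preferred direction).
    """

    def __init__(self, params: BandParams | None = None):
        self.params = params or BandParams()

    def accumulate_phases(self, traj: Trajectory) -> np.ndarray:
        """VCO phases theta_n(t), shape ``(n_samples, n_populations)``."""
        p = self.params
        pref_rad = np.radians(np.asarray(p.phi_preferred_deg, dtype=float))
        # Per-step projected displacement: dx*cos(pref) + dy*sin(pref)
        # == speed*cos(heading - pref)*dt, exactly.
        proj = np.outer(traj.dx, np.cos(pref_rad)) + np.outer(traj.dy, np.sin(pref_rad))
        motion_phase = np.cumsum(p.phase_gain * p.beta * proj, axis=0)
        baseline_phase = p.omega_b * traj.t[:, None] + p.phi_offsets_rad[None, :]
        return baseline_phase + motion_phase

    def outputs(self, traj: Trajectory, gated: bool = True) -> np.ndarray:
        """Rectified population outputs HD_n(t), shape ``(n_samples, n)``."""
        theta = self.accumulate_phases(traj)
        return band_output(theta, traj.t, traj.heading, self.params, gated=gated)

    def summed_input(self, traj: Trajectory) -> np.ndarray:
        """Total input current to the grid cell, ``I(t) = G_I * sum_n HD_n``."""
        return summed_input(self.outputs(traj), self.params)


def band_output(
    theta: np.ndarray,
    t: np.ndarray,
    heading: np.ndarray,
    params: BandParams,
    gated: bool = True,
) -> np.ndarray:
    """Population outputs ``S(cos(w_b t + off_n) + cos(theta_n)) * H(...)``.

    The offset that makes ``S(0) = 0`` leaves the sigmoid marginally
    negative for negative drive; since the populations model purely
    excitatory firing-rate output, values are clamped at zero, keeping
    every input to the grid cell non-negative.
    """
    t = np.asarray(t, dtype=float)
    baseline = np.cos(params.omega_b * t[:, None] + params.phi_offsets_rad[None, :])
    interference = baseline + np.cos(theta)
    out = sigmoid_activation(interference, params.sigmoid_a, params.sigmoid_T)
    out = np.maximum(out, 0.0)
    if gated:
        gate = direction_gate(
            np.asarray(heading, dtype=float)[:, None],
            np.asarray(params.phi_preferred_deg, dtype=float)[None, :],
        )
        out = out * gate
    return out


def summed_input(hd_outputs: np.ndarray, params: BandParams) -> np.ndarray:
    """Scale and sum population outputs into the grid-cell input current."""
    return params.input_gain * np.sum(hd_outputs, axis=-1)
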