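"""Leaky integrate-and-fire neuron with adaptation current (LIFAC).

Spike-frequency adaptation combined with the membrane's low-pass property
forms a tunable band-pass for pulse periods.  Driving the LIFAC with the
instantaneous output of the rebound model and thresholding its total spike
count isolates individual resonant peaks of the rebound preference field:
switching the membrane time constant moves the band-pass and thereby hides
one peak and reveals another without creating intermediates — a substrate
for saltatory evolution of song preference.

Dynamics (forward Euler):

    tau_m   dV/dt = -V + I - A
    tau_ada dA/dt = -A

On ``V >= v_thres``: a spike is recorded, ``V <- v_reset``, ``A <- A + alpha``,
and both V and A are frozen for the refractory period ``tau_ref``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .minimal import ReboundParams, rebound_drive_matrix
from .ppf import PreferenceField
from .stimuli import StimulusGrid

__all__ = [
    "LIFACParams",
    "lifac_simulate",
    "lifac_spike_counts",
    "lifac_field",
    "PERIOD_VARIANTS",
]


@dataclass(frozen=True)
class LIFACParams:
    """LIFAC parameters; potentials in mV, times in ms.

    ``theta_relu`` thresholds the total spike count; ``input_gain`` scales
    the (dimensionless) rebound drive into an input current large enough
    that preferred stimuli elicit on the order of 10^2 spikes per 400 ms
    train (the scale on which the spike-count thresholds are meaningful).
    """

    tau_m: float
    theta_relu: float
    tau_ada: float = 5.0
    alpha: float = 10.0
    v_thres: float = 0.5
    v_reset: float = 0.0
    tau_ref: float = 1.0
    relu_gain: float = 1.0
    input_gain: float = 150.0
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_ada, self.tau_ref) <= 0:
            raise ValueError("time constants must be positive")
        if not self.v_thres > self.v_reset:
            raise ValueError("v_thres must exceed v_reset")


#: per-period parameter variants isolating the resonant peaks near 4, 8
#: and 16 ms (membrane time constant and spike-count threshold per row).
PERIOD_VARIANTS: dict[str, dict[str, float]] = {
    "4ms": {"tau_m": 4.0, "theta_relu": 125.0},
    "8ms": {"tau_m": 8.8, "theta_relu": 72.0},
    "16ms": {"tau_m": 12.0, "theta_relu": 0.0},
}


@njit(cache=True)
def _lifac_core(I, dt, tau_m, tau_ada, alpha, v_thres, v_reset, tau_ref):  # pragma: no cover
    n = I.size
    V = np.zeros(n)
    A = np.zeros(n)
    spikes = np.zeros(n)
    v = 0.0
    a = 0.0
    ref = 0.0
    for t in range(n):
        if ref > 0.0:
            ref -= dt
        else:
            v += dt / tau_m * (-v + I[t] - a)
            a += dt / tau_ada * (-a)
            if v >= v_thres:
                spikes[t] = 1.0
                v = v_reset
                a += alpha
                ref = tau_ref
        V[t] = v
        A[t] = a
    return V, A, spikes


def lifac_simulate(
    input_current: np.ndarray, params: LIFACParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the LIFAC driven by an input current sampled at 1/dt.

    Returns (spike_times_ms, V, A, spike_raster).
    """
    I = np.ascontiguousarray(np.asarray(input_current, dtype=np.float64))
    V, A, spikes = _lifac_core(
        I,
        params.dt_ms,
        params.tau_m,
        params.tau_ada,
        params.alpha,
        params.v_thres,
        params.v_reset,
        params.tau_ref,
    )
    spike_times = np.flatnonzero(spikes) * params.dt_ms
    return spike_times, V, A, spikes


@njit(cache=True)
def _lifac_counts(drive, dt, tau_m, tau_ada, alpha, v_thres, v_reset, tau_ref):  # pragma: no cover
    n_stim, n_samp = drive.shape
    counts = np.zeros(n_stim)
    for i in range(n_stim):
        v = 0.0
        a = 0.0
        ref = 0.0
        for t in range(n_samp):
            if ref > 0.0:
                ref -= dt
            else:
                v += dt / tau_m * (-v + drive[i, t] - a)
                a += dt / tau_ada * (-a)
                if v >= v_thres:
                    counts[i] += 1.0
                    v = v_reset
                    a += alpha
                    ref = tau_ref
    return counts


def lifac_spike_counts(drive_matrix: np.ndarray, params: LIFACParams) -> np.ndarray:
    """Total spike counts for each row of a drive matrix."""
    d = np.ascontiguousarray(drive_matrix.astype(np.float64))
    return _lifac_counts(
        d,
        params.dt_ms,
        params.tau_m,
        params.tau_ada,
        params.alpha,
        params.v_thres,
        params.v_reset,
        params.tau_ref,
    )


def lifac_field(
    rebound_params: ReboundParams,
    lifac_params: LIFACParams,
    grid: StimulusGrid,
) -> PreferenceField:
    """Preference field of the rebound->LIFAC->relu cascade over a grid.

    For each grid stimulus the instantaneous (non-integrated) rebound-model
    output drives the LIFAC; the total spike count passes the rectifier
    ``relu_gain * max(0, count - theta_relu)``.
    """
    fs = 1000.0 / lifac_params.dt_ms
    rb = ReboundParams(
        delay_rb=rebound_params.delay_rb,
        inh_gain=rebound_params.inh_gain,
        inh_duration=rebound_params.inh_duration,
        exc_gain=rebound_params.exc_gain,
        exc_duration=rebound_params.exc_duration,
        sample_rate=fs,
    )
    drive = lifac_params.input_gain * rebound_drive_matrix(rb, grid)
    counts = lifac_spike_counts(drive, lifac_params)
    values_flat = lifac_params.relu_gain * np.maximum(0.0, counts - lifac_params.theta_relu)
    pulses = np.unique(grid.pulse_ms)
    pauses = np.unique(grid.pause_ms)
    values = np.full((pulses.size, pauses.size), np.nan)
    pi = np.searchsorted(pulses, grid.pulse_ms)
    qi = np.searchsorted(pauses, grid.pause_ms)
    values[pi, qi] = values_flat
    if np.isnan(values).any():
        raise ValueError("grid is not a complete lattice")
    return PreferenceField(
        pulse_axis=pulses, pause_axis=pauses, values=values, resolution=float(grid.step)
    )
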