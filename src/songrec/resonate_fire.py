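"""Resonate-and-fire (R&F) neuron model.

A two-variable spiking neuron with a current-like variable ``x`` and a
voltage-like variable ``y`` coupled into a damped oscillator:

    dx/dt = b*x - w*y + gs*s(t)
    dy/dt = w*x + b*y

with intrinsic angular frequency ``w = 2*pi*f_rf`` and damping ``b <= 0``.
Inputs arriving during positive phases of the membrane oscillation amplify
it, inputs during negative phases suppress it, which makes the neuron
selective for pulse periods at integer multiples of ``1/f_rf`` (subharmonics)
while suppressing fractions (harmonics).  When ``y`` crosses threshold from
below a spike is recorded and the state is reset to ``x = 0, y = 1``.

Because the reset leaves ``y`` exactly at threshold, spike detection uses
upward-crossing semantics: a new spike requires ``y`` to fall below
threshold first.  Integration is forward Euler with a 0.1 ms step.

Each spike is treated as a unit-area event scaled by the output gain, so the
integrated spiking response of a trace equals ``spike_amp x spike count``;
this is the scale on which the fitted output gain is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .stimuli import PulseTrain, StimulusGrid, render_matrix

__all__ = ["RFParams", "RFTrace", "rf_simulate", "rf_scores"]


@dataclass(frozen=True)
class RFParams:
    """Resonate-and-fire parameters (defaults: fit to Anurogryllus behaviour)."""

    freq_rf: float = 109.34  # intrinsic frequency, Hz
    damping_b: float = -0.0005  # per ms; <= 0 for damped dynamics
    gain_s: float = 0.027  # stimulus input gain
    spike_amp: float = 0.0025  # output gain per spike
    y_threshold: float = 1.0
    x_reset: float = 0.0
    y_reset: float = 1.0
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.freq_rf <= 0:
            raise ValueError("freq_rf must be positive")
        if self.damping_b > 0:
            raise ValueError("damping_b must be <= 0 for damped dynamics")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency in radians per ms."""
        return 2.0 * np.pi * self.freq_rf / 1000.0

    @property
    def sample_rate(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass(frozen=True)
class RFTrace:
    """State traces of an R&F simulation; ``spikes`` holds spike_amp at spike samples."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    spikes: np.ndarray
    sample_rate: float

    @property
    def spike_count(self) -> int:
        return int(np.count_nonzero(self.spikes))

    @property
    def output(self) -> np.ndarray:
        """Unit-area spike train scaled by spike_amp (for phonotaxis integration)."""
        return self.spikes * self.sample_rate / 1000.0


@njit(cache=True)
def _rf_trace(stim, dt, b, omega, gs, thr, x_reset, y_reset):  # pragma: no cover
    n = stim.size
    xs = np.zeros(n)
    ys = np.zeros(n)
    spikes = np.zeros(n)
    x = 0.0
    y = 0.0
    below = True
    for t in range(n):
        xn = x + dt * (b * x - omega * y + gs * stim[t])
        yn = y + dt * (omega * x + b * y)
        if yn >= thr and below:
            spikes[t] = 1.0
            xn = x_reset
            yn = y_reset
            below = False
        elif yn < thr:
            below = True
        x = xn
        y = yn
        xs[t] = x
        ys[t] = y
    return xs, ys, spikes


def rf_simulate(stim: PulseTrain, params: RFParams) -> RFTrace:
    """Euler-integrate the R&F neuron driven by a pulse train.

    The stimulus must be rendered at the model's 1/dt sample rate.
    """
    if abs(stim.sample_rate - params.sample_rate) > 1e-6:
        raise ValueError(
            f"stimulus sample rate {stim.sample_rate} Hz incompatible with dt={params.dt_ms} ms"
        )
    xs, ys, spikes = _rf_trace(
        stim.samples.astype(np.float64),
        params.dt_ms,
        params.damping_b,
        params.omega,
        params.gain_s,
        params.y_threshold,
        params.x_reset,
        params.y_reset,
    )
    return RFTrace(
        time_ms=stim.time_ms,
        x=xs,
        y=ys,
        spikes=spikes * params.spike_amp,
        sample_rate=stim.sample_rate,
    )


def rf_scores(
    params: RFParams, grid: StimulusGrid, stim_matrix: np.ndarray | None = None
) -> np.ndarray:
    """Vectorised phonotaxis predictions: spike_amp-scaled windowed spike rate.

    Spikes within the integration window are counted per stimulus; each
    spike contributes unit area times ``spike_amp``.
    """
    s = stim_matrix if stim_matrix is not None else render_matrix(grid, params.sample_rate)
    counts = _rf_windowed_counts(
        s.astype(np.float64),
        params.dt_ms,
        params.damping_b,
        params.omega,
        params.gain_s,
        params.y_threshold,
        params.x_reset,
        params.y_reset,
    )
    ds = s.shape[1] * params.dt_ms
    return params.spike_amp * counts / (ds - 35.0)


@njit(cache=True)
def _rf_windowed_counts(stims, dt, b, omega, gs, thr, x_reset, y_reset):  # pragma: no cover
    n_stim, n_samp = stims.shape
    ds = n_samp * dt
    i0 = int(round(25.0 / dt))
    i1 = int(round((ds - 10.0) / dt))
    counts = np.zeros(n_stim, dtype=np.float64)
    for i in range(n_stim):
        x = 0.0
        y = 0.0
        below = True
        for t in range(n_samp):
            xn = x + dt * (b * x - omega * y + gs * stims[i, t])
            yn = y + dt * (omega * x + b * y)
            if yn >= thr and below:
                if i0 <= t < i1:
                    counts[i] += 1.0
                xn = x_reset
                yn = y_reset
                below = False
            elif yn < thr:
                below = True
            x = xn
            y = yn
    return counts
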