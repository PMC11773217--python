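"""Rectangular pulse-train stimuli and stimulus grids.

Cricket calling song is modelled as a periodic train of rectangular sound
pulses, parameterised by pulse duration ``D`` (ms) and pause ``P`` (ms).
Derived quantities are the period ``T = D + P`` (the song's rhythm) and the
duty cycle ``DC = D / T`` (the fraction of the period filled by sound).
Models consume the envelope only, so a stimulus is a 0/1 sample trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseTrainSpec",
    "PulseTrain",
    "StimulusGrid",
    "render_pulse_train",
    "render_matrix",
    "make_fit_grid",
    "transect_points",
]


class InvalidSpecError(ValueError):
    """Raised for stimulus specifications that violate their invariants."""


@dataclass(frozen=True)
class PulseTrainSpec:
    """Geometry of a rectangular pulse train.

    Parameters
    ----------
    pulse_duration : float
        Pulse duration D in ms, > 0.
    pause : float
        Pause between pulses in ms, >= 0 (0 is a continuous tone).
    total_duration : float
        Length of the rendered train in ms (default 400).
    amplitude : float
        Envelope amplitude of the pulses (default 1).
    sample_rate : float
        Rendering sample rate in Hz.
    """

    pulse_duration: float
    pause: float
    total_duration: float = 400.0
    amplitude: float = 1.0
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if not self.pulse_duration > 0:
            raise InvalidSpecError(f"pulse_duration must be > 0, got {self.pulse_duration}")
        if self.pause < 0:
            raise InvalidSpecError(f"pause must be >= 0, got {self.pause}")
        if not self.total_duration > self.pulse_duration:
            raise InvalidSpecError("total_duration must exceed pulse_duration")
        if not self.sample_rate > 0:
            raise InvalidSpecError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def period(self) -> float:
        """Pulse period T = D + P in ms."""
        return self.pulse_duration + self.pause

    @property
    def duty_cycle(self) -> float:
        """Duty cycle D / (D + P), in (0, 1]."""
        return self.pulse_duration / self.period


@dataclass(frozen=True)
class PulseTrain:
    """A rendered pulse train: envelope samples plus its spec."""

    samples: np.ndarray
    sample_rate: float
    spec: PulseTrainSpec

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * (1000.0 / self.sample_rate)

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.sample_rate


def _pulse_mask(spec: PulseTrainSpec, n_samples: int, sample_rate: float) -> np.ndarray:
    """0/1 envelope built from per-pulse onset/offset sample indices.

    Onsets are placed at k*T; using rounded integer indices per pulse avoids
    float-modulo jitter at pulse boundaries.  The final cycle is truncated.
    """
    mask = np.zeros(n_samples, dtype=float)
    period = spec.period
    ms_to_samp = sample_rate / 1000.0
    n_periods = int(np.ceil(n_samples / (period * ms_to_samp))) + 1
    for k in range(n_periods):
        onset = k * period
        i0 = int(round(onset * ms_to_samp))
        i1 = int(round((onset + spec.pulse_duration) * ms_to_samp))
        if i0 >= n_samples:
            break
        mask[i0 : min(i1, n_samples)] = 1.0
    return mask


def render_pulse_train(spec: PulseTrainSpec) -> PulseTrain:
    """Render a spec into a 0/amplitude envelope trace.

    The trace alternates ``pulse_duration`` of ``amplitude`` with ``pause``
    of silence, periodically extended and truncated at ``total_duration``
    (a final partial pulse is kept).
    """
    n = int(round(spec.total_duration * spec.sample_rate / 1000.0))
    samples = spec.amplitude * _pulse_mask(spec, n, spec.sample_rate)
    return PulseTrain(samples=samples, sample_rate=spec.sample_rate, spec=spec)


@dataclass(frozen=True)
class StimulusGrid:
    """Ordered collection of pulse-train specs on a (pulse, pause) lattice."""

    specs: tuple[PulseTrainSpec, ...]
    step: float

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self) -> Iterator[PulseTrainSpec]:
        return iter(self.specs)

    @property
    def pulse_ms(self) -> np.ndarray:
        return np.array([s.pulse_duration for s in self.specs])

    @property
    def pause_ms(self) -> np.ndarray:
        return np.array([s.pause for s in self.specs])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_ms": self.pulse_ms,
                "pause_ms": self.pause_ms,
                "period_ms": self.pulse_ms + self.pause_ms,
                "duty_cycle": self.pulse_ms / (self.pulse_ms + self.pause_ms),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def make_fit_grid(
    max_ms: float = 20.0,
    step_ms: float = 0.5,
    *,
    total_duration: float = 400.0,
    sample_rate: float = 10_000.0,
) -> StimulusGrid:
    """All (pulse, pause) combinations on the lattice {step, 2*step, ..., max}.

    The grid used for model fitting spans pulse and pause durations up to
    20 ms in 0.5 ms steps, i.e. (20/0.5)^2 = 1600 stimuli.  Zero-length
    coordinates are excluded: a 0 ms pulse is no stimulus and a 0 ms pause
    is a tone, so lattices start at one step.
    """
    if not 0 < step_ms <= max_ms:
        raise InvalidSpecError("need 0 < step_ms <= max_ms")
    n = max_ms / step_ms
    if abs(n - round(n)) > 1e-9:
        raise InvalidSpecError(f"step_ms={step_ms} does not divide max_ms={max_ms}")
    n = int(round(n))
    values = (np.arange(n) + 1) * step_ms
    specs = tuple(
        PulseTrainSpec(
            pulse_duration=float(d),
            pause=float(p),
            total_duration=total_duration,
            sample_rate=sample_rate,
        )
        for d in values
        for p in values
    )
    return StimulusGrid(specs=specs, step=step_ms)


def render_matrix(grid: StimulusGrid | Sequence[PulseTrainSpec], sample_rate: float | None = None) -> np.ndarray:
    """Render a grid as a (n_stimuli, n_samples) matrix of envelopes.

    All specs must share the same total duration.  ``sample_rate`` overrides
    the per-spec rate (models simulate at their own resolution).
    """
    specs = list(grid)
    totals = {s.total_duration for s in specs}
    if len(totals) != 1:
        raise InvalidSpecError("all specs in a rendered matrix must share total_duration")
    total = totals.pop()
    fs = sample_rate if sample_rate is not None else specs[0].sample_rate
    n = int(round(total * fs / 1000.0))
    out = np.empty((len(specs), n))
    for i, s in enumerate(specs):
        out[i] = s.amplitude * _pulse_mask(s, n, fs)
    return out


def transect_points(
    kind: Literal["constant_dc", "constant_period"],
    value: float,
    axis_range: tuple[float, float],
    n: int,
) -> np.ndarray:
    """(pulse, pause) pairs along a PPF transect.

    ``constant_dc``: points (DC*T, (1-DC)*T) for T spanning ``axis_range``
    inclusively (period-tuning transect, a diagonal of the PPF).
    ``constant_period``: points (D, T-D) for D in the open interval (0, T)
    (DC-tuning transect, an anti-diagonal); ``axis_range`` is ignored beyond
    clipping, and D takes values T*k/(n+1) for k = 1..n.

    Returns an (n, 2) array of (pulse_ms, pause_ms).
    """
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    if kind == "constant_dc":
        dc = value
        if not 0 < dc < 1:
            raise InvalidSpecError(f"duty cycle must be in (0, 1), got {dc}")
        lo, hi = axis_range
        if hi < lo:
            raise InvalidSpecError("empty axis_range")
        periods = np.linspace(lo, hi, n)
        return np.column_stack([dc * periods, (1 - dc) * periods])
    if kind == "constant_period":
        period = value
        if not period > 0:
            raise InvalidSpecError(f"period must be > 0, got {period}")
        pulses = period * np.arange(1, n + 1) / (n + 1)
        return np.column_stack([pulses, period - pulses])
    raise InvalidSpecError(f"unknown transect kind {kind!r}")
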