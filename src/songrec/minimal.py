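"""Minimal recognition models: autocorrelation, rebound, rebound + FFI.

All three models map a pulse-train envelope ``s(t)`` onto a response trace
``r(t)`` whose windowed time average is the predicted phonotaxis score:

* **Autocorrelation** — a delay line and a multiplicative coincidence
  detector: ``r(t) = g_ac * s(t) * s(t - delay_ac)``.  Coincidence occurs
  when the period divides the delay, so response peaks sit at periods
  ``delay_ac / n``.
* **Rebound** — the non-delayed path is filtered by a biphasic
  (inhibit-then-excite) kernel whose rectified output mimics a
  post-inhibitory rebound: a transient at each pulse offset.  The rebound
  is multiplied with the delayed raw stimulus, so peaks sit at periods
  ``(delay_rb - D) / n`` for pulse duration ``D``.
* **Rebound + feedforward inhibition (FFI)** — adds a delayed inhibitory
  pathway (negative part of a second biphasic filter) onto the rebound
  model's coincidence output; the rectified sum sharpens duty-cycle tuning.

Sign convention for the rebound kernel: the kernel is written as an
inhibitory lobe of height ``-inh_gain`` for ``inh_duration`` followed by an
excitatory lobe of ``+exc_gain`` for ``exc_duration``, indexed over time
into the past, and the stimulus is sign-inverted before filtering.  In
convolution form this makes the effective kernel ``-h`` reversed:
``-exc_gain`` for ``exc_duration`` (recent past) then ``+inh_gain`` for
``inh_duration`` (distant past).  With the fitted gains this yields the
documented rebound phenomenology: the filter output is a small positive
plateau ``gi*Ti - ge*Te`` during long pulses (hence reduced but non-zero
responses to continuous tones), and a rebound transient at each pulse
offset that peaks ``exc_duration`` after the offset, saturates once the
pulse covers the inhibitory lobe, and is truncated when the next pulse
arrives within ``exc_duration``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import PulseTrain, StimulusGrid, render_matrix

__all__ = [
    "AutocorrParams",
    "ReboundParams",
    "FFIParams",
    "ResponseTrace",
    "predict_phonotaxis",
    "integrate_window",
    "autocorr_response",
    "rebound_kernel",
    "rebound_response",
    "ffi_response",
    "autocorr_scores",
    "rebound_scores",
    "ffi_scores",
    "rebound_drive_matrix",
]

#: integration window used to turn responses into phonotaxis predictions:
#: the first 25 ms and the last 10 ms of the stimulus are excluded to reduce
#: the impact of onset/offset transients.
WINDOW_SKIP_START_MS = 25.0
WINDOW_SKIP_END_MS = 10.0


@dataclass(frozen=True)
class AutocorrParams:
    """Delay (ms) and output gain of the autocorrelation model."""

    delay_ac: float = 17.0
    gain_ac: float = 0.21
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.delay_ac <= 0 or self.gain_ac <= 0:
            raise ValueError("delay_ac and gain_ac must be positive")


@dataclass(frozen=True)
class ReboundParams:
    """Rebound-model parameters: delay plus the biphasic kernel lobes.

    Gains are magnitudes; the inhibitory lobe enters the kernel negatively.
    """

    delay_rb: float = 22.93
    inh_gain: float = 0.045
    inh_duration: float = 5.06
    exc_gain: float = 0.1
    exc_duration: float = 2.00
    sample_rate: float = 4_000.0

    def __post_init__(self) -> None:
        for name in ("delay_rb", "inh_gain", "inh_duration", "exc_gain", "exc_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FFIParams:
    """Feedforward-inhibition branch parameters; the rebound base is fixed."""

    delay_ffi: float = 7.29
    ffi_inh_gain: float = 1.01
    ffi_inh_duration: float = 2.43
    ffi_exc_gain: float = 0.63
    ffi_exc_duration: float = 2.45
    base: ReboundParams = field(default_factory=ReboundParams)

    @property
    def sample_rate(self) -> float:
        return self.base.sample_rate


@dataclass(frozen=True)
class ResponseTrace:
    """Named component traces of a model simulation (equal lengths)."""

    time_ms: np.ndarray
    components: Mapping[str, np.ndarray]
    sample_rate: float

    def __post_init__(self) -> None:
        n = self.time_ms.size
        for name, trace in self.components.items():
            if trace.size != n:
                raise ValueError(f"component {name!r} length mismatch")

    @property
    def output(self) -> np.ndarray:
        return self.components["output"]

    @property
    def duration_ms(self) -> float:
        return self.time_ms.size * 1000.0 / self.sample_rate


def integrate_window(outputs: np.ndarray, sample_rate: float) -> np.ndarray:
    """Windowed time average of response rows -> predicted phonotaxis.

    ``p = 1/(Ds - 35 ms) * integral_{25 ms}^{Ds - 10 ms} r(t) dt`` where
    ``Ds`` is the stimulus duration.  Accepts a 1-D trace or an
    (n_stimuli, n_samples) matrix.
    """
    outputs = np.atleast_2d(outputs)
    n = outputs.shape[1]
    dt_ms = 1000.0 / sample_rate
    ds = n * dt_ms
    if ds <= WINDOW_SKIP_START_MS + WINDOW_SKIP_END_MS:
        raise ValueError(f"trace duration {ds} ms too short for the 25/10 ms window")
    i0 = int(round(WINDOW_SKIP_START_MS / dt_ms))
    i1 = int(round((ds - WINDOW_SKIP_END_MS) / dt_ms))
    p = outputs[:, i0:i1].sum(axis=1) * dt_ms / (ds - WINDOW_SKIP_START_MS - WINDOW_SKIP_END_MS)
    return p


def predict_phonotaxis(trace: ResponseTrace | np.ndarray, sample_rate: float | None = None) -> float:
    """Predicted phonotaxis score from a response trace (see integrate_window)."""
    if isinstance(trace, ResponseTrace):
        out, fs = trace.output, trace.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        out, fs = np.asarray(trace), sample_rate
    return float(integrate_window(out, fs)[0])


def _delay_samples(delay_ms: float, sample_rate: float) -> int:
    return int(round(delay_ms * sample_rate / 1000.0))


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples along the last axis, zero-padded (signal 0 before onset)."""
    if k == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[..., k:] = x[..., :-k]
    return out


# ---------------------------------------------------------------------------
# autocorrelation


def autocorr_response(stim: PulseTrain, params: AutocorrParams) -> ResponseTrace:
    """Coincidence of the stimulus with its delayed copy."""
    s = stim.samples
    sd = _shift(s, _delay_samples(params.delay_ac, stim.sample_rate))
    out = params.gain_ac * s * sd
    return ResponseTrace(
        time_ms=stim.time_ms,
        components={"stimulus": s, "delayed": sd, "output": out},
        sample_rate=stim.sample_rate,
    )


def autocorr_scores(
    params: AutocorrParams, grid: StimulusGrid, stim_matrix: np.ndarray | None = None
) -> np.ndarray:
    """Vectorised phonotaxis predictions over a stimulus grid."""
    s = stim_matrix if stim_matrix is not None else render_matrix(grid, params.sample_rate)
    sd = _shift(s, _delay_samples(params.delay_ac, params.sample_rate))
    return integrate_window(params.gain_ac * s * sd, params.sample_rate)


# ---------------------------------------------------------------------------
# rebound


def rebound_kernel(params: ReboundParams, sample_rate: float) -> np.ndarray:
    """Biphasic kernel: -inh_gain for inh_duration then +exc_gain for exc_duration.

    This is the kernel as written (indexed over time into the past; see the
    module docstring for the effective convolution form).  Discrete
    convolution results are multiplied by dt downstream, so the continuous
    lobe integrals -gi*Ti and +ge*Te are sample-rate invariant.
    """
    n_inh = int(round(params.inh_duration * sample_rate / 1000.0))
    n_exc = int(round(params.exc_duration * sample_rate / 1000.0))
    if n_inh < 1 or (params.exc_gain > 0 and n_exc < 1):
        raise ValueError("kernel lobe durations below one sample")
    return np.concatenate([-params.inh_gain * np.ones(n_inh), params.exc_gain * np.ones(n_exc)])


def _rebound_filter(s: np.ndarray, params: ReboundParams, sample_rate: float) -> np.ndarray:
    """Filter the sign-inverted stimulus with the past-indexed biphasic kernel.

    Implemented as a causal convolution with ``-rebound_kernel(...)[::-1]``,
    dt-normalised.
    """
    kernel = -rebound_kernel(params, sample_rate)[::-1]
    dt_ms = 1000.0 / sample_rate
    n = s.shape[-1]
    if s.ndim == 1:
        return np.convolve(s, kernel)[:n] * dt_ms
    return fftconvolve(s, kernel[None, :], mode="full", axes=1)[:, :n] * dt_ms


def rebound_response(stim: PulseTrain, params: ReboundParams) -> ResponseTrace:
    """Rectified rebound multiplied with the delayed raw stimulus."""
    s = stim.samples
    sf = _rebound_filter(s, params, stim.sample_rate)
    sr = np.maximum(sf, 0.0)
    sd = _shift(s, _delay_samples(params.delay_rb, stim.sample_rate))
    out = sr * sd
    return ResponseTrace(
        time_ms=stim.time_ms,
        components={"stimulus": s, "filtered": sf, "rebound": sr, "delayed": sd, "output": out},
        sample_rate=stim.sample_rate,
    )


def rebound_drive_matrix(
    params: ReboundParams, grid: StimulusGrid, stim_matrix: np.ndarray | None = None
) -> np.ndarray:
    """(n_stimuli, n_samples) matrix of instantaneous rebound-model outputs."""
    s = stim_matrix if stim_matrix is not None else render_matrix(grid, params.sample_rate)
    sf = _rebound_filter(s, params, params.sample_rate)
    sr = np.maximum(sf, 0.0)
    sd = _shift(s, _delay_samples(params.delay_rb, params.sample_rate))
    return sr * sd


def rebound_scores(
    params: ReboundParams, grid: StimulusGrid, stim_matrix: np.ndarray | None = None
) -> np.ndarray:
    return integrate_window(rebound_drive_matrix(params, grid, stim_matrix), params.sample_rate)


# ---------------------------------------------------------------------------
# rebound + feedforward inhibition


def _ffi_kernel(params: FFIParams, sample_rate: float) -> np.ndarray:
    as_rb = ReboundParams(
        delay_rb=params.delay_ffi,
        inh_gain=params.ffi_inh_gain,
        inh_duration=params.ffi_inh_duration,
        exc_gain=params.ffi_exc_gain,
        exc_duration=params.ffi_exc_duration,
        sample_rate=sample_rate,
    )
    return rebound_kernel(as_rb, sample_rate)


def _ffi_inhibition(s: np.ndarray, params: FFIParams, sample_rate: float) -> np.ndarray:
    """Inhibitory pathway: negative part of the biphasic-filtered, delayed stimulus.

    Uses the same past-indexed kernel convention as the rebound filter.
    """
    kernel = -_ffi_kernel(params, sample_rate)[::-1]
    dt_ms = 1000.0 / sample_rate
    n = s.shape[-1]
    sdel = _shift(s, _delay_samples(params.delay_ffi, sample_rate))
    if s.ndim == 1:
        filt = np.convolve(sdel, kernel)[:n] * dt_ms
    else:
        filt = fftconvolve(sdel, kernel[None, :], mode="full", axes=1)[:, :n] * dt_ms
    return np.minimum(filt, 0.0)


def ffi_response(stim: PulseTrain, params: FFIParams) -> ResponseTrace:
    """LN4-like unit: rebound coincidence output plus feedforward inhibition.

    Inhibition is already negative and is added; the sum passes a rectifier
    with threshold 0 and gain 1.
    """
    base = rebound_response(stim, replace(params.base, sample_rate=stim.sample_rate))
    inh = _ffi_inhibition(stim.samples, params, stim.sample_rate)
    drive = base.output + inh
    out = np.maximum(drive, 0.0)
    comps = dict(base.components)
    comps.update({"coincidence": base.output, "inhibition": inh, "drive": drive, "output": out})
    return ResponseTrace(time_ms=stim.time_ms, components=comps, sample_rate=stim.sample_rate)


def ffi_scores(
    params: FFIParams, grid: StimulusGrid, stim_matrix: np.ndarray | None = None
) -> np.ndarray:
    s = stim_matrix if stim_matrix is not None else render_matrix(grid, params.base.sample_rate)
    coincidence = rebound_drive_matrix(params.base, grid, s)
    inh = _ffi_inhibition(s, params, params.base.sample_rate)
    return integrate_window(np.maximum(coincidence + inh, 0.0), params.base.sample_rate)
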