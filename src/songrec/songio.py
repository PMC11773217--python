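"""Song waveform analysis: pulse segmentation and carrier estimation.

Follows the standard bioacoustics pipeline for pulsed insect song: the
envelope is obtained by rectification (squaring) and low-pass filtering at
200 Hz (a temporal resolution of about 2.5 ms), normalised to its peak, and
pulses are the maximal intervals where the envelope stays at or above a
threshold fraction of the peak (default 12.5%, the midpoint of the 10-15%
range conventionally used).  The carrier frequency is the location of the
magnitude-spectrum maximum of the raw waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = ["SongSegmentation", "segment_song", "carrier_frequency", "write_segmentation"]


@dataclass(frozen=True)
class SongSegmentation:
    """Pulse intervals and their summary statistics (all times in ms)."""

    onsets_ms: np.ndarray
    offsets_ms: np.ndarray

    def __post_init__(self) -> None:
        if self.onsets_ms.size != self.offsets_ms.size:
            raise ValueError("onsets and offsets must pair up")
        if np.any(self.offsets_ms <= self.onsets_ms):
            raise ValueError("each offset must follow its onset")
        if np.any(np.diff(self.onsets_ms) <= 0):
            raise ValueError("pulse intervals must be ordered")

    @property
    def n_pulses(self) -> int:
        return self.onsets_ms.size

    @property
    def durations_ms(self) -> np.ndarray:
        return self.offsets_ms - self.onsets_ms

    @property
    def pauses_ms(self) -> np.ndarray:
        """Gap after each pulse (one fewer than pulses)."""
        return self.onsets_ms[1:] - self.offsets_ms[:-1]

    @property
    def periods_ms(self) -> np.ndarray:
        """Pulse duration plus following pause = onset-to-onset interval."""
        return np.diff(self.onsets_ms)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and sd of duration, pause, period, duty cycle and pulse rate."""
        if self.n_pulses < 2:
            raise ValueError("need at least 2 pulses for summary statistics")
        dur = self.durations_ms[:-1]  # pair each duration with its following pause
        per = self.periods_ms
        dc = dur / per
        rate = 1000.0 / per
        out = {}
        for name, v in [
            ("duration_ms", dur),
            ("pause_ms", self.pauses_ms),
            ("period_ms", per),
            ("duty_cycle", dc),
            ("rate_hz", rate),
        ]:
            out[name] = (float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
        return out


def _envelope(waveform: np.ndarray, sample_rate: float, cutoff_hz: float = 200.0) -> np.ndarray:
    sos = butter(4, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    env = sosfiltfilt(sos, np.asarray(waveform, dtype=float) ** 2)
    return np.clip(env, 0.0, None)


def segment_song(
    waveform: np.ndarray,
    sample_rate: float,
    threshold_fraction: float = 0.125,
) -> SongSegmentation:
    """Segment pulses by threshold crossings of the normalised envelope.

    Partial pulses touching the recording edges are discarded.  Silent
    input yields an empty segmentation (not an error).
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    env = _envelope(waveform, sample_rate)
    peak = env.max()
    if peak <= 0:
        return SongSegmentation(onsets_ms=np.empty(0), offsets_ms=np.empty(0))
    active = env / peak >= threshold_fraction
    edges = np.diff(active.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if active[0] and offsets.size:  # partial pulse at the start
        offsets = offsets[1:]
    if active[-1] and onsets.size and (offsets.size == 0 or onsets[-1] > offsets[-1]):
        onsets = onsets[:-1]  # partial pulse at the end
    n = min(onsets.size, offsets.size)
    ms = 1000.0 / sample_rate
    return SongSegmentation(onsets_ms=onsets[:n] * ms, offsets_ms=offsets[:n] * ms)


def carrier_frequency(waveform: np.ndarray, sample_rate: float) -> float:
    """Frequency (Hz) of the magnitude-spectrum maximum of the raw waveform."""
    w = np.asarray(waveform, dtype=float)
    if w.size < 16:
        raise ValueError("waveform shorter than the minimum analysis window")
    if not np.any(w):
        raise ValueError("all-zero waveform has no defined spectral peak")
    spectrum = np.abs(np.fft.rfft(w - w.mean()))
    freqs = np.fft.rfftfreq(w.size, d=1.0 / sample_rate)
    return float(freqs[np.argmax(spectrum)])


def write_segmentation(seg: SongSegmentation, path) -> None:
    """Delimited text: onset_ms, offset_ms, duration_ms, pause_ms."""
    pauses = np.append(seg.pauses_ms, np.nan) if seg.n_pulses else np.empty(0)
    pd.DataFrame(
        {
            "onset_ms": seg.onsets_ms,
            "offset_ms": seg.offsets_ms,
            "duration_ms": seg.durations_ms,
            "pause_ms": pauses,
        }
    ).to_csv(path, index=False)
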