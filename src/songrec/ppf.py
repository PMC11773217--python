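"""Pulse-pause preference fields (PPFs).

A PPF maps the strength of female phonotaxis over the two-dimensional space
of pulse duration x pause duration.  Behavioural experiments sample this
space at scattered stimulus coordinates; the field is reconstructed by
scattered-data interpolation onto a regular lattice.  Phonotaxis scores are
normalised to an attractive control (so typically 0..1), but single
measurements may fall outside that range; interpolated fields are clipped
at zero.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "PhonotaxisRecord",
    "PreferenceField",
    "interpolate_field",
    "period_transect",
    "dc_transect",
    "peak_significance",
    "read_phonotaxis_table",
    "write_phonotaxis_table",
    "read_field",
    "write_field",
]


class InterpolationError(ValueError):
    """Raised when a field cannot be interpolated from the given records."""


@dataclass(frozen=True)
class PhonotaxisRecord:
    """Mean phonotaxis score for one (pulse, pause) stimulus.

    ``score`` is the across-female mean; ``per_female_scores`` optionally
    keeps the individual values (needed for paired significance tests).
    """

    pulse_duration: float
    pause: float
    score: float
    n_females: int = 1
    per_female_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.per_female_scores is not None:
            m = float(np.mean(self.per_female_scores))
            if abs(m - self.score) > 1e-6 + 1e-6 * abs(m):
                raise ValueError("per_female_scores mean does not match score")


@dataclass(frozen=True)
class PreferenceField:
    """A non-negative score grid over pulse duration x pause.

    ``values[i, j]`` is the score at ``pulse_axis[i]``, ``pause_axis[j]``.
    Axes are uniform with spacing ``resolution`` (ms).
    """

    pulse_axis: np.ndarray
    pause_axis: np.ndarray
    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        if self.values.shape != (self.pulse_axis.size, self.pause_axis.size):
            raise ValueError("values shape inconsistent with axes")
        for ax in (self.pulse_axis, self.pause_axis):
            if ax.size > 1 and not np.allclose(np.diff(ax), self.resolution, atol=1e-9):
                raise ValueError("axes must be uniform with the stated resolution")

    @property
    def extent(self) -> float:
        return float(self.pulse_axis[-1])

    def value_at(self, pulse_ms, pause_ms) -> np.ndarray:
        """Bilinear lookup at (pulse, pause) coordinates (clipped to the grid)."""
        pulse_ms = np.asarray(pulse_ms, dtype=float)
        pause_ms = np.asarray(pause_ms, dtype=float)
        xi = np.clip(
            (pulse_ms - self.pulse_axis[0]) / self.resolution, 0, self.pulse_axis.size - 1
        )
        yi = np.clip(
            (pause_ms - self.pause_axis[0]) / self.resolution, 0, self.pause_axis.size - 1
        )
        i0 = np.clip(np.floor(xi).astype(int), 0, self.pulse_axis.size - 2) if self.pulse_axis.size > 1 else np.zeros_like(xi, int)
        j0 = np.clip(np.floor(yi).astype(int), 0, self.pause_axis.size - 2) if self.pause_axis.size > 1 else np.zeros_like(yi, int)
        fx = xi - i0
        fy = yi - j0
        v = self.values
        if self.pulse_axis.size == 1:
            fx = np.zeros_like(fx)
            i1 = i0
        else:
            i1 = i0 + 1
        if self.pause_axis.size == 1:
            fy = np.zeros_like(fy)
            j1 = j0
        else:
            j1 = j0 + 1
        out = (
            v[i0, j0] * (1 - fx) * (1 - fy)
            + v[i1, j0] * fx * (1 - fy)
            + v[i0, j1] * (1 - fx) * fy
            + v[i1, j1] * fx * fy
        )
        return out


def interpolate_field(
    records: Sequence[PhonotaxisRecord],
    resolution: float = 0.5,
    extent: float = 20.0,
) -> PreferenceField:
    """Interpolate scattered phonotaxis records onto a regular lattice.

    Uses Delaunay-based piecewise-linear interpolation (exact at the data
    points, continuous, local), with nearest-inside fill beyond the convex
    hull of the records.  Negative interpolated values are clipped to 0.
    """
    if len(records) < 3:
        raise InterpolationError("need at least 3 records to interpolate a field")
    pts = np.array([(r.pulse_duration, r.pause) for r in records])
    scores = np.array([r.score for r in records])
    axis = np.arange(0.0, extent + resolution / 2, resolution)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    try:
        lin = LinearNDInterpolator(pts, scores)
    except QhullError as err:
        raise InterpolationError(f"records are collinear or degenerate: {err}") from None
    vals = lin(gx, gy)
    if np.all(np.isnan(vals)):
        raise InterpolationError("interpolation produced no values inside the hull")
    near = NearestNDInterpolator(pts, scores)
    mask = np.isnan(vals)
    if mask.any():
        vals[mask] = near(gx[mask], gy[mask])
    vals = np.clip(vals, 0.0, None)
    return PreferenceField(pulse_axis=axis, pause_axis=axis.copy(), values=vals, resolution=resolution)


def period_transect(field: PreferenceField, dc: float) -> tuple[np.ndarray, np.ndarray]:
    """Period tuning at constant duty cycle: field along (DC*T, (1-DC)*T).

    Returns (periods_ms, values) for all periods representable on the grid.
    """
    if not 0 < dc < 1:
        raise ValueError(f"duty cycle must be in (0, 1), got {dc}")
    t_max = min(field.pulse_axis[-1] / dc, field.pause_axis[-1] / (1 - dc))
    periods = np.arange(field.resolution, t_max + field.resolution / 2, field.resolution)
    vals = field.value_at(dc * periods, (1 - dc) * periods)
    return periods, vals


def dc_transect(field: PreferenceField, period: float) -> tuple[np.ndarray, np.ndarray]:
    """DC tuning at constant period: field along (D, T-D) for D in (0, T).

    Returns (duty_cycles, values).  Points where either coordinate leaves
    the grid (periods beyond the extent) are omitted.
    """
    extent = min(field.pulse_axis[-1], field.pause_axis[-1])
    if not 0 < period <= 2 * extent:
        raise ValueError(f"period {period} beyond grid reach (max {2 * extent})")
    pulses = np.arange(field.resolution, period, field.resolution)
    pauses = period - pulses
    ok = (pulses <= field.pulse_axis[-1]) & (pauses <= field.pause_axis[-1])
    pulses, pauses = pulses[ok], pauses[ok]
    if pulses.size == 0:
        raise ValueError(f"no grid points on the period-{period} transect")
    vals = field.value_at(pulses, pauses)
    return pulses / period, vals


def peak_significance(
    per_female_scores_at_peak: Sequence[float],
    per_female_scores_reference: Sequence[float],
) -> float:
    """One-sided paired t-test p-value for 'peak > reference'.

    Scores are paired by female.  With zero variance of the paired
    differences the t statistic is undefined: the p-value degenerates to
    0.5 for identical vectors and to 0 for a uniform positive shift
    (a warning is emitted in the degenerate case).
    """
    a = np.asarray(per_female_scores_at_peak, dtype=float)
    b = np.asarray(per_female_scores_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired females")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.5
        warnings.warn("zero variance of paired differences; p-value degenerate", RuntimeWarning)
        return 0.0 if d.mean() > 0 else 1.0
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(stats.t.sf(t, df=d.size - 1))


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_phonotaxis_table(records: Sequence[PhonotaxisRecord], path) -> None:
    """Write records as CSV: pulse_ms,pause_ms,score,n_females[,female_1..k]."""
    n_fem_max = max((len(r.per_female_scores) if r.per_female_scores else 0) for r in records)
    rows = []
    for r in records:
        row = {
            "pulse_ms": r.pulse_duration,
            "pause_ms": r.pause,
            "score": r.score,
            "n_females": r.n_females,
        }
        for k in range(n_fem_max):
            if r.per_female_scores is not None and k < len(r.per_female_scores):
                row[f"female_{k + 1}"] = r.per_female_scores[k]
            else:
                row[f"female_{k + 1}"] = np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phonotaxis_table(path) -> list[PhonotaxisRecord]:
    df = pd.read_csv(path)
    fem_cols = [c for c in df.columns if c.startswith("female_")]
    records = []
    for _, row in df.iterrows():
        per_female = None
        if fem_cols:
            vals = tuple(float(row[c]) for c in fem_cols if np.isfinite(row[c]))
            per_female = vals if vals else None
        records.append(
            PhonotaxisRecord(
                pulse_duration=float(row["pulse_ms"]),
                pause=float(row["pause_ms"]),
                score=float(row["score"]),
                n_females=int(row["n_females"]),
                per_female_scores=per_female,
            )
        )
    return records


def write_field(field: PreferenceField, path) -> None:
    """Gridded delimited format with a small metadata header."""
    gx, gy = np.meshgrid(field.pulse_axis, field.pause_axis, indexing="ij")
    df = pd.DataFrame(
        {"pulse_ms": gx.ravel(), "pause_ms": gy.ravel(), "value": field.values.ravel()}
    )
    buf = io.StringIO()
    buf.write(f"# resolution_ms: {field.resolution}\n")
    buf.write(f"# extent_ms: {field.extent}\n")
    buf.write("# negative values clipped to 0\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_field(path) -> PreferenceField:
    with open(path) as fh:
        lines = fh.readlines()
    meta = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    resolution = float(meta.get("resolution_ms", np.diff(np.unique(df["pulse_ms"]))[0]))
    pulse_axis = np.unique(df["pulse_ms"].to_numpy())
    pause_axis = np.unique(df["pause_ms"].to_numpy())
    values = (
        df.pivot(index="pulse_ms", columns="pause_ms", values="value")
        .reindex(index=pulse_axis, columns=pause_axis)
        .to_numpy()
    )
    return PreferenceField(
        pulse_axis=pulse_axis, pause_axis=pause_axis, values=values, resolution=resolution
    )
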