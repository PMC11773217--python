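"""Model fitting: multi-start Nelder-Mead against a target preference field.

Each model exposes its free parameters as a flat vector.  Because delays,
durations, gains and frequencies are positive by construction (and the R&F
damping is negative), the optimiser works in log-magnitude space with the
signs of the initial vector held fixed — Nelder-Mead then stays
unconstrained while the model only ever sees admissible parameters.

The loss is the mean squared error between the model's predicted phonotaxis
scores and the target field sampled on the fitting grid.  Fits restart from
seeded, jittered initial vectors (restart 0 is unjittered) to avoid local
minima; the best restart wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from . import minimal, resonate_fire
from .minimal import AutocorrParams, FFIParams, ReboundParams
from .ppf import PreferenceField
from .resonate_fire import RFParams
from .stimuli import StimulusGrid, make_fit_grid, render_matrix

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelAdapter",
    "AutocorrModel",
    "ReboundModel",
    "FFIModel",
    "RFModel",
    "mse_objective",
    "fit_model",
    "target_scores_on_grid",
]

_PENALTY = 1e6


@dataclass(frozen=True)
class FitConfig:
    """Multi-start Nelder-Mead configuration."""

    n_restarts: int = 8
    jitter_scale: float = 0.1  # sd of the seeded perturbation in log space
    seed: int = 0
    max_iterations: int = 2000
    tolerance: float = 1e-6  # simplex fatol on the loss
    polish_rounds: int = 0  # fresh-simplex re-runs from the incumbent best

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


@dataclass(frozen=True)
class RestartResult:
    params: object
    loss: float
    iterations: int


@dataclass(frozen=True)
class FitResult:
    """Best parameters plus per-restart provenance."""

    best_params: object
    best_loss: float
    restarts: tuple[RestartResult, ...]
    seed: int

    def summary(self) -> str:
        lines = [f"best loss: {self.best_loss:.6g} (seed {self.seed})"]
        for i, r in enumerate(self.restarts):
            lines.append(f"  restart {i}: loss {r.loss:.6g} after {r.iterations} iterations")
        lines.append(f"best parameters: {self.best_params}")
        return "\n".join(lines)


class ModelAdapter:
    """Bridges a parameter dataclass and a vectorised score predictor.

    ``fit_fields`` lists the dataclass fields exposed to the optimiser;
    everything else (sample rates, fixed sub-models) is carried through.
    """

    name: str = "model"
    fit_fields: tuple[str, ...] = ()

    def __init__(self, initial_params, grid: StimulusGrid | None = None):
        self.initial_params = initial_params
        self.grid = grid if grid is not None else make_fit_grid()
        self._stim_matrix: np.ndarray | None = None

    # -- parameter vector <-> dataclass -------------------------------------
    def to_vector(self, params) -> np.ndarray:
        return np.array([getattr(params, f) for f in self.fit_fields], dtype=float)

    def from_vector(self, vec: np.ndarray):
        return replace(self.initial_params, **dict(zip(self.fit_fields, map(float, vec))))

    # -- prediction ----------------------------------------------------------
    @property
    def sample_rate(self) -> float:
        return self.initial_params.sample_rate

    def stim_matrix(self) -> np.ndarray:
        if self._stim_matrix is None:
            self._stim_matrix = render_matrix(self.grid, self.sample_rate)
        return self._stim_matrix

    def predict_scores(self, params) -> np.ndarray:
        raise NotImplementedError


class AutocorrModel(ModelAdapter):
    """Autocorrelation model with a cached fast score path.

    The windowed integral of ``s(t) * s(t - delay)`` over all grid stimuli
    is a cross-correlation of the windowed stimulus with itself, so it is
    precomputed once for every integer-sample lag; predictions for any
    delay are then lookups.  Identical (to rounding of the delay to one
    sample, as in the direct path) to ``minimal.autocorr_scores``.
    """

    name = "autocorrelation"
    fit_fields = ("delay_ac", "gain_ac")

    def __init__(self, initial_params: AutocorrParams | None = None, grid=None):
        super().__init__(initial_params or AutocorrParams(), grid)
        self._corr: np.ndarray | None = None

    def _corr_table(self) -> np.ndarray:
        if self._corr is None:
            s = self.stim_matrix()
            fs = self.sample_rate
            dt_ms = 1000.0 / fs
            n = s.shape[1]
            ds = n * dt_ms
            i0 = int(round(minimal.WINDOW_SKIP_START_MS / dt_ms))
            i1 = int(round((ds - minimal.WINDOW_SKIP_END_MS) / dt_ms))
            sw = np.zeros_like(s)
            sw[:, i0:i1] = s[:, i0:i1]
            n_lag = n
            n_fft = 1 << int(np.ceil(np.log2(2 * n)))
            F = np.fft.rfft(s, n_fft, axis=1)
            Fw = np.fft.rfft(sw, n_fft, axis=1)
            full = np.fft.irfft(Fw * np.conj(F), n_fft, axis=1)[:, :n_lag]
            self._corr = full * dt_ms / (ds - minimal.WINDOW_SKIP_START_MS - minimal.WINDOW_SKIP_END_MS)
        return self._corr

    def predict_scores(self, params: AutocorrParams) -> np.ndarray:
        corr = self._corr_table()
        k = int(round(params.delay_ac * self.sample_rate / 1000.0))
        if k >= corr.shape[1]:
            k = corr.shape[1] - 1
        return params.gain_ac * corr[:, k]


class ReboundModel(ModelAdapter):
    """Rebound model with a cached fast score path.

    The effective rebound kernel is piecewise constant (two rectangular
    lobes), so its convolution with the stimulus is a combination of two
    shifted differences of the stimulus cumulative sum, which is
    precomputed once.  Numerically identical to ``minimal.rebound_scores``
    (same sample quantisation of durations and delay).
    """

    name = "rebound"
    fit_fields = ("delay_rb", "inh_gain", "inh_duration", "exc_gain", "exc_duration")

    def __init__(self, initial_params: ReboundParams | None = None, grid=None):
        super().__init__(initial_params or ReboundParams(), grid)
        self._cumsum: np.ndarray | None = None

    def _stim_cumsum(self) -> np.ndarray:
        if self._cumsum is None:
            s = self.stim_matrix()
            self._cumsum = np.concatenate(
                [np.zeros((s.shape[0], 1)), np.cumsum(s, axis=1)], axis=1
            )
        return self._cumsum

    def _lagged_cumsum(self, lag: float) -> np.ndarray:
        """C(i - lag) for all sample indices i, fractional lag by linear interp."""
        c = self._stim_cumsum()
        n = c.shape[1] - 1
        idx = np.arange(n) + 1
        k = int(np.floor(lag))
        frac = lag - k
        lo = np.maximum(idx - k - 1, 0)
        hi = np.maximum(idx - k, 0)
        return (1.0 - frac) * c[:, hi] + frac * c[:, lo]

    def predict_scores(self, params: ReboundParams) -> np.ndarray:
        """Smooth-in-parameters evaluation of the rebound model.

        Lobe durations and the delay enter with fractional-sample linear
        interpolation so the fitting objective has no sample-quantisation
        plateaus; at integer-sample parameter values this coincides with
        the direct simulation.
        """
        fs = self.sample_rate
        dt_ms = 1000.0 / fs
        n_exc = params.exc_duration * fs / 1000.0
        n_inh = params.inh_duration * fs / 1000.0
        if n_inh < 1 or (params.exc_gain > 0 and n_exc < 1):
            raise ValueError("kernel lobe durations below one sample")
        s = self.stim_matrix()
        c = self._stim_cumsum()
        n = s.shape[1]
        here = c[:, 1:]
        at_exc = self._lagged_cumsum(n_exc)
        at_end = self._lagged_cumsum(n_exc + n_inh)
        # effective kernel: -ge over the most recent exc_duration, then +gi
        # over the preceding inh_duration (see minimal._rebound_filter)
        sf = (-params.exc_gain * (here - at_exc) + params.inh_gain * (at_exc - at_end)) * dt_ms
        sr = np.maximum(sf, 0.0)
        lag = params.delay_rb * fs / 1000.0
        k = int(np.floor(lag))
        frac = lag - k
        sd = np.zeros_like(s)
        if k < n:
            sd[:, k:] = (1.0 - frac) * s[:, : n - k]
        if k + 1 < n:
            sd[:, k + 1 :] += frac * s[:, : n - k - 1]
        return minimal.integrate_window(sr * sd, fs)


class FFIModel(ModelAdapter):
    """Fits only the feedforward-inhibition branch; the rebound base is frozen."""

    name = "rebound_ffi"
    fit_fields = ("delay_ffi", "ffi_inh_gain", "ffi_inh_duration", "ffi_exc_gain", "ffi_exc_duration")

    def __init__(self, initial_params: FFIParams | None = None, grid=None):
        super().__init__(initial_params or FFIParams(), grid)

    @property
    def sample_rate(self) -> float:
        return self.initial_params.base.sample_rate

    def predict_scores(self, params: FFIParams) -> np.ndarray:
        return minimal.ffi_scores(params, self.grid, self.stim_matrix())


class RFModel(ModelAdapter):
    name = "resonate_and_fire"
    fit_fields = ("freq_rf", "damping_b", "gain_s", "spike_amp")

    def __init__(self, initial_params: RFParams | None = None, grid=None):
        super().__init__(initial_params or RFParams(), grid)

    def predict_scores(self, params: RFParams) -> np.ndarray:
        return resonate_fire.rf_scores(params, self.grid, self.stim_matrix())


def target_scores_on_grid(target: PreferenceField, grid: StimulusGrid) -> np.ndarray:
    """Sample a target field at the grid's (pulse, pause) coordinates."""
    return target.value_at(grid.pulse_ms, grid.pause_ms)


def mse_objective(
    model: ModelAdapter,
    params,
    target: PreferenceField | np.ndarray,
    grid: StimulusGrid | None = None,
    penalty: Callable[[object], float] | None = None,
) -> float:
    """Mean squared error between predicted and target scores.

    Non-finite predictions are mapped to a large penalised loss.  An
    optional ``penalty`` callable (e.g. a sustained-activity constraint when
    fitting the full network) is added to the loss.
    """
    grid = grid if grid is not None else model.grid
    tgt = target_scores_on_grid(target, grid) if isinstance(target, PreferenceField) else np.asarray(target)
    try:
        pred = model.predict_scores(params)
    except (FloatingPointError, ValueError):
        return _PENALTY
    if not np.all(np.isfinite(pred)):
        return _PENALTY
    loss = float(np.mean((pred - tgt) ** 2))
    if penalty is not None:
        loss += float(penalty(params))
    return loss


def _to_log_space(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    signs = np.sign(vec)
    if np.any(signs == 0):
        raise ValueError("initial parameters must be non-zero for the log transform")
    return np.log(np.abs(vec)), signs


def fit_model(
    model: ModelAdapter,
    target: PreferenceField | np.ndarray,
    config: FitConfig | None = None,
    penalty: Callable[[object], float] | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead fit of a model to a target field.

    Restart 0 starts from the model's initial parameters; later restarts
    jitter the log-space vector with seeded Gaussian noise of sd
    ``jitter_scale``.  Deterministic under a fixed seed and config.
    """
    config = config or FitConfig()
    tgt = (
        target_scores_on_grid(target, model.grid)
        if isinstance(target, PreferenceField)
        else np.asarray(target, dtype=float)
    )
    v0 = model.to_vector(model.initial_params)
    log0, signs = _to_log_space(v0)
    rng = np.random.default_rng(config.seed)

    def loss_of(log_vec: np.ndarray) -> float:
        params = model.from_vector(signs * np.exp(log_vec))
        return mse_objective(model, params, tgt, model.grid, penalty)

    restarts: list[RestartResult] = []
    for k in range(config.n_restarts):
        start = log0 if k == 0 else log0 + rng.normal(0.0, config.jitter_scale, size=log0.size)
        res = minimize(
            loss_of,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iterations,
                "fatol": config.tolerance,
                "xatol": 1e-6,
            },
        )
        restarts.append(
            RestartResult(
                params=model.from_vector(signs * np.exp(res.x)),
                loss=float(res.fun),
                iterations=int(res.nit),
            )
        )
    finite = [r for r in restarts if np.isfinite(r.loss) and r.loss < _PENALTY]
    if not finite:
        raise RuntimeError("all restarts produced non-finite losses; fit failed")
    best = min(finite, key=lambda r: r.loss)
    # polish: Nelder-Mead terminates when the simplex collapses, which on a
    # plateaued loss can happen away from the basin optimum; re-running from
    # the incumbent best with a freshly inflated simplex resumes the descent
    for _ in range(config.polish_rounds):
        x0, _sgn = _to_log_space(model.to_vector(best.params))
        step = 0.05
        simplex = np.vstack([x0] + [x0 + step * np.eye(x0.size)[i] for i in range(x0.size)])
        res = minimize(
            loss_of,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iterations,
                "fatol": config.tolerance,
                "xatol": 1e-6,
                "initial_simplex": simplex,
            },
        )
        if np.isfinite(res.fun) and res.fun < best.loss:
            best = RestartResult(
                params=model.from_vector(signs * np.exp(res.x)),
                loss=float(res.fun),
                iterations=int(res.nit),
            )
    return FitResult(
        best_params=best.params,
        best_loss=best.loss,
        restarts=tuple(restarts),
        seed=config.seed,
    )
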