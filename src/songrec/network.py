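"""Five-neuron song-recognition network ("mother network").

The circuit described from *Gryllus bimaculatus* recognises pulse song in
five steps: AN1 relays an intensity-invariant copy of the pulse pattern to
the brain; LN2 follows the pattern and inhibits LN5 and LN4; the non-spiking
LN5 produces a post-inhibitory rebound at each pulse offset; LN3 detects the
coincidence of the LN5 rebound with a delayed copy of AN1; LN4 combines LN3
excitation with feedforward inhibition from LN2, which sharpens the tuning.

The implementation is a rate-based (graded) feed-forward network.  Each
neuron is a chain of stages applied to the delayed, gained sum of its
inputs: linear filters built from parametric lobes, static nonlinearities
(sigmoid or rectifier), and divisive-normalisation adaptation.  Functional
forms are declared here (the parameter tables alone do not pin them down):

* Gaussian lobe: ``gain * exp(-(t - mu)^2 / (2 sigma^2))`` with
  ``mu = duration/2``, truncated at ``duration``.
* Exponential lobe: ``gain * exp(-t / tau)`` truncated at ``duration``.
* Differentiated Gaussian: the first derivative of a Gaussian spanning
  ``duration`` (sigma = duration/6), scaled so the second lobe peaks at
  ``gain``; the sign of ``gain`` sets the polarity.  With positive gain it
  turns a sustained input into a negative onset and a positive offset
  transient; with negative gain the transients swap edges.
* Sigmoid: ``baseline + gain / (1 + exp(-slope (x - shift)))``, with the
  resting value (response to zero input) subtracted so silence maps to
  silence throughout the network.
* Rectifier: ``gain * max(0, x - threshold)``.
* Divisive normalisation: ``x / (x0 + w * a)`` where ``a`` is a low-pass
  (time constant ``tau``) of ``x`` with ``a(0) = 0``.

Discrete convolutions are multiplied by the sample interval, so filter
output amplitudes are sample-rate invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.signal import correlate, correlation_lags, lfilter

from .minimal import integrate_window
from .stimuli import PulseTrain, PulseTrainSpec, render_pulse_train

__all__ = [
    "FilterLobe",
    "Sigmoid",
    "Relu",
    "AdaptationSpec",
    "SynapseSpec",
    "NeuronSpec",
    "NetworkParams",
    "Filter",
    "apply_filter",
    "divisive_norm",
    "simulate_network",
    "network_scores",
    "effective_ln3_input_delay",
    "an1_sustained_penalty",
    "free_parameter_count",
    "get_free_parameters",
    "set_free_parameters",
    "anurogryllus_network",
]

STIMULUS = "stimulus"


class NetworkConfigError(ValueError):
    """Raised for cyclic graphs, missing sources, or bad stage configs."""


@dataclass
class FilterLobe:
    """One lobe of a linear filter kernel."""

    shape: Literal["gaussian", "exponential", "differentiated_gaussian"]
    width_or_tau: float  # sigma (gaussian) or decay tau (exponential), ms
    duration: float  # truncation length, ms
    gain: float  # signed; negative = inhibitory lobe
    center: float | None = None  # gaussian mean, ms; None = duration/2
    fixed: frozenset = field(default_factory=frozenset)

    PARAMS = ("width_or_tau", "duration", "gain")

    def kernel(self, sample_rate: float) -> np.ndarray:
        dt = 1000.0 / sample_rate
        n = int(round(self.duration / dt))
        if n < 1:
            raise NetworkConfigError(f"lobe duration {self.duration} ms below one sample")
        t = np.arange(n) * dt
        if self.shape == "gaussian":
            mu = self.duration / 2.0 if self.center is None else self.center
            return self.gain * np.exp(-((t - mu) ** 2) / (2.0 * self.width_or_tau**2))
        if self.shape == "exponential":
            return self.gain * np.exp(-t / self.width_or_tau)
        if self.shape == "differentiated_gaussian":
            mu = self.duration / 2.0
            sigma = self.duration / 6.0
            raw = (t - mu) * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))
            raw -= raw.mean()  # enforce zero DC despite truncation asymmetry
            peak = raw.max()
            if peak <= 0:
                raise NetworkConfigError("degenerate differentiated-gaussian lobe")
            return self.gain * raw / peak
        raise NetworkConfigError(f"unknown lobe shape {self.shape!r}")


@dataclass
class Filter:
    """A linear filter stage: causal convolution with summed lobe kernels."""

    lobes: tuple[FilterLobe, ...] = ()

    def __call__(self, signal: np.ndarray, sample_rate: float) -> np.ndarray:
        return apply_filter(signal, self.lobes, sample_rate)


@dataclass
class Sigmoid:
    """Saturating nonlinearity, rest-subtracted so zero input gives zero output."""

    slope: float
    shift: float
    gain: float
    baseline: float
    fixed: frozenset = field(default_factory=frozenset)

    PARAMS = ("slope", "shift", "gain", "baseline")

    def _raw(self, x):
        return self.baseline + self.gain / (1.0 + np.exp(-self.slope * (x - self.shift)))

    def __call__(self, x: np.ndarray, sample_rate: float) -> np.ndarray:
        return self._raw(x) - self._raw(0.0)


@dataclass
class Relu:
    """Rectifying linear nonlinearity: gain * max(0, x - threshold).

    Rest-subtracted like the sigmoid: for a negative threshold the constant
    response to zero input is removed (and the result re-rectified), so
    silence maps to silence while outputs stay non-negative.
    """

    threshold: float = 0.0
    gain: float = 1.0
    fixed: frozenset = field(default_factory=frozenset)

    PARAMS = ("threshold", "gain")

    def __call__(self, x: np.ndarray, sample_rate: float) -> np.ndarray:
        rest = max(0.0, -self.threshold)
        return self.gain * np.maximum(0.0, np.maximum(0.0, x - self.threshold) - rest)


@dataclass
class AdaptationSpec:
    """Divisive normalisation: x / (x0 + w * lowpass_tau(x)), a(0) = 0."""

    tau: float
    strength_w: float
    offset_x0: float = 1.0
    fixed: frozenset = field(default_factory=frozenset)

    PARAMS = ("tau", "strength_w", "offset_x0")

    def __call__(self, x: np.ndarray, sample_rate: float) -> np.ndarray:
        return divisive_norm(x, self, sample_rate)


@dataclass
class SynapseSpec:
    """Delayed, gained input from a source neuron (or the stimulus)."""

    source: str
    delay: float = 0.0  # ms, >= 0
    gain: float = 1.0  # signed; negative = inhibition
    fixed: frozenset = field(default_factory=frozenset)

    PARAMS = ("delay", "gain")

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise NetworkConfigError("synaptic delay must be >= 0")


@dataclass
class NeuronSpec:
    """Ordered processing stages applied to the summed synaptic input."""

    name: str
    inputs: tuple[SynapseSpec, ...]
    stages: tuple = ()


@dataclass
class NetworkParams:
    """A feed-forward network: named neurons plus the output neuron."""

    neurons: dict[str, NeuronSpec]
    output: str = "LN4"
    sample_rate: float = 10_000.0
    n_tied: int = 0  # parameters shared between components, counted once

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(name: str) -> None:
            if state.get(name) == 1:
                raise NetworkConfigError(f"cycle through neuron {name!r}")
            if state.get(name) == 2:
                return
            if name not in self.neurons:
                raise NetworkConfigError(f"missing source neuron {name!r}")
            state[name] = 1
            for syn in self.neurons[name].inputs:
                if syn.source != STIMULUS:
                    visit(syn.source)
            state[name] = 2
            order.append(name)

        for name in self.neurons:
            visit(name)
        return order


def apply_filter(
    signal: np.ndarray, lobes: Iterable[FilterLobe], sample_rate: float
) -> np.ndarray:
    """Causal convolution with the summed lobe kernels, dt-normalised.

    An empty lobe list is the identity.
    """
    lobes = tuple(lobes)
    if not lobes:
        return np.asarray(signal, dtype=float).copy()
    kernels = [lobe.kernel(sample_rate) for lobe in lobes]
    n_k = max(k.size for k in kernels)
    kernel = np.zeros(n_k)
    for k in kernels:
        kernel[: k.size] += k
    dt = 1000.0 / sample_rate
    n = signal.shape[-1]
    return np.convolve(signal, kernel)[:n] * dt


def divisive_norm(signal: np.ndarray, spec: AdaptationSpec, sample_rate: float) -> np.ndarray:
    """Divisive normalisation with a first-order low-pass adaptation state."""
    dt = 1000.0 / sample_rate
    k = dt / spec.tau
    # a[t] = (1-k) a[t-1] + k x[t-1]; a[0] = 0
    a = lfilter([0.0, k], [1.0, -(1.0 - k)], signal)
    denom = spec.offset_x0 + spec.strength_w * a
    if np.any(denom <= 0):
        raise FloatingPointError("divisive normalisation denominator reached <= 0")
    return signal / denom


def _delay_samples(delay_ms: float, sample_rate: float) -> int:
    return int(round(delay_ms * sample_rate / 1000.0))


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return x.copy()
    out = np.zeros_like(x)
    out[k:] = x[:-k]
    return out


def _neuron_drive(
    spec: NeuronSpec, traces: dict[str, np.ndarray], sample_rate: float
) -> np.ndarray:
    drive = None
    for syn in spec.inputs:
        if syn.source not in traces:
            raise NetworkConfigError(f"missing source {syn.source!r} for {spec.name!r}")
        contrib = syn.gain * _shift(traces[syn.source], _delay_samples(syn.delay, sample_rate))
        drive = contrib if drive is None else drive + contrib
    if drive is None:
        raise NetworkConfigError(f"neuron {spec.name!r} has no inputs")
    return drive


def simulate_network(
    stim: PulseTrain, params: NetworkParams
) -> tuple[dict[str, np.ndarray], float]:
    """Evaluate all neurons in topological order.

    Returns (per-neuron output traces, phonotaxis score of the output
    neuron).  The stimulus envelope enters under the source name
    ``"stimulus"``.
    """
    if abs(stim.sample_rate - params.sample_rate) > 1e-6:
        raise NetworkConfigError("stimulus must be rendered at the network sample rate")
    fs = params.sample_rate
    traces: dict[str, np.ndarray] = {STIMULUS: stim.samples.astype(float)}
    for name in params.topological_order():
        spec = params.neurons[name]
        x = _neuron_drive(spec, traces, fs)
        for stage in spec.stages:
            x = stage(x, fs)
        traces[name] = x
    score = float(integrate_window(traces[params.output], fs)[0])
    return traces, score


def network_scores(specs, params: NetworkParams) -> np.ndarray:
    """Phonotaxis predictions for a collection of stimulus specs."""
    out = np.empty(len(list(specs)))
    for i, s in enumerate(specs):
        stim = render_pulse_train(
            PulseTrainSpec(
                pulse_duration=s.pulse_duration,
                pause=s.pause,
                total_duration=s.total_duration,
                amplitude=s.amplitude,
                sample_rate=params.sample_rate,
            )
        )
        out[i] = simulate_network(stim, params)[1]
    return out


def effective_ln3_input_delay(
    params: NetworkParams,
    pulse_duration: float = 5.0,
    total_duration: float = 200.0,
    coincidence_neuron: str = "LN3",
) -> float:
    """Lag (ms) between the two input drives of the coincidence detector.

    Simulates a single isolated pulse and cross-correlates the two synaptic
    drives of ``coincidence_neuron`` (e.g. the AN1 path vs the LN5 rebound
    path of LN3); returns the lag of the correlation maximum, positive when
    the second listed input trails the first.
    """
    spec = params.neurons[coincidence_neuron]
    if len(spec.inputs) != 2:
        raise NetworkConfigError("effective delay needs exactly two inputs")
    stim = render_pulse_train(
        PulseTrainSpec(
            pulse_duration=pulse_duration,
            pause=total_duration,  # no second pulse within the trace
            total_duration=total_duration,
            sample_rate=params.sample_rate,
        )
    )
    traces, _ = simulate_network(stim, params)
    fs = params.sample_rate
    drives = [
        syn.gain * _shift(traces[syn.source], _delay_samples(syn.delay, fs))
        for syn in spec.inputs
    ]
    d0, d1 = (d - d.mean() for d in drives)
    if np.allclose(d0, 0) or np.allclose(d1, 0):
        raise NetworkConfigError("degenerate flat input drive; lag undefined")
    corr = correlate(d1, d0, mode="full")
    lags = correlation_lags(d1.size, d0.size, mode="full")
    return float(lags[np.argmax(corr)] * 1000.0 / fs)


def an1_sustained_penalty(
    params: NetworkParams,
    pulse_duration: float = 5.1,
    pause: float = 3.4,
    weight: float = 10.0,
) -> float:
    """Penalty for AN1 activity dying out during a conspecific train.

    AN1 should respond throughout conspecific song, not just at its onset;
    solutions that recognise the song with a purely transient AN1 response
    are physiologically unrealistic.  Operationalised as: AN1's peak in the
    last 100 ms of a 400 ms conspecific train must reach at least 50% of
    its global peak (onset transient excluded); the shortfall, scaled by
    ``weight``, is added to the fitting loss.
    """
    stim = render_pulse_train(
        PulseTrainSpec(
            pulse_duration=pulse_duration,
            pause=pause,
            total_duration=400.0,
            sample_rate=params.sample_rate,
        )
    )
    traces, _ = simulate_network(stim, params)
    t = stim.time_ms
    an1 = traces["AN1"]
    peak = an1[t > 25.0].max()
    if peak <= 0:
        return weight
    late = an1[t > 300.0].max()
    return weight * max(0.0, 0.5 - late / peak)


# ---------------------------------------------------------------------------
# parameter bookkeeping


def _component_free(comp) -> int:
    return len(comp.PARAMS) - len(comp.fixed & set(comp.PARAMS))


def free_parameter_count(params: NetworkParams) -> int:
    """Number of free (fitted) parameters in the network."""
    n = 0
    for spec in params.neurons.values():
        for syn in spec.inputs:
            n += _component_free(syn)
        for stage in spec.stages:
            if isinstance(stage, Filter):
                for lobe in stage.lobes:
                    n += _component_free(lobe)
            else:
                n += _component_free(stage)
    return n - params.n_tied


def free_parameter_items(params: NetworkParams) -> list[tuple[object, str]]:
    """(component, field-name) pairs for every free parameter, in stable order."""
    items: list[tuple[object, str]] = []
    for name in sorted(params.neurons):
        spec = params.neurons[name]
        comps: list[object] = list(spec.inputs)
        for stage in spec.stages:
            if isinstance(stage, Filter):
                comps.extend(stage.lobes)
            else:
                comps.append(stage)
        for comp in comps:
            for pname in comp.PARAMS:
                if pname not in comp.fixed:
                    items.append((comp, pname))
    return items


def get_free_parameters(params: NetworkParams) -> np.ndarray:
    return np.array([getattr(c, p) for c, p in free_parameter_items(params)])


def set_free_parameters(params: NetworkParams, values: np.ndarray) -> None:
    items = free_parameter_items(params)
    if len(items) != len(values):
        raise ValueError("parameter vector length mismatch")
    for (comp, pname), v in zip(items, values):
        setattr(comp, pname, float(v))


# ---------------------------------------------------------------------------
# the fitted Anurogryllus network


def anurogryllus_network(sample_rate: float = 10_000.0) -> NetworkParams:
    """The 5-neuron network with the parameter set fitted to Anurogryllus.

    Conventions not determined by the parameter table are declared here and
    were chosen once, by calibration against the network's documented
    qualitative behaviour (resonant peaks at the song period and twice the
    period, no response at half the period, coincidence-path delay ~25 ms):

    * AN1's slow inhibitory Gaussian lobe is centred at the kernel origin,
      acting as fast opponent inhibition (centred at duration/2 it becomes
      a 146 ms delayed subtraction that silences AN1 mid-train).
    * LN2's inhibitory exponential lobe carries a fixed gain of -0.4
      (chosen so LN2 follows the pulse pattern of conspecific song rather
      than responding only at train onset, matching its physiological role).
    * LN5's differentiated Gaussian has leading-edge polarity (positive
      lobe first), producing one transient per LN2 burst with the path
      timing that reproduces the published effective LN3 input delay.
    * LN5's slow rebound-filter exponential acts positively (it integrates
      the rectified transient into a sustained rebound; with an inhibitory
      sign its magnitude would silence LN5 entirely).
    * The rectifier gain 6.82 shared by LN3's postsynaptic nonlinearity and
      LN4's output nonlinearity is treated as a single tied parameter.
    """
    fixed_thr = frozenset({"threshold"})
    fixed_dur = frozenset({"duration"})
    neurons = {
        "AN1": NeuronSpec(
            name="AN1",
            inputs=(SynapseSpec(source=STIMULUS, delay=2.26, gain=1.0, fixed=frozenset({"gain"})),),
            stages=(
                Filter(
                    lobes=(
                        FilterLobe("gaussian", width_or_tau=3.88, duration=7.59, gain=1.0, fixed=frozenset({"gain"})),
                        FilterLobe("gaussian", width_or_tau=3.81, duration=293.04, gain=-0.87, center=0.0),
                    )
                ),
                Sigmoid(slope=10.33, shift=0.62, gain=1.19, baseline=-0.29),
                AdaptationSpec(tau=9999.93, strength_w=85.75, offset_x0=1.0, fixed=frozenset({"offset_x0"})),
            ),
        ),
        "LN2": NeuronSpec(
            name="LN2",
            inputs=(SynapseSpec(source="AN1", delay=7.59, gain=1.93),),
            stages=(
                Filter(
                    lobes=(
                        FilterLobe("gaussian", width_or_tau=9.76, duration=11.87, gain=0.59),
                        FilterLobe(
                            "exponential", width_or_tau=15.87, duration=1000.0, gain=-0.4,
                            fixed=frozenset({"duration", "gain"}),
                        ),
                    )
                ),
                Relu(threshold=0.0, gain=4.22, fixed=fixed_thr),
            ),
        ),
        "LN5": NeuronSpec(
            name="LN5",
            inputs=(SynapseSpec(source="LN2", delay=13.13, gain=0.43),),
            stages=(
                Filter(lobes=(FilterLobe("differentiated_gaussian", width_or_tau=8.94 / 6.0, duration=8.94, gain=-0.41, fixed=frozenset({"width_or_tau"})),)),
                Relu(threshold=0.0, gain=0.57, fixed=fixed_thr),
                Filter(
                    lobes=(
                        FilterLobe("gaussian", width_or_tau=0.02, duration=5.18, gain=-0.007),
                        FilterLobe("exponential", width_or_tau=17.29, duration=1000.0, gain=6.5, fixed=fixed_dur),
                    )
                ),
                Relu(threshold=0.0, gain=0.006, fixed=fixed_thr),
            ),
        ),
        "LN3": NeuronSpec(
            name="LN3",
            inputs=(
                SynapseSpec(source="AN1", delay=16.59, gain=0.65),
                SynapseSpec(source="LN5", delay=9.67, gain=43.73),
            ),
            stages=(
                Relu(threshold=0.24, gain=6.82),
                AdaptationSpec(tau=1463.98, strength_w=0.16, offset_x0=1.0, fixed=frozenset({"offset_x0"})),
                Relu(threshold=5.1, gain=3.51),
            ),
        ),
        "LN4": NeuronSpec(
            name="LN4",
            inputs=(
                SynapseSpec(source="LN2", delay=11.44, gain=-58.26),
                SynapseSpec(source="LN3", delay=7.15, gain=3.75),
            ),
            stages=(Relu(threshold=-0.003, gain=6.82),),
        ),
    }
    return NetworkParams(neurons=neurons, output="LN4", sample_rate=sample_rate, n_tied=1)
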