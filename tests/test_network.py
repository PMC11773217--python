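import numpy as np
import pytest
from conftest import local_maxima

from songrec.network import (
    AdaptationSpec,
    Filter,
    FilterLobe,
    NetworkConfigError,
    NetworkParams,
    NeuronSpec,
    Relu,
    Sigmoid,
    SynapseSpec,
    an1_sustained_penalty,
    apply_filter,
    divisive_norm,
    effective_ln3_input_delay,
    free_parameter_count,
    get_free_parameters,
    set_free_parameters,
    simulate_network,
    anurogryllus_network,
)
from songrec.stimuli import PulseTrainSpec, render_pulse_train

FS = 10_000.0


def train(pulse, pause, total=400.0, amplitude=1.0):
    return render_pulse_train(
        PulseTrainSpec(pulse, pause, total, amplitude=amplitude, sample_rate=FS)
    )


class TestFilterStage:
    def test_delta_input_returns_the_kernel(self):
        lobe = FilterLobe("gaussian", width_or_tau=1.0, duration=4.0, gain=0.5)
        delta = np.zeros(100)
        delta[0] = 1.0 / (1000.0 / FS)  # unit-area impulse
        out = apply_filter(delta, [lobe], FS)
        np.testing.assert_allclose(out[: lobe.kernel(FS).size], lobe.kernel(FS), atol=1e-9)

    def test_constant_input_through_differentiated_gaussian_vanishes(self):
        lobe = FilterLobe("differentiated_gaussian", width_or_tau=8.94 / 6, duration=8.94, gain=0.41)
        out = apply_filter(np.ones(2000), [lobe], FS)
        assert np.abs(out[500:]).max() < 1e-6  # zero after the transient

    def test_step_through_exponential_lobe_has_closed_form_asymptote(self):
        tau, duration = 15.87, 1000.0
        lobe = FilterLobe("exponential", width_or_tau=tau, duration=duration, gain=-1.0)
        out = apply_filter(np.ones(30_000), [lobe], FS)
        expected = -tau * (1.0 - np.exp(-duration / tau))
        assert out[-1] == pytest.approx(expected, rel=1e-2)

    def test_empty_lobe_list_is_identity(self):
        x = np.sin(np.arange(50) * 0.3)
        np.testing.assert_array_equal(apply_filter(x, [], FS), x)

    def test_sub_sample_lobe_raises(self):
        with pytest.raises(NetworkConfigError):
            FilterLobe("gaussian", 1.0, 0.01, 1.0).kernel(FS)


class TestDivisiveNorm:
    def test_zero_strength_divides_by_offset(self):
        spec = AdaptationSpec(tau=100.0, strength_w=0.0, offset_x0=2.0)
        x = np.linspace(0, 1, 100)
        np.testing.assert_allclose(divisive_norm(x, spec, FS), x / 2.0)

    def test_constant_input_converges_to_fixed_point(self):
        c, w = 3.0, 0.5
        spec = AdaptationSpec(tau=20.0, strength_w=w, offset_x0=1.0)
        out = divisive_norm(np.full(20_000, c), spec, FS)
        assert out[-1] == pytest.approx(c / (1.0 + w * c), rel=1e-3)

    def test_zero_input_gives_zero_output(self):
        spec = AdaptationSpec(tau=20.0, strength_w=0.5)
        assert np.all(divisive_norm(np.zeros(100), spec, FS) == 0.0)

    def test_nonpositive_denominator_raises(self):
        spec = AdaptationSpec(tau=5.0, strength_w=10.0, offset_x0=0.1)
        with pytest.raises(FloatingPointError):
            divisive_norm(np.full(5000, -1.0), spec, FS)


def pure_delay_network(d1, d2):
    """Toy coincidence detector with two pure-delay inputs from the stimulus."""
    neurons = {
        "A": NeuronSpec("A", inputs=(SynapseSpec("stimulus", delay=0.0, gain=1.0),)),
        "C": NeuronSpec(
            "C",
            inputs=(
                SynapseSpec("A", delay=d1, gain=1.0),
                SynapseSpec("A", delay=d2, gain=1.0),
            ),
            stages=(Relu(),),
        ),
    }
    return NetworkParams(neurons=neurons, output="C", sample_rate=FS)


class TestSimulateNetwork:
    def test_zero_stimulus_silences_every_neuron(self):
        net = anurogryllus_network()
        traces, score = simulate_network(train(5.1, 3.4, amplitude=0.0), net)
        for name in ("AN1", "LN2", "LN5", "LN3", "LN4"):
            np.testing.assert_allclose(traces[name], 0.0, atol=1e-12)
        assert score == 0.0

    def test_rectifier_outputs_are_non_negative(self):
        net = anurogryllus_network()
        traces, _ = simulate_network(train(8.6, 8.6), net)
        for name in ("LN2", "LN5", "LN3", "LN4"):
            assert traces[name].min() >= 0.0

    def test_sigmoid_output_is_bounded(self):
        sig = Sigmoid(slope=10.33, shift=0.62, gain=1.19, baseline=-0.29)
        x = np.linspace(-10, 10, 1001)
        out = sig(x, FS)
        rest = sig(np.zeros(1), FS)[0]
        assert rest == 0.0
        assert out.min() >= -0.29 - sig._raw(0.0) - 1e-9
        assert out.max() <= -0.29 + 1.19 - sig._raw(0.0) + 1e-9

    def test_cycle_raises_configuration_error(self):
        neurons = {
            "A": NeuronSpec("A", inputs=(SynapseSpec("B", 1.0, 1.0),)),
            "B": NeuronSpec("B", inputs=(SynapseSpec("A", 1.0, 1.0),)),
        }
        with pytest.raises(NetworkConfigError):
            NetworkParams(neurons=neurons, output="B").topological_order()

    def test_missing_source_raises(self):
        neurons = {"A": NeuronSpec("A", inputs=(SynapseSpec("ghost", 1.0, 1.0),))}
        with pytest.raises(NetworkConfigError):
            NetworkParams(neurons=neurons, output="A").topological_order()


class TestEffectiveDelay:
    def test_identical_pathways_have_zero_lag(self):
        net = pure_delay_network(5.0, 5.0)
        assert effective_ln3_input_delay(net, coincidence_neuron="C") == pytest.approx(0.0)

    def test_pure_delay_difference_is_recovered(self):
        net = pure_delay_network(5.0, 12.0)
        assert effective_ln3_input_delay(net, coincidence_neuron="C") == pytest.approx(7.0, abs=0.2)

    def test_fitted_network_lag_is_close_to_the_rebound_model_delay(self):
        """The coincidence detector's effective input delay matches the
        ~23-25 ms delay of the fitted simple rebound model."""
        lag = effective_ln3_input_delay(anurogryllus_network())
        assert 23.0 <= lag <= 26.0

    def test_flat_drive_raises(self):
        net = pure_delay_network(5.0, 12.0)
        net.neurons["C"].inputs[0].gain = 0.0
        with pytest.raises(NetworkConfigError):
            effective_ln3_input_delay(net, coincidence_neuron="C")


class TestParameters:
    def test_free_parameter_count_is_45(self):
        assert free_parameter_count(anurogryllus_network()) == 45

    def test_get_set_free_parameters_round_trip(self):
        net = anurogryllus_network()
        v = get_free_parameters(net)
        assert v.size == free_parameter_count(net) + net.n_tied
        v2 = v * 1.01
        set_free_parameters(net, v2)
        np.testing.assert_allclose(get_free_parameters(net), v2)


@pytest.fixture(scope="module")
def period_tuning():
    net = anurogryllus_network()
    periods = np.arange(3.0, 24.01, 0.5)
    curves = {}
    for dc in (0.33, 0.5, 0.8):
        vals = [simulate_network(train(dc * T, (1 - dc) * T), net)[1] for T in periods]
        curves[dc] = np.array(vals)
    return periods, curves


class TestQualitativeTuning:
    """Resonant behaviour of the fitted network (period structure)."""

    def test_peaks_near_song_period_and_twice_it(self, period_tuning):
        periods, curves = period_tuning
        best = np.maximum.reduce(list(curves.values()))
        peaks = periods[local_maxima(best, 0.4)]
        assert any(abs(p - 8.5) <= 2.0 for p in peaks), peaks
        assert any(abs(p - 17.2) <= 2.0 for p in peaks), peaks

    def test_no_comparable_response_at_half_the_song_period(self, period_tuning):
        periods, curves = period_tuning
        best = np.maximum.reduce(list(curves.values()))
        near_half = best[(periods >= 3.3) & (periods <= 5.3)].max()
        assert near_half < 0.5 * best.max()


class TestSustainedActivityPenalty:
    def test_sustained_toy_network_is_not_penalised(self):
        neurons = {
            "AN1": NeuronSpec(
                "AN1", inputs=(SynapseSpec("stimulus", delay=0.0, gain=1.0),), stages=(Relu(),)
            ),
            "LN4": NeuronSpec("LN4", inputs=(SynapseSpec("AN1", delay=0.0, gain=1.0),)),
        }
        net = NetworkParams(neurons=neurons, output="LN4", sample_rate=FS)
        assert an1_sustained_penalty(net) == 0.0

    def test_transient_an1_is_penalised(self):
        # a differentiated-Gaussian AN1 responds only at onsets relative to a
        # slow negative lobe that silences it as the train progresses
        neurons = {
            "AN1": NeuronSpec(
                "AN1",
                inputs=(SynapseSpec("stimulus", delay=0.0, gain=1.0),),
                stages=(
                    Filter(
                        lobes=(
                            FilterLobe("gaussian", 2.0, 6.0, 1.0),
                            FilterLobe("exponential", 200.0, 1000.0, -1.0),
                        )
                    ),
                    Relu(),
                ),
            ),
            "LN4": NeuronSpec("LN4", inputs=(SynapseSpec("AN1", delay=0.0, gain=1.0),)),
        }
        net = NetworkParams(neurons=neurons, output="LN4", sample_rate=FS)
        assert an1_sustained_penalty(net) > 0.0
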