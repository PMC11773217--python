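import numpy as np
import pytest
from conftest import local_maxima

from songrec.minimal import (
    AutocorrParams,
    FFIParams,
    ReboundParams,
    autocorr_response,
    autocorr_scores,
    ffi_response,
    ffi_scores,
    predict_phonotaxis,
    rebound_kernel,
    rebound_response,
    rebound_scores,
)
from songrec.stimuli import PulseTrainSpec, StimulusGrid, render_pulse_train


def train(pulse, pause, total=400.0, fs=4000.0, amplitude=1.0):
    return render_pulse_train(
        PulseTrainSpec(pulse, pause, total, amplitude=amplitude, sample_rate=fs)
    )


def transect_grid(points, fs, total=400.0):
    specs = tuple(PulseTrainSpec(d, p, total, sample_rate=fs) for d, p in points)
    return StimulusGrid(specs=specs, step=0.25)


class TestPredictPhonotaxis:
    def test_constant_output_averages_to_itself(self):
        out = np.ones(4000)
        assert predict_phonotaxis(out, 10_000.0) == pytest.approx(1.0)

    def test_zero_output_gives_zero(self):
        assert predict_phonotaxis(np.zeros(4000), 10_000.0) == 0.0

    def test_onset_transient_is_excluded(self):
        out = np.zeros(4000)
        out[:250] = 1.0  # only the first 25 ms
        assert predict_phonotaxis(out, 10_000.0) == 0.0

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            predict_phonotaxis(np.ones(300), 10_000.0)


class TestAutocorrelation:
    def test_tone_gives_gain_after_delay(self):
        p = AutocorrParams()
        tone = train(8.0, 0.0, fs=10_000.0)
        tr = autocorr_response(tone, p)
        t = tr.time_ms
        assert np.all(tr.output[t >= p.delay_ac + 0.1] == pytest.approx(p.gain_ac))
        assert np.all(tr.output[t < p.delay_ac - 0.1] == 0.0)

    def test_period_equal_to_delay_gives_perfect_coincidence(self):
        p = AutocorrParams(delay_ac=17.0, gain_ac=0.21)
        tr = autocorr_response(train(8.5, 8.5, fs=10_000.0), p)
        t = tr.time_ms
        stim = tr.components["stimulus"]
        after = t >= 17.0
        np.testing.assert_allclose(tr.output[after], p.gain_ac * stim[after])

    def test_period_twice_delay_low_dc_gives_zero_overlap(self):
        p = AutocorrParams(delay_ac=17.0)
        tr = autocorr_response(train(8.5, 25.5, fs=10_000.0), p)  # T = 34, DC 25%
        assert np.all(tr.output[tr.time_ms >= 17.0] == 0.0)

    def test_resonance_peaks_match_brute_force_interval_oracle(self):
        """At DC 50% the score peaks at delay/n; checked against an
        interval-arithmetic oracle for the mean pulse-set overlap."""
        p = AutocorrParams(delay_ac=17.0, gain_ac=1.0, sample_rate=10_000.0)
        periods = np.arange(2.0, 25.01, 0.25)
        grid = transect_grid([(T / 2, T / 2) for T in periods], fs=10_000.0)
        scores = autocorr_scores(p, grid)

        def oracle_score(T):
            # mean over the window of s(t)s(t-delay): overlap of the pulse set
            # with itself shifted by delay, computed per period by intervals
            D = T / 2
            shift = p.delay_ac % T
            # overlap length between [0, D) and [shift, shift+D) on the circle
            a = max(0.0, min(D, shift + D) - max(0.0, shift))
            b = max(0.0, min(D, shift + D - T) - 0.0)
            return (a + b) / T

        oracle = np.array([oracle_score(T) for T in periods])
        peaks_model = set(np.round(periods[local_maxima(scores, 0.5)], 2))
        peaks_oracle = set(np.round(periods[local_maxima(oracle, 0.5)], 2))
        # every oracle peak (delay/n) has a model peak within one grid step
        for T in peaks_oracle:
            assert any(abs(T - Tm) <= 0.25 + 1e-9 for Tm in peaks_model)
        for n in (1, 2, 3):
            assert any(abs(17.0 / n - Tm) <= 0.25 + 1e-9 for Tm in peaks_model)

    def test_dc_monotonicity_at_resonant_period(self):
        p = AutocorrParams(delay_ac=17.0)
        dcs = np.arange(0.1, 0.95, 0.05)
        grid = transect_grid([(dc * 17.0, (1 - dc) * 17.0) for dc in dcs], fs=10_000.0)
        scores = autocorr_scores(p, grid)
        assert np.all(np.diff(scores) >= -1e-12)

    def test_output_is_bilinear_in_amplitude_and_gain(self):
        base = autocorr_scores(AutocorrParams(gain_ac=0.21), transect_grid([(4, 4)], 10_000.0))
        double_gain = autocorr_scores(AutocorrParams(gain_ac=0.42), transect_grid([(4, 4)], 10_000.0))
        amp = transect_grid([(4, 4)], 10_000.0)
        amp2 = StimulusGrid(
            specs=(PulseTrainSpec(4, 4, 400, amplitude=2.0, sample_rate=10_000.0),), step=0.25
        )
        double_amp = autocorr_scores(AutocorrParams(gain_ac=0.21), amp2)
        assert double_gain[0] == pytest.approx(2 * base[0])
        assert double_amp[0] == pytest.approx(4 * base[0])  # amplitude enters both paths


class TestReboundKernel:
    def test_lobe_integrals_match_gain_times_duration(self):
        k = rebound_kernel(ReboundParams(), 4000.0)
        dt = 0.25
        n_inh = int(round(5.06 * 4))
        assert k[:n_inh].sum() * dt == pytest.approx(-0.045 * n_inh * dt)
        assert k[:n_inh].sum() * dt == pytest.approx(-0.2277, abs=3e-3)  # Ti quantised to 0.25 ms samples
        assert k[n_inh:].sum() * dt == pytest.approx(0.2000, abs=1e-9)

    def test_kernel_length(self):
        k = rebound_kernel(ReboundParams(), 4000.0)
        assert k.size == round((5.06 + 2.0) * 4)

    def test_zero_inhibitory_gain_silences_the_rebound(self):
        # the positive rebound mass is carried by the gi lobe; without it the
        # filtered signal is never positive and the rectified output vanishes
        p = ReboundParams(inh_gain=0.0)
        tr = rebound_response(train(5.0, 5.0), p)
        assert np.all(tr.components["rebound"] == 0.0)
        assert np.all(tr.output == 0.0)

    def test_sub_sample_duration_raises(self):
        with pytest.raises(ValueError):
            rebound_kernel(ReboundParams(inh_duration=0.01), 4000.0)


class TestReboundResponse:
    def test_zero_stimulus_gives_zero_traces(self):
        tr = rebound_response(train(5.0, 5.0, amplitude=0.0), ReboundParams())
        for name in ("filtered", "rebound", "output"):
            assert np.all(tr.components[name] == 0.0)

    def test_rebound_is_a_transient_at_pulse_offset(self):
        p = ReboundParams()
        tr = rebound_response(train(10.0, 380.0), p)
        t = tr.time_ms
        rb = tr.components["rebound"]
        in_pulse = rb[(t >= 1.0) & (t < 10.0)]
        after = rb[(t >= 10.0) & (t < 25.0)]
        # small positive plateau during the pulse, dominant transient at offset
        assert after.max() > 5 * in_pulse.max()
        t_peak = t[(t >= 10.0) & (t < 25.0)][np.argmax(after)]
        assert t_peak - 10.0 == pytest.approx(p.exc_duration, abs=1.0)

    def test_tone_response_is_reduced_but_non_zero(self):
        p = ReboundParams()
        tone = transect_grid([(8.0, 0.0)], 4000.0)
        pulsed = transect_grid([(5.0, 3.5)], 4000.0)
        s_tone = rebound_scores(p, tone)[0]
        s_pulse = rebound_scores(p, pulsed)[0]
        assert 0 < s_tone < s_pulse
        # plateau value gi*Ti - ge*Te
        assert s_tone == pytest.approx(0.045 * 5.06 - 0.1 * 2.0, abs=5e-3)

    def test_short_pause_truncates_the_rebound(self):
        p = ReboundParams()
        dense = rebound_response(train(8.0, 1.0), p)
        sparse = rebound_response(train(8.0, 10.0), p)
        t = dense.time_ms

        def per_offset_rebound(tr, period):
            rb = tr.components["rebound"]
            # integral of the rebound in the cycle following the first offset
            window = (t >= 8.0) & (t < 8.0 + period)
            return rb[window].sum() * 0.25

        assert per_offset_rebound(dense, 9.0) < per_offset_rebound(sparse, 18.0)

    def test_resonance_law_peaks_near_delay_minus_duration_over_n(self):
        """Period-tuning peaks at fixed pulse duration sit near (delay - D)/n.

        The rebound's finite width shifts the product-overlap optimum
        below the idealised law (by up to ~1.5 ms for n = 1, less for
        higher n), so the tolerance is 1.5 ms.
        """
        p = ReboundParams()
        D = 4.0
        periods = np.arange(4.5, 26.01, 0.25)
        grid = transect_grid([(D, T - D) for T in periods], 4000.0)
        scores = rebound_scores(p, grid)
        peaks = periods[local_maxima(scores, 0.35)]
        for n in (1, 2, 3):
            law = (p.delay_rb - D) / n
            assert any(abs(Tm - law) <= 1.5 for Tm in peaks), (n, law, peaks)

    def test_dc_tuning_at_song_period_is_band_pass(self):
        p = ReboundParams()
        dcs = np.arange(0.1, 0.99, 0.05)
        grid = transect_grid([(dc * 8.6, (1 - dc) * 8.6) for dc in dcs], 4000.0)
        scores = rebound_scores(p, grid)
        i95 = np.argmin(np.abs(dcs - 0.95))
        assert scores[i95] < scores.max()
        assert dcs[np.argmax(scores)] == pytest.approx(0.6, abs=0.15)


class TestFFI:
    def test_zero_ffi_gains_reduce_to_rebound_model(self):
        base = ReboundParams()
        p = FFIParams(ffi_inh_gain=0.0, ffi_exc_gain=0.0, base=base)
        stim = train(5.0, 3.5)
        np.testing.assert_allclose(
            ffi_response(stim, p).output, rebound_response(stim, base).output
        )

    def test_zero_stimulus_gives_zero_output(self):
        tr = ffi_response(train(5.0, 5.0, amplitude=0.0), FFIParams())
        assert np.all(tr.output == 0.0)

    def test_dc_50_suppressed_relative_to_dc_75_at_twice_song_period(self):
        p = FFIParams()
        T = 17.2
        grid50 = transect_grid([(0.5 * T, 0.5 * T)], 4000.0)
        grid75 = transect_grid([(0.75 * T, 0.25 * T)], 4000.0)
        assert ffi_scores(p, grid50)[0] < ffi_scores(p, grid75)[0]

    def test_dc_tuning_at_twice_song_period_prefers_high_dc(self):
        p = FFIParams()
        dcs = np.arange(0.1, 0.96, 0.05)
        grid = transect_grid([(dc * 17.2, (1 - dc) * 17.2) for dc in dcs], 4000.0)
        scores = ffi_scores(p, grid)
        assert scores[dcs > 0.55].max() > scores[dcs < 0.45].max()

    def test_output_is_rectified(self):
        tr = ffi_response(train(8.6, 8.6), FFIParams())
        assert np.all(tr.output >= 0.0)
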