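"""Build rectangular pulse-train stimuli and the standard fitting grid."""

from songrec import PulseTrainSpec, make_fit_grid, render_pulse_train, transect_points

spec = PulseTrainSpec(pulse_duration=5.1, pause=3.4, total_duration=400.0, sample_rate=10_000.0)
train = render_pulse_train(spec)
print(f"conspecific train: period {spec.period:.1f} ms, duty cycle {100 * spec.duty_cycle:.0f}%, "
      f"{train.samples.size} samples, sound fraction {train.samples.mean():.2f}")
# the sound fraction of the rendered trace approaches the duty cycle

grid = make_fit_grid(20.0, 0.5)
print(f"fitting grid: {len(grid)} stimuli on the 0.5 ms pulse x pause lattice up to 20 ms")

pts = transect_points("constant_period", 17.2, (0.0, 17.2), 3)
print("DC transect at the 17.2 ms period (pulse, pause):", [(float(a), float(b)) for a, b in pts.round(1)])
# anti-diagonal stimuli share a period; varying the split varies the duty cycle
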