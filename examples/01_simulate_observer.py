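"""Simulate a single noisy metacognitive observer and inspect its trials.

An observer at 80% expected accuracy with moderate metacognitive noise
(sigma_m = 0.2) performs 1000 binary categorization trials.
"""

import numpy as np

from metanoise import GenerativeParams, sigma_for_accuracy, simulate_session

params = GenerativeParams(mu=1.0, sigma_s=sigma_for_accuracy(0.8), sigma_m=0.2)
trials = simulate_session(params, 1000, np.random.default_rng(0))

print(trials.head())
print(f"\nsigma_s = {params.sigma_s:.3f} -> expected accuracy "
      f"{params.expected_accuracy:.3f}, observed {trials['correct'].mean():.3f}")
print(f"mean confidence | correct:   {trials.loc[trials['correct'], 'confidence'].mean():.3f}")
print(f"mean confidence | incorrect: {trials.loc[~trials['correct'], 'confidence'].mean():.3f}")
# Correct trials attract higher reported confidence; the gap shrinks as
# sigma_m grows and vanishes at sigma_m = 0.5 (uniform random reports).
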