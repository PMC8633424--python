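"""Test-retest reliability of M_ratio as a function of trials per session.

Simulates small cohorts (sigma_m uniform in [0, 0.5], fixed per subject)
at 60% and 80% accuracy and reports the mean Pearson correlation between
two independent sessions. Reliability climbs with trial count and with
type 1 performance; at 60% accuracy and 250 trials it is very poor. At
full scale (100 subjects, >= 10 iterations; see scripts/acceptance.py)
the values stabilize near r = 0.2 for 60%/250 trials and r = 0.8 for
80%/500 trials.
"""

from metanoise import mratio_test_retest

for accuracy in (0.60, 0.80):
    for n_trials in (250, 500):
        r = mratio_test_retest(accuracy, n_trials, n_subjects=60,
                               n_iterations=3, seed=2)
        print(f"accuracy {accuracy:.0%}, {n_trials:>4} trials/session: "
              f"test-retest r = {r:.2f}")
# The same measure can be unusable or solid depending on the design.
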