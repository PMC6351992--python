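"""Fit and apply the linear creation-time model.

Fits ordinary least squares to synthetic timing observations, compares
the coefficients with the reference model, and estimates how long an
803-concept enumeration would take to build versus its 2-concept rule.
"""

import numpy as np

import hierset as hs

rng = np.random.default_rng(0)
counts = rng.integers(2, 300, size=12)
observations = [
    hs.TimingObservation(
        label=f"set-{i}",
        n_concepts=int(n),
        minutes=float(hs.STUDY_TIME_MODEL.slope * n + hs.STUDY_TIME_MODEL.intercept
                      + rng.normal(0, 0.5)),
    )
    for i, n in enumerate(counts)
]

model = hs.fit_time_model(observations)
print(f"fitted: time(min) = {model.slope:.4f} * n + {model.intercept:.4f}")
print(f"reference: time(min) = {hs.STUDY_TIME_MODEL.slope} * n + {hs.STUDY_TIME_MODEL.intercept}")

minutes_ext, rounded_ext = hs.predict_time(hs.STUDY_TIME_MODEL, 803)
minutes_int, rounded_int = hs.predict_time(hs.STUDY_TIME_MODEL, 2)
print(f"estimated build of an 803-concept enumeration: ~{rounded_ext} min")
print(f"estimated build of its 2-concept rule:          ~{rounded_int} min")
comparison = hs.time_comparison(minutes_ext, minutes_int)
print(f"difference {comparison.difference:.1f} min, ratio {comparison.ratio}")

# The intercept is the obligate setup cost of any value set (~4 min);
# the slope (~25 s/concept) is what makes large flat lists expensive.
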