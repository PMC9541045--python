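"""Generate a synthetic running-wheel cohort and inspect its structure.

Builds the default two-group mouse cohort (15 exercised + 15 unexercised
subjects, 4 spectra each) and prints the hierarchical layout plus the
running-distance covariate drawn for the exercised mice.
"""

import numpy as np

import ramanmuscle as rm

cohort, truth = rm.generate_cohort(
    rm.default_config(seed=1), ["unexercised", "exercised"]
)
print(f"cohort: {len(cohort)} spectra from {len(truth.subjects)} subjects")
first = cohort.spectra[0]
print(
    f"grid: {first.wavenumber[0]:.0f}..{first.wavenumber[-1]:.0f} cm^-1, "
    f"{len(first)} points"
)

distances = [t.covariate for t in truth.subjects.values() if t.covariate is not None]
print(
    f"distances run (exercised, km): mean {np.mean(distances):.1f}, "
    f"range {min(distances):.1f}-{max(distances):.1f}"
)
# Each exercised subject's effect magnitude scales with its distance, so
# mice that ran further carry stronger spectral alterations.
strongest = max(
    (t for t in truth.subjects.values() if t.group == "exercised"),
    key=lambda t: t.effect_scale,
)
print(
    f"strongest-effect mouse: {strongest.subject_id} "
    f"(ran {strongest.covariate:.1f} km, effect x{strongest.effect_scale:.2f})"
)
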