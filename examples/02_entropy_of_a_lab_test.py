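"""Entropy of a single lab test after the standard preprocessing chain.

Daily medians -> drop values outside the 1st/99th percentiles -> 20
equal-width bins -> plug-in entropy. With 20 bins the ceiling is
log2(20) = 4.32 bits; a test whose values pile into few bins carries far
less information than one spread across the range.
"""

import math

from icuinfo import (
    apply_binning,
    daily_median,
    day_entropy,
    default_icu_specs,
    fit_binning,
    generate_cohort,
    percentile_filter,
)

specs, config = default_icu_specs(n_patients=2000, seed=7)
obs = generate_cohort(config, specs)

daily = daily_median(obs)
retained, discarded = percentile_filter(daily)
print(f"daily medians: {len(daily)}, retained after percentile trim: {len(retained)}")
print(f"discarded per variable: {discarded.to_dict()}\n")

schemes = fit_binning(retained, n_bins=20)
binned = apply_binning(retained, schemes)

print(f"maximum achievable entropy with 20 bins: {math.log2(20):.2f} bits\n")
print("day-1 entropy per lab test (bits):")
for name in sorted(schemes):
    h, n = day_entropy(binned, name, day=1)
    print(f"  {name:<12s} {h:5.2f}  (n={n}, bin width {schemes[name].bin_width:.3g})")

# Heavily skewed analytes (creatinine, lactate) concentrate in the lowest
# bins and sit well below the 4.32-bit ceiling; near-symmetric ones
# (sodium, hematocrit) come closer to it.
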