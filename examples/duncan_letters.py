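"""Compact letter display for a four-group comparison.

One-way ANOVA plus Duncan's multiple range test on per-plant biomass
replicates; groups sharing a letter are not significantly different
at the 5% level.
"""

import numpy as np

from soilmulch import duncan_mrt, one_way_anova

rng = np.random.default_rng(1)
groups = {
    "newspaper": rng.normal(2000, 300, 12),
    "bran": rng.normal(1450, 300, 12),
    "grass": rng.normal(1300, 300, 12),
    "bare": rng.normal(1100, 300, 12),
}

anova = one_way_anova(groups)
print(f"one-way ANOVA: F = {anova.f_stat:.2f}, p = {anova.p_value:.2e}, "
      f"MS_error = {anova.ms_error:.0f} on {anova.df_error} df")

res = duncan_mrt(groups, alpha=0.05)
print("\ngroup       mean   letters")
for g in sorted(groups, key=lambda g: res.means[g], reverse=True):
    print(f"{g:10} {res.means[g]:7.0f}   {res.letters[g]}")
# 'a' marks the top mean; a shared letter (e.g. bran/grass both 'b')
# means the range test cannot separate those treatments.
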