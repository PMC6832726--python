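"""How many participants does a paired pre/post gait-quality trial need?

Uses the repeated-measures sample-size formula
n = 2*s2_total*(1 - r*s2_bs/s2_total)*(t_{n-1,1-beta} + t_{n-1,1-alpha/2})^2
/ Delta^2 with the effect standardized by the total SD (Delta = d*sqrt(s2_total)),
evaluated over small/medium/large Cohen's d and three assumed pre/post
correlations.
"""

import gaitqual as gq

# published composite-score variance components
s2_bs, s2_ws, s2_e = 0.54700, 0.08068, 0.05759
s2_total = s2_bs + s2_ws + s2_e

n = gq.required_n(s2_total, s2_bs, gq.PowerSpec(d=0.5, r_assumed=0.6))
print(f"medium effect (d=0.5), assumed r=0.6: n = {n} participants")

vc = gq.VarComp("composite", 0.51369, s2_bs, s2_ws, s2_e, s2_total,
                p_week=0.64, pearson_r=0.81, n_subjects=163,
                separable_error=True)
grid = gq.sample_size_grid([vc])
print("\nrequired n over effect size (d) x assumed correlation (r):")
print(grid.to_string())
print("\nn falls as the anticipated effect grows and as pre/post "
      "measurements correlate more strongly.")
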