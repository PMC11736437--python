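"""How C regulation shapes cell-to-cell M/R variability, and what happens
after plasmid loss.

A 500-cell ensemble of the Esp1396I system is simulated for 10 divisions
in regulated and constitutive (matched-median) modes, then plasmids are
removed and molecules dilute through 7 further divisions. Regulation
broadens the M/R distribution several-fold; after loss the robust CV
(IQR/median) stays flat while molecule numbers are high, then rises
sharply -- the statistical signature relevant to post-segregational
killing.
"""

from dataclasses import replace

import numpy as np

from rmdyn.stochastic import calibrate_rates, simulate, summarize

cfg = calibrate_rates(n_cells=500, seed=7)
regulated = simulate(cfg)
constitutive = simulate(replace(cfg, mode="constitutive"))

s_reg = summarize(regulated, 10)
s_con = summarize(constitutive, 10)
print("equilibrium after 10 divisions (median M/R matched by calibration):")
print(f"  regulated:    median M/R = {s_reg.median_mr:.3f}  robust CV = {s_reg.robust_cv_mr:.3f}")
print(f"  constitutive: median M/R = {s_con.median_mr:.3f}  robust CV = {s_con.robust_cv_mr:.3f}")
print(f"  noise amplification by regulation: {s_reg.robust_cv_mr / s_con.robust_cv_mr:.1f}x")

post = simulate(replace(cfg, mode="post_segregational", n_divisions=7), initial=regulated)
print("\npost-segregational dynamics (plasmids removed at division 0):")
print("  division   median R   robust CV of M/R")
for d in range(8):
    s = summarize(post, d)
    print(f"    {d:2d}       {s.median_r:7.0f}     {s.robust_cv_mr:.3f}")
print(
    "\nMedian R halves each division; the M/R robust CV is nearly flat "
    "through division 4 and then climbs steeply as counts become small."
)
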