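"""M-to-R ratio versus expression strength for the three P.M architectures.

The ratio of methyltransferase to endonuclease sets how permeable the cell
is to incoming DNA. Along each stable branch the ratio falls as the
expression strength r rises (more plasmids, or slower growth): cells with
high R-M dosage are better defended, low-dosage cells are more open to
horizontal gene transfer.
"""

import numpy as np

from rmdyn import load_preset, stability_boundary
from rmdyn.pm_models import mr_curve, trend_window

for name, s in (("esp1396i", 0.2), ("ahdi", 0.0043), ("ecorv", 0.2)):
    preset = load_preset(name)
    boundary = stability_boundary(preset.internal)
    lo, hi = trend_window(s, boundary)
    df = mr_curve(s, preset, np.geomspace(lo, hi, 60), boundary=boundary)
    stable = df[df.branch.str.startswith("stable")]
    print(f"\n{name} (s={s}), r in [{lo:.2f}, {hi:.2f}]:")
    for branch, sub in stable.groupby("branch"):
        sub = sub.sort_values("r")
        print(
            f"  {branch:12s} M/R falls {sub.m_over_r.iloc[0]:.3f} -> "
            f"{sub.m_over_r.iloc[-1]:.3f}"
        )
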