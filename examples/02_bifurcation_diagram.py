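"""Bifurcation structure of Esp1396I at low versus high promoter leakage.

At s = 0.02 (below the ~0.05 bistability bound) the steady-state curve
folds: a band of expression strengths r carries two stable states
separated by an unstable one (hysteresis). At s = 0.08 the same system is
monostable for every r.
"""

import numpy as np

from rmdyn import bifurcation_diagram, load_preset, stability_boundary

esp = load_preset("esp1396i")
boundary = stability_boundary(esp.internal)

for s in (0.02, 0.08):
    diagram = bifurcation_diagram(s, esp.internal, np.geomspace(0.5, 20, 60), boundary=boundary)
    print(f"\nleakage s = {s}: fold interval = {diagram.fold_interval}")
    counts = diagram.table.groupby("r").size()
    n_bistable = int((counts == 3).sum())
    print(f"  grid points with three steady states: {n_bistable} / {len(counts)}")
    if diagram.fold_interval:
        lo, hi = diagram.fold_interval
        r_mid = float(np.sqrt(lo * hi))
        rows = diagram.table.iloc[(diagram.table.r - r_mid).abs().argsort()[:3]]
        rows = rows[rows.r == rows.r.iloc[0]].sort_values("c_total")
        print("  states at the middle of the fold interval:")
        for _, row in rows.iterrows():
            print(f"    C_t = {row.c_total:.4f}  ({row.stability})")
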