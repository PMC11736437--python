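"""Steady-state methyltransferase (M) levels for the three P.M architectures
and M-to-R ratio curves along the expression-strength axis.

The M promoter P.M is strongly expressed at system entry and then repressed,
by a mechanism that differs between systems:

* **Esp1396I** -- the C dimer itself represses P.M:
  ``Mt = phi r / (1 + gamma C^2)`` with ``gamma = K_d2 / K_dM``.
* **AhdI** -- M autorepresses: the M monomer dimerizes (dimer-formation
  parameter ``alpha_m``) and the dimer represses P.M, giving the fixed
  point ``Mt = phi r / (1 + M(Mt)^2)``.
* **EcoRV** -- P.M overlaps P.CR divergently and fires only when RNA
  polymerase is not engaged at P.CR, i.e. for the empty and repressed
  C-binding configurations.

Total R tracks total C linearly (co-transcription), so the M-to-R ratio on
every stable branch follows directly from the C steady states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import ExternalParams, SystemPreset
from .pcr_model import free_monomer, r_total
from .stability import (
    StabilityBoundary,
    fold_interval,
    stability_boundary,
    steady_states,
)

__all__ = [
    "MSteadyState",
    "m_esp1396i",
    "m_ahdi",
    "m_ecorv",
    "m_total_for",
    "mr_curve",
    "trend_window",
]


def trend_window(s: float, boundary: StabilityBoundary) -> tuple[float, float]:
    """Standard r-window for the decreasing M-to-R trend around the fold.

    The M/R ratio falls with expression strength throughout the
    bifurcation region but eventually turns back up far above it, where
    promoter leakage dominates R production while P.M repression
    saturates. The figure-scale window on which the decreasing trend is
    asserted is therefore tied to the fold structure: up to 1.2x the upper
    fold r when the leakage admits bistability, or 1.5x the cusp r when
    monostable, starting at 5% of the cusp r in both cases.
    """
    r_cusp = boundary.cusp[0]
    interval = fold_interval(s, boundary)
    upper = 1.2 * interval[1] if interval is not None else 1.5 * r_cusp
    return (0.05 * r_cusp, upper)


@dataclass(frozen=True)
class MSteadyState:
    """Steady-state M level; ``m_free`` only meaningful for AhdI."""

    m_total: float
    architecture: str
    m_free: float | None = None


def m_esp1396i(c_free, r, phi, gamma):
    """C-dimer repression of P.M: ``Mt = phi r / (1 + gamma c_free^2)``."""
    if phi <= 0 or r <= 0:
        raise ValueError("phi and r must be > 0")
    c_free = np.asarray(c_free, dtype=float)
    if np.any(c_free < 0) or gamma < 0:
        raise ValueError("c_free and gamma must be >= 0")
    out = phi * r / (1.0 + gamma * c_free**2)
    return out if out.ndim else float(out)


def m_ahdi(r, phi, alpha_m) -> MSteadyState:
    """M autorepression with monomer-dimer equilibrium.

    Solves ``Mt (1 + M(Mt)^2) = phi r`` where ``M(Mt)`` is the free-monomer
    map with dimer-formation parameter ``alpha_m``. The residual is
    strictly increasing in ``Mt`` (the repressed production is decreasing
    while the identity grows), so a single bracketed root exists in
    [0, phi r]; it is refined by Brent's method to 1e-12.
    """
    if r <= 0 or phi <= 0 or alpha_m <= 0:
        raise ValueError("r, phi and alpha_m must be > 0")
    target = phi * r

    def residual(mt):
        m = free_monomer(mt, alpha_m)
        return mt * (1.0 + m * m) - target

    if target == 0.0:
        mt = 0.0
    else:
        mt = brentq(residual, 0.0, target, xtol=1e-12, rtol=8.9e-16)
    return MSteadyState(m_total=mt, architecture="ahdi", m_free=free_monomer(mt, alpha_m))


def m_ecorv(c_free, r, phi, p, omega):
    """Overlapping-promoter control: P.M active for empty/repressed P.CR.

    ``Mt = phi r (1 + z2 + z3) / (1 + z1 + z2 + z3)`` with the rescaled
    C-binding weights; maximal (phi r) at zero and saturating C, with a
    single interior minimum where P.CR activation peaks.
    """
    if phi <= 0 or r <= 0:
        raise ValueError("phi and r must be > 0")
    c_free = np.asarray(c_free, dtype=float)
    if np.any(c_free < 0):
        raise ValueError("c_free must be >= 0")
    c2 = c_free**2
    rep = (1.0 / p) * c2 + (omega / p) * c2**2
    out = phi * r * (1.0 + rep) / (1.0 + c2 + rep)
    return out if out.ndim else float(out)


def m_total_for(preset: SystemPreset, c_free: float, r: float) -> float:
    """Architecture dispatch: steady-state total M for one C steady state."""
    pm = preset.pm
    if pm.architecture == "esp1396i":
        return float(m_esp1396i(c_free, r, pm.phi, pm.gamma))
    if pm.architecture == "ahdi":
        return m_ahdi(r, pm.phi, pm.alpha_m).m_total
    return float(m_ecorv(c_free, r, pm.phi, preset.internal.p, preset.internal.omega))


def mr_curve(
    s: float,
    preset: SystemPreset,
    r_grid,
    boundary: StabilityBoundary | None = None,
) -> pd.DataFrame:
    """M, R and M/R along every steady-state branch over an r grid.

    Columns: ``r, branch, c_total, m_total, r_total, m_over_r``. When the
    leakage admits bistability the stable branches are labelled coherently
    across the fold interval: ``stable-low`` for the low branch (including
    its monostable continuation below the interval), ``stable-high`` for
    the high branch and its continuation above, ``unstable`` in between;
    for monostable leakage the single branch is labelled ``stable``. The
    ratio is NaN where total R vanishes (C steady state at zero).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r_grid must be positive")
    internal = preset.internal
    boundary = boundary if boundary is not None else stability_boundary(internal)
    interval = fold_interval(s, boundary)
    rows = []
    for r in r_grid:
        sset = steady_states(ExternalParams(s=s, r=r), internal)
        n = len(sset)
        for i, root in enumerate(sset.roots):
            if n >= 3:
                branch = ("stable-low", "unstable", "stable-high")[min(i, 2)]
            elif interval is not None and root.stable:
                branch = "stable-low" if r <= interval[0] else (
                    "stable-high" if r >= interval[1] else "stable"
                )
            else:
                branch = "stable" if root.stable else "unstable"
            ct = root.c_total
            cf = free_monomer(ct, internal.alpha)
            mt = m_total_for(preset, cf, float(r))
            rt = r_total(ct, preset.k_rc)
            ratio = mt / rt if rt > 0 else np.nan
            rows.append((float(r), branch, ct, mt, rt, ratio))
    return pd.DataFrame(
        rows, columns=["r", "branch", "c_total", "m_total", "r_total", "m_over_r"]
    )
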