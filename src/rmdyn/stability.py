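"""Steady states, the analytic fold (saddle-node) boundary, bifurcation
diagrams and the cusp catastrophe surface of the rescaled C dynamics.

The steady states of ``dCt/dtau = s + f(C(Ct)) - Ct/r`` fold at parameter
values where additionally ``d(rhs)/dCt = 0``. Solving the two saddle-node
conditions in closed form for ``r`` and then ``s`` yields the fold locus as
an explicit parametric curve over the steady-state coordinate ``Ct``::

    r(Ct) = 1 / (f'(C) * dC/dCt),      s(Ct) = Ct / r(Ct) - f(C),

admissible wherever ``f' > 0``, i.e. for free monomer ``C < (p/omega)^(1/4)``.
Plotting ``s`` against ``r`` traces the wedge-shaped bistable region in the
(r, s) plane; its tip (the cusp, where the two fold branches meet) sits at
the maximum of ``s`` along the curve and gives the largest leakage that
still admits bistability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import ExternalParams, InternalParams
from .pcr_model import (
    c_dynamics_rhs,
    c_dynamics_rhs_derivative,
    free_monomer,
    free_monomer_derivative,
    regulated_activity,
    regulated_activity_derivative,
    total_from_free,
)

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "StabilityBoundary",
    "BifurcationDiagram",
    "CuspSurface",
    "steady_states",
    "stability_boundary",
    "fold_interval",
    "is_bistable",
    "bifurcation_diagram",
    "cusp_surface",
    "bistable_region_area",
]


@dataclass(frozen=True)
class SteadyState:
    c_total: float
    stable: bool

    @property
    def stability(self) -> str:
        return "stable" if self.stable else "unstable"


@dataclass(frozen=True)
class SteadyStateSet:
    """All steady states at one (r, s), sorted ascending in total C."""

    roots: tuple[SteadyState, ...]
    external: ExternalParams
    internal: InternalParams
    degenerate: bool = False  # root count not in {1, 3}: at/near a fold

    def __len__(self) -> int:
        return len(self.roots)

    @property
    def c_values(self) -> np.ndarray:
        return np.array([r.c_total for r in self.roots])

    @property
    def stable_values(self) -> np.ndarray:
        return np.array([r.c_total for r in self.roots if r.stable])


def steady_states(
    external: ExternalParams,
    internal: InternalParams,
    n_grid: int = 2000,
    dedup_rtol: float = 1e-8,
) -> SteadyStateSet:
    """Find every root of the rescaled C dynamics in [0, r(s+1)].

    Roots are bracketed by sign changes of the rhs over ``n_grid``
    log-spaced points (activity < s+1 bounds all roots by r(s+1)), refined
    by Brent's method to 1e-12, deduplicated, and classified stable when
    the analytic derivative of the rhs is negative.
    """
    r, s = external.r, external.s
    upper = r * (s + 1.0)
    # log-spaced interior grid; include 0 explicitly
    grid = np.concatenate(([0.0], np.geomspace(upper * 1e-12, upper, n_grid)))
    vals = c_dynamics_rhs(grid, external, internal)

    roots: list[float] = []
    if s == 0.0:
        roots.append(0.0)  # rhs(0) = 0 exactly when leakage vanishes
    f = lambda ct: float(c_dynamics_rhs(ct, external, internal))
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0 and a > 0.0:
            roots.append(a)
        elif fa * fb < 0.0:
            roots.append(brentq(f, a, b, xtol=1e-12, rtol=8.9e-16))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    # dedup
    roots.sort()
    dedup: list[float] = []
    for x in roots:
        if not dedup or abs(x - dedup[-1]) > dedup_rtol * max(1.0, abs(dedup[-1])):
            dedup.append(x)

    labelled = tuple(
        SteadyState(
            c_total=x,
            stable=bool(c_dynamics_rhs_derivative(x, external, internal) < 0),
        )
        for x in dedup
    )
    return SteadyStateSet(
        roots=labelled,
        external=external,
        internal=internal,
        degenerate=len(labelled) not in (1, 3),
    )


@dataclass(frozen=True)
class StabilityBoundary:
    """Parametric fold locus (r(Ct), s(Ct)) and the cusp point."""

    internal: InternalParams
    c_total: np.ndarray  # parameter grid (steady-state total C at the fold)
    r_curve: np.ndarray
    s_curve: np.ndarray
    cusp: tuple[float, float, float]  # (r, s, c_total) at the wedge tip
    s_max: float
    cusp_index: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"c_total": self.c_total, "r": self.r_curve, "s": self.s_curve}
        )
        df["is_cusp"] = False
        df.loc[self.cusp_index, "is_cusp"] = True
        return df


def stability_boundary(internal: InternalParams, grid_size: int = 2000) -> StabilityBoundary:
    """Compute the fold boundary parametrically over the admissible range.

    The free monomer at a fold must satisfy ``f'(C) > 0``, i.e.
    ``C < (p/omega)^(1/4)``; the total-C grid is log-spaced from 1e-8 up to
    the total corresponding to 0.999999 of that bound (``r`` diverges at
    both ends, so log spacing resolves the cusp region well).
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    p, omega, alpha = internal.p, internal.omega, internal.alpha
    c_free_max = 0.999999 * (p / omega) ** 0.25
    ct_max = total_from_free(c_free_max, alpha)
    ct = np.geomspace(1e-8, ct_max, grid_size)
    c = free_monomer(ct, alpha)
    fp = regulated_activity_derivative(c, p, omega)
    g = free_monomer_derivative(ct, alpha)
    r = 1.0 / (fp * g)
    s = ct / r - regulated_activity(c, p, omega)
    i = int(np.argmax(s))
    return StabilityBoundary(
        internal=internal,
        c_total=ct,
        r_curve=r,
        s_curve=s,
        cusp=(float(r[i]), float(s[i]), float(ct[i])),
        s_max=float(s[i]),
        cusp_index=i,
    )


def fold_interval(
    s: float, boundary: StabilityBoundary
) -> Optional[tuple[float, float]]:
    """The r-interval of bistability at leakage ``s``, or None if monostable.

    Intersects the horizontal line at ``s`` with the two fold branches on
    either side of the cusp (``s`` is monotone along each branch).
    """
    if s <= 0 or s >= boundary.s_max:
        return None
    i = boundary.cusp_index
    r_at = []
    for sl in (slice(0, i + 1), slice(i, None)):
        sb, rb = boundary.s_curve[sl], boundary.r_curve[sl]
        order = np.argsort(sb)
        sb, rb = sb[order], rb[order]
        if s < sb[0] or s > sb[-1]:
            return None
        r_at.append(float(np.interp(s, sb, rb)))
    lo, hi = min(r_at), max(r_at)
    return (lo, hi) if hi > lo else None


def is_bistable(r: float, s: float, boundary: StabilityBoundary) -> bool:
    """Whether (r, s) lies strictly inside the bistable wedge."""
    iv = fold_interval(s, boundary)
    return iv is not None and iv[0] < r < iv[1]


@dataclass(frozen=True)
class BifurcationDiagram:
    """Steady-state branches versus r at fixed leakage s."""

    s: float
    internal: InternalParams
    table: pd.DataFrame  # columns: r, c_total, stability
    fold_interval: Optional[tuple[float, float]]


def bifurcation_diagram(
    s: float,
    internal: InternalParams,
    r_grid,
    boundary: Optional[StabilityBoundary] = None,
) -> BifurcationDiagram:
    """Root sets per r at fixed leakage, with the fold interval attached."""
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be positive and strictly increasing")
    boundary = boundary if boundary is not None else stability_boundary(internal)
    rows = []
    for r in r_grid:
        sset = steady_states(ExternalParams(s=s, r=r), internal)
        for root in sset.roots:
            rows.append((r, root.c_total, root.stability))
    return BifurcationDiagram(
        s=s,
        internal=internal,
        table=pd.DataFrame(rows, columns=["r", "c_total", "stability"]),
        fold_interval=fold_interval(s, boundary),
    )


@dataclass(frozen=True)
class CuspSurface:
    """Up to three steady-state sheets over an (r, s) grid.

    ``sheets`` has shape (3, len(s_grid), len(r_grid)): index 0 is the low
    stable sheet, 1 the unstable connector, 2 the high stable sheet; NaN
    where a sheet does not exist. Monostable cells populate exactly one
    stable sheet (low or high, split at the cusp total-C level).
    """

    internal: InternalParams
    r_grid: np.ndarray
    s_grid: np.ndarray
    sheets: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        names = ["low_stable", "unstable", "high_stable"]
        rows = []
        for j, s in enumerate(self.s_grid):
            for k, r in enumerate(self.r_grid):
                for i, name in enumerate(names):
                    v = self.sheets[i, j, k]
                    if np.isfinite(v):
                        rows.append((r, s, name, v))
        return pd.DataFrame(rows, columns=["r", "s", "sheet", "c_total"])


def cusp_surface(
    internal: InternalParams,
    r_grid,
    s_grid,
    boundary: Optional[StabilityBoundary] = None,
) -> CuspSurface:
    """Assemble the folded steady-state surface over an (r, s) grid."""
    r_grid = np.asarray(r_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(s_grid < 0):
        raise ValueError("grids must be positive (s may include 0)")
    boundary = boundary if boundary is not None else stability_boundary(internal)
    c_cusp = boundary.cusp[2]
    sheets = np.full((3, len(s_grid), len(r_grid)), np.nan)
    for j, s in enumerate(s_grid):
        for k, r in enumerate(r_grid):
            sset = steady_states(ExternalParams(s=s, r=r), internal)
            if len(sset) >= 3:
                c = sset.c_values
                sheets[0, j, k] = c[0]
                sheets[1, j, k] = c[1]
                sheets[2, j, k] = c[-1]
            elif len(sset) >= 1:
                c = float(sset.c_values[0])
                sheets[0 if c <= c_cusp else 2, j, k] = c
    return CuspSurface(internal=internal, r_grid=r_grid, s_grid=s_grid, sheets=sheets)


def bistable_region_area(
    internal: InternalParams,
    r_max: float,
    boundary: Optional[StabilityBoundary] = None,
    n_s: int = 2000,
) -> float:
    """Area of the bistable wedge clipped to the window [0, r_max] x [0, 1].

    The wedge is unbounded in r, so a finite window is required; the area
    is the integral over s of the clipped fold-interval width.
    """
    if not np.isfinite(r_max) or r_max <= 0:
        raise ValueError("r_max must be positive and finite")
    boundary = boundary if boundary is not None else stability_boundary(internal)
    if r_max <= boundary.cusp[0]:
        warnings.warn(
            "r_max does not reach the cusp; clipped bistable area is zero",
            stacklevel=2,
        )
        return 0.0
    s_vals = np.linspace(0.0, min(boundary.s_max, 1.0), n_s + 1)[1:-1]
    widths = np.zeros_like(s_vals)
    for i, s in enumerate(s_vals):
        iv = fold_interval(float(s), boundary)
        if iv is not None:
            lo, hi = min(iv[0], r_max), min(iv[1], r_max)
            widths[i] = max(0.0, hi - lo)
    return float(np.trapezoid(widths, s_vals))
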