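"""Inference of the promoter leakage ``s`` (and nuisance scales) from
expression measurements, plus the synthetic fixture generator used to test
recovery.

Three kinds of data constrain the leakage:

* **activity curves** -- P.CR activity versus C amount; activity is
  ``A * (s + f(C))`` for an overall scale ``A``, so ``s`` enters as the
  basal offset relative to the regulated amplitude;
* **expression time series** -- total R versus time during system
  establishment from zero; the early rise is leakage-driven, so fitting
  the rescaled production-dilution dynamics recovers ``s`` along with an
  amplitude and a time scale;
* **steady-state levels versus plasmid copy number** -- R and M steady
  states across copy-number conditions; the leakage determines how the
  M-to-R ratio bends with expression strength.

All fits are unit-invariant: rescaling data amplitudes rescales only the
amplitude estimate, never ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize_scalar

from .params import ExternalParams, InternalParams, SystemPreset, load_preset
from .pcr_model import (
    c_dynamics_rhs,
    free_monomer,
    pcr_activity,
    r_total,
    regulated_activity,
)
from .pm_models import m_total_for
from .stability import fold_interval, stability_boundary, steady_states

__all__ = [
    "ActivityDataset",
    "TimeSeriesDataset",
    "SteadyStateVsCopyNumber",
    "FitResult",
    "generate_fixture",
    "fit_s_from_activity",
    "fit_s_from_dynamics",
    "fit_steady_state_scales",
    "simulate_dynamics",
]


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class ActivityDataset:
    """Promoter-activity-versus-C records in rescaled units.

    ``c_kind`` says whether the C column holds total or free monomer
    amounts (total amounts are mapped through the monomer-dimer
    equilibrium before evaluating the activity).
    """

    c: np.ndarray
    activity: np.ndarray
    c_kind: str = "total"  # "total" | "free"
    weight: Optional[np.ndarray] = None

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "activity", a)
        if self.c_kind not in ("total", "free"):
            raise ValueError("c_kind must be 'total' or 'free'")
        if c.size < 4:
            raise ValueError("activity dataset needs >= 4 records")
        if np.any(a < 0) or np.any(c < 0):
            raise ValueError("activities and C amounts must be >= 0")


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Total-R-versus-time records with the known expression strength."""

    time: np.ndarray
    r_amount: np.ndarray
    r_strength: float  # external parameter r during the measurement
    internal: InternalParams = field(
        default_factory=lambda: load_preset("esp1396i").internal
    )

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.r_amount, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "r_amount", y)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("R amounts must be >= 0")
        if self.r_strength <= 0:
            raise ValueError("r_strength must be > 0")


@dataclass(frozen=True)
class SteadyStateVsCopyNumber:
    """Steady-state R and M levels at several plasmid copy numbers."""

    copy_number: np.ndarray
    r_level: np.ndarray
    m_level: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.copy_number, dtype=float)
        r = np.asarray(self.r_level, dtype=float)
        m = np.asarray(self.m_level, dtype=float)
        for name, v in (("copy_number", n), ("r_level", r), ("m_level", m)):
            object.__setattr__(self, name, v)
        if np.unique(n).size < 3:
            raise ValueError("need >= 3 distinct copy-number conditions")
        if np.any(n <= 0) or np.any(r < 0) or np.any(m < 0):
            raise ValueError("copy numbers must be > 0 and levels >= 0")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    residual_norm: float
    converged: bool
    bounds: dict[str, tuple[float, float]]
    notes: str = ""


# ---------------------------------------------------------------------------
# forward models


def simulate_dynamics(s, r, internal: InternalParams, tau, c0=0.0):
    """Integrate the rescaled total-C dynamics on the grid ``tau``.

    Adaptive stiff-capable integration (LSODA, rtol 1e-8, atol 1e-10)
    from ``Ct(0) = c0``; returns total C at the requested times.
    """
    tau = np.asarray(tau, dtype=float)
    ext = ExternalParams(s=s, r=r)
    sol = solve_ivp(
        lambda t, y: [float(c_dynamics_rhs(max(y[0], 0.0), ext, internal))],
        (0.0, float(tau[-1])),
        [float(c0)],
        t_eval=tau,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message} (s={s}, r={r})")
    return np.clip(sol.y[0], 0.0, None)


def _lognormal_factors(rng, noise_level, size):
    """Mean-one multiplicative noise with coefficient of variation ``noise_level``."""
    if noise_level == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(noise_level**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_fixture(kind, truth: dict, noise_level=0.0, n_points=20, seed=0):
    """Forward-simulate a calibration dataset with multiplicative noise.

    ``kind`` selects the dataset: ``activity`` (truth keys: internal, s,
    amplitude, c_max), ``timeseries`` (internal, s, r, amplitude,
    t_scale, t_max), or ``steady_vs_n`` (preset, s, n_scale, r_amplitude,
    m_amplitude, copy_numbers). Noise is mean-one log-normal with CV
    ``noise_level``; output is deterministic given ``seed``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    if kind == "activity":
        internal: InternalParams = truth["internal"]
        s, amp = truth["s"], truth.get("amplitude", 1.0)
        c_max = truth.get("c_max", 10.0)
        ct = np.linspace(c_max / n_points, c_max, n_points)
        cf = free_monomer(ct, internal.alpha)
        y = amp * pcr_activity(cf, s, internal.p, internal.omega)
        y = y * _lognormal_factors(rng, noise_level, y.shape)
        return ActivityDataset(c=ct, activity=y, c_kind="total")
    if kind == "timeseries":
        internal = truth["internal"]
        s, r = truth["s"], truth.get("r", 2.0)
        amp, t_scale = truth.get("amplitude", 1.0), truth.get("t_scale", 1.0)
        # establishment time course: geometric grid (denser early sampling
        # resolves the leakage-driven onset) out to four relaxation times
        t_max = truth.get("t_max", 4.0 * t_scale * r)
        t = np.geomspace(t_max / 80.0, t_max, n_points)
        ct = simulate_dynamics(s, r, internal, t / t_scale)
        y = amp * ct * _lognormal_factors(rng, noise_level, ct.shape)
        return TimeSeriesDataset(time=t, r_amount=y, r_strength=r, internal=internal)
    if kind == "steady_vs_n":
        preset: SystemPreset = truth["preset"]
        s = truth["s"]
        n_scale = truth.get("n_scale", 1.0)
        amp_r, amp_m = truth.get("r_amplitude", 1.0), truth.get("m_amplitude", 1.0)
        ns = np.asarray(
            truth.get("copy_numbers", np.linspace(5, 60, max(n_points, 3)))
        )
        r_pred, m_pred = _steady_levels(preset, s, n_scale * ns)
        noise_r = _lognormal_factors(rng, noise_level, ns.shape)
        noise_m = _lognormal_factors(rng, noise_level, ns.shape)
        return SteadyStateVsCopyNumber(
            copy_number=ns,
            r_level=amp_r * r_pred * noise_r,
            m_level=amp_m * m_pred * noise_m,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


def _steady_levels(preset: SystemPreset, s, r_values, branch="low"):
    """Deterministic (R, M) steady states along one stable branch.

    In the bistable band the requested branch ('low' or 'high') is taken;
    in monostable regions the unique stable root is used.
    """
    r_out, m_out = [], []
    for r in np.asarray(r_values, dtype=float):
        sset = steady_states(ExternalParams(s=float(s), r=float(r)), preset.internal)
        stable = sorted(root.c_total for root in sset.roots if root.stable)
        ct = stable[0] if (branch == "low" or len(stable) == 1) else stable[-1]
        cf = free_monomer(ct, preset.internal.alpha)
        r_out.append(r_total(ct, preset.k_rc))
        m_out.append(m_total_for(preset, cf, float(r)))
    return np.asarray(r_out), np.asarray(m_out)


# ---------------------------------------------------------------------------
# fits


def fit_s_from_activity(data: ActivityDataset, internal: InternalParams) -> FitResult:
    """Least-squares fit of ``activity = A (s + f(C))`` over (A, s).

    The model is linear in (A*s, A): solved by linear least squares on
    the design [1, f(C)], then clipped to s in [0, 1] (with a bounded
    nonlinear refit if the unconstrained solution falls outside).
    """
    if data.c.size < 2:
        raise ValueError("underdetermined: need more points than parameters")
    cf = (
        free_monomer(data.c, internal.alpha) if data.c_kind == "total" else data.c
    )
    f = regulated_activity(cf, internal.p, internal.omega)
    w = np.ones_like(f) if data.weight is None else np.asarray(data.weight, float)
    design = np.column_stack([w, w * f])
    coef, *_ = np.linalg.lstsq(design, w * data.activity, rcond=None)
    b0, a = coef
    if a > 0 and 0.0 <= b0 / a <= 1.0:
        s_hat, a_hat = b0 / a, a
    else:  # basal offset outside [0, 1]: refit with bounds
        res = least_squares(
            lambda th: w * (th[1] * (th[0] + f) - data.activity),
            x0=[0.01, max(a, 1e-6)],
            bounds=([0.0, 1e-12], [1.0, np.inf]),
        )
        s_hat, a_hat = res.x
    resid = w * (a_hat * (s_hat + f) - data.activity)
    return FitResult(
        estimates={"s": float(s_hat), "amplitude": float(a_hat)},
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        bounds={"s": (0.0, 1.0), "amplitude": (0.0, np.inf)},
    )


def fit_s_from_dynamics(
    data: TimeSeriesDataset,
    internal: Optional[InternalParams] = None,
    n_starts: int = 8,
    late_fraction: float = 0.6,
) -> FitResult:
    """Fit (s, amplitude, time scale) of the establishment dynamics to R(t).

    Integrates the rescaled production-dilution dynamics from zero initial
    C and matches ``amplitude * Ct(t / t_scale)`` to the measured R. Only
    the last ``late_fraction`` of the time points enter the objective
    (later points carry more molecules, hence less relative background
    and counting noise). Multi-start over log-spaced s values guards
    against the fold-induced nonconvexity of the objective.
    """
    internal = internal if internal is not None else data.internal
    t, y = data.time, data.r_amount
    n_late = max(int(np.ceil(late_fraction * t.size)), 3)
    sel = slice(t.size - n_late, t.size)
    y_sel = y[sel]

    # rough scales for initialisation
    t_scale0 = t[-1] / (3.0 * data.r_strength)

    def residual(theta):
        log_s, log_amp, log_ts = theta
        s = np.exp(log_s)
        if s > 1.0:
            s = 1.0
        ct = simulate_dynamics(s, data.r_strength, internal, t / np.exp(log_ts))
        return np.exp(log_amp) * ct[sel] - y_sel

    best = None
    for s0 in np.geomspace(1e-3, 0.9, n_starts):
        ct0 = simulate_dynamics(s0, data.r_strength, internal, t / t_scale0)
        amp0 = max(np.median(y_sel) / max(np.median(ct0[sel]), 1e-12), 1e-12)
        try:
            res = least_squares(
                residual,
                x0=[np.log(s0), np.log(amp0), np.log(t_scale0)],
                bounds=(
                    [np.log(1e-6), -np.inf, -np.inf],
                    [0.0, np.inf, np.inf],
                ),
                xtol=1e-12,
                ftol=1e-12,
            )
        except RuntimeError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("dynamics fit failed from every start")
    s_hat, amp_hat, ts_hat = np.exp(best.x)
    return FitResult(
        estimates={
            "s": float(min(s_hat, 1.0)),
            "amplitude": float(amp_hat),
            "t_scale": float(ts_hat),
        },
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
        bounds={"s": (1e-6, 1.0)},
        notes=f"late_fraction={late_fraction}, n_starts={n_starts}",
    )


def fit_steady_state_scales(
    data: SteadyStateVsCopyNumber,
    preset: SystemPreset,
    n_s_grid: int = 25,
) -> FitResult:
    """Fit (s, n-scale, R amplitude, M amplitude) to steady levels vs copy number.

    Grid search over s (log-spaced in [0.001, 1]) with, at each s, a 1-D
    optimisation of the copy-number-to-r scale; the two amplitudes are
    profiled out in closed form. The best grid point is polished by a
    local bounded refinement of (s, n_scale). Reports whether the fitted
    s lies in the bistable band of the preset and, if so, which stable
    branch was used.
    """
    if np.unique(data.copy_number).size < 3:
        raise ValueError("underdetermined: need >= 3 distinct copy numbers")
    boundary = stability_boundary(preset.internal)
    ns = data.copy_number
    y_r, y_m = data.r_level, data.m_level

    def profiled_cost(s, n_scale, branch):
        r_pred, m_pred = _steady_levels(preset, s, n_scale * ns, branch)
        a_r = (y_r @ r_pred) / max(r_pred @ r_pred, 1e-300)
        a_m = (y_m @ m_pred) / max(m_pred @ m_pred, 1e-300)
        cost = np.sum((a_r * r_pred - y_r) ** 2) + np.sum((a_m * m_pred - y_m) ** 2)
        return cost, a_r, a_m

    def best_nscale(s, branch):
        res = minimize_scalar(
            lambda log_c: profiled_cost(s, np.exp(log_c), branch)[0],
            bounds=(np.log(1e-3), np.log(1e3)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return np.exp(res.x), res.fun

    best = None
    for s in np.geomspace(1e-3, 1.0, n_s_grid):
        branches = ["low"]
        if fold_interval(float(s), boundary) is not None:
            branches.append("high")
        for br in branches:
            n_scale, cost = best_nscale(float(s), br)
            if best is None or cost < best[0]:
                best = (cost, float(s), n_scale, br)
    _, s0, c0, br0 = best

    # local polish of (s, n_scale) around the best grid point
    res = least_squares(
        lambda th: _polish_residual(th, preset, ns, y_r, y_m, br0),
        x0=[np.log(s0), np.log(c0)],
        bounds=([np.log(1e-4), np.log(1e-4)], [0.0, np.log(1e4)]),
        xtol=1e-12,
        ftol=1e-14,
        diff_step=1e-5,
    )
    s_hat, c_hat = np.exp(res.x)
    cost, a_r, a_m = profiled_cost(s_hat, c_hat, br0)
    bistable = fold_interval(float(s_hat), boundary) is not None
    return FitResult(
        estimates={
            "s": float(s_hat),
            "n_scale": float(c_hat),
            "r_amplitude": float(a_r),
            "m_amplitude": float(a_m),
        },
        residual_norm=float(np.sqrt(cost)),
        converged=bool(res.success),
        bounds={"s": (1e-4, 1.0), "n_scale": (1e-4, 1e4)},
        notes=f"regime={'bistable' if bistable else 'monostable'}, branch={br0}",
    )


def _polish_residual(theta, preset, ns, y_r, y_m, branch):
    s, n_scale = np.exp(theta)
    r_pred, m_pred = _steady_levels(preset, min(s, 1.0), n_scale * ns, branch)
    a_r = (y_r @ r_pred) / max(r_pred @ r_pred, 1e-300)
    a_m = (y_m @ m_pred) / max(m_pred @ m_pred, 1e-300)
    return np.concatenate([a_r * r_pred - y_r, a_m * m_pred - y_m])
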