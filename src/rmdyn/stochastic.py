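"""Monte-Carlo simulation of single-cell R-M dynamics across cell divisions.

Three modes are simulated over an ensemble of cells:

* **regulated** -- C, R and M are produced from ``n`` plasmids with the
  full transcriptional regulation: the C (and co-transcribed R) channel
  fires at ``n * (phi_l + phi_m * f(C_free/K_d))`` with the free monomer
  from the count-unit dimerization equilibrium, and the M channel at
  ``n * phi_M / (1 + D/K_dM)`` with ``D`` the C-dimer count (C-dimer
  repression of P.M);
* **constitutive** -- the same channels with constant per-plasmid rates
  calibrated to reproduce the regulated equilibrium levels, isolating the
  generic (partitioning + production) noise floor;
* **post_segregational** -- plasmids removed at time zero; molecules only
  dilute by random partitioning at each division.

Time is measured in cell-division units; divisions are deterministic, one
per unit time. At a division, plasmids replicate to ``2n`` and partition
binomially; each molecular species partitions ``Binomial(count, 1/2)``
independently. There is no degradation channel: stable proteins dilute
through division only. Between divisions the simulation is exact: rates
change only at C-production events, so waiting times are exponential and
R/M production over a cycle is Poisson with the integrated intensity.

Ensemble statistics for the M-to-R ratio use the median and the
interquartile range (robust CV = IQR/median) alongside the plain CV,
because the regulated ratio distribution is strongly non-Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import ExternalParams, SystemPreset, load_preset
from .pcr_model import regulated_activity
from .stability import steady_states

__all__ = [
    "StochasticConfig",
    "Ensemble",
    "EnsembleSummary",
    "calibrate_rates",
    "deterministic_reference",
    "simulate",
    "summarize",
    "summarize_all",
    "equilibrium_check",
]

MODES = ("constitutive", "regulated", "post_segregational")


@dataclass(frozen=True)
class StochasticConfig:
    """Absolute-unit simulation parameters (molecules per cell, division-time units).

    ``phi_l_abs``/``phi_m_abs``/``phi_M_abs`` are per-plasmid production
    rates; ``kd1_n``/``kd2_n``/``kd_m_n`` are dissociation constants in
    molecule-count units (fixed effective cell volume); ``p``/``omega``
    are the dimensionless binding parameters of the P.CR model;
    ``const_*`` are the per-plasmid constitutive rates used in
    constitutive mode. ``seed`` is mandatory.
    """

    mode: str
    seed: int
    phi_l_abs: float
    phi_m_abs: float
    phi_M_abs: float
    k_rc: float
    kd1_n: float
    kd2_n: float
    kd_m_n: float
    p: float
    omega: float
    n_target: int = 30
    n_cells: int = 2000
    n_divisions: int = 10
    cotranscribe: bool = False
    const_c: float = 0.0
    const_r: float = 0.0
    const_m: float = 0.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic simulation")
        for name in ("phi_l_abs", "phi_m_abs", "phi_M_abs", "const_c", "const_r", "const_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("k_rc", "kd1_n", "kd2_n", "kd_m_n", "p", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 1 or self.n_divisions < 1 or self.n_target < 0:
            raise ValueError("n_cells, n_divisions must be >= 1 and n_target >= 0")

    @property
    def kd_n(self) -> float:
        return math.sqrt(self.kd1_n * self.kd2_n)


@dataclass(frozen=True)
class Ensemble:
    """Trajectories sampled at division boundaries.

    Arrays have shape ``(n_cells, n_divisions + 1)``. For the growth modes
    column ``d >= 1`` holds the state just before the d-th division (end of
    cycle d) and column 0 the initial (start-of-cycle) state; for the
    post-segregational mode column ``d`` holds the state after the d-th
    halving, column 0 the initial equilibrium state.
    """

    config: StochasticConfig
    n: np.ndarray
    c: np.ndarray
    r_mol: np.ndarray
    m_mol: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.n.shape[0]

    @property
    def n_divisions(self) -> int:
        return self.n.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        cells, cols = self.n.shape
        cell_id = np.repeat(np.arange(cells), cols)
        division = np.tile(np.arange(cols), cells)
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "division": division,
                "n": self.n.ravel(),
                "c": self.c.ravel(),
                "r": self.r_mol.ravel(),
                "m": self.m_mol.ravel(),
            }
        )


@dataclass(frozen=True)
class EnsembleSummary:
    """Robust ensemble statistics of the M-to-R ratio at one division."""

    division: int
    median_mr: float
    iqr_mr: float
    cv_mr: float
    robust_cv_mr: float
    median_r: float
    n_excluded: int
    n_retained: int
    defined: bool = True


# ---------------------------------------------------------------------------
# deterministic cycle map (calibration + equilibrium reference)


def _cycle_rhs(c_count, n, cfg: StochasticConfig):
    """Per-cell deterministic C production rate (count units)."""
    cf = 2.0 * c_count / (1.0 + math.sqrt(1.0 + 8.0 * c_count / cfg.kd1_n))
    act = cfg.phi_l_abs + cfg.phi_m_abs * regulated_activity(cf / cfg.kd_n, cfg.p, cfg.omega)
    return n * act


def _m_rate(c_count, n, cfg: StochasticConfig, phi_M=None):
    cf = 2.0 * c_count / (1.0 + math.sqrt(1.0 + 8.0 * c_count / cfg.kd1_n))
    dimer = cf * cf / cfg.kd1_n
    phi_M = cfg.phi_M_abs if phi_M is None else phi_M
    return n * phi_M / (1.0 + dimer / cfg.kd_m_n)


def _integrate_cycle(c0, n, cfg: StochasticConfig):
    """One division cycle of the deterministic model.

    Returns (C at end of cycle, integral of the per-cycle C rate -- equal
    to the C produced, integral of the M rate at unit phi_M).
    """

    def rhs(t, y):
        rate_c = _cycle_rhs(y[0], n, cfg)
        return [rate_c, _m_rate(y[0], n, cfg, phi_M=1.0)]

    sol = solve_ivp(rhs, (0.0, 1.0), [float(c0), 0.0], method="LSODA", rtol=1e-9, atol=1e-9)
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")
    return float(sol.y[0, -1]), float(sol.y[0, -1] - c0), float(sol.y[1, -1])


def _cycle_fixed_point(cfg: StochasticConfig, n=None, n_iter=60, tol=1e-10):
    """End-of-cycle C at the periodic (production/halving) steady state."""
    n = cfg.n_target if n is None else n
    c_end = 2.0 * _cycle_rhs(0.0, n, cfg)  # crude start
    for _ in range(n_iter):
        new_end, _, _ = _integrate_cycle(c_end / 2.0, n, cfg)
        if abs(new_end - c_end) <= tol * max(1.0, c_end):
            c_end = new_end
            break
        c_end = new_end
    return c_end


def calibrate_rates(
    preset: Optional[SystemPreset] = None,
    s: float = 0.2,
    c_target: float = 800.0,
    r_target: float = 1600.0,
    m_target: float = 400.0,
    n_target: int = 30,
    r_operating: float = 15.0,
    n_cells: int = 2000,
    n_divisions: int = 10,
    seed: int = 0,
    mode: str = "regulated",
) -> StochasticConfig:
    """Build a simulation config whose equilibrium matches target medians.

    The rescaled deterministic steady state at ``(r_operating, s)`` fixes
    the count-unit dissociation constant ``K_d`` so that the target total
    C sits at the same rescaled operating point; ``phi_m_abs`` is then
    refined by a 1-D bracketed search so the deterministic division-cycle
    fixed point hits ``c_target`` exactly (end-of-cycle, before halving).
    ``k_rc`` and ``phi_M_abs`` follow in closed form (R tracks C; M is
    linear in its rate). Constitutive per-plasmid rates reproduce the
    same end-of-cycle levels (production P per cycle gives a stationary
    mean 2P at division boundaries).
    """
    preset = preset if preset is not None else load_preset("esp1396i")
    internal = preset.internal
    gamma = preset.pm.gamma if preset.pm.gamma is not None else 5.1
    sset = steady_states(ExternalParams(s=s, r=r_operating), internal)
    ct_star = float(sorted(st.c_total for st in sset.roots if st.stable)[0])
    kd_n = c_target / ct_star
    kd1_n = internal.alpha * kd_n
    kd2_n = kd_n / internal.alpha
    kd_m_n = kd2_n / gamma

    lam = math.log(2.0)
    phi_m0 = r_operating * lam * kd_n / n_target  # continuous-dilution estimate

    def gap(log_phi_m):
        phi_m = math.exp(log_phi_m)
        cfg = StochasticConfig(
            mode="regulated",
            seed=seed,
            phi_l_abs=s * phi_m,
            phi_m_abs=phi_m,
            phi_M_abs=1.0,
            k_rc=1.0,
            kd1_n=kd1_n,
            kd2_n=kd2_n,
            kd_m_n=kd_m_n,
            p=internal.p,
            omega=internal.omega,
            n_target=n_target,
        )
        return _cycle_fixed_point(cfg) - c_target

    lo, hi = math.log(phi_m0) - 1.5, math.log(phi_m0) + 1.5
    phi_m = math.exp(brentq(gap, lo, hi, xtol=1e-10))

    cfg = StochasticConfig(
        mode="regulated",
        seed=seed,
        phi_l_abs=s * phi_m,
        phi_m_abs=phi_m,
        phi_M_abs=1.0,
        k_rc=r_target / c_target,
        kd1_n=kd1_n,
        kd2_n=kd2_n,
        kd_m_n=kd_m_n,
        p=internal.p,
        omega=internal.omega,
        n_target=n_target,
        n_cells=n_cells,
        n_divisions=n_divisions,
    )
    # phi_M from the equilibrium cycle: end-of-cycle M = 2 * phi_M * integral
    c_end = _cycle_fixed_point(cfg)
    _, _, m_integral = _integrate_cycle(c_end / 2.0, n_target, cfg)
    phi_M = m_target / (2.0 * m_integral)
    cfg = replace(
        cfg,
        phi_M_abs=phi_M,
        # constitutive per-plasmid rates: stationary end-of-cycle mean is
        # twice the per-cycle production
        const_c=c_target / (2.0 * n_target),
        const_r=r_target / (2.0 * n_target),
        const_m=m_target / (2.0 * n_target),
        mode=mode,
    )
    return cfg


def deterministic_reference(
    cfg: StochasticConfig, n_divisions: Optional[int] = None, from_zero: bool = False
) -> pd.DataFrame:
    """Deterministic end-of-cycle (C, R, M) per division for the regulated model.

    Starting either from the periodic steady state (default) or from an
    empty cell; plasmid number fixed at ``n_target`` (the deterministic
    analogue has no partitioning noise). Columns: division, c, r, m.
    """
    n_div = cfg.n_divisions if n_divisions is None else n_divisions
    n = cfg.n_target
    if from_zero:
        c = r = m = 0.0
    else:
        c_end = _cycle_fixed_point(cfg)
        c = c_end / 2.0
        _, dc, mi = _integrate_cycle(c, n, cfg)
        r = cfg.k_rc * dc  # stationary start-of-cycle = per-cycle production
        m = cfg.phi_M_abs * mi
    rows = []
    for d in range(1, n_div + 1):
        c_new, dc, mi = _integrate_cycle(c, n, cfg)
        r_new = r + cfg.k_rc * dc
        m_new = m + cfg.phi_M_abs * mi
        rows.append((d, c_new, r_new, m_new))
        c, r, m = c_new / 2.0, r_new / 2.0, m_new / 2.0
    return pd.DataFrame(rows, columns=["division", "c", "r", "m"])


# ---------------------------------------------------------------------------
# stochastic kernels


def _regulated_cycle(rng, n, c, cfg: StochasticConfig):
    """Exact simulation of one division cycle; returns (c_new, r_add, m_add).

    Rates change only when C changes, so each inter-event interval has
    constant intensities: the C waiting time is exponential and the R/M
    totals over the cycle are Poisson with the integrated intensity.
    """
    kd1, kdn, kdm = cfg.kd1_n, cfg.kd_n, cfg.kd_m_n
    phi_l, phi_m, phi_M = cfg.phi_l_abs, cfg.phi_m_abs, cfg.phi_M_abs
    p, omega = cfg.p, cfg.omega
    t = 0.0
    int_c = 0.0  # integral of the C-production rate (for R)
    int_m = 0.0
    events = 0
    while True:
        cf = 2.0 * c / (1.0 + math.sqrt(1.0 + 8.0 * c / kd1))
        ctil2 = (cf / kdn) ** 2
        f = ctil2 / (1.0 + (1.0 + 1.0 / p) * ctil2 + (omega / p) * ctil2 * ctil2)
        rate_c = n * (phi_l + phi_m * f)
        rate_m = n * phi_M / (1.0 + (cf * cf / kd1) / kdm)
        if rate_c <= 0.0:
            dt = 1.0 - t
        else:
            dt = min(rng.exponential(1.0 / rate_c), 1.0 - t)
        int_c += rate_c * dt
        int_m += rate_m * dt
        t += dt
        if t >= 1.0:
            break
        c += 1
        events += 1
    if cfg.cotranscribe:
        r_add = rng.poisson(cfg.k_rc * events) if events else 0
    else:
        r_add = rng.poisson(cfg.k_rc * int_c)
    m_add = rng.poisson(int_m)
    return c, r_add, m_add


def simulate(cfg: StochasticConfig, initial: Optional[Ensemble] = None) -> Ensemble:
    """Simulate the cell ensemble; bit-reproducible for a given config.

    ``initial`` provides per-cell starting states; the post-segregational
    mode requires it (equilibrium states from a regulated run, plasmids
    are then removed). Growth modes default to the deterministic
    equilibrium start-of-cycle state for every cell.
    """
    rng = np.random.default_rng(cfg.seed)
    cells, n_div = cfg.n_cells, cfg.n_divisions
    shape = (cells, n_div + 1)
    n_arr = np.zeros(shape, dtype=np.int64)
    c_arr = np.zeros(shape, dtype=np.int64)
    r_arr = np.zeros(shape, dtype=np.int64)
    m_arr = np.zeros(shape, dtype=np.int64)

    if cfg.mode == "post_segregational":
        if initial is None:
            raise ValueError(
                "post_segregational mode requires an initial ensemble from the "
                "equilibrium simulation of the regulated model"
            )
        last = initial.n_divisions
        if initial.n_cells != cells:
            raise ValueError("initial ensemble size does not match n_cells")
        c0 = initial.c[:, last].copy()
        r0 = initial.r_mol[:, last].copy()
        m0 = initial.m_mol[:, last].copy()
        c_arr[:, 0], r_arr[:, 0], m_arr[:, 0] = c0, r0, m0
        for d in range(1, n_div + 1):
            c0 = rng.binomial(c0, 0.5)
            r0 = rng.binomial(r0, 0.5)
            m0 = rng.binomial(m0, 0.5)
            c_arr[:, d], r_arr[:, d], m_arr[:, d] = c0, r0, m0
        return Ensemble(config=cfg, n=n_arr, c=c_arr, r_mol=r_arr, m_mol=m_arr)

    # growth modes
    if initial is not None:
        n0 = initial.n[:, 0].astype(np.int64).copy()
        c0 = initial.c[:, 0].astype(np.int64).copy()
        r0 = initial.r_mol[:, 0].astype(np.int64).copy()
        m0 = initial.m_mol[:, 0].astype(np.int64).copy()
    else:
        ref = deterministic_reference(cfg, n_divisions=1)
        n0 = np.full(cells, cfg.n_target, dtype=np.int64)
        c0 = np.full(cells, int(round(ref.c[0] / 2.0)), dtype=np.int64)
        r0 = np.full(cells, int(round(ref.r[0] / 2.0)), dtype=np.int64)
        m0 = np.full(cells, int(round(ref.m[0] / 2.0)), dtype=np.int64)
    n_arr[:, 0], c_arr[:, 0], r_arr[:, 0], m_arr[:, 0] = n0, c0, r0, m0

    constitutive = cfg.mode == "constitutive"
    for i in range(cells):
        n, c, r, m = int(n0[i]), int(c0[i]), int(r0[i]), int(m0[i])
        for d in range(1, n_div + 1):
            if constitutive:
                c += rng.poisson(n * cfg.const_c)
                r += rng.poisson(n * cfg.const_r)
                m += rng.poisson(n * cfg.const_m)
            else:
                c, r_add, m_add = _regulated_cycle(rng, n, c, cfg)
                r += r_add
                m += m_add
            n_arr[i, d], c_arr[i, d], r_arr[i, d], m_arr[i, d] = n, c, r, m
            # division: plasmids replicate then partition; molecules halve
            n = int(rng.binomial(2 * n, 0.5))
            c = int(rng.binomial(c, 0.5))
            r = int(rng.binomial(r, 0.5))
            m = int(rng.binomial(m, 0.5))
    return Ensemble(config=cfg, n=n_arr, c=c_arr, r_mol=r_arr, m_mol=m_arr)


# ---------------------------------------------------------------------------
# statistics


def summarize(ensemble: Ensemble, at_division: int) -> EnsembleSummary:
    """Median/IQR/CV of M/R over retained (R > 0) trajectories.

    Quartiles use linear interpolation of order statistics. If every
    trajectory is excluded the statistics are flagged undefined (NaN)
    rather than raising.
    """
    r = ensemble.r_mol[:, at_division].astype(float)
    m = ensemble.m_mol[:, at_division].astype(float)
    keep = r > 0
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        return EnsembleSummary(
            division=at_division,
            median_mr=np.nan,
            iqr_mr=np.nan,
            cv_mr=np.nan,
            robust_cv_mr=np.nan,
            median_r=float(np.median(r)),
            n_excluded=n_excluded,
            n_retained=0,
            defined=False,
        )
    ratio = m[keep] / r[keep]
    q1, med, q3 = np.percentile(ratio, [25.0, 50.0, 75.0])
    mean = float(np.mean(ratio))
    sd = float(np.std(ratio, ddof=1)) if ratio.size > 1 else 0.0
    return EnsembleSummary(
        division=at_division,
        median_mr=float(med),
        iqr_mr=float(q3 - q1),
        cv_mr=sd / mean if mean > 0 else np.nan,
        robust_cv_mr=float((q3 - q1) / med) if med > 0 else np.nan,
        median_r=float(np.median(r)),
        n_excluded=n_excluded,
        n_retained=int(np.sum(keep)),
    )


def summarize_all(ensemble: Ensemble) -> pd.DataFrame:
    """Per-division summary table (columns mirror EnsembleSummary fields)."""
    rows = [summarize(ensemble, d) for d in range(ensemble.n_divisions + 1)]
    return pd.DataFrame(
        {
            "division": [s.division for s in rows],
            "median_mr": [s.median_mr for s in rows],
            "iqr_mr": [s.iqr_mr for s in rows],
            "cv_mr": [s.cv_mr for s in rows],
            "robust_cv_mr": [s.robust_cv_mr for s in rows],
            "median_r": [s.median_r for s in rows],
            "n_excluded": [s.n_excluded for s in rows],
        }
    )


def equilibrium_check(
    ensemble: Ensemble,
    reference: pd.DataFrame,
    rtol: float = 0.15,
    n_last: int = 3,
) -> tuple[bool, dict]:
    """Whether the ensemble has reached the deterministic equilibrium.

    Compares ensemble medians of C, R, M at the last ``n_last`` recorded
    divisions with the deterministic end-of-cycle trajectory, and checks
    stationarity (successive medians within tolerance of each other).
    """
    divisions = [d for d in range(1, ensemble.n_divisions + 1)][-n_last:]
    report: dict = {"divisions": divisions, "rtol": rtol}
    ok = True
    meds = {}
    for field_name, arr in (("c", ensemble.c), ("r", ensemble.r_mol), ("m", ensemble.m_mol)):
        med = np.array([np.median(arr[:, d]) for d in divisions], dtype=float)
        ref = np.array(
            [float(reference.loc[reference.division == d, field_name].iloc[0]) for d in divisions]
        )
        rel = np.abs(med - ref) / np.maximum(ref, 1e-12)
        stat = np.abs(np.diff(med)) / np.maximum(med[:-1], 1e-12)
        meds[field_name] = med
        report[f"{field_name}_rel_error"] = rel
        report[f"{field_name}_stationarity"] = stat
        if np.any(rel > rtol) or np.any(stat > rtol):
            ok = False
    report["medians"] = meds
    return ok, report
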