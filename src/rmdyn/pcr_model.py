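"""Thermodynamic model of the P.CR promoter and rescaled C-protein dynamics.

The C protein dimerizes in solution; the dimer binds a distal site (DBS,
activating, statistical weight ``z1``), a proximal site (PBS, repressing,
``z2``-forming partner and ``z3`` alone), and the two bound dimers interact
cooperatively to form a repressing tetramer (``z2``). Transcription
activity is the activation weight over the partition function plus a basal
leakage, and total C obeys a production-dilution balance. Everything here
is in rescaled (dimensionless) units: concentrations in units of
``K_d = sqrt(K_d1 * K_d2)`` and time in units of ``K_d / (n * phi_m)``.

All functions are vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DissociationConstants, ExternalParams, InternalParams

__all__ = [
    "BindingWeights",
    "free_monomer",
    "free_monomer_derivative",
    "total_from_free",
    "binding_weights",
    "regulated_activity",
    "regulated_activity_derivative",
    "pcr_activity",
    "c_dynamics_rhs",
    "c_dynamics_rhs_derivative",
    "c_dynamics_rhs_absolute",
    "r_total",
]


@dataclass(frozen=True)
class BindingWeights:
    """Statistical weights of the three C-binding configurations (rescaled)."""

    z1: np.ndarray | float  # DBS dimer, activation
    z2: np.ndarray | float  # DBS+PBS tetramer, repression
    z3: np.ndarray | float  # PBS dimer, repression


def _check_nonnegative(name, x):
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def free_monomer(c_total, alpha):
    """Free-monomer concentration from total, at monomer-dimer equilibrium.

    Solves ``c + 2 c^2 / alpha = c_total`` for the positive root. Written
    as ``2 c_total / (1 + sqrt(1 + 8 c_total / alpha))`` -- algebraically
    the textbook quadratic root ``(alpha/4)(sqrt(1 + 8 c_total/alpha) - 1)``
    but immune to cancellation when ``c_total << alpha``.
    """
    c_total = np.asarray(c_total, dtype=float)
    _check_nonnegative("c_total", c_total)
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be > 0")
    out = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * c_total / alpha))
    return out if out.ndim else float(out)


def free_monomer_derivative(c_total, alpha):
    """d(free)/d(total) = 1/sqrt(1 + 8 c_total / alpha), in (0, 1]."""
    c_total = np.asarray(c_total, dtype=float)
    out = 1.0 / np.sqrt(1.0 + 8.0 * c_total / alpha)
    return out if out.ndim else float(out)


def total_from_free(c_free, alpha):
    """Inverse conservation map: ``c_total = c_free + 2 c_free^2 / alpha``."""
    c_free = np.asarray(c_free, dtype=float)
    out = c_free + 2.0 * c_free**2 / alpha
    return out if out.ndim else float(out)


def binding_weights(c_free, p, omega) -> BindingWeights:
    """Rescaled configuration weights: z1 = c^2, z3 = c^2/p, z2 = (omega/p) c^4."""
    c_free = np.asarray(c_free, dtype=float)
    _check_nonnegative("c_free", c_free)
    c2 = c_free**2
    z1 = c2
    z3 = c2 / p
    z2 = (omega / p) * c2**2
    if c_free.ndim:
        return BindingWeights(z1=z1, z2=z2, z3=z3)
    return BindingWeights(z1=float(z1), z2=float(z2), z3=float(z3))


def regulated_activity(c_free, p, omega):
    """Regulated part of P.CR activity: z1 over the partition function.

    f(c) = c^2 / (1 + (1 + 1/p) c^2 + (omega/p) c^4), in [0, 1).
    """
    c_free = np.asarray(c_free, dtype=float)
    c2 = c_free**2
    out = c2 / (1.0 + (1.0 + 1.0 / p) * c2 + (omega / p) * c2**2)
    return out if out.ndim else float(out)


def regulated_activity_derivative(c_free, p, omega):
    """df/dc = 2 c (1 - (omega/p) c^4) / den^2.

    Positive for ``c < (p/omega)^(1/4)`` (activation-dominated), negative
    beyond (tetramer repression dominates); the sign change is what makes
    the fold boundary possible.
    """
    c_free = np.asarray(c_free, dtype=float)
    c2 = c_free**2
    den = 1.0 + (1.0 + 1.0 / p) * c2 + (omega / p) * c2**2
    out = 2.0 * c_free * (1.0 - (omega / p) * c2**2) / den**2
    return out if out.ndim else float(out)


def pcr_activity(c_free, s, p, omega):
    """Total P.CR activity: leakage plus the regulated term; in [s, s + 1)."""
    if s < 0:
        raise ValueError("leakage s must be >= 0")
    out = s + regulated_activity(c_free, p, omega)
    return out


def c_dynamics_rhs(c_total, external: ExternalParams, internal: InternalParams):
    """Right-hand side of the rescaled total-C dynamics.

    dCt/dtau = s + f(C(Ct)) - Ct / r, with C the free monomer at
    monomer-dimer equilibrium. Steady states are the zeros of this
    function; all of them lie in [0, r (s + 1)].
    """
    c = free_monomer(c_total, internal.alpha)
    return (
        external.s
        + regulated_activity(c, internal.p, internal.omega)
        - np.asarray(c_total, dtype=float) / external.r
    )


def c_dynamics_rhs_derivative(c_total, external: ExternalParams, internal: InternalParams):
    """Analytic d(rhs)/dCt = f'(C) * dC/dCt - 1/r (negative => stable)."""
    c = free_monomer(c_total, internal.alpha)
    fp = regulated_activity_derivative(c, internal.p, internal.omega)
    return fp * free_monomer_derivative(c_total, internal.alpha) - 1.0 / external.r


def c_dynamics_rhs_absolute(c_total_abs, phi_l, phi_m, n, lam, kds: DissociationConstants):
    """Unscaled total-C dynamics in physical units.

    dCt/dt = n phi_l + n phi_m * f(C / K_d) - lam * Ct, with the free
    monomer from the dimerization constant kd1 and K_d = sqrt(kd1 kd2).
    Dividing by ``n phi_m`` and measuring concentration in K_d units
    recovers :func:`c_dynamics_rhs` with s = phi_l/phi_m and
    r = n phi_m / (lam K_d).
    """
    for name, v in (("phi_l", phi_l), ("phi_m", phi_m), ("n", n), ("lam", lam)):
        if v < 0 or (name != "phi_l" and v == 0):
            raise ValueError(f"{name} must be positive (phi_l may be zero)")
    c_total_abs = np.asarray(c_total_abs, dtype=float)
    kd = np.sqrt(kds.kd1 * kds.kd2)
    p = kds.kd3 / kds.kd2
    omega = kds.kd2 * kds.kd3 / kds.kd23
    # free monomer in absolute units from the dimerization quadratic
    c_free = 2.0 * c_total_abs / (1.0 + np.sqrt(1.0 + 8.0 * c_total_abs / kds.kd1))
    f = regulated_activity(c_free / kd, p, omega)
    return n * phi_l + n * phi_m * f - lam * c_total_abs


def r_total(c_total, k_rc=1.0):
    """Total R from total C: R and C are co-transcribed, so Rt = k_rc * Ct."""
    if k_rc <= 0:
        raise ValueError("k_rc must be > 0")
    return k_rc * np.asarray(c_total, dtype=float) if np.ndim(c_total) else k_rc * float(c_total)
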