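"""Bell–Evans rupture kinetics under a constant loading rate.

A transition with zero-force rate ``k0`` and transition distance ``x``
(positive when force accelerates the transition) has the Bell rate

    k(F) = k0 * exp(F * x / kBT).

Under a linear force ramp ``F = r t`` the first-passage (rupture) force has
the Evans–Ritchie distribution; its mean has a closed form in the exponential
integral E1, which is used both to calibrate ``k0`` against a target mean
rupture force and as the independent oracle for the kinetic Monte-Carlo
simulator.  Negative ``x`` describes the reverse case — a transition (e.g.
rezipping) whose rate grows as the force is ramped *down* at rate ``|r|``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import exp1

__all__ = [
    "bell_rate",
    "mean_rupture_force",
    "calibrate_k0",
    "sample_rupture_forces",
]

_EULER_GAMMA = 0.5772156649015329


def bell_rate(k0: float, x_dagger: float, force, kbt: float):
    """Bell rate ``k0 * exp(force * x_dagger / kbt)`` in 1/s.

    Accepts scalar or array ``force``; the exponent is clipped at +-700 to
    stay inside float range.
    """
    if k0 <= 0:
        raise ValueError("k0 must be > 0")
    if kbt <= 0:
        raise ValueError("kbt must be > 0")
    arg = np.clip(np.asarray(force, dtype=float) * x_dagger / kbt, -700.0, 700.0)
    out = k0 * np.exp(arg)
    return float(out) if np.isscalar(force) else out


def _scaled_exp1(a: float) -> float:
    """exp(a) * E1(a) for a > 0, stable for large a."""
    if a < 500.0:
        return math.exp(a) * exp1(a)
    # asymptotic series, relative error < 1e-10 for a > 500
    inv = 1.0 / a
    return inv * (1.0 - inv * (1.0 - 2.0 * inv * (1.0 - 3.0 * inv)))


def mean_rupture_force(k0: float, x_dagger: float, loading_rate: float,
                       kbt: float) -> float:
    """Evans–Ritchie mean first-passage force under a linear ramp, pN.

    For ``x_dagger > 0`` the force is ramped up from zero at ``loading_rate``
    and the mean is ``(kBT/x) e^a E1(a)`` with ``a = k0 kBT / (x r)``.  For
    ``x_dagger < 0`` the force is ramped *down* from far above the transition
    and the mean is ``(kBT/|x|) (ln b + gamma + E1(b))`` with
    ``b = k0 kBT / (|x| r)``.
    """
    if k0 <= 0 or loading_rate <= 0 or kbt <= 0:
        raise ValueError("k0, loading_rate and kbt must be > 0")
    if x_dagger == 0:
        raise ValueError("x_dagger must be nonzero")
    x = abs(x_dagger)
    a = k0 * kbt / (x * loading_rate)
    if x_dagger > 0:
        return (kbt / x) * _scaled_exp1(a)
    return (kbt / x) * (math.log(a) + _EULER_GAMMA + exp1(a))


def calibrate_k0(target_mean_rupture_force: float, loading_rate: float,
                 x_dagger: float, kbt: float) -> float:
    """Invert the Evans–Ritchie mean to the zero-force rate ``k0``.

    Returns the ``k0`` whose mean rupture force under the given ramp equals
    the target.  Raises ``ValueError`` when no ``k0`` in [1e-280, 1e280]
    brackets the target.
    """
    if target_mean_rupture_force <= 0 or loading_rate <= 0:
        raise ValueError("target force and loading rate must be > 0")

    def g(log10_k0: float) -> float:
        return (mean_rupture_force(10.0 ** log10_k0, x_dagger, loading_rate, kbt)
                - target_mean_rupture_force)

    lo, hi = -280.0, 280.0
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ValueError(
            "target mean rupture force not bracketable for these parameters")
    return 10.0 ** brentq(g, lo, hi, xtol=1e-12)


def sample_rupture_forces(k0: float, x_dagger: float, loading_rate: float,
                          kbt: float, n: int, rng,
                          start_force: float | None = None) -> np.ndarray:
    """Draw ``n`` first-passage forces by exact inversion of the hazard.

    For ``x_dagger > 0`` the ramp starts at zero force; for ``x_dagger < 0``
    it starts at ``start_force`` (required) and runs down, and draws that
    survive to zero force are returned as 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x = abs(x_dagger)
    beta = x / kbt
    a = k0 * kbt / (x * loading_rate)
    e = rng.exponential(1.0, size=n)
    if x_dagger > 0:
        return np.log1p(e / a) / beta
    if start_force is None:
        raise ValueError("start_force required for a down-ramp (x_dagger < 0)")
    tail = math.exp(-beta * start_force)
    arg = tail + e / a
    with np.errstate(over="ignore"):
        f = -np.log(arg) / beta
    return np.clip(f, 0.0, start_force)
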