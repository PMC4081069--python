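"""Force–extension relations for the conformational states of a tethered construct.

Each construct is a mechanical series of duplex/single-strand segments plus a
single-stranded handle, held by an optical trap of stiffness ``k``.  The trap
reads out force versus trap position; a conformational change that lengthens
the construct at fixed trap position therefore shows up as a force drop.

Elasticity laws
---------------
* double-stranded segments (B-form, S-form): extensible worm-like chain,
  Marko–Siggia interpolation with an enthalpic stretch term,
  ``F = (kT/Lp) [ 1/(4(1-l)^2) - 1/4 + l ]`` with ``l = x/L - F/S``,
  inverted numerically for ``x(F)``;
* single-stranded segments (peeled strand, handles): extensible freely-jointed
  chain (Langevin function) with Kuhn length ``2 Lp``, explicit in force;
* a segment melted with both strands sharing tension extends as two identical
  single strands in parallel, i.e. ``x(F) = x_ss(F/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CONFORMATIONS",
    "BOLTZMANN_PN_NM_PER_K",
    "kbt_at",
    "ElasticParams",
    "SegmentState",
    "TrapProtocol",
    "segment_extension",
    "construct_extension",
    "solve_force",
]

#: Allowed segment conformations.
CONFORMATIONS = frozenset(
    {"B_FORM", "S_FORM", "PEELED_SS", "MELTED_SHARED", "HANDLE_SS"}
)

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM_PER_K = 0.0138065


def kbt_at(temperature_c: float) -> float:
    """Thermal energy kB*T in pN nm at the given temperature in Celsius."""
    return BOLTZMANN_PN_NM_PER_K * (temperature_c + 273.15)


@dataclass(frozen=True)
class ElasticParams:
    """Elastic description of one segment conformation.

    Parameters
    ----------
    contour_length_per_unit : float
        Contour length in nm per bp (duplex conformations) or per nt
        (single-stranded conformations).
    persistence_length : float
        Persistence length in nm.  For the FJC law the Kuhn length is twice
        this value.
    stretch_modulus : float, optional
        Enthalpic stretch modulus in pN.  ``None`` means inextensible: the
        extension then stays strictly below the contour length at any finite
        force.
    law : {"wlc", "fjc"}
        Which interpolation formula to use.
    """

    contour_length_per_unit: float
    persistence_length: float
    stretch_modulus: Optional[float] = None
    law: str = "wlc"

    def __post_init__(self) -> None:
        if self.contour_length_per_unit <= 0:
            raise ValueError("contour_length_per_unit must be > 0")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.stretch_modulus is not None and self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0 or None")
        if self.law not in ("wlc", "fjc"):
            raise ValueError(f"unknown elasticity law {self.law!r}")


@dataclass(frozen=True)
class SegmentState:
    """One segment of a construct in a definite conformation."""

    segment_id: str
    n_units: int
    conformation: str

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.conformation not in CONFORMATIONS:
            raise ValueError(f"unknown conformation {self.conformation!r}")


@dataclass(frozen=True)
class TrapProtocol:
    """Constant-velocity pull–relax protocol of the optical trap.

    Defaults follow the measurement protocol emulated throughout: 50 nm/s trap
    velocity, 1 kHz sampling, 22.8 C, and a trap stiffness of 0.156 pN/nm so
    that 50 nm/s corresponds to a nominal loading rate of 7.8 pN/s.
    """

    force_min: float
    force_max: float
    trap_velocity: float = 50.0
    trap_stiffness: float = 0.156
    sample_rate: float = 1000.0
    temperature_c: float = 22.8

    def __post_init__(self) -> None:
        if not self.force_min < self.force_max:
            raise ValueError("force_min must be < force_max")
        if self.trap_velocity <= 0:
            raise ValueError("trap_velocity must be > 0")
        if self.trap_stiffness <= 0:
            raise ValueError("trap_stiffness must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def kbt(self) -> float:
        """Thermal energy at the protocol temperature, pN nm."""
        return kbt_at(self.temperature_c)

    @property
    def nominal_loading_rate(self) -> float:
        """Trap-dominated loading rate ``k * v`` in pN/s."""
        return self.trap_stiffness * self.trap_velocity


def _wlc_force_of_rel_ext(rel_ext: float, lp: float, kbt: float) -> float:
    # Marko–Siggia interpolation, valid for 0 <= rel_ext < 1.
    return (kbt / lp) * (0.25 / (1.0 - rel_ext) ** 2 - 0.25 + rel_ext)


def _wlc_extension(force: float, contour: float, lp: float,
                   stretch: Optional[float], kbt: float) -> float:
    if force == 0.0:
        return 0.0
    enth = force / stretch if stretch else 0.0

    def g(l: float) -> float:
        return _wlc_force_of_rel_ext(l, lp, kbt) - force

    l = brentq(g, 0.0, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16)
    return contour * (l + enth)


def _fjc_extension(force: float, contour: float, lp: float,
                   stretch: Optional[float], kbt: float) -> float:
    if force == 0.0:
        return 0.0
    kuhn = 2.0 * lp
    u = force * kuhn / kbt
    if u < 1e-8:
        langevin = u / 3.0
    else:
        langevin = 1.0 / np.tanh(u) - 1.0 / u
    enth = 1.0 + (force / stretch if stretch else 0.0)
    return contour * langevin * enth


def segment_extension(params: ElasticParams, state: SegmentState,
                      force: float, kbt: float) -> float:
    """Extension in nm of one segment at the given tension.

    ``MELTED_SHARED`` divides the tension equally between the two strands, so
    the segment extends as a single strand at half the applied force.
    Raises ``ValueError`` for negative force.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    f_eff = force / 2.0 if state.conformation == "MELTED_SHARED" else force
    contour = params.contour_length_per_unit * state.n_units
    if params.law == "wlc":
        return _wlc_extension(f_eff, contour, params.persistence_length,
                              params.stretch_modulus, kbt)
    return _fjc_extension(f_eff, contour, params.persistence_length,
                          params.stretch_modulus, kbt)


def construct_extension(spec, states: Sequence[SegmentState],
                        force: float, kbt: Optional[float] = None) -> float:
    """Total extension of a construct in a given set of segment conformations.

    The construct extension is the series sum of its segment extensions plus
    the handle extension.  A ``PEELED_SS`` segment contributes only the
    tension-bearing strand (the relaxed complementary strand contributes
    zero); this is already encoded by the single-strand elastic parameters.

    Parameters
    ----------
    spec
        A construct description exposing ``segment_ids``,
        ``elastic_params(segment_id, conformation)`` and ``handle_state`` /
        ``handle_params`` attributes (see :class:`forcemelt.constructs.ConstructSpec`).
    states
        One :class:`SegmentState` per duplex segment of ``spec``, each segment
        covered exactly once.
    """
    if kbt is None:
        kbt = kbt_at(22.8)
    ids = [s.segment_id for s in states]
    expected = list(spec.segment_ids)
    if sorted(ids) != sorted(expected):
        raise ValueError(
            f"states must cover segments {expected} exactly once, got {ids}")
    total = 0.0
    for st in states:
        total += segment_extension(spec.elastic_params(st.segment_id,
                                                       st.conformation),
                                   st, force, kbt)
    total += segment_extension(spec.handle_params, spec.handle_state,
                               force, kbt)
    return total


def solve_force(trap_position: float, spec, states: Sequence[SegmentState],
                protocol: TrapProtocol) -> float:
    """Force balance of the construct–trap series at a given trap position.

    Returns the unique ``F`` with ``F = k * (trap_position - x_c(F))`` where
    ``x_c`` is the construct extension; uniqueness follows from ``x_c`` being
    strictly increasing in force.  A state change to a longer conformation at
    fixed trap position strictly lowers the returned force.
    """
    k = protocol.trap_stiffness
    kbt = protocol.kbt

    def g(f: float) -> float:
        return k * (trap_position - construct_extension(spec, states, f, kbt)) - f

    if trap_position < 0:
        raise ValueError("trap_position must be >= construct rest extension")
    g0 = g(0.0)
    if g0 < 0:
        raise ValueError("trap_position below construct rest extension")
    if g0 == 0.0:
        return 0.0
    hi = max(1.0, k * trap_position)
    for _ in range(80):
        if g(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"no bracketing force in [0, {hi}] for trap_position={trap_position}")
    return brentq(g, 0.0, hi, xtol=1e-10, rtol=8.9e-16)
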