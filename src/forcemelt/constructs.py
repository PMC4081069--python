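"""Construct descriptions, parameter files and simulation scenarios.

A *scenario* bundles everything the kinetic Monte-Carlo engine needs for one
construct x salt condition: the mechanical states (each with a construct-level
extension law), the allowed transitions with their Bell parameters, the trap
protocol and the measurement-noise level.  Scenario parameters live in
plain-text ``key = value`` files shipped as package data, one file per
construct x salt condition.

Elastic parameters are not taken ab initio: the per-unit contour lengths of
the melted/stretched conformations are calibrated at scenario build time so
that the state-to-state extension differences at the reference forces equal
the measured values (e.g. 14.7 nm between peeled and B-form 5'AT at 61.5 pN).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .kinetics import calibrate_k0
from .polymer import (ElasticParams, SegmentState, TrapProtocol,
                      kbt_at, segment_extension)

__all__ = [
    "CONSTRUCT_NAMES",
    "SALT_NAMES",
    "ConfigError",
    "read_config",
    "Segment",
    "ConstructSpec",
    "MechState",
    "Transition",
    "Scenario",
    "load_scenario",
    "available_scenarios",
]

CONSTRUCT_NAMES = ("FIVE_PRIME_AT", "THREE_FIVE_PRIME_AT", "ATGC")
SALT_NAMES = ("HIGH_1M", "LOW_5MM")

# default elastic constants; melted/stretched contours are overwritten by
# calibration at scenario build time
DS_B = dict(contour_length_per_unit=0.34, persistence_length=45.0,
            stretch_modulus=1200.0, law="wlc")
DS_S = dict(contour_length_per_unit=0.58, persistence_length=10.0,
            stretch_modulus=1000.0, law="wlc")
SS = dict(contour_length_per_unit=0.56, persistence_length=0.75,
          stretch_modulus=800.0, law="fjc")


class ConfigError(ValueError):
    """Malformed or missing scenario configuration."""


def read_config(source) -> Dict[str, str]:
    """Parse a ``key = value`` configuration file into a string dict.

    Lines starting with ``#`` and blank lines are ignored; inline ``#``
    comments are stripped.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ConfigError(f"line {lineno}: empty key or value in {raw!r}")
        out[key] = value
    return out


def _cfg_float(cfg: Dict[str, str], key: str) -> float:
    try:
        return float(cfg[key])
    except KeyError:
        raise ConfigError(f"missing configuration key {key!r}") from None
    except ValueError:
        raise ConfigError(f"key {key!r} is not a number: {cfg[key]!r}") from None


def _cfg_floats(cfg: Dict[str, str], key: str) -> Tuple[float, ...]:
    return tuple(float(p) for p in cfg[key].split(","))


@dataclass(frozen=True)
class Segment:
    segment_id: str
    n_bp: int
    composition: str  # AT_RICH or GC_RICH


@dataclass
class ConstructSpec:
    """A designed duplex with its elastic parameter set.

    ``elastic`` maps ``(segment_id, conformation)`` to :class:`ElasticParams`;
    the handle is a single effective single-stranded compliance.
    """

    name: str
    duplex_bp: int
    segments: List[Segment]
    linker_config: str
    salt: str
    elastic: Dict[Tuple[str, str], ElasticParams] = field(default_factory=dict)
    handle_params: ElasticParams = field(
        default_factory=lambda: ElasticParams(150.0, 0.75, 800.0, law="fjc"))

    def __post_init__(self) -> None:
        if self.name not in CONSTRUCT_NAMES:
            raise ValueError(f"unknown construct {self.name!r}")
        if self.salt not in SALT_NAMES:
            raise ValueError(f"unknown salt condition {self.salt!r}")
        if self.name == "FIVE_PRIME_AT" and self.linker_config != "ONE_END":
            raise ValueError("FIVE_PRIME_AT requires linker_config ONE_END")
        if self.name == "THREE_FIVE_PRIME_AT" and self.linker_config != "BOTH_ENDS":
            raise ValueError("THREE_FIVE_PRIME_AT requires linker_config BOTH_ENDS")
        if self.name == "ATGC":
            comps = [s.composition for s in self.segments]
            if comps != ["AT_RICH", "GC_RICH"]:
                raise ValueError("ATGC requires segments (AT_RICH, GC_RICH)")
        if sum(s.n_bp for s in self.segments) != self.duplex_bp:
            raise ValueError("segment lengths must sum to duplex_bp")

    @property
    def segment_ids(self) -> List[str]:
        return [s.segment_id for s in self.segments]

    @property
    def handle_state(self) -> SegmentState:
        return SegmentState("handle", 1, "HANDLE_SS")

    def elastic_params(self, segment_id: str, conformation: str) -> ElasticParams:
        try:
            return self.elastic[(segment_id, conformation)]
        except KeyError:
            raise KeyError(
                f"no elastic parameters for segment {segment_id!r} in "
                f"conformation {conformation!r}") from None


@dataclass
class MechState:
    """One mechanical state of the construct-trap series.

    ``extension`` maps force (pN) to construct extension (nm), handle
    included.  ``label`` is the short ground-truth label recorded per sample
    (e.g. ``B``, ``I``, ``S``, ``M``).
    """

    name: str
    label: str
    extension: Callable[[float], float]


@dataclass(frozen=True)
class Transition:
    """A Bell-rate transition between two mechanical states."""

    name: str
    src: str
    dst: str
    k0: float
    x_dagger: float
    is_event: bool = True  # rip/zip-scale event (vs fast hopping)


@dataclass
class Scenario:
    """Everything the simulator needs for one construct x salt condition."""

    construct: ConstructSpec
    protocol: TrapProtocol
    states: Dict[str, MechState]
    transitions: List[Transition]
    initial_state: str
    noise_sd: float = 0.3
    hysteretic_pathway_probability: float = 0.0
    # (equilibrium state, frozen state): at the start of a relax phase drawn
    # as HYSTERETIC, a molecule sitting in the equilibrium state is moved to
    # the frozen (fully molten) state and returns only via its rezip channel
    frozen_relax: Optional[Tuple[str, str]] = None
    analysis: Dict[str, tuple] = field(default_factory=dict)
    config: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.hysteretic_pathway_probability <= 1.0:
            raise ValueError("hysteretic_pathway_probability must be in [0, 1]")
        names = set(self.states)
        if self.initial_state not in names:
            raise ValueError("initial_state not among states")
        for tr in self.transitions:
            if tr.src not in names or tr.dst not in names:
                raise ValueError(f"transition {tr.name} references unknown state")

    @property
    def kbt(self) -> float:
        return self.protocol.kbt

    def transitions_from(self, state: str) -> List[Transition]:
        return [t for t in self.transitions if t.src == state]

    def metadata(self) -> Dict[str, object]:
        p = self.protocol
        return {
            "construct": self.construct.name,
            "salt": self.construct.salt,
            "duplex_bp": self.construct.duplex_bp,
            "temperature_C": p.temperature_c,
            "trap_stiffness_pN_nm": p.trap_stiffness,
            "trap_velocity_nm_s": p.trap_velocity,
            "sample_rate_hz": p.sample_rate,
            "force_min_pN": p.force_min,
            "force_max_pN": p.force_max,
            "noise_sd_pN": self.noise_sd,
        }


# ---------------------------------------------------------------------------
# calibration helpers

def _ext_fn(params: ElasticParams, n_units: int, conformation: str,
            kbt: float) -> Callable[[float], float]:
    state = SegmentState("seg", n_units, conformation)

    def f(force: float) -> float:
        return segment_extension(params, state, force, kbt)

    return f


def _calibrate_contour(base: ElasticParams, n_units: int, conformation: str,
                       kbt: float, reference: Callable[[float], float],
                       target_delta: float, at_force: float,
                       lo: float = 0.2, hi: float = 1.5) -> ElasticParams:
    """Solve the per-unit contour so that ext - reference = target at at_force."""

    def g(c: float) -> float:
        p = replace(base, contour_length_per_unit=c)
        return (_ext_fn(p, n_units, conformation, kbt)(at_force)
                - reference(at_force) - target_delta)

    c = brentq(g, lo, hi, xtol=1e-12)
    return replace(base, contour_length_per_unit=c)


def _protocol_from(cfg: Dict[str, str]) -> TrapProtocol:
    return TrapProtocol(
        force_min=_cfg_float(cfg, "force_min_pN"),
        force_max=_cfg_float(cfg, "force_max_pN"),
        trap_velocity=_cfg_float(cfg, "trap_velocity_nm_s"),
        trap_stiffness=_cfg_float(cfg, "trap_stiffness_pN_nm"),
        sample_rate=_cfg_float(cfg, "sample_rate_hz"),
        temperature_c=_cfg_float(cfg, "temperature_C"),
    )


def _handle(cfg: Dict[str, str]) -> ElasticParams:
    return ElasticParams(_cfg_float(cfg, "handle_contour_nm"), SS["persistence_length"],
                         SS["stretch_modulus"], law="fjc")


def _hop_pair(name_open: str, name_close: str, src: str, dst: str,
              crossing: float, dx: float, attempt: float,
              kbt: float) -> List[Transition]:
    """Detailed-balance pair of hopping transitions around a crossing force.

    Rates are ``a * exp(+-(F - Fc) dx / (2 kBT))`` so that the forward/reverse
    ratio is the two-state Boltzmann factor ``exp((F - Fc) dx / kBT)``.
    """
    half = dx / (2.0 * kbt)
    return [
        Transition(name_open, src, dst, attempt * float(np.exp(-crossing * half)),
                   dx / 2.0, is_event=False),
        Transition(name_close, dst, src, attempt * float(np.exp(crossing * half)),
                   -dx / 2.0, is_event=False),
    ]


# ---------------------------------------------------------------------------
# per-construct scenario builders

def _build_five_prime_at(cfg: Dict[str, str]) -> Scenario:
    protocol = _protocol_from(cfg)
    kbt = protocol.kbt
    n_bp = int(cfg["duplex_bp"])
    handle = _handle(cfg)

    spec = ConstructSpec(
        name="FIVE_PRIME_AT", duplex_bp=n_bp,
        segments=[Segment("AT64", n_bp, "AT_RICH")],
        linker_config="ONE_END", salt=cfg["salt"], handle_params=handle)

    ds = ElasticParams(**DS_B)
    x_b_duplex = _ext_fn(ds, n_bp, "B_FORM", kbt)
    ss = _calibrate_contour(
        ElasticParams(**SS), n_bp, "PEELED_SS", kbt, x_b_duplex,
        _cfg_float(cfg, "peel_extension_nm"), _cfg_float(cfg, "peel_extension_at_pN"))
    spec.elastic = {("AT64", "B_FORM"): ds, ("AT64", "PEELED_SS"): ss}

    x_handle = _ext_fn(handle, 1, "HANDLE_SS", kbt)
    n_hop = int(cfg["hop_peeled_bp"])
    x_b_part = _ext_fn(ds, n_bp - n_hop, "B_FORM", kbt)
    x_ss_part = _ext_fn(ss, n_hop, "PEELED_SS", kbt)
    x_ss_full = _ext_fn(ss, n_bp, "PEELED_SS", kbt)

    states = {
        "B": MechState("B", "B", lambda f: x_b_duplex(f) + x_handle(f)),
        "I": MechState("I", "I",
                       lambda f: x_b_part(f) + x_ss_part(f) + x_handle(f)),
        "M": MechState("M", "M", lambda f: x_ss_full(f) + x_handle(f)),
    }

    r = protocol.nominal_loading_rate
    melt_x = _cfg_float(cfg, "melt_x_nm")
    k0_melt = calibrate_k0(_cfg_float(cfg, "melt_force_pN"), r, melt_x, kbt)
    rezip_x = _cfg_float(cfg, "rezip_x_nm")
    k0_rezip = calibrate_k0(_cfg_float(cfg, "rezip_force_pN"), r, -rezip_x, kbt)

    fc = _cfg_float(cfg, "hop_crossing_pN")
    dx_hop = states["I"].extension(fc) - states["B"].extension(fc)
    attempt = _cfg_float(cfg, "hop_attempt_rate_hz")
    transitions = _hop_pair("hop_open", "hop_close", "B", "I", fc, dx_hop,
                            attempt, kbt)
    # the melt hazard is identical from B and I so the rupture-force
    # distribution stays exactly Evans-Ritchie regardless of hopping
    transitions += [
        Transition("melt", "B", "M", k0_melt, melt_x),
        Transition("melt", "I", "M", k0_melt, melt_x),
        Transition("rezip", "M", "B", k0_rezip, -rezip_x),
    ]

    return Scenario(
        construct=spec, protocol=protocol, states=states,
        transitions=transitions, initial_state="B",
        noise_sd=_cfg_float(cfg, "noise_sd_pN"),
        hysteretic_pathway_probability=_cfg_float(cfg, "hysteretic_pathway_probability"),
        config=cfg)


def _build_three_five_prime_at(cfg: Dict[str, str]) -> Scenario:
    protocol = _protocol_from(cfg)
    kbt = protocol.kbt
    n_bp = int(cfg["duplex_bp"])
    handle = _handle(cfg)

    spec = ConstructSpec(
        name="THREE_FIVE_PRIME_AT", duplex_bp=n_bp,
        segments=[Segment("AT64", n_bp, "AT_RICH")],
        linker_config="BOTH_ENDS", salt=cfg["salt"], handle_params=handle)

    ds = ElasticParams(**DS_B)
    x_b_duplex = _ext_fn(ds, n_bp, "B_FORM", kbt)
    melted = _calibrate_contour(
        ElasticParams(**SS), n_bp, "MELTED_SHARED", kbt, x_b_duplex,
        _cfg_float(cfg, "melt_extension_nm"), _cfg_float(cfg, "melt_extension_at_pN"))
    spec.elastic = {("AT64", "B_FORM"): ds, ("AT64", "MELTED_SHARED"): melted}

    x_handle = _ext_fn(handle, 1, "HANDLE_SS", kbt)
    x_melted = _ext_fn(melted, n_bp, "MELTED_SHARED", kbt)

    noise = _cfg_float(cfg, "noise_sd_pN")
    p_hyst = _cfg_float(cfg, "hysteretic_pathway_probability")
    r = protocol.nominal_loading_rate

    if cfg.get("equilibrium_mode", "false").lower() == "true":
        f_tr = _cfg_float(cfg, "f_tr_pN")
        delta = _cfg_float(cfg, "cooperative_length_nm")

        def x_eq(f: float, _b=x_b_duplex, _m=x_melted, _h=x_handle) -> float:
            # instantaneous Boltzmann melt fraction: continuous transition
            phi = 1.0 / (1.0 + np.exp(-delta * (f - f_tr) / kbt))
            return (1.0 - phi) * _b(f) + phi * _m(f) + _h(f)

        states = {
            "EQ": MechState("EQ", "EQ", x_eq),
            "MOLTEN": MechState("MOLTEN", "M",
                                lambda f: x_melted(f) + x_handle(f)),
        }
        rz_x = _cfg_float(cfg, "hysteretic_rezip_x_nm")
        k0_rz = calibrate_k0(_cfg_float(cfg, "hysteretic_rezip_force_pN"), r,
                             -rz_x, kbt)
        transitions = [Transition("rezip", "MOLTEN", "EQ", k0_rz, -rz_x)]
        analysis = {
            "branch_low_window_pN": _cfg_floats(cfg, "branch_low_window_pN"),
            "branch_high_window_pN": _cfg_floats(cfg, "branch_high_window_pN"),
        }
        return Scenario(
            construct=spec, protocol=protocol, states=states,
            transitions=transitions, initial_state="EQ", noise_sd=noise,
            hysteretic_pathway_probability=p_hyst,
            frozen_relax=("EQ", "MOLTEN"), analysis=analysis, config=cfg)

    # low salt: single abrupt internal melt with hysteretic rezip
    states = {
        "B": MechState("B", "B", lambda f: x_b_duplex(f) + x_handle(f)),
        "MOLTEN": MechState("MOLTEN", "M", lambda f: x_melted(f) + x_handle(f)),
    }
    melt_x = _cfg_float(cfg, "melt_x_nm")
    rezip_x = _cfg_float(cfg, "rezip_x_nm")
    transitions = [
        Transition("melt", "B", "MOLTEN",
                   calibrate_k0(_cfg_float(cfg, "melt_force_pN"), r, melt_x, kbt),
                   melt_x),
        Transition("rezip", "MOLTEN", "B",
                   calibrate_k0(_cfg_float(cfg, "rezip_force_pN"), r, -rezip_x, kbt),
                   -rezip_x),
    ]
    return Scenario(
        construct=spec, protocol=protocol, states=states,
        transitions=transitions, initial_state="B", noise_sd=noise,
        hysteretic_pathway_probability=p_hyst, config=cfg)


def _build_atgc(cfg: Dict[str, str]) -> Scenario:
    protocol = _protocol_from(cfg)
    kbt = protocol.kbt
    at_bp = int(cfg["at_bp"])
    gc_bp = int(cfg["gc_bp"])
    handle = _handle(cfg)

    spec = ConstructSpec(
        name="ATGC", duplex_bp=at_bp + gc_bp,
        segments=[Segment("AT", at_bp, "AT_RICH"), Segment("GC", gc_bp, "GC_RICH")],
        linker_config="ONE_END", salt=cfg["salt"], handle_params=handle)

    ds = ElasticParams(**DS_B)
    x_at_b = _ext_fn(ds, at_bp, "B_FORM", kbt)
    x_gc_b = _ext_fn(ds, gc_bp, "B_FORM", kbt)
    x_all_b = _ext_fn(ds, at_bp + gc_bp, "B_FORM", kbt)
    x_handle = _ext_fn(handle, 1, "HANDLE_SS", kbt)

    # single-strand contour: AT-peel step equals the measured first step
    ss = _calibrate_contour(
        ElasticParams(**SS), at_bp, "PEELED_SS", kbt, x_at_b,
        _cfg_float(cfg, "peel_extension_nm"), _cfg_float(cfg, "peel_extension_at_pN"))
    x_at_peeled = _ext_fn(ss, at_bp, "PEELED_SS", kbt)

    # S-form contour: total stretched-minus-B separation equals the measured
    # total extension at the overall transition force
    def stretched_minus_b(c: float) -> float:
        p = replace(ElasticParams(**DS_S), contour_length_per_unit=c)
        f0 = _cfg_float(cfg, "total_extension_at_pN")
        return (x_at_peeled(f0) + _ext_fn(p, gc_bp, "S_FORM", kbt)(f0)
                - x_all_b(f0) - _cfg_float(cfg, "total_extension_nm"))

    c_s = brentq(stretched_minus_b, 0.35, 1.2, xtol=1e-12)
    s_form = replace(ElasticParams(**DS_S), contour_length_per_unit=c_s)
    x_gc_s = _ext_fn(s_form, gc_bp, "S_FORM", kbt)

    spec.elastic = {
        ("AT", "B_FORM"): ds, ("AT", "PEELED_SS"): ss,
        ("GC", "B_FORM"): ds, ("GC", "S_FORM"): s_form,
    }

    noise = _cfg_float(cfg, "noise_sd_pN")
    p_hyst = _cfg_float(cfg, "hysteretic_pathway_probability")
    attempt = _cfg_float(cfg, "attempt_rate_hz")
    r = protocol.nominal_loading_rate

    def x_b(f: float) -> float:
        return x_all_b(f) + x_handle(f)

    def x_stretched(f: float) -> float:
        return x_at_peeled(f) + x_gc_s(f) + x_handle(f)

    if cfg["salt"] == "HIGH_1M":
        f_i = _cfg_float(cfg, "f_tr_I_pN")
        f_ii = _cfg_float(cfg, "f_tr_II_pN")
        dx_i = _cfg_float(cfg, "x_intermediate_nm")
        dx_s = _cfg_float(cfg, "x_stretched_nm")

        # Intermediate branch: AT peeled + GC B-form, plus an excess
        # compliance active between the two crossing forces, sized so the
        # S-minus-I separation at F_tr_II equals the measured second step.
        # This realises the split-intermediate picture (an internal
        # sub-transition gives the intermediate its smaller force-position
        # gradient inside the transition region, saturating outside it).
        second = _cfg_float(cfg, "second_step_nm")

        def x_i_base(f: float) -> float:
            return x_at_peeled(f) + x_gc_b(f) + x_handle(f)

        c_extra = (x_stretched(f_ii) - x_i_base(f_ii) - second) / (f_ii - f_i)

        def x_intermediate(f: float) -> float:
            return x_i_base(f) + c_extra * (min(max(f, f_i), f_ii) - f_i)

        states = {
            "B": MechState("B", "B", x_b),
            "I": MechState("I", "I", x_intermediate),
            "S": MechState("S", "S", x_stretched),
        }
        transitions = (
            _hop_pair("a_open", "a_close", "B", "I", f_i, dx_i, attempt, kbt)
            + _hop_pair("b_open", "b_close", "I", "S", f_ii, dx_s - dx_i,
                        attempt, kbt))
        analysis = {"f_tr_I": (f_i,), "f_tr_II": (f_ii,)}
        return Scenario(
            construct=spec, protocol=protocol, states=states,
            transitions=transitions, initial_state="B", noise_sd=noise,
            hysteretic_pathway_probability=p_hyst, analysis=analysis,
            config=cfg)

    # low salt: split AT peel (a., a'.), B-to-S (b.), irreversible full melt
    n_half = int(cfg["half_peel_nt"])
    x_at_b_rest = _ext_fn(ds, at_bp - n_half, "B_FORM", kbt)
    x_at_half = _ext_fn(ss, n_half, "PEELED_SS", kbt)
    x_full_ss = _ext_fn(ss, at_bp + gc_bp, "PEELED_SS", kbt)

    states = {
        "B": MechState("B", "B", x_b),
        "I1": MechState("I1", "I1",
                        lambda f: x_at_half(f) + x_at_b_rest(f) + x_gc_b(f) + x_handle(f)),
        "I2": MechState("I2", "I2",
                        lambda f: x_at_peeled(f) + x_gc_b(f) + x_handle(f)),
        "S": MechState("S", "S", x_stretched),
        "M": MechState("M", "M", lambda f: x_full_ss(f) + x_handle(f)),
    }
    f_a = _cfg_float(cfg, "crossing_a_pN")
    f_a2 = _cfg_float(cfg, "crossing_a2_pN")
    f_b = _cfg_float(cfg, "crossing_b_pN")
    dx_a = states["I1"].extension(f_a) - states["B"].extension(f_a)
    dx_a2 = states["I2"].extension(f_a2) - states["I1"].extension(f_a2)
    dx_b = states["S"].extension(f_b) - states["I2"].extension(f_b)
    fm_x = _cfg_float(cfg, "full_melt_x_nm")
    rz_x = _cfg_float(cfg, "rezip_x_nm")
    transitions = (
        _hop_pair("a_open", "a_close", "B", "I1", f_a, dx_a, attempt, kbt)
        + _hop_pair("a2_open", "a2_close", "I1", "I2", f_a2, dx_a2, attempt, kbt)
        + _hop_pair("b_open", "b_close", "I2", "S", f_b, dx_b, attempt, kbt)
        + [
            Transition("full_melt", "S", "M",
                       calibrate_k0(_cfg_float(cfg, "full_melt_force_pN"), r,
                                    fm_x, kbt), fm_x),
            Transition("rezip", "M", "B",
                       calibrate_k0(_cfg_float(cfg, "rezip_force_pN"), r,
                                    -rz_x, kbt), -rz_x),
        ])
    return Scenario(
        construct=spec, protocol=protocol, states=states,
        transitions=transitions, initial_state="B", noise_sd=noise,
        hysteretic_pathway_probability=p_hyst, config=cfg)


_BUILDERS = {
    "FIVE_PRIME_AT": _build_five_prime_at,
    "THREE_FIVE_PRIME_AT": _build_three_five_prime_at,
    "ATGC": _build_atgc,
}

_FILE_SALT = {"HIGH_1M": "1M", "LOW_5MM": "5mM"}
_FILE_NAME = {"FIVE_PRIME_AT": "five_prime_at",
              "THREE_FIVE_PRIME_AT": "three_five_prime_at",
              "ATGC": "atgc"}


def available_scenarios() -> List[Tuple[str, str]]:
    """All (construct, salt) combinations shipped as package data."""
    return [(c, s) for c in CONSTRUCT_NAMES for s in SALT_NAMES]


def load_scenario(construct: str, salt: str,
                  config_path: Optional[str] = None,
                  **overrides) -> Scenario:
    """Build the simulation scenario for a construct x salt condition.

    Parameters are read from the shipped configuration file (or
    ``config_path`` if given); ``overrides`` replace individual configuration
    values, e.g. ``load_scenario("FIVE_PRIME_AT", "HIGH_1M",
    noise_sd_pN="0.1")``.
    """
    if construct not in CONSTRUCT_NAMES:
        raise ConfigError(f"unknown construct {construct!r}; "
                          f"expected one of {CONSTRUCT_NAMES}")
    if salt not in SALT_NAMES:
        raise ConfigError(f"unknown salt {salt!r}; expected one of {SALT_NAMES}")
    if config_path is not None:
        cfg = read_config(config_path)
    else:
        fname = f"{_FILE_NAME[construct]}_{_FILE_SALT[salt]}.cfg"
        ref = importlib.resources.files("forcemelt") / "configs" / fname
        with importlib.resources.as_file(ref) as path:
            cfg = read_config(path)
    cfg.update({k: str(v) for k, v in overrides.items()})
    if cfg["construct"] != construct or cfg["salt"] != salt:
        raise ConfigError("configuration file does not match requested "
                          f"construct/salt ({cfg.get('construct')}, {cfg.get('salt')})")
    return _BUILDERS[construct](cfg)
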