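"""Kinetic Monte-Carlo simulation of constant-velocity pull-relax cycles.

The trap moves at constant velocity; at every 1 kHz sample the force on the
construct is the root of the trap-construct force balance for the current
mechanical state (precomputed per state as a force -> trap-position grid and
inverted by interpolation).  Stochastic transitions fire with Bell rates via
a Gillespie loop inside each sampling interval, so fast bistable hopping and
rare rupture events are handled by the same machinery.  Every state change
lengthening the construct produces a force drop at fixed trap position, and
every shortening a force rise.

A ground-truth log records each transition (time, name, pre-event force, trap
position), the per-sample state labels, and the relaxation pathway drawn for
each cycle, so detectors and fits can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constructs import Scenario
from .trajectory_io import Trajectory

__all__ = [
    "Event",
    "CycleLog",
    "MoleculeLog",
    "simulate_cycle",
    "simulate_molecule",
    "write_log",
    "read_log",
]

_RATE_CAP = 1.0e7  # 1/s; bounds the Gillespie loop per sampling interval


@dataclass(frozen=True)
class Event:
    """One logged state change."""

    time: float
    name: str
    force: float  # pN, immediately before the transition
    trap_position: float  # nm


@dataclass
class CycleLog:
    """Ground truth for one pull-relax cycle."""

    cycle_index: int
    pathway: str  # REVERSIBLE or HYSTERETIC
    events: List[Event] = field(default_factory=list)
    state_labels: Optional[np.ndarray] = None  # per-sample state label

    def events_named(self, name: str) -> List[Event]:
        return [e for e in self.events if e.name == name]


@dataclass
class MoleculeLog:
    """Ground-truth log for a molecule: one :class:`CycleLog` per cycle."""

    cycles: List[CycleLog] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cycle": c.cycle_index, "time_s": e.time, "event": e.name,
             "force_pN": e.force, "trap_position_nm": e.trap_position}
            for c in self.cycles for e in c.events
        ]
        return pd.DataFrame(rows, columns=["cycle", "time_s", "event",
                                           "force_pN", "trap_position_nm"])


# ---------------------------------------------------------------------------
# scenario compilation: per-state force->trap-position grids

@dataclass
class _TransRec:
    name: str
    dst: str
    k0: float
    x_over_kbt: float
    is_event: bool


def _compile(scenario: Scenario):
    cached = scenario.__dict__.get("_compiled")
    if cached is not None:
        return cached
    p = scenario.protocol
    # hard cap of the modelled force range: the elasticity laws and state
    # machines are not meant to extrapolate beyond ~overstretching forces
    f_hi = 120.0
    if p.force_max > f_hi - 10.0:
        raise ValueError(
            f"force_max {p.force_max} pN unreachable within the modelled "
            f"force range (limit {f_hi - 10.0} pN)")
    f_grid = np.linspace(0.0, f_hi, int(round(f_hi / 0.05)) + 1)
    k = p.trap_stiffness
    xtrap = {}
    for name, st in scenario.states.items():
        x = np.array([st.extension(f) for f in f_grid])
        xtrap[name] = x + f_grid / k
    kbt = p.kbt
    trans: Dict[str, List[_TransRec]] = {name: [] for name in scenario.states}
    for tr in scenario.transitions:
        trans[tr.src].append(
            _TransRec(tr.name, tr.dst, tr.k0, tr.x_dagger / kbt, tr.is_event))
    compiled = {"f_grid": f_grid, "xtrap": xtrap, "trans": trans}
    scenario.__dict__["_compiled"] = compiled
    return compiled


def _rate(rec: _TransRec, force: float) -> float:
    arg = force * rec.x_over_kbt
    if arg > 700.0:
        arg = 700.0
    return min(rec.k0 * math.exp(arg), _RATE_CAP)


# ---------------------------------------------------------------------------

def simulate_cycle(scenario: Scenario, seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   pathway: Optional[str] = None, cycle_index: int = 0,
                   t0: float = 0.0) -> Tuple[Trajectory, CycleLog]:
    """Simulate one pull-relax cycle.

    The trap ramps up until the (noise-free) force reaches
    ``protocol.force_max``, then back down until ``protocol.force_min``.
    ``seed`` fixes all randomness (identical seed, identical output); a
    pre-built ``rng`` may be passed instead.  ``pathway`` forces the
    relaxation pathway; by default it is drawn with the scenario's
    hysteretic-pathway probability.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if pathway is None:
        pathway = ("HYSTERETIC"
                   if rng.random() < scenario.hysteretic_pathway_probability
                   else "REVERSIBLE")
    if pathway not in ("REVERSIBLE", "HYSTERETIC"):
        raise ValueError(f"unknown pathway {pathway!r}")

    comp = _compile(scenario)
    f_grid = comp["f_grid"]
    p = scenario.protocol
    if p.force_max > f_grid[-1]:
        raise ValueError(
            f"force_max {p.force_max} pN unreachable (grid limit {f_grid[-1]})")
    k, v = p.trap_stiffness, p.trap_velocity
    dt = 1.0 / p.sample_rate
    step = v * dt

    state = scenario.initial_state
    xg = comp["xtrap"]
    xtrap = float(np.interp(p.force_min, f_grid, xg[state]))
    t = t0

    times: List[float] = []
    positions: List[float] = []
    forces: List[float] = []
    labels: List[str] = []
    phases: List[str] = []
    events: List[Event] = []

    def force_at(state_name: str, x: float) -> float:
        return float(np.interp(x, xg[state_name], f_grid))

    # initial sample at the lower force limit
    f = force_at(state, xtrap)
    times.append(t)
    positions.append(xtrap)
    forces.append(f)
    labels.append(scenario.states[state].label)
    phases.append("PULL")

    span = (p.force_max - p.force_min) / k + 200.0
    max_steps = int(8 * span / step) + 1000

    for phase, direction in (("PULL", 1.0), ("RELAX", -1.0)):
        limit = p.force_max if phase == "PULL" else p.force_min
        if (phase == "RELAX" and pathway == "HYSTERETIC"
                and scenario.frozen_relax is not None
                and state == scenario.frozen_relax[0]):
            f_now = force_at(state, xtrap)
            state = scenario.frozen_relax[1]
            events.append(Event(t, "freeze", f_now, xtrap))
        steps = 0
        while True:
            trs = comp["trans"][state]
            if not trs:
                # no outgoing transitions: purely elastic to the phase end
                x_end = float(np.interp(limit, f_grid, xg[state]))
                n_steps = max(int(math.ceil((x_end - xtrap) / (direction * step))), 1)
                xs = xtrap + direction * step * np.arange(1, n_steps + 1)
                fs = np.interp(xs, xg[state], f_grid)
                ts = t + dt * np.arange(1, n_steps + 1)
                times.extend(ts.tolist())
                positions.extend(xs.tolist())
                forces.extend(fs.tolist())
                lab = scenario.states[state].label
                labels.extend([lab] * n_steps)
                phases.extend([phase] * n_steps)
                t = float(ts[-1])
                xtrap = float(xs[-1])
                break
            steps += 1
            if steps > max_steps:
                raise RuntimeError(
                    f"phase {phase} did not terminate within {max_steps} steps; "
                    f"force limit {limit} pN may be unreachable")
            xtrap += direction * step
            t += dt
            f = force_at(state, xtrap)
            # Gillespie within the sampling interval at fixed trap position
            t_local = 0.0
            while True:
                total = 0.0
                rates = []
                for rec in trs:
                    r = _rate(rec, f)
                    rates.append(r)
                    total += r
                if total * (dt - t_local) < 1e-9:
                    break
                tau = rng.exponential(1.0 / total)
                if t_local + tau > dt:
                    break
                t_local += tau
                u = rng.random() * total
                acc = 0.0
                chosen = trs[-1]
                for rec, r in zip(trs, rates):
                    acc += r
                    if u <= acc:
                        chosen = rec
                        break
                events.append(Event(t - dt + t_local, chosen.name, f, xtrap))
                state = chosen.dst
                trs = comp["trans"][state]
                f = force_at(state, xtrap)
            times.append(t)
            positions.append(xtrap)
            forces.append(f)
            labels.append(scenario.states[state].label)
            phases.append(phase)
            if (phase == "PULL" and f >= limit) or \
               (phase == "RELAX" and f <= limit):
                break

    force_arr = np.asarray(forces)
    if scenario.noise_sd > 0:
        force_arr = force_arr + rng.normal(0.0, scenario.noise_sd,
                                           size=force_arr.size)
    metadata = scenario.metadata()
    metadata.update({"seed": -1 if seed is None else int(seed),
                     "cycle": cycle_index, "pathway": pathway})
    traj = Trajectory(np.asarray(times), np.asarray(positions), force_arr,
                      metadata, np.asarray(phases))
    log = CycleLog(cycle_index, pathway, events, np.asarray(labels))
    return traj, log


def simulate_molecule(scenario: Scenario, n_cycles: int, seed: int,
                      hysteretic_pathway_probability: Optional[float] = None
                      ) -> Tuple[List[Trajectory], MoleculeLog]:
    """Simulate repeated pull-relax cycles on one molecule.

    Per relax phase the HYSTERETIC pathway is drawn independently with the
    given probability (default: the scenario's configured value) and recorded
    in the log.  Returns the per-cycle trajectories and the molecule log.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    prob = (scenario.hysteretic_pathway_probability
            if hysteretic_pathway_probability is None
            else hysteretic_pathway_probability)
    if not 0.0 <= prob <= 1.0:
        raise ValueError("hysteretic_pathway_probability must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cycles + 1)
    pathway_rng = np.random.default_rng(children[0])
    trajs: List[Trajectory] = []
    log = MoleculeLog()
    t0 = 0.0
    for i in range(n_cycles):
        pathway = ("HYSTERETIC" if pathway_rng.random() < prob
                   else "REVERSIBLE")
        traj, clog = simulate_cycle(
            scenario, rng=np.random.default_rng(children[i + 1]),
            pathway=pathway, cycle_index=i, t0=t0)
        t0 = float(traj.time[-1]) + 1.0 / scenario.protocol.sample_rate
        trajs.append(traj)
        log.cycles.append(clog)
    return trajs, log


# ---------------------------------------------------------------------------
# ground-truth log I/O (companion TSV)

_LOG_COLUMNS = ("cycle", "time_s", "event", "force_pN", "trap_position_nm")


def write_log(log: MoleculeLog, destination) -> None:
    lines = [f"# pathway_cycle_{c.cycle_index} = {c.pathway}"
             for c in log.cycles]
    lines.append("\t".join(_LOG_COLUMNS))
    for c in log.cycles:
        for e in c.events:
            lines.append(f"{c.cycle_index}\t{e.time:.12g}\t{e.name}\t"
                         f"{e.force:.12g}\t{e.trap_position:.12g}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_log(source) -> MoleculeLog:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    pathways: Dict[int, str] = {}
    rows: List[Tuple[int, float, str, float, float]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            key, value = (s.strip() for s in body.split("=", 1))
            pathways[int(key.rsplit("_", 1)[1])] = value
            continue
        parts = line.split("\t")
        if not header_seen:
            if tuple(parts) != _LOG_COLUMNS:
                raise ValueError(f"line {lineno}: bad log header {parts}")
            header_seen = True
            continue
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 columns")
        rows.append((int(parts[0]), float(parts[1]), parts[2],
                     float(parts[3]), float(parts[4])))
    log = MoleculeLog()
    indices = sorted(set(pathways) | {r[0] for r in rows})
    for idx in indices:
        events = [Event(t, name, f, x)
                  for (c, t, name, f, x) in rows if c == idx]
        log.cycles.append(
            CycleLog(idx, pathways.get(idx, "REVERSIBLE"), events))
    return log
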