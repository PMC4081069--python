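"""Detection of abrupt rips/zips, bistable hopping, and hysteresis.

A rip (abrupt lengthening during pull) appears as a distinct force drop at
nearly fixed trap position; a zip (abrupt shortening during relax) as a force
rise.  The detector compares the mean force of a leading window against the
trailing-window mean corrected for the loading ramp (estimated as the
phase-wide median force increment, which is robust to the events
themselves), so the constant ramp does not register as a jump.  The event
force convention is the force immediately preceding the jump, estimated from
the trailing window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .trajectory_io import Trajectory

__all__ = [
    "TransitionEvent",
    "HysteresisCall",
    "HoppingSegment",
    "detect_rips",
    "detect_hopping",
    "measure_extension",
    "classify_hysteresis",
]


@dataclass(frozen=True)
class TransitionEvent:
    """One detected abrupt extension (RIP) or contraction (ZIP)."""

    kind: str  # RIP or ZIP
    phase: str  # PULL or RELAX
    index: int  # sample index of the jump
    time: float
    force: float  # pN, immediately preceding the jump
    trap_position: float
    force_drop: float  # pN, magnitude of the force change
    extension_change: float  # nm, force_drop / stiffness (nan if unknown)


@dataclass(frozen=True)
class HysteresisCall:
    cycle_id: int
    verdict: str  # REVERSIBLE or HYSTERETIC
    rezip_force: Optional[float]
    max_gap: float  # pN, maximum pull-relax force gap at matched positions


@dataclass(frozen=True)
class HoppingSegment:
    start_index: int
    stop_index: int
    n_switches: int
    dwell_low: int  # samples assigned to the lower branch
    dwell_high: int
    upper_isolated: bool  # True if the longer state persists without return


def _rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def detect_rips(phase_traj: Trajectory, min_drop: float = 1.5,
                window: int = 30, stiffness: Optional[float] = None
                ) -> List[TransitionEvent]:
    """Locate abrupt force jumps in one pull or relax phase.

    A jump is scored at boundary ``i`` as the leading-window mean minus the
    ramp-corrected trailing-window mean; boundaries
    where the magnitude reaches ``min_drop`` are clustered (no two events
    closer than ``window`` samples) and refined to the largest single-sample
    force step.  ``stiffness`` (pN/nm) converts the force drop into the
    extension change of the event; if omitted it is taken from trajectory
    metadata when present.
    """
    f = phase_traj.force
    n = f.size
    if n < 2 * window:
        raise ValueError(f"need at least {2 * window} samples, got {n}")
    noise = phase_traj.metadata.get("noise_sd_pN")
    if noise is not None and min_drop < 3.0 * float(noise):
        warnings.warn(
            f"min_drop {min_drop} pN is below 3x the noise sd {noise} pN: "
            "high false-positive risk", stacklevel=2)
    if stiffness is None:
        stiffness = phase_traj.metadata.get("trap_stiffness_pN_nm")

    w = window
    # ramp slope per sample, from the phase-wide median increment: robust to
    # the events themselves, unlike a windowed linear fit
    med_slope = float(np.median(np.diff(f)))
    means = _rolling_mean(f, w)  # means[j] = mean(f[j:j+w])
    # boundary i uses trailing window f[i-w:i] and leading window f[i:i+w];
    # window centres are w samples apart
    pre_mean = means[:n - 2 * w + 1]
    post_mean = means[w:]
    jump = post_mean - (pre_mean + med_slope * w)
    bounds = np.arange(w, n - w + 1)

    hits = np.nonzero(np.abs(jump) >= min_drop)[0]
    events: List[TransitionEvent] = []
    phase_label = (str(phase_traj.phase[0]) if phase_traj.phase is not None
                   else "PULL")
    last_event = -10 * w
    i = 0
    while i < hits.size:
        j = i
        while j + 1 < hits.size and hits[j + 1] - hits[j] <= w:
            j += 1
        cluster = hits[i:j + 1]
        peak = cluster[np.argmax(np.abs(jump[cluster]))]
        boundary = bounds[peak]
        # refine to the largest single-sample step near the boundary
        lo = max(boundary - w, 1)
        hi = min(boundary + w, n - 1)
        steps = np.diff(f[lo - 1:hi])
        rel = np.argmax(np.abs(steps) * np.sign(steps) * np.sign(jump[peak]))
        event_idx = lo + rel  # first sample after the jump
        if event_idx - last_event >= w:
            drop = float(np.abs(jump[peak]))
            kind = "RIP" if jump[peak] < 0 else "ZIP"
            # trailing-window mean propagated to the last pre-event sample
            # (window centre sits (w + 1) / 2 samples before the boundary)
            pre_force = float(pre_mean[peak] + med_slope
                              * (event_idx - boundary + (w - 1) / 2.0))
            ext = drop / float(stiffness) if stiffness else float("nan")
            events.append(TransitionEvent(
                kind=kind, phase=phase_label, index=event_idx,
                time=float(phase_traj.time[event_idx]),
                force=pre_force,
                trap_position=float(phase_traj.trap_position[event_idx]),
                force_drop=drop, extension_change=ext))
            last_event = event_idx
        i = j + 1
    return events


def _branch_position(branch, force):
    if branch.slope == 0:
        raise ValueError("degenerate branch: zero slope")
    return (np.asarray(force, dtype=float) - branch.intercept) / branch.slope


def measure_extension(branch_low, branch_high, at_force: float) -> float:
    """Extension difference between two branches at a given force.

    Implements the convention of measuring relative extensions as the
    difference in trap position at a specific force: positive when
    ``branch_high`` is the longer state.  Evaluation outside a branch's
    fitted force window is permitted but flagged with a warning.
    """
    for br in (branch_low, branch_high):
        lo, hi = br.force_window
        if not (lo <= at_force <= hi):
            warnings.warn(
                f"extrapolating branch fitted on [{lo:.3g}, {hi:.3g}] pN to "
                f"{at_force:.3g} pN", stacklevel=2)
    pos_low = _branch_position(branch_low, at_force)
    pos_high = _branch_position(branch_high, at_force)
    if pos_high == pos_low and branch_low.slope == branch_high.slope \
            and branch_low.intercept != branch_high.intercept:
        raise ValueError("parallel-in-position degenerate branches")
    return float(pos_high - pos_low)


def detect_hopping(phase_traj: Trajectory, branch_low, branch_high,
                   min_switches: int = 4, max_gap: int = 500
                   ) -> List[HoppingSegment]:
    """Locate reversible two-state hopping between two fitted branches.

    Each sample is assigned to the branch minimising the trap-position
    residual at its force; contiguous stretches whose assignment alternates
    at least ``min_switches`` times (switches separated by at most
    ``max_gap`` samples) are reported with per-branch dwell counts.  Returns
    empty with a warning when the branches are separated by less than three
    residual standard deviations.
    """
    sep = abs(_branch_position(branch_high, branch_low.force_window[1])
              - _branch_position(branch_low, branch_low.force_window[1]))
    sigma = max(branch_low.residual_sd, branch_high.residual_sd)
    if branch_low.slope > 0 and sigma > 0 and sep < 3.0 * sigma / branch_low.slope:
        warnings.warn("branch separation below 3 sigma: hopping undetectable",
                      stacklevel=2)
        return []
    pos = phase_traj.trap_position
    f = phase_traj.force
    r_low = np.abs(pos - _branch_position(branch_low, f))
    r_high = np.abs(pos - _branch_position(branch_high, f))
    assign = (r_high < r_low).astype(int)  # 1 = upper branch
    switches = np.nonzero(np.diff(assign) != 0)[0]
    segments: List[HoppingSegment] = []
    i = 0
    while i < switches.size:
        j = i
        while j + 1 < switches.size and switches[j + 1] - switches[j] <= max_gap:
            j += 1
        count = j - i + 1
        if count >= min_switches:
            start = int(switches[i])
            stop = int(switches[j]) + 1
            seg = assign[start:stop + 1]
            upper_isolated = bool(assign[stop:].all()) and assign.size > stop
            segments.append(HoppingSegment(
                start_index=start, stop_index=stop, n_switches=count,
                dwell_low=int((seg == 0).sum()), dwell_high=int((seg == 1).sum()),
                upper_isolated=upper_isolated))
        i = j + 1
    return segments


def _binned_mean(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(x, edges) - 1
    out = np.full(edges.size - 1, np.nan)
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.any():
            out[b] = y[sel].mean()
    return out


def classify_hysteresis(pull: Trajectory, relax: Trajectory,
                        gap_threshold: float = 1.0,
                        bin_width_nm: float = 1.0,
                        cycle_id: int = 0) -> HysteresisCall:
    """Classify a pull-relax cycle as REVERSIBLE or HYSTERETIC.

    The pull and relax force-position curves are compared at matched trap
    positions (binned means over ``bin_width_nm``); the cycle is REVERSIBLE
    when the maximum force gap stays at or below ``gap_threshold``, otherwise
    HYSTERETIC with the rezip force taken from the relax-phase ZIP event.

    The 1 pN default threshold sits between the binned-noise scatter of
    reversible cycles (a few tenths of a pN) and the smallest genuine
    hysteresis loop of the constructs studied here; recordings with strong
    bistable hopping near a crossing may need a higher value.
    """
    lo = max(pull.trap_position.min(), relax.trap_position.min())
    hi = min(pull.trap_position.max(), relax.trap_position.max())
    if hi <= lo:
        raise ValueError("pull and relax phases share no trap-position range")
    edges = np.arange(lo, hi + bin_width_nm, bin_width_nm)
    if edges.size < 3:
        raise ValueError("overlapping trap-position range too narrow")
    f_pull = _binned_mean(pull.trap_position, pull.force, edges)
    f_relax = _binned_mean(relax.trap_position, relax.force, edges)
    gap = f_pull - f_relax
    valid = np.isfinite(gap)
    max_gap = float(np.nanmax(gap[valid])) if valid.any() else 0.0
    if max_gap <= gap_threshold:
        return HysteresisCall(cycle_id, "REVERSIBLE", None, max_gap)
    rezip = None
    try:
        zips = [e for e in detect_rips(relax, min_drop=min(1.0, gap_threshold))
                if e.kind == "ZIP"]
        if zips:
            rezip = max(zips, key=lambda e: e.force_drop).force
    except ValueError:
        pass
    return HysteresisCall(cycle_id, "HYSTERETIC", rezip, max_gap)
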