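"""End-to-end analysis pipelines: trajectory in, fitted quantities out.

These helpers chain segmentation, rip detection, branch fitting and the
equilibrium fits in the same way for simulated and recorded data.  Force is
boxcar-smoothed (default 25 ms) before extent-of-reaction computation for the
continuous internal-melting analysis; raw samples are used everywhere an
abrupt event must stay sharp.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import classify_hysteresis, detect_rips, measure_extension
from .equilibrium import (BranchFit, ThreeStateModel, ThreeStateResults,
                          TwoStateModel, TwoStateResults, assign_states,
                          fit_branches, population_curves, reaction_extent)
from .trajectory_io import Trajectory

__all__ = [
    "smooth_force",
    "PeelingCycleResult",
    "analyze_peeling_cycle",
    "two_state_from_cycles",
    "three_state_from_cycles",
]


@contextmanager
def _expected_extrapolation():
    # the per-event branch evaluation extrapolates a few pN by construction
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="extrapolating",
                                category=UserWarning)
        yield


def smooth_force(traj: Trajectory, window: int = 25) -> Trajectory:
    """Centred boxcar smoothing of the force channel (window in samples)."""
    if window <= 1:
        return traj
    kernel = np.ones(window) / window
    f = np.convolve(traj.force, kernel, mode="same")
    # repair the edge bias of the truncated kernel
    half = window // 2
    f[:half] = traj.force[:half]
    f[-half:] = traj.force[-half:]
    return Trajectory(traj.time, traj.trap_position, f, dict(traj.metadata),
                      traj.phase)


@dataclass
class PeelingCycleResult:
    """Per-cycle measurements for an abrupt (peeling-type) transition."""

    cycle_id: int
    melt_force: Optional[float]  # F_m, pN
    rezip_force: Optional[float]  # F_r, pN
    extension_at_melt: Optional[float]  # nm, branch separation at F_m
    contraction_at_rezip: Optional[float]  # nm
    verdict: Optional[str]
    max_gap: Optional[float]


def _clipped_branch(position: np.ndarray, force: np.ndarray,
                    window: Tuple[float, float], smooth: int = 10,
                    n_iter: int = 4, clip: float = 1.5) -> BranchFit:
    """Branch fit robust to bistable-hopping excursions.

    The force is boxcar-smoothed and samples whose force falls more than
    ``clip`` robust standard deviations *below* the fitted line are discarded
    and the line refitted: dwells on a longer (hopped) branch sit at lower
    force for the same trap position and would otherwise tilt the fit.
    """
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        force = np.convolve(force, kernel, mode="same")
    branch = fit_branches(position, force, [window])[0]
    for _ in range(n_iter):
        sel = (force >= window[0]) & (force <= window[1])
        resid = force[sel] - branch.force_at(position[sel])
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        keep = resid > -clip * sigma
        if keep.all() or keep.sum() < 10:
            break
        branch = fit_branches(position[sel][keep], force[sel][keep],
                              [window])[0]
    return branch


def _lower_branch(position: np.ndarray, force: np.ndarray,
                  event_force: float, span: float = 8.0,
                  smooth: int = 10) -> BranchFit:
    """B-form branch below a rip, avoiding the bistable-hopping region.

    An anchor fit well below the event locates the hopping onset (the force
    above which a sizeable fraction of samples drops below the anchor line);
    the branch is then fitted with one-sided clipping on a window capped at
    that onset, keeping the extrapolation to the event force short.
    """
    anchor_win = (event_force - 14.0, event_force - 8.0)
    anchor = _clipped_branch(position, force, anchor_win, smooth=smooth)
    kernel = np.ones(smooth) / smooth
    fs = np.convolve(force, kernel, mode="same")
    resid = fs - anchor.force_at(position)
    sigma = max(anchor.residual_sd, 1e-3)
    top = event_force - 4.0
    for centre in np.arange(event_force - 7.5, event_force - 3.5, 0.5):
        sel = (fs >= centre - 0.25) & (fs <= centre + 0.25)
        if sel.sum() >= 20 and np.mean(resid[sel] < -3.0 * sigma) > 0.3:
            top = centre - 0.5
            break
    return _clipped_branch(position, force, (top - span, top), smooth=smooth)


def _branches_around_event(traj: Trajectory, event_index: int,
                           event_force: float,
                           high_span: float = 7.0
                           ) -> Tuple[BranchFit, BranchFit]:
    """Linear branches below (pre-event) and above (post-event) a rip."""
    pos, f = traj.trap_position, traj.force
    pre = slice(0, event_index)
    post = slice(event_index + 1, len(traj))
    low = _lower_branch(pos[pre], f[pre], event_force)
    hi_vals = f[post]
    hi_lo = float(hi_vals.min()) if hi_vals.size else event_force
    high = fit_branches(pos[post], f[post],
                        [(hi_lo + 0.5, hi_lo + 0.5 + high_span)])[0]
    return low, high


def analyze_peeling_cycle(pull: Trajectory, relax: Trajectory,
                          min_drop: float = 1.5, window: int = 30,
                          gap_threshold: float = 1.0,
                          cycle_id: int = 0) -> PeelingCycleResult:
    """Measure melt/rezip forces, transition extension and hysteresis.

    The melt force is read off the pull phase as the force immediately before
    the first RIP; the transition extension is the separation of the pre- and
    post-event branch fits at that force.
    """
    rips = [e for e in detect_rips(pull, min_drop=min_drop, window=window)
            if e.kind == "RIP"]
    melt_force = ext = None
    if rips:
        ev = rips[0]
        low, high = _branches_around_event(pull, ev.index, ev.force)
        melt_force = ev.force
        with _expected_extrapolation():
            ext = measure_extension(low, high, ev.force)
    # rezip zips are smaller than melt rips (lower force, shorter
    # contraction), so the relax phase is scanned at a lower threshold
    zips = [e for e in detect_rips(relax, min_drop=min(min_drop, 1.2),
                                   window=window)
            if e.kind == "ZIP"]
    rezip_force = contraction = None
    if zips:
        ev = max(zips, key=lambda e: e.force_drop)
        rezip_force = ev.force
        # relax: pre-event branch is the long (molten) state, post the B-form
        pos, f = relax.trap_position, relax.force
        pre = slice(0, ev.index)
        post = slice(ev.index + 1, len(relax))
        molten = fit_branches(pos[pre], f[pre],
                              [(ev.force + 1.0, ev.force + 9.0)])[0]
        bform = fit_branches(pos[post], f[post],
                             [(max(ev.force - 8.0, 0.5), ev.force + 1.0)])[0]
        with _expected_extrapolation():
            contraction = measure_extension(bform, molten, ev.force)
    call = classify_hysteresis(pull, relax, gap_threshold=gap_threshold,
                               cycle_id=cycle_id)
    return PeelingCycleResult(cycle_id, melt_force, rezip_force, ext,
                              contraction, call.verdict, call.max_gap)


def two_state_from_cycles(cycles: Sequence[Tuple[Trajectory, Trajectory]],
                          low_window: Tuple[float, float],
                          high_window: Tuple[float, float],
                          kbt: float, smooth_window: int = 25,
                          margin: float = 0.5, bin_width: float = 0.25,
                          drop_hysteretic: bool = True,
                          gap_threshold: float = 1.0) -> TwoStateResults:
    """Two-state fit pooled over pull and relax phases of several cycles.

    Branches are fitted per phase in the given force windows; extent points
    between the windows (with ``margin`` pN clearance) are pooled, binned,
    and fitted to the logistic two-state law.  Relax phases classified
    HYSTERETIC are excluded by default: a molecule frozen in the molten
    state is not sampling the equilibrium populations.
    """
    forces: List[np.ndarray] = []
    extents: List[np.ndarray] = []
    for pull, relax in cycles:
        if (drop_hysteretic and pull is not None and relax is not None
                and classify_hysteresis(pull, relax,
                                        gap_threshold).verdict == "HYSTERETIC"):
            relax = None
        for phase in (pull, relax):
            if phase is None:
                continue
            tr = smooth_force(phase, smooth_window)
            low, high = fit_branches(tr.trap_position, tr.force,
                                     [low_window, high_window])
            f, phi = reaction_extent(
                tr.trap_position, tr.force, low, high,
                force_range=(low_window[1] + margin, high_window[0] - margin))
            forces.append(f)
            extents.append(phi)
    model = TwoStateModel(np.concatenate(forces), np.concatenate(extents),
                          kbt, bin_width=bin_width)
    return model.fit()


def three_state_from_cycles(cycles: Sequence[Tuple[Trajectory, Trajectory]],
                            windows: Sequence[Tuple[float, float]],
                            kbt: float, bin_width: float = 0.5,
                            fit_range: Optional[Tuple[float, float]] = None,
                            presmooth: int = 1, n_refine: int = 3
                            ) -> Tuple[ThreeStateResults, pd.DataFrame]:
    """Three-state population fit pooled over pull and relax phases.

    ``windows`` are the three branch force windows (B, intermediate,
    stretched).  The outer branches are fitted on the pooled samples with
    sigma-clipping; the intermediate branch, whose force window is never free
    of excursions to the flanking states, is refined by ``n_refine`` rounds
    of assign-then-refit on the samples labelled intermediate.  Every sample
    in ``fit_range`` (default: between the outer windows with 2 pN
    clearance) is then assigned to its nearest branch and the binned
    populations are fitted to the Boltzmann three-state model.  Returns the
    results plus the population table.
    """
    phases = [ph for cyc in cycles for ph in cyc if ph is not None]
    pos = np.concatenate([p.trap_position for p in phases])
    force = np.concatenate([p.force for p in phases])
    branches = list(fit_branches(pos, force, windows, robust=3))
    if fit_range is None:
        fit_range = (windows[0][1] + 2.0, windows[-1][0] - 2.0)
    sel = (force >= fit_range[0]) & (force <= fit_range[1])
    w_mid = windows[1]
    for _ in range(n_refine):
        labels = assign_states(pos[sel], force[sel], branches,
                               presmooth=presmooth)
        mid = (labels == 1) & (force[sel] >= w_mid[0]) & (force[sel] <= w_mid[1])
        if mid.sum() < 10:
            break
        slope, intercept = np.polyfit(pos[sel][mid], force[sel][mid], 1)
        resid = force[sel][mid] - (intercept + slope * pos[sel][mid])
        branches[1] = BranchFit(float(slope), float(intercept), w_mid,
                                float(resid.std()), int(mid.sum()))
    labels = assign_states(pos[sel], force[sel], branches,
                           presmooth=presmooth)
    pops, _dropped = population_curves(labels, force[sel],
                                       bin_width=bin_width)
    model = ThreeStateModel(pops, kbt)
    return model.fit(), pops
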