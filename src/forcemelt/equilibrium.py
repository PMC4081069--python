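"""Equilibrium models of the force-induced transitions.

This is the inference core of the package, organised as statsmodels-style
Model/Results pairs.

Two-state model
---------------
The extent of reaction phi(F) — the relative distance of each force-position
sample to linear fits below and above the transition region — is fitted to
the equilibrium two-state force law

    phi(F) = 1 / (1 + exp(-delta (F - F_tr) / kBT)),

where ``F_tr`` is the transition midpoint force and ``delta`` the cooperative
length: the transition distance in the Boltzmann exponent, which sets the
force width of the transition (F at phi=0.95 minus F at phi=0.05 equals
``2 ln(19) kBT / delta``).

Three-state model
-----------------
For a construct with an intermediate, per-sample state labels (assigned by
proximity to three branch fits) are binned in force into occupation
probabilities and fitted to Boltzmann populations

    P_i(F) = w_i / sum_j w_j,   w_i = exp(-(G_i - F x_i)/kBT),

with the B-form as reference (G_B = 0, x_B = 0).  Derived forces: F_tr^I
solves P_B = P_I (closed form G_I/x_I), F_tr^II solves P_I = P_S (closed
form (G_S - G_I)/(x_S - x_I)), and F_tr is the maximum of the intermediate
population (closed form (G_S + kBT ln(x_I/(x_S - x_I)))/x_S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

__all__ = [
    "BranchFit",
    "fit_branches",
    "branch_position",
    "reaction_extent",
    "TwoStateModel",
    "TwoStateResults",
    "assign_states",
    "population_curves",
    "ThreeStateModel",
    "ThreeStateResults",
]


@dataclass(frozen=True)
class BranchFit:
    """Least-squares linear force-versus-position model for one branch."""

    slope: float  # pN/nm
    intercept: float  # pN
    force_window: Tuple[float, float]
    residual_sd: float  # pN
    n: int

    def force_at(self, position) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(position, dtype=float)


def branch_position(branch: BranchFit, force) -> np.ndarray:
    """Trap position of a branch at the given force(s)."""
    if branch.slope == 0:
        raise ValueError("degenerate branch: zero slope")
    return (np.asarray(force, dtype=float) - branch.intercept) / branch.slope


def fit_branches(position: np.ndarray, force: np.ndarray,
                 force_windows: Sequence[Tuple[float, float]],
                 min_samples: int = 10, robust: int = 0) -> List[BranchFit]:
    """Ordinary least squares of force on trap position per force window.

    With ``robust > 0``, that many sigma-clipping passes are applied after
    the initial fit: samples further than 2.5 robust standard deviations (in
    force) from the line are discarded and the line refitted.  This guards a
    branch window against dwells of a neighbouring conformational state.
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    fits: List[BranchFit] = []
    for lo, hi in force_windows:
        sel = (force >= lo) & (force <= hi)
        n = int(sel.sum())
        if n < min_samples:
            raise ValueError(
                f"window ({lo}, {hi}) pN contains {n} samples (< {min_samples})")
        x, y = position[sel], force[sel]
        if np.ptp(x) == 0:
            raise ValueError(f"singular design in window ({lo}, {hi}): "
                             "constant trap position")
        slope, intercept = np.polyfit(x, y, 1)
        for _ in range(robust):
            resid = y - (intercept + slope * x)
            sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            keep = np.abs(resid) <= 2.5 * max(sigma, 1e-9)
            if keep.all() or keep.sum() < min_samples:
                break
            x, y = x[keep], y[keep]
            slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        sd = float(np.sqrt(resid @ resid / max(x.size - 2, 1)))
        fits.append(BranchFit(float(slope), float(intercept), (lo, hi), sd,
                              int(x.size)))
    return fits


def reaction_extent(position: np.ndarray, force: np.ndarray,
                    branch_low: BranchFit, branch_high: BranchFit,
                    force_range: Optional[Tuple[float, float]] = None,
                    clamp: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Extent of reaction phi for each sample in the transition region.

    phi is the relative distance of the sample's trap position to the two
    branch positions evaluated at the sample's force,
    ``(x - x_low(F)) / (x_high(F) - x_low(F))``, clamped to [0, 1].
    ``force_range`` restricts the samples used (default: between the two
    branch windows).  Warns when the branch separation is within three
    residual standard deviations.
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    if force_range is None:
        force_range = (branch_low.force_window[1], branch_high.force_window[0])
    sel = (force > force_range[0]) & (force < force_range[1])
    f = force[sel]
    x = position[sel]
    x_low = branch_position(branch_low, f)
    x_high = branch_position(branch_high, f)
    gap = x_high - x_low
    sigma = max(branch_low.residual_sd, branch_high.residual_sd)
    slope = min(abs(branch_low.slope), abs(branch_high.slope))
    if slope > 0 and gap.size and np.min(np.abs(gap)) < 3.0 * sigma / slope:
        warnings.warn("branch separation below 3x residual sd: extent is "
                      "ill-determined", stacklevel=2)
    phi = (x - x_low) / gap
    if clamp:
        phi = np.clip(phi, 0.0, 1.0)
    return f, phi


# ---------------------------------------------------------------------------
# two-state model


class TwoStateModel:
    """Equilibrium two-state fit of extent-of-reaction data.

    Parameters
    ----------
    force, extent : array_like
        Pooled extent-of-reaction points (phi in [0, 1]) versus force in pN.
    kbt : float
        Thermal energy in pN nm.
    weights : array_like, optional
        Per-point weights (1/sigma); default unweighted.
    bin_width : float, optional
        If set, points are first averaged in force bins of this width and
        the fit weighted by the inverse standard error per bin.
    """

    def __init__(self, force, extent, kbt: float, weights=None,
                 bin_width: Optional[float] = None):
        force = np.asarray(force, dtype=float)
        extent = np.asarray(extent, dtype=float)
        if force.size != extent.size:
            raise ValueError("force and extent must have equal length")
        if force.size < 5:
            raise ValueError("need at least 5 extent points")
        if bin_width is not None:
            force, extent, weights = self._bin(force, extent, bin_width)
        self.force = force
        self.extent = extent
        self.weights = None if weights is None else np.asarray(weights, float)
        self.kbt = float(kbt)
        if extent.min() > 0.2 or extent.max() < 0.8:
            warnings.warn("extent points do not span (0.2, 0.8): the "
                          "two-state fit may be poorly constrained",
                          stacklevel=2)

    @staticmethod
    def _bin(force, extent, width):
        edges = np.arange(force.min(), force.max() + width, width)
        idx = np.digitize(force, edges) - 1
        fs, ms, ws = [], [], []
        for b in range(edges.size - 1):
            sel = idx == b
            n = int(sel.sum())
            if n < 3:
                continue
            fs.append(force[sel].mean())
            ms.append(extent[sel].mean())
            se = extent[sel].std(ddof=1) / np.sqrt(n)
            ws.append(1.0 / max(se, 1e-3))
        return np.asarray(fs), np.asarray(ms), np.asarray(ws)

    def predict(self, force, f_tr: float, delta: float) -> np.ndarray:
        return expit(delta * (np.asarray(force, float) - f_tr) / self.kbt)

    def _initial(self) -> Tuple[float, float]:
        order = np.argsort(self.force)
        f, m = self.force[order], self.extent[order]
        f_tr0 = float(np.interp(0.5, np.clip(m, 0, 1), f))
        lo = float(np.interp(0.25, np.clip(m, 0, 1), f))
        hi = float(np.interp(0.75, np.clip(m, 0, 1), f))
        width = max(hi - lo, 0.5)
        delta0 = 2.0 * np.log(3.0) * self.kbt / width
        return f_tr0, delta0

    def fit(self, f_tr0: Optional[float] = None,
            delta0: Optional[float] = None) -> "TwoStateResults":
        """Weighted least squares of the logistic force law.

        Raises RuntimeError with the last iterate on non-convergence.
        """
        g0 = self._initial()
        params = Parameters()
        params.add("f_tr", value=f_tr0 if f_tr0 is not None else g0[0])
        params.add("delta", value=delta0 if delta0 is not None else g0[1],
                   min=1e-6)

        def residual(p):
            r = self.extent - self.predict(self.force, p["f_tr"].value,
                                           p["delta"].value)
            return r if self.weights is None else r * self.weights

        out = minimize(residual, params)
        if not out.success:
            raise RuntimeError(
                "two-state fit did not converge; last iterate "
                f"F_tr={out.params['f_tr'].value:.4g}, "
                f"delta={out.params['delta'].value:.4g}")
        return TwoStateResults(self, out)


class TwoStateResults:
    """Fitted two-state transition: midpoint force and cooperative length."""

    def __init__(self, model: TwoStateModel, minimizer_result):
        self.model = model
        self.mresult = minimizer_result
        self.f_tr = float(minimizer_result.params["f_tr"].value)
        self.delta = float(minimizer_result.params["delta"].value)
        self.f_tr_stderr = minimizer_result.params["f_tr"].stderr
        self.delta_stderr = minimizer_result.params["delta"].stderr
        self.covar = minimizer_result.covar
        self.redchi = minimizer_result.redchi
        self.nobs = int(minimizer_result.ndata)
        if not (model.force.min() <= self.f_tr <= model.force.max()):
            warnings.warn("fitted midpoint lies outside the observed force "
                          "range", stacklevel=2)

    def predict(self, force) -> np.ndarray:
        return self.model.predict(force, self.f_tr, self.delta)

    def transition_width(self, lo: float = 0.05, hi: float = 0.95) -> float:
        """Force interval between extents ``lo`` and ``hi`` (pN)."""
        logit = lambda p: np.log(p / (1.0 - p))
        return float((logit(hi) - logit(lo)) * self.model.kbt / self.delta)

    def summary(self) -> str:
        se = lambda v: "      --" if v is None else f"{v:8.3f}"
        lines = [
            "Two-state equilibrium transition",
            "=" * 44,
            f"{'':18s}{'value':>10s}{'stderr':>10s}",
            f"{'F_tr (pN)':18s}{self.f_tr:10.3f}{se(self.f_tr_stderr):>10s}",
            f"{'delta (nm)':18s}{self.delta:10.3f}{se(self.delta_stderr):>10s}",
            "-" * 44,
            f"{'n points':18s}{self.nobs:10d}",
            f"{'red. chi^2':18s}{self.redchi:10.3g}",
            f"{'width 5-95% (pN)':18s}{self.transition_width():10.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.force, self.model.extent, "o", ms=3, alpha=0.5,
                label="extent")
        fg = np.linspace(self.model.force.min(), self.model.force.max(), 200)
        ax.plot(fg, self.predict(fg), "r-", label="two-state fit")
        ax.set_xlabel("force (pN)")
        ax.set_ylabel("extent of reaction")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# three-state model

STATE_ORDER = ("B", "I", "S")


def assign_states(position: np.ndarray, force: np.ndarray,
                  branches: Sequence[BranchFit],
                  presmooth: int = 1) -> np.ndarray:
    """Assign each sample to the branch with the smallest position residual.

    ``branches`` are ordered by increasing extension (B, intermediate,
    stretched).  Ties break toward the lower-extension state.  ``presmooth``
    applies a centred running-median of that many samples to the force before
    computing residuals (1 = off).
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    if presmooth > 1:
        from scipy.ndimage import median_filter
        force = median_filter(force, size=presmooth, mode="nearest")
    resid = np.stack([np.abs(position - branch_position(br, force))
                      for br in branches])
    # bias lower-extension states by well under any physical scale so that
    # numerical ties resolve toward the lower state
    resid += 1e-9 * np.arange(len(branches))[:, None]
    return np.argmin(resid, axis=0)


def population_curves(labels: np.ndarray, forces: np.ndarray,
                      bin_width: float = 0.5, n_states: int = 3,
                      min_count: int = 5
                      ) -> Tuple[pd.DataFrame, List[float]]:
    """Occupation probability of each state per force bin.

    Returns a frame with columns ``force`` (bin centre), ``n`` and ``p_0`` ..
    ``p_{n_states-1}``, and the list of bin centres dropped for having fewer
    than ``min_count`` samples.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    labels = np.asarray(labels)
    forces = np.asarray(forces, dtype=float)
    lo = np.floor(forces.min() / bin_width) * bin_width
    edges = np.arange(lo, forces.max() + bin_width, bin_width)
    idx = np.digitize(forces, edges) - 1
    rows = []
    dropped: List[float] = []
    for b in range(edges.size - 1):
        centre = edges[b] + bin_width / 2.0
        sel = idx == b
        n = int(sel.sum())
        if n < min_count:
            if n > 0:
                dropped.append(float(centre))
            continue
        row = {"force": float(centre), "n": n}
        for s in range(n_states):
            row[f"p_{s}"] = float((labels[sel] == s).mean())
        rows.append(row)
    return pd.DataFrame(rows), dropped


class ThreeStateModel:
    """Boltzmann three-state population fit (B-form, intermediate, stretched).

    Built from the output of :func:`population_curves`.  Free parameters are
    the free-energy offsets and transition distances (G_I, x_I, G_S, x_S)
    with the B-form as reference; per-bin binomial variance is used as the
    fit weight.
    """

    def __init__(self, populations: pd.DataFrame, kbt: float):
        required = {"force", "n", "p_0", "p_1", "p_2"}
        if not required.issubset(populations.columns):
            raise ValueError(f"populations must have columns {sorted(required)}")
        if len(populations) < 4:
            raise ValueError("need at least 4 populated force bins")
        self.populations = populations.reset_index(drop=True)
        self.kbt = float(kbt)

    def predict(self, force, g_i, x_i, g_s, x_s) -> np.ndarray:
        """Populations (3, n) at the given forces for given parameters."""
        f = np.asarray(force, dtype=float)
        expo = np.stack([
            np.zeros_like(f),
            (f * x_i - g_i) / self.kbt,
            (f * x_s - g_s) / self.kbt,
        ])
        expo -= expo.max(axis=0, keepdims=True)
        w = np.exp(expo)
        return w / w.sum(axis=0, keepdims=True)

    def _initial(self):
        df = self.populations
        f = df["force"].to_numpy()
        # crossing estimates from the empirical curves
        d_bi = df["p_0"].to_numpy() - df["p_1"].to_numpy()
        d_is = df["p_1"].to_numpy() - df["p_2"].to_numpy()
        f_i = f[np.argmin(np.abs(d_bi))]
        f_ii = f[np.argmin(np.abs(d_is))]
        if f_ii <= f_i:
            f_ii = f_i + 1.0
        x_i, x_s = 8.0, 20.0
        return dict(g_i=f_i * x_i, x_i=x_i, g_s=f_i * x_i + f_ii * (x_s - x_i),
                    x_s=x_s)

    def fit(self) -> "ThreeStateResults":
        df = self.populations
        f = df["force"].to_numpy()
        n = df["n"].to_numpy()
        obs = df[["p_0", "p_1", "p_2"]].to_numpy().T
        sigma = np.sqrt(np.clip(obs * (1 - obs), 0.0025, None) / n)
        init = self._initial()
        params = Parameters()
        params.add("g_i", value=init["g_i"])
        params.add("x_i", value=init["x_i"], min=1e-3)
        params.add("g_s", value=init["g_s"])
        params.add("x_s", value=init["x_s"], min=1e-3)

        def residual(p):
            pred = self.predict(f, p["g_i"].value, p["x_i"].value,
                                p["g_s"].value, p["x_s"].value)
            return ((obs - pred) / sigma).ravel()

        out = minimize(residual, params)
        if not out.success:
            raise RuntimeError("three-state fit did not converge")
        return ThreeStateResults(self, out)


class ThreeStateResults:
    """Fitted three-state populations and the derived transition forces."""

    def __init__(self, model: ThreeStateModel, minimizer_result):
        self.model = model
        self.mresult = minimizer_result
        p = minimizer_result.params
        self.g_i = float(p["g_i"].value)
        self.x_i = float(p["x_i"].value)
        self.g_s = float(p["g_s"].value)
        self.x_s = float(p["x_s"].value)
        self.covar = minimizer_result.covar
        self.redchi = minimizer_result.redchi
        if not self.x_s > self.x_i > 0:
            warnings.warn("fitted transition distances violate "
                          "x_S > x_I > 0", stacklevel=2)
        self.degenerate = not self._intermediate_dominates()
        if self.degenerate:
            warnings.warn("intermediate population never exceeds both other "
                          "states: degenerate fit; crossings still reported",
                          stacklevel=2)

    # closed forms under the force-linear Boltzmann weights
    @property
    def f_tr_I(self) -> float:
        """B/intermediate population crossing, pN (= G_I / x_I)."""
        return self.g_i / self.x_i

    @property
    def f_tr_II(self) -> float:
        """Intermediate/stretched crossing, pN (= (G_S - G_I)/(x_S - x_I))."""
        return (self.g_s - self.g_i) / (self.x_s - self.x_i)

    @property
    def f_tr(self) -> float:
        """Force of maximum intermediate population, pN."""
        return (self.g_s + self.model.kbt
                * np.log(self.x_i / (self.x_s - self.x_i))) / self.x_s

    def populations(self, force) -> np.ndarray:
        return self.model.predict(force, self.g_i, self.x_i, self.g_s,
                                  self.x_s)

    def _intermediate_dominates(self) -> bool:
        p = self.populations(self.f_tr)
        return bool(p[1] >= p[0] and p[1] >= p[2])

    def crossing_numeric(self, which: str, bracket: float = 30.0) -> float:
        """Numerically locate a population crossing (oracle for closed forms).

        ``which`` is ``"BI"`` (P_B = P_I) or ``"IS"`` (P_I = P_S).
        """
        a, b = (0, 1) if which == "BI" else (1, 2)
        guess = self.f_tr_I if which == "BI" else self.f_tr_II

        def g(f):
            p = self.populations(f)
            return p[a] - p[b]

        return float(brentq(g, guess - bracket, guess + bracket,
                            xtol=1e-10))

    def f_tr_numeric(self) -> float:
        """Numerically locate the intermediate-population maximum."""
        res = minimize_scalar(lambda f: -self.populations(f)[1],
                              bracket=(self.f_tr_I, self.f_tr_II),
                              method="brent", options={"xtol": 1e-12})
        return float(res.x)

    def summary(self) -> str:
        lines = [
            "Three-state Boltzmann population fit",
            "=" * 48,
            f"{'':14s}{'G (pN nm)':>12s}{'x (nm)':>10s}",
            f"{'B (ref)':14s}{0.0:12.2f}{0.0:10.3f}",
            f"{'intermediate':14s}{self.g_i:12.2f}{self.x_i:10.3f}",
            f"{'stretched':14s}{self.g_s:12.2f}{self.x_s:10.3f}",
            "-" * 48,
            f"{'F_tr^I  (pN)':16s}{self.f_tr_I:10.3f}   (B = I crossing)",
            f"{'F_tr    (pN)':16s}{self.f_tr:10.3f}   (max intermediate)",
            f"{'F_tr^II (pN)':16s}{self.f_tr_II:10.3f}   (I = S crossing)",
            f"{'red. chi^2':16s}{self.redchi:10.3g}",
        ]
        if self.degenerate:
            lines.append("WARNING: degenerate fit (intermediate never dominant)")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        df = self.model.populations
        fg = np.linspace(df["force"].min(), df["force"].max(), 300)
        pred = self.populations(fg)
        for s, (name, colour) in enumerate(zip(("B-form", "intermediate",
                                                "stretched"),
                                               ("C0", "C2", "C3"))):
            ax.plot(df["force"], df[f"p_{s}"], "o", ms=4, color=colour)
            ax.plot(fg, pred[s], "-", color=colour, label=name)
        ax.set_xlabel("force (pN)")
        ax.set_ylabel("population")
        ax.legend()
        return ax
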