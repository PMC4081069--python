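"""Aggregation of per-cycle measurements and unit conversions for reporting.

Report fields are rounded half-up at the precision used throughout the
results (3 decimals for per-bp extensions); full precision is retained
internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "per_bp_extension",
    "bform_contour",
    "cooperative_length_bp",
    "MoleculeSummary",
    "aggregate",
]


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def per_bp_extension(extension: float, n_bp: int) -> float:
    """Transition extension per base pair, nm/bp, half-up to 3 decimals."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return _round_half_up(extension / n_bp, 3)


def bform_contour(n_bp: int, rise: float = 0.34) -> float:
    """B-form contour length in nm at the canonical 0.34 nm/bp rise."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return n_bp * rise


def cooperative_length_bp(delta: float, per_bp_midpoint: float) -> int:
    """Cooperative length in base pairs: delta over the per-bp midpoint
    extension, rounded half-up to the nearest integer."""
    if delta <= 0 or per_bp_midpoint <= 0:
        raise ValueError("delta and per_bp_midpoint must be > 0")
    return int(Decimal(repr(delta / per_bp_midpoint))
               .quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass
class MoleculeSummary:
    """Per-construct/salt summary statistics over cycles."""

    construct: str
    salt: str
    n_cycles: int
    mean_melt_force: Optional[float] = None
    sd_melt_force: Optional[float] = None
    mean_rezip_force: Optional[float] = None
    sd_rezip_force: Optional[float] = None
    mean_f_tr: Optional[float] = None
    sd_f_tr: Optional[float] = None
    mean_extension: Optional[float] = None
    sd_extension: Optional[float] = None
    per_bp: Optional[float] = None
    hysteretic_fraction: Optional[float] = None


def _stats(values: List[float]) -> Tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def aggregate(records: pd.DataFrame, duplex_bp: Optional[Dict[str, int]] = None,
              hist_bin: float = 1.0
              ) -> Tuple[pd.DataFrame, Dict[Tuple[str, str, str], Tuple[np.ndarray, np.ndarray]]]:
    """Summarise per-cycle measurements into a per-construct/salt table.

    ``records`` has one row per cycle with columns ``construct``, ``salt``
    and any of ``melt_force``, ``rezip_force``, ``f_tr``, ``extension``,
    ``verdict``.  Returns the summary frame plus force histograms
    (counts, bin edges) keyed by (construct, salt, quantity) with the given
    bin width in pN.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    duplex_bp = duplex_bp or {}
    rows = []
    histograms: Dict[Tuple[str, str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for (construct, salt), grp in records.groupby(["construct", "salt"],
                                                  sort=True):
        summ = MoleculeSummary(construct=construct, salt=salt,
                               n_cycles=len(grp))

        def column(name: str) -> List[float]:
            if name not in grp.columns:
                return []
            return [float(v) for v in grp[name] if pd.notna(v)]

        summ.mean_melt_force, summ.sd_melt_force = _stats(column("melt_force"))
        summ.mean_rezip_force, summ.sd_rezip_force = _stats(column("rezip_force"))
        summ.mean_f_tr, summ.sd_f_tr = _stats(column("f_tr"))
        summ.mean_extension, summ.sd_extension = _stats(column("extension"))
        if summ.mean_extension is not None and construct in duplex_bp:
            summ.per_bp = per_bp_extension(summ.mean_extension,
                                           duplex_bp[construct])
        if "verdict" in grp.columns:
            verdicts = grp["verdict"].dropna()
            if len(verdicts):
                summ.hysteretic_fraction = float(
                    (verdicts == "HYSTERETIC").mean())
        for name in ("melt_force", "rezip_force"):
            vals = column(name)
            if vals:
                lo = np.floor(min(vals) / hist_bin) * hist_bin
                hi = np.ceil(max(vals) / hist_bin) * hist_bin + hist_bin
                edges = np.arange(lo, hi, hist_bin)
                counts, edges = np.histogram(vals, bins=edges)
                histograms[(construct, salt, name)] = (counts, edges)
        rows.append(vars(summ))
    return pd.DataFrame(rows), histograms
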