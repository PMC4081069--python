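"""Plain-text trajectory and ground-truth-log I/O, and pull/relax segmentation.

Dialect: tab-separated columns ``time_s``, ``trap_position_nm``, ``force_pN``
preceded by ``# key = value`` metadata lines (UTF-8, ``.`` decimal
separator).  Ground-truth logs are a companion TSV with columns ``cycle``,
``time_s``, ``event``, ``force_pN``, ``trap_position_nm``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryFormatError",
    "REQUIRED_METADATA",
    "write_trajectory",
    "read_trajectory",
    "segment_cycles",
    "concat_trajectories",
]

REQUIRED_METADATA = ("construct", "salt", "temperature_C",
                     "trap_stiffness_pN_nm", "trap_velocity_nm_s",
                     "sample_rate_hz")

_COLUMNS = ("time_s", "trap_position_nm", "force_pN")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


@dataclass
class Trajectory:
    """Time-ordered (time, trap position, force) samples with metadata.

    ``phase`` is an optional per-sample label array (``"PULL"``/``"RELAX"``),
    set by the simulator or by :func:`segment_cycles`.
    """

    time: np.ndarray
    trap_position: np.ndarray
    force: np.ndarray
    metadata: Dict[str, object] = field(default_factory=dict)
    phase: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.trap_position = np.asarray(self.trap_position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.trap_position.size != n or self.force.size != n:
            raise ValueError("time, trap_position and force must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.size != n:
                raise ValueError("phase labels must match sample count")

    def __len__(self) -> int:
        return self.time.size

    def slice(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            self.time[start:stop], self.trap_position[start:stop],
            self.force[start:stop], dict(self.metadata),
            None if self.phase is None else self.phase[start:stop])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time,
            "trap_position_nm": self.trap_position,
            "force_pN": self.force,
        })
        if self.phase is not None:
            df["phase"] = self.phase
        return df


def _format_meta_value(v: object) -> str:
    if isinstance(v, float):
        return format(v, ".12g")
    return str(v)


def write_trajectory(traj: Trajectory, destination) -> None:
    """Write a trajectory in the TSV dialect (metadata then a header row)."""
    missing = [k for k in REQUIRED_METADATA if k not in traj.metadata]
    if missing:
        raise TrajectoryFormatError(f"missing metadata keys: {missing}")
    lines = [f"# {k} = {_format_meta_value(v)}" for k, v in traj.metadata.items()]
    lines.append("\t".join(_COLUMNS))
    for t, x, f in zip(traj.time, traj.trap_position, traj.force):
        lines.append(f"{t:.12g}\t{x:.12g}\t{f:.12g}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def read_trajectory(source) -> Trajectory:
    """Read a trajectory file; raises :class:`TrajectoryFormatError` with the
    offending line number on malformed input."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    metadata: Dict[str, object] = {}
    rows: List[Tuple[float, float, float]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise TrajectoryFormatError(
                    f"line {lineno}: metadata line without '=': {raw!r}")
            key, value = (p.strip() for p in body.split("=", 1))
            metadata[key] = _parse_meta_value(value)
            continue
        parts = line.split("\t")
        if not header_seen:
            if tuple(parts) != _COLUMNS:
                raise TrajectoryFormatError(
                    f"line {lineno}: expected header {_COLUMNS}, got {parts}")
            header_seen = True
            continue
        if len(parts) != 3:
            raise TrajectoryFormatError(
                f"line {lineno}: expected 3 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError:
            raise TrajectoryFormatError(
                f"line {lineno}: non-numeric sample {raw!r}") from None
    missing = [k for k in REQUIRED_METADATA if k not in metadata]
    if missing:
        raise TrajectoryFormatError(f"missing metadata keys: {missing}")
    if not rows:
        raise TrajectoryFormatError("no samples in file")
    arr = np.asarray(rows, dtype=float)
    return Trajectory(arr[:, 0], arr[:, 1], arr[:, 2], metadata)


def concat_trajectories(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate consecutive trajectories (e.g. cycles of one molecule)."""
    if not trajs:
        raise ValueError("no trajectories to concatenate")
    phase = None
    if all(t.phase is not None for t in trajs):
        phase = np.concatenate([t.phase for t in trajs])
    return Trajectory(
        np.concatenate([t.time for t in trajs]),
        np.concatenate([t.trap_position for t in trajs]),
        np.concatenate([t.force for t in trajs]),
        dict(trajs[0].metadata), phase)


def segment_cycles(traj: Trajectory, smooth_window: int = 50
                   ) -> List[Tuple[Optional[Trajectory], Optional[Trajectory]]]:
    """Split a recording into (pull, relax) phase pairs.

    Phase boundaries sit at sign changes of the trap velocity, smoothed over
    ``smooth_window`` samples (default 50 = 50 ms at 1 kHz) to suppress
    noise-induced sign flips.  Each cycle is one PULL phase plus the following
    RELAX phase; a missing partner is returned as ``None``.  A recording with
    no direction change yields a single-phase result and a warning.
    """
    n = len(traj)
    if n < 2:
        warnings.warn("trajectory too short to segment", stacklevel=2)
        return [(traj, None)]
    v = np.diff(traj.trap_position)
    if smooth_window > 1:
        w = min(smooth_window, v.size)
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    sign = np.where(v >= 0, 1, -1)
    # sign[i] is the smoothed direction of the step into sample i+1; a flip
    # between sign[i] and sign[i+1] puts the turnaround at sample i+1, which
    # is kept as the last sample of the finishing phase
    flips = np.nonzero(np.diff(sign) != 0)[0]
    starts = [0, *(int(i) + 2 for i in flips)]
    segments: List[Tuple[int, int, int]] = []  # (start, stop, direction)
    for k, a in enumerate(starts):
        b = starts[k + 1] if k + 1 < len(starts) else n
        if b <= a:
            continue
        direction = int(sign[max(a - 1, 0)])
        segments.append((a, b, direction))
    if len(segments) == 1:
        warnings.warn("no trap direction change found: single-phase recording",
                      stacklevel=2)
        a, b, d = segments[0]
        phase = traj.slice(a, b)
        phase.phase = np.full(len(phase), "PULL" if d > 0 else "RELAX")
        return [(phase, None) if d > 0 else (None, phase)]
    cycles: List[Tuple[Optional[Trajectory], Optional[Trajectory]]] = []
    i = 0
    while i < len(segments):
        a, b, d = segments[i]
        part = traj.slice(a, b)
        part.phase = np.full(len(part), "PULL" if d > 0 else "RELAX")
        if d > 0:
            relax = None
            if i + 1 < len(segments) and segments[i + 1][2] < 0:
                a2, b2, _ = segments[i + 1]
                relax = traj.slice(a2, b2)
                relax.phase = np.full(len(relax), "RELAX")
                i += 1
            cycles.append((part, relax))
        else:
            cycles.append((None, part))
        i += 1
    return cycles
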