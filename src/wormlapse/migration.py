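"""Distal-tip-cell (DTC) migration: trajectories, smoothing, velocities, events.

The two gonadal distal tip cells trace a U-shaped path over roughly 30 h:
outward along the ventral side during L2-L3, a rapid ventral-to-dorsal turn
near the end of L3 (about 3 h), and inward movement on the dorsal side during
L4.  Positions are body coordinates (s, t); ``s`` is measured relative to a
stage-appropriate origin — the midbody (halfway between the posterior
pharyngeal bulb and the anus) for L1-L3, or the vulval invagination for
L3-L4.  Small apparent A-P shifts between the Z-slices containing a DTC are
corrected by subtracting the mean displacement of anatomical markers seen in
both slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .staging import DevelopmentalTimeline

__all__ = [
    "Trajectory",
    "AnatomicalMarkers",
    "correct_ap_offset",
    "reference_origin",
    "smooth_trajectory",
    "velocity",
    "align_to_event",
    "cohort_average",
    "detect_midline_crossing",
]


@dataclass(frozen=True)
class Trajectory:
    """(time, s, t) samples of one migrating cell; times strictly increasing."""

    cell: str
    time_h: np.ndarray
    s_um: np.ndarray
    t_um: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time_h", "s_um", "t_um"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if not (len(self.time_h) == len(self.s_um) == len(self.t_um)):
            raise ValueError("time, s and t must have equal length")
        if len(self.time_h) and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell": self.cell, "time_h": self.time_h,
             "s_um": self.s_um, "t_um": self.t_um}
        )


@dataclass
class AnatomicalMarkers:
    """Per-Z-slice arc-length positions (um) of anatomical reference
    structures (pharyngeal bulbs, vulva, anus): ``positions[slice][marker]``."""

    positions: dict[int, dict[str, float]] = field(default_factory=dict)

    def displacement(self, slice_a: int, slice_b: int) -> float | None:
        """Mean A-P displacement (um) of markers seen in both slices, or
        ``None`` when no marker is shared."""
        a = self.positions.get(slice_a, {})
        b = self.positions.get(slice_b, {})
        shared = sorted(set(a) & set(b))
        if not shared:
            return None
        return float(np.mean([b[m] - a[m] for m in shared]))


def correct_ap_offset(
    raw_s: float,
    markers: AnatomicalMarkers,
    slice_pair: tuple[int, int],
) -> float:
    """Correct a DTC A-P position for body movement between two Z-slices.

    ``slice_pair`` is (reference slice, slice containing the DTC); the mean
    marker displacement between them is subtracted from ``raw_s``.  With no
    shared marker the correction is skipped with a warning.
    """
    ds = markers.displacement(*slice_pair)
    if ds is None:
        warnings.warn(
            f"no anatomical marker shared between Z-slices {slice_pair}; "
            "A-P offset correction skipped",
            stacklevel=2,
        )
        return raw_s
    return raw_s - ds


def reference_origin(
    markers: dict[str, float], stage: str, axis=None
) -> float:
    """Arc-length origin (um) for DTC positions at a given larval stage.

    L1-L3: the midbody, halfway between the posterior pharyngeal bulb and
    the anus; L4 (and late L3 where annotated): the vulval invagination.
    ``markers`` maps marker names (``posterior_bulb``, ``anus``, ``vulva``)
    to arc-length positions.
    """
    if stage in ("L1", "L2", "L3"):
        missing = [m for m in ("posterior_bulb", "anus") if m not in markers]
        if missing:
            raise ValueError(f"missing anatomical marker(s): {missing}")
        return 0.5 * (markers["posterior_bulb"] + markers["anus"])
    if stage == "L4":
        if "vulva" not in markers:
            raise ValueError("missing anatomical marker(s): ['vulva']")
        return markers["vulva"]
    raise ValueError(f"no DTC reference origin defined for stage {stage!r}")


def _sliding_average(time: np.ndarray, values: np.ndarray, window: float):
    half = window / 2.0
    out = np.empty_like(values)
    for i, t0 in enumerate(time):
        sel = np.abs(time - t0) <= half + 1e-12
        out[i] = values[sel].mean()
    return out


def smooth_trajectory(traj: Trajectory, window: float = 1.0) -> Trajectory:
    """Centred sliding average of the (s, t) series with a time window (h).

    Samples within +-window/2 of each time point are averaged with uniform
    weight; the window truncates at the trajectory ends (no padding).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return replace(
        traj,
        s_um=_sliding_average(traj.time_h, traj.s_um, window),
        t_um=_sliding_average(traj.time_h, traj.t_um, window),
    )


def _central_diff(time: np.ndarray, values: np.ndarray) -> np.ndarray:
    v = np.empty_like(values)
    v[1:-1] = (values[2:] - values[:-2]) / (time[2:] - time[:-2])
    v[0] = (values[1] - values[0]) / (time[1] - time[0])
    v[-1] = (values[-1] - values[-2]) / (time[-1] - time[-2])
    return v


def velocity(traj: Trajectory) -> pd.DataFrame:
    """A-P and D-V migration velocities (um/h) of a smoothed trajectory.

    Central finite differences on the actual (possibly non-uniform)
    timestamps, one-sided at the ends.  ``v_ap`` is signed so that positive
    means outward movement (away from the s origin) for both DTCs:
    ``v_ap = sign(s) * ds/dt``.  ``v_dv = dt/dt`` is positive dorsal-ward.
    """
    if len(traj) < 2:
        raise ValueError("velocity requires at least 2 samples")
    ds_dt = _central_diff(traj.time_h, traj.s_um)
    dt_dt = _central_diff(traj.time_h, traj.t_um)
    outward_sign = np.where(traj.s_um >= 0, 1.0, -1.0)
    return pd.DataFrame(
        {
            "time_h": traj.time_h,
            "v_ap_um_per_h": outward_sign * ds_dt,
            "v_dv_um_per_h": dt_dt,
        }
    )


def align_to_event(
    time_h: np.ndarray, tl: DevelopmentalTimeline, event: str
) -> np.ndarray:
    """Shift a time axis to hours relative to a timeline event (event = 0)."""
    return np.asarray(time_h, dtype=float) - tl.event_time(event)


def cohort_average(
    times: list[np.ndarray],
    values: list[np.ndarray],
    bin_edges: np.ndarray,
) -> pd.DataFrame:
    """Cross-animal average of aligned series on a common time grid.

    Returns per-bin mean, s.e.m. and the number of contributing samples.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    t_all = np.concatenate([np.asarray(t, float) for t in times])
    v_all = np.concatenate([np.asarray(v, float) for v in values])
    idx = np.digitize(t_all, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = v_all[idx == b]
        n = len(sel)
        rows.append(
            {
                "bin_centre_h": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                "mean": sel.mean() if n else np.nan,
                "sem": sel.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def detect_midline_crossing(
    traj: Trajectory, window: float = 1.0
) -> float | None:
    """First ventral-to-dorsal midline crossing time (h), or ``None``.

    The t series is smoothed with the standard 1 h sliding average; the
    first sign change from negative to positive is located by linear
    interpolation between the bracketing samples.
    """
    if len(traj) == 0:
        return None
    sm = smooth_trajectory(traj, window)
    t = sm.t_um
    for i in range(len(t) - 1):
        if t[i] < 0 <= t[i + 1]:
            if t[i + 1] == t[i]:
                return float(sm.time_h[i + 1])
            frac = -t[i] / (t[i + 1] - t[i])
            return float(sm.time_h[i] + frac * (sm.time_h[i + 1] - sm.time_h[i]))
    return None
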