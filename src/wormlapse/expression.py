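"""Reporter-expression quantification: kymographs, traces, nuclear masks, peaks.

Molting-cycle genes (e.g. *mlt-10*, *wrt-2*) pulse once per larval stage,
peaking shortly before each ecdysis.  This module quantifies such dynamics
from fluorescence channels:

* A-P kymographs — mean intensity versus normalized body position, averaging
  over a dorsoventral window |t| < 60 um, with positions expressed as % of
  body length so animals of different sizes align;
* regional traces — intensity integrated over 5%-of-body-length windows
  centred at 25, 50 and 75% of body length, and whole-animal totals;
* single-nucleus intensities — Otsu segmentation of a 5 um x 5 um region
  around an annotated nucleus, then the mean over the resulting mask;
* per-stage peak times — Gaussian smoothing (sigma = 1 h) followed by the
  in-stage argmax, optionally re-expressed relative to the ecdysis;
* pairwise Pearson correlation of traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .geometry import BodyAxis, PixelGrid, straighten_image
from .staging import STAGES, DevelopmentalTimeline

__all__ = [
    "Kymograph",
    "ExpressionTrace",
    "NuclearROI",
    "build_kymograph",
    "regional_trace",
    "total_intensity",
    "nuclear_mean_intensity",
    "smooth_trace",
    "detect_stage_peak",
    "peak_relative_to_event",
    "trace_correlation",
]


@dataclass(frozen=True)
class Kymograph:
    """Mean intensity indexed by (time point, normalized A-P position)."""

    values: np.ndarray  # (T, n_bins), >= 0 for physical intensities
    time_h: np.ndarray
    position_pct: np.ndarray  # bin centres, % of body length
    dv_window_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.time_h, name="time_h"),
            columns=pd.Index(np.round(self.position_pct, 3), name="position_pct"),
        )


@dataclass(frozen=True)
class ExpressionTrace:
    """Intensity time series for one cell or body region."""

    label: str
    time_h: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_h", np.asarray(self.time_h, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))
        if len(self.time_h) != len(self.intensity):
            raise ValueError("time and intensity must have equal length")
        if len(self.time_h) > 1 and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass(frozen=True)
class NuclearROI:
    """Square region around a nucleus with its Otsu segmentation mask."""

    centre_um: tuple[float, float]
    side_um: float
    threshold: float
    mask: np.ndarray  # boolean, shape of the ROI crop
    roi: np.ndarray  # the cropped intensities


def build_kymograph(
    frames: list[np.ndarray],
    axes: list[BodyAxis],
    time_h: np.ndarray,
    grid: PixelGrid,
    dv_window: float = 60.0,
    n_bins: int = 100,
) -> Kymograph:
    """A-P expression kymograph from fluorescence frames.

    For each time point the frame is resampled onto the body grid and the
    mean intensity within the dorsoventral window ``|t| < dv_window`` is
    binned into ``n_bins`` equal bins of normalized position s/L, so one row
    spans 0-100% of body length regardless of the animal's absolute size.
    """
    if dv_window <= 0:
        raise ValueError("D-V window must be positive")
    if not (len(frames) == len(axes) == len(time_h)):
        raise ValueError("frames, axes and time axis must have equal length")
    rows = np.empty((len(frames), n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for k, (frame, axis) in enumerate(zip(frames, axes)):
        st = straighten_image(frame, axis, half_width=dv_window, grid=grid)
        col_frac = (np.arange(st.shape[1]) + 0.5) / st.shape[1]
        which = np.clip(np.digitize(col_frac, edges) - 1, 0, n_bins - 1)
        col_mean = st.mean(axis=0)
        rows[k] = [
            col_mean[which == b].mean() if np.any(which == b) else np.nan
            for b in range(n_bins)
        ]
    centres = 100.0 * 0.5 * (edges[:-1] + edges[1:])
    return Kymograph(
        values=rows,
        time_h=np.asarray(time_h, float),
        position_pct=centres,
        dv_window_um=dv_window,
    )


def regional_trace(
    kymo: Kymograph, centre_pct: float, width_pct: float = 5.0
) -> ExpressionTrace:
    """Intensity integrated over a band of body length centred at
    ``centre_pct`` (e.g. 25, 50 or 75%) with width ``width_pct``."""
    if width_pct <= 0:
        raise ValueError("region width must be positive")
    lo, hi = centre_pct - width_pct / 2, centre_pct + width_pct / 2
    if lo < 0 or hi > 100:
        raise ValueError("region extends outside the body (0-100%)")
    sel = (kymo.position_pct >= lo) & (kymo.position_pct < hi)
    if not np.any(sel):
        raise ValueError("region narrower than one kymograph bin")
    return ExpressionTrace(
        label=f"region_{centre_pct:g}pct",
        time_h=kymo.time_h,
        intensity=np.nansum(kymo.values[:, sel], axis=1),
    )


def total_intensity(
    frame: np.ndarray,
    axis: BodyAxis,
    grid: PixelGrid,
    half_width: float = 60.0,
    subtract_background: bool = True,
) -> float:
    """Whole-animal fluorescence: summed intensity over the body band.

    The body region is ``|t| < half_width`` around the centre line, sampled
    on the straightened grid.  The per-pixel background, estimated as the
    median intensity of camera pixels outside the body band, is subtracted
    so constant illumination offsets cancel.
    """
    st = straighten_image(frame, axis, half_width=half_width, grid=grid)
    background = 0.0
    if subtract_background:
        frame = np.asarray(frame, dtype=float)
        yy, xx = np.meshgrid(
            np.arange(frame.shape[0]) * grid.pixel_size,
            np.arange(frame.shape[1]) * grid.pixel_size,
            indexing="ij",
        )
        # distance to the dense centre-line polyline approximates |t|
        from scipy.spatial import cKDTree

        tree = cKDTree(axis._points_dense[::5])
        dist, _ = tree.query(
            np.column_stack([xx.ravel(), yy.ravel()]),
            distance_upper_bound=half_width,
        )
        outside = ~np.isfinite(dist).reshape(frame.shape)
        if np.any(outside):
            background = float(np.median(frame[outside]))
    return float(np.sum(st - background))


def nuclear_mean_intensity(
    image: np.ndarray,
    roi_centre_um: tuple[float, float],
    grid: PixelGrid,
    roi_side_um: float = 5.0,
) -> tuple[float, NuclearROI]:
    """Mean nuclear intensity via Otsu segmentation of a square ROI.

    A ``roi_side_um`` x ``roi_side_um`` region (default 5 um) is cropped
    around the nucleus centre, an Otsu threshold computed on its histogram
    (one bin per integer grey level for integer images, so the threshold is
    the exact between-class-variance maximizer), and the mean intensity of
    above-threshold pixels returned together with the mask.
    """
    image = np.asarray(image)
    half_px = int(round(roi_side_um / (2 * grid.pixel_size)))
    cx, cy = (np.asarray(roi_centre_um, float) / grid.pixel_size).round().astype(int)
    y0, y1 = cy - half_px, cy + half_px + 1
    x0, x1 = cx - half_px, cx + half_px + 1
    if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValueError("nuclear ROI extends outside the image")
    roi = image[y0:y1, x0:x1]
    if np.ptp(roi) == 0:
        raise ValueError("no contrast for segmentation (uniform ROI)")
    if np.issubdtype(roi.dtype, np.integer):
        nbins = int(np.ptp(roi)) + 1
    else:
        nbins = 256
    thr = threshold_otsu(roi, nbins=nbins)
    mask = roi > thr
    if not np.any(mask):  # pragma: no cover - Otsu always leaves one class
        raise ValueError("segmentation produced an empty mask")
    result = NuclearROI(
        centre_um=tuple(np.asarray(roi_centre_um, float)),
        side_um=roi_side_um,
        threshold=float(thr),
        mask=mask,
        roi=roi.astype(float),
    )
    return float(roi[mask].mean()), result


def smooth_trace(
    trace: ExpressionTrace, sigma_h: float = 1.0
) -> ExpressionTrace:
    """Gaussian smoothing of an intensity series (sigma in hours).

    The kernel is evaluated on the actual timestamps, truncated at +-3
    sigma and renormalized, so irregular sampling and series edges are
    handled without padding.
    """
    if sigma_h <= 0:
        raise ValueError("filter width must be positive")
    t = trace.time_h
    out = np.empty_like(trace.intensity)
    for i, t0 in enumerate(t):
        dt = t - t0
        sel = np.abs(dt) <= 3 * sigma_h
        w = np.exp(-0.5 * (dt[sel] / sigma_h) ** 2)
        out[i] = np.sum(w * trace.intensity[sel]) / np.sum(w)
    return ExpressionTrace(trace.label, t, out)


def detect_stage_peak(
    trace: ExpressionTrace,
    tl: DevelopmentalTimeline,
    filter_width: float = 1.0,
) -> pd.DataFrame:
    """Per-larval-stage expression peak times.

    The trace is Gaussian-smoothed (sigma = ``filter_width`` hours) and, for
    each stage, the time of the in-stage maximum is reported.  Maxima at the
    first or last in-stage sample are flagged as boundary peaks (the true
    peak may lie outside the covered window).  Stages with no samples are
    reported as missing.
    """
    sm = smooth_trace(trace, filter_width)
    rows = []
    for stage in STAGES:
        t0, t1 = tl.stage_start(stage), tl.stage_end(stage)
        sel = np.flatnonzero((sm.time_h >= t0) & (sm.time_h < t1))
        if len(sel) == 0:
            rows.append({"stage": stage, "peak_time_h": np.nan, "boundary": False})
            continue
        k = sel[np.argmax(sm.intensity[sel])]
        rows.append(
            {
                "stage": stage,
                "peak_time_h": float(sm.time_h[k]),
                "boundary": bool(k == sel[0] or k == sel[-1]),
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def peak_relative_to_event(
    peaks: pd.DataFrame, tl: DevelopmentalTimeline, event_stage: str | None = None
) -> pd.Series:
    """Hours between each stage's expression peak and its ecdysis.

    Returns ``ecdysis_time - peak_time`` per stage (positive when the peak
    precedes the ecdysis, the normal physiology); restrict to one stage by
    passing ``event_stage``.
    """
    stages = [event_stage] if event_stage else list(peaks.index)
    out = {
        stage: tl.stage_end(stage) - peaks.loc[stage, "peak_time_h"]
        for stage in stages
    }
    return pd.Series(out, name="peak_lead_h")


def trace_correlation(a: ExpressionTrace, b: ExpressionTrace) -> float:
    """Pearson correlation R of two traces over their shared time points.

    Times are matched exactly (to 1e-9 h); at least 3 shared points are
    required.  A zero-variance trace has no defined correlation and yields
    NaN.
    """
    ta = np.round(a.time_h / 1e-9).astype(np.int64)
    tb = np.round(b.time_h / 1e-9).astype(np.int64)
    common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
    if len(common) < 3:
        raise ValueError("traces share fewer than 3 time points")
    xa, xb = a.intensity[ia], b.intensity[ib]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb).statistic)
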