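"""Ground-truthed synthetic worm movies for end-to-end pipeline testing.

The generator emulates a single larva developing in a microchamber, imaged
every 20 minutes from hatch to the L4 ecdysis: a bent, growing body rendered
in a transmitted-light channel (dark band on bright background) and a
fluorescence channel (nuclei as Gaussian spots on a dim body glow), together
with the complete ground truth — per-frame centre line and body length,
per-cell (s, t) and camera positions, the division schedule, the
developmental timeline, distal-tip-cell paths and per-cell expression
traces — and an annotation file identical in format to what a human
annotator would produce.

Defaults mirror the measured biology: mean larval-stage durations
(11.1, 7.3, 7.1, 10.2) h with animal-to-animal jitter (0.2, 0.2, 0.3, 0.4) h,
seam-cell division-time variability of 0.3 h, a ventral-to-dorsal DTC turn
lasting 3 h that straddles the L3 ecdysis, and molting-cycle expression
pulses peaking 1.1 h before each ecdysis.  Spatial scale is reduced to desk
size (1.5 um pixels, 256 x 256 frames, body growing from 100 to ~240 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotations import (
    AnimalAnnotations,
    CellAnnotation,
    FrameAnnotation,
    MarkerAnnotation,
)
from .geometry import BodyAxis, BodyPoint, PixelGrid, fit_body_axis, from_body_coords
from .lineage import LINEAGES, LineageTree, SeamCellID, wild_type_tree
from .migration import Trajectory
from .staging import STAGES, DevelopmentalTimeline

__all__ = ["WormConfig", "GroundTruth", "SyntheticMovie", "generate_movie", "generate_cohort"]

# fractional A-P anchor of each seam-cell founder
_SEAM_ANCHORS = {
    "H1": 0.10, "H2": 0.17, "V1": 0.25, "V2": 0.35, "V3": 0.45,
    "V4": 0.55, "V5": 0.65, "V6": 0.77, "T": 0.90,
}
# centre-early / head-and-tail-late division sequence (h, relative offsets)
_DIVISION_OFFSETS = {
    "H1": 0.30, "H2": 0.20, "V1": 0.05, "V2": -0.20, "V3": -0.40,
    "V4": -0.20, "V5": -0.30, "V6": 0.25, "T": 0.50,
}


@dataclass(frozen=True)
class WormConfig:
    """Parameters of the synthetic worm movie; the seed fixes every draw."""

    seed: int = 0
    # camera
    pixel_size_um: float = 1.5
    image_shape: tuple[int, int] = (256, 256)
    frame_interval_h: float = 1.0 / 3.0  # 20 min
    # timeline (h)
    hatch_h: float = 1.0
    stage_mean_h: tuple[float, ...] = (11.1, 7.3, 7.1, 10.2)
    stage_sd_h: tuple[float, ...] = (0.2, 0.2, 0.3, 0.4)
    # body geometry (um)
    length_at_hatch_um: float = 100.0
    growth_rates_um_per_h: tuple[float, ...] = (2.5, 3.5, 4.5, 5.0)
    body_half_width_um: float = 12.0
    midline_amplitude_um: float = 18.0
    midline_wavelength_um: float = 170.0
    bend_phase_step: float = 0.35  # rad random-walk step per frame
    rigid_jitter_um: float = 2.0
    n_centerline_points: int = 12
    # seam cells
    seam_t_um: float = -7.0  # ventral-side offset of seam nuclei
    division_offsets_h: dict = field(
        default_factory=lambda: dict(_DIVISION_OFFSETS)
    )
    division_sd_h: float = 0.3
    division_phase: float = 0.5  # fraction of stage at mean division
    l2_round_gap_h: float = 1.6  # L2 symmetric-to-asymmetric round spacing
    # distal tip cells
    dtc_t_um: float = -7.0
    dtc_outward_rate: float = 5.0  # um/h
    dtc_inward_rate: float = 6.0
    dtc_turn_lead_h: float = 3.0  # turn onset before L3 ecdysis
    dtc_turn_duration_h: float = 3.0
    dtc_anterior_cross_lead_h: float = 0.6
    interslice_shift_um: float = 2.0  # planted A-P shift between Z-slices
    # expression model
    pulse_amplitude: float = 120.0
    pulse_width_h: float = 1.0
    pulse_lag_h: float = 1.1  # peak precedes each ecdysis by this much
    expression_noise_sd: float = 24.0  # SNR 5 at default amplitude
    expression_cells: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5")
    # rendering
    nucleus_sigma_um: float = 1.6
    fluor_background: float = 10.0
    body_glow: float = 6.0
    read_noise_sd: float = 2.0
    trans_background: float = 200.0
    trans_body: float = 80.0

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(self.pixel_size_um)


@dataclass
class GroundTruth:
    """Everything the generator knows, for direct comparison with analysis."""

    timeline: DevelopmentalTimeline
    time_h: np.ndarray
    axes: list[BodyAxis]  # true per-frame geometry
    body_length_um: np.ndarray
    cells: pd.DataFrame  # frame, time_h, name, s_um, t_um, x_um, y_um
    lineage: LineageTree
    dtc: dict[str, Trajectory]  # s relative to the midbody origin
    interslice_shift_um: np.ndarray
    expression: pd.DataFrame  # time_h, cell, intensity (noisy), signal (clean)


@dataclass
class SyntheticMovie:
    config: WormConfig
    truth: GroundTruth
    annotations: AnimalAnnotations
    fluorescence: np.ndarray | None  # (T, H, W) float32
    transmitted: np.ndarray | None


# ---------------------------------------------------------------------------
# timeline and scalar schedules


def _sample_timeline(cfg: WormConfig, rng: np.random.Generator) -> DevelopmentalTimeline:
    durations = np.asarray(cfg.stage_mean_h) + rng.normal(
        0.0, cfg.stage_sd_h, size=4
    )
    if np.any(durations <= 0):
        raise ValueError("sampled non-positive stage duration; reduce jitter")
    ecd = cfg.hatch_h + np.cumsum(durations)
    return DevelopmentalTimeline(cfg.hatch_h, tuple(ecd))


def _body_length_at(cfg: WormConfig, tl: DevelopmentalTimeline, t: float) -> float:
    """Piecewise-linear growth: stage-dependent rate, frozen after L4 ecdysis."""
    length = cfg.length_at_hatch_um
    starts = [tl.hatch_time, *tl.ecdysis_times[:3]]
    ends = list(tl.ecdysis_times)
    for rate, t0, t1 in zip(cfg.growth_rates_um_per_h, starts, ends):
        length += rate * max(0.0, min(t, t1) - t0)
    return length


def _pulse_signal(cfg: WormConfig, tl: DevelopmentalTimeline, t: np.ndarray) -> np.ndarray:
    """Sum of per-stage Gaussian expression pulses, one peak per stage."""
    sig = np.zeros_like(t, dtype=float)
    for stage in STAGES:
        peak = tl.stage_end(stage) - cfg.pulse_lag_h
        sig += cfg.pulse_amplitude * np.exp(
            -0.5 * ((t - peak) / cfg.pulse_width_h) ** 2
        )
    return sig


# ---------------------------------------------------------------------------
# geometry


def _sine_extent(length: float, amplitude: float, wavelength: float) -> float:
    """x-extent whose sine arc y = A sin(2 pi x / lam) has the given arc length."""
    k = 2 * np.pi / wavelength
    x = np.linspace(0.0, 2.0 * length, 4000)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(amplitude * np.sin(k * x))))]
    )
    return float(np.interp(length, arc, x))


def _true_axis(
    cfg: WormConfig, length: float, phase: float, offset: np.ndarray
) -> BodyAxis:
    """Ground-truth axis: spline through 40 dense points of a bent midline."""
    k = 2 * np.pi / cfg.midline_wavelength_um
    extent = _sine_extent(length, cfg.midline_amplitude_um, cfg.midline_wavelength_um)
    h, w = cfg.image_shape
    centre = np.array([w, h], dtype=float) * cfg.pixel_size_um / 2.0
    x = np.linspace(0.0, extent, 40)
    y = cfg.midline_amplitude_um * np.sin(k * x + phase)
    pts = np.column_stack([x - extent / 2.0, y - y.mean()]) + centre + offset
    # provisional marker on one fixed side; that side becomes "ventral"
    mid = len(x) // 2
    tang = pts[mid + 1] - pts[mid - 1]
    tang = tang / np.linalg.norm(tang)
    marker = pts[mid] + 16.0 * np.array([-tang[1], tang[0]])
    return fit_body_axis(pts, marker)


# ---------------------------------------------------------------------------
# division schedule


def _division_times(cfg: WormConfig, tl: DevelopmentalTimeline, rng):
    """Division-time callable for :func:`wild_type_tree`.

    Mean time sits at ``division_phase`` of the stage plus the per-lineage
    offset (centre cells early, head/tail late); cell-to-cell noise has
    s.d. ``division_sd_h``.  L2 second-round (asymmetric) divisions follow
    the symmetric round by ``l2_round_gap_h``, clamped after their parent.
    """
    times: dict[str, float] = {}

    def fn(cell: SeamCellID, stage: str, rnd: int) -> float:
        base = tl.stage_start(stage) + cfg.division_phase * (
            tl.stage_end(stage) - tl.stage_start(stage)
        )
        t = (
            base
            + cfg.division_offsets_h.get(cell.lineage, 0.0)
            + rnd * cfg.l2_round_gap_h
            + rng.normal(0.0, cfg.division_sd_h)
        )
        parent = cell.parent_name
        if parent in times:
            t = max(t, times[parent] + 0.05)
        times[cell.name] = t
        return t

    return fn


def _cells_alive(tree: LineageTree, name: str, t: float) -> list[str]:
    """Names of the live seam descendants of ``name`` at time ``t``."""
    rec = tree.records.get(name)
    if rec is None or rec.time is None or t < rec.time or rec.division_class == 0:
        return [name]
    out: list[str] = []
    for d in rec.seam_daughters:
        out.extend(_cells_alive(tree, d.name, t))
    return out


# ---------------------------------------------------------------------------
# DTC paths


def _dtc_path(cfg: WormConfig, tl: DevelopmentalTimeline, which: str, t: np.ndarray):
    """Piecewise DTC path in origin-relative (s, t) coordinates.

    Born at the L1 ecdysis near the midbody; outward on the ventral side
    during L2-L3; a ventral-to-dorsal turn of ``dtc_turn_duration_h`` ending
    at the L3 ecdysis (anterior cell leading by ``dtc_anterior_cross_lead_h``);
    inward on the dorsal side during L4.
    """
    sign = -1.0 if which == "DTC_anterior" else 1.0
    lead = cfg.dtc_anterior_cross_lead_h / 2.0
    turn_end = tl.stage_end("L3") - (lead if which == "DTC_anterior" else -lead)
    turn_start = turn_end - cfg.dtc_turn_duration_h
    born = tl.stage_end("L1")

    s = np.zeros_like(t)
    tv = np.full_like(t, cfg.dtc_t_um)
    for i, ti in enumerate(t):
        if ti <= born:
            s[i] = sign * 4.0
        elif ti <= turn_start:
            s[i] = sign * (4.0 + cfg.dtc_outward_rate * (ti - born))
        elif ti <= turn_end:
            s[i] = sign * (4.0 + cfg.dtc_outward_rate * (turn_start - born))
            frac = (ti - turn_start) / cfg.dtc_turn_duration_h
            tv[i] = cfg.dtc_t_um * (1.0 - 2.0 * frac)  # linear ventral->dorsal
        else:
            s_turn = sign * (4.0 + cfg.dtc_outward_rate * (turn_start - born))
            step = cfg.dtc_inward_rate * (ti - turn_end)
            s[i] = sign * max(4.0, abs(s_turn) - step)
            tv[i] = -cfg.dtc_t_um
    mask = t >= born
    return Trajectory(cell=which, time_h=t[mask], s_um=s[mask], t_um=tv[mask])


# ---------------------------------------------------------------------------
# rendering


def _render_frame(
    cfg: WormConfig,
    axis: BodyAxis,
    spots: list[tuple[np.ndarray, float]],
    glow: float,
    rng: np.random.Generator,
):
    h, w = cfg.image_shape
    px = cfg.pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w]
    pix_um = np.column_stack([(xx.ravel() * px), (yy.ravel() * px)])
    tree = cKDTree(axis._points_dense[::5])
    dist, _ = tree.query(
        pix_um, distance_upper_bound=cfg.body_half_width_um
    )
    body = np.isfinite(dist).reshape(h, w)

    trans = np.full((h, w), cfg.trans_background, dtype=float)
    trans[body] = cfg.trans_body
    fluor = np.full((h, w), cfg.fluor_background, dtype=float)
    fluor[body] += glow

    sig_px = cfg.nucleus_sigma_um / px
    rad = int(np.ceil(4 * sig_px))
    for pos_um, amp in spots:
        cx, cy = pos_um / px
        x0, x1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
        y0, y1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gy, gx = np.mgrid[y0c:y1c, x0c:x1c]
        fluor[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sig_px**2)
        )
    if cfg.read_noise_sd > 0:
        fluor = fluor + rng.normal(0.0, cfg.read_noise_sd, size=fluor.shape)
        trans = trans + rng.normal(0.0, cfg.read_noise_sd, size=trans.shape)
    return fluor.astype(np.float32), trans.astype(np.float32)


# ---------------------------------------------------------------------------
# top-level generation


def generate_movie(cfg: WormConfig, render: bool = True) -> SyntheticMovie:
    """Generate one synthetic animal: frames, ground truth, annotations.

    Deterministic for a fixed ``cfg.seed``.  With ``render=False`` only the
    tables (truth + annotation file) are produced, which is sufficient for
    timeline, lineage and trajectory analyses and much faster.
    """
    for name in (
        "pixel_size_um",
        "frame_interval_h",
        "body_half_width_um",
        "pulse_width_h",
        "length_at_hatch_um",
    ):
        if not getattr(cfg, name) > 0:
            raise ValueError(f"config error: {name} must be positive")
    if max(abs(cfg.seam_t_um), abs(cfg.dtc_t_um)) > cfg.body_half_width_um:
        raise ValueError(
            "config error: nuclei placed outside the body half-width"
        )
    rng = np.random.default_rng(cfg.seed)
    tl = _sample_timeline(cfg, rng)
    # imaging continues past the final ecdysis (sessions outlast L4 exit);
    # full filter support around the last expression peak needs >= 3 h
    t_end = tl.ecdysis_times[3] + 2.5
    times = np.arange(cfg.hatch_h, t_end, cfg.frame_interval_h)

    # per-frame geometry: phase random walk plus rigid jitter
    phases = np.cumsum(rng.normal(0.0, cfg.bend_phase_step, size=len(times)))
    offsets = rng.normal(0.0, cfg.rigid_jitter_um, size=(len(times), 2))
    axes, lengths, ann_frames = [], [], []
    cell_rows = []

    tree = wild_type_tree("synthetic", division_time=_division_times(cfg, tl, rng))

    dtc = {
        name: _dtc_path(cfg, tl, name, times)
        for name in ("DTC_anterior", "DTC_posterior")
    }
    shifts = rng.normal(0.0, cfg.interslice_shift_um, size=len(times))

    exp_t = times
    signal = _pulse_signal(cfg, tl, exp_t)
    exp_rows = []
    noise = {
        c: rng.normal(0.0, cfg.expression_noise_sd, size=len(exp_t))
        for c in cfg.expression_cells
    }
    for c in cfg.expression_cells:
        for k, tk in enumerate(exp_t):
            exp_rows.append(
                {
                    "time_h": tk,
                    "cell": c,
                    "signal": signal[k],
                    "intensity": signal[k] + noise[c][k],
                }
            )
    expression = pd.DataFrame(exp_rows)

    fluor_stack = [] if render else None
    trans_stack = [] if render else None

    # marker anchors as fractions of body length (midbody == vulva by design)
    marker_frac = {"posterior_bulb": 0.15, "anus": 0.95, "vulva": 0.55}

    for f, (tf, phase, off) in enumerate(zip(times, phases, offsets)):
        length = _body_length_at(cfg, tl, tf)
        axis = _true_axis(cfg, length, phase, off)
        axes.append(axis)
        lengths.append(axis.length)

        # annotated centre line: n points at equal arc length (manual clicks)
        s_click = np.linspace(0.0, axis.length, cfg.n_centerline_points)
        clicks = axis.curve(s_click)
        ventral = from_body_coords(BodyPoint(0.55 * axis.length, -16.0), axis)

        origin = marker_frac["vulva"] * axis.length
        spots: list[tuple[np.ndarray, float]] = []
        cells: list[CellAnnotation] = []
        markers: list[MarkerAnnotation] = []
        for mname, frac in marker_frac.items():
            pos0 = from_body_coords(BodyPoint(frac * axis.length, 0.0), axis)
            pos1 = from_body_coords(
                BodyPoint(
                    np.clip(frac * axis.length + shifts[f], 0, axis.length), 0.0
                ),
                axis,
            )
            markers.append(MarkerAnnotation(mname, tuple(pos0), z_slice=0))
            markers.append(MarkerAnnotation(mname, tuple(pos1), z_slice=1))

        # seam nuclei: live descendants of each founder at their anchors
        for lin, frac in _SEAM_ANCHORS.items():
            alive = _cells_alive(tree, f"{lin}L", tf)
            for j, name in enumerate(alive):
                s_pos = np.clip(
                    frac * axis.length + 6.0 * (j - (len(alive) - 1) / 2),
                    0.0,
                    axis.length,
                )
                bp = BodyPoint(float(s_pos), cfg.seam_t_um)
                cam = from_body_coords(bp, axis)
                amp = 60.0
                base = name.split(".")[0][:-1]
                if base in cfg.expression_cells:
                    amp = max(
                        5.0,
                        float(
                            expression.loc[
                                (expression.cell == base)
                                & (expression.time_h == tf),
                                "intensity",
                            ].iloc[0]
                        ),
                    )
                spots.append((cam, amp))
                cells.append(CellAnnotation(name, tuple(cam), z_slice=0))
                cell_rows.append(
                    {
                        "frame": f,
                        "time_h": tf,
                        "name": name,
                        "s_um": bp.s,
                        "t_um": bp.t,
                        "x_um": cam[0],
                        "y_um": cam[1],
                    }
                )

        # DTCs: annotated in Z-slice 1, displaced by the planted shift
        for name, traj in dtc.items():
            k = np.searchsorted(traj.time_h, tf)
            if k >= len(traj.time_h) or abs(traj.time_h[k] - tf) > 1e-9:
                continue
            s_abs = np.clip(origin + traj.s_um[k], 0.0, axis.length)
            bp = BodyPoint(float(s_abs), float(traj.t_um[k]))
            cam_true = from_body_coords(bp, axis)
            s_shifted = np.clip(s_abs + shifts[f], 0.0, axis.length)
            cam_seen = from_body_coords(
                BodyPoint(float(s_shifted), float(traj.t_um[k])), axis
            )
            spots.append((cam_true, 90.0))
            cells.append(CellAnnotation(name, tuple(cam_seen), z_slice=1))
            cell_rows.append(
                {
                    "frame": f,
                    "time_h": tf,
                    "name": name,
                    "s_um": bp.s,
                    "t_um": bp.t,
                    "x_um": cam_true[0],
                    "y_um": cam_true[1],
                }
            )

        ann_frames.append(
            FrameAnnotation(
                index=f,
                time_h=float(tf),
                centerline_um=clicks,
                ventral_marker_um=tuple(ventral),
                markers=markers,
                cells=cells,
            )
        )
        if render:
            glow = cfg.body_glow * (1.0 + signal[f] / cfg.pulse_amplitude)
            fl, tr = _render_frame(cfg, axis, spots, glow, rng)
            fluor_stack.append(fl)
            trans_stack.append(tr)

    # annotated division times snap to the first frame at/after the event
    ann_divisions = []
    for rec in tree.records.values():
        if rec.time is None:
            ann_divisions.append(rec)
            continue
        k = int(np.searchsorted(times, rec.time - 1e-9))
        snapped = float(times[min(k, len(times) - 1)])
        ann_divisions.append(replace(rec, time=snapped))

    annotations = AnimalAnnotations(
        animal=f"synthetic-{cfg.seed}",
        pixel_size_um=cfg.pixel_size_um,
        timeline=tl,
        frames=ann_frames,
        divisions=ann_divisions,
    )
    truth = GroundTruth(
        timeline=tl,
        time_h=times,
        axes=axes,
        body_length_um=np.asarray(lengths),
        cells=pd.DataFrame(cell_rows),
        lineage=tree,
        dtc=dtc,
        interslice_shift_um=shifts,
        expression=expression,
    )
    return SyntheticMovie(
        config=cfg,
        truth=truth,
        annotations=annotations,
        fluorescence=np.stack(fluor_stack) if render else None,
        transmitted=np.stack(trans_stack) if render else None,
    )


def generate_cohort(
    cfg: WormConfig, n_animals: int, render: bool = False
) -> list[SyntheticMovie]:
    """Generate ``n_animals`` independent animals with jittered timelines.

    Per-animal seeds derive from ``cfg.seed`` so the cohort is reproducible;
    expression pulses keep a fixed lag before each animal's own ecdyses.
    """
    if n_animals < 1:
        raise ValueError("cohort needs at least one animal")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_animals) % (2**31)
    return [
        generate_movie(replace(cfg, seed=int(s)), render=render) for s in seeds
    ]
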