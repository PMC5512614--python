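"""Annotation file IO: the plain-JSON schema connecting annotation to analysis.

An annotation file describes one animal: the camera pixel size, the hatch and
ecdysis event times, per-frame manual annotations (centre-line points, the
ventral-side landmark, anatomical markers, labelled cell positions) and the
seam-cell division list.  All stored coordinates are camera-frame pixels;
they are converted to micrometres exactly once, at load time, and body-frame
quantities are always derived from the stored camera coordinates rather than
stored themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import BodyAxis, PixelGrid, fit_body_axis
from .lineage import DivisionRecord, LineageTree, SeamCellID
from .migration import AnatomicalMarkers, Trajectory
from .staging import DevelopmentalTimeline

__all__ = [
    "SCHEMA_VERSION",
    "CellAnnotation",
    "FrameAnnotation",
    "AnimalAnnotations",
    "load_annotations",
    "save_annotations",
    "fit_axes",
    "lineage_tree_from_annotations",
    "dtc_trajectories",
]

SCHEMA_VERSION = 1

# non-seam cell labels accepted in cell records
EXTRA_CELL_VOCABULARY = ("DTC_anterior", "DTC_posterior")
MARKER_VOCABULARY = ("anterior_bulb", "posterior_bulb", "vulva", "anus", "gonad")


class AnnotationError(ValueError):
    """Schema violation, reported with the offending field path."""


@dataclass
class CellAnnotation:
    name: str
    pos_um: tuple[float, float]
    z_slice: int = 0
    near_objective: bool = True


@dataclass
class MarkerAnnotation:
    name: str
    pos_um: tuple[float, float]
    z_slice: int = 0


@dataclass
class FrameAnnotation:
    index: int
    time_h: float
    centerline_um: np.ndarray  # (n, 2)
    ventral_marker_um: tuple[float, float]
    markers: list[MarkerAnnotation] = field(default_factory=list)
    cells: list[CellAnnotation] = field(default_factory=list)


@dataclass
class AnimalAnnotations:
    animal: str
    pixel_size_um: float
    timeline: DevelopmentalTimeline
    frames: list[FrameAnnotation]
    divisions: list[DivisionRecord] = field(default_factory=list)

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(self.pixel_size_um)


def _validate_cell_name(name: str, where: str) -> None:
    if name in EXTRA_CELL_VOCABULARY:
        return
    try:
        SeamCellID.parse(name)
    except ValueError as exc:
        raise AnnotationError(
            f"{where}: unknown cell name {name!r}; expected a seam cell "
            f"(H1, H2, V1-V6, T with side L/R and optional .a/.p sublineage) "
            f"or one of {list(EXTRA_CELL_VOCABULARY)}"
        ) from exc


def load_annotations(path) -> AnimalAnnotations:
    """Load and validate an annotation file, converting pixels to um."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    raw = json.loads(path.read_text())
    return annotations_from_dict(raw)


def annotations_from_dict(raw: dict) -> AnimalAnnotations:
    def need(d: dict, key: str, where: str):
        if key not in d:
            raise AnnotationError(f"{where}: missing required field {key!r}")
        return d[key]

    version = need(raw, "schema_version", "$")
    if version != SCHEMA_VERSION:
        raise AnnotationError(f"$.schema_version: unsupported version {version}")
    px = float(need(raw, "pixel_size_um", "$"))
    if px <= 0:
        raise AnnotationError("$.pixel_size_um: must be positive")
    events = need(raw, "events", "$")
    timeline = DevelopmentalTimeline(
        hatch_time=float(need(events, "hatch_h", "$.events")),
        ecdysis_times=tuple(need(events, "ecdysis_h", "$.events")),
    )

    frames = []
    prev_time = -np.inf
    for i, fr in enumerate(need(raw, "frames", "$")):
        where = f"$.frames[{i}]"
        pts = np.asarray(need(fr, "centerline_px", where), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
            raise AnnotationError(
                f"{where}.centerline_px: insufficient centre-line points "
                "(need at least 4 [x, y] pairs)"
            )
        time_h = float(need(fr, "time_h", where))
        if time_h < prev_time:
            raise AnnotationError(f"{where}.time_h: timestamps must be non-decreasing")
        prev_time = time_h
        cells = []
        for j, c in enumerate(fr.get("cells", [])):
            cwhere = f"{where}.cells[{j}]"
            name = need(c, "name", cwhere)
            _validate_cell_name(name, f"{cwhere}.name")
            cells.append(
                CellAnnotation(
                    name=name,
                    pos_um=tuple(np.asarray(need(c, "pos_px", cwhere), float) * px),
                    z_slice=int(c.get("z_slice", 0)),
                    near_objective=bool(c.get("near_objective", True)),
                )
            )
        markers = []
        for j, m in enumerate(fr.get("markers", [])):
            mwhere = f"{where}.markers[{j}]"
            mname = need(m, "name", mwhere)
            if mname not in MARKER_VOCABULARY:
                raise AnnotationError(
                    f"{mwhere}.name: unknown marker {mname!r}; "
                    f"expected one of {list(MARKER_VOCABULARY)}"
                )
            markers.append(
                MarkerAnnotation(
                    name=mname,
                    pos_um=tuple(np.asarray(need(m, "pos_px", mwhere), float) * px),
                    z_slice=int(m.get("z_slice", 0)),
                )
            )
        frames.append(
            FrameAnnotation(
                index=int(need(fr, "index", where)),
                time_h=time_h,
                centerline_um=pts * px,
                ventral_marker_um=tuple(
                    np.asarray(need(fr, "ventral_marker_px", where), float) * px
                ),
                markers=markers,
                cells=cells,
            )
        )

    divisions = []
    for i, d in enumerate(raw.get("divisions", [])):
        where = f"$.divisions[{i}]"
        name = need(d, "cell", where)
        _validate_cell_name(name, f"{where}.cell")
        divisions.append(
            DivisionRecord(
                cell=SeamCellID.parse(name),
                stage=need(d, "stage", where),
                division_class=int(need(d, "class", where)),
                time=None if d.get("time_h") is None else float(d["time_h"]),
                seam_daughter=d.get("seam_daughter"),
            )
        )

    return AnimalAnnotations(
        animal=str(raw.get("animal", "unnamed")),
        pixel_size_um=px,
        timeline=timeline,
        frames=frames,
        divisions=divisions,
    )


def annotations_to_dict(ann: AnimalAnnotations) -> dict:
    px = ann.pixel_size_um
    return {
        "schema_version": SCHEMA_VERSION,
        "animal": ann.animal,
        "pixel_size_um": px,
        "events": {
            "hatch_h": ann.timeline.hatch_time,
            "ecdysis_h": list(ann.timeline.ecdysis_times),
        },
        "frames": [
            {
                "index": fr.index,
                "time_h": fr.time_h,
                "centerline_px": (np.asarray(fr.centerline_um) / px).tolist(),
                "ventral_marker_px": (
                    np.asarray(fr.ventral_marker_um) / px
                ).tolist(),
                "markers": [
                    {
                        "name": m.name,
                        "pos_px": (np.asarray(m.pos_um) / px).tolist(),
                        "z_slice": m.z_slice,
                    }
                    for m in fr.markers
                ],
                "cells": [
                    {
                        "name": c.name,
                        "pos_px": (np.asarray(c.pos_um) / px).tolist(),
                        "z_slice": c.z_slice,
                        "near_objective": c.near_objective,
                    }
                    for c in fr.cells
                ],
            }
            for fr in ann.frames
        ],
        "divisions": [
            {
                "cell": d.cell.name,
                "stage": d.stage,
                "class": d.division_class,
                "time_h": d.time,
                "seam_daughter": d.seam_daughter,
            }
            for d in ann.divisions
        ],
    }


def save_annotations(ann: AnimalAnnotations, path) -> None:
    """Write an annotation file (um converted back to pixels)."""
    Path(path).write_text(
        json.dumps(annotations_to_dict(ann), indent=1, sort_keys=True) + "\n"
    )


# -- derived pipeline objects -------------------------------------------


def fit_axes(ann: AnimalAnnotations) -> list[BodyAxis]:
    """Fit the per-frame body axis from each frame's annotations."""
    return [
        fit_body_axis(fr.centerline_um, fr.ventral_marker_um)
        for fr in ann.frames
    ]


def lineage_tree_from_annotations(ann: AnimalAnnotations) -> LineageTree:
    """Assemble the animal's seam-cell lineage tree from division records."""
    tree = LineageTree(animal=ann.animal)
    for rec in sorted(
        ann.divisions, key=lambda r: (np.inf if r.time is None else r.time)
    ):
        tree.add(rec)
    return tree


def frame_markers(fr: FrameAnnotation, axis: BodyAxis) -> AnatomicalMarkers:
    """Arc-length marker positions per Z-slice for one frame."""
    from .geometry import to_body_coords

    out = AnatomicalMarkers()
    for m in fr.markers:
        s = to_body_coords(m.pos_um, axis).s
        out.positions.setdefault(m.z_slice, {})[m.name] = s
    return out


def dtc_trajectories(
    ann: AnimalAnnotations, axes: list[BodyAxis] | None = None
) -> dict[str, Trajectory]:
    """Body-coordinate trajectories of the two distal tip cells."""
    from .geometry import to_body_coords

    if axes is None:
        axes = fit_axes(ann)
    series: dict[str, list[tuple[float, float, float]]] = {
        name: [] for name in EXTRA_CELL_VOCABULARY
    }
    for fr, axis in zip(ann.frames, axes):
        for c in fr.cells:
            if c.name in series:
                bp = to_body_coords(c.pos_um, axis, frame_index=fr.index)
                series[c.name].append((fr.time_h, bp.s, bp.t))
    return {
        name: Trajectory(
            cell=name,
            time_h=[r[0] for r in rows],
            s_um=[r[1] for r in rows],
            t_um=[r[2] for r in rows],
        )
        for name, rows in series.items()
        if rows
    }
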