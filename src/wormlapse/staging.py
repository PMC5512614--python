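"""Developmental staging: hatch/ecdysis timelines and larval-stage mapping.

Post-embryonic development runs through four larval stages, L1-L4, each
ending in an ecdysis (shedding of the old cuticle).  Ecdysis is an
instantaneous annotated event, defined by the first appearance of a newly
shed cuticle in the chamber.  Stage intervals are half-open: the ecdysis
itself belongs to the next stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "DevelopmentalTimeline",
    "assign_stage",
    "stage_durations",
    "ecdysis_fraction",
]

STAGES = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class DevelopmentalTimeline:
    """Hatch time plus the four ecdysis times (hours) of one animal."""

    hatch_time: float
    ecdysis_times: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        times = (self.hatch_time, *self.ecdysis_times)
        if len(self.ecdysis_times) != 4:
            raise ValueError("exactly four ecdysis times required")
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError(
                "timeline must satisfy hatch < ecdysis L1 < ... < ecdysis L4"
            )

    def stage_start(self, stage: str) -> float:
        """Start time (h) of a larval stage."""
        i = STAGES.index(stage)
        return self.hatch_time if i == 0 else self.ecdysis_times[i - 1]

    def stage_end(self, stage: str) -> float:
        """End time (h) of a larval stage (its ecdysis)."""
        return self.ecdysis_times[STAGES.index(stage)]

    def event_time(self, event: str) -> float:
        """Time of a named event: ``hatch`` or ``ecdysis_L1`` .. ``ecdysis_L4``."""
        if event == "hatch":
            return self.hatch_time
        if event.startswith("ecdysis_"):
            return self.stage_end(event.removeprefix("ecdysis_"))
        raise ValueError(f"unknown event {event!r}")


def assign_stage(time: float, tl: DevelopmentalTimeline) -> str:
    """Larval stage containing ``time`` (hours).

    Intervals are half-open with the ecdysis belonging to the next stage:
    [hatch, ecd1) -> L1, ..., [ecd4, inf) -> adult; before hatch -> embryo.
    """
    if time < tl.hatch_time:
        return "embryo"
    for stage, end in zip(STAGES, tl.ecdysis_times):
        if time < end:
            return stage
    return "adult"


def stage_durations(tl: DevelopmentalTimeline) -> tuple[float, ...]:
    """Durations (h) of L1-L4: successive differences starting at hatch."""
    times = np.array([tl.hatch_time, *tl.ecdysis_times])
    return tuple(np.diff(times))


def ecdysis_fraction(
    timelines: list[DevelopmentalTimeline], bin_width: float
) -> pd.Series:
    """Per-time-bin fraction of animals with an ecdysis event in the bin.

    Bins are aligned to multiples of ``bin_width``; the fraction normalizes
    by the total number of animals, so summing ``fraction * N`` over bins
    recovers the total event count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not timelines:
        raise ValueError("at least one timeline required")
    events = np.concatenate([tl.ecdysis_times for tl in timelines])
    lo = np.floor(events.min() / bin_width) * bin_width
    hi = np.floor(events.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(events, bins=edges)
    return pd.Series(
        counts / len(timelines),
        index=pd.Index(edges[:-1], name="bin_start_h"),
        name="ecdysis_fraction",
    )
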