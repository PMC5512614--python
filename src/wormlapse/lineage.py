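"""Seam-cell lineage records, division-timing statistics and error probability.

Seam cells (H1, H2, V1-V6, T on each body side) divide in a stereotyped
stage-specific pattern of asymmetric divisions (one seam-fated and one
differentiating daughter) and, in L2, symmetric divisions that double the
seam-cell number.  Each division carries a class ``d``:

    d = 0   no division
    d = 1   symmetric division (two seam-fated daughters)
    d = 2   asymmetric division (exactly one seam-fated daughter)

Cells are named by founder lineage, body side and sublineage suffix over
``{a, p}`` (anterior/posterior daughter), e.g. ``V2L.pp`` is the
posterior-posterior granddaughter of the left V2 founder.

The mutant lineage-error probability ``P(l, s)`` is, for lineage ``l`` and
larval stage ``s``, the mean over all (mutant animal, shared cell) pairs of
``1 - delta(d_wt, d_mut)``, where the shared cells are those present in both
the reference lineage and the mutant animal.  A cell created by an upstream
error has a name absent from the reference and is thereby excluded, so each
(sub-)lineage is scored only at the first point of deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staging import STAGES

__all__ = [
    "LINEAGES",
    "SIDES",
    "SeamCellID",
    "DivisionRecord",
    "LineageTree",
    "LineageErrorResult",
    "relative_division_time",
    "division_time_variability",
    "error_probability",
    "wild_type_tree",
]

LINEAGES = ("H1", "H2", "V1", "V2", "V3", "V4", "V5", "V6", "T")
SIDES = ("L", "R")

# founders whose seam cell performs the L2 symmetric (doubling) division
_L2_SYMMETRIC = frozenset({"H1", "V1", "V2", "V3", "V4", "V6"})


@dataclass(frozen=True)
class SeamCellID:
    lineage: str
    side: str
    sublineage: str = ""

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(
                f"unknown lineage {self.lineage!r}; expected one of {LINEAGES}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if any(ch not in "ap" for ch in self.sublineage):
            raise ValueError("sublineage must be a string over {a, p}")

    @property
    def name(self) -> str:
        base = f"{self.lineage}{self.side}"
        return f"{base}.{self.sublineage}" if self.sublineage else base

    @property
    def generation(self) -> int:
        return len(self.sublineage)

    def daughter(self, which: str) -> "SeamCellID":
        return SeamCellID(self.lineage, self.side, self.sublineage + which)

    @property
    def parent_name(self) -> str | None:
        if not self.sublineage:
            return None
        return SeamCellID(self.lineage, self.side, self.sublineage[:-1]).name

    @classmethod
    def parse(cls, name: str) -> "SeamCellID":
        base, _, sub = name.partition(".")
        lineage, side = base[:-1], base[-1:]
        return cls(lineage, side, sub)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class DivisionRecord:
    """Observed behaviour of one seam cell during one larval stage.

    ``time`` is hours after hatch (``None`` for class-only reference
    lineages or non-dividing cells); ``seam_daughter`` names which daughter
    retains seam fate for asymmetric divisions.
    """

    cell: SeamCellID
    stage: str
    division_class: int
    time: float | None = None
    seam_daughter: str | None = None  # 'a' or 'p', asymmetric only

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.division_class not in (0, 1, 2):
            raise ValueError("division class must be 0, 1 or 2")
        if self.division_class == 2 and self.seam_daughter not in ("a", "p"):
            raise ValueError("asymmetric division must name its seam daughter")
        if self.division_class != 2 and self.seam_daughter is not None:
            raise ValueError("seam_daughter only applies to asymmetric divisions")

    @property
    def seam_daughters(self) -> tuple[SeamCellID, ...]:
        if self.division_class == 0:
            return ()
        if self.division_class == 1:
            return (self.cell.daughter("a"), self.cell.daughter("p"))
        return (self.cell.daughter(self.seam_daughter),)


@dataclass
class LineageTree:
    """All division records of one animal, keyed by cell name."""

    animal: str
    records: dict[str, DivisionRecord] = field(default_factory=dict)

    def add(self, record: DivisionRecord) -> None:
        name = record.cell.name
        if name in self.records:
            raise ValueError(f"duplicate record for {name}")
        parent = record.cell.parent_name
        if (
            parent in self.records
            and record.time is not None
            and self.records[parent].time is not None
            and not self.records[parent].time < record.time
        ):
            raise ValueError(
                f"parent {parent} must divide before daughter {name}"
            )
        self.records[name] = record

    def stage_records(self, stage: str) -> list[DivisionRecord]:
        return [r for r in self.records.values() if r.stage == stage]

    def __len__(self) -> int:
        return len(self.records)


def relative_division_time(tree: LineageTree, stage: str) -> pd.Series:
    """Per-cell division time relative to the animal's stage mean.

    Returns ``dT_i = T_i - <T>`` for every cell dividing in ``stage``, with
    ``<T>`` the mean division time over all lineages of that animal and
    stage; the returned values therefore average to zero.
    """
    recs = [
        r
        for r in tree.stage_records(stage)
        if r.division_class != 0 and r.time is not None
    ]
    if not recs:
        return pd.Series(dtype=float, name="dT_h")
    times = pd.Series(
        {r.cell.name: r.time for r in recs}, name="dT_h", dtype=float
    )
    return times - times.mean()


def division_time_variability(
    trees: list[LineageTree], cell, stage: str
) -> tuple[float, float]:
    """Mean and sample s.d. (n-1) of a cell's division time across animals."""
    name = cell.name if isinstance(cell, SeamCellID) else str(cell)
    times = [
        r.time
        for tree in trees
        if (r := tree.records.get(name)) is not None
        and r.stage == stage
        and r.division_class != 0
        and r.time is not None
    ]
    if len(times) < 2:
        raise ValueError(
            f"cell {name} divides in fewer than 2 animals at stage {stage}"
        )
    arr = np.asarray(times, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


@dataclass
class LineageErrorResult:
    """P(l, s) matrix with comparison counts and marginal means."""

    matrix: pd.DataFrame  # lineages x stages, NaN where undefined
    n_comparisons: pd.DataFrame
    stage_means: pd.Series
    lineage_means: pd.Series


def error_probability(
    wt: LineageTree, mutants: list[LineageTree]
) -> LineageErrorResult:
    """Lineage-error probability P(l, s) of mutants against a reference tree.

    For every mutant animal, cells present (by name) in both the reference
    and the mutant are compared; a comparison scores 1 when the division
    classes differ.  P(l, s) pools both body sides into the named lineage
    and averages over all (animal, cell) comparisons; (l, s) combinations
    with no shared cells are reported as missing (NaN), not zero.
    """
    mismatches = pd.DataFrame(0.0, index=list(LINEAGES), columns=list(STAGES))
    counts = pd.DataFrame(0, index=list(LINEAGES), columns=list(STAGES))
    for mut in mutants:
        for name, wt_rec in wt.records.items():
            mut_rec = mut.records.get(name)
            if mut_rec is None:
                continue
            l, s = wt_rec.cell.lineage, wt_rec.stage
            counts.loc[l, s] += 1
            if mut_rec.division_class != wt_rec.division_class:
                mismatches.loc[l, s] += 1
    matrix = mismatches.where(counts > 0) / counts.where(counts > 0)
    return LineageErrorResult(
        matrix=matrix,
        n_comparisons=counts,
        stage_means=matrix.mean(axis=0, skipna=True),
        lineage_means=matrix.mean(axis=1, skipna=True),
    )


def wild_type_tree(
    animal: str = "WT",
    division_time=None,
    sides: tuple[str, ...] = SIDES,
) -> LineageTree:
    """Build the canonical wild-type seam-cell lineage.

    Pattern: every seam cell divides asymmetrically in L1, L3 and L4; in L2
    the H1, V1-V4 and V6 seam cells first divide symmetrically (doubling the
    seam-cell number) and both daughters then divide asymmetrically, while
    H2, V5 and T divide asymmetrically only.  The posterior daughter is
    taken as the seam-fated daughter of every asymmetric division.

    ``division_time(cell, stage, round_index)`` may supply times (hours);
    by default records are class-only (time ``None``).
    """
    tree = LineageTree(animal=animal)

    def t(cell: SeamCellID, stage: str, rnd: int):
        return None if division_time is None else division_time(cell, stage, rnd)

    current: dict[tuple[str, str], list[SeamCellID]] = {
        (lin, side): [SeamCellID(lin, side)]
        for lin, side in itertools.product(LINEAGES, sides)
    }
    for stage in STAGES:
        for key, cells in current.items():
            lin = key[0]
            new_cells: list[SeamCellID] = []
            for cell in cells:
                if stage == "L2" and lin in _L2_SYMMETRIC:
                    rec = DivisionRecord(cell, stage, 1, time=t(cell, stage, 0))
                    tree.add(rec)
                    for d in rec.seam_daughters:
                        rec2 = DivisionRecord(
                            d, stage, 2, time=t(d, stage, 1), seam_daughter="p"
                        )
                        tree.add(rec2)
                        new_cells.extend(rec2.seam_daughters)
                else:
                    rec = DivisionRecord(
                        cell, stage, 2, time=t(cell, stage, 0), seam_daughter="p"
                    )
                    tree.add(rec)
                    new_cells.extend(rec.seam_daughters)
            current[key] = new_cells
    return tree
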