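"""Brood-cell fate records: data model, CSV I/O, imputation and exclusion rules.

Colonies are photographed weekly and every brood cell is numbered and tracked
from its first appearance (an undifferentiated egg "clump") through larval,
cocoon and eclosed stages, or until it dies or disappears from view.  This
module holds the per-cell fate trajectories, estimates cell counts for brood
clumps that never partitioned into distinct cells, and applies the exclusion
rules that keep ambiguous fates out of the survival and development-time
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StageCode",
    "BroodCell",
    "ClumpRecord",
    "Exclusion",
    "ValidationError",
    "read_brood_table",
    "brood_cells_from_frame",
    "read_clump_table",
    "impute_indistinct_clumps",
    "apply_exclusion_rules",
    "write_exclusion_report",
]


class ValidationError(ValueError):
    """Raised when an input table violates the brood-record contract."""


class StageCode(Enum):
    """Developmental stage of a brood cell at one photograph.

    CLUMP through ECLOSED are living stages in fixed developmental order;
    DEAD and UNSEEN are terminal / censoring codes.
    """

    CLUMP = "clump"
    PREDIFF = "prediff"
    DIFF = "diff"
    COCOON = "cocoon"
    ECLOSED = "eclosed"
    DEAD = "dead"
    UNSEEN = "unseen"

    @property
    def is_living(self) -> bool:
        return self in _LIVING_ORDER

    @property
    def living_rank(self) -> int:
        return _LIVING_ORDER[self]


_LIVING_ORDER = {
    StageCode.CLUMP: 0,
    StageCode.PREDIFF: 1,
    StageCode.DIFF: 2,
    StageCode.COCOON: 3,
    StageCode.ECLOSED: 4,
}

#: Size classes used to impute cell counts for clumps that never partitioned.
CLUMP_SIZE_CATEGORIES = ("tiny", "small", "medium", "large", "extra_large")


@dataclass
class BroodCell:
    """Fate trajectory of one numbered brood cell across photograph dates."""

    cell_id: str
    colony_id: str
    clump_id: str
    observations: list[tuple[int, StageCode]] = field(default_factory=list)
    imputed: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the cell is valid)."""
        problems: list[str] = []
        days = [d for d, _ in self.observations]
        if days != sorted(days) or len(set(days)) != len(days):
            problems.append("observations not strictly increasing in study_day")
        seen_dead = False
        last_rank = -1
        for day, stage in self.observations:
            if seen_dead and stage.is_living:
                problems.append(f"living stage after DEAD at day {day}")
            if stage is StageCode.DEAD:
                seen_dead = True
            if stage.is_living:
                if stage.living_rank < last_rank:
                    problems.append(f"stage regression at day {day}")
                last_rank = stage.living_rank
        return problems

    # -- fate summaries ----------------------------------------------------
    def first_day(self, stage: StageCode) -> int | None:
        for day, s in self.observations:
            if s is stage:
                return day
        return None

    @property
    def first_stage(self) -> StageCode:
        return self.observations[0][1]

    @property
    def terminal_stage(self) -> StageCode:
        return self.observations[-1][1]

    def last_living_day(self) -> int | None:
        days = [d for d, s in self.observations if s.is_living]
        return days[-1] if days else None


@dataclass
class ClumpRecord:
    """One brood clump, with its cell count observed or to be imputed."""

    clump_id: str
    colony_id: str
    size_category: str
    n_cells: int | None
    distinct: bool
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.size_category not in CLUMP_SIZE_CATEGORIES:
            raise ValidationError(
                f"clump {self.clump_id}: unknown size category {self.size_category!r}"
            )
        if self.distinct and self.n_cells is None:
            raise ValidationError(
                f"clump {self.clump_id}: distinct clump must have an observed n_cells"
            )


@dataclass(frozen=True)
class Exclusion:
    """One cell dropped from one analysis, with a machine-readable reason."""

    cell_id: str
    analysis: str  # "survival" or "devtime"
    reason: str


def read_brood_table(path: str | Path) -> list[BroodCell]:
    """Read a brood-cell CSV into validated :class:`BroodCell` records.

    The table has one row per cell per photograph with columns
    ``cell_id,colony_id,clump_id,study_day,stage``.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "colony_id": str, "clump_id": str})
    return brood_cells_from_frame(df, source=str(path))


def brood_cells_from_frame(df: pd.DataFrame, source: str = "<frame>"
                           ) -> list[BroodCell]:
    """Build validated cells from an in-memory brood table."""
    path = source
    required = {"cell_id", "colony_id", "clump_id", "study_day", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []

    stages = []
    for idx, raw in df["stage"].items():
        try:
            stages.append(StageCode(str(raw).strip().lower()))
        except ValueError:
            raise ValidationError(
                f"{path}: row {idx + 2}: unknown stage {raw!r}"
            ) from None
    df = df.assign(_stage=stages)

    dup = df.duplicated(subset=["cell_id", "study_day"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:10])
        raise ValidationError(f"{path}: duplicate (cell_id, study_day) at rows {rows}")

    cells: list[BroodCell] = []
    problems: list[str] = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("study_day")
        cell = BroodCell(
            cell_id=str(cell_id),
            colony_id=str(grp["colony_id"].iloc[0]),
            clump_id=str(grp["clump_id"].iloc[0]),
            observations=[
                (int(d), s) for d, s in zip(grp["study_day"], grp["_stage"])
            ],
        )
        for p in cell.validate():
            problems.append(f"cell {cell_id}: {p}")
        cells.append(cell)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return cells


def read_clump_table(path: str | Path) -> list[ClumpRecord]:
    """Read a clump CSV (``clump_id,colony_id,size_category,n_cells,distinct``)."""
    df = pd.read_csv(path, dtype={"clump_id": str, "colony_id": str})
    out = []
    for _, row in df.iterrows():
        n = row["n_cells"]
        out.append(
            ClumpRecord(
                clump_id=str(row["clump_id"]),
                colony_id=str(row["colony_id"]),
                size_category=str(row["size_category"]),
                n_cells=None if pd.isna(n) else int(n),
                distinct=bool(row["distinct"]),
            )
        )
    return out


def impute_indistinct_clumps(clumps: Sequence[ClumpRecord]) -> list[ClumpRecord]:
    """Assign cell counts to indistinct clumps from size-category means.

    Each clump that never partitioned into distinct cells receives the mean
    cell count of the distinct clumps in its visual size category, rounded
    half-to-even to an integer.  Idempotent: counts are always recomputed
    from the distinct clumps only.
    """
    means: dict[str, float] = {}
    by_cat: dict[str, list[int]] = {}
    for c in clumps:
        if c.distinct:
            by_cat.setdefault(c.size_category, []).append(int(c.n_cells))
    for cat, counts in by_cat.items():
        means[cat] = sum(counts) / len(counts)

    out: list[ClumpRecord] = []
    for c in clumps:
        if c.distinct:
            out.append(replace(c, imputed=False))
        else:
            if c.size_category not in means:
                raise ValidationError(
                    f"clump {c.clump_id}: no distinct reference clump in size "
                    f"category {c.size_category!r}"
                )
            # round half to even: cell counts are integers and unbiased
            # rounding avoids systematic inflation of egg production
            out.append(replace(c, n_cells=round(means[c.size_category]), imputed=True))
    return out


def _unseen_gap(cell: BroodCell) -> int | None:
    """Days between the last living sighting and the first UNSEEN photograph."""
    last_living = None
    for day, stage in cell.observations:
        if stage.is_living:
            last_living = day
        elif stage is StageCode.UNSEEN and last_living is not None:
            return day - last_living
    return None


def apply_exclusion_rules(
    cells: Sequence[BroodCell], max_gap_days: int = 8
) -> tuple[list[BroodCell], list[BroodCell], list[Exclusion]]:
    """Partition cells into the survival and development-time analysis sets.

    A cell whose fate ends UNSEEN is dropped from the survival analysis when
    more than ``max_gap_days`` passed between its last sighting and the
    photograph on which it had vanished (its fate cannot be unambiguously
    mapped; the conventional cap is 8 days, half a normal ~16-day
    development).  The development-time set additionally requires that the
    cell was first seen in the CLUMP stage and was seen ECLOSED.

    Returns ``(survival_set, devtime_set, exclusions)``; every input cell is
    in exactly one of survival_set / survival-excluded.
    """
    if max_gap_days <= 0:
        raise ValueError("max_gap_days must be positive")
    survival: list[BroodCell] = []
    devtime: list[BroodCell] = []
    excluded: list[Exclusion] = []
    for cell in cells:
        in_survival = True
        if cell.terminal_stage is StageCode.UNSEEN:
            gap = _unseen_gap(cell)
            if gap is not None and gap > max_gap_days:
                in_survival = False
                excluded.append(
                    Exclusion(
                        cell.cell_id,
                        "survival",
                        f"ambiguous fate: unseen gap {gap} > {max_gap_days} days",
                    )
                )
        if in_survival:
            survival.append(cell)

        # development time needs an unambiguous egg-to-eclosion span
        dev_ok = in_survival
        if dev_ok and cell.first_stage is not StageCode.CLUMP:
            dev_ok = False
            excluded.append(Exclusion(cell.cell_id, "devtime", "no clump sighting"))
        if dev_ok and cell.first_day(StageCode.ECLOSED) is None:
            dev_ok = False
            excluded.append(Exclusion(cell.cell_id, "devtime", "no eclosion observed"))
        if not in_survival:
            excluded.append(
                Exclusion(cell.cell_id, "devtime", "excluded from survival analysis")
            )
        if dev_ok:
            devtime.append(cell)
    return survival, devtime, excluded


def write_exclusion_report(excluded: Iterable[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [(e.cell_id, e.analysis, e.reason) for e in excluded],
        columns=["cell_id", "analysis", "reason"],
    ).to_csv(path, index=False)
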