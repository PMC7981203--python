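"""Vital-rate response tables and lagged worker-size-composition matrices.

Five vital rates describe weekly worker production in a colony: egg
production (counts per photo interval, with the interval length as an
offset), larval development time (days from first clump sighting to first
eclosed sighting), daily larval survival (interval day-trials), and the mean
and coefficient of variation of callow (newly emerged) worker size.

The functional covariate is the worker size composition: the number of
workers in each intertegular-span bin present at a colony's weekly survey.
Egg production and survival are paired with the composition of the previous
week; the other rates with the composition averaged over the relevant larval
development window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .brood_data import BroodCell, StageCode

__all__ = [
    "SizeGrid",
    "WorkerRecord",
    "CompositionMatrix",
    "VitalRateTable",
    "build_size_grid",
    "read_worker_table",
    "workers_from_frame",
    "weekly_egg_production",
    "development_time",
    "development_time_table",
    "survival_trials",
    "survival_table",
    "callow_cohort_stats",
    "callow_size_tables",
    "composition_for_week",
    "weekly_compositions",
    "lagged_composition",
]

logger = logging.getLogger(__name__)

#: Typical egg-to-eclosion development span (days); used as the default
#: lookback window when pairing cohort responses with compositions.
TYPICAL_DEVELOPMENT_DAYS = 14


@dataclass(frozen=True)
class SizeGrid:
    """Equal-width discretization of intertegular span (mm) into size bins."""

    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing, length >= 2")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bin_index(self, spans) -> np.ndarray:
        """Bin assignment; half-open bins, last bin closed, out-of-range clamped."""
        spans = np.atleast_1d(np.asarray(spans, dtype=float))
        idx = np.searchsorted(self.bin_edges, spans, side="right") - 1
        out_of_range = (spans < self.bin_edges[0]) | (spans > self.bin_edges[-1])
        if np.any(out_of_range):
            logger.warning(
                "%d span(s) outside grid range [%g, %g]; clamped to end bins",
                int(out_of_range.sum()), self.bin_edges[0], self.bin_edges[-1],
            )
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class WorkerRecord:
    """One tagged worker: size at first capture and survey-night presence."""

    worker_id: str
    colony_id: str
    first_capture_day: int
    it_span: float  # mm
    wet_weight: float  # mg
    presence: set[int] = field(default_factory=set)

    def __post_init__(self):
        if self.it_span <= 0:
            raise ValueError(f"worker {self.worker_id}: it_span must be positive")
        if self.presence and self.first_capture_day > min(self.presence):
            raise ValueError(
                f"worker {self.worker_id}: first_capture_day after first presence"
            )


@dataclass
class CompositionMatrix:
    """Worker counts per size bin per observation unit (the functional covariate)."""

    unit_ids: list[str]
    counts: np.ndarray  # (n_units, n_bins), nonnegative
    grid: SizeGrid
    lag_convention: str = "previous_week"  # or "development_window_mean"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.unit_ids):
            raise ValueError("counts must be (n_units, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("composition counts must be nonnegative")

    def row(self, unit_id: str) -> np.ndarray:
        return self.counts[self.unit_ids.index(unit_id)]

    def to_frame(self) -> pd.DataFrame:
        centers = self.grid.bin_centers
        rows = [
            (u, c, self.counts[i, b])
            for i, u in enumerate(self.unit_ids)
            for b, c in enumerate(centers)
        ]
        return pd.DataFrame(rows, columns=["unit_id", "bin_center_mm", "count"])


@dataclass
class VitalRateTable:
    """Modeling-ready rows for one vital rate.

    ``df`` columns: ``unit_id, colony_id, response`` (or
    ``successes, failures`` for the binomial rate), optional ``offset_days``,
    and ``week`` / window columns used to look up compositions.
    """

    rate: str
    family: str  # gaussian | binomial | negative_binomial
    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    def response_matrix(self) -> np.ndarray:
        if self.family == "binomial":
            return self.df[["successes", "failures"]].to_numpy(float)
        return self.df["response"].to_numpy(float)


# ---------------------------------------------------------------------------
# grids and workers


def build_size_grid(it_spans: Sequence[float], n_bins: int) -> SizeGrid:
    """Equal-width bins spanning the observed intertegular-span range."""
    spans = np.asarray(it_spans, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(np.min(spans)), float(np.max(spans))
    if not hi > lo:
        raise ValueError("degenerate grid: all spans identical")
    return SizeGrid(np.linspace(lo, hi, n_bins + 1))


def read_worker_table(path: str | Path) -> list[WorkerRecord]:
    """Read a worker survey CSV: one row per worker per survey night.

    Columns: ``worker_id,colony_id,survey_day,it_span_mm,wet_weight_mg,present``.
    """
    df = pd.read_csv(path, dtype={"worker_id": str, "colony_id": str})
    return workers_from_frame(df)


def workers_from_frame(df: pd.DataFrame) -> list[WorkerRecord]:
    """Build worker records from an in-memory survey table."""
    workers: list[WorkerRecord] = []
    for wid, grp in df.groupby("worker_id", sort=True):
        present_days = {
            int(d) for d, p in zip(grp["survey_day"], grp["present"]) if bool(p)
        }
        workers.append(
            WorkerRecord(
                worker_id=str(wid),
                colony_id=str(grp["colony_id"].iloc[0]),
                first_capture_day=int(grp["survey_day"].min()),
                it_span=float(grp["it_span_mm"].iloc[0]),
                wet_weight=float(grp["wet_weight_mg"].iloc[0]),
                presence=present_days,
            )
        )
    return workers


# ---------------------------------------------------------------------------
# responses


def weekly_egg_production(
    cells: Sequence[BroodCell], photo_days: Mapping[str, Sequence[int]]
) -> VitalRateTable:
    """Count newly visible clump/predifferentiated cells per photo interval.

    For each colony and each interval between consecutive photographs the
    response is the number of cells first seen in the CLUMP or PREDIFF stage
    at the interval's closing photograph; the interval length (days) is the
    model offset.  Cells first seen at a later stage were laid at an unknown
    earlier time and are excluded (logged).  Cells already present at the
    first photograph have no bracketing interval and are likewise excluded.
    """
    new_at: dict[tuple[str, int], int] = {}
    for cell in cells:
        day0, stage0 = cell.observations[0]
        if stage0 not in (StageCode.CLUMP, StageCode.PREDIFF):
            logger.info("cell %s first seen at %s: excluded from egg counts",
                        cell.cell_id, stage0.name)
            continue
        new_at[(cell.colony_id, day0)] = new_at.get((cell.colony_id, day0), 0) + 1

    rows = []
    for colony, days in photo_days.items():
        days = sorted(days)
        for prev, close in zip(days[:-1], days[1:]):
            rows.append(
                {
                    "unit_id": f"{colony}:{close}",
                    "colony_id": colony,
                    "response": new_at.get((colony, close), 0),
                    "offset_days": close - prev,
                    "week": close,
                }
            )
    return VitalRateTable("egg_production", "negative_binomial", pd.DataFrame(rows))


def development_time(cell: BroodCell) -> int:
    """Days from first CLUMP sighting to first ECLOSED sighting."""
    start = cell.first_day(StageCode.CLUMP)
    end = cell.first_day(StageCode.ECLOSED)
    if cell.first_stage is not StageCode.CLUMP or start is None or end is None:
        raise ValueError(
            f"cell {cell.cell_id}: needs a first CLUMP sighting and an ECLOSED "
            "sighting (should have been excluded upstream)"
        )
    return end - start


def development_time_table(devtime_cells: Sequence[BroodCell]) -> VitalRateTable:
    rows = [
        {
            "unit_id": c.cell_id,
            "colony_id": c.colony_id,
            "response": development_time(c),
            "window_start": c.first_day(StageCode.CLUMP),
            "window_end": c.first_day(StageCode.ECLOSED),
        }
        for c in devtime_cells
    ]
    return VitalRateTable("development_time", "negative_binomial", pd.DataFrame(rows))


def survival_trials(
    cell: BroodCell | None, interval_days: int, died_in_interval: bool
) -> tuple[int, int]:
    """Day-trial coding of one cell over one photo interval.

    The day of death within an interval is unknown, so a surviving cell
    contributes ``interval_days`` successes and a dying cell
    ``interval_days - 1`` successes and one failure; successes + failures
    always equals the interval length.
    """
    if interval_days < 1:
        raise ValueError("interval_days must be >= 1")
    if died_in_interval:
        return interval_days - 1, 1
    return interval_days, 0


def survival_table(survival_cells: Sequence[BroodCell]) -> VitalRateTable:
    """One row per cell per bracketing photo interval, coded as day trials.

    A cell is at risk from its first sighting until it ecloses, dies, or
    disappears; a retained UNSEEN fate (gap within the cap) is treated as a
    death in the bracketing interval.
    """
    rows = []
    for cell in survival_cells:
        obs = cell.observations
        for (d0, s0), (d1, s1) in zip(obs[:-1], obs[1:]):
            if not s0.is_living or s0 is StageCode.ECLOSED:
                break
            died = s1 in (StageCode.DEAD, StageCode.UNSEEN)
            succ, fail = survival_trials(cell, d1 - d0, died)
            rows.append(
                {
                    "unit_id": f"{cell.cell_id}:{d1}",
                    "colony_id": cell.colony_id,
                    "successes": succ,
                    "failures": fail,
                    "week": d1,
                }
            )
            if died:
                break
    return VitalRateTable("larval_survival", "binomial", pd.DataFrame(rows))


def callow_cohort_stats(
    workers: Sequence[WorkerRecord], cohort_days: set[int]
) -> tuple[float, float]:
    """Mean and CV of intertegular span at first capture for one cohort.

    CV uses the sample (ddof=1) standard deviation and is scale-invariant.
    Returns NaN for an empty cohort, and a NaN CV for a singleton cohort.
    """
    spans = [w.it_span for w in workers if w.first_capture_day in cohort_days]
    if not spans:
        return math.nan, math.nan
    mean = float(np.mean(spans))
    if len(spans) < 2:
        return mean, math.nan
    return mean, float(np.std(spans, ddof=1) / mean)


def callow_size_tables(
    workers: Sequence[WorkerRecord],
    survey_days: Mapping[str, Sequence[int]],
    window_days: int = TYPICAL_DEVELOPMENT_DAYS,
) -> tuple[VitalRateTable, VitalRateTable]:
    """Per-survey-night cohort mean and CV of callow size, per colony.

    Each survey night's newly captured workers form one cohort; the paired
    composition window spans that cohort's larval development, approximated
    as the ``window_days`` preceding the survey.  Cohorts with no captures
    are dropped (logged); singleton cohorts appear in the mean table only.
    """
    by_colony: dict[str, list[WorkerRecord]] = {}
    for w in workers:
        by_colony.setdefault(w.colony_id, []).append(w)

    mean_rows, cv_rows = [], []
    for colony, days in survey_days.items():
        for day in sorted(days):
            mean, cv = callow_cohort_stats(by_colony.get(colony, []), {int(day)})
            base = {
                "unit_id": f"{colony}:{day}",
                "colony_id": colony,
                # the cohort's larval window: surveys before its emergence
                "window_start": int(day) - window_days,
                "window_end": int(day) - 1,
            }
            if math.isnan(mean):
                logger.info("colony %s day %d: empty callow cohort", colony, day)
                continue
            mean_rows.append({**base, "response": mean})
            if not math.isnan(cv):
                cv_rows.append({**base, "response": cv})
    return (
        VitalRateTable("mean_callow_size", "gaussian", pd.DataFrame(mean_rows)),
        VitalRateTable("cv_callow_size", "gaussian", pd.DataFrame(cv_rows)),
    )


# ---------------------------------------------------------------------------
# compositions


def composition_for_week(
    workers: Sequence[WorkerRecord], grid: SizeGrid, survey_day: int
) -> np.ndarray:
    """Workers present on one survey night, counted per size bin."""
    present = [w.it_span for w in workers if survey_day in w.presence]
    counts = np.zeros(grid.n_bins)
    if present:
        np.add.at(counts, grid.bin_index(present), 1.0)
    return counts


def weekly_compositions(
    workers: Sequence[WorkerRecord],
    grid: SizeGrid,
    survey_days: Mapping[str, Sequence[int]],
) -> CompositionMatrix:
    """Stack per-survey-night compositions for every colony."""
    by_colony: dict[str, list[WorkerRecord]] = {}
    for w in workers:
        by_colony.setdefault(w.colony_id, []).append(w)
    unit_ids, rows = [], []
    for colony, days in survey_days.items():
        for day in sorted(days):
            unit_ids.append(f"{colony}:{day}")
            rows.append(
                composition_for_week(by_colony.get(colony, []), grid, int(day))
            )
    counts = np.vstack(rows) if rows else np.zeros((0, grid.n_bins))
    return CompositionMatrix(unit_ids, counts, grid, "weekly")


def lagged_composition(
    weekly: CompositionMatrix,
    table: VitalRateTable,
    convention: str,
) -> tuple[CompositionMatrix, VitalRateTable]:
    """Pair each response row with its lagged composition.

    ``previous_week``: the composition from the survey one week before the
    row's closing week (the latest survey strictly before the interval's
    close and at or before its opening).  ``development_window_mean``: the
    elementwise mean of the weekly compositions surveyed within the row's
    ``[window_start, window_end]`` (both endpoints included).  Rows with no
    survey in the lookup window are dropped with a logged reason; the
    returned table contains exactly the retained rows, aligned with the
    returned matrix.
    """
    if convention not in ("previous_week", "development_window_mean"):
        raise ValueError(f"unknown lag convention {convention!r}")
    # survey days per colony from the weekly matrix unit ids "colony:day"
    surveys: dict[str, list[tuple[int, int]]] = {}
    for i, uid in enumerate(weekly.unit_ids):
        colony, day = uid.rsplit(":", 1)
        surveys.setdefault(colony, []).append((int(day), i))
    for v in surveys.values():
        v.sort()

    kept_idx, rows = [], []
    for ridx, row in table.df.iterrows():
        colony = row["colony_id"]
        cols = surveys.get(colony, [])
        vec = None
        if convention == "previous_week":
            close = int(row["week"])
            prior = [i for d, i in cols if d < close]
            if prior:
                vec = weekly.counts[prior[-1]]
        else:
            w0, w1 = int(row["window_start"]), int(row["window_end"])
            within = [i for d, i in cols if w0 <= d <= w1]
            if within:
                vec = weekly.counts[within].mean(axis=0)
        if vec is None:
            logger.info("row %s: no survey in lookup window; dropped", row["unit_id"])
            continue
        kept_idx.append(ridx)
        rows.append(vec)

    kept = table.df.loc[kept_idx].reset_index(drop=True)
    counts = np.vstack(rows) if rows else np.zeros((0, weekly.grid.n_bins))
    comp = CompositionMatrix(list(kept["unit_id"]), counts, weekly.grid, convention)
    return comp, VitalRateTable(table.rate, table.family, kept)
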