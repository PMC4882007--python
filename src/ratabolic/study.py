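"""Longitudinal study tables: per-animal records, arm aggregation,
intake imputation, and tidy CSV / spreadsheet I/O.

The canonical on-disk format is a tidy long CSV with one row per
(animal, day) and columns::

    animal_id, arm, dose_mg_per_kg, day, bw_g, intake_kcal, fm_g

Empty cells mean "not measured that day".  An ``intake_g`` column may
replace ``intake_kcal`` when a diet energy density (kcal/g) is supplied,
and a wide rendering (one row per animal and variable, day columns) is
supported for spreadsheet-style sources.  XLSX files are read through
pandas with an optional column-mapping dict for vendor layouts.

Analysis works on arm-level means: the fitting pipeline compares model
output with mean body weight daily and mean fat mass on the sparse
body-composition (DXA) days, with fat-free mass derived from the means
(``FFM = mean BW - mean FM``) because it is not measured directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import IntakeSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "AnimalRecord",
    "StudyArm",
    "load_study",
    "write_study",
    "aggregate_arms",
    "impute_intake",
]

LONG_COLUMNS = ("animal_id", "arm", "dose_mg_per_kg", "day", "bw_g", "intake_kcal", "fm_g")
_WIDE_ID_COLUMNS = ("animal_id", "arm", "dose_mg_per_kg", "variable")
#: intake days at or before this mark belong to the pre-study baseline phase
BASELINE_DAY_CUTOFF = -4


@dataclass
class AnimalRecord:
    """All measurements of one animal, keyed by study day.

    ``bw`` (g) and ``intake`` (kcal/day) are daily where measured;
    ``fm`` (g) is sparse (DXA days only).  ``dose`` is 0 for vehicle and
    ad-libitum/restriction arms.
    """

    animal_id: str
    arm: str
    dose: float
    bw: dict[int, float] = field(default_factory=dict)
    intake: dict[int, float] = field(default_factory=dict)
    fm: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        for day, val in self.bw.items():
            if val <= 0:
                raise ValueError(f"animal {self.animal_id}: bw <= 0 on day {day}")
        for day, val in self.intake.items():
            if val < 0:
                raise ValueError(f"animal {self.animal_id}: intake < 0 on day {day}")
        for day, val in self.fm.items():
            if val < 0:
                raise ValueError(f"animal {self.animal_id}: fm < 0 on day {day}")
            if day in self.bw and val >= self.bw[day]:
                raise ValueError(
                    f"animal {self.animal_id}: fm >= bw on day {day} "
                    f"({val} g vs {self.bw[day]} g)"
                )


@dataclass
class StudyArm:
    """One treatment arm aggregated to daily means and SEMs.

    SEM is ``sd / sqrt(n)`` over the animals measured that day (NaN when
    only one animal contributes).  ``ffm_mean = bw_mean - fm_mean`` on
    body-composition days, derived from the means exactly as in the
    fitting objective.  ``i0`` is the arm's baseline intake (kcal/day).
    """

    label: str
    dose: float
    n: int
    bw_days: np.ndarray
    bw_mean: np.ndarray
    bw_sem: np.ndarray
    intake_days: np.ndarray
    intake_mean: np.ndarray
    bc_days: np.ndarray
    fm_mean: np.ndarray
    fm_sem: np.ndarray
    ffm_mean: np.ndarray
    i0: float

    def bw_on(self, day: int) -> float:
        idx = np.flatnonzero(self.bw_days == day)
        if idx.size == 0:
            raise KeyError(f"arm {self.label}: no body weight on day {day}")
        return float(self.bw_mean[idx[0]])


def _records_from_long(df: pd.DataFrame, diet_kcal_per_g: float | None) -> list[AnimalRecord]:
    cols = set(df.columns)
    intake_col = None
    if "intake_kcal" in cols:
        intake_col = "intake_kcal"
        scale = 1.0
    elif "intake_g" in cols:
        if diet_kcal_per_g is None:
            raise ValueError("intake_g column requires diet_kcal_per_g")
        intake_col = "intake_g"
        scale = float(diet_kcal_per_g)
    required = {"animal_id", "arm", "dose_mg_per_kg", "day", "bw_g", "fm_g"}
    missing = sorted(required - cols)
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    allowed = required | {"intake_kcal", "intake_g"}
    unknown = sorted(cols - allowed)
    if unknown:
        raise ValueError(f"unknown columns: {', '.join(unknown)}")
    if intake_col is None:
        raise ValueError("missing required columns: intake_kcal (or intake_g)")

    dup = df.duplicated(subset=["animal_id", "day"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "day"]].drop_duplicates()
        listing = ", ".join(f"({a}, day {int(d)})" for a, d in pairs.itertuples(index=False))
        raise ValueError(f"duplicate (animal, day) rows: {listing}")

    records: dict[str, AnimalRecord] = {}
    n_missing = 0
    for row in df.itertuples(index=False):
        aid = str(row.animal_id)
        if aid not in records:
            records[aid] = AnimalRecord(aid, str(row.arm), float(row.dose_mg_per_kg))
        rec = records[aid]
        if rec.arm != str(row.arm) or rec.dose != float(row.dose_mg_per_kg):
            raise ValueError(f"animal {aid}: inconsistent arm/dose across rows")
        day = int(row.day)
        bw = getattr(row, "bw_g")
        if pd.notna(bw):
            rec.bw[day] = float(bw)
        else:
            n_missing += 1
        intake = getattr(row, intake_col)
        if pd.notna(intake):
            rec.intake[day] = float(intake) * scale
        else:
            n_missing += 1
        fm = getattr(row, "fm_g")
        if pd.notna(fm):
            rec.fm[day] = float(fm)
    out = list(records.values())
    for rec in out:
        rec.validate()
    logger.info(
        "loaded %d animals, %d arms, %d empty bw/intake cells",
        len(out),
        len({r.arm for r in out}),
        n_missing,
    )
    return out


def _long_from_wide(df: pd.DataFrame) -> pd.DataFrame:
    missing = sorted(set(_WIDE_ID_COLUMNS) - set(df.columns))
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    day_cols = [c for c in df.columns if c.startswith("day_")]
    unknown = sorted(set(df.columns) - set(_WIDE_ID_COLUMNS) - set(day_cols))
    if unknown:
        raise ValueError(f"unknown columns: {', '.join(unknown)}")
    melted = df.melt(
        id_vars=list(_WIDE_ID_COLUMNS), value_vars=day_cols, var_name="day", value_name="value"
    )
    melted["day"] = melted["day"].str.removeprefix("day_").astype(int)
    wide = melted.pivot_table(
        index=["animal_id", "arm", "dose_mg_per_kg", "day"],
        columns="variable",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    for col in ("bw_g", "intake_kcal", "intake_g", "fm_g"):
        if col not in wide.columns and col in set(df["variable"]):
            wide[col] = np.nan
    keep = [c for c in LONG_COLUMNS if c in wide.columns] + (
        ["intake_g"] if "intake_g" in wide.columns else []
    )
    return wide[keep]


def load_study(
    path: str | Path,
    dialect: str = "long",
    diet_kcal_per_g: float | None = None,
    column_map: dict[str, str] | None = None,
) -> list[AnimalRecord]:
    """Load per-animal records from a tidy CSV or XLSX study table.

    Parameters
    ----------
    path : str or Path
        CSV (UTF-8, '.' decimal) or XLSX file.
    dialect : {"long", "wide"}
        ``long``: one row per (animal, day).  ``wide``: one row per
        animal and variable with ``day_<d>`` columns.
    diet_kcal_per_g : float, optional
        Diet energy density; required when intake is recorded in g/day
        (column ``intake_g``), converted as ``kcal = g * density``.
    column_map : dict, optional
        Mapping of source column names to the canonical schema (for
        spreadsheet layouts).

    Raises
    ------
    ValueError
        On unknown columns, negative values, fm >= bw, inconsistent
        arm/dose, or duplicate (animal, day) rows — each error lists the
        offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    if dialect == "wide":
        df = _long_from_wide(df)
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _records_from_long(df, diet_kcal_per_g)


def write_study(records: list[AnimalRecord], path: str | Path, dialect: str = "long") -> None:
    """Write records to CSV in the long or wide dialect (round-trips with
    :func:`load_study`)."""
    rows = []
    for rec in records:
        days = sorted(set(rec.bw) | set(rec.intake) | set(rec.fm))
        for day in days:
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "arm": rec.arm,
                    "dose_mg_per_kg": rec.dose,
                    "day": day,
                    "bw_g": rec.bw.get(day, np.nan),
                    "intake_kcal": rec.intake.get(day, np.nan),
                    "fm_g": rec.fm.get(day, np.nan),
                }
            )
    df = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    if dialect == "long":
        df.to_csv(path, index=False)
        return
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    melted = df.melt(
        id_vars=["animal_id", "arm", "dose_mg_per_kg", "day"],
        value_vars=["bw_g", "intake_kcal", "fm_g"],
        var_name="variable",
        value_name="value",
    ).dropna(subset=["value"])
    wide = melted.pivot_table(
        index=["animal_id", "arm", "dose_mg_per_kg", "variable"],
        columns="day",
        values="value",
        aggfunc="first",
    )
    wide.columns = [f"day_{int(c)}" for c in wide.columns]
    wide.reset_index().to_csv(path, index=False)


def aggregate_arms(records: list[AnimalRecord], baseline: str = "auto") -> list[StudyArm]:
    """Aggregate per-animal records to arm-level means and SEMs.

    Fat mass is aggregated only on body-composition days (days where any
    animal has an FM measurement); fat-free mass is derived from the
    arm means.  Baseline intake ``i0`` is taken as the mean over the
    pre-study baseline days (days <= -4) when present, else the day-0
    mean (policies ``pre_study_mean`` / ``day0`` / ``auto``).

    Arms are returned sorted by dose then label; the output is invariant
    to the order of the input records.
    """
    if baseline not in ("auto", "pre_study_mean", "day0"):
        raise ValueError(f"unknown baseline policy {baseline!r}")
    if not records:
        raise ValueError("no animal records to aggregate")
    by_arm: dict[str, list[AnimalRecord]] = {}
    for rec in records:
        by_arm.setdefault(rec.arm, []).append(rec)
    arms = []
    for label in sorted(by_arm):
        group = sorted(by_arm[label], key=lambda r: r.animal_id)
        if not group:
            raise ValueError(f"arm {label!r} is empty")
        doses = {r.dose for r in group}
        if len(doses) != 1:
            raise ValueError(f"arm {label!r} mixes doses {sorted(doses)}")
        dose = doses.pop()

        def day_stats(field_name: str):
            days = sorted({d for r in group for d in getattr(r, field_name)})
            mean, sem = [], []
            for day in days:
                vals = np.array(
                    [getattr(r, field_name)[day] for r in group if day in getattr(r, field_name)]
                )
                mean.append(vals.mean())
                sem.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan)
            return np.array(days), np.array(mean), np.array(sem)

        bw_days, bw_mean, bw_sem = day_stats("bw")
        intake_days, intake_mean, _ = day_stats("intake")
        bc_days, fm_mean, fm_sem = day_stats("fm")
        if bc_days.size == 0:
            raise ValueError(f"arm {label!r} has no body-composition days")
        ffm_mean = np.empty_like(fm_mean)
        for j, day in enumerate(bc_days):
            idx = np.flatnonzero(bw_days == day)
            if idx.size == 0:
                raise ValueError(f"arm {label!r}: BC day {day} lacks a body-weight mean")
            ffm_mean[j] = bw_mean[idx[0]] - fm_mean[j]

        base_mask = intake_days <= BASELINE_DAY_CUTOFF
        if baseline == "pre_study_mean" or (baseline == "auto" and base_mask.any()):
            if not base_mask.any():
                raise ValueError(f"arm {label!r}: no pre-study baseline intake days")
            i0 = float(intake_mean[base_mask].mean())
        else:
            idx = np.flatnonzero(intake_days == 0)
            if idx.size == 0:
                raise ValueError(f"arm {label!r}: no day-0 intake for baseline")
            i0 = float(intake_mean[idx[0]])

        arms.append(
            StudyArm(
                label=label,
                dose=dose,
                n=len(group),
                bw_days=bw_days,
                bw_mean=bw_mean,
                bw_sem=bw_sem,
                intake_days=intake_days,
                intake_mean=intake_mean,
                bc_days=bc_days,
                fm_mean=fm_mean,
                fm_sem=fm_sem,
                ffm_mean=ffm_mean,
                i0=i0,
            )
        )
    arms.sort(key=lambda a: (a.dose, a.label))
    return arms


def impute_intake(arm: StudyArm, horizon: tuple[int, int]) -> IntakeSchedule:
    """Daily intake schedule over ``[t0, t1)`` with the study imputation
    rules applied.

    Measured values are never altered.  Gaps between the initial
    body-composition measurement and the first intake measurement are
    filled with the baseline intake ``i0``; gaps after the last intake
    measurement (e.g. the washout tail before the final BC day) carry
    the last measured value forward; interior gaps are filled by
    last-observation-carried-forward with a logged warning.
    """
    t0, t1 = int(horizon[0]), int(horizon[1])
    first_bc = int(arm.bc_days.min())
    if t0 < first_bc:
        raise ValueError(
            f"horizon starts at day {t0}, before the first BC day {first_bc}"
        )
    in_window = (arm.intake_days >= t0) & (arm.intake_days < t1)
    measured = dict(zip(arm.intake_days[in_window], arm.intake_mean[in_window]))
    if not measured:
        raise ValueError(f"arm {arm.label}: no intake measurements inside {horizon}")
    first_meas = min(measured)
    last_meas = max(measured)
    values = np.empty(t1 - t0)
    last_val = arm.i0
    interior_gaps = []
    for j, day in enumerate(range(t0, t1)):
        if day in measured:
            last_val = measured[day]
            values[j] = last_val
        elif day < first_meas:
            values[j] = arm.i0
        elif day > last_meas:
            values[j] = measured[last_meas]
        else:
            interior_gaps.append(day)
            values[j] = last_val
    if interior_gaps:
        logger.warning(
            "arm %s: interior intake gap on days %s filled by carry-forward",
            arm.label,
            interior_gaps,
        )
    return IntakeSchedule(start_day=t0, values=values, i0=arm.i0)
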