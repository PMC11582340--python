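"""Data model, validation and delimited-text I/O for TMA cell maps and clinical tables.

Coordinates are continuous micrometres with the origin at the core-disc
center (no pixel grid: cell detection happens upstream). Cores are discs
of ``core_radius_um`` (default 500 um, i.e. a 1-mm-diameter TMA core);
cells slightly outside the disc are kept but flagged, because real
detection exports are noisy at the punch boundary. Missing categorical
values are carried as an explicit ``"missing"`` level and never silently
dropped — downstream operations decide exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

MISSING = "missing"


class Region(str, Enum):
    CENTER = "center"
    MARGIN = "margin"


class Marker(str, Enum):
    CD3 = "CD3"
    CD8 = "CD8"


class CellClass(str, Enum):
    TUMOR = "tumor"
    IMMUNE = "immune"
    OTHER = "other"


AGE_CLASSES = ("<65", "65-75", ">75")
CCI_CLASSES = ("0-2", "3", ">=4")
TREATMENTS = ("nRT", "SRT", "CRT")
STAGES = ("I", "II", "III", "IV")
RADICALITY = ("R0", "R1", "R2")


class CohortFormatError(ValueError):
    """A table does not conform to the configured dialect (missing column, bad enum...)."""


class CohortParseError(ValueError):
    """A cell value could not be parsed; the message cites the offending row."""


@dataclass
class CoreCellMap:
    """One TMA core's classified cell coordinates.

    ``x_um``/``y_um`` are parallel float arrays, ``cls`` a parallel array of
    :class:`CellClass` values. ``(case_id, core_id)`` identifies the core
    within a cohort.
    """

    case_id: str
    core_id: str
    region: Region
    marker: Marker
    x_um: np.ndarray
    y_um: np.ndarray
    cls: np.ndarray
    core_radius_um: float = 500.0

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.cls = np.asarray(self.cls, dtype=object)
        self.region = Region(self.region)
        self.marker = Marker(self.marker)
        if self.core_radius_um <= 0:
            raise CohortFormatError("core_radius_um must be positive")
        if not (len(self.x_um) == len(self.y_um) == len(self.cls)):
            raise CohortFormatError("x_um, y_um and cls must have equal length")
        if self.x_um.size and not (
            np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))
        ):
            raise CohortFormatError("cell coordinates must be finite")
        try:
            self.cls = np.asarray([CellClass(c) for c in self.cls], dtype=object)
        except ValueError as exc:
            raise CohortFormatError(f"unknown cell class: {exc}") from None

    @property
    def n_cells(self) -> int:
        return int(self.x_um.size)

    def points(self, cls: CellClass | None = None) -> np.ndarray:
        """Return an (n, 2) coordinate array, optionally restricted to one class."""
        pts = np.column_stack([self.x_um, self.y_um]) if self.n_cells else np.empty((0, 2))
        if cls is None:
            return pts
        return pts[self._mask(cls)]

    def _mask(self, cls: CellClass) -> np.ndarray:
        # object-array comparison against a str-enum scalar is unreliable in
        # numpy; compare against the plain string value instead
        return self.cls == CellClass(cls).value

    def count(self, cls: CellClass) -> int:
        return int(np.sum(self._mask(cls)))


@dataclass
class ClinicalRecord:
    """Covariates, outcomes and exclusion flags for one case.

    ``time_dss``/``time_os`` are years from surgery; they are separate
    clocks and neither bounds the other. ``trg`` (tumor regression grade,
    fibrosis <25% / 25-50% / >50%) is only defined after preoperative
    therapy; untreated (nRT) cases enter regression-adjusted models as
    grade 1 via :attr:`trg_modeled`.
    """

    case_id: str
    age_class: str
    sex: str
    cci_class: str
    treatment: str
    tnm_stage: str
    radicality: str
    lvi: bool
    trg: int | None
    postop_death: bool
    time_dss: float
    event_dss: bool
    time_os: float
    event_os: bool
    follicle_count: int
    front_length_mm: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise CohortFormatError(f"unknown treatment {self.treatment!r}")
        if self.tnm_stage not in STAGES:
            raise CohortFormatError(f"TNM stage must be one of {STAGES}, got {self.tnm_stage!r}")
        if self.radicality not in RADICALITY:
            raise CohortFormatError(f"unknown radicality {self.radicality!r}")
        if self.cci_class not in CCI_CLASSES + (MISSING,):
            raise CohortFormatError(f"unknown CCI class {self.cci_class!r}")
        if self.age_class not in AGE_CLASSES + (MISSING,):
            raise CohortFormatError(f"unknown age class {self.age_class!r}")
        if self.sex not in ("male", "female"):
            raise CohortFormatError(f"unknown sex {self.sex!r}")
        if self.trg is not None and self.trg not in (1, 2, 3):
            raise CohortFormatError("trg must be 1, 2, 3 or absent")
        if min(self.time_dss, self.time_os) < 0:
            raise CohortFormatError("survival times must be >= 0")
        if self.follicle_count < 0:
            raise CohortFormatError("follicle_count must be >= 0")
        if self.front_length_mm <= 0:
            raise CohortFormatError("front_length_mm must be > 0")

    @property
    def trg_modeled(self) -> int:
        """TRG for modelling: untreated tumors are included in the TRG 1 group."""
        return self.trg if self.trg is not None else 1


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


class CellFormatConfig(BaseModel):
    """Dialect of a cell-table export (delimiter, column names, label aliases)."""

    delimiter: str = "\t"
    case_id: str = "case_id"
    core_id: str = "core_id"
    region: str = "region"
    marker: str = "marker"
    x: str = "x_um"
    y: str = "y_um"
    cls: str = "class"
    class_aliases: dict[str, str] = Field(default_factory=dict)
    region_aliases: dict[str, str] = Field(default_factory=dict)
    marker_aliases: dict[str, str] = Field(default_factory=dict)
    core_radius_um: float = 500.0

    def mandatory_columns(self) -> list[str]:
        return [self.case_id, self.core_id, self.region, self.marker, self.x, self.y, self.cls]


class ClinicalFormatConfig(BaseModel):
    """Dialect of the one-row-per-case clinical table."""

    delimiter: str = "\t"
    columns: dict[str, str] = Field(default_factory=dict)  # field name -> column name
    true_values: tuple[str, ...] = ("1", "true", "yes", "y")
    false_values: tuple[str, ...] = ("0", "false", "no", "n")

    def column(self, fieldname: str) -> str:
        return self.columns.get(fieldname, fieldname)


_CLINICAL_FIELDS = (
    "case_id",
    "age_class",
    "sex",
    "cci_class",
    "treatment",
    "tnm_stage",
    "radicality",
    "lvi",
    "trg",
    "postop_death",
    "time_dss",
    "event_dss",
    "time_os",
    "event_os",
    "follicle_count",
    "front_length_mm",
)


def _parse_float_column(series: pd.Series, colname: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortParseError(
            f"non-numeric value {series.iloc[row]!r} in column {colname!r} at data row {row + 1}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise CohortParseError(f"empty value in column {colname!r} at data row {row + 1}")
    return vals.to_numpy(dtype=float)


def read_cell_table(path: str | Path, fmt: CellFormatConfig | None = None) -> list[CoreCellMap]:
    """Read a delimited cell table into one :class:`CoreCellMap` per (case, core).

    Unknown class labels are rejected unless mapped via ``fmt.class_aliases``.
    """
    fmt = fmt or CellFormatConfig()
    df = pd.read_csv(path, sep=fmt.delimiter, dtype=str)
    missing = [c for c in fmt.mandatory_columns() if c not in df.columns]
    if missing:
        raise CohortFormatError(f"cell table {path} is missing mandatory column(s) {missing}")

    x = _parse_float_column(df[fmt.x], fmt.x)
    y = _parse_float_column(df[fmt.y], fmt.y)

    def _map(values: pd.Series, aliases: Mapping[str, str], enum, what: str) -> np.ndarray:
        out = []
        for i, v in enumerate(values):
            v = aliases.get(v, v)
            try:
                out.append(enum(v))
            except ValueError:
                raise CohortFormatError(
                    f"unknown {what} label {v!r} at data row {i + 1}"
                ) from None
        return np.asarray(out, dtype=object)

    cls = _map(df[fmt.cls], fmt.class_aliases, CellClass, "cell class")
    region = _map(df[fmt.region], fmt.region_aliases, Region, "region")
    marker = _map(df[fmt.marker], fmt.marker_aliases, Marker, "marker")

    cores: list[CoreCellMap] = []
    keys = pd.Series(list(zip(df[fmt.case_id], df[fmt.core_id])))
    for (case_id, core_id), idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        regs, marks = set(region[idx]), set(marker[idx])
        if len(regs) > 1 or len(marks) > 1:
            raise CohortFormatError(
                f"core ({case_id}, {core_id}) mixes regions/markers: {regs}, {marks}"
            )
        cores.append(
            CoreCellMap(
                case_id=str(case_id),
                core_id=str(core_id),
                region=regs.pop(),
                marker=marks.pop(),
                x_um=x[idx],
                y_um=y[idx],
                cls=cls[idx],
                core_radius_um=fmt.core_radius_um,
            )
        )
    cores.sort(key=lambda c: (c.case_id, c.core_id))
    logger.info("read %d cells in %d cores from %s", len(df), len(cores), path)
    return cores


_STAGE_ALIASES = {"1": "I", "2": "II", "3": "III", "4": "IV"}
_CCI_ALIASES = {"0": "0-2", "1": "0-2", "2": "0-2", "4": ">=4", "≥4": ">=4", "4+": ">=4"}
_AGE_ALIASES = {"65–75": "65-75"}
_SEX_ALIASES = {"m": "male", "f": "female", "M": "male", "F": "female"}


def read_clinical_table(
    path: str | Path, fmt: ClinicalFormatConfig | None = None
) -> list[ClinicalRecord]:
    """Read the per-case clinical table.

    Records with an empty CCI field are retained with ``cci_class="missing"``
    (cohorts document such missingness; exclusion is a downstream choice).
    Duplicate case ids and stages outside I-IV are errors.
    """
    fmt = fmt or ClinicalFormatConfig()
    df = pd.read_csv(path, sep=fmt.delimiter, dtype=str)
    missing_cols = [f for f in _CLINICAL_FIELDS if fmt.column(f) not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"clinical table {path} missing column(s) for {missing_cols}")

    def _bool(v: str, colname: str, row: int) -> bool:
        s = str(v).strip().lower()
        if s in fmt.true_values:
            return True
        if s in fmt.false_values:
            return False
        raise CohortParseError(f"cannot parse boolean {v!r} in {colname!r} at data row {row + 1}")

    def _is_na(v) -> bool:
        return pd.isna(v) or str(v).strip() in ("", "NA", "nan")

    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        case_id = str(row[fmt.column("case_id")])
        if case_id in seen:
            raise CohortFormatError(f"duplicate case_id {case_id!r} in clinical table")
        seen.add(case_id)

        def col(f: str):
            return row[fmt.column(f)]

        stage_raw = str(col("tnm_stage")).strip()
        stage = _STAGE_ALIASES.get(stage_raw, stage_raw)
        if stage not in STAGES:
            raise CohortFormatError(
                f"TNM stage {stage_raw!r} outside I-IV for case {case_id!r}"
            )
        cci_raw = col("cci_class")
        cci = MISSING if _is_na(cci_raw) else _CCI_ALIASES.get(str(cci_raw).strip(), str(cci_raw).strip())
        trg_raw = col("trg")
        trg = None if _is_na(trg_raw) else int(float(trg_raw))
        age_raw = str(col("age_class")).strip()
        sex_raw = str(col("sex")).strip()
        extras = {
            c: row[c]
            for c in df.columns
            if c not in {fmt.column(f) for f in _CLINICAL_FIELDS}
        }
        records.append(
            ClinicalRecord(
                case_id=case_id,
                age_class=_AGE_ALIASES.get(age_raw, age_raw),
                sex=_SEX_ALIASES.get(sex_raw, sex_raw.lower()),
                cci_class=cci,
                treatment=str(col("treatment")).strip(),
                tnm_stage=stage,
                radicality=str(col("radicality")).strip(),
                lvi=_bool(col("lvi"), "lvi", i),
                trg=trg,
                postop_death=_bool(col("postop_death"), "postop_death", i),
                time_dss=float(col("time_dss")),
                event_dss=_bool(col("event_dss"), "event_dss", i),
                time_os=float(col("time_os")),
                event_os=_bool(col("event_os"), "event_os", i),
                follicle_count=int(float(col("follicle_count"))),
                front_length_mm=float(col("front_length_mm")),
                extras=extras,
            )
        )
    logger.info("read %d clinical records from %s", len(records), path)
    return records


def validate_cohort(
    cells: Sequence[CoreCellMap],
    clinical: Sequence[ClinicalRecord],
    geometry_tolerance_um: float = 10.0,
) -> ValidationReport:
    """Cross-check cell maps against clinical records.

    Errors: duplicate (case, core) keys, cases present in only one table.
    Warnings: cells outside the core disc by more than the tolerance.
    """
    report = ValidationReport()
    seen_cores: set[tuple[str, str]] = set()
    for core in cells:
        key = (core.case_id, core.core_id)
        if key in seen_cores:
            report.errors.append((f"core {key}", "duplicate (case_id, core_id)"))
        seen_cores.add(key)
        if core.n_cells:
            r = np.hypot(core.x_um, core.y_um)
            n_out = int(np.sum(r > core.core_radius_um + geometry_tolerance_um))
            if n_out:
                report.warnings.append(
                    (f"core {key}", f"{n_out} cell(s) outside core geometry")
                )

    cell_cases = {c.case_id for c in cells}
    clin_cases = {r.case_id for r in clinical}
    for case in sorted(clin_cases - cell_cases):
        report.errors.append((f"case {case}", "case without cores"))
    for case in sorted(cell_cases - clin_cases):
        report.errors.append((f"case {case}", "cores without clinical record"))

    report.counts = {
        "cases": len(clin_cases | cell_cases),
        "cores": len(cells),
        "cells": {
            cls.value: int(sum(core.count(cls) for core in cells)) for cls in CellClass
        },
    }
    return report


# ---------------------------------------------------------------------------
# Scores table I/O

_SCORE_FLOAT_PRECISION = 6

SCORE_COLUMNS = [
    "case_id",
    "density_cd3_center",
    "density_cd3_margin",
    "density_cd8_center",
    "density_cd8_margin",
    "gcross_cd3_center",
    "gcross_cd3_margin",
    "gcross_cd8_center",
    "gcross_cd8_margin",
    "p_density_cd3_center",
    "p_density_cd3_margin",
    "p_density_cd8_center",
    "p_density_cd8_margin",
    "mean_density_percentile",
    "p_gcross_cd3_center",
    "p_gcross_cd3_margin",
    "p_gcross_cd8_center",
    "p_gcross_cd8_margin",
    "mean_gcross_percentile",
    "ds_category",
    "ps_category",
    "follicle_count",
    "front_length_mm",
    "clr_density",
    "clr_class",
    "clr_cutoff",
    "ig_grade",
    "ig_dichot",
]


def write_scores_table(scores: Iterable, path: str | Path, delimiter: str = "\t") -> None:
    """Write one row per case; missing values as empty fields; stable column order."""
    from .scoring import score_record_to_row  # local import avoids a module cycle

    rows = [score_record_to_row(s) for s in scores]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    for c in df.columns:
        if df[c].dtype == float:
            df[c] = df[c].round(_SCORE_FLOAT_PRECISION)
    df.to_csv(path, sep=delimiter, index=False)


def read_scores_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a scores table back as a DataFrame (round-trips write_scores_table)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"scores table {path} missing column(s) {missing}")
    return df
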