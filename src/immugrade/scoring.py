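"""Cohort-relative percentile scoring: density score, proximity score, CLR, immune grade.

Following the Immunoscore principle, raw per-region immune-cell densities
(and, analogously, G-cross values at 20 um) are converted to cohort-wide
percentiles, averaged over the four marker x region combinations (CD3 and
CD8, tumor center and invasive margin), and binned into three categories:
low (0-25], intermediate (>25-70] and high (>70-100]. The percentile of a
value is 100 * midrank / n (ties share the average of their ranks), so the
cohort maximum maps to exactly 100 and the top bin is reachable.

Crohn's-like reaction (CLR) density is follicle count per mm of analyzed
invasive front; a case is CLR-high when density strictly exceeds the
cutoff (default 0.25 follicles/mm, originally chosen by Youden-optimal ROC
against disease-specific mortality). The immune grade adds one category to
the proximity score when CLR is high, yielding a 0-3 scale dichotomized as
low (0-1) vs high (2-3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .cohort_io import ClinicalRecord, Marker, Region
from .spatial import RegionMeasure

logger = logging.getLogger(__name__)

CATEGORY_LABELS = {0: "low", 1: "intermediate", 2: "high"}
DEFAULT_BOUNDARIES = (25.0, 70.0)
DEFAULT_CLR_CUTOFF = 0.25
DEFAULT_MIN_COMPONENTS = 3

#: the four marker x region components of every score, in canonical order
COMPONENTS = (
    (Marker.CD3, Region.CENTER),
    (Marker.CD3, Region.MARGIN),
    (Marker.CD8, Region.CENTER),
    (Marker.CD8, Region.MARGIN),
)


class ScoreKind(IntEnum):
    DS = 0  # density score
    PS = 1  # proximity score


@dataclass
class PercentileVector:
    """Per-case percentiles of the four score components plus their mean."""

    components: dict  # (Marker, Region) -> float | None
    mean_percentile: float | None
    n_available: int


@dataclass
class CategoryScore:
    kind: ScoreKind
    category: int  # 0 | 1 | 2

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self.category]


@dataclass
class CLRMeasure:
    follicle_count: int
    front_length_mm: float
    density: float
    cutoff: float | None = None
    classified: str | None = None  # "low" | "high"


@dataclass
class ImmuneGrade:
    grade: int  # 0..3

    @property
    def dichot(self) -> str:
        return "low" if self.grade <= 1 else "high"


@dataclass
class RocCutoff:
    cutoff: float
    youden_j: float
    degenerate: bool = False
    low_confidence: bool = False


@dataclass
class ScoreRecord:
    """All per-case scores: raw values, percentiles, DS, PS, CLR and immune grade."""

    case_id: str
    densities: dict = field(default_factory=dict)  # (Marker, Region) -> float | None
    gcross: dict = field(default_factory=dict)
    pv_density: PercentileVector | None = None
    pv_gcross: PercentileVector | None = None
    ds: CategoryScore | None = None
    ps: CategoryScore | None = None
    clr: CLRMeasure | None = None
    ig: ImmuneGrade | None = None


def to_percentiles(values: Sequence[float | None]) -> np.ndarray:
    """Convert raw values to cohort percentiles 100 * midrank / n in (0, 100].

    Missing entries (None/NaN) receive NaN and do not affect the ranks of
    the others; n counts non-missing values only.
    """
    arr = np.array([np.nan if v is None else float(v) for v in values], dtype=float)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("to_percentiles requires at least one non-missing value")
    out = np.full(arr.shape, np.nan)
    out[mask] = 100.0 * rankdata(arr[mask], method="average") / n
    return out


def score_from_percentiles(
    pv: PercentileVector,
    kind: ScoreKind,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
    min_components: int = DEFAULT_MIN_COMPONENTS,
) -> CategoryScore | None:
    """Bin the mean percentile into low/intermediate/high.

    Boundaries are inclusive on the low side: mean 25 -> low, 70 ->
    intermediate, anything strictly above 70 -> high. Returns None (a
    missing-score signal) when fewer than ``min_components`` of the four
    components are available.
    """
    if pv.n_available < min_components or pv.mean_percentile is None:
        return None
    low, high = boundaries
    m = pv.mean_percentile
    category = 0 if m <= low else (1 if m <= high else 2)
    return CategoryScore(kind=kind, category=category)


def clr_density(follicle_count: int, front_length_mm: float) -> CLRMeasure:
    """CLR density = follicle count / invasive-front length (follicles/mm)."""
    if front_length_mm <= 0:
        raise ValueError("front_length_mm must be positive")
    if follicle_count < 0:
        raise ValueError("follicle_count must be >= 0")
    return CLRMeasure(
        follicle_count=int(follicle_count),
        front_length_mm=float(front_length_mm),
        density=follicle_count / front_length_mm,
    )


def roc_cutoff(
    densities: Sequence[float],
    death_events: Sequence[bool],
    j_threshold: float = 0.2,
) -> RocCutoff:
    """Youden-optimal density cutoff for predicting disease-specific death.

    Low density is treated as predicting death: at a candidate cutoff c,
    a case tests positive when its density < c. Candidates are midpoints
    between adjacent sorted distinct densities; J = sensitivity +
    specificity - 1 is maximized, ties broken toward the smaller cutoff.
    """
    d = np.asarray(densities, dtype=float)
    e = np.asarray(death_events, dtype=bool)
    if d.shape != e.shape or d.ndim != 1:
        raise ValueError("densities and death_events must be 1-d and aligned")
    if e.all() or (~e).all():
        raise ValueError("roc_cutoff requires both deaths and survivors")

    distinct = np.unique(d)
    if len(distinct) == 1:
        warnings.warn("all densities identical: degenerate separation, J = 0")
        return RocCutoff(cutoff=float(distinct[0]), youden_j=0.0, degenerate=True,
                         low_confidence=True)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    n_pos, n_neg = int(e.sum()), int((~e).sum())
    best = RocCutoff(cutoff=float(candidates[0]), youden_j=-np.inf)
    for c in candidates:
        pred = d < c
        sens = np.sum(pred & e) / n_pos
        spec = np.sum(~pred & ~e) / n_neg
        j = float(sens + spec - 1.0)
        if j > best.youden_j:  # strict: ties keep the smaller (earlier) cutoff
            best = RocCutoff(cutoff=float(c), youden_j=j)
    best.low_confidence = best.youden_j < j_threshold
    return best


def classify_clr(measure: CLRMeasure, cutoff: float = DEFAULT_CLR_CUTOFF) -> CLRMeasure:
    """High iff density strictly exceeds the cutoff ("exceeded" is strict)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    measure.cutoff = float(cutoff)
    measure.classified = "high" if measure.density > cutoff else "low"
    return measure


def immune_grade(ps: CategoryScore | None, clr: CLRMeasure) -> ImmuneGrade | None:
    """PS category raised by one when CLR is high: the four-step immune grade."""
    if ps is None:
        return None
    if ps.kind != ScoreKind.PS:
        raise ValueError("immune_grade expects a proximity score")
    if clr.classified is None:
        raise ValueError("CLR measure must be classified before grading")
    return ImmuneGrade(grade=ps.category + (1 if clr.classified == "high" else 0))


@dataclass
class ScoringConfig:
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
    clr_cutoff: float | str = DEFAULT_CLR_CUTOFF  # or "derive" for ROC re-derivation
    min_components: int = DEFAULT_MIN_COMPONENTS
    reference_population: str = "cohort"  # or "treatment"


def compute_cohort_scores(
    measures: Sequence[RegionMeasure],
    clinical: Sequence[ClinicalRecord],
    config: ScoringConfig | None = None,
) -> list[ScoreRecord]:
    """Score every case: DS from densities, PS from G-cross, CLR, immune grade.

    Percentiles are computed over the configured reference population
    (default: the whole loaded cohort; optionally within treatment group).
    Missing components propagate as missing-score signals, never imputed.
    When ``clr_cutoff`` is "derive", the cutoff is re-derived by ROC
    against the cohort's disease-specific death events.
    """
    config = config or ScoringConfig()
    clin_by_case = {r.case_id: r for r in clinical}
    case_ids = sorted(clin_by_case)

    raw_density: dict[tuple, dict[str, float]] = {comp: {} for comp in COMPONENTS}
    raw_gcross: dict[tuple, dict[str, float]] = {comp: {} for comp in COMPONENTS}
    for m in measures:
        comp = (m.marker, m.region)
        raw_density[comp][m.case_id] = m.density_cells_per_mm2
        if m.gcross_r is not None:
            raw_gcross[comp][m.case_id] = m.gcross_r

    if config.reference_population == "treatment":
        groups = {t: [c for c in case_ids if clin_by_case[c].treatment == t]
                  for t in {r.treatment for r in clinical}}
    else:
        groups = {"cohort": list(case_ids)}

    def percentile_table(raw: Mapping[tuple, Mapping[str, float]]) -> dict[tuple, dict[str, float]]:
        table: dict[tuple, dict[str, float]] = {comp: {} for comp in COMPONENTS}
        for comp in COMPONENTS:
            for members in groups.values():
                vals = [raw[comp].get(c) for c in members]
                if not any(v is not None for v in vals):
                    continue
                pct = to_percentiles(vals)
                for c, p in zip(members, pct):
                    if np.isfinite(p):
                        table[comp][c] = float(p)
        return table

    pct_density = percentile_table(raw_density)
    pct_gcross = percentile_table(raw_gcross)

    if config.clr_cutoff == "derive":
        densities, events = [], []
        for c in case_ids:
            rec = clin_by_case[c]
            densities.append(rec.follicle_count / rec.front_length_mm)
            events.append(rec.event_dss)
        cutoff = roc_cutoff(densities, events).cutoff
        logger.info("CLR cutoff re-derived by ROC: %.4f follicles/mm", cutoff)
    else:
        cutoff = float(config.clr_cutoff)

    def make_pv(table: Mapping[tuple, Mapping[str, float]], case: str) -> PercentileVector:
        comps = {comp: table[comp].get(case) for comp in COMPONENTS}
        avail = [v for v in comps.values() if v is not None]
        return PercentileVector(
            components=comps,
            mean_percentile=float(np.mean(avail)) if avail else None,
            n_available=len(avail),
        )

    records: list[ScoreRecord] = []
    for case in case_ids:
        rec = clin_by_case[case]
        pv_d = make_pv(pct_density, case)
        pv_g = make_pv(pct_gcross, case)
        ds = score_from_percentiles(pv_d, ScoreKind.DS, config.boundaries, config.min_components)
        ps = score_from_percentiles(pv_g, ScoreKind.PS, config.boundaries, config.min_components)
        clr = classify_clr(clr_density(rec.follicle_count, rec.front_length_mm), cutoff)
        ig = immune_grade(ps, clr)
        records.append(
            ScoreRecord(
                case_id=case,
                densities={comp: raw_density[comp].get(case) for comp in COMPONENTS},
                gcross={comp: raw_gcross[comp].get(case) for comp in COMPONENTS},
                pv_density=pv_d,
                pv_gcross=pv_g,
                ds=ds,
                ps=ps,
                clr=clr,
                ig=ig,
            )
        )
    n_missing_ps = sum(1 for r in records if r.ps is None)
    if n_missing_ps:
        logger.info("%d/%d cases have a missing proximity score", n_missing_ps, len(records))
    return records


def score_record_to_row(s: ScoreRecord) -> dict:
    """Flatten a ScoreRecord for the delimited scores table."""
    def comp_cols(d: Mapping, prefix: str) -> dict:
        return {
            f"{prefix}_{m.value.lower()}_{r.value}": d.get((m, r))
            for (m, r) in COMPONENTS
        }

    row = {"case_id": s.case_id}
    row.update(comp_cols(s.densities, "density"))
    row.update(comp_cols(s.gcross, "gcross"))
    row.update(comp_cols(s.pv_density.components if s.pv_density else {}, "p_density"))
    row["mean_density_percentile"] = s.pv_density.mean_percentile if s.pv_density else None
    row.update(comp_cols(s.pv_gcross.components if s.pv_gcross else {}, "p_gcross"))
    row["mean_gcross_percentile"] = s.pv_gcross.mean_percentile if s.pv_gcross else None
    row["ds_category"] = s.ds.category if s.ds else None
    row["ps_category"] = s.ps.category if s.ps else None
    row["follicle_count"] = s.clr.follicle_count if s.clr else None
    row["front_length_mm"] = s.clr.front_length_mm if s.clr else None
    row["clr_density"] = s.clr.density if s.clr else None
    row["clr_class"] = s.clr.classified if s.clr else None
    row["clr_cutoff"] = s.clr.cutoff if s.clr else None
    row["ig_grade"] = s.ig.grade if s.ig else None
    row["ig_dichot"] = s.ig.dichot if s.ig else None
    return row
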