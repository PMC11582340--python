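"""Synthetic TMA cohorts with the statistical structure the pipeline assumes.

Tumor cells form an aggregated parent-offspring (Thomas-type) cluster
process clipped to the core disc; immune cells are a two-component
mixture in which a fraction rho of cells is "attracted" (placed as
Gaussian offsets from randomly chosen tumor cells) and the remainder is
uniform on the disc — rho is the single co-localization knob and maps
monotonically to the G-cross statistic. Per-case CLR densities come from
a two-component mixture straddling the 0.25 follicles/mm threshold, with
treatment-dependent high fractions. Outcomes follow a proportional-
hazards model whose default coefficients mirror the multivariable
hazard-ratio structure of the rectal-cancer cohort the scoring system
was developed on (immune-grade-low HR 3.17 for disease-specific
survival); overall survival adds a comorbidity-graded non-disease
mortality hazard, with disease and other death as competing latent
times. Every artifact is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .cohort_io import (
    CellClass,
    ClinicalRecord,
    CoreCellMap,
    Marker,
    Region,
)

_LOG = math.log


class GeometryConfig(BaseModel):
    radius_um: float = 500.0  # 1-mm-diameter TMA core


class TumorPatternConfig(BaseModel):
    parent_intensity_per_mm2: float = 8.0
    mean_offspring: float = 40.0
    sigma_clust_um: float = 25.0


class ImmunePatternConfig(BaseModel):
    # expected immune cells per core, by marker and treatment; echoes the
    # observed ordering SRT < CRT <= nRT for CD3 and the marked CD8 drop after SRT
    expected_count: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "CD3": {"nRT": 300.0, "SRT": 140.0, "CRT": 200.0},
            "CD8": {"nRT": 150.0, "SRT": 55.0, "CRT": 145.0},
        }
    )
    rho_range: tuple[float, float] = (0.05, 0.9)  # per-case attraction fraction
    sigma_prox_um: float = 10.0


class FollicleConfig(BaseModel):
    threshold: float = 0.25  # follicles/mm; the mixture straddles it
    p_high: dict[str, float] = Field(
        default_factory=lambda: {"nRT": 0.66, "SRT": 0.56, "CRT": 0.22}
    )
    low_beta: tuple[float, float] = (2.0, 2.5)  # density = threshold * Beta(a, b)
    high_beta: tuple[float, float] = (1.5, 3.0)  # threshold + (max - threshold) * Beta
    max_density: float = 1.5
    front_length_range_mm: tuple[float, float] = (10.0, 40.0)


class CovariateConfig(BaseModel):
    stage_probs: dict[str, tuple[float, float, float, float]] = Field(
        default_factory=lambda: {
            "nRT": (0.34, 0.26, 0.27, 0.13),
            "SRT": (0.24, 0.36, 0.33, 0.07),
            "CRT": (0.21, 0.30, 0.35, 0.14),
        }
    )
    cci_probs: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {
            "nRT": (0.32, 0.27, 0.41),
            "SRT": (0.44, 0.30, 0.26),
            "CRT": (0.47, 0.32, 0.21),
        }
    )
    p_male: dict[str, float] = Field(
        default_factory=lambda: {"nRT": 0.60, "SRT": 0.64, "CRT": 0.68}
    )
    p_lvi: dict[str, float] = Field(
        default_factory=lambda: {"nRT": 0.23, "SRT": 0.19, "CRT": 0.19}
    )
    age_probs: tuple[float, float, float] = (0.35, 0.36, 0.29)
    trg_probs: tuple[float, float, float] = (0.66, 0.22, 0.12)  # treated cases only
    radicality_probs: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {
            "nRT": (0.84, 0.05, 0.11),
            "SRT": (0.93, 0.03, 0.04),
            "CRT": (0.83, 0.06, 0.11),
        }
    )
    p_postop_death: float = 0.015


class SurvivalConfig(BaseModel):
    """Exponential baseline scaled by exp(linear predictor); competing other-death."""

    dss_baseline_rate_per_year: float = 0.033  # ~85% 5-year DSS at lp = 0
    log_hr: dict[str, float] = Field(
        default_factory=lambda: {
            "ig_low": _LOG(3.17),
            "cci_3": _LOG(1.36),
            "cci_4": _LOG(1.13),
            "male": _LOG(1.14),
            "stage_II": _LOG(1.48),
            "stage_III": _LOG(1.80),
            "stage_IV": _LOG(14.67),
            "lvi": _LOG(2.74),
            "treat_nRT": _LOG(0.57),
            "treat_SRT": _LOG(0.25),
            "trg_2": _LOG(0.32),
            "trg_3": _LOG(0.71),
        }
    )
    other_death_rate_by_cci: dict[str, float] = Field(
        default_factory=lambda: {"0-2": 0.010, "3": 0.022, ">=4": 0.040}
    )
    admin_censor_range_years: tuple[float, float] = (3.0, 16.0)
    random_censor_rate_per_year: float = 0.005


class SyntheticConfig(BaseModel):
    n_cases: int = 346
    treatment_probs: dict[str, float] = Field(
        default_factory=lambda: {"nRT": 154 / 346, "SRT": 95 / 346, "CRT": 97 / 346}
    )
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    tumor: TumorPatternConfig = Field(default_factory=TumorPatternConfig)
    immune: ImmunePatternConfig = Field(default_factory=ImmunePatternConfig)
    other_expected_count: float = 400.0
    follicle: FollicleConfig = Field(default_factory=FollicleConfig)
    covariates: CovariateConfig = Field(default_factory=CovariateConfig)
    survival: SurvivalConfig = Field(default_factory=SurvivalConfig)
    seed: int = 0

    def model_post_init(self, _ctx) -> None:
        s = sum(self.treatment_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"treatment_probs must sum to 1, got {s}")
        lo, hi = self.immune.rho_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("rho_range must satisfy 0 <= lo <= hi <= 1")


def default_config(seed: int = 0, n_cases: int = 346) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_cases=n_cases)


def fixture_config(seed: int = 7, n_cases: int = 40) -> SyntheticConfig:
    """A small, fast cohort (<= ~300 cells/core) for tests and smoke runs."""
    cfg = SyntheticConfig(seed=seed, n_cases=n_cases)
    cfg.tumor.parent_intensity_per_mm2 = 4.0
    cfg.tumor.mean_offspring = 25.0
    cfg.immune.expected_count = {
        "CD3": {"nRT": 110.0, "SRT": 55.0, "CRT": 75.0},
        "CD8": {"nRT": 60.0, "SRT": 25.0, "CRT": 55.0},
    }
    cfg.other_expected_count = 100.0
    return cfg


@dataclass
class SyntheticCohort:
    cores: list[CoreCellMap]
    clinical: list[ClinicalRecord]
    truth: list[dict]  # ground truth sidecar, never read by the pipeline
    config: SyntheticConfig


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_core(
    config: SyntheticConfig,
    rho_i: float,
    marker: Marker,
    region: Region,
    treatment: str,
    seed,
    case_id: str = "case",
    core_id: str = "core",
) -> CoreCellMap:
    """One core: clustered tumor cells, attraction-mixture immune cells, uniform other.

    A Binomial(n, rho_i) share of immune cells is placed as Gaussian
    offsets (sigma_prox) from uniformly chosen tumor cells; the rest is
    uniform on the disc. Attracted cells may land slightly outside the
    disc, as real boundary detections do. Fully reproducible from seed.
    """
    rng = _as_rng(seed)
    R = config.geometry.radius_um
    area_mm2 = np.pi * (R / 1000.0) ** 2

    n_parents = rng.poisson(config.tumor.parent_intensity_per_mm2 * area_mm2)
    parents = _uniform_disc(rng, n_parents, R)
    tumor_pts = np.empty((0, 2))
    if n_parents:
        counts = rng.poisson(config.tumor.mean_offspring, size=n_parents)
        centers = np.repeat(parents, counts, axis=0)
        pts = centers + rng.normal(0, config.tumor.sigma_clust_um, size=centers.shape)
        tumor_pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= R]  # clip to disc

    mean_immune = config.immune.expected_count[Marker(marker).value][treatment]
    n_immune = rng.poisson(mean_immune)
    n_attracted = rng.binomial(n_immune, rho_i) if len(tumor_pts) else 0
    attracted = np.empty((0, 2))
    if n_attracted:
        anchors = tumor_pts[rng.integers(0, len(tumor_pts), size=n_attracted)]
        attracted = anchors + rng.normal(
            0, config.immune.sigma_prox_um, size=(n_attracted, 2)
        )
    immune_pts = np.vstack([attracted, _uniform_disc(rng, n_immune - n_attracted, R)])

    other_pts = _uniform_disc(rng, rng.poisson(config.other_expected_count), R)

    pts = np.vstack([tumor_pts, immune_pts, other_pts])
    cls = np.array(
        [CellClass.TUMOR] * len(tumor_pts)
        + [CellClass.IMMUNE] * len(immune_pts)
        + [CellClass.OTHER] * len(other_pts),
        dtype=object,
    )
    return CoreCellMap(
        case_id=case_id,
        core_id=core_id,
        region=Region(region),
        marker=Marker(marker),
        x_um=pts[:, 0],
        y_um=pts[:, 1],
        cls=cls,
        core_radius_um=R,
    )


def _categorical(rng, levels, probs) -> str:
    p = np.asarray(probs, dtype=float)
    return levels[rng.choice(len(levels), p=p / p.sum())]


def simulate_case(
    config: SyntheticConfig,
    case_index: int,
    seed,
    with_cells: bool = True,
) -> tuple[list[CoreCellMap], ClinicalRecord, dict]:
    """Draw one case: covariates, attraction rho, CLR, cores; survival is filled in later.

    The "true" proximity-score category is the tercile of the case's rho
    quantile under the low/intermediate/high boundaries (25/70), so that
    the generator's intended immune grade is known without running the
    pipeline.
    """
    rng = _as_rng(seed)
    cov = config.covariates
    case_id = f"case{case_index:04d}"

    treatment = _categorical(rng, ("nRT", "SRT", "CRT"), list(config.treatment_probs.values()))
    stage = _categorical(rng, ("I", "II", "III", "IV"), cov.stage_probs[treatment])
    cci = _categorical(rng, ("0-2", "3", ">=4"), cov.cci_probs[treatment])
    sex = "male" if rng.uniform() < cov.p_male[treatment] else "female"
    age = _categorical(rng, ("<65", "65-75", ">75"), cov.age_probs)
    lvi = bool(rng.uniform() < cov.p_lvi[treatment])
    trg = None if treatment == "nRT" else int(_categorical(rng, ("1", "2", "3"), cov.trg_probs))
    radicality = _categorical(rng, ("R0", "R1", "R2"), cov.radicality_probs[treatment])
    postop_death = bool(radicality == "R0" and rng.uniform() < cov.p_postop_death)

    # attraction fraction and its quantile within the configured range
    rho_u = float(rng.uniform())
    lo, hi = config.immune.rho_range
    rho = lo + rho_u * (hi - lo)
    true_ps = 0 if rho_u * 100 <= 25 else (1 if rho_u * 100 <= 70 else 2)

    # CLR density mixture straddling the threshold
    fol = config.follicle
    clr_high = bool(rng.uniform() < fol.p_high[treatment])
    if clr_high:
        a, b = fol.high_beta
        density = fol.threshold + (fol.max_density - fol.threshold) * rng.beta(a, b)
    else:
        a, b = fol.low_beta
        density = fol.threshold * rng.beta(a, b)
    front = float(rng.uniform(*fol.front_length_range_mm))
    follicles = int(round(density * front))
    # the mixture component defines the case's CLR class; keep the integer
    # count on the same side of the threshold as the drawn density
    boundary = math.floor(fol.threshold * front)
    if clr_high and follicles <= fol.threshold * front:
        follicles = boundary + 1
    elif not clr_high and follicles > fol.threshold * front:
        follicles = boundary

    true_ig = true_ps + (1 if clr_high else 0)
    ig_low = true_ig <= 1

    beta = config.survival.log_hr
    lp = (
        beta["ig_low"] * ig_low
        + beta["cci_3"] * (cci == "3")
        + beta["cci_4"] * (cci == ">=4")
        + beta["male"] * (sex == "male")
        + beta["stage_II"] * (stage == "II")
        + beta["stage_III"] * (stage == "III")
        + beta["stage_IV"] * (stage == "IV")
        + beta["lvi"] * lvi
        + beta["treat_nRT"] * (treatment == "nRT")
        + beta["treat_SRT"] * (treatment == "SRT")
        + beta["trg_2"] * ((trg or 1) == 2)
        + beta["trg_3"] * ((trg or 1) == 3)
    )

    cores: list[CoreCellMap] = []
    if with_cells:
        for marker in (Marker.CD3, Marker.CD8):
            for region in (Region.CENTER, Region.MARGIN):
                for k in (1, 2):
                    cores.append(
                        simulate_core(
                            config,
                            rho,
                            marker,
                            region,
                            treatment,
                            rng,
                            case_id=case_id,
                            core_id=f"{marker.value}_{region.value}_{k}",
                        )
                    )

    record = ClinicalRecord(
        case_id=case_id,
        age_class=age,
        sex=sex,
        cci_class=cci,
        treatment=treatment,
        tnm_stage=stage,
        radicality=radicality,
        lvi=lvi,
        trg=trg,
        postop_death=postop_death,
        time_dss=0.0,
        event_dss=False,
        time_os=0.0,
        event_os=False,
        follicle_count=follicles,
        front_length_mm=front,
    )
    truth = {
        "case_id": case_id,
        "rho": rho,
        "rho_quantile": rho_u,
        "true_ps": true_ps,
        "clr_high": clr_high,
        "clr_density_drawn": density,
        "true_ig": true_ig,
        "ig_low": ig_low,
        "lp_dss": float(lp),
    }
    return cores, record, truth


def _latent_exponential(rng, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def simulate_survival(
    records: Sequence[ClinicalRecord],
    truths: Sequence[dict],
    config: SyntheticConfig,
    seed,
) -> None:
    """Fill in DSS/OS times and events from the proportional-hazards model.

    Disease death and other-cause death are competing latent exponential
    times; censoring is the minimum of a uniform administrative horizon
    and a random exponential censoring time. DSS treats other-cause death
    as censoring; OS counts any death.
    """
    rng = _as_rng(seed)
    sv = config.survival
    n = len(records)
    lp = np.array([t["lp_dss"] for t in truths])
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")

    t_disease = np.array(
        [_latent_exponential(rng, sv.dss_baseline_rate_per_year * math.exp(l), 1)[0] for l in lp]
    )
    other_rates = np.array([sv.other_death_rate_by_cci.get(r.cci_class, 0.0) for r in records])
    t_other = np.array([_latent_exponential(rng, r, 1)[0] for r in other_rates])
    admin = rng.uniform(*sv.admin_censor_range_years, size=n)
    t_cens = np.minimum(admin, _latent_exponential(rng, sv.random_censor_rate_per_year, n))

    t_death = np.minimum(t_disease, t_other)
    t_obs = np.minimum(t_death, t_cens)
    for i, rec in enumerate(records):
        rec.time_os = float(t_obs[i])
        rec.event_os = bool(t_death[i] <= t_cens[i])
        rec.time_dss = float(t_obs[i])
        rec.event_dss = bool(t_disease[i] <= min(t_other[i], t_cens[i]))


def simulate_cohort(
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
    with_cells: bool = True,
) -> SyntheticCohort:
    """Generate a full cohort; optionally write cell/clinical tables and truth sidecar.

    Per-case randomness is spawned from the config seed, so the cohort is
    reproducible case-by-case regardless of generation order.
    """
    config = config or SyntheticConfig()
    root = np.random.SeedSequence(config.seed)
    case_seeds = root.spawn(config.n_cases)
    survival_seed = np.random.default_rng(root.spawn(1)[0])

    cores: list[CoreCellMap] = []
    clinical: list[ClinicalRecord] = []
    truths: list[dict] = []
    for i, ss in enumerate(case_seeds):
        c, rec, truth = simulate_case(config, i, np.random.default_rng(ss), with_cells)
        cores.extend(c)
        clinical.append(rec)
        truths.append(truth)
    simulate_survival(clinical, truths, config, survival_seed)

    cohort = SyntheticCohort(cores=cores, clinical=clinical, truth=truths, config=config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def truth_frame(cohort: SyntheticCohort):
    """Ground-truth modelling frame (true immune-grade dichotomy, survival filter applied).

    Used for parameter-recovery checks: fitting the standard multivariable
    Cox model on this frame should recover the generator's coefficients.
    """
    import pandas as pd

    rows = []
    for rec, tr in zip(cohort.clinical, cohort.truth):
        if rec.radicality != "R0" or rec.postop_death:
            continue
        rows.append(
            {
                "case_id": rec.case_id,
                "cci_class": rec.cci_class,
                "sex": rec.sex,
                "tnm_stage": rec.tnm_stage,
                "ig_dichot": "low" if tr["ig_low"] else "high",
                "lvi": "yes" if rec.lvi else "no",
                "treatment": rec.treatment,
                "trg_modeled": rec.trg_modeled,
                "time_dss": rec.time_dss,
                "event_dss": rec.event_dss,
                "time_os": rec.time_os,
                "event_os": rec.event_os,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write cells.tsv / clinical.tsv in the pipeline's input formats plus truth.json."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for core in cohort.cores:
        for x, y, c in zip(core.x_um, core.y_um, core.cls):
            rows.append(
                {
                    "case_id": core.case_id,
                    "core_id": core.core_id,
                    "region": core.region.value,
                    "marker": core.marker.value,
                    "x_um": round(float(x), 3),
                    "y_um": round(float(y), 3),
                    "class": CellClass(c).value,
                }
            )
    cells_path = out / "cells.tsv"
    pd.DataFrame(rows).to_csv(cells_path, sep="\t", index=False)

    clin_rows = []
    for r in cohort.clinical:
        clin_rows.append(
            {
                "case_id": r.case_id,
                "age_class": r.age_class,
                "sex": r.sex,
                "cci_class": r.cci_class,
                "treatment": r.treatment,
                "tnm_stage": r.tnm_stage,
                "radicality": r.radicality,
                "lvi": int(r.lvi),
                "trg": "" if r.trg is None else r.trg,
                "postop_death": int(r.postop_death),
                "time_dss": round(r.time_dss, 6),
                "event_dss": int(r.event_dss),
                "time_os": round(r.time_os, 6),
                "event_os": int(r.event_os),
                "follicle_count": r.follicle_count,
                "front_length_mm": round(r.front_length_mm, 6),
            }
        )
    clinical_path = out / "clinical.tsv"
    pd.DataFrame(clin_rows).to_csv(clinical_path, sep="\t", index=False)

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=1))
    return {"cells": cells_path, "clinical": clinical_path, "truth": truth_path}
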