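"""Cohort statistics: cross-tabulations, Spearman correlation, KM/log-rank, Cox models, reports.

Conventions: Pearson chi-square without continuity correction (this is
what reproduces printed cross-tab p-values on the published counts);
complete-case handling of missing levels; two-sided tests throughout.
Survival analyses are restricted to R0 resections with immediate
postoperative deaths excluded (see :func:`survival_filter`); survival at
a horizon is the right-continuous step-function value at the horizon.
Cox models use Efron tie handling and Wald 95% intervals, with
categorical covariates expanded against explicit reference levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .cohort_io import MISSING, ClinicalRecord
from .scoring import ScoreRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross-tabulation


@dataclass
class CrossTab:
    row_levels: list
    col_levels: list
    counts: np.ndarray  # R x C integers
    chi2: float
    df: int
    p: float
    n: int


def _complete_mask(*columns) -> np.ndarray:
    mask = np.ones(len(columns[0]), dtype=bool)
    for col in columns:
        arr = np.asarray(col, dtype=object)
        for i, v in enumerate(arr):
            if v is None or v == MISSING or (isinstance(v, float) and np.isnan(v)):
                mask[i] = False
    return mask


def crosstab_chisq(
    factor_a: Sequence,
    factor_b: Sequence,
    row_levels: Sequence | None = None,
    col_levels: Sequence | None = None,
) -> CrossTab:
    """Pearson chi-square on the complete-case contingency table (no Yates correction)."""
    a = np.asarray(factor_a, dtype=object)
    b = np.asarray(factor_b, dtype=object)
    mask = _complete_mask(a, b)
    a, b = a[mask], b[mask]
    rows = list(row_levels) if row_levels is not None else sorted(set(a), key=str)
    cols = list(col_levels) if col_levels is not None else sorted(set(b), key=str)
    counts = np.array(
        [[int(np.sum((a == r) & (b == c))) for c in cols] for r in rows], dtype=int
    )
    # drop empty margins (a level absent from the complete cases)
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        dropped = [r for r, k in zip(rows, keep_r) if not k] + [
            c for c, k in zip(cols, keep_c) if not k
        ]
        warnings.warn(f"dropping zero-margin level(s) {dropped} from contingency table")
        rows = [r for r, k in zip(rows, keep_r) if k]
        cols = [c for c, k in zip(cols, keep_c) if k]
        counts = counts[np.ix_(keep_r, keep_c)]
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("chi-square needs at least 2 levels per factor after dropping missing")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return CrossTab(
        row_levels=rows,
        col_levels=cols,
        counts=counts,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        n=int(counts.sum()),
    )


def chisq_from_counts(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square directly from a printed counts matrix."""
    chi2, p, df, _ = sps.chi2_contingency(np.asarray(counts), correction=False)
    return float(chi2), int(df), float(p)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on complete pairs; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("spearman_corr requires at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Survival


def survival_filter(
    records: Sequence[ClinicalRecord],
) -> tuple[list[ClinicalRecord], dict]:
    """Keep R0 resections without immediate postoperative death; log removals."""
    n0 = len(records)
    r0 = [r for r in records if r.radicality == "R0"]
    kept = [r for r in r0 if not r.postop_death]
    log = {
        "input": n0,
        "removed_not_r0": n0 - len(r0),
        "removed_postop_death": len(r0) - len(kept),
        "retained": len(kept),
    }
    logger.info(
        "survival filter: %(input)d in, %(removed_not_r0)d non-R0 removed, "
        "%(removed_postop_death)d postoperative deaths removed, %(retained)d retained",
        log,
    )
    return kept, log


@dataclass
class KMResult:
    groups: list
    curves: dict  # group -> DataFrame(time, survival)
    survival_at_horizon: dict  # group -> float
    n: dict  # group -> subjects
    events: dict  # group -> observed events
    horizon_years: float
    logrank_chi2: float | None
    logrank_df: int | None
    logrank_p: float | None


def km_survival(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
    horizon_years: float = 5.0,
) -> KMResult:
    """Product-limit survival per group with a log-rank comparison across groups."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("survival times must be >= 0")
    g = np.asarray(["all"] * len(t) if groups is None else groups, dtype=object)
    mask = _complete_mask(g)
    t, e, g = t[mask], e[mask], g[mask]
    levels = sorted(set(g), key=str)
    if not levels:
        raise ValueError("no subjects after dropping missing group labels")

    curves, s_h, ns, evs = {}, {}, {}, {}
    for lev in levels:
        sel = g == lev
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        curves[lev] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        s_h[lev] = float(kmf.predict(horizon_years))
        ns[lev] = int(sel.sum())
        evs[lev] = int(e[sel].sum())

    chi2 = df = p = None
    if len(levels) >= 2:
        res = multivariate_logrank_test(t, g, e)
        chi2, p = float(res.test_statistic), float(res.p_value)
        df = len(levels) - 1
    return KMResult(
        groups=levels,
        curves=curves,
        survival_at_horizon=s_h,
        n=ns,
        events=evs,
        horizon_years=horizon_years,
        logrank_chi2=chi2,
        logrank_df=df,
        logrank_p=p,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxTerm:
    """One model covariate: categorical (levels + reference) or numeric."""

    column: str
    levels: tuple | None = None  # None -> numeric
    reference: object | None = None


def standard_cox_terms() -> list[CoxTerm]:
    """The standard multivariable adjustment set with its reference levels.

    References: CCI 0-2, female sex, TNM stage I, high immune grade, no
    LVI, chemoradiotherapy, TRG 1 (untreated cases coded TRG 1).
    """
    return [
        CoxTerm("cci_class", ("0-2", "3", ">=4"), "0-2"),
        CoxTerm("sex", ("female", "male"), "female"),
        CoxTerm("tnm_stage", ("I", "II", "III", "IV"), "I"),
        CoxTerm("ig_dichot", ("high", "low"), "high"),
        CoxTerm("lvi", ("no", "yes"), "no"),
        CoxTerm("treatment", ("CRT", "nRT", "SRT"), "CRT"),
        CoxTerm("trg_modeled", (1, 2, 3), 1),
    ]


@dataclass
class CoxResult:
    table: pd.DataFrame  # index: term labels; columns hr, ci_low, ci_high, p
    references: dict  # column -> reference level
    n: int
    events: int
    log_likelihood: float
    penalizer: float = 0.0
    convergence_warnings: list = field(default_factory=list)


def cox_model(
    df: pd.DataFrame,
    terms: Sequence[CoxTerm],
    duration_col: str,
    event_col: str,
    penalizer: float = 0.0,
) -> CoxResult:
    """Efron-tie partial-likelihood fit with Wald 95% CIs on complete cases.

    Categorical terms are dummy-expanded against their declared reference
    level; rows with a missing value in any model column are dropped.
    Possible separation (a dummy nearly determining the event) is flagged
    via ``convergence_warnings``; a ridge ``penalizer`` can stabilize
    small-sample fits at the cost of some shrinkage.
    """
    cols = [duration_col, event_col] + [t.column for t in terms]
    work = df[cols].copy()
    for c in cols:
        work = work[_complete_mask(work[c].to_numpy())]
    n = len(work)

    X = pd.DataFrame(index=work.index)
    references: dict[str, object] = {}
    labels: list[str] = []
    for term in terms:
        if term.levels is None:
            X[term.column] = pd.to_numeric(work[term.column])
            labels.append(term.column)
            continue
        references[term.column] = term.reference
        observed = set(work[term.column])
        unknown = observed - set(term.levels)
        if unknown:
            raise ValueError(f"unexpected level(s) {unknown} in {term.column!r}")
        for lev in term.levels:
            if lev == term.reference:
                continue
            label = f"{term.column}={lev}"
            X[label] = (work[term.column] == lev).astype(float)
            labels.append(label)

    X[duration_col] = pd.to_numeric(work[duration_col])
    X[event_col] = work[event_col].astype(bool).astype(int)

    cph = CoxPHFitter(penalizer=penalizer)  # Efron tie handling is the lifelines default
    conv_warnings: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(X, duration_col=duration_col, event_col=event_col)
        conv_warnings = [
            str(w.message) for w in caught if "convergence" in str(w.category).lower()
            or "separation" in str(w.message).lower()
        ]
    except Exception as exc:  # convergence failure / separation
        raise RuntimeError(
            f"Cox model failed to converge on n={n} rows "
            f"({int(X[event_col].sum())} events): {exc}"
        ) from exc

    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    ).loc[labels]
    return CoxResult(
        table=table,
        references=references,
        n=n,
        events=int(X[event_col].sum()),
        log_likelihood=float(cph.log_likelihood_),
        penalizer=penalizer,
        convergence_warnings=conv_warnings,
    )


# ---------------------------------------------------------------------------
# Report builders


def join_scores_clinical(
    scores: Sequence[ScoreRecord], clinical: Sequence[ClinicalRecord]
) -> pd.DataFrame:
    """One-row-per-case modelling frame joining clinical covariates and scores."""
    s_by_case = {s.case_id: s for s in scores}
    rows = []
    for rec in clinical:
        s = s_by_case.get(rec.case_id)
        rows.append(
            {
                "case_id": rec.case_id,
                "age_class": rec.age_class,
                "sex": rec.sex,
                "cci_class": rec.cci_class,
                "treatment": rec.treatment,
                "tnm_stage": rec.tnm_stage,
                "radicality": rec.radicality,
                "lvi": "yes" if rec.lvi else "no",
                "trg_modeled": rec.trg_modeled,
                "postop_death": rec.postop_death,
                "time_dss": rec.time_dss,
                "event_dss": rec.event_dss,
                "time_os": rec.time_os,
                "event_os": rec.event_os,
                "ds": s.ds.category if s and s.ds else None,
                "ps": s.ps.category if s and s.ps else None,
                "clr_class": s.clr.classified if s and s.clr else None,
                "ig": s.ig.grade if s and s.ig else None,
                "ig_dichot": s.ig.dichot if s and s.ig else None,
            }
        )
    return pd.DataFrame(rows)


CHARACTERISTICS_VARIABLES = [
    ("Age", "age_class"),
    ("Sex", "sex"),
    ("CCI", "cci_class"),
    ("TNM stage", "tnm_stage"),
    ("Radicality of surgery", "radicality"),
    ("T-cell density score", "ds"),
    ("T-cell proximity score", "ps"),
    ("Immune grade", "ig"),
    ("CLR density", "clr_class"),
    ("Lymphovascular invasion", "lvi"),
]

SURVIVAL_STRATA_VARIABLES = [
    ("Sex", "sex"),
    ("Charlson comorbidity index", "cci_class"),
    ("TNM stage", "tnm_stage"),
    ("T-cell density score", "ds"),
    ("T-cell proximity score", "ps"),
    ("CLR density", "clr_class"),
    ("Immune grade", "ig"),
    ("Immune grade (dichotomized)", "ig_dichot"),
    ("Lymphovascular invasion", "lvi"),
]


@dataclass
class ReportBundle:
    characteristics: pd.DataFrame
    survival_strata: pd.DataFrame
    cox: dict  # outcome -> CoxResult
    cox_frames: dict  # outcome -> formatted DataFrame
    filter_log: dict

    def write(self, out_dir) -> list:
        """Emit delimited-text and machine-readable forms; returns paths written."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in [
            ("crosstabs_by_treatment.tsv", self.characteristics),
            ("survival_by_stratum.tsv", self.survival_strata),
        ]:
            p = out / name
            frame.to_csv(p, sep="\t", index=False)
            paths.append(p)
        for outcome, frame in self.cox_frames.items():
            p = out / f"cox_{outcome.lower()}.tsv"
            frame.to_csv(p, sep="\t")
            paths.append(p)
        payload = {
            "filter_log": self.filter_log,
            "characteristics": self.characteristics.to_dict(orient="records"),
            "survival_strata": self.survival_strata.to_dict(orient="records"),
            "cox": {
                k: {
                    "rows": self.cox[k].table.round(6).reset_index().to_dict(orient="records"),
                    "references": {c: str(r) for c, r in self.cox[k].references.items()},
                    "n": self.cox[k].n,
                    "events": self.cox[k].events,
                }
                for k in self.cox
            },
        }
        p = out / "reports.json"
        p.write_text(json.dumps(payload, indent=1, default=str))
        paths.append(p)
        return paths


def _fmt_p(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "n/a"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def build_characteristics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts, column percentages and chi-square p per variable, by treatment."""
    treatments = ["nRT", "SRT", "CRT"]
    blocks = []
    for title, col in CHARACTERISTICS_VARIABLES:
        if col not in frame.columns or frame[col].isna().all():
            continue
        ct = crosstab_chisq(frame[col], frame["treatment"], col_levels=treatments)
        col_tot = ct.counts.sum(axis=0)
        all_tot = ct.counts.sum()
        for i, lev in enumerate(ct.row_levels):
            row = {"variable": title, "level": str(lev)}
            for j, tr in enumerate(ct.col_levels):
                c = ct.counts[i, j]
                row[f"{tr}_n"] = int(c)
                row[f"{tr}_pct"] = round(100.0 * c / col_tot[j]) if col_tot[j] else 0
            row["all_n"] = int(ct.counts[i].sum())
            row["all_pct"] = round(100.0 * ct.counts[i].sum() / all_tot)
            row["p"] = _fmt_p(ct.p) if i == 0 else ""
            blocks.append(row)
    return pd.DataFrame(blocks)


def build_survival_strata_table(frame: pd.DataFrame, horizon_years: float = 5.0) -> pd.DataFrame:
    """Per-stratum survival at the horizon with log-rank p, for nRT and pooled pRT.

    pRT pools SRT and CRT at reporting level only; the data are unchanged.
    """
    filtered = frame[(frame["radicality"] == "R0") & (~frame["postop_death"].astype(bool))]
    groups = {
        "nRT": filtered[filtered["treatment"] == "nRT"],
        "pRT": filtered[filtered["treatment"].isin(["SRT", "CRT"])],
    }
    rows = []
    for title, col in SURVIVAL_STRATA_VARIABLES:
        for outcome, (tcol, ecol) in {
            "DSS": ("time_dss", "event_dss"),
            "OS": ("time_os", "event_os"),
        }.items():
            for gname, sub in groups.items():
                sub2 = sub[_complete_mask(sub[col].to_numpy())]
                if sub2.empty or sub2[col].nunique() < 2:
                    continue
                km = km_survival(
                    sub2[tcol], sub2[ecol].astype(bool), sub2[col], horizon_years
                )
                for lev in km.groups:
                    rows.append(
                        {
                            "variable": title,
                            "level": str(lev),
                            "outcome": outcome,
                            "group": gname,
                            "n": km.n[lev],
                            f"survival_{int(horizon_years)}y_pct": round(
                                100.0 * km.survival_at_horizon[lev]
                            ),
                            "logrank_p": _fmt_p(km.logrank_p),
                        }
                    )
    return pd.DataFrame(rows)


def build_cox_tables(frame: pd.DataFrame) -> tuple[dict, dict]:
    """Multivariable Cox for DSS and OS on the filtered cohort."""
    filtered = frame[(frame["radicality"] == "R0") & (~frame["postop_death"].astype(bool))]
    results, formatted = {}, {}
    for outcome, (tcol, ecol) in {
        "DSS": ("time_dss", "event_dss"),
        "OS": ("time_os", "event_os"),
    }.items():
        try:
            res = cox_model(filtered, standard_cox_terms(), tcol, ecol)
        except RuntimeError:
            # small cohorts can separate on rare dummies; retry with a mild
            # ridge penalty and flag the fit as penalized
            logger.warning("unpenalized Cox fit failed for %s; retrying with ridge 0.1", outcome)
            res = cox_model(filtered, standard_cox_terms(), tcol, ecol, penalizer=0.1)
        results[outcome] = res
        fmt = res.table.copy()
        fmt["HR (95% CI)"] = [
            f"{hr:.2f} ({lo:.2f}-{hi:.2f})"
            for hr, lo, hi in zip(fmt["hr"], fmt["ci_low"], fmt["ci_high"])
        ]
        fmt["p"] = [_fmt_p(p) for p in fmt["p"]]
        formatted[outcome] = fmt[["HR (95% CI)", "p"]]
    return results, formatted


def build_reports(
    scores: Sequence[ScoreRecord],
    clinical: Sequence[ClinicalRecord],
    horizon_years: float = 5.0,
) -> ReportBundle:
    """Assemble the three report shapes from scored clinical data."""
    frame = join_scores_clinical(scores, clinical)
    _, flog = survival_filter(list(clinical))
    characteristics = build_characteristics_table(frame)
    survival_strata = build_survival_strata_table(frame, horizon_years)
    cox, cox_frames = build_cox_tables(frame)
    return ReportBundle(
        characteristics=characteristics,
        survival_strata=survival_strata,
        cox=cox,
        cox_frames=cox_frames,
        filter_log=flog,
    )
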