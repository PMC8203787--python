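"""KDM5D-deficiency classification and survival modelling.

Deficiency is a fixed-threshold rule on standardized tumour KDM5D expression
among males (>= k SD below the male mean, boundary inclusive). Prognosis is
modelled with a multivariate Cox proportional hazards fit (Efron ties, via
lifelines) over age, sex, histology, smoking and stage plus the deficiency
("outlier") indicator, and non-nested Cox models over the same subjects are
compared with a Vuong-type variance-weighted likelihood-ratio statistic
built from per-subject log partial-likelihood contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

DEFICIENCY_SD = 1.5


class NoEventsError(ValueError):
    """Survival fit attempted with fewer than two observed events."""


@dataclass
class DeficiencyCalls:
    table: pd.DataFrame  # patient_id, kdm5d_z, deficient
    threshold_sd: float


def classify_deficiency(expression: pd.Series, k: float = DEFICIENCY_SD) -> DeficiencyCalls:
    """Flag male tumours with expression <= mean - k*SD (sample SD, n-1).

    ``expression`` maps patient id -> tumour KDM5D expression for MALE
    patients only; females are by definition never deficient and should not
    be passed here (the cohort-level helper adds them back as False).
    """
    x = expression.astype(float)
    if x.size < 3:
        raise ValueError("need >= 3 male tumour samples")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation; deficiency rule undefined")
    z = (x - x.mean()) / sd
    # boundary inclusive ("k SD below or more"); epsilon guards float round-off
    table = pd.DataFrame({"patient_id": x.index, "kdm5d_z": z.values,
                          "deficient": (z <= -k + 1e-12).values})
    return DeficiencyCalls(table=table, threshold_sd=k)


# ---------------------------------------------------------------------------
# Cox model


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, hr, ci lower/upper, p
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    per_subject: pd.Series = field(repr=False, default=None)  # log-PL terms
    design: pd.DataFrame = field(repr=False, default=None)


_SMOKING_LEVELS = ("NS", "EX", "CS")
_STAGE_ORDER = ("IA", "IB", "II", "IIA", "IIB", "III", "IIIA", "IIIB", "IV")


def encode_covariates(metadata: pd.DataFrame, covariates: list[str],
                      outlier: pd.Series | None = None,
                      stage_as_ordinal: bool = True) -> pd.DataFrame:
    """Patient-level design matrix with time/event columns.

    One row per patient (tumour-sample attributes win when both tissues are
    present). Categoricals are reference-coded (sex M vs F, histology LUSC
    vs LUAD, smoking EX/CS vs NS); stage is an ordered integer by default.
    Smoking 'NR' and missing stage rows are dropped (complete-case), with
    counts logged. ``outlier`` maps patient id -> bool.
    """
    per_patient = (metadata.sort_values("tissue", ascending=False)
                   .drop_duplicates("patient_id"))  # tumour row preferred
    df = per_patient.set_index("patient_id")
    out = pd.DataFrame(index=df.index)
    out["time"] = pd.to_numeric(df["time"], errors="coerce")
    out["event"] = df["event"].astype(bool)
    for cov in covariates:
        if cov == "age":
            out["age"] = pd.to_numeric(df["age"], errors="coerce")
        elif cov == "sex":
            out["sex_M"] = (df["sex"] == "M").astype(float)
        elif cov == "histology":
            out["histology_LUSC"] = (df["histology"] == "LUSC").astype(float)
        elif cov == "smoking":
            smoke = df["smoking"].where(df["smoking"].isin(_SMOKING_LEVELS))
            out["smoking_EX"] = (smoke == "EX").astype(float)
            out["smoking_CS"] = (smoke == "CS").astype(float)
            out.loc[smoke.isna(), ["smoking_EX", "smoking_CS"]] = np.nan
        elif cov == "stage":
            stage = df["stage"].map({s: i + 1 for i, s in enumerate(_STAGE_ORDER)})
            if stage_as_ordinal:
                out["stage"] = stage.astype(float)
            else:
                for s in _STAGE_ORDER[1:]:
                    out[f"stage_{s}"] = (df["stage"] == s).astype(float)
                out.loc[stage.isna(), [c for c in out if c.startswith("stage_")]] = np.nan
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    if outlier is not None:
        flags = outlier.reindex(out.index)
        out["outlier"] = flags.astype("boolean").fillna(False).astype(float)
    n0 = len(out)
    out = out.dropna()
    if len(out) < n0:
        logger.info("complete-case filter: %d of %d patients retained",
                    len(out), n0)
    return out


def fit_cox(design: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Maximise the Cox partial likelihood over the design's covariates.

    ``design`` must carry time/event plus numeric covariate columns (use
    encode_covariates). Efron tie handling by default; per-subject log-PL
    contributions (Breslow risk-set form, zero for censored subjects) are
    attached for non-nested model comparison.
    """
    n_events = int(design["event"].sum())
    if n_events < 2:
        raise NoEventsError("need >= 2 observed events to fit")
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event",
                fit_options={"precision": 1e-10, "max_steps": 100})
    except Exception as exc:  # lifelines raises ConvergenceError/Warning
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    runaway = s.index[s["coef"].abs() > 10.0]
    if len(runaway):
        raise RuntimeError(
            f"monotone partial likelihood (complete separation) for "
            f"covariate {runaway[0]!r}")
    summary = pd.DataFrame({
        "covariate": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": np.exp(s["coef"].to_numpy()),
        "hr_ci_lower": np.exp(s["coef lower 95%"].to_numpy()),
        "hr_ci_upper": np.exp(s["coef upper 95%"].to_numpy()),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    beta = s["coef"].to_numpy()
    covs = list(s.index)
    contrib = _per_subject_contributions(design, covs, beta)
    ll = float(cph.log_likelihood_)
    return CoxResult(summary=summary, log_likelihood=ll,
                     aic=float(cph.AIC_partial_), n=len(design),
                     n_events=n_events, per_subject=contrib,
                     design=design)


def _per_subject_contributions(design: pd.DataFrame, covariates: list[str],
                               beta: np.ndarray) -> pd.Series:
    """l_i = x_i'b - log sum_{j in R(t_i)} exp(x_j'b) for events, else 0."""
    X = design[covariates].to_numpy(dtype=float)
    t = design["time"].to_numpy(dtype=float)
    e = design["event"].to_numpy(dtype=bool)
    eta = X @ beta
    # stabilise
    c = eta.max()
    w = np.exp(eta - c)
    order = np.argsort(-t)  # decreasing time; cumulative sums give risk sets
    csum = np.cumsum(w[order])
    # risk set of subject i: all j with t_j >= t_i (ties included)
    t_sorted = t[order]
    contrib = np.zeros(len(design))
    for i in np.flatnonzero(e):
        k = np.searchsorted(-t_sorted, -t[i], side="right") - 1
        contrib[i] = eta[i] - (np.log(csum[k]) + c)
    return pd.Series(contrib, index=design.index)


def compare_nonnested_cox(m1: CoxResult, m2: CoxResult):
    """Variance-weighted LR statistic for non-nested Cox models (Vuong-type).

    T = (l1 - l2) / (sqrt(n) * omega), omega^2 the sample variance of the
    per-subject differences in log partial-likelihood contributions;
    two-sided normal p. Identical per-subject contributions give (0, 1).
    """
    if m1.per_subject is None or m2.per_subject is None:
        raise ValueError("models lack per-subject contributions")
    if not m1.per_subject.index.equals(m2.per_subject.index):
        raise ValueError("models must be fitted on the same subjects")
    d = (m1.per_subject - m2.per_subject).to_numpy()
    n = d.size
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    omega = d.std(ddof=1)
    if omega == 0:
        raise ValueError("models are indistinguishable (zero variance of "
                         "contribution differences)")
    t_stat = d.sum() / (np.sqrt(n) * omega)
    return float(t_stat), float(2.0 * stats.norm.sf(abs(t_stat)))


# ---------------------------------------------------------------------------
# Kaplan–Meier and mortality summary


def km_estimate(design_or_meta: pd.DataFrame, groups: pd.Series):
    """Kaplan–Meier product-limit curves per group with Greenwood CIs.

    Returns (curves, medians): curves is a tidy frame (group, time,
    survival, ci lower/upper), medians maps group -> median survival.
    """
    df = design_or_meta
    curves = []
    medians = {}
    for g in pd.unique(groups.dropna()):
        mask = (groups == g).reindex(df.index).fillna(False)
        sub = df[mask]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"].astype(bool), label=str(g))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        frame = pd.DataFrame({
            "group": str(g),
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        })
        curves.append(frame)
        medians[g] = float(kmf.median_survival_time_)
    return pd.concat(curves, ignore_index=True), medians


def summarize_mortality(calls: DeficiencyCalls, metadata: pd.DataFrame):
    """Deceased x deficiency cross-tabulation with row/column percentages.

    Restricted to male patients with known vital status.
    """
    per_patient = (metadata.sort_values("tissue", ascending=False)
                   .drop_duplicates("patient_id").set_index("patient_id"))
    males = per_patient[per_patient["sex"] == "M"]
    dead = males["event"].astype("boolean").dropna()
    deficient = calls.table.set_index("patient_id")["deficient"]
    joined = pd.DataFrame({"deceased": dead}).join(deficient, how="inner")
    joined["deficient"] = joined["deficient"].fillna(False)
    counts = pd.crosstab(joined["deceased"], joined["deficient"])
    counts = counts.reindex(index=[False, True], columns=[False, True],
                            fill_value=0)
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return {"counts": counts, "row_pct": row_pct, "col_pct": col_pct}
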