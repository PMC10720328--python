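"""Clinical characterization and event-risk analysis of the phenogroups.

Given the cohort covariate/outcome table and the cluster labels, this module
compares clinical characteristics across clusters (two-sample Z tests for
means, chi-square tests for proportions), computes per-cluster incidence
rates (first event per subject, per 1,000 person-years), Kaplan-Meier
cumulative incidence curves with Greenwood variance, and covariate-adjusted
Cox proportional-hazards contrasts.

Cluster membership enters the Cox model with sum-to-zero **deviation
coding**, so each exp(beta_c) is the hazard of cluster c relative to the
cohort-average hazard rather than to a reference cluster; the omitted
level's coefficient is recovered as -sum(beta) with a delta-method standard
error.  Continuous covariates are scaled per SD before fitting
("standardized" hazard ratios); ties are handled with the Breslow
approximation.

Cohort-table utilities implement the outcome-derived echocardiographic
rules: LV hypertrophy from the LV mass index (g/m^2.7, sex-specific
thresholds) and LV diastolic dysfunction from E/e' with ancillary criteria
(low peak LA strain, LA enlargement, tricuspid regurgitation velocity,
prolonged reverse atrial flow).  Missing inputs propagate as unknown, never
as "no".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "ClusterComparison",
    "compare_clusters",
    "incidence_rates",
    "km_cumulative_incidence",
    "CoxClusterResult",
    "cox_cluster_hr",
    "cox_score",
    "classify_risk_rules",
    "DEFAULT_COX_COVARIATES",
]

#: Baseline risk factors used to adjust the cluster hazard ratios.
DEFAULT_COX_COVARIATES = [
    "age",
    "female",
    "bmi",
    "total_cholesterol",
    "sbp",
    "smoking",
    "cardiac_history",
    "diabetes",
]


def _outcome_cols(outcome: str) -> tuple[str, str]:
    if outcome not in ("cv", "cardiac"):
        raise ValueError("outcome must be 'cv' or 'cardiac'")
    return f"event_{outcome}", f"event_time_{outcome}_years"


# --- cluster characteristics --------------------------------------------------


@dataclass
class ClusterComparison:
    """Per-cluster summaries plus unadjusted pairwise tests (Table-style)."""

    summary: pd.DataFrame  # variable x cluster summary statistics
    pairwise: pd.DataFrame  # variable, cluster_a, cluster_b, statistic, p


def _z_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / a.size + vb / b.size)
    if denom == 0:
        return 0.0, 1.0
    z = (a.mean() - b.mean()) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _chi2_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    table = np.array(
        [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0):  # a category absent in both clusters
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_clusters(
    records: pd.DataFrame,
    labels: Sequence[int],
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ClusterComparison:
    """Cluster-wise means/proportions with pairwise Z and chi-square tests.

    Pairwise p-values are unadjusted by default (a Bonferroni switch is
    provided); significance at ``alpha`` is flagged per comparison.
    """
    labels = np.asarray(labels)
    if len(records) != labels.size:
        raise ValueError("labels must align with records")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters to compare")
    for lab in uniq:
        if not np.any(labels == lab):  # pragma: no cover
            raise ValueError(f"empty cluster {lab}")
    if continuous is None:
        continuous = [
            c
            for c in records.columns
            if records[c].dtype.kind == "f" and records[c].nunique() > 2
        ]
    if categorical is None:
        categorical = [
            c
            for c in records.columns
            if c not in continuous
            and c != "subject_id"
            and records[c].dropna().isin([0, 1]).all()
        ]

    n_pairs = uniq.size * (uniq.size - 1) // 2
    adj = n_pairs if bonferroni else 1

    summary_rows, pair_rows = [], []
    for var in list(continuous) + list(categorical):
        is_cont = var in continuous
        row: dict = {"variable": var, "type": "continuous" if is_cont else "binary"}
        groups = {}
        for lab in uniq:
            vals = records.loc[labels == lab, var].dropna().to_numpy(dtype=float)
            groups[lab] = vals
            if is_cont:
                row[f"cluster_{lab}"] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
                row[f"mean_{lab}"] = vals.mean()
            else:
                row[f"cluster_{lab}"] = f"{int(vals.sum())} ({100 * vals.mean():.1f}%)"
                row[f"prop_{lab}"] = vals.mean()
        summary_rows.append(row)
        for ia, a in enumerate(uniq):
            for b in uniq[ia + 1 :]:
                test = _z_test if is_cont else _chi2_test
                stat, p = test(groups[a], groups[b])
                p = min(p * adj, 1.0)
                pair_rows.append(
                    {
                        "variable": var,
                        "cluster_a": int(a),
                        "cluster_b": int(b),
                        "statistic": stat,
                        "p": p,
                        "significant": p < alpha,
                    }
                )
    return ClusterComparison(
        summary=pd.DataFrame(summary_rows), pairwise=pd.DataFrame(pair_rows)
    )


# --- incidence and survival ---------------------------------------------------


def incidence_rates(
    records: pd.DataFrame, labels: Sequence[int] | None, outcome: str = "cv"
) -> pd.DataFrame:
    """Events, person-years and rate per 1,000 person-years, per cluster and overall.

    Follow-up counts up to the first event per subject (the event time) or
    to censoring; cluster person-years and events sum to the cohort totals.
    """
    ev_col, t_col = _outcome_cols(outcome)
    times = records[t_col].to_numpy(dtype=float)
    events = records[ev_col].to_numpy(dtype=float)
    if np.any(times <= 0):
        raise ValueError("all follow-up times must be strictly positive")
    labels = (
        np.zeros(len(records), dtype=int) if labels is None else np.asarray(labels)
    )
    rows = []
    for lab in np.unique(labels):
        m = labels == lab
        py = times[m].sum()
        if py == 0:
            raise ValueError(f"zero person-years in cluster {lab}")
        rows.append(
            {
                "cluster": int(lab),
                "n": int(m.sum()),
                "events": int(events[m].sum()),
                "person_years": py,
                "rate_per_1000py": 1000.0 * events[m].sum() / py,
            }
        )
    total_py = times.sum()
    rows.append(
        {
            "cluster": "overall",
            "n": len(records),
            "events": int(events.sum()),
            "person_years": total_py,
            "rate_per_1000py": 1000.0 * events.sum() / total_py,
        }
    )
    return pd.DataFrame(rows)


def km_cumulative_incidence(
    records: pd.DataFrame, labels: Sequence[int] | None, outcome: str = "cv"
) -> dict[int, pd.DataFrame]:
    """Kaplan-Meier cumulative incidence (1 - S) per cluster with Greenwood SE.

    Returns one DataFrame per cluster with columns ``time``,
    ``cumulative_incidence``, ``survival``, ``se`` (Greenwood), ``at_risk``.
    """
    ev_col, t_col = _outcome_cols(outcome)
    times = records[t_col].to_numpy(dtype=float)
    events = records[ev_col].to_numpy(dtype=int)
    if np.any(times < 0):
        raise ValueError("negative event times")
    labels = (
        np.zeros(len(records), dtype=int) if labels is None else np.asarray(labels)
    )
    out: dict[int, pd.DataFrame] = {}
    for lab in np.unique(labels):
        m = labels == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        table = kmf.event_table
        S = kmf.survival_function_["KM_estimate"].to_numpy()
        # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
        n_risk = table["at_risk"].to_numpy(dtype=float)
        d = table["observed"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n_risk * (n_risk - d) > 0, d / (n_risk * (n_risk - d)), 0.0)
        se = S * np.sqrt(np.cumsum(term))
        out[int(lab)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "survival": S,
                "cumulative_incidence": 1.0 - S,
                "se": se,
                "at_risk": n_risk.astype(int),
            }
        )
    return out


# --- Cox regression with deviation-coded clusters -----------------------------


@dataclass
class CoxClusterResult:
    """Deviation-coded cluster hazard ratios plus covariate effects.

    ``cluster_effects`` rows: one per cluster (including the omitted level,
    recovered as -sum(beta) with delta-method SE) with ``beta``, ``se``,
    ``hr``, ``hr_lo``, ``hr_hi`` (95% CI) and Wald ``p``.
    """

    cluster_effects: pd.DataFrame
    covariate_effects: pd.DataFrame
    n_events: int
    outcome: str
    fitter: CoxPHFitter = field(repr=False, default=None)


def _deviation_design(labels: np.ndarray) -> tuple[pd.DataFrame, list[int]]:
    uniq = sorted(int(u) for u in np.unique(labels))
    cols = {}
    last = uniq[-1]
    for c in uniq[:-1]:
        col = np.where(labels == c, 1.0, np.where(labels == last, -1.0, 0.0))
        cols[f"dev_cluster_{c}"] = col
    return pd.DataFrame(cols), uniq


def cox_cluster_hr(
    records: pd.DataFrame,
    labels: Sequence[int],
    covariates: Sequence[str] = tuple(DEFAULT_COX_COVARIATES),
    outcome: str = "cv",
    ties: str = "breslow",
) -> CoxClusterResult:
    """Adjusted hazard of each cluster versus the cohort-average hazard.

    Cluster terms are deviation coded (sum-to-zero), so the log hazard
    ratios across clusters sum to 0 by construction and exp(beta_c)
    contrasts cluster c with the cohort average.  Continuous covariates are
    z-scored (per-SD hazard ratios); binary covariates enter as 0/1.
    """
    ev_col, t_col = _outcome_cols(outcome)
    labels = np.asarray(labels)
    design, uniq = _deviation_design(labels)
    dev_cols = list(design.columns)
    for cov in covariates:
        vals = records[cov].to_numpy(dtype=float)
        if np.unique(vals[~np.isnan(vals)]).size > 2:
            sd = np.nanstd(vals, ddof=1)
            vals = (vals - np.nanmean(vals)) / sd
        design[cov] = vals
    design[t_col] = records[t_col].to_numpy(dtype=float)
    design[ev_col] = records[ev_col].to_numpy(dtype=int)

    n_events = int(design[ev_col].sum())
    n_params = design.shape[1] - 2
    if n_events < 10 * n_params:
        import warnings

        warnings.warn(
            f"only {n_events} events for {n_params} parameters "
            "(< 10 events per parameter)",
            stacklevel=2,
        )

    if ties != "breslow":
        raise ValueError("only the Breslow tie approximation is supported")
    cph = CoxPHFitter()  # lifelines maximizes the Breslow partial likelihood
    cph.fit(
        design,
        duration_col=t_col,
        event_col=ev_col,
        robust=False,
        fit_options={"precision": 1e-12},  # solve score equations tightly
    )

    beta = cph.params_
    var = cph.variance_matrix_
    rows = []
    dev_beta = beta[dev_cols].to_numpy()
    for c, name in zip(uniq[:-1], dev_cols):
        b = float(beta[name])
        se = float(np.sqrt(var.loc[name, name]))
        rows.append((c, b, se))
    # omitted level: beta_last = -sum(beta_c), Var = 1' Sigma 1
    sub = var.loc[dev_cols, dev_cols].to_numpy()
    b_last = -float(dev_beta.sum())
    se_last = float(np.sqrt(np.ones(len(dev_cols)) @ sub @ np.ones(len(dev_cols))))
    rows.append((uniq[-1], b_last, se_last))

    with np.errstate(over="ignore"):  # an infinite CI bound is fine at tiny n
        cluster_effects = pd.DataFrame(
            [
                {
                    "cluster": c,
                    "beta": b,
                    "se": se,
                    "hr": np.exp(b),
                    "hr_lo": np.exp(b - 1.959963984540054 * se),
                    "hr_hi": np.exp(b + 1.959963984540054 * se),
                    "p": 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan,
                }
                for c, b, se in rows
            ]
        )
    cov_rows = []
    for covname in covariates:
        b = float(beta[covname])
        se = float(np.sqrt(var.loc[covname, covname]))
        cov_rows.append(
            {
                "covariate": covname,
                "beta": b,
                "se": se,
                "hr": np.exp(b),
                "p": 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan,
            }
        )
    return CoxClusterResult(
        cluster_effects=cluster_effects,
        covariate_effects=pd.DataFrame(cov_rows),
        n_events=n_events,
        outcome=outcome,
        fitter=cph,
    )


def cox_score(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> np.ndarray:
    """Breslow partial-likelihood score vector at ``beta`` (oracle utility).

    Independent of any fitting library; used to verify that a returned
    estimate solves the score equations and that the score test at beta=0
    for a single binary covariate reproduces the log-rank statistic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    eta = X @ np.atleast_1d(beta)
    w = np.exp(eta)
    score = np.zeros(X.shape[1])
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ws = w[risk]
        score += X[i] - (ws @ X[risk]) / ws.sum()
    return score


# --- echocardiographic rule classifiers ---------------------------------------


def classify_risk_rules(
    records: pd.DataFrame,
    lvh_threshold_men: float = 50.0,
    lvh_threshold_women: float = 47.0,
) -> pd.DataFrame:
    """Per-subject LV hypertrophy and diastolic-dysfunction flags.

    * LV hypertrophy: LV mass index (g/m^2.7) above the sex-specific
      threshold (defaults 50 men / 47 women).
    * LV diastolic dysfunction: E/e' >= 9.5, or borderline E/e' in
      [8.5, 9.5) combined with any of: peak LA strain < 23%, LAVI >= 45
      ml/m^2, TR velocity > 2.5 m/s, or prolonged reverse atrial flow
      (mitral A-flow duration <= PV reversal duration - 10 ms).

    Missing inputs yield ``pd.NA`` (unknown), not False: Kleene logic makes
    e.g. a borderline E/e' with one ancillary criterion positive True even
    if the others are missing.
    """

    def col(name: str) -> pd.Series:
        if name in records:
            return pd.to_numeric(records[name], errors="coerce")
        return pd.Series(np.nan, index=records.index, dtype=float)

    def gt(s: pd.Series, v: float) -> pd.Series:
        return pd.Series(s > v, dtype="boolean").mask(s.isna())

    def ge(s: pd.Series, v: float) -> pd.Series:
        return pd.Series(s >= v, dtype="boolean").mask(s.isna())

    def lt(s: pd.Series, v: float) -> pd.Series:
        return pd.Series(s < v, dtype="boolean").mask(s.isna())

    lvmi = col("lvmi_gm27")
    female = col("female")
    thr = np.where(female == 1, lvh_threshold_women, lvh_threshold_men)
    lvh = pd.Series(lvmi.to_numpy() > thr, dtype="boolean", index=records.index).mask(
        lvmi.isna() | female.isna()
    )

    ee = col("e_over_eprime")
    la_strain = col("la_peak_strain")
    lavi = col("lavi")
    tr = col("tr_velocity")
    a_dur = col("mitral_a_duration_ms")
    pv_dur = col("pv_reversal_duration_ms")

    definite = ge(ee, 9.5)
    borderline = ge(ee, 8.5) & lt(ee, 9.5)
    prolonged = pd.Series(
        a_dur <= pv_dur - 10.0, dtype="boolean", index=records.index
    ).mask(a_dur.isna() | pv_dur.isna())
    ancillary = lt(la_strain, 23.0) | ge(lavi, 45.0) | gt(tr, 2.5) | prolonged
    dysfunction = definite | (borderline & ancillary)

    return pd.DataFrame(
        {
            "subject_id": records.get("subject_id", pd.Series(records.index).astype(str)),
            "lv_hypertrophy": lvh,
            "diastolic_dysfunction": dysfunction,
        }
    )
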