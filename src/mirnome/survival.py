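"""Expression-cutpoint survival screening.

For each miRNA, patients are dichotomized into low/high expression groups at
the cutpoint maximizing the log-rank chi-square over all admissible splits
(every midpoint between consecutive distinct expression values leaving both
groups at least ``min_fraction`` of patients) — a transparent re-creation of
X-tile-style cohort separation.  Discovery-cohort log-rank p-values are BH
corrected across features; validation uses raw p < 0.05.  Candidates are then
tested for independence from cell of origin (COO) and the International
Prognostic Index (IPI) in a multivariate Cox proportional-hazards model,
and replication requires independence for both endpoints in both cohorts
with concordant effect direction.

Note the selection caveat: the maximally selected log-rank p is
anti-conservative (it is the minimum over many correlated tests).  The screen
applies BH to it as-is, reproducing the published procedure; it is a ranking
device, not a calibrated error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .diffexp import bh_adjust
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

ENDPOINTS = ("OS", "PFS")


@dataclass
class ClinicalTable:
    """Per-patient outcome and covariate data.

    Columns: os_time, os_event (death from any cause), pfs_time, pfs_event
    (progression or death from any cause), ipi (ordinal 0-5 or a low/high
    label), coo (ABC/GCB/unclassified), cohort (discovery/validation).
    Times are in days.
    """

    table: pd.DataFrame

    REQUIRED = ("os_time", "os_event", "pfs_time", "pfs_event", "ipi", "coo", "cohort")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        for col in ("os_time", "pfs_time"):
            if (self.table[col] < 0).any():
                raise ValueError(f"negative times in {col}")
        for col in ("os_event", "pfs_event"):
            if not self.table[col].isin([0, 1]).all():
                raise ValueError(f"non-binary events in {col}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    def endpoint(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        which = which.upper()
        if which not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {which!r}")
        prefix = which.lower()
        return (
            self.table[f"{prefix}_time"].to_numpy(dtype=float),
            self.table[f"{prefix}_event"].to_numpy(dtype=int),
        )

    def subset(self, patient_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(patient_ids)])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "patient_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        return cls(table=pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class CutpointResult:
    feature_id: str
    endpoint: str
    cutpoint: float
    group_labels: pd.Series  # per-patient 'low' / 'high'
    logrank_chisq: float
    logrank_p: float
    logrank_q: float = np.nan
    candidate: bool = False
    cox_feature_p: float = np.nan
    cox_feature_coef: float = np.nan
    cox_coefficients: pd.DataFrame = field(default_factory=pd.DataFrame)
    independent: bool = False


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a DataFrame with columns (time, survival); censored-only data stay
    flat at 1.0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p.

    Observed minus expected events in group 1, with the hypergeometric
    variance at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups).astype(bool)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be non-empty")
    stat = _logrank_chi2(times, events, groups)
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return float(stat), p


def _logrank_chi2(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> float:
    all_event = np.sort(times[events == 1])
    if all_event.size == 0:
        return 0.0
    uniq = np.unique(all_event)
    sorted_times = np.sort(times)
    n_at = times.size - np.searchsorted(sorted_times, uniq, side="left")
    d = (
        np.searchsorted(all_event, uniq, side="right")
        - np.searchsorted(all_event, uniq, side="left")
    )
    g_times = np.sort(times[groups])
    n1_at = g_times.size - np.searchsorted(g_times, uniq, side="left")
    g_event = np.sort(times[(events == 1) & groups])
    d1 = (
        np.searchsorted(g_event, uniq, side="right")
        - np.searchsorted(g_event, uniq, side="left")
    )
    frac = n1_at / n_at
    e1 = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n_at > 1, d * frac * (1 - frac) * (n_at - d) / (n_at - 1), 0.0)
    var = v.sum()
    if var <= 0:
        return 0.0
    return float((d1.sum() - e1.sum()) ** 2 / var)


def optimal_cutpoint(
    expression: pd.Series,
    clinical: ClinicalTable,
    endpoint: str = "OS",
    min_fraction: float = 0.10,
) -> CutpointResult:
    """Exhaustive maximal log-rank dichotomization.

    Every midpoint between consecutive distinct sorted expression values whose
    split leaves both groups >= ``min_fraction`` of patients is evaluated; the
    cutpoint with the largest log-rank chi-square wins, ties broken toward the
    more balanced split, then the smaller cutpoint.
    """
    expr = expression.loc[clinical.patient_ids].to_numpy(dtype=float)
    n = expr.size
    distinct = np.unique(expr)
    if distinct.size < 2:
        raise ValueError("all expression values identical")
    min_count = min_fraction * n
    times, events = clinical.endpoint(endpoint)
    best = None  # (chi2, balance, -cutpoint)
    best_cut = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        high = expr > cut
        n_high = int(high.sum())
        if n_high < min_count or (n - n_high) < min_count:
            continue
        chi2 = _logrank_chi2(times, events, high)
        balance = min(n_high, n - n_high)
        key = (chi2, balance, -cut)
        if best is None or key > best:
            best = key
            best_cut = cut
    if best is None:
        raise ValueError("no admissible split satisfies the minimum group size")
    high = expr > best_cut
    labels = pd.Series(np.where(high, "high", "low"), index=clinical.patient_ids)
    chi2 = best[0]
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return CutpointResult(
        feature_id=str(expression.name),
        endpoint=endpoint,
        cutpoint=float(best_cut),
        group_labels=labels,
        logrank_chisq=float(chi2),
        logrank_p=p,
    )


def _encode_covariates(group_labels: pd.Series, clinical: ClinicalTable) -> pd.DataFrame:
    """Design matrix: high-expression indicator, COO as two indicators (GCB
    reference), IPI as ordinal (or a high-group indicator for labelled IPI)."""
    tab = clinical.table
    df = pd.DataFrame(index=tab.index)
    df["expr_high"] = (group_labels.loc[tab.index] == "high").astype(float)
    df["coo_ABC"] = (tab["coo"] == "ABC").astype(float)
    df["coo_unclassified"] = (tab["coo"] == "unclassified").astype(float)
    ipi = tab["ipi"]
    if ipi.dtype == object:
        df["ipi"] = (ipi.astype(str).str.lower() == "high").astype(float)
    else:
        df["ipi"] = ipi.astype(float)
    return df


def cox_multivariate(
    group_labels: pd.Series,
    clinical: ClinicalTable,
    endpoint: str = "OS",
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of the expression group adjusted for COO
    and IPI (Efron tie handling).  Returns per-covariate (coef, hr, p)."""
    times, events = clinical.endpoint(endpoint)
    if events.sum() == 0:
        raise ValueError("no events")
    df = _encode_covariates(group_labels, clinical)
    if extra_covariates is not None:
        df = pd.concat([df, extra_covariates.loc[df.index]], axis=1)
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    df = df.drop(columns=constant)
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines convergence / collinearity
        raise ValueError(f"Cox fit failed ({exc})") from exc
    out = pd.DataFrame(
        {
            "coef": cph.params_,
            "hr": np.exp(cph.params_),
            "p": cph.summary["p"],
        }
    )
    for c in constant:
        out.loc[c] = [np.nan, np.nan, np.nan]
    return out


def survival_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    endpoints=("OS", "PFS"),
    mode: str = "discovery",
    min_fraction: float = 0.10,
    q_max: float = 0.05,
    p_max: float = 0.05,
    cox_p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-feature, per-endpoint cutpoint screen with Cox independence gate.

    Discovery mode: features are candidates iff the BH-adjusted maximal
    log-rank p is < q_max (BH across features within an endpoint).
    Validation mode: candidates iff the raw p is < p_max.  Candidates are
    then fit with the multivariate Cox model; ``independent`` marks a Cox
    feature p < cox_p_max.  Per-feature failures are skipped with a log
    message, never aborting the screen.
    """
    if mode not in ("discovery", "validation"):
        raise ValueError(f"unknown mode {mode!r}")
    patients = [p for p in clinical.patient_ids if p in set(expr.sample_ids)]
    if not patients:
        raise ValueError("no patients shared between expression and clinical data")
    clin = clinical.subset(patients)
    rows = []
    cut_results: dict[tuple[str, str], CutpointResult] = {}
    for endpoint in endpoints:
        for fid in expr.feature_ids:
            series = expr.values.loc[fid, patients]
            series.name = fid
            try:
                res = optimal_cutpoint(series, clin, endpoint=endpoint, min_fraction=min_fraction)
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", fid, endpoint, exc)
                continue
            cut_results[(fid, endpoint)] = res
            rows.append(
                {
                    "feature_id": fid,
                    "endpoint": endpoint,
                    "cutpoint": res.cutpoint,
                    "logrank_chisq": res.logrank_chisq,
                    "logrank_p": res.logrank_p,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["logrank_q"] = np.nan
    result["candidate"] = False
    for endpoint in endpoints:
        mask = result["endpoint"] == endpoint
        if mode == "discovery":
            q = bh_adjust(result.loc[mask, "logrank_p"].to_numpy())
            result.loc[mask, "logrank_q"] = q
            result.loc[mask, "candidate"] = q < q_max
        else:
            result.loc[mask, "candidate"] = result.loc[mask, "logrank_p"] < p_max
    result["cox_feature_p"] = np.nan
    result["cox_feature_coef"] = np.nan
    result["independent"] = False
    for idx, row in result[result["candidate"]].iterrows():
        res = cut_results[(row["feature_id"], row["endpoint"])]
        try:
            coeffs = cox_multivariate(res.group_labels, clin, endpoint=row["endpoint"])
        except ValueError as exc:
            logger.warning("Cox skipped for %s/%s: %s", row["feature_id"], row["endpoint"], exc)
            continue
        res.cox_coefficients = coeffs
        res.cox_feature_p = float(coeffs.loc["expr_high", "p"])
        res.cox_feature_coef = float(coeffs.loc["expr_high", "coef"])
        result.loc[idx, "cox_feature_p"] = res.cox_feature_p
        result.loc[idx, "cox_feature_coef"] = res.cox_feature_coef
        result.loc[idx, "independent"] = res.cox_feature_p < cox_p_max
    return result


def independent_both_endpoints(results: pd.DataFrame, endpoints=("OS", "PFS")) -> pd.DataFrame:
    """Features independent of COO/IPI for every requested endpoint, with the
    feature's Cox coefficient per endpoint."""
    if results.empty:
        return pd.DataFrame(columns=["feature_id"])
    ind = results[results["independent"]]
    piv = ind.pivot_table(index="feature_id", columns="endpoint", values="cox_feature_coef", aggfunc="first")
    have_all = piv.dropna(subset=[e for e in endpoints if e in piv.columns])
    if set(endpoints) - set(piv.columns):
        return pd.DataFrame(columns=["feature_id"]).set_index("feature_id")
    return have_all


def replicate(
    discovery_results: pd.DataFrame,
    validation_results: pd.DataFrame,
    endpoints=("OS", "PFS"),
) -> list[str]:
    """Features independently associated with every endpoint in both cohorts,
    with concordant (same-sign) Cox coefficients per endpoint."""
    disc = independent_both_endpoints(discovery_results, endpoints)
    valid = independent_both_endpoints(validation_results, endpoints)
    shared = sorted(set(disc.index) & set(valid.index))
    out = []
    for fid in shared:
        if all(np.sign(disc.loc[fid, e]) == np.sign(valid.loc[fid, e]) for e in endpoints):
            out.append(fid)
    return out
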