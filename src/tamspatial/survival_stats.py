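"""Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards
models for median-split biomarker screens.

The KM estimator and log-rank test are delegated to lifelines; Cox partial-
likelihood fits go through statsmodels ``PHReg`` with Efron tie handling by
default (Breslow selectable for cross-checks against other software). All
derived columns keep the standard identities HR = exp(B),
Wald = (B/SE)², CI95 = exp(B ± 1.96·SE) exactly, with the Wald p computed
from the same z so the printed columns are mutually consistent.

Time is in months. Records with time exactly zero are perturbed by half the
smallest positive time (logged) so the partial likelihood is well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .hypothesis_tests import bh_adjust
from .spatial_metrics import HIGH_OR_LONG, LOW_OR_CLOSE, dichotomize

logger = logging.getLogger(__name__)

#: SE beyond which a binary-covariate fit is flagged as separated
_SEPARATION_SE = 50.0


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time_months: float
    event: bool  # True = dead, False = censored

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise SurvivalError(
                f"{self.sample_id}: negative survival time")


def records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    df = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "time": [float(r.time_months) for r in records],
        "event": [bool(r.event) for r in records],
    }).set_index("sample_id")
    zero = df["time"] == 0
    if zero.any():
        positive = df.loc[df["time"] > 0, "time"]
        eps = 0.5 * float(positive.min()) if len(positive) else 0.5
        logger.info("perturbing %d zero survival times by +%g", zero.sum(), eps)
        df.loc[zero, "time"] += eps
    return df


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: S(t) step function with at-risk counts at
    every observed (event or censoring) time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator. Censored times do not drop the
    curve; at-risk counts decrement on both events and censorings."""
    if not records:
        raise SurvivalError("km_estimate needs >= 1 record")
    df = records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank(groups: Mapping[str, Sequence[SurvivalRecord]]) -> LogRankResult:
    """Log-rank test across >= 2 groups (observed vs expected events over
    pooled event times; chi-square with df = k - 1)."""
    if len(groups) < 2:
        raise SurvivalError("logrank needs >= 2 groups")
    times, events, labels = [], [], []
    for name, recs in groups.items():
        if not recs:
            raise SurvivalError(f"group {name!r} has no records")
        frame = records_frame(list(recs))
        times.append(frame["time"].to_numpy())
        events.append(frame["event"].to_numpy())
        labels.extend([name] * len(frame))
    res = multivariate_logrank_test(
        np.concatenate(times), np.asarray(labels, dtype=object),
        np.concatenate(events))
    return LogRankResult(chi2=float(res.test_statistic),
                         df=len(groups) - 1, p=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxCoefficient:
    covariate: str
    B: float
    SE: float
    wald: float
    HR: float
    ci95_low: float
    ci95_high: float
    p: float
    flagged: Optional[str] = None  # "constant" | "separation"


@dataclass
class CoxResult:
    coefficients: dict[str, CoxCoefficient]
    n: int
    n_events: int
    ties: str

    def __getitem__(self, name: str) -> CoxCoefficient:
        return self.coefficients[name]

    def frame(self) -> pd.DataFrame:
        rows = [{
            "covariate": c.covariate, "B": c.B, "SE": c.SE, "Wald": c.wald,
            "HR": c.HR, "CI95_low": c.ci95_low, "CI95_high": c.ci95_high,
            "p": c.p, "flag": c.flagged or "",
        } for c in self.coefficients.values()]
        return pd.DataFrame(rows)


def _coefficient(name: str, b: float, se: float,
                 flagged: Optional[str] = None) -> CoxCoefficient:
    z = b / se if np.isfinite(se) and se > 0 else 0.0
    with np.errstate(over="ignore"):  # exp(inf) CI bound for dropped terms
        return CoxCoefficient(
            covariate=name, B=b, SE=se, wald=z * z, HR=float(np.exp(b)),
            ci95_low=float(np.exp(b - 1.96 * se)),
            ci95_high=float(np.exp(b + 1.96 * se)),
            p=float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0,
            flagged=flagged)


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame | Mapping[str, Mapping[str, float]],
    ties: str = "efron",
) -> CoxResult:
    """Multivariable Cox PH fit by partial-likelihood maximization.

    ``covariates`` maps covariate name -> per-sample value (or a DataFrame
    indexed by sample_id). Constant covariates are dropped with a warning
    (zero information); a separated binary covariate is returned with its
    huge SE and a ``separation`` flag rather than an exception.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError("ties must be 'efron' or 'breslow'")
    df = records_frame(records)
    if not df["event"].any():
        raise SurvivalError("cox_fit needs >= 1 event")
    cov = (covariates if isinstance(covariates, pd.DataFrame)
           else pd.DataFrame(covariates))
    cov = cov.astype(float)
    missing = set(df.index) - set(cov.index)
    if missing:
        raise SurvivalError(f"covariates missing for samples {sorted(missing)}")
    cov = cov.loc[df.index]

    kept, dropped = [], []
    for name in cov.columns:
        if cov[name].nunique() <= 1:
            dropped.append(name)
            logger.warning("covariate %r is constant; dropped (no "
                           "information)", name)
        else:
            kept.append(name)

    coeffs: dict[str, CoxCoefficient] = {}
    if kept:
        model = PHReg(df["time"].to_numpy(), cov[kept].to_numpy(),
                      status=df["event"].to_numpy(dtype=int), ties=ties)
        params = bse = None
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="newton", disp=False, maxiter=200)
            if np.all(np.isfinite(res.params)):
                params, bse = res.params, res.bse
        except np.linalg.LinAlgError:
            pass
        if params is None:
            # monotone likelihood (complete separation): the unpenalized
            # Hessian is singular; refit with a small ridge so a finite,
            # clearly-flagged large-SE answer is returned
            separated = True
            logger.warning("cox_fit: singular/non-finite unpenalized fit; "
                           "refitting with a small ridge (likely complete "
                           "separation)")
            from lifelines import CoxPHFitter
            frame = cov[kept].copy()
            frame["_T"], frame["_E"] = df["time"], df["event"]
            cph = CoxPHFitter(penalizer=1e-3)
            cph.fit(frame, duration_col="_T", event_col="_E")
            params = cph.params_.to_numpy()
            bse = cph.standard_errors_.to_numpy()
        for i, name in enumerate(kept):
            b, se = float(params[i]), float(bse[i])
            flag = ("separation"
                    if separated or se > _SEPARATION_SE else None)
            if flag:
                logger.warning("covariate %r: likely complete separation "
                               "(B=%.3g, SE=%.3g)", name, b, se)
            coeffs[name] = _coefficient(name, b, se, flag)
        if not separated:
            grad = np.asarray(model.score(params), dtype=float)
            if np.max(np.abs(grad)) > 1e-4 and not any(
                    c.flagged for c in coeffs.values()):
                raise SurvivalError(
                    f"cox_fit gradient norm {np.max(np.abs(grad)):.3g} "
                    f"after maximization; params={params}")
    for name in dropped:
        coeffs[name] = _coefficient(name, 0.0, float("inf"),
                                    flagged="constant")
    # preserve caller's covariate order
    coeffs = {name: coeffs[name] for name in cov.columns}
    return CoxResult(coefficients=coeffs, n=len(df),
                     n_events=int(df["event"].sum()), ties=ties)


# ---------------------------------------------------------------------------
# median-split screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    feature: str
    n_low: int
    n_high: int
    km_low: KMCurve
    km_high: KMCurve
    logrank_chi2: float
    logrank_p: float
    cox: Optional[CoxResult]


def survival_screen(
    records: Sequence[SurvivalRecord],
    feature_table: pd.DataFrame,
    adjusters: Optional[pd.DataFrame] = None,
    ties: str = "efron",
    include_cox: bool = True,
) -> tuple[list[ScreenRow], pd.DataFrame]:
    """Median-split screen of per-sample features against overall survival.

    For each feature column: dichotomize at the cohort median (ties go to
    the low/close group), estimate KM curves per group, test them with the
    (unadjusted) log-rank test, and fit a Cox model for the low-vs-high
    indicator (low = 1) adjusted by the ``adjusters`` columns.

    Returns the detailed rows plus a flat results frame; the frame carries a
    BH-adjusted column alongside the raw unadjusted p-values for
    convenience — the primary screen criterion is the unadjusted p.
    """
    rec_by_id = {r.sample_id: r for r in records}
    rows: list[ScreenRow] = []
    for feature in feature_table.columns:
        values = feature_table[feature].dropna()
        values = values[values.index.isin(rec_by_id)]
        if values.nunique() <= 1:
            logger.info("feature %r: all values tied or missing; skipped",
                        feature)
            continue
        labels = dichotomize(values.to_dict())
        low = [rec_by_id[s] for s, g in labels.items() if g == LOW_OR_CLOSE]
        high = [rec_by_id[s] for s, g in labels.items() if g == HIGH_OR_LONG]
        if not high:  # median == max: the split is degenerate
            logger.info("feature %r: no samples above the median; skipped",
                        feature)
            continue
        lr = logrank({LOW_OR_CLOSE: low, HIGH_OR_LONG: high})

        cox_res: Optional[CoxResult] = None
        if include_cox:
            ids = list(labels)
            cov = pd.DataFrame(
                {"low_vs_high": [1.0 if labels[s] == LOW_OR_CLOSE else 0.0
                                 for s in ids]}, index=ids)
            if adjusters is not None:
                cov = pd.concat([adjusters.loc[ids].astype(float), cov],
                                axis=1)
            try:
                cox_res = cox_fit([rec_by_id[s] for s in ids], cov,
                                  ties=ties)
            except SurvivalError as exc:
                logger.warning("feature %r: Cox fit failed (%s)", feature,
                               exc)
        rows.append(ScreenRow(
            feature=feature, n_low=len(low), n_high=len(high),
            km_low=km_estimate(low), km_high=km_estimate(high),
            logrank_chi2=lr.chi2, logrank_p=lr.p, cox=cox_res))

    flat = pd.DataFrame([{
        "feature": r.feature, "n_low": r.n_low, "n_high": r.n_high,
        "logrank_chi2": r.logrank_chi2, "logrank_p": r.logrank_p,
        "cox_B": r.cox["low_vs_high"].B if r.cox else np.nan,
        "cox_SE": r.cox["low_vs_high"].SE if r.cox else np.nan,
        "cox_HR": r.cox["low_vs_high"].HR if r.cox else np.nan,
        "cox_CI95_low": r.cox["low_vs_high"].ci95_low if r.cox else np.nan,
        "cox_CI95_high": r.cox["low_vs_high"].ci95_high if r.cox else np.nan,
        "cox_p": r.cox["low_vs_high"].p if r.cox else np.nan,
    } for r in rows])
    if len(flat):
        flat["logrank_p_bh"] = bh_adjust(flat["logrank_p"].to_numpy())
    return rows, flat
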