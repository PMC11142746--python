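"""Biomarker cutoffs, patient stratification, and survival analysis.

Cutoffs dichotomize a patient-level marker MFI either at the value
maximizing the Youden index (sensitivity + specificity - 1) of an ROC
analysis against the death indicator, or at the sample median. Strata feed
Kaplan-Meier curves, the log-rank test, a single-covariate Cox
proportional-hazards model (Efron tie handling), and a logistic regression
of death on the continuous marker. KM/log-rank/Cox go through lifelines and
the logistic fit through statsmodels; the ROC cutoff search is implemented
here because its candidate set is the midpoints between consecutive
distinct values (plus the two infinite endpoints), with ties broken toward
the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import AnalysisError, ConfigurationError, DegenerateInputError, FitConvergenceError


def _safe_exp(x: float) -> float:
    """exp() that saturates to inf instead of raising OverflowError."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


# --------------------------------------------------------------------------
# cutoffs
# --------------------------------------------------------------------------

@dataclass
class CutoffSpec:
    """A dichotomizing threshold for one marker/compartment readout.

    ``direction`` records which side of the threshold predicts death in the
    ROC analysis (``"ge"``: values >= threshold predict death). Stratum
    labels are always expression-based: ``high`` means value > threshold.
    """

    marker: str
    compartment_class: str
    method: str                   # {"roc", "median"}
    threshold: float
    sensitivity: float = math.nan
    specificity: float = math.nan
    auc: float = math.nan
    direction: str = "ge"
    degenerate: bool = False

    def assign(self, value: float) -> str | float:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return math.nan
        return "high" if value > self.threshold else "low"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "marker", "compartment_class", "method", "threshold",
            "sensitivity", "specificity", "auc", "direction", "degenerate")}


def _rank_auc(values: np.ndarray, outcome: np.ndarray) -> float:
    """P(value_death > value_survivor) + 0.5 P(tie), by the rank method."""
    pos = values[outcome == 1]
    neg = values[outcome == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def roc_cutoff(
    values: np.ndarray,
    outcome: np.ndarray,
    marker: str = "",
    compartment_class: str = "epithelial",
) -> CutoffSpec:
    """ROC-derived cutoff maximizing the Youden index.

    The score orientation is chosen so the AUC is >= 0.5 (if deaths sit at
    lower values, low values predict death). Candidate thresholds are the
    midpoints between consecutive distinct sorted values plus the +/-inf
    endpoints; among ties in Youden the smallest threshold wins. With all
    values identical the cutoff is degenerate (AUC 0.5, flagged).
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if values.ndim != 1 or values.shape != outcome.shape:
        raise ConfigurationError("values and outcome must be equal-length 1-D arrays")
    if np.isnan(values).any():
        raise ConfigurationError("missing marker values must be filtered before ROC analysis")
    if len(np.unique(outcome)) < 2:
        raise DegenerateInputError("outcome has a single class; ROC undefined")

    if np.ptp(values) == 0:
        return CutoffSpec(marker, compartment_class, "roc", float(values[0]),
                          sensitivity=math.nan, specificity=math.nan,
                          auc=0.5, direction="ge", degenerate=True)

    auc_high = _rank_auc(values, outcome)
    direction = "ge" if auc_high >= 0.5 else "lt"
    auc = auc_high if direction == "ge" else 1.0 - auc_high

    distinct = np.unique(values)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    n_pos = (outcome == 1).sum()
    n_neg = (outcome == 0).sum()
    best = None
    for thr in candidates:
        pred_death = values >= thr if direction == "ge" else values < thr
        sens = (pred_death & (outcome == 1)).sum() / n_pos
        spec = (~pred_death & (outcome == 0)).sum() / n_neg
        youden = sens + spec - 1.0
        if best is None or youden > best[0] + 1e-12:
            best = (youden, thr, sens, spec)
    _, thr, sens, spec = best
    return CutoffSpec(marker, compartment_class, "roc", float(thr),
                      sensitivity=float(sens), specificity=float(spec),
                      auc=float(auc), direction=direction)


def median_cutoff(
    values: np.ndarray, marker: str = "", compartment_class: str = "epithelial"
) -> CutoffSpec:
    """Median-MFI cutoff: ``high`` is value > median, ``low`` is <= median."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ConfigurationError("median cutoff needs at least 2 values")
    return CutoffSpec(marker, compartment_class, "median", float(np.median(values)))


def stratify(
    patients: pd.DataFrame,
    cutoffs: list[CutoffSpec],
    combine: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Attach per-marker high/low stratum columns (and a combined one).

    For each cutoff, column ``stratum_<marker>_<class>`` is ``high`` when
    ``<marker>_<class>`` exceeds the threshold, ``low`` otherwise, missing
    when the value is missing. ``combine=(m1, m2)`` adds
    ``stratum_<m1>_<m2>`` with four-way ``hi/lo`` labels based on the two
    epithelial strata.
    """
    out = patients.copy()
    by_marker: dict[tuple[str, str], CutoffSpec] = {}
    for cut in cutoffs:
        col = f"{cut.marker}_{cut.compartment_class}"
        if col not in out.columns:
            raise ConfigurationError(f"patient table lacks column {col!r} for cutoff")
        out[f"stratum_{col}"] = out[col].map(cut.assign)
        by_marker[(cut.marker, cut.compartment_class)] = cut
    if combine is not None:
        m1, m2 = combine
        c1, c2 = f"stratum_{m1}_epithelial", f"stratum_{m2}_epithelial"
        for c in (c1, c2):
            if c not in out.columns:
                raise ConfigurationError(f"combined stratification needs column {c!r}")
        short = {"high": "hi", "low": "lo"}

        def _comb(row):
            a, b = row[c1], row[c2]
            if pd.isna(a) or pd.isna(b):
                return math.nan
            return f"{short[a]}/{short[b]}"

        out[f"stratum_{m1}_{m2}"] = out.apply(_comb, axis=1)
    return out


# --------------------------------------------------------------------------
# survival fits
# --------------------------------------------------------------------------

@dataclass
class StratumKM:
    """Kaplan-Meier summary of one stratum."""

    label: str
    n: int
    n_events: int
    table: pd.DataFrame            # time, n_at_risk, n_events, survival
    median_os: float | None        # months; None = not reached
    rate_at: dict[float, float]    # horizon (months) -> S(horizon)


@dataclass
class SurvivalFit:
    strata: dict[str, StratumKM]
    logrank_chi2: float = math.nan
    logrank_p: float = math.nan
    cox: dict | None = None


def kaplan_meier(
    times: np.ndarray, events: np.ndarray, horizons: list[float] = (), label: str = ""
) -> StratumKM:
    """Product-limit estimate for one stratum.

    Median OS is the first time the curve drops to <= 0.5 (None when never
    reached); ``rate_at`` evaluates the right-continuous step function at
    each horizon (e.g. 60 months for the 5-year overall-survival rate).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise AnalysisError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "n_at_risk": et["at_risk"].to_numpy(dtype=int),
            "n_events": et["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
        }
    )
    med = kmf.median_survival_time_
    median_os = None if np.isinf(med) else float(med)
    rate_at = {}
    for h in horizons:
        below = surv[surv.index <= h]
        rate_at[float(h)] = float(below.iloc[-1]) if len(below) else 1.0
    return StratumKM(label=label, n=len(times), n_events=int(events.sum()),
                     table=table, median_os=median_os, rate_at=rate_at)


def km_logrank(
    patients: pd.DataFrame,
    stratum_col: str,
    horizons: list[float] = (60.0,),
    time_col: str = "os_months",
    event_col: str = "event",
) -> SurvivalFit:
    """Kaplan-Meier per stratum plus the (k-1)-df log-rank test.

    Patients with a missing stratum are dropped. Raises ``AnalysisError``
    with fewer than two non-empty strata or zero events overall.
    """
    df = patients.dropna(subset=[stratum_col])
    groups = sorted(df[stratum_col].unique())
    if len(groups) < 2:
        raise AnalysisError(
            f"log-rank needs >= 2 strata in {stratum_col!r}, found {groups}"
        )
    if df[event_col].sum() == 0:
        raise AnalysisError("no events observed in any stratum")
    strata = {
        g: kaplan_meier(sub[time_col], sub[event_col], horizons, label=str(g))
        for g, sub in df.groupby(stratum_col)
    }
    res = multivariate_logrank_test(df[time_col], df[stratum_col], df[event_col])
    return SurvivalFit(
        strata=strata,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_fit(
    patients: pd.DataFrame,
    covariate_col: str,
    time_col: str = "os_months",
    event_col: str = "event",
    reference: str = "low",
) -> dict:
    """Single-covariate Cox proportional-hazards fit (Efron ties).

    A two-level string stratum column is coded 0 for ``reference`` and 1
    otherwise, so the hazard ratio is non-reference vs reference (with
    strata ``high``/``low`` and the default reference, HR = high vs low).
    Returns ``{"hazard_ratio", "ci_low", "ci_high", "p", "coef"}``. Raises
    ``FitConvergenceError`` on non-convergence or monotone likelihood.
    """
    df = patients.dropna(subset=[covariate_col, time_col, event_col]).copy()
    col = df[covariate_col]
    if col.dtype == object:
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ConfigurationError(
                f"string covariate {covariate_col!r} must have 2 levels, found {levels}"
            )
        if reference not in levels:
            raise ConfigurationError(f"reference {reference!r} not among {levels}")
        df["_x"] = (col != reference).astype(float)
    else:
        df["_x"] = col.astype(float)
    if df[event_col].sum() < 1:
        raise AnalysisError("Cox fit needs at least one event")
    if df["_x"].nunique() < 2:
        raise DegenerateInputError("covariate is constant; hazard ratio undefined")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[time_col, event_col, "_x"]], duration_col=time_col,
                    event_col=event_col)
    except ConvergenceError as exc:
        raise FitConvergenceError(f"Cox model did not converge: {exc}") from exc
    coef = float(cph.params_["_x"])
    se = float(cph.standard_errors_["_x"])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 20:
        raise FitConvergenceError("monotone partial likelihood (perfect separation)")
    return {
        "hazard_ratio": _safe_exp(coef),
        "ci_low": _safe_exp(coef - 1.959963984540054 * se),
        "ci_high": _safe_exp(coef + 1.959963984540054 * se),
        "p": float(cph.summary.loc["_x", "p"]),
        "coef": coef,
    }


def logistic_death_association(
    patients: pd.DataFrame,
    value_col: str,
    event_col: str = "event",
    per_sd: bool = False,
) -> dict:
    """Logistic regression of the death indicator on a marker level.

    Returns the odds ratio per unit (or per SD) with Wald 95% CI and p.
    Raises ``FitConvergenceError`` on perfect separation.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = patients.dropna(subset=[value_col, event_col])
    y = df[event_col].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("death indicator has a single class")
    x = df[value_col].astype(float).to_numpy()
    if per_sd:
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("marker values are constant")
        x = x / sd
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitConvergenceError(f"logistic fit failed: {exc}") from exc
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or abs(beta) > 50:
        raise FitConvergenceError("perfect separation in logistic fit")
    return {
        "odds_ratio": _safe_exp(beta),
        "ci_low": _safe_exp(beta - 1.959963984540054 * se),
        "ci_high": _safe_exp(beta + 1.959963984540054 * se),
        "p": float(fit.pvalues[1]),
        "per": "sd" if per_sd else "unit",
    }
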