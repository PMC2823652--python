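"""Kaplan-Meier estimation, log-rank comparison and Cox regression,
plus the endpoint-derivation rules used for cohort follow-up records.

Endpoint policies
-----------------
overall
    Death from any cause is the event; censoring at last follow-up.
disease_specific
    Death from the disease is the event.  Deaths from other causes are
    treated as event-free through follow-up (event 0 at the last
    follow-up time).
distant_metastasis
    First distant metastasis is the event.  A prior local recurrence,
    axillary recurrence, contralateral cancer or second primary censors
    the patient at that time (later metastases are not analysed); an
    ipsilateral supra-clavicular recurrence counts as the first clinical
    evidence of metastatic disease, i.e. an event.

Estimation is delegated to established implementations — lifelines for
the product-limit estimator and the log-rank test, statsmodels PHReg
(Breslow tie handling, Newton-type fit) for the Cox model — behind the
interfaces below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg

from .containers import ClinicalTable, ValidationError

logger = logging.getLogger(__name__)

EVENT_CODES = {
    "death_disease",
    "death_other",
    "distant_metastasis",
    "local_recurrence",
    "axillary_recurrence",
    "contralateral",
    "second_primary",
    "supraclavicular_recurrence",
    "last_followup",
}

_DM_CENSORING = {
    "local_recurrence",
    "axillary_recurrence",
    "contralateral",
    "second_primary",
}
_DM_EVENTS = {"distant_metastasis", "supraclavicular_recurrence"}


# ----------------------------------------------------------- endpoint
def derive_endpoint(event_log: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Map raw per-patient event logs to (time, event) pairs.

    ``event_log`` columns: sample_id, event_type (one of EVENT_CODES),
    time (years).  Every patient needs a ``last_followup`` record.
    Returns a frame with sample_id, time, event.
    """
    if endpoint not in ("overall", "disease_specific", "distant_metastasis"):
        raise ValidationError(f"unknown endpoint '{endpoint}'")
    unknown = set(event_log["event_type"]) - EVENT_CODES
    if unknown:
        raise ValidationError(f"unknown event codes: {sorted(unknown)}")

    out = []
    for sid, grp in event_log.groupby("sample_id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        fup = grp[grp["event_type"] == "last_followup"]
        if fup.empty:
            raise ValidationError(f"patient {sid} has no last_followup record")
        t_fup = float(fup["time"].max())
        time, event = t_fup, 0
        for _, rec in grp.iterrows():
            etype, t = rec["event_type"], float(rec["time"])
            if endpoint == "overall":
                if etype in ("death_disease", "death_other"):
                    time, event = t, 1
                    break
            elif endpoint == "disease_specific":
                if etype == "death_disease":
                    time, event = t, 1
                    break
                # death from other causes: event-free through follow-up
            else:  # distant_metastasis
                if etype in _DM_CENSORING:
                    time, event = t, 0
                    break
                if etype in _DM_EVENTS:
                    time, event = t, 1
                    break
        out.append({"sample_id": sid, "time": time, "event": event})
    return pd.DataFrame(out)


# ----------------------------------------------------------------- KM
@dataclass
class KMEstimate:
    """Product-limit estimate with its risk table."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("km_curve requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMEstimate(
        event_times=event_times,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_pvalue(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError("log-rank test requires exactly two groups")
    a = groups == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------- Cox
@dataclass
class CoxResults:
    """Fitted proportional-hazards model.

    coef/hr/se/ci/p are indexed by covariate name; hr = exp(coef), the
    95% CI is Wald (exp(coef +/- 1.96 se)) and p is the Wald test.
    """

    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    n: int
    n_events: int

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coef)

    @property
    def ci(self) -> pd.DataFrame:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return pd.DataFrame({"hr_lower95": lo, "hr_upper95": hi})

    @property
    def p_values(self) -> pd.Series:
        from scipy.stats import norm

        z = self.coef / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.coef.index)

    def summary(self) -> str:
        ci = self.ci
        lines = [
            "Cox proportional hazards (Breslow ties)",
            "=======================================",
            f"subjects: {self.n}    events: {self.n_events}",
            f"{'covariate':<16}{'coef':>10}{'HR':>10}{'95% CI':>20}{'p':>12}",
        ]
        for name in self.covariates:
            lines.append(
                f"{name:<16}{self.coef[name]:>10.4f}{self.hr[name]:>10.3f}"
                f"{ci.loc[name, 'hr_lower95']:>9.3f}-{ci.loc[name, 'hr_upper95']:<10.3f}"
                f"{self.p_values[name]:>12.3g}"
            )
        return "\n".join(lines)


def cox_fit(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
    ties: str = "breslow",
) -> CoxResults:
    """Fit a Cox model by partial-likelihood maximization.

    ``covariates`` is numeric (binary covariates 0/1 encoded), one
    column per term; supports multiple covariates, e.g. signature group
    plus ER status.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    X = covariates.astype(float)
    if X.isna().any().any():
        raise ValidationError("covariates contain missing values")
    model = PHReg(times, X.to_numpy(), status=events, ties=ties)
    try:
        res = model.fit(disp=False)
    except Exception as exc:  # pragma: no cover - numerical failure path
        raise ValidationError(
            f"Cox fit failed ({exc}); Firth-type handling for separation "
            "is out of scope"
        ) from exc
    coef = pd.Series(res.params, index=list(X.columns))
    se = pd.Series(res.bse, index=list(X.columns))
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)) or np.any(
        np.abs(coef) > 20
    ):
        raise ValidationError(
            "Cox fit did not converge (monotone likelihood / separation); "
            "Firth-type handling is out of scope"
        )
    return CoxResults(
        covariates=list(X.columns),
        coef=coef,
        se=se,
        n=len(times),
        n_events=int(events.sum()),
    )


# ------------------------------------------------------- group compare
@dataclass
class SurvivalFit:
    """Two-group survival comparison: per-group KM curves, log-rank test
    and a Cox fit on the group indicator (optionally adjusted)."""

    km_by_group: dict[str, KMEstimate]
    logrank_statistic: float
    logrank_p: float
    cox: CoxResults

    def summary(self) -> str:
        lines = [
            f"log-rank chi2 = {self.logrank_statistic:.4g}, p = {self.logrank_p:.3g}",
            self.cox.summary(),
        ]
        return "\n".join(lines)


def compare_groups(
    clinical: ClinicalTable,
    groups: pd.Series,
    adjust: list[str] | None = None,
) -> SurvivalFit:
    """KM + log-rank + Cox for a high/low grouping of a cohort.

    ``groups`` maps sample_id -> 'high'/'low'.  Covariates named in
    ``adjust`` are taken from the clinical table; string covariates with
    two levels are 0/1 encoded (lexicographically larger level = 1).
    """
    df = clinical.data.set_index("sample_id")
    common = [s for s in groups.index if s in df.index]
    if not common:
        raise ValidationError("no overlap between grouping and clinical table")
    df = df.loc[common]
    g = groups.loc[common]

    km = {
        level: km_curve(
            df.loc[g == level, "time"].to_numpy(),
            df.loc[g == level, "event"].to_numpy(),
        )
        for level in ("high", "low")
        if (g == level).any()
    }
    stat, p = logrank_pvalue(
        df["time"].to_numpy(), df["event"].to_numpy(), g.to_numpy()
    )
    X = pd.DataFrame({"group_high": (g == "high").astype(float)})
    for cov in adjust or []:
        if cov not in df.columns:
            raise ValidationError(f"covariate '{cov}' not in clinical table")
        col = df[cov]
        if col.dtype == object:
            levels = sorted(col.unique())
            if len(levels) != 2:
                raise ValidationError(
                    f"covariate '{cov}' must be binary or numeric"
                )
            col = (col == levels[1]).astype(float)
        X[cov] = col.astype(float).to_numpy()
    cox = cox_fit(df["time"].to_numpy(), df["event"].to_numpy(), X)
    return SurvivalFit(
        km_by_group=km, logrank_statistic=stat, logrank_p=p, cox=cox
    )
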