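"""Time-to-event and cohort-comparison analyses.

Kaplan-Meier curves, Mantel-Cox log-rank tests with O/E hazard ratios (and
the Mantel-Haenszel fallback when one group has no events), calendar-date
landmark analysis with exposure status frozen at the landmark, per-period
adverse-event rates, and logistic propensity-score matching with
standardized-mean-difference balance diagnostics.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .data import CohortDataset
from .errors import (
    DegenerateInputError,
    ParameterError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "LandmarkResult",
    "EventRate",
    "PropensityModel",
    "MatchResult",
    "km_estimator",
    "logrank_test",
    "landmark_analysis",
    "event_rate_intervals",
    "encode_covariates",
    "fit_propensity",
    "match_with_replacement",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S nonincreasing, S(0) = 1, drops at events."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    p: float
    hazard_ratio: float
    hr_ci: tuple
    hr_method: str  # "logrank" | "mantel_haenszel"
    observed: tuple = (0.0, 0.0)
    expected: tuple = (0.0, 0.0)


@dataclass
class LandmarkResult:
    pre: LogRankResult | None
    post: LogRankResult | None
    flags: list = field(default_factory=list)
    n_pre: tuple = (0, 0)
    n_post: tuple = (0, 0)


@dataclass
class EventRate:
    events: int
    days_at_risk: float

    @property
    def rate(self) -> float:
        return self.events / self.days_at_risk if self.days_at_risk > 0 else float("nan")


@dataclass
class PropensityModel:
    coefficients: pd.Series  # includes 'intercept'
    scores: pd.Series  # patient_id -> Pr(vaccinated | X)
    features: pd.DataFrame
    labels: pd.Series


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # unvaccinated_id, vaccinated_id, score_a, score_b
    balance: pd.DataFrame  # covariate x (smd_before, smd_after)


def km_estimator(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (events precede censorings at
    tied times)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DegenerateInputError("empty survival input")
    if np.any(t < 0):
        raise ParameterError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    grid = kmf.event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=kmf.event_table["at_risk"].to_numpy(dtype=float),
        events=kmf.event_table["observed"].to_numpy(dtype=float),
        censored=kmf.event_table["censored"].to_numpy(dtype=float),
    )


def _logrank_components(ta, ea, tb, eb):
    pooled_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    Oa = Ob = Ea = Eb = V = 0.0
    for t in pooled_event_times:
        na = float(np.sum(ta >= t))
        nb = float(np.sum(tb >= t))
        n = na + nb
        da = float(np.sum((ta == t) & ea))
        db = float(np.sum((tb == t) & eb))
        d = da + db
        if n <= 1 or d == 0:
            continue
        Oa += da
        Ob += db
        Ea += d * na / n
        Eb += d * nb / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return Oa, Ob, Ea, Eb, V


def logrank_test(group_a, group_b) -> LogRankResult:
    """Mantel-Cox log-rank test with a hazard ratio for group a vs b.

    HR defaults to (O_a/E_a)/(O_b/E_b) with CI HR * exp(+-1.96/sqrt(V));
    when either group has zero events the Mantel-Haenszel one-step estimate
    exp((O_a - E_a)/V) is reported instead, per the zero-event convention.
    """
    ta, ea = (np.asarray(group_a[0], float), np.asarray(group_a[1], bool))
    tb, eb = (np.asarray(group_b[0], float), np.asarray(group_b[1], bool))
    if ta.size == 0 or tb.size == 0:
        raise DegenerateInputError("both groups must be nonempty")
    Oa, Ob, Ea, Eb, V = _logrank_components(ta, ea, tb, eb)
    if Oa + Ob == 0:
        raise DegenerateInputError("no events in either group: log-rank undefined")
    if V <= 0:
        return LogRankResult(
            statistic=0.0, p=1.0, hazard_ratio=1.0, hr_ci=(np.nan, np.nan),
            hr_method="logrank", observed=(Oa, Ob), expected=(Ea, Eb),
        )
    stat = (Oa - Ea) ** 2 / V
    p = float(sps.chi2.sf(stat, df=1))
    half = 1.96 / np.sqrt(V)
    if Oa > 0 and Ob > 0:
        hr = (Oa / Ea) / (Ob / Eb)
        ci = (hr * np.exp(-half), hr * np.exp(half))
        method = "logrank"
    else:
        log_hr = (Oa - Ea) / V
        hr = float(np.exp(log_hr))
        ci = (float(np.exp(log_hr - half)), float(np.exp(log_hr + half)))
        method = "mantel_haenszel"
    return LogRankResult(
        statistic=float(stat), p=p, hazard_ratio=float(hr),
        hr_ci=(float(ci[0]), float(ci[1])), hr_method=method,
        observed=(Oa, Ob), expected=(Ea, Eb),
    )


def landmark_analysis(
    cohort: CohortDataset, landmark_date: datetime.date
) -> LandmarkResult:
    """Survival comparison before and after a calendar landmark.

    Pre-landmark: follow-up from ICI start truncated at the landmark,
    comparing ever-vaccinated vs never-vaccinated.  Post-landmark: patients
    alive at the landmark (ICI started on or before it), time measured from
    the landmark, vaccination status frozen at the landmark (vaccinated only
    if the first dose was given on or before it).  Degenerate strata are
    flagged rather than raised.
    """
    flags: list[str] = []
    pre_a, pre_b = [], []  # (time, event) per group; a = vaccinated
    post_a, post_b = [], []
    for p in cohort.patients:
        lm_offset = (landmark_date - p.ici_start_date).days
        # pre-landmark stratum: survival truncated at the landmark
        if lm_offset > 0:
            t_pre = min(p.survival_days, lm_offset)
            e_pre = p.death_observed and p.survival_days <= lm_offset
            (pre_a if p.vaccinated else pre_b).append((t_pre, e_pre))
        # post-landmark stratum: alive at landmark, status frozen there
        if lm_offset >= 0 and p.survival_days > lm_offset:
            frozen_vax = (
                p.vaccinated
                and p.vax1_date is not None
                and p.vax1_date <= landmark_date
            )
            t_post = p.survival_days - lm_offset
            (post_a if frozen_vax else post_b).append((t_post, p.death_observed))

    def run(group_a, group_b, name):
        if not group_a or not group_b:
            flags.append(f"{name}: degenerate stratum (empty group)")
            return None
        a = (np.array([t for t, _ in group_a]), np.array([e for _, e in group_a]))
        b = (np.array([t for t, _ in group_b]), np.array([e for _, e in group_b]))
        try:
            return logrank_test(a, b)
        except DegenerateInputError as exc:
            flags.append(f"{name}: {exc}")
            return None

    pre = run(pre_a, pre_b, "pre_landmark")
    post = run(post_a, post_b, "post_landmark")
    return LandmarkResult(
        pre=pre, post=post, flags=flags,
        n_pre=(len(pre_a), len(pre_b)), n_post=(len(post_a), len(post_b)),
    )


def event_rate_intervals(
    cohort: CohortDataset,
    split_days: int = 28,
    counting: str = "first_event",
) -> dict:
    """Adverse-event rates (events per patient-day) per follow-up interval.

    Vaccinated follow-up is partitioned at the first dose and at
    ``split_days`` after it (half-open intervals); unvaccinated patients
    contribute their whole follow-up.  ``counting`` selects the first
    qualifying event per patient per interval or all events.
    """
    if counting not in ("first_event", "all_events"):
        raise ParameterError("counting must be 'first_event' or 'all_events'")
    by_patient: dict[str, list] = {}
    for a in cohort.adverse_events:
        p = cohort.patient(a.patient_id)
        if a.onset_date < p.ici_start_date:
            raise ValidationError(
                f"adverse event for {a.patient_id} before ICI start"
            )
        by_patient.setdefault(a.patient_id, []).append(
            (a.onset_date - p.ici_start_date).days
        )

    out = {
        "unvaccinated": [0, 0.0],
        "pre_vax": [0, 0.0],
        "post_le28d": [0, 0.0],
        "post_gt28d": [0, 0.0],
    }

    def tally(key, onsets, lo, hi):
        """Count events with onset in (lo, hi] and add the days at risk."""
        if hi <= lo:
            return
        out[key][1] += hi - lo
        hits = [o for o in onsets if lo < o <= hi]
        if hits:
            out[key][0] += 1 if counting == "first_event" else len(hits)

    for p in cohort.patients:
        end = float(p.survival_days)
        onsets = by_patient.get(p.patient_id, [])
        if not p.vaccinated:
            tally("unvaccinated", onsets, -1e-9, end)
            continue
        v1 = (p.vax1_date - p.ici_start_date).days
        tally("pre_vax", onsets, -1e-9, min(v1, end))
        tally("post_le28d", onsets, v1, min(v1 + split_days, end))
        tally("post_gt28d", onsets, v1 + split_days, end)

    return {k: EventRate(events=v[0], days_at_risk=v[1]) for k, v in out.items()}


def encode_covariates(cohort: CohortDataset, which=("age", "sex", "insurance")) -> pd.DataFrame:
    """Numeric design matrix for the propensity model.

    age -> years; sex -> 1 for female; insurance -> 1 for private;
    ecog -> 1 for ECOG > 1 (the dichotomization used for matching).
    """
    rows = {}
    for p in cohort.patients:
        row = {}
        for w in which:
            if w == "age":
                row["age"] = float(p.age_years)
            elif w == "sex":
                row["sex"] = 1.0 if p.sex == "female" else 0.0
            elif w == "insurance":
                row["insurance"] = 1.0 if p.insurance == "private" else 0.0
            elif w == "ecog":
                row["ecog"] = 1.0 if p.ecog > 1 else 0.0
            else:
                raise ParameterError(f"unknown covariate {w!r}")
        rows[p.patient_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_propensity(features: pd.DataFrame, labels: pd.Series) -> PropensityModel:
    """Maximum-likelihood logistic propensity model with intercept.

    log(pi / (1 - pi)) = X beta, fitted by iteratively reweighted least
    squares (GLM, binomial family).  Diverging coefficients — the signature
    of perfect separation — raise :class:`SeparationError`.
    """
    import statsmodels.api as sm

    y = labels.loc[features.index].astype(float)
    if y.nunique() < 2:
        raise DegenerateInputError("both classes must be present")
    if features.isna().any().any():
        raise ParameterError("features must be complete (no missing values)")
    X = sm.add_constant(features.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
        except Exception as exc:  # statsmodels raises on hopeless separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    coefs = fit.params
    if np.abs(coefs.to_numpy()).max() > 15.0 or not np.all(np.isfinite(coefs)):
        raise SeparationError(
            "diverging coefficients: covariates perfectly separate the classes"
        )
    scores = pd.Series(fit.predict(X), index=features.index, name="propensity")
    coefs = coefs.rename(index={"const": "intercept"})
    return PropensityModel(
        coefficients=coefs, scores=scores, features=features, labels=labels
    )


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Standardized mean difference (pooled-variance denominator)."""
    v_t = np.var(x_t, ddof=1) if len(x_t) > 1 else 0.0
    v_c = np.var(x_c, ddof=1) if len(x_c) > 1 else 0.0
    var = (v_t + v_c) / 2.0
    if var == 0:
        return 0.0
    return float((np.mean(x_t) - np.mean(x_c)) / np.sqrt(var))


def match_with_replacement(model: PropensityModel) -> MatchResult:
    """Match every unexposed patient to the nearest-propensity exposed one.

    Matching is with replacement; ties in |score difference| break toward
    the smallest patient id for determinism.  The balance report gives the
    standardized mean difference per covariate before and after matching
    (after = matched exposed multiset vs the unexposed patients).
    """
    treated = sorted(model.labels.index[model.labels == 1])
    control = sorted(model.labels.index[model.labels == 0])
    if not treated:
        raise DegenerateInputError("no vaccinated (exposed) patients to match against")
    t_scores = model.scores.loc[treated]
    rows = []
    for cid in control:
        diffs = (t_scores - model.scores.loc[cid]).abs()
        best = diffs.min()
        match_id = min(diffs.index[diffs == best])  # deterministic tie-break
        rows.append(
            {
                "unvaccinated_id": cid,
                "vaccinated_id": match_id,
                "score_a": float(model.scores.loc[cid]),
                "score_b": float(t_scores.loc[match_id]),
            }
        )
    pairs = pd.DataFrame(rows, columns=["unvaccinated_id", "vaccinated_id", "score_a", "score_b"])

    bal = {}
    matched_ids = pairs["vaccinated_id"].tolist()
    for cov in model.features.columns:
        before = _smd(
            model.features.loc[treated, cov].to_numpy(),
            model.features.loc[control, cov].to_numpy(),
        )
        after = _smd(
            model.features.loc[matched_ids, cov].to_numpy(),
            model.features.loc[control, cov].to_numpy(),
        )
        bal[cov] = {"smd_before": before, "smd_after": after}
    balance = pd.DataFrame.from_dict(bal, orient="index")
    return MatchResult(pairs=pairs, balance=balance)
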