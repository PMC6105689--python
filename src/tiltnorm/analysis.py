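"""Participant-level and group-level analysis of the tilt-repulsion task.

Covers the full statistical chain applied to each simulated (or imported)
cohort: overall accuracy and the chance-performance exclusion rule, two
psychometric fits per participant (single-varies and compound-varies), the
illusion-strength statistic (half-difference of the two PSEs), one- and
two-sample t-tests on illusion strength, and Pearson correlations of
illusion strength with the covariates (autistic-traits score and IQ).

Two-sample tests use the pooled-variance (Student) form with
df = n1 + n2 - 2; the statistic is signed as mean(group 2) - mean(group 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InvalidInputError,
    UndefinedStatisticError,
)
from .psychometric import (
    DEFAULT_LAPSE_MAX,
    PsychometricFit,
    fit_ml,
    parametric_bootstrap,
)

__all__ = [
    "GroupComparison",
    "ParticipantResult",
    "overall_accuracy",
    "bin_trials",
    "fit_participant",
    "apply_exclusion",
    "illusion_strength",
    "two_sample_t",
    "one_sample_t",
    "pearson_r",
    "analyze_cohort",
    "group_report",
]

#: Default chance-performance exclusion threshold (strict <).
DEFAULT_EXCLUSION_THRESHOLD = 0.55


@dataclass(frozen=True)
class GroupComparison:
    """Result of a t-test, with the group summaries it was computed from."""

    statistic: float
    df: int
    p: float
    kind: str  # "one-sample" | "two-sample"
    summaries: tuple = ()


def overall_accuracy(trials: pd.DataFrame) -> float:
    """Fraction of trials on which the chosen interval was truly most CCW.

    Ground truth comes from the sign of the varied orientation: a positive
    value on the choice axis means the varied grating was the
    counterclockwise one, so the response is correct exactly when it chose
    the varied interval.  The design has no 0° level, so there are no ties.
    """
    resp = trials["response_chose_varied"]
    if resp.isna().any():
        raise InvalidInputError("trials contain missing responses")
    theta = trials["varied_orientation_deg"].to_numpy(dtype=float)
    chose = resp.to_numpy(dtype=float).astype(int)
    return float(np.mean(chose == (theta > 0)))


def bin_trials(trials: pd.DataFrame, condition: str):
    """Collapse one condition's trials to binned (levels, n, k) arrays."""
    sub = trials[trials["condition"] == condition]
    if sub.empty:
        raise InvalidInputError(f"no trials for condition {condition!r}")
    grouped = sub.groupby("varied_orientation_deg")["response_chose_varied"]
    agg = grouped.agg(["count", "sum"])
    levels = agg.index.to_numpy(dtype=float)
    return levels, agg["count"].to_numpy(dtype=float), agg["sum"].to_numpy(dtype=float)


@dataclass
class ParticipantResult:
    """Everything the group analysis needs about one participant."""

    participant_id: str
    group: str
    overall_accuracy: float
    included: bool = True
    fit_single: Optional[PsychometricFit] = None
    fit_compound: Optional[PsychometricFit] = None
    illusion_strength: Optional[float] = None
    pse_single_ci: tuple = (np.nan, np.nan)
    pse_compound_ci: tuple = (np.nan, np.nan)
    srs: float = np.nan
    fsiq: float = np.nan
    age: float = np.nan


def fit_participant(
    trials: pd.DataFrame,
    *,
    lapse_max: float = DEFAULT_LAPSE_MAX,
    n_bootstrap: int = 0,
    coverage: float = 0.95,
    seed: int = 0,
) -> ParticipantResult:
    """Fit both psychometric functions for one participant's trials.

    ``n_bootstrap = 0`` skips the (slow) bootstrap confidence intervals.
    """
    pid = str(trials["participant_id"].iloc[0])
    group = str(trials["group"].iloc[0]) if "group" in trials else ""
    acc = overall_accuracy(trials)
    res = ParticipantResult(pid, group, acc)
    fits = {}
    for i, cond in enumerate(("single", "compound")):
        levels, n, k = bin_trials(trials, cond)
        fit = fit_ml(levels, n, k, lapse_max=lapse_max)
        fits[cond] = fit
        if n_bootstrap > 0:
            boot = parametric_bootstrap(
                fit, levels, n, k, n_samples=n_bootstrap, coverage=coverage,
                seed=seed + i, lapse_max=lapse_max,
            )
            if cond == "single":
                res.pse_single_ci = boot.ci["pse"]
            else:
                res.pse_compound_ci = boot.ci["pse"]
    res.fit_single = fits["single"]
    res.fit_compound = fits["compound"]
    if fits["single"].converged and fits["compound"].converged:
        res.illusion_strength = illusion_strength(fits["single"], fits["compound"])
    return res


def apply_exclusion(
    results: list, threshold: float = DEFAULT_EXCLUSION_THRESHOLD
) -> list:
    """Flag chance-level performers: excluded iff accuracy < threshold (strict).

    All records are returned with their ``included`` flag set; accuracy equal
    to the threshold is retained.
    """
    for r in results:
        r.included = not (r.overall_accuracy < threshold)
    return results


def illusion_strength(
    fit_single: PsychometricFit, fit_compound: PsychometricFit
) -> float:
    """Half-difference of the two PSEs, in degrees.

    ``(pse_compound - pse_single) / 2``: positive for a repulsive observer,
    whose compound-varies PSE is shifted clockwise-positive and single-varies
    PSE the mirror way.  The two conditions are two measurements of the same
    perceptual bias, so their half-difference averages them.
    """
    if not (fit_single.converged and fit_compound.converged):
        raise UndefinedStatisticError(
            "illusion strength requires two converged fits"
        )
    return 0.5 * (fit_compound.pse - fit_single.pse)


def _summary(values):
    v = np.asarray(values, dtype=float)
    return (float(np.mean(v)), float(np.std(v, ddof=1)), int(v.size))


def two_sample_t(*args) -> GroupComparison:
    """Pooled-variance two-tailed two-sample t-test, df = n1 + n2 - 2.

    Call either with two raw value vectors, ``two_sample_t(x1, x2)``, or with
    six summary statistics ``two_sample_t(mean1, sd1, n1, mean2, sd2, n2)``.
    The statistic is signed as mean2 - mean1.
    """
    if len(args) == 2:
        s1, s2 = _summary(args[0]), _summary(args[1])
    elif len(args) == 6:
        m1, sd1, n1, m2, sd2, n2 = args
        s1, s2 = (float(m1), float(sd1), int(n1)), (float(m2), float(sd2), int(n2))
    else:
        raise InvalidInputError("pass two vectors or six summary statistics")
    (m1, sd1, n1), (m2, sd2, n2) = s1, s2
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InvalidInputError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return GroupComparison(0.0, df, 1.0, "two-sample", (s1, s2))
        raise UndefinedStatisticError(
            "zero pooled variance with unequal means: statistic is infinite"
        )
    # scipy's statistic is mean1 - mean2; swap groups for the mean2 - mean1 sign
    res = stats.ttest_ind_from_stats(m2, sd2, n2, m1, sd1, n1, equal_var=True)
    return GroupComparison(
        float(res.statistic), df, float(res.pvalue), "two-sample", (s1, s2)
    )


def one_sample_t(values, mu0: float = 0.0) -> GroupComparison:
    """Two-tailed one-sample t-test against ``mu0``, df = n - 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("need n >= 2 values")
    m, sd, n = _summary(v)
    if sd == 0:
        if m == mu0:
            return GroupComparison(0.0, n - 1, 1.0, "one-sample", ((m, sd, n),))
        raise UndefinedStatisticError(
            "zero variance with mean != mu0: statistic is infinite"
        )
    res = stats.ttest_1samp(v, mu0)
    return GroupComparison(
        float(res.statistic), n - 1, float(res.pvalue), "one-sample", ((m, sd, n),)
    )


def pearson_r(x, y):
    """Pearson correlation with two-tailed p from the t-transform (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def analyze_cohort(
    trials: pd.DataFrame,
    participants: Optional[pd.DataFrame] = None,
    *,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    lapse_max: float = DEFAULT_LAPSE_MAX,
    n_bootstrap: int = 0,
    coverage: float = 0.95,
    seed: int = 0,
) -> list:
    """Per-participant accuracy, exclusion, and psychometric fits for a cohort.

    Exclusion is decided from accuracy before fitting; excluded participants
    keep their accuracy but are not fitted (mirroring an analysis that drops
    chance performers before modelling).  Covariates are merged in from the
    participant table when given.
    """
    results = []
    covar = {}
    if participants is not None:
        covar = participants.set_index("participant_id").to_dict("index")
    for i, (pid, sub) in enumerate(trials.groupby("participant_id", sort=False)):
        acc = overall_accuracy(sub)
        if acc < exclusion_threshold:
            res = ParticipantResult(
                str(pid),
                str(sub["group"].iloc[0]) if "group" in sub else "",
                acc,
                included=False,
            )
        else:
            res = fit_participant(
                sub,
                lapse_max=lapse_max,
                n_bootstrap=n_bootstrap,
                coverage=coverage,
                seed=seed + 1000 * i,
            )
        row = covar.get(pid, {})
        res.srs = float(row.get("srs", np.nan))
        res.fsiq = float(row.get("fsiq", np.nan))
        res.age = float(row.get("age", np.nan))
        results.append(res)
    return apply_exclusion(results, exclusion_threshold)


def results_table(results: list) -> pd.DataFrame:
    """One row per participant, flat columns, suitable for CSV output."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "overall_accuracy": r.overall_accuracy,
                "included": int(r.included),
                "pse_single": r.fit_single.pse if r.fit_single else np.nan,
                "sigma_single": r.fit_single.sigma if r.fit_single else np.nan,
                "lapse_single": r.fit_single.lapse if r.fit_single else np.nan,
                "deviance_single": r.fit_single.deviance if r.fit_single else np.nan,
                "pse_compound": r.fit_compound.pse if r.fit_compound else np.nan,
                "sigma_compound": r.fit_compound.sigma if r.fit_compound else np.nan,
                "lapse_compound": r.fit_compound.lapse if r.fit_compound else np.nan,
                "deviance_compound": (
                    r.fit_compound.deviance if r.fit_compound else np.nan
                ),
                "pse_single_ci_low": r.pse_single_ci[0],
                "pse_single_ci_high": r.pse_single_ci[1],
                "pse_compound_ci_low": r.pse_compound_ci[0],
                "pse_compound_ci_high": r.pse_compound_ci[1],
                "illusion_strength": (
                    r.illusion_strength if r.illusion_strength is not None else np.nan
                ),
                "srs": r.srs,
                "fsiq": r.fsiq,
                "age": r.age,
            }
        )
    return pd.DataFrame(rows)


def group_report(results: list, alpha: float = 0.05) -> dict:
    """Group-level inference on illusion strength.

    Per group: mean/SD/n and a one-sample t against zero.  Across the first
    two groups: a pooled two-sample t.  Pooled over included participants:
    Pearson correlations of illusion strength with SRS score and IQ (when
    covariates are present).
    """
    included = [r for r in results if r.included and r.illusion_strength is not None]
    groups = {}
    for r in included:
        groups.setdefault(r.group, []).append(r)
    report = {"alpha": alpha, "n_included": len(included),
              "n_excluded": sum(not r.included for r in results), "groups": {}}
    for label, members in groups.items():
        vals = [r.illusion_strength for r in members]
        entry = {
            "n": len(vals),
            "mean_illusion": float(np.mean(vals)),
            "sd_illusion": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
        }
        if len(vals) >= 2:
            t = one_sample_t(vals, 0.0)
            entry["one_sample_t"] = {
                "t": t.statistic, "df": t.df, "p": t.p,
                "significant": t.p < alpha,
            }
        report["groups"][label] = entry
    labels = list(groups)
    if len(labels) >= 2:
        v1 = [r.illusion_strength for r in groups[labels[0]]]
        v2 = [r.illusion_strength for r in groups[labels[1]]]
        t = two_sample_t(v1, v2)
        report["between_groups"] = {
            "groups": labels[:2], "t": t.statistic, "df": t.df, "p": t.p,
            "significant": t.p < alpha,
        }
    ill = np.array([r.illusion_strength for r in included])
    for name in ("srs", "fsiq"):
        cov = np.array([getattr(r, name) for r in included])
        ok = ~np.isnan(cov)
        if ok.sum() >= 3 and np.std(cov[ok]) > 0 and np.std(ill[ok]) > 0:
            r_, p_ = pearson_r(ill[ok], cov[ok])
            report[f"correlation_illusion_{name}"] = {"r": r_, "p": p_, "n": int(ok.sum())}
    return report
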