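"""Synthetic 2-IFC observers and cohorts.

Emulates the study design this package analyses: each participant runs a
1,200-trial two-interval forced-choice session (6 orientation levels x 2
conditions x 2 interval orders x 50 repetitions).  On every trial one
stimulus is a single grating and the other a compound grating (vertical
target + fixed 45° clockwise mask); either the single or the compound
target varies around vertical, and the observer reports which interval
looked most tilted counterclockwise.

Responses are drawn from a cumulative-Gaussian observer,

    P(choose varied) = lapse/2 + (1 - lapse) * Phi((theta - pse_cond) / sigma),

where ``theta`` is the varied orientation on the choice axis (positive =
more counterclockwise, i.e. more evidence for choosing the varied interval)
and the illusion enters only through condition-specific points of subjective
equality: a repulsive observer has ``pse_single = -b`` and
``pse_compound = +b`` for bias ``b > 0``, so the illusion strength
``(pse_compound - pse_single)/2`` recovers ``b``.

Cohort generation scales this to two groups with covariates (SRS-like
autistic-traits score, full-scale IQ, age).  Per-participant biases are
drawn either from a normal distribution or, in DN-link mode, from the
population model's predicted repulsion at a group-specific kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import InvalidInputError, InvalidParameterError
from .model import (
    GratingComponent,
    NormalizationParams,
    predicted_repulsion,
)

__all__ = [
    "SessionDesign",
    "ObserverModel",
    "GroupSpec",
    "CohortSpec",
    "build_session",
    "simulate_responses",
    "generate_cohort",
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
]

#: Orientation levels of the default session (degrees on the choice axis).
DEFAULT_LEVELS = (-4.0, -2.4, -0.8, 0.8, 2.4, 4.0)

CONDITIONS = ("single", "compound")
INTERVAL_ORDERS = (1, 2)

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "varied_orientation_deg",
    "varied_interval",
    "response_chose_varied",
    "correct",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "srs",
    "fsiq",
    "age",
    "true_pse_single",
    "true_pse_compound",
    "true_sigma",
    "true_lapse",
]


@dataclass(frozen=True)
class SessionDesign:
    """Fully crossed factorial 2-IFC session design."""

    orientation_levels: tuple = DEFAULT_LEVELS
    reps_per_cell: int = 50
    conditions: tuple = CONDITIONS
    interval_orders: tuple = INTERVAL_ORDERS

    def __post_init__(self):
        if len(self.orientation_levels) == 0:
            raise InvalidInputError("design needs at least one orientation level")
        if any(level == 0 for level in self.orientation_levels):
            raise InvalidInputError("orientation levels must be nonzero (no ties)")
        if self.reps_per_cell < 1:
            raise InvalidInputError("reps_per_cell must be >= 1")

    @property
    def n_trials(self) -> int:
        return (
            len(self.orientation_levels)
            * len(self.conditions)
            * len(self.interval_orders)
            * self.reps_per_cell
        )


@dataclass(frozen=True)
class ObserverModel:
    """Generative cumulative-Gaussian 2-IFC observer.

    ``sigma`` is the inverse-slope (degrees); ``lapse`` is the total
    stimulus-independent error rate, split evenly between the asymptotes.
    """

    pse_single: float = -1.5
    pse_compound: float = 1.5
    sigma: float = 3.0
    lapse: float = 0.02

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise InvalidParameterError("lapse must lie in [0, 0.5)")

    @property
    def is_repulsion_consistent(self) -> bool:
        """Whether the PSE pair has the sign pattern of a repulsive illusion."""
        return self.pse_single <= 0.0 <= self.pse_compound

    @property
    def bias(self) -> float:
        """Generative illusion strength: half-difference of the two PSEs."""
        return 0.5 * (self.pse_compound - self.pse_single)

    def pse_for(self, condition: str) -> float:
        if condition == "single":
            return self.pse_single
        if condition == "compound":
            return self.pse_compound
        raise InvalidInputError(f"unknown condition {condition!r}")

    def choice_probability(self, theta, condition: str):
        """P(choose the varied grating) at orientation ``theta``."""
        theta = np.asarray(theta, dtype=float)
        z = (theta - self.pse_for(condition)) / self.sigma
        p = self.lapse / 2.0 + (1.0 - self.lapse) * norm.cdf(z)
        return p if p.ndim else float(p)


def build_session(
    design: SessionDesign = SessionDesign(),
    seed: int = 0,
    participant_id: str = "obs",
    group: str = "",
) -> pd.DataFrame:
    """Enumerate the fully crossed trial list, shuffled by ``seed``.

    Responses are left empty (NaN); the default design yields 1,200 trials
    (6 levels x 2 conditions x 2 interval orders x 50 repetitions).
    """
    levels = np.asarray(design.orientation_levels, dtype=float)
    grid = pd.MultiIndex.from_product(
        [design.conditions, levels, design.interval_orders, range(design.reps_per_cell)],
        names=["condition", "varied_orientation_deg", "varied_interval", "rep"],
    ).to_frame(index=False)
    rng = np.random.default_rng(seed)
    grid = grid.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "condition": grid["condition"],
            "varied_orientation_deg": grid["varied_orientation_deg"],
            "varied_interval": grid["varied_interval"].astype(int),
            "response_chose_varied": np.nan,
            "correct": np.nan,
        }
    )


def simulate_responses(
    trials: pd.DataFrame, observer: ObserverModel, seed: int = 0
) -> pd.DataFrame:
    """Fill a session's responses from the generative observer.

    Bernoulli draws from ``observer.choice_probability``; ``correct`` marks
    whether the chosen interval really contained the most-counterclockwise
    grating (varied orientation > 0 on the choice axis means the varied
    grating was the counterclockwise one).  Deterministic given
    (trials, observer, seed); interval order has no generative effect.
    """
    if trials["response_chose_varied"].notna().any():
        raise InvalidInputError("trials already contain responses")
    out = trials.copy()
    theta = out["varied_orientation_deg"].to_numpy(dtype=float)
    p = np.empty_like(theta)
    for cond in np.unique(out["condition"]):
        sel = (out["condition"] == cond).to_numpy()
        p[sel] = observer.choice_probability(theta[sel], str(cond))
    rng = np.random.default_rng(seed)
    chose = (rng.random(len(out)) < p).astype(int)
    out["response_chose_varied"] = chose
    out["correct"] = (chose == (theta > 0)).astype(int)
    return out


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Normal draw clipped at a lower bound (simple truncation by clipping)."""
    return np.clip(rng.normal(mean, sd, size=size), lower, None)


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one participant group.

    The bias (illusion strength) is drawn N(bias_mean, bias_sd) unless
    ``kappa`` is set, in which case DN-link mode derives the group-level
    bias from the population model's predicted repulsion at that kappa,
    scaled by ``bias_gain`` with individual jitter ``bias_jitter_sd``.
    Covariate defaults follow the matched-groups summary table of the study
    this design emulates.
    """

    label: str
    n: int
    bias_mean: float = 1.5
    bias_sd: float = 0.75
    kappa: Optional[float] = None
    bias_gain: float = 1.0
    bias_jitter_sd: float = 0.0
    sigma_mean: float = 3.0
    sigma_sd: float = 0.75
    lapse: float = 0.02
    srs_mean: float = 51.33
    srs_sd: float = 7.70
    fsiq_mean: float = 109.91
    fsiq_sd: float = 8.37
    age_mean: float = 21.33
    age_sd: float = 3.77

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError("each group needs n >= 2 participants")
        for name in ("bias_sd", "bias_jitter_sd", "sigma_sd", "srs_sd", "fsiq_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort specification (any number of groups is allowed)."""

    groups: tuple

    def __post_init__(self):
        groups = tuple(self.groups)
        if not groups:
            raise InvalidParameterError("cohort needs at least one group")
        object.__setattr__(self, "groups", groups)

    @classmethod
    def matched_default(
        cls,
        n_td: int = 12,
        n_asd: int = 11,
        bias_mean: float = 1.5,
        bias_sd: float = 0.75,
    ) -> "CohortSpec":
        """Default TD/ASD cohort with equal generative bias in both groups.

        Covariates follow the study's matched-group summary statistics:
        groups matched on IQ and age, ASD group higher on the SRS.
        """
        td = GroupSpec("td", n_td, bias_mean=bias_mean, bias_sd=bias_sd)
        asd = GroupSpec(
            "asd",
            n_asd,
            bias_mean=bias_mean,
            bias_sd=bias_sd,
            srs_mean=65.18,
            srs_sd=11.54,
            fsiq_mean=109.09,
            fsiq_sd=6.71,
            age_mean=24.0,
            age_sd=3.35,
        )
        return cls((td, asd))

    @classmethod
    def dn_link_default(
        cls,
        kappa_td: float = 1.0,
        kappa_asd: float = 0.75,
        bias_gain: float = 1.0,
        bias_jitter_sd: float = 0.0,
    ) -> "CohortSpec":
        """DN-link cohort: group biases derived from the population model.

        The ASD group gets a 25% reduced normalization scaling by default,
        the hypothesis the behavioural design was built to test.
        """
        base = cls.matched_default()
        td, asd = base.groups
        from dataclasses import replace

        return cls(
            (
                replace(td, kappa=kappa_td, bias_gain=bias_gain,
                        bias_jitter_sd=bias_jitter_sd),
                replace(asd, kappa=kappa_asd, bias_gain=bias_gain,
                        bias_jitter_sd=bias_jitter_sd),
            )
        )


def _group_bias(group: GroupSpec, rng, model_params: NormalizationParams) -> float:
    if group.kappa is None:
        return float(rng.normal(group.bias_mean, group.bias_sd))
    from dataclasses import replace

    params = replace(model_params, kappa=group.kappa)
    target = GratingComponent(0.0, 100.0, 1.5)
    mask = GratingComponent(45.0, 100.0, 3.75)
    b = group.bias_gain * predicted_repulsion(target, mask, params, decimals=None)
    if group.bias_jitter_sd > 0:
        b += float(rng.normal(0.0, group.bias_jitter_sd))
    return float(b)


def generate_cohort(
    spec: CohortSpec = None,
    design: SessionDesign = SessionDesign(),
    seed: int = 0,
    model_params: NormalizationParams = None,
):
    """Simulate full sessions for a cohort; returns (trials, participants).

    Each participant gets an independent generator derived from
    ``(seed, participant index)`` so cohorts are reproducible
    participant-by-participant.  Covariates are truncated to plausible
    ranges (SRS >= 0, IQ >= 40, age >= 16).
    """
    if spec is None:
        spec = CohortSpec.matched_default()
    if model_params is None:
        model_params = NormalizationParams()
    trial_frames = []
    participant_rows = []
    idx = 0
    for group in spec.groups:
        for j in range(group.n):
            pid = f"{group.label}{j + 1:02d}"
            rng = np.random.default_rng([int(seed), idx])
            b = _group_bias(group, rng, model_params)
            sigma = float(_truncated_normal(rng, group.sigma_mean, group.sigma_sd, 0.5))
            observer = ObserverModel(
                pse_single=-b, pse_compound=+b, sigma=sigma, lapse=group.lapse
            )
            srs = float(_truncated_normal(rng, group.srs_mean, group.srs_sd, 0.0))
            fsiq = float(_truncated_normal(rng, group.fsiq_mean, group.fsiq_sd, 40.0))
            age = float(_truncated_normal(rng, group.age_mean, group.age_sd, 16.0))
            session = build_session(
                design, seed=rng.integers(2**31), participant_id=pid, group=group.label
            )
            session = simulate_responses(session, observer, seed=rng.integers(2**31))
            trial_frames.append(session)
            participant_rows.append(
                {
                    "participant_id": pid,
                    "group": group.label,
                    "srs": srs,
                    "fsiq": fsiq,
                    "age": age,
                    "true_pse_single": -b,
                    "true_pse_compound": +b,
                    "true_sigma": sigma,
                    "true_lapse": group.lapse,
                }
            )
            idx += 1
    trials = pd.concat(trial_frames, ignore_index=True)
    participants = pd.DataFrame(participant_rows, columns=PARTICIPANT_COLUMNS)
    return trials, participants
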