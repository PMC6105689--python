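# Methods

## Scope

`tiltnorm` packages, as one reproducible chain, the computational test of the
decreased-divisive-normalization account of autism in low-level vision: a
forward population-coding model of cross-orientation suppression that predicts
illusory tilt ("repulsion") of a vertical grating superimposed with a 45°
clockwise mask, a synthetic two-interval forced-choice (2-IFC) cohort standing
in for human participants, maximum-likelihood psychometric fitting with a
parametric bootstrap, and the group-level statistics on the resulting
illusion-strength measure. The synthetic cohort is first-class, tested code:
it defines the generative world in which the statistical chain is validated.

## The divisive-normalization population model

Each V1 neuron's mean rate to a stimulus with components `(c_j, s_j)`
(% Michelson contrast, orientation in degrees) is

    r = r0 + rmax * E / (c50^p + kappa * N)
    E = sum_j [c_j * f(s_j)]^p,   N = sum_j [c_j * g(s_j)]^p

with `f` and `g` von Mises tuning functions on the doubled-angle (period-180°)
circle, `g` (the suppressive-pool tuning) much broader than `f`, and `p = 2`
by default. Summing excitatory and pool drives across components before the
ratio is the standard normalization account of overlay (cross-orientation)
suppression; with one component the expression is the familiar Naka-Rushton
form. Consequences the tests pin down: the saturating rate at the preferred
orientation is `r0 + rmax/kappa` (so halving `kappa` from 1 to 0.5 doubles a
50 Hz asymptote to 100 Hz), `c = c50` gives half the asymptote in the
standard model, lowering `c50` shifts the contrast-response function leftward,
and raising the mask contrast *lowers* a target-tuned neuron's rate. That last
point means the rate is deliberately *not* monotone in a compound's mask
contrast — cross-orientation suppression is the phenomenon, not a bug.

Parameters and defaults: `r0 = 0 Hz`, `rmax = 50 Hz`, `c50 = 20 %`,
`kappa = 1` (the standard model; 0.75 encodes the hypothesised 25% reduction),
`p = 2`. The tuning widths are not constrained by the design beyond "the pool
is much broader"; we fix half-width-at-half-height 20° (excitatory) and 60°
(pool), exposed in the config, and therefore treat only ordinal model claims
(repulsion grows with `kappa`) as substantive — the predicted magnitude
(≈1.2° at `kappa = 1` with these defaults) depends on the unconstrained
widths.

### Decoding perceived orientation

No decoding rule is dictated by the behavioural design, so the package makes
one explicit: the perceived target orientation is the *local* doubled-angle
population vector of baseline-subtracted rates within ±22.5° of the target
mode. A global vector average over the bimodal compound profile would measure
attraction toward the mask rather than the shift of the target mode. Two
numerical refinements matter:

- the window is re-centred iteratively on the running estimate until it sits
  on the mode itself; a window fixed at the reference orientation truncates
  the profile asymmetrically and biases the estimate toward the reference by
  several tenths of a degree;
- the window is raised-cosine tapered, since a hard cutoff through the flank
  of the profile makes the estimate jump with the discrete grid (default 181
  preferred orientations tiling [−90°, 90°)).

With both, a noise-free tuning profile centred at −2° decodes to −2° within
1e-5°, and decoded orientations are reported to 0.01°. Degenerate inputs
(flat profile at baseline) raise an explicit undecodable error.

## The synthetic 2-IFC experiment

A session is the fully crossed design: 6 orientation levels
[−4, −2.4, −0.8, 0.8, 2.4, 4]°, 2 conditions (single grating varies /
compound's target varies), 2 interval orders, 50 repetitions — 1,200 trials,
order shuffled by seed. Responses come from

    P(choose varied) = lapse/2 + (1 − lapse) * Phi((theta − pse_cond) / sigma)

where `theta` is the varied orientation on the choice axis (positive = more
counterclockwise, the direction the task asks about), and the illusion enters
only through condition-specific PSEs: a repulsive observer has
`pse_single = −b`, `pse_compound = +b`, so the illusion strength
`(pse_compound − pse_single)/2` equals the generative bias `b`. Which
condition carries which sign is unobservable in the synthetic world (only the
half-difference matters); the package fixes the labelling above once and uses
it consistently in generation and analysis. Correctness of a response is
derived from the sign of `theta`; there is no 0° level, so no ties. Interval
order is carried in the data but has no generative effect, and lapses are
split evenly between the asymptotes.

Cohort defaults emulate the matched two-group study the design comes from:
n = 12 ("td") and n = 11 ("asd"), covariates drawn from normal distributions
truncated to plausible ranges (SRS ≥ 0, IQ ≥ 40, age ≥ 16) with the groups'
published summary means/SDs. Generative observer parameters were chosen once
from the study's printed behaviour and frozen: bias mean 1.5° with
between-subject SD 0.75° reproduces one-sample illusion t-statistics near
6.4–6.5 at these group sizes; `sigma` mean 3.0° (SD 0.75°, truncated at 0.5°)
and lapse 0.02 reproduce overall accuracy near 0.75. In DN-link mode the
group bias is instead `bias_gain` times the population model's predicted
repulsion at a group-specific `kappa` (default 1.0 vs 0.75) plus optional
jitter, tying the generator to the forward model.

What the generator does *not* emulate: learning or fatigue across blocks,
interval-order bias, reaction times, non-stationary lapses, and any
relationship between covariates and performance (covariates are independent
of the observer parameters under the null cohort). Passing tests therefore
validate the statistical chain's behaviour under a stationary
cumulative-Gaussian observer, not the richness of real psychophysical data.

Reproducibility: every participant gets an independent generator seeded by
(master seed, participant index), so cohorts are bit-for-bit reproducible and
stable participant-by-participant.

## Psychometric fitting

Fits are maximum likelihood on binned (level, n, k) counts — equivalent to
the trial-level Bernoulli likelihood up to a constant, since the design has 6
fixed levels. The parameterisation is (pse, sigma, lapse) with `sigma > 0`
and `lapse ∈ [0, 0.05]` by default (the lapse bound is configurable; no
forced-choice guess floor is modelled because the response scale spans 0–1).
Numerical choices:

- probabilities are clamped to `[1e-9, 1 − 1e-9]` in the likelihood so
  saturated cells stay finite;
- multi-start: the NLL is scored on a deterministic grid (PSE over the level
  range plus an empirical 50%-crossing guess, sigma over {0.5, 1, 2, 4, 8}°,
  lapse over {0, 0.02}) and bounded L-BFGS-B with analytic gradients runs
  from the three best points (function tolerance 1e-9); a Nelder-Mead
  fallback guards against total gradient failure;
- bootstrap refits start from the original solution only — the standard
  warm-start — which keeps 10,000 refits tractable;
- responses constant across all levels raise a non-identifiability error
  rather than returning a boundary fit; all-or-nothing data that *straddle*
  a level boundary converge to a steep finite fit with the PSE in the gap.

Goodness of fit is the deviance against the saturated model (simulation puts
its mean near the nominal levels − parameters ≈ 3 under well-specified data).
Confidence intervals are percentile intervals from a parametric Monte-Carlo
bootstrap (default 10,000 samples): simulate binomial counts from the fitted
curve at the observed levels, refit, take quantiles. Percentile rather than
BCa intervals match the plain Monte-Carlo description of the procedure being
emulated; measured coverage for the PSE is 97% at nominal 95% over 200
simulated sessions. Refit failures are dropped and counted, with a warning
flag above 20%.

The estimator face (`CumulativeGaussianPsychometric`) follows scikit-learn
conventions so fits compose with sklearn tooling; it bins trial-level input
and delegates to the same `fit_ml` core.

## Group analysis

Overall accuracy is the fraction of trials whose chosen interval truly
contained the most-counterclockwise grating; participants below 0.55 (strict)
are flagged excluded before fitting, mirroring the chance-performance rule of
the emulated study, and excluded records are retained with flags. Illusion
strength is the half-difference of the two PSEs. Group inference uses
pooled-variance (Student) t-tests — the printed df = 21 for groups of 12 and
11 implies pooling, and the package reproduces the published descriptive
statistics (trait score t = 3.41, age t = 1.79, full-scale IQ t = −0.26) to
the printed precision — plus one-sample t-tests of illusion strength against
zero per group and Pearson correlations of illusion strength with the trait
score and IQ. No multiple-testing correction is applied, matching the
analysis being emulated. Two of the published IQ-subscale t-values
(verbal −0.84, performance 0.54) are not reproducible from their own printed
means/SDs under any standard t variant and are treated as typographical;
they are not checked.

## Problem sizes in the test suite

Stochastic suites run at sizes chosen to give stable verdicts: parameter
recovery at the full 1,200-trial session size; bootstrap coverage over 200
simulated sessions at 500 bootstrap samples each; type-I calibration of the
between-group test over 200 full null cohorts (equal generative bias in both
groups), which rejects at 4.5% against the nominal 5%. The oracle-equivalence
test compares the optimizer against an exhaustive (pse, sigma) grid search
over the binomial likelihood at 0.05° resolution on small instances.

## Known limitations

- The predicted repulsion magnitude is conditional on the chosen tuning
  widths; only its ordering in `kappa` is treated as a substantive claim.
- The forward model is a mean-rate simulator: no response variability, no
  spatial structure, no surround suppression, no contrast adaptation
  (static `c50` manipulation only).
- The generator's observer is stationary and lapse-symmetric; exclusion-rule
  behaviour under strongly biased-but-sensitive observers is exercised only
  lightly by the default cohorts.
- Truncation of covariate draws is by clipping, which slightly inflates mass
  at the bounds for extreme specs; defaults sit far from the bounds.
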