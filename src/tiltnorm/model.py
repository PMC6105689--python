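"""Divisive-normalization population model of V1 orientation coding.

Implements the Naka-Rushton contrast-response function with divisive
normalization,

    r = r0 + rmax * E / (c50**p + kappa * N),

where for a stimulus made of one or two superimposed gratings the excitatory
drive ``E = sum_j [c_j * f(s_j)]**p`` and the normalization-pool drive
``N = sum_j [c_j * g(s_j)]**p`` are each summed across grating components
before the ratio.  ``f`` and ``g`` are von Mises orientation tuning functions
on the doubled-angle (period-180°) circle; the pool tuning ``g`` is much
broader than the excitatory tuning ``f``.  Cross-orientation (overlay)
suppression then shifts the population-response mode for a target grating
away from a superimposed mask: the tilt-repulsion illusion.  The strength of
that repulsion grows with the normalization scaling ``kappa``, which is the
behavioural prediction of the decreased-normalization account of autism
(a reduced kappa should weaken the illusion).

Orientation convention: degrees, vertical = 0, clockwise positive, period
180°.  All orientation arithmetic uses doubled angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DivergenceError,
    InvalidInputError,
    InvalidParameterError,
    UndecodableError,
)

__all__ = [
    "OrientationTuning",
    "NormalizationParams",
    "GratingComponent",
    "CompoundStimulus",
    "PopulationResponse",
    "concentration_from_hwhh",
    "tuning_value",
    "contrast_response",
    "asymptotic_response",
    "population_response",
    "decode_orientation",
    "predicted_repulsion",
]

#: Default excitatory half-width at half height (degrees of orientation).
DEFAULT_EXCITATORY_HWHH = 20.0
#: Default normalization-pool half-width at half height; the pool is much broader.
DEFAULT_POOL_HWHH = 60.0

#: Default decoding window around the target mode (degrees of orientation).
DEFAULT_DECODE_WINDOW = 22.5
#: Default population grid size over one 180° period.
DEFAULT_N_NEURONS = 181


def _wrap_orientation(delta_deg):
    """Signed orientation difference wrapped into [-90, 90)."""
    return (np.asarray(delta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def concentration_from_hwhh(hwhh_deg: float) -> float:
    """Von Mises concentration (doubled-angle circle) from a half width.

    Solves ``exp(k * (cos(2*h) - 1)) = 1/2`` for ``k`` given the half-width-
    at-half-height ``h`` in degrees of orientation.
    """
    if not 0.0 < hwhh_deg < 90.0:
        raise InvalidParameterError(
            f"half width must lie in (0, 90) degrees, got {hwhh_deg}"
        )
    return math.log(2.0) / (1.0 - math.cos(2.0 * math.radians(hwhh_deg)))


@dataclass(frozen=True)
class OrientationTuning:
    """Von Mises orientation tuning on the period-180° circle.

    The tuning value peaks at exactly 1 at ``preferred_orientation`` and is
    symmetric about it.
    """

    preferred_orientation: float = 0.0
    concentration: float = field(
        default_factory=lambda: concentration_from_hwhh(DEFAULT_EXCITATORY_HWHH)
    )

    def __post_init__(self):
        if not np.isfinite(self.preferred_orientation):
            raise InvalidParameterError("preferred_orientation must be finite")
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise InvalidParameterError(
                f"concentration must be positive, got {self.concentration}"
            )

    @classmethod
    def from_half_width(
        cls, hwhh_deg: float, preferred_orientation: float = 0.0
    ) -> "OrientationTuning":
        return cls(preferred_orientation, concentration_from_hwhh(hwhh_deg))

    def __call__(self, s):
        return tuning_value(s, self)


def tuning_value(s, tuning: OrientationTuning):
    """Evaluate the von Mises tuning curve at orientation ``s`` (degrees).

    Returns ``exp(concentration * (cos(2*delta) - 1))`` with ``delta`` the
    angular difference to the preferred orientation; lies in (0, 1].
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError("stimulus orientation must be finite")
    delta = np.radians(s - tuning.preferred_orientation)
    out = np.exp(tuning.concentration * (np.cos(2.0 * delta) - 1.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NormalizationParams:
    """Parameter set of the divisive-normalization contrast-response function.

    Attributes
    ----------
    r0 : float
        Spontaneous discharge (Hz), >= 0.
    rmax : float
        Response-rate scale (Hz), > 0.  Note the saturating rate is
        ``r0 + rmax/kappa`` at the preferred orientation, not ``rmax``.
    c50 : float
        Semi-saturation contrast (% Michelson), > 0; sets the horizontal
        position of the contrast-response function.
    kappa : float
        Normalization scaling, > 0; equals 1 in the standard model, and a
        reduction (e.g. 0.75) models decreased normalization.
    exponent : float
        Accelerating nonlinearity applied to each linear drive (default 2).
    excitatory_tuning, pool_tuning : OrientationTuning
        Tuning of the excitatory drive f and of the suppressive pool g; the
        pool must be broader (smaller concentration).
    """

    r0: float = 0.0
    rmax: float = 50.0
    c50: float = 20.0
    kappa: float = 1.0
    exponent: float = 2.0
    excitatory_tuning: OrientationTuning = field(
        default_factory=lambda: OrientationTuning.from_half_width(
            DEFAULT_EXCITATORY_HWHH
        )
    )
    pool_tuning: OrientationTuning = field(
        default_factory=lambda: OrientationTuning.from_half_width(DEFAULT_POOL_HWHH)
    )

    def __post_init__(self):
        if self.r0 < 0:
            raise InvalidParameterError("r0 must be nonnegative")
        if self.rmax <= 0:
            raise InvalidParameterError("rmax must be positive")
        if self.c50 <= 0:
            raise InvalidParameterError("c50 must be positive")
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be nonnegative")
        if self.exponent <= 0:
            raise InvalidParameterError("exponent must be positive")
        if self.pool_tuning.concentration >= self.excitatory_tuning.concentration:
            raise InvalidParameterError(
                "pool tuning must be broader than excitatory tuning"
            )

    def at_preferred(self, preferred_orientation: float) -> "NormalizationParams":
        """Copy of the parameters recentred on a new preferred orientation."""
        return replace(
            self,
            excitatory_tuning=replace(
                self.excitatory_tuning, preferred_orientation=preferred_orientation
            ),
            pool_tuning=replace(
                self.pool_tuning, preferred_orientation=preferred_orientation
            ),
        )


@dataclass(frozen=True)
class GratingComponent:
    """One sinusoidal grating component of a stimulus.

    Spatial frequency is metadata only (it makes components distinguishable
    to observers); the contrast-response function has no frequency term.
    """

    orientation: float
    contrast: float
    spatial_frequency: float = 1.5

    def __post_init__(self):
        if not np.isfinite(self.orientation):
            raise InvalidParameterError("orientation must be finite")
        if not 0.0 <= self.contrast <= 100.0:
            raise InvalidParameterError(
                f"contrast must lie in [0, 100] % Michelson, got {self.contrast}"
            )


@dataclass(frozen=True)
class CompoundStimulus:
    """One or two superimposed grating components."""

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if not 1 <= len(comps) <= 2:
            raise InvalidInputError(
                f"a stimulus has 1 or 2 components, got {len(comps)}"
            )
        object.__setattr__(self, "components", comps)

    @classmethod
    def single(cls, orientation: float, contrast: float = 100.0) -> "CompoundStimulus":
        return cls((GratingComponent(orientation, contrast),))

    @classmethod
    def compound(
        cls,
        target_orientation: float,
        mask_orientation: float = 45.0,
        target_contrast: float = 100.0,
        mask_contrast: float = 100.0,
    ) -> "CompoundStimulus":
        return cls(
            (
                GratingComponent(target_orientation, target_contrast, 1.5),
                GratingComponent(mask_orientation, mask_contrast, 3.75),
            )
        )


@dataclass(frozen=True)
class PopulationResponse:
    """Firing rates of a grid of neurons tiling one 180° period."""

    preferred_orientations: np.ndarray
    rates: np.ndarray
    r0: float = 0.0

    def __post_init__(self):
        prefs = np.asarray(self.preferred_orientations, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if prefs.shape != rates.shape:
            raise InvalidInputError("orientation grid and rates must align")
        object.__setattr__(self, "preferred_orientations", prefs)
        object.__setattr__(self, "rates", rates)


def _drives(stimulus: CompoundStimulus, params: NormalizationParams, prefs):
    """Excitatory and pool drives summed over components, per neuron."""
    prefs = np.atleast_1d(np.asarray(prefs, dtype=float))
    p = params.exponent
    exc = np.zeros_like(prefs)
    pool = np.zeros_like(prefs)
    for comp in stimulus.components:
        d = np.radians(comp.orientation - prefs)
        cos2d = np.cos(2.0 * d)
        f = np.exp(params.excitatory_tuning.concentration * (cos2d - 1.0))
        g = np.exp(params.pool_tuning.concentration * (cos2d - 1.0))
        exc += (comp.contrast * f) ** p
        pool += (comp.contrast * g) ** p
    return exc, pool


def contrast_response(
    stimulus: CompoundStimulus, params: NormalizationParams
) -> float:
    """Firing rate (Hz) of one neuron to a single or compound grating.

    ``r0 + rmax * E / (c50**p + kappa * N)`` with drives summed across
    components; reduces to the single-stimulus Naka-Rushton form for one
    component.  Monotone nondecreasing in each component's contrast and
    bounded below by ``r0``.
    """
    if not stimulus.components:
        raise InvalidInputError("stimulus has no components")
    pref = params.excitatory_tuning.preferred_orientation
    exc, pool = _drives(stimulus, params, pref)
    denom = params.c50 ** params.exponent + params.kappa * pool[0]
    return float(params.r0 + params.rmax * exc[0] / denom)


def asymptotic_response(params: NormalizationParams, s: float = None) -> float:
    """Saturating (contrast -> infinity) rate for a single grating at ``s``.

    Equals ``r0 + (rmax/kappa) * (f(s)/g(s))**p``; at the preferred
    orientation (where f = g = 1) this is ``r0 + rmax/kappa``, so halving
    kappa doubles the saturating rate.
    """
    if params.kappa == 0:
        raise DivergenceError("response is unbounded when kappa = 0")
    if s is None:
        s = params.excitatory_tuning.preferred_orientation
    f = tuning_value(s, params.excitatory_tuning)
    g = tuning_value(s, params.pool_tuning)
    return float(
        params.r0 + (params.rmax / params.kappa) * (f / g) ** params.exponent
    )


def population_grid(n_neurons: int) -> np.ndarray:
    """Preferred-orientation grid tiling [-90, 90) without endpoint duplication."""
    if n_neurons < 8:
        raise InvalidParameterError("need at least 8 neurons in the population")
    return -90.0 + 180.0 * np.arange(n_neurons) / n_neurons


def population_response(
    stimulus: CompoundStimulus,
    params: NormalizationParams,
    n_neurons: int = DEFAULT_N_NEURONS,
) -> PopulationResponse:
    """Rates of a homogeneous population whose preferred orientations tile 180°.

    Every neuron shares ``params`` apart from its preferred orientation.  A
    single grating yields a unimodal profile peaked at the grating
    orientation; a 0°+45° compound yields a bimodal profile.
    """
    prefs = population_grid(n_neurons)
    exc, pool = _drives(stimulus, params, prefs)
    denom = params.c50 ** params.exponent + params.kappa * pool
    rates = params.r0 + params.rmax * exc / denom
    return PopulationResponse(prefs, rates, r0=params.r0)


def decode_orientation(
    pop: PopulationResponse,
    reference: float = 0.0,
    window: float = DEFAULT_DECODE_WINDOW,
    decimals: int | None = 2,
) -> float:
    """Decode the orientation of the response mode nearest ``reference``.

    Local doubled-angle population-vector average: rates (baseline ``r0``
    subtracted) of neurons preferring orientations within ``window`` degrees
    of the mode weight a vector sum on the doubled circle.  A local readout
    is used because a global vector average over a bimodal profile measures
    attraction toward the second mode rather than the shift of the target
    mode.  Starting from ``reference``, the window is re-centred on each
    successive estimate until it converges on the mode itself; a window
    fixed at the reference would truncate the profile asymmetrically and
    bias the estimate toward the reference.  The window has a raised-cosine
    taper, so neurons at its edge get smoothly vanishing weight: a hard
    cutoff through the flank of the profile would make the estimate jump
    with the discrete grid.
    """

    def _vector_average(center):
        d = _wrap_orientation(pop.preferred_orientations - center)
        in_window = np.abs(d) <= window
        if np.count_nonzero(in_window) < 3:
            raise InvalidInputError(
                "need at least 3 neurons inside the decode window"
            )
        taper = np.cos(0.5 * np.pi * d[in_window] / window) ** 2
        w = np.clip(pop.rates[in_window] - pop.r0, 0.0, None)
        if not np.any(w > 0):
            raise UndecodableError("all in-window rates are at baseline")
        w = w * taper
        ang = 2.0 * np.radians(d[in_window])
        return float(
            _wrap_orientation(
                center
                + 0.5
                * math.degrees(
                    math.atan2(
                        float(np.sum(w * np.sin(ang))),
                        float(np.sum(w * np.cos(ang))),
                    )
                )
            )
        )

    decoded = float(reference)
    for _ in range(100):
        new = _vector_average(decoded)
        if abs(_wrap_orientation(new - decoded)) < 1e-9:
            decoded = new
            break
        decoded = new
    return round(decoded, decimals) if decimals is not None else decoded


def predicted_repulsion(
    target: GratingComponent,
    mask: GratingComponent,
    params: NormalizationParams,
    n_neurons: int = DEFAULT_N_NEURONS,
    window: float = DEFAULT_DECODE_WINDOW,
    decimals: int | None = 2,
) -> float:
    """Predicted illusory tilt of ``target`` away from ``mask`` (degrees).

    Computed as (target orientation) - (decoded orientation of the target
    mode of the compound's population response), so the sign mirrors when
    the mask changes side.  For the standard clockwise mask (+45°) the
    decoded target shifts counterclockwise and the returned value is
    positive; its magnitude grows with the normalization scaling kappa,
    which is the model's core behavioural prediction.
    """
    if _wrap_orientation(target.orientation - mask.orientation) == 0.0:
        raise InvalidInputError("target and mask orientations must differ")
    stim = CompoundStimulus((target, mask))
    pop = population_response(stim, params, n_neurons)
    decoded = decode_orientation(pop, reference=target.orientation, window=window,
                                 decimals=None)
    rep = float(_wrap_orientation(target.orientation - decoded))
    return round(rep, decimals) if decimals is not None else rep
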