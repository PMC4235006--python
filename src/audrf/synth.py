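"""Synthetic populations of auditory midbrain units with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* **FRA archetypes** -- a V-shaped excitatory region (two linear threshold
  flanks in octave-vs-attenuation space meeting at the characteristic
  frequency) and four nonV deformations observed in the inferior colliculus:
  *low-tilt* (skewed trough), *narrow* (bandwidth-clipped), *closed* (an upper
  sound-level bound on excitation) and *broad* (shallow flanks).  Inside the
  excitatory region a unit fires at its driven rate, outside at its
  spontaneous rate; trial counts are independent Poisson draws.

* **RLF archetypes** -- five rate-level function types: ``straight`` (linear
  in dB), ``saturating`` (sigmoid drive reaching a plateau), ``monotonic``
  (sigmoid drive, no plateau within the tested range), ``non-monotonic``
  (sigmoid drive with high-level suppression) and ``flat`` (weakly
  responsive).

* **Deactivation effects** -- silencing the opposite colliculus is modelled
  as parameter transforms: multiplicative gains on driven and spontaneous
  rates, an additive threshold shift, and (nonV FRAs only) a scaling of the
  excitatory-region frequency extent.  For RLFs the driven gain acts on the
  synaptic drive *upstream* of the sigmoid output stage, so a gain below one
  both lowers rates and shifts the function toward louder sounds -- the
  commissural gain-control signature.  Recovery re-samples the control
  archetype with fresh noise, giving a clean null for recovery-vs-control
  comparisons.

Everything is a pure function of the configuration: a fixed seed reproduces
the population bit for bit, and the returned ground-truth ledger records
every archetype parameter and effect so the true value of each downstream
estimand (CF, threshold, area, half-max level, monotonicity) is computable
analytically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_io import (
    ConditionTriplet,
    RateLevelFunction,
    ResponseGrid,
    StimulusGrid,
    UnitRecord,
    ValidationError,
)

__all__ = [
    "FRAArchetype",
    "RLFArchetype",
    "DeactivationEffect",
    "RLFDeactivationEffect",
    "PopulationConfig",
    "SyntheticUnit",
    "Population",
    "fra_grid",
    "rlf_levels",
    "threshold_contour",
    "region_mask",
    "expected_rate_surface",
    "apply_deactivation",
    "sample_trials",
    "noiseless_grid",
    "expected_rlf_curve",
    "apply_rlf_deactivation",
    "make_rlf",
    "make_population",
]

FRA_CLASSES = ("V", "low-tilt", "narrow", "closed", "broad")
RLF_TYPES = ("straight", "saturating", "monotonic", "non-monotonic", "flat")

DEFAULT_CALIBRATION = 100.0  # dB SPL maximum output in the flat speaker region


def fra_grid(
    reference_cf: float,
    *,
    calibration: float | None = DEFAULT_CALIBRATION,
) -> StimulusGrid:
    """The FRA stimulus grid: -3 to +2 octaves re the estimated CF in
    0.1-octave steps (51 tones), 10-90 dB attenuation in 5 dB steps."""
    octs = np.round(np.arange(-30, 21) / 10.0, 10)
    freqs = reference_cf * 2.0 ** octs
    levels = np.arange(10.0, 91.0, 5.0)
    return StimulusGrid(freqs, levels, calibration=calibration,
                        reference_frequency=reference_cf)


def rlf_levels() -> np.ndarray:
    """The RLF level series: 10-90 dB attenuation in 10 dB steps."""
    return np.arange(10.0, 91.0, 10.0)


# ---------------------------------------------------------------------------
# FRA archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FRAArchetype:
    """Parametric frequency response area.

    ``min_threshold`` is the attenuation of the excitatory trough (largest
    attenuation = most sensitive point); flanks fall away from it at
    ``slope_low`` / ``slope_high`` dB per octave.  ``closed_upper_bound``
    (closed class) is the attenuation below which (i.e. for louder sounds)
    excitation ceases; ``tilt`` (low-tilt class) skews the contour;
    ``bandwidth_cap`` (narrow class) clips total bandwidth in octaves.
    Rates are expected spikes per 75-ms presentation.
    """

    fra_class: str
    cf: float  # Hz
    min_threshold: float  # dB attenuation of the trough
    slope_low: float  # dB/octave, low-frequency flank (> 0)
    slope_high: float  # dB/octave, high-frequency flank (> 0)
    driven_rate: float
    spontaneous_rate: float = 0.0
    closed_upper_bound: float | None = None  # dB attenuation (closed only)
    tilt: float = 0.0  # dB/octave (low-tilt only)
    bandwidth_cap: float | None = None  # octaves (narrow only)

    def __post_init__(self) -> None:
        if self.fra_class not in FRA_CLASSES:
            raise ValidationError(f"unknown FRA class {self.fra_class!r}")
        if self.slope_low <= 0 or self.slope_high <= 0:
            raise ValidationError("flank slopes must be positive")
        if not (self.driven_rate > self.spontaneous_rate >= 0):
            raise ValidationError("need driven_rate > spontaneous_rate >= 0")
        if self.fra_class == "closed":
            if self.closed_upper_bound is None:
                raise ValidationError("closed archetype requires closed_upper_bound")
            if self.closed_upper_bound >= self.min_threshold:
                raise ValidationError(
                    "closed_upper_bound must be louder (smaller attenuation) than the trough"
                )
        if self.fra_class == "narrow" and not self.bandwidth_cap:
            raise ValidationError("narrow archetype requires bandwidth_cap")
        if self.fra_class == "low-tilt":
            if abs(self.tilt) >= min(self.slope_low, self.slope_high):
                raise ValidationError("tilt must be smaller than both flank slopes")

    @property
    def is_v(self) -> bool:
        return self.fra_class == "V"


def threshold_contour(arch: FRAArchetype, octaves: np.ndarray) -> np.ndarray:
    """Excitatory threshold contour in dB attenuation as a function of the
    octave distance from CF.  A sound at attenuation ``a`` excites the unit
    iff ``a <= contour`` (and, for closed FRAs, ``a >= closed_upper_bound``)."""
    d = np.asarray(octaves, dtype=float)
    contour = arch.min_threshold - np.where(d < 0, arch.slope_low * (-d), arch.slope_high * d)
    if arch.fra_class == "low-tilt":
        contour = contour + arch.tilt * d
    return contour


def region_mask(arch: FRAArchetype, grid: StimulusGrid) -> np.ndarray:
    """Boolean (n_frequencies, n_levels) ground-truth excitatory region."""
    octs = np.log2(grid.frequencies / arch.cf)
    if octs[0] > 0 or octs[-1] < 0:
        raise ValidationError("grid does not span the archetype CF")
    contour = threshold_contour(arch, octs)
    mask = grid.levels[None, :] <= contour[:, None]
    if arch.fra_class == "narrow":
        mask &= (np.abs(octs) <= arch.bandwidth_cap / 2.0)[:, None]
    if arch.fra_class == "closed":
        mask &= grid.levels[None, :] >= arch.closed_upper_bound
    return mask


def expected_rate_surface(arch: FRAArchetype, grid: StimulusGrid) -> np.ndarray:
    """Expected spikes per presentation for every (frequency, level) bin."""
    mask = region_mask(arch, grid)
    return np.where(mask, arch.driven_rate, arch.spontaneous_rate)


@dataclass(frozen=True)
class DeactivationEffect:
    """Transform applied to an FRA archetype under contralateral deactivation.

    ``area_scale`` multiplies the frequency extent of the excitatory region
    (flank slopes divided, bandwidth cap multiplied) and is only admissible
    for nonV archetypes: V-shaped receptive fields change firing rate but not
    area under commissural deactivation, and the generator enforces that in
    ground truth.
    """

    gain: float = 1.0
    spont_gain: float = 1.0
    threshold_shift: float = 0.0  # dB added to the trough attenuation
    area_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gain, self.spont_gain, self.area_scale) < 0:
            raise ValidationError("gain, spont_gain and area_scale must be >= 0")


def apply_deactivation(arch: FRAArchetype, effect: DeactivationEffect) -> FRAArchetype:
    """Return the archetype as seen during deactivation."""
    if effect.area_scale != 1.0 and arch.is_v:
        raise ValidationError("area_scale != 1 is not admissible for V archetypes")
    if effect.area_scale == 0:
        raise ValidationError("area_scale must be positive when applied")
    kwargs = dict(
        driven_rate=arch.driven_rate * effect.gain,
        spontaneous_rate=arch.spontaneous_rate * effect.spont_gain,
        min_threshold=arch.min_threshold + effect.threshold_shift,
        slope_low=arch.slope_low / effect.area_scale,
        slope_high=arch.slope_high / effect.area_scale,
        # tilt is a contour slope in the same dB/octave coordinate and
        # scales with the frequency extent like the flanks
        tilt=arch.tilt / effect.area_scale,
    )
    if arch.bandwidth_cap is not None:
        kwargs["bandwidth_cap"] = arch.bandwidth_cap * effect.area_scale
    if kwargs["driven_rate"] <= kwargs["spontaneous_rate"]:
        # keep the archetype valid when a strong gain drop meets high spont
        kwargs["spontaneous_rate"] = kwargs["driven_rate"] * 0.99
    return replace(arch, **kwargs)


def sample_trials(
    expected: np.ndarray,
    grid: StimulusGrid,
    n_trials: int,
    seed: int | np.random.Generator,
) -> ResponseGrid:
    """Draw independent Poisson trial counts around a per-bin expectation."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValidationError("expected rates must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(expected[:, :, None], size=expected.shape + (n_trials,))
    return ResponseGrid(grid, counts)


def noiseless_grid(arch: FRAArchetype, grid: StimulusGrid) -> ResponseGrid:
    """Deterministic grid with counts equal to the rounded expected surface
    (useful for exercising the analysis on noise-free input)."""
    expected = expected_rate_surface(arch, grid)
    return ResponseGrid(grid, np.round(expected).astype(int)[:, :, None])


# ---------------------------------------------------------------------------
# RLF archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RLFArchetype:
    """Parametric rate-level function at CF.

    Levels are parameterized in dB SPL.  ``max_driven`` is the saturating
    driven rate in spikes per presentation.  Sigmoid-drive types
    (``saturating``, ``monotonic``, ``non-monotonic``) rise as a logistic of
    ``(spl - midpoint) / width``; ``straight`` rises linearly from
    ``threshold`` to the top of the tested range; ``flat`` barely responds.
    ``best_level`` / ``reduction_fraction`` shape the high-level suppression
    of the non-monotonic type.
    """

    rlf_type: str
    max_driven: float
    spontaneous_rate: float = 0.1
    threshold: float = 25.0  # dB SPL, straight type ramp onset
    midpoint: float = 45.0  # dB SPL, sigmoid midpoint
    width: float = 6.0  # dB, sigmoid slope constant
    best_level: float = 60.0  # dB SPL (non-monotonic)
    reduction_fraction: float = 0.0  # drop above best level (non-monotonic)
    suppression_width: float = 8.0  # dB (non-monotonic)

    def __post_init__(self) -> None:
        if self.rlf_type not in RLF_TYPES:
            raise ValidationError(f"unknown RLF type {self.rlf_type!r}")
        if self.max_driven < 0 or self.spontaneous_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.reduction_fraction < 0:
            raise ValidationError("reduction_fraction must be >= 0")
        if self.width <= 0 or self.suppression_width <= 0:
            raise ValidationError("widths must be positive")


@dataclass(frozen=True)
class RLFDeactivationEffect:
    """Transform applied to an RLF archetype under contralateral deactivation.

    ``gain`` multiplies the synaptic drive ahead of the output sigmoid (pure
    output scale for straight/flat types); ``nonmono_relief`` multiplies the
    high-level suppression fraction (removal of the commissurally generated
    inhibition that creates non-monotonicity); ``threshold_shift`` moves the
    function along the level axis in dB.
    """

    gain: float = 1.0
    spont_gain: float = 1.0
    threshold_shift: float = 0.0
    nonmono_relief: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gain, self.spont_gain, self.nonmono_relief) < 0:
            raise ValidationError("effect factors must be >= 0")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def expected_rlf_curve(
    arch: RLFArchetype,
    levels_spl: np.ndarray,
    effect: RLFDeactivationEffect | None = None,
) -> np.ndarray:
    """Noise-free expected spikes per presentation at each level (dB SPL)."""
    eff = effect or RLFDeactivationEffect()
    spl = np.asarray(levels_spl, dtype=float) - eff.threshold_shift
    g, spont = eff.gain, arch.spontaneous_rate * eff.spont_gain
    top = float(np.max(spl))
    if arch.rlf_type == "straight":
        span = max(top - arch.threshold, 1.0)
        driven = g * arch.max_driven * np.clip((spl - arch.threshold) / span, 0.0, None)
    elif arch.rlf_type == "flat":
        driven = g * arch.max_driven * np.full_like(spl, 0.5)
    else:
        # sigmoid output stage with divisive gain on the drive:
        # D = g * exp((L - midpoint)/width);  rate = max_driven * D / (1 + D)
        drive = g * np.exp((spl - arch.midpoint) / arch.width)
        frac = drive / (1.0 + drive)
        if arch.rlf_type == "non-monotonic":
            # high-level suppression engaging above the best level: no effect
            # at the best level itself, approaching the full reduction
            # fraction asymptotically, so the noiseless curve drops by that
            # fraction above the peak by construction
            rho = arch.reduction_fraction * eff.nonmono_relief
            supp = 2.0 * (_sigmoid(
                np.maximum(spl - arch.best_level, 0.0) / arch.suppression_width
            ) - 0.5)
            frac = frac * (1.0 - rho * supp)
        # reduced drive also lowers the attainable output: the ceiling scales
        # with the gain while the operating point shifts along the sigmoid
        driven = g * arch.max_driven * frac
    return spont + driven


def apply_rlf_deactivation(
    arch: RLFArchetype, effect: RLFDeactivationEffect
) -> RLFArchetype:
    """Fold a deactivation effect into archetype parameters where possible.

    The divisive drive gain is equivalent to shifting the sigmoid midpoint by
    ``width * ln(1/gain)``; the straight/flat gain scales ``max_driven``.
    Used to keep the ground-truth ledger analytic.
    """
    kwargs: dict = dict(
        spontaneous_rate=arch.spontaneous_rate * effect.spont_gain,
    )
    if arch.rlf_type in ("straight", "flat"):
        kwargs["max_driven"] = arch.max_driven * effect.gain
        kwargs["threshold"] = arch.threshold + effect.threshold_shift
    else:
        kwargs["max_driven"] = arch.max_driven * effect.gain
        kwargs["midpoint"] = (
            arch.midpoint + arch.width * float(np.log(1.0 / max(effect.gain, 1e-12)))
            + effect.threshold_shift
        )
        if arch.rlf_type == "non-monotonic":
            kwargs["reduction_fraction"] = arch.reduction_fraction * effect.nonmono_relief
            kwargs["best_level"] = arch.best_level + effect.threshold_shift
    return replace(arch, **kwargs)


def make_rlf(
    arch: RLFArchetype,
    n_trials: int = 20,
    seed: int | np.random.Generator = 0,
    *,
    effect: RLFDeactivationEffect | None = None,
    levels: np.ndarray | None = None,
    calibration: float = DEFAULT_CALIBRATION,
) -> RateLevelFunction:
    """Sample a trial-wise RLF (levels in dB attenuation, Poisson trials)."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    lv = rlf_levels() if levels is None else np.asarray(levels, dtype=float)
    expected = expected_rlf_curve(arch, calibration - lv, effect)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(expected[:, None], size=(lv.size, n_trials))
    return RateLevelFunction(
        frequency=1000.0, levels=lv, counts=counts, calibration=calibration,
        allowed_trials=None,
    )


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Study-scale synthetic population.

    Defaults mirror the recorded samples: 49 V and 50 nonV FRA units, 38 RLF
    units of which 16 also carry FRA triplets (the subset entering the
    half-max-vs-threshold correlation).  FRA bins hold five sweeps per tone
    (spikes counted per stimulus and pooled across sweeps); RLFs 50 trials
    per level.  ``null_effects`` freezes every deactivation effect at identity --
    the zero-effect generator used for type-I-error calibration.
    ``rlf_drive_gain`` overrides the sampled RLF drive gain with a uniform
    value (all other RLF effect fields identity), the condition used to probe
    direction-of-effect recovery.
    """

    seed: int = 0
    n_v: int = 49
    n_nonv: int = 50
    n_rlf: int = 38
    n_rlf_with_fra: int = 16
    n_trials_fra: int = 5
    n_trials_rlf: int = 50
    calibration: float = DEFAULT_CALIBRATION
    null_effects: bool = False
    rlf_drive_gain: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_v, self.n_nonv, self.n_rlf) < 0:
            raise ValidationError("unit counts must be >= 0")
        if self.n_rlf_with_fra > self.n_rlf:
            raise ValidationError("n_rlf_with_fra cannot exceed n_rlf")


@dataclass
class SyntheticUnit:
    record: UnitRecord
    fra: ConditionTriplet | None
    rlf: ConditionTriplet | None
    truth: dict


@dataclass
class Population:
    config: PopulationConfig
    units: list[SyntheticUnit]
    ledger: dict


_NONV_SUBTYPES = ("low-tilt", "narrow", "closed", "broad")

# default RLF type mix: 12/38 non-monotonic as in the recorded sample,
# remainder spread over the other four types
_RLF_MIX = ("non-monotonic",) * 12 + ("saturating",) * 10 + ("monotonic",) * 8 + (
    "straight",
) * 6 + ("flat",) * 2


def _sample_fra_archetype(rng: np.random.Generator, fra_class: str) -> FRAArchetype:
    cf = float(2.0 ** rng.uniform(np.log2(1000.0), np.log2(8000.0)))
    min_threshold = float(rng.uniform(55.0, 80.0))
    driven = float(rng.uniform(3.0, 6.0))
    spont = float(rng.uniform(0.05, 0.4))
    slope = lambda lo, hi: float(rng.uniform(lo, hi))
    kwargs: dict = {}
    if fra_class in ("V", "low-tilt", "narrow", "closed"):
        s_lo, s_hi = slope(45.0, 100.0), slope(45.0, 100.0)
    else:  # broad
        s_lo, s_hi = slope(15.0, 35.0), slope(15.0, 35.0)
    if fra_class == "low-tilt":
        kwargs["tilt"] = float(rng.uniform(8.0, 0.8 * min(s_lo, s_hi)) * rng.choice([-1, 1]))
    if fra_class == "narrow":
        kwargs["bandwidth_cap"] = float(rng.uniform(0.25, 0.6))
    if fra_class == "closed":
        kwargs["closed_upper_bound"] = min_threshold - float(rng.uniform(20.0, 35.0))
    return FRAArchetype(
        fra_class=fra_class, cf=cf, min_threshold=min_threshold,
        slope_low=s_lo, slope_high=s_hi,
        driven_rate=driven, spontaneous_rate=spont, **kwargs,
    )


def _sample_fra_effect(rng: np.random.Generator, fra_class: str, null: bool) -> DeactivationEffect:
    if null:
        return DeactivationEffect()
    if fra_class == "V":
        # firing-rate changes with a mild bias toward increases, no area change
        log_gain = rng.normal(0.10, 0.30)
        area_scale = 1.0
    else:
        log_gain = rng.normal(-0.05, 0.35)
        area_scale = float(np.exp(rng.normal(0.0, 0.45)))
    return DeactivationEffect(
        gain=float(np.exp(log_gain)),
        spont_gain=float(np.exp(rng.normal(0.0, 0.25))),
        threshold_shift=float(rng.normal(0.0, 3.0)),
        area_scale=area_scale,
    )


def _sample_rlf_archetype(rng: np.random.Generator, rlf_type: str) -> RLFArchetype:
    """Draw an archetype whose *noiseless* curve classifies as its label.

    The parameter ranges keep draws inside their class region; the rare
    draw landing exactly on a classification boundary is rejected and
    redrawn, so ledger labels are guaranteed by construction.
    """
    from .rlf import classify_rlf  # local import: rlf does not import synth

    spl = np.sort(DEFAULT_CALIBRATION - rlf_levels())
    for _ in range(20):
        arch = _draw_rlf_archetype(rng, rlf_type)
        if classify_rlf(expected_rlf_curve(arch, spl), spl) == rlf_type:
            return arch
    raise ValidationError(f"could not draw a valid {rlf_type!r} archetype")


def _draw_rlf_archetype(rng: np.random.Generator, rlf_type: str) -> RLFArchetype:
    max_driven = float(rng.uniform(2.5, 7.0))
    spont = float(rng.uniform(0.05, 0.25))
    if rlf_type == "straight":
        # ramp onset at or below the quietest tested level: linear over the range
        return RLFArchetype(rlf_type, max_driven, spont, threshold=float(rng.uniform(0.0, 10.0)))
    if rlf_type == "flat":
        return RLFArchetype(rlf_type, float(rng.uniform(0.2, 0.7)), spont)
    if rlf_type == "saturating":
        return RLFArchetype(
            rlf_type, max_driven, spont,
            midpoint=float(rng.uniform(35.0, 55.0)), width=float(rng.uniform(4.0, 7.0)),
        )
    if rlf_type == "monotonic":
        return RLFArchetype(
            rlf_type, max_driven, spont,
            midpoint=float(rng.uniform(68.0, 78.0)), width=float(rng.uniform(8.0, 13.0)),
        )
    # non-monotonic
    return RLFArchetype(
        rlf_type, max_driven, spont,
        midpoint=float(rng.uniform(32.0, 48.0)), width=float(rng.uniform(4.0, 7.0)),
        best_level=float(rng.uniform(55.0, 65.0)),
        reduction_fraction=float(rng.uniform(0.55, 0.8)),
        suppression_width=float(rng.uniform(5.0, 8.0)),
    )


def _sample_rlf_effect(rng: np.random.Generator, cfg: PopulationConfig) -> RLFDeactivationEffect:
    if cfg.null_effects:
        return RLFDeactivationEffect()
    if cfg.rlf_drive_gain is not None:
        # uniform multiplicative deactivation: drive and spontaneous firing
        # are scaled together (deactivation lowers both in the recordings)
        return RLFDeactivationEffect(gain=cfg.rlf_drive_gain,
                                     spont_gain=cfg.rlf_drive_gain)
    # heterogeneous gain drop plus a systematic rightward rescaling of the
    # level axis: deactivated units need louder sounds for the same relative
    # firing, the supra-threshold gain-control signature of the commissure
    return RLFDeactivationEffect(
        gain=float(np.exp(rng.normal(np.log(0.65), 0.30))),
        spont_gain=float(np.exp(rng.normal(0.0, 0.20))),
        threshold_shift=float(rng.normal(5.0, 3.0)),
        nonmono_relief=float(rng.uniform(0.15, 1.0)),
    )


def _fra_triplet(
    arch: FRAArchetype,
    effect: DeactivationEffect,
    cfg: PopulationConfig,
    rng: np.random.Generator,
) -> tuple[ConditionTriplet, StimulusGrid, FRAArchetype]:
    grid = fra_grid(arch.cf, calibration=cfg.calibration)
    deact_arch = apply_deactivation(arch, effect)
    control = sample_trials(expected_rate_surface(arch, grid), grid, cfg.n_trials_fra, rng)
    deact = sample_trials(expected_rate_surface(deact_arch, grid), grid, cfg.n_trials_fra, rng)
    recov = sample_trials(expected_rate_surface(arch, grid), grid, cfg.n_trials_fra, rng)
    return ConditionTriplet(control, deact, recov), grid, deact_arch


def _rlf_triplet(
    arch: RLFArchetype,
    effect: RLFDeactivationEffect,
    cfg: PopulationConfig,
    rng: np.random.Generator,
) -> ConditionTriplet:
    control = make_rlf(arch, cfg.n_trials_rlf, rng, calibration=cfg.calibration)
    deact = make_rlf(arch, cfg.n_trials_rlf, rng, effect=effect, calibration=cfg.calibration)
    recov = make_rlf(arch, cfg.n_trials_rlf, rng, calibration=cfg.calibration)
    return ConditionTriplet(control, deact, recov)


def make_population(config: PopulationConfig) -> Population:
    """Generate the full synthetic study: FRA units, RLF units, ground truth.

    Deterministic in ``config`` (including its seed).  The ledger maps unit
    ids to their true archetype parameters, applied effects, and analytic
    ground-truth quantities (region bin count, CF, trough threshold,
    non-monotonicity of the noise-free curve, ...).
    """
    rng = np.random.default_rng(config.seed)
    units: list[SyntheticUnit] = []
    ledger: dict[str, dict] = {}

    fra_classes = ["V"] * config.n_v + [
        _NONV_SUBTYPES[i % len(_NONV_SUBTYPES)] for i in range(config.n_nonv)
    ]
    for i, fra_class in enumerate(fra_classes):
        uid = f"fra{i:03d}"
        arch = _sample_fra_archetype(rng, fra_class)
        effect = _sample_fra_effect(rng, "V" if fra_class == "V" else "nonV", config.null_effects)
        triplet, grid, deact_arch = _fra_triplet(arch, effect, config, rng)
        record = UnitRecord(
            unit_id=uid, estimated_cf=arch.cf,
            fra_class="V" if fra_class == "V" else "nonV",
            subtype=None if fra_class == "V" else fra_class,
            deactivation_method="cooling" if rng.random() < 0.75 else "MDP",
        )
        truth = {
            "archetype": dataclasses.asdict(arch),
            "effect": dataclasses.asdict(effect),
            "cf": arch.cf,
            "threshold": arch.min_threshold,
            "area_bins": int(region_mask(arch, grid).sum()),
            "area_bins_deactivated": int(region_mask(deact_arch, grid).sum()),
        }
        units.append(SyntheticUnit(record, triplet, None, truth))
        ledger[uid] = truth

    rlf_types = list(_RLF_MIX)
    if config.n_rlf <= len(rlf_types):
        rlf_types = rlf_types[: config.n_rlf]
    else:
        rlf_types += [RLF_TYPES[i % 5] for i in range(config.n_rlf - len(rlf_types))]
    # interleave so any prefix (e.g. the FRA-carrying subset) mixes types
    order = rng.permutation(len(rlf_types))
    rlf_types = [rlf_types[i] for i in order]

    lv = rlf_levels()
    for i, rlf_type in enumerate(rlf_types):
        uid = f"rlf{i:03d}"
        arch = _sample_rlf_archetype(rng, rlf_type)
        effect = _sample_rlf_effect(rng, config)
        deact_arch = apply_rlf_deactivation(arch, effect)
        rlf_trip = _rlf_triplet(arch, effect, config, rng)
        fra_trip = None
        truth: dict = {
            "rlf_archetype": dataclasses.asdict(arch),
            "rlf_effect": dataclasses.asdict(effect),
            "rlf_type": rlf_type,
            "expected_control": expected_rlf_curve(arch, config.calibration - lv).tolist(),
            "expected_deactivated": expected_rlf_curve(
                arch, config.calibration - lv, effect
            ).tolist(),
        }
        record_kwargs = dict(unit_id=uid, estimated_cf=2000.0, fra_class="V")
        if i < config.n_rlf_with_fra:
            fra_arch = _sample_fra_archetype(rng, "V")
            fra_effect = _sample_fra_effect(rng, "V", config.null_effects)
            fra_trip, grid, fra_deact = _fra_triplet(fra_arch, fra_effect, config, rng)
            record_kwargs["estimated_cf"] = fra_arch.cf
            truth["archetype"] = dataclasses.asdict(fra_arch)
            truth["effect"] = dataclasses.asdict(fra_effect)
            truth["cf"] = fra_arch.cf
            truth["threshold"] = fra_arch.min_threshold
            truth["area_bins"] = int(region_mask(fra_arch, grid).sum())
        record = UnitRecord(**record_kwargs)
        units.append(SyntheticUnit(record, fra_trip, rlf_trip, truth))
        ledger[uid] = truth

    return Population(config=config, units=units, ledger=ledger)
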