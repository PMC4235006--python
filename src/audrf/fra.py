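"""Frequency response area analysis: spontaneous rate, excitatory region,
frequency tuning curve, CF, threshold, area and total spikes.

The chain follows the classical FRA workflow for inferior colliculus
recordings:

1. the responses at the quietest tested level (highest attenuation), pooled
   across all frequencies and trials, estimate the spontaneous firing rate
   (mean and SD in spikes per presentation);
2. a bin is *excitatory* when its mean count exceeds the spontaneous mean by
   more than ``sd_multiplier`` (default 2) standard deviations -- a strict
   inequality, so with SD = 0 any spiking above the mean counts;
3. per frequency, the quietest excitatory level is that frequency's
   excitatory threshold;
4. the threshold array, in octave coordinates, is least-squares fitted with a
   polynomial (requested degree 10, clamped to one less than the number of
   available thresholds) -- the excitatory frequency tuning curve (FTC);
5. the most sensitive point of the FTC (minimum sound level, i.e. maximum
   attenuation) defines the unit's CF and threshold;
6. the FRA *area* is the number of grid bins at levels at or above the FTC at
   their frequency; for FRAs the polynomial does not describe well, a
   fallback counts bins whose summed count exceeds a spike criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .data_io import ResponseGrid, StimulusGrid, ValidationError

__all__ = [
    "SpontaneousEstimate",
    "FTCFit",
    "FTCResult",
    "estimate_spontaneous",
    "excitatory_mask",
    "excitatory_thresholds",
    "fit_ftc",
    "extract_cf_threshold",
    "fra_area",
    "fra_area_fallback",
    "total_spikes",
    "analyze_fra",
]


@dataclass(frozen=True)
class SpontaneousEstimate:
    """Spontaneous firing estimated from the quietest stimulation row."""

    mean: float  # spikes per presentation
    sd: float
    n_bins: int  # number of frequencies contributing

    def criterion(self, sd_multiplier: float = 2.0) -> float:
        return self.mean + sd_multiplier * self.sd


@dataclass(frozen=True)
class FTCFit:
    """A fitted excitatory frequency tuning curve.

    The polynomial is fitted in octave coordinates (re the grid's reference
    frequency) on a centered/scaled abscissa; ``octave_span`` is the range of
    frequencies that contributed thresholds, outside which the curve is not
    evaluated.
    """

    poly: np.polynomial.Polynomial
    degree_used: int
    octave_span: tuple[float, float]
    present: np.ndarray  # boolean per frequency

    def __call__(self, octaves) -> np.ndarray:
        return self.poly(np.asarray(octaves, dtype=float))


@dataclass(frozen=True)
class FTCResult:
    """Summary of one FRA: tuning curve, CF, threshold, area, total spikes."""

    excitatory_thresholds: np.ndarray  # dB attenuation per frequency, NaN = absent
    poly_coeffs: np.ndarray | None  # power-series coefficients, None for fallback
    cf: float  # Hz (NaN if unresponsive)
    threshold: float  # dB attenuation of the FTC's most sensitive point
    area_bins: int
    total_spikes: int
    method: str  # {"polynomial", "fallback"}
    spontaneous: SpontaneousEstimate
    degree_used: int | None = None
    threshold_spl: float | None = None  # calibration - threshold, when available
    area_bins_mask: int | None = None  # diagnostic: raw 2-SD mask bin count


def estimate_spontaneous(fra: ResponseGrid, *, ddof: int = 1) -> SpontaneousEstimate:
    """Mean and SD of spikes per presentation at the quietest level.

    Pools all frequencies and trials of the highest-attenuation row.  The SD
    is the sample estimate (``ddof=1``); a single pooled sample degenerates
    to SD 0.
    """
    if fra.grid.n_levels < 1:
        raise ValidationError("empty grid")
    quiet = fra.counts[:, -1, :].ravel().astype(float)  # levels increase in attenuation
    sd = float(quiet.std(ddof=ddof)) if quiet.size > ddof else 0.0
    return SpontaneousEstimate(mean=float(quiet.mean()), sd=sd, n_bins=fra.grid.n_frequencies)


def excitatory_mask(
    fra: ResponseGrid,
    spont: SpontaneousEstimate,
    *,
    sd_multiplier: float = 2.0,
) -> np.ndarray:
    """Boolean (n_freq, n_levels) grid: mean count strictly above the
    spontaneous mean plus ``sd_multiplier`` standard deviations."""
    return fra.mean_counts() > spont.criterion(sd_multiplier)


def excitatory_thresholds(mask: np.ndarray, grid: StimulusGrid) -> np.ndarray:
    """Per-frequency excitatory threshold: the quietest (largest-attenuation)
    excitatory level; NaN where the frequency has no excitatory bin."""
    mask = np.asarray(mask, dtype=bool)
    out = np.full(grid.n_frequencies, np.nan)
    any_exc = mask.any(axis=1)
    # levels are stored in increasing attenuation: the last True per row wins
    idx = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
    out[any_exc] = grid.levels[idx[any_exc]]
    return out


def fit_ftc(
    octaves: np.ndarray,
    thresholds: np.ndarray,
    degree: int = 10,
) -> FTCFit:
    """Least-squares polynomial through the present excitatory thresholds.

    Fitted in octave coordinates on numpy's centered/scaled domain; the
    degree is clamped to (number of present thresholds - 1) so sparse
    threshold arrays never produce an underdetermined fit.
    """
    octaves = np.asarray(octaves, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    present = np.isfinite(thresholds)
    n = int(present.sum())
    if n < 2:
        raise ValidationError(
            f"only {n} excitatory threshold(s): polynomial FTC undefined, use the fallback"
        )
    deg = int(min(degree, n - 1))
    poly = np.polynomial.Polynomial.fit(octaves[present], thresholds[present], deg)
    span = (float(octaves[present].min()), float(octaves[present].max()))
    return FTCFit(poly=poly, degree_used=deg, octave_span=span, present=present)


def extract_cf_threshold(
    fit: FTCFit,
    reference_frequency: float,
    *,
    points_per_octave: int = 200,
) -> tuple[float, float]:
    """CF (Hz) and threshold (dB attenuation) at the FTC's most sensitive point.

    The most sensitive point is the minimum sound level of the fitted curve,
    i.e. the *maximum* in the attenuation coordinate.  Located by dense
    evaluation over the span of present thresholds followed by bounded local
    refinement; exact ties break toward the lower frequency.
    """
    lo, hi = fit.octave_span
    n = max(int(np.ceil((hi - lo) * points_per_octave)) + 1, 2)
    x = np.linspace(lo, hi, n)
    y = fit(x)
    i = int(np.argmax(y))  # first occurrence = lowest frequency on ties
    a, b = x[max(i - 1, 0)], x[min(i + 1, n - 1)]
    if a < b:
        res = minimize_scalar(lambda t: -fit(t), bounds=(a, b), method="bounded")
        x_star = float(res.x)
        if -res.fun < y[i]:  # refinement must not lose to the dense scan
            x_star = float(x[i])
    else:
        x_star = float(x[i])
    return reference_frequency * 2.0 ** x_star, float(fit(x_star))


def fra_area(fra: ResponseGrid, fit: FTCFit) -> int:
    """Bins contained within the FTC classifier: for each frequency with a
    present threshold, the number of levels at or above (louder than or equal
    to, i.e. attenuation <=) the fitted curve.

    Bins are 5-dB cells, so the fitted curve is snapped to the nearest tested
    level before counting (a bin belongs to the classifier when the curve
    passes within its cell's half-width).  A curve louder than the loudest
    tested level at some frequency classifies no bins there; one quieter than
    the quietest level admits the whole column.
    """
    grid = fra.grid
    octs = grid.octaves()
    ftc = fit(octs[fit.present])
    step = float(np.min(np.diff(grid.levels))) if grid.n_levels > 1 else 1.0
    lo = grid.levels[0]
    snapped = lo + np.round((ftc - lo) / step) * step
    snapped = np.minimum(snapped, grid.levels[-1])
    snapped[ftc < lo] = lo - step  # beyond the loudest tested level: no bins
    return int((grid.levels[None, :] <= snapped[:, None]).sum())


def fra_area_fallback(fra: ResponseGrid, spike_criterion: int = 1) -> int:
    """Bins whose summed spike count across trials strictly exceeds the
    criterion -- the method used when the polynomial FTC is not an accurate
    description of the FRA."""
    if spike_criterion < 0:
        raise ValidationError("spike_criterion must be >= 0")
    return int((fra.counts.sum(axis=2) > spike_criterion).sum())


def total_spikes(fra: ResponseGrid) -> int:
    """Total spikes elicited across every bin and trial of the FRA."""
    return int(fra.counts.sum())



def _main_response_run(thresholds: np.ndarray) -> np.ndarray:
    """Restrict a threshold array to its largest contiguous run of present
    frequencies.

    Isolated excitatory columns disconnected from the main response area are
    almost always criterion false positives under trial noise; fitting a
    high-degree polynomial through them makes the curve oscillate violently
    across the gaps.  Only the fit is restricted; the full threshold array is
    reported unchanged.
    """
    present = np.isfinite(thresholds)
    if not present.any():
        return thresholds
    best_len = run_len = 0
    best_start = run_start = 0
    for i, ok in enumerate(present):
        if ok:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    out = np.full_like(thresholds, np.nan)
    sl = slice(best_start, best_start + best_len)
    out[sl] = thresholds[sl]
    return out


def _robust_fit(
    octaves: np.ndarray,
    thresholds: np.ndarray,
    degree: int,
    *,
    outlier_db: float = 15.0,
) -> FTCFit:
    """Polynomial FTC fit with rejection of gross threshold outliers.

    Single spurious excitatory bins at quiet levels inflate individual
    column thresholds by tens of dB, and a tenth-order least-squares
    polynomial has enough capacity to chase them, so self-residuals cannot
    flag them.  Instead each threshold is compared to the running 5-point
    median of its neighbours: columns sitting more than ``outlier_db``
    (default three grid steps) *quieter* than that local baseline are
    treated as criterion false positives and excluded from the fit.  A
    genuine sharp trough exceeds its local median by at most two grid steps
    for physiological flank slopes, so it is never rejected; the cut is
    one-sided because false positives can only raise a threshold.
    """
    thr = np.asarray(thresholds, dtype=float).copy()
    present = np.flatnonzero(np.isfinite(thr))
    if present.size >= 5:
        vals = thr[present]
        for j in range(vals.size):
            window = vals[max(0, j - 2): j + 3]
            if vals[j] - np.median(window) > outlier_db:
                thr[present[j]] = np.nan
    return fit_ftc(octaves, thr, degree)


def analyze_fra(
    fra: ResponseGrid,
    *,
    sd_multiplier: float = 2.0,
    degree: int = 10,
    use_fallback: bool = False,
    fallback_criterion: int = 1,
) -> FTCResult:
    """Run the full single-FRA chain and return an :class:`FTCResult`.

    ``use_fallback`` forces the spike-criterion area method (the per-unit
    flag for FRAs the polynomial does not describe); the fallback also
    engages automatically when fewer than two frequencies have excitatory
    thresholds.  In the fallback, CF and threshold are read from the raw
    excitatory mask (most sensitive excitatory bin, ties toward the lower
    frequency).
    """
    grid = fra.grid
    spont = estimate_spontaneous(fra)
    mask = excitatory_mask(fra, spont, sd_multiplier=sd_multiplier)
    thresholds = excitatory_thresholds(mask, grid)
    fit_thresholds = _main_response_run(thresholds)
    mask_area = int(mask.sum())
    n_spikes = total_spikes(fra)
    calib = grid.calibration if np.ndim(grid.calibration) == 0 else None

    fit = None
    if not use_fallback:
        try:
            fit = _robust_fit(grid.octaves(), fit_thresholds, degree)
        except ValidationError:
            fit = None

    if fit is not None:
        cf, thr = extract_cf_threshold(fit, grid.reference_frequency)
        return FTCResult(
            excitatory_thresholds=thresholds,
            poly_coeffs=fit.poly.convert().coef,
            cf=cf,
            threshold=thr,
            area_bins=fra_area(fra, fit),
            total_spikes=n_spikes,
            method="polynomial",
            spontaneous=spont,
            degree_used=fit.degree_used,
            threshold_spl=(calib - thr) if calib is not None else None,
            area_bins_mask=mask_area,
        )

    # fallback: raw-mask CF/threshold + spike-criterion area
    if np.isfinite(thresholds).any():
        thr = float(np.nanmax(thresholds))
        cf = float(grid.frequencies[int(np.nanargmax(thresholds))])
    else:
        thr, cf = float("nan"), float("nan")
    return FTCResult(
        excitatory_thresholds=thresholds,
        poly_coeffs=None,
        cf=cf,
        threshold=thr,
        area_bins=fra_area_fallback(fra, fallback_criterion),
        total_spikes=n_spikes,
        method="fallback",
        spontaneous=spont,
        degree_used=None,
        threshold_spl=(calib - thr) if (calib is not None and np.isfinite(thr)) else None,
        area_bins_mask=mask_area,
    )
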