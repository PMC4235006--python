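"""Rate-level function analysis: type classification, half-maximum level,
and ROC-based sound-level discriminability.

A rate-level function (RLF) is the spike count of a unit to CF tones across
sound levels -- a vertical transect of the FRA at CF.  Three quantities drive
the population analyses:

* the **type label**: non-monotonic RLFs are those whose firing drops by 25%
  or more at a level above the best (maximal-firing) level; monotonic RLFs
  subdivide into saturating, straight (linear in dB) and plain monotonic,
  with a flat/unresponsive catch-all.  The non-monotonicity rule is a
  published criterion; the remaining boundaries are named configuration
  constants.
* the **half-maximum level**: after normalizing to the maximum firing rate,
  the sound level at which the function first crosses half of its maximum
  (linear interpolation between tested levels), a supra-threshold
  sensitivity measure.
* the **Discriminability Index (DI)**: for every adjacent pair of levels an
  ROC curve is built from the two trial-count distributions and its area
  (the probability an ideal observer ranks a draw from the louder level
  above one from the quieter, ties counting one half) is computed; the DI is
  the sum of |AUC - 0.5| over pairs.  With nine levels the DI lies in
  [0, 4].  The plain AUC sum is retained as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_io import RateLevelFunction, ValidationError

__all__ = [
    "RLFMetrics",
    "rlf_rates",
    "classify_monotonicity",
    "classify_rlf",
    "half_max_level",
    "roc_auc",
    "discriminability_index",
    "analyze_rlf",
]

#: default classification constants (the five-type taxonomy names the
#: boundaries; only the 25% non-monotonicity rule is a published criterion)
NONMONO_FRACTION = 0.25
PLATEAU_TOL = 0.10  # fraction of max within which a level joins the plateau
R2_STRAIGHT = 0.95  # variance a linear (in dB) fit must explain
FLAT_FLOOR = 1.0  # spikes/trial dynamic range below which an RLF is flat


@dataclass(frozen=True)
class RLFMetrics:
    """Per-condition summary of one rate-level function."""

    type_label: str
    is_nonmonotonic: bool
    max_rate: float  # spikes per trial
    best_level: float  # quietest level attaining the maximum rate
    half_max_level: float  # first 0.5 crossing of the normalized RLF
    pair_aucs: np.ndarray  # adjacent-pair ROC areas, quiet to loud
    di: float  # sum of |AUC - 0.5|
    di_sumauc: float  # diagnostic: plain sum of AUCs
    level_coordinate: str  # "spl" or "attenuation"
    flags: tuple[str, ...] = ()


def rlf_rates(rlf: RateLevelFunction) -> dict[str, np.ndarray]:
    """Per-level mean (authoritative for classification and half-max) plus
    median and IQR (reporting), ordered from quiet to loud."""
    if rlf.n_levels < 2:
        raise ValidationError("an RLF needs at least two levels")
    levels, counts = rlf.quiet_to_loud()
    q25, q50, q75 = np.percentile(counts, [25, 50, 75], axis=1)
    return {
        "levels": levels,
        "mean": counts.mean(axis=1),
        "median": q50,
        "iqr": q75 - q25,
    }


def classify_monotonicity(
    rates: np.ndarray, *, nonmono_fraction: float = NONMONO_FRACTION
) -> bool:
    """True when firing drops by ``nonmono_fraction`` (default 25%) or more
    at some level above the best level.

    ``rates`` are per-level means ordered quiet to loud.  With tied maxima
    the *quietest* tied level is the best level, so louder tied levels still
    count toward the rule.  A silent RLF (max 0) is monotonic by convention.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValidationError("need at least two levels")
    max_rate = rates.max()
    if max_rate <= 0:
        return False
    best = int(np.argmax(rates))  # first occurrence = quietest tied level
    above = rates[best + 1:]
    if above.size == 0:
        return False
    return bool(above.min() / max_rate <= 1.0 - nonmono_fraction)


def classify_rlf(
    rates: np.ndarray,
    levels: np.ndarray | None = None,
    *,
    nonmono_fraction: float = NONMONO_FRACTION,
    plateau_tol: float = PLATEAU_TOL,
    r2_straight: float = R2_STRAIGHT,
    flat_floor: float = FLAT_FLOOR,
) -> str:
    """Rule-based five-type label for a mean-rate curve (quiet to loud).

    Precedence: flat (dynamic range below ``flat_floor``), then
    non-monotonic (the 25% rule), then saturating (>= 2 loudest levels
    within ``plateau_tol`` of the maximum), then straight (linear fit in dB
    explains >= ``r2_straight`` of variance), else monotonic.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size < 3:
        raise ValidationError("need at least three levels to classify")
    if levels is None:
        levels = np.arange(rates.size, dtype=float)
    if rates.max() - rates.min() < flat_floor:
        return "flat"
    if classify_monotonicity(rates, nonmono_fraction=nonmono_fraction):
        return "non-monotonic"
    # trailing plateau: loudest levels within tolerance of the maximum
    near_max = rates >= (1.0 - plateau_tol) * rates.max()
    trailing = 0
    for v in near_max[::-1]:
        if not v:
            break
        trailing += 1
    if trailing >= 2:
        return "saturating"
    coef = np.polyfit(levels, rates, 1)
    resid = rates - np.polyval(coef, levels)
    ss_tot = float(((rates - rates.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r2 >= r2_straight:
        return "straight"
    return "monotonic"


def half_max_level(rates: np.ndarray, levels: np.ndarray) -> float:
    """Sound level at which the max-normalized RLF first reaches one half.

    ``rates`` and ``levels`` run from quiet to loud (any monotone level
    coordinate).  The crossing is linearly interpolated between adjacent
    tested levels; if the quietest level already sits at or above half
    maximum, that level is returned.  Undefined (error) for a silent RLF.
    """
    rates = np.asarray(rates, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if rates.size != levels.size or rates.size < 2:
        raise ValidationError("rates and levels must be equal-length, size >= 2")
    max_rate = rates.max()
    if max_rate <= 0:
        raise ValidationError("half-maximum undefined for a silent RLF")
    norm = rates / max_rate
    if norm[0] >= 0.5:
        return float(levels[0])
    i = int(np.argmax(norm >= 0.5))  # first index at/above half
    frac = (0.5 - norm[i - 1]) / (norm[i] - norm[i - 1])
    return float(levels[i - 1] + frac * (levels[i] - levels[i - 1]))


def roc_auc(counts_lo, counts_hi) -> float:
    """Area under the ROC curve separating two trial-count samples.

    Equals the probability that a random draw from ``counts_hi`` exceeds one
    from ``counts_lo``, ties counting one half -- computed through the
    rank-sum (Mann-Whitney U) identity, exactly equivalent to the all-pairs
    count.
    """
    lo = np.asarray(counts_lo, dtype=float).ravel()
    hi = np.asarray(counts_hi, dtype=float).ravel()
    if lo.size == 0 or hi.size == 0:
        raise ValidationError("roc_auc requires two non-empty samples")
    ranks = rankdata(np.concatenate([lo, hi]))
    u = ranks[lo.size:].sum() - hi.size * (hi.size + 1) / 2.0
    return float(u / (lo.size * hi.size))


def discriminability_index(rlf: RateLevelFunction) -> tuple[np.ndarray, float]:
    """Adjacent-pair ROC areas (quiet to loud) and the DI = sum |AUC - 0.5|."""
    if rlf.n_levels < 2:
        raise ValidationError("an RLF needs at least two levels")
    _, counts = rlf.quiet_to_loud()
    aucs = np.array(
        [roc_auc(counts[i], counts[i + 1]) for i in range(counts.shape[0] - 1)]
    )
    return aucs, float(np.abs(aucs - 0.5).sum())


def analyze_rlf(
    rlf: RateLevelFunction,
    *,
    nonmono_fraction: float = NONMONO_FRACTION,
    plateau_tol: float = PLATEAU_TOL,
    r2_straight: float = R2_STRAIGHT,
    flat_floor: float = FLAT_FLOOR,
) -> RLFMetrics:
    """Full single-RLF summary: type, best level, half-max, pair AUCs, DI."""
    stats = rlf_rates(rlf)
    levels, rates = stats["levels"], stats["mean"]
    flags: list[str] = []
    max_rate = float(rates.max())
    if max_rate <= 0:
        flags.append("silent")
        half = float("nan")
        label = "flat"
        nonmono = False
    else:
        nonmono = classify_monotonicity(rates, nonmono_fraction=nonmono_fraction)
        label = classify_rlf(
            rates, levels,
            nonmono_fraction=nonmono_fraction, plateau_tol=plateau_tol,
            r2_straight=r2_straight, flat_floor=flat_floor,
        )
        half = half_max_level(rates, levels)
    aucs, di = discriminability_index(rlf)
    return RLFMetrics(
        type_label=label,
        is_nonmonotonic=nonmono,
        max_rate=max_rate,
        best_level=float(levels[int(np.argmax(rates))]),
        half_max_level=half,
        pair_aucs=aucs,
        di=di,
        di_sumauc=float(aucs.sum()),
        level_coordinate=rlf.level_coordinate,
        flags=tuple(flags),
    )
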