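"""Change metrics and the nonparametric test battery for paired-condition
deactivation experiments.

Every unit serves as its own control, so the population statistics are built
from paired and matched comparisons:

* a **modulation index** MI = (deactivated - control) / (deactivated +
  control), bounded in [-1, 1], for firing-rate and area changes;
* a 20%-change criterion classifying each unit as increased / decreased /
  unchanged;
* a two-sample Kolmogorov-Smirnov test comparing MI distributions between
  receptive-field classes;
* Friedman's repeated-measures ANOVA on ranks across the three conditions,
  with Sidak-corrected Wilcoxon signed-rank post hocs (exact p by
  enumeration for n <= 25, tie-corrected normal approximation with
  continuity correction above);
* Spearman rank correlation (exact permutation p for n <= 9);
* Fisher's exact test on an r x 2 contingency table by complete enumeration,
  "more extreme" meaning tables whose multivariate-hypergeometric
  probability does not exceed the observed table's -- the standard
  convention for r x c exact tests;
* a percentile-bootstrap confidence interval for medians (for
  median [95% CI] population summaries).

Exact p-values are flagged as such in the returned :class:`StatResult`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .data_io import ValidationError

__all__ = [
    "StatResult",
    "ChangeSummary",
    "modulation_index",
    "classify_change",
    "ks_two_sample",
    "friedman_test",
    "wilcoxon_signed_rank",
    "sidak_alpha",
    "spearman_correlation",
    "fisher_exact_rx2",
    "bootstrap_median_ci",
]


@dataclass(frozen=True)
class StatResult:
    """One statistical test outcome with its provenance flags."""

    method: str
    statistic: float
    p: float
    exact: bool  # exact (enumeration) vs asymptotic p
    df: int | None = None
    n: int | None = None
    alpha_used: float | None = None
    note: str = ""

    @property
    def significant(self) -> bool | None:
        if self.alpha_used is None:
            return None
        return self.p < self.alpha_used


@dataclass(frozen=True)
class ChangeSummary:
    """Condition values and change metrics of one measure for one unit."""

    unit_id: str
    measure: str  # total_spikes / area_bins / half_max_level / di / threshold
    control: float
    deactivated: float | None = None
    recovery: float | None = None
    mi: float | None = None
    change_class: str | None = None  # increase / decrease / none


def modulation_index(control: float, deactivated: float) -> float:
    """MI = (deactivated - control) / (deactivated + control).

    Defined for non-negative inputs not both zero; the both-zero case is
    returned as NaN so callers can exclude it from distributions.
    """
    if control < 0 or deactivated < 0:
        raise ValidationError("modulation index expects non-negative measures")
    denom = control + deactivated
    if denom == 0:
        return float("nan")
    return (deactivated - control) / denom


def classify_change(
    control: float, deactivated: float, criterion: float = 0.20
) -> str:
    """Classify a paired change with a fractional criterion (default 20%).

    The boundary is inclusive: a change of exactly ``criterion`` counts.
    A silent control is a flagged special case: any deactivated spiking is an
    increase.
    """
    if control < 0 or deactivated < 0:
        raise ValidationError("classify_change expects non-negative measures")
    if control == 0:
        return "increase" if deactivated > 0 else "none"
    if deactivated >= control * (1.0 + criterion):
        return "increase"
    if deactivated <= control * (1.0 - criterion):
        return "decrease"
    return "none"


def ks_two_sample(x, y, *, alpha: float | None = None) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test, two-tailed.

    Exact p when the sample-size product permits, otherwise the asymptotic
    distribution (flagged in the result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    exact = x.size * y.size <= 10_000
    note = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sps.ks_2samp(x, y, method="exact" if exact else "asymp")
    if any("Switching to method=asymp" in str(w.message) for w in caught):
        exact = False
        note = "exact unavailable (ties); asymptotic p"
    return StatResult(
        method="ks_two_sample", statistic=float(res.statistic), p=float(res.pvalue),
        exact=exact, n=x.size + y.size, alpha_used=alpha, note=note,
    )


def friedman_test(matrix, *, alpha: float | None = None) -> StatResult:
    """Friedman's repeated-measures ANOVA on ranks (subjects x conditions).

    Within-subject mid-ranks, tie-corrected chi-square statistic with k-1
    degrees of freedom and asymptotic p.  A fully tied matrix (no variation
    anywhere) yields chi-square 0, p 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValidationError("need a 2-D matrix with k >= 3 conditions")
    if np.isnan(m).any():
        raise ValidationError("missing cells are not allowed")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k))
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = 1.0 - tie_term / (n * (k**3 - k))
    chi2 = 0.0 if denom <= 0 else chi2 / denom
    p = float(sps.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return StatResult(
        method="friedman", statistic=float(chi2), p=p, exact=False,
        df=k - 1, n=n, alpha_used=alpha,
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-tailed p of the signed-rank statistic by DP enumeration.

    ``ranks2`` are the doubled mid-ranks (integers); ``w2`` the doubled
    observed positive-rank sum.  Enumerates the 2^n equiprobable sign
    assignments through their generating polynomial.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w2))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(
    x, y=None, *, alpha: float | None = None, exact_max_n: int = 25
) -> StatResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    Zero differences are excluded; tied absolute differences get mid-ranks.
    The two-tailed p is exact (complete enumeration of sign assignments) for
    up to ``exact_max_n`` nonzero differences, and otherwise uses the
    tie-corrected normal approximation with continuity correction.  The
    reported statistic is the signed standardized deviate Z (its sign
    follows deactivated-style ``x - y`` shifts); the positive-rank sum is in
    ``note``.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if y is not None and x.size != np.asarray(y).size:
        raise ValidationError("paired samples must have equal length")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValidationError("all differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var_w > 0:
        delta = w_pos - mean_w
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var_w) if delta != 0 else 0.0
    else:
        z = 0.0
    if n <= exact_max_n:
        p = _signed_rank_exact_p(np.round(2 * ranks).astype(int), 2 * w_pos)
        exact = True
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        exact = False
    return StatResult(
        method="wilcoxon_signed_rank", statistic=float(z), p=min(p, 1.0),
        exact=exact, n=n, alpha_used=alpha, note=f"W+={w_pos}",
    )


def sidak_alpha(alpha_family: float, m: int) -> float:
    """Per-test alpha under the Sidak correction for m tests:
    1 - (1 - alpha_family)^(1/m)."""
    if not 0 < alpha_family < 1:
        raise ValidationError("alpha_family must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 1.0 - (1.0 - alpha_family) ** (1.0 / m)


def spearman_correlation(
    x, y, *, alpha: float | None = None, exact_max_n: int = 9
) -> StatResult:
    """Spearman rank correlation with mid-ranks, two-tailed p.

    Exact permutation p (all n! orderings) for n <= ``exact_max_n``, else the
    t-distribution approximation.  Zero rank variance is undefined and
    flagged via NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length samples with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return StatResult(
            method="spearman", statistic=float("nan"), p=float("nan"),
            exact=False, n=x.size, alpha_used=alpha, note="zero rank variance",
        )
    n = x.size
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        exact = True
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
        exact = False
    return StatResult(
        method="spearman", statistic=rho, p=min(p, 1.0), exact=exact,
        n=n, alpha_used=alpha,
    )


def _log_table_prob(col0: np.ndarray, rows: np.ndarray, c0: int, total: int) -> float:
    """log multivariate-hypergeometric probability of an r x 2 table with
    first column ``col0`` given row margins and first-column margin."""
    logc = gammaln(rows + 1) - gammaln(col0 + 1) - gammaln(rows - col0 + 1)
    log_denom = gammaln(total + 1) - gammaln(c0 + 1) - gammaln(total - c0 + 1)
    return float(logc.sum() - log_denom)


def fisher_exact_rx2(
    table, *, alpha: float | None = None, max_tables: int = 2_000_000
) -> StatResult:
    """Fisher's exact test for an r x 2 contingency table.

    The p-value is the total multivariate-hypergeometric probability, over
    all tables with the observed margins, of tables whose probability does
    not exceed the observed table's (the probability of the observed
    distribution occurring or one more extreme).  Computed by complete
    enumeration with margin pruning; tables beyond ``max_tables`` abort with
    an error suggesting a Monte-Carlo fallback.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValidationError("need an r x 2 table with r >= 2")
    if np.any(t < 0):
        raise ValidationError("table entries must be non-negative")
    rows = t.sum(axis=1)
    if np.any(rows == 0):
        t = t[rows > 0]
        rows = t.sum(axis=1)
        if t.shape[0] < 2:
            return StatResult(
                method="fisher_exact_rx2", statistic=1.0, p=1.0, exact=True,
                n=int(t.sum()), alpha_used=alpha, note="degenerate margins",
            )
    c0 = int(t[:, 0].sum())
    total = int(t.sum())
    if c0 == 0 or c0 == total:
        return StatResult(
            method="fisher_exact_rx2", statistic=1.0, p=1.0, exact=True,
            n=total, alpha_used=alpha, note="one column empty",
        )
    r = t.shape[0]
    rowsf = rows.astype(float)
    obs_logp = _log_table_prob(t[:, 0].astype(float), rowsf, c0, total)
    log_denom = float(gammaln(total + 1) - gammaln(c0 + 1) - gammaln(total - c0 + 1))
    suffix = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])  # capacity after row i

    # per-row log binomial coefficients log C(row_i, a), precomputed
    logc = [
        gammaln(rowsf[i] + 1)
        - gammaln(np.arange(rows[i] + 1) + 1.0)
        - gammaln(rowsf[i] - np.arange(rows[i] + 1) + 1.0)
        for i in range(r)
    ]

    count = 0
    p_sum = 0.0

    def recurse(i: int, remaining: int, log_num: float) -> None:
        nonlocal count, p_sum
        if i == r - 1:
            if remaining > rows[i]:
                return
            count += 1
            if count > max_tables:
                raise ValidationError(
                    "enumeration budget exceeded; use a Monte-Carlo approximation"
                )
            logp = log_num + float(logc[i][remaining]) - log_denom
            if logp <= obs_logp + 1e-9:
                p_sum += float(np.exp(logp))
            return
        lo = max(0, remaining - int(suffix[i]))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, log_num + float(logc[i][a]))

    recurse(0, c0, 0.0)
    p = min(1.0, p_sum)
    return StatResult(
        method="fisher_exact_rx2", statistic=float(np.exp(obs_logp)), p=p,
        exact=True, n=total, alpha_used=alpha,
    )


def bootstrap_median_ci(
    x, level: float = 0.95, n_boot: int = 10_000, seed: int | np.random.Generator = 0
) -> tuple[float, float, float]:
    """Median with a seeded percentile-bootstrap confidence interval."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two observations")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    med = float(np.median(x))
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = np.median(x[idx], axis=1)
    lo, hi = np.percentile(boot, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return med, float(lo), float(hi)
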