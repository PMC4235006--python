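# Methods

`audrf` implements the analysis chain used to quantify how reversibly
silencing one inferior colliculus (IC) changes single-unit responses in the
other: receptive-field extraction from frequency response areas (FRAs),
rate-level function (RLF) classification and half-maximum rescaling, an
ROC-based discriminability index, and a nonparametric population battery in
which every unit serves as its own control across the conditions
{control, deactivated, recovery}. A synthetic-population generator with
analytic ground truth stands in for the (undeposited) recordings and makes
every stage testable.

## Coordinates and units

Sound levels are stored in **dB attenuation** re maximum system output
(larger = quieter), the acquisition coordinate; dB SPL is a derived view,
`SPL = calibration − attenuation`, with a default calibration of 100 dB SPL
(the flat region of the stimulus system). Frequencies are carried both in Hz
and in octaves re the unit's estimated CF; the octave coordinate is used for
grid-spacing checks and the tuning-curve fit. Firing is expressed in spikes
per 75-ms presentation throughout.

## FRA analysis

1. **Spontaneous rate** — mean and sample SD (ddof = 1) of the counts at the
   quietest tested level (90 dB attenuation), pooled over all 51 frequencies
   and all sweeps.
2. **Excitatory mask** — a bin is excitatory when its mean count strictly
   exceeds `mean + 2·SD`. The strict inequality matters in the degenerate
   SD = 0 case: any spiking above the mean counts, and an all-zero quiet row
   never marks the whole grid excitatory.
3. **Thresholds** — per frequency, the quietest excitatory level; absent if
   a column has no excitatory bin.
4. **Tuning curve (FTC)** — a least-squares polynomial of requested degree
   10 through the present thresholds in octave coordinates, on numpy's
   centered/scaled domain (degree-10 fits in raw Hz are hopelessly
   ill-conditioned). The degree is clamped to one less than the number of
   available thresholds. Two robustness rules guard the fit under trial
   noise, both operating on which points enter the fit, never on the
   per-operation contracts:
   - the fit is restricted to the **largest contiguous run** of threshold
     columns — isolated excitatory columns far from the response area are
     almost always criterion false positives, and a degree-10 polynomial
     forced through them oscillates across the gaps;
   - a threshold more than 15 dB (three grid steps) quieter than the running
     5-point median of its neighbours is excluded — a single spurious bin at
     a quiet level inflates one column by tens of dB, and because the
     polynomial has the capacity to chase such a point its own residuals
     cannot flag it. A genuine sharp trough exceeds its local median by at
     most ~two grid steps for physiological flank slopes, so it is never
     rejected; the cut is one-sided because false positives can only raise a
     threshold.
5. **CF and threshold** — the most sensitive point of the fitted curve
   (minimum SPL = maximum attenuation), located by dense evaluation at 200
   points/octave over the span of fitted thresholds followed by bounded
   local refinement; ties break toward the lower frequency.
6. **Area** — the number of grid bins at levels at/above the fitted curve at
   their frequency, restricted to frequencies with present thresholds. Bins
   are 5-dB cells, so the curve is snapped to the nearest tested level
   before counting; without this, a fit residual of ±ε at a threshold lying
   exactly on a grid level drops or adds a whole bin. A curve louder than
   the loudest tested level classifies no bins at that frequency; one
   quieter than the quietest admits the whole column.
7. **Fallback** — for FRAs the polynomial does not describe (a per-unit
   flag, or automatically when fewer than two thresholds exist), the area is
   the count of bins whose summed count strictly exceeds a spike criterion
   (default 1), and CF/threshold are read from the raw mask.

On noiseless generator V units this chain recovers CF within 0.05 octave and
area within 5% of ground truth; under Poisson noise with driven rate ≥ 5×
spontaneous, CF lands within 0.2 octave in ≥ 95% of units.

## RLF analysis

Per-level trial means drive everything (median ± IQR are computed for
reporting only). The level axis runs quiet → loud, in SPL when a calibration
exists.

- **Non-monotonicity** — a drop of 25% or more below the maximum at a level
  above the best level; the boundary is inclusive, and with tied maxima the
  *quietest* tied level is the best level (conservative toward detecting the
  drop).
- **Five-type label** — precedence: *flat* (dynamic range < 1 spike/trial),
  *non-monotonic* (the 25% rule), *saturating* (≥ 2 loudest levels within
  10% of the maximum), *straight* (linear fit in dB with R² ≥ 0.95), else
  *monotonic*. The 25% rule is a published criterion; the other three
  boundary constants name the taxonomy but are package conventions, exposed
  as configuration.
- **Half-maximum level** — after normalizing to the maximum rate, the first
  quiet-to-loud crossing of 0.5, linearly interpolated between tested
  levels; if the quietest level already sits at/above half maximum, that
  level is returned (the measure targets the rising limb; multiple crossings
  occur only for non-monotonic RLFs, where the first crossing is the
  physiologically relevant one). Undefined for a silent RLF.
- **Discriminability Index** — for each adjacent level pair, the ROC area
  computed through the rank-sum identity (probability that a draw from the
  louder level exceeds one from the quieter, ties = ½), then
  `DI = Σ |AUC − 0.5|`; for nine levels DI ∈ [0, 4]. The plain AUC sum is
  kept as a diagnostic variant. Counts are used directly — tone duration is
  constant within an RLF, so any rate normalization is a strictly increasing
  transform and leaves every AUC unchanged.

## Population statistics

- **Modulation index** MI = (deactivated − control)/(deactivated + control),
  in [−1, 1]; undefined (excluded) when both are zero.
- **20% change criterion**, boundary inclusive; a silent control with any
  deactivated spiking counts as an increase.
- **Kolmogorov–Smirnov** (two-sample, two-tailed) on MI distributions of V
  vs nonV units, exact when the size product permits; when ties make the
  exact method unavailable the asymptotic p is used and flagged.
- **Friedman** ANOVA on within-unit ranks across the three conditions, with
  mid-ranks and tie correction; a fully tied matrix returns χ² = 0 (scipy's
  implementation divides by zero there, which is why the statistic is
  computed in-house and cross-checked against scipy elsewhere).
- **Wilcoxon signed-rank** post hocs (deactivated vs control, recovery vs
  control) at a Šidák-corrected per-test alpha
  `1 − (1 − α)^(1/2) = 0.0253`. Zero differences are excluded, tied absolute
  differences get mid-ranks; p is exact by dynamic-programming enumeration
  of all 2ⁿ sign assignments for n ≤ 25 (works with ties, unlike the scipy
  exact path) and a tie-corrected normal approximation with continuity
  correction above.
- **Spearman** rank correlation between half-max change and FRA threshold
  change; exact permutation p for n ≤ 9, t-approximation above.
- **Fisher's exact test** on the r × 2 RLF type-transition table (rows =
  control type, columns = changed/unchanged), by complete enumeration of all
  margin-consistent tables with pruning; "more extreme" means tables whose
  multivariate-hypergeometric probability does not exceed the observed
  table's — the standard convention for r × c exact tests. Empty rows are
  dropped (positive margins are required); an enumeration budget guards
  pathological margins.
- **Median confidence intervals** — seeded percentile bootstrap (default
  10,000 resamples). The CI method behind published median CIs of this kind
  is rarely stated; the bootstrap is this package's declared convention.

## Synthetic populations

FRA archetypes are threshold contours in octave-vs-attenuation space: a
V-shaped pair of linear flanks meeting at (CF, minimum threshold), deformed
per class — *low-tilt* (a linear skew added to the contour), *narrow* (a
bandwidth cap), *closed* (an upper-level bound on excitation), *broad*
(shallow flanks). Inside the region a unit fires at its driven rate
(3–6 spikes/presentation), outside at its spontaneous rate (0.05–0.4);
trials are independent Poisson draws, 5 sweeps per tone by default (~14 min
of recording per FRA at 5 presentations/s, compatible with deactivations
shorter than 30 min; with fewer sweeps the 2-SD criterion's false positives
overwhelm the threshold array, which is visibly not the regime the method
was used in). Deactivation multiplies driven/spontaneous rates, shifts the
trough, and — for nonV units only — scales the frequency extent of the
region (V-unit areas are invariant in ground truth, matching the class
distinction the analysis is meant to detect). Recovery re-samples the
control archetype with fresh noise, a clean null for recovery-vs-control
tests.

RLF archetypes cover the five types. The sigmoid-drive types (saturating,
monotonic, non-monotonic) fire at
`rate = spont + g·max·[gD/(1+gD)]` with drive `D = exp((L − midpoint)/width)`:
a deactivation gain g < 1 both scales the attainable output down and shifts
the operating point toward louder sounds (equivalently, midpoint shifts by
`width·ln(1/g)`), reproducing the two empirical signatures of commissural
deactivation — a rightward half-max shift and a DI decline — from a single
multiplicative parameter. A pure output gain would leave the max-normalized
half-max exactly invariant, which is why the drive formulation is used.
Straight and flat types scale linearly (their normalized shape is
gain-invariant, so only some RLF types change shape under deactivation).
Non-monotonic archetypes add a high-level suppression term that is zero at
the best level and approaches the full reduction fraction asymptotically;
the deactivation `nonmono_relief` factor shrinks it, letting non-monotonic
units become monotonic or straight. Archetype parameter ranges are chosen so
that every noiseless curve classifies as its intended label (the sampler
rejects the rare boundary draw), making the ground-truth ledger exact. The
default sampled deactivation effect combines a heterogeneous gain
(log-normal, median 0.65) with a systematic rightward level rescaling
(threshold shift ~ N(+5 dB, 3 dB)) — the supra-threshold gain-control
pattern seen in the recordings. RLFs use 50 trials per level (of the two
conventional repetition counts, 20 and 50).

Default population sizes mirror the recorded samples: 49 V and 50 nonV FRA
units, 38 RLF units of which 16 also carry FRA triplets (the subset entering
the half-max-vs-threshold correlation).

What the generator does *not* emulate: overdispersed or correlated spike
counts (Poisson only; an extension point), spike timing, adaptation or
drift across a session, intermediate/continuum receptive-field shapes,
frequency-dependent calibration, and incomplete recovery. Passing tests
therefore show that the chain recovers the effects the generator encodes
under Poisson variability — not that real recordings are this well-behaved.
Generator DI values (control medians near 1.0) are conservative relative to
strongly level-coding midbrain units.

## Calibration and numerical conventions

- Type-I error: over ≥ 400 zero-effect populations, Friedman, Wilcoxon,
  Spearman and the KS on firing-rate MI reject at α = 0.05 within the
  two-sided binomial 99% band. Two battery members are conservative by
  construction and are held to the one-sided bound instead: the exact KS on
  *area* MI (under the null most units reproduce their integer area exactly,
  so both MI distributions carry a large atom at zero), and Fisher's exact
  test (discrete exact tests reject below nominal; moreover its homogeneity
  null concerns type-wise change rates, and noise-driven type flips are
  inherently type-dependent, so Fisher's calibration is checked on
  margin-matched tables with iid change flags).
- Degenerate inputs: all-tied Friedman matrices → χ² = 0; all-zero
  differences → Wilcoxon undefined (error); silent RLFs → half-max undefined
  (error), DI still computed; zero rank variance → Spearman flagged NaN;
  both-zero MI → NaN, excluded from distributions.
- Determinism: every stochastic component takes a seed (or numpy Generator);
  populations are pure functions of their configuration, and `run_repro`
  writes byte-identical tables for identical configurations, with a config
  hash and seed in the provenance block.
- Problem sizes in the test suite (noise studies of 50–400 replicates,
  calibration populations of 15+15+15 units) are chosen as the smallest
  sizes at which the binomial assertions have reasonable resolving power.
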