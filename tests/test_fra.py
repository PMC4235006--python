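"""FRA chain: spontaneous rate, excitatory mask, thresholds, FTC, CF, area."""

import numpy as np
import pytest

import audrf
from audrf import (
    StimulusGrid,
    ResponseGrid,
    ValidationError,
    analyze_fra,
    estimate_spontaneous,
    excitatory_mask,
    excitatory_thresholds,
    extract_cf_threshold,
    fit_ftc,
    fra_area,
    fra_area_fallback,
    fra_grid,
    noiseless_grid,
    region_mask,
    total_spikes,
)
from audrf.fra import FTCFit, SpontaneousEstimate
from audrf.synth import _sample_fra_archetype


def grid_with_quiet_row(quiet_counts):
    """4-frequency x 2-level grid whose quietest row holds the given counts."""
    quiet_counts = np.asarray(quiet_counts)
    grid = StimulusGrid([1, 2, 4, 8], [10.0, 90.0])
    counts = np.zeros((4, 2, 1), dtype=int)
    counts[:, 1, 0] = quiet_counts  # level 90 dB attenuation = quietest
    return ResponseGrid(grid, counts)


class TestEstimateSpontaneous:
    @pytest.mark.parametrize(
        "quiet, mean, sd",
        [
            ([0, 0, 0, 0], 0.0, 0.0),
            ([2, 2, 2, 2], 2.0, 0.0),
            # hand summation: mean 3, sum of squared deviations 14, ddof=1
            ([1, 2, 3, 6], 3.0, np.sqrt(14 / 3)),
        ],
    )
    def test_examples(self, quiet, mean, sd):
        est = estimate_spontaneous(grid_with_quiet_row(quiet))
        assert est.mean == pytest.approx(mean)
        assert est.sd == pytest.approx(sd)
        assert est.n_bins == 4

    def test_pools_trials(self):
        grid = StimulusGrid([1, 2], [10.0, 90.0])
        counts = np.zeros((2, 2, 2), dtype=int)
        counts[:, 1, :] = [[1, 2], [3, 6]]
        est = estimate_spontaneous(ResponseGrid(grid, counts))
        assert est.mean == pytest.approx(3.0)


class TestExcitatoryMask:
    def test_zero_spont_any_spike_is_excitatory(self, tiny_grid):
        spont = SpontaneousEstimate(0.0, 0.0, 2)
        mask = excitatory_mask(tiny_grid, spont)
        assert np.array_equal(mask, tiny_grid.mean_counts() > 0)

    def test_strict_inequality_at_criterion(self):
        grid = StimulusGrid([1, 2], [10.0, 20.0])
        counts = np.array([[[4, 4], [4, 5]], [[0, 0], [0, 0]]])  # means 4, 4.5
        rg = ResponseGrid(grid, counts)
        mask = excitatory_mask(rg, SpontaneousEstimate(2.0, 1.0, 2))
        assert not mask[0, 0]  # mean 4 == criterion, strict > excludes it
        assert mask[0, 1]  # mean 4.5 exceeds

    def test_noiseless_v_mask_matches_generative_region(self, v_unit):
        arch, grid, rg = v_unit
        spont = estimate_spontaneous(rg)
        mask = excitatory_mask(rg, spont)
        assert np.array_equal(mask, region_mask(arch, grid))

    def test_monotone_in_criterion(self):
        rng = np.random.default_rng(0)
        grid = fra_grid(2000.0)
        rg = ResponseGrid(grid, rng.poisson(1.0, (51, 17, 2)))
        spont = estimate_spontaneous(rg)
        sizes = [
            excitatory_mask(rg, spont, sd_multiplier=m).sum() for m in (0.5, 1, 2, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestExcitatoryThresholds:
    def test_quietest_excitatory_level_wins(self):
        grid = StimulusGrid([1000.0], [10.0, 20.0, 30.0, 40.0])
        mask = np.array([[True, True, True, False]])  # excitatory at 10, 20, 30
        thr = excitatory_thresholds(mask, grid)
        assert thr[0] == 30.0

    def test_all_false_column_is_absent(self):
        grid = StimulusGrid([1000.0, 2000.0], [10.0, 20.0])
        thr = excitatory_thresholds(np.array([[False, False], [True, False]]), grid)
        assert np.isnan(thr[0]) and thr[1] == 10.0

    def test_noiseless_v_traces_contour_within_one_step(self, v_unit):
        arch, grid, rg = v_unit
        mask = excitatory_mask(rg, estimate_spontaneous(rg))
        thr = excitatory_thresholds(mask, grid)
        contour = audrf.synth.threshold_contour(arch, grid.octaves())
        present = np.isfinite(thr) & (contour >= grid.levels[0])
        assert np.all(np.abs(thr[present] - contour[present]) <= 5.0)


class TestFitFTC:
    def test_line_is_reproduced_exactly(self):
        x = np.linspace(-1, 1, 21)
        y = 50.0 - 10.0 * x
        fit = fit_ftc(x, y, degree=10)
        assert np.allclose(fit(x), y, atol=1e-8)

    def test_degree_clamped_to_n_minus_one(self):
        x = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        y = np.array([50.0, 60.0, 70.0, 60.0, 50.0])
        fit = fit_ftc(x, y, degree=10)
        assert fit.degree_used == 4

    def test_too_few_points_directs_to_fallback(self):
        with pytest.raises(ValidationError, match="fallback"):
            fit_ftc(np.array([0.0, 0.1]), np.array([50.0, np.nan]), 10)

    def test_symmetric_v_minimum_at_center(self):
        x = np.round(np.arange(-10, 11) / 10, 10)
        y = 70.0 - 60.0 * np.abs(x)  # attenuation trough at x = 0
        fit = fit_ftc(x, y, degree=10)
        cf, thr = extract_cf_threshold(fit, reference_frequency=4000.0)
        assert abs(np.log2(cf / 4000.0)) < 0.05  # within half a 0.1-oct step
        assert thr == pytest.approx(70.0, abs=6.0)


class TestExtractCF:
    def test_threshold_rising_with_frequency_puts_cf_at_low_edge(self):
        # attenuation falls with octave = SPL threshold rises: most sensitive
        # point is the lowest frequency of the span
        x = np.linspace(-1, 1, 21)
        fit = fit_ftc(x, 50.0 - 20.0 * x, degree=1)
        cf, _ = extract_cf_threshold(fit, reference_frequency=1000.0)
        assert cf == pytest.approx(1000.0 * 2.0 ** -1.0, rel=1e-3)

    def test_parabolic_trough_vertex_recovered(self):
        x = np.linspace(-1, 1, 41)
        y = 70.0 - 40.0 * (x - 0.25) ** 2  # most sensitive at +0.25 octaves
        fit = fit_ftc(x, y, degree=2)
        cf, thr = extract_cf_threshold(fit, reference_frequency=4000.0)
        assert np.log2(cf / 4000.0) == pytest.approx(0.25, abs=1e-3)
        assert thr == pytest.approx(70.0, abs=1e-6)

    def test_noiseless_v_cf_within_half_step(self, v_unit):
        arch, grid, rg = v_unit
        res = analyze_fra(rg)
        assert abs(np.log2(res.cf / arch.cf)) < 0.05


class TestFRAArea:
    def _const_fit(self, grid, value):
        poly = np.polynomial.Polynomial([value])
        return FTCFit(poly=poly, degree_used=0, octave_span=(-3.0, 2.0),
                      present=np.ones(grid.n_frequencies, dtype=bool))

    def test_ftc_below_quietest_level_counts_whole_grid(self):
        grid = fra_grid(2000.0)
        rg = ResponseGrid(grid, np.zeros((51, 17, 1), dtype=int))
        assert fra_area(rg, self._const_fit(grid, 95.0)) == 867

    def test_ftc_above_loudest_level_counts_nothing(self):
        grid = fra_grid(2000.0)
        rg = ResponseGrid(grid, np.zeros((51, 17, 1), dtype=int))
        assert fra_area(rg, self._const_fit(grid, 7.0)) == 0

    def test_noiseless_v_area_within_5pct_of_ledger(self, v_unit):
        arch, grid, rg = v_unit
        res = analyze_fra(rg)
        truth = int(region_mask(arch, grid).sum())
        assert abs(res.area_bins - truth) / truth <= 0.05

    def test_fallback_examples(self, tiny_grid):
        grid = fra_grid(2000.0)
        zero = ResponseGrid(grid, np.zeros((51, 17, 1), dtype=int))
        assert fra_area_fallback(zero, 1) == 0
        assert fra_area_fallback(tiny_grid, 1) == 2  # bins holding 2 and 3

    def test_fallback_agrees_with_ftc_area_on_clean_v(self, v_unit):
        arch, grid, rg = v_unit
        res = analyze_fra(rg)
        fb = fra_area_fallback(rg, 1)
        assert abs(fb - res.area_bins) / res.area_bins <= 0.10


class TestTotalSpikes:
    def test_examples(self, tiny_grid):
        grid = fra_grid(2000.0)
        assert total_spikes(ResponseGrid(grid, np.zeros((51, 17, 1), dtype=int))) == 0
        assert total_spikes(tiny_grid) == 6

    def test_poisson_total_within_clt_bound(self):
        grid = fra_grid(2000.0)
        expected = np.full((51, 17), 2.0)
        rg = audrf.sample_trials(expected, grid, 3, seed=5)
        t_exp = expected.sum() * 3
        assert abs(total_spikes(rg) - t_exp) < 3 * np.sqrt(t_exp)


class TestAnalyzeFRA:
    def test_bounds_invariants(self, v_unit):
        _, grid, rg = v_unit
        res = analyze_fra(rg)
        assert 0 <= res.area_bins <= grid.n_frequencies * grid.n_levels
        assert res.total_spikes >= 0
        assert grid.frequencies[0] <= res.cf <= grid.frequencies[-1]

    def test_forced_fallback_method(self, v_unit):
        _, _, rg = v_unit
        res = analyze_fra(rg, use_fallback=True)
        assert res.method == "fallback" and res.poly_coeffs is None
        assert res.area_bins == fra_area_fallback(rg, 1)

    def test_unresponsive_grid_falls_back(self):
        grid = fra_grid(2000.0)
        rg = ResponseGrid(grid, np.zeros((51, 17, 1), dtype=int))
        res = analyze_fra(rg)
        assert res.method == "fallback" and np.isnan(res.cf)

    def test_noisy_cf_recovery_rate(self):
        """Poisson-noised V units (driven >= 5x spont): CF within 0.2 octave
        in at least 95 of 100 seeded units."""
        ok = 0
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            arch = _sample_fra_archetype(rng, "V")
            grid = fra_grid(arch.cf)
            rg = audrf.sample_trials(
                audrf.expected_rate_surface(arch, grid), grid, 5, rng
            )
            res = analyze_fra(rg)
            ok += abs(np.log2(res.cf / arch.cf)) <= 0.2
        assert ok >= 95
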