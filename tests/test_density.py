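"""KDE, bandwidth, mode detection, post-processing and summary stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpnmodes import (
    DensityEstimate,
    Mode,
    bandwidth_scott,
    classify_modes,
    detect_modes,
    estimate_density,
    find_modes,
    assign_masses,
    postprocess_modes,
    summary_stats,
)
from cpnmodes.density import STATS_COLUMNS


class TestBandwidth:
    def test_hand_example(self):
        # sd = 3.7417, IQR/1.34 = 3.7313, 1.06 * 3.7313 * 6^(-1/5)
        h = bandwidth_scott(np.array([0.0, 2, 4, 6, 8, 10]))
        assert h == pytest.approx(2.764, abs=1e-3)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            bandwidth_scott(np.array([1.0]))

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            bandwidth_scott(np.full(50, 3.0))

    @pytest.mark.parametrize("c", [0.1, 2.0, 17.5])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert bandwidth_scott(c * x) == pytest.approx(
            c * bandwidth_scott(x), rel=1e-12
        )


class TestEstimateDensity:
    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.7, 0.1, 100)
        de = estimate_density(x)
        brute = np.zeros_like(de.grid)
        for xi in x:
            z = (de.grid - xi) / de.h
            brute += np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        brute /= x.size * de.h
        np.testing.assert_allclose(de.density, brute, rtol=1e-12)

    def test_integral_close_to_one(self, unimodal_values):
        de = estimate_density(unimodal_values)
        assert de.integral() == pytest.approx(1.0, abs=1e-3)

    def test_grid_spans_data_plus_three_bandwidths(self, unimodal_values):
        de = estimate_density(unimodal_values)
        assert de.grid[0] <= unimodal_values.min() - 3 * de.h
        assert de.grid[-1] >= unimodal_values.max() + 3 * de.h

    def test_single_point_peak_height(self):
        de = estimate_density(np.array([0.7]), h=0.05)
        peak = de.density.max()
        # the true peak may fall between grid points; half a grid step off
        assert peak == pytest.approx(1 / (0.05 * np.sqrt(2 * np.pi)), rel=1e-4)
        assert de.grid[np.argmax(de.density)] == pytest.approx(0.7, abs=1e-3)

    def test_kde_consistency_at_the_mean(self):
        rng = np.random.default_rng(2)
        de = estimate_density(rng.normal(0.7, 0.05, 5000))
        assert de.grid[np.argmax(de.density)] == pytest.approx(0.7, abs=0.02)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([]))


class TestFindModes:
    def test_single_bump(self, unimodal_values):
        de = estimate_density(unimodal_values)
        maxima, minima = find_modes(de)
        assert maxima.size == 1
        assert minima.size == 0

    def test_two_bumps(self, bimodal_values):
        de = estimate_density(bimodal_values)
        maxima, minima = find_modes(de)
        assert maxima.size == 2
        assert minima.size == 1
        pos = np.sort(de.grid[maxima])
        assert pos[0] == pytest.approx(0.45, abs=0.05)
        assert pos[1] == pytest.approx(0.95, abs=0.05)
        assert de.grid[minima[0]] == pytest.approx(0.7, abs=0.1)

    def test_monotone_density_has_no_interior_extrema(self):
        grid = np.linspace(0, 1, 128)
        de = DensityEstimate(h=0.1, grid=grid, density=np.exp(grid), n=10)
        maxima, minima = find_modes(de)
        assert maxima.size == 0 and minima.size == 0

    def test_plateau_collapses_to_midpoint(self):
        grid = np.linspace(0, 1, 101)
        dens = np.concatenate(
            [np.linspace(0, 1, 40), np.full(21, 1.0), np.linspace(1, 0, 40)]
        )
        de = DensityEstimate(h=0.1, grid=grid, density=dens, n=10)
        maxima, minima = find_modes(de)
        assert maxima.size == 1
        assert abs(int(maxima[0]) - 50) <= 1


class TestAssignMasses:
    def test_single_mode_mass_one(self, unimodal_values):
        de = estimate_density(unimodal_values)
        modes = assign_masses(de, *find_modes(de))
        assert len(modes) == 1
        assert modes[0].mass == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_mixture_splits_evenly(self, bimodal_values):
        de = estimate_density(bimodal_values)
        modes = assign_masses(de, *find_modes(de))
        masses = sorted(m.mass for m in modes)
        assert masses[0] == pytest.approx(0.5, abs=0.05)
        assert sum(m.mass for m in modes) == pytest.approx(1.0, abs=1e-6)

    def test_unbalanced_mixture_masses(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(0.4, 0.05, 3600), rng.normal(1.0, 0.05, 400)]
        )
        de = estimate_density(x)
        modes = assign_masses(de, *find_modes(de))
        masses = sorted(m.mass for m in modes)
        assert masses[-1] == pytest.approx(0.9, abs=0.05)
        assert masses[0] == pytest.approx(0.1, abs=0.05)

    def test_mass_equals_integral_between_bounds(self, bimodal_values):
        de = estimate_density(bimodal_values)
        modes = assign_masses(de, *find_modes(de))
        total = de.integral()
        for m in modes:
            sel = (de.grid >= m.left_bound) & (de.grid <= m.right_bound)
            integral = np.trapezoid(de.density[sel], de.grid[sel]) / total
            assert m.mass == pytest.approx(integral, abs=1e-6)


def _mode(pos, mass, height=1.0):
    return Mode(
        position=pos, mass=mass, left_bound=pos - 0.1,
        right_bound=pos + 0.1, height=height,
    )


class TestPostprocess:
    def test_close_modes_merge(self):
        ms = postprocess_modes([_mode(0.55, 0.5, 2.0), _mode(0.65, 0.5, 1.0)])
        assert len(ms.modes) == 1
        assert ms.modes[0].position == 0.55  # higher-density member wins
        assert ms.modes[0].mass == pytest.approx(1.0)
        assert "close" in ms.modes[0].flags
        assert ms.n_close_merged == 1

    def test_weak_mode_pruned_with_mass_reassigned(self):
        ms = postprocess_modes([_mode(0.4, 0.995), _mode(0.9, 0.005)])
        assert len(ms.modes) == 1
        assert ms.modes[0].position == 0.4
        assert ms.modes[0].mass == pytest.approx(1.0)

    def test_both_rules_inert(self):
        ms = postprocess_modes([_mode(0.4, 0.6), _mode(0.9, 0.4)])
        assert [m.position for m in ms.modes] == [0.4, 0.9]
        assert ms.n_close_merged == 0

    def test_chain_merge_nearest_pair_first(self):
        ms = postprocess_modes(
            [_mode(0.4, 0.3, 3.0), _mode(0.55, 0.3, 1.0), _mode(0.62, 0.4, 2.0)]
        )
        # 0.55/0.62 merge first (gap 0.07), survivor 0.62; then 0.4/0.62 stay
        assert [m.position for m in ms.modes] == [0.4, 0.62]
        assert ms.modes[1].mass == pytest.approx(0.7)

    def test_consecutive_modes_separated_after_merge(self):
        rng = np.random.default_rng(13)
        positions = np.sort(rng.uniform(0, 1, 8))
        modes = [_mode(p, 1 / 8, rng.uniform(0.5, 2)) for p in positions]
        ms = postprocess_modes(modes)
        gaps = np.diff([m.position for m in ms.modes])
        assert np.all(gaps >= 0.2)
        assert sum(m.mass for m in ms.modes) == pytest.approx(1.0, abs=1e-9)

    def test_weak_flag_below_ten_percent(self):
        ms = postprocess_modes([_mode(0.4, 0.95), _mode(0.9, 0.05)])
        assert "weak" in ms.modes[1].flags
        assert "weak" not in ms.modes[0].flags

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            postprocess_modes([])


class TestClassify:
    def test_threshold(self, unimodal_values):
        ms = detect_modes(unimodal_values)
        labels = classify_modes(ms)
        assert labels == ["non-methylated"]

    @pytest.mark.parametrize(
        "pos,label",
        [(0.47, "methylated"), (0.75, "non-methylated"), (1.0, "non-methylated")],
    )
    def test_boundary(self, pos, label):
        from cpnmodes import ModeSet

        ms = ModeSet(modes=[_mode(pos, 1.0)], n_raw_modes=1)
        assert classify_modes(ms) == [label]


class TestPipelineProperties:
    def test_shift_equivariance(self, bimodal_values):
        c = 3.7
        ms0 = detect_modes(bimodal_values)
        ms1 = detect_modes(bimodal_values + c)
        np.testing.assert_allclose(
            ms1.positions, ms0.positions + c, atol=1e-9
        )
        np.testing.assert_allclose(ms1.masses, ms0.masses, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bimodal_recovery(self, seed):
        rng = np.random.default_rng(seed)
        centers = (0.5, 1.0)
        x = np.concatenate(
            [rng.normal(c, 0.06, 2000) for c in centers]
        )
        ms = detect_modes(x)
        assert len(ms.modes) == 2
        for m, c in zip(ms.modes, centers):
            assert m.position == pytest.approx(c, abs=0.05)

    @pytest.mark.parametrize("seed,sd", [(3, 0.05), (4, 0.15)])
    def test_unimodal_recovery(self, seed, sd):
        rng = np.random.default_rng(seed)
        ms = detect_modes(rng.normal(0.8, sd, 4000))
        assert len(ms.modes) == 1

    def test_mass_conservation_through_pipeline(self, skewed_mixture_values):
        de = estimate_density(skewed_mixture_values)
        raw = assign_masses(de, *find_modes(de))
        assert sum(m.mass for m in raw) == pytest.approx(1.0, abs=1e-6)
        ms = postprocess_modes(raw, min_mass=0.2)  # force pruning
        assert sum(m.mass for m in ms.modes) == pytest.approx(1.0, abs=1e-6)


class TestSummaryStats:
    def test_symmetric_sample(self):
        values = np.array([1.0, 2, 3, 4, 5])
        ms = detect_modes(values)
        row = summary_stats(values, ms, "sym")
        assert row["Nonparametric skew"] == pytest.approx(0.0, abs=1e-12)
        assert row["Q50 skewness"] == pytest.approx(0.0, abs=1e-12)
        assert row["Name"] == "sym"

    def test_sd_matches_two_pass_formula(self, unimodal_values):
        ms = detect_modes(unimodal_values)
        row = summary_stats(unimodal_values, ms)
        mu = unimodal_values.mean()
        sd = np.sqrt(
            ((unimodal_values - mu) ** 2).sum() / (unimodal_values.size - 1)
        )
        assert row["SD"] == pytest.approx(sd, rel=1e-12)
        assert row["Total number of sequences"] == unimodal_values.size

    def test_minor_mode_counting_thresholds(self, skewed_mixture_values):
        ms = detect_modes(skewed_mixture_values)
        row = summary_stats(skewed_mixture_values, ms)
        assert row["Number of modes"] == 2
        assert row["Number of modes (5% excluded)"] == 2
        assert row["Number of modes (10% excluded)"] == 1
        assert row["Peak 2"] == pytest.approx(1.1, abs=0.05)
        assert row["Probability Mass 2"] == pytest.approx(0.08, abs=0.05)
        assert row["Peak 3"] is None

    def test_column_order_is_exact(self, unimodal_values):
        ms = detect_modes(unimodal_values)
        row = summary_stats(unimodal_values, ms)
        assert tuple(row.keys()) == STATS_COLUMNS

    def test_robust_spreads(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0.8, 0.1, 2000)
        row = summary_stats(x, detect_modes(x))
        q = lambda p: np.quantile(x, p)
        assert row["IQR 80"] == pytest.approx(q(0.9) - q(0.1))
        assert row["IQR 90"] == pytest.approx(q(0.95) - q(0.05))
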