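"""The spectral decomposition: beta grid, IRF basis, NNLS fits, S_v, bands."""

import numpy as np
import pytest
from scipy.integrate import quad

from protonrange import (
    NUCLIDES,
    FrameSchedule,
    build_irf_basis,
    default_bands,
    fit_voxel,
    make_beta_grid,
    sv_statistic,
    threshold_mask,
)
from protonrange.spectral import NuclideBands, _frame_averaged_irf

LN2 = np.log(2.0)


def mono_tac(schedule, beta, amplitude=1.0):
    """Frame counts of a single impulse-produced exponential component."""
    return amplitude * (np.exp(-beta * schedule.start_s)
                        - np.exp(-beta * schedule.end_s)) / beta


class TestBetaGrid:
    def test_default_grid_endpoints_and_size(self, beta_grid):
        assert len(beta_grid) == 1000
        assert beta_grid.values[0] == 1e-4
        assert beta_grid.values[-1] == 0.1

    def test_two_point_grid(self):
        g = make_beta_grid(1e-3, 1e-2, 2)
        np.testing.assert_array_equal(g.values, [1e-3, 1e-2])

    def test_constant_ratio(self, beta_grid):
        r = beta_grid.values[1:] / beta_grid.values[:-1]
        np.testing.assert_allclose(r, r[0], rtol=1e-12)

    @pytest.mark.parametrize("lo,hi,m", [(0.0, 0.1, 10), (0.1, 0.01, 10),
                                         (1e-4, 0.1, 1)])
    def test_invalid_parameters_rejected(self, lo, hi, m):
        with pytest.raises(ValueError):
            make_beta_grid(lo, hi, m)


class TestIRFBasis:
    def test_slow_decay_limit_is_one(self):
        t1, t2 = np.array([0.0]), np.array([60.0])
        assert _frame_averaged_irf(t1, t2, 1e-12)[0] == pytest.approx(1.0)

    def test_entry_matches_quadrature(self):
        beta = 1e-3
        oracle, _ = quad(lambda t: np.exp(-beta * t), 0.0, 60.0)
        val = _frame_averaged_irf(np.array([0.0]), np.array([60.0]), beta)[0]
        assert val == pytest.approx(oracle / 60.0, rel=1e-10)

    def test_entries_in_unit_interval_and_columns_decreasing(self, basis75):
        m = basis75.matrix
        assert np.all(m > 0) and np.all(m <= 1.0)
        assert np.all(np.diff(m, axis=0) < 0)

    def test_basis_referenced_to_schedule_start(self, beta_grid):
        """A late acquisition window uses window-relative times, so its
        first-frame IRF equals that of a window starting at zero."""
        late = build_irf_basis(FrameSchedule.uniform(10, 60.0, t0_s=900.0),
                               beta_grid)
        early = build_irf_basis(FrameSchedule.uniform(10, 60.0), beta_grid)
        np.testing.assert_allclose(late.matrix, early.matrix, rtol=1e-12)


class TestFitVoxel:
    def test_all_zero_tac_gives_zero_fit(self, basis75):
        fit = fit_voxel(np.zeros(75), basis75)
        assert np.all(fit.alpha == 0) and fit.residual == 0.0

    def test_length_mismatch_rejected(self, basis75):
        with pytest.raises(ValueError, match="length"):
            fit_voxel(np.ones(10), basis75)

    def test_negative_counts_rejected(self, basis75):
        tac = np.ones(75)
        tac[3] = -1
        with pytest.raises(ValueError):
            fit_voxel(tac, basis75)

    @pytest.mark.parametrize("name", ["C11", "N13", "O15"])
    def test_mono_exponential_recovery_within_one_grid_step(
            self, schedule75, basis75, name):
        """A noiseless single-nuclide TAC is recovered with its
        amplitude-weighted beta within one grid step of the truth."""
        beta = NUCLIDES[name].decay_constant_s
        fit = fit_voxel(mono_tac(schedule75, beta), basis75)
        step = basis75.grid.values[1] / basis75.grid.values[0]
        recovered = fit.weighted_beta(basis75.grid.values[0],
                                      basis75.grid.values[-1] * 1.001)
        assert beta / step <= recovered <= beta * step

    def test_residual_beats_single_component_brute_force(self, schedule75,
                                                         basis75):
        """NNLS over the full grid can never do worse than the best
        single-exponential fit found by exhaustive search."""
        tac = (mono_tac(schedule75, NUCLIDES["C11"].decay_constant_s, 2.0)
               + mono_tac(schedule75, NUCLIDES["O15"].decay_constant_s, 0.7))
        fit = fit_voxel(tac, basis75)
        best = np.inf
        for col in basis75.matrix.T:
            a = max(0.0, float(tac @ col) / float(col @ col))
            best = min(best, float(np.linalg.norm(tac - a * col)))
        assert fit.residual <= best + 1e-12
        assert fit.residual <= np.linalg.norm(tac)

    def test_fit_scales_linearly(self, schedule75, basis75):
        tac = mono_tac(schedule75, 1.3e-3)
        a1 = fit_voxel(tac, basis75).alpha
        a5 = fit_voxel(5.0 * tac, basis75).alpha
        np.testing.assert_allclose(a5, 5.0 * a1, rtol=1e-6,
                                   atol=1e-9 * a1.max())


class TestSvStatistic:
    def test_zero_alpha_zero_sv(self, basis75):
        assert sv_statistic(fit_voxel(np.zeros(75), basis75)) == 0.0

    def test_single_term(self, beta_grid, basis75):
        from protonrange.spectral import SpectralFit

        alpha = np.zeros(len(beta_grid))
        alpha[500] = 2.5
        fit = SpectralFit(alpha, 0.0, beta_grid)
        assert sv_statistic(fit) == pytest.approx(2.5 * beta_grid.values[500])

    def test_short_half_life_enhanced(self, schedule75, basis75):
        """Equal-amplitude voxels rank S_v(15O) > S_v(13N) > S_v(11C):
        the statistic up-weights fast decay."""
        sv = {name: sv_statistic(fit_voxel(
            mono_tac(schedule75, NUCLIDES[name].decay_constant_s), basis75))
            for name in NUCLIDES}
        assert sv["O15"] > sv["N13"] > sv["C11"]

    def test_sv_linearity_over_combined_fits(self, schedule75, basis75):
        ta = mono_tac(schedule75, 5e-4)
        tb = mono_tac(schedule75, 4e-3)
        sv_parts = (sv_statistic(fit_voxel(ta, basis75))
                    + sv_statistic(fit_voxel(tb, basis75)))
        from protonrange.spectral import SpectralFit

        combined = SpectralFit(fit_voxel(ta, basis75).alpha
                               + fit_voxel(tb, basis75).alpha, 0.0,
                               basis75.grid)
        assert sv_statistic(combined) == pytest.approx(sv_parts, rel=1e-12)


class TestThreshold:
    def test_empty_when_all_zero(self):
        assert not threshold_mask(np.zeros((3, 3))).any()

    def test_strict_inequality_at_threshold(self):
        sv = np.array([1.5, 1.5 + 1e-9, 2.0])
        np.testing.assert_array_equal(threshold_mask(sv, 1.5),
                                      [False, True, True])

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(3)
        sv = rng.uniform(0, 5, size=(6, 6))
        lower = threshold_mask(sv, 1.0)
        higher = threshold_mask(sv, 2.5)
        assert np.all(lower[higher])


class TestBands:
    def test_default_band_edges_at_geometric_midpoints(self, beta_grid):
        bands = default_bands(beta_grid)
        lam = {n: NUCLIDES[n].decay_constant_s for n in NUCLIDES}
        assert bands["C11"][1] == pytest.approx(
            np.sqrt(lam["C11"] * lam["N13"]), rel=1e-12)
        assert bands["N13"][1] == pytest.approx(
            np.sqrt(lam["N13"] * lam["O15"]), rel=1e-12)
        for name in NUCLIDES:
            lo, hi = bands[name]
            assert lo <= lam[name] < hi

    def test_unknown_nuclide_rejected(self, beta_grid):
        with pytest.raises(KeyError):
            default_bands(beta_grid)["F18"]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            NuclideBands({"a": (1e-4, 1e-3), "b": (5e-4, 1e-2)})

    @pytest.mark.parametrize("pure,other", [("C11", "N13"), ("N13", "N13")])
    def test_band_leakage(self, schedule75, basis75, pure, other):
        """A pure noiseless 11C voxel leaks <1% of its amplitude into the
        13N band; a pure 13N voxel keeps >=90% in its own band."""
        bands = default_bands(basis75.grid)
        fit = fit_voxel(mono_tac(schedule75,
                                 NUCLIDES[pure].decay_constant_s), basis75)
        frac = fit.band_amplitude(*bands[other]) / fit.alpha.sum()
        if pure == other:
            assert frac >= 0.90
        else:
            assert frac < 0.01
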