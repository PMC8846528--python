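"""Decay kinetics, frame synthesis, noise, and the on-disk trio."""

import numpy as np
import pytest
from scipy.integrate import quad

from protonrange import (
    BeamSpec,
    DynamicSeries,
    FrameSchedule,
    NUCLIDES,
    PhantomSpec,
    activity_at,
    add_poisson_noise,
    build_frames,
    decays_between,
    load_series,
    save_series,
    yield_map_3d,
)
from protonrange.activation import YieldMap


@pytest.fixture(scope="module")
def tiny_maps(bk_model, xs_all):
    phantom = PhantomSpec(size_mm=(12, 12, 70), voxel_mm=(4, 4, 1.0))
    return yield_map_3d(BeamSpec(80.0, diameter_mm=6.0), phantom, NUCLIDES,
                        xs_all, bk_model)


class TestActivity:
    def test_initial_activity(self):
        lam = NUCLIDES["N13"].decay_constant_s
        assert activity_at(100.0, lam, 0.0) == pytest.approx(lam * 100.0)

    def test_half_life_halves_activity(self):
        spec = NUCLIDES["C11"]
        lam = spec.decay_constant_s
        assert activity_at(100.0, lam, spec.half_life_s) == pytest.approx(
            lam * 50.0)

    def test_nonpositive_decay_constant_rejected(self):
        with pytest.raises(ValueError):
            activity_at(1.0, 0.0, 10.0)

    def test_frame_integral_matches_quadrature(self):
        """Closed-form decays over [t1, t2] against numerical integration
        of the activity curve."""
        lam = NUCLIDES["O15"].decay_constant_s
        for t1, t2 in [(0.0, 60.0), (300.0, 360.0), (1800.0, 4500.0)]:
            oracle, _ = quad(lambda t: activity_at(7.0, lam, t), t1, t2)
            assert decays_between(7.0, lam, t1, t2) == pytest.approx(
                oracle, rel=1e-9)


class TestSchedule:
    def test_default_is_75_one_minute_frames(self):
        s = FrameSchedule.uniform()
        assert len(s) == 75
        assert s.start_s[0] == 0.0
        assert s.end_s[-1] == 75 * 60.0
        assert np.all(s.durations_s == 60.0)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 30.0]), np.array([60.0, 90.0]))

    def test_inverted_frame_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0]), np.array([0.0]))


class TestBuildFrames:
    def test_total_decays_single_infinite_frame(self, tiny_maps):
        one = {"N13": tiny_maps["N13"]}
        sched = FrameSchedule(np.array([0.0]), np.array([1e9]))
        series = build_frames(one, sched)
        np.testing.assert_allclose(series.data[..., 0],
                                   tiny_maps["N13"].values, rtol=1e-12)

    def test_o15_vanishes_after_30_minutes(self, tiny_maps):
        """The short-lived 15O signal after 30 min is below 0.01% of its
        first-frame contribution."""
        series = build_frames({"O15": tiny_maps["O15"]},
                              FrameSchedule.uniform(75, 60.0))
        i, j, k = np.unravel_index(np.argmax(series.data[..., 0]),
                                   series.data.shape[:3])
        tac = series.voxel_tac(i, j, k)
        assert np.all(tac[30:] < 1e-4 * tac[0])

    def test_decay_conservation_and_limit(self, tiny_maps):
        total_n0 = sum(m.values.sum() for m in tiny_maps.values())
        short = build_frames(tiny_maps, FrameSchedule.uniform(75, 60.0))
        longer = build_frames(tiny_maps, FrameSchedule.uniform(600, 60.0))
        assert short.data.sum() <= total_n0 + 1e-6
        assert longer.data.sum() > short.data.sum()
        assert longer.data.sum() == pytest.approx(total_n0, rel=1e-3)

    def test_counts_equal_closed_form_integrals(self, tiny_maps):
        """Per-voxel frame counts against direct per-nuclide arithmetic."""
        sched = FrameSchedule.uniform(20, 60.0)
        series = build_frames(tiny_maps, sched)
        i, j, k = 1, 1, 30
        expected = np.zeros(len(sched))
        for name, m in tiny_maps.items():
            lam = NUCLIDES[name].decay_constant_s
            expected += decays_between(m.values[i, j, k], lam,
                                       sched.start_s, sched.end_s)
        np.testing.assert_allclose(series.voxel_tac(i, j, k), expected,
                                   rtol=1e-9)

    def test_decay_ordering_in_mixed_voxel(self, tiny_maps):
        """Last-to-first frame count ratio orders by half-life:
        11C slowest, then 13N, then 15O."""
        sched = FrameSchedule.uniform(75, 60.0)
        ratios = {}
        for name, m in tiny_maps.items():
            s = build_frames({name: m}, sched)
            i, j, k = 1, 1, 10
            tac = s.voxel_tac(i, j, k)
            ratios[name] = tac[-1] / tac[0]
        assert ratios["C11"] > ratios["N13"] > ratios["O15"]

    def test_grid_mismatch_rejected(self, tiny_maps):
        other = YieldMap(np.zeros((3, 3, 10)), (4.0, 4.0, 1.0), "N13", 80.0)
        with pytest.raises(ValueError, match="grid"):
            build_frames({"N13": other, "C11": tiny_maps["C11"]},
                         FrameSchedule.uniform(5, 60.0))


@pytest.fixture(scope="module")
def clean(tiny_maps):
    return build_frames(tiny_maps, FrameSchedule.uniform(10, 60.0), scale=1e4)


class TestPoissonNoise:

    def test_zero_count_voxels_stay_zero(self, clean):
        noisy = add_poisson_noise(clean, seed=7)
        assert np.all(noisy.data[clean.data == 0] == 0)

    def test_same_seed_bit_identical(self, clean):
        a = add_poisson_noise(clean, scale=2.0, seed=42)
        b = add_poisson_noise(clean, scale=2.0, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empirical_mean_matches_poisson_moments(self, clean):
        i, j, k = 1, 1, 10
        mu = clean.data[i, j, k, 0]
        assert mu > 10
        rng_draws = np.array([
            add_poisson_noise(clean, seed=s).data[i, j, k, 0]
            for s in range(400)])
        se = np.sqrt(mu / rng_draws.size)
        assert abs(rng_draws.mean() - mu) < 3 * se

    def test_nonpositive_scale_rejected(self, clean):
        with pytest.raises(ValueError):
            add_poisson_noise(clean, scale=0.0, seed=1)


class TestSeriesIO:
    def test_round_trip(self, tiny_maps, tmp_path):
        series = build_frames(tiny_maps, FrameSchedule.uniform(12, 60.0),
                              meta={"note": "round-trip"})
        save_series(series, tmp_path / "run")
        back = load_series(tmp_path / "run")
        np.testing.assert_allclose(back.data, series.data, rtol=1e-6)
        np.testing.assert_array_equal(back.schedule.start_s,
                                      series.schedule.start_s)
        assert back.voxel_mm == series.voxel_mm
        assert back.meta["note"] == "round-trip"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DynamicSeries(-np.ones((2, 2, 2, 1)),
                          FrameSchedule.uniform(1, 60.0), (1.0, 1.0, 1.0))
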