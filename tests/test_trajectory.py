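"""Acquisition design: tiny golden angles, spiral feasibility, kz orderings,
and angular coverage after cardiac binning."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from cineimoco.trajectory import (
    GAMMA_KHZ_PER_MT,
    InfeasibleTrajectoryError,
    SCHEME_FIXED,
    SCHEME_PER_TR,
    SCHEME_VARIABLE,
    build_schedule,
    coverage_report,
    design_vd_spiral,
    kz_density_profile,
    pseudo_rotation_increment,
    rotation_step_count,
    tiny_golden_angle,
)

GOLDEN = (1 + math.sqrt(5)) / 2


class TestTinyGoldenAngle:
    def test_known_values(self):
        assert tiny_golden_angle(1) == pytest.approx(180.0 / GOLDEN, abs=1e-9)
        assert tiny_golden_angle(1) == pytest.approx(111.246, abs=1e-3)
        assert tiny_golden_angle(4) == pytest.approx(180.0 / (GOLDEN + 3), abs=1e-9)
        assert tiny_golden_angle(4) == pytest.approx(38.98, abs=0.01)

    def test_sequence_strictly_decreasing(self):
        vals = [tiny_golden_angle(n) for n in range(1, 11)]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_rejects_bad_order(self, bad):
        with pytest.raises(ValueError):
            tiny_golden_angle(bad)


class TestPseudoRotation:
    def test_quantizes_psi4_onto_119_grid(self):
        inc = pseudo_rotation_increment(tiny_golden_angle(4), 119)
        assert inc == pytest.approx(13 * 360.0 / 119, abs=1e-12)
        assert inc == pytest.approx(39.3, abs=0.05)
        assert rotation_step_count(38.98, 119) == 13

    def test_exact_multiple_unchanged(self):
        assert pseudo_rotation_increment(90.0, 4) == pytest.approx(90.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pseudo_rotation_increment(0.0, 119)


class TestKzDensity:
    def test_uniform_limit(self):
        d = kz_density_profile(80, math.inf)
        assert np.allclose(d.probabilities, 1.0 / 80)

    def test_gaussian_center_probability(self):
        d = kz_density_profile(80, 10.8)
        # normalized discrete Gaussian at zero offset ~ 1/(sqrt(2 pi) sigma)
        assert d.probabilities[40] == pytest.approx(0.037, abs=0.001)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_about_center(self):
        d = kz_density_profile(81, 9.0)
        p = d.probabilities
        assert np.allclose(p, p[::-1], rtol=1e-12)


class TestSpiralDesign:
    @pytest.fixture(scope="class")
    def protocol_spiral(self):
        return design_vd_spiral(384.0, 192, 32, 2.5, 16.0, 180.0)

    def test_protocol_feasible_and_within_limits(self, protocol_spiral):
        sp = protocol_spiral
        assert sp.readout_duration <= 2.5
        assert sp.radius().max() == pytest.approx(96.0, rel=1e-6)
        assert np.allclose(sp.k_coords[0], [0.0, 0.0])
        gmag = np.hypot(*sp.gradient_waveform.T)
        assert gmag.max() <= 16.0 + 1e-9
        slew = np.diff(sp.gradient_waveform, axis=0) / sp.dwell_time
        assert np.hypot(*slew.T).max() <= 180.0 + 1e-9

    def test_gradient_reintegrates_to_trajectory(self, protocol_spiral):
        sp = protocol_spiral
        t = np.arange(sp.n_samples) * sp.dwell_time
        k = cumulative_trapezoid(
            sp.gradient_waveform * GAMMA_KHZ_PER_MT * 0.384, t,
            initial=0.0, axis=0,
        )
        assert np.abs(k - sp.k_coords).max() / sp.k_max < 1e-3

    def test_inner_region_satisfies_nyquist(self, protocol_spiral):
        sp = protocol_spiral
        r = sp.radius()
        theta = np.unwrap(np.arctan2(sp.k_coords[:, 1], sp.k_coords[:, 0]))
        spacing = np.gradient(r, theta) * 2 * np.pi / sp.n_interleaves
        inner = (r > 2) & (r < 0.25 * sp.k_max)
        assert spacing[inner].max() <= 1.01

    def test_unconstrained_limits_shorten_readout(self, protocol_spiral):
        fast = design_vd_spiral(384.0, 192, 32, 2.5, 1e5, 1e7)
        assert fast.readout_duration < 0.1 * protocol_spiral.readout_duration
        gmag = np.hypot(*fast.gradient_waveform.T)
        assert gmag.max() <= 1e5

    def test_infeasible_raises_named_constraint(self):
        with pytest.raises(InfeasibleTrajectoryError, match="gmax|smax"):
            design_vd_spiral(384.0, 192, 32, 0.3, 16.0, 180.0)


class TestSchedules:
    def test_linear_sweep_and_angle_advance(self):
        sch = build_schedule(SCHEME_PER_TR, 80, 119, 4.5, 5000.0)
        first = sch.kz_index[:80]
        assert np.array_equal(np.sort(first), np.arange(80))
        steps = np.diff(sch.angle_index.astype(int)) % 119
        assert np.all(steps == 13)

    def test_fixed_scheme_rotates_per_slice_loop(self):
        sch = build_schedule(SCHEME_FIXED, 80, 119, 4.5, 5000.0)
        assert np.all(sch.angle_index[:80] == sch.angle_index[0])
        assert sch.angle_index[80] == (sch.angle_index[0] + 13) % 119

    def test_entry_count_and_times(self):
        sch = build_schedule(SCHEME_PER_TR, 80, 119, 4.5, 350_000.0)
        assert len(sch) in (77_777, 77_778)
        assert np.allclose(np.diff(sch.times), 4.5)

    @pytest.fixture(scope="class")
    def vd_schedule(self):
        density = kz_density_profile(80, 10.8)
        return build_schedule(
            SCHEME_VARIABLE, 80, 119, 4.5, 350_000.0, density=density, seed=3
        ), density

    def test_vd_step_bound_and_navigator_window(self, vd_schedule):
        sch, _ = vd_schedule
        assert np.abs(np.diff(sch.kz_index)).max() <= 8
        nav_times = sch.times[sch.is_dc_navigator]
        assert np.diff(nav_times).max() <= 360.0 + 1e-9

    def test_vd_histogram_matches_density(self, vd_schedule):
        sch, density = vd_schedule
        hist = np.bincount(sch.kz_index, minlength=80) / len(sch)
        tv = 0.5 * np.abs(hist - density.probabilities).sum()
        assert tv < 0.02
        center_count = (sch.kz_index == 40).sum()
        expect = density.probabilities[40] * len(sch)
        assert abs(center_count - expect) < 0.02 * expect + 80

    def test_angle_multisets_match_between_per_tr_schemes(self):
        density = kz_density_profile(40, 10.0)
        a = build_schedule(SCHEME_PER_TR, 40, 119, 4.5, 30_000.0)
        b = build_schedule(SCHEME_VARIABLE, 40, 119, 4.5, 30_000.0,
                           density=density, seed=0)
        assert np.array_equal(np.bincount(a.angle_index, minlength=119),
                              np.bincount(b.angle_index, minlength=119))

    def test_navigator_guarantee_unsatisfiable_raises(self):
        thin = kz_density_profile(80, math.inf)
        # 1 TR per window makes even uniform density infeasible
        with pytest.raises(ValueError, match="navigator"):
            build_schedule(SCHEME_VARIABLE, 80, 119, 4.5, 10_000.0,
                           density=thin, seed=0, nav_window_ms=9.0)

    def test_roundtrip_text_export(self, tmp_path):
        density = kz_density_profile(16, 4.0)
        sch = build_schedule(SCHEME_VARIABLE, 16, 21, 4.5, 2000.0,
                             density=density, seed=1, max_kz_step=3)
        path = tmp_path / "sched.tsv"
        sch.save_txt(path)
        from cineimoco.trajectory import SamplingSchedule

        back = SamplingSchedule.load_txt(path)
        assert np.array_equal(back.kz_index, sch.kz_index)
        assert np.array_equal(back.angle_index, sch.angle_index)
        assert back.tr == sch.tr


class TestCoverage:
    def test_complete_coverage_is_100_percent(self):
        sch = build_schedule(SCHEME_PER_TR, 4, 7, 4.5, 4 * 7 * 4.5 + 1)
        labels = np.zeros(len(sch), dtype=int)
        rep = coverage_report(sch, labels, n_phases=1)
        assert rep.fill_fraction[0].max() == 1.0

    def test_occupancy_matches_coupon_collector_expectation(self):
        # m pseudo-random angles at one partition: expected distinct fraction
        # is 1 - (1 - 1/A)^m; check against a Monte-Carlo draw
        rng = np.random.default_rng(0)
        A, m = 119, 40
        fills = []
        for _ in range(200):
            fills.append(np.unique(rng.integers(0, A, m)).size / A)
        expect = 1 - (1 - 1 / A) ** m
        assert np.mean(fills) == pytest.approx(expect, abs=0.01)

    def test_unlabeled_entries_rejected(self):
        sch = build_schedule(SCHEME_PER_TR, 4, 7, 4.5, 500.0)
        with pytest.raises(ValueError):
            coverage_report(sch, np.full(len(sch), np.nan))

    def test_scheme2_headline_matches_analytic_occupancy(self):
        """The center-partition fill of the linear per-TR sweep follows the
        random-occupancy formula 1-(1-1/A)^m within 2 points.

        A strictly periodic heart beat aliases against the 360 ms slice
        loop (deviations up to ~5 points depending on RR), so the beat
        model includes the physiological RR variability that decorrelates
        the two periods.
        """
        from cineimoco.gating import cardiac_phase_labels
        from cineimoco.phantom import simulate_ecg_triggers

        sch = build_schedule(SCHEME_PER_TR, 80, 119, 4.5, 350_000.0)
        trig = simulate_ecg_triggers(350_000.0, 1000.0, 50.0,
                                     np.random.default_rng(12))
        labels = cardiac_phase_labels(sch.times, trig, 25)
        rep = coverage_report(sch, labels, n_phases=25)
        nav = sch.kz_index == 40
        m = (labels[nav] >= 0).sum() / 25.0
        expect = 100.0 * (1 - (1 - 1 / 119) ** m)
        assert rep.center_fill_percent == pytest.approx(expect, abs=2.0)
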