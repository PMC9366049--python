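"""Distance-matching machinery: MFPT/MFPV, transition solver, staircase,
orbit prediction and the excitable threshold."""

import math

import numpy as np
import pytest

import hedgehog as hh
from hedgehog.sisr import Y0_LEFT_DEFAULT, matching_lhs, rest_state_y


class TestMfpt:
    def test_diverges_as_noise_vanishes(self, geom_l):
        assert hh.mfpt(0.0, "left", 1e-4, geom_l) > 1e100
        t1 = hh.mfpt(0.0, "left", 0.5, geom_l)
        t2 = hh.mfpt(0.0, "left", 0.4, geom_l)
        assert t2 > t1

    def test_large_noise_limit_is_bare_prefactor(self, geom_l):
        cb = geom_l.interp(0.0, "curv_branch")
        cm = geom_l.interp(0.0, "curv_barrier")
        pref = 2 * math.pi / math.sqrt(cb * cm)
        assert hh.mfpt(0.0, "left", 1e6, geom_l) == pytest.approx(pref, rel=1e-3)

    def test_rejects_fold_neighborhood(self, geom_r):
        with pytest.raises(ValueError):
            hh.mfpt(float(geom_r.y_grid[-1]), "right", 0.1, geom_r)

    def test_mfpv_times_mfpt_is_distance(self, geom_l):
        for y in (-0.5, -0.2, 0.1):
            v = hh.mfpv(y, "left", 0.3, geom_l)
            t = hh.mfpt(y, "left", 0.3, geom_l)
            assert v * t == pytest.approx(float(geom_l.interp(y, "S")), rel=1e-12)

    def test_mfpv_increasing_in_sigma(self, geom_r):
        vals = [hh.mfpv(-0.3, "right", s, geom_r) for s in (0.05, 0.1, 0.2, 0.4)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestMatchingLhs:
    def test_empty_interval_is_zero(self, geom_l):
        assert matching_lhs(0.1, 0.1, 0.1, "left", geom_l) == 0.0

    def test_monotone_downstream(self, geom_l, geom_r):
        vals_l = [matching_lhs(0.2, y, 0.1, "left", geom_l) for y in (0.0, -0.2, -0.4)]
        assert all(b > a >= 0 for a, b in zip(vals_l, vals_l[1:]))
        vals_r = [matching_lhs(-0.6, y, 0.1, "right", geom_r) for y in (-0.4, -0.2, 0.0)]
        assert all(b > a >= 0 for a, b in zip(vals_r, vals_r[1:]))

    def test_monotone_in_sigma(self, geom_l):
        vals = [matching_lhs(0.2, -0.3, s, "left", geom_l) for s in (0.05, 0.1, 0.2)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_rejects_interval_outside_table(self, geom_l):
        with pytest.raises(ValueError):
            matching_lhs(0.5, 0.0, 0.1, "left", geom_l)


class TestSolveTransition:
    def test_self_consistency_residual(self, geom_l, geom_r):
        for branch, geom in (("left", geom_l), ("right", geom_r)):
            for sigma in (0.01, 0.05, 0.15):
                sol = hh.solve_transition(branch, sigma, None, geom)
                assert sol.converged
                S = float(geom.interp(sol.y_star, "S"))
                assert sol.residual < 1e-8 * max(1.0, S)

    def test_left_position_increases_with_sigma(self, geom_l):
        ys = [hh.solve_transition("left", s, None, geom_l).y_star
              for s in np.logspace(-2.3, -0.8, 8)]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_right_position_steps_down_with_sigma(self, geom_r):
        sols = [hh.solve_transition("right", s, None, geom_r)
                for s in np.logspace(-3, -0.8, 12)]
        ys = [s.y_star for s in sols]
        regs = [s.region_index for s in sols]
        assert all(b <= a + 1e-9 for a, b in zip(ys, ys[1:]))
        assert all(b <= a for a, b in zip(regs, regs[1:]))
        assert regs[0] == 6  # weakest noise escapes in the topmost lobe
        assert len(set(regs)) >= 3

    def test_escape_before_region_tip(self, geom_r):
        for s in (0.01, 0.05, 0.1):
            sol = hh.solve_transition("right", s, None, geom_r)
            reg = geom_r.regions[sol.region_index - 1]
            assert reg.y_start < sol.y_star <= reg.y_tip + 1e-6

    def test_unconverged_flag_at_tiny_sigma(self, geom_l):
        sol = hh.solve_transition("left", 1e-4, None, geom_l)
        assert not sol.converged


class TestRefinePair:
    def test_matches_unrefined_when_well_separated(self, geom_l, geom_r):
        s = 1e-3
        left, right = hh.refine_pair(s, geom_l, geom_r)
        ul = hh.solve_transition("left", s, None, geom_l)
        assert right.converged
        assert abs(left.y_star - ul.y_star) < 1e-4

    def test_orientation_below_crossing(self, geom_l, geom_r, staircase_curve):
        sigma_c = staircase_curve.crossing[0]
        for s in (0.01, 0.05, 0.1, 0.9 * sigma_c):
            left, right = hh.refine_pair(s, geom_l, geom_r)
            assert left.y_star < right.y_star

    def test_insensitive_to_starting_position(self, geom_l):
        # y0 can sit anywhere well upstream of the transition position
        s = 0.01
        base = hh.solve_transition("left", s, 0.15, geom_l).y_star
        for dy in (-0.05, 0.05):
            alt = hh.solve_transition("left", s, 0.15 + dy, geom_l).y_star
            assert abs(alt - base) < 1e-4


class TestStaircase:
    def test_crossing_location(self, staircase_curve):
        sigma_c, y_c = staircase_curve.crossing
        assert sigma_c == pytest.approx(0.173, rel=0.05)
        assert y_c == pytest.approx(-0.253, abs=0.02)

    def test_gap_shrinks_below_crossing(self, staircase_curve):
        sc = staircase_curve
        gap = sc.ystar_right[sc.valid] - sc.ystar_left[sc.valid]
        assert np.all(gap > 0)
        assert np.all(np.diff(gap) < 0)

    def test_plateaus_match_regions_visited(self, staircase_curve):
        regs = staircase_curve.region_of[staircase_curve.valid]
        assert set(regs) <= set(range(1, 7))
        assert len(set(regs)) <= 6

    def test_fhn_limit_monotone_single_structure(self, fhn_geoms, fhn_params):
        gl, gr = fhn_geoms
        grid = np.logspace(-1.6, -0.4, 8)
        sc = hh.staircase(grid, gl, gr, fhn_params)
        ok = sc.valid
        assert ok.sum() >= 3
        assert np.all(np.diff(sc.ystar_left[ok]) >= -1e-9)
        assert np.all(np.diff(sc.ystar_right[ok]) <= 1e-9)
        assert set(sc.region_of[ok]) == {1}


class TestPredictOrbit:
    @pytest.mark.parametrize(
        "sigma,spikes", [(0.00455, 6), (0.0207, 5), (0.0695, 3), (0.16, 1)]
    )
    def test_noise_tuned_spike_counts(self, geom_l, geom_r, sigma, spikes):
        pair = hh.refine_pair(sigma, geom_l, geom_r)
        orbit = hh.predict_orbit(sigma, pair, geom_l, geom_r)
        assert orbit.spike_count == spikes

    def test_period_and_extent_shrink_with_noise(self, geom_l, geom_r):
        orbits = []
        for s in (0.00455, 0.0207, 0.0695, 0.16):
            pair = hh.refine_pair(s, geom_l, geom_r)
            orbits.append(hh.predict_orbit(s, pair, geom_l, geom_r))
        periods = [o.period for o in orbits]
        extents = [o.y_cr - o.y_cl for o in orbits]
        assert all(b <= a for a, b in zip(periods, periods[1:]))
        assert all(b < a for a, b in zip(extents, extents[1:]))
        for o in orbits:
            assert o.y_cl < o.y_cr and o.period > 0 and o.spike_count >= 1

    def test_small_noise_period_approaches_relaxation_skeleton(self, geom_l, geom_r):
        sigma = 0.00455  # weak noise: orbit nearly spans the full windows
        pair = hh.refine_pair(sigma, geom_l, geom_r)
        orbit = hh.predict_orbit(sigma, pair, geom_l, geom_r)
        # full-window skeleton period
        p = geom_l.params
        y_lo = max(geom_l.y_grid[0], geom_r.y_grid[0])
        y_hi = min(geom_l.y_grid[-1], geom_r.y_grid[-1])
        yy = np.linspace(y_lo, y_hi, 2000)
        t_full = np.trapezoid(
            1.0 / (p.eps * np.abs(geom_l.interp(yy, "x_of_y") + p.a)), yy
        ) + np.trapezoid(
            1.0 / (p.eps * np.abs(geom_r.interp(yy, "x_of_y") + p.a)), yy
        )
        assert orbit.period == pytest.approx(t_full, rel=0.05)

    def test_rejects_unconverged_pair(self, geom_l, geom_r):
        pair = hh.refine_pair(1e-4, geom_l, geom_r)
        with pytest.raises(ValueError):
            hh.predict_orbit(1e-4, pair, geom_l, geom_r)


class TestExcitableThreshold:
    def test_monotone_in_bifurcation_parameter(self, geom_l):
        thresholds = [hh.excitable_threshold(a, geom_l) for a in (1.1, 1.2, 1.3, 1.4, 1.5)]
        assert all(b > a for a, b in zip(thresholds, thresholds[1:]))
        assert all(t > 0 for t in thresholds)

    def test_rest_state_location(self, geom_l):
        y_fp = rest_state_y(geom_l, 1.2)
        assert geom_l.interp(y_fp, "x_of_y") == pytest.approx(-1.2, abs=1e-3)

    def test_threshold_separates_escape(self, geom_l):
        a = 1.2
        p = hh.DEFAULT_PARAMS.replace(a=a)
        thr = hh.excitable_threshold(a, geom_l)
        y_fp = rest_state_y(geom_l, a)
        below = hh.solve_transition("left", 0.5 * thr, None, geom_l, p, y_min=y_fp + 0.02)
        above = hh.solve_transition("left", 2.0 * thr, None, geom_l, p, y_min=y_fp + 0.02)
        assert not below.converged
        assert above.converged
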