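"""Full operon model: fixed points, stability, trajectories, null-clines."""

import dataclasses

import numpy as np
import pytest

from taswitch import (
    InvalidInputError,
    TAParams,
    classify_stability,
    dilution_rate_ratio,
    enumerate_fixed_points,
    enumerate_fixed_points_newton,
    growth_factor,
    is_bistable,
    nullcline_intersections,
    nullclines,
    rhs,
    simulate_rk4,
)
from taswitch.tamodel import rhs_no_feedback

FOLDS = 2.0 ** np.arange(-3, 4)
SAMPLEABLE = ("beta_A", "Gamma_A", "K_D", "K1", "K2", "k_tl", "k_g")


def random_params(rng, **fixed):
    kw = {n: getattr(TAParams(), n) * float(rng.choice(FOLDS)) for n in SAMPLEABLE}
    kw.update(fixed)
    return TAParams(**kw)


class TestRHS:
    def test_empty_cell_produces_at_maximal_rate(self, reference):
        assert rhs((0.0, 0.0), reference) == pytest.approx([100.0, 1.0])

    def test_zero_feedback_reduces_to_plain_operon(self, reference, rng):
        p0 = reference.without_feedback()
        for _ in range(25):
            s = rng.uniform(0.0, 5.0, size=2)
            assert rhs(s, p0) == pytest.approx(rhs_no_feedback(s, reference))

    def test_negative_state_rejected(self, reference):
        with pytest.raises(InvalidInputError):
            rhs((-0.1, 1.0), reference)

    def test_growing_state_has_negligible_free_toxin(self, reference):
        fps = enumerate_fixed_points(reference)
        low = min((f for f in fps if f.stable), key=lambda f: f.T_tot)
        assert low.freeT < reference.K1


class TestFixedPointStructure:
    def test_reference_bistable_two_stable_one_saddle(self, reference):
        fps = enumerate_fixed_points(reference)
        assert [f.klass for f in fps] == ["stable", "saddle", "stable"]
        assert is_bistable(reference)

    def test_reference_growing_state_coordinates(self, reference):
        low = enumerate_fixed_points(reference)[0]
        assert low.A_tot == pytest.approx(1.2397, rel=1e-3)
        assert low.T_tot == pytest.approx(0.1250, rel=1e-3)
        assert low.A_tot / low.T_tot == pytest.approx(10.0, rel=0.1)

    def test_no_feedback_is_monostable(self, reference):
        fps = enumerate_fixed_points(reference.without_feedback())
        assert [f.klass for f in fps] == ["stable"]
        assert not is_bistable(reference.without_feedback())

    def test_growth_feedback_alone_is_required(self, reference):
        """Production inhibition without growth inhibition cannot give
        dormancy: the antitoxin:toxin ratio stays pinned near 10."""
        p = dataclasses.replace(reference, k_g=0.0)
        fps = enumerate_fixed_points(p)
        assert sum(f.stable for f in fps) == 1
        only = fps[0]
        assert only.A_tot / only.T_tot == pytest.approx(10.0, rel=0.15)

    def test_growing_state_insensitive_to_feedback(self, reference):
        """The antitoxin-dominated state of the full model sits within 5%
        of the no-feedback operon's fixed point (free toxin ~ 0 there)."""
        low = enumerate_fixed_points(reference)[0]
        base = enumerate_fixed_points(reference.without_feedback())[0]
        assert abs(low.A_tot - base.A_tot) / base.A_tot < 0.05
        assert abs(low.T_tot - base.T_tot) / base.T_tot < 0.05

    def test_reduction_agrees_with_multistart_newton(self, rng):
        """1-D reduction vs independent 2-D Newton enumeration."""
        checked = 0
        for _ in range(100):
            p = random_params(rng)
            a = enumerate_fixed_points(p)
            b = enumerate_fixed_points_newton(p)
            # Newton multistart may miss points; every Newton point must be
            # in the reduction's set, and counts must agree when both see
            # the full structure.
            for fb in b:
                assert any(
                    abs(fb.A_tot - fa.A_tot) <= 1e-4 * max(fa.A_tot, 1e-9)
                    and abs(fb.T_tot - fa.T_tot) <= 1e-4 * max(fa.T_tot, 1e-9)
                    for fa in a
                ), (p, fa, fb)
            if len(b) == len(a):
                checked += 1
        assert checked >= 70


class TestStability:
    def test_stable_point_attracts_small_perturbations(self, reference):
        # the dormant state relaxes at roughly the arrested growth rate
        # (slowest eigenvalue ~ -8e-3), so the horizon must cover several
        # of its relaxation times
        for fp in enumerate_fixed_points(reference):
            if not fp.stable:
                continue
            slow = min(abs(e.real) for e in fp.eigenvalues)
            t_end = min(1500.0, max(40.0, 12.0 / slow))
            start = (1.01 * fp.A_tot, 1.01 * fp.T_tot)
            traj = simulate_rk4(start, reference, dt=5e-2, t_end=t_end)
            end = traj.states[-1]
            assert abs(end[0] - fp.A_tot) < 1e-3 * fp.A_tot
            assert abs(end[1] - fp.T_tot) < 1e-3 * fp.T_tot

    def test_saddle_has_opposite_sign_eigenvalues(self, reference):
        saddle = [f for f in enumerate_fixed_points(reference) if f.klass == "saddle"]
        assert len(saddle) == 1
        re = sorted(e.real for e in saddle[0].eigenvalues)
        assert re[0] < 0 < re[1]

    def test_non_fixed_point_rejected(self, reference):
        with pytest.raises(InvalidInputError):
            classify_stability((5.0, 5.0), reference)


class TestTrajectories:
    def test_pure_decay_matches_closed_form(self):
        p = TAParams(beta_A=1e-12, beta_T=1e-12, k_tl=0.0, k_g=0.0)
        a0, t0 = 2.0, 0.5
        traj = simulate_rk4((a0, t0), p, dt=1e-3, t_end=1.0)
        expect_a = a0 * np.exp(-p.Gamma_A * traj.times)
        expect_t = t0 * np.exp(-traj.times)
        assert np.max(np.abs(traj.states[:, 0] - expect_a)) < 1e-8
        assert np.max(np.abs(traj.states[:, 1] - expect_t)) < 1e-10

    def test_basins_reach_their_fixed_points(self, reference):
        fps = enumerate_fixed_points(reference)
        low, high = fps[0], fps[-1]
        tr = simulate_rk4((2.0, 0.05), reference, dt=5e-3, t_end=40.0)
        assert tr.states[-1] == pytest.approx([low.A_tot, low.T_tot], rel=1e-3)
        tr = simulate_rk4((0.05, 1.1), reference, dt=2e-2, t_end=600.0)
        assert tr.states[-1] == pytest.approx([high.A_tot, high.T_tot], rel=2e-2)

    def test_bad_steps_rejected(self, reference):
        with pytest.raises(InvalidInputError):
            simulate_rk4((1.0, 1.0), reference, dt=0.0, t_end=1.0)


class TestNullclines:
    def test_no_feedback_single_intersection(self, reference):
        inter = nullcline_intersections(reference.without_feedback())
        assert len(inter) == 1

    def test_intersections_match_fixed_points(self, reference):
        fps = enumerate_fixed_points(reference)
        inter = nullcline_intersections(reference)
        assert len(inter) == len(fps)
        for (a, t), fp in zip(inter, fps):
            assert abs(a - fp.A_tot) < 1e-6 * max(1.0, fp.A_tot)
            assert abs(t - fp.T_tot) < 1e-6 * max(1.0, fp.T_tot)

    def test_curve_points_are_roots(self, reference):
        grid = np.logspace(-2, 0.5, 12)
        for which, comp in (("A", 0), ("T", 1)):
            pts = nullclines(reference, grid, which)
            assert pts, which
            for T, A in pts:
                assert abs(rhs((A, T), reference)[comp]) < 1e-8


class TestDilutionRatio:
    def test_reference_contrast_far_above_one(self, reference):
        r = dilution_rate_ratio(reference)
        assert r == pytest.approx(77.2, rel=0.05)
        assert r >= 1.0

    def test_monostable_input_rejected(self, reference):
        with pytest.raises(InvalidInputError):
            dilution_rate_ratio(reference.without_feedback())

    def test_no_growth_feedback_means_unit_ratio(self):
        assert growth_factor(0.3, 0.0) / growth_factor(0.01, 0.0) == pytest.approx(1.0)

    def test_random_bistable_sets_have_ratio_above_one(self, rng):
        found = 0
        while found < 10:
            p = random_params(rng)
            if is_bistable(p):
                assert dilution_rate_ratio(p) >= 1.0
                found += 1
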