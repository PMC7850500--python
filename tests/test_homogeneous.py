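"""Homogeneous (0-D) actin-nucleator dynamics and its bifurcations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actinwaves import (FHNParams, ModelParams, classify_fhn,
                        classify_homogeneous, extrema_roots, find_fixpoint,
                        integrate_ode, nullcline_c_of_na, rhs_homogeneous)
from actinwaves.homogeneous import (EXTREMA_THRESHOLD,
                                    extrema_roots_arcsine_branch,
                                    extrema_roots_trig, fhn_rhs,
                                    jacobian_homogeneous,
                                    limit_cycle_period,
                                    nullcline_tangent_intercept,
                                    oscillation_frequency_estimate,
                                    _fixpoint_residual)


@pytest.fixture(scope="module")
def params():
    return ModelParams()          # working defaults, omega_d = 0.35


class TestRhsHomogeneous:
    def test_empty_state_produces_activation_only(self, params):
        dc, dna = rhs_homogeneous((0.0, 0.0), params)
        assert dc == 0.0
        assert dna == params.n_tot

    def test_fixpoint_is_stationary(self, params):
        fix = find_fixpoint(params)
        dc, dna = rhs_homogeneous((fix.c0, fix.n_a0), params)
        scale = params.alpha * fix.n_a0
        assert abs(dc) < 1e-9 * scale
        assert abs(dna) < 1e-9 * scale

    def test_hand_evaluated_arithmetic(self):
        # independent evaluation at c = 1, n_a = 1, omega_d = 0.4:
        # dc  = -176*1 + 588*1 = 412
        # dna = (1 + 6e-3*1)*(700 - 1) - 0.4*1*1
        #     = 1.006*699 - 0.4 = 703.194 - 0.4 = 702.794
        p = ModelParams(omega_d=0.4)
        dc, dna = rhs_homogeneous((1.0, 1.0), p)
        assert dc == pytest.approx(412.0, abs=1e-12)
        assert dna == pytest.approx(702.794, abs=1e-9)


class TestNullcline:
    def test_matches_dna_zero_locus(self, params):
        for n_a in (1.0, 50.0, 300.0, 699.0):
            c = nullcline_c_of_na(n_a, params)
            _, dna = rhs_homogeneous((float(c), n_a), params)
            assert abs(dna) < 1e-8 * max(abs(c) * params.omega_d * n_a, 1.0)

    def test_no_cooperativity_limit_is_decreasing(self):
        # omega = 0: c(n_a) = (n_tot - n_a)/(omega_d n_a)
        p = ModelParams(omega=0.0)
        na = np.linspace(1.0, 699.0, 50)
        c = nullcline_c_of_na(na, p)
        expected = (p.n_tot - na) / (p.omega_d * na)
        np.testing.assert_allclose(c, expected, rtol=1e-12)
        assert np.all(np.diff(c) < 0)

    def test_rejects_nonpositive_na(self, params):
        with pytest.raises(ValueError):
            nullcline_c_of_na(0.0, params)

    def test_tangent_intercept_positive_on_physical_range(self, params):
        # the single-intersection (no bistability) argument
        na = np.linspace(0.0, params.n_tot, 2000)
        assert np.all(nullcline_tangent_intercept(na, params) > 0)


class TestExtremaRoots:
    def test_below_threshold_single_negative_root(self):
        p = ModelParams(omega=26.0 / 700.0 ** 2)
        ext = extrema_roots(p)
        assert not ext.has_three
        assert ext.n_a_minus < 0

    def test_exact_threshold_double_root(self):
        # at omega n_tot^2 = 27 the two positive roots merge at n_tot/3
        # and the negative root sits at -n_tot/6 (checked by substitution)
        p = ModelParams(omega=27.0 / 700.0 ** 2)
        ext = extrema_roots(p)
        assert not ext.has_three          # strict inequality required
        roots = np.sort(ext.roots)
        assert roots[0] == pytest.approx(-700.0 / 6.0, rel=1e-9)
        assert roots[-1] == pytest.approx(700.0 / 3.0, rel=1e-6)

    def test_working_point_roots_satisfy_cubic(self, params):
        ext = extrema_roots(params)
        assert ext.has_three
        w, nt = params.omega, params.n_tot
        for r in ext.roots:
            resid = -nt - 2.0 * w * r ** 3 + w * nt * r ** 2
            assert abs(resid) < 1e-9 * (nt + 2 * w * abs(r) ** 3)
        assert ext.n_a_minus < 0 < ext.n_a_zero <= ext.n_a_plus

    def test_flag_flips_exactly_at_27(self):
        # bisect the composite parameter omega n_tot^2 over the flag
        lo, hi = 1.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if extrema_roots(ModelParams(omega=mid / 700.0 ** 2)).has_three:
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(EXTREMA_THRESHOLD,
                                                abs=1e-6)

    def test_trig_closed_form_matches_numeric(self):
        for x in (27.5, 40.0, 54.0, 100.0, 2940.0):
            p = ModelParams(omega=x / 700.0 ** 2)
            ext = extrema_roots(p)
            plus, zero, minus = extrema_roots_trig(p)
            assert plus == pytest.approx(ext.n_a_plus, rel=1e-9)
            assert zero == pytest.approx(ext.n_a_zero, rel=1e-9)
            assert minus == pytest.approx(ext.n_a_minus, rel=1e-9)

    def test_arcsine_branch_report(self):
        """Neither sign of the arcsine-branch closed form reproduces all
        three numeric roots: the flipped-argument branch recovers the two
        positive roots, the printed sign only the negative one; both
        coincide with the numeric roots at omega n_tot^2 = 54."""
        p = ModelParams()             # omega n_tot^2 = 2940
        ext = extrema_roots(p)
        plus_f, zero_f, _ = extrema_roots_arcsine_branch(p, flip_sign=True)
        assert plus_f == pytest.approx(ext.n_a_plus, rel=1e-9)
        assert zero_f == pytest.approx(ext.n_a_zero, rel=1e-9)
        _, _, minus_p = extrema_roots_arcsine_branch(p, flip_sign=False)
        assert minus_p == pytest.approx(ext.n_a_minus, rel=1e-9)
        p54 = ModelParams(omega=54.0 / 700.0 ** 2)
        ext54 = extrema_roots(p54)
        for flip in (True, False):
            plus, zero, minus = extrema_roots_arcsine_branch(p54, flip)
            assert plus == pytest.approx(ext54.n_a_plus, rel=1e-9)
            assert zero == pytest.approx(ext54.n_a_zero, rel=1e-9)


class TestFixpoint:
    def test_no_inactivation_puts_everything_active(self):
        p = ModelParams(omega_d=0.0)
        fix = find_fixpoint(p)
        assert fix.n_a0 == pytest.approx(p.n_tot)
        assert fix.c0 == pytest.approx(p.alpha * p.n_tot / p.k_d)
        assert fix.n_i0 == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_bisection(self):
        p = ModelParams(omega_d=0.4)
        fix = find_fixpoint(p)
        lo, hi = 0.0, p.n_tot
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _fixpoint_residual(lo, p) * _fixpoint_residual(mid, p) <= 0:
                hi = mid
            else:
                lo = mid
        assert fix.n_a0 == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_consistency_relations(self, params):
        fix = find_fixpoint(params)
        assert fix.c0 == pytest.approx(
            params.alpha * fix.n_a0 / params.k_d)
        assert fix.n_i0 == pytest.approx(params.n_tot - fix.n_a0)
        assert 0 <= fix.n_a0 <= params.n_tot

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(1e-5, 0.1), st.floats(0.05, 0.6),
           st.floats(10.0, 400.0), st.floats(20.0, 1000.0),
           st.floats(50.0, 2000.0))
    def test_unique_sign_change(self, omega, omega_d, k_d, alpha, n_tot):
        """The fixpoint equation has exactly one sign change on
        [0, n_tot] for any valid parameter set."""
        p = ModelParams(omega=omega, omega_d=omega_d, k_d=k_d,
                        alpha=alpha, n_tot=n_tot)
        na = np.linspace(0.0, n_tot, 4000)
        g = np.array([_fixpoint_residual(x, p) for x in na])
        signs = np.sign(g)
        signs = signs[signs != 0]
        assert np.sum(np.diff(signs) != 0) == 1


class TestJacobian:
    def test_trace_determinant_identities(self, params):
        fix = find_fixpoint(params)
        J = jacobian_homogeneous(fix.n_a0, fix.c0, params)
        a = J[1, 1]
        assert np.trace(J) == pytest.approx(a - params.k_d)
        assert np.linalg.det(J) == pytest.approx(
            -params.k_d * a + params.alpha * params.omega_d * fix.n_a0)

    def test_eigenvalues_match_quadratic_formula(self, params):
        fix = find_fixpoint(params)
        J = jacobian_homogeneous(fix.n_a0, fix.c0, params)
        tr, det = np.trace(J), np.linalg.det(J)
        disc = complex(tr * tr - 4.0 * det) ** 0.5
        expected = sorted([(tr + disc) / 2, (tr - disc) / 2],
                          key=lambda s: s.real)
        got = sorted(fix.eigenvalues, key=lambda s: s.real)
        for e, g in zip(expected, got):
            assert g == pytest.approx(e, rel=1e-9)

    def test_frequency_estimate_near_onset(self):
        """For a spiral fixpoint the imaginary part of the eigenvalues is
        sqrt(det - tr^2/4); the onset estimate omega_F =
        sqrt(alpha omega_d n_a0) approximates it when that term dominates
        the trace."""
        p = ModelParams(k_d=80.0, alpha=400.0)
        fix = find_fixpoint(p)
        omega_f = oscillation_frequency_estimate(p, fix.n_a0)
        im = abs(fix.eigenvalues[0].imag)
        J = jacobian_homogeneous(fix.n_a0, fix.c0, p)
        exact = np.sqrt(np.linalg.det(J) - 0.25 * np.trace(J) ** 2)
        assert im == pytest.approx(exact, rel=1e-9)
        assert omega_f == pytest.approx(im, rel=0.2)


class TestClassification:
    @pytest.mark.parametrize("k_d,alpha,expected", [
        (5.0, 50.0, "oscillatory"),
        (80.0, 400.0, "excitable"),
    ])
    def test_phase_portraits(self, k_d, alpha, expected):
        p = ModelParams(k_d=k_d, alpha=alpha)
        assert classify_homogeneous(p) == expected

    def test_no_cooperativity_is_stable(self):
        p = ModelParams(omega=0.0, k_d=80.0, alpha=400.0)
        assert classify_homogeneous(p) == "stable_stationary"

    def test_oscillatory_orbit_does_not_decay(self):
        p = ModelParams(k_d=5.0, alpha=50.0)
        fix = find_fixpoint(p)
        t, y = integrate_ode(
            lambda s: rhs_homogeneous((s[0], s[1]), p),
            [fix.c0 * 1.05, fix.n_a0], (0.0, 60.0), tol=1e-8,
            n_eval=6000)
        c = y[0]
        amp_mid = np.ptp(c[len(c) // 3: 2 * len(c) // 3])
        amp_late = np.ptp(c[2 * len(c) // 3:])
        assert amp_late > 0.5 * amp_mid > 0
        period = limit_cycle_period(t, c)
        assert period > 0

    def test_stable_orbit_decays(self):
        p = ModelParams(omega=0.0)   # guaranteed stable
        fix = find_fixpoint(p)
        t, y = integrate_ode(
            lambda s: rhs_homogeneous((s[0], s[1]), p),
            [fix.c0 * 1.2, fix.n_a0], (0.0, 2.0), tol=1e-8)
        c = y[0]
        assert abs(c[-1] - fix.c0) < 0.01 * abs(c[0] - fix.c0)


class TestFHN:
    @pytest.mark.parametrize("a,I,expected", [
        (2.0, 0.0, "bistable"),
        (0.04, 2.0, "limit_cycle"),
        (0.4, 2.0, "excitable"),
    ])
    def test_reference_phase_portraits(self, a, I, expected):
        assert classify_fhn(FHNParams(a=a, I=I)) == expected

    def test_bistable_intersections(self):
        # a = 2, I = 0: nullclines cross at v = 0 and +/- sqrt(1.5)
        coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / 2.0, 0.0]
        roots = np.sort(np.roots(coeffs).real)
        np.testing.assert_allclose(
            roots, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12)

    def test_rhs_signs(self):
        p = FHNParams(a=0.4, I=2.0)
        dv, dw = fhn_rhs((0.0, 0.0), p)
        assert dv == pytest.approx(2.0)      # I + f(0) = 2
        assert dw == pytest.approx(0.0)


class TestIntegrateOde:
    def test_zero_rhs_constant(self):
        t, y = integrate_ode(lambda s: [0.0], [3.5], (0.0, 1.0), 1e-9)
        np.testing.assert_allclose(y[0], 3.5, rtol=1e-12)

    def test_linear_decay_closed_form(self):
        k = 2.3
        t, y = integrate_ode(lambda s: [-k * s[0]], [1.0], (0.0, 3.0),
                             1e-10)
        np.testing.assert_allclose(y[0], np.exp(-k * t), atol=1e-7)

    def test_ringing_frequency_matches_eigenvalues_near_onset(self):
        """Just below the oscillatory onset the integrated transient rings
        at the linear frequency |Im eigenvalue|.  (The onset itself is
        strongly subcritical in this fast-slow system: immediately past it
        the cycle is a large relaxation oscillation whose period no longer
        reflects the linear one, so the damped spiral side is the regime
        where the eigenvalue oracle applies.)"""
        from scipy.signal import find_peaks
        p = ModelParams(k_d=60.0, alpha=400.0, omega_d=0.32)
        fix = find_fixpoint(p)
        assert max(e.real for e in fix.eigenvalues) < 0
        t, y = integrate_ode(
            lambda s: rhs_homogeneous((s[0], s[1]), p),
            [fix.c0 * 1.001, fix.n_a0], (0.0, 0.6), tol=1e-10,
            n_eval=12000)
        peaks, _ = find_peaks(y[0] - fix.c0)
        period = np.mean(np.diff(t[peaks[:6]]))
        omega_lin = abs(fix.eigenvalues[0].imag)
        assert 2.0 * np.pi / period == pytest.approx(omega_lin, rel=0.10)

    def test_rejects_bad_tolerance(self):
        with pytest.raises(ValueError):
            integrate_ode(lambda s: [0.0], [1.0], (0.0, 1.0), tol=-1.0)
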