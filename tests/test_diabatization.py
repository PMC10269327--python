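"""Diabatic <-> adiabatic transforms and the gauge-fixed pseudodiabatization."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conikit.diabatization import (
    AdiabaticPoint, DiabaticPoint, DegenerateBranchingPlaneError, Gauge,
    adiabatic_from_diabatic, circular_mean, diabatize_history, diabatize_point,
    fit_omega, minimal_plane_rotation, orth_mgs, resolve_h_sign)

from conftest import random_adiabatic_point, random_gauge


def random_diabatic_point(rng, m=5):
    return DiabaticPoint(
        q=rng.normal(size=m), alpha=-78.0 + rng.normal() * 0.3,
        beta=-78.0 + rng.normal() * 0.3, gamma=rng.normal() * 0.2,
        grad_alpha=rng.normal(size=m), grad_beta=rng.normal(size=m),
        grad_gamma=rng.normal(size=m))


class TestAdiabaticFromDiabatic:
    def test_gap_is_closed_form_of_2x2_eigenvalues(self, rng):
        for _ in range(20):
            d = random_diabatic_point(rng)
            p = adiabatic_from_diabatic(d)
            delta = 0.5 * (d.alpha - d.beta)
            assert p.E_A - p.E_B == pytest.approx(
                2.0 * math.hypot(delta, d.gamma), abs=1e-12)
            ev = np.linalg.eigvalsh(np.array([[d.alpha, d.gamma],
                                              [d.gamma, d.beta]]))
            assert p.E_B == pytest.approx(ev[0], abs=1e-12)
            assert p.E_A == pytest.approx(ev[1], abs=1e-12)

    def test_g_and_h_match_numeric_diagonalization(self, rng):
        """g must be the gradient of (E_A - E_B)/2 and h the difference-scaled
        coupling of the frozen linear model, both checked by finite
        differences of the numerically diagonalized 2x2 Hamiltonian."""
        d = random_diabatic_point(rng, m=3)

        def hmat(q):
            dq = q - d.q
            return np.array([
                [d.alpha + d.grad_alpha @ dq, d.gamma + d.grad_gamma @ dq],
                [d.gamma + d.grad_gamma @ dq, d.beta + d.grad_beta @ dq]])

        p = adiabatic_from_diabatic(d)
        eps = 1e-6
        g_fd = np.zeros(3)
        h_fd = np.zeros(3)
        for k in range(3):
            e = np.zeros(3)
            e[k] = eps
            evp, vecp = np.linalg.eigh(hmat(d.q + e))
            evm, vecm = np.linalg.eigh(hmat(d.q - e))
            g_fd[k] = ((evp[1] - evp[0]) - (evm[1] - evm[0])) / (4 * eps)
            # phase-align eigenvectors before differencing for the coupling
            ev0, vec0 = np.linalg.eigh(hmat(d.q))
            for vv in (vecp, vecm):
                for c in range(2):
                    if vv[:, c] @ vec0[:, c] < 0:
                        vv[:, c] *= -1
            dvec_b = (vecp[:, 1] - vecm[:, 1]) / (2 * eps)
            h_fd[k] = (ev0[1] - ev0[0]) * (vec0[:, 0] @ dvec_b)
        assert np.allclose(p.g, g_fd, atol=1e-5)
        assert np.allclose(np.abs(p.h), np.abs(h_fd), atol=1e-4)

    def test_exact_degeneracy_flagged(self):
        m = 3
        grad = np.array([0.1, -0.2, 0.3])
        d = DiabaticPoint(q=np.zeros(m), alpha=-78.0, beta=-78.0, gamma=0.0,
                          grad_alpha=grad, grad_beta=grad,
                          grad_gamma=np.zeros(m))
        p = adiabatic_from_diabatic(d)
        assert p.degenerate
        assert p.E_A == p.E_B == -78.0
        assert np.allclose(p.s, grad)


class TestMinimalPlaneRotation:
    def test_identity_when_already_in_plane(self, rng):
        gauge = random_gauge(rng, m=6)
        g = 0.7 * gauge.k_delta - 0.2 * gauge.k_gamma
        h = 0.4 * gauge.k_delta + 0.9 * gauge.k_gamma
        pr = minimal_plane_rotation(g, h, gauge)
        assert np.allclose(pr.g_prime, g, atol=1e-12)
        assert np.allclose(pr.h_prime, h, atol=1e-12)
        assert pr.singular_values == pytest.approx((1.0, 1.0), abs=1e-12)
        assert pr.conditioning_ok

    def test_orthogonal_planes_flagged(self):
        m = 4
        gauge = Gauge(q_ref=np.zeros(m), k_delta=np.eye(m)[0],
                      k_gamma=np.eye(m)[1])
        with pytest.warns(RuntimeWarning):
            pr = minimal_plane_rotation(np.eye(m)[2], np.eye(m)[3], gauge)
        assert not pr.conditioning_ok
        assert pr.singular_values[0] * pr.singular_values[1] < 1e-12

    def test_rotated_vectors_lie_in_plane(self, rng):
        """Projection residual against a brute-force projector built by
        independent orthonormalization (QR)."""
        for _ in range(10):
            gauge = random_gauge(rng, m=6)
            g, h = rng.normal(size=6), rng.normal(size=6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pr = minimal_plane_rotation(g, h, gauge)
            qmat, _ = np.linalg.qr(
                np.column_stack([gauge.k_delta, gauge.k_gamma]))
            proj = qmat @ qmat.T
            assert np.linalg.norm(pr.g_prime - proj @ pr.g_prime) <= 1e-10
            assert np.linalg.norm(pr.h_prime - proj @ pr.h_prime) <= 1e-10
            # the minimal rotation preserves norms
            assert np.linalg.norm(pr.g_prime) == pytest.approx(
                np.linalg.norm(g), rel=1e-12)

    def test_parallel_g_h_rejected(self, rng):
        gauge = random_gauge(rng, m=4)
        g = rng.normal(size=4)
        with pytest.raises(DegenerateBranchingPlaneError):
            minimal_plane_rotation(g, 2.0 * g, gauge)


class TestCircularMean:
    @pytest.mark.parametrize("x,y,expected", [
        (0.1, 0.3, 0.2),
        (1.7, 1.7, 1.7),
        (-2.0, -2.0, -2.0),
        (3.0, -3.0, math.pi),           # mean crosses the branch cut
        (-0.1, 0.1, 0.0),
    ])
    def test_midpoint_of_short_arc(self, x, y, expected):
        assert circular_mean(x, y) == pytest.approx(expected, abs=1e-12)

    def test_antipodal_tie_break_deterministic(self):
        assert circular_mean(0.0, math.pi) == pytest.approx(math.pi / 2)
        assert circular_mean(1.0, 1.0 + math.pi) == pytest.approx(
            1.0 + math.pi / 2)

    @given(st.floats(-3.0, 3.0), st.floats(-1.5, 1.5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equidistant_on_short_arc(self, x, d):
        mean = circular_mean(x, x + d)
        assert abs(math.remainder(mean - x, 2 * math.pi)) == pytest.approx(
            abs(d) / 2, abs=1e-9)


class TestFitOmega:
    def test_reference_gauge_gives_zero(self, rng):
        gauge = random_gauge(rng, m=5)
        pr = minimal_plane_rotation(1.3 * gauge.k_delta, 0.8 * gauge.k_gamma,
                                    gauge)
        omega, omega_g, omega_h = fit_omega(pr, gauge)
        assert omega == pytest.approx(0.0, abs=1e-12)
        assert omega_g == pytest.approx(0.0, abs=1e-12)
        assert omega_h == pytest.approx(0.0, abs=1e-12)

    def test_matches_moore_penrose_solve_on_linear_data(self, rng, linear_model):
        """On exact linear data the angle fit must reduce to extracting omega
        from pinv([k_delta k_gamma]) [g h]."""
        q_ref = rng.normal(size=linear_model.m)
        ref = linear_model.adiabatic(q_ref)
        gauge = Gauge(q_ref=q_ref, k_delta=ref.g, k_gamma=ref.h)
        kmat = np.column_stack([gauge.k_delta, gauge.k_gamma])
        for _ in range(30):
            p = linear_model.adiabatic(rng.normal(size=linear_model.m))
            pr = minimal_plane_rotation(p.g, p.h, gauge)
            omega, _, _ = fit_omega(pr, gauge)
            rot = np.linalg.pinv(kmat) @ np.column_stack([p.g, p.h])
            omega_ref = math.atan2(rot[1, 0], rot[0, 0])
            assert abs(math.remainder(omega - omega_ref, 2 * math.pi)) <= 1e-10

    @pytest.mark.parametrize("chi", [0.3, -1.2, 2.9, 0.01])
    def test_in_plane_rotation_shifts_omega_by_2chi(self, rng, chi):
        """Wavefunction-rotation covariance: the (g, h) pair of a two-state
        point is an in-plane rotation of the gauge frame; rotating the pair
        by a further 2*chi shifts the fitted omega by exactly 2*chi."""
        gauge = random_gauge(rng, m=5)
        omega_true = 0.7
        c0, s0 = math.cos(omega_true), math.sin(omega_true)
        g = c0 * gauge.k_delta + s0 * gauge.k_gamma
        h = -s0 * gauge.k_delta + c0 * gauge.k_gamma
        omega0, *_ = fit_omega(minimal_plane_rotation(g, h, gauge), gauge)
        c, s = math.cos(2 * chi), math.sin(2 * chi)
        g2 = c * g + s * h
        h2 = -s * g + c * h
        omega2, *_ = fit_omega(minimal_plane_rotation(g2, h2, gauge), gauge)
        assert abs(math.remainder(omega2 - omega0 - 2 * chi,
                                  2 * math.pi)) <= 1e-9


class TestResolveHSign:
    def test_small_disagreement_keeps_h(self, rng):
        h = rng.normal(size=4)
        h_out, flipped = resolve_h_sign(0.0, 0.1, h)
        assert not flipped
        assert np.allclose(h_out, h)

    def test_large_disagreement_flips_h(self, rng):
        h = rng.normal(size=4)
        h_out, flipped = resolve_h_sign(0.0, math.pi - 0.1, h)
        assert flipped
        assert np.allclose(h_out, -h)

    def test_involution(self, rng):
        h = rng.normal(size=4)
        h1, f1 = resolve_h_sign(0.0, 2.0, h)
        assert f1
        h2, f2 = resolve_h_sign(0.0, 2.0 - math.pi, h1)
        assert not f2
        assert np.allclose(h2, -h)


class TestDiabatizePoint:
    def test_round_trip_reproduces_adiabatic_data(self, rng):
        gauge = random_gauge(rng, m=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(50):
                p = random_adiabatic_point(rng, m=6)
                d = diabatize_point(p, gauge)
                r = adiabatic_from_diabatic(d)
                sign = -1.0 if d.h_flipped else 1.0
                scale = max(1.0, abs(p.E_A))
                assert abs(r.E_A - p.E_A) <= 1e-10 * scale
                assert abs(r.E_B - p.E_B) <= 1e-10 * scale
                assert np.allclose(r.s, p.s, atol=1e-10)
                assert np.allclose(r.g, p.g, atol=1e-10)
                assert np.allclose(r.h, sign * p.h, atol=1e-10)
                assert r.E_A - r.E_B >= 0.0

    def test_reference_point_gets_omega_zero(self, rng):
        p = random_adiabatic_point(rng, m=5)
        gauge = Gauge(q_ref=p.q, k_delta=p.g, k_gamma=p.h)
        d = diabatize_point(p, gauge)
        assert d.omega == pytest.approx(0.0, abs=1e-12)
        assert d.gamma == pytest.approx(0.0, abs=1e-12)
        assert d.alpha - d.beta == pytest.approx(p.E_A - p.E_B, abs=1e-12)

    def test_degenerate_branching_plane_rejected(self, rng):
        gauge = random_gauge(rng, m=4)
        p = AdiabaticPoint(q=rng.normal(size=4), E_A=-78.0, E_B=-78.0,
                           s=rng.normal(size=4), g=np.zeros(4),
                           h=np.zeros(4))
        with pytest.raises(DegenerateBranchingPlaneError):
            diabatize_point(p, gauge)


class TestDiabatizeHistory:
    def test_single_point_history(self, rng):
        p = random_adiabatic_point(rng, m=4)
        dpoints, gauge = diabatize_history([p], mode="ci")
        assert len(dpoints) == 1
        assert dpoints[0].omega == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(gauge.q_ref, p.q)

    def test_spin_mode_gamma_identically_zero(self, rng):
        pts = []
        for _ in range(4):
            e_b = -78.0 + rng.normal() * 0.1
            pts.append(AdiabaticPoint(
                q=rng.normal(size=3), E_A=e_b + 0.1, E_B=e_b,
                s=rng.normal(size=3), g=rng.normal(size=3),
                h=np.zeros(3), h_defined=False))
        dpoints, gauge = diabatize_history(pts, mode="spin")
        assert gauge is None
        for d, p in zip(dpoints, pts):
            assert d.gamma == 0.0
            assert np.all(d.grad_gamma == 0.0)
            assert d.alpha == p.E_A and d.beta == p.E_B
            assert np.allclose(d.grad_alpha, p.s + p.g)

    def test_linear_model_gives_global_diabatic_gradients(self, rng, linear_model):
        """Linear diabats are global: every history point must yield the same
        grad alpha, beta, gamma (up to 1e-9)."""
        pts = [linear_model.adiabatic(rng.normal(size=linear_model.m) * 0.5)
               for _ in range(6)]
        dpoints, _ = diabatize_history(pts, mode="ci")
        ref = dpoints[-1]
        for d in dpoints:
            assert np.allclose(d.grad_alpha, ref.grad_alpha, atol=1e-9)
            assert np.allclose(d.grad_beta, ref.grad_beta, atol=1e-9)
            assert np.allclose(d.grad_gamma, ref.grad_gamma, atol=1e-9)

    def test_random_h_phases_leave_diabats_unchanged(self, rng, linear_model):
        """The sign-flip rule makes the diabatic surfaces independent of the
        per-point phase of h (the reference point's phase fixes the gauge and
        is held; flipping it too just reverses the sign of gamma globally)."""
        pts = [linear_model.adiabatic(rng.normal(size=linear_model.m) * 0.5)
               for _ in range(8)]
        d_ref, _ = diabatize_history(pts, mode="ci")
        flip = rng.random(len(pts)) < 0.5
        flip[-1] = False  # keep the gauge reference phase
        flipped_pts = [
            AdiabaticPoint(q=p.q, E_A=p.E_A, E_B=p.E_B, s=p.s, g=p.g,
                           h=-p.h if f else p.h)
            for p, f in zip(pts, flip)]
        d_flip, _ = diabatize_history(flipped_pts, mode="ci")
        for a, b in zip(d_ref, d_flip):
            assert a.alpha == pytest.approx(b.alpha, abs=1e-9)
            assert a.beta == pytest.approx(b.beta, abs=1e-9)
            assert a.gamma == pytest.approx(b.gamma, abs=1e-9)
            assert np.allclose(a.grad_gamma, b.grad_gamma, atol=1e-9)

    def test_reference_phase_flip_is_a_pure_gauge_change(self, rng, linear_model):
        """Reversing the reference h flips gamma's sign everywhere while the
        reconstructed adiabatic surfaces are untouched."""
        pts = [linear_model.adiabatic(rng.normal(size=linear_model.m) * 0.5)
               for _ in range(5)]
        d_ref, _ = diabatize_history(pts, mode="ci")
        pts2 = pts[:-1] + [AdiabaticPoint(
            q=pts[-1].q, E_A=pts[-1].E_A, E_B=pts[-1].E_B, s=pts[-1].s,
            g=pts[-1].g, h=-pts[-1].h)]
        d2, _ = diabatize_history(pts2, mode="ci")
        for a, b in zip(d_ref, d2):
            assert a.gamma == pytest.approx(-b.gamma, abs=1e-9)
            assert a.alpha == pytest.approx(b.alpha, abs=1e-9)
            ra, rb = adiabatic_from_diabatic(a), adiabatic_from_diabatic(b)
            assert ra.E_A == pytest.approx(rb.E_A, abs=1e-10)
            assert ra.E_B == pytest.approx(rb.E_B, abs=1e-10)

    def test_gauge_rotation_covariance_of_history(self, rng, linear_model):
        """Rotating (g, h) at every point by the same 2*chi shifts every
        fitted omega by 2*chi and leaves the reconstructed adiabats alone."""
        chi = 0.45
        pts = [linear_model.adiabatic(rng.normal(size=linear_model.m) * 0.5)
               for _ in range(5)]
        gauge = Gauge(q_ref=pts[-1].q, k_delta=pts[-1].g, k_gamma=pts[-1].h)
        c, s = math.cos(2 * chi), math.sin(2 * chi)
        for p in pts:
            d0 = diabatize_point(p, gauge)
            p_rot = AdiabaticPoint(q=p.q, E_A=p.E_A, E_B=p.E_B, s=p.s,
                                   g=c * p.g + s * p.h, h=-s * p.g + c * p.h)
            d1 = diabatize_point(p_rot, gauge)
            assert abs(math.remainder(d1.omega - d0.omega - 2 * chi,
                                      2 * math.pi)) <= 1e-9
            r0, r1 = adiabatic_from_diabatic(d0), adiabatic_from_diabatic(d1)
            assert r0.E_A == pytest.approx(r1.E_A, abs=1e-10)
            assert r0.E_B == pytest.approx(r1.E_B, abs=1e-10)

    def test_model_diabats_recovered_up_to_constant_rotation(self, rng, linear_model):
        """Against the model's own diabats: magnitudes match and the angular
        offset is one constant in-plane rotation shared by all points."""
        pts = [linear_model.adiabatic(rng.normal(size=linear_model.m) * 0.5)
               for _ in range(8)]
        dpoints, _ = diabatize_history(pts, mode="ci")
        offsets = []
        for d in dpoints:
            delta_m = linear_model.k_delta @ d.q
            gamma_m = linear_model.k_gamma @ d.q
            delta = 0.5 * (d.alpha - d.beta)
            assert math.hypot(delta, d.gamma) == pytest.approx(
                math.hypot(delta_m, gamma_m), abs=1e-9)
            if math.hypot(delta_m, gamma_m) > 1e-6:
                offsets.append(math.remainder(
                    math.atan2(d.gamma, delta)
                    - math.atan2(gamma_m, delta_m), 2 * math.pi))
        assert np.ptp([math.remainder(o - offsets[0], 2 * math.pi)
                       for o in offsets]) <= 1e-8


def test_orth_mgs_produces_orthonormal_columns(rng):
    a = rng.normal(size=(7, 3))
    q = orth_mgs(a)
    assert np.allclose(q.T @ q, np.eye(3), atol=1e-12)
    # column span preserved
    assert np.linalg.matrix_rank(np.column_stack([a, q])) == 3
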