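"""Pinning ODE: equilibria, tear-off, stability — with brute-force oracles."""

import numpy as np
import pytest

from borderzone.drift_ode import (
    DriftModel, assess_stability, drift_rhs, find_equilibria,
    integrate_drift, superpose, tear_off_threshold)
from borderzone.force_estimation import SpecificForce


def exp_model(hg=np.exp(-2.0), delta_alpha=1.0, d_max=10.0,
              n_samples=12001):
    # dense sampling keeps the monotone-cubic interpolation error of
    # e^{-d} below 1e-12 so the analytic radius is recovered to 1e-10
    d = np.linspace(0.5, d_max, n_samples)
    return DriftModel(f_grad=hg + 0.0j, delta_alpha=delta_alpha, d=d,
                      f_r=-np.exp(-d), f_theta=np.zeros_like(d))


def humped_model(hg=0.15, delta_alpha=-1.0):
    # attraction rising to a hump then decaying: supports stable pinning
    d = np.linspace(0.05, 12.0, 2400)
    return DriftModel(f_grad=hg + 0.0j, delta_alpha=delta_alpha, d=d,
                      f_r=-d * np.exp(-d), f_theta=np.zeros_like(d))


def random_model(rng, attracting=None):
    """Smooth random two-exponential interaction curve plus drag."""
    d = np.linspace(0.4, 12.0, 500)
    a1, a2 = rng.uniform(0.3, 1.5), rng.uniform(0.0, 0.5)
    b1, b2 = rng.uniform(0.3, 1.2), rng.uniform(0.05, 0.25)
    sgn = -1.0
    f_r = sgn * (a1 * np.exp(-b1 * d) + a2 * np.exp(-b2 * d))
    f_t = rng.uniform(-0.5, 0.5) * np.exp(-rng.uniform(0.2, 0.8) * d)
    da = rng.choice([-1.0, 1.0]) if attracting is None else \
        (-1.0 if attracting else 1.0)
    m_max = np.max(np.hypot(f_r, f_t))
    hg = rng.uniform(0.05, 0.95) * m_max
    gamma = rng.uniform(0, 2 * np.pi)
    return DriftModel(f_grad=hg * np.exp(1j * gamma), delta_alpha=da,
                      d=d, f_r=f_r, f_theta=f_t)


class TestDriftRhs:
    def test_pure_gradient_when_no_contrast(self):
        m = exp_model(delta_alpha=0.0)
        for z in (1 + 1j, -3 + 0.5j, 2 - 4j):
            assert drift_rhs(z, m) == pytest.approx(m.f_grad)

    def test_zero_everything_gives_zero(self):
        d = np.linspace(0.5, 5, 50)
        m = DriftModel(f_grad=0j, delta_alpha=1.0, d=d,
                       f_r=np.zeros_like(d), f_theta=np.zeros_like(d))
        assert drift_rhs(2.0 + 1.0j, m) == 0.0

    def test_singular_at_origin(self):
        with pytest.raises(ZeroDivisionError):
            drift_rhs(0.0 + 0.0j, exp_model())

    def test_complex_equals_polar_form(self):
        """dR/dt in complex form == (dr/dt, r dtheta/dt) recombined."""
        rng = np.random.default_rng(11)
        m = random_model(rng)
        for _ in range(100):
            r = rng.uniform(m.d[0] + 0.1, m.d[-1] - 0.1)
            th = rng.uniform(0, 2 * np.pi)
            z = r * np.exp(1j * th)
            v = drift_rhs(z, m)
            fr, ft = m.interaction(r)
            hg, gamma = m.hg, m.gamma
            dr = hg * np.cos(gamma - th) - m.delta_alpha * float(fr)
            rdth = hg * np.sin(gamma - th) - m.delta_alpha * float(ft)
            v_polar = (dr + 1j * rdth) * np.exp(1j * th)
            assert v == pytest.approx(v_polar, abs=1e-12)


class TestTearOff:
    def test_zero_curve(self):
        d = np.linspace(0.5, 5, 50)
        m = DriftModel(f_grad=1j, delta_alpha=2.0, d=d,
                       f_r=np.zeros_like(d), f_theta=np.zeros_like(d))
        assert tear_off_threshold(m) == 0.0

    def test_monotone_max_at_left_end(self):
        m = exp_model()
        assert tear_off_threshold(m) == pytest.approx(np.exp(-0.5),
                                                      rel=1e-6)

    def test_linear_in_contrast(self):
        m1 = exp_model(delta_alpha=1.0)
        m2 = exp_model(delta_alpha=2.0)
        assert tear_off_threshold(m2) == pytest.approx(
            2 * tear_off_threshold(m1))


class TestFindEquilibria:
    def test_analytic_exponential_radius(self):
        # |da| e^{-r} = e^{-2}  ->  r* = 2 exactly
        eqs = find_equilibria(exp_model())
        radii = sorted(e.radius for e in eqs)
        assert any(abs(r - 2.0) < 1e-10 for r in radii)

    def test_empty_above_tear_off(self):
        m = exp_model(hg=1.0)
        assert tear_off_threshold(m) < 1.0
        assert find_equilibria(m) == []

    def test_residuals_verified(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_model(rng)
            for eq in find_equilibria(m):
                assert abs(drift_rhs(eq.position, m)) <= \
                    1e-10 * max(m.hg, tear_off_threshold(m)) + 1e-13

    def test_matches_brute_force_scan(self):
        """Oracle: dense polar grid scan for |velocity| minima."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = random_model(rng)
            eqs = find_equilibria(m)
            rr = np.linspace(m.d[0], m.d[-1], 900)
            th = np.linspace(0, 2 * np.pi, 540, endpoint=False)
            z = rr[:, None] * np.exp(1j * th[None, :])
            fr, ft = m.interaction(rr)
            speed = np.abs(m.f_grad
                           - m.delta_alpha * (fr + 1j * ft)[:, None]
                           * z / rr[:, None])
            dr = rr[1] - rr[0]
            dth = th[1] - th[0]
            vmax = max(m.hg, tear_off_threshold(m))
            # near-zero-velocity cells of the scan
            hits = z[speed < 2.0 * vmax * max(dr, m.d[-1] * dth)]
            for eq in eqs:
                assert np.min(np.abs(hits - eq.position)) < 0.1 \
                    if len(hits) else False
            # conversely every tight cluster of hits has an equilibrium
            if len(eqs) == 0:
                assert np.min(speed) > 0.01 * vmax

    def test_existence_iff_below_tear_off(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            m = random_model(rng)
            eqs = find_equilibria(m)
            hc = tear_off_threshold(m)
            if m.hg < 0.98 * hc:
                assert len(eqs) >= 1
            if m.hg > 1.02 * hc:
                assert len(eqs) == 0

    def test_at_least_two_equilibria_for_humped_curve(self):
        # interaction rising then decaying: the balance is crossed twice
        d = np.linspace(0.2, 12, 600)
        f_r = -d * np.exp(-d)
        m = DriftModel(f_grad=0.5 * np.max(np.abs(f_r)) + 0j,
                       delta_alpha=1.0, d=d, f_r=f_r,
                       f_theta=np.zeros_like(d))
        assert len(find_equilibria(m)) >= 2


class TestStability:
    def test_attracting_hump_stable_inside_maximum(self):
        # attracting disk (da < 0): the equilibrium on the rising branch
        # of the interaction curve (left of its maximum at d = 1) is
        # stable, the outer one is not
        m = humped_model()
        eqs = sorted(find_equilibria(m), key=lambda e: e.radius)
        assert len(eqs) >= 2
        inner = assess_stability(m, eqs[0])
        outer = assess_stability(m, eqs[-1])
        assert inner.radius < 1.0 < outer.radius
        assert inner.stable is True
        assert outer.stable is False

    def test_monotone_attracting_curve_has_no_stable_pinning(self):
        # monotone decaying attraction balanced against constant drag is
        # radially unstable everywhere
        m = exp_model(delta_alpha=-1.0)
        eqs = find_equilibria(m)
        assert eqs
        for e in eqs:
            assert assess_stability(m, e).stable is False

    def test_repelling_monotone_curve_unstable(self):
        eqs = find_equilibria(exp_model())   # da > 0, repelling
        assert eqs
        for e in eqs:
            assess_stability(m := exp_model(), e)
            assert e.stable is False

    def test_conditions_match_jacobian_on_random_curves(self):
        """The two closed-form conditions agree with the numerical
        Jacobian in every non-marginal case (assess_stability raises on
        disagreement)."""
        rng = np.random.default_rng(99)
        n_eq = 0
        for _ in range(100):
            m = random_model(rng)
            for eq in find_equilibria(m):
                if not (m.d[0] + 0.05 < eq.radius < m.d[-1] - 0.05):
                    continue
                assess_stability(m, eq)
                n_eq += 1
        assert n_eq >= 60   # the ensemble actually exercised the check

    def test_stability_confirmed_by_integration(self):
        """Independent oracle: trajectories converge to stable equilibria
        and leave unstable ones."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(30):
            m = random_model(rng)
            for eq in find_equilibria(m):
                if not (m.d[0] + 0.1 < eq.radius < m.d[-1] - 0.1):
                    continue
                eq = assess_stability(m, eq)
                if eq.marginal or eq.stable is None:
                    continue
                slowest = max(abs(eq.eigenvalues.real).min(), 1e-4)
                horizon = min(5.0 / slowest, 1e6)
                z0 = eq.position * (1 + 1e-3) + 1e-3j
                tr = integrate_drift(m, z0, horizon)
                dev = abs(tr.z[-1] - eq.position)
                if eq.stable:
                    assert dev < 1e-2 * max(abs(eq.position), 1.0)
                else:
                    assert dev > 2e-3 * max(abs(eq.position), 1.0)
                checked += 1
                if checked >= 12:
                    return
        assert checked > 0

    def test_non_equilibrium_rejected(self):
        m = exp_model()
        from borderzone.drift_ode import Equilibrium
        fake = Equilibrium(radius=3.3, angle=0.0, position=3.3 + 0j)
        with pytest.raises(ValueError):
            assess_stability(m, fake)


class TestIntegrateDrift:
    def test_stay_at_stable_equilibrium(self):
        m = humped_model()
        eq = next(e for e in find_equilibria(m)
                  if assess_stability(m, e).stable)
        tr = integrate_drift(m, eq.position, 500.0)
        assert np.all(np.abs(tr.z - eq.position) < 1e-8)

    def test_tolerance_convergence(self):
        m = exp_model(hg=0.8)   # above tear-off: free drift
        tr1 = integrate_drift(m, 3 + 1j, 20.0, rtol=1e-8)
        tr2 = integrate_drift(m, 3 + 1j, 20.0, rtol=4e-9, atol=5e-11)
        length = np.sum(np.abs(np.diff(tr1.z))) + 1e-12
        assert abs(tr1.z[-1] - tr2.z[-1]) < 1e-6 * length + 1e-9

    def test_escape_event_recorded(self):
        m = exp_model(hg=1.0)
        tr = integrate_drift(m, 1 + 0j, 500.0)
        assert tr.escaped
        assert tr.events and tr.events[0][0] == "escape"


class TestSuperpose:
    def test_identity(self):
        f = SpecificForce(value=0.3 + 0.2j, uncertainty=0.01,
                          convention="c", chirality=-1)
        assert superpose([(1.0, f)]) == f.value

    def test_cancellation(self):
        f = SpecificForce(value=0.3 + 0.2j, uncertainty=0.01,
                          convention="c", chirality=-1)
        assert superpose([(1.0, f), (-1.0, f)]) == 0.0

    def test_random_triples_componentwise(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mags = rng.standard_normal(3)
            vals = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            expected = np.sum(mags * vals)
            got = superpose(list(zip(mags, vals)))
            assert got == pytest.approx(expected, abs=1e-15)

    def test_mixed_chirality_rejected(self):
        f1 = SpecificForce(value=1j, uncertainty=0.1, convention="c",
                           chirality=1)
        f2 = SpecificForce(value=1j, uncertainty=0.1, convention="c",
                           chirality=-1)
        with pytest.raises(ValueError):
            superpose([(1.0, f1), (1.0, f2)])
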