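"""Grid, border-zone profiles, heterogeneity and coupling operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from borderzone.tissue_model import (
    BorderZoneConfig, GridSpec, HeterogeneityField, ParameterFields,
    build_parameter_fields, coupling_term, profile_D, profile_alpha,
    sample_heterogeneity)


@pytest.fixture
def cfg():
    return BorderZoneConfig(D0=0.01, Dmin=0.001, alpha_top=0.4,
                            alpha_bottom=0.0, y1_0=1.0, y2_0=2.0, u=-0.002)


class TestGridSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            GridSpec(nx=2, ny=10)
        with pytest.raises(ValueError):
            GridSpec(nx=10, ny=10, h=0.0)

    def test_shape_and_ndim(self):
        assert GridSpec(nx=5, ny=4).shape == (4, 5)
        assert GridSpec(nx=5, ny=4, nz=3).shape == (4, 5, 3)
        assert GridSpec(nx=5, ny=4).ndim == 2
        assert GridSpec(nx=5, ny=4, nz=3).ndim == 3


class TestProfiles:
    def test_clamp_below(self, cfg):
        t = 100.0
        assert profile_D(cfg.y1(t) - 1.0, t, cfg) == cfg.Dmin
        assert profile_alpha(cfg.y1(t) - 5.0, t, cfg) == cfg.alpha_bottom

    def test_clamp_above(self, cfg):
        t = 100.0
        assert profile_D(cfg.y2(t) + 1.0, t, cfg) == cfg.D0
        assert profile_alpha(cfg.y2(t) + 5.0, t, cfg) == cfg.alpha_top

    def test_linear_midpoint(self, cfg):
        t = 37.0
        mid = 0.5 * (cfg.y1(t) + cfg.y2(t))
        assert profile_D(mid, t, cfg) == pytest.approx(
            0.5 * (cfg.Dmin + cfg.D0))

    def test_moving_frame_identity(self, cfg):
        # a feature riding the border at y(t) moves to y + u dt by t + dt
        y, t, dt = 1.3, 50.0, 123.0
        assert profile_alpha(y, t, cfg) == pytest.approx(
            profile_alpha(y + cfg.u * dt, t + dt, cfg), abs=1e-12)

    def test_monotone_ramp(self, cfg):
        y = np.linspace(-1, 5, 500)
        d = profile_D(y, 0.0, cfg)
        assert np.all(np.diff(d) >= 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            BorderZoneConfig(D0=0.01, Dmin=0.02, alpha_top=0.4,
                             alpha_bottom=0.0, y1_0=0.0, y2_0=1.0)
        with pytest.raises(ValueError):
            BorderZoneConfig(D0=0.01, Dmin=0.0, alpha_top=0.4,
                             alpha_bottom=0.0, y1_0=1.0, y2_0=1.0)


class TestHeterogeneity:
    def test_determinism(self):
        grid = GridSpec(nx=20, ny=15)
        h1 = sample_heterogeneity(grid, 0.1, seed=42)
        h2 = sample_heterogeneity(grid, 0.1, seed=42)
        np.testing.assert_array_equal(h1.xi, h2.xi)

    def test_zero_intensity_gives_pure_profile(self, cfg):
        grid = GridSpec(nx=10, ny=40, h=0.1)
        het = sample_heterogeneity(grid, 0.0, seed=1)
        pf = build_parameter_fields(grid, cfg, het, t=0.0)
        expected = np.clip(profile_alpha(grid.y_coords(), 0.0, cfg),
                           0.0, 1.0 - 1e-9)
        np.testing.assert_allclose(pf.alpha_cell,
                                   expected[:, None] * np.ones((1, 10)))

    def test_sample_std_within_chi2_bound(self):
        # for n = 10^4 i.i.d. normals the sample std lies within 5% of
        # the true value far beyond the 99.99% level
        grid = GridSpec(nx=100, ny=100)
        nu = 0.2
        het = sample_heterogeneity(grid, nu, seed=7)
        assert abs(np.std(nu * het.xi) - nu) < 0.05 * nu

    def test_negative_nu_rejected(self):
        with pytest.raises(ValueError):
            sample_heterogeneity(GridSpec(nx=5, ny=5), -0.1, seed=0)

    def test_alpha_clamped(self, cfg):
        grid = GridSpec(nx=50, ny=50, h=0.1)
        het = sample_heterogeneity(grid, 5.0, seed=3)
        pf = build_parameter_fields(grid, cfg, het, t=0.0)
        assert np.all(pf.alpha_cell >= 0.0)
        assert np.all(pf.alpha_cell < 1.0)


def _random_fields(grid, rng, d_scale=0.01):
    d = rng.uniform(0.0, d_scale, size=grid.shape)
    a = rng.uniform(0.0, 0.6, size=grid.shape)
    return ParameterFields(D=d, alpha_cell=a)


class TestCoupling:
    def test_uniform_voltage_gives_zero(self):
        grid = GridSpec(nx=8, ny=6)
        pf = _random_fields(grid, np.random.default_rng(0))
        v = np.full(grid.shape, -40.0)
        np.testing.assert_allclose(coupling_term(v, pf, grid), 0.0)

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_grid_sum_vanishes(self, seed):
        rng = np.random.default_rng(seed)
        grid = GridSpec(nx=9, ny=7)
        pf = _random_fields(grid, rng)
        v = rng.uniform(-90, 30, size=grid.shape)
        out = coupling_term(v, pf, grid)
        scale = np.max(np.abs(out)) + 1e-30
        assert abs(np.sum(out)) / scale < 1e-10

    def test_grid_sum_vanishes_3d(self):
        rng = np.random.default_rng(5)
        grid = GridSpec(nx=6, ny=5, nz=4)
        pf = _random_fields(grid, rng)
        v = rng.uniform(-90, 30, size=grid.shape)
        out = coupling_term(v, pf, grid)
        assert abs(np.sum(out)) / (np.max(np.abs(out)) + 1e-30) < 1e-10

    def test_two_cell_antisymmetry(self):
        grid = GridSpec(nx=3, ny=3, h=0.5)
        d = np.full(grid.shape, 0.02)
        pf = ParameterFields(D=d, alpha_cell=np.zeros(grid.shape))
        v = np.full(grid.shape, -80.0)
        v[1, 2] = -60.0
        out = coupling_term(v, pf, grid)
        # flux between (1,1) and (1,2): g = 0.02, dV = 20 mV, h^2 = 0.25
        assert out[1, 1] == pytest.approx(0.02 * 20.0 / 0.25)

    def test_zero_diffusivity_isolates_cell(self):
        rng = np.random.default_rng(1)
        grid = GridSpec(nx=7, ny=7)
        d = rng.uniform(0.001, 0.01, size=grid.shape)
        d[3, 3] = 0.0
        pf = ParameterFields(D=d, alpha_cell=np.zeros(grid.shape))
        v = rng.uniform(-90, 30, size=grid.shape)
        for rule in ("arithmetic", "harmonic"):
            out = coupling_term(v, pf, grid, rule=rule)
            assert out[3, 3] == 0.0
            # and the isolated cell's voltage does not influence others
            v2 = v.copy()
            v2[3, 3] += 55.0
            np.testing.assert_array_equal(
                np.delete(coupling_term(v2, pf, grid, rule=rule), 24),
                np.delete(out, 24))

    def test_shape_mismatch_raises(self):
        grid = GridSpec(nx=5, ny=5)
        pf = _random_fields(grid, np.random.default_rng(2))
        with pytest.raises(ValueError):
            coupling_term(np.zeros((4, 5)), pf, grid)

    def test_invalid_parameter_fields(self):
        with pytest.raises(ValueError):
            ParameterFields(D=np.full((3, 3), -1.0),
                            alpha_cell=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ParameterFields(D=np.zeros((3, 3)),
                            alpha_cell=np.ones((3, 3)))
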