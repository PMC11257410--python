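"""Single-layer potentials, quadrature and the localization bound."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from oxsplit2d import (
    BoundarySpec,
    Source,
    build_grid,
    build_neighborhoods,
    localization_error_bound,
    rapid_field,
    unit_potential,
)
from oxsplit2d.potentials import unit_potential_grad
from oxsplit2d.quadrature import line_quadrature, simpson_nodes_weights, tensor_cell_rule

D = 2000.0
R = 4.8


class TestPotential:
    def test_closed_form_values(self):
        c = np.array([0.0, 0.0])
        # zero on the wall and inside
        pts = np.array([[R, 0.0], [0.5 * R, 0.0], [0.0, 0.0]])
        assert np.allclose(unit_potential(pts, c, R, D), 0.0)
        # q = 2 pi D at rho = e R gives exactly -1 concentration unit
        v = unit_potential(np.array([[math.e * R, 0.0]]), c, R, D)[0]
        assert v * 2 * math.pi * D == pytest.approx(-1.0, rel=1e-12)

    def test_gradient_matches_finite_difference(self):
        c = np.array([10.0, -3.0])
        rng = np.random.default_rng(1)
        pts = c + rng.uniform(2 * R, 10 * R, (20, 2)) * rng.choice([-1, 1], (20, 2))
        grad = unit_potential_grad(pts, c, R, D)
        eps = 1e-4
        for i, p in enumerate(pts):
            fd = np.array([
                (unit_potential(p + [eps, 0], c, R, D) - unit_potential(p - [eps, 0], c, R, D))[0],
                (unit_potential(p + [0, eps], c, R, D) - unit_potential(p - [0, eps], c, R, D))[0],
            ]) / (2 * eps)
            assert np.allclose(grad[i], fd, atol=1e-9)

    def test_harmonic_away_from_disk(self):
        # 5-point discrete Laplacian of g vanishes at O(delta^2)
        c = np.array([0.0, 0.0])
        p = np.array([30.0, 17.0])
        for delta in (1.0, 0.5):
            stencil = np.array([[delta, 0], [-delta, 0], [0, delta], [0, -delta]])
            lap = (unit_potential(p + stencil, c, R, D).sum()
                   - 4 * unit_potential(p[None, :], c, R, D)[0]) / delta ** 2
            assert abs(lap) < 1e-9

    def test_zero_net_flux_through_external_wall(self):
        # conservativeness: a potential centered outside a disk drives no
        # net flux through that disk's wall (harmonic inside)
        c_far = np.array([100.0, 0.0])
        wall_c = np.array([0.0, 0.0])
        theta = np.linspace(0, 2 * np.pi, 2001)[:-1]
        pts = wall_c + R * np.column_stack([np.cos(theta), np.sin(theta)])
        n = (pts - wall_c) / R
        grad = unit_potential_grad(pts, c_far, R, D)
        flux = (grad * n).sum(axis=1).mean() * 2 * np.pi * R
        assert abs(flux) < 1e-12


class TestRapidField:
    def test_empty_neighborhood_is_zero(self):
        g = build_grid(240.0, 5, BoundarySpec.dirichlet(0.0))
        src = Source((120.0, 120.0), R, 137.0, 2000.0)
        nb = build_neighborhoods(g, [src], 3)
        val, grad = rapid_field(nb, 0, np.array([1e5]), np.array([[24.0, 24.0]]), D,
                                gradient=True)
        assert val[0] == 0.0 and np.allclose(grad, 0.0)

    def test_two_source_superposition(self):
        g = build_grid(240.0, 5, BoundarySpec.dirichlet(0.0))
        s1 = Source((110.0, 120.0), R, 137.0, 2000.0)
        s2 = Source((130.0, 120.0), R, 0.0, 2000.0)
        nb = build_neighborhoods(g, [s1, s2], 3)
        q = np.array([2.0e5, -1.0e5])
        x = np.array([[150.0, 150.0]])
        k = g.locate_cell((120.0, 120.0))
        val = rapid_field(nb, k, q, x, D)
        expect = (q[0] * unit_potential(x, s1.xy, R, D)
                  + q[1] * unit_potential(x, s2.xy, R, D))
        assert val[0] == pytest.approx(expect[0], rel=1e-14)


class TestLocalizationBound:
    def test_zero_when_all_sources_local(self):
        g = build_grid(240.0, 5, BoundarySpec.dirichlet(0.0))
        src = Source((120.0, 120.0), R, 137.0, 2000.0)
        nb = build_neighborhoods(g, [src], 5)
        assert localization_error_bound(nb, np.array([1e5]), D=D)[0] == 0.0

    def test_quartering_with_doubled_width(self):
        g = build_grid(240.0, 15, BoundarySpec.dirichlet(0.0))
        s1 = Source((24.0, 120.0), R, 137.0, 2000.0)
        s2 = Source((216.0, 120.0), R, 0.0, 2000.0)
        q = np.array([1.0e5, -1.0e5])
        b3 = localization_error_bound(build_neighborhoods(g, [s1, s2], 3), q, D=D)
        b5 = localization_error_bound(build_neighborhoods(g, [s1, s2], 5), q, D=D)
        # (n-1) doubles from 2 to 4 -> bound quarters
        assert b3[0] == pytest.approx(4.0 * b5[0], rel=1e-12)
        assert (b3 >= 0).all()


class TestQuadrature:
    def test_simpson_weights_normalized(self):
        for n in (3, 11, 21):
            t, w = simpson_nodes_weights(n)
            assert w.sum() == pytest.approx(1.0, rel=1e-14)
        with pytest.raises(ValueError):
            simpson_nodes_weights(4)

    def test_line_quadrature_matches_adaptive(self):
        p0, p1 = np.array([0.0, 0.0]), np.array([10.0, 0.0])

        def f(pts):
            return np.exp(-0.3 * pts[:, 0]) * np.sin(pts[:, 0])

        ref, _ = quad(lambda x: math.exp(-0.3 * x) * math.sin(x), 0, 10)
        val = line_quadrature(f, p0, p1, n0=11, tol=1e-12, max_doublings=8)
        assert val == pytest.approx(ref, rel=1e-9)

    def test_near_singular_refinement(self):
        # integrand peaked at distance 0.5 from the segment: the doubling
        # refinement must resolve it to the requested tolerance
        p0, p1 = np.array([0.0, 0.0]), np.array([48.0, 0.0])
        yc = 0.5

        def f(pts):
            return 1.0 / ((pts[:, 0] - 24.0) ** 2 + yc ** 2)

        ref, _ = quad(lambda x: 1.0 / ((x - 24.0) ** 2 + yc ** 2), 0, 48, limit=200)
        val = line_quadrature(f, p0, p1, n0=11, tol=1e-9, max_doublings=8)
        assert val == pytest.approx(ref, rel=1e-6)

    def test_tensor_rule_area_and_polynomial(self):
        pts, w = tensor_cell_rule(2.0, 3.0, 48.0, 11)
        assert w.sum() == pytest.approx(48.0 ** 2, rel=1e-13)
        # exact for cubics in each variable
        val = (w * (pts[:, 0] ** 3 * pts[:, 1])).sum()
        exact = (50.0 ** 4 - 2.0 ** 4) / 4 * (51.0 ** 2 - 3.0 ** 2) / 2
        assert val == pytest.approx(exact, rel=1e-13)
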