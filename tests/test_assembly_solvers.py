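"""Block-system assembly, linear solves and Newton iteration."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from oxsplit2d import (
    BoundarySpec,
    Neumann,
    PhysicalParams,
    Source,
    assemble_system,
    build_grid,
    build_neighborhoods,
    metabolic_vector,
    solve_nonreactive,
    solve_reactive,
)
from oxsplit2d.assembly import IllPosedError

D = 2000.0
KEFF = 2000.0
R = 4.8
L = 240.0


class TestAssembly:
    def test_constant_dirichlet_no_sources(self):
        g = build_grid(L, 5, BoundarySpec.dirichlet(7.0))
        nb = build_neighborhoods(g, [], 3)
        st = solve_nonreactive(assemble_system(g, [], nb, PhysicalParams()))
        assert np.allclose(st.s, 7.0, atol=1e-12)

    def test_system_size_and_sparsity(self):
        g = build_grid(L, 5, BoundarySpec.dirichlet(0.0))
        src = Source((120.0, 120.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        b = assemble_system(g, [src], nb, PhysicalParams())
        assert b.full_matrix().shape == (26, 26)  # F + S unknowns
        row_nnz = np.diff(b.A.tocsr().indptr)
        assert row_nnz.max() <= 5
        assert np.diff(b.C.tocsr().indptr).max() <= 4

    def test_ill_posed_rejected(self):
        g = build_grid(L, 5, BoundarySpec(left=Neumann(), right=Neumann(),
                                          bottom=Neumann(), top=Neumann()))
        nb = build_neighborhoods(g, [], 3)
        with pytest.raises(IllPosedError):
            assemble_system(g, [], nb, PhysicalParams())

    def test_manufactured_monopole_exact_with_full_block(self, monopole):
        # with the neighborhood covering the whole grid the splitting
        # reproduces the single-source field exactly: s == 0, q == q*
        _, st = monopole.solve(cells=5, n=5)
        assert abs(st.q[0] - monopole.q_exact) / monopole.q_exact < 1e-12
        assert np.max(np.abs(st.s)) < 1e-10

    def test_manufactured_monopole_offcenter_localized(self, offcenter_monopole):
        # with a 3x3 neighborhood the slow field carries the log tail;
        # the wall flux stays within the coarse-grid error level
        _, st = offcenter_monopole.solve(cells=5, n=3)
        assert abs(st.q[0] - offcenter_monopole.q_exact) / offcenter_monopole.q_exact < 5e-3


class TestConservation:
    def test_periodic_single_source_equilibrates(self):
        g = build_grid(L, 8, BoundarySpec.periodic())
        src = Source((30.0, 30.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        st = solve_nonreactive(assemble_system(g, [src], nb, PhysicalParams()))
        assert abs(st.q[0]) < 1e-6 * KEFF * 137.0
        assert np.ptp(st.s) < 1e-9

    def test_periodic_dipole_flux_balance(self):
        g = build_grid(L, 8, BoundarySpec.periodic())
        s1 = Source((10.0, 120.0), R, 137.0, KEFF)
        s2 = Source((230.0, 120.0), R, 0.0, KEFF)
        nb = build_neighborhoods(g, [s1, s2], 5)
        st = solve_nonreactive(assemble_system(g, [s1, s2], nb, PhysicalParams()))
        assert abs(st.q.sum()) < 1e-9 * np.abs(st.q).max()
        assert st.q[0] > 0 > st.q[1]

    def test_dirichlet_total_flux_matches_sources(self):
        # discrete conservation: sum q equals the TPFA flux of s + r
        # through the Dirichlet boundary
        g = build_grid(L, 5, BoundarySpec.dirichlet(0.0))
        src = Source((100.0, 130.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        blocks = assemble_system(g, [src], nb, PhysicalParams())
        st = solve_nonreactive(blocks)
        # row-sum identity: summing all cell balances telescopes interior
        # fluxes; the boundary terms must absorb sum q / D
        res = blocks.A @ st.s + blocks.B @ st.q - blocks.b_cell
        assert np.abs(res).max() < 1e-10 * max(1.0, np.abs(blocks.b_cell).max())
        ones = np.ones(g.n_cells)
        total_boundary = float(ones @ (blocks.A @ st.s + blocks.B @ st.q))
        # interior jump terms are not exactly antisymmetric face-by-face,
        # but the assembled balance guarantees the total closes on b
        assert total_boundary == pytest.approx(float(ones @ blocks.b_cell), abs=1e-8)

    def test_periodic_reactive_mass_balance(self):
        # K << phi: consumption saturates at M and sum q -> M * area
        g = build_grid(L, 8, BoundarySpec.periodic())
        caps = [Source((x, y), R, 137.0, KEFF)
                for x in (40.0, 120.0, 200.0) for y in (40.0, 120.0, 200.0)]
        nb = build_neighborhoods(g, caps, 5)
        p = PhysicalParams(M=10.0, K=1e-6 * 137.0)
        st = solve_reactive(assemble_system(g, caps, nb, p))
        assert st.q.sum() == pytest.approx(10.0 * L * L, rel=1e-4)


class TestMetabolism:
    def _blocks(self, M=40.0, K=13.7):
        g = build_grid(L, 5, BoundarySpec.dirichlet(0.0))
        src = Source((100.0, 130.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        return assemble_system(g, [src], nb, PhysicalParams(M=M, K=K))

    def test_zero_rate_gives_zero_vector(self):
        b = self._blocks(M=0.0)
        s = np.full(b.n_cells, 50.0)
        q = np.array([1e5])
        assert np.all(metabolic_vector(b, s, q) == 0.0)

    def test_small_k_zeroth_order_limit(self):
        b = self._blocks(M=40.0, K=1e-9)
        s = np.full(b.n_cells, 50.0)
        q = np.array([0.0])
        vec = metabolic_vector(b, s, q)
        assert np.allclose(vec, -40.0 / D * 48.0 ** 2, rel := 1e-6)

    def test_simpson_matches_adaptive_cubature(self):
        b = self._blocks()
        s = np.full(b.n_cells, 60.0)
        q = np.array([1.0e5])
        # a neighborhood cell that does not contain the disk itself, so the
        # integrand is smooth and Simpson converges at full order
        k = b.grid.locate_cell((150.0, 130.0))
        vec = metabolic_vector(b, s, q, n_nodes=21)
        ix, iy = b.grid.ij(k)
        h = b.grid.h
        entries = b.nbhd.sources_of(k)

        def integrand(y, x):
            pts = np.array([[x, y]])
            from oxsplit2d.potentials import rapid_coeff_matrix
            idx, G = rapid_coeff_matrix(entries, b.sources, pts, D)
            phi = 60.0 + float(q[idx] @ G[:, 0])
            return phi / (phi + 13.7)

        ref, _ = dblquad(integrand, ix * h, (ix + 1) * h, iy * h, (iy + 1) * h,
                         epsabs=1e-10, epsrel=1e-9)
        assert vec[k] == pytest.approx(-40.0 / D * ref, rel=2e-6)

    def test_pole_raises_with_cell_index(self):
        b = self._blocks()
        s = np.full(b.n_cells, -100.0)
        with pytest.raises(ValueError, match="cell"):
            metabolic_vector(b, s, np.array([0.0]))


class TestNewton:
    def test_m_zero_reduces_to_linear_solve(self):
        g = build_grid(L, 5, BoundarySpec.dirichlet(0.0))
        src = Source((120.0, 120.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        b = assemble_system(g, [src], nb, PhysicalParams(M=0.0))
        lin = solve_nonreactive(b)
        newt = solve_reactive(b)
        assert np.array_equal(lin.s, newt.s) and np.array_equal(lin.q, newt.q)

    def test_consumption_lowers_concentration(self):
        g = build_grid(L, 5, BoundarySpec.dirichlet(10.0))
        src = Source((120.0, 120.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        lin = solve_nonreactive(assemble_system(g, [src], nb, PhysicalParams()))
        rea = solve_reactive(assemble_system(g, [src], nb, PhysicalParams(M=40.0)))
        assert np.all(rea.cell_center_concentration() <= lin.cell_center_concentration() + 1e-9)

    def test_residual_history_contracts(self):
        g = build_grid(L, 5, BoundarySpec.dirichlet(10.0))
        src = Source((120.0, 120.0), R, 137.0, KEFF)
        nb = build_neighborhoods(g, [src], 3)
        st = solve_reactive(assemble_system(g, [src], nb, PhysicalParams(M=40.0)))
        h = st.residuals
        assert h[-1] <= 1e-10
        # super-linear contraction near the solution
        assert h[-1] < 1e-3 * h[-2] if len(h) >= 2 else True

    def test_bit_reproducibility(self):
        def run():
            g = build_grid(L, 5, BoundarySpec.dirichlet(0.0))
            src = Source((100.0, 130.0), R, 137.0, KEFF)
            nb = build_neighborhoods(g, [src], 3)
            return solve_reactive(assemble_system(g, [src], nb, PhysicalParams(M=40.0)))
        a, b = run(), run()
        assert np.array_equal(a.s, b.s) and np.array_equal(a.q, b.q)
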