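"""Configuration generators and experiment drivers."""

import numpy as np
import pytest

from oxsplit2d.core import LAYERS, R_CAP, R_CYL, R_PA
from oxsplit2d.experiments import (
    BENCH_SIDE,
    POG_SIDE,
    multi_source_configuration,
    neighborhood_for,
    periarteriolar_sources,
    run_periarteriolar,
    sample_hardcore_sources,
    solve_periarteriolar,
    sweep_dipole,
)


class TestHardCoreSampling:
    def test_zero_count_empty(self):
        rng = np.random.default_rng(0)
        pts = sample_hardcore_sources(240.0, 0, rng)
        assert pts.shape == (0, 2)

    def test_min_separation_on_torus(self):
        rng = np.random.default_rng(1)
        pts = sample_hardcore_sources(240.0, 17, rng, min_sep=25.0, periodic=True)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = pts[i] - pts[j]
                d -= 240.0 * np.round(d / 240.0)
                assert np.hypot(*d) >= 25.0

    def test_exclusion_region_respected(self):
        rng = np.random.default_rng(2)
        pts = sample_hardcore_sources(
            400.0, 40, rng, exclusion_center=(200.0, 200.0), exclusion_radius=100.0)
        d = np.hypot(pts[:, 0] - 200.0, pts[:, 1] - 200.0)
        assert (d >= 100.0).all()

    def test_reproducible_per_seed(self):
        a = sample_hardcore_sources(240.0, 10, np.random.default_rng(7))
        b = sample_hardcore_sources(240.0, 10, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_infeasible_packing_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(RuntimeError):
            sample_hardcore_sources(100.0, 60, rng, min_sep=25.0, max_tries=5000)

    def test_density_matches_request(self):
        # mean realized density equals the requested count by construction;
        # check spatial homogeneity loosely: quadrant counts within
        # binomial fluctuation range over seeds
        counts = []
        for seed in range(10):
            pts = sample_hardcore_sources(240.0, 16, np.random.default_rng(seed))
            counts.append((pts[:, 0] < 120.0).sum())
        assert 4 <= np.mean(counts) <= 12


class TestConfigurations:
    def test_multi_source_composition(self):
        srcs = multi_source_configuration(0)
        assert len(srcs) == 17
        cvs = np.array([s.cv for s in srcs])
        assert (cvs > 0).sum() == 6          # one third sources ...
        assert (cvs == 0).sum() == 11        # ... two thirds sinks
        assert all(s.radius == R_CAP for s in srcs)

    def test_neighborhood_extent_rule(self):
        assert neighborhood_for(48.0) == 3    # 3 x 48 = 144 exactly (30 R)
        assert neighborhood_for(20.0) == 7    # 7 x 20 = 140
        assert neighborhood_for(24.0) == 5    # tie 5/7 -> smaller
        assert neighborhood_for(80.0) == 3

    def test_periarteriolar_sources(self):
        rng = np.random.default_rng(11)
        srcs = periarteriolar_sources(LAYERS["II"], rng)
        pa, caps = srcs[0], srcs[1:]
        assert pa.radius == R_PA
        assert pa.center == (POG_SIDE / 2, POG_SIDE / 2)
        d = np.array([np.hypot(s.center[0] - 200.0, s.center[1] - 200.0) for s in caps])
        assert (d >= R_CYL).all()
        cvs = np.array([s.cv for s in caps])
        assert (cvs >= 0.05 * pa.cv).all()
        # density: count = E2DSD x available area
        assert len(caps) == 42


class TestDipole:
    def test_large_neighborhood_beats_small_at_separation(self):
        # d = 60 R: the dipole spans well beyond a 3x3 block, so the n=5
        # treatment (which keeps the partner analytic) is more accurate
        df = sweep_dipole(d_over_R=(60.0,), n_list=(3, 5), fine_cells=160)
        e3 = df[df.n == 3].eps_q_global.iloc[0]
        e5 = df[df.n == 5].eps_q_global.iloc[0]
        assert e5 < e3
        assert e5 < 0.01


class TestPeriarteriolar:
    def test_diffusion_only_profile_bounded(self):
        st = solve_periarteriolar(LAYERS["II"], seed=5, M=0.0)
        phis = st.cell_center_concentration()
        phi_pa = LAYERS["II"].phi_pa
        assert phis.max() <= phi_pa * 1.001
        assert phis.min() >= 0.0

    def test_reactive_three_regime_profile(self):
        res = run_periarteriolar("II", seeds=range(2), raster_resolution=80)
        mp = res.mean_profile
        v = mp.set_index("r")["mean"]
        # plateau inside the PA at the wall value
        inner = v[v.index <= R_PA * 0.8]
        assert inner.std() < 1e-3
        # fast decay across the capillary-free region
        at_30 = v.iloc[int(np.abs(v.index.values - 30).argmin())]
        at_90 = v.iloc[int(np.abs(v.index.values - 90).argmin())]
        assert at_90 < 0.7 * at_30
        # re-increase beyond the minimum (capillary-fed outer region)
        beyond = v[(v.index > R_CYL)]
        assert beyond.iloc[-5:].mean() > beyond.min()
        # CMRO2 heterogeneity is reported and positive
        assert (res.cmro2_max_dev > 0).all()


class TestReactiveAccuracy:
    def test_reactive_error_tracks_nonreactive(self):
        # consumption barely degrades the flux accuracy: the reactive
        # single-source error stays within one percentage point of the
        # nonreactive one on the same grid
        import numpy as np
        from oxsplit2d import (BoundarySpec, Dirichlet, Neumann, Periodic,
                               PhysicalParams, Source, assemble_system,
                               build_grid, build_neighborhoods, error_metrics,
                               solve_nonreactive, solve_reactive, solve_reference)
        bc = BoundarySpec(left=Periodic(), right=Periodic(), bottom=Neumann(),
                          top=Dirichlet(68.5))
        src = Source((120.0, 120.0), 4.8, 137.0, 2000.0)
        g = build_grid(240.0, 5, bc)
        nb = build_neighborhoods(g, [src], 3)
        p0 = PhysicalParams()
        pr = PhysicalParams(M=40.0)
        ref0 = solve_reference(240.0, bc, [src], p0, fine_cells=160)
        refr = solve_reference(240.0, bc, [src], pr, fine_cells=160)
        e0 = error_metrics(solve_nonreactive(assemble_system(g, [src], nb, p0)), ref0)
        er = error_metrics(solve_reactive(assemble_system(g, [src], nb, pr)), refr)
        assert er.global_q <= e0.global_q + 0.01
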