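"""Seeded benchmark drivers: single-source grid / boundary / position
sweeps, the dipole study, the randomized multi-vessel error benchmark,
and the periarteriolar oxygen-gradient (POG) laminar study.

All benchmark domains are L = 240 um squares with R = 4.8 um vessel
cross-sections, i.e. deliberately small domains that stress the
splitting assumptions and give upper-bound error estimates.  The
single-source benchmark uses one Dirichlet side (baseline tissue
concentration phi_max/2 at the top), a zero-flux bottom and periodic
lateral sides, so that all three boundary-condition kinds are exercised;
the sweeps that probe a specific side keep Dirichlet(0) elsewhere.
Every randomized experiment is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assembly import assemble_system
from .baselines import error_metrics, solve_coarse_fv
from .core import (
    LAYERS,
    BoundarySpec,
    Dirichlet,
    K_EFF_CAP,
    LayerSpec,
    M_MAX,
    Neumann,
    Periodic,
    PhysicalParams,
    PHI_MAX,
    R_CAP,
    R_CYL,
    R_PA,
    Source,
    build_grid,
    build_neighborhoods,
)
from .reconstruction import cmro2_rate, mean_outside_radius, radial_profile, raster_field
from .reference import solve_reference
from .solvers import solve_nonreactive, solve_reactive

__all__ = [
    "BENCH_SIDE",
    "benchmark_bc",
    "neighborhood_for",
    "sweep_grid_size",
    "sweep_boundary_distance",
    "sweep_source_position",
    "sweep_dipole",
    "sample_hardcore_sources",
    "multi_source_configuration",
    "sweep_neighborhood_size",
    "PeriarteriolarResult",
    "run_periarteriolar",
    "run_layer_sweep",
]

BENCH_SIDE = 240.0
POG_SIDE = 400.0          # 20x20 grid at h ~ 20 um
POG_CELLS = 20
POG_N = 10
KEFF_LARGE = 1.0e3 * K_EFF_CAP   # asymptotically large wall exchange (quasi-Dirichlet walls)
HARD_CORE_SEP = 25.0             # minimum capillary center separation [um]


def benchmark_bc(phi_top: float = PHI_MAX / 2.0) -> BoundarySpec:
    """Single-source benchmark boundary set: periodic lateral sides,
    zero-flux bottom, Dirichlet top at a baseline tissue concentration."""
    return BoundarySpec(left=Periodic(), right=Periodic(), bottom=Neumann(),
                        top=Dirichlet(phi_top))


def neighborhood_for(h: float, extent: float = 30.0 * R_CAP) -> int:
    """Odd n >= 3 whose block extent n*h is closest to ``extent`` (~30 R)."""
    return min(range(3, 41, 2), key=lambda n: (abs(n * h - extent), n))


def _model_and_baseline(grid, sources, params, n, reference, wall_mode="interpolated"):
    nbhd = build_neighborhoods(grid, sources, n)
    blocks = assemble_system(grid, sources, nbhd, params, wall_mode=wall_mode)
    solve = solve_reactive if params.reactive else solve_nonreactive
    state = solve(blocks)
    er = error_metrics(state, reference)
    fv = solve_coarse_fv(grid, sources, params)
    erf = error_metrics(fv, reference)
    return state, er, fv, erf


def sweep_grid_size(
    cells_list: Sequence[int] = (12, 10, 8, 6, 5, 4, 3),
    reactive: bool = False,
    fine_cells: int = 256,
    phi_top: float = PHI_MAX / 2.0,
) -> pd.DataFrame:
    """Single-source error vs grid size h (multiscale and coarse FV).

    The source sits at the cell center nearest the domain center of each
    grid (the in-cell position effect is studied separately by
    :func:`sweep_source_position`); the neighborhood extent is kept at
    about 30 R.  Errors are measured against the resolved reference.
    """
    params = PhysicalParams(M=M_MAX if reactive else 0.0)
    bc = benchmark_bc(phi_top)
    rows = []
    for cells in cells_list:
        grid = build_grid(BENCH_SIDE, cells, bc)
        k = grid.locate_cell((BENCH_SIDE / 2.0, BENCH_SIDE / 2.0))
        src = Source(tuple(grid.cell_center(k)), R_CAP, PHI_MAX, K_EFF_CAP)
        ref = solve_reference(BENCH_SIDE, bc, [src], params, fine_cells=fine_cells)
        n = neighborhood_for(grid.h)
        _, er, _, erf = _model_and_baseline(grid, [src], params, n, ref)
        rows.append({
            "cells": cells, "h_over_L": 1.0 / cells, "n": n,
            "eps_q_multiscale": er.global_q, "eps_phi_multiscale": er.global_phi,
            "eps_q_coarse_fv": erf.global_q, "eps_phi_coarse_fv": erf.global_phi,
        })
    return pd.DataFrame(rows)


def sweep_boundary_distance(
    d_over_h: Sequence[float] = (0.0, 0.1, 0.25, 0.5, 0.7, 0.9, 1.2),
    fine_cells: int = 320,
    n_harmonics: int = 16,
) -> pd.DataFrame:
    """Single source approaching the zero-flux bottom side (5x5 grid, n=3).

    ``d`` is the gap between the source wall and the boundary; at
    tangency the wall is offset inward by 1e-2 R in both the model and
    the reference (identical geometry for a fair comparison).
    """
    params = PhysicalParams()
    bc = BoundarySpec(left=Periodic(), right=Periodic(), bottom=Neumann(),
                      top=Dirichlet(0.0))
    grid = build_grid(BENCH_SIDE, 5, bc)
    h = grid.h
    rows = []
    for doh in d_over_h:
        yc = max(doh * h + R_CAP, 1.01 * R_CAP)
        src = Source((BENCH_SIDE / 2.0, yc), R_CAP, PHI_MAX, K_EFF_CAP)
        ref = solve_reference(BENCH_SIDE, bc, [src], params,
                              fine_cells=fine_cells, n_harmonics=n_harmonics,
                              max_outer=600)
        _, er, _, erf = _model_and_baseline(grid, [src], params, 3, ref)
        rows.append({"d_over_h": doh, "eps_q_multiscale": er.global_q,
                     "eps_q_coarse_fv": erf.global_q})
    return pd.DataFrame(rows)


def sweep_source_position(
    positions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    fine_cells: int = 256,
) -> pd.DataFrame:
    """Source moved from a cell center to a cell corner (5x5 grid, n=3).

    Compares the two wall-average closures: ``nearest_cell`` (host-cell
    discrete value, no sub-grid interpolation) and ``interpolated``
    (dual-mesh evaluation of I_phi at the source center).  All-Dirichlet(0)
    outer boundary; position parameter t moves the center diagonally,
    t=1 placing it exactly on a grid-cell corner.
    """
    params = PhysicalParams()
    bc = BoundarySpec.dirichlet(0.0)
    grid = build_grid(BENCH_SIDE, 5, bc)
    rows = []
    for t in positions:
        c = (120.0 + t * grid.h / 2.0, 120.0 + t * grid.h / 2.0)
        src = Source(c, R_CAP, PHI_MAX, K_EFF_CAP)
        ref = solve_reference(BENCH_SIDE, bc, [src], params, fine_cells=fine_cells)
        row = {"t": t}
        for mode in ("nearest_cell", "interpolated"):
            _, er, _, _ = _model_and_baseline(grid, [src], params, 3, ref, wall_mode=mode)
            row[f"eps_q_{mode}"] = er.global_q
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_dipole(
    d_over_R: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0),
    n_list: Sequence[int] = (3, 5),
    fine_cells: int = 256,
) -> pd.DataFrame:
    """Source/sink pair separated by d, symmetric about the domain center.

    The sink has <C_v> = 0, the source phi_max; h/L = 0.2.  The pair is
    laid along the domain diagonal so separations up to ~60 R fit inside
    the L = 240 um box.  Probes the interplay between the separation
    distance and the neighborhood size (analytic cross-influence inside
    shared neighborhoods vs the localization error when the
    neighborhoods no longer overlap).
    """
    params = PhysicalParams()
    bc = benchmark_bc()
    grid = build_grid(BENCH_SIDE, 5, bc)
    rows = []
    u = np.array([1.0, 1.0]) / math.sqrt(2.0)
    mid = np.array([BENCH_SIDE / 2.0, BENCH_SIDE / 2.0])
    for dR in d_over_R:
        d = dR * R_CAP
        sink = Source(tuple(mid - d / 2.0 * u), R_CAP, 0.0, K_EFF_CAP)
        srce = Source(tuple(mid + d / 2.0 * u), R_CAP, PHI_MAX, K_EFF_CAP)
        pair = [sink, srce]
        ref = solve_reference(BENCH_SIDE, bc, pair, params, fine_cells=fine_cells)
        for n in n_list:
            st, er, _, _ = _model_and_baseline(grid, pair, params, n, ref)
            rows.append({
                "d_over_R": dR, "n": n,
                "eps_q_sink": er.eps_q[0], "eps_q_source": er.eps_q[1],
                "eps_q_global": er.global_q,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Randomized configurations


def sample_hardcore_sources(
    side: float,
    count: int,
    rng: np.random.Generator,
    min_sep: float = HARD_CORE_SEP,
    radius: float = R_CAP,
    periodic: bool = True,
    exclusion_center: Sequence[float] | None = None,
    exclusion_radius: float = 0.0,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Uniform hard-core (minimum-separation) point sample; (count, 2).

    Distances are measured on the torus when ``periodic``.  Points whose
    center falls within ``exclusion_radius`` of ``exclusion_center`` are
    rejected (the capillary-free periarteriolar cylinder); a margin of
    one radius keeps disks inside a non-periodic domain.
    """
    pts: list[np.ndarray] = []
    tries = 0
    lo, hi = (0.0, side) if periodic else (radius, side - radius)
    while len(pts) < count:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"hard-core sampling infeasible: placed {len(pts)}/{count} "
                f"after {max_tries} tries")
        cand = rng.uniform(lo, hi, 2)
        if exclusion_center is not None:
            d = cand - np.asarray(exclusion_center, float)
            if periodic:
                d -= side * np.round(d / side)
            if math.hypot(*d) < exclusion_radius:
                continue
        ok = True
        for p in pts:
            d = cand - p
            if periodic:
                d -= side * np.round(d / side)
            if math.hypot(*d) < min_sep:
                ok = False
                break
        if ok:
            pts.append(cand)
    return np.asarray(pts).reshape(len(pts), 2)


def multi_source_configuration(seed: int, count: int = 17,
                               source_fraction: float = 1.0 / 3.0) -> list[Source]:
    """Randomized stand-in for a capillary-bed cross-section: ``count``
    vessels placed hard-core on the periodic L=240 um domain, one third
    assigned as sources (<C_v> = phi_max) and the rest as sinks (0)."""
    rng = np.random.default_rng(seed)
    pts = sample_hardcore_sources(BENCH_SIDE, count, rng, periodic=True)
    n_src = int(round(source_fraction * count))
    cv = np.zeros(count)
    cv[rng.permutation(count)[:n_src]] = PHI_MAX
    return [Source(tuple(p), R_CAP, c, K_EFF_CAP) for p, c in zip(pts, cv)]


def sweep_neighborhood_size(
    n_list: Sequence[int] = (3, 5, 7, 9),
    seeds: Iterable[int] = range(10),
    cells: int = 16,
    reactive: bool = False,
    fine_cells: int = 256,
) -> pd.DataFrame:
    """Global flux/concentration error vs neighborhood size for the
    17-vessel realistic configuration (periodic BCs, 16x16 grid),
    averaged over placement seeds."""
    params = PhysicalParams(M=M_MAX if reactive else 0.0)
    bc = BoundarySpec.periodic()
    grid = build_grid(BENCH_SIDE, cells, bc)
    rows = []
    for seed in seeds:
        srcs = multi_source_configuration(seed)
        ref = solve_reference(BENCH_SIDE, bc, srcs, params,
                              fine_cells=fine_cells, n_harmonics=10, n_theta=128)
        fv = solve_coarse_fv(grid, srcs, params)
        erf = error_metrics(fv, ref)
        for n in n_list:
            nbhd = build_neighborhoods(grid, srcs, n)
            blocks = assemble_system(grid, srcs, nbhd, params)
            st = (solve_reactive if params.reactive else solve_nonreactive)(blocks)
            er = error_metrics(st, ref)
            rows.append({"seed": seed, "n": n,
                         "eps_q": er.global_q, "eps_phi": er.global_phi,
                         "eps_q_coarse_fv": erf.global_q})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Periarteriolar oxygen gradients


def periarteriolar_sources(layer: LayerSpec, rng: np.random.Generator) -> list[Source]:
    """One central penetrating arteriole plus a hard-core capillary bed.

    The PA (R = 20 um) sits at the domain center inside a capillary-free
    cylinder of radius R_cyl = 100 um; capillaries (R = 4.8 um) are
    placed outside it at the layer's equivalent 2D source density with
    wall concentrations ~ N(ratio * phi_PA, 0.1 phi_PA) truncated at
    0.05 phi_PA.  Wall exchange uses an asymptotically large K_eff so
    the wall concentrations are effectively prescribed.
    """
    phi_pa = layer.phi_pa
    center = (POG_SIDE / 2.0, POG_SIDE / 2.0)
    area = POG_SIDE ** 2 - math.pi * R_CYL ** 2
    count = int(round(layer.e2dsd * 1e-6 * area))
    pts = sample_hardcore_sources(
        POG_SIDE, count, rng, periodic=True,
        exclusion_center=center, exclusion_radius=R_CYL)
    cvs = rng.normal(layer.phi_cap_ratio * phi_pa, 0.1 * phi_pa, count)
    cvs = np.maximum(cvs, 0.05 * phi_pa)
    out = [Source(center, R_PA, phi_pa, KEFF_LARGE)]
    out += [Source(tuple(p), R_CAP, c, KEFF_LARGE) for p, c in zip(pts, cvs)]
    return out


@dataclass
class PeriarteriolarResult:
    layer: str
    M: float
    seeds: list[int]
    profiles: pd.DataFrame          # per-seed radial profiles of phi/phi_PA
    mean_profile: pd.DataFrame      # r, mean, sd over seeds
    mean_outside: np.ndarray        # per-seed <phi/phi_PA> for r > R_cyl
    cmro2_max_dev: np.ndarray       # per-seed max |CMRO2 - mean| / mean in r < R_cyl
    cmro2_max_dev_outer: np.ndarray  # same, r > R_cyl


def solve_periarteriolar(layer: LayerSpec, seed: int, M: float = M_MAX):
    """Assemble and solve one reactive periarteriolar realization."""
    rng = np.random.default_rng(seed)
    params = PhysicalParams(M=M)
    bc = BoundarySpec.periodic()
    grid = build_grid(POG_SIDE, POG_CELLS, bc)
    srcs = periarteriolar_sources(layer, rng)
    nbhd = build_neighborhoods(grid, srcs, POG_N)
    blocks = assemble_system(grid, srcs, nbhd, params)
    solve = solve_reactive if params.reactive else solve_nonreactive
    return solve(blocks)


def run_periarteriolar(
    layer: str = "II",
    M: float = M_MAX,
    seeds: Iterable[int] = range(30),
    raster_resolution: int = 160,
    profile_dr: float = 2.0,
    n_theta: int = 360,
) -> PeriarteriolarResult:
    """Radial POG profiles, periarteriolar CMRO2 heterogeneity and the
    outer-region mean oxygenation, averaged over seeded realizations."""
    spec = LAYERS[layer]
    phi_pa = spec.phi_pa
    center = np.array([POG_SIDE / 2.0, POG_SIDE / 2.0])
    seeds = list(seeds)
    profs = []
    mean_out = []
    dev_in = []
    dev_out = []
    for seed in seeds:
        st = solve_periarteriolar(spec, seed, M)
        prof = radial_profile(st, center, dr=profile_dr, n_theta=n_theta)
        prof["phi_norm"] = prof["mean"] / phi_pa
        prof["seed"] = seed
        profs.append(prof)
        mean_out.append(mean_outside_radius(st, center, R_CYL, resolution=raster_resolution) / phi_pa)
        if M > 0:
            xs, ys, phi, in_disk = raster_field(st, raster_resolution)
            gx, gy = np.meshgrid(xs, ys)
            r = np.hypot(gx - center[0], gy - center[1])
            cm = cmro2_rate(phi, st.params)
            sel_in = (r < R_CYL) & (r > R_PA) & ~in_disk
            m_in = cm[sel_in].mean()
            dev_in.append(np.max(np.abs(cm[sel_in] - m_in)) / m_in)
            sel_out = (r >= R_CYL) & ~in_disk
            m_out = cm[sel_out].mean()
            dev_out.append(np.max(np.abs(cm[sel_out] - m_out)) / m_out)
    profiles = pd.concat(profs, ignore_index=True)
    mp = profiles.groupby("r")["phi_norm"].agg(["mean", "std", "count"]).reset_index()
    return PeriarteriolarResult(
        layer=layer, M=M, seeds=seeds, profiles=profiles, mean_profile=mp,
        mean_outside=np.asarray(mean_out),
        cmro2_max_dev=np.asarray(dev_in) if dev_in else np.empty(0),
        cmro2_max_dev_outer=np.asarray(dev_out) if dev_out else np.empty(0),
    )


def run_layer_sweep(
    M: float = M_MAX,
    realizations: int = 30,
    seed: int = 0,
    raster_resolution: int = 160,
    layers: Sequence[str] = ("I", "II", "III", "IV"),
) -> dict:
    """Mean normalized tissue oxygenation outside R_cyl per cortical layer
    and its least-squares line against the layer source density (E2DSD).

    Returns the per-layer means, the fitted slope and intercept (x in
    mm^-2), and their spread over realizations (per-realization refits).
    """
    per_layer = {}
    for li, name in enumerate(layers):
        spec = LAYERS[name]
        vals = []
        for r in range(realizations):
            child_seed = int((seed * 1_000_003 + li * 7919 + r) % (2 ** 31 - 1))
            st = solve_periarteriolar(spec, child_seed, M)
            center = np.array([POG_SIDE / 2.0, POG_SIDE / 2.0])
            vals.append(mean_outside_radius(st, center, R_CYL,
                                            resolution=raster_resolution) / spec.phi_pa)
        per_layer[name] = np.asarray(vals)
    x = np.array([LAYERS[n].e2dsd for n in layers])
    y = np.array([per_layer[n].mean() for n in layers])
    slope, intercept = np.polyfit(x, y, 1)
    fits = np.array([
        np.polyfit(x, [per_layer[n][r] for n in layers], 1)
        for r in range(realizations)
    ])
    return {
        "per_layer": per_layer,
        "e2dsd": x,
        "means": y,
        "slope": float(slope),
        "intercept": float(intercept),
        "slope_sd": float(fits[:, 0].std(ddof=1)) if realizations > 1 else 0.0,
        "intercept_sd": float(fits[:, 1].std(ddof=1)) if realizations > 1 else 0.0,
    }
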