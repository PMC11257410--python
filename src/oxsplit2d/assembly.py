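"""Assembly of the coupled discrete system

    A s + B q = b_cell        (per-cell slow-term mass balance)
    C s + D q = b_src         (per-source wall-average exchange closure)

Rows of A/B are written in concentration units: an interior face
contributes (s_m - s_k) + J_km where the jump functional

    J_km = 1/2 int_face n.(grad r_m - grad r_k) dl + 1/h int_face (r_m - r_k) dl

transfers the localization discontinuities of the rapid term into the
slow-field balance.  A Dirichlet boundary face contributes
2 (avg(phi_D - r_k) - s_k) (half-cell TPFA distance); a zero-flux face
imposes zero total flux of s + r, i.e. the slow flux balances the
face-integrated rapid flux.  The physical face flux is D times a row
term, which is why fluxes are reconstructed with D a posteriori.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .core import CartesianGrid, Dirichlet, Neumann, NeighborhoodMap, PhysicalParams, Source
from .potentials import rapid_coeff_matrix, rapid_grad_coeff_matrix
from .quadrature import default_face_nodes, line_quadrature, tensor_cell_rule
from .reconstruction import Interpolator

__all__ = ["SystemBlocks", "assemble_system", "metabolic_vector", "IllPosedError"]


class IllPosedError(ValueError):
    """Raised for configurations with no Dirichlet side and no source."""


@dataclass
class SystemBlocks:
    A: sp.csr_matrix
    B: sp.csr_matrix
    C: sp.csr_matrix
    D: sp.csr_matrix
    b_cell: np.ndarray
    b_src: np.ndarray
    grid: CartesianGrid
    sources: list[Source]
    nbhd: NeighborhoodMap
    params: PhysicalParams
    interp: Interpolator
    wall_mode: str
    # per-cell metabolic quadrature workspace, built lazily
    _metab_cache: dict | None = None

    @property
    def n_cells(self) -> int:
        return self.grid.n_cells

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def full_matrix(self) -> sp.csr_matrix:
        return sp.bmat([[self.A, self.B], [self.C, self.D]], format="csc")

    def rhs(self) -> np.ndarray:
        return np.concatenate([self.b_cell, self.b_src])

    def export_text(self, directory) -> None:
        """Dump the blocks as Matrix Market text files (debug aid)."""
        import pathlib

        from scipy.io import mmwrite

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("A", "B", "C", "D"):
            mmwrite(d / f"{name}.mtx", getattr(self, name))
        np.savetxt(d / "b_cell.txt", self.b_cell)
        np.savetxt(d / "b_src.txt", self.b_src)


def _face_entries(nbhd: NeighborhoodMap, k: int) -> dict[int, tuple[int, np.ndarray]]:
    return {j: (j, eff) for j, eff in nbhd.sources_of(k)}


def assemble_system(
    grid: CartesianGrid,
    sources: Sequence[Source],
    nbhd: NeighborhoodMap,
    params: PhysicalParams,
    wall_mode: str = "interpolated",
    face_tol: float = 1e-9,
) -> SystemBlocks:
    """Build the block system for the multiscale (splitting) model."""
    sources = list(sources)
    F = grid.n_cells
    S = len(sources)
    if not grid.bc.has_dirichlet and S == 0:
        raise IllPosedError("no Dirichlet side and no source: concentration level is undetermined")
    D = params.D
    h = grid.h
    r_min = min((s.radius for s in sources), default=h)
    n0 = default_face_nodes(h, r_min)

    A = sp.lil_matrix((F, F))
    B = sp.lil_matrix((F, S))
    b_cell = np.zeros(F)

    # -- interior (and periodic wrap) faces --------------------------------
    for face in grid.faces:
        k, m = face.k, face.m
        A[k, k] -= 1.0
        A[k, m] += 1.0
        A[m, m] -= 1.0
        A[m, k] += 1.0
        ek = _face_entries(nbhd, k)
        em = _face_entries(nbhd, m)
        jump = []          # (j, entry_k or None, entry_m or None)
        for j in sorted(set(ek) | set(em)):
            in_k, in_m = j in ek, j in em
            if in_k and in_m and np.allclose(ek[j][1], em[j][1] + face.offset):
                continue   # identical analytic treatment on both sides: no jump
            jump.append((j, ek.get(j), em.get(j)))
        if not jump:
            continue

        nj = len(jump)
        rows_k = [a for a, (_, e_k, _) in enumerate(jump) if e_k is not None]
        ent_k = [e_k for _, e_k, _ in jump if e_k is not None]
        rows_m = [a for a, (_, _, e_m) in enumerate(jump) if e_m is not None]
        ent_m = [e_m for _, _, e_m in jump if e_m is not None]

        def integrand(pts):
            # rows: per jump source, [n.(grad g_m - grad g_k); g_m - g_k]
            out = np.zeros((2 * nj, pts.shape[0]))
            if ent_m:
                pts_m = pts - face.offset
                _, G = rapid_coeff_matrix(ent_m, sources, pts_m, D)
                _, Gg = rapid_grad_coeff_matrix(ent_m, sources, pts_m, D)
                out[rows_m] += Gg @ face.normal
                out[[nj + a for a in rows_m]] += G
            if ent_k:
                _, G = rapid_coeff_matrix(ent_k, sources, pts, D)
                _, Gg = rapid_grad_coeff_matrix(ent_k, sources, pts, D)
                out[rows_k] -= Gg @ face.normal
                out[[nj + a for a in rows_k]] -= G
            return out

        vals = line_quadrature(integrand, face.p0, face.p1, n0=n0, tol=face_tol)
        for a, (j, _, _) in enumerate(jump):
            grad_part = 0.5 * vals[a]
            val_part = vals[nj + a] / h
            B[k, j] += grad_part + val_part     # J_{k,m}
            B[m, j] += grad_part - val_part     # J_{m,k}

    # -- boundary faces ----------------------------------------------------
    for bf in grid.boundary_faces:
        cond = grid.bc.side(bf.side)
        k = bf.k
        entries = nbhd.sources_of(k)
        if isinstance(cond, Dirichlet):
            A[k, k] -= 2.0

            def phi_d(pts, _c=cond):
                return _c(pts[:, 0], pts[:, 1])

            # balance: ... + 2 (avg(phi_D) - avg(r_k) - s_k) = 0; constants to RHS
            b_cell[k] -= 2.0 * line_quadrature(phi_d, bf.p0, bf.p1, n0=n0, tol=face_tol) / h
            for j, eff in entries:

                def gj(pts, _j=j, _eff=eff):
                    return rapid_coeff_matrix([(_j, _eff)], sources, pts, D)[1][0]

                B[k, j] += -2.0 * line_quadrature(gj, bf.p0, bf.p1, n0=n0, tol=face_tol) / h
        elif isinstance(cond, Neumann):
            for j, eff in entries:

                def dgj(pts, _j=j, _eff=eff):
                    _, Gg = rapid_grad_coeff_matrix([(_j, _eff)], sources, pts, D)
                    return Gg[0] @ bf.normal

                B[k, j] += -line_quadrature(dgj, bf.p0, bf.p1, n0=n0, tol=face_tol)

    # -- wall-average exchange rows ---------------------------------------
    interp = Interpolator(grid, sources, nbhd, D)
    C = sp.lil_matrix((S, F))
    Dmat = sp.lil_matrix((S, S))
    b_src = np.zeros(S)
    for j, src in enumerate(sources):
        f = interp.wall_functional(j, wall_mode)
        Dmat[j, j] += 1.0
        for k, c in f.s.items():
            C[j, k] += src.keff * c
        for i, c in f.q.items():
            Dmat[j, i] += src.keff * c
        b_src[j] = src.keff * (src.cv - f.const)

    return SystemBlocks(
        A=A.tocsr(), B=B.tocsr(), C=C.tocsr(), D=Dmat.tocsr(),
        b_cell=b_cell, b_src=b_src,
        grid=grid, sources=sources, nbhd=nbhd, params=params,
        interp=interp, wall_mode=wall_mode,
    )


# ---------------------------------------------------------------------------
# Metabolism


def _metab_workspace(blocks: SystemBlocks, n_nodes: int = 11) -> dict:
    """Per-cell tensor Simpson nodes and rapid-field coefficient matrices."""
    if blocks._metab_cache is not None and blocks._metab_cache["n_nodes"] == n_nodes:
        return blocks._metab_cache
    grid = blocks.grid
    h = grid.h
    cells = []
    for k in range(grid.n_cells):
        ix, iy = grid.ij(k)
        pts, wts = tensor_cell_rule(ix * h, iy * h, h, n_nodes)
        entries = blocks.nbhd.sources_of(k)
        if entries:
            idx, G = rapid_coeff_matrix(entries, blocks.sources, pts, blocks.params.D)
        else:
            idx, G = np.empty(0, dtype=int), np.zeros((0, len(pts)))
        cells.append((idx, G, wts))
    blocks._metab_cache = {"n_nodes": n_nodes, "cells": cells}
    return blocks._metab_cache


def metabolic_vector(
    blocks: SystemBlocks,
    s: np.ndarray,
    q: np.ndarray,
    n_nodes: int = 11,
    jacobian: bool = False,
):
    """Integral Michaelis-Menten consumption per cell, in row units.

    Returns ``vec`` with ``vec[k] = -(1/D) int_{V_k} M phi/(phi + K) dV``
    where phi = s_k + r_k(x) is the reconstructed in-cell concentration,
    and optionally the Jacobian blocks d vec / d s (diagonal, as a
    vector) and d vec / d q (sparse F x S).
    """
    p = blocks.params
    F, S = blocks.n_cells, blocks.n_sources
    vec = np.zeros(F)
    if p.M == 0.0:
        if jacobian:
            return vec, np.zeros(F), sp.csr_matrix((F, S))
        return vec
    ws = _metab_workspace(blocks, n_nodes)
    dvec_ds = np.zeros(F)
    dq_rows: list[int] = []
    dq_cols: list[int] = []
    dq_vals: list[float] = []
    scale = p.M / p.D
    for k, (idx, G, wts) in enumerate(ws["cells"]):
        phi = s[k] + (q[idx] @ G if len(idx) else 0.0)
        if np.min(phi) <= -p.K:
            raise ValueError(
                f"metabolic integrand pole: concentration <= -K inside cell {k}"
            )
        sat = phi / (phi + p.K)
        vec[k] = -scale * float(wts @ np.broadcast_to(sat, wts.shape))
        if jacobian:
            dsat = p.K / (phi + p.K) ** 2
            dvec_ds[k] = -scale * float(wts @ np.broadcast_to(dsat, wts.shape))
            if len(idx):
                contrib = -scale * (G * (dsat * wts)[None, :]).sum(axis=1)
                dq_rows.extend([k] * len(idx))
                dq_cols.extend(idx.tolist())
                dq_vals.extend(contrib.tolist())
    if jacobian:
        dvec_dq = sp.csr_matrix((dq_vals, (dq_rows, dq_cols)), shape=(F, S))
        return vec, dvec_ds, dvec_dq
    return vec
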