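"""Sub-grid reconstruction of the concentration field.

The slow term is interpolated bilinearly on the dual mesh obtained by
joining the FV cell centers (boundary dual cells use nodes projected
onto the domain boundary, which carry the discrete Dirichlet/Neumann
closure).  Each dual-cell corner i contributes its nodal slow value plus
its cell's rapid field continued analytically to the evaluation point,

    I_phi(x) = sum_i gamma_i(x) * (s_i + r_i^c(q; x)),

which is continuous across all FV faces (the continued rapid terms
bridge the localization jumps) and interpolates the cell-center values
exactly.  The same linear-in-(s, q) functional provides the wall-average
closure q_j = K_eff (<C_v>_j - I_phi(x_j)) used by the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CartesianGrid, Dirichlet, Neumann, NeighborhoodMap, PhysicalParams, Source
from .potentials import rapid_coeff_matrix, unit_potential, unit_potential_grad

__all__ = [
    "LinearFunc",
    "Interpolator",
    "raster_field",
    "cmro2_rate",
    "radial_profile",
    "mean_outside_radius",
]


@dataclass
class LinearFunc:
    """An affine functional  value = sum_k s_coef[k] s_k + sum_j q_coef[j] q_j + const."""

    s: dict[int, float] = field(default_factory=dict)
    q: dict[int, float] = field(default_factory=dict)
    const: float = 0.0

    def add_s(self, k: int, c: float) -> None:
        if c:
            self.s[k] = self.s.get(k, 0.0) + c

    def add_q(self, j: int, c: float) -> None:
        if c:
            self.q[j] = self.q.get(j, 0.0) + c

    def value(self, s_vec: np.ndarray, q_vec: np.ndarray) -> float:
        out = self.const
        for k, c in self.s.items():
            out += c * s_vec[k]
        for j, c in self.q.items():
            out += c * q_vec[j]
        return out


class _Axis:
    """Dual-mesh node lattice along one axis."""

    def __init__(self, side: float, cells: int, periodic: bool):
        self.side = side
        self.cells = cells
        self.h = side / cells
        self.periodic = periodic
        centers = (np.arange(cells) + 0.5) * self.h
        if periodic:
            self.coords = centers                      # F nodes, wrap interval
        else:
            self.coords = np.concatenate([[0.0], centers, [side]])

    def locate(self, x: float) -> tuple[int, int, float, float, float]:
        """(left node, right node, weight t, eval coord at left, at right).

        Eval coords are the point expressed in each node's primary frame
        (they differ by the domain period for wrap intervals).
        """
        h, F = self.h, self.cells
        if self.periodic:
            u = (x - 0.5 * h) % self.side
            i = min(int(u // h), F - 1)
            t = (u - i * h) / h
            il, ir = i, (i + 1) % F
            el = self.coords[il] + t * h
            er = self.coords[ir] - (1.0 - t) * h
            return il, ir, t, el, er
        x = min(max(x, 0.0), self.side)
        i = int(np.searchsorted(self.coords, x, side="right")) - 1
        i = min(max(i, 0), len(self.coords) - 2)
        t = (x - self.coords[i]) / (self.coords[i + 1] - self.coords[i])
        return i, i + 1, t, x, x

    def node_kind(self, node: int) -> tuple[str, int]:
        """('low'|'center'|'high', owning cell column/row)."""
        if self.periodic:
            return "center", node
        if node == 0:
            return "low", 0
        if node == len(self.coords) - 1:
            return "high", self.cells - 1
        return "center", node - 1

    def node_coord(self, node: int) -> float:
        return float(self.coords[node])


class Interpolator:
    """Evaluates I_phi and its linear-in-(s, q) functionals on a solved grid."""

    def __init__(
        self,
        grid: CartesianGrid,
        sources: Sequence[Source],
        nbhd: NeighborhoodMap,
        D: float,
    ):
        self.grid = grid
        self.sources = list(sources)
        self.nbhd = nbhd
        self.D = D
        self.ax = _Axis(grid.side, grid.cells, grid.bc.periodic_x)
        self.ay = _Axis(grid.side, grid.cells, grid.bc.periodic_y)

    # ------------------------------------------------------------------
    def _node_base(self, nx: int, ny: int) -> tuple[int, LinearFunc]:
        """Host cell and the nodal slow-value functional of node (nx, ny).

        The nodal value excludes the continued rapid term (added by the
        caller at the evaluation point):

        * interior node (cell center k): s_k
        * Dirichlet boundary node: phi_D(x_node) - r_host(x_node)
        * zero-flux boundary node: s_host - (h/2) n . grad r_host(x_node)
          (linear extrapolation with the slow-term face gradient implied
          by the zero total-flux closure)
        """
        g = self.grid
        kx, cx = self.ax.node_kind(nx)
        ky, cy = self.ay.node_kind(ny)
        host = g.index(cx, cy)
        pos = np.array([self.ax.node_coord(nx), self.ay.node_coord(ny)])
        f = LinearFunc()

        sides = []
        if kx == "low":
            sides.append(("left", np.array([-1.0, 0.0])))
        elif kx == "high":
            sides.append(("right", np.array([1.0, 0.0])))
        if ky == "low":
            sides.append(("bottom", np.array([0.0, -1.0])))
        elif ky == "high":
            sides.append(("top", np.array([0.0, 1.0])))

        if not sides:
            f.add_s(host, 1.0)
            return host, f

        entries = self.nbhd.sources_of(host)
        dirichlet = [(s, n) for s, n in sides if isinstance(g.bc.side(s), Dirichlet)]
        if dirichlet:
            conds = [g.bc.side(s) for s, _ in dirichlet]
            f.const = float(np.mean([c(pos[0], pos[1]) for c in conds]))
            for j, eff in entries:
                f.add_q(j, -float(unit_potential(pos[None, :], eff, self.sources[j].radius, self.D)[0]))
            return host, f

        # all adjoining sides are zero-flux
        f.add_s(host, 1.0)
        for s, n in sides:
            for j, eff in entries:
                gr = unit_potential_grad(pos[None, :], eff, self.sources[j].radius, self.D)[0]
                f.add_q(j, -(g.h / 2.0) * float(n @ gr))
        return host, f

    def _corners(self, point) -> list[tuple[int, int, float, np.ndarray]]:
        """Four (nx, ny, weight, eval point in corner frame) tuples for ``point``."""
        x, y = float(point[0]), float(point[1])
        ilx, irx, tx, elx, erx = self.ax.locate(x)
        ily, iry, ty, ely, ery = self.ay.locate(y)
        return [
            (ilx, ily, (1 - tx) * (1 - ty), np.array([elx, ely])),
            (irx, ily, tx * (1 - ty), np.array([erx, ely])),
            (ilx, iry, (1 - tx) * ty, np.array([elx, ery])),
            (irx, iry, tx * ty, np.array([erx, ery])),
        ]

    def functional(self, point) -> LinearFunc:
        """The affine functional x -> I_phi(s, q; x) at a single point."""
        f = LinearFunc()
        for nx, ny, w, ev in self._corners(point):
            if w == 0.0:
                continue
            host, base = self._node_base(nx, ny)
            for k, c in base.s.items():
                f.add_s(k, w * c)
            for j, c in base.q.items():
                f.add_q(j, w * c)
            f.const += w * base.const
            for j, eff in self.nbhd.sources_of(host):
                f.add_q(j, w * float(unit_potential(ev[None, :], eff, self.sources[j].radius, self.D)[0]))
        return f

    # ------------------------------------------------------------------
    def evaluate(self, s: np.ndarray, q: np.ndarray, points: np.ndarray) -> np.ndarray:
        """I_phi at many points (vectorized per dual cell)."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(pts))
        # group points by dual cell for batched rapid-field evaluation
        keys = np.empty(len(pts), dtype=np.int64)
        locs = []
        for p_idx, (x, y) in enumerate(pts):
            lx = self.ax.locate(x)
            ly = self.ay.locate(y)
            locs.append((lx, ly))
            keys[p_idx] = lx[0] * 10_000 + ly[0]
        node_cache: dict[tuple[int, int], tuple[int, LinearFunc, float]] = {}

        def node_val(nx, ny):
            if (nx, ny) not in node_cache:
                host, base = self._node_base(nx, ny)
                val = base.value(s, q)
                node_cache[(nx, ny)] = (host, base, val)
            return node_cache[(nx, ny)]

        order = np.argsort(keys, kind="stable")
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and keys[order[j]] == keys[order[i]]:
                j += 1
            batch = order[i:j]
            lx0 = locs[batch[0]][0]
            ly0 = locs[batch[0]][1]
            txs = np.array([locs[b][0][2] for b in batch])
            tys = np.array([locs[b][1][2] for b in batch])
            evx = np.array([(locs[b][0][3], locs[b][0][4]) for b in batch])
            evy = np.array([(locs[b][1][3], locs[b][1][4]) for b in batch])
            weights = [
                (0, 0, (1 - txs) * (1 - tys)),
                (1, 0, txs * (1 - tys)),
                (0, 1, (1 - txs) * tys),
                (1, 1, txs * tys),
            ]
            nodes_x = (lx0[0], lx0[1])
            nodes_y = (ly0[0], ly0[1])
            acc = np.zeros(len(batch))
            for cx, cy, w in weights:
                nx, ny = nodes_x[cx], nodes_y[cy]
                host, base, val = node_val(nx, ny)
                corner_pts = np.column_stack([evx[:, cx], evy[:, cy]])
                entries = self.nbhd.sources_of(host)
                rc = np.zeros(len(batch))
                if entries:
                    idx, G = rapid_coeff_matrix(entries, self.sources, corner_pts, self.D)
                    rc = np.asarray(q)[idx] @ G
                acc += w * (val + rc)
            out[batch] = acc
            i = j
        return out

    # ------------------------------------------------------------------
    def wall_functional(self, j: int, mode: str = "interpolated") -> LinearFunc:
        """Affine functional giving the wall average phi_bar_j.

        ``interpolated`` evaluates I_phi at the source center (Gauss
        mean-value closure; the source's own retained potential is zero
        there).  ``nearest_cell`` uses the host cell's discrete value
        plus the analytic contribution of the other neighborhood sources
        (the non-interpolated coarse closure).
        """
        src = self.sources[j]
        if mode == "interpolated":
            return self.functional(self.grid.wrap_point(src.xy))
        if mode == "nearest_cell":
            f = LinearFunc()
            k = self.grid.locate_cell(src.xy)
            f.add_s(k, 1.0)
            xj = self.grid.wrap_point(src.xy)
            for i, eff in self.nbhd.sources_of(k):
                f.add_q(i, float(unit_potential(xj[None, :], eff, self.sources[i].radius, self.D)[0]))
            return f
        raise ValueError(f"unknown wall-average mode: {mode!r}")


# ---------------------------------------------------------------------------
# Post-processing of a solved state (duck-typed: needs .interp, .s, .q,
# .sources, .grid and .wall_average(j))


def _source_mask(state, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mask of points inside any source disk, per-point owning source)."""
    g = state.grid
    inside = np.full(len(pts), -1, dtype=int)
    for j, src in enumerate(state.sources):
        d = pts - g.wrap_point(src.xy)
        if g.bc.periodic_x:
            d[:, 0] -= g.side * np.round(d[:, 0] / g.side)
        if g.bc.periodic_y:
            d[:, 1] -= g.side * np.round(d[:, 1] / g.side)
        hit = np.hypot(d[:, 0], d[:, 1]) <= src.radius
        inside[hit] = j
    return inside >= 0, inside


def raster_field(state, resolution: int):
    """Sample the reconstruction I_phi on a uniform raster.

    Returns ``(xs, ys, phi, in_disk)``; ``phi`` has shape (resolution,
    resolution) indexed [iy, ix].  Points falling inside a source disk
    carry that source's wall-average concentration and are flagged in
    ``in_disk``.
    """
    g = state.grid
    xs = (np.arange(resolution) + 0.5) * g.side / resolution
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    phi = state.interp.evaluate(state.s, state.q, pts)
    mask, owner = _source_mask(state, pts)
    if mask.any():
        walls = {j: state.wall_average(j) for j in np.unique(owner[mask])}
        for j, wv in walls.items():
            phi[owner == j] = wv
    return xs, xs, phi.reshape(resolution, resolution), mask.reshape(resolution, resolution)


def cmro2_rate(phi, params: PhysicalParams):
    """Pointwise Michaelis-Menten consumption rate M phi / (phi + K)."""
    phi = np.asarray(phi, float)
    return params.M * phi / (phi + params.K)


def radial_profile(state, center, dr: float = 2.0, n_theta: int = 360, r_max: float | None = None):
    """Azimuthal average of the reconstructed concentration around ``center``.

    Returns a DataFrame with bin center radius ``r``, azimuthal ``mean``
    and the number of valid rays per bin.  Points inside a source disk
    take the disk's wall value (for r <= the central source radius the
    profile is therefore flat); points outside a non-periodic domain are
    dropped.
    """
    import pandas as pd

    g = state.grid
    center = np.asarray(center, float)
    if r_max is None:
        r_max = g.side / 2.0
    radii = np.arange(dr / 2.0, r_max, dr)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rows = []
    ct, stheta = np.cos(theta), np.sin(theta)
    for r in radii:
        pts = center[None, :] + r * np.column_stack([ct, stheta])
        keep = np.ones(len(pts), bool)
        if not g.bc.periodic_x:
            keep &= (pts[:, 0] >= 0) & (pts[:, 0] <= g.side)
        if not g.bc.periodic_y:
            keep &= (pts[:, 1] >= 0) & (pts[:, 1] <= g.side)
        if not keep.any():
            continue
        pts = pts[keep]
        vals = state.interp.evaluate(state.s, state.q, pts)
        mask, owner = _source_mask(state, pts)
        if mask.any():
            for j in np.unique(owner[mask]):
                vals[owner == j] = state.wall_average(int(j))
        rows.append((r, float(vals.mean()), int(len(vals))))
    return pd.DataFrame(rows, columns=["r", "mean", "n"])


def mean_outside_radius(state, center, r_cut: float, resolution: int = 200) -> float:
    """Area-weighted raster mean of the reconstruction over r > r_cut."""
    g = state.grid
    if r_cut >= g.side / 2.0:
        raise ValueError("r_cut must be smaller than half the domain side")
    xs, ys, phi, in_disk = raster_field(state, resolution)
    gx, gy = np.meshgrid(xs, ys)
    d = np.hypot(gx - center[0], gy - center[1])
    sel = d > r_cut
    return float(phi[sel].mean())
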