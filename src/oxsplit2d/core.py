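"""Domain geometry, physical parameters, coarse grid and source bookkeeping.

Internal unit system: micrometre (um) for length, second for time and
nmol/cm^3 for concentration.  In these units the tissue diffusion
coefficient D = 2e-5 cm^2/s becomes 2e3 um^2/s and the maximal metabolic
rate M = 2.4 umol/cm^3/min becomes 40 nmol/cm^3/s, so all quantities are
O(1)-O(1000) and the assembled systems are well conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhysicalParams",
    "Source",
    "Dirichlet",
    "Neumann",
    "Periodic",
    "BoundarySpec",
    "CartesianGrid",
    "Face",
    "BoundaryFace",
    "NeighborhoodMap",
    "LayerSpec",
    "LAYERS",
    "build_grid",
    "build_neighborhoods",
    "effective_permeability",
    "D_TISSUE",
    "K_EFF_CAP",
    "PHI_MAX",
    "M_MAX",
    "K_HALF",
    "ALPHA_O2",
    "R_CAP",
    "R_PA",
    "R_CYL",
]

# Reference parameter values (um / s / nmol cm^-3 unit system).
D_TISSUE = 2.0e3      # tissue diffusion coefficient, um^2/s  (2e-5 cm^2/s)
K_EFF_CAP = 2.0e3     # effective capillary wall exchange coefficient, um^2/s
PHI_MAX = 137.0       # arteriolar inlet concentration, nmol/cm^3
M_MAX = 40.0          # maximal CMRO2, nmol/cm^3/s  (2.4 umol/cm^3/min)
K_HALF = PHI_MAX / 10.0  # Michaelis-Menten half-saturation (EC50), nmol/cm^3
ALPHA_O2 = 1.39       # O2 solubility, nmol/cm^3 per mmHg
R_CAP = 4.8           # capillary cross-section radius, um
R_PA = 20.0           # penetrating arteriole radius, um
R_CYL = 100.0         # capillary-free cylinder radius around a PA, um


def effective_permeability(d_beta: float, k_m: float, radius: float) -> float:
    """Effective wall exchange coefficient K_eff = 8*pi*D_beta / (1 + 4*D_beta/(K_m*R)).

    Combines the intravascular diffusion coefficient ``d_beta`` and the
    diffusive wall permeability ``k_m`` into the single coefficient that
    relates the wall flux to the cross-section averaged intravascular
    concentration; it accounts for intravascular radial concentration
    gradients.  K_eff lies in [0, 8*pi*D_beta) and tends to the upper
    bound as the wall becomes infinitely permeable.
    """
    if d_beta <= 0 or k_m <= 0 or radius <= 0:
        raise ValueError("effective_permeability requires strictly positive arguments")
    return 8.0 * math.pi * d_beta / (1.0 + 4.0 * d_beta / (k_m * radius))


@dataclass(frozen=True)
class PhysicalParams:
    """Tissue transport and consumption parameters.

    D : tissue diffusion coefficient [um^2/s]
    M : maximal metabolic rate CMRO2_max [nmol/cm^3/s]; 0 disables consumption
    K : half-saturation concentration EC50 [nmol/cm^3]
    alpha : oxygen solubility [nmol/cm^3/mmHg] (used only to convert to PO2)
    phi_max : reference arteriolar concentration [nmol/cm^3]
    """

    D: float = D_TISSUE
    M: float = 0.0
    K: float = K_HALF
    alpha: float = ALPHA_O2
    phi_max: float = PHI_MAX

    def __post_init__(self) -> None:
        if self.D <= 0 or self.alpha <= 0 or self.phi_max <= 0:
            raise ValueError("D, alpha and phi_max must be strictly positive")
        if self.M < 0:
            raise ValueError("M must be non-negative")
        if self.M > 0 and self.K <= 0:
            raise ValueError("K must be strictly positive when M > 0")

    @property
    def reactive(self) -> bool:
        return self.M > 0


@dataclass(frozen=True)
class Source:
    """A circular vessel cross-section embedded in the tissue domain.

    center : (x, y) position of the disk center [um]
    radius : disk radius R_j [um]
    cv : cross-section averaged intravascular concentration <C_v>_j [nmol/cm^3]
    keff : effective wall exchange coefficient K_eff [um^2/s]
    """

    center: tuple[float, float]
    radius: float
    cv: float
    keff: float = K_EFF_CAP

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("source radius must be strictly positive")
        if self.keff <= 0:
            raise ValueError("source keff must be strictly positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


# ---------------------------------------------------------------------------
# Boundary conditions


@dataclass(frozen=True)
class Dirichlet:
    """Prescribed concentration phi_D on a side; constant or callable(x, y)."""

    value: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 0.0

    def __call__(self, x, y):
        if callable(self.value):
            return np.asarray(self.value(np.asarray(x, float), np.asarray(y, float)), float)
        return np.full_like(np.asarray(x, dtype=float), float(self.value))


@dataclass(frozen=True)
class Neumann:
    """Zero total oxygen flux through the side."""


@dataclass(frozen=True)
class Periodic:
    """Periodic wrap; must be set on both opposite sides."""


SIDES = ("left", "right", "bottom", "top")


@dataclass(frozen=True)
class BoundarySpec:
    left: Dirichlet | Neumann | Periodic = field(default_factory=Dirichlet)
    right: Dirichlet | Neumann | Periodic = field(default_factory=Dirichlet)
    bottom: Dirichlet | Neumann | Periodic = field(default_factory=Dirichlet)
    top: Dirichlet | Neumann | Periodic = field(default_factory=Dirichlet)

    def __post_init__(self) -> None:
        if isinstance(self.left, Periodic) != isinstance(self.right, Periodic):
            raise ValueError("periodic sides must come in opposite pairs (left/right)")
        if isinstance(self.bottom, Periodic) != isinstance(self.top, Periodic):
            raise ValueError("periodic sides must come in opposite pairs (bottom/top)")

    def side(self, name: str):
        return getattr(self, name)

    @property
    def periodic_x(self) -> bool:
        return isinstance(self.left, Periodic)

    @property
    def periodic_y(self) -> bool:
        return isinstance(self.bottom, Periodic)

    @property
    def has_dirichlet(self) -> bool:
        return any(isinstance(self.side(s), Dirichlet) for s in SIDES)

    @classmethod
    def dirichlet(cls, value: float | Callable = 0.0) -> "BoundarySpec":
        return cls(Dirichlet(value), Dirichlet(value), Dirichlet(value), Dirichlet(value))

    @classmethod
    def periodic(cls) -> "BoundarySpec":
        return cls(Periodic(), Periodic(), Periodic(), Periodic())


# ---------------------------------------------------------------------------
# Coarse cartesian grid


@dataclass(frozen=True)
class Face:
    """Interior (possibly periodic-wrapped) face between cells k and m.

    Geometry is expressed in cell k's frame; ``offset`` is the lattice
    vector such that a point x on the face reads ``x - offset`` in cell
    m's frame (non-zero only for periodic wrap faces).
    """

    k: int
    m: int
    p0: np.ndarray        # face endpoint, k frame
    p1: np.ndarray
    normal: np.ndarray    # unit outward normal of cell k (points towards m)
    offset: np.ndarray


@dataclass(frozen=True)
class BoundaryFace:
    k: int
    side: str
    p0: np.ndarray
    p1: np.ndarray
    normal: np.ndarray    # outward normal of the domain


class CartesianGrid:
    """Square coarse FV tessellation of a square domain [0, L]^2.

    Cells are half-open, ``[x, x+h) x [y, y+h)``, owned row-major with
    index ``k = iy * cells + ix``.  Opposite periodic sides identify the
    wrap faces as interior faces.
    """

    def __init__(self, side: float, cells: int, bc: BoundarySpec):
        if cells < 3:
            raise ValueError("grid needs at least 3 cells per side")
        if side <= 0:
            raise ValueError("domain side must be positive")
        self.side = float(side)
        self.cells = int(cells)
        self.h = self.side / self.cells
        self.bc = bc
        self.n_cells = self.cells * self.cells
        ix = np.arange(self.cells)
        xc = (ix + 0.5) * self.h
        self._xc = xc
        gx, gy = np.meshgrid(xc, xc, indexing="xy")
        self.centers = np.column_stack([gx.ravel(), gy.ravel()])
        self._faces: list[Face] | None = None
        self._bfaces: list[BoundaryFace] | None = None

    # -- indexing -----------------------------------------------------------
    def index(self, ix: int, iy: int) -> int:
        return iy * self.cells + ix

    def ij(self, k: int) -> tuple[int, int]:
        return k % self.cells, k // self.cells

    def cell_center(self, k: int) -> np.ndarray:
        return self.centers[k]

    def wrap_point(self, point) -> np.ndarray:
        """Map a point into the primary domain along periodic axes."""
        p = np.array(point, dtype=float)
        if self.bc.periodic_x:
            p[0] %= self.side
        if self.bc.periodic_y:
            p[1] %= self.side
        return p

    def locate_cell(self, point) -> int:
        """Index of the half-open cell owning ``point`` (periodic wrap applied).

        Points exactly on an interior face belong to the +x/+y cell.
        """
        p = self.wrap_point(point)
        eps = 1e-12 * self.side
        if not self.bc.periodic_x and not (-eps <= p[0] <= self.side + eps):
            raise ValueError(f"point x={p[0]} outside non-periodic domain")
        if not self.bc.periodic_y and not (-eps <= p[1] <= self.side + eps):
            raise ValueError(f"point y={p[1]} outside non-periodic domain")
        ix = min(max(int(np.floor(p[0] / self.h)), 0), self.cells - 1)
        iy = min(max(int(np.floor(p[1] / self.h)), 0), self.cells - 1)
        return self.index(ix, iy)

    # -- topology -----------------------------------------------------------
    @property
    def faces(self) -> list[Face]:
        """Interior faces, including periodic wrap faces."""
        if self._faces is None:
            self._faces = self._build_faces()
        return self._faces

    @property
    def boundary_faces(self) -> list[BoundaryFace]:
        if self._bfaces is None:
            self._bfaces = self._build_boundary_faces()
        return self._bfaces

    def _build_faces(self) -> list[Face]:
        h, n = self.h, self.cells
        faces: list[Face] = []
        ex = np.array([1.0, 0.0])
        ey = np.array([0.0, 1.0])
        zero = np.zeros(2)
        for iy in range(n):
            for ix in range(n):
                k = self.index(ix, iy)
                # east face
                if ix + 1 < n:
                    m = self.index(ix + 1, iy)
                    x = (ix + 1) * h
                    faces.append(Face(k, m, np.array([x, iy * h]), np.array([x, (iy + 1) * h]), ex, zero))
                elif self.bc.periodic_x:
                    m = self.index(0, iy)
                    x = self.side
                    faces.append(Face(k, m, np.array([x, iy * h]), np.array([x, (iy + 1) * h]), ex,
                                      np.array([self.side, 0.0])))
                # north face
                if iy + 1 < n:
                    m = self.index(ix, iy + 1)
                    y = (iy + 1) * h
                    faces.append(Face(k, m, np.array([ix * h, y]), np.array([(ix + 1) * h, y]), ey, zero))
                elif self.bc.periodic_y:
                    m = self.index(ix, 0)
                    y = self.side
                    faces.append(Face(k, m, np.array([ix * h, y]), np.array([(ix + 1) * h, y]), ey,
                                      np.array([0.0, self.side]))
                                 )
        return faces

    def _build_boundary_faces(self) -> list[BoundaryFace]:
        h, n = self.h, self.cells
        out: list[BoundaryFace] = []
        for i in range(n):
            if not self.bc.periodic_x:
                out.append(BoundaryFace(self.index(0, i), "left",
                                        np.array([0.0, i * h]), np.array([0.0, (i + 1) * h]),
                                        np.array([-1.0, 0.0])))
                out.append(BoundaryFace(self.index(n - 1, i), "right",
                                        np.array([self.side, i * h]), np.array([self.side, (i + 1) * h]),
                                        np.array([1.0, 0.0])))
            if not self.bc.periodic_y:
                out.append(BoundaryFace(self.index(i, 0), "bottom",
                                        np.array([i * h, 0.0]), np.array([(i + 1) * h, 0.0]),
                                        np.array([0.0, -1.0])))
                out.append(BoundaryFace(self.index(i, n - 1), "top",
                                        np.array([i * h, self.side]), np.array([(i + 1) * h, self.side]),
                                        np.array([0.0, 1.0])))
        return out

    def neighbors(self, k: int) -> list[int]:
        ix, iy = self.ij(k)
        out = []
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jx, jy = ix + dx, iy + dy
            if self.bc.periodic_x:
                jx %= self.cells
            if self.bc.periodic_y:
                jy %= self.cells
            if 0 <= jx < self.cells and 0 <= jy < self.cells:
                out.append(self.index(jx, jy))
        return out


def build_grid(side: float, cells: int, bc: BoundarySpec | None = None) -> CartesianGrid:
    """Construct the coarse FV grid (square cells, half-open ownership)."""
    return CartesianGrid(side, cells, bc if bc is not None else BoundarySpec.dirichlet(0.0))


# ---------------------------------------------------------------------------
# Localization neighborhoods


class NeighborhoodMap:
    """For each source j, the n x n block of cells in which its potential is
    treated analytically, and the inverse map cell -> analytic source set.

    ``cell_sources[k]`` holds ``(j, effective_center)`` pairs: on periodic
    grids the effective center is the periodic image of source j nearest to
    cell k's center, so a cell adjacent to the wrap boundary sees the
    correct nearby image.
    """

    def __init__(self, grid: CartesianGrid, sources: Sequence[Source], n: int):
        if n < 3:
            raise ValueError("neighborhood size n must be >= 3")
        self.grid = grid
        self.sources = list(sources)
        self.n = int(n)
        self.blocks: list[list[int]] = []
        self.cell_sources: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(grid.n_cells)]
        for j, src in enumerate(self.sources):
            block = self._block_cells(src)
            self.blocks.append(block)
            for k in block:
                self.cell_sources[k].append((j, self._effective_center(k, src)))

    def _axis_range(self, host: int, coord: float, periodic: bool) -> list[int]:
        n, cells, h = self.n, self.grid.cells, self.grid.h
        if n % 2 == 1:
            i0 = host - (n - 1) // 2
        else:
            # even block: pick the window whose center is nearest the source
            cands = (host - n // 2, host - n // 2 + 1)
            i0 = min(cands, key=lambda i: (abs((i + n / 2.0) * h - coord), i))
        idx = range(i0, i0 + n)
        if periodic:
            return sorted({i % cells for i in idx})
        return [i for i in idx if 0 <= i < cells]

    def _block_cells(self, src: Source) -> list[int]:
        g = self.grid
        host = g.locate_cell(src.xy)
        hx, hy = g.ij(host)
        c = g.wrap_point(src.xy)
        xs = self._axis_range(hx, c[0], g.bc.periodic_x)
        ys = self._axis_range(hy, c[1], g.bc.periodic_y)
        return [g.index(ix, iy) for iy in ys for ix in xs]

    def _effective_center(self, k: int, src: Source) -> np.ndarray:
        g = self.grid
        c = g.wrap_point(src.xy)
        xc = g.cell_center(k)
        eff = c.copy()
        if g.bc.periodic_x:
            eff[0] = xc[0] + (c[0] - xc[0] + g.side / 2) % g.side - g.side / 2
        if g.bc.periodic_y:
            eff[1] = xc[1] + (c[1] - xc[1] + g.side / 2) % g.side - g.side / 2
        return eff

    def sources_of(self, k: int) -> list[tuple[int, np.ndarray]]:
        """E(V_hat_k) with per-cell effective (periodic-image) centers."""
        return self.cell_sources[k]

    def in_block(self, j: int, k: int) -> bool:
        return k in self.blocks[j]


def build_neighborhoods(grid: CartesianGrid, sources: Sequence[Source], n: int) -> NeighborhoodMap:
    return NeighborhoodMap(grid, sources, n)


# ---------------------------------------------------------------------------
# Cortical layer table (laminar capillary density and oxygenation)


@dataclass(frozen=True)
class LayerSpec:
    """Layer-specific capillary statistics for the periarteriolar study.

    cld : capillary length density [m/mm^3]
    e2dsd : equivalent 2D source density of a cross-section [mm^-2]
    depth : cortical depth range [um]
    po2_pa : arteriolar PO2 [mmHg]
    po2_cap : mean capillary PO2 [mmHg]
    phi_cap_ratio : phi_cap / phi_PA (dimensionless)
    """

    label: str
    cld: float
    e2dsd: float
    depth: tuple[float, float]
    po2_pa: float
    po2_cap: float
    phi_cap_ratio: float

    @property
    def phi_pa(self) -> float:
        """Arteriolar wall concentration [nmol/cm^3]."""
        return self.po2_pa * ALPHA_O2


LAYERS: dict[str, LayerSpec] = {
    "I": LayerSpec("I", 0.8, 250.0, (0.0, 100.0), 99.0, 39.0, 0.40),
    "II": LayerSpec("II", 0.94, 325.0, (100.0, 200.0), 92.0, 42.0, 0.45),
    "III": LayerSpec("III", 1.08, 400.0, (200.0, 300.0), 87.0, 44.0, 0.50),
    "IV": LayerSpec("IV", 1.2, 475.0, (300.0, 400.0), 85.0, 47.0, 0.55),
}
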