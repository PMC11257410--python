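"""Shared fixtures: small grids, manufactured harmonic solutions."""

from __future__ import annotations

import numpy as np
import pytest

from oxsplit2d import (
    BoundarySpec,
    PhysicalParams,
    Source,
    assemble_system,
    build_grid,
    build_neighborhoods,
    solve_nonreactive,
)

D = 2000.0
KEFF = 2000.0
R = 4.8
L = 240.0


@pytest.fixture(scope="session")
def params():
    return PhysicalParams()


class MonopoleCase:
    """Manufactured solution phi* = A ln(R/rho): a single uniform-flux disk
    with the exact field imposed on the Dirichlet outer boundary.

    The exact wall flux is q* = 2 pi D A and the exact wall average is 0,
    so <C_v> = q*/K_eff closes the Robin exchange exactly.
    """

    def __init__(self, center=(120.0, 120.0), amplitude=1.0):
        self.center = np.asarray(center, float)
        self.A = amplitude
        self.q_exact = 2.0 * np.pi * D * amplitude
        self.source = Source(tuple(center), R, self.q_exact / KEFF, KEFF)

    def phi(self, x, y):
        rho = np.hypot(np.asarray(x, float) - self.center[0],
                       np.asarray(y, float) - self.center[1])
        return self.A * np.log(R / rho)

    def bc(self):
        return BoundarySpec.dirichlet(lambda x, y: self.phi(x, y))

    def solve(self, cells=5, n=5, wall_mode="interpolated"):
        grid = build_grid(L, cells, self.bc())
        nbhd = build_neighborhoods(grid, [self.source], n)
        blocks = assemble_system(grid, [self.source], nbhd, PhysicalParams(),
                                 wall_mode=wall_mode)
        return grid, solve_nonreactive(blocks)


@pytest.fixture
def monopole():
    return MonopoleCase()


@pytest.fixture
def offcenter_monopole():
    return MonopoleCase(center=(100.0, 130.0))
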