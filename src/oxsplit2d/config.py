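"""YAML configuration loading for the command-line interface.

Schema (lengths in um, concentrations in nmol/cm^3, rates per second)::

    domain:
      side_um: 240.0
      cells: 5
      bc: {left: dirichlet, right: dirichlet, top: dirichlet, bottom: neumann}
      bc_values: {left: 0.0, right: 0.0, top: 68.5}     # Dirichlet only
    sources:
      - {x_um: 120.0, y_um: 120.0, r_um: 4.8, cv: 137.0, keff: 2000.0}
    params: {D: 2000.0, M: 0.0, K: 13.7, alpha: 1.39, phi_max: 137.0}
    solver: {n: 3, tol: 1.0e-10, max_iter: 50, seed: 0}
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .core import BoundarySpec, Dirichlet, Neumann, Periodic, PhysicalParams, Source, build_grid

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    grid: object
    sources: list[Source]
    params: PhysicalParams
    n: int
    tol: float
    max_iter: int
    seed: int


def _side(kind: str, value: float):
    kind = kind.lower()
    if kind == "dirichlet":
        return Dirichlet(value)
    if kind in ("neumann", "zero_flux", "no_flux"):
        return Neumann()
    if kind == "periodic":
        return Periodic()
    raise ValueError(f"unknown boundary condition kind {kind!r}")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    dom = raw["domain"]
    bc_kinds = dom.get("bc", {})
    bc_values = dom.get("bc_values", {})
    bc = BoundarySpec(**{
        s: _side(bc_kinds.get(s, "dirichlet"), float(bc_values.get(s, 0.0)))
        for s in ("left", "right", "bottom", "top")
    })
    grid = build_grid(float(dom["side_um"]), int(dom["cells"]), bc)
    sources = [
        Source((float(s["x_um"]), float(s["y_um"])), float(s["r_um"]),
               float(s["cv"]), float(s.get("keff", 2000.0)))
        for s in raw.get("sources", [])
    ]
    p = raw.get("params", {})
    params = PhysicalParams(
        D=float(p.get("D", 2000.0)), M=float(p.get("M", 0.0)),
        K=float(p.get("K", 13.7)), alpha=float(p.get("alpha", 1.39)),
        phi_max=float(p.get("phi_max", 137.0)),
    )
    sol = raw.get("solver", {})
    return RunConfig(
        grid=grid, sources=sources, params=params,
        n=int(sol.get("n", 3)), tol=float(sol.get("tol", 1e-10)),
        max_iter=int(sol.get("max_iter", 50)), seed=int(sol.get("seed", 0)),
    )
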