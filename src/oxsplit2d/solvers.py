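"""Direct solution of the nonreactive system and Newton-Raphson for the
reactive (Michaelis-Menten) system."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import SystemBlocks, metabolic_vector
from .potentials import rapid_field
from .reconstruction import Interpolator

__all__ = ["SolutionState", "solve_nonreactive", "solve_reactive", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residuals: list[float]):
        super().__init__(f"{msg}; residual trace: {residuals}")
        self.residuals = residuals


@dataclass
class SolutionState:
    """Solved slow field s (one value per cell) and wall fluxes q (per source).

    q is the 2D per-unit-depth vessel-tissue exchange
    [nmol cm^-3 um^2 s^-1]; positive q delivers oxygen to the tissue.
    """

    blocks: SystemBlocks
    s: np.ndarray
    q: np.ndarray
    iterations: int = 0
    residuals: list[float] = field(default_factory=list)

    @property
    def grid(self):
        return self.blocks.grid

    @property
    def sources(self):
        return self.blocks.sources

    @property
    def params(self):
        return self.blocks.params

    @property
    def interp(self) -> Interpolator:
        return self.blocks.interp

    # -- reconstruction access -------------------------------------------
    def cell_center_concentration(self, k: int | None = None):
        """phi_tilde_k = s_k + r_k(x_k) at one cell or all cells."""
        if k is not None:
            return float(self.s[k] + rapid_field(
                self.blocks.nbhd, k, self.q, self.grid.cell_center(k), self.params.D)[0])
        out = np.empty(self.grid.n_cells)
        for i in range(self.grid.n_cells):
            out[i] = self.s[i] + rapid_field(
                self.blocks.nbhd, i, self.q, self.grid.cell_center(i), self.params.D)[0]
        return out

    def interpolate(self, points) -> np.ndarray:
        """Sub-grid reconstruction I_phi at arbitrary points."""
        return self.interp.evaluate(self.s, self.q, points)

    def wall_average(self, j: int, mode: str = "interpolated") -> float:
        f = self.interp.wall_functional(j, mode)
        return f.value(self.s, self.q)

    def residual_norm(self) -> float:
        b = self.blocks
        metab = metabolic_vector(b, self.s, self.q) if b.params.reactive else 0.0
        r_cell = b.A @ self.s + b.B @ self.q - b.b_cell
        if b.params.reactive:
            r_cell = r_cell + metab
        r_src = b.C @ self.s + b.D @ self.q - b.b_src
        rhs = np.linalg.norm(np.concatenate([b.b_cell, b.b_src])) or 1.0
        return float(np.linalg.norm(np.concatenate([r_cell, r_src])) / rhs)


def _direct_solve(blocks: SystemBlocks) -> tuple[np.ndarray, np.ndarray]:
    M = blocks.full_matrix()
    rhs = blocks.rhs()
    try:
        lu = spla.splu(M.tocsc())
    except RuntimeError as exc:  # singular factorization
        raise ConvergenceError(f"linear system is singular or ill-conditioned: {exc}", [])
    x = lu.solve(rhs)
    F = blocks.n_cells
    return x[:F], x[F:]


def solve_nonreactive(blocks: SystemBlocks, tol: float = 1e-10) -> SolutionState:
    """Sparse direct solve of the linear (no-consumption) system."""
    s, q = _direct_solve(blocks)
    state = SolutionState(blocks, s, q, iterations=1)
    # verify with the nonreactive residual regardless of params.M
    b = blocks
    r = np.concatenate([b.A @ s + b.B @ q - b.b_cell, b.C @ s + b.D @ q - b.b_src])
    rel = float(np.linalg.norm(r) / (np.linalg.norm(blocks.rhs()) or 1.0))
    state.residuals = [rel]
    if not np.isfinite(rel) or rel > tol:
        raise ConvergenceError(f"direct solve residual {rel:.3e} above {tol:.1e}", [rel])
    return state


def solve_reactive(
    blocks: SystemBlocks,
    tol: float = 1e-10,
    max_iter: int = 50,
    max_halvings: int = 8,
    metab_nodes: int = 11,
) -> SolutionState:
    """Newton-Raphson on the coupled reactive system.

    The nonreactive solution is the initial guess; steps are damped by
    halving whenever the residual norm increases.  With M = 0 the metabolic
    vector vanishes and the method reduces to the direct linear solve.
    """
    state = solve_nonreactive(blocks)
    if not blocks.params.reactive:
        return state
    b = blocks
    s, q = state.s.copy(), state.q.copy()
    rhs_norm = np.linalg.norm(blocks.rhs()) or 1.0

    def residual(s_, q_):
        metab = metabolic_vector(b, s_, q_, n_nodes=metab_nodes)
        return np.concatenate([
            b.A @ s_ + b.B @ q_ + metab - b.b_cell,
            b.C @ s_ + b.D @ q_ - b.b_src,
        ])

    res = residual(s, q)
    history = [float(np.linalg.norm(res) / rhs_norm)]
    F = b.n_cells
    for it in range(1, max_iter + 1):
        if history[-1] <= tol:
            return SolutionState(b, s, q, iterations=it - 1, residuals=history)
        _, dms, dmq = metabolic_vector(b, s, q, n_nodes=metab_nodes, jacobian=True)
        J = sp.bmat([
            [b.A + sp.diags(dms), b.B + dmq],
            [b.C, b.D],
        ], format="csc")
        delta = spla.splu(J).solve(-res)
        step = 1.0
        accepted = None
        for _ in range(max_halvings + 1):
            s_new = s + step * delta[:F]
            q_new = q + step * delta[F:]
            try:
                res_new = residual(s_new, q_new)
            except ValueError:
                step *= 0.5
                continue
            accepted = (s_new, q_new, res_new)
            if np.linalg.norm(res_new) / rhs_norm < history[-1] or step <= 2.0 ** -max_halvings:
                break
            step *= 0.5
        if accepted is None:
            raise ConvergenceError(
                "Newton step hits the metabolic pole even after maximal damping", history)
        s, q, res = accepted
        history.append(float(np.linalg.norm(res) / rhs_norm))
    if history[-1] <= tol:
        return SolutionState(b, s, q, iterations=max_iter, residuals=history)
    raise ConvergenceError("Newton iteration did not converge", history)
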