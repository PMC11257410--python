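"""Resolved reference solution of the original boundary-value problem.

The reference resolves the concentration field around every circular
vessel wall, including its azimuthal variations, and serves as the
error oracle for the coarse multiscale model.  It represents the field
as

    phi(x) = H(x) + W(x),

where W is the sum over sources (and, on periodic domains, their
neighbouring periodic images) of exact exterior harmonics

    W_j = A_j0 ln(R_j/rho) + sum_m (R_j/rho)^m (A_jm cos m theta + B_jm sin m theta)

and H is the globally smooth harmonic remainder, solved on a fine
uniform grid (standard 5-point stencil, the same Dirichlet / zero-flux
/ periodic outer conditions as the model, with the known W contribution
moved to the data).  The multipole coefficients are fixed by collocation
on each wall: the monopole carries the Robin exchange
q_j = K_eff (<C_v>_j - phi_bar_j) and the higher harmonics cancel the
azimuthal components of the normal flux so the wall carries the uniform
flux density q_j / (2 pi R_j) of the vessel-wall condition.  Because W
is exact, the fine grid only ever represents a smooth field and the
wall fluxes converge at second order in the grid step with spectral
accuracy in the harmonics.

For the nonlinear problem the Michaelis-Menten sink (restricted to the
tissue, i.e. excluded from the vessel lumina by an area-fraction mask)
enters the H equation and is solved by Newton iteration on the same
grid inside the collocation loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RectBivariateSpline

from .core import BoundarySpec, Dirichlet, Neumann, PhysicalParams, Source

__all__ = ["ReferenceSolution", "solve_reference"]


class _Multipoles:
    """Exterior harmonic expansions of all sources (plus periodic images)."""

    def __init__(self, sources: Sequence[Source], n_harm: int, shifts: np.ndarray):
        self.sources = list(sources)
        self.n_harm = n_harm
        self.shifts = shifts            # (T, 2) tile translations, includes (0, 0)
        S = len(self.sources)
        self.coef = np.zeros((S, n_harm + 1), dtype=complex)  # coef[:,0]=A0, coef[:,m]=Am+iBm

    def _centers(self, j: int, exclude_primary: int | None) -> np.ndarray:
        cx, cy = self.sources[j].center
        cz = complex(cx, cy) + self.shifts[:, 0] + 1j * self.shifts[:, 1]
        if exclude_primary == j:
            keep = ~((self.shifts[:, 0] == 0.0) & (self.shifts[:, 1] == 0.0))
            cz = cz[keep]
        return cz

    def value(self, pts: np.ndarray, exclude_primary: int | None = None) -> np.ndarray:
        pts = np.atleast_2d(pts)
        z0 = pts[:, 0] + 1j * pts[:, 1]
        out = np.zeros(len(pts))
        for j in range(len(self.sources)):
            R = self.sources[j].radius
            c = self.coef[j]
            z = z0[None, :] - self._centers(j, exclude_primary)[:, None]
            np.copyto(z, 1e-12, where=np.abs(z) < 1e-12)
            rz = R / z
            f = c[0] * np.log(rz)
            p = np.ones_like(z)
            for m in range(1, self.n_harm + 1):
                p = p * rz
                f = f + c[m] * p
            out += np.real(f).sum(axis=0)
        return out

    def grad(self, pts: np.ndarray, exclude_primary: int | None = None) -> np.ndarray:
        pts = np.atleast_2d(pts)
        z0 = pts[:, 0] + 1j * pts[:, 1]
        gx = np.zeros(len(pts))
        gy = np.zeros(len(pts))
        for j in range(len(self.sources)):
            R = self.sources[j].radius
            c = self.coef[j]
            z = z0[None, :] - self._centers(j, exclude_primary)[:, None]
            np.copyto(z, 1e-12, where=np.abs(z) < 1e-12)
            rz = R / z
            fp = -c[0] / z
            p = np.ones_like(z)
            for m in range(1, self.n_harm + 1):
                p = p * rz
                fp = fp - m * c[m] * p / z
            fps = fp.sum(axis=0)
            gx += np.real(fps)
            gy -= np.imag(fps)
        return np.column_stack([gx, gy])


@dataclass
class ReferenceSolution:
    """Resolved field phi_ref = H + W and per-source wall fluxes q_ref."""

    side: float
    sources: list[Source]
    params: PhysicalParams
    q: np.ndarray
    wall_means: np.ndarray
    fine_cells: int
    n_harmonics: int
    iterations: int
    converged: bool
    _spline: RectBivariateSpline = field(repr=False, default=None)
    _poles: _Multipoles = field(repr=False, default=None)

    phi0: float = 0.0

    def phi(self, points) -> np.ndarray:
        """phi_ref at points (outside the source disks; inside a disk the
        analytic continuation is returned and is not physical)."""
        pts = np.atleast_2d(np.asarray(points, float))
        return self._spline.ev(pts[:, 0], pts[:, 1]) + self._poles.value(pts) + self.phi0

    def inside_any_disk(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        mask = np.zeros(len(pts), bool)
        for src in self.sources:
            for sx, sy in self._poles.shifts:
                d = pts - (src.xy + np.array([sx, sy]))
                mask |= np.hypot(d[:, 0], d[:, 1]) <= src.radius
        return mask


def _laplacian_1d(n: int, kind_low: str, kind_high: str, periodic: bool) -> sp.csr_matrix:
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    if periodic:
        L[0, -1] += 1.0
        L[-1, 0] += 1.0
    else:
        for pos, kind in ((0, kind_low), (n - 1, kind_high)):
            if kind == "dirichlet":
                L[pos, pos] = -3.0      # one interior face (+1 nbr) + half-cell wall (-2)
            else:  # zero-flux: only the interior face
                L[pos, pos] = -1.0
    return L.tocsr()


def _tissue_fraction(side: float, N: int, sources, shifts, sub: int = 6) -> np.ndarray:
    hr = side / N
    xc = (np.arange(N) + 0.5) * hr
    chi = np.ones((N, N))  # [iy, ix]
    for src in sources:
        for sx, sy in shifts:
            cx, cy = src.center[0] + sx, src.center[1] + sy
            R = src.radius
            if cx < -R or cx > side + R or cy < -R or cy > side + R:
                continue
            ix0 = max(int((cx - R) / hr) - 1, 0)
            ix1 = min(int((cx + R) / hr) + 2, N)
            iy0 = max(int((cy - R) / hr) - 1, 0)
            iy1 = min(int((cy + R) / hr) + 2, N)
            for iy in range(iy0, iy1):
                for ix in range(ix0, ix1):
                    d = math.hypot(xc[ix] - cx, xc[iy] - cy)
                    if d <= R - hr:
                        chi[iy, ix] = 0.0
                    elif d < R + hr:
                        xs = xc[ix] - hr / 2 + (np.arange(sub) + 0.5) * hr / sub
                        ys = xc[iy] - hr / 2 + (np.arange(sub) + 0.5) * hr / sub
                        gx, gy = np.meshgrid(xs, ys)
                        frac = np.mean((gx - cx) ** 2 + (gy - cy) ** 2 > R * R)
                        chi[iy, ix] = min(chi[iy, ix], frac)
    return chi


def solve_reference(
    side: float,
    bc: BoundarySpec,
    sources: Sequence[Source],
    params: PhysicalParams,
    fine_cells: int | None = None,
    n_harmonics: int = 12,
    n_theta: int = 256,
    tol: float = 1e-10,
    max_outer: int = 400,
    relax: float = 0.8,
) -> ReferenceSolution:
    """Solve the resolved BVP; see the module docstring for the method."""
    sources = list(sources)
    S = len(sources)
    if fine_cells is None:
        r_min = min((s.radius for s in sources), default=side)
        fine_cells = int(min(max(192, round(4.0 * side / r_min / 16) * 16), 320))
    N = int(fine_cells)
    hr = side / N
    D = params.D

    shifts = [(0.0, 0.0)]
    xs_sh = (-side, 0.0, side) if bc.periodic_x else (0.0,)
    ys_sh = (-side, 0.0, side) if bc.periodic_y else (0.0,)
    shifts = np.array([(sx, sy) for sx in xs_sh for sy in ys_sh])
    poles = _Multipoles(sources, n_harmonics, shifts)

    # ---- constant 5-point operator -------------------------------------
    Lx = _laplacian_1d(
        N,
        "dirichlet" if isinstance(bc.left, Dirichlet) else "flux",
        "dirichlet" if isinstance(bc.right, Dirichlet) else "flux",
        bc.periodic_x,
    )
    Ly = _laplacian_1d(
        N,
        "dirichlet" if isinstance(bc.bottom, Dirichlet) else "flux",
        "dirichlet" if isinstance(bc.top, Dirichlet) else "flux",
        bc.periodic_y,
    )
    I = sp.identity(N, format="csr")
    Lap = (sp.kron(I, Lx) + sp.kron(Ly, I)).tocsc()
    singular = not bc.has_dirichlet
    if singular:
        # rank-deficient (constant nullspace): pin cell 0 and project the
        # RHS onto the compatible subspace; a dense Lagrange bordering
        # would destroy the sparsity of the factorization
        Lap_pin = Lap.tolil()
        Lap_pin.rows[0] = [0]
        Lap_pin.data[0] = [1.0]
        lu = spla.splu(Lap_pin.tocsc())
    else:
        lu = spla.splu(Lap)

    xc = (np.arange(N) + 0.5) * hr
    chi = _tissue_fraction(side, N, sources, shifts)
    reactive = params.reactive
    centers_x, centers_y = np.meshgrid(xc, xc)  # [iy, ix]
    centers = np.column_stack([centers_x.ravel(), centers_y.ravel()])

    theta = (np.arange(n_theta) + 0.5) * 2.0 * math.pi / n_theta

    # initial monopoles: plain Robin guess with phi_bar = 0
    q = np.array([s.keff * s.cv * 0.5 for s in sources])
    poles.coef[:, 0] = q / (2.0 * math.pi * D)

    def boundary_rhs() -> np.ndarray:
        """Constants b_bc of the balance rows (moved to the RHS at solve time)."""
        b = np.zeros((N, N))  # [iy, ix]
        W_needed = S > 0
        # Dirichlet / zero-flux sides
        for sname, sel, mids, nvec in (
            ("left", (slice(None), 0), np.column_stack([np.zeros(N), xc]), (-1.0, 0.0)),
            ("right", (slice(None), N - 1), np.column_stack([np.full(N, side), xc]), (1.0, 0.0)),
            ("bottom", (0, slice(None)), np.column_stack([xc, np.zeros(N)]), (0.0, -1.0)),
            ("top", (N - 1, slice(None)), np.column_stack([xc, np.full(N, side)]), (0.0, 1.0)),
        ):
            cond = bc.side(sname)
            if isinstance(cond, Dirichlet):
                g = cond(mids[:, 0], mids[:, 1])
                if W_needed:
                    g = g - poles.value(mids)
                b[sel] += 2.0 * g
            elif isinstance(cond, Neumann):
                if W_needed:
                    gw = poles.grad(mids)
                    b[sel] += -hr * (gw @ np.array(nvec))
        # periodic wrap faces: symmetric continuation constants
        # Periodic wrap faces: each row continues H in its own frame,
        # H(x + L) = H(x) + W(x) - W(x + L), so the two sides of a seam
        # face carry different constants (W is not periodic).
        if bc.periodic_x and W_needed:
            pts_r = np.column_stack([np.full(N, side - hr / 2), xc])
            pts_l = np.column_stack([np.full(N, hr / 2), xc])
            Lv = np.array([side, 0.0])
            b[:, N - 1] += poles.value(pts_l) - poles.value(pts_l + Lv)
            b[:, 0] -= poles.value(pts_r - Lv) - poles.value(pts_r)
        if bc.periodic_y and W_needed:
            pts_t = np.column_stack([xc, np.full(N, side - hr / 2)])
            pts_b = np.column_stack([xc, np.full(N, hr / 2)])
            Lv = np.array([0.0, side])
            b[N - 1, :] += poles.value(pts_b) - poles.value(pts_b + Lv)
            b[0, :] -= poles.value(pts_t - Lv) - poles.value(pts_t)
        return b.ravel()

    W_centers = np.zeros(N * N)
    react_lu = None

    def solve_H(b_bc: np.ndarray, H0: np.ndarray) -> np.ndarray:
        if not reactive:
            rhs = -b_bc
            if singular:
                rhs = rhs - rhs.mean()
                rhs[0] = 0.0
                H = lu.solve(rhs)
                return H - H.mean()
            return lu.solve(rhs)
        # Newton on Lap H + b_bc - f_react(H) = 0.  The Jacobian changes
        # little between collocation iterations, so its factorization is
        # reused (modified Newton) and refreshed only when progress stalls.
        nonlocal react_lu
        H = H0.copy()
        chi_flat = chi.ravel()
        scale = params.M / D * hr * hr
        hscale = np.max(np.abs(H)) + np.max(np.abs(W_centers)) + abs(phi0) + 1.0
        floor = -0.9 * params.K  # keep phi away from the Michaelis-Menten pole

        def res_of(H_):
            phi = np.maximum(H_ + W_centers + phi0, floor)
            sat = np.where(chi_flat > 0, phi / (phi + params.K), 0.0)
            return phi, Lap @ H_ + b_bc - scale * chi_flat * sat

        phi, Gres = res_of(H)
        rnorm = np.linalg.norm(Gres)
        for inner in range(60):
            if react_lu is None or inner % 4 == 3:
                dsat = np.where(chi_flat > 0, params.K / (phi + params.K) ** 2, 0.0)
                # the reaction derivative renders J nonsingular even
                # without a Dirichlet side, so no pinning is needed here
                J = Lap - sp.diags(scale * chi_flat * dsat)
                react_lu = spla.splu(J.tocsc())
            dH = react_lu.solve(-Gres)
            step = 1.0
            for _ in range(20):
                phi_n, Gres_n = res_of(H + step * dH)
                rn = np.linalg.norm(Gres_n)
                if rn < rnorm or step < 1e-3:
                    break
                step *= 0.5
            H = H + step * dH
            phi, Gres, rnorm = phi_n, Gres_n, rn
            if np.max(np.abs(dH)) * step <= 1e-11 * hscale:
                break
        return H

    def build_spline(H: np.ndarray) -> RectBivariateSpline:
        Hg = H.reshape(N, N)  # [iy, ix]
        ext = np.empty((N + 2, N + 2))
        ext[1:-1, 1:-1] = Hg
        # x ghosts (columns) at -hr/2 and side+hr/2, interior rows
        for sname, col_int, col_gh, xb, xg, n_out in (
            ("left", 0, 0, 0.0, -hr / 2, np.array([-1.0, 0.0])),
            ("right", N - 1, N + 1, side, side + hr / 2, np.array([1.0, 0.0])),
        ):
            cond = bc.side(sname)
            mids = np.column_stack([np.full(N, xb), xc])
            if isinstance(cond, Dirichlet):
                g = cond(mids[:, 0], mids[:, 1]) - (poles.value(mids) if S else 0.0)
                ext[1:-1, col_gh] = 2.0 * g - Hg[:, col_int]
            elif isinstance(cond, Neumann):
                corr = -hr * (poles.grad(mids) @ n_out) if S else np.zeros(N)
                ext[1:-1, col_gh] = Hg[:, col_int] + corr
            else:  # periodic
                opp = N - 1 if col_int == 0 else 0
                pts_g = np.column_stack([np.full(N, xg), xc])
                shift = np.array([side if col_int == 0 else -side, 0.0])
                wdiff = poles.value(pts_g + shift) - poles.value(pts_g) if S else 0.0
                ext[1:-1, col_gh] = Hg[:, opp] + wdiff
        # y ghosts (rows) over the extended columns
        x_ext = np.concatenate([[-hr / 2], xc, [side + hr / 2]])
        for sname, row_int, row_gh, yb, yg, n_out in (
            ("bottom", 0, 0, 0.0, -hr / 2, np.array([0.0, -1.0])),
            ("top", N - 1, N + 1, side, side + hr / 2, np.array([0.0, 1.0])),
        ):
            cond = bc.side(sname)
            mids = np.column_stack([x_ext, np.full(N + 2, yb)])
            if isinstance(cond, Dirichlet):
                g = cond(mids[:, 0], mids[:, 1]) - (poles.value(mids) if S else 0.0)
                ext[row_gh, :] = 2.0 * g - ext[1 + row_int, :]
            elif isinstance(cond, Neumann):
                corr = -hr * (poles.grad(mids) @ n_out) if S else np.zeros(N + 2)
                ext[row_gh, :] = ext[1 + row_int, :] + corr
            else:
                opp = N - 1 if row_int == 0 else 0
                pts_g = np.column_stack([x_ext, np.full(N + 2, yg)])
                shift = np.array([0.0, side if row_int == 0 else -side])
                wdiff = poles.value(pts_g + shift) - poles.value(pts_g) if S else 0.0
                ext[row_gh, :] = ext[1 + opp, :] + wdiff
        y_ext = x_ext
        return RectBivariateSpline(x_ext, y_ext, ext.T, kx=3, ky=3)

    # ---- collocation fixed point ---------------------------------------
    H = np.zeros(N * N)
    wall_means = np.zeros(S)
    converged = False
    it = 0
    spline = None
    dq_hist: list[float] = []
    phi0 = 0.0  # free level of a pure periodic/zero-flux problem, fixed by the Robin closure
    keff_sum = sum(s.keff for s in sources) or 1.0
    for it in range(1, max_outer + 1):
        if S and reactive:
            W_centers = poles.value(centers)
        b_bc = boundary_rhs()
        H = solve_H(b_bc, H)
        spline = build_spline(H)
        if S == 0:
            converged = True
            break
        # batched wall sampling for all sources
        nvec = np.column_stack([np.cos(theta), np.sin(theta)])
        wall_all = np.concatenate(
            [src.xy[None, :] + src.radius * nvec for src in sources], axis=0)
        phi_all = spline.ev(wall_all[:, 0], wall_all[:, 1]) + poles.value(wall_all) + phi0
        grad_all = np.column_stack([
            spline.ev(wall_all[:, 0], wall_all[:, 1], dx=1),
            spline.ev(wall_all[:, 0], wall_all[:, 1], dy=1),
        ]) + poles.grad(wall_all)
        means = phi_all.reshape(S, n_theta).mean(axis=1)

        # with no Dirichlet side the field level is free: update it exactly
        # so that the total exchange balances the total consumption (zero
        # for the nonreactive problem) -- the collective level mode has a
        # destabilizing gain if handled by the relaxed fixed point
        if singular:
            if reactive:
                phi_c = H + W_centers + phi0
                sat = np.where(chi.ravel() > 0, phi_c / (phi_c + params.K), 0.0)
                q_target = params.M * float((chi.ravel() * sat).sum()) * hr * hr
            else:
                q_target = 0.0
            delta0 = (sum(s.keff * (s.cv - means[j]) for j, s in enumerate(sources)) - q_target) / keff_sum
            phi0 += delta0
            phi_all = phi_all + delta0
            means = means + delta0

        max_dq = 0.0
        max_dc = 0.0
        new_coef = poles.coef.copy()
        for j, src in enumerate(sources):
            R = src.radius
            sl = slice(j * n_theta, (j + 1) * n_theta)
            wall = wall_all[sl]
            wall_means[j] = means[j]
            q_new = src.keff * (src.cv - wall_means[j])
            # radial derivative of the smooth remainder G_j = phi - own primary term:
            # subtract the own primary multipole gradient from the batched total
            own = _Multipoles([src], n_harmonics, np.zeros((1, 2)))
            own.coef[0] = poles.coef[j]
            dGdr = ((grad_all[sl] - own.grad(wall)) * nvec).sum(axis=1)
            spec = np.fft.rfft(dGdr) / n_theta
            # account for the half-sample phase offset of the theta grid
            ms = np.arange(len(spec))
            spec = spec * np.exp(-1j * ms * theta[0])
            max_dq = max(max_dq, abs(q_new - q[j]))
            q[j] = (1 - relax) * q[j] + relax * q_new
            new_coef[j, 0] = q[j] / (2.0 * math.pi * D)
            for m in range(1, n_harmonics + 1):
                cm = 2.0 * spec[m]  # cos/sin amplitudes: c_m = Re, s_m = -Im
                target = (R / m) * complex(cm.real, -cm.imag)
                cur = poles.coef[j, m]
                upd = (1 - relax) * cur + relax * target
                max_dc = max(max_dc, abs(upd - cur))
                new_coef[j, m] = upd
        poles.coef = new_coef
        qscale = np.max(np.abs(q)) + 1e-300
        # adaptive damping: if the update envelope has not halved over the
        # last window the fixed point is under-damped (strong wall-image
        # coupling near tangency); halve the relaxation factor
        dq_hist.append(max_dq)
        if len(dq_hist) >= 12 and relax > 0.11:
            if dq_hist[-1] > 0.5 * dq_hist[-12] and dq_hist[-1] > 1e-9 * qscale:
                relax *= 0.5
                dq_hist.clear()
        if max_dq / qscale < tol and max_dc * 2 * math.pi * D / qscale < tol * 10:
            converged = True
            break

    return ReferenceSolution(
        side=side, sources=sources, params=params,
        q=q.copy(), wall_means=wall_means.copy(),
        fine_cells=N, n_harmonics=n_harmonics,
        iterations=it, converged=converged,
        _spline=spline, _poles=poles, phi0=phi0,
    )
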