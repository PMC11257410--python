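"""Analytic rapid-term machinery: single-layer potentials of circular
sources, per-cell rapid fields and face-jump functionals.

The retained part of the single-source potential is

    P_j(x) = q_j * g_j(x),    g_j(x) = ln(R_j / ||x - x_j||) / (2 pi D)

outside the disk and 0 inside (and on) the wall.  The additive constant
(the wall average phi_bar_j printed alongside the log term in the
potential-theory expression) is deliberately NOT part of the rapid term:
it is absorbed into the slow field, which keeps the wall-average closure
q_j = K_eff (<C_v>_j - I_phi(x_j)) non-circular, and makes the retained
potential vanish identically on its own wall and disk.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import NeighborhoodMap, Source

__all__ = [
    "unit_potential",
    "unit_potential_grad",
    "rapid_coeff_matrix",
    "rapid_grad_coeff_matrix",
    "rapid_field",
    "localization_error_bound",
]


def unit_potential(points: np.ndarray, center: np.ndarray, radius: float, D: float) -> np.ndarray:
    """g_j at ``points`` (N, 2): the potential per unit flux q_j.

    Continuous across the wall (ln 1 = 0) and identically zero inside the
    disk; the in-disk constancy of the full potential is represented by
    the absorbed wall-average constant.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    d = pts - np.asarray(center, float)[None, :]
    rho = np.hypot(d[:, 0], d[:, 1])
    out = np.zeros(len(pts))
    mask = rho > radius
    out[mask] = np.log(radius / rho[mask]) / (2.0 * math.pi * D)
    return out


def unit_potential_grad(points: np.ndarray, center: np.ndarray, radius: float, D: float) -> np.ndarray:
    """grad g_j at ``points``: exact radial log-gradient, zero inside the disk."""
    pts = np.atleast_2d(np.asarray(points, float))
    d = pts - np.asarray(center, float)[None, :]
    rho2 = d[:, 0] ** 2 + d[:, 1] ** 2
    grad = np.zeros_like(pts)
    mask = rho2 > radius * radius
    grad[mask] = -d[mask] / (2.0 * math.pi * D * rho2[mask, None])
    return grad


def rapid_coeff_matrix(
    entries: Sequence[tuple[int, np.ndarray]],
    sources: Sequence[Source],
    points: np.ndarray,
    D: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients of the cell rapid field r_k at ``points``.

    ``entries`` is the per-cell list of (source index, effective center)
    pairs from a :class:`NeighborhoodMap`.  Returns ``(idx, G)`` with
    ``G[a, p] = g_{idx[a]}(points[p])`` so that ``r_k(points) = q[idx] @ G``.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    idx = np.array([j for j, _ in entries], dtype=int)
    G = np.zeros((len(entries), len(pts)))
    for a, (j, eff) in enumerate(entries):
        G[a] = unit_potential(pts, eff, sources[j].radius, D)
    return idx, G


def rapid_grad_coeff_matrix(
    entries: Sequence[tuple[int, np.ndarray]],
    sources: Sequence[Source],
    points: np.ndarray,
    D: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`rapid_coeff_matrix` but for gradients: (idx, G (n_src, N, 2))."""
    pts = np.atleast_2d(np.asarray(points, float))
    idx = np.array([j for j, _ in entries], dtype=int)
    G = np.zeros((len(entries), len(pts), 2))
    for a, (j, eff) in enumerate(entries):
        G[a] = unit_potential_grad(pts, eff, sources[j].radius, D)
    return idx, G


def rapid_field(
    nbhd: NeighborhoodMap,
    k: int,
    q: np.ndarray,
    points: np.ndarray,
    D: float,
    gradient: bool = False,
):
    """Evaluate r_k (and optionally grad r_k) at arbitrary points.

    The evaluation is the analytic continuation of the cell's rapid
    field; restriction to the cell is the caller's concern.
    """
    entries = nbhd.sources_of(k)
    pts = np.atleast_2d(np.asarray(points, float))
    if not entries:
        val = np.zeros(len(pts))
        return (val, np.zeros_like(pts)) if gradient else val
    idx, G = rapid_coeff_matrix(entries, nbhd.sources, pts, D)
    val = np.asarray(q)[idx] @ G
    if not gradient:
        return val
    _, Gg = rapid_grad_coeff_matrix(entries, nbhd.sources, pts, D)
    grad = np.einsum("a,apc->pc", np.asarray(q)[idx], Gg)
    return val, grad


def localization_error_bound(
    nbhd: NeighborhoodMap,
    q: np.ndarray,
    D: float | None = None,
) -> np.ndarray:
    """Per-source upper-bound estimate of the localization error.

    For source i the neglected potentials are those of sources outside
    its neighborhood block; the bound sums 4 |q_j| / (2 pi D (n-1)^2)
    over those sources, decaying as 1/(n-1)^2 with the neighborhood
    half-width n.  Returned in concentration units (the O(1) prefactor
    of the estimate is not resolved by the analysis).
    """
    if D is None:
        raise ValueError("D must be provided")
    n = nbhd.n
    q = np.asarray(q, float)
    out = np.zeros(len(nbhd.sources))
    for i in range(len(nbhd.sources)):
        host = nbhd.grid.locate_cell(nbhd.sources[i].xy)
        neglect = [j for j in range(len(nbhd.sources)) if j != i and host not in nbhd.blocks[j]]
        out[i] = sum(4.0 * abs(q[j]) for j in neglect) / (2.0 * math.pi * D * (n - 1) ** 2)
    return out
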