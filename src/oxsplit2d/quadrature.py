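"""Composite Simpson quadrature on line segments and cells."""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["simpson_nodes_weights", "line_quadrature", "default_face_nodes", "tensor_cell_rule"]


def simpson_nodes_weights(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes (on [0, 1]) and weights of composite Simpson with ``n_nodes`` points.

    ``n_nodes`` must be odd and >= 3; the weights sum to 1.
    """
    if n_nodes < 3 or n_nodes % 2 == 0:
        raise ValueError("composite Simpson needs an odd number of nodes >= 3")
    t = np.linspace(0.0, 1.0, n_nodes)
    # composite Simpson: (h/3) * [1, 4, 2, ..., 2, 4, 1] with h = 1/(n-1)
    w = np.ones(n_nodes)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= 1.0 / (3.0 * (n_nodes - 1))
    return t, w


def default_face_nodes(h: float, r_min: float) -> int:
    """Default Simpson node count for a face of length h with smallest source radius r_min."""
    n = 2 * math.ceil(h / max(r_min, 1e-300)) + 1
    return max(n, 11)


def line_quadrature(
    fvec: Callable[[np.ndarray], np.ndarray],
    p0: np.ndarray,
    p1: np.ndarray,
    n0: int = 11,
    tol: float = 1e-9,
    max_doublings: int = 4,
) -> np.ndarray:
    """Integrate a (vector-valued) function along segment p0-p1.

    ``fvec(points)`` maps an (N, 2) array of points to an array whose last
    axis has length N; the integral is taken over that axis.  Composite
    Simpson, with panel doubling until two successive values agree to
    ``tol`` in relative terms (integrands with a source disk close to the
    face need the refinement; smooth ones stop after one doubling).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    n = n0 if n0 % 2 == 1 else n0 + 1
    prev = None
    for _ in range(max_doublings + 1):
        t, w = simpson_nodes_weights(n)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        vals = np.asarray(fvec(pts))
        integral = (vals * w).sum(axis=-1) * length
        if prev is not None:
            scale = np.max(np.abs(integral)) + np.max(np.abs(prev)) + 1e-300
            if np.max(np.abs(integral - prev)) <= tol * scale:
                return integral
        prev = integral
        n = 2 * (n - 1) + 1
    return integral


def tensor_cell_rule(x0: float, y0: float, h: float, n_nodes: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Simpson rule over the square cell [x0, x0+h] x [y0, y0+h].

    Returns (points (n^2, 2), weights (n^2,)); weights sum to the cell area.
    """
    t, w = simpson_nodes_weights(n_nodes)
    xs = x0 + t * h
    ys = y0 + t * h
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    wts = np.outer(w, w).ravel() * h * h
    return pts, wts
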