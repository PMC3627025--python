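"""Permeability tensor parameterisation from vessels in an RVE.

Three methods, all yielding symmetric positive (semi-)definite 3x3 tensors
in mm^2 Pa^-1 s^-1 at each evaluation point:

``iso``
    porosity-scaled isotropic, ``K = phi(x) I``;
``hvc``
    the Huyghe-Van Campen entrywise sum over RVE vessels,
    ``K_ij = pi / (128 vol_RVE dx0 mu) * sum d^4 dx_i dx_j / l``
    with ``d`` the vessel diameter and ``dx`` the endpoint coordinate
    differences;
``pca``
    projected principal component analysis of conductance-scaled vessel
    directions: the eigenbasis of the (reflection-symmetrised) covariance of
    direction data scaled by Poiseuille conductance, with each vessel's
    conductance distributed over the eigendirections by its normalised
    absolute projections.

Degenerate vessel sets give semi-definite tensors; ``regularize_spd`` floors
the eigenvalues to keep downstream solves well posed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .poiseuille import DEFAULT_VISCOSITY
from .rve import RVEAverager, RVESpec, nearest_fill

__all__ = [
    "TensorField",
    "k_isotropic",
    "k_hvc",
    "k_pca",
    "regularize_spd",
    "parameterise_field",
]

logger = logging.getLogger(__name__)

METHODS = ("iso", "hvc", "pca")


@dataclass
class TensorField:
    """Per-point symmetric 3x3 permeability tensors (mm^2 Pa^-1 s^-1)."""

    points: np.ndarray  # (M, 3)
    K: np.ndarray  # (M, 3, 3)
    method_tag: str
    scale: float = 1.0

    def scaled(self, s: float) -> "TensorField":
        return TensorField(self.points, self.K * s, self.method_tag, self.scale * s)


def k_isotropic(phi) -> np.ndarray:
    """Porosity-scaled identity tensors: K(x) = phi(x) I."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if np.any(phi < 0):
        raise ValueError("porosity must be non-negative")
    out = np.zeros((phi.size, 3, 3))
    out[:, [0, 1, 2], [0, 1, 2]] = phi[:, None]
    return out


def k_hvc(
    x: Sequence[float],
    rve: RVESpec,
    compartment: Optional[int],
    index: RVEAverager,
    delta_x0: float = 1.0,
    mu: float = DEFAULT_VISCOSITY,
) -> Optional[np.ndarray]:
    """Huyghe-Van Campen tensor at ``x``; ``None`` when the ball is empty.

    Partially-inside vessels are weighted by their inside-length fraction.
    """
    x = np.asarray(x, dtype=float)
    idx, frac = index.fractions(x, rve.radius)
    if compartment is not None:
        keep = index.compartment[idx] == compartment
        idx, frac = idx[keep], frac[keep]
    if idx.size == 0:
        return None
    vol = index.ball_volume_in_domain(x, rve)
    d4 = (2.0 * index.radius[idx]) ** 4
    dx = index.pb[idx] - index.pa[idx]
    w = frac * d4 / index.length[idx]
    k = np.einsum("v,vi,vj->ij", w, dx, dx)
    return math.pi / (128.0 * vol * delta_x0 * mu) * k


def k_pca(
    x: Sequence[float],
    rve: RVESpec,
    compartment: Optional[int],
    index: RVEAverager,
    mu: float = DEFAULT_VISCOSITY,
) -> Optional[np.ndarray]:
    """Projected-PCA tensor at ``x``; ``None`` when the ball is empty.

    Each vessel contributes a datum: its unit direction (oriented away from
    the node nearest ``x``) scaled by its Poiseuille conductance, reflected
    through the origin to zero the mean.  The covariance eigenbasis receives
    each vessel's conductance split across eigendirections in proportion to
    the absolute projections of the vessel direction.
    """
    x = np.asarray(x, dtype=float)
    idx, frac = index.fractions(x, rve.radius)
    if compartment is not None:
        keep = index.compartment[idx] == compartment
        idx, frac = idx[keep], frac[keep]
    if idx.size == 0:
        return None
    cond = frac * index.conductance[idx]
    pa, pb = index.pa[idx], index.pb[idx]
    # orient each vessel away from its endpoint nearest to x
    da = np.linalg.norm(pa - x, axis=1)
    db = np.linalg.norm(pb - x, axis=1)
    sign = np.where(da <= db, 1.0, -1.0)
    dirs = (pb - pa) / index.length[idx][:, None] * sign[:, None]
    data = dirs * cond[:, None]
    # reflection through 0 doubles the set but leaves sum(d d^T)/n unchanged
    cov = data.T @ data / data.shape[0]
    _, vecs = np.linalg.eigh(cov)
    proj = np.abs(dirs @ vecs)  # (n_vessels, 3) absolute projections
    norm = proj.sum(axis=1, keepdims=True)
    lam = ((proj / norm) * cond[:, None]).sum(axis=0)
    return (vecs * lam) @ vecs.T


def regularize_spd(K: np.ndarray, epsilon_rel: float = 1e-6) -> np.ndarray:
    """Floor eigenvalues at ``epsilon_rel * max(trace, tiny)``; keep symmetry."""
    K = np.asarray(K, dtype=float)
    single = K.ndim == 2
    Ks = K[None] if single else K
    if not np.allclose(Ks, np.swapaxes(Ks, -1, -2), rtol=0, atol=1e-12 * (1 + np.abs(Ks).max())):
        raise ValueError("input tensor is not symmetric")
    out = np.empty_like(Ks)
    for m in range(Ks.shape[0]):
        vals, vecs = np.linalg.eigh(Ks[m])
        floor = epsilon_rel * max(vals.sum(), np.finfo(float).tiny)
        vals = np.maximum(vals, floor)
        out[m] = (vecs * vals) @ vecs.T
        out[m] = 0.5 * (out[m] + out[m].T)
    return out[0] if single else out


def parameterise_field(
    points: np.ndarray,
    rve: RVESpec,
    compartment: Optional[int],
    method: str,
    index: RVEAverager,
    mu: float = DEFAULT_VISCOSITY,
    delta_x0: float = 1.0,
    regularize: bool = True,
) -> TensorField:
    """Permeability tensor field at ``points`` by the chosen method.

    Points whose ball holds no vessel of the compartment are filled from the
    nearest populated point (logged); tensors are SPD-regularised.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    points = np.asarray(points, dtype=float)
    M = len(points)
    K = np.full((M, 3, 3), np.nan)
    if method == "iso":
        phi = np.array([index.porosity(x, rve, compartment) for x in points])
        K = k_isotropic(phi)
        # porosity is 0 (not undefined) for empty balls; treat 0 as missing
        empty = phi == 0.0
        if empty.all():
            raise ValueError("RVE radius too small: no point sees any vessel")
        K[empty] = np.nan
    else:
        fn = k_hvc if method == "hvc" else k_pca
        for m, x in enumerate(points):
            if method == "hvc":
                k = k_hvc(x, rve, compartment, index, delta_x0=delta_x0, mu=mu)
            else:
                k = k_pca(x, rve, compartment, index, mu=mu)
            if k is not None:
                K[m] = k
    missing = ~np.isfinite(K[:, 0, 0])
    if missing.all():
        raise ValueError("RVE radius too small: no point sees any vessel")
    if missing.any():
        logger.warning(
            "%s: filling %d/%d empty-RVE tensors by nearest neighbour",
            method, int(missing.sum()), M,
        )
        for a in range(3):
            for b in range(3):
                K[:, a, b] = nearest_fill(points, K[:, a, b])
    if regularize:
        K = regularize_spd(K)
    return TensorField(points=points, K=K, method_tag=method)
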