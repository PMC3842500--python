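"""Sphere sampling and real even-order spherical-harmonic (SH) machinery.

Antipodally symmetric spherical functions (fibre orientation distributions,
diffusion signal shells) are represented on the real, orthonormal, even-order
SH basis.  Conventions used throughout the package:

* complex harmonics are scipy's ``sph_harm_y(l, m, theta, phi)`` with
  ``theta`` the polar angle from +z and Condon–Shortley phase included;
* the real basis element for ``m > 0`` is ``sqrt(2) * (-1)^m * Re(Y_l^m)``,
  for ``m < 0`` it is ``sqrt(2) * (-1)^m * Im(Y_l^|m|)``, and ``Y_l^0`` for
  ``m = 0`` — an orthonormal basis on the sphere;
* coefficient vectors enumerate even ``l = 0, 2, ..., lmax`` with
  ``m = -l..l`` inside each order, giving ``(lmax+1)(lmax+2)/2`` terms.

Self-consistency of the sign/normalisation choices is enforced by the
rotation-equivariance tests rather than trusted by convention.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_sh_coeffs",
    "sh_degrees",
    "sh_basis",
    "zonal_expand",
    "delta_sh",
    "sphere_points",
    "hemisphere_points_electrostatic",
    "cart_to_polar",
]


def n_sh_coeffs(lmax: int) -> int:
    """Number of even-order real SH coefficients up to ``lmax``."""
    if lmax % 2:
        raise ValueError("lmax must be even")
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees(lmax: int) -> np.ndarray:
    """Degree ``l`` of each coefficient in the even-order enumeration."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, lmax + 1, 2)]
    )


def cart_to_polar(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit cartesian vectors -> (polar theta from +z, azimuth phi)."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    return theta, phi


def sh_basis(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the real even-order basis at unit directions.

    Parameters
    ----------
    lmax : even int
    dirs : (n, 3) array of unit vectors

    Returns
    -------
    (n, n_sh_coeffs(lmax)) design matrix.
    """
    theta, phi = cart_to_polar(dirs)
    cols = []
    for l in range(0, lmax + 1, 2):
        # scipy evaluates all m at once via broadcasting over m
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=1)


def zonal_expand(zonal: np.ndarray, lmax: int) -> np.ndarray:
    """Zonal (m=0 only) coefficients -> full even-order coefficient vector."""
    out = np.zeros(n_sh_coeffs(lmax))
    i = 0
    for k, l in enumerate(range(0, lmax + 1, 2)):
        out[i + l] = zonal[k]  # m = 0 sits l slots into the 2l+1 block
        i += 2 * l + 1
    return out


def delta_sh(direction: np.ndarray, lmax: int) -> np.ndarray:
    """SH coefficients of the band-limited (truncated) delta at ``direction``.

    The spherical delta has coefficients ``Y_lm(direction)``; truncation at
    ``lmax`` yields the narrowest non-negative-lobe approximation the basis
    supports.  Its integral over the sphere is 1.
    """
    return sh_basis(lmax, np.asarray(direction, dtype=float)[None, :])[0]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the full sphere (Fibonacci)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def hemisphere_points_electrostatic(
    n: int, seed: int, n_iter: int = 500, step: float = 0.05
) -> np.ndarray:
    """Quasi-uniform antipodally-symmetric direction set via repulsion.

    Starts from a seeded random set and runs fixed-step gradient descent on
    the electrostatic energy ``sum 1/|xi-xj|^2 + 1/|xi+xj|^2`` (each point
    interacts with every other point and its antipode), projecting back to
    the sphere each step.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[pts[:, 2] < 0] *= -1.0
    for _ in range(n_iter):
        diff = pts[:, None, :] - pts[None, :, :]       # xi - xj
        s = pts[:, None, :] + pts[None, :, :]          # xi + xj
        d2 = np.sum(diff**2, axis=2)
        np.fill_diagonal(d2, np.inf)
        s2 = np.sum(s**2, axis=2)
        np.fill_diagonal(s2, np.inf)
        s2[s2 < 1e-12] = np.inf
        # force ~ d/|d|^4 (gradient of 1/|d|^2)
        f = (diff / d2[:, :, None] ** 2).sum(axis=1) + (
            s / s2[:, :, None] ** 2
        ).sum(axis=1)
        # remove radial component, take a capped tangential step
        f -= pts * np.sum(f * pts, axis=1, keepdims=True)
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts = pts + step * f / norm
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[pts[:, 2] < 0] *= -1.0
    return pts
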