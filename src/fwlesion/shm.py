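"""Real even-order spherical harmonics, sphere sampling and quadrature.

Conventions: the real orthonormal basis built from complex harmonics
Y_l^m(theta, phi) with theta the polar angle from +z,

    B_{l,m} = sqrt(2) * Im(Y_l^{|m|})   for m < 0
    B_{l,0} = Re(Y_l^0)
    B_{l,m} = sqrt(2) * Re(Y_l^m)       for m > 0

restricted to even l (antipodally symmetric functions such as fiber
orientation distributions and diffusion signals). Coefficient vectors are
ordered (l, m) = (0,0), (2,-2) ... (2,2), (4,-4) ... so a vector for order
``lmax`` has (lmax+1)(lmax+2)/2 entries.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "sh_degrees",
    "sh_basis",
    "zonal_indices",
    "sphere_points",
    "quadrature_grid",
    "cart_to_spherical",
]


def n_coeffs(lmax: int) -> int:
    """Number of even-order real SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be a nonnegative even integer")
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index arrays for the even-order basis up to ``lmax``."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def cart_to_spherical(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (theta polar, phi azimuth)."""
    xyz = np.asarray(xyz, dtype=float)
    theta = np.arccos(np.clip(xyz[..., 2], -1.0, 1.0))
    phi = np.arctan2(xyz[..., 1], xyz[..., 0])
    return theta, phi


def sh_basis(lmax: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real even-order basis at unit ``directions``.

    Returns an array of shape (n_directions, n_coeffs(lmax)).
    """
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    theta, phi = cart_to_spherical(directions)
    ls, ms = sh_degrees(lmax)
    out = np.empty((directions.shape[0], ls.size))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            out[:, j] = np.sqrt(2.0) * y.imag
        elif m == 0:
            out[:, j] = y.real
        else:
            out[:, j] = np.sqrt(2.0) * y.real
    return out


def zonal_indices(lmax: int) -> np.ndarray:
    """Positions of the m = 0 coefficients within the coefficient vector."""
    ls, ms = sh_degrees(lmax)
    return np.nonzero(ms == 0)[0]


def sphere_points(n: int, hemisphere: bool = False, n_repel: int = 40) -> np.ndarray:
    """n approximately uniform unit vectors (electrostatic-refined spiral)."""
    from .gradients import _hemisphere_spiral, _repel

    if hemisphere:
        return _repel(_hemisphere_spiral(n), n_iter=n_repel)
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def quadrature_grid(n_polar: int = 24, n_azimuth: int = 48) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre x uniform-azimuth product quadrature on the sphere.

    Returns (points (N,3), weights (N,)) with sum(w) = 4*pi. Exact for
    spherical polynomials of degree < min(2*n_polar, n_azimuth) - useful as an
    independent oracle for SH surface integrals.
    """
    x, wx = np.polynomial.legendre.leggauss(n_polar)  # x = cos(theta)
    phi = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    wphi = 2.0 * np.pi / n_azimuth
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct**2)
    pts = np.column_stack(
        [(st * np.cos(ph)).ravel(), (st * np.sin(ph)).ravel(), ct.ravel()]
    )
    w = (wx[:, None] * wphi * np.ones_like(ph)).ravel()
    return pts, w


def rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ v = +z (v a unit 3-vector)."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(v @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis /= s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)
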