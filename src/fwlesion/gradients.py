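"""Diffusion gradient tables (b-values and unit direction vectors).

A single-shell acquisition is described by a :class:`GradientTable`: a few
b = 0 s/mm^2 measurements plus one shell of diffusion-sensitizing directions
on the unit sphere. Directions are laid out on a hemisphere (the diffusion
signal is antipodally symmetric) by a golden-section spiral followed by a few
rounds of electrostatic repulsion, then rotated by a seeded random rotation so
different seeds give different (but equally uniform) schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientTable", "make_gradient_table", "read_bvals_bvecs", "write_bvals_bvecs"]

B0_THRESHOLD = 50.0  # s/mm^2; below this an entry counts as b=0


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, one row per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) lengths differ"
            )
        if not np.any(bvals < self.b0_threshold):
            raise ValueError("gradient table needs at least one b=0 entry")
        dwi = bvals >= self.b0_threshold
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if dwi.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("nonzero-b directions must be unit vectors (|norm - 1| <= 1e-6)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values (rounded to 1 s/mm^2)."""
        return np.unique(np.round(self.bvals[self.dwi_mask]))

    def __len__(self) -> int:
        return self.bvals.shape[0]


def _hemisphere_spiral(n: int) -> np.ndarray:
    """Golden-section spiral on the upper hemisphere; n unit vectors."""
    i = np.arange(n) + 0.5
    z = i / n  # uniform in z over (0, 1) -> hemisphere
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _repel(points: np.ndarray, n_iter: int = 30, step: float = 0.005) -> np.ndarray:
    """A few gradient-descent rounds of electrostatic repulsion with antipodal
    symmetry, projected back to the sphere after each step."""
    p = points.copy()
    for _ in range(n_iter):
        full = np.vstack([p, -p])
        diff = p[:, None, :] - full[None, :, :]  # (n, 2n, 3)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.clip(d2, 1e-6, None, out=d2)
        force = (diff / d2[..., None] ** 1.5).sum(axis=1)
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        p[p[:, 2] < 0] *= -1.0
    return p


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def make_gradient_table(
    n_directions: int, b: float = 1000.0, n_b0: int = 1, seed: int = 0
) -> GradientTable:
    """Build a single-shell table: ``n_b0`` b=0 entries followed by
    ``n_directions`` approximately uniform hemisphere directions at b.

    Deterministic given ``seed`` (the seed only rotates the direction set).
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions (tensor underdetermined)")
    if b <= 0:
        raise ValueError("shell b-value must be positive")
    rng = np.random.default_rng(seed)
    dirs = _repel(_hemisphere_spiral(n_directions))
    dirs = dirs @ _random_rotation(rng).T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def write_bvals_bvecs(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-dialect bval/bvec text files (one row of b-values; three rows
    of direction components)."""
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.9g")


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-dialect bval/bvec files into a :class:`GradientTable`."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    # re-normalize nonzero rows; files are typically printed at limited precision
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 1e-8
    bvecs[nz] /= norms[nz, None]
    return GradientTable(bvals, bvecs)
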