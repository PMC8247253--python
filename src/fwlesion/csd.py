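"""Single-shell 3-tissue constrained spherical deconvolution and AFD.

The white-matter fiber orientation distribution (FOD) is expanded in real
even-order spherical harmonics and recovered jointly with nonnegative gray-
matter and CSF signal fractions by least squares against the b0 + shell
signals, subject to FOD nonnegativity at a dense set of constraint
directions. The constrained problem is solved exactly per voxel through its
dual nonnegative-least-squares formulation (see ``_ConstrainedSolver``), so
residual FOD negativity is at numerical noise level — far inside the
documented epsilon tolerance.

Apparent fiber density (AFD) is the surface integral of the WM FOD, which
for the orthonormal real basis is simply c00 * 2 * sqrt(pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .gradients import GradientTable
from .io import DWIVolume
from .shm import n_coeffs, sh_basis, sh_degrees, sphere_points, zonal_indices, rotation_to_z
from .tensorfit import fit_dti

__all__ = [
    "ResponseSet",
    "FODField",
    "estimate_responses",
    "average_responses",
    "fit_ss3t_csd",
    "normalize_fods",
    "afd_map",
]

log = logging.getLogger(__name__)

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)
NEG_TOL = 1e-4  # FOD amplitude >= -NEG_TOL * max amplitude after fitting
N_CONSTRAINT_DIRS = 300


@dataclass(frozen=True)
class ResponseSet:
    """Per-tissue response functions for one b0 + single-shell acquisition.

    ``wm_shell`` holds the zonal (m = 0) SH coefficients of the single-fiber
    signal aligned with +z, for even l up to ``lmax``; ``wm_b0`` the l = 0
    zonal coefficient at b0. ``gm`` and ``csf`` are (b0, shell) mean signals.
    """

    shell_b: float
    wm_b0: float
    wm_shell: np.ndarray
    gm: tuple[float, float]
    csf: tuple[float, float]
    lmax: int

    def __post_init__(self):
        if self.gm[0] <= 0 or self.csf[0] <= 0:
            raise ValueError("GM/CSF responses must be positive")
        if self.wm_shell.shape[0] != self.lmax // 2 + 1:
            raise ValueError("wm_shell length inconsistent with lmax")


@dataclass
class FODField:
    """Per-voxel WM FOD SH coefficients plus isotropic tissue fractions."""

    coeffs: np.ndarray  # (..., n_coeffs(lmax)), NaN outside mask
    gm_fraction: np.ndarray
    csf_fraction: np.ndarray
    lmax: int
    mask: np.ndarray

    def __post_init__(self):
        if self.coeffs.shape[-1] != n_coeffs(self.lmax):
            raise ValueError(
                f"coefficient vector length {self.coeffs.shape[-1]} != "
                f"(lmax+1)(lmax+2)/2 = {n_coeffs(self.lmax)}"
            )


def estimate_responses(
    dwi: DWIVolume,
    gtab: GradientTable | None = None,
    masks: dict | None = None,
    lmax: int = 8,
    fa_threshold: float = 0.7,
    max_voxels: int = 300,
) -> ResponseSet:
    """Estimate WM/GM/CSF responses from the data themselves.

    WM: single-fiber voxels are taken as the ``max_voxels`` highest-FA voxels
    above ``fa_threshold`` inside the WM mask; each voxel's signal is rotated
    (principal tensor eigenvector to +z) and projected on the zonal SH basis,
    then averaged. GM/CSF: mean signal per shell over their masks.
    """
    gtab = gtab or dwi.gtab
    if masks is None or any(k not in masks for k in ("wm", "gm", "csf")):
        raise ValueError("masks must provide 'wm', 'gm' and 'csf'")
    for name in ("wm", "gm", "csf"):
        if not np.any(masks[name]):
            raise ValueError(f"{name} mask is empty")
    shells = gtab.shells
    if shells.size != 1:
        raise ValueError("response estimation expects single-shell data")
    b = float(shells[0])

    tf, metrics = fit_dti(dwi, gtab, masks["wm"])
    fa = np.where(tf.mask, metrics.fa, -np.inf)
    candidates = np.argwhere(fa > fa_threshold)
    if candidates.shape[0] == 0:
        raise ValueError(
            f"no single-fiber voxels with FA > {fa_threshold}; relax the FA threshold"
        )
    order = np.argsort(fa[tuple(candidates.T)])[::-1][:max_voxels]
    selected = candidates[order]

    mats = tf.as_matrices()
    dwi_dirs = gtab.bvecs[gtab.dwi_mask]
    ls = np.arange(0, lmax + 1, 2)
    zonal_sum = np.zeros(ls.size)
    b0_sum = 0.0
    for idx in map(tuple, selected):
        evals, evecs = np.linalg.eigh(mats[idx])
        e1 = evecs[:, np.argmax(evals)]
        rot = rotation_to_z(e1)
        rotated = dwi_dirs @ rot.T
        design = sh_basis(lmax, rotated)[:, zonal_indices(lmax)]
        sig = dwi.data[idx][gtab.dwi_mask]
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        zonal_sum += coef
        b0_sum += dwi.data[idx][gtab.b0_mask].mean()
    n = selected.shape[0]
    wm_shell = zonal_sum / n
    wm_b0 = (b0_sum / n) * TWO_SQRT_PI  # l=0 zonal coefficient of a constant

    def iso_response(mask):
        sig = dwi.data[mask]
        return float(sig[:, gtab.b0_mask].mean()), float(sig[:, gtab.dwi_mask].mean())

    return ResponseSet(b, wm_b0, wm_shell, iso_response(masks["gm"]),
                       iso_response(masks["csf"]), lmax)


def average_responses(per_subject: list[ResponseSet]) -> ResponseSet:
    """Arithmetic mean of responses across subjects (equal lmax and shell)."""
    if not per_subject:
        raise ValueError("need at least one ResponseSet")
    first = per_subject[0]
    for r in per_subject[1:]:
        if r.lmax != first.lmax or abs(r.shell_b - first.shell_b) > 1e-6:
            raise ValueError("mismatched lmax or shell b-values across subjects")
    return ResponseSet(
        first.shell_b,
        float(np.mean([r.wm_b0 for r in per_subject])),
        np.mean([r.wm_shell for r in per_subject], axis=0),
        tuple(np.mean([r.gm for r in per_subject], axis=0)),
        tuple(np.mean([r.csf for r in per_subject], axis=0)),
        first.lmax,
    )


class _ConstrainedSolver:
    """Exact solver for min 1/2 x'Px - q'x subject to C x >= 0.

    With one b0 and a single shell the three isotropic columns (WM l = 0,
    GM, CSF) are linearly dependent, so P = A'A alone is singular; a tiny
    ridge makes the QP strictly convex, and the inequality constraints pin
    the remaining flat direction. The QP is solved through its dual, which
    for P = LL' is the nonnegative least-squares problem
    min_{mu >= 0} || L^-1 C' mu + L^-1 q ||^2 (Lawson-Hanson NNLS); the
    primal solution is x = L^-T (L^-1 q + L^-1 C' mu). This is exact, so
    constraint violations are at numerical noise level.
    """

    def __init__(self, a: np.ndarray, cmat: np.ndarray, ridge: float = 1e-8):
        from scipy.linalg import cho_factor, solve_triangular

        p = a.T @ a
        p += ridge * (np.trace(p) / p.shape[0]) * np.eye(p.shape[0])
        self._solve_triangular = solve_triangular
        self.low = np.linalg.cholesky(p)
        self.mt = solve_triangular(self.low, cmat.T, lower=True)  # L^-1 C'

    def solve(self, q: np.ndarray) -> np.ndarray:
        from scipy.optimize import nnls

        u = self._solve_triangular(self.low, q, lower=True)
        mu, _ = nnls(self.mt, -u)
        return self._solve_triangular(self.low.T, u + self.mt @ mu, lower=False)


def _forward_matrix(gtab: GradientTable, responses: ResponseSet, lmax: int) -> np.ndarray:
    """Signal = M @ [fod coeffs, gm, csf] for all volumes in the table."""
    nvol = len(gtab)
    nc = n_coeffs(lmax)
    ls, _ = sh_degrees(lmax)
    m = np.zeros((nvol, nc + 2))
    # convolution weights per harmonic degree (Funk-Hecke)
    r_l = np.zeros(nc)
    for j, l in enumerate(ls):
        k = l // 2
        if k < responses.wm_shell.size:
            r_l[j] = np.sqrt(4.0 * np.pi / (2.0 * l + 1.0)) * responses.wm_shell[k]
    shell_rows = gtab.dwi_mask
    basis = sh_basis(lmax, gtab.bvecs[shell_rows])
    m[shell_rows, :nc] = basis * r_l[None, :]
    # b0 rows: only the l = 0 term survives
    m[gtab.b0_mask, 0] = np.sqrt(4.0 * np.pi) * responses.wm_b0 / TWO_SQRT_PI
    m[gtab.b0_mask, nc] = responses.gm[0]
    m[shell_rows, nc] = responses.gm[1]
    m[gtab.b0_mask, nc + 1] = responses.csf[0]
    m[shell_rows, nc + 1] = responses.csf[1]
    return m


def fit_ss3t_csd(
    dwi: DWIVolume,
    gtab: GradientTable | None = None,
    responses: ResponseSet | None = None,
    lmax: int = 8,
    mask: np.ndarray | None = None,
) -> FODField:
    """Joint WM-FOD + GM + CSF deconvolution of b0 + single-shell data.

    ``lmax`` is lowered automatically (with a warning) if the acquisition has
    fewer measurements than unknowns.
    """
    if responses is None:
        raise ValueError("group-averaged responses are required")
    gtab = gtab or dwi.gtab
    if lmax % 2:
        raise ValueError("lmax must be even")
    if gtab.shells.size != 1:
        raise ValueError("SS3T-CSD expects a single shell plus b0")
    nvol = len(gtab)
    eff_lmax = min(lmax, responses.lmax)
    while n_coeffs(eff_lmax) + 2 > nvol and eff_lmax > 0:
        eff_lmax -= 2
    if eff_lmax != lmax:
        log.warning("lmax lowered from %d to %d (%d measurements)", lmax, eff_lmax, nvol)
    if n_coeffs(eff_lmax) + 2 > nvol:
        raise ValueError("more unknowns than measurements; lower lmax or add directions")
    lmax = eff_lmax
    nc = n_coeffs(lmax)

    shape = dwi.grid_shape
    mask = np.ones(shape, dtype=bool) if mask is None else mask.astype(bool)
    fwd = _forward_matrix(gtab, responses, lmax)
    cdirs = sphere_points(N_CONSTRAINT_DIRS, hemisphere=True)
    cbasis = sh_basis(lmax, cdirs)

    # inequality rows: FOD amplitude at the constraint directions, then the
    # gm and csf fractions themselves
    cmat = np.zeros((cbasis.shape[0] + 2, nc + 2))
    cmat[: cbasis.shape[0], :nc] = cbasis
    cmat[cbasis.shape[0], nc] = 1.0
    cmat[cbasis.shape[0] + 1, nc + 1] = 1.0
    solver = _ConstrainedSolver(fwd, cmat)

    signals = dwi.data[mask]
    n = signals.shape[0]
    out = np.zeros((n, nc + 2))
    atb = signals @ fwd  # (n, nc+2)

    for v in range(n):
        out[v] = solver.solve(atb[v])

    coeffs = np.full(shape + (nc,), np.nan)
    gm = np.full(shape, np.nan)
    csf = np.full(shape, np.nan)
    coeffs[mask] = out[:, :nc]
    gm[mask] = np.clip(out[:, nc], 0.0, None)
    csf[mask] = np.clip(out[:, nc + 1], 0.0, None)
    return FODField(coeffs, gm, csf, lmax, mask.copy())


def normalize_fods(fod: FODField, wm_mask: np.ndarray | None = None) -> FODField:
    """Global intensity normalization: scale the subject's FODs and tissue
    fractions by one factor so the median (over WM voxels) total tissue
    signal (WM FOD integral + gm + csf) equals 1."""
    region = fod.mask if wm_mask is None else (wm_mask.astype(bool) & fod.mask)
    total = afd_map(fod) + fod.gm_fraction + fod.csf_fraction
    med = float(np.nanmedian(total[region]))
    if not np.isfinite(med) or med == 0:
        raise ValueError("median total tissue signal is zero; cannot normalize")
    s = 1.0 / med
    return replace(
        fod,
        coeffs=fod.coeffs * s,
        gm_fraction=fod.gm_fraction * s,
        csf_fraction=fod.csf_fraction * s,
    )


def afd_map(fod: FODField) -> np.ndarray:
    """AFD = surface integral of the FOD = c00 * 2 * sqrt(pi)."""
    return fod.coeffs[..., 0] * TWO_SQRT_PI
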