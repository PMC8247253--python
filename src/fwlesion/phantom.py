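"""Synthetic diffusion-MRI cohorts with known ground truth.

The phantom emulates the structure a free-water / fiber-density lesion
analysis assumes, on a common voxel grid shared by all subjects:

* a white-matter (WM) slab with fibers mostly along +x and a configurable
  fraction of voxels holding two fiber populations crossing at 90 degrees;
* lesion blobs ("WMH") seeded toward one face of the grid that stands in for
  the lateral ventricle; inside lesions the ground-truth free-water fraction
  (FW) rises toward that face, spanning ``fw_lesion_range``;
* fiber density negatively coupled to FW (``density = base + beta * FW``,
  clipped at zero), the mechanism behind the expected FW-AFD anticorrelation;
* per-voxel signals from a free-water + tissue mixture, where the tissue
  compartment mixes oriented fiber tensors (weighted by fiber density) with a
  hindered isotropic pool, plus Rician noise at a configurable SNR;
* per-subject covariates (age, gender, hypertension, disease duration, ICV)
  and binary outcomes (lacunes, microbleeds) drawn from logistic models on
  the mean lesion FW, with hypertension built in as a true confounder of the
  FW-microbleed association.

Everything is deterministic given ``PhantomConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .gradients import GradientTable, make_gradient_table, write_bvals_bvecs
from .io import DWIVolume, save_volume

__all__ = [
    "OutcomeModel",
    "PhantomConfig",
    "SubjectTruth",
    "simulate_voxel_signal",
    "add_rician_noise",
    "simulate_cohort",
    "draw_outcomes",
    "write_cohort",
]

D_FREE_WATER = 3.0e-3  # mm^2/s, free water at body temperature


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for one binary outcome: logit = intercept +
    fw_slope * (mean lesion FW) + hypertension_coef * hypertension."""

    intercept: float
    fw_slope: float
    hypertension_coef: float = 0.0

    def logit(self, mean_fw: float, hypertension: int) -> float:
        return self.intercept + self.fw_slope * mean_fw + self.hypertension_coef * hypertension


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (24, 24, 14)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 20
    n_directions: int = 30
    n_b0: int = 1
    b_value: float = 1000.0
    snr: float = 40.0  # b0 signal over Rician sigma; inf -> noiseless
    s0: float = 100.0
    d_iso: float = D_FREE_WATER
    # healthy fiber tensor; GM-rim voxels are purely isotropic at d_tissue_iso
    d_fiber_axial: float = 1.7e-3
    d_fiber_radial: float = 0.3e-3
    d_tissue_iso: float = 1.2e-3
    # fiber damage (1 - density) lowers axial and raises radial diffusivity,
    # the axonal-degeneration + demyelination signature
    damage_ad_slope: float = 0.3e-3
    damage_rd_slope: float = 0.5e-3
    fw_lesion_range: tuple[float, float] = (0.15, 0.70)
    fw_nawm: float = 0.10
    coupling_beta: float = -0.8
    density_base: float = 0.95
    crossing_fraction: float = 0.3
    n_lesions_range: tuple[int, int] = (2, 4)
    lesion_radius_range: tuple[float, float] = (1.5, 3.5)  # voxels, per axis
    hypertension_model: tuple[float, float] = (-3.5, 6.0)  # intercept, FW slope
    outcome_logodds: dict = field(
        default_factory=lambda: {
            "lacune": OutcomeModel(-2.5, 8.0),
            "microbleed": OutcomeModel(-4.0, 8.0, hypertension_coef=1.5),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        lo, hi = self.fw_lesion_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("fw_lesion_range must satisfy 0 <= low <= high <= 1")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class SubjectTruth:
    """Ground-truth maps and tabular data for one synthetic subject.

    ``gm_mask`` is a rim of purely hindered-isotropic tissue around the WM
    slab and ``csf_mask`` the remaining free-water background; both exist so
    3-tissue response functions can be estimated from the phantom itself.
    """

    fw_map: np.ndarray
    tissue_tensor_map: np.ndarray  # (..., 3, 3), mm^2/s
    fiber_density_map: np.ndarray
    wm_mask: np.ndarray
    wmh_mask: np.ndarray
    gm_mask: np.ndarray
    csf_mask: np.ndarray
    covariates: dict
    outcomes: dict


def simulate_voxel_signal(
    fw: float,
    tensor: np.ndarray,
    gtab: GradientTable,
    s0: float = 100.0,
    d_iso: float = D_FREE_WATER,
) -> np.ndarray:
    """Noiseless bi-tensor signal S(g, b) = s0 * [fw * exp(-b * d_iso)
    + (1 - fw) * exp(-b * g' T g)], one value per gradient entry."""
    if not 0.0 <= fw <= 1.0:
        raise ValueError("fw must lie in [0, 1]")
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T):
        raise ValueError("tensor must be a symmetric 3x3 matrix")
    if np.min(np.linalg.eigvalsh(tensor)) < -1e-15:
        raise ValueError("tensor must be positive semidefinite")
    b = gtab.bvals
    g = gtab.bvecs
    adc = np.einsum("ij,jk,ik->i", g, tensor, g)
    return s0 * (fw * np.exp(-b * d_iso) + (1.0 - fw) * np.exp(-b * adc))


def add_rician_noise(signal: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Rician-corrupt a signal: sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    ``seed`` may be an int or a numpy Generator; sigma = 0 returns the input.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# cohort construction


def _wm_slab(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    wm = np.zeros(shape, dtype=bool)
    zlo, zhi = nz // 3, nz - nz // 3
    wm[2 : nx - 2, 2 : ny - 2, zlo:zhi] = True
    return wm


def _gm_rim(wm: np.ndarray) -> np.ndarray:
    """One-voxel dilation shell around the WM slab (pure hindered tissue)."""
    from scipy.ndimage import binary_dilation

    return binary_dilation(wm, np.ones((3, 3, 3), bool)) & ~wm


def _smooth_field(shape, rng, sigma=2.0) -> np.ndarray:
    """Zero-mean, unit-std smooth random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _lesion_mask(config: PhantomConfig, wm: np.ndarray, rng) -> np.ndarray:
    nx, ny, nz = config.grid_shape
    ys, ye = 2, ny - 2  # WM y-extent; y = 0 face is the "ventricle"
    r_max = config.lesion_radius_range[1]
    wm_half = min(nx - 4, ny - 4, int(wm.sum(axis=(0, 1)).max())) / 2.0
    if r_max > wm_half:
        raise ValueError(
            f"lesion radius {r_max} exceeds the WM extent (half-width {wm_half:.1f})"
        )
    xx, yy, zz = np.meshgrid(*(np.arange(s) for s in config.grid_shape), indexing="ij")
    n_lesions = rng.integers(config.n_lesions_range[0], config.n_lesions_range[1] + 1)
    zlo = nz // 3
    zhi = nz - nz // 3
    mask = np.zeros(config.grid_shape, dtype=bool)
    for _ in range(n_lesions):
        # centers biased toward the ventricle face
        cy = ys + abs(rng.normal(0.0, 0.3 * (ye - ys)))
        cy = min(cy, ye - 1)
        cx = rng.uniform(3, nx - 3)
        cz = rng.uniform(zlo + 0.5, zhi - 0.5)
        rx, ry, rz = rng.uniform(*config.lesion_radius_range, size=3)
        rz = min(rz, (zhi - zlo) / 2.0)
        blob = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0
        mask |= blob
    return mask & wm


def _fw_and_density(config: PhantomConfig, wm, wmh, rng):
    """Ground-truth FW and fiber-density maps on the full grid."""
    ny = config.grid_shape[1]
    lo, hi = config.fw_lesion_range
    fw = np.ones(config.grid_shape)  # outside WM: CSF-like free water
    fw[wm] = np.clip(config.fw_nawm + 0.02 * _smooth_field(config.grid_shape, rng)[wm],
                     0.02, 0.3)
    # inside lesions FW rises toward the y = 0 ("ventricle") face
    yy = np.meshgrid(*(np.arange(s) for s in config.grid_shape), indexing="ij")[1]
    frac = (yy - 2) / max(ny - 5, 1)  # 0 at the face-side WM edge
    lesion_fw = hi - (hi - lo) * np.clip(frac, 0.0, 1.0)
    fw[wmh] = np.clip(lesion_fw[wmh], lo, hi)
    base = config.density_base + 0.03 * _smooth_field(config.grid_shape, rng)
    density = np.clip(base + config.coupling_beta * fw, 0.0, None)
    density[~wm] = 0.0
    return fw, density


def _damaged_diffusivities(config: PhantomConfig, density: np.ndarray):
    """Per-voxel fiber (axial, radial) diffusivity under damage 1 - density."""
    damage = np.clip(1.0 - density, 0.0, 1.0)
    ad = config.d_fiber_axial - config.damage_ad_slope * damage
    rd = config.d_fiber_radial + config.damage_rd_slope * damage
    return ad, rd


def draw_outcomes(mean_fw: float, hypertension: int, config: PhantomConfig, rng) -> dict:
    """Bernoulli outcomes from the configured logistic models."""
    out = {}
    for name, model in config.outcome_logodds.items():
        p = 1.0 / (1.0 + np.exp(-model.logit(mean_fw, hypertension)))
        out[name] = int(rng.random() < p)
    return out


def _covariates(mean_fw: float, config: PhantomConfig, rng) -> dict:
    a, b = config.hypertension_model
    p_htn = 1.0 / (1.0 + np.exp(-(a + b * mean_fw)))
    return {
        "age": float(np.clip(rng.normal(49.7, 6.5), 25.0, 75.0)),
        "gender": int(rng.random() < 0.711),
        "hypertension": int(rng.random() < p_htn),
        "duration": float(np.exp(rng.normal(np.log(2.0), 1.0))),
        "icv": float(rng.normal(4200.0, 300.0)),
    }


def simulate_subject(config: PhantomConfig, gtab: GradientTable, rng) -> tuple[DWIVolume, SubjectTruth]:
    wm = _wm_slab(config.grid_shape)
    gm = _gm_rim(wm)
    csf = ~(wm | gm)
    wmh = _lesion_mask(config, wm, rng)
    while not wmh.sum() >= 8:  # ensure enough lesion voxels for quartiles
        wmh = _lesion_mask(config, wm, rng)
    fw, density = _fw_and_density(config, wm, wmh, rng)
    fw[gm] = config.fw_nawm  # GM rim: hindered isotropic tissue, low FW
    crossing = wm & (rng.random(config.grid_shape) < config.crossing_fraction)

    ad, rd = _damaged_diffusivities(config, density)
    b, g = gtab.bvals, gtab.bvecs
    gx2, gy2 = g[:, 0] ** 2, g[:, 1] ** 2
    # fibers along +x, crossing population along +y; diag tensors, so the
    # ADC is ad*g_par^2 + rd*(1 - g_par^2)
    adc_x = ad[..., None] * gx2 + rd[..., None] * (1.0 - gx2)
    adc_y = ad[..., None] * gy2 + rd[..., None] * (1.0 - gy2)
    e_x = np.exp(-b * adc_x)
    e_y = np.exp(-b * adc_y)
    e_it = np.exp(-b * config.d_tissue_iso)
    e_fw = np.exp(-b * config.d_iso)

    tissue_att = np.where(crossing[..., None], 0.5 * (e_x + e_y), e_x)
    tissue_att[gm] = e_it  # GM rim: purely hindered isotropic tissue
    signal = config.s0 * (fw[..., None] * e_fw + (1.0 - fw[..., None]) * tissue_att)
    sigma = 0.0 if np.isinf(config.snr) else config.s0 / config.snr
    signal = add_rician_noise(signal, sigma, rng)

    # population-mean tensor as the single-tensor truth summary
    t_x = np.zeros(config.grid_shape + (3, 3))
    t_x[..., 0, 0], t_x[..., 1, 1], t_x[..., 2, 2] = ad, rd, rd
    t_y = np.zeros_like(t_x)
    t_y[..., 0, 0], t_y[..., 1, 1], t_y[..., 2, 2] = rd, ad, rd
    tensor = np.where(crossing[..., None, None], 0.5 * (t_x + t_y), t_x)
    tensor[gm] = config.d_tissue_iso * np.eye(3)

    mean_lesion_fw = float(fw[wmh].mean())
    cov = _covariates(mean_lesion_fw, config, rng)
    outcomes = draw_outcomes(mean_lesion_fw, cov["hypertension"], config, rng)

    dwi = DWIVolume(signal, gtab, config.voxel_size)
    truth = SubjectTruth(fw, tensor, density, wm, wmh, gm, csf, cov, outcomes)
    return dwi, truth


def simulate_cohort(config: PhantomConfig) -> list[tuple[DWIVolume, SubjectTruth]]:
    """Simulate ``config.n_subjects`` subjects on the shared grid.

    All randomness derives from ``config.seed``; each subject gets an
    independent child generator so cohorts are reproducible bit for bit.
    """
    gtab = make_gradient_table(
        config.n_directions, config.b_value, config.n_b0, seed=config.seed
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return [
        simulate_subject(config, gtab, np.random.default_rng(s)) for s in seeds
    ]


def simulate_outcome_table(
    n: int,
    exposure_logodds: float,
    confounder_to_exposure: float = 0.0,
    confounder_logodds: float = 0.0,
    intercept: float = -0.5,
    seed: int | np.random.Generator = 0,
):
    """Tabular cohort for logistic-regression studies: a standardized
    continuous exposure, a binary confounder linked to the exposure
    (``confounder_to_exposure`` on the logit of the confounder) and to the
    outcome (``confounder_logodds``), and a Bernoulli outcome with
    ``exposure_logodds`` per unit exposure.

    With both confounder couplings nonzero the crude exposure odds ratio is
    biased away from exp(exposure_logodds); adjusting recovers it — the
    textbook change-in-estimate scenario.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    p_conf = 1.0 / (1.0 + np.exp(-(-0.5 + confounder_to_exposure * x)))
    conf = (rng.random(n) < p_conf).astype(int)
    logit = intercept + exposure_logodds * x + confounder_logodds * conf
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    noise = rng.standard_normal(n)  # a null candidate, unrelated to anything
    return pd.DataFrame(
        {"exposure": x, "confounder": conf, "noise": noise, "outcome": y}
    )


def covariates_table(cohort) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for i, (_, truth) in enumerate(cohort):
        row = {"subject": f"sub-{i:03d}", **truth.covariates, **truth.outcomes}
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort, config: PhantomConfig, outdir: str | Path) -> None:
    """Write per-subject NIfTI/bval/bvec/mask/truth files plus covariates.tsv
    and the config (seed included) as phantom_config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (dwi, truth) in enumerate(cohort):
        sdir = outdir / f"sub-{i:03d}"
        sdir.mkdir(exist_ok=True)
        save_volume(dwi.data, sdir / "dwi.nii.gz", config.voxel_size)
        write_bvals_bvecs(dwi.gtab, sdir / "dwi.bval", sdir / "dwi.bvec")
        save_volume(truth.wm_mask.astype(np.uint8), sdir / "wm_mask.nii.gz", config.voxel_size)
        save_volume(truth.wmh_mask.astype(np.uint8), sdir / "wmh_mask.nii.gz", config.voxel_size)
        save_volume(truth.fw_map, sdir / "truth_fw.nii.gz", config.voxel_size)
        save_volume(truth.fiber_density_map, sdir / "truth_density.nii.gz", config.voxel_size)
    covariates_table(cohort).to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["outcome_logodds"] = {k: asdict(v) for k, v in config.outcome_logodds.items()}
    with open(outdir / "phantom_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
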