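"""End-to-end orchestration: phantom -> model fits -> masks/ROIs -> LPM ->
statistics, as one reproducible, seeded run.

A run is described by a :class:`RunConfig` (phantom parameters plus fitting
and analysis options). ``run_pipeline`` executes the stages in order,
collects per-subject regional tables, builds the FW-quartile lesion
probability maps, runs the statistics battery and returns a
:class:`RunReport`. Voxel-model results are cached on disk keyed by a hash
of the configuration, so the statistics can be rerun without refitting.

Statistics on small cohorts can legitimately fail (e.g. separation in a
logistic model on 20 subjects); such failures are recorded as structured
per-analysis statuses in the report rather than aborting the run. Cohorts
of fewer than 4 subjects skip the statistics stage with an explicit
"insufficient subjects" status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd as csd_mod
from . import masks as masks_mod
from . import stats as stats_mod
from .gradients import GradientTable
from .io import DWIVolume, save_volume
from .phantom import PhantomConfig, simulate_cohort, covariates_table
from .tensorfit import FreeWaterOptions, fit_dti, fit_freewater

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)

METRICS_TISSUE = ["FW", "AFD", "FAt", "MDt", "ADt", "RDt"]
METRICS_CONVENTIONAL = ["FA", "MD", "AD", "RD"]


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    d_iso: float = 3.0e-3
    smooth_weight: float = 0.3
    lmax: int = 8
    cie_threshold: float = 0.10
    cie_candidates: tuple[str, ...] = (
        "age",
        "gender",
        "hypertension",
        "wmh_volume_corrected",
        "AFD_WMH",
    )
    alpha: float = 0.05
    erode_voxels: int = 2
    outdir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["phantom"]["outcome_logodds"] = {
            k: asdict(v) for k, v in self.phantom.outcome_logodds.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    stages: dict
    regional_table: pd.DataFrame | None
    statistics: dict
    qualitative: dict
    config_hash: str

    def stage_ok(self, name: str) -> bool:
        return self.stages.get(name, {}).get("status") == "ok"


def _timed(stages: dict, name: str):
    class _Timer:
        def __enter__(self):
            stages.setdefault(name, {})
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            entry = stages.setdefault(name, {})
            entry["seconds"] = round(time.perf_counter() - self.t0, 3)
            if exc_type is None:
                entry.setdefault("status", "ok")
            else:
                entry["status"] = "failed"
                entry["error"] = f"{exc_type.__name__}: {exc}"
            return False

    return _Timer()


def _subject_regional_row(i, dwi, truth, config: RunConfig):
    """Fit all models for one subject and extract regional means."""
    gtab = dwi.gtab
    wm = truth.wm_mask
    fw_opts = FreeWaterOptions(d_iso=config.d_iso, smooth_weight=config.smooth_weight)

    _, conv = fit_dti(dwi, gtab, wm)
    fwres = fit_freewater(dwi, gtab, wm, fw_opts)
    responses = csd_mod.estimate_responses(
        dwi, gtab, {"wm": wm, "gm": truth.gm_mask, "csf": truth.csf_mask},
        lmax=config.lmax,
    )
    return conv, fwres, responses


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full phantom-to-statistics pipeline (see module docs)."""
    stages: dict = {}
    statistics: dict = {}
    qualitative: dict = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    cached = _load_cached_table(outdir, chash)
    if cached is not None:
        stages["simulate"] = stages["fit_models"] = stages["regions"] = {
            "status": "cached"
        }
        regional = cached
        if len(regional) < 4:
            stages["statistics"] = {
                "status": "skipped",
                "reason": f"insufficient subjects (n={len(regional)})",
            }
        else:
            with _timed(stages, "statistics"):
                statistics = _run_statistics(regional, config)
        with _timed(stages, "qualitative"):
            qualitative = _qualitative_summary(regional)
        return RunReport(stages, regional, statistics, qualitative, chash)

    with _timed(stages, "simulate"):
        cohort = simulate_cohort(config.phantom)
        cov_table = covariates_table(cohort)
        stages["simulate"]["n_subjects"] = len(cohort)

    # --- per-subject voxel models ------------------------------------------
    per_subject = []
    with _timed(stages, "fit_models"):
        fits = []
        for i, (dwi, truth) in enumerate(cohort):
            try:
                fits.append(_subject_regional_row(i, dwi, truth, config))
            except Exception as exc:
                raise RuntimeError(f"stage fit_models failed at subject {i}: {exc}") from exc
        group_response = csd_mod.average_responses([f[2] for f in fits])
        for i, (dwi, truth) in enumerate(cohort):
            conv, fwres, _ = fits[i]
            fod = csd_mod.fit_ss3t_csd(
                dwi, dwi.gtab, group_response, lmax=config.lmax, mask=truth.wm_mask
            )
            fod = csd_mod.normalize_fods(fod, truth.wm_mask)
            afd = csd_mod.afd_map(fod)
            per_subject.append((conv, fwres, afd))

    # --- masks and regional tables -----------------------------------------
    rows = []
    quartile_masks: dict[int, list] = {0: [], 1: [], 2: [], 3: []}
    with _timed(stages, "regions"):
        for i, (dwi, truth) in enumerate(cohort):
            conv, fwres, afd = per_subject[i]
            nawm = masks_mod.make_nawm(truth.wm_mask, truth.wmh_mask, config.erode_voxels)
            fwq = masks_mod.split_fw_quartiles(fwres.fw, truth.wmh_mask)
            for q in range(4):
                quartile_masks[q].append(fwq[q])
            mset = masks_mod.MaskSet(truth.wm_mask, truth.wmh_mask, nawm, fwq)
            mset.validate()
            metric_maps = {
                "FW": fwres.fw,
                "AFD": afd,
                "FAt": fwres.fat,
                "MDt": fwres.mdt,
                "ADt": fwres.adt,
                "RDt": fwres.rdt,
                "FA": conv.fa,
                "MD": conv.md,
                "AD": conv.ad,
                "RD": conv.rd,
            }
            row = {"subject": f"sub-{i:03d}"}
            row.update(masks_mod.regional_means(metric_maps, mset))
            row["wmh_volume_corrected"] = masks_mod.corrected_volume(
                truth.wmh_mask, dwi.voxel_size, truth.covariates["icv"]
            )
            for q in range(4):
                row[f"fwq{q + 1}_volume_corrected"] = masks_mod.corrected_volume(
                    fwq[q], dwi.voxel_size, truth.covariates["icv"]
                )
            rows.append(row)
        regional = pd.DataFrame(rows).merge(cov_table, on="subject")

    # --- lesion probability maps -------------------------------------------
    with _timed(stages, "lpm"):
        lpms = {
            f"FWq{q + 1}": masks_mod.build_lpm(
                quartile_masks[q], config.phantom.voxel_size
            )
            for q in range(4)
        }
        stages["lpm"]["peaks"] = {
            k: {"peak_probability": v.peak_probability,
                "peak_cluster_size_mm3": v.peak_cluster_size}
            for k, v in lpms.items()
        }

    # --- statistics ---------------------------------------------------------
    n_sub = len(cohort)
    if n_sub < 4:
        stages["statistics"] = {
            "status": "skipped",
            "reason": f"insufficient subjects (n={n_sub})",
        }
    else:
        with _timed(stages, "statistics"):
            statistics = _run_statistics(regional, config)

    # --- qualitative recovery summary --------------------------------------
    with _timed(stages, "qualitative"):
        qualitative = _qualitative_summary(regional)

    if outdir:
        with _timed(stages, "write"):
            regional.to_csv(outdir / "regional_table.tsv", sep="\t", index=False)
            (outdir / "config_hash.txt").write_text(chash + "\n")
            for name, lpm in lpms.items():
                save_volume(lpm.probability, outdir / f"lpm_{name}.nii.gz",
                            config.phantom.voxel_size)
            with open(outdir / "run_report.json", "w") as fh:
                json.dump(
                    {
                        "config_hash": chash,
                        "stages": stages,
                        "statistics": _jsonable(statistics),
                        "qualitative": qualitative,
                    },
                    fh, indent=2, default=str,
                )
    return RunReport(stages, regional, statistics, qualitative, chash)


def _run_statistics(regional: pd.DataFrame, config: RunConfig) -> dict:
    """The analysis battery; individual failures are recorded, not raised."""
    out: dict = {}

    def guarded(name, fn):
        try:
            out[name] = {"status": "ok", "result": fn()}
        except Exception as exc:
            out[name] = {"status": "failed", "error": str(exc)}

    # paired comparisons WMH vs NAWM for every metric
    def paired():
        res = {}
        for m in METRICS_TISSUE + METRICS_CONVENTIONAL:
            t, df, p = stats_mod.paired_t(regional[f"{m}_WMH"], regional[f"{m}_NAWM"])
            res[m] = {"t": t, "df": df, "p": p}
        return res

    guarded("paired_wmh_vs_nawm", paired)

    # MANOVA across the four FW-quartile subregions
    def manova():
        metrics = ["AFD", "FAt", "MDt", "ADt", "RDt"]
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "group": f"FWq{q}",
                        **{m: regional[f"{m}_FWq{q}"] for m in metrics},
                    }
                )
                for q in range(1, 5)
            ],
            ignore_index=True,
        ).dropna()
        rep = stats_mod.oneway_manova(long, metrics)
        return {
            "pillai": rep.pillai,
            "pillai_p": rep.pillai_p,
            "univariate": rep.univariate,
            "posthoc": rep.posthoc,
        }

    guarded("manova_subregions", manova)

    # FW/AFD vs tissue-metric correlations in WMH, crude and adjusted
    def correlations():
        pairs = [
            ("FW_WMH", "AFD_WMH"),
            ("FW_WMH", "MDt_WMH"),
            ("AFD_WMH", "FAt_WMH"),
            ("AFD_WMH", "ADt_WMH"),
            ("AFD_WMH", "RDt_WMH"),
        ]
        return stats_mod.correlation_suite(
            regional, pairs, ["age", "gender", "wmh_volume_corrected"], config.alpha
        )

    guarded("correlations_wmh", correlations)

    # logistic CIE for each outcome on WMH-mean FW
    for outcome in ("lacune", "microbleed"):
        def cie(outcome=outcome):
            candidates = [c for c in config.cie_candidates if c in regional.columns]
            rep = stats_mod.logistic_cie(
                regional, outcome, "FW_WMH", candidates, config.cie_threshold
            )
            return rep

        guarded(f"cie_{outcome}", cie)
    return out


def _qualitative_summary(regional: pd.DataFrame) -> dict:
    """Signs and orderings the phantom construction implies."""
    fw_diff = regional["FW_WMH"] - regional["FW_NAWM"]
    afd_q = regional[[f"AFD_FWq{q}" for q in range(1, 5)]].to_numpy()
    mdt_q = regional[[f"MDt_FWq{q}" for q in range(1, 5)]].to_numpy()
    r = np.corrcoef(regional["FW_WMH"], regional["AFD_WMH"])[0, 1]
    return {
        "fw_higher_in_wmh_fraction": float((fw_diff > 0).mean()),
        "fw_wmh_minus_nawm_mean": float(fw_diff.mean()),
        "fw_afd_corr_wmh": float(r),
        "afd_q1_gt_q4_fraction": float((afd_q[:, 0] > afd_q[:, 3]).mean()),
        "mdt_q4_gt_q1_fraction": float((mdt_q[:, 3] > mdt_q[:, 0]).mean()),
    }


def _load_cached_table(outdir: Path | None, chash: str) -> pd.DataFrame | None:
    """Regional table from a previous run with the same config hash, if any."""
    if outdir is None:
        return None
    table = outdir / "regional_table.tsv"
    marker = outdir / "config_hash.txt"
    if table.exists() and marker.exists() and marker.read_text().strip() == chash:
        log.info("reusing cached regional table (config hash %s)", chash)
        return pd.read_csv(table, sep="\t")
    return None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, stats_mod.CIEModelReport):
        d = asdict(obj)
        d["ledger"] = obj.ledger.to_dict(orient="records")
        return d
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def validate_inputs(
    volumes: dict[str, np.ndarray], gtab: GradientTable, covariates: pd.DataFrame | None = None
) -> dict:
    """Report-only consistency checks on a subject's inputs.

    ``volumes`` maps names to arrays (first entry sets the reference grid).
    Returns {check name: {"passed": bool, "detail": str}}.
    """
    report = {}
    names = list(volumes)
    ref_name = names[0]
    ref_shape = volumes[ref_name].shape[:3]
    for name in names[1:]:
        shape = volumes[name].shape[:3]
        report[f"grid_{name}"] = {
            "passed": shape == ref_shape,
            "detail": f"{name} {shape} vs {ref_name} {ref_shape}",
        }
    dwi_like = [n for n in names if volumes[n].ndim == 4]
    for n in dwi_like:
        ok = volumes[n].shape[3] == len(gtab)
        report[f"volumes_match_gradients_{n}"] = {
            "passed": ok,
            "detail": f"{volumes[n].shape[3]} volumes vs {len(gtab)} gradient entries",
        }
    norms = np.linalg.norm(gtab.bvecs[gtab.dwi_mask], axis=1)
    bad = np.nonzero(np.abs(norms - 1.0) > 1e-3)[0]
    report["bvec_norms"] = {
        "passed": bad.size == 0,
        "detail": "all unit" if bad.size == 0 else f"off-unit rows {bad.tolist()}",
    }
    report["single_shell"] = {
        "passed": gtab.shells.size == 1,
        "detail": f"shells {gtab.shells.tolist()}",
    }
    report["has_b0"] = {
        "passed": bool(gtab.b0_mask.any()),
        "detail": f"{int(gtab.b0_mask.sum())} b0 volumes",
    }
    if covariates is not None:
        required = {"age", "gender", "hypertension", "icv"}
        missing = sorted(required - set(covariates.columns))
        nan_cols = sorted(covariates.columns[covariates.isna().any()].tolist())
        report["covariates_complete"] = {
            "passed": not missing and not nan_cols,
            "detail": f"missing columns {missing}; columns with NaN {nan_cols}",
        }
    return report
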