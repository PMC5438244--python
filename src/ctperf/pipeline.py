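"""End-to-end orchestration of the perfusion pipeline and cohort tables.

The full run mirrors the acquisition/processing schematic: segment the four
scans, run the three deformable registrations (mutual information along the
precontrast inflation chain, normalized cross correlation for the
postcontrast pair), align the precontrast stack, fit the voxel-wise
HU-vs-volume model, correct the precontrast end-inspiratory HU to the
postcontrast inflation level, warp the postcontrast scan, subtract, and
analyze.  Every stage's outputs land in the run directory together with a
manifest (inputs, effective config, seed, package version, checksums);
rerunning with the same config and seed reproduces all numbers bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    coefficient_of_variation,
    coronal_roi_means,
    gradient_regression,
    overall_enhancement,
)
from .core import ImageVolume, read_volume, warp, write_field, write_volume
from .errors import ContractError
from .hu_correction import (
    build_aligned_stack,
    compute_perfusion,
    correct_hu,
    fit_hu_volume_model,
)
from .phantom import SCAN_NAMES, PhantomSpec, generate_series
from .registration import RegistrationConfig, register
from .segmentation import (
    DEFAULT_THRESHOLD_HU,
    lung_volume,
    percent_volume_difference,
    segment_lung,
    union_mask,
)
from .validation import save_landmarks

logger = logging.getLogger(__name__)

STAGES = ("segment", "register", "align", "fit", "correct", "warp_post",
          "perfuse", "analyze")

#: registration scan pairs as (fixed, moving) with the default similarity
REGISTRATION_PAIRS = {
    "exp_to_mid": ("mid_ins_pre", "end_exp_pre", "mi"),
    "mid_to_ins": ("end_ins_pre", "mid_ins_pre", "mi"),
    "post_to_ins": ("end_ins_pre", "end_ins_post", "ncc"),
}


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Exactly one of ``scan_paths`` (mapping the four scan names to volume
    files) or ``phantom`` must be provided.
    """

    out_dir: str
    scan_paths: dict[str, str] | None = None
    phantom: PhantomSpec | None = None
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    registration: dict[str, RegistrationConfig] = field(default_factory=dict)
    n_rois: int = 5
    sd_ddof: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scan_paths is None) == (self.phantom is None):
            raise ContractError("provide exactly one of scan_paths or phantom")
        if self.scan_paths is not None:
            missing = [s for s in SCAN_NAMES if s not in self.scan_paths]
            if missing:
                raise ContractError(f"scan paths missing for {missing}")
            absent = [p for p in self.scan_paths.values() if not os.path.exists(p)]
            if absent:
                raise ContractError(f"scan file(s) not found: {absent}")
        for key, (_, _, default_sim) in REGISTRATION_PAIRS.items():
            if key not in self.registration:
                self.registration[key] = RegistrationConfig(
                    similarity=default_sim, seed=self.seed
                )

    def to_dict(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "scan_paths": self.scan_paths,
            "phantom": dataclasses.asdict(self.phantom) if self.phantom else None,
            "threshold_hu": self.threshold_hu,
            "registration": {k: dataclasses.asdict(v) for k, v in self.registration.items()},
            "n_rois": self.n_rois,
            "sd_ddof": self.sd_ddof,
            "seed": self.seed,
        }
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_transform(transform, path: str) -> None:
    payload = {
        "format": "ctperf-bspline-1",
        "mapping": "fixed world point x (mm) -> x + displacement(x)",
        "grid_spacing_mm": list(transform.grid_spacing),
        "grid_origin_mm": list(transform.grid_origin),
        "coefficient_shape": list(transform.coefficients.shape),
        "coefficients_mm": transform.coefficients.ravel().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def run_study(
    scans: dict[str, "ImageVolume"],
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    registration: dict[str, RegistrationConfig] | None = None,
    n_rois: int = 5,
    sd_ddof: int = 1,
    on_stage=None,
) -> dict:
    """Run the perfusion computation in memory and return every artifact.

    ``scans`` maps the four scan names to volumes on a common grid.  Returns a
    dict with masks, segmented volumes (cm³), the three transforms and their
    cost breakdowns/logs, the aligned precontrast stack, the voxel-wise
    HU-vs-volume model, the corrected precontrast and deformed postcontrast
    volumes, the perfusion map, and the analysis summary.  ``on_stage`` is an
    optional callback ``(stage_name, result_so_far, info_dict)`` fired as each
    of the eight stages completes.
    """
    registration = dict(registration or {})
    for key, (_, _, default_sim) in REGISTRATION_PAIRS.items():
        registration.setdefault(key, RegistrationConfig(similarity=default_sim))
    result: dict = {}

    def done(stage, **info):
        if on_stage is not None:
            on_stage(stage, result, info)

    masks = {name: segment_lung(vol, threshold=threshold_hu) for name, vol in scans.items()}
    volumes = {name: lung_volume(mask) for name, mask in masks.items()}
    result.update(masks=masks, volumes=volumes)
    done("segment", volumes_cm3=volumes)

    transforms, costs, logs = {}, {}, {}
    for key, (fixed_name, moving_name, _) in REGISTRATION_PAIRS.items():
        merged = union_mask(masks[fixed_name], masks[moving_name])
        transform, cost, log = register(
            scans[fixed_name], scans[moving_name], merged, registration[key]
        )
        transforms[key], costs[key], logs[key] = transform, cost, log
    result.update(transforms=transforms, costs=costs, logs=logs)
    done("register", pairs=list(REGISTRATION_PAIRS),
         final_costs={k: c.total for k, c in costs.items()})

    aligned = build_aligned_stack(
        scans["end_exp_pre"], scans["mid_ins_pre"], scans["end_ins_pre"],
        t_exp_to_mid=transforms["exp_to_mid"], t_mid_to_ins=transforms["mid_to_ins"],
    )
    result["aligned"] = aligned
    done("align")

    fit_mask = masks["end_ins_pre"]
    model = fit_hu_volume_model(
        aligned,
        (volumes["end_exp_pre"], volumes["mid_ins_pre"], volumes["end_ins_pre"]),
        fit_mask,
    )
    result["model"] = model
    done("fit", volume_range_cm3=list(model.volume_range))

    corrected = correct_hu(scans["end_ins_pre"], model, volumes["end_ins_post"])
    result["corrected"] = corrected
    done("correct", target_volume_cm3=volumes["end_ins_post"])

    deformed_post = warp(
        scans["end_ins_post"], transforms["post_to_ins"].rasterize(scans["end_ins_pre"])
    )
    result["deformed_post"] = deformed_post
    done("warp_post")

    perfusion = compute_perfusion(corrected, deformed_post, fit_mask)
    result["perfusion"] = perfusion
    done("perfuse", mean_hu=perfusion.mean, sd_hu=perfusion.sd,
         negative_fraction=perfusion.negative_fraction)

    mean, sd = overall_enhancement(perfusion, ddof=sd_ddof)
    report = gradient_regression(coronal_roi_means(perfusion, n_rois))
    analysis = {
        "mean_enhancement_hu": mean,
        "sd_enhancement_hu": sd,
        "cov": coefficient_of_variation(perfusion, ddof=sd_ddof),
        "negative_fraction": perfusion.negative_fraction,
        "negative_count": perfusion.negative_count,
        "roi_means_hu": report.roi_means.tolist(),
        "roi_distances": report.distances.tolist(),
        "gradient_slope_hu": report.slope,
        "gradient_intercept_hu": report.intercept,
        "gradient_r_squared": report.r_squared,
        "gradient_p_value": report.p_value,
        "lung_volumes_cm3": volumes,
    }
    result["analysis"] = analysis
    result["gradient_report"] = report
    done("analyze", **{k: v for k, v in analysis.items() if not isinstance(v, (list, dict))})
    return result


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the eight-stage perfusion pipeline; returns the run directory."""
    t_start = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    def _write_manifest():
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def _done(stage: str, **info):
        manifest["stages"][stage] = {"status": "complete", **info}
        _write_manifest()
        logger.info("stage %s complete (%.1fs elapsed)", stage, time.time() - t_start)

    try:
        if config.phantom is not None:
            scans, truth = generate_series(config.phantom)
            save_landmarks(truth.landmarks, os.path.join(out, "truth_landmarks.csv"))
        else:
            scans = {name: read_volume(path) for name, path in config.scan_paths.items()}
            truth = None

        def write_stage(stage, result, info):
            if stage == "segment":
                for name, mask in result["masks"].items():
                    write_volume(mask.as_volume(), os.path.join(out, f"mask_{name}.nii.gz"))
            elif stage == "register":
                for key, transform in result["transforms"].items():
                    _save_transform(transform, os.path.join(out, f"transform_{key}.json"))
                    pd.DataFrame(result["logs"][key]).drop(columns="trace").to_csv(
                        os.path.join(out, f"costlog_{key}.csv"), index=False
                    )
                    write_field(transform.rasterize(scans["end_ins_pre"]),
                                os.path.join(out, f"dvf_{key}.nii.gz"))
                manifest["registration"] = {
                    key: {
                        "similarity": config.registration[key].similarity,
                        "final_cost": c.total,
                        "final_similarity": c.similarity,
                        "final_bending": c.bending,
                    }
                    for key, c in result["costs"].items()
                }
            elif stage == "correct":
                write_volume(result["corrected"], os.path.join(out, "corrected_pre.nii.gz"))
            elif stage == "warp_post":
                write_volume(result["deformed_post"], os.path.join(out, "deformed_post.nii.gz"))
            elif stage == "perfuse":
                write_volume(result["perfusion"].enhancement,
                             os.path.join(out, "perfusion.nii.gz"))
            elif stage == "analyze":
                report = result["gradient_report"]
                pd.DataFrame({"relative_distance": report.distances,
                              "mean_enhancement_hu": report.roi_means}).to_csv(
                    os.path.join(out, "roi_means.csv"), index=False)
                with open(os.path.join(out, "report.json"), "w") as fh:
                    json.dump(result["analysis"], fh, indent=2)
            _done(stage, **{k: v for k, v in info.items()
                            if not isinstance(v, (list, dict)) or k in ("volumes_cm3",
                                                                        "volume_range_cm3")})

        run_study(
            scans,
            threshold_hu=config.threshold_hu,
            registration=config.registration,
            n_rois=config.n_rois,
            sd_ddof=config.sd_ddof,
            on_stage=write_stage,
        )
    except Exception as exc:
        stage = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest()
        raise

    for name in sorted(os.listdir(out)):
        path = os.path.join(out, name)
        if name != "manifest.json" and os.path.isfile(path):
            manifest["outputs"][name] = _sha256(path)
    _write_manifest()
    return out


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def table_one_from_volumes(volumes: pd.DataFrame) -> pd.DataFrame:
    """Cohort lung-volume table with the two % difference columns.

    Expects columns subject, group, and the four ``*_cm3`` scan volumes;
    appends per-group mean rows.  The differences are midinspiration vs
    end-expiration and postcontrast vs precontrast end-inspiration, each as
    100 × (new − ref)/ref.
    """
    df = volumes.copy()
    df["pct_diff_mid_vs_exp"] = [
        percent_volume_difference(r, n)
        for r, n in zip(df["end_exp_pre_cm3"], df["mid_ins_pre_cm3"])
    ]
    df["pct_diff_post_vs_ins"] = [
        percent_volume_difference(r, n)
        for r, n in zip(df["end_ins_pre_cm3"], df["end_ins_post_cm3"])
    ]
    means = []
    numeric = [c for c in df.columns if c not in ("subject", "group")]
    for grp, sub in df.groupby("group", sort=False):
        row = {"subject": "mean", "group": grp}
        row.update({c: sub[c].mean() for c in numeric})
        means.append(row)
    return pd.concat([df, pd.DataFrame(means)], ignore_index=True)


def make_table_one(masks_per_subject: dict[str, dict], groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Build the cohort volume table from per-subject lung masks.

    ``masks_per_subject`` maps subject id -> {scan name -> LungMask}; subjects
    with a missing scan are flagged incomplete (NaN volumes, no differences).
    """
    rows = []
    for subject, masks in masks_per_subject.items():
        row: dict = {"subject": subject,
                     "group": (groups or {}).get(subject, "all")}
        complete = True
        for scan in SCAN_NAMES:
            if scan in masks:
                row[f"{scan}_cm3"] = lung_volume(masks[scan])
            else:
                row[f"{scan}_cm3"] = np.nan
                complete = False
        row["complete"] = complete
        rows.append(row)
    df = pd.DataFrame(rows)
    full = table_one_from_volumes(df[df["complete"]].drop(columns="complete"))
    if not df["complete"].all():
        incomplete = df[~df["complete"]].drop(columns="complete")
        full = pd.concat([full, incomplete], ignore_index=True)
    return full
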