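"""Orchestration: simulate -> velocimetry -> segmentation -> fields -> metrics -> stats.

Every stage is the library function the corresponding module exposes; this
module only wires them together, derives ROIs from the segmented CSF mask,
and records provenance so a manifest plus a seed reproduces every number.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _version
from .fields import PhaseContrastSeries
from .fluid_mechanics import RAD_TO_CYCLES, pressure_gradient, rotation
from .phantoms import CohortSimConfig, FluidProperties, simulate_cohort
from .roi import RoiMask, SubjectMetrics, roi_timeseries, subject_metric, validate_roi
from .segmentation import SpatialFuzzyCMeans, mask_from_membership
from .stats import GroupComparison, compare_groups, evaluate_group_pattern
from .velocimetry import detect_aliasing, phase_to_velocity, unwrap_temporal

__all__ = ["RoiPlacement", "SegmentationConfig", "RunConfig", "run_subject", "run_cohort", "CohortResult"]

log = logging.getLogger("aqueflow")

METRICS = ("velocity", "pressure_gradient", "rotation")


class RoiPlacement(BaseModel):
    """Programmatic stand-in for the study's manual entry/outlet ROIs.

    ROIs are placed on two axial slices (aqueduct entry and outlet) at the
    in-plane center of mass of the segmented CSF lumen, taking the nearest
    ``velocity_pixels`` (4-8) resp. ``rotation_pixels`` (12-20) lumen pixels.
    """

    model_config = ConfigDict(frozen=True)

    entry_slice: int = 2
    outlet_slice: int = -3
    velocity_pixels: int = Field(default=7, ge=4, le=8)
    rotation_pixels: int = Field(default=16, ge=12, le=20)


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_clusters: int = 3
    m: float = 2.0
    p: float = 1.0
    q: float = 1.0
    neighborhood_radius: int = 1
    tol: float = 1.0e-5
    max_iter: int = 200
    membership_threshold: float = 0.5


class RunConfig(BaseModel):
    """Full study-emulation configuration; every default is echoed into the
    run manifest."""

    model_config = ConfigDict(frozen=True)

    sim: CohortSimConfig = CohortSimConfig()
    fluid: FluidProperties = FluidProperties()
    segmentation: SegmentationConfig = SegmentationConfig()
    roi: RoiPlacement = RoiPlacement()
    reduction: str = "peak"
    unwrap_aliasing: bool = False
    alpha: float = 0.05
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        sim = self.sim.model_copy(update={"seed": seed})
        return self.model_copy(update={"sim": sim, "seed": seed})


def _slice_roi(
    csf: np.ndarray, z: int, n_pixels: int, quantity: str, name: str
) -> RoiMask:
    """Nearest-to-center lumen pixels on one axial slice."""
    plane = csf[:, :, z]
    ij = np.argwhere(plane)
    if ij.shape[0] < n_pixels:
        raise ValueError(
            f"slice z={z} has only {ij.shape[0]} lumen pixels, "
            f"need {n_pixels} for the {quantity} ROI"
        )
    center = ij.mean(axis=0)
    d = np.linalg.norm(ij - center, axis=1)
    order = np.lexsort((ij[:, 1], ij[:, 0], np.round(d, 9)))
    chosen = ij[order[:n_pixels]]
    idx = np.column_stack([chosen, np.full(n_pixels, z)])
    return RoiMask(indices=idx, quantity=quantity, name=name)


def run_subject(
    cfg: RunConfig,
    series: PhaseContrastSeries,
    subject_id: str = "subject",
    group: str = "unknown",
) -> SubjectMetrics:
    """Process one subject's phase-contrast series to scalar metrics.

    Deterministic given the series and config. Stage errors propagate with
    the stage name and subject id attached.
    """
    stage = "velocimetry"
    try:
        vf = phase_to_velocity(series)
        if cfg.unwrap_aliasing:
            vf = unwrap_temporal(vf, series.venc)

        stage = "segmentation"
        seg = cfg.segmentation
        est = SpatialFuzzyCMeans(
            n_clusters=seg.n_clusters, m=seg.m, p=seg.p, q=seg.q,
            neighborhood_radius=seg.neighborhood_radius, tol=seg.tol,
            max_iter=seg.max_iter,
        )
        mm = est.fit(series.magnitude.mean(axis=3)).membership_map()
        csf = mask_from_membership(mm, cluster=seg.n_clusters - 1,
                                   threshold=seg.membership_threshold)
        vf = vf.copy_with(mask=csf)

        stage = "fields"
        gp, _terms = pressure_gradient(vf, cfg.fluid)
        rot = rotation(vf)

        stage = "roi"
        nz = series.grid_shape[2]
        slices = {
            "entry": cfg.roi.entry_slice % nz,
            "outlet": cfg.roi.outlet_slice % nz,
        }
        per_quantity: dict[str, list[float]] = {m: [] for m in METRICS}
        rot_area_cm2 = cfg.roi.rotation_pixels * (series.voxel_size / 10.0) ** 2
        provenance: dict = {
            "roi_slices": slices, "reduction": cfg.reduction,
            "pixel_counts": {}, "segmentation_converged": mm.converged,
            "aliased_voxels": int(detect_aliasing(vf, series.venc)[csf].sum()),
        }
        for name, z in slices.items():
            vel_roi = validate_roi(
                _slice_roi(csf, z, cfg.roi.velocity_pixels, "velocity", name)
            )
            pg_roi = validate_roi(
                RoiMask(vel_roi.indices, "pressure_gradient", name), gp.valid
            )
            rot_roi = validate_roi(
                _slice_roi(csf, z, cfg.roi.rotation_pixels, "rotation", name),
                rot.valid,
            )
            per_quantity["velocity"].append(
                subject_metric(roi_timeseries(vf, vel_roi), cfg.reduction)
            )
            per_quantity["pressure_gradient"].append(
                subject_metric(roi_timeseries(gp, pg_roi), cfg.reduction)
            )
            per_quantity["rotation"].append(
                subject_metric(roi_timeseries(rot, rot_roi), cfg.reduction)
                * RAD_TO_CYCLES
            )
            provenance["pixel_counts"][name] = {
                "velocity": vel_roi.pixel_count,
                "pressure_gradient": pg_roi.pixel_count,
                "rotation": rot_roi.pixel_count,
            }
        # entry/outlet aggregation: arithmetic mean
        rot_metric = float(np.mean(per_quantity["rotation"]))
        return SubjectMetrics(
            subject_id=subject_id,
            group=group,
            velocity=float(np.mean(per_quantity["velocity"])),
            pressure_gradient=float(np.mean(per_quantity["pressure_gradient"])),
            rotation=rot_metric,
            rotation_per_area=rot_metric / rot_area_cm2,
            provenance=provenance,
        )
    except Exception as exc:
        raise RuntimeError(f"[{subject_id}] stage '{stage}' failed: {exc}") from exc


class CohortResult(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    table: pd.DataFrame
    truth: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    pattern: dict
    manifest: dict
    failures: list[str] = []

    def metrics_csv(self) -> str:
        return self.table.to_csv(index=False)


def run_cohort(cfg: RunConfig, out_dir: Optional[str | Path] = None) -> CohortResult:
    """Simulate and analyze a full cohort (19 controls / 10 iNPH / 7 AD by
    default), returning metrics, statistics and a reproducibility manifest.

    Individual subject failures are recorded and skipped; the run continues.
    """
    t0 = time.time()
    sim = cfg.sim.model_copy(update={"seed": cfg.seed}) if cfg.sim.seed != cfg.seed else cfg.sim
    subjects, truth = simulate_cohort(sim)
    log.info("simulated %d subjects in %.1fs", len(subjects), time.time() - t0)

    rows, failures = [], []
    for s in subjects:
        try:
            m = run_subject(cfg, s["series"], s["subject_id"], s["group"])
        except RuntimeError as exc:
            log.warning("%s", exc)
            failures.append(str(exc))
            continue
        rows.append(dict(
            subject_id=m.subject_id, group=m.group,
            velocity_cm_s=m.velocity, pg_Pa_m=m.pressure_gradient,
            rot_cyc_s=m.rotation, rot_cyc_s_cm2=m.rotation_per_area,
            velocity_pixels=m.provenance["pixel_counts"]["entry"]["velocity"],
            rotation_pixels=m.provenance["pixel_counts"]["entry"]["rotation"],
        ))
    table = pd.DataFrame(rows)
    col_of = {
        "velocity": "velocity_cm_s",
        "pressure_gradient": "pg_Pa_m",
        "rotation": "rot_cyc_s",
    }
    comparisons = {
        metric: _renamed(compare_groups(table, col), metric)
        for metric, col in col_of.items()
    }
    groups_present = list(dict.fromkeys(table["group"]))
    if "control" in groups_present and len(groups_present) >= 2:
        patients = tuple(g for g in groups_present if g != "control")
        pattern = evaluate_group_pattern(comparisons, patients=patients, alpha=cfg.alpha)
    else:
        pattern = {"matches_study_pattern": None}
    manifest = {
        "aqueflow_version": _version,
        "config": json.loads(cfg.model_dump_json()),
        "n_subjects": len(rows),
        "n_failures": len(failures),
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = CohortResult(
        table=table, truth=truth, comparisons=comparisons, pattern=pattern,
        manifest=manifest, failures=failures,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
        pd.concat(
            [c.to_frame() for c in comparisons.values()], ignore_index=True
        ).to_csv(out / "statistics.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "pattern.json").write_text(json.dumps(pattern, indent=2))
    return result


def _renamed(comp: GroupComparison, metric: str) -> GroupComparison:
    comp.metric = metric
    return comp
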