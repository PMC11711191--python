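"""End-to-end pipeline runner: synthesize (optional) → preprocess →
intensity → orientation → entanglement → report, with provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .core import SampleMeta
from .entanglement import multi_roi_density
from .intensity import intensity_contrast, roi_mean_intensity, sample_rois
from .io import write_mask, write_stack, write_tables
from .morphometry import strip_thickness, thickness_table
from .orientation import extract_fibers, roi_orientation_analysis
from .phantom import PhantomTruth, gen_fiber_stack, gen_layer_image, gen_paired_stacks
from .preprocess import process_stack
from .stats_report import report_bundle


class StageError(RuntimeError):
    def __init__(self, stage: str, ident: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed on {ident!r}: {cause}")


def run_pipeline(config: PipelineConfig, write_images: bool = False):
    """Execute the configured pipeline and write the report to
    ``config.out_dir``.  Deterministic given the config (seed included);
    report files contain no timestamps, so two runs with the same config
    are byte-identical."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if not config.synthesize:
        raise NotImplementedError(
            "running on externally supplied images is driven via the "
            "library API (io.read_stack / io.read_mask + module functions)"
        )

    # ---- synthesize -------------------------------------------------
    try:
        profiles = []
        for i, surface in enumerate(("dorsal", "ventral")):
            truth = PhantomTruth(
                layer_thickness_mm=dict(config.layer_thickness_mm),
                boundary_undulation_mm=config.boundary_undulation_mm,
                seed=config.seed + i,
            )
            mask = gen_layer_image(
                truth, width_px=config.mask_width_px,
                pixel_size_mm=config.mask_pixel_size_mm,
                meta=SampleMeta(surface=surface, distance_from_tip_cm=3.0),
            )
            if write_images:
                write_mask(mask, out / f"mask_{surface}.tif")
            profiles.append(strip_thickness(mask))

        base = PhantomTruth(
            n_fibers=config.n_fibers,
            mixture_weights=tuple(config.mixture_weights),
            fiber_radius_um=config.fiber_radius_um,
            planted_crossing_count=config.planted_crossing_count,
            intensity_scale=config.intensity_scale,
            noise_sigma_frac=config.noise_sigma_frac,
            seed=config.seed,
        )
        ventral, dorsal = gen_paired_stacks(
            base, config.intensity_ratio,
            shape_px=tuple(config.stack_shape_px),
            voxel_um=tuple(config.voxel_um),
        )
        stacks = {"dorsal": dorsal, "ventral": ventral}
    except Exception as exc:                     # noqa: BLE001
        raise StageError("synthesize", "phantom", exc) from exc

    # ---- preprocess -------------------------------------------------
    processed = {}
    for name, s in stacks.items():
        try:
            processed[name] = process_stack(
                s, clip=tuple(config.clip),
                sigma_px=config.blur_sigma_px,
                ball_radius_px=config.ball_radius_px,
            )
            if write_images:
                write_stack(processed[name], out / f"shg_{name}_processed.tif")
        except Exception as exc:                 # noqa: BLE001
            raise StageError("preprocess", name, exc) from exc

    # ---- intensity --------------------------------------------------
    try:
        intensity_results = {}
        for name, s in processed.items():
            rois = sample_rois(
                s, n=config.intensity_n_rois,
                size_um=tuple(config.intensity_roi_um),
                margin_px=config.intensity_margin_px,
                seed=config.seed,
            )
            intensity_results[name] = roi_mean_intensity(s, rois)
        contrast = intensity_contrast(
            intensity_results["ventral"], intensity_results["dorsal"]
        )
    except Exception as exc:                     # noqa: BLE001
        raise StageError("intensity", "dorsal/ventral", exc) from exc

    # ---- orientation ------------------------------------------------
    try:
        orientation_pooled = {
            name: roi_orientation_analysis(
                s, n_rois=config.orient_n_rois,
                size_um=tuple(config.orient_roi_um),
                margin_px=config.orient_margin_px,
                seed=config.seed,
                keep_fraction=config.keep_fraction,
                min_length_um=config.min_length_um,
            )
            for name, s in processed.items()
        }
    except Exception as exc:                     # noqa: BLE001
        raise StageError("orientation", "dorsal/ventral", exc) from exc

    # ---- entanglement -----------------------------------------------
    try:
        crossing_summaries = {}
        vz, vy, vx = config.voxel_um
        nz, ny, nx = config.stack_shape_px
        extent = (max(nz * vz, config.crossing_depth_um), ny * vy, nx * vx)
        for name, s in processed.items():
            fs = extract_fibers(
                s, keep_fraction=config.keep_fraction,
                min_length_um=config.min_length_um, voxel_um=tuple(config.voxel_um),
            )
            crossing_summaries[name] = multi_roi_density(
                fs, field_extent_um=extent, n_rois=4,
                voxel_um=tuple(config.voxel_um),
                roi_px=tuple(config.crossing_roi_px),
                depth_um=config.crossing_depth_um,
                seed=config.seed,
                contact_dist_um=2 * config.fiber_radius_um,
            )
    except Exception as exc:                     # noqa: BLE001
        raise StageError("entanglement", "dorsal/ventral", exc) from exc

    # ---- report -----------------------------------------------------
    report = report_bundle(
        thickness_table=thickness_table(profiles),
        intensity_results=intensity_results,
        orientation_pooled=orientation_pooled,
        crossing_summaries=crossing_summaries,
    )
    report.comparisons["intensity fold change (ventral/dorsal)"] = contrast.stat
    report.n_comparisons = len(report.comparisons)
    write_tables(report, out)

    config.to_yaml(out / "config.yaml")
    # hash a path-independent view of the config so identical analyses in
    # different directories carry identical provenance
    hashed = dataclasses.replace(config, out_dir="")
    provenance = {
        "config_sha256": hashlib.sha256(hashed.to_yaml().encode()).hexdigest(),
        "seed": config.seed,
        "fiberweave_version": __version__,
        "fold_change_ventral_over_dorsal": contrast.fold_change,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return report
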