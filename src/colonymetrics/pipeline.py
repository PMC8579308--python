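"""Config-driven orchestration: segment → distance map → requested analyses.

``run_pipeline`` ties the stages together, writes one CSV per result table
plus a metrics JSON and a provenance JSON, and is deterministic: identical
config and input produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import geometry, io, profiles, viability
from .config import RunConfig
from .types import ColonyMask, VoxelImage

__all__ = ["run_pipeline", "PipelineError", "analyze_image"]

_ANALYSIS_ROLES = {
    "biovolume": ["stable_reporter"],
    "morphology": ["stable_reporter"],
    "shell": ["stable_reporter"],
    "axial": ["stable_reporter"],
    "basal": ["stable_reporter"],
    "viability": ["stable_reporter", "dead_stain"],
    "ratio": ["stable_reporter", "unstable_reporter"],
}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _check_roles(config: RunConfig, image: VoxelImage) -> None:
    for analysis in config.analyses:
        if analysis not in _ANALYSIS_ROLES:
            raise ValueError(f"unknown analysis {analysis!r}; known: {sorted(_ANALYSIS_ROLES)}")
        for role in _ANALYSIS_ROLES[analysis]:
            if role not in image.channels:
                raise ValueError(f"analysis {analysis!r} requires channel role {role!r}, which is not mapped")


def analyze_image(image: VoxelImage, config: RunConfig) -> tuple[dict, dict]:
    """Run the configured analyses on one stack.

    Returns ``(tables, metrics)``: a dict of named DataFrames and a dict of
    scalar metrics.
    """
    _check_roles(config, image)
    tables: dict = {}
    metrics: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    if "beads" in image.channels:
        try:
            base_z = geometry.locate_focal_plane(image)
        except ValueError:
            base_z = None
    else:
        base_z = None

    mask = stage(
        "segment",
        lambda: geometry.segment_stack(
            image,
            smooth_sigma_px=config.smooth_sigma_px,
            gradient_threshold=config.gradient_threshold,
            min_area_px=config.min_slice_area_px,
        ),
    )
    if not mask.data.any():
        raise PipelineError("segment", ValueError("no colony detected in the stack"))
    if base_z is None:
        base_z = int(np.nonzero(mask.data.any(axis=(1, 2)))[0][0])
    metrics["base_z_index"] = base_z

    distmap = stage("distance_map", lambda: profiles.surface_distance_map(mask, include_base=config.include_base_as_surface))
    stable = image.channel("stable_reporter")
    bg_stable = profiles.estimate_background(stable, mask)
    metrics["background_stable"] = bg_stable

    if "biovolume" in config.analyses:
        total, per_slice = stage("biovolume", lambda: geometry.biovolume(image, mask=mask))
        tables["slice_areas"] = per_slice
        metrics["biovolume_um3"] = total

    if "morphology" in config.analyses:
        def _morph():
            profile = geometry.height_radius_profile(mask)
            tables["height_radius"] = profile.to_frame()
            vol = metrics.get("biovolume_um3")
            if vol is None:
                vol, _ = geometry.biovolume(image, mask=mask)
            try:
                slope = geometry.slope_at_height(
                    profile, config.slope_query_height_um, smooth_window=config.slope_smooth_bins
                )
            except ValueError:
                slope = None
            return geometry.morphology_metrics(mask, vol), slope

        morph, slope = stage("morphology", _morph)
        metrics["height_um"] = morph.height_um
        metrics["radius_um"] = morph.radius_um
        metrics["biovolume_um3"] = morph.biovolume_um3
        metrics["slope_at_height"] = slope
        metrics["slope_query_height_um"] = config.slope_query_height_um

    if "shell" in config.analyses:
        def _shell():
            prof = profiles.shell_profile(
                stable - bg_stable,
                distmap,
                bin_width_um=config.shell_bin_um,
                surface_reference_um=config.surface_reference_um,
            )
            lam, r2 = profiles.fit_decay_length(prof)
            return prof, lam, r2

        prof, lam, r2 = stage("shell_profile", _shell)
        tables["shell_profile"] = prof.to_frame()
        metrics["decay_length_shell_um"] = lam
        metrics["decay_fit_r2_shell"] = r2

    if "axial" in config.analyses:
        def _axial():
            prof = profiles.axial_cylinder_profile(
                stable - bg_stable,
                mask,
                cylinder_radius_um=config.cylinder_radius_um,
                surface_reference_um=config.surface_reference_um,
            )
            lam, r2 = profiles.fit_decay_length(prof)
            return prof, lam, r2

        prof, lam, r2 = stage("axial_profile", _axial)
        tables["axial_profile"] = prof.to_frame()
        metrics["decay_length_axial_um"] = lam
        metrics["decay_fit_r2_axial"] = r2

    if "basal" in config.analyses:
        prof = stage(
            "basal_profile",
            lambda: profiles.basal_plane_profile(
                stable - bg_stable, mask, base_z=base_z, bin_width_um=config.shell_bin_um
            ),
        )
        tables["basal_profile"] = prof.to_frame()

    metrics["fluorescent_fraction"] = stage(
        "fluorescent_fraction", lambda: profiles.fluorescent_fraction(stable, mask)
    )

    if "viability" in config.analyses:
        prof = stage(
            "viability",
            lambda: viability.dead_fraction_profile(
                stable,
                image.channel("dead_stain"),
                mask,
                distmap,
                shell_depth_um=config.oxic_shell_um,
                height_bin_um=config.height_bin_um,
                threshold_rule=config.threshold_rule,
                stable_threshold=config.stable_threshold,
                dead_threshold=config.dead_threshold,
                base_z=base_z,
            ),
        )
        tables["viability"] = prof.to_frame()

    if "ratio" in config.analyses:
        def _ratio():
            unstable = image.channel("unstable_reporter")
            bg_u = profiles.estimate_background(unstable, mask)
            return viability.reporter_ratio_foldchange(
                unstable,
                stable,
                mask,
                distmap,
                h_hi_um=config.ratio_height_hi_um,
                h_lo_um=config.ratio_height_lo_um,
                shell_depth_um=config.oxic_shell_um,
                height_bin_um=config.height_bin_um,
                background_unstable=bg_u,
                background_stable=bg_stable,
                base_z=base_z,
            )

        fold, table = stage("ratio", _ratio)
        tables["reporter_ratio"] = table
        metrics["ratio_foldchange"] = fold
        metrics["ratio_heights_um"] = [config.ratio_height_hi_um, config.ratio_height_lo_um]

    return tables, metrics


def run_pipeline(config: RunConfig, input_path: str | Path, out_dir: str | Path) -> dict:
    """Read a stack, run all configured analyses, write tables + provenance.

    Returns the metrics dict.  Identical config and input produce
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        image = io.read_stack(input_path, config)
    except Exception as exc:
        raise PipelineError("read", exc) from exc
    tables, metrics = analyze_image(image, config)
    for name, table in sorted(tables.items()):
        io.write_table(table, out / f"{name}.csv")
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    io.write_provenance(out / "provenance.json", config, extra={"input": str(Path(input_path).name)})
    return metrics
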