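"""Config-driven orchestration of the full analysis workflow.

One run mirrors the assay end to end, per condition and replicate: obtain a
stack (synthetic phantom or files on disk) -> average intensity projection ->
background threshold mask -> spectral phasor transform -> ROI segmentation in
the phasor plane (ROIs from JSON, or derived from pure-class reference
spectra) -> back-projection -> segment spectra -> ratiometric, percent-area
and volumetric quantification -> group statistics across conditions.  Every
threshold, seed and ROI actually used is recorded in a machine-readable
summary JSON, and a run with the same config and seed reproduces that JSON
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import phasor_core, quantify, synth_phantom
from .errors import ConfigError, SRSPhasorError, StageError
from .hyperstack_io import (
    HyperStack,
    average_projection,
    background_mask,
    read_labels,
    read_stack,
    write_labels,
)

__all__ = ["ConditionConfig", "RunConfig", "RunReport", "run"]

_PRESETS = {
    "default": synth_phantom.default_phantom_config,
    "control": synth_phantom.control_phantom_config,
    "steatosis": synth_phantom.steatosis_phantom_config,
    "phospholipidosis": synth_phantom.phospholipidosis_phantom_config,
    "coloc": synth_phantom.coloc_phantom_config,
}

_DEFAULT_ROI_CLASSES = ("nucleus", "cytoplasm", "steatosis", "phospholipidosis")


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental condition: a phantom recipe or stack files on disk."""

    name: str
    phantom: synth_phantom.PhantomConfig | None = None
    stack_path: str | None = None
    sidecar_path: str | None = None
    instances_path: str | None = None

    def __post_init__(self):
        has_phantom = self.phantom is not None
        has_stack = self.stack_path is not None
        if has_phantom == has_stack:
            raise ConfigError(
                f"condition {self.name!r} must have exactly one input source "
                "(phantom or stack_path)"
            )


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full analysis run."""

    conditions: tuple[ConditionConfig, ...]
    seed: int
    output_dir: str
    n_replicates: int = 1
    mask_method: str = "otsu"
    manual_threshold: float | None = None
    harmonic: int = 1
    roi_json: str | None = None
    roi_classes: tuple[str, ...] = _DEFAULT_ROI_CLASSES
    roi_padding: float = 0.025
    reference_shape: tuple[int, int] = (24, 24)
    quantify_ratio: bool = True
    quantify_percent_area: bool = True
    quantify_volume: bool = True
    quantify_coloc: bool = False
    figures: bool = True

    def __post_init__(self):
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.mask_method not in ("otsu", "manual"):
            raise ConfigError(f"unknown mask method {self.mask_method!r}")
        if self.mask_method == "manual" and self.manual_threshold is None:
            raise ConfigError("mask_method='manual' requires manual_threshold")
        if self.harmonic < 1:
            raise ConfigError("harmonic must be >= 1")
        if self.roi_json is not None and not os.path.exists(self.roi_json):
            raise ConfigError(f"ROI file {self.roi_json!r} does not exist")
        for cond in self.conditions:
            for p in (cond.stack_path, cond.sidecar_path, cond.instances_path):
                if p is not None and not os.path.exists(p):
                    raise ConfigError(f"condition {cond.name!r}: file {p!r} does not exist")
        unknown = set(self.roi_classes) - set(phasor_core.ROI_LABEL_IDS)
        if unknown:
            raise ConfigError(f"unknown ROI classes {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path!r}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        try:
            conditions = []
            for entry in raw.get("conditions", []):
                name = entry["name"]
                if "preset" in entry:
                    preset = entry["preset"]
                    if preset not in _PRESETS:
                        raise ConfigError(
                            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
                        )
                    overrides = entry.get("overrides", {})
                    phantom = _PRESETS[preset](seed=0, **overrides)
                    conditions.append(ConditionConfig(name=name, phantom=phantom))
                else:
                    conditions.append(
                        ConditionConfig(
                            name=name,
                            stack_path=entry.get("stack"),
                            sidecar_path=entry.get("sidecar"),
                            instances_path=entry.get("instances"),
                        )
                    )
            kwargs = {
                k: raw[k]
                for k in (
                    "n_replicates", "mask_method", "manual_threshold", "harmonic",
                    "roi_json", "roi_padding", "quantify_ratio", "quantify_percent_area",
                    "quantify_volume", "quantify_coloc", "figures",
                )
                if k in raw
            }
            if "roi_classes" in raw:
                kwargs["roi_classes"] = tuple(raw["roi_classes"])
            if "reference_shape" in raw:
                kwargs["reference_shape"] = tuple(raw["reference_shape"])
            return cls(
                conditions=tuple(conditions),
                seed=int(raw["seed"]),
                output_dir=str(raw["output_dir"]),
                **kwargs,
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid config: {exc}") from exc


@dataclass
class RunReport:
    """Outputs of one run: summary dict plus the assembled tables and paths."""

    summary: dict
    cell_stats: pd.DataFrame
    droplets: pd.DataFrame
    spectra: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _replicate_seed(base_seed: int, cond_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), cond_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def _reference_phasor_map(model, axis, noise, intensity_scale, shape, seed, harmonic):
    """Phasor cloud of a homogeneous stack of one spectral model at run noise."""
    spectrum = intensity_scale * synth_phantom.evaluate_spectrum(model, axis)
    data = np.broadcast_to(spectrum, (*shape, axis.n_channels)).copy()
    rng = np.random.default_rng(seed)
    if noise.poisson_scale > 0:
        p = noise.poisson_scale
        data = rng.poisson(data / p).astype(float) * p
    if noise.gaussian_sd > 0:
        data = np.clip(data + rng.normal(0.0, noise.gaussian_sd, size=data.shape), 0.0, None)
    return phasor_core.phasor_transform(data, harmonic=harmonic)


def derive_class_rois(
    classes,
    axis,
    noise=None,
    intensity_scale: float = 1000.0,
    padding: float = 0.025,
    reference_shape=(24, 24),
    seed: int = 0,
    harmonic: int = 1,
    library: dict | None = None,
    compartment_models: dict | None = None,
) -> list[phasor_core.PhasorROI]:
    """Derive one phasor ROI per class from its reference spectral model.

    With a noise model the reference is a small homogeneous noisy stack
    (so the ROI hull adapts to the run's phasor scatter); without one the
    analytic model phasor is used and the ROI is the padding disc around it.
    """
    library = library or synth_phantom.default_library()
    models = dict(synth_phantom._default_compartment_models())
    if compartment_models:
        models.update(compartment_models)
    rois = []
    for i, cls in enumerate(classes):
        model = library[models[cls]]
        if noise is not None and not noise.is_noiseless:
            ref = _reference_phasor_map(
                model, axis, noise, intensity_scale, reference_shape,
                seed=_replicate_seed(seed, 7700 + i, 0), harmonic=harmonic,
            )
        else:
            ref = model
        rois.append(
            phasor_core.derive_roi_from_reference(
                ref, padding=padding, label=cls, axis=axis, harmonic=harmonic
            )
        )
    return rois


def _stage(name):
    """Decorator-free stage guard: wraps exceptions with the stage name."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Guard()


def _load_condition_stack(cond: ConditionConfig, seed: int):
    if cond.phantom is not None:
        phantom = synth_phantom.generate_phantom(cond.phantom.replace(seed=seed))
        stack = phantom.stack
        if stack.is_volumetric and stack.data.shape[0] == 1:
            planar = stack.plane(0)
        else:
            planar = stack
        return stack, planar, phantom.truth_labels, phantom.cell_instances
    stack = read_stack(cond.stack_path, cond.sidecar_path)
    planar = stack.plane(0) if (stack.is_volumetric and stack.data.shape[0] == 1) else stack
    instances = read_labels(cond.instances_path) if cond.instances_path else None
    return stack, planar, None, instances


def run(config: RunConfig) -> RunReport:
    """Execute the full workflow and write all outputs to ``config.output_dir``."""
    os.makedirs(config.output_dir, exist_ok=True)
    summary: dict = {
        "seed": int(config.seed),
        "harmonic": int(config.harmonic),
        "mask_method": config.mask_method,
        "roi_padding": float(config.roi_padding),
        "library_version": synth_phantom.LIBRARY_VERSION,
        "conditions": {},
    }
    paths: dict = {}
    cell_rows, droplet_frames, spectra_rows = [], [], []

    with _stage("rois"):
        if config.roi_json is not None:
            rois = phasor_core.load_rois(config.roi_json)
            summary["roi_source"] = "json"
        else:
            first = config.conditions[0]
            axis = (
                first.phantom.resolved_axis()
                if first.phantom is not None
                else read_stack(first.stack_path, first.sidecar_path).axis
            )
            noise = first.phantom.noise if first.phantom is not None else None
            scale = first.phantom.intensity_scale if first.phantom is not None else 1000.0
            models = first.phantom.compartment_models if first.phantom is not None else None
            rois = derive_class_rois(
                config.roi_classes, axis, noise=noise, intensity_scale=scale,
                padding=config.roi_padding, reference_shape=config.reference_shape,
                seed=config.seed, harmonic=config.harmonic, compartment_models=models,
            )
            summary["roi_source"] = "derived-from-reference-models"
        roi_path = os.path.join(config.output_dir, "rois.json")
        phasor_core.save_rois(rois, roi_path)
        paths["rois"] = roi_path
        summary["rois"] = {
            r.label: [[float(g), float(s)] for g, s in r.vertices] for r in rois
        }

    for ci, cond in enumerate(config.conditions):
        cond_summary: dict = {"replicates": {}}
        summary["conditions"][cond.name] = cond_summary
        for rep in range(config.n_replicates):
            rep_key = f"rep{rep}"
            rep_summary: dict = {}
            cond_summary["replicates"][rep_key] = rep_summary

            with _stage("input"):
                seed = _replicate_seed(config.seed, ci, rep)
                stack, planar, truth, instances = _load_condition_stack(cond, seed)
                rep_summary["seed"] = seed
                rep_summary["spatial_shape"] = list(planar.spatial_shape)

            with _stage("mask"):
                avg = average_projection(planar)
                mask = background_mask(avg, config.mask_method, config.manual_threshold)
                rep_summary["background_threshold"] = mask.provenance["threshold"]

            with _stage("phasor"):
                pmap = phasor_core.phasor_transform(planar, config.harmonic, mask)
                rep_summary["n_valid_pixels"] = int(pmap.valid.sum())

            with _stage("segment"):
                labels = phasor_core.segment_by_rois(pmap, rois)
                label_path = os.path.join(
                    config.output_dir, f"{cond.name}_{rep_key}_labels.tif"
                )
                write_labels(labels, label_path)
                paths.setdefault("labels", []).append(label_path)

            with _stage("spectra"):
                for roi in rois:
                    lab = phasor_core.ROI_LABEL_IDS.get(roi.label)
                    if lab is None or not np.any(labels == lab):
                        continue
                    seg = phasor_core.segment_spectrum(planar, labels, lab, "max")
                    for nu, val in zip(planar.axis.values, seg.mean_spectrum):
                        spectra_rows.append(
                            {
                                "condition": cond.name, "replicate": rep,
                                "segment": roi.label, "wavenumber_cm1": float(nu),
                                "normalized_intensity": float(val),
                                "pixel_count": seg.pixel_count,
                            }
                        )

            with _stage("quantify"):
                if instances is None:
                    inst2d = mask.mask.astype(np.uint16)  # whole foreground as one cell
                elif instances.ndim == 3 and labels.ndim == 2:
                    inst2d = instances[0] if instances.shape[0] == 1 else instances.max(axis=0)
                else:
                    inst2d = instances
                rmap = quantify.ratio_map(planar, mask=mask) if config.quantify_ratio else None

                droplets = None
                if config.quantify_volume and stack.is_volumetric and stack.data.shape[0] > 1:
                    vol = stack.channel(quantify.CH2_SHIFT)
                    fg3d = np.broadcast_to(mask.mask, vol.shape)
                    inst3d = instances if (instances is not None and instances.ndim == 3) else None
                    droplets, _ = quantify.ld_segment_3d(
                        vol, stack.pixel_size, stack.z_step,
                        foreground=fg3d, cell_instances=inst3d,
                    )
                    droplets.insert(0, "condition", cond.name)
                    droplets.insert(1, "replicate", rep)
                    droplet_frames.append(droplets)
                    rep_summary["n_droplets"] = int(len(droplets))

                if rmap is not None and config.quantify_percent_area:
                    table = quantify.cell_stats_table(
                        cond.name, rmap, labels, inst2d, mask.mask, droplets
                    )
                    table.insert(1, "replicate", rep)
                    cell_rows.append(table)

                if config.quantify_coloc:
                    r = quantify.colocalize(
                        planar.channel(quantify.CH2_SHIFT), planar.channel(2233.0), mask
                    )
                    rep_summary["coloc_pearson_r"] = float(r)

    cell_stats = (
        pd.concat(cell_rows, ignore_index=True)
        if cell_rows
        else pd.DataFrame(
            columns=[
                "cell_id", "replicate", "condition", "mean_ratio",
                "total_droplet_volume_um3", "pct_area_steatosis",
                "pct_area_phospholipidosis",
            ]
        )
    )
    droplet_table = (
        pd.concat(droplet_frames, ignore_index=True) if droplet_frames else pd.DataFrame()
    )
    spectra_table = pd.DataFrame(spectra_rows)

    with _stage("stats"):
        if len(config.conditions) >= 2 and len(cell_stats):
            stats_block = {}
            for col in ("pct_area_phospholipidosis", "pct_area_steatosis", "mean_ratio"):
                counts = cell_stats.groupby("condition")[col].count()
                if (counts >= 2).sum() >= 2:
                    stats_block[col] = quantify.group_tests(cell_stats, col, "condition")
            summary["stats"] = stats_block

    with _stage("report"):
        for name, frame in (
            ("cell_stats", cell_stats),
            ("droplets", droplet_table),
            ("segment_spectra", spectra_table),
        ):
            p = os.path.join(config.output_dir, f"{name}.csv")
            frame.to_csv(p, index=False)
            paths[name] = p
        summary["n_cells_total"] = int(len(cell_stats))
        per_cond = {}
        for cond in config.conditions:
            sub = cell_stats[cell_stats["condition"] == cond.name]
            if len(sub):
                per_cond[cond.name] = {
                    "n_cells": int(len(sub)),
                    "mean_ratio": float(sub["mean_ratio"].mean()),
                    "mean_pct_area_steatosis": float(sub["pct_area_steatosis"].mean()),
                    "mean_pct_area_phospholipidosis": float(
                        sub["pct_area_phospholipidosis"].mean()
                    ),
                }
        summary["per_condition"] = per_cond
        summary_path = os.path.join(config.output_dir, "summary.json")
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        paths["summary"] = summary_path

    if config.figures:
        with _stage("figures"):
            _write_figures(config, paths)

    return RunReport(
        summary=summary,
        cell_stats=cell_stats,
        droplets=droplet_table,
        spectra=spectra_table,
        paths=paths,
    )


def _write_figures(config: RunConfig, paths: dict) -> None:
    """Phasor density and ratio-map figures for the first replicate per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for ci, cond in enumerate(config.conditions):
        seed = _replicate_seed(config.seed, ci, 0)
        stack, planar, _, _ = _load_condition_stack(cond, seed)
        avg = average_projection(planar)
        mask = background_mask(avg, config.mask_method, config.manual_threshold)
        pmap = phasor_core.phasor_transform(planar, config.harmonic, mask)
        counts, ge, se = phasor_core.phasor_density(pmap, bins=256)
        rmap = quantify.ratio_map(planar, mask=mask)

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].imshow(
            np.log1p(counts.T), origin="lower", extent=[ge[0], ge[-1], se[0], se[-1]],
            cmap="inferno", aspect="equal",
        )
        axes[0].set_xlabel("G")
        axes[0].set_ylabel("S")
        axes[0].set_title(f"{cond.name}: phasor density")
        shown = np.clip(rmap.ratio, *rmap.display_clamp)
        im = axes[1].imshow(shown, cmap="rainbow", vmin=0, vmax=1)
        axes[1].set_title("CH2/CH3 ratio")
        axes[1].axis("off")
        fig.colorbar(im, ax=axes[1], shrink=0.8)
        fig.tight_layout()
        out = os.path.join(config.output_dir, f"{cond.name}_overview.png")
        fig.savefig(out, dpi=120)
        plt.close(fig)
        paths.setdefault("figures", []).append(out)
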