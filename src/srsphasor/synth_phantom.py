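"""Synthetic hyperspectral SRS cell phantoms with known ground truth.

This module renders HepG2-like cell fields as hyperspectral stimulated Raman
scattering stacks: ellipsoidal cells with a nucleus (holding 1-3 brighter
nucleoli), cytoplasm, and spherical lipid inclusions of configurable classes
(steatosis-type neutral-lipid droplets, phospholipidosis-type lamellar
inclusions, alkyne-tagged drug deposits).  Every voxel is assigned exactly one
compartment class and one cell instance, the class's Lorentzian spectral model
is evaluated on the wavenumber axis, and shot-like noise is applied.  The
returned :class:`LabeledPhantom` carries the stack together with the ground
truth, so every downstream operation (phasor segmentation, ratio maps,
volumetry) can be scored against a known answer.

The spectral library (:func:`default_library`) is versioned package data; see
``_library.yaml`` for the design rationale of band positions and amplitudes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .axis import WavenumberAxis, build_wavenumber_axis
from .errors import InvalidParameterError, PlacementError
from .hyperstack_io import HyperStack

__all__ = [
    "SpectralBand",
    "SpectrumModel",
    "evaluate_spectrum",
    "default_library",
    "default_axis",
    "NEAT_LIPIDS",
    "LIBRARY_VERSION",
    "CLASS_IDS",
    "CLASS_NAMES",
    "NoiseModel",
    "PhantomConfig",
    "LabeledPhantom",
    "generate_phantom",
    "write_phantom",
    "default_phantom_config",
    "control_phantom_config",
    "steatosis_phantom_config",
    "phospholipidosis_phantom_config",
    "coloc_phantom_config",
]

# ground-truth class ids (0 is background)
CLASS_IDS = {
    "background": 0,
    "nucleus": 1,
    "cytoplasm": 2,
    "steatosis": 3,
    "phospholipidosis": 4,
    "alkyne": 5,
}
CLASS_NAMES = {v: k for k, v in CLASS_IDS.items()}

_PLACEMENT_ATTEMPTS = 300


# --------------------------------------------------------------------------
# spectral models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralBand:
    """A single Lorentzian Raman band: center (cm^-1), FWHM (cm^-1), amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if not (np.isfinite(self.center) and np.isfinite(self.fwhm) and np.isfinite(self.amplitude)):
            raise InvalidParameterError("band parameters must be finite")
        if self.fwhm <= 0:
            raise InvalidParameterError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise InvalidParameterError(f"band amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SpectrumModel:
    """A named spectrum: sum of Lorentzian bands plus a constant baseline."""

    name: str
    bands: tuple[SpectralBand, ...]
    baseline: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        if len(self.bands) == 0:
            raise InvalidParameterError(f"model {self.name!r} must have at least one band")
        if not np.isfinite(self.baseline) or self.baseline < 0:
            raise InvalidParameterError(f"baseline must be >= 0, got {self.baseline}")


def evaluate_spectrum(model: SpectrumModel, axis: WavenumberAxis | np.ndarray) -> np.ndarray:
    """Evaluate a spectral model on a wavenumber axis.

    Each band contributes ``amplitude * (G/2)^2 / ((v - center)^2 + (G/2)^2)``
    (a Lorentzian with unit apex), so a band's amplitude is its peak height.
    Bands whose center lies outside the axis window still contribute their
    tails.  The result is nonnegative everywhere.
    """
    nu = axis.values if isinstance(axis, WavenumberAxis) else np.asarray(axis, dtype=float)
    out = np.full(nu.shape, float(model.baseline))
    for band in model.bands:
        hwhm2 = (band.fwhm / 2.0) ** 2
        out += band.amplitude * hwhm2 / ((nu - band.center) ** 2 + hwhm2)
    return out


def _load_library_data() -> dict:
    text = resources.files(__package__).joinpath("_library.yaml").read_text()
    return yaml.safe_load(text)


_LIBRARY_DATA = _load_library_data()

#: version tag of the bundled spectral library
LIBRARY_VERSION: int = int(_LIBRARY_DATA["version"])

#: the nine neat lipid species used for phasor reference measurements
NEAT_LIPIDS: tuple[str, ...] = tuple(_LIBRARY_DATA["neat_lipids"])


def default_library() -> dict[str, SpectrumModel]:
    """The bundled spectral library.

    Contains the nine neat lipid species (see :data:`NEAT_LIPIDS`) plus the
    cellular compartment models (nucleus, cytoplasm, steatosis-droplet,
    phospholipidosis-inclusion, alkyne-drug and variants, background).
    """
    models = {}
    for name, entry in _LIBRARY_DATA["models"].items():
        bands = tuple(SpectralBand(c, w, a) for c, w, a in entry["bands"])
        models[name] = SpectrumModel(name=name, bands=bands, baseline=float(entry.get("baseline", 0.0)))
    return models


def default_axis() -> WavenumberAxis:
    """The study acquisition axis: 2800-3050 cm^-1, 0.4 nm pump retune, 1031.4 nm Stokes."""
    return build_wavenumber_axis(1031.4, 2800.0, 3050.0, 0.4)


# --------------------------------------------------------------------------
# phantom configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Shot-like noise: variance-proportional-to-intensity Poisson scaling
    (``poisson_scale`` counts per event; 0 disables) followed by additive
    Gaussian read noise (``gaussian_sd`` counts; 0 disables)."""

    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0

    def __post_init__(self):
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise InvalidParameterError("noise parameters must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return self.poisson_scale == 0 and self.gaussian_sd == 0


def _default_compartment_models() -> dict[str, str]:
    return {
        "background": "background",
        "nucleus": "nucleus",
        "cytoplasm": "cytoplasm",
        "steatosis": "steatosis-droplet",
        "phospholipidosis": "phospholipidosis-inclusion",
        "alkyne": "alkyne-drug",
    }


def _default_droplet_counts() -> dict[str, int]:
    return {"steatosis": 4, "phospholipidosis": 4, "alkyne": 0}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic cell field.

    Geometry is voxel-indexed (z, y, x), 0-based; physical sizes are carried
    separately (``pixel_size`` in-plane, ``z_step`` axial, both um).  Defaults
    emulate the study acquisition: a 32 x 32 um field (0.25 um pixels) of
    HepG2-like cells imaged over 2800-3050 cm^-1 in 40 frames, z planes 1 um
    apart, with droplet loads per cell set by ``droplet_counts``.
    """

    seed: int
    image_shape: tuple[int, int, int] = (1, 128, 128)
    pixel_size: float = 0.25
    z_step: float = 1.0
    n_cells: int = 3
    droplet_counts: dict[str, int] = field(default_factory=_default_droplet_counts)
    droplet_radius_range: tuple[float, float] = (0.4, 0.9)
    cell_radius_range: tuple[float, float] = (4.0, 6.0)
    nucleus_fraction: float = 0.45
    nucleoli_brightness: float = 1.6
    intensity_scale: float = 1000.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    alkyne_colocalized: bool = True
    compartment_models: dict[str, str] = field(default_factory=_default_compartment_models)
    axis: WavenumberAxis | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.z_step <= 0:
            raise InvalidParameterError("z_step must be > 0")
        if len(self.image_shape) != 3 or any(s < 1 for s in self.image_shape):
            raise InvalidParameterError("image_shape must be (z, y, x) with positive sizes")
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        lo, hi = self.droplet_radius_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("droplet_radius_range must be increasing and positive")
        if lo < self.pixel_size:
            raise InvalidParameterError(
                f"droplet radii must be >= pixel_size ({self.pixel_size} um), got minimum {lo}"
            )
        for cls, n in self.droplet_counts.items():
            if cls not in ("steatosis", "phospholipidosis", "alkyne"):
                raise InvalidParameterError(f"unknown droplet class {cls!r}")
            if n < 0:
                raise InvalidParameterError("droplet counts must be >= 0")
        if not (0 < self.nucleus_fraction < 1):
            raise InvalidParameterError("nucleus_fraction must be in (0, 1)")

    def resolved_axis(self) -> WavenumberAxis:
        return self.axis if self.axis is not None else default_axis()

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class LabeledPhantom:
    """A rendered phantom plus its ground truth.

    ``truth_labels`` uses the class ids in :data:`CLASS_IDS` (0 background,
    1 nucleus, 2 cytoplasm, 3 steatosis droplet, 4 phospholipidosis
    inclusion, 5 alkyne-drug inclusion); ``cell_instances`` numbers cells
    from 1.  ``clip_fraction`` is the fraction of intensities clipped to
    zero after noise.
    """

    stack: HyperStack
    truth_labels: np.ndarray
    cell_instances: np.ndarray
    config: PhantomConfig
    clip_fraction: float = 0.0

    def __post_init__(self):
        if self.truth_labels.shape != self.stack.data.shape[:-1]:
            raise InvalidParameterError("truth_labels must match the stack's spatial shape")
        if self.cell_instances.shape != self.truth_labels.shape:
            raise InvalidParameterError("cell_instances must match truth_labels")
        if np.any((self.truth_labels > 0) & (self.cell_instances == 0)):
            raise InvalidParameterError("every non-background voxel must belong to a cell instance")


# --------------------------------------------------------------------------
# geometry rendering
# --------------------------------------------------------------------------

def _coordinate_grids(shape, pixel_size, z_step):
    nz, ny, nx = shape
    z = np.arange(nz, dtype=float) * z_step
    y = np.arange(ny, dtype=float) * pixel_size
    x = np.arange(nx, dtype=float) * pixel_size
    return np.meshgrid(z, y, x, indexing="ij")


def _ellipsoid_mask(grids, center, radii):
    """Boundary-inclusive ellipsoid; a zero z-radius means 'infinite' (2D mode)."""
    Z, Y, X = grids
    cz, cy, cx = center
    rz, ry, rx = radii
    val = ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2
    if rz > 0:
        val = val + ((Z - cz) / rz) ** 2
    return val <= 1.0


def _sphere_mask(grids, center, radius):
    Z, Y, X = grids
    cz, cy, cx = center
    return (Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= radius ** 2


def _place_cells(rng, config, grids):
    """Rejection-sample non-overlapping ellipsoidal cells; returns their geometry."""
    nz, ny, nx = config.image_shape
    Ly, Lx = ny * config.pixel_size, nx * config.pixel_size
    Lz = nz * config.z_step
    cells = []
    for _ in range(config.n_cells):
        for attempt in range(_PLACEMENT_ATTEMPTS):
            r_y = rng.uniform(*config.cell_radius_range)
            r_x = rng.uniform(*config.cell_radius_range)
            cy = rng.uniform(r_y, Ly - r_y) if Ly > 2 * r_y else Ly / 2
            cx = rng.uniform(r_x, Lx - r_x) if Lx > 2 * r_x else Lx / 2
            if nz > 1:
                r_z = 0.8 * (r_y + r_x) / 2
                r_z = min(r_z, max(Lz / 2 - config.z_step / 2, config.z_step))
                cz = Lz / 2
            else:
                r_z, cz = 0.0, 0.0
            ok = all(
                np.hypot(cy - c["cy"], cx - c["cx"]) > (max(r_y, r_x) + max(c["ry"], c["rx"]) + 0.5)
                for c in cells
            )
            if ok:
                cells.append(dict(cz=cz, cy=cy, cx=cx, rz=r_z, ry=r_y, rx=r_x))
                break
        else:
            raise PlacementError("cell")
    return cells


def _ellipse_value(point, center, radii):
    """Normalized ellipsoid coordinate of a point (<= 1 means inside)."""
    val = 0.0
    for p, c, r in zip(point, center, radii):
        if r > 0:
            val += ((p - c) / r) ** 2
    return val


def _place_droplets_in_cell(rng, cell, nucleus, counts, radius_range, nz, z_extent):
    """Sample non-overlapping spherical droplets inside the cytoplasm of one cell."""
    placed = []  # (class_name, center, radius)
    order = ["steatosis", "phospholipidosis", "alkyne"]
    for cls in order:
        for _ in range(counts.get(cls, 0)):
            for attempt in range(_PLACEMENT_ATTEMPTS):
                r = rng.uniform(*radius_range)
                # sample a center inside the cell ellipse, shrunk by the radius
                u, v = rng.uniform(-1, 1, size=2)
                if u * u + v * v > 1:
                    continue
                cy = cell["cy"] + u * max(cell["ry"] - r - 0.1, 0.1)
                cx = cell["cx"] + v * max(cell["rx"] - r - 0.1, 0.1)
                if nz > 1:
                    cz = rng.uniform(
                        max(cell["cz"] - cell["rz"] + r, 0.0),
                        min(cell["cz"] + cell["rz"] - r, z_extent),
                    )
                else:
                    cz = 0.0
                center = (cz, cy, cx)
                # keep out of the (slightly dilated) nucleus
                nuc_radii = tuple(nr + r for nr in nucleus["radii"])
                if _ellipse_value(center, nucleus["center"], nuc_radii) <= 1.2:
                    continue
                # stay inside the cell ellipse
                cell_radii = (
                    max(cell["rz"] - r, 0.0) if cell["rz"] > 0 else 0.0,
                    max(cell["ry"] - r, 0.2),
                    max(cell["rx"] - r, 0.2),
                )
                if _ellipse_value(center, (cell["cz"], cell["cy"], cell["cx"]), cell_radii) > 1.0:
                    continue
                # no droplet-droplet overlap
                if any(
                    np.sqrt(sum((a - b) ** 2 for a, b in zip(center, p[1]))) <= r + p[2]
                    for p in placed
                ):
                    continue
                placed.append((cls, center, r))
                break
            else:
                raise PlacementError(cls)
    return placed


def generate_phantom(config: PhantomConfig) -> LabeledPhantom:
    """Render a labeled hyperspectral phantom.

    Deterministic for a fixed config (the config's seed drives all
    randomness).  Raises :class:`PlacementError` naming the object class if
    geometry cannot be placed without overlap within a bounded number of
    attempts.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.resolved_axis()
    nz, ny, nx = config.image_shape
    grids = _coordinate_grids(config.image_shape, config.pixel_size, config.z_step)

    labels = np.zeros(config.image_shape, dtype=np.uint8)
    instances = np.zeros(config.image_shape, dtype=np.uint16)
    boost = np.ones(config.image_shape, dtype=float)

    cells = _place_cells(rng, config, grids)
    for i, cell in enumerate(cells, start=1):
        cell_mask = _ellipsoid_mask(
            grids, (cell["cz"], cell["cy"], cell["cx"]), (cell["rz"], cell["ry"], cell["rx"])
        )
        labels[cell_mask] = CLASS_IDS["cytoplasm"]
        instances[cell_mask] = i

        # nucleus: concentric ellipsoid, slightly offset in-plane
        f = config.nucleus_fraction
        off = 0.15 * min(cell["ry"], cell["rx"])
        n_center = (
            cell["cz"],
            cell["cy"] + rng.uniform(-off, off),
            cell["cx"] + rng.uniform(-off, off),
        )
        n_radii = (cell["rz"] * f, cell["ry"] * f, cell["rx"] * f)
        nucleus = {"center": n_center, "radii": n_radii}
        n_mask = _ellipsoid_mask(grids, n_center, n_radii)
        labels[n_mask] = CLASS_IDS["nucleus"]

        # 1-3 brighter nucleoli sharing the nucleus spectrum
        for _ in range(int(rng.integers(1, 4))):
            u, v = rng.uniform(-0.55, 0.55, size=2)
            nucleolus_center = (
                n_center[0],
                n_center[1] + u * n_radii[1],
                n_center[2] + v * n_radii[2],
            )
            r_nucleolus = 0.22 * min(n_radii[1], n_radii[2])
            nl_mask = _sphere_mask(grids, nucleolus_center, max(r_nucleolus, config.pixel_size))
            nl_mask &= n_mask
            boost[nl_mask] = config.nucleoli_brightness

        counts = dict(config.droplet_counts)
        n_alk = counts.get("alkyne", 0)
        if config.alkyne_colocalized and n_alk > 0:
            if counts.get("phospholipidosis", 0) < n_alk:
                raise InvalidParameterError(
                    "colocalized alkyne inclusions require at least as many "
                    "phospholipidosis inclusions per cell"
                )
            counts = {**counts, "alkyne": 0}

        droplets = _place_droplets_in_cell(
            rng, cell, nucleus, counts, config.droplet_radius_range, nz, (nz - 1) * config.z_step
        )
        pl_droplets = []
        for cls, center, r in droplets:
            d_mask = _sphere_mask(grids, center, r)
            labels[d_mask] = CLASS_IDS[cls]
            instances[d_mask] = i
            if cls == "phospholipidosis":
                pl_droplets.append((center, r))
        if config.alkyne_colocalized and n_alk > 0:
            # alkyne-loaded cores carved inside phospholipidosis inclusions
            for center, r in pl_droplets[:n_alk]:
                core = _sphere_mask(grids, center, 0.8 * r)
                labels[core] = CLASS_IDS["alkyne"]
                instances[core] = i

    # render spectra: one model evaluation per class, broadcast by label
    library = default_library()
    spec_lut = np.zeros((6, axis.n_channels))
    for cls, cid in CLASS_IDS.items():
        model_name = config.compartment_models[cls]
        spec_lut[cid] = config.intensity_scale * evaluate_spectrum(library[model_name], axis)
    data = spec_lut[labels] * boost[..., None]

    clip_fraction = 0.0
    if config.noise.poisson_scale > 0:
        p = config.noise.poisson_scale
        data = rng.poisson(data / p).astype(float) * p
    if config.noise.gaussian_sd > 0:
        data = data + rng.normal(0.0, config.noise.gaussian_sd, size=data.shape)
        clip_fraction = float(np.mean(data < 0))
        np.clip(data, 0.0, None, out=data)

    stack = HyperStack(data=data, axis=axis, pixel_size=config.pixel_size, z_step=config.z_step)
    return LabeledPhantom(
        stack=stack,
        truth_labels=labels,
        cell_instances=instances,
        config=config,
        clip_fraction=clip_fraction,
    )


def write_phantom(phantom: LabeledPhantom, directory) -> dict[str, str]:
    """Write a phantom as TIFFs plus a YAML sidecar; returns the paths."""
    import os

    from . import hyperstack_io as hio

    os.makedirs(directory, exist_ok=True)
    paths = {
        "stack": os.path.join(directory, "stack.tif"),
        "sidecar": os.path.join(directory, "stack.yaml"),
        "truth": os.path.join(directory, "truth_labels.tif"),
        "instances": os.path.join(directory, "cell_instances.tif"),
        "phantom": os.path.join(directory, "phantom.yaml"),
    }
    hio.write_stack(phantom.stack, paths["stack"], paths["sidecar"])
    hio.write_labels(phantom.truth_labels, paths["truth"])
    hio.write_labels(phantom.cell_instances, paths["instances"])
    meta = {
        "seed": int(phantom.config.seed),
        "library_version": LIBRARY_VERSION,
        "clip_fraction": float(phantom.clip_fraction),
        "n_cells": int(phantom.config.n_cells),
        "droplet_counts": {k: int(v) for k, v in phantom.config.droplet_counts.items()},
        "pixel_size_um": float(phantom.config.pixel_size),
        "z_step_um": float(phantom.config.z_step),
        "class_ids": {k: int(v) for k, v in CLASS_IDS.items()},
    }
    with open(paths["phantom"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


# --------------------------------------------------------------------------
# study-condition presets
# --------------------------------------------------------------------------

def default_phantom_config(seed: int, **overrides) -> PhantomConfig:
    """The default phantom: 3 cells with both droplet classes present."""
    return PhantomConfig(seed=seed, **overrides)


def control_phantom_config(seed: int, **overrides) -> PhantomConfig:
    """Vehicle-control-like condition: sparse basal lipid, no phospholipidosis."""
    kw = dict(droplet_counts={"steatosis": 1, "phospholipidosis": 0, "alkyne": 0})
    kw.update(overrides)
    return PhantomConfig(seed=seed, **kw)


def steatosis_phantom_config(seed: int, **overrides) -> PhantomConfig:
    """Steatosis-inducing treatment: many large neutral-lipid droplets."""
    kw = dict(
        droplet_counts={"steatosis": 7, "phospholipidosis": 1, "alkyne": 0},
        droplet_radius_range=(0.5, 1.1),
    )
    kw.update(overrides)
    return PhantomConfig(seed=seed, **kw)


def phospholipidosis_phantom_config(seed: int, **overrides) -> PhantomConfig:
    """DIPL-inducing treatment: many lamellar-body-like inclusions."""
    kw = dict(droplet_counts={"steatosis": 1, "phospholipidosis": 7, "alkyne": 0})
    kw.update(overrides)
    return PhantomConfig(seed=seed, **kw)


def coloc_phantom_config(seed: int, colocalized: bool = True, **overrides) -> PhantomConfig:
    """Alkyne-tagged-drug condition for colocalization analysis.

    With ``colocalized=True`` the alkyne signal sits in cores of the
    phospholipidosis inclusions and carries a phospholipid-like CH profile
    (drug sequestered in lamellar bodies); with ``False`` the drug deposits
    are placed independently in the cytoplasm with a free-drug spectrum.
    """
    models = _default_compartment_models()
    models["alkyne"] = "alkyne-lamellar" if colocalized else "alkyne-drug"
    kw = dict(
        droplet_counts={"steatosis": 0, "phospholipidosis": 6, "alkyne": 4},
        alkyne_colocalized=colocalized,
        compartment_models=models,
    )
    kw.update(overrides)
    return PhantomConfig(seed=seed, **kw)
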