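"""Hyperspectral stack I/O, projections, and background masking.

Stacks are stored as multi-frame TIFFs (one frame per channel; for
volumetric stacks the frame order is z-major, channel-minor) accompanied by
a YAML sidecar holding the wavenumber axis and the physical geometry.  The
sidecar is mandatory on read: a stack without its axis would silently become
channel-index data, which this package refuses to guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

from .axis import WavenumberAxis
from .errors import DegenerateHistogramError, FormatError, InvalidParameterError

__all__ = [
    "HyperStack",
    "PixelMask",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "average_projection",
    "max_projection",
    "background_mask",
]


@dataclass(frozen=True)
class HyperStack:
    """A hyperspectral SRS stack: (y, x, nu) or (z, y, x, nu) intensities.

    The last axis is the spectral axis and must match ``axis.n_channels``;
    intensities are finite and nonnegative.  ``pixel_size`` is the in-plane
    pixel pitch (um); ``z_step`` the axial plane spacing (um) for volumetric
    stacks, ``None`` otherwise.
    """

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size: float
    z_step: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim not in (3, 4):
            raise InvalidParameterError(
                f"stack must be (y, x, nu) or (z, y, x, nu), got ndim={data.ndim}"
            )
        if data.shape[-1] != self.axis.n_channels:
            raise FormatError(
                f"stack has {data.shape[-1]} channels but axis has "
                f"{self.axis.n_channels} values"
            )
        if not np.all(np.isfinite(data)):
            raise InvalidParameterError("stack intensities must be finite")
        if np.any(data < 0):
            raise InvalidParameterError("stack intensities must be >= 0")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.is_volumetric and self.z_step is None:
            raise InvalidParameterError("volumetric stacks require z_step")

    @property
    def is_volumetric(self) -> bool:
        return self.data.ndim == 4

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    def channel(self, shift_cm1: float, tol: float = 5.0) -> np.ndarray:
        """The single-frequency image nearest ``shift_cm1`` (within ``tol`` cm^-1)."""
        return self.data[..., self.axis.index_of(shift_cm1, tol)]

    def plane(self, z: int) -> "HyperStack":
        """Extract one z plane of a volumetric stack as a planar stack."""
        if not self.is_volumetric:
            raise InvalidParameterError("plane() requires a volumetric stack")
        return HyperStack(self.data[z], self.axis, self.pixel_size, None)


@dataclass(frozen=True)
class PixelMask:
    """Boolean foreground mask over the spatial shape, with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


# --------------------------------------------------------------------------
# TIFF + sidecar round trip
# --------------------------------------------------------------------------

def write_stack(stack: HyperStack, path, sidecar_path=None) -> None:
    """Write a stack as a multi-frame TIFF plus a YAML sidecar.

    Planar stacks are written channel-by-channel; volumetric stacks z-major
    then channel (frame index = z * n_channels + channel).  The sidecar
    records the full-precision wavenumber axis and the physical geometry, so
    a read reproduces the stack bit-exactly.
    """
    sidecar_path = sidecar_path or str(path) + ".yaml"
    if stack.is_volumetric:
        nz = stack.data.shape[0]
        frames = np.moveaxis(stack.data, -1, 1).reshape(
            nz * stack.axis.n_channels, *stack.data.shape[1:3]
        )
    else:
        nz = None
        frames = np.moveaxis(stack.data, -1, 0)
    tifffile.imwrite(path, np.ascontiguousarray(frames))
    meta = {
        "format": "srsphasor-hyperstack",
        "wavenumbers_cm1": [float(v) for v in stack.axis.values],
        "stokes_wavelength_nm": stack.axis.stokes_wavelength,
        "retune_step_nm": stack.axis.retune_step,
        "acquisition_order": stack.axis.acquisition_order,
        "pixel_size_um": float(stack.pixel_size),
        "z_step_um": None if stack.z_step is None else float(stack.z_step),
        "n_z": nz,
        "frame_order": "z-major, channel-minor" if nz else "channel",
        "dtype": str(stack.data.dtype),
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_stack(path, sidecar_path=None) -> HyperStack:
    """Read a stack written by :func:`write_stack`.

    Raises :class:`FormatError` if the sidecar is missing or the TIFF frame
    count is inconsistent with the axis (and z count).
    """
    sidecar_path = sidecar_path or str(path) + ".yaml"
    try:
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError:
        raise FormatError(
            f"sidecar {sidecar_path!r} not found; refusing to invent a "
            "channel-index wavenumber axis"
        ) from None
    try:
        values = meta["wavenumbers_cm1"]
    except (TypeError, KeyError):
        raise FormatError(f"sidecar {sidecar_path!r} lacks 'wavenumbers_cm1'") from None
    axis = WavenumberAxis(
        values=np.asarray(values, dtype=float),
        stokes_wavelength=meta.get("stokes_wavelength_nm"),
        retune_step=meta.get("retune_step_nm"),
        acquisition_order=meta.get("acquisition_order", "ascending"),
    )
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    n = axis.n_channels
    nz = meta.get("n_z")
    expected = n * (nz or 1)
    if frames.shape[0] != expected:
        raise FormatError(
            f"TIFF has {frames.shape[0]} frames but the sidecar axis implies "
            f"{expected} ({n} channels" + (f" x {nz} z planes" if nz else "") + ")"
        )
    if nz:
        data = np.moveaxis(frames.reshape(nz, n, *frames.shape[1:]), 1, -1)
    else:
        data = np.moveaxis(frames, 0, -1)
    return HyperStack(
        data=data,
        axis=axis,
        pixel_size=float(meta["pixel_size_um"]),
        z_step=meta.get("z_step_um"),
    )


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label/mask image as an integer TIFF (8-bit when it fits)."""
    labels = np.asarray(labels)
    if labels.dtype == bool or labels.max(initial=0) < 256:
        labels = labels.astype(np.uint8)
    else:
        labels = labels.astype(np.uint16)
    tifffile.imwrite(path, np.ascontiguousarray(labels))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path)


# --------------------------------------------------------------------------
# projections and background masking
# --------------------------------------------------------------------------

def average_projection(stack: HyperStack | np.ndarray) -> np.ndarray:
    """Pixelwise mean over the spectral axis (the average intensity projection)."""
    data = stack.data if isinstance(stack, HyperStack) else np.asarray(stack)
    if data.size == 0:
        raise InvalidParameterError("empty stack")
    return data.mean(axis=-1)


def max_projection(zstack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection of a single-channel z-stack (z, y, x) -> (y, x)."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.size == 0:
        raise InvalidParameterError("max_projection expects a nonempty (z, y, x) volume")
    return zstack.max(axis=0)


def background_mask(
    avg_projection: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> PixelMask:
    """Foreground mask by intensity threshold on the average projection.

    ``method="otsu"`` picks the threshold maximizing between-class variance;
    ``method="manual"`` uses ``manual_threshold``.  Foreground is every pixel
    with intensity >= threshold; the threshold used is recorded in the mask's
    provenance.
    """
    image = np.asarray(avg_projection, dtype=float)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateHistogramError(
                "cannot Otsu-threshold a constant image (single-valued histogram)"
            )
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(image))
    elif method == "manual":
        if manual_threshold is None:
            raise InvalidParameterError("method='manual' requires manual_threshold")
        threshold = float(manual_threshold)
    else:
        raise InvalidParameterError(f"unknown background method {method!r}")
    return PixelMask(
        mask=image >= threshold,
        provenance={"method": method, "threshold": threshold},
    )
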