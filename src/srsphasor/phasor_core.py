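"""Spectral phasor transform, phasor-domain segmentation, and segment spectra.

The spectral phasor of a pixel with spectrum ``I_k`` (k = 0..N-1, channels in
ascending wavenumber order over the acquired window) at harmonic ``n`` is

    G = sum_k I_k cos(2 pi n k / N) / sum_k I_k
    S = sum_k I_k sin(2 pi n k / N) / sum_k I_k

i.e. the intensity-normalized n-th Fourier coefficient of the spectrum with
the acquisition window treated as one period.  For nonnegative spectra the
phasor lies in the unit disc; narrow bands map near the unit circle, broad or
flat spectra near the origin, and a nonnegative mixture of two spectra lies
on the chord between their phasors (weighted by total intensity).  Those
properties are what make the phasor plane a convenient segmentation domain:
spectrally similar pixels cluster, clusters are delimited with polygonal
regions of interest, and the regions are projected back onto the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon, box

from .axis import WavenumberAxis
from .errors import (
    AmbiguousReferenceError,
    DegenerateReferenceError,
    DegenerateSpectrumError,
    EmptySegmentError,
    InvalidParameterError,
)
from .hyperstack_io import HyperStack, PixelMask
from .synth_phantom import SpectrumModel, evaluate_spectrum

__all__ = [
    "PhasorMap",
    "PhasorROI",
    "SegmentSpectrum",
    "ROI_LABEL_IDS",
    "phasor_transform",
    "spectrum_phasor",
    "phasor_density",
    "segment_by_rois",
    "derive_roi_from_reference",
    "segment_spectrum",
    "phasor_polar",
    "local_maximum_shift",
    "save_rois",
    "load_rois",
]

#: label-image ids for the standard phasor classes (0 is reserved for invalid)
ROI_LABEL_IDS = {
    "nucleus": 1,
    "cytoplasm": 2,
    "steatosis": 3,
    "phospholipidosis": 4,
    "alkyne": 5,
    "total_lipid": 6,
}

_ROI_BOUND = 1.05  # ROI polygons must fit in [-1.05, 1.05]^2


@dataclass(frozen=True)
class PhasorMap:
    """Per-pixel phasor coordinates plus a validity mask.

    ``G``/``S`` share the stack's spatial shape; ``valid`` marks pixels with
    positive total intensity inside the foreground mask.  Invalid pixels
    carry G = S = 0 but are excluded from every downstream computation.
    """

    G: np.ndarray
    S: np.ndarray
    harmonic: int
    valid: np.ndarray

    def __post_init__(self):
        if self.G.shape != self.S.shape or self.G.shape != self.valid.shape:
            raise InvalidParameterError("G, S and valid must share one shape")
        if self.harmonic < 1:
            raise InvalidParameterError("harmonic must be >= 1")

    def points(self) -> np.ndarray:
        """(n_valid, 2) array of (G, S) coordinates of the valid pixels."""
        return np.column_stack([self.G[self.valid], self.S[self.valid]])


@dataclass(frozen=True)
class PhasorROI:
    """A named polygonal region in (G, S) space.

    The polygon must be simple (non-self-intersecting), have at least three
    vertices, and fit inside [-1.05, 1.05]^2.  Membership is boundary
    inclusive.
    """

    label: str
    vertices: np.ndarray
    color: str | None = None

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", verts)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise InvalidParameterError("ROI needs >= 3 (G, S) vertices")
        if np.any(np.abs(verts) > _ROI_BOUND):
            raise InvalidParameterError(f"ROI vertices must lie within [-{_ROI_BOUND}, {_ROI_BOUND}]^2")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise InvalidParameterError(f"ROI {self.label!r} polygon must be simple with nonzero area")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership of an (n, 2) array of (G, S) points."""
        pts = shapely.points(np.asarray(points, dtype=float))
        return shapely.covers(self.polygon(), pts)


@dataclass(frozen=True)
class SegmentSpectrum:
    """Mean spectrum of one segmented class, normalized to max = 1 or unit area."""

    label: str | int
    mean_spectrum: np.ndarray
    normalization: str
    pixel_count: int

    def __post_init__(self):
        if self.pixel_count < 1:
            raise EmptySegmentError(f"segment {self.label!r} has no pixels")


# --------------------------------------------------------------------------
# transform
# --------------------------------------------------------------------------

def phasor_transform(
    stack: HyperStack | np.ndarray,
    harmonic: int = 1,
    mask: PixelMask | np.ndarray | None = None,
) -> PhasorMap:
    """Per-pixel spectral phasor transform of a hyperspectral stack.

    Pixels with nonpositive total intensity, or outside ``mask``, are marked
    invalid.  The transform is invariant to positive rescaling of the stack.
    """
    data = stack.data if isinstance(stack, HyperStack) else np.asarray(stack, dtype=float)
    if harmonic < 1:
        raise InvalidParameterError("harmonic must be >= 1")
    n_channels = data.shape[-1]
    if n_channels < 2:
        raise DegenerateSpectrumError("phasor transform needs at least 2 channels")
    k = np.arange(n_channels)
    angles = 2.0 * np.pi * harmonic * k / n_channels
    cos_k, sin_k = np.cos(angles), np.sin(angles)

    total = data.sum(axis=-1)
    valid = total > 0
    if mask is not None:
        m = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask, dtype=bool)
        if m.shape != valid.shape:
            raise InvalidParameterError("mask shape must match the stack's spatial shape")
        valid &= m

    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(valid, data @ cos_k / np.where(total > 0, total, 1.0), 0.0)
        S = np.where(valid, data @ sin_k / np.where(total > 0, total, 1.0), 0.0)
    return PhasorMap(G=G, S=S, harmonic=int(harmonic), valid=valid)


def spectrum_phasor(spectrum: np.ndarray, harmonic: int = 1) -> tuple[float, float]:
    """Phasor (G, S) of a single spectrum (the transform of a 1-pixel image)."""
    spectrum = np.asarray(spectrum, dtype=float)
    pmap = phasor_transform(spectrum[None, None, :], harmonic=harmonic)
    if not pmap.valid[0, 0]:
        raise DegenerateSpectrumError("spectrum has nonpositive total intensity")
    return float(pmap.G[0, 0]), float(pmap.S[0, 0])


def phasor_polar(pmap: PhasorMap) -> tuple[np.ndarray, np.ndarray]:
    """Modulation sqrt(G^2+S^2) in [0, 1] and phase atan2(S, G) in (-pi, pi].

    Modulation is the distance from the phasor origin: narrow spectra sit
    near 1, broad/flat spectra near 0 (lipid unsaturation is read out this
    way: more C=C means broader spectral content, hence lower modulation).
    """
    modulation = np.hypot(pmap.G, pmap.S)
    modulation = np.clip(modulation, 0.0, 1.0)
    phase = np.arctan2(pmap.S, pmap.G)
    return modulation, phase


# --------------------------------------------------------------------------
# density plot
# --------------------------------------------------------------------------

def phasor_density(pmap: PhasorMap, bins: int = 256):
    """2D histogram of the valid phasors over [-1, 1]^2.

    Returns ``(counts, g_edges, s_edges)``; counts sum to the number of
    valid pixels (phasors of nonnegative spectra cannot leave the disc).
    """
    if bins < 2:
        raise InvalidParameterError("bins must be >= 2")
    pts = pmap.points()
    counts, g_edges, s_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=[[-1.0, 1.0], [-1.0, 1.0]]
    )
    return counts, g_edges, s_edges


# --------------------------------------------------------------------------
# ROI segmentation and back-projection
# --------------------------------------------------------------------------

def _roi_label_id(roi: PhasorROI, custom_ids: dict[str, int]) -> int:
    if roi.label in ROI_LABEL_IDS:
        return ROI_LABEL_IDS[roi.label]
    if roi.label not in custom_ids:
        custom_ids[roi.label] = max(ROI_LABEL_IDS.values()) + 1 + len(custom_ids)
    return custom_ids[roi.label]


def segment_by_rois(pmap: PhasorMap, rois: list[PhasorROI]) -> np.ndarray:
    """Back-project phasor-plane ROIs onto the image as an integer label map.

    Each valid pixel gets the id of the ROI containing its (G, S) point
    (boundary inclusive); invalid pixels get 0.  Overlaps resolve by listed
    order (later wins), except that ``total_lipid`` — the umbrella region
    enclosing the specific lipid classes — never overwrites a pixel already
    claimed by ``steatosis``, ``phospholipidosis`` or ``alkyne``.
    """
    labels = np.zeros(pmap.G.shape, dtype=np.uint8)
    pts = pmap.points()
    flat = labels[pmap.valid]
    specific = (ROI_LABEL_IDS["steatosis"], ROI_LABEL_IDS["phospholipidosis"], ROI_LABEL_IDS["alkyne"])
    custom_ids: dict[str, int] = {}
    for roi in rois:
        lab = _roi_label_id(roi, custom_ids)
        inside = roi.contains(pts)
        if roi.label == "total_lipid":
            inside &= ~np.isin(flat, specific)
        flat = np.where(inside, lab, flat)
    labels[pmap.valid] = flat
    return labels


def derive_roi_from_reference(
    reference: PhasorMap | SpectrumModel | np.ndarray,
    padding: float = 0.025,
    label: str = "custom",
    axis: WavenumberAxis | None = None,
    harmonic: int = 1,
    color: str | None = None,
) -> PhasorROI:
    """Build a class ROI from a pure-class reference.

    ``reference`` is either a :class:`PhasorMap` of a homogeneous region
    (at least 10 valid pixels), a :class:`SpectrumModel` (evaluated on
    ``axis``), or a 1D reference spectrum.  The ROI is the convex hull of
    the reference phasor cloud dilated by ``padding`` in (G, S) units — an
    automated stand-in for the manual region placement the phasor plot is
    normally segmented with, so derived ROIs should be reviewed on the
    density plot.

    Raises :class:`AmbiguousReferenceError` when the cloud spans more than
    half the unit disc, and :class:`DegenerateReferenceError` when the
    dilated hull has zero area (e.g. a single point with zero padding).
    """
    if isinstance(reference, PhasorMap):
        pts = reference.points()
        if pts.shape[0] < 10:
            raise InvalidParameterError("reference region needs at least 10 valid pixels")
    elif isinstance(reference, SpectrumModel):
        if axis is None:
            raise InvalidParameterError("deriving an ROI from a model requires an axis")
        pts = np.array([spectrum_phasor(evaluate_spectrum(reference, axis), harmonic)])
    else:
        spectrum = np.asarray(reference, dtype=float)
        if spectrum.ndim != 1:
            raise InvalidParameterError("reference spectrum must be 1D")
        pts = np.array([spectrum_phasor(spectrum, harmonic)])

    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
    if span > 1.0:  # half of the unit disc's diameter
        raise AmbiguousReferenceError(
            f"reference phasor cloud spans {span:.2f} in (G, S); not a single class"
        )
    hull = MultiPoint(pts).convex_hull.buffer(padding, quad_segs=4)
    hull = hull.intersection(box(-_ROI_BOUND, -_ROI_BOUND, _ROI_BOUND, _ROI_BOUND))
    if hull.is_empty or hull.area == 0:
        raise DegenerateReferenceError(
            "reference cloud with zero padding collapses to a degenerate ROI"
        )
    verts = np.asarray(hull.exterior.coords)[:-1]
    return PhasorROI(label=label, vertices=verts, color=color)


# --------------------------------------------------------------------------
# segment spectra
# --------------------------------------------------------------------------

def segment_spectrum(
    stack: HyperStack | np.ndarray,
    label_image: np.ndarray,
    label: int | str,
    normalization: str = "max",
) -> SegmentSpectrum:
    """Channelwise mean spectrum over one label of a segmentation.

    ``label`` may be an integer id or a standard class name.  The mean is
    normalized to ``max`` = 1 (default) or unit ``area``.
    """
    data = stack.data if isinstance(stack, HyperStack) else np.asarray(stack, dtype=float)
    lab = ROI_LABEL_IDS[label] if isinstance(label, str) else int(label)
    sel = np.asarray(label_image) == lab
    if sel.shape != data.shape[:-1]:
        raise InvalidParameterError("label image must match the stack's spatial shape")
    count = int(sel.sum())
    if count == 0:
        raise EmptySegmentError(f"label {label!r} has no pixels")
    mean = data[sel].mean(axis=0)
    if normalization == "max":
        peak = mean.max()
        if peak > 0:
            mean = mean / peak
    elif normalization == "area":
        total = mean.sum()
        if total > 0:
            mean = mean / total
    else:
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    return SegmentSpectrum(label=label, mean_spectrum=mean, normalization=normalization, pixel_count=count)


def local_maximum_shift(
    spectrum: np.ndarray,
    axis: WavenumberAxis,
    window: tuple[float, float],
) -> float:
    """Raman shift (cm^-1) of the local maximum of a spectrum within a window.

    A channel is a local maximum when it is >= both neighbors (band edges
    compare against the available neighbor only).  If several local maxima
    fall inside the window the highest wins; if none do, the window's argmax
    channel is returned.
    """
    values = np.asarray(spectrum, dtype=float)
    nu = axis.values
    lo, hi = sorted(window)
    in_window = (nu >= lo) & (nu <= hi)
    if not np.any(in_window):
        raise InvalidParameterError(f"window {window} contains no channels")
    left = np.r_[-np.inf, values[:-1]]
    right = np.r_[values[1:], -np.inf]
    is_local_max = (values >= left) & (values >= right)
    candidates = in_window & is_local_max
    if not np.any(candidates):
        candidates = in_window
    idx = np.flatnonzero(candidates)
    return float(nu[idx[np.argmax(values[idx])]])


# --------------------------------------------------------------------------
# ROI serialization
# --------------------------------------------------------------------------

def save_rois(rois: list[PhasorROI], path) -> None:
    payload = [
        {"label": r.label, "color": r.color, "vertices": [[float(g), float(s)] for g, s in r.vertices]}
        for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_rois(path) -> list[PhasorROI]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        PhasorROI(label=e["label"], vertices=np.asarray(e["vertices"], dtype=float), color=e.get("color"))
        for e in payload
    ]
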