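"""Quantitative readouts: ratio maps, per-cell statistics, 3D droplet
volumetry, percent-area per class, colocalization, and group tests.

The CH2/CH3 ratio map R = I(2851)/I(2930) contrasts lipid against protein:
neutral-lipid droplets run high (> 0.8), nuclei low (< 0.2).  Droplet
volumetry thresholds a single-frequency z-stack at the CH2 channel, labels
26-connected components and converts voxel counts to um^3.  Percent-area
readouts score each phasor-segmented class against the cell's foreground
area.  Group statistics mirror the assay's reporting: one-way ANOVA with
post-hoc Tukey across conditions and Student's t (pooled; Welch optional)
for pairwise panels, with N.S./*/**/*** tiers at 0.05/0.01/0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .hyperstack_io import HyperStack, PixelMask, background_mask
from .phasor_core import ROI_LABEL_IDS

__all__ = [
    "RatioMap",
    "ratio_map",
    "per_cell_ratio",
    "ld_segment_3d",
    "percent_area",
    "colocalize",
    "group_tests",
    "render_report",
    "dice_coefficient",
    "cell_stats_table",
]

logger = logging.getLogger(__name__)

CH2_SHIFT = 2851.0
CH3_SHIFT = 2930.0

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cutoff, tier in SIGNIFICANCE_TIERS:
        if p <= cutoff:
            return tier
    return "N.S."


@dataclass(frozen=True)
class RatioMap:
    """Pixelwise band ratio R = I(num)/I(den) on the foreground.

    ``ratio`` is NaN where undefined (background, or denominator <= eps);
    ``defined`` marks the usable pixels.  The conventional [0, 1] display
    clamp is a rendering choice recorded in ``display_clamp`` and never
    applied to the data.
    """

    ratio: np.ndarray
    defined: np.ndarray
    shift_num: float
    shift_den: float
    provenance: dict = field(default_factory=dict)
    display_clamp: tuple[float, float] = (0.0, 1.0)

    def mean_over(self, mask: np.ndarray) -> float:
        """Mean ratio over the defined pixels of ``mask``."""
        sel = np.asarray(mask, dtype=bool) & self.defined
        if not np.any(sel):
            return float("nan")
        return float(self.ratio[sel].mean())


def ratio_map(
    source: HyperStack | tuple[np.ndarray, np.ndarray],
    shift_num: float = CH2_SHIFT,
    shift_den: float = CH3_SHIFT,
    mask: PixelMask | np.ndarray | None = None,
    eps: float = 1e-9,
) -> RatioMap:
    """Band-ratio map from a hyperspectral stack or two single-frequency images.

    For a stack the nearest channels to ``shift_num``/``shift_den`` are used
    (within 5 cm^-1, else :class:`AxisMismatchError`).  Foreground pixels
    with denominator <= ``eps`` are flagged undefined rather than producing
    infinities.
    """
    if isinstance(source, HyperStack):
        num = source.channel(shift_num)
        den = source.channel(shift_den)
    else:
        num, den = (np.asarray(a, dtype=float) for a in source)
        if num.shape != den.shape:
            raise InvalidParameterError("numerator and denominator images must share a shape")
    fg = np.ones(num.shape, dtype=bool)
    if mask is not None:
        fg = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask, dtype=bool)
        if fg.shape != num.shape:
            raise InvalidParameterError("mask shape must match the images")
    defined = fg & (den > eps)
    ratio = np.full(num.shape, np.nan)
    ratio[defined] = num[defined] / den[defined]
    return RatioMap(
        ratio=ratio,
        defined=defined,
        shift_num=float(shift_num),
        shift_den=float(shift_den),
        provenance={"mask": getattr(mask, "provenance", None), "eps": eps},
    )


def per_cell_ratio(rmap: RatioMap, cell_instances: np.ndarray) -> pd.DataFrame:
    """One row per cell instance: mean ratio over the cell's defined pixels."""
    inst = np.asarray(cell_instances)
    if inst.shape != rmap.ratio.shape:
        raise InvalidParameterError("instance mask must match the ratio map shape")
    rows = []
    for cid in np.unique(inst[inst > 0]):
        sel = (inst == cid) & rmap.defined
        n = int(sel.sum())
        if n == 0:
            logger.warning("cell %d has no defined foreground pixels; mean ratio undefined", cid)
            rows.append({"cell_id": int(cid), "mean_ratio": np.nan, "n_pixels": 0})
        else:
            rows.append({"cell_id": int(cid), "mean_ratio": float(rmap.ratio[sel].mean()), "n_pixels": n})
    return pd.DataFrame(rows, columns=["cell_id", "mean_ratio", "n_pixels"])


# --------------------------------------------------------------------------
# 3D droplet volumetry
# --------------------------------------------------------------------------

def ld_segment_3d(
    volume: np.ndarray,
    pixel_size: float,
    z_step: float | None,
    threshold: str | float = "otsu",
    min_voxels: int = 4,
    foreground: np.ndarray | None = None,
    cell_instances: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment lipid droplets in a single-frequency z-stack.

    Threshold (Otsu within the foreground by default, or a fixed value),
    26-connected components, size filter at ``min_voxels``, per-droplet
    volume = voxel count x pixel_size^2 x z_step.  Returns the droplet
    table and the labeled volume.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise InvalidParameterError("ld_segment_3d expects a (z, y, x) volume")
    if z_step is None or z_step <= 0:
        raise GeometryError("droplet volumetry requires a positive z_step")
    if pixel_size <= 0:
        raise GeometryError("droplet volumetry requires a positive pixel_size")

    fg = np.ones(vol.shape, dtype=bool) if foreground is None else np.asarray(foreground, dtype=bool)
    if threshold == "otsu":
        t = background_mask(vol[fg], method="otsu").provenance["threshold"]
    else:
        t = float(threshold)
    binary = (vol >= t) & fg

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(binary, structure=structure)
    voxel_volume = pixel_size * pixel_size * z_step

    rows = []
    keep = np.zeros(n + 1, dtype=bool)
    if n:
        counts = np.bincount(labeled.ravel(), minlength=n + 1)
        centroids = ndimage.center_of_mass(binary, labeled, index=np.arange(1, n + 1))
        next_id = 1
        for comp in range(1, n + 1):
            if counts[comp] < min_voxels:
                continue
            keep[comp] = True
            cz, cy, cx = centroids[comp - 1]
            cell_id = 0
            if cell_instances is not None:
                sel = labeled == comp
                inst = cell_instances[sel]
                inst = inst[inst > 0]
                cell_id = int(np.bincount(inst).argmax()) if inst.size else 0
            rows.append(
                {
                    "droplet_id": next_id,
                    "cell_id": cell_id,
                    "voxel_count": int(counts[comp]),
                    "volume_um3": float(counts[comp] * voxel_volume),
                    "centroid_z": float(cz),
                    "centroid_y": float(cy),
                    "centroid_x": float(cx),
                }
            )
            next_id += 1
    # relabel compactly, dropping filtered components
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[np.flatnonzero(keep)] = np.arange(1, int(keep.sum()) + 1)
    out_labels = remap[labeled]
    df = pd.DataFrame(
        rows,
        columns=[
            "droplet_id", "cell_id", "voxel_count", "volume_um3",
            "centroid_z", "centroid_y", "centroid_x",
        ],
    )
    return df, out_labels


# --------------------------------------------------------------------------
# percent area and colocalization
# --------------------------------------------------------------------------

def percent_area(
    label_image: np.ndarray,
    class_label: int | str,
    cell_instances: np.ndarray,
    foreground: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percent of each cell's foreground area occupied by one segmented class.

    The denominator is the cell's foreground pixel count (per-cell area, the
    assay's reporting convention), the numerator the class pixels inside
    that cell.
    """
    labels = np.asarray(label_image)
    inst = np.asarray(cell_instances)
    if labels.shape != inst.shape:
        raise InvalidParameterError("label image and instances must share a shape")
    lab = ROI_LABEL_IDS[class_label] if isinstance(class_label, str) else int(class_label)
    fg = labels > 0 if foreground is None else np.asarray(foreground, dtype=bool)
    rows = []
    for cid in np.unique(inst[inst > 0]):
        cell_fg = (inst == cid) & fg
        area = int(cell_fg.sum())
        hits = int(((labels == lab) & (inst == cid)).sum())
        pct = 100.0 * hits / area if area else np.nan
        rows.append({"cell_id": int(cid), "percent_area": pct, "class_pixels": hits, "cell_pixels": area})
    return pd.DataFrame(rows, columns=["cell_id", "percent_area", "class_pixels", "cell_pixels"])


def colocalize(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: PixelMask | np.ndarray | None = None,
) -> float:
    """Pearson correlation of two single-frequency images over a mask.

    Used to test whether an alkyne-tagged drug (2233 cm^-1) accumulates
    where the lipid signal (2851 cm^-1) sits.  Requires at least 10 masked
    pixels and nonzero variance in both images.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("images must share a shape")
    if mask is not None:
        m = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 10:
        raise InsufficientDataError(f"colocalization needs >= 10 masked pixels, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined: an image has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def group_tests(
    table: pd.DataFrame,
    value_col: str,
    group_col: str = "condition",
    welch: bool = False,
) -> dict:
    """ANOVA + Tukey across all groups and pairwise t tests.

    Requires >= 2 groups with >= 2 observations each.  The t test is
    Student's (pooled variance) by default; ``welch=True`` switches to
    Welch's.  Each p value is annotated with its significance tier.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    clean = table[[group_col, value_col]].dropna()
    groups = {name: sub[value_col].to_numpy(dtype=float) for name, sub in clean.groupby(group_col)}
    if len(groups) < 2:
        raise InsufficientDataError("group tests need at least 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError("every group needs at least 2 observations")

    names = sorted(groups)
    f_stat, f_p = stats.f_oneway(*(groups[n] for n in names))
    report: dict = {
        "value": value_col,
        "groups": {n: {"n": int(len(groups[n])), "mean": float(np.mean(groups[n])),
                       "sd": float(np.std(groups[n], ddof=1))} for n in names},
        "anova": {"F": float(f_stat), "p": float(f_p), "tier": significance_tier(float(f_p))},
    }

    tukey = pairwise_tukeyhsd(clean[value_col].to_numpy(dtype=float),
                              clean[group_col].to_numpy(), alpha=0.05)
    pairs = [(row[0], row[1]) for row in tukey.summary().data[1:]]
    report["tukey"] = [
        {
            "group_a": str(a), "group_b": str(b),
            "mean_diff": float(diff), "p_adj": float(p),
            "reject": bool(rej), "tier": significance_tier(float(p)),
        }
        for (a, b), diff, p, rej in zip(pairs, tukey.meandiffs, tukey.pvalues, tukey.reject)
    ]

    ttests = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
            ttests.append(
                {"group_a": a, "group_b": b, "t": float(t), "p": float(p),
                 "welch": bool(welch), "tier": significance_tier(float(p))}
            )
    report["ttests"] = ttests
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a :func:`group_tests` report."""
    lines = [f"Group comparison of {report['value']!r}"]
    for name, g in report["groups"].items():
        lines.append(f"  {name}: n={g['n']}, mean={g['mean']:.4g}, sd={g['sd']:.4g}")
    a = report["anova"]
    lines.append(f"  one-way ANOVA: F={a['F']:.4g}, p={a['p']:.3g} [{a['tier']}]")
    for row in report["tukey"]:
        lines.append(
            f"  Tukey {row['group_a']} vs {row['group_b']}: "
            f"diff={row['mean_diff']:.4g}, p_adj={row['p_adj']:.3g} [{row['tier']}]"
        )
    for row in report["ttests"]:
        kind = "Welch" if row["welch"] else "Student"
        lines.append(
            f"  {kind} t {row['group_a']} vs {row['group_b']}: "
            f"t={row['t']:.4g}, p={row['p']:.3g} [{row['tier']}]"
        )
    return "\n".join(lines)


# --------------------------------------------------------------------------
# helpers shared by tests and the pipeline
# --------------------------------------------------------------------------

def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def cell_stats_table(
    condition: str,
    rmap: RatioMap,
    label_image: np.ndarray,
    cell_instances: np.ndarray,
    foreground: np.ndarray,
    droplets: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell summary table for one condition.

    Columns: cell_id, condition, mean_ratio, total_droplet_volume_um3,
    pct_area_steatosis, pct_area_phospholipidosis.
    """
    ratios = per_cell_ratio(rmap, cell_instances).set_index("cell_id")
    st = percent_area(label_image, "steatosis", cell_instances, foreground).set_index("cell_id")
    pl = percent_area(label_image, "phospholipidosis", cell_instances, foreground).set_index("cell_id")
    rows = []
    for cid in ratios.index:
        vol = 0.0
        if droplets is not None and len(droplets):
            vol = float(droplets.loc[droplets["cell_id"] == cid, "volume_um3"].sum())
        rows.append(
            {
                "cell_id": int(cid),
                "condition": condition,
                "mean_ratio": float(ratios.loc[cid, "mean_ratio"]),
                "total_droplet_volume_um3": vol,
                "pct_area_steatosis": float(st.loc[cid, "percent_area"]),
                "pct_area_phospholipidosis": float(pl.loc[cid, "percent_area"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "condition", "mean_ratio", "total_droplet_volume_um3",
            "pct_area_steatosis", "pct_area_phospholipidosis",
        ],
    )
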