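"""Binary/labeled 3D regions: thresholding, components, morphology, volumes.

Thresholding is strict (``intensity > t``).  Morphological operations run
slice-wise in 2D by default, matching the per-z-slice scripts the measures
were defined with; a 3D mode is available.  Pixel radii refer to the xy
pixel grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, ball

from .imgio import ImageStack

logger = logging.getLogger("synmorph")


class EmptyRegionError(ValueError):
    """Raised when an operation requires a non-empty region."""


@dataclass
class Mask3D:
    """A binary ``(z, y, x)`` voxel mask with its physical voxel size."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("Mask3D expects a (z, y, x) grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class LabeledRegions:
    """Integer-labeled regions (0 = background) with a per-label table.

    Labels are ordered by decreasing voxel count; ties are broken by the
    lexicographic (z, y, x) order of the centroid, so label 1 is always the
    largest component.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size: tuple[float, float, float]

    def mask_of(self, label: int) -> Mask3D:
        return Mask3D(self.labels == label, self.voxel_size)

    @property
    def n_regions(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_channel(
    stack: ImageStack,
    role: str,
    method: str = "otsu",
    params: dict | None = None,
) -> Mask3D:
    """Threshold one channel into a binary mask.

    ``method`` is one of ``otsu`` (global Otsu), ``fixed`` (strict
    ``intensity > params['threshold']``), ``percentile``
    (``params['percentile']`` of nonzero intensities), ``half_max``
    (``intensity > factor * max``, default factor 0.5 — robust for
    point-like channels whose foreground is far too sparse for Otsu) or
    any callable ``f(channel, **params) -> bool array`` (pluggable pixel
    classifier).  An all-background result yields an empty mask with a
    warning.
    """
    params = params or {}
    img = stack.channel(role)
    if callable(method):
        mask = np.asarray(method(img, **params), dtype=bool)
    elif method == "half_max":
        mask = img > float(params.get("factor", 0.5)) * img.max()
    elif method == "noise_floor":
        # background sigma from the 84.13th percentile (median of the
        # unclipped read-noise distribution is 0, so this percentile is
        # one sigma when foreground is sparse)
        sigma = float(np.percentile(img, 84.13))
        mask = img > float(params.get("nsigma", 6.0)) * sigma
        mask &= img > 0
    elif method == "otsu":
        if img.max() <= 0:
            mask = np.zeros_like(img, dtype=bool)
        else:
            mask = img > threshold_otsu(img)
    elif method == "fixed":
        mask = img > float(params["threshold"])
    elif method == "percentile":
        q = float(params.get("percentile", 90.0))
        nz = img[img > 0]
        mask = (
            img > np.percentile(nz, q) if nz.size else np.zeros_like(img, dtype=bool)
        )
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    if not mask.any():
        warnings.warn(f"segmentation of channel {role!r} produced an empty mask")
    return Mask3D(mask, stack.voxel_size)


def connected_components(mask: Mask3D, connectivity: int = 26) -> LabeledRegions:
    """Label 3D connected components (6- or 26-connectivity)."""
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    structure = ndi.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    raw, n = ndi.label(mask.voxels, structure=structure)
    if n == 0:
        return LabeledRegions(
            raw,
            pd.DataFrame(columns=["label", "voxel_count", "volume_um3",
                                  "centroid_z", "centroid_y", "centroid_x"]),
            mask.voxel_size,
        )
    counts = ndi.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1))
    centroids = np.array(ndi.center_of_mass(mask.voxels, raw, np.arange(1, n + 1)))
    phys = centroids * np.asarray(mask.voxel_size)
    order = sorted(
        range(n), key=lambda i: (-counts[i], tuple(np.round(phys[i], 9)))
    )
    relabel = np.zeros(n + 1, dtype=raw.dtype)
    for new, old in enumerate(order, start=1):
        relabel[old + 1] = new
    labels = relabel[raw]
    table = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "voxel_count": counts[order].astype(int),
            "volume_um3": counts[order] * mask.voxel_volume,
            "centroid_z": phys[order, 0],
            "centroid_y": phys[order, 1],
            "centroid_x": phys[order, 2],
        }
    )
    return LabeledRegions(labels, table, mask.voxel_size)


def largest_component(mask: Mask3D, connectivity: int = 26) -> Mask3D:
    """The largest connected component (empty input passes through)."""
    if mask.is_empty():
        return mask
    regions = connected_components(mask, connectivity)
    return regions.mask_of(1)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def morph_op(mask: Mask3D, op: str, radius_px: int, mode: str = "2d") -> Mask3D:
    """Erode or dilate with a disk (per z-slice, default) or ball footprint."""
    if op not in ("erode", "dilate"):
        raise ValueError("op must be 'erode' or 'dilate'")
    radius_px = int(radius_px)
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return Mask3D(mask.voxels.copy(), mask.voxel_size)
    fn = ndi.binary_erosion if op == "erode" else ndi.binary_dilation
    if mode == "2d":
        footprint = disk(radius_px)[None, :, :]
    elif mode == "3d":
        footprint = ball(radius_px)
    else:
        raise ValueError("mode must be '2d' or '3d'")
    return Mask3D(fn(mask.voxels, structure=footprint), mask.voxel_size)


def dilate_um(mask: Mask3D, margin_um: float) -> Mask3D:
    """Anisotropy-aware dilation by a physical distance (um)."""
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    if margin_um == 0 or mask.is_empty():
        return Mask3D(mask.voxels.copy(), mask.voxel_size)
    dist = ndi.distance_transform_edt(~mask.voxels, sampling=mask.voxel_size)
    return Mask3D(mask.voxels | (dist <= margin_um), mask.voxel_size)


def fill_holes_2d(mask: Mask3D) -> Mask3D:
    """Fill holes independently in every z-slice (turns shells into bodies)."""
    out = np.zeros_like(mask.voxels)
    for i in range(mask.voxels.shape[0]):
        out[i] = ndi.binary_fill_holes(mask.voxels[i])
    return Mask3D(out, mask.voxel_size)


# ---------------------------------------------------------------------------
# Measures on masks
# ---------------------------------------------------------------------------

def center_of_mass(source, role: str | None = None, weighting: str = "binary") -> np.ndarray:
    """Physical (z, y, x) centre of mass in um.

    ``source`` is a :class:`Mask3D` (binary weighting) or an
    :class:`ImageStack` with ``role`` given; ``weighting`` selects binary
    or intensity weights for stacks.
    """
    if isinstance(source, Mask3D):
        if source.is_empty():
            raise EmptyRegionError("empty region")
        weights = source.voxels.astype(float)
        voxel = source.voxel_size
    elif isinstance(source, ImageStack):
        if role is None:
            raise ValueError("role is required when source is an ImageStack")
        img = source.channel(role)
        weights = (img > 0).astype(float) if weighting == "binary" else img.astype(float)
        voxel = source.voxel_size
        if weights.sum() == 0:
            raise EmptyRegionError("empty region")
    else:
        raise TypeError("source must be a Mask3D or an ImageStack")
    idx = np.array(ndi.center_of_mass(weights))
    return idx * np.asarray(voxel)


def write_mask(mask: Mask3D, path) -> None:
    """Export a mask as an 8-bit label TIFF (255 = foreground)."""
    import tifffile

    tifffile.imwrite(
        path, mask.voxels.astype(np.uint8) * 255, photometric="minisblack"
    )


def masked_intensity_cm(
    stack: ImageStack, role: str, method: str = "half_max", params: dict | None = None
) -> np.ndarray:
    """Intensity-weighted centre of mass restricted to the segmented signal.

    Camera background pulls a whole-channel intensity CM toward the stack
    centre; segmenting first and weighting only in-mask intensities makes
    the CM of point-like structures (MTOC, bead, lysosomes) robust.
    """
    mask = segment_channel(stack, role, method, params)
    if mask.is_empty():
        raise EmptyRegionError(f"empty region for channel {role!r}")
    weights = stack.channel(role) * mask.voxels
    idx = np.array(ndi.center_of_mass(weights))
    return idx * np.asarray(stack.voxel_size)


def mask_volume(mask: Mask3D) -> float:
    """Volume in um^3 by voxel counting."""
    return mask.count * mask.voxel_volume


def intersect_masks(a: Mask3D, b: Mask3D) -> Mask3D:
    """Voxelwise AND of two same-shape masks."""
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(
            f"mask shapes differ: {a.voxels.shape} vs {b.voxels.shape}"
        )
    return Mask3D(a.voxels & b.voxels, a.voxel_size)


def overlap_fraction_with_tolerance(
    lamin: Mask3D,
    actin: Mask3D,
    erosion_px: int = 1,
    tolerance_px: int = 2,
    per_slice_average: bool = False,
) -> float:
    """Fraction of the (eroded) lamin signal covered by (dilated) actin.

    The lamin mask is eroded by ``erosion_px`` to refine boundaries; the
    actin mask is dilated by ``tolerance_px`` to absorb diffraction-scale
    misregistration (2 px at a 70 nm pixel is about 140 nm).  Both run
    slice-wise in 2D.  Voxel counts are pooled over all z-slices by default
    (``per_slice_average`` switches to the mean of per-slice ratios).
    Returns NaN with a warning when nothing survives the erosion.
    """
    if lamin.voxels.shape != actin.voxels.shape:
        raise ValueError("lamin and actin masks must share a shape")
    lam = morph_op(lamin, "erode", erosion_px, mode="2d")
    act = morph_op(actin, "dilate", tolerance_px, mode="2d")
    if lam.is_empty():
        warnings.warn("lamin mask empty after erosion; overlap fraction undefined")
        return float("nan")
    inter = lam.voxels & act.voxels
    if per_slice_average:
        ratios = []
        for i in range(lam.voxels.shape[0]):
            denom = lam.voxels[i].sum()
            if denom:
                ratios.append(inter[i].sum() / denom)
        return float(np.mean(ratios)) if ratios else float("nan")
    return float(inter.sum() / lam.voxels.sum())
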