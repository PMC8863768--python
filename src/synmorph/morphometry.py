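"""Quantitative measures of nuclear morphology and immune-synapse organization.

Implements, on segmented 3D stacks, the full measurement set used to
characterize B-cell activation at the immune synapse:

* orientation of the principal nuclear groove toward a bead or toward the
  synaptic plane, with the Polarized / Central / Antipolarized classification;
* nuclear groove depth (normalized to the cell diameter), groove area, and
  the rotation of the lobe baseline relative to the synaptic plane;
* MTOC and lysosome (LAMP1) polarity indexes by projection onto the
  cell-to-bead axis, and the LAMP1 "ring" fraction around the bead;
* z-profiles of lysosomes or surface BCR from the synapse, lysosome-cluster
  position relative to the perinuclear region, radial Exo70 profiles;
* antigen-extraction percentages from OVA-bead time courses and surface-BCR
  MFI on sum projections.

Angles are reported in degrees in [0, 180]; fractions in [0, 1]; profiles
as percentages summing to 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
import scipy.ndimage as ndi
from skimage.morphology import convex_hull_image

from .imgio import ImageStack
from .segmentation import (
    EmptyRegionError,
    Mask3D,
    center_of_mass,
    connected_components,
    dilate_um,
)

logger = logging.getLogger("synmorph")


class GrooveNotFoundError(ValueError):
    """The nucleus has no concavity above the minimal-volume cutoff."""


class DegenerateGeometryError(ValueError):
    """A direction vector required by a measure has zero length."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class GrooveGeometry:
    """Principal-groove region with its landmarks (positions in um).

    ``groove_cm`` is the binary centre of mass of the groove region (symbol
    ``c``); ``lobe_apices`` are the two nuclear-surface points bounding the
    groove opening, whose connecting segment is the depth baseline;
    ``depth_point`` is the groove point farthest from that baseline.
    """

    groove_mask: Mask3D
    groove_cm: np.ndarray
    lobe_apices: tuple[np.ndarray, np.ndarray]
    depth_point: np.ndarray
    source: str = "auto"            # auto | manual
    section_axis: int = 0           # stack axis normal to the section plane
    section_index: int = 0


@dataclass
class PolarityResult:
    """Signed projection-based polarity index and its geometry."""

    index: float
    cell_cm: np.ndarray
    bead_cm: np.ndarray
    target_cm: np.ndarray
    projection: np.ndarray          # Pj: target projected onto the cell-bead axis


@dataclass
class MorphometryRecord:
    """One row per cell: every measure the pipeline can produce.

    Missing values are ``None`` (scalars/categories) or NaN inside profiles;
    a reason is logged whenever a measure cannot be computed.
    """

    cell_id: str
    condition: str | None = None
    mode: str | None = None
    groove_angle_deg: float | None = None
    orientation_category: str | None = None
    dish_groove_angle_deg: float | None = None
    lobe_rotation_deg: float | None = None
    lobe_rotation_raw_deg: float | None = None
    groove_depth_norm: float | None = None
    groove_area_um2: float | None = None
    nucleus_volume_um3: float | None = None
    actin_volume_um3: float | None = None
    perinuclear_actin_volume_um3: float | None = None
    lamin_actin_overlap_frac: float | None = None
    mtoc_polarity_index: float | None = None
    lamp_polarity_index: float | None = None
    lamp_ring_frac: float | None = None
    z_profile_lamp: list | None = None
    z_profile_bcr: list | None = None
    cluster_position: str | None = None
    exo70_profile: dict | None = None
    ova_remaining_pct: float | None = None
    bcr_surface_mfi: float | None = None
    nucleus_to_synapse_cm_dist_um: float | None = None


# ---------------------------------------------------------------------------
# Vector helpers
# ---------------------------------------------------------------------------

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("degenerate geometry: zero-length vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _point_line_distance(point: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("coincident apices")
    return float(np.linalg.norm(np.cross(point - a, d)) / n)


# ---------------------------------------------------------------------------
# Groove detection
# ---------------------------------------------------------------------------

def detect_groove(
    nucleus_mask: Mask3D,
    hint_direction: np.ndarray | None = None,
    section_axis: int = 0,
    min_volume_um3: float = 0.5,
    manual_roi: Mask3D | None = None,
    intensity_image: np.ndarray | None = None,
) -> GrooveGeometry:
    """Locate the principal nuclear groove as a convex-hull deficit.

    The hull deficit ``convex_hull(section) - section`` is computed per 2D
    section normal to ``section_axis`` and the sections are linked into 3D
    components; the groove is the largest component (or the component best
    aligned with ``hint_direction`` from the nucleus centre, when a hint is
    given, which mirrors the manual identification of the principal groove).
    Apices and the depth point are then extracted in the section through
    the groove centre of mass: the apices are the endpoints of the
    convex-hull edge bridging the groove opening and the depth point is
    the groove pixel farthest from that edge.

    A ``manual_roi`` mask overrides detection (``source='manual'``).
    A nucleus without a concavity above ``min_volume_um3`` raises
    :class:`GrooveNotFoundError`.
    """
    if nucleus_mask.is_empty():
        raise EmptyRegionError("empty nucleus mask")
    voxel = nucleus_mask.voxel_size

    if manual_roi is not None:
        groove = Mask3D(manual_roi.voxels & ~nucleus_mask.voxels, voxel)
        if groove.is_empty():
            groove = manual_roi
        source = "manual"
    else:
        other = tuple(i for i in range(3) if i != section_axis)
        areas = nucleus_mask.voxels.sum(axis=other)
        # thin polar caps split into disjoint lobe islands whose inter-lobe
        # gaps are hull deficits but not grooves; skip them
        area_cutoff = 0.3 * areas.max()
        deficit_vox = np.zeros_like(nucleus_mask.voxels)
        for i in range(nucleus_mask.voxels.shape[section_axis]):
            sl = np.take(nucleus_mask.voxels, i, axis=section_axis)
            if sl.sum() < max(3, area_cutoff):
                continue
            hull2 = convex_hull_image(sl)
            idx = [slice(None)] * 3
            idx[section_axis] = i
            deficit_vox[tuple(idx)] = hull2 & ~sl
        deficit = Mask3D(deficit_vox, voxel)
        regions = connected_components(deficit, connectivity=26)
        table = regions.table[regions.table.volume_um3 >= min_volume_um3]
        if len(table) == 0:
            raise GrooveNotFoundError(
                "no groove found: nucleus has no concavity above "
                f"{min_volume_um3} um^3"
            )
        if hint_direction is not None:
            nuc_cm = center_of_mass(nucleus_mask)
            hint = np.asarray(hint_direction, dtype=float)
            hint = hint / np.linalg.norm(hint)
            best, best_score = None, -np.inf
            for row in table.itertuples():
                centroid = np.array([row.centroid_z, row.centroid_y, row.centroid_x])
                direction = centroid - nuc_cm
                norm = np.linalg.norm(direction)
                if norm == 0:
                    continue
                score = float(np.dot(direction / norm, hint)) * row.volume_um3
                if score > best_score:
                    best, best_score = row.label, score
            label = best if best is not None else int(table.label.iloc[0])
        else:
            label = int(table.label.iloc[0])
        groove = regions.mask_of(label)
        source = "auto"

    if intensity_image is not None:
        # optional lamin-intensity weighting of the groove centre
        weights = np.asarray(intensity_image, float) * groove.voxels
        groove_cm = np.array(ndi.center_of_mass(weights)) * np.asarray(voxel)
    else:
        groove_cm = center_of_mass(groove)

    # --- 2D landmark extraction in the section through the groove CM ------
    axis = section_axis
    section = int(round(groove_cm[axis] / voxel[axis]))
    areas = groove.voxels.sum(axis=tuple(i for i in range(3) if i != axis))
    if areas[section] == 0:
        section = int(np.argmax(areas))
    nuc2 = np.take(nucleus_mask.voxels, section, axis=axis)
    grv2 = np.take(groove.voxels, section, axis=axis)
    plane_axes = [i for i in range(3) if i != axis]
    spacing = np.array([voxel[i] for i in plane_axes])

    apex_a, apex_b = _groove_apices_2d(nuc2, grv2, spacing)

    def lift(p2):
        p3 = np.empty(3)
        p3[axis] = section * voxel[axis]
        p3[plane_axes[0]], p3[plane_axes[1]] = p2
        return p3

    grv_pts = np.argwhere(grv2) * spacing
    dists = _dists_to_line(grv_pts, apex_a, apex_b)
    depth_point = lift(grv_pts[int(np.argmax(dists))])

    return GrooveGeometry(
        groove_mask=groove,
        groove_cm=groove_cm,
        lobe_apices=(lift(apex_a), lift(apex_b)),
        depth_point=depth_point,
        source=source,
        section_axis=axis,
        section_index=section,
    )


def _dists_to_line(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise DegenerateGeometryError("coincident apices")
    rel = points - a
    cross = rel[:, 0] * d[1] - rel[:, 1] * d[0]
    return np.abs(cross) / n

def _groove_apices_2d(nucleus2d, groove2d, spacing):
    """Endpoints of the hull edge bridging the groove opening (physical 2D)."""
    pts = np.argwhere(nucleus2d) * spacing
    if len(pts) < 3:
        raise GrooveNotFoundError("nucleus section too small for apex extraction")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GrooveNotFoundError(f"degenerate nucleus section: {exc}") from exc
    verts = pts[hull.vertices]
    grv_pts = np.argwhere(groove2d) * spacing
    grv_cm = grv_pts.mean(axis=0)
    # distance map off the nucleus, to test whether an edge midpoint spans a gap
    dist_out = ndi.distance_transform_edt(~nucleus2d, sampling=spacing)
    px = max(spacing)
    best_edge, best_score = None, -np.inf
    n = len(verts)
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        mid = 0.5 * (a + b)
        idx = tuple(np.clip(np.round(mid / spacing).astype(int), 0,
                            np.array(nucleus2d.shape) - 1))
        if dist_out[idx] <= 1.5 * px:
            continue  # edge hugs the nucleus boundary
        # prefer the bridging edge closest to the groove region
        score = -np.linalg.norm(mid - grv_cm)
        if score > best_score:
            best_edge, best_score = (a, b), score
    if best_edge is None:
        # fall back: the longest hull edge
        lengths = [np.linalg.norm(verts[(i + 1) % n] - verts[i]) for i in range(n)]
        i = int(np.argmax(lengths))
        best_edge = (verts[i], verts[(i + 1) % n])
    return _refine_apices(best_edge, pts, grv_cm, px)


def _refine_apices(edge, nucleus_pts, groove_cm, px):
    """Refine hull-edge endpoints toward the true tangency points.

    On a pixelated boundary the hull touches each lobe over a flat contact
    segment rather than at a point, and the raw edge endpoints can overshoot
    by several pixels.  The deviation of the true (smooth) boundary from the
    tangent line grows quadratically away from the tangency, so the contact
    pixels within a sub-pixel band of the baseline cluster symmetrically
    around it: their median position along the edge is the apex estimate.
    """
    a, b = edge
    d = b - a
    length = np.linalg.norm(d)
    dh = d / length
    rel = nucleus_pts - a
    off = np.abs(rel[:, 0] * dh[1] - rel[:, 1] * dh[0])
    near = off <= 1.0 * px
    if not near.any():
        return a, b
    s = rel[near] @ dh
    s_groove = float((groove_cm - a) @ dh)
    left, right = s < s_groove, s > s_groove
    if not (left.any() and right.any()):
        return a, b
    s_a, s_b = float(np.median(s[left])), float(np.median(s[right]))
    if s_b - s_a < 4 * px:
        return a, b
    return a + s_a * dh, a + s_b * dh


# ---------------------------------------------------------------------------
# Orientation measures
# ---------------------------------------------------------------------------

def groove_orientation_bead(bead_cm, cell_cm, groove_cm) -> float:
    """Angle (deg) between the cell->bead vector and the cell->groove vector."""
    a = np.asarray(bead_cm, float)
    b = np.asarray(cell_cm, float)
    c = np.asarray(groove_cm, float)
    return _angle_deg(a - b, c - b)


def classify_orientation(angle_deg: float, bin_edges=(0.0, 45.0, 135.0, 180.0)) -> str:
    """Polarized on [0, 45], Central on (45, 135], Antipolarized on (135, 180].

    The lower bin is closed so the Polarized supremum is exactly the first
    interior edge.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"angle must be in [0, 180], got {angle_deg}")
    e = list(bin_edges)
    if angle_deg <= e[1]:
        return "Polarized"
    if angle_deg <= e[2]:
        return "Central"
    return "Antipolarized"


def groove_orientation_dish(cell_cm, groove_cm, synapse_plane_z: float) -> float:
    """Angle (deg) between cell->groove and the perpendicular toward the plane.

    0 deg means the groove faces the synaptic plane ``z = synapse_plane_z``.
    """
    b = np.asarray(cell_cm, float)
    c = np.asarray(groove_cm, float)
    if b[0] == synapse_plane_z:
        raise DegenerateGeometryError("cell centre lies on the synaptic plane")
    foot = np.array([synapse_plane_z, b[1], b[2]])
    return _angle_deg(c - b, foot - b)


def lobe_rotation(apices, synapse_plane_z: float = 0.0) -> tuple[float, float]:
    """Angle between the apex baseline and the synaptic plane.

    Returns ``(folded, raw)``: folded in [0, 90] (0 = baseline parallel to
    the plane, i.e. a fully rotated groove) and the raw baseline-to-normal
    angle in [0, 180].
    """
    a1, a2 = (np.asarray(a, float) for a in apices)
    if np.allclose(a1, a2):
        raise DegenerateGeometryError("coincident apices")
    baseline = a2 - a1
    normal = np.array([1.0, 0.0, 0.0])  # z axis; plane is z = const
    raw = _angle_deg(baseline, normal)
    folded = abs(90.0 - raw)
    return folded, raw


# ---------------------------------------------------------------------------
# Groove depth / area
# ---------------------------------------------------------------------------

def groove_depth(groove: GrooveGeometry, cell_mask: Mask3D) -> float:
    """Normalized groove depth h / cell diameter.

    ``h`` is the distance from the depth point to the apex baseline; the
    cell diameter is the maximum Feret diameter of the cell mask in the
    groove's section plane.
    """
    if cell_mask.is_empty():
        raise EmptyRegionError("empty cell mask")
    h = _point_line_distance(groove.depth_point, *groove.lobe_apices)
    axis = groove.section_axis
    cell2 = np.take(cell_mask.voxels, groove.section_index, axis=axis)
    plane_axes = [i for i in range(3) if i != axis]
    spacing = np.array([cell_mask.voxel_size[i] for i in plane_axes])
    diameter = _feret_diameter_2d(cell2, spacing)
    if diameter == 0:
        raise EmptyRegionError("cell mask empty in the groove section")
    return h / diameter


def _feret_diameter_2d(mask2d: np.ndarray, spacing: np.ndarray) -> float:
    pts = np.argwhere(mask2d) * spacing
    if len(pts) < 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        verts = pts
    diff = verts[:, None, :] - verts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def groove_area(
    nucleus_mask: Mask3D,
    geometry: GrooveGeometry | None = None,
    section_axis: int = 0,
    hint_direction: np.ndarray | None = None,
) -> float | None:
    """Maximum cross-sectional area (um^2) of the principal groove.

    Mirrors delineating the groove at its maximum size: the groove region
    area is evaluated in every section and the maximum is returned.
    Returns ``None`` with a warning when no groove is detectable.
    """
    if geometry is None:
        try:
            geometry = detect_groove(
                nucleus_mask, hint_direction=hint_direction, section_axis=section_axis
            )
        except GrooveNotFoundError as exc:
            warnings.warn(f"groove area unavailable: {exc}")
            return None
    axis = geometry.section_axis
    voxel = nucleus_mask.voxel_size
    plane_axes = [i for i in range(3) if i != axis]
    pixel_area = voxel[plane_axes[0]] * voxel[plane_axes[1]]
    areas = geometry.groove_mask.voxels.sum(
        axis=tuple(i for i in range(3) if i != axis)
    )
    return float(areas.max() * pixel_area)


# ---------------------------------------------------------------------------
# Polarity
# ---------------------------------------------------------------------------

def polarity_index(target_cm, cell_cm, bead_cm, planar: bool = False) -> PolarityResult:
    """Signed projection polarity index in [-1, 1].

    The target (MTOC point, or intensity-weighted LAMP1 centre of mass) is
    projected onto the Cellmc->Beadmc axis; the index is the signed ratio of
    the projected distance to the cell-bead distance: +1 fully polarized
    (target at the bead), 0 at the cell centre, -1 anti-polarized.  Values
    are clamped to [-1, 1] since segmented centres can project slightly
    beyond the bead.  ``planar=True`` drops the z components first
    (single-plane convention).
    """
    t = np.asarray(target_cm, float).copy()
    b = np.asarray(cell_cm, float).copy()
    a = np.asarray(bead_cm, float).copy()
    if planar:
        t[0] = b[0] = a[0] = 0.0
    axis = a - b
    norm2 = float(np.dot(axis, axis))
    if norm2 == 0:
        raise DegenerateGeometryError("cell and bead centres coincide")
    scalar = float(np.dot(t - b, axis) / norm2)
    projection = b + scalar * axis
    return PolarityResult(
        index=float(np.clip(scalar, -1.0, 1.0)),
        cell_cm=b, bead_cm=a, target_cm=t, projection=projection,
    )


def lamp_ring_fraction(
    stack: ImageStack,
    bead_cm,
    ring_radius_um: float = 3.5,
    mode: str = "3d",
    cell_mask: Mask3D | None = None,
    role: str = "lamp1",
) -> float:
    """Fraction of LAMP1 fluorescence inside the ring around the bead.

    ``mode='3d'`` sums inside the radius-``ring_radius_um`` sphere around
    the bead centre; ``mode='2d'`` uses the disc in the bead's z-slice.
    Normalized by total LAMP1 intensity (within ``cell_mask`` when given).
    Returns NaN when the channel carries no signal.
    """
    img = stack.channel(role).astype(float)
    if cell_mask is not None:
        img = img * cell_mask.voxels
    total = img.sum()
    if total == 0:
        warnings.warn("zero total LAMP1 intensity; ring fraction undefined")
        return float("nan")
    bead = np.asarray(bead_cm, float)
    dz, dy, dx = stack.voxel_size
    nz, ny, nx = stack.shape
    if mode == "3d":
        d2 = (
            ((np.arange(nz) * dz - bead[0]) ** 2)[:, None, None]
            + ((np.arange(ny) * dy - bead[1]) ** 2)[None, :, None]
            + ((np.arange(nx) * dx - bead[2]) ** 2)[None, None, :]
        )
        inside = img[d2 <= ring_radius_um**2].sum()
    elif mode == "2d":
        zi = int(np.clip(round(bead[0] / dz), 0, nz - 1))
        d2 = (
            ((np.arange(ny) * dy - bead[1]) ** 2)[:, None]
            + ((np.arange(nx) * dx - bead[2]) ** 2)[None, :]
        )
        inside = img[zi][d2 <= ring_radius_um**2].sum()
    else:
        raise ValueError("mode must be '3d' or '2d'")
    return float(inside / total)


# ---------------------------------------------------------------------------
# Profiles and distributions
# ---------------------------------------------------------------------------

def z_distribution(
    stack: ImageStack,
    role: str,
    synapse_z_index: int = 0,
    n_slices: int = 10,
    step_um: float = 0.2,
    cell_mask: Mask3D | None = None,
    normalize: str = "slices",
) -> np.ndarray:
    """Percent MFI per z-slice, starting at the synapse and moving into the cell.

    The per-slice mean fluorescence intensity (within the cell mask when
    given) is normalized to the total over the ``n_slices`` analyzed slices
    and multiplied by 100, so the output sums to 100 whenever signal exists
    (``normalize='stack'`` divides by the whole-stack total instead).
    All-zero signal yields NaNs.
    """
    img = stack.channel(role).astype(float)
    dz = stack.voxel_size[0]
    stride = max(1, int(round(step_um / dz)))
    idx = synapse_z_index + stride * np.arange(n_slices)
    if idx[-1] >= img.shape[0]:
        raise ValueError(
            f"z_distribution needs slice {idx[-1]} but the stack has "
            f"{img.shape[0]} slices"
        )
    mfi = np.empty(n_slices)
    for i, zi in enumerate(idx):
        if cell_mask is not None:
            sel = cell_mask.voxels[zi]
            mfi[i] = img[zi][sel].mean() if sel.any() else 0.0
        else:
            mfi[i] = img[zi].mean()
    denom = mfi.sum() if normalize == "slices" else img.mean(axis=(1, 2)).sum()
    if denom == 0:
        warnings.warn(f"all-zero {role} signal; z distribution undefined")
        return np.full(n_slices, np.nan)
    return 100.0 * mfi / denom


def cluster_position(
    lamp_mask: Mask3D, nucleus_mask: Mask3D, margin_um: float = 1.0
) -> str:
    """Position of the largest LAMP1 cluster relative to the perinuclear region.

    The perinuclear region is a shell of width ``margin_um`` around the
    nucleus; a cluster that touches the nucleus or that shell at one or more
    voxels — including clusters only partially inside — is ``"inside"``,
    otherwise ``"outside"``.
    """
    if lamp_mask.is_empty():
        warnings.warn("empty lysosome mask; cluster position undefined")
        return None
    inside_zone = dilate_um(nucleus_mask, margin_um)
    regions = connected_components(lamp_mask, connectivity=26)
    largest = regions.mask_of(1)
    touches = (largest.voxels & inside_zone.voxels).any()
    return "inside" if touches else "outside"


def radial_profile(
    stack: ImageStack,
    role: str,
    ref_point,
    r_max_um: float = 2.0,
    dr_um: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """MFI over growing discs around a reference point (xy, at the ref z-slice).

    Returns ``(radii, mfi)`` for disc radii ``dr, 2*dr, ..., r_max``.
    """
    ref = np.asarray(ref_point, float)
    dz, dy, dx = stack.voxel_size
    nz, ny, nx = stack.shape
    zi = int(round(ref[0] / dz))
    if not (0 <= zi < nz and 0 <= ref[1] <= (ny - 1) * dy and 0 <= ref[2] <= (nx - 1) * dx):
        raise ValueError("reference point lies outside the image")
    plane = stack.channel(role)[zi].astype(float)
    d2 = (
        ((np.arange(ny) * dy - ref[1]) ** 2)[:, None]
        + ((np.arange(nx) * dx - ref[2]) ** 2)[None, :]
    )
    radii = np.arange(dr_um, r_max_um + dr_um / 2, dr_um)
    mfi = np.array([plane[d2 <= r**2].mean() for r in radii])
    return radii, mfi


# ---------------------------------------------------------------------------
# Sum-projection measures
# ---------------------------------------------------------------------------

def _sum_projection(stack: ImageStack, role: str) -> np.ndarray:
    return stack.channel(role).astype(float).sum(axis=0)


def antigen_extraction_pct(
    stacks: list[ImageStack],
    bead_cms: list,
    area_radius_um: float = 2.5,
    role: str = "ova",
    background_correction: bool = True,
) -> np.ndarray:
    """Percent antigen extracted per timepoint from OVA-bead fluorescence.

    For each stack, the OVA intensity is summed over z (sum projection)
    within a fixed disc of radius ``area_radius_um`` around the bead's xy
    position; extraction at time ``t`` is the percent fluorescence lost
    relative to the first (t = 0) timepoint, clamped to [0, 100].
    ``background_correction`` subtracts the projection's median (the bead
    occupies a small area, so the median estimates the camera background).
    """
    if len(stacks) == 0:
        raise ValueError("missing t=0 stack: the series is empty")
    if len(bead_cms) != len(stacks):
        raise ValueError("bead_cms must match the number of timepoints")
    sums = []
    for stack, bead in zip(stacks, bead_cms):
        proj = _sum_projection(stack, role)
        if background_correction:
            proj = np.clip(proj - np.median(proj), 0.0, None)
        _, dy, dx = stack.voxel_size
        ny, nx = proj.shape
        b = np.asarray(bead, float)
        d2 = (
            ((np.arange(ny) * dy - b[1]) ** 2)[:, None]
            + ((np.arange(nx) * dx - b[2]) ** 2)[None, :]
        )
        sums.append(proj[d2 <= area_radius_um**2].sum())
    i0 = sums[0]
    if i0 == 0:
        raise ValueError("zero OVA signal at t=0; extraction undefined")
    pct = (1.0 - np.asarray(sums) / i0) * 100.0
    return np.clip(pct, 0.0, 100.0)


def surface_mfi(stack: ImageStack, role: str = "bcr", region2d: np.ndarray | None = None) -> float:
    """MFI of a channel on the z sum projection within a fixed 2D area."""
    proj = _sum_projection(stack, role)
    if region2d is None:
        region2d = np.ones_like(proj, dtype=bool)
    region2d = np.asarray(region2d, dtype=bool)
    if not region2d.any():
        raise EmptyRegionError("empty surface region")
    return float(proj[region2d].mean())


def synapse_center_distance(nucleus_cm, synapse_cm) -> float:
    """Euclidean xy distance (um) between nucleus and synapse centres of mass."""
    n = np.asarray(nucleus_cm, float)
    s = np.asarray(synapse_cm, float)
    return float(np.hypot(n[1] - s[1], n[2] - s[2]))
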