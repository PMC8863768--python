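"""Synthetic confocal B-cell scenes with exact ground truth.

A phantom emulates the two activation geometries used to study nuclear
reorientation at the immune synapse:

* **bead conjugates** — a spherical cell next to a 3 um antigen-coated bead,
  the reference axis running from the cell centre of mass (symbol ``b``)
  to the bead centre of mass (``a``);
* **coverslip synapse ("dish")** — the cell sitting on the synaptic plane,
  which is the low-z face of the stack; the reference axis points from the
  cell centre toward the plane.

The nucleus is a union of 3-4 overlapping lobe spheres placed on a ring,
minus a parallel-sided slot that carves the principal groove.  The slot
opens along the configured groove direction, so the groove centre of mass
lies exactly on that direction by symmetry, the two lobe apices and the
groove floor are analytic, and the normalized groove depth equals
``groove_depth_frac`` by construction.  Every derived quantity (polarity
index implied by the MTOC position, orientation angles, depth, lysosome
ring fraction) is therefore known exactly before any rendering.

Rendering voxelizes each structure into its own channel, convolves with a
Gaussian PSF and applies Poisson then Gaussian read noise.  Every channel
amplitude means peak photon counts per structure voxel: volume-like
structures (nucleus, actin, bead, OVA, BCR) are binary bodies at that
amplitude, point-like structures (MTOC/tubulin, lysosomes/LAMP1, Exo70)
are Gaussian puncta with that peak, so all structures share a realistic
brightness scale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import convex_hull_image

from .imgio import ConfigError, ImageStack, write_stack

__all__ = [
    "NoiseModel", "SceneConfig", "CellScene",
    "make_scene", "render_stack", "make_timecourse", "apply_noise",
    "write_scene", "desk_scale_config",
]

# angular position (deg) of the two main lobes flanking the groove,
# measured from the groove axis; the remaining lobes fill the back
_MAIN_LOBE_ANGLE_DEG = 68.0
_BACK_LOBE_ANGLES = {3: (180.0,), 4: (150.0, -150.0)}
#: ring radius as a fraction of the cell radius
_LOBE_RING_FRAC = 0.32
#: sigma (um) of rendered point structures (MTOC, lysosome puncta)
_PUNCTUM_SIGMA_UM = 0.25
#: guard band (um) kept between lysosome puncta and the ring boundary so the
#: configured inside-fraction is crisp despite the PSF
_RING_GUARD_UM = 0.6
_STACK_MARGIN_UM = 1.2


@dataclass
class NoiseModel:
    """Poisson shot noise (scaled) followed by additive Gaussian read noise."""

    poisson_scale: float = 1.0   # photons per count; 0 disables shot noise
    gaussian_sd: float = 2.0     # counts; 0 disables read noise

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ConfigError("noise parameters must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gaussian_sd > 0


def _default_amplitudes() -> dict[str, float]:
    # peak counts per structure voxel, uniform across channels
    return {role: 500.0 for role in
            ("nucleus", "actin", "tubulin", "lamp1", "bead", "ova", "exo70", "bcr")}


@dataclass
class SceneConfig:
    """Parameters of one synthetic cell scene.

    ``groove_orientation`` is the angle (deg) between the groove opening and
    the reference axis (cell->bead, or cell->synaptic plane when no bead is
    present).  ``groove_depth_frac`` is the target normalized depth
    h / cell diameter.  ``mtoc_offset`` places the MTOC on the reference
    axis so that its implied polarity index equals the offset exactly.
    """

    cell_radius: float = 5.0
    nucleus_lobe_count: int = 3
    lobe_radii: tuple[float, ...] | None = None
    groove_half_angle: float = 12.0
    groove_orientation: float = 0.0
    groove_depth_frac: float = 0.2
    bead_present: bool = True
    bead_radius: float = 1.5
    bead_center: tuple[float, float, float] | None = None
    mtoc_offset: float = 0.8
    lysosome_count: int = 12
    lysosome_mode: str = "synaptic_central"
    lysosome_inside_fraction: float | None = None
    channel_amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    psf_sigma: tuple[float, float, float] = (0.35, 0.13, 0.13)
    noise: NoiseModel = field(default_factory=NoiseModel)
    voxel_size: tuple[float, float, float] = (0.2, 0.07, 0.07)
    stack_shape: tuple[int, int, int] | None = None
    rng_seed: int = 0
    ring_radius_um: float = 3.5   # lysosome-ring radius used for placement truth
    exo70_sigma_um: float = 0.6

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        if self.cell_radius <= 0 or self.bead_radius <= 0:
            raise ConfigError("cell_radius and bead_radius must be > 0")
        if self.nucleus_lobe_count not in (3, 4):
            raise ConfigError(
                f"nucleus_lobe_count must be 3 or 4, got {self.nucleus_lobe_count}"
            )
        if self.lobe_radii is None:
            self.lobe_radii = tuple([0.64 * self.cell_radius] * self.nucleus_lobe_count)
        self.lobe_radii = tuple(float(r) for r in self.lobe_radii)
        if len(self.lobe_radii) != self.nucleus_lobe_count:
            raise ConfigError("lobe_radii length must equal nucleus_lobe_count")
        if min(self.lobe_radii) <= 0:
            raise ConfigError("lobe_radii must be > 0")
        if self.lobe_radii[0] != self.lobe_radii[1]:
            raise ConfigError("the two main lobes must share a radius")
        ring = _LOBE_RING_FRAC * self.cell_radius
        if ring + max(self.lobe_radii) > self.cell_radius:
            raise ConfigError(
                "nucleus larger than cell: lobe ring radius + lobe radius "
                f"({ring + max(self.lobe_radii):.2f} um) exceeds cell radius "
                f"({self.cell_radius} um)"
            )
        if not 0.0 <= self.groove_depth_frac <= 1.0:
            raise ConfigError("groove_depth_frac must be in [0, 1]")
        if not -1.0 <= self.mtoc_offset <= 1.0:
            raise ConfigError("mtoc_offset must be in [-1, 1]")
        if not 0.0 <= self.groove_orientation <= 180.0:
            raise ConfigError("groove_orientation must be in [0, 180] degrees")
        if not 0 < self.groove_half_angle < 45:
            raise ConfigError("groove_half_angle must be in (0, 45) degrees")
        if self.lysosome_mode not in (
            "perinuclear", "synaptic_central", "synaptic_dispersed"
        ):
            raise ConfigError(f"unknown lysosome_mode {self.lysosome_mode!r}")
        if self.lysosome_inside_fraction is not None and not (
            0.0 <= self.lysosome_inside_fraction <= 1.0
        ):
            raise ConfigError("lysosome_inside_fraction must be in [0, 1]")
        if min(self.psf_sigma) <= 0:
            raise ConfigError("psf_sigma must be strictly positive")
        if min(v for v in self.channel_amplitudes.values()) <= 0:
            raise ConfigError("channel amplitudes must be strictly positive")
        if min(self.voxel_size) <= 0:
            raise ConfigError("voxel_size must be strictly positive")
        # groove slot geometry feasibility: apices must survive the carve
        geo = _groove_geometry(self)
        if geo["w_apex"] <= geo["slot_half_width"] + 0.2:
            raise ConfigError(
                "groove_half_angle too wide: the carved slot would swallow "
                "the lobe apices"
            )


def _groove_geometry(config: SceneConfig) -> dict:
    """Analytic slot/apex geometry in the groove frame (u = groove axis)."""
    ring = _LOBE_RING_FRAC * config.cell_radius
    gamma = np.deg2rad(_MAIN_LOBE_ANGLE_DEG)
    r_main = config.lobe_radii[0]
    u_apex = ring * np.cos(gamma) + r_main
    w_apex = ring * np.sin(gamma)
    slot_half_width = np.sin(np.deg2rad(config.groove_half_angle)) * u_apex
    # depth of the natural crevice between the two main lobes (no carve)
    natural_h = r_main - np.sqrt(max(r_main**2 - w_apex**2, 0.0))
    target_h = config.groove_depth_frac * 2.0 * config.cell_radius
    if 0 < target_h < natural_h:
        warnings.warn(
            f"groove_depth_frac {config.groove_depth_frac} is shallower than "
            f"the natural inter-lobe crevice ({natural_h / (2 * config.cell_radius):.3f}); "
            "the realized depth is the natural one"
        )
    h = natural_h if target_h == 0 else max(target_h, natural_h)
    return {
        "ring": ring,
        "gamma": gamma,
        "u_apex": u_apex,
        "w_apex": w_apex,
        "slot_half_width": slot_half_width,
        "u_floor": u_apex - h,
        "depth_um": h,
        "carve": target_h > 0,
    }


@dataclass
class CellScene:
    """Analytic ground truth for one phantom (all positions in stack um).

    Symbols follow the measurement definitions: ``cell_cm`` is ``b`` /
    ``Cellmc``, ``bead_cm`` is ``a`` / ``Beadmc``, ``groove_cm`` is ``c``.
    """

    config: SceneConfig
    cell_cm: np.ndarray
    bead_cm: np.ndarray | None
    groove_cm: np.ndarray
    lobe_apices: tuple[np.ndarray, np.ndarray]
    depth_point: np.ndarray
    mtoc: np.ndarray
    lysosome_centers: np.ndarray          # (n, 3) um
    groove_depth_true: float              # normalized h / diameter
    groove_axis: np.ndarray               # unit vector u (z, y, x)
    groove_width_axis: np.ndarray         # unit vector w
    lobe_centers: np.ndarray              # (n_lobes, 3) um
    synapse_z_um: float
    stack_shape: tuple[int, int, int]
    lysosome_ring_fraction_true: float | None
    bead_signal_per_time: list[float] | None = None
    ova_remaining: float = 1.0
    _nucleus_volume: float | None = None

    @property
    def mtoc_polarity_index_true(self) -> float:
        return float(self.config.mtoc_offset)

    @property
    def groove_orientation_true(self) -> float:
        return float(self.config.groove_orientation)

    def inside_nucleus(self, points: np.ndarray) -> np.ndarray:
        """Analytic nucleus indicator for ``(..., 3)`` physical points (um)."""
        pts = np.asarray(points, dtype=float)
        rel = pts - self.cell_cm
        in_lobe = np.zeros(pts.shape[:-1], dtype=bool)
        for centre, radius in zip(self.lobe_centers, self.config.lobe_radii):
            in_lobe |= np.sum((pts - centre) ** 2, axis=-1) <= radius**2
        geo = _groove_geometry(self.config)
        if geo["carve"]:
            uu = rel @ self.groove_axis
            ww = rel @ self.groove_width_axis
            in_slot = (uu > geo["u_floor"]) & (np.abs(ww) < geo["slot_half_width"])
            in_lobe &= ~in_slot
        return in_lobe

    def inside_cell(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.sum((pts - self.cell_cm) ** 2, axis=-1) <= self.config.cell_radius**2

    @property
    def nucleus_volume_true(self) -> float:
        """Nucleus volume (um^3) from fine-grid integration of the analytic body."""
        if self._nucleus_volume is None:
            step = 0.04
            r = _LOBE_RING_FRAC * self.config.cell_radius + max(self.config.lobe_radii)
            ax = [np.arange(c - r, c + r + step, step) for c in self.cell_cm]
            zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=True)
            pts_mask = np.zeros((len(ax[0]), len(ax[1]), len(ax[2])), bool)
            # evaluate slab-wise to bound memory
            for i, z in enumerate(ax[0]):
                pts = np.stack(
                    np.broadcast_arrays(
                        np.full((len(ax[1]), len(ax[2])), z),
                        ax[1][:, None],
                        ax[2][None, :],
                    ),
                    axis=-1,
                )
                pts_mask[i] = self.inside_nucleus(pts)
            self._nucleus_volume = float(pts_mask.sum() * step**3)
        return self._nucleus_volume

    def to_dict(self) -> dict:
        d = {
            "cell_cm": self.cell_cm.tolist(),
            "bead_cm": None if self.bead_cm is None else self.bead_cm.tolist(),
            "groove_cm": self.groove_cm.tolist(),
            "lobe_apices": [a.tolist() for a in self.lobe_apices],
            "depth_point": self.depth_point.tolist(),
            "mtoc": self.mtoc.tolist(),
            "lysosome_centers": self.lysosome_centers.tolist(),
            "groove_depth_true": self.groove_depth_true,
            "groove_axis": self.groove_axis.tolist(),
            "nucleus_volume_true": self.nucleus_volume_true,
            "mtoc_polarity_index_true": self.mtoc_polarity_index_true,
            "groove_orientation_true": self.groove_orientation_true,
            "lysosome_ring_fraction_true": self.lysosome_ring_fraction_true,
            "synapse_z_um": self.synapse_z_um,
            "voxel_size": list(self.config.voxel_size),
            "stack_shape": list(self.stack_shape),
        }
        return d


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _basis(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reference axis and groove frame (u, w, v), all unit (z, y, x) vectors."""
    theta = np.deg2rad(config.groove_orientation)
    if config.bead_present:
        ref = np.array([0.0, 0.0, 1.0])                      # +x toward bead
        u = np.array([0.0, np.sin(theta), np.cos(theta)])    # groove in xy plane
        w = np.array([0.0, np.cos(theta), -np.sin(theta)])
        v = np.array([1.0, 0.0, 0.0])
    else:
        ref = np.array([-1.0, 0.0, 0.0])                     # -z toward the plane
        u = np.array([-np.cos(theta), 0.0, np.sin(theta)])   # groove in zx plane
        w = np.array([np.sin(theta), 0.0, np.cos(theta)])
        v = np.array([0.0, 1.0, 0.0])
    return ref, u, w, v


def make_scene(config: SceneConfig) -> CellScene:
    """Construct the analytic ground-truth geometry for one phantom.

    Deterministic given ``config.rng_seed``; raises :class:`ConfigError`
    for infeasible geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[0])
    R = config.cell_radius
    geo = _groove_geometry(config)
    ref, u, w, v = _basis(config)

    # --- world frame: cell at origin, then shift into the stack -----------
    cell = np.zeros(3)
    if config.bead_present:
        if config.bead_center is not None:
            bead = np.asarray(config.bead_center, dtype=float)
            gap = np.linalg.norm(bead - cell) - (R + config.bead_radius)
            if gap < -0.5 * config.bead_radius:
                raise ConfigError("bead overlaps the cell interior beyond the contact cap")
        else:
            bead = cell + (R + config.bead_radius) * ref
    else:
        bead = None

    axis_len = np.linalg.norm(bead - cell) if bead is not None else R
    mtoc = cell + config.mtoc_offset * axis_len * ref

    lobe_angles = [np.rad2deg(geo["gamma"]), -np.rad2deg(geo["gamma"])]
    lobe_angles += list(_BACK_LOBE_ANGLES[config.nucleus_lobe_count])
    lobe_centers = np.array(
        [
            cell
            + geo["ring"] * (np.cos(np.deg2rad(a)) * u + np.sin(np.deg2rad(a)) * w)
            for a in lobe_angles
        ]
    )
    apex1 = cell + geo["u_apex"] * u + geo["w_apex"] * w
    apex2 = cell + geo["u_apex"] * u - geo["w_apex"] * w
    depth_point = cell + geo["u_floor"] * u
    # the groove floor must sit on nuclear material
    floor_probe = cell + (geo["u_floor"] - 0.05) * u
    if not any(
        np.linalg.norm(floor_probe - c) <= r
        for c, r in zip(lobe_centers, config.lobe_radii)
    ):
        raise ConfigError(
            "groove_depth_frac too deep: the groove floor falls outside the nucleus"
        )

    groove_cm = cell + _groove_cm_offset(config, geo, lobe_centers - cell, u, w) * u

    lysosomes, ring_frac = _place_lysosomes(config, rng, cell, bead, u)

    # --- shift everything into stack coordinates --------------------------
    bounds = [cell - R, cell + R]
    if bead is not None:
        bounds += [bead - config.bead_radius, bead + config.bead_radius]
    bounds += [mtoc - 0.8, mtoc + 0.8]
    lo = np.min(np.array(bounds), axis=0) - _STACK_MARGIN_UM
    hi = np.max(np.array(bounds), axis=0) + _STACK_MARGIN_UM
    if not config.bead_present:
        lo[0] = -R - 0.6   # synaptic plane sits 0.6 um above the stack bottom
    voxel = np.asarray(config.voxel_size)
    if config.stack_shape is None:
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel[i])) + 1 for i in range(3))
        offset = -lo
    else:
        shape = tuple(int(s) for s in config.stack_shape)
        extent = np.array([(s - 1) * voxel[i] for i, s in enumerate(shape)])
        need = hi - lo
        for i, axname in enumerate("zyx"):
            if need[i] > extent[i]:
                clipped = "bead" if (bead is not None and i == 2) else "cell"
                raise ConfigError(
                    f"stack_shape too small along {axname}: the {clipped} "
                    f"would be clipped ({need[i]:.1f} um needed, "
                    f"{extent[i]:.1f} um available)"
                )
        offset = -lo + (extent - need) / 2.0

    def shift(p):
        return None if p is None else np.asarray(p, dtype=float) + offset

    scene = CellScene(
        config=config,
        cell_cm=shift(cell),
        bead_cm=shift(bead),
        groove_cm=shift(groove_cm),
        lobe_apices=(shift(apex1), shift(apex2)),
        depth_point=shift(depth_point),
        mtoc=shift(mtoc),
        lysosome_centers=np.array([shift(p) for p in lysosomes])
        if len(lysosomes)
        else np.zeros((0, 3)),
        groove_depth_true=geo["depth_um"] / (2.0 * R),
        groove_axis=u,
        groove_width_axis=w,
        lobe_centers=np.array([shift(c) for c in lobe_centers]),
        synapse_z_um=float((cell + offset)[0] - R) if not config.bead_present else 0.0,
        stack_shape=shape,
        lysosome_ring_fraction_true=ring_frac,
    )
    return scene


def _groove_cm_offset(config, geo, lobe_centers_rel, u, w) -> float:
    """Distance of the groove-region centroid from the cell centre, along u.

    The groove region (convex-hull deficit of the nucleus cross-section in
    the groove plane) is symmetric about the groove axis, so only the along-
    axis coordinate is nonzero; it is integrated on a fine 2D grid.
    """
    R = config.cell_radius
    step = 0.02
    uu, ww = np.meshgrid(
        np.arange(-R, R + step, step), np.arange(-R, R + step, step), indexing="ij"
    )
    nucleus = np.zeros_like(uu, dtype=bool)
    for centre, radius in zip(lobe_centers_rel, config.lobe_radii):
        cu, cw = centre @ u, centre @ w
        nucleus |= (uu - cu) ** 2 + (ww - cw) ** 2 <= radius**2
    if geo["carve"]:
        nucleus &= ~((uu > geo["u_floor"]) & (np.abs(ww) < geo["slot_half_width"]))
    deficit = convex_hull_image(nucleus) & ~nucleus
    labels, _ = ndi.label(deficit)
    seed = (
        int(round((geo["u_floor"] + 0.1 + R) / step)),
        int(round((0.0 + R) / step)),
    )
    lab = labels[seed]
    if lab == 0:  # seed fell on nucleus/background; take largest component
        counts = np.bincount(labels.ravel())[1:]
        lab = int(np.argmax(counts)) + 1
    region = labels == lab
    return float(uu[region].mean())


def _place_lysosomes(config, rng, cell, bead, u):
    """Sample lysosome centres; returns (centres, true ring fraction or None)."""
    n = config.lysosome_count
    if n == 0:
        return [], None
    R = config.cell_radius
    ring_r = config.ring_radius_um
    anchor = bead if bead is not None else cell - R * np.array([1.0, 0, 0])

    def sample_inside():
        while True:
            p = cell + _random_in_ball(rng, R - 0.4)
            if np.linalg.norm(p - anchor) <= ring_r - _RING_GUARD_UM:
                return p

    def sample_outside():
        while True:
            p = cell + _random_in_ball(rng, R - 0.4)
            if np.linalg.norm(p - anchor) >= ring_r + _RING_GUARD_UM:
                return p

    def sample_perinuclear():
        d = rng.uniform(0.76, 0.92) * R
        return cell + d * _random_direction(rng)

    if config.lysosome_inside_fraction is not None:
        n_in = int(round(config.lysosome_inside_fraction * n))
        pts = [sample_inside() for _ in range(n_in)]
        pts += [sample_outside() for _ in range(n - n_in)]
    elif config.lysosome_mode == "synaptic_central":
        pts = [sample_inside() for _ in range(n)]
    elif config.lysosome_mode == "synaptic_dispersed":
        pts = [sample_outside() for _ in range(n)]
    else:  # perinuclear
        pts = [sample_perinuclear() for _ in range(n)]

    if bead is not None:
        inside = sum(np.linalg.norm(p - bead) <= ring_r for p in pts)
        ring_frac = inside / n
    else:
        ring_frac = None
    return pts, ring_frac


def _random_direction(rng):
    vec = rng.normal(size=3)
    return vec / np.linalg.norm(vec)


def _random_in_ball(rng, radius):
    return _random_direction(rng) * radius * rng.uniform() ** (1 / 3)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _grid_axes(scene: CellScene):
    voxel = scene.config.voxel_size
    return [np.arange(scene.stack_shape[i]) * voxel[i] for i in range(3)]


def _ball_image(scene, centre, radius) -> np.ndarray:
    az, ay, ax = _grid_axes(scene)
    d2 = (
        (az - centre[0])[:, None, None] ** 2
        + (ay - centre[1])[None, :, None] ** 2
        + (ax - centre[2])[None, None, :] ** 2
    )
    return (d2 <= radius**2).astype(float)


def _shell_image(scene, centre, r_in, r_out) -> np.ndarray:
    az, ay, ax = _grid_axes(scene)
    d2 = (
        (az - centre[0])[:, None, None] ** 2
        + (ay - centre[1])[None, :, None] ** 2
        + (ax - centre[2])[None, None, :] ** 2
    )
    return ((d2 <= r_out**2) & (d2 > r_in**2)).astype(float)


def _nucleus_image(scene) -> np.ndarray:
    az, ay, ax = _grid_axes(scene)
    shape = scene.stack_shape
    out = np.zeros(shape, dtype=float)
    for i, z in enumerate(az):
        pts = np.stack(
            np.broadcast_arrays(
                np.full((shape[1], shape[2]), z), ay[:, None], ax[None, :]
            ),
            axis=-1,
        )
        out[i] = scene.inside_nucleus(pts)
    return out


def _add_punctum(img, scene, centre, peak_amplitude, sigma_um) -> None:
    """Add a Gaussian punctum with the given peak counts per voxel."""
    voxel = np.asarray(scene.config.voxel_size)
    axes = _grid_axes(scene)
    sigma = np.broadcast_to(np.asarray(sigma_um, dtype=float), (3,))
    sl, prof = [], []
    for i in range(3):
        half = 4.0 * sigma[i]
        i0 = max(0, int(np.floor((centre[i] - half) / voxel[i])))
        i1 = min(img.shape[i] - 1, int(np.ceil((centre[i] + half) / voxel[i])))
        coords = axes[i][i0 : i1 + 1]
        sl.append(slice(i0, i1 + 1))
        prof.append(np.exp(-0.5 * ((coords - centre[i]) / sigma[i]) ** 2))
    img[tuple(sl)] += (
        peak_amplitude
        * prof[0][:, None, None]
        * prof[1][None, :, None]
        * prof[2][None, None, :]
    )


def apply_noise(image: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Apply the scaled-Poisson + Gaussian noise model to one channel."""
    out = np.asarray(image, dtype=float)
    if noise.poisson_scale > 0:
        out = rng.poisson(out * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def render_stack(scene: CellScene, config: SceneConfig | None = None) -> ImageStack:
    """Voxelize a scene into a multi-channel stack (PSF + noise applied).

    Only the channels listed in ``config.channel_amplitudes`` are rendered.
    Bit-identical for identical configs (noise seeded from ``rng_seed``).
    """
    config = config or scene.config
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    R = config.cell_radius
    amps = config.channel_amplitudes
    roles = tuple(r for r in _default_amplitudes() if r in amps)

    channels = []
    for role in roles:
        amp = amps[role]
        if role == "nucleus":
            img = amp * _nucleus_image(scene)
        elif role == "actin":
            img = amp * _shell_image(scene, scene.cell_cm, R - 0.4, R)
            img += 0.1 * amp * _ball_image(scene, scene.cell_cm, R - 0.4)
        elif role == "bead":
            img = (
                amp * _ball_image(scene, scene.bead_cm, config.bead_radius)
                if scene.bead_cm is not None
                else np.zeros(scene.stack_shape)
            )
        elif role == "ova":
            img = (
                amp
                * scene.ova_remaining
                * _ball_image(scene, scene.bead_cm, config.bead_radius)
                if scene.bead_cm is not None
                else np.zeros(scene.stack_shape)
            )
        elif role == "bcr":
            img = amp * _shell_image(scene, scene.cell_cm, R - 0.3, R)
        elif role == "tubulin":
            img = np.zeros(scene.stack_shape)
            _add_punctum(img, scene, scene.mtoc, amp, _PUNCTUM_SIGMA_UM)
        elif role == "exo70":
            img = np.zeros(scene.stack_shape)
            _add_punctum(img, scene, scene.mtoc, amp, config.exo70_sigma_um)
        elif role == "lamp1":
            img = np.zeros(scene.stack_shape)
            for centre in scene.lysosome_centers:
                _add_punctum(img, scene, centre, amp, _PUNCTUM_SIGMA_UM)
        else:
            raise ConfigError(f"unknown channel role {role!r}")

        sigma_vox = [config.psf_sigma[i] / config.voxel_size[i] for i in range(3)]
        img = ndi.gaussian_filter(img, sigma_vox, mode="constant")
        if config.noise.enabled:
            img = apply_noise(img, config.noise, rng)
        channels.append(img)

    return ImageStack(
        np.stack(channels),
        config.voxel_size,
        roles,
        metadata={"rng_seed": config.rng_seed, "synapse_z_um": scene.synapse_z_um},
    )


def make_timecourse(
    config: SceneConfig, times: list[float], extraction_fracs: list[float]
) -> list[tuple[float, CellScene, ImageStack]]:
    """Render an antigen-extraction time course.

    The OVA signal on the bead at time ``t`` is the initial amplitude times
    ``1 - extraction_fracs[t]``; extraction is monotone in this model, so a
    decreasing fraction sequence is rejected.  Geometry is held fixed across
    timepoints; noise differs per timepoint.
    """
    fracs = [float(f) for f in extraction_fracs]
    if len(fracs) != len(times):
        raise ConfigError("extraction_fracs and times must have equal length")
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ConfigError("extraction_fracs must lie in [0, 1]")
    if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
        raise ConfigError("extraction_fracs must be non-decreasing (monotone model)")
    if not config.bead_present:
        raise ConfigError("an extraction time course requires a bead")

    out = []
    amp0 = config.channel_amplitudes.get("ova", _default_amplitudes()["ova"])
    for i, (t, frac) in enumerate(zip(times, fracs)):
        cfg_t = dataclasses.replace(
            config,
            rng_seed=int(config.rng_seed + 10_000 * (i + 1)),
            channel_amplitudes=dict(config.channel_amplitudes),
        )
        scene = make_scene(cfg_t)
        scene.ova_remaining = 1.0 - frac
        scene.bead_signal_per_time = [amp0 * (1.0 - f) for f in fracs]
        out.append((t, scene, render_stack(scene, cfg_t)))
    return out


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def write_scene(scene: CellScene, stack: ImageStack, out_dir: str | Path, name: str) -> None:
    """Write one rendered scene (OME-TIFF) plus its ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out_dir / f"{name}.ome.tif")
    (out_dir / f"{name}.truth.json").write_text(json.dumps(scene.to_dict(), indent=1))


def desk_scale_config(**overrides) -> SceneConfig:
    """A scene configuration sampled coarsely enough for fast validation runs.

    Identical geometry, amplitudes and noise to the defaults, but rendered
    at (0.2, 0.15, 0.15) um voxels so a seeded multi-phantom recovery grid
    completes quickly.
    """
    params = dict(voxel_size=(0.2, 0.15, 0.15))
    params.update(overrides)
    return SceneConfig(**params)
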