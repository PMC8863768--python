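"""Shared phantom fixtures and brute-force oracles.

All fixtures are deterministic (fixed seeds) and session-scoped; renders
use the coarse validation voxel size so the whole suite stays fast.
"""

import numpy as np
import pytest

import synmorph as sm


NOISE_OFF = sm.NoiseModel(poisson_scale=0.0, gaussian_sd=0.0)


@pytest.fixture(scope="session")
def bead_cfg_clean():
    """Noise-free bead-conjugate phantom: polarized MTOC, 0.2-deep groove,
    40% of lysosome intensity inside the 3.5-um ring."""
    return sm.desk_scale_config(
        rng_seed=11,
        mtoc_offset=0.8,
        groove_depth_frac=0.2,
        groove_orientation=0.0,
        lysosome_inside_fraction=0.4,
        noise=NOISE_OFF,
    )


@pytest.fixture(scope="session")
def bead_scene_clean(bead_cfg_clean):
    return sm.make_scene(bead_cfg_clean)


@pytest.fixture(scope="session")
def bead_stack_clean(bead_cfg_clean, bead_scene_clean):
    return sm.render_stack(bead_scene_clean, bead_cfg_clean)


@pytest.fixture(scope="session")
def bead_cfg_noisy():
    """Same geometry at the default noise model."""
    return sm.desk_scale_config(
        rng_seed=12,
        mtoc_offset=0.8,
        groove_depth_frac=0.2,
        groove_orientation=0.0,
        lysosome_inside_fraction=0.4,
    )


@pytest.fixture(scope="session")
def bead_scene_noisy(bead_cfg_noisy):
    return sm.make_scene(bead_cfg_noisy)


@pytest.fixture(scope="session")
def bead_stack_noisy(bead_cfg_noisy, bead_scene_noisy):
    return sm.render_stack(bead_scene_noisy, bead_cfg_noisy)


@pytest.fixture(scope="session")
def dish_cfg():
    return sm.desk_scale_config(
        rng_seed=13,
        bead_present=False,
        groove_orientation=30.0,
        channel_amplitudes={
            "nucleus": 500.0, "actin": 500.0, "lamp1": 500.0, "bcr": 500.0,
        },
        lysosome_mode="synaptic_central",
    )


@pytest.fixture(scope="session")
def dish_scene(dish_cfg):
    return sm.make_scene(dish_cfg)


@pytest.fixture(scope="session")
def dish_stack(dish_cfg, dish_scene):
    return sm.render_stack(dish_scene, dish_cfg)


# ---------------------------------------------------------------------------
# Brute-force oracles over the analytic scene
# ---------------------------------------------------------------------------

def brute_nucleus_volume(scene, n_samples=200_000, seed=0):
    """Monte-Carlo volume of the analytic nucleus body."""
    rng = np.random.default_rng(seed)
    r = 0.32 * scene.config.cell_radius + max(scene.config.lobe_radii)
    lo, hi = scene.cell_cm - r, scene.cell_cm + r
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    frac = scene.inside_nucleus(pts).mean()
    return frac * np.prod(hi - lo)


def brute_groove_depth(scene, step=0.005):
    """Max distance from the apex baseline to the analytic groove surface.

    Scans the groove section plane densely between the two apices: on each
    line parallel to the groove axis, the nuclear surface closest to the
    opening is found, and the depth is the largest gap between that surface
    and the apex baseline.  Returns depth / cell diameter.
    """
    u, w = scene.groove_axis, scene.groove_width_axis
    a1 = scene.lobe_apices[0]
    u_apex = float((a1 - scene.cell_cm) @ u)
    w_apex = abs(float((a1 - scene.cell_cm) @ w))
    uu = np.arange(-u_apex, u_apex + step, step)
    ww = np.arange(-w_apex, w_apex + step, step)
    UU, WW = np.meshgrid(uu, ww, indexing="ij")
    pts = scene.cell_cm + UU[..., None] * u + WW[..., None] * w
    nucleus = scene.inside_nucleus(pts)
    depth = 0.0
    for j in range(nucleus.shape[1]):
        col = nucleus[:, j]
        if col.any():
            top_u = uu[np.flatnonzero(col).max()]
            depth = max(depth, u_apex - top_u)
    return depth / (2.0 * scene.config.cell_radius)


def brute_center(indicator, lo, hi, step=0.05):
    """Grid centroid of an analytic indicator function over a box."""
    axes = [np.arange(lo[i], hi[i] + step, step) for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    mask = indicator(pts)
    return np.array([zz[mask].mean(), yy[mask].mean(), xx[mask].mean()])
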