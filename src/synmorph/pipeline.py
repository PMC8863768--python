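"""Per-cell and per-experiment orchestration, plus the self-validation loop.

``analyze_cell`` composes segmentation and every applicable measure into one
:class:`~synmorph.morphometry.MorphometryRecord`; ``run_experiment`` maps it
over a manifest of stacks and aggregates per-condition summaries (counts,
means, medians, orientation-category percentages — no statistical testing,
the per-cell table is exported for any stats package).  ``validate`` runs
the simulate -> analyze -> recover loop that backs the package's accuracy
claims: phantoms across a grid of ground-truth parameters, full pipeline,
bias/RMSE per measure against the analytic truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imgio import AnalysisConfig, ImageStack, read_stack, write_measurements
from .phantom import desk_scale_config, make_scene, make_timecourse, render_stack
from .segmentation import (
    Mask3D,
    center_of_mass,
    dilate_um,
    fill_holes_2d,
    intersect_masks,
    largest_component,
    mask_volume,
    masked_intensity_cm,
    overlap_fraction_with_tolerance,
    segment_channel,
)
from . import morphometry as mm

logger = logging.getLogger("synmorph")


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _try(record_field: str, cell_id: str):
    """Decorator-ish context: log and swallow per-measure failures."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.info("cell %s: %s unavailable (%s)", cell_id, record_field, exc)
                return True
            return False

    return _Ctx()


def analyze_cell(
    stack: ImageStack,
    config: AnalysisConfig | None = None,
    mode: str = "bead",
    cell_id: str = "cell",
    bead_cm=None,
    synapse_z_index: int | None = None,
    groove_roi: Mask3D | None = None,
    groove_hint=None,
) -> mm.MorphometryRecord:
    """Measure one cell; measures lacking inputs are left missing with a log.

    ``mode`` is ``"bead"`` (bead-conjugate geometry, groove sectioned in xy)
    or ``"dish"`` (coverslip synapse at low z, groove sectioned in zx).
    ``bead_cm`` overrides / replaces the bead-channel centre of mass — real
    acquisitions rarely carry a bead channel.
    """
    config = config or AnalysisConfig()
    if mode not in ("bead", "dish"):
        raise ValueError("mode must be 'bead' or 'dish'")
    if not stack.has_channel("nucleus"):
        raise ValueError("a nucleus channel is required")
    rec = mm.MorphometryRecord(cell_id=cell_id, mode=mode)
    method, params = config.segmentation_method, {}

    def seg(role):
        p = dict(params)
        if method == "fixed":
            p["threshold"] = config.thresholds.get(role)
        return segment_channel(stack, role, method, p)

    nucleus_mask = largest_component(seg("nucleus"))
    rec.nucleus_volume_um3 = mask_volume(nucleus_mask)
    nucleus_cm = center_of_mass(nucleus_mask)

    cell_mask = None
    cell_cm = None
    if stack.has_channel("actin"):
        actin_mask = seg("actin")
        rec.actin_volume_um3 = mask_volume(actin_mask)
        cell_mask = largest_component(fill_holes_2d(actin_mask))
        cell_cm = center_of_mass(cell_mask)
        with _try("perinuclear_actin_volume_um3", cell_id):
            peri = dilate_um(nucleus_mask, config.perinuclear_margin_um)
            rec.perinuclear_actin_volume_um3 = mask_volume(
                intersect_masks(actin_mask, peri)
            )
        with _try("lamin_actin_overlap_frac", cell_id):
            rec.lamin_actin_overlap_frac = overlap_fraction_with_tolerance(
                nucleus_mask, actin_mask, config.erosion_px, config.tolerance_px
            )

    if bead_cm is None and stack.has_channel("bead"):
        with _try("bead position", cell_id):
            bead_cm = masked_intensity_cm(stack, "bead")

    synapse_z = 0 if synapse_z_index is None else int(synapse_z_index)

    # --- groove geometry ---------------------------------------------------
    groove = None
    section_axis = 0 if mode == "bead" else 1
    with _try("groove geometry", cell_id):
        groove = mm.detect_groove(
            nucleus_mask,
            hint_direction=groove_hint,
            section_axis=section_axis,
            manual_roi=groove_roi,
        )
    if groove is not None:
        ref_cm = cell_cm if cell_cm is not None else nucleus_cm
        if mode == "bead" and bead_cm is not None:
            with _try("groove_angle_deg", cell_id):
                rec.groove_angle_deg = mm.groove_orientation_bead(
                    bead_cm, ref_cm, groove.groove_cm
                )
                rec.orientation_category = mm.classify_orientation(
                    rec.groove_angle_deg, config.angle_bin_edges_deg
                )
        if mode == "dish":
            with _try("dish_groove_angle_deg", cell_id):
                plane_z = synapse_z * stack.voxel_size[0]
                rec.dish_groove_angle_deg = mm.groove_orientation_dish(
                    ref_cm, groove.groove_cm, plane_z
                )
                rec.orientation_category = mm.classify_orientation(
                    rec.dish_groove_angle_deg, config.angle_bin_edges_deg
                )
            with _try("lobe_rotation_deg", cell_id):
                folded, raw = mm.lobe_rotation(groove.lobe_apices)
                rec.lobe_rotation_deg, rec.lobe_rotation_raw_deg = folded, raw
        with _try("groove_depth_norm", cell_id):
            diam_mask = cell_mask if cell_mask is not None else nucleus_mask
            rec.groove_depth_norm = mm.groove_depth(groove, diam_mask)
        with _try("groove_area_um2", cell_id):
            rec.groove_area_um2 = mm.groove_area(nucleus_mask, geometry=groove)

    # --- polarity ----------------------------------------------------------
    if bead_cm is not None and cell_cm is not None:
        if stack.has_channel("tubulin"):
            with _try("mtoc_polarity_index", cell_id):
                mtoc = masked_intensity_cm(stack, "tubulin")
                rec.mtoc_polarity_index = mm.polarity_index(
                    mtoc, cell_cm, bead_cm
                ).index
        if stack.has_channel("lamp1"):
            with _try("lamp_polarity_index", cell_id):
                lamp_cm = masked_intensity_cm(stack, "lamp1", "noise_floor")
                rec.lamp_polarity_index = mm.polarity_index(
                    lamp_cm, cell_cm, bead_cm
                ).index
            with _try("lamp_ring_frac", cell_id):
                rec.lamp_ring_frac = mm.lamp_ring_fraction(
                    stack, bead_cm, config.ring_radius_um,
                    cell_mask=segment_channel(stack, "lamp1", "noise_floor"),
                )

    # --- lysosome cluster / z-profiles --------------------------------------
    if stack.has_channel("lamp1"):
        with _try("cluster_position", cell_id):
            lamp_mask = segment_channel(stack, "lamp1", "noise_floor")
            rec.cluster_position = mm.cluster_position(
                lamp_mask, nucleus_mask, config.perinuclear_margin_um
            )
        if mode == "dish":
            with _try("z_profile_lamp", cell_id):
                rec.z_profile_lamp = mm.z_distribution(
                    stack, "lamp1", synapse_z, config.z_slice_count,
                    config.z_slice_step_um, cell_mask,
                ).tolist()
    if stack.has_channel("bcr"):
        if mode == "dish":
            with _try("z_profile_bcr", cell_id):
                rec.z_profile_bcr = mm.z_distribution(
                    stack, "bcr", synapse_z, config.z_slice_count,
                    config.z_slice_step_um, cell_mask,
                ).tolist()
        with _try("bcr_surface_mfi", cell_id):
            region = None
            if cell_mask is not None:
                proj = cell_mask.voxels.any(axis=0)
                region = dilate_um(
                    Mask3D(proj[None], cell_mask.voxel_size), 0.5
                ).voxels[0]
            rec.bcr_surface_mfi = mm.surface_mfi(stack, "bcr", region)

    # --- Exo70 radial profile -----------------------------------------------
    if stack.has_channel("exo70") and stack.has_channel("tubulin"):
        with _try("exo70_profile", cell_id):
            mtoc = masked_intensity_cm(stack, "tubulin")
            radii, mfi = mm.radial_profile(
                stack, "exo70", mtoc, config.exo70_profile_rmax_um
            )
            rec.exo70_profile = {"radius_um": radii.tolist(), "mfi": mfi.tolist()}

    # ova_remaining_pct needs a t=0 baseline; see analyze_timecourse

    # --- nucleus-to-synapse distance (dish) ----------------------------------
    if mode == "dish" and cell_mask is not None:
        with _try("nucleus_to_synapse_cm_dist_um", cell_id):
            bottom = cell_mask.voxels[synapse_z]
            if bottom.any():
                idx = np.argwhere(bottom).mean(axis=0)
                syn_cm = np.array(
                    [synapse_z * stack.voxel_size[0],
                     idx[0] * stack.voxel_size[1],
                     idx[1] * stack.voxel_size[2]]
                )
                rec.nucleus_to_synapse_cm_dist_um = mm.synapse_center_distance(
                    nucleus_cm, syn_cm
                )
    return rec


def analyze_timecourse(
    stacks: list[ImageStack],
    config: AnalysisConfig | None = None,
    mode: str = "bead",
    cell_id: str = "cell",
    bead_cms=None,
) -> list[mm.MorphometryRecord]:
    """Analyze an antigen-extraction time course (first stack is t = 0).

    Each timepoint gets a full :func:`analyze_cell` record, plus
    ``ova_remaining_pct`` computed against the t = 0 OVA signal on the bead.
    """
    config = config or AnalysisConfig()
    if not stacks:
        raise ValueError("missing t=0 stack: the series is empty")
    if bead_cms is None:
        bead_cms = [masked_intensity_cm(s, "bead") for s in stacks]
    records = [
        analyze_cell(s, config, mode=mode, cell_id=f"{cell_id}_t{i}", bead_cm=b)
        for i, (s, b) in enumerate(zip(stacks, bead_cms))
    ]
    extracted = mm.antigen_extraction_pct(stacks, bead_cms, config.ova_area_radius_um)
    for rec, pct in zip(records, extracted):
        rec.ova_remaining_pct = 100.0 - float(pct)
    return records


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> list[dict]:
    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list) or not entries:
        raise ValueError("manifest must be a non-empty list of entries")
    for e in entries:
        if "stack_path" not in e or not e.get("condition"):
            raise ValueError("each manifest entry needs stack_path and condition")
        if e.get("mode", "bead") not in ("bead", "dish"):
            raise ValueError(f"invalid mode in manifest entry: {e}")
    return entries


def run_experiment(
    manifest: list[dict] | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every manifest entry; return (per-cell table, per-condition summary)."""
    config = config or AnalysisConfig()
    if not isinstance(manifest, list):
        manifest = load_manifest(manifest)
    logger.info(
        "run_experiment: %d entries, config %s, synmorph %s",
        len(manifest), _config_hash(config), __version__,
    )
    records, failures = [], []
    for i, entry in enumerate(manifest):
        cell_id = entry.get("cell_id", f"cell{i:03d}")
        try:
            stack = entry.get("_stack") or read_stack(entry["stack_path"])
            if config.channel_role_map:
                from .imgio import apply_role_map

                stack = apply_role_map(stack, config.channel_role_map)
            rec = analyze_cell(
                stack,
                config,
                mode=entry.get("mode", "bead"),
                cell_id=cell_id,
                bead_cm=entry.get("bead_cm"),
            )
            rec.condition = entry["condition"]
            records.append(rec)
        except Exception as exc:  # per-cell failure, keep going
            logger.warning("cell %s failed: %s", cell_id, exc)
            failures.append((cell_id, str(exc)))
    if not records:
        raise RuntimeError(f"all cells failed: {failures}")

    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    summary = _summarize(table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measurements(records, out_dir / "cells.csv")
        summary.to_csv(out_dir / "summary.csv", index=False)
    return table, summary


_CATEGORIES = ("Polarized", "Central", "Antipolarized")


def _summarize(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    numeric = [
        c for c in table.columns
        if table[c].dtype.kind in "fi" and c not in ("cell_id",)
    ]
    for condition, grp in table.groupby("condition", dropna=False):
        row = {"condition": condition, "n": len(grp)}
        for col in numeric:
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_median"] = grp[col].median()
        cats = grp["orientation_category"].dropna()
        for cat in _CATEGORIES:
            row[f"pct_{cat.lower()}"] = (
                100.0 * (cats == cat).sum() / len(cats) if len(cats) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Self-validation (simulate -> analyze -> recover)
# ---------------------------------------------------------------------------

#: recovery tolerances per measure (max |bias + noise| per phantom batch)
VALIDATION_TOLERANCES = {
    "mtoc_polarity_index": 0.05,
    "groove_angle_deg": 2.0,
    "groove_depth_norm": 0.03,
    "lamp_ring_frac": 0.05,
    "extraction_pct": 2.0,
}

_POLARITY_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)
_ORIENTATION_GRID = (0.0, 30.0, 60.0, 90.0, 135.0, 180.0)
_DEPTH_GRID = (0.1, 0.2, 0.3)
_EXTRACTION_FRACS = (0.0, 0.25, 0.60)


def _recover_batch(measure, truths, estimates):
    err = np.asarray(estimates, float) - np.asarray(truths, float)
    return {
        "measure": measure,
        "n": int(err.size),
        "bias": float(err.mean()),
        "rmse": float(np.sqrt((err**2).mean())),
        "max_abs_err": float(np.abs(err).max()),
        "tolerance": VALIDATION_TOLERANCES[measure],
        "ok": bool(np.abs(err).max() <= VALIDATION_TOLERANCES[measure]),
    }


def validate(seed: int = 0, n_per_condition: int = 20, noise=None) -> dict:
    """Simulate phantoms over the ground-truth grid and report recovery.

    Returns a dict with a ``measures`` list (bias/RMSE/max error per
    measure) and an overall ``ok`` flag; intended both as the user-facing
    self-test and as the acceptance harness.
    """
    seed = int(seed) % (2**31 - 1)
    config = AnalysisConfig()
    report = {"seed": seed, "n_per_condition": n_per_condition, "measures": []}

    def scfg(i, **kw):
        base = dict(rng_seed=(seed * 1_000_003 + i) % (2**31 - 1))
        if noise is not None:
            base["noise"] = noise
        base.update(kw)
        return desk_scale_config(**base)

    # polarity-index recovery -------------------------------------------------
    truths, ests = [], []
    for offset in _POLARITY_GRID:
        for rep in range(n_per_condition):
            cfg = scfg(
                hash((0, offset, rep)) % 10**6,
                mtoc_offset=offset,
                channel_amplitudes={"actin": 500.0, "tubulin": 500.0, "bead": 500.0},
                lysosome_count=0,
            )
            scene = make_scene(cfg)
            stack = render_stack(scene, cfg)
            rec = _analyze_phantom(stack, config, needs_nucleus=False)
            truths.append(offset)
            ests.append(rec["mtoc_polarity_index"])
    report["measures"].append(_recover_batch("mtoc_polarity_index", truths, ests))

    # groove-orientation recovery --------------------------------------------
    truths, ests = [], []
    for angle in _ORIENTATION_GRID:
        for rep in range(n_per_condition):
            cfg = scfg(
                hash((1, angle, rep)) % 10**6,
                groove_orientation=angle,
                channel_amplitudes={"nucleus": 500.0, "actin": 500.0, "bead": 500.0},
                lysosome_count=0,
            )
            scene = make_scene(cfg)
            stack = render_stack(scene, cfg)
            rec = analyze_cell(stack, config, mode="bead")
            truths.append(angle)
            ests.append(rec.groove_angle_deg)
    report["measures"].append(_recover_batch("groove_angle_deg", truths, ests))

    # groove-depth recovery ---------------------------------------------------
    truths, ests = [], []
    for frac in _DEPTH_GRID:
        for rep in range(n_per_condition):
            cfg = scfg(
                hash((2, frac, rep)) % 10**6,
                groove_depth_frac=frac,
                channel_amplitudes={"nucleus": 500.0, "actin": 500.0, "bead": 500.0},
                lysosome_count=0,
            )
            scene = make_scene(cfg)
            stack = render_stack(scene, cfg)
            rec = analyze_cell(stack, config, mode="bead")
            truths.append(scene.groove_depth_true)
            ests.append(rec.groove_depth_norm)
    report["measures"].append(_recover_batch("groove_depth_norm", truths, ests))

    # LAMP ring-fraction recovery ----------------------------------------------
    truths, ests = [], []
    for frac in (0.0, 0.4, 1.0):
        for rep in range(n_per_condition):
            cfg = scfg(
                hash((3, frac, rep)) % 10**6,
                lysosome_inside_fraction=frac,
                channel_amplitudes={"lamp1": 500.0, "bead": 500.0},
            )
            scene = make_scene(cfg)
            stack = render_stack(scene, cfg)
            bead = masked_intensity_cm(stack, "bead")
            truths.append(scene.lysosome_ring_fraction_true)
            ests.append(
                mm.lamp_ring_fraction(
                    stack, bead, config.ring_radius_um,
                    cell_mask=segment_channel(stack, "lamp1", "noise_floor"),
                )
            )
    report["measures"].append(_recover_batch("lamp_ring_frac", truths, ests))

    # antigen-extraction recovery ----------------------------------------------
    truths, ests = [], []
    for rep in range(n_per_condition):
        cfg = scfg(
            hash((4, rep)) % 10**6,
            channel_amplitudes={"ova": 500.0, "bead": 500.0},
            lysosome_count=0,
        )
        series = make_timecourse(cfg, [0.0, 30.0, 120.0], list(_EXTRACTION_FRACS))
        stacks = [s for _, _, s in series]
        beads = [scene.bead_cm for _, scene, _ in series]
        pct = mm.antigen_extraction_pct(stacks, beads, config.ova_area_radius_um)
        truths.extend(100.0 * f for f in _EXTRACTION_FRACS)
        ests.extend(pct.tolist())
    report["measures"].append(_recover_batch("extraction_pct", truths, ests))

    report["ok"] = all(m["ok"] for m in report["measures"])
    return report


def _analyze_phantom(stack, config, needs_nucleus=True):
    """Minimal per-phantom polarity analysis when no nucleus channel exists."""
    cell_mask = largest_component(fill_holes_2d(segment_channel(stack, "actin")))
    cell_cm = center_of_mass(cell_mask)
    bead_cm = masked_intensity_cm(stack, "bead")
    mtoc = masked_intensity_cm(stack, "tubulin")
    return {
        "mtoc_polarity_index": mm.polarity_index(mtoc, cell_cm, bead_cm).index,
        "cell_cm": cell_cm,
        "bead_cm": bead_cm,
    }
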