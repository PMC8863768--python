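"""Image stack container, TIFF/OME-TIFF IO, analysis configuration and result tables.

Internal conventions (applied everywhere in the package):

* axis order is always ``channels, z, y, x``, whatever the file layout;
* voxel indices are 0-based and the physical position of voxel ``(i, j, k)``
  is ``(i*dz, j*dy, k*dx)`` micrometres relative to the stack origin
  (voxel-centre coordinates);
* in coverslip ("dish") assays the synaptic plane is the low-z side of the
  stack.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("synmorph")

#: canonical channel roles understood by the analysis
CHANNEL_ROLES = (
    "nucleus", "actin", "tubulin", "lamp1", "ova", "exo70", "bcr", "bead",
)


class ConfigError(ValueError):
    """Invalid analysis or scene configuration."""


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack with physical voxel size.

    Parameters
    ----------
    intensities
        Array of shape ``(channels, z, y, x)``, finite and non-negative.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, strictly positive.
    channel_roles
        One role label per channel (e.g. ``"nucleus"``, ``"lamp1"``).
    metadata
        Free-form dictionary (acquisition notes, scene parameters, ...).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be (channels, z, y, x); got shape "
                f"{self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be three strictly positive um values")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.intensities.shape[0]:
            raise ValueError(
                f"channel count ({self.intensities.shape[0]}) does not match "
                f"role count ({len(self.channel_roles)})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)`` in voxels."""
        return self.intensities.shape[1:]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` intensity grid for one channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not present; available: "
                f"{self.channel_roles}"
            ) from None
        return self.intensities[idx]


# ---------------------------------------------------------------------------
# TIFF / OME-TIFF
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with voxel size and roles."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": list(stack.channel_roles)},
    }
    data = stack.intensities
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def _parse_ome_voxel_size(ome_xml: str) -> dict[str, float]:
    sizes = {}
    for axis in "XYZ":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if m:
            sizes[axis.lower()] = float(m.group(1))
    return sizes


def _parse_ome_channel_names(ome_xml: str) -> list[str]:
    return re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome_xml)


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_roles: tuple[str, ...] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack, normalizing axes to ``(C, Z, Y, X)``.

    ``voxel_size`` and ``channel_roles`` override (or supply, when the file
    carries none) the corresponding metadata.  A file without a voxel size
    and no override is an error; a plain 2D image is accepted as a
    single-slice stack with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        ome_xml = tif.ome_metadata or ""

    # normalize axes to CZYX, inserting missing singleton axes
    order = [a for a in axes if a in "CZYX"]
    if len(order) != data.ndim:
        # squeeze axes tifffile labels differently (S, T, Q...)
        keep = [i for i, a in enumerate(axes) if a in "CZYX"]
        data = np.squeeze(
            data, axis=tuple(i for i in range(data.ndim) if i not in keep)
        )
    for a in "CZYX":
        if a not in order:
            data = data[np.newaxis]
            order.insert(0, a)
    data = np.moveaxis(
        data, [order.index(a) for a in "CZYX"], [0, 1, 2, 3]
    )
    if "Z" not in axes:
        logger.warning("%s is a 2D image; treating as a single-slice stack", path)

    if voxel_size is None:
        sizes = _parse_ome_voxel_size(ome_xml)
        if not {"x", "y"} <= sizes.keys():
            raise ValueError(
                f"{path}: no voxel size in metadata and none supplied"
            )
        voxel_size = (sizes.get("z", sizes["x"]), sizes["y"], sizes["x"])

    if channel_roles is None:
        names = _parse_ome_channel_names(ome_xml)
        if len(names) == data.shape[0]:
            channel_roles = tuple(names)
        else:
            channel_roles = tuple(f"channel{i}" for i in range(data.shape[0]))
    elif len(channel_roles) != data.shape[0]:
        raise ValueError(
            f"{path}: file has {data.shape[0]} channels but "
            f"{len(channel_roles)} roles were configured"
        )

    return ImageStack(data, voxel_size, channel_roles, metadata={"path": str(path)})


def apply_role_map(stack: ImageStack, role_map: dict) -> ImageStack:
    """Relabel channels via a {channel index or current name: role} mapping."""
    roles = list(stack.channel_roles)
    for key, role in role_map.items():
        if isinstance(key, int) or (isinstance(key, str) and key.isdigit()):
            roles[int(key)] = role
        elif key in roles:
            roles[roles.index(key)] = role
        else:
            raise KeyError(f"channel_role_map key {key!r} matches no channel")
    return ImageStack(stack.intensities, stack.voxel_size, tuple(roles), stack.metadata)


def load_roi(path: str | Path, shape=None, voxel_size=None):
    """Load a manual ROI as a boolean (z, y, x) mask.

    Accepts a label-mask TIFF (nonzero = ROI) or a polygon JSON of the form
    ``{"slices": {"<z-index>": [[y, x], ...]}}`` with per-slice polygon
    vertices in pixel coordinates (``shape`` required for polygons).
    Returns ``(mask, voxel_size_or_None)``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.series[0].asarray()
        mask = np.asarray(data) > 0
        if mask.ndim == 2:
            mask = mask[np.newaxis]
        return mask, voxel_size
    from skimage.draw import polygon as _polygon

    doc = json.loads(path.read_text())
    if shape is None:
        raise ValueError("shape is required for polygon ROIs")
    mask = np.zeros(shape, dtype=bool)
    for z_key, verts in doc.get("slices", {}).items():
        verts = np.asarray(verts, dtype=float)
        rr, cc = _polygon(verts[:, 0], verts[:, 1], shape=shape[1:])
        mask[int(z_key), rr, cc] = True
    return mask, voxel_size


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Fixed constants of the measurement procedures.

    Defaults follow the imaging conventions the measures were designed for:
    a 3.5 um lysosome ring around the bead, ten 0.2 um z-slices from the
    synapse, an Exo70 profile out to 2 um, 1 px lamin erosion with a 2 px
    actin dilation tolerance, and orientation bins [0, 45], (45, 135],
    (135, 180] degrees.
    """

    channel_role_map: dict | None = None
    segmentation_method: str = "otsu"
    thresholds: dict = field(default_factory=dict)
    ring_radius_um: float = 3.5
    z_slice_count: int = 10
    z_slice_step_um: float = 0.2
    exo70_profile_rmax_um: float = 2.0
    perinuclear_margin_um: float = 1.0
    ova_area_radius_um: float = 2.5
    angle_bin_edges_deg: tuple[float, ...] = (0.0, 45.0, 135.0, 180.0)
    erosion_px: int = 1
    tolerance_px: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ring_radius_um", "z_slice_step_um", "exo70_profile_rmax_um",
                     "perinuclear_margin_um", "ova_area_radius_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.z_slice_count < 1:
            raise ConfigError("z_slice_count must be >= 1")
        if self.erosion_px < 0 or self.tolerance_px < 0:
            raise ConfigError("erosion_px and tolerance_px must be >= 0")
        edges = tuple(float(e) for e in self.angle_bin_edges_deg)
        if list(edges) != sorted(set(edges)):
            raise ConfigError("angle_bin_edges_deg must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 180.0:
            raise ConfigError("angle_bin_edges_deg must span [0, 180]")
        self.angle_bin_edges_deg = edges
        if self.segmentation_method not in {"otsu", "fixed", "percentile", "half_max"} and not callable(
            self.segmentation_method
        ):
            raise ConfigError(
                f"unknown segmentation_method {self.segmentation_method!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["angle_bin_edges_deg"] = list(self.angle_bin_edges_deg)
        return d


def load_config(path_or_dict) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML/JSON (or a dict).

    Unknown keys are an error rather than silently ignored; an empty file
    yields all defaults.
    """
    if isinstance(path_or_dict, dict):
        doc = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path_or_dict}: config document must be a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**doc)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

#: units written as header comments above the per-cell CSV
_FIELD_UNITS = {
    "cell_id": "",
    "condition": "",
    "mode": "",
    "groove_angle_deg": "deg",
    "orientation_category": "",
    "dish_groove_angle_deg": "deg",
    "lobe_rotation_deg": "deg (folded to [0,90])",
    "lobe_rotation_raw_deg": "deg",
    "groove_depth_norm": "h / cell diameter",
    "groove_area_um2": "um^2",
    "nucleus_volume_um3": "um^3",
    "actin_volume_um3": "um^3",
    "perinuclear_actin_volume_um3": "um^3",
    "lamin_actin_overlap_frac": "fraction of lamin volume",
    "mtoc_polarity_index": "[-1, 1]",
    "lamp_polarity_index": "[-1, 1]",
    "lamp_ring_frac": "fraction of total LAMP1",
    "cluster_position": "inside/outside perinuclear region",
    "ova_remaining_pct": "% of t0 bead fluorescence",
    "bcr_surface_mfi": "counts/px (sum projection)",
    "nucleus_to_synapse_cm_dist_um": "um (xy)",
}

#: profile-valued fields serialized to the JSON sidecar, not the CSV
PROFILE_FIELDS = ("z_profile_lamp", "z_profile_bcr", "exo70_profile")


def _record_dict(record) -> dict:
    if dataclasses.is_dataclass(record):
        return dataclasses.asdict(record)
    return dict(record)


def write_measurements(records, path: str | Path) -> Path:
    """Write per-cell records to a CSV (scalars) plus a JSON sidecar (profiles).

    All records must share the same schema; an empty list produces a
    header-only CSV with the canonical columns.  Returns the sidecar path.
    """
    path = Path(path)
    dicts = [_record_dict(r) for r in records]
    if dicts:
        keys = set(dicts[0])
        for d in dicts[1:]:
            if set(d) != keys:
                diff = sorted(set(d) ^ keys)
                raise ValueError(f"records have differing keys: {diff}")
        columns = [k for k in dicts[0] if k not in PROFILE_FIELDS]
    else:
        columns = [k for k in _FIELD_UNITS]

    header_lines = [
        f"# {col} [{_FIELD_UNITS[col]}]" if _FIELD_UNITS.get(col) else f"# {col}"
        for col in columns
    ]
    scalar_rows = [{k: d[k] for k in columns} for d in dicts]
    frame = pd.DataFrame(scalar_rows, columns=columns)
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        frame.to_csv(fh, index=False, float_format="%.15g")

    sidecar = path.with_suffix(".profiles.json")
    profiles = {}
    for d in dicts:
        entry = {}
        for key in PROFILE_FIELDS:
            value = d.get(key)
            if value is not None:
                entry[key] = _jsonify(value)
        profiles[str(d.get("cell_id"))] = entry
    sidecar.write_text(json.dumps(profiles, indent=1))
    return sidecar


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path, comment="#")


def _jsonify(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value
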