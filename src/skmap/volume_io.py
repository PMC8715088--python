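"""I/O for label volumes, particle tables, synapse metadata and result sets.

Conventions used throughout the package:

* Label volumes are 3D integer grids indexed ``(z, y, x)`` — TIFF page ``k``
  is z index ``k`` and pixel ``(row, col)`` maps to ``(y, x)``. Label 0 is
  background.
* All physical coordinates are nanometres in a single volume frame with the
  origin at the corner of voxel ``(0, 0, 0)``: the *center* of voxel
  ``(k, j, i)`` sits at ``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``.
  Particle CSVs store nm, never pixels, so resampling the image grid never
  rewrites particle files.
* Output tables use "." as decimal separator regardless of locale.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSpacing",
    "LabelVolume",
    "CompartmentMeta",
    "ParticleRecord",
    "SynapseMeta",
    "FormatError",
    "SchemaError",
    "read_label_volume",
    "write_label_volume",
    "read_particle_table",
    "write_particle_table",
    "read_compartment_meta",
    "read_synapse_meta",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


class SchemaError(ValueError):
    """Raised when a table is missing required columns or has bad values."""


#: Default acquisition spacing: 5 nm/pixel in-plane, 20 nm milling step.
DEFAULT_SPACING = (5.0, 5.0, 20.0)


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in nm: ``dx``, ``dy`` in-plane, ``dz`` per section."""

    dx: float = 5.0
    dy: float = 5.0
    dz: float = 20.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"spacing must be strictly positive, got {self}")

    @property
    def is_isotropic(self) -> bool:
        return self.dx == self.dy == self.dz

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx * self.dy * self.dz

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


@dataclass
class LabelVolume:
    """A segmented 3D compartment map with physical spacing.

    ``labels`` is a ``(nz, ny, nx)`` non-negative integer array; 0 is
    background, any other value identifies one compartment.
    """

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"label grid must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label grid must be integer, got {self.labels.dtype}")
        if self.labels.size == 0:
            raise FormatError("empty label volume")
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # (nz, ny, nx)

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) of the volume in nm."""
        nz, ny, nx = self.shape
        s = self.spacing
        return (nx * s.dx, ny * s.dy, nz * s.dz)

    def label_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels))

    def voxel_center_nm(self, k: int, j: int, i: int) -> tuple[float, float, float]:
        """Physical (x, y, z) coordinate of the center of voxel (k, j, i)."""
        s = self.spacing
        return ((i + 0.5) * s.dx, (j + 0.5) * s.dy, (k + 0.5) * s.dz)

    def voxel_index(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        """Voxel (k, j, i) containing physical point (x, y, z) nm.

        Raises ``ValueError`` for points outside the physical bounds.
        """
        ex, ey, ez = self.extent_nm
        if not (0 <= x <= ex and 0 <= y <= ey and 0 <= z <= ez):
            raise ValueError(
                f"point ({x}, {y}, {z}) nm outside volume bounds ({ex}, {ey}, {ez})"
            )
        s = self.spacing
        nz, ny, nx = self.shape
        i = min(int(x / s.dx), nx - 1)
        j = min(int(y / s.dy), ny - 1)
        k = min(int(z / s.dz), nz - 1)
        return (k, j, i)


@dataclass(frozen=True)
class CompartmentMeta:
    """Identity of one traced compartment."""

    label_id: int
    kind: str  # pyramidal_shaft | spine | interneuron_shaft
    parent_id: int | None = None  # spine -> its shaft label

    KINDS = ("pyramidal_shaft", "spine", "interneuron_shaft")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown compartment kind {self.kind!r}")
        if self.kind == "spine" and self.parent_id is None:
            raise ValueError(f"spine label {self.label_id} requires a parent_id")


@dataclass
class ParticleRecord:
    """One immunogold particle in the volume frame (nm)."""

    particle_id: int
    x: float
    y: float
    z: float
    compartment_id: int | None = None
    localization: str | None = None  # "PM" | "intracellular"
    nearest_surface_node: int | None = None

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class SynapseMeta:
    """One synaptic specialization patch painted in the synapse volume."""

    patch_id: int
    type: str  # "asymmetric" (excitatory) | "symmetric" (inhibitory)
    compartment_id: int

    TYPES = ("asymmetric", "symmetric")

    def __post_init__(self) -> None:
        if self.type not in self.TYPES:
            raise ValueError(f"synapse type must be one of {self.TYPES}, got {self.type!r}")


# ---------------------------------------------------------------------------
# label volumes


def read_label_volume(path: str | Path, spacing: VoxelSpacing | Sequence[float]) -> LabelVolume:
    """Read a multi-page TIFF stack as a :class:`LabelVolume`.

    Page ``k`` becomes z index ``k``; pixel ``(row, col)`` maps to ``(y, x)``.
    """
    if not isinstance(spacing, VoxelSpacing):
        spacing = VoxelSpacing(*spacing)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:  # single-page stack
        arr = arr[None, :, :]
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label TIFF must have integer pixel type, got {arr.dtype}")
    return LabelVolume(labels=arr, spacing=spacing)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as a multi-page TIFF (one page per section)."""
    arr = vol.labels
    if arr.max() < 2**8:
        arr = arr.astype(np.uint8)
    elif arr.max() < 2**16:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.uint32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# particle tables

_PARTICLE_REQUIRED = ["particle_id", "x_nm", "y_nm", "z_nm"]
_PARTICLE_OPTIONAL = ["compartment_id", "localization", "nearest_surface_node"]


def read_particle_table(path: str | Path) -> list[ParticleRecord]:
    """Read a particle CSV (columns particle_id, x_nm, y_nm, z_nm [+optional]).

    Row order is preserved. Raises :class:`SchemaError` on a missing
    column, a non-numeric coordinate, or a duplicated particle_id.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PARTICLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for c in ("x_nm", "y_nm", "z_nm"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any() and not df[c].isna().any():
            bad = df.loc[coerced.isna(), c].iloc[0]
            raise SchemaError(f"{path}: non-numeric coordinate {bad!r} in column {c}")
        df[c] = coerced
    if df["particle_id"].duplicated().any():
        dup = df.loc[df["particle_id"].duplicated(), "particle_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate particle_id {dup}")

    records = []
    has_comp = "compartment_id" in df.columns
    has_loc = "localization" in df.columns
    has_node = "nearest_surface_node" in df.columns
    for row in df.itertuples(index=False):
        comp = getattr(row, "compartment_id", None) if has_comp else None
        loc = getattr(row, "localization", None) if has_loc else None
        node = getattr(row, "nearest_surface_node", None) if has_node else None
        records.append(
            ParticleRecord(
                particle_id=int(row.particle_id),
                x=float(row.x_nm),
                y=float(row.y_nm),
                z=float(row.z_nm),
                compartment_id=None if comp is None or pd.isna(comp) else int(comp),
                localization=None if loc is None or pd.isna(loc) else str(loc),
                nearest_surface_node=None if node is None or pd.isna(node) else int(node),
            )
        )
    return records


def particles_to_frame(particles: Iterable[ParticleRecord]) -> pd.DataFrame:
    rows = []
    for p in particles:
        rows.append(
            {
                "particle_id": p.particle_id,
                "x_nm": p.x,
                "y_nm": p.y,
                "z_nm": p.z,
                "compartment_id": p.compartment_id,
                "localization": p.localization,
                "nearest_surface_node": p.nearest_surface_node,
            }
        )
    return pd.DataFrame(
        rows, columns=_PARTICLE_REQUIRED + _PARTICLE_OPTIONAL
    )


def write_particle_table(particles: Iterable[ParticleRecord], path: str | Path) -> None:
    particles_to_frame(particles).to_csv(path, index=False)


def read_compartment_meta(path: str | Path) -> list[CompartmentMeta]:
    """Read compartment metadata CSV (label_id, kind[, parent_id])."""
    df = pd.read_csv(path)
    for c in ("label_id", "kind"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c}")
    if df["label_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate label_id")
    out = []
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent_id", None)
        out.append(
            CompartmentMeta(
                label_id=int(row.label_id),
                kind=str(row.kind),
                parent_id=None if parent is None or pd.isna(parent) else int(parent),
            )
        )
    return out


def read_synapse_meta(path: str | Path) -> list[SynapseMeta]:
    """Read synapse patch metadata CSV (patch_id, type, compartment_id)."""
    df = pd.read_csv(path)
    for c in ("patch_id", "type", "compartment_id"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c}")
    return [
        SynapseMeta(
            patch_id=int(r.patch_id), type=str(r.type), compartment_id=int(r.compartment_id)
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# result sets


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write result tables as CSVs plus a JSON run manifest.

    ``tables`` maps a short name to a DataFrame; each becomes
    ``<name>.csv`` with its existing column order. The manifest records
    inputs, seed and parameters so a run can be reproduced; re-running
    with identical inputs and seed reproduces byte-identical CSVs (the
    manifest differs only in its timestamp field).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    doc = dict(manifest or {})
    doc.setdefault("package", "skmap")
    doc.setdefault("python", platform.python_version())
    doc["tables"] = sorted(f"{name}.csv" for name in tables)
    doc["timestamp"] = datetime.now(timezone.utc).isoformat()
    mp = out / "manifest.json"
    mp.write_text(json.dumps(doc, indent=2, sort_keys=True, default=_jsonify) + "\n")
    written.append(mp)
    return written


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
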