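"""Raster geometry and image/label/field IO.

All voxel arrays in this package are indexed ``[x, y, z]`` (fastest-varying
axis last in memory is irrelevant; the index order is what matters).  Voxel
indices are 0-based and the world coordinate (mm) of voxel ``v`` is
``origin + v * spacing`` — axis aligned, no direction matrix.  Files whose
header carries a non-identity direction matrix are read with the matrix
ignored and a warning logged; oblique acquisitions are out of scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import SimpleITK as sitk
import yaml

logger = logging.getLogger("atlaslink")

__all__ = [
    "ImageGrid",
    "ScalarImage",
    "LabelMap",
    "BinaryMask",
    "FormatError",
    "DimensionalityError",
    "read_image",
    "write_image",
    "read_displacement_field",
    "write_displacement_field",
    "split_labels",
    "read_bspline_json",
    "write_bspline_json",
    "load_config",
    "array_hash",
]


class FormatError(ValueError):
    """File could not be parsed as a supported image format."""


class DimensionalityError(ValueError):
    """Input volume is not three-dimensional."""


@dataclass(frozen=True)
class ImageGrid:
    """Shared raster geometry: shape (voxels), spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise DimensionalityError("grids are three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be > 0, got {self.spacing}")

    # -- coordinate conversions -------------------------------------------
    def world_from_index(self, indices: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices, (N, 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_from_world(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world mm coordinates, (N, 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (mm) from first to last voxel center along each axis."""
        return tuple((s - 1) * sp for s, sp in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ScalarImage:
    """A 3D scalar intensity image (CT-like, arbitrary units) on a grid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class LabelMap:
    """Integer structure labels per voxel; 0 is background."""

    grid: ImageGrid
    labels: np.ndarray
    structure_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label maps hold integer values")
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"label shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.labels < 0):
            raise ValueError("labels are non-negative")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        if not self.structure_names:
            self.structure_names = {v: f"structure_{v}" for v in sorted(present)}
        missing = present - set(self.structure_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")


@dataclass
class BinaryMask:
    """Per-voxel membership of a single structure."""

    grid: ImageGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.inside.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_mm3(self) -> float:
        return float(self.inside.sum()) * self.grid.voxel_volume


# ---------------------------------------------------------------------------
# SimpleITK boundary.  sitk arrays come back [z, y, x]; we transpose so all
# in-memory arrays are [x, y, z] with spacing/origin in matching order.
# ---------------------------------------------------------------------------

_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise FormatError(
            f"unsupported image format for {path!s}; expected one of {_SUFFIXES}"
        )


def _read_sitk(path: str | Path) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all its IO failures in RuntimeError
        raise FormatError(f"could not read {path!s}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path!s} is {img.GetDimension()}-D; only 3-D volumes are supported"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3)):
        logger.warning("%s has a non-identity direction matrix; ignored", path)
    return img


def _grid_of(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def read_image(path: str | Path) -> ScalarImage | LabelMap:
    """Read a NIfTI/MetaImage volume.

    Integer voxel types come back as :class:`LabelMap`, floating point as
    :class:`ScalarImage`.  Label values round-trip exactly.
    """
    img = _read_sitk(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise DimensionalityError(f"{path!s} does not hold a scalar 3-D volume")
    arr = arr.transpose(2, 1, 0)
    grid = _grid_of(img)
    if np.issubdtype(arr.dtype, np.integer):
        return LabelMap(grid, arr.astype(np.int32))
    return ScalarImage(grid, arr.astype(np.float64))


def write_image(obj: ScalarImage | LabelMap | BinaryMask, path: str | Path) -> None:
    """Write a volume as NIfTI/MetaImage; labels/masks as int, scalars float32."""
    path = Path(path)
    _check_path(path)
    if isinstance(obj, ScalarImage):
        arr = obj.values.astype(np.float32)
    elif isinstance(obj, LabelMap):
        arr = obj.labels.astype(np.int32)
    elif isinstance(obj, BinaryMask):
        arr = obj.inside.astype(np.uint8)
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(obj.grid.spacing)
    img.SetOrigin(obj.grid.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_displacement_field(path: str | Path):
    """Read a 3-component vector volume (mm displacements) as a field."""
    from .transforms import DisplacementField

    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise FormatError(f"{path!s} is not a 3-vector field")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x, 3]
    arr = arr.transpose(2, 1, 0, 3)
    return DisplacementField(_grid_of(img), arr.astype(np.float64))


def write_displacement_field(field_obj, path: str | Path) -> None:
    path = Path(path)
    _check_path(path)
    arr = field_obj.vectors.astype(np.float64).transpose(2, 1, 0, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    img.SetSpacing(field_obj.grid.spacing)
    img.SetOrigin(field_obj.grid.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Label splitting
# ---------------------------------------------------------------------------

def split_labels(labels: LabelMap) -> list[tuple[str, BinaryMask]]:
    """One binary mask per distinct nonzero label, in ascending label order."""
    out: list[tuple[str, BinaryMask]] = []
    for value in sorted(int(v) for v in np.unique(labels.labels) if v != 0):
        name = labels.structure_names.get(value, f"structure_{value}")
        out.append((name, BinaryMask(labels.grid, labels.labels == value)))
    return out


# ---------------------------------------------------------------------------
# B-spline transform JSON schema
# ---------------------------------------------------------------------------

def write_bspline_json(transform, path: str | Path) -> None:
    """Serialize a B-spline free-form deformation to the JSON schema."""
    doc = {
        "grid_spacing_mm": list(transform.control_spacing),
        "grid_origin_mm": list(transform.control_origin),
        "coefficient_shape": list(transform.coefficients.shape[:3]),
        "coefficients": transform.coefficients.ravel().tolist(),
        "domain": {
            "shape": list(transform.domain.shape),
            "spacing": list(transform.domain.spacing),
            "origin": list(transform.domain.origin),
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def read_bspline_json(path: str | Path):
    from .transforms import BSplineTransform

    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["coefficient_shape"])
    coeffs = np.asarray(doc["coefficients"], dtype=float).reshape(*shape, 3)
    domain = ImageGrid(**doc["domain"])
    return BSplineTransform(
        control_origin=tuple(doc["grid_origin_mm"]),
        control_spacing=tuple(doc["grid_spacing_mm"]),
        coefficients=coeffs,
        domain=domain,
    )


# ---------------------------------------------------------------------------
# Config and provenance helpers
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline configuration file into a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path!s} must be a mapping")
    return cfg


def array_hash(arr: np.ndarray) -> str:
    """Short content hash used to log pipeline inputs for traceability."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]
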