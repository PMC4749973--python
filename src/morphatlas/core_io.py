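"""Domain types and file I/O shared by every stage of the pipeline.

Axis convention (global): volumes are indexed ``data[x, y, z]`` with 0-based
indices; the world coordinate of voxel ``(i, j, k)`` is ``(i*sx, j*sy, k*sz)``
in micrometres.  On disk, a multi-page TIFF stores one XY page per z-plane
with the page's *row* index mapping to x and its *column* index to y.

Spacing travels in a JSON blob inside the TIFF ImageDescription tag; files
written by other software fall back to the X/Y resolution tags and finally to
1 µm isotropic (with a logged warning).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_DESCRIPTION_FORMAT = "morphatlas-volume"
_OTS_FORMAT = "morphatlas-ots"
_OTS_VERSION = 1

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths (µm), got {spacing!r}")
    return spacing


@dataclass
class IntensityVolume:
    """3D scalar image with anisotropic voxel spacing in µm."""

    data: np.ndarray
    spacing: Spacing
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all extents >= 1, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("intensity volumes must be non-negative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class LabelVolume:
    """Binary segmentation mask with voxel spacing in µm."""

    data: np.ndarray
    spacing: Spacing
    object_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"label must be 3D with all extents >= 1, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"label volume must be strictly binary, found values {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def is_valid_segmentation(self) -> bool:
        """A usable segmentation has at least one foreground voxel."""
        return self.voxel_count > 0


Volume = Union[IntensityVolume, LabelVolume]


@dataclass
class LandmarkSet:
    """Named 3D points in µm tied to one object.

    Names are unique within a set; corresponding sets across objects share an
    identical name list (validated where sets are compared, not here).
    """

    object_id: str
    points: list[tuple[str, float, float, float]]

    def __post_init__(self) -> None:
        names = [p[0] for p in self.points]
        if len(set(names)) != len(names):
            raise ValueError("landmark names must be unique within a set")
        self.points = [(str(n), float(x), float(y), float(z)) for n, x, y, z in self.points]

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.points]

    def coords(self) -> np.ndarray:
        """(L, 3) array of coordinates in µm, in point order."""
        return np.array([[x, y, z] for _, x, y, z in self.points], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.points), 3):
            raise ValueError("coordinate array shape does not match point count")
        pts = [(n, *c) for (n, *_), c in zip(self.points, coords)]
        return LandmarkSet(self.object_id, pts)

    def __len__(self) -> int:
        return len(self.points)


class OrthoPlane(Enum):
    """An orthogonal section plane; projection runs along the remaining axis."""

    YZ = "YZ"
    ZX = "ZX"
    XY = "XY"

    @property
    def projection_axis(self) -> int:
        return {"YZ": 0, "ZX": 1, "XY": 2}[self.value]

    @property
    def inplane_axes(self) -> tuple[int, int]:
        """Volume axes forming the plane, in the order named (u, v)."""
        return {"YZ": (1, 2), "ZX": (2, 0), "XY": (0, 1)}[self.value]


DEFAULT_PLANE_ORDER = (OrthoPlane.YZ, OrthoPlane.ZX, OrthoPlane.XY)


@dataclass
class TransformRecord:
    """One per-plane step of an orthogonal transform sequence."""

    iteration_index: int
    plane: OrthoPlane
    transform: "BSplineGrid2D"  # noqa: F821 - defined in elastic2d

    def __post_init__(self) -> None:
        if self.iteration_index < 1:
            raise ValueError("iteration_index must be >= 1")


@dataclass
class OrthogonalTransformSequence:
    """Ordered, replayable record of per-plane 2D transforms for one object."""

    object_id: str
    volume_shape: tuple[int, int, int]
    spacing: Spacing
    records: list[TransformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.spacing = _validate_spacing(self.spacing)
        for rec in self.records:
            a, b = rec.plane.inplane_axes
            expect = (self.volume_shape[a], self.volume_shape[b])
            if tuple(rec.transform.image_extent) != expect:
                raise ValueError(
                    f"record transform extent {rec.transform.image_extent} inconsistent "
                    f"with plane {rec.plane.value} extent {expect}"
                )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (one XY page per z index)."""
    path = Path(path)
    kind = "label" if isinstance(vol, LabelVolume) else "intensity"
    meta = {
        "format": _DESCRIPTION_FORMAT,
        "version": 1,
        "kind": kind,
        "spacing_um": list(vol.spacing),
    }
    if kind == "label":
        meta["object_id"] = vol.object_id
    else:
        meta["channel_name"] = vol.channel_name
    pages = np.moveaxis(vol.data, 2, 0)  # (z, x, y): page rows = x, cols = y
    sx, sy = vol.spacing[0], vol.spacing[1]
    tifffile.imwrite(
        path,
        pages,
        description=json.dumps(meta),
        resolution=(1.0 / sy, 1.0 / sx),  # TIFF x-resolution is along columns (our y)
        photometric="minisblack",
    )


def _spacing_from_tiff(tif: tifffile.TiffFile) -> Spacing | None:
    page = tif.pages[0]
    desc = page.description
    if desc:
        try:
            meta = json.loads(desc)
            if meta.get("format") == _DESCRIPTION_FORMAT:
                return _validate_spacing(meta["spacing_um"])
        except (ValueError, KeyError):
            pass
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sy = xres[1] / xres[0]  # columns = y under our page layout
        sx = yres[1] / yres[0]
        # resolution 1:1 is the writer default, i.e. no real information
        if sx > 0 and sy > 0 and not (sx == 1.0 and sy == 1.0):
            return (float(sx), float(sy), 1.0)
    except (KeyError, ZeroDivisionError):
        pass
    return None


def read_volume(
    path: str | Path,
    as_label: bool = False,
    spacing: Sequence[float] | None = None,
) -> Volume:
    """Read a multi-page TIFF as an IntensityVolume (or LabelVolume on request).

    ``spacing`` overrides anything found in the file; absent both, 1 µm
    isotropic is assumed with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta_spacing = _spacing_from_tiff(tif)
        desc_meta = {}
        if tif.pages[0].description:
            try:
                desc_meta = json.loads(tif.pages[0].description)
            except ValueError:
                desc_meta = {}
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page 2D TIFF, got ndim={pages.ndim}")
    data = np.moveaxis(pages, 0, 2)  # (x, y, z)

    if spacing is not None:
        sp = _validate_spacing(spacing)
    elif meta_spacing is not None:
        sp = meta_spacing
    else:
        logger.warning("%s: no spacing metadata found; assuming 1 µm isotropic", path)
        sp = (1.0, 1.0, 1.0)

    if as_label or desc_meta.get("kind") == "label":
        vals = np.unique(data)
        if len(vals) > 2 or (len(vals) == 2 and vals[0] != 0):
            raise ValueError(f"{path}: non-binary data cannot be read as a label (values {vals[:10]})")
        return LabelVolume((data > 0).astype(np.uint8), sp, object_id=str(desc_meta.get("object_id", path.stem)))
    return IntensityVolume(data, sp, channel_name=str(desc_meta.get("channel_name", path.stem)))


# ---------------------------------------------------------------------------
# landmark I/O
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path, object_id: str | None = None) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV (coordinates in µm), preserving row order."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
            raise ValueError(f"{path}: expected header 'name,x,y,z', got {header!r}")
        points = []
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            name = row[0].strip()
            try:
                x, y, z = (float(v) for v in row[1:4])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: non-numeric coordinates in row {row!r}") from exc
            points.append((name, x, y, z))
    if not points:
        raise ValueError(f"{path}: landmark file contains no points")
    return LandmarkSet(object_id if object_id is not None else path.stem, points)


def write_landmarks(pts: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, x, y, z in pts.points:
            writer.writerow([name, repr(x), repr(y), repr(z)])


# ---------------------------------------------------------------------------
# OTS I/O (self-defined versioned JSON container)
# ---------------------------------------------------------------------------

def write_ots(ots: OrthogonalTransformSequence, path: str | Path) -> None:
    from .elastic2d import BSplineGrid2D  # noqa: F401 - type check via attribute access

    doc = {
        "format": _OTS_FORMAT,
        "version": _OTS_VERSION,
        "object_id": ots.object_id,
        "volume_shape": list(ots.volume_shape),
        "spacing_um": list(ots.spacing),
        "records": [
            {
                "iteration_index": rec.iteration_index,
                "plane": rec.plane.value,
                "image_extent": list(rec.transform.image_extent),
                "pixel_spacing_um": list(rec.transform.pixel_spacing),
                "coeff_shape": list(rec.transform.coeffs.shape),
                "coeffs": rec.transform.coeffs.ravel().tolist(),
            }
            for rec in ots.records
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_ots(path: str | Path) -> OrthogonalTransformSequence:
    from .elastic2d import BSplineGrid2D

    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != _OTS_FORMAT:
        raise ValueError(f"{path}: not an OTS container")
    if doc.get("version") != _OTS_VERSION:
        raise ValueError(f"{path}: unsupported OTS version {doc.get('version')!r}")
    records = []
    for rec in doc["records"]:
        shape = tuple(rec["coeff_shape"])
        coeffs = np.asarray(rec["coeffs"], dtype=float)
        if coeffs.size != int(np.prod(shape)):
            raise ValueError(f"{path}: corrupted coefficient block")
        transform = BSplineGrid2D(
            coeffs=coeffs.reshape(shape),
            image_extent=tuple(rec["image_extent"]),
            pixel_spacing=tuple(rec["pixel_spacing_um"]),
        )
        records.append(TransformRecord(rec["iteration_index"], OrthoPlane(rec["plane"]), transform))
    return OrthogonalTransformSequence(
        object_id=doc["object_id"],
        volume_shape=tuple(doc["volume_shape"]),
        spacing=tuple(doc["spacing_um"]),
        records=records,
    )
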