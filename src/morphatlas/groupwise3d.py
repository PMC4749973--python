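"""Group-wise 3D registration via sequential orthogonal 2D registrations.

Each iteration sweeps the configured plane order.  Per plane, every object is
projected (mean along the plane's projection axis, rescaled to [0, 1]); each
unordered object pair is registered elastically in 2D; each object receives
the mean of its per-peer transform lattices (plus its own identity lattice
when configured); and that mean transform is applied to every slice of the
object's stack along the projection axis.  The per-object transform history
is the orthogonal transform sequence (OTS), replayable onto any volume or
landmark set sharing the original geometry.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import (
    DEFAULT_PLANE_ORDER,
    IntensityVolume,
    LabelVolume,
    LandmarkSet,
    OrthoPlane,
    OrthogonalTransformSequence,
    TransformRecord,
    Volume,
)
from .elastic2d import (
    BSplineGrid2D,
    ElasticParams,
    InversionError,
    invert_point,
    mean_transforms,
    register_pair,
    register_pair_both,
    warp_coords,
    zero_transform,
)

logger = logging.getLogger(__name__)


@dataclass
class GroupwiseConfig:
    plane_order: tuple[OrthoPlane, ...] = DEFAULT_PLANE_ORDER
    iterations: int = 6
    include_self: bool = True
    elastic: ElasticParams = field(default_factory=ElasticParams)
    label_interp: str = "linear"  # linear + 0.5 threshold, or nearest

    def __post_init__(self) -> None:
        if sorted(p.value for p in self.plane_order) != ["XY", "YZ", "ZX"]:
            raise ValueError("plane_order must be a permutation of YZ, ZX, XY")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.label_interp not in ("linear", "nearest"):
            raise ValueError("label_interp must be 'linear' or 'nearest'")


@dataclass
class IterationMetrics:
    iteration: int
    overlap_pct: float
    landmark_dist_um: float | None = None


@dataclass
class RegistrationReport:
    iterations: list[IterationMetrics] = field(default_factory=list)
    pairs_per_plane: int = 0

    def to_rows(self) -> list[dict]:
        return [
            {
                "iteration": m.iteration,
                "overlap_pct": m.overlap_pct,
                "landmark_dist_um": "" if m.landmark_dist_um is None else m.landmark_dist_um,
            }
            for m in self.iterations
        ]

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["iteration", "overlap_pct", "landmark_dist_um"])
            writer.writeheader()
            writer.writerows(self.to_rows())


def average_projection(vol: Volume | np.ndarray, plane: OrthoPlane) -> np.ndarray:
    """Mean projection along the plane's projection axis, rescaled to [0, 1]."""
    data = vol if isinstance(vol, np.ndarray) else vol.data
    img = np.asarray(data, dtype=float).mean(axis=plane.projection_axis)
    a, b = plane.inplane_axes
    if a > b:  # remaining axes come out in index order; plane may name them swapped
        img = img.T
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def _plane_spacing(spacing, plane: OrthoPlane) -> tuple[float, float]:
    a, b = plane.inplane_axes
    return (spacing[a], spacing[b])


def warp_volume_inplane(
    data: np.ndarray, plane: OrthoPlane, t: BSplineGrid2D, interp: str = "linear", binarize: bool = False
) -> np.ndarray:
    """Apply a 2D transform to every slice of ``data`` along the plane's axis."""
    a, b = plane.inplane_axes
    view = np.moveaxis(data, plane.projection_axis, 0)
    swapped = a > b
    if swapped:
        view = np.swapaxes(view, 1, 2)
    if view.shape[1:] != t.image_extent:
        raise ValueError(f"slice extent {view.shape[1:]} != transform extent {t.image_extent}")
    coords = warp_coords(t)
    order = {"nearest": 0, "linear": 1}[interp]
    out = np.empty_like(view, dtype=float)
    for s in range(view.shape[0]):
        out[s] = ndimage.map_coordinates(view[s].astype(float), coords, order=order, mode="constant", cval=0.0)
    if binarize:
        out = (out > 0.5).astype(np.uint8)
    if swapped:
        out = np.swapaxes(out, 1, 2)
    return np.moveaxis(out, 0, plane.projection_axis)


def register_plane_groupwise(
    projections: list[np.ndarray],
    cfg: GroupwiseConfig | None = None,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> list[BSplineGrid2D]:
    """One group-wise 2D step: a mean transform per object.

    For object i each peer j contributes the transform estimated with
    ``source = projection_i, target = projection_j`` — in the backward
    convention this lattice maps output coordinates back into i's frame, so
    warping i's stack through it pulls i toward j.  Averaging over peers
    (plus i's own identity lattice when ``include_self``) pulls i toward the
    group mean.
    """
    cfg = cfg or GroupwiseConfig()
    n = len(projections)
    if n < 1:
        raise ValueError("need at least one projection")
    extent = projections[0].shape
    for p in projections[1:]:
        if p.shape != extent:
            raise ValueError("projection extents differ")
    ident = zero_transform(extent, cfg.elastic.final_grid_intervals, pixel_spacing)
    if n == 1:
        return [ident]

    pair: dict[tuple[int, int], BSplineGrid2D] = {}
    bidirectional = cfg.elastic.consistency_weight > 0
    for i in range(n):
        for j in range(i + 1, n):
            if bidirectional:
                t_ij, t_ji = register_pair_both(projections[i], projections[j], cfg.elastic, pixel_spacing)
            else:
                t_ij = register_pair(projections[i], projections[j], cfg.elastic, pixel_spacing)
                t_ji = register_pair(projections[j], projections[i], cfg.elastic, pixel_spacing)
            pair[(i, j)] = t_ij  # source i, target j: moves object i toward j
            pair[(j, i)] = t_ji

    means = []
    for i in range(n):
        lattices = [pair[(i, j)] for j in range(n) if j != i]
        if cfg.include_self:
            lattices.append(ident)
        means.append(mean_transforms(lattices))
    return means


def register_groupwise(
    labels: list[LabelVolume],
    cfg: GroupwiseConfig | None = None,
    landmarks: list[LandmarkSet] | None = None,
) -> tuple[list[OrthogonalTransformSequence], list[LabelVolume], RegistrationReport]:
    """Iteratively align a group of label volumes toward consensus morphology."""
    from .evaluation import mean_landmark_distance, volumetric_overlap

    cfg = cfg or GroupwiseConfig()
    if not labels:
        raise ValueError("need at least one label volume")
    shape = labels[0].shape
    spacing = labels[0].spacing
    for lab in labels[1:]:
        if lab.shape != shape or lab.spacing != spacing:
            raise ValueError("all objects must share extents and spacing")
    if landmarks is not None and len(landmarks) != len(labels):
        raise ValueError("one landmark set per object required")

    n = len(labels)
    current = [lab.data.astype(np.uint8).copy() for lab in labels]
    cur_marks = copy.deepcopy(landmarks) if landmarks is not None else None
    ots = [
        OrthogonalTransformSequence(object_id=lab.object_id or f"object_{i}", volume_shape=shape, spacing=spacing)
        for i, lab in enumerate(labels)
    ]
    report = RegistrationReport(pairs_per_plane=n * (n - 1) // 2)

    for it in range(1, cfg.iterations + 1):
        for plane in cfg.plane_order:
            px_spacing = _plane_spacing(spacing, plane)
            projections = [average_projection(vol, plane) for vol in current]
            means = register_plane_groupwise(projections, cfg, px_spacing)
            for i, t in enumerate(means):
                current[i] = warp_volume_inplane(
                    current[i], plane, t, interp=cfg.label_interp, binarize=cfg.label_interp == "linear"
                ).astype(np.uint8)
                ots[i].records.append(TransformRecord(it, plane, t))
                if cur_marks is not None:
                    cur_marks[i] = _move_points_inplane(cur_marks[i], plane, t, spacing)
        overlap = volumetric_overlap(
            [LabelVolume(vol, spacing, object_id=o.object_id) for vol, o in zip(current, ots)]
        ).mean_pct
        dist = mean_landmark_distance(cur_marks).mean_um if cur_marks is not None and n >= 2 else None
        report.iterations.append(IterationMetrics(it, overlap, dist))
        logger.info("iteration %d: overlap %.2f%%%s", it, overlap, f", landmarks {dist:.2f} µm" if dist else "")

    registered = [
        LabelVolume(vol, spacing, object_id=o.object_id) for vol, o in zip(current, ots)
    ]
    return ots, registered, report


def _move_points_inplane(pts: LandmarkSet, plane: OrthoPlane, t: BSplineGrid2D, spacing) -> LandmarkSet:
    """Move landmark content forward through one record (numerical inversion)."""
    a, b = plane.inplane_axes
    coords = pts.coords()
    moved = coords.copy()
    for r, c in enumerate(coords):
        q = np.array([c[a] / spacing[a], c[b] / spacing[b]])
        try:
            p = invert_point(t, q, tol=1e-3, max_iter=50)
        except InversionError as exc:
            logger.warning("landmark %s: %s (using best iterate)", pts.points[r][0], exc)
            p = q - displacement_best_effort(t, q)
        moved[r, a] = p[0] * spacing[a]
        moved[r, b] = p[1] * spacing[b]
    return pts.with_coords(moved)


def displacement_best_effort(t: BSplineGrid2D, q: np.ndarray) -> np.ndarray:
    from .elastic2d import _displacement

    nu, nv = t.image_extent
    clamped = np.clip(np.atleast_2d(q), 0.0, [nu - 1, nv - 1])
    return _displacement(t, clamped)[0]


def apply_ots_volume(vol: Volume, ots: OrthogonalTransformSequence, interp: str = "linear") -> Volume:
    """Replay an OTS onto a volume sharing the original geometry."""
    if vol.shape != tuple(ots.volume_shape):
        raise ValueError(f"volume shape {vol.shape} != OTS shape {ots.volume_shape}")
    is_label = isinstance(vol, LabelVolume)
    data = vol.data.astype(np.uint8 if is_label else float).copy()
    for rec in ots.records:
        data = warp_volume_inplane(
            data, rec.plane, rec.transform, interp=interp, binarize=is_label and interp == "linear"
        )
        if is_label:
            data = data.astype(np.uint8) if interp == "linear" else (data > 0.5).astype(np.uint8)
    if is_label:
        return LabelVolume(data, vol.spacing, object_id=vol.object_id)
    return IntensityVolume(np.maximum(data, 0.0), vol.spacing, channel_name=vol.channel_name)


def apply_ots_points(pts: LandmarkSet, ots: OrthogonalTransformSequence) -> LandmarkSet:
    """Replay an OTS onto landmarks so they move with the image content."""
    out = pts
    for rec in ots.records:
        out = _move_points_inplane(out, rec.plane, rec.transform, ots.spacing)
    return out
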