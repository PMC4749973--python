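"""Seeded generators for every fixture the tests and experiments need.

Each generator returns its own ground truth beside the data and is fully
deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core_io import IntensityVolume, LabelVolume, LandmarkSet, Spacing
from .signal_mapping import NucleusRecord, SignalVolume

logger = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Two-lobed superellipsoid blob with deterministic landmarks."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: Spacing = (2.0, 2.0, 2.0)
    radii_frac: tuple[float, float, float] = (0.26, 0.30, 0.28)  # of the half-extent
    lobe_offset_frac: float = 0.28  # lobe centre offset along x, of the half-extent
    superellipse_power: float = 2.4
    smooth_sigma_vox: float = 1.5
    landmark_count: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_count < 1:
            raise ValueError("landmark_count must be >= 1")


@dataclass
class DeformSpec:
    """Seeded smooth random deformation from a coarse displacement lattice."""

    lattice_shape: tuple[int, int, int] = (4, 4, 4)
    amplitude_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lattice_shape) < 2:
            raise ValueError("lattice must have at least 2 nodes per axis")
        if self.amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")


def make_phantom(spec: PhantomSpec | None = None) -> tuple[LabelVolume, LandmarkSet]:
    """Smooth binary blob plus landmarks at surface extremes and centroid."""
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    half = np.array([nx, ny, nz]) / 2.0
    centre = half - 0.5
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    radii = np.array(spec.radii_frac) * np.array([nx, ny, nz])
    p = spec.superellipse_power

    def lobe(cx):
        r = (
            (np.abs(x - cx) / radii[0]) ** p
            + (np.abs(y - centre[1]) / radii[1]) ** p
            + (np.abs(z - centre[2]) / radii[2]) ** p
        )
        return r <= 1.0

    off = spec.lobe_offset_frac * nx / 2.0
    blob = lobe(centre[0] - off) | lobe(centre[0] + off)
    smooth = ndimage.gaussian_filter(blob.astype(float), sigma=spec.smooth_sigma_vox)
    mask = smooth > 0.5
    fg = np.argwhere(mask)
    if fg.size == 0:
        raise ValueError("phantom spec produced an empty blob")
    margin = 4
    if fg.min() < margin or np.any(fg.max(axis=0) >= np.array(spec.shape) - margin):
        raise ValueError("blob too close to the grid boundary (need >= 4 voxel margin)")

    landmarks_vox = []
    for axis in range(3):
        for pick in (np.argmin, np.argmax):
            idx = pick(fg[:, axis])
            # deterministic tie-break: lexicographically smallest voxel at that extreme
            extreme = fg[fg[:, axis] == fg[idx, axis]]
            order = np.lexsort((extreme[:, 2], extreme[:, 1], extreme[:, 0]))
            landmarks_vox.append(extreme[order[0]].astype(float))
    landmarks_vox.append(fg.mean(axis=0))  # centroid, 7th landmark
    rng = np.random.default_rng(spec.seed)
    while len(landmarks_vox) < spec.landmark_count:
        cand = fg[rng.integers(0, len(fg))]
        landmarks_vox.append(cand.astype(float))
    landmarks_vox = landmarks_vox[: spec.landmark_count]

    spacing = np.asarray(spec.spacing, dtype=float)
    pts = [
        (f"L{i + 1}", *(np.asarray(v) * spacing))
        for i, v in enumerate(landmarks_vox)
    ]
    label = LabelVolume(mask.astype(np.uint8), spec.spacing, object_id=f"phantom_seed{spec.seed}")
    return label, LandmarkSet(label.object_id, pts)


def _lattice_field(shape, spacing, spec: DeformSpec):
    """Dense µm displacement field interpolated from a seeded coarse lattice."""
    extent_um = [(n - 1) * s for n, s in zip(shape, spacing)]
    node_spacing = min(e / (m - 1) for e, m in zip(extent_um, spec.lattice_shape))
    if spec.amplitude_um >= node_spacing / 2.0:
        raise ValueError(
            f"amplitude {spec.amplitude_um} µm violates the diffeomorphic bound "
            f"(must be < half the lattice node spacing {node_spacing:.1f} µm)"
        )
    rng = np.random.default_rng(spec.seed)
    nodes = rng.uniform(-spec.amplitude_um, spec.amplitude_um, size=(*spec.lattice_shape, 3))
    nodes[0, :, :, 0] = nodes[-1, :, :, 0] = 0.0  # pin boundary-normal motion
    axes = [np.linspace(0.0, extent_um[a], spec.lattice_shape[a]) for a in range(3)]
    method = "cubic" if min(spec.lattice_shape) >= 4 else "linear"
    interp = RegularGridInterpolator(axes, nodes, method=method, bounds_error=False, fill_value=None)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    pts_um = np.stack([g.ravel() for g in grids], axis=1)
    return interp(pts_um).reshape(*shape, 3), interp


def deform_phantom(
    label: LabelVolume, pts: LandmarkSet, spec: DeformSpec
) -> tuple[LabelVolume, LandmarkSet]:
    """Warp a phantom by a seeded smooth field, moving landmarks with content.

    The field d (µm) acts in the backward convention: out(q) = in(q + d(q)).
    Landmarks therefore move to q solving q + d(q) = p (fixed-point iteration).
    """
    shape = label.shape
    spacing = np.asarray(label.spacing, dtype=float)
    if spec.amplitude_um == 0:
        return LabelVolume(label.data.copy(), label.spacing, object_id=label.object_id), LandmarkSet(
            pts.object_id, list(pts.points)
        )
    field_um, interp = _lattice_field(shape, spacing, spec)
    coords = np.stack(
        [
            np.arange(shape[a], dtype=float)[
                tuple(slice(None) if k == a else None for k in range(3))
            ]
            + field_um[..., a] / spacing[a]
            for a in range(3)
        ]
    )
    warped = ndimage.map_coordinates(label.data.astype(float), coords, order=1, mode="constant", cval=0.0)
    out_label = LabelVolume((warped > 0.5).astype(np.uint8), label.spacing, object_id=f"{label.object_id}_def{spec.seed}")

    moved = pts.coords().copy()
    for r, p_um in enumerate(pts.coords()):
        q = p_um.copy()
        for _ in range(60):
            step = p_um - interp(q[None])[0] - q
            q = q + step
            if np.linalg.norm(step) < 1e-6:
                break
        moved[r] = q
    out_pts = LandmarkSet(out_label.object_id, [(n, *c) for (n, *_), c in zip(pts.points, moved)])
    return out_label, out_pts


def make_benchmark_triplet(
    seed: int = 1,
    n_objects: int = 3,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: Spacing = (2.0, 2.0, 2.0),
    amplitude_um: float = 32.0,
    lattice_shape: tuple[int, int, int] = (2, 2, 2),
) -> tuple[list[LabelVolume], list[LandmarkSet], LabelVolume, LandmarkSet]:
    """Deformed copies of one blob carrying the same seven material landmarks.

    The deformations are smooth global trilinear fields (coarse 2x2x2 lattice),
    emulating gross manual deformation of a single source object; amplitude is
    calibrated so a three-object triplet at the default settings starts from a
    mean pairwise landmark distance in the tens of µm.
    Returns (deformed labels, deformed landmark sets, base label, base landmarks).
    """
    base, marks = make_phantom(PhantomSpec(shape=shape, spacing=spacing, seed=seed))
    labels, sets = [], []
    for i in range(n_objects):
        lab, pts = deform_phantom(
            base, marks,
            DeformSpec(lattice_shape=lattice_shape, amplitude_um=amplitude_um, seed=1000 * seed + i),
        )
        labels.append(lab)
        sets.append(pts)
    return labels, sets, base, marks


def make_nuclei_scene(
    label: LabelVolume,
    n_nuclei: int,
    ratio_field,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius_um: tuple[float, float] = (2.0, 3.0),
    base_intensity: float = 100.0,
    background: float = 2.0,
    max_tries: int = 20000,
) -> tuple[IntensityVolume, IntensityVolume, list[NucleusRecord]]:
    """Two-channel scene of non-overlapping spherical nuclei inside the label.

    ``ratio_field(x, y, z)`` (µm) gives the true protein/counterstain ratio at
    a nucleus centroid; ``noise_sd`` is the relative Gaussian noise level.
    """
    if not label.is_valid_segmentation():
        raise ValueError("label is empty")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(label.spacing, dtype=float)
    shape = label.shape
    fg = np.argwhere(label.data > 0)
    centres, radii = [], []
    tries = 0
    while len(centres) < n_nuclei and tries < max_tries:
        tries += 1
        cand_vox = fg[rng.integers(0, len(fg))] + rng.uniform(-0.5, 0.5, 3)
        cand_um = cand_vox * spacing
        r = rng.uniform(*radius_um)
        if any(np.linalg.norm(cand_um - c) < r + rc + 1.0 for c, rc in zip(centres, radii)):
            continue
        # nucleus must fit inside the label: check centre voxel and radius margin
        lo = np.floor((cand_um - r) / spacing).astype(int)
        hi = np.ceil((cand_um + r) / spacing).astype(int) + 1
        if np.any(lo < 0) or np.any(hi > shape):
            continue
        centres.append(cand_um)
        radii.append(r)
    if len(centres) < n_nuclei:
        raise ValueError(f"could not place {n_nuclei} non-overlapping nuclei (achieved {len(centres)})")

    counter = np.full(shape, float(background))
    protein = np.full(shape, float(background))
    grids_um = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    truth: list[NucleusRecord] = []
    for k, (c_um, r) in enumerate(zip(centres, radii), start=1):
        dist2 = sum((g - c) ** 2 for g, c in zip(grids_um, c_um))
        inside = dist2 <= r ** 2
        if not inside.any():
            inside = tuple(np.round(c_um / spacing).astype(int))
            counter[inside] = base_intensity
            inside_mask = np.zeros(shape, bool)
            inside_mask[inside] = True
            inside = inside_mask
        c_level = base_intensity * rng.uniform(0.8, 1.2)
        ratio = float(ratio_field(*c_um))
        counter[inside] = c_level
        protein[inside] = c_level * ratio
        truth.append(
            NucleusRecord(k, tuple(c_um), int(inside.sum()), c_level * ratio, c_level, ratio)
        )
    if noise_sd > 0:
        counter = counter * (1.0 + rng.normal(0.0, noise_sd, shape))
        protein = protein * (1.0 + rng.normal(0.0, noise_sd, shape))
    counter = np.clip(counter, 0.0, None)
    protein = np.clip(protein, 0.0, None)
    return (
        IntensityVolume(protein, label.spacing, channel_name="protein"),
        IntensityVolume(counter, label.spacing, channel_name="counterstain"),
        truth,
    )


def make_zoned_signal(
    consensus: LabelVolume,
    k_zones: int,
    channel_means: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> tuple[list[SignalVolume], np.ndarray]:
    """Axis-slab zone partition of the label with planted per-channel means.

    Returns one SignalVolume per channel and the full-resolution truth zone
    map (ints 1..k inside the label, 0 outside).
    """
    channel_means = np.atleast_2d(np.asarray(channel_means, dtype=float))
    if channel_means.shape[0] != k_zones:
        raise ValueError("channel_means must have one row per zone")
    mask = consensus.data.astype(bool)
    if not mask.any():
        raise ValueError("empty consensus")
    xs = np.argwhere(mask)[:, 0]
    # slab boundaries at foreground x-quantiles for roughly equal zone sizes
    edges = np.quantile(xs, np.linspace(0, 1, k_zones + 1))
    if len(np.unique(np.floor(edges))) < k_zones + 1:
        raise ValueError(f"cannot realize {k_zones} contiguous x-slabs on this mask")
    x_idx = np.arange(consensus.shape[0])
    zone_of_x = np.clip(np.searchsorted(edges[1:-1], x_idx, side="right") + 1, 1, k_zones)
    truth = np.where(mask, zone_of_x[:, None, None], 0).astype(np.int32)

    rng = np.random.default_rng(seed)
    names = channel_names or [f"channel_{c}" for c in range(channel_means.shape[1])]
    volumes = []
    for c in range(channel_means.shape[1]):
        data = np.zeros(consensus.shape, dtype=float)
        for z in range(1, k_zones + 1):
            data[truth == z] = channel_means[z - 1, c]
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, consensus.shape)
        data = np.clip(data, 0.0, None)
        data[~mask] = 0.0
        volumes.append(SignalVolume(data, consensus.spacing, valid_mask=mask.copy(), channel_name=names[c]))
    return volumes, truth
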