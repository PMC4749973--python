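"""Nuclear signal quantification, projection onto morphology, replicate merging.

Per-nucleus signal is the mean protein intensity over the nucleus's voxels
divided by the mean counterstain intensity over the same voxels.  Projection
tiles the volume with target cubes and assigns each the mean nuclear signal
found inside a larger concentric sample cube (defaults 12 µm / 36 µm), then
crops to the segmentation label.  Merging normalises each registered
replicate to its own background scalar before voxel-wise averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core_io import IntensityVolume, LabelVolume, Spacing

logger = logging.getLogger(__name__)


@dataclass
class NucleusRecord:
    nucleus_id: int
    centroid_um: tuple[float, float, float]
    voxel_count: int
    mean_protein: float
    mean_counterstain: float
    ratio: float


@dataclass
class SignalVolume:
    """Per-voxel relative signal; 0 means no nucleus / no assigned value."""

    data: np.ndarray
    spacing: Spacing
    valid_mask: np.ndarray = None
    normalised: bool = False
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("signal volume must be 3D")
        if self.data.min() < 0:
            raise ValueError("signal values must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = self.data > 0
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.data.shape:
            raise ValueError("valid_mask shape mismatch")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ProjectionParams:
    target_edge: float = 12.0  # µm
    sample_edge: float = 36.0  # µm

    def __post_init__(self) -> None:
        if not (self.sample_edge >= self.target_edge > 0):
            raise ValueError("require sample_edge >= target_edge > 0")


def segment_nuclei(
    counterstain: IntensityVolume,
    smooth_sigma_um: float = 1.0,
    min_volume_um3: float = 50.0,
) -> np.ndarray:
    """Smooth -> Otsu threshold -> 3D connected components -> size filter.

    Returns an int32 volume with components labelled 1..K.
    """
    sigma_vox = [smooth_sigma_um / s for s in counterstain.spacing]
    smoothed = ndimage.gaussian_filter(counterstain.data.astype(float), sigma=sigma_vox)
    if smoothed.max() == smoothed.min():
        raise ValueError("counterstain is constant; no nuclei found")
    mask = smoothed > threshold_otsu(smoothed)
    labelled, k = ndimage.label(mask)
    if k == 0:
        raise ValueError("no nuclei found above threshold")
    voxel_um3 = float(np.prod(counterstain.spacing))
    min_vox = min_volume_um3 / voxel_um3
    counts = np.bincount(labelled.ravel())
    keep = np.flatnonzero(counts >= min_vox)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise ValueError("no nuclei survive the size filter")
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[labelled]


def extract_nuclear_signal(
    protein: IntensityVolume,
    counterstain: IntensityVolume,
    nuclei: np.ndarray,
) -> tuple[list[NucleusRecord], SignalVolume]:
    """Per-nucleus protein/counterstain ratio, painted back as a SignalVolume."""
    if protein.shape != counterstain.shape or protein.shape != nuclei.shape:
        raise ValueError("channel and nucleus map shapes must match")
    ids = np.unique(nuclei)
    ids = ids[ids != 0]
    records: list[NucleusRecord] = []
    ratio_lut = np.zeros(int(nuclei.max()) + 1 if ids.size else 1, dtype=float)
    spacing = counterstain.spacing
    if ids.size:
        mean_p = ndimage.mean(protein.data.astype(float), labels=nuclei, index=ids)
        mean_c = ndimage.mean(counterstain.data.astype(float), labels=nuclei, index=ids)
        counts = ndimage.sum_labels(np.ones_like(nuclei), labels=nuclei, index=ids)
        centroids = ndimage.center_of_mass(np.ones_like(nuclei, dtype=float), labels=nuclei, index=ids)
        for nid, mp, mc, cnt, com in zip(ids, mean_p, mean_c, counts, centroids):
            if mc <= 0:
                logger.warning("nucleus %d excluded: zero counterstain mean", nid)
                continue
            centroid = tuple(float(c) * s for c, s in zip(com, spacing))
            ratio = float(mp / mc)
            records.append(NucleusRecord(int(nid), centroid, int(cnt), float(mp), float(mc), ratio))
            ratio_lut[int(nid)] = ratio
    data = ratio_lut[nuclei]
    return records, SignalVolume(data, spacing, valid_mask=nuclei > 0, channel_name=protein.channel_name)


def _box_sum(cumsum: np.ndarray, lo: tuple[int, int, int], hi: tuple[int, int, int]) -> float:
    """Sum over the half-open box [lo, hi) using a zero-padded 3D cumsum."""
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    c = cumsum
    return (
        c[x1, y1, z1] - c[x0, y1, z1] - c[x1, y0, z1] - c[x1, y1, z0]
        + c[x0, y0, z1] + c[x0, y1, z0] + c[x1, y0, z0] - c[x0, y0, z0]
    )


def project_to_label(
    signal: SignalVolume,
    label: LabelVolume,
    params: ProjectionParams | None = None,
    aggregation: str = "voxel",
    records: list[NucleusRecord] | None = None,
) -> SignalVolume:
    """Local-averaging projection of nuclear signal onto the segmented shape.

    ``aggregation='voxel'`` (default) averages over all nuclear voxels in each
    sample cube, weighting large nuclei more; ``'centroid'`` averages one
    ratio per nucleus placed at its centroid (requires ``records``).
    """
    params = params or ProjectionParams()
    if signal.shape != label.shape:
        raise ValueError("signal and label shapes must match")
    if not label.is_valid_segmentation():
        raise ValueError("label is empty")
    if aggregation not in ("voxel", "centroid"):
        raise ValueError("aggregation must be 'voxel' or 'centroid'")
    if aggregation == "centroid":
        if not records:
            raise ValueError("centroid aggregation requires nucleus records")
        data = np.zeros(signal.shape)
        mask = np.zeros(signal.shape, dtype=bool)
        for rec in records:
            vox = tuple(
                int(np.clip(round(c / s), 0, n - 1))
                for c, s, n in zip(rec.centroid_um, signal.spacing, signal.shape)
            )
            data[vox] = rec.ratio
            mask[vox] = True
        signal = SignalVolume(data, signal.spacing, valid_mask=mask, channel_name=signal.channel_name)
    spacing = signal.spacing
    shape = signal.shape
    tile_vox = [max(1, round(params.target_edge / s)) for s in spacing]
    half_sample_um = params.sample_edge / 2.0

    valid = signal.valid_mask.astype(float)
    sig_cs = np.pad(signal.data * signal.valid_mask, ((1, 0),) * 3).cumsum(0).cumsum(1).cumsum(2)
    val_cs = np.pad(valid, ((1, 0),) * 3).cumsum(0).cumsum(1).cumsum(2)

    out = np.zeros(shape, dtype=float)
    out_valid = np.zeros(shape, dtype=bool)
    starts = [range(0, shape[a], tile_vox[a]) for a in range(3)]
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                lo_t = (x0, y0, z0)
                hi_t = tuple(min(lo_t[a] + tile_vox[a], shape[a]) for a in range(3))
                centre_um = [(lo_t[a] + hi_t[a]) / 2.0 * spacing[a] for a in range(3)]
                lo_s = tuple(
                    max(0, int(np.floor((centre_um[a] - half_sample_um) / spacing[a]))) for a in range(3)
                )
                hi_s = tuple(
                    min(shape[a], int(np.ceil((centre_um[a] + half_sample_um) / spacing[a]))) for a in range(3)
                )
                count = _box_sum(val_cs, lo_s, hi_s)
                if count > 0:
                    value = _box_sum(sig_cs, lo_s, hi_s) / count
                    sl = tuple(slice(lo_t[a], hi_t[a]) for a in range(3))
                    out[sl] = value
                    out_valid[sl] = True
    inside = label.data.astype(bool)
    out[~inside] = 0.0
    out_valid &= inside
    return SignalVolume(out, spacing, valid_mask=out_valid, channel_name=signal.channel_name)


def merge_registered(
    replicates: list[SignalVolume],
    background: str | float = "median",
) -> SignalVolume:
    """Background-normalise each replicate, then voxel-wise mean where valid.

    ``background`` is 'median' (default) or 'mean' of each replicate's
    positive in-mask values, or an explicit positive scalar applied to all.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    shape = replicates[0].shape
    spacing = replicates[0].spacing
    for r in replicates[1:]:
        if r.shape != shape:
            raise ValueError("replicate shapes differ")
    total = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=np.int32)
    for r in replicates:
        vals = r.data[r.valid_mask & (r.data > 0)]
        if isinstance(background, str):
            if vals.size == 0:
                raise ValueError("replicate has no positive in-mask values")
            scalar = float(np.median(vals)) if background == "median" else float(np.mean(vals))
        else:
            scalar = float(background)
            if scalar <= 0:
                raise ValueError("background scalar must be positive")
        total += np.where(r.valid_mask, r.data / scalar, 0.0)
        count += r.valid_mask
    merged = np.divide(total, count, out=np.zeros(shape), where=count > 0)
    return SignalVolume(
        merged, spacing, valid_mask=count > 0, normalised=True,
        channel_name=replicates[0].channel_name,
    )
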