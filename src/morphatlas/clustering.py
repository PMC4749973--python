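"""Supervoxel sampling, hierarchical zone clustering and zone reconstruction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import LabelVolume
from .signal_mapping import SignalVolume

logger = logging.getLogger(__name__)


@dataclass
class SamplingParams:
    edge: float = 18.0  # supervoxel edge length, µm
    min_coverage: float = 0.5  # fraction of supervoxel inside the consensus mask

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("edge must be positive")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass
class ClusterTable:
    """Supervoxel-by-channel feature matrix plus grid bookkeeping."""

    grid_indices: np.ndarray  # (R, 3) int cells on the sampling grid
    centroids_um: np.ndarray  # (R, 3) world centroids
    values: np.ndarray  # (R, C) mean normalised signal (NaN = missing)
    channels: list[str]
    grid_origin: tuple[int, int, int]  # voxel offset of grid cell (0,0,0)
    cell_vox: tuple[int, int, int]  # voxels per cell along each axis
    volume_shape: tuple[int, int, int]

    @property
    def n_rows(self) -> int:
        return self.grid_indices.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        for k, ax in enumerate("xyz"):
            df.insert(k, f"grid_{ax}", self.grid_indices[:, k])
        for k, ax in enumerate("xyz"):
            df.insert(3 + k, f"centroid_{ax}_um", self.centroids_um[:, k])
        return df

    def write_tsv(self, path) -> None:
        """Tab-delimited export in the rows-as-items layout Cluster 3.0 reads."""
        with open(path, "w") as fh:
            fh.write("UID\tNAME\tGWEIGHT\t" + "\t".join(self.channels) + "\n")
            fh.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in self.channels) + "\n")
            for r in range(self.n_rows):
                uid = "SV_{}_{}_{}".format(*self.grid_indices[r])
                vals = "\t".join("" if np.isnan(v) else repr(float(v)) for v in self.values[r])
                fh.write(f"{uid}\t{uid}\t1\t{vals}\n")


@dataclass
class Dendrogram:
    """Agglomerative merge list over the kept (complete-case) table rows."""

    merges: np.ndarray  # scipy linkage matrix (m-1, 4): node_a, node_b, height, size
    leaf_count: int
    row_indices: np.ndarray  # table-row index of each leaf

    def write_newick(self, path) -> None:
        n = self.leaf_count

        def render(node: int) -> str:
            if node < n:
                return f"R{int(self.row_indices[node])}"
            a, b, h, _ = self.merges[node - n]
            return f"({render(int(a))},{render(int(b))}):{h:.6g}"

        with open(path, "w") as fh:
            fh.write(render(n + len(self.merges) - 1) + ";\n")


@dataclass
class ZoneAssignment:
    """Zone id per table row; 0 marks rows dropped before clustering."""

    row_zones: np.ndarray  # (R,) ints in 0..k
    k: int


def sample_for_clustering(
    channels: list[SignalVolume],
    consensus: LabelVolume,
    params: SamplingParams | None = None,
) -> ClusterTable:
    """Average each channel over an isotropic cubic grid covering the consensus."""
    params = params or SamplingParams()
    if not channels:
        raise ValueError("need at least one channel")
    shape = consensus.shape
    spacing = consensus.spacing
    for ch in channels:
        if ch.shape != shape:
            raise ValueError("channel shape differs from consensus")
    mask = consensus.data.astype(bool)
    if not mask.any():
        raise ValueError("empty consensus mask")
    fg = np.argwhere(mask)
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1  # bounding box, half-open
    cell_vox = tuple(max(1, round(params.edge / s)) for s in spacing)

    rows, cents, vals = [], [], []
    n_cells = [int(np.ceil((hi[a] - lo[a]) / cell_vox[a])) for a in range(3)]
    for ix in range(n_cells[0]):
        for iy in range(n_cells[1]):
            for iz in range(n_cells[2]):
                idx = (ix, iy, iz)
                lo_c = [lo[a] + idx[a] * cell_vox[a] for a in range(3)]
                hi_c = [min(shape[a], lo_c[a] + cell_vox[a]) for a in range(3)]
                sl = tuple(slice(lo_c[a], hi_c[a]) for a in range(3))
                cell_mask = mask[sl]
                # coverage relative to the nominal cell volume, so border cells
                # only partially inside the mask are penalized
                coverage = cell_mask.sum() / float(np.prod(cell_vox))
                if coverage < params.min_coverage:
                    continue
                row_vals = []
                for ch in channels:
                    valid = ch.valid_mask[sl] & cell_mask
                    row_vals.append(float(ch.data[sl][valid].mean()) if valid.any() else np.nan)
                if np.all(np.isnan(row_vals)):
                    continue
                rows.append(idx)
                cents.append([(lo_c[a] + hi_c[a]) / 2.0 * spacing[a] for a in range(3)])
                vals.append(row_vals)
    if not rows:
        raise ValueError("no supervoxels meet the coverage threshold")
    names = [ch.channel_name or f"channel_{i}" for i, ch in enumerate(channels)]
    return ClusterTable(
        grid_indices=np.asarray(rows, dtype=int),
        centroids_um=np.asarray(cents, dtype=float),
        values=np.asarray(vals, dtype=float),
        channels=names,
        grid_origin=tuple(int(v) for v in lo),
        cell_vox=cell_vox,
        volume_shape=shape,
    )


def hierarchical_cluster(
    table: ClusterTable, metric: str = "euclidean", method: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of complete-case rows (deterministic: scipy
    linkage with its documented tie-breaking on the condensed distance order)."""
    if method not in ("single", "average", "complete"):
        raise ValueError("supported linkages: single, average, complete")
    complete_rows = ~np.isnan(table.values).any(axis=1)
    if complete_rows.sum() < table.n_rows:
        logger.warning("dropping %d rows with missing channels", table.n_rows - complete_rows.sum())
    kept = np.flatnonzero(complete_rows)
    if kept.size < 2:
        raise ValueError("need at least two complete rows to cluster")
    merges = linkage(table.values[kept], method=method, metric=metric)
    return Dendrogram(merges=merges, leaf_count=kept.size, row_indices=kept)


def cut_zones(dend: Dendrogram, k: int) -> ZoneAssignment:
    """Cut into exactly k zones, ids 1..k by decreasing size (ties: smallest row)."""
    if not 1 <= k <= dend.leaf_count:
        raise ValueError(f"k must be in [1, {dend.leaf_count}]")
    flat = fcluster(dend.merges, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        # maxclust can undershoot on exact height ties; fall back to an explicit cut
        heights = sorted(dend.merges[:, 2])
        for h in heights:
            flat = fcluster(dend.merges, t=h - 1e-12, criterion="distance")
            if len(np.unique(flat)) <= k:
                break
    labels = np.unique(flat)
    order = sorted(
        labels,
        key=lambda lab: (-(flat == lab).sum(), int(dend.row_indices[flat == lab].min())),
    )
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    n_total = int(dend.row_indices.max()) + 1 if dend.row_indices.size else 0
    row_zones = np.zeros(n_total, dtype=int)
    for leaf, lab in zip(dend.row_indices, flat):
        row_zones[leaf] = remap[lab]
    return ZoneAssignment(row_zones=row_zones, k=k)


def zone_profiles(
    table: ClusterTable,
    zones: ZoneAssignment,
    extra: ClusterTable | None = None,
) -> pd.DataFrame:
    """Mean signal per zone per channel; held-out channels join by grid index."""
    values = table.values
    channels = list(table.channels)
    if extra is not None:
        index = {tuple(g): r for r, g in enumerate(extra.grid_indices)}
        aligned = np.full((table.n_rows, extra.values.shape[1]), np.nan)
        for r, g in enumerate(table.grid_indices):
            er = index.get(tuple(g))
            if er is None:
                raise ValueError("extra table grid does not cover the clustered rows")
            aligned[r] = extra.values[er]
        values = np.hstack([values, aligned])
        channels = channels + list(extra.channels)
    zone_ids = np.arange(1, zones.k + 1)
    rows = []
    zl = zones.row_zones[: table.n_rows]
    for z in zone_ids:
        sel = zl == z
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(values[sel], axis=0) if sel.any() else np.full(len(channels), np.nan))
    return pd.DataFrame(rows, index=pd.Index(zone_ids, name="zone"), columns=channels)


def reconstruct_zone_volume(
    zones: ZoneAssignment, table: ClusterTable, consensus: LabelVolume
) -> IntZoneMap:
    """Paint each consensus voxel with its supervoxel's zone id (0 if dropped)."""
    if consensus.shape != table.volume_shape:
        raise ValueError("consensus shape differs from the sampled volume")
    out = np.zeros(consensus.shape, dtype=np.int32)
    lo = table.grid_origin
    cv = table.cell_vox
    for r in range(table.n_rows):
        z = int(zones.row_zones[r]) if r < len(zones.row_zones) else 0
        if z == 0:
            continue
        g = table.grid_indices[r]
        sl = tuple(
            slice(lo[a] + g[a] * cv[a], min(consensus.shape[a], lo[a] + (g[a] + 1) * cv[a]))
            for a in range(3)
        )
        out[sl] = z
    out[~consensus.data.astype(bool)] = 0
    return IntZoneMap(out, consensus.spacing)


@dataclass
class IntZoneMap:
    """Integer zone map at full resolution (0 = outside / dropped)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def shape(self):
        return self.data.shape
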