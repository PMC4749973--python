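"""Alignment-quality metrics: volumetric overlap vs consensus, landmark distances."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core_io import LabelVolume, LandmarkSet

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    per_object: list[float]  # percent, one per object, vs the group consensus
    mean_pct: float
    sd_pct: float

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["object_index", "overlap_pct"])
            for i, v in enumerate(self.per_object):
                writer.writerow([i, v])
            writer.writerow(["mean", self.mean_pct])
            writer.writerow(["sd", self.sd_pct])


@dataclass
class LandmarkDistanceResult:
    per_pair: list[tuple[str, int, int, float]]  # (landmark, object_a, object_b, distance µm)
    mean_um: float
    sd_um: float
    pair_count: int

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["landmark", "object_a", "object_b", "distance_um"])
            for row in self.per_pair:
                writer.writerow(row)
            writer.writerow(["mean", "", "", self.mean_um])
            writer.writerow(["sd", "", "", self.sd_um])


def _check_group(labels: list[LabelVolume]) -> None:
    if not labels:
        raise ValueError("need at least one label volume")
    shape = labels[0].shape
    spacing = labels[0].spacing
    for lab in labels[1:]:
        if lab.shape != shape:
            raise ValueError("label shapes differ")
        if lab.spacing != spacing:
            raise ValueError("label spacings differ")


def consensus_mask(labels: list[LabelVolume]) -> LabelVolume:
    """Majority-vote mask: foreground where >= ceil(n/2) objects agree."""
    _check_group(labels)
    n = len(labels)
    counts = np.zeros(labels[0].shape, dtype=np.int32)
    for lab in labels:
        counts += lab.data
    threshold = int(np.ceil(n / 2))
    return LabelVolume((counts >= threshold).astype(np.uint8), labels[0].spacing, object_id="consensus")


def volumetric_overlap(labels: list[LabelVolume], method: str = "jaccard") -> OverlapResult:
    """Per-object overlap (%) against the majority consensus (Jaccard default,
    Dice behind a flag); mean and sd over objects."""
    _check_group(labels)
    if method not in ("jaccard", "dice"):
        raise ValueError("method must be 'jaccard' or 'dice'")
    cons = consensus_mask(labels).data.astype(bool)
    if not cons.any():
        logger.warning("empty consensus mask; overlaps defined as 0")
        per = [0.0] * len(labels)
    else:
        per = []
        for lab in labels:
            obj = lab.data.astype(bool)
            inter = np.logical_and(obj, cons).sum()
            if method == "jaccard":
                denom = np.logical_or(obj, cons).sum()
            else:
                denom = (obj.sum() + cons.sum()) / 2.0
            per.append(100.0 * inter / denom if denom > 0 else 0.0)
    arr = np.asarray(per, dtype=float)
    return OverlapResult(per_object=list(arr), mean_pct=float(arr.mean()), sd_pct=float(arr.std()))


def mean_landmark_distance(sets: list[LandmarkSet]) -> LandmarkDistanceResult:
    """Euclidean distance (µm) of every landmark over every unordered object pair."""
    if len(sets) < 2:
        raise ValueError("need at least two landmark sets")
    names = sets[0].names
    for s in sets[1:]:
        if s.names != names:
            raise ValueError(f"landmark name lists differ: {names} vs {s.names}")
    coords = [s.coords() for s in sets]
    per_pair = []
    for a, b in combinations(range(len(sets)), 2):
        dists = np.linalg.norm(coords[a] - coords[b], axis=1)
        for name, d in zip(names, dists):
            per_pair.append((name, a, b, float(d)))
    values = np.array([row[3] for row in per_pair])
    return LandmarkDistanceResult(
        per_pair=per_pair,
        mean_um=float(values.mean()),
        sd_um=float(values.std()),
        pair_count=len(per_pair),
    )
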