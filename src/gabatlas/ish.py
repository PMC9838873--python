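"""ISH slice-stack processing: interpolation, binarization, region intensities.

In situ hybridization experiments image one 25 um coronal section every
200 um, so a gene's expression arrives as a sparse stack of aligned 2D
images.  The stack is assembled into a 3D volume by linear intensity
interpolation between neighbouring slices, binarized with Otsu's threshold
(all-or-none filter: a pixel is 1 iff it shows a cell reacting to the
marker), and summarized per brain region as the mean binarized intensity
over the region's subtree — the predictor of the marker-positive cell
density.

Planes outside the sampled rostro-caudal range are left at 0 and flagged
uncovered; uncovered voxels are excluded from region means rather than
counted as 0 (ISH experiments do not cover the whole brain).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .atlas import AnnotationVolume, RegionHierarchy, ScalarVolume

__all__ = [
    "SliceStack",
    "RegionIntensity",
    "interpolate_stack",
    "otsu_threshold",
    "binarize",
    "combine_experiments",
    "region_mean_intensity",
]


@dataclass
class SliceStack:
    """Aligned 2D sections of one ISH experiment.

    ``positions`` are plane indices along axis 0 of the reference volume,
    strictly increasing; every slice shares the reference cross-section
    shape.
    """

    slices: list[np.ndarray]
    positions: list[int]
    marker: str = "GAD67"

    def __post_init__(self):
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        self.positions = [int(p) for p in self.positions]
        if not self.slices:
            raise ValueError("a slice stack needs at least one slice")
        if len(self.slices) != len(self.positions):
            raise ValueError("slices and positions differ in length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("slice positions must be strictly increasing")
        shape = self.slices[0].shape
        if any(s.shape != shape for s in self.slices):
            raise ValueError("all slices must share one shape")
        if any(np.any(s < 0) for s in self.slices):
            raise ValueError("slice intensities must be non-negative")

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def save(self, directory) -> None:
        """Write slices as TIFFs plus a sidecar CSV of plane positions."""
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "positions.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filename", "position", "marker"])
            for i, (sl, pos) in enumerate(zip(self.slices, self.positions)):
                fname = f"slice_{i:04d}.tif"
                tifffile.imwrite(directory / fname, sl.astype(np.float32))
                w.writerow([fname, pos, self.marker])

    @classmethod
    def load(cls, directory) -> "SliceStack":
        import tifffile

        directory = Path(directory)
        slices, positions, marker = [], [], "GAD67"
        with open(directory / "positions.csv") as fh:
            for row in csv.DictReader(fh):
                slices.append(tifffile.imread(directory / row["filename"]))
                positions.append(int(row["position"]))
                marker = row.get("marker", marker)
        return cls(slices, positions, marker)


@dataclass
class RegionIntensity:
    """Per-region mean binarized intensity with voxel support counts.

    ``mean``/``support`` are hierarchical (over the region's subtree);
    ``own_mean``/``own_support`` cover only voxels labeled exactly with the
    region id (the parent's directly-labeled part).
    """

    mean: dict[int, float]
    support: dict[int, int]
    own_mean: dict[int, float] = field(default_factory=dict)
    own_support: dict[int, int] = field(default_factory=dict)
    marker: str = "GAD67"

    def covered(self, rid: int) -> bool:
        return self.support.get(rid, 0) > 0

    def __getitem__(self, rid: int) -> float:
        if not self.covered(rid):
            raise KeyError(f"region {rid} has no covered voxels (mean undefined)")
        return self.mean[rid]


def interpolate_stack(
    stack: SliceStack,
    reference_shape: tuple[int, int, int],
    voxel_size=(25.0, 25.0, 25.0),
    tag: str = "ish-filtered",
) -> tuple[ScalarVolume, np.ndarray]:
    """Assemble a 3D volume from a slice stack by per-pixel linear interpolation.

    Returns ``(volume, covered)`` where ``covered`` is a boolean mask over
    axis-0 planes; planes outside [first, last] slice position are 0 and
    uncovered.
    """
    n0 = reference_shape[0]
    if stack.slice_shape != tuple(reference_shape[1:]):
        raise ValueError(
            f"slice shape {stack.slice_shape} does not match reference "
            f"cross-section {tuple(reference_shape[1:])}"
        )
    if stack.positions[0] < 0 or stack.positions[-1] >= n0:
        raise ValueError("slice positions fall outside the reference extent")
    grid = np.zeros(reference_shape, dtype=float)
    covered = np.zeros(n0, dtype=bool)
    pos = np.asarray(stack.positions)
    data = np.stack(stack.slices)
    for z in range(pos[0], pos[-1] + 1):
        j = int(np.searchsorted(pos, z, side="right")) - 1
        if pos[j] == z:
            grid[z] = data[j]
        else:
            w = (z - pos[j]) / (pos[j + 1] - pos[j])
            grid[z] = (1.0 - w) * data[j] + w * data[j + 1]
        covered[z] = True
    return ScalarVolume(grid, voxel_size=voxel_size, tag=tag), covered


def _coverage_volume(covered, shape) -> np.ndarray:
    covered = np.asarray(covered)
    if covered.shape == shape:
        return covered.astype(bool)
    if covered.ndim == 1 and covered.size == shape[0]:
        return np.broadcast_to(covered[:, None, None], shape).astype(bool)
    raise ValueError("coverage mask must be per-plane or full-volume")


def otsu_threshold(
    volume: ScalarVolume | np.ndarray,
    annotation: AnnotationVolume | None = None,
    covered=None,
    nbins: int = 256,
) -> float:
    """Otsu threshold over in-brain, covered voxels.

    Maximizes the between-class variance over a 256-bin histogram of the
    selected voxel values.  Restricting to in-brain voxels (annotation != 0)
    keeps the abundant outside-brain zeros from dominating the histogram.
    """
    grid = volume.grid if isinstance(volume, ScalarVolume) else np.asarray(volume, dtype=float)
    mask = np.ones(grid.shape, dtype=bool)
    if annotation is not None:
        mask &= annotation.grid != 0
    if covered is not None:
        mask &= _coverage_volume(covered, grid.shape)
    values = grid[mask]
    if values.size == 0 or np.ptp(values) == 0:
        raise ValueError("no threshold separates classes: constant input")
    return float(threshold_otsu(values, nbins=nbins))


def binarize(volume: ScalarVolume, threshold: float) -> ScalarVolume:
    """All-or-none filter: 1 iff strictly above the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return ScalarVolume(
        (volume.grid > threshold).astype(float),
        voxel_size=volume.voxel_size,
        tag="binarized",
    )


def combine_experiments(
    volumes: Sequence[ScalarVolume],
    coverages: Sequence[np.ndarray] | None = None,
) -> tuple[ScalarVolume, np.ndarray]:
    """Voxelwise mean over the experiments covering each voxel.

    Coverage of the combination is the union of the per-experiment coverage
    masks; voxels covered by no experiment are 0.
    """
    if not volumes:
        raise ValueError("no experiments to combine")
    shape = volumes[0].grid.shape
    tag = volumes[0].tag
    for v in volumes[1:]:
        if v.grid.shape != shape or v.tag != tag:
            raise ValueError("experiments must share shape and semantics")
    if coverages is None:
        coverages = [np.ones(shape, dtype=bool) for _ in volumes]
    acc = np.zeros(shape, dtype=float)
    n = np.zeros(shape, dtype=float)
    for vol, cov in zip(volumes, coverages):
        m = _coverage_volume(cov, shape)
        acc += np.where(m, vol.grid, 0.0)
        n += m
    union = n > 0
    mean = np.divide(acc, n, out=np.zeros_like(acc), where=union)
    return ScalarVolume(mean, voxel_size=volumes[0].voxel_size, tag=tag), union


def region_mean_intensity(
    binarized: ScalarVolume,
    annotation: AnnotationVolume,
    hierarchy: RegionHierarchy,
    covered=None,
    marker: str = "GAD67",
) -> RegionIntensity:
    """Mean binarized intensity per region over its subtree's covered voxels.

    Parents aggregate their descendants' voxels, so regions with no directly
    labeled voxels still get an intensity.  Regions whose subtree has no
    covered voxels are flagged (support 0, mean undefined).
    """
    binarized.check_paired(annotation)
    mask = annotation.grid != 0
    if covered is not None:
        mask &= _coverage_volume(covered, annotation.grid.shape)
    labels = annotation.grid[mask]
    vals = binarized.grid[mask]
    own_sum: dict[int, float] = {}
    own_n: dict[int, int] = {}
    order = np.argsort(labels, kind="stable")
    labels_s, vals_s = labels[order], vals[order]
    uniq, starts = np.unique(labels_s, return_index=True)
    bounds = list(starts) + [labels_s.size]
    for rid, a, b in zip(uniq.tolist(), bounds[:-1], bounds[1:]):
        own_sum[int(rid)] = float(vals_s[a:b].sum())
        own_n[int(rid)] = int(b - a)
    mean: dict[int, float] = {}
    support: dict[int, int] = {}
    own_mean: dict[int, float] = {}
    own_support: dict[int, int] = {}
    # children before parents, so subtree sums accumulate in one pass
    sub_sum: dict[int, float] = {}
    sub_n: dict[int, int] = {}
    from .atlas import depth_ordering

    for rid in depth_ordering(hierarchy):
        s = own_sum.get(rid, 0.0) + sum(sub_sum[c] for c in hierarchy.children(rid))
        n = own_n.get(rid, 0) + sum(sub_n[c] for c in hierarchy.children(rid))
        sub_sum[rid], sub_n[rid] = s, n
        support[rid] = n
        if n > 0:
            mean[rid] = s / n
        own_support[rid] = own_n.get(rid, 0)
        if own_support[rid] > 0:
            own_mean[rid] = own_sum[rid] / own_n[rid]
    return RegionIntensity(
        mean=mean, support=support, own_mean=own_mean, own_support=own_support,
        marker=marker,
    )
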