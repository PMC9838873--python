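"""Synthetic toy brains with known ground truth.

A toy brain is a nested-box parcellation of a small 3D grid: the root keeps
a slab of its own voxels and splits the remainder equally among its
children, cycling the split axis with depth.  The first two children of the
root play the roles of the cerebellum (high densities) and the isocortex,
so the per-group transfer-function machinery exercises all three groups.

Ground-truth counts satisfy every consistency constraint exactly by
construction: per own-voxel block, a neuron density is drawn, a GABAergic
fraction of it, and PV/SST/VIP fractions of the GABAergic part summing to
less than one; totals follow by hierarchy aggregation.  A perfect pipeline
must therefore return the truth unchanged (objective 0) when all noise
scales are zero.

The emulated data are:

* a Nissl-like volume proportional to total cell density,
* per-marker ISH slice stacks whose binarized region mean intensity equals
  the true marker density divided by the group's true slope alpha (sections
  every ``slice_step`` planes, emulating 25 um sections every 200 um, with a
  slice on both sides of every rostro-caudal region boundary so that linear
  interpolation is exact when noise is off),
* a literature table with multiplicative log-normal between-source noise of
  a chosen CV, mixing density, count and percentage record kinds.

Real data differ in ways the fixtures deliberately ignore: anatomy is not
box-shaped, ISH coverage is incomplete and misaligned (only emulated via
the shift/dropout knobs), and literature spread is heavier-tailed than
log-normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .atlas import (
    AnnotationVolume,
    Region,
    RegionHierarchy,
    ScalarVolume,
    aggregate_to_parents,
    region_volumes,
)
from .ish import SliceStack
from .literature import MARKERS, LiteratureRecord
from .transfer import GROUPS

__all__ = ["ToyBrainSpec", "ToyBrain", "make_toy_atlas", "make_ish", "make_literature"]

_MARKER_BASE_ALPHA = {"GAD67": 4.0e5, "PV": 2.5e5, "SST": 2.2e5, "VIP": 1.2e5}
_GROUP_ALPHA_SCALE = {"cerebellum": 1.4, "isocortex": 1.0, "rest": 0.8}


def default_alphas() -> dict[tuple[str, str], float]:
    """True slopes per (marker, group), cells/mm**3 per unit intensity."""
    return {
        (m, g): _MARKER_BASE_ALPHA[m] * _GROUP_ALPHA_SCALE[g]
        for m in MARKERS
        for g in GROUPS
    }


@dataclass
class ToyBrainSpec:
    """Parameters of a synthetic brain; defaults are the standard conditions.

    Densities are cells/mm**3, voxel size um.  ``literature_cv`` is the
    between-source coefficient of variation of the log-normal noise;
    ``literature_coverage`` the fraction of regions with published records.
    """

    depth: int = 2
    branching: int = 3
    grid_shape: tuple[int, int, int] = (48, 24, 24)
    voxel_size: float = 25.0
    slice_step: int = 8  # 25 um sections every 200 um
    neuron_density_range: tuple[float, float] = (20_000.0, 80_000.0)
    cerebellum_density_scale: float = 3.0
    neuron_fraction: float = 0.5  # neurons per cell
    gad_fraction_range: tuple[float, float] = (0.15, 0.45)
    subtype_total_range: tuple[float, float] = (0.5, 0.85)  # of nGAD
    alphas: dict[tuple[str, str], float] = field(default_factory=default_alphas)
    purely_inhibitory_leaves: int = 1  # isocortex-L1-like regions
    literature_cv: float = 0.2
    literature_coverage: float = 0.5
    records_per_region: tuple[int, int] = (1, 3)
    nissl_noise_cv: float = 0.0
    ish_dropout: float = 0.0
    misalignment_shift: int = 0
    seed: int = 0


@dataclass
class ToyBrain:
    """A generated toy brain with its complete ground truth."""

    spec: ToyBrainSpec
    hierarchy: RegionHierarchy
    annotation: AnnotationVolume
    nissl: ScalarVolume
    groups: dict[int, str]
    own_boxes: dict[int, tuple[slice, slice, slice]]
    neu_own: dict[int, float]
    neu_total: dict[int, float]
    counts_own: dict[tuple[int, str], float]  # per (region, marker)
    counts_total: dict[tuple[int, str], float]
    purely_inhibitory: list[int]

    @property
    def volumes_own(self) -> dict[int, float]:
        return region_volumes(self.annotation, self.hierarchy, hierarchical=False)

    @property
    def volumes_total(self) -> dict[int, float]:
        return region_volumes(self.annotation, self.hierarchy, hierarchical=True)

    def density_own(self, rid: int, marker: str) -> float:
        box = self.own_boxes[rid]
        nvox = math.prod(s.stop - s.start for s in box)
        vol = nvox * self.annotation.voxel_volume_mm3
        return self.counts_own[(rid, marker)] / vol if vol > 0 else 0.0


def _snap_to_pixels(
    counts_own: dict[tuple[int, str], float],
    rid: int,
    box: tuple[slice, slice, slice],
    vol: float,
    spec: "ToyBrainSpec",
    group: str,
) -> None:
    """Quantize a region's marker counts to whole foreground pixels.

    The emulated ISH encodes density/alpha as a foreground-pixel fraction
    over the block's cross-section, which only takes multiples of
    1/(pixels per section).  The ground truth is defined on that same grid,
    so a noiseless fixture is exactly representable and a perfect pipeline
    recovers it with zero correction.  A repair pass keeps the subtype sum
    at or below the GAD67 count after rounding.
    """
    n_jk = (box[1].stop - box[1].start) * (box[2].stop - box[2].start)
    pixels: dict[str, int] = {}
    for m in MARKERS:
        alpha = spec.alphas[(m, group)]
        p = counts_own[(rid, m)] / vol / alpha
        pixels[m] = min(int(round(p * n_jk)), n_jk)

    def count(m: str) -> float:
        return pixels[m] / n_jk * spec.alphas[(m, group)] * vol

    for m in pixels:
        counts_own[(rid, m)] = count(m)
    gad = counts_own[(rid, "GAD67")]
    while sum(count(m) for m in ("PV", "SST", "VIP")) > gad:
        biggest = max(("PV", "SST", "VIP"), key=count)
        if pixels[biggest] == 0:
            break
        pixels[biggest] -= 1
        counts_own[(rid, biggest)] = count(biggest)


def _build_tree(depth: int, branching: int) -> RegionHierarchy:
    regions: dict[int, Region] = {}
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0]

    def build(d: int, parent: int | None, label: str) -> int:
        rid = new_id()
        kids: list[int] = []
        regions[rid] = Region(rid, label, label, parent, ())
        if d < depth:
            for b in range(branching):
                if parent is None and b == 0:
                    child_label = "CB"
                elif parent is None and b == 1:
                    child_label = "Isocortex"
                else:
                    child_label = f"{label}-{b}" if label != "root" else f"RST{b}"
                kids.append(build(d + 1, rid, child_label))
            regions[rid] = Region(rid, label, label, parent, tuple(kids))
        return rid

    build(0, None, "root")
    return RegionHierarchy(regions)


def make_toy_atlas(spec: ToyBrainSpec) -> ToyBrain:
    """Deterministically generate hierarchy, annotation, Nissl and truth."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    hierarchy = _build_tree(spec.depth, spec.branching)
    grid = np.zeros(spec.grid_shape, dtype=np.int32)
    own_boxes: dict[int, tuple[slice, slice, slice]] = {}

    def carve(rid: int, box: tuple[slice, slice, slice], d: int) -> None:
        kids = hierarchy.children(rid)
        if not kids:
            own_boxes[rid] = box
            grid[box] = rid
            return
        axis = d % 3
        lo, hi = box[axis].start, box[axis].stop
        extent = hi - lo
        n_parts = len(kids) + 1
        part = extent // n_parts
        if part < 1:
            raise ValueError(
                f"grid too small for hierarchy: {extent} planes along axis {axis} "
                f"cannot host {n_parts} blocks"
            )
        cuts = [lo + part * i for i in range(n_parts)] + [hi]
        own_box = tuple(
            slice(cuts[0], cuts[1]) if a == axis else box[a] for a in range(3)
        )
        own_boxes[rid] = own_box
        grid[own_box] = rid
        for i, c in enumerate(kids):
            child_box = tuple(
                slice(cuts[i + 1], cuts[i + 2]) if a == axis else box[a]
                for a in range(3)
            )
            carve(c, child_box, d + 1)

    carve(hierarchy.root, tuple(slice(0, s) for s in spec.grid_shape), 0)
    annotation = AnnotationVolume(grid, voxel_size=spec.voxel_size)

    from .transfer import assign_groups

    try:
        groups = assign_groups(hierarchy)
        # designated purely-inhibitory regions: first isocortex-subtree leaves
        iso = hierarchy.find_acronym("Isocortex")
        iso_leaves = [r for r in hierarchy.subtree(iso) if hierarchy.is_leaf(r)]
        purely = sorted(iso_leaves)[: spec.purely_inhibitory_leaves]
    except (ValueError, KeyError):
        # degenerate shapes (no cerebellum/isocortex subtrees): all "rest"
        groups = {rid: "rest" for rid in hierarchy.ids}
        purely = []

    vv = annotation.voxel_volume_mm3
    neu_own: dict[int, float] = {}
    counts_own: dict[tuple[int, str], float] = {}
    density_neu: dict[int, float] = {}
    for rid in sorted(hierarchy.ids):
        box = own_boxes[rid]
        nvox = math.prod(s.stop - s.start for s in box)
        lo_d, hi_d = spec.neuron_density_range
        d_neu = rng.uniform(lo_d, hi_d)
        if groups[rid] == "cerebellum":
            d_neu *= spec.cerebellum_density_scale
        density_neu[rid] = d_neu
        vol = nvox * vv
        neu_own[rid] = d_neu * vol
        if rid in purely:
            f_gad = 1.0
        else:
            f_gad = rng.uniform(*spec.gad_fraction_range)
        sub_total = rng.uniform(*spec.subtype_total_range)
        shares = rng.dirichlet([2.0, 2.0, 2.0]) * sub_total
        gad = f_gad * neu_own[rid]
        counts_own[(rid, "GAD67")] = gad
        for m, share in zip(("PV", "SST", "VIP"), shares):
            counts_own[(rid, m)] = share * gad
        _snap_to_pixels(counts_own, rid, box, vol, spec, groups[rid])
        if rid in purely:  # keep nGAD = nNeu exact on the pixel grid
            neu_own[rid] = counts_own[(rid, "GAD67")]

    neu_total = aggregate_to_parents(neu_own, hierarchy)
    counts_total: dict[tuple[int, str], float] = {}
    for m in MARKERS:
        agg = aggregate_to_parents({r: counts_own[(r, m)] for r in hierarchy.ids}, hierarchy)
        for r, v in agg.items():
            counts_total[(r, m)] = v

    nissl_grid = np.zeros(spec.grid_shape, dtype=float)
    for rid, box in own_boxes.items():
        cell_density = density_neu[rid] / spec.neuron_fraction
        nissl_grid[box] = cell_density
    nissl_grid /= nissl_grid.max()
    if spec.nissl_noise_cv > 0:
        s = math.sqrt(math.log1p(spec.nissl_noise_cv**2))
        nissl_grid *= rng.lognormal(-0.5 * s * s, s, size=nissl_grid.shape)
    nissl = ScalarVolume(nissl_grid, voxel_size=spec.voxel_size, tag="nissl-intensity")

    return ToyBrain(
        spec=spec,
        hierarchy=hierarchy,
        annotation=annotation,
        nissl=nissl,
        groups=groups,
        own_boxes=own_boxes,
        neu_own=neu_own,
        neu_total=neu_total,
        counts_own=counts_own,
        counts_total=counts_total,
        purely_inhibitory=list(purely),
    )


def make_ish(brain: ToyBrain, marker: str) -> SliceStack:
    """Emulated filtered ISH stack for one marker.

    Per own-voxel block, a foreground pattern constant along the
    rostro-caudal axis covers a pixel fraction equal to the true marker
    density divided by the group's true alpha, so the binarized region mean
    intensity recovers density/alpha up to pixel quantization.  Fractions
    above 1 are clipped.  Slice positions sample every ``slice_step`` planes
    plus both planes around each rostro-caudal boundary.
    """
    spec = brain.spec
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 211, MARKERS.index(marker)])
    )
    fg, bg = 0.9, 0.1
    vol = np.full(spec.grid_shape, 0.0, dtype=float)
    for rid, box in brain.own_boxes.items():
        alpha = brain.spec.alphas[(marker, brain.groups[rid])]
        p = brain.density_own(rid, marker) / alpha
        p = min(p, 1.0)
        shape_jk = (box[1].stop - box[1].start, box[2].stop - box[2].start)
        n_jk = shape_jk[0] * shape_jk[1]
        n_fg = int(round(p * n_jk))
        mask = np.zeros(n_jk, dtype=bool)
        mask[rng.permutation(n_jk)[:n_fg]] = True
        mask = mask.reshape(shape_jk)
        pattern = np.where(mask, fg, bg)
        if spec.ish_dropout > 0:
            drop = rng.random(shape_jk) < spec.ish_dropout
            pattern = np.where(mask & drop, bg, pattern)
        vol[box] = pattern[None, :, :]
    if spec.misalignment_shift:
        vol = np.roll(vol, spec.misalignment_shift, axis=1)

    n0 = spec.grid_shape[0]
    changed = np.any(vol[1:] != vol[:-1], axis=(1, 2)) | np.any(
        brain.annotation.grid[1:] != brain.annotation.grid[:-1], axis=(1, 2)
    )
    positions = set(range(0, n0, spec.slice_step)) | {n0 - 1}
    for z in np.flatnonzero(changed):
        positions.update((int(z), int(z) + 1))
    positions = sorted(positions)
    return SliceStack([vol[z] for z in positions], positions, marker=marker)


def make_literature(
    brain: ToyBrain,
    coverage: float | None = None,
    cv: float | None = None,
    seed: int | None = None,
) -> list[LiteratureRecord]:
    """Noisy literature table for a toy brain.

    A seeded random subset of regions (fraction ``coverage``) gets 1-3
    records per (region, marker); source means are truth times a
    mean-preserving log-normal of coefficient of variation ``cv``, reported
    stds are cv times the mean, and kinds are mixed among density, count and
    percentage-of-neurons.  Purely-inhibitory regions are always covered by
    their rule-generated records downstream, not here.
    """
    spec = brain.spec
    coverage = spec.literature_coverage if coverage is None else coverage
    cv = spec.literature_cv if cv is None else cv
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 307])
    )
    candidates = [r for r in brain.hierarchy.ids if r not in brain.purely_inhibitory]
    n_cover = int(round(coverage * len(candidates)))
    covered = sorted(rng.permutation(candidates)[:n_cover].tolist())
    vol_tot = brain.volumes_total
    records: list[LiteratureRecord] = []
    s = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    lo, hi = spec.records_per_region
    for rid in covered:
        for marker in MARKERS:
            true_density = brain.counts_total[(rid, marker)] / vol_tot[rid]
            for k in range(int(rng.integers(lo, hi + 1))):
                noise = rng.lognormal(-0.5 * s * s, s) if cv > 0 else 1.0
                dens = true_density * noise
                std_d = cv * dens if cv > 0 else None
                kind = rng.choice(["density", "count", "pct_neurons"], p=[0.6, 0.3, 0.1])
                if kind == "density":
                    value, std = dens, std_d
                elif kind == "count":
                    value = dens * vol_tot[rid]
                    std = None if std_d is None else std_d * vol_tot[rid]
                else:
                    pct = 100.0 * dens * vol_tot[rid] / brain.neu_total[rid]
                    if pct > 100.0:
                        kind, value, std = "density", dens, std_d
                    else:
                        value = pct
                        std = None if std_d is None else cv * pct
                records.append(
                    LiteratureRecord(
                        source_id=f"src-{rid}-{marker}-{k}",
                        marker=marker,
                        region_id=rid,
                        kind=str(kind),
                        value=value,
                        std=std,
                    )
                )
    return records
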