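"""Conversion of per-region counts into explicit 3D cell positions.

Placement is acceptance-rejection in spirit: voxels of a region are sampled
with probability proportional to the local cell density until the region
holds its target number of cells, then type labels are assigned by nested
uniform selection — inhibitory (GAD67) among all neurons of the region, PV
among the inhibitory ones, SST among the non-PV inhibitory ones, VIP among
the remaining unlabeled inhibitory ones; leftovers are InhR and the
non-inhibitory neurons ExcOther.  Finally each cell gets a uniform position
inside its voxel.

Counts are conserved exactly: fractional targets are rounded by largest
remainder within each region so regional totals are preserved, and every
stage draws from an independent substream of one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume, RegionHierarchy, ScalarVolume, aggregate_to_parents

__all__ = [
    "LABELS",
    "largest_remainder",
    "place_cells",
    "assign_types",
    "jitter_positions",
    "place_atlas",
]

LABELS = ("PV", "SST", "VIP", "InhR", "ExcOther")


def largest_remainder(values: Sequence[float], total: int | None = None) -> np.ndarray:
    """Round non-negative reals to integers preserving their (rounded) sum."""
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("largest_remainder requires non-negative values")
    if total is None:
        total = int(round(vals.sum()))
    base = np.floor(vals).astype(int)
    short = total - int(base.sum())
    if short < 0:  # total below the floor sum: take away from smallest remainders
        order = np.argsort(vals - base, kind="stable")
        for i in order:
            if short == 0:
                break
            if base[i] > 0:
                base[i] -= 1
                short += 1
    else:
        remainder = vals - base
        order = np.lexsort((np.arange(vals.size), -remainder))
        base[order[:short]] += 1
    return base


def place_cells(
    density: ScalarVolume,
    targets: Mapping[int, float],
    annotation: AnnotationVolume,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign cells to voxels, region by region.

    For each region id in ``targets``, exactly ``round(target)`` cells are
    distributed over the voxels labeled with that id, each draw picking a
    voxel with probability proportional to its density.  Deterministic given
    the generator state.  Returns a frame with voxel indices and region ids.
    """
    density.check_paired(annotation)
    grid = annotation.grid
    rows = []
    for rid in sorted(targets):
        n = int(round(targets[rid]))
        if n < 0:
            raise ValueError(f"negative target for region {rid}")
        if n == 0:
            continue
        idx = np.argwhere(grid == rid)
        if idx.size == 0:
            raise ValueError(f"region {rid} has a positive target but no voxels")
        w = density.grid[tuple(idx.T)]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"region {rid} has a positive target but zero total density")
        counts = rng.multinomial(n, w / total)
        for (i, j, k), c in zip(idx[counts > 0], counts[counts > 0]):
            rows.extend([(int(i), int(j), int(k), int(rid))] * int(c))
    return pd.DataFrame(rows, columns=["i", "j", "k", "region_id"])


def assign_types(
    cells: pd.DataFrame,
    type_counts: Mapping[int, Mapping[str, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Label placed cells by nested uniform selection within each region.

    ``type_counts[rid]`` provides nNeu, nGAD, nPV, nSST, nVIP for the cells
    of region ``rid`` (the frame must contain exactly nNeu cells there).
    Requires nGAD <= nNeu and nPV + nSST + nVIP <= nGAD.
    """
    out = cells.copy()
    out["label"] = "ExcOther"
    for rid, counts in sorted(type_counts.items()):
        sel = np.flatnonzero((out["region_id"] == rid).to_numpy())
        n_here = sel.size
        tc = {k: int(round(v)) for k, v in dict(counts).items()}
        n_gad = tc.get("nGAD", 0)
        n_pv, n_sst, n_vip = tc.get("nPV", 0), tc.get("nSST", 0), tc.get("nVIP", 0)
        if n_gad > n_here:
            raise ValueError(f"region {rid}: nGAD {n_gad} exceeds placed neurons {n_here}")
        if n_pv + n_sst + n_vip > n_gad:
            raise ValueError(
                f"region {rid}: subtype sum {n_pv + n_sst + n_vip} exceeds nGAD {n_gad}"
            )
        inhibitory = rng.choice(sel, size=n_gad, replace=False)
        pool = rng.permutation(inhibitory)
        labels = out["label"].to_numpy()
        labels[pool[:n_pv]] = "PV"
        labels[pool[n_pv:n_pv + n_sst]] = "SST"
        labels[pool[n_pv + n_sst:n_pv + n_sst + n_vip]] = "VIP"
        labels[pool[n_pv + n_sst + n_vip:]] = "InhR"
        out["label"] = labels
    return out


def jitter_positions(
    cells: pd.DataFrame,
    voxel_size,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """World positions (um): uniform within each cell's voxel bounds."""
    vs = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    out = cells.copy()
    u = rng.random((len(out), 3))
    corners = out[["i", "j", "k"]].to_numpy() * vs
    pos = corners + u * vs
    out[["x", "y", "z"]] = pos
    return out


def place_atlas(
    density: ScalarVolume,
    annotation: AnnotationVolume,
    hierarchy: RegionHierarchy,
    nneu_own: Mapping[int, float],
    x_own_counts: Mapping[tuple[int, str], float],
    seed: int,
) -> pd.DataFrame:
    """Full placement: per-region neurons, nested type labels, jittered positions.

    ``x_own_counts`` holds the reconciled own-voxel counts per (region, type)
    (for leaves these equal the region totals).  Per region, the five label
    counts are rounded by largest remainder so they sum to the rounded
    own-voxel neuron count; the master ``seed`` spawns one substream per
    stage.
    """
    ss = np.random.SeedSequence(seed)
    rng_place, rng_types, rng_jitter = (np.random.default_rng(s) for s in ss.spawn(3))
    targets: dict[int, float] = {}
    type_counts: dict[int, dict[str, int]] = {}
    for rid in hierarchy.ids:
        nn = float(nneu_own.get(rid, 0.0))
        n_cells = int(round(nn))
        if n_cells == 0:
            continue
        g = x_own_counts.get((rid, "GAD67"), 0.0)
        p = x_own_counts.get((rid, "PV"), 0.0)
        s = x_own_counts.get((rid, "SST"), 0.0)
        v = x_own_counts.get((rid, "VIP"), 0.0)
        parts = largest_remainder(
            [p, s, v, max(g - (p + s + v), 0.0), max(nn - g, 0.0)], total=n_cells
        )
        n_pv, n_sst, n_vip, n_rest, _ = (int(a) for a in parts)
        targets[rid] = n_cells
        type_counts[rid] = {
            "nNeu": n_cells,
            "nGAD": n_pv + n_sst + n_vip + n_rest,
            "nPV": n_pv,
            "nSST": n_sst,
            "nVIP": n_vip,
        }
    cells = place_cells(density, targets, annotation, rng_place)
    cells = assign_types(cells, type_counts, rng_types)
    return jitter_positions(cells, annotation.voxel_size, rng_jitter)
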