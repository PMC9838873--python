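"""Region-hierarchy and voxel-volume primitives.

A brain parcellation is described by two coupled objects: a
:class:`RegionHierarchy` — the tree of region ids from an AIBS-style nested
ontology — and an :class:`AnnotationVolume` — a 3D grid assigning every voxel
a region id (0 means outside the brain).  Voxels may carry non-leaf labels:
the set of voxels labeled exactly ``r`` is the "own-voxel" part of region
``r``, while the region as an anatomical entity is its whole subtree.

Counts are kept dimensionless; densities are always cells/mm**3; voxel sizes
are micrometres.  World coordinate of a voxel corner = index * voxel_size,
axis 0 being the rostro-caudal axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Region",
    "RegionHierarchy",
    "HierarchyError",
    "AnnotationVolume",
    "ScalarVolume",
    "RegionCounts",
    "parse_hierarchy",
    "region_volumes",
    "aggregate_to_parents",
    "depth_ordering",
    "homogeneity_metric",
]


class HierarchyError(ValueError):
    """Raised when an ontology document violates the hierarchy invariants."""


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    acronym: str
    parent_id: int | None
    children: tuple[int, ...]


class RegionHierarchy:
    """Tree of brain regions with parent/child links and depths.

    Invariants: exactly one root, no cycles, every non-root's parent is in
    the set, ``depth(child) == depth(parent) + 1`` and id 0 is reserved for
    outside-brain and never a region.
    """

    def __init__(self, regions: Mapping[int, Region]):
        self._regions = dict(regions)
        roots = [r.id for r in self._regions.values() if r.parent_id is None]
        if len(roots) != 1:
            raise HierarchyError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        if 0 in self._regions:
            raise HierarchyError("region id 0 is reserved for outside-brain")
        self.depth: dict[int, int] = {}
        stack = [(self.root, 0)]
        while stack:
            rid, d = stack.pop()
            if rid in self.depth:
                raise HierarchyError(f"cycle detected at region {rid}")
            self.depth[rid] = d
            for c in self._regions[rid].children:
                if c not in self._regions:
                    raise HierarchyError(f"child {c} of {rid} missing from set")
                stack.append((c, d + 1))
        if len(self.depth) != len(self._regions):
            orphans = set(self._regions) - set(self.depth)
            raise HierarchyError(f"unreachable regions (broken parents): {sorted(orphans)}")

    # -- basic accessors -------------------------------------------------
    def __contains__(self, rid: int) -> bool:
        return rid in self._regions

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __getitem__(self, rid: int) -> Region:
        return self._regions[rid]

    @property
    def ids(self) -> list[int]:
        return sorted(self._regions)

    @property
    def leaves(self) -> list[int]:
        return sorted(r.id for r in self._regions.values() if not r.children)

    def children(self, rid: int) -> tuple[int, ...]:
        return self._regions[rid].children

    def parent(self, rid: int) -> int | None:
        return self._regions[rid].parent_id

    def is_leaf(self, rid: int) -> bool:
        return not self._regions[rid].children

    def ancestors(self, rid: int) -> list[int]:
        """Ancestors from parent up to the root (exclusive of ``rid``)."""
        out = []
        p = self._regions[rid].parent_id
        while p is not None:
            out.append(p)
            p = self._regions[p].parent_id
        return out

    def subtree(self, rid: int) -> list[int]:
        """``rid`` and all its descendants (preorder)."""
        out = []
        stack = [rid]
        while stack:
            r = stack.pop()
            out.append(r)
            stack.extend(self._regions[r].children)
        return out

    def to_dict(self) -> dict:
        """Serialize back to the nested AIBS ontology layout."""

        def node(rid: int) -> dict:
            r = self._regions[rid]
            return {
                "id": r.id,
                "name": r.name,
                "acronym": r.acronym,
                "children": [node(c) for c in r.children],
            }

        return node(self.root)

    def acronym_to_id(self) -> dict[str, int]:
        return {r.acronym: r.id for r in self._regions.values()}

    def find_acronym(self, acronym: str) -> int:
        for r in self._regions.values():
            if r.acronym == acronym:
                return r.id
        raise KeyError(f"no region with acronym {acronym!r}")


def parse_hierarchy(document) -> RegionHierarchy:
    """Parse an AIBS-style nested ontology into a :class:`RegionHierarchy`.

    ``document`` may be the root node dict (fields ``id``, ``name``,
    ``acronym``, ``children``), the AIBS envelope ``{"msg": [root]}``, a JSON
    string, or a path to a JSON file.
    """
    if isinstance(document, (str, bytes)):
        s = document if isinstance(document, str) else document.decode()
        if s.lstrip().startswith(("{", "[")):
            document = json.loads(s)
        else:
            with open(s) as fh:
                document = json.load(fh)
    if isinstance(document, dict) and "msg" in document:
        msg = document["msg"]
        if not msg:
            raise HierarchyError("empty 'msg' envelope: missing root node")
        document = msg[0]
    if not isinstance(document, dict) or "id" not in document:
        raise HierarchyError("missing root node with an 'id' field")

    regions: dict[int, Region] = {}

    def visit(node: dict, parent_id: int | None) -> None:
        rid = int(node["id"])
        if rid in regions:
            raise HierarchyError(f"duplicate region id {rid} ({node.get('name')})")
        kids = node.get("children") or []
        regions[rid] = Region(
            id=rid,
            name=str(node.get("name", str(rid))),
            acronym=str(node.get("acronym", str(rid))),
            parent_id=parent_id,
            children=tuple(int(c["id"]) for c in kids),
        )
        for c in kids:
            visit(c, rid)

    visit(document, None)
    return RegionHierarchy(regions)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    a = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3 or np.any(a <= 0):
        raise ValueError("voxel_size must be a positive scalar or 3-vector (um)")
    return tuple(float(v) for v in a)


@dataclass
class AnnotationVolume:
    """3D grid of integer region labels; 0 = outside the brain."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("annotation grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("annotation grid must be integer-typed")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod([v / 1000.0 for v in self.voxel_size]))

    def validate_labels(self, hierarchy: RegionHierarchy) -> None:
        labels = set(np.unique(self.grid).tolist()) - {0}
        unknown = labels - set(hierarchy.ids)
        if unknown:
            raise ValueError(f"annotation labels not in hierarchy: {sorted(unknown)}")


@dataclass
class ScalarVolume:
    """3D grid of non-negative reals paired with an annotation volume.

    ``tag`` records the semantics: ``nissl-intensity``, ``ish-filtered``,
    ``binarized`` or ``cell-density`` (cells/mm**3).
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)
    tag: str = "nissl-intensity"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("scalar grid must be 3D")
        if np.any(self.grid < 0):
            raise ValueError("scalar volumes are non-negative")
        if self.tag == "binarized" and not np.isin(self.grid, (0.0, 1.0)).all():
            raise ValueError("binarized volume must contain only {0, 1}")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    def check_paired(self, annotation: AnnotationVolume) -> None:
        if self.grid.shape != annotation.grid.shape:
            raise ValueError(
                f"shape mismatch: {self.grid.shape} vs {annotation.grid.shape}"
            )
        if not np.allclose(self.voxel_size, annotation.voxel_size):
            raise ValueError("voxel_size differs from the paired annotation")


@dataclass
class RegionCounts:
    """Per-region non-negative values with a semantic tag.

    Tags follow the neuron bookkeeping: ``nNeu``, ``nGAD``, ``nPV``, ``nSST``,
    ``nVIP``, ``nRest``, ``nExcOther`` or ``cells``.
    """

    values: dict[int, float]
    tag: str = "cells"
    hierarchy_consistent: bool = False

    def __post_init__(self):
        self.values = {int(k): float(v) for k, v in self.values.items()}
        bad = {k: v for k, v in self.values.items() if v < 0 or not np.isfinite(v)}
        if bad:
            raise ValueError(f"negative or non-finite counts: {bad}")

    def __getitem__(self, rid: int) -> float:
        return self.values[rid]

    def get(self, rid: int, default: float = 0.0) -> float:
        return self.values.get(rid, default)

    def total(self) -> float:
        return float(sum(self.values.values()))


def region_volumes(
    annotation: AnnotationVolume,
    hierarchy: RegionHierarchy,
    hierarchical: bool = False,
) -> dict[int, float]:
    """Volume (mm**3) per region id.

    Own-voxel variant counts voxels labeled exactly ``r``; the hierarchical
    variant adds all descendants' volumes.  Regions absent from the
    annotation get volume 0.
    """
    annotation.validate_labels(hierarchy)
    ids, counts = np.unique(annotation.grid, return_counts=True)
    vv = annotation.voxel_volume_mm3
    own = {int(r): 0.0 for r in hierarchy.ids}
    for rid, n in zip(ids.tolist(), counts.tolist()):
        if rid != 0:
            own[int(rid)] = n * vv
    if not hierarchical:
        return own
    return aggregate_to_parents(own, hierarchy)


def aggregate_to_parents(
    own_voxel_values: Mapping[int, float] | RegionCounts,
    hierarchy: RegionHierarchy,
) -> dict[int, float]:
    """Hierarchy-consistent totals: total(r) = own(r) + sum of children totals."""
    vals = own_voxel_values.values if isinstance(own_voxel_values, RegionCounts) else own_voxel_values
    bad = {k: v for k, v in vals.items() if v < 0}
    if bad:
        raise ValueError(f"negative own-voxel values: {bad}")
    totals: dict[int, float] = {}
    for rid in depth_ordering(hierarchy):  # deepest first: children before parents
        totals[rid] = float(vals.get(rid, 0.0)) + sum(
            totals[c] for c in hierarchy.children(rid)
        )
    return totals


def depth_ordering(hierarchy: RegionHierarchy) -> list[int]:
    """Regions ordered deepest-first, ties broken by ascending region id."""
    return sorted(hierarchy.ids, key=lambda r: (-hierarchy.depth[r], r))


def homogeneity_metric(
    neuron_counts: Mapping[int, float] | RegionCounts,
    hierarchy: RegionHierarchy | None = None,
    region_ids: Iterable[int] | None = None,
) -> float:
    """Population standard deviation of the per-region neuron-count distribution.

    A well-aligned annotation keeps dense and sparse regions distinct, so the
    spread of counts across regions is large; misalignment smears counts
    across boundaries and shrinks it.  Larger is better.  By default the
    metric is taken over the supplied counts' keys (callers typically pass
    leaf regions with nonzero annotated volume).
    """
    vals = neuron_counts.values if isinstance(neuron_counts, RegionCounts) else dict(neuron_counts)
    if region_ids is not None:
        vals = {r: vals[r] for r in region_ids}
    if len(vals) < 2:
        raise ValueError("homogeneity metric needs at least 2 regions")
    return float(np.std(list(vals.values())))  # population convention
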