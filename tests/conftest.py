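"""Shared fixtures: tiny hand-built hierarchies and standard toy brains."""

from __future__ import annotations

import numpy as np
import pytest

from gabatlas.atlas import AnnotationVolume, parse_hierarchy
from gabatlas.synth import ToyBrainSpec, make_ish, make_literature, make_toy_atlas

MARKER_LIST = ("GAD67", "PV", "SST", "VIP")


def hierarchy_from_nested(node: dict):
    """Build a RegionHierarchy from a plain nested dict (id/children)."""
    return parse_hierarchy(node)


@pytest.fixture
def chain_hierarchy():
    # root(1) -> a(2) -> b(3)
    return parse_hierarchy(
        {"id": 1, "name": "root", "acronym": "root",
         "children": [{"id": 2, "name": "a", "acronym": "a",
                       "children": [{"id": 3, "name": "b", "acronym": "b", "children": []}]}]}
    )


@pytest.fixture
def small_tree():
    # root(1) with children 2, 3; 2 has child 4
    return parse_hierarchy(
        {"id": 1, "name": "root", "acronym": "root", "children": [
            {"id": 2, "name": "c1", "acronym": "c1", "children": [
                {"id": 4, "name": "g", "acronym": "g", "children": []}]},
            {"id": 3, "name": "c2", "acronym": "c2", "children": []},
        ]}
    )


@pytest.fixture
def seven_region_hierarchy():
    # root(1); children 2, 3; 2 -> 4, 5; 3 -> 6, 7
    return parse_hierarchy(
        {"id": 1, "name": "root", "acronym": "root", "children": [
            {"id": 2, "name": "L", "acronym": "L", "children": [
                {"id": 4, "name": "L1", "acronym": "L1", "children": []},
                {"id": 5, "name": "L2", "acronym": "L2", "children": []}]},
            {"id": 3, "name": "R", "acronym": "R", "children": [
                {"id": 6, "name": "R1", "acronym": "R1", "children": []},
                {"id": 7, "name": "R2", "acronym": "R2", "children": []}]},
        ]}
    )


@pytest.fixture
def toy_annotation(seven_region_hierarchy):
    """8x4x4 grid: root own slab, two mid regions with own slabs, four leaves."""
    grid = np.zeros((8, 4, 4), dtype=np.int32)
    grid[0:2] = 1  # root own voxels
    grid[2:5] = 2
    grid[5:8] = 3
    grid[2:5, 0:1] = 2  # own slab of region 2
    grid[2:5, 1:2] = 4
    grid[2:5, 2:4] = 5
    grid[5:8, 0:1] = 3
    grid[5:8, 1:2] = 6
    grid[5:8, 2:4] = 7
    return AnnotationVolume(grid, voxel_size=25.0)


@pytest.fixture(scope="session")
def noisy_brain():
    """Standard noisy fixture: literature CV 0.2, coverage 0.5."""
    return make_toy_atlas(ToyBrainSpec(seed=11))


@pytest.fixture(scope="session")
def noisy_records(noisy_brain):
    return make_literature(noisy_brain)


@pytest.fixture(scope="session")
def noisy_stacks(noisy_brain):
    return {m: [make_ish(noisy_brain, m)] for m in MARKER_LIST}


@pytest.fixture(scope="session")
def clean_brain():
    """Noiseless fixture: full coverage, zero literature CV."""
    return make_toy_atlas(ToyBrainSpec(seed=5, literature_cv=0.0, literature_coverage=1.0))


@pytest.fixture(scope="session")
def clean_records(clean_brain):
    return make_literature(clean_brain)


@pytest.fixture(scope="session")
def clean_stacks(clean_brain):
    return {m: [make_ish(clean_brain, m)] for m in MARKER_LIST}
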