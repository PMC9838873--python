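"""End-to-end orchestration: densities, fitting, reconciliation, placement.

The stages mirror the production workflow: (1) scale a Nissl-like volume
into cell/neuron densities per region, (2) turn per-marker ISH stacks into
region mean binarized intensities, (3) normalize the literature table and
fit per-marker, per-group transfer functions, (4) assemble unconstrained
estimates for every (region, type), reconcile them with the consistency LP,
and (5) place labeled cells.  Each stage is callable on its own; this module
wires them and records every exclusion, clip and flag in a log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    AnnotationVolume,
    RegionHierarchy,
    ScalarVolume,
    aggregate_to_parents,
    region_volumes,
)
from .ish import (
    RegionIntensity,
    SliceStack,
    binarize,
    combine_experiments,
    interpolate_stack,
    otsu_threshold,
    region_mean_intensity,
)
from .literature import (
    MARKERS,
    LiteratureRecord,
    build_region_literature,
    purely_inhibitory_records,
)
from .optimize import (
    EstimateSet,
    LPProblem,
    LPSolution,
    assemble_estimates,
    build_lp,
    derive_residuals,
    flag_corrections,
    initial_solution,
    solve_lp,
)
from .transfer import (
    GROUPS,
    FitPoint,
    TransferFunction,
    assign_groups,
    build_fit_points,
    fit_alpha,
)

__all__ = [
    "PipelineResult",
    "compute_cell_densities",
    "process_marker",
    "fit_transfer_functions",
    "run_density_pipeline",
    "consistent_counts_table",
]


def compute_cell_densities(
    nissl: ScalarVolume,
    annotation: AnnotationVolume,
    hierarchy: RegionHierarchy,
    total_cells: float,
    neuron_fraction: float = 0.5,
) -> tuple[ScalarVolume, dict[int, float], dict[int, float]]:
    """Cell-density volume and per-region neuron counts from a Nissl volume.

    Voxel cell density is proportional to Nissl intensity, globally scaled so
    the brain total equals ``total_cells``; neurons are a configured fraction
    of cells.  Returns (density volume in cells/mm**3, own-voxel nNeu,
    hierarchy-consistent total nNeu).
    """
    nissl.check_paired(annotation)
    inside = annotation.grid != 0
    signal = float(nissl.grid[inside].sum())
    if signal <= 0:
        raise ValueError("zero total Nissl signal inside the brain")
    vv = annotation.voxel_volume_mm3
    cells_per_voxel = np.where(inside, nissl.grid * (total_cells / signal), 0.0)
    density = ScalarVolume(cells_per_voxel / vv, voxel_size=nissl.voxel_size, tag="cell-density")
    neu_own: dict[int, float] = {rid: 0.0 for rid in hierarchy.ids}
    labels = annotation.grid[inside]
    neu_vals = cells_per_voxel[inside] * neuron_fraction
    order = np.argsort(labels, kind="stable")
    labels_s, vals_s = labels[order], neu_vals[order]
    uniq, starts = np.unique(labels_s, return_index=True)
    bounds = list(starts) + [labels_s.size]
    for rid, a, b in zip(uniq.tolist(), bounds[:-1], bounds[1:]):
        neu_own[int(rid)] = float(vals_s[a:b].sum())
    neu_total = aggregate_to_parents(neu_own, hierarchy)
    return density, neu_own, neu_total


def process_marker(
    stacks: Sequence[SliceStack],
    annotation: AnnotationVolume,
    hierarchy: RegionHierarchy,
    marker: str,
    log: list | None = None,
) -> RegionIntensity:
    """Interpolate, combine, binarize and summarize one marker's experiments.

    Stacks are assembled to volumes, averaged over their coverage union,
    Otsu-binarized over in-brain covered voxels, and reduced to region mean
    intensities.
    """
    log = log if log is not None else []
    vols, covs = [], []
    for st in stacks:
        vol, cov = interpolate_stack(st, annotation.grid.shape, annotation.voxel_size)
        vols.append(vol)
        covs.append(cov)
    combined, coverage = combine_experiments(vols, covs)
    thr = otsu_threshold(combined, annotation, coverage)
    log.append(f"{marker}: Otsu threshold {thr:.6g} over {len(stacks)} experiment(s)")
    binarized = binarize(combined, thr)
    return region_mean_intensity(binarized, annotation, hierarchy, coverage, marker)


def fit_transfer_functions(
    intensities: Mapping[str, RegionIntensity],
    region_literature: Mapping,
    volumes_total: Mapping[int, float],
    groups: Mapping[int, str],
    hierarchy: RegionHierarchy | None = None,
    purely_inhibitory: Iterable[int] = (),
    log: list | None = None,
) -> tuple[dict[tuple[str, str], TransferFunction], dict[tuple[str, str], list[FitPoint]]]:
    """Per-(marker, group) through-origin fits with pooled-per-marker fallback.

    Regions whose subtree straddles a group boundary (ancestors of the
    cerebellum or isocortex roots) mix heterogeneous intensity/density
    relations and are left out of the fitting; their estimates come from
    aggregation.  A group without at least two usable points falls back to
    the fit pooled over all groups of that marker (logged); a marker with
    fewer than two points overall gets no transfer function and its
    uncovered regions resolve by aggregation downstream.
    """
    log = log if log is not None else []
    zero_inh = set()
    for (rid, mk), lit in region_literature.items():
        if mk == "GAD67" and lit.eta == 0:
            zero_inh.add(rid)
    if hierarchy is not None:
        for rid in hierarchy.ids:
            if len({groups[s] for s in hierarchy.subtree(rid)}) > 1:
                zero_inh.add(rid)  # straddles groups: not a fit point
    fits: dict[tuple[str, str], TransferFunction] = {}
    points_by_key: dict[tuple[str, str], list[FitPoint]] = {}
    for marker in MARKERS:
        ri = intensities.get(marker)
        if ri is None:
            log.append(f"{marker}: no expression data; no transfer function")
            continue
        points = build_fit_points(
            ri, region_literature, volumes_total, marker,
            purely_inhibitory=purely_inhibitory, zero_inhibitory=zero_inh,
        )
        pooled = fit_alpha(points, marker, "all") if len(points) >= 2 else None
        for group in GROUPS:
            gpts = [p for p in points if groups[p.region_id] == group]
            points_by_key[(marker, group)] = gpts
            if len(gpts) >= 2:
                fits[(marker, group)] = fit_alpha(gpts, marker, group)
            elif pooled is not None:
                log.append(f"{marker}/{group}: {len(gpts)} point(s); pooled fit used")
                fits[(marker, group)] = TransferFunction(
                    marker, group, pooled.alpha, pooled.std_alpha, pooled.n_points, pooled.r2
                )
            else:
                log.append(f"{marker}/{group}: insufficient fit data; no prediction")
    return fits, points_by_key


@dataclass
class PipelineResult:
    hierarchy: RegionHierarchy
    volumes_own: dict[int, float]
    volumes_total: dict[int, float]
    nneu_own: dict[int, float]
    nneu_total: dict[int, float]
    groups: dict[int, str]
    intensities: dict[str, RegionIntensity]
    region_literature: dict
    fits: dict[tuple[str, str], TransferFunction]
    fit_points: dict[tuple[str, str], list[FitPoint]]
    estimates: EstimateSet
    problem: LPProblem
    solution: LPSolution
    corrections: pd.DataFrame
    residuals: dict[str, dict[int, float]]
    log: list[str] = field(default_factory=list)

    def density(self, rid: int, type_: str) -> float:
        """Consistent density (cells/mm**3) of one type in one region."""
        vol = self.volumes_total[rid]
        return self.solution.x[(rid, type_)] / vol if vol > 0 else 0.0


def run_density_pipeline(
    hierarchy: RegionHierarchy,
    annotation: AnnotationVolume,
    records: Sequence[LiteratureRecord],
    nneu_own: Mapping[int, float],
    stacks: Mapping[str, Sequence[SliceStack]] | None = None,
    intensities: Mapping[str, RegionIntensity] | None = None,
    cell_counts: Mapping[int, float] | None = None,
    purely_inhibitory: Iterable[int] = (),
    cerebellum_acronym: str = "CB",
    isocortex_acronym: str = "Isocortex",
    sigma_floor_fraction: float = 0.1,
    outlier_ratio: float = 5.0,
    drop_sources: Iterable[str] = (),
    lp_rtol: float = 1e-7,
) -> PipelineResult:
    """Steps 3-4: estimates for every (region, type) reconciled by the LP.

    ``nneu_own`` are the own-voxel neuron counts from the density stage
    (assumed correct); expression enters either as raw ``stacks`` or as
    precomputed ``intensities``.
    """
    log: list[str] = []
    volumes_own = region_volumes(annotation, hierarchy, hierarchical=False)
    volumes_total = region_volumes(annotation, hierarchy, hierarchical=True)
    nneu_own = {rid: float(nneu_own.get(rid, 0.0)) for rid in hierarchy.ids}
    nneu_total = aggregate_to_parents(nneu_own, hierarchy)
    groups = assign_groups(hierarchy, cerebellum_acronym, isocortex_acronym)

    if intensities is None:
        intensities = {}
        for marker, marker_stacks in (stacks or {}).items():
            if marker_stacks:
                intensities[marker] = process_marker(
                    marker_stacks, annotation, hierarchy, marker, log
                )
    else:
        intensities = dict(intensities)

    pure_records, pure_flags = purely_inhibitory_records(
        purely_inhibitory, nneu_total, hierarchy
    )
    all_records = list(records) + pure_records
    region_literature = build_region_literature(
        all_records,
        hierarchy,
        volumes_total,
        neuron_counts=nneu_total,
        cell_counts=cell_counts,
        sigma_floor_fraction=sigma_floor_fraction,
        outlier_ratio=outlier_ratio,
        drop_sources=drop_sources,
    )
    for lit in region_literature.values():
        for src, reason in lit.excluded:
            log.append(f"excluded {src} for region {lit.region_id}/{lit.marker}: {reason}")

    fits, fit_points = fit_transfer_functions(
        intensities, region_literature, volumes_total, groups, hierarchy,
        pure_flags, log,
    )
    estimates = assemble_estimates(
        hierarchy, region_literature, intensities, fits, groups,
        volumes_total, volumes_own, sigma_floor_fraction, log,
    )
    init = initial_solution(estimates, nneu_own, log)
    problem = build_lp(estimates, nneu_total, nneu_own, sigma_floor_fraction)
    solution = solve_lp(problem, initial=init, rtol=lp_rtol)
    corrections = flag_corrections(solution, estimates)
    residuals = derive_residuals(solution, nneu_total)
    return PipelineResult(
        hierarchy=hierarchy,
        volumes_own=volumes_own,
        volumes_total=volumes_total,
        nneu_own=nneu_own,
        nneu_total=nneu_total,
        groups=groups,
        intensities=intensities,
        region_literature=dict(region_literature),
        fits=fits,
        fit_points=fit_points,
        estimates=estimates,
        problem=problem,
        solution=solution,
        corrections=corrections,
        residuals=residuals,
        log=log,
    )


def consistent_counts_table(result: PipelineResult) -> pd.DataFrame:
    """Per-region output table: counts, densities, sigmas, provenance, flags."""
    h = result.hierarchy
    flags = {
        (int(r.region_id), r.type): bool(r.flagged)
        for r in result.corrections.itertuples()
    }
    rows = []
    for rid in h.ids:
        vol = result.volumes_total[rid]
        row = {
            "region_id": rid,
            "acronym": h[rid].acronym,
            "name": h[rid].name,
            "volume_mm3": vol,
            "nNeu": result.nneu_total[rid],
        }
        for t in ("GAD67", "PV", "SST", "VIP"):
            est = result.estimates.totals[(rid, t)]
            x = result.solution.x[(rid, t)]
            row[f"{t}_count"] = x
            row[f"{t}_density"] = x / vol if vol > 0 else 0.0
            row[f"{t}_sigma"] = est.sigma
            row[f"{t}_provenance"] = est.provenance
            row[f"{t}_flagged"] = flags[(rid, t)]
        row["nRest"] = result.residuals["nRest"][rid]
        row["nExcOther"] = result.residuals["nExcOther"][rid]
        rows.append(row)
    return pd.DataFrame(rows)
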