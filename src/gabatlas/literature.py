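"""Literature-record normalization, exclusion rules, and coverage statistics.

Published measurements of inhibitory neuron numbers are heterogeneous: some
report densities (cells/mm**3), some absolute counts, some percentages of
neurons or of all cells in a region.  This module converts them all to the
canonical internal unit — counts per region — using the annotated region
volumes and the neuron/cell count tables, applies the conflicting-source
exclusion rule (a source is dropped when its mean is at least 5x larger or
smaller than every other source for the same region), emits the synthetic
GAD67 records for regions treated as purely inhibitory, and summarizes
per-marker coverage and between-source variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionHierarchy

__all__ = [
    "MARKERS",
    "LiteratureRecord",
    "RegionLiterature",
    "to_count",
    "to_density",
    "exclude_outliers",
    "aggregate_region",
    "build_region_literature",
    "purely_inhibitory_records",
    "coverage_summary",
    "read_literature_csv",
    "write_literature_csv",
    "parse_review_excel",
]

MARKERS = ("GAD67", "PV", "SST", "VIP")
KINDS = ("density", "count", "pct_neurons", "pct_cells")

PURELY_INHIBITORY_SOURCE = "purely-inhibitory-rule"


@dataclass
class LiteratureRecord:
    """One published measurement for a (region, marker) pair."""

    source_id: str
    marker: str
    region_id: int
    kind: str  # density | count | pct_neurons | pct_cells
    value: float
    std: float | None = None
    notes: str = ""

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        self.value = float(self.value)
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"value must be finite and >= 0, got {self.value}")
        if self.kind.startswith("pct") and not 0 <= self.value <= 100:
            raise ValueError(f"percentage out of [0, 100]: {self.value}")
        if self.std is not None:
            self.std = float(self.std)
            if not np.isfinite(self.std) or self.std < 0:
                raise ValueError(f"std must be finite and >= 0, got {self.std}")


@dataclass
class RegionLiterature:
    """Aggregated literature estimate for one (region, marker) pair."""

    region_id: int
    marker: str
    eta: float  # mean count
    sigma: float  # std of the count
    sources: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...] = ()  # (source, reason)
    purely_inhibitory: bool = False


def to_count(
    record: LiteratureRecord,
    region_volumes: Mapping[int, float],
    neuron_counts: Mapping[int, float] | None = None,
    cell_counts: Mapping[int, float] | None = None,
) -> tuple[float, float | None]:
    """Convert one record to (mean count, std count) for its region.

    Densities are multiplied by the annotated region volume (mm**3);
    percentages by the reference neuron or cell count / 100; the std is
    transformed by the same linear factor.  An absent std stays absent.
    """
    rid = record.region_id
    if record.kind == "count":
        factor = 1.0
    elif record.kind == "density":
        vol = region_volumes.get(rid, 0.0)
        if vol <= 0:
            raise ValueError(
                f"density record for region {rid} with zero annotated volume"
            )
        factor = vol
    elif record.kind == "pct_neurons":
        if neuron_counts is None or rid not in neuron_counts:
            raise ValueError(f"pct_neurons record for region {rid} without nNeu")
        factor = neuron_counts[rid] / 100.0
    else:  # pct_cells
        if cell_counts is None or rid not in cell_counts:
            raise ValueError(f"pct_cells record for region {rid} without cell count")
        factor = cell_counts[rid] / 100.0
    std = None if record.std is None else record.std * factor
    return record.value * factor, std


def to_density(
    record: LiteratureRecord,
    region_volumes: Mapping[int, float],
    neuron_counts: Mapping[int, float] | None = None,
    cell_counts: Mapping[int, float] | None = None,
) -> tuple[float, float | None]:
    """Convert one record to (mean density, std density) in cells/mm**3."""
    vol = region_volumes.get(record.region_id, 0.0)
    if vol <= 0:
        raise ValueError(
            f"cannot express region {record.region_id} on density scale: zero volume"
        )
    cnt, std = to_count(record, region_volumes, neuron_counts, cell_counts)
    return cnt / vol, None if std is None else std / vol


def exclude_outliers(
    records: Sequence[LiteratureRecord],
    means: Sequence[float],
    ratio: float = 5.0,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Conflicting-source rule for one (region, marker) group.

    A record is excluded iff its mean is at least ``ratio`` times bigger than
    every other source's mean, or at least ``ratio`` times smaller.  Returns
    (kept indices, [(excluded index, reason)]).  Order-independent; with a
    single record nothing is excluded.
    """
    n = len(records)
    if n != len(means):
        raise ValueError("records and means differ in length")
    if n < 2:
        return list(range(n)), []
    kept, excluded = [], []
    for i, m in enumerate(means):
        others = [means[j] for j in range(n) if j != i]
        if all(o > 0 and m >= ratio * o for o in others):
            excluded.append((i, f"mean {m:.6g} at least {ratio:g}x above all other sources"))
        elif m >= 0 and all(m * ratio <= o for o in others) and any(o > 0 for o in others):
            excluded.append((i, f"mean {m:.6g} at least {ratio:g}x below all other sources"))
        else:
            kept.append(i)
    if not kept:  # all mutually conflicting: keep everything rather than nothing
        return list(range(n)), []
    return kept, excluded


def aggregate_region(
    counts: Sequence[tuple[float, float | None]],
    sigma_floor_fraction: float = 0.1,
) -> tuple[float, float]:
    """Average the kept sources of one (region, marker) pair.

    eta is the arithmetic mean of the source means; sigma the arithmetic
    mean of the available source stds.  When no source reports a std,
    sigma = sigma_floor_fraction * eta (the downstream optimization weights
    by 1/sigma, so sigma must not vanish silently).
    """
    if not counts:
        raise ValueError("aggregate_region needs at least one record")
    means = [m for m, _ in counts]
    stds = [s for _, s in counts if s is not None]
    eta = float(np.mean(means))
    sigma = float(np.mean(stds)) if stds else sigma_floor_fraction * eta
    return eta, sigma


def purely_inhibitory_records(
    region_ids: Iterable[int],
    neuron_counts: Mapping[int, float],
    hierarchy: RegionHierarchy,
) -> tuple[list[LiteratureRecord], set[int]]:
    """Synthetic GAD67 records for regions whose neurons are all GABAergic.

    Layer 1 of the isocortex, the cerebellar molecular layer and the thalamic
    reticular nucleus (configurable upstream) get nGAD = nNeu.  The returned
    region set must be excluded from transfer-function fitting.
    """
    records, flagged = [], set()
    for rid in region_ids:
        if rid not in hierarchy:
            raise ValueError(f"unknown purely-inhibitory region id {rid}")
        if rid not in neuron_counts:
            raise ValueError(f"no neuron count for purely-inhibitory region {rid}")
        records.append(
            LiteratureRecord(
                source_id=PURELY_INHIBITORY_SOURCE,
                marker="GAD67",
                region_id=rid,
                kind="count",
                value=neuron_counts[rid],
                std=None,
                notes="nGAD set to nNeu",
            )
        )
        flagged.add(rid)
    return records, flagged


def build_region_literature(
    records: Sequence[LiteratureRecord],
    hierarchy: RegionHierarchy,
    region_volumes: Mapping[int, float],
    neuron_counts: Mapping[int, float] | None = None,
    cell_counts: Mapping[int, float] | None = None,
    sigma_floor_fraction: float = 0.1,
    outlier_ratio: float = 5.0,
    drop_sources: Iterable[str] = (),
) -> dict[tuple[int, str], RegionLiterature]:
    """Full normalization: convert, exclude, aggregate per (region, marker).

    ``drop_sources`` removes a source everywhere (the whole-source removal
    variant of the exclusion rule).
    """
    drop = set(drop_sources)
    groups: dict[tuple[int, str], list[LiteratureRecord]] = {}
    dropped: dict[tuple[int, str], list[tuple[str, str]]] = {}
    for rec in records:
        if rec.region_id not in hierarchy:
            raise ValueError(f"record region {rec.region_id} not in hierarchy")
        key = (rec.region_id, rec.marker)
        if rec.source_id in drop:
            dropped.setdefault(key, []).append((rec.source_id, "source dropped globally"))
            continue
        groups.setdefault(key, []).append(rec)

    out: dict[tuple[int, str], RegionLiterature] = {}
    for key, recs in groups.items():
        counts = [to_count(r, region_volumes, neuron_counts, cell_counts) for r in recs]
        kept_idx, excl_idx = exclude_outliers(recs, [c[0] for c in counts], outlier_ratio)
        excl = list(dropped.get(key, ())) + [
            (recs[i].source_id, reason) for i, reason in excl_idx
        ]
        kept_counts = [counts[i] for i in kept_idx]
        eta, sigma = aggregate_region(kept_counts, sigma_floor_fraction)
        out[key] = RegionLiterature(
            region_id=key[0],
            marker=key[1],
            eta=eta,
            sigma=sigma,
            sources=tuple(recs[i].source_id for i in kept_idx),
            excluded=tuple(excl),
            purely_inhibitory=any(
                recs[i].source_id == PURELY_INHIBITORY_SOURCE for i in kept_idx
            ),
        )
    return out


def coverage_summary(
    records: Sequence[LiteratureRecord],
    hierarchy: RegionHierarchy,
    region_volumes: Mapping[int, float],
    neuron_counts: Mapping[int, float] | None = None,
    cell_counts: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Per-marker coverage and between-source variability summary.

    For each marker: number of distinct sources, number (and fraction) of
    hierarchy regions covered, and — over regions with at least two sources —
    the per-region coefficient of variation of the source means on the
    density scale, its median, and the skewness of the CV distribution
    s = (1/n) sum(((CV - mean) / std)**3) (the moment skewness, computed with
    ``scipy.stats.skew``).  Skewness is NaN when fewer than 2 CVs exist.
    """
    rows = []
    for marker in MARKERS:
        recs = [r for r in records if r.marker == marker]
        sources = {r.source_id for r in recs}
        regions = {r.region_id for r in recs}
        by_region: dict[int, dict[str, list[float]]] = {}
        for r in recs:
            try:
                dens, _ = to_density(r, region_volumes, neuron_counts, cell_counts)
            except ValueError:
                continue  # zero-volume region: counts only for coverage
            by_region.setdefault(r.region_id, {}).setdefault(r.source_id, []).append(dens)
        cvs = []
        for rid, per_source in by_region.items():
            source_means = [float(np.mean(v)) for v in per_source.values()]
            if len(source_means) >= 2 and np.mean(source_means) > 0:
                cvs.append(np.std(source_means, ddof=1) / np.mean(source_means))
        rows.append(
            {
                "marker": marker,
                "n_sources": len(sources),
                "n_regions": len(regions),
                "region_fraction": len(regions) / len(hierarchy),
                "n_cv_regions": len(cvs),
                "median_cv": float(np.median(cvs)) if cvs else np.nan,
                "cv_skewness": float(stats.skew(cvs, bias=True)) if len(cvs) >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["source", "marker", "region_id", "kind", "value", "std", "notes"]


def write_literature_csv(path, records: Sequence[LiteratureRecord]) -> None:
    pd.DataFrame(
        [
            {
                "source": r.source_id,
                "marker": r.marker,
                "region_id": r.region_id,
                "kind": r.kind,
                "value": r.value,
                "std": "" if r.std is None else r.std,
                "notes": r.notes,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)


def read_literature_csv(path, hierarchy: RegionHierarchy | None = None) -> list[LiteratureRecord]:
    """Read the package's literature table (columns source, marker, region_id,
    kind, value, std, notes; region may alternatively be given as acronym)."""
    df = pd.read_csv(path)
    acr = hierarchy.acronym_to_id() if hierarchy is not None else {}
    out = []
    for _, row in df.iterrows():
        rid = row.get("region_id")
        if pd.isna(rid) and "region" in df.columns:
            rid = acr[str(row["region"])]
        std = row.get("std")
        out.append(
            LiteratureRecord(
                source_id=str(row["source"]),
                marker=str(row["marker"]),
                region_id=int(rid),
                kind=str(row["kind"]),
                value=float(row["value"]),
                std=None if pd.isna(std) or std == "" else float(std),
                notes="" if pd.isna(row.get("notes")) else str(row.get("notes")),
            )
        )
    return out


_COLUMN_ALIASES = {
    "source": ("source", "reference", "citation", "paper", "source_id"),
    "marker": ("marker", "gene", "cell type", "celltype"),
    "region": ("region", "acronym", "brain region", "region acronym"),
    "region_id": ("region_id", "region id", "id"),
    "kind": ("kind", "type", "measurement", "measurement type", "unit"),
    "value": ("value", "mean", "mean value", "density"),
    "std": ("std", "sd", "stdev", "standard deviation", "sem"),
    "notes": ("notes", "comment", "comments"),
}

_KIND_PATTERNS = (
    ("pct_neurons", ("% neuron", "percentage of neurons", "pct_neurons", "% of neurons")),
    ("pct_cells", ("% cell", "percentage of cells", "pct_cells", "% of cells")),
    ("density", ("density", "cells/mm", "mm^-3", "mm-3", "/mm3", "mm3")),
    ("count", ("count", "number", "cells", "absolute")),
)


def parse_review_excel(path, hierarchy: RegionHierarchy, sheet=0) -> list[LiteratureRecord]:
    """Parse a literature-review spreadsheet in the published supplementary
    layout (one row per measurement; columns for source, marker, region
    acronym, measurement type, value and std).

    Column headers are matched case-insensitively against common aliases and
    the measurement type is classified from its wording, so minor layout
    variations between review versions parse unchanged.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    cols = {str(c).strip().lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for target, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in cols:
                resolved[target] = cols[a]
                break
    for required in ("source", "marker", "value"):
        if required not in resolved:
            raise ValueError(f"review table is missing a {required!r} column")
    acr = hierarchy.acronym_to_id()
    out = []
    for _, row in df.iterrows():
        if "region_id" in resolved and not pd.isna(row[resolved["region_id"]]):
            rid = int(row[resolved["region_id"]])
        elif "region" in resolved:
            key = str(row[resolved["region"]]).strip()
            if key not in acr:
                continue  # region not in this hierarchy release
            rid = acr[key]
        else:
            raise ValueError("review table needs a region or region_id column")
        kind_text = str(row[resolved["kind"]]).lower() if "kind" in resolved else "density"
        kind = next(
            (k for k, pats in _KIND_PATTERNS if any(p in kind_text for p in pats)),
            "density",
        )
        marker = str(row[resolved["marker"]]).strip().upper()
        marker = {"GAD": "GAD67", "GAD1": "GAD67"}.get(marker, marker)
        if marker not in MARKERS or pd.isna(row[resolved["value"]]):
            continue
        std = row[resolved["std"]] if "std" in resolved else None
        out.append(
            LiteratureRecord(
                source_id=str(row[resolved["source"]]),
                marker=marker,
                region_id=rid,
                kind=kind,
                value=float(row[resolved["value"]]),
                std=None if std is None or pd.isna(std) else float(std),
                notes=str(row[resolved["notes"]]) if "notes" in resolved and not pd.isna(row[resolved["notes"]]) else "",
            )
        )
    return out
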