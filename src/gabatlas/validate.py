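"""Literature-robustness experiments: subsampling and hold-out validation.

Both experiments rerun the estimate-assembly and reconciliation stages with
random subsets of the literature table while the expression data stay
fixed.  The subsampling experiment measures, for fractions f of the
available records (70% up to 95%, 20 trials each), the per-region spread of
the reconciled densities across trials, and extrapolates that spread to
f = 100% — the pipeline's confidence in its final densities.  The hold-out
experiment fits on 90% of the records and compares the reconciled densities
against the withheld measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AnnotationVolume, RegionHierarchy
from .ish import RegionIntensity
from .literature import MARKERS, LiteratureRecord, to_density
from .pipeline import run_density_pipeline

__all__ = ["subsampling_experiment", "holdout_experiment"]


def _subset_records(
    records: Sequence[LiteratureRecord],
    n_keep: int,
    rng: np.random.Generator,
    max_attempts: int = 50,
    log: list | None = None,
) -> list[LiteratureRecord]:
    """Random subset keeping every marker represented (resampled if not)."""
    markers_present = {m for m in MARKERS if any(r.marker == m for r in records)}
    for attempt in range(max_attempts):
        idx = rng.permutation(len(records))[:n_keep]
        subset = [records[i] for i in idx]
        if {r.marker for r in subset} >= markers_present:
            if attempt and log is not None:
                log.append(f"subset resampled {attempt} time(s) to keep all markers")
            return subset
    raise RuntimeError("could not draw a subset covering every marker")


def subsampling_experiment(
    hierarchy: RegionHierarchy,
    annotation: AnnotationVolume,
    records: Sequence[LiteratureRecord],
    nneu_own: Mapping[int, float],
    intensities: Mapping[str, RegionIntensity],
    fractions: Sequence[float] = (0.70, 0.80, 0.90, 0.95),
    trials: int = 20,
    seed: int = 0,
    **pipeline_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Density spread sigma(r, f) across literature subsets, per fraction.

    Returns ``(per_fraction, extrapolated)``: the first frame holds, per
    (region, type, fraction), the across-trial standard deviation of the
    reconciled density and its mean; the second the per-(region, type)
    least-squares extrapolation of sigma to f = 1 (floored at 0).
    """
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if trials < 2:
        raise ValueError("need at least 2 trials per fraction")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 401]))
    log: list[str] = []
    rows = []
    keys = None
    for f in fractions:
        n_keep = max(1, int(round(f * len(records))))
        dens_per_trial = []
        for _ in range(trials):
            subset = _subset_records(records, n_keep, rng, log=log)
            result = run_density_pipeline(
                hierarchy, annotation, subset, nneu_own,
                intensities=intensities, **pipeline_kwargs,
            )
            if keys is None:
                keys = sorted(result.solution.x)
            dens_per_trial.append(
                [result.solution.x[k] / max(result.volumes_total[k[0]], 1e-300) for k in keys]
            )
        arr = np.asarray(dens_per_trial)  # trials x keys
        sd = arr.std(axis=0, ddof=1)
        mean = arr.mean(axis=0)
        for (rid, t), s, m in zip(keys, sd, mean):
            rows.append(
                {"region_id": rid, "type": t, "fraction": f,
                 "sigma_density": float(s), "mean_density": float(m)}
            )
    per_fraction = pd.DataFrame(rows)
    extr_rows = []
    for (rid, t), grp in per_fraction.groupby(["region_id", "type"]):
        if grp["fraction"].nunique() >= 2:
            fit = stats.linregress(grp["fraction"], grp["sigma_density"])
            at_full = float(fit.intercept + fit.slope)
        else:  # single fraction: no trend to extrapolate
            at_full = float(grp["sigma_density"].mean())
        extr_rows.append(
            {"region_id": rid, "type": t, "sigma_at_full": max(0.0, at_full)}
        )
    extrapolated = pd.DataFrame(extr_rows)
    per_fraction.attrs["log"] = log
    return per_fraction, extrapolated


def holdout_experiment(
    hierarchy: RegionHierarchy,
    annotation: AnnotationVolume,
    records: Sequence[LiteratureRecord],
    nneu_own: Mapping[int, float],
    intensities: Mapping[str, RegionIntensity],
    holdout: float = 0.1,
    trials: int = 5,
    seed: int = 0,
    sigma_floor_fraction: float = 0.1,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Predicted vs held-out literature densities.

    Per trial, a random ``holdout`` fraction of records is withheld, the
    pipeline runs on the rest, and each held-out record is compared with the
    reconciled density of its (region, marker).  The returned frame has one
    row per held-out record; ``attrs["within_interval_fraction"]`` is the
    share of predictions inside the held-out mean +/- std interval.
    """
    if not 0 < holdout < 1:
        raise ValueError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 419]))
    rows = []
    for trial in range(trials):
        n_keep = len(records) - max(1, int(round(holdout * len(records))))
        idx = rng.permutation(len(records))
        kept = [records[i] for i in idx[:n_keep]]
        held = [records[i] for i in idx[n_keep:]]
        result = run_density_pipeline(
            hierarchy, annotation, kept, nneu_own,
            intensities=intensities,
            sigma_floor_fraction=sigma_floor_fraction,
            **pipeline_kwargs,
        )
        for rec in held:
            vol = result.volumes_total.get(rec.region_id, 0.0)
            if vol <= 0:
                continue
            mean_d, std_d = to_density(
                rec, result.volumes_total,
                neuron_counts=result.nneu_total,
            )
            if std_d is None:
                std_d = sigma_floor_fraction * mean_d
            pred = result.solution.x[(rec.region_id, rec.marker)] / vol
            rows.append(
                {"trial": trial, "region_id": rec.region_id, "marker": rec.marker,
                 "literature_density": mean_d, "literature_std": std_d,
                 "predicted_density": pred,
                 "within": bool(abs(pred - mean_d) <= std_d)}
            )
    out = pd.DataFrame(rows)
    out.attrs["within_interval_fraction"] = float(out["within"].mean()) if len(out) else np.nan
    return out
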