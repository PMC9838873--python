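"""Linear transfer functions from region mean intensity to cell density.

For regions with no published measurement, densities are predicted from the
binarized ISH expression: the mean binarized intensity x of a region
correlates with the density y of marker-positive cells, and the simplest
monotone model is a through-origin line y = alpha * x (no expression implies
no cells, and the fit report carries only a slope).  Fits are computed per
marker and per region group — cerebellum, isocortex, and the rest of the
brain — because cerebellar densities are far higher than elsewhere and
isocortical composition is similar across its subregions.

The goodness-of-fit statistic used throughout is the explained-sum ratio

    R2 = S_model / (S_model + S_res),
    S_model = sum((f(x_i) - mean(y))**2),  S_res = sum((y_i - f(x_i))**2)

which coincides with the textbook coefficient of determination only when the
residuals are orthogonal to the fit; it is the form reported alongside the
fitted slopes and is kept as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionHierarchy
from .ish import RegionIntensity
from .literature import RegionLiterature

__all__ = [
    "GROUPS",
    "FitPoint",
    "TransferFunction",
    "assign_groups",
    "build_fit_points",
    "fit_alpha",
    "r_squared",
    "predict_density",
    "pearson_diagnostic",
    "fit_report",
]

GROUPS = ("cerebellum", "isocortex", "rest")


@dataclass(frozen=True)
class FitPoint:
    """One (region mean intensity, literature density) pair."""

    region_id: int
    marker: str
    x: float  # dimensionless, in (0, 1]
    y: float  # cells/mm**3
    weight: float = 1.0

    def __post_init__(self):
        if not self.x > 0:
            raise ValueError("fit points require x > 0 (zero-intensity regions are excluded)")
        if self.y < 0:
            raise ValueError("literature density must be >= 0")


@dataclass
class TransferFunction:
    marker: str
    group: str
    alpha: float  # cells/mm**3 per unit intensity
    std_alpha: float
    n_points: int
    r2: float | None

    def __call__(self, intensity: float) -> float:
        return self.alpha * intensity


def assign_groups(
    hierarchy: RegionHierarchy,
    cerebellum_acronym: str = "CB",
    isocortex_acronym: str = "Isocortex",
) -> dict[int, str]:
    """Map every region to cerebellum / isocortex / rest by subtree membership."""
    try:
        cb_root = hierarchy.find_acronym(cerebellum_acronym)
        iso_root = hierarchy.find_acronym(isocortex_acronym)
    except KeyError as e:
        raise ValueError(f"designated group root missing from hierarchy: {e}") from e
    groups = {rid: "rest" for rid in hierarchy.ids}
    for rid in hierarchy.subtree(cb_root):
        groups[rid] = "cerebellum"
    for rid in hierarchy.subtree(iso_root):
        groups[rid] = "isocortex"
    return groups


def build_fit_points(
    region_intensities: RegionIntensity,
    region_literature: Mapping[tuple[int, str], RegionLiterature],
    region_volumes: Mapping[int, float],
    marker: str,
    purely_inhibitory: Iterable[int] = (),
    zero_inhibitory: Iterable[int] = (),
) -> list[FitPoint]:
    """One point per literature-covered region, on the density scale.

    Excluded: regions with null mean intensity (misalignment / coverage
    artifacts), purely-inhibitory regions (their nGAD comes from neuron
    counts, not from expression) and regions with no inhibitory neurons.
    All points carry the same weight.
    """
    skip = set(purely_inhibitory) | set(zero_inhibitory)
    points = []
    for (rid, mk), lit in region_literature.items():
        if mk != marker or rid in skip or lit.purely_inhibitory:
            continue
        if not region_intensities.covered(rid):
            continue
        x = region_intensities[rid]
        if x <= 0:
            continue
        vol = region_volumes.get(rid, 0.0)
        if vol <= 0:
            continue
        points.append(FitPoint(region_id=rid, marker=marker, x=x, y=lit.eta / vol))
    return points


def fit_alpha(
    points: Sequence[FitPoint],
    marker: str = "",
    group: str = "",
) -> TransferFunction:
    """Through-origin least squares: alpha = sum(x*y) / sum(x**2).

    The slope uncertainty is the standard error of the through-origin
    estimator, std_alpha = sqrt(sum((y - alpha*x)**2) / ((n-1) * sum(x**2)));
    a pathological negative slope is clipped to 0 with a warning (densities
    cannot be negative).
    """
    if len(points) < 2:
        raise ValueError("insufficient fit data: need at least 2 points")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("insufficient fit data: all intensities are 0")
    alpha = float(np.sum(x * y) / sxx)
    resid = y - alpha * x
    std_alpha = float(np.sqrt(np.sum(resid**2) / ((len(points) - 1) * sxx)))
    if alpha < 0:
        warnings.warn(
            f"negative fitted slope {alpha:.4g} for {marker}/{group}; clipped to 0",
            stacklevel=2,
        )
        alpha = 0.0
    tf = TransferFunction(
        marker=marker, group=group, alpha=alpha, std_alpha=std_alpha,
        n_points=len(points), r2=None,
    )
    tf.r2 = r_squared(tf, x, y)
    return tf


def r_squared(f: Callable[[float], float], x, y) -> float | None:
    """Explained-sum ratio S_model / (S_model + S_res) (see module docstring).

    Returns None (flagged undefined) when both sums vanish, i.e. f is the
    constant mean of y and fits perfectly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fx = np.array([f(v) for v in x], dtype=float)
    s_model = float(np.sum((fx - y.mean()) ** 2))
    s_res = float(np.sum((y - fx) ** 2))
    if s_model + s_res == 0:
        return None
    return s_model / (s_model + s_res)


def predict_density(
    tf: TransferFunction,
    intensity: float,
    region_volume: float,
) -> tuple[float, float]:
    """Predicted (eta, sigma) counts for a region without literature.

    eta = alpha * intensity * volume; sigma propagates the slope uncertainty,
    sigma = std_alpha * intensity * volume.
    """
    if intensity < 0 or region_volume < 0:
        raise ValueError("intensity and volume must be >= 0")
    return tf.alpha * intensity * region_volume, tf.std_alpha * intensity * region_volume


def pearson_diagnostic(points: Sequence[FitPoint]) -> float:
    """Pearson correlation between intensities and literature densities."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic)


def fit_report(fits: Mapping[tuple[str, str], TransferFunction]) -> pd.DataFrame:
    """Tabular fit report: marker x group -> alpha, std_alpha, R2, n_points."""
    rows = [
        {
            "marker": tf.marker,
            "group": tf.group,
            "alpha": tf.alpha,
            "std_alpha": tf.std_alpha,
            "r_squared": np.nan if tf.r2 is None else tf.r2,
            "n_points": tf.n_points,
        }
        for tf in fits.values()
    ]
    return pd.DataFrame(rows).set_index(["marker", "group"]).sort_index()
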