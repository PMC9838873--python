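"""Reconciliation of per-region type estimates into consistent counts.

The unconstrained estimates eta (with uncertainty sigma) for the four
inhibitory populations — GAD67 (all GABAergic), PV, SST, VIP — come from
independent sources (literature averages, transfer-function predictions,
child aggregation) and can contradict each other or the neuron counts.
Consistency means, for every region r:

    bounds      0 <= n_t(r) <= nNeu(r)                         for each type t
    subtype sum 0 <= nGAD(r) - (nPV + nSST + nVIP)(r) <= nNeu(r)
    hierarchy   n_t(parent) = n_t(own voxels) + sum over children of n_t

The corrected counts x minimize the total correction weighted by confidence,
sum(|x - eta| / sigma), a convex piecewise-linear objective turned into a
linear program with slack variables z >= |x - eta|.  A greedy feasibility
pre-pass (cap-to-neurons, then coherence restoration; both walk regions
deepest-first and prefer staying within eta +/- sigma while preserving the
PV:SST:VIP proportions) provides a feasible reference point whose objective
the LP must match or beat.

Regions carry one "total" variable per type (the region as a subtree) and,
for regions with children, one "own-voxel" variable per type for the voxels
labeled with the parent id itself; the hierarchy constraint links the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import brentq, linprog

from .atlas import RegionHierarchy, aggregate_to_parents, depth_ordering
from .ish import RegionIntensity
from .literature import RegionLiterature
from .transfer import TransferFunction, predict_density

__all__ = [
    "TYPES",
    "DensityEstimate",
    "EstimateSet",
    "LPProblem",
    "LPSolution",
    "assemble_estimates",
    "cap_to_neurons",
    "enforce_coherence",
    "initial_solution",
    "build_lp",
    "solve_lp",
    "flag_corrections",
    "derive_residuals",
    "write_lp_dump",
]

TYPES = ("GAD67", "PV", "SST", "VIP")
SUBTYPES = ("PV", "SST", "VIP")


@dataclass
class DensityEstimate:
    """Unconstrained count estimate for one (region, type)."""

    region_id: int
    type: str
    eta: float
    sigma: float
    provenance: str  # literature | fitted | purely-inhibitory | aggregated

    def __post_init__(self):
        if self.type not in TYPES:
            raise ValueError(f"unknown type {self.type!r}")
        if not (np.isfinite(self.eta) and np.isfinite(self.sigma)):
            raise ValueError("eta and sigma must be finite")
        if self.eta < 0 or self.sigma < 0:
            raise ValueError("eta and sigma must be >= 0")

    @property
    def interval(self) -> tuple[float, float]:
        return max(self.eta - self.sigma, 0.0), self.eta + self.sigma


class EstimateSet:
    """Estimates for every (region, type): totals plus parents' own-voxel parts."""

    def __init__(
        self,
        totals: Mapping[tuple[int, str], DensityEstimate],
        own: Mapping[tuple[int, str], DensityEstimate],
        hierarchy: RegionHierarchy,
    ):
        self.totals = dict(totals)
        self.own = dict(own)
        self.hierarchy = hierarchy
        missing = [
            (r, t) for r in hierarchy.ids for t in TYPES if (r, t) not in self.totals
        ]
        if missing:
            raise ValueError(f"missing total estimates for {missing[:5]}...")
        parents = [r for r in hierarchy.ids if not hierarchy.is_leaf(r)]
        missing_own = [(r, t) for r in parents for t in TYPES if (r, t) not in self.own]
        if missing_own:
            raise ValueError(f"missing own-voxel estimates for {missing_own[:5]}...")

    def __len__(self) -> int:
        return len(self.totals)


def _sigma_floor(eta: float, sigma: float, fraction: float) -> float:
    return max(sigma, fraction * max(eta, 1.0))


def assemble_estimates(
    hierarchy: RegionHierarchy,
    region_literature: Mapping[tuple[int, str], RegionLiterature],
    intensities: Mapping[str, RegionIntensity],
    fits: Mapping[tuple[str, str], TransferFunction],
    groups: Mapping[int, str],
    volumes_total: Mapping[int, float],
    volumes_own: Mapping[int, float],
    sigma_floor_fraction: float = 0.1,
    log: list | None = None,
) -> EstimateSet:
    """Resolve (eta, sigma) for every (region, type), totals and own parts.

    Priority per (region, type): literature average (incl. the
    purely-inhibitory rule) > transfer-function prediction from the subtree
    mean intensity > aggregation of the children's estimates plus the
    own-voxel prediction.  A region with no literature, no intensity and no
    children gets eta 0 with sigma = max(eta, floor) and a logged warning.
    """
    log = log if log is not None else []
    totals: dict[tuple[int, str], DensityEstimate] = {}
    own: dict[tuple[int, str], DensityEstimate] = {}

    def predicted(rid: int, t: str, volume: float, use_own: bool) -> tuple[float, float] | None:
        ri = intensities.get(t)
        if ri is None or volume <= 0:
            return None
        sup = ri.own_support if use_own else ri.support
        vals = ri.own_mean if use_own else ri.mean
        if sup.get(rid, 0) <= 0:
            return None
        tf = fits.get((t, groups[rid]))
        if tf is None:
            return None
        return predict_density(tf, vals[rid], volume)

    for rid in depth_ordering(hierarchy):  # children resolved before parents
        for t in TYPES:
            lit = region_literature.get((rid, t))
            if lit is not None:
                prov = "purely-inhibitory" if lit.purely_inhibitory else "literature"
                totals[(rid, t)] = DensityEstimate(rid, t, lit.eta, lit.sigma, prov)
                continue
            pred = predicted(rid, t, volumes_total.get(rid, 0.0), use_own=False)
            if pred is not None:
                totals[(rid, t)] = DensityEstimate(rid, t, pred[0], pred[1], "fitted")
                continue
            kids = hierarchy.children(rid)
            if kids:
                eta = sum(totals[(c, t)].eta for c in kids)
                sigma = sum(totals[(c, t)].sigma for c in kids)
                own_pred = predicted(rid, t, volumes_own.get(rid, 0.0), use_own=True)
                if own_pred is not None:
                    eta += own_pred[0]
                    sigma += own_pred[1]
                totals[(rid, t)] = DensityEstimate(rid, t, eta, sigma, "aggregated")
            else:
                log.append(f"region {rid} type {t}: no literature, intensity or children")
                totals[(rid, t)] = DensityEstimate(
                    rid, t, 0.0, _sigma_floor(0.0, 0.0, sigma_floor_fraction), "aggregated"
                )
        if not hierarchy.is_leaf(rid):
            for t in TYPES:
                own_pred = predicted(rid, t, volumes_own.get(rid, 0.0), use_own=True)
                if own_pred is not None:
                    eta, sigma = own_pred
                    prov = "fitted"
                else:
                    # unobserved own part: weakly constrained around 0
                    eta, sigma, prov = 0.0, max(totals[(rid, t)].eta, 1.0), "aggregated"
                own[(rid, t)] = DensityEstimate(rid, t, eta, sigma, prov)
    return EstimateSet(totals, own, hierarchy)


# ---------------------------------------------------------------------------
# feasibility pre-pass (greedy initial solution)
# ---------------------------------------------------------------------------

def cap_to_neurons(
    estimates: Mapping[tuple[int, str], DensityEstimate],
    nneu: Mapping[int, float],
    regions: Iterable[int],
    values: Mapping[tuple[int, str], float] | None = None,
    tol: float = 1e-9,
    log: list | None = None,
) -> dict[tuple[int, str], float]:
    """Cap GAD67 and the PV+SST+VIP sum at the region neuron count.

    Per region (callers pass them deepest-first): the GAD67 estimate is
    clipped to nNeu within its interval when possible; an excess of the
    subtype sum over nNeu is removed proportionally to the current
    PV:SST:VIP ratios, freezing any subtype that reaches the bottom of its
    eta +/- sigma interval and redistributing the remainder.  When the
    intervals are exhausted the subtypes are rescaled below their intervals
    and the move is logged.
    """
    log = log if log is not None else []
    vals = {k: (values[k] if values is not None else est.eta) for k, est in estimates.items()}
    for rid in regions:
        cap = nneu.get(rid, 0.0)
        g = vals[(rid, "GAD67")]
        if g > cap + tol:
            lo, _ = estimates[(rid, "GAD67")].interval
            if cap < lo - tol:
                log.append(f"region {rid}: GAD67 capped to {cap:.6g} below interval [{lo:.6g}, ...]")
            vals[(rid, "GAD67")] = cap
        subtotal = sum(vals[(rid, t)] for t in SUBTYPES)
        if subtotal > cap + tol:
            active = list(SUBTYPES)
            lo = {t: estimates[(rid, t)].interval[0] for t in SUBTYPES}
            while True:
                subtotal = sum(vals[(rid, t)] for t in SUBTYPES)
                diff = subtotal - cap
                if diff <= tol or not active:
                    break
                movable = sum(vals[(rid, t)] for t in active)
                if movable <= 0:
                    break
                proposal = {t: vals[(rid, t)] * (1 - diff / movable) for t in active}
                frozen = [t for t in active if proposal[t] < lo[t] - tol]
                if not frozen:
                    for t in active:
                        vals[(rid, t)] = max(proposal[t], 0.0)
                    break
                for t in frozen:
                    vals[(rid, t)] = lo[t]
                    active.remove(t)
            subtotal = sum(vals[(rid, t)] for t in SUBTYPES)
            if subtotal > cap + max(tol, 1e-9 * max(cap, 1.0)):
                scale = cap / subtotal if subtotal > 0 else 0.0
                for t in SUBTYPES:
                    vals[(rid, t)] *= scale
                log.append(
                    f"region {rid}: subtype intervals exhausted; "
                    f"rescaled below intervals to sum {cap:.6g}"
                )
    return vals


def enforce_coherence(
    estimates: Mapping[tuple[int, str], DensityEstimate],
    nneu: Mapping[int, float],
    regions: Iterable[int],
    values: Mapping[tuple[int, str], float],
    tol: float = 1e-9,
    log: list | None = None,
) -> dict[tuple[int, str], float]:
    """Restore nGAD >= nPV + nSST + nVIP with the smallest interval fraction q.

    q in [0, 1] raises GAD67 by q*sigma_GAD (capped at its interval top and
    at nNeu) and lowers each subtype by q*sigma_t (clamped at its interval
    bottom) until the sum condition holds.  If q = 1 is insufficient the
    subtypes are rescaled proportionally to equal GAD67, logged as an
    out-of-interval move.
    """
    log = log if log is not None else []
    vals = dict(values)
    for rid in regions:
        g = vals[(rid, "GAD67")]
        s = sum(vals[(rid, t)] for t in SUBTYPES)
        if g + tol >= s:
            continue
        eg = estimates[(rid, "GAD67")]
        cap = nneu.get(rid, 0.0)
        g_hi = min(eg.interval[1], cap)
        up = max(0.0, g_hi - g)
        down = {
            t: max(0.0, vals[(rid, t)] - estimates[(rid, t)].interval[0])
            for t in SUBTYPES
        }

        def gap(q: float) -> float:
            g_q = g + min(q * eg.sigma, up)
            s_q = sum(
                vals[(rid, t)] - min(q * estimates[(rid, t)].sigma, down[t])
                for t in SUBTYPES
            )
            return g_q - s_q

        if gap(1.0) >= 0:
            q = 0.0 if gap(0.0) >= 0 else brentq(gap, 0.0, 1.0, xtol=1e-12)
            vals[(rid, "GAD67")] = g + min(q * eg.sigma, up)
            for t in SUBTYPES:
                vals[(rid, t)] -= min(q * estimates[(rid, t)].sigma, down[t])
        else:
            g_new = g + up
            s_cur = sum(vals[(rid, t)] for t in SUBTYPES)
            scale = g_new / s_cur if s_cur > 0 else 0.0
            vals[(rid, "GAD67")] = g_new
            for t in SUBTYPES:
                vals[(rid, t)] *= scale
            log.append(
                f"region {rid}: coherence unreachable within intervals (q=1); "
                f"subtypes rescaled to GAD67 = {g_new:.6g}"
            )
    return vals


def initial_solution(
    estimates: EstimateSet,
    nneu_own: Mapping[int, float],
    log: list | None = None,
) -> tuple[dict[tuple[int, str], float], dict[tuple[int, str], float]]:
    """Feasible starting point: pre-pass on own-voxel parts, then aggregation.

    Own-voxel blocks (for leaves: the region itself) are corrected
    deepest-first with the cap and coherence passes against the own-voxel
    neuron counts; totals follow by hierarchy aggregation, which preserves
    the bound and subtype-sum constraints under summation.
    """
    h = estimates.hierarchy
    order = depth_ordering(h)
    own_est = {
        (r, t): (estimates.totals[(r, t)] if h.is_leaf(r) else estimates.own[(r, t)])
        for r in h.ids
        for t in TYPES
    }
    vals = cap_to_neurons(own_est, nneu_own, order, log=log)
    vals = enforce_coherence(own_est, nneu_own, order, vals, log=log)
    x_tot: dict[tuple[int, str], float] = {}
    for t in TYPES:
        per_region = {r: vals[(r, t)] for r in h.ids}
        agg = aggregate_to_parents(per_region, h)
        for r, v in agg.items():
            x_tot[(r, t)] = v
    x_own = {k: v for k, v in vals.items() if not h.is_leaf(k[0])}
    return x_tot, x_own


# ---------------------------------------------------------------------------
# linear program
# ---------------------------------------------------------------------------

@dataclass
class LPProblem:
    """Weighted-slack LP: min sum(z / sigma) subject to consistency."""

    hierarchy: RegionHierarchy
    var_index: dict[tuple[str, int, str], int]  # ("total"|"own", region, type)
    n_x: int
    n_density_variables: int  # the per-region totals: 4 * |regions|
    eta: np.ndarray  # per x variable
    sigma: np.ndarray  # floored, per x variable
    c: np.ndarray  # objective over [x, z]
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    nneu_total: dict[int, float]
    nneu_own: dict[int, float]

    @property
    def n_variables(self) -> int:
        return 2 * self.n_x

    def objective_of(
        self,
        x_tot: Mapping[tuple[int, str], float],
        x_own: Mapping[tuple[int, str], float] | None = None,
    ) -> float:
        """Objective value of a candidate point (z set to |x - eta|)."""
        total = 0.0
        for (kind, rid, t), i in self.var_index.items():
            x = (x_tot if kind == "total" else (x_own or {})).get((rid, t))
            if x is None:
                raise ValueError(f"candidate point missing {(kind, rid, t)}")
            total += abs(x - self.eta[i]) / self.sigma[i]
        return total


def build_lp(
    estimates: EstimateSet,
    nneu_total: Mapping[int, float],
    nneu_own: Mapping[int, float],
    sigma_floor_fraction: float = 0.1,
) -> LPProblem:
    """Assemble the consistency LP from the estimate set.

    Variables: x(total) per (region, type) — 4 per region, the "density
    variables" — plus x(own) per (parent, type), plus one slack z per x.
    Constraints: 0 <= x <= nNeu (variable bounds), the two-sided subtype-sum
    inequality per region (totals) and per parent own-voxel block, the
    hierarchy equality per parent and type, and the slack envelope
    -z <= x - eta <= z.  Objective: sum of z / sigma.
    """
    h = estimates.hierarchy
    ids = h.ids
    for r in ids:
        if r not in nneu_total:
            raise ValueError(f"missing neuron count for region {r}")
    parents = [r for r in ids if not h.is_leaf(r)]
    for r in parents:
        if r not in nneu_own:
            raise ValueError(f"missing own-voxel neuron count for parent {r}")

    var_index: dict[tuple[str, int, str], int] = {}
    eta_list: list[float] = []
    sigma_list: list[float] = []
    ub_list: list[float] = []
    for r in ids:
        for t in TYPES:
            var_index[("total", r, t)] = len(eta_list)
            est = estimates.totals[(r, t)]
            eta_list.append(est.eta)
            sigma_list.append(_sigma_floor(est.eta, est.sigma, sigma_floor_fraction))
            ub_list.append(float(nneu_total[r]))
    for r in parents:
        for t in TYPES:
            var_index[("own", r, t)] = len(eta_list)
            est = estimates.own[(r, t)]
            eta_list.append(est.eta)
            sigma_list.append(_sigma_floor(est.eta, est.sigma, sigma_floor_fraction))
            ub_list.append(float(nneu_own[r]))
    n_x = len(eta_list)
    eta = np.asarray(eta_list)
    sigma = np.asarray(sigma_list)

    rows, cols, data, b_ub = [], [], [], []

    def add_row(entries: Sequence[tuple[int, float]], rhs: float) -> None:
        rix = len(b_ub)
        for j, v in entries:
            rows.append(rix)
            cols.append(j)
            data.append(v)
        b_ub.append(rhs)

    def subtype_rows(kind: str, r: int, cap: float) -> None:
        gi = var_index[(kind, r, "GAD67")]
        sub = [var_index[(kind, r, t)] for t in SUBTYPES]
        add_row([(j, 1.0) for j in sub] + [(gi, -1.0)], 0.0)  # PV+SST+VIP <= GAD
        add_row([(gi, 1.0)] + [(j, -1.0) for j in sub], cap)  # GAD - sum <= nNeu

    for r in ids:
        subtype_rows("total", r, float(nneu_total[r]))
    for r in parents:
        subtype_rows("own", r, float(nneu_own[r]))
    for i in range(n_x):  # slack envelope: x - z <= eta, -x - z <= -eta
        add_row([(i, 1.0), (n_x + i, -1.0)], float(eta[i]))
        add_row([(i, -1.0), (n_x + i, -1.0)], float(-eta[i]))
    A_ub = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(b_ub), 2 * n_x)
    ).tocsr()

    e_rows, e_cols, e_data, b_eq = [], [], [], []
    for r in parents:
        for t in TYPES:
            rix = len(b_eq)
            e_rows.append(rix); e_cols.append(var_index[("total", r, t)]); e_data.append(1.0)
            e_rows.append(rix); e_cols.append(var_index[("own", r, t)]); e_data.append(-1.0)
            for c_ in h.children(r):
                e_rows.append(rix); e_cols.append(var_index[("total", c_, t)]); e_data.append(-1.0)
            b_eq.append(0.0)
    A_eq = sparse.coo_matrix(
        (e_data, (e_rows, e_cols)), shape=(len(b_eq), 2 * n_x)
    ).tocsr()

    lb = np.zeros(2 * n_x)
    ub = np.concatenate([np.asarray(ub_list), np.full(n_x, np.inf)])
    c = np.concatenate([np.zeros(n_x), 1.0 / sigma])
    return LPProblem(
        hierarchy=h,
        var_index=var_index,
        n_x=n_x,
        n_density_variables=4 * len(ids),
        eta=eta,
        sigma=sigma,
        c=c,
        A_ub=A_ub,
        b_ub=np.asarray(b_ub),
        A_eq=A_eq,
        b_eq=np.asarray(b_eq),
        lb=lb,
        ub=ub,
        nneu_total={int(k): float(nneu_total[k]) for k in ids},
        nneu_own={int(k): float(nneu_own[k]) for k in parents},
    )


@dataclass
class LPSolution:
    x: dict[tuple[int, str], float]  # totals
    x_own: dict[tuple[int, str], float]
    z: dict[tuple[int, str], float]
    objective: float
    status: str
    initial_objective: float | None = None
    max_violation: float = 0.0


def _check_feasible(problem: LPProblem, xz: np.ndarray, rtol: float) -> float:
    scale = max(1.0, float(np.abs(problem.b_ub).max(initial=0.0)),
                float(np.abs(xz).max(initial=0.0)))
    v_ub = float(np.max(problem.A_ub @ xz - problem.b_ub, initial=0.0))
    v_eq = float(np.max(np.abs(problem.A_eq @ xz - problem.b_eq), initial=0.0)) if problem.b_eq.size else 0.0
    v_lb = float(np.max(problem.lb - xz, initial=0.0))
    finite = np.isfinite(problem.ub)
    v_b = float(np.max((xz - problem.ub)[finite], initial=0.0)) if finite.any() else 0.0
    worst = max(v_ub, v_eq, v_lb, v_b)
    if worst > rtol * scale:
        raise RuntimeError(f"solution violates constraints: {worst:.3e} (scale {scale:.3e})")
    return worst


def solve_lp(
    problem: LPProblem,
    initial: tuple[Mapping, Mapping] | None = None,
    rtol: float = 1e-7,
) -> LPSolution:
    """Solve the consistency LP (HiGHS) and validate the optimum.

    ``initial`` is an optional feasible reference point (x_tot, x_own) whose
    objective is recorded; the LP optimum is checked to not exceed it.
    x = 0 with z = eta is always feasible, so an infeasible status signals a
    malformed problem and raises.
    """
    res = linprog(
        problem.c,
        A_ub=problem.A_ub,
        b_ub=problem.b_ub,
        A_eq=problem.A_eq if problem.b_eq.size else None,
        b_eq=problem.b_eq if problem.b_eq.size else None,
        bounds=np.column_stack([problem.lb, problem.ub]),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
    worst = _check_feasible(problem, res.x, rtol)
    x_tot: dict[tuple[int, str], float] = {}
    x_own: dict[tuple[int, str], float] = {}
    z: dict[tuple[int, str], float] = {}
    for (kind, rid, t), i in problem.var_index.items():
        val = float(res.x[i])
        if kind == "total":
            x_tot[(rid, t)] = val
            z[(rid, t)] = float(res.x[problem.n_x + i])
        else:
            x_own[(rid, t)] = val
    init_obj = None
    if initial is not None:
        init_obj = problem.objective_of(initial[0], initial[1])
        if res.fun > init_obj + 1e-6 * max(1.0, abs(init_obj)):
            raise RuntimeError(
                f"LP optimum {res.fun:.6g} exceeds the initial solution's "
                f"objective {init_obj:.6g}"
            )
    return LPSolution(
        x=x_tot,
        x_own=x_own,
        z=z,
        objective=float(res.fun),
        status="optimal",
        initial_objective=init_obj,
        max_violation=worst,
    )


def flag_corrections(
    solution: LPSolution,
    estimates: EstimateSet,
) -> pd.DataFrame:
    """Per (region, type) correction flags: |x - eta| > sigma.

    The returned frame has one row per (region, type) with the correction
    size; ``attrs["region_fraction_flagged"]`` holds the fraction of regions
    with at least one flagged type.
    """
    rows = []
    flagged_regions = set()
    for (rid, t), est in estimates.totals.items():
        x = solution.x[(rid, t)]
        out = abs(x - est.eta) > est.sigma
        if out:
            flagged_regions.add(rid)
        rows.append(
            {
                "region_id": rid,
                "type": t,
                "eta": est.eta,
                "sigma": est.sigma,
                "x": x,
                "correction": x - est.eta,
                "flagged": bool(out),
                "provenance": est.provenance,
            }
        )
    df = pd.DataFrame(rows).sort_values(["region_id", "type"]).reset_index(drop=True)
    df.attrs["region_fraction_flagged"] = len(flagged_regions) / len(estimates.hierarchy)
    return df


def derive_residuals(
    solution: LPSolution,
    nneu_total: Mapping[int, float],
    rtol: float = 1e-6,
) -> dict[str, dict[int, float]]:
    """Residual populations per region from the neuron-balance identities.

    nRest = nGAD - (nPV + nSST + nVIP) and nExcOther = nNeu - nGAD; both are
    guaranteed non-negative by the LP constraints, so a violation beyond
    tolerance raises.  Tiny negative round-off is clamped to 0.
    """
    rest: dict[int, float] = {}
    excother: dict[int, float] = {}
    for rid, nn in nneu_total.items():
        g = solution.x[(rid, "GAD67")]
        s = sum(solution.x[(rid, t)] for t in SUBTYPES)
        r_val = g - s
        e_val = nn - g
        scale = max(1.0, nn)
        if r_val < -rtol * scale or e_val < -rtol * scale:
            raise ValueError(
                f"constraint violation in region {rid}: nRest={r_val:.4g}, "
                f"nExcOther={e_val:.4g}"
            )
        rest[rid] = max(r_val, 0.0)
        excother[rid] = max(e_val, 0.0)
    return {"nRest": rest, "nExcOther": excother}


def write_lp_dump(path, problem: LPProblem) -> None:
    """Human/machine-readable LP dump for cross-solver audits (CPLEX LP format)."""
    inv = {i: k for k, i in problem.var_index.items()}

    def vname(i: int) -> str:
        if i < problem.n_x:
            kind, rid, t = inv[i]
            return f"x_{kind}_{rid}_{t}"
        kind, rid, t = inv[i - problem.n_x]
        return f"z_{kind}_{rid}_{t}"

    with open(path, "w") as fh:
        fh.write("\\ gabatlas consistency LP\nMinimize\n obj:")
        terms = [
            f" + {problem.c[j]:.12g} {vname(j)}"
            for j in range(2 * problem.n_x)
            if problem.c[j] != 0
        ]
        fh.write("".join(terms) + "\nSubject To\n")
        A = problem.A_ub.tocoo()
        by_row: dict[int, list[str]] = {}
        for r, c_, v in zip(A.row, A.col, A.data):
            by_row.setdefault(int(r), []).append(f"{v:+.12g} {vname(int(c_))}")
        for r in range(problem.b_ub.size):
            fh.write(f" ub{r}: {' '.join(by_row.get(r, []))} <= {problem.b_ub[r]:.12g}\n")
        E = problem.A_eq.tocoo()
        by_row = {}
        for r, c_, v in zip(E.row, E.col, E.data):
            by_row.setdefault(int(r), []).append(f"{v:+.12g} {vname(int(c_))}")
        for r in range(problem.b_eq.size):
            fh.write(f" eq{r}: {' '.join(by_row.get(r, []))} = {problem.b_eq[r]:.12g}\n")
        fh.write("Bounds\n")
        for j in range(2 * problem.n_x):
            hi = problem.ub[j]
            hi_s = "+inf" if not np.isfinite(hi) else f"{hi:.12g}"
            fh.write(f" {problem.lb[j]:.12g} <= {vname(j)} <= {hi_s}\n")
        fh.write("End\n")
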