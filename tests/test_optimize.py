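"""Feasibility pre-pass, LP construction/solution, flags and residuals.

The solver is cross-checked against two independent oracles: a dense LP
assembled by a completely separate code path (naive loops over a variable
dictionary) and a two-stage grid search on a problem whose optimum lives in
a two-dimensional slice.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from gabatlas.atlas import parse_hierarchy
from gabatlas.optimize import (
    SUBTYPES,
    TYPES,
    DensityEstimate,
    EstimateSet,
    build_lp,
    cap_to_neurons,
    derive_residuals,
    enforce_coherence,
    flag_corrections,
    initial_solution,
    solve_lp,
    write_lp_dump,
)


def single_region_hierarchy():
    return parse_hierarchy({"id": 1, "children": []})


def est_set(hierarchy, eta, sigma=None, own_eta=None):
    """Estimates from dicts keyed (region, type); sigma defaults to 10% of eta."""
    totals = {}
    for r in hierarchy.ids:
        for t in TYPES:
            e = eta[(r, t)]
            s = (sigma or {}).get((r, t), 0.1 * max(e, 1.0))
            totals[(r, t)] = DensityEstimate(r, t, e, s, "literature")
    own = {}
    for r in hierarchy.ids:
        if not hierarchy.is_leaf(r):
            for t in TYPES:
                e = (own_eta or {}).get((r, t), 0.0)
                own[(r, t)] = DensityEstimate(r, t, e, max(e, 1.0), "aggregated")
    return EstimateSet(totals, own, hierarchy)


class TestCapToNeurons:
    def _est(self, values, sigmas):
        return {
            (1, t): DensityEstimate(1, t, v, s, "literature")
            for t, v, s in zip(TYPES, values, sigmas)
        }

    def test_proportional_subtraction_trace(self):
        # nNeu=100, subtypes (50, 40, 30) with wide intervals -> scaled by 100/120
        est = self._est([60, 50, 40, 30], [100, 100, 100, 100])
        vals = cap_to_neurons(est, {1: 100.0}, [1])
        assert vals[(1, "PV")] == pytest.approx(50 * 100 / 120)
        assert vals[(1, "SST")] == pytest.approx(40 * 100 / 120)
        assert vals[(1, "VIP")] == pytest.approx(30 * 100 / 120)

    def test_gad_clipped_within_interval(self):
        est = self._est([120, 10, 10, 10], [30, 1, 1, 1])
        vals = cap_to_neurons(est, {1: 100.0}, [1])
        assert vals[(1, "GAD67")] == 100.0  # inside [90, 150]

    def test_no_violation_is_identity(self):
        est = self._est([50, 20, 15, 10], [5, 2, 2, 2])
        vals = cap_to_neurons(est, {1: 100.0}, [1])
        for t, v in zip(TYPES, [50, 20, 15, 10]):
            assert vals[(1, t)] == v

    def test_frozen_at_interval_bottom_redistributes(self):
        # PV can only drop to 45; the rest of the excess comes from SST/VIP
        est = self._est([200, 50, 40, 30], [300, 5, 100, 100])
        vals = cap_to_neurons(est, {1: 100.0}, [1])
        assert vals[(1, "PV")] == pytest.approx(45.0)
        assert vals[(1, "SST")] + vals[(1, "VIP")] == pytest.approx(55.0)
        # remaining excess split proportionally to SST:VIP = 40:30
        assert vals[(1, "SST")] == pytest.approx(40 - 15 * 40 / 70)
        assert vals[(1, "VIP")] == pytest.approx(30 - 15 * 30 / 70)

    def test_interval_exhaustion_rescales_and_logs(self):
        est = self._est([300, 150, 100, 50], [1, 1, 1, 1])
        log = []
        vals = cap_to_neurons(est, {1: 100.0}, [1], log=log)
        assert sum(vals[(1, t)] for t in SUBTYPES) == pytest.approx(100.0)
        assert any("exhausted" in line for line in log)

    def test_within_interval_unless_logged(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals_in = rng.uniform(0, 200, 4)
            sig = rng.uniform(1, 60, 4)
            est = self._est(vals_in, sig)
            log = []
            out = cap_to_neurons(est, {1: float(rng.uniform(10, 250))}, [1], log=log)
            if not log:
                for t in TYPES:
                    lo, hi = est[(1, t)].interval
                    assert lo - 1e-9 <= out[(1, t)] <= hi + 1e-9


class TestEnforceCoherence:
    def _est(self, values, sigmas):
        return {
            (1, t): DensityEstimate(1, t, v, s, "literature")
            for t, v, s in zip(TYPES, values, sigmas)
        }

    def test_satisfied_is_identity(self):
        est = self._est([100, 30, 20, 10], [10, 5, 3, 2])
        vals = {(1, t): est[(1, t)].eta for t in TYPES}
        out = enforce_coherence(est, {1: 500.0}, [1], vals)
        assert out == vals

    def test_closed_form_half_sigma_correction(self):
        # GAD 90 +/- 10 vs subtype sum 100 with sigmas (5, 3, 2):
        # q solves 90 + 10q = 100 - 10q -> q = 1/2, both sides meet at 95
        est = self._est([90, 50, 30, 20], [10, 5, 3, 2])
        vals = {(1, t): est[(1, t)].eta for t in TYPES}
        out = enforce_coherence(est, {1: 500.0}, [1], vals)
        assert out[(1, "GAD67")] == pytest.approx(95.0, abs=1e-6)
        assert sum(out[(1, t)] for t in SUBTYPES) == pytest.approx(95.0, abs=1e-6)
        assert out[(1, "PV")] == pytest.approx(50 - 0.5 * 5, abs=1e-6)
        assert out[(1, "SST")] == pytest.approx(30 - 0.5 * 3, abs=1e-6)
        assert out[(1, "VIP")] == pytest.approx(20 - 0.5 * 2, abs=1e-6)

    def test_exhausted_intervals_rescale_to_gad(self):
        est = self._est([50, 100, 80, 60], [5, 1, 1, 1])
        vals = {(1, t): est[(1, t)].eta for t in TYPES}
        log = []
        out = enforce_coherence(est, {1: 500.0}, [1], vals, log=log)
        s = sum(out[(1, t)] for t in SUBTYPES)
        assert s == pytest.approx(out[(1, "GAD67")], rel=1e-9)
        assert any("unreachable" in line for line in log)
        # proportions preserved in the rescale branch
        assert out[(1, "PV")] / out[(1, "SST")] == pytest.approx(100 / 80)


# ---------------------------------------------------------------------------
# independent dense-LP oracle (deliberately separate assembly path)
# ---------------------------------------------------------------------------

def oracle_lp_objective(estimates: EstimateSet, nneu_total, nneu_own) -> float:
    """Naive dense formulation of the same optimization, built variable by
    variable with plain loops; shares nothing with gabatlas.optimize.build_lp
    except the mathematical definition."""
    h = estimates.hierarchy
    names = []
    for r in h.ids:
        for t in TYPES:
            names.append(("T", r, t))
    for r in h.ids:
        if h.children(r):
            for t in TYPES:
                names.append(("O", r, t))
    idx = {n: i for i, n in enumerate(names)}
    nx = len(names)
    # variables: x then z (same length)
    c = np.zeros(2 * nx)
    eta = np.zeros(nx)
    bounds = []
    for n, i in idx.items():
        kind, r, t = n
        est = estimates.totals[(r, t)] if kind == "T" else estimates.own[(r, t)]
        eta[i] = est.eta
        sig = max(est.sigma, 0.1 * max(est.eta, 1.0))
        c[nx + i] = 1.0 / sig
        cap = nneu_total[r] if kind == "T" else nneu_own[r]
        bounds.append((0.0, cap))
    bounds += [(0.0, None)] * nx

    A_ub, b_ub = [], []
    blocks = [("T", r) for r in h.ids] + [("O", r) for r in h.ids if h.children(r)]
    for kind, r in blocks:
        cap = nneu_total[r] if kind == "T" else nneu_own[r]
        row = np.zeros(2 * nx)
        for t in SUBTYPES:
            row[idx[(kind, r, t)]] = 1.0
        row[idx[(kind, r, "GAD67")]] = -1.0
        A_ub.append(row.copy())
        b_ub.append(0.0)
        A_ub.append(-row)
        b_ub.append(cap)
    for n, i in idx.items():
        row = np.zeros(2 * nx)
        row[i], row[nx + i] = 1.0, -1.0
        A_ub.append(row)
        b_ub.append(eta[i])
        row = np.zeros(2 * nx)
        row[i], row[nx + i] = -1.0, -1.0
        A_ub.append(row)
        b_ub.append(-eta[i])
    A_eq, b_eq = [], []
    for r in h.ids:
        kids = h.children(r)
        if not kids:
            continue
        for t in TYPES:
            row = np.zeros(2 * nx)
            row[idx[("T", r, t)]] = 1.0
            row[idx[("O", r, t)]] = -1.0
            for k in kids:
                row[idx[("T", k, t)]] = -1.0
            A_eq.append(row)
            b_eq.append(0.0)
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq) if A_eq else None,
                  b_eq=np.array(b_eq) if b_eq else None,
                  bounds=bounds, method="highs")
    assert res.status == 0
    return float(res.fun)


def random_toy_problem(rng):
    """Random hierarchy (<= 12 regions) with random estimates and capacities."""
    n_children = int(rng.integers(1, 4))
    doc = {"id": 1, "children": []}
    next_id = 2
    for _ in range(n_children):
        node = {"id": next_id, "children": []}
        next_id += 1
        for _ in range(int(rng.integers(0, 3))):
            node["children"].append({"id": next_id, "children": []})
            next_id += 1
        doc["children"].append(node)
    h = parse_hierarchy(doc)
    nneu_own = {r: float(rng.uniform(50, 500)) for r in h.ids}
    from gabatlas.atlas import aggregate_to_parents

    nneu_total = aggregate_to_parents(nneu_own, h)
    eta, sigma, own_eta = {}, {}, {}
    for r in h.ids:
        base = nneu_total[r]
        eta[(r, "GAD67")] = float(rng.uniform(0, 1.2) * base)
        for t in SUBTYPES:
            eta[(r, t)] = float(rng.uniform(0, 0.6) * base)
        for t in TYPES:
            sigma[(r, t)] = float(rng.uniform(0.05, 0.5) * max(eta[(r, t)], 1.0))
        if h.children(r):
            for t in TYPES:
                own_eta[(r, t)] = float(rng.uniform(0, 0.3) * nneu_own[r])
    return h, est_set(h, eta, sigma, own_eta), nneu_total, nneu_own


def two_region_deficit_problem():
    """Root + leaf with a GAD deficit; optimum lives in the leaf's (GAD, PV)
    plane (root own-voxel capacity 0, SST/VIP estimates 0)."""
    h = parse_hierarchy({"id": 1, "children": [{"id": 2, "children": []}]})
    sig = {"GAD67": 10.0, "PV": 5.0, "SST": 1.0, "VIP": 1.0}
    eta_leaf = {"GAD67": 50.0, "PV": 80.0, "SST": 0.0, "VIP": 0.0}
    eta = {}
    for t in TYPES:
        eta[(2, t)] = eta_leaf[t]
        eta[(1, t)] = eta_leaf[t]
    sigma = {(r, t): sig[t] for r in (1, 2) for t in TYPES}
    es = est_set(h, eta, sigma, own_eta={(1, t): 0.0 for t in TYPES})
    return es, {1: 100.0, 2: 100.0}, {1: 0.0, 2: 100.0}, sig, eta_leaf


def grid_search_oracle_objective(sig, eta_leaf, n=241):
    """Two-stage uniform grid over the feasible (GAD, PV) plane."""
    floors = {t: max(sig[t], 0.1 * max(eta_leaf[t], 1.0)) for t in TYPES}

    def objective(g, p):
        per_region = (abs(g - eta_leaf["GAD67"]) / floors["GAD67"]
                      + abs(p - eta_leaf["PV"]) / floors["PV"])
        return 2 * per_region  # root totals mirror the leaf

    def grid_best(g_lo, g_hi, p_lo, p_hi):
        gs = np.linspace(g_lo, g_hi, n)
        ps = np.linspace(p_lo, p_hi, n)
        G, P = np.meshgrid(gs, ps, indexing="ij")
        vals = np.where(P <= G, objective(G, P), np.inf)
        k = np.unravel_index(np.argmin(vals), vals.shape)
        return gs[k[0]], ps[k[1]], float(vals[k])

    g0, p0, _ = grid_best(0, 100, 0, 100)
    step = 100 / (n - 1)
    _, _, best = grid_best(max(g0 - step, 0), min(g0 + step, 100),
                           max(p0 - step, 0), min(p0 + step, 100))
    return best


class TestBuildLP:
    def test_single_region_structure(self):
        h = single_region_hierarchy()
        es = est_set(h, {(1, t): 10.0 for t in TYPES})
        lp = build_lp(es, {1: 100.0}, {1: 100.0})
        assert lp.n_density_variables == 4
        assert lp.n_x == 4  # no own-voxel block for a childless root
        assert lp.b_eq.size == 0
        # rows: 2 subtype-sum + 2 envelope rows per variable
        assert lp.b_ub.size == 2 + 2 * 4

    def test_hierarchy_equalities_count(self, seven_region_hierarchy):
        h = seven_region_hierarchy
        es = est_set(h, {(r, t): 10.0 for r in h.ids for t in TYPES},
                     own_eta={(r, t): 1.0 for r in (1, 2, 3) for t in TYPES})
        lp = build_lp(es, {r: 100.0 for r in h.ids}, {r: 20.0 for r in h.ids})
        assert lp.n_density_variables == 28
        assert lp.n_x == 28 + 12  # 3 parents x 4 own variables
        assert lp.b_eq.size == 12  # per parent per type

    def test_constraint_matrix_matches_hand_enumeration(self):
        """Small two-region problem: check every row against hand-built rows."""
        h = parse_hierarchy({"id": 1, "children": [{"id": 2, "children": []}]})
        es = est_set(h, {(r, t): 10.0 for r in h.ids for t in TYPES},
                     own_eta={(1, t): 2.0 for t in TYPES})
        lp = build_lp(es, {1: 100.0, 2: 60.0}, {1: 40.0, 2: 60.0})
        A = lp.A_ub.toarray()
        # first row: PV+SST+VIP - GAD <= 0 for region 1 totals
        i = {k: v for k, v in lp.var_index.items()}
        row0 = np.zeros(2 * lp.n_x)
        for t in SUBTYPES:
            row0[i[("total", 1, t)]] = 1.0
        row0[i[("total", 1, "GAD67")]] = -1.0
        np.testing.assert_array_equal(A[0], row0)
        assert lp.b_ub[0] == 0.0
        # equality block: T(1,t) - O(1,t) - T(2,t) = 0
        E = lp.A_eq.toarray()
        for k, t in enumerate(TYPES):
            row = np.zeros(2 * lp.n_x)
            row[i[("total", 1, t)]] = 1.0
            row[i[("own", 1, t)]] = -1.0
            row[i[("total", 2, t)]] = -1.0
            np.testing.assert_array_equal(E[k], row)

    def test_missing_neuron_count_rejected(self):
        h = single_region_hierarchy()
        es = est_set(h, {(1, t): 10.0 for t in TYPES})
        with pytest.raises(ValueError, match="missing neuron count"):
            build_lp(es, {}, {})


class TestSolveLP:
    def test_consistent_estimates_untouched(self, seven_region_hierarchy):
        h = seven_region_hierarchy
        own = {(r, t): 10.0 for r in h.ids for t in TYPES}
        from gabatlas.atlas import aggregate_to_parents

        eta = {}
        for t in TYPES:
            agg = aggregate_to_parents({r: own[(r, t)] for r in h.ids}, h)
            for r, v in agg.items():
                eta[(r, t)] = v
        # make GAD dominate subtypes: GAD 40 own, others 10
        for r in h.ids:
            eta[(r, "GAD67")] = eta[(r, "GAD67")] * 4
        own_eta = {(r, t): (40.0 if t == "GAD67" else 10.0) for r in (1, 2, 3) for t in TYPES}
        es = est_set(h, eta, own_eta=own_eta)
        nneu_own = {r: 200.0 for r in h.ids}
        nneu_total = aggregate_to_parents(nneu_own, h)
        sol = solve_lp(build_lp(es, nneu_total, nneu_own))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        for k, v in sol.x.items():
            assert v == pytest.approx(eta[k], abs=1e-6)

    def test_matches_independent_formulation_on_random_problems(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            h, es, nneu_total, nneu_own = random_toy_problem(rng)
            sol = solve_lp(build_lp(es, nneu_total, nneu_own))
            oracle = oracle_lp_objective(es, nneu_total, nneu_own)
            assert sol.objective == pytest.approx(oracle, abs=1e-6, rel=1e-6)

    def test_objective_not_above_prepass_initial_solution(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            h, es, nneu_total, nneu_own = random_toy_problem(rng)
            init = initial_solution(es, nneu_own)
            sol = solve_lp(build_lp(es, nneu_total, nneu_own), initial=init)
            assert sol.initial_objective is not None
            assert sol.objective <= sol.initial_objective + 1e-6

    def test_grid_search_oracle_two_region_deficit(self):
        es, nneu_total, nneu_own, sig, eta_leaf = two_region_deficit_problem()
        sol = solve_lp(build_lp(es, nneu_total, nneu_own))
        best = grid_search_oracle_objective(sig, eta_leaf)
        assert sol.objective == pytest.approx(best, abs=1e-3)

    def test_idempotent_on_own_solution(self):
        rng = np.random.default_rng(17)
        h, es, nneu_total, nneu_own = random_toy_problem(rng)
        sol = solve_lp(build_lp(es, nneu_total, nneu_own))
        # feed the solution back as estimates
        totals2 = {
            k: DensityEstimate(k[0], k[1], sol.x[k], es.totals[k].sigma, "literature")
            for k in es.totals
        }
        own2 = {
            k: DensityEstimate(k[0], k[1], sol.x_own[k], es.own[k].sigma, "aggregated")
            for k in es.own
        }
        es2 = EstimateSet(totals2, own2, h)
        sol2 = solve_lp(build_lp(es2, nneu_total, nneu_own))
        assert sol2.objective == pytest.approx(0.0, abs=1e-7)
        for k in sol.x:
            assert sol2.x[k] == pytest.approx(sol.x[k], abs=1e-6)

    def test_lp_dump_written(self, tmp_path):
        h = single_region_hierarchy()
        es = est_set(h, {(1, t): 10.0 for t in TYPES})
        lp = build_lp(es, {1: 100.0}, {1: 100.0})
        write_lp_dump(tmp_path / "p.lp", lp)
        text = (tmp_path / "p.lp").read_text()
        assert "Minimize" in text and "x_total_1_GAD67" in text


class TestFlagsAndResiduals:
    def _solved(self):
        h = parse_hierarchy({"id": 1, "children": []})
        eta = {(1, "GAD67"): 100.0, (1, "PV"): 30.0, (1, "SST"): 20.0, (1, "VIP"): 10.0}
        es = est_set(h, eta)
        sol = solve_lp(build_lp(es, {1: 500.0}, {1: 500.0}))
        return h, es, sol

    def test_no_flags_when_untouched(self):
        _, es, sol = self._solved()
        flags = flag_corrections(sol, es)
        assert not flags["flagged"].any()
        assert flags.attrs["region_fraction_flagged"] == 0.0

    def test_two_sigma_move_flagged(self):
        h, es, sol = self._solved()
        sol.x[(1, "PV")] = es.totals[(1, "PV")].eta + 2.5 * es.totals[(1, "PV")].sigma
        flags = flag_corrections(sol, es)
        row = flags[(flags.region_id == 1) & (flags.type == "PV")].iloc[0]
        assert bool(row.flagged)
        assert flags.attrs["region_fraction_flagged"] == 1.0

    def test_residual_arithmetic(self):
        _, es, sol = self._solved()
        res = derive_residuals(sol, {1: 500.0})
        assert res["nRest"][1] == pytest.approx(100 - 60)
        assert res["nExcOther"][1] == pytest.approx(400.0)

    def test_balance_conservation(self):
        rng = np.random.default_rng(3)
        h, es, nneu_total, nneu_own = random_toy_problem(rng)
        sol = solve_lp(build_lp(es, nneu_total, nneu_own))
        res = derive_residuals(sol, nneu_total)
        for r in h.ids:
            total = (sum(sol.x[(r, t)] for t in SUBTYPES)
                     + res["nRest"][r] + res["nExcOther"][r])
            assert total == pytest.approx(nneu_total[r], rel=1e-9, abs=1e-6)

    def test_violation_raises(self):
        _, es, sol = self._solved()
        sol.x[(1, "GAD67")] = 10.0  # below the subtype sum
        with pytest.raises(ValueError, match="constraint violation"):
            derive_residuals(sol, {1: 500.0})
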