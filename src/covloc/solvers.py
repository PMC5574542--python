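"""Maximal covering location problem (MCLP) solvers.

Given binary coverage a_ij (demand node i reachable from site j within the
travel-time threshold T) and demand weights h_i, choose at most P sites to
maximise the covered demand

    max  sum_i h_i Z_i
    s.t. Z_i <= sum_j a_ij X_j        (a node counts only if some open
         sum_j X_j <= P                site covers it)
         X_j, Z_i in {0, 1}

Five methods are provided: a greedy add-only heuristic (the (1 - 1/e)
approximation for monotone submodular maximisation), an exact
branch-and-bound solve through the HiGHS MILP backend, brute-force subset
enumeration (the test oracle for small instances), and three seeded
metaheuristics (simulated annealing, a genetic algorithm and tabu search).
The metaheuristics start from the greedy solution, so they never return a
worse objective than greedy.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .instance import TravelTimeMatrix, ValidationError

__all__ = [
    "CoverageMatrix",
    "SolveSpec",
    "Solution",
    "build_coverage",
    "solve_greedy",
    "solve_exact",
    "enumerate_optimal",
    "solve_metaheuristic",
    "solve",
    "DEFAULT_PARAMS",
]

SOLVERS = ("greedy", "exact", "sa", "ga", "tabu", "enumerate")
STOCHASTIC_SOLVERS = ("sa", "ga", "tabu")

# Calibration defaults; override per method via ``params``.
DEFAULT_PARAMS: dict[str, dict] = {
    "sa": {"evaluations": 20_000, "cooling": 0.995, "t0_frac": 0.02},
    "ga": {"population": 100, "generations": 200, "tournament": 3,
           "elite": 2, "crossover_rate": 0.9},
    "tabu": {"iterations": 2_000, "tenure": 7},
}


@dataclass(frozen=True)
class CoverageMatrix:
    """Binary coverage indicators a_ij at threshold T for one transport mode."""

    a: np.ndarray  # bool, (|I|, |J|)
    threshold_minutes: float
    mode: str

    @property
    def n_demand(self) -> int:
        return self.a.shape[0]

    @property
    def n_sites(self) -> int:
        return self.a.shape[1]


@dataclass(frozen=True)
class SolveSpec:
    """Which method to run and with what budget.

    ``P`` is the facility budget (``None`` = unbounded, i.e. |J|); ``seed``
    drives all randomness of the stochastic methods.
    """

    P: int | None = None
    solver: str = "greedy"
    seed: int = 0
    solver_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValidationError(
                f"unknown solver {self.solver!r}; choose from {SOLVERS}"
            )
        if self.P is not None and self.P < 0:
            raise ValidationError("facility budget P must be >= 0")


@dataclass
class Solution:
    """A feasible MCLP solution: open sites X, covered flags Z, objective."""

    selected: list[int]
    covered: np.ndarray  # bool, (|I|,)
    covered_demand: float
    coverage_fraction: float
    objective_trace: list[float]
    solver_meta: dict


def build_coverage(travel: TravelTimeMatrix, T: float) -> CoverageMatrix:
    """Threshold a travel-time matrix: a_ij = 1 iff t_ij <= T (inclusive)."""
    if T < 0:
        raise ValidationError(f"coverage threshold must be >= 0, got {T}")
    return CoverageMatrix(a=travel.times <= T, threshold_minutes=float(T),
                          mode=travel.mode)


def _check_dims(cov: CoverageMatrix, demands: np.ndarray) -> np.ndarray:
    h = np.asarray(demands, dtype=float)
    if h.shape != (cov.n_demand,):
        raise ValidationError(
            f"demand vector length {h.shape} inconsistent with coverage "
            f"matrix ({cov.n_demand} rows)"
        )
    if np.any(h < 0):
        raise ValidationError("demands must be non-negative")
    return h


def _make_solution(
    cov: CoverageMatrix,
    h: np.ndarray,
    selected: Sequence[int],
    trace: Sequence[float],
    meta: dict,
) -> Solution:
    selected = sorted(int(j) for j in selected)
    covered = (
        cov.a[:, selected].any(axis=1)
        if selected
        else np.zeros(cov.n_demand, dtype=bool)
    )
    covered_demand = float(h[covered].sum())
    total = float(h.sum())
    meta = dict(meta)
    meta.setdefault("mode", cov.mode)
    meta.setdefault("threshold_minutes", cov.threshold_minutes)
    return Solution(
        selected=selected,
        covered=covered,
        covered_demand=covered_demand,
        coverage_fraction=covered_demand / total if total > 0 else 0.0,
        objective_trace=[float(v) for v in trace],
        solver_meta=meta,
    )


# -- greedy -------------------------------------------------------------------


def solve_greedy(
    cov: CoverageMatrix,
    demands: np.ndarray,
    P: int | None = None,
) -> Solution:
    """Add-only greedy: repeatedly open the site with the largest uncovered-
    demand gain.

    Stops at the budget P, or as soon as no candidate adds positive gain
    (which also handles instances where some demand is uncoverable by any
    candidate).  Ties break to the lowest candidate id, so the method is
    deterministic.  The per-iteration gains are non-increasing (coverage is
    submodular), so the cumulative trace doubles as the greedy trade-off
    curve.
    """
    h = _check_dims(cov, demands)
    budget = cov.n_sites if P is None else min(P, cov.n_sites)
    t0 = time.perf_counter()

    uncovered = np.ones(cov.n_demand, dtype=bool)
    selected: list[int] = []
    trace: list[float] = []
    covered_total = 0.0
    A = cov.a
    while len(selected) < budget:
        gains = (A & uncovered[:, None]).T @ h  # gain_j = uncovered demand of j
        best = int(np.argmax(gains))  # argmax takes the lowest index on ties
        if gains[best] <= 0:
            break
        selected.append(best)
        covered_total += float(gains[best])
        trace.append(covered_total)
        uncovered &= ~A[:, best]

    meta = {
        "method": "greedy",
        "seed": None,
        "iterations": len(selected),
        "runtime_s": time.perf_counter() - t0,
        "P": P,
    }
    return _make_solution(cov, h, selected, trace, meta)


# -- exact (MILP) -------------------------------------------------------------


def _milp_solve(
    A: np.ndarray,
    h: np.ndarray,
    P: int,
    min_coverage: float | None = None,
) -> tuple[np.ndarray, float]:
    """One MILP: max h.Z (or min #sites if ``min_coverage`` given) over the
    MCLP polytope.  Variables are x = [X_1..X_J, Z_1..Z_I]."""
    n, m = A.shape
    nz = A.astype(float)
    # Z_i - sum_j a_ij X_j <= 0
    link = sparse.hstack([sparse.csr_matrix(-nz), sparse.eye(n, format="csr")])
    budget = sparse.hstack(
        [sparse.csr_matrix(np.ones((1, m))), sparse.csr_matrix((1, n))]
    )
    constraints = [
        LinearConstraint(link, -np.inf, 0.0),
        LinearConstraint(budget, -np.inf, float(P)),
    ]
    if min_coverage is None:
        c = np.concatenate([np.zeros(m), -h])
    else:
        c = np.concatenate([np.ones(m), np.zeros(n)])
        cov_row = sparse.hstack([sparse.csr_matrix((1, m)),
                                 sparse.csr_matrix(h.reshape(1, -1))])
        constraints.append(LinearConstraint(cov_row, min_coverage, np.inf))
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(m + n),
        bounds=Bounds(0, 1),
    )
    if not res.success:  # pragma: no cover - HiGHS handles all well-posed cases
        raise RuntimeError(
            f"MILP backend failed ({res.message}); for small instances "
            f"(|J| <= 15) fall back to enumerate_optimal"
        )
    x = np.round(res.x[:m]).astype(bool)
    return x, float(res.fun)


def solve_exact(
    cov: CoverageMatrix,
    demands: np.ndarray,
    P: int | None = None,
) -> Solution:
    """Provably optimal MCLP solution via branch-and-bound (HiGHS).

    Among coverage-optimal solutions, a second solve minimises the number of
    opened sites, so the reported facility count is the smallest that attains
    the optimum — without this lexicographic step the count is arbitrary
    whenever redundant sites exist.
    """
    h = _check_dims(cov, demands)
    budget = cov.n_sites if P is None else min(P, cov.n_sites)
    t0 = time.perf_counter()
    if budget == 0:
        meta = {"method": "exact", "seed": None, "iterations": 0,
                "runtime_s": time.perf_counter() - t0, "P": P}
        return _make_solution(cov, h, [], [], meta)

    x, fun = _milp_solve(cov.a, h, budget)
    opt = -fun
    # Stage 2: smallest site set attaining the optimum (tiny slack absorbs
    # MILP round-off; it is far below any demand weight).
    slack = 1e-9 * max(1.0, abs(opt))
    x2, _ = _milp_solve(cov.a, h, budget, min_coverage=opt - slack)
    selected = np.flatnonzero(x2)
    meta = {
        "method": "exact",
        "seed": None,
        "iterations": 2,
        "runtime_s": time.perf_counter() - t0,
        "P": P,
        "backend": "scipy.optimize.milp (HiGHS)",
    }
    return _make_solution(cov, h, selected, [opt], meta)


# -- exhaustive enumeration (oracle) ------------------------------------------


def enumerate_optimal(
    cov: CoverageMatrix,
    demands: np.ndarray,
    P: int,
) -> Solution:
    """Brute force over all site subsets of size <= P.

    Canonical tie-break: among optima, the minimum cardinality, then the
    lexicographically smallest id set — achieved by scanning sizes in
    ascending order and keeping only strict improvements.  Intended as the
    independent oracle on small instances; refuses > 1e6 subsets.
    """
    h = _check_dims(cov, demands)
    m = cov.n_sites
    budget = min(P, m)
    n_subsets = sum(math.comb(m, k) for k in range(budget + 1))
    if n_subsets > 1_000_000:
        raise ValidationError(
            f"enumeration over {n_subsets} subsets exceeds the 1e6 cap; "
            f"use solve_exact"
        )
    t0 = time.perf_counter()
    A = cov.a
    best_obj = 0.0
    best_set: tuple[int, ...] = ()
    for k in range(1, budget + 1):
        combos = np.array(list(itertools.combinations(range(m), k)))
        # (|I|, n_comb, k) -> any over k -> (|I|, n_comb)
        covered = A[:, combos].any(axis=2)
        objs = h @ covered
        idx = int(np.argmax(objs))  # first = lexicographically smallest
        if objs[idx] > best_obj + 1e-12:
            best_obj = float(objs[idx])
            best_set = tuple(int(j) for j in combos[idx])
    meta = {"method": "enumerate", "seed": None, "iterations": n_subsets,
            "runtime_s": time.perf_counter() - t0, "P": P}
    return _make_solution(cov, h, best_set, [best_obj], meta)


# -- metaheuristics -----------------------------------------------------------


class _IncrementalCoverage:
    """Coverage-count bookkeeping for move-based search.

    Maintains, for the incumbent site set, how many selected sites cover each
    demand node; a swap updates the counts with two column adds instead of a
    full re-evaluation.
    """

    def __init__(self, A: np.ndarray, h: np.ndarray):
        self.A = A
        self.Ai = A.astype(np.int32)
        self.h = h

    def counts(self, selected: Sequence[int]) -> np.ndarray:
        sel = list(selected)
        return (
            self.Ai[:, sel].sum(axis=1)
            if sel
            else np.zeros(self.A.shape[0], dtype=np.int32)
        )

    def objective(self, counts: np.ndarray) -> float:
        return float(self.h[counts > 0].sum())

    def eval_set(self, selected: Sequence[int]) -> float:
        return self.objective(self.counts(selected))


def _greedy_start(cov: CoverageMatrix, h: np.ndarray, budget: int) -> list[int]:
    return list(solve_greedy(cov, h, P=budget).selected)


def _sa(
    inc: _IncrementalCoverage,
    cov: CoverageMatrix,
    h: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    params: dict,
) -> tuple[list[int], list[float]]:
    """Simulated annealing: single-site swap/flip moves, geometric cooling,
    Metropolis acceptance; incumbent seeded from greedy."""
    m = cov.n_sites
    current = _greedy_start(cov, h, budget)
    counts = inc.counts(current)
    cur_obj = inc.objective(counts)
    best, best_obj = list(current), cur_obj
    temp = params["t0_frac"] * max(float(h.sum()), 1.0)
    cooling = params["cooling"]
    trace = [best_obj]
    for _ in range(int(params["evaluations"])):
        in_set = set(current)
        out_pool = [j for j in range(m) if j not in in_set]
        if not out_pool:
            break
        j_in = int(rng.choice(out_pool))
        move_counts = counts + inc.Ai[:, j_in]
        new = current + [j_in]
        if len(current) >= budget or (current and rng.random() < 0.5):
            j_out = int(current[rng.integers(len(current))])
            move_counts = move_counts - inc.Ai[:, j_out]
            new = [j for j in new if j != j_out]
        new_obj = inc.objective(move_counts)
        delta = new_obj - cur_obj
        if delta >= 0 or (temp > 1e-12 and rng.random() < math.exp(delta / temp)):
            current, counts, cur_obj = new, move_counts, new_obj
            if cur_obj > best_obj:
                best, best_obj = list(current), cur_obj
        temp *= cooling
        trace.append(best_obj)
    return best, trace


def _repair(bits: np.ndarray, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Drop random sites until the cardinality constraint holds."""
    excess = int(bits.sum()) - budget
    if excess > 0:
        on = np.flatnonzero(bits)
        drop = rng.choice(on, size=excess, replace=False)
        bits = bits.copy()
        bits[drop] = False
    return bits


def _ga(
    inc: _IncrementalCoverage,
    cov: CoverageMatrix,
    h: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    params: dict,
) -> tuple[list[int], list[float]]:
    """Genetic algorithm on binary site vectors: tournament selection, uniform
    crossover, bit-flip mutation, cardinality repair and elitism.  The greedy
    solution is injected into the initial population."""
    m = cov.n_sites
    pop_size = int(params["population"])
    mut_rate = 1.0 / max(m, 1)

    def fitness(bits: np.ndarray) -> float:
        return inc.eval_set(np.flatnonzero(bits))

    pop = np.zeros((pop_size, m), dtype=bool)
    greedy_bits = np.zeros(m, dtype=bool)
    greedy_bits[_greedy_start(cov, h, budget)] = True
    pop[0] = greedy_bits
    for k in range(1, pop_size):
        size = int(rng.integers(0, budget + 1))
        if size:
            pop[k, rng.choice(m, size=size, replace=False)] = True
    fit = np.array([fitness(ind) for ind in pop])
    trace = [float(fit.max())]

    tsize = int(params["tournament"])
    elite = int(params["elite"])
    for _ in range(int(params["generations"])):
        order = np.argsort(-fit, kind="stable")
        new_pop = [pop[i].copy() for i in order[:elite]]
        while len(new_pop) < pop_size:
            picks = rng.integers(0, pop_size, size=(2, tsize))
            pa = pop[picks[0][np.argmax(fit[picks[0]])]]
            pb = pop[picks[1][np.argmax(fit[picks[1]])]]
            if rng.random() < params["crossover_rate"]:
                mask = rng.random(m) < 0.5
                child = np.where(mask, pa, pb)
            else:
                child = pa.copy()
            child = child ^ (rng.random(m) < mut_rate)
            new_pop.append(_repair(child, budget, rng))
        pop = np.array(new_pop[:pop_size])
        fit = np.array([fitness(ind) for ind in pop])
        trace.append(float(fit.max()))
    best = pop[int(np.argmax(fit))]
    return [int(j) for j in np.flatnonzero(best)], trace


def _tabu(
    inc: _IncrementalCoverage,
    cov: CoverageMatrix,
    h: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    params: dict,
) -> tuple[list[int], list[float]]:
    """Tabu search: best-admissible swap neighbourhood, fixed-tenure tabu list
    on moved sites, aspiration on improving the best known objective."""
    m = cov.n_sites
    tenure = int(params["tenure"])
    if tenure < 0:
        raise ValidationError("tabu tenure must be >= 0")
    current = _greedy_start(cov, h, budget)
    # pad up to the budget if greedy stopped early, so the swap neighbourhood
    # explores full-cardinality sets (extra zero-gain sites are harmless)
    spare = [j for j in range(m) if j not in current]
    while len(current) < budget and spare:
        current.append(spare.pop())
    counts = inc.counts(current)
    best_obj = inc.objective(counts)
    best = list(current)
    tabu_until = np.zeros(m, dtype=np.int64)  # iteration until which j is tabu
    trace = [best_obj]

    for it in range(1, int(params["iterations"]) + 1):
        cand_obj = -np.inf
        cand_move: tuple[int, int] | None = None  # (j_out, j_in)
        sel_mask = np.zeros(m, dtype=bool)
        sel_mask[current] = True
        for j_out in current:
            base = counts - inc.Ai[:, j_out]
            objs = inc.h @ ((base[:, None] + inc.Ai) > 0)
            objs[sel_mask] = -np.inf
            tabu = (tabu_until >= it) & (objs <= best_obj)  # aspiration lifts
            objs[tabu] = -np.inf
            j_in = int(np.argmax(objs))
            if objs[j_in] > cand_obj:
                cand_obj = float(objs[j_in])
                cand_move = (j_out, j_in)
        if cand_move is None or not np.isfinite(cand_obj):
            break
        j_out, j_in = cand_move
        current = [j for j in current if j != j_out] + [j_in]
        counts = counts - inc.Ai[:, j_out] + inc.Ai[:, j_in]
        tabu_until[j_out] = it + tenure
        tabu_until[j_in] = it + tenure
        if cand_obj > best_obj:
            best_obj = cand_obj
            best = list(current)
        trace.append(best_obj)
    return best, trace


_METHODS = {"sa": _sa, "ga": _ga, "tabu": _tabu}


def solve_metaheuristic(
    method: str,
    cov: CoverageMatrix,
    demands: np.ndarray,
    P: int | None = None,
    seed: int = 0,
    params: dict | None = None,
) -> Solution:
    """Run one seeded metaheuristic (``sa``, ``ga`` or ``tabu``).

    Fully reproducible from ``seed``; default budgets come from
    ``DEFAULT_PARAMS`` and can be overridden per key.  All three start from
    the greedy solution, so their objective is never below greedy's.
    """
    if method not in _METHODS:
        raise ValidationError(
            f"unknown metaheuristic {method!r}; choose from {tuple(_METHODS)}"
        )
    h = _check_dims(cov, demands)
    budget = cov.n_sites if P is None else min(P, cov.n_sites)
    merged = {**DEFAULT_PARAMS[method], **(params or {})}
    for key, val in merged.items():
        if isinstance(val, (int, float)) and val < 0:
            raise ValidationError(f"{method} parameter {key!r} must be >= 0")
    t0 = time.perf_counter()
    if budget == 0:
        meta = {"method": method, "seed": seed, "iterations": 0,
                "runtime_s": time.perf_counter() - t0, "P": P}
        return _make_solution(cov, h, [], [], meta)
    rng = np.random.default_rng(seed)
    inc = _IncrementalCoverage(cov.a, h)
    best, trace = _METHODS[method](inc, cov, h, budget, rng, merged)
    # drop sites contributing nothing so facility counts are meaningful
    best = _prune_redundant(cov.a, h, best)
    meta = {
        "method": method,
        "seed": seed,
        "iterations": len(trace) - 1,
        "runtime_s": time.perf_counter() - t0,
        "P": P,
        "params": merged,
    }
    return _make_solution(cov, h, best, trace, meta)


def _prune_redundant(A: np.ndarray, h: np.ndarray, selected: list[int]) -> list[int]:
    """Remove sites whose removal leaves the covered demand unchanged."""
    sel = sorted(selected)
    counts = A[:, sel].astype(np.int32).sum(axis=1) if sel else None
    if counts is None:
        return sel
    obj = float(h[counts > 0].sum())
    kept = list(sel)
    for j in sorted(sel, key=lambda j: float(h @ A[:, j])):  # weakest first
        if len(kept) == 1:
            break
        trial = counts - A[:, j].astype(np.int32)
        if float(h[trial > 0].sum()) >= obj - 1e-12:
            counts = trial
            kept.remove(j)
    return kept


# -- dispatch -----------------------------------------------------------------


def solve(cov: CoverageMatrix, demands: np.ndarray, spec: SolveSpec) -> Solution:
    """Run the solver named in ``spec`` on one coverage matrix."""
    if spec.solver == "greedy":
        return solve_greedy(cov, demands, spec.P)
    if spec.solver == "exact":
        return solve_exact(cov, demands, spec.P)
    if spec.solver == "enumerate":
        P = cov.n_sites if spec.P is None else spec.P
        return enumerate_optimal(cov, demands, P)
    return solve_metaheuristic(
        spec.solver, cov, demands, spec.P, seed=spec.seed,
        params=spec.solver_params,
    )
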