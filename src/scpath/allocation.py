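"""Constrained P-median location-allocation for POCT placement.

Selects k diagnostic sites minimizing the population-weighted sum of travel
times from demand points (populated places) to their nearest chosen site,
with an optional set of *required* sites that must appear in the solution
(modelling "keep the existing devices where they are"). An exact enumerator
serves as the oracle for small instances; a greedy + vertex-substitution
(Teitz–Bart-style swap) local search with random restarts scales beyond it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_EXACT_CAP = 200_000


class ProblemError(ValueError):
    """Invalid P-median problem definition."""


@dataclass(frozen=True)
class PMedianProblem:
    """Choose ``k_total`` sites from ``candidates`` (superset of ``required``)
    minimizing sum_i weight_i * t(i, nearest chosen site).

    ``times`` is a demand x candidate travel-time matrix in minutes (rows:
    demand ids, columns: candidate facility ids).
    """

    demand: tuple[tuple[str, float], ...]  # (place id, weight >= 0)
    candidates: tuple[str, ...]
    required: frozenset[str]
    k_total: int
    times: pd.DataFrame = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        cand = set(self.candidates)
        if not self.required <= cand:
            raise ProblemError("required sites must be a subset of candidates")
        if not (len(self.required) <= self.k_total <= len(cand)):
            raise ProblemError(
                f"need |required| <= k_total <= |candidates|, got "
                f"{len(self.required)} <= {self.k_total} <= {len(cand)}"
            )
        for pid, w in self.demand:
            if w < 0:
                raise ProblemError(f"negative weight for demand point {pid!r}")
            if pid not in self.times.index:
                raise ProblemError(f"demand point {pid!r} missing from times matrix")
        for c in self.candidates:
            if c not in self.times.columns:
                raise ProblemError(f"candidate {c!r} missing from times matrix")


def make_problem(
    demand: Sequence[tuple[str, float]],
    candidates: Sequence[str],
    required: Sequence[str],
    k_total: int,
    times: pd.DataFrame,
) -> PMedianProblem:
    return PMedianProblem(
        demand=tuple((str(i), float(w)) for i, w in demand),
        candidates=tuple(sorted(str(c) for c in candidates)),
        required=frozenset(str(r) for r in required),
        k_total=int(k_total),
        times=times,
    )


@dataclass(frozen=True)
class PMedianSolution:
    chosen: frozenset[str]
    objective: float
    assignment: Mapping[str, str]  # demand id -> chosen facility id


def _arrays(problem: PMedianProblem) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Weight vector and demand x candidate time matrix as dense arrays."""
    ids = [i for i, _ in problem.demand]
    w = np.array([wt for _, wt in problem.demand], dtype=float)
    cols = list(problem.candidates)
    t = problem.times.loc[ids, cols].to_numpy(dtype=float)
    return w, t, cols


def evaluate(problem: PMedianProblem, chosen: Sequence[str]) -> PMedianSolution:
    """Objective and nearest-site assignment for a given site set.

    Each demand point is assigned to its nearest chosen site; ties go to the
    smallest facility id.
    """
    chosen_sorted = sorted(set(str(c) for c in chosen))
    if not set(chosen_sorted) <= set(problem.candidates):
        raise ProblemError("chosen sites must be candidates")
    w, t, cols = _arrays(problem)
    idx = [cols.index(c) for c in chosen_sorted]
    sub = t[:, idx]
    nearest = np.argmin(sub, axis=1)  # first minimum -> smallest id (sorted cols)
    t_near = sub[np.arange(len(sub)), nearest]
    objective = float((w * t_near).sum())
    assignment = {
        pid: chosen_sorted[j] for (pid, _), j in zip(problem.demand, nearest)
    }
    return PMedianSolution(frozenset(chosen_sorted), objective, assignment)


def solve_exact(problem: PMedianProblem, cap: int = DEFAULT_EXACT_CAP) -> PMedianSolution:
    """Global optimum by exhaustive enumeration of candidate subsets.

    Deterministic tie-break: the lexicographically smallest chosen set among
    optima (free candidates are enumerated in sorted order and only strict
    improvements replace the incumbent). Refuses instances whose free-choice
    count C(|candidates \\ required|, k_free) exceeds ``cap``.
    """
    free = sorted(set(problem.candidates) - problem.required)
    k_free = problem.k_total - len(problem.required)
    n_comb = math.comb(len(free), k_free)
    if n_comb > cap:
        raise ProblemError(
            f"{n_comb} candidate subsets exceeds the exact-solver cap {cap}; "
            "use solve_heuristic"
        )
    w, t, cols = _arrays(problem)
    col_idx = {c: j for j, c in enumerate(cols)}
    req_idx = [col_idx[c] for c in sorted(problem.required)]
    best_obj = math.inf
    best_set: tuple[str, ...] | None = None
    base = t[:, req_idx].min(axis=1) if req_idx else np.full(t.shape[0], math.inf)
    for combo in itertools.combinations(free, k_free):
        idx = [col_idx[c] for c in combo]
        t_near = np.minimum(base, t[:, idx].min(axis=1)) if idx else base
        obj = float((w * t_near).sum())
        if obj < best_obj:
            best_obj = obj
            best_set = combo
    assert best_set is not None
    return evaluate(problem, list(problem.required) + list(best_set))


def _greedy(problem: PMedianProblem, start: set[str]) -> set[str]:
    """Greedy addition until k_total sites; ties by smallest id."""
    w, t, cols = _arrays(problem)
    col_idx = {c: j for j, c in enumerate(cols)}
    chosen = set(start)
    near = (
        t[:, [col_idx[c] for c in sorted(chosen)]].min(axis=1)
        if chosen
        else np.full(t.shape[0], math.inf)
    )
    while len(chosen) < problem.k_total:
        best_c, best_obj = None, math.inf
        for c in sorted(set(problem.candidates) - chosen):
            obj = float((w * np.minimum(near, t[:, col_idx[c]])).sum())
            if obj < best_obj:
                best_c, best_obj = c, obj
        assert best_c is not None
        chosen.add(best_c)
        near = np.minimum(near, t[:, col_idx[best_c]])
    return chosen


def _swap_descent(problem: PMedianProblem, chosen: set[str]) -> tuple[set[str], float]:
    """Best-improvement single-swap (vertex substitution) local search."""
    w, t, cols = _arrays(problem)
    col_idx = {c: j for j, c in enumerate(cols)}

    def obj_of(sites: set[str]) -> float:
        idx = [col_idx[c] for c in sites]
        return float((w * t[:, idx].min(axis=1)).sum())

    current = set(chosen)
    current_obj = obj_of(current)
    improved = True
    while improved:
        improved = False
        best_move, best_obj = None, current_obj
        removable = sorted(current - problem.required)
        addable = sorted(set(problem.candidates) - current)
        for out in removable:
            for inc in addable:
                trial = (current - {out}) | {inc}
                o = obj_of(trial)
                if o < best_obj - 1e-12:
                    best_move, best_obj = (out, inc), o
        if best_move is not None:
            out, inc = best_move
            current = (current - {out}) | {inc}
            current_obj = best_obj
            improved = True
    return current, current_obj


def solve_heuristic(
    problem: PMedianProblem, seed: int = 0, n_restarts: int = 5
) -> PMedianSolution:
    """Greedy construction plus swap local search, best of random restarts.

    Restart 0 starts from the deterministic greedy solution; subsequent
    restarts start from the required set plus a random fill. Deterministic
    given ``seed``; among equal objectives the lexicographically smallest
    site set wins.
    """
    rng = np.random.default_rng(seed)
    free = sorted(set(problem.candidates) - problem.required)
    k_free = problem.k_total - len(problem.required)
    best: tuple[float, tuple[str, ...]] | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = _greedy(problem, set(problem.required))
        else:
            fill = rng.choice(free, size=k_free, replace=False) if k_free else []
            start = set(problem.required) | {str(c) for c in fill}
        sites, obj = _swap_descent(problem, start)
        key = (obj, tuple(sorted(sites)))
        if best is None or key < best:
            best = key
    assert best is not None
    return evaluate(problem, list(best[1]))


STRATEGIES = ("rearrange", "keep_plus_k", "rearrange_plus_k")


def build_strategy(
    strategy: str,
    existing_poct: Sequence[str],
    k_extra: int,
    candidates: Sequence[str],
    demand: Sequence[tuple[str, float]],
    times: pd.DataFrame,
) -> PMedianProblem:
    """Translate a limited-resource placement strategy into a P-median problem.

    - ``rearrange``: relocate the existing devices freely (required = none,
      budget = |existing|).
    - ``keep_plus_k``: keep existing devices in place, add ``k_extra`` new
      ones optimally (required = existing, budget = |existing| + k_extra).
    - ``rearrange_plus_k``: relocate everything and add ``k_extra``
      (required = none, budget = |existing| + k_extra).
    """
    existing = sorted(set(str(e) for e in existing_poct))
    cand = sorted(set(str(c) for c in candidates))
    if not set(existing) <= set(cand):
        raise ProblemError("existing POCT sites must be candidates")
    if strategy == "rearrange":
        required: Sequence[str] = []
        k_total = len(existing)
    elif strategy == "keep_plus_k":
        required = existing
        k_total = len(existing) + int(k_extra)
    elif strategy == "rearrange_plus_k":
        required = []
        k_total = len(existing) + int(k_extra)
    else:
        raise ProblemError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if k_total > len(cand):
        raise ProblemError(
            f"budget {k_total} exceeds the {len(cand)} available candidate sites"
        )
    return make_problem(demand, cand, required, k_total, times)


def solution_to_dict(sol: PMedianSolution) -> dict:
    return {
        "chosen": sorted(sol.chosen),
        "objective": sol.objective,
        "assignment": dict(sorted(sol.assignment.items())),
    }
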