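"""Steady-state LP formulation and flux balance analysis.

The model is solved as the linear program

    max / min  c' v
    s.t.       S v = 0
               lb <= v <= ub

optionally with extra linear inequality rows (used by flux variability
analysis to pin the objective to a fraction of its optimum). The solver
seam is deliberately narrow -- matrix, bounds and objective in; status,
objective value and a primal vector out -- so the backend can be swapped.
The default backend is HiGHS through ``scipy.optimize.linprog``.

Degeneracy: only the objective value (and FVA range endpoints) are
deterministic quantities. The returned flux vector is *some* optimal vertex;
alternate optima are pervasive in metabolic LPs and callers must not rely on
uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .errors import NoObjectiveError, SolverEnvironmentError, UnknownIdError
from .model import MetabolicModel, stoichiometry_matrix

__all__ = [
    "Tolerances",
    "LpProblem",
    "FluxSolution",
    "build_lp",
    "solve_lp",
    "fba",
    "OPTIMAL",
    "INFEASIBLE",
    "UNBOUNDED",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class Tolerances:
    """Solver tolerances.

    feasibility: primal/dual feasibility tolerance passed to the backend.
    optimality: relative tolerance to which objective values are trusted,
        used by downstream comparisons.
    """

    feasibility: float = 1e-9
    optimality: float = 1e-6


DEFAULT_TOLERANCES = Tolerances()


@dataclass
class LpProblem:
    """A fully assembled steady-state LP.

    ``a_eq v = b_eq`` are the mass-balance rows; optional ``a_ub v <= b_ub``
    rows carry analysis-specific constraints such as the FVA objective
    fraction.
    """

    a_eq: sparse.spmatrix
    b_eq: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c: np.ndarray
    sense: str = "max"  # "max" | "min"
    a_ub: Optional[sparse.spmatrix] = None
    b_ub: Optional[np.ndarray] = None
    reaction_ids: list[str] = field(default_factory=list)
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = self.a_eq.shape[1]
        if not (len(self.lower) == len(self.upper) == len(self.c) == n):
            raise ValueError(
                "inconsistent LP dimensions: "
                f"{self.a_eq.shape[1]} columns, {len(self.lower)} lower bounds, "
                f"{len(self.upper)} upper bounds, {len(self.c)} objective entries"
            )
        if self.sense not in ("max", "min"):
            raise ValueError(f"unknown sense {self.sense!r}")

    def with_objective(self, c: np.ndarray, sense: str) -> "LpProblem":
        """Same constraints, different objective (no copies of the matrix)."""
        return LpProblem(
            a_eq=self.a_eq,
            b_eq=self.b_eq,
            lower=self.lower,
            upper=self.upper,
            c=np.asarray(c, dtype=float),
            sense=sense,
            a_ub=self.a_ub,
            b_ub=self.b_ub,
            reaction_ids=self.reaction_ids,
            metabolite_ids=self.metabolite_ids,
        )


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``objective_value`` and ``fluxes`` are meaningful only when ``status ==
    "optimal"``; an optimal solution satisfies ``|S v|_inf <= 1e-6`` and the
    bounds to within the same slack.
    """

    status: str
    objective_value: Optional[float] = None
    fluxes: Optional[dict[str, float]] = None

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


def build_lp(
    model: MetabolicModel,
    objective: Optional[Mapping[str, float]] = None,
    sense: str = "max",
) -> LpProblem:
    """Formulate the steady-state LP ``S v = 0`` with the model's bounds.

    The objective defaults to the model's nonzero objective coefficients;
    an explicit ``objective`` map overrides them. Raises
    :class:`NoObjectiveError` when neither source provides a nonzero
    objective.
    """
    s = stoichiometry_matrix(model)
    n = len(model.reactions)
    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)

    c = np.zeros(n)
    if objective is None:
        for j, r in enumerate(model.reactions):
            c[j] = r.objective_coefficient
        if not np.any(c):
            raise NoObjectiveError(
                f"model {model.model_id!r} has no objective coefficients and "
                "no explicit objective was given"
            )
    else:
        idx = model.reaction_index()
        for rid, w in objective.items():
            if rid not in idx:
                raise UnknownIdError(f"unknown reaction id {rid!r} in objective")
            c[idx[rid]] = float(w)
        if not np.any(c):
            raise NoObjectiveError("explicit objective is identically zero")

    return LpProblem(
        a_eq=s,
        b_eq=np.zeros(s.shape[0]),
        lower=lower,
        upper=upper,
        c=c,
        sense=sense,
        reaction_ids=model.reaction_ids,
        metabolite_ids=model.metabolite_ids,
    )


def solve_lp(
    problem: LpProblem, tolerances: Tolerances = DEFAULT_TOLERANCES
) -> FluxSolution:
    """Solve an :class:`LpProblem` with the HiGHS backend.

    Status strings faithfully report the solver outcome (``optimal``,
    ``infeasible``, ``unbounded``); any other backend state raises
    :class:`SolverEnvironmentError`.
    """
    from scipy.optimize import linprog

    sign = -1.0 if problem.sense == "max" else 1.0
    res = linprog(
        c=sign * problem.c,
        A_eq=problem.a_eq,
        b_eq=problem.b_eq,
        A_ub=problem.a_ub,
        b_ub=problem.b_ub,
        bounds=np.column_stack([problem.lower, problem.upper]),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": tolerances.feasibility,
            "dual_feasibility_tolerance": tolerances.feasibility,
        },
    )
    # scipy linprog status codes: 0 optimal, 1 iteration limit, 2 infeasible,
    # 3 unbounded, 4 numerical trouble.
    if res.status == 0:
        fluxes = None
        if problem.reaction_ids:
            fluxes = dict(zip(problem.reaction_ids, (float(v) for v in res.x)))
        elif res.x is not None:
            fluxes = {str(j): float(v) for j, v in enumerate(res.x)}
        return FluxSolution(
            status=OPTIMAL,
            objective_value=float(sign * res.fun),
            fluxes=fluxes,
        )
    if res.status == 2:
        return FluxSolution(status=INFEASIBLE)
    if res.status == 3:
        return FluxSolution(status=UNBOUNDED)
    raise SolverEnvironmentError(
        f"LP backend failed (scipy linprog status {res.status}): {res.message}"
    )


ModelEdit = Callable[[MetabolicModel], MetabolicModel]


def _apply_edit(model: MetabolicModel, edit) -> MetabolicModel:
    # Accepts plain callables as well as transform descriptors from the
    # screening framework (anything with an .apply(model) method).
    if hasattr(edit, "apply"):
        return edit.apply(model)
    return edit(model)


def fba(
    model: MetabolicModel,
    modifications: Optional[Sequence[ModelEdit]] = None,
    objective: Optional[Mapping[str, float]] = None,
    sense: str = "max",
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> FluxSolution:
    """Flux balance analysis: maximize the objective subject to steady state.

    ``modifications`` (model edits: bound changes, knockouts, objective
    changes, or any ``model -> model`` callable) are applied left-to-right
    to a copy of the model; the caller's model is never mutated.
    """
    if modifications:
        work = model
        for edit in modifications:
            work = _apply_edit(work, edit)
        model = work
    problem = build_lp(model, objective=objective, sense=sense)
    return solve_lp(problem, tolerances=tolerances)
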