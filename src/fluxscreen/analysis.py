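"""Ready-to-use flux analyses: variability, gene deletions, envelopes.

Every analysis here decomposes into independent single-LP tasks dispatched
through the screening framework's worker pool (:func:`~fluxscreen.screen.
parallel_map`), so all of them parallelize with the same contract: results
are deterministic and ordered by the caller's input order regardless of
worker count or scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InfeasibleModelError, UnknownIdError
from .model import MetabolicModel, apply_knockout
from .optimize import (
    DEFAULT_TOLERANCES,
    OPTIMAL,
    FluxSolution,
    LpProblem,
    Tolerances,
    build_lp,
    fba,
    solve_lp,
)
from .screen import parallel_map, register_analysis

__all__ = [
    "FluxRange",
    "DeletionResult",
    "EnvelopeRow",
    "EnvelopeTable",
    "fva",
    "fva_frame",
    "single_gene_deletion",
    "pair_gene_deletion",
    "deletion_frame",
    "production_envelope",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxRange:
    """Feasible flux interval of one reaction under the objective-fraction
    constraint. Endpoints are meaningful only for optimal statuses."""

    reaction_id: str
    minimum: Optional[float]
    maximum: Optional[float]
    status_min: str = OPTIMAL
    status_max: str = OPTIMAL


@dataclass(frozen=True)
class DeletionResult:
    """Objective after knocking out one gene (or a gene pair).

    ``status == "optimal"`` with objective 0 means zero growth and is
    reported as such, distinct from ``infeasible``; the two are never
    conflated.
    """

    genes: tuple[str, ...]
    status: str
    objective_value: Optional[float]

    @property
    def gene_id(self) -> str:
        return ",".join(self.genes)


@dataclass(frozen=True)
class EnvelopeRow:
    level: float
    target_min: Optional[float]
    target_max: Optional[float]
    status_min: str = OPTIMAL
    status_max: str = OPTIMAL


@dataclass
class EnvelopeTable:
    """Production envelope: extreme target fluxes at each level of the
    modulated reaction, levels strictly increasing."""

    target_reaction: str
    modulated_reaction: str
    rows: list[EnvelopeRow] = field(default_factory=list)

    @property
    def levels(self) -> list[float]:
        return [r.level for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [r.level for r in self.rows],
                "target_min": [r.target_min for r in self.rows],
                "target_max": [r.target_max for r in self.rows],
                "status_min": [r.status_min for r in self.rows],
                "status_max": [r.status_max for r in self.rows],
            }
        )


def fva_frame(ranges: Sequence[FluxRange]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reaction": [r.reaction_id for r in ranges],
            "minimum": [r.minimum for r in ranges],
            "maximum": [r.maximum for r in ranges],
            "status_min": [r.status_min for r in ranges],
            "status_max": [r.status_max for r in ranges],
        }
    )


def deletion_frame(results: Sequence[DeletionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genes": [r.gene_id for r in results],
            "status": [r.status for r in results],
            "objective": [r.objective_value for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Flux variability analysis
# ---------------------------------------------------------------------------

# Worker-side state for the per-LP FVA tasks, installed by the pool
# initializer (one LpProblem shared by all tasks of one fva() call).
_FVA_STATE: dict = {}


def _init_fva(problem: LpProblem, tolerances: Tolerances):
    _FVA_STATE.update(problem=problem, tolerances=tolerances)


def _fva_task(task):
    j, sense = task
    problem: LpProblem = _FVA_STATE["problem"]
    c = np.zeros(len(problem.c))
    c[j] = 1.0
    sol = solve_lp(problem.with_objective(c, sense), _FVA_STATE["tolerances"])
    return (sol.status, sol.objective_value)


def fva(
    model: MetabolicModel,
    gamma: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
    workers: int = 1,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[FluxRange]:
    """Flux variability analysis.

    First solves the wild-type FBA problem for the optimum Z*, then
    constrains the objective expression to retain at least the fraction
    ``gamma`` of it (``c'v >= gamma * Z*`` for maximization, ``<=`` for
    minimization) and, for each requested reaction, minimizes and maximizes
    that reaction's flux. Each min/max solve is an independent task run
    through the worker pool.

    The gamma constraint is a linear row on the objective *expression*, not
    a bound change on any single reaction, so it is correct when the
    objective spans several reactions. When Z* = 0 the constraint
    degenerates to ``objective >= 0`` for every gamma; this is documented
    behavior, not special-cased.

    Raises :class:`InfeasibleModelError` before any per-reaction solve if
    the wild-type problem is not optimal.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    base = build_lp(model)
    wt = solve_lp(base, tolerances)
    if wt.status != OPTIMAL:
        raise InfeasibleModelError(
            f"wild-type problem is {wt.status}; no variability to compute",
            status=wt.status,
        )
    zstar = wt.objective_value

    # objective-fraction row: for max, c'v >= gamma*Z*  <=>  -c'v <= -gamma*Z*
    if base.sense == "max":
        a_ub = sparse.csr_matrix(-base.c)
        b_ub = np.array([-gamma * zstar])
    else:
        a_ub = sparse.csr_matrix(base.c)
        b_ub = np.array([gamma * zstar])
    constrained = LpProblem(
        a_eq=base.a_eq,
        b_eq=base.b_eq,
        lower=base.lower,
        upper=base.upper,
        c=base.c,
        sense=base.sense,
        a_ub=a_ub,
        b_ub=b_ub,
        reaction_ids=[],  # workers only need the objective value
        metabolite_ids=[],
    )

    idx = model.reaction_index()
    if reactions is None:
        wanted = model.reaction_ids
    else:
        unknown = [r for r in reactions if r not in idx]
        if unknown:
            raise UnknownIdError("unknown reaction id(s): " + ", ".join(unknown))
        wanted = list(reactions)

    tasks = [(idx[rid], sense) for rid in wanted for sense in ("min", "max")]
    outcomes = parallel_map(
        _fva_task,
        tasks,
        workers=workers,
        initializer=_init_fva,
        initargs=(constrained, tolerances),
    )

    ranges = []
    for k, rid in enumerate(wanted):
        status_min, vmin = outcomes[2 * k]
        status_max, vmax = outcomes[2 * k + 1]
        ranges.append(
            FluxRange(
                reaction_id=rid,
                minimum=vmin,
                maximum=vmax,
                status_min=status_min,
                status_max=status_max,
            )
        )
    return ranges


# ---------------------------------------------------------------------------
# Gene deletion screens
# ---------------------------------------------------------------------------

_DEL_STATE: dict = {}


def _init_deletions(model: MetabolicModel, tolerances: Tolerances):
    _DEL_STATE.update(model=model, tolerances=tolerances)


def _deletion_task(genes: tuple[str, ...]):
    knocked = apply_knockout(_DEL_STATE["model"], set(genes))
    sol = fba(knocked, tolerances=_DEL_STATE["tolerances"])
    return (sol.status, sol.objective_value)


def _deletion_screen(model, gene_sets, workers, tolerances):
    outcomes = parallel_map(
        _deletion_task,
        gene_sets,
        workers=workers,
        initializer=_init_deletions,
        initargs=(model, tolerances),
    )
    return [
        DeletionResult(genes=gs, status=status, objective_value=obj)
        for gs, (status, obj) in zip(gene_sets, outcomes)
    ]


def single_gene_deletion(
    model: MetabolicModel,
    genes: Optional[Sequence[str]] = None,
    workers: int = 1,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[DeletionResult]:
    """FBA objective after each single-gene knockout.

    Defaults to all genes in model order. Each knockout is an independent
    task; results are returned in input gene order regardless of execution
    order.
    """
    if genes is None:
        genes = model.gene_ids
    else:
        known = set(model.gene_ids)
        unknown = [g for g in genes if g not in known]
        if unknown:
            raise UnknownIdError("unknown gene id(s): " + ", ".join(unknown))
    gene_sets = [(g,) for g in genes]
    return _deletion_screen(model, gene_sets, workers, tolerances)


def pair_gene_deletion(
    model: MetabolicModel,
    pairs: Sequence[tuple[str, str]],
    workers: int = 1,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> list[DeletionResult]:
    """FBA objective after each two-gene knockout.

    Knockouts have set semantics: the pair (g, g) equals the single
    deletion of g.
    """
    known = set(model.gene_ids)
    for a, b in pairs:
        unknown = [g for g in (a, b) if g not in known]
        if unknown:
            raise UnknownIdError("unknown gene id(s): " + ", ".join(unknown))
    gene_sets = [tuple(dict.fromkeys(p)) for p in pairs]  # dedupe, keep order
    return _deletion_screen(model, gene_sets, workers, tolerances)


# ---------------------------------------------------------------------------
# Production envelope
# ---------------------------------------------------------------------------

_ENV_STATE: dict = {}


def _init_envelope(problem, mod_index, target_index, tolerances):
    _ENV_STATE.update(
        problem=problem,
        mod_index=mod_index,
        target_index=target_index,
        tolerances=tolerances,
    )


def _envelope_task(task):
    level, sense = task
    problem: LpProblem = _ENV_STATE["problem"]
    j = _ENV_STATE["mod_index"]
    lower = problem.lower.copy()
    upper = problem.upper.copy()
    lower[j] = upper[j] = level
    c = np.zeros(len(problem.c))
    c[_ENV_STATE["target_index"]] = 1.0
    fixed = LpProblem(
        a_eq=problem.a_eq,
        b_eq=problem.b_eq,
        lower=lower,
        upper=upper,
        c=c,
        sense=sense,
    )
    sol = solve_lp(fixed, _ENV_STATE["tolerances"])
    return (sol.status, sol.objective_value)


def production_envelope(
    model: MetabolicModel,
    target_reaction: str,
    modulated_reaction: str,
    n_points: int = 10,
    workers: int = 1,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> EnvelopeTable:
    """Sweep the modulated reaction across its feasible range and record the
    extreme achievable fluxes of the target reaction at each level.

    The feasible range [lo, hi] of the modulated reaction is found with two
    plain LPs (no objective-fraction constraint); ``n_points`` evenly spaced
    levels spanning it inclusive of both endpoints are then each fixed in
    turn and the target is minimized and maximized. When hi - lo < 1e-9 the
    grid degenerates to a single level. Every level/sense solve is an
    independent worker-pool task.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    idx = model.reaction_index()
    for rid in (target_reaction, modulated_reaction):
        if rid not in idx:
            raise UnknownIdError(f"unknown reaction id {rid!r}")
    j_mod = idx[modulated_reaction]
    j_target = idx[target_reaction]

    lo_sol = fba(model, objective={modulated_reaction: 1.0}, sense="min",
                 tolerances=tolerances)
    hi_sol = fba(model, objective={modulated_reaction: 1.0}, sense="max",
                 tolerances=tolerances)
    for sol in (lo_sol, hi_sol):
        if sol.status != OPTIMAL:
            raise InfeasibleModelError(
                f"range of {modulated_reaction!r} is {sol.status}; "
                "cannot build envelope",
                status=sol.status,
            )
    lo, hi = lo_sol.objective_value, hi_sol.objective_value

    if hi - lo < 1e-9:
        levels = np.array([lo])
    else:
        levels = np.linspace(lo, hi, n_points)

    problem = build_lp(model, objective={target_reaction: 1.0})
    tasks = [(float(lvl), sense) for lvl in levels for sense in ("min", "max")]
    outcomes = parallel_map(
        _envelope_task,
        tasks,
        workers=workers,
        initializer=_init_envelope,
        initargs=(problem, j_mod, j_target, tolerances),
    )

    rows = []
    for k, lvl in enumerate(levels):
        status_min, vmin = outcomes[2 * k]
        status_max, vmax = outcomes[2 * k + 1]
        rows.append(
            EnvelopeRow(
                level=float(lvl),
                target_min=vmin,
                target_max=vmax,
                status_min=status_min,
                status_max=status_max,
            )
        )
    return EnvelopeTable(
        target_reaction=target_reaction,
        modulated_reaction=modulated_reaction,
        rows=rows,
    )


# ---------------------------------------------------------------------------
# Built-in screenable analyses
# ---------------------------------------------------------------------------

@register_analysis("fba_objective")
def _screen_fba_objective(model: MetabolicModel) -> float:
    """FBA optimum as a bare float; NaN when the variant is infeasible or
    unbounded (kept as a value so result arrays stay dense and numeric)."""
    sol = fba(model)
    return sol.objective_value if sol.status == OPTIMAL else float("nan")


@register_analysis("fba")
def _screen_fba(model: MetabolicModel) -> FluxSolution:
    return fba(model)


@register_analysis("fva")
def _screen_fva(model: MetabolicModel, gamma: float = 1.0,
                reactions: Optional[Sequence[str]] = None) -> list[FluxRange]:
    # cells run single-threaded: the grid, not the inner LPs, is the unit of
    # parallelism inside a screen
    return fva(model, gamma=gamma, reactions=reactions, workers=1)


@register_analysis("envelope")
def _screen_envelope(
    model: MetabolicModel,
    target_reaction: str,
    modulated_reaction: str,
    n_points: int = 10,
) -> EnvelopeTable:
    return production_envelope(
        model, target_reaction, modulated_reaction, n_points=n_points, workers=1
    )
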