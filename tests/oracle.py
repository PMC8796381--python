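"""Independent brute-force LP oracle used to cross-check the implementation.

Deliberately coded on a different path from the package: the system is built
densely, entry by entry, straight from each reaction's stoichiometry
dictionary (never via ``stoichiometry_matrix``), equality rows are expressed
as paired inequalities (A v <= 0 and -A v <= 0), and GPR rules are evaluated
by an independent recursive walk rather than ``eval_gpr``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from fluxscreen.model import BoolExpr, GeneRef


def dense_system(model):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    a = np.zeros((len(model.metabolites), n))
    for j, reaction in enumerate(model.reactions):
        for mid, coef in reaction.stoichiometry.items():
            a[met_index[mid], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    c = np.array([r.objective_coefficient for r in model.reactions], dtype=float)
    return a, lb, ub, c


def _solve(a, lb, ub, c, sense="max", extra_a=None, extra_b=None):
    # steady state as paired inequalities -- a formulation path distinct
    # from the implementation's A_eq route
    a_ub = np.vstack([a, -a])
    b_ub = np.zeros(2 * a.shape[0])
    if extra_a is not None:
        a_ub = np.vstack([a_ub, np.atleast_2d(extra_a)])
        b_ub = np.concatenate([b_ub, np.atleast_1d(extra_b)])
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", float(sign * res.fun), res.x
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise RuntimeError(f"oracle solve failed: {res.message}")


def oracle_fba(model, objective=None, sense="max"):
    """(status, objective value) by the independent dense formulation."""
    a, lb, ub, c = dense_system(model)
    if objective is not None:
        c = np.zeros(len(c))
        rid_index = {r.id: j for j, r in enumerate(model.reactions)}
        for rid, w in objective.items():
            c[rid_index[rid]] = w
    status, value, _ = _solve(a, lb, ub, c, sense=sense)
    return status, value


def oracle_fva(model, gamma, reactions=None):
    """Brute force: one independent min and max LP per reaction with the
    objective-fraction row appended. Returns {reaction_id: (min, max)}."""
    a, lb, ub, c = dense_system(model)
    status, zstar, _ = _solve(a, lb, ub, c, sense="max")
    assert status == "optimal", "oracle wild type must be optimal"
    extra_a = -c
    extra_b = np.array([-gamma * zstar])

    wanted = reactions or [r.id for r in model.reactions]
    rid_index = {r.id: j for j, r in enumerate(model.reactions)}
    out = {}
    for rid in wanted:
        j = rid_index[rid]
        cj = np.zeros(len(c))
        cj[j] = 1.0
        _, vmin, _ = _solve(a, lb, ub, cj, "min", extra_a, extra_b)
        _, vmax, _ = _solve(a, lb, ub, cj, "max", extra_a, extra_b)
        out[rid] = (vmin, vmax)
    return out


def _rule_true(node, absent):
    if node is None:
        return True
    if isinstance(node, GeneRef):
        return node.gene not in absent
    if isinstance(node, BoolExpr) and node.op == "and":
        return all(_rule_true(child, absent) for child in node.children)
    if isinstance(node, BoolExpr) and node.op == "or":
        return any(_rule_true(child, absent) for child in node.children)
    raise TypeError(f"unexpected GPR node {node!r}")


def oracle_knockout_fba(model, genes):
    """Direct FBA on a manually edited dense system: bounds of reactions
    whose rule goes false are zeroed by hand."""
    absent = set(genes)
    a, lb, ub, c = dense_system(model)
    for j, reaction in enumerate(model.reactions):
        if reaction.gpr.root is None:
            continue
        if not _rule_true(reaction.gpr.root, absent):
            lb[j] = ub[j] = 0.0
    status, value, _ = _solve(a, lb, ub, c, sense="max")
    return status, value


def oracle_envelope(model, target, modulated, levels):
    """Per-level LP oracle: fix the modulated reaction's bounds at each
    level and min/max the target. Returns [(level, tmin, tmax), ...]."""
    a, lb, ub, c = dense_system(model)
    rid_index = {r.id: j for j, r in enumerate(model.reactions)}
    j_mod = rid_index[modulated]
    j_target = rid_index[target]
    out = []
    for level in levels:
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[j_mod] = ub2[j_mod] = level
        ct = np.zeros(len(c))
        ct[j_target] = 1.0
        _, tmin, _ = _solve(a, lb2, ub2, ct, "min")
        _, tmax, _ = _solve(a, lb2, ub2, ct, "max")
        out.append((level, tmin, tmax))
    return out
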