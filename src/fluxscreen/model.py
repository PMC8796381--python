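"""Core data structures for constraint-based metabolic models.

A genome-scale metabolic model is treated as a constrained linear system:
a stoichiometric matrix ``S`` (metabolites x reactions), per-reaction flux
bounds, and a linear objective. Reactions may be gated by boolean
gene-protein-reaction (GPR) rules over gene identifiers; knocking out genes
closes the bounds of reactions whose rule evaluates false.

All edit operations (:func:`change_bounds`, :func:`apply_knockout`,
:func:`set_objective`) return modified copies and never mutate their input.
This value-semantics contract is what makes the screening framework safe:
many variants of the same base model can be built concurrently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

from .errors import (
    BoundsError,
    GprParseError,
    ModelValidationError,
    UnknownIdError,
)

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "GeneRef",
    "BoolExpr",
    "GprRule",
    "EMPTY_GPR",
    "MetabolicModel",
    "ValidationReport",
    "parse_gpr",
    "eval_gpr",
    "stoichiometry_matrix",
    "change_bounds",
    "apply_knockout",
    "set_objective",
    "validate_model",
]

#: Default bounds applied when a file format omits them.
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRef:
    """Leaf of a GPR expression tree: a single gene identifier."""

    gene: str


@dataclass(frozen=True)
class BoolExpr:
    """Internal node of a GPR expression tree: ``and`` / ``or`` over two or
    more children."""

    op: str  # "and" | "or"
    children: tuple["GprNode", ...]

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs at least two children")


GprNode = Union[GeneRef, BoolExpr]


@dataclass(frozen=True)
class GprRule:
    """Boolean gene-availability rule gating a reaction.

    ``root is None`` is the distinguished empty rule: always satisfied,
    i.e. the reaction does not depend on any gene.
    """

    root: Optional[GprNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        """All gene ids appearing in the rule."""
        out: set[str] = set()

        def walk(node: GprNode):
            if isinstance(node, GeneRef):
                out.add(node.gene)
            else:
                for c in node.children:
                    walk(c)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, absent_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction is available when ``absent_genes`` are
        knocked out. The empty rule is always true."""
        return eval_gpr(self, absent_genes)

    def to_string(self) -> str:
        """Render back to rule text. ``and`` binds tighter than ``or``, so
        only ``or`` children of an ``and`` need parentheses."""
        if self.root is None:
            return ""

        def render(node: GprNode, parent_op: Optional[str]) -> str:
            if isinstance(node, GeneRef):
                return node.gene
            sep = f" {node.op} "
            text = sep.join(render(c, node.op) for c in node.children)
            if node.op == "or" and parent_op == "and":
                return f"({text})"
            return text

        return render(self.root, None)

    def __str__(self) -> str:
        return self.to_string()


#: Shared always-satisfied rule.
EMPTY_GPR = GprRule()

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GprRule:
    """Parse GPR rule text into an expression tree.

    Grammar: identifiers are maximal runs of non-whitespace characters other
    than parentheses and the bare keywords ``and``/``or`` (case-insensitive);
    ``and`` binds tighter than ``or``; whitespace is insignificant; empty or
    blank text yields the always-satisfied rule. There is no negation.

    Raises :class:`GprParseError` with the character offset on malformed
    input (unbalanced parentheses, dangling operators).
    """
    if text is None or not text.strip():
        return EMPTY_GPR

    tokens = [(m.group(0), m.start()) for m in _GPR_TOKEN.finditer(text)]
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or() -> GprNode:
        nonlocal pos
        children = [parse_and()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "or":
                pos += 1
                children.append(parse_and())
            else:
                break
        if len(children) == 1:
            return children[0]
        return BoolExpr("or", tuple(children))

    def parse_and() -> GprNode:
        nonlocal pos
        children = [parse_atom()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "and":
                pos += 1
                children.append(parse_atom())
            else:
                break
        if len(children) == 1:
            return children[0]
        return BoolExpr("and", tuple(children))

    def parse_atom() -> GprNode:
        nonlocal pos
        tok, off = peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", off)
        if tok == "(":
            pos += 1
            node = parse_or()
            tok2, off2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parenthesis", off2)
            pos += 1
            return node
        if tok == ")":
            raise GprParseError("unexpected ')'", off)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", off)
        pos += 1
        return GeneRef(tok)

    root = parse_or()
    tok, off = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", off)
    return GprRule(root)


def eval_gpr(rule: GprRule, absent_genes: Iterable[str] = ()) -> bool:
    """Evaluate a GPR rule with the given genes knocked out.

    A leaf is true iff its gene is not absent; ``and``/``or`` have their
    standard semantics; the empty rule is true.
    """
    absent = frozenset(absent_genes)
    if rule.root is None:
        return True

    def walk(node: GprNode) -> bool:
        if isinstance(node, GeneRef):
            return node.gene not in absent
        if node.op == "and":
            return all(walk(c) for c in node.children)
        return any(walk(c) for c in node.children)

    return walk(rule.root)


# ---------------------------------------------------------------------------
# Model entities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None


@dataclass(frozen=True)
class Gene:
    id: str
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    """A reaction: sparse stoichiometry over metabolite ids (negative =
    consumed, positive = produced), flux bounds in mmol/gDW/h, an optional
    GPR rule and an objective coefficient.

    Reversibility is derived, not stored: a reaction is reversible iff
    ``lower_bound < 0``.
    """

    id: str
    name: str = ""
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    gpr: GprRule = EMPTY_GPR
    objective_coefficient: float = 0.0

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites, reactions and genes.

    Entity order is significant: it fixes the row/column order of the
    stoichiometric matrix and thereby the coordinates of every analysis
    result, which must stay stable across model variants.
    """

    model_id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def objective(self) -> dict[str, float]:
        """Nonzero objective coefficients keyed by reaction id."""
        return {
            r.id: r.objective_coefficient
            for r in self.reactions
            if r.objective_coefficient != 0.0
        }

    # -- copying ------------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        """Structural copy safe to edit independently of the original.

        Entities are frozen dataclasses, but stoichiometry mappings and the
        annotations dict are copied so no mutable state is shared.
        """
        return MetabolicModel(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry))
                for r in self.reactions
            ],
            genes=list(self.genes),
            annotations=dict(self.annotations),
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_model`: a list of (code, message) errors
    and warnings. ``errors`` empty iff the model satisfies every structural
    invariant."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self):
        if self.errors:
            lines = "; ".join(f"{c}: {m}" for c, m in self.errors)
            raise ModelValidationError(f"invalid model: {lines}", report=self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check structural invariants; all problems go into the report.

    Errors: duplicate metabolite/reaction/gene ids, empty ids, stoichiometry
    referencing unknown metabolites, GPRs referencing unknown genes,
    inverted bounds. Warnings: metabolites used by no reaction, reactions
    with empty stoichiometry.
    """
    report = ValidationReport()

    def check_unique(ids, kind):
        seen = set()
        for i in ids:
            if not i:
                report.errors.append((f"empty_{kind}_id", f"{kind} with empty id"))
            elif i in seen:
                report.errors.append(
                    (f"duplicate_{kind}_id", f"duplicate {kind} id {i!r}")
                )
            seen.add(i)

    check_unique(model.metabolite_ids, "metabolite")
    check_unique(model.reaction_ids, "reaction")
    check_unique(model.gene_ids, "gene")

    met_ids = set(model.metabolite_ids)
    gene_ids = set(model.gene_ids)
    used_mets: set[str] = set()

    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            report.errors.append(
                (
                    "inverted_bounds",
                    f"reaction {r.id!r} has lower bound {r.lower_bound} "
                    f"> upper bound {r.upper_bound}",
                )
            )
        if not r.stoichiometry:
            report.warnings.append(
                ("empty_stoichiometry", f"reaction {r.id!r} has no metabolites")
            )
        for mid in r.stoichiometry:
            if mid not in met_ids:
                report.errors.append(
                    (
                        "dangling_metabolite",
                        f"reaction {r.id!r} references unknown metabolite {mid!r}",
                    )
                )
            used_mets.add(mid)
        for g in r.gpr.genes():
            if g not in gene_ids:
                report.errors.append(
                    (
                        "dangling_gene",
                        f"reaction {r.id!r} GPR references unknown gene {g!r}",
                    )
                )

    for mid in model.metabolite_ids:
        if mid not in used_mets:
            report.warnings.append(
                ("orphan_metabolite", f"metabolite {mid!r} used by no reaction")
            )
    return report


def stoichiometry_matrix(model: MetabolicModel, validate: bool = True):
    """Assemble the sparse stoichiometric matrix S.

    Rows follow metabolite order, columns follow reaction order; entry
    (i, j) is the coefficient of metabolite i in reaction j, with absent
    pairs as structural zeros. Returns a ``scipy.sparse.csc_matrix`` of
    shape (n_metabolites, n_reactions).
    """
    from scipy import sparse

    if validate:
        validate_model(model).raise_if_invalid()

    met_index = model.metabolite_index()
    rows, cols, data = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    return sparse.csc_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


def change_bounds(
    model: MetabolicModel,
    reaction_id: str,
    lower: Optional[float] = None,
    upper: Optional[float] = None,
) -> MetabolicModel:
    """Return a copy of the model with the reaction's bounds replaced.

    Omitted sides stay unchanged. Raises :class:`UnknownIdError` for an
    unknown reaction and :class:`BoundsError` if the resulting bounds are
    inverted. The input model is not mutated.
    """
    idx = model.reaction_index()
    if reaction_id not in idx:
        raise UnknownIdError(f"unknown reaction id {reaction_id!r}")
    out = model.copy()
    j = idx[reaction_id]
    r = out.reactions[j]
    new_lb = r.lower_bound if lower is None else float(lower)
    new_ub = r.upper_bound if upper is None else float(upper)
    if new_lb > new_ub:
        raise BoundsError(
            f"inverted bounds ({new_lb}, {new_ub}) for reaction {reaction_id!r}"
        )
    out.reactions[j] = replace(r, lower_bound=new_lb, upper_bound=new_ub)
    return out


def apply_knockout(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Return a copy with the given genes knocked out.

    Every reaction whose GPR evaluates false under the knockout gets bounds
    (0, 0); reactions with the empty rule are untouched. Disabled reactions
    are closed rather than deleted so matrix dimensions and entity indices
    stay identical across variants.
    """
    absent = frozenset(genes)
    known = set(model.gene_ids)
    unknown = absent - known
    if unknown:
        raise UnknownIdError(
            "unknown gene id(s): " + ", ".join(sorted(unknown))
        )
    out = model.copy()
    for j, r in enumerate(out.reactions):
        if r.gpr.is_empty:
            continue
        if not eval_gpr(r.gpr, absent):
            out.reactions[j] = replace(r, lower_bound=0.0, upper_bound=0.0)
    return out


def set_objective(
    model: MetabolicModel, weights: Mapping[str, float]
) -> MetabolicModel:
    """Return a copy whose objective coefficients equal ``weights`` exactly
    (coefficients of reactions not in the map are reset to zero)."""
    idx = model.reaction_index()
    unknown = set(weights) - set(idx)
    if unknown:
        raise UnknownIdError(
            "unknown reaction id(s) in objective: " + ", ".join(sorted(unknown))
        )
    out = model.copy()
    for j, r in enumerate(out.reactions):
        w = float(weights.get(r.id, 0.0))
        if w != r.objective_coefficient:
            out.reactions[j] = replace(r, objective_coefficient=w)
    return out
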