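"""Deterministic synthetic models with analytically known answers.

These generators stand in for external model repositories in tests and
examples. Each recipe documents its analytic FBA/FVA answers so every
analysis can be checked against closed-form expectations as well as against
an independent LP oracle. Ids follow the conventions of real genome-scale
models (``EX_`` exchange prefixes, ``_e``/``_c`` compartment suffixes) so
exchange-detection heuristics are exercised honestly.

Randomness enters only through one injectable ``numpy`` generator seeded by
an explicit integer; the same recipe and seed always produce byte-identical
models (and byte-identical JSON renderings).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import (
    EMPTY_GPR,
    Gene,
    Metabolite,
    MetabolicModel,
    Reaction,
    parse_gpr,
)
from .io import JSON_EXTRA_KEY

__all__ = [
    "make_chain",
    "make_branched",
    "make_diamond",
    "make_random_viable",
    "RECIPES",
    "model_to_sbml_string",
    "write_mat_model",
]


def _fixture_annotations(name: str, **params) -> dict:
    # stored under the JSON extras key so they survive a JSON round trip
    return {JSON_EXTRA_KEY: {"model": {"fixture": {"name": name, **params}}}}


def make_chain(n_internal: int = 1, uptake_ub: float = 10.0) -> MetabolicModel:
    """Linear pathway: uptake -> ``n_internal`` conversions -> export.

    The export carries the objective. Analytic answers: FBA optimum equals
    ``uptake_ub``; at gamma = 1 every reaction's FVA range is
    [uptake_ub, uptake_ub] (the flux is fully determined by stoichiometry).
    """
    if n_internal < 1:
        raise ValueError("n_internal must be >= 1")
    met_ids = ["A_e"] + [f"M{i}_c" for i in range(1, n_internal)] + ["P_e"]
    metabolites = [
        Metabolite(id=m, compartment="e" if m.endswith("_e") else "c")
        for m in met_ids
    ]
    reactions = [
        Reaction(
            id="EX_A_e",
            name="substrate uptake",
            stoichiometry={"A_e": 1.0},
            lower_bound=0.0,
            upper_bound=float(uptake_ub),
        )
    ]
    for i in range(n_internal):
        reactions.append(
            Reaction(
                id=f"CONV{i + 1}",
                stoichiometry={met_ids[i]: -1.0, met_ids[i + 1]: 1.0},
            )
        )
    reactions.append(
        Reaction(
            id="EX_P_e",
            name="product export",
            stoichiometry={"P_e": -1.0},
            objective_coefficient=1.0,
        )
    )
    return MetabolicModel(
        model_id="chain",
        metabolites=metabolites,
        reactions=reactions,
        annotations=_fixture_annotations(
            "chain", n_internal=n_internal, uptake_ub=float(uptake_ub)
        ),
    )


def make_branched(
    uptake_ub: float = 10.0,
    yield_p: float = 1.0,
    yield_w: float = 0.5,
    gene_gating: bool = True,
    isozyme: bool = False,
) -> MetabolicModel:
    """Substrate splitting into a high-yield product branch and a wasteful
    branch.

    The product branch converts one substrate into ``yield_p`` product and
    (with ``gene_gating``) is gated by gene ``gP`` -- or by the isozyme rule
    ``gP or gP2`` when ``isozyme`` is set. The wasteful branch is ungated
    and converts one substrate into ``yield_w`` product plus one unit of
    waste, so it is a genuine low-yield alternative route.

    Analytic answers (objective = product export):

    * optimum = ``uptake_ub * max(yield_p, yield_w)``;
    * knocking out the product branch leaves ``uptake_ub * yield_w``;
    * with ``yield_w = 0`` the waste branch makes no product, so one unit of
      waste export displaces exactly one unit of substrate from the product
      branch -- the classic linear production envelope.
    """
    metabolites = [
        Metabolite(id="A_e", compartment="e"),
        Metabolite(id="P_e", compartment="e"),
        Metabolite(id="W_e", compartment="e"),
    ]
    if gene_gating:
        gpr = parse_gpr("gP or gP2") if isozyme else parse_gpr("gP")
        genes = [Gene(id="gP"), Gene(id="gP2"), Gene(id="gU", name="unused")]
    else:
        gpr = EMPTY_GPR
        genes = []

    waste_stoich = {"A_e": -1.0, "W_e": 1.0}
    if yield_w != 0.0:
        waste_stoich["P_e"] = float(yield_w)

    reactions = [
        Reaction(
            id="EX_A_e",
            name="substrate uptake",
            stoichiometry={"A_e": 1.0},
            upper_bound=float(uptake_ub),
        ),
        Reaction(
            id="BRANCH_P",
            name="high-yield product branch",
            stoichiometry={"A_e": -1.0, "P_e": float(yield_p)},
            gpr=gpr,
        ),
        Reaction(
            id="BRANCH_W",
            name="wasteful branch",
            stoichiometry=waste_stoich,
        ),
        Reaction(
            id="EX_P_e",
            name="product export",
            stoichiometry={"P_e": -1.0},
            objective_coefficient=1.0,
        ),
        Reaction(
            id="EX_W_e",
            name="waste export",
            stoichiometry={"W_e": -1.0},
        ),
    ]
    return MetabolicModel(
        model_id="branched",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        annotations=_fixture_annotations(
            "branched",
            uptake_ub=float(uptake_ub),
            yield_p=float(yield_p),
            yield_w=float(yield_w),
            gene_gating=gene_gating,
            isozyme=isozyme,
        ),
    )


def make_diamond(uptake_ub: float = 10.0) -> MetabolicModel:
    """Two equivalent parallel routes A -> B.

    The split between the routes is unconstrained at the optimum, so each
    route's gamma = 1 FVA range is [0, uptake_ub] while their sum is pinned
    to ``uptake_ub``. The canonical degenerate-optimum fixture.
    """
    metabolites = [
        Metabolite(id="A_e", compartment="e"),
        Metabolite(id="B_e", compartment="e"),
    ]
    reactions = [
        Reaction(id="EX_A_e", stoichiometry={"A_e": 1.0},
                 upper_bound=float(uptake_ub)),
        Reaction(id="ROUTE1", stoichiometry={"A_e": -1.0, "B_e": 1.0}),
        Reaction(id="ROUTE2", stoichiometry={"A_e": -1.0, "B_e": 1.0}),
        Reaction(id="EX_B_e", stoichiometry={"B_e": -1.0},
                 objective_coefficient=1.0),
    ]
    return MetabolicModel(
        model_id="diamond",
        metabolites=metabolites,
        reactions=reactions,
        annotations=_fixture_annotations("diamond", uptake_ub=float(uptake_ub)),
    )


def make_random_viable(
    n_pathways: int = 3, pathway_len: int = 4, seed: int = 0
) -> MetabolicModel:
    """Union of independently generated linear pathway motifs sharing one
    substrate; always feasible with a positive, analytically known optimum.

    Each pathway draws substrate through a capacity-limited entry reaction
    (capacity drawn from the seeded generator), runs it through
    ``pathway_len - 1`` conversions and exports its product with objective
    weight one. Roughly half the entries are gated by a pathway gene, every
    third gated entry by an isozyme pair. The shared uptake bound is drawn
    around the total pathway capacity, so sometimes the uptake binds and
    sometimes the capacities do:

        optimum = min(uptake_ub, sum of pathway capacities)

    The value is recorded in the fixture annotations as
    ``analytic_optimum``. Reaction count is ``1 + n_pathways *
    (pathway_len + 1)``.
    """
    if n_pathways < 1 or pathway_len < 1:
        raise ValueError("n_pathways and pathway_len must be >= 1")
    rng = np.random.default_rng(seed)
    caps = np.round(rng.uniform(2.0, 8.0, size=n_pathways), 2)
    uptake_ub = float(np.round(rng.uniform(0.4, 1.2) * caps.sum(), 2))
    optimum = float(min(uptake_ub, float(caps.sum())))

    metabolites = [Metabolite(id="S_e", compartment="e")]
    reactions = [
        Reaction(id="EX_S_e", name="shared substrate uptake",
                 stoichiometry={"S_e": 1.0}, upper_bound=uptake_ub)
    ]
    genes: list[Gene] = []

    for p in range(n_pathways):
        chain_mets = [f"P{p}M{k}_c" for k in range(pathway_len - 1)]
        chain_mets.append(f"P{p}_e")
        for m in chain_mets:
            metabolites.append(
                Metabolite(id=m, compartment="e" if m.endswith("_e") else "c")
            )
        gpr = EMPTY_GPR
        if rng.random() < 0.5:
            if p % 3 == 0:
                genes.extend([Gene(id=f"g{p}"), Gene(id=f"g{p}b")])
                gpr = parse_gpr(f"g{p} or g{p}b")
            else:
                genes.append(Gene(id=f"g{p}"))
                gpr = parse_gpr(f"g{p}")
        reactions.append(
            Reaction(
                id=f"P{p}_IN",
                name=f"pathway {p} entry",
                stoichiometry={"S_e": -1.0, chain_mets[0]: 1.0},
                upper_bound=float(caps[p]),
                gpr=gpr,
            )
        )
        for k in range(pathway_len - 1):
            reactions.append(
                Reaction(
                    id=f"P{p}_C{k + 1}",
                    stoichiometry={chain_mets[k]: -1.0, chain_mets[k + 1]: 1.0},
                )
            )
        reactions.append(
            Reaction(
                id=f"EX_P{p}_e",
                stoichiometry={chain_mets[-1]: -1.0},
                objective_coefficient=1.0,
            )
        )

    return MetabolicModel(
        model_id=f"random_viable_{seed}",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        annotations=_fixture_annotations(
            "random_viable",
            n_pathways=n_pathways,
            pathway_len=pathway_len,
            seed=int(seed),
            uptake_ub=uptake_ub,
            capacities=[float(c) for c in caps],
            analytic_optimum=optimum,
        ),
    )


def analytic_optimum(model: MetabolicModel) -> Optional[float]:
    """The documented analytic FBA optimum of a fixture, if recorded."""
    fixture = (
        model.annotations.get(JSON_EXTRA_KEY, {})
        .get("model", {})
        .get("fixture", {})
    )
    if "analytic_optimum" in fixture:
        return float(fixture["analytic_optimum"])
    if fixture.get("name") == "chain":
        return float(fixture["uptake_ub"])
    if fixture.get("name") == "branched":
        return float(fixture["uptake_ub"]) * max(
            fixture["yield_p"], fixture["yield_w"]
        )
    if fixture.get("name") == "diamond":
        return float(fixture["uptake_ub"])
    return None


RECIPES = {
    "chain": make_chain,
    "branched": make_branched,
    "diamond": make_diamond,
    "random": make_random_viable,
}


# ---------------------------------------------------------------------------
# Cross-format twins (test support)
# ---------------------------------------------------------------------------

def model_to_sbml_string(model: MetabolicModel) -> str:
    """Render a model as an SBML L3 + fbc v2 document string.

    This is a minimal writer used to materialize cross-format twins of the
    fixtures for reader tests; JSON remains the canonical write format and
    this function covers only the fields the package models carry.
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.model_id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = sorted(
        {m.compartment or "c" for m in model.metabolites} or {"c"}
    )
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment or "c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for gene in model.genes:
        gp = fbc.createGeneProduct()
        gp.setId(gene.id)
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc.setActiveObjectiveId("obj")

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(r.gpr.to_string(), True, False)
        if r.objective_coefficient != 0.0:
            fo = objective.createFluxObjective()
            fo.setReaction(r.id)
            fo.setCoefficient(float(r.objective_coefficient))

    return libsbml.writeSBMLToString(doc)


def write_mat_model(model: MetabolicModel, path) -> None:
    """Write a COBRA Toolbox MAT struct twin of a model (test support for
    the MAT reader; the struct carries the core field set only)."""
    from scipy import io as sio

    from .model import stoichiometry_matrix

    n = len(model.reactions)
    m = len(model.metabolites)

    def cell(strings):
        arr = np.empty((len(strings), 1), dtype=object)
        for i, s in enumerate(strings):
            arr[i, 0] = s
        return arr

    struct = {
        "S": stoichiometry_matrix(model),
        "lb": np.array([[r.lower_bound] for r in model.reactions]),
        "ub": np.array([[r.upper_bound] for r in model.reactions]),
        "c": np.array([[r.objective_coefficient] for r in model.reactions]),
        "b": np.zeros((m, 1)),
        "rxns": cell(model.reaction_ids),
        "mets": cell(model.metabolite_ids),
        "rxnNames": cell([r.name for r in model.reactions]),
        "metNames": cell([x.name for x in model.metabolites]),
        "genes": cell(model.gene_ids),
        "grRules": cell([r.gpr.to_string() for r in model.reactions]),
        "modelID": model.model_id,
    }
    sio.savemat(path, {"model": struct})
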