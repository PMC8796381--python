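"""Model input/output.

Three dialects are supported:

* **COBRA JSON** (schema v1, the COBRApy interchange format) -- read and
  write; this is the canonical write format. Unknown document keys are
  preserved in the model's annotations and re-emitted on write.
* **SBML Level 3** with the flux-balance-constraints (fbc v2) package --
  read only, through libsbml. Flux bounds come from the fbc bound
  parameters; the ``reversible`` attribute is ignored (with a warning when
  it contradicts the bounds). Boundary-condition species are excluded from
  the stoichiometric constraint set.
* **COBRA Toolbox MAT struct** -- read only, through scipy.io.

Writers emit keys in a fixed order and numbers at full binary64 precision,
so writing the same model twice gives byte-identical files.
"""

from __future__ import annotations

import enum
import json
import logging
import os
from typing import IO, Union

import numpy as np

from .errors import FormatError, GprParseError, UnsupportedDialectError
from .model import (
    DEFAULT_IRREVERSIBLE_BOUNDS,
    DEFAULT_REVERSIBLE_BOUNDS,
    BoolExpr,
    Gene,
    GeneRef,
    GprRule,
    EMPTY_GPR,
    Metabolite,
    MetabolicModel,
    Reaction,
    parse_gpr,
    validate_model,
)

__all__ = [
    "FormatDialect",
    "read_json",
    "write_json",
    "read_sbml",
    "read_mat",
    "detect_format",
    "load_model",
    "convert",
]

logger = logging.getLogger(__name__)

PathOrStream = Union[str, "os.PathLike[str]", IO]

#: annotations key under which unknown JSON document keys are preserved
JSON_EXTRA_KEY = "cobra_json_extra"

_MET_KEYS = {"id", "name", "compartment", "formula", "charge"}
_RXN_KEYS = {
    "id",
    "name",
    "metabolites",
    "lower_bound",
    "upper_bound",
    "gene_reaction_rule",
    "objective_coefficient",
}
_GENE_KEYS = {"id", "name"}
_MODEL_KEYS = {"metabolites", "reactions", "genes", "id", "compartments", "version"}


class FormatDialect(enum.Enum):
    COBRA_JSON = "cobra_json"
    SBML_FBC = "sbml_fbc"
    COBRA_MAT = "cobra_mat"


# ---------------------------------------------------------------------------
# COBRA JSON
# ---------------------------------------------------------------------------

def _extras(entry: dict, known: set) -> dict:
    return {k: v for k, v in entry.items() if k not in known}


def read_json(source: PathOrStream) -> MetabolicModel:
    """Read a COBRA JSON (schema v1) document into a model.

    Required top-level keys: ``metabolites``, ``reactions``, ``genes``.
    Reactions missing bounds get the package defaults: (-1000, 1000) when
    the reaction carries a truthy ``reversible``/``reversibility`` marker,
    (0, 1000) otherwise. ``gene_reaction_rule`` strings are parsed into GPR
    trees; a parse failure is reported with the offending reaction id.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("top-level JSON value must be an object")
    for key in ("metabolites", "reactions", "genes"):
        if key not in doc:
            raise FormatError(f"missing required key at $.{key}")

    extra = {"model": _extras(doc, _MODEL_KEYS)}

    metabolites = []
    met_extra = {}
    for i, m in enumerate(doc["metabolites"]):
        if "id" not in m:
            raise FormatError(f"missing required key at $.metabolites[{i}].id")
        charge = m.get("charge")
        metabolites.append(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula"),
                charge=int(charge) if charge is not None else None,
            )
        )
        e = _extras(m, _MET_KEYS)
        if e:
            met_extra[m["id"]] = e

    reactions = []
    rxn_extra = {}
    for i, r in enumerate(doc["reactions"]):
        if "id" not in r:
            raise FormatError(f"missing required key at $.reactions[{i}].id")
        rid = r["id"]
        reversible = bool(r.get("reversible", r.get("reversibility", False)))
        default_lb, default_ub = (
            DEFAULT_REVERSIBLE_BOUNDS if reversible else DEFAULT_IRREVERSIBLE_BOUNDS
        )
        rule_text = r.get("gene_reaction_rule", "")
        try:
            gpr = parse_gpr(rule_text)
        except GprParseError as exc:
            raise FormatError(
                f"bad gene_reaction_rule in reaction {rid!r}: {exc}"
            ) from exc
        stoich = r.get("metabolites", {})
        if not isinstance(stoich, dict):
            raise FormatError(
                f"$.reactions[{i}].metabolites must be an id -> coefficient map"
            )
        reactions.append(
            Reaction(
                id=rid,
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in stoich.items()},
                lower_bound=float(r.get("lower_bound", default_lb)),
                upper_bound=float(r.get("upper_bound", default_ub)),
                gpr=gpr,
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
        )
        e = _extras(r, _RXN_KEYS | {"reversible", "reversibility"})
        if e:
            rxn_extra[rid] = e

    genes = []
    gene_extra = {}
    for i, g in enumerate(doc["genes"]):
        if "id" not in g:
            raise FormatError(f"missing required key at $.genes[{i}].id")
        genes.append(Gene(id=g["id"], name=g.get("name", "")))
        e = _extras(g, _GENE_KEYS)
        if e:
            gene_extra[g["id"]] = e

    if met_extra:
        extra["metabolites"] = met_extra
    if rxn_extra:
        extra["reactions"] = rxn_extra
    if gene_extra:
        extra["genes"] = gene_extra

    annotations = {}
    if any(extra.values()):
        annotations[JSON_EXTRA_KEY] = extra

    model = MetabolicModel(
        model_id=doc.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        annotations=annotations,
    )
    validate_model(model).raise_if_invalid()
    return model


def write_json(model: MetabolicModel, dest: PathOrStream) -> None:
    """Write a model as COBRA JSON (schema v1).

    Keys are emitted in a fixed order (metabolites, reactions, genes, id,
    compartments, version) and floats at full precision, so output is
    byte-identical across writes of the same model. Empty GPRs are emitted
    as ``""``. Unknown keys preserved from a previous read are merged back.
    """
    extra = model.annotations.get(JSON_EXTRA_KEY, {})
    met_extra = extra.get("metabolites", {})
    rxn_extra = extra.get("reactions", {})
    gene_extra = extra.get("genes", {})

    mets = []
    for m in model.metabolites:
        entry = {"id": m.id, "name": m.name, "compartment": m.compartment}
        if m.formula is not None:
            entry["formula"] = m.formula
        if m.charge is not None:
            entry["charge"] = m.charge
        entry.update(met_extra.get(m.id, {}))
        mets.append(entry)

    rxns = []
    for r in model.reactions:
        entry = {
            "id": r.id,
            "name": r.name,
            "metabolites": {k: float(v) for k, v in r.stoichiometry.items()},
            "lower_bound": float(r.lower_bound),
            "upper_bound": float(r.upper_bound),
            "gene_reaction_rule": r.gpr.to_string(),
            "objective_coefficient": float(r.objective_coefficient),
        }
        entry.update(rxn_extra.get(r.id, {}))
        rxns.append(entry)

    genes = []
    for g in model.genes:
        entry = {"id": g.id, "name": g.name}
        entry.update(gene_extra.get(g.id, {}))
        genes.append(entry)

    compartments = {}
    for m in model.metabolites:
        if m.compartment:
            compartments.setdefault(m.compartment, m.compartment)

    doc = {
        "metabolites": mets,
        "reactions": rxns,
        "genes": genes,
        "id": model.model_id,
        "compartments": compartments,
        "version": "1",
    }
    doc.update(extra.get("model", {}))

    text = json.dumps(doc, indent=1, ensure_ascii=False)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# SBML L3 + fbc
# ---------------------------------------------------------------------------

def _gpr_from_association(assoc, libsbml) -> GprRule:
    def walk(node):
        if isinstance(node, libsbml.GeneProductRef):
            return GeneRef(node.getGeneProduct())
        if isinstance(node, libsbml.FbcAnd):
            return BoolExpr(
                "and",
                tuple(walk(node.getAssociation(i))
                      for i in range(node.getNumAssociations())),
            )
        if isinstance(node, libsbml.FbcOr):
            return BoolExpr(
                "or",
                tuple(walk(node.getAssociation(i))
                      for i in range(node.getNumAssociations())),
            )
        raise FormatError(
            f"unsupported gene association node {type(node).__name__}"
        )

    return GprRule(walk(assoc))


def read_sbml(source: PathOrStream) -> MetabolicModel:
    """Read an SBML Level 3 document that uses the fbc (v2) package.

    Species become metabolites (boundary-condition species are dropped from
    the constraint set and from reaction stoichiometries), reactions take
    their stoichiometry from reactants (negative) and products (positive),
    flux bounds come from the fbc bound parameters, the objective from the
    active fbc objective, and GPRs from fbc gene-product associations.

    Documents without the fbc package raise
    :class:`UnsupportedDialectError`; a reaction missing a bound parameter
    raises :class:`FormatError` naming the reaction.
    """
    import libsbml

    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        doc = libsbml.readSBMLFromString(data)
    else:
        doc = libsbml.readSBMLFromString(
            open(source, "r", encoding="utf-8").read()
        )
    if doc is None:
        raise FormatError("unreadable SBML document")
    if doc.getNumErrors() > 0:
        fatal = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if fatal:
            raise FormatError("SBML parse errors: " + "; ".join(fatal))

    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML document contains no model")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise UnsupportedDialectError(
            "SBML document does not use the flux-balance-constraints (fbc) "
            "package; only SBML L3 + fbc is supported"
        )

    boundary: set[str] = set()
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "",
                formula=formula,
                charge=charge,
            )
        )

    genes = []
    for i in range(fbc.getNumGeneProducts()):
        gp = fbc.getGeneProduct(i)
        gid = gp.getIdAttribute()
        name = gp.getName()
        if not name:
            # fall back to the label when it adds information beyond the id
            label = gp.getLabel()
            name = label if label and label != gid else ""
        genes.append(Gene(id=gid, name=name))

    objective = {}
    active = fbc.getActiveObjective()
    if active is not None:
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            objective[fo.getReaction()] = float(fo.getCoefficient())

    def bound_value(param_id: str, rid: str, side: str) -> float:
        if not param_id:
            raise FormatError(
                f"reaction {rid!r} has no fbc {side} flux bound parameter"
            )
        param = sbml_model.getParameter(param_id)
        if param is None or not param.isSetValue():
            raise FormatError(
                f"reaction {rid!r}: bound parameter {param_id!r} missing or "
                "without value"
            )
        return float(param.getValue())

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - float(
                ref.getStoichiometry()
            )
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + float(
                ref.getStoichiometry()
            )
        rplug = rx.getPlugin("fbc")
        if rplug is None:
            raise FormatError(f"reaction {rid!r} lacks the fbc plugin")
        lb = bound_value(rplug.getLowerFluxBound(), rid, "lower")
        ub = bound_value(rplug.getUpperFluxBound(), rid, "upper")
        if rx.isSetReversible() and rx.getReversible() != (lb < 0):
            logger.warning(
                "reaction %r: 'reversible' attribute disagrees with bound "
                "parameters; bounds win",
                rid,
            )
        gpr = EMPTY_GPR
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None and gpa.getAssociation() is not None:
            gpr = _gpr_from_association(gpa.getAssociation(), libsbml)
        reactions.append(
            Reaction(
                id=rid,
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                objective_coefficient=objective.get(rid, 0.0),
            )
        )

    model = MetabolicModel(
        model_id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
    )
    validate_model(model).raise_if_invalid()
    return model


# ---------------------------------------------------------------------------
# COBRA Toolbox MAT
# ---------------------------------------------------------------------------

def _mat_strings(arr) -> list[str]:
    if arr is None:
        return []
    if isinstance(arr, str):
        return [arr]
    out = []
    flat = np.asarray(arr, dtype=object).ravel()
    for x in flat:
        while isinstance(x, np.ndarray):
            if x.size == 0:
                x = ""
                break
            x = x.item() if x.size == 1 else x.ravel()[0]
        out.append("" if x is None else str(x))
    return out


def read_mat(path) -> MetabolicModel:
    """Read a COBRA Toolbox MATLAB struct model.

    The file must contain a single struct with at least the core fields
    ``S``, ``lb``, ``ub``, ``rxns``, ``mets``; ``genes``, ``grRules`` and
    ``c`` are honored when present (no ``grRules`` means every GPR is empty,
    an all-zero ``c`` means no objective is set).
    """
    from scipy import io as sio
    from scipy import sparse

    raw = sio.loadmat(path, simplify_cells=True)
    structs = {
        k: v for k, v in raw.items()
        if not k.startswith("__") and isinstance(v, dict)
    }
    if not structs:
        raise FormatError("MAT file contains no model struct")
    name, data = next(iter(structs.items()))

    for fieldname in ("S", "lb", "ub", "rxns", "mets"):
        if fieldname not in data:
            raise FormatError(f"MAT struct {name!r} lacks required field {fieldname!r}")

    s = data["S"]
    if not sparse.issparse(s):
        s = sparse.coo_matrix(np.atleast_2d(np.asarray(s, dtype=float)))
    else:
        s = s.tocoo()
    mets = _mat_strings(data["mets"])
    rxns = _mat_strings(data["rxns"])
    if s.shape != (len(mets), len(rxns)):
        raise FormatError(
            f"S is {s.shape} but there are {len(mets)} mets x {len(rxns)} rxns"
        )
    lb = np.asarray(data["lb"], dtype=float).ravel()
    ub = np.asarray(data["ub"], dtype=float).ravel()
    c = np.asarray(data.get("c", np.zeros(len(rxns))), dtype=float).ravel()
    rules = _mat_strings(data.get("grRules")) if "grRules" in data else [""] * len(rxns)
    if len(rules) != len(rxns):
        raise FormatError("grRules length does not match rxns")

    gene_ids = _mat_strings(data.get("genes")) if "genes" in data else []
    met_names = _mat_strings(data.get("metNames")) if "metNames" in data else [""] * len(mets)
    rxn_names = _mat_strings(data.get("rxnNames")) if "rxnNames" in data else [""] * len(rxns)

    def compartment_of(met_id: str) -> str:
        # the MAT dialect has no compartment field; use the conventional
        # id suffix ("glc_e" or "glc[e]") when present
        if len(met_id) > 3 and met_id[-3] == "[" and met_id[-1] == "]":
            return met_id[-2]
        if len(met_id) > 2 and met_id[-2] == "_" and met_id[-1].isalpha():
            return met_id[-1]
        return ""

    metabolites = [
        Metabolite(id=m, name=met_names[i], compartment=compartment_of(m))
        for i, m in enumerate(mets)
    ]
    stoichs: list[dict[str, float]] = [{} for _ in rxns]
    for i, j, v in zip(s.row, s.col, s.data):
        stoichs[j][mets[i]] = float(v)
    reactions = []
    for j, rid in enumerate(rxns):
        stoich = stoichs[j]
        try:
            gpr = parse_gpr(rules[j])
        except GprParseError as exc:
            raise FormatError(f"bad grRule for reaction {rid!r}: {exc}") from exc
        reactions.append(
            Reaction(
                id=rid,
                name=rxn_names[j],
                stoichiometry=stoich,
                lower_bound=float(lb[j]),
                upper_bound=float(ub[j]),
                gpr=gpr,
                objective_coefficient=float(c[j]),
            )
        )

    model = MetabolicModel(
        model_id=str(data.get("modelID", name)),
        metabolites=metabolites,
        reactions=reactions,
        genes=[Gene(id=g) for g in gene_ids],
    )
    validate_model(model).raise_if_invalid()
    return model


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

_EXTENSIONS = {
    ".json": FormatDialect.COBRA_JSON,
    ".xml": FormatDialect.SBML_FBC,
    ".sbml": FormatDialect.SBML_FBC,
    ".mat": FormatDialect.COBRA_MAT,
}


def detect_format(path) -> FormatDialect:
    """Detect the dialect of a model file.

    Content sniffing (leading ``{`` for JSON, ``<`` for XML, the MAT-file
    header magic) overrides the file extension; the extension decides when
    the content is ambiguous.
    """
    with open(path, "rb") as fh:
        head = fh.read(128)
    stripped = head.lstrip()
    if stripped.startswith(b"{"):
        return FormatDialect.COBRA_JSON
    if stripped.startswith(b"<"):
        return FormatDialect.SBML_FBC
    if b"MATLAB" in head[:116]:
        return FormatDialect.COBRA_MAT
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _EXTENSIONS:
        return _EXTENSIONS[ext]
    raise FormatError(
        f"cannot detect model dialect of {path!r}; supported: "
        + ", ".join(d.value for d in FormatDialect)
    )


def load_model(path) -> MetabolicModel:
    """Load a model from any supported dialect, auto-detected."""
    dialect = detect_format(path)
    if dialect is FormatDialect.COBRA_JSON:
        return read_json(path)
    if dialect is FormatDialect.SBML_FBC:
        return read_sbml(path)
    return read_mat(path)


def convert(in_path, out_path) -> MetabolicModel:
    """Convert any readable dialect to COBRA JSON (the canonical write
    format); returns the loaded model."""
    model = load_model(in_path)
    write_json(model, out_path)
    return model
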