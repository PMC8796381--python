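"""Multi-organism community models.

Member models are joined into one model that trades metabolites through a
shared environment compartment: each member keeps its internal network
untouched (ids prefixed ``memberId#``), its exchange reaction for every
shared metabolite is rewired into a member<->environment transfer, and one
environment exchange reaction per shared metabolite connects the community
to the outside.

Abundance convention: abundances are normalized to sum to one and scale the
environment-side stoichiometry of each member's transfer reactions, so one
unit of a member's exchange flux moves ``abundance`` units of the shared
environment metabolite. Several abundance conventions exist in the
literature; this is the biomass-fraction scaling commonly used in
steady-state community FBA, and it is stated here explicitly because the
choice changes the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .errors import FluxscreenError, ModelValidationError, UnknownIdError
from .model import (
    BoolExpr,
    Gene,
    GeneRef,
    GprRule,
    Metabolite,
    MetabolicModel,
    Reaction,
    validate_model,
)

__all__ = [
    "CommunityMember",
    "CommunitySpec",
    "join_models",
    "community_objective",
    "is_exchange",
    "bare_metabolite_id",
]

#: compartment id used for the shared environment
ENV_COMPARTMENT = "env"


def is_exchange(reaction: Reaction) -> bool:
    """Exchange detection: a reaction with exactly one participating
    metabolite. An ``EX_`` id prefix is the conventional marker, but when
    the two criteria disagree the structural one wins (an ``EX_``-named
    reaction touching two metabolites is not an exchange)."""
    return len(reaction.stoichiometry) == 1


def bare_metabolite_id(met_id: str) -> str:
    """Strip the extracellular compartment suffix (``_e`` or ``[e]``) so
    the same substrate can be matched across members that use different
    naming styles."""
    if met_id.endswith("[e]"):
        return met_id[:-3]
    if met_id.endswith("_e"):
        return met_id[:-2]
    return met_id


@dataclass(frozen=True)
class CommunityMember:
    member_id: str
    model: MetabolicModel
    abundance: float = 1.0


@dataclass
class CommunitySpec:
    """Recipe for joining member models.

    ``environment_bounds`` maps a shared metabolite id to the (lower, upper)
    bounds of its environment exchange reaction ``EX_<X>_env`` (stoichiometry
    ``{<X>_env: -1}``, so a negative flux imports the metabolite into the
    environment); shared metabolites without an entry get wide-open bounds.
    ``shared_id_overrides[member_id][shared_id]`` can name the member
    metabolite explicitly when suffix stripping is not enough.
    """

    members: list[CommunityMember]
    shared_metabolites: list[str]
    environment_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    shared_id_overrides: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate(self):
        ids = [m.member_id for m in self.members]
        if not ids:
            raise FluxscreenError("community needs at least one member")
        if len(set(ids)) != len(ids):
            raise FluxscreenError("member ids must be unique")
        for mid in ids:
            if "#" in mid:
                raise FluxscreenError(
                    f"member id {mid!r} contains '#', which is reserved for "
                    "id prefixing"
                )
        if any(m.abundance < 0 for m in self.members):
            raise FluxscreenError("abundances must be non-negative")
        if sum(m.abundance for m in self.members) <= 0:
            raise FluxscreenError("abundances must sum to a positive value")

    def normalized_abundances(self) -> dict[str, float]:
        total = sum(m.abundance for m in self.members)
        return {m.member_id: m.abundance / total for m in self.members}


def _prefix_gpr(rule: GprRule, prefix: str) -> GprRule:
    if rule.root is None:
        return rule

    def walk(node):
        if isinstance(node, GeneRef):
            return GeneRef(prefix + node.gene)
        return BoolExpr(node.op, tuple(walk(c) for c in node.children))

    return GprRule(walk(rule.root))


def _find_exchange_for(model: MetabolicModel, met_id: str) -> Optional[int]:
    for j, r in enumerate(model.reactions):
        if is_exchange(r) and next(iter(r.stoichiometry)) == met_id:
            return j
    return None


def join_models(spec: CommunitySpec) -> MetabolicModel:
    """Join member models into one community model.

    The result contains, per member, all metabolites/reactions/genes with
    ids prefixed ``memberId#``; per shared metabolite X, one environment
    metabolite ``X_env`` plus one exchange ``EX_X_env`` with the spec's
    bounds; and each member's exchange for X rewired into a transfer whose
    environment-side coefficient is scaled by the member's normalized
    abundance. Member objective coefficients are carried over scaled by
    abundance, so FBA on the join maximizes the abundance-weighted community
    objective out of the box.

    Raises when a member has no exchange reaction for a listed shared
    metabolite, or when ids collide after prefixing.
    """
    spec.validate()
    for m in spec.members:
        report = validate_model(m.model)
        if not report.ok:
            raise ModelValidationError(
                f"member {m.member_id!r} is invalid", report=report
            )
    abundances = spec.normalized_abundances()

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    genes: list[Gene] = []

    # member id -> shared id -> index into `reactions` of the transfer to rewire
    transfer_sites: dict[str, dict[str, int]] = {}

    for member in spec.members:
        mid = member.member_id
        prefix = f"{mid}#"
        model = member.model
        overrides = spec.shared_id_overrides.get(mid, {})

        # map shared id -> member metabolite id
        shared_map: dict[str, str] = {}
        bare = {bare_metabolite_id(x.id): x.id for x in model.metabolites}
        for shared in spec.shared_metabolites:
            target = overrides.get(shared) or bare.get(shared)
            if target is None or _find_exchange_for(model, target) is None:
                raise UnknownIdError(
                    f"member {mid!r} has no exchange reaction for shared "
                    f"metabolite {shared!r}"
                )
            shared_map[shared] = target

        for x in model.metabolites:
            metabolites.append(replace(x, id=prefix + x.id))
        for g in model.genes:
            genes.append(replace(g, id=prefix + g.id))

        offset = len(reactions)
        for r in model.reactions:
            reactions.append(
                Reaction(
                    id=prefix + r.id,
                    name=r.name,
                    stoichiometry={prefix + k: v for k, v in r.stoichiometry.items()},
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    gpr=_prefix_gpr(r.gpr, prefix),
                    objective_coefficient=r.objective_coefficient * abundances[mid],
                )
            )
        transfer_sites[mid] = {
            shared: offset + _find_exchange_for(model, met_id)
            for shared, met_id in shared_map.items()
        }

    # environment metabolites, transfer rewiring, environment exchanges
    for shared in spec.shared_metabolites:
        env_id = f"{shared}_env"
        metabolites.append(
            Metabolite(id=env_id, name=f"{shared} (environment)",
                       compartment=ENV_COMPARTMENT)
        )
        for member in spec.members:
            mid = member.member_id
            j = transfer_sites[mid][shared]
            r = reactions[j]
            (member_met, coef), = r.stoichiometry.items()
            # one unit of transfer flux moves `abundance` units of the
            # environment metabolite, in the opposite direction of the
            # member-side coefficient (mass moves between compartments)
            stoich = dict(r.stoichiometry)
            stoich[env_id] = -coef * abundances[mid]
            reactions[j] = replace(r, stoichiometry=stoich)
        lb, ub = spec.environment_bounds.get(shared, (-1000.0, 1000.0))
        reactions.append(
            Reaction(
                id=f"EX_{shared}_env",
                name=f"{shared} environment exchange",
                stoichiometry={env_id: -1.0},
                lower_bound=float(lb),
                upper_bound=float(ub),
            )
        )

    joined = MetabolicModel(
        model_id="community_" + "_".join(m.member_id for m in spec.members),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        annotations={
            "community_members": [m.member_id for m in spec.members],
            "community_abundances": abundances,
            "community_shared": list(spec.shared_metabolites),
        },
    )
    report = validate_model(joined)
    dup = [e for e in report.errors if e[0].startswith("duplicate")]
    if dup:
        raise ModelValidationError(
            "id collision after prefixing: " + "; ".join(m for _, m in dup),
            report=report,
        )
    report.raise_if_invalid()
    return joined


def community_objective(
    model: MetabolicModel,
    member_growth_reactions: Mapping[str, str],
    weights: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Abundance-weighted objective map over member growth reactions.

    ``member_growth_reactions`` maps member id to the *unprefixed* growth
    reaction id; weights default to the abundances recorded on the joined
    model (equal weights if absent) and are normalized to sum one.
    Zero-weight members are excluded from the map but stay in the model.
    Use the result as the explicit ``objective`` of :func:`~fluxscreen.
    optimize.fba`.
    """
    if weights is None:
        recorded = model.annotations.get("community_abundances", {})
        weights = {
            mid: recorded.get(mid, 1.0) for mid in member_growth_reactions
        }
    unknown_members = set(weights) - set(member_growth_reactions)
    if unknown_members:
        raise UnknownIdError(
            "weights given for unknown member(s): "
            + ", ".join(sorted(unknown_members))
        )
    total = sum(weights.values())
    if total <= 0:
        raise FluxscreenError("weights must sum to a positive value")

    known_reactions = set(model.reaction_ids)
    objective = {}
    for mid, rid in member_growth_reactions.items():
        prefixed = f"{mid}#{rid}"
        if prefixed not in known_reactions:
            raise UnknownIdError(
                f"growth reaction {rid!r} of member {mid!r} "
                f"({prefixed!r}) not present in the joined model"
            )
        w = weights.get(mid, 0.0) / total
        if w != 0.0:
            objective[prefixed] = w
    return objective
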