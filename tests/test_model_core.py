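import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fluxscreen import (
    BoundsError,
    GprParseError,
    ModelValidationError,
    UnknownIdError,
    apply_knockout,
    change_bounds,
    eval_gpr,
    parse_gpr,
    stoichiometry_matrix,
    validate_model,
)
from fluxscreen.model import (
    BoolExpr,
    GeneRef,
    Gene,
    Metabolite,
    MetabolicModel,
    Reaction,
)


# ---------------------------------------------------------------------------
# stoichiometry matrix
# ---------------------------------------------------------------------------

def test_matrix_transcribes_chain(hand_chain):
    s = stoichiometry_matrix(hand_chain)
    assert s.shape == (2, 3)
    np.testing.assert_array_equal(
        s.toarray(), [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
    )


def test_matrix_empty_model():
    model = MetabolicModel(metabolites=[Metabolite(id="A")])
    s = stoichiometry_matrix(model)
    assert s.shape == (1, 0)


def test_matrix_matches_reaction_dicts_entrywise():
    from fluxscreen import fixtures

    model = fixtures.make_random_viable(6, 5, seed=11)
    s = stoichiometry_matrix(model).toarray()
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    # rebuild entry-by-entry in an independent loop
    expected = np.zeros_like(s)
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            expected[met_index[mid], j] = coef
    np.testing.assert_array_equal(s, expected)
    # column sums = net mass creation per reaction
    np.testing.assert_allclose(
        s.sum(axis=0),
        [sum(r.stoichiometry.values()) for r in model.reactions],
    )


def test_matrix_round_trips_stoichiometry(hand_chain):
    s = stoichiometry_matrix(hand_chain).tocsc()
    for j, r in enumerate(hand_chain.reactions):
        col = s[:, [j]].tocoo()
        rebuilt = {
            hand_chain.metabolites[i].id: v for i, v in zip(col.row, col.data)
        }
        assert rebuilt == dict(r.stoichiometry)


def test_matrix_rejects_invalid_model():
    model = MetabolicModel(
        metabolites=[Metabolite(id="A")],
        reactions=[Reaction(id="r", stoichiometry={"X": 1.0})],
    )
    with pytest.raises(ModelValidationError):
        stoichiometry_matrix(model)


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("g1 and g2", BoolExpr("and", (GeneRef("g1"), GeneRef("g2")))),
        (
            "g1 or g2 and g3",  # and binds tighter than or
            BoolExpr(
                "or",
                (GeneRef("g1"), BoolExpr("and", (GeneRef("g2"), GeneRef("g3")))),
            ),
        ),
        (
            "(g1 or g2) and (g3 or g4)",
            BoolExpr(
                "and",
                (
                    BoolExpr("or", (GeneRef("g1"), GeneRef("g2"))),
                    BoolExpr("or", (GeneRef("g3"), GeneRef("g4"))),
                ),
            ),
        ),
        ("G1 AND g2", BoolExpr("and", (GeneRef("G1"), GeneRef("g2")))),
        ("  g1  ", GeneRef("g1")),
    ],
)
def test_parse_gpr_trees(text, expected):
    assert parse_gpr(text).root == expected


@pytest.mark.parametrize("text", ["", "   ", None])
def test_parse_gpr_blank_is_always_satisfied(text):
    rule = parse_gpr(text)
    assert rule.is_empty
    assert eval_gpr(rule, {"anything"})


@pytest.mark.parametrize("text", ["(g1 and g2", "g1 and", "and g1", "g1 g2)", "()"])
def test_parse_gpr_errors_carry_offset(text):
    with pytest.raises(GprParseError) as exc:
        parse_gpr(text)
    assert exc.value.offset >= 0


def test_gpr_string_round_trip():
    for text in ["g1 and (g2 or g3)", "g1 or g2 and g3", "a and b and c"]:
        rule = parse_gpr(text)
        assert parse_gpr(rule.to_string()) == rule


@pytest.mark.parametrize(
    "text,absent,expected",
    [
        ("g1 and g2 or g3", {"g1"}, True),  # OR(AND(g1,g2), g3), g3 alive
        ("g1 and g2", {"g2"}, False),
        ("g1 and g2", set(), True),
        ("g1 or g2", {"g1", "g2"}, False),
    ],
)
def test_eval_gpr(text, absent, expected):
    assert eval_gpr(parse_gpr(text), absent) is expected


_genes = st.sampled_from([f"g{i}" for i in range(5)])
_rule_text = st.recursive(
    _genes,
    lambda children: st.tuples(
        st.sampled_from(["and", "or"]), children, children
    ).map(lambda t: f"({t[1]} {t[0]} {t[2]})"),
    max_leaves=8,
)


@given(_rule_text)
def test_eval_gpr_matches_truth_table(text):
    """Parsed-rule evaluation agrees with Python's own boolean semantics on
    every assignment of the (small) gene set."""
    rule = parse_gpr(text)
    genes = sorted(rule.genes())
    for n_absent in range(len(genes) + 1):
        for absent in itertools.combinations(genes, n_absent):
            env = {g: g not in absent for g in genes}
            expected = eval(text, {"__builtins__": {}}, env)  # independent path
            assert eval_gpr(rule, set(absent)) is expected


# ---------------------------------------------------------------------------
# model edits
# ---------------------------------------------------------------------------

def test_change_bounds_replaces_only_target(chain_model):
    out = change_bounds(chain_model, "CONV1", 0.0, 0.0)
    assert out.get_reaction("CONV1").bounds == (0.0, 0.0)
    for rid in ("EX_A_e", "EX_P_e"):
        assert out.get_reaction(rid) == chain_model.get_reaction(rid)
    # source unchanged
    assert chain_model.get_reaction("CONV1").bounds == (0.0, 1000.0)


def test_change_bounds_one_side():
    model = MetabolicModel(
        metabolites=[Metabolite(id="A")],
        reactions=[Reaction(id="r", stoichiometry={"A": 1.0},
                            lower_bound=-1000.0, upper_bound=1000.0)],
    )
    out = change_bounds(model, "r", lower=-5.0)
    assert out.get_reaction("r").bounds == (-5.0, 1000.0)


def test_change_bounds_errors(chain_model):
    with pytest.raises(BoundsError):
        change_bounds(chain_model, "CONV1", 1.0, -1.0)
    with pytest.raises(UnknownIdError):
        change_bounds(chain_model, "nope", 0.0, 0.0)


def test_knockout_closes_gated_reaction(branched_model):
    out = apply_knockout(branched_model, {"gP"})
    assert out.get_reaction("BRANCH_P").bounds == (0.0, 0.0)
    assert out.get_reaction("BRANCH_W").bounds == (0.0, 1000.0)


def test_knockout_isozyme_survives(branched_isozyme_model):
    out = apply_knockout(branched_isozyme_model, {"gP"})
    assert out.get_reaction("BRANCH_P").bounds == (0.0, 1000.0)


def test_knockout_empty_set_is_identity(branched_model):
    assert apply_knockout(branched_model, set()) == branched_model


def test_knockout_idempotent(branched_model):
    once = apply_knockout(branched_model, {"gP"})
    twice = apply_knockout(once, {"gP"})
    assert once == twice


def test_knockout_unknown_gene(branched_model):
    with pytest.raises(UnknownIdError):
        apply_knockout(branched_model, {"gZZZ"})


def test_edits_do_not_alias_source(branched_model):
    import copy

    snapshot = copy.deepcopy(branched_model)
    apply_knockout(branched_model, {"gP"})
    change_bounds(branched_model, "EX_A_e", 0.0, 1.0)
    assert branched_model == snapshot


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_validate_clean_fixture(chain_model):
    report = validate_model(chain_model)
    assert report.ok and not report.warnings


def test_validate_dangling_metabolite():
    model = MetabolicModel(
        metabolites=[Metabolite(id="A")],
        reactions=[Reaction(id="r", stoichiometry={"A": -1.0, "X": 1.0})],
    )
    report = validate_model(model)
    assert [c for c, _ in report.errors] == ["dangling_metabolite"]


def test_validate_orphan_metabolite_warns():
    model = MetabolicModel(
        metabolites=[Metabolite(id="A"), Metabolite(id="lonely")],
        reactions=[Reaction(id="r", stoichiometry={"A": 1.0})],
    )
    report = validate_model(model)
    assert report.ok
    assert ("orphan_metabolite" in [c for c, _ in report.warnings])


def test_validate_duplicates_and_inverted_bounds():
    model = MetabolicModel(
        metabolites=[Metabolite(id="A"), Metabolite(id="A")],
        reactions=[Reaction(id="r", stoichiometry={"A": 1.0},
                            lower_bound=5.0, upper_bound=-5.0)],
        genes=[Gene(id="g"), Gene(id="g")],
    )
    codes = {c for c, _ in validate_model(model).errors}
    assert {"duplicate_metabolite_id", "duplicate_gene_id",
            "inverted_bounds"} <= codes
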