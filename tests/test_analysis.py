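import dataclasses

import pytest

from fluxscreen import (
    InfeasibleModelError,
    UnknownIdError,
    change_bounds,
    fba,
    fixtures,
    fva,
    pair_gene_deletion,
    production_envelope,
    single_gene_deletion,
)
from fluxscreen.model import Gene, parse_gpr
from fluxscreen.optimize import OPTIMAL

from .oracle import oracle_envelope, oracle_fva, oracle_knockout_fba

GAMMAS = [0.0, 0.5, 0.9, 1.0]


def ranges_by_id(ranges):
    return {r.reaction_id: (r.minimum, r.maximum) for r in ranges}


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_chain_fully_determined(chain_model):
    for r in fva(chain_model, gamma=1.0):
        assert r.minimum == pytest.approx(10.0, abs=1e-6)
        assert r.maximum == pytest.approx(10.0, abs=1e-6)


def test_fva_diamond_routes_free(diamond_model):
    got = ranges_by_id(fva(diamond_model, gamma=1.0))
    for route in ("ROUTE1", "ROUTE2"):
        assert got[route][0] == pytest.approx(0.0, abs=1e-6)
        assert got[route][1] == pytest.approx(10.0, abs=1e-6)
    # flux through the routes must still sum to the optimum
    assert got["EX_B_e"] == (pytest.approx(10.0, abs=1e-6),) * 2


def test_fva_waste_branch_opens_at_low_gamma(branched_model):
    tight = ranges_by_id(fva(branched_model, gamma=1.0))
    loose = ranges_by_id(fva(branched_model, gamma=0.0))
    assert tight["BRANCH_W"] == (pytest.approx(0.0, abs=1e-6),) * 2
    assert loose["BRANCH_W"][1] == pytest.approx(10.0, abs=1e-6)


@pytest.mark.parametrize("gamma", GAMMAS)
def test_fva_matches_bruteforce_oracle(all_named_fixtures, gamma):
    for name, model in all_named_fixtures.items():
        got = ranges_by_id(fva(model, gamma=gamma))
        expected = oracle_fva(model, gamma)
        for rid, (lo, hi) in expected.items():
            assert got[rid][0] == pytest.approx(lo, abs=1e-6), (name, rid)
            assert got[rid][1] == pytest.approx(hi, abs=1e-6), (name, rid)


def test_fva_ranges_nested_in_gamma():
    model = fixtures.make_random_viable(4, 3, seed=23)
    previous = None
    for gamma in GAMMAS:
        current = ranges_by_id(fva(model, gamma=gamma))
        if previous is not None:
            for rid, (lo, hi) in current.items():
                plo, phi = previous[rid]
                assert lo >= plo - 1e-6
                assert hi <= phi + 1e-6
        previous = current


def test_fba_flux_inside_gamma1_range(branched_isozyme_model):
    sol = fba(branched_isozyme_model)
    got = ranges_by_id(fva(branched_isozyme_model, gamma=1.0))
    for rid, flux in sol.fluxes.items():
        lo, hi = got[rid]
        assert lo - 1e-6 <= flux <= hi + 1e-6


def test_fva_subset_and_unknown_reaction(branched_model):
    subset = fva(branched_model, gamma=1.0, reactions=["BRANCH_W"])
    assert [r.reaction_id for r in subset] == ["BRANCH_W"]
    with pytest.raises(UnknownIdError):
        fva(branched_model, reactions=["nope"])


def test_fva_infeasible_wild_type_raises(chain_model):
    broken = change_bounds(chain_model, "EX_P_e", 11.0, 1000.0)
    with pytest.raises(InfeasibleModelError):
        fva(broken)


def test_fva_worker_count_invariance(branched_isozyme_model):
    one = fva(branched_isozyme_model, gamma=0.5, workers=1)
    two = fva(branched_isozyme_model, gamma=0.5, workers=2)
    assert one == two


# ---------------------------------------------------------------------------
# deletions
# ---------------------------------------------------------------------------

def test_single_deletion_matches_manual_edits(branched_model):
    results = {r.genes[0]: r for r in single_gene_deletion(branched_model)}
    for gene, expected_value in [("gP", 5.0), ("gU", 10.0), ("gP2", 10.0)]:
        status, oracle_value = oracle_knockout_fba(branched_model, {gene})
        r = results[gene]
        assert r.status == status == OPTIMAL
        assert r.objective_value == pytest.approx(oracle_value, rel=1e-6)
        assert r.objective_value == pytest.approx(expected_value, rel=1e-6)


def test_deletion_of_essential_gene_gives_zero_growth(chain_model):
    # gate the single conversion step by a gene: knocking it out starves the
    # model, reported as optimal with objective zero (not infeasible)
    gated = chain_model.copy()
    gated.genes = [Gene(id="gE")]
    j = gated.reaction_index()["CONV1"]
    gated.reactions[j] = dataclasses.replace(
        gated.reactions[j], gpr=parse_gpr("gE")
    )
    (result,) = single_gene_deletion(gated, ["gE"])
    assert result.status == OPTIMAL
    assert result.objective_value == pytest.approx(0.0, abs=1e-9)


def test_isozyme_single_deletions_harmless(branched_isozyme_model):
    results = single_gene_deletion(branched_isozyme_model, ["gP", "gP2"])
    for r in results:
        assert r.objective_value == pytest.approx(10.0, rel=1e-6)


def test_synthetic_lethal_pair(branched_isozyme_model):
    (pair,) = pair_gene_deletion(branched_isozyme_model, [("gP", "gP2")])
    status, expected = oracle_knockout_fba(branched_isozyme_model, {"gP", "gP2"})
    assert pair.status == status == OPTIMAL
    assert pair.objective_value == pytest.approx(expected, rel=1e-6)
    assert pair.objective_value == pytest.approx(5.0, rel=1e-6)


def test_pair_of_unused_genes_is_wild_type(branched_isozyme_model):
    wild = fba(branched_isozyme_model).objective_value
    (r,) = pair_gene_deletion(branched_isozyme_model, [("gU", "gU")])
    assert r.objective_value == pytest.approx(wild, rel=1e-6)


def test_duplicated_pair_equals_single(branched_model):
    (single,) = single_gene_deletion(branched_model, ["gP"])
    (pair,) = pair_gene_deletion(branched_model, [("gP", "gP")])
    assert pair.objective_value == pytest.approx(
        single.objective_value, rel=1e-9
    )


def test_deletion_results_ordered_and_deterministic(branched_isozyme_model):
    genes = ["gU", "gP", "gP2"]
    one = single_gene_deletion(branched_isozyme_model, genes, workers=1)
    two = single_gene_deletion(branched_isozyme_model, genes, workers=2)
    assert [r.genes for r in one] == [("gU",), ("gP",), ("gP2",)]
    assert one == two


def test_deletion_unknown_gene(branched_model):
    with pytest.raises(UnknownIdError):
        single_gene_deletion(branched_model, ["missing"])


# ---------------------------------------------------------------------------
# production envelope
# ---------------------------------------------------------------------------

def test_envelope_waste_displaces_product(envelope_model):
    table = production_envelope(envelope_model, "EX_P_e", "EX_W_e", n_points=3)
    assert table.levels == pytest.approx([0.0, 5.0, 10.0], abs=1e-6)
    assert [r.target_max for r in table.rows] == pytest.approx(
        [10.0, 5.0, 0.0], abs=1e-6
    )
    expected = oracle_envelope(envelope_model, "EX_P_e", "EX_W_e", table.levels)
    for row, (_, tmin, tmax) in zip(table.rows, expected):
        assert row.target_min == pytest.approx(tmin, abs=1e-6)
        assert row.target_max == pytest.approx(tmax, abs=1e-6)


def test_envelope_level_zero_max_is_fba_optimum(envelope_model):
    table = production_envelope(envelope_model, "EX_P_e", "EX_W_e", n_points=5)
    assert table.rows[0].target_max == pytest.approx(
        fba(envelope_model).objective_value, rel=1e-6
    )


def test_envelope_two_points_are_range_endpoints(envelope_model):
    table = production_envelope(envelope_model, "EX_P_e", "EX_W_e", n_points=2)
    assert table.levels == pytest.approx([0.0, 10.0], abs=1e-6)


def test_envelope_degenerate_range_single_row(chain_model):
    # pin the uptake so the conversion flux is fixed by stoichiometry
    pinned = change_bounds(chain_model, "EX_A_e", 10.0, 10.0)
    table = production_envelope(pinned, "EX_P_e", "CONV1", n_points=5)
    assert len(table.rows) == 1
    assert table.rows[0].level == pytest.approx(10.0, abs=1e-6)


def test_envelope_monotone_levels_and_min_le_max(envelope_model):
    table = production_envelope(envelope_model, "EX_P_e", "EX_W_e", n_points=7)
    levels = table.levels
    assert all(b > a for a, b in zip(levels, levels[1:]))
    for row in table.rows:
        if row.status_min == row.status_max == OPTIMAL:
            assert row.target_min <= row.target_max + 1e-6


def test_envelope_worker_invariance(envelope_model):
    one = production_envelope(envelope_model, "EX_P_e", "EX_W_e", 4, workers=1)
    two = production_envelope(envelope_model, "EX_P_e", "EX_W_e", 4, workers=2)
    assert one == two
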