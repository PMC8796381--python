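import copy
import os
import pickle

import numpy as np
import pytest

from fluxscreen import (
    BoundChange,
    Knockout,
    ObjectiveChange,
    ScreenConfigError,
    ScreenError,
    UnknownIdError,
    Variant,
    apply_variant,
    fva,
    screen,
    screen_fallible,
    variant_grid,
)

IDENTITY = Variant(())
KO_GP = Variant((Knockout({"gP"}),), label="ko_gP")


def test_apply_variant_composes_left_to_right(branched_model):
    v = Variant((Knockout({"gP"}), BoundChange("EX_A_e", 0.0, 5.0)))
    out = apply_variant(branched_model, v)
    assert out.get_reaction("BRANCH_P").bounds == (0.0, 0.0)
    assert out.get_reaction("EX_A_e").bounds == (0.0, 5.0)


def test_apply_variant_last_write_wins(branched_model):
    v = Variant((BoundChange("BRANCH_P", 0.0, 5.0), Knockout({"gP"})))
    out = apply_variant(branched_model, v)
    assert out.get_reaction("BRANCH_P").bounds == (0.0, 0.0)


def test_apply_variant_identity_is_deep_copy(branched_model):
    out = apply_variant(branched_model, IDENTITY)
    assert out == branched_model
    assert out is not branched_model


def test_apply_variant_unknown_id_names_variant(branched_model):
    bad = Variant((Knockout({"nope"}),), label="my_bad_variant")
    with pytest.raises(UnknownIdError, match="my_bad_variant"):
        apply_variant(branched_model, bad)


def test_objective_change_descriptor(branched_model):
    v = Variant((ObjectiveChange({"EX_W_e": 1.0}),))
    out = apply_variant(branched_model, v)
    assert out.objective() == {"EX_W_e": 1.0}


def test_variant_grid_shapes_and_row_major_order():
    a = [Variant((), label="a0"), Variant((), label="a1")]
    b = [Variant((), label=f"b{i}") for i in range(3)]
    grid = variant_grid([a, b])
    assert grid.shape == (2, 3)
    labels = [v.label for v in grid]
    assert labels == ["a0|b0", "a0|b1", "a0|b2", "a1|b0", "a1|b1", "a1|b2"]

    assert variant_grid([b]).shape == (3,)
    assert variant_grid([a, a, a]).size == 8

    with pytest.raises(ScreenConfigError):
        variant_grid([a, []])
    with pytest.raises(ScreenConfigError):
        variant_grid([])


def test_screen_knockout_axis_objectives(branched_model):
    result = screen(branched_model, [[IDENTITY, KO_GP]], "fba_objective")
    assert result.shape == (2,)
    assert result.values.tolist() == pytest.approx([10.0, 5.0], rel=1e-6)
    assert result.labels.tolist() == ["identity", "ko_gP"]


def test_screen_deterministic_across_worker_counts(branched_isozyme_model):
    axes = [
        [IDENTITY, Variant((Knockout({"gP"}),)),
         Variant((Knockout({"gP", "gP2"}),))],
        [Variant((BoundChange("EX_A_e", 0.0, ub),)) for ub in (10.0, 4.0)],
    ]
    results = [
        screen(branched_isozyme_model, axes, "fba_objective", workers=w)
        for w in (1, 2, max(2, os.cpu_count() or 1))
    ]
    blobs = {
        pickle.dumps((r.values.tolist(), r.labels.tolist(), r.axis_labels))
        for r in results
    }
    assert len(blobs) == 1
    assert results[0].shape == (3, 2)


def test_screen_identity_embedding_equals_direct_analysis(branched_model):
    result = screen(
        branched_model, [[IDENTITY]], "fva", analysis_args={"gamma": 1.0}
    )
    assert result.values[(0,)] == fva(branched_model, gamma=1.0)


def test_screen_leaves_base_model_untouched(branched_model):
    snapshot = copy.deepcopy(branched_model)
    screen(branched_model, [[IDENTITY, KO_GP]], "fba_objective", workers=2)
    assert branched_model == snapshot


def test_screen_fva_over_knockouts(branched_model):
    """The flagship composition: flux variability inside each knockout."""
    result = screen(
        branched_model,
        [[IDENTITY, KO_GP]],
        "fva",
        analysis_args={"gamma": 1.0},
    )
    ko_ranges = {r.reaction_id: r for r in result.values[(1,)]}
    assert ko_ranges["BRANCH_P"].minimum == pytest.approx(0.0, abs=1e-6)
    assert ko_ranges["BRANCH_P"].maximum == pytest.approx(0.0, abs=1e-6)
    # and in the knockout all flux must run through the wasteful branch
    assert ko_ranges["BRANCH_W"].minimum == pytest.approx(10.0, abs=1e-6)


def test_screen_strict_aborts_on_bad_cell(branched_model):
    bad = Variant((Knockout({"ghost"}),), label="ghost_ko")
    with pytest.raises(UnknownIdError):
        screen(branched_model, [[IDENTITY, bad]], "fba_objective")


def test_screen_fallible_stores_error_values(branched_model):
    bad = Variant((Knockout({"ghost"}),), label="ghost_ko")
    result = screen_fallible(
        branched_model, [[IDENTITY, bad, KO_GP]], "fba_objective"
    )
    assert result.shape == (3,)
    assert result.values[0] == pytest.approx(10.0)
    err = result.values[1]
    assert isinstance(err, ScreenError)
    assert err.label == "ghost_ko" and "ghost" in err.message
    assert result.values[2] == pytest.approx(5.0)
    assert result.n_failed == 1


def test_screen_fallible_equals_screen_without_failures(branched_model):
    axes = [[IDENTITY, KO_GP]]
    strict = screen(branched_model, axes, "fba_objective")
    loose = screen_fallible(branched_model, axes, "fba_objective")
    assert strict.values.tolist() == loose.values.tolist()
    assert strict.labels.tolist() == loose.labels.tolist()


def test_screen_all_cells_fail(branched_model):
    bad = Variant((Knockout({"ghost"}),))
    result = screen_fallible(branched_model, [[bad, bad]], "fba_objective")
    assert all(isinstance(v, ScreenError) for v in result.values)
    assert result.n_failed == 2


def test_cell_count_conservation(branched_isozyme_model):
    rng = np.random.default_rng(5)
    genes = ["gP", "gP2", "gU"]
    for _ in range(3):
        shape = tuple(int(x) for x in rng.integers(1, 4, size=2))
        axes = [
            [Variant((Knockout({rng.choice(genes)}),)) for _ in range(k)]
            for k in shape
        ]
        result = screen_fallible(
            branched_isozyme_model, axes, "fba_objective", workers=2
        )
        assert result.shape == shape
        assert result.values.size == int(np.prod(shape))
        assert not any(v is None for v in result.values.flat)


def test_unregistered_analysis_fails_fast(branched_model):
    with pytest.raises(ScreenConfigError, match="not registered"):
        screen(branched_model, [[IDENTITY]], "no_such_analysis")
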