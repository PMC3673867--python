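import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import vertex_fva
from voltflux import fixtures
from voltflux.errors import UnknownIdError
from voltflux.fatmin import (
    augment_network,
    identify_targets,
    run_fatmin,
    weighted_ranges,
)
from voltflux.lp_engine import flux_variability, minimize_reaction_flux, optimize


class TestWeightedRanges:
    def test_sign_and_scale_arithmetic(self, mini):
        ranges = {"ACOX": (0.0, 4.5), "ETC": (1.0, 3.0), "EX_ac": (-18.0, 0.0)}
        w = weighted_ranges(mini, ranges, "nadh")
        assert w["ACOX"] == pytest.approx((0.0, 18.0))  # coefficient +4
        assert w["ETC"] == pytest.approx((-3.0, -1.0))  # coefficient -1
        assert "EX_ac" not in w  # no NADH in the exchange

    def test_matches_per_reaction_hand_computation(self, mini):
        fva = flux_variability(mini)
        w = weighted_ranges(mini, fva, "nadh")
        for rid, (lo, hi) in w.items():
            coeff = mini.reactions[rid].stoichiometry["nadh"]
            expect = sorted((coeff * fva[rid][0], coeff * fva[rid][1]))
            assert (lo, hi) == pytest.approx(tuple(expect))

    def test_unknown_metabolite_rejected(self, mini):
        with pytest.raises(UnknownIdError):
            weighted_ranges(mini, {}, "ghost")


class TestIdentifyTargets:
    @pytest.mark.parametrize(
        "wrange, expected",
        [
            ({"r": (0.0, 150.0)}, [("r", False)]),  # high producer
            ({"r": (-150.0, 150.0)}, [("r", True)]),  # reversible, needs split
            ({"r": (-150.0, 50.0)}, [("r", True)]),  # high consumer
            ({"r": (-50.0, 99.0)}, []),  # within threshold
        ],
    )
    def test_threshold_classification(self, wrange, expected):
        assert identify_targets(wrange, 100.0) == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            identify_targets({}, 0.0)


class TestAugmentNetwork:
    def test_fluxmin_is_sum_of_producing_fluxes(self, fig5):
        # tagging every producer of C reproduces the drain identity
        # FluxMin = v1 + v2 + v5 + v6
        producers = [(rid, False) for rid in ("R1", "R2", "R5A", "R6A")]
        aug, _f, drain = augment_network(fig5, producers, "C")
        sol = optimize(aug)
        total = sum(sol.fluxes[r] for r, _ in producers)
        assert sol.fluxes[drain] == pytest.approx(total, abs=1e-6)

    def test_augmentation_preserves_optimum(self, fig5, mini):
        for model, targets, met in (
            (fig5, [("R5A", False), ("R6A", False)], "C"),
            (mini, [("NADHL2", False)], "nadh"),
        ):
            aug, _f, _d = augment_network(model, targets, met)
            assert optimize(aug).objective_value == pytest.approx(
                optimize(model).objective_value, abs=1e-6
            )

    def test_augmentation_alone_leaves_fva_bounds_unchanged(self, fig5):
        pre = flux_variability(fig5)
        aug, _f, _d = augment_network(
            fig5, [("R5A", False), ("R6A", False)], "C"
        )
        post = flux_variability(aug)
        for rid in fig5.reactions:
            assert post[rid][0] == pytest.approx(pre[rid][0], abs=1e-6)
            assert post[rid][1] == pytest.approx(pre[rid][1], abs=1e-6)

    def test_id_collision_renames_with_warning(self, fig5):
        fig5.add_metabolite(fixtures.Metabolite("F"))
        fig5.add_reaction(fixtures.Reaction("FluxMin", {"F": -1.0}, 0, 10))
        with pytest.warns(UserWarning, match="already exists"):
            aug, f_id, drain_id = augment_network(fig5, [("R5A", False)], "C")
        assert f_id == "F_1" and drain_id == "FluxMin_1"

    def test_zero_targets_flagged(self, fig5):
        with pytest.warns(UserWarning, match="inert"):
            augment_network(fig5, [], "C")


class TestRunFatmin:
    def test_figure5_cycles_collapse_production_preserved(self, fig5):
        result = run_fatmin(fig5, metabolite="C", threshold=100.0)
        assert {r for r, _ in result.target_reactions} == {
            "R5A", "R5B", "R6A", "R6B"
        }
        assert result.fluxmin_minimum == pytest.approx(0.0, abs=1e-6)
        for rid in fixtures.FIGURE5_CYCLE_REACTIONS:
            lo, hi = result.flux_ranges[rid]
            assert (lo, hi) == pytest.approx((0.0, 0.0), abs=1e-5)
        # total production v1 + v2 keeps its full [0, 10] spread per route
        for rid in fixtures.FIGURE5_PRODUCTION_REACTIONS:
            assert result.flux_ranges[rid] == pytest.approx((0.0, 10.0), abs=1e-5)

    def test_no_targets_degenerates_to_plain_fva(self, fig5):
        result = run_fatmin(fig5, metabolite="C", threshold=2000.0)
        assert result.target_reactions == []
        assert result.ranges == result.pre_ranges

    def test_post_ranges_subset_of_pre_ranges(self, mini):
        result = run_fatmin(mini, metabolite="nadh", threshold=100.0)
        for rid, (lo, hi) in result.ranges.items():
            plo, phi = result.pre_ranges[rid]
            assert lo >= plo - 1e-5 and hi <= phi + 1e-5

    def test_mini_fixture_loop_eliminated_real_producers_kept(self, mini):
        result = run_fatmin(mini, metabolite="nadh", threshold=100.0)
        assert {r for r, _ in result.target_reactions} == set(
            fixtures.MINI_GEOBACTER_LOOP
        )
        for rid in fixtures.MINI_GEOBACTER_LOOP:
            assert result.ranges[rid] == pytest.approx((0.0, 0.0), abs=1e-4)
        # the physiological producer keeps its committed flux: at maximal
        # growth ACOX = 18 - 10*g = 6.0375, times 4 NADH per acetate
        assert result.ranges["ACOX"][1] == pytest.approx(4 * 6.0375, abs=1e-3)

    def test_post_ranges_match_vertex_oracle(self):
        model, spec = fixtures.random_loop_network(
            fixtures.LoopSpec(n_reactions=12, n_loops=2, seed=3)
        )
        result = run_fatmin(model, metabolite="tgt", threshold=100.0)
        final = result.augmented_model
        _z, oracle = vertex_fva(final)
        for rid, (lo, hi) in result.flux_ranges.items():
            assert lo == pytest.approx(oracle[rid][0], abs=1e-4)
            assert hi == pytest.approx(oracle[rid][1], abs=1e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_loops=st.integers(1, 4),
        share=st.booleans(),
    )
    def test_planted_loops_always_recovered(self, seed, n_loops, share):
        model, spec = fixtures.random_loop_network(
            fixtures.LoopSpec(
                n_reactions=8 + 3 * n_loops, n_loops=n_loops,
                seed=seed, share_backbone=share,
            )
        )
        result = run_fatmin(model, metabolite="tgt", threshold=100.0)
        for members in spec.loop_members:
            for rid in members:
                lo, hi = result.flux_ranges[rid]
                if share and rid.startswith("B"):
                    # superposition: the producing reaction shared with the
                    # backbone keeps exactly its productive component
                    assert (lo, hi) == pytest.approx((10.0, 10.0), abs=1e-4)
                else:
                    assert (lo, hi) == pytest.approx((0.0, 0.0), abs=1e-4)

    def test_superposed_loop_reduced_to_productive_component(self):
        model, spec = fixtures.random_loop_network(
            fixtures.LoopSpec(n_reactions=12, n_loops=2, seed=1, share_backbone=True)
        )
        result = run_fatmin(model, metabolite="tgt", threshold=100.0)
        producer = [r for r in spec.loop_members[0] if r.startswith("B")][0]
        ret = [r for r in spec.loop_members[0] if not r.startswith("B")][0]
        assert result.flux_ranges[producer] == pytest.approx((10.0, 10.0), abs=1e-4)
        assert result.flux_ranges[ret] == pytest.approx((0.0, 0.0), abs=1e-4)
        assert result.fluxmin_minimum == pytest.approx(10.0, abs=1e-4)

    def test_fluxmin_bounded_by_producing_wmax_sum(self, mini):
        result = run_fatmin(mini, metabolite="nadh", threshold=100.0)
        cap = sum(hi for _lo, hi in result.pre_ranges.values() if hi > 0)
        assert 0.0 <= result.fluxmin_minimum <= cap + 1e-6

    def test_two_target_metabolites_compose_sequentially(self, mini):
        # a second pass over another metabolite introduces its own artificial
        # metabolite/drain and leaves the first pass's conclusions intact
        first = run_fatmin(mini, metabolite="qxh", threshold=100.0)
        assert first.target_reactions  # the loop runs through qxh too
        assert first.fluxmin_id in first.augmented_model.reactions
        # the second metabolite is analysed on the already-augmented model;
        # its loop flux is gone, so the pass degenerates to clean FVA with
        # the first drain still in place
        second = run_fatmin(first.augmented_model, metabolite="nadh", threshold=100.0)
        assert second.target_reactions == []
        for rid in fixtures.MINI_GEOBACTER_LOOP:
            lo, hi = second.ranges[rid]
            assert (lo, hi) == pytest.approx((0.0, 0.0), abs=1e-4)
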