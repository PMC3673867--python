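import math

import pytest

from voltflux import fixtures
from voltflux.errors import ModelParseError, ModelValidationError, UnknownIdError
from voltflux.lp_engine import flux_variability, optimize
from voltflux.model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    load_model,
    parse_toy_format,
    read_sbml,
    set_flux_bounds,
    split_reversible,
    stoich_coefficient,
    write_sbml,
    write_toy_format,
)

TOY_TEXT = """\
# two-route toy
SRC : --> A[c] | 0 10
R1 : A[c] --> C[c]
R2 : [c] : A --> C
REV : C[c] <==> D[c] | -5 5
DRAIN : C[c] --> | 0 1000 | 1.0
PAPERISH : [c] : akg + coa + nad --> co2 + nadh + succoa
CYT : (2) ficytcc[c] + mql7[c] --> (2) focytcc[c] + h[e] + h[c] + mqn7[c]
"""


def _structurally_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    if set(a.reactions) != set(b.reactions) or set(a.metabolites) != set(b.metabolites):
        return False
    for rid, rxn in a.reactions.items():
        other = b.reactions[rid]
        if rxn.stoichiometry != other.stoichiometry:
            return False
        if (rxn.lower_bound, rxn.upper_bound) != (other.lower_bound, other.upper_bound):
            return False
    return a.objective == b.objective


class TestToyFormat:
    def test_parse_basics(self):
        model = parse_toy_format(TOY_TEXT)
        assert set(model.objective) == {"DRAIN"}
        assert model.reactions["SRC"].upper_bound == 10
        # default bounds: irreversible [0, 1000], reversible [-1000, 1000]
        assert (model.reactions["R1"].lower_bound, model.reactions["R1"].upper_bound) == (0, 1000)
        assert model.reactions["REV"].reversible
        # compartment-prefix dialect equals per-metabolite brackets
        assert model.reactions["R2"].stoichiometry == model.reactions["R1"].stoichiometry

    def test_parenthesised_coefficients_and_compartments(self):
        model = parse_toy_format(TOY_TEXT)
        assert model.reactions["CYT"].stoichiometry["ficytcc"] == -2
        assert model.reactions["CYT"].stoichiometry["focytcc"] == 2
        # h appears in both compartments as distinct species
        assert "h" in model.metabolites and "h_e" in model.metabolites
        assert model.reactions["PAPERISH"].stoichiometry["nadh"] == 1

    def test_roundtrip_is_fixed_point(self):
        first = parse_toy_format(TOY_TEXT)
        second = parse_toy_format(write_toy_format(first))
        assert _structurally_equal(first, second)

    @pytest.mark.parametrize(
        "bad",
        [
            "R1 : A[c] C[c]",  # no arrow
            "R1 : A[c] --> C[c] | zero ten",  # bad bounds
            " : A[c] --> C[c]",  # missing id
        ],
    )
    def test_parse_errors(self, bad):
        with pytest.raises(ModelParseError):
            parse_toy_format(bad)

    def test_empty_model_rejected(self):
        with pytest.raises(ModelValidationError):
            parse_toy_format("# only a comment\n")


class TestSBML:
    def test_roundtrip_preserves_structure(self, tmp_path, mini):
        path = tmp_path / "mini.xml"
        write_sbml(mini, path)
        back = read_sbml(path)
        assert _structurally_equal(mini, back)
        assert back.biomass_reaction_id == "BIOMASS"

    def test_load_model_dispatches_by_content(self, tmp_path, fig5):
        sbml_path = tmp_path / "fig5.xml"
        toy_path = tmp_path / "fig5.txt"
        write_sbml(fig5, sbml_path)
        toy_path.write_text(write_toy_format(fig5))
        assert _structurally_equal(load_model(sbml_path), load_model(toy_path))

    def test_malformed_document_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model><notclosed></model></sbml>")
        with pytest.raises(ModelParseError):
            read_sbml(bad)

    def test_missing_file_raises(self):
        with pytest.raises(ModelParseError):
            load_model("/no/such/model.xml")


class TestValidation:
    def test_dangling_metabolite_rejected(self):
        model = MetabolicModel(id="bad")
        model.add_metabolite(Metabolite("a"))
        with pytest.raises(ModelValidationError, match="undeclared"):
            model.add_reaction(Reaction("r", {"a": -1, "ghost": 1}))

    def test_dangling_objective_rejected(self, fig5):
        fig5.objective["ghost"] = 1.0
        with pytest.raises(ModelValidationError):
            fig5.validate()

    def test_bad_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", {"a": 1}, lower_bound=2, upper_bound=1)


class TestEditing:
    def test_set_flux_bounds_updates_one_reaction(self, mini):
        capped = set_flux_bounds(mini, "EX_ac", -9.0, 0.0)
        assert capped.reactions["EX_ac"].lower_bound == -9.0
        assert mini.reactions["EX_ac"].lower_bound == -18.0  # original untouched
        for rid in mini.reactions:
            if rid != "EX_ac":
                assert capped.reactions[rid].lower_bound == mini.reactions[rid].lower_bound

    def test_set_flux_bounds_errors(self, mini):
        with pytest.raises(UnknownIdError):
            set_flux_bounds(mini, "ghost", 0, 1)
        with pytest.raises(ModelValidationError):
            set_flux_bounds(mini, "EX_ac", 1, 0)

    def test_equality_bound_forces_flux(self, mini):
        # pinning ACOX to 5 must make the FBA witness carry exactly 5
        pinned = set_flux_bounds(mini, "ACOX", 5.0, 5.0)
        sol = optimize(pinned)
        assert sol.fluxes["ACOX"] == pytest.approx(5.0, abs=1e-6)

    def test_zero_bound_blocks_reaction(self):
        # without the maintenance-ATP floor, blocking the oxidation step
        # removes the only NADH/ATP source and growth collapses to zero
        model = fixtures.mini_geobacter(ngam=0.0)
        blocked = set_flux_bounds(model, "ACOX", 0.0, 0.0)
        sol = optimize(blocked)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_stoich_coefficient(self, mini):
        assert stoich_coefficient(mini, "ACOX", "nadh") == 4
        assert stoich_coefficient(mini, "CYOR1m", "ficytcc") == -2
        assert stoich_coefficient(mini, "ACOX", "absent_metabolite") == 0
        with pytest.raises(UnknownIdError):
            stoich_coefficient(mini, "ghost", "nadh")


class TestSplitReversible:
    def test_split_definition(self, mini):
        split = split_reversible(mini, "EX_ac")
        fwd, bwd = split.reactions["EX_ac_fwd"], split.reactions["EX_ac_bwd"]
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 0.0)
        assert (bwd.lower_bound, bwd.upper_bound) == (0.0, 18.0)
        assert bwd.stoichiometry == {"ac_e": 1.0}
        # forward copy keeps the column, backward copy negates it, so any
        # original flux v maps to (max(v,0), max(-v,0)) with the same S·v
        orig = mini.reactions["EX_ac"].stoichiometry
        assert fwd.stoichiometry == orig
        assert bwd.stoichiometry == {m: -c for m, c in orig.items()}

    def test_split_preserves_fba_optimum(self, mini):
        before = optimize(mini).objective_value
        after = optimize(split_reversible(mini, "EX_ac")).objective_value
        assert after == pytest.approx(before, abs=1e-6)

    def test_split_preserves_net_fva_range(self, mini):
        # the split pair admits a fwd+bwd futile cycle, so individual ranges
        # widen; the *net* flux fwd - bwd must keep the original FVA range.
        # A tracking metabolite/reaction turns the net flux into a reaction
        # whose FVA range can be read off directly.
        obj = {"BIOMASS": 1.0}
        pre = flux_variability(mini, obj)["EX_co2"]
        split = split_reversible(mini, "EX_co2")
        split.add_metabolite(Metabolite("net_trk"))
        split.reactions["EX_co2_fwd"].stoichiometry["net_trk"] = 1.0
        split.reactions["EX_co2_bwd"].stoichiometry["net_trk"] = -1.0
        split.add_reaction(Reaction("NET", {"net_trk": -1.0}, -1000.0, 1000.0))
        post = flux_variability(split, obj)["NET"]
        assert post[0] == pytest.approx(pre[0], abs=1e-5)
        assert post[1] == pytest.approx(pre[1], abs=1e-5)

    def test_split_irreversible_is_noop_with_warning(self, mini):
        with pytest.warns(UserWarning, match="no-op"):
            out = split_reversible(mini, "ACOX")
        assert set(out.reactions) == set(mini.reactions)
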