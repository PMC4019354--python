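"""Formula parsing, stoichiometric matrix construction and elemental
bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyc3hp import (
    FormulaError,
    Metabolite,
    Model,
    Reaction,
    build_stoichiometric_matrix,
    check_mass_balance,
    formula_to_string,
    net_biomass_carbon,
    parse_formula,
)
from glyc3hp.core import ModelValidationError


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C3H8O3", {"C": 3, "H": 8, "O": 3}),  # glycerol
            ("H2O", {"H": 2, "O": 1}),
            ("C10H12N5O10P2", {"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}),
            ("", {}),
            ("Fe2S2", {"Fe": 2, "S": 2}),
            ("CHO2", {"C": 1, "H": 1, "O": 2}),
        ],
    )
    def test_examples(self, formula, expected):
        assert parse_formula(formula) == expected

    def test_carbon_count_defaults_to_zero(self):
        assert parse_formula("H2O").get("C", 0) == 0
        assert parse_formula("C10H12N5O10P2")["C"] == 10

    @pytest.mark.parametrize("bad", ["c3H8", "3CH8", "C3h8", "C3-H8", "C3 H8"])
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises(FormulaError, match="offset"):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "Mg"]),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_roundtrip_through_string(self, counts):
        assert parse_formula(formula_to_string(counts)) == counts


class TestStoichiometricMatrix:
    def test_shape_and_bijection(self, core_model):
        sm = build_stoichiometric_matrix(core_model)
        assert sm.shape == (len(core_model.metabolites), len(core_model.reactions))
        # one column per reaction, in input order
        assert list(sm.col_index) == [r.id for r in core_model.reactions]
        assert list(sm.row_index) == [m.id for m in core_model.metabolites]
        assert len(set(sm.col_index.values())) == len(core_model.reactions)

    def test_coefficients_match_reactions(self, core_model):
        sm = build_stoichiometric_matrix(core_model)
        dense = sm.S.toarray()
        rxn = core_model.reaction("GLYK")
        j = sm.col_index["GLYK"]
        for met_id, coef in rxn.stoichiometry.items():
            assert dense[sm.row_index[met_id], j] == coef
        # untouched entries are zero
        assert np.count_nonzero(dense[:, j]) == len(rxn.stoichiometry)

    def test_exchange_columns_have_one_entry(self, core_model):
        sm = build_stoichiometric_matrix(core_model)
        dense = sm.S.toarray()
        for rxn in core_model.exchanges:
            assert np.count_nonzero(dense[:, sm.col_index[rxn.id]]) == 1


class TestMassBalance:
    def test_fixture_is_balanced(self, core_model):
        result = check_mass_balance(core_model, elements=("C", "H", "O", "N", "P", "S"))
        assert result.balanced, result.imbalances
        assert not result.missing

    def test_corrupted_reaction_reports_imbalance(self, core_model):
        broken = core_model.copy()
        # drop the water product of the lumped glyoxalase step
        del broken.reaction("GLYOX").stoichiometry["h2o_c"]
        result = check_mass_balance(broken, elements=("C", "H", "O"))
        found = {(r, e): x for r, e, x in result.imbalances}
        assert abs(found[("GLYOX", "H")]) == pytest.approx(2)
        assert abs(found[("GLYOX", "O")]) == pytest.approx(1)
        assert ("GLYOX", "C") not in found

    def test_exchanges_and_biomass_are_exempt(self, core_model):
        result = check_mass_balance(core_model)
        assert "EX_glyc_e" in result.skipped
        assert "BIOMASS" in result.skipped

    def test_missing_formula_reported_not_fatal(self, core_model):
        broken = core_model.copy()
        broken.metabolite("mthgxl_c").formula.clear()
        result = check_mass_balance(broken)
        assert ("GLYOX", "mthgxl_c") in result.missing


class TestNetBiomassCarbon:
    @staticmethod
    def _toy(stoich_extra=None):
        mets = [
            Metabolite("x_c", formula={"C": 1}),
            Metabolite("atp_c", formula={"C": 10}),
            Metabolite("adp_c", formula={"C": 10}),
            Metabolite("pi_c", formula={"P": 1, "O": 4, "H": 1}),
        ]
        stoich = {"x_c": -40.0}
        stoich.update(stoich_extra or {})
        rxns = [
            Reaction("BIO", stoichiometry=stoich),
            Reaction("DUMMY", stoichiometry={"x_c": 1.0}),
        ]
        return Model("toy", mets, rxns, biomass_reaction_id="BIO")

    def test_toy_biomass(self):
        assert net_biomass_carbon(self._toy()) == pytest.approx(40.0)

    def test_atp_hydrolysis_cancels(self):
        with_gam = self._toy({"atp_c": -30.0, "adp_c": 30.0, "pi_c": 30.0})
        assert net_biomass_carbon(with_gam) == pytest.approx(40.0)

    def test_missing_formula_names_metabolite(self):
        model = self._toy()
        model.metabolite("x_c").formula.clear()
        with pytest.raises(ModelValidationError, match="x_c"):
            net_biomass_carbon(model)

    def test_fixture_value_matches_spec_carbon_content(self, core_model):
        assert net_biomass_carbon(core_model) == pytest.approx(40.0)
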