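"""Carbon-molar yield accounting, flux-map normalization and the OUR sweep."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyc3hp import (
    apply_knockout,
    cmol_yield,
    normalize_flux_map,
    our_sweep,
    relative_growth,
    solve_lexicographic,
    yield_table,
)


class TestCmolYield:
    @pytest.mark.parametrize(
        "pf, pc, sf, sc, expected",
        [
            (15.0, 3, 15.0, 3, 100.0),  # all carbon to a C3 product
            (0.0, 3, 15.0, 3, 0.0),
            (10.575, 3, 15.0, 3, 70.5),
            (7.5, 2, 15.0, 3, 100.0 / 3),  # C2 product
        ],
    )
    def test_examples(self, pf, pc, sf, sc, expected):
        assert cmol_yield(pf, pc, sf, sc) == pytest.approx(expected)

    def test_zero_substrate_rejected(self):
        with pytest.raises(ValueError):
            cmol_yield(1.0, 3, 0.0, 3)
        with pytest.raises(ValueError):
            cmol_yield(1.0, 3, -5.0, 3)

    @given(
        pf=st.floats(0.01, 100), sf=st.floats(0.01, 100), k=st.floats(0.1, 10)
    )
    @settings(max_examples=100, derandomize=True)
    def test_linearity(self, pf, sf, k):
        base = cmol_yield(pf, 3, sf, 3)
        assert cmol_yield(k * pf, 3, sf, 3) == pytest.approx(k * base, rel=1e-9)
        assert cmol_yield(pf, 3, k * sf, 3) == pytest.approx(base / k, rel=1e-9)


class TestRelativeGrowth:
    def test_examples(self):
        assert relative_growth(0.5, 0.5) == 100.0
        assert relative_growth(0.0, 0.5) == 0.0
        assert relative_growth(0.24, 0.48) == pytest.approx(50.0)

    def test_zero_wildtype_rejected(self):
        with pytest.raises(ValueError):
            relative_growth(0.1, 0.0)


class TestYieldTable:
    def test_carbon_closure(self, conditioned_model):
        """Product + CO2 + biomass yields close the carbon balance at 100."""
        sol = solve_lexicographic(conditioned_model, secondary="EX_3hp_e")
        report = yield_table(sol, conditioned_model)
        assert report.total_carbon_recovery == pytest.approx(100.0, abs=0.1)

    def test_knockout_closure_and_absent_products(self, conditioned_model):
        ko = apply_knockout(conditioned_model, ["tpiA", "zwf"])
        sol = solve_lexicographic(ko, secondary="EX_3hp_e")
        report = yield_table(sol, ko)
        assert report.total_carbon_recovery == pytest.approx(100.0, abs=0.1)
        assert report.product_yields["succinate"] == 0.0
        assert report.product_yields["13pdo"] == 0.0
        assert report.product_yields["3hp"] > 0.0

    def test_substrate_is_consumed_flux_not_bound(self, producer_model):
        from glyc3hp import Condition, set_condition, solve_fba

        # offer far more glycerol than the cell can use oxygen for
        rich = set_condition(producer_model, Condition(100.0, 2.0))
        sol = solve_fba(rich)
        report = yield_table(sol, rich)
        assert report.consumed_glycerol_flux <= 100.0
        assert report.total_carbon_recovery == pytest.approx(100.0, abs=0.1)

    def test_zero_uptake_rejected(self, conditioned_model):
        closed = conditioned_model.copy()
        for rxn in closed.exchanges:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        closed.reaction("ATPM").lower_bound = 0.0
        from glyc3hp import solve_fba

        sol = solve_fba(closed)
        with pytest.raises(ValueError, match="yield basis"):
            yield_table(sol, closed)


class TestNormalizeFluxMap:
    def test_glycerol_uptake_is_100_percent(self, conditioned_model):
        sol = solve_lexicographic(conditioned_model, secondary="EX_3hp_e")
        fm = normalize_flux_map(sol, ["EX_glyc_e"])
        assert fm["EX_glyc_e"] == pytest.approx(-100.0)

    def test_disabled_reaction_maps_to_zero(self, conditioned_model):
        ko = apply_knockout(conditioned_model, ["tpiA"])
        sol = solve_lexicographic(ko, secondary="EX_3hp_e")
        assert normalize_flux_map(sol, ["TPI"])["TPI"] == 0.0

    def test_ed_flux_zero_in_tpiA_zwf_double_knockout(self, conditioned_model):
        ko = apply_knockout(conditioned_model, ["tpiA", "zwf"])
        sol = solve_lexicographic(ko, secondary="EX_3hp_e")
        fm = normalize_flux_map(sol, ["EDD", "MGSA"])
        assert fm["EDD"] == pytest.approx(0.0, abs=1e-4)
        assert fm["MGSA"] > 1.0  # methylglyoxal shunt carries the carbon

    def test_unknown_reaction_raises(self, conditioned_model):
        sol = solve_lexicographic(conditioned_model, secondary="EX_3hp_e")
        with pytest.raises(KeyError):
            normalize_flux_map(sol, ["NOPE"])


class TestOurSweep:
    def test_reference_point_matches_single_run(self, producer_model):
        rows = our_sweep(producer_model, 15.0, [10.0])
        from glyc3hp import Condition, set_condition

        cond = set_condition(producer_model, Condition(15.0, 10.0))
        sol = solve_lexicographic(cond, secondary="EX_3hp_e")
        report = yield_table(sol, cond)
        our, mu, yld = rows[0]
        assert our == 10.0
        assert mu == pytest.approx(sol.primary_value, abs=1e-9)
        assert yld == pytest.approx(report.product_yields["3hp"], abs=1e-9)

    def test_growth_nondecreasing_in_our(self, producer_model):
        ko = apply_knockout(producer_model, ["tpiA", "zwf"])
        rows = our_sweep(ko, 15.0, [5, 8, 10, 12, 15, 18, 20])
        growth = [mu for _, mu, _ in rows]
        assert all(b >= a - 1e-6 for a, b in zip(growth, growth[1:]))

    def test_rows_in_input_order(self, producer_model):
        rows = our_sweep(producer_model, 15.0, [12.0, 8.0, 10.0])
        assert [r[0] for r in rows] == [12.0, 8.0, 10.0]
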