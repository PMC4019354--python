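"""Gene deletion through GPR rules and single/double knockout screens."""

import itertools

import pytest

from glyc3hp import (
    apply_knockout,
    disabled_reactions,
    double_knockout_screen,
    single_knockout_screen,
    solve_lexicographic,
    yield_table,
)
from conftest import FIXTURE_GENES


class TestApplyKnockout:
    def test_tpiA_disables_triosephosphate_isomerase(self, conditioned_model):
        ko = apply_knockout(conditioned_model, ["tpiA"])
        rxn = ko.reaction("TPI")
        assert rxn.lower_bound == rxn.upper_bound == 0.0
        # the input model is untouched
        assert conditioned_model.reaction("TPI").upper_bound > 0

    def test_zwf_disables_g6p_dehydrogenase(self, conditioned_model):
        assert disabled_reactions(conditioned_model, ["zwf"]) == {"G6PDH2r"}

    def test_or_isozyme_deletion_disables_nothing(self, conditioned_model):
        # tktA has an isozyme (tktB) on the lumped non-oxidative PPP step
        assert disabled_reactions(conditioned_model, ["tktA"]) == frozenset()

    def test_and_complex_subunit_deletion_disables(self, conditioned_model):
        assert disabled_reactions(conditioned_model, ["dhaK"]) == {"DHAPT"}

    def test_unknown_gene_lists_near_matches(self, conditioned_model):
        with pytest.raises(KeyError, match="tpiA"):
            apply_knockout(conditioned_model, ["tpia"])

    def test_pair_superset_property(self, conditioned_model):
        for a, b in itertools.combinations(FIXTURE_GENES, 2):
            both = disabled_reactions(conditioned_model, [a, b])
            assert both >= disabled_reactions(conditioned_model, [a])
            assert both >= disabled_reactions(conditioned_model, [b])


def _manual_record(model, genes):
    """Independent per-deletion solve used as the screen oracle."""
    ko = apply_knockout(model, genes)
    sol = solve_lexicographic(ko, secondary="EX_3hp_e")
    if not sol.optimal or sol.primary_value <= 1e-7:
        return (0.0, 0.0)
    report = yield_table(sol, ko)
    return (sol.primary_value, report.product_yields["3hp"])


class TestSingleScreen:
    def test_records_match_manual_solves(self, conditioned_model):
        records = single_knockout_screen(conditioned_model, list(FIXTURE_GENES))
        assert [sorted(r.genes)[0] for r in records] == list(FIXTURE_GENES)
        for record in records:
            mu, yld = _manual_record(conditioned_model, record.genes)
            assert record.growth_rate == pytest.approx(mu, abs=1e-6)
            assert record.threehp_yield == pytest.approx(yld, abs=1e-4)

    def test_no_single_knockout_produces_3hp(self, conditioned_model):
        records = single_knockout_screen(conditioned_model, list(FIXTURE_GENES))
        assert max(r.threehp_yield for r in records) == pytest.approx(0.0, abs=0.01)

    def test_empty_gene_list(self, conditioned_model):
        assert single_knockout_screen(conditioned_model, []) == []


class TestDoubleScreen:
    FIVE = ("tpiA", "zwf", "gldA", "mgsA", "pgi")

    def test_matches_exhaustive_pairwise_solves(self, conditioned_model):
        records = double_knockout_screen(conditioned_model, list(self.FIVE))
        assert len(records) == 10
        by_pair = {r.genes: r for r in records}
        for pair in itertools.combinations(self.FIVE, 2):
            record = by_pair[frozenset(pair)]
            mu, yld = _manual_record(conditioned_model, pair)
            assert record.growth_rate == pytest.approx(mu, abs=1e-6)
            assert record.threehp_yield == pytest.approx(yld, abs=1e-4)

    def test_ranking_is_sorted_and_deterministic(self, conditioned_model):
        records = double_knockout_screen(conditioned_model, list(self.FIVE))
        keys = [r.sort_key() for r in records]
        assert keys == sorted(keys)
        again = double_knockout_screen(conditioned_model, list(self.FIVE))
        assert [r.genes for r in again] == [r.genes for r in records]

    def test_top_k_truncates(self, conditioned_model):
        records = double_knockout_screen(conditioned_model, list(self.FIVE), top_k=3)
        assert len(records) == 3

    def test_single_gene_list_yields_no_pairs(self, conditioned_model):
        assert double_knockout_screen(conditioned_model, ["tpiA"]) == []

    def test_growth_monotonicity(self, conditioned_model):
        """A double deletion never grows faster than either single."""
        singles = {
            sorted(r.genes)[0]: r.growth_rate
            for r in single_knockout_screen(conditioned_model, list(FIXTURE_GENES))
        }
        doubles = double_knockout_screen(conditioned_model, list(FIXTURE_GENES))
        for record in doubles:
            a, b = sorted(record.genes)
            assert record.growth_rate <= min(singles[a], singles[b]) + 1e-6

    def test_relative_growth_bounded(self, conditioned_model):
        for record in double_knockout_screen(conditioned_model, list(self.FIVE)):
            assert 0.0 <= record.relative_growth <= 100.0
            assert 0.0 <= record.threehp_yield <= 100.0 + 1e-6


class TestDeduplication:
    def test_equivalent_deletions_share_identical_records(self, conditioned_model):
        """Pairs disabling the same reactions come from one shared LP."""
        records = double_knockout_screen(
            conditioned_model, ["tpiA", "dhaK", "dhaL"]
        )
        by_pair = {r.genes: r for r in records}
        # dhaK and dhaL are subunits of the same complex, so either
        # deletion disables exactly the same reaction set
        a = by_pair[frozenset({"tpiA", "dhaK"})]
        b = by_pair[frozenset({"tpiA", "dhaL"})]
        assert a.disabled_reactions == b.disabled_reactions
        assert a.growth_rate == b.growth_rate  # bitwise: one LP, shared result
        assert a.threehp_yield == b.threehp_yield
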