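"""Model container, stoichiometric matrix, balance checks, knockouts."""

import numpy as np
import pytest

from butyflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    build_stoich_matrix,
    check_mass_balance,
    knockout,
    model_summary,
    orf_coverage,
    random_model,
    solve_fba,
)
from butyflux.core import parse_formula


def tiny(stoichs, bounds=None, compartments=None):
    m = MetabolicModel(compartments=compartments or {"c": "cyt", "e": "ext"})
    mets = {mid for s in stoichs.values() for mid in s}
    for mid in sorted(mets):
        comp = "e" if mid.endswith("_e") else "c"
        m.add_metabolite(Metabolite(mid, compartment=comp))
    for rid, s in stoichs.items():
        lb, ub = (bounds or {}).get(rid, (0.0, 1000.0))
        m.add_reaction(Reaction(rid, rid, s, lb, ub))
    return m


class TestStoichMatrix:
    def test_single_reaction_column(self):
        m = tiny({"R1": {"A_c": -1.0, "B_c": 1.0}})
        S, mi, ri = build_stoich_matrix(m)
        assert S.shape == (2, 1)
        assert S[mi["A_c"], ri["R1"]] == -1.0
        assert S[mi["B_c"], ri["R1"]] == 1.0

    def test_random_fixture_reproduced_entry_by_entry(self):
        model, truth = random_model(10, 15, seed=42)
        S, mi, ri = build_stoich_matrix(model)
        for rid, mid, coeff in truth:
            assert S[mi[mid], ri[rid]] == pytest.approx(coeff)
        # zeros elsewhere
        assert np.count_nonzero(S) == len(truth)

    def test_index_maps_are_bijections(self):
        model, _ = random_model(8, 12, seed=1)
        S, mi, ri = build_stoich_matrix(model)
        assert sorted(mi.values()) == list(range(S.shape[0]))
        assert sorted(ri.values()) == list(range(S.shape[1]))

    def test_duplicate_ids_are_hard_errors(self):
        m = tiny({"R1": {"A_c": -1.0, "B_c": 1.0}})
        with pytest.raises(ValidationError, match="duplicate"):
            m.add_reaction(Reaction("R1", "", {"A_c": -1.0, "B_c": 1.0}))
        with pytest.raises(ValidationError, match="duplicate"):
            m.add_metabolite(Metabolite("A_c"))

    def test_zero_or_nonfinite_coefficients_rejected(self):
        m = tiny({"R1": {"A_c": -1.0, "B_c": 1.0}})
        for bad in (0.0, float("nan"), float("inf")):
            with pytest.raises(ValidationError):
                m.add_reaction(Reaction("RX", "", {"A_c": bad}))


class TestFormulaAndBalance:
    @pytest.mark.parametrize(
        "formula, counts",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("C2H3OX", {"C": 2, "H": 3, "O": 1, "X": 1}),
            ("Fd", {"Fd": 1}),
        ],
    )
    def test_formula_parsing(self, formula, counts):
        assert parse_formula(formula) == counts

    @pytest.mark.parametrize("bad", ["", "6C", "c6h12", "C6-H12"])
    def test_unparseable_formula(self, bad):
        with pytest.raises(ValidationError):
            parse_formula(bad)

    def test_balanced_reaction_passes(self):
        m = tiny({"R1": {"glc_c": -1.0, "lac_c": 2.0}})
        m.metabolites["glc_c"].formula = "C6H12O6"
        m.metabolites["lac_c"].formula = "C3H6O3"
        assert check_mass_balance(m, exempt_metabolites=[]) == {}

    def test_unbalanced_reaction_flagged_with_deficit(self):
        m = tiny({"R1": {"glc_c": -1.0, "lac_c": 1.0}})
        m.metabolites["glc_c"].formula = "C6H12O6"
        m.metabolites["lac_c"].formula = "C3H6O3"
        report = check_mass_balance(m, exempt_metabolites=[])
        assert report["R1"] == pytest.approx({"C": -3.0, "H": -6.0, "O": -3.0})

    def test_exchanges_and_exempt_reactions_skipped(self):
        m = tiny({"EX": {"glc_e": -1.0}, "R1": {"glc_e": -1.0, "h_c": 1.0}})
        m.metabolites["glc_e"].formula = "C6H12O6"
        # EX is an exchange; R1 touches the exempt proton: nothing flagged
        assert check_mass_balance(m) == {}

    def test_missing_formula_is_an_error(self):
        m = tiny({"R1": {"A_c": -1.0, "B_c": 1.0}})
        with pytest.raises(ValidationError, match="A_c"):
            check_mass_balance(m, exempt_metabolites=[])


class TestSummary:
    def test_empty_model(self):
        m = MetabolicModel(compartments={"c": "cyt"})
        s = model_summary(m)
        assert (s.n_reactions, s.n_metabolites, s.n_genes, s.n_exchanges) == (0, 0, 0, 0)

    def test_core_counts_match_manifest(self, core_model, core_manifest):
        s = model_summary(core_model)
        assert s.n_reactions == core_manifest["n_reactions"]
        assert s.n_metabolites == core_manifest["n_metabolites"]
        assert s.n_genes == core_manifest["n_genes"]
        assert int(s.by_subsystem["total"].sum()) == s.n_reactions

    def test_gene_associated_means_nonempty_rule(self, core_model):
        s = model_summary(core_model)
        manual = sum(1 for r in core_model.reactions.values() if r.gene_rule.strip())
        assert s.n_gene_associated == manual
        assert s.n_non_gene_associated == s.n_reactions - manual


class TestKnockout:
    def chain(self):
        m = tiny(
            {
                "EX_A": {"A_e": -1.0},
                "T": {"A_e": -1.0, "B_c": 1.0},
                "EX_B": {"B_c": -1.0},
            },
            bounds={"EX_A": (-10.0, 0.0)},
        )
        m.metabolites["B_c"].boundary = True
        m.objective_reaction_id = "EX_B"
        return m

    def test_cutting_the_only_path_zeroes_the_objective(self):
        m = self.chain()
        assert solve_fba(m).objective_value == pytest.approx(10.0)
        assert solve_fba(knockout(m, ["T"])).objective_value == pytest.approx(0.0)

    def test_original_model_is_untouched(self):
        m = self.chain()
        knockout(m, ["T"])
        assert m.reactions["T"].upper_bound == 1000.0

    def test_unknown_ids_listed(self):
        m = self.chain()
        with pytest.raises(ValidationError, match=r"nope.*also"):
            knockout(m, ["nope", "also"])

    def test_idempotent_and_commutative(self, core_model):
        a = knockout(knockout(core_model, ["HYDA"]), ["HYDA"])
        b = knockout(core_model, ["HYDA"])
        assert a.reactions["HYDA"].upper_bound == b.reactions["HYDA"].upper_bound == 0.0
        ab = knockout(knockout(core_model, ["HYDA"]), ["PFL"])
        ba = knockout(knockout(core_model, ["PFL"]), ["HYDA"])
        for rid in ab.reactions:
            assert ab.reactions[rid].lower_bound == ba.reactions[rid].lower_bound
            assert ab.reactions[rid].upper_bound == ba.reactions[rid].upper_bound

    def test_knocking_out_blocked_reaction_is_a_noop(self, core_model):
        # EX_xu is a dead end: removing it cannot change the optimum
        before = solve_fba(core_model).objective_value
        after = solve_fba(knockout(core_model, ["EX_xu"])).objective_value
        assert after == pytest.approx(before, abs=1e-9)


class TestFormulaProperty:
    """Composing a formula from counts and parsing it back is lossless."""

    from hypothesis import given, settings, strategies as st

    element = st.from_regex(r"[A-Z][a-z]{0,2}", fullmatch=True)
    counts = st.dictionaries(element, st.integers(1, 999), min_size=1, max_size=6)

    @given(counts=counts)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip(self, counts):
        formula = "".join(
            f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items())
        )
        assert parse_formula(formula) == {k: float(v) for k, v in counts.items()}


class TestKnockoutProperty:
    from hypothesis import given, settings, strategies as st

    ids = ["GLYC", "PFOR", "PFL", "LDH", "HYDA", "RNF", "CAT1", "THL"]

    @given(subset=st.sets(st.sampled_from(ids), max_size=4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_independent(self, core_model, subset):
        subset = sorted(subset)
        one_shot = knockout(core_model, subset)
        stepwise = core_model
        for rid in reversed(subset):
            stepwise = knockout(stepwise, [rid])
        for rid in core_model.reactions:
            assert one_shot.reactions[rid].lower_bound == stepwise.reactions[rid].lower_bound
            assert one_shot.reactions[rid].upper_bound == stepwise.reactions[rid].upper_bound


def test_orf_coverage_matches_printed_genome_statistics():
    # 583 model genes over 3180 open reading frames -> 18.3%
    assert round(orf_coverage(583, 3180), 1) == 18.3
    with pytest.raises(ValueError):
        orf_coverage(10, 0)
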