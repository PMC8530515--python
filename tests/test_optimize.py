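import math
from dataclasses import replace

import pytest

from tlfopt.elongation import transition_line
from tlfopt.errors import BudgetInfeasibleError, ParameterError
from tlfopt.kinetics import CATALYTIC, sequestered_fraction
from tlfopt.optimize import (
    DIRECT,
    effective_fraction,
    optimal_aars,
    optimal_elongation,
    optimal_initiation,
    optimal_sqrt_term,
    optimal_termination,
    solve_self_consistent,
)
from tlfopt.params import FactorSpec, GlobalParams

from conftest import levels_without

LAM = 5e-4


def spec_with_kon(name, step, length_aa, kon, P=2.6e6, **kwargs):
    return FactorSpec(name=name, step=step, length_aa=length_aa,
                      kon_hat=kon * length_aa / P, **kwargs)


class TestSqrtTerm:
    def test_absent_pathway_is_free(self):
        assert optimal_sqrt_term(0.0, LAM, 2.6e6) == 0.0

    def test_square_root_scaling_in_growth_rate(self):
        assert optimal_sqrt_term(1.0, 4 * LAM, 2.6e6) == pytest.approx(
            2 * optimal_sqrt_term(1.0, LAM, 2.6e6))

    def test_negative_coefficient_is_internal_error(self):
        with pytest.raises(ParameterError):
            optimal_sqrt_term(-1.0, LAM, 2.6e6)

    def test_release_factor_coefficient_reproduces_rescaled_form(self, params):
        """sqrt(len_ribo*len_RF/(avg_len*kon_hat) * lam/P) equals
        sqrt(len_ribo*lam/(avg_len*kon)) after the kon rescale."""
        spec = spec_with_kon("RFI", "termination", 362, 4e4, params.P)
        coeff = params.len_ribo * spec.length_aa / (params.avg_len * spec.kon_hat)
        via_table = optimal_sqrt_term(coeff, LAM, params.P)
        via_kon = math.sqrt(params.len_ribo * LAM
                            / (params.avg_len * spec.kon(params.P)))
        assert via_table == pytest.approx(via_kon, rel=1e-12)


@pytest.fixture(scope="module")
def rf_specs(params):
    return {"RFI": spec_with_kon("RFI", "termination", 362, 4e4, params.P),
            "RF4": spec_with_kon("RF4", "termination", 185, 4e4, params.P)}


class TestTermination:

    def test_hand_evaluated_optimum(self, params, rf_specs):
        rfi, _ = optimal_termination(params, rf_specs, LAM)
        assert rfi.phi_star == pytest.approx(6.755e-4, rel=1e-4)

    def test_no_flux_no_factor(self, params, rf_specs):
        rfi, rf4 = optimal_termination(params, rf_specs, 0.0)
        assert rfi.phi_star == 0.0 and rf4.phi_star == 0.0

    def test_zero_specificity_recovers_single_factor(self, params, rf_specs):
        with_delta, _ = optimal_termination(params, rf_specs, LAM, delta=0.06)
        plain, _ = optimal_termination(params, rf_specs, LAM, delta=0.0)
        assert with_delta.phi_star == pytest.approx(
            plain.phi_star * math.sqrt(1.06), rel=1e-12)

    def test_catalytic_term_matches_sequestration_convention(self, params):
        specs = {"RFI": spec_with_kon("RFI", "termination", 362, 4e4,
                                      params.P, kcat=2.0),
                 "RF4": spec_with_kon("RF4", "termination", 185, 4e4,
                                      params.P, kcat=2.0)}
        rfi, _ = optimal_termination(params, specs, LAM, mode=CATALYTIC)
        assert rfi.term("catalytic") == pytest.approx(
            sequestered_fraction(specs["RFI"], LAM, params), rel=1e-12)


class TestElongationOptima:
    def test_elongation_termination_separation(self, params):
        """With equal rescaled association rates the EF-G optimum exceeds
        the release-factor optimum by exactly sqrt(avg_len)."""
        specs = {
            "RFI": spec_with_kon("RFI", "termination", 362, 4e4, params.P),
            "RF4": spec_with_kon("RF4", "termination", 185, 4e4, params.P),
            "EF-G": spec_with_kon("EF-G", "elongation", 704, 4e4, params.P,
                                  per_protein_uses=params.avg_len),
            "EF-Ts": spec_with_kon("EF-Ts", "elongation", 283, 4e4, params.P,
                                   per_protein_uses=params.avg_len),
            "EF-Tu": spec_with_kon("EF-Tu", "elongation", 394, 4e4, params.P,
                                   per_protein_uses=params.avg_len),
            "TC": spec_with_kon("TC", "elongation", 394, 4e4, params.P,
                                codon_specific=True,
                                per_protein_uses=params.avg_len),
        }
        efg, _, _ = optimal_elongation(params, specs, LAM)
        rfi, _ = optimal_termination(params, specs, LAM)
        assert efg.phi_star / rfi.phi_star == pytest.approx(
            math.sqrt(params.avg_len), rel=1e-12)

    def test_eftu_efg_ratio_at_equal_kon_hat(self, params, specs):
        """Equal bimolecular rate constants: the EF-Tu lead term exceeds
        EF-G by sqrt(n_aa * len_Tu / len_G)."""
        equal = dict(specs)
        equal["TC"] = replace(specs["TC"], kon_hat=specs["EF-G"].kon_hat)
        efg, _, eftu = optimal_elongation(params, equal, LAM)
        expected = math.sqrt(params.n_aa * specs["EF-Tu"].length_aa
                             / specs["EF-G"].length_aa)
        assert eftu.term(DIRECT) / efg.phi_star == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_zero_growth_rate(self, params, specs):
        assert all(f.phi_star == 0.0
                   for f in optimal_elongation(params, specs, 0.0))

    def test_efts_pool_equals_eftu_other_term(self, params, specs):
        _, efts, eftu = optimal_elongation(params, specs, LAM)
        assert eftu.term("diffusion_other:EF-Ts") == pytest.approx(
            efts.phi_star, rel=1e-12)


class TestAars:
    def test_infinite_budget_leaves_catalytic_only(self, params, specs):
        rich = replace(params, psi_trna=1e6)
        cat_specs = dict(specs)
        cat_specs["aaRS"] = replace(specs["aaRS"], kcat=10.0)
        factor = optimal_aars(rich, cat_specs, LAM, mode=CATALYTIC)
        assert factor.term(DIRECT) < 1e-9
        assert factor.term("catalytic") == pytest.approx(
            650 * LAM / 10.0, rel=1e-12)

    def test_budget_exhaustion_raises(self, params, specs):
        poor = replace(params, psi_trna=1e-6)
        with pytest.raises(BudgetInfeasibleError):
            optimal_aars(poor, specs, LAM)

    def test_optimum_sits_on_transition_line(self, alloc_default, specs, params):
        """Substituting (phi_Tu*, phi_aaRS*) into the transition-line
        equation reproduces the aaRS optimum to high precision."""
        rs = alloc_default.factors["aaRS"]
        tu_total = alloc_default.phi_star("EF-Tu")
        tc_star = rs.meta["phi_TC_star"]
        fixed = levels_without(alloc_default, "EF-Tu", "aaRS")
        _, line_aars, feasible = transition_line(
            [tc_star], fixed, specs, params,
            phi_Tu_extra=tu_total - tc_star,
            phi_aaRS_alloc=rs.phi_star)
        assert feasible[0]
        assert line_aars[0] == pytest.approx(rs.phi_star, rel=1e-6)


class TestInitiation:
    def test_if2_single_term_reduction(self, params, specs):
        if1, if2, if3 = optimal_initiation(params, specs, LAM)
        expected = math.sqrt(0.75 * params.len_ribo * specs["IF2"].length_aa
                             * LAM / (params.avg_len * specs["IF2"].kon_hat
                                      * params.P))
        assert if2.term(DIRECT) == pytest.approx(expected, rel=1e-12)

    def test_if1_bracket_inflates_release_factor_form(self, params, specs):
        """With the 30S-complex mass bracket divided out, the IF1 direct
        term is exactly the release-factor solution at IF1's parameters."""
        if1, _, _ = optimal_initiation(params, specs, LAM)
        bracket = 1 + (specs["IF2"].length_aa
                       + specs["IF3"].length_aa) / params.len_ribo
        rf_form = math.sqrt(params.len_ribo * specs["IF1"].length_aa * LAM
                            / (params.avg_len * specs["IF1"].kon_hat * params.P))
        assert if1.term(DIRECT) == pytest.approx(
            rf_form * math.sqrt(bracket), rel=1e-12)

    def test_if_levels_scale_as_sqrt_lambda(self, params, specs):
        low = optimal_initiation(params, specs, LAM)
        high = optimal_initiation(params, specs, 4 * LAM)
        for f_low, f_high in zip(low, high):
            assert f_high.phi_star == pytest.approx(2 * f_low.phi_star,
                                                    rel=1e-12)


class TestEffectiveFraction:
    def test_am_gm_minimum_at_optimum(self, params, specs, alloc_plain):
        """The effective fraction (factor + idle ribosomes) is minimized,
        at value 2*phi*, exactly at the optimum."""
        lam = alloc_plain.lambda_star
        kon = specs["RFI"].kon(params.P)
        phi_star = alloc_plain.factors["RFI"].free_star
        at_opt = effective_fraction(phi_star, lam, kon, params)
        assert at_opt == pytest.approx(2 * phi_star, rel=1e-10)
        for off in (0.5, 2.0):
            assert effective_fraction(off * phi_star, lam, kon, params) > at_opt


class TestSelfConsistentOptimum:
    def test_allocation_closes(self, alloc_default, params):
        total = (params.phi_ribo_inactive + alloc_default.phi_ribo_active_star
                 + alloc_default.total_factor_fraction())
        assert total == pytest.approx(params.phi_tl, rel=1e-10)

    def test_growth_law_holds_at_fixed_point(self, alloc_default, params):
        lam = (alloc_default.phi_ribo_active_star * params.avg_len
               / (alloc_default.cycle_star.tau_tl * params.len_ribo))
        assert lam == pytest.approx(alloc_default.lambda_star, rel=1e-10)

    def test_equipartition_free_equals_waiting(self, alloc_default):
        for factor in alloc_default.factors.values():
            if factor.equipartition is None:
                continue
            free, waiting = factor.equipartition
            assert waiting == pytest.approx(free, rel=1e-8)

    def test_convergence_metadata(self, alloc_default):
        assert alloc_default.convergence["iterations"] < 500
        assert alloc_default.convergence["residual"] < 1e-10
        assert len(alloc_default.convergence["trace"]) >= 2

    def test_larger_sector_grows_faster(self, params, specs):
        small = solve_self_consistent(replace(params, phi_tl=0.08), specs)
        assert alloc_lambda(small) < alloc_lambda(
            solve_self_consistent(params, specs))

    def test_kon_rescaling_preserves_stoichiometry(self, params, specs):
        """Scaling every association rate constant leaves all pairwise
        binding-limited ratios unchanged (sqrt-law structure)."""
        # a reduced sector keeps the faster-kinetics optimum inside the
        # tRNA budget so both solves converge
        p = replace(params, phi_tl=0.08)
        base = solve_self_consistent(p, specs, delta=0.0)
        scaled_specs = {
            name: (replace(s, kon_hat=s.kon_hat * 4.0)
                   if s.kon_hat is not None else s)
            for name, s in specs.items()}
        scaled = solve_self_consistent(p, scaled_specs, delta=0.0)
        names = ["RFI", "RF4", "EF-G", "EF-Ts", "EF-Tu", "IF1", "IF2", "IF3"]
        for a in names:
            for b in names:
                r_base = base.phi_star(a) / base.phi_star(b)
                r_scaled = scaled.phi_star(a) / scaled.phi_star(b)
                assert r_scaled == pytest.approx(r_base, rel=1e-9)

    def test_catalytic_mode_raises_totals_above_free(self, params, specs):
        cat_specs = {name: (replace(s, kcat=30.0) if name in
                            ("RFI", "RF4", "EF-G", "EF-Ts") else s)
                     for name, s in specs.items()}
        alloc = solve_self_consistent(params, cat_specs, mode=CATALYTIC)
        for name in ("RFI", "RF4", "EF-G", "EF-Ts"):
            factor = alloc.factors[name]
            assert factor.term("catalytic") > 0
            assert factor.phi_star > factor.free_star
            assert factor.term("catalytic") == pytest.approx(
                sequestered_fraction(cat_specs[name], alloc.lambda_star,
                                     params), rel=1e-12)

    def test_serialization_is_json_ready(self, alloc_default):
        import json
        doc = alloc_default.to_dict()
        json.dumps(doc)
        assert doc["factors"]["EF-Tu"]["phi_star"] > 0
        assert doc["doubling_time_s"] == pytest.approx(
            math.log(2) / alloc_default.lambda_star)


def alloc_lambda(alloc):
    return alloc.lambda_star
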