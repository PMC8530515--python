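"""Closed-form growth-optimal factor abundances and the self-consistent optimum.

At the growth optimum the marginal benefit of every factor balances its
proteome cost, which for a diffusive wait ``1/(kon*phi)`` yields the
square-root law

    phi* = sqrt(coeff * lambda* / P)

with a per-factor coefficient built from protein lengths and association
rate constants.  Equivalently (arithmetic-geometric mean inequality) the
optimum is the equipartition point where the free-factor fraction equals
the fraction of ribosomes waiting for it.  Factors decouple at the optimum
and are connected only through lambda*, which a damped fixed-point
iteration makes self-consistent with the proteome-allocation constraint.

Each optimal abundance is a sum of labelled terms: ``diffusion_direct``
(the factor's own search time), ``diffusion_other:<source>`` (the factor
sequestered while a partner reaction completes), and ``catalytic`` (the
factor bound at its chemical step, proportional to lambda*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from tlfopt.errors import (
    AllocationInfeasibleError, BudgetInfeasibleError, ConvergenceError,
    ParameterError,
)
from tlfopt.kinetics import (
    BINDING_LIMITED, CATALYTIC, CycleTimes, FactorLevels, IF23_PREFACTOR,
    cycle_times, growth_rate_from_active, if1_bracket, stop_codon_delta,
)
from tlfopt.params import FactorSpec, GlobalParams

DIRECT = "diffusion_direct"
CATALYTIC_TERM = "catalytic"


def _other(source: str) -> str:
    return f"diffusion_other:{source}"


@dataclass
class OptimalFactor:
    """Optimal proteome fraction of one factor with its term decomposition.

    ``equipartition`` pairs the free-factor fraction with the matching
    waiting pool (ribosomes for most factors, EF-Tu(GDP) for EF-Ts) at the
    optimum.
    """

    name: str
    terms: list[tuple[str, float]]
    equipartition: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for label, value in self.terms:
            if value < 0:
                raise ParameterError(f"{self.name}: negative term {label}={value}")

    @property
    def phi_star(self) -> float:
        return sum(value for _, value in self.terms)

    @property
    def free_star(self) -> float:
        """Free fraction at optimum (the direct diffusion term)."""
        return dict(self.terms).get(DIRECT, 0.0)

    def term(self, label: str) -> float:
        return dict(self.terms).get(label, 0.0)


def optimal_sqrt_term(coeff: float, lambda_: float, P: float) -> float:
    """Elementary building block sqrt(coeff * lambda / P) of every
    diffusion-column entry."""
    if coeff < 0:
        raise ParameterError(f"coefficient must be >= 0, got {coeff}")
    return math.sqrt(coeff * lambda_ / P)


def _catalytic(length_aa: float, lambda_: float, kcat: float,
               per_protein: bool) -> float:
    """Catalytic-sequestration term; zero in the binding-limited limit."""
    if math.isinf(kcat):
        return 0.0
    return length_aa * lambda_ / kcat if per_protein else 0.0


def optimal_termination(params: GlobalParams, specs: Mapping[str, FactorSpec],
                        lambda_: float, mode: str = BINDING_LIMITED,
                        delta: float = 0.0) -> tuple[OptimalFactor, OptimalFactor]:
    """Optimal release-factor (RFI, or RF1+RF2 via delta) and RF4 fractions.

    ``delta = 2*f_UAG*f_UGA`` inflates the combined RF1+RF2 radicand; zero
    recovers the single non-specific release factor.
    """
    out = []
    for name, spec_delta in (("RFI", delta), ("RF4", 0.0)):
        spec = specs[name]
        coeff = (params.len_ribo * spec.length_aa * (1.0 + spec_delta)
                 / (params.avg_len * spec.kon_hat))
        terms = [(DIRECT, optimal_sqrt_term(coeff, lambda_, params.P))]
        if mode == CATALYTIC:
            terms.append((CATALYTIC_TERM,
                          spec.length_aa * lambda_ / (params.avg_len * spec.kcat)
                          if not math.isinf(spec.kcat) else 0.0))
        free = terms[0][1]
        waiting = ((1.0 + spec_delta) * lambda_ * params.len_ribo
                   / (params.avg_len * spec.kon(params.P) * free)
                   if free > 0 else 0.0)
        out.append(OptimalFactor(name, terms, equipartition=(free, waiting)))
    return tuple(out)


def optimal_elongation(params: GlobalParams, specs: Mapping[str, FactorSpec],
                       lambda_: float, mode: str = BINDING_LIMITED,
                       ) -> tuple[OptimalFactor, OptimalFactor, OptimalFactor]:
    """Optimal EF-G, EF-Ts and EF-Tu fractions.

    Elongation factors act avg_len times per protein, which removes the
    1/avg_len from their radicands and separates them from the
    initiation/termination class by sqrt(avg_len).  EF-Tu additionally pays
    the n_aa codon-specificity dilution of the ternary-complex delivery and
    carries the EF-Ts-cycle pool (EF-Tu(GDP) awaiting nucleotide exchange)
    as a ``diffusion_other`` term.
    """
    g, ts, tu, tc = specs["EF-G"], specs["EF-Ts"], specs["EF-Tu"], specs["TC"]

    coeff_g = params.len_ribo * g.length_aa / g.kon_hat
    g_terms = [(DIRECT, optimal_sqrt_term(coeff_g, lambda_, params.P))]
    if mode == CATALYTIC and not math.isinf(g.kcat):
        g_terms.append((CATALYTIC_TERM, g.length_aa * lambda_ / g.kcat))
    g_wait = (lambda_ * params.len_ribo / (g.kon(params.P) * g_terms[0][1])
              if g_terms[0][1] > 0 else 0.0)
    efg = OptimalFactor("EF-G", g_terms,
                        equipartition=(g_terms[0][1], g_wait))

    coeff_ts = tu.length_aa * ts.length_aa / ts.kon_hat
    ts_terms = [(DIRECT, optimal_sqrt_term(coeff_ts, lambda_, params.P))]
    if mode == CATALYTIC and not math.isinf(ts.kcat):
        ts_terms.append((CATALYTIC_TERM, ts.length_aa * lambda_ / ts.kcat))
    # EF-Ts pairs with the EF-Tu(GDP) pool awaiting nucleotide exchange
    ts_wait = (lambda_ * tu.length_aa / (ts.kon(params.P) * ts_terms[0][1])
               if ts_terms[0][1] > 0 else 0.0)
    efts = OptimalFactor("EF-Ts", ts_terms,
                         equipartition=(ts_terms[0][1], ts_wait))

    coeff_tu = params.len_ribo * tu.length_aa * params.n_aa / tc.kon_hat
    tu_terms = [(DIRECT, optimal_sqrt_term(coeff_tu, lambda_, params.P)),
                (_other("EF-Ts"), optimal_sqrt_term(coeff_ts, lambda_, params.P))]
    if mode == CATALYTIC:
        inv = _inv_or_zero(tc.kcat) + _inv_or_zero(ts.kcat)
        if inv:
            tu_terms.append((CATALYTIC_TERM, tu.length_aa * lambda_ * inv))
    tu_wait = (lambda_ * params.len_ribo * params.n_aa
               / (tc.kon(params.P) * tu_terms[0][1])
               if tu_terms[0][1] > 0 else 0.0)
    eftu = OptimalFactor("EF-Tu", tu_terms,
                         equipartition=(tu_terms[0][1], tu_wait))
    return efg, efts, eftu


def _inv_or_zero(rate: float) -> float:
    return 0.0 if math.isinf(rate) else 1.0 / rate


def optimal_aars(params: GlobalParams, specs: Mapping[str, FactorSpec],
                 lambda_: float, phi_Tu_star: float | None = None,
                 phi_TC_star: float | None = None,
                 mode: str = BINDING_LIMITED) -> OptimalFactor:
    """Optimal aminoacyl-tRNA-synthetase fraction from the excess-tRNA budget.

    The optimum is the intersection of the transition line with the EF-Tu
    optimum: just enough synthetase flux to keep tRNA charging co-limiting
    given the tRNA budget left after ribosome- and TC-held tRNAs,

        phi_aaRS* = n_aa * lambda* / (kon_aaRS * Delta_tRNA*),

    so that the pair (phi_Tu*, phi_aaRS*) satisfies the transition-line
    equation identically.  The only factor whose optimum is growth-rate
    dependent beyond sqrt(lambda) (through Delta_tRNA*).
    """
    rs, tu, tc = specs["aaRS"], specs["EF-Tu"], specs["TC"]
    if phi_TC_star is None:
        coeff_tu = params.len_ribo * tu.length_aa * params.n_aa / tc.kon_hat
        phi_TC_star = optimal_sqrt_term(coeff_tu, lambda_, params.P)
    delta = (params.psi_trna
             - params.n_aa * lambda_ / (tc.kon(params.P) * phi_TC_star)
             - 2.0 * lambda_ / params.k_el_max
             - phi_TC_star / tu.length_aa)
    if mode == CATALYTIC:
        delta -= lambda_ * _inv_or_zero(rs.kcat)
    if delta <= 0:
        raise BudgetInfeasibleError(
            f"excess tRNA at the EF-Tu optimum is {delta:.4g} <= 0: the tRNA "
            f"budget psi_trna = {params.psi_trna:.4g} admits no aaRS optimum")
    diff = params.n_aa * lambda_ / (rs.kon(params.P) * delta)
    terms = [(DIRECT, diff)]
    if mode == CATALYTIC and not math.isinf(rs.kcat):
        terms.append((CATALYTIC_TERM, rs.length_aa * lambda_ / rs.kcat))
    return OptimalFactor("aaRS", terms, equipartition=None,
                         meta={"delta_trna": delta, "phi_TC_star": phi_TC_star})


def optimal_initiation(params: GlobalParams, specs: Mapping[str, FactorSpec],
                       lambda_: float, mode: str = BINDING_LIMITED,
                       ) -> tuple[OptimalFactor, OptimalFactor, OptimalFactor]:
    """Optimal IF1, IF2 and IF3 fractions (30S pre-initiation scheme).

    Direct terms carry the structural prefactors of the ordered scheme (the
    IF2/IF3 mass bracket on IF1, the 3/4 on IF2/IF3); the ``diffusion_other``
    terms account for each factor riding on 30S complexes that wait for IF1
    binding and 50S joining; catalytic terms cover mRNA loading and joining.
    """
    if1, if2, if3, s50 = specs["IF1"], specs["IF2"], specs["IF3"], specs["50S"]
    bracket = if1_bracket(specs, params)
    c_if1_direct = (params.len_ribo * if1.length_aa * bracket
                    / (params.avg_len * if1.kon_hat))
    c_if1_bare = params.len_ribo * if1.length_aa / (params.avg_len * if1.kon_hat)
    c_50s = params.avg_len / s50.kon_hat

    def cat_term(spec):
        inv = _inv_or_zero(params.k_rna) + _inv_or_zero(params.k_cat_ini)
        return spec.length_aa / params.avg_len * inv * lambda_

    out = []
    for spec, c_direct, c_other in (
        (if1, c_if1_direct, if1.length_aa / params.avg_len * c_50s),
        (if2, IF23_PREFACTOR * params.len_ribo * if2.length_aa
              / (params.avg_len * if2.kon_hat),
         if2.length_aa / params.avg_len * (c_if1_bare + c_50s)),
        (if3, IF23_PREFACTOR * params.len_ribo * if3.length_aa
              / (params.avg_len * if3.kon_hat),
         if3.length_aa / params.avg_len * (c_if1_bare + c_50s)),
    ):
        terms = [(DIRECT, optimal_sqrt_term(c_direct, lambda_, params.P)),
                 (_other("50S" if spec is if1 else "IF1+50S"),
                  optimal_sqrt_term(c_other, lambda_, params.P))]
        if mode == CATALYTIC:
            value = cat_term(spec)
            if value:
                terms.append((CATALYTIC_TERM, value))
        free = terms[0][1]
        prefactor = bracket if spec is if1 else IF23_PREFACTOR
        waiting = (prefactor * lambda_ * params.len_ribo
                   / (params.avg_len * spec.kon(params.P) * free)
                   if free > 0 else 0.0)
        out.append(OptimalFactor(spec.name, terms, equipartition=(free, waiting)))
    return tuple(out)


def effective_fraction(phi_factor: float, lambda_: float, kon: float,
                       params: GlobalParams) -> float:
    """Effective proteome fraction of a single-wait process.

    Sum of the factor itself and the ribosomes idling for it,
    ``phi + (lambda/(phi*kon)) * len_ribo/avg_len``; by AM-GM it is
    minimized, at value 2*phi*, where the two pools are equal.
    """
    if not (phi_factor > 0 and lambda_ > 0 and kon > 0):
        raise ParameterError("inputs must be > 0")
    return phi_factor + (lambda_ / (phi_factor * kon)) * params.len_ribo / params.avg_len


@dataclass
class OptimalAllocation:
    """Self-consistent growth optimum: all factor fractions plus lambda*."""

    factors: dict[str, OptimalFactor]
    lambda_star: float
    phi_ribo_active_star: float
    cycle_star: CycleTimes
    levels_star: FactorLevels
    params: GlobalParams
    mode: str
    convergence: dict

    @property
    def doubling_time(self) -> float:
        """Cell doubling time ln(2)/lambda*, seconds."""
        return math.log(2.0) / self.lambda_star

    def phi_star(self, name: str) -> float:
        return self.factors[name].phi_star

    def total_factor_fraction(self) -> float:
        return sum(f.phi_star for f in self.factors.values())

    def to_dict(self) -> dict:
        return {
            "lambda_star_per_s": self.lambda_star,
            "doubling_time_s": self.doubling_time,
            "mode": self.mode,
            "phi_ribo_active_star": self.phi_ribo_active_star,
            "cycle_times_s": {
                "tau_ini": self.cycle_star.tau_ini,
                "tau_el": self.cycle_star.tau_el,
                "tau_ter": self.cycle_star.tau_ter,
                "tau_tl": self.cycle_star.tau_tl,
            },
            "factors": {
                name: {"phi_star": f.phi_star, "terms": dict(f.terms),
                       **({"delta_trna": f.meta["delta_trna"]}
                          if "delta_trna" in f.meta else {})}
                for name, f in self.factors.items()
            },
            "convergence": {k: v for k, v in self.convergence.items()
                            if k != "trace"},
        }


def _all_factors(params, specs, lambda_, mode, delta, include_ts_cycle):
    rfi, rf4 = optimal_termination(params, specs, lambda_, mode, delta)
    efg, efts, eftu = optimal_elongation(params, specs, lambda_, mode)
    if not include_ts_cycle:
        efts = OptimalFactor("EF-Ts", [(DIRECT, 0.0)])
        eftu = OptimalFactor("EF-Tu", [t for t in eftu.terms
                                       if not t[0].startswith("diffusion_other")],
                             equipartition=eftu.equipartition)
    rs = optimal_aars(params, specs, lambda_,
                      phi_TC_star=eftu.free_star, mode=mode)
    if1, if2, if3 = optimal_initiation(params, specs, lambda_, mode)
    ordered = [eftu, efg, rs, efts, if1, if2, if3, rfi, rf4]
    return {f.name: f for f in ordered}


def solve_self_consistent(params: GlobalParams,
                          specs: Mapping[str, FactorSpec],
                          mode: str = BINDING_LIMITED,
                          delta: float | None = None,
                          include_ts_cycle: bool = True,
                          lambda_init: float = 2.0e-4,
                          damping: float = 0.5,
                          tol: float = 1e-12,
                          max_iter: int = 500) -> OptimalAllocation:
    """Damped fixed-point iteration closing the loop lambda* <-> phi_i*.

    Given an iterate lambda_t, all optimal fractions are evaluated, the
    cycle time is rebuilt from the free fractions, and the allocation
    constraint returns the next growth rate.  Converges when the relative
    lambda update drops below ``tol``.

    ``delta=None`` derives the RF1/RF2 stop-specificity correction from the
    genomic stop-codon frequencies; ``include_ts_cycle=False`` drops the
    EF-Ts leg (EF-Tu then carries no nucleotide-exchange pool), matching
    the reduced conservation model of the elongation solver.
    """
    if delta is None:
        delta = stop_codon_delta(params.stop_freqs[1], params.stop_freqs[2])
    lam = lambda_init
    trace = [lam]
    for iteration in range(1, max_iter + 1):
        factors = _all_factors(params, specs, lam, mode, delta, include_ts_cycle)
        totals = {name: f.phi_star for name, f in factors.items()}
        free = {name: f.free_star for name, f in factors.items()}
        free["TC"] = factors["EF-Tu"].free_star
        levels = FactorLevels(total={**totals, "TC": free["TC"]}, free=free)
        cycle = cycle_times(levels, specs, params, mode)
        phi_act = (params.phi_tl - params.phi_ribo_inactive
                   - sum(totals.values()))
        if phi_act <= 0:
            raise AllocationInfeasibleError(
                f"optimal factor fractions (sum {sum(totals.values()):.4g}) "
                f"exhaust phi_tl = {params.phi_tl:.4g} at lambda = {lam:.4g}")
        lam_new = growth_rate_from_active(phi_act, cycle.tau_tl, params)
        if abs(lam_new - lam) / lam < tol:
            break
        lam = lam + damping * (lam_new - lam)
        trace.append(lam)
    else:
        raise ConvergenceError(
            f"no fixed point after {max_iter} iterations (last lambda {lam:.6g})",
            trace=trace)

    factors = _all_factors(params, specs, lam, mode, delta, include_ts_cycle)
    totals = {name: f.phi_star for name, f in factors.items()}
    free = {name: f.free_star for name, f in factors.items()}
    free["TC"] = factors["EF-Tu"].free_star
    levels = FactorLevels(total={**totals, "TC": free["TC"]}, free=free)
    cycle = cycle_times(levels, specs, params, mode)
    phi_act = params.phi_tl - params.phi_ribo_inactive - sum(totals.values())
    residual = abs(growth_rate_from_active(phi_act, cycle.tau_tl, params) - lam) / lam
    return OptimalAllocation(
        factors=factors, lambda_star=lam, phi_ribo_active_star=phi_act,
        cycle_star=cycle, levels_star=levels, params=params, mode=mode,
        convergence={"iterations": iteration, "residual": residual,
                     "trace": trace},
    )
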