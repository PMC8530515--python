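"""Independent numerical maximization of the growth rate over factor levels.

Serves as the verification oracle for the analytic optima: a deterministic
log-spaced grid scan of the full growth-rate landscape followed by
coordinate-wise golden-section refinement.  The growth rate is always
evaluated through the kinetics modules -- including the nested
tRNA-conservation solve when EF-Tu/aaRS are free, and the EF-Tu(GDP)
bookkeeping when EF-Ts is free -- never through the analytic solutions
under test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from tlfopt.errors import (
    AllocationInfeasibleError, BudgetInfeasibleError, InputError,
)
from tlfopt.elongation import _context, solve_tc
from tlfopt.kinetics import (
    BINDING_LIMITED, CATALYTIC, FactorLevels, _as_levels, cycle_times,
    growth_rate, tau_initiation, tau_termination,
)
from tlfopt.params import FactorSpec, GlobalParams

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SearchSpec:
    """Search domain for the brute-force growth maximization.

    ``bounds`` are per-factor (lo, hi) proteome fractions scanned on a
    logarithmic grid of ``resolution`` points per axis; ``refine``
    coordinate-wise golden-section passes polish the grid argmax to
    relative precision ~1e-6.
    """

    free_factors: list[str]
    bounds: dict[str, tuple[float, float]]
    resolution: int = 32
    refine: int = 3

    def __post_init__(self):
        if not self.free_factors:
            raise InputError("free_factors must not be empty")
        if self.resolution < 16:
            raise InputError("resolution must be >= 16")
        for name in self.free_factors:
            if name not in self.bounds:
                raise InputError(f"no bounds for free factor {name}")
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise InputError(f"{name}: bounds must satisfy 0 < lo < hi")


def make_growth_objective(free_factors, params: GlobalParams,
                          specs: Mapping[str, FactorSpec], fixed_levels,
                          mode: str = BINDING_LIMITED,
                          ) -> Callable[[Mapping[str, float]], float]:
    """Build lambda(levels) for the given set of free factors.

    Dispatches on which part of the cycle is being optimized:

    * EF-Tu and/or aaRS free: the ternary-complex level comes from the
      nonlinear tRNA-conservation solve at each trial point.
    * EF-Ts free (with EF-Tu): the EF-Tu(GDP) pool awaiting nucleotide
      exchange is deducted from the ternary-complex-forming EF-Tu, with the
      growth rate solved self-consistently.
    * otherwise: plain transit-time evaluation with the supplied levels.

    Infeasible points (allocation exhausted, tRNA budget blown) map to
    -inf so optimizers can penalize rather than crash.
    """
    fixed = _as_levels(fixed_levels)
    free_set = set(free_factors)

    if free_set & {"EF-Tu", "aaRS"} and "EF-Ts" not in free_set:
        # EF-Tu and aaRS are the plane coordinates: the conservation-solve
        # context must not charge them to the allocation a second time.
        stripped = FactorLevels(
            total={k: v for k, v in fixed.total.items()
                   if k not in ("EF-Tu", "aaRS")},
            free=fixed.free)
        ctx = _context(stripped, specs, params, mode)

        def objective(trial: Mapping[str, float]) -> float:
            phi_tu = trial.get("EF-Tu", fixed.total.get("EF-Tu"))
            phi_rs = trial.get("aaRS", fixed.total.get("aaRS"))
            if ctx.phi_avail - phi_tu - phi_rs <= 0:
                return -math.inf
            try:
                state = solve_tc(phi_tu, phi_rs, stripped, specs, params, mode,
                                 _ctx=ctx)
            except BudgetInfeasibleError:
                return -math.inf
            return state.lambda_

        return objective

    if "EF-Ts" in free_set:
        if not free_set <= {"EF-Ts", "EF-Tu"}:
            raise InputError(
                "the EF-Ts cycle objective supports free factors "
                "{EF-Ts, EF-Tu} only")
        tau_rest = (tau_initiation(fixed, specs, params, mode)
                    + tau_termination(fixed, specs, params, mode)
                    + params.avg_len / (specs["EF-G"].kon(params.P)
                                        * fixed.binding("EF-G")))
        if mode == CATALYTIC:
            tau_rest += params.avg_len / params.k_el_max
        phi_fixed = sum(phi for name, phi in fixed.total.items()
                        if name not in ("EF-Ts", "EF-Tu")
                        and name not in ("ribosome", "TC", "50S"))
        kon_ts = specs["EF-Ts"].kon(params.P)
        kon_tc = specs["TC"].kon(params.P)
        len_tu = specs["EF-Tu"].length_aa

        def objective(trial: Mapping[str, float]) -> float:
            phi_ts = trial.get("EF-Ts", fixed.total.get("EF-Ts"))
            phi_tu = trial.get("EF-Tu", fixed.total.get("EF-Tu"))
            phi_act = (params.phi_tl - params.phi_ribo_inactive - phi_fixed
                       - phi_ts - phi_tu)
            if phi_act <= 0 or phi_ts <= 0 or phi_tu <= 0:
                return -math.inf

            def growth_at(lam):
                phi_tc = phi_tu - lam * len_tu / (kon_ts * phi_ts)
                if phi_tc <= 0:
                    return 0.0
                tau = tau_rest + params.avg_len * params.n_aa / (kon_tc * phi_tc)
                return phi_act * params.avg_len / (params.len_ribo * tau)

            lam_ub = growth_at(0.0)
            if lam_ub <= 0:
                return -math.inf
            g = lambda lam: lam - growth_at(lam)
            if g(lam_ub) <= 0:
                return lam_ub
            return brentq(g, lam_ub * 1e-12, lam_ub, rtol=1e-15)

        return objective

    def objective(trial: Mapping[str, float]) -> float:
        total = dict(fixed.total)
        total.update(trial)
        free = dict(fixed.free or {})
        free.update(trial)
        levels = FactorLevels(total=total, free=free)
        cycle = cycle_times(levels, specs, params, mode)
        try:
            return growth_rate(levels, cycle, params)
        except AllocationInfeasibleError:
            return -math.inf

    return objective


def _golden_max(f: Callable[[float], float], lo: float, hi: float,
                rel_tol: float = 1e-7) -> tuple[float, float]:
    """Golden-section maximization on a log axis."""
    a, b = math.log(lo), math.log(hi)
    c = b - GOLDEN * (b - a)
    d = a + GOLDEN * (b - a)
    fc, fd = f(math.exp(c)), f(math.exp(d))
    while (b - a) > rel_tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - GOLDEN * (b - a)
            fc = f(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b - a)
            fd = f(math.exp(d))
    x = math.exp((a + b) / 2.0)
    return x, f(x)


def grid_maximize(search: SearchSpec, params: GlobalParams,
                  specs: Mapping[str, FactorSpec], fixed_levels,
                  mode: str = BINDING_LIMITED,
                  objective: Callable | None = None):
    """Maximize the growth rate over the search domain.

    Returns ``(argmax_levels, lambda_max, trace)`` where ``trace`` lists
    every evaluated point as a dict (factor fractions plus ``"lambda"``).
    Exhaustive log-grid scan for up to three free factors (coordinate-wise
    scans beyond that), then ``refine`` golden-section passes per
    coordinate.  Fully deterministic.
    """
    if objective is None:
        objective = make_growth_objective(search.free_factors, params, specs,
                                          fixed_levels, mode)
    names = list(search.free_factors)
    axes = {name: np.logspace(math.log10(search.bounds[name][0]),
                              math.log10(search.bounds[name][1]),
                              search.resolution)
            for name in names}
    trace: list[dict] = []

    def evaluate(point: dict) -> float:
        lam = objective(point)
        trace.append({**point, "lambda": lam})
        return lam

    best_point = {name: axes[name][search.resolution // 2] for name in names}
    best_lam = -math.inf
    if len(names) <= 3:
        for combo in itertools.product(*(axes[name] for name in names)):
            point = dict(zip(names, combo))
            lam = evaluate(point)
            if lam > best_lam:
                best_lam, best_point = lam, point
    else:
        for _ in range(2):
            for name in names:
                for x in axes[name]:
                    point = {**best_point, name: x}
                    lam = evaluate(point)
                    if lam > best_lam:
                        best_lam, best_point = lam, point
    if not math.isfinite(best_lam):
        raise AllocationInfeasibleError("every grid point is infeasible")

    # per-axis log step of the scan grid; golden refinement brackets one
    # step around the incumbent, clipped to the bounds
    for _ in range(search.refine):
        for name in names:
            lo_b, hi_b = search.bounds[name]
            step = (hi_b / lo_b) ** (1.0 / (search.resolution - 1))
            x0 = best_point[name]
            lo = max(lo_b, x0 / step)
            hi = min(hi_b, x0 * step)

            def f1d(x, _name=name):
                return evaluate({**best_point, _name: x})

            x_best, lam = _golden_max(f1d, lo, hi)
            if lam > best_lam:
                best_lam = lam
                best_point = {**best_point, name: x_best}
    return best_point, best_lam, trace
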