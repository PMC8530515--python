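"""Steady state of the tRNA / ternary-complex cycle over the EF-Tu x aaRS plane.

The ternary complex (TC, charged tRNA bound to activated EF-Tu) feeds the
ribosomal A site; its steady-state level is pinned by conservation of the
total tRNA budget ``psi_trna`` (per in-protein amino acid) across free
uncharged tRNA, free charged tRNA, TC, and ribosome-held tRNA:

    psi = n_aa*lam/(kon_TC*phi_TC)              (empty-A-site ribosomes)
        + 2*lam/k_el_max                         (occupied-A-site ribosomes)
        + n_aa*lam/(kon_aaRS*phi_aaRS)           (free uncharged tRNA)
        + n_aa*lam/(kon_TC*phi_TC) * lam/(kon_Tu*phi_Tu_GTP)   (free charged)
        + phi_TC/len_Tu                          (tRNA inside TC)

with ``phi_Tu_GTP = phi_Tu - phi_TC`` and the growth rate itself a function
of phi_TC through the elongation time (a Michaelis-type saturation
``lam = a*phi_TC/(K + phi_TC)``).  The equation has a unique root in
``(0, phi_Tu)``: the residual is finite at phi_TC -> 0 (the growth rate
vanishes there, capping the empty-site demand at phi_act/len_ribo) and
diverges to -inf as phi_TC -> phi_Tu (free EF-Tu exhausted).

Two sharply separated regimes emerge -- EF-Tu-limited (phi_TC ~ phi_Tu) and
charging-limited -- whose boundary, the transition line, carries the growth
optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from tlfopt.errors import BudgetInfeasibleError, InputError
from tlfopt.kinetics import (
    BINDING_LIMITED, CATALYTIC, FactorLevels, _as_levels,
    tau_initiation, tau_termination,
)
from tlfopt.params import FactorSpec, GlobalParams

#: Sentinel for landscape cells whose tRNA budget cannot cover the minimal
#: occupancies (distinct from numeric zero so plateau truncation is visible).
MASKED = math.nan


@dataclass(frozen=True)
class TCContext:
    """Precomputed pieces of lam(phi_TC) for fixed non-(Tu, aaRS) levels.

    ``tau_rest`` is the full cycle time minus the TC-delivery wait;
    ``phi_avail`` the sector fraction left after inactive ribosomes and all
    fixed factor totals.  The growth rate is then the saturation curve
    ``lam(x) = amp * x / (K_TC + x)`` with both constants exact.
    """

    params: GlobalParams
    kon_tc: float
    kon_tu: float
    kon_aars: float
    kcat_aars: float
    len_tu: float
    tau_rest: float
    phi_avail: float

    def lambda_of(self, phi_TC: float, phi_Tu_alloc: float,
                  phi_aaRS_alloc: float) -> float:
        """Growth rate at a given TC level and (Tu, aaRS) allocation."""
        phi_act = self.phi_avail - phi_Tu_alloc - phi_aaRS_alloc
        if phi_act <= 0 or phi_TC <= 0:
            return 0.0
        p = self.params
        amp = phi_act * p.avg_len / (p.len_ribo * self.tau_rest)
        return amp * phi_TC / (self.k_tc_half + phi_TC)

    @property
    def k_tc_half(self) -> float:
        """Half-saturation TC fraction K_TC of the growth curve (exact)."""
        p = self.params
        return p.avg_len * p.n_aa / (self.kon_tc * self.tau_rest)


def _context(levels, specs: Mapping[str, FactorSpec], params: GlobalParams,
             mode: str = BINDING_LIMITED) -> TCContext:
    """Build the lam(phi_TC) closure from fixed factor levels.

    ``levels`` carries every factor except EF-Tu and aaRS (their fractions
    are the free coordinates of the plane); EF-G, the initiation factors and
    the release factors set the TC-independent part of the cycle time.
    """
    levels = _as_levels(levels)
    tau_rest = (tau_initiation(levels, specs, params, mode)
                + tau_termination(levels, specs, params, mode)
                + params.avg_len / (specs["EF-G"].kon(params.P)
                                    * levels.binding("EF-G")))
    if mode == CATALYTIC:
        tau_rest += params.avg_len / params.k_el_max
    phi_avail = (params.phi_tl - params.phi_ribo_inactive - levels.allocated())
    return TCContext(
        params=params,
        kon_tc=specs["TC"].kon(params.P),
        kon_tu=specs["EF-Tu"].kon(params.P),
        kon_aars=specs["aaRS"].kon(params.P),
        kcat_aars=specs["aaRS"].kcat,
        len_tu=specs["EF-Tu"].length_aa,
        tau_rest=tau_rest,
        phi_avail=phi_avail,
    )


@dataclass
class ElongationState:
    """Solved steady state of the elongation cycle at one (Tu, aaRS) point.

    All tRNA pools are per-P concentrations (same normalization as
    ``psi_trna``); ``residual`` is the conservation mismatch at the root.
    """

    phi_TC: float
    phi_Tu: float
    phi_aaRS: float
    phi_Tu_GTP: float
    free_charged_trna: float
    free_uncharged_trna: float
    ribo_A_site_empty: float
    ribo_A_site_filled: float
    tc_trna: float
    lambda_: float
    residual: float

    @property
    def trna_total(self) -> float:
        """Bookkeeping sum of all tRNA pools (should equal psi_trna)."""
        return (self.free_charged_trna + self.free_uncharged_trna
                + self.ribo_A_site_empty + self.ribo_A_site_filled
                + self.tc_trna)


def _occupancies(phi_TC, phi_Tu, phi_aaRS, ctx: TCContext,
                 phi_Tu_alloc, phi_aaRS_alloc):
    p = ctx.params
    lam = ctx.lambda_of(phi_TC, phi_Tu_alloc, phi_aaRS_alloc)
    r_empty = p.n_aa * lam / (ctx.kon_tc * phi_TC) if phi_TC > 0 else math.inf
    phi_tu_gtp = phi_Tu - phi_TC
    if phi_tu_gtp <= 0:
        charged = math.inf
    else:
        charged = r_empty * lam / (ctx.kon_tu * phi_tu_gtp)
    uncharged = p.n_aa * lam / (ctx.kon_aars * phi_aaRS)
    filled = 2.0 * lam / p.k_el_max
    return lam, r_empty, filled, uncharged, charged, phi_tu_gtp


def conservation_residual(phi_TC: float, phi_Tu: float, phi_aaRS: float,
                          levels, specs: Mapping[str, FactorSpec],
                          params: GlobalParams, mode: str = BINDING_LIMITED,
                          _ctx: TCContext | None = None) -> float:
    """tRNA-conservation residual psi_trna minus all tRNA pools.

    Positive when the budget exceeds the steady-state demand at the trial
    phi_TC; the solver finds its unique zero.  ``phi_TC == phi_Tu`` is the
    free-EF-Tu-exhausted limit and returns -inf.
    """
    if not 0 < phi_TC <= phi_Tu:
        raise InputError(f"phi_TC must lie in (0, phi_Tu], got {phi_TC} vs {phi_Tu}")
    ctx = _ctx or _context(levels, specs, params, mode)
    lam, r_empty, filled, uncharged, charged, _ = _occupancies(
        phi_TC, phi_Tu, phi_aaRS, ctx, phi_Tu, phi_aaRS)
    tc_trna = phi_TC / ctx.len_tu
    return params.psi_trna - (r_empty + filled + uncharged + charged + tc_trna)


def solve_tc(phi_Tu: float, phi_aaRS: float, levels,
             specs: Mapping[str, FactorSpec], params: GlobalParams,
             mode: str = BINDING_LIMITED,
             _ctx: TCContext | None = None) -> ElongationState:
    """Solve the conservation equation for phi_TC at given (Tu, aaRS).

    Bracketed root refinement to relative tolerance ~1e-13; raises
    :class:`BudgetInfeasibleError` when the tRNA budget cannot cover the
    minimal occupancies anywhere in ``(0, phi_Tu)``.
    """
    if not (phi_Tu > 0 and phi_aaRS > 0):
        raise InputError("phi_Tu and phi_aaRS must be > 0")
    ctx = _ctx or _context(levels, specs, params, mode)

    # Root-find in the logit coordinate v = ln(phi_TC / (phi_Tu - phi_TC)):
    # both the phi_TC -> 0 (charging-limited) and phi_TC -> phi_Tu
    # (EF-Tu-exhausted) boundaries stay well conditioned, so the residual at
    # the root reaches ~1e-12 * psi even when free EF-Tu is a ~1e-9 sliver.
    def _sigmoid(v):
        if v >= 0:
            return 1.0 / (1.0 + math.exp(-v))
        ev = math.exp(v)
        return ev / (1.0 + ev)

    def f(v):
        x = phi_Tu * _sigmoid(v)
        gap = phi_Tu * _sigmoid(-v)
        lam = ctx.lambda_of(x, phi_Tu, phi_aaRS)
        r_empty = params.n_aa * lam / (ctx.kon_tc * x)
        charged = r_empty * lam / (ctx.kon_tu * gap)
        uncharged = params.n_aa * lam / (ctx.kon_aars * phi_aaRS)
        filled = 2.0 * lam / params.k_el_max
        return params.psi_trna - (r_empty + filled + uncharged + charged
                                  + x / ctx.len_tu)

    v_lo, v_hi = -45.0, 45.0
    if f(v_lo) <= 0:
        raise BudgetInfeasibleError(
            f"tRNA budget psi_trna = {params.psi_trna:.4g} cannot cover the "
            f"minimal steady-state occupancies at phi_Tu = {phi_Tu:.4g}, "
            f"phi_aaRS = {phi_aaRS:.4g}")
    if f(v_hi) > 0:  # pragma: no cover - needs a pathological parameter set
        raise BudgetInfeasibleError("conservation residual has no sign change")
    v_root = brentq(f, v_lo, v_hi, xtol=1e-13, rtol=8.9e-16)
    root = phi_Tu * _sigmoid(v_root)

    phi_tu_gtp = phi_Tu * _sigmoid(-v_root)
    lam = ctx.lambda_of(root, phi_Tu, phi_aaRS)
    r_empty = params.n_aa * lam / (ctx.kon_tc * root)
    return ElongationState(
        phi_TC=root, phi_Tu=phi_Tu, phi_aaRS=phi_aaRS,
        phi_Tu_GTP=phi_tu_gtp,
        free_charged_trna=r_empty * lam / (ctx.kon_tu * phi_tu_gtp),
        free_uncharged_trna=params.n_aa * lam / (ctx.kon_aars * phi_aaRS),
        ribo_A_site_empty=r_empty,
        ribo_A_site_filled=2.0 * lam / params.k_el_max,
        tc_trna=root / ctx.len_tu,
        lambda_=lam, residual=f(v_root),
    )


def excess_trna(phi_Tu_bar: float, levels, specs: Mapping[str, FactorSpec],
                params: GlobalParams, mode: str = BINDING_LIMITED,
                phi_Tu_extra: float = 0.0, phi_aaRS_alloc: float = 0.0,
                _ctx: TCContext | None = None) -> float:
    """Excess tRNA Delta_tRNA on the transition line at phi_Tu_bar.

    Transition-line convention: all EF-Tu is complexed (phi_TC = phi_Tu_bar)
    and the free charged pool is empty, so the leftover budget is

        Delta = psi - n_aa*lam/(kon_TC*phi_Tu_bar) - 2*lam/k_el_max
                    - phi_Tu_bar/len_Tu   [- lam/kcat_aaRS in catalytic mode]

    ``phi_Tu_extra`` charges additional (sequestered) EF-Tu mass to the
    allocation, ``phi_aaRS_alloc`` likewise for a fixed aaRS fraction.
    May be negative: the budget is exhausted past the plateau.
    """
    if not phi_Tu_bar > 0:
        raise InputError("phi_Tu_bar must be > 0")
    ctx = _ctx or _context(levels, specs, params, mode)
    lam = ctx.lambda_of(phi_Tu_bar, phi_Tu_bar + phi_Tu_extra, phi_aaRS_alloc)
    delta = (params.psi_trna
             - params.n_aa * lam / (ctx.kon_tc * phi_Tu_bar)
             - 2.0 * lam / params.k_el_max
             - phi_Tu_bar / ctx.len_tu)
    if mode == CATALYTIC:
        delta -= lam / ctx.kcat_aars
    return delta


def transition_line(phi_Tu_samples, levels, specs: Mapping[str, FactorSpec],
                    params: GlobalParams, mode: str = BINDING_LIMITED,
                    phi_Tu_extra: float = 0.0, phi_aaRS_alloc: float = 0.0):
    """aaRS level co-limiting with EF-Tu for each sampled phi_Tu_bar.

    Returns ``(phi_Tu_bar, phi_aaRS_bar, feasible)`` arrays; points whose
    excess tRNA is non-positive (the far side of the budget plateau) are
    marked infeasible with a NaN sentinel.
    """
    ctx = _context(levels, specs, params, mode)
    tu = np.asarray(phi_Tu_samples, dtype=float)
    if np.any(tu <= 0):
        raise InputError("phi_Tu samples must be > 0")
    aars = np.full_like(tu, MASKED)
    feasible = np.zeros(tu.shape, dtype=bool)
    for i, tu_bar in enumerate(tu):
        delta = excess_trna(tu_bar, levels, specs, params, mode,
                            phi_Tu_extra, phi_aaRS_alloc, _ctx=ctx)
        if delta > 0:
            lam = ctx.lambda_of(tu_bar, tu_bar + phi_Tu_extra, phi_aaRS_alloc)
            aars[i] = params.n_aa * lam / (ctx.kon_aars * delta)
            feasible[i] = True
    return tu, aars, feasible


@dataclass
class TCLandscape:
    """Dense steady-state solution over an (EF-Tu, aaRS) expression grid.

    Arrays are indexed ``[i, j]`` for ``(tu_grid[i], aars_grid[j])``;
    infeasible cells carry NaN and ``mask[i, j] = True``.  ``k_tc_half`` is
    the half-saturation TC fraction of lam(phi_TC) used to scale the
    ternary-complex panel.
    """

    tu_grid: np.ndarray
    aars_grid: np.ndarray
    phi_tc: np.ndarray
    free_tu_fraction: np.ndarray
    free_charged_fraction: np.ndarray
    lambda_grid: np.ndarray
    residuals: np.ndarray
    mask: np.ndarray
    k_tc_half: float
    line_tu: np.ndarray = field(default=None)
    line_aars: np.ndarray = field(default=None)

    @property
    def phi_tc_scaled(self) -> np.ndarray:
        return self.phi_tc / self.k_tc_half

    def to_dict(self) -> dict:
        """JSON-serializable document (NaN encoded as None)."""
        def arr(a):
            return np.where(np.isnan(a), None, np.round(a, 15)).tolist()
        return {
            "tu_grid": self.tu_grid.tolist(),
            "aars_grid": self.aars_grid.tolist(),
            "phi_tc": arr(self.phi_tc),
            "free_tu_fraction": arr(self.free_tu_fraction),
            "free_charged_fraction": arr(self.free_charged_fraction),
            "lambda": arr(self.lambda_grid),
            "mask": self.mask.tolist(),
            "k_tc_half": self.k_tc_half,
            "transition_line": {
                "phi_tu": arr(self.line_tu),
                "phi_aars": arr(self.line_aars),
            },
        }


def landscape(tu_grid, aars_grid, levels, specs: Mapping[str, FactorSpec],
              params: GlobalParams, mode: str = BINDING_LIMITED) -> TCLandscape:
    """Solve the conservation equation on every cell of a (Tu, aaRS) grid."""
    tu = np.asarray(tu_grid, dtype=float)
    aars = np.asarray(aars_grid, dtype=float)
    if np.any(tu <= 0) or np.any(aars <= 0):
        raise InputError("grids must be strictly positive")
    if np.any(np.diff(tu) <= 0) or np.any(np.diff(aars) <= 0):
        raise InputError("grids must be strictly increasing")
    ctx = _context(levels, specs, params, mode)

    shape = (tu.size, aars.size)
    phi_tc = np.full(shape, MASKED)
    free_tu = np.full(shape, MASKED)
    free_charged = np.full(shape, MASKED)
    lam = np.full(shape, MASKED)
    residuals = np.full(shape, MASKED)
    mask = np.zeros(shape, dtype=bool)
    for i, tu_i in enumerate(tu):
        for j, rs_j in enumerate(aars):
            if ctx.phi_avail - tu_i - rs_j <= 0:
                mask[i, j] = True
                continue
            try:
                state = solve_tc(tu_i, rs_j, levels, specs, params, mode,
                                 _ctx=ctx)
            except BudgetInfeasibleError:
                mask[i, j] = True
                continue
            phi_tc[i, j] = state.phi_TC
            free_tu[i, j] = state.phi_Tu_GTP / tu_i
            free_charged[i, j] = state.free_charged_trna / params.psi_trna
            lam[i, j] = state.lambda_
            residuals[i, j] = state.residual

    line_tu, line_aars, _ = transition_line(tu, levels, specs, params, mode)
    return TCLandscape(
        tu_grid=tu, aars_grid=aars, phi_tc=phi_tc,
        free_tu_fraction=free_tu, free_charged_fraction=free_charged,
        lambda_grid=lam, residuals=residuals, mask=mask,
        k_tc_half=ctx.k_tc_half, line_tu=line_tu, line_aars=line_aars,
    )


def default_grids(n: int = 200, lo: float = 1e-4, hi: float = 1e-1):
    """Logarithmic default grids spanning the physiological dynamic range."""
    g = np.logspace(math.log10(lo), math.log10(hi), n)
    return g, g.copy()
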