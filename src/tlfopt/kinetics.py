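"""Coarse-grained ribosome transit times and the growth/allocation relations.

The translation cycle is three sequential steps -- initiation, elongation,
termination -- each catalyzed by dedicated factors.  In steady state every
step carries the same ribosome flux, and the growth rate follows the
generalized growth law

    lambda = phi_ribo_act / tau_tl * (avg_len / len_ribo),

with ``tau_tl = tau_ini + tau_el + tau_ter`` the full cycle time.  In the
binding-limited regime each sub-reaction contributes a diffusive search time
``1/(kon * phi)``; finite catalytic rates add ``1/kcat`` residences and
sequester a factor fraction proportional to the flux it carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from tlfopt.errors import AllocationInfeasibleError, InputError
from tlfopt.params import FactorSpec, GlobalParams

#: Species that never count against the translation-factor allocation sum:
#: the ribosome and its 50S subunit belong to the ribosomal budget, and the
#: ternary complex is EF-Tu mass already counted under EF-Tu.
NON_ALLOCATED = frozenset({"ribosome", "TC", "50S"})

BINDING_LIMITED = "binding_limited"
CATALYTIC = "catalytic"

#: Structural prefactors of the initiation binding waits (from the ordered
#: 30S pre-initiation scheme): IF2 and IF3 waits carry 3/4; the IF1 wait is
#: inflated by the IF2/IF3 mass riding on the 30S complex (length bracket,
#: computed where lengths are known).
IF23_PREFACTOR = 0.75


@dataclass
class FactorLevels:
    """Per-factor proteome fractions, optionally split total vs. free.

    Binding waits use the free fraction when available (catalytic mode
    sequesters part of each factor at its chemical step); the allocation
    constraint always consumes totals.
    """

    total: dict[str, float]
    free: dict[str, float] | None = None

    def __post_init__(self):
        for name, phi in self.total.items():
            if phi < 0 or phi >= 1:
                raise InputError(f"{name}: fraction must be in [0, 1), got {phi}")

    def binding(self, name: str) -> float:
        """Fraction available for binding (free if split, else total)."""
        if self.free is not None and name in self.free:
            return self.free[name]
        return self.total[name]

    def allocated(self) -> float:
        """Summed factor fractions counted against the translation sector."""
        return sum(phi for name, phi in self.total.items()
                   if name not in NON_ALLOCATED)


def _as_levels(levels) -> FactorLevels:
    if isinstance(levels, FactorLevels):
        return levels
    return FactorLevels(total=dict(levels))


@dataclass
class CycleTimes:
    """Ribosome transit times per translation step, seconds.

    ``breakdown`` holds the per-subreaction waits (keys like ``"stop"``,
    ``"recyc"``, ``"aa"`` for the single-codon elongation time).
    """

    tau_ini: float
    tau_el: float
    tau_ter: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("tau_ini", "tau_el", "tau_ter"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @property
    def tau_tl(self) -> float:
        return self.tau_ini + self.tau_el + self.tau_ter


def _wait(kon: float, phi: float, prefactor: float = 1.0) -> float:
    """Diffusive search time prefactor/(kon*phi); infinite at phi = 0."""
    if phi <= 0:
        return math.inf
    return prefactor / (kon * phi)


def _inv(rate: float) -> float:
    return 0.0 if math.isinf(rate) else 1.0 / rate


def stop_codon_delta(f_UAG: float, f_UGA: float) -> float:
    """Stop-codon specificity correction delta = 2*f_UAG*f_UGA.

    Nonzero delta inflates the combined RF1+RF2 requirement because each of
    the two class-I release factors only recognizes two of the three stop
    codons.
    """
    for name, f in (("f_UAG", f_UAG), ("f_UGA", f_UGA)):
        if not 0 <= f <= 1:
            raise InputError(f"{name} must be in [0, 1], got {f}")
    if f_UAG + f_UGA > 1 + 1e-12:
        raise InputError("f_UAG + f_UGA must not exceed 1")
    return 2.0 * f_UAG * f_UGA


def tau_termination(levels, specs: Mapping[str, FactorSpec],
                    params: GlobalParams, mode: str = BINDING_LIMITED) -> float:
    """Termination time: peptide-release wait (RFI) + recycling wait (RF4).

    Each wait is ``1/(kon*phi)``; catalytic mode adds the ``1/kcat``
    residence of each step.  Zero factor levels give an infinite time
    (signal, not an exception) so optimizers can penalize the boundary.
    """
    levels = _as_levels(levels)
    tau = 0.0
    for name in ("RFI", "RF4"):
        spec = specs[name]
        tau += _wait(spec.kon(params.P), levels.binding(name))
        if mode == CATALYTIC:
            tau += _inv(spec.kcat)
    return tau


def tau_codon(phi_TC: float, phi_G: float, specs: Mapping[str, FactorSpec],
              params: GlobalParams, mode: str = BINDING_LIMITED) -> float:
    """Single-codon elongation time: TC delivery wait + EF-G wait.

    The ternary-complex association is codon-specific, so its rate carries
    the 1/n_aa coarse-graining dilution.  Catalytic mode adds the
    ``1/k_el_max`` residence of the chemical steps (peptidyl transfer,
    translocation) per codon.
    """
    tc, g = specs["TC"], specs["EF-G"]
    n_tc = params.n_aa if tc.codon_specific else 1.0
    n_g = params.n_aa if g.codon_specific else 1.0
    tau = _wait(tc.kon(params.P) / n_tc, phi_TC) + _wait(g.kon(params.P) / n_g, phi_G)
    if mode == CATALYTIC:
        tau += _inv(params.k_el_max)
    return tau


def if1_bracket(specs: Mapping[str, FactorSpec], params: GlobalParams) -> float:
    """Mass bracket 1 + (len_IF2 + len_IF3)/len_ribo on the IF1 wait.

    IF2 and IF3 ride on the 30S complex that waits for IF1, so their mass
    adds to the proteomic cost of that waiting pool.
    """
    return 1.0 + (specs["IF2"].length_aa + specs["IF3"].length_aa) / params.len_ribo


def tau_initiation(levels, specs: Mapping[str, FactorSpec],
                   params: GlobalParams, mode: str = BINDING_LIMITED) -> float:
    """Initiation time: IF binding waits, optional 50S-joining wait, catalysis.

    The IF1 wait carries the mass bracket ``1 + (len_IF2+len_IF3)/len_ribo``
    and the IF2/IF3 waits the structural 3/4 prefactor of the ordered 30S
    scheme.  A ``"50S"`` entry in ``levels`` adds the subunit-joining wait.
    Catalytic mode adds the mRNA-loading and joining residences
    ``1/k_rna + 1/k_cat_ini``.
    """
    levels = _as_levels(levels)
    prefactors = {"IF1": if1_bracket(specs, params), "IF2": IF23_PREFACTOR,
                  "IF3": IF23_PREFACTOR}
    tau = 0.0
    for name, pref in prefactors.items():
        tau += _wait(specs[name].kon(params.P), levels.binding(name), pref)
    if "50S" in levels.total:
        tau += _wait(specs["50S"].kon(params.P), levels.binding("50S"))
    if mode == CATALYTIC:
        tau += _inv(params.k_rna) + _inv(params.k_cat_ini)
    return tau


def cycle_times(levels, specs: Mapping[str, FactorSpec], params: GlobalParams,
                mode: str = BINDING_LIMITED) -> CycleTimes:
    """Assemble the full cycle times from a set of factor levels.

    ``levels`` must provide the initiation and termination factors plus
    ``"TC"`` (ternary complex available for A-site delivery) and ``"EF-G"``.
    """
    levels = _as_levels(levels)
    tau_aa = tau_codon(levels.binding("TC"), levels.binding("EF-G"), specs,
                       params, mode)
    breakdown = {
        "aa": tau_aa,
        "stop": _wait(specs["RFI"].kon(params.P), levels.binding("RFI")),
        "recyc": _wait(specs["RF4"].kon(params.P), levels.binding("RF4")),
    }
    return CycleTimes(
        tau_ini=tau_initiation(levels, specs, params, mode),
        tau_el=params.avg_len * tau_aa,
        tau_ter=tau_termination(levels, specs, params, mode),
        breakdown=breakdown,
    )


def active_ribosome_fraction(levels, params: GlobalParams) -> float:
    """phi_act = phi_tl - phi_ribo_inactive - sum(factor fractions)."""
    levels = _as_levels(levels)
    total = levels.allocated()
    phi_act = params.phi_tl - params.phi_ribo_inactive - total
    if phi_act <= 0:
        raise AllocationInfeasibleError(
            f"factor fractions (sum {total:.4g}) plus inactive ribosomes "
            f"({params.phi_ribo_inactive:.4g}) exhaust the translation sector "
            f"phi_tl = {params.phi_tl:.4g}")
    return phi_act


def growth_rate_from_active(phi_ribo_active: float, tau_tl: float,
                            params: GlobalParams) -> float:
    """Growth law: lambda = phi_act * avg_len / (tau_tl * len_ribo)."""
    if tau_tl <= 0:
        raise InputError(f"tau_tl must be > 0, got {tau_tl}")
    return phi_ribo_active * params.avg_len / (tau_tl * params.len_ribo)


def growth_rate(levels, cycle: CycleTimes, params: GlobalParams) -> float:
    """Growth rate from factor levels and cycle times (allocation closed)."""
    return growth_rate_from_active(active_ribosome_fraction(levels, params),
                                   cycle.tau_tl, params)


def ribosome_occupancies(cycle: CycleTimes,
                         phi_ribo_active: float) -> dict[str, float]:
    """Active-ribosome fraction held at each step, phi * tau_step/tau_tl.

    Steady-state flux equality means the share of ribosomes at a step equals
    the share of cycle time spent there; the fractions sum to the active
    pool exactly.
    """
    tau_tl = cycle.tau_tl
    if tau_tl <= 0:
        raise InputError("tau_tl must be > 0")
    occ = {
        "initiation": phi_ribo_active * cycle.tau_ini / tau_tl,
        "elongation": phi_ribo_active * cycle.tau_el / tau_tl,
        "termination": phi_ribo_active * cycle.tau_ter / tau_tl,
    }
    return occ


def queuing_factor(tau_ter: float, initiation_rate: float,
                   backend: Callable[[float, float], float] | None = None) -> float:
    """Multiplicative correction for ribosome queues at stop codons.

    In the physiological fast-termination regime no queues form and the
    factor is 1; a ``backend`` hook accepts alternative closures for slow
    termination.  Any backend must return >= 1.
    """
    if tau_ter < 0 or initiation_rate < 0:
        raise InputError("inputs must be >= 0")
    if backend is None:
        return 1.0
    q = backend(tau_ter, initiation_rate)
    if q < 1.0:
        raise InputError(f"queuing factor must be >= 1, backend gave {q}")
    return q


def sequestered_fraction(spec: FactorSpec, lambda_: float,
                         params: GlobalParams) -> float:
    """Factor fraction bound at its catalytic step at growth rate lambda.

    Each completed protein uses the factor ``per_protein_uses`` times, the
    protein completion flux per unit proteome is ``lambda/avg_len``, and
    every use holds one factor copy for ``1/kcat``:

        phi_seq = uses * lambda * len / (avg_len * kcat)

    Zero in the binding-limited limit kcat -> inf.
    """
    if math.isinf(spec.kcat):
        return 0.0
    return (spec.per_protein_uses * lambda_ * spec.length_aa
            / (params.avg_len * spec.kcat))
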