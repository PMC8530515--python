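import pytest

from tlfopt.kinetics import FactorLevels
from tlfopt.optimize import solve_self_consistent
from tlfopt.params import default_factors, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def specs(params):
    return default_factors(params)


@pytest.fixture(scope="session")
def alloc_default(params, specs):
    """Self-consistent optimum with all default refinements."""
    return solve_self_consistent(params, specs)


@pytest.fixture(scope="session")
def alloc_plain(params, specs):
    """Optimum matching the coarse kinetic scheme exactly.

    Stop-codon specificity off (the lumped release-factor scheme) and the
    EF-Ts leg excluded (matching the reduced tRNA-conservation model), so
    analytic solutions and brute-force maximization share one model.
    """
    return solve_self_consistent(params, specs, delta=0.0,
                                 include_ts_cycle=False)


@pytest.fixture(scope="session")
def alloc_ts(params, specs):
    """Optimum with the EF-Ts cycle included but no stop specificity."""
    return solve_self_consistent(params, specs, delta=0.0)


def levels_without(alloc, *names, keep=None):
    """Fixed-factor levels of an allocation with some factors removed."""
    total = {k: v for k, v in alloc.levels_star.total.items()
             if k not in names and (keep is None or k in keep)}
    free = {k: v for k, v in alloc.levels_star.free.items()
            if k not in names and (keep is None or k in keep)}
    return FactorLevels(total=total, free=free)


@pytest.fixture(scope="session")
def landscape_levels(alloc_ts):
    """Non-(EF-Tu, aaRS) factor levels for steady-state landscape work."""
    keep = ("RFI", "RF4", "IF1", "IF2", "IF3", "EF-G", "EF-Ts")
    return levels_without(alloc_ts, keep=keep)
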