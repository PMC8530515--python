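"""Predicted-vs-observed comparison, scaling tables, and tRNA diagnostics.

Observed synthesis fractions (ribosome-profiling proteome synthesis shares,
equal to proteome mass fractions for a stable proteome) are compared
factor by factor against the model's optimal allocation.  The package also
tabulates how the optimum moves as the translation sector is swept: all
binding-limited optima scale as sqrt(lambda*), so their pairwise ratios are
growth-rate invariant (aaRS excepted, through the excess-tRNA budget).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from dataclasses import replace as _replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tlfopt.errors import InputError
from tlfopt.kinetics import BINDING_LIMITED
from tlfopt.optimize import OptimalAllocation, solve_self_consistent
from tlfopt.errors import AllocationInfeasibleError, BudgetInfeasibleError
from tlfopt.params import FactorSpec, GlobalParams

logger = logging.getLogger(__name__)

CANONICAL_FACTORS = frozenset({
    "IF1", "IF2", "IF3", "EF-Tu", "EF-Ts", "EF-G", "aaRS",
    "RF1", "RF2", "RFI", "RF4",
})

_OBSERVED_COLUMNS = ["species", "factor", "synthesis_fraction"]

#: tRNA sites on an elongating ribosome (A and P).
TRNA_SITES_PER_RIBOSOME = 2
#: Measured endogenous EF-Tu : ribosome stoichiometry (~4 at fast growth).
EFTU_PER_RIBOSOME = 4.0


def min_trna_per_ribosome(ribosome_sites: int = TRNA_SITES_PER_RIBOSOME,
                          eftu_per_ribosome: float = EFTU_PER_RIBOSOME) -> float:
    """Minimal tRNA : ribosome ratio for the model's regime to apply.

    Every elongating ribosome holds tRNAs in its A/P sites and every EF-Tu
    can sequester one charged tRNA in a ternary complex, so the cellular
    budget must cover both pools (2 + 4 = 6 with the measured EF-Tu
    stoichiometry); cellular estimates of 6-7 tRNA/ribosome barely clear it.
    """
    return ribosome_sites + eftu_per_ribosome


@dataclass
class ObservedTable:
    """Observed per-species synthesis fractions of translation factors."""

    data: pd.DataFrame
    provenance: str = ""

    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def fractions(self, species: str) -> dict[str, float]:
        """factor -> fraction for one species, with RFI = RF1 + RF2 derived."""
        sub = self.data[self.data["species"] == species]
        out = dict(zip(sub["factor"], sub["synthesis_fraction"]))
        if "RFI" not in out and {"RF1", "RF2"} <= out.keys():
            out["RFI"] = out["RF1"] + out["RF2"]
        return out

    def mean_fractions(self) -> dict[str, float]:
        """Unweighted arithmetic mean across species, factor by factor."""
        per_species = [self.fractions(sp) for sp in self.species()]
        factors = set().union(*per_species)
        return {f: float(np.mean([d[f] for d in per_species if f in d]))
                for f in factors}


def load_observed(path) -> ObservedTable:
    """Read a tab-separated ``species<TAB>factor<TAB>synthesis_fraction`` file.

    Unknown factor names warn but load; malformed rows raise with their
    line number; fractions must lie in (0, 1).
    """
    provenance = []
    rows = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                provenance.append(line.lstrip("# "))
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                if header != _OBSERVED_COLUMNS:
                    raise InputError(
                        f"line {lineno}: header must be "
                        f"{_OBSERVED_COLUMNS}, got {header}")
                continue
            if len(cells) != 3:
                raise InputError(f"line {lineno}: expected 3 columns, got {len(cells)}")
            species, factor = cells[0].strip(), cells[1].strip()
            try:
                fraction = float(cells[2])
            except ValueError as exc:
                raise InputError(f"line {lineno}: bad fraction {cells[2]!r}") from exc
            if not 0 < fraction < 1:
                raise InputError(
                    f"line {lineno}: synthesis fraction must be in (0, 1), "
                    f"got {fraction}")
            if factor not in CANONICAL_FACTORS:
                logger.warning("line %d: unknown factor name %r", lineno, factor)
            rows.append((species, factor, fraction))
    if header is None or not rows:
        raise InputError(f"{path}: no observed rows found")
    frame = pd.DataFrame(rows, columns=_OBSERVED_COLUMNS)
    return ObservedTable(data=frame, provenance="\n".join(provenance))


def default_observed() -> ObservedTable:
    """Bundled synthetic three-species fixture (see its provenance header)."""
    with resources.as_file(
            resources.files("tlfopt.data")
            .joinpath("observed_synthesis_fractions_synthetic.tsv")) as path:
        return load_observed(path)


@dataclass
class ComparisonReport:
    """Factor-by-factor comparison of predicted vs. observed abundances."""

    table: pd.DataFrame
    eftu_efg_observed: dict[str, float]
    eftu_efg_predicted: float
    elongation_termination_observed: float
    elongation_termination_predicted: float
    hierarchy_ok: bool
    max_fold_deviation: float
    outside_2_5x: list[str] = field(default_factory=list)
    min_trna_per_ribosome: float = min_trna_per_ribosome()

    def to_dict(self) -> dict:
        return {
            "factors": self.table.to_dict(orient="index"),
            "eftu_efg_observed": self.eftu_efg_observed,
            "eftu_efg_predicted": self.eftu_efg_predicted,
            "elongation_termination_observed": self.elongation_termination_observed,
            "elongation_termination_predicted": self.elongation_termination_predicted,
            "hierarchy_ok": self.hierarchy_ok,
            "max_fold_deviation": self.max_fold_deviation,
            "outside_2_5x": self.outside_2_5x,
            "min_trna_per_ribosome": self.min_trna_per_ribosome,
        }


def compare(allocation: OptimalAllocation, observed: ObservedTable) -> ComparisonReport:
    """Compare an optimal allocation with observed synthesis fractions.

    Observed species means are unweighted; the ratio column is
    observed/predicted.  Factors outside 2x-5x agreement on either side are
    flagged.  The hierarchy check asserts the predicted elongation >
    initiation/termination ordering (EF-Tu > EF-G > every IF and RF).
    """
    predicted = {name: f.phi_star for name, f in allocation.factors.items()}
    mean_obs = observed.mean_fractions()
    overlap = sorted(set(predicted) & set(mean_obs))
    if not overlap:
        raise InputError("no overlapping factors between prediction and observation")

    species = observed.species()
    rows = {}
    for name in overlap:
        per_species = {sp: observed.fractions(sp).get(name, math.nan)
                       for sp in species}
        rows[name] = {
            "predicted": predicted[name],
            "observed_mean": mean_obs[name],
            "ratio_obs_pred": mean_obs[name] / predicted[name],
            **{f"observed_{sp}": v for sp, v in per_species.items()},
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    ratios = table["ratio_obs_pred"]
    fold = np.maximum(ratios, 1.0 / ratios)
    outside = sorted(ratios.index[(ratios > 5.0) | (ratios < 0.2)])

    eftu_obs = {}
    for sp in species:
        fr = observed.fractions(sp)
        if "EF-Tu" in fr and "EF-G" in fr:
            eftu_obs[sp] = fr["EF-Tu"] / fr["EF-G"]
    eftu_pred = (predicted["EF-Tu"] / predicted["EF-G"]
                 if {"EF-Tu", "EF-G"} <= predicted.keys() else math.nan)

    elong = ["EF-Tu", "EF-G", "EF-Ts", "aaRS"]
    term = ["RFI", "RF4"]

    def _ratio(values: Mapping[str, float]) -> float:
        num = sum(values[f] for f in elong if f in values)
        den = sum(values[f] for f in term if f in values)
        return num / den if den else math.nan

    small = [predicted.get(n, math.inf) for n in
             ("IF1", "IF2", "IF3", "RFI", "RF4") if n in predicted]
    hierarchy_ok = (predicted.get("EF-Tu", 0) > predicted.get("EF-G", 0)
                    and predicted.get("EF-G", 0) > max(small, default=0))

    return ComparisonReport(
        table=table,
        eftu_efg_observed=eftu_obs,
        eftu_efg_predicted=eftu_pred,
        elongation_termination_observed=_ratio(mean_obs),
        elongation_termination_predicted=_ratio(predicted),
        hierarchy_ok=hierarchy_ok,
        max_fold_deviation=float(fold.max()),
        outside_2_5x=outside,
    )


def scaling_table(params: GlobalParams, specs: Mapping[str, FactorSpec],
                  phi_tl_values: Sequence[float],
                  mode: str = BINDING_LIMITED, **solve_kwargs) -> pd.DataFrame:
    """Sweep the translation sector, re-solving the growth optimum.

    One row per feasible ``phi_tl`` with lambda*, each factor's optimal
    fraction, and the normalized column ``<factor>/sqrt(lambda)`` that is
    constant for binding-limited factors (the sqrt-lambda law); infeasible
    sector values are skipped with a warning.
    """
    rows = []
    for phi_tl in phi_tl_values:
        try:
            p = _replace(params, phi_tl=phi_tl)
            allocation = solve_self_consistent(p, specs, mode=mode, **solve_kwargs)
        except (AllocationInfeasibleError, BudgetInfeasibleError) as exc:
            logger.warning("phi_tl = %g infeasible: %s", phi_tl, exc)
            continue
        row = {"phi_tl": phi_tl, "lambda_star": allocation.lambda_star}
        sqrt_lam = math.sqrt(allocation.lambda_star)
        for name, factor in allocation.factors.items():
            row[name] = factor.phi_star
            row[f"{name}/sqrt(lambda)"] = factor.phi_star / sqrt_lam
        rows.append(row)
    if not rows:
        raise InputError("no feasible phi_tl values in the sweep")
    return pd.DataFrame(rows)
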