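"""Global and per-factor parameter registry, unit conversions, rate estimation.

All abundances are handled internally as proteome fractions (phi, dry-mass
fraction of the proteome).  Molar concentrations exist only at the I/O
boundary, connected through the in-protein amino-acid concentration ``P``:

    phi_A = [A] * len_A / P

Association rate constants come in two flavours: ``kon_hat`` in the usual
uM^-1 s^-1 (how rates are measured) and the rescaled ``kon = kon_hat * P /
len`` in s^-1 per unit proteome fraction, such that ``kon_hat * [A] == kon *
phi_A`` identically.

Missing biophysical parameters are estimated with a diffusion-based scaling:
association rate constants scale with the sum of the reactants' diffusion
coefficients relative to the measured ternary-complex/ribosome reference,
and unmeasured diffusion coefficients follow Stokes-Einstein cube-root
scaling with protein length from a measured anchor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

from tlfopt.errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: Measured association rate constant of the ternary complex with the
#: ribosome A site, uM^-1 s^-1 (the diffusion-scaling reference reaction).
KON_HAT_TC = 6.4

_STEPS = frozenset({"initiation", "elongation", "termination", "reference"})

_FACTOR_TABLE_COLUMNS = [
    "name", "step", "length_aa", "diffusion_um2_s", "kon_hat_uM_s",
    "kcat_s", "codon_specific", "per_protein_uses",
]


@dataclass(frozen=True)
class GlobalParams:
    """Cell-scale constants of the translation-cycle model.

    Parameters
    ----------
    P : float
        In-protein amino-acid concentration, uM (~2.6e6 in fast-growing
        bacteria, roughly growth-rate independent).
    avg_len : float
        Expression-weighted mean number of codons per protein.
    len_ribo : float
        Amino acids in the ribosomal proteins of one ribosome.
    n_aa : float
        Number of coarse-grained codon/amino-acid classes; codon-specific
        association rates are diluted by 1/n_aa in the one-codon model.
    phi_tl : float
        Proteome fraction of the translation sector (ribosomes + factors).
    phi_ribo_inactive : float
        Proteome fraction of inactive (assembling/hibernating) ribosomes.
    psi_trna : float
        Total tRNA concentration divided by P (dimensionless budget).
    k_el_max : float
        Maximal codon elongation rate, s^-1 (catalytic ceiling; enters the
        tRNA bookkeeping through ribosomes with occupied A sites).
    stop_freqs : tuple
        Genomic usage fractions of the stop codons (UAA, UAG, UGA).
    k_rna, k_cat_ini : float
        Catalytic rates of the mRNA-loading and subunit-joining steps of
        initiation, s^-1; infinite in the binding-limited idealization.
    """

    P: float = 2.6e6
    avg_len: float = 200.0
    len_ribo: float = 7300.0
    n_aa: float = 20.0
    phi_tl: float = 0.145
    phi_ribo_inactive: float = 0.01
    psi_trna: float = 2.0e-4
    k_el_max: float = 22.0
    stop_freqs: tuple = (0.6, 0.1, 0.3)
    k_rna: float = math.inf
    k_cat_ini: float = math.inf

    def __post_init__(self):
        positive = {
            "P": self.P, "avg_len": self.avg_len, "len_ribo": self.len_ribo,
            "n_aa": self.n_aa, "phi_tl": self.phi_tl,
            "phi_ribo_inactive": self.phi_ribo_inactive,
            "psi_trna": self.psi_trna, "k_el_max": self.k_el_max,
            "k_rna": self.k_rna, "k_cat_ini": self.k_cat_ini,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if len(self.stop_freqs) != 3 or any(f < 0 for f in self.stop_freqs):
            raise ParameterError(f"stop_freqs must be three fractions >= 0, got {self.stop_freqs}")
        if abs(sum(self.stop_freqs) - 1.0) > 1e-12:
            raise ParameterError(f"stop_freqs must sum to 1, got {self.stop_freqs}")
        if not self.phi_tl < 1:
            raise ParameterError(f"phi_tl must be < 1, got {self.phi_tl}")
        if not self.phi_ribo_inactive < self.phi_tl:
            raise ParameterError("phi_ribo_inactive must be smaller than phi_tl")

    @property
    def rescale_factor(self) -> float:
        """Growth-law rescaling factor len_ribo / avg_len (~36.5)."""
        return self.len_ribo / self.avg_len


@dataclass
class FactorSpec:
    """Biophysical parameters and cycle role of one translation factor.

    ``kcat = inf`` marks the binding-limited idealization in which the
    reaction time is purely the diffusive search 1/(kon*phi).
    ``codon_specific`` reactions carry the 1/n_aa coarse-graining dilution
    of their association rate.  ``per_protein_uses`` counts how many times
    the factor acts per completed protein (1 for initiation/termination,
    avg_len for elongation factors).
    """

    name: str
    step: str
    length_aa: float
    diffusion: float | None = None
    kon_hat: float | None = None
    kcat: float = math.inf
    codon_specific: bool = False
    per_protein_uses: float = 1.0

    def __post_init__(self):
        if self.step not in _STEPS:
            raise ParameterError(f"{self.name}: unknown step {self.step!r}")
        if not self.length_aa >= 1:
            raise ParameterError(f"{self.name}: length_aa must be >= 1")
        for attr in ("diffusion", "kon_hat"):
            value = getattr(self, attr)
            if value is not None and not value > 0:
                raise ParameterError(f"{self.name}: {attr} must be > 0, got {value}")
        if not self.kcat > 0:
            raise ParameterError(f"{self.name}: kcat must be > 0, got {self.kcat}")
        if not self.per_protein_uses >= 1:
            raise ParameterError(f"{self.name}: per_protein_uses must be >= 1")

    def kon(self, P: float) -> float:
        """Rescaled association rate, s^-1 per unit proteome fraction."""
        if self.kon_hat is None:
            raise ParameterError(f"{self.name}: kon_hat is not set (estimate it first)")
        return kon_rescale(self.kon_hat, self.length_aa, P)


# ---------------------------------------------------------------------------
# unit conversions


def conc_to_phi(conc: float, length_aa: float, P: float) -> float:
    """Convert a molar concentration (uM) to a proteome fraction."""
    if not P > 0:
        raise ParameterError(f"P must be > 0, got {P}")
    if conc < 0 or length_aa < 0:
        raise ParameterError("concentration and length must be >= 0")
    return conc * length_aa / P


def phi_to_conc(phi: float, length_aa: float, P: float) -> float:
    """Convert a proteome fraction back to a molar concentration (uM)."""
    if not P > 0:
        raise ParameterError(f"P must be > 0, got {P}")
    if not length_aa > 0:
        raise ParameterError(f"length_aa must be > 0, got {length_aa}")
    return phi * P / length_aa


def kon_rescale(kon_hat: float, length_aa: float, P: float) -> float:
    """Rescale kon_hat (uM^-1 s^-1) to proteome-fraction units (s^-1).

    Satisfies ``kon_hat * [A] == kon * phi_A`` exactly for any concentration.
    """
    if not length_aa > 0:
        raise ParameterError(f"length_aa must be > 0, got {length_aa}")
    if not (kon_hat > 0 and P > 0):
        raise ParameterError("kon_hat and P must be > 0")
    return kon_hat * P / length_aa


def kon_from_diffusion(D_A: float, D_B: float, ref_kon_hat: float = KON_HAT_TC,
                       D_TC: float | None = None, D_ribo: float | None = None) -> float:
    """Estimate an association rate constant by diffusion scaling.

    Scales the measured ternary-complex/ribosome rate by the summed
    diffusion coefficients of the reactant pair:
    ``kon_hat_AB = ref * (D_A + D_B) / (D_TC + D_ribo)``.
    """
    if D_TC is None:
        D_TC = D_TC_DEFAULT
    if D_ribo is None:
        D_ribo = D_RIBO_DEFAULT
    for name, value in (("D_A", D_A), ("D_B", D_B), ("D_TC", D_TC), ("D_ribo", D_ribo)):
        if not value > 0:
            raise ParameterError(f"{name} must be > 0, got {value}")
    return ref_kon_hat * (D_A + D_B) / (D_TC + D_ribo)


def diffusion_from_length(length_aa: float, ref_length: float, ref_D: float) -> float:
    """Stokes-Einstein estimate: D scales as the cube root of inverse length."""
    if not (length_aa > 0 and ref_length > 0 and ref_D > 0):
        raise ParameterError("all inputs must be > 0")
    return ref_D * (ref_length / length_aa) ** (1.0 / 3.0)


def avg_protein_length(expression_table: Iterable[tuple[float, float]]) -> float:
    """Expression-weighted mean protein length, sum(e_i*len_i)/sum(e_i).

    ``expression_table`` holds (length_in_codons, synthesis_rate) pairs.
    """
    rows = list(expression_table)
    if not rows:
        raise InputError("expression table is empty")
    total_w = 0.0
    total_wl = 0.0
    for length, weight in rows:
        if weight < 0:
            raise InputError(f"negative synthesis rate {weight}")
        total_w += weight
        total_wl += weight * length
    if total_w == 0:
        raise InputError("all synthesis rates are zero")
    return total_wl / total_w


# ---------------------------------------------------------------------------
# defaults and I/O

#: In vivo diffusion coefficients, um^2 s^-1.  EF-Tu is the measured
#: cube-root anchor for unmeasured factors; the ribosome and ternary-complex
#: values set the denominator of the rate-scaling estimate; free tRNA enters
#: the EF-Tu and aaRS binding reactions.
D_TU_ANCHOR = 2.6
D_RIBO_DEFAULT = 0.04
D_TC_DEFAULT = 2.2
D_TRNA_DEFAULT = 8.0


def _bundled(name: str):
    return resources.files("tlfopt.data").joinpath(name)


def load_factor_table(path, params: GlobalParams | None = None,
                      estimate_missing: bool = True) -> dict[str, FactorSpec]:
    """Read a tab-separated factor table into a name -> FactorSpec mapping.

    Empty cells mean "absent"; ``inf`` is accepted for ``kcat_s``.  With
    ``estimate_missing`` (default), absent diffusion coefficients are filled
    by cube-root length scaling from a measured anchor and absent
    association rate constants by diffusion scaling against the
    ternary-complex/ribosome reference (ribosome assumed as the binding
    partner).  A factor providing both a measured ``kon_hat`` and a
    diffusion coefficient keeps the measured rate (logged).
    """
    params = params or GlobalParams()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing_cols = set(_FACTOR_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InputError(f"factor table is missing columns {sorted(missing_cols)}")

    specs: dict[str, FactorSpec] = {}
    for _, row in df.iterrows():
        def cell(col):
            value = row[col]
            if pd.isna(value) or str(value).strip() == "":
                return None
            return str(value).strip()

        name = cell("name")
        if name is None:
            raise InputError("factor table row without a name")
        uses_raw = cell("per_protein_uses") or "1"
        uses = params.avg_len if uses_raw == "avg_len" else float(uses_raw)
        if uses not in (1.0, params.avg_len):
            raise ParameterError(
                f"{name}: per_protein_uses must be 1 or avg_len, got {uses_raw}")
        spec = FactorSpec(
            name=name,
            step=cell("step") or "reference",
            length_aa=float(cell("length_aa")),
            diffusion=(None if cell("diffusion_um2_s") is None
                       else float(cell("diffusion_um2_s"))),
            kon_hat=(None if cell("kon_hat_uM_s") is None
                     else float(cell("kon_hat_uM_s"))),
            kcat=(math.inf if cell("kcat_s") in (None, "inf")
                  else float(cell("kcat_s"))),
            codon_specific=(cell("codon_specific") or "0") in ("1", "true", "True"),
            per_protein_uses=uses,
        )
        specs[name] = spec

    if estimate_missing:
        specs = estimate_missing_rates(specs, params)
    return specs


def estimate_missing_rates(specs: Mapping[str, FactorSpec],
                           params: GlobalParams) -> dict[str, FactorSpec]:
    """Fill absent diffusion coefficients and association rate constants.

    Diffusion anchors on the first factor (EF-Tu preferred) with a measured
    coefficient; association rates are scaled against the measured
    ternary-complex reference assuming the ribosome as binding partner.
    """
    specs = dict(specs)
    anchor = specs.get("EF-Tu")
    if anchor is None or anchor.diffusion is None:
        anchor = next((s for s in specs.values() if s.diffusion is not None), None)
    for name, spec in specs.items():
        if spec.diffusion is None:
            if anchor is None:
                raise ParameterError(
                    "no factor has a measured diffusion coefficient to anchor on")
            est = diffusion_from_length(spec.length_aa, anchor.length_aa, anchor.diffusion)
            specs[name] = spec = replace(spec, diffusion=est)
            logger.debug("estimated diffusion for %s: %.3g um^2/s", name, est)

    d_tc = specs["TC"].diffusion if "TC" in specs else D_TC_DEFAULT
    d_ribo = specs["ribosome"].diffusion if "ribosome" in specs else D_RIBO_DEFAULT
    ref = specs["TC"].kon_hat if ("TC" in specs and specs["TC"].kon_hat) else KON_HAT_TC
    for name, spec in specs.items():
        if name == "ribosome":
            continue
        if spec.kon_hat is None:
            est = kon_from_diffusion(spec.diffusion, d_ribo, ref, d_tc, d_ribo)
            specs[name] = replace(spec, kon_hat=est)
            logger.debug("estimated kon_hat for %s: %.3g /uM/s", name, est)
        elif spec.diffusion is not None and name != "TC":
            logger.warning(
                "%s: measured kon_hat %.3g overrides the diffusion-scaling estimate",
                name, spec.kon_hat)
    return specs


def default_factors(params: GlobalParams | None = None) -> dict[str, FactorSpec]:
    """Bundled factor table (E. coli lengths, in vivo diffusion anchors)."""
    with resources.as_file(_bundled("factors.tsv")) as path:
        return load_factor_table(path, params=params)


def default_params(**overrides) -> GlobalParams:
    """Bundled cell-scale defaults, optionally overridden field by field."""
    return GlobalParams(**overrides)


def load_global_config(path) -> GlobalParams:
    """Read a YAML key-value file of GlobalParams fields; unknown keys fail."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputError("global config must be a key-value mapping")
    known = set(GlobalParams.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown global-config keys: {sorted(unknown)}")
    if "stop_freqs" in raw:
        raw["stop_freqs"] = tuple(float(f) for f in raw["stop_freqs"])
    for key, value in raw.items():
        if key == "stop_freqs":
            continue
        if value in ("inf", ".inf"):
            raw[key] = math.inf
        else:
            # YAML 1.1 reads "2.6e6" (no sign) as a string; coerce scalars
            raw[key] = float(value)
    return GlobalParams(**raw)
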