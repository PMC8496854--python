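"""Pseudoisomer (Legendre-transform) corrections and unit conversions.

A compound in solution is a Boltzmann mixture of protonation states
("pseudoisomers").  Regression is carried out on energies of a single
reference pseudoisomer (the most abundant species at pH 7, I = 0.25 M);
observed apparent equilibrium data, measured over the whole mixture at some
pH/ionic strength/temperature, must be corrected to that reference before
training, and predictions corrected back before reporting.

For one compound the correction is

    ddG = Delta_f G'std - Delta_f Gstd
        = RT ln10 * m * pH
          - RT * ln sum_{n=0..N_H} exp[ ln10 * sum_{i=m+1..n} (pKa_i - pH)
                                        + A (z_n^2 - n) sqrt(I) / (RT (1 + 1.6 sqrt(I))) ]

with m the proton count of the reference pseudoisomer, N_H the number of
dissociable protons (= number of pKas), z_n = z_ref + (n - m) the charge of
pseudoisomer n, and A = 2.91482 kJ mol^-1 M^-1/2 the extended Debye-Hueckel
constant at 298.15 K (Alberty's convention, saturation denominator
1 + 1.6 sqrt(I)).  The inner sum runs downward with negated sign when
n < m and is empty when n = m.  The Boltzmann sum is evaluated with
log-sum-exp for overflow safety.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Gas constant, kJ mol^-1 K^-1.
R = 8.31446e-3

#: Extended Debye-Hueckel coefficient, kJ mol^-1 M^-1/2.
DEBYE_HUECKEL_A = 2.91482

#: Ion-size saturation coefficient, M^-1/2.
DEBYE_HUECKEL_B = 1.6

LN10 = math.log(10.0)


@dataclass(frozen=True)
class Conditions:
    """Aqueous conditions for transformed Gibbs energies.

    Defaults are the biochemical standard state: pH 7.0, ionic strength
    0.25 M, 298.15 K.
    """

    ph: float = 7.0
    ionic_strength: float = 0.25
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.ionic_strength < 0:
            raise ValueError(f"ionic strength must be nonnegative, got {self.ionic_strength}")
        if not 0.0 <= self.ph <= 14.0:
            logger.warning("pH %.2f outside [0, 14]", self.ph)

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return R * self.temperature


@dataclass(frozen=True)
class PseudoisomerSpec:
    """Protonation ladder of one compound.

    ``pka_list[i-1]`` is the pKa of the equilibrium between the pseudoisomer
    carrying ``i`` dissociable protons and the one carrying ``i - 1``
    (ordering consistent with the summation index of the transform).
    ``m`` is the dissociable-proton count of the reference pseudoisomer and
    ``z_ref`` its charge; pseudoisomer ``n`` has charge ``z_ref + (n - m)``.
    """

    compound_id: str
    pka_list: tuple[float, ...] = ()
    m: int = 0
    z_ref: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pka_list", tuple(float(p) for p in self.pka_list))
        if not 0 <= self.m <= self.n_h:
            raise ValueError(
                f"{self.compound_id}: reference proton count m={self.m} must lie "
                f"in [0, N_H={self.n_h}]"
            )

    @property
    def n_h(self) -> int:
        """Maximum number of dissociable protons (= number of pKas)."""
        return len(self.pka_list)

    def charge(self, n: int) -> int:
        return self.z_ref + (n - self.m)


@dataclass(frozen=True)
class TransformResult:
    """Per-compound transform offset Delta_f G'std - Delta_f Gstd, kJ/mol."""

    ddg: float


def _debye_hueckel(z: int, n: int, ionic_strength: float, temperature: float) -> float:
    """Ionic-strength term inside the Boltzmann exponent (dimensionless)."""
    if ionic_strength == 0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength)
    return (
        DEBYE_HUECKEL_A
        * (z * z - n)
        * sqrt_i
        / (R * temperature * (1.0 + DEBYE_HUECKEL_B * sqrt_i))
    )


def pseudoisomer_exponents(spec: PseudoisomerSpec, cond: Conditions) -> np.ndarray:
    """Log Boltzmann weight of each pseudoisomer n = 0..N_H (relative to the
    reference), the terms summed inside the transform."""
    exps = np.empty(spec.n_h + 1)
    for n in range(spec.n_h + 1):
        if n > spec.m:
            pka_sum = sum(spec.pka_list[i - 1] - cond.ph for i in range(spec.m + 1, n + 1))
        elif n < spec.m:
            pka_sum = -sum(spec.pka_list[i - 1] - cond.ph for i in range(n + 1, spec.m + 1))
        else:
            pka_sum = 0.0
        exps[n] = LN10 * pka_sum + _debye_hueckel(
            spec.charge(n), n, cond.ionic_strength, cond.temperature
        )
    return exps


def pseudoisomer_ddg(spec: PseudoisomerSpec, cond: Conditions) -> TransformResult:
    """Transform offset ddG = Delta_f G'std - Delta_f Gstd for one compound."""
    rt = cond.rt
    ddg = rt * LN10 * spec.m * cond.ph - rt * float(logsumexp(pseudoisomer_exponents(spec, cond)))
    return TransformResult(ddg=ddg)


def kprime_to_drgo(k_prime: float, temperature: float = 298.15) -> float:
    """Apparent equilibrium constant K' -> Delta_r G'std = -RT ln K' (kJ/mol)."""
    if k_prime <= 0:
        raise ValueError(f"K' must be positive, got {k_prime}")
    return -R * temperature * math.log(k_prime)


def _reaction_ddg(
    rxn, specs: Mapping[str, PseudoisomerSpec], cond: Conditions
) -> float:
    coeffs: Mapping[str, float] = getattr(rxn, "coeffs", rxn)
    total = 0.0
    for cid, coeff in coeffs.items():
        spec = specs.get(cid)
        if spec is None:
            logger.warning(
                "no pseudoisomer spec for compound %s; assuming ddG = 0", cid
            )
            continue
        total += float(coeff) * pseudoisomer_ddg(spec, cond).ddg
    return total


def untransform_reaction(
    drg_prime_obs: float,
    rxn,
    specs: Mapping[str, PseudoisomerSpec],
    cond: Conditions,
) -> float:
    """Observed Delta_r G'std -> reference-pseudoisomer Delta_r Gstd.

    Compounds without a spec contribute ddG = 0 (with a logged warning).
    Exact inverse of :func:`transform_prediction` at identical conditions.
    """
    return drg_prime_obs - _reaction_ddg(rxn, specs, cond)


def transform_prediction(
    drg_standard: float,
    rxn,
    specs: Mapping[str, PseudoisomerSpec],
    cond: Conditions,
) -> float:
    """Reference-pseudoisomer Delta_r Gstd -> transformed Delta_r G'std."""
    return drg_standard + _reaction_ddg(rxn, specs, cond)


def concentration_adjust(
    drg_prime_standard: float,
    concentrations: Mapping[str, float],
    rxn,
    temperature: float = 298.15,
) -> float:
    """Actual reaction Gibbs energy at given concentrations (mol/L):

    Delta_r G' = Delta_r G'std + RT * sum_i S_i ln c_i
    """
    coeffs: Mapping[str, float] = getattr(rxn, "coeffs", rxn)
    total = 0.0
    for cid, coeff in coeffs.items():
        try:
            c = concentrations[cid]
        except KeyError:
            raise KeyError(f"no concentration given for compound {cid!r}") from None
        if c <= 0:
            raise ValueError(f"concentration for {cid!r} must be positive, got {c}")
        total += float(coeff) * math.log(c)
    return drg_prime_standard + R * temperature * total


def load_pseudoisomer_table(path) -> dict[str, PseudoisomerSpec]:
    """Read a pseudoisomer TSV: compound_id, pka_list (';'-separated), m, z_ref.

    An optional ``n_h`` column is validated against the pKa count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "pka_list", "m", "z_ref"}
    missing = required - set(c.lower() for c in df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    specs: dict[str, PseudoisomerSpec] = {}
    for _, row in df.iterrows():
        raw = row["pka_list"]
        pkas = tuple(
            float(p) for p in str(raw).split(";") if p.strip()
        ) if pd.notna(raw) else ()
        spec = PseudoisomerSpec(
            compound_id=row["compound_id"],
            pka_list=pkas,
            m=int(row["m"]),
            z_ref=int(row["z_ref"]),
        )
        if "n_h" in df.columns and pd.notna(row.get("n_h")):
            if int(row["n_h"]) != spec.n_h:
                raise ValueError(
                    f"{path}: compound {spec.compound_id}: n_h={row['n_h']} does not "
                    f"match {spec.n_h} pKa values"
                )
        if spec.compound_id in specs:
            raise ValueError(f"{path}: duplicate compound id {spec.compound_id!r}")
        specs[spec.compound_id] = spec
    return specs
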