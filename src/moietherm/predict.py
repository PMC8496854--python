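"""Reaction parsing and end-to-end transformed Gibbs energy prediction.

A reaction string such as ``"C00096 <=> C02280"`` or
``"C01745 + C00004 <=> N00001 + C00003 + C00001"`` is parsed into a signed
stoichiometry (reactants negative, products positive).  Ids absent from the
compound table must come with a structure (the ``N#####`` convention for
novel metabolites; the prefix itself is not enforced).  Prediction builds
the moiety-change vector, applies the regression model, and adds the
pseudoisomer correction for the requested pH/ionic strength/temperature.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import pandas as pd
from rdkit import Chem

from .chem import CompoundTable, MoleculeRecord, parse_compound
from .errors import ReactionParseError, UnknownCompoundError
from .fragment import IncidenceMatrix, build_incidence, moiety_change
from .regress import RidgeModel, predict_mean_std
from .thermo import Conditions, PseudoisomerSpec, transform_prediction

logger = logging.getLogger(__name__)

_ARROW = re.compile(r"<=>|<->|(?<![<>=])=(?![<>=])")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


@dataclass(frozen=True)
class ReactionStoich:
    """Signed stoichiometry over compound ids (reactants < 0, products > 0)."""

    coeffs: Mapping[str, Fraction]
    source: str = ""
    rxn_id: str = ""

    def __post_init__(self):
        clean = {cid: Fraction(c) for cid, c in self.coeffs.items() if c != 0}
        object.__setattr__(self, "coeffs", clean)
        if not clean:
            # degenerate but well-defined (e.g. "2 A <=> A + A"); callers can
            # check is_null instead of being blocked here
            logger.warning(
                "reaction %r: all coefficients cancel (null reaction)",
                self.source or self.rxn_id,
            )
            return
        if not any(c < 0 for c in clean.values()) or not any(c > 0 for c in clean.values()):
            raise ReactionParseError(
                f"reaction {self.source!r} needs at least one reactant and one product"
            )

    @property
    def is_null(self) -> bool:
        """True when the two sides cancel exactly."""
        return not self.coeffs

    def reverse(self) -> "ReactionStoich":
        return ReactionStoich(
            coeffs={cid: -c for cid, c in self.coeffs.items()},
            source=self.source,
            rxn_id=self.rxn_id + ".rev" if self.rxn_id else "",
        )

    def scaled(self, k) -> "ReactionStoich":
        k = Fraction(k)
        return ReactionStoich(
            coeffs={cid: k * c for cid, c in self.coeffs.items()},
            source=self.source,
            rxn_id=self.rxn_id,
        )

    def compound_ids(self) -> tuple[str, ...]:
        return tuple(self.coeffs)


def _parse_side(side: str, text: str) -> Counter:
    counts: Counter = Counter()
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ReactionParseError(f"malformed reaction string {text!r}: empty term")
        match = _TERM.match(term)
        if match is None:
            raise ReactionParseError(f"malformed term {term!r} in reaction {text!r}")
        coef_txt, cid = match.groups()
        coef = Fraction(coef_txt) if coef_txt else Fraction(1)
        if coef <= 0:
            raise ReactionParseError(f"nonpositive coefficient in term {term!r}")
        counts[cid] += coef
    return counts


def parse_reaction(
    text: str,
    compounds: CompoundTable | None = None,
    novel_structures: Mapping[str, str] | None = None,
    rxn_id: str = "",
) -> ReactionStoich:
    """Parse ``[coef] ID (+ [coef] ID)* <=> [coef] ID (+ [coef] ID)*``.

    ``=`` and ``<->`` are accepted as arrow synonyms; the default
    coefficient is 1.  When a compound table is supplied, every id must
    either be present in it or have a structure in ``novel_structures``.
    A reaction whose two sides cancel exactly raises
    :class:`NullReactionError`.
    """
    parts = _ARROW.split(text)
    if len(parts) != 2:
        raise ReactionParseError(
            f"malformed reaction string {text!r}: expected exactly one '<=>' arrow"
        )
    left = _parse_side(parts[0], text)
    right = _parse_side(parts[1], text)
    net: Counter = Counter()
    for cid, c in left.items():
        net[cid] -= c
    for cid, c in right.items():
        net[cid] += c
    if compounds is not None:
        novel_structures = novel_structures or {}
        for cid in net:
            if cid not in compounds and cid not in novel_structures:
                raise UnknownCompoundError(
                    cid, "not in compound table and no novel structure supplied"
                )
    return ReactionStoich(coeffs=dict(net), source=text.strip(), rxn_id=rxn_id)


def resolve_compounds(
    rxn: ReactionStoich,
    compounds: CompoundTable,
    novel_structures: Mapping[str, str] | None = None,
) -> CompoundTable:
    """Table restricted to the reaction's compounds, parsing novel ones."""
    novel_structures = novel_structures or {}
    records: dict[str, MoleculeRecord] = {}
    for cid in rxn.compound_ids():
        if cid in compounds:
            records[cid] = compounds[cid]
        elif cid in novel_structures:
            records[cid] = parse_compound(cid, novel_structures[cid])
        else:
            raise UnknownCompoundError(cid, "no structure available")
    return CompoundTable(records)


def element_imbalance(rxn: ReactionStoich, compounds: CompoundTable) -> dict[str, Fraction]:
    """Net heavy-element change of the reaction (empty dict when balanced).

    Hydrogen is excluded: proton bookkeeping belongs to the pseudoisomer
    transform, not to the structural balance check.
    """
    net: Counter = Counter()
    for cid, coeff in rxn.coeffs.items():
        mol = compounds[cid].mol
        for atom in mol.GetAtoms():
            net[atom.GetSymbol()] += coeff
    return {el: c for el, c in net.items() if c != 0}


@dataclass(frozen=True)
class PredictionReport:
    """Everything the predictor knows about one reaction."""

    reaction: ReactionStoich
    drg_standard: float
    std: float
    drg_prime_standard: float
    conditions: Conditions
    moiety_change: Mapping[str, float]
    unseen_moieties: tuple[str, ...]
    unbalanced: Mapping[str, Fraction] = field(default_factory=dict)
    missing_specs: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "reaction": self.reaction.source,
            "drg_standard_kj_mol": self.drg_standard,
            "std_kj_mol": self.std,
            "drg_prime_standard_kj_mol": self.drg_prime_standard,
            "ph": self.conditions.ph,
            "ionic_strength_M": self.conditions.ionic_strength,
            "temperature_K": self.conditions.temperature,
            "moiety_change": {k: float(v) for k, v in self.moiety_change.items()},
            "unseen_moieties": list(self.unseen_moieties),
            "unbalanced": {el: str(c) for el, c in self.unbalanced.items()},
            "missing_pseudoisomer_specs": list(self.missing_specs),
        }


def predict_reaction(
    rxn: ReactionStoich,
    model: RidgeModel,
    compounds: CompoundTable,
    specs: Mapping[str, PseudoisomerSpec] | None = None,
    cond: Conditions = Conditions(),
    novel_structures: Mapping[str, str] | None = None,
) -> PredictionReport:
    """Predict Delta_r Gstd (mean, std) and Delta_r G'std for one reaction.

    The moiety-change vector is built at the radii/stereo settings the model
    was trained with.  Unseen moieties widen the predictive interval but do
    not block the prediction; element imbalance sets a flag but is not an
    error (rule-like transformations may keep cofactor bookkeeping
    external).  The std passes through the pseudoisomer transform unchanged
    (the transform is deterministic given the specs).
    """
    specs = specs or {}
    table = resolve_compounds(rxn, compounds, novel_structures)
    radii = model.metadata.get("radii", [1, 2])
    stereo = bool(model.metadata.get("stereo", True))
    G = build_incidence(table, radii=radii, stereo=stereo)
    x = moiety_change(rxn, G)
    stats = predict_mean_std(model, x)
    missing = tuple(cid for cid in rxn.compound_ids() if cid not in specs)
    if missing and specs:
        logger.warning("no pseudoisomer specs for: %s", ", ".join(missing))
    drg_prime = transform_prediction(stats.mean, rxn, specs, cond)
    nonzero = {lab: float(v) for lab, v in x.items() if v != 0}
    return PredictionReport(
        reaction=rxn,
        drg_standard=stats.mean,
        std=stats.std,
        drg_prime_standard=drg_prime,
        conditions=cond,
        moiety_change=nonzero,
        unseen_moieties=stats.unseen,
        unbalanced=element_imbalance(rxn, table),
        missing_specs=missing if specs else tuple(rxn.compound_ids()),
    )
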