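"""Reaction rules: deduplicated moiety-change vectors with directionality.

Retrosynthetic pathway design tools operate on reaction *rules* -- the net
substrate-to-product change a family of reactions performs.  Reactions with
the same moiety-change vector share a rule, and a rule can be flagged
irreversible when its predicted Gibbs energy interval is confidently away
from zero:

    irreversible  iff  0 is outside [mean - k*std, mean + k*std]
                       and |mean| > cutoff

with defaults k = 3 (a 99.7% credible interval) and
cutoff = 20 kJ/mol.  The magnitude cutoff is a concentration safeguard:
reversing a reaction with |Delta_r G'std| > 20 kJ/mol would require
physiologically implausible concentration ratios, while smaller energies
can be tilted by metabolite levels, so such rules stay reversible.
A negative mean means the written direction is spontaneous (forward-only);
a positive mean means only the reverse direction is deployable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment import IncidenceMatrix, moiety_change
from .regress import RidgeModel, predict_mean_std

Label = Literal["reversible", "forward_only", "reverse_only"]

DEFAULT_K = 3.0
DEFAULT_CUTOFF = 20.0


def classify_rule(
    mean: float, std: float, k: float = DEFAULT_K, cutoff: float = DEFAULT_CUTOFF
) -> Label:
    """Directionality label from a predicted mean and std (kJ/mol)."""
    if std < 0:
        raise ValueError(f"std must be nonnegative, got {std}")
    lo, hi = mean - k * std, mean + k * std
    excludes_zero = lo > 0 or hi < 0
    if excludes_zero and abs(mean) > cutoff:
        return "forward_only" if mean < 0 else "reverse_only"
    return "reversible"


@dataclass
class ReactionRule:
    """One deduplicated moiety-change vector and its member reactions.

    ``members`` maps reaction id to its orientation (+1 when the reaction
    matches the rule's canonical direction, -1 when it is the reverse).
    """

    rule_id: str
    change: pd.Series
    members: Mapping[str, int]
    mean: float | None = None
    std: float | None = None
    k: float = DEFAULT_K
    cutoff: float = DEFAULT_CUTOFF
    label: Label | None = None

    @property
    def interval(self) -> tuple[float, float] | None:
        if self.mean is None or self.std is None:
            return None
        return (self.mean - self.k * self.std, self.mean + self.k * self.std)

    def nonzero(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in self.change.items() if v != 0}


def _canonical_orientation(x: pd.Series) -> tuple[pd.Series, int]:
    """Orient so the first nonzero entry (lexicographic moiety order) is
    positive; returns the oriented vector and the sign applied."""
    for v in x.values:
        if v != 0:
            return (x, 1) if v > 0 else (-x, -1)
    return x, 1


def build_rule_table(
    reactions: Sequence,
    G: IncidenceMatrix,
    model: RidgeModel | None = None,
    k: float = DEFAULT_K,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ReactionRule]:
    """Deduplicate reactions into rules by exact moiety-change equality.

    A rule and its negation are unified under a canonical orientation, and
    each member records whether it runs with or against that orientation.
    When a model is given, every rule gets a predicted mean/std (in the
    canonical direction) and a directionality label.
    """
    index: dict[tuple, int] = {}
    rules: list[dict] = []
    for i, rxn in enumerate(reactions):
        rxn_id = getattr(rxn, "rxn_id", "") or getattr(rxn, "source", "") or f"rxn{i:05d}"
        x = moiety_change(rxn, G)
        oriented, sign = _canonical_orientation(x)
        key = tuple(oriented.values)
        if key not in index:
            index[key] = len(rules)
            rules.append({"change": oriented, "members": {}})
        rules[index[key]]["members"][rxn_id] = sign
    out: list[ReactionRule] = []
    for i, r in enumerate(rules):
        rule = ReactionRule(
            rule_id=f"rule{i:05d}",
            change=r["change"],
            members=r["members"],
            k=k,
            cutoff=cutoff,
        )
        if model is not None:
            stats = predict_mean_std(model, rule.change)
            rule.mean, rule.std = stats.mean, stats.std
            rule.label = classify_rule(stats.mean, stats.std, k=k, cutoff=cutoff)
        out.append(rule)
    return out


def rules_to_frame(rules: Sequence[ReactionRule]) -> pd.DataFrame:
    """Tabular summary: one row per rule (TSV-ready)."""
    rows = []
    for r in rules:
        lo, hi = r.interval if r.interval else (np.nan, np.nan)
        rows.append(
            {
                "rule_id": r.rule_id,
                "n_members": len(r.members),
                "mean": r.mean,
                "std": r.std,
                "ci_lo": lo,
                "ci_hi": hi,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)
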