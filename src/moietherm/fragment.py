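"""Moiety fragmentation and the incidence matrix G.

Every non-hydrogen atom of a molecule is described by its bonding
environment: the induced subgraph on all atoms within ``radius`` bonds
(including bonds between two peripheral atoms, as in circular-fingerprint
conventions), rendered as a canonical SMILES fragment.  The moiety vector of
a molecule therefore always sums to its heavy-atom count -- one environment
per atom.  Radius 0 is excluded by construction (it would just relabel
atoms) and radii above 2 are rejected: the moiety vocabulary explodes
combinatorially and overfits the available thermodynamic data.

Stereochemistry is part of the key when ``stereo=True``; with
``stereo=False`` chirality annotations are stripped before
canonicalization, so the stereo-off moiety set is always a coarsening of
the stereo-on set.  Formal charges are always part of the key: the
major-pseudoisomer convention fixes one charge state per compound and
charged environments (e.g. phosphates) carry distinct energetics.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import CompoundTable, MoleculeRecord, toolkit_version
from .errors import DecompositionError, UnknownCompoundError

logger = logging.getLogger(__name__)

VALID_RADII = (1, 2)


class Moiety(NamedTuple):
    """One canonical atom-environment key."""

    key: str
    radius: int
    stereo: bool

    @property
    def label(self) -> str:
        """Column label; the radius prefix keeps radius-1 and radius-2
        vocabularies from colliding."""
        return f"r{self.radius}|{self.key}"


def _check_radius(radius: int) -> None:
    if radius == 0:
        raise ValueError("radius 0 is excluded: it would encode each atom as its own moiety")
    if radius not in VALID_RADII:
        raise ValueError(
            f"radius {radius} not supported; radii above 2 inflate the moiety "
            "vocabulary and overfit the training data"
        )


def canonical_fragment_key(fragment_smiles: str) -> str:
    """Re-canonicalize a stereo-free fragment SMILES.

    Fragments are generally not valence-complete molecules, so they are
    re-parsed without sanitization; ring perception is restored before
    writing.  The result is a fixpoint: applying this function twice gives
    the same string.

    Only meaningful for keys without chirality annotations: a fragment's
    chirality is defined relative to its parent molecule (inside the
    fragment alone the centre may have tied substituents), so re-writing a
    stereo-aware key as a standalone molecule would drop the tags.
    Stereo-aware keys are canonical as emitted by the fragment writer,
    deterministically derived from the parent's canonical form.
    """
    mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    if mol is None:  # pragma: no cover - fragment output always re-parses
        return fragment_smiles
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return Chem.MolToSmiles(mol)


def _environment_atoms(mol: Chem.Mol, atom_index: int, radius: int) -> set[int]:
    """Indices of all atoms within ``radius`` bonds of ``atom_index`` (BFS)."""
    seen = {atom_index}
    frontier = {atom_index}
    for _ in range(radius):
        nxt: set[int] = set()
        for idx in frontier:
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetIdx() not in seen:
                    nxt.add(nb.GetIdx())
        seen |= nxt
        frontier = nxt
    return seen


def atom_environment(
    mol: MoleculeRecord | Chem.Mol, atom_index: int, radius: int, stereo: bool = True
) -> Moiety:
    """Canonical moiety of one atom.

    When the molecule is smaller than the radius allows, the environment is
    the truncated reachable subgraph (small molecules like NH2OH are valid
    inputs, not errors).
    """
    _check_radius(radius)
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    n = rdmol.GetNumHeavyAtoms()
    if not 0 <= atom_index < n:
        raise IndexError(f"atom index {atom_index} out of range for {n} heavy atoms")
    atoms = _environment_atoms(rdmol, atom_index, radius)
    bonds = [
        b.GetIdx()
        for b in rdmol.GetBonds()
        if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms
    ]
    key = Chem.MolFragmentToSmiles(
        rdmol,
        atomsToUse=sorted(atoms),
        bondsToUse=bonds or None,
        canonical=True,
        isomericSmiles=stereo,
    )
    return Moiety(key=key, radius=radius, stereo=stereo)


def decompose(
    mol: MoleculeRecord | Chem.Mol, radius: int, stereo: bool = True
) -> dict[Moiety, int]:
    """Moiety vector of one molecule: counts over canonical environments.

    The counts always sum to the heavy-atom count.
    """
    _check_radius(radius)
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    counts: Counter[Moiety] = Counter(
        atom_environment(rdmol, i, radius, stereo) for i in range(rdmol.GetNumHeavyAtoms())
    )
    return dict(counts)


@dataclass
class IncidenceMatrix:
    """Compound-by-moiety count matrix G.

    ``df`` has compound ids as the index and moiety labels (``r<radius>|<key>``)
    as columns, ordered lexicographically by (radius, key) so the matrix is
    reproducible across runs.  ``metadata`` records radii, the stereo flag and
    the toolkit version, because moiety keys are canonicalization-dependent.
    """

    df: pd.DataFrame
    moieties: tuple[Moiety, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def labels(self) -> list[str]:
        return list(self.df.columns)

    def row(self, compound_id: str) -> pd.Series:
        if compound_id not in self.df.index:
            raise UnknownCompoundError(compound_id, "no row in incidence matrix")
        return self.df.loc[compound_id]

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        """Write the matrix as TSV plus a JSON metadata sidecar."""
        path = str(path)
        self.df.to_csv(path, sep="\t", index_label="compound_id")
        sidecar = sidecar or path + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, sidecar: str | None = None) -> "IncidenceMatrix":
        path = str(path)
        df = pd.read_csv(path, sep="\t", index_col="compound_id")
        sidecar = sidecar or path + ".meta.json"
        try:
            with open(sidecar) as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            metadata = {}
        stereo = bool(metadata.get("stereo", True))
        moieties = tuple(
            Moiety(key=c.split("|", 1)[1], radius=int(c[1 : c.index("|")]), stereo=stereo)
            for c in df.columns
        )
        return cls(df=df, moieties=moieties, metadata=metadata)


def build_incidence(
    compounds: CompoundTable | Mapping[str, MoleculeRecord],
    radii: Iterable[int] = (1, 2),
    stereo: bool = True,
) -> IncidenceMatrix:
    """Assemble G over a compound table.

    With ``radii={1, 2}`` the matrix is the horizontal concatenation of the
    per-radius matrices (the combined-radius model).  Failures are collected
    per compound and reported together.
    """
    radii = sorted(set(radii))
    for r in radii:
        _check_radius(r)
    rows: dict[str, Counter[str]] = {}
    failures: dict[str, str] = {}
    all_moieties: dict[str, Moiety] = {}
    for cid, rec in compounds.items():
        counts: Counter[str] = Counter()
        try:
            for r in radii:
                for moiety, c in decompose(rec, r, stereo).items():
                    counts[moiety.label] += c
                    all_moieties[moiety.label] = moiety
        except Exception as exc:  # keep scanning, report all failures at once
            failures[cid] = str(exc)
            continue
        rows[cid] = counts
    if failures:
        raise DecompositionError(failures)
    labels = sorted(all_moieties, key=lambda lab: (all_moieties[lab].radius, all_moieties[lab].key))
    df = pd.DataFrame(
        [[rows[cid].get(lab, 0) for lab in labels] for cid in compounds],
        index=list(compounds),
        columns=labels,
        dtype=np.int64,
    )
    moieties = tuple(all_moieties[lab] for lab in labels)
    metadata = {
        "radii": list(radii),
        "stereo": bool(stereo),
        "toolkit": toolkit_version(),
    }
    return IncidenceMatrix(df=df, moieties=moieties, metadata=metadata)


def moiety_change(reaction, G: IncidenceMatrix) -> pd.Series:
    """Net signed moiety-change vector x = sum_i S_i * G[i, :] of a reaction.

    ``reaction`` is anything with a ``coeffs`` mapping (or a plain mapping)
    of compound id to signed stoichiometric coefficient.  Antisymmetric under
    reaction reversal.
    """
    coeffs: Mapping[str, float] = getattr(reaction, "coeffs", reaction)
    x = pd.Series(0.0, index=G.df.columns)
    for cid, coeff in coeffs.items():
        x = x + float(coeff) * G.row(cid)
    return x


def stripped_key(key: str) -> str:
    """Stereo-stripped canonical form of a moiety key."""
    mol = Chem.MolFromSmiles(key, sanitize=False)
    if mol is None:  # pragma: no cover
        return key
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False)
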