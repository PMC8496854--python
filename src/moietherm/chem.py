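"""Compound parsing, canonicalization and compound tables.

Structures enter the package as InChI or SMILES strings, are parsed with
RDKit and canonicalized to isomeric canonical SMILES.  Hydrogens are kept
implicit throughout; the encoded protonation state is taken at face value
(one "major pseudoisomer" per compound -- protonation corrections happen in
:mod:`moietherm.thermo`, not here).  "H+" is never a compound.

Moiety keys are canonicalization-dependent, so the RDKit version is recorded
in every downstream artifact (see :func:`toolkit_version`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd
import rdkit
from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    SanitizationError,
    StructureParseError,
    UnknownCompoundError,
    UnsupportedStructureError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

# Elements allowed in compound structures.  Everything else (alkali/alkaline
# earth/transition metals, metalloids beyond the usual organics) is rejected:
# the moiety-additivity assumption has no support for metal centres.
_ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "Te", "I"]
)


def toolkit_version() -> str:
    """RDKit version string, pinned into model and matrix metadata."""
    return f"rdkit-{rdkit.__version__}"


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed, canonicalized compound.

    Attributes
    ----------
    compound_id:
        Opaque identifier (KEGG ``C#####``, novel ``N#####``, or anything).
    inchi:
        Standard InChI of the structure.
    canonical_smiles:
        Isomeric canonical SMILES (RDKit dialect); idempotent under
        re-canonicalization.
    heavy_atom_count:
        Number of non-hydrogen atoms.
    formal_charge:
        Net formal charge of the encoded species.
    num_protons:
        Total hydrogen count of the encoded protonation state.
    """

    compound_id: str
    inchi: str
    canonical_smiles: str
    heavy_atom_count: int
    formal_charge: int
    num_protons: int
    mol: Chem.Mol = field(repr=False, compare=False, hash=False)


def _mol_from_structure(compound_id: str, structure: str) -> Chem.Mol:
    structure = structure.strip()
    if not structure:
        raise StructureParseError(compound_id, structure, "empty string")
    if structure.startswith("InChI="):
        mol = Chem.MolFromInchi(structure, sanitize=False, treatWarningAsError=False)
    else:
        mol = Chem.MolFromSmiles(structure, sanitize=False)
    if mol is None:
        raise StructureParseError(compound_id, structure)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several unrelated types
        raise SanitizationError(compound_id, str(exc)) from exc
    return mol


def parse_compound(compound_id: str, structure: str) -> MoleculeRecord:
    """Parse an InChI or SMILES string into a :class:`MoleculeRecord`.

    Stereo annotations present in the input are preserved in
    ``canonical_smiles``.  Structures containing metal atoms or ``*``
    repeat-unit wildcards raise :class:`UnsupportedStructureError`.
    """
    mol = _mol_from_structure(compound_id, structure)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise UnsupportedStructureError(
                f"compound {compound_id!r} contains a wildcard/repeat-unit atom; "
                "polymeric structures are not supported"
            )
        if atom.GetSymbol() not in _ALLOWED_ELEMENTS:
            raise UnsupportedStructureError(
                f"compound {compound_id!r} contains unsupported element "
                f"{atom.GetSymbol()!r}; structures with metals are not supported"
            )
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    # iterate to the canonical fixpoint and store the Mol re-parsed from it:
    # InChI-derived mols carry explicit hydrogens whose first SMILES rendering
    # is not yet canonical, and fragment keys depend on canonical atom order
    smiles = Chem.MolToSmiles(Chem.RemoveHs(mol))
    canon = None
    for _ in range(3):
        canon = Chem.MolFromSmiles(smiles)
        if canon is None:  # pragma: no cover - canonical output always re-parses
            raise StructureParseError(compound_id, smiles, "canonical SMILES round-trip")
        out = Chem.MolToSmiles(canon)
        if out == smiles:
            break
        smiles = out
    return MoleculeRecord(
        compound_id=compound_id,
        inchi=Chem.MolToInchi(canon),
        canonical_smiles=Chem.MolToSmiles(canon),
        heavy_atom_count=canon.GetNumHeavyAtoms(),
        formal_charge=Chem.GetFormalCharge(canon),
        num_protons=sum(a.GetTotalNumHs() for a in canon.GetAtoms()),
        mol=canon,
    )


class CompoundTable(Mapping[str, MoleculeRecord]):
    """Immutable mapping ``compound_id -> MoleculeRecord``."""

    def __init__(self, records: Mapping[str, MoleculeRecord] | list[MoleculeRecord]):
        if not isinstance(records, Mapping):
            records = {r.compound_id: r for r in records}
        self._records = dict(records)

    def __getitem__(self, compound_id: str) -> MoleculeRecord:
        try:
            return self._records[compound_id]
        except KeyError:
            raise UnknownCompoundError(compound_id, "not in compound table") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, compound_id: object) -> bool:
        return compound_id in self._records

    def merged(self, other: "CompoundTable") -> "CompoundTable":
        """New table with ``other``'s records added (duplicates must agree)."""
        merged = dict(self._records)
        for cid, rec in other._records.items():
            if cid in merged and merged[cid].canonical_smiles != rec.canonical_smiles:
                raise ValueError(f"conflicting structures for compound {cid!r}")
            merged[cid] = rec
        return CompoundTable(merged)


def load_compound_table(path) -> CompoundTable:
    """Read a TSV with columns ``compound_id`` and ``inchi`` (or ``smiles``).

    Duplicate compound ids are rejected.  An empty file yields an empty table
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "compound_id" not in cols:
        raise ValueError(f"{path}: missing required column 'compound_id'")
    struct_col = cols.get("inchi") or cols.get("smiles")
    if struct_col is None:
        raise ValueError(f"{path}: need a structure column, 'inchi' or 'smiles'")
    if df.empty:
        logger.warning("%s: compound table is empty", path)
        return CompoundTable({})
    ids = df[cols["compound_id"]]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate compound ids: {dupes}")
    records = {}
    for _, row in df.iterrows():
        cid = row[cols["compound_id"]]
        records[cid] = parse_compound(cid, row[struct_col])
    return CompoundTable(records)
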