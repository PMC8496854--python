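"""Self-contained synthetic corpora with known ground-truth energetics.

The generator emulates the statistical structure of the experimental
training problem (a compendium of enzyme-reaction equilibrium measurements
over a few hundred metabolites) while remaining fully reproducible offline:

* a molecule library built from a fixed template grammar -- carbon chains of
  length 2-8 decorated with substituents from {OH, NH2, SH, CH3, Cl} and
  optional stereocentres -- so every structure is chemically valid without
  random graph generation;
* true moiety contributions drawn from a zero-mean normal, so each
  molecule's formation energy is exactly additive in its radius-1,
  stereo-aware moieties;
* sparse signed integer stoichiometries over the library, with observations
  y = x . truth + Normal(0, noise_sd).

The library always contains one enantiomer pair, (R)- and (S)-butan-2-ol,
and the reaction set always begins with the reaction interconverting them:
its stereo-blind moiety-change vector is exactly zero while the stereo-aware
vector is not (the isomerase scenario).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import CompoundTable, parse_compound
from .fragment import IncidenceMatrix, build_incidence
from .predict import ReactionStoich
from .regress import TrainingSet
from .thermo import PseudoisomerSpec

logger = logging.getLogger(__name__)

_CHAIN_LENGTHS = range(2, 9)
_SUBSTITUENTS = ("O", "N", "S", "C", "Cl")  # OH, NH2, SH, CH3, Cl as branches

#: The embedded enantiomer pair (always present): (R)- and (S)-butan-2-ol.
ENANTIOMER_PAIR = ("C[C@@H](O)CC", "C[C@H](O)CC")

#: (+)-epi-isozizaene, the tricyclic sesquiterpene used as the stereo
#: worked example: 2,3,6,6-tetramethyltricyclo[5.3.1.0(1,5)]undec-2-ene.
#: Its 15 carbons resolve into 7 distinct radius-1 moieties with
#: stereochemistry (the two methines have opposite handedness and the
#: ring-fusion quaternary carbon is chiral) but only 5 without.
EPI_ISOZIZAENE_SMILES = "CC1=C(C)[C@@]23CCC[C@H](C2)C(C)(C)[C@@H]3C1"

#: Default true-contribution spread, kJ/mol.  Fitted moiety contributions on
#: experimental data span roughly +/- 100 kJ/mol with a prior std near
#: 30 kJ/mol; 25 kJ/mol keeps synthetic reaction energies in a realistic
#: few-hundred-kJ/mol range.
DEFAULT_CONTRIBUTION_SD = 25.0


def _random_molecule_smiles(rng: np.random.Generator) -> str:
    """One template molecule: a chain with 0-2 substituents, 0-2 stereocentres."""
    length = int(rng.choice(list(_CHAIN_LENGTHS)))
    n_subs = int(rng.integers(0, 3))
    atoms = ["C"] * length
    branches: dict[int, str] = {}
    positions = [p for p in range(length) if p not in (0,)]
    rng.shuffle(positions)
    for pos in positions[:n_subs]:
        branches[pos] = str(rng.choice(_SUBSTITUENTS))
    # mark substituted interior carbons as stereocentres with probability 1/2
    stereo_marks: dict[int, str] = {}
    for pos, sub in branches.items():
        if 0 < pos < length - 1 and rng.random() < 0.5:
            stereo_marks[pos] = "@" if rng.random() < 0.5 else "@@"
    parts = []
    for i in range(length):
        if i in stereo_marks:
            parts.append(f"[C{stereo_marks[i]}H]")
        else:
            parts.append("C")
        if i in branches:
            parts.append(f"({branches[i]})")
    return "".join(parts)


def build_molecule_library(n_molecules: int, rng: np.random.Generator) -> CompoundTable:
    """Distinct, canonicalized template molecules; the enantiomer pair first."""
    if n_molecules < 5:
        raise ValueError("need at least 5 molecules")
    smiles: list[str] = []
    seen: set[str] = set()
    for smi in ENANTIOMER_PAIR:
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        smiles.append(canon)
        seen.add(canon)
    attempts = 0
    max_attempts = 200 * n_molecules
    while len(smiles) < n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"template grammar exhausted after {attempts} attempts "
                f"({len(smiles)}/{n_molecules} distinct molecules)"
            )
        mol = Chem.MolFromSmiles(_random_molecule_smiles(rng))
        if mol is None:
            continue
        # drop stereo marks that do not designate actual stereocentres
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        smiles.append(canon)
    records = {
        f"M{i:05d}": parse_compound(f"M{i:05d}", smi) for i, smi in enumerate(smiles)
    }
    return CompoundTable(records)


def _random_reactions(
    compound_ids: list[str], n_reactions: int, rng: np.random.Generator
) -> list[ReactionStoich]:
    """Sparse signed integer stoichiometries; reaction 0 is the isomerase."""
    reactions = [
        ReactionStoich(
            coeffs={"M00000": Fraction(-1), "M00001": Fraction(1)},
            source="M00000 <=> M00001",
            rxn_id="R00000",
        )
    ]
    while len(reactions) < n_reactions:
        n_cpds = int(rng.integers(2, 5))
        chosen = [str(c) for c in rng.choice(compound_ids, size=n_cpds, replace=False)]
        signs = rng.choice([-1, 1], size=n_cpds)
        if (signs > 0).all():
            signs[0] = -1
        if (signs < 0).all():
            signs[-1] = 1
        mags = rng.integers(1, 3, size=n_cpds)
        coeffs = {
            cid: Fraction(int(s * m)) for cid, s, m in zip(chosen, signs, mags)
        }
        i = len(reactions)
        reactions.append(
            ReactionStoich(coeffs=coeffs, source="", rxn_id=f"R{i:05d}")
        )
    return reactions


@dataclass
class SyntheticCorpus:
    """A molecule library, moiety ground truth and noisy reaction energies.

    Note on identifiability: radius-1 environment counts obey exact linear
    "handshake" identities -- for every element X, each X--Y bond is counted
    once by the X-centred environment and once as an X neighbour of the
    Y-centred one, which ties the columns of G together.  The reaction
    design matrix X = S^T G therefore never has full column rank; individual
    contributions are recoverable only along the row space of X.  The
    generator guarantees the reactions lose no information beyond that
    (rank(X) = rank(G)), and :meth:`identifiable_mask` marks the coordinates
    that are point-identifiable.
    """

    compounds: CompoundTable
    incidence: IncidenceMatrix
    truth: pd.Series
    reactions: list[ReactionStoich]
    y: np.ndarray
    noise_sd: float
    seed: int

    @property
    def training_set(self) -> TrainingSet:
        return TrainingSet.from_reactions(self.reactions, self.incidence, self.y)

    def design_matrix(self) -> np.ndarray:
        return self.training_set.X.values.astype(float)

    def identifiable_mask(self, tol: float = 1e-8) -> np.ndarray:
        """Boolean mask of moieties whose unit vector lies in the row space
        of the design matrix (their contribution is point-identifiable)."""
        X = self.design_matrix()
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        rank = int(np.sum(s > s.max() * tol))
        v_r = vt[:rank].T
        diag_p = np.einsum("ij,ij->i", v_r, v_r)
        return diag_p > 1.0 - 1e-6

    def write_tsvs(self, out_dir) -> dict[str, Path]:
        """Write the compound, training and pseudoisomer TSVs plus G."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        cpd = pd.DataFrame(
            {
                "compound_id": list(self.compounds),
                "smiles": [self.compounds[c].canonical_smiles for c in self.compounds],
                "inchi": [self.compounds[c].inchi for c in self.compounds],
            }
        )
        paths["compounds"] = out / "compounds.tsv"
        cpd.to_csv(paths["compounds"], sep="\t", index=False)
        train = pd.DataFrame(
            {
                "reaction_id": [r.rxn_id for r in self.reactions],
                "reaction": [
                    r.source
                    or " + ".join(f"{-c} {cid}" for cid, c in r.coeffs.items() if c < 0)
                    + " <=> "
                    + " + ".join(f"{c} {cid}" for cid, c in r.coeffs.items() if c > 0)
                    for r in self.reactions
                ],
                "drg_prime_obs": self.y,
                "ph": 7.0,
                "ionic_strength": 0.0,
                "temperature": 298.15,
            }
        )
        paths["training"] = out / "training.tsv"
        train.to_csv(paths["training"], sep="\t", index=False)
        pseudo = pd.DataFrame(
            [
                {
                    "compound_id": s.compound_id,
                    "pka_list": ";".join(str(p) for p in s.pka_list),
                    "n_h": s.n_h,
                    "m": s.m,
                    "z_ref": s.z_ref,
                }
                for s in fixture_pseudoisomer_specs().values()
            ]
        )
        paths["pseudoisomers"] = out / "pseudoisomers.tsv"
        pseudo.to_csv(paths["pseudoisomers"], sep="\t", index=False)
        paths["incidence"] = out / "incidence.tsv"
        self.incidence.to_tsv(paths["incidence"])
        return paths


def generate_corpus(
    n_molecules: int = 200,
    n_reactions: int = 1000,
    noise_sd: float = 1.0,
    seed: int = 0,
    contribution_sd: float = DEFAULT_CONTRIBUTION_SD,
    check_rank: bool | None = None,
    max_retries: int = 20,
) -> SyntheticCorpus:
    """Deterministic synthetic corpus with known moiety contributions.

    When ``n_reactions >= 2 * n_moieties`` (or ``check_rank=True``) the
    reaction set is regenerated until the design matrix spans the full row
    space of G -- rank(S^T G) = rank(G) -- so the reactions lose no
    identifiable information about the contributions (full column rank is
    unattainable in principle; see :class:`SyntheticCorpus`).
    """
    rng = np.random.default_rng(seed)
    compounds = build_molecule_library(n_molecules, rng)
    G = build_incidence(compounds, radii=(1,), stereo=True)
    m = G.df.shape[1]
    truth = pd.Series(
        rng.normal(0.0, contribution_sd, size=m), index=G.df.columns, name="dgg_true"
    )
    formation = G.df.values @ truth.values  # exactly additive formation energies
    cids = list(compounds)
    want_rank = check_rank if check_rank is not None else n_reactions >= 2 * m
    rank_g = np.linalg.matrix_rank(G.df.values.astype(float))
    pos = {cid: i for i, cid in enumerate(cids)}
    for attempt in range(max_retries):
        reactions = _random_reactions(cids, n_reactions, rng)
        if not want_rank:
            break
        S = np.zeros((len(cids), n_reactions))
        for j, rxn in enumerate(reactions):
            for cid, c in rxn.coeffs.items():
                S[pos[cid], j] = float(c)
        X = S.T @ G.df.values
        if np.linalg.matrix_rank(X) == rank_g:
            break
    else:
        raise RuntimeError(
            f"reaction design lost rank in {max_retries} attempts "
            f"({n_reactions} reactions, rank(G) = {rank_g})"
        )
    idx = {cid: i for i, cid in enumerate(cids)}
    y = np.array(
        [
            sum(float(c) * formation[idx[cid]] for cid, c in rxn.coeffs.items())
            for rxn in reactions
        ]
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return SyntheticCorpus(
        compounds=compounds,
        incidence=G,
        truth=truth,
        reactions=reactions,
        y=y,
        noise_sd=noise_sd,
        seed=seed,
    )


def fixture_pseudoisomer_specs() -> dict[str, PseudoisomerSpec]:
    """Three hand-written protonation ladders with closed-form offsets.

    At I = 0:

    * ``P0`` (no pKa): ddG = 0 at any pH.
    * ``P1`` (one pKa above the reference, m = 0):
      ddG = -RT ln(1 + 10^(pKa - pH)).
    * ``P2`` (two pKas, reference in the middle, m = 1, z_ref = 0):
      ddG = RT ln10 pH - RT ln(1 + 10^(pKa2 - pH) + 10^(pH - pKa1) * w)
      with w the Debye-Hueckel factor of the deprotonated, charged species
      (w = 1 at I = 0).
    """
    return {
        "P0": PseudoisomerSpec(compound_id="P0", pka_list=(), m=0, z_ref=0),
        "P1": PseudoisomerSpec(compound_id="P1", pka_list=(4.75,), m=0, z_ref=-1),
        "P2": PseudoisomerSpec(compound_id="P2", pka_list=(2.15, 7.2), m=1, z_ref=0),
    }


#: Files expected in a locally downloaded copy of the public
#: component-contribution training distribution.
_CC_URL = "https://github.com/eladnoor/component-contribution"
_CC_TECRDB = os.path.join("data", "TECRDB.tsv")

#: Reaction/metabolite counts of the public corpus, used only for logging a
#: sanity comparison after loading.
EXPECTED_CC_REACTIONS = 4001
EXPECTED_CC_METABOLITES = 673


def load_component_contribution(directory) -> pd.DataFrame:
    """Load the optional public training corpus (never downloads).

    Expects ``data/TECRDB.tsv`` inside ``directory`` -- the equilibrium
    compendium shipped with the public component-contribution repository --
    and returns the rows holding an apparent equilibrium constant together
    with their conditions.  Compound structures are not bundled there, so
    turning this table into a :class:`TrainingSet` additionally requires a
    compound table mapping the KEGG ids to structures.
    """
    directory = Path(directory)
    path = directory / _CC_TECRDB
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: download the public training corpus from "
            f"{_CC_URL} and point at the checkout directory"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"reaction", "K_prime", "temperature", "ionic_strength", "p_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing expected columns {sorted(missing)}; the file "
            f"layout may have changed upstream ({_CC_URL})"
        )
    df = df[df["K_prime"].notna()].reset_index(drop=True)
    cpds: set[str] = set()
    for rxn in df["reaction"]:
        for tok in str(rxn).replace("=", " ").replace("+", " ").split():
            if tok.startswith("C") and tok[1:].isdigit():
                cpds.add(tok)
    logger.info(
        "component-contribution corpus: %d usable reactions (expected ~%d), "
        "%d metabolites (expected ~%d)",
        len(df),
        EXPECTED_CC_REACTIONS,
        len(cpds),
        EXPECTED_CC_METABOLITES,
    )
    return df
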