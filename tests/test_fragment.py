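"""Fragmentation, the incidence matrix and moiety-change vectors."""

from collections import Counter

import numpy as np
import pytest
from rdkit import Chem

from moietherm import (
    CompoundTable,
    UnknownCompoundError,
    atom_environment,
    build_incidence,
    decompose,
    moiety_change,
    parse_compound,
)
from moietherm.fragment import IncidenceMatrix, canonical_fragment_key, stripped_key
from moietherm.predict import ReactionStoich


def brute_force_environment_keys(smiles: str, radius: int) -> Counter:
    """Independent stereo-free decomposition: hand-rolled BFS per atom plus a
    from-scratch RWMol copy of the induced subgraph, canonicalized on its own."""
    mol = Chem.MolFromSmiles(smiles)
    keys: Counter = Counter()
    for start in range(mol.GetNumAtoms()):
        dist = {start: 0}
        queue = [start]
        while queue:
            a = queue.pop(0)
            if dist[a] == radius:
                continue
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() not in dist:
                    dist[nb.GetIdx()] = dist[a] + 1
                    queue.append(nb.GetIdx())
        members = sorted(dist)
        sub = Chem.RWMol()
        remap = {}
        for a in members:
            atom = mol.GetAtomWithIdx(a)
            new = Chem.Atom(atom.GetAtomicNum())
            new.SetFormalCharge(atom.GetFormalCharge())
            new.SetIsAromatic(atom.GetIsAromatic())
            new.SetNoImplicit(True)
            new.SetNumExplicitHs(atom.GetTotalNumHs())
            remap[a] = sub.AddAtom(new)
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in remap and j in remap:
                sub.AddBond(remap[i], remap[j], bond.GetBondType())
        frag = sub.GetMol()
        frag.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(frag)
        keys[Chem.MolToSmiles(frag, isomericSmiles=False)] += 1
    return keys


def normalize_h(key: str) -> str:
    """Strip explicit-H annotations so parent-implicit and explicit-H forms
    of the same environment compare equal."""
    mol = Chem.MolFromSmiles(key, sanitize=False)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


class TestAtomEnvironment:
    def test_water_truncates_to_whole_molecule(self):
        rec = parse_compound("W", "O")
        assert atom_environment(rec, 0, 2).key == "O"

    def test_out_of_range_index(self):
        rec = parse_compound("W", "O")
        with pytest.raises(IndexError):
            atom_environment(rec, 1, 1)

    @pytest.mark.parametrize("radius", [0, 3])
    def test_invalid_radius_rejected(self, radius):
        rec = parse_compound("W", "CCO")
        with pytest.raises(ValueError):
            atom_environment(rec, 0, radius)

    def test_methine_stereo_on_vs_off(self):
        # (S)-3-methylhexane: the methine has three carbon substituents
        rec = parse_compound("A", "CC[C@@H](C)CCC")
        keys_on = {atom_environment(rec, i, 1, True).key for i in range(rec.heavy_atom_count)}
        keys_off = {atom_environment(rec, i, 1, False).key for i in range(rec.heavy_atom_count)}
        assert any("@" in k for k in keys_on)
        assert not any("@" in k for k in keys_off)


class TestDecompose:
    def test_worked_example_stereo_resolution(self, epi_isozizaene):
        """The tricyclic sesquiterpene splits into 7 stereo-aware radius-1
        moieties but only 5 stereo-blind ones."""
        on = decompose(epi_isozizaene, 1, True)
        off = decompose(epi_isozizaene, 1, False)
        assert len(on) == 7
        assert len(off) == 5
        assert "C[C@@H](C)C" in {m.key for m in on}
        assert "CC(C)C" in {m.key for m in off}

    def test_hydroxylamine_small_molecule(self):
        """Tiny molecules decompose fine; both atoms of NH2OH see the whole
        molecule as their (truncated) environment, so the two environments
        share one unrooted key with count 2."""
        rec = parse_compound("H", "NO")
        vec = decompose(rec, 1, True)
        assert sum(vec.values()) == 2
        assert {m.key for m in vec} == {"NO"}

    @pytest.mark.parametrize("radius", [1, 2])
    @pytest.mark.parametrize("stereo", [True, False])
    def test_conservation_on_corpus(self, small_corpus, radius, stereo):
        """One environment per heavy atom: counts always sum to the heavy-atom
        count, for every molecule, radius and stereo mode."""
        for cid in small_corpus.compounds:
            rec = small_corpus.compounds[cid]
            vec = decompose(rec, radius, stereo)
            assert sum(vec.values()) == rec.heavy_atom_count

    def test_stereo_refinement(self, small_corpus):
        """Stripping stereo from the stereo-aware moiety set recovers exactly
        the stereo-blind set (a coarsening, never something new)."""
        for cid in list(small_corpus.compounds)[:15]:
            rec = small_corpus.compounds[cid]
            on = decompose(rec, 1, True)
            off = decompose(rec, 1, False)
            assert len(off) <= len(on)
            collapsed: Counter = Counter()
            for m, c in on.items():
                collapsed[stripped_key(m.key)] += c
            assert collapsed == Counter({m.key: c for m, c in off.items()})

    @pytest.mark.parametrize("radius", [1, 2])
    def test_brute_force_oracle_agreement(self, small_corpus, radius):
        """Stereo-free decomposition matches an independent BFS + subgraph-copy
        reimplementation on molecules of <= 12 heavy atoms."""
        checked = 0
        for cid in small_corpus.compounds:
            rec = small_corpus.compounds[cid]
            if rec.heavy_atom_count > 12:
                continue
            mine = Counter()
            for m, c in decompose(rec, radius, False).items():
                mine[normalize_h(m.key)] += c
            oracle = Counter()
            for k, c in brute_force_environment_keys(rec.canonical_smiles, radius).items():
                oracle[normalize_h(k)] += c
            assert mine == oracle, cid
            checked += 1
        assert checked >= 10


class TestIncidenceMatrix:
    def test_single_water_is_one_by_one(self):
        table = CompoundTable([parse_compound("W", "O")])
        G = build_incidence(table, radii=(1,))
        assert G.df.shape == (1, 1)
        assert G.df.values.tolist() == [[1]]

    def test_identical_structures_identical_rows(self):
        table = CompoundTable([parse_compound("A", "CCO"), parse_compound("B", "OCC")])
        G = build_incidence(table, radii=(1, 2))
        assert (G.df.loc["A"] == G.df.loc["B"]).all()

    def test_column_count_matches_independent_enumeration(self, small_corpus):
        """Distinct stereo-free radius-1 keys over 20 molecules, enumerated
        atom-by-atom by the independent oracle, equals the column count."""
        ids = list(small_corpus.compounds)[:20]
        table = CompoundTable({cid: small_corpus.compounds[cid] for cid in ids})
        G = build_incidence(table, radii=(1,), stereo=False)
        oracle_keys = set()
        for cid in ids:
            for k in brute_force_environment_keys(
                small_corpus.compounds[cid].canonical_smiles, 1
            ):
                oracle_keys.add(normalize_h(k))
        assert len({normalize_h(c.split("|", 1)[1]) for c in G.df.columns}) == len(oracle_keys)

    def test_combined_radii_concatenates(self, small_corpus):
        ids = list(small_corpus.compounds)[:10]
        table = CompoundTable({cid: small_corpus.compounds[cid] for cid in ids})
        g1 = build_incidence(table, radii=(1,))
        g2 = build_incidence(table, radii=(2,))
        g12 = build_incidence(table, radii=(1, 2))
        assert set(g12.df.columns) == set(g1.df.columns) | set(g2.df.columns)
        for cid in ids:
            n = table[cid].heavy_atom_count
            assert g1.df.loc[cid].sum() == n
            assert g2.df.loc[cid].sum() == n
            assert g12.df.loc[cid].sum() == 2 * n

    def test_columns_sorted_and_integer(self, incidence_r1):
        assert list(incidence_r1.df.columns) == sorted(incidence_r1.df.columns)
        assert (incidence_r1.df.values >= 0).all()
        assert incidence_r1.df.values.dtype == np.int64

    def test_tsv_round_trip(self, incidence_r1, tmp_path):
        path = tmp_path / "G.tsv"
        incidence_r1.to_tsv(path)
        back = IncidenceMatrix.from_tsv(path)
        assert (back.df == incidence_r1.df).all().all()
        assert back.metadata["radii"] == [1]


class TestMoietyChange:
    def test_reverse_negates(self, small_corpus):
        rxn = small_corpus.reactions[3]
        x = moiety_change(rxn, small_corpus.incidence)
        x_rev = moiety_change(rxn.reverse(), small_corpus.incidence)
        assert (x_rev == -x).all()

    def test_isomerase_pair_stereo_sensitivity(self, small_corpus):
        """An enantiomer interconversion has zero stereo-blind change but a
        nonzero stereo-aware change vector."""
        iso = small_corpus.reactions[0]
        x_on = moiety_change(iso, small_corpus.incidence)
        g_off = build_incidence(small_corpus.compounds, radii=(1,), stereo=False)
        x_off = moiety_change(iso, g_off)
        assert (x_on != 0).any()
        assert (x_off == 0).all()

    def test_mass_balance_shadow(self, enantiomer_records):
        """For a heavy-atom-balanced reaction the signed counts at a fixed
        radius sum to zero."""
        r, s = enantiomer_records
        table = CompoundTable([r, s])
        G = build_incidence(table, radii=(1,))
        rxn = ReactionStoich(coeffs={"BUTR": -1, "BUTS": 1}, rxn_id="iso")
        assert moiety_change(rxn, G).sum() == 0

    def test_unknown_compound_named(self, incidence_r1):
        rxn = ReactionStoich(coeffs={"M00000": -1, "NOPE": 1}, rxn_id="bad")
        with pytest.raises(UnknownCompoundError, match="NOPE"):
            moiety_change(rxn, incidence_r1)


def test_decomposition_input_format_invariant(small_corpus):
    """SMILES and InChI input of the same compound give identical moiety
    vectors, including the handedness of chiral fragment keys (the stored
    molecule is pinned to canonical atom order)."""
    for cid in list(small_corpus.compounds)[:12]:
        rec = small_corpus.compounds[cid]
        via_inchi = parse_compound(cid, rec.inchi)
        assert decompose(via_inchi, 1, True) == decompose(rec, 1, True)
        assert decompose(via_inchi, 2, True) == decompose(rec, 2, True)


def test_stereo_free_keys_are_recanonicalization_fixpoints(small_corpus):
    for cid in list(small_corpus.compounds)[:10]:
        for m in decompose(small_corpus.compounds[cid], 2, False):
            assert canonical_fragment_key(m.key) == canonical_fragment_key(
                canonical_fragment_key(m.key)
            )
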