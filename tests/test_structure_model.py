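import numpy as np
import pytest

from abag_eval.structure_model import (Atom, ComplexPartition, Residue,
                                       StructureModel, extract_plddt,
                                       map_chains, partition_complex,
                                       read_structure, write_pdb)
from abag_eval.synthetic_data import build_toy_complex


def small_structure(n_per_chain=10, chains=("H", "A"), seed=0):
    cx = build_toy_complex(seed=seed)
    trimmed = {}
    for cid in chains:
        source = "H" if cid == "H" else "A"
        trimmed[cid] = [r for r in cx.reference.chains[source][:n_per_chain]]
    return StructureModel(chains=trimmed, label="small")


class TestReadWrite:
    def test_fixture_counts(self, tmp_path):
        st = small_structure()
        path = tmp_path / "small.pdb"
        write_pdb(st, path)
        back = read_structure(path)
        assert back.chain_ids() == ["H", "A"]
        assert sum(len(v) for v in back.chains.values()) == 20

    def test_round_trip_preserves_coordinates_and_keys(self, tmp_path, toy_complex):
        path = tmp_path / "toy.pdb"
        write_pdb(toy_complex.reference, path)
        back = read_structure(path)
        assert back.chain_ids() == toy_complex.reference.chain_ids()
        for cid in back.chain_ids():
            orig = toy_complex.reference.chains[cid]
            got = back.chains[cid]
            assert [r.key for r in got] == [r.key for r in orig]
            for ro, rg in zip(orig, got):
                for ao, ag in zip(ro.atoms, rg.atoms):
                    # PDB precision is 0.001 A
                    assert np.allclose(ao.position, ag.position, atol=5e-4)

    def test_double_round_trip_identical(self, tmp_path, toy_complex):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(toy_complex.reference, p1)
        write_pdb(read_structure(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_water_only_file_rejected(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1      10.000  10.000  10.000  1.00  0.00           O\n"
            "END\n")
        with pytest.raises(ValueError, match="no polymer residues"):
            read_structure(path)

    def test_unparseable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("data_x\n_loop nonsense garbage\n")
        with pytest.raises((ValueError, FileNotFoundError)):
            read_structure(path)

    def test_mmcif_read_matches_pdb(self, tmp_path, toy_complex):
        import gemmi
        pdb_path = tmp_path / "toy.pdb"
        write_pdb(toy_complex.reference, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        st.assign_label_seq_id()
        cif_path = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        from_pdb = read_structure(pdb_path)
        from_cif = read_structure(cif_path)
        assert from_cif.source_format == "mmcif"
        assert from_cif.chain_ids() == from_pdb.chain_ids()
        assert [r.key for r in from_cif.chains["H"]] == [r.key for r in from_pdb.chains["H"]]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N\n"
            "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.60 11.00           N\n"
            "ATOM      3  CA  ALA A   1       1.000   1.000   1.000  1.00 12.00           C\n"
            "END\n")
        st = read_structure(path)
        res = st.chains["A"][0]
        n_atom = res.get_atom("N")
        assert n_atom.position[0] == pytest.approx(5.0)
        assert len([a for a in res.atoms if a.name == "N"]) == 1


class TestInvariants:
    def test_atom_validation(self):
        with pytest.raises(ValueError):
            Atom(name="CA", element="C", position=[0, 0], occupancy=1.0)
        with pytest.raises(ValueError):
            Atom(name="CA", element="C", position=[0, 0, 0], occupancy=1.5)

    def test_residue_needs_atoms(self):
        with pytest.raises(ValueError):
            Residue("A", 1, "", "ALA", atoms=[])

    def test_duplicate_residue_keys_rejected(self):
        atom = Atom("CA", "C", [0.0, 0, 0])
        res = Residue("A", 1, "", "ALA", [atom])
        with pytest.raises(ValueError, match="duplicate"):
            StructureModel(chains={"A": [res, Residue("A", 1, "", "GLY", [atom])]})


class TestPartition:
    def test_heavy_light_partition(self, toy_complex_ab):
        p = partition_complex(toy_complex_ab.reference, "H", "L", ["A"])
        assert p.antibody_chains == ("H", "L")
        assert not p.is_nanobody

    def test_nanobody_partition(self, toy_complex):
        p = partition_complex(toy_complex.reference, "H", None, ["A"])
        assert p.is_nanobody

    def test_overlap_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="overlap"):
            partition_complex(toy_complex.reference, "H", None, ["H"])

    def test_light_without_heavy_rejected(self):
        with pytest.raises(ValueError):
            ComplexPartition(heavy_chain=None, light_chain="L", antigen_chains=("A",))

    def test_missing_chain_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="not present"):
            partition_complex(toy_complex.reference, "X", None, ["A"])


class TestMapChains:
    def test_identity_mapping(self, toy_complex):
        ref = toy_complex.reference
        mapping = map_chains(ref, ref, toy_complex.partition)
        for mod_key, ref_key in mapping.all_pairs():
            assert mod_key == ref_key
        assert len(mapping.all_pairs()) == len(ref.polymer_residues())

    def test_terminal_extras_omitted(self, toy_complex):
        ref = toy_complex.reference
        model = ref.copy()
        extra = [Residue("H", 200 + i, "", "GLY",
                         [Atom("CA", "C", [500.0 + i, 0, 0])]) for i in range(3)]
        model.chains["H"] = model.chains["H"] + extra
        mapping = map_chains(model, ref, toy_complex.partition)
        h_pairs = mapping.pairs[("H", "H")]
        assert len(h_pairs) == len(ref.chains["H"])
        mapped_model_keys = {k for k, _ in h_pairs}
        assert all(r.key not in mapped_model_keys for r in extra)

    def test_internal_gap_skipped(self, toy_complex):
        ref = toy_complex.reference
        gapped = ref.copy()
        removed = [r.key for r in gapped.chains["H"][60:62]]
        gapped.chains["H"] = gapped.chains["H"][:60] + gapped.chains["H"][62:]
        mapping = map_chains(ref, gapped, toy_complex.partition)
        ref_keys = {rk for _, rk in mapping.pairs[("H", "H")]}
        assert len(mapping.pairs[("H", "H")]) == len(ref.chains["H"]) - 2
        assert not (set(removed) & ref_keys)

    def test_symmetric_cardinality(self, toy_complex):
        ref = toy_complex.reference
        model = ref.copy()
        model.chains["H"] = model.chains["H"][3:]
        fwd = map_chains(model, ref, toy_complex.partition)
        rev = map_chains(ref, model, toy_complex.partition)
        assert len(fwd.all_pairs()) == len(rev.all_pairs())

    def test_unrelated_sequences_rejected(self, toy_complex):
        other = build_toy_complex(seed=99)
        with pytest.raises(ValueError, match="identity"):
            map_chains(other.reference, toy_complex.reference, toy_complex.partition)


class TestExtractPlddt:
    def test_uniform_tempfactor(self, toy_complex):
        model = toy_complex.reference.copy()
        for res in model.polymer_residues():
            for atom in res.atoms:
                atom.tempfactor = 91.5
        scores = extract_plddt(model)
        assert len(scores) == len(model.polymer_residues())
        assert all(v == 91.5 for v in scores.values())

    def test_ca_is_representative(self, toy_complex):
        model = toy_complex.reference.copy()
        res = model.chains["H"][0]
        for atom in res.atoms:
            atom.tempfactor = 55.0
        res.get_atom("CA").tempfactor = 80.0
        assert extract_plddt(model)[res.key] == 80.0

    def test_mean_fallback_without_ca(self, toy_complex):
        model = toy_complex.reference.copy()
        res = model.chains["H"][0]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        res.atoms[0].tempfactor = 70.0
        res.atoms[1].tempfactor = 74.0
        res.atoms[2].tempfactor = 72.0
        assert extract_plddt(model)[res.key] == pytest.approx(72.0)

    def test_all_zero_warns(self, toy_complex):
        model = toy_complex.reference.copy()
        for res in model.polymer_residues():
            for atom in res.atoms:
                atom.tempfactor = 0.0
        with pytest.warns(UserWarning, match="zero"):
            scores = extract_plddt(model)
        assert set(scores.values()) == {0.0}
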