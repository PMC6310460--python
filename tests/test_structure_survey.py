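import numpy as np
import pytest

from ntpchain.chain_model import InternalChainSpec
from ntpchain.structure_survey import (
    LigandAtlas,
    collect_overlay_sets,
    load_structure,
    measure_structure,
    records_table,
    screen_structure,
    superpose_ploops,
    survey_structures,
)
from ntpchain.synthetic_data import (
    FixtureStructureSpec,
    generate_fixture_structure,
)

from conftest import random_rotation


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    """A small panel of fixture structures with known ground truth."""
    root = tmp_path_factory.mktemp("fixtures")
    panel = {}
    specs = {
        "atp_k": FixtureStructureSpec(
            ligand_id="ATP",
            chain_spec=InternalChainSpec(theta_bridge=136.3, target_d_pa_pg=5.40),
            cation="K", cation_site="AG", cation_distance=2.7,
            lys_nz_distance=2.8),
        "gdp_alf_k": FixtureStructureSpec(
            ligand_id="GDP", mimic_id="ALF",
            chain_spec=InternalChainSpec(theta_bridge=136.3, target_d_pa_pg=5.40),
            cation="K", cation_site="AG", cation_distance=2.7,
            lys_nz_distance=2.8),
        "gnp_water": FixtureStructureSpec(
            ligand_id="GNP", water_at_ag=True, cation=None,
            chain_spec=InternalChainSpec(theta_bridge=129.2, target_d_pa_pg=5.1),
            cation_distance=3.0),
        "anp_k": FixtureStructureSpec(
            ligand_id="ANP", cation="K", cation_site="AG",
            chain_spec=InternalChainSpec(theta_bridge=124.5, target_d_pa_pg=5.1)),
        "atp_arg": FixtureStructureSpec(ligand_id="ATP", arg_at_ag=True),
        "adp_bare": FixtureStructureSpec(ligand_id="ADP"),
        "atp_no_mg": FixtureStructureSpec(ligand_id="ATP", include_mg=False),
        "atp_far_lys": FixtureStructureSpec(ligand_id="ATP",
                                            lys_nz_distance=10.0),
    }
    for name, spec in specs.items():
        path = root / f"{name}.pdb"
        panel[name] = (path, generate_fixture_structure(spec, path))
    return panel


class TestAtlas:
    def test_default_atlas_contents(self):
        atlas = LigandAtlas.default()
        for lid in ("ATP", "GTP", "ANP", "GNP", "ACP", "GCP", "GSP",
                    "ADP", "GDP"):
            assert lid in atlas.classes
        assert set(atlas.mimic_ids) == {"ALF", "AF3", "MGF", "BEF"}
        assert atlas.classes["ANP"] == "non_hydrolyzable"
        assert atlas.classes["ADP"] == "product"

    def test_substitution_mapping(self):
        atlas = LigandAtlas.default()
        coords, mimic, subs = atlas.map_atoms(
            "ANP", {"PA": np.zeros(3), "N3B": np.ones(3)})
        assert "O3B" in coords and "N3B" not in coords
        assert subs == ["N3B>O3B"]
        assert not mimic

    def test_mimic_mapping_flags(self):
        atlas = LigandAtlas.default()
        coords, mimic, _ = atlas.map_atoms(
            "ALF", {"AL": np.zeros(3), "F1": np.ones(3), "F2": np.ones(3),
                    "F3": np.ones(3), "F4": np.ones(3)})
        assert set(coords) == {"PG", "O1G", "O2G", "O3G", "F4"}
        assert all(mimic.values())

    def test_unknown_ligand(self):
        with pytest.raises(KeyError):
            LigandAtlas.default().map_atoms("XYZ", {})


class TestScreening:
    def test_complete_candidate(self, fixture_dir):
        path, truth = fixture_dir["atp_k"]
        cands, excl = screen_structure(path)
        assert len(cands) == 1 and not excl
        assert cands[0].analog_class == "substrate"
        assert cands[0].lys_contacts

    def test_far_lys_excluded(self, fixture_dir):
        path, _ = fixture_dir["atp_far_lys"]
        cands, excl = screen_structure(path)
        assert not cands
        assert len(excl) == 1 and "Lys" in excl[0]["reason"]

    def test_no_mg_excluded(self, fixture_dir):
        path, _ = fixture_dir["atp_no_mg"]
        cands, excl = screen_structure(path)
        assert not cands
        assert len(excl) == 1 and "Mg" in excl[0]["reason"]

    def test_transition_state_class(self, fixture_dir):
        path, _ = fixture_dir["gdp_alf_k"]
        cands, _ = screen_structure(path)
        assert len(cands) == 1
        assert cands[0].analog_class == "transition_state"
        assert cands[0].mimic_id == "ALF"
        assert cands[0].chain.is_complete

    def test_idempotent_and_exhaustive(self, fixture_dir):
        for name in ("atp_k", "atp_no_mg", "adp_bare"):
            path, _ = fixture_dir[name]
            c1, e1 = screen_structure(path)
            c2, e2 = screen_structure(path)
            assert len(c1) == len(c2) and e1 == e2
            # every non-candidate has exactly one reason
            sites = {c.label for c in c1}
            reasons = [e["ligand"] for e in e1]
            assert len(reasons) == len(set(reasons))

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            screen_structure(bad)


class TestMeasurement:
    def test_embed_oracle_round_trip(self, fixture_dir):
        path, truth = fixture_dir["atp_k"]
        cands, _ = screen_structure(path)
        rec = measure_structure(cands[0])
        want = truth["descriptors"]
        # PDB coordinates carry three decimals
        assert rec.descriptors.d_pa_pg == pytest.approx(want["d_pa_pg"], abs=5e-3)
        assert rec.descriptors.theta_bridge == pytest.approx(
            want["theta_bridge"], abs=0.1)
        assert rec.occupant == truth["expected_occupant"]
        assert rec.occupant_dist_alpha == pytest.approx(
            truth["occupant_dist_alpha"], abs=0.02)
        assert rec.occupant_dist_gamma == pytest.approx(
            truth["occupant_dist_gamma"], abs=0.02)

    def test_mimic_measurement_flagged(self, fixture_dir):
        path, truth = fixture_dir["gdp_alf_k"]
        cands, _ = screen_structure(path)
        rec = measure_structure(cands[0])
        assert rec.descriptors.mimic_derived
        assert rec.descriptors.d_pa_pg == pytest.approx(
            truth["descriptors"]["d_pa_pg"], abs=5e-3)
        assert rec.occupant == "K"

    def test_water_occupant(self, fixture_dir):
        path, truth = fixture_dir["gnp_water"]
        cands, _ = screen_structure(path)
        rec = measure_structure(cands[0])
        assert rec.occupant == "water"
        assert rec.substitutions == ["N3B>O3B"]

    def test_arg_occupant(self, fixture_dir):
        path, _ = fixture_dir["atp_arg"]
        rec = measure_structure(screen_structure(path)[0][0])
        assert rec.occupant == "ARG-N"

    def test_incomplete_ndp_record(self, fixture_dir):
        path, _ = fixture_dir["adp_bare"]
        cands, _ = screen_structure(path)
        assert len(cands) == 1 and not cands[0].complete
        rec = measure_structure(cands[0])
        assert rec.descriptors is None
        assert not rec.complete

    def test_survey_batch_and_table(self, fixture_dir):
        paths = [fixture_dir[n][0] for n in
                 ("atp_k", "gdp_alf_k", "anp_k", "atp_no_mg")]
        records, exclusions = survey_structures(paths)
        assert len(records) == 3
        assert len(exclusions) == 1
        table = records_table(records)
        assert set(table["analog_class"]) == {
            "substrate", "transition_state", "non_hydrolyzable"}

    def test_missing_file_logged(self, tmp_path):
        with pytest.warns(UserWarning):
            records, exclusions = survey_structures([tmp_path / "nope.pdb"])
        assert not records
        assert exclusions[0]["reason"] == "file not found"


class TestMmcif:
    def test_mmcif_round_trip(self, fixture_dir, tmp_path):
        from Bio.PDB.mmcifio import MMCIFIO

        path, truth = fixture_dir["atp_k"]
        structure = load_structure(path)
        io = MMCIFIO()
        io.set_structure(structure)
        cif_path = tmp_path / "atp_k.cif"
        io.save(str(cif_path))
        cands, _ = screen_structure(cif_path)
        assert len(cands) == 1
        rec = measure_structure(cands[0])
        assert rec.descriptors.d_pa_pg == pytest.approx(
            truth["descriptors"]["d_pa_pg"], abs=5e-3)


class TestSuperposition:
    def _ploop_structure(self, rng, jitter=0.0):
        # tiny helical stub as a Bio.PDB structure
        from Bio.PDB.Atom import Atom
        from Bio.PDB.Chain import Chain
        from Bio.PDB.Model import Model
        from Bio.PDB.Residue import Residue
        from Bio.PDB.Structure import Structure

        s = Structure("stub")
        m = Model(0)
        ch = Chain("A")
        for i in range(5):
            res = Residue((" ", 10 + i, " "), "GLY", "")
            base = np.array([1.5 * i, np.sin(i), np.cos(i)])
            for j, name in enumerate(("N", "CA", "C", "O")):
                pos = base + [0.3 * j, 0.2 * j, 0.1 * j]
                if jitter:
                    pos = pos + rng.standard_normal(3) * jitter
                res.add(Atom(name, pos.astype(np.float32), 1.0, 1.0, " ",
                             name, j + 1, name[0]))
            ch.add(res)
        m.add(ch)
        s.add(m)
        return s

    def test_self_superposition(self, rng):
        s = self._ploop_structure(rng)
        _, _, rmsd = superpose_ploops(s[0], s[0], ("A", 10, 14), ("A", 10, 14))
        assert rmsd < 1e-6

    def test_rotated_copy(self, rng):
        s = self._ploop_structure(rng)
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 8.0])
        mob = self._ploop_structure(rng)
        for atom in mob[0].get_atoms():
            atom.set_coord((R @ atom.get_coord() + t).astype(np.float32))
        _, _, rmsd = superpose_ploops(mob[0], s[0], ("A", 10, 14),
                                      ("A", 10, 14))
        assert rmsd < 1e-4  # float32 coordinate storage

    def test_mismatched_ranges(self, rng):
        s = self._ploop_structure(rng)
        with pytest.raises(ValueError, match="differ"):
            superpose_ploops(s[0], s[0], ("A", 10, 13), ("A", 10, 14))


class TestOverlays:
    def test_empty_records(self):
        assert collect_overlay_sets([]) == {}

    def test_class_split(self, fixture_dir):
        paths = [fixture_dir[n][0] for n in ("atp_k", "gdp_alf_k", "anp_k")]
        records, _ = survey_structures(paths)
        sets = collect_overlay_sets(records)
        assert len(sets["transition_state"]) == 1
        assert len(sets["non_hydrolyzable"]) == 1
        assert len(sets["substrate"]) == 1
        d, theta = sets["transition_state"][0]
        assert d == pytest.approx(5.40, abs=5e-3)
        assert theta == pytest.approx(136.3, abs=0.1)
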