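"""Structure I/O, numbering, solvent accessibility and superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
import biotite.structure as struc

from serpinmap import synthetic_data as sd
from serpinmap.structure_core import (
    StructureParseError,
    atom_sasa,
    compute_sasa,
    convert_numbering,
    kabsch_superpose,
    read_structure,
    surface_residues,
)


class TestReadStructure:
    def test_minimal_fixture(self, minimal_pdb):
        structure = read_structure(minimal_pdb)
        assert structure.n_residues == 2
        assert int(structure.ca_mask().sum()) == 2
        assert structure.residue_name(1) == "ALA"

    def test_duplicated_residue_index_rejected(self, duplicate_residue_pdb):
        with pytest.raises(StructureParseError, match="residue index 1"):
            read_structure(duplicate_residue_pdb)

    def test_generated_helix_roundtrip(self, helix, tmp_path):
        path = sd.write_structure_pdb(helix, tmp_path / "helix.pdb")
        again = read_structure(path)
        # PDB coordinate fields carry three decimals
        assert np.abs(helix.atoms.coord - again.atoms.coord).max() < 1e-3

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises((StructureParseError, ValueError)):
            read_structure(bad)


class TestNumbering:
    def test_trento_site_mature_to_precursor(self):
        # the helix-C variant site: mature 75 is precursor Glu99
        assert convert_numbering(75, "mature_to_precursor") == 99

    def test_precursor_to_mature_inverse(self):
        assert convert_numbering(99, "precursor_to_mature") == 75

    def test_z_site_offset(self):
        # the Z variant site E342K carries the same signal-peptide offset
        assert convert_numbering(342, "mature_to_precursor") == 366

    @given(st.integers(min_value=1, max_value=500))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_identity(self, index):
        forward = convert_numbering(index, "mature_to_precursor")
        assert convert_numbering(forward, "precursor_to_mature") == index

    def test_signal_peptide_range_rejected(self):
        with pytest.raises(ValueError):
            convert_numbering(10, "precursor_to_mature")
        with pytest.raises(ValueError):
            convert_numbering(0, "mature_to_precursor")


def _lone_atoms(coords, elements):
    atoms = struc.AtomArray(len(coords))
    atoms.coord = np.asarray(coords, dtype=float)
    atoms.atom_name = np.array([f"{e}{i+1}" for i, e in enumerate(elements)])
    atoms.element = np.array(elements)
    atoms.res_id = np.arange(1, len(coords) + 1)
    atoms.res_name = np.full(len(coords), "LIG")
    atoms.chain_id = np.full(len(coords), "A")
    return atoms


class TestSasa:
    def test_two_sphere_analytic_cap(self):
        """Shrake--Rupley area of two overlapping carbon spheres matches
        the closed-form spherical-cap solution within 2%."""
        d = 2.5
        atoms = _lone_atoms([[0, 0, 0], [d, 0, 0]], ["C", "C"])
        sampled = atom_sasa(atoms, probe_radius=1.4, n_points=5000)
        r = 1.70 + 1.4
        cap_height = r - d / 2
        expected = 4 * np.pi * r**2 - 2 * np.pi * r * cap_height
        assert sampled == pytest.approx(expected, rel=0.02)

    def test_isolated_residue_fully_exposed(self, minimal_pdb):
        structure = read_structure(minimal_pdb)
        single = structure.atoms[structure.atoms.res_id == 1]
        from serpinmap.structure_core import Structure

        profile = compute_sasa(Structure(atoms=single))
        assert profile.relative[0] == pytest.approx(1.0, abs=0.05)

    def test_enclosed_residue_fully_buried(self):
        """A residue inside a dense shell of dummy atoms scores 0."""
        core = [[0.0, 0.0, 0.0]]
        elements = ["C"]
        # icosahedral-ish shell at 4 Å, dense enough to exclude the probe
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(80):
            z = 1 - 2 * (i + 0.5) / 80
            radius = np.sqrt(1 - z * z)
            theta = golden * i
            core.append(
                [4 * radius * np.cos(theta), 4 * radius * np.sin(theta), 4 * z]
            )
            elements.append("C")
        atoms = _lone_atoms(core, elements)
        sampled = atom_sasa(atoms)
        assert sampled[0] == pytest.approx(0.0, abs=1e-6)

    def test_occlusion_never_increases_sasa(self, helix):
        base = compute_sasa(helix)
        occluded = sd.make_two_helix_bundle(n_per_helix=20)
        prof = compute_sasa(occluded)
        # helix A residues 1..20 are the same geometry, now facing helix B
        assert np.all(prof.relative[:20] <= base.relative + 0.02)

    def test_surface_threshold_semantics(self, helix):
        profile = compute_sasa(helix)
        assert surface_residues(profile, 0.0) == set(
            int(r) for r in helix.residue_ids
        )
        brute = {
            int(r)
            for r, v in zip(profile.residue_ids, profile.relative)
            if v >= 0.6
        }
        assert surface_residues(profile, 0.6) == brute

    def test_occluded_face_excluded(self):
        """In a two-helix bundle the buried faces score lower than the
        exposed faces, and thresholding keeps only the exposed set."""
        bundle = sd.make_two_helix_bundle(n_per_helix=20, separation=8.0)
        profile = compute_sasa(bundle)
        exposed = surface_residues(profile, 0.75)
        buried = set(int(r) for r in bundle.residue_ids) - exposed
        assert exposed and buried  # the threshold splits the faces


class TestKabsch:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        assert kabsch_superpose(coords, coords).rmsd == pytest.approx(0, abs=1e-10)

    def test_rigid_transform_invariance(self, rng):
        coords = rng.normal(size=(10, 3))
        for seed in range(5):
            rot = Rotation.random(random_state=seed).as_matrix()
            moved = coords @ rot.T + rng.normal(size=3)
            result = kabsch_superpose(coords, moved)
            assert result.rmsd <= 1e-8
            assert np.abs(result.apply(moved) - coords).max() <= 1e-7

    def test_rotation_is_proper(self, rng):
        a = rng.normal(size=(12, 3))
        b = -a  # a reflection of a generic set cannot be matched exactly
        result = kabsch_superpose(a, b)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        assert result.rmsd > 0

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-10
        )

    def test_monte_carlo_lower_bound(self, rng):
        """The closed form never loses to random-rotation search."""
        rotations = Rotation.random(1000, random_state=7).as_matrix()
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        da = a - a.mean(axis=0)
        db = b - b.mean(axis=0)
        sampled = np.einsum("rij,nj->rni", rotations, db)
        rmsds = np.sqrt(((sampled - da) ** 2).sum(axis=2).mean(axis=1))
        assert kabsch_superpose(a, b).rmsd <= rmsds.min() + 1e-9

    def test_input_validation(self, rng):
        a = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(a, a[:4])
        with pytest.raises(ValueError):
            kabsch_superpose(a[:2], a[:2])
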