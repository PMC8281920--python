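"""Topological feature vectors, image tensors and table assembly."""

import dataclasses

import numpy as np
import pytest

from aspholib.conjugation import CC
from aspholib.diagram_metrics import IDENTITY
from aspholib.features import (BOTTLENECK, DEFAULT_FEATURE_ROWS, IMAGE_ETAS,
                               IMAGE_KAPPAS, WASSERSTEIN, FeatureConfig,
                               all_feature_columns, asph_distance_feature,
                               assemble_feature_table, feature_names,
                               packing_density, ph_image,
                               topo_feature_vector)
from aspholib.filtration import EXPONENTIAL, KernelSpec
from aspholib.io_structures import Atom, ProteinStructure


def lone_calpha_structure(extra=()):
    atoms = [Atom(1, "CA", "C", np.zeros(3), 15.0, 1.0, "ALA", 1, "A")]
    atoms.extend(extra)
    return ProteinStructure("tiny", tuple(atoms), 2.0, 0.2)


class TestDistanceFeature:
    def test_isolated_calpha_costs_half_the_essential_bar(self):
        """Full diagram {[0, 1]}, reduced diagram empty: the unmatched
        essential class pays its diagonal distance, 0.5."""
        s = lone_calpha_structure()
        value = asph_distance_feature(
            s, s.atoms[0], CC, KernelSpec(EXPONENTIAL, 2.0, 1.0),
            transform=IDENTITY, metric=BOTTLENECK, dim=0)
        assert value == pytest.approx(0.5)

    def test_coincident_center_contributes_nothing(self):
        """A duplicate atom at the centre leaves only a zero-persistence
        interval when removed, so the conjugated distance is 0."""
        twin = Atom(2, "CB", "C", np.zeros(3), 15.0, 1.0, "ALA", 1, "A")
        far = Atom(3, "CG", "C", np.array([4.0, 0, 0]), 15.0, 1.0, "ALA", 2,
                   "A")
        s = lone_calpha_structure((twin, far))
        for metric in (BOTTLENECK, WASSERSTEIN):
            value = asph_distance_feature(
                s, s.atoms[0], CC, KernelSpec(EXPONENTIAL, 2.0, 1.0),
                metric=metric, dim=0)
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_non_negative_and_rigid_motion_invariant(self, structure, rng):
        from scipy.spatial.transform import Rotation
        calpha = structure.calphas[4]
        kernel = KernelSpec(EXPONENTIAL, 10.0, 1.0)
        value = asph_distance_feature(structure, calpha, CC, kernel,
                                      metric=WASSERSTEIN, dim=1)
        assert value >= 0.0
        rot = Rotation.random(random_state=5).as_matrix()
        moved = dataclasses.replace(structure, atoms=tuple(
            dataclasses.replace(a, coords=rot @ a.coords + 7.0)
            for a in structure.atoms))
        moved_value = asph_distance_feature(
            moved, moved.calphas[4], CC, kernel, metric=WASSERSTEIN, dim=1)
        assert moved_value == pytest.approx(value, abs=1e-9)


class TestFeatureVector:
    def test_default_configuration_yields_sixty_features(self, structure):
        vec = topo_feature_vector(structure, structure.calphas[0])
        assert vec.shape == (60,)
        assert np.all(vec >= 0)
        assert np.all(np.isfinite(vec))

    def test_each_row_contributes_twelve_features(self):
        names = feature_names()
        assert len(names) == 60
        for row in DEFAULT_FEATURE_ROWS:
            assert sum(1 for n in names if n.startswith(row.label)) == 12
        assert len(set(names)) == 60

    def test_atom_order_permutation_leaves_vector_unchanged(self, structure,
                                                            rng):
        calpha = structure.calphas[2]
        vec = topo_feature_vector(structure, calpha)
        perm = rng.permutation(len(structure.atoms))
        shuffled = dataclasses.replace(
            structure, atoms=tuple(structure.atoms[i] for i in perm))
        vec2 = topo_feature_vector(shuffled, calpha)
        np.testing.assert_allclose(vec, vec2, atol=1e-12)

    def test_scaling_coordinates_and_eta_together_is_neutral(self, structure):
        """Kernel features depend on d/eta only: doubling both every
        coordinate and eta leaves the vector unchanged."""
        scale = 2.0
        calpha = structure.calphas[1]
        rows = (dataclasses.replace(
            DEFAULT_FEATURE_ROWS[1],
            kernel=KernelSpec(EXPONENTIAL, 10.0, 1.0)),)
        config = FeatureConfig(rows=rows, cutoff=11.0)
        vec = topo_feature_vector(structure, calpha, config)
        scaled_structure = dataclasses.replace(structure, atoms=tuple(
            dataclasses.replace(a, coords=a.coords * scale)
            for a in structure.atoms))
        scaled_rows = (dataclasses.replace(
            rows[0], kernel=KernelSpec(EXPONENTIAL, 10.0 * scale, 1.0)),)
        scaled_config = FeatureConfig(rows=scaled_rows, cutoff=11.0 * scale)
        scaled_calpha = next(a for a in scaled_structure.calphas
                             if a.serial == calpha.serial)
        vec2 = topo_feature_vector(scaled_structure, scaled_calpha,
                                   scaled_config)
        np.testing.assert_allclose(vec, vec2, atol=1e-10)

    def test_locality_distant_atoms_are_invisible(self, structure):
        calpha = structure.calphas[0]
        vec = topo_feature_vector(structure, calpha)
        intruder = Atom(999, "CB", "C", calpha.coords + 50.0, 9.0, 1.0,
                        "GLY", 999, "A")
        augmented = dataclasses.replace(
            structure, atoms=structure.atoms + (intruder,))
        vec2 = topo_feature_vector(augmented, calpha)
        np.testing.assert_allclose(vec, vec2, atol=1e-12)


class TestImage:
    def test_shape_and_grid(self, structure):
        img = ph_image(structure, structure.calphas[3])
        assert img.shape == (8, 10, 3)
        assert np.all(img >= 0) and np.all(np.isfinite(img))
        assert IMAGE_ETAS == (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 20.0)
        assert IMAGE_KAPPAS == tuple(float(k) for k in range(1, 11))

    def test_cell_matches_single_feature_call(self, structure):
        calpha = structure.calphas[3]
        img = ph_image(structure, calpha, metric=WASSERSTEIN, dim=0)
        single = asph_distance_feature(
            structure, calpha, CC, KernelSpec(EXPONENTIAL, 10.0, 1.0),
            metric=WASSERSTEIN, dim=0)
        eta_row = IMAGE_ETAS.index(10.0)
        kappa_col = IMAGE_KAPPAS.index(1.0)
        assert img[eta_row, kappa_col, 0] == pytest.approx(single, abs=1e-12)


class TestPackingDensity:
    def test_isolated_calpha_has_zero_density(self):
        s = lone_calpha_structure()
        assert packing_density(s, s.atoms[0]) == 0

    def test_strict_cutoff(self):
        extras = tuple(
            Atom(k, "CB", "C", np.array([d, 0.0, 0.0]), 9.0, 1.0, "GLY", k,
                 "A")
            for k, d in [(2, 5.0), (3, 5.0), (4, 5.0), (5, 12.0)])
        s = lone_calpha_structure(extras)
        assert packing_density(s, s.atoms[0], cutoff=11.0) == 3


class TestTableAssembly:
    def test_one_row_per_calpha_no_missing_values(self, structure):
        table = assemble_feature_table([structure])
        assert len(table) == len(structure.calphas)
        for col in all_feature_columns():
            assert col in table.columns
            assert not table[col].isna().any()
        assert (table["bfactor"] > 0).all()
        # one-hot blocks sum to 1
        aa_cols = [c for c in table.columns if c.startswith("aa_")]
        ss_cols = [c for c in table.columns if c.startswith("ss_")]
        assert (table[aa_cols].sum(axis=1) == 1.0).all()
        assert (table[ss_cols].sum(axis=1) == 1.0).all()

    def test_identical_proteins_share_identical_topology_blocks(
            self, structure):
        clone = dataclasses.replace(structure, pdb_id="clone")
        table = assemble_feature_table([structure, clone])
        cols = feature_names()
        a = table[table.pdb_id == structure.pdb_id][cols].to_numpy()
        b = table[table.pdb_id == "clone"][cols].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_structures_without_headers_are_rejected(self, structure):
        bare = dataclasses.replace(structure, resolution=None)
        with pytest.raises(ValueError, match="resolution"):
            assemble_feature_table([bare])
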