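"""Voxel occupancy deposition, Gaussian blur, and full featurization."""

import numpy as np
import pytest
from scipy import ndimage

import voxbind as vb
from voxbind.pocket import Pocket
from voxbind.structure import Atom
from voxbind.voxelize import (
    BONDI_VDW_RADII, GridSpec, featurize_complex, gaussian_blur,
    voxelize_atoms,
)


def atom(coords, element="C", serial=1, hetero=False):
    return Atom(serial=serial, name=element, element=element, residue_name="A",
                residue_index=1, chain_id="A",
                coords=np.array(coords, float), is_hetero=hetero)


def pocket_of(rna_coords, lig_coords, elements=None, lig_elements=None):
    elements = elements or ["C"] * len(rna_coords)
    lig_elements = lig_elements or ["C"] * len(lig_coords)
    return Pocket(
        rna_atoms=[atom(c, e, i) for i, (c, e) in
                   enumerate(zip(rna_coords, elements))],
        ligand_atoms=[atom(c, e, 500 + i, hetero=True) for i, (c, e) in
                      enumerate(zip(lig_coords, lig_elements))],
        radius=10.0, center=np.zeros(3), centered=True,
    )


def lattice_count(position, radius, spec):
    """Brute-force count of in-box voxel centres within ``radius``."""
    centers = spec.voxel_centers_1d()
    xx, yy, zz = np.meshgrid(centers, centers, centers, indexing="ij")
    d2 = (xx - position[0]) ** 2 + (yy - position[1]) ** 2 + (zz - position[2]) ** 2
    return int(np.sum(d2 <= radius ** 2))


class TestVoxelize:
    def test_centered_carbon_fills_19_voxels(self):
        spec = GridSpec()
        g = voxelize_atoms(pocket_of([], [[0.0, 0.0, 0.0]]), spec)
        c_channel = g.values[..., spec.channels.index("C")]
        assert c_channel.sum() == 19  # integer lattice points with norm <= 1.70
        assert lattice_count([0, 0, 0], BONDI_VDW_RADII["C"], spec) == 19
        assert g.values.sum() == 19  # no other channel touched

    def test_atom_outside_box_contributes_nothing(self):
        spec = GridSpec()
        g = voxelize_atoms(pocket_of([[30.0, 0, 0]], [[0.0, 0, 0]]), spec)
        assert g.values.sum() == lattice_count([0, 0, 0], 1.70, spec)

    def test_out_of_vocabulary_element_skipped(self):
        spec = GridSpec()
        g = voxelize_atoms(
            pocket_of([], [[0.0, 0, 0]], lig_elements=["S"]), spec
        )
        assert g.values.sum() == 0

    def test_mass_matches_brute_force_on_random_fixture(self):
        spec = GridSpec()
        rng = np.random.default_rng(11)
        coords = rng.uniform(-15, 15, size=(50, 3))
        elements = rng.choice(["C", "N", "O", "P"], size=50)
        g = voxelize_atoms(pocket_of(coords[:40], coords[40:],
                                     elements=list(elements[:40]),
                                     lig_elements=list(elements[40:])), spec)
        expected = sum(
            lattice_count(c, BONDI_VDW_RADII[e], spec)
            for c, e in zip(coords, elements)
        )
        assert g.values.sum() == expected

    def test_uncentered_pocket_rejected(self):
        p = pocket_of([], [[0.0, 0, 0]])
        p.centered = False
        with pytest.raises(ValueError, match="centered"):
            voxelize_atoms(p, GridSpec())


class TestBlur:
    def test_central_delta_conserves_mass(self):
        spec = GridSpec()
        g = vb.VoxelGrid(np.zeros(spec.shape), spec)
        g.values[20, 20, 20, 0] = 1.0
        blurred = gaussian_blur(g, 1.0)
        assert blurred.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_sigma_zero_is_identity(self):
        spec = GridSpec()
        rng = np.random.default_rng(5)
        g = vb.VoxelGrid(rng.random(spec.shape), spec)
        np.testing.assert_array_equal(gaussian_blur(g, 0.0).values, g.values)

    def test_corner_delta_loses_exactly_out_of_box_kernel_mass(self):
        spec = GridSpec()
        g = vb.VoxelGrid(np.zeros(spec.shape), spec)
        g.values[0, 0, 0, 0] = 1.0
        blurred = gaussian_blur(g, 1.0)
        # direct kernel-sum oracle: separable normalized kernel, radius 4
        r = int(spec.blur_truncate * 1.0 + 0.5)
        k = np.exp(-0.5 * np.arange(-r, r + 1) ** 2)
        k /= k.sum()
        in_box = k[r:].sum()  # offsets 0..r stay inside from index 0
        assert blurred.values.sum() == pytest.approx(in_box ** 3, abs=1e-9)

    def test_zero_channel_stays_zero(self):
        spec = GridSpec()
        g = voxelize_atoms(pocket_of([], [[0.0, 0, 0]]), spec)
        blurred = gaussian_blur(g, 1.0)
        for c, el in enumerate(spec.channels):
            if el != "C":
                assert np.all(blurred.values[..., c] == 0)

    def test_negative_sigma_rejected(self):
        spec = GridSpec()
        g = vb.VoxelGrid(np.zeros(spec.shape), spec)
        with pytest.raises(ValueError):
            gaussian_blur(g, -1.0)


class TestRotationEquivariance:
    def test_quarter_turn_about_z(self):
        """Rotating coordinates 90 deg about z equals rotating the array."""
        spec = GridSpec()
        rng = np.random.default_rng(9)
        coords = rng.uniform(-12, 12, size=(20, 3))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        g = voxelize_atoms(pocket_of(coords[:15], coords[15:]), spec)
        g_rot = voxelize_atoms(
            pocket_of(coords[:15] @ R.T, coords[15:] @ R.T), spec
        )
        # for each channel, array rotation in the (x, y) plane
        expected = np.rot90(g.values, k=1, axes=(0, 1))
        np.testing.assert_array_equal(g_rot.values, expected)
        post = gaussian_blur(g_rot, 1.0).values
        post_expected = np.rot90(gaussian_blur(g, 1.0).values, k=1, axes=(0, 1))
        np.testing.assert_allclose(post, post_expected, atol=1e-6)


class TestFeaturize:
    def test_default_shape_41(self, synthetic_record):
        g = featurize_complex(synthetic_record.pair, 10.0, GridSpec())
        assert g.shape == (41, 41, 41, 8)
        assert np.all(g.values >= 0) and np.all(np.isfinite(g.values))

    def test_box_31_shape(self, synthetic_record):
        g = featurize_complex(synthetic_record.pair, 10.0,
                              GridSpec(box_size=31.0))
        assert g.shape == (31, 31, 31, 8)

    def test_empty_pocket_propagates(self):
        from voxbind.pocket import EmptyPocketError
        from tests.test_pocket import pair_from_coords

        pair = pair_from_coords([[50.0, 0, 0]], [[0.0, 0, 0]])
        with pytest.raises(EmptyPocketError):
            featurize_complex(pair, 10.0, GridSpec())


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        GridSpec(box_size=40.0)  # even voxel count
    with pytest.raises(ValueError):
        GridSpec(sigma=-0.5)
    with pytest.raises(ValueError):
        GridSpec(channels=("C", "Xx"))
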