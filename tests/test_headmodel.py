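import numpy as np
import pytest
from numpy.polynomial import legendre
from scipy.special import eval_legendre

import eegsel as es
from eegsel.headmodel import (
    DEFAULT_SHELL_CONDUCTIVITIES,
    DEFAULT_SHELL_RADII,
    InvalidGeometryError,
    LeadFieldFormatError,
    fibonacci_sphere,
    three_shell_radial_coeffs,
)


class TestThreeShellPotential:
    def test_homogeneous_limit_matches_closed_form(self):
        """Equal conductivities reduce to the classic single-sphere series
        V = sum (2l+1) beta^(l-1) P_l / (4 pi sigma) (up to the unit scale)."""
        sigma = 0.33
        c = three_shell_radial_coeffs(70.0, DEFAULT_SHELL_RADII, (sigma, sigma, sigma), 40)
        el = np.arange(1, 41)
        beta = 70.0 / DEFAULT_SHELL_RADII[2]
        ref = (2 * el + 1) * beta ** (el - 1) / (4 * np.pi * sigma)
        np.testing.assert_allclose(c[1:] / c[1], ref / ref[0], rtol=1e-12)

    def test_mirror_symmetric_electrodes_see_equal_potentials(self):
        """Two electrodes mirror-symmetric about a radial dipole's axis are at
        equal angular distance from it, hence equal potentials."""
        coeffs = three_shell_radial_coeffs(70.0, DEFAULT_SHELL_RADII, DEFAULT_SHELL_CONDUCTIVITIES, 80)
        r = DEFAULT_SHELL_RADII[2]
        dipole_axis = np.array([0.0, 0.0, 1.0])
        e1 = np.array([0.6, 0.0, 0.8])
        e2 = np.array([-0.6, 0.0, 0.8])
        v1 = legendre.legval(float(e1 @ dipole_axis), coeffs)
        v2 = legendre.legval(float(e2 @ dipole_axis), coeffs)
        assert abs(v1 - v2) < 1e-9

    def test_series_truncation_against_high_order_oracle(self):
        """A lead-field column agrees with an independent evaluation of the
        same analytic series truncated at 4x the default order."""
        lf = es.build_spherical_leadfield(24, 40, seed=3)
        coeffs = three_shell_radial_coeffs(70.0, DEFAULT_SHELL_RADII, DEFAULT_SHELL_CONDUCTIVITIES, 4 * 80)
        j = 7
        cosg = np.clip(
            (lf.channel_positions / DEFAULT_SHELL_RADII[2]) @ lf.source_orientations[j],
            -1.0,
            1.0,
        )
        # independent route: explicit per-degree Legendre polynomials
        oracle = sum(coeffs[el] * eval_legendre(el, cosg) for el in range(1, len(coeffs)))
        rel = np.linalg.norm(lf.matrix[:, j] - oracle) / np.linalg.norm(oracle)
        assert rel < 1e-6

    @pytest.mark.parametrize(
        "radii, sigmas",
        [((92, 86, 80), DEFAULT_SHELL_CONDUCTIVITIES), ((80, 80, 92), DEFAULT_SHELL_CONDUCTIVITIES), ((80, 86, 92), (0.33, -1.0, 0.33))],
    )
    def test_invalid_geometry_rejected(self, radii, sigmas):
        with pytest.raises(InvalidGeometryError):
            three_shell_radial_coeffs(70.0, radii, sigmas, 20)


class TestBuildSphericalLeadfield:
    def test_deterministic_for_fixed_seed(self):
        a = es.build_spherical_leadfield(16, 30, seed=5)
        b = es.build_spherical_leadfield(16, 30, seed=5)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.channel_positions, b.channel_positions)

    def test_different_seeds_rotate_layout(self):
        a = es.build_spherical_leadfield(16, 30, seed=5)
        b = es.build_spherical_leadfield(16, 30, seed=6)
        assert not np.array_equal(a.channel_positions, b.channel_positions)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            es.build_spherical_leadfield(1, 30)

    def test_geometry_invariants(self, small_leadfield):
        lf = small_leadfield
        assert len(set(lf.channel_labels)) == lf.n_channels
        np.testing.assert_allclose(np.linalg.norm(lf.source_orientations, axis=1), 1.0, atol=1e-9)
        assert np.linalg.norm(lf.channel_positions, axis=1).min() >= np.linalg.norm(lf.source_positions, axis=1).max()

    def test_fibonacci_lattice_is_quasi_uniform(self):
        pts = fibonacci_sphere(200, 1.0)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, rtol=1e-12)
        # nearest-neighbour spacing should be narrow around its median
        d2 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = d2.min(axis=1)
        assert nn.max() / nn.min() < 2.5


class TestLeadFieldValidation:
    def test_duplicate_labels_rejected(self, small_leadfield):
        lf = small_leadfield
        labels = list(lf.channel_labels)
        labels[1] = labels[0]
        with pytest.raises(ValueError, match="unique"):
            es.LeadField(lf.matrix, labels, lf.channel_positions, lf.source_positions, lf.source_orientations)

    def test_non_unit_orientations_rejected(self, small_leadfield):
        lf = small_leadfield
        with pytest.raises(ValueError, match="unit"):
            es.LeadField(lf.matrix, lf.channel_labels, lf.channel_positions, lf.source_positions, 2.0 * lf.source_orientations)

    def test_channel_inside_source_sphere_rejected(self, small_leadfield):
        lf = small_leadfield
        pos = lf.channel_positions.copy()
        pos[0] = [0.0, 0.0, 1.0]
        with pytest.raises(ValueError, match="bounding sphere"):
            es.LeadField(lf.matrix, lf.channel_labels, pos, lf.source_positions, lf.source_orientations)


class TestArchiveIO:
    def test_round_trip(self, tmp_path, small_leadfield):
        path = tmp_path / "lf.h5"
        es.save_leadfield(small_leadfield, path)
        lf = es.load_leadfield(path)
        assert np.array_equal(lf.matrix, small_leadfield.matrix)
        assert lf.channel_labels == small_leadfield.channel_labels
        assert np.array_equal(lf.source_positions, small_leadfield.source_positions)

    def test_missing_source_positions_named_in_error(self, tmp_path, small_leadfield):
        import h5py

        path = tmp_path / "bad.h5"
        es.save_leadfield(small_leadfield, path)
        with h5py.File(path, "a") as f:
            del f["srcpos"]
        with pytest.raises(LeadFieldFormatError, match="srcpos"):
            es.load_leadfield(path)

    def test_resolution_groups(self, tmp_path, small_leadfield):
        import h5py

        path = tmp_path / "multi.h5"
        with h5py.File(path, "w") as f:
            for group in ("high", "inverse"):
                g = f.create_group(group)
                g.create_dataset("M", data=small_leadfield.matrix)
                g.create_dataset("chanlocs", data=small_leadfield.channel_positions)
                g.create_dataset("chanlabels", data=np.array(small_leadfield.channel_labels, dtype=h5py.string_dtype()))
                g.create_dataset("srcpos", data=small_leadfield.source_positions)
                g.create_dataset("srcori", data=small_leadfield.source_orientations)
        lf = es.load_leadfield(path, resolution="inverse")
        assert lf.n_sources == small_leadfield.n_sources

    def test_free_orientation_collapse(self, tmp_path, small_leadfield):
        """A (d, n, 3) free-orientation matrix is projected onto the fixed
        orientations at load time."""
        import h5py

        lf = small_leadfield
        free = np.einsum("dn,nk->dnk", lf.matrix, lf.source_orientations)
        path = tmp_path / "free.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("M", data=free)
            f.create_dataset("chanlocs", data=lf.channel_positions)
            f.create_dataset("chanlabels", data=np.array(lf.channel_labels, dtype=h5py.string_dtype()))
            f.create_dataset("srcpos", data=lf.source_positions)
            f.create_dataset("srcori", data=lf.source_orientations)
        loaded = es.load_leadfield(path)
        np.testing.assert_allclose(loaded.matrix, lf.matrix, atol=1e-12)


class TestMontageMask:
    def test_full_mask(self, small_leadfield):
        mask = es.make_montage_mask(small_leadfield, "full")
        assert mask.included.all() and mask.n_included == small_leadfield.n_channels

    def test_explicit_label_list(self, small_leadfield):
        labels = small_leadfield.channel_labels[:5]
        mask = es.make_montage_mask(small_leadfield, labels)
        assert mask.n_included == 5
        assert mask.included[:5].all() and not mask.included[5:].any()

    def test_unknown_label_listed_in_error(self, small_leadfield):
        with pytest.raises(KeyError, match="Zz9"):
            es.make_montage_mask(small_leadfield, ["E001", "Zz9"])

    def test_packaged_submontages_on_default_fixture(self):
        lf = es.build_spherical_leadfield(231, 40, seed=0)
        assert es.make_montage_mask(lf, "sub128").n_included == 128
        assert es.make_montage_mask(lf, "sub60").n_included == 60

    def test_mask_never_resizes_leadfield(self, small_leadfield):
        mask = es.make_montage_mask(small_leadfield, small_leadfield.channel_labels[:4])
        assert mask.included.size == small_leadfield.n_channels
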