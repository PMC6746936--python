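"""Meshing and material chain: thickness, densities, modulus law, binning."""

import math

import numpy as np
import pytest

from dxafem.materials import (
    MorganLaw,
    abmd_to_volumetric,
    bin_moduli,
    build_material_field,
    morgan_modulus,
    plate_thickness,
    volumetric_to_apparent,
)
from dxafem.meshing import build_mesh, nearest_pixel
from dxafem.phantom import generate_femur_image


class TestThickness:
    def test_area_match_closed_form(self):
        assert plate_thickness(32.0, "area") == pytest.approx(math.pi * 32 / 4)

    def test_inertia_match_closed_form(self):
        assert plate_thickness(32.0, "inertia") == pytest.approx(3 * math.pi * 32 / 16)

    def test_mean_is_average(self):
        assert plate_thickness(32.0, "mean") == pytest.approx(
            0.5 * (plate_thickness(32.0, "area") + plate_thickness(32.0, "inertia"))
        )

    def test_degenerate_width(self):
        with pytest.raises(ValueError):
            plate_thickness(0.0)


class TestMesh:
    def test_square_mask_structured_grid(self):
        mesh = build_mesh(np.ones((20, 20), bool), 0.5, 0.5, thickness_t=1.0)
        assert mesh.n_elements == 400
        assert mesh.n_nodes == 441
        assert mesh.area() == pytest.approx(100.0)

    def test_phantom_mesh_area_matches_pixel_count(self):
        image, masks, _ = generate_femur_image(seed=1)
        mesh = build_mesh(masks["femur"], image.spacing_mm, 0.5, thickness_t=10.0)
        mask_area = masks["femur"].sum() * image.spacing_mm**2
        assert mesh.area() == pytest.approx(mask_area, rel=0.02)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ValueError, match="2 connected components"):
            build_mesh(mask, 0.5, 0.5, thickness_t=1.0)

    def test_element_centroids_map_to_source_pixels(self):
        """Each element centroid lies within half a pixel diagonal of the
        center of the pixel it takes its gray value from."""
        image, masks, _ = generate_femur_image(seed=1)
        h = image.spacing_mm
        mesh = build_mesh(masks["femur"], h, h, thickness_t=10.0)
        pix = nearest_pixel(mesh.element_centroids(), h, masks["femur"].shape)
        n_rows = masks["femur"].shape[0]
        centers = np.stack(
            [(pix[:, 1] + 0.5) * h, (n_rows - pix[:, 0] - 0.5) * h], axis=1
        )
        dist = np.linalg.norm(mesh.element_centroids() - centers, axis=1)
        assert dist.max() <= h * math.sqrt(2) / 2 + 1e-12
        assert np.all(masks["femur"][pix[:, 0], pix[:, 1]])


class TestDensityChain:
    def test_areal_to_volumetric(self):
        assert abmd_to_volumetric(0.8, 20.0) == pytest.approx(0.4)
        assert abmd_to_volumetric(0.0, 20.0) == 0.0
        assert abmd_to_volumetric(1.2, 18.850) == pytest.approx(0.6366, abs=5e-4)

    def test_volumetric_to_apparent(self):
        assert volumetric_to_apparent(0.4, 0.6) == pytest.approx(0.4 / 0.6)
        assert volumetric_to_apparent(0.7, 1.0) == pytest.approx(0.7)
        assert volumetric_to_apparent(0.0) == 0.0

    def test_monotone_end_to_end(self):
        """Higher gray (hence aBMD) never yields a lower raw modulus."""
        abmd = np.linspace(0.0, 2.0, 200)
        rho = volumetric_to_apparent(abmd_to_volumetric(abmd, 20.0))
        e = morgan_modulus(rho)
        assert np.all(np.diff(e) >= 0)


class TestMorgan:
    def test_unit_density_high_branch(self):
        assert morgan_modulus(1.0) == pytest.approx(6850.0)

    @pytest.mark.parametrize(
        "rho", [0.20, 0.28, 1.0, 0.05, 0.5, 1.8]
    )
    def test_against_direct_power_law_evaluation(self, rho):
        law = MorganLaw()
        expected = (
            law.c_low * rho**law.p_low
            if rho <= law.rho_switch
            else law.c_high * rho**law.p_high
        )
        assert morgan_modulus(rho) == pytest.approx(expected, rel=1e-12)

    def test_low_branch_applies_at_switch_boundary(self):
        law = MorganLaw()
        assert morgan_modulus(0.28) == pytest.approx(15010.0 * 0.28**2.18, rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            morgan_modulus(-0.1)


class TestBinning:
    def test_constant_field_unchanged(self):
        field = bin_moduli(np.full(10, 1234.0))
        np.testing.assert_array_equal(field.e_mpa, 1234.0)
        assert field.n_distinct == 1

    def test_singleton_bins_preserve_values(self):
        e = np.arange(100.0, 3600.0, 100.0)  # 35 values, one per bin
        field = bin_moduli(e, n_bins=35)
        np.testing.assert_allclose(field.e_mpa, e)

    def test_hand_binning_with_median(self):
        field = bin_moduli(np.array([100.0, 110.0, 3500.0]), n_bins=35)
        np.testing.assert_allclose(field.e_mpa, [105.0, 105.0, 3500.0])
        assert field.bin_id[0] == field.bin_id[1] == 1
        assert field.bin_id[2] == 35

    def test_bin_count_and_width_bound_on_phantom(self):
        """<= 35 distinct values; binning moves E by at most one bin width."""
        image, masks, truth = generate_femur_image(seed=2)
        fg = masks["femur"]
        field = build_material_field(truth.true_bmd_map[fg], 20.0)
        assert field.n_distinct <= 35
        width = (field.e_raw_mpa.max() - field.e_raw_mpa.min()) / 35
        assert np.abs(field.e_mpa - field.e_raw_mpa).max() <= width + 1e-9
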