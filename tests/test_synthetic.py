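"""Generator contracts: determinism, ground-truth fidelity, geometry."""

import numpy as np
import pytest

from spheroquant import (SectionSpec, generate_brightfield_spheroid,
                         generate_fluorescence_section, generate_stained_section)


@pytest.mark.parametrize("generator", [generate_fluorescence_section,
                                       generate_stained_section,
                                       generate_brightfield_spheroid])
def test_seeded_determinism(generator):
    """Identical specs render bit-identical images and ground truth."""
    a_img, a_gt = generator(SectionSpec(seed=7, image_size=(256, 256), radius=100.0))
    b_img, b_gt = generator(SectionSpec(seed=7, image_size=(256, 256), radius=100.0))
    assert np.array_equal(a_img.pixels, b_img.pixels)
    assert np.array_equal(a_gt.mask, b_gt.mask)
    assert a_gt.equivalent_diameter == b_gt.equivalent_diameter


def test_different_seeds_differ():
    a, _ = generate_fluorescence_section(SectionSpec(seed=1, image_size=(256, 256),
                                                     radius=100.0))
    b, _ = generate_fluorescence_section(SectionSpec(seed=2, image_size=(256, 256),
                                                     radius=100.0))
    assert not np.array_equal(a.pixels, b.pixels)


class TestFluorescence:
    def test_uniform_density_flat(self):
        """Uniform label mode gives a near-flat realized radial density."""
        spec = SectionSpec(seed=5, label_mode="uniform", n_clusters=500,
                           noise_sigma=0.0)
        _, gt = generate_fluorescence_section(spec)
        d = gt.rim_density
        assert d.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.max() / d.min() <= 1.5

    def test_central_support(self):
        """Central mode confines all label mass to the inner fifth."""
        spec = SectionSpec(seed=5, label_mode="central", n_clusters=300,
                           noise_sigma=0.0)
        _, gt = generate_fluorescence_section(spec)
        assert gt.rim_density[:10].sum() == pytest.approx(1.0, abs=1e-9)

    def test_peripheral_support(self):
        spec = SectionSpec(seed=5, label_mode="peripheral", n_clusters=300,
                           noise_sigma=0.0)
        _, gt = generate_fluorescence_section(spec)
        assert gt.rim_density[40:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_cluster_centers_inside_mask(self):
        spec = SectionSpec(seed=3, boundary_irregularity=0.2, n_clusters=200)
        _, gt = generate_fluorescence_section(spec)
        rows = np.clip(np.rint(gt.cluster_centers[:, 0]).astype(int), 0,
                       gt.mask.shape[0] - 1)
        cols = np.clip(np.rint(gt.cluster_centers[:, 1]).astype(int), 0,
                       gt.mask.shape[1] - 1)
        assert gt.mask[rows, cols].all()
        assert (gt.cluster_centers[:, 2] <= 1.0).all()

    def test_structure_confined_to_mask(self):
        """Outside the section only noise remains (zero at sigma = 0)."""
        spec = SectionSpec(seed=4, noise_sigma=0.0, n_clusters=300)
        img, gt = generate_fluorescence_section(spec)
        assert img.pixels[~gt.mask].max() == 0

    def test_rejects_zero_clusters_with_nonzero_density(self):
        with pytest.raises(ValueError, match="n_clusters"):
            generate_fluorescence_section(SectionSpec(seed=0, n_clusters=0))

    def test_custom_zero_density_gives_blank_section(self):
        spec = SectionSpec(seed=0, label_mode="custom",
                           label_density=np.zeros(50), n_clusters=0,
                           noise_sigma=0.0)
        img, gt = generate_fluorescence_section(spec)
        assert gt.rim_density.sum() == 0
        # only the autofluorescence baseline remains
        assert img.pixels[gt.mask].std() == 0


class TestStained:
    def test_no_fibers_at_zero_fraction(self):
        spec = SectionSpec(seed=2, collagen_fraction=0.0, noise_sigma=0.0)
        img, gt = generate_stained_section(spec)
        assert gt.collagen_pixel_fraction == 0.0
        g = img.pixels[..., 1][gt.mask]
        # no section pixel drops below the cytoplasm green baseline
        assert g.min() >= g.max() - 1  # quantization only

    def test_realized_fraction_near_target(self):
        spec = SectionSpec(seed=2, collagen_fraction=0.2, noise_sigma=0.0)
        _, gt = generate_stained_section(spec)
        assert gt.collagen_pixel_fraction == pytest.approx(0.2, abs=0.02)

    def test_fraction_monotone(self):
        fracs = []
        for f in (0.1, 0.3):
            spec = SectionSpec(seed=2, collagen_fraction=f)
            _, gt = generate_stained_section(spec)
            fracs.append(gt.collagen_pixel_fraction)
        assert fracs[0] < fracs[1]

    def test_fiber_color_red_on_yellow(self):
        spec = SectionSpec(seed=2, collagen_fraction=0.2, noise_sigma=0.0)
        img, gt = generate_stained_section(spec)
        r, g, b = (img.pixels[..., c].astype(float) for c in range(3))
        fiber_px = gt.mask & (g < 100)
        assert fiber_px.any()
        assert (r[fiber_px] > 150).all()  # fibers: high R, low G


class TestBrightfield:
    def test_disk_diameter(self):
        spec = SectionSpec(seed=1, radius=100.0, image_size=(256, 256),
                           boundary_irregularity=0.0)
        _, gt = generate_brightfield_spheroid(spec)
        assert gt.equivalent_diameter == pytest.approx(200.0, rel=0.01)

    def test_diameter_scales_with_pixel_size(self):
        a = SectionSpec(seed=1, radius=100.0, image_size=(256, 256), pixel_size=1.0)
        b = SectionSpec(seed=1, radius=100.0, image_size=(256, 256), pixel_size=2.0)
        _, gta = generate_brightfield_spheroid(a)
        _, gtb = generate_brightfield_spheroid(b)
        assert np.array_equal(gta.mask, gtb.mask)
        assert gtb.equivalent_diameter == pytest.approx(2 * gta.equivalent_diameter)

    def test_irregular_boundary_area(self):
        """Mild boundary perturbation keeps the area near the disk's."""
        spec = SectionSpec(seed=6, radius=100.0, image_size=(300, 300),
                           boundary_irregularity=0.1)
        _, gt = generate_brightfield_spheroid(spec)
        assert gt.mask.sum() == pytest.approx(np.pi * 100**2, rel=0.15)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(radius=200.0, image_size=(256, 256)),       # does not fit
        dict(collagen_fraction=1.5),
        dict(necrotic_core_fraction=1.0),
        dict(label_mode="sideways"),
        dict(label_mode="custom", label_density=np.ones(10)),
        dict(label_mode="custom", label_density=-np.ones(50)),
        dict(boundary_irregularity=0.5),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SectionSpec(seed=0, **kwargs).validate()

    def test_default_size_in_emulated_range(self):
        spec = SectionSpec()
        diameter = 2 * spec.radius * spec.pixel_size
        assert 170 <= diameter <= 830
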