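"""Concentric-rim decomposition and radial profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheroquant import (CentroidOutsideMask, IntensityImage, SectionSpec,
                         SpheroidMask, aggregate_profiles, compare_profiles,
                         compute_rims, generate_fluorescence_section,
                         radial_profile, welch_ttest)
from spheroquant.radial import AllZeroProfileWarning

from _oracles import circular_labels, rim_means_bruteforce, star_convex_labels


class TestComputeRims:
    @pytest.mark.parametrize("mode", ["star_convex", "circular", "edt"])
    def test_center_and_boundary_rims(self, disk_mask, mode):
        """Centroid pixel lands in rim 1, boundary contour in rim 50."""
        rm = compute_rims(disk_mask, 50, mode)
        cy, cx = (int(round(c)) for c in disk_mask.centroid)
        assert rm.labels[cy, cx] == 1
        boundary = np.rint(disk_mask.boundary).astype(int)
        labs = rm.labels[boundary[:, 0], boundary[:, 1]]
        labs = labs[labs > 0]
        assert np.median(labs) >= 49

    def test_all_inmask_pixels_labeled(self, disk_mask):
        rm = compute_rims(disk_mask, 50)
        assert (rm.labels[disk_mask.mask] >= 1).all()
        assert (rm.labels[disk_mask.mask] <= 50).all()
        assert (rm.labels[~disk_mask.mask] == 0).all()

    @pytest.mark.parametrize("mode,oracle", [("star_convex", star_convex_labels),
                                             ("circular", circular_labels)])
    def test_matches_bruteforce_oracle_exactly(self, mode, oracle):
        """Vectorized rim labels equal the scalar per-pixel oracle bit for bit."""
        for seed in range(3):
            spec = SectionSpec(seed=900 + seed, image_size=(96, 96), radius=32.0,
                               boundary_irregularity=0.2)
            from spheroquant import generate_brightfield_spheroid
            _, gt = generate_brightfield_spheroid(spec)
            mask = SpheroidMask(gt.mask)
            got = compute_rims(mask, 50, mode).labels
            want = oracle(mask.mask, mask.centroid, 50)
            assert np.array_equal(got, want)

    def test_modes_consistent_on_disk(self, disk_mask):
        """On a perfect disk the three geometries agree to within one rim
        almost everywhere (bin edges are sub-pixel, so exact-bin
        disagreement at edges is expected quantization)."""
        labs = {mode: compute_rims(disk_mask, 50, mode).labels
                for mode in ("star_convex", "circular", "edt")}
        m = disk_mask.mask
        for a in ("circular", "edt"):
            diff = np.abs(labs["star_convex"][m] - labs[a][m])
            assert (diff <= 1).mean() >= 0.99
            assert (diff == 0).mean() >= 0.75

    def test_rim_areas_increase_on_disk(self):
        """Annulus area grows like 2i-1, so pixel counts strictly increase
        with rim index (rims a few px wide, so quantization cannot mask it)."""
        yy, xx = np.mgrid[:441, :441]
        mask = SpheroidMask((yy - 220) ** 2 + (xx - 220) ** 2 <= 200**2)
        rm = compute_rims(mask, 50, "circular")
        counts = np.bincount(rm.labels[mask.mask], minlength=51)[1:]
        assert (np.diff(counts) > 0).all()
        assert counts[-1] > 10 * counts[0]

    def test_centroid_outside_mask_raises(self):
        yy, xx = np.mgrid[:101, :101]
        ring = ((yy - 50) ** 2 + (xx - 50) ** 2 <= 45**2) & \
               ((yy - 50) ** 2 + (xx - 50) ** 2 >= 30**2)
        with pytest.raises(CentroidOutsideMask):
            compute_rims(SpheroidMask(ring), 50, "star_convex")
        rm = compute_rims(SpheroidMask(ring), 50, "edt")  # edt handles it
        assert (rm.labels[ring] >= 1).all()

    def test_n_rims_validation(self, disk_mask):
        with pytest.raises(ValueError):
            compute_rims(disk_mask, 1)


class TestRadialProfile:
    def test_uniform_disk_profile(self, disk_mask):
        """Constant intensity: every rim mean is c and every p_i = 0.02."""
        img = np.where(disk_mask.mask, 37.0, 0.0)
        rm = compute_rims(disk_mask, 50)
        prof = radial_profile(img, rm)
        assert np.allclose(prof.rim_means, 37.0)
        assert np.allclose(prof.normalized, 0.02)
        assert prof.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_outer_ring_only(self, disk_mask):
        rm = compute_rims(disk_mask, 50)
        img = np.where(rm.labels == 50, 1.0, 0.0)
        prof = radial_profile(img, rm)
        assert prof.normalized[49] == pytest.approx(1.0, abs=1e-12)
        assert np.all(prof.normalized[:49] == 0)

    def test_gradient_matches_bruteforce(self, small_disk_mask):
        """I(r) = r on a disk: rim means match scalar accumulation exactly
        and are within 2% of the ideal mid-bin value."""
        rm = compute_rims(small_disk_mask, 10, "circular")
        cy, cx = small_disk_mask.centroid
        yy, xx = np.mgrid[:64, :64]
        r_eq = np.sqrt(small_disk_mask.area / np.pi)
        img = np.hypot(yy - cy, xx - cx) / r_eq
        prof = radial_profile(img, rm)
        want = rim_means_bruteforce(img, rm.labels, 10)
        assert np.allclose(prof.rim_means, want, rtol=1e-12)

    def test_all_zero_profile_warns(self, disk_mask):
        rm = compute_rims(disk_mask, 50)
        with pytest.warns(AllZeroProfileWarning):
            prof = radial_profile(np.zeros(rm.shape), rm)
        assert prof.normalized is None

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_sums_to_one(self, seed):
        """Any nonnegative image with signal yields a sum-to-one profile."""
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[:64, :64]
        mask = SpheroidMask((yy - 32) ** 2 + (xx - 32) ** 2 <= 25**2)
        img = rng.uniform(0.1, 200.0, (64, 64))
        prof = radial_profile(img, compute_rims(mask, 50, "circular"))
        assert prof.normalized.sum() == pytest.approx(1.0, abs=1e-9)
        assert (prof.normalized >= 0).all()

    def test_rotation_invariance(self):
        """Rotating a synthetic section by 90 degrees leaves the profile
        essentially unchanged."""
        spec = SectionSpec(seed=21, label_mode="uniform", n_clusters=400,
                           noise_sigma=0.0, image_size=(401, 401), radius=170.0)
        img, gt = generate_fluorescence_section(spec)
        p0 = radial_profile(img, compute_rims(SpheroidMask(gt.mask), 50))
        rot_img = np.rot90(img.pixels).copy()
        rot_mask = np.rot90(gt.mask).copy()
        p1 = radial_profile(rot_img, compute_rims(SpheroidMask(rot_mask), 50))
        assert np.abs(p0.normalized - p1.normalized).max() <= 0.005


class TestProfileRecovery:
    def test_custom_density_recovered(self):
        """Radial-mass profile of a noise-free section recovers the
        requested 50-bin density to within 0.03 at 1000 clusters."""
        i = np.arange(50)
        density = 0.5 + 1.5 * (i + 0.5) / 50
        density /= density.sum()
        spec = SectionSpec(seed=11, label_mode="custom", label_density=density,
                           n_clusters=1000, noise_sigma=0.0)
        img, gt = generate_fluorescence_section(spec)
        rm = compute_rims(SpheroidMask(gt.mask), 50)
        prof = radial_profile(img, rm)
        assert np.abs(prof.mass_fraction - density).max() <= 0.03
        assert np.abs(prof.mass_fraction - gt.rim_density).max() <= 0.03


class TestGroupsAndComparison:
    def _profiles(self, values):
        from spheroquant import RadialProfile
        return [RadialProfile(rim_means=np.asarray(v, dtype=float),
                              n_pixels_per_rim=np.ones(len(v), dtype=int))
                for v in values]

    def test_identical_profiles_aggregate(self):
        profs = self._profiles([[1.0, 2.0, 3.0, 4.0]] * 4)
        grp = aggregate_profiles(profs)
        assert np.allclose(grp.mean, np.array([1, 2, 3, 4]) / 10)
        assert np.allclose(grp.sd, 0.0)

    def test_hand_computed_mean(self):
        profs = self._profiles([[1.0, 3.0], [3.0, 1.0]])
        grp = aggregate_profiles(profs)
        assert np.allclose(grp.mean, [0.5, 0.5])

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles(self._profiles([[1.0, 2.0]]))

    def test_mixed_rim_counts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_profiles(self._profiles([[1.0, 2.0], [1.0, 2.0, 3.0]]))

    def test_identical_groups_no_significance(self):
        rng = np.random.default_rng(0)
        profs = self._profiles(rng.uniform(1, 5, (6, 50)))
        grp = aggregate_profiles(profs)
        cmp_ = compare_profiles(grp, grp)
        assert cmp_.table["significant"].sum() == 0
        assert np.allclose(cmp_.table["t"], 0.0)
        assert np.allclose(cmp_.table["p_raw"], 1.0)
        assert (cmp_.table["p_holm"] >= cmp_.table["p_raw"]).all()

    def test_per_rim_matches_welch(self):
        """Rim-wise t and p delegate to the Welch test on the same values."""
        rng = np.random.default_rng(1)
        a = aggregate_profiles(self._profiles(rng.uniform(1, 5, (5, 8))))
        b = aggregate_profiles(self._profiles(rng.uniform(2, 6, (5, 8))))
        cmp_ = compare_profiles(a, b)
        for i in range(8):
            res = welch_ttest(a.values[:, i], b.values[:, i])
            assert cmp_.table.loc[i, "t"] == pytest.approx(res.statistic)
            assert cmp_.table.loc[i, "p_raw"] == pytest.approx(res.p_value)
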