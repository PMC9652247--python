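"""Synthetic phantom generator: determinism, geometry, contrasts, round trips."""

import numpy as np
import pytest

from swefuse.phantom import (PhantomParams, compose_screenshot, crop_box,
                             generate_dataset, generate_phantom_pair,
                             load_dataset, save_dataset)


def _gray3(us):
    return np.repeat(us[:, :, None], 3, axis=2)


class TestPairGeneration:
    def test_deterministic_under_fixed_seed(self, small_params):
        a = generate_phantom_pair(small_params, label=1, seed=7)
        b = generate_phantom_pair(small_params, label=1, seed=7)
        assert np.array_equal(a.us_image, b.us_image)
        assert np.array_equal(a.swe_image, b.swe_image)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)
        assert a.roi_box == b.roi_box

    @pytest.mark.parametrize("label", [0, 1])
    def test_zero_irregularity_gives_ellipse(self, small_params, label):
        params = small_params.with_(malignant_irregularity=0.0,
                                    benign_irregularity=0.0)
        pair = generate_phantom_pair(params, label=label, seed=3)
        mask = pair.lesion_mask
        # boundary radial variance of a discretized ellipse is ~0: recover the
        # implicit ellipse equation from mask moments and check the boundary
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        # all boundary pixels should sit at normalized radius ~1
        from scipy.ndimage import binary_erosion
        boundary = mask & ~binary_erosion(mask)
        by, bx = np.nonzero(boundary)
        d = np.stack([by - cy, bx - cx])
        cov = np.cov(np.stack([ys - cy, xs - cx]))
        rho = np.sqrt(np.einsum("ij,jk,ik->i", d.T, np.linalg.inv(4 * cov), d.T))
        assert np.std(rho) < 0.06

    def test_swe_equals_us_outside_roi_exactly(self, one_pair):
        outside = np.ones(one_pair.us_image.shape, bool)
        r0, c0, r1, c1 = one_pair.roi_box
        outside[r0:r1, c0:c1] = False
        assert np.array_equal(one_pair.swe_image[outside],
                              _gray3(one_pair.us_image)[outside])
        # and inside the ROI the color map actually changed something
        assert not np.array_equal(one_pair.swe_image[~outside],
                                  _gray3(one_pair.us_image)[~outside])

    def test_roi_contains_lesion_and_lies_in_bounds(self, small_params):
        for seed in range(5):
            pair = generate_phantom_pair(small_params, label=seed % 2, seed=seed)
            r0, c0, r1, c1 = pair.roi_box
            h, w = pair.us_image.shape
            assert 0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w
            ys, xs = np.nonzero(pair.lesion_mask)
            assert r0 <= ys.min() and ys.max() < r1
            assert c0 <= xs.min() and xs.max() < c1

    def test_oversized_lesion_raises(self, small_params):
        params = small_params.with_(lesion_radius_range=(80.0, 90.0))
        with pytest.raises(ValueError, match="fit"):
            generate_phantom_pair(params, label=1, seed=0)

    def test_stiffness_contrast_matches_configuration(self, small_params):
        """Monte-Carlo: rendered lesion stiffness recovers the configured
        malignant-benign mean difference within 3 SE over 50 pairs each."""
        m = {lab: [] for lab in (0, 1)}
        for lab in (0, 1):
            for seed in range(50):
                pair = generate_phantom_pair(small_params, lab, seed=1000 * lab + seed)
                m[lab].append(float(pair.stiffness_field[pair.lesion_mask].mean()))
        diff = np.mean(m[1]) - np.mean(m[0])
        se = np.sqrt(np.var(m[1], ddof=1) / 50 + np.var(m[0], ddof=1) / 50)
        expected = (small_params.stiffness_malignant_mean
                    - small_params.stiffness_benign_mean)
        assert diff > 0
        assert abs(diff - expected) < 3 * se + 1e-9

    def test_malignant_boundary_more_irregular(self, small_params):
        """The configured irregularity contrast is visible in the masks."""
        def roughness(pair):
            from scipy.ndimage import binary_erosion
            mask = pair.lesion_mask
            perimeter = (mask & ~binary_erosion(mask)).sum()
            area = mask.sum()
            return perimeter / (2 * np.sqrt(np.pi * area))  # 1 for a disc
        r1 = np.mean([roughness(generate_phantom_pair(small_params, 1, s))
                      for s in range(20)])
        r0 = np.mean([roughness(generate_phantom_pair(small_params, 0, s + 500))
                      for s in range(20)])
        assert r1 > r0


class TestParams:
    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(stiffness_benign_mean=70, stiffness_malignant_mean=30)
        with pytest.raises(ValueError):
            PhantomParams(malignant_irregularity=0.01, benign_irregularity=0.2)
        with pytest.raises(ValueError):
            PhantomParams(class_balance=1.5)


class TestDataset:
    def test_clinical_class_counts(self, small_params):
        """n=746 at the clinical balance gives exactly 486 malignant, 260 benign."""
        params = small_params.with_(n_patients=207)
        samples, manifest = generate_dataset(params, 746, seed=1)
        assert int(manifest["label"].sum()) == 486
        assert int((manifest["label"] == 0).sum()) == 260
        assert manifest["patient_id"].nunique() == 207

    def test_degenerate_balance_all_benign(self, small_params):
        params = small_params.with_(class_balance=0.0, n_patients=3)
        samples, manifest = generate_dataset(params, 10, seed=1)
        assert (manifest["label"] == 0).all()

    def test_patient_grouping_contract(self, small_params):
        params = small_params.with_(n_patients=5)
        samples, manifest = generate_dataset(params, 20, seed=1)
        assert manifest["patient_id"].nunique() == 5
        assert (manifest.groupby("patient_id")["label"].nunique() == 1).all()

    def test_too_many_patients_raises(self, small_params):
        with pytest.raises(ValueError, match="n_patients"):
            generate_dataset(small_params.with_(n_patients=50), 10, seed=1)

    def test_manifest_round_trip(self, small_cohort, tmp_path):
        samples, manifest = small_cohort
        written = save_dataset(samples, manifest, tmp_path, compose_seed=None)
        reloaded, manifest2 = load_dataset(tmp_path / "manifest.csv")
        assert len(reloaded) == len(samples)
        for orig, back in zip(samples, reloaded):
            assert back.sample_id == orig.sample_id
            assert back.label == orig.label
            assert back.roi_box == orig.roi_box
            assert np.abs(back.us_image - orig.us_image).max() <= 0.5 / 255 + 1e-6
            assert np.abs(back.swe_image - orig.swe_image).max() <= 0.5 / 255 + 1e-6


class TestCompoundScreenshot:
    def test_panel_extraction_is_bitwise(self, one_pair):
        shot = compose_screenshot(one_pair, layout_seed=5)
        assert np.array_equal(crop_box(shot.raster, shot.us_panel_box),
                              _gray3(one_pair.us_image))
        assert np.array_equal(crop_box(shot.raster, shot.swe_panel_box),
                              one_pair.swe_image)

    def test_layout_randomness_isolated_to_margins(self, one_pair):
        a = compose_screenshot(one_pair, layout_seed=1)
        b = compose_screenshot(one_pair, layout_seed=2)
        assert np.array_equal(crop_box(a.raster, a.us_panel_box),
                              crop_box(b.raster, b.us_panel_box))
        assert np.array_equal(crop_box(a.raster, a.swe_panel_box),
                              crop_box(b.raster, b.swe_panel_box))
        assert (a.raster.shape != b.raster.shape
                or not np.array_equal(a.raster, b.raster))

    def test_panels_disjoint_equal_size_inside_raster(self, one_pair):
        shot = compose_screenshot(one_pair, layout_seed=9)
        (ar0, ac0, ar1, ac1) = shot.us_panel_box
        (br0, bc0, br1, bc1) = shot.swe_panel_box
        h, w = shot.raster.shape[:2]
        assert (ar1 - ar0, ac1 - ac0) == (br1 - br0, bc1 - bc0)
        assert 0 <= ar0 and ar1 <= h and 0 <= bc0 and bc1 <= w
        no_row_overlap = ar1 <= br0 or br1 <= ar0
        no_col_overlap = ac1 <= bc0 or bc1 <= ac0
        assert no_row_overlap or no_col_overlap
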