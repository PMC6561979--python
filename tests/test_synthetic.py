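"""Synthetic cohort generator: determinism, rendered structure, dials."""

import numpy as np
import pytest
from scipy.stats import norm

from pulmorad.features import extract_size_shape
from pulmorad.qc import concordance_correlation
from pulmorad.synthetic import (AIRSPACE_HU, ClassDistribution, CohortConfig,
                                InvalidConfigError, NoduleParams,
                                apply_kernel_variant, generate_cohort,
                                generate_feature_table_direct,
                                generate_retest_pair, render_nodule,
                                subject_table)


def small_config(**kw):
    base = dict(n_per_class=3, grid_shape=(48, 48, 48))
    base.update(kw)
    return CohortConfig(**base)


class TestGenerateCohort:
    def test_seeded_determinism_bit_identical(self):
        cfg = small_config(n_per_class=5, retest_noise_sd=0.0)
        c1 = generate_cohort(cfg, seed=42)
        c2 = generate_cohort(cfg, seed=42)
        assert len(c1) == 10
        for (v1, l1), (v2, l2) in zip(c1, c2):
            assert l1 == l2
            assert np.array_equal(v1.hu_grid, v2.hu_grid)
            assert np.array_equal(v1.mask, v2.mask)

    def test_labels_balanced_and_hu_clipped(self):
        cfg = small_config(n_per_class=4)
        cohort = generate_cohort(cfg, seed=0)
        labels = [lab for _, lab in cohort]
        assert sum(labels) == 4
        for vol, _ in cohort:
            assert vol.hu_grid.min() >= -1024
            assert vol.hu_grid.max() <= 3071
            assert vol.mask.sum() >= 1

    def test_class_diameter_means_match_sampling_oracle(self):
        # near-smooth nodules: extracted longest diameters should recover
        # the class mean sizes (sample-mean oracle over generated masks)
        cfg = CohortConfig(
            n_per_class=50,
            malignant=ClassDistribution(diameter_mean=14.0, diameter_sd=1.5,
                                        spiculation_mean=0.02,
                                        spiculation_sd=0.01),
            benign=ClassDistribution(diameter_mean=7.0, diameter_sd=1.5,
                                     spiculation_mean=0.02,
                                     spiculation_sd=0.01))
        cohort = generate_cohort(cfg, seed=3)
        diams = {0: [], 1: []}
        for vol, lab in cohort:
            f = extract_size_shape(vol.hu_grid, vol.mask, vol.spacing_mm)
            diams[lab].append(f["longest_diameter_mm"])
        for lab, target in ((1, 14.0), (0, 7.0)):
            d = np.array(diams[lab])
            se = d.std(ddof=1) / np.sqrt(len(d))
            # 2-SE band around the class mean, plus one voxel of
            # discretization slack on the surface-to-surface distance
            assert abs(d.mean() - target) < 2 * se + 1.0

    def test_zero_airspace_class_has_no_airspace_voxels(self):
        params = NoduleParams("benign", 12.0, airspace_fraction=0.0,
                              heterogeneity_sd=80.0, rng_seed=5)
        vol = render_nodule(params, small_config())
        assert vol.hu_grid[vol.mask].min() >= AIRSPACE_HU

    def test_airspace_fraction_is_respected(self):
        params = NoduleParams("malignant", 16.0, airspace_fraction=0.15,
                              heterogeneity_sd=30.0, rng_seed=6)
        vol = render_nodule(params, small_config())
        frac = (vol.hu_grid[vol.mask] < AIRSPACE_HU).mean()
        assert 0.05 < frac < 0.35

    def test_invalid_config_raises(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(n_per_class=0)
        with pytest.raises(InvalidConfigError):
            CohortConfig(spacing_mm=(1.0, 0.0, 1.0))
        with pytest.raises(InvalidConfigError):
            NoduleParams("benign", -3.0)
        with pytest.raises(InvalidConfigError):
            NoduleParams("benign", 10.0, airspace_fraction=1.0)


class TestRetestPairs:
    def test_zero_noise_zero_shift_identical(self):
        cfg = small_config(retest_noise_sd=0.0, retest_shift_mm=0.0)
        params = NoduleParams("benign", 10.0, rng_seed=1)
        a, b = generate_retest_pair(params, cfg, seed=2)
        assert np.array_equal(a.hu_grid, b.hu_grid)
        assert concordance_correlation(
            a.hu_grid[a.mask], b.hu_grid[b.mask]) == 1.0

    def test_reproducible_from_seed(self):
        cfg = small_config()
        params = NoduleParams("malignant", 14.0, rng_seed=3)
        a1, b1 = generate_retest_pair(params, cfg, seed=7)
        a2, b2 = generate_retest_pair(params, cfg, seed=7)
        assert np.array_equal(a1.hu_grid, a2.hu_grid)
        assert np.array_equal(b1.hu_grid, b2.hu_grid)

    def test_mean_hu_ccc_decreases_with_retest_noise(self):
        """CCC of an intensity feature is non-increasing in retest noise,
        averaged over a panel of nodules."""
        cccs = []
        for noise in (2.0, 60.0):
            cfg = small_config(retest_noise_sd=noise, retest_shift_mm=0.0)
            xs, ys = [], []
            for i in range(20):
                params = NoduleParams("benign", 8.0 + (i % 6),
                                      heterogeneity_sd=20.0, rng_seed=i)
                a, b = generate_retest_pair(params, cfg, seed=100 + i)
                xs.append(a.hu_grid[a.mask].mean())
                ys.append(b.hu_grid[b.mask].mean())
            cccs.append(concordance_correlation(xs, ys))
        assert cccs[1] < cccs[0]
        assert cccs[0] > 0.95


class TestKernelVariants:
    def test_smooth_sigma_zero_is_identity(self):
        cfg = small_config(kernel_variants={"smooth_sigma_mm": 0.0,
                                            "sharp_gain": 1.0,
                                            "sharp_sigma_mm": 1.0})
        vol = render_nodule(NoduleParams("benign", 10.0, rng_seed=4), cfg)
        out = apply_kernel_variant(vol, "smooth", cfg)
        assert np.array_equal(out.hu_grid, vol.hu_grid)

    def test_smooth_reduces_interior_sd(self):
        # direct comparison on the nodule core (away from the nodule/lung
        # edge, whose partial-volume mixing is not a texture property)
        from scipy import ndimage as ndi
        cfg = small_config()
        vol = render_nodule(NoduleParams("malignant", 16.0,
                                         heterogeneity_sd=70.0, rng_seed=8),
                            cfg)
        out = apply_kernel_variant(vol, "smooth", cfg)
        core = ndi.binary_erosion(vol.mask, iterations=3)
        assert core.sum() > 20
        assert out.hu_grid[core].std() < vol.hu_grid[core].std()

    def test_mask_unchanged_and_unknown_variant_raises(self):
        cfg = small_config()
        vol = render_nodule(NoduleParams("benign", 9.0, rng_seed=9), cfg)
        for variant in ("smooth", "sharp"):
            out = apply_kernel_variant(vol, variant, cfg)
            assert out.mask.sum() == vol.mask.sum()
        with pytest.raises(InvalidConfigError):
            apply_kernel_variant(vol, "bone", cfg)


class TestDirectFeatureTables:
    def test_null_features_have_auc_half(self):
        from pulmorad.discriminant import auroc
        test, _, y = generate_feature_table_direct(400, 400, p_noise=6, seed=1)
        aucs = [auroc(test[c], y) for c in test.columns]
        assert np.allclose(aucs, 0.5, atol=0.06)

    def test_planted_effect_reaches_closed_form_auc(self):
        from pulmorad.discriminant import auroc
        test, _, y = generate_feature_table_direct(
            500, 500, p_noise=0, planted=[(3.0, 1)], seed=2)
        assert auroc(test["planted_000"], y) == pytest.approx(
            norm.cdf(3.0 / np.sqrt(2)), abs=0.01)

    def test_exact_affine_redundancy_block(self):
        test, _, _ = generate_feature_table_direct(
            50, 50, p_noise=0, redundancy_blocks=[(3, 1.0)], seed=3)
        cols = [c for c in test.columns if c.startswith("block0")]
        r = np.corrcoef(test[cols].to_numpy(), rowvar=False) ** 2
        assert np.allclose(r, 1.0)

    def test_retest_ccc_targets_are_honored(self):
        test, retest, _ = generate_feature_table_direct(
            600, 600, p_noise=3, seed=4,
            retest_ccc_targets={"noise_000": 0.9, "noise_001": 0.3})
        c0 = concordance_correlation(test["noise_000"], retest["noise_000"])
        c1 = concordance_correlation(test["noise_001"], retest["noise_001"])
        assert c0 == pytest.approx(0.9, abs=0.06)
        assert c1 == pytest.approx(0.3, abs=0.1)
        c2 = concordance_correlation(test["noise_002"], retest["noise_002"])
        assert c2 == 1.0


def test_diameter_gap_dial_increases_longest_diameter_auc():
    """Widening the between-class diameter gap strictly increases the AUROC
    of the longest-diameter feature (Monte Carlo at 3 gap levels)."""
    from pulmorad.discriminant import auroc
    aucs = []
    for gap in (0.0, 3.0, 6.0):
        cfg = CohortConfig(
            n_per_class=25, grid_shape=(48, 48, 48),
            malignant=ClassDistribution(diameter_mean=9.0 + gap,
                                        diameter_sd=1.5),
            benign=ClassDistribution(diameter_mean=9.0, diameter_sd=1.5))
        cohort = generate_cohort(cfg, seed=11)
        d, y = [], []
        for vol, lab in cohort:
            f = extract_size_shape(vol.hu_grid, vol.mask, vol.spacing_mm)
            d.append(f["longest_diameter_mm"])
            y.append(lab)
        aucs.append(auroc(d, y))
    assert aucs[0] < aucs[1] < aucs[2]
    assert aucs[2] > 0.95


def test_subject_table_schema():
    cfg = small_config(n_per_class=3)
    cohort = generate_cohort(cfg, seed=0)
    subjects = subject_table(cohort, seed=0)
    assert list(subjects.columns) == ["label", "age", "sex", "pack_years",
                                      "smoke_status"]
    assert len(subjects) == 6
    assert not subjects.isna().any().any()
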