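import numpy as np
import pandas as pd
import pytest

from ecmatlas import deposition as depo
from ecmatlas.deposition import ZONES


def _series(values):
    return pd.Series(dict(zip(ZONES, values)), name="raw_mean").astype(float)


class TestMeasureRegionIntensities:
    def _masks(self, h=12, w=12):
        zone = np.zeros((h, w), dtype=int)
        bg = np.zeros((h, w), dtype=int)
        for z in range(6):
            zone[0:6, z * 2:(z + 1) * 2] = z + 1
            bg[6:12, z * 2:(z + 1) * 2] = z + 1
        return zone, bg

    def test_uniform_zone_minus_background(self):
        zone, bg = self._masks()
        image = np.where(zone > 0, 120.0, 20.0)
        raw = depo.measure_region_intensities(image, zone, bg)
        np.testing.assert_allclose(raw.to_numpy(), 100.0)

    def test_background_exceeding_signal_clips_to_zero(self):
        zone, bg = self._masks()
        image = np.where(zone > 0, 10.0, 50.0)
        raw = depo.measure_region_intensities(image, zone, bg)
        assert (raw == 0.0).all()

    def test_pixels_outside_masks_ignored(self):
        zone, bg = self._masks()
        image = np.where(zone > 0, 120.0, np.where(bg > 0, 20.0, 0.0))
        noisy = image.copy()
        outside = (zone == 0) & (bg == 0)
        assert not outside.any()  # strips tile the frame here; widen it
        zone2 = np.pad(zone, ((0, 4), (0, 0)))
        bg2 = np.pad(bg, ((0, 4), (0, 0)))
        img2 = np.pad(image, ((0, 4), (0, 0)), constant_values=0)
        img3 = np.pad(image, ((0, 4), (0, 0)), constant_values=9999.0)
        a = depo.measure_region_intensities(img2, zone2, bg2)
        b = depo.measure_region_intensities(img3, zone2, bg2)
        pd.testing.assert_series_equal(a, b)

    def test_empty_zone_and_shape_mismatch_rejected(self):
        zone, bg = self._masks()
        zone_missing = zone.copy()
        zone_missing[zone_missing == 3] = 0
        image = np.zeros_like(zone, dtype=float)
        with pytest.raises(ValueError, match="UB"):
            depo.measure_region_intensities(image, zone_missing, bg)
        with pytest.raises(ValueError, match="shape"):
            depo.measure_region_intensities(image[:6], zone, bg)


class TestRelativeNormalize:
    def test_proportionality(self):
        relative = depo.relative_normalize(_series([2, 8, 4, 0, 0, 0]))
        np.testing.assert_allclose(relative.to_numpy(), [25, 100, 50, 0, 0, 0])

    def test_maximum_zone_reads_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = _series(rng.uniform(0, 50, 6))
            assert depo.relative_normalize(raw).max() == pytest.approx(100.0)

    def test_scale_invariance(self):
        raw = _series([3, 7, 1, 9, 2, 5])
        a = depo.relative_normalize(raw)
        b = depo.relative_normalize(raw * 13.7)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no deposition"):
            depo.relative_normalize(_series([0] * 6))


class TestRegionEnrichment:
    def test_friedman_worked_example(self):
        # 3 blocks × 3 treatments, each block ranks (1,2,3):
        # chi2 = 12/(3*3*4) * (9 + 36 + 81) - 3*3*4 = 6, df = 2
        profiles = pd.DataFrame(
            [[1, 2, 3], [10, 20, 30], [2, 5, 9]], columns=["z1", "z2", "z3"]
        )
        out = depo.region_enrichment_test(profiles)
        assert out["friedman_chi2"] == pytest.approx(6.0)
        assert out["friedman_df"] == 2

    def test_identical_zones_no_pairwise(self):
        profiles = pd.DataFrame(
            np.tile([[4.0], [7.0], [1.0]], (1, 6)), columns=list(ZONES)
        )
        out = depo.region_enrichment_test(profiles)
        assert out["friedman_p"] == 1.0
        assert out["pairwise"] is None

    def test_bonferroni_factor_counts_comparisons(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 20, size=(8, 6))
        base[:, 3] += 100  # strong MB enrichment
        profiles = pd.DataFrame(base, columns=list(ZONES))
        out = depo.region_enrichment_test(profiles)
        assert out["friedman_p"] < 0.05
        pairwise = out["pairwise"]
        assert len(pairwise) == 15  # C(6, 2)
        np.testing.assert_allclose(
            pairwise["p_bonferroni"], np.minimum(1.0, pairwise["p"] * 15)
        )

    def test_too_few_blocks_rejected(self):
        profiles = pd.DataFrame(np.ones((2, 6)), columns=list(ZONES))
        with pytest.raises(ValueError):
            depo.region_enrichment_test(profiles)


class TestConcordance:
    def _mrna(self, basal=0, li=0, ub=0, mb=0, hg=0):
        return pd.Series({"Basal": basal, "LI": li, "UB": ub, "MB": mb, "HG": hg},
                         dtype=float)

    def test_perfect_colocalization_consistent(self):
        call = depo.concordance_call(
            "g", self._mrna(mb=10), _series([0, 0, 0, 8, 0, 0])
        )
        assert call.pearson_r == pytest.approx(1.0)
        assert call.verdict == "consistent"

    def test_peak_mismatch_is_discrepant_despite_high_r(self):
        mrna = self._mrna(basal=10, li=9, ub=1, mb=1, hg=1)
        protein = _series([9, 10, 1, 1, 1, 1])  # peaks in LI, r ≈ 0.98
        call = depo.concordance_call("g", mrna, protein)
        assert call.pearson_r > 0.9
        assert call.verdict == "discrepant"

    def test_low_r_is_discrepant_despite_shared_peak(self):
        mrna = self._mrna(basal=10, li=0, ub=9, mb=0, hg=9)
        protein = _series([10.5, 9, 0, 9.4, 0.1, 0.2])
        call = depo.concordance_call("g", mrna, protein)
        assert "IFE" in call.mrna_peak_zones and "IFE" in call.protein_peak_zones
        assert call.pearson_r < 0.5
        assert call.verdict == "discrepant"

    def test_r_exactly_half_is_discrepant(self):
        # construct protein with Pearson r = 0.5 against the mRNA vector and a
        # shared peak: the strict r > 0.5 arm must fail
        # mRNA maps to (2,0,1,1,1,1); protein (2,1,0,1,1,1): cov = 1/3,
        # var = 1/3 each, so r = 1/2 exactly (also exact in floats)
        mrna_pop = self._mrna(basal=2, li=0, ub=1, mb=1, hg=1)
        protein = _series([2, 1, 0, 1, 1, 1])
        call = depo.concordance_call("g", mrna_pop, protein)
        assert call.pearson_r == 0.5
        assert set(call.mrna_peak_zones) & set(call.protein_peak_zones)
        assert call.verdict == "discrepant"

    def test_hg_peak_accepts_either_hg_zone(self):
        mrna = self._mrna(hg=10, basal=1)
        protein = _series([1, 0, 0, 0, 0, 8])  # peak in the interface zone only
        call = depo.concordance_call("g", mrna, protein)
        assert call.verdict == "consistent"

    def test_zero_variance_profile_flagged_discrepant(self):
        call = depo.concordance_call("g", self._mrna(), _series([5, 5, 5, 5, 5, 5]))
        assert call.verdict == "discrepant"
        assert call.flag == "zero_variance"
        assert np.isnan(call.pearson_r)

    def test_pearson_matches_covariance_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            mrna = pd.Series(
                {"Basal": x[0], "LI": x[1], "UB": x[2], "MB": x[3], "HG": x[4]}
            )
            aligned = depo.map_mrna_to_zones(mrna).to_numpy()
            expected = (
                np.mean((aligned - aligned.mean()) * (y - y.mean()))
                / (np.std(aligned) * np.std(y))
            )
            call = depo.concordance_call("g", mrna, pd.Series(y, index=list(ZONES)))
            assert call.pearson_r == pytest.approx(expected, abs=1e-12)


class TestMorphometry:
    def test_hemidesmosome_density(self):
        assert depo.hemidesmosome_density(6, 3.0) == 2.0
        assert depo.hemidesmosome_density(0, 3.0) == 0.0
        assert depo.hemidesmosome_density(12, 6.0) == depo.hemidesmosome_density(6, 3.0)
        with pytest.raises(ValueError):
            depo.hemidesmosome_density(1, 0.0)

    def test_dp_volume(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[:4, :5, :5] = 1  # 100 voxels
        labels[5:7, 5:9, 5:9] = 2  # 32 voxels
        volumes = depo.dp_volume(labels, (0.5, 0.5, 0.5))
        assert volumes[1] == pytest.approx(12.5)
        assert volumes[1] + volumes[2] == pytest.approx((100 + 32) * 0.125)
        with pytest.raises(ValueError):
            depo.dp_volume(labels, (0.5, -1, 0.5))

    def test_pigmented_fraction(self):
        rng = np.random.default_rng(2)
        image = rng.uniform(0, 255, size=(20, 50))
        threshold = np.quantile(image, 0.25)
        frac, mask = depo.pigmented_fraction(image, threshold)
        assert frac == pytest.approx((image < threshold).mean())
        assert frac == pytest.approx(0.25, abs=0.01)
        assert depo.pigmented_fraction(image, image.min() - 1)[0] == 0.0
        fracs = [depo.pigmented_fraction(image, t)[0] for t in np.linspace(0, 255, 9)]
        assert fracs == sorted(fracs)
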