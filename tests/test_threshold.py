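"""Threshold schemes, plaque segmentation, and Agatston scoring."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from aohu import (
    ThresholdScheme,
    agatston_score,
    agatston_weight,
    effective_threshold,
    sample_scan,
    segment_plaque,
)
from aohu.central_zone import CentralZoneStats
from aohu.phantom import AortaScan, ScanMeta


def _stats(mean, sd):
    return CentralZoneStats("s", "L3", 2, mean, sd, 100)


def _scan_from_image(img, mask=None, truth=None):
    img = np.asarray(img)
    mask = np.ones_like(img, dtype=bool) if mask is None else mask
    truth = np.zeros_like(mask) if truth is None else truth
    meta = ScanMeta("T-0", "T", "arterial", "M", 60.0, 80.0)
    return AortaScan(img, mask, truth, tuple(["L3"] * img.shape[0]), meta)


class TestEffectiveThreshold:
    def test_dynamic_three_sd_delayed(self):
        assert effective_threshold(ThresholdScheme("dynamic", N=3), _stats(110, 16)) == 158.0

    def test_uniform_ignores_stats(self):
        scheme = ThresholdScheme("uniform", T=130)
        assert effective_threshold(scheme) == 130.0
        assert effective_threshold(scheme, _stats(500, 99)) == 130.0

    def test_dynamic_zero_sd_multiplier_is_the_mean(self):
        assert effective_threshold(ThresholdScheme("dynamic", N=0), _stats(180, 30)) == 180.0

    def test_dynamic_without_stats_rejected(self):
        with pytest.raises(ValueError):
            effective_threshold(ThresholdScheme("dynamic", N=3))

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ThresholdScheme("uniform")
        with pytest.raises(ValueError):
            ThresholdScheme("dynamic", N=-1)
        with pytest.raises(ValueError):
            ThresholdScheme("percentile", T=130)


class TestSegmentation:
    def test_sub_threshold_vessel_is_empty(self):
        scan = _scan_from_image(np.full((1, 16, 16), 100.0))
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130))
        assert not seg.plaque_mask.any()
        assert seg.lesions == []

    def test_plaque_free_dynamic_fraction_matches_normal_tail(self, tiny_params):
        # float pixels so the comparison is against the exact normal tail
        p = replace(tiny_params, slice_shape=(160, 160), vessel_radius_px=(70, 70),
                    quantize=False, phase_popSD_HU={**tiny_params.phase_popSD_HU, "arterial": 0.0})
        counts = total = 0
        for i in range(70):
            meta = ScanMeta(f"T-{i}", "T", "arterial", "M", 60.0, 80.0, rng_stream_id=i)
            scan = sample_scan(p, meta)
            st = _stats(scan.scan_mean_HU, p.within_scan_SD_HU)
            seg = segment_plaque(scan, ThresholdScheme("dynamic", N=3), st)
            counts += int(seg.plaque_mask.sum())
            total += int(scan.aorta_mask.sum())
        frac = counts / total
        expected = float(norm.sf(3))
        assert total >= 10**6
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / total))

    def test_rim_detected_only_at_low_threshold(self):
        """A dense 20-px core is found by both 130 and 400 HU cutoffs;
        its partial-volume rim (130-399 HU) only by the lower one."""
        img = np.full((1, 24, 24), 60.0)
        core = np.zeros((1, 24, 24), dtype=bool)
        core[0, 10:14, 8:13] = True  # 20 px
        rim = np.zeros_like(core)
        rim[0, 9, 8:13] = True
        img[core] = 450.0
        img[rim] = 220.0
        scan = _scan_from_image(img, truth=core | rim)
        low = segment_plaque(scan, ThresholdScheme("uniform", T=130))
        high = segment_plaque(scan, ThresholdScheme("uniform", T=400))
        assert np.array_equal(high.plaque_mask, core)
        assert np.array_equal(low.plaque_mask, core | rim)

    def test_min_lesion_size_filters_specks(self):
        img = np.full((1, 16, 16), 60.0)
        img[0, 2, 2] = 500.0  # single-pixel speck
        img[0, 8:11, 8:11] = 500.0  # 9-px lesion
        scan = _scan_from_image(img)
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130), min_lesion_px=4)
        assert len(seg.lesions) == 1
        assert seg.lesions[0].area_px == 9
        assert not seg.plaque_mask[0, 2, 2]

    def test_uniform_threshold_monotone(self, params, arterial_meta):
        scan = sample_scan(replace(params, plaque_prevalence=1.0), arterial_meta)
        prev = None
        for T in (130, 200, 300, 400, 550):
            seg = segment_plaque(scan, ThresholdScheme("uniform", T=T))
            if prev is not None:
                assert not np.any(seg.plaque_mask & ~prev)  # mask shrinks
            prev = seg.plaque_mask


class TestAgatston:
    @pytest.mark.parametrize(
        "hu,weight",
        [(130, 1), (150, 1), (199, 1), (200, 2), (299, 2), (300, 3), (399, 3), (400, 4), (1400, 4)],
    )
    def test_bin_table(self, hu, weight):
        assert agatston_weight(hu) == weight

    def test_below_bins_rejected(self):
        with pytest.raises(ValueError):
            agatston_weight(129.9)

    @settings(deadline=None, max_examples=100)
    @given(a=st.floats(130, 3000), b=st.floats(130, 3000))
    def test_weight_non_decreasing_in_peak_hu(self, a, b):
        lo, hi = sorted((a, b))
        assert agatston_weight(lo) <= agatston_weight(hi)

    def test_hand_computed_score(self):
        img = np.full((1, 16, 16), 60.0)
        img[0, 5:7, 5:10] = 250.0  # 10 px, peak 250 -> weight 2
        scan = _scan_from_image(img)
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130), pixel_spacing_mm=0.5)
        res = agatston_score(seg, pixel_spacing_mm=0.5)
        assert res.lesion_weights == [2]
        assert res.total_score == pytest.approx(2 * 10 * 0.25)  # weight x area mm^2

    def test_empty_segmentation_scores_zero(self):
        scan = _scan_from_image(np.full((1, 8, 8), 50.0))
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130))
        res = agatston_score(seg, 0.7, slice_thickness_mm=3.0)
        assert res.total_score == 0.0
        assert res.total_area_mm2 == 0.0
        assert res.total_volume_mm3 == 0.0

    def test_score_scales_with_pixel_area(self):
        img = np.full((1, 16, 16), 60.0)
        img[0, 4:8, 4:8] = 500.0
        scan = _scan_from_image(img)
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130))
        s1 = agatston_score(seg, pixel_spacing_mm=0.5)
        s2 = agatston_score(seg, pixel_spacing_mm=1.0)
        assert s2.total_score == pytest.approx(4 * s1.total_score)

    def test_per_pixel_variant_leq_uses_own_bins(self):
        img = np.full((1, 16, 16), 60.0)
        img[0, 5, 5:9] = [150.0, 250.0, 350.0, 450.0]
        scan = _scan_from_image(img)
        seg = segment_plaque(scan, ThresholdScheme("uniform", T=130))
        lesion_max = agatston_score(seg, 1.0)
        per_pixel = agatston_score(seg, 1.0, per_pixel_weights=True, image=scan.image)
        assert lesion_max.total_score == 4 * 4  # peak bin applied to all 4 px
        assert per_pixel.total_score == 1 + 2 + 3 + 4
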