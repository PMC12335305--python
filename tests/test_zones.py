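"""Zone segmentation, Otsu thresholding and per-zone colour measurement."""

import numpy as np
import pytest

from mupadkit import color, zones
from mupadkit.errors import DegenerateInputError, InputDomainError, SegmentationError
from mupadkit.synthetic import ResponseParams, SyntheticSpec, render_image
from mupadkit.zones import ZoneMask, measure_zone, segment_zones, threshold_otsu

from conftest import BASE_SEED


def otsu_bruteforce(hist):
    """Independent oracle: exhaustive scan minimising within-class variance."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256)
    best_t, best_within = None, np.inf
    total = hist.sum()
    for t in range(256):
        lo, hi = hist[: t + 1], hist[t + 1 :]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        mu_lo = (levels[: t + 1] * lo).sum() / lo.sum()
        mu_hi = (levels[t + 1 :] * hi).sum() / hi.sum()
        within = (lo * (levels[: t + 1] - mu_lo) ** 2).sum() + (
            hi * (levels[t + 1 :] - mu_hi) ** 2
        ).sum()
        within /= total
        if within < best_within - 1e-12:  # strict improvement → smallest maximiser
            best_within, best_t = within, t
    return best_t


class TestOtsu:
    def test_two_delta_histogram_smallest_maximiser(self):
        hist = np.zeros(256)
        hist[10] = 500
        hist[200] = 500
        assert threshold_otsu(hist) == 10

    def test_matches_bruteforce_on_planted_mixture(self, rng):
        sample = np.concatenate([
            rng.normal(40, 10, size=5000), rng.normal(180, 10, size=5000)])
        hist = np.bincount(np.clip(np.rint(sample), 0, 255).astype(int), minlength=256)
        assert threshold_otsu(hist) == otsu_bruteforce(hist)

    def test_matches_bruteforce_on_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            if np.count_nonzero(hist) < 2:
                continue
            assert threshold_otsu(hist) == otsu_bruteforce(hist)

    def test_constant_image_rejected(self):
        hist = np.zeros(256)
        hist[42] = 1000
        with pytest.raises(DegenerateInputError):
            threshold_otsu(hist)

    def test_malformed_histogram_rejected(self):
        with pytest.raises(InputDomainError):
            threshold_otsu(np.zeros(100))


def _flat_disk_image(sat=60.0, noise_sd=2.0, seed=0):
    """Four disks of equal saturation on white paper (the canonical layout)."""
    spec = SyntheticSpec(
        concentrations=(1.0, 1.0, 1.0, 1.0),
        response=ResponseParams(channel="S", intercept=sat - 1.0, slope=1.0,
                                linear_range=(0.0, 10.0)),
        noise_sd=noise_sd, seed=seed,
    )
    img, truth = render_image(spec)
    return spec, img, truth


class TestSegmentZones:
    def test_planted_disks_recovered(self):
        spec, img, truth = _flat_disk_image(sat=60.0, noise_sd=2.0, seed=BASE_SEED)
        masks = segment_zones(img, 4)
        assert [m.zone_id for m in masks] == [1, 2, 3, 4]
        full_area = np.pi * spec.zone_radius_px**2
        for mask, t in zip(masks, truth):
            assert np.hypot(mask.centroid[0] - t["centre"][0],
                            mask.centroid[1] - t["centre"][1]) < 1.0
            # erosion removes 10 % of the radius → ~81 % of the full disk area
            expected = np.pi * (0.9 * spec.zone_radius_px) ** 2
            assert abs(mask.area - expected) < 0.05 * full_area

    def test_blank_image_reports_zero_components(self):
        img = np.full((100, 120, 3), 255, dtype=np.uint8)
        with pytest.raises(SegmentationError) as exc_info:
            segment_zones(img, 4)
        assert exc_info.value.found == 0

    def test_rotated_image_remaps_reading_order(self, noiseless_spec):
        img, truth = render_image(noiseless_spec)
        rotated = img[::-1, ::-1].copy()
        base = [measure_zone(img, m).mean_s for m in segment_zones(img, 4)]
        rot = [measure_zone(rotated, m).mean_s for m in segment_zones(rotated, 4)]
        # 180° rotation of the 2×2 layout reverses reading order
        assert rot == pytest.approx(base[::-1], abs=1e-9)

    def test_mixed_intensity_zones_all_found(self, noisy_spec):
        masks = segment_zones(render_image(noisy_spec)[0], 4)
        assert len(masks) == 4

    def test_layout_hint_resolves_extra_components(self, noiseless_spec):
        img, _ = render_image(noiseless_spec)
        masks = segment_zones(img, 4, layout=noiseless_spec.zone_centres)
        for mask, centre in zip(masks, noiseless_spec.zone_centres):
            assert np.hypot(mask.centroid[0] - centre[0],
                            mask.centroid[1] - centre[1]) < 1.0


class TestMeasureZone:
    def _disk_mask(self, centre, radius, zone_id=1):
        rr, cc = np.mgrid[0:200, 0:200]
        inside = np.hypot(rr - centre[0], cc - centre[1]) <= radius
        rows, cols = np.nonzero(inside)
        return ZoneMask(zone_id, rows, cols)

    def test_uniform_red_disk(self):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        mask = self._disk_mask((100, 100), 30)
        img[mask.rows, mask.cols] = (255, 0, 0)
        m = measure_zone(img, mask)
        assert m.mean_h == pytest.approx(0.0, abs=1e-12)
        assert m.mean_s == pytest.approx(100.0, abs=1e-12)
        assert m.mean_v == pytest.approx(100.0, abs=1e-12)
        assert m.mean_gray == pytest.approx(76.245, abs=1e-9)

    def test_noisy_disk_channel_means_within_clt_bound(self, rng):
        planted_rgb = np.array(color.hsv_to_rgb(300, 50, 80))
        img = np.full((200, 200, 3), 255.0)
        mask = self._disk_mask((100, 100), 40)
        noise = rng.normal(0, 3.0, size=(mask.area, 3))
        img[mask.rows, mask.cols] = planted_rgb + noise
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        m = measure_zone(img, mask)
        bound = 3.0 * 3.0 / np.sqrt(mask.area)
        for got, true in zip((m.mean_r, m.mean_g, m.mean_b), planted_rgb):
            assert abs(got - true) < bound
        assert abs(m.mean_gray - color.rgb_to_gray(*planted_rgb)) < bound

    def test_singleton_mask_returns_exact_pixel(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[3, 7] = (30, 144, 255)
        m = measure_zone(img, ZoneMask(1, [3], [7]))
        h, s, v = color.rgb_to_hsv(30, 144, 255)
        assert (m.mean_r, m.mean_g, m.mean_b) == (30.0, 144.0, 255.0)
        assert (m.mean_h, m.mean_s, m.mean_v) == pytest.approx((h, s, v), abs=1e-9)

    def test_pixel_order_invariance(self, rng):
        img = rng.integers(0, 256, size=(50, 50, 3)).astype(np.uint8)
        rows, cols = np.nonzero(np.ones((50, 50), dtype=bool))
        perm = rng.permutation(rows.size)
        a = measure_zone(img, ZoneMask(1, rows, cols))
        b = measure_zone(img, ZoneMask(1, rows[perm], cols[perm]))
        assert a.mean_s == pytest.approx(b.mean_s, abs=1e-9)
        assert a.mean_h == pytest.approx(b.mean_h, abs=1e-9)

    def test_mask_outside_image_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(InputDomainError):
            measure_zone(img, ZoneMask(1, [11], [2]))

    def test_empty_mask_rejected(self):
        with pytest.raises(InputDomainError):
            ZoneMask(1, [], [])


class TestStatisticalProperties:
    def test_noise_contraction_scales_with_sqrt_area(self):
        """SD of mean_s across replicates ≈ σ_RGB/√area (within 1.5×).

        Uses a dark, saturated zone colour whose saturation responds with
        ≈ unit gain to RGB perturbation, so the RGB noise SD is the right
        per-pixel scale for saturation too.
        """
        sigma = 2.0
        spec = SyntheticSpec(
            concentrations=(1.0,) * 4,
            response=ResponseParams(channel="S", intercept=89.0, slope=1.0,
                                    linear_range=(0.0, 10.0),
                                    base_hsv=(20.0, 10.0, 40.0)),
            noise_sd=sigma,
        )
        means, areas = [], []
        for seed in range(100):
            spec_i = SyntheticSpec(**{**spec.__dict__, "seed": BASE_SEED + seed})
            img, _ = render_image(spec_i)
            masks = segment_zones(img, 4)
            means.append(measure_zone(img, masks[0]).mean_s)
            areas.append(masks[0].area)
        observed_sd = np.std(means, ddof=1)
        predicted_sd = sigma / np.sqrt(np.mean(areas))
        assert predicted_sd / 1.5 < observed_sd < predicted_sd * 1.5

    def test_erosion_preserves_uniform_zone_mean(self):
        spec, img, truth = _flat_disk_image(sat=60.0, noise_sd=0.0)
        masks = segment_zones(img, 4)
        rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        for mask, t in zip(masks, truth):
            # interior (un-eroded minus rim) mean equals eroded-mask mean exactly
            inside = np.hypot(rr - t["centre"][0], cc - t["centre"][1]) <= t["radius_px"] - 1.5
            rows, cols = np.nonzero(inside)
            full = measure_zone(img, ZoneMask(mask.zone_id, rows, cols))
            eroded = measure_zone(img, mask)
            assert eroded.mean_s == pytest.approx(full.mean_s, abs=1e-9)

    def test_noiseless_roundtrip_within_quantisation(self, noiseless_spec):
        img, truth = render_image(noiseless_spec)
        masks = segment_zones(img, 4)
        for mask, t in zip(masks, truth):
            m = measure_zone(img, mask)
            for got, true in zip((m.mean_r, m.mean_g, m.mean_b), t["rgb"]):
                assert abs(got - true) <= 0.5


class TestIO:
    def test_png_roundtrip_and_csv_export(self, tmp_path, noiseless_spec):
        img, _ = render_image(noiseless_spec)
        path = tmp_path / "pad.png"
        zones.write_image(path, img)
        loaded = zones.read_image(path)
        assert np.array_equal(img, loaded)
        measurements = zones.measure_image(loaded, 4)
        csv_path = tmp_path / "zones.csv"
        zones.write_measurements_csv(measurements, csv_path)
        header = csv_path.read_text().splitlines()[0]
        assert header == ",".join(zones.CSV_COLUMNS)
        assert len(csv_path.read_text().splitlines()) == 5

    def test_alpha_channel_ignored_with_warning(self, tmp_path, caplog):
        from PIL import Image

        rgba = np.zeros((20, 20, 4), dtype=np.uint8)
        rgba[..., :3] = 128
        rgba[..., 3] = 255
        path = tmp_path / "a.png"
        Image.fromarray(rgba, mode="RGBA").save(path)
        with caplog.at_level("WARNING"):
            arr = zones.read_image(path)
        assert arr.shape == (20, 20, 3)
        assert any("alpha" in r.message for r in caplog.records)
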