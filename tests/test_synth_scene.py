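"""Scene generator: spectra, camera rendering, frames, datasets, slides."""

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import small_scene, tiny_dataset_config
from filasense.constants import CLASSES
from filasense.synth_scene import (CameraModel, ClassSpectrumParams,
                                   DatasetConfig, SlideConfig,
                                   build_image_dataset, make_emission_spectrum,
                                   render_darkfield_slide, render_frame,
                                   spectrum_to_rgb)

FWHM = 2.3548200450309493


class TestEmissionSpectra:
    def test_salt_peaks_at_sodium_d_line(self):
        s = make_emission_spectrum("salt", 1.0)
        peak = s.wavelength_nm[np.argmax(s.intensity)]
        assert 585.0 <= peak <= 595.0

    def test_zero_amplitudes_zero_noise_gives_zero_spectrum(self):
        params = ClassSpectrumParams("chalk", lines=((500.0, 5.0, 0.0),))
        s = make_emission_spectrum("chalk", 1.0, params)
        assert np.all(s.intensity == 0)

    def test_pollen_band_fraction_by_quadrature(self):
        """Independent quadrature of the parametric Gaussians confirms >=60%
        of pollen emission lies in 450-650 nm with the peak in 500-550 nm."""
        from filasense.synth_scene import DEFAULT_SPECTRA
        p = DEFAULT_SPECTRA["pollen"]

        def model(x):
            total = 0.0
            comps = list(p.lines) + ([p.continuum] if p.continuum else [])
            for c, w, a in comps:
                total += a * np.exp(-0.5 * ((x - c) / (w / FWHM)) ** 2)
            return total

        inside, _ = quad(model, 450, 650)
        total, _ = quad(model, 350, 800)
        assert inside / total >= 0.60

        s = make_emission_spectrum("pollen", 1.0)
        peak = s.wavelength_nm[np.argmax(s.intensity)]
        assert 500.0 <= peak <= 550.0
        # implementation agrees with the quadrature oracle
        wl, inten = s.wavelength_nm, s.intensity
        m = (wl >= 450) & (wl <= 650)
        impl_frac = np.trapezoid(inten[m], wl[m]) / np.trapezoid(inten, wl)
        assert impl_frac == pytest.approx(inside / total, abs=1e-3)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            make_emission_spectrum("dust", 1.0)

    def test_mismatched_params_rejected(self):
        with pytest.raises(ValueError):
            make_emission_spectrum("salt", 1.0, ClassSpectrumParams("chalk"))

    def test_blank_is_pure_continuum(self):
        s = make_emission_spectrum("blank", 1.0)
        assert s.intensity.max() > 0
        assert s.wavelength_nm[np.argmax(s.intensity)] < 500  # broad blue-ish band


class TestSpectrumToRGB:
    def test_zero_spectrum_gives_black(self):
        s = make_emission_spectrum(
            "chalk", 1.0, ClassSpectrumParams("chalk", lines=((500.0, 5.0, 0.0),)))
        np.testing.assert_array_equal(spectrum_to_rgb(s), np.zeros(3))

    def test_line_at_red_center_matches_gaussian_product_integral(self):
        """Analytic oracle: integral of two Gaussians with equal centers is
        amp * sqrt(2*pi * s1^2*s2^2 / (s1^2+s2^2))."""
        cam = CameraModel()
        line_fwhm, amp = 2.0, 1.0
        params = ClassSpectrumParams("salt", lines=((600.0, line_fwhm, amp),))
        rgb = spectrum_to_rgb(make_emission_spectrum("salt", 1.0, params), cam)
        s1 = line_fwhm / FWHM
        for ch, (center, fwhm, gain) in enumerate((cam.red, cam.green, cam.blue)):
            s2 = fwhm / FWHM
            delta = 600.0 - center
            expect = (gain * amp * np.sqrt(2 * np.pi * s1 ** 2 * s2 ** 2 /
                                           (s1 ** 2 + s2 ** 2))
                      * np.exp(-0.5 * delta ** 2 / (s1 ** 2 + s2 ** 2)))
            assert rgb[ch] == pytest.approx(expect, rel=1e-4)
        assert rgb[0] == rgb.max()
        assert rgb[2] < 0.05 * rgb[0]

    def test_salt_chromaticity_is_orange_dominant(self):
        rgb = spectrum_to_rgb(make_emission_spectrum("salt", 1.0))
        r, g, b = rgb / rgb.sum()
        assert r > g > b


class TestRenderFrame:
    def test_blank_with_zero_noise_is_stripe_only(self):
        scene = small_scene(noise_sd=0.0, background=10.0)
        frame = render_frame("blank", scene, seed=3)
        img = frame.pixels.astype(float)
        stripe_rows = slice(scene.stripe_row - 40, scene.stripe_row + 40)
        outside = np.ones(img.shape[0], dtype=bool)
        outside[stripe_rows] = False
        assert np.all(img[outside] == 10)       # background exactly
        assert img[scene.stripe_row].max() > 50  # stripe present
        assert frame.events == []

    def test_fixed_seed_reproduces_identical_bytes(self):
        a = render_frame("chalk", small_scene(), seed=11)
        b = render_frame("chalk", small_scene(), seed=11)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.events == b.events

    def test_chalk_event_count_recovers_poisson_mean(self):
        """Monte-Carlo mean of drawn event counts vs the configured mean 5."""
        scene = small_scene()
        counts = [len(render_frame("chalk", scene, seed=s).events)
                  for s in range(500)]
        mean = np.mean(counts)
        band = 4 * np.sqrt(5.0 / len(counts))
        assert abs(mean - 5.0) < band

    def test_event_colors_separate_in_chromaticity(self):
        """Rendered chalk/pollen/salt event colours occupy disjoint (r, g)
        regions and the blank stripe is near neutral."""
        centroids = {}
        for cls in ("chalk", "pollen", "salt"):
            cols = []
            for s in range(30):
                for e in render_frame(cls, small_scene(), seed=s).events:
                    c = np.asarray(e.color)
                    cols.append(c[:2] / c.sum())
            centroids[cls] = np.mean(cols, axis=0)
        names = list(centroids)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.linalg.norm(centroids[a] - centroids[b]) > 0.05
        blank = render_frame("blank", small_scene(noise_sd=0.0), seed=0).pixels
        bright = blank.reshape(-1, 3).astype(float)
        top = bright[np.argsort(-bright.sum(axis=1))[:30]]
        rg = top[:, :2] / top.sum(axis=1, keepdims=True)
        assert np.linalg.norm(rg.mean(axis=0) - [1 / 3, 1 / 3]) < 0.05

    def test_power_reduction_dims_events(self):
        hi = render_frame("salt", small_scene(noise_sd=0.0), seed=5)
        lo = render_frame("salt", small_scene(noise_sd=0.0, power_fraction=0.5), seed=5)
        assert max(e.peak for e in lo.events) < max(e.peak for e in hi.events)

    def test_oversized_event_radius_rejected(self):
        with pytest.raises(ValueError):
            small_scene(event_sigma_max=200.0)


class TestDatasetBuild:
    def test_tiny_counts_and_split_sizes(self):
        cfg = tiny_dataset_config()
        manifest = build_image_dataset(cfg, seed=5)
        counts = manifest.records.groupby("split").size()
        assert counts["train"] == 24 and counts["val"] == 8
        assert counts["test"] == 8 and counts["robustness"] == 8
        assert (manifest.records[manifest.records.split == "robustness"]
                ["power_fraction"] == 0.85).all()

    def test_single_image_all_train_manifest(self):
        ones = {c: 1 for c in CLASSES}
        zeros = {c: 0 for c in CLASSES}
        cfg = DatasetConfig(curated=ones, train=ones, val=zeros, test=zeros,
                            robustness=zeros, scene=small_scene())
        manifest = build_image_dataset(cfg, seed=1)
        assert len(manifest.records) == 4
        assert set(manifest.records["split"]) == {"train"}

    def test_same_seed_reproduces_manifest_and_pixels(self):
        cfg = tiny_dataset_config()
        m1 = build_image_dataset(cfg, seed=9)
        m2 = build_image_dataset(cfg, seed=9)
        assert m1.records.equals(m2.records)
        assert all(np.array_equal(a, b) for a, b in zip(m1.images, m2.images))

    def test_images_never_shared_between_splits(self):
        manifest = build_image_dataset(tiny_dataset_config(), seed=2)
        keys = manifest.records[["frame_seed", "segment"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_nonblank_curated_segments_contain_events(self):
        """Curation: every non-blank manifest image shows at least one
        emission blob (pixels well above the stripe-free background)."""
        manifest = build_image_dataset(tiny_dataset_config(), seed=4)
        recs = manifest.records
        for i in recs.index[recs.label == "pollen"]:
            img = manifest.images[recs.loc[i, "image_id"]].astype(float)
            assert img.max() > 100

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(curated={"blank": 2, "chalk": 1, "pollen": 1, "salt": 1},
                          train={"blank": 2, "chalk": 1, "pollen": 1, "salt": 1},
                          val={"blank": 1, "chalk": 0, "pollen": 0, "salt": 0})

    def test_materialized_dataset_round_trips(self, tmp_path):
        import imageio.v3 as iio
        import pandas as pd
        cfg = tiny_dataset_config(n_train=1, n_val=1, n_test=0, n_rob=0)
        manifest = build_image_dataset(cfg, seed=3, out_dir=tmp_path)
        on_disk = pd.read_csv(tmp_path / "manifest.csv")
        assert len(on_disk) == len(manifest.records) == 8
        first = on_disk.iloc[0]
        img = iio.imread(tmp_path / first["path"])
        np.testing.assert_array_equal(img, manifest.images[first["image_id"]])


class TestDarkfieldSlides:
    def test_empty_slide(self):
        img, table = render_darkfield_slide("chalk", 0, seed=1)
        assert len(table) == 0
        assert img.mean() < 20   # dark background up to noise

    def test_single_circular_particle_ground_truth(self):
        slide = SlideConfig(sizes={"pollen": (20.0, 0.01, 19.99, 20.01)},
                            shapes={"pollen": (0.98, 0.0)})
        _, table = render_darkfield_slide("pollen", 1, slide, seed=7)
        row = table.iloc[0]
        assert row.d_eq_um == pytest.approx(20.0, abs=0.05)
        assert row.eccentricity < 0.1
        assert row.circularity > 0.9

    def test_pollen_mean_diameter_recovery(self):
        """Truncated-normal mean recovery: 500 draws within 20.7 +- 4*sd/sqrt(n)."""
        slide = SlideConfig(pixel_scale_um=1.0)
        _, table = render_darkfield_slide("pollen", 500, slide, seed=12)
        assert len(table) == 500
        band = 4 * 3.8 / np.sqrt(500)
        assert abs(table.d_eq_um.mean() - 20.7) < band

    def test_diameters_respect_truncation_range(self):
        slide = SlideConfig(pixel_scale_um=1.0)
        _, table = render_darkfield_slide("salt", 200, slide, seed=3)
        assert table.d_eq_um.between(12.0, 37.0).all()

    def test_ground_truth_shape_statistics_near_targets(self):
        slide = SlideConfig(pixel_scale_um=1.0)
        _, table = render_darkfield_slide("chalk", 300, slide, seed=8)
        assert table.circularity.mean() == pytest.approx(0.74, abs=0.03)
        assert table.eccentricity.mean() == pytest.approx(0.60, abs=0.06)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            render_darkfield_slide("blank", 5)
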