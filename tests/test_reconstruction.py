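"""Photon-unit reconstruction: unit conversion, background removal,
noise-map prediction against the Monte-Carlo oracle, and histograms."""

import numpy as np
import pytest

from quantsim import (
    CalibrationError,
    ContrastFit,
    GainFit,
    LayoutError,
    PhaseTriplet,
    monte_carlo_oracle,
    noise_sectioned,
    noise_widefield,
    photon_noise_histograms,
    process_stack,
    process_triplet,
    render_stack,
    render_triplet,
    split_concatenated,
    to_photons,
    uniform_scene,
)

from conftest import sinusoid_triplet


class TestToPhotons:
    def test_conversion_and_subdark_retention(self):
        gain = GainFit(gain_dn_per_photon=2.0, offset_dn=100.0, read_noise_var_dn2=4.0)
        dn = np.array([[300.0, 100.0, 99.0]])
        np.testing.assert_allclose(to_photons(dn, gain), [[100.0, 0.0, -0.5]])


class TestProcessTriplet:
    @pytest.mark.parametrize("phi", [0.0, 0.7, 2.1, 4.4])
    def test_noiseless_closed_form(self, exact_profile, default_camera, phi):
        """F=200, B=400, m=0.5 noiseless: widefield 600, sectioned 200 exactly
        (on the uncorrected path; the bias correction targets noisy data)."""
        scene = uniform_scene((6, 32), 200.0, 400.0, modulation_contrast=0.5,
                              grid_phase_rad=phi)
        concat = render_triplet(scene, default_camera, noiseless=True)
        result = process_triplet(split_concatenated(concat), exact_profile,
                                 bias_corrected=False)
        np.testing.assert_allclose(result.widefield_photons, 600.0, rtol=1e-9)
        np.testing.assert_allclose(result.sectioned_photons, 200.0, rtol=1e-9)

    def test_pure_background_has_zero_sectioned(self, exact_profile, default_camera):
        scene = uniform_scene((6, 32), 0.0, 400.0, modulation_contrast=0.5)
        concat = render_triplet(scene, default_camera, noiseless=True)
        result = process_triplet(split_concatenated(concat), exact_profile,
                                 bias_corrected=False)
        np.testing.assert_allclose(result.sectioned_photons, 0.0, atol=1e-6)
        np.testing.assert_allclose(result.widefield_photons, 400.0, rtol=1e-9)

    def test_ensemble_mean_sectioned_is_unbiased(self, exact_profile, default_camera):
        scene = uniform_scene((16, 24), 200.0, 400.0, modulation_contrast=0.5)
        stats = monte_carlo_oracle(scene, default_camera, exact_profile,
                                   n_reps=800, seed=101)
        assert float(stats.mean["sectioned"].mean()) == pytest.approx(200.0, rel=0.01)

    def test_invalid_contrast_rejected(self):
        with pytest.raises(CalibrationError, match="\\(0, 1\\]"):
            ContrastFit(modulation_contrast=0.0)

    def test_output_contract_four_images_photon_units(self, exact_profile,
                                                      default_camera):
        scene = uniform_scene((9, 15), 100.0, 50.0)
        concat = render_triplet(scene, default_camera, seed=4)
        result = process_triplet(split_concatenated(concat), exact_profile)
        images = result.images()
        assert set(images) == {"widefield", "sectioned",
                               "widefield_noise", "sectioned_noise"}
        for img in images.values():
            assert img.shape == (9, 15)
        assert np.all(images["sectioned"] >= 0)
        assert np.all(images["widefield_noise"] >= 0)
        assert np.all(images["sectioned_noise"] >= 0)


class TestNoiseWidefield:
    def test_poisson_mean_of_three(self):
        gain = GainFit(gain_dn_per_photon=1.0, offset_dn=0.0, read_noise_var_dn2=0.0)
        t = PhaseTriplet(*[np.full((2, 2), 300.0)] * 3)
        np.testing.assert_allclose(noise_widefield(t, gain), 10.0)

    def test_dark_pixels_have_zero_shot_noise(self):
        gain = GainFit(gain_dn_per_photon=1.0, offset_dn=0.0, read_noise_var_dn2=0.0)
        t = PhaseTriplet(*[np.zeros((2, 2))] * 3)
        np.testing.assert_allclose(noise_widefield(t, gain), 0.0)

    def test_read_noise_contributes_in_photon_units(self):
        gain = GainFit(gain_dn_per_photon=2.0, offset_dn=0.0, read_noise_var_dn2=16.0)
        t = PhaseTriplet(*[np.zeros((1, 1))] * 3)
        # 3 * (16/4) / 9 = 4/3 photons^2
        assert noise_widefield(t, gain)[0, 0] == pytest.approx(np.sqrt(4.0 / 3.0))


class TestNoiseSectioned:
    def test_phase_averaged_closed_form(self):
        """For F=200, B=400, m=0.5 the predicted sigma averaged over the grid
        phase equals sqrt((2/3)(F+B))/m = 40 photons."""
        gain = GainFit(gain_dn_per_photon=1.0, offset_dn=0.0, read_noise_var_dn2=0.0)
        sigmas = []
        for phi in np.linspace(0, 2 * np.pi, 60, endpoint=False):
            t = sinusoid_triplet(600.0, 100.0, phi)  # F(1+m cos)+B with Fm=100
            sigmas.append(noise_sectioned(t, 0.5, gain, bias_corrected=False)[0, 0])
        assert np.mean(sigmas) == pytest.approx(40.0, rel=0.01)

    def test_unmodulated_pixel_uses_phase_averaged_limit(self):
        gain = GainFit(gain_dn_per_photon=1.0, offset_dn=0.0, read_noise_var_dn2=0.0)
        t = PhaseTriplet(*[np.full((1, 1), 600.0)] * 3)
        sigma = noise_sectioned(t, 0.5, gain)
        assert np.isfinite(sigma[0, 0])
        assert sigma[0, 0] == pytest.approx(np.sqrt((2.0 / 3.0) * 600.0) / 0.5)

    def test_monotone_in_background(self, exact_profile, default_camera):
        gain = exact_profile.gain
        sigmas = []
        for background in (0.0, 200.0, 400.0, 800.0):
            scene = uniform_scene((4, 16), 200.0, background,
                                  modulation_contrast=0.5)
            concat = render_triplet(scene, default_camera, noiseless=True)
            t = split_concatenated(concat)
            tp = PhaseTriplet(*(to_photons(p, gain) for p in t.phases()))
            sigmas.append(noise_sectioned(tp, 0.5, gain))
        for lo, hi in zip(sigmas, sigmas[1:]):
            assert np.all(hi > lo)

    def test_monotone_decreasing_in_contrast(self, exact_profile, default_camera):
        scene = uniform_scene((4, 16), 200.0, 400.0, modulation_contrast=0.5)
        concat = render_triplet(scene, default_camera, noiseless=True)
        tp = PhaseTriplet(*(to_photons(p, exact_profile.gain)
                            for p in split_concatenated(concat).phases()))
        previous = None
        for m in (0.2, 0.4, 0.6, 0.8, 1.0):
            sigma = noise_sectioned(tp, m, exact_profile.gain)
            if previous is not None:
                assert np.all(sigma < previous)
            previous = sigma

    def test_sectioned_noise_exceeds_widefield_noise(self, exact_profile,
                                                     default_camera):
        scene = uniform_scene((8, 24), 150.0, 300.0, modulation_contrast=0.5)
        concat = render_triplet(scene, default_camera, seed=8)
        result = process_triplet(split_concatenated(concat), exact_profile)
        assert np.all(result.sectioned_noise >= result.widefield_noise)

    def test_invalid_contrast_rejected(self):
        gain = GainFit(gain_dn_per_photon=1.0, offset_dn=0.0, read_noise_var_dn2=0.0)
        t = PhaseTriplet(*[np.ones((1, 1))] * 3)
        with pytest.raises(CalibrationError):
            noise_sectioned(t, 0.0, gain)


class TestNoiseMapFidelity:
    def test_predictions_match_ensemble_std(self, exact_profile, default_camera):
        """Median relative deviation between predicted noise maps and the
        Monte-Carlo ensemble standard deviation is below 5%."""
        scene = uniform_scene((16, 24), 200.0, 400.0, modulation_contrast=0.5)
        stats = monte_carlo_oracle(scene, default_camera, exact_profile,
                                   n_reps=800, seed=55)
        concat = render_triplet(scene, default_camera, noiseless=True)
        predicted = process_triplet(split_concatenated(concat), exact_profile)
        for name, pred in (("widefield", predicted.widefield_noise),
                           ("sectioned", predicted.sectioned_noise)):
            rel = np.abs(pred / stats.std[name] - 1.0)
            assert np.median(rel) < 0.05, name


class TestProcessStack:
    def test_depth_indexing_and_z_step(self, exact_profile, default_camera):
        scene = uniform_scene((8, 16), 100.0, 50.0)
        pages = render_stack([scene] * 5, default_camera, seed=2)
        results = process_stack(pages, exact_profile, z_step_um=2.0)
        assert [r.depth_index for r in results] == [0, 1, 2, 3, 4]
        assert [r.depth_um for r in results] == [0.0, 2.0, 4.0, 6.0, 8.0]

    def test_identical_pages_give_identical_results(self, exact_profile,
                                                    default_camera):
        scene = uniform_scene((8, 16), 100.0, 50.0)
        page = render_triplet(scene, default_camera, seed=3)
        results = process_stack([page, page], exact_profile)
        np.testing.assert_array_equal(
            results[0].sectioned_photons, results[1].sectioned_photons
        )

    def test_empty_stack_rejected(self, exact_profile):
        with pytest.raises(LayoutError, match="empty"):
            process_stack([], exact_profile)

    def test_inconsistent_pages_rejected(self, exact_profile):
        with pytest.raises(LayoutError, match="page 1"):
            process_stack([np.zeros((6, 4)), np.zeros((9, 4))], exact_profile)


class TestHistograms:
    def test_constant_image_single_bin(self, exact_profile):
        from quantsim import QuantResult

        img = np.full((4, 4), 10.0)
        result = QuantResult(img, img, img, img)
        hists = photon_noise_histograms(result, bin_width=5.0)
        for name, (edges, counts) in hists.items():
            assert counts.sum() == 16
            assert (counts > 0).sum() == 1

    def test_nonpositive_bin_width_rejected(self):
        from quantsim import QuantResult

        img = np.ones((2, 2))
        result = QuantResult(img, img, img, img)
        with pytest.raises(ValueError, match="positive"):
            photon_noise_histograms(result, bin_width=0.0)

    def test_sectioning_creates_dark_pixels_and_noisier_pixels(
        self, exact_profile, default_camera
    ):
        """Half-covered scene over uniform background: the sectioned image
        piles counts in the lowest photon bin (background removed), while its
        noise histogram sits above the wide-field one (demodulation noise
        amplification)."""
        f = np.zeros((32, 32))
        f[:, 16:] = 300.0
        scene_f = np.broadcast_to(f, (32, 32))
        from quantsim import SyntheticScene

        scene = SyntheticScene(
            in_focus_photons=scene_f,
            background_photons=np.full((32, 32), 200.0),
            modulation_contrast=0.5,
        )
        concat = render_triplet(scene, default_camera, seed=77)
        result = process_triplet(split_concatenated(concat), exact_profile)
        hists = photon_noise_histograms(result, bin_width=25.0)
        assert hists["sectioned"][1][0] > hists["widefield"][1][0]

        def hist_mean(edges, counts):
            centers = (edges[:-1] + edges[1:]) / 2.0
            return float((centers * counts).sum() / counts.sum())

        assert hist_mean(*hists["sectioned_noise"]) > hist_mean(*hists["widefield_noise"])
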