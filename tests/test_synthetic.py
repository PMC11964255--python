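import numpy as np
import pytest

from collafib import mechanics, synthetic
from collafib.constants import DBAND_BLUR_MAX_NM, DBAND_DEPTH_MIN


class TestPhantomImageConfig:
    def test_non_integer_grid_rejected(self):
        with pytest.raises(ValueError, match="integer pixel grid"):
            synthetic.PhantomImageConfig(field_size_um=1.5, px_per_um=51)

    def test_zero_fibrils_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_fibril_image(synthetic.PhantomImageConfig(n_fibrils=0))

    @pytest.mark.parametrize("field,value", [("dband_depth", 1.5), ("kink_prob", -0.1),
                                             ("fibril_width_nm", -1.0)])
    def test_invalid_ranges_rejected(self, field, value):
        with pytest.raises(ValueError):
            synthetic.PhantomImageConfig(**{field: value})


class TestGenerateFibrilImage:
    def test_seeded_determinism(self):
        cfg = synthetic.PhantomImageConfig(field_size_um=2.0, n_fibrils=10,
                                           kink_prob=0.5, noise_sigma_nm=1.0, seed=42)
        img_a, lab_a = synthetic.generate_fibril_image(cfg)
        img_b, lab_b = synthetic.generate_fibril_image(cfg)
        assert np.array_equal(img_a.heights, img_b.heights)
        assert lab_a.equals(lab_b)

    def test_zero_banding_depth_labels_absent(self):
        cfg = synthetic.PhantomImageConfig(field_size_um=2.0, n_fibrils=10,
                                           dband_depth=0.0, seed=1)
        _, labels = synthetic.generate_fibril_image(cfg)
        assert (labels["dbanding"] == 0).all()

    def test_label_cutoffs_respected(self):
        # just above the blur cutoff -> banding label false even at full depth
        cfg = synthetic.PhantomImageConfig(field_size_um=2.0, n_fibrils=10,
                                           dband_depth=0.8,
                                           blur_sigma_nm=DBAND_BLUR_MAX_NM + 1.0, seed=1)
        _, labels = synthetic.generate_fibril_image(cfg)
        assert (labels["dbanding"] == 0).all()
        cfg2 = synthetic.PhantomImageConfig(field_size_um=2.0, n_fibrils=10,
                                            dband_depth=DBAND_DEPTH_MIN, seed=1)
        _, labels2 = synthetic.generate_fibril_image(cfg2)
        assert (labels2["dbanding"] == 1).all()

    def test_orientation_label_follows_mode(self):
        cfg = synthetic.PhantomImageConfig(field_size_um=2.0, n_fibrils=10,
                                           orientation_mode="aligned", seed=1)
        _, labels = synthetic.generate_fibril_image(cfg)
        assert (labels["random_orientation"] == 0).all()

    def test_kinked_rois_labelled_nonlinear(self):
        cfg = synthetic.PhantomImageConfig(field_size_um=10.0, n_fibrils=100,
                                           kink_prob=1.0, kink_spacing_um=0.35, seed=3)
        _, labels = synthetic.generate_fibril_image(cfg)
        assert (labels["linearity"] == 0).mean() > 0.5
        straight = synthetic.PhantomImageConfig(field_size_um=10.0, n_fibrils=100, seed=3)
        _, labels2 = synthetic.generate_fibril_image(straight)
        assert (labels2["linearity"] == 1).all()

    def test_dband_period_autocorrelation_oracle(self):
        """Independent periodogram oracle: the dominant axial period of an
        aligned, unblurred banded phantom is 67 nm +/- 5%."""
        cfg = synthetic.PhantomImageConfig(
            field_size_um=10.0, n_fibrils=12, orientation_mode="aligned",
            aligned_axis_deg=0.0, dband_depth=0.8, dband_period_nm=67.0, seed=7,
        )
        image, _ = synthetic.generate_fibril_image(cfg)
        h = image.heights
        px_nm = image.px_size_nm
        periods = []
        pad = 8192
        freqs = np.fft.rfftfreq(pad)  # cycles / px
        band = (freqs > 0.1) & (freqs < 0.5)
        for row in range(h.shape[0]):
            profile = h[row]
            if profile.max() < 0.5 * cfg.fibril_height_nm:
                continue
            spec = np.abs(np.fft.rfft(profile - profile.mean(), pad)) ** 2
            f_peak = freqs[band][np.argmax(spec[band])]
            periods.append(px_nm / f_peak)
        assert len(periods) > 20
        mean_period = float(np.mean(periods))
        assert abs(mean_period - 67.0) / 67.0 < 0.05


class TestGenerateForceCurve:
    def test_noiseless_matches_closed_form(self):
        cfg = synthetic.ForceCurveConfig(E_true_GPa=3.0, seed=0)
        curve = synthetic.generate_force_curve(cfg)
        C = mechanics.hertz_prefactor(cfg.half_angle_deg, cfg.poisson_ratio)
        delta_max = np.sqrt(cfg.max_load_nN / (C * cfg.E_true_GPa))
        delta = np.clip(delta_max - curve.distance_nm, 0.0, None)
        np.testing.assert_allclose(curve.force_nN, C * cfg.E_true_GPa * delta ** 2,
                                   rtol=0, atol=1e-12)

    def test_doubling_modulus_doubles_force_at_fixed_depth(self):
        c1 = synthetic.generate_force_curve(
            synthetic.ForceCurveConfig(E_true_GPa=2.0, contact_offset_nm=0.0))
        c2 = synthetic.generate_force_curve(
            synthetic.ForceCurveConfig(E_true_GPa=4.0, contact_offset_nm=0.0))
        # compare at matched indentation depths via the closed form
        C = mechanics.hertz_prefactor()
        d1 = np.sqrt(100.0 / (C * 2.0)) - c1.distance_nm
        d2 = np.sqrt(100.0 / (C * 4.0)) - c2.distance_nm
        f1 = np.interp(3.0, d1, c1.force_nN)
        f2 = np.interp(3.0, d2, c2.force_nN)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-3)

    def test_contact_depth_scale_at_paper_parameters(self):
        """Closed-form inversion of the forward model at the printed
        control modulus and load cap; same-order as the ~10 nm depth scale
        (the exact closed form gives ~7.6 nm, see notes)."""
        depth = mechanics.contact_depth_for_load(100.0, 4.82)
        expected = np.sqrt(100.0 / (mechanics.hertz_prefactor(20.8, 0.5) * 4.82))
        assert depth == pytest.approx(expected, rel=1e-12)
        assert 5.0 < depth < 15.0

    def test_invalid_modulus_rejected(self):
        with pytest.raises(ValueError):
            synthetic.ForceCurveConfig(E_true_GPa=-1.0)


class TestGenerateDecayHistogram:
    def test_total_counts_near_n_photons(self):
        cfg = synthetic.DecayConfig(n_photons=1e5, seed=5)
        hist = synthetic.generate_decay_histogram(cfg)
        assert abs(hist.total_photons - 1e5) < 4 * np.sqrt(1e5)

    def test_single_exponential_log_linear(self):
        cfg = synthetic.DecayConfig(amplitudes=(1.0, 0.0, 0.0),
                                    lifetimes_ns=(2.0, 1.0, 1.0), n_photons=1e6)
        centers, mean = synthetic.expected_decay_counts(cfg)
        sel = mean > 10
        slope = np.polyfit(centers[sel], np.log(mean[sel]), 1)[0]
        assert slope == pytest.approx(-1.0 / 2.0, rel=1e-3)

    def test_bin_means_match_analytic_integral(self):
        """Independent oracle: closed-form per-bin integral of the decay,
        recomputed here, matches sampled counts within Monte-Carlo error."""
        cfg = synthetic.DecayConfig(amplitudes=(0.5, 0.3, 0.2),
                                    lifetimes_ns=(0.5, 2.0, 6.0),
                                    n_photons=1e6, seed=11)
        hist = synthetic.generate_decay_histogram(cfg)
        edges = np.arange(cfg.n_bins + 1) * cfg.bin_width_ps / 1000.0
        a = np.array(cfg.amplitudes)
        tau = np.array(cfg.lifetimes_ns)
        mass = sum(
            a[i] * tau[i] * (np.exp(-edges[:-1] / tau[i]) - np.exp(-edges[1:] / tau[i]))
            for i in range(3)
        )
        mean = cfg.n_photons * mass / mass.sum()
        sel = mean >= 10.0  # populated bins: standardized residuals ~ N(0, 1)
        resid = (hist.counts[sel] - mean[sel]) / np.sqrt(mean[sel])
        assert abs(resid.mean()) < 0.1
        assert 0.8 < resid.std() < 1.2

    def test_all_zero_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.DecayConfig(amplitudes=(0.0, 0.0, 0.0))

    def test_non_integer_bin_count_rejected(self):
        with pytest.raises(ValueError):
            synthetic.DecayConfig(window_ns=200.0, bin_width_ps=51.0)

    def test_determinism(self):
        cfg = synthetic.DecayConfig(seed=9)
        a = synthetic.generate_decay_histogram(cfg)
        b = synthetic.generate_decay_histogram(cfg)
        assert np.array_equal(a.counts, b.counts)


class TestGenerateFtirSpectrum:
    def test_native_band_positions(self):
        spec = synthetic.generate_ftir_spectrum(synthetic.SpectrumConfig())
        wn, ab = spec.wavenumbers_cm1, spec.absorbance
        for target in (1630.0, 1540.0, 1205.0, 1235.0, 1280.0):
            sel = np.abs(wn - target) <= 5.0
            window = np.abs(wn - target) <= 20.0
            assert ab[sel].max() >= ab[window].max() - 1e-9

    def test_denatured_has_no_triplet(self):
        spec = synthetic.generate_ftir_spectrum(synthetic.SpectrumConfig(state="denatured"))
        wn, ab = spec.wavenumbers_cm1, spec.absorbance
        sel = (wn >= 1200.0) & (wn <= 1300.0)
        interior = ab[sel][1:-1]
        assert not np.any((interior > ab[sel][:-2]) & (interior > ab[sel][2:]) &
                          (interior > 0.01))

    def test_band_outside_range_rejected(self):
        with pytest.raises(ValueError):
            synthetic.SpectrumConfig(bands={"oops": (5000.0, 10.0, 1.0),
                                            **synthetic.NATIVE_BANDS})

    def test_denatured_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            synthetic.SpectrumConfig(state="denatured", bands=synthetic.NATIVE_BANDS)
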