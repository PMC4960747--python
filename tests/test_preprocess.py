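import numpy as np
import pytest

from gluedit.preprocess import (
    apodize,
    auto_phase,
    combine_channels,
    eddy_current_correct,
    preprocess_set,
    to_spectrum,
)
from gluedit.quantify import fit_lorentzian
from gluedit.simulator import (
    default_artifacts,
    make_phantom_system,
    simulate_acquisition,
)
from gluedit.spectral_model import RawFID, lorentzian, phantom_protocol, ppm_axis


def make_fid(samples, dwell=1 / 6000.0, n_avg=1, ch=0):
    return RawFID(samples=np.asarray(samples, complex), dwell_s=dwell,
                  n_averages=n_avg, channel_index=ch)


def decaying_line(params, offset_hz, fwhm_hz, amp=1.0, phase=0.0):
    t = np.arange(params.n_points) * params.dwell_s
    return amp * np.exp(1j * phase) * np.exp(
        2j * np.pi * offset_hz * t - np.pi * fwhm_hz * t
    )


class TestCombineChannels:
    def test_single_channel_is_unit_phase_rotation(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, 0.0, 15.0, phase=0.9))
        out = combine_channels([fid], [fid])
        np.testing.assert_allclose(np.abs(out.samples), np.abs(fid.samples), rtol=1e-12)
        # phase of the first sample is zeroed by the matched filter
        assert abs(np.angle(out.samples[0])) < 1e-12

    def test_two_channel_matched_filter_oracle(self, phantom_params):
        base = decaying_line(phantom_params, -100.0, 15.0)
        ch0 = make_fid(base)
        ch1 = make_fid(base * np.exp(1j * np.pi / 2))
        combined = combine_channels([ch0, ch1], [ch0, ch1])
        # exhaustive phase-rotation oracle: best coherent sum of two equal-
        # magnitude channels has twice the single-channel magnitude, then
        # weight normalization (sum |w|^2 = 1) divides by sqrt(2)
        phis = np.linspace(0, 2 * np.pi, 721)
        best = max(
            np.abs(base[0] + base[0] * np.exp(1j * (np.pi / 2 - p))) for p in phis
        )
        assert np.abs(combined.samples[0]) == pytest.approx(best / np.sqrt(2), rel=1e-6)

    def test_combination_improves_snr(self, fsi, ir):
        params = phantom_protocol(n_points=512)
        system = make_phantom_system(9.0)
        snr_combined, snr_single = [], []
        for seed in range(100):
            noisy = simulate_acquisition(
                system, params, default_artifacts(seed=seed, noise_sigma=20.0),
                fsi, ir, "phantom",
            )
            clean = simulate_acquisition(
                system, params, default_artifacts(seed=seed, noise_sigma=0.0),
                fsi, ir, "phantom",
            )
            wn = [f.copy_with(f.samples / f.n_averages) for f in noisy.blocks["water_ref"]]
            wc = [f.copy_with(f.samples / f.n_averages) for f in clean.blocks["water_ref"]]
            comb_noisy = combine_channels(wn, wn)
            comb_clean = combine_channels(wc, wn)  # same weights, clean signal
            noise = comb_noisy.samples - comb_clean.samples
            snr_combined.append(
                np.linalg.norm(comb_clean.samples) / np.linalg.norm(noise)
            )
            per_ch = [
                np.linalg.norm(c.samples) / np.linalg.norm(n.samples - c.samples)
                for n, c in zip(wn, wc)
            ]
            snr_single.append(max(per_ch))
        assert np.mean(snr_combined) >= np.mean(snr_single)

    def test_zero_water_errors(self, phantom_params):
        z = make_fid(np.zeros(phantom_params.n_points))
        with pytest.raises(ValueError):
            combine_channels([z], [z])


class TestEddyCurrentCorrection:
    def test_real_positive_water_is_identity(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -698.0, 15.0))
        water = make_fid(np.abs(decaying_line(phantom_params, 0.0, 15.0)) + 0.0j)
        out, _ = eddy_current_correct(fid, water)
        np.testing.assert_allclose(out.samples, fid.samples, rtol=1e-12)

    def test_water_self_correction_is_real(self, phantom_params):
        t = np.arange(phantom_params.n_points) * phantom_params.dwell_s
        phi = 1.2 * np.exp(-t / 0.004)
        water = make_fid(decaying_line(phantom_params, 0.0, 15.0) * np.exp(1j * phi))
        out, _ = eddy_current_correct(water, water)
        assert np.max(np.abs(out.samples.imag)) < 1e-12
        assert np.all(out.samples.real >= 0)

    @pytest.mark.parametrize(
        "conc,rel_tol",
        [
            # water-only voxel: the water FID's instantaneous phase IS the
            # transient, so the correction is exact
            (0.0, 1e-10),
            # with metabolites present their 1.6e-4 contribution to the
            # unsuppressed water FID bounds the achievable accuracy
            (9.0, 1e-3),
        ],
    )
    def test_shared_transient_removed(self, fsi, ir, phantom_params, conc, rel_tol):
        """Klose closure: correcting with the simulated water reference
        reproduces the transient-free simulation."""
        system = make_phantom_system(conc)
        with_eddy = default_artifacts(
            noise_sigma=0.0, channel_sensitivities=((1.0, 0.0),)
        )
        no_eddy = default_artifacts(
            noise_sigma=0.0, eddy_terms=(), channel_sensitivities=((1.0, 0.0),)
        )
        acq = simulate_acquisition(system, phantom_params, with_eddy, fsi, ir, "phantom")
        ref = simulate_acquisition(system, phantom_params, no_eddy, fsi, ir, "phantom")
        water = acq.blocks["water_ref"][0]
        water = water.copy_with(water.samples / water.n_averages)
        for label in ("control1", "selinv1"):
            fid = acq.blocks[label][0]
            fid = fid.copy_with(fid.samples / fid.n_averages)
            corrected, _ = eddy_current_correct(fid, water)
            expect = ref.blocks[label][0]
            expect = expect.samples / expect.n_averages
            np.testing.assert_allclose(
                corrected.samples, expect, rtol=0,
                atol=rel_tol * np.abs(expect).max(),
            )

    def test_low_signal_phase_carry_forward_flagged(self, phantom_params):
        water_samples = decaying_line(phantom_params, 0.0, 400.0)  # decays to ~0
        water = make_fid(water_samples)
        fid = make_fid(decaying_line(phantom_params, -698.0, 15.0))
        out, flagged = eddy_current_correct(fid, water, magnitude_floor=1e-3)
        assert flagged
        assert np.isfinite(out.samples).all()


class TestApodize:
    def test_zero_lb_is_identity(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -100.0, 15.0))
        np.testing.assert_array_equal(apodize(fid, 0.0).samples, fid.samples)

    def test_linewidths_add(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -698.4, 15.0))
        spec = to_spectrum(apodize(fid, 7.0), phantom_params)
        fit = fit_lorentzian(spec, (2.1, 2.6), f0_mhz=297.2)
        assert fit.fwhm_hz == pytest.approx(22.0, abs=0.1)

    def test_first_sample_and_integral_preserved(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -100.0, 15.0))
        assert apodize(fid, 7.0).samples[0] == fid.samples[0]


class TestToSpectrum:
    def test_delta_fid_gives_flat_spectrum(self, phantom_params):
        s = np.zeros(phantom_params.n_points, complex)
        s[0] = 1.0
        spec = to_spectrum(make_fid(s), phantom_params)
        assert np.ptp(np.abs(spec.values)) < 1e-12

    def test_offset_maps_to_expected_ppm(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -698.4, 15.0))
        spec = to_spectrum(fid, phantom_params)
        peak = spec.ppm_axis[np.argmax(np.abs(spec.values))]
        assert abs(peak - 2.35) <= 6000.0 / 4096 / 297.2 + 1e-9

    def test_parseval(self, phantom_params):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(4096) + 1j * rng.standard_normal(4096)
        spec = np.fft.fft(s)
        assert np.sum(np.abs(s) ** 2) == pytest.approx(
            np.sum(np.abs(spec) ** 2) / 4096, rel=1e-12
        )

    def test_lineshape_matches_analytic_lorentzian(self, phantom_params):
        """A decaying complex sinusoid transforms into the closed-form
        complex Lorentzian with fwhm = decay_rate / pi."""
        fwhm, off = 15.0, -698.4
        fid = make_fid(decaying_line(phantom_params, off, fwhm, amp=2.5))
        spec = to_spectrum(fid, phantom_params)
        f_hz = (spec.ppm_axis - 4.7) * 297.2
        expect = lorentzian(f_hz, 2.5, off, fwhm)
        mask = np.abs(f_hz - off) < 300
        np.testing.assert_allclose(
            spec.values[mask], expect[mask],
            atol=2e-3 * np.abs(expect).max(),
        )


class TestAutoPhase:
    def test_already_real_water_gives_zero_phase(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, 0.0, 15.0))
        spec = to_spectrum(fid, phantom_params)
        out = auto_phase(spec, spec)
        assert abs(out.provenance[-1]["phi0_rad"]) < 1e-9

    @pytest.mark.parametrize("phi", [np.pi / 4, -1.1, 2.6])
    def test_recovers_applied_phase(self, phantom_params, phi):
        fid = make_fid(decaying_line(phantom_params, 0.0, 15.0))
        spec = to_spectrum(fid, phantom_params)
        rotated = spec.with_values(spec.values * np.exp(1j * phi))
        out = auto_phase(rotated, rotated)
        assert out.provenance[-1]["phi0_rad"] == pytest.approx(-phi, abs=0.01)

    def test_idempotent(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, 0.0, 15.0))
        spec = to_spectrum(fid, phantom_params)
        rotated = spec.with_values(spec.values * np.exp(1j * 0.8))
        once = auto_phase(rotated, rotated)
        twice = auto_phase(once, once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestPreprocessSet:
    def test_water_suppression_visible_after_processing(
        self, fsi, ir, phantom_params, noiseless_artifacts
    ):
        acq = simulate_acquisition(
            make_phantom_system(9.0), phantom_params, noiseless_artifacts,
            fsi, ir, "phantom",
        )
        proc = preprocess_set(acq)
        wmask = np.abs(proc["water_ref"].ppm_axis - 4.7) < 0.3
        ref_peak = proc["water_ref"].values.real[wmask].max()
        c1_peak = proc["control1"].values.real[wmask].max()
        assert ref_peak / c1_peak >= 100.0

    def test_blocks_share_weights_and_phase(self, fsi, ir, phantom_params,
                                            noiseless_artifacts):
        acq = simulate_acquisition(
            make_phantom_system(9.0), phantom_params, noiseless_artifacts,
            fsi, ir, "phantom",
        )
        proc = preprocess_set(acq)
        phis = {
            label: next(
                step["phi0_rad"] for step in spec.provenance
                if step.get("step") == "auto_phase"
            )
            for label, spec in proc.items()
        }
        assert len(set(phis.values())) == 1

    def test_average_normalization_equalizes_water_integral(
        self, fsi, ir, clean_artifacts
    ):
        # 8 water averages vs 32 control averages: after normalization the
        # water line integral (before suppression scaling) matches
        params = phantom_protocol(
            averages={"water_ref": 8, "control1": 32, "selinv1": 32}
        )
        art = default_artifacts(
            noise_sigma=0.0, eddy_terms=(),
            channel_sensitivities=((1.0, 0.0),),
            water_suppression_factor=1.0,  # disable suppression for this check
        )
        acq = simulate_acquisition(
            make_phantom_system(0.0), params, art, fsi, ir, "phantom"
        )
        proc = preprocess_set(acq)
        wmask = np.abs(proc["water_ref"].ppm_axis - 4.7) < 0.3
        ref = np.trapezoid(proc["water_ref"].values.real[wmask])
        c1 = np.trapezoid(proc["control1"].values.real[wmask])
        # equality is limited by the ~1e-7 off-resonance tail of the control
        # inversion pulse acting on the water line
        assert c1 == pytest.approx(ref, rel=1e-5)

    def test_linear_in_input(self, fsi, ir, phantom_params, clean_artifacts):
        acq = simulate_acquisition(
            make_phantom_system(9.0), phantom_params, clean_artifacts,
            fsi, ir, "phantom",
        )
        proc1 = preprocess_set(acq)
        for label in acq.blocks:
            for fid in acq.blocks[label]:
                fid.samples = fid.samples * 3.0
        proc3 = preprocess_set(acq)
        np.testing.assert_allclose(
            proc3["selinv1"].values, 3.0 * proc1["selinv1"].values,
            atol=1e-9 * np.abs(proc1["selinv1"].values).max(),
        )

    def test_ecc_and_apodization_commute(self, phantom_params):
        fid = make_fid(decaying_line(phantom_params, -698.4, 15.0))
        t = np.arange(phantom_params.n_points) * phantom_params.dwell_s
        water = make_fid(
            decaying_line(phantom_params, 0.0, 15.0)
            * np.exp(1j * 0.9 * np.exp(-t / 0.01))
        )
        a, _ = eddy_current_correct(apodize(fid, 7.0), water)
        b = apodize(eddy_current_correct(fid, water)[0], 7.0)
        np.testing.assert_allclose(a.samples, b.samples, rtol=1e-12, atol=1e-300)

    def test_missing_water_ref_errors(self, fsi, ir, phantom_params,
                                      clean_artifacts):
        acq = simulate_acquisition(
            make_phantom_system(9.0), phantom_params, clean_artifacts,
            fsi, ir, "phantom",
        )
        del acq.blocks["water_ref"]
        with pytest.raises(ValueError, match="water_ref"):
            preprocess_set(acq)
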