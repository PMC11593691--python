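import numpy as np
import pandas as pd
import pytest

from tanspec.calibration import calibrate
from tanspec.errors import InvalidParameterError
from tanspec.models import fit_plsr
from tanspec.synthetic import (
    ANALYTES,
    DEFAULT_ORIGIN_PROFILES,
    BaselineSpec,
    OriginProfile,
    PureSpectrum,
    default_pure_spectra,
    make_dataset,
    simulate_concentrations,
    simulate_raw_frames,
    simulate_reflectance,
)


class TestOriginProfiles:
    def test_default_reference_values(self):
        sd = DEFAULT_ORIGIN_PROFILES[0]
        assert sd.origin == "SD"
        assert sd.mean_mgg == (1.090, 2.807, 3.616)
        assert sd.sd_mgg == (0.373, 0.983, 2.070)

    def test_negative_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            OriginProfile("X", (-1.0, 0.0, 0.0), (0.1, 0.1, 0.1))


class TestPureSpectra:
    def test_each_analyte_has_a_swir_band(self):
        for p in default_pure_spectra():
            assert any(1220 <= c <= 2580 for c in p.band_centers_nm)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidParameterError):
            PureSpectrum("x", (1300.0,), (40.0,), (-0.1,))


class TestSimulateConcentrations:
    def test_zero_variance_gives_exact_means(self):
        prof = OriginProfile("Z", (1.0, 2.0, 3.0), (0.0, 0.0, 0.0))
        df = simulate_concentrations([prof], n_per_origin=5, seed=0)
        assert np.allclose(df[list(ANALYTES)], [1.0, 2.0, 3.0])

    def test_total_is_exact_component_sum(self):
        df = simulate_concentrations(n_per_origin=20, seed=3)
        assert np.array_equal(
            df["total"].to_numpy(), df[list(ANALYTES)].sum(axis=1).to_numpy()
        )

    def test_sample_means_match_profile_parameters(self):
        """Monte-Carlo check of the truncated-normal sampler: per-origin means
        within 3*SD/sqrt(n) of the profile means (truncation bias is well
        below that tolerance for these mean/SD ratios, except for strongly
        truncated analytes which shift upward but stay inside the band)."""
        n = 84
        df = simulate_concentrations(n_per_origin=n, seed=42)
        for prof in DEFAULT_ORIGIN_PROFILES:
            sub = df[df["origin"] == prof.origin]
            for k, a in enumerate(ANALYTES):
                m, s = prof.mean_mgg[k], prof.sd_mgg[k]
                # truncation at zero only raises the mean; allow that shift
                tol = 3 * s / np.sqrt(n)
                from scipy import stats

                trunc_mean = stats.truncnorm.mean((0 - m) / s, np.inf, loc=m, scale=s)
                assert abs(sub[a].mean() - trunc_mean) < tol

    def test_contents_nonnegative(self):
        df = simulate_concentrations(n_per_origin=200, seed=1)
        assert (df[list(ANALYTES)] >= 0).all().all()

    def test_empty_profiles_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_concentrations([], n_per_origin=5)


class TestSimulateReflectance:
    def _noiseless(self, samples, axis):
        return simulate_reflectance(
            samples,
            axis=axis,
            scatter_sd=0.0,
            baseline=BaselineSpec(offset_sd=0.0),
            noise_sd=0.0,
        )

    def test_noiseless_equal_concentrations_identical_spectra(self, mini_axis):
        prof = OriginProfile("Z", (1.0, 2.0, 3.0), (0.0, 0.0, 0.0))
        samples = simulate_concentrations([prof], n_per_origin=3, seed=0)
        ds = self._noiseless(samples, mini_axis)
        assert np.array_equal(ds.reflectance[0], ds.reflectance[1])
        assert np.array_equal(ds.reflectance[0], ds.reflectance[2])

    def test_zero_concentration_zero_baseline_gives_unit_reflectance(self, mini_axis):
        prof = OriginProfile("Z", (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        samples = simulate_concentrations([prof], n_per_origin=2, seed=0)
        zero_base = BaselineSpec(
            vis_edge_amp=0.0, shared_bands=(), origin_bands={}, offset_sd=0.0
        )
        ds = simulate_reflectance(
            samples, axis=mini_axis, scatter_sd=0, baseline=zero_base, noise_sd=0
        )
        assert np.allclose(ds.reflectance, 1.0)

    def test_absorbance_affine_in_concentration(self, mini_axis):
        """Beer-Lambert: -log(reflectance) at a band center is affine in the
        analyte concentration across noiseless samples (R^2 = 1)."""
        rows = [
            {"sample_id": f"s{i}", "origin": "Z", "tan_i": c, "tan_iia": 0.0, "cts": 0.0}
            for i, c in enumerate([0.2, 0.5, 1.1, 1.9, 2.5])
        ]
        samples = pd.DataFrame(rows)
        samples["total"] = samples[list(ANALYTES)].sum(axis=1)
        ds = self._noiseless(samples, mini_axis)
        band_nm = default_pure_spectra()[0].band_centers_nm[0]
        j = int(np.argmin(np.abs(mini_axis.wavelengths_nm - band_nm)))
        absorb = -np.log(ds.reflectance[:, j])
        conc = samples["tan_i"].to_numpy()
        fit = np.polyfit(conc, absorb, 1)
        resid = absorb - np.polyval(fit, conc)
        ss_tot = np.sum((absorb - absorb.mean()) ** 2)
        assert 1 - np.sum(resid**2) / ss_tot > 1 - 1e-10

    def test_reflectance_within_physical_range(self, mini_dataset):
        r = mini_dataset.reflectance
        assert r.min() > 0 and r.max() <= 1.2

    def test_seed_determinism_bit_identical(self, mini_axis):
        a = make_dataset(seed=99, n_per_origin=4, axis=mini_axis)
        b = make_dataset(seed=99, n_per_origin=4, axis=mini_axis)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert a.samples.equals(b.samples)
        assert a.truth.equals(b.truth)

    def test_origin_mean_spectra_differ_in_swir(self, mini_dataset):
        """SD- and HB-origin mean spectra must differ well above the noise
        floor inside the tanshinone-informative 1220-2580 nm region."""
        wl = mini_dataset.axis.wavelengths_nm
        region = (wl >= 1220) & (wl <= 2580)
        X = mini_dataset.reflectance
        origin = mini_dataset.samples["origin"].to_numpy()
        mean_sd = X[origin == "SD"].mean(axis=0)
        mean_hb = X[origin == "HB"].mean(axis=0)
        noise_sd = float(mini_dataset.truth["noise_sd"].iloc[0])
        assert np.max(np.abs(mean_sd - mean_hb)[region]) > 10 * noise_sd

    def test_noiseless_concentration_recovery_by_plsr(self, noiseless_dataset):
        """With no noise, PLSR on absorbance with one LV per analyte refits
        each analyte's concentration exactly (training R^2 = 1)."""
        ds = noiseless_dataset
        A = -np.log(ds.reflectance)
        for a in ANALYTES:
            y = ds.samples[a].to_numpy()
            model = fit_plsr(A, y, n_lv=len(ANALYTES))
            pred = model.predict(A)
            r2 = np.corrcoef(y, pred)[0, 1] ** 2
            assert r2 > 1 - 1e-6

    def test_mismatched_axis_rejected(self, mini_axis):
        samples = simulate_concentrations(n_per_origin=2, seed=0)
        bad = (
            PureSpectrum("tan_i", (2220.0,), (45.0,), (0.1,)),
            PureSpectrum("tan_iia", (1740.0,), (45.0,), (0.1,)),
        )
        with pytest.raises(InvalidParameterError):
            simulate_reflectance(samples, pures=bad, axis=mini_axis)


class TestSimulateRawFrames:
    def test_calibration_inverts_frames(self, mini_dataset):
        frames = simulate_raw_frames(mini_dataset)
        assert np.allclose(
            calibrate(frames), mini_dataset.reflectance, rtol=0, atol=1e-12
        )

    def test_unit_reflectance_gives_white_frame(self, mini_axis):
        prof = OriginProfile("Z", (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        samples = simulate_concentrations([prof], n_per_origin=2, seed=0)
        zero_base = BaselineSpec(vis_edge_amp=0.0, shared_bands=(), origin_bands={}, offset_sd=0.0)
        ds = simulate_reflectance(samples, axis=mini_axis, scatter_sd=0, baseline=zero_base, noise_sd=0)
        frames = simulate_raw_frames(ds, white_level=800.0, dark_level=50.0)
        assert np.allclose(frames.raw, frames.white)

    def test_unit_levels_give_raw_equal_reflectance(self, mini_dataset):
        frames = simulate_raw_frames(mini_dataset, white_level=1.0, dark_level=0.0)
        assert np.allclose(frames.raw, mini_dataset.reflectance)

    def test_white_below_dark_rejected(self, mini_dataset):
        with pytest.raises(InvalidParameterError):
            simulate_raw_frames(mini_dataset, white_level=10.0, dark_level=10.0)
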