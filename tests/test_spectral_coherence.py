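"""Welch cross-spectra, MSC/phase, bands, AR(1) surrogates, partial coherence."""

import numpy as np
import pytest
from scipy import signal as sps

from lcmem import spectral_coherence as spec
from lcmem.config import CohortConfig, CouplingSpec
from lcmem.synthetic_data import gen_coupled_series

GRID = spec.SpectralGrid()  # 90 bins on 0-0.5 Hz at 1 Hz


def _profile(x, y, grid=GRID):
    m = spec.cross_spectra({"x": x, "y": y}, grid)
    return spec.coherence_profile(m, ("x", "y")), m


class TestCrossSpectra:
    def test_white_noise_autospectrum_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10**4)
        m = spec.cross_spectra({"x": x}, GRID)
        psd = np.real(m.pair("x", "x"))
        # integral of the one-sided PSD equals the variance
        area = np.trapezoid(psd, m.freqs)
        assert area == pytest.approx(np.var(x), rel=0.05)
        # flat within sampling error: no bin strays far from the mean level
        assert np.all(np.abs(psd[1:-1] / psd[1:-1].mean() - 1.0) < 0.5)

    def test_sinusoid_peak_location(self):
        t = np.arange(2000.0)
        x = np.sin(2 * np.pi * 0.2 * t)
        m = spec.cross_spectra({"x": x}, GRID)
        peak = m.freqs[np.argmax(np.real(m.pair("x", "x")))]
        assert abs(peak - 0.2) <= m.freqs[1]

    def test_hermitian_symmetry(self):
        rng = np.random.default_rng(1)
        m = spec.cross_spectra({"a": rng.standard_normal(900), "b": rng.standard_normal(900)}, GRID)
        assert np.allclose(m.pair("a", "b"), np.conj(m.pair("b", "a")))
        assert np.all(np.real(m.pair("a", "a")) >= 0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 1200))
        m = spec.cross_spectra({"x": x, "y": y}, GRID)
        f_ref, p_ref = sps.welch(x, fs=GRID.fs, window="hamming", nperseg=GRID.nperseg,
                                 noverlap=GRID.noverlap, detrend="constant")
        assert np.allclose(m.freqs, f_ref)
        assert np.allclose(np.real(m.pair("x", "x")), p_ref, rtol=1e-10)
        # scipy's csd conjugates its first argument
        _, c_ref = sps.csd(x, y, fs=GRID.fs, window="hamming", nperseg=GRID.nperseg,
                           noverlap=GRID.noverlap, detrend="constant")
        assert np.allclose(np.conj(m.pair("x", "y")), c_ref, rtol=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(spec.SpectralError):
            spec.cross_spectra({"x": np.zeros(100)}, GRID)


class TestMscAndPhase:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(900)
        prof, _ = _profile(x, x.copy())
        assert np.allclose(prof.msc, 1.0, atol=1e-10)
        assert np.allclose(prof.phase, 0.0, atol=1e-8)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 1500))
        m = spec.cross_spectra({"x": x, "y": y}, GRID)
        ab = spec.msc(m, ("x", "y")).msc
        ba = spec.msc(m, ("y", "x")).msc
        assert np.all((ab >= 0) & (ab <= 1))
        assert np.allclose(ab, ba)
        pab = spec.phase_lag(m, ("x", "y")).phase
        pba = spec.phase_lag(m, ("y", "x")).phase
        # antisymmetric modulo 2*pi (bins at exactly +/- pi are self-negative)
        assert np.allclose(np.angle(np.exp(1j * (pab + pba))), 0.0, atol=1e-8)

    def test_no_coherence_expectation_one_over_k(self):
        # with K non-overlapping segments, E[MSC] = 1/K for independent noise
        grid = spec.SpectralGrid(n_bins=17, overlap=0.0)  # nperseg 32
        rng = np.random.default_rng(5)
        means = []
        for _ in range(200):
            x, y = rng.standard_normal((2, 8 * 32))
            prof, _ = _profile(x, y, grid)
            means.append(prof.msc[1:-1].mean())
        assert np.mean(means) == pytest.approx(1.0 / 8.0, abs=0.02)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 900))
        prof1, _ = _profile(x, y)
        prof2, _ = _profile(3.7 * x, 0.004 * y)
        assert np.allclose(prof1.msc, prof2.msc, atol=1e-12)

    def test_quarter_cycle_delay_phase(self):
        # B lags A by a quarter cycle of a 0.2 Hz tone => phase(A,B) = +pi/2
        rng = np.random.default_rng(7)
        t = np.arange(1500.0)
        a = np.sin(2 * np.pi * 0.2 * t) + 0.1 * rng.standard_normal(len(t))
        b = np.sin(2 * np.pi * 0.2 * (t - 1.25)) + 0.1 * rng.standard_normal(len(t))
        prof, m = _profile(a, b)
        k = np.argmin(np.abs(m.freqs - 0.2))
        assert prof.phase[k] == pytest.approx(np.pi / 2, abs=0.1)
        assert prof.phase_reliable[k]


class TestBand:
    def _peaked_profile(self, peak_freq, rng):
        freqs = GRID.freqs
        msc = 0.1 * rng.random(len(freqs))
        msc[np.argmin(np.abs(freqs - peak_freq))] = 0.9
        return spec.CoherenceProfile(freqs=freqs, msc=msc, phase=np.zeros(len(freqs)))

    def test_degenerate_band_when_all_peak_together(self):
        rng = np.random.default_rng(8)
        profiles = [self._peaked_profile(0.2, rng) for _ in range(10)]
        band = spec.band_of_max_coherence(profiles, n_boot=500, seed=0)
        peak = GRID.freqs[np.argmin(np.abs(GRID.freqs - 0.2))]
        assert band.median == band.lower == band.upper == pytest.approx(peak)

    def test_ci_contains_median(self):
        rng = np.random.default_rng(9)
        profiles = [self._peaked_profile(f, rng) for f in rng.uniform(0.1, 0.4, 15)]
        band = spec.band_of_max_coherence(profiles, n_boot=500, seed=1)
        assert band.lower <= band.median <= band.upper

    def test_synthetic_cohort_recovers_band_center(self):
        cfg = CohortConfig(n_subjects=1, sampling_interval=1.0, series_length=1920, seed=0)
        cs = CouplingSpec(band_center=0.2, band_width=0.02, target_msc=0.7)
        rng = np.random.default_rng(10)
        profiles = []
        for _ in range(20):
            x, y = gen_coupled_series(cfg, cs, rng)
            profiles.append(_profile(x, y)[0])
        band = spec.band_of_max_coherence(profiles, n_boot=1000, seed=2)
        assert abs(band.median - 0.2) <= GRID.freqs[1]

    def test_flat_profiles_rejected(self):
        flat = spec.CoherenceProfile(freqs=GRID.freqs, msc=np.full(len(GRID.freqs), 0.5))
        with pytest.raises(spec.SpectralError):
            spec.band_of_max_coherence([flat] * 5, n_boot=100, seed=0)

    def test_band_summary_constant_and_single_bin(self):
        prof = spec.CoherenceProfile(freqs=GRID.freqs, msc=np.full(len(GRID.freqs), 0.42),
                                     phase=np.zeros(len(GRID.freqs)))
        assert spec.band_summary(prof, (0.1, 0.3))[0] == pytest.approx(0.42)
        single = spec.band_summary(prof, (GRID.freqs[10] - 1e-9, GRID.freqs[10] + 1e-9))
        assert single[0] == pytest.approx(0.42)

    def test_band_summary_linear_profile_median_at_mid_bin(self):
        prof = spec.CoherenceProfile(freqs=GRID.freqs, msc=GRID.freqs.copy(),
                                     phase=np.zeros(len(GRID.freqs)))
        sel = (GRID.freqs >= 0.1) & (GRID.freqs <= 0.3)
        expected = float(np.median(GRID.freqs[sel]))
        assert spec.band_summary(prof, (0.1, 0.3))[0] == pytest.approx(expected)

    def test_empty_band_rejected(self):
        prof = spec.CoherenceProfile(freqs=GRID.freqs, msc=np.full(len(GRID.freqs), 0.5))
        with pytest.raises(spec.SpectralError):
            spec.band_summary(prof, (0.201, 0.2015))


class TestAr1:
    def test_white_noise_coefficient_near_zero(self):
        x = np.random.default_rng(11).standard_normal(2000)
        phi, _ = spec.fit_ar1(x)
        assert phi == pytest.approx(0.0, abs=0.05)

    def test_recovery(self):
        rng = np.random.default_rng(12)
        x = sps.lfilter([1.0], [1.0, -0.8], rng.standard_normal(2000))
        phi, innov = spec.fit_ar1(x)
        assert phi == pytest.approx(0.8, abs=0.05)
        assert innov == pytest.approx(np.var(x) * (1 - phi**2), rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(spec.SpectralError):
            spec.fit_ar1(np.ones(100))

    def test_surrogate_properties(self):
        rng = np.random.default_rng(13)
        x = sps.lfilter([1.0], [1.0, -0.6], rng.standard_normal(2000)) + 5.0
        surrogate = spec.ar1_surrogate(x, rng)
        phi_s, _ = spec.fit_ar1(surrogate)
        assert phi_s == pytest.approx(spec.fit_ar1(x)[0], abs=0.1)
        assert 0.9 <= np.var(surrogate) / np.var(x) <= 1.1

    def test_surrogate_incoherent_with_original(self):
        grid = spec.SpectralGrid(n_bins=17, overlap=0.0)
        rng = np.random.default_rng(14)
        meds = []
        for _ in range(100):
            x = sps.lfilter([1.0], [1.0, -0.4], rng.standard_normal(8 * 32))
            s = spec.ar1_surrogate(x, rng)
            prof, _ = _profile(x, s, grid)
            meds.append(prof.msc[1:-1].mean())
        assert np.mean(meds) == pytest.approx(1.0 / 8.0, abs=0.03)


class TestCoherenceNull:
    GRID16 = spec.SpectralGrid(n_bins=16, overlap=0.2)  # nperseg 30: many windows at n=240

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(15)
        x, y = rng.standard_normal((2, 240))
        a = spec.coherence_null(x, y, (0.15, 0.25), n_surrogates=50, seed=7, grid=self.GRID16)
        b = spec.coherence_null(x, y, (0.15, 0.25), n_surrogates=50, seed=7, grid=self.GRID16)
        assert np.array_equal(a.values, b.values)

    def test_power_against_strong_coupling(self):
        cfg = CohortConfig(n_subjects=1, sampling_interval=1.0, series_length=240, seed=0)
        cs = CouplingSpec(band_center=0.2, band_width=0.04, target_msc=0.8)
        rng = np.random.default_rng(16)
        hits = 0
        reps = 60
        for _ in range(reps):
            x, y = gen_coupled_series(cfg, cs, rng)
            prof, _ = _profile(x, y, self.GRID16)
            obs = spec.band_summary(prof, (0.18, 0.22))[0]
            null = spec.coherence_null(x, y, (0.18, 0.22), n_surrogates=100,
                                       seed=rng, grid=self.GRID16)
            hits += null.p_value(obs) < 0.05
        assert hits / reps > 0.9


class TestPartialCoherence:
    def test_empty_conditioning_reduces_to_msc(self):
        rng = np.random.default_rng(17)
        m = spec.cross_spectra({"a": rng.standard_normal(900), "b": rng.standard_normal(900)}, GRID)
        assert np.allclose(
            spec.partial_coherence(m, ("a", "b")).msc, spec.msc(m, ("a", "b")).msc
        )

    def test_independent_conditioner_preserves_coherence(self):
        cfg = CohortConfig(n_subjects=1, sampling_interval=1.0, series_length=712, seed=0)
        cs = CouplingSpec(band_center=0.2, band_width=0.02, target_msc=0.7)
        rng = np.random.default_rng(18)
        diffs = []
        for _ in range(20):
            x, y = gen_coupled_series(cfg, cs, rng)
            z = rng.standard_normal(len(x))
            m = spec.cross_spectra({"x": x, "y": y, "z": z}, GRID)
            sel = (m.freqs >= 0.19) & (m.freqs <= 0.21)
            ordinary = np.median(spec.msc(m, ("x", "y")).msc[sel])
            partial = np.median(spec.partial_coherence(m, ("x", "y"), ("z",)).msc[sel])
            diffs.append(partial - ordinary)
        assert abs(np.mean(diffs)) < 0.05

    def test_common_driver_removed(self):
        rng = np.random.default_rng(19)
        n = 1200
        ordinary_all, partial_all = [], []
        for _ in range(10):
            z = rng.standard_normal(n)
            x = z + 0.3 * rng.standard_normal(n)
            y = z + 0.3 * rng.standard_normal(n)
            m = spec.cross_spectra({"x": x, "y": y, "z": z}, GRID)
            sel = (m.freqs > 0.05) & (m.freqs < 0.45)
            ordinary_all.append(np.median(spec.msc(m, ("x", "y")).msc[sel]))
            partial_all.append(np.median(spec.partial_coherence(m, ("x", "y"), ("z",)).msc[sel]))
        k = m.n_windows
        assert np.mean(ordinary_all) > 0.8
        assert np.mean(partial_all) < 2.5 / k  # at the no-coherence null level ~1/K

    def test_batched_matches_per_pair(self):
        rng = np.random.default_rng(20)
        data = {name: rng.standard_normal(900) for name in ("a", "b", "c")}
        m = spec.cross_spectra(data, GRID)
        batched = spec.partial_coherence_all(m)
        single = spec.partial_coherence(m, ("a", "b"), ("c",)).msc
        assert np.allclose(batched[("a", "b")], single, atol=1e-10, equal_nan=True)

    def test_partial_test_degenerate_and_directional(self):
        # exact binary fractions so the shifted differences are exactly tied
        obs = 0.5 + np.arange(8) / 8.0
        z, p = spec.partial_coherence_test(obs, obs.copy())
        assert (z, p) == (0.0, 1.0)
        z, p = spec.partial_coherence_test(obs + 0.25, obs)
        n = len(obs)
        var = n * (n + 1) * (2 * n + 1) / 24 - (n**3 - n) / 48  # all |d| tied
        z_max = (n * (n + 1) / 4 - 0.5) / np.sqrt(var)
        assert z == pytest.approx(z_max, abs=1e-9)
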