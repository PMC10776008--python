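import numpy as np
import pytest

from scwforge.nmr import (
    DEFAULT_TAU_GRID_MS,
    PeakModel,
    RecoveryCurve,
    Spectrum1D,
    SpinDiffusionFit,
    deconvolve,
    default_peaks,
    distance_class,
    fit_tsd,
    peak_area,
    pseudo_voigt,
    recovery_fraction,
)
from scwforge.synth import gen_recovery_dataset, gen_spectrum


@pytest.fixture
def three_peaks():
    return [
        PeakModel(150.0, 3.0, 0.5, "A", "lignin"),
        PeakModel(100.0, 2.0, 0.7, "B", "cellulose"),
        PeakModel(22.0, 2.0, 0.6, "C", "xylan"),
    ]


class TestDeconvolve:
    def test_noiseless_recovery_to_0p1_percent(self, three_peaks):
        amps = np.array([2.0, 1.3, 0.4])
        spec, _ = gen_spectrum(three_peaks, amps, noise_sd=0.0, seed=0)
        df = deconvolve(spec, three_peaks)
        assert np.all(np.abs(df.amplitude.to_numpy() - amps) / amps < 1e-3)

    def test_all_zero_spectrum(self, three_peaks):
        spec = Spectrum1D(np.linspace(200, 0, 1024), np.zeros(1024))
        df = deconvolve(spec, three_peaks)
        assert np.all(df.area.to_numpy() <= 1e-6)

    def test_gaussian_closed_form_area(self):
        p = [PeakModel(100.0, 2.0, 1.0, "G", "xylan")]
        spec, _ = gen_spectrum(p, [3.0], noise_sd=0.0, seed=0)
        df = deconvolve(spec, p)
        expected = 3.0 * 2.0 * np.sqrt(np.pi / (4 * np.log(2)))
        assert df.area[0] == pytest.approx(expected, rel=1e-4)

    def test_lorentzian_closed_form_area(self):
        assert peak_area(2.0, 3.0, 0.0) == pytest.approx(2.0 * 3.0 * np.pi / 2)

    def test_shift_tolerance_recovers_offset_center(self, three_peaks):
        shifted = [
            PeakModel(p.center + 0.3, p.fwhm, p.gauss_fraction, p.assignment,
                      p.polymer_class)
            for p in three_peaks
        ]
        spec, _ = gen_spectrum(shifted, [1.0, 1.0, 1.0], noise_sd=0.0, seed=0)
        df = deconvolve(spec, three_peaks, shift_tol=0.5)
        assert np.allclose(df.center, [p.center for p in shifted], atol=0.05)
        assert np.allclose(df.amplitude, 1.0, atol=1e-3)

    def test_areas_nonnegative(self, three_peaks):
        rng = np.random.default_rng(0)
        spec = Spectrum1D(
            np.linspace(200, 0, 1024), rng.normal(0, 1.0, 1024), noise_sd=1.0
        )
        df = deconvolve(spec, three_peaks)
        assert np.all(df.area.to_numpy() >= 0.0)


class TestRecoveryFraction:
    def test_identical_spectra_fraction_one(self, three_peaks):
        spec, _ = gen_spectrum(three_peaks, [1.0, 2.0, 0.5], noise_sd=0.0, seed=0)
        df = recovery_fraction(spec, spec, three_peaks)
        assert np.allclose(df.fraction, 1.0)

    def test_zero_selective_fraction_zero(self, three_peaks):
        ref, _ = gen_spectrum(three_peaks, [1.0, 2.0, 0.5], noise_sd=0.0, seed=0)
        sel = Spectrum1D(ref.ppm.copy(), np.zeros_like(ref.intensity))
        df = recovery_fraction(sel, ref, three_peaks)
        assert np.allclose(df.fraction, 0.0)

    def test_zero_nonselective_flagged_undefined(self, three_peaks):
        ref, _ = gen_spectrum(three_peaks, [1.0, 0.0, 0.5], noise_sd=0.0, seed=0)
        sel, _ = gen_spectrum(three_peaks, [0.5, 0.0, 0.2], noise_sd=0.0, seed=1)
        df = recovery_fraction(sel, ref, three_peaks)
        row = df[df.assignment == "B"].iloc[0]
        assert not row.defined
        assert np.isnan(row.fraction)

    def test_scale_invariance(self, three_peaks):
        sel, _ = gen_spectrum(three_peaks, [0.6, 0.9, 0.1], noise_sd=0.0, seed=0)
        ref, _ = gen_spectrum(three_peaks, [1.0, 2.0, 0.5], noise_sd=0.0, seed=0)
        df1 = recovery_fraction(sel, ref, three_peaks)
        sel2 = Spectrum1D(sel.ppm.copy(), sel.intensity * 37.0)
        ref2 = Spectrum1D(ref.ppm.copy(), ref.intensity * 37.0)
        df2 = recovery_fraction(sel2, ref2, three_peaks)
        assert np.allclose(df1.fraction, df2.fraction)

    def test_paper_regime_fractions_recovered(self):
        """Generation at {lignin 0.25, cellulose 0.05} recovered within the
        propagated error at tau = 500 ms."""
        peaks = default_peaks()
        pairs = {}
        for p in peaks:
            if p.polymer_class == "lignin":
                pairs[p.assignment] = (0.25, 1.0)   # instant, so f(500ms)=0.25
            elif p.polymer_class == "cellulose":
                pairs[p.assignment] = (0.05, 1.0)
        tau, sel, ref, _gt = gen_recovery_dataset(
            peaks, pairs, "Xn AcMe", tau_grid=(500.0,), noise_frac=0.02, seed=2
        )
        df = recovery_fraction(sel[0], ref[0], peaks)
        pf = df.attrs["polymer_fractions"].set_index("polymer_class")
        for pol, expect in (("lignin", 0.25), ("cellulose", 0.05)):
            got = pf.loc[pol, "fraction"]
            err = pf.loc[pol, "fraction_err"]
            assert abs(got - expect) < max(3 * err, 0.02), (pol, got, err)


class TestFitTsd:
    def test_noiseless_exact_recovery(self):
        tau = np.array(DEFAULT_TAU_GRID_MS)
        f = 0.7 * (1 - np.exp(-tau / 300.0))
        fit = fit_tsd(RecoveryCurve("s", "k", tau, f, np.full(len(tau), 0.01)))
        assert fit.T_SD == pytest.approx(300.0, rel=1e-6)
        assert fit.asymptote == pytest.approx(0.7, rel=1e-6)

    def test_flat_at_asymptote(self):
        tau = np.array([1.0, 10.0, 100.0, 1000.0, 5000.0])
        f = np.array([0.35, 0.5, 0.5, 0.5, 0.5])
        fit = fit_tsd(RecoveryCurve("s", "k", tau, f, np.full(5, 0.01)))
        assert fit.asymptote == pytest.approx(0.5, abs=0.01)

    def test_flat_zero_raises(self):
        tau = np.array([1.0, 10.0, 100.0, 1000.0])
        with pytest.raises(ValueError, match="no transfer"):
            fit_tsd(RecoveryCurve("s", "k", tau, np.zeros(4), np.full(4, 0.01)))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_tsd(RecoveryCurve("s", "k", [1, 2, 3], [0.1, 0.2, 0.3], [0.01] * 3))

    def test_montecarlo_bias_and_coverage(self):
        """Bias < 5% per T; 68% coverage pooled over the grid in [55, 80]%."""
        tau = np.array(DEFAULT_TAU_GRID_MS)
        covered = 0
        n_rep = 0
        for T in (100.0, 300.0, 1000.0, 3000.0):
            errs = []
            for noise in (0.02, 0.05, 0.10):
                rng = np.random.default_rng(int(T) * 100 + int(noise * 100))
                for _ in range(70):
                    f = 0.8 * (1 - np.exp(-tau / T)) + rng.normal(0, noise, len(tau))
                    fit = fit_tsd(
                        RecoveryCurve("s", "k", tau, f, np.full(len(tau), noise))
                    )
                    errs.append((fit.T_SD - T) / T)
                    if noise == 0.05:
                        n_rep += 1
                        if abs(fit.T_SD - T) <= fit.T_SD_err:
                            covered += 1
            assert abs(np.median(errs)) < 0.05, f"T={T}"
        assert 0.55 <= covered / n_rep <= 0.80

    def test_symmetric_two_pool_exchange(self):
        """Source/sink exchange on symmetric synthetic data gives equal T_SD
        within fit error."""
        tau = np.array(DEFAULT_TAU_GRID_MS)
        T_true = 300.0
        rng = np.random.default_rng(8)
        noise = 0.02
        f_ab = 0.9 * (1 - np.exp(-tau / T_true)) + rng.normal(0, noise, len(tau))
        f_ba = 0.9 * (1 - np.exp(-tau / T_true)) + rng.normal(0, noise, len(tau))
        fit_ab = fit_tsd(RecoveryCurve("A", "B", tau, f_ab, np.full(len(tau), noise)))
        fit_ba = fit_tsd(RecoveryCurve("B", "A", tau, f_ba, np.full(len(tau), noise)))
        joint = np.hypot(fit_ab.T_SD_err, fit_ba.T_SD_err)
        assert abs(fit_ab.T_SD - fit_ba.T_SD) < 3 * joint

    def test_auto_prefers_mono_for_mono_data(self):
        tau = np.array(DEFAULT_TAU_GRID_MS)
        rng = np.random.default_rng(3)
        f = 0.8 * (1 - np.exp(-tau / 300.0)) + rng.normal(0, 0.01, len(tau))
        fit = fit_tsd(
            RecoveryCurve("s", "k", tau, f, np.full(len(tau), 0.01)), model="auto"
        )
        assert fit.model == "monoexponential"

    def test_bi_model_components(self):
        tau = np.array(DEFAULT_TAU_GRID_MS)
        f = 0.4 * (1 - np.exp(-tau / 100.0)) + 0.4 * (1 - np.exp(-tau / 2000.0))
        fit = fit_tsd(
            RecoveryCurve("s", "k", tau, f, np.full(len(tau), 0.005)), model="bi"
        )
        Ts = sorted(t for _a, t in fit.components)
        assert Ts[0] == pytest.approx(100.0, rel=0.05)
        assert Ts[1] == pytest.approx(2000.0, rel=0.05)


class TestDistanceClass:
    def _fit(self, T):
        return SpinDiffusionFit(T, 0.8, 1.0, 0.01, "monoexponential")

    @pytest.mark.parametrize(
        "T,label",
        [
            (100.0, "3-5 A"),
            (300.0, "3-5 A"),
            (500.0, "3-5 A"),       # boundary -> lower bin
            (501.0, "5-10 A"),
            (1500.0, "5-10 A"),
            (2500.0, "5-10 A"),     # boundary -> lower bin
            (3500.0, "5 to >10 A"),
        ],
    )
    def test_bins(self, T, label):
        assert distance_class(self._fit(T)) == label
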