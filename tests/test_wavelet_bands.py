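import numpy as np
import pytest
from scipy.signal import periodogram

from lateroflux.wavelet_bands import (BAND_REGISTRY, ConfigError,
                                      SpecError, band_average,
                                      band_time_series, decompose_bands,
                                      default_freq_grid, morlet_cwt)


def tone(freq, fs, duration, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def ridge_amplitude(scal, freq):
    i = int(np.argmin(np.abs(scal.freqs - freq)))
    valid = scal.valid_mask()[i]
    assert valid.any(), "no COI-free samples at requested frequency"
    return scal.amplitude[i][valid].max()


class TestMorletCWT:
    def test_zero_signal_gives_zero_scalogram(self):
        scal = morlet_cwt(np.zeros(4096), fs=16.0,
                          freqs=default_freq_grid(0.02, 1.6))
        assert np.all(scal.amplitude == 0.0)

    def test_tone_ridge_amplitude_three_pu(self):
        scal = morlet_cwt(tone(1.0, 64, 600, amplitude=3.0), fs=64.0)
        assert ridge_amplitude(scal, 1.0) == pytest.approx(3.0, rel=0.02)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(SpecError):
            morlet_cwt(np.zeros(1024), fs=2.0, freqs=np.array([0.5, 2.0]))

    def test_constant_signal_gives_near_zero(self):
        scal = morlet_cwt(np.full(9600, 37.0), fs=16.0,
                          freqs=default_freq_grid(0.02, 1.6))
        assert scal.amplitude.max() < 1e-9

    def test_coi_grows_toward_low_frequency(self):
        scal = morlet_cwt(np.zeros(9600), fs=16.0)
        assert np.all(np.diff(scal.coi_s) < 0)  # freqs ascending, COI shrinking


class TestBandAverage:
    def test_zero_scalogram_gives_zero(self):
        scal = morlet_cwt(np.zeros(9600), fs=16.0)
        assert band_average(scal, "neurogenic").value == 0.0

    def test_tone_lands_in_its_band_not_neighbours(self):
        scal = morlet_cwt(tone(0.03, 16, 600, amplitude=2.0), fs=16.0)
        neuro = band_average(scal, "neurogenic").value
        myo = band_average(scal, "myogenic").value
        assert neuro > 0.1
        assert myo < 0.1 * neuro

    def test_homogeneity_value_scales_with_amplitude(self):
        x = tone(0.03, 16, 600)
        v1 = band_average(morlet_cwt(x, 16.0), "neurogenic").value
        v2 = band_average(morlet_cwt(3.5 * x, 16.0), "neurogenic").value
        assert v2 == pytest.approx(3.5 * v1, rel=1e-9)

    def test_empty_band_slice_is_config_error(self):
        scal = morlet_cwt(np.zeros(4096), fs=16.0,
                          freqs=np.array([0.01, 1.0]))
        with pytest.raises(ConfigError):
            band_average(scal, "myogenic")

    def test_slowest_band_flagged_unreliable_in_600s_window(self):
        x = tone(0.0069, 16, 600, amplitude=1.0)
        scal = morlet_cwt(x, 16.0)
        assert not band_average(scal, "endo_no_indep").reliable
        assert band_average(scal, "neurogenic").reliable


class TestDecomposeBands:
    def test_six_tone_amplitude_ordering_recovered(self):
        # geometric band centres, amplitudes spaced 3x so band-width dilution
        # (< 2.2x between bands) cannot reorder them
        fs, dur = 64.0, 600.0
        amps = {bid: 0.5 * 3.0 ** i for i, bid in enumerate(BAND_REGISTRY)}
        x = sum(tone(np.sqrt(lo * hi), fs, dur, amps[bid], phase=0.7 * i)
                for i, (bid, (lo, hi)) in enumerate(BAND_REGISTRY.items()))
        comps = decompose_bands(x, fs)
        values = [comps[bid].value for bid in BAND_REGISTRY]
        assert values == sorted(values)

    def test_pure_cardiac_tone_leaks_below_10pct(self):
        x = tone(0.8, 64, 600, amplitude=2.0)
        comps = decompose_bands(x, 64.0)
        cardiac = comps["cardiac"].value
        for bid, comp in comps.items():
            if bid != "cardiac":
                assert comp.value < 0.1 * cardiac

    def test_constant_signal_gives_all_zero_components(self):
        comps = decompose_bands(np.full(38400, 25.0), 64.0)
        assert all(c.value < 1e-9 for c in comps.values())

    def test_linearity_across_all_bands(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 9600)
        a = decompose_bands(x, 16.0)
        b = decompose_bands(2.5 * x, 16.0)
        for bid in BAND_REGISTRY:
            assert b[bid].value == pytest.approx(2.5 * a[bid].value, rel=1e-9)

    def test_shift_covariance_under_one_percent(self):
        x = tone(0.1, 16, 600)
        a = decompose_bands(x, 16.0)["myogenic"].value
        b = decompose_bands(np.roll(x, 160), 16.0)["myogenic"].value
        assert b == pytest.approx(a, rel=0.01)

    def test_decimated_path_matches_native_rate(self):
        x = tone(0.1, 64, 600, amplitude=1.5)
        fast = decompose_bands(x, 64.0, work_fs=16.0)["myogenic"].value
        native = decompose_bands(x, 64.0, work_fs=None)["myogenic"].value
        assert fast == pytest.approx(native, rel=0.02)


class TestPeriodogramOracle:
    @pytest.mark.parametrize("freq", [0.014, 0.035, 0.095, 0.25, 1.0])
    def test_single_tone_amplitude_agrees_with_welch(self, freq):
        fs = 16.0
        dur = max(600.0, 20.0 / freq)
        x = tone(freq, fs, dur, amplitude=1.3)
        scal = morlet_cwt(x, fs)
        # ridge amplitude vs the periodogram amplitude estimate
        ridge = ridge_amplitude(scal, freq)
        f, p = periodogram(x, fs=fs)
        df = f[1] - f[0]
        lo, hi = freq * 0.7, freq * 1.4
        amp_est = np.sqrt(2.0 * p[(f >= lo) & (f <= hi)].sum() * df)
        assert ridge == pytest.approx(amp_est, rel=0.10)

    def test_two_tone_cross_band_leakage_below_5pct(self):
        fs = 16.0
        x = tone(0.01, fs, 3600) + tone(1.0, fs, 3600)
        scal = morlet_cwt(x, fs)
        f, p = periodogram(x, fs=fs)
        df = f[1] - f[0]

        def band_energy_cwt(lo, hi):
            sel = (scal.freqs >= lo) & (scal.freqs < hi)
            valid = scal.valid_mask()[sel]
            rows = scal.amplitude[sel]
            return float(np.mean([
                (rows[i][valid[i]] ** 2).mean() for i in range(rows.shape[0])
                if valid[i].any()]))

        endo = band_energy_cwt(*BAND_REGISTRY["endo_no_dep"])
        cardiac = band_energy_cwt(*BAND_REGISTRY["cardiac"])
        # each tone's energy should stay in its own band: the in-band mean
        # square amplitude dwarfs what the other band sees of it
        neuro = band_energy_cwt(*BAND_REGISTRY["neurogenic"])
        myo = band_energy_cwt(*BAND_REGISTRY["myogenic"])
        assert neuro < 0.05 * endo
        assert myo < 0.05 * cardiac
        # periodogram oracle: the two tones carry equal power
        e_lo = p[(f > 0.005) & (f < 0.02)].sum() * df
        e_hi = p[(f > 0.4) & (f < 1.6)].sum() * df
        assert e_lo == pytest.approx(e_hi, rel=0.05)


class TestBandTimeSeries:
    def test_series_mean_matches_band_average(self):
        x = tone(0.1, 16, 600, amplitude=2.0)
        scal = morlet_cwt(x, 16.0)
        comp = band_average(scal, "myogenic")
        _, series, valid = band_time_series(scal, "myogenic")
        assert series[valid].mean() == pytest.approx(comp.value, rel=0.01)
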