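"""Filtering, MBLL conversion, component denoising, despiking and repair."""

import numpy as np
import pytest
from scipy import signal as sps

from nirswave.errors import ConfigurationError, DataQualityError, PreprocessingError
from nirswave.preprocess import (
    FilterSpec,
    bandpass,
    despike_moving_average,
    mbll_convert,
    mbll_forward,
    pca_ica_denoise,
    spline_repair,
)
from nirswave.wavelet_amplitude import channel_wa

from conftest import FS, tone


class TestMBLL:
    def test_zero_in_zero_out(self):
        z = np.zeros(100)
        o2, hb = mbll_convert(z, z)
        np.testing.assert_array_equal(o2, 0)
        np.testing.assert_array_equal(hb, 0)

    def test_forward_round_trip(self):
        rng = np.random.default_rng(1)
        o2 = rng.standard_normal(500)
        hb = rng.standard_normal(500)
        od1, od2 = mbll_forward(o2, hb)
        r_o2, r_hb = mbll_convert(od1, od2)
        np.testing.assert_allclose(r_o2, o2, atol=1e-10)
        np.testing.assert_allclose(r_hb, hb, atol=1e-10)

    def test_linearity(self):
        x = tone(0.03, 60)
        o2a, hba = mbll_convert(x, 0.5 * x)
        o2b, hbb = mbll_convert(2 * x, x)
        np.testing.assert_allclose(o2b, 2 * o2a, atol=1e-12)
        np.testing.assert_allclose(hbb, 2 * hba, atol=1e-12)

    def test_singular_system_rejected(self):
        x = np.zeros(10)
        degenerate = {740.0: (1.0, 1.0), 850.0: (2.0, 2.0)}
        with pytest.raises(ConfigurationError):
            mbll_convert(x, x, extinction=degenerate)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = tone(0.05)
        y = bandpass(x, FS)
        core = slice(1000, -1000)  # avoid filter edge transients
        ratio = np.std(y[core]) / np.std(x[core])
        assert abs(ratio - 1) < 0.02

    def test_dc_removed(self):
        y = bandpass(np.full(6000, 3.7), FS)
        assert np.abs(y).max() < 1e-9

    def test_out_of_band_attenuated(self):
        x = tone(4.0)
        y = bandpass(x, FS)
        core = slice(1000, -1000)
        atten_db = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert atten_db < -20

    def test_zero_phase(self):
        """Peak cross-correlation of an in-band tone and its filtrate is at lag 0."""
        x = tone(0.05)
        y = bandpass(x, FS)
        core = slice(1000, -1000)
        xc, yc = x[core] - x[core].mean(), y[core] - y[core].mean()
        corr = sps.correlate(yc, xc, mode="full")
        lag = np.argmax(corr) - (len(xc) - 1)
        assert lag == 0

    def test_too_short_rejected(self):
        with pytest.raises(PreprocessingError):
            bandpass(np.ones(50), FS)

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            bandpass(np.ones(6000), FS, FilterSpec(low_hz=3.0, high_hz=6.0))


class TestPcaIca:
    @staticmethod
    def _mixture(seed=0, n_ch=6):
        rng = np.random.default_rng(seed)
        slow, fast = tone(0.04), tone(1.0)
        mixing = rng.standard_normal((n_ch, 2))
        return mixing @ np.stack([slow, fast]) + 0.01 * rng.standard_normal(
            (n_ch, slow.size)
        )

    def test_out_of_band_component_removed(self):
        x = self._mixture()
        cleaned, report = pca_ica_denoise(x, FS, seed=0)
        rejected = [c for c in report.components if not c.retained]
        assert rejected, "the 1 Hz component should be dropped"
        f, psd = sps.welch(cleaned[0], FS, nperseg=4096)
        p_fast = psd[np.argmin(np.abs(f - 1.0))]
        p_slow = psd[np.argmin(np.abs(f - 0.04))]
        assert p_slow > 100 * p_fast

    def test_threshold_zero_keeps_everything(self):
        x = self._mixture(seed=1)
        cleaned, report = pca_ica_denoise(
            x, FS, retain_fraction_threshold=0.0, seed=0, variance_to_keep=0.999999
        )
        assert all(c.retained for c in report.components)
        np.testing.assert_allclose(cleaned, x, atol=1e-6 * np.abs(x).max())

    def test_manual_override_rejects_component(self):
        x = self._mixture(seed=2)
        _, auto = pca_ica_denoise(x, FS, retain_fraction_threshold=0.0, seed=0)
        target = auto.retained_indices[0]
        _, manual = pca_ica_denoise(
            x, FS, retain_fraction_threshold=0.0, manual_overrides=[target], seed=0
        )
        entry = manual.components[target]
        assert not entry.retained and entry.reason == "manual"

    def test_report_invariants(self):
        _, report = pca_ica_denoise(self._mixture(seed=3), FS, seed=0)
        for c in report.components:
            assert 0.0 <= c.band_fraction <= 1.0
        assert set(report.retained_indices) <= {c.index for c in report.components}

    def test_needs_two_channels(self):
        with pytest.raises(PreprocessingError):
            pca_ica_denoise(tone(0.04)[np.newaxis, :], FS)


class TestDespike:
    def test_clean_sine_unflagged(self):
        mask = despike_moving_average(tone(0.05), FS)
        assert mask.sum() == 0

    def test_single_spike_flagged_locally(self):
        x = tone(0.05)
        x[3000] += 10.0
        mask = despike_moving_average(x, FS)
        assert mask[3000]
        flagged = np.flatnonzero(mask)
        assert np.all(np.abs(flagged - 3000) < 30)  # only the spike neighborhood

    def test_infinite_threshold_empty(self):
        x = tone(0.05) + np.random.default_rng(0).standard_normal(6000)
        assert despike_moving_average(x, FS, k=np.inf).sum() == 0


class TestSplineRepair:
    def test_empty_mask_identity(self):
        x = tone(0.05)
        np.testing.assert_array_equal(spline_repair(x, np.zeros_like(x, bool)), x)

    def test_cubic_reproduced_exactly(self):
        t = np.linspace(-1, 1, 500)
        x = 2 * t**3 - t**2 + 0.5 * t - 1
        mask = np.zeros_like(x, bool)
        mask[200:230] = True
        out = spline_repair(x, mask)
        np.testing.assert_allclose(out, x, atol=1e-8)

    def test_sine_gap_bounded_by_reference_interpolation(self):
        from scipy.interpolate import CubicSpline

        x = tone(0.05)
        mask = np.zeros_like(x, bool)
        mask[3000:3020] = True
        out = spline_repair(x, mask)
        idx = np.arange(x.size)
        ref = CubicSpline(idx[~mask], x[~mask])(idx[mask])
        ref_err = np.abs(ref - x[mask]).max()
        assert np.abs(out[mask] - x[mask]).max() <= ref_err + 1e-12

    def test_excessive_mask_rejected(self):
        x = tone(0.05)
        mask = np.ones_like(x, bool)
        mask[:100] = False
        with pytest.raises(DataQualityError):
            spline_repair(x, mask)


def test_chain_neutral_on_clean_signal():
    """The full chain changes the band WA of an in-band signal by < 5%."""
    rng = np.random.default_rng(7)
    n = 6000
    freqs = np.fft.rfftfreq(n, 1 / FS)
    coef = np.where((freqs >= 0.02) & (freqs <= 0.06),
                    rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size), 0)
    clean = np.fft.irfft(coef, n)
    clean /= clean.std()
    channels = np.stack([clean * g for g in (1.0, 0.8, 1.2)])

    x = bandpass(channels, FS)
    x, _ = pca_ica_denoise(x, FS, seed=0)
    x = np.stack([
        spline_repair(row, despike_moving_average(row, FS)) for row in x
    ])
    wa_before = channel_wa(channels, FS)
    wa_after = channel_wa(x, FS)
    assert np.all(np.abs(wa_after / wa_before - 1) < 0.05)
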